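"""On-disk formats: matrix CSVs, cohort HDF5 stores, manifests, tree edge
lists, tidy score/metric tables.

Matrix CSV dialect: comma-separated, header row and first column are the
ROI labels (no ambiguous index column); values at full float precision so
round trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import pandas as pd

from .cohort import TIMEPOINTS, SyntheticSubject
from .connectivity import ConnectivityMatrix, RoiEpoch
from .errors import ConsistencyError
from .mst import SpanningTree

__all__ = [
    "write_matrix_csv", "read_matrix_csv",
    "write_cohort_matrices", "read_cohort_matrices",
    "write_cohort_hdf5", "read_cohort_hdf5",
    "write_tree_csv", "read_tree_csv",
]


def write_matrix_csv(c: ConnectivityMatrix, path: Path) -> None:
    df = pd.DataFrame(c.weights, index=c.roi_labels, columns=c.roi_labels)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.17g")


def read_matrix_csv(path: Path, band: str = "broadband",
                    provenance: str = "single_epoch") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ConsistencyError(f"{path}: row and column labels differ")
    return ConnectivityMatrix(df.values, band=band,
                              roi_labels=[str(x) for x in df.index],
                              provenance=provenance)


def _manifest_rows(subjects: list[SyntheticSubject], path_of) -> pd.DataFrame:
    rows = [
        dict(subject_id=s.subject_id, group=s.group, timepoint=tp,
             lambda_true=s.lambda_true[tp], path=str(path_of(s, tp)))
        for s in subjects for tp in TIMEPOINTS
    ]
    return pd.DataFrame(rows)


def write_cohort_matrices(subjects: list[SyntheticSubject],
                          outdir: Path) -> Path:
    """Matrix-mode cohort: per-epoch CSVs plus a manifest.csv."""
    outdir = Path(outdir)
    for s in subjects:
        for tp in TIMEPOINTS:
            for k, m in enumerate(s.epochs[tp]):
                write_matrix_csv(
                    m, outdir / s.subject_id / tp / f"epoch_{k:02d}.csv")
    manifest = _manifest_rows(
        subjects, lambda s, tp: Path(s.subject_id) / tp)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False, float_format="%.17g")
    return manifest_path


def read_cohort_matrices(manifest_path: Path) -> list[SyntheticSubject]:
    root = Path(manifest_path).parent
    manifest = pd.read_csv(manifest_path)
    subjects: dict[str, SyntheticSubject] = {}
    for row in manifest.itertuples():
        s = subjects.setdefault(
            row.subject_id,
            SyntheticSubject(row.subject_id, row.group, {}, {}))
        s.lambda_true[row.timepoint] = float(row.lambda_true)
        epoch_files = sorted((root / row.path).glob("epoch_*.csv"))
        if not epoch_files:
            raise ConsistencyError(f"no epoch files under {root / row.path}")
        s.epochs[row.timepoint] = [read_matrix_csv(f) for f in epoch_files]
    return list(subjects.values())


def write_cohort_hdf5(subjects: list[SyntheticSubject], outdir: Path) -> Path:
    """Time-series cohort: one HDF5 store (/subject/timepoint/epoch_k)
    plus a manifest.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h5path = outdir / "cohort.h5"
    with h5py.File(h5path, "w") as f:
        for s in subjects:
            for tp in TIMEPOINTS:
                grp = f.create_group(f"{s.subject_id}/{tp}")
                grp.attrs["group"] = s.group
                grp.attrs["lambda_true"] = s.lambda_true[tp]
                for k, ep in enumerate(s.epochs[tp]):
                    ds = grp.create_dataset(f"epoch_{k:02d}", data=ep.data)
                    ds.attrs["fs"] = ep.fs
                    ds.attrs["roi_labels"] = [str(x) for x in ep.roi_labels]
    manifest = _manifest_rows(
        subjects, lambda s, tp: f"cohort.h5:/{s.subject_id}/{tp}")
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False, float_format="%.17g")
    return manifest_path


def read_cohort_hdf5(h5path: Path) -> list[SyntheticSubject]:
    subjects = []
    with h5py.File(h5path, "r") as f:
        for sid in sorted(f):
            lam, epochs = {}, {}
            group = None
            for tp in sorted(f[sid]):
                grp = f[sid][tp]
                group = str(grp.attrs["group"])
                lam[tp] = float(grp.attrs["lambda_true"])
                epochs[tp] = [
                    RoiEpoch(grp[name][()], float(grp[name].attrs["fs"]),
                             [str(x) for x in grp[name].attrs["roi_labels"]])
                    for name in sorted(grp)
                ]
            subjects.append(SyntheticSubject(sid, group, lam, epochs))
    return subjects


def write_tree_csv(t: SpanningTree, path: Path, header: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lab = t.roi_labels
    rows = sorted((lab[i], lab[j]) for i, j in t.edges)
    with open(path, "w") as f:
        if header:
            f.write(f"# {header}\n")
        f.write("roi_a,roi_b\n")
        for a, b in rows:
            f.write(f"{a},{b}\n")


def read_tree_csv(path: Path, roi_labels: list[str]) -> SpanningTree:
    df = pd.read_csv(path, comment="#")
    index = {lab: i for i, lab in enumerate(roi_labels)}
    try:
        edges = frozenset(
            (index[str(r.roi_a)], index[str(r.roi_b)])
            for r in df.itertuples())
    except KeyError as e:  # pragma: no cover
        raise ConsistencyError(f"{path}: unknown ROI label {e}") from e
    return SpanningTree(len(roi_labels), edges, list(roi_labels))
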