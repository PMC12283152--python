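"""End-to-end orchestration: simulate -> connect -> mst -> similarity ->
stats, with reproducible run artifacts.

``score_cohort`` is the computational core shared by the drivers, the CLI
and the tests: it turns a cohort (per-epoch connectivity matrices, or raw
time series that are first pushed through the spectral stack) into the tidy
similarity-score table the statistics run on.  ``run_pipeline`` wraps it
with on-disk artifacts: resolved config, manifest, reference trees,
scores.csv, test tables and a log with per-file checksums.  Identical
config + seed reproduces every numerical output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (TIMEPOINTS, CohortConfig, SyntheticSubject,
                     generate_cohort)
from .connectivity import (DEFAULT_BANDS, ConnectivityMatrix, aecc_matrix,
                           band_by_name, downsample, epoch_average)
from .errors import ConfigurationError, ConsistencyError
from .io import (write_cohort_hdf5, write_cohort_matrices, write_matrix_csv,
                 write_tree_csv)
from .mst import mst_from_connectivity, metrics_over_epochs
from .similarity import (reference_mst, subject_similarity,
                         subject_similarity_mean_adjacency)
from .stats import run_comparisons

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "score_cohort", "cohort_band_matrices",
           "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Everything a full run needs; serialized back into the run directory."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    bands: tuple = tuple(b.name for b in DEFAULT_BANDS)
    downsample_factor: int = 4
    similarity_mode: str = "per_epoch_mean"
    q: float = 0.05
    seed: int = 0
    output_dir: str = "run"
    write_cohort: bool = False

    def __post_init__(self):
        if self.similarity_mode not in ("per_epoch_mean", "mean_adjacency"):
            raise ConfigurationError(
                f"unknown similarity mode {self.similarity_mode!r}")
        if self.downsample_factor < 1:
            raise ConfigurationError("downsample_factor must be >= 1")
        self.cohort.seed = self.seed


def cohort_band_matrices(subjects: list[SyntheticSubject],
                         bands: tuple = ("broadband",),
                         downsample_factor: int = 4) -> dict:
    """Per-epoch connectivity for every subject/timepoint/band.

    Matrix-mode cohorts already hold connectivity (band key "broadband");
    time-series cohorts are decimated and run through the AECc estimator
    for each requested band.

    Returns {(subject_id, timepoint, band): [ConnectivityMatrix, ...]}.
    """
    out = {}
    for s in subjects:
        for tp, epochs in s.epochs.items():
            if epochs and isinstance(epochs[0], ConnectivityMatrix):
                out[(s.subject_id, tp, "broadband")] = list(epochs)
            else:
                decimated = [downsample(ep, downsample_factor)
                             for ep in epochs]
                for band_name in bands:
                    band = band_by_name(band_name)
                    out[(s.subject_id, tp, band_name)] = [
                        aecc_matrix(ep, band) for ep in decimated]
    return out


def score_cohort(subjects: list[SyntheticSubject],
                 bands: tuple = ("broadband",),
                 downsample_factor: int = 4,
                 mode: str = "per_epoch_mean",
                 matrices: dict | None = None,
                 reference_trees: dict | None = None) -> pd.DataFrame:
    """Tidy similarity-score table for a cohort.

    Reference MSTs are built per band and timepoint from the epoch-mean
    matrices of the two anchor groups only; intermediate (cibi) subjects
    never enter a reference.  Every subject is then scored against both
    references.  ``reference_trees``, if given a dict, is filled with the
    built ReferenceTree objects keyed by (label, band, timepoint).
    """
    group_of = {s.subject_id: s.group for s in subjects}
    lam_of = {(s.subject_id, tp): s.lambda_true.get(tp, np.nan)
              for s in subjects for tp in s.epochs}
    if matrices is None:
        matrices = cohort_band_matrices(subjects, bands, downsample_factor)
    all_bands = sorted({b for (_, _, b) in matrices})
    all_tps = sorted({tp for (_, tp, _) in matrices})

    epoch_means = {key: epoch_average(mats) for key, mats in matrices.items()}

    rows = []
    for band in all_bands:
        for tp in all_tps:
            refs = {}
            for label in ("motor", "bvftd"):
                members = [sid for sid, g in group_of.items() if g == label]
                assert all(group_of[sid] != "cibi" for sid in members)
                mats = [epoch_means[(sid, tp, band)] for sid in members
                        if (sid, tp, band) in epoch_means]
                if not mats:
                    raise ConsistencyError(
                        f"no {label} subjects for band={band} tp={tp}")
                refs[label] = reference_mst(mats, label, band=band,
                                            timepoint=tp)
                if reference_trees is not None:
                    reference_trees[(label, band, tp)] = refs[label]
            for s in subjects:
                key = (s.subject_id, tp, band)
                if key not in matrices:
                    continue
                epoch_mats = matrices[key]
                if mode == "per_epoch_mean":
                    trees = [mst_from_connectivity(m) for m in epoch_mats]
                    scores = {label: subject_similarity(trees, ref,
                                                        s.subject_id)
                              for label, ref in refs.items()}
                else:
                    scores = {label: subject_similarity_mean_adjacency(
                        epoch_mats, ref, s.subject_id)
                        for label, ref in refs.items()}
                for label, sc in scores.items():
                    rows.append(dict(
                        subject_id=s.subject_id, group=s.group,
                        timepoint=tp, band=band, reference=label,
                        mode=sc.mode, similarity=sc.value,
                        lambda_true=lam_of.get((s.subject_id, tp), np.nan)))
    return pd.DataFrame(rows)


def spectrum_delta(scores: pd.DataFrame) -> pd.DataFrame:
    """Per subject/timepoint/band spectrum coordinate
    Delta = sim(bvftd ref) - sim(motor ref)."""
    wide = scores.pivot_table(
        index=["subject_id", "group", "timepoint", "band", "lambda_true"],
        columns="reference", values="similarity").reset_index()
    wide["delta"] = wide["bvftd"] - wide["motor"]
    return wide


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write all artifacts under config.output_dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines, t0 = [], time.perf_counter()

    def stage(name):
        log_lines.append(f"[{time.perf_counter() - t0:8.2f}s] {name}")
        log.info("stage: %s", name)

    resolved = {"cohort": asdict(config.cohort),
                **{k: v for k, v in asdict(config).items() if k != "cohort"}}
    with open(outdir / "config.yaml", "w") as f:
        yaml.safe_dump(resolved, f, sort_keys=True)

    stage("simulate")
    subjects = generate_cohort(config.cohort)
    if config.write_cohort:
        if config.cohort.mode == "matrix":
            write_cohort_matrices(subjects, outdir / "cohort")
        else:
            write_cohort_hdf5(subjects, outdir / "cohort")
    else:
        rows = [dict(subject_id=s.subject_id, group=s.group, timepoint=tp,
                     lambda_true=s.lambda_true[tp], path="")
                for s in subjects for tp in TIMEPOINTS]
        pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False,
                                  float_format="%.17g")

    stage("connect")
    matrices = cohort_band_matrices(subjects, config.bands,
                                    config.downsample_factor)
    conn_dir = outdir / "connectivity"
    for (sid, tp, band), mats in matrices.items():
        write_matrix_csv(epoch_average(mats),
                         conn_dir / sid / tp / f"{band}_epoch_mean.csv")

    stage("mst+similarity")
    refs: dict = {}
    scores = score_cohort(subjects, config.bands, config.downsample_factor,
                          mode=config.similarity_mode, matrices=matrices,
                          reference_trees=refs)
    tree_dir = outdir / "trees"
    for (label, band, tp), ref in refs.items():
        write_tree_csv(ref.tree, tree_dir / f"ref_{label}_{band}_{tp}.csv",
                       header=f"reference={label} band={band} timepoint={tp}")
    scores_path = outdir / "scores.csv"
    scores.to_csv(scores_path, index=False, float_format="%.17g")

    stage("tree metrics")
    metric_rows = []
    for (sid, tp, band), mats in matrices.items():
        tm = metrics_over_epochs([mst_from_connectivity(m) for m in mats])
        for name, value in (("leaf_fraction", tm.leaf_fraction),
                            ("diameter", tm.diameter_edges),
                            ("diameter_norm", tm.diameter_norm),
                            ("tree_hierarchy", tm.tree_hierarchy)):
            metric_rows.append(dict(subject_id=sid, timepoint=tp, band=band,
                                    metric=name, value=value))
    pd.DataFrame(metric_rows).to_csv(outdir / "tree_metrics.csv",
                                     index=False, float_format="%.17g")

    stage("stats")
    tables = run_comparisons(scores, q=config.q)
    tables.table.to_csv(outdir / "stat_tests.csv", index=False,
                        float_format="%.17g")

    stage("checksums")
    checks = {p.name: _sha256(p)
              for p in sorted(outdir.glob("*.csv"))}
    summary = dict(seed=config.seed,
                   n_subjects=len(subjects),
                   n_score_rows=len(scores),
                   checksums=checks)
    with open(outdir / "run_summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(manifest_path: Path,
                    n_epochs_expected: int | None = None) -> list[dict]:
    """Check a matrix-mode cohort directory; returns a machine-readable
    issue list (empty when clean).  Never mutates inputs."""
    issues: list[dict] = []
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        return [dict(kind="missing_manifest", path=str(manifest_path))]
    manifest = pd.read_csv(manifest_path)
    root = manifest_path.parent
    labels_ref = None
    epoch_counts = {}
    for row in manifest.itertuples():
        files = sorted((root / row.path).glob("epoch_*.csv"))
        epoch_counts[(row.subject_id, row.timepoint)] = len(files)
        for f in files:
            try:
                df = pd.read_csv(f, index_col=0)
            except Exception as e:  # pragma: no cover
                issues.append(dict(kind="unreadable", path=str(f),
                                   error=str(e)))
                continue
            w = df.values
            asym = float(np.abs(w - w.T).max())
            if asym > 1e-9:
                ij = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
                issues.append(dict(kind="asymmetry", path=str(f),
                                   at=f"({ij[0]},{ij[1]})", max_abs=asym))
            labels = tuple(str(x) for x in df.index)
            if labels_ref is None:
                labels_ref = labels
            elif labels != labels_ref:
                issues.append(dict(kind="label_mismatch", path=str(f)))
    expected = n_epochs_expected or max(epoch_counts.values(), default=0)
    for (sid, tp), n in epoch_counts.items():
        if n != expected:
            issues.append(dict(kind="epoch_count", subject_id=sid,
                               timepoint=tp, found=n, expected=expected,
                               missing=[f"epoch_{k:02d}" for k in
                                        range(expected)
                                        if not (root / sid / tp /
                                                f"epoch_{k:02d}.csv").exists()]))
    return issues
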