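"""Paired nonparametric inference on similarity scores.

Two families of Wilcoxon signed-rank tests mirror the study design:

- cross-sectional: within the intermediate (cibi) group, similarity to the
  motor reference vs similarity to the bvFTD reference, per band and
  timepoint;
- longitudinal: baseline vs follow-up similarity, per band and reference.

Each family (6 bands x 2 = 12 tests) is corrected with Benjamini-Hochberg
FDR.  The signed-rank test discards zero differences, uses average ranks
for ties, enumerates the exact null for small n and otherwise a
tie-corrected normal approximation without continuity correction (the
convention of mainstream commercial statistics software, which reports a
Z statistic).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, DegenerateDataError, MissingDataError

log = logging.getLogger(__name__)

__all__ = [
    "PairedTestResult",
    "FdrResult",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "run_comparisons",
]

#: Largest n for which the exact permutation null is enumerated.
EXACT_N_MAX = 15


@dataclass
class PairedTestResult:
    comparison: str
    band: str
    n_pairs: int
    w_statistic: float     # W+ = sum of ranks of positive differences
    z: float
    p_two_sided: float
    method: str = "exact"

    def __post_init__(self):
        if self.n_pairs < 1:
            raise DegenerateDataError("no nonzero paired differences")
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ConsistencyError("p must lie in (0, 1]")


@dataclass
class FdrResult:
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    q: float = 0.05
    family_size: int = 0

    def __post_init__(self):
        self.p_raw = np.asarray(self.p_raw, dtype=float)
        self.p_adjusted = np.asarray(self.p_adjusted, dtype=float)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        self.family_size = len(self.p_raw)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating all 2^n sign assignments of the
    observed |difference| ranks: p = min(1, 2*min(P(W+ <= w), P(W+ >= w)))."""
    n = len(ranks)
    bits = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    sums = bits @ ranks
    tol = 1e-9
    p_le = np.mean(sums <= w_plus + tol)
    p_ge = np.mean(sums >= w_plus - tol)
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(a, b, method: str = "auto",
                         comparison: str = "", band: str = ""
                         ) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (classic Wilcoxon).  ``method`` is
    "exact" (full sign enumeration), "normal" (tie-corrected Z, no
    continuity correction), or "auto" (exact for n <= 15).  The Z statistic
    is reported for both methods; its sign follows W+ - E[W+], so swapping
    the samples flips the sign and leaves p unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConsistencyError("need two equal-length 1-D paired samples")
    diffs = a - b
    nonzero = diffs != 0.0
    n_dropped = int(np.sum(~nonzero))
    if n_dropped:
        log.info("discarding %d zero differences", n_dropped)
    d = diffs[nonzero]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        log.warning("only %d nonzero pairs; the test has little power", n)

    ranks = ss.rankdata(np.abs(d))          # average ranks for ties
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if var == 0 else (w_plus - mu) / math.sqrt(var)

    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "normal"
    if method == "exact":
        if n > EXACT_N_MAX:
            raise ConsistencyError(
                f"exact enumeration limited to n <= {EXACT_N_MAX}")
        p = _exact_two_sided_p(ranks, w_plus)
    elif method == "normal":
        p = 2.0 * ss.norm.sf(abs(z))
    else:
        raise ConsistencyError(f"unknown method {method!r}")
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return PairedTestResult(comparison=comparison, band=band, n_pairs=n,
                            w_statistic=w_plus, z=z, p_two_sided=p,
                            method=method)


def bh_fdr(p_values, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Rejects the k smallest p-values where k = max{i : p(i) <= q i/m};
    adjusted p-values are the standard monotone cumulative-minimum form.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return FdrResult(p, p.copy(), np.zeros(0, dtype=bool), q=q)
    if np.any((p < 0) | (p > 1)):
        raise ConsistencyError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ConsistencyError("q must lie in (0, 1)")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FdrResult(p, p_adj, rejected, q=q)


# ---------------------------------------------------------------------------
# the study's two test families


@dataclass
class ComparisonTables:
    """Tidy per-family results; ``table`` concatenates both families."""

    cross_sectional: pd.DataFrame
    longitudinal: pd.DataFrame

    @property
    def table(self) -> pd.DataFrame:
        return pd.concat([self.cross_sectional, self.longitudinal],
                         ignore_index=True)


def _pivot(scores: pd.DataFrame, band: str, timepoint: str, reference: str
           ) -> pd.Series:
    sel = scores[(scores["band"] == band)
                 & (scores["timepoint"] == timepoint)
                 & (scores["reference"] == reference)]
    return sel.set_index("subject_id")["similarity"]


def run_comparisons(scores: pd.DataFrame, q: float = 0.05,
                    group: str = "cibi", method: str = "auto",
                    timepoints: tuple[str, str] = ("baseline", "followup"),
                    ) -> ComparisonTables:
    """Both families of paired tests on a tidy similarity-score table.

    ``scores`` needs columns subject_id, group, timepoint, band, reference,
    similarity.  Only rows of ``group`` (the intermediate cohort scored
    against both anchors) enter the tests.  FDR is applied within each
    family separately.
    """
    required = {"subject_id", "group", "timepoint", "band", "reference",
                "similarity"}
    if not required.issubset(scores.columns):
        raise ConsistencyError(
            f"score table lacks columns {sorted(required - set(scores.columns))}")
    sub = scores[scores["group"] == group]
    if sub.empty:
        raise MissingDataError(f"no scores for group {group!r}")
    bands = sorted(sub["band"].unique())
    subjects = sorted(sub["subject_id"].unique())

    missing = [
        (s, band, tp)
        for band in bands for tp in timepoints for s in subjects
        for ref in ("motor", "bvftd")
        if sub[(sub["subject_id"] == s) & (sub["band"] == band)
               & (sub["timepoint"] == tp) & (sub["reference"] == ref)].empty
    ]
    if missing:
        raise MissingDataError(
            f"absent score cells: {sorted(set(missing))[:10]}"
            + ("..." if len(set(missing)) > 10 else ""),
            missing=sorted(set(missing)))

    cross_rows = []
    for band in bands:
        for tp in timepoints:
            m = _pivot(sub, band, tp, "motor").loc[subjects]
            b = _pivot(sub, band, tp, "bvftd").loc[subjects]
            res = wilcoxon_signed_rank(
                m.values, b.values, method=method,
                comparison=f"motor_ref_vs_bvftd_ref@{tp}", band=band)
            cross_rows.append(dict(
                family="cross_sectional", comparison=res.comparison,
                band=band, timepoint=tp, reference="both",
                n_pairs=res.n_pairs, w=res.w_statistic, z=res.z,
                p_raw=res.p_two_sided, method=res.method))

    long_rows = []
    for band in bands:
        for ref in ("motor", "bvftd"):
            t0 = _pivot(sub, band, timepoints[0], ref).loc[subjects]
            t1 = _pivot(sub, band, timepoints[1], ref).loc[subjects]
            res = wilcoxon_signed_rank(
                t0.values, t1.values, method=method,
                comparison=f"{timepoints[0]}_vs_{timepoints[1]}@{ref}_ref",
                band=band)
            long_rows.append(dict(
                family="longitudinal", comparison=res.comparison,
                band=band, timepoint="both", reference=ref,
                n_pairs=res.n_pairs, w=res.w_statistic, z=res.z,
                p_raw=res.p_two_sided, method=res.method))

    out = []
    for rows in (cross_rows, long_rows):
        df = pd.DataFrame(rows)
        fdr = bh_fdr(df["p_raw"].values, q=q)
        df["p_adj"] = fdr.p_adjusted
        df["rejected"] = fdr.rejected
        out.append(df)
    return ComparisonTables(cross_sectional=out[0], longitudinal=out[1])
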