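"""Band-specific leakage-corrected amplitude-envelope connectivity (AECc).

Source-reconstructed MEG region signals share instantaneous (zero-lag)
variance because of the limited spatial resolution of the inverse solution
("signal leakage").  The corrected amplitude envelope correlation removes
that shared variance by pairwise time-domain orthogonalization before
correlating the band-limited amplitude envelopes, and symmetrizes by
averaging the two orthogonalization directions.

The processing chain per epoch is: decimate (anti-aliased), band-pass
filter (zero-phase FIR), Hilbert envelope, pairwise leakage correction,
Pearson correlation of envelopes, and finally averaging over epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ConsistencyError

log = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "RoiEpoch",
    "ConnectivityMatrix",
    "DEFAULT_BANDS",
    "downsample",
    "bandpass",
    "amplitude_envelope",
    "aecc_pair",
    "aecc_matrix",
    "epoch_average",
]

#: Fraction of samples dropped at each end of an envelope before correlating,
#: to discard filter/Hilbert transients.
EDGE_FRACTION = 0.05

#: Relative variance below which a residual is treated as fully leaked.
_ZERO_VAR_RTOL = 1e-12


@dataclass(frozen=True)
class BandSpec:
    """A frequency band, e.g. ``BandSpec("theta", 4.0, 8.0)``."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0.0 < self.f_lo < self.f_hi):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )

    def validate_for(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ConfigurationError(
                f"band {self.name!r} upper edge {self.f_hi} Hz is not below the "
                f"Nyquist frequency {fs / 2} Hz"
            )


#: The canonical six-band decomposition of resting-state MEG.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha1", 8.0, 10.0),
    BandSpec("alpha2", 10.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 48.0),
)


def band_by_name(name: str) -> BandSpec:
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise ConfigurationError(f"unknown band {name!r}; known: "
                             f"{[b.name for b in DEFAULT_BANDS]}")


@dataclass
class RoiEpoch:
    """One artifact-free epoch of multichannel region time series.

    data : (n_rois, n_samples) array
    fs : sampling rate in Hz
    roi_labels : one label per row of ``data``
    """

    data: np.ndarray
    fs: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConsistencyError("epoch data must be 2-D (ROI x sample)")
        n_rois, n_samples = self.data.shape
        if n_rois < 2:
            raise ConsistencyError("an epoch needs at least 2 ROIs")
        if n_samples < 64:
            raise ConsistencyError("an epoch needs at least 64 samples")
        if not np.all(np.isfinite(self.data)):
            raise ConsistencyError("epoch data must be finite")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not self.roi_labels:
            self.roi_labels = [f"roi{i:03d}" for i in range(n_rois)]
        if len(self.roi_labels) != n_rois:
            raise ConsistencyError(
                f"{len(self.roi_labels)} labels for {n_rois} ROIs"
            )

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative ROI x ROI coupling weights for one band.

    ``provenance`` records how the matrix was obtained: a single epoch, an
    average over a subject's epochs, or an average over a group of subjects.
    """

    weights: np.ndarray
    band: str = "broadband"
    roi_labels: list[str] = field(default_factory=list)
    provenance: str = "single_epoch"

    _PROVENANCES = ("single_epoch", "epoch_mean", "group_mean")

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConsistencyError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ConsistencyError("weights must be finite")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ConsistencyError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ConsistencyError("diagonal must be exactly zero")
        if w.min() < 0.0 or w.max() > 1.0:
            raise ConsistencyError("weights must lie in [0, 1]")
        if self.provenance not in self._PROVENANCES:
            raise ConsistencyError(f"unknown provenance {self.provenance!r}")
        self.weights = w
        if not self.roi_labels:
            self.roi_labels = [f"roi{i:03d}" for i in range(w.shape[0])]
        if len(self.roi_labels) != w.shape[0]:
            raise ConsistencyError("label count must equal matrix size")

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# filtering


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def _fir_numtaps(fs: float, transition_hz: float, n_samples: int) -> int:
    """Hamming-window FIR length for a given transition width.

    Capped so that filtfilt's default padding (3 x numtaps) fits the epoch;
    very narrow bands on short epochs therefore get a wider transition.
    """
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    cap = max((n_samples - 4) // 3, 9)
    return _odd(min(max(numtaps, 9), cap))


def downsample(epoch: RoiEpoch, factor: int) -> RoiEpoch:
    """Anti-aliased decimation by an integer factor.

    A zero-phase FIR low-pass with cutoff at the new Nyquist frequency is
    applied before keeping every ``factor``-th sample.  ``factor=1`` is the
    identity.  A tail that does not divide evenly is truncated (logged).
    """
    factor = int(factor)
    if factor <= 0:
        raise ConfigurationError(f"decimation factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(epoch, data=epoch.data.copy())

    data = epoch.data
    if data.shape[1] % factor:
        keep = data.shape[1] - (data.shape[1] % factor)
        log.info("truncating %d trailing samples before decimation",
                 data.shape[1] - keep)
        data = data[:, :keep]

    new_nyq = epoch.fs / (2 * factor)
    numtaps = _fir_numtaps(epoch.fs, transition_hz=0.05 * new_nyq,
                           n_samples=data.shape[1])
    taps = sps.firwin(numtaps, new_nyq, fs=epoch.fs)
    filtered = sps.filtfilt(taps, [1.0], data, axis=-1)
    return RoiEpoch(filtered[:, ::factor], epoch.fs / factor,
                    list(epoch.roi_labels))


def bandpass(epoch: RoiEpoch, band: BandSpec) -> RoiEpoch:
    """Zero-phase windowed-sinc band-pass; output has the band edges inside
    the flat passband (transition bands sit outside [f_lo, f_hi])."""
    band.validate_for(epoch.fs)
    tw_lo = 0.25 * band.f_lo
    tw_hi = 0.25 * band.f_hi
    lo = max(band.f_lo - tw_lo / 2, 1e-3)
    hi = min(band.f_hi + tw_hi / 2, 0.499 * epoch.fs)
    numtaps = _fir_numtaps(epoch.fs, transition_hz=min(tw_lo, tw_hi),
                           n_samples=epoch.n_samples)
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=epoch.fs)
    filtered = sps.filtfilt(taps, [1.0], epoch.data, axis=-1)
    return replace(epoch, data=filtered)


def amplitude_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert envelope), same length."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 64:
        raise ConsistencyError("need at least 64 samples for an envelope")
    return np.abs(sps.hilbert(x, axis=-1))


# ---------------------------------------------------------------------------
# AECc


def _trim(v: np.ndarray, frac: float) -> np.ndarray:
    k = int(round(frac * v.shape[-1]))
    return v[..., k:v.shape[-1] - k] if k else v


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return 0.0
    return float((a @ b) / denom)


def _oriented_aec(x: np.ndarray, y: np.ndarray, env_x: np.ndarray,
                  edge_fraction: float) -> float:
    """Correlation of envelope(y orthogonalized w.r.t. x) with envelope(x)."""
    beta = (x @ y) / (x @ x)
    resid = y - beta * x
    if resid @ resid <= _ZERO_VAR_RTOL * (y @ y):
        log.warning("leakage correction removed all variance; AECc term = 0")
        return 0.0
    env_r = amplitude_envelope(resid)
    return _corr(_trim(env_r, edge_fraction), _trim(env_x, edge_fraction))


def aecc_pair(x: np.ndarray, y: np.ndarray,
              edge_fraction: float = EDGE_FRACTION) -> float:
    """Leakage-corrected amplitude envelope correlation of two band-limited
    signals, in [0, 1].

    Each signal is regressed out of the other in the time domain (least
    squares); the Hilbert envelope of the residual is correlated with the
    envelope of the predictor; the two directions are averaged and negative
    values clipped to zero.  The first and last ``edge_fraction`` of samples
    are excluded from the correlation.  A perfectly leaked copy (y = c*x)
    yields exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConsistencyError("aecc_pair needs two equal-length 1-D signals")
    if x.shape[0] < 64:
        raise ConsistencyError("need at least 64 samples")
    x = x - x.mean()
    y = y - y.mean()
    if (x @ x) == 0.0 or (y @ y) == 0.0:
        log.warning("zero-variance input to aecc_pair; returning 0")
        return 0.0
    env_x = amplitude_envelope(x)
    env_y = amplitude_envelope(y)
    r1 = _oriented_aec(x, y, env_x, edge_fraction)
    r2 = _oriented_aec(y, x, env_y, edge_fraction)
    return float(np.clip(0.5 * (r1 + r2), 0.0, 1.0))


def aecc_matrix(epoch: RoiEpoch, band: BandSpec,
                edge_fraction: float = EDGE_FRACTION) -> ConnectivityMatrix:
    """AECc for every unordered ROI pair of one (already decimated) epoch."""
    filtered = bandpass(epoch, band)
    n = filtered.n_rois
    sigs = filtered.data - filtered.data.mean(axis=1, keepdims=True)
    envs = np.abs(sps.hilbert(sigs, axis=-1))
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, yj = sigs[i], sigs[j]
            if (xi @ xi) == 0.0 or (yj @ yj) == 0.0:
                log.warning("zero-variance ROI in epoch; AECc(%d,%d)=0", i, j)
                continue
            r1 = _oriented_aec(xi, yj, envs[i], edge_fraction)
            r2 = _oriented_aec(yj, xi, envs[j], edge_fraction)
            w[i, j] = w[j, i] = np.clip(0.5 * (r1 + r2), 0.0, 1.0)
    return ConnectivityMatrix(w, band=band.name,
                              roi_labels=list(filtered.roi_labels),
                              provenance="single_epoch")


def epoch_average(matrices: list[ConnectivityMatrix],
                  provenance: str = "epoch_mean") -> ConnectivityMatrix:
    """Entrywise mean of connectivity matrices from the same band/labels."""
    if not matrices:
        raise ConsistencyError("epoch_average needs at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.weights.shape != first.weights.shape:
            raise ConsistencyError("matrices have mixed shapes")
        if m.roi_labels != first.roi_labels:
            raise ConsistencyError("matrices have mixed ROI labels")
        if m.band != first.band:
            raise ConsistencyError(
                f"cannot average across bands ({m.band!r} vs {first.band!r})"
            )
    mean = np.mean([m.weights for m in matrices], axis=0)
    return ConnectivityMatrix(mean, band=first.band,
                              roi_labels=list(first.roi_labels),
                              provenance=provenance)
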