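"""Resting-state fMRI metrics: FALFF and ReHo.

Implements the voxel-wise metric chain applied to a (post-realignment,
common-grid) 4-D time-series volume:

1. discard initial volumes,
2. linear detrend,
3. nuisance regression (Friston-24 motion expansion, global/tissue means),
4. FALFF -- fractional amplitude of low-frequency fluctuations, the ratio of
   sqrt-power summed over the 0.01-0.1 Hz band to sqrt-power summed over all
   positive-frequency bins (DC excluded),
5. ReHo -- Kendall's coefficient of concordance (KCC, W in [0, 1]) between
   each voxel's band-pass-filtered series and its 26 neighbours,
6. standardization by the within-mask mean, optional Gaussian smoothing.

Conventions: voxel indices are 0-based; world (mm) coordinates follow the
NIfTI affine; masks are boolean arrays on the volume grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy import linalg as sla
from scipy.stats import rankdata

from .errors import CollinearityError, InputError

DEFAULT_BAND = (0.01, 0.1)  # Hz
DEFAULT_N_DISCARD = 10
DEFAULT_FWHM_MM = 4.0
GM_MASK_THRESHOLD = 0.2

# 26-connected neighbourhood offsets (face + edge + corner), excluding (0,0,0).
NEIGHBOR_OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelTimeSeriesVolume:
    """A 4-D scalar grid (x, y, z, t) with its affine and repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise InputError(f"expected 4-D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise InputError("time series must have at least 2 volumes")
        if self.tr <= 0:
            raise InputError(f"tr must be positive, got {self.tr}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise InputError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class MetricMap:
    """A 3-D voxel-wise metric map (FALFF, ReHo or a thickness proxy)."""

    data: np.ndarray
    affine: np.ndarray
    metric_name: str
    standardized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise InputError(f"expected 3-D data, got shape {self.data.shape}")


@dataclass
class NuisanceDesign:
    """A t x k nuisance regressor matrix with column labels."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not self.labels:
            self.labels = [f"reg{i}" for i in range(self.matrix.shape[1])]
        if len(self.labels) != self.matrix.shape[1]:
            raise InputError("number of labels must match number of columns")


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def discard_initial_volumes(vol: VoxelTimeSeriesVolume, n_discard: int) -> VoxelTimeSeriesVolume:
    """Drop the first ``n_discard`` frames, keeping the remainder unchanged."""
    if n_discard < 0:
        raise InputError(f"n_discard must be non-negative, got {n_discard}")
    if n_discard >= vol.n_volumes:
        raise InputError(
            f"cannot discard {n_discard} of {vol.n_volumes} volumes"
        )
    if n_discard == 0:
        return vol
    return replace(vol, data=vol.data[..., n_discard:].copy())


def detrend_linear(ts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Residual of an ordinary least-squares fit of intercept + slope.

    Works on 1-D series or N-D arrays along ``axis``.  The residual has zero
    mean and zero covariance with the time index by construction.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[axis]
    if n < 3:
        raise InputError(f"need at least 3 timepoints to detrend, got {n}")
    x = np.moveaxis(ts, axis, -1)
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    slope = (x * t_c).sum(axis=-1, keepdims=True) / (t_c ** 2).sum()
    resid = x - x.mean(axis=-1, keepdims=True) - slope * t_c
    return np.moveaxis(resid, -1, axis)


def expand_friston24(motion: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Friston-24 expansion of 6 rigid-body motion parameters.

    Column layout: ``[R, R^2, R_lag1, R_lag1^2]`` (6 columns each); the first
    row of the lagged blocks is zero.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise InputError(
            f"motion table must have 6 columns, got shape {motion.shape}"
        )
    lag = np.zeros_like(motion)
    lag[1:] = motion[:-1]
    return np.hstack([motion, motion ** 2, lag, lag ** 2])


def _check_full_rank(matrix: np.ndarray, labels: list[str]) -> None:
    """Raise ``CollinearityError`` naming dependent columns if rank deficient."""
    _, r, piv = sla.qr(matrix, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(matrix.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < matrix.shape[1]:
        bad = [labels[i] for i in sorted(piv[rank:])]
        raise CollinearityError(bad)


def regress_nuisance(ts: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """OLS residual of ``ts`` against all design columns.

    ``ts`` may be 1-D (t,) or 2-D (t, m) with series in columns; residuals are
    orthogonal to every design column.
    """
    X = design.matrix
    y = np.asarray(ts, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise InputError(
            f"series length {y.shape[0]} != design rows {X.shape[0]}"
        )
    _check_full_rank(X, design.labels)
    q, _ = np.linalg.qr(X)
    return y - q @ (q.T @ y)


def bandpass_filter(ts: np.ndarray, tr: float, band: tuple[float, float] = DEFAULT_BAND,
                    axis: int = -1, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis."""
    f_lo, f_hi = band
    nyq = 0.5 / tr
    if not (0 < f_lo < f_hi <= nyq):
        raise InputError(f"band {band} outside (0, Nyquist={nyq:g}] Hz")
    sos = signal.butter(order, [f_lo / nyq, f_hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=axis)


# ---------------------------------------------------------------------------
# FALFF
# ---------------------------------------------------------------------------

def _sqrt_power_spectrum(ts: np.ndarray, tr: float, axis: int = -1):
    amp = np.abs(np.fft.rfft(np.asarray(ts, dtype=float), axis=axis))
    freqs = np.fft.rfftfreq(ts.shape[axis], d=tr)
    return amp, freqs


def compute_falff(ts: np.ndarray, tr: float, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Fractional amplitude of low-frequency fluctuations of one series.

    Ratio of sqrt-power summed over DFT bins with ``f_lo <= f <= f_hi``
    (closed interval) to sqrt-power summed over all positive-frequency bins.
    The DC bin is excluded; a flat (zero-power) series returns 0 with a
    warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 1:
        raise InputError("compute_falff expects a single 1-D series")
    if ts.size < 8:
        raise InputError(f"series too short for FALFF: {ts.size} < 8")
    f_lo, f_hi = band
    nyq = 0.5 / tr
    if not (0 < f_lo < f_hi <= nyq + 1e-12):
        raise InputError(f"band {band} outside (0, Nyquist={nyq:g}] Hz")
    amp, freqs = _sqrt_power_spectrum(ts, tr)
    pos = freqs > 0
    total = amp[pos].sum()
    if total <= 0:
        warnings.warn("zero total power; FALFF set to 0", stacklevel=2)
        return 0.0
    in_band = pos & (freqs >= f_lo) & (freqs <= f_hi)
    return float(amp[in_band].sum() / total)


def compute_falff_map(vol: VoxelTimeSeriesVolume, mask: np.ndarray,
                      band: tuple[float, float] = DEFAULT_BAND) -> MetricMap:
    """Voxel-wise FALFF over ``mask`` (out-of-mask voxels are 0)."""
    mask = _check_mask(mask, vol.data.shape[:3])
    series = vol.data[mask]  # (V, t)
    amp = np.abs(np.fft.rfft(series, axis=-1))
    freqs = np.fft.rfftfreq(vol.n_volumes, d=vol.tr)
    pos = freqs > 0
    in_band = pos & (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise InputError(f"band {band} contains no DFT bins at tr={vol.tr}")
    total = amp[:, pos].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(total > 0, amp[:, in_band].sum(axis=1) / total, 0.0)
    if (total <= 0).any():
        warnings.warn("constant voxel series inside mask; FALFF set to 0", stacklevel=2)
    out = np.zeros(vol.data.shape[:3])
    out[mask] = vals
    return MetricMap(out, vol.affine, "FALFF")


# ---------------------------------------------------------------------------
# ReHo / KCC
# ---------------------------------------------------------------------------

def _tie_term_1d(values: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of one series."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t ** 3 - t).sum())


def compute_kcc(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance W of k series over n timepoints.

    ``series`` is (k, n).  Ranks are computed over time within each series
    (mid-ranks for ties); with rank sums R_t over timepoints,
    ``S = sum_t (R_t - mean R)^2`` and
    ``W = 12 S / (k^2 (n^3 - n) - k * sum_j T_j)`` where ``T_j`` is the tie
    correction of series j.  A zero denominator (all series constant) yields
    0 with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise InputError("compute_kcc expects a (k, n) array")
    k, n = series.shape
    if k < 2 or n < 2:
        raise InputError(f"need k >= 2 and n >= 2, got k={k}, n={n}")
    ranks = rankdata(series, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie = sum(_tie_term_1d(series[j]) for j in range(k))
    denom = k ** 2 * (n ** 3 - n) - k * tie
    if denom <= 0:
        warnings.warn("degenerate KCC denominator (constant series); W set to 0",
                      stacklevel=2)
        return 0.0
    return float(12.0 * s / denom)


def _check_mask(mask: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise InputError(f"mask shape {mask.shape} != grid shape {tuple(shape)}")
    if not mask.any():
        raise InputError("mask is empty")
    return mask


def _shift3d(arr: np.ndarray, dx: int, dy: int, dz: int) -> np.ndarray:
    """Shift a 3-D(+) array without wrap-around, zero-filling."""
    out = np.zeros_like(arr)
    src = [slice(max(-d, 0), arr.shape[i] - max(d, 0)) for i, d in enumerate((dx, dy, dz))]
    dst = [slice(max(d, 0), arr.shape[i] + min(d, 0)) for i, d in enumerate((dx, dy, dz))]
    out[tuple(dst)] = arr[tuple(src)]
    return out


def compute_reho_map(vol: VoxelTimeSeriesVolume, mask: np.ndarray) -> MetricMap:
    """Voxel-wise ReHo: KCC of each in-mask voxel with its in-mask subset of
    26 neighbours.  Voxels whose neighbourhood has fewer than 2 in-mask
    members (including the voxel itself) are set to 0.
    """
    mask = _check_mask(mask, vol.data.shape[:3])
    n = vol.n_volumes
    ranks = np.zeros_like(vol.data)
    ranks[mask] = rankdata(vol.data[mask], axis=-1)

    # Per-voxel tie-correction terms; continuous data essentially never ties,
    # so only compute the exact term where ties are present.
    tie = np.zeros(mask.shape)
    in_series = vol.data[mask]
    srt = np.sort(in_series, axis=-1)
    has_tie = (np.diff(srt, axis=-1) == 0).any(axis=-1)
    if has_tie.any():
        tie_vals = np.zeros(in_series.shape[0])
        for idx in np.nonzero(has_tie)[0]:
            tie_vals[idx] = _tie_term_1d(in_series[idx])
        tie[mask] = tie_vals

    m = mask.astype(float)
    rank_sum = ranks.copy()
    k_count = m.copy()
    tie_sum = tie.copy()
    for off in NEIGHBOR_OFFSETS_26:
        rank_sum += _shift3d(ranks, *off)
        k_count += _shift3d(m, *off)
        tie_sum += _shift3d(tie, *off)

    mean_rank = k_count[..., None] * (n + 1) / 2.0
    s = ((rank_sum - mean_rank) ** 2).sum(axis=-1)
    denom = k_count ** 2 * (n ** 3 - n) - k_count * tie_sum
    out = np.zeros(mask.shape)
    valid = mask & (k_count >= 2) & (denom > 0)
    out[valid] = 12.0 * s[valid] / denom[valid]
    degenerate = mask & ~valid
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} in-mask voxel(s) with degenerate "
            "neighbourhood; ReHo set to 0", stacklevel=2)
    return MetricMap(out, vol.affine, "ReHo")


# ---------------------------------------------------------------------------
# Map post-processing
# ---------------------------------------------------------------------------

def standardize_map(metric_map: MetricMap, mask: np.ndarray) -> MetricMap:
    """Divide by the mean over ``mask`` so the in-mask mean becomes 1."""
    mask = _check_mask(mask, metric_map.data.shape)
    mean = metric_map.data[mask].mean()
    if mean == 0:
        raise InputError("in-mask mean is zero; cannot standardize")
    return MetricMap(metric_map.data / mean, metric_map.affine,
                     metric_map.metric_name, standardized=True)


def gaussian_smooth(metric_map: MetricMap, fwhm_mm: float,
                    voxel_size_mm: np.ndarray | float | None = None) -> MetricMap:
    """Separable Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    ``fwhm_mm = 0`` is the identity.  Voxel sizes default to the affine's
    column norms.
    """
    if fwhm_mm < 0:
        raise InputError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return metric_map
    if voxel_size_mm is None:
        voxel_size_mm = np.linalg.norm(metric_map.affine[:3, :3], axis=0)
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    smoothed = ndimage.gaussian_filter(metric_map.data, sigma=sigma_vox, mode="constant")
    return MetricMap(smoothed, metric_map.affine, metric_map.metric_name,
                     standardized=metric_map.standardized)


def build_group_gm_mask(prob_maps: list[np.ndarray],
                        threshold: float = GM_MASK_THRESHOLD) -> np.ndarray:
    """Boolean mask where the voxel-wise mean gray-matter probability across
    subjects is >= ``threshold``."""
    if not prob_maps:
        raise InputError("no probability maps given")
    if not (0 <= threshold <= 1):
        raise InputError(f"threshold must lie in [0, 1], got {threshold}")
    shapes = {np.asarray(p).shape for p in prob_maps}
    if len(shapes) != 1:
        raise InputError(f"probability maps on mismatched grids: {sorted(shapes)}")
    mean = np.mean([np.asarray(p, dtype=float) for p in prob_maps], axis=0)
    return mean >= threshold


# ---------------------------------------------------------------------------
# Subject-level chain
# ---------------------------------------------------------------------------

def build_nuisance_design(motion: np.ndarray, data: np.ndarray,
                          brain_mask: np.ndarray,
                          wm_mask: np.ndarray | None = None,
                          csf_mask: np.ndarray | None = None) -> NuisanceDesign:
    """Assemble intercept + Friston-24 + global (and optional WM/CSF) mean
    signals for the retained frames.  ``data`` is the (x, y, z, t) array the
    mean signals are extracted from."""
    fr24 = expand_friston24(motion)
    cols = [np.ones((fr24.shape[0], 1)), fr24]
    labels = ["intercept"] + [
        f"{block}{i}" for block in ("mot", "mot_sq", "mot_lag", "mot_lag_sq")
        for i in range(6)
    ]
    cols.append(data[brain_mask].mean(axis=0, keepdims=True).T)
    labels.append("global")
    for name, tissue in (("wm", wm_mask), ("csf", csf_mask)):
        if tissue is not None and np.asarray(tissue, bool).any():
            cols.append(data[np.asarray(tissue, bool)].mean(axis=0, keepdims=True).T)
            labels.append(name)
    return NuisanceDesign(np.hstack(cols), labels)


def compute_subject_metric_maps(
    vol: VoxelTimeSeriesVolume,
    motion: np.ndarray | pd.DataFrame,
    gm_prob: np.ndarray,
    *,
    n_discard: int = DEFAULT_N_DISCARD,
    band: tuple[float, float] = DEFAULT_BAND,
    fwhm_mm: float = 0.0,
    gm_mask_threshold: float = 0.5,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    metrics: tuple[str, ...] = ("FALFF", "ReHo"),
) -> dict[str, MetricMap]:
    """Full single-subject chain from raw volume to standardized metric maps.

    Discards initial frames, detrends, regresses nuisance signals, then
    computes FALFF on the residuals and ReHo on band-pass-filtered residuals.
    Maps are standardized by the subject brain-mask mean and (optionally)
    smoothed.  Smoothing defaults to off for functional maps.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != vol.n_volumes:
        raise InputError(
            f"motion rows {motion.shape[0]} != n_volumes {vol.n_volumes}")
    vol = discard_initial_volumes(vol, n_discard)
    motion = motion[n_discard:]
    data = detrend_linear(vol.data, axis=-1)

    brain_mask = np.asarray(gm_prob, dtype=float) >= gm_mask_threshold
    if not brain_mask.any():
        raise InputError("subject brain mask is empty")
    design = build_nuisance_design(motion, data, brain_mask, wm_mask, csf_mask)
    flat = data.reshape(-1, vol.n_volumes).T  # (t, V)
    resid = regress_nuisance(flat, design)
    data = resid.T.reshape(data.shape)
    clean = replace(vol, data=data)

    out: dict[str, MetricMap] = {}
    if "FALFF" in metrics:
        falff = compute_falff_map(clean, brain_mask, band=band)
        falff = standardize_map(falff, brain_mask)
        out["FALFF"] = gaussian_smooth(falff, fwhm_mm) if fwhm_mm else falff
    if "ReHo" in metrics:
        filtered = replace(clean, data=bandpass_filter(clean.data, clean.tr, band))
        reho = compute_reho_map(filtered, brain_mask)
        reho = standardize_map(reho, brain_mask)
        out["ReHo"] = gaussian_smooth(reho, fwhm_mm) if fwhm_mm else reho
    return out
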