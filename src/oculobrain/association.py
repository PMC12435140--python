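"""Two-stage multivariable linear regression linking cognition, retinal
biometrics and brain metrics.

The per-element model is

    Y = b0 + b1 * x_obj + b2 * x_age + b3 * x_sex + b4 * x_edu
           + b5 * x_hyp + b6 * x_dia [+ b7 * x_etiv]

where x_obj is a brain metric (FALFF/ReHo at a voxel, or cortical thickness
at a DKT ROI) and ETIV enters only for thickness analyses.  Stage 1 tests a
cognitive score as Y over the gray-matter mask (voxel-wise, permutation
max-|t| FWE) or over the 62 DKT ROIs (Bonferroni p < 1/62, strict).  Stage 2
re-tests an ophthalmic biometric as Y *only inside* the stage-1 selection,
with FWE over the reduced domain.

Permutation inference uses Freedman-Lane residual permutation: the score is
residualized against the covariates, the residuals permuted, and the max-|t|
over the domain recorded per permutation; the identity permutation is
included so the procedure is valid (slightly conservative) at any n_perm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, InputError
from .fmri import MetricMap, _check_full_rank

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 1000
BONFERRONI_M = 62

FUNCTIONAL_COVARIATES = ("age", "sex", "education", "hypertension", "diabetes")
STRUCTURAL_COVARIATES = FUNCTIONAL_COVARIATES + ("etiv",)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """OLS fit of the association model; ``t``/``p`` refer to b1 (x_obj)."""

    beta: np.ndarray
    se: np.ndarray
    t: float
    p: float
    n: int
    df: int
    labels: list[str] = field(default_factory=list)


@dataclass
class SignificanceMask:
    """Elements surviving a correction step, with their t statistics.

    ``domain`` is either a boolean voxel grid or a list of ROI labels;
    ``selected`` is boolean per domain element and ``stat_map`` holds the
    per-element t for b1.
    """

    domain: np.ndarray | list[str]
    selected: np.ndarray
    stat_map: np.ndarray
    correction: dict
    stage: str

    @property
    def n_selected(self) -> int:
        return int(np.asarray(self.selected).sum())


@dataclass
class PeakLocation:
    """Location of the maximum |t| inside a selected set."""

    peak_abs_t: float
    voxel_index: tuple[int, int, int] | None = None
    world_mm: tuple[float, float, float] | None = None
    roi_label: str | None = None


# ---------------------------------------------------------------------------
# Core OLS
# ---------------------------------------------------------------------------

def _design(x_obj: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    n = len(x_obj)
    return np.column_stack([np.ones(n), x_obj, covariates])


def fit_mlr(y: np.ndarray, x_obj: np.ndarray, covariates: np.ndarray,
            covariate_labels: list[str] | None = None) -> RegressionFit:
    """Ordinary least squares for the association model.

    Returns coefficients b0..bk, their standard errors, and the t statistic
    and two-sided p-value for b1 (the x_obj coefficient) on n - k - 1
    residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    x_obj = np.asarray(x_obj, dtype=float).ravel()
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != len(y):
        covariates = covariates.T
    if not (len(y) == len(x_obj) == covariates.shape[0]):
        raise InputError("y, x_obj and covariates must have equal length")
    if not np.isfinite(y).all() or not np.isfinite(x_obj).all() \
            or not np.isfinite(covariates).all():
        raise InputError("missing/non-finite values must be dropped upstream")
    X = _design(x_obj, covariates)
    n, k1 = X.shape
    if n <= k1 + 1:
        raise InputError(f"too few observations (n={n}) for {k1} parameters")
    labels = ["intercept", "x_obj"] + list(
        covariate_labels or [f"cov{i}" for i in range(covariates.shape[1])])
    _check_full_rank(X, labels)

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k1
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = float(beta[1] / se[1]) if se[1] > 0 else np.inf * np.sign(beta[1])
    p1 = float(2.0 * stats.t.sf(abs(t1), df)) if np.isfinite(t1) else 0.0
    return RegressionFit(beta=beta, se=se, t=t1, p=p1, n=n, df=df, labels=labels)


def prepare_covariates(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Return a dense covariate matrix, dropping zero-variance columns with a
    warning (e.g. no diabetics in a small pooled group pair)."""
    keep, dropped = [], []
    for col in covariates.columns:
        if np.ptp(np.asarray(covariates[col], dtype=float)) == 0:
            dropped.append(col)
        else:
            keep.append(col)
    if dropped:
        warnings.warn(f"dropping constant covariate column(s): {dropped}", stacklevel=3)
        logger.info("dropped constant covariates: %s", dropped)
    return np.asarray(covariates[keep], dtype=float), keep


# ---------------------------------------------------------------------------
# Vectorized voxel-wise inference (Frisch-Waugh + Freedman-Lane)
# ---------------------------------------------------------------------------

def _massunivariate_t(y: np.ndarray, X: np.ndarray, Z: np.ndarray):
    """t statistics for b1 of y ~ x_v + Z, vectorized over columns of X.

    ``Z`` must include the intercept.  Returns (t, b, helper arrays) where the
    helpers allow recomputing t for permuted responses cheaply.
    """
    q, _ = np.linalg.qr(Z)
    y_r = y - q @ (q.T @ y)
    X_r = X - q @ (q.T @ X)
    xtx = (X_r ** 2).sum(axis=0)
    df = len(y) - Z.shape[1] - 1
    b, t = _t_from_residualized(y_r, X_r, xtx, df)
    return t, b, (q, X_r, xtx, df)


def _t_from_residualized(y_r: np.ndarray, X_r: np.ndarray,
                         xtx: np.ndarray, df: int):
    yty = float(y_r @ y_r) if y_r.ndim == 1 else (y_r ** 2).sum(axis=0)
    num = X_r.T @ y_r  # (V,) or (V, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        if y_r.ndim == 1:
            b = np.where(xtx > 0, num / np.where(xtx > 0, xtx, 1.0), 0.0)
            rss = np.clip(yty - b * num, 0, None)
            t = b / np.sqrt(np.where(rss > 0, rss / (df * np.where(xtx > 0, xtx, 1.0)), np.inf))
        else:
            xtx_c = np.where(xtx > 0, xtx, 1.0)[:, None]
            b = np.where(xtx[:, None] > 0, num / xtx_c, 0.0)
            rss = np.clip(yty[None, :] - b * num, 0, None)
            t = b / np.sqrt(np.where(rss > 0, rss / (df * xtx_c), np.inf))
    return b, np.nan_to_num(t, nan=0.0, posinf=1e30, neginf=-1e30)


def _permutation_max_abs_t(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                           n_perm: int, rng: np.random.Generator):
    """Observed per-column |t| plus the Freedman-Lane max-|t| null distribution."""
    t_obs, b_obs, (q, X_r, xtx, df) = _massunivariate_t(y, X, Z)
    e = y - q @ (q.T @ y)  # reduced-model residuals
    perms = np.empty((len(y), n_perm))
    perms[:, 0] = e  # identity permutation for validity
    for j in range(1, n_perm):
        perms[:, j] = e[rng.permutation(len(y))]
    perms -= q @ (q.T @ perms)  # re-residualize permuted responses
    _, t_perm = _t_from_residualized(perms, X_r, xtx, df)
    max_abs = np.abs(t_perm).max(axis=0)
    return t_obs, b_obs, max_abs, df


def stage1_voxelwise(metric_maps, score, covariates: pd.DataFrame,
                     gm_mask: np.ndarray, alpha: float = DEFAULT_ALPHA,
                     n_perm: int = DEFAULT_N_PERM,
                     seed: int | np.random.Generator = 0) -> SignificanceMask:
    """Stage 1: cognition ~ voxel metric + covariates over the gray-matter
    mask, FWE-controlled by the permutation max-|t| distribution.

    ``metric_maps`` is a list of per-subject :class:`MetricMap` (or 3-D
    arrays).  Selected voxels are those with |t| >= the (1 - alpha) quantile
    of the max-|t| null distribution.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for FWE estimation", stacklevel=2)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if not gm_mask.any():
        raise InputError("gray-matter mask is empty")
    data = np.stack([m.data if isinstance(m, MetricMap) else np.asarray(m, float)
                     for m in metric_maps])
    X = data[:, gm_mask]  # (n, V)
    y = np.asarray(score, dtype=float)
    cov, _ = prepare_covariates(covariates)
    Z = np.column_stack([np.ones(len(y)), cov])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs, _, max_abs, _ = _permutation_max_abs_t(y, X, Z, n_perm, rng)
    threshold = float(np.quantile(max_abs, 1 - alpha, method="higher")) if alpha < 1 else 0.0
    stat_map = np.zeros(gm_mask.shape)
    stat_map[gm_mask] = t_obs
    selected = np.zeros(gm_mask.shape, dtype=bool)
    selected[gm_mask] = np.abs(t_obs) >= threshold
    return SignificanceMask(
        domain=gm_mask, selected=selected, stat_map=stat_map,
        correction={"method": "permutation-FWE", "alpha": alpha,
                    "n_perm": n_perm, "threshold": threshold},
        stage="stage1-voxelwise")


def stage1_roiwise(thickness: pd.DataFrame, score, covariates: pd.DataFrame,
                   threshold: float = 1.0 / BONFERRONI_M) -> SignificanceMask:
    """Stage 1 over DKT ROIs: cognition ~ ROI thickness + covariates (+ETIV),
    selecting ROIs with p strictly below the Bonferroni threshold (1/62)."""
    from .dkt import DKT_LABELS
    missing = [lab for lab in DKT_LABELS if lab not in thickness.columns]
    if missing:
        raise InputError(f"missing ROI columns: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    labels = list(DKT_LABELS)
    y = np.asarray(score, dtype=float)
    cov, cov_labels = prepare_covariates(covariates)
    t_vals = np.zeros(len(labels))
    p_vals = np.ones(len(labels))
    for i, lab in enumerate(labels):
        fit = fit_mlr(y, np.asarray(thickness[lab], float), cov, cov_labels)
        t_vals[i], p_vals[i] = fit.t, fit.p
    selected = p_vals < threshold  # strict inequality at the boundary
    return SignificanceMask(
        domain=labels, selected=selected, stat_map=t_vals,
        correction={"method": "bonferroni", "threshold": threshold, "p": p_vals},
        stage="stage1-roiwise")


def stage2(metric_maps, biometric, covariates: pd.DataFrame,
           stage1_mask: SignificanceMask, alpha: float = DEFAULT_ALPHA,
           n_perm: int = DEFAULT_N_PERM,
           seed: int | np.random.Generator = 0
           ) -> tuple[SignificanceMask, list[RegressionFit]]:
    """Stage 2: biometric ~ brain metric + covariates, restricted to the
    stage-1 selection, with FWE over the reduced domain only.

    Voxel domains use permutation max-|t|; ROI domains use Bonferroni with
    threshold 1/|domain|.  An empty stage-1 selection yields an empty result
    with a warning.
    """
    y = np.asarray(biometric, dtype=float)
    cov, cov_labels = prepare_covariates(covariates)
    if stage1_mask.n_selected == 0:
        warnings.warn("stage-1 selection is empty; stage-2 result is empty",
                      stacklevel=2)
        empty = SignificanceMask(
            domain=stage1_mask.selected, selected=np.zeros_like(np.asarray(stage1_mask.selected), dtype=bool),
            stat_map=np.zeros_like(np.asarray(stage1_mask.stat_map, dtype=float)),
            correction={"method": "none", "note": "empty stage-1 mask"},
            stage="stage2")
        return empty, []

    if isinstance(stage1_mask.domain, list):  # ROI domain
        labels = [lab for lab, s in zip(stage1_mask.domain, stage1_mask.selected) if s]
        thr = 1.0 / len(labels)
        t_vals = np.zeros(len(stage1_mask.domain))
        selected = np.zeros(len(stage1_mask.domain), dtype=bool)
        fits = []
        thickness = metric_maps  # DataFrame in the ROI case
        for lab in labels:
            fit = fit_mlr(y, np.asarray(thickness[lab], float), cov, cov_labels)
            i = stage1_mask.domain.index(lab)
            t_vals[i] = fit.t
            selected[i] = fit.p < thr
            fits.append(fit)
        sig = SignificanceMask(
            domain=stage1_mask.domain, selected=selected, stat_map=t_vals,
            correction={"method": "bonferroni", "threshold": thr,
                        "domain_size": len(labels)},
            stage="stage2-roiwise")
        _assert_nested(sig, stage1_mask)
        return sig, fits

    sel = np.asarray(stage1_mask.selected, dtype=bool)
    data = np.stack([m.data if isinstance(m, MetricMap) else np.asarray(m, float)
                     for m in metric_maps])
    X = data[:, sel]
    Z = np.column_stack([np.ones(len(y)), cov])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs, b_obs, max_abs, df = _permutation_max_abs_t(y, X, Z, n_perm, rng)
    threshold = float(np.quantile(max_abs, 1 - alpha, method="higher")) if alpha < 1 else 0.0
    stat_map = np.zeros(sel.shape)
    stat_map[sel] = t_obs
    selected = np.zeros(sel.shape, dtype=bool)
    selected[sel] = np.abs(t_obs) >= threshold
    sig = SignificanceMask(
        domain=sel, selected=selected, stat_map=stat_map,
        correction={"method": "permutation-FWE", "alpha": alpha,
                    "n_perm": n_perm, "threshold": threshold},
        stage="stage2-voxelwise")
    _assert_nested(sig, stage1_mask)
    fits = []
    sel_idx = np.argwhere(sel)
    se = np.where(np.abs(t_obs) > 0, np.abs(b_obs / np.where(t_obs == 0, 1, t_obs)), 0.0)
    for j in range(len(sel_idx)):
        p = float(2 * stats.t.sf(abs(t_obs[j]), df))
        fits.append(RegressionFit(
            beta=np.array([np.nan, b_obs[j]]), se=np.array([np.nan, se[j]]),
            t=float(t_obs[j]), p=p, n=len(y), df=df,
            labels=["intercept", "x_obj"]))
    return sig, fits


def _assert_nested(stage2_mask: SignificanceMask, stage1_mask: SignificanceMask) -> None:
    s2 = np.asarray(stage2_mask.selected, dtype=bool)
    s1 = np.asarray(stage1_mask.selected, dtype=bool)
    if (s2 & ~s1).any():
        raise AssertionError("stage-2 selection escapes the stage-1 mask")


# ---------------------------------------------------------------------------
# Peak localization
# ---------------------------------------------------------------------------

def find_peak(mask: SignificanceMask, affine: np.ndarray | None = None) -> PeakLocation:
    """Element with maximum |t| inside the selection; ties resolve to the
    smallest linear index."""
    sel = np.asarray(mask.selected, dtype=bool)
    if not sel.any():
        raise InputError("empty selection has no peak")
    stat = np.asarray(mask.stat_map, dtype=float)
    abs_t = np.where(sel, np.abs(stat), -np.inf)
    flat_idx = int(np.argmax(abs_t))  # argmax takes the first (lowest) index on ties
    peak = float(abs_t.ravel()[flat_idx])
    if isinstance(mask.domain, list):
        return PeakLocation(peak_abs_t=peak, roi_label=mask.domain[flat_idx])
    ijk = np.unravel_index(flat_idx, sel.shape)
    world = None
    if affine is not None:
        w = np.asarray(affine, float) @ np.array([*ijk, 1.0])
        world = tuple(float(v) for v in w[:3])
    return PeakLocation(peak_abs_t=peak, voxel_index=tuple(int(i) for i in ijk),
                        world_mm=world)


# ---------------------------------------------------------------------------
# Group-pair driver
# ---------------------------------------------------------------------------

COGNITIVE_SCORES = ("MMSE", "MoCA", "BNT", "CDT", "BDST", "TMT-A", "TMT-B")
OPHTHALMIC_BIOMETRICS = ("faz_area_mm2", "faz_perimeter_mm", "rbvc_per_mm",
                         "rnfl_thickness_um", "gcl_ipl_thickness_um")


def run_group_pair_analysis(
    subjects: pd.DataFrame,
    pair: tuple[str, str],
    *,
    metric_maps: dict[str, list] | None = None,
    thickness: pd.DataFrame | None = None,
    gm_mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    scores: tuple[str, ...] = COGNITIVE_SCORES,
    biometrics: tuple[str, ...] = OPHTHALMIC_BIOMETRICS,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict:
    """Full two-stage analysis for one pooled group pair (HC + one stage).

    ``subjects`` holds one row per subject with group labels, covariates,
    cognitive scores and ophthalmic biometrics; ``metric_maps`` maps metric
    names ("FALFF"/"ReHo") to per-subject maps aligned with the *pooled*
    subject order; ``thickness`` is the subjects x 62 ROI table.  Returns a
    structured report keyed by metric and score, each stage-2 entry carrying
    the sign of b1 and the peak label/voxel.
    """
    ref, other = pair
    for g in pair:
        if not (subjects["group"] == g).any():
            raise InputError(f"group {g!r} absent from cohort")
    in_pair = subjects["group"].isin(pair).to_numpy()
    sub = subjects.loc[in_pair].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    func_cov = sub[list(FUNCTIONAL_COVARIATES)]
    struct_cov = sub[list(STRUCTURAL_COVARIATES)]

    report: dict = {"pair": list(pair), "n": int(in_pair.sum()), "results": []}
    metric_items: list[tuple[str, object]] = []
    if metric_maps:
        for name, maps in metric_maps.items():
            sel_maps = [m for m, keep in zip(maps, in_pair) if keep]
            metric_items.append((name, sel_maps))
    if thickness is not None:
        metric_items.append(("thickness", thickness.loc[in_pair].reset_index(drop=True)))

    for metric_name, metric_data in metric_items:
        structural = metric_name == "thickness"
        cov1 = struct_cov if structural else func_cov
        for score in scores:
            y1 = sub[score].to_numpy(dtype=float)
            if structural:
                m1 = stage1_roiwise(metric_data, y1, cov1)
            else:
                m1 = stage1_voxelwise(metric_data, y1, cov1, gm_mask,
                                      alpha=alpha, n_perm=n_perm, seed=rng)
            entry = {"metric": metric_name, "score": score,
                     "stage1_n_selected": m1.n_selected, "stage2": []}
            if m1.n_selected:
                for bio in biometrics:
                    y2 = sub[bio].to_numpy(dtype=float)
                    m2, fits = stage2(metric_data, y2, cov1, m1,
                                      alpha=alpha, n_perm=n_perm, seed=rng)
                    res = {"biometric": bio, "n_selected": m2.n_selected}
                    if m2.n_selected:
                        peak = find_peak(m2, affine=affine)
                        stat = np.asarray(m2.stat_map)[np.asarray(m2.selected, bool)]
                        res["beta1_sign"] = int(np.sign(stat[np.argmax(np.abs(stat))]))
                        res["peak"] = {
                            "abs_t": peak.peak_abs_t,
                            "roi_label": peak.roi_label,
                            "voxel_index": peak.voxel_index,
                            "world_mm": peak.world_mm,
                        }
                    entry["stage2"].append(res)
            report["results"].append(entry)
    return report
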