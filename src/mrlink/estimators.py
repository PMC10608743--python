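"""Univariable two-sample MR estimators and diagnostics.

Implements the Wald ratio, inverse-variance-weighted (IVW) regression through
the origin, MR-Egger regression with a free pleiotropy intercept, the weighted
median of per-instrument ratios, Cochran's Q heterogeneity statistic, and
leave-one-out IVW.

All estimators consume a :class:`~mrlink.sumstats.HarmonizedInstrumentSet`.
Binary outcomes are analysed on the log odds-ratio scale; odds ratios and
their CIs are exponentiated only at reporting time (``MREstimate.or_scale``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InputError, InsufficientInstrumentsError, UndefinedRatioError
from .sumstats import HarmonizedInstrumentSet

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method.

    ``beta`` is the effect of a one-unit increase in the exposure on the
    outcome (log-OR per unit for binary outcomes). ``or_scale`` holds the
    exponentiated (OR, CI low, CI high) triple when the outcome is binary.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = math.nan
    ci_high: float = math.nan
    or_scale: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    def with_or(self) -> "MREstimate":
        """Attach the exponentiated odds-ratio representation."""
        self.or_scale = (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))
        return self


@dataclass
class HeterogeneityResult:
    """Cochran's Q against the pooled slope; df = n_snp − (1 for IVW, 2 for Egger)."""

    Q: float
    df: int
    p_h: float


@dataclass
class PleiotropyResult:
    """MR-Egger intercept: average directional pleiotropy per instrument."""

    intercept: float
    intercept_se: float
    p_intercept: float


def wald_ratio(
    beta_x: float, se_x: float, beta_y: float, se_y: float
) -> MREstimate:
    """Single-instrument causal estimate β_Y / β_X.

    The standard error is the first-order delta approximation se_Y / |β_X|
    (exposure-side uncertainty ignored, the usual two-sample convention).
    """
    if beta_x == 0:
        raise UndefinedRatioError("Wald ratio undefined for zero exposure effect")
    beta = beta_y / beta_x
    se = se_y / abs(beta_x)
    p = 2 * stats.norm.sf(abs(beta / se))
    return MREstimate(method="wald_ratio", beta=beta, se=se, pval=float(p), n_snp=1)


def ivw(
    hset: HarmonizedInstrumentSet,
    effects_model: str = "multiplicative_random",
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate: WLS of β_Y on β_X through the origin.

    With weights w_j = 1/se_Yj²::

        beta = Σ w_j β_Xj β_Yj / Σ w_j β_Xj²
        se_fixed = (Σ w_j β_Xj²)^(−1/2)
        Q = Σ w_j (β_Yj − beta·β_Xj)²     (df = n_snp − 1)

    Under ``multiplicative_random`` (the default) the fixed-effects SE is
    scaled by max(1, sqrt(Q/df)), so under-dispersed instrument sets fall
    back to the fixed-effects SE. A single instrument reduces to the Wald
    ratio (Q degenerate).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise InputError(f"unknown effects model {effects_model!r}")
    j = hset.n_snp
    if j == 0:
        raise InputError("IVW requires at least one instrument")
    if j == 1:
        est = wald_ratio(
            hset.beta_exposure[0],
            hset.se_exposure[0],
            hset.beta_outcome[0],
            hset.se_outcome[0],
        )
        return est, HeterogeneityResult(Q=0.0, df=0, p_h=float("nan"))
    bx, by, sy = hset.beta_exposure, hset.beta_outcome, hset.se_outcome
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = j - 1
    p_h = float(stats.chi2.sf(q, df))
    scale = 1.0
    if effects_model == "multiplicative_random":
        scale = max(1.0, math.sqrt(q / df))
    se = se_fixed * scale
    p = 2 * stats.norm.sf(abs(beta / se))
    est = MREstimate(method="ivw", beta=beta, se=se, pval=float(p), n_snp=j)
    return est, HeterogeneityResult(Q=q, df=df, p_h=p_h)


def mr_egger(
    hset: HarmonizedInstrumentSet,
) -> tuple[MREstimate, PleiotropyResult, HeterogeneityResult]:
    """MR-Egger: weighted regression of β_Y on β_X with a free intercept.

    Rows are first oriented so every β_Xj ≥ 0 (both members of a pair are
    negated when β_Xj < 0); this orientation is internal and never mutates
    the harmonized set. Weights are 1/se_Yj². SEs carry the multiplicative
    overdispersion scale max(1, sqrt(Q_egger/(n−2))); p-values use a t
    reference with n−2 degrees of freedom. The intercept estimates average
    directional pleiotropy; the slope is the causal effect under InSIDE.
    """
    j = hset.n_snp
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    sign = np.where(hset.beta_exposure < 0, -1.0, 1.0)
    bx = sign * hset.beta_exposure
    by = sign * hset.beta_outcome
    sy = hset.se_outcome
    w = 1.0 / sy**2

    # closed-form 2-parameter WLS (intercept, slope)
    sw = w.sum()
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        raise InputError("degenerate exposure effects: Egger design is singular")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    df = j - 2
    scale = max(1.0, math.sqrt(q / df))
    se_slope = math.sqrt(sw / det) * scale
    se_int = math.sqrt(swxx / det) * scale
    p_slope = 2 * stats.t.sf(abs(slope / se_slope), df)
    p_int = 2 * stats.t.sf(abs(intercept / se_int), df)
    p_h = float(stats.chi2.sf(q, df))

    est = MREstimate(
        method="egger_slope", beta=float(slope), se=se_slope, pval=float(p_slope), n_snp=j
    )
    pleio = PleiotropyResult(
        intercept=float(intercept), intercept_se=se_int, p_intercept=float(p_int)
    )
    return est, pleio, HeterogeneityResult(Q=q, df=df, p_h=p_h)


def _weighted_median_core(theta: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Interpolated weighted median along the last axis.

    ``theta`` and ``weights`` are (..., J); weights need not be normalized.
    The estimate interpolates the sorted ratios at cumulative midpoint
    positions p_j = S_j − w_j/2 evaluated at 0.5.
    """
    theta = np.atleast_2d(theta)
    weights = np.atleast_2d(weights)
    order = np.argsort(theta, axis=-1)
    th = np.take_along_axis(theta, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    w = w / w.sum(axis=-1, keepdims=True)
    cum = np.cumsum(w, axis=-1)
    pos = cum - w / 2.0
    out = np.empty(th.shape[0])
    for i in range(th.shape[0]):
        out[i] = np.interp(0.5, pos[i], th[i])
    return out


def weighted_median(
    hset: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median of per-instrument Wald ratios.

    Ratios θ_j = β_Yj/β_Xj carry weights w_j = β_Xj²/se_Yj² (the inverse
    variance of θ_j to first order, non-penalized form). The estimate is the
    interpolated weighted 50% quantile, consistent when at least half the
    weight comes from valid instruments. The SE is the sample SD of the
    estimate over ``n_boot`` parametric-bootstrap replicates drawing
    β*_Xj ~ N(β_Xj, se_Xj) and β*_Yj ~ N(β_Yj, se_Yj); ``seed`` makes the
    bootstrap reproducible.
    """
    j = hset.n_snp
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 instruments")
    if seed is None:
        raise InputError("weighted_median requires an explicit bootstrap seed")
    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome
    if (bx == 0).any():
        raise UndefinedRatioError("zero exposure effect produces an undefined ratio")
    theta = by / bx
    w = bx**2 / sy**2
    estimate = float(_weighted_median_core(theta, w)[0])

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_boot, j))
    by_s = rng.normal(by, sy, size=(n_boot, j))
    bx_s = np.where(bx_s == 0, np.finfo(float).tiny, bx_s)
    reps = _weighted_median_core(by_s / bx_s, bx_s**2 / sy**2)
    se = float(np.std(reps, ddof=1))
    p = 2 * stats.norm.sf(abs(estimate / se)) if se > 0 else float("nan")
    return MREstimate(
        method="weighted_median", beta=estimate, se=se, pval=float(p), n_snp=j
    )


def leave_one_out(
    hset: HarmonizedInstrumentSet,
    effects_model: str = "multiplicative_random",
) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated with each instrument removed in turn.

    Flags instruments that single-handedly drive the pooled estimate; with
    two instruments each fit degenerates to the remaining Wald ratio.
    """
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out requires at least 2 instruments")
    results = []
    for i, vid in enumerate(hset.variant_ids):
        mask = np.ones(hset.n_snp, dtype=bool)
        mask[i] = False
        est, _ = ivw(hset.subset(mask), effects_model=effects_model)
        results.append((vid, est))
    return results
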