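"""MR-PRESSO: pleiotropy residual sum and outlier test.

A Monte-Carlo test of horizontal pleiotropy. The observed residual sum of
squares (each instrument's weighted squared deviation from the leave-itself-out
IVW slope) is compared with its distribution under a simulated null in which
every instrument is valid; instruments whose own residual is extreme are
flagged as outliers, the IVW estimate is recomputed without them, and a
distortion test asks whether the correction moved the estimate more than
removing the same number of random instruments would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, ivw
from .exceptions import DegenerateCorrectionError, InputError, InsufficientInstrumentsError
from .sumstats import HarmonizedInstrumentSet


@dataclass
class PressoResult:
    """Global test, per-variant outliers, corrected estimate and distortion test.

    ``p_global`` is the add-one empirical p-value (never below 1/(n_sim+1)).
    ``estimate_corrected`` and ``p_distortion`` are present only when at least
    one outlier was flagged — mirroring the "NA" convention of reports with no
    outliers to remove.
    """

    rss_observed: float
    p_global: float
    outliers: list[tuple[str, float]]
    estimate_raw: MREstimate
    estimate_corrected: MREstimate | None
    p_distortion: float | None
    n_sim: int
    seed: int


def _loo_slopes(w: np.ndarray, bx: np.ndarray, by: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW slopes, vectorized over leading axes.

    ``bx``/``by`` are (..., J); returns θ_(−j) with the same shape.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    alpha_outlier: float = 0.05,
    seed: int | None = None,
    effects_model: str = "multiplicative_random",
    n_distortion: int = 1000,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized set.

    Procedure: (1) RSS_obs = Σ_j w_j (β_Yj − θ_(−j) β_Xj)² with w_j = 1/se_Yj²
    and θ_(−j) the leave-j-out IVW slope; (2) ``n_sim`` null datasets are drawn
    as β*_Xj ~ N(β_Xj, se_Xj) (betas held fixed when exposure SEs are absent)
    and β*_Yj ~ N(θ_(−j)·β_Xj, se_Yj), and the full RSS recomputed on each;
    p_global = (1 + #{RSS* ≥ RSS_obs}) / (1 + n_sim); (3) each variant's
    observed weighted residual is compared against its simulated distribution
    and Bonferroni-adjusted by n_snp; variants below ``alpha_outlier`` are
    flagged; (4) the corrected estimate is IVW on unflagged variants;
    (5) the distortion p compares the raw→corrected slope shift against slopes
    under random removal of the same number of variants.

    All randomness flows from ``seed`` (mandatory); the result is bit-identical
    across runs with identical inputs.
    """
    j = hset.n_snp
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 instruments")
    if n_sim < 100:
        raise InputError("n_sim must be at least 100")
    if seed is None:
        raise InputError("presso requires an explicit seed")

    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(w, bx, by)
    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    have_sx = bool(np.all(np.isfinite(sx)) and np.all(sx > 0))
    if have_sx:
        bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    else:
        bx_sim = np.broadcast_to(bx, (n_sim, j)).copy()
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    theta_sim = _loo_slopes(w, bx_sim, by_sim)
    resid_sim = w * (by_sim - theta_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=-1)

    p_global = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    p_out = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (1 + n_sim)
    p_bonf = np.minimum(1.0, p_out * j)
    flagged = p_bonf < alpha_outlier

    estimate_raw, _ = ivw(hset, effects_model=effects_model)
    outliers = [
        (vid, float(p)) for vid, p, f in zip(hset.variant_ids, p_bonf, flagged) if f
    ]

    estimate_corrected: MREstimate | None = None
    p_distortion: float | None = None
    if flagged.any():
        if flagged.all():
            raise DegenerateCorrectionError("every instrument flagged as an outlier")
        estimate_corrected, _ = ivw(hset.subset(~flagged), effects_model=effects_model)
        estimate_corrected.method = "presso_corrected"
        if hset.outcome_trait_type == "binary":
            estimate_corrected.with_or()

        n_out = int(flagged.sum())
        d_obs = estimate_corrected.beta - estimate_raw.beta
        sxx_all = float(np.sum(w * bx * bx))
        sxy_all = float(np.sum(w * bx * by))
        d_null = np.empty(n_distortion)
        for b in range(n_distortion):
            drop = rng.choice(j, size=n_out, replace=False)
            sxx = sxx_all - float(np.sum(w[drop] * bx[drop] ** 2))
            sxy = sxy_all - float(np.sum(w[drop] * bx[drop] * by[drop]))
            d_null[b] = sxy / sxx - estimate_raw.beta
        p_distortion = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_distortion)
        )

    if hset.outcome_trait_type == "binary":
        estimate_raw.with_or()
    return PressoResult(
        rss_observed=rss_obs,
        p_global=p_global,
        outliers=outliers,
        estimate_raw=estimate_raw,
        estimate_corrected=estimate_corrected,
        p_distortion=p_distortion,
        n_sim=n_sim,
        seed=seed,
    )
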