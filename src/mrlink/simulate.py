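"""Synthetic GWAS summary statistics with known ground truth.

Three generators cover every pipeline stage:

* :func:`simulate_two_sample` — per-variant exposure/outcome effect pairs under
  a linear causal model with configurable horizontal pleiotropy, for
  validating the univariable estimators and MR-PRESSO;
* :func:`simulate_region` — LD-structured regional z-scores with shared or
  distinct causal variants, for colocalization;
* :func:`simulate_mediation` — an exposure→mediator→outcome effect chain with
  known path coefficients, for the mediation pipeline.

Summary statistics are simulated directly (no individual-level genotypes):
the pipeline consumes only summary data, and desk-scale testing needs speed.
Every generator is bit-reproducible under a fixed seed; per-table substreams
are derived deterministically from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import RegionSumstats
from .exceptions import ConfigError
from .sumstats import STANDARD_COLUMNS, SumstatsTable

#: Non-palindromic default allele coding for synthetic variants.
_DEFAULT_ALLELES = ("A", "G")


@dataclass
class PleiotropyConfig:
    """Horizontal-pleiotropy settings for the two-sample generator.

    A ``fraction_invalid`` share of instruments receive a direct effect on the
    outcome drawn from N(mean_alpha, sd_alpha); ``balanced`` forces the mean
    to zero (balanced pleiotropy, InSIDE-respecting), otherwise the offsets
    are directional.
    """

    fraction_invalid: float = 0.0
    mean_alpha: float = 0.0
    sd_alpha: float = 0.0
    balanced: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_invalid <= 1.0:
            raise ConfigError("fraction_invalid must lie in [0, 1]")


@dataclass
class SimConfig:
    """Two-sample scenario: J instruments, true effect theta, noise levels.

    Defaults are the calibration conditions used throughout the test suite:
    50 instruments with true effects N(0.15, 0.08²) (per-variant F well above
    the weak-instrument bar), exposure sampling SE 0.01, outcome sampling SE
    0.05, no pleiotropy, causal effect 0.3.
    """

    J: int = 50
    theta: float = 0.3
    beta_x_dist: tuple[float, float] = (0.15, 0.08)
    se_x: float | Sequence[float] = 0.01
    se_y: float | Sequence[float] = 0.05
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ConfigError("J must be at least 1")
        if np.any(np.asarray(self.se_x) <= 0) or np.any(np.asarray(self.se_y) <= 0):
            raise ConfigError("sampling SEs must be positive")


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _make_table(
    trait_name: str,
    trait_type: str,
    variant_ids: Sequence[str],
    beta: np.ndarray,
    se: np.ndarray,
    eaf: np.ndarray,
    alleles: list[tuple[str, str]],
    n: float | None = None,
) -> SumstatsTable:
    df = pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "chrom": "1",
            "pos": np.arange(1, len(variant_ids) + 1) * 100_000,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": np.nan if n is None else n,
        },
        columns=list(STANDARD_COLUMNS),
    )
    return SumstatsTable(trait_name, trait_type, df)


def simulate_two_sample(
    config: SimConfig,
) -> tuple[SumstatsTable, SumstatsTable, dict]:
    """Draw one two-sample MR dataset.

    True instrument effects b_j ~ N(*beta_x_dist*); invalid instruments get a
    pleiotropy offset α_j; observed effects are β_Xj ~ N(b_j, se_x) and
    β_Yj ~ N(θ·b_j + α_j, se_y). Returns (exposure table, outcome table,
    truth record) where the truth record carries θ, b, α and the invalid
    index set.
    """
    ss = np.random.SeedSequence(config.seed)
    s_truth, s_x, s_y = ss.spawn(3)
    rng_t = np.random.default_rng(s_truth)
    rng_x = np.random.default_rng(s_x)
    rng_y = np.random.default_rng(s_y)

    j = config.J
    b = rng_t.normal(config.beta_x_dist[0], config.beta_x_dist[1], size=j)
    alpha = np.zeros(j)
    pl = config.pleiotropy
    n_invalid = int(round(pl.fraction_invalid * j))
    invalid_idx = np.sort(rng_t.choice(j, size=n_invalid, replace=False))
    if n_invalid:
        mean_a = 0.0 if pl.balanced else pl.mean_alpha
        alpha[invalid_idx] = rng_t.normal(mean_a, pl.sd_alpha, size=n_invalid)
    eaf = rng_t.uniform(0.05, 0.95, size=j)
    alleles = [_DEFAULT_ALLELES] * j
    n_pal = int(round(config.palindromic_fraction * j))
    if n_pal:
        pal_idx = rng_t.choice(j, size=n_pal, replace=False)
        for i in pal_idx:
            alleles[i] = ("A", "T")

    se_x = np.broadcast_to(np.asarray(config.se_x, dtype=float), (j,))
    se_y = np.broadcast_to(np.asarray(config.se_y, dtype=float), (j,))
    beta_x = rng_x.normal(b, se_x)
    beta_y = rng_y.normal(config.theta * b + alpha, se_y)

    vids = [f"rs{100000 + i}" for i in range(j)]
    exposure = _make_table("exposure", "continuous", vids, beta_x, se_x, eaf, alleles)
    outcome = _make_table("outcome", "binary", vids, beta_y, se_y, eaf, alleles)
    truth = {
        "theta": config.theta,
        "beta_true": b,
        "alpha": alpha,
        "invalid_idx": invalid_idx,
        "seed": config.seed,
    }
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# Regional data for colocalization
# ---------------------------------------------------------------------------


@dataclass
class RegionSimConfig:
    """Regional scenario: M variants under AR(1) LD with chosen causal layout.

    ``causal_config`` is one of ``shared`` (one causal variant for both
    traits), ``distinct`` (one per trait, far apart), ``trait1_only``, or
    ``none``. Defaults give |z| ≈ 10 at the causal variant
    (effect 0.1 SD at n = 10 000).
    """

    M: int = 200
    rho: float = 0.9
    causal_config: str = "shared"
    effect1: float = 0.1
    effect2: float = 0.1
    n1: int = 10_000
    n2: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ConfigError("|rho| must be < 1")
        if self.M < 1:
            raise ConfigError("M must be at least 1")
        if self.causal_config not in ("shared", "distinct", "trait1_only", "none"):
            raise ConfigError(f"unknown causal_config {self.causal_config!r}")


def ar1_ld(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix Σ_ij = rho^|i−j| (positive definite for |rho|<1)."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_region(config: RegionSimConfig) -> RegionSumstats:
    """Draw marginal regional z-scores for two traits under shared LD.

    With LD correlation Σ and a causal non-centrality vector λ (zero except
    λ = effect·sqrt(n) at the causal index), each trait's marginal z-vector is
    drawn MVN(Σλ, Σ); betas and SEs are backed out at the stated sample sizes
    (se = 1/sqrt(n), beta = z·se, i.e. standardized per-SD effects).
    """
    ss = np.random.SeedSequence(config.seed)
    rng1, rng2 = (np.random.default_rng(s) for s in ss.spawn(2))
    m = config.M
    sigma = ar1_ld(m, config.rho)
    chol = np.linalg.cholesky(sigma)

    def causal_indices() -> tuple[int | None, int | None]:
        c = config.causal_config
        if c == "shared":
            return m // 2, m // 2
        if c == "distinct":
            return m // 4, (3 * m) // 4
        if c == "trait1_only":
            return m // 2, None
        return None, None

    c1, c2 = causal_indices()

    def draw(rng, causal, effect, n):
        lam = np.zeros(m)
        if causal is not None:
            lam[causal] = effect * np.sqrt(n)
        z = sigma @ lam + chol @ rng.standard_normal(m)
        se = np.full(m, 1.0 / np.sqrt(n))
        return z * se, se

    beta1, se1 = draw(rng1, c1, config.effect1, config.n1)
    beta2, se2 = draw(rng2, c2, config.effect2, config.n2)
    vids = [f"rs{200000 + i}" for i in range(m)]
    return RegionSumstats(
        variant_ids=vids, beta1=beta1, se1=se1, beta2=beta2, se2=se2
    )


# ---------------------------------------------------------------------------
# Mediation chain
# ---------------------------------------------------------------------------


@dataclass
class MediationSimConfig:
    """Exposure→mediator→outcome chain with known path coefficients.

    The exposure acts on the outcome directly (``theta_direct``) and through
    the mediator (``theta_xm · theta_my``); the implied total effect is
    ``theta_direct + theta_xm·theta_my`` and the true proportion mediated is
    the ratio of the indirect to the total effect. Defaults match the worked
    chain used in the tests (0.6, −0.4, −0.1 → proportion ≈ 0.706).
    """

    theta_xm: float = 0.6
    theta_my: float = -0.4
    theta_direct: float = -0.1
    J_exposure: int = 50
    J_mediator: int = 50
    beta_dist: tuple[float, float] = (0.15, 0.05)
    se_x: float = 0.01
    se_m: float = 0.02
    se_y: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.theta_direct + self.theta_xm * self.theta_my
        if total == 0:
            raise ConfigError("total effect is zero: proportion mediated undefined")
        if min(self.se_x, self.se_m, self.se_y) <= 0:
            raise ConfigError("sampling SEs must be positive")

    @property
    def truth(self) -> dict:
        total = self.theta_direct + self.theta_xm * self.theta_my
        indirect = self.theta_xm * self.theta_my
        return {
            "theta_xm": self.theta_xm,
            "theta_my": self.theta_my,
            "theta_direct": self.theta_direct,
            "theta_total": total,
            "theta_indirect": indirect,
            "proportion_mediated": indirect / total,
        }


def simulate_mediation(
    config: MediationSimConfig,
) -> tuple[SumstatsTable, SumstatsTable, SumstatsTable, dict]:
    """Draw one mediation dataset (exposure, mediator, outcome tables, truth).

    The exposure has its own instruments (effects b_x); the mediator has an
    independent instrument set (effects b_m) plus induced effects
    theta_xm·b_x at the exposure's instruments; outcome effects are
    (theta_direct + theta_xm·theta_my)·b_x at exposure instruments and
    theta_my·b_m at mediator instruments. All three tables cover the union of
    variants, so univariable and multivariable fits can be harmonized from
    the same files.
    """
    ss = np.random.SeedSequence(config.seed)
    s_truth, s_x, s_m, s_y = ss.spawn(4)
    rng_t = np.random.default_rng(s_truth)
    rng_x = np.random.default_rng(s_x)
    rng_m = np.random.default_rng(s_m)
    rng_y = np.random.default_rng(s_y)

    jx, jm = config.J_exposure, config.J_mediator
    j = jx + jm
    mu, sd = config.beta_dist
    b_x = rng_t.normal(mu, sd, size=jx)
    b_m = rng_t.normal(mu, sd, size=jm)

    true_exp = np.concatenate([b_x, np.zeros(jm)])
    true_med = np.concatenate([config.theta_xm * b_x, b_m])
    true_out = np.concatenate(
        [
            (config.theta_direct + config.theta_xm * config.theta_my) * b_x,
            config.theta_my * b_m,
        ]
    )
    se_x = np.full(j, config.se_x)
    se_m = np.full(j, config.se_m)
    se_y = np.full(j, config.se_y)
    obs_exp = rng_x.normal(true_exp, se_x)
    obs_med = rng_m.normal(true_med, se_m)
    obs_out = rng_y.normal(true_out, se_y)

    eaf = rng_t.uniform(0.05, 0.95, size=j)
    alleles = [_DEFAULT_ALLELES] * j
    vids = [f"rsX{300000 + i}" for i in range(jx)] + [f"rsM{400000 + i}" for i in range(jm)]
    exposure = _make_table("exposure", "continuous", vids, obs_exp, se_x, eaf, alleles)
    mediator = _make_table("mediator", "continuous", vids, obs_med, se_m, eaf, alleles)
    outcome = _make_table("outcome", "binary", vids, obs_out, se_y, eaf, alleles)
    truth = dict(config.truth, seed=config.seed,
                 exposure_instruments=vids[:jx], mediator_instruments=vids[jx:])
    return exposure, mediator, outcome, truth
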