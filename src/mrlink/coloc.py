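"""Bayesian colocalization of two traits in one genomic region.

Under the one-causal-variant-per-trait assumption, each variant's evidence of
association with each trait is summarized by a Wakefield approximate Bayes
factor, and five hypotheses are enumerated:

* H0 — no association with either trait;
* H1 / H2 — association with trait 1 / trait 2 only;
* H3 — both traits associated, two distinct causal variants;
* H4 — both traits associated, one shared causal variant.

PP4 (the posterior probability of H4) is the usual "colocalization
probability". All hypothesis arithmetic is in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import InputError

#: Field-standard per-configuration prior probabilities.
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
#: Default prior SD on the causal effect, by trait type.
DEFAULT_PRIOR_SD = {"continuous": 0.2, "binary": 0.15}


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one variant, one trait.

    With z = beta/se, V = se², W = prior_sd² and shrinkage r = W/(V+W)::

        log ABF = 0.5·(log(1 − r) + r·z²)

    Positive values favour association over the null; at z = 0 the value is
    negative (the prior penalizes an uninformative signal), and it tends to 0
    as the prior SD shrinks to zero.
    """
    if np.any(np.asarray(se) <= 0):
        raise InputError("se must be positive")
    if prior_sd <= 0:
        raise InputError("prior_sd must be positive")
    z = np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    r = prior_sd**2 / (v + prior_sd**2)
    return 0.5 * (np.log1p(-r) + r * z**2)


@dataclass
class RegionSumstats:
    """Two traits' summary statistics over a shared, ordered variant list."""

    variant_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait_types: tuple[str, str] = ("continuous", "continuous")
    priors: tuple[float, float, float] = DEFAULT_PRIORS
    prior_sd: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("beta1", "se1", "beta2", "se2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        m = len(self.variant_ids)
        if any(len(getattr(self, a)) != m for a in ("beta1", "se1", "beta2", "se2")):
            raise InputError("per-trait arrays must match the variant list length")
        if (self.se1 <= 0).any() or (self.se2 <= 0).any():
            raise InputError("all standard errors must be positive")
        p1, p2, p12 = self.priors
        if min(p1, p2, p12) <= 0 or p1 + p2 + p12 >= 1:
            raise InputError("priors must be positive with p1+p2+p12 < 1")
        if self.prior_sd is None:
            self.prior_sd = (
                DEFAULT_PRIOR_SD[self.trait_types[0]],
                DEFAULT_PRIOR_SD[self.trait_types[1]],
            )


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities and per-variant log Bayes factors."""

    pp: tuple[float, float, float, float, float]
    labf1: np.ndarray = field(repr=False)
    labf2: np.ndarray = field(repr=False)
    n_variants: int = 0

    @property
    def pp4(self) -> float:
        return self.pp[4]


def colocalize(region: RegionSumstats) -> ColocResult:
    """Enumerate the five colocalization hypotheses over a region.

    With per-variant log ABFs L1_j, L2_j and priors (p1, p2, p12), the
    unnormalized log hypothesis masses are::

        H0: 0
        H1: log p1 + logsumexp_j L1_j
        H2: log p2 + logsumexp_j L2_j
        H3: log p1 + log p2 + log( Σ_{j≠k} exp(L1_j + L2_k) )
        H4: log p12 + logsumexp_j (L1_j + L2_j)

    The H3 cross-sum is computed as the stable log-difference
    a + log1p(−exp(b − a)) with a = lse(L1) + lse(L2) and b = lse(L1 + L2);
    a single-variant region makes H3 impossible (mass exactly 0).
    The five posteriors are the softmax of the masses and sum to one.
    """
    if len(region.variant_ids) < 1:
        raise InputError("region must contain at least one variant")
    p1, p2, p12 = region.priors
    sd1, sd2 = region.prior_sd
    l1 = np.asarray(log_abf(region.beta1, region.se1, sd1))
    l2 = np.asarray(log_abf(region.beta2, region.se2, sd2))

    lse1 = float(logsumexp(l1))
    lse2 = float(logsumexp(l2))
    lse12 = float(logsumexp(l1 + l2))

    h0 = 0.0
    h1 = math.log(p1) + lse1
    h2 = math.log(p2) + lse2
    h4 = math.log(p12) + lse12
    a = lse1 + lse2
    b = lse12
    if len(region.variant_ids) == 1 or b >= a:
        # single variant (or numerically indistinguishable): no distinct-pair mass
        h3 = -np.inf
    else:
        h3 = math.log(p1) + math.log(p2) + a + math.log1p(-math.exp(b - a))

    masses = np.array([h0, h1, h2, h3, h4])
    pp = np.exp(masses - logsumexp(masses))
    pp = pp / pp.sum()
    return ColocResult(pp=tuple(float(x) for x in pp), labf1=l1, labf2=l2,
                       n_variants=len(region.variant_ids))


def coloc_decision(result: ColocResult, threshold: float = 0.70) -> str:
    """Call the region colocalized iff PP4 strictly exceeds ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise InputError("threshold must lie in (0, 1)")
    return "colocalized" if result.pp4 > threshold else "not_colocalized"
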