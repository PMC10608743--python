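"""Multivariable MR and two-step mediation analysis.

The mediation pipeline asks how much of an exposure's total effect on an
outcome flows through a candidate mediator:

1. screen many candidate mediators with two univariable MR steps
   (exposure→mediator, mediator→outcome), each controlled at FDR < 0.05
   by Benjamini–Hochberg;
2. for each surviving mediator, fit a two-exposure multivariable MR of the
   outcome on (mediator, exposure) to get the mediator's adjusted effect (β2)
   and the exposure's direct effect (βdirect);
3. form the indirect effect by difference of coefficients
   (βindirect = βtotal − βdirect) and the proportion mediated
   (βindirect/βtotal), with first-order delta-method standard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import Z95, MREstimate, ivw
from .exceptions import CollinearityError, InputError, UndefinedRatioError
from .sumstats import HarmonizedInstrumentSet, LdMatrix, SumstatsTable, harmonize, select_instruments

logger = logging.getLogger(__name__)


@dataclass
class MvmrInput:
    """Joint per-variant design for K exposures against one outcome."""

    variant_ids: list[str]
    beta_exposures: np.ndarray  # (n_variants, K)
    se_exposures: np.ndarray  # (n_variants, K)
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_names: list[str]

    def __post_init__(self) -> None:
        self.beta_exposures = np.atleast_2d(np.asarray(self.beta_exposures, dtype=float))
        self.se_exposures = np.atleast_2d(np.asarray(self.se_exposures, dtype=float))
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        n, k = self.beta_exposures.shape
        if k < 2:
            raise InputError("multivariable MR requires at least 2 exposures")
        if n <= k:
            raise InputError("multivariable MR requires more variants than exposures")
        if len(set(self.variant_ids)) != n:
            raise InputError("duplicate variants in MVMR input")
        if (self.se_outcome <= 0).any():
            raise InputError("outcome standard errors must be positive")


def mvmr_ivw(mv: MvmrInput) -> list[MREstimate]:
    """Multivariable IVW: WLS of β_Y on the K exposure-beta columns, no intercept.

    Weights are 1/se_Yj². Standard errors carry the multiplicative
    overdispersion scale max(1, sqrt(Q/(n−K))); p-values use a normal
    reference. A rank-deficient design raises
    :class:`~mrlink.exceptions.CollinearityError` naming the redundant
    exposures.
    """
    x = mv.beta_exposures
    y = mv.beta_outcome
    w = 1.0 / mv.se_outcome**2
    n, k = x.shape
    sw = np.sqrt(w)
    xw = x * sw[:, None]
    rank = np.linalg.matrix_rank(xw)
    if rank < k:
        # name exposures whose removal leaves the rank unchanged
        offending = [
            name
            for i, name in enumerate(mv.exposure_names)
            if np.linalg.matrix_rank(np.delete(xw, i, axis=1)) == rank
        ]
        raise CollinearityError(
            f"rank-deficient MVMR design; collinear exposures: {offending or mv.exposure_names}"
        )
    xtwx = xw.T @ xw
    xtwy = xw.T @ (y * sw)
    coefs = np.linalg.solve(xtwx, xtwy)
    resid = y - x @ coefs
    q = float(np.sum(w * resid**2))
    df = n - k
    scale = max(1.0, math.sqrt(q / df))
    cov = np.linalg.inv(xtwx) * scale**2
    ses = np.sqrt(np.diag(cov))
    out = []
    for name, b, s in zip(mv.exposure_names, coefs, ses):
        p = 2 * stats.norm.sf(abs(b / s))
        out.append(
            MREstimate(method=f"mvmr_ivw[{name}]", beta=float(b), se=float(s),
                       pval=float(p), n_snp=n)
        )
    return out


# ---------------------------------------------------------------------------
# Two-step mediator screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Per-mediator screen statistics and the surviving candidate set."""

    table: pd.DataFrame  # mediator, beta1, p1, q1, pass1, beta2, p2, q2, pass2
    selected: list[str]
    skipped: dict[str, str]


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values (q-values); monotone, q >= p."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def two_step_screen(
    exposure: SumstatsTable,
    exposure_instruments: Sequence[str],
    mediators: Mapping[str, SumstatsTable],
    outcome: SumstatsTable,
    fdr_threshold: float = 0.05,
    mediator_p_threshold: float = 5e-6,
    ld: LdMatrix | None = None,
    r2_threshold: float = 0.01,
    drop_palindromic: bool = True,
) -> ScreenResult:
    """Two-step MR screen of candidate mediators.

    Step 1 estimates exposure→mediator by univariable IVW for every mediator
    and applies BH across them; step 2 estimates mediator→outcome (each
    mediator instrumented by its own variants at ``mediator_p_threshold``)
    for the step-1 survivors and applies BH again. The final candidates pass
    both steps at ``fdr_threshold``. Mediators that cannot be harmonized or
    instrumented are skipped with a logged reason, never silently dropped.
    """
    rows = []
    skipped: dict[str, str] = {}
    for name, med in mediators.items():
        try:
            h1 = harmonize(exposure, med, exposure_instruments,
                           drop_palindromic=drop_palindromic)
            est1, _ = ivw(h1)
        except Exception as exc:  # noqa: BLE001 - reason recorded, not swallowed
            skipped[name] = f"step1: {exc}"
            logger.warning("mediator %s skipped at step 1: %s", name, exc)
            continue
        rows.append({"mediator": name, "beta1": est1.beta, "se1": est1.se, "p1": est1.pval})
    tab = pd.DataFrame(rows, columns=["mediator", "beta1", "se1", "p1"])
    if not tab.empty:
        tab["q1"] = benjamini_hochberg(tab["p1"])
        tab["pass1"] = tab["q1"] < fdr_threshold
    else:
        tab["q1"] = []
        tab["pass1"] = []

    tab["beta2"] = np.nan
    tab["se2"] = np.nan
    tab["p2"] = np.nan
    step2_rows = []
    for i, row in tab.iterrows():
        if not row["pass1"]:
            continue
        name = row["mediator"]
        med = mediators[name]
        try:
            instr = select_instruments(med, mediator_p_threshold, ld, r2_threshold)
            if not instr:
                raise InputError("no instruments pass the mediator p threshold")
            h2 = harmonize(med, outcome, instr, drop_palindromic=drop_palindromic)
            est2, _ = ivw(h2)
        except Exception as exc:  # noqa: BLE001
            skipped[name] = f"step2: {exc}"
            logger.warning("mediator %s skipped at step 2: %s", name, exc)
            tab.loc[i, "pass1"] = False
            continue
        tab.loc[i, ["beta2", "se2", "p2"]] = est2.beta, est2.se, est2.pval
        step2_rows.append(i)

    tab["q2"] = np.nan
    tab["pass2"] = False
    if step2_rows:
        q2 = benjamini_hochberg(tab.loc[step2_rows, "p2"])
        tab.loc[step2_rows, "q2"] = q2
        tab.loc[step2_rows, "pass2"] = q2 < fdr_threshold
    selected = list(tab.loc[tab["pass1"] & tab["pass2"], "mediator"])
    return ScreenResult(table=tab, selected=selected, skipped=skipped)


# ---------------------------------------------------------------------------
# Mediation assembly
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with delta-method uncertainty.

    ``beta_indirect = beta_total − beta_direct`` exactly (difference of
    coefficients); ``proportion_mediated = beta_indirect / beta_total``.
    """

    beta_total: MREstimate
    beta_direct: MREstimate
    beta_indirect: float
    se_indirect: float
    proportion_mediated: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    beta1: MREstimate | None = None  # exposure -> mediator
    beta2: MREstimate | None = None  # mediator -> outcome, adjusted for exposure


def mediate(
    beta_total: MREstimate,
    beta_direct: MREstimate,
    beta1: MREstimate | None = None,
    beta2: MREstimate | None = None,
) -> MediationResult:
    """Difference-of-coefficients mediation with delta-method SEs.

    The indirect effect is βtotal − βdirect with
    se = sqrt(se_total² + se_direct²), treating the two fits as independent
    (a working assumption: the covariance between the total and direct
    estimates from separate regressions is unavailable from summary data).
    The proportion mediated is βindirect/βtotal with first-order delta SE::

        sqrt( se_ind²/βtotal² + βind²·se_total²/βtotal⁴ )

    and a symmetric 95% CI. A zero total effect leaves the proportion
    undefined and raises.
    """
    bt, st = beta_total.beta, beta_total.se
    bd, sd = beta_direct.beta, beta_direct.se
    if bt == 0:
        raise UndefinedRatioError("proportion mediated undefined for zero total effect")
    b_ind = bt - bd
    se_ind = math.sqrt(st**2 + sd**2)
    prop = b_ind / bt
    prop_se = math.sqrt(se_ind**2 / bt**2 + (b_ind**2 * st**2) / bt**4)
    ci = (prop - Z95 * prop_se, prop + Z95 * prop_se)
    return MediationResult(
        beta_total=beta_total,
        beta_direct=beta_direct,
        beta_indirect=b_ind,
        se_indirect=se_ind,
        proportion_mediated=prop,
        proportion_se=prop_se,
        proportion_ci=ci,
        beta1=beta1,
        beta2=beta2,
    )


def product_of_coefficients(beta1: MREstimate, beta2: MREstimate) -> tuple[float, float]:
    """Indirect effect as β1·β2 with delta SE; cross-check for :func:`mediate`."""
    b = beta1.beta * beta2.beta
    se = math.sqrt(beta1.beta**2 * beta2.se**2 + beta2.beta**2 * beta1.se**2)
    return b, se


def run_mediation_analysis(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    mediator: SumstatsTable,
    exposure_instruments: Sequence[str],
    mediator_p_threshold: float = 5e-6,
    ld: LdMatrix | None = None,
    r2_threshold: float = 0.01,
    drop_palindromic: bool = True,
) -> MediationResult:
    """Full single-mediator decomposition.

    βtotal and β1 come from univariable IVW (exposure→outcome and
    exposure→mediator, using the exposure's instruments); β2 and βdirect come
    from one two-exposure multivariable fit of the outcome on
    (mediator, exposure), instrumented by the union of the exposure's and the
    mediator's instruments restricted to variants present in all three tables.
    """
    h_total = harmonize(exposure, outcome, exposure_instruments,
                        drop_palindromic=drop_palindromic)
    beta_total, _ = ivw(h_total)
    h1 = harmonize(exposure, mediator, exposure_instruments,
                   drop_palindromic=drop_palindromic)
    beta1, _ = ivw(h1)

    med_instr = select_instruments(mediator, mediator_p_threshold, ld, r2_threshold)
    union = list(dict.fromkeys(list(exposure_instruments) + med_instr))
    present = [
        v
        for v in union
        if v in set(exposure.table["variant_id"])
        and v in set(mediator.table["variant_id"])
        and v in set(outcome.table["variant_id"])
    ]
    if len(present) < 3:
        raise InputError("fewer than 3 shared instruments for the multivariable fit")
    # align both regressors' effects to the exposure table's effect alleles
    h_exp_out = harmonize(exposure, outcome, present, drop_palindromic=drop_palindromic)
    h_exp_med = harmonize(exposure, mediator, present, drop_palindromic=drop_palindromic)
    common = [v for v in h_exp_out.variant_ids if v in set(h_exp_med.variant_ids)]
    io = {v: i for i, v in enumerate(h_exp_out.variant_ids)}
    im = {v: i for i, v in enumerate(h_exp_med.variant_ids)}
    idx_o = [io[v] for v in common]
    idx_m = [im[v] for v in common]
    mv = MvmrInput(
        variant_ids=common,
        beta_exposures=np.column_stack(
            [h_exp_med.beta_outcome[idx_m], h_exp_out.beta_exposure[idx_o]]
        ),
        se_exposures=np.column_stack(
            [h_exp_med.se_outcome[idx_m], h_exp_out.se_exposure[idx_o]]
        ),
        beta_outcome=h_exp_out.beta_outcome[idx_o],
        se_outcome=h_exp_out.se_outcome[idx_o],
        exposure_names=[mediator.trait_name, exposure.trait_name],
    )
    beta2, beta_direct = mvmr_ivw(mv)
    return mediate(beta_total, beta_direct, beta1=beta1, beta2=beta2)
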