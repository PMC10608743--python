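"""GWAS summary-statistics containers, I/O, harmonization and instrument selection.

The central objects are :class:`SumstatsTable` (one trait's per-variant
associations), :class:`LdMatrix` (squared-correlation structure used for
clumping) and :class:`HarmonizedInstrumentSet` (per-variant exposure/outcome
effect pairs aligned to a common effect allele — the unit every MR estimator
consumes).

Conventions: genome coordinates are 1-based; alleles are stored uppercase;
effects are per copy of the effect allele (log odds ratios for binary traits,
SD units for continuous traits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Standard internal column names, in canonical order.
STANDARD_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Column-map preset for the common exported layout.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
}

_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise InputError(f"{self.variant_id}: standard error must be positive")
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.variant_id}: identical alleles")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise InputError(f"{self.variant_id}: eaf outside [0, 1]")


@dataclass
class SumstatsTable:
    """Per-variant GWAS associations for a single trait.

    Parameters
    ----------
    trait_name
        Human-readable trait label, carried into result tables.
    trait_type
        ``"continuous"`` (effects in SD units) or ``"binary"`` (log odds).
    table
        DataFrame with the :data:`STANDARD_COLUMNS` layout, indexed 0..n-1.
        ``variant_id`` values must be unique.
    """

    trait_name: str
    trait_type: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if self.table["variant_id"].duplicated().any():
            dups = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise InputError(f"duplicate variant ids: {sorted(set(dups))[:5]}")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(
        cls, trait_name: str, trait_type: str, records: Iterable[VariantAssociation]
    ) -> "SumstatsTable":
        rows = [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele.upper(),
                "other_allele": r.other_allele.upper(),
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": np.nan if r.n is None else r.n,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(STANDARD_COLUMNS))
        return cls(trait_name, trait_type, df)

    def lookup(self, variant_id: str) -> pd.Series:
        hit = self.table[self.table["variant_id"] == variant_id]
        if hit.empty:
            from .exceptions import VariantNotFoundError

            raise VariantNotFoundError(
                f"variant {variant_id!r} not found in table {self.trait_name!r}"
            )
        return hit.iloc[0]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(
    path: str | Path,
    trait_name: str,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> SumstatsTable:
    """Read a delimited summary-statistics file into a :class:`SumstatsTable`.

    Rows failing validation (non-positive SE, malformed alleles, p-value
    outside (0, 1]) are dropped and counted in the log, not raised.

    Parameters
    ----------
    column_map
        Mapping from standard field name to the column name in the file.
        Defaults to :data:`DEFAULT_COLUMN_MAP`. Missing optional fields
        (``chrom``, ``pos``, ``eaf``, ``n``) are tolerated; missing mandatory
        fields raise :class:`~mrlink.exceptions.ConfigError`.
    sep
        Field separator; ``None`` auto-detects tab vs comma from the header.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise InputError(f"{path}: empty file")
        sep = "," if ("," in header and "\t" not in header) else "\t"
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        raise InputError(f"{path}: no data rows")
    if column_map is None:
        # identity mapping when the header already uses the standard names,
        # otherwise the common exported layout
        if all(c in raw.columns for c in _MANDATORY):
            cmap = {c: c for c in STANDARD_COLUMNS}
        else:
            cmap = dict(DEFAULT_COLUMN_MAP)
    else:
        cmap = dict(column_map)
    for std in _MANDATORY:
        col = cmap.get(std)
        if col is None or col not in raw.columns:
            raise ConfigError(f"{path}: missing mandatory column {std!r} (mapped to {col!r})")

    df = pd.DataFrame(index=raw.index)
    for std in STANDARD_COLUMNS:
        col = cmap.get(std)
        if col is not None and col in raw.columns:
            df[std] = raw[col]
        else:
            df[std] = "" if std in ("chrom",) else np.nan
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").fillna(0).astype(int)
    for c in ("eaf", "beta", "se", "pval", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()

    valid_allele = set("ACGT")
    ok = (
        df["se"].gt(0)
        & df["beta"].notna()
        & df["pval"].gt(0)
        & df["pval"].le(1)
        & df["effect_allele"].isin(valid_allele)
        & df["other_allele"].isin(valid_allele)
        & (df["effect_allele"] != df["other_allele"])
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows during validation", path, n_dropped)
    df = df.loc[ok].reset_index(drop=True)
    df = df[list(STANDARD_COLUMNS)]
    return SumstatsTable(trait_name, trait_type, df)


# ---------------------------------------------------------------------------
# LD and instrument selection
# ---------------------------------------------------------------------------


@dataclass
class LdMatrix:
    """Squared-correlation (r²) matrix over an ordered set of variants."""

    variant_ids: Sequence[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        m = self.r2
        if m.shape != (len(self.variant_ids),) * 2:
            raise InputError("LD matrix shape does not match variant list")
        if not np.allclose(m, m.T, atol=1e-8):
            raise InputError("LD matrix not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal must be 1")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise InputError("LD r² entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    def r2_between(self, a: str, b: str) -> float:
        """r² between two variants; variants absent from the panel count as unlinked."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])


def select_instruments(
    table: SumstatsTable,
    p_threshold: float,
    ld: LdMatrix | None = None,
    r2_threshold: float = 0.01,
) -> list[str]:
    """Greedy LD clumping of genome-wide associations.

    Variants with ``pval < p_threshold`` are sorted by ascending p-value
    (ties broken lexicographically by variant id, for determinism); the
    smallest-p variant is kept and every remaining variant with
    ``r² >= r2_threshold`` against it is discarded, repeatedly. Variants
    absent from the LD panel are treated as unlinked, with a logged warning.

    Returns the kept variant ids; empty (with a warning) when nothing passes
    the p-value threshold.
    """
    df = table.table
    hits = df.loc[df["pval"] < p_threshold, ["variant_id", "pval"]]
    if hits.empty:
        logger.warning(
            "%s: no variant passes p < %g; empty instrument set", table.trait_name, p_threshold
        )
        return []
    hits = hits.sort_values(["pval", "variant_id"], kind="mergesort")
    candidates = list(hits["variant_id"])
    if ld is not None:
        missing = [v for v in candidates if v not in ld._index]
        if missing:
            logger.warning(
                "%s: %d candidate variants absent from LD panel; treated as unlinked",
                table.trait_name,
                len(missing),
            )
    kept: list[str] = []
    remaining = candidates
    while remaining:
        index_variant = remaining[0]
        kept.append(index_variant)
        if ld is None:
            remaining = remaining[1:]
        else:
            # r2 == 0 never counts as linkage, so a zero threshold prunes each
            # connected LD component to its top variant rather than everything
            remaining = [
                v
                for v in remaining[1:]
                if (r := ld.r2_between(index_variant, v)) < r2_threshold or r == 0.0
            ]
    return kept


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _complement(allele: str) -> str:
    return _COMPLEMENT.get(allele, "?")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or G/C pairs: strand orientation is ambiguous in summary data."""
    return _complement(effect_allele) == other_allele


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effect pairs aligned to the exposure's effect allele.

    ``beta_exposure[j]`` and ``beta_outcome[j]`` are the j-th instrument's
    effects on exposure and outcome per copy of the same allele; all MR
    estimators consume this container.
    """

    exposure_name: str
    outcome_name: str
    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    outcome_trait_type: str = "continuous"
    n_removed_palindromic: int = 0
    n_removed_mismatch: int = 0
    n_missing_outcome: int = 0
    dropped: dict[str, str] = field(default_factory=dict)  # variant -> removal reason

    def __post_init__(self) -> None:
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise InputError("duplicate variants in harmonized set")
        if (self.se_exposure <= 0).any() or (self.se_outcome <= 0).any():
            raise InputError("all standard errors must be strictly positive")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def subset(self, mask: np.ndarray) -> "HarmonizedInstrumentSet":
        mask = np.asarray(mask, dtype=bool)
        return HarmonizedInstrumentSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            variant_ids=[v for v, m in zip(self.variant_ids, mask) if m],
            beta_exposure=self.beta_exposure[mask],
            se_exposure=self.se_exposure[mask],
            beta_outcome=self.beta_outcome[mask],
            se_outcome=self.se_outcome[mask],
            outcome_trait_type=self.outcome_trait_type,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "beta_exposure": self.beta_exposure,
                "se_exposure": self.se_exposure,
                "beta_outcome": self.beta_outcome,
                "se_outcome": self.se_outcome,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write the retained rows plus provenance rows for dropped variants."""
        df = self.to_frame()
        df["filter"] = "kept"
        if self.dropped:
            extra = pd.DataFrame(
                {"variant_id": list(self.dropped), "filter": list(self.dropped.values())}
            )
            df = pd.concat([df, extra], ignore_index=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _orient_outcome_row(
    exp_ea: str, exp_oa: str, out_ea: str, out_oa: str
) -> int | None:
    """How to align an outcome row to the exposure's alleles.

    Returns +1 (same orientation), -1 (flip outcome beta / complement eaf),
    or None (alleles unresolvable → mismatch).
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return 1
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return -1
    # retry on the complementary strand
    c_ea, c_oa = _complement(out_ea), _complement(out_oa)
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return 1
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return -1
    return None


def harmonize(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    instruments: Sequence[str],
    drop_palindromic: bool = True,
    palindromic_eaf_window: float | None = None,
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect alleles for a set of instruments.

    For each instrument present in both tables: identical allele pairs are kept
    as-is; swapped pairs have the outcome beta negated and eaf complemented;
    strand-complementary pairs are complemented then re-matched; anything else
    is a mismatch and removed. Palindromic variants (A/T, G/C) are removed when
    ``drop_palindromic`` is set, unless ``palindromic_eaf_window`` is given and
    both traits' effect-allele frequencies sit outside 0.5 ± window on the same
    side (frequency-based rescue; off by default).

    Exposure betas are left in their native orientation; estimator-level
    orientation (e.g. MR-Egger's β_X ≥ 0) is not applied here.
    """
    if not list(instruments):
        raise InputError("instrument list is empty")
    exp_idx = exposure.table.set_index("variant_id")
    out_idx = outcome.table.set_index("variant_id")

    kept_rows = []
    dropped: dict[str, str] = {}
    n_pal = n_mis = n_missing = 0
    for vid in instruments:
        if vid not in exp_idx.index:
            n_missing += 1
            dropped[vid] = "missing_in_exposure"
            continue
        if vid not in out_idx.index:
            n_missing += 1
            dropped[vid] = "missing_in_outcome"
            continue
        e = exp_idx.loc[vid]
        o = out_idx.loc[vid]
        if is_palindromic(e["effect_allele"], e["other_allele"]):
            rescued = False
            if drop_palindromic and palindromic_eaf_window is not None:
                e_eaf, o_eaf = e["eaf"], o["eaf"]
                if (
                    np.isfinite(e_eaf)
                    and np.isfinite(o_eaf)
                    and abs(e_eaf - 0.5) > palindromic_eaf_window
                    and abs(o_eaf - 0.5) > palindromic_eaf_window
                    and (e_eaf - 0.5) * (o_eaf - 0.5) > 0
                ):
                    rescued = True
            if drop_palindromic and not rescued:
                n_pal += 1
                dropped[vid] = "palindromic"
                continue
        sign = _orient_outcome_row(
            e["effect_allele"], e["other_allele"], o["effect_allele"], o["other_allele"]
        )
        if sign is None:
            n_mis += 1
            dropped[vid] = "allele_mismatch"
            continue
        kept_rows.append(
            (vid, float(e["beta"]), float(e["se"]), sign * float(o["beta"]), float(o["se"]))
        )

    if not kept_rows:
        raise InputError(
            "no variants survived harmonization: "
            f"{n_missing} missing in a table, {n_pal} palindromic, {n_mis} mismatching"
        )
    vids, bx, sx, by, sy = zip(*kept_rows)
    return HarmonizedInstrumentSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        variant_ids=list(vids),
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        outcome_trait_type=outcome.trait_type,
        n_removed_palindromic=n_pal,
        n_removed_mismatch=n_mis,
        n_missing_outcome=n_missing,
        dropped=dropped,
    )


def instrument_strength(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, float]:
    """Per-variant F statistics F_j = (β_Xj / se_Xj)² and their arithmetic mean.

    Mean F > 10 is the conventional bar against weak-instrument bias.
    """
    if hset.n_snp == 0:
        raise InputError("empty instrument set")
    f = (hset.beta_exposure / hset.se_exposure) ** 2
    return f, float(f.mean())
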