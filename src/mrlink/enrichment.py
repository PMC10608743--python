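"""Hypergeometric over-representation analysis of metabolite sets.

Given a selected set of metabolites (e.g. mediation-screen survivors) and a
library of pathways over a metabolite universe, each pathway is scored by the
upper-tail hypergeometric probability of its overlap with the selection, with
Benjamini–Hochberg adjustment across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .exceptions import InputError
from .mediation import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class PathwayLibrary:
    """Named metabolite sets over a common universe."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}
        self.universe = frozenset(self.universe)
        for name, members in self.pathways.items():
            if not members:
                raise InputError(f"pathway {name!r} is empty")
            if not members <= self.universe:
                raise InputError(f"pathway {name!r} contains metabolites outside the universe")

    @classmethod
    def from_mapping(
        cls, pathways: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None
    ) -> "PathwayLibrary":
        pw = {k: frozenset(v) for k, v in pathways.items()}
        uni = frozenset(universe) if universe is not None else frozenset().union(*pw.values())
        return cls(pw, uni)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PathwayLibrary":
        """Two-column (pathway, metabolite) TSV; universe = union of members."""
        df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "metabolite"],
                         comment="#")
        if df.empty:
            raise InputError(f"{path}: empty pathway file")
        grouped = {k: frozenset(g["metabolite"]) for k, g in df.groupby("pathway")}
        return cls.from_mapping(grouped)

    @classmethod
    def read_gmt(cls, path: str | Path) -> "PathwayLibrary":
        """GMT format: name <tab> description <tab> member..."""
        pathways: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                pathways[parts[0]] = frozenset(p for p in parts[2:] if p)
        if not pathways:
            raise InputError(f"{path}: no pathways parsed")
        return cls.from_mapping(pathways)


def ora(selected: Iterable[str], library: PathwayLibrary) -> pd.DataFrame:
    """Rank pathways by hypergeometric over-representation of ``selected``.

    For a universe of size N, pathway of size m and selection of size n with
    overlap k, p = P(X ≥ k) under sampling without replacement. Selected
    identifiers outside the universe are logged and intersected away. Returns
    a DataFrame (pathway, pathway_size, overlap, p, q) sorted by p then name.
    """
    sel = set(selected)
    if not sel:
        raise InputError("empty metabolite selection")
    stray = sel - library.universe
    if stray:
        logger.warning("%d selected metabolites outside the universe; ignored", len(stray))
        sel &= library.universe
    if not sel:
        raise InputError("no selected metabolites remain inside the universe")
    n_universe = len(library.universe)
    n_sel = len(sel)
    rows = []
    for name in sorted(library.pathways):
        members = library.pathways[name]
        k = len(sel & members)
        m = len(members)
        p = float(hypergeom.sf(k - 1, n_universe, m, n_sel))
        rows.append({"pathway": name, "pathway_size": m, "overlap": k, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = benjamini_hochberg(df["p"])
    df = df.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    return df
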