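"""Study orchestration: forward MR, bidirectional MR, colocalization,
mediator screen, enrichment and per-mediator mediation behind one config.

A study is described by a YAML config naming trait files (exposures,
outcomes, mediators), thresholds and analysis toggles. ``run_full_study``
executes every configured stage, writes tidy TSV outputs, and records a JSON
manifest with per-stage row counts, failures and sha256 checksums of every
output — reruns with the same config and seeds are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import RegionSumstats, coloc_decision, colocalize
from .enrichment import PathwayLibrary, ora
from .estimators import ivw, leave_one_out, mr_egger, wald_ratio, weighted_median
from .exceptions import ConfigError, InsufficientInstrumentsError, MrlinkError
from .mediation import run_mediation_analysis, two_step_screen
from .presso import presso
from .simulate import _make_table
from .sumstats import (
    LdMatrix,
    SumstatsTable,
    harmonize,
    instrument_strength,
    read_sumstats,
    select_instruments,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class TraitSpec:
    """One named trait entry in the study config."""

    name: str
    file: str
    trait_type: str = "continuous"
    p_threshold: float = 5e-8
    column_map: dict | None = None

    def load(self, base: Path) -> SumstatsTable:
        path = Path(self.file)
        if not path.is_absolute():
            path = base / path
        return read_sumstats(path, self.name, self.trait_type, column_map=self.column_map)


@dataclass
class StudyConfig:
    """Declarative study description (see :func:`load_config`)."""

    exposures: list[TraitSpec]
    outcomes: list[TraitSpec]
    mediators: list[TraitSpec] = field(default_factory=list)
    seed: int = 0
    r2_threshold: float = 0.01
    fdr_threshold: float = 0.05
    coloc_threshold: float = 0.70
    ld_file: str | None = None
    presso_enabled: bool = True
    bidirectional_enabled: bool = True
    single_variant: str | None = None
    coloc_regions: list[dict] = field(default_factory=list)
    mediation: list[str] = field(default_factory=list)
    pathways_file: str | None = None
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold <= 1):
            raise ConfigError("r2 threshold must lie in (0, 1]")
        if not (0 < self.fdr_threshold <= 1):
            raise ConfigError("fdr threshold must lie in (0, 1]")
        if not (0 < self.coloc_threshold < 1):
            raise ConfigError("coloc posterior threshold must lie in (0, 1)")
        for spec in [*self.exposures, *self.outcomes, *self.mediators]:
            path = Path(spec.file)
            if not path.is_absolute():
                path = self.base_dir / path
            if not path.exists():
                raise ConfigError(f"trait file does not exist: {path}")


def load_config(path: str | Path) -> StudyConfig:
    """Parse and validate a YAML study config."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")

    def traits(key: str) -> list[TraitSpec]:
        return [TraitSpec(**entry) for entry in raw.get(key, [])]

    thresholds = raw.get("thresholds", {})
    analyses = raw.get("analyses", {})
    return StudyConfig(
        exposures=traits("exposures"),
        outcomes=traits("outcomes"),
        mediators=traits("mediators"),
        seed=int(raw.get("seed", 0)),
        r2_threshold=float(thresholds.get("r2", 0.01)),
        fdr_threshold=float(thresholds.get("fdr", 0.05)),
        coloc_threshold=float(thresholds.get("coloc_pp4", 0.70)),
        ld_file=raw.get("ld_file"),
        presso_enabled=bool(analyses.get("presso", True)),
        bidirectional_enabled=bool(analyses.get("bidirectional", True)),
        single_variant=analyses.get("single_variant"),
        coloc_regions=list(analyses.get("coloc_regions", [])),
        mediation=list(analyses.get("mediation", [])),
        pathways_file=analyses.get("pathways_file"),
        base_dir=path.parent,
    )


def _pair_seed(base_seed: int, tag: str) -> int:
    """Stable per-analysis substream seed below 2^31."""
    h = hashlib.sha256(f"{base_seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _load_ld(config: StudyConfig) -> LdMatrix | None:
    if config.ld_file is None:
        return None
    path = Path(config.ld_file)
    if not path.is_absolute():
        path = config.base_dir / path
    return LdMatrix.read_tsv(path)


def _estimate_row(exposure, outcome, est, het=None, egger_p=None, presso_p=None,
                  mean_f=math.nan):
    binary = outcome.trait_type == "binary"
    if binary:
        est.with_or()
    return {
        "exposure": exposure.trait_name,
        "outcome": outcome.trait_name,
        "method": est.method,
        "n_snp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pval": est.pval,
        "or": est.or_scale[0] if binary else math.nan,
        "or_ci_low": est.or_scale[1] if binary else math.nan,
        "or_ci_high": est.or_scale[2] if binary else math.nan,
        "Q": het.Q if het else math.nan,
        "p_h": het.p_h if het else math.nan,
        "egger_intercept_p": math.nan if egger_p is None else egger_p,
        "presso_p_global": math.nan if presso_p is None else presso_p,
        "mean_F": mean_f,
    }


def _mr_pair(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    p_threshold: float,
    ld: LdMatrix | None,
    r2_threshold: float,
    seed: int,
    presso_enabled: bool,
) -> list[dict]:
    """All estimators for one exposure→outcome pair; one output row per method."""
    instruments = select_instruments(exposure, p_threshold, ld, r2_threshold)
    if not instruments:
        raise InsufficientInstrumentsError(
            f"{exposure.trait_name}: no instruments at p < {p_threshold:g}"
        )
    hset = harmonize(exposure, outcome, instruments)
    _, mean_f = instrument_strength(hset)
    rows = []
    est_ivw, het = ivw(hset)
    rows.append(_estimate_row(exposure, outcome, est_ivw, het, mean_f=mean_f))
    if hset.n_snp >= 3:
        slope, pleio, het_e = mr_egger(hset)
        rows.append(
            _estimate_row(exposure, outcome, slope, het_e, egger_p=pleio.p_intercept)
        )
        wm = weighted_median(hset, seed=_pair_seed(seed, f"wm:{exposure.trait_name}:{outcome.trait_name}"))
        rows.append(_estimate_row(exposure, outcome, wm))
    if presso_enabled and hset.n_snp >= 4:
        pres = presso(
            hset, seed=_pair_seed(seed, f"presso:{exposure.trait_name}:{outcome.trait_name}")
        )
        rows[0]["presso_p_global"] = pres.p_global
        if pres.estimate_corrected is not None:
            rows.append(_estimate_row(exposure, outcome, pres.estimate_corrected))
    return rows


def run_forward_mr(config: StudyConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Forward MR over every exposure×outcome pair; per-pair failures isolated."""
    ld = _load_ld(config)
    rows: list[dict] = []
    failures: dict[str, str] = {}
    for espec in config.exposures:
        exposure = espec.load(config.base_dir)
        for ospec in config.outcomes:
            outcome = ospec.load(config.base_dir)
            tag = f"{espec.name}->{ospec.name}"
            try:
                rows.extend(
                    _mr_pair(exposure, outcome, espec.p_threshold, ld,
                             config.r2_threshold, config.seed, config.presso_enabled)
                )
            except MrlinkError as exc:
                failures[tag] = str(exc)
                logger.error("forward MR failed for %s: %s", tag, exc)
    return pd.DataFrame(rows), failures


def run_bidirectional(config: StudyConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Reverse-direction MR: each outcome's instruments against each exposure."""
    ld = _load_ld(config)
    rows: list[dict] = []
    failures: dict[str, str] = {}
    for ospec in config.outcomes:
        rev_exposure = ospec.load(config.base_dir)
        for espec in config.exposures:
            rev_outcome = espec.load(config.base_dir)
            tag = f"{ospec.name}->{espec.name}"
            try:
                rows.extend(
                    _mr_pair(rev_exposure, rev_outcome, ospec.p_threshold, ld,
                             config.r2_threshold, config.seed, config.presso_enabled)
                )
            except MrlinkError as exc:
                failures[tag] = str(exc)
                logger.error("bidirectional MR failed for %s: %s", tag, exc)
    return pd.DataFrame(rows), failures


def run_single_variant(config: StudyConfig, variant_id: str) -> pd.DataFrame:
    """Wald-ratio estimate of a single named variant for every pair."""
    rows = []
    for espec in config.exposures:
        exposure = espec.load(config.base_dir)
        for ospec in config.outcomes:
            outcome = ospec.load(config.base_dir)
            hset = harmonize(exposure, outcome, [variant_id], drop_palindromic=False)
            est = wald_ratio(
                hset.beta_exposure[0], hset.se_exposure[0],
                hset.beta_outcome[0], hset.se_outcome[0],
            )
            row = _estimate_row(exposure, outcome, est)
            row["variant_id"] = variant_id
            rows.append(row)
    return pd.DataFrame(rows)


def region_from_tables(
    trait1: SumstatsTable,
    trait2: SumstatsTable,
    variant_ids: Sequence[str] | None = None,
) -> RegionSumstats:
    """Assemble a colocalization region from two trait tables.

    The shared variant list defaults to the intersection, in trait-1 order.
    The ABF depends only on z², so allele orientation is irrelevant here.
    """
    ids2 = set(trait2.table["variant_id"])
    if variant_ids is None:
        variant_ids = [v for v in trait1.table["variant_id"] if v in ids2]
    t1 = trait1.table.set_index("variant_id").loc[list(variant_ids)]
    t2 = trait2.table.set_index("variant_id").loc[list(variant_ids)]
    return RegionSumstats(
        variant_ids=list(variant_ids),
        beta1=t1["beta"].to_numpy(),
        se1=t1["se"].to_numpy(),
        beta2=t2["beta"].to_numpy(),
        se2=t2["se"].to_numpy(),
        trait_types=(trait1.trait_type, trait2.trait_type),
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Execute every configured stage and write outputs plus a manifest.

    Stage failures are isolated and recorded in the manifest; the manifest
    maps each output file to its sha256 so reruns can be verified
    byte-identical. Returns the manifest dict (also written to
    ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mrlink_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "r2": config.r2_threshold,
            "fdr": config.fdr_threshold,
            "coloc_pp4": config.coloc_threshold,
        },
        "stages": {},
    }

    def record(stage: str, status: str, n_rows: int = 0,
               files: list[Path] | None = None, extra: dict | None = None) -> None:
        entry: dict = {"status": status, "n_rows": n_rows}
        if files:
            entry["outputs"] = {f.name: _sha256(f) for f in files}
        if extra:
            entry.update(extra)
        manifest["stages"][stage] = entry

    t0 = time.perf_counter()

    # forward MR
    try:
        fwd, failures = run_forward_mr(config)
        path = outdir / "forward_mr.tsv"
        _write(fwd, path)
        record("forward_mr", "ok", len(fwd), [path], {"failures": failures})
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        record("forward_mr", f"failed: {exc}")
    logger.info("forward MR done in %.1fs", time.perf_counter() - t0)

    if config.single_variant:
        try:
            sv = run_single_variant(config, config.single_variant)
            path = outdir / "single_variant.tsv"
            _write(sv, path)
            record("single_variant", "ok", len(sv), [path])
        except Exception as exc:  # noqa: BLE001
            record("single_variant", f"failed: {exc}")

    if config.bidirectional_enabled:
        try:
            rev, failures = run_bidirectional(config)
            path = outdir / "bidirectional_mr.tsv"
            _write(rev, path)
            record("bidirectional_mr", "ok", len(rev), [path], {"failures": failures})
        except Exception as exc:  # noqa: BLE001
            record("bidirectional_mr", f"failed: {exc}")

    if config.coloc_regions:
        rows = []
        abf_frames = []
        status = "ok"
        for entry in config.coloc_regions:
            try:
                name = entry["name"]
                t1 = read_sumstats(config.base_dir / entry["trait1_file"], f"{name}_t1",
                                   entry.get("trait1_type", "continuous"))
                t2 = read_sumstats(config.base_dir / entry["trait2_file"], f"{name}_t2",
                                   entry.get("trait2_type", "continuous"))
                region = region_from_tables(t1, t2)
                res = colocalize(region)
                rows.append(
                    {
                        "region": name,
                        "n_variants": res.n_variants,
                        "pp0": res.pp[0], "pp1": res.pp[1], "pp2": res.pp[2],
                        "pp3": res.pp[3], "pp4": res.pp[4],
                        "decision": coloc_decision(res, config.coloc_threshold),
                    }
                )
                abf_frames.append(
                    pd.DataFrame(
                        {"region": name, "variant_id": region.variant_ids,
                         "labf_trait1": res.labf1, "labf_trait2": res.labf2}
                    )
                )
            except Exception as exc:  # noqa: BLE001
                status = f"failed: {exc}"
        files = []
        if rows:
            path = outdir / "coloc.tsv"
            _write(pd.DataFrame(rows), path)
            files.append(path)
            abf_path = outdir / "coloc_abf.tsv"
            _write(pd.concat(abf_frames, ignore_index=True), abf_path)
            files.append(abf_path)
        record("coloc", status, len(rows), files)

    screen_selected: list[str] | None = None
    if config.mediators:
        try:
            espec = config.exposures[0]
            ospec = config.outcomes[0]
            exposure = espec.load(config.base_dir)
            outcome = ospec.load(config.base_dir)
            ld = _load_ld(config)
            instruments = select_instruments(exposure, espec.p_threshold, ld,
                                             config.r2_threshold)
            meds = {m.name: m.load(config.base_dir) for m in config.mediators}
            med_p = min((m.p_threshold for m in config.mediators), default=5e-6)
            screen = two_step_screen(
                exposure, instruments, meds, outcome,
                fdr_threshold=config.fdr_threshold,
                mediator_p_threshold=med_p, ld=ld, r2_threshold=config.r2_threshold,
            )
            path = outdir / "mediator_screen.tsv"
            _write(screen.table, path)
            screen_selected = screen.selected
            record("mediator_screen", "ok", len(screen.table), [path],
                   {"selected": screen.selected, "skipped": screen.skipped})
        except Exception as exc:  # noqa: BLE001
            record("mediator_screen", f"failed: {exc}")

    if config.pathways_file and screen_selected:
        try:
            lib_path = Path(config.pathways_file)
            if not lib_path.is_absolute():
                lib_path = config.base_dir / lib_path
            if lib_path.suffix == ".gmt":
                lib = PathwayLibrary.read_gmt(lib_path)
            else:
                lib = PathwayLibrary.read_tsv(lib_path)
            enriched = ora(screen_selected, lib)
            path = outdir / "enrichment.tsv"
            _write(enriched, path)
            record("enrichment", "ok", len(enriched), [path])
        except Exception as exc:  # noqa: BLE001
            record("enrichment", f"failed: {exc}")

    if config.mediation:
        rows = []
        status = "ok"
        espec = config.exposures[0]
        ospec = config.outcomes[0]
        exposure = espec.load(config.base_dir)
        outcome = ospec.load(config.base_dir)
        ld = _load_ld(config)
        instruments = select_instruments(exposure, espec.p_threshold, ld,
                                         config.r2_threshold)
        med_by_name = {m.name: m for m in config.mediators}
        for name in config.mediation:
            try:
                mspec = med_by_name[name]
                mediator = mspec.load(config.base_dir)
                res = run_mediation_analysis(
                    exposure, outcome, mediator, instruments,
                    mediator_p_threshold=mspec.p_threshold, ld=ld,
                    r2_threshold=config.r2_threshold,
                )
                rows.append(
                    {
                        "exposure": espec.name,
                        "outcome": ospec.name,
                        "mediator": name,
                        "beta1": res.beta1.beta, "se1": res.beta1.se,
                        "beta2": res.beta2.beta, "se2": res.beta2.se,
                        "beta_total": res.beta_total.beta,
                        "se_total": res.beta_total.se,
                        "beta_direct": res.beta_direct.beta,
                        "se_direct": res.beta_direct.se,
                        "beta_indirect": res.beta_indirect,
                        "se_indirect": res.se_indirect,
                        "proportion_mediated": res.proportion_mediated,
                        "proportion_se": res.proportion_se,
                        "proportion_ci_low": res.proportion_ci[0],
                        "proportion_ci_high": res.proportion_ci[1],
                    }
                )
            except Exception as exc:  # noqa: BLE001
                status = f"failed: {exc}"
        files = []
        if rows:
            path = outdir / "mediation.tsv"
            _write(pd.DataFrame(rows), path)
            files.append(path)
        record("mediation", status, len(rows), files)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("study complete in %.1fs", time.perf_counter() - t0)
    return manifest


# ---------------------------------------------------------------------------
# Bundled synthetic demo study
# ---------------------------------------------------------------------------


def write_demo_study(outdir: str | Path, seed: int = 0) -> Path:
    """Generate a self-contained synthetic study directory and its config.

    The demo mirrors the workflow shape of an omega-3-fatty-acid → IBD
    analysis at desk scale: one continuous exposure with 50 instruments whose
    effect chain runs through one true mediator (paths 0.6, −0.4 and direct
    −0.1, so the true total effect is −0.34 and ~70.6% of it is mediated),
    two null mediators, a binary outcome with its own 30 reverse instruments
    carrying no reverse effect, one shared-causal-variant colocalization
    region and one distinct-variant region, and a small pathway library.

    Returns the path to ``study.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _write_demo_study_impl(outdir, seed)


def _write_demo_study_impl(outdir: Path, seed: int) -> Path:
    from .simulate import MediationSimConfig, RegionSimConfig, simulate_mediation, simulate_region

    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))

    exposure, mediator, outcome, truth = simulate_mediation(
        MediationSimConfig(seed=_pair_seed(seed, "demo:mediation"))
    )
    jx = len(truth["exposure_instruments"])

    # two null mediators: own instruments, no exposure->mediator or
    # mediator->outcome path; their variants are appended to every table
    core_vids = list(exposure.table["variant_id"])

    def null_mediator(tag: str, j: int = 30):
        vids = [f"rsN{tag}{500000 + i}" for i in range(j)]
        b = rng.normal(0.15, 0.05, size=j)
        eaf = rng.uniform(0.05, 0.95, size=j)
        alleles = [("A", "G")] * j
        med_rows = _make_table(f"null_mediator_{tag}", "continuous", vids,
                               rng.normal(b, 0.02), np.full(j, 0.02), eaf, alleles)
        # noise-only rows at the core variants, so the screen can test (and
        # reject) the null mediator instead of skipping it
        med_core = _make_table(f"null_mediator_{tag}", "continuous", core_vids,
                               rng.normal(0, 0.02, size=len(core_vids)),
                               np.full(len(core_vids), 0.02),
                               rng.uniform(0.05, 0.95, size=len(core_vids)),
                               [("A", "G")] * len(core_vids))
        med_rows = SumstatsTable(
            med_rows.trait_name, "continuous",
            pd.concat([med_rows.table, med_core.table], ignore_index=True),
        )
        # the null mediator has no effect anywhere else: noise-only rows
        exp_rows = _make_table("exposure", "continuous", vids,
                               rng.normal(0, 0.01, size=j), np.full(j, 0.01), eaf, alleles)
        out_rows = _make_table("outcome", "binary", vids,
                               rng.normal(0, 0.05, size=j), np.full(j, 0.05), eaf, alleles)
        return vids, med_rows, exp_rows, out_rows

    # reverse instruments: strong on the outcome (disease liability), no
    # effect on exposure or mediator (no reverse causation in truth)
    j_rev = 30
    rev_vids = [f"rsR{600000 + i}" for i in range(j_rev)]
    b_rev = rng.normal(0.2, 0.05, size=j_rev)
    eaf_rev = rng.uniform(0.05, 0.95, size=j_rev)
    alleles_rev = [("A", "G")] * j_rev
    out_rev = _make_table("outcome", "binary", rev_vids, rng.normal(b_rev, 0.02),
                          np.full(j_rev, 0.02), eaf_rev, alleles_rev)
    exp_rev = _make_table("exposure", "continuous", rev_vids,
                          rng.normal(0, 0.01, size=j_rev), np.full(j_rev, 0.01),
                          eaf_rev, alleles_rev)

    null1_vids, null1_med, null1_exp, null1_out = null_mediator("A")
    null2_vids, null2_med, null2_exp, null2_out = null_mediator("B")

    def extend(base: SumstatsTable, *others: SumstatsTable) -> SumstatsTable:
        df = pd.concat([base.table, *[o.table for o in others]], ignore_index=True)
        return SumstatsTable(base.trait_name, base.trait_type, df)

    exposure = extend(exposure, null1_exp, null2_exp, exp_rev)
    outcome = extend(outcome, null1_out, null2_out, out_rev)
    # the true mediator needs rows for the null/reverse variants too
    pad_vids = null1_vids + null2_vids + rev_vids
    pad_eaf = rng.uniform(0.05, 0.95, size=len(pad_vids))
    mediator_pad = _make_table("mediator", "continuous", pad_vids,
                               rng.normal(0, 0.02, size=len(pad_vids)),
                               np.full(len(pad_vids), 0.02), pad_eaf,
                               [("A", "G")] * len(pad_vids))
    mediator = extend(mediator, mediator_pad)
    null_med_1 = extend(null1_med, )
    null_med_2 = extend(null2_med, )

    exposure.write_tsv(outdir / "exposure.tsv")
    mediator.write_tsv(outdir / "mediator.tsv")
    null_med_1.write_tsv(outdir / "null_mediator_a.tsv")
    null_med_2.write_tsv(outdir / "null_mediator_b.tsv")
    outcome.write_tsv(outdir / "outcome.tsv")

    # colocalization regions: shared causal variant vs distinct causal variants
    for name, causal in (("region_shared", "shared"), ("region_distinct", "distinct")):
        region = simulate_region(
            RegionSimConfig(causal_config=causal, seed=_pair_seed(seed, f"demo:{name}"))
        )
        m = len(region.variant_ids)
        eaf = np.full(m, 0.5)
        alleles = [("A", "G")] * m
        _make_table(f"{name}_t1", "continuous", region.variant_ids, region.beta1,
                    region.se1, eaf, alleles).write_tsv(outdir / f"{name}_t1.tsv")
        _make_table(f"{name}_t2", "binary", region.variant_ids, region.beta2,
                    region.se2, eaf, alleles).write_tsv(outdir / f"{name}_t2.tsv")

    # small pathway library over the mediator identifiers
    pathways = [
        ("fatty_acid_metabolism", "mediator"),
        ("fatty_acid_metabolism", "null_mediator_A"),
        ("histidine_metabolism", "null_mediator_B"),
        ("histidine_metabolism", "decoy_1"),
        ("unrelated_pathway", "decoy_2"),
        ("unrelated_pathway", "decoy_3"),
    ]
    with open(outdir / "pathways.tsv", "w") as fh:
        for pw, met in pathways:
            fh.write(f"{pw}\t{met}\n")

    truth_path = outdir / "truth.json"
    truth_out = {k: v for k, v in truth.items()
                 if k not in ("exposure_instruments", "mediator_instruments")}
    truth_path.write_text(json.dumps(truth_out, indent=2, sort_keys=True) + "\n")

    config = {
        "seed": seed,
        "thresholds": {"r2": 0.01, "fdr": 0.05, "coloc_pp4": 0.70},
        "exposures": [
            {"name": "exposure", "file": "exposure.tsv",
             "trait_type": "continuous", "p_threshold": 5e-8}
        ],
        "outcomes": [
            {"name": "outcome", "file": "outcome.tsv",
             "trait_type": "binary", "p_threshold": 5e-8}
        ],
        "mediators": [
            {"name": "mediator", "file": "mediator.tsv",
             "trait_type": "continuous", "p_threshold": 5e-6},
            {"name": "null_mediator_A", "file": "null_mediator_a.tsv",
             "trait_type": "continuous", "p_threshold": 5e-6},
            {"name": "null_mediator_B", "file": "null_mediator_b.tsv",
             "trait_type": "continuous", "p_threshold": 5e-6},
        ],
        "analyses": {
            "presso": True,
            "bidirectional": True,
            "single_variant": truth["exposure_instruments"][0]
            if "exposure_instruments" in truth else None,
            "coloc_regions": [
                {"name": "region_shared", "trait1_file": "region_shared_t1.tsv",
                 "trait2_file": "region_shared_t2.tsv",
                 "trait1_type": "continuous", "trait2_type": "binary"},
                {"name": "region_distinct", "trait1_file": "region_distinct_t1.tsv",
                 "trait2_file": "region_distinct_t2.tsv",
                 "trait1_type": "continuous", "trait2_type": "binary"},
            ],
            "mediation": ["mediator"],
            "pathways_file": "pathways.tsv",
        },
    }
    config_path = outdir / "study.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
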