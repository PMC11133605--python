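"""Orchestration of the full virtual-metabolomics inference chain.

Stage gates mirror the multi-stage validation design of a PGS-PheWAS +
two-sample MR study:

1. *discovery* — metabolite PGS (weights from exposure-cohort GWAS at the
   genome-wide threshold) are scanned against PheCode case/control sets;
   pairs significant at BH FDR < ``fdr`` move on.
2. *MR screen* — per pair, an instrument is built from the exposure
   summary statistics (suggestive threshold, LD clumping against the
   discovery panel), per-SNP outcome associations are computed in the
   discovery cohort, and IVW / MR-Egger / weighted-median estimates plus
   Cochran's Q are produced; BH FDR is applied per phenotype.  Pairs with
   heterogeneity (p_het below the gate) are routed to MR-PRESSO.
3. *replication* — pairs with >= ``min_snps_validation`` independent SNPs
   and no heterogeneity are re-tested against an independent outcome GWAS;
   a pair replicates when its replication FDR p is below the level *and*
   the effect direction matches discovery.

Every pair entering the MR screen gets exactly one ledger row recording
the gates passed, the diagnostics, and a machine-readable ``drop_reason``
when it leaves the funnel.  One failing pair never aborts the scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig, SimulationConfig
from .dataio import ScoreEntry, ScoreModel, VariantKey
from .instruments import HarmonizedInstrument, harmonize, ld_clump, select_candidates
from .mrcore import MREstimate, egger, ivw, method_consistency, weighted_median
from .presso import PressoResult, run_presso
from .scores import (InstrumentError, assemble_case_control, bh_adjust,
                     compute_pgs, phewas_scan, snp_outcome_gwas)
from .synth import StudyData, simulate_study

__all__ = [
    "PipelineResult",
    "score_models_from_stats",
    "run_discovery",
    "run_mr_screen",
    "run_replication",
    "run_all",
]

STAGES = ["phewas_sig", "mr_sig", "validation_eligible", "replicated"]

LEDGER_COLUMNS = [
    "metabolite_id", "phecode", "phewas_beta", "phewas_q",
    "mr_beta", "mr_se", "mr_p", "mr_q", "p_het", "n_snps", "consistent",
    "presso_p_global", "presso_n_outliers", "presso_beta_post",
    "presso_p_distortion", "rep_beta", "rep_p", "rep_q",
    "stage_reached", "drop_reason",
]


@dataclass
class PipelineResult:
    phewas: pd.DataFrame
    mr: pd.DataFrame
    ledger: pd.DataFrame
    instruments: dict[tuple[str, str], HarmonizedInstrument] = field(default_factory=dict)
    presso: dict[tuple[str, str], PressoResult] = field(default_factory=dict)


def score_models_from_stats(stats: dict[str, pd.DataFrame],
                            p_threshold: float = 5e-8) -> dict[str, ScoreModel]:
    """Build PGS weight files from exposure GWAS summary statistics: one
    entry per variant below the threshold, weighted by its beta."""
    models = {}
    for mid, df in stats.items():
        sel = df[df["p"] < p_threshold]
        entries = [
            ScoreEntry(
                VariantKey(str(r.chrom), int(r.pos), str(r.other_allele),
                           str(r.effect_allele), str(r.variant)),
                str(r.effect_allele), float(r.beta))
            for r in sel.itertuples()
        ]
        models[mid] = ScoreModel(mid, entries, p_threshold)
    return models


def run_discovery(study: StudyData, pcfg: PipelineConfig | None = None):
    """PGS PheWAS over all metabolites and analyzable phenotypes.

    Returns ``(phewas table, significant (metabolite, phecode) pairs,
    case/control sets)``.
    """
    pcfg = pcfg or PipelineConfig()
    models = score_models_from_stats(study.exposure_stats, pcfg.pgs_snp_p)
    study.phecode_map.min_cases = pcfg.min_cases
    study.phecode_map.min_instances = pcfg.min_instances
    cc = assemble_case_control(study.events, study.phecode_map, study.covariates)
    pgs = []
    for mid, model in models.items():
        if len(model) == 0:
            continue  # no genome-wide SNPs: metabolite has no score
        try:
            pgs.append(compute_pgs(study.panel, model))
        except InstrumentError:
            continue
    phewas = phewas_scan(pgs, {cc.phecode: cc}, study.covariates,
                         fdr=pcfg.fdr, fdr_scope=pcfg.fdr_scope)
    sig = [
        (r.metabolite_id, r.phecode)
        for r in phewas.itertuples() if bool(r.significant)
    ]
    return phewas, sig, {cc.phecode: cc}


def _mr_estimates(inst: HarmonizedInstrument, pcfg: PipelineConfig,
                  seed: int) -> tuple[dict[str, MREstimate], object]:
    est: dict[str, MREstimate] = {}
    est_ivw, het = ivw(inst, model="multiplicative_random")
    est["ivw_re"] = est_ivw
    if inst.n_snps >= 3:
        est["egger"] = egger(inst)[0]
        est["weighted_median"] = weighted_median(inst, n_boot=pcfg.wm_boot, seed=seed)
    return est, het


def run_mr_screen(study: StudyData, pairs: list[tuple[str, str]],
                  cc_sets: dict, phewas: pd.DataFrame,
                  pcfg: PipelineConfig | None = None) -> PipelineResult:
    """Instrument construction, MR estimation and gate bookkeeping for
    every PheWAS-significant pair."""
    pcfg = pcfg or PipelineConfig()
    phewas_ix = phewas.set_index(["metabolite_id", "phecode"])
    records, instruments, pressos, mr_rows = [], {}, {}, []
    for i, (mid, code) in enumerate(pairs):
        rec = dict.fromkeys(LEDGER_COLUMNS)
        rec.update(metabolite_id=mid, phecode=code, stage_reached="phewas_sig",
                   consistent=False)
        if (mid, code) in phewas_ix.index:
            rec["phewas_beta"] = float(phewas_ix.loc[(mid, code), "beta"])
            rec["phewas_q"] = float(phewas_ix.loc[(mid, code), "q"])
        try:
            if mid not in study.exposure_stats:
                raise InstrumentError("no_exposure_gwas")
            cand = select_candidates(study.exposure_stats[mid], pcfg.instrument_p)
            if cand.empty:
                raise InstrumentError("no_instrument_snps")
            clumped, clump_log = ld_clump(
                cand, study.panel, pcfg.clump_r2, pcfg.clump_kb,
                pcfg.ld_missing_policy)
            outcome = snp_outcome_gwas(
                study.panel, cc_sets[code], study.covariates,
                variants=list(clumped["variant"]))
            if outcome.empty:
                raise InstrumentError("no_outcome_stats")
            inst = harmonize(clumped, outcome, mid, code,
                             pcfg.palindromic_policy, pcfg.palindromic_maf)
            inst.provenance = clump_log + inst.provenance
        except InstrumentError as exc:
            rec["drop_reason"] = str(exc)
            records.append(rec)
            continue
        instruments[(mid, code)] = inst
        seed = (study.cfg.seed * 9973 + i) % (2 ** 31)
        est, het = _mr_estimates(inst, pcfg, seed)
        e = est["ivw_re"]
        rec.update(mr_beta=e.beta, mr_se=e.se, mr_p=e.p, n_snps=inst.n_snps,
                   consistent=method_consistency(list(est.values())))
        if het is not None:
            rec["p_het"] = het.p_het
        for name, m in est.items():
            mr_rows.append({"metabolite_id": mid, "phecode": code,
                            "method": name, "beta": m.beta, "se": m.se,
                            "p": m.p, "ci_lo": m.ci95[0], "ci_hi": m.ci95[1],
                            "n_snps": m.n_snps, "intercept": m.intercept,
                            "intercept_p": m.intercept_p})
        if (het is not None and het.p_het < pcfg.het_p and inst.n_snps >= 4):
            pres = run_presso(inst, n_sim=pcfg.presso_nsim, seed=seed,
                              outlier_alpha=pcfg.outlier_alpha)
            pressos[(mid, code)] = pres
            rec.update(presso_p_global=pres.p_global,
                       presso_n_outliers=len(pres.outliers),
                       presso_beta_post=pres.beta_post,
                       presso_p_distortion=pres.p_distortion)
        records.append(rec)
    ledger = pd.DataFrame(records, columns=LEDGER_COLUMNS)
    # BH FDR on the IVW p-values, scoped per phenotype across metabolites
    ok = ledger["mr_p"].notna()
    if ok.any():
        if pcfg.fdr_scope == "global":
            ledger.loc[ok, "mr_q"] = bh_adjust(ledger.loc[ok, "mr_p"].to_numpy())
        else:
            for code in ledger.loc[ok, "phecode"].unique():
                sel = ok & (ledger["phecode"] == code)
                ledger.loc[sel, "mr_q"] = bh_adjust(ledger.loc[sel, "mr_p"].to_numpy())
    for idx, row in ledger.iterrows():
        if row["drop_reason"] is not None or pd.isna(row["mr_q"]):
            continue
        if row["mr_q"] < pcfg.fdr:
            ledger.loc[idx, "stage_reached"] = "mr_sig"
            if (row["n_snps"] >= pcfg.min_snps_validation
                    and pd.notna(row["p_het"]) and row["p_het"] > pcfg.het_p):
                ledger.loc[idx, "stage_reached"] = "validation_eligible"
            else:
                ledger.loc[idx, "drop_reason"] = (
                    "too_few_snps" if row["n_snps"] < pcfg.min_snps_validation
                    else "heterogeneity")
        else:
            ledger.loc[idx, "drop_reason"] = "mr_not_significant"
    mr = pd.DataFrame(mr_rows)
    return PipelineResult(phewas=phewas, mr=mr, ledger=ledger,
                          instruments=instruments, presso=pressos)


def run_replication(study: StudyData, result: PipelineResult,
                    pcfg: PipelineConfig | None = None,
                    replication_stats: pd.DataFrame | dict[str, pd.DataFrame] | None = None
                    ) -> PipelineResult:
    """Re-test validation-eligible pairs against an independent outcome
    GWAS and update the ledger in place."""
    pcfg = pcfg or PipelineConfig()
    ledger = result.ledger
    eligible = ledger.index[ledger["stage_reached"] == "validation_eligible"]
    if len(eligible) == 0:
        return result
    needed = sorted({
        v for idx in eligible
        for v in result.instruments[
            (ledger.loc[idx, "metabolite_id"], ledger.loc[idx, "phecode"])
        ].snps["variant"]
    })
    rep_default = None
    if replication_stats is None:
        rep_default = study.replication_stats(needed)
    rep_rows = []
    for idx in eligible:
        mid, code = ledger.loc[idx, "metabolite_id"], ledger.loc[idx, "phecode"]
        if isinstance(replication_stats, dict):
            rep = replication_stats.get(code)
        else:
            rep = replication_stats if replication_stats is not None else rep_default
        if rep is None:
            ledger.loc[idx, "drop_reason"] = "no_external_data"
            continue
        inst = result.instruments[(mid, code)]
        try:
            rinst = harmonize(inst.snps.rename(columns={
                "beta_exp": "beta", "se_exp": "se", "eaf_exp": "eaf"}),
                rep, mid, code, pcfg.palindromic_policy, pcfg.palindromic_maf)
            est, _ = ivw(rinst, model="multiplicative_random")
        except InstrumentError as exc:
            ledger.loc[idx, "drop_reason"] = f"no_external_data: {exc}"
            continue
        rep_rows.append({"idx": idx, "beta": est.beta, "p": est.p})
    if not rep_rows:
        return result
    rep_df = pd.DataFrame(rep_rows)
    rep_df["q"] = bh_adjust(rep_df["p"].to_numpy())
    for r in rep_df.itertuples():
        ledger.loc[r.idx, ["rep_beta", "rep_p", "rep_q"]] = [r.beta, r.p, r.q]
        same_sign = np.sign(r.beta) == np.sign(ledger.loc[r.idx, "mr_beta"])
        if r.q < pcfg.fdr and same_sign:
            ledger.loc[r.idx, "stage_reached"] = "replicated"
        else:
            ledger.loc[r.idx, "drop_reason"] = (
                "replication_not_significant" if r.q >= pcfg.fdr
                else "replication_sign_discordant")
    return result


def run_all(cfg: SimulationConfig, pcfg: PipelineConfig | None = None,
            study: StudyData | None = None) -> PipelineResult:
    """Simulate (or accept) a study and run discovery -> MR screen ->
    replication end to end."""
    pcfg = pcfg or PipelineConfig()
    if study is None:
        study = simulate_study(cfg)
    phewas, pairs, cc_sets = run_discovery(study, pcfg)
    result = run_mr_screen(study, pairs, cc_sets, phewas, pcfg)
    return run_replication(study, result, pcfg)
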