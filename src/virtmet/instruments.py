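"""Instrument construction for two-sample MR: candidate selection, greedy
LD clumping and exposure/outcome allele harmonization.

Clumping follows PLINK semantics: candidates are sorted by ascending
p-value (ties broken by chromosome then position), the best remaining SNP
becomes an index SNP, and every remaining SNP on the same chromosome within
the physical window whose r^2 with the index reaches the threshold is
removed.  r^2 is the squared Pearson correlation of dosages on the LD
reference.  Harmonization aligns outcome effects to the exposure effect
allele per SNP, trying direct allele match first and strand complement
second; palindromic SNPs are resolved by allele frequency when it is
informative and dropped otherwise.  Every drop and flip lands in the
instrument's provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import GenotypePanel, VariantKey, complement
from .scores import InstrumentError

__all__ = [
    "HarmonizedInstrument",
    "select_candidates",
    "ld_clump",
    "harmonize",
    "instrument_from_frames",
]

INSTRUMENT_COLUMNS = [
    "variant", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out",
]


@dataclass
class HarmonizedInstrument:
    """Aligned exposure/outcome per-SNP effects for one metabolite-phenotype
    test, with a provenance log of every harmonization action."""

    metabolite_id: str
    phenotype_id: str
    snps: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in INSTRUMENT_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"instrument table missing columns {missing}")
        if len(self.snps) < 1:
            raise InstrumentError(
                f"{self.metabolite_id}->{self.phenotype_id}: empty instrument")
        if (self.snps["se_exp"] <= 0).any() or (self.snps["se_out"] <= 0).any():
            raise ValueError("instrument SEs must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, se_x, Gamma, se_y) exposure/outcome effect arrays."""
        s = self.snps
        return (s["beta_exp"].to_numpy(float), s["se_exp"].to_numpy(float),
                s["beta_out"].to_numpy(float), s["se_out"].to_numpy(float))

    def drop_variants(self, variants: set[str], reason: str) -> "HarmonizedInstrument":
        keep = ~self.snps["variant"].isin(variants)
        log = self.provenance + [
            {"variant": v, "action": "drop", "reason": reason} for v in variants]
        return HarmonizedInstrument(
            self.metabolite_id, self.phenotype_id,
            self.snps[keep].reset_index(drop=True), log)


def select_candidates(stats: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Rows with ``p`` strictly below the threshold, order preserved."""
    if "p" not in stats.columns:
        raise ValueError("summary table lacks a 'p' column")
    return stats[stats["p"] < p_threshold].reset_index(drop=True)


def _r2_from_panel(panel: GenotypePanel, variants: list[str]) -> tuple[pd.DataFrame, list[str]]:
    vindex = panel.variant_index()
    present = [v for v in variants if v in vindex]
    if not present:
        return pd.DataFrame(), [v for v in variants if v not in vindex]
    X = panel.dosages[:, [vindex[v] for v in present]]
    sd = X.std(axis=0)
    ok = sd > 0
    Xn = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    r = (Xn.T @ Xn) / Xn.shape[0]
    names = [v for v, o in zip(present, ok) if o]
    r2 = pd.DataFrame(r ** 2, index=names, columns=names)
    missing = [v for v in variants if v not in set(names)]
    return r2, missing


def ld_clump(candidates: pd.DataFrame,
             ld_source: GenotypePanel | pd.DataFrame,
             r2_threshold: float = 0.05, window_kb: float = 1000.0,
             missing_policy: str = "assume_independent") -> tuple[pd.DataFrame, list[dict]]:
    """Greedy p-ordered LD clumping; returns (index SNPs, decision log).

    ``ld_source`` is a genotype panel (r^2 from dosage correlation) or a
    precomputed r^2 matrix indexed by variant id.  Candidates absent from
    the LD source are dropped or assumed independent per
    ``missing_policy``.  The window is measured index-SNP to candidate and
    is inclusive at exactly ``window_kb``.
    """
    if missing_policy not in ("drop", "assume_independent"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if candidates.empty:
        return candidates.copy(), []
    if isinstance(ld_source, GenotypePanel):
        r2, missing = _r2_from_panel(ld_source, list(candidates["variant"]))
    else:
        r2 = ld_source
        known = set(r2.index)
        missing = [v for v in candidates["variant"] if v not in known]
    missing_set = set(missing)
    log = [{"variant": v, "action": "missing_ld",
            "resolution": missing_policy} for v in missing]
    work = candidates.copy()
    if missing_policy == "drop" and missing_set:
        work = work[~work["variant"].isin(missing_set)]
    order = work.sort_values(
        ["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    removed: set[str] = set()
    kept: list[str] = []
    window = window_kb * 1000.0
    for row in order.itertuples():
        if row.variant in removed:
            continue
        kept.append(row.variant)
        for other in order.itertuples():
            if other.variant in removed or other.variant == row.variant:
                continue
            if other.variant in kept:
                continue
            if other.chrom != row.chrom or abs(other.pos - row.pos) > window:
                continue
            if row.variant in missing_set or other.variant in missing_set:
                continue  # assume independent
            if float(r2.loc[row.variant, other.variant]) >= r2_threshold:
                removed.add(other.variant)
                log.append({"variant": other.variant, "action": "clumped",
                            "index_snp": row.variant,
                            "r2": float(r2.loc[row.variant, other.variant])})
    kept_set = set(kept)
    out = candidates[candidates["variant"].isin(kept_set)].reset_index(drop=True)
    return out, log


def _key(row) -> VariantKey:
    return VariantKey(str(row.chrom), int(row.pos), str(row.other_allele),
                      str(row.effect_allele), str(row.variant))


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              metabolite_id: str = "exposure", phenotype_id: str = "outcome",
              palindromic_policy: str = "frequency",
              palindromic_maf: float = 0.42) -> HarmonizedInstrument:
    """Align outcome summary statistics to the exposure effect alleles.

    For each SNP shared by (chrom, pos): matching effect alleles copy the
    outcome effect; swapped alleles negate the outcome beta (and reflect
    its EAF); strand-complement matches are complemented first.
    Palindromic SNPs (A/T, C/G) cannot be strand-resolved: with the
    ``frequency`` policy they are kept only when the minor-allele frequency
    is below ``palindromic_maf`` in both tables and aligned by frequency;
    the ``drop`` policy removes them outright.  Unmatchable allele pairs
    are dropped.  Raises when no SNP survives.
    """
    if palindromic_policy not in ("frequency", "drop"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")
    out_by_pos: dict[tuple, object] = {}
    for row in outcome.itertuples():
        out_by_pos[(str(row.chrom), int(row.pos))] = row
    rows, log = [], []
    for row in exposure.itertuples():
        vid = str(row.variant)
        other = out_by_pos.get((str(row.chrom), int(row.pos)))
        if other is None:
            log.append({"variant": vid, "action": "drop", "reason": "absent_in_outcome"})
            continue
        exp_key = _key(row)
        if exp_key.is_palindromic:
            if palindromic_policy == "drop":
                log.append({"variant": vid, "action": "drop", "reason": "palindromic"})
                continue
            maf_e = min(row.eaf, 1 - row.eaf)
            maf_o = min(other.eaf, 1 - other.eaf)
            if maf_e > palindromic_maf or maf_o > palindromic_maf:
                log.append({"variant": vid, "action": "drop",
                            "reason": "palindromic_ambiguous_frequency"})
                continue
            # align by frequency: same minor allele side => same effect allele
            same = (row.eaf < 0.5) == (other.eaf < 0.5)
            beta_out = other.beta if same else -other.beta
            eaf_out = other.eaf if same else 1 - other.eaf
            if not same:
                log.append({"variant": vid, "action": "flip",
                            "reason": "palindromic_frequency_aligned"})
            rows.append((row, beta_out, other.se, eaf_out))
            continue
        how = exp_key.match(_key(other))
        if how is None:
            log.append({"variant": vid, "action": "drop", "reason": "allele_mismatch"})
            continue
        oa_eff = str(other.effect_allele) if how == "direct" else complement(str(other.effect_allele))
        if oa_eff == str(row.effect_allele):
            beta_out, eaf_out = other.beta, other.eaf
            if how == "complement":
                log.append({"variant": vid, "action": "complement", "reason": "strand"})
        else:
            beta_out, eaf_out = -other.beta, 1 - other.eaf
            log.append({"variant": vid, "action": "flip",
                        "reason": "effect_allele_swap" if how == "direct"
                        else "strand_and_swap"})
        rows.append((row, beta_out, other.se, eaf_out))
    if not rows:
        raise InstrumentError(
            f"{metabolite_id}->{phenotype_id}: no SNPs survived harmonization")
    snps = pd.DataFrame([{
        "variant": r.variant, "chrom": str(r.chrom), "pos": int(r.pos),
        "effect_allele": r.effect_allele, "other_allele": r.other_allele,
        "beta_exp": float(r.beta), "se_exp": float(r.se),
        "beta_out": float(b), "se_out": float(s),
        "eaf_exp": float(r.eaf), "eaf_out": float(e),
    } for r, b, s, e in rows])
    return HarmonizedInstrument(metabolite_id, phenotype_id, snps, log)


def instrument_from_frames(metabolite_id: str, phenotype_id: str,
                           exposure: pd.DataFrame, outcome: pd.DataFrame,
                           ld_source, p_threshold: float = 5e-6,
                           r2_threshold: float = 0.05, window_kb: float = 1000.0,
                           missing_policy: str = "assume_independent",
                           palindromic_policy: str = "frequency",
                           palindromic_maf: float = 0.42) -> HarmonizedInstrument:
    """select -> clump -> harmonize in one call."""
    cand = select_candidates(exposure, p_threshold)
    if cand.empty:
        raise InstrumentError(
            f"{metabolite_id}->{phenotype_id}: no candidates below p={p_threshold}")
    clumped, clump_log = ld_clump(cand, ld_source, r2_threshold, window_kb,
                                  missing_policy)
    inst = harmonize(clumped, outcome, metabolite_id, phenotype_id,
                     palindromic_policy, palindromic_maf)
    inst.provenance = clump_log + inst.provenance
    return inst
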