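"""Synthetic three-cohort study generator with known causal ground truth.

The generator emulates the data layout of a virtual-metabolomics study:

* a *discovery* biobank cohort with individual-level genotypes, PheCode
  event records and covariates (used for the PGS PheWAS and the per-SNP
  outcome associations of the MR screen);
* an *exposure GWAS* cohort in which per-variant metabolite summary
  statistics are computed (the exposure side of two-sample MR);
* an independent *outcome GWAS* cohort providing replication summary
  statistics for the phenotype.

The three cohorts share variant metadata and metabolite architecture but
never share individuals, so every two-sample assumption downstream holds by
construction.  Genotypes come from a Gaussian copula: per LD block a latent
AR(1) process is thresholded into haplotype alleles, with the latent
autocorrelation calibrated numerically so the *genotype* correlation of
adjacent variants matches the requested ``within_block_r``.  Metabolites
are sparse linear functions of dosages plus Gaussian noise with a
population-scaled heritability; the binary phenotype follows a logistic
liability with a metabolite-mediated effect, optional direct (horizontally
pleiotropic) variant effects, and an intercept solved so the marginal
prevalence matches the target.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .config import SimulationConfig
from .dataio import GenotypePanel, PhecodeMap

__all__ = [
    "GroundTruth",
    "simulate_genotypes",
    "simulate_metabolites",
    "simulate_phenotype",
    "simulate_summary_stats",
    "simulate_exposure_stats",
    "default_phecode_map",
    "StudyData",
    "simulate_study",
]

_COHORT_STREAM = {"discovery": 0, "exposure": 1, "outcome": 2}
_COHORT_PREFIX = {"discovery": "D", "exposure": "E", "outcome": "O"}
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class GroundTruth:
    """True generative parameters, for parameter-recovery tests.

    ``metabolite_weights`` maps metabolite id to its (variant id, effect per
    alt-allele dosage) pairs; ``direct_effects`` holds per-variant direct
    log-odds effects on the phenotype (horizontal pleiotropy);
    ``causal_effect`` is the log-odds per SD of the causal metabolite.
    """

    metabolite_ids: list[str]
    metabolite_weights: dict[str, list[tuple[str, float]]]
    direct_effects: dict[str, float]
    causal_effect: float
    causal_metabolite: str
    pleiotropy_mode: str
    block_of_variant: dict[str, int]
    within_block_r: float

    def __post_init__(self) -> None:
        vals = [v for v in self.direct_effects.values() if v != 0.0]
        if self.pleiotropy_mode == "directional" and vals:
            if not (all(v > 0 for v in vals) or all(v < 0 for v in vals)):
                raise ValueError("directional pleiotropy requires one shared sign")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "metabolite_ids": self.metabolite_ids,
            "metabolite_weights": self.metabolite_weights,
            "direct_effects": self.direct_effects,
            "causal_effect": self.causal_effect,
            "causal_metabolite": self.causal_metabolite,
            "pleiotropy_mode": self.pleiotropy_mode,
            "block_of_variant": self.block_of_variant,
            "within_block_r": self.within_block_r,
        }, indent=1))


# ---------------------------------------------------------------------------
# latent-correlation calibration for the Gaussian copula


@functools.lru_cache(maxsize=4096)
def _calibrated_rho(t1: float, t2: float, target: float) -> float:
    """Latent Gaussian correlation giving binary-indicator correlation
    ``target`` for alleles thresholded at ``t1``/``t2`` (quantiles)."""
    if target <= 0.0:
        return 0.0
    p1, p2 = stats.norm.cdf(t1), stats.norm.cdf(t2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def binary_corr(rho: float) -> float:
        p11 = stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2])
        return (p11 - p1 * p2) / denom

    hi = 0.999
    if binary_corr(hi) <= target:  # target unattainable for these MAFs
        return hi
    return float(optimize.brentq(lambda r: binary_corr(r) - target, 0.0, hi, xtol=1e-4))


@functools.lru_cache(maxsize=64)
def _variant_layout(seed: int, n_variants: int, n_blocks: int,
                    maf_lo: float, maf_hi: float, within_r: float):
    """Variant metadata shared by all cohorts of one simulation.

    Blocks are placed >=10 Mb apart (cycling over 22 chromosomes) with 10 kb
    between adjacent variants inside a block, so cross-block pairs always
    fall outside any physically sensible clumping window.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), n_variants)
    block_of = np.concatenate([
        np.full(len(part), b)
        for b, part in enumerate(np.array_split(np.arange(n_variants), n_blocks))
    ])
    # one MAF per block: variants in tight LD share allele frequencies, and
    # equal thresholds keep the requested correlation attainable under the
    # thresholded-copula (Frechet) bound
    block_maf = rng.uniform(maf_lo, maf_hi, n_blocks)
    mafs = block_maf[block_of]
    rows, rho_adj = [], np.zeros(n_variants)
    thresholds = stats.norm.ppf(mafs)
    pos_in_block = 0
    for j in range(n_variants):
        b = int(block_of[j])
        pos_in_block = pos_in_block + 1 if j > 0 and block_of[j - 1] == b else 0
        chrom = str(b % 22 + 1)
        base = 1 + (b // 22) * 10_000_000
        ref, alt = _ALLELE_PAIRS[allele_idx[j]]
        rows.append({
            "variant": f"rs{j + 1}", "chrom": chrom,
            "pos": base + pos_in_block * 10_000, "ref": ref, "alt": alt,
            "eaf": mafs[j],
        })
        if pos_in_block > 0 and within_r > 0:
            rho_adj[j] = _calibrated_rho(
                round(float(thresholds[j - 1]), 4),
                round(float(thresholds[j]), 4),
                round(within_r, 4),
            )
    return pd.DataFrame(rows), block_of, thresholds, rho_adj


def simulate_genotypes(cfg: SimulationConfig,
                       cohort: Literal["discovery", "exposure", "outcome"] = "discovery",
                       n: int | None = None) -> GenotypePanel:
    """Simulate a dosage panel for one cohort of the study.

    All cohorts share variant metadata (positions, alleles, target MAFs, LD
    structure); individuals are drawn from disjoint random streams so the
    cohorts never overlap.  Dosages are hard calls in {0, 1, 2} unless
    ``cfg.dosage_noise`` adds imputation-style jitter.
    """
    variants, block_of, thresholds, rho_adj = _variant_layout(
        cfg.seed, cfg.n_variants, cfg.n_ld_blocks,
        cfg.maf_range[0], cfg.maf_range[1], cfg.within_block_r,
    )
    if n is None:
        n = {"discovery": cfg.n_discovery, "exposure": cfg.n_exposure_gwas,
             "outcome": cfg.n_outcome_gwas}[cohort]
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 11, _COHORT_STREAM[cohort]]))
    m = cfg.n_variants
    # two haplotypes per individual; latent AR(1) within each block
    z = np.empty((2 * n, m))
    for j in range(m):
        eps = rng.standard_normal(2 * n)
        if rho_adj[j] > 0:
            r = rho_adj[j]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1 - r * r) * eps
        else:
            z[:, j] = eps
    alleles = (z < thresholds).astype(float)
    dosages = alleles[0::2] + alleles[1::2]
    if cfg.dosage_noise:
        dosages = np.clip(dosages + rng.normal(0.0, 0.05, dosages.shape), 0.0, 2.0)
    prefix = _COHORT_PREFIX[cohort]
    sample_ids = [f"{prefix}{i:06d}" for i in range(n)]
    variants = variants.copy()
    variants["eaf"] = dosages.mean(axis=0) / 2.0
    return GenotypePanel(sample_ids, variants, dosages)


# ---------------------------------------------------------------------------
# metabolite architecture


@functools.lru_cache(maxsize=64)
def _architecture(seed: int, n_variants: int, n_blocks: int, n_metabolites: int,
                  snps_per: int, h2: float, dist: str, n_pleio: int,
                  mode: str, scale: float, causal_effect: float,
                  maf_lo: float, maf_hi: float, within_r: float) -> GroundTruth:
    variants, block_of, _, _ = _variant_layout(
        seed, n_variants, n_blocks, maf_lo, maf_hi, within_r)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    mafs = dict(zip(variants["variant"], variants["eaf"]))
    # target mafs drawn in _variant_layout (eaf column pre-genotypes)
    met_ids = [f"met{k:03d}" for k in range(n_metabolites)]
    weights: dict[str, list[tuple[str, float]]] = {}
    vids = variants["variant"].to_numpy()
    for mid in met_ids:
        if h2 == 0.0:
            weights[mid] = []
            continue
        if n_blocks >= snps_per:
            # one SNP per distinct block so clumped instruments keep >= snps_per
            blocks = rng.choice(n_blocks, size=snps_per, replace=False)
            idx = np.array([
                rng.choice(np.flatnonzero(block_of == b)) for b in blocks
            ])
        else:
            idx = rng.choice(n_variants, size=snps_per, replace=False)
        if dist == "equal":
            raw = rng.choice([-1.0, 1.0], size=snps_per)
        else:
            raw = rng.standard_normal(snps_per)
            raw[raw == 0.0] = 1.0
        # population variance of the genetic component, incl. within-block LD
        var_g = 0.0
        for a in range(snps_per):
            pa = mafs[vids[idx[a]]]
            var_g += raw[a] ** 2 * 2 * pa * (1 - pa)
            for b in range(a + 1, snps_per):
                if block_of[idx[a]] == block_of[idx[b]]:
                    pb = mafs[vids[idx[b]]]
                    r_ab = within_r ** abs(int(idx[a]) - int(idx[b]))
                    var_g += (2 * raw[a] * raw[b] * r_ab
                              * np.sqrt(2 * pa * (1 - pa) * 2 * pb * (1 - pb)))
        c = np.sqrt(h2 / var_g)
        weights[mid] = [(vids[i], float(c * raw[a])) for a, i in enumerate(idx)]
    causal_mid = met_ids[0]
    # pleiotropic variants preferentially overlap the causal instrument,
    # so the violation is visible to the MR diagnostics downstream
    direct: dict[str, float] = {}
    if n_pleio > 0:
        causal_snps = [v for v, _ in weights.get(causal_mid, [])]
        pool = causal_snps + [v for v in vids if v not in causal_snps]
        chosen = pool[:n_pleio] if n_pleio <= len(pool) else pool
        for v in chosen:
            if mode == "directional":
                direct[v] = scale
            else:
                direct[v] = float(rng.choice([-1.0, 1.0]) * scale)
    return GroundTruth(
        metabolite_ids=met_ids, metabolite_weights=weights,
        direct_effects=direct, causal_effect=causal_effect,
        causal_metabolite=causal_mid, pleiotropy_mode=mode,
        block_of_variant={v: int(b) for v, b in zip(vids, block_of)},
        within_block_r=within_r,
    )


def ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """The (deterministic) generative architecture implied by ``cfg``."""
    return _architecture(
        cfg.seed, cfg.n_variants, cfg.n_ld_blocks, cfg.n_metabolites,
        cfg.snps_per_metabolite, cfg.h2_metabolite, cfg.effect_size_dist,
        cfg.n_pleiotropic, cfg.pleiotropy_mode, cfg.pleiotropy_scale,
        cfg.causal_effect, cfg.maf_range[0], cfg.maf_range[1],
        cfg.within_block_r,
    )


def simulate_metabolites(panel: GenotypePanel, cfg: SimulationConfig,
                         stream: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Metabolite matrix (individuals x metabolites) for one cohort.

    Each metabolite is its genetic component (true per-dosage effects times
    alt dosages) plus independent Gaussian noise with variance ``1 - h2``.
    Effects are scaled against the population dosage variance, so the same
    ground-truth weights generate every cohort; realized sample variance is
    1 up to sampling error and columns are mean-centered.
    """
    truth = ground_truth(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 21, stream]))
    vindex = panel.variant_index()
    n = panel.n_individuals
    met = np.empty((n, cfg.n_metabolites))
    sd_e = np.sqrt(1.0 - cfg.h2_metabolite)
    for k, mid in enumerate(truth.metabolite_ids):
        g = np.zeros(n)
        for vid, w in truth.metabolite_weights[mid]:
            g += w * panel.dosages[:, vindex[vid]]
        met[:, k] = g + rng.normal(0.0, sd_e, n)
        met[:, k] -= met[:, k].mean()
    return met, truth


# ---------------------------------------------------------------------------
# phenotype


def default_phecode_map(cfg: SimulationConfig) -> PhecodeMap:
    """Exclusion map for the simulated target code: its whole integer
    family (e.g. 574.x for code 574.1) is the closely-related range."""
    base = float(int(float(cfg.phecode)))
    return PhecodeMap(cfg.phecode, [(base, base + 0.99)])


def _related_code(cfg: SimulationConfig) -> str:
    return f"{float(cfg.phecode) + 0.1:.2f}".rstrip("0").rstrip(".")


def simulate_phenotype(panel: GenotypePanel, metabolite: np.ndarray,
                       truth: GroundTruth, cfg: SimulationConfig,
                       stream: int = 0) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Binary phenotype, PheCode event table and covariates for a cohort.

    Case probability is logistic in the causal metabolite, any direct
    (pleiotropic) variant effects, and small age/sex effects; the intercept
    is solved numerically so the marginal prevalence matches the target.
    Every case receives two event rows for the target code (the minimum
    satisfying the two-instance case rule); ``cfg.event_jitter`` adds
    extras, and a small fraction of non-cases receive one row for a closely
    related code so the exclusion logic is exercised.
    """
    if len(metabolite) != panel.n_individuals:
        raise ValueError("metabolite vector length must match panel individuals")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 40, stream]))
    n = panel.n_individuals
    age = rng.uniform(18.0, 85.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    pcs = rng.standard_normal((n, 10))
    if cfg.confound_pcs:
        burden = panel.dosages.mean(axis=1)
        pcs[:, 0] = 0.7 * (burden - burden.mean()) / burden.std() + 0.3 * pcs[:, 0]
    vindex = panel.variant_index()
    lin = cfg.causal_effect * metabolite
    for vid, eff in truth.direct_effects.items():
        d = panel.dosages[:, vindex[vid]]
        lin = lin + eff * (d - d.mean())
    lin = lin + cfg.age_effect * (age - age.mean()) + cfg.sex_effect * (sex - 0.5)

    def marginal(alpha: float) -> float:
        return float(np.mean(expit(alpha + lin))) - cfg.prevalence

    alpha = optimize.brentq(marginal, -30.0, 30.0, xtol=1e-10)
    y = (rng.uniform(size=n) < expit(alpha + lin)).astype(int)

    ids = np.asarray(panel.sample_ids)
    rows = []
    jitter = rng.uniform(size=n)
    related = rng.uniform(size=n)
    rel_code = _related_code(cfg)
    for i in np.flatnonzero(y == 1):
        rows.append((ids[i], cfg.phecode, 1))
        rows.append((ids[i], cfg.phecode, 1))
        if jitter[i] < cfg.event_jitter:
            rows.append((ids[i], cfg.phecode, 1))
    for i in np.flatnonzero(y == 0):
        if related[i] < cfg.related_code_rate:
            rows.append((ids[i], rel_code, 1))
    events = pd.DataFrame(rows, columns=["individual_id", "phecode", "count"])
    cov = pd.DataFrame(
        {"age": age, "sex": sex, **{f"PC{j + 1}": pcs[:, j] for j in range(10)}},
        index=pd.Index(ids, name="individual_id"),
    )
    return y, events, cov


# ---------------------------------------------------------------------------
# two-sample summary statistics


def simulate_exposure_stats(cfg: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-metabolite GWAS summary statistics from the exposure cohort.

    One fresh cohort is simulated and every metabolite is regressed on every
    variant with simple per-variant linear regression (normal-theory
    two-sided p).  Returns ``{metabolite_id: summary table}``.
    """
    from .scores import linear_gwas

    panel = simulate_genotypes(cfg, cohort="exposure")
    met, truth = simulate_metabolites(panel, cfg, stream=1)
    return {
        mid: linear_gwas(panel, met[:, k])
        for k, mid in enumerate(truth.metabolite_ids)
    }


def simulate_summary_stats(cfg: SimulationConfig, truth: GroundTruth | None,
                           trait: str, variants: list[str] | None = None) -> pd.DataFrame:
    """GWAS summary statistics for one trait from a fresh, disjoint cohort.

    ``trait`` is a metabolite id (linear per-variant regression in the
    exposure cohort) or ``"phenotype"`` (additive logistic per-variant
    regression adjusted for age, sex and 10 PCs in the outcome cohort).
    """
    from .scores import linear_gwas, snp_outcome_gwas

    if truth is None:
        truth = ground_truth(cfg)
    if trait == "phenotype":
        panel = simulate_genotypes(cfg, cohort="outcome")
        met, _ = simulate_metabolites(panel, cfg, stream=2)
        k = truth.metabolite_ids.index(truth.causal_metabolite)
        y, _, cov = simulate_phenotype(panel, met[:, k], truth, cfg, stream=2)
        return snp_outcome_gwas(panel, y, cov, variants=variants)
    if trait not in truth.metabolite_ids:
        raise ValueError(f"unknown trait {trait!r}")
    panel = simulate_genotypes(cfg, cohort="exposure")
    met, _ = simulate_metabolites(panel, cfg, stream=1)
    k = truth.metabolite_ids.index(trait)
    out = linear_gwas(panel, met[:, k])
    if variants is not None:
        out = out[out["variant"].isin(variants)].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# whole-study convenience container


@dataclass
class StudyData:
    """All inputs of one simulated study, with the outcome cohort cached."""

    cfg: SimulationConfig
    panel: GenotypePanel
    metabolites: np.ndarray
    truth: GroundTruth
    y: np.ndarray
    events: pd.DataFrame
    covariates: pd.DataFrame
    phecode_map: PhecodeMap
    exposure_stats: dict[str, pd.DataFrame]
    _outcome_cohort: tuple | None = field(default=None, repr=False)

    def replication_stats(self, variants: list[str]) -> pd.DataFrame:
        """Outcome-cohort summary statistics for the requested variants."""
        from .scores import snp_outcome_gwas

        if self._outcome_cohort is None:
            panel = simulate_genotypes(self.cfg, cohort="outcome")
            met, _ = simulate_metabolites(panel, self.cfg, stream=2)
            k = self.truth.metabolite_ids.index(self.truth.causal_metabolite)
            y, _, cov = simulate_phenotype(panel, met[:, k], self.truth, self.cfg, stream=2)
            self._outcome_cohort = (panel, y, cov)
        panel, y, cov = self._outcome_cohort
        return snp_outcome_gwas(panel, y, cov, variants=variants)


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Simulate the full three-cohort study implied by ``cfg``."""
    panel = simulate_genotypes(cfg, cohort="discovery")
    met, truth = simulate_metabolites(panel, cfg, stream=0)
    k = truth.metabolite_ids.index(truth.causal_metabolite)
    y, events, cov = simulate_phenotype(panel, met[:, k], truth, cfg, stream=0)
    return StudyData(
        cfg=cfg, panel=panel, metabolites=met, truth=truth, y=y,
        events=events, covariates=cov, phecode_map=default_phecode_map(cfg),
        exposure_stats=simulate_exposure_stats(cfg),
    )
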