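"""Configuration objects for the simulation and the analysis pipeline.

Two configs drive everything: :class:`SimulationConfig` fixes the synthetic
three-cohort study design (discovery biobank, exposure GWAS cohort,
independent outcome GWAS cohort), and :class:`PipelineConfig` collects the
analysis thresholds (instrument p-value cut, LD-clumping parameters, FDR
level, case-count floors, heterogeneity gate).  Both round-trip through YAML
so a whole run is reproducible from a single file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["SimulationConfig", "PipelineConfig", "load_yaml", "dump_yaml"]


@dataclass
class SimulationConfig:
    """Design of the synthetic three-cohort virtual-metabolomics study.

    The three cohorts are drawn independently and never share individuals,
    which is the defining contract of two-sample Mendelian randomization:

    * ``n_discovery`` — biobank-style cohort with individual-level genotypes,
      PheCode events and covariates, used for the PGS PheWAS and for the
      per-SNP outcome associations of the MR screen.
    * ``n_exposure_gwas`` — cohort in which metabolite GWAS summary
      statistics (the exposure side of MR) are computed.
    * ``n_outcome_gwas`` — cohort in which the replication outcome GWAS
      summary statistics are computed.

    Genotypes are organised into ``n_ld_blocks`` blocks; adjacent variants
    within a block have genotype correlation near ``within_block_r`` and
    variants in different blocks are independent.  Each metabolite is a
    sparse linear function of ``snps_per_metabolite`` variant dosages plus
    Gaussian noise, with genetic variance fraction ``h2_metabolite``.  The
    binary phenotype follows a logistic model with log-odds
    ``causal_effect`` per SD of the causal metabolite, optional direct
    (horizontally pleiotropic) variant effects, and an intercept solved so
    the marginal prevalence matches ``prevalence``.
    """

    n_discovery: int = 20_000
    n_exposure_gwas: int = 6_000
    n_outcome_gwas: int = 20_000
    n_variants: int = 60
    n_ld_blocks: int = 30
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_metabolites: int = 20
    snps_per_metabolite: int = 3
    h2_metabolite: float = 0.3
    causal_effect: float = 0.5
    n_pleiotropic: int = 0
    pleiotropy_mode: Literal["balanced", "directional"] = "balanced"
    pleiotropy_scale: float = 0.2
    prevalence: float = 0.1
    seed: int = 0
    # ---- secondary knobs -------------------------------------------------
    #: distribution of per-SNP metabolite effects: "equal" draws fixed
    #: magnitudes with random signs (controlled instrument strength),
    #: "normal" draws N(0,1) effects before variance scaling.
    effect_size_dist: Literal["equal", "normal"] = "equal"
    #: add continuous dosage noise (imputed-dosage style) to genotypes
    dosage_noise: bool = False
    #: tie the first principal-component column to genotypes (confounding
    #: stress test); off by default so covariates are genotype-independent
    confound_pcs: bool = False
    age_effect: float = 0.01
    sex_effect: float = 0.2
    phecode: str = "574.1"
    #: probability that a non-case individual receives a single event for a
    #: closely related code (lands in the exclusion range of the target)
    related_code_rate: float = 0.02
    #: probability per case of one extra event row beyond the mandatory two
    event_jitter: float = 0.0

    def __post_init__(self) -> None:
        counts = {
            "n_discovery": self.n_discovery,
            "n_exposure_gwas": self.n_exposure_gwas,
            "n_outcome_gwas": self.n_outcome_gwas,
            "n_variants": self.n_variants,
            "n_ld_blocks": self.n_ld_blocks,
            "n_metabolites": self.n_metabolites,
            "snps_per_metabolite": self.snps_per_metabolite,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.n_pleiotropic < 0:
            raise ValueError("n_pleiotropic must be >= 0")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.h2_metabolite < 1.0:
            raise ValueError("h2_metabolite must lie in [0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError("pleiotropy_mode must be 'balanced' or 'directional'")
        if self.effect_size_dist not in ("equal", "normal"):
            raise ValueError("effect_size_dist must be 'equal' or 'normal'")
        if self.snps_per_metabolite > self.n_variants:
            raise ValueError("snps_per_metabolite cannot exceed n_variants")
        if self.n_ld_blocks > self.n_variants:
            raise ValueError("n_ld_blocks cannot exceed n_variants")


@dataclass
class PipelineConfig:
    """Analysis thresholds, one named default per stage gate."""

    #: GWAS-significance cut used when deriving PGS weights
    pgs_snp_p: float = 5e-8
    #: suggestive-significance cut for MR instrument candidates
    instrument_p: float = 5e-6
    clump_r2: float = 0.05
    clump_kb: float = 1000.0
    fdr: float = 0.05
    min_cases: int = 100
    min_instances: int = 2
    #: minimum independent SNPs for an instrument to enter replication
    min_snps_validation: int = 3
    #: Cochran's Q heterogeneity gate (p below this routes to MR-PRESSO)
    het_p: float = 0.05
    #: per-SNP outlier call threshold in the MR-PRESSO outlier test
    outlier_alpha: float = 0.05
    presso_nsim: int = 5000
    wm_boot: int = 2000
    #: scope of the BH correction in the MR screen: within each phenotype
    #: across metabolites ("within_phenotype") or over all pairs ("global")
    fdr_scope: Literal["within_phenotype", "global"] = "within_phenotype"
    #: policy for clump candidates absent from the LD source
    ld_missing_policy: Literal["drop", "assume_independent"] = "assume_independent"
    #: palindromic-SNP handling during harmonization
    palindromic_policy: Literal["frequency", "drop"] = "frequency"
    palindromic_maf: float = 0.42

    def __post_init__(self) -> None:
        for name in ("pgs_snp_p", "instrument_p", "fdr", "het_p", "outlier_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must lie in [0, 1]")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")
        if self.min_cases < 1 or self.min_instances < 1 or self.min_snps_validation < 1:
            raise ValueError("count thresholds must be >= 1")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_yaml(cfg: SimulationConfig | PipelineConfig, path: str | Path) -> None:
    """Serialize a config dataclass to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def load_yaml(path: str | Path, kind: type) -> SimulationConfig | PipelineConfig:
    """Load a config dataclass of type ``kind`` from YAML, applying defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(kind)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys for {kind.__name__}: {sorted(unknown)}")
    if "maf_range" in raw and raw["maf_range"] is not None:
        raw["maf_range"] = tuple(raw["maf_range"])
    return kind(**raw)
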