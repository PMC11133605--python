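"""Readers, writers and validated record types for every format the
pipeline touches.

Dialects
--------
* genotypes: VCF 4.x (GT, alt-allele dosage) or a dosage TSV with columns
  ``variant chrom pos ref alt eaf`` followed by one column per sample
  (variants as rows, ``NA`` for missing);
* summary statistics: TSV with header
  ``variant chrom pos effect_allele other_allele eaf beta se p n``;
* score models (PLINK-score style): TSV
  ``variant chrom pos ref alt effect_allele weight``;
* PheCode events: TSV ``individual_id phecode count``;
* covariates: TSV ``individual_id age sex PC1..PC10``;
* PheCode map: TSV ``phecode exclusion_low exclusion_high`` (one row per
  exclusion interval, several rows per code allowed).

Coordinates are 1-based, inclusive (VCF convention) everywhere. Alt-allele
dosage is the canonical genotype encoding; missing dosages are flagged at
the boundary and resolved by the PGS engine, never imputed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantKey",
    "ScoreEntry",
    "ScoreModel",
    "GenotypePanel",
    "PhecodeMap",
    "SUMMARY_COLUMNS",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "read_score_model",
    "write_score_model",
    "read_summary_stats",
    "write_summary_stats",
    "validate_summary_stats",
    "read_events",
    "write_events",
    "read_covariates",
    "write_covariates",
    "read_phecode_map",
    "write_phecode_map",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PALINDROMES = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def complement(allele: str) -> str:
    """Strand complement of a SNP allele string."""
    return allele.translate(_COMPLEMENT)


@dataclass(frozen=True)
class VariantKey:
    """Identity of a SNP: chromosome, 1-based position and allele pair."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for a in (self.ref, self.alt):
            if not a or any(c not in "ACGT" for c in a):
                raise ValueError(f"invalid SNP allele {a!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.ref, self.alt}) in _PALINDROMES

    def match(self, other: "VariantKey") -> str | None:
        """How ``other`` aligns to this key.

        Returns ``"direct"`` when the allele sets agree as written,
        ``"complement"`` when they agree after strand complement, and
        ``None`` when (chrom, pos) differ or the allele pairs are
        irreconcilable.
        """
        if (self.chrom, self.pos) != (other.chrom, other.pos):
            return None
        mine = {self.ref, self.alt}
        if mine == {other.ref, other.alt}:
            return "direct"
        if mine == {complement(other.ref), complement(other.alt)}:
            return "complement"
        return None


@dataclass(frozen=True)
class ScoreEntry:
    key: VariantKey
    effect_allele: str
    weight: float


@dataclass
class ScoreModel:
    """One metabolite's genetic predictor: SNPs, effect alleles, weights."""

    metabolite_id: str
    entries: list[ScoreEntry]
    source_p_threshold: float = 5e-8

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for e in self.entries:
            if e.effect_allele not in (e.key.ref, e.key.alt):
                raise ValueError(
                    f"{self.metabolite_id}: effect allele {e.effect_allele} not in "
                    f"{{{e.key.ref},{e.key.alt}}} at {e.key.chrom}:{e.key.pos}"
                )
            if not math.isfinite(e.weight):
                raise ValueError(f"{self.metabolite_id}: non-finite weight at {e.key}")
            kk = (e.key.chrom, e.key.pos, frozenset({e.key.ref, e.key.alt}))
            if kk in seen:
                raise ValueError(f"{self.metabolite_id}: duplicate variant {e.key}")
            seen.add(kk)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GenotypePanel:
    """Alt-allele dosage matrix (individuals x variants) plus metadata.

    ``variants`` carries columns ``variant chrom pos ref alt eaf``;
    ``missing`` is a boolean mask aligned with ``dosages`` (missing entries
    hold 0 in ``dosages`` and are resolved downstream).
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows must match sample_ids")
        if m != len(self.variants):
            raise ValueError("dosage columns must match variant table")
        if self.missing is None:
            self.missing = np.zeros_like(self.dosages, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants["variant"])}

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), str(r.variant))
            for r in self.variants.itertuples()
        ]

    def empirical_eaf(self) -> np.ndarray:
        """Alt-allele frequency from observed (non-missing) dosages."""
        d = np.where(self.missing, np.nan, self.dosages)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0


@dataclass
class PhecodeMap:
    """A PheCode with its exclusion ranges and analysis floors.

    Exclusion ranges are closed numeric intervals on the PheCode axis
    (v1.2-style decimal codes); the code itself always belongs to its own
    exclusion range.
    """

    phecode: str
    exclusion_range: list[tuple[float, float]] = field(default_factory=list)
    min_cases: int = 100
    min_instances: int = 2

    def __post_init__(self) -> None:
        own = float(self.phecode)
        if not any(lo <= own <= hi for lo, hi in self.exclusion_range):
            warnings.warn(
                f"PheCode {self.phecode}: exclusion range did not contain the code "
                "itself; adding it",
                stacklevel=2,
            )
            self.exclusion_range.append((own, own))

    def excludes(self, code: str) -> bool:
        try:
            x = float(code)
        except ValueError:
            return False
        return any(lo <= x <= hi for lo, hi in self.exclusion_range)


# ---------------------------------------------------------------------------
# genotypes


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    mat = panel.dosages.T.astype(object)
    mat[panel.missing.T] = "NA"
    samples = pd.DataFrame(mat, columns=panel.sample_ids)
    df = pd.concat([panel.variants.reset_index(drop=True), samples], axis=1)
    df.to_csv(path, sep="\t", index=False)


def _read_dosage_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant", "chrom", "pos", "ref", "alt", "eaf"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    raw = df[sample_ids].to_numpy(dtype=object).T
    missing = np.zeros(raw.shape, dtype=bool)
    dos = np.zeros(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = raw[i, j]
            if isinstance(v, str) and v.strip().upper() in ("NA", "."):
                missing[i, j] = True
            else:
                try:
                    x = float(v)
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"{path}: malformed dosage at line {j + 2}, sample "
                        f"{sample_ids[i]}: {v!r}"
                    ) from exc
                if math.isnan(x):
                    missing[i, j] = True
                elif not 0.0 <= x <= 2.0:
                    raise ValueError(
                        f"{path}: dosage {x} outside [0, 2] at line {j + 2}"
                    )
                else:
                    dos[i, j] = x
    return GenotypePanel(sample_ids, df[meta_cols].reset_index(drop=True), dos, missing)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT calls from integer-valued dosages.

    Non-integer dosages (dosage-noise panels) are rounded to the nearest
    hard call; missing entries become ``./.``.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.sample_ids),
    ]
    for j, r in enumerate(panel.variants.itertuples()):
        calls = []
        for i in range(panel.n_individuals):
            if panel.missing[i, j]:
                calls.append("./.")
            else:
                calls.append(gt_map[int(round(panel.dosages[i, j]))])
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.variant}\t{r.ref}\t{r.alt}\t.\t.\t.\tGT\t"
            + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf(path: Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, dosage_cols, missing_cols = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}")
        gts = np.asarray(rec.gt_types, dtype=float)  # 0,1,2 copies alt; 3 missing
        miss = gts == 3
        gts[miss] = 0.0
        rows.append(
            {
                "variant": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "eaf": float(np.mean(gts[~miss]) / 2.0) if (~miss).any() else np.nan,
            }
        )
        dosage_cols.append(gts)
        missing_cols.append(miss)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(sample_ids), 0))
    missing = np.column_stack(missing_cols) if missing_cols else np.empty((len(sample_ids), 0), bool)
    return GenotypePanel(sample_ids, variants, dosages, missing)


def read_genotypes(path: str | Path, format: Literal["vcf", "dosage_tsv"] | None = None) -> GenotypePanel:
    """Read a genotype panel from VCF or dosage TSV.

    Dosages are counted on the alt allele; missing genotypes are flagged in
    ``panel.missing`` and left for the downstream missing-dosage policy.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# score models


def write_score_model(model: ScoreModel, path: str | Path) -> None:
    rows = [
        {
            "variant": e.key.id or f"{e.key.chrom}:{e.key.pos}",
            "chrom": e.key.chrom,
            "pos": e.key.pos,
            "ref": e.key.ref,
            "alt": e.key.alt,
            "effect_allele": e.effect_allele,
            "weight": e.weight,
        }
        for e in model.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_score_model(path: str | Path, metabolite_id: str | None = None,
                     source_p_threshold: float = 5e-8) -> ScoreModel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["variant", "chrom", "pos", "ref", "alt", "effect_allele", "weight"]
    for c in required:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    if not np.issubdtype(df["weight"].dtype, np.number):
        bad = df.index[pd.to_numeric(df["weight"], errors="coerce").isna()]
        raise ValueError(f"{path}: non-numeric weight at line {bad[0] + 2}")
    entries = [
        ScoreEntry(
            VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), str(r.variant)),
            str(r.effect_allele),
            float(r.weight),
        )
        for r in df.itertuples()
    ]
    name = metabolite_id if metabolite_id is not None else path.stem
    return ScoreModel(name, entries, source_p_threshold)


# ---------------------------------------------------------------------------
# summary statistics

SUMMARY_COLUMNS = [
    "variant", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]


def validate_summary_stats(df: pd.DataFrame, p_tol: float | None = 1e-6,
                           source: str = "summary stats") -> pd.DataFrame:
    """Validate a summary-statistic table against its type invariants.

    Rejects non-positive SEs, p-values outside (0, 1], EAFs outside [0, 1]
    and, when ``p_tol`` is not ``None``, p-values inconsistent with the
    two-sided normal p implied by |beta/se| beyond ``p_tol``.
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    if (df["se"] <= 0).any():
        i = int(np.argmax((df["se"] <= 0).to_numpy()))
        raise ValueError(f"{source}: non-positive se at row {i} (variant {df['variant'].iloc[i]})")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError(f"{source}: p-values must lie in (0, 1]")
    if ((df["eaf"] < 0) | (df["eaf"] > 1)).any():
        raise ValueError(f"{source}: eaf must lie in [0, 1]")
    if p_tol is not None:
        z = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
        implied = 2.0 * stats.norm.sf(z)
        bad = np.abs(implied - df["p"].to_numpy()) > p_tol
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"{source}: p inconsistent with beta/se at variant "
                f"{df['variant'].iloc[i]} (stated {df['p'].iloc[i]:.3g}, "
                f"implied {implied[i]:.3g})"
            )
    return df


def read_summary_stats(path: str | Path, p_tol: float | None = 1e-6) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_summary_stats(df, p_tol=p_tol, source=str(path))


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# events / covariates / phecode map


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "phecode": str})
    for c in ("individual_id", "phecode", "count"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    if (df["count"] < 1).any():
        raise ValueError(f"{path}: event counts must be >= 1")
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df[["individual_id", "phecode", "count"]].to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'individual_id'")
    return df.set_index("individual_id")


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_phecode_map(path: str | Path, min_cases: int = 100,
                     min_instances: int = 2) -> list[PhecodeMap]:
    df = pd.read_csv(path, sep="\t", dtype={"phecode": str})
    for c in ("phecode", "exclusion_low", "exclusion_high"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    out = []
    for code, grp in df.groupby("phecode", sort=True):
        ranges = [(float(r.exclusion_low), float(r.exclusion_high)) for r in grp.itertuples()]
        out.append(PhecodeMap(str(code), ranges, min_cases=min_cases, min_instances=min_instances))
    return out


def write_phecode_map(maps: Iterable[PhecodeMap], path: str | Path) -> None:
    rows = [
        {"phecode": m.phecode, "exclusion_low": lo, "exclusion_high": hi}
        for m in maps
        for lo, hi in m.exclusion_range
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
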