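"""Polygenic scores, PheCode case/control assembly, the PheWAS scan and
per-variant association statistics.

The PGS is the classical weighted allele score: for individual *i*,
``score_i = sum_j w_j * d_ij`` where ``d_ij`` is the effect-allele dosage.
Scores are standardized to SD 1 before association so PheWAS effect sizes
are log-odds per SD of score and comparable across metabolites.  Case
status follows the two-instance rule (>= ``min_instances`` events of the
target code); individuals carrying any closely related code are excluded
from the control pool, and controls must fall inside the observed case age
window.  Association models are maximum-likelihood logistic regressions
(Wald normal p-values); Benjamini–Hochberg FDR is applied within each
phenotype across metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .dataio import GenotypePanel, PhecodeMap, ScoreModel, SUMMARY_COLUMNS, complement

__all__ = [
    "PgsVector",
    "CaseControlSet",
    "LogisticFit",
    "InstrumentError",
    "compute_pgs",
    "assemble_case_control",
    "fit_logistic",
    "phewas_scan",
    "snp_outcome_gwas",
    "linear_gwas",
    "bh_adjust",
]


class InstrumentError(ValueError):
    """No usable variants for a score or instrument."""


@dataclass
class PgsVector:
    """Per-individual raw polygenic score for one metabolite."""

    metabolite_id: str
    sample_ids: list[str]
    values: np.ndarray
    n_variants_used: int
    n_missing_handled: int

    def __post_init__(self) -> None:
        if len(self.values) != len(self.sample_ids):
            raise ValueError("score length must equal cohort size")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def standardized(self) -> np.ndarray:
        sd = float(np.std(self.values))
        if sd == 0.0:
            raise ValueError(
                f"{self.metabolite_id}: constant score cannot be standardized")
        return (self.values - self.values.mean()) / sd

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids, name=self.metabolite_id)


@dataclass
class CaseControlSet:
    """Case/control/excluded partition of a cohort for one PheCode."""

    phecode: str
    case_ids: list[str]
    control_ids: list[str]
    excluded_ids: list[str]
    age_window: tuple[float, float] | None
    analyzable: bool = True

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


@dataclass
class LogisticFit:
    beta: float
    se: float
    p: float
    converged: bool
    reason: str | None = None
    nobs: int = 0


def compute_pgs(panel: GenotypePanel, model: ScoreModel,
                missing_policy: str = "mean_impute") -> PgsVector:
    """Weighted allele score of ``model`` over the panel.

    Score entries are matched to panel variants by (chrom, pos) and allele
    set, directly or after strand complement.  ``mean_impute`` replaces a
    missing effect-allele dosage with twice the panel EAF of that allele
    (the PLINK convention); ``drop_variant`` removes any variant with
    missing calls from the score entirely.
    """
    if missing_policy not in ("mean_impute", "drop_variant"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    by_pos = {(k.chrom, k.pos): i for i, k in enumerate(panel.keys())}
    panel_keys = panel.keys()
    eaf = panel.empirical_eaf()
    raw = np.zeros(panel.n_individuals)
    used, n_missing, unmatched = 0, 0, []
    for e in model.entries:
        j = by_pos.get((e.key.chrom, e.key.pos))
        how = panel_keys[j].match(e.key) if j is not None else None
        if how is None:
            unmatched.append(e.key)
            continue
        effect = e.effect_allele if how == "direct" else complement(e.effect_allele)
        d = panel.dosages[:, j].copy()
        miss = panel.missing[:, j]
        if effect == panel_keys[j].ref:
            d = 2.0 - d
            fill = 2.0 * (1.0 - eaf[j])
        else:
            fill = 2.0 * eaf[j]
        if miss.any():
            if missing_policy == "drop_variant":
                n_missing += int(miss.sum())
                continue
            d[miss] = fill
            n_missing += int(miss.sum())
        raw += e.weight * d
        used += 1
    if used == 0:
        raise InstrumentError(
            f"{model.metabolite_id}: no score variants present in panel; "
            f"missing keys: {[f'{k.chrom}:{k.pos}' for k in unmatched]}")
    return PgsVector(model.metabolite_id, list(panel.sample_ids), raw, used, n_missing)


def assemble_case_control(events: pd.DataFrame, map_entry: PhecodeMap,
                          covariates: pd.DataFrame) -> CaseControlSet:
    """Partition the cohort into cases, controls and exclusions.

    Case: at least ``min_instances`` summed event counts of the target
    code.  Excluded: any event inside the exclusion range without meeting
    the case rule, or age outside the observed case age window.  Control:
    everyone else.
    """
    code = map_entry.phecode
    target = events[events["phecode"] == code]
    counts = target.groupby("individual_id")["count"].sum()
    cases = set(counts.index[counts >= map_entry.min_instances])
    in_range = set(
        events.loc[events["phecode"].map(map_entry.excludes), "individual_id"])
    cohort = list(covariates.index)
    if not cases:
        return CaseControlSet(code, [], [], list(cohort), None, analyzable=False)
    age = covariates["age"]
    case_ids = [i for i in cohort if i in cases]
    lo, hi = float(age.loc[case_ids].min()), float(age.loc[case_ids].max())
    controls, excluded = [], []
    for i in cohort:
        if i in cases:
            continue
        if i in in_range or not (lo <= float(age.loc[i]) <= hi):
            excluded.append(i)
        else:
            controls.append(i)
    analyzable = len(case_ids) >= map_entry.min_cases
    return CaseControlSet(code, case_ids, controls, excluded, (lo, hi), analyzable)


def fit_logistic(y: np.ndarray, x: np.ndarray,
                 covariates: np.ndarray | pd.DataFrame | None = None,
                 maxiter: int = 25, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression of ``y`` on ``x`` plus
    covariates; returns the Wald statistics for the ``x`` coefficient.

    Separation or non-convergence yields a flagged (``converged=False``)
    result rather than an exception; a rank-deficient design raises.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (constant exposure?)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=0,
                warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return LogisticFit(np.nan, np.nan, np.nan, False, f"separation: {exc}", len(y))
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not res.mle_retvals.get("converged", False):
        return LogisticFit(beta, se, np.nan, False, "no convergence", len(y))
    if not np.isfinite(se) or se == 0.0 or abs(beta) > 50:
        return LogisticFit(beta, se, np.nan, False, "unstable fit", len(y))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return LogisticFit(beta, se, max(p, np.nextafter(0, 1)), True, None, len(y))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def phewas_scan(pgs_vectors: list[PgsVector] | dict[str, PgsVector],
                cc_sets: dict[str, CaseControlSet] | list[CaseControlSet],
                covariates: pd.DataFrame, fdr: float = 0.05,
                fdr_scope: str = "within_phenotype") -> pd.DataFrame:
    """Associate every metabolite PGS with every analyzable phenotype.

    Per cell: logistic regression of case status on the standardized score,
    adjusting for age and sex.  BH adjustment runs within each phenotype
    across metabolites (or globally with ``fdr_scope="global"``);
    non-converged fits are flagged and left out of the adjustment so they
    cannot deflate the step-up denominator.
    """
    if isinstance(pgs_vectors, dict):
        pgs_vectors = list(pgs_vectors.values())
    if isinstance(cc_sets, list):
        cc_sets = {c.phecode: c for c in cc_sets}
    adj_cols = [c for c in ("age", "sex") if c in covariates.columns]
    rows = []
    for code, cc in cc_sets.items():
        if not cc.analyzable:
            continue
        ids = cc.case_ids + cc.control_ids
        y = np.concatenate([np.ones(cc.n_cases), np.zeros(cc.n_controls)])
        cov = covariates.loc[ids, adj_cols].to_numpy()
        for pgs in pgs_vectors:
            try:
                z = pd.Series(pgs.standardized(), index=pgs.sample_ids)
            except ValueError as exc:
                rows.append({"metabolite_id": pgs.metabolite_id, "phecode": code,
                             "beta": np.nan, "se": np.nan, "p": np.nan,
                             "n_cases": cc.n_cases, "n_controls": cc.n_controls,
                             "converged": False, "reason": str(exc)})
                continue
            fit = fit_logistic(y, z.loc[ids].to_numpy(), cov)
            rows.append({"metabolite_id": pgs.metabolite_id, "phecode": code,
                         "beta": fit.beta, "se": fit.se, "p": fit.p,
                         "n_cases": cc.n_cases, "n_controls": cc.n_controls,
                         "converged": fit.converged, "reason": fit.reason})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    out["q"] = np.nan
    ok = out["converged"].to_numpy()
    if fdr_scope == "global":
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    else:
        for code in out["phecode"].unique():
            sel = ok & (out["phecode"] == code).to_numpy()
            if sel.any():
                out.loc[sel, "q"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def _as_case_vector(panel: GenotypePanel, y_or_cc, covariates: pd.DataFrame):
    """Resolve a binary outcome aligned with panel rows, subsetting to the
    case/control universe when a CaseControlSet is given."""
    if isinstance(y_or_cc, CaseControlSet):
        ids = y_or_cc.case_ids + y_or_cc.control_ids
        pos = {s: i for i, s in enumerate(panel.sample_ids)}
        idx = np.array([pos[i] for i in ids])
        y = np.concatenate([np.ones(y_or_cc.n_cases), np.zeros(y_or_cc.n_controls)])
        return idx, y, covariates.loc[ids]
    y = np.asarray(y_or_cc, dtype=float)
    if len(y) != panel.n_individuals:
        raise ValueError("outcome length must match panel individuals")
    return np.arange(panel.n_individuals), y, covariates


def snp_outcome_gwas(panel: GenotypePanel, y_or_cc, covariates: pd.DataFrame,
                     variants: list[str] | None = None) -> pd.DataFrame:
    """Per-variant additive logistic regression of case status on alt
    dosage, adjusted for age, sex and the 10 principal components.

    Returns a summary-statistic table in the standard dialect (effect
    allele = alt).  Monomorphic or non-converged variants are flagged and
    omitted from the table; their ids are kept in ``df.attrs['flagged']``.
    """
    idx, y, cov = _as_case_vector(panel, y_or_cc, covariates)
    adj_cols = [c for c in cov.columns if c in ("age", "sex") or c.startswith("PC")]
    C = cov[adj_cols].to_numpy()
    vindex = panel.variant_index()
    if variants is None:
        variants = list(panel.variants["variant"])
    n = len(y)
    rows, flagged = [], []
    for vid in variants:
        j = vindex[vid]
        d = panel.dosages[idx, j]
        meta = panel.variants.iloc[j]
        if np.var(d) == 0.0:
            flagged.append((vid, "monomorphic"))
            continue
        fit = fit_logistic(y, d, C)
        if not fit.converged:
            flagged.append((vid, fit.reason or "failed"))
            continue
        rows.append({
            "variant": vid, "chrom": meta["chrom"], "pos": int(meta["pos"]),
            "effect_allele": meta["alt"], "other_allele": meta["ref"],
            "eaf": float(d.mean() / 2.0), "beta": fit.beta, "se": fit.se,
            "p": fit.p, "n": n,
        })
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    out.attrs["flagged"] = flagged
    return out


def linear_gwas(panel: GenotypePanel, y: np.ndarray,
                variants: list[str] | None = None) -> pd.DataFrame:
    """Vectorized per-variant simple linear regression of a quantitative
    trait on alt dosage (normal-theory two-sided p).

    This is the summary-statistic generator for quantitative exposures;
    monomorphic variants are dropped and recorded in
    ``df.attrs['flagged']``.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != panel.n_individuals:
        raise ValueError("trait length must match panel individuals")
    if variants is None:
        sel = np.arange(panel.n_variants)
    else:
        vindex = panel.variant_index()
        sel = np.array([vindex[v] for v in variants])
    X = panel.dosages[:, sel]
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    poly = sxx == 0.0
    sxx_safe = np.where(poly, 1.0, sxx)
    sxy = xc.T @ yc
    beta = sxy / sxx_safe
    rss = (yc ** 2).sum() - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    z = np.where(se > 0, np.abs(beta) / np.where(se > 0, se, 1.0), np.inf)
    p = np.maximum(2.0 * stats.norm.sf(z), np.nextafter(0, 1))
    meta = panel.variants.iloc[sel]
    out = pd.DataFrame({
        "variant": meta["variant"].to_numpy(),
        "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(),
        "effect_allele": meta["alt"].to_numpy(),
        "other_allele": meta["ref"].to_numpy(),
        "eaf": X.mean(axis=0) / 2.0,
        "beta": beta, "se": se, "p": p, "n": n,
    })
    out.attrs["flagged"] = [(v, "monomorphic") for v in out.loc[poly, "variant"]]
    return out[~poly].reset_index(drop=True)
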