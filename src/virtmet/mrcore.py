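"""Two-sample Mendelian randomization estimators and heterogeneity
diagnostics, written from scratch on the summary-statistic scale.

Notation: for SNP *j*, gamma_j / sigma_Xj are the exposure association and
its SE, Gamma_j / sigma_Yj the outcome association and its SE.  The Wald
ratio is ``beta_j = Gamma_j / gamma_j`` with first-order SE
``sigma_Yj / |gamma_j|``; the inverse-variance weights are
``w_j = gamma_j^2 / sigma_Yj^2``.  Estimators:

* IVW — ``beta = sum(w_j beta_j) / sum(w_j)``; the multiplicative
  random-effects variant inflates the fixed-effect SE by
  ``max(1, sqrt(Q / (n - 1)))`` where Q is Cochran's statistic, so the SE
  never shrinks below the fixed-effect one.
* MR-Egger — weighted regression of Gamma_j on gamma_j with a free
  intercept (weights 1/sigma_Yj^2) after orienting gamma_j >= 0; the
  intercept estimates average directional pleiotropy and SEs carry the
  same multiplicative overdispersion floor with n - 2 degrees of freedom.
* Weighted median — the Wald ratio at the point where cumulative
  normalized weight crosses one half (ties at the boundary average the
  bracketing ratios); its SE comes from a parametric bootstrap.

All p-values are two-sided normal, the large-sample GWAS convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import HarmonizedInstrument
from .scores import InstrumentError

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "method_consistency",
]

_Z95 = 1.96


def _two_sided_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else np.nan


@dataclass
class MREstimate:
    """A causal-effect estimate (log-OR outcome per unit exposure)."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - _Z95 * self.se, self.beta + _Z95 * self.se)


@dataclass
class HeterogeneityResult:
    """Cochran's Q diagnostic for instrument heterogeneity."""

    Q: float
    df: int
    p_het: float

    @property
    def phi(self) -> float:
        """Multiplicative overdispersion Q/df."""
        return self.Q / self.df if self.df > 0 else np.nan


def _ratios_weights(inst: HarmonizedInstrument):
    gamma, se_x, Gamma, se_y = inst.arrays()
    if np.any(gamma == 0.0):
        bad = inst.snps.loc[gamma == 0.0, "variant"].tolist()
        raise InstrumentError(f"zero exposure effect for {bad}: Wald ratio undefined")
    ratios = Gamma / gamma
    weights = gamma ** 2 / se_y ** 2
    return ratios, weights, gamma, se_x, Gamma, se_y


def wald_ratio(gamma: float, se_x: float, Gamma: float, se_y: float) -> MREstimate:
    """Single-SNP causal estimate: ratio of outcome to exposure effect with
    first-order SE ``se_y / |gamma|``."""
    if gamma == 0.0:
        raise InstrumentError("zero exposure effect: Wald ratio undefined")
    beta = Gamma / gamma
    se = se_y / abs(gamma)
    return MREstimate("wald", float(beta), float(se), _two_sided_p(beta, se), 1)


def ivw(inst: HarmonizedInstrument,
        model: str = "multiplicative_random") -> tuple[MREstimate, HeterogeneityResult | None]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    ``model="fixed"`` keeps the fixed-effect SE; the default multiplicative
    random-effects model scales it by ``max(1, sqrt(Q/(n-1)))``.  With a
    single SNP the estimate collapses to the Wald ratio and Q is undefined
    (returned as ``None``).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    ratios, w, *_ = _ratios_weights(inst)
    n = inst.n_snps
    if model == "multiplicative_random" and n < 2:
        pass  # degenerates to fixed below; Q unavailable
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if n >= 2:
        Q = float(np.sum(w * (ratios - beta) ** 2))
        het = HeterogeneityResult(Q, n - 1, float(stats.chi2.sf(Q, n - 1)))
        scale = max(1.0, np.sqrt(Q / (n - 1))) if model == "multiplicative_random" else 1.0
    else:
        het = None
        scale = 1.0
    se = se_fixed * scale
    method = "ivw_re" if model == "multiplicative_random" else "ivw_fe"
    return MREstimate(method, beta, se, _two_sided_p(beta, se), n), het


def egger(inst: HarmonizedInstrument) -> tuple[MREstimate, HeterogeneityResult]:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept measuring average directional pleiotropy.

    SNPs are oriented so every exposure effect is non-negative before the
    fit (the InSIDE convention); SEs are inflated by the overdispersion
    floor ``max(1, sqrt(Q_egger/(n-2)))``.
    """
    if inst.n_snps < 3:
        raise InstrumentError("MR-Egger requires at least 3 SNPs")
    gamma, se_x, Gamma, se_y = inst.arrays()
    flip = np.sign(gamma)
    flip[flip == 0] = 1.0
    x = gamma * flip
    y = Gamma * flip
    w = 1.0 / se_y ** 2
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0.0:
        raise InstrumentError("MR-Egger: no variation in exposure effects")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    Q = float(np.sum(w * resid ** 2))
    n = inst.n_snps
    scale = max(1.0, np.sqrt(Q / (n - 2)))
    se_slope = float(np.sqrt(1.0 / sxx) * scale)
    se_int = float(np.sqrt(1.0 / sw + xbar ** 2 / sxx) * scale)
    est = MREstimate(
        "egger", slope, se_slope, _two_sided_p(slope, se_slope), n,
        intercept=intercept, intercept_se=se_int,
        intercept_p=_two_sided_p(intercept, se_int))
    het = HeterogeneityResult(Q, n - 2, float(stats.chi2.sf(Q, n - 2)))
    return est, het


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Wald ratio at the 50% point of cumulative normalized weight.

    Scan the ratios in ascending order accumulating normalized weight; the
    first ratio whose cumulative weight strictly exceeds one half is the
    estimate, and an exact hit at one half averages the two bracketing
    ratios.  A SNP carrying more than half the total weight therefore
    always returns its own ratio.
    """
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    cw = np.cumsum(weights[order]) / weights.sum()
    j = int(np.searchsorted(cw, 0.5, side="left"))
    if np.isclose(cw[j], 0.5) and j + 1 < len(r):
        return float(0.5 * (r[j] + r[j + 1]))
    return float(r[j])


def weighted_median(inst: HarmonizedInstrument, n_boot: int = 2000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Uses the IVW weights ``gamma^2/sigma_Y^2``; consistent when valid
    instruments carry at least half the total weight.  The bootstrap
    redraws (Gamma_j, gamma_j) from normal(observed, SE) ``n_boot`` times
    with a fixed seed.
    """
    if inst.n_snps < 3:
        raise InstrumentError("weighted median requires at least 3 SNPs")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ratios, w, gamma, se_x, Gamma, se_y = _ratios_weights(inst)
    beta = _weighted_median_point(ratios, w)
    rng = np.random.default_rng(seed)
    g_star = rng.normal(gamma, se_x, size=(n_boot, inst.n_snps))
    G_star = rng.normal(Gamma, se_y, size=(n_boot, inst.n_snps))
    g_star[g_star == 0.0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rb = G_star[b] / g_star[b]
        wb = g_star[b] ** 2 / se_y ** 2
        boots[b] = _weighted_median_point(rb, wb)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", beta, se, _two_sided_p(beta, se),
                      inst.n_snps)


def method_consistency(estimates: list[MREstimate]) -> bool:
    """Whether all point estimates share one sign (the agreement rule used
    when requiring "consistent findings" across MR methods).

    A single estimate is vacuously consistent.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    signs = {np.sign(e.beta) for e in estimates if e.beta != 0.0}
    return len(signs) <= 1
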