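"""MR-PRESSO: simulation-based pleiotropy residual sum of squares and
outlier diagnostics.

Three stages, all on the harmonized summary-statistic scale:

1. *Global test* — the observed residual sum of squares
   ``RSS = sum_j (Gamma_j - beta_(-j) gamma_j)^2 / sigma_Yj^2`` (with
   ``beta_(-j)`` the leave-one-out IVW estimate) is compared against a
   Monte-Carlo null built by redrawing ``Gamma*_j ~ N(beta_(-j) gamma_j,
   sigma_Yj)`` and ``gamma*_j ~ N(gamma_j, sigma_Xj)`` and recomputing the
   RSS each time.
2. *Outlier test* — each SNP's observed squared residual is compared to
   its own simulated null residuals; the per-SNP Monte-Carlo p is
   Bonferroni-adjusted over SNPs and calls below ``outlier_alpha`` are
   flagged.
3. *Distortion test* — the relative change of the IVW estimate after
   removing the flagged outliers is compared to the change produced by
   removing equally many random non-outlier SNPs.

All Monte-Carlo p-values use the (1 + k)/(1 + n_sim) estimator, so they
are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instruments import HarmonizedInstrument
from .mrcore import ivw
from .scores import InstrumentError

__all__ = [
    "PressoResult",
    "presso_global",
    "presso_outlier",
    "presso_distortion",
    "run_presso",
]


@dataclass
class PressoResult:
    """Bundle of the three MR-PRESSO stages for one instrument."""

    rss_obs: float
    p_global: float
    outlier_p: dict[str, float]
    outliers: list[str]
    beta_pre: float
    beta_post: float | None
    p_distortion: float | None
    n_sim: int
    seed: int


def _loo_ivw(ratios: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates beta_(-j), vectorized."""
    s1 = np.sum(w * ratios)
    s0 = np.sum(w)
    return (s1 - w * ratios) / (s0 - w)


def _residual_pieces(gamma: np.ndarray, se_y: np.ndarray, Gamma: np.ndarray):
    ratios = Gamma / gamma
    w = gamma ** 2 / se_y ** 2
    loo = _loo_ivw(ratios, w)
    resid2 = (Gamma - loo * gamma) ** 2 / se_y ** 2
    return loo, resid2


def _check(inst: HarmonizedInstrument, n_sim: int) -> None:
    if inst.n_snps < 4:
        raise InstrumentError("MR-PRESSO requires at least 4 SNPs")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for stable Monte-Carlo p-values")


def _simulate_null_resid2(inst: HarmonizedInstrument, n_sim: int,
                          seed: int) -> tuple[np.ndarray, np.ndarray]:
    """(observed per-SNP squared residuals, simulated n_sim x J matrix)."""
    gamma, se_x, Gamma, se_y = inst.arrays()
    loo, obs2 = _residual_pieces(gamma, se_y, Gamma)
    rng = np.random.default_rng(seed)
    J = inst.n_snps
    G_star = rng.normal(loo * gamma, se_y, size=(n_sim, J))
    g_star = rng.normal(gamma, se_x, size=(n_sim, J))
    g_star[g_star == 0.0] = np.finfo(float).tiny
    ratios = G_star / g_star
    w = g_star ** 2 / se_y ** 2
    s1 = np.sum(w * ratios, axis=1, keepdims=True)
    s0 = np.sum(w, axis=1, keepdims=True)
    loo_star = (s1 - w * ratios) / (s0 - w)
    sim2 = (G_star - loo_star * g_star) ** 2 / se_y ** 2
    return obs2, sim2


def presso_global(inst: HarmonizedInstrument, n_sim: int = 5000,
                  seed: int = 0) -> tuple[float, float]:
    """Global pleiotropy test; returns (observed RSS, Monte-Carlo p)."""
    _check(inst, n_sim)
    obs2, sim2 = _simulate_null_resid2(inst, n_sim, seed)
    rss_obs = float(obs2.sum())
    rss_star = sim2.sum(axis=1)
    p = float((1 + np.sum(rss_star >= rss_obs)) / (1 + n_sim))
    return rss_obs, p


def presso_outlier(inst: HarmonizedInstrument, n_sim: int = 5000, seed: int = 0,
                   outlier_alpha: float = 0.05) -> tuple[dict[str, float], list[str]]:
    """Per-SNP outlier test; returns (Bonferroni-adjusted p per SNP,
    flagged outliers)."""
    _check(inst, n_sim)
    obs2, sim2 = _simulate_null_resid2(inst, n_sim, seed)
    J = inst.n_snps
    raw = (1 + np.sum(sim2 >= obs2[None, :], axis=0)) / (1 + n_sim)
    adj = np.minimum(raw * J, 1.0)
    variants = list(inst.snps["variant"])
    outlier_p = dict(zip(variants, adj.astype(float)))
    outliers = [v for v, pj in outlier_p.items() if pj < outlier_alpha]
    return outlier_p, outliers


def presso_distortion(inst: HarmonizedInstrument, outliers: list[str],
                      n_sim: int = 5000, seed: int = 0) -> tuple[float, float, float]:
    """Distortion test; returns (beta_pre, beta_post, p_distortion).

    ``beta_post`` is the IVW estimate on the outlier-free instrument; the
    null removes random non-outlier subsets of the same size instead.
    """
    if not outliers:
        raise ValueError("distortion test requires a nonempty outlier set")
    if len(outliers) >= inst.n_snps:
        raise InstrumentError("cannot remove every SNP in the distortion test")
    beta_pre = ivw(inst)[0].beta
    clean = inst.drop_variants(set(outliers), "presso_outlier")
    beta_post = ivw(clean)[0].beta
    if beta_post == 0.0:
        raise InstrumentError("distortion undefined: outlier-free IVW estimate is 0")
    d_obs = (beta_pre - beta_post) / abs(beta_post)
    rng = np.random.default_rng(seed)
    non_out = [v for v in inst.snps["variant"] if v not in set(outliers)]
    k = len(outliers)
    if k >= len(non_out):
        raise InstrumentError("too few non-outlier SNPs for the distortion null")
    gamma, se_x, Gamma, se_y = inst.arrays()
    variants = list(inst.snps["variant"])
    non_idx = np.array([variants.index(v) for v in non_out])
    ratios = Gamma / gamma
    w = gamma ** 2 / se_y ** 2
    s1, s0 = np.sum(w * ratios), np.sum(w)
    d_null = np.empty(n_sim)
    for b in range(n_sim):
        drop = rng.choice(non_idx, size=k, replace=False)
        b_sub = (s1 - np.sum(w[drop] * ratios[drop])) / (s0 - np.sum(w[drop]))
        d_null[b] = (beta_pre - b_sub) / abs(b_sub) if b_sub != 0 else np.inf
    p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_sim))
    return float(beta_pre), float(beta_post), p


def run_presso(inst: HarmonizedInstrument, n_sim: int = 5000, seed: int = 0,
               outlier_alpha: float = 0.05) -> PressoResult:
    """Run the full three-stage MR-PRESSO workflow."""
    rss_obs, p_global = presso_global(inst, n_sim, seed)
    outlier_p, outliers = presso_outlier(inst, n_sim, seed, outlier_alpha)
    beta_pre = ivw(inst)[0].beta
    beta_post, p_dist = None, None
    if outliers and len(outliers) < inst.n_snps - 1:
        beta_pre, beta_post, p_dist = presso_distortion(inst, outliers, n_sim, seed)
    return PressoResult(rss_obs, p_global, outlier_p, outliers,
                        float(beta_pre), beta_post, p_dist, n_sim, seed)
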