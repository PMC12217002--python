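"""Heterogeneity, pleiotropy, outlier and power diagnostics.

Cochran's Q tests heterogeneity of the per-SNP ratio estimates; MR-PRESSO
detects horizontal pleiotropy via a parametric-bootstrap residual-sum test
(applicable only with more than 3 SNPs — with 3 or fewer the pipeline falls
back to the Egger intercept test); radial-IVW decomposes Q into per-SNP
contributions (modified second-order weights) and removes SNPs whose
contribution is individually significant; power for a binary outcome uses
the standard normal approximation of the published calculator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .instruments import HarmonizedSet


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    per_snp_p: list
    outlier_indices: list
    n_sim: int
    seed: int


@dataclass
class PowerResult:
    n: int
    r2: float
    case_fraction: float
    beta: float
    alpha: float
    power: float


def cochran_q(h: HarmonizedSet, theta: float):
    """Q = sum_i w_i (ratio_i - theta)^2 with w_i = (beta_exp_i/se_out_i)^2,
    referred to chi-square(n_snp - 1)."""
    if h.n_snp < 2:
        raise InsufficientDataError("Cochran's Q needs >= 2 SNPs", n=h.n_snp, required=2)
    bx, sx, by, sy = h.arrays()
    w = (bx / sy) ** 2
    q = float(np.sum(w * (by / bx - theta) ** 2))
    df = h.n_snp - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_ivw(bx, by, w):
    """Leave-one-out fixed-effect IVW estimates, vectorized.

    Accepts 1-D observed arrays or 2-D (n_sim x n_snp) simulated draws;
    returns theta_(-i) with matching shape.
    """
    num = w * bx * by
    den = w * bx ** 2
    tot_num = num.sum(axis=-1, keepdims=True)
    tot_den = den.sum(axis=-1, keepdims=True)
    return (tot_num - num) / (tot_den - den)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """MR-PRESSO global and outlier tests.

    The observed residual sum of squares (standardized leave-one-out IVW
    residuals) is compared with its parametric-bootstrap null, with effects
    resampled under the fitted model; per-SNP outlier p-values come from each
    SNP's simulated residual distribution, Bonferroni-corrected across SNPs.
    """
    if h.n_snp <= 3:
        raise InsufficientDataError(
            "MR-PRESSO requires more than 3 SNPs; fall back to the Egger "
            "intercept test", n=h.n_snp, required=4)
    bx, sx, by, sy = h.arrays()
    n = h.n_snp
    w = 1.0 / sy ** 2
    theta_loo = _loo_ivw(bx, by, w)
    obs_resid2 = ((by - theta_loo * bx) / sy) ** 2
    rss_obs = float(obs_resid2.sum())

    rng = np.random.default_rng(seed)
    bx_sim = bx + sx * rng.standard_normal((n_sim, n))
    by_sim = theta_loo * bx + sy * rng.standard_normal((n_sim, n))
    theta_loo_sim = _loo_ivw(bx_sim, by_sim, w)
    sim_resid2 = ((by_sim - theta_loo_sim * bx_sim) / sy) ** 2
    rss_sim = sim_resid2.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(sim_resid2 >= obs_resid2, axis=0)) / (n_sim + 1)
    corrected = np.minimum(per_snp_p * n, 1.0)
    outliers = [int(i) for i in np.nonzero(corrected < 0.05)[0]]
    return PressoResult(global_rss=rss_obs, global_p=global_p,
                        per_snp_p=[float(p) for p in per_snp_p],
                        outlier_indices=outliers, n_sim=n_sim, seed=seed)


def radial_outliers(h: HarmonizedSet, alpha: float = 0.05):
    """Radial IVW outlier detection.

    Fit the radial regression (ratio_i * sqrt(w_i) on sqrt(w_i) through the
    origin) with modified second-order weights, decompose total Q into
    per-SNP chi-square(1) contributions, and flag SNPs with contribution
    p < alpha. Returns (outlier_indices, cleaned HarmonizedSet).
    """
    if h.n_snp < 3:
        raise InsufficientDataError("radial IVW needs >= 3 SNPs", n=h.n_snp, required=3)
    bx, sx, by, sy = h.arrays()
    ratio = by / bx
    w1 = bx ** 2 / sy ** 2  # first-order
    theta = float(np.sum(w1 * ratio) / np.sum(w1))
    # modified second-order weights evaluated at the current estimate
    w2 = 1.0 / (sy ** 2 / bx ** 2 + theta ** 2 * sx ** 2 / bx ** 2)
    theta = float(np.sum(w2 * ratio) / np.sum(w2))
    q_i = w2 * (ratio - theta) ** 2
    p_i = stats.chi2.sf(q_i, 1)
    outliers = [int(i) for i in np.nonzero(p_i < alpha)[0]]
    cleaned = h.drop_rows(outliers) if outliers else h
    return outliers, cleaned, {"q_total": float(q_i.sum()),
                               "q_contributions": q_i.tolist(), "theta": theta}


def power_binary(n: int, r2: float, case_fraction: float, beta: float,
                 alpha: float = 0.05) -> PowerResult:
    """Power of a two-sample MR test for a binary outcome:
    Phi(|beta| * sqrt(n * r2 * phi * (1 - phi)) - z_{1-alpha/2})."""
    for frac, name in ((r2, "r2"), (case_fraction, "case_fraction")):
        if not (0 < frac < 1):
            raise ValueError(f"{name} must be in (0, 1)")
    z_crit = stats.norm.ppf(1 - alpha / 2)
    ncp = abs(beta) * np.sqrt(n * r2 * case_fraction * (1 - case_fraction))
    return PowerResult(n=n, r2=r2, case_fraction=case_fraction, beta=beta,
                       alpha=alpha, power=float(stats.norm.cdf(ncp - z_crit)))
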