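"""Inverse-variance meta-analysis and two-step mediation.

Per-dataset causal estimates are pooled by fixed-effect (inverse-variance)
or DerSimonian-Laird random-effects meta-analysis. The pipeline's headline
model is fixed effects when the between-study Cochran Q p-value exceeds
0.05, random effects otherwise.

Mediation follows the product-of-coefficients decomposition of a total
effect c into the indirect path c' = a * b (exposure -> mediator ->
outcome) and the direct effect c - c'; the proportion mediated is c'/c on
the log-odds scale, with the first-order (Sobel) delta-method SE
sqrt(a^2 se_b^2 + b^2 se_a^2) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .estimators import MREstimate


@dataclass
class MetaResult:
    model: str  # fixed | random
    beta: float
    se: float
    pval: float
    q: float
    q_p: float
    i2: float
    tau2: float
    k: int


@dataclass
class MediationResult:
    c: float
    a: float
    b: float
    c_prime: float
    direct: float
    proportion: float | None
    se_c_prime: float
    p_mediation: float
    status: str = "ok"


def _norm_p(z: float) -> float:
    return float(np.clip(2 * stats.norm.sf(abs(z)), 1e-300, 1.0))


def _check(estimates) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) < 2:
        raise InsufficientDataError("meta-analysis needs >= 2 studies",
                                    n=len(estimates), required=2)
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    return beta, se


def _q_stats(beta, se):
    w = 1.0 / se ** 2
    pooled = np.sum(w * beta) / np.sum(w)
    q = float(np.sum(w * (beta - pooled) ** 2))
    df = len(beta) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, i2, w


def meta_fixed(estimates) -> MetaResult:
    """Fixed-effect pooling with weights 1/se^2."""
    beta, se = _check(estimates)
    q, df, i2, w = _q_stats(beta, se)
    pooled = float(np.sum(w * beta) / np.sum(w))
    se_p = float(1.0 / np.sqrt(np.sum(w)))
    return MetaResult("fixed", pooled, se_p, _norm_p(pooled / se_p),
                      q=q, q_p=float(stats.chi2.sf(q, df)), i2=i2, tau2=0.0,
                      k=len(beta))


def meta_random(estimates) -> MetaResult:
    """DerSimonian-Laird random effects:
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); equals the
    fixed model exactly when Q <= k-1."""
    beta, se = _check(estimates)
    q, df, i2, w = _q_stats(beta, se)
    c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (se ** 2 + tau2)
    pooled = float(np.sum(w_star * beta) / np.sum(w_star))
    se_p = float(1.0 / np.sqrt(np.sum(w_star)))
    return MetaResult("random", pooled, se_p, _norm_p(pooled / se_p),
                      q=q, q_p=float(stats.chi2.sf(q, df)), i2=i2,
                      tau2=float(tau2), k=len(beta))


def select_meta(estimates) -> MetaResult:
    """Headline model: fixed effects when the between-study Q p-value
    exceeds 0.05, random effects otherwise."""
    fixed = meta_fixed(estimates)
    return fixed if fixed.q_p > 0.05 else meta_random(estimates)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha / n_tests, reported to 4 significant digits."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(f"{alpha / n_tests:.4g}")


def benjamini_hochberg(pvals, alpha: float = 0.05):
    """Optional FDR alternative to Bonferroni: boolean rejections at level
    alpha by the step-up procedure."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    thresh = alpha * (np.arange(1, m + 1) / m)
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def mediate(c_meta: MetaResult, a_meta: MetaResult, b_est: MREstimate,
            second_order: bool = False) -> MediationResult:
    """Decompose the meta-analyzed total effect using the meta-analyzed
    exposure->mediator effect and the mediator->outcome MR estimate.

    All inputs must be on the same (oriented) scale. With c = 0 the
    proportion mediated is undefined and reported as missing.
    """
    a, se_a = a_meta.beta, a_meta.se
    b, se_b = b_est.beta, b_est.se
    c = c_meta.beta
    c_prime = a * b
    direct = c - c_prime
    var = a ** 2 * se_b ** 2 + b ** 2 * se_a ** 2
    if second_order:
        var += se_a ** 2 * se_b ** 2
    se_cp = float(np.sqrt(var))
    p_med = _norm_p(c_prime / se_cp) if se_cp > 0 else 1.0
    if c == 0:
        return MediationResult(c=c, a=a, b=b, c_prime=c_prime, direct=direct,
                               proportion=None, se_c_prime=se_cp,
                               p_mediation=p_med,
                               status="proportion undefined: total effect is 0")
    return MediationResult(c=c, a=a, b=b, c_prime=c_prime, direct=direct,
                           proportion=c_prime / c, se_c_prime=se_cp,
                           p_mediation=p_med)
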