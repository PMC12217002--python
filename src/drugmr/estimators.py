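"""Causal-effect estimation from harmonized summary statistics.

The consensus trio used by the pipeline is IVW, the weighted median, and
cML-MA (constrained maximum likelihood with model averaging); MR-Egger is
provided as the directional-pleiotropy diagnostic. Because the exposures are
drug-target gene effects and the drugs *inhibit* those targets, estimates are
negated before conversion to odds ratios (``orient_for_inhibition``), so an
OR < 1 reads as "inhibiting the target lowers outcome risk".

Two-sided p-values come from the normal distribution throughout, the usual
summary-data MR convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, StateError
from .instruments import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    method: str  # wald | ivw_fe | ivw_mre | egger | weighted_median | cml_ma
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    oriented_for_inhibition: bool = False
    status: str = "ok"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
            self.ci_high = self.beta + Z95 * self.se


@dataclass
class SignificanceCall:
    n_tests: int
    level: str  # significant | suggestive | null
    direction_consistent: bool
    pval: float


def _norm_p(z: float) -> float:
    return float(np.clip(2 * stats.norm.sf(abs(z)), 1e-300, 1.0))


def _require(h: HarmonizedSet, k: int, what: str) -> None:
    if h.n_snp < k:
        raise InsufficientDataError(f"{what} needs >= {k} SNPs, got {h.n_snp}",
                                    n=h.n_snp, required=k)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order
    (default) or second-order delta-method SE."""
    if beta_exp == 0:
        raise ValueError("wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    var = se_out ** 2 / beta_exp ** 2
    if second_order:
        var += beta_out ** 2 * se_exp ** 2 / beta_exp ** 4
    se = float(np.sqrt(var))
    return MREstimate("wald", float(beta), se, _norm_p(beta / se), 1)


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate: regression of beta_out on beta_exp
    through the origin with weights 1/se_out^2. The multiplicative
    random-effects model inflates the SE by sqrt(max(1, Q/(n-1)))."""
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    _require(h, 1, "IVW")
    bx, sx, by, sy = h.arrays()
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by) / denom)
    se = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    n = h.n_snp
    if model == "multiplicative_random" and n > 1:
        se *= float(np.sqrt(max(1.0, q / (n - 1))))
    method = "ivw_fe" if model == "fixed" else "ivw_mre"
    return MREstimate(method, beta, se, _norm_p(beta / se), n,
                      extras={"q": q, "q_df": n - 1,
                              "q_p": float(stats.chi2.sf(q, n - 1)) if n > 1 else np.nan})


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with an
    intercept (weights 1/se_out^2). The slope is the causal estimate; the
    intercept is the average directional pleiotropy (intercept p > 0.05 read
    as no evidence of directional pleiotropy)."""
    _require(h, 3, "MR-Egger")
    import statsmodels.api as sm
    bx, sx, by, sy = h.arrays()
    # orient so that all exposure effects are positive (standard Egger setup)
    sign = np.sign(bx)
    sign[sign == 0] = 1.0
    bx, by = bx * sign, by * sign
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy ** 2).fit()
    inter, slope = fit.params
    se_inter, se_slope = fit.bse
    resid = by - fit.fittedvalues
    q = float(np.sum((resid / sy) ** 2))
    return MREstimate("egger", float(slope), float(se_slope),
                      _norm_p(slope / se_slope), h.n_snp,
                      egger_intercept=float(inter),
                      egger_intercept_se=float(se_inter),
                      egger_intercept_p=_norm_p(inter / se_inter),
                      extras={"q": q, "q_df": h.n_snp - 2})


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios with inverse-variance
    weights; consistent when >= 50% of the weight comes from valid
    instruments. SE by seeded parametric bootstrap."""
    _require(h, 3, "weighted median")
    bx, sx, by, sy = h.arrays()

    def wm(bxi, byi):
        ratios = byi / bxi
        w = bxi ** 2 / sy ** 2  # first-order inverse variance of the ratio
        order = np.argsort(ratios)
        r, w_ = ratios[order], w[order]
        cum = np.cumsum(w_) - 0.5 * w_
        cum /= np.sum(w_)
        return float(np.interp(0.5, cum, r))

    beta = wm(bx, by)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = wm(bx + sx * rng.standard_normal(len(bx)),
                      by + sy * rng.standard_normal(len(by)))
    se = float(np.std(draws, ddof=1))
    return MREstimate("weighted_median", beta, se, _norm_p(beta / se), h.n_snp)


def cml_ma(h: HarmonizedSet, max_invalid: int | None = None,
           max_iter: int = 200) -> MREstimate:
    """Constrained maximum likelihood with model averaging.

    For each allowed number K of invalid instruments, a profile likelihood is
    maximized by coordinate descent: given theta, the K largest standardized
    residuals absorb unconstrained direct effects; given the invalid set,
    theta is the fixed-effect IVW of the valid set. Estimates are averaged
    over K with BIC weights (effective sample size n_snp); the SE combines
    within- and between-model variance.
    """
    _require(h, 3, "cML-MA")
    bx, sx, by, sy = h.arrays()
    n = h.n_snp
    if max_invalid is None:
        max_invalid = n // 2
    if max_invalid >= n:
        raise ValueError("max_invalid must be < n_snp")
    w = 1.0 / sy ** 2

    def ivw_subset(mask):
        denom = np.sum(w[mask] * bx[mask] ** 2)
        return float(np.sum(w[mask] * bx[mask] * by[mask]) / denom), float(1 / np.sqrt(denom))

    thetas, ses, bics, statuses = [], [], [], []
    for K in range(max_invalid + 1):
        valid = np.ones(n, dtype=bool)
        theta, se_k = ivw_subset(valid)
        converged = K == 0
        for _ in range(max_iter):
            resid2 = ((by - theta * bx) / sy) ** 2
            invalid_idx = np.argsort(-resid2, kind="stable")[:K]
            new_valid = np.ones(n, dtype=bool)
            new_valid[invalid_idx] = False
            theta_new, se_k = ivw_subset(new_valid)
            if np.array_equal(new_valid, valid) and abs(theta_new - theta) < 1e-12:
                theta = theta_new
                converged = True
                break
            valid, theta = new_valid, theta_new
        statuses.append(converged)
        nll2 = float(np.sum(((by[valid] - theta * bx[valid]) / sy[valid]) ** 2))
        bics.append(nll2 + K * np.log(n))
        thetas.append(theta)
        ses.append(se_k)

    bics = np.array(bics)
    wts = np.exp(-(bics - bics.min()) / 2)
    wts /= wts.sum()
    theta_ma = float(np.sum(wts * np.array(thetas)))
    se_ma = float(np.sqrt(np.sum(wts * (np.array(ses) ** 2
                                        + (np.array(thetas) - theta_ma) ** 2))))
    best_k = int(np.argmax(wts))
    resid2 = ((by - thetas[best_k] * bx) / sy) ** 2
    invalid_best = sorted(int(i) for i in np.argsort(-resid2, kind="stable")[:best_k])
    status = "ok" if all(statuses) else "non-convergence for some K"
    return MREstimate("cml_ma", theta_ma, se_ma, _norm_p(theta_ma / se_ma), n,
                      status=status,
                      extras={"bic_weights": wts.tolist(), "best_k": best_k,
                              "invalid_indices": invalid_best})


def orient_for_inhibition(e: MREstimate) -> MREstimate:
    """Negate the estimate (and swap/negate the CI) so that it describes
    pharmacological *inhibition* of the target; p is unchanged."""
    if e.oriented_for_inhibition:
        raise StateError("estimate already oriented for inhibition")
    return replace(e, beta=-e.beta, ci_low=-e.ci_high, ci_high=-e.ci_low,
                   oriented_for_inhibition=True)


def to_odds_ratio(beta: float, ci_low: float, ci_high: float):
    """Elementwise exponential reported to 3 decimals."""
    if not (ci_low <= beta <= ci_high):
        raise ValueError("CI must bracket the point estimate")
    return tuple(round(float(np.exp(v)), 3) for v in (beta, ci_low, ci_high))


def classify_significance(p: float, n_tests: int, directions) -> SignificanceCall:
    """The study's decision rule: significant iff p < 0.05/n_tests with all
    method estimates sharing one sign; suggestive for 0.05/n_tests <= p <
    0.05 with consistent signs; otherwise null."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    directions = [d for d in directions]
    if not directions:
        raise ValueError("directions must be non-empty")
    signs = {1 if d > 0 else (-1 if d < 0 else 0) for d in directions}
    consistent = len(signs) == 1 and 0 not in signs
    bonf = 0.05 / n_tests
    if p < bonf and consistent:
        level = "significant"
    elif p < 0.05 and consistent:
        level = "suggestive"
    else:
        level = "null"
    return SignificanceCall(n_tests=n_tests, level=level,
                            direction_consistent=consistent, pval=p)
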