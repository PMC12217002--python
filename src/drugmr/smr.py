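"""Summary-data-based MR (SMR) and the HEIDI test.

SMR tests whether gene expression and the outcome share an effect at the top
cis-eQTL: b_SMR = beta_GWAS / beta_eQTL at the top SNP, with the test
statistic T = z_GWAS^2 * z_eQTL^2 / (z_GWAS^2 + z_eQTL^2) on chi-square(1).
HEIDI (heterogeneity in dependent instruments) asks whether the b_SMR values
implied by surrounding SNPs in LD with the top SNP are mutually consistent:
under a single shared causal variant they are; under linkage (distinct
causal variants) they differ systematically and HEIDI rejects (p < 0.05).

SNP-selection constants follow the SMR software defaults: candidate cis SNPs
with eQTL p < 1.57e-3 and r^2 to the top SNP within [0.05, 0.9], capped at
20 by ascending eQTL p, at least 3 required; MAF > 0.01 on both tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import quad

from .sumstats import GeneRegion, LDMatrix, SummaryStats

HEIDI_P_EQTL = 1.57e-3
HEIDI_R2_RANGE = (0.05, 0.9)
HEIDI_MAX_SNPS = 20
HEIDI_MIN_SNPS = 3


@dataclass
class SMRResult:
    probe_id: str
    top_snp: str | None
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0
    status: str = "ok"


def _maf_mask(s: SummaryStats, min_maf: float = 0.01):
    eaf = s.table["eaf"]
    return np.minimum(eaf, 1 - eaf) > min_maf


def smr_test(eqtl: SummaryStats, gwas: SummaryStats, region: GeneRegion,
             p_eqtl_threshold: float = 5e-8, window_kb: int = 2000,
             min_maf: float = 0.01) -> SMRResult:
    """SMR at the top cis-eQTL (smallest eQTL p in the cis window shared with
    the GWAS). Returns a not-testable status when no SNP passes the eQTL
    threshold."""
    e = eqtl.in_window(region, window_kb)
    e = SummaryStats(e.trait_id, e.trait_type, e.table[_maf_mask(e)].reset_index(drop=True))
    g_t = gwas.table[_maf_mask(gwas)].set_index("snp_id")
    et = e.table[e.table["snp_id"].isin(g_t.index)]
    if et.empty or et["pval"].min() >= p_eqtl_threshold:
        return SMRResult(eqtl.trait_id, None, np.nan, np.nan, np.nan,
                         status="not testable: no cis-eQTL below threshold")
    top = et.loc[et["pval"].idxmin()]
    gw = g_t.loc[top["snp_id"]]
    z_e = top["beta"] / top["se"]
    z_g = gw["beta"] / gw["se"]
    b = float(gw["beta"] / top["beta"])
    denom = z_g ** 2 + z_e ** 2
    t_smr = float(z_g ** 2 * z_e ** 2 / denom) if denom > 0 else 0.0
    p = float(stats.chi2.sf(t_smr, 1)) if t_smr > 0 else 1.0
    se = float(abs(b) / np.sqrt(t_smr)) if t_smr > 0 else np.inf
    return SMRResult(eqtl.trait_id, str(top["snp_id"]), b, se, p)


def imhof_pvalue(q: float, eigenvalues: np.ndarray) -> float:
    """P(sum_j lambda_j chi^2_1 > q) by Imhof numerical inversion of the
    characteristic function; Satterthwaite moment matching as fallback when
    the integral misbehaves."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    import warnings as _warnings
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            val, err = quad(integrand, 0, np.inf, limit=200)
        p = 0.5 + val / np.pi
        if err > 1e-4 or not np.isfinite(p):
            raise RuntimeError
    except Exception:
        scale = np.sum(lam ** 2) / np.sum(lam)
        df = np.sum(lam) ** 2 / np.sum(lam ** 2)
        p = stats.chi2.sf(q / scale, df)
    return float(np.clip(p, 1e-300, 1.0))


def heidi_test(eqtl: SummaryStats, gwas: SummaryStats, ld: LDMatrix,
               top_snp: str, p_eqtl: float = HEIDI_P_EQTL,
               r2_range: tuple = HEIDI_R2_RANGE, max_snps: int = HEIDI_MAX_SNPS,
               min_snps: int = HEIDI_MIN_SNPS):
    """HEIDI: test homogeneity of b_SMR across SNPs in LD with the top SNP.

    For each candidate i, d_i = b_SMR(i) - b_SMR(top); the joint covariance
    of the d vector follows from the LD correlations and per-SNP standard
    errors by the delta method, and sum_i z_{d_i}^2 is referred to the
    matching quadratic form in correlated normals (eigenvalue-weighted
    chi-square). Returns (p_heidi, n_used); p_heidi is None with a status
    when fewer than ``min_snps`` candidates survive the filters.
    """
    e_t = eqtl.table.set_index("snp_id")
    g_t = gwas.table.set_index("snp_id")
    if top_snp not in e_t.index or top_snp not in g_t.index:
        return None, 0, "top SNP missing from input tables"
    cand = []
    for snp in e_t.index:
        if snp == top_snp or snp not in g_t.index:
            continue
        if e_t.loc[snp, "pval"] >= p_eqtl:
            continue
        r2 = ld.r_between(snp, top_snp) ** 2
        if not (r2_range[0] <= r2 <= r2_range[1]):
            continue
        cand.append((e_t.loc[snp, "pval"], snp))
    cand.sort()
    snps = [s for _, s in cand[:max_snps]]
    if len(snps) < min_snps:
        return None, len(snps), f"only {len(snps)} usable SNPs (< {min_snps})"

    order = [top_snp] + snps
    be = e_t.loc[order, "beta"].to_numpy()
    se_e = e_t.loc[order, "se"].to_numpy()
    bg = g_t.loc[order, "beta"].to_numpy()
    se_g = g_t.loc[order, "se"].to_numpy()
    r = ld.submatrix(order)

    # delta-method covariance of b_i = bg_i / be_i across SNPs:
    # cov(b_i, b_j) = r_ij se_g_i se_g_j / (be_i be_j)
    #               + r_ij se_e_i se_e_j bg_i bg_j / (be_i^2 be_j^2)
    inv_be = 1.0 / be
    cov_b = (r * np.outer(se_g * inv_be, se_g * inv_be)
             + r * np.outer(se_e * bg * inv_be ** 2, se_e * bg * inv_be ** 2))
    k = len(snps)
    d = (bg[1:] * inv_be[1:]) - (bg[0] * inv_be[0])
    # cov(d_i, d_j) = cov(b_i,b_j) - cov(b_i,b_top) - cov(b_j,b_top) + var(b_top)
    cov_d = (cov_b[1:, 1:] - cov_b[1:, [0]] - cov_b[[0], 1:] + cov_b[0, 0])
    sd_d = np.sqrt(np.diag(cov_d))
    z_d = d / sd_d
    corr_d = cov_d / np.outer(sd_d, sd_d)
    stat = float(np.sum(z_d ** 2))
    eig = np.linalg.eigvalsh((corr_d + corr_d.T) / 2)
    p = imhof_pvalue(stat, eig)
    return p, k, "ok"
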