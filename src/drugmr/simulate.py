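"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of the study's real
sources — cis LD blocks around drug-target genes, several unequally sized
exposure GWAS, a rare binary outcome reported on the log-odds scale,
mediation chains, pleiotropic outliers, and the five colocalization
hypotheses — so that every pipeline stage can be exercised and calibrated
without any download.

Effects are drawn on the standardized (per-SD-of-genotype) scale,
propagated through LD to marginal effects (beta_marginal = R @ beta_causal)
and converted to per-allele units by 1/sqrt(2*p*(1-p)). Sampling noise is
multivariate normal with correlation equal to the LD matrix, which is what
summary statistics from a single cohort exhibit. Binary outcomes use the
standard large-sample approximation se = 1/sqrt(2*p*(1-p)*n*phi*(1-phi))
with phi the case fraction, rather than individual-level logistic
simulation; a slow individual-level path is provided for cross-validation
at small m.

All generators are pure functions of their :class:`SimConfig` (seed
included): identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .sumstats import P_FLOOR, GeneRegion, LDMatrix, SummaryStats

_NONPAL_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Study conditions for one synthetic region.

    Sample-size defaults emulate the study sources: three LDL-c exposure
    GWAS of ~1.3M / 170k / 70k individuals, a binary outcome GWAS of
    409,127 individuals with 725 cases, and mediator (protein) GWAS of
    3,301 individuals.
    """

    seed: int = 0
    m_snps: int = 60
    ld_rho: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    n_exposure: tuple = (1_300_000, 170_000, 70_000)
    n_outcome: int = 409_127
    case_fraction: float = 725 / 409_127
    theta: float = 0.0              # causal effect, log-odds per exposure SD
    a_true: float = 0.0             # exposure -> mediator
    b_true: float = 0.0             # mediator -> outcome
    direct: float = 0.0             # exposure -> outcome not via mediator
    n_causal: int = 3
    pleiotropy: tuple = ()          # ((snp_index, per-allele direct effect), ...)
    scenario: str | None = None     # H0..H4 for coloc fixtures
    palindromic_fraction: float = 0.10
    flip_fraction: float = 0.30     # outcome rows stored with swapped alleles
    strand_fraction: float = 0.10   # outcome rows stored on the other strand
    n_mediator: int = 3_301
    causal_z: float = 8.0           # coloc scenarios: causal-SNP |z| target
    trait2_type: str = "binary"     # coloc scenarios: second trait's type
    causal_beta_range: tuple = (0.03, 0.08)  # exposure cis effects, SD units
    linkage_sep: int | None = None  # H3: index distance between causal SNPs

    def validate(self) -> None:
        if self.m_snps < 1:
            raise ConfigError("m_snps must be positive")
        if not (0 <= self.ld_rho < 1):
            raise ConfigError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        for n in (*self.n_exposure, self.n_outcome, self.n_mediator):
            if n < 100:
                raise ConfigError("all sample sizes must be >= 100")
        if not (0 < self.case_fraction < 1):
            raise ConfigError("case_fraction must be in (0, 1)")
        if self.n_causal > self.m_snps:
            raise ConfigError("n_causal must be <= m_snps")
        for idx, _ in self.pleiotropy:
            if not (0 <= idx < self.m_snps):
                raise ConfigError("pleiotropy index out of range")
        if self.scenario is not None and self.scenario not in ("H0", "H1", "H2", "H3", "H4"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")


@dataclass
class TruthRecord:
    theta: float
    a_true: float
    b_true: float
    causal_snp_indices: list = field(default_factory=list)
    outlier_indices: list = field(default_factory=list)
    direct: float = 0.0
    beta_exp_true: np.ndarray | None = None  # per-allele marginal truth

    @property
    def c_total(self) -> float:
        return self.direct + self.a_true * self.b_true


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2 ** 31), stream])


def gen_ld_matrix(cfg: SimConfig, snp_ids=None) -> LDMatrix:
    """AR(1) correlation matrix r[i,j] = ld_rho ** |i-j| (always PSD)."""
    cfg.validate()
    idx = np.arange(cfg.m_snps)
    r = cfg.ld_rho ** np.abs(idx[:, None] - idx[None, :])
    ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in idx]
    return LDMatrix(snp_ids=ids, r=r)


def _positions(cfg: SimConfig, region: GeneRegion, window_kb: int = 250) -> np.ndarray:
    lo = region.start - window_kb * 1000
    hi = region.end + window_kb * 1000
    return np.linspace(lo, hi, cfg.m_snps).round().astype(np.int64)


def _default_region() -> GeneRegion:
    return GeneRegion("SYNTH", "1", 10_000_000, 10_030_000)


def _alleles(cfg: SimConfig, rng: np.random.Generator):
    pal = rng.random(cfg.m_snps) < cfg.palindromic_fraction
    ea, oa = [], []
    for i in range(cfg.m_snps):
        pool = _PAL_PAIRS if pal[i] else _NONPAL_PAIRS
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)
    return np.array(ea), np.array(oa)


def _chol(r: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(r + 1e-10 * np.eye(r.shape[0]))


def _pvals(z: np.ndarray) -> np.ndarray:
    return np.clip(2 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)


def _make_table(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": _pvals(beta / se),
        "n": np.full(len(snp_ids), n, dtype=np.int64),
    })


class _Scaffold:
    """Shared genetic architecture of one region: LD, frequencies, alleles,
    per-allele true exposure effects."""

    def __init__(self, cfg: SimConfig, region: GeneRegion | None):
        cfg.validate()
        self.cfg = cfg
        self.region = region or _default_region()
        self.pos = _positions(cfg, self.region)
        self.snp_ids = [f"rs_{self.region.chrom}_{p}" for p in self.pos]
        self.ld = gen_ld_matrix(cfg, snp_ids=self.snp_ids)
        self.L = _chol(self.ld.r)
        rng = _rng(cfg, 1)
        maf = rng.uniform(*cfg.maf_range, cfg.m_snps)
        orient = rng.random(cfg.m_snps) < 0.5
        self.eaf = np.where(orient, maf, 1 - maf)
        self.ea, self.oa = _alleles(cfg, rng)
        # cis causal architecture on the standardized scale
        self.causal_idx = np.sort(rng.choice(cfg.m_snps, cfg.n_causal, replace=False))
        lo, hi = cfg.causal_beta_range
        mags = rng.uniform(lo, hi, cfg.n_causal)
        signs = rng.choice([-1.0, 1.0], cfg.n_causal)
        beta_causal = np.zeros(cfg.m_snps)
        beta_causal[self.causal_idx] = mags * signs
        self.beta_marg_std = self.ld.r @ beta_causal
        self.scale = 1.0 / np.sqrt(2 * self.eaf * (1 - self.eaf))
        self.beta_exp_true = self.beta_marg_std * self.scale  # per-allele

    def noisy(self, true_beta, se, rng) -> np.ndarray:
        return true_beta + se * (self.L @ rng.standard_normal(self.cfg.m_snps))

    def exposure_se(self, n: int) -> np.ndarray:
        return self.scale / np.sqrt(n)

    def outcome_se(self) -> np.ndarray:
        phi = self.cfg.case_fraction
        return self.scale / np.sqrt(self.cfg.n_outcome * phi * (1 - phi))


def _restore_outcome_orientation(cfg, sc, table: pd.DataFrame, rng) -> pd.DataFrame:
    """Re-express some outcome rows with swapped alleles or on the opposite
    strand so that harmonization has real work to do. The encoded association
    is unchanged."""
    from .sumstats import COMPLEMENT
    t = table.copy()
    u = rng.random(len(t))
    swap = u < cfg.flip_fraction
    strand = (u >= cfg.flip_fraction) & (u < cfg.flip_fraction + cfg.strand_fraction)
    ea, oa = t["effect_allele"].to_numpy().copy(), t["other_allele"].to_numpy().copy()
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    t.loc[swap, "beta"] = -t.loc[swap, "beta"]
    t.loc[swap, "eaf"] = 1 - t.loc[swap, "eaf"]
    pal = np.array([COMPLEMENT[a] == b for a, b in zip(ea, oa)])
    strand &= ~pal  # complementing a palindromic pair is indistinguishable from a swap
    ea[strand] = [COMPLEMENT[a] for a in ea[strand]]
    oa[strand] = [COMPLEMENT[a] for a in oa[strand]]
    t["effect_allele"], t["other_allele"] = ea, oa
    return t


def gen_region_study(cfg: SimConfig, region: GeneRegion | None = None,
                     outcome_reps: int = 1):
    """One cis region: exposure tables (one per entry of ``n_exposure``) and
    binary-outcome table(s).

    Returns ``(tables, truth)`` where ``tables`` lists the exposure
    SummaryStats followed by ``outcome_reps`` outcome SummaryStats. The
    default single outcome mirrors the real design, where all exposure
    datasets are tested against one outcome GWAS; independent outcome
    replicates (``outcome_reps == len(n_exposure)``) give the regime in
    which a fixed-effect meta-analysis of the per-dataset estimates is
    calibrated.
    """
    sc = _Scaffold(cfg, region)
    tables = []
    for k, n in enumerate(cfg.n_exposure):
        rng = _rng(cfg, 10 + k)
        se = sc.exposure_se(n)
        beta = sc.noisy(sc.beta_exp_true, se, rng)
        t = _make_table(sc.snp_ids, sc.region.chrom, sc.pos, sc.ea, sc.oa,
                        sc.eaf, beta, se, n)
        tables.append(SummaryStats(f"exposure_{k}", "quantitative", t, n=n))

    pleio = np.zeros(cfg.m_snps)
    for idx, eff in cfg.pleiotropy:
        pleio[idx] += eff
    beta_out_true = cfg.theta * sc.beta_exp_true + pleio
    se_out = sc.outcome_se()
    n_case = int(round(cfg.n_outcome * cfg.case_fraction))
    for rep in range(outcome_reps):
        rng = _rng(cfg, 100 + rep)
        beta = sc.noisy(beta_out_true, se_out, rng)
        t = _make_table(sc.snp_ids, sc.region.chrom, sc.pos, sc.ea, sc.oa,
                        sc.eaf, beta, se_out, cfg.n_outcome)
        t = _restore_outcome_orientation(cfg, sc, t, _rng(cfg, 200 + rep))
        tables.append(SummaryStats(
            "outcome" if outcome_reps == 1 else f"outcome_{rep}", "binary", t,
            n=cfg.n_outcome, n_case=n_case, n_control=cfg.n_outcome - n_case))

    truth = TruthRecord(theta=cfg.theta, a_true=cfg.a_true, b_true=cfg.b_true,
                        causal_snp_indices=list(map(int, sc.causal_idx)),
                        outlier_indices=[int(i) for i, _ in cfg.pleiotropy],
                        direct=cfg.direct, beta_exp_true=sc.beta_exp_true)
    return tables, truth


def gen_mediation_chain(cfg: SimConfig, region: GeneRegion | None = None):
    """Exposure -> mediator -> outcome chain with total effect
    c = direct + a_true * b_true by construction."""
    sc = _Scaffold(cfg, region)
    n_exp = cfg.n_exposure[0]
    rng = _rng(cfg, 10)
    se_exp = sc.exposure_se(n_exp)
    exp_t = _make_table(sc.snp_ids, sc.region.chrom, sc.pos, sc.ea, sc.oa, sc.eaf,
                        sc.noisy(sc.beta_exp_true, se_exp, rng), se_exp, n_exp)
    exposure = SummaryStats("exposure", "quantitative", exp_t, n=n_exp)

    med_true = cfg.a_true * sc.beta_exp_true
    se_med = sc.exposure_se(cfg.n_mediator)
    rng = _rng(cfg, 20)
    med_t = _make_table(sc.snp_ids, sc.region.chrom, sc.pos, sc.ea, sc.oa, sc.eaf,
                        sc.noisy(med_true, se_med, rng), se_med, cfg.n_mediator)
    mediator = SummaryStats("mediator", "quantitative", med_t, n=cfg.n_mediator)

    out_true = cfg.b_true * med_true + cfg.direct * sc.beta_exp_true
    se_out = sc.outcome_se()
    rng = _rng(cfg, 30)
    n_case = int(round(cfg.n_outcome * cfg.case_fraction))
    out_t = _make_table(sc.snp_ids, sc.region.chrom, sc.pos, sc.ea, sc.oa, sc.eaf,
                        sc.noisy(out_true, se_out, rng), se_out, cfg.n_outcome)
    outcome = SummaryStats("outcome", "binary", out_t, n=cfg.n_outcome,
                           n_case=n_case, n_control=cfg.n_outcome - n_case)

    truth = TruthRecord(theta=cfg.direct + cfg.a_true * cfg.b_true,
                        a_true=cfg.a_true, b_true=cfg.b_true,
                        causal_snp_indices=list(map(int, sc.causal_idx)),
                        direct=cfg.direct, beta_exp_true=sc.beta_exp_true)
    return exposure, mediator, outcome, truth


def _h3_separation(cfg: SimConfig) -> int:
    if cfg.linkage_sep is not None:
        return cfg.linkage_sep
    if cfg.ld_rho == 0:
        return max(1, cfg.m_snps // 3)
    # smallest index distance with r^2 <= 0.09 between the two causal SNPs
    return int(np.ceil(np.log(0.3) / np.log(cfg.ld_rho)))


def gen_coloc_scenario(cfg: SimConfig, region: GeneRegion | None = None):
    """Two-trait region under one of the five colocalization hypotheses.

    H0: neither trait has a causal variant; H1/H2: only trait 1 / trait 2;
    H3: distinct causal variants (default r^2 <= 0.09 between them);
    H4: the same causal variant. Causal effects are sized so that the causal
    SNP reaches |z| = ``causal_z`` in expectation (genome-wide significant
    at the configured sample sizes).
    """
    if cfg.scenario is None:
        raise ConfigError("scenario must be set for gen_coloc_scenario")
    cfg.validate()
    sc = _Scaffold(cfg, region)
    m = cfg.m_snps
    i1 = m // 3
    i2 = i1 if cfg.scenario == "H4" else min(m - 1, i1 + _h3_separation(cfg))

    n1 = cfg.n_exposure[0]
    phi = cfg.case_fraction
    binary2 = cfg.trait2_type == "binary"
    se1_std = 1.0 / np.sqrt(n1)
    se2_std = 1.0 / np.sqrt(cfg.n_outcome * phi * (1 - phi)) if binary2 \
        else 1.0 / np.sqrt(cfg.n_outcome)

    causal1 = np.zeros(m)
    causal2 = np.zeros(m)
    if cfg.scenario in ("H1", "H3", "H4"):
        causal1[i1] = cfg.causal_z * se1_std
    if cfg.scenario == "H2":
        causal2[i1] = cfg.causal_z * se2_std
    elif cfg.scenario == "H3":
        causal2[i2] = cfg.causal_z * se2_std
    elif cfg.scenario == "H4":
        causal2[i1] = cfg.causal_z * se2_std

    out = []
    for j, (causal, se_std, n, ttype) in enumerate([
            (causal1, se1_std, n1, "quantitative"),
            (causal2, se2_std, cfg.n_outcome, "binary" if binary2 else "quantitative")]):
        true_std = sc.ld.r @ causal
        se = se_std * sc.scale
        rng = _rng(cfg, 300 + j)
        beta = sc.noisy(true_std * sc.scale, se, rng)
        t = _make_table(sc.snp_ids, sc.region.chrom, sc.pos, sc.ea, sc.oa,
                        sc.eaf, beta, se, n)
        kw = {}
        if ttype == "binary":
            kw = dict(n_case=int(round(n * phi)), n_control=n - int(round(n * phi)))
        out.append(SummaryStats(f"trait{j + 1}", ttype, t, n=n, **kw))
    return out[0], out[1], sc.ld


def simulate_individual_binary(cfg: SimConfig, beta_perallele: np.ndarray,
                               eaf: np.ndarray, intercept: float | None = None):
    """Slow cross-validation path: individual-level logistic simulation of a
    binary GWAS (marginal per-SNP fits), for m <= 50 only."""
    m = len(beta_perallele)
    if m > 50:
        raise ConfigError("individual-level path is restricted to m <= 50")
    rng = _rng(cfg, 999)
    n = cfg.n_outcome
    g = (rng.random((n, m)) < eaf).astype(np.int8) + (rng.random((n, m)) < eaf).astype(np.int8)
    if intercept is None:
        intercept = float(np.log(cfg.case_fraction / (1 - cfg.case_fraction))
                          - 2 * eaf @ beta_perallele)
    eta = intercept + g @ beta_perallele
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    import statsmodels.api as sm
    betas, ses = np.empty(m), np.empty(m)
    for j in range(m):
        fit = sm.GLM(y, sm.add_constant(g[:, j].astype(float)),
                     family=sm.families.Binomial()).fit()
        betas[j], ses[j] = fit.params[1], fit.bse[1]
    return betas, ses
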