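"""Instrumental-variable selection and exposure/outcome harmonization.

Selection follows the drug-target design: cis instruments are SNPs within
+/-250 kb of the gene body (inclusive at both ends) passing P < 5e-8, thinned
by greedy LD clumping at r^2 < 0.3; trans instruments (for mediator GWAS) use
P < 5e-6, r^2 < 0.001 within a 10,000 kb window; LDL-c-specific instruments
are genome-wide hits at P < 5e-8, r^2 < 0.001, 10,000 kb, with every SNP in
any of the eight target-gene windows removed. Weak instruments (per-SNP
F = (beta/se)^2 < 10) and rare variants (MAF < 0.01) are excluded.
Harmonization uses no proxy SNPs and removes palindromic (A/T, C/G) variants
unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import COMPLEMENT, GeneRegion, LDMatrix, SummaryStats

_IV_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "beta_exp", "se_exp", "pval_exp", "f_stat"]


@dataclass
class InstrumentSet:
    exposure_id: str
    table: pd.DataFrame  # _IV_COLUMNS
    provenance: dict = field(default_factory=dict)
    status: str = "ok"

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def empty(self) -> bool:
        return len(self.table) == 0


@dataclass
class HarmonizedSet:
    """Exposure/outcome rows joined on SNP after allele alignment; the direct
    input to every MR estimator."""

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame  # snp_id, alleles, beta_exp, se_exp, beta_out, se_out, eaf_exp, eaf_out
    dropped: dict = field(default_factory=dict)
    status: str = "ok"

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (t["beta_exp"].to_numpy(), t["se_exp"].to_numpy(),
                t["beta_out"].to_numpy(), t["se_out"].to_numpy())

    def drop_rows(self, indices) -> "HarmonizedSet":
        keep = self.table.drop(self.table.index[list(indices)]).reset_index(drop=True)
        return HarmonizedSet(self.exposure_id, self.outcome_id, keep,
                             dropped=dict(self.dropped), status=self.status)


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument-strength F approximation (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def _sort_candidates(t: pd.DataFrame) -> pd.DataFrame:
    # p ascending; ties broken by (chrom, pos, snp_id) for platform-stable output
    return t.sort_values(["pval", "chrom", "pos", "snp_id"],
                         kind="mergesort").reset_index(drop=True)


def _greedy_clump(t: pd.DataFrame, ld: LDMatrix, clump_r2: float,
                  window_kb: int | None = None) -> pd.DataFrame:
    """Retain the smallest-p SNP, discard all remaining SNPs with r^2 above
    the threshold against it, repeat. Pairs beyond ``window_kb`` (or on
    different chromosomes, or absent from the LD index) are treated as
    unlinked."""
    t = _sort_candidates(t)
    keep = []
    alive = t.to_dict("records")
    while alive:
        top = alive.pop(0)
        keep.append(top)
        survivors = []
        for row in alive:
            linked_scope = (row["chrom"] == top["chrom"]
                            and (window_kb is None
                                 or abs(row["pos"] - top["pos"]) <= window_kb * 1000))
            r = ld.r_between(top["snp_id"], row["snp_id"]) if linked_scope else 0.0
            if r * r > clump_r2:
                continue
            survivors.append(row)
        alive = survivors
    out = pd.DataFrame(keep, columns=t.columns)
    return out.sort_values(["chrom", "pos", "snp_id"], kind="mergesort").reset_index(drop=True)


def _as_iv_table(t: pd.DataFrame) -> pd.DataFrame:
    out = t.rename(columns={"beta": "beta_exp", "se": "se_exp", "pval": "pval_exp"}).copy()
    out["f_stat"] = (out["beta_exp"] / out["se_exp"]) ** 2
    return out[_IV_COLUMNS + [c for c in ("n",) if c in out.columns]].reset_index(drop=True)


def _empty_result(exposure_id: str, provenance: dict, why: str) -> InstrumentSet:
    return InstrumentSet(exposure_id, pd.DataFrame(columns=_IV_COLUMNS),
                         provenance=provenance, status=f"empty: {why}")


def select_cis_instruments(s: SummaryStats, region: GeneRegion, ld: LDMatrix,
                           window_kb: int = 250, p_threshold: float = 5e-8,
                           clump_r2: float = 0.3) -> InstrumentSet:
    """Cis instruments for one drug-target gene (window inclusive at both
    ends), with weak instruments (F < 10) excluded before clumping."""
    prov = {"window_kb": window_kb, "p_threshold": p_threshold, "clump_r2": clump_r2,
            "clump_window_kb": None, "excluded_regions": [], "region": region.symbol}
    cand = s.in_window(region, window_kb).table
    cand = _as_iv_table(cand)
    cand = cand[(cand["pval_exp"] < p_threshold) & (cand["f_stat"] >= 10)]
    if cand.empty:
        return _empty_result(s.trait_id, prov, f"no SNP in {region.symbol} window at p<{p_threshold:g}")
    kept = _greedy_clump(cand.rename(columns={"pval_exp": "pval"}), ld, clump_r2)
    kept = kept.rename(columns={"pval": "pval_exp"})
    return InstrumentSet(s.trait_id, kept.reset_index(drop=True), provenance=prov)


def select_trans_instruments(s: SummaryStats, ld: LDMatrix,
                             p_threshold: float = 5e-6, clump_r2: float = 0.001,
                             clump_window_kb: int = 10_000) -> InstrumentSet:
    """Genome-wide instrument selection for mediator GWAS (P < 5e-6,
    r^2 < 0.001 within 10,000 kb)."""
    prov = {"window_kb": None, "p_threshold": p_threshold, "clump_r2": clump_r2,
            "clump_window_kb": clump_window_kb, "excluded_regions": []}
    cand = _as_iv_table(s.table)
    cand = cand[(cand["pval_exp"] < p_threshold) & (cand["f_stat"] >= 10)]
    if cand.empty:
        return _empty_result(s.trait_id, prov, f"no SNP at p<{p_threshold:g}")
    kept = _greedy_clump(cand.rename(columns={"pval_exp": "pval"}), ld, clump_r2,
                         window_kb=clump_window_kb)
    return InstrumentSet(s.trait_id, kept.rename(columns={"pval": "pval_exp"}),
                         provenance=prov)


def remove_region_overlaps(iv: InstrumentSet, regions, window_kb: int = 250) -> InstrumentSet:
    """Drop instruments inside any of the given gene windows (gene body
    +/- window, inclusive), recording the excluded symbols."""
    t = iv.table
    mask = np.zeros(len(t), dtype=bool)
    for g in regions:
        lo, hi = g.start - window_kb * 1000, g.end + window_kb * 1000
        mask |= ((t["chrom"].astype(str) == str(g.chrom))
                 & (t["pos"] >= lo) & (t["pos"] <= hi)).to_numpy()
    prov = dict(iv.provenance)
    prov["excluded_regions"] = [g.symbol for g in regions]
    kept = t[~mask].reset_index(drop=True)
    status = "ok" if len(kept) else "empty: all instruments inside excluded target windows"
    return InstrumentSet(iv.exposure_id, kept, provenance=prov, status=status)


def build_ldlc_specific_ivs(s: SummaryStats, target_regions, ld: LDMatrix,
                            p_threshold: float = 5e-8, clump_r2: float = 0.001,
                            clump_window_kb: int = 10_000,
                            exclusion_window_kb: int = 250) -> InstrumentSet:
    """Exposure instruments purged of the drug-target genes: genome-wide
    selection at P < 5e-8, r^2 < 0.001, 10,000 kb, then removal of every SNP
    within any target-gene window."""
    iv = select_trans_instruments(s, ld, p_threshold=p_threshold,
                                  clump_r2=clump_r2, clump_window_kb=clump_window_kb)
    if iv.empty:
        return iv
    return remove_region_overlaps(iv, target_regions, window_kb=exclusion_window_kb)


def maf_filter(iv: InstrumentSet, min_maf: float = 0.01) -> InstrumentSet:
    """Remove instruments with folded minor-allele frequency < min_maf
    (strict less-than: MAF exactly at the bound is retained)."""
    t = iv.table
    if t.empty:
        return iv
    maf = np.minimum(t["eaf"], 1 - t["eaf"])
    kept = t[maf >= min_maf].reset_index(drop=True)
    status = iv.status if len(kept) else "empty: all instruments below MAF bound"
    return InstrumentSet(iv.exposure_id, kept, provenance=dict(iv.provenance), status=status)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonize(iv: InstrumentSet, outcome: SummaryStats) -> HarmonizedSet:
    """Inner join on snp_id (no proxies), align outcome alleles to the
    exposure orientation (direct, swapped, strand-flipped, or
    strand-flipped-and-swapped), drop palindromic SNPs unconditionally and
    audit irreconcilable pairs."""
    dropped = {"not_in_outcome": 0, "palindromic": 0, "allele_mismatch": 0}
    out_t = outcome.table.set_index("snp_id")
    rows = []
    for row in iv.table.itertuples():
        if row.snp_id not in out_t.index:
            dropped["not_in_outcome"] += 1
            continue
        if _is_palindromic(row.effect_allele, row.other_allele):
            dropped["palindromic"] += 1
            continue
        o = out_t.loc[row.snp_id]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        ea_x, oa_x = row.effect_allele, row.other_allele
        flip = None
        if (ea_o, oa_o) == (ea_x, oa_x):
            flip = False
        elif (ea_o, oa_o) == (oa_x, ea_x):
            flip = True
        elif (COMPLEMENT[ea_o], COMPLEMENT[oa_o]) == (ea_x, oa_x):
            flip = False
        elif (COMPLEMENT[ea_o], COMPLEMENT[oa_o]) == (oa_x, ea_x):
            flip = True
        if flip is None:
            dropped["allele_mismatch"] += 1
            continue
        beta_out = -o["beta"] if flip else o["beta"]
        eaf_out = 1 - o["eaf"] if flip else o["eaf"]
        rows.append({
            "snp_id": row.snp_id, "chrom": row.chrom, "pos": row.pos,
            "effect_allele": ea_x, "other_allele": oa_x,
            "beta_exp": row.beta_exp, "se_exp": row.se_exp,
            "pval_exp": row.pval_exp,
            "beta_out": float(beta_out), "se_out": float(o["se"]),
            "eaf_exp": row.eaf, "eaf_out": float(eaf_out),
        })
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "effect_allele",
                                        "other_allele", "beta_exp", "se_exp",
                                        "pval_exp", "beta_out", "se_out",
                                        "eaf_exp", "eaf_out"])
    status = "ok" if len(table) else "empty: no harmonizable SNPs"
    return HarmonizedSet(iv.exposure_id, outcome.trait_id, table,
                         dropped=dropped, status=status)


def harmonized_to_parts(h: HarmonizedSet) -> tuple[InstrumentSet, SummaryStats]:
    """Re-split a HarmonizedSet into an instrument set and an outcome table in
    the aligned orientation (used for idempotence checks and re-analysis
    after outlier removal)."""
    t = h.table
    iv = InstrumentSet(h.exposure_id, pd.DataFrame({
        "snp_id": t["snp_id"], "chrom": t["chrom"], "pos": t["pos"],
        "effect_allele": t["effect_allele"], "other_allele": t["other_allele"],
        "eaf": t["eaf_exp"], "beta_exp": t["beta_exp"], "se_exp": t["se_exp"],
        "pval_exp": t["pval_exp"],
        "f_stat": (t["beta_exp"] / t["se_exp"]) ** 2,
    }))
    from scipy import stats as _st
    out = SummaryStats(h.outcome_id, "binary", pd.DataFrame({
        "snp_id": t["snp_id"], "chrom": t["chrom"], "pos": t["pos"],
        "effect_allele": t["effect_allele"], "other_allele": t["other_allele"],
        "eaf": t["eaf_out"], "beta": t["beta_out"], "se": t["se_out"],
        "pval": np.clip(2 * _st.norm.sf(np.abs(t["beta_out"] / t["se_out"])), 1e-300, 1.0),
    }))
    return iv, out


def clump_certificate(iv: InstrumentSet, full_candidates: pd.DataFrame,
                      ld: LDMatrix, clump_r2: float) -> bool:
    """Certificate check: every discarded candidate has r^2 > clump_r2 with
    some retained SNP of smaller-or-equal p."""
    kept = iv.table
    kept_ids = set(kept["snp_id"])
    for row in full_candidates.itertuples():
        if row.snp_id in kept_ids:
            continue
        ok = any(ld.r_between(row.snp_id, k.snp_id) ** 2 > clump_r2
                 and k.pval_exp <= row.pval
                 for k in kept.itertuples())
        if not ok:
            return False
    # and retained SNPs are pairwise below the threshold
    ids = list(kept["snp_id"])
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if ld.r_between(ids[i], ids[j]) ** 2 > clump_r2:
                return False
    return True
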