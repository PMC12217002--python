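"""GWAS summary-statistics, LD-matrix and gene-region containers and their
on-disk dialects.

The canonical on-disk format for summary statistics is a tab-separated table
with one header line, optionally preceded by ``#key=value`` metadata lines
(trait id, trait type, sample sizes). Two alternative column dialects are
supported through ``column_map``: the GCTA ``.ma`` layout
(``SNP A1 A2 freq b se p N``) used by SMR-formatted eQTL resources, and an
IEU-style layout. All coordinates are 1-based GRCh37 throughout the package.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

log = logging.getLogger("drugmr")

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: minimum representable p-value; zeros are clamped here so that -log10(p)
#: and z-score reconstruction stay finite downstream
P_FLOOR = 1e-300

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval",
]
OPTIONAL_COLUMNS = ["n", "n_case", "n_control"]

#: GCTA .ma dialect (SNP A1 A2 freq b se p N) -> canonical names
MA_COLUMN_MAP = {
    "SNP": "snp_id", "A1": "effect_allele", "A2": "other_allele",
    "freq": "eaf", "b": "beta", "se": "se", "p": "pval", "N": "n",
}

#: IEU-style dialect -> canonical names
IEU_COLUMN_MAP = {
    "rsid": "snp_id", "chr": "chrom", "position": "pos",
    "ea": "effect_allele", "nea": "other_allele", "eaf": "eaf",
    "beta": "beta", "se": "se", "p": "pval", "n": "n",
}


@dataclass
class ReadAudit:
    """Row accounting from a read/validation pass; never mutates values."""

    n_input: int = 0
    n_retained: int = 0
    n_dropped: int = 0
    reasons: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def drop(self, reason: str, count: int) -> None:
        if count:
            self.n_dropped += count
            self.reasons[reason] = self.reasons.get(reason, 0) + count


@dataclass
class SummaryStats:
    """One GWAS association table for one trait.

    ``table`` holds the canonical columns; ``beta`` is on the log-odds scale
    for binary traits. ``n`` is the default sample size, overridable per row
    through an ``n`` column.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    table: pd.DataFrame
    n: int | None = None
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def zscores(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()

    def in_window(self, region: "GeneRegion", window_kb: int) -> "SummaryStats":
        """Rows with 1-based position inside region +/- window (both ends
        inclusive)."""
        lo = region.start - window_kb * 1000
        hi = region.end + window_kb * 1000
        t = self.table
        mask = (t["chrom"].astype(str) == str(region.chrom)) & (t["pos"] >= lo) & (t["pos"] <= hi)
        return SummaryStats(self.trait_id, self.trait_type, t[mask].reset_index(drop=True),
                            n=self.n, n_case=self.n_case, n_control=self.n_control)

    def validate(self) -> ReadAudit:
        return _validate_table(self.table, audit=ReadAudit(n_input=len(self.table)))


@dataclass
class LDMatrix:
    """SNP-indexed correlation matrix for one genomic region."""

    snp_ids: list
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise FormatError("LD block must be square")
        if len(self.snp_ids) != self.r.shape[0]:
            raise FormatError("SNP index length does not match LD block")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DataError("duplicate SNP ids in LD matrix")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise DataError("LD matrix entry outside [-1, 1]")
        dev = np.max(np.abs(self.r - self.r.T)) if self.r.size else 0.0
        if dev > 1e-6:
            warnings.warn(f"asymmetric LD matrix (max deviation {dev:.3g}); symmetrizing")
        self.r = (self.r + self.r.T) / 2.0
        if self.r.size and np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise DataError("LD matrix diagonal must be 1")
        if self.r.size:
            w = np.linalg.eigvalsh(self.r)
            if w.min() < -1e-8:
                raise DataError(f"LD matrix not PSD (min eigenvalue {w.min():.3g})")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def submatrix(self, snp_ids) -> np.ndarray:
        """Pairwise r for the requested SNPs; SNPs absent from the index are
        treated as unlinked (r = 0 off-diagonal)."""
        k = len(snp_ids)
        out = np.eye(k)
        idx = [self._index.get(s) for s in snp_ids]
        for a in range(k):
            for b in range(a + 1, k):
                if idx[a] is not None and idx[b] is not None:
                    out[a, b] = out[b, a] = self.r[idx[a], idx[b]]
        return out

    def r_between(self, snp_a: str, snp_b: str) -> float:
        ia, ib = self._index.get(snp_a), self._index.get(snp_b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib])


@dataclass
class GeneRegion:
    """Gene body coordinates (1-based inclusive, GRCh37)."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise DataError(f"region {self.symbol}: start > end")


#: GRCh37 gene bodies of the eight LDL-c-lowering drug-target genes
DEFAULT_TARGET_REGIONS = [
    GeneRegion("HMGCR", "5", 74632154, 74657929),
    GeneRegion("NPC1L1", "7", 44552134, 44580914),
    GeneRegion("PCSK9", "1", 55505221, 55530525),
    GeneRegion("CETP", "16", 56995762, 57017757),
    GeneRegion("APOB", "2", 21224301, 21266945),
    GeneRegion("ABCG5", "2", 44039611, 44065923),
    GeneRegion("ABCG8", "2", 44066103, 44105605),
    GeneRegion("LDLR", "19", 11200038, 11244506),
]


def _validate_table(t: pd.DataFrame, audit: ReadAudit) -> ReadAudit:
    if len(t) == 0:
        raise DataError("empty summary-statistics table after parsing")
    if t["snp_id"].duplicated().any():
        raise DataError("duplicate snp_id in summary statistics")
    if (t["effect_allele"] == t["other_allele"]).any():
        raise DataError("effect_allele == other_allele for some rows")
    # p-value consistency with |beta/se| under the normal approximation:
    # warn (never fail) when -log10 p deviates by more than 10% relative
    from scipy import stats
    z = np.abs(t["beta"] / t["se"])
    with np.errstate(divide="ignore"):
        expected = -(stats.norm.logsf(z) + np.log(2)) / np.log(10)
        observed = -np.log10(t["pval"].to_numpy())
    # only meaningful away from p ~ 1; floor-clamped p-values are by
    # construction smaller than they print, so they are exempt
    mask = (observed > 1.0) & (t["pval"].to_numpy() > P_FLOOR)
    rel = np.abs(observed[mask] - expected[mask]) / np.maximum(observed[mask], 1e-12)
    n_bad = int((rel > 0.10).sum())
    if n_bad:
        msg = f"{n_bad} rows with pval inconsistent with |beta/se| (>10% on -log10 scale)"
        audit.warnings.append(msg)
        warnings.warn(msg)
    audit.n_retained = len(t)
    return audit


def read_sumstats(path, column_map: dict | None = None, *, trait_id: str | None = None,
                  trait_type: str | None = None, n: int | None = None,
                  n_case: int | None = None, n_control: int | None = None,
                  sep: str = "\t") -> tuple[SummaryStats, ReadAudit]:
    """Read a summary-statistics table, returning the stats and a row audit.

    ``column_map`` maps file-dialect column names to canonical field names
    (see :data:`MA_COLUMN_MAP`, :data:`IEU_COLUMN_MAP`); ``None`` means the
    file already uses canonical names. Rows with unparseable numeric fields
    are dropped and counted in the audit. Header ``#key=value`` lines carry
    trait metadata and are overridden by the keyword arguments.
    """
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#") and "=" in line:
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
            body_start += 1
        else:
            break
    raw = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep=sep, dtype=str)
    if column_map:
        missing = [c for c in column_map if c not in raw.columns]
        if missing:
            raise ConfigError(f"mapped column(s) absent from file: {missing}")
        raw = raw.rename(columns=column_map)
    mandatory = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval"]
    for col in mandatory:
        if col not in raw.columns:
            raise ConfigError(f"missing mandatory column {col!r}")
    audit = ReadAudit(n_input=len(raw))

    t = raw.copy()
    for col in ["chrom", "pos"]:  # optional in the .ma dialect
        if col not in t.columns:
            t[col] = "0" if col == "chrom" else "0"
    numeric = ["pos", "eaf", "beta", "se", "pval"] + [c for c in OPTIONAL_COLUMNS if c in t.columns]

    def parse_float(v):
        # python float() is correctly rounded; pandas' fast parser is not
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    for col in numeric:
        t[col] = t[col].map(parse_float)
    bad = t[numeric].isna().any(axis=1)
    audit.drop("unparseable_numeric", int(bad.sum()))
    t = t[~bad].copy()

    t["effect_allele"] = t["effect_allele"].str.upper()
    t["other_allele"] = t["other_allele"].str.upper()
    indel = ~(t["effect_allele"].isin(VALID_ALLELES) & t["other_allele"].isin(VALID_ALLELES))
    audit.drop("indel_or_invalid_allele", int(indel.sum()))
    t = t[~indel].copy()

    out_of_range = ~((t["eaf"] > 0) & (t["eaf"] < 1) & (t["se"] > 0) & (t["pval"] <= 1) & (t["pval"] >= 0))
    audit.drop("out_of_range", int(out_of_range.sum()))
    t = t[~out_of_range].copy()

    n_zero_p = int((t["pval"] == 0).sum())
    if n_zero_p:
        warnings.warn(f"{n_zero_p} p-values of 0 clamped to {P_FLOOR}")
        t.loc[t["pval"] == 0, "pval"] = P_FLOOR

    if len(t) == 0:
        raise DataError(f"no valid rows left after parsing {path}")
    t["pos"] = t["pos"].astype(np.int64)
    t["chrom"] = t["chrom"].astype(str)
    order = CANONICAL_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in t.columns]
    t = t[order].reset_index(drop=True)

    stats = SummaryStats(
        trait_id=trait_id or meta.get("trait_id", "trait"),
        trait_type=trait_type or meta.get("trait_type", "quantitative"),
        table=t,
        n=n if n is not None else (int(meta["n"]) if "n" in meta else None),
        n_case=n_case if n_case is not None else (int(meta["n_case"]) if "n_case" in meta else None),
        n_control=n_control if n_control is not None else (int(meta["n_control"]) if "n_control" in meta else None),
    )
    _validate_table(stats.table, audit)
    return stats, audit


def write_sumstats(s: SummaryStats, path) -> str:
    """Write canonical TSV with metadata header; full decimal precision so
    read(write(s)) round-trips exactly."""
    with open(path, "w") as fh:
        fh.write(f"#trait_id={s.trait_id}\n#trait_type={s.trait_type}\n")
        if s.n is not None:
            fh.write(f"#n={s.n}\n")
        if s.n_case is not None:
            fh.write(f"#n_case={s.n_case}\n")
        if s.n_control is not None:
            fh.write(f"#n_control={s.n_control}\n")
        s.table.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return str(path)


def write_sumstats_ma(s: SummaryStats, path) -> str:
    """Write the GCTA .ma dialect (SNP A1 A2 freq b se p N)."""
    t = s.table
    n_col = t["n"] if "n" in t.columns else pd.Series([s.n or 0] * len(t))
    ma = pd.DataFrame({
        "SNP": t["snp_id"], "A1": t["effect_allele"], "A2": t["other_allele"],
        "freq": t["eaf"], "b": t["beta"], "se": t["se"], "p": t["pval"], "N": n_col,
    })
    ma.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return str(path)


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix TSV: first column SNP id, remaining columns numeric,
    header row of SNP ids."""
    t = pd.read_csv(path, sep="\t", index_col=0)
    if t.shape[0] != t.shape[1]:
        raise FormatError(f"LD block in {path} is not square: {t.shape}")
    r = t.to_numpy(dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise DataError(f"LD matrix {path} has |r| > 1")
    return LDMatrix(snp_ids=list(t.index.astype(str)), r=r)


def write_ld_matrix(ld: LDMatrix, path) -> str:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.17g")
    return str(path)


def read_regions(path) -> list[GeneRegion]:
    """Read a 4-column TSV (symbol, chrom, start, end; 1-based inclusive)."""
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("symbol", "chrom", "start", "end"):
        if col not in t.columns:
            raise ConfigError(f"region table missing column {col!r}")
    return [GeneRegion(r.symbol, str(r.chrom), int(r.start), int(r.end))
            for r in t.itertuples()]


def write_regions(regions, path) -> str:
    pd.DataFrame([{"symbol": g.symbol, "chrom": g.chrom, "start": g.start, "end": g.end}
                  for g in regions]).to_csv(path, sep="\t", index=False)
    return str(path)
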