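"""Readers and writers for GWAS summary statistics and annotation files.

All tables are plain delimited text (tab by default, comma accepted).
Internal genomic coordinates are uniformly 1-based inclusive; the BED
dialect (0-based, half-open) is converted at the boundary on ingestion.
Ingestion never alters beta/se/pval; the only permitted transformations
are allele case normalization and coordinate-dialect conversion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

#: canonical summary-statistic columns, in writing order
SUMSTAT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association with one trait.

    ``beta`` is on the per-unit trait scale for a continuous exposure and on
    the log-odds scale for a binary outcome.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when missing
    beta: float
    se: float
    pval: float
    n: int | None = None


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents) plus the analysis universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            members: set[str] = set()
            for genes in self.sets.values():
                members |= set(genes)
            self.universe = frozenset(members)


class LDTable:
    """Pairwise r-squared values keyed by unordered SNP-id pairs.

    Missing pairs are taken as unlinked (r2 = 0); the diagonal is 1.
    """

    def __init__(self, entries=None, positions=None):
        self.entries: dict[tuple[str, str], float] = {}
        self.positions: dict[str, tuple[str, int]] = dict(positions or {})
        for (a, b), r2 in dict(entries or {}).items():
            self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise FormatError(f"r2 for pair ({a}, {b}) outside [0, 1]: {r2}")
        if a == b:
            return  # diagonal is implicit
        self.entries[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.entries.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self.entries)


def _resolve_sep(path, sep):
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_sumstats(path, column_map=None, sep=None, na_token="NA",
                  return_rejected=False):
    """Read a delimited summary-statistics table into canonical columns.

    ``column_map`` maps canonical roles (see :data:`SUMSTAT_COLUMNS`) to the
    column names used in the file; identity by default. Rows violating the
    record invariants (se <= 0, p outside (0, 1], equal or non-ACGT alleles,
    pos < 1) are rejected with row-numbered diagnostics and a logged count.
    """
    column_map = dict(column_map or {})
    for role in SUMSTAT_COLUMNS:
        column_map.setdefault(role, role)
    try:
        raw = pd.read_csv(path, sep=_resolve_sep(path, sep),
                          na_values=[na_token], keep_default_na=False,
                          dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty summary-statistics file: {path}") from None
    if raw.empty and raw.columns.empty:
        raise FormatError(f"empty summary-statistics file: {path}")
    missing = [column_map[r] for r in SUMSTAT_COLUMNS
               if r not in ("eaf", "n") and column_map[r] not in raw.columns]
    if missing:
        raise FormatError(f"missing mapped column(s) {missing} in {path}")

    df = pd.DataFrame(index=raw.index)
    for role in SUMSTAT_COLUMNS:
        col = column_map[role]
        df[role] = raw[col] if col in raw.columns else np.nan
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)

    reasons = {}

    def _flag(mask, reason):
        for idx in df.index[mask.fillna(True)]:
            reasons.setdefault(idx, reason)

    _flag(~(df["se"] > 0), "se must be > 0")
    _flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0, 1]")
    _flag(~df["beta"].notna(), "beta missing or non-numeric")
    _flag(~(df["pos"] >= 1), "pos must be >= 1")
    _flag(~df["effect_allele"].str.match(_ALLELE_RE), "invalid effect allele")
    _flag(~df["other_allele"].str.match(_ALLELE_RE), "invalid other allele")
    _flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
    _flag(eaf_bad, "eaf outside (0, 1)")
    n_bad = df["n"].notna() & ~(df["n"] > 0)
    _flag(n_bad, "n must be positive")

    if reasons:
        for idx, reason in sorted(reasons.items()):
            logger.warning("row %d rejected: %s", idx + 2, reason)  # 1-based + header
        logger.warning("rejected %d of %d rows in %s",
                       len(reasons), len(df), path)
    keep = df.drop(index=list(reasons))
    keep = keep.reset_index(drop=True)
    keep["pos"] = keep["pos"].astype(np.int64)
    keep["n"] = keep["n"].astype("Int64")
    indels = (keep["effect_allele"].str.len() > 1) | (keep["other_allele"].str.len() > 1)
    if indels.any():
        logger.warning("%d records carry multi-base alleles (kept, flagged)",
                       int(indels.sum()))
    if return_rejected:
        rejected = pd.DataFrame(
            {"row": [i + 2 for i in sorted(reasons)],
             "reason": [reasons[i] for i in sorted(reasons)]})
        return keep, rejected
    return keep


def write_sumstats(df, path, sep="\t", na_token="NA"):
    """Write canonical summary statistics; read(write(x)) == x field-for-field."""
    out = df.loc[:, SUMSTAT_COLUMNS].copy()
    out.to_csv(path, sep=sep, index=False, na_rep=na_token)


def records_to_frame(records) -> pd.DataFrame:
    """Build a canonical DataFrame from SumStatRecord instances."""
    rows = [{**r.__dict__} for r in records]
    df = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)
    df["n"] = pd.array([r.n for r in records], dtype="Int64")
    return df


def read_gene_intervals(path, dialect="bed", sep=None):
    """Read gene intervals into 1-based inclusive internal coordinates.

    ``bed`` rows (chrom, start, end, gene_id; 0-based half-open) become
    (start+1, end); ``one_based`` rows (chrom, start, end, gene_id) are taken
    verbatim.
    """
    if dialect not in ("bed", "one_based"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep=_resolve_sep(path, sep), header=None,
                     comment="#",
                     names=["chrom", "start", "end", "gene_id"],
                     dtype={"chrom": str, "gene_id": str})
    if dialect == "bed":
        df["start"] = df["start"] + 1
    bad = df["start"] > df["end"]
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise FormatError(f"interval with start > end at data line {row}")
    return df.loc[:, ["gene_id", "chrom", "start", "end"]]


def write_gene_intervals(df, path, dialect="one_based", sep="\t"):
    out = df.loc[:, ["chrom", "start", "end", "gene_id"]].copy()
    if dialect == "bed":
        out["start"] = out["start"] - 1
    out.to_csv(path, sep=sep, index=False, header=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, members, tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} has {len(fields)} fields (need >= 3)")
            name = fields[0]
            sets[name] = frozenset(fields[2:])
    if n_lines == 0:
        raise FormatError(f"empty GMT file: {path}")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path):
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_ld_table(path, sep=None, positions=None) -> LDTable:
    """Read a three-column (snp_a, snp_b, r2) delimited LD table."""
    df = pd.read_csv(path, sep=_resolve_sep(path, sep))
    needed = {"snp_a", "snp_b", "r2"}
    if not needed <= set(df.columns):
        raise FormatError(f"LD table must have columns {sorted(needed)}")
    if (df["r2"] < 0).any():
        raise FormatError("negative r2 in LD table")
    table = LDTable(positions=positions)
    for a, b, r2 in df.itertuples(index=False):
        table.set(str(a), str(b), r2)
    return table


def write_ld_table(table: LDTable, path, sep="\t"):
    rows = [(a, b, r2) for (a, b), r2 in sorted(table.entries.items())]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
        path, sep=sep, index=False)


def read_taxon_registry(path, sep=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_resolve_sep(path, sep), dtype=str)
    needed = {"taxon_id", "rank", "name"}
    if not needed <= set(df.columns):
        raise FormatError(f"taxon registry must have columns {sorted(needed)}")
    if df["taxon_id"].duplicated().any():
        raise FormatError("duplicate taxon_id in registry")
    bad = ~df["rank"].isin(_RANKS)
    if bad.any():
        raise FormatError(f"unknown rank(s): {sorted(df.loc[bad, 'rank'].unique())}")
    return df


def write_taxon_registry(df, path, sep="\t"):
    df.loc[:, ["taxon_id", "rank", "name"]].to_csv(path, sep=sep, index=False)
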