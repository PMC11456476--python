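"""Nearest-gene mapping and hypergeometric over-representation analysis.

Causal SNPs are assigned to their nearest gene on the same chromosome
(distance 0 when contained in the gene interval, otherwise the distance to
the nearest interval boundary). Over-representation of the resulting query
genes in user-supplied gene sets (GMT) is tested with the hypergeometric
upper tail and Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    pval: float
    fdr_q: float


def nearest_gene(snp: tuple[str, int], intervals: pd.DataFrame,
                 ) -> str | None:
    """Nearest gene to a (chrom, pos) SNP; None when the chromosome has no
    intervals. Ties break to the smaller start, then lexicographic gene_id.
    The result is independent of interval input order."""
    chrom, pos = snp
    sub = intervals[intervals["chrom"] == chrom]
    if sub.empty:
        return None
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    inside = (start <= pos) & (pos <= end)
    dist = np.where(inside, 0,
                    np.minimum(np.abs(pos - start), np.abs(pos - end)))
    order = sorted(range(len(sub)),
                   key=lambda i: (dist[i], start[i], sub["gene_id"].iat[i]))
    return str(sub["gene_id"].iat[order[0]])


def map_snps_to_genes(snps: pd.DataFrame, intervals: pd.DataFrame,
                      ) -> pd.DataFrame:
    """Nearest gene for each SNP row (needs chrom, pos columns); SNPs on
    chromosomes without intervals get gene_id None."""
    genes = [nearest_gene((r["chrom"], int(r["pos"])), intervals)
             for _, r in snps.iterrows()]
    out = snps.loc[:, ["snp_id", "chrom", "pos"]].copy()
    out["gene_id"] = genes
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (input order kept)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~((p > 0) & (p <= 1))):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(query, sets: GeneSetCollection, universe=None) -> pd.DataFrame:
    """Hypergeometric over-representation of query genes in each set.

    For a universe of N genes, a set of K and a query of n genes with k in
    common, p = P(X >= k) for X hypergeometric(N, K, n). Query members
    outside the universe are dropped with a warning; each set is intersected
    with the universe. Returns a DataFrame sorted by p-value.
    """
    universe = set(universe if universe is not None else sets.universe)
    if not universe:
        raise DomainError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped",
                       len(outside))
        query &= universe
    if not query:
        raise DomainError("empty query after universe restriction")

    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.sets.items():
        inset = set(members) & universe
        K = len(inset)
        k = len(query & inset)
        # P(X >= k); sf(k-1) is exact for the integer support
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N,
                     "pval": min(max(p, 1e-300), 1.0)})
    df = pd.DataFrame(rows)
    df["fdr_q"] = bh_adjust(df["pval"].to_numpy())
    return df.sort_values("pval", kind="mergesort").reset_index(drop=True)
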