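"""Instrumental-variable selection for two-sample MR.

Four filters are applied in a fixed, documented order:

1. association threshold (locus-wide significance, p < 1e-5 by default);
2. greedy LD clumping (r2 < 0.001 within a ±10,000 kb window by default);
3. exclusion of palindromic (A/T, C/G) SNPs, whose strand cannot be
   resolved from alleles alone;
4. weak-instrument filter on the F-statistic, F = (beta/se)^2 >= 10.

Per-stage record counts are kept as provenance so attrition is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DomainError
from .io import LDTable

logger = logging.getLogger(__name__)

#: provenance stages in application order
STAGES = ("input", "after_threshold", "after_clumping",
          "after_palindrome_filter", "after_f_filter")


@dataclass(frozen=True)
class InstrumentSelectionConfig:
    pval_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    exclude_palindromic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.pval_threshold <= 1.0:
            raise ConfigError(f"pval_threshold: must lie in (0, 1] "
                              f"(got {self.pval_threshold!r})")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ConfigError(f"clump_r2: must lie in [0, 1] "
                              f"(got {self.clump_r2!r})")
        if self.clump_window_kb <= 0:
            raise ConfigError(f"clump_window_kb: must be positive "
                              f"(got {self.clump_window_kb!r})")
        if self.f_min < 0:
            raise ConfigError(f"f_min: must be >= 0 (got {self.f_min!r})")


@dataclass
class InstrumentSet:
    """Retained instruments plus per-stage attrition counts."""

    records: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)
    F: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.records)


def f_statistic(beta: float, se: float) -> float:
    """Instrument strength F = (beta / se)^2."""
    if np.any(np.asarray(se) <= 0):
        raise DomainError(f"se must be positive (got {se!r})")
    return (np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)) ** 2


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G (either order).

    Multi-base alleles are never palindromic here: only true SNPs have an
    ambiguous strand.
    """
    return (effect_allele, other_allele) in (
        ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


def greedy_clump(records: pd.DataFrame, ld: LDTable, r2_threshold: float,
                 window_kb: int) -> pd.DataFrame:
    """Greedy LD clumping on summary statistics.

    Records are processed in ascending p-value order (ties broken by
    ascending position, then snp_id, making the result independent of input
    row order). A record is retained iff its r2 with every already-retained
    record on the same chromosome within ±window_kb * 1000 bp is below
    ``r2_threshold``. Pairs absent from the LD table count as unlinked.
    """
    if records.empty:
        return records.copy()
    missing = [s for s in records["snp_id"] if s not in ld.positions]
    if missing and ld.positions:
        logger.warning("%d SNPs absent from LD table; treated as unlinked",
                       len(missing))
    window_bp = int(window_kb) * 1000
    order = records.sort_values(
        ["pval", "pos", "snp_id"], kind="mergesort").index
    retained_idx: list[int] = []
    for idx in order:
        row = records.loc[idx]
        ok = True
        for kept in retained_idx:
            kept_row = records.loc[kept]
            if kept_row["chrom"] != row["chrom"]:
                continue
            if abs(int(kept_row["pos"]) - int(row["pos"])) > window_bp:
                continue
            if ld.r2(row["snp_id"], kept_row["snp_id"]) >= r2_threshold:
                ok = False
                break
        if ok:
            retained_idx.append(idx)
    return records.loc[sorted(retained_idx)].copy()


def select_instruments(records: pd.DataFrame, ld: LDTable,
                       config: InstrumentSelectionConfig | None = None,
                       ) -> InstrumentSet:
    """Apply the four selection filters in order and record provenance.

    An empty surviving set is returned (with a warning), not raised: batch
    screening treats instrument-poor traits as skipped rows.
    """
    config = config or InstrumentSelectionConfig()
    provenance = {"input": len(records)}

    stage = records[records["pval"] < config.pval_threshold]
    provenance["after_threshold"] = len(stage)

    stage = greedy_clump(stage, ld, config.clump_r2, config.clump_window_kb)
    provenance["after_clumping"] = len(stage)

    if config.exclude_palindromic and not stage.empty:
        pal = stage.apply(
            lambda r: is_palindromic(r["effect_allele"], r["other_allele"]),
            axis=1)
        stage = stage[~pal]
    provenance["after_palindrome_filter"] = len(stage)

    if not stage.empty:
        F = f_statistic(stage["beta"].to_numpy(), stage["se"].to_numpy())
        stage = stage[F >= config.f_min]
    provenance["after_f_filter"] = len(stage)

    stage = stage.reset_index(drop=True)
    F = (f_statistic(stage["beta"].to_numpy(), stage["se"].to_numpy())
         if len(stage) else np.empty(0))
    if len(stage) == 0:
        logger.warning("no instruments survive selection "
                       "(provenance: %s)", provenance)
    return InstrumentSet(records=stage, provenance=provenance, F=F)
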