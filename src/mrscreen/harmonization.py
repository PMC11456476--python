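"""Harmonize exposure and outcome summary statistics to a common effect allele.

For each SNP shared between the two tables the outcome record is aligned to
the exposure's effect allele:

* identical allele pairs are kept as-is;
* swapped pairs (effect <-> other) flip the sign of the outcome beta (and
  would complement the effect-allele frequency);
* strand-complementary pairs (e.g. A/G vs T/C) are complemented first, then
  matched as above — allowed only for non-palindromic single-base alleles,
  where the complement is unambiguous;
* anything else is dropped with reason ``allele_mismatch``.

Palindromic (A/T, C/G) SNPs reaching this stage are dropped outright with
reason ``palindromic``: their strand cannot be resolved from alleles, and no
frequency-based rescue is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DataError
from .instruments import InstrumentSet, is_palindromic

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effect pairs, ready for estimation."""

    snp_ids: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    flipped: np.ndarray
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def __len__(self) -> int:
        return self.n_snp

    def subset(self, mask) -> "HarmonizedSet":
        mask = np.asarray(mask)
        return HarmonizedSet(
            snp_ids=self.snp_ids[mask], beta_x=self.beta_x[mask],
            se_x=self.se_x[mask], beta_y=self.beta_y[mask],
            se_y=self.se_y[mask], flipped=self.flipped[mask],
            dropped=dict(self.dropped))

    @classmethod
    def from_arrays(cls, beta_x, se_x, beta_y, se_y, snp_ids=None):
        beta_x = np.asarray(beta_x, dtype=float)
        if snp_ids is None:
            snp_ids = np.array([f"snp{i + 1}" for i in range(len(beta_x))])
        return cls(snp_ids=np.asarray(snp_ids),
                   beta_x=beta_x,
                   se_x=np.asarray(se_x, dtype=float),
                   beta_y=np.asarray(beta_y, dtype=float),
                   se_y=np.asarray(se_y, dtype=float),
                   flipped=np.zeros(len(beta_x), dtype=bool))


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def _check_unique(df: pd.DataFrame, side: str) -> None:
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate snp_id on {side} side: {sorted(set(dup))}")


def harmonize(exposure, outcome: pd.DataFrame, *,
              allow_strand_flip: bool = True,
              exclude_palindromic: bool = True) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    ``exposure`` may be an :class:`InstrumentSet` or a canonical summary
    DataFrame. Palindrome exclusion here is a safety net — the instruments
    module normally removes them earlier.
    """
    exp_df = exposure.records if isinstance(exposure, InstrumentSet) else exposure
    _check_unique(exp_df, "exposure")
    _check_unique(outcome, "outcome")

    out_by_id = outcome.set_index("snp_id")
    shared = [s for s in exp_df["snp_id"] if s in out_by_id.index]

    keep_rows = []
    dropped: dict[str, str] = {}
    for _, erow in exp_df[exp_df["snp_id"].isin(shared)].iterrows():
        snp = erow["snp_id"]
        orow = out_by_id.loc[snp]
        ea_x, oa_x = erow["effect_allele"], erow["other_allele"]
        ea_y, oa_y = orow["effect_allele"], orow["other_allele"]

        if exclude_palindromic and (is_palindromic(ea_x, oa_x)
                                    or is_palindromic(ea_y, oa_y)):
            dropped[snp] = "palindromic"
            continue

        flipped = None
        if (ea_y, oa_y) == (ea_x, oa_x):
            flipped = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flipped = True
        elif allow_strand_flip:
            cea, coa = _complement(ea_y), _complement(oa_y)
            if cea is not None and coa is not None:
                if (cea, coa) == (ea_x, oa_x):
                    flipped = False
                elif (cea, coa) == (oa_x, ea_x):
                    flipped = True
        if flipped is None:
            dropped[snp] = "allele_mismatch"
            continue

        keep_rows.append({
            "snp_id": snp,
            "beta_x": float(erow["beta"]), "se_x": float(erow["se"]),
            "beta_y": -float(orow["beta"]) if flipped else float(orow["beta"]),
            "se_y": float(orow["se"]),
            "flipped": flipped,
        })

    if keep_rows:
        kept = pd.DataFrame(keep_rows)
        hset = HarmonizedSet(
            snp_ids=kept["snp_id"].to_numpy(),
            beta_x=kept["beta_x"].to_numpy(), se_x=kept["se_x"].to_numpy(),
            beta_y=kept["beta_y"].to_numpy(), se_y=kept["se_y"].to_numpy(),
            flipped=kept["flipped"].to_numpy(dtype=bool), dropped=dropped)
    else:
        empty = np.empty(0)
        hset = HarmonizedSet(snp_ids=np.empty(0, dtype=object),
                             beta_x=empty, se_x=empty, beta_y=empty,
                             se_y=empty, flipped=np.empty(0, dtype=bool),
                             dropped=dropped)
    return hset


def orient_positive_exposure(hset: HarmonizedSet) -> HarmonizedSet:
    """Recode effect alleles so every exposure beta is non-negative.

    Negating both betas leaves Wald ratios — and every orientation-invariant
    estimator — unchanged; MR-Egger regression requires this orientation.
    """
    neg = hset.beta_x < 0
    out = replace(hset,
                  beta_x=np.where(neg, -hset.beta_x, hset.beta_x),
                  beta_y=np.where(neg, -hset.beta_y, hset.beta_y),
                  flipped=hset.flipped.copy())
    return out


def write_harmonized(hset: HarmonizedSet, path, sep="\t") -> None:
    """Serialize retained rows plus a dropped-SNP audit block."""
    rows = [{"snp_id": s, "beta_x": bx, "se_x": sx, "beta_y": by, "se_y": sy,
             "flipped": fl, "status": "retained", "drop_reason": ""}
            for s, bx, sx, by, sy, fl in zip(
                hset.snp_ids, hset.beta_x, hset.se_x, hset.beta_y,
                hset.se_y, hset.flipped)]
    rows += [{"snp_id": s, "beta_x": np.nan, "se_x": np.nan,
              "beta_y": np.nan, "se_y": np.nan, "flipped": False,
              "status": "dropped", "drop_reason": reason}
             for s, reason in hset.dropped.items()]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_harmonized(path, sep="\t") -> HarmonizedSet:
    df = pd.read_csv(path, sep=sep, dtype={"snp_id": str})
    df["drop_reason"] = df.get("drop_reason", "").fillna("")
    kept = df[df["status"] == "retained"]
    dropped = {r["snp_id"]: r["drop_reason"]
               for _, r in df[df["status"] == "dropped"].iterrows()}
    return HarmonizedSet(
        snp_ids=kept["snp_id"].to_numpy(),
        beta_x=kept["beta_x"].to_numpy(dtype=float),
        se_x=kept["se_x"].to_numpy(dtype=float),
        beta_y=kept["beta_y"].to_numpy(dtype=float),
        se_y=kept["se_y"].to_numpy(dtype=float),
        flipped=kept["flipped"].to_numpy(dtype=bool),
        dropped=dropped)
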