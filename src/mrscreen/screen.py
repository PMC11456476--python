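"""Batch causal screening of many taxa against an outcome.

For each exposure (bacterial taxon) the pipeline runs instrument selection,
harmonization against the outcome GWAS, all five MR estimators and the full
sensitivity suite, then applies the study decision rules:

* suggestive association: IVW p < 0.05;
* Bonferroni significance: IVW p < 0.05 / (number of taxa at the taxon's
  rank in the registry) — a whole-registry divisor (0.05 / total taxa) is
  available via ``bonferroni_scope="registry"``;
* direction filter: a suggestive taxon whose MR-Egger slope disagrees in
  sign with IVW is excluded (status ``excluded_direction``);
* final multi-method support: all computed estimates sharing the IVW sign.

Taxa left with fewer than 3 harmonized instruments are reported with status
``skipped_insufficient_ivs`` (estimates limited to what J permits), never
silently dropped. Reverse screening swaps the exposure and outcome roles
using the same selection thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from . import sensitivity as sens
from .exceptions import DomainError
from .harmonization import HarmonizedSet, harmonize
from .instruments import InstrumentSelectionConfig, select_instruments
from .io import LDTable

logger = logging.getLogger(__name__)

STATUS_RETAINED = "retained"
STATUS_EXCLUDED_DIRECTION = "excluded_direction"
STATUS_SKIPPED = "skipped_insufficient_ivs"


@dataclass
class ScreenRow:
    """One taxon-outcome pair's full verdict."""

    taxon_id: str
    rank: str | None
    taxon_name: str | None
    outcome_label: str
    direction: str  # "forward" | "reverse"
    estimates: dict[str, est.MREstimate]
    n_snp: int
    suggestive: bool
    bonferroni_threshold: float
    bonferroni_significant: bool
    egger_direction_consistent: bool | None
    all_methods_direction_consistent: bool | None
    sensitivity: dict
    status: str
    provenance: dict[str, int] = field(default_factory=dict)
    harmonized: HarmonizedSet | None = None


def bonferroni_threshold(rank: str, registry: pd.DataFrame,
                         scope: str = "rank") -> float:
    """0.05 divided by the number of taxa tested at the given rank
    (or by the whole registry size when scope="registry")."""
    if scope == "registry":
        return 0.05 / len(registry)
    count = int((registry["rank"] == rank).sum())
    if count == 0:
        raise DomainError(f"rank {rank!r} absent from registry")
    return 0.05 / count


def _analyze_pair(hset: HarmonizedSet, *, n_boot, presso_n_sim, seed,
                  run_sensitivity=True):
    """All estimators plus the sensitivity suite that J permits."""
    J = hset.n_snp
    estimates: dict[str, est.MREstimate] = {}
    sensitivity: dict = {"q_ivw_pval": None, "q_egger_pval": None,
                         "egger_intercept": None, "egger_intercept_pval": None,
                         "presso_global_pval": None, "presso_outliers": None,
                         "loo_stable": None, "loo": None, "presso": None}
    if J == 0:
        return estimates, sensitivity
    estimates["ivw"] = est.ivw(hset)
    if J >= 2:
        estimates["max_likelihood"] = est.max_likelihood(hset)
    if J >= 3:
        estimates["egger"] = est.egger(hset)
        estimates["weighted_median"] = est.weighted_median(
            hset, n_boot=n_boot, seed=seed)
        estimates["weighted_mode"] = est.weighted_mode(
            hset, n_boot=n_boot, seed=seed + 1)
    if not run_sensitivity:
        return estimates, sensitivity
    if J >= 2:
        sensitivity["q_ivw_pval"] = sens.cochran_q(hset, "ivw").pval
    if J >= 3:
        sensitivity["q_egger_pval"] = sens.cochran_q(hset, "egger").pval
        a, _, ap = sens.egger_intercept_test(hset)
        sensitivity["egger_intercept"] = a
        sensitivity["egger_intercept_pval"] = ap
        loo = sens.leave_one_out(hset)
        sensitivity["loo"] = loo
        sensitivity["loo_stable"] = loo.stable
    if J >= 4:
        presso = sens.mr_presso(hset, n_sim=presso_n_sim, seed=seed + 2)
        sensitivity["presso"] = presso
        sensitivity["presso_global_pval"] = presso.global_pval
        sensitivity["presso_outliers"] = sorted(presso.outlier_ids)
    return estimates, sensitivity


def _build_row(taxon_id, rank, name, outcome_label, direction, hset,
               provenance, registry, bonferroni_scope, n_boot,
               presso_n_sim, seed, run_sensitivity):
    estimates, sensitivity = _analyze_pair(
        hset, n_boot=n_boot, presso_n_sim=presso_n_sim, seed=seed,
        run_sensitivity=run_sensitivity)
    J = hset.n_snp
    if registry is not None and rank is not None:
        bonf = bonferroni_threshold(rank, registry, scope=bonferroni_scope)
    else:
        bonf = 0.05
    iv = estimates.get("ivw")
    suggestive = bool(iv is not None and iv.pval < 0.05)
    bonf_sig = bool(iv is not None and iv.pval < bonf)

    egger_cons = all_cons = None
    if iv is not None and "egger" in estimates:
        egger_cons = bool(np.sign(estimates["egger"].theta)
                          == np.sign(iv.theta))
        all_cons = bool(all(np.sign(e.theta) == np.sign(iv.theta)
                            for e in estimates.values()))
    if J < 3:
        status = STATUS_SKIPPED
    elif egger_cons is False:
        status = STATUS_EXCLUDED_DIRECTION
    else:
        status = STATUS_RETAINED
    return ScreenRow(
        taxon_id=taxon_id, rank=rank, taxon_name=name,
        outcome_label=outcome_label, direction=direction,
        estimates=estimates, n_snp=J, suggestive=suggestive,
        bonferroni_threshold=bonf, bonferroni_significant=bonf_sig,
        egger_direction_consistent=egger_cons,
        all_methods_direction_consistent=all_cons,
        sensitivity=sensitivity, status=status,
        provenance=provenance, harmonized=hset)


def run_forward_screen(exposures: dict[str, pd.DataFrame],
                       outcome: pd.DataFrame, ld: LDTable,
                       registry: pd.DataFrame | None = None, *,
                       outcome_label: str = "outcome",
                       selection: InstrumentSelectionConfig | None = None,
                       bonferroni_scope: str = "rank",
                       n_boot: int = 1000, presso_n_sim: int = 1000,
                       seed: int = 0, run_sensitivity: bool = True,
                       ) -> list[ScreenRow]:
    """Forward MR of every taxon on the outcome; one ScreenRow per taxon.

    ``exposures`` maps taxon_id to its exposure summary table. Taxa are
    processed in sorted id order with per-taxon seeds derived from ``seed``,
    so the report is a pure function of (inputs, config, seed).
    """
    selection = selection or InstrumentSelectionConfig()
    reg_idx = (registry.set_index("taxon_id") if registry is not None
               else None)
    rows = []
    for i, taxon_id in enumerate(sorted(exposures)):
        rank = name = None
        if reg_idx is not None and taxon_id in reg_idx.index:
            rank = reg_idx.loc[taxon_id, "rank"]
            name = reg_idx.loc[taxon_id, "name"]
        inst = select_instruments(exposures[taxon_id], ld, selection)
        hset = harmonize(inst, outcome)
        rows.append(_build_row(
            taxon_id, rank, name, outcome_label, "forward", hset,
            dict(inst.provenance), registry, bonferroni_scope, n_boot,
            presso_n_sim, seed + 1000 * (i + 1), run_sensitivity))
        logger.info("screened %s: J=%d status=%s", taxon_id,
                    rows[-1].n_snp, rows[-1].status)
    return rows


def run_reverse(outcome_exposure: pd.DataFrame,
                taxon_outcomes: dict[str, pd.DataFrame], ld: LDTable,
                registry: pd.DataFrame | None = None, *,
                exposure_label: str = "outcome",
                selection: InstrumentSelectionConfig | None = None,
                bonferroni_scope: str = "rank",
                n_boot: int = 1000, presso_n_sim: int = 1000,
                seed: int = 0, run_sensitivity: bool = True,
                ) -> list[ScreenRow]:
    """Reverse MR: the clinical outcome as exposure, each (forward-positive)
    taxon as outcome, with the same selection thresholds."""
    selection = selection or InstrumentSelectionConfig()
    if not taxon_outcomes:
        return []
    reg_idx = (registry.set_index("taxon_id") if registry is not None
               else None)
    inst = select_instruments(outcome_exposure, ld, selection)
    rows = []
    for i, taxon_id in enumerate(sorted(taxon_outcomes)):
        rank = name = None
        if reg_idx is not None and taxon_id in reg_idx.index:
            rank = reg_idx.loc[taxon_id, "rank"]
            name = reg_idx.loc[taxon_id, "name"]
        hset = harmonize(inst, taxon_outcomes[taxon_id])
        rows.append(_build_row(
            taxon_id, rank, name, f"{exposure_label}->{taxon_id}",
            "reverse", hset, dict(inst.provenance), registry,
            bonferroni_scope, n_boot, presso_n_sim,
            seed + 1000 * (i + 1), run_sensitivity))
    return rows


def report_frame(rows: list[ScreenRow]) -> pd.DataFrame:
    """Flatten rows to one record per taxon x outcome x method."""
    records = []
    for row in rows:
        base = {
            "taxon_id": row.taxon_id, "rank": row.rank,
            "outcome": row.outcome_label, "direction": row.direction,
            "n_snp": row.n_snp, "suggestive": row.suggestive,
            "bonferroni_threshold": row.bonferroni_threshold,
            "bonferroni_significant": row.bonferroni_significant,
            "egger_direction_consistent": row.egger_direction_consistent,
            "all_methods_direction_consistent":
                row.all_methods_direction_consistent,
            "q_ivw_pval": row.sensitivity.get("q_ivw_pval"),
            "q_egger_pval": row.sensitivity.get("q_egger_pval"),
            "egger_intercept_pval":
                row.sensitivity.get("egger_intercept_pval"),
            "presso_global_pval": row.sensitivity.get("presso_global_pval"),
            "loo_stable": row.sensitivity.get("loo_stable"),
            "status": row.status,
        }
        if not row.estimates:
            records.append({**base, "method": None, "theta": np.nan,
                            "se": np.nan, "pval": np.nan, "or": np.nan,
                            "ci_low": np.nan, "ci_high": np.nan})
        for method, e in row.estimates.items():
            records.append({**base, "method": method, "theta": e.theta,
                            "se": e.se, "pval": e.pval, "or": e.or_point,
                            "ci_low": e.or_ci95[0], "ci_high": e.or_ci95[1]})
    return pd.DataFrame(records)


def export_report(rows: list[ScreenRow], path, sep="\t") -> None:
    report_frame(rows).to_csv(path, sep=sep, index=False)


def export_plot_data(rows: list[ScreenRow], kind: str, path, sep="\t",
                     ) -> None:
    """Export per-SNP and per-method data behind the standard MR figures.

    kind="scatter": per-SNP effect pairs plus one (slope, intercept) line per
    method; kind="forest": per-SNP Wald ratios with 95% CIs plus the combined
    estimates; kind="loo": leave-one-out estimate rows.
    """
    records = []
    for row in rows:
        hset = row.harmonized
        if kind == "scatter":
            if hset is None:
                continue
            for j in range(hset.n_snp):
                records.append({
                    "taxon_id": row.taxon_id, "row_type": "snp",
                    "snp_id": hset.snp_ids[j],
                    "beta_x": hset.beta_x[j], "se_x": hset.se_x[j],
                    "beta_y": hset.beta_y[j], "se_y": hset.se_y[j],
                    "method": None, "slope": np.nan, "intercept": np.nan})
            for method, e in row.estimates.items():
                records.append({
                    "taxon_id": row.taxon_id, "row_type": "method",
                    "snp_id": None, "beta_x": np.nan, "se_x": np.nan,
                    "beta_y": np.nan, "se_y": np.nan, "method": method,
                    "slope": e.theta,
                    "intercept": e.extras.get("intercept", 0.0)})
        elif kind == "forest":
            if hset is None:
                continue
            for j in range(hset.n_snp):
                theta = hset.beta_y[j] / hset.beta_x[j]
                se = hset.se_y[j] / abs(hset.beta_x[j])
                records.append({
                    "taxon_id": row.taxon_id, "row_type": "snp",
                    "label": hset.snp_ids[j], "theta": theta,
                    "ci_low": theta - est.Z95 * se,
                    "ci_high": theta + est.Z95 * se})
            for method, e in row.estimates.items():
                records.append({
                    "taxon_id": row.taxon_id, "row_type": "combined",
                    "label": method, "theta": e.theta,
                    "ci_low": e.theta - est.Z95 * e.se,
                    "ci_high": e.theta + est.Z95 * e.se})
        elif kind == "loo":
            loo = row.sensitivity.get("loo")
            if loo is None:
                continue
            for _, r in loo.rows.iterrows():
                records.append({
                    "taxon_id": row.taxon_id,
                    "excluded_snp": r["excluded_snp"], "theta": r["theta"],
                    "se": r["se"], "pval": r["pval"]})
        else:
            raise ValueError(f"unknown plot-data kind: {kind!r}")
    pd.DataFrame(records).to_csv(path, sep=sep, index=False)
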