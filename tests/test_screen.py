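import numpy as np
import pandas as pd
import pytest

from mrscreen import screen
from mrscreen.exceptions import DomainError
from mrscreen.harmonization import harmonize
from mrscreen.synth import (SynthConfig, simulate_screen_inputs,
                            simulate_taxonomy_registry)

from conftest import make_hset


@pytest.fixture(scope="module")
def registry():
    return simulate_taxonomy_registry()


def test_bonferroni_per_rank_thresholds(registry):
    assert screen.bonferroni_threshold("genus", registry) == 0.05 / 131
    assert screen.bonferroni_threshold("family", registry) == 0.05 / 35
    assert screen.bonferroni_threshold("phylum", registry) == 0.05 / 9
    assert screen.bonferroni_threshold(
        "genus", registry, scope="registry") == 0.05 / 211
    single = pd.DataFrame({"taxon_id": ["p1"], "rank": ["phylum"],
                           "name": ["A"]})
    assert screen.bonferroni_threshold("phylum", single) == 0.05
    with pytest.raises(DomainError):
        screen.bonferroni_threshold("kingdom", registry)


@pytest.fixture(scope="module")
def small_screen():
    cfg = SynthConfig(n_snps=20, instrument_effect_sd=0.3,
                      palindromic_fraction=0.0, seed=100)
    exposures, outcome, ld, truths = simulate_screen_inputs(
        10, cfg, causal_thetas={"taxon004": 0.6})
    rows = screen.run_forward_screen(
        exposures, outcome, ld, registry=None, outcome_label="outcome",
        n_boot=32, presso_n_sim=99, seed=1)
    return exposures, outcome, ld, truths, rows


def test_forward_screen_flags_causal_taxon(small_screen):
    exposures, outcome, ld, truths, rows = small_screen
    by_id = {r.taxon_id: r for r in rows}
    assert by_id["taxon004"].suggestive
    null_suggestive = [r.taxon_id for r in rows
                       if r.suggestive and r.taxon_id != "taxon004"]
    assert len(null_suggestive) <= 2  # ~5% false-positive rate among 9 nulls
    causal = by_id["taxon004"].estimates["ivw"]
    assert abs(causal.theta - 0.6) < 4 * causal.se


def test_screen_rows_carry_harmonized_sizes_and_flags(small_screen):
    exposures, outcome, _, _, rows = small_screen
    for r in rows:
        assert r.n_snp == r.harmonized.n_snp
        assert r.n_snp <= len(harmonize(exposures[r.taxon_id], outcome))
        assert set(r.estimates) <= {"ivw", "egger", "weighted_median",
                                    "weighted_mode", "max_likelihood"}
        if r.bonferroni_significant:
            assert r.suggestive
        if r.status == screen.STATUS_EXCLUDED_DIRECTION:
            assert r.egger_direction_consistent is False
        if r.all_methods_direction_consistent is not None:
            iv_sign = np.sign(r.estimates["ivw"].theta)
            agree = all(np.sign(e.theta) == iv_sign
                        for e in r.estimates.values())
            assert r.all_methods_direction_consistent == agree


def test_screen_is_deterministic(small_screen):
    exposures, outcome, ld, _, rows = small_screen
    again = screen.run_forward_screen(
        exposures, outcome, ld, registry=None, outcome_label="outcome",
        n_boot=32, presso_n_sim=99, seed=1)
    pd.testing.assert_frame_equal(screen.report_frame(rows),
                                  screen.report_frame(again))


def test_inside_violation_yields_excluded_direction():
    """Strong InSIDE-violating pleiotropy forces the Egger slope sign
    against IVW and the taxon is excluded from positives."""
    cfg = SynthConfig(n_snps=50, theta_true=0.0, instrument_effect_sd=0.3,
                      pleiotropy_mean=0.05, pleiotropy_sd=0.02,
                      inside_violation_corr=-0.9,
                      palindromic_fraction=0.0, seed=11)
    exposures, outcome, ld, _ = simulate_screen_inputs(1, cfg)
    rows = screen.run_forward_screen(exposures, outcome, ld, n_boot=32,
                                     presso_n_sim=99, seed=2)
    (row,) = rows
    assert np.sign(row.estimates["egger"].theta) != np.sign(
        row.estimates["ivw"].theta)
    assert row.status == screen.STATUS_EXCLUDED_DIRECTION


def test_insufficient_instruments_reported_not_dropped():
    cfg = SynthConfig(n_snps=4, instrument_effect_sd=0.01,
                      palindromic_fraction=0.0, seed=3)
    exposures, outcome, ld, _ = simulate_screen_inputs(2, cfg)
    rows = screen.run_forward_screen(exposures, outcome, ld, n_boot=16,
                                     presso_n_sim=49, seed=0)
    assert len(rows) == 2
    assert all(r.status == screen.STATUS_SKIPPED for r in rows)


def test_reverse_screen_null_when_outcome_does_not_cause_taxon():
    """The outcome phenotype's own instruments have no effect on the taxon,
    so reverse MR comes back null."""
    from mrscreen.synth import simulate_ld_table, simulate_summary_pair

    cfg = SynthConfig(n_snps=40, instrument_effect_sd=0.3, theta_true=0.0,
                      palindromic_fraction=0.0, seed=200)
    outcome_gwas, taxon_gwas, _ = simulate_summary_pair(cfg)
    ld = simulate_ld_table(cfg)
    rows = screen.run_reverse(outcome_gwas, {"taxon001": taxon_gwas},
                              ld, n_boot=16, presso_n_sim=49, seed=5)
    assert len(rows) == 1
    assert rows[0].direction == "reverse"
    assert "taxon001" in rows[0].outcome_label
    assert rows[0].estimates["ivw"].pval > 0.05

    assert screen.run_reverse(outcome_gwas, {}, ld) == []


def test_null_screen_suggestive_count_calibrated():
    """Across many null taxa the suggestive fraction stays near 5%."""
    cfg = SynthConfig(n_snps=15, instrument_effect_sd=0.3,
                      palindromic_fraction=0.0, seed=42)
    exposures, outcome, ld, _ = simulate_screen_inputs(120, cfg)
    rows = screen.run_forward_screen(exposures, outcome, ld, n_boot=8,
                                     presso_n_sim=49, seed=7,
                                     run_sensitivity=False)
    n_sug = sum(r.suggestive for r in rows)
    expected = 120 * 0.05
    assert abs(n_sug - expected) <= 3 * np.sqrt(120 * 0.05 * 0.95)


def _two_snp_row():
    hset = make_hset([0.5, 0.2], [0.01, 0.01], [0.25, 0.10], [0.1, 0.1])
    hset.snp_ids = np.array(["rs1", "rs2"])
    return screen._build_row("taxonX", None, None, "outcome", "forward",
                             hset, {}, None, "rank", 16, 49, 0, True)


def test_scatter_export_line_counts(tmp_path, small_screen):
    *_, rows = small_screen
    retained = [r for r in rows if r.status == screen.STATUS_RETAINED][:1]
    path = tmp_path / "scatter.tsv"
    screen.export_plot_data(retained, "scatter", path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) - 1 == retained[0].n_snp + len(retained[0].estimates)

    p2 = tmp_path / "scatter2.tsv"
    screen.export_plot_data(retained, "scatter", p2)
    assert path.read_bytes() == p2.read_bytes()


def test_forest_export_homogeneous_fixture(tmp_path):
    row = _two_snp_row()
    path = tmp_path / "forest.tsv"
    screen.export_plot_data([row], "forest", path)
    df = pd.read_csv(path, sep="\t")
    snp = df[df["row_type"] == "snp"]
    combined = df[df["row_type"] == "combined"]
    np.testing.assert_allclose(snp["theta"], 0.5)
    np.testing.assert_allclose(combined["theta"], 0.5, atol=1e-10)


def test_loo_export_and_report(tmp_path, small_screen):
    *_, rows = small_screen
    path = tmp_path / "loo.tsv"
    screen.export_plot_data(rows, "loo", path)
    df = pd.read_csv(path, sep="\t")
    with_loo = [r for r in rows if r.sensitivity.get("loo") is not None]
    assert len(df) == sum(r.n_snp for r in with_loo)
    with pytest.raises(ValueError):
        screen.export_plot_data(rows, "violin", tmp_path / "x.tsv")

    report_path = tmp_path / "report.tsv"
    screen.export_report(rows, report_path)
    report = pd.read_csv(report_path, sep="\t")
    assert len(report) == sum(max(len(r.estimates), 1) for r in rows)
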