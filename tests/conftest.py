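import numpy as np
import pandas as pd
import pytest

from mrscreen.harmonization import HarmonizedSet, harmonize
from mrscreen.io import SUMSTAT_COLUMNS
from mrscreen.synth import SynthConfig, simulate_summary_pair


def make_sumstats(snp_ids, betas, ses, *, chrom="chr1", pos_start=1_000_000,
                  ea="A", oa="G", eaf=0.3, n=10_000, pvals=None):
    """Small canonical summary table with sensible defaults."""
    J = len(snp_ids)
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if pvals is None:
        from scipy import stats
        pvals = np.clip(2 * stats.norm.sf(np.abs(betas / ses)), 1e-300, 1.0)
    as_list = lambda v: list(v) if not np.isscalar(v) else [v] * J
    return pd.DataFrame({
        "snp_id": list(snp_ids), "chrom": as_list(chrom),
        "pos": [pos_start + 10_000 * i for i in range(J)],
        "effect_allele": as_list(ea), "other_allele": as_list(oa),
        "eaf": as_list(eaf), "beta": betas, "se": ses, "pval": pvals,
        "n": pd.array(as_list(n), dtype="Int64"),
    }, columns=SUMSTAT_COLUMNS)


def make_hset(beta_x, se_x, beta_y, se_y):
    return HarmonizedSet.from_arrays(beta_x, se_x, beta_y, se_y)


def simulate_hset(select=True, **config_kwargs):
    """Harmonized set straight from the generator, plus the truth record.

    By default the exposure passes through instrument selection first
    (locus-wide threshold and weak-instrument filter), mirroring the study
    design; this also removes near-null SNPs whose exposure-effect sign is
    ambiguous. No palindromes are generated, so nothing drops at
    harmonization.
    """
    from mrscreen.instruments import select_instruments
    from mrscreen.io import LDTable

    config_kwargs.setdefault("palindromic_fraction", 0.0)
    cfg = SynthConfig(**config_kwargs)
    exp, out, truth = simulate_summary_pair(cfg)
    if select:
        exp = select_instruments(exp, LDTable()).records
    return harmonize(exp, out), truth


@pytest.fixture
def homogeneous_pair():
    """Two SNPs whose Wald ratios are both exactly 0.5."""
    return make_hset([0.5, 0.2], [0.01, 0.01], [0.25, 0.10], [0.1, 0.1])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
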