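"""Synthetic two-sample GWAS generator with analytic ground truth.

The generator emulates the statistical structure of a microbiome-exposure /
binary-outcome MR design: a continuous, unit-variance exposure (rank-normalized
taxon abundance) measured in one sample and a log-odds outcome measured in a
second, non-overlapping sample. Only summary statistics are produced — outcome
effects are drawn directly on the log-odds scale with normal errors, which
keeps the causal truth analytic.

Generative model for SNP j (J SNPs):

    maf_j ~ Uniform(maf_range)
    b_xj  ~ N(0, instrument_effect_sd^2)  with prob 1 - prop_null_instruments, else 0
    alpha_j = pleiotropy_mean + pleiotropy_sd * z_j          (horizontal pleiotropy)
    b_yj  = theta_true * b_xj + sign(b_xj) * alpha_j  (+ outlier offsets)

    se_xj = 1 / sqrt(2 maf_j (1 - maf_j) n_exposure)   (unit-variance trait)
    beta_xj ~ N(b_xj, se_xj^2);  analogously for the outcome sample.

The pleiotropic effect alpha_j is attached to the exposure-increasing
allele (the sign(b_xj) factor; +1 for null SNPs), the frame in which
"directional" pleiotropy is defined: with pleiotropy_mean != 0 the MR-Egger
intercept targets pleiotropy_mean. Balanced pleiotropy is pleiotropy_sd > 0
with zero mean. A nonzero inside_violation_corr correlates alpha_j with the
instrument strength |b_xj| (z_j is the standardized |b_xj| for non-null
SNPs), breaking the InSIDE assumption MR-Egger relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .io import SUMSTAT_COLUMNS, GeneSetCollection, LDTable

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
#: taxonomic rank composition of the default registry
REGISTRY_RANK_COUNTS = {
    "phylum": 9, "class": 16, "order": 20, "family": 35, "genus": 131,
}
_MIN_P = 1e-300


@dataclass(frozen=True)
class SynthConfig:
    """Conditions under which a synthetic exposure/outcome pair is generated.

    Defaults describe one typical taxon of the emulated study: ~10 independent
    locus-wide-significant instruments, exposure GWAS of 18,340, binary outcome
    GWAS of 6,021, no true causal effect and no pleiotropy.
    """

    n_snps: int = 10
    theta_true: float = 0.0
    prop_null_instruments: float = 0.0
    instrument_effect_sd: float = 0.15
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation_corr: float = 0.0
    n_exposure: int = 18340
    n_outcome: int = 6021
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.2
    ld_block_size: int = 1
    ld_within_block_r2: float = 0.0
    n_outliers: int = 0
    outlier_offset_se: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        def _fail(name, why):
            raise ConfigError(f"{name}: {why} (got {getattr(self, name)!r})")

        if self.n_snps < 1:
            _fail("n_snps", "must be a positive integer")
        for name in ("instrument_effect_sd", "n_exposure", "n_outcome",
                     "ld_block_size"):
            if getattr(self, name) <= 0:
                _fail(name, "must be strictly positive")
        for name in ("prop_null_instruments", "palindromic_fraction",
                     "ld_within_block_r2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                _fail(name, "must lie in [0, 1]")
        if self.pleiotropy_sd < 0:
            _fail("pleiotropy_sd", "must be non-negative")
        if not -1.0 <= self.inside_violation_corr <= 1.0:
            _fail("inside_violation_corr", "must lie in [-1, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            _fail("maf_range", "must satisfy 0 < low <= high <= 0.5")
        if self.n_outliers < 0 or self.n_outliers > self.n_snps:
            _fail("n_outliers", "must lie in [0, n_snps]")


@dataclass
class SynthTruth:
    """Ground truth behind one simulated exposure/outcome pair."""

    theta_true: float
    b_x: np.ndarray
    alpha: np.ndarray
    outlier_indices: set[int] = field(default_factory=set)


def _layout_positions(config: SynthConfig):
    """One pseudo-chromosome per LD block; in-block SNPs 100 kb apart."""
    j = np.arange(config.n_snps)
    block = j // config.ld_block_size
    within = j % config.ld_block_size
    chrom = np.array([f"chr{b + 1}" for b in block])
    pos = 1_000_000 + within * 100_000
    return chrom, pos.astype(np.int64), block


def _draw_alleles(rng, n, palindromic_fraction):
    is_pal = rng.random(n) < palindromic_fraction
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    for i in range(n):
        pair = (_PALINDROMIC_PAIRS[pal_idx[i]] if is_pal[i]
                else _NONPALINDROMIC_PAIRS[non_idx[i]])
        ea[i], oa[i] = pair
    return ea, oa


def _orient_sign(b_x):
    """+1 on the exposure-increasing allele's side (ties count as +1)."""
    return np.where(b_x < 0, -1.0, 1.0)


def _draw_pleiotropy(rng, config, b_x, nonnull):
    """alpha ~ N(mean, sd^2), correlated with |b_x| for non-null SNPs."""
    rho = config.inside_violation_corr
    z_ind = rng.standard_normal(len(b_x))
    # standardized half-normal |b_x|: mean sd*sqrt(2/pi), var sd^2*(1 - 2/pi)
    sd = config.instrument_effect_sd
    m_half = sd * np.sqrt(2.0 / np.pi)
    s_half = sd * np.sqrt(1.0 - 2.0 / np.pi)
    z_b = np.where(nonnull, (np.abs(b_x) - m_half) / s_half, 0.0)
    z = np.where(nonnull, rho * z_b + np.sqrt(max(0.0, 1 - rho**2)) * z_ind,
                 z_ind)
    return config.pleiotropy_mean + config.pleiotropy_sd * z


def _two_sided_p(beta, se):
    z = np.abs(np.asarray(beta) / np.asarray(se))
    return np.clip(2.0 * stats.norm.sf(z), _MIN_P, 1.0)


def simulate_summary_pair(config: SynthConfig):
    """Simulate one (exposure table, outcome table, truth) triple.

    Identical config (including seed) gives byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], J)
    nonnull = rng.random(J) >= config.prop_null_instruments
    b_x = np.where(nonnull, rng.normal(0.0, config.instrument_effect_sd, J), 0.0)

    alpha = _draw_pleiotropy(rng, config, b_x, nonnull)

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)

    b_y = config.theta_true * b_x + _orient_sign(b_x) * alpha
    outliers: set[int] = set()
    if config.n_outliers:
        chosen = rng.choice(J, size=config.n_outliers, replace=False)
        outliers = set(int(i) for i in chosen)
        b_y = b_y.copy()
        b_y[chosen] += config.outlier_offset_se * se_y[chosen]

    beta_x = rng.normal(b_x, se_x)
    beta_y = rng.normal(b_y, se_y)

    chrom, pos, _ = _layout_positions(config)
    ea, oa = _draw_alleles(rng, J, config.palindromic_fraction)
    snp_id = np.array([f"rs{j + 1:06d}" for j in range(J)])

    def _table(beta, se, n):
        return pd.DataFrame({
            "snp_id": snp_id, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": maf,
            "beta": beta, "se": se, "pval": _two_sided_p(beta, se),
            "n": pd.array([n] * J, dtype="Int64"),
        }, columns=SUMSTAT_COLUMNS)

    truth = SynthTruth(theta_true=config.theta_true, b_x=b_x, alpha=alpha,
                       outlier_indices=outliers)
    return (_table(beta_x, se_x, config.n_exposure),
            _table(beta_y, se_y, config.n_outcome), truth)


def simulate_screen_inputs(n_taxa: int, config: SynthConfig,
                           causal_thetas: dict[str, float] | None = None):
    """Inputs for a batch screen: per-taxon exposure tables sharing one SNP
    universe, a single outcome table, and per-taxon truth.

    All taxa share MAFs, alleles and positions (drawn once from ``config``);
    each taxon gets its own instrument effects. The outcome aggregates the
    causal contributions of the taxa named in ``causal_thetas`` (taxon id ->
    theta) plus per-taxon pleiotropy, all observed with sampling noise.

    Returns (exposures dict, outcome table, LDTable, truths dict).
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], J)
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)
    chrom, pos, _ = _layout_positions(config)
    ea, oa = _draw_alleles(rng, J, config.palindromic_fraction)
    snp_id = np.array([f"rs{j + 1:06d}" for j in range(J)])
    causal_thetas = causal_thetas or {}

    def _table(beta, se, n):
        return pd.DataFrame({
            "snp_id": snp_id, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": maf,
            "beta": beta, "se": se, "pval": _two_sided_p(beta, se),
            "n": pd.array([n] * J, dtype="Int64"),
        }, columns=SUMSTAT_COLUMNS)

    exposures: dict[str, pd.DataFrame] = {}
    truths: dict[str, SynthTruth] = {}
    b_y = np.zeros(J)
    for t in range(n_taxa):
        taxon = f"taxon{t + 1:03d}"
        nonnull = rng.random(J) >= config.prop_null_instruments
        b_x = np.where(nonnull,
                       rng.normal(0.0, config.instrument_effect_sd, J), 0.0)
        alpha = _draw_pleiotropy(rng, config, b_x, nonnull)
        theta = causal_thetas.get(taxon, config.theta_true)
        b_y = b_y + theta * b_x + _orient_sign(b_x) * alpha
        exposures[taxon] = _table(rng.normal(b_x, se_x), se_x,
                                  config.n_exposure)
        truths[taxon] = SynthTruth(theta_true=theta, b_x=b_x, alpha=alpha)
    outcome = _table(rng.normal(b_y, se_y), se_y, config.n_outcome)
    return exposures, outcome, simulate_ld_table(config), truths


def simulate_taxonomy_registry() -> pd.DataFrame:
    """Registry of 211 bacterial taxa: 9 phyla, 16 classes, 20 orders,
    35 families and 131 genera, with unique identifiers."""
    rows = []
    for rank, count in REGISTRY_RANK_COUNTS.items():
        for i in range(1, count + 1):
            rows.append({
                "taxon_id": f"{rank}.{rank[0].upper()}{i:03d}",
                "rank": rank,
                "name": f"Synthetic{rank.capitalize()}{i:03d}",
            })
    return pd.DataFrame(rows, columns=["taxon_id", "rank", "name"])


def simulate_ld_table(config: SynthConfig) -> LDTable:
    """Block-diagonal LD: within-block pairs share ld_within_block_r2,
    cross-block pairs are unlinked."""
    chrom, pos, block = _layout_positions(config)
    snp_id = [f"rs{j + 1:06d}" for j in range(config.n_snps)]
    positions = {snp_id[j]: (chrom[j], int(pos[j]))
                 for j in range(config.n_snps)}
    table = LDTable(positions=positions)
    if config.ld_within_block_r2 > 0:
        for b in np.unique(block):
            members = np.where(block == b)[0]
            for i_idx, i in enumerate(members):
                for j in members[i_idx + 1:]:
                    table.set(snp_id[i], snp_id[j], config.ld_within_block_r2)
    return table


def simulate_gene_annotation(n_genes: int, n_sets: int, seed: int = 0):
    """Synthetic gene intervals and gene sets for enrichment fixtures.

    Intervals are 1-based inclusive, laid out with random gaps and lengths on
    a few synthetic chromosomes (so some overlap is possible); each gene set
    samples genes without replacement.
    """
    if n_genes < 2:
        raise ConfigError(f"n_genes: must be >= 2 (got {n_genes!r})")
    if n_sets < 1:
        raise ConfigError(f"n_sets: must be >= 1 (got {n_sets!r})")
    rng = np.random.default_rng(seed)
    n_chroms = max(1, n_genes // 8)
    rows = []
    cursors = {c: 1 for c in range(1, n_chroms + 1)}
    for g in range(1, n_genes + 1):
        c = int(rng.integers(1, n_chroms + 1))
        start = cursors[c] + int(rng.integers(0, 50_000))
        length = int(rng.integers(1_000, 100_000))
        rows.append({"gene_id": f"GENE{g:04d}", "chrom": f"chr{c}",
                     "start": start, "end": start + length - 1})
        # advance by less than the gene length now and then -> overlaps
        cursors[c] = start + int(rng.integers(500, length + 50_000))
    intervals = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    gene_ids = intervals["gene_id"].tolist()
    sets = {}
    for s in range(1, n_sets + 1):
        size = int(rng.integers(2, max(3, n_genes // 2) + 1))
        members = rng.choice(gene_ids, size=min(size, n_genes), replace=False)
        sets[f"SET{s:03d}"] = frozenset(str(m) for m in members)
    return intervals, GeneSetCollection(sets=sets,
                                        universe=frozenset(gene_ids))


def write_truth(truth: SynthTruth, path) -> None:
    """Sidecar ground-truth record as structured text (JSON)."""
    import json

    payload = {
        "theta_true": truth.theta_true,
        "b_x": [float(v) for v in truth.b_x],
        "alpha": [float(v) for v in truth.alpha],
        "outlier_indices": sorted(truth.outlier_indices),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> SynthTruth:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return SynthTruth(theta_true=payload["theta_true"],
                      b_x=np.asarray(payload["b_x"], dtype=float),
                      alpha=np.asarray(payload["alpha"], dtype=float),
                      outlier_indices=set(payload["outlier_indices"]))
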