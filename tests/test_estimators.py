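import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.base import clone

from mrscreen import estimators as est
from mrscreen.exceptions import (DomainError, InsufficientInstrumentsError)
from mrscreen.harmonization import orient_positive_exposure

from conftest import make_hset, simulate_hset


def _random_hset(rng, J=20):
    return make_hset(rng.normal(0, 0.3, J), rng.uniform(0.005, 0.02, J),
                     rng.normal(0, 0.15, J), rng.uniform(0.02, 0.1, J))


# ---------------------------------------------------------------- Wald ratio

@pytest.mark.parametrize("bx,sx,by,sy,theta,se", [
    (0.1, 0.02, 0.05, 0.01, 0.5, 0.1),
    (-0.1, 0.02, 0.05, 0.01, -0.5, 0.1),
    (0.1, 0.05, 0.0, 0.01, 0.0, 0.1),
])
def test_wald_ratio(bx, sx, by, sy, theta, se):
    e = est.wald_ratio(bx, sx, by, sy)
    assert e.theta == pytest.approx(theta)
    assert e.se == pytest.approx(se)
    assert e.n_snp == 1


def test_wald_ratio_zero_exposure_is_domain_error():
    with pytest.raises(DomainError):
        est.wald_ratio(0.0, 0.01, 0.05, 0.01)


# ----------------------------------------------------------------------- IVW

def test_ivw_homogeneous_two_snp_closed_form(homogeneous_pair):
    fixed = est.ivw(homogeneous_pair, variance_model="fixed")
    random = est.ivw(homogeneous_pair)
    assert fixed.theta == pytest.approx(0.5, abs=1e-12)
    assert fixed.extras["Q"] == pytest.approx(0.0, abs=1e-20)
    # sum of w * bx^2 = 100 * (0.25 + 0.04) = 29
    assert fixed.se == pytest.approx(np.sqrt(1 / 29), abs=1e-12)
    assert random.se == fixed.se  # Q = 0 -> floor at the fixed-effect SE


def test_ivw_empty_and_single_snp():
    with pytest.raises(InsufficientInstrumentsError):
        est.IVW().fit(make_hset([], [], [], []))
    single = make_hset([0.1], [0.02], [0.05], [0.01])
    e = est.ivw(single)
    w = est.wald_ratio(0.1, 0.02, 0.05, 0.01)
    assert (e.theta, e.se) == (w.theta, w.se)
    assert e.method == "ivw"


@pytest.mark.parametrize("seed", range(5))
def test_ivw_matches_weighted_least_squares_oracle(seed):
    hset = _random_hset(np.random.default_rng(seed))
    fit = sm.WLS(hset.beta_y, hset.beta_x, weights=1 / hset.se_y**2).fit()
    ours = est.ivw(hset)
    assert ours.theta == pytest.approx(fit.params[0], abs=1e-10)
    # with Q/(J-1) > 1 the multiplicative-random SE equals the WLS one
    if fit.mse_resid > 1:
        assert ours.se == pytest.approx(fit.bse[0], abs=1e-10)


# --------------------------------------------------------------------- Egger

def test_egger_perfect_line():
    hset = make_hset([0.2, 0.4, 0.6], [0.01] * 3, [0.18, 0.26, 0.34],
                     [0.05, 0.08, 0.03])
    fit = est.EggerRegression().fit(hset)
    assert fit.theta_ == pytest.approx(0.4, abs=1e-12)
    assert fit.intercept_ == pytest.approx(0.1, abs=1e-12)
    assert fit.extras_["rss"] == pytest.approx(0.0, abs=1e-18)


@pytest.mark.parametrize("seed", range(5))
def test_egger_matches_weighted_regression_oracle(seed):
    hset = orient_positive_exposure(_random_hset(np.random.default_rng(seed)))
    X = sm.add_constant(hset.beta_x)
    fit = sm.WLS(hset.beta_y, X, weights=1 / hset.se_y**2).fit()
    ours = est.EggerRegression().fit(hset)
    assert ours.intercept_ == pytest.approx(fit.params[0], abs=1e-10)
    assert ours.theta_ == pytest.approx(fit.params[1], abs=1e-10)
    if fit.mse_resid > 1:  # SE inflation active on both sides
        assert ours.intercept_se_ == pytest.approx(fit.bse[0], abs=1e-10)
        assert ours.se_ == pytest.approx(fit.bse[1], abs=1e-10)


def test_egger_needs_three_snps(homogeneous_pair):
    with pytest.raises(InsufficientInstrumentsError):
        est.egger(homogeneous_pair)


# ----------------------------------------------------------- weighted median

def test_weighted_median_middle_of_odd_equal_weight_set():
    hset = make_hset([1, 1, 1], [1e-6] * 3, [0.2, 0.5, 0.9], [1.0] * 3)
    e = est.weighted_median(hset, n_boot=50, seed=0)
    assert e.theta == pytest.approx(0.5)


def test_weighted_median_interpolation_between_two_ratios():
    # hand evaluation: s = (0.25, 0.75); interpolate r at s = 0.5 -> 0.55
    assert est._weighted_median(np.array([0.2, 0.9]),
                                np.array([1.0, 1.0])) == pytest.approx(0.55)


def test_weighted_median_robust_to_minority_invalid_instruments():
    """49%-by-weight shared pleiotropic offset leaves the median near truth
    while the (fixed-effect) IVW estimate is visibly biased."""
    hset, truth = simulate_hset(n_snps=50, theta_true=0.4,
                                instrument_effect_sd=0.3, seed=77)
    oriented = orient_positive_exposure(hset)
    # corrupt the lowest-weight 49% of SNPs (< 50% of the total weight)
    weight = oriented.beta_x**2 / oriented.se_y**2
    invalid = np.argsort(weight)[:int(0.49 * hset.n_snp)]
    assert weight[invalid].sum() < 0.5 * weight.sum()
    beta_y = oriented.beta_y.copy()
    beta_y[invalid] += 0.1
    corrupted = make_hset(oriented.beta_x, oriented.se_x, beta_y,
                          oriented.se_y)
    med = est.weighted_median(corrupted, n_boot=500, seed=1)
    assert abs(med.theta - truth.theta_true) < 3 * med.se
    ivw_fixed = est.ivw(corrupted, variance_model="fixed")
    assert abs(ivw_fixed.theta - truth.theta_true) > 3 * ivw_fixed.se


# ------------------------------------------------------------- weighted mode

def test_weighted_mode_follows_dominant_cluster():
    hset = make_hset([1, 1, 1, 1], [1e-6] * 4, [0.48, 0.50, 0.52, 5.0],
                     [1.0] * 4)
    e = est.weighted_mode(hset, n_boot=50, seed=0)
    assert 0.48 <= e.theta <= 0.52


def test_weighted_mode_degenerate_cluster():
    hset = make_hset([1, 2, 4], [1e-6] * 3, [0.7, 1.4, 2.8], [1, 1, 1])
    e = est.weighted_mode(hset, n_boot=50, seed=0)
    assert e.theta == pytest.approx(0.7, abs=1e-9)


def test_mode_count_never_increases_with_bandwidth(rng):
    ratios = np.concatenate([rng.normal(0.5, 0.02, 8),
                             rng.normal(2.0, 0.05, 5)])
    weights = np.ones_like(ratios)

    def n_modes(phi):
        from scipy import stats
        h = est._mode_bandwidth(ratios, phi)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        dens = stats.norm.pdf(grid[:, None], ratios[None, :], h).sum(axis=1)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        return int(interior.sum())

    counts = [n_modes(phi) for phi in (0.5, 1.0, 2.0, 4.0)]
    assert counts == sorted(counts, reverse=True)


# --------------------------------------------------------- maximum likelihood

def test_ml_matches_fixed_ivw_when_exposure_noise_vanishes(rng):
    hset = make_hset(rng.normal(0, 0.3, 15), np.full(15, 1e-8),
                     rng.normal(0, 0.1, 15), rng.uniform(0.02, 0.1, 15))
    ml = est.max_likelihood(hset)
    iv = est.ivw(hset, variance_model="fixed")
    assert ml.theta == pytest.approx(iv.theta, abs=1e-4)


def test_ml_single_snp_equals_wald_ratio():
    hset = make_hset([0.1], [0.02], [0.05], [0.01])
    e = est.max_likelihood(hset)
    assert e.theta == pytest.approx(0.5)
    assert e.method == "max_likelihood"


@pytest.mark.parametrize("seed", range(3))
def test_ml_profile_optimum_matches_grid_search(seed):
    hset = _random_hset(np.random.default_rng(seed))
    fit = est.MaximumLikelihood().fit(hset)
    wx, wy = 1 / hset.se_x**2, 1 / hset.se_y**2

    def negll(theta):
        b = (hset.beta_x * wx + theta * hset.beta_y * wy) / (wx + theta**2 * wy)
        return np.sum(wy * (hset.beta_y - theta * b) ** 2
                      + wx * (hset.beta_x - b) ** 2) / 2

    coarse = np.linspace(fit.theta_ - 0.5, fit.theta_ + 0.5, 20001)
    best = coarse[np.argmin([negll(t) for t in coarse])]
    assert fit.theta_ == pytest.approx(best, abs=1e-4)
    # refine locally to the 1e-6 scale
    fine = np.linspace(best - 5e-5, best + 5e-5, 101)
    best_fine = fine[np.argmin([negll(t) for t in fine])]
    assert fit.theta_ == pytest.approx(best_fine, abs=1e-6)


# ------------------------------------------------------ cross-method properties

def test_homogeneity_all_methods_return_common_ratio():
    hset = make_hset([0.5, 0.2, 0.4, 0.3], [0.001] * 4,
                     [0.25, 0.10, 0.20, 0.15], [0.1, 0.1, 0.2, 0.1])
    for e in (est.ivw(hset), est.ivw(hset, "fixed"),
              est.weighted_median(hset, n_boot=50, seed=0),
              est.weighted_mode(hset, n_boot=50, seed=0),
              est.max_likelihood(hset)):
        assert e.theta == pytest.approx(0.5, abs=1e-4), e.method


def test_scale_equivariance(rng):
    hset = _random_hset(rng)
    c = 3.7
    scaled = make_hset(hset.beta_x, hset.se_x, c * hset.beta_y, c * hset.se_y)
    pairs = [
        (est.ivw(hset), est.ivw(scaled)),
        (est.egger(hset), est.egger(scaled)),
        (est.weighted_median(hset, n_boot=50, seed=0),
         est.weighted_median(scaled, n_boot=50, seed=0)),
        (est.weighted_mode(hset, n_boot=50, seed=0),
         est.weighted_mode(scaled, n_boot=50, seed=0)),
        (est.max_likelihood(hset), est.max_likelihood(scaled)),
    ]
    for before, after in pairs:
        assert after.theta == pytest.approx(c * before.theta, rel=1e-5), \
            before.method


def test_orientation_invariance(rng):
    hset = _random_hset(rng)
    oriented = orient_positive_exposure(hset)
    for f in (est.ivw, est.max_likelihood,
              lambda h: est.weighted_median(h, n_boot=50, seed=0),
              lambda h: est.weighted_mode(h, n_boot=50, seed=0)):
        assert f(hset).theta == pytest.approx(f(oriented).theta, rel=1e-9)


# --------------------------------------------------------------- OR reporting

def test_to_odds_ratio_null_effect():
    orp, (lo, hi) = est.to_odds_ratio(0.0, 0.1)
    assert orp == 1.0
    assert lo == pytest.approx(np.exp(-0.196))
    assert hi == pytest.approx(np.exp(0.196))


def test_to_odds_ratio_reproduces_reported_interval():
    orp, (lo, hi) = est.to_odds_ratio(np.log(0.40), 0.3315)
    assert (round(lo, 2), round(hi, 2)) == (0.21, 0.77)


def test_to_odds_ratio_monotone():
    ors = [est.to_odds_ratio(t, 0.2)[0] for t in (-0.5, 0.0, 0.5, 1.0)]
    assert ors == sorted(ors)


@pytest.mark.parametrize("triple,expected", [
    ((0.40, 0.21, 0.77), 0.006),
    ((0.63, 0.41, 0.98), 0.038),
    ((4.17, 1.29, 13.52), 0.017),
    ((2.12, 1.10, 4.11), 0.025),
])
def test_p_from_or_ci_reproduces_reported_pvalues(triple, expected):
    assert round(est.p_from_or_ci(*triple), 3) == expected


def test_p_from_or_ci_null_and_domain():
    assert est.p_from_or_ci(1.0, 0.5, 2.0) == pytest.approx(1.0)
    with pytest.raises(DomainError):
        est.p_from_or_ci(0.5, 0.6, 0.9)


# ------------------------------------------------------------- sklearn API

def test_estimators_follow_sklearn_protocol(rng):
    hset = _random_hset(rng)
    model = est.WeightedMedian(n_boot=64, random_state=3)
    assert model.get_params() == {"n_boot": 64, "random_state": 3}
    cloned = clone(model)
    a = model.fit(hset).theta_
    b = cloned.fit(hset.beta_x, hset.beta_y, se_x=hset.se_x,
                   se_y=hset.se_y).theta_
    assert a == pytest.approx(b, abs=1e-15)
    iv = est.IVW().set_params(variance_model="fixed").fit(hset)
    assert iv.estimate_.extras["variance_model"] == "fixed"
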