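"""Wald ratio, IVW, MR-Egger and weighted-median estimators.

The independent oracle for the regression-based estimators is statsmodels
WLS (with and without intercept), which shares no code with the closed-form
implementations under test.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import assume, given, settings, strategies as st

from mrkit.estimators import (
    Z_95,
    egger,
    ivw,
    or_ci,
    single_wald,
    wald_ratio,
    weighted_median,
)

from conftest import instrument_set_from_arrays, make_instrument, random_instrument_set


def wls_oracle(bx, by, sy, intercept):
    """Independent weighted-least-squares fit of by on bx with weights 1/sy^2."""
    X = sm.add_constant(bx) if intercept else bx[:, None]
    return sm.WLS(by, X, weights=1.0 / np.asarray(sy) ** 2).fit()


class TestWaldRatio:
    def test_lipid_locus_example(self, aspirin_instruments):
        ins = {i.variant_id: i for i in aspirin_instruments}["rs10455872"]
        wr = wald_ratio(ins)
        assert wr.ratio == pytest.approx(-0.51114, rel=1e-4)
        assert wr.weight == pytest.approx(12.611, rel=1e-3)
        assert wr.weight * wr.se_first_order**2 == pytest.approx(1.0)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        wr = wald_ratio(make_instrument(by=0.0))
        assert wr.ratio == 0.0 and wr.se_first_order > 0

    def test_simultaneous_sign_flip_invariance(self):
        a = wald_ratio(make_instrument(bx=0.01, by=0.004))
        b = wald_ratio(make_instrument(bx=-0.01, by=-0.004))
        assert a.ratio == b.ratio and a.weight == b.weight

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="ratio undefined"):
            wald_ratio(make_instrument(bx=0.0))


class TestIVW:
    def test_two_equal_weight_instruments_closed_form(self):
        # ratios 1 and 3 with unit weights: beta = 2, fixed SE = 1/sqrt(2)
        ins = instrument_set_from_arrays(
            bx=[1.0, 1.0], sx=[0.1, 0.1], by=[1.0, 3.0], sy=[1.0, 1.0]
        )
        fit = ivw(ins, variance_model="fixed")
        assert fit.beta == pytest.approx(2.0)
        assert fit.se == pytest.approx(1 / np.sqrt(2))
        assert fit.df == 1

    def test_identical_ratios_have_zero_dispersion(self):
        ins = instrument_set_from_arrays(
            bx=[0.01, 0.02, 0.04], sx=[0.001] * 3,
            by=[0.005, 0.010, 0.020], sy=[0.002, 0.002, 0.002],
        )
        fit = ivw(ins)
        assert fit.beta == pytest.approx(0.5)
        assert fit.metadata["phi2"] == pytest.approx(0.0, abs=1e-20)

    def test_fixture_point_estimate_and_fixed_se(self, aspirin_instruments):
        fit = ivw(aspirin_instruments, variance_model="fixed")
        assert fit.beta == pytest.approx(-0.3030, abs=5e-4)
        assert fit.se == pytest.approx(0.1366, abs=5e-4)
        assert fit.n_snps == 7 and fit.df == 6

    def test_underdispersion_floor(self, aspirin_instruments):
        floored = ivw(aspirin_instruments, allow_underdispersion=False)
        free = ivw(aspirin_instruments, allow_underdispersion=True)
        assert floored.se >= free.se
        assert floored.metadata["phi2"] == 1.0  # fixture underdisperses

    def test_matches_zero_intercept_wls_oracle(self):
        rng = np.random.default_rng(7)
        for L in (2, 5, 12, 20):
            ins = random_instrument_set(rng, L)
            fit = ivw(ins, variance_model="fixed")
            oracle = wls_oracle(
                ins.beta_exposure, ins.beta_outcome, ins.se_outcome, intercept=False
            )
            assert fit.beta == pytest.approx(oracle.params[0], rel=1e-10)

    def test_single_instrument_degenerates_to_wald(self):
        one = make_instrument()
        assert ivw([one]).beta == pytest.approx(single_wald(one).beta)

    def test_no_instruments_is_error(self):
        with pytest.raises(ValueError):
            ivw([])


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.005, 0.01, 0.02, 0.04])
        alpha, slope = 0.002, -0.4
        ins = instrument_set_from_arrays(
            bx=bx, sx=[0.001] * 4, by=alpha + slope * bx, sy=[0.002] * 4
        )
        fit = egger(ins)
        assert fit.intercept == pytest.approx(alpha, abs=1e-12)
        assert fit.beta == pytest.approx(slope, abs=1e-10)
        assert fit.metadata["weighted_rss"] == pytest.approx(0.0, abs=1e-18)

    def test_no_pleiotropy_limit_zero_intercept(self):
        bx = np.array([0.005, 0.01, 0.02, 0.04])
        ins = instrument_set_from_arrays(
            bx=bx, sx=[0.001] * 4, by=-0.4 * bx, sy=[0.002] * 4
        )
        assert egger(ins).intercept == pytest.approx(0.0, abs=1e-12)

    def test_fixture_slope_and_intercept(self, aspirin_instruments):
        fit = egger(aspirin_instruments)
        assert fit.beta == pytest.approx(-0.712, abs=1e-3)
        assert fit.intercept == pytest.approx(0.0032, abs=1e-4)
        assert fit.df == 5

    def test_matches_wls_oracle_after_orientation(self):
        rng = np.random.default_rng(11)
        for L in (3, 7, 15):
            ins = random_instrument_set(rng, L)
            bx, by, sy = ins.beta_exposure, ins.beta_outcome, ins.se_outcome
            s = np.where(bx < 0, -1.0, 1.0)
            oracle = wls_oracle(bx * s, by * s, sy, intercept=True)
            fit = egger(ins)
            assert fit.intercept == pytest.approx(oracle.params[0], rel=1e-8, abs=1e-12)
            assert fit.beta == pytest.approx(oracle.params[1], rel=1e-8)
            # statsmodels' WLS SEs use the same RSS/(L-2) residual scale
            assert fit.se == pytest.approx(oracle.bse[1], rel=1e-8)

    def test_input_orientation_invariance(self):
        rng = np.random.default_rng(3)
        ins = random_instrument_set(rng, 8)
        flip = rng.choice([-1.0, 1.0], 8)
        flipped = instrument_set_from_arrays(
            ins.beta_exposure * flip,
            ins.se_exposure,
            ins.beta_outcome * flip,
            ins.se_outcome,
        )
        a, b = egger(ins), egger(flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.intercept == pytest.approx(b.intercept)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger([make_instrument(vid="a"), make_instrument(vid="b")])

    def test_constant_exposure_beta_unidentifiable(self):
        ins = instrument_set_from_arrays(
            bx=[0.01] * 4, sx=[0.001] * 4, by=[0.001, 0.002, 0.003, 0.004], sy=[0.002] * 4
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            egger(ins)


class TestWeightedMedian:
    def test_equal_weights_symmetric_median(self):
        ins = instrument_set_from_arrays(
            bx=[0.01] * 3, sx=[0.001] * 3, by=[0.01, 0.02, 0.03], sy=[0.002] * 3
        )
        fit = weighted_median(ins, n_boot=50, seed=0)
        assert fit.beta == pytest.approx(2.0)

    def test_two_equal_weights_interpolate_to_midpoint(self):
        # p_j = (0.25, 0.75): interpolation at 0.5 gives the midpoint
        from mrkit.estimators import _weighted_median_point

        est = _weighted_median_point(np.array([1.0, 3.0]), np.array([1.0, 1.0]))
        assert est == pytest.approx(2.0)

    def test_fixture_reproduces_published_estimate(self, aspirin_instruments):
        fit = weighted_median(aspirin_instruments, n_boot=100, seed=1)
        assert fit.beta == pytest.approx(-0.4155, rel=5e-3)

    def test_bootstrap_se_reproducible_from_seed(self, aspirin_instruments):
        a = weighted_median(aspirin_instruments, n_boot=200, seed=42)
        b = weighted_median(aspirin_instruments, n_boot=200, seed=42)
        c = weighted_median(aspirin_instruments, n_boot=200, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_estimate_brackets_and_equal_weight_reduction(self):
        rng = np.random.default_rng(5)
        ins = random_instrument_set(rng, 9)
        ratios = ins.beta_outcome / ins.beta_exposure
        fit = weighted_median(ins, n_boot=10, seed=0)
        assert ratios.min() <= fit.beta <= ratios.max()

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            weighted_median(
                [make_instrument(vid="a"), make_instrument(vid="b")], n_boot=10, seed=0
            )


class TestOrCi:
    @pytest.mark.parametrize(
        "beta, se, expected",
        [
            # published three-method rows round-trip with z = 1.96
            (-0.3742, 0.3809, (0.6878, 0.3260, 1.4512)),
            (-0.4155, 0.1655, (0.6600, 0.4772, 0.9129)),
            (-0.349, 0.1356, (0.7054, 0.5408, 0.9201)),
        ],
    )
    def test_published_rows_round_trip(self, beta, se, expected):
        orp, lo, hi = or_ci(beta, se, level_z=1.96)
        assert orp == pytest.approx(expected[0], abs=5e-5)
        assert lo == pytest.approx(expected[1], abs=5e-5)
        assert hi == pytest.approx(expected[2], abs=5e-5)

    def test_null_effect_gives_unit_or(self):
        for s in (0.01, 1.0, 10.0):
            assert or_ci(0.0, s)[0] == 1.0

    def test_bounds_order(self):
        orp, lo, hi = or_ci(0.3, 0.2)
        assert lo < orp < hi


# ---------------------------------------------------------------------------
# Property-based invariants

positive = st.floats(1e-4, 1e-2, allow_nan=False)
effects = st.floats(-0.05, 0.05, allow_nan=False).filter(lambda b: abs(b) > 1e-4)


@st.composite
def instrument_arrays(draw, min_size=3, max_size=20):
    L = draw(st.integers(min_size, max_size))
    bx = np.array([draw(effects) for _ in range(L)])
    # constant |bx| leaves the Egger slope legitimately unidentifiable
    assume(np.ptp(np.abs(bx)) > 1e-5)
    sx = np.array([draw(positive) for _ in range(L)])
    by = np.array([draw(st.floats(-0.05, 0.05, allow_nan=False)) for _ in range(L)])
    sy = np.array([draw(positive) for _ in range(L)])
    return bx, sx, by, sy


@settings(max_examples=40, deadline=None)
@given(arrays=instrument_arrays(min_size=2))
def test_ivw_equals_zero_intercept_wls(arrays):
    bx, sx, by, sy = arrays
    ins = instrument_set_from_arrays(bx, sx, by, sy)
    fit = ivw(ins, variance_model="fixed")
    oracle = wls_oracle(bx, by, sy, intercept=False)
    assert fit.beta == pytest.approx(oracle.params[0], rel=1e-8, abs=1e-12)


@settings(max_examples=40, deadline=None)
@given(arrays=instrument_arrays())
def test_egger_with_zero_intercept_constraint_is_ivw(arrays):
    """Dropping the Egger intercept collapses the regression onto IVW."""
    bx, sx, by, sy = arrays
    ins = instrument_set_from_arrays(bx, sx, by, sy)
    constrained = wls_oracle(bx, by, sy, intercept=False)
    assert ivw(ins).beta == pytest.approx(constrained.params[0], rel=1e-8, abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(arrays=instrument_arrays(), c=st.floats(0.1, 10, allow_nan=False))
def test_scale_equivariance_of_all_estimators(arrays, c):
    """Scaling every outcome beta and SE by c scales estimates and SEs by c."""
    bx, sx, by, sy = arrays
    base = instrument_set_from_arrays(bx, sx, by, sy)
    scaled = instrument_set_from_arrays(bx, sx, c * by, c * sy)
    for fit_fn in (
        lambda s: ivw(s),
        lambda s: egger(s),
        lambda s: weighted_median(s, n_boot=20, seed=9),
    ):
        a, b = fit_fn(base), fit_fn(scaled)
        assert b.beta == pytest.approx(c * a.beta, rel=1e-6, abs=1e-10)
        assert b.se == pytest.approx(c * a.se, rel=1e-6, abs=1e-10)


@settings(max_examples=30, deadline=None)
@given(arrays=instrument_arrays(), data=st.data())
def test_orientation_invariance_ivw_and_weighted_median(arrays, data):
    bx, sx, by, sy = arrays
    flips = np.array(
        data.draw(st.lists(st.sampled_from([-1.0, 1.0]), min_size=len(bx), max_size=len(bx)))
    )
    base = instrument_set_from_arrays(bx, sx, by, sy)
    flipped = instrument_set_from_arrays(bx * flips, sx, by * flips, sy)
    assert ivw(base).beta == pytest.approx(ivw(flipped).beta, rel=1e-10, abs=1e-14)
    a = weighted_median(base, n_boot=1, seed=0)
    b = weighted_median(flipped, n_boot=1, seed=0)
    assert a.beta == pytest.approx(b.beta, rel=1e-10, abs=1e-14)
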