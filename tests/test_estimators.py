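import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpath.estimators import (
    egger,
    instrument_strength,
    ivw,
    median_point,
    mode_point,
    ratio_set,
    wald_ratio,
    weighted_median,
    weighted_mode,
    UnivariableMR,
)
from mrpath.exceptions import InsufficientInstrumentsError, UndefinedRatioError

from conftest import make_harmonized, weighted_ls_oracle, weighted_median_oracle


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,sx,by,sy,beta,se",
        [
            (0.2, 0.01, 0.1, 0.05, 0.5, 0.25),
            (0.2, 0.01, 0.0, 0.05, 0.0, 0.25),
            (-0.2, 0.01, 0.1, 0.05, -0.5, 0.25),
        ],
    )
    def test_point_and_se(self, bx, sx, by, sy, beta, se):
        est = wald_ratio(bx, sx, by, sy)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)
        assert est.ci_low <= est.beta <= est.ci_high

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)


class TestIVW:
    def test_closed_form_example(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.02, 0.05, 0.09], sy=0.01)
        est = ivw(h, random_effects=False)
        assert est.beta == pytest.approx(0.039 / 0.14)

    def test_perfect_proportionality_no_heterogeneity(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.5 * bx, sy=0.01)
        est = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert est.extras["cochran_q"] == pytest.approx(0.0, abs=1e-20)
        assert est.extras["re_scale"] == 1.0

    def test_random_effects_floored_at_fixed(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.5 * bx + np.array([1e-4, -1e-4, 5e-5, -5e-5])  # tiny heterogeneity
        h = make_harmonized(bx, by, sy=0.01)
        fe = ivw(h, random_effects=False)
        re = ivw(h, random_effects=True)
        assert re.extras["cochran_q"] / re.extras["q_df"] < 1
        assert re.se == fe.se

    def test_matches_weighted_ls_oracle_on_random_instances(self, rng):
        for _ in range(20):
            k = rng.integers(2, 50)
            bx = rng.normal(0, 0.1, k)
            by = rng.normal(0, 0.1, k)
            sy = rng.uniform(0.005, 0.05, k)
            h = make_harmonized(bx, by, sy=sy)
            est = ivw(h)
            oracle = weighted_ls_oracle(bx, by, 1 / sy**2)[0]
            assert est.beta == pytest.approx(oracle, abs=1e-10)

    def test_single_instrument_rejected(self):
        h = make_harmonized([0.1], [0.05])
        with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
            ivw(h)

    def test_binary_outcome_reports_odds_ratio(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, -0.5 * bx, sy=0.01, binary=True)
        est = ivw(h)
        assert est.odds_ratio == pytest.approx(np.exp(est.beta))
        assert est.or_ci_low == pytest.approx(np.exp(est.ci_low))


class TestEgger:
    def test_exact_linear_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.03 + 0.4 * bx, sy=0.01)
        est = egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.extras["egger_intercept"] == pytest.approx(0.03, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            k = rng.integers(3, 50)
            bx = np.abs(rng.normal(0, 0.1, k))
            by = rng.normal(0, 0.1, k)
            sy = rng.uniform(0.005, 0.05, k)
            h = make_harmonized(bx, by, sy=sy)
            est = egger(h)
            X = np.column_stack([np.ones(k), bx])
            oracle = weighted_ls_oracle(X, by, 1 / sy**2)
            assert est.extras["egger_intercept"] == pytest.approx(oracle[0], abs=1e-10)
            assert est.beta == pytest.approx(oracle[1], abs=1e-10)

    def test_all_zero_outcome_gives_zero_fit(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], sy=0.01)
        est = egger(h)
        assert est.beta == pytest.approx(0.0, abs=1e-14)
        assert est.extras["egger_intercept"] == pytest.approx(0.0, abs=1e-14)

    def test_coincides_with_ivw_for_exact_null_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.7 * bx, sy=0.01)
        assert egger(h).beta == pytest.approx(ivw(h).beta, abs=1e-12)

    def test_negative_exposure_rows_flipped(self):
        bx = np.array([0.1, -0.2, 0.3])
        by = 0.03 * np.sign(bx) + 0.4 * bx  # intercept on oriented scale
        h = make_harmonized(bx, by, sy=0.01)
        est = egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.extras["flipped_variants"] == ["rs2"]

    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_symmetric_middle(self):
        assert median_point([0.4, 0.5, 0.6], [1, 1, 1]) == pytest.approx(0.5)

    def test_contaminated_minority_ignored(self):
        est = median_point([0.5, 0.5, 0.5, 5.0], [0.2, 0.2, 0.2, 0.4])
        assert est == pytest.approx(0.5, abs=1e-9)

    def test_dominant_weight_wins(self):
        est = median_point([0.1, 0.3, 0.7], [0.005, 0.005, 0.99])
        assert est == pytest.approx(0.7, abs=0.01)

    def test_equal_weights_equals_plain_median(self, rng):
        for k in (3, 5, 7, 4, 6):
            ratios = rng.normal(0, 1, k)
            assert median_point(ratios, np.ones(k)) == pytest.approx(
                np.median(ratios), abs=1e-12
            )

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 30))
            ratios = rng.normal(0, 1, k)
            weights = rng.uniform(0.1, 5, k)
            assert median_point(ratios, weights) == pytest.approx(
                weighted_median_oracle(ratios, weights), abs=1e-12
            )

    def test_order_invariance(self, rng):
        ratios = rng.normal(0, 1, 9)
        weights = rng.uniform(0.1, 2, 9)
        perm = rng.permutation(9)
        assert median_point(ratios, weights) == pytest.approx(
            median_point(ratios[perm], weights[perm]), abs=1e-14
        )

    def test_estimator_with_bootstrap_se(self):
        bx = np.linspace(0.05, 0.3, 8)
        by = 0.5 * bx
        h = make_harmonized(bx, by, sy=0.01)
        est = weighted_median(h, n_boot=300, seed=5)
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert est.se > 0
        # seeded: reproducible
        est2 = weighted_median(h, n_boot=300, seed=5)
        assert est.se == est2.se


class TestWeightedMode:
    def test_majority_cluster(self):
        est = mode_point([0.5, 0.49, 0.51, 2.0], [1, 1, 1, 1])
        assert est == pytest.approx(0.5, abs=0.05)

    def test_identical_ratios_exact(self):
        assert mode_point([0.3, 0.3, 0.3], [1, 2, 3]) == 0.3

    def test_bimodal_prefers_heavier_cluster(self, rng):
        ratios = np.concatenate([rng.normal(0.2, 0.01, 12), rng.normal(1.0, 0.01, 8)])
        weights = np.ones(20)
        est = mode_point(ratios, weights)
        # independent dense-grid oracle over the same KDE
        wm = median_point(ratios, weights)
        mad = median_point(np.abs(ratios - wm), weights)
        bw = 0.9 * 1.4826 * mad * 20 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 200_001)
        dens = np.sum(np.exp(-0.5 * ((grid[:, None] - ratios) / bw) ** 2), axis=1)
        oracle = grid[np.argmax(dens)]
        assert est == pytest.approx(oracle, abs=1e-4)
        assert abs(est - 0.2) < 0.1

    def test_estimator_with_bootstrap_se(self):
        bx = np.linspace(0.05, 0.3, 8)
        h = make_harmonized(bx, 0.5 * bx, sy=0.01)
        est = weighted_mode(h, n_boot=200, seed=5)
        assert est.beta == pytest.approx(0.5, abs=0.02)
        assert est.se > 0


class TestInstrumentStrength:
    def test_f_statistics_and_flags(self):
        h = make_harmonized([0.1, 0.03], [0.0, 0.0], sx=np.array([0.01, 0.01]))
        res = instrument_strength(h)
        assert res.f_stats[0] == pytest.approx(100)
        assert res.f_stats[1] == pytest.approx(9)
        assert res.weak == ["rs2"]

    def test_all_strong_gives_empty_flags(self):
        h = make_harmonized([0.1, 0.2], [0.0, 0.0], sx=np.array([0.01, 0.01]))
        assert instrument_strength(h).weak == []


class TestOrientationInvariance:
    """Flipping every variant's allele coding (negate exposure and outcome
    betas together) must leave all estimates unchanged."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_all_estimators_invariant(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 20))
        bx = rng.normal(0, 0.1, k)
        bx[np.abs(bx) < 1e-3] = 1e-3
        by = rng.normal(0, 0.05, k)
        sy = rng.uniform(0.005, 0.05, k)
        h = make_harmonized(bx, by, sy=sy)
        h_flip = make_harmonized(-bx, -by, sy=sy)
        assert ivw(h).beta == pytest.approx(ivw(h_flip).beta, abs=1e-12)
        assert egger(h).beta == pytest.approx(egger(h_flip).beta, abs=1e-12)
        r, rf = ratio_set(h), ratio_set(h_flip)
        assert median_point(r.ratios, r.weights) == pytest.approx(
            median_point(rf.ratios, rf.weights), abs=1e-12
        )


class TestUnivariableModel:
    def test_fit_dispatch_and_table(self):
        bx = np.linspace(0.05, 0.4, 10)
        h = make_harmonized(bx, 0.3 * bx, sy=0.01)
        model = UnivariableMR(h, seed=1)
        assert model.fit("ivw").method == "ivw_re"
        assert model.fit("ivw_fe").method == "ivw_fe"
        df = model.fit_all(n_boot=100)
        assert set(df["method"]) == {"ivw_re", "egger", "weighted_median", "weighted_mode"}
        assert (df["n_snps"] == 10).all()

    def test_unknown_method_raises(self):
        h = make_harmonized([0.1, 0.2], [0.0, 0.0])
        with pytest.raises(ValueError):
            UnivariableMR(h).fit("nope")
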