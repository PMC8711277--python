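"""Growth model, restructuring, curve scoring and the ELEFAN GA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shorepop.growth import (GrowthParams, LengthFrequency, GASettings,
                             sovbgf_length, age_from_length,
                             recruit_threshold, build_lfq, restructure_lfq,
                             score_growth_curve, elefan_ga, phi_prime,
                             validate_against_ages, decimal_year,
                             response_surface)


class TestForwardModel:
    def test_plain_vbgf_when_c_zero(self):
        p = GrowthParams(Linf=65.25, K=0.12, t0=0.52, C=0.0, ts=0.0)
        assert sovbgf_length(p, 1.52) == pytest.approx(
            65.25 * (1 - math.exp(-0.12)), abs=1e-9)

    def test_zero_length_at_anchor(self, west_params):
        assert sovbgf_length(west_params, west_params.t0) == 0.0

    def test_seasonal_terms_cancel_at_integer_ages(self):
        # frac(t) == frac(t0) makes S_t - S_t0 vanish: plain VBGF value
        p = GrowthParams(Linf=65.25, K=0.12, t0=0.52, C=0.42, ts=0.56)
        assert sovbgf_length(p, 5.52) == pytest.approx(
            65.25 * (1 - math.exp(-0.6)), abs=1e-9)

    def test_rejects_time_before_anchor(self, west_params):
        with pytest.raises(ValueError):
            sovbgf_length(west_params, 0.1)

    @given(t=st.floats(0.52, 40.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_below_linf(self, t):
        p = GrowthParams(Linf=65.25, K=0.12, t0=0.52, C=0.42, ts=0.56)
        L = sovbgf_length(p, t)
        assert 0.0 <= L < p.Linf

    def test_monotone_and_asymptotic(self, west_params):
        t = np.linspace(west_params.t0, west_params.t0 + 90, 2000)
        L = sovbgf_length(west_params, t)
        assert np.all(np.diff(L) >= -1e-12)
        t10 = west_params.t0 + 10.0 / west_params.K
        assert sovbgf_length(west_params, t10) > 0.999 * west_params.Linf

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(Linf=-5, K=0.1)
        with pytest.raises(ValueError):
            GrowthParams(Linf=60, K=0.1, C=1.5)


class TestInverse:
    def test_zero_length_maps_to_anchor(self, west_params):
        assert age_from_length(west_params, 0.0) == west_params.t0

    def test_closed_form_inverse_without_seasonality(self):
        p = GrowthParams(Linf=65.25, K=0.12, C=0.0)
        t = age_from_length(p, 29.44)
        expected = p.t0 - math.log(1 - 29.44 / 65.25) / 0.12
        assert t == pytest.approx(expected, abs=1e-7)

    def test_round_trip_grid(self, west_params):
        for L in np.linspace(0.01, 0.99 * west_params.Linf, 100):
            t = age_from_length(west_params, L)
            assert sovbgf_length(west_params, t) == pytest.approx(L, abs=1e-6)

    def test_rejects_length_at_or_above_linf(self, west_params):
        with pytest.raises(ValueError):
            age_from_length(west_params, west_params.Linf)


class TestRecruitThreshold:
    def test_plain_vbgf_value_at_one_month(self):
        p = GrowthParams(Linf=65.25, K=0.12, C=0.0)
        assert recruit_threshold(p, 1 / 12) == pytest.approx(
            65.25 * (1 - math.exp(-0.01)), abs=1e-9)

    def test_increasing_in_k(self):
        ths = [recruit_threshold(GrowthParams(Linf=65.25, K=k))
               for k in (0.05, 0.12, 0.3, 0.8)]
        assert ths == sorted(ths)

    def test_vanishes_as_age_shrinks(self, west_params):
        assert recruit_threshold(west_params, 1e-9) < 1e-6
        with pytest.raises(ValueError):
            recruit_threshold(west_params, 0.0)


class TestBuildLfq:
    def test_basic_binning(self):
        lfq = build_lfq([1.0, 1.4, 2.1], [2019.5] * 3, bin_width=1.0)
        assert lfq.counts[:, 0].tolist() == [2, 1]
        assert lfq.bin_lower_edges.tolist() == [1.0, 2.0]

    def test_edge_goes_to_upper_bin(self):
        lfq = build_lfq([2.0], [2019.5], bin_width=1.0)
        assert lfq.bin_lower_edges[0] == 2.0

    def test_conserves_individuals(self):
        rng = np.random.default_rng(0)
        lengths = rng.uniform(1, 60, 720)
        dates = np.repeat([2019.2, 2019.4, 2019.6], 240)
        lfq = build_lfq(lengths, dates)
        assert lfq.counts.sum() == 720

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_lfq([], [], bin_width=1.0)

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        lfq = build_lfq(rng.uniform(1, 40, 300), np.repeat([2019.1, 2019.6], 150))
        path = tmp_path / "lfq.csv"
        lfq.to_csv(path)
        back = LengthFrequency.from_csv(path)
        np.testing.assert_array_equal(back.counts, lfq.counts)
        np.testing.assert_allclose(back.dates, lfq.dates, atol=1e-6)


def _single_column_lfq(counts):
    counts = np.asarray(counts).reshape(-1, 1)
    return LengthFrequency(np.arange(counts.shape[0], dtype=float), 1.0,
                           np.array([2019.0]), counts)


class TestRestructure:
    def test_flat_column_scores_zero(self):
        r = restructure_lfq(_single_column_lfq([5] * 9), ma=3)
        np.testing.assert_allclose(r.scores, 0.0, atol=1e-9)

    def test_spike_sign_pattern(self):
        r = restructure_lfq(_single_column_lfq([0, 0, 10, 0, 0]), ma=3)
        col = r.scores[:, 0]
        assert col[2] > 0 and col[1] < 0 and col[3] < 0

    def test_hand_computed_oracle(self):
        # frozen restructuring steps executed by hand for (0,0,10,0,0), ma=3:
        # truncated MA (0,10/3,10/3,10/3,0); ratio-1 (0,-1,2,-1,0);
        # isolated-peak factor 1/3 on the spike (no non-zero neighbours);
        # negative mass scaled to the positive mass (2/3); column divided
        # by its positive maximum.
        r = restructure_lfq(_single_column_lfq([0, 0, 10, 0, 0]), ma=3)
        np.testing.assert_allclose(r.scores[:, 0], [0.0, -0.5, 1.0, -0.5, 0.0],
                                   atol=1e-12)

    def test_scores_bounded(self):
        rng = np.random.default_rng(3)
        lfq = build_lfq(rng.uniform(0, 50, 2000),
                        np.repeat([2019.0, 2019.5], 1000), bin_width=2.0)
        r = restructure_lfq(lfq, ma=9)
        assert r.scores.max() <= 1.0 + 1e-12
        assert r.scores.min() >= -1.0 - 1e-12
        assert all(abs(r.scores[:, j].max() - 1.0) < 1e-12
                   for j in range(lfq.n_dates))

    def test_date_permutation_permutes_columns(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=(12, 3))
        lfq = LengthFrequency(np.arange(12.0), 1.0,
                              np.array([2019.0, 2019.3, 2019.6]), counts)
        perm = [2, 0, 1]
        lfq_p = LengthFrequency(np.arange(12.0), 1.0,
                                np.array([2019.0, 2019.3, 2019.6]),
                                counts[:, perm])
        r, rp = restructure_lfq(lfq, 5), restructure_lfq(lfq_p, 5)
        np.testing.assert_allclose(rp.scores, r.scores[:, perm], atol=1e-12)

    def test_invalid_ma_rejected(self):
        lfq = _single_column_lfq([1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            restructure_lfq(lfq, ma=4)
        with pytest.raises(ValueError):
            restructure_lfq(lfq, ma=7)


def _brute_force_score(params, restructured, neg_weight=0.5):
    """Independent plain-loop reimplementation of the frozen scoring rule."""
    lfq = restructured.lfq
    scores = restructured.scores
    asp = sum(m for col in restructured.peak_runs for (_, _, m) in col)
    # run membership lookup
    run_of = {}
    runs = []
    for j, col in enumerate(restructured.peak_runs):
        for (a, b, m) in col:
            rid = len(runs)
            runs.append(m)
            for i in range(a, b):
                run_of[(i, j)] = rid
    # cohort anchors: same rule as the implementation, recomputed here
    upper = lfq.bin_lower_edges[-1] + lfq.bin_width
    frac = min(upper / params.Linf, 0.99)
    amax = min(-math.log(1 - frac) / params.K + 1.0, 50.0)
    n_lo = math.floor(lfq.dates[0] - amax - params.t0)
    n_hi = math.ceil(lfq.dates[-1] - params.t0)
    credit, neg_seen, esp_neg = {}, set(), 0.0
    for n in range(n_lo, n_hi + 1):
        tb = params.t0 + n
        for j, t in enumerate(lfq.dates):
            if t < tb:
                continue
            s = params.C * params.K / (2 * math.pi)
            expo = (-(params.K * (t - tb))
                    + s * math.sin(2 * math.pi * (t - params.ts))
                    - s * math.sin(2 * math.pi * (tb - params.ts)))
            L = params.Linf * (1 - math.exp(expo))
            i = math.floor((L - lfq.bin_lower_edges[0]) / lfq.bin_width)
            if not 0 <= i < lfq.n_bins:
                continue
            if (i, j) in run_of:
                rid = run_of[(i, j)]
                credit[rid] = max(credit.get(rid, 0.0), scores[i, j])
            elif scores[i, j] < 0 and (i, j) not in neg_seen:
                neg_seen.add((i, j))
                esp_neg += scores[i, j]
    return (sum(credit.values()) + neg_weight * esp_neg) / asp


class TestScoring:
    def _toy(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 40, size=(10, 3))
        lfq = LengthFrequency(np.arange(0, 20, 2.0), 2.0,
                              np.array([2019.1, 2019.5, 2019.9]), counts)
        return restructure_lfq(lfq, ma=3)

    def test_matches_brute_force_enumeration(self):
        r = self._toy()
        for params in [GrowthParams(Linf=22, K=0.4, t0=0.3, C=0.2, ts=0.6),
                       GrowthParams(Linf=30, K=0.15, t0=0.7),
                       GrowthParams(Linf=18, K=0.9, t0=0.1, C=0.8, ts=0.2)]:
            assert score_growth_curve(params, r) == pytest.approx(
                _brute_force_score(params, r), abs=1e-12)

    def test_perfect_single_peak_scores_one(self):
        # one positive run per date, positioned exactly on a growth curve
        params = GrowthParams(Linf=50, K=0.5, t0=0.0, C=0.0)
        dates = np.array([2019.25, 2019.75])
        counts = np.zeros((25, 2), dtype=int)
        edges = np.arange(0, 50, 2.0)
        for j, t in enumerate(dates):
            L = sovbgf_length(params, t, anchor=params.t0 + 2019.0)
            counts[int(L // 2), j] = 50
        lfq = LengthFrequency(edges, 2.0, dates, counts)
        r = restructure_lfq(lfq, ma=3)
        assert score_growth_curve(params, r) == pytest.approx(1.0)

    def test_curve_outside_range_scores_nonpositive(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 40, size=(10, 3))
        lfq = LengthFrequency(np.arange(10, 30, 2.0), 2.0,
                              np.array([2019.1, 2019.5, 2019.9]), counts)
        r = restructure_lfq(lfq, ma=3)
        tiny = GrowthParams(Linf=5.0, K=0.01, t0=0.99)  # never reaches 10 mm
        assert score_growth_curve(tiny, r) <= 0.0

    def test_degenerate_lfq_rejected(self):
        flat = LengthFrequency(np.arange(9.0), 1.0, np.array([2019.0]),
                               np.full((9, 1), 7))
        r = restructure_lfq(flat, ma=3)
        with pytest.raises(ValueError, match="degenerate"):
            score_growth_curve(GrowthParams(Linf=10, K=0.5), r)


class TestElefanGA:
    FAST = GASettings(pop_size=20, n_generations=15, stagnation_stop=8,
                      n_restarts=1, polish=False)

    def _small_lfq(self, seed=5):
        from shorepop.simulate import simulate_lfq_lengths
        p = GrowthParams(Linf=65, K=0.12, t0=0.5, C=0.4, ts=0.5)
        dates = [2019 + (m + 0.5) / 6 for m in range(6)]
        L, D = simulate_lfq_lengths(p, dates, 150, seed=seed)
        return build_lfq(L, D, bin_width=2.0)

    def test_seeded_determinism(self):
        lfq = self._small_lfq()
        f1 = elefan_ga(lfq, ma=9, n_boot=2, seed=42, settings=self.FAST)
        f2 = elefan_ga(lfq, ma=9, n_boot=2, seed=42, settings=self.FAST)
        assert f1.params == f2.params
        assert f1.score == f2.score
        assert f1.bootstrap_params == f2.bootstrap_params

    def test_collapsed_search_space_returns_point(self):
        lfq = self._small_lfq()
        point = {"Linf": (65.0, 65.0), "K": (0.12, 0.12), "t0": (0.5, 0.5),
                 "C": (0.4, 0.4), "ts": (0.5, 0.5)}
        fit = elefan_ga(lfq, point, ma=9, n_boot=0, seed=1, settings=self.FAST)
        assert fit.params == GrowthParams(65.0, 0.12, 0.5, 0.4, 0.5)

    def test_single_date_rejected(self):
        lfq = build_lfq([5.0, 9.0, 14.0], [2019.5] * 3, bin_width=2.0)
        with pytest.raises(ValueError):
            elefan_ga(lfq, seed=0)

    def test_elitism_score_history_non_decreasing(self):
        lfq = self._small_lfq()
        fit = elefan_ga(lfq, ma=9, n_boot=0, seed=3, settings=self.FAST)
        assert np.all(np.diff(fit.score_history) >= 0)
        assert fit.score >= fit.score_history[-1]

    def test_phi_prime_consistent_with_params(self):
        lfq = self._small_lfq()
        fit = elefan_ga(lfq, ma=9, n_boot=0, seed=3, settings=self.FAST)
        assert fit.phi_prime == phi_prime(fit.params.K, fit.params.Linf)

    def test_bootstrap_percentiles_shape(self):
        lfq = self._small_lfq()
        fit = elefan_ga(lfq, ma=9, n_boot=3, seed=9, settings=self.FAST)
        pct = fit.bootstrap_percentiles()
        assert set(pct) == {"Linf", "K", "t0", "C", "ts"}
        assert pct["Linf"]["p2.5"] <= pct["Linf"]["p50"] <= pct["Linf"]["p97.5"]

    def test_response_surface_shape_and_range(self):
        lfq = self._small_lfq()
        r = restructure_lfq(lfq, 9)
        rsa = response_surface(r, linf_grid=np.linspace(50, 90, 5),
                               k_grid=np.geomspace(0.05, 0.5, 5),
                               t0_grid=np.linspace(0, 0.75, 4))
        assert len(rsa) == 25
        assert rsa["score"].max() <= 1.0


class TestPhiPrime:
    @pytest.mark.parametrize("k, linf, expected", [
        (0.12, 65.25, 2.71),   # West shore
        (0.19, 62.54, 2.87),   # East shore
        (1.0, 10.0, 2.0),
    ])
    def test_known_values(self, k, linf, expected):
        assert round(phi_prime(k, linf), 2) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            phi_prime(0.0, 60.0)
        with pytest.raises(ValueError):
            phi_prime(0.1, -1.0)


class TestValidateAgainstAges:
    def test_zero_rmse_on_curve(self, west_params):
        ages = np.linspace(1.0, 9.0, 17)
        lengths = sovbgf_length(west_params, ages)
        resid, rmse = validate_against_ages(west_params, ages, lengths)
        assert rmse == pytest.approx(0.0, abs=1e-10)

    def test_noise_bounds_rmse(self, west_params):
        rng = np.random.default_rng(0)
        rmses = []
        for _ in range(1000):
            ages = rng.uniform(1, 10, 17)
            lengths = sovbgf_length(west_params, ages) + rng.uniform(-2, 2, 17)
            rmses.append(validate_against_ages(west_params, ages, lengths)[1])
        assert max(rmses) <= 2.0

    def test_empty_rejected(self, west_params):
        with pytest.raises(ValueError):
            validate_against_ages(west_params, [], [])


def test_decimal_year_conversions():
    assert decimal_year(2019.5) == 2019.5
    assert decimal_year("2019-01-01") == 2019.0
    assert decimal_year("2019-07-02") == pytest.approx(2019 + 182 / 365, abs=1e-9)
    assert decimal_year("2019.25") == 2019.25
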