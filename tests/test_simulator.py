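"""Stochastic simulator: founder sampling, division-time law, dynamics."""

import numpy as np
import pytest
from scipy.stats import truncnorm

import labelkin as lk
from labelkin.models import decode, standard_model

from conftest import point_division_model, single_founder_histogram


class TestSampleDivisionTime:
    def test_near_degenerate_sd_stays_at_mean(self, rng):
        law = lk.DivisionLaw(100.0, 0.01, 21.0, 504.0)
        draws = lk.sample_division_times(law, 1000, rng)
        assert np.all(np.abs(draws - 100.0) < 0.05)

    def test_matches_truncated_normal_analytic_mean(self, rng):
        """1e5 draws agree with the closed-form truncated-normal mean to 1%."""
        law = lk.DivisionLaw(44.94, 19.71, 21.0, 504.0)
        a = (21.0 - 44.94) / 19.71
        b = (504.0 - 44.94) / 19.71
        expected = truncnorm.mean(a, b, loc=44.94, scale=19.71)
        draws = lk.sample_division_times(law, 100_000, rng)
        assert np.all((draws >= 21.0) & (draws <= 504.0))
        assert draws.mean() == pytest.approx(expected, rel=0.01)

    def test_point_support_is_constant(self, rng):
        law = lk.DivisionLaw(50.0, 1.0, 50.0, 50.0)
        assert lk.sample_division_time(law, rng) == 50.0


class TestSampleFounders:
    def test_zero_founders(self, rng, toy_hist):
        assert lk.sample_founders(toy_hist, 0, rng) == []

    def test_single_bin_bounds(self, rng):
        h = lk.FluorescenceHistogram([100, 1000], [17])
        cells = lk.sample_founders(h, 50, rng)
        assert all(100 <= c.fluorescence < 1000 for c in cells)

    def test_multinomial_frequencies(self, rng):
        """Empirical bin shares within 3 multinomial standard errors."""
        h = lk.FluorescenceHistogram([1, 10, 100, 1000], [2, 5, 3])
        n = 100_000
        cells = lk.sample_founders(h, n, rng)
        f = np.array([c.fluorescence for c in cells])
        counts, _ = np.histogram(f, bins=h.bin_edges)
        p = h.probabilities()
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * se)

    def test_all_zero_histogram_raises(self, rng):
        z = lk.FluorescenceHistogram([1, 10], [0])
        with pytest.raises(ValueError):
            lk.sample_founders(z, 5, rng)


class TestAnalyticExpectedState:
    @pytest.mark.parametrize(
        "f0,tau,horizon,expected",
        [
            (1024, 50, 168, (3, 8, 128.0)),
            (1000, 600, 504, (0, 1, 1000.0)),
            (512, 504, 504, (1, 2, 256.0)),
        ],
    )
    def test_closed_form(self, f0, tau, horizon, expected):
        assert lk.analytic_expected_state(f0, tau, horizon) == expected


class TestSimulate:
    def test_deterministic_synchronous_lineage(self):
        """One founder, constant 50 h cycles, 168 h: 8 cells at ~128 a.u."""
        model = point_division_model(50.0)
        init = single_founder_histogram(1024.0, threshold=1.0)
        ev, info = lk.simulate_events(
            model, init, lk.SimulationConfig(168, 1, synchronous_start=True),
            np.random.default_rng(0),
        )
        assert info["n_alive"] == 8
        np.testing.assert_allclose(ev, 1024.0 / 8, rtol=1e-9)

    def test_lineage_untracked_below_threshold(self):
        """1000 a.u. founder with threshold 10 leaves tracking after division 7."""
        model = point_division_model(50.0)
        init = single_founder_histogram(1000.0, threshold=10.0)
        ev, info = lk.simulate_events(
            model, init, lk.SimulationConfig(504, 1, synchronous_start=True),
            np.random.default_rng(0),
        )
        assert info["n_alive"] == 0
        assert info["n_dropped_cells"] == 2**7

    def test_population_bounded_by_division_cap(self):
        model = point_division_model(21.0)
        init = single_founder_histogram(1e6, threshold=0.0)
        ev, info = lk.simulate_events(
            model, init, lk.SimulationConfig(504, 3, synchronous_start=True),
            np.random.default_rng(0),
        )
        assert info["n_alive"] == 3 * 2**8  # capped at 8 divisions each

    def test_quiescent_fixed_point(self, paper_like_experiment):
        """An all-quiescent model returns the input distribution up to
        founder-sampling noise."""
        exp = paper_like_experiment
        model = decode([1.0, 44.94, 19.71], standard_model(2))
        h = lk.simulate(
            model, exp.initial, lk.SimulationConfig(504, 10_000),
            np.random.default_rng(3),
        )
        ref = lk.truncate_at_threshold(exp.initial)
        assert lk.hellinger(h, ref, "probability") < 0.05

    def test_fixed_seed_is_bit_reproducible(self, paper_like_experiment):
        exp = paper_like_experiment
        model = exp.ground_truth.decode()
        cfg = lk.SimulationConfig(168, 2000)
        a = lk.simulate(model, exp.initial, cfg, np.random.default_rng(42))
        b = lk.simulate(model, exp.initial, cfg, np.random.default_rng(42))
        assert a == b

    def test_fluorescence_halves_per_division(self):
        """Total lineage fluorescence is invariant under division."""
        model = point_division_model(50.0)
        init = single_founder_histogram(1024.0, threshold=0.0)
        ev, _ = lk.simulate_events(
            model, init, lk.SimulationConfig(168, 1, synchronous_start=True),
            np.random.default_rng(0),
        )
        assert ev.sum() == pytest.approx(1024.0, rel=1e-9)

    def test_raising_threshold_never_adds_events(self, paper_like_experiment):
        exp = paper_like_experiment
        model = exp.ground_truth.decode()
        totals = []
        for thr in (0.0, 100.0, 300.0):
            init = lk.FluorescenceHistogram(
                exp.initial.bin_edges, exp.initial.counts, thr
            )
            h = lk.simulate(
                model, init, lk.SimulationConfig(168, 3000),
                np.random.default_rng(9),
            )
            totals.append(h.total)
        assert totals == sorted(totals, reverse=True)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(lk.ConfigurationError):
            lk.SimulationConfig(horizon=0, founders=10)
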