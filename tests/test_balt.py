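import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from gonadatlas import balt


TRUTH = balt.BALTParams(B=6.0, A=3.0, L=56.0, T=4.0)


def _simulate(params=TRUTH, t=None, sd=0.0, seed=0):
    t = np.arange(45.0, 75.0, 1.0) if t is None else np.asarray(t, float)
    y = balt.balt_evaluate(params, t)
    if sd:
        y = y + np.random.default_rng(seed).normal(0, sd, t.size)
    return t, y


class TestEvaluate:
    def test_midpoint_is_half_amplitude(self):
        assert balt.balt_evaluate(TRUTH, TRUTH.L) == pytest.approx(7.5)

    def test_asymptotes(self):
        assert balt.balt_evaluate(TRUTH, -1e6) == pytest.approx(6.0)
        assert balt.balt_evaluate(TRUTH, 1e6) == pytest.approx(9.0)

    def test_rise_time_equals_T(self):
        def crossing(frac):
            return brentq(
                lambda t: balt.balt_evaluate(TRUTH, t) - (TRUTH.B + frac * TRUTH.A),
                TRUTH.L - 50, TRUTH.L + 50, xtol=1e-12)
        assert crossing(0.9) - crossing(0.1) == pytest.approx(TRUTH.T, abs=1e-9)

    def test_extreme_exponent_saturates(self):
        fast = balt.BALTParams(B=6.0, A=3.0, L=56.0, T=1e-3)
        assert balt.balt_evaluate(fast, 0.0) == 6.0
        assert balt.balt_evaluate(fast, 1e5) == 9.0
        assert np.isfinite(balt.balt_evaluate(fast, 56.0))

    def test_nonpositive_T_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            balt.BALTParams(B=6.0, A=3.0, L=56.0, T=0.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(-5, 15), st.floats(-6, 6), st.floats(40, 80),
           st.floats(0.5, 40))
    def test_monotone_and_bounded(self, b, a, loc, dur):
        p = balt.BALTParams(b, a, loc, dur)
        t = np.linspace(30, 90, 121)
        y = balt.balt_evaluate(p, t)
        lo, hi = min(b, b + a) - 1e-9, max(b, b + a) + 1e-9
        assert np.all((y >= lo) & (y <= hi))
        dy = np.diff(y)
        if a > 0:
            assert np.all(dy >= -1e-12)
        elif a < 0:
            assert np.all(dy <= 1e-12)


def _grid_oracle_rss(t, y):
    """Exhaustive (L, T) grid with (B, A) solved by linear least squares."""
    best = math.inf
    for loc in np.linspace(t.min() - 5, t.max() + 5, 60):
        for dur in np.geomspace(0.2, 3 * (t.max() - t.min()), 40):
            s = 1.0 / (1.0 + np.exp(np.clip(
                2 * math.log(9) / dur * (loc - t), -700, 700)))
            design = np.column_stack([np.ones_like(t), s])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(np.sum((design @ coef - y) ** 2))
            best = min(best, rss)
    return best


class TestFit:
    def test_noiseless_recovery_to_1e4(self):
        t, y = _simulate()
        fit = balt.balt_fit(t, y)
        p = fit.params
        assert abs(p.B - 6.0) < 1e-4 and abs(p.A - 3.0) < 1e-4
        assert abs(p.L - 56.0) < 1e-4 and abs(p.T - 4.0) < 1e-4
        assert fit.rss < 1e-10 and fit.converged

    def test_noisy_localisation_within_two_days(self):
        t, y = _simulate(sd=0.25, seed=1)
        fit = balt.balt_fit(t, y)
        assert abs(fit.params.L - 56.0) <= 2.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beats_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = balt.BALTParams(B=rng.uniform(4, 8), A=rng.uniform(-3, 3.5),
                            L=rng.uniform(48, 70), T=rng.uniform(1, 20))
        t = np.sort(rng.uniform(45, 74, 25))
        y = balt.balt_evaluate(p, t) + rng.normal(0, 0.3, t.size)
        fit = balt.balt_fit(t, y)
        assert fit.rss <= _grid_oracle_rss(t, y) + 1e-6

    def test_time_shift_equivariance(self):
        t, y = _simulate(sd=0.2, seed=4)
        fit = balt.balt_fit(t, y)
        shifted = balt.balt_fit(t + 11.5, y)
        assert shifted.params.L == pytest.approx(fit.params.L + 11.5, abs=1e-3)
        assert shifted.params.B == pytest.approx(fit.params.B, abs=1e-3)
        assert shifted.params.A == pytest.approx(fit.params.A, abs=1e-3)
        assert shifted.params.T == pytest.approx(fit.params.T, abs=1e-3)

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(ValueError, match="distinct time"):
            balt.balt_fit([50, 50, 51, 51], [1, 1, 2, 2])

    def test_parameter_recovery_median_error_below_one_day(self):
        errors = []
        for seed in range(50):
            t, y = _simulate(sd=0.25, seed=seed)
            errors.append(abs(balt.balt_fit(t, y).params.L - TRUTH.L))
        assert np.median(errors) < 1.0


class TestSelectModel:
    def test_flat_truth_prefers_constant(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(45.0, 75.0, 1.0)
            y = 6.0 + rng.normal(0, 0.25, t.size)
            wins += balt.select_model(t, y).model == "constant"
        assert wins >= 95

    def test_sigmoid_truth_prefers_sigmoid(self):
        wins = 0
        for seed in range(100):
            t, y = _simulate(sd=0.25, seed=1000 + seed)
            wins += balt.select_model(t, y).model == "sigmoid"
        assert wins >= 95

    def test_exact_sigmoid_on_five_points(self):
        t = np.array([45.0, 52.0, 56.0, 60.0, 74.0])
        y = balt.balt_evaluate(TRUTH, t)
        fit = balt.select_model(t, y)
        assert fit.model == "sigmoid"
        assert fit.rss == pytest.approx(0.0, abs=1e-10)

    def test_constant_input_selects_constant_level(self):
        t = np.arange(45.0, 75.0, 1.0)
        fit = balt.select_model(t, np.full(t.size, 6.0))
        assert fit.model == "constant" and fit.B == 6.0


class TestMCMC:
    def _fit_and_sample(self, sd=0.05, n=30, seed=0, **kw):
        t = np.linspace(45, 74, n)
        rng = np.random.default_rng(seed)
        y = balt.balt_evaluate(TRUTH, t) + rng.normal(0, sd, n)
        fit = balt.balt_fit(t, y)
        opts = balt.MCMCOptions(chains=2, iterations=2500, burn_in=500,
                                seed=seed, **kw)
        return fit, t, y, balt.balt_mcmc(fit, t, y, opts)

    def test_tight_data_gives_narrow_covering_interval(self):
        _, _, _, summary = self._fit_and_sample(sd=0.05, n=30, seed=5)
        assert summary.lower["L"] <= TRUTH.L <= summary.upper["L"]
        assert summary.upper["L"] - summary.lower["L"] < 2.0

    def test_seeded_determinism(self):
        _, _, _, s1 = self._fit_and_sample(seed=6)
        _, _, _, s2 = self._fit_and_sample(seed=6)
        assert s1.median == s2.median and s1.lower == s2.lower

    def test_degenerate_prior_pins_posterior(self):
        fit, t, y, _ = self._fit_and_sample(seed=7)
        opts = balt.MCMCOptions(chains=1, iterations=500, burn_in=100, seed=7,
                                prior_bounds={"B": (6.0, 6.0), "A": (3.0, 3.0),
                                              "L": (56.0, 56.0), "T": (4.0, 4.0)})
        summary = balt.balt_mcmc(fit, t, y, opts)
        assert summary.median["L"] == 56.0 and summary.median["T"] == \
            pytest.approx(4.0)

    def test_interval_coverage_over_replicates(self):
        covered = 0
        n_rep = 50
        for seed in range(n_rep):
            t = np.arange(45.0, 75.0, 1.0)
            rng = np.random.default_rng(seed)
            y = balt.balt_evaluate(TRUTH, t) + rng.normal(0, 0.25, t.size)
            fit = balt.balt_fit(t, y)
            s = balt.balt_mcmc(fit, t, y, balt.MCMCOptions(
                chains=2, iterations=2500, burn_in=500, seed=seed))
            covered += s.lower["L"] <= TRUTH.L <= s.upper["L"]
        assert covered / n_rep >= 0.9

    def test_requires_converged_sigmoid_fit(self):
        t = np.arange(45.0, 75.0, 1.0)
        flat = balt.constant_fit(t, np.full(t.size, 6.0))
        with pytest.raises(ValueError, match="sigmoid"):
            balt.balt_mcmc(flat, t, np.full(t.size, 6.0))


class TestClassifyProfile:
    WINDOW = (45.0, 74.0)

    def _fit(self, b, a, loc, dur):
        return balt.BALTFit(params=balt.BALTParams(b, a, loc, dur),
                            model="sigmoid", rss=0.0, r2=1.0, n=30,
                            converged=True, B=b)

    def test_curvilinear_for_incomplete_transition(self):
        # SOX9-like: slow rise still in progress at the window edge
        assert balt.classify_profile(self._fit(6, 1, 70, 25),
                                     self.WINDOW) == "curvilinear_incomplete"

    def test_switch_up_for_completed_transition(self):
        assert balt.classify_profile(self._fit(6, 3, 56, 4),
                                     self.WINDOW) == "switch_up"

    def test_switch_down_for_negative_amplitude(self):
        assert balt.classify_profile(self._fit(6, -3, 56, 4),
                                     self.WINDOW) == "switch_down"

    def test_small_amplitude_is_flat(self):
        assert balt.classify_profile(self._fit(6, 0.3, 56, 4),
                                     self.WINDOW) == "flat"

    def test_constant_model_is_flat(self):
        fit = balt.BALTFit(params=None, model="constant", rss=0.0, r2=1.0,
                           n=30, converged=True, B=6.0)
        assert balt.classify_profile(fit, self.WINDOW) == "flat"

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            balt.classify_profile(self._fit(6, 3, 56, 4), (74.0, 45.0))


class TestOnsetWindow:
    def _fit(self, loc, dur=4.0, a=3.0):
        return balt.BALTFit(params=balt.BALTParams(6.0, a, loc, dur),
                            model="sigmoid", rss=0.0, r2=1.0, n=30,
                            converged=True, B=6.0)

    def test_singleton(self):
        s = balt.onset_window([self._fit(56.0)])
        assert s.mean_l == s.median_l == 56.0
        assert s.iqr_l == (56.0, 56.0) and s.n_genes == 1

    def test_flat_fits_excluded(self):
        flat = balt.BALTFit(params=None, model="constant", rss=0.0, r2=1.0,
                            n=30, converged=True, B=6.0)
        s = balt.onset_window([self._fit(55.0), self._fit(57.0), flat,
                               self._fit(6.0, a=0.1)])
        assert s.n_genes == 2 and s.mean_l == 56.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no switch"):
            balt.onset_window([])

    def test_simulated_onset_genes_recover_printed_window(self):
        # 8 steroidogenesis-like genes, true onset 55.5 dpc, noise sd 0.25
        rng = np.random.default_rng(42)
        truth = balt.BALTParams(B=6.0, A=3.0, L=55.5, T=4.0)
        t = np.repeat(np.arange(45.0, 74.5, 1.5), 2)
        fits = []
        for _ in range(8):
            y = balt.balt_evaluate(truth, t) + rng.normal(0, 0.25, t.size)
            fits.append(balt.balt_fit(t, y))
        s = balt.onset_window(fits, window=(45.0, 74.0))
        assert 54.0 <= s.mean_l <= 57.0


class TestMatchReference:
    WINDOW = (45.0, 74.0)

    def _fits(self):
        def f(b, a, loc, dur):
            return balt.BALTFit(params=balt.BALTParams(b, a, loc, dur),
                                model="sigmoid", rss=0.0, r2=1.0, n=30,
                                converged=True, B=b)
        flat = balt.BALTFit(params=None, model="constant", rss=0.0, r2=1.0,
                            n=30, converged=True, B=6.0)
        return {
            "SOX9": f(6, 1.0, 70, 25), "CITED1": f(6, 1.2, 68, 22),
            "DHH": f(6, 0.9, 72, 28), "STAR": f(6, 3, 56, 4),
            "FLAT1": flat, "FLAT2": flat,
        }

    def test_planted_curvilinear_genes_recovered(self):
        hits = balt.match_reference(self._fits(), "SOX9", tol_l=5.0,
                                    tol_t=5.0, window=self.WINDOW)
        assert set(hits) == {"SOX9", "CITED1", "DHH"}

    def test_reference_matches_itself(self):
        hits = balt.match_reference(self._fits(), "STAR", tol_l=1.0,
                                    tol_t=1.0, window=self.WINDOW)
        assert "STAR" in hits

    def test_zero_tolerance_keeps_identical_parameters_only(self):
        hits = balt.match_reference(self._fits(), "STAR", tol_l=0.0,
                                    tol_t=0.0, window=self.WINDOW)
        assert hits == ["STAR"]

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            balt.match_reference(self._fits(), "FLAT1", 5, 5, self.WINDOW)
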