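import numpy as np
import pytest

from cueloc import mixture_model as mx
from cueloc.datatypes import GridSpec, DEFAULT_GRID
from cueloc.synthetic_data import generate_mixture_sample


@pytest.mark.parametrize("grid, expected", [
    (DEFAULT_GRID, 1.0 / (1280 * 1024)),
    (GridSpec(1, 1, 1.0), 1.0),
    (GridSpec(100, 200, 10.0), 5e-5),
])
def test_guessing_density(grid, expected):
    assert mx.guessing_density(grid) == pytest.approx(expected, rel=1e-12)


class TestMixtureNLL:
    def test_pure_guessing_closed_form(self):
        rng = np.random.default_rng(0)
        n = 37
        anchors = rng.uniform(100, 900, size=(n, 2))
        placements = rng.uniform(0, 1000, size=(n, 2))
        params = mx.MixtureParams(0.0, 50.0)
        assert mx.mixture_nll(params, anchors, placements) == pytest.approx(
            n * np.log(1280 * 1024), rel=1e-12)

    def test_gaussian_peak_single_trial(self):
        params = mx.MixtureParams(1.0, 10.0)
        nll = mx.mixture_nll(params, [(500.0, 500.0)], [(500.0, 500.0)])
        assert nll == pytest.approx(-np.log(1.0 / (2 * np.pi * 100.0)),
                                    rel=1e-12)

    def test_matches_literal_reimplementation(self):
        # independent oracle: the two-line direct sum
        rng = np.random.default_rng(42)
        anchors = rng.uniform(200, 800, size=(50, 2))
        placements = anchors + rng.normal(0, 60, size=(50, 2))
        p, sigma = 0.8, 55.0
        g = 1.0 / (1280 * 1024)
        sq = np.sum((placements - anchors) ** 2, axis=1)
        lik = p * np.exp(-sq / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2) \
            + (1 - p) * g
        oracle = -np.sum(np.log(lik))
        got = mx.mixture_nll(mx.MixtureParams(p, sigma), anchors, placements)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_finite_at_p_one_with_far_outlier(self):
        # underflow of the Gaussian tail is clamped, not -inf
        params = mx.MixtureParams(1.0, 1.0)
        nll = mx.mixture_nll(params, [(0.0, 0.0)], [(1000.0, 1000.0)])
        assert np.isfinite(nll)

    def test_empty_trials_error(self):
        with pytest.raises(ValueError):
            mx.mixture_nll(mx.MixtureParams(0.5, 50.0),
                           np.empty((0, 2)), np.empty((0, 2)))


def test_params_validation():
    with pytest.raises(ValueError):
        mx.MixtureParams(1.2, 50.0)
    with pytest.raises(ValueError):
        mx.MixtureParams(0.5, 0.5)


class TestFitMixture:
    def test_recovery_at_reference_point(self):
        anchors, placements = generate_mixture_sample(0.93, 45.0, 2000,
                                                      seed=1)
        fit = mx.fit_mixture(anchors, placements)
        assert fit.converged
        assert fit.params.p_success == pytest.approx(0.93, abs=0.02)
        assert fit.params.sigma_px == pytest.approx(45.0, rel=0.05)

    def test_degenerate_all_at_anchor(self):
        anchors = np.random.default_rng(0).uniform(100, 900, size=(50, 2))
        fit = mx.fit_mixture(anchors, anchors.copy())
        assert fit.params.sigma_px == pytest.approx(1.0, abs=1e-6)
        assert fit.params.p_success > 0.99

    def test_recovery_at_null(self):
        anchors, placements = generate_mixture_sample(0.0, 50.0, 4000,
                                                      seed=3)
        fit = mx.fit_mixture(anchors, placements)
        assert fit.params.p_success < 0.05

    def test_grid_oracle_single_instance(self):
        anchors, placements = generate_mixture_sample(0.7, 120.0, 300,
                                                      seed=9)
        fit = mx.fit_mixture(anchors, placements)
        ps = np.linspace(0, 1, 101)
        sigmas = np.linspace(1, 800, 101)
        sq = np.sum((placements - anchors) ** 2, axis=1)
        g = mx.guessing_density(DEFAULT_GRID)
        dens = np.exp(-sq[None, :] / (2 * sigmas[:, None] ** 2)) \
            / (2 * np.pi * sigmas[:, None] ** 2)          # (101, n)
        lik = ps[:, None, None] * dens[None] + (1 - ps)[:, None, None] * g
        grid_min = -np.log(np.maximum(lik, 1e-300)).sum(axis=2).min()
        assert fit.nll <= grid_min + 1e-9


class TestClassifyTrials:
    def _fit(self, sigma=45.0, p=0.9):
        return mx.MixtureFit(params=mx.MixtureParams(p, sigma), nll=0.0,
                             anchor_mode="remembered", n_trials=10,
                             converged=True, n_starts=5)

    def test_at_anchor_is_success(self):
        labels = mx.classify_trials(self._fit(), [(500, 500)], [(500, 500)])
        assert bool(labels["success"].iloc[0])
        assert labels["gaussian_density"].iloc[0] == pytest.approx(
            1 / (2 * np.pi * 45 ** 2))
        assert labels["guessing_density"].iloc[0] == pytest.approx(
            1 / (1280 * 1024))

    def test_far_tail_is_guess(self):
        labels = mx.classify_trials(self._fit(), [(500, 500)],
                                    [(500 + 450, 500)])
        assert not bool(labels["success"].iloc[0])

    def test_radial_cutoff_closed_form(self):
        # label flips exactly at r* = sigma*sqrt(-2 ln(2 pi sigma^2 g))
        sigma = 45.0
        g = 1 / (1280 * 1024)
        r_star = sigma * np.sqrt(-2 * np.log(2 * np.pi * sigma ** 2 * g))
        rng = np.random.default_rng(5)
        radii = rng.uniform(0, 3 * r_star, 1000)
        anchors = np.full((1000, 2), 500.0)
        theta = rng.uniform(0, 2 * np.pi, 1000)
        placements = anchors + radii[:, None] * np.column_stack(
            [np.cos(theta), np.sin(theta)])
        labels = mx.classify_trials(self._fit(sigma), anchors, placements)
        np.testing.assert_array_equal(labels["success"], radii < r_star)

    def test_weighted_rule_differs_when_p_small(self):
        fit = self._fit(sigma=45.0, p=0.01)
        # just inside the unweighted cutoff: unweighted success, weighted not
        g = 1 / (1280 * 1024)
        r_star = 45.0 * np.sqrt(-2 * np.log(2 * np.pi * 45.0 ** 2 * g))
        pl = [(500.0 + r_star * 0.999, 500.0)]
        unw = mx.classify_trials(fit, [(500, 500)], pl)
        wei = mx.classify_trials(fit, [(500, 500)], pl, weighted=True)
        assert bool(unw["success"].iloc[0])
        assert not bool(wei["success"].iloc[0])

    def test_nonconverged_fit_rejected(self):
        bad = mx.MixtureFit(params=mx.MixtureParams(0.5, 50.0), nll=0.0,
                            anchor_mode="remembered", n_trials=10,
                            converged=False, n_starts=5)
        with pytest.raises(ValueError):
            mx.classify_trials(bad, [(0, 0)], [(0, 0)])


def test_classification_consistency_large_sample():
    # fraction labeled success approaches p at well-separated scales
    p = 0.8
    anchors, placements = generate_mixture_sample(p, 40.0, 5000, seed=21)
    fit = mx.fit_mixture(anchors, placements)
    labels = mx.classify_trials(fit, anchors, placements)
    assert labels["success"].mean() == pytest.approx(p, abs=0.02)


def test_sigma_monotonicity():
    medians = []
    for sigma in (30.0, 60.0, 120.0):
        est = []
        for rep in range(5):
            a, pl = generate_mixture_sample(0.9, sigma, 800,
                                            seed=100 * rep + int(sigma))
            est.append(mx.fit_mixture(a, pl).params.sigma_px)
        medians.append(np.median(est))
    assert medians[0] < medians[1] < medians[2]


class TestGroupLevel:
    def test_group_fit_and_success_rates(self, default_experiment):
        trials = default_experiment.trials
        fit = mx.group_fit(trials, anchor_mode="remembered")
        assert fit.converged
        # generator delayed drift SD is 42 px for uncued, less for cued
        assert 30 < fit.params.sigma_px < 55
        rates = mx.participant_success_rates(trials, fit)
        piv = rates.groupby("cue_status")["success"].mean()
        assert piv["cued"] >= piv["uncued"] - 0.02

    def test_success_rate_aggregation(self, small_experiment):
        trials = small_experiment.trials
        fit = mx.group_fit(trials)
        rates = mx.participant_success_rates(trials, fit)
        assert ((rates["success"] >= 0) & (rates["success"] <= 1)).all()
        n_sub = trials["participant_id"].nunique()
        assert len(rates) == n_sub * 2 * 2  # condition x round

    def test_anchor_precision_prefers_remembered(self, default_experiment):
        per = mx.compare_anchor_precision(default_experiment.trials)
        # delayed placements are generated around the immediate placement,
        # so the remembered anchor must look more precise
        assert (per["sigma_remembered"] < per["sigma_studied"]).mean() > 0.9
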