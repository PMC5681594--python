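import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cueloc import group_inference as gi

from conftest import make_trials


def _long(values: np.ndarray, factor_names=("A",)) -> pd.DataFrame:
    """values shaped (n_subjects, *levels) -> long-format frame."""
    n = values.shape[0]
    rows = []
    for s in range(n):
        for idx in np.ndindex(values.shape[1:]):
            row = {"subject": f"s{s}", "y": values[(s, *idx)]}
            for name, lev in zip(factor_names, idx):
                row[name] = f"{name}{lev}"
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_level_factor_equals_paired_t_squared(self, rng):
        vals = rng.normal(0, 1, size=(15, 2))
        res = gi.rm_anova(_long(vals), "y", ["A"], "subject")["A"]
        t = gi.paired_t(vals[:, 0], vals[:, 1])
        assert res.F == pytest.approx(t.t ** 2, abs=1e-9)
        assert res.p == pytest.approx(t.p, abs=1e-9)
        assert res.df_num == 1 and res.df_den == 14

    def test_partial_eta_sq_identity(self, rng):
        vals = rng.normal(0, 1, size=(12, 2, 2))
        out = gi.rm_anova(_long(vals, ("A", "B")), "y", ["A", "B"], "subject")
        for res in out.values():
            assert res.partial_eta_sq == pytest.approx(
                res.F * res.df_num / (res.F * res.df_num + res.df_den),
                abs=1e-12)

    def test_manual_sums_of_squares_2x2(self, rng):
        # independent oracle: literal within-subject SS decomposition
        vals = rng.normal(0, 1, size=(10, 2, 2))
        n = 10
        grand = vals.mean()
        a_means = vals.mean(axis=(0, 2))
        s_a_means = vals.mean(axis=2)       # subject x A
        ss_a = n * 2 * ((a_means - grand) ** 2).sum()
        subj_means = vals.mean(axis=(1, 2))
        ss_as = 2 * ((s_a_means - a_means[None, :]
                      - subj_means[:, None] + grand) ** 2).sum()
        F_a = (ss_a / 1) / (ss_as / (n - 1))
        out = gi.rm_anova(_long(vals, ("A", "B")), "y", ["A", "B"], "subject")
        assert out["A"].F == pytest.approx(F_a, abs=1e-9)

    def test_degenerate_constant_data_flagged(self):
        vals = np.ones((8, 2))
        res = gi.rm_anova(_long(vals), "y", ["A"], "subject")["A"]
        assert res.degenerate
        assert res.F == 0.0

    def test_incomplete_design_rejected(self, rng):
        df = _long(rng.normal(size=(6, 2)))
        df = df.drop(df.index[0])
        with pytest.raises(ValueError):
            gi.rm_anova(df, "y", ["A"], "subject")

    def test_replicates_are_cell_averaged(self, rng):
        vals = rng.normal(size=(9, 2))
        long = _long(vals)
        doubled = pd.concat([long, long], ignore_index=True)
        a = gi.rm_anova(long, "y", ["A"], "subject")["A"]
        b = gi.rm_anova(doubled, "y", ["A"], "subject")["A"]
        assert a.F == pytest.approx(b.F, abs=1e-12)


class TestTTests:
    def test_identical_samples(self):
        a = np.arange(10.0)
        res = gi.paired_t(a, a.copy())
        assert res.t == 0.0 and res.cohens_d == 0.0

    def test_closed_form_t_equals_d_root_n(self):
        # difference vector with mean 1 and SD 1 -> t = sqrt(n), d = 1
        rng = np.random.default_rng(3)
        diff = rng.normal(size=25)
        diff = (diff - diff.mean()) / diff.std(ddof=1) + 1.0
        res = gi.paired_t(diff, np.zeros(25))
        assert res.t == pytest.approx(5.0, abs=1e-9)
        assert res.cohens_d == pytest.approx(1.0, abs=1e-12)

    def test_paired_cross_check_scipy(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        res = gi.paired_t(a, b)
        t, p = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)

    def test_unpaired_pooled_d(self, rng):
        a = rng.normal(1.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 40)
        res = gi.unpaired_t(a, b)
        pooled = np.sqrt((29 * a.var(ddof=1) + 39 * b.var(ddof=1)) / 68)
        assert res.cohens_d == pytest.approx((a.mean() - b.mean()) / pooled)
        assert res.df == 68


class TestLearningFactor:
    def test_rank_one_case(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        fac = gi.learning_factor(x, 2 * x + 5)
        np.testing.assert_allclose(np.abs(fac.loadings),
                                   [1 / np.sqrt(2)] * 2, atol=1e-12)
        assert fac.variance_explained == pytest.approx(1.0)

    def test_isotropic_case(self):
        x = pd.Series([1.0, -1.0, 1.0, -1.0])
        y = pd.Series([1.0, 1.0, -1.0, -1.0])  # exactly uncorrelated
        fac = gi.learning_factor(x, y)
        assert fac.variance_explained == pytest.approx(0.5)

    def test_orientation_higher_is_worse(self, default_experiment):
        trials = default_experiment.trials
        from cueloc.memory_metrics import euclidean_error
        err = euclidean_error(
            trials[["immediate_x", "immediate_y"]].to_numpy(float),
            trials[["studied_x", "studied_y"]].to_numpy(float))
        per = trials.assign(err=err).groupby("participant_id").agg(
            imm=("err", "mean"), rounds=("n_training_rounds", "mean"))
        fac = gi.learning_factor(per["imm"], per["rounds"])
        assert np.corrcoef(fac.scores, per["imm"])[0, 1] > 0
        # generator links ability to both noise and training rounds
        assert np.corrcoef(fac.scores, per["rounds"])[0, 1] > 0
        assert (fac.loadings > 0).all()


class TestSplitHalf:
    def _trials(self, errors, status="cued"):
        rows = []
        for i, e in enumerate(errors):
            rows.append(("p1", f"o{i}", (0, 0), (e, 0), (0, 0), (0, 0), 2,
                         status, "HC_uncued"))
        return make_trials(rows)

    def test_ordered_errors(self):
        t = self._trials([1, 2, 3, 4, 5, 6, 7, 8])
        out = gi.split_half_by_initial_memory(t)
        low = set(out.loc[out["initial_stratum"] == "low", "object_id"])
        assert low == {"o0", "o1", "o2", "o3"}

    def test_tie_break_by_object_id(self):
        t = self._trials([5.0] * 8)
        out = gi.split_half_by_initial_memory(t)
        low = set(out.loc[out["initial_stratum"] == "low", "object_id"])
        assert low == {"o0", "o1", "o2", "o3"}

    def test_strata_exhaustive_and_disjoint(self, small_experiment):
        out = gi.split_half_by_initial_memory(small_experiment.trials)
        active = out[out["cue_status"] != "flagged"]
        assert active["initial_stratum"].notna().all()
        sizes = active.groupby(
            ["participant_id", "cue_status", "initial_stratum"],
            observed=True).size()
        assert (sizes == 4).all()
        assert out.loc[out["cue_status"] == "flagged",
                       "initial_stratum"].isna().all()


class TestDiscrimination:
    def _ratings(self, cued_hc, uncued_hc, n=8):
        rows = []
        for i in range(n):
            rows.append({"participant_id": "p1", "object_id": f"c{i}",
                         "cue_status": "cued",
                         "rating": "HC_cued" if i < cued_hc else "HC_uncued"})
            rows.append({"participant_id": "p1", "object_id": f"u{i}",
                         "cue_status": "uncued",
                         "rating": "HC_cued" if i < uncued_hc else "LC_uncued"})
        return pd.DataFrame(rows)

    def test_perfect_discrimination_closed_form(self):
        res = gi.discrimination_chi2(self._ratings(8, 0))[0]
        # 2x2 chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 16
        assert res.chi_sq == pytest.approx(16.0)
        assert res.p < 0.001
        assert res.label == "discriminator"
        assert res.hc_hit_rate == 1.0 and res.hc_fa_rate == 0.0

    def test_identical_distributions(self):
        res = gi.discrimination_chi2(self._ratings(4, 4))[0]
        assert res.chi_sq == pytest.approx(0.0)
        assert res.label == "non_discriminator"

    def test_zero_margin_convention(self):
        res = gi.discrimination_chi2(self._ratings(0, 0))[0]
        assert res.chi_sq == 0.0
        assert res.label == "non_discriminator"

    def test_trend_threshold(self):
        # chi2 = 3.27, p ~ 0.07 < 0.1 -> discriminator under the trend rule
        res = gi.discrimination_chi2(self._ratings(6, 2))[0]
        assert stats.chi2.sf(res.chi_sq, 1) < 0.1
        assert res.label == "discriminator"

    def test_chi2_against_scipy_when_margins_ok(self):
        a, b, c, d = 6, 2, 3, 5
        chi, p = gi.chi2_2x2(a, b, c, d)
        exp = stats.chi2_contingency([[a, b], [c, d]],
                                     correction=False)
        assert chi == pytest.approx(exp.statistic, abs=1e-12)
        assert p == pytest.approx(exp.pvalue, abs=1e-12)


class TestRatingDistribution:
    def test_rows_sum_to_one(self, small_experiment):
        ratings = small_experiment.ratings.merge(
            small_experiment.trials[
                ["participant_id", "object_id", "cue_status"]],
            on=["participant_id", "object_id"])
        props = gi.rating_distribution(ratings)
        sums = props[list(("HC_cued", "LC_cued", "LC_uncued",
                           "HC_uncued"))].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_cued_rated_cued_more_often(self, default_experiment):
        ratings = default_experiment.ratings.merge(
            default_experiment.trials[
                ["participant_id", "object_id", "cue_status"]],
            on=["participant_id", "object_id"])
        props = gi.rating_distribution(ratings).groupby("cue_status")[
            "HC_cued"].mean()
        assert props["cued"] > props["uncued"]


class TestLabeledSubset:
    def test_subset_selection_and_dropping(self):
        rows = []
        # p1 has cued+uncued trials rated uncued; p2's cued all rated cued
        for pid, oid, status, rating in [
            ("p1", "a", "cued", "LC_uncued"), ("p1", "b", "uncued", "HC_uncued"),
            ("p2", "c", "cued", "HC_cued"), ("p2", "d", "uncued", "LC_uncued"),
        ]:
            rows.append((pid, oid, (0, 0), (0, 0), (10, 0), (10, 0), 2,
                         status, rating))
        trials = make_trials(rows)
        res = gi.labeled_subset_contrast(trials, "rated_uncued_only")
        assert res["n_retained"] == 1  # p2 lacks a cued cell
        with pytest.raises(ValueError):
            gi.labeled_subset_contrast(trials, "nope")

    def test_benefit_survives_exclusion_on_generator(self, default_experiment):
        res = gi.labeled_subset_contrast(default_experiment.trials,
                                         "rated_uncued_only")
        assert res["n_retained"] >= 2
        # cued stability error below uncued in the rated-uncued subset
        t = res["test"]
        assert t is not None and t.paired
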