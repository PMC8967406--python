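"""Paired-comparison designs, scores, planned contrasts and PSE estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_1samp

from chromashade import psychophysics as psy


class TestAllPairsDesign:
    @pytest.mark.parametrize("n_images,n_pairs", [(14, 91), (21, 210)])
    def test_pair_counts_match_combinatorics(self, n_images, n_pairs):
        ids = [f"img{i}" for i in range(n_images)]
        d = psy.all_pairs_design(ids, ["o1"], seed=0)
        assert len(d) == n_pairs

    def test_no_self_pairs_each_pair_once(self):
        ids = list("abcdef")
        d = psy.all_pairs_design(ids, ["o1", "o2"], seed=1)
        for _, grp in d.groupby("observer"):
            pairs = {frozenset((r.image_a, r.image_b))
                     for r in grp.itertuples()}
            assert len(pairs) == 15
            assert all(len(p) == 2 for p in pairs)

    def test_left_right_randomized_by_seed(self):
        ids = [f"i{k}" for k in range(10)]
        a = psy.all_pairs_design(ids, ["o"], seed=0)
        b = psy.all_pairs_design(ids, ["o"], seed=1)
        assert not a.equals(b)
        assert a.equals(psy.all_pairs_design(ids, ["o"], seed=0))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            psy.all_pairs_design(["a", "a", "b"], ["o"])


class TestProportionChosen:
    def _trials(self, winner_map):
        ids = list(winner_map)
        design = psy.all_pairs_design(ids, ["o1"], seed=2)
        rows = []
        for r in design.itertuples(index=False):
            # higher strength wins deterministically
            win = r.image_a if winner_map[r.image_a] > winner_map[r.image_b] \
                else r.image_b
            rows.append((r.observer, r.image_a, r.image_b, win,
                         "shape_clarity"))
        return pd.DataFrame(rows, columns=psy.TRIAL_COLUMNS)

    def test_dominant_image_scores_one(self):
        t = self._trials({f"i{k}": k for k in range(14)})
        scores = psy.proportion_chosen(t)
        assert scores.pooled["i13"] == 1.0
        assert scores.pooled["i0"] == 0.0

    def test_total_wins_equal_trial_count(self):
        t = self._trials({f"i{k}": k for k in range(14)})
        scores = psy.proportion_chosen(t)
        wins = scores.per_observer.loc["o1"] * 13
        assert wins.sum() == pytest.approx(91)

    def test_scores_in_unit_interval(self):
        t = self._trials({f"i{k}": (k * 7) % 5 for k in range(8)})
        scores = psy.proportion_chosen(t)
        assert ((scores.pooled >= 0) & (scores.pooled <= 1)).all()


class TestPlannedContrast:
    def test_zero_scores_zero_F(self):
        S = np.zeros((5, 4))
        r = psy.planned_contrast_F(S, [1, -1, 1, -1])
        assert r.F == 0.0
        assert r.df == (1, 4)

    def test_zero_variance_degenerate_flag(self):
        S = np.tile([1.0, 0.0, 0.0], (3, 1))
        r = psy.planned_contrast_F(S, [2, -1, -1])
        assert r.degenerate
        assert np.isinf(r.F)

    def test_matches_t_squared_oracle(self):
        """F equals the square of a one-sample t on the contrast scores."""
        rng = np.random.default_rng(10)
        S = rng.random((4, 6))
        w = np.array([-5, -3, -1, 1, 3, 5], dtype=float)
        r = psy.planned_contrast_F(S, w)
        t = ttest_1samp(S @ w, 0.0)
        assert r.F == pytest.approx(t.statistic**2)
        assert r.p == pytest.approx(t.pvalue)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        S = rng.random((6, 4))
        w = [1, -1, 1, -1]
        assert psy.planned_contrast_F(S, w).F == pytest.approx(
            psy.planned_contrast_F(10.0 * S, w).F)

    def test_nonzero_weight_sum_rejected(self):
        with pytest.raises(ValueError):
            psy.planned_contrast_F(np.zeros((3, 2)), [1, 1])

    def test_single_observer_rejected(self):
        with pytest.raises(ValueError):
            psy.planned_contrast_F(np.zeros((1, 2)), [1, -1])


class TestContrastWeights:
    def test_sums_and_orthogonality(self):
        ws = psy.contrast_weight_sets()
        names = list(ws)
        for w in ws.values():
            assert abs(w.sum()) < 1e-12
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert abs(np.dot(ws[a], ws[b])) < 1e-12

    def test_linear_weights_match_orthogonal_polynomial_table(self):
        """Linear trend weights for 7 levels: -3,-2,-1,0,1,2,3."""
        trend = psy.contrast_weight_sets()["linear_trend"]
        assert list(trend[:7]) == [-3, -2, -1, 0, 1, 2, 3]
        assert list(trend[7:]) == [-3, -2, -1, 0, 1, 2, 3]


class TestEstimatePse:
    def test_exact_half_returns_level(self):
        r = psy.estimate_pse([10, 20, 30], [0.9, 0.5, 0.1])
        assert r.pse == 20
        assert r.in_range

    def test_midpoint_interpolation(self):
        r = psy.estimate_pse([10, 20], [0.6, 0.4])
        assert r.pse == pytest.approx(15.0)
        assert r.bracketing_levels == (10.0, 20.0)

    def test_no_crossing_flagged(self):
        r = psy.estimate_pse([10, 20, 30], [0.9, 0.8, 0.7])
        assert r.pse is None
        assert not r.in_range

    @pytest.mark.parametrize("n_per_level", [50, 500, 5000])
    def test_logistic_recovery_within_one_level(self, n_per_level):
        """PSE recovered within one level spacing from binomial data."""
        rng = np.random.default_rng(100 + n_per_level)
        levels = np.arange(10, 90, 8.0)
        true_mid, slope = 43.0, 0.15
        p_true = 1.0 / (1.0 + np.exp(slope * (levels - true_mid)))
        props = rng.binomial(n_per_level, p_true) / n_per_level
        r = psy.estimate_pse(levels, props)
        assert r.in_range
        assert abs(r.pse - true_mid) <= 8.0

    def test_bias_shrinks_with_trials(self):
        """Consistency: average absolute error decreases with n per level."""
        levels = np.arange(10, 90, 8.0)
        true_mid, slope = 43.0, 0.15
        p_true = 1.0 / (1.0 + np.exp(slope * (levels - true_mid)))
        err = {}
        for n in (50, 5000):
            rng = np.random.default_rng(7)
            errs = []
            for _ in range(30):
                props = rng.binomial(n, p_true) / n
                r = psy.estimate_pse(levels, props)
                errs.append(abs(r.pse - true_mid))
            err[n] = np.mean(errs)
        assert err[5000] < err[50]


class TestTrialIO:
    def _trials(self):
        return pd.DataFrame(
            [("o1", "a", "b", "a", "shape_clarity"),
             ("o1", "a", "c", "c", "shape_clarity")],
            columns=psy.TRIAL_COLUMNS)

    def test_round_trip_identity(self, tmp_path):
        t = self._trials()
        path = tmp_path / "trials.csv"
        psy.write_trials(t, path)
        assert psy.load_trials(path).equals(t)

    def test_invalid_chosen_rejected_with_row_number(self, tmp_path):
        t = self._trials()
        t.loc[1, "chosen"] = "z"
        path = tmp_path / "bad.csv"
        t.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 1"):
            psy.load_trials(path)

    def test_header_remapping(self, tmp_path):
        t = self._trials().rename(columns={"observer": "subj",
                                           "chosen": "response"})
        path = tmp_path / "alt.csv"
        t.to_csv(path, index=False)
        loaded = psy.load_trials(
            path, column_map={"subj": "observer", "response": "chosen"})
        assert list(loaded["observer"]) == ["o1", "o1"]

    def test_scores_written_with_pooled_row(self, tmp_path):
        scores = psy.proportion_chosen(self._trials())
        psy.write_scores(scores, tmp_path / "scores.csv")
        out = pd.read_csv(tmp_path / "scores.csv", index_col=0)
        assert "pooled" in out.index
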