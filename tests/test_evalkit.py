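"""Challenge scoring metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from petrelease.evalkit import (
    ChallengeTruth,
    Submission,
    fp_tp_ratio,
    jaccard,
    rmse_displacement,
    rmse_percent,
    score_submission,
)


class TestRMSEPercent:
    def test_perfect_estimate_is_zero(self):
        assert rmse_percent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_worked_example(self):
        assert rmse_percent([1.0, 3.0], [2.0, 2.0]) == pytest.approx(50.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        est, tru = rng.random(50), rng.random(50) + 0.5
        a = rmse_percent(est, tru)
        b = rmse_percent(3.7 * est, 3.7 * tru)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_truth_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rmse_percent([1.0, -1.0], [1.0, -1.0])


class TestRMSEDisplacement:
    def _maps(self):
        shape = (6, 6, 3)
        region = np.zeros(shape, dtype=bool)
        region[1:4, 1:4, 1] = True
        truth_pre = np.full(shape, 2.0)
        truth_post = truth_pre.copy()
        truth_post[region] = 2.0 * (1 - 0.25)
        return region, truth_pre, truth_post

    def test_perfect_delta_scores_zero(self):
        region, pre, post = self._maps()
        assert rmse_displacement(pre, post, pre, post, region) == 0.0

    def test_uniform_10pct_error_scores_10(self):
        region, pre, post = self._maps()
        est_post = pre - 1.1 * (pre - post)  # overestimates delta by 10%
        val = rmse_displacement(pre, est_post, pre, post, region)
        assert val == pytest.approx(10.0)

    def test_common_additive_bias_cancels(self):
        region, pre, post = self._maps()
        val = rmse_displacement(pre + 0.7, post + 0.7, pre, post, region)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_zero_displacement_rejected(self):
        region, pre, _ = self._maps()
        with pytest.raises(ZeroDivisionError):
            rmse_displacement(pre, pre, pre, pre, region)


class TestJaccard:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 2), dtype=bool)
        m[1:3, 1:3, 0] = True
        assert jaccard(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 2), dtype=bool)
        b = np.zeros((4, 4, 2), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 1] = True
        assert jaccard(a, b) == 0.0

    def test_direct_set_count(self):
        a = np.zeros(6, dtype=bool)
        b = np.zeros(6, dtype=bool)
        a[[0, 1, 2]] = True   # TP {0,1}, FP {2}
        b[[0, 1, 3]] = True   # FN {3}
        assert jaccard(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        with pytest.warns(UserWarning):
            assert jaccard(np.zeros(3, bool), np.zeros(3, bool)) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(bool, 30), hnp.arrays(bool, 30))
    def test_symmetry(self, a, b):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert jaccard(a, b) == jaccard(b, a)
            assert 0.0 <= jaccard(a, b) <= 1.0

    def test_monotone_in_false_positives(self):
        truth = np.zeros(40, dtype=bool)
        truth[:10] = True
        prev = 1.0
        mask = truth.copy()
        for extra in (12, 14, 16):
            mask[extra] = True
            j = jaccard(mask, truth)
            assert j < prev
            prev = j


class TestFpTpRatio:
    def test_perfect_mask_zero(self):
        m = np.zeros(10, dtype=bool)
        m[:4] = True
        assert fp_tp_ratio(m, m) == 0.0

    def test_counting_example(self):
        truth = np.zeros(30, dtype=bool)
        truth[:10] = True
        mask = truth.copy()
        mask[15] = True  # 1 extra FP per 10 TP
        assert fp_tp_ratio(mask, truth) == pytest.approx(10.0)

    def test_independent_of_true_negatives(self):
        truth = np.zeros(20, dtype=bool)
        truth[:5] = True
        mask = truth.copy()
        mask[10] = True
        big_truth = np.concatenate([truth, np.zeros(100, bool)])
        big_mask = np.concatenate([mask, np.zeros(100, bool)])
        assert fp_tp_ratio(mask, truth) == fp_tp_ratio(big_mask, big_truth)

    def test_no_true_positives_undefined(self):
        truth = np.zeros(5, dtype=bool)
        truth[0] = True
        assert np.isnan(fp_tp_ratio(np.zeros(5, bool), truth))


def _tiny_truth(rng, n_subjects=3):
    shape = (8, 8, 4)
    brain = np.zeros(shape, dtype=bool)
    brain[1:7, 1:7, :] = True
    rois = np.zeros(shape, dtype=np.int16)
    rois[2:4, 2:4, 1] = 1
    rois[5:6, 5:7, 2] = 2
    pre = [rng.random(shape) + 1.0 for _ in range(n_subjects)]
    post = []
    for m in pre:
        p = m.copy()
        p[rois == 1] *= 0.75
        p[rois == 2] *= 0.80
        post.append(p)
    return ChallengeTruth(bp_pre=pre, bp_post=post, roi_labels=rois,
                          deltas=(0.25, 0.20), brain_mask=brain)


class TestScoreSubmission:
    def test_truth_scores_itself_perfectly(self):
        truth = _tiny_truth(np.random.default_rng(1))
        sub = Submission(bp_pre=[m.copy() for m in truth.bp_pre],
                         bp_post=[m.copy() for m in truth.bp_post],
                         displacement_mask=truth.displacement_mask.copy())
        rep = score_submission(sub, truth)
        assert rep.rmse_bp_mean == 0.0
        assert rep.rmse_displacement_pooled == 0.0
        assert rep.jaccard == 1.0
        assert rep.fp == 0 and rep.fn == 0

    def test_per_map_values_average_to_reported_mean(self):
        rng = np.random.default_rng(2)
        truth = _tiny_truth(rng)
        sub = Submission(
            bp_pre=[m + 0.1 * rng.random(m.shape) for m in truth.bp_pre],
            bp_post=[m + 0.1 * rng.random(m.shape) for m in truth.bp_post],
            displacement_mask=truth.displacement_mask.copy(),
        )
        rep = score_submission(sub, truth)
        assert rep.rmse_bp_mean == pytest.approx(np.mean(rep.rmse_bp_per_map))
        assert len(rep.rmse_bp_per_map) == 2 * truth.n_subjects

    def test_pooled_metrics_match_brute_force(self):
        rng = np.random.default_rng(3)
        truth = _tiny_truth(rng)
        est_pre = [m + 0.05 for m in truth.bp_pre]
        est_post = [m - 0.02 for m in truth.bp_post]
        sub = Submission(est_pre, est_post, truth.displacement_mask.copy())
        rep = score_submission(sub, truth)
        brain = truth.brain_mask
        est = np.concatenate([m[brain] for m in est_pre + est_post])
        tru = np.concatenate([m[brain] for m in truth.bp_pre + truth.bp_post])
        assert rep.rmse_bp_pooled == pytest.approx(rmse_percent(est, tru))

    def test_missing_maps_reported(self):
        truth = _tiny_truth(np.random.default_rng(4))
        sub = Submission(bp_pre=truth.bp_pre[:1], bp_post=truth.bp_post,
                         displacement_mask=truth.displacement_mask)
        with pytest.raises(ValueError, match="expected 3 pre"):
            score_submission(sub, truth)

    def test_graded_submissions_rank_consistently(self):
        # noisier displacement estimates must score lower J and higher
        # displacement RMSE (rank association between the two criteria)
        rng = np.random.default_rng(5)
        truth = _tiny_truth(rng, n_subjects=4)
        rmses, js = [], []
        for noise in (0.0, 0.05, 0.15, 0.4, 0.9):
            sub = Submission(
                bp_pre=[m + noise * rng.standard_normal(m.shape)
                        for m in truth.bp_pre],
                bp_post=[m + noise * rng.standard_normal(m.shape)
                         for m in truth.bp_post],
                displacement_mask=(
                    truth.displacement_mask
                    if noise == 0 else
                    truth.displacement_mask
                    ^ (rng.random(truth.brain_mask.shape) < noise / 3)),
            )
            rep = score_submission(sub, truth)
            rmses.append(rep.rmse_displacement_pooled)
            js.append(rep.jaccard)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(rmses, js)
        assert rho < 0

    def test_report_serialisation(self, tmp_path):
        truth = _tiny_truth(np.random.default_rng(6))
        sub = Submission([m.copy() for m in truth.bp_pre],
                         [m.copy() for m in truth.bp_post],
                         truth.displacement_mask.copy())
        rep = score_submission(sub, truth)
        out = tmp_path / "report.json"
        rep.to_json(out)
        import json

        loaded = json.loads(out.read_text())
        assert loaded["jaccard"] == 1.0
        table = rep.to_table()
        assert "metric" in table.columns
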