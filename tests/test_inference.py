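"""Nested CV, metrics, permutation machinery, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from roimkl import (
    RunConfig,
    build_kernels,
    fdr_bh,
    nmse,
    pearson_r,
    permutation_test,
    run_nested_cv,
)
from roimkl.io import DegenerateLabelsError

from conftest import make_study


class TestPearsonR:
    def test_identity_and_reversal(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # (1,2,4) vs (2,2,5): cov 5/3? direct formula gives 5/sqrt(42/9*6)
        assert pearson_r([1, 2, 4], [2, 2, 5]) == pytest.approx(5 / np.sqrt(28))

    def test_constant_input_is_undefined(self):
        with pytest.raises(DegenerateLabelsError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestNMSE:
    def test_arithmetic_by_definition(self):
        # MSE 25, range 10 -> 2.5
        assert nmse([0.0, 10.0], [5.0, 5.0]) == pytest.approx(2.5)

    def test_perfect_prediction_is_zero(self):
        assert nmse([1.0, 4.0, 2.0], [1.0, 4.0, 2.0]) == 0.0

    def test_homogeneity_in_label_scale(self):
        rng = np.random.default_rng(0)
        y, p = rng.normal(size=8), rng.normal(size=8)
        k = 3.7
        assert nmse(k * y, k * p) == pytest.approx(k * nmse(y, p))

    def test_zero_range_raises(self):
        with pytest.raises(DegenerateLabelsError):
            nmse([2.0, 2.0], [1.0, 3.0])


finite_vecs = arrays(np.float64, 6,
                     elements=st.floats(-50, 50, allow_nan=False))


@settings(max_examples=30, deadline=None)
@given(y=finite_vecs, p=finite_vecs)
def test_pearson_r_bounded_and_symmetric(y, p):
    if np.std(y) == 0 or np.std(p) == 0:
        return
    r = pearson_r(y, p)
    assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
    assert r == pytest.approx(pearson_r(p, y))


@settings(max_examples=30, deadline=None)
@given(y=finite_vecs, p=finite_vecs,
       shift=st.floats(-100, 100, allow_nan=False))
def test_nmse_invariant_to_common_shift(y, p, shift):
    if np.ptp(y) == 0:
        return
    assert nmse(y + shift, p + shift) == pytest.approx(nmse(y, p), rel=1e-9,
                                                       abs=1e-9)


class TestFdrBH:
    def test_hand_computed_step_up(self):
        # thresholds q*k/m = .0125,.025,.0375,.05 -> first three rejected
        reject, p_adj = fdr_bh([0.001, 0.012, 0.02, 0.8], q=0.05)
        assert reject.sum() == 3
        assert not reject[3]

    def test_all_ones_reject_nothing(self):
        reject, _ = fdr_bh([1.0, 1.0, 1.0])
        assert reject.sum() == 0

    def test_single_p_reduces_to_raw_threshold(self):
        reject, p_adj = fdr_bh([0.04], q=0.05)
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_empty_family_raises(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestRunNestedCV:
    def test_noiseless_signal_is_decoded(self, strong_study):
        parc, labels, data, ks = strong_study
        cv = run_nested_cv(ks, labels, RunConfig())
        assert cv.r > 0.9
        assert cv.nmse_divisor == pytest.approx(np.ptp(labels.values))

    def test_null_decoding_shows_no_positive_bias(self, fast_cfg):
        # under the null, leave-one-subject-out predictions are pulled toward
        # the training mean, which *anti*-correlates with the held-out label;
        # what must hold for valid inference is the absence of positive bias
        rs = []
        for seed in range(50):
            _, labels, _, ks = make_study(
                n_subjects=20, n_regions=1, grid_shape=(8, 8, 8),
                blocks=(), seed=seed,
            )
            rs.append(run_nested_cv(ks, labels, fast_cfg).r)
        assert np.mean(rs) < 0.1
        assert np.median(rs) <= 0.0

    def test_minimal_three_subject_run_completes(self, fast_cfg):
        _, labels, _, ks = make_study(n_subjects=3, seed=5)
        cv = run_nested_cv(ks, labels, fast_cfg)
        assert cv.y_pred.shape == (3,)
        assert len(cv.per_fold) == 3
        assert all(fm.model.train_idx.size == 2 for fm in cv.per_fold)

    def test_degenerate_labels_rejected(self, fast_cfg):
        _, labels, _, ks = make_study(n_subjects=6, seed=6)
        with pytest.raises(DegenerateLabelsError):
            run_nested_cv(ks, np.full(6, 3.0), fast_cfg)

    def test_chosen_C_comes_from_grid(self, strong_study, fast_cfg):
        _, labels, _, ks = strong_study
        cv = run_nested_cv(ks, labels, fast_cfg)
        assert set(fm.C for fm in cv.per_fold) <= set(fast_cfg.C_grid)

    def test_heldout_corruption_leaves_fold_model_untouched(self, fast_cfg):
        # the held-out subject's label and features never reach its fold model
        parc, labels, data, ks = make_study(n_subjects=8, seed=21)
        cv = run_nested_cv(ks, labels, fast_cfg)
        s = 3
        y_bad = labels.values.copy()
        y_bad[s] += 500.0
        cv_bad = run_nested_cv(ks, y_bad, fast_cfg)
        a, b = cv.per_fold[s].model, cv_bad.per_fold[s].model
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.dual_coef, b.dual_coef)
        assert a.offset == b.offset and cv.per_fold[s].C == cv_bad.per_fold[s].C

    def test_label_vector_subject_mismatch_raises(self, fast_cfg):
        _, labels, _, ks = make_study(n_subjects=6, seed=7)
        labels.subjects = labels.subjects[::-1]
        with pytest.raises(ValueError):
            run_nested_cv(ks, labels, fast_cfg)


class TestPermutationTest:
    def test_strong_signal_hits_boundary_p(self, fast_cfg):
        _, labels, _, ks = make_study(
            n_subjects=12, n_regions=1, grid_shape=(8, 8, 8),
            blocks=(("R01", "harmful"),), noise_sd=1e-3, effect_size=1.0,
            seed=11,
        )
        cv = run_nested_cv(ks, labels, fast_cfg)
        perm = permutation_test(ks, labels, fast_cfg, cv)
        # formula consistency with the returned null draws
        assert perm.p_r == pytest.approx(
            (1 + np.sum(perm.null_r >= cv.r)) / (1 + fast_cfg.n_permutations)
        )
        # observed r beats all 99 nulls -> p = 1/100 with add-one correction
        assert perm.p_r == pytest.approx(0.01)
        assert cv.p_r == perm.p_r

    def test_bit_reproducible_given_seed(self, fast_cfg):
        _, labels, _, ks = make_study(n_subjects=8, seed=31)
        cfg = RunConfig(C_grid=[1.0, 100.0], n_permutations=10, seed=77)
        cv = run_nested_cv(ks, labels, cfg)
        a = permutation_test(ks, labels, cfg, cv)
        b = permutation_test(ks, labels, cfg, cv)
        assert np.array_equal(a.null_r, b.null_r)
        assert np.array_equal(a.null_nmse, b.null_nmse)

    def test_detects_moderate_signal_more_often_than_not(self):
        # power floor: at an effect giving population decoding r around 0.6
        # the permutation test at alpha=.05 should reject in most studies
        rejections = 0
        n_studies = 15
        for s in range(n_studies):
            _, labels, _, ks = make_study(
                n_subjects=16, n_regions=1, grid_shape=(8, 8, 8),
                blocks=(("R01", "harmful"),), effect_size=2.5,
                noise_sd=1.0, seed=2000 + s,
            )
            cfg_s = RunConfig(C_grid=[1.0, 100.0], n_permutations=49, seed=s)
            cv = run_nested_cv(ks, labels, cfg_s)
            perm = permutation_test(ks, labels, cfg_s, cv)
            rejections += perm.p_r <= 0.05
        assert rejections > n_studies / 2
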