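"""Feature-relevance scorers, ensemble combination, top-K selection."""

import numpy as np
import pytest

from frfteeg.selection import (
    REPORTED_SELECTED_FEATURES,
    combine_scores,
    ensemble_select,
    relieff_scores,
    score_cfs,
    score_information_gain,
    score_nca,
    score_relieff,
    score_variance,
    select_top_k,
)


# ---- information gain -------------------------------------------------------

def test_ig_perfect_split_of_balanced_classes_is_one_bit():
    y = np.repeat([0, 1], 50)
    x = np.where(y == 0, 1.0, 2.0)
    assert score_information_gain(x, y) == pytest.approx(1.0)


def test_ig_constant_feature_is_zero():
    assert score_information_gain(np.full(20, 3.0), np.repeat([0, 1], 10)) == 0.0


def test_ig_binning_separates_distant_clusters():
    assert score_information_gain(
        np.array([1.0, 1.1, 9.0, 9.1]), np.array([0, 0, 1, 1])
    ) == pytest.approx(1.0)


def test_ig_invariant_to_affine_rescaling(rng):
    y = rng.integers(0, 2, 100)
    x = rng.normal(size=100) + y
    a = score_information_gain(x, y)
    b = score_information_gain(7.0 * x - 3.0, y)
    assert b == pytest.approx(a)


# ---- ReliefF ---------------------------------------------------------------

def test_relieff_ranks_label_copy_feature_first():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 200)
    X = rng.normal(size=(200, 10))
    X[:, 3] = y.astype(float)
    w = relieff_scores(X, y)
    assert int(np.argmax(w)) == 3


def test_relieff_constant_feature_scores_zero(rng):
    y = np.repeat([0, 1], 20)
    X = rng.normal(size=(40, 4))
    X[:, 2] = 5.0
    assert relieff_scores(X, y)[2] == pytest.approx(0.0)


def test_relieff_null_feature_near_zero():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 500)
    X = rng.uniform(size=(500, 3))
    w = relieff_scores(X, y)
    assert np.all(np.abs(w) < 0.1)


def test_relieff_single_feature_wrapper_matches_batch(rng):
    y = np.repeat([0, 1], 25)
    X = rng.normal(size=(50, 5))
    batch = relieff_scores(X, y)
    assert score_relieff(X[:, 2], X, y) == pytest.approx(batch[2])


def test_relieff_single_class_rejected(rng):
    with pytest.raises(ValueError):
        relieff_scores(rng.normal(size=(10, 2)), np.zeros(10))


# ---- variance, NCA, CFS ----------------------------------------------------

@pytest.mark.parametrize(
    "x,expected", [([0, 2], 1.0), ([4, 4, 4], 0.0), ([1, 2, 3], 2 / 3)]
)
def test_population_variance_formula(x, expected):
    assert score_variance(np.asarray(x, float)) == pytest.approx(expected)


def test_nca_constant_feature_gives_same_class_fraction():
    y = np.repeat([0, 1], 50)
    x = np.full(100, 2.0)
    assert score_nca(x, y) == pytest.approx(49 / 99)


def test_nca_separated_clusters_approach_closed_form_limit():
    """Two far-apart class-pure clusters: the adaptive kernel width caps the
    score below 1. For balanced clusters at separation d the width tends to
    ~0.505*d, so cross-class weights tend to exp(-1/0.505) and the score to
    49 / (49 + 50*exp(-1/0.505)) ~ 0.876 -- far above the 0.495 null."""
    rng = np.random.default_rng(4)
    y = np.repeat([0, 1], 50)
    x = np.where(y == 0, 0.0, 100.0) + rng.normal(0, 0.5, 100)
    got = score_nca(x, y)
    limit = 49 / (49 + 50 * np.exp(-1 / (2 * 50 * 50 / (100 * 99))))
    assert got == pytest.approx(limit, abs=0.02)
    assert got > 0.85


def test_nca_permutation_null_matches_prior():
    vals = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], 50)
        x = rng.normal(size=100)
        vals.append(score_nca(x, rng.permutation(y)))
    # balanced prior: same-class share of the other 99 samples = 49/99
    assert np.mean(vals) == pytest.approx(49 / 99, abs=0.05)


def test_nca_scale_invariant(rng):
    y = np.repeat([0, 1], 30)
    x = rng.normal(size=60) + 2 * y
    assert score_nca(5.0 * x + 1.0, y) == pytest.approx(score_nca(x, y))


def test_cfs_label_copy_and_constants():
    y = np.repeat([0, 1], 10)
    assert score_cfs(y.astype(float), y) == pytest.approx(1.0)
    assert score_cfs(np.full(20, 2.0), y) == 0.0


def test_cfs_point_biserial_example():
    assert score_cfs(
        np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1])
    ) == pytest.approx(0.89443, abs=1e-5)


# ---- aggregation and selection ---------------------------------------------

def test_combine_identical_rows_returns_normalized_row():
    row = np.array([2.0, 4.0, 6.0])
    per = np.tile(row, (5, 1))
    assert np.allclose(combine_scores(per), [0.0, 0.5, 1.0])


def test_combine_degenerate_weights_select_one_scorer(rng):
    per = rng.uniform(size=(5, 6))
    out = combine_scores(per, weights=[1, 0, 0, 0, 0])
    span = per[0].max() - per[0].min()
    assert np.allclose(out, (per[0] - per[0].min()) / span)


def test_combine_rejects_all_zero_weights(rng):
    with pytest.raises(ValueError):
        combine_scores(rng.uniform(size=(5, 3)), weights=[0] * 5)


def test_top_k_tie_break_by_lower_index():
    assert select_top_k(np.array([0.9, 0.2, 0.9, 0.5]), 2) == [0, 2]
    assert select_top_k(np.array([0.9, 0.5, 0.1]), 3) == [0, 1, 2]
    assert select_top_k(np.array([0.9, 0.5, 0.1]), 1) == [0]
    with pytest.raises(ValueError):
        select_top_k(np.array([1.0, 0.5]), 3)


def test_planted_signal_recovery(planted_matrix):
    hits = 0
    for seed in range(6):
        X, y, planted = planted_matrix(seed)
        res = ensemble_select(X, y, k=5)
        hits += len(set(res.selected) & planted) >= 4
    assert hits == 6


def test_cfs_mode_ranks_by_correlation_only(planted_matrix):
    X, y, _ = planted_matrix(0)
    res = ensemble_select(X, y, k=5, mode="cfs")
    cfs_row = res.per_scorer[4]
    assert res.selected == select_top_k(cfs_row, 5)


def test_reported_preset_is_a_valid_16_feature_subset():
    assert len(REPORTED_SELECTED_FEATURES) == 16
    assert len(set(REPORTED_SELECTED_FEATURES)) == 16
    assert all(0 <= i < 34 for i in REPORTED_SELECTED_FEATURES)


def test_ensemble_scores_bounded(planted_matrix):
    X, y, _ = planted_matrix(1)
    res = ensemble_select(X, y, k=16)
    assert np.all(res.ensemble >= 0.0) and np.all(res.ensemble <= 1.0)
    assert len(res.selected) == 16
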