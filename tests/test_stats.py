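"""Permutation inference: cluster, direction-swap, spread, paired, FDR."""

import itertools

import numpy as np
import pytest

from thetaflow.data import ConfigurationError, ENCODING, EpochWindow, ValidationError
from thetaflow.stats import (
    GridMap,
    balanced_subsample_stat,
    cluster_perm_test,
    direction_swap_null,
    fdr_correct,
    paired_perm_test,
    spatial_spread_test,
)


# -- cluster test -----------------------------------------------------------

def test_planted_offset_recovered_as_single_cluster(rng):
    a = rng.standard_normal((30, 17))
    b = rng.standard_normal((30, 17))
    a[:, 5:9] += 1.5  # indices 5..8, a contiguous frequency band
    res = cluster_perm_test(a, b, n_perm=200, seed=0)
    sig = res.significant
    assert len(sig) == 1
    assert set(range(5, 9)) <= set(sig[0].indices.tolist())
    assert sig[0].p <= 0.01


def test_cluster_grid_adjacency(rng):
    a = rng.standard_normal((25, 8, 8))
    b = rng.standard_normal((25, 8, 8))
    a[:, 2:4, 2:4] += 2.0
    res = cluster_perm_test(a, b, n_perm=100, adjacency="grid4", seed=1)
    sig = res.significant
    assert sig, "planted 2x2 grid blob not detected"
    flat = {int(i) for i in sig[0].indices}
    assert {2 * 8 + 2, 2 * 8 + 3, 3 * 8 + 2, 3 * 8 + 3} <= flat


def test_cluster_test_type_one_error_calibrated(rng):
    hits = 0
    n_rep = 150
    for r in range(n_rep):
        a = rng.standard_normal((12, 10))
        b = rng.standard_normal((12, 10))
        res = cluster_perm_test(a, b, n_perm=100, seed=5_000 + r)
        hits += bool(res.significant)
    rate = hits / n_rep
    level = 5 / 101  # finest achievable p <= .05 at n_perm = 100
    se = np.sqrt(level * (1 - level) / n_rep)
    assert abs(rate - level) < 3 * se + 1e-9


def test_cluster_test_rejects_too_few_permutations(rng):
    a, b = rng.standard_normal((5, 4)), rng.standard_normal((5, 4))
    with pytest.raises(ConfigurationError):
        cluster_perm_test(a, b, n_perm=0)
    with pytest.raises(ConfigurationError):
        cluster_perm_test(a, b, n_perm=10)


# -- direction-swap null ----------------------------------------------------

def test_direction_swap_detects_strong_coupling(focus_correct_highload):
    res = direction_swap_null(
        focus_correct_highload, ("GRID_C2", "HIPP1"), ENCODING,
        n_perm=100, seed=3,
    )
    assert res.observed < 0  # encoding flow is cortex -> hippocampus
    assert res.p <= 0.05
    assert res.p >= 1.0 / (res.n_perm + 1)


def test_direction_swap_identical_channels_p_one(rng):
    from conftest import make_trialset

    x = rng.standard_normal((24, 1, 80))
    ts = make_trialset(np.concatenate([x, x], axis=1), fs=40.0)
    res = direction_swap_null(
        ts, ("ch0", "ch1"), EpochWindow("c", -2.0, 0.0),
        n_perm=50, seed=0, padding_s=5.0,
    )
    assert res.observed == pytest.approx(0.0, abs=1e-10)
    assert res.p == 1.0


def test_direction_swap_deterministic(focus_correct_highload):
    kw = dict(n_perm=30, seed=9, padding_s=5.0)
    a = direction_swap_null(focus_correct_highload, ("GRID_C2", "HIPP1"), ENCODING, **kw)
    b = direction_swap_null(focus_correct_highload, ("GRID_C2", "HIPP1"), ENCODING, **kw)
    assert a.p == b.p and a.observed == b.observed
    np.testing.assert_array_equal(a.null_distribution, b.null_distribution)


# -- spatial spread test ----------------------------------------------------

def test_spread_planted_focus_significant(rng):
    focus = np.zeros(64)
    focus[18] = 2.0
    focus[[17, 19, 10, 26]] = 1.0
    task = 0.5 * rng.standard_normal((30, 64)) + focus
    fix = 0.5 * rng.standard_normal((30, 64))
    res = spatial_spread_test(task, fix, seed=2)
    assert res.extras["significant_median_rule"]
    assert res.p <= 0.05


def test_spread_identical_maps_degenerate_true_distribution(rng):
    one = np.tile(rng.standard_normal(64), (20, 1))
    fix = 0.1 * rng.standard_normal((20, 64))
    res = spatial_spread_test(one, fix, seed=4)
    true = res.extras["true_distribution"]
    norm2 = float(one[0] @ one[0])
    np.testing.assert_allclose(true, norm2, rtol=1e-9)
    assert res.extras["significant_median_rule"]


def test_spread_null_not_significant(rng):
    pool = rng.standard_normal((24, 64))
    res = spatial_spread_test(pool, rng.standard_normal((24, 64)), seed=6)
    assert res.p > 0.05
    with pytest.raises(ValidationError):
        spatial_spread_test(pool[:3], pool[:8])


def test_spread_excludes_missing_contacts_consistently(rng):
    task = rng.standard_normal((10, 64)) + 1.0
    fix = rng.standard_normal((10, 64))
    task[:, 5] = np.nan
    res = spatial_spread_test(task, fix, n_iter=50, n_perm=30, seed=1)
    assert np.isfinite(res.observed)


# -- balanced subsampling ---------------------------------------------------

def test_subsample_mean_matches_grand_mean(rng):
    values = rng.normal(3.0, 1.0, 300)
    med, reps = balanced_subsample_stat(
        values, None, stat_fn=np.mean, fraction=0.10, n_reps=200, seed=0
    )
    subsample_sd = values.std() / np.sqrt(30)
    assert abs(med - values.mean()) < 2 * subsample_sd
    assert reps.shape == (200,)


def test_subsample_fraction_one_is_identity(rng):
    values = rng.normal(size=40)
    med, reps = balanced_subsample_stat(values, None, np.mean, fraction=1.0,
                                        n_reps=10, seed=1)
    np.testing.assert_allclose(reps, values.mean())


def test_subsample_deterministic_and_min_bound(rng):
    values = rng.normal(size=50)
    a = balanced_subsample_stat(values, None, np.mean, seed=7)
    b = balanced_subsample_stat(values, None, np.mean, seed=7)
    assert a[0] == b[0]
    with pytest.raises(ConfigurationError, match="minimum"):
        balanced_subsample_stat(values, None, np.mean, fraction=0.02,
                                min_trials=5)


# -- paired permutation -----------------------------------------------------

def test_paired_identical_gives_p_one(rng):
    a = rng.normal(size=10)
    res = paired_perm_test(a, a.copy(), n_perm=100, seed=0)
    assert res.observed == 0.0
    assert res.p == 1.0


def test_paired_separated_pairs_hit_resolution_floor(rng):
    a = -np.abs(rng.normal(1.0, 0.05, 15))
    b = np.abs(rng.normal(1.0, 0.05, 15))
    res = paired_perm_test(a, b, n_perm=2**15, seed=0)
    assert res.p == pytest.approx(2.0 / 2**15)  # both all-plus and all-minus


def test_paired_matches_exhaustive_enumeration(rng):
    n = 10
    a, b = rng.normal(size=n), rng.normal(size=n)
    res = paired_perm_test(a, b, n_perm=2**n, seed=0)
    d = a - b
    obs = d.mean()
    count = sum(
        abs(np.dot(signs, d) / n) >= abs(obs) - 1e-12
        for signs in itertools.product([-1.0, 1.0], repeat=n)
    )
    assert res.p == pytest.approx(count / 2**n)


def test_paired_requires_two_pairs():
    with pytest.raises(ValidationError):
        paired_perm_test(np.array([1.0]), np.array([2.0]))


# -- FDR --------------------------------------------------------------------

def test_fdr_step_up_hand_example():
    adj, reject = fdr_correct([0.001, 0.01, 0.02, 0.5])
    assert list(reject) == [True, True, True, False]
    adj1, rej1 = fdr_correct([0.03])
    assert adj1[0] == pytest.approx(0.03) and rej1[0]
    _, rej_all1 = fdr_correct([1.0, 1.0, 1.0])
    assert not rej_all1.any()
    with pytest.raises(ValidationError):
        fdr_correct([])
    with pytest.raises(ValidationError):
        fdr_correct([0.5, 1.2])


# -- GridMap ----------------------------------------------------------------

def test_grid_map_vector_and_argmax():
    v = np.full((8, 8), np.nan)
    v[2, 1] = 0.5
    v[3, 3] = 1.5
    gm = GridMap(values=v)
    assert gm.argmax_position() == ("D", 4)
    assert gm.vector().tolist() == [0.5, 1.5]
    with pytest.raises(ValidationError):
        GridMap(values=np.zeros((4, 4)))
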