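"""Permutation-based inference for spectra, grid maps and paired scalars.

All tests are nonparametric: cluster-based permutation tests in the style of
Maris & Oostenveld control multiplicity over frequencies / grid contacts /
sources; the direction-swap null destroys consistent directionality for the
net-Granger statistic while keeping per-channel trial counts fixed; the
spatial spread test captures the collinearity of grid activation patterns
through scalar products of split-half mean maps; balanced subsampling guards
correct-vs-incorrect comparisons against unequal trial counts.

Every routine takes an explicit seed, reports the permutation count, and
floors p-values at 1/(n_perm + 1) — a permutation p of exactly zero is never
returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .data import ConfigurationError, EpochWindow, TrialSet, ValidationError
from . import granger as _granger

GRID_SHAPE = (8, 8)


@dataclass
class GridMap:
    """One scalar per 8x8 grid contact: values[column A..H, row 1..8].

    Absent contacts are NaN.
    """

    values: np.ndarray
    measure: str = "delta_granger"
    band: tuple[float, float] | None = None
    window: EpochWindow | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != GRID_SHAPE:
            raise ValidationError(f"grid map must be 8x8, got {self.values.shape}")

    def vector(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Flattened values over present contacts (optionally a shared mask)."""
        if mask is None:
            mask = ~np.isnan(self.values)
        return self.values[mask]

    def argmax_position(self) -> tuple[str, int]:
        idx = np.unravel_index(np.nanargmax(self.values), GRID_SHAPE)
        return "ABCDEFGH"[idx[0]], idx[1] + 1


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p: float
    threshold_95: float
    n_perm: int
    seed: int
    extras: dict = field(default_factory=dict)


@dataclass
class Cluster:
    indices: np.ndarray  # indices into the statistic's (flattened) axes
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    alpha: float
    tail: str = "two-sided"

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= self.alpha]


# --------------------------------------------------------------------------
# cluster-based permutation test
# --------------------------------------------------------------------------

def _t_stat(a_sum, a_sq, n_a, b_sum, b_sq, n_b):
    """Independent two-sample t from group sums/sums-of-squares."""
    ma, mb = a_sum / n_a, b_sum / n_b
    va = (a_sq - n_a * ma**2) / (n_a - 1)
    vb = (b_sq - n_b * mb**2) / (n_b - 1)
    sp = np.sqrt(np.maximum(va / n_a + vb / n_b, 1e-300))
    return (ma - mb) / sp


def _components(mask: np.ndarray, adjacency, shape: tuple[int, ...]) -> list[np.ndarray]:
    """Connected True-components of a flattened mask under the adjacency."""
    if not mask.any():
        return []
    if sparse.issparse(adjacency) or isinstance(adjacency, np.ndarray):
        adj = sparse.csr_matrix(adjacency)
        sel = np.flatnonzero(mask)
        sub = adj[sel][:, sel]
        n, lab = connected_components(sub, directed=False)
        return [sel[lab == i] for i in range(n)]
    if adjacency == "chain":
        idx = np.flatnonzero(mask)
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        return [g for g in np.split(idx, splits)]
    if adjacency == "grid4":
        lab, n = ndimage.label(
            mask.reshape(shape), structure=ndimage.generate_binary_structure(2, 1)
        )
        lab = lab.ravel()
        return [np.flatnonzero(lab == i) for i in range(1, n + 1)]
    raise ConfigurationError(f"unknown adjacency {adjacency!r}")


def cluster_perm_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 200,
    alpha: float = 0.05,
    adjacency="chain",
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test between two trial-level conditions.

    ``cond_a`` / ``cond_b``: (n_trials, *shape) observations.  The pointwise
    statistic is a two-sample t; the cluster-forming threshold is the
    pointwise two-sided permutation ``cluster_alpha`` quantile; cluster mass
    is the summed t within a connected suprathreshold component, and the
    null is the maximum |mass| over label permutations.
    """
    if n_perm < 20:
        raise ConfigurationError(f"n_perm={n_perm} too coarse; need >= 20")
    a, b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if a.shape[1:] != b.shape[1:]:
        raise ValidationError("condition shapes differ")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("need >= 2 trials per condition")
    shape = a.shape[1:]
    pooled = np.concatenate([a, b]).reshape(a.shape[0] + b.shape[0], -1)
    n_a, n_tot = a.shape[0], pooled.shape[0]
    rng = np.random.default_rng(seed)

    sq = pooled**2
    tot_sum, tot_sq = pooled.sum(0), sq.sum(0)
    stats = np.empty((n_perm + 1, pooled.shape[1]))
    for i in range(n_perm + 1):
        sel = np.arange(n_a) if i == 0 else rng.permutation(n_tot)[:n_a]
        a_sum, a_sq = pooled[sel].sum(0), sq[sel].sum(0)
        stats[i] = _t_stat(a_sum, a_sq, n_a, tot_sum - a_sum, tot_sq - a_sq, n_tot - n_a)

    lo = np.quantile(stats[1:], cluster_alpha / 2, axis=0)
    hi = np.quantile(stats[1:], 1 - cluster_alpha / 2, axis=0)

    def masses(stat_map):
        out = []
        for comp in _components(stat_map > hi, adjacency, shape):
            out.append((comp, stat_map[comp].sum()))
        for comp in _components(stat_map < lo, adjacency, shape):
            out.append((comp, stat_map[comp].sum()))
        return out

    null_max = np.zeros(n_perm)
    for i in range(1, n_perm + 1):
        m = masses(stats[i])
        null_max[i - 1] = max((abs(v) for _, v in m), default=0.0)

    clusters = []
    for comp, mass in masses(stats[0]):
        p = (1 + np.sum(null_max >= abs(mass))) / (n_perm + 1)
        clusters.append(Cluster(indices=comp, mass=float(mass), p=float(p)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(clusters=clusters, alpha=alpha)


# --------------------------------------------------------------------------
# direction-swap null for net Granger flow
# --------------------------------------------------------------------------

def _swapped_csd_batch(products: np.ndarray, swap_masks: np.ndarray) -> np.ndarray:
    """Average per-trial CSD products with channel labels exchanged per mask.

    ``products``: (n_trials, n_freqs, 2, 2); ``swap_masks``: (batch,
    n_trials) booleans marking trials whose channel labels are swapped.
    """
    swapped = products[:, :, ::-1, :][:, :, :, ::-1]
    n_trials = products.shape[0]
    return np.where(
        swap_masks[:, :, None, None, None], swapped[None], products[None]
    ).sum(axis=1) / n_trials


def direction_swap_null(
    ts: TrialSet,
    pair: tuple[str, str],
    window: EpochWindow,
    band: tuple[float, float] = (4.0, 8.0),
    n_perm: int = 200,
    seed: int = 0,
    **gc_cfg,
) -> PermutationResult:
    """Permutation test of net flow against a direction-scrambled null.

    The observed statistic is the band-averaged Delta-Granger of the pair.
    Each permutation exchanges the two channels' labels in a random half of
    the trials (trial counts per channel unchanged), recomputes both
    directional spectra and takes their band difference; the two-sided p is
    the exceedance fraction of |null| over |observed|.
    """
    products, freqs, fs = _granger.trial_csd_products(
        ts, list(pair), window, **gc_cfg
    )
    n_trials = products.shape[0]
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm + 1, n_trials), dtype=bool)
    for i in range(1, n_perm + 1):
        masks[i, rng.permutation(n_trials)[: n_trials // 2]] = True
    s_batch = _swapped_csd_batch(products, masks)
    deltas = _granger.band_delta_batch(s_batch, freqs, fs, band)
    observed, null = float(deltas[0]), deltas[1:]
    p = float((1 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1))
    return PermutationResult(
        observed=observed,
        null_distribution=null,
        p=p,
        threshold_95=float(np.percentile(np.abs(null), 95)),
        n_perm=n_perm,
        seed=seed,
    )


# --------------------------------------------------------------------------
# spatial spread (scalar-product) test
# --------------------------------------------------------------------------

def _as_matrix(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return maps.reshape(maps.shape[0], -1)
    return np.stack([m.values.ravel() for m in maps])


def spatial_spread_test(
    per_trial_maps_task,
    per_trial_maps_fixation,
    n_iter: int = 200,
    n_perm: int = 100,
    inner_iter: int = 20,
    seed: int = 0,
) -> PermutationResult:
    """Split-half scalar-product test of a spatially structured grid effect.

    TRUE distribution: ``n_iter`` random 50/50 splits of the task trials;
    each draw is the scalar product of the two half-mean map vectors.  NULL
    distribution: the same, but the two halves are drawn from trials mixed
    across task and fixation.  The headline criterion is
    ``median(true) > 95th percentile(null)`` (with a stricter variant,
    ``5th percentile(true) > 95th percentile(null)``, also reported); the
    returned p-value is calibrated by an outer permutation that recomputes
    the median statistic under random task/fixation relabelings.

    Contacts that are missing (NaN) in either condition are excluded from
    both map vectors.
    """
    task = _as_matrix(per_trial_maps_task)
    fix = _as_matrix(per_trial_maps_fixation)
    if task.shape[0] < 4 or fix.shape[0] < 4:
        raise ValidationError("need >= 4 trials in each condition")
    ok = ~(np.isnan(task).any(axis=0) | np.isnan(fix).any(axis=0))
    task, fix = task[:, ok], fix[:, ok]
    rng = np.random.default_rng(seed)
    n_task = task.shape[0]
    half = n_task // 2

    def split_products(mat: np.ndarray, n: int, it: int, r) -> np.ndarray:
        out = np.empty(it)
        for i in range(it):
            perm = r.permutation(mat.shape[0])
            v1 = mat[perm[:n]].mean(axis=0)
            v2 = mat[perm[n : 2 * n]].mean(axis=0)
            out[i] = v1 @ v2
        return out

    true_dist = split_products(task, half, n_iter, rng)
    pool = np.concatenate([task, fix])
    null_dist = split_products(pool, half, n_iter, rng)

    observed = float(np.median(true_dist))
    thr95 = float(np.percentile(null_dist, 95))
    null_medians = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pool.shape[0])
        pseudo_task = pool[perm[:n_task]]
        null_medians[b] = np.median(split_products(pseudo_task, half, inner_iter, rng))
    p = float((1 + np.sum(null_medians >= observed)) / (n_perm + 1))
    return PermutationResult(
        observed=observed,
        null_distribution=null_medians,
        p=p,
        threshold_95=thr95,
        n_perm=n_perm,
        seed=seed,
        extras={
            "true_distribution": true_dist,
            "null_split_distribution": null_dist,
            "significant_median_rule": observed > thr95,
            "significant_strict_rule": float(np.percentile(true_dist, 5)) > thr95,
        },
    )


# --------------------------------------------------------------------------
# balanced subsampling, paired permutation, FDR
# --------------------------------------------------------------------------

def balanced_subsample_stat(
    correct_trials,
    incorrect_trials,
    stat_fn,
    fraction: float | None = 0.10,
    n_reps: int = 200,
    min_trials: int = 2,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Median of ``stat_fn`` over random subsets of the correct trials.

    Balances a correct-vs-incorrect comparison by evaluating the statistic
    on ``n_reps`` random subsets of ``fraction`` of the correct trials
    (default 10 %, the typical error rate).  With ``fraction=None`` the
    subset size is matched exactly to the number of incorrect trials.
    """
    n = correct_trials.n_trials if isinstance(correct_trials, TrialSet) else len(correct_trials)
    if fraction is None:
        if incorrect_trials is None:
            raise ConfigurationError(
                "fraction=None requires incorrect_trials for size matching"
            )
        size = (incorrect_trials.n_trials
                if isinstance(incorrect_trials, TrialSet)
                else len(incorrect_trials))
    else:
        size = n if fraction >= 1.0 else int(round(fraction * n))
    if size < min_trials:
        raise ConfigurationError(
            f"subset of {size} trials below the statistic's minimum of {min_trials}"
        )
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        idx = np.sort(rng.permutation(n)[:size])
        if isinstance(correct_trials, TrialSet):
            sub = TrialSet(
                data=correct_trials.data[idx],
                fs=correct_trials.fs,
                t0_offset=correct_trials.t0_offset,
                channels=list(correct_trials.channels),
                trials=[correct_trials.trials[i] for i in idx],
            )
        else:
            sub = np.asarray(correct_trials)[idx]
        reps[r] = stat_fn(sub)
    return float(np.median(reps)), reps


def paired_perm_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
) -> PermutationResult:
    """Paired permutation test on per-participant scalars (sign-flip null).

    Observed statistic: mean(a - b).  When ``n_perm >= 2**n`` the null is
    the exact enumeration of all sign assignments; otherwise ``n_perm``
    random sign flips.  Two-sided p with floor 1/(n_perm + 1).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("values_a and values_b must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValidationError("need >= 2 pairs")
    d = a - b
    observed = float(d.mean())
    if n_perm >= 2**n:
        bits = np.arange(2**n)[:, None] >> np.arange(n) & 1
        signs = np.where(bits, 1.0, -1.0)
        null = signs @ d / n
        n_eff = signs.shape[0]
        p = float(np.sum(np.abs(null) >= abs(observed) - 1e-12) / n_eff)
        p = max(p, 1.0 / n_eff)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        null = signs @ d / n
        n_eff = n_perm
        p = float((1 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1))
    return PermutationResult(
        observed=observed,
        null_distribution=null,
        p=p,
        threshold_95=float(np.percentile(np.abs(null), 95)),
        n_perm=n_eff,
        seed=seed,
    )


def fdr_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask at q)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, reject
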