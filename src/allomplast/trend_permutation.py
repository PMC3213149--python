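"""Permutation test for a trend in SMA slope against a covariate.

Is an organ's nutritional plasticity (its SMA slope against body size)
changing systematically with a covariate such as rearing temperature?  The
observed trend coefficient b_O is the OLS regression coefficient of
per-group SMA slope on covariate value.  The null distribution is built by
(1) centering each group at its bivariate mean so groups differ only in
shape, (2) pooling all centered points, and (3) repeatedly dealing the
pooled points back into groups of the original sizes without replacement,
recomputing the per-group slopes and the trend coefficient b_A each time.
The default p-value is the raw proportion of b_A at or beyond b_O in the
chosen tail (lower tail: fraction of b_A <= b_O, ties counted); the
add-one estimator (k + 1)/(n_perm + 1), which can never return exactly
zero, is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_io import ConfigurationError

__all__ = [
    "PermutationTrendResult",
    "center_groups",
    "slope_trend",
    "permutation_trend_test",
]

TAILS = ("lower", "upper", "two_sided")


@dataclass(frozen=True)
class PermutationTrendResult:
    """Observed trend b_O, permuted trends b_A, and the resulting p-value."""

    observed_b: float
    permuted_b: tuple[float, ...] = field(repr=False)
    n_perm: int
    p_value: float
    p_value_add_one: float
    tail: str
    seed: int
    group_sizes: dict[float, int]
    n_redraws: int = 0

    def recompute_p(self) -> float:
        """Re-apply the tail rule to the stored coefficients (audit hook)."""
        return _tail_p(np.asarray(self.permuted_b), self.observed_b, self.tail)


def _tail_p(b_a: np.ndarray, b_o: float, tail: str) -> float:
    if tail == "lower":
        return float(np.mean(b_a <= b_o))
    if tail == "upper":
        return float(np.mean(b_a >= b_o))
    return float(np.mean(np.abs(b_a) >= abs(b_o)))


def _coerce_groups(groups: Mapping) -> tuple[np.ndarray, list[np.ndarray]]:
    covs, arrs = [], []
    for cov, data in groups.items():
        arr = np.asarray(data, float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ConfigurationError("each group must be an (n, 2) array of (log body, log organ)")
        if len(arr) == 0:
            raise ConfigurationError(f"group {cov!r} is empty")
        if len(arr) < 2:
            raise ConfigurationError(f"group {cov!r} needs >= 2 points to carry a slope")
        if len(arr) == 2:
            warnings.warn(f"group {cov!r} has only 2 points; its SMA slope is exact but noisy")
        covs.append(float(cov))
        arrs.append(arr)
    return np.asarray(covs), arrs


def center_groups(groups: Mapping) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each group at its bivariate mean and pool.

    Returns (pooled (N, 2) array, group index per point, covariate value
    per group).  Centering leaves each group's SMA slope unchanged.
    """
    covs, arrs = _coerce_groups(groups)
    centered = [a - a.mean(axis=0) for a in arrs]
    labels = np.concatenate([np.full(len(a), i) for i, a in enumerate(centered)])
    return np.vstack(centered), labels, covs


def _batch_group_slopes(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """SMA slopes for each row of paired (P, k) blocks; NaN where degenerate."""
    mx = X.mean(axis=1)
    my = Y.mean(axis=1)
    vx = (X * X).mean(axis=1) - mx * mx
    vy = (Y * Y).mean(axis=1) - my * my
    cov = (X * Y).mean(axis=1) - mx * my
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.sign(cov) * np.sqrt(vy / vx)
    bad = (vx <= 0) | (vy <= 0) | (cov == 0)
    slopes[bad] = np.nan
    return slopes


def _slopes_for_index(pooled: np.ndarray, idx: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-group SMA slopes for each permutation row of index matrix idx."""
    P = idx.shape[0]
    G = len(edges) - 1
    out = np.empty((P, G))
    X, Y = pooled[:, 0], pooled[:, 1]
    for g in range(G):
        block = idx[:, edges[g]:edges[g + 1]]
        out[:, g] = _batch_group_slopes(X[block], Y[block])
    return out


def slope_trend(groups: Mapping, permissive: bool = False) -> float:
    """OLS coefficient of per-group SMA slope on covariate value.

    Needs >= 3 covariate values to regress; with exactly 2 the two-point
    slope is returned only in permissive mode, with a warning.
    """
    covs, arrs = _coerce_groups(groups)
    if len(covs) < 3:
        if len(covs) == 2 and permissive:
            warnings.warn("trend over 2 groups is a two-point slope, not a regression")
        else:
            raise ConfigurationError("slope_trend needs >= 3 covariate values")
    slopes = []
    for arr in arrs:
        s = _batch_group_slopes(arr[None, :, 0], arr[None, :, 1])[0]
        if np.isnan(s):
            raise ConfigurationError("a group has zero variance or zero correlation; slope undefined")
        slopes.append(s)
    slopes = np.asarray(slopes)
    tc = covs - covs.mean()
    return float((slopes @ tc) / (tc @ tc))


def permutation_trend_test(
    groups: Mapping,
    tail: str = "lower",
    n_perm: int = 1000,
    seed: int | None = None,
    max_redraws: int = 10_000,
) -> PermutationTrendResult:
    """Permutation test of the slope-on-covariate trend coefficient.

    ``groups`` maps covariate value (e.g. temperature in °C) to an (n, 2)
    array of (log body, log organ) points.  Permutations that produce a
    degenerate group (zero variance or exactly zero correlation, so the SMA
    slope is undefined) are redrawn; the redraw count is reported.
    """
    if tail not in TAILS:
        raise ConfigurationError(f"tail must be one of {TAILS}")
    if seed is None:
        raise ConfigurationError("permutation_trend_test requires a seed")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")

    observed = slope_trend(groups)
    pooled, labels, covs = center_groups(groups)
    sizes = np.bincount(labels.astype(int))
    edges = np.concatenate([[0], np.cumsum(sizes)])
    N = len(pooled)
    tc = covs - covs.mean()
    denom = float(tc @ tc)

    rng = np.random.default_rng(seed)

    def trend_for(idx: np.ndarray) -> np.ndarray:
        slopes = _slopes_for_index(pooled, idx, edges)
        return (slopes @ tc) / denom  # NaN propagates from degenerate groups

    idx = rng.permuted(np.tile(np.arange(N), (n_perm, 1)), axis=1)
    b_a = trend_for(idx)
    n_redraws = 0
    while np.isnan(b_a).any():
        bad = np.flatnonzero(np.isnan(b_a))
        n_redraws += len(bad)
        if n_redraws > max_redraws:
            raise RuntimeError("too many degenerate permutations; data are near-degenerate")
        redraw = rng.permuted(np.tile(np.arange(N), (len(bad), 1)), axis=1)
        b_a[bad] = trend_for(redraw)

    p_raw = _tail_p(b_a, observed, tail)
    if tail == "lower":
        k = int(np.count_nonzero(b_a <= observed))
    elif tail == "upper":
        k = int(np.count_nonzero(b_a >= observed))
    else:
        k = int(np.count_nonzero(np.abs(b_a) >= abs(observed)))
    return PermutationTrendResult(
        observed_b=observed,
        permuted_b=tuple(b_a.tolist()),
        n_perm=n_perm,
        p_value=p_raw,
        p_value_add_one=(k + 1.0) / (n_perm + 1.0),
        tail=tail,
        seed=seed,
        group_sizes={float(c): int(s) for c, s in zip(covs, sizes)},
        n_redraws=n_redraws,
    )
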