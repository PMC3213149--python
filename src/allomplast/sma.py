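"""Standardized major axis (SMA) line fitting and common-slope tests.

SMA (reduced major axis) is the model-II regression appropriate when both
variables carry error, as with log organ size against log body size.  Its
slope magnitude is sd(y)/sd(x) with the sign of the correlation; on a
log-log plot of organ against body size this slope is the allometric
coefficient b, the quantity used throughout to measure nutritional
plasticity of one trait relative to another.

Two between-group slope-homogeneity tests are provided:

* ``likelihood_ratio`` — the standard SMA common-slope construction.  At a
  candidate common slope b the residual axis ``y − b·x`` and fitted axis
  ``y + b·x`` are uncorrelated within a group if and only if b is that
  group's SMA slope, so the statistic

      T(b) = −Σ_i (n_i − 5/2) · log(1 − r_i(b)²)

  (r_i(b) the residual/fitted correlation in group i, with the small-sample
  weight of Warton & Weber) is minimized over b to estimate the common
  slope, and min T is referred to a chi-square with (g − 1) degrees of
  freedom.
* ``permutation`` — group labels of group-centered points are permuted and
  the statistic recomputed; assumption-light internal cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_io import ConfigurationError

__all__ = ["SMAFit", "CommonSlopeResult", "fit_sma", "common_slope_test"]


class InsufficientDataError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class SMAFit:
    """An SMA line fit: slope b (the allometric coefficient), intercept c.

    ``ci_lower <= slope_b <= ci_upper`` is the (1 − alpha) confidence
    interval from the correlation-based construction
    ``B = F(1−alpha; 1, n−2)·(1−r²)/(n−2);  ci = b·(√(B+1) ∓ √B)``.
    """

    n: int
    slope_b: float
    intercept_c: float
    r: float
    ci_lower: float
    ci_upper: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.slope_b <= self.ci_upper):
            raise ValueError("CI must bracket the slope")


@dataclass(frozen=True)
class CommonSlopeResult:
    """Outcome of a slope-homogeneity test across ≥ 2 groups."""

    group_fits: dict[str, SMAFit]
    common_slope: float
    statistic: float
    df: int
    p_value: float
    method: str
    n_perm: int | None = None
    seed: int | None = None
    alpha: float = 0.05
    permuted_statistics: tuple[float, ...] | None = field(default=None, repr=False)


def _moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Sample variances and covariance (ddof=1)."""
    xc = x - x.mean()
    yc = y - y.mean()
    n1 = len(x) - 1
    return float(xc @ xc) / n1, float(yc @ yc) / n1, float(xc @ yc) / n1


def fit_sma(x, y, alpha: float = 0.05) -> SMAFit:
    """Fit the standardized major axis of y on x.

    Requires n >= 3 and positive variance on both axes.  r = 0 exactly is
    an error: the SMA slope magnitude sd(y)/sd(x) is well defined but its
    sign is not, so no line is reported (inspect the correlation, or choose
    an axis-asymmetric estimator, if a fit is still wanted).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"SMA needs at least 3 points, got {n}")
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    sxx, syy, sxy = _moments(x, y)
    if sxx <= 0 or syy <= 0:
        raise DegenerateDataError("zero variance on one axis; SMA slope undefined")
    r = sxy / math.sqrt(sxx * syy)
    if r == 0:
        raise DegenerateDataError(
            "correlation is exactly zero: SMA slope sign is undefined"
        )
    b = math.copysign(math.sqrt(syy / sxx), r)
    c = float(y.mean() - b * x.mean())

    # correlation-based CI; collapses to zero width at |r| = 1
    B = stats.f.ppf(1.0 - alpha, 1, n - 2) * max(0.0, 1.0 - r * r) / (n - 2)
    lo = b * (math.sqrt(B + 1.0) - math.sqrt(B))
    hi = b * (math.sqrt(B + 1.0) + math.sqrt(B))
    if lo > hi:
        lo, hi = hi, lo
    return SMAFit(n=n, slope_b=b, intercept_c=c, r=float(r), ci_lower=lo, ci_upper=hi, alpha=alpha)


def _group_stats(groups: dict) -> tuple[list[str], list[np.ndarray], list[np.ndarray]]:
    labels, xs, ys = [], [], []
    for label, (x, y) in groups.items():
        labels.append(str(label))
        xs.append(np.asarray(x, float))
        ys.append(np.asarray(y, float))
    return labels, xs, ys


def _lr_statistic_fn(xs: list[np.ndarray], ys: list[np.ndarray]):
    """Return T(b) plus the per-group second moments it uses."""
    moms = []
    for x, y in zip(xs, ys):
        sxx, syy, sxy = _moments(x, y)
        moms.append((len(x), sxx, syy, sxy))

    def T(b: float) -> float:
        total = 0.0
        for n, sxx, syy, sxy in moms:
            num = syy - b * b * sxx
            den = (syy - 2 * b * sxy + b * b * sxx) * (syy + 2 * b * sxy + b * b * sxx)
            r2 = (num * num) / den if den > 0 else 1.0
            r2 = min(r2, 1.0 - 1e-15)
            total += -(n - 2.5) * math.log1p(-r2)
        return total

    return T, moms


def _lr_common_slope(xs: list[np.ndarray], ys: list[np.ndarray]) -> tuple[float, float]:
    """Minimize the LR statistic over the common slope b.

    The minimizer lies in the sign-cone of the group slopes for coherent
    data; the search brackets the group SMA slopes and widens if needed.
    Inner tolerance on b: 1e-10.
    """
    T, moms = _lr_statistic_fn(xs, ys)
    slopes = [math.copysign(math.sqrt(syy / sxx), sxy if sxy != 0 else 1.0) for _, sxx, syy, sxy in moms]
    lo, hi = min(slopes), max(slopes)
    span = max(hi - lo, 1e-6 * max(abs(lo), abs(hi), 1.0))
    lo, hi = lo - 0.5 * span, hi + 0.5 * span
    # widen the bracket until the interior minimum is enclosed
    for _ in range(60):
        res = optimize.minimize_scalar(T, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
        b = float(res.x)
        if b - lo > 1e-9 * (hi - lo) and hi - b > 1e-9 * (hi - lo):
            break
        width = hi - lo
        lo, hi = lo - width, hi + width
    return b, float(T(b))


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def common_slope_test(
    groups: dict,
    alpha: float = 0.05,
    method: str = "likelihood_ratio",
    n_perm: int = 1000,
    seed: int | None = None,
) -> CommonSlopeResult:
    """Test homogeneity of SMA slopes across groups.

    ``groups`` maps label -> (x, y) vectors (log sizes).  The permutation
    variant centers each group at its bivariate mean, pools the points,
    reassigns group labels without replacement and recomputes the
    likelihood-ratio statistic; it requires a seed for reproducibility.
    """
    if len(groups) < 2:
        raise ConfigurationError("common_slope_test needs at least 2 groups")
    labels, xs, ys = _group_stats(groups)
    fits = {lab: fit_sma(x, y, alpha=alpha) for lab, x, y in zip(labels, xs, ys)}

    b_common, stat = _lr_common_slope(xs, ys)
    df = len(groups) - 1

    if method == "likelihood_ratio":
        p = float(stats.chi2.sf(stat, df))
        return CommonSlopeResult(fits, b_common, stat, df, p, method, alpha=alpha)
    if method != "permutation":
        raise ConfigurationError(f"unknown method {method!r}")
    if seed is None:
        raise ConfigurationError("permutation method requires a seed (reproducibility contract)")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")

    rng = np.random.default_rng(seed)
    pooled = np.column_stack(
        [np.concatenate([_center(x) for x in xs]), np.concatenate([_center(y) for y in ys])]
    )
    sizes = [len(x) for x in xs]
    edges = np.cumsum([0, *sizes])
    perm_stats = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.permutation(len(pooled))
        pxs = [pooled[idx[a:b], 0] for a, b in zip(edges[:-1], edges[1:])]
        pys = [pooled[idx[a:b], 1] for a, b in zip(edges[:-1], edges[1:])]
        try:
            _, perm_stats[k] = _lr_common_slope(pxs, pys)
        except (ValueError, ZeroDivisionError):
            perm_stats[k] = np.inf  # degenerate shuffle counts as extreme
    # add-one estimator: valid finite-sample p, equals 1 when the statistic is 0
    p = (1.0 + np.count_nonzero(perm_stats >= stat)) / (n_perm + 1.0)
    return CommonSlopeResult(
        fits, b_common, stat, df, float(p), method, n_perm=n_perm, seed=seed,
        alpha=alpha, permuted_statistics=tuple(np.round(perm_stats, 12)),
    )
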