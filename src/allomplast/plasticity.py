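"""Organ-level nutritional-plasticity analyses built on SMA.

Under nutrition-driven size variation, the allometric coefficient — the
SMA slope of log organ size on log body (or another organ's) size —
measures how plastic that organ is relative to its reference: slope 1 is
proportional scaling, a shallow slope (e.g. genitalia) means the organ is
buffered against nutritional variation.  This module layers on that core:
per-organ coefficients, multi-organ comparisons with common-slope tests,
perturbation effect sizes with bootstrap intervals, a permutation test for
organ × treatment interaction (does a perturbation shrink one organ more
than another?), and a quadratic expression-vs-plasticity trend fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import AllometryDataset, ConfigurationError, StateError
from .proliferation import holm_adjust
from .sma import CommonSlopeResult, SMAFit, common_slope_test, fit_sma

__all__ = [
    "PlasticityEstimate",
    "EffectSizeResult",
    "QuadraticTrendFit",
    "allometric_coefficient",
    "compare_organ_plasticity",
    "relative_size_effect",
    "differential_effect_test",
    "quadratic_trend",
]


@dataclass(frozen=True)
class PlasticityEstimate:
    organ: str
    reference: str
    fit: SMAFit
    n_pairs: int


@dataclass(frozen=True)
class EffectSizeResult:
    """Proportional reduction of an organ's mean size under a perturbation."""

    organ: str
    control_mean: float
    perturbed_mean: float
    proportional_reduction: float
    ci_lower: float
    ci_upper: float
    n_control: int
    n_perturbed: int
    n_boot: int
    seed: int


@dataclass(frozen=True)
class InteractionTestResult:
    """Organ × treatment interaction: difference between organs of the
    log-mean treatment effect, with a label-permutation p-value."""

    organ_a: str
    organ_b: str
    interaction: float
    p_value: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class QuadraticTrendFit:
    a0: float
    a1: float
    a2: float
    n: int
    rss: float
    extremum_x: float | None
    band_x: tuple[float, ...]
    band_lower: tuple[float, ...]
    band_upper: tuple[float, ...]

    def predict(self, x):
        x = np.asarray(x, float)
        return self.a0 + self.a1 * x + self.a2 * x * x


def _require_log(dataset: AllometryDataset) -> None:
    if dataset.size_scale != "log":
        raise StateError("plasticity analyses require a log-transformed dataset")


def allometric_coefficient(
    dataset: AllometryDataset, organ: str, reference: str = "body", alpha: float = 0.05
) -> PlasticityEstimate:
    """SMA slope of log organ size on log reference size (default: body)."""
    _require_log(dataset)
    x, y = dataset.pairs(organ, reference)
    if len(x) < 3:
        raise ConfigurationError(
            f"fewer than 3 complete ({organ}, {reference}) pairs after missing-data exclusion"
        )
    fit = fit_sma(x, y, alpha=alpha)
    return PlasticityEstimate(organ=organ, reference=reference, fit=fit, n_pairs=len(x))


def compare_organ_plasticity(
    dataset: AllometryDataset,
    organs: list[str],
    reference: str = "body",
    alpha: float = 0.05,
    method: str = "likelihood_ratio",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[dict[str, PlasticityEstimate], pd.DataFrame]:
    """Per-organ allometric coefficients plus all pairwise common-slope tests.

    Pairwise p-values are Holm-adjusted across the family (raw values are
    also reported).  The result is independent of the order in which organs
    are listed.
    """
    if len(organs) < 2:
        raise ConfigurationError("compare_organ_plasticity needs at least 2 organs")
    _require_log(dataset)
    estimates = {o: allometric_coefficient(dataset, o, reference, alpha) for o in organs}

    rows = []
    for a, b in combinations(sorted(organs), 2):
        xa, ya = dataset.pairs(a, reference)
        xb, yb = dataset.pairs(b, reference)
        res: CommonSlopeResult = common_slope_test(
            {a: (xa, ya), b: (xb, yb)}, alpha=alpha, method=method,
            n_perm=n_perm, seed=seed,
        )
        rows.append(
            {
                "organ_a": a, "organ_b": b,
                "slope_a": res.group_fits[a].slope_b, "slope_b": res.group_fits[b].slope_b,
                "common_slope": res.common_slope, "statistic": res.statistic,
                "p_raw": res.p_value,
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"])
    table.attrs.update({"reference": reference, "method": method, "alpha": alpha})
    return estimates, table


def relative_size_effect(
    control: AllometryDataset,
    perturbed: AllometryDataset,
    organ: str,
    n_boot: int = 2000,
    seed: int | None = None,
) -> EffectSizeResult:
    """Proportional reduction 1 − perturbed/control of group mean organ size.

    Computed on the raw scale (matching "reduced by ~30%" style summaries)
    with a seeded percentile bootstrap resampling individuals within each
    group independently.
    """
    if seed is None:
        raise ConfigurationError("relative_size_effect requires a seed")
    for ds, name in ((control, "control"), (perturbed, "perturbed")):
        if ds.size_scale != "raw":
            raise StateError(f"{name} dataset must be raw-scale for mean-ratio effect sizes")
    c = control.frame[organ].dropna().to_numpy(float) if organ in control.organs else None
    p = perturbed.frame[organ].dropna().to_numpy(float) if organ in perturbed.organs else None
    if c is None or p is None:
        raise ConfigurationError(f"organ {organ!r} must be present in both datasets")
    if len(c) < 2 or len(p) < 2:
        raise ConfigurationError("each group needs at least 2 measured individuals")

    reduction = 1.0 - p.mean() / c.mean()
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = 1.0 - rng.choice(p, len(p)).mean() / rng.choice(c, len(c)).mean()
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return EffectSizeResult(
        organ=organ, control_mean=float(c.mean()), perturbed_mean=float(p.mean()),
        proportional_reduction=float(reduction), ci_lower=float(lo), ci_upper=float(hi),
        n_control=len(c), n_perturbed=len(p), n_boot=n_boot, seed=seed,
    )


def _interaction_stat(log_a: np.ndarray, log_b: np.ndarray, is_perturbed: np.ndarray) -> float:
    """Difference between organs of the control-minus-perturbed log-mean shift."""
    ctrl = ~is_perturbed
    da = log_a[ctrl].mean() - log_a[is_perturbed].mean()
    db = log_b[ctrl].mean() - log_b[is_perturbed].mean()
    return float(da - db)


def differential_effect_test(
    control: AllometryDataset,
    perturbed: AllometryDataset,
    organ_a: str,
    organ_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    strict: bool = True,
) -> InteractionTestResult:
    """Does the perturbation shrink organ_a more (or less) than organ_b?

    The statistic is the organ × treatment interaction on the log scale:
    (control − perturbed) difference of log-mean sizes for organ_a minus the
    same for organ_b.  The null is built by permuting treatment labels over
    individuals (each individual carries both organ measurements, so the
    within-individual organ pairing is preserved).  Two-sided add-one p.
    """
    if seed is None:
        raise ConfigurationError("differential_effect_test requires a seed")
    if n_perm < 100:
        msg = "n_perm < 100 gives an unusably coarse permutation p"
        if strict:
            raise ConfigurationError(msg)
    for organ in (organ_a, organ_b):
        if organ not in control.organs or organ not in perturbed.organs:
            raise ConfigurationError(f"organ {organ!r} must be present in both datasets")

    def logs(ds: AllometryDataset, organ: str) -> np.ndarray:
        vals = ds.frame[organ].to_numpy(float)
        return vals if ds.size_scale == "log" else np.log(vals)

    la = np.concatenate([logs(control, organ_a), logs(perturbed, organ_a)])
    lb = np.concatenate([logs(control, organ_b), logs(perturbed, organ_b)])
    keep = ~(np.isnan(la) | np.isnan(lb))
    is_pert = np.concatenate(
        [np.zeros(len(control.frame), bool), np.ones(len(perturbed.frame), bool)]
    )
    la, lb, is_pert = la[keep], lb[keep], is_pert[keep]
    if is_pert.all() or not is_pert.any():
        raise ConfigurationError("both treatment groups must contain complete individuals")

    obs = _interaction_stat(la, lb, is_pert)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(is_pert)
        if abs(_interaction_stat(la, lb, perm)) >= abs(obs) - 1e-15:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return InteractionTestResult(
        organ_a=organ_a, organ_b=organ_b, interaction=obs, p_value=float(p),
        n_perm=n_perm, seed=seed,
    )


def quadratic_trend(x, y, alpha: float = 0.05, n_band: int = 50) -> QuadraticTrendFit:
    """Least-squares quadratic y = a0 + a1 x + a2 x^2 with a pointwise band.

    Reports the fitted extremum location −a1/(2·a2) when a2 ≠ 0 (the
    expression level at which plasticity peaks or bottoms out).  The band
    is the OLS (1 − alpha) pointwise confidence interval for the mean curve
    evaluated on a grid spanning the observed x-range.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-d vectors of equal length")
    if len(x) < 4:
        raise ConfigurationError("quadratic fit needs at least 4 points")
    if np.ptp(x) == 0:
        raise ConfigurationError("degenerate design: all x values equal")

    X = np.column_stack([np.ones_like(x), x, x * x])
    model = sm.OLS(y, X).fit()
    a0, a1, a2 = model.params
    rss = float(model.ssr)

    grid = np.linspace(x.min(), x.max(), n_band)
    Xg = np.column_stack([np.ones_like(grid), grid, grid * grid])
    pred = model.get_prediction(Xg).conf_int(alpha=alpha)
    extremum = float(-a1 / (2.0 * a2)) if a2 != 0 else None
    return QuadraticTrendFit(
        a0=float(a0), a1=float(a1), a2=float(a2), n=len(x), rss=rss,
        extremum_x=extremum,
        band_x=tuple(grid), band_lower=tuple(pred[:, 0]), band_upper=tuple(pred[:, 1]),
    )
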