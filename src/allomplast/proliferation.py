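"""Clonal-analysis statistics for mitotic (MARCM-style) clones.

Each clone is a lineage grown from a single marked founder cell in an
imaginal disc; under exponential growth its per-hour proliferation rate is
ln(N)/t for N cells at clone age t hours.  Larvae — not clones — are the
independent experimental units, so rates are estimated in two stages:
clone rates are averaged per larva per disc, then averaged (unweighted)
across larvae within each disc × genotype cell.  A larva-level variance
component is reported by method of moments, and pairwise cell contrasts use
a larva-level permutation test with Holm adjustment across the requested
family — a transparent analogue of a mixed-model ANOVA with larva as
random effect followed by Tukey comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ConfigurationError

__all__ = [
    "CloneRecord",
    "CloneDataset",
    "RateEstimate",
    "clone_rate",
    "estimate_rates",
    "pairwise_rate_comparison",
    "cell_size_summary",
    "read_clones_csv",
]

CLONE_COLUMNS = ["larva_id", "disc_type", "genotype", "clone_id", "cell_count", "clone_age_h"]


@dataclass(frozen=True)
class CloneRecord:
    """One clone: N cells of age t hours, nested in a larva's disc."""

    larva_id: str
    disc_type: str
    genotype: str
    clone_id: str
    cell_count: int
    clone_age_h: float
    mean_cell_area: float | None = None

    def __post_init__(self) -> None:
        if self.cell_count < 1:
            raise ValueError(f"cell_count must be >= 1, got {self.cell_count}")
        if not (self.clone_age_h > 0):
            raise ValueError(f"clone_age_h must be > 0, got {self.clone_age_h}")


@dataclass
class CloneDataset:
    """Clone records backed by a DataFrame (one row per clone)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLONE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"clone frame is missing columns {missing}")
        if "mean_cell_area" not in self.frame.columns:
            self.frame = self.frame.assign(mean_cell_area=np.nan)
        counts = self.frame["cell_count"].to_numpy()
        ages = self.frame["clone_age_h"].to_numpy(float)
        if (counts < 1).any():
            raise ValueError("all cell counts must be >= 1")
        if (ages <= 0).any():
            raise ValueError("all clone ages must be > 0")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[CloneRecord]:
        out = []
        for _, row in self.frame.iterrows():
            area = None if pd.isna(row["mean_cell_area"]) else float(row["mean_cell_area"])
            out.append(
                CloneRecord(
                    str(row["larva_id"]), str(row["disc_type"]), str(row["genotype"]),
                    str(row["clone_id"]), int(row["cell_count"]), float(row["clone_age_h"]),
                    area,
                )
            )
        return out

    def with_rates(self, base: float = math.e) -> pd.DataFrame:
        frame = self.frame.copy()
        frame["rate"] = clone_rate(
            frame["cell_count"].to_numpy(), frame["clone_age_h"].to_numpy(float), base=base
        )
        return frame


@dataclass(frozen=True)
class RateEstimate:
    """Mean proliferation rate for one disc × genotype cell.

    ``mean_rate`` and ``se`` are in log(cells)/hour in the chosen base;
    ``se`` is the model-based standard error of the unweighted larva-mean
    estimator (larvae are the independent units) and is NaN when only one
    larva is available.  ``larva_variance`` is the method-of-moments
    estimate of the between-larva variance component.
    """

    disc_type: str
    genotype: str
    mean_rate: float
    se: float
    n_larvae: int
    n_clones: int
    larva_variance: float
    log_base: float = math.e


def clone_rate(N, t, base: float = math.e):
    """Per-clone proliferation rate log(N)/t per hour.

    Natural log by default; base 2 gives doublings per hour (a base change
    rescales every rate by the same constant).  Vectorized.
    """
    N_arr = np.asarray(N)
    t_arr = np.asarray(t, float)
    if np.any(N_arr < 1):
        raise ValueError("cell count N must be >= 1")
    if np.any(t_arr <= 0):
        raise ValueError("clone age t must be > 0")
    if not (base > 0) or base == 1:
        raise ConfigurationError(f"log base must be positive and != 1, got {base}")
    out = np.log(N_arr) / np.log(base) / t_arr
    return out if out.ndim else float(out)


def _larva_means(clones: CloneDataset, base: float) -> pd.DataFrame:
    frame = clones.with_rates(base=base)
    return (
        frame.groupby(["disc_type", "genotype", "larva_id"], sort=True)
        .agg(rate=("rate", "mean"), n_clones=("rate", "size"))
        .reset_index()
    )


def estimate_rates(clones: CloneDataset, base: float = math.e) -> list[RateEstimate]:
    """Two-stage rate estimates per disc × genotype.

    Stage 1 averages clone rates within each larva; stage 2 takes the
    unweighted mean across larvae.  The larva variance component tau^2 is
    var(larva means) minus the expected contribution of within-larva clone
    noise, sigma_w^2 * mean(1/k), truncated at zero (one-way random-effects
    method of moments for unbalanced clone counts k per larva).  The
    standard error is the model-based one for the unweighted larva-mean
    estimator, sqrt(tau^2/n + sigma_w^2 * mean(1/k)/n) — the same quantity
    a mixed model with larva as random effect reports, and better
    calibrated than sd(larva means)/sqrt(n) because the within-larva part
    carries clone-level degrees of freedom.
    """
    if len(clones) == 0:
        raise ConfigurationError("empty clone dataset")
    frame = clones.with_rates(base=base)
    within = frame.groupby(["disc_type", "genotype", "larva_id"], sort=True)["rate"]
    larva = _larva_means(clones, base)

    out = []
    for (disc, geno), sub in larva.groupby(["disc_type", "genotype"], sort=True):
        m = sub["rate"].to_numpy(float)
        k = sub["n_clones"].to_numpy(float)
        n_larvae = len(m)
        cell = frame[(frame["disc_type"] == disc) & (frame["genotype"] == geno)]
        # pooled within-larva clone variance (needs larvae with >= 2 clones)
        per_larva_var = cell.groupby("larva_id")["rate"].agg(["var", "size"]).dropna()
        if len(per_larva_var):
            dfs = per_larva_var["size"] - 1
            sigma_w2 = float((per_larva_var["var"] * dfs).sum() / dfs.sum())
        else:
            sigma_w2 = 0.0
        if n_larvae >= 2:
            var_means = float(np.var(m, ddof=1))
            mean_inv_k = float(np.mean(1.0 / k))
            larva_var = max(0.0, var_means - sigma_w2 * mean_inv_k)
            if len(per_larva_var):
                se = math.sqrt((larva_var + sigma_w2 * mean_inv_k) / n_larvae)
            else:
                se = math.sqrt(var_means / n_larvae)  # no within-larva replication
        else:
            se = math.nan  # flagged: a single larva supports no between-larva se
            larva_var = math.nan
        out.append(
            RateEstimate(
                disc_type=str(disc), genotype=str(geno),
                mean_rate=float(np.mean(m)), se=se,
                n_larvae=n_larvae, n_clones=int(len(cell)),
                larva_variance=larva_var, log_base=base,
            )
        )
    return out


def _perm_p_two_sample(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> tuple[float, float]:
    """Two-sided permutation p for a difference of means, larva-level units."""
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    na = len(a)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(pooled))
        d = pooled[idx[:na]].mean() - pooled[idx[na:]].mean()
        if abs(d) >= abs(obs) - 1e-15:
            count += 1
    return float(obs), (count + 1.0) / (n_perm + 1.0)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down family-wise error adjustment."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def pairwise_rate_comparison(
    clones: CloneDataset,
    contrasts: Sequence[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    base: float = math.e,
) -> pd.DataFrame:
    """Permutation contrasts of larva-mean rates between disc × genotype cells.

    ``contrasts`` lists pairs of (disc_type, genotype) cells; by default all
    pairwise combinations present in the data are compared.  Larvae are
    relabeled between the two cells (the larva is the exchangeable unit);
    p-values use the add-one estimator and are Holm-adjusted across the
    family.  Returns a tidy frame with observed differences and both raw
    and adjusted p-values.
    """
    if seed is None:
        raise ConfigurationError("pairwise_rate_comparison requires a seed")
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100 for a usable permutation p")
    larva = _larva_means(clones, base)
    cells = {
        (str(d), str(g)): sub["rate"].to_numpy(float)
        for (d, g), sub in larva.groupby(["disc_type", "genotype"], sort=True)
    }
    larvae_by_cell = {
        (str(d), str(g)): set(sub["larva_id"])
        for (d, g), sub in larva.groupby(["disc_type", "genotype"], sort=True)
    }
    if contrasts is None:
        contrasts = list(combinations(sorted(cells), 2))

    rng = np.random.default_rng(seed)
    rows = []
    for cell_a, cell_b in contrasts:
        for cell in (cell_a, cell_b):
            if tuple(cell) not in cells:
                raise ConfigurationError(f"design cell {cell} not present in data")
        a, b = cells[tuple(cell_a)], cells[tuple(cell_b)]
        if len(a) < 2 or len(b) < 2:
            raise ConfigurationError(f"contrast {cell_a} vs {cell_b} needs >= 2 larvae per cell")
        shared = larvae_by_cell[tuple(cell_a)] & larvae_by_cell[tuple(cell_b)]
        if cell_a[1] != cell_b[1] and shared:
            # one larva cannot carry two genotypes; same-larva discs are fine
            raise ValueError(f"larvae {sorted(shared)} appear in both genotypes: data integrity error")
        obs, p = _perm_p_two_sample(a, b, n_perm, rng)
        rows.append(
            {
                "disc_a": cell_a[0], "genotype_a": cell_a[1],
                "disc_b": cell_b[0], "genotype_b": cell_b[1],
                "rate_diff": obs, "p_raw": p,
            }
        )
    result = pd.DataFrame(rows)
    result["p_holm"] = holm_adjust(result["p_raw"])
    result.attrs.update({"n_perm": n_perm, "seed": seed, "unit": "larva", "log_base": base})
    return result


def cell_size_summary(
    clones: CloneDataset,
    control_genotype: str,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Larva-aggregated mean cell areas and proportional change vs control.

    For each disc × genotype with area data, reports the mean over larva
    means of clone mean cell areas, and 1 − genotype/control per disc with
    a seeded percentile bootstrap interval (resampling larvae within each
    cell independently).
    """
    if seed is None:
        raise ConfigurationError("cell_size_summary requires a seed")
    frame = clones.frame.dropna(subset=["mean_cell_area"])
    if len(frame) == 0:
        raise ConfigurationError("no cell-area measurements present")
    if control_genotype not in set(frame["genotype"]):
        raise ConfigurationError(f"control genotype {control_genotype!r} absent")
    larva = (
        frame.groupby(["disc_type", "genotype", "larva_id"], sort=True)["mean_cell_area"]
        .mean()
        .reset_index()
    )
    rng = np.random.default_rng(seed)
    rows = []
    for disc, disc_sub in larva.groupby("disc_type", sort=True):
        ctrl = disc_sub[disc_sub["genotype"] == control_genotype]["mean_cell_area"].to_numpy(float)
        if len(ctrl) == 0:
            continue
        for geno, sub in disc_sub.groupby("genotype", sort=True):
            areas = sub["mean_cell_area"].to_numpy(float)
            change = 1.0 - areas.mean() / ctrl.mean()
            if geno == control_genotype:
                lo = hi = 0.0
            else:
                boots = np.empty(n_boot)
                for i in range(n_boot):
                    bm = rng.choice(areas, len(areas)).mean()
                    bc = rng.choice(ctrl, len(ctrl)).mean()
                    boots[i] = 1.0 - bm / bc
                lo, hi = np.quantile(boots, [0.025, 0.975])
            rows.append(
                {
                    "disc_type": disc, "genotype": geno,
                    "mean_area": areas.mean(), "n_larvae": len(areas),
                    "prop_change_vs_control": change,
                    "ci_lower": float(lo), "ci_upper": float(hi),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs.update({"control_genotype": control_genotype, "n_boot": n_boot, "seed": seed})
    return out


def read_clones_csv(path: str | Path, column_map: Mapping[str, str] | None = None) -> CloneDataset:
    """Read a per-clone CSV (same fixed dialect as the allometry reader)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, encoding="utf-8", sep=",")
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CLONE_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"clone CSV missing columns {missing}")
    return CloneDataset(raw)
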