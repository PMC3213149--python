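"""Seeded generators for allometry and clone datasets.

The generators emulate the statistical structure the analyses assume, so
every pipeline stage is testable without the original fly measurements:

* :func:`simulate_allometry` — bivariate log-size data in which each organ
  has an organ-specific true scaling slope against body size (genitalia
  shallow, wing roughly proportional), genotype-level slope offsets, a
  linear temperature effect on slope, and observation noise on BOTH axes.
* :func:`simulate_clones` — mitotic-clone (MARCM-style) data with
  exponential clone growth, larva-level random effects, 5–30 clones per
  disc and 8–10 larvae per group.
* :func:`simulate_foxo_experiment` — named scenario bundles matching the
  study designs the analyses were built for.

Noise-model identification
--------------------------
The SMA slope estimand equals sd(y)/sd(x), so for the generating slope b to
be what SMA estimates, observation noise must load both axes in proportion:
here log body receives noise of sd ``x_noise_sd`` and each organ's log size
receives noise of sd ``|b_effective| * x_noise_sd`` (biological plus
measurement variation pooled), giving noise-variance ratio b² exactly.
This is the package's stated identification choice; overriding an organ's
``noise_sd`` breaks the proportion and biases SMA toward or away from b
(useful for robustness experiments, documented, never the default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AllometryDataset, ConfigurationError
from .proliferation import CloneDataset

__all__ = [
    "OrganSpec",
    "AllometrySimParams",
    "CloneSimParams",
    "simulate_allometry",
    "simulate_clones",
    "simulate_foxo_experiment",
]

#: printed-value defaults: genital-vs-wing slope 0.55 in controls and 0.93 in
#: FOXO mutants; wing scales roughly proportionally with body (slope 1)
GENITAL_SLOPE_CONTROL = 0.55
GENITAL_SLOPE_MUTANT = 0.93
WING_SLOPE = 1.0
#: observed slope-on-temperature trend magnitude used as the realistic
#: effect size for trend scenarios (per degree Celsius)
TEMPERATURE_SLOPE_TREND = -0.0105


@dataclass(frozen=True)
class OrganSpec:
    """True log-log scaling of one organ against body size."""

    slope: float
    intercept: float = 0.0
    noise_sd: float | None = None  # None => SMA-consistent |b_eff| * x_noise_sd


@dataclass(frozen=True)
class AllometrySimParams:
    """Parameters of the allometry generator.

    The starvation design removes larvae from food at different sizes, so
    adult body size varies continuously; ``body_log_sd`` is the sd of that
    latent log body size and ``body_log_mean`` may differ per nutrition
    treatment (fed larger than starved).  ``group_slope_offsets`` adds a
    genotype effect to each organ's slope and ``temp_slope_per_degree``
    adds a linear temperature effect relative to ``reference_temperature``.
    """

    organs: Mapping[str, OrganSpec] = field(
        default_factory=lambda: {"wing": OrganSpec(WING_SLOPE), "genital": OrganSpec(GENITAL_SLOPE_CONTROL)}
    )
    groups: tuple[str, ...] = ("control",)
    treatments: tuple[str | None, ...] = (None,)
    temperatures: tuple[float | None, ...] = (None,)
    n_per_cell: int = 60
    body_log_mean: float | Mapping[str | None, float] = 0.0
    body_log_sd: float = 0.2
    x_noise_sd: float = 0.06  # observation noise on log body size
    group_slope_offsets: Mapping[str, float] = field(default_factory=dict)
    temp_slope_per_degree: float = 0.0
    reference_temperature: float = 23.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_log_sd < 0 or self.x_noise_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")
        if self.n_per_cell < 3:
            raise ConfigurationError("n_per_cell must be >= 3 (fits need 3 points)")
        if not self.organs:
            raise ConfigurationError("at least one organ is required")

    def effective_slope(self, organ: str, group: str, temperature: float | None) -> float:
        b = self.organs[organ].slope + self.group_slope_offsets.get(group, 0.0)
        if temperature is not None:
            b += self.temp_slope_per_degree * (temperature - self.reference_temperature)
        return b


def simulate_allometry(params: AllometrySimParams) -> AllometryDataset:
    """Generate a raw-scale allometry dataset, one cell per group × treatment × temperature.

    Per individual: latent log body z ~ Normal(mean_treatment, body_log_sd);
    observed log body = z + e_x; per organ, observed log size =
    c + b_effective·z + e_y with sd(e_y) = |b_effective|·sd(e_x) by default
    (see module docstring).  All sizes are exponentiated to raw scale.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    idx = 0
    for group in params.groups:
        for treatment in params.treatments:
            for temperature in params.temperatures:
                n = params.n_per_cell
                mu = (
                    params.body_log_mean.get(treatment, 0.0)
                    if isinstance(params.body_log_mean, Mapping)
                    else params.body_log_mean
                )
                z = rng.normal(mu, params.body_log_sd, n)
                x_obs = z + rng.normal(0.0, params.x_noise_sd, n)
                organ_cols = {}
                for organ, spec in params.organs.items():
                    b = params.effective_slope(organ, group, temperature)
                    sd_y = abs(b) * params.x_noise_sd if spec.noise_sd is None else spec.noise_sd
                    organ_cols[organ] = spec.intercept + b * z + rng.normal(0.0, sd_y, n)
                for i in range(n):
                    rows.append(
                        {
                            "individual_id": f"ind{idx + i}",
                            "group": group,
                            "temperature": np.nan if temperature is None else temperature,
                            "treatment": treatment,
                            "body": math.exp(x_obs[i]),
                            **{o: math.exp(organ_cols[o][i]) for o in params.organs},
                        }
                    )
                idx += n
    frame = pd.DataFrame(rows)
    return AllometryDataset(frame, tuple(params.organs), "raw", None)


@dataclass(frozen=True)
class CloneSimParams:
    """Parameters of the MARCM-style clone generator.

    ``rates`` maps (disc_type, genotype) to the true mean proliferation
    rate in ln(cells)/hour; ln(64)/48 ≈ 0.0866 corresponds to six cell
    doublings in ~48 h, a typical wild-type disc figure.  Larvae are the
    independent units: each larva draws a random rate offset of sd
    ``larva_sd``, and each clone adds noise of sd ``clone_sd``.  Ages are
    uniform on ``age_range_h`` (dissection timing varies around ~48 h);
    clone counts per disc and larvae per group follow the study design
    (5–30 and 8–10 respectively).
    """

    rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("wing", "wild-type"): math.log(64.0) / 48.0,
            ("genital", "wild-type"): math.log(64.0) / 48.0,
        }
    )
    larva_sd: float = 0.004
    clone_sd: float = 0.02
    age_range_h: tuple[float, float] = (44.0, 52.0)
    clones_per_disc: tuple[int, int] = (5, 30)
    larvae_per_group: tuple[int, int] = (8, 10)
    cell_area_means: Mapping[str, float] = field(default_factory=dict)
    cell_area_log_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ConfigurationError("rates must be >= 0")
        if self.larva_sd < 0 or self.clone_sd < 0:
            raise ConfigurationError("sds must be >= 0")
        lo, hi = self.clones_per_disc
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid clones_per_disc range")
        lo, hi = self.larvae_per_group
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid larvae_per_group range")
        if self.age_range_h[0] <= 0 or self.age_range_h[0] > self.age_range_h[1]:
            raise ConfigurationError("invalid age range")


def simulate_clones(params: CloneSimParams) -> CloneDataset:
    """Generate a clone dataset.

    Per larva: rate offset u ~ Normal(0, larva_sd).  Per clone: rate
    r = group rate + u + Normal(0, clone_sd), age t ~ Uniform(age range),
    cell count N = max(1, round(exp(r·t))) — an observed clone contains at
    least its founder cell.  Cell areas, when a genotype mean is supplied,
    are lognormal around that mean.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    larva_counter = 0
    for (disc, genotype), rate in params.rates.items():
        n_larvae = int(rng.integers(params.larvae_per_group[0], params.larvae_per_group[1] + 1))
        for _ in range(n_larvae):
            larva_id = f"larva{larva_counter}"
            larva_counter += 1
            u = rng.normal(0.0, params.larva_sd)
            n_clones = int(rng.integers(params.clones_per_disc[0], params.clones_per_disc[1] + 1))
            ages = rng.uniform(*params.age_range_h, n_clones)
            rates_i = rate + u + rng.normal(0.0, params.clone_sd, n_clones)
            counts = np.maximum(1, np.round(np.exp(rates_i * ages))).astype(int)
            if genotype in params.cell_area_means:
                mu = params.cell_area_means[genotype]
                areas = np.exp(rng.normal(math.log(mu), params.cell_area_log_sd, n_clones))
            else:
                areas = np.full(n_clones, np.nan)
            for j in range(n_clones):
                rows.append(
                    {
                        "larva_id": larva_id,
                        "disc_type": disc,
                        "genotype": genotype,
                        "clone_id": f"{larva_id}_c{j}",
                        "cell_count": int(counts[j]),
                        "clone_age_h": float(ages[j]),
                        "mean_cell_area": float(areas[j]),
                    }
                )
    return CloneDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# named scenarios

_SCENARIOS = ("foxo_scaling", "organ_panel", "temperature_trend", "genocopy")


def simulate_foxo_experiment(
    scenario: str,
    n: int = 60,
    seed: int = 0,
    trend_per_degree: float | None = None,
) -> dict:
    """Generate the dataset bundle for a named study design.

    ``foxo_scaling``       control vs FOXO-mutant flies; genital-vs-wing
                           scaling slopes 0.55 and 0.93.
    ``organ_panel``        three organs against body: genital (slope 0.55)
                           vs wing and maxillary palp (slope ≈ 1).
    ``temperature_trend``  four rearing temperatures with a linear
                           temperature trend in the wing-body slope
                           (default −0.0105 per °C; pass
                           ``trend_per_degree=0`` for a null configuration)
                           plus fed/starved labels, suitable for the trend
                           permutation test and the temperature
                           normalization end-to-end.
    ``genocopy``           control vs IIS-perturbed flies in which the wing
                           is reduced ~30% and the genitalia ~15% at
                           matched body size (the genetic perturbation
                           mimicking starvation).
    """
    if scenario not in _SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}; choose from {_SCENARIOS}")
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    if scenario == "foxo_scaling":
        base = AllometrySimParams(
            organs={"wing": OrganSpec(WING_SLOPE), "genital": OrganSpec(GENITAL_SLOPE_CONTROL)},
            n_per_cell=n,
        )
        control = simulate_allometry(replace(base, groups=("control",), seed=sub()))
        # slope offset applied to the genital only; the wing stays at slope 1
        mutant = simulate_allometry(
            replace(
                base,
                organs={"wing": OrganSpec(WING_SLOPE), "genital": OrganSpec(GENITAL_SLOPE_MUTANT)},
                groups=("FOXO-mutant",),
                seed=sub(),
            )
        )
        return {"control": control, "mutant": mutant}

    if scenario == "organ_panel":
        params = AllometrySimParams(
            organs={
                "wing": OrganSpec(WING_SLOPE),
                "palp": OrganSpec(WING_SLOPE),
                "genital": OrganSpec(GENITAL_SLOPE_CONTROL),
            },
            n_per_cell=n,
            seed=sub(),
        )
        return {"pooled": simulate_allometry(params)}

    if scenario == "temperature_trend":
        trend = TEMPERATURE_SLOPE_TREND if trend_per_degree is None else trend_per_degree
        params = AllometrySimParams(
            organs={"wing": OrganSpec(WING_SLOPE)},
            groups=("control",),
            treatments=("fed", "starved"),
            temperatures=(17.0, 20.0, 23.0, 25.0),
            body_log_mean={"fed": 0.12, "starved": -0.12},
            n_per_cell=max(3, n // 2),
            temp_slope_per_degree=trend,
            seed=sub(),
        )
        return {"pooled": simulate_allometry(params)}

    # genocopy: organ means shifted at matched body size via intercepts
    base = AllometrySimParams(
        organs={"wing": OrganSpec(WING_SLOPE), "genital": OrganSpec(GENITAL_SLOPE_CONTROL)},
        n_per_cell=n,
    )
    control = simulate_allometry(replace(base, groups=("control",), seed=sub()))
    perturbed = simulate_allometry(
        replace(
            base,
            organs={
                "wing": OrganSpec(WING_SLOPE, intercept=math.log(0.70)),
                "genital": OrganSpec(GENITAL_SLOPE_CONTROL, intercept=math.log(0.85)),
            },
            groups=("IIS-perturbed",),
            seed=sub(),
        )
    )
    return {"control": control, "perturbed": perturbed}
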