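import math
from itertools import combinations

import numpy as np
import pytest

from allomplast import (
    AllometrySimParams,
    OrganSpec,
    allometric_coefficient,
    compare_organ_plasticity,
    dataset_from_arrays,
    differential_effect_test,
    log_transform,
    quadratic_trend,
    relative_size_effect,
    simulate_allometry,
    simulate_foxo_experiment,
)
from allomplast.core_io import ConfigurationError, StateError
from allomplast.plasticity import _interaction_stat
from allomplast.sma import DegenerateDataError


def log_ds(params):
    return log_transform(simulate_allometry(params))


class TestAllometricCoefficient:
    def test_isometric_organ_has_slope_one(self):
        body = np.exp(np.linspace(-0.3, 0.3, 10))
        ds = log_transform(dataset_from_arrays(body, {"wing": 3.0 * body}))
        est = allometric_coefficient(ds, "wing")
        assert est.fit.slope_b == pytest.approx(1.0)
        assert est.n_pairs == 10

    def test_completely_insensitive_organ_is_degenerate(self):
        body = np.exp(np.linspace(-0.3, 0.3, 10))
        ds = log_transform(dataset_from_arrays(body, {"genital": np.full(10, 2.0)}))
        with pytest.raises(DegenerateDataError):
            allometric_coefficient(ds, "genital")

    def test_requires_log_scale(self):
        ds = dataset_from_arrays([1.0, 2.0, 3.0], {"wing": [1.0, 2.0, 3.0]})
        with pytest.raises(StateError):
            allometric_coefficient(ds, "wing")

    def test_unknown_organ(self, genital_dataset):
        with pytest.raises(ConfigurationError):
            allometric_coefficient(genital_dataset, "antenna")

    def test_recovers_genital_slope_055(self, genital_dataset):
        est = allometric_coefficient(genital_dataset, "genital")
        assert est.fit.ci_lower <= 0.55 <= est.fit.ci_upper

    def test_missing_pairs_excluded_pairwise(self, genital_dataset):
        frame = genital_dataset.frame.copy()
        frame.loc[frame.index[:5], "genital"] = np.nan
        ds = genital_dataset.copy()
        ds.frame = frame
        est = allometric_coefficient(ds, "genital")
        assert est.n_pairs == len(frame) - 5

    def test_slope_invariant_to_raw_rescaling(self):
        params = AllometrySimParams(organs={"wing": OrganSpec(0.8)}, n_per_cell=30, seed=7)
        raw = simulate_allometry(params)
        rescaled = raw.copy()
        rescaled.frame["wing"] *= 1000.0  # unit change
        a = allometric_coefficient(log_transform(raw), "wing")
        b = allometric_coefficient(log_transform(rescaled), "wing")
        assert a.fit.slope_b == pytest.approx(b.fit.slope_b)
        assert a.fit.intercept_c != pytest.approx(b.fit.intercept_c)


class TestCompareOrganPlasticity:
    def test_single_organ_is_configuration_error(self, genital_dataset):
        with pytest.raises(ConfigurationError):
            compare_organ_plasticity(genital_dataset, ["genital"])

    def test_order_invariance(self):
        ds = log_ds(
            AllometrySimParams(
                organs={"wing": OrganSpec(1.0), "palp": OrganSpec(1.0), "genital": OrganSpec(0.55)},
                n_per_cell=40,
                seed=11,
            )
        )
        _, t1 = compare_organ_plasticity(ds, ["wing", "palp", "genital"])
        _, t2 = compare_organ_plasticity(ds, ["genital", "wing", "palp"])
        key = ["organ_a", "organ_b"]
        m1 = t1.set_index(key)["p_raw"].sort_index()
        m2 = t2.set_index(key)["p_raw"].sort_index()
        assert (m1 == m2).all()

    def test_genital_vs_wing_difference_detected(self):
        ds = log_ds(
            AllometrySimParams(
                organs={"wing": OrganSpec(1.0), "genital": OrganSpec(0.55)},
                n_per_cell=60,
                seed=12,
            )
        )
        estimates, table = compare_organ_plasticity(ds, ["wing", "genital"])
        assert estimates["genital"].fit.slope_b < estimates["wing"].fit.slope_b
        assert table["p_holm"].iloc[0] < 0.05

    def test_holm_at_least_raw(self):
        ds = log_ds(
            AllometrySimParams(
                organs={"wing": OrganSpec(1.0), "palp": OrganSpec(1.0), "genital": OrganSpec(0.55)},
                n_per_cell=40,
                seed=13,
            )
        )
        _, table = compare_organ_plasticity(ds, ["wing", "palp", "genital"])
        assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()


class TestRelativeSizeEffect:
    def test_arithmetic(self):
        control = dataset_from_arrays([1.0, 1.0], {"wing": [100.0, 100.0]})
        perturbed = dataset_from_arrays([1.0, 1.0], {"wing": [70.0, 70.0]})
        res = relative_size_effect(control, perturbed, "wing", n_boot=50, seed=0)
        assert res.proportional_reduction == pytest.approx(0.30)

    def test_identical_groups_interval_straddles_zero(self, rng):
        wing = np.exp(rng.normal(0, 0.1, 30))
        control = dataset_from_arrays(np.ones(30), {"wing": wing})
        res = relative_size_effect(control, control, "wing", n_boot=500, seed=1)
        assert res.proportional_reduction == pytest.approx(0.0)
        assert res.ci_lower < 0.0 < res.ci_upper

    def test_requires_raw_scale(self, genital_dataset):
        with pytest.raises(StateError):
            relative_size_effect(genital_dataset, genital_dataset, "genital", seed=1)

    def test_seed_mandatory(self):
        ds = dataset_from_arrays([1.0, 1.0], {"wing": [1.0, 1.0]})
        with pytest.raises(ConfigurationError, match="seed"):
            relative_size_effect(ds, ds, "wing")

    def test_genocopy_scenario_reductions(self):
        bundle = simulate_foxo_experiment("genocopy", n=200, seed=21)
        wing = relative_size_effect(bundle["control"], bundle["perturbed"], "wing", seed=2)
        genital = relative_size_effect(bundle["control"], bundle["perturbed"], "genital", seed=2)
        # wing reduced ~30%, genitalia ~15%: the genocopy-of-starvation pattern
        assert wing.ci_lower <= 0.30 <= wing.ci_upper
        assert genital.ci_lower <= 0.15 <= genital.ci_upper
        assert wing.proportional_reduction > genital.proportional_reduction


class TestDifferentialEffectTest:
    def test_equal_proportional_shrink_gives_no_interaction(self, rng):
        n = 50
        body = np.exp(rng.normal(0, 0.2, n))
        wing = body * np.exp(rng.normal(0, 0.05, n))
        genital = body**0.55 * np.exp(rng.normal(0, 0.05, n))
        control = dataset_from_arrays(body, {"wing": wing, "genital": genital})
        perturbed = dataset_from_arrays(body, {"wing": 0.8 * wing, "genital": 0.8 * genital})
        res = differential_effect_test(control, perturbed, "wing", "genital", n_perm=2000, seed=5)
        assert abs(res.interaction) < 1e-12
        assert res.p_value > 0.5

    def test_differential_shrink_detected(self):
        bundle = simulate_foxo_experiment("genocopy", n=40, seed=31)
        res = differential_effect_test(
            bundle["control"], bundle["perturbed"], "wing", "genital", n_perm=2000, seed=6
        )
        assert res.interaction == pytest.approx(math.log(0.85) - math.log(0.70), abs=0.15)
        assert res.p_value < 0.05

    def test_enumeration_oracle_on_six_individuals(self):
        # 3 control + 3 perturbed flies; enumerate all C(6,3) treatment labelings
        body = np.array([1.0, 1.1, 0.9])
        control = dataset_from_arrays(body, {"wing": [1.0, 1.2, 0.9], "genital": [0.8, 0.85, 0.75]})
        perturbed = dataset_from_arrays(body, {"wing": [0.7, 0.75, 0.8], "genital": [0.7, 0.72, 0.68]})
        la = np.log(np.concatenate([control.frame["wing"], perturbed.frame["wing"]]))
        lb = np.log(np.concatenate([control.frame["genital"], perturbed.frame["genital"]]))
        obs = _interaction_stat(la, lb, np.array([0, 0, 0, 1, 1, 1], bool))
        hits = total = 0
        for pert_idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(pert_idx)] = True
            total += 1
            hits += abs(_interaction_stat(la, lb, mask)) >= abs(obs) - 1e-15
        p_enum = hits / total
        res = differential_effect_test(control, perturbed, "wing", "genital", n_perm=20_000, seed=7)
        assert res.p_value == pytest.approx(p_enum, abs=0.02)

    def test_small_n_perm_rejected_in_strict_mode(self):
        ds = dataset_from_arrays([1.0, 2.0], {"wing": [1.0, 2.0], "genital": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            differential_effect_test(ds, ds, "wing", "genital", n_perm=50, seed=1)


class TestQuadraticTrend:
    def test_exact_quadratic(self):
        x = np.linspace(-2, 2, 9)
        fit = quadratic_trend(x, 1.0 + 2.0 * x - x * x)
        assert (fit.a0, fit.a1, fit.a2) == pytest.approx((1.0, 2.0, -1.0))
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.extremum_x == pytest.approx(1.0)

    def test_linear_data_nests_linear_fit(self, rng):
        x = np.linspace(0, 1, 20)
        y = 0.3 + 0.5 * x + rng.normal(0, 0.01, 20)
        fit = quadratic_trend(x, y)
        coef = np.polyfit(x, y, 1)
        rss_lin = float(np.sum((y - np.polyval(coef, x)) ** 2))
        assert fit.rss <= rss_lin + 1e-10

    def test_hump_shape_recovered(self, rng):
        x = rng.uniform(0, 2, 49)
        y = 1.0 + 1.6 * x - 0.8 * x * x + rng.normal(0, 0.05, 49)
        fit = quadratic_trend(x, y)
        assert fit.a2 < 0
        assert x.min() < fit.extremum_x < x.max()
        assert (np.asarray(fit.band_lower) <= np.asarray(fit.band_upper)).all()

    def test_degenerate_design(self):
        with pytest.raises(ConfigurationError):
            quadratic_trend([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
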