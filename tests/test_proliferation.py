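import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from allomplast import (
    CloneDataset,
    CloneSimParams,
    cell_size_summary,
    clone_rate,
    estimate_rates,
    pairwise_rate_comparison,
    simulate_clones,
)
from allomplast.core_io import ConfigurationError
from allomplast.proliferation import holm_adjust, read_clones_csv


def clone_frame(rows):
    return CloneDataset(pd.DataFrame(rows))


def make_cell(disc, geno, larva_rates, ages=48.0):
    """One design cell: a dict larva_id -> list of clone rates (ln cells/h)."""
    rows = []
    for larva, rates in larva_rates.items():
        for j, r in enumerate(rates):
            rows.append(
                {
                    "larva_id": larva, "disc_type": disc, "genotype": geno,
                    "clone_id": f"{larva}_{disc}_{j}",
                    "cell_count": max(1, round(math.exp(r * ages))),
                    "clone_age_h": ages,
                }
            )
    return rows


class TestCloneRate:
    def test_single_founder_has_rate_zero(self):
        assert clone_rate(1, 17.0) == 0.0

    def test_closed_forms(self):
        assert clone_rate(7, 1.0) == pytest.approx(math.log(7))
        assert clone_rate(64, 48.0) == pytest.approx(math.log(64) / 48.0)
        assert clone_rate(64, 48.0) == pytest.approx(0.08664, abs=5e-6)

    def test_base_two_gives_doublings_per_hour(self):
        assert clone_rate(64, 48.0, base=2) == pytest.approx(6.0 / 48.0)

    def test_monotonicity(self):
        assert clone_rate(10, 48.0) < clone_rate(20, 48.0)
        assert clone_rate(20, 50.0) < clone_rate(20, 48.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            clone_rate(0, 48.0)
        with pytest.raises(ValueError):
            clone_rate(10, 0.0)


class TestEstimateRates:
    def test_single_larva_mean_with_flagged_se(self):
        ds = clone_frame(make_cell("wing", "wt", {"L1": [0.06, 0.10]}))
        (est,) = estimate_rates(ds)
        # counts are rounded to integers, so rates recover approximately
        assert est.mean_rate == pytest.approx(0.08, abs=0.002)
        assert math.isnan(est.se) and est.n_larvae == 1 and est.n_clones == 2

    def test_duplicating_clones_within_larvae_leaves_estimates_unchanged(self):
        rows = make_cell("wing", "wt", {"L1": [0.05, 0.07], "L2": [0.09], "L3": [0.08, 0.06, 0.1]})
        ds = clone_frame(rows)
        doubled = pd.concat([ds.frame, ds.frame.assign(clone_id=ds.frame["clone_id"] + "_dup")])
        (a,) = estimate_rates(ds)
        (b,) = estimate_rates(CloneDataset(doubled))
        assert b.mean_rate == pytest.approx(a.mean_rate)
        assert b.n_clones == 2 * a.n_clones

    def test_unweighted_across_larvae(self):
        # larva means 0.06 and 0.10 -> group mean 0.08 regardless of clone counts
        rows = make_cell("wing", "wt", {"L1": [0.06] * 10, "L2": [0.10]})
        (est,) = estimate_rates(clone_frame(rows))
        assert est.mean_rate == pytest.approx(0.08, abs=0.002)

    def test_recovery_on_simulated_defaults(self):
        params = CloneSimParams(seed=42)
        ests = estimate_rates(simulate_clones(params))
        for est in ests:
            truth = params.rates[(est.disc_type, est.genotype)]
            assert abs(est.mean_rate - truth) <= 3 * est.se
            assert est.larva_variance >= 0
            assert 8 <= est.n_larvae <= 10

    def test_empty_dataset_is_error(self):
        with pytest.raises(Exception):
            estimate_rates(CloneDataset(pd.DataFrame(columns=["larva_id", "disc_type", "genotype", "clone_id", "cell_count", "clone_age_h"])))


class TestPairwiseRateComparison:
    def test_enumeration_oracle_three_vs_three(self):
        a = {"L1": [0.080, 0.082], "L2": [0.086], "L3": [0.091, 0.089]}
        b = {"L4": [0.070, 0.072], "L5": [0.078], "L6": [0.069]}
        ds = clone_frame(make_cell("wing", "wt", a) + make_cell("wing", "inr", b))
        larva_means = (
            ds.with_rates().groupby(["genotype", "larva_id"])["rate"].mean()
        )
        ma = larva_means["wt"].to_numpy()
        mb = larva_means["inr"].to_numpy()
        obs = ma.mean() - mb.mean()
        pooled = np.concatenate([ma, mb])
        hits = total = 0
        for idx in combinations(range(6), 3):
            sel = np.zeros(6, bool)
            sel[list(idx)] = True
            total += 1
            hits += abs(pooled[sel].mean() - pooled[~sel].mean()) >= abs(obs) - 1e-15
        p_enum = hits / total
        table = pairwise_rate_comparison(
            ds, [(("wing", "wt"), ("wing", "inr"))], n_perm=20_000, seed=11
        )
        assert table["p_raw"].iloc[0] == pytest.approx(p_enum, abs=0.02)

    def test_same_larvae_in_both_genotypes_is_integrity_error(self):
        rows = make_cell("wing", "wt", {"L1": [0.08], "L2": [0.09]}) + make_cell(
            "wing", "inr", {"L1": [0.07], "L3": [0.06]}
        )
        with pytest.raises(ValueError, match="integrity"):
            pairwise_rate_comparison(
                clone_frame(rows), [(("wing", "wt"), ("wing", "inr"))], n_perm=200, seed=1
            )

    def test_same_larvae_across_discs_is_allowed(self):
        # discs dissected from the same larva share larva ids by design
        rows = make_cell("wing", "wt", {"L1": [0.08], "L2": [0.09], "L3": [0.07]}) + make_cell(
            "genital", "wt", {"L1": [0.085], "L2": [0.088], "L3": [0.09]}
        )
        table = pairwise_rate_comparison(
            clone_frame(rows), [(("wing", "wt"), ("genital", "wt"))], n_perm=200, seed=2
        )
        assert 0 < table["p_raw"].iloc[0] <= 1

    def test_detects_generated_rate_gap(self):
        params = CloneSimParams(
            rates={("wing", "wild-type"): 0.0866, ("wing", "InrE19"): 0.074},
            seed=3,
        )
        ds = simulate_clones(params)
        table = pairwise_rate_comparison(ds, n_perm=2000, seed=4)
        assert table["p_holm"].iloc[0] < 0.05

    def test_seed_mandatory(self):
        ds = clone_frame(make_cell("wing", "wt", {"L1": [0.08], "L2": [0.09]}))
        with pytest.raises(ConfigurationError, match="seed"):
            pairwise_rate_comparison(ds, n_perm=200)

    def test_holm_adjustment_monotone(self):
        # sorted raw (0.01, 0.03, 0.04) -> (3x, 2x, 1x) = (0.03, 0.06, 0.04),
        # monotonized upward to (0.03, 0.06, 0.06)
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])


class TestCellSizeSummary:
    def area_dataset(self, ctrl_area=10.0, factor=0.9):
        rows = []
        for geno, mult in (("wt", 1.0), ("inr", factor)):
            for larva in range(4):
                rows.append(
                    {
                        "larva_id": f"{geno}{larva}", "disc_type": "wing", "genotype": geno,
                        "clone_id": f"{geno}{larva}c", "cell_count": 10, "clone_age_h": 48.0,
                        "mean_cell_area": ctrl_area * mult,
                    }
                )
        return clone_frame(rows)

    def test_exact_ten_percent_reduction(self):
        table = cell_size_summary(self.area_dataset(factor=0.9), "wt", n_boot=50, seed=1)
        row = table[table["genotype"] == "inr"].iloc[0]
        assert row["prop_change_vs_control"] == pytest.approx(0.10)

    def test_identical_genotypes_change_zero(self):
        table = cell_size_summary(self.area_dataset(factor=1.0), "wt", n_boot=50, seed=1)
        assert table["prop_change_vs_control"].abs().max() == pytest.approx(0.0)

    def test_control_absent_is_error(self):
        with pytest.raises(ConfigurationError):
            cell_size_summary(self.area_dataset(), "missing", seed=1)

    def test_bootstrap_interval_covers_simulated_reduction(self):
        params = CloneSimParams(
            rates={("wing", "wild-type"): 0.0866, ("wing", "InrE19"): 0.0866},
            cell_area_means={"wild-type": 10.0, "InrE19": 9.0},
            seed=5,
        )
        table = cell_size_summary(simulate_clones(params), "wild-type", n_boot=500, seed=6)
        row = table[table["genotype"] == "InrE19"].iloc[0]
        assert row["ci_lower"] <= 0.10 <= row["ci_upper"]


def test_read_clones_csv_round_trip(tmp_path):
    ds = simulate_clones(CloneSimParams(seed=7))
    path = tmp_path / "clones.csv"
    ds.frame.to_csv(path, index=False)
    back = read_clones_csv(path)
    pd.testing.assert_frame_equal(back.frame, ds.frame, check_dtype=False)
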