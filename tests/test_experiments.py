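import math

import numpy as np
import pandas as pd
import pytest

from crowdrank.core_model import CrowdDataset, Universe
from crowdrank.experiments import (
    coupled_vs_separate,
    group_size_sweep,
    individual_error_distribution,
    iqr_outlier_filter,
    run_pipeline,
    self_consistency,
)
from crowdrank.synthetic_data import NoiseProfile, SimulationConfig, simulate_crowd

from .conftest import make_record


def tau_b_oracle(x, y):
    """Brute-force tie-adjusted Kendall tau over all pairs."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[i] - x[j])
            sy = np.sign(y[i] - y[j])
            if sx == 0 and sy == 0:
                continue
            if sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


class TestSelfConsistency:
    def test_consistent_records_all_one(self, small_universe, consistent_records):
        ds = CrowdDataset(small_universe, consistent_records, task_size=3)
        rows = self_consistency(ds).rows
        assert np.allclose(rows[["kendall", "spearman", "pearson"]], 1.0)

    def test_exact_reversal_minus_one(self, small_universe):
        rec = make_record(
            "p0",
            {"A": 70.0, "B": 60.0, "C": 50.0},
            positions={"A": 1, "B": 2, "C": 3},
        )
        ds = CrowdDataset(small_universe, [rec], task_size=3)
        rows = self_consistency(ds).rows
        assert np.allclose(rows[["kendall", "spearman", "pearson"]], -1.0)

    def test_tau_b_matches_pair_oracle(self, small_universe):
        # one tie in the converted numerical ranking
        rec = make_record(
            "p0",
            {"A": 50.0, "B": 50.0, "C": 60.0, "D": 55.0},
            positions={"A": 1, "B": 2, "C": 4, "D": 3},
        )
        ds = CrowdDataset(small_universe, [rec], task_size=4)
        got = float(self_consistency(ds).rows["kendall"].iloc[0])
        a = [1, 2, 4, 3]
        rb = [1, 1, 4, 3]
        assert got == pytest.approx(tau_b_oracle(a, rb))

    def test_undefined_on_all_tied(self, small_universe):
        rec = make_record(
            "p0",
            {"A": 50.0, "B": 50.0},
            positions={"A": 1, "B": 2},
        )
        ds = CrowdDataset(small_universe, [rec], task_size=2)
        rows = self_consistency(ds).rows
        assert rows[["kendall", "spearman", "pearson"]].isna().all().all()


class TestErrorDistribution:
    def test_zero_noise_all_in_bin_zero(self):
        cfg = SimulationConfig(
            n_participants=30,
            task_size=5,
            noise=NoiseProfile(sigma_ordinal=0, sigma_numerical=0, complementarity=0),
            seed=1,
        )
        hist = individual_error_distribution(simulate_crowd(cfg))
        at_zero = hist[hist["discordant_pairs"] == 0]["percent"]
        assert (at_zero == 100.0).all()

    def test_bins_span_max_pairs(self):
        cfg = SimulationConfig(n_participants=10, task_size=6, seed=2)
        hist = individual_error_distribution(simulate_crowd(cfg))
        assert hist["discordant_pairs"].max() == 15
        assert set(hist["discordant_pairs"]) == set(range(16))

    def test_percentages_sum_to_100(self):
        cfg = SimulationConfig(n_participants=30, task_size=5, seed=3)
        hist = individual_error_distribution(simulate_crowd(cfg))
        for _, grp in hist.groupby("task_size"):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_hand_built_fixture_bins(self, small_universe):
        # truth over A..D is A<B<C<D; p0 perfect, p1 one swap, p2 reversal
        recs = [
            make_record("p0", {"A": 50.0, "B": 55.0, "C": 60.0}),
            make_record("p1", {"A": 55.0, "B": 50.0, "C": 60.0}),
            make_record("p2", {"A": 60.0, "B": 55.0, "C": 50.0}),
        ]
        ds = CrowdDataset(small_universe, recs, task_size=3)
        hist = individual_error_distribution(ds, source="converted_numerical")
        by_bin = dict(zip(hist["discordant_pairs"], hist["percent"]))
        assert by_bin[0] == pytest.approx(100 / 3)
        assert by_bin[1] == pytest.approx(100 / 3)
        assert by_bin[3] == pytest.approx(100 / 3)
        assert by_bin[2] == 0.0

    def test_ordinal_source_uses_submitted_ballot(self, small_universe):
        rec = make_record(
            "p0",
            {"A": 50.0, "B": 55.0, "C": 60.0},  # perfect counts
            positions={"C": 1, "B": 2, "A": 3},  # reversed ordering
        )
        ds = CrowdDataset(small_universe, [rec], task_size=3)
        h_ord = individual_error_distribution(ds, source="ordinal")
        h_num = individual_error_distribution(ds, source="converted_numerical")
        assert dict(zip(h_ord["discordant_pairs"], h_ord["percent"]))[3] == 100.0
        assert dict(zip(h_num["discordant_pairs"], h_num["percent"]))[0] == 100.0


class TestGroupSizeSweep:
    def test_full_group_is_deterministic(self):
        cfg = SimulationConfig(n_participants=30, task_size=5, seed=4)
        ds = simulate_crowd(cfg)
        sweep = group_size_sweep(
            ds, methods=["borda"], group_sizes=[30], replicates=4, seed=0
        )
        assert sweep.rows["d_star"].nunique() == 1

    def test_zero_noise_complete_ballots_perfect_everywhere(self):
        # exact recovery needs complete ballots: with partial coverage the
        # voting scores also carry subset-composition sampling noise, so
        # even error-free ballots need not pin down the global ordering
        cfg = SimulationConfig(
            n_participants=30,
            task_size=6,
            n_images=6,
            count_min=50,
            count_max=79,
            noise=NoiseProfile(sigma_ordinal=0, sigma_numerical=0, complementarity=0),
            seed=5,
        )
        ds = simulate_crowd(cfg)
        sweep = group_size_sweep(
            ds,
            methods=["plurality", "borda", "copeland"],
            group_sizes=[6, 30],
            replicates=3,
            seed=1,
        )
        assert (sweep.rows["d_star"] == 0.0).all()

    def test_zero_noise_partial_ballots_borda_near_perfect_at_scale(self):
        # with partial ballots, zero noise drives Borda's d* to (near)
        # zero only as per-image view counts grow
        cfg = SimulationConfig(
            n_participants=300,
            task_size=5,
            noise=NoiseProfile(sigma_ordinal=0, sigma_numerical=0, complementarity=0),
            seed=5,
        )
        ds = simulate_crowd(cfg)
        sweep = group_size_sweep(
            ds, methods=["borda"], group_sizes=[300], replicates=1, seed=1
        )
        assert float(sweep.rows["d_star"].iloc[0]) <= 0.05

    def test_woc_direction_borda(self):
        cfg = SimulationConfig(n_participants=300, task_size=5, seed=11)
        ds = simulate_crowd(cfg)
        sweep = group_size_sweep(
            ds, methods=["borda"], group_sizes=[30, 75, 150, 300], replicates=20, seed=5
        )
        med = sweep.summaries().sort_values("group_size")["median"].tolist()
        bin_width = 1 / (30 * 29 / 2)
        assert all(b <= a + bin_width for a, b in zip(med, med[1:]))

    def test_d_star_rows_in_unit_interval_and_counts(self):
        cfg = SimulationConfig(n_participants=60, task_size=5, seed=6)
        ds = simulate_crowd(cfg)
        sweep = group_size_sweep(
            ds, methods=["borda", "copeland"], group_sizes=[12, 30], replicates=5, seed=2
        )
        assert sweep.rows["d_star"].between(0, 1).all()
        counts = sweep.rows.groupby(["method", "group_size"]).size()
        assert (counts == 5).all()
        sm = sweep.summaries()
        merged = sweep.rows.groupby(["method", "group_size"])["d_star"].agg(
            ["median", "min", "max"]
        )
        pd.testing.assert_frame_equal(
            sm.set_index(["method", "group_size"]), merged
        )

    def test_oversized_group_raises(self):
        cfg = SimulationConfig(n_participants=12, task_size=3, seed=7)
        ds = simulate_crowd(cfg)
        with pytest.raises(ValueError, match="group size"):
            group_size_sweep(ds, group_sizes=[13], replicates=1, seed=0)

    def test_coa_method_on_small_universe(self):
        cfg = SimulationConfig(
            n_participants=6, task_size=2, n_images=6, count_min=50, count_max=79, seed=8
        )
        ds = simulate_crowd(cfg)
        sweep = group_size_sweep(
            ds,
            methods=["coa", "borda"],
            group_sizes=[6],
            replicates=1,
            seed=0,
            coa_options={"exact": True},
        )
        assert set(sweep.rows["method"]) == {"coa", "borda"}
        assert sweep.rows["d_star"].between(0, 1).all()


class TestCoupledVsSeparate:
    def test_zero_noise_complete_ballots_all_zero(self):
        cfg = SimulationConfig(
            task_size=6,
            n_images=6,
            count_min=50,
            count_max=79,
            noise=NoiseProfile(sigma_ordinal=0, sigma_numerical=0, complementarity=0),
            seed=9,
        )
        df = coupled_vs_separate(
            cfg, coupled_sizes=[20], separate_size_pairs=[(20, 20)], replicates=3, seed=3
        )
        assert (df["d_star"] == 0.0).all()

    def test_participant_bookkeeping(self):
        cfg = SimulationConfig(task_size=3, seed=10)
        df = coupled_vs_separate(
            cfg, coupled_sizes=[20], separate_size_pairs=[(20, 20)], replicates=2, seed=4
        )
        sep = df[df["setting"] == "separate"]
        assert (sep["n_participants"] == 40).all()
        cou = df[df["setting"] == "coupled"]
        assert (cou["n_participants"] == 20).all()

    def test_coupled_direction_default_noise(self):
        cfg = SimulationConfig(task_size=5, seed=11)
        df = coupled_vs_separate(
            cfg,
            coupled_sizes=[100],
            separate_size_pairs=[(100, 100)],
            replicates=20,
            seed=7,
        )
        med = df.groupby("setting")["d_star"].median()
        assert med["coupled"] <= med["separate"]


class TestIQRFilter:
    def test_tight_data_nothing_flagged(self):
        kept, flags = iqr_outlier_filter([10, 11, 12, 13, 14])
        assert not any(flags)
        assert kept == [10, 11, 12, 13, 14]

    def test_hand_computed_fences(self):
        values = list(range(1, 11)) + [1000]
        # linear-interpolation quartiles: Q1 = 3.5, Q3 = 8.5, IQR = 5,
        # fences [-4, 16]
        q1, q3 = np.percentile(values, [25, 75])
        assert (q1, q3) == (3.5, 8.5)
        kept, flags = iqr_outlier_filter(values)
        assert flags == [False] * 10 + [True]
        assert kept == list(map(float, range(1, 11)))

    def test_collapsed_fences_flag_any_deviant(self):
        kept, flags = iqr_outlier_filter([5, 5, 5, 5, 5, 7])
        assert flags == [False] * 5 + [True]

    def test_affine_invariance(self):
        rng = np.random.default_rng(12)
        values = list(rng.normal(50, 5, size=40)) + [500.0]
        _, base = iqr_outlier_filter(values)
        _, scaled = iqr_outlier_filter([3.0 * v - 11.0 for v in values])
        assert base == scaled

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError, match="at least 4"):
            iqr_outlier_filter([1, 2, 3])


class TestRunPipeline:
    def test_end_to_end_artifacts(self, tmp_path):
        cfg = SimulationConfig(n_participants=30, task_size=5, seed=13)
        summary = run_pipeline(
            cfg, tmp_path, group_sizes=[6, 30], replicates=3
        )
        for name in ("consistency.csv", "error_hist.csv", "sweep.csv", "summary.json"):
            assert (tmp_path / name).exists()
        assert summary["n_records"] == 30

    def test_rerun_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_participants=20, task_size=3, seed=14)
        run_pipeline(cfg, tmp_path / "a", group_sizes=[10, 20], replicates=2)
        run_pipeline(cfg, tmp_path / "b", group_sizes=[10, 20], replicates=2)
        for name in ("consistency.csv", "error_hist.csv", "sweep.csv", "summary.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_runs_on_provided_dataset(self, tmp_path, small_dataset):
        cfg = SimulationConfig(n_participants=8, task_size=4, n_images=4,
                               count_min=50, count_max=65, seed=15)
        summary = run_pipeline(
            cfg, tmp_path, group_sizes=[4, 8], replicates=2, dataset=small_dataset
        )
        assert summary["n_records"] == 8
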