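"""Generative model: binomial labeling, exponential bleaching, bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import smstoich as sm
from smstoich.config import copy_mixture_for_multimeric_fraction
from smstoich.simulate import simulate_complexes


class TestDrawLabeledCopies:
    def test_full_and_zero_labeling_are_degenerate(self, rng):
        assert all(sm.draw_labeled_copies(3, 1.0, rng) == 3 for _ in range(20))
        assert all(sm.draw_labeled_copies(3, 0.0, rng) == 0 for _ in range(20))

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            sm.draw_labeled_copies(3, 1.5, rng)
        with pytest.raises(ValueError):
            sm.draw_labeled_copies(-1, 0.5, rng)

    def test_matches_binomial_distribution(self, rng):
        draws = np.array([sm.draw_labeled_copies(3, 0.4, rng) for _ in range(100_000)])
        freq = np.bincount(draws, minlength=4) / len(draws)
        expected = np.array([0.216, 0.432, 0.288, 0.064])
        assert np.allclose(freq, expected, atol=0.01)

    def test_thinning_composes_multiplicatively(self, rng):
        """Thinning by p1 then p2 equals one thinning by p1*p2 (chi-square)."""
        n, p1, p2 = 5, 0.7, 0.6
        first = rng.binomial(n, p1, size=100_000)
        double = rng.binomial(first, p2)
        counts = np.bincount(double, minlength=n + 1)
        expected = sps.binom.pmf(np.arange(n + 1), n, p1 * p2) * len(first)
        _, p = sps.chisquare(counts, expected)
        assert p > 0.01


class TestSimulateTrace:
    def test_zero_fluorophores_is_noise_about_baseline(self, rng):
        cfg = sm.SimulationConfig(frames=200)
        trace, times = sm.simulate_trace(0, "farred", cfg, rng)
        assert len(times) == 0
        assert abs(trace.values.mean() - cfg.baseline) < 3 * cfg.noise_sd / np.sqrt(200)
        ann = sm.count_steps_reference(trace.values)
        assert ann.rejected and ann.n_steps == 0

    def test_single_fluorophore_noise_free_gives_one_exact_step(self, rng):
        cfg = sm.SimulationConfig(frames=500, noise_sd=0.0)
        trace, times = sm.simulate_trace(1, "farred", cfg, rng)
        assert len(times) == 1 and times[0] < cfg.total_time  # seeded: bleaches in window
        drops = np.flatnonzero(np.diff(trace.values) != 0)
        assert len(drops) == 1
        bleach_frame = drops[0] + 1
        assert bleach_frame == int(np.ceil(times[0] / cfg.frame_interval))
        assert trace.values[bleach_frame - 1] - trace.values[bleach_frame] == cfg.step_height

    def test_bleach_times_sorted_and_nonnegative(self, rng):
        cfg = sm.SimulationConfig(frames=10)
        _, times = sm.simulate_trace(5, "farred", cfg, rng)
        assert np.all(np.diff(times) >= 0) and np.all(times >= 0)

    def test_half_of_fluorophores_bleach_by_half_time(self, rng):
        cfg = sm.SimulationConfig(frames=4)
        n = 10_000
        times = np.array(
            [sm.simulate_trace(1, "farred", cfg, rng)[1][0] for _ in range(n)]
        )
        frac = (times <= cfg.farred_half_time).mean()
        se = 0.5 / np.sqrt(n)
        assert abs(frac - 0.5) <= 3 * se

    def test_survival_is_exponential(self, rng):
        """Kolmogorov-Smirnov against exp(-t ln2 / t_half) at alpha = 0.01."""
        cfg = sm.SimulationConfig(frames=4)
        times = np.array(
            [sm.simulate_trace(1, "green", cfg, rng)[1][0] for _ in range(10_000)]
        )
        scale = cfg.green_half_time / np.log(2.0)
        _, p = sps.kstest(times, "expon", args=(0, scale))
        assert p > 0.01

    def test_expected_trace_non_increasing(self, rng):
        """Mean over many traces decreases monotonically apart from noise."""
        cfg = sm.SimulationConfig(frames=100, noise_sd=0.0)
        mean = np.mean(
            [sm.simulate_trace(3, "farred", cfg, rng)[0].values for _ in range(500)], axis=0
        )
        assert np.all(np.diff(mean) <= 1e-9)


class TestSimulateExperiment:
    def test_bookkeeping_row_counts_and_unique_ids(self, rng):
        cfg = sm.SimulationConfig(frames=20, spots_per_field=100, n_bio=2, n_tech=2)
        traces, truth = sm.simulate_experiment(cfg, rng)
        assert len(truth) == 400
        assert truth["spot_id"].is_unique
        farred = traces[traces["channel"] == "farred"]
        assert len(farred) == 400
        assert set(traces["spot_id"]) <= set(truth["spot_id"])

    def test_green_trace_present_only_when_labeled(self, rng):
        cfg = sm.SimulationConfig(
            frames=20, spots_per_field=200, n_bio=1, n_tech=1, green_labeling_prob=0.5
        )
        traces, truth = sm.simulate_experiment(cfg, rng)
        greens = set(traces.loc[traces["channel"] == "green", "spot_id"])
        assert greens == set(truth.loc[truth["green_labeled"], "spot_id"])

    def test_deterministic_copy_dist_fully_labeled(self, rng):
        cfg = sm.SimulationConfig(
            frames=20, spots_per_field=100, n_bio=1, n_tech=1,
            copy_number_dist={1: 1.0}, labeling_prob=1.0,
        )
        _, truth = sm.simulate_experiment(cfg, rng)
        assert (truth["labeled_farred_copies"] == 1).all()

    def test_multimeric_fraction_matches_binomial_arithmetic(self, rng):
        """P(>=2 labeled) for {1:0.6, 3:0.4} at p=0.4 is 0.4*(1-0.6^3-3*0.4*0.6^2)."""
        cfg = sm.SimulationConfig(
            frames=20, spots_per_field=20_000, n_bio=1, n_tech=1,
            copy_number_dist={1: 0.6, 3: 0.4}, labeling_prob=0.4,
        )
        complexes = simulate_complexes(cfg, rng)
        frac = np.mean([c.labeled_farred_copies >= 2 for c in complexes])
        assert abs(frac - 0.1408) < 0.01

    def test_same_seed_gives_identical_tables(self):
        cfg = sm.SimulationConfig(frames=30, spots_per_field=50, n_bio=1, n_tech=2)
        t1, g1 = sm.simulate_experiment(cfg, np.random.default_rng(7))
        t2, g2 = sm.simulate_experiment(cfg, np.random.default_rng(7))
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1, g2)


class TestCopyMixture:
    def test_default_mixture_hits_target_observed_multimeric(self):
        mix = copy_mixture_for_multimeric_fraction(0.39, 0.4)
        obs = sm.expected_observed_classes(mix, 0.4)
        multim = sum(v for k, v in obs.items() if k >= 2)
        detected = 1.0 - obs[0]
        assert abs(multim / detected - 0.39) < 1e-9

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError):
            copy_mixture_for_multimeric_fraction(0.99, 0.4)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"labeling_prob": 1.2},
            {"frames": 1},
            {"copy_number_dist": {1: 0.5, 2: 0.6}},
            {"copy_number_dist": {1: -0.5, 2: 1.5}},
            {"farred_half_time": -1.0},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sm.SimulationConfig(**kwargs)

    def test_default_half_times_follow_imaging_time(self):
        cfg = sm.SimulationConfig()
        assert cfg.total_time == pytest.approx(50.0)
        assert cfg.farred_half_time == pytest.approx(10.0)
        assert cfg.green_half_time == pytest.approx(5.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = sm.SimulationConfig(frames=77, copy_number_dist={0: 0.5, 2: 0.5})
        path = tmp_path / "cfg.yaml"
        cfg.to_file(path)
        loaded = sm.SimulationConfig.from_file(path)
        assert loaded.frames == 77
        assert loaded.copy_number_dist == cfg.copy_number_dist


class TestMakeLabeledDataset:
    def test_single_copy_fully_labeled_yields_one_step_labels(self):
        cfg = sm.SimulationConfig(
            frames=400, noise_sd=0.0, labeling_prob=1.0, copy_number_dist={1: 1.0},
            n_bio=1, n_tech=1, spots_per_field=60,
        )
        rng = np.random.default_rng(5)
        ds = sm.make_labeled_dataset(cfg, rng)
        counts = ds.class_counts()
        # a fluorophore surviving the whole window (or bleaching at the very
        # edge) produces no countable step; all others must be 1-step
        assert counts["2-step"] == 0 and counts["3plus"] == 0
        assert counts["1-step"] >= 0.85 * len(ds)

    def test_high_noise_forces_rejection(self):
        cfg = sm.SimulationConfig(
            frames=300, noise_sd=2.0 * 50.0, copy_number_dist={1: 1.0},
            labeling_prob=1.0, n_bio=1, n_tech=1, spots_per_field=40,
        )
        ds = sm.make_labeled_dataset(cfg, np.random.default_rng(6))
        assert ds.class_counts()["rejected"] > len(ds) / 2

    def test_balanced_mixture_gives_roughly_equal_classes(self):
        cfg = sm.SimulationConfig(
            frames=1000, noise_sd=0.0, labeling_prob=1.0,
            copy_number_dist={0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25},
            n_bio=1, n_tech=1, spots_per_field=1200,
        )
        ds = sm.make_labeled_dataset(cfg, np.random.default_rng(7))
        counts = ds.class_counts()
        for cls in ds.class_names:
            assert abs(counts[cls] / len(ds) - 0.25) < 0.05

    def test_traces_are_zscored(self, small_config):
        ds = sm.make_labeled_dataset(small_config, np.random.default_rng(8))
        keep = ds.X.std(axis=1) > 0  # degenerate traces stored as zeros
        assert np.allclose(ds.X[keep].mean(axis=1), 0.0, atol=1e-5)
        assert np.allclose(ds.X[keep].std(axis=1), 1.0, atol=1e-4)
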