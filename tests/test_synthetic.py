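"""Synthetic-cohort generator: morphology, determinism, median fidelity."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import wristpulse as wp
from wristpulse.synthetic import (
    CycleShape, GROUP_PERIODS, GROUP_SHAPES, TIME_DOMAIN_FEATURES,
    MSE_FEATURES, shape_features,
)


def single_bump_shape(mu=0.3, sigma=0.06):
    return CycleShape(1.0, mu, sigma, 0.0, mu + 0.2, 0.05, 0.0, mu + 0.4, 0.05)


class TestGenerateCycle:
    def test_sample_count_follows_rounding_rule(self):
        wave, _ = wp.generate_cycle(GROUP_SHAPES[1], 0.761, 200.0)
        assert wave.size == 152  # round(0.761 * 200)

    def test_single_component_peaks_at_its_center(self):
        shape = single_bump_shape(mu=0.3)
        wave, fid = wp.generate_cycle(shape, 0.8, 200.0)
        expected = 0.3 * wave.size
        assert abs(fid["B"] - expected) <= 1
        assert fid["C"] is None and fid["D"] is None and fid["E"] is None

    def test_dicrotic_notch_is_unique_minimum_between_components(self):
        # brute-force extrema scan of the densely sampled analytic curve
        for g in (1, 2, 3):
            shape = GROUP_SHAPES[g]
            frac = np.linspace(0, 1, 50001, endpoint=False)
            y = shape.evaluate(frac)
            d = np.sign(np.diff(y))
            ext = np.flatnonzero(d[1:] != d[:-1]) + 1
            minima = [i for i in ext if d[i - 1] < 0
                      and shape.mu_tidal < frac[i] < shape.mu_dicrotic]
            assert len(minima) == 1

    def test_ground_truth_matches_sampled_extrema(self):
        wave, fid = wp.generate_cycle(GROUP_SHAPES[1], 0.761, 200.0)
        assert fid["A"] == 0 and fid["G"] == wave.size - 1
        assert fid["B"] == int(np.argmax(wave))
        e = fid["E"]
        assert wave[e] < wave[e - 1] and wave[e] < wave[e + 1]
        assert fid["B"] < fid["C"] <= fid["D"] < fid["E"] < fid["F"]

    def test_unresolvable_cycle_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            wp.generate_cycle(GROUP_SHAPES[1], 0.04, 200.0)

    def test_shape_invariants_enforced(self):
        with pytest.raises(ValueError):
            CycleShape(1.0, 0.2, 0.05, 1.2, 0.4, 0.05, 0.3, 0.6, 0.05)
        with pytest.raises(ValueError):
            CycleShape(1.0, 0.5, 0.05, 0.5, 0.3, 0.05, 0.3, 0.6, 0.05)


class TestGenerateSignal:
    def test_zero_jitter_gives_equal_periods_and_autocorrelation_peak(self):
        cfg = replace(wp.CohortConfig(), period_cv=0.0, subject_period_cv=0.0,
                      amp_jitter=0.0, noise_sd=0.0, wander_amp=0.0)
        sig, truth = wp.generate_signal(cfg, 1, seed=5)
        lengths = {c.end - c.start for c in truth.cycles}
        assert lengths == {152}
        x = sig.samples - sig.samples.mean()
        ac = np.correlate(x, x, mode="full")[x.size:]
        lag = 100 + int(np.argmax(ac[100:250]))
        assert abs(lag - 152) <= 1

    def test_seed_determinism(self):
        cfg = wp.CohortConfig()
        s1, t1 = wp.generate_signal(cfg, 2, seed=9)
        s2, t2 = wp.generate_signal(cfg, 2, seed=9)
        np.testing.assert_array_equal(s1.samples, s2.samples)
        assert [c.start for c in t1.cycles] == [c.start for c in t2.cycles]

    def test_duration_and_annotation_bounds(self):
        cfg = wp.CohortConfig()
        sig, truth = wp.generate_signal(cfg, 3, seed=2)
        assert sig.samples.size == round(cfg.duration * cfg.fs)
        assert all(c.end <= sig.samples.size for c in truth.cycles)

    def test_group3_preset_shifts_downstream_medians(self, clean_config):
        """Extractor-recovered medians reproduce the group-3 contrast
        (shorter cycle, lower dicrotic-notch ratio) on 30 subjects/group."""
        meds = {}
        for g in (1, 3):
            rng = np.random.default_rng(42)
            T, h = [], []
            for _ in range(30):
                sig, _ = wp.generate_signal(clean_config, g, rng=rng)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f, _ = wp.extract_subject_features(sig, band=None)
                T.append(f.T)
                h.append(f.h4_h1)
            meds[g] = (np.median(T), np.median(h))
        assert meds[3][0] < meds[1][0]  # shorter cycle
        assert meds[3][1] < meds[1][1]  # lower h4/h1


class TestFeatureTable:
    def test_layout_and_determinism(self):
        cfg = wp.CohortConfig(n_per_group=(12, 5, 7))
        t1 = wp.generate_feature_table(cfg, seed=3)
        t2 = wp.generate_feature_table(cfg, seed=3)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == 24
        assert list(t1["group"].value_counts().sort_index()) == [12, 5, 7]
        for col in TIME_DOMAIN_FEATURES + MSE_FEATURES + ["age", "sex", "bmi"]:
            assert col in t1.columns

    def test_median_fidelity_large_sample(self):
        """Sample medians converge to the configured group medians (2% rel)."""
        cfg = wp.CohortConfig(n_per_group=(10000, 5000, 5000))
        t = wp.generate_feature_table(cfg, seed=11)
        g1 = t[t.group == 1]
        assert abs(g1["h4_h1"].median() - 0.478) <= 0.01
        for feat, target in [("T", 0.761), ("t5", 0.413), ("w1", 0.191),
                             ("MSE_1", 0.035), ("MSE_5", 0.187)]:
            assert abs(g1[feat].median() - target) / target < 0.02

    def test_zero_variance_config_degenerates_to_preset(self, presets):
        frozen = {k: tuple((m, 0.0) for m, _ in v) for k, v in presets.items()}
        cfg = wp.CohortConfig(n_per_group=(4, 4, 4), feature_presets=frozen)
        t = wp.generate_feature_table(cfg, seed=0)
        g2 = t[t.group == 2]
        assert (g2["T"] == presets["T"][1][0]).all()
        assert (g2["MSE_3"] == presets["MSE_3"][1][0]).all()


def test_shape_features_consistent_with_presets():
    """Dense-grid features of each group shape hit that group's median
    waveform proportions.

    Tolerance 2.5%: the group medians of w1, T and w1/T come from different
    subjects' distributions, so median(w1)/median(T) differs from the median
    ratio by ~2%; one deterministic waveform can only realize one of the two.
    """
    for g, targets in {
        1: dict(t1_T=0.190, h4_h1=0.478, w1_T=0.255, w2_T=0.189),
        2: dict(t1_T=0.183, h4_h1=0.468, w1_T=0.250, w2_T=0.185),
        3: dict(t1_T=0.200, h4_h1=0.419, w1_T=0.240, w2_T=0.175),
    }.items():
        f = shape_features(GROUP_SHAPES[g], GROUP_PERIODS[g])
        for k, v in targets.items():
            assert abs(f[k] - v) / v < 0.025, (g, k, f[k], v)
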