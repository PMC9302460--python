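"""Synthetic layouts, stimulus tables and epoch generation."""

import numpy as np
import pandas as pd
import pytest

from sensorlight.containers import EffectSpec, SensorLayout
from sensorlight.synth import (
    CATEGORIES,
    make_layout,
    make_stimulus_table,
    simulate_epochs,
)


def brute_force_degrees(layout: SensorLayout) -> np.ndarray:
    """Independent neighbor count from raw pairwise distances."""
    pos = layout.positions
    deg = np.zeros(len(pos), dtype=int)
    for i in range(len(pos)):
        for j in range(len(pos)):
            if i == j:
                continue
            d = np.hypot(*(pos[i] - pos[j]))
            if d < layout.neighbor_threshold:
                deg[i] += 1
    return deg


class TestMakeLayout:
    def test_grid3_degrees_match_brute_force(self, grid3):
        deg = grid3.adjacency().sum(axis=1)
        assert np.array_equal(deg, brute_force_degrees(grid3))
        # 4-neighborhood: corners 2, edges 3, center 4
        assert deg[0] == 2 and deg[4] == 4

    def test_single_channel_has_no_neighbors(self):
        lay = make_layout(1, 1, 1.0)
        assert lay.adjacency().sum() == 0

    @pytest.mark.parametrize("shape", [(2, 2), (3, 5), (4, 4)])
    def test_interior_degree_at_least_corner_degree(self, shape):
        lay = make_layout(*shape, 1.0)
        deg = lay.adjacency().sum(axis=1)
        assert deg.max() >= deg[0]

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            make_layout(0, 3, 1.0)
        with pytest.raises(ValueError):
            make_layout(3, 3, 0.0)

    def test_neighbor_relation_symmetric_irreflexive(self, grid4):
        adj = grid4.adjacency()
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()


class TestStimulusTable:
    def test_length_density_correlation_near_target(self, table134):
        r = np.corrcoef(table134["n_syllables"], table134["n_phon_neighbors"])[0, 1]
        assert abs(r - (-0.67)) < 0.15

    def test_frequency_correlations_near_targets(self, table134):
        r_fl = np.corrcoef(table134["frequency"], table134["n_syllables"])[0, 1]
        r_fd = np.corrcoef(table134["frequency"], table134["n_phon_neighbors"])[0, 1]
        assert abs(r_fl - (-0.37)) < 0.2
        assert abs(r_fd - 0.32) < 0.2

    def test_zero_targets_give_independence(self):
        t = make_stimulus_table(134, seed=11, targets={})
        cols = ["n_syllables", "n_phon_neighbors", "frequency"]
        corr = t[cols].corr().to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.2)

    def test_categories_balanced(self, table134):
        counts = table134["category"].value_counts()
        assert set(counts.index) == set(CATEGORIES)
        assert counts.max() - counts.min() <= 2

    def test_length_class_definition(self, table134):
        short = table134["n_syllables"] == 1
        assert (table134.loc[short, "length_class"] == "short").all()
        assert (table134.loc[~short, "length_class"] == "long").all()

    def test_visual_features_independent_of_lexical(self, table134):
        for vis in ("contrast", "edge_density", "colorfulness"):
            r = np.corrcoef(table134[vis], table134["n_phon_neighbors"])[0, 1]
            assert abs(r) < 0.25

    def test_rejects_too_few_items(self):
        with pytest.raises(ValueError):
            make_stimulus_table(8, seed=0)

    def test_rejects_infeasible_targets(self):
        bad = {
            ("n_syllables", "n_phon_neighbors"): -0.9,
            ("frequency", "n_syllables"): -0.9,
            ("frequency", "n_phon_neighbors"): -0.9,
        }
        with pytest.raises(ValueError, match="positive semidefinite"):
            make_stimulus_table(50, seed=0, targets=bad)

    def test_deterministic_given_seed(self):
        a = make_stimulus_table(40, seed=5)
        b = make_stimulus_table(40, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateEpochs:
    def test_no_effects_no_noise_gives_zero_data(self, grid4, table24):
        eps = simulate_epochs(
            table24, grid4, [], noise_sd=0.0, n_subjects=2, n_reps=2,
            fs=100.0, epoch_ms=(-100, 500), seed=5,
        )
        assert len(eps) == 2
        assert np.all(eps[0].data == 0.0)

    def test_effect_mean_difference_matches_amplitude(self, grid4):
        # many repetitions so trial means are tight
        table = make_stimulus_table(24, seed=7)
        amp = 2.0
        eff = EffectSpec(
            variable="length_class",
            channels=("CH0101",),
            window_ms=(100.0, 300.0),
            amplitudes={"short": 0.0, "long": amp},
        )
        eps = simulate_epochs(
            table, grid4, [eff], noise_sd=0.5, n_subjects=1, n_reps=20,
            fs=60.0, epoch_ms=(-100, 400), invalid_fraction=0.0,
            artifact_fraction=0.0, seed=3,
        )[0]
        y = eps.trials["length_class"].to_numpy()
        ch = eps.channel_ids.index("CH0101")
        times = eps.times_ms
        # flat-top region well inside the window (past the 10 ms ramps)
        core = (times >= 130) & (times <= 270)
        outside = times < 50
        diff_in = (
            eps.data[y == "long"][:, ch][:, core].mean()
            - eps.data[y == "short"][:, ch][:, core].mean()
        )
        diff_out = (
            eps.data[y == "long"][:, ch][:, outside].mean()
            - eps.data[y == "short"][:, ch][:, outside].mean()
        )
        assert abs(diff_in - amp) < 0.1
        assert abs(diff_out) < 0.1
        other = eps.channel_ids.index("CH0202")
        diff_other = (
            eps.data[y == "long"][:, other][:, core].mean()
            - eps.data[y == "short"][:, other][:, core].mean()
        )
        assert abs(diff_other) < 0.1

    def test_invalid_fraction_emulates_exclusion_rate(self, grid3):
        # 134 items x 3 reps = 402 trials; 17% invalid leaves ~334
        table = make_stimulus_table(134, seed=3)
        eps = simulate_epochs(
            table, grid3, [], noise_sd=1.0, n_subjects=1, n_reps=3,
            fs=30.0, epoch_ms=(0, 200), seed=1,
        )[0]
        assert eps.n_trials == 402
        assert eps.trials["valid"].sum() == 402 - round(0.17 * 402)

    def test_rejects_unknown_channel_and_variable(self, grid4, table24):
        bad_ch = EffectSpec(
            variable="length_class", channels=("NOPE",),
            window_ms=(0, 100), amplitudes={"short": 0, "long": 1},
        )
        with pytest.raises(ValueError, match="unknown channel"):
            simulate_epochs(table24, grid4, [bad_ch], seed=0, n_subjects=1)
        bad_var = EffectSpec(
            variable="nonexistent", channels=("CH0000",),
            window_ms=(0, 100), amplitudes={"a": 0, "b": 1},
        )
        with pytest.raises(ValueError, match="unknown variable"):
            simulate_epochs(table24, grid4, [bad_var], seed=0, n_subjects=1)

    def test_rejects_effect_window_outside_epoch(self, grid4, table24):
        eff = EffectSpec(
            variable="length_class", channels=("CH0000",),
            window_ms=(800, 900), amplitudes={"short": 0, "long": 1},
        )
        with pytest.raises(ValueError, match="outside the epoch"):
            simulate_epochs(
                table24, grid4, [eff], seed=0, n_subjects=1,
                epoch_ms=(-100, 500),
            )

    def test_bit_identical_regeneration(self, grid4, table24):
        kw = dict(noise_sd=1.0, n_subjects=2, n_reps=2, fs=60.0,
                  epoch_ms=(-100, 300), seed=9)
        a = simulate_epochs(table24, grid4, [], **kw)
        b = simulate_epochs(table24, grid4, [], **kw)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.data, eb.data)
            assert np.array_equal(ea.missing_mask, eb.missing_mask)
            pd.testing.assert_frame_equal(ea.trials, eb.trials)

    def test_ground_truth_recorded(self, effect_epochs):
        eps, effect = effect_epochs
        assert eps.info["effects"] == [effect]

    def test_effect_spec_requires_two_amplitudes(self):
        with pytest.raises(ValueError, match="distinct class amplitudes"):
            EffectSpec(
                variable="x", channels=("a",), window_ms=(0, 100),
                amplitudes={"u": 1.0, "v": 1.0},
            )
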