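"""Bandpass/decimation, planar gradients and trial selection."""

import numpy as np
import pandas as pd
import pytest

from sensorlight.containers import EpochSet
from sensorlight.preprocess import (
    bandpass_downsample,
    combine_planar,
    planar_gradient,
    select_valid_trials,
)
from sensorlight.synth import make_layout


def make_epochs(data, fs, layout=None, trials=None, mask=None, t0=0.0):
    n, c, s = data.shape
    ids = tuple(layout.channel_ids) if layout else tuple(f"c{i}" for i in range(c))
    return EpochSet(
        data=data,
        fs=fs,
        t0_ms=t0,
        trials=trials if trials is not None else pd.DataFrame({"trial": range(n)}),
        missing_mask=mask if mask is not None else np.zeros_like(data, dtype=bool),
        channel_ids=ids,
    )


def fft_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    spec = np.abs(np.fft.rfft(x)) * 2 / x.size
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestBandpassDownsample:
    def test_1200_to_300_divides_sample_count_by_four(self):
        rng = np.random.default_rng(0)
        eps = make_epochs(rng.standard_normal((2, 3, 1200)), 1200.0)
        out = bandpass_downsample(eps, 1.0, 30.0, 300.0)
        assert out.n_samples == 300
        assert out.fs == 300.0

    def test_passband_sinusoid_preserved(self):
        fs = 600.0
        t = np.arange(int(fs * 4)) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        eps = make_epochs(sig[None, None, :], fs)
        out = bandpass_downsample(eps, 1.0, 30.0, 300.0)
        amp = fft_amplitude(out.data[0, 0], 300.0, 10.0)
        assert abs(amp - 1.0) < 0.05

    def test_stopband_sinusoid_attenuated_20db(self):
        fs = 600.0
        t = np.arange(int(fs * 4)) / fs
        sig = np.sin(2 * np.pi * 100.0 * t)
        eps = make_epochs(sig[None, None, :], fs)
        out = bandpass_downsample(eps, 1.0, 30.0, 300.0)
        amp = fft_amplitude(out.data[0, 0], 300.0, 100.0)
        assert 20 * np.log10(amp / 1.0) < -20.0

    def test_rejects_cutoff_at_target_nyquist(self):
        eps = make_epochs(np.zeros((1, 1, 600)), 600.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_downsample(eps, 1.0, 40.0, 60.0)

    def test_rejects_non_integer_factor(self):
        eps = make_epochs(np.zeros((1, 1, 600)), 600.0)
        with pytest.raises(ValueError, match="divide"):
            bandpass_downsample(eps, 1.0, 30.0, 250.0)

    def test_mask_propagates_any_missing(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((1, 1, 400))
        mask = np.zeros_like(data, dtype=bool)
        mask[0, 0, 100:102] = True  # falls inside block 25 at factor 4
        eps = make_epochs(data, 400.0, mask=mask)
        out = bandpass_downsample(eps, 1.0, 30.0, 100.0)
        assert out.missing_mask[0, 0, 25]
        assert not out.missing_mask[0, 0, 24]
        assert out.missing_mask.sum() == 1


class TestPlanarGradient:
    def test_uniform_field_gives_zero_components(self, grid4):
        data = np.full((2, grid4.n_channels, 5), 3.7)
        eps = make_epochs(data, 100.0, layout=grid4)
        planar = planar_gradient(eps, grid4)
        assert np.allclose(planar.h, 0.0, atol=1e-12)
        assert np.allclose(planar.v, 0.0, atol=1e-12)

    def test_linear_field_recovers_slope(self, grid4):
        # field F = alpha * x: horizontal ~ alpha, vertical ~ 0 (interior)
        alpha = 2.5
        field = alpha * grid4.positions[:, 0]
        data = np.tile(field[None, :, None], (1, 1, 3))
        eps = make_epochs(data, 100.0, layout=grid4)
        planar = planar_gradient(eps, grid4)
        interior = [
            i for i, (x, y) in enumerate(grid4.positions)
            if 0 < x < 3 and 0 < y < 3
        ]
        assert np.allclose(planar.h[0, interior, 0], alpha, atol=1e-9)
        assert np.allclose(planar.v[0, interior, 0], 0.0, atol=1e-9)

    def test_operator_linearity(self, grid4, rng):
        f1 = rng.standard_normal((2, grid4.n_channels, 4))
        f2 = rng.standard_normal((2, grid4.n_channels, 4))
        a, b = 1.7, -0.4
        p1 = planar_gradient(make_epochs(f1, 100.0, layout=grid4), grid4)
        p2 = planar_gradient(make_epochs(f2, 100.0, layout=grid4), grid4)
        p12 = planar_gradient(
            make_epochs(a * f1 + b * f2, 100.0, layout=grid4), grid4
        )
        assert np.allclose(p12.h, a * p1.h + b * p2.h, atol=1e-10)
        assert np.allclose(p12.v, a * p1.v + b * p2.v, atol=1e-10)

    def test_isolated_channel_flagged_missing(self):
        lay = make_layout(2, 2, 1.0, neighbor_threshold=0.5)
        eps = make_epochs(np.ones((1, 4, 3)), 100.0, layout=lay)
        planar = planar_gradient(eps, lay)
        assert planar.missing_mask.all()
        assert len(planar.info["isolated_channels"]) == 4

    def test_mask_dilates_to_neighbors(self, grid4):
        data = np.zeros((1, grid4.n_channels, 3))
        mask = np.zeros_like(data, dtype=bool)
        mask[0, 5, 1] = True
        eps = make_epochs(data, 100.0, layout=grid4, mask=mask)
        planar = planar_gradient(eps, grid4)
        adj = grid4.adjacency()
        affected = np.flatnonzero(adj[5]) .tolist() + [5]
        assert set(np.flatnonzero(planar.missing_mask[0, :, 1])) == set(affected)
        assert not planar.missing_mask[0, :, 0].any()


class TestCombinePlanar:
    def test_three_four_five(self, grid4):
        eps = make_epochs(np.zeros((1, grid4.n_channels, 1)), 100.0, layout=grid4)
        planar = planar_gradient(eps, grid4)
        planar.h[:] = 3.0
        planar.v[:] = 4.0
        out = combine_planar(planar)
        assert np.allclose(out.data, 5.0)

    def test_zero_vertical_gives_absolute_horizontal(self, grid4):
        eps = make_epochs(np.zeros((1, grid4.n_channels, 2)), 100.0, layout=grid4)
        planar = planar_gradient(eps, grid4)
        planar.h[:] = -2.5
        planar.v[:] = 0.0
        assert np.allclose(combine_planar(planar).data, 2.5)

    def test_rotation_invariance_and_nonnegativity(self, grid4, rng):
        eps = make_epochs(
            rng.standard_normal((2, grid4.n_channels, 4)), 100.0, layout=grid4
        )
        planar = planar_gradient(eps, grid4)
        base = combine_planar(planar).data
        assert (base >= 0).all()
        theta = 0.83
        h2 = np.cos(theta) * planar.h - np.sin(theta) * planar.v
        v2 = np.sin(theta) * planar.h + np.cos(theta) * planar.v
        planar.h, planar.v = h2, v2
        assert np.allclose(combine_planar(planar).data, base, atol=1e-12)


class TestTrialOrderCommutation:
    def test_filter_and_planar_commute_with_trial_reordering(self, grid4, rng):
        data = rng.standard_normal((6, grid4.n_channels, 120))
        trials = pd.DataFrame({"i": np.arange(6)})
        eps = make_epochs(data, 120.0, layout=grid4, trials=trials)
        perm = rng.permutation(6)

        def process(e):
            out = bandpass_downsample(e, 1.0, 25.0, 60.0)
            return combine_planar(planar_gradient(out, grid4)).data

        straight = process(eps)[perm]
        permuted = process(
            make_epochs(data[perm], 120.0, layout=grid4,
                        trials=trials.iloc[perm].reset_index(drop=True))
        )
        assert np.allclose(straight, permuted, atol=1e-12)


class TestSelectValidTrials:
    def test_all_valid_is_identity(self):
        data = np.arange(24.0).reshape(4, 2, 3)
        trials = pd.DataFrame({"valid": [True] * 4})
        out = select_valid_trials(make_epochs(data, 10.0, trials=trials))
        assert np.array_equal(out.data, data)

    def test_retained_count_equals_flag_count(self, rng):
        n = 50
        flags = rng.random(n) > 0.3
        data = rng.standard_normal((n, 2, 3))
        trials = pd.DataFrame({"valid": flags, "i": np.arange(n)})
        out = select_valid_trials(make_epochs(data, 10.0, trials=trials))
        assert out.n_trials == flags.sum()
        assert np.array_equal(out.trials["i"].to_numpy(), np.flatnonzero(flags))
        assert np.array_equal(out.data, data[flags])

    def test_zero_valid_rejected(self):
        trials = pd.DataFrame({"valid": [False, False]})
        eps = make_epochs(np.zeros((2, 1, 2)), 10.0, trials=trials)
        with pytest.raises(ValueError, match="zero valid"):
            select_valid_trials(eps)
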