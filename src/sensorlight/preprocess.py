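"""Preprocessing: bandpass + decimation, planar gradients, trial selection.

Axial-gradiometer-like epochs are bandpass filtered (default 1-30 Hz,
zero-phase 4th-order Butterworth), decimated to the target rate, and
transformed to synthetic planar gradients: per channel, the tangential
field derivatives are estimated by a least-squares plane fit to the field
differences toward the first-order neighbors, and the horizontal/vertical
components are combined as a per-sample Euclidean norm so that activity is
maximal above the source and invariant to a rotation of the planar axes.

Missing-data contract: masked cells never enter downstream statistics.  A
decimated cell is missing if any contributing source cell was missing; a
planar/combined cell is missing if the channel or any neighbor feeding its
gradient estimate was missing at that sample.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochSet, PlanarEpochSet, SensorLayout

__all__ = [
    "bandpass_downsample",
    "planar_gradient",
    "combine_planar",
    "select_valid_trials",
]


def bandpass_downsample(
    epochs: EpochSet,
    low: float = 1.0,
    high: float = 30.0,
    target_fs: float | None = None,
    order: int = 4,
) -> EpochSet:
    """Zero-phase bandpass then integer-factor decimation.

    ``target_fs`` must divide the sampling rate; trailing samples that do
    not fill a decimation block are dropped.  Masked samples are linearly
    interpolated before filtering (so the IIR filter never sees NaN) and
    the mask is propagated conservatively: a downsampled cell is missing if
    any source cell in its block was missing.
    """
    from scipy import signal

    fs = epochs.fs
    if target_fs is None:
        target_fs = fs
    if not (0 < low < high < fs / 2):
        raise ValueError("need 0 < low < high < Nyquist of the input rate")
    if high >= target_fs / 2:
        raise ValueError("high cutoff at or above the Nyquist of target_fs")
    factor = fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("target_fs must divide the sampling rate")
    factor = int(round(factor))

    data = epochs.data
    mask = epochs.missing_mask
    if mask.any() or np.isnan(data).any():
        data = _interpolate_masked(data, mask | np.isnan(data))

    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, data, axis=-1)

    n_keep = (epochs.n_samples // factor) * factor
    filtered = filtered[..., :n_keep:factor]
    block_mask = mask[..., :n_keep].reshape(mask.shape[0], mask.shape[1], -1, factor)
    down_mask = block_mask.any(axis=-1)

    return epochs.copy_with(
        data=filtered,
        missing_mask=down_mask,
        fs=target_fs,
        info={**epochs.info, "bandpass_hz": (low, high)},
    )


def planar_gradient(epochs: EpochSet, layout: SensorLayout) -> PlanarEpochSet:
    """Estimate horizontal/vertical planar-gradient components per channel.

    For channel *i* with neighbor positions ``p_j`` the gradient ``g`` is
    the least-squares solution of ``(p_j - p_i) . g = F_j - F_i`` over the
    first-order neighbors, i.e. a local plane fit to the field differences;
    on a regular grid a field linear in x yields exactly (slope, 0).  The
    operator is linear in the field.  Channels without neighbors are
    flagged and their components set missing.
    """
    if tuple(epochs.channel_ids) != tuple(layout.channel_ids):
        raise ValueError("epochs and layout channel sets disagree")
    adj = layout.adjacency()
    n_ch = layout.n_channels
    # weight matrices W[axis] with g[:, i, :] = sum_c W[axis][i, c] * data[:, c, :]
    wh = np.zeros((n_ch, n_ch))
    wv = np.zeros((n_ch, n_ch))
    isolated = np.zeros(n_ch, dtype=bool)
    for i in range(n_ch):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size == 0:
            isolated[i] = True
            continue
        a = layout.positions[nbrs] - layout.positions[i]  # (k, 2)
        m = np.linalg.pinv(a)  # (2, k): g = m @ (F_nbrs - F_i)
        wh[i, nbrs] = m[0]
        wh[i, i] = -m[0].sum()
        wv[i, nbrs] = m[1]
        wv[i, i] = -m[1].sum()

    h = np.einsum("ic,ncs->nis", wh, epochs.data, optimize=True)
    v = np.einsum("ic,ncs->nis", wv, epochs.data, optimize=True)

    # a planar cell is missing if the channel or any neighbor is missing
    stencil = adj | np.eye(n_ch, dtype=bool)
    mask = np.einsum("ic,ncs->nis", stencil.astype(float), epochs.missing_mask.astype(float)) > 0
    if isolated.any():
        mask[:, isolated, :] = True

    return PlanarEpochSet(
        h=h,
        v=v,
        fs=epochs.fs,
        t0_ms=epochs.t0_ms,
        trials=epochs.trials,
        missing_mask=mask,
        channel_ids=epochs.channel_ids,
        info={**epochs.info, "planar": "least-squares neighbor plane fit",
              "isolated_channels": [epochs.channel_ids[i] for i in np.flatnonzero(isolated)]},
    )


def combine_planar(planar: PlanarEpochSet) -> EpochSet:
    """Combine components as the per-sample Euclidean norm sqrt(h^2 + v^2)."""
    combined = np.hypot(planar.h, planar.v)
    return EpochSet(
        data=combined,
        fs=planar.fs,
        t0_ms=planar.t0_ms,
        trials=planar.trials,
        missing_mask=planar.missing_mask.copy(),
        channel_ids=planar.channel_ids,
        info={**planar.info, "combined": "euclidean-norm"},
    )


def select_valid_trials(epochs: EpochSet, flag_column: str = "valid") -> EpochSet:
    """Keep only trials whose metadata flag is true; re-index the table."""
    if flag_column not in epochs.trials.columns:
        raise ValueError(f"trial table has no {flag_column!r} column")
    keep = epochs.trials[flag_column].to_numpy(dtype=bool)
    if not keep.any():
        raise ValueError("zero valid trials")
    return epochs.copy_with(
        data=epochs.data[keep],
        missing_mask=epochs.missing_mask[keep],
        trials=epochs.trials.loc[keep].reset_index(drop=True),
    )


def _interpolate_masked(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linearly interpolate masked samples along time (per trial/channel)."""
    out = data.copy()
    bad_tc = np.argwhere(mask.any(axis=-1))
    n = data.shape[-1]
    idx = np.arange(n)
    for tr, ch in bad_tc:
        m = mask[tr, ch]
        if m.all():
            out[tr, ch] = 0.0
        else:
            out[tr, ch, m] = np.interp(idx[m], idx[~m], data[tr, ch, ~m])
    return out
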