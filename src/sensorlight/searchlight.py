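"""Spatiotemporal searchlight geometry and per-center feature extraction.

A searchlight at (channel, time) collects the channel's first-order
neighborhood (optionally including the center channel itself) and a time
window of fixed duration — 150 ms, i.e. 45 samples at 300 Hz — and
flattens the windowed data of those channels into one feature vector per
trial, channel-major.  Centers whose window does not fit inside the epoch
are marked undefined rather than silently truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EpochSet, SensorLayout

__all__ = [
    "NeighborGraph",
    "SearchlightSpec",
    "neighbor_graph",
    "searchlight_channels",
    "window_bounds",
    "defined_centers",
    "searchlight_features",
]


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric first-order channel adjacency with degree statistics."""

    channel_ids: tuple[str, ...]
    adjacency: np.ndarray  # (C, C) bool, irreflexive

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape[0] != adj.shape[1] or not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be square and symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        object.__setattr__(self, "adjacency", adj)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def degree_stats(self) -> dict:
        d = self.degrees
        return {
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
            "min": int(d.min()),
            "max": int(d.max()),
        }

    def to_edge_list(self):
        """Edges as (channel_a, channel_b) pairs, each once, a < b."""
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return [(self.channel_ids[i], self.channel_ids[j]) for i, j in zip(ii, jj)]


@dataclass(frozen=True)
class SearchlightSpec:
    """Searchlight geometry: window duration, alignment, center inclusion.

    ``alignment`` places the window relative to the evaluation time point:
    ``trailing`` (default) uses the 150 ms ending at the center time — a
    causal window, so an effect can never be detected before its onset;
    ``centered`` and ``leading`` are also available.
    """

    window_ms: float = 150.0
    alignment: str = "trailing"
    include_center: bool = True

    def __post_init__(self) -> None:
        if self.alignment not in ("centered", "trailing", "leading"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if not self.window_ms > 0:
            raise ValueError("window_ms must be positive")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))


def neighbor_graph(layout: SensorLayout) -> NeighborGraph:
    """First-order adjacency by the layout's distance threshold."""
    adj = layout.adjacency()
    graph = NeighborGraph(channel_ids=tuple(layout.channel_ids), adjacency=adj)
    if (graph.degrees == 0).any():
        lonely = [layout.channel_ids[i] for i in np.flatnonzero(graph.degrees == 0)]
        warnings.warn(f"channels with no neighbors at this threshold: {lonely}")
    return graph


def searchlight_channels(graph: NeighborGraph, center: int | str,
                         include_center: bool = True) -> np.ndarray:
    """Sorted channel indices forming the searchlight set at a center."""
    c = graph.channel_ids.index(center) if isinstance(center, str) else int(center)
    idx = np.flatnonzero(graph.adjacency[c])
    if include_center:
        idx = np.union1d(idx, [c])
    return idx


def window_bounds(center_time_index: int, window_samples: int,
                  alignment: str) -> tuple[int, int]:
    """Half-open sample range [start, stop) of the window at a center."""
    w = window_samples
    if alignment == "trailing":
        start = center_time_index - w + 1
    elif alignment == "leading":
        start = center_time_index
    else:  # centered
        start = center_time_index - w // 2
    return start, start + w


def defined_centers(n_samples: int, window_samples: int, alignment: str) -> np.ndarray:
    """Boolean mask over time indices whose window fits inside the epoch."""
    idx = np.arange(n_samples)
    starts = np.array([window_bounds(i, window_samples, alignment)[0] for i in idx])
    return (starts >= 0) & (starts + window_samples <= n_samples)


def searchlight_features(
    epochs: EpochSet,
    center_channel: int | str,
    center_time_index: int,
    spec: SearchlightSpec,
    graph: NeighborGraph,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial feature matrix for one searchlight center.

    Returns ``(X, kept)`` where ``X`` is trials x (window_samples *
    n_searchlight_channels), flattened channel-major (all samples of the
    first channel, then the next), and ``kept`` indexes the trials with no
    missing cell anywhere in the searchlight; the others are dropped.

    Returns ``(None, None)`` when the window does not fit inside the epoch
    (the center is undefined, not an error).
    """
    w = spec.window_samples(epochs.fs)
    start, stop = window_bounds(int(center_time_index), w, spec.alignment)
    if start < 0 or stop > epochs.n_samples:
        return None, None
    chans = searchlight_channels(graph, center_channel, spec.include_center)
    block = epochs.data[:, chans, start:stop]          # (n, k, w)
    bad = epochs.missing_mask[:, chans, start:stop].any(axis=(1, 2))
    kept = np.flatnonzero(~bad)
    X = block[kept].reshape(kept.size, -1)             # channel-major
    return X, kept
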