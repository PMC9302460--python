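"""Core in-memory containers shared by every pipeline stage.

The containers are deliberately thin: plain dataclasses wrapping numpy
arrays and a pandas trial table, with the invariants every stage relies on
checked at construction time.  Epoched data are stored as
``trials x channels x samples`` arrays accompanied by a boolean
``missing_mask`` of the same shape; masked cells are ignored by all
downstream computation (trials touching a masked cell inside a searchlight
are dropped for that searchlight).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorLayout",
    "EffectSpec",
    "EpochSet",
    "PlanarEpochSet",
    "save_epochs",
    "load_epochs",
]


@dataclass(frozen=True)
class SensorLayout:
    """Sensor identities, flattened 2-D positions and a distance threshold.

    The neighbor relation is ``0 < distance(i, j) < neighbor_threshold``;
    it is symmetric and irreflexive by construction.  The same relation
    drives the planar-gradient estimate, the searchlight channel sets and
    the spatial adjacency of the cluster test.
    """

    channel_ids: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2) float
    neighbor_threshold: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n_channels, 2) array")
        if len(self.channel_ids) != pos.shape[0]:
            raise ValueError("channel_ids and positions disagree in length")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if not self.neighbor_threshold > 0:
            raise ValueError("neighbor_threshold must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def adjacency(self) -> np.ndarray:
        """Boolean (C, C) first-order neighbor matrix (no self loops)."""
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        adj = (d < self.neighbor_threshold) & (d > 0)
        return adj


@dataclass(frozen=True)
class EffectSpec:
    """A class-dependent evoked component injected by the simulator.

    ``amplitudes`` maps each level of the trial variable to a signal
    offset; the offset is multiplied by a smooth temporal envelope and
    added on ``channels`` inside ``window_ms``.  ``channel_weights``
    optionally scales the offset per channel (e.g. alternating signs to
    mimic the spatially differentiated field pattern a planar transform
    responds to); unlisted channels default to weight 1.  The spec doubles
    as the ground truth record that recovery tests compare against.
    """

    variable: str
    channels: tuple[str, ...]
    window_ms: tuple[float, float]
    amplitudes: dict[str, float]
    waveform: str = "half_cosine"
    channel_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.window_ms[1] <= self.window_ms[0]:
            raise ValueError("effect window must have positive duration")
        if len(set(self.amplitudes.values())) < 2:
            raise ValueError(
                "need >= 2 distinct class amplitudes for a decodable effect"
            )


@dataclass
class EpochSet:
    """Epoched multichannel data for one subject.

    Attributes
    ----------
    data : (n_trials, n_channels, n_samples) float array
    fs : sampling rate in Hz
    t0_ms : time of the first sample relative to stimulus onset
    trials : per-trial metadata (one row per trial; class labels, valid flag)
    missing_mask : boolean array, ``True`` where a cell is unusable
    channel_ids : channel labels matching the second data axis
    info : free-form provenance (e.g. injected ground-truth effects)
    """

    data: np.ndarray
    fs: float
    t0_ms: float
    trials: pd.DataFrame
    missing_mask: np.ndarray
    channel_ids: tuple[str, ...]
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.data.shape != self.missing_mask.shape:
            raise ValueError("data and missing_mask shapes disagree")
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.data.shape[1] != len(self.channel_ids):
            raise ValueError("channel axis does not match channel_ids")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial table does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.fs

    def copy_with(self, **kw) -> "EpochSet":
        out = EpochSet(
            data=kw.get("data", self.data),
            fs=kw.get("fs", self.fs),
            t0_ms=kw.get("t0_ms", self.t0_ms),
            trials=kw.get("trials", self.trials),
            missing_mask=kw.get("missing_mask", self.missing_mask),
            channel_ids=kw.get("channel_ids", self.channel_ids),
            info=kw.get("info", dict(self.info)),
        )
        return out


@dataclass
class PlanarEpochSet:
    """Planar-gradient components derived from an axial EpochSet.

    ``h`` and ``v`` hold the horizontal and vertical tangential-derivative
    estimates, one pair of series per original channel.  The combined
    (norm) series is produced by :func:`sensorlight.preprocess.combine_planar`.
    """

    h: np.ndarray
    v: np.ndarray
    fs: float
    t0_ms: float
    trials: pd.DataFrame
    missing_mask: np.ndarray
    channel_ids: tuple[str, ...]
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.h.shape != self.v.shape or self.h.shape != self.missing_mask.shape:
            raise ValueError("h, v and missing_mask shapes must agree")


# ---------------------------------------------------------------------------
# serialization: one .npz per subject plus a JSON sidecar and a TSV trial table
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an EpochSet as ``<path>.npz`` + ``<path>.json`` + ``<path>.trials.tsv``."""
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        data=epochs.data,
        missing_mask=epochs.missing_mask,
    )
    sidecar = {
        "fs": epochs.fs,
        "t0_ms": epochs.t0_ms,
        "channel_ids": list(epochs.channel_ids),
        "trial_table": path.with_suffix(".trials.tsv").name,
        "info": _jsonable(epochs.info),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    epochs.trials.to_csv(path.with_suffix(".trials.tsv"), sep="\t", index=False)


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    trials = pd.read_csv(path.parent / sidecar["trial_table"], sep="\t")
    return EpochSet(
        data=arrays["data"],
        fs=sidecar["fs"],
        t0_ms=sidecar["t0_ms"],
        trials=trials,
        missing_mask=arrays["missing_mask"],
        channel_ids=tuple(sidecar["channel_ids"]),
        info=sidecar.get("info", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, EffectSpec):
        return {
            "variable": obj.variable,
            "channels": list(obj.channels),
            "window_ms": list(obj.window_ms),
            "amplitudes": dict(obj.amplitudes),
            "waveform": obj.waveform,
            "channel_weights": dict(obj.channel_weights) if obj.channel_weights else None,
        }
    return obj
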