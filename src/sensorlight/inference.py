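"""Permutation nulls, Z-standardization and cluster-based group inference.

Single-subject chance level is estimated empirically: the decoding map is
recomputed on label randomizations (default 100) and each cell's observed
accuracy is Z-standardized by the null mean and SD.  Randomization can be
constrained to strata — labels are permuted within each stratum only — so
that a covariate entangled with the target variable (object category for
the phonological contrasts; visual-feature bins for the category contrast)
cannot masquerade as decodable signal: whatever that covariate contributes
is present in the null too.

Group inference is a nonparametric cluster-based permutation test across
space and time: per cell a one-sample T of the subject Z scores against 0,
cells exceeding the one-sided critical t at ``alpha_cluster`` clustered by
the searchlight's spatial adjacency plus temporal adjacency, cluster mass
= sum of T, and the familywise null is the maximum cluster mass under
random sign-flips of whole-subject Z maps (exact enumeration available for
small groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .containers import EpochSet
from .decoding import AccuracyMap, CvScheme, decode_map
from .searchlight import NeighborGraph, SearchlightSpec

__all__ = [
    "StratifiedNull",
    "Cluster",
    "ClusterResult",
    "constrained_shuffle",
    "build_null",
    "z_standardize",
    "cluster_permutation_test",
    "strata_from_columns",
]


@dataclass
class StratifiedNull:
    """Per-cell null accuracy mean/SD over label randomizations."""

    mean: np.ndarray              # (C, T)
    sd: np.ndarray                # (C, T), ddof=1
    n_rand: int
    defined: np.ndarray           # (C, T) bool: defined in every randomization
    strata: str                   # description of the strata used
    variable: str


@dataclass(frozen=True)
class Cluster:
    """One spatiotemporally contiguous supra-threshold set."""

    cells: tuple[tuple[int, int], ...]   # (channel index, time-center index)
    mass: float                          # sum of cell T values
    p_value: float

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted({c for c, _ in self.cells}))

    @property
    def time_indices(self) -> tuple[int, ...]:
        return tuple(sorted({t for _, t in self.cells}))


@dataclass
class ClusterResult:
    clusters: list[Cluster]              # sorted by decreasing mass
    t_map: np.ndarray                    # (C, T) cell-level T statistic
    threshold: float                     # cluster-forming t threshold
    n_perm: int
    alpha_cluster: float
    center_times_ms: np.ndarray = None
    channel_ids: tuple[str, ...] = None
    meta: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cl in enumerate(self.clusters):
            for ch, ti in cl.cells:
                rows.append(
                    {
                        "cluster": i,
                        "channel": self.channel_ids[ch] if self.channel_ids else ch,
                        "time_ms": (
                            self.center_times_ms[ti]
                            if self.center_times_ms is not None
                            else ti
                        ),
                        "t": self.t_map[ch, ti],
                        "mass": cl.mass,
                        "p_value": cl.p_value,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# constrained label randomization
# ---------------------------------------------------------------------------

def constrained_shuffle(labels, strata, seed) -> np.ndarray:
    """Permute labels uniformly at random within each stratum.

    The per-stratum label multiset is conserved exactly; no label crosses a
    stratum boundary.  ``strata=None`` degenerates to an ordinary uniform
    permutation; singleton strata keep their label fixed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels)
    out = labels.copy()
    if strata is None:
        return out[rng.permutation(labels.size)]
    strata = np.asarray(strata)
    if strata.shape[0] != labels.shape[0]:
        raise ValueError("strata must assign one stratum per trial")
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = labels[idx[rng.permutation(idx.size)]]
    return out


def strata_from_columns(trials: pd.DataFrame, columns) -> np.ndarray | None:
    """Joint strata: one stratum per combination of the given columns."""
    if not columns:
        return None
    key = trials[list(columns)].astype(str).agg("|".join, axis=1)
    return key.to_numpy()


# ---------------------------------------------------------------------------
# empirical null and Z scores
# ---------------------------------------------------------------------------

def build_null(
    epochs: EpochSet,
    label_variable: str,
    strata_variables,
    spec: SearchlightSpec,
    scheme: CvScheme,
    n_rand: int = 100,
    seed: int = 0,
    graph: NeighborGraph = None,
    time_stride: int = 1,
    engine: str = "fast",
    dtype=np.float64,
) -> StratifiedNull:
    """Null accuracy mean/SD from ``n_rand`` constrained randomizations.

    Each randomization shuffles the labels within the strata defined by
    ``strata_variables`` (a list of trial-table columns; empty/None for an
    unconstrained shuffle) and reruns the full decoding map with the same
    CV scheme as the observed map.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    labels = epochs.trials[label_variable].to_numpy()
    strata = strata_from_columns(epochs.trials, strata_variables)
    if strata is not None:
        sizes = pd.Series(strata).value_counts()
        if (sizes == 1).any():
            warnings.warn(
                f"{int((sizes == 1).sum())} singleton strata: labels fixed there"
            )
    s1 = s2 = None
    defined = None
    for r in range(n_rand):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 389, r]))
        y_r = constrained_shuffle(labels, strata, rng)
        amap = decode_map(
            epochs, label_variable, spec, scheme, graph,
            time_stride=time_stride, engine=engine, labels=y_r, dtype=dtype,
        )
        acc = amap.accuracy
        if s1 is None:
            s1 = np.zeros_like(acc)
            s2 = np.zeros_like(acc)
            defined = amap.defined.copy()
        else:
            defined &= amap.defined
        s1 += np.nan_to_num(acc)
        s2 += np.nan_to_num(acc) ** 2
    mean = s1 / n_rand
    var = np.maximum(s2 / n_rand - mean**2, 0.0) * n_rand / (n_rand - 1)
    sd = np.sqrt(var)
    mean[~defined] = np.nan
    sd[~defined] = np.nan
    return StratifiedNull(
        mean=mean,
        sd=sd,
        n_rand=n_rand,
        defined=defined,
        strata="+".join(strata_variables) if strata_variables else "none",
        variable=label_variable,
    )


def z_standardize(amap: AccuracyMap, null: StratifiedNull) -> AccuracyMap:
    """Z = (accuracy - null mean) / null SD per cell; NaN where SD = 0.

    Returns a map of the same shape whose ``accuracy`` field holds Z
    scores (``variable`` is suffixed with ``:z``).
    """
    if amap.accuracy.shape != null.mean.shape:
        raise ValueError("map and null shapes disagree")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (amap.accuracy - null.mean) / null.sd
    z[~np.isfinite(z)] = np.nan
    defined = amap.defined & null.defined & np.isfinite(z)
    return AccuracyMap(
        accuracy=z,
        n_used=amap.n_used,
        defined=defined,
        center_time_indices=amap.center_time_indices,
        center_times_ms=amap.center_times_ms,
        channel_ids=amap.channel_ids,
        variable=f"{amap.variable}:z",
        subject=amap.subject,
        meta={**amap.meta, "null_n_rand": null.n_rand, "null_strata": null.strata},
    )


# ---------------------------------------------------------------------------
# group-level cluster permutation test
# ---------------------------------------------------------------------------

def cluster_permutation_test(
    z_maps: list,
    graph: NeighborGraph,
    alpha_cluster: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
    exhaustive: bool = False,
    center_times_ms: np.ndarray = None,
) -> ClusterResult:
    """One-sided cluster-mass permutation test of subject Z maps against 0.

    ``z_maps`` are (C, T) arrays (or AccuracyMap-like objects carrying Z in
    ``.accuracy``), one per subject, on a shared grid.  Cells undefined in
    any subject are excluded.  The null distribution of the maximum
    cluster mass is formed by random sign-flips of whole-subject maps
    (``exhaustive=True`` enumerates all 2^n flips); p-values use the
    add-one estimator and are therefore never exactly 0.
    """
    arrays, defined, center_times_ms, channel_ids = _collect_maps(
        z_maps, center_times_ms
    )
    n_sub = arrays.shape[0]
    if n_sub < 2:
        raise ValueError("need >= 2 subjects")
    df = n_sub - 1
    threshold = stats.t.ppf(1.0 - alpha_cluster, df)

    flat = arrays.reshape(n_sub, -1)
    flat = np.where(defined.ravel()[None, :], flat, 0.0)
    sq_sum = (flat**2).sum(axis=0)

    t_obs = _t_from_signs(np.ones(n_sub), flat, sq_sum, defined.ravel())
    t_map = t_obs.reshape(defined.shape)

    adj = _cell_adjacency(graph, defined)
    obs_clusters = _find_clusters(t_map, threshold, defined, adj)

    if exhaustive:
        signs = np.array(
            [[1 if (i >> s) & 1 else -1 for s in range(n_sub)]
             for i in range(2**n_sub)],
            dtype=float,
        )
        n_draws = signs.shape[0]
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 577]))
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
        n_draws = n_perm

    null_max = np.empty(n_draws)
    for i in range(n_draws):
        t_perm = _t_from_signs(signs[i], flat, sq_sum, defined.ravel())
        null_max[i] = _max_cluster_mass(
            t_perm.reshape(defined.shape), threshold, defined, adj
        )

    clusters = []
    for cells, mass in obs_clusters:
        if exhaustive:
            p = float((null_max >= mass - 1e-12).mean())
        else:
            p = float((1 + (null_max >= mass - 1e-12).sum()) / (1 + n_perm))
        clusters.append(Cluster(cells=tuple(map(tuple, cells)), mass=mass, p_value=p))
    clusters.sort(key=lambda c: -c.mass)

    return ClusterResult(
        clusters=clusters,
        t_map=t_map,
        threshold=float(threshold),
        n_perm=n_draws,
        alpha_cluster=alpha_cluster,
        center_times_ms=center_times_ms,
        channel_ids=channel_ids,
        meta={"exhaustive": exhaustive, "n_subjects": n_sub},
    )


def _collect_maps(z_maps, center_times_ms):
    arrays = []
    defined = None
    channel_ids = None
    for m in z_maps:
        if hasattr(m, "accuracy"):
            arr = m.accuracy
            d = m.defined
            center_times_ms = m.center_times_ms
            channel_ids = m.channel_ids
        else:
            arr = np.asarray(m, dtype=float)
            d = np.isfinite(arr)
        arrays.append(arr)
        defined = d.copy() if defined is None else (defined & d)
    arrays = np.stack(arrays)
    if arrays.ndim != 3:
        raise ValueError("z maps must share a (channels, times) grid")
    defined &= np.isfinite(arrays).all(axis=0)
    return arrays, defined, center_times_ms, channel_ids


def _t_from_signs(signs, flat, sq_sum, defined_flat):
    """One-sample t per cell under a sign assignment.

    Sign-flipping leaves per-cell squared sums unchanged, so only the mean
    needs recomputing per permutation.
    """
    n = signs.size
    mean = signs @ flat / n
    var = (sq_sum - n * mean**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~defined_flat] = 0.0
    t[~np.isfinite(t)] = 0.0
    return t


def _cell_adjacency(graph: NeighborGraph, defined: np.ndarray) -> sparse.csr_matrix:
    """Sparse adjacency of the (C, T) cell grid.

    Spatial edges connect neighbor channels at the same time center;
    temporal edges connect consecutive time centers of the same channel.
    (No diagonal space-time edges.)
    """
    n_ch, n_t = defined.shape
    eye_t = sparse.identity(n_t, format="coo")
    spatial = sparse.kron(sparse.coo_matrix(graph.adjacency), eye_t)
    temporal_t = sparse.diags([np.ones(n_t - 1)], [1], format="coo")
    temporal = sparse.kron(sparse.identity(n_ch, format="coo"), temporal_t + temporal_t.T)
    return (spatial + temporal).tocsr()


def _find_clusters(t_map, threshold, defined, adj):
    """Maximal connected supra-threshold sets with their masses."""
    supra = (t_map > threshold) & defined
    idx = np.flatnonzero(supra.ravel())
    if idx.size == 0:
        return []
    sub = adj[idx][:, idx]
    n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
    n_t = t_map.shape[1]
    out = []
    for comp in range(n_comp):
        cells_flat = idx[labels == comp]
        cells = np.column_stack(np.divmod(cells_flat, n_t))
        mass = float(t_map.ravel()[cells_flat].sum())
        out.append((cells, mass))
    return out


def _max_cluster_mass(t_map, threshold, defined, adj) -> float:
    clusters = _find_clusters(t_map, threshold, defined, adj)
    if not clusters:
        return 0.0
    return max(mass for _, mass in clusters)
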