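"""Gaussian naive Bayes searchlight decoding with repeated stratified CV.

The classifier is Gaussian naive Bayes: per class, a prior (class
frequency in the training set) and per-feature univariate Gaussian
densities with maximum-likelihood means and variances (variance floored at
a small multiple of the mean feature variance).  Prediction is the argmax
of ``log prior + sum of per-feature log densities``; ties break toward the
lexicographically first class.

Cross-validation follows the decoding literature's standard recipe:
random undersampling to equalize class counts (applied once per repeat,
before fold assignment, so training and test sets are both balanced),
stratified 5-fold splits, the whole scheme repeated 5 times with fresh
fold assignments, and the pooled fraction of correct test predictions
reported.

``decode_map`` evaluates this procedure at every (channel, time)
searchlight center.  Because the naive Bayes log-likelihood is a sum of
independent per-feature terms, per-cell CV factorizes: class statistics
and per-trial log densities are computed once per (channel, sample) and
aggregated per center by a windowed cumulative sum over time and a sparse
adjacency product over channels.  This fast engine is exactly equivalent
to the per-cell reference path (``engine='exact'``); centers whose
searchlight contains masked training cells fall back to the per-cell
computation so the missing-data contract holds in both engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet
from .searchlight import (
    NeighborGraph,
    SearchlightSpec,
    defined_centers,
    searchlight_channels,
    searchlight_features,
    window_bounds,
)

__all__ = [
    "GnbModel",
    "CvScheme",
    "AccuracyMap",
    "fit_gnb",
    "predict_gnb",
    "log_joint",
    "undersample",
    "cross_validate",
    "decode_map",
]

#: relative variance floor: floor = VAR_FLOOR_REL * mean feature variance
VAR_FLOOR_REL = 1e-9
#: absolute fallback when every feature variance is zero
VAR_FLOOR_ABS = 1e-12


@dataclass(frozen=True)
class GnbModel:
    """Fitted Gaussian naive Bayes parameters."""

    classes: np.ndarray          # (K,) sorted labels
    priors: np.ndarray           # (K,)
    means: np.ndarray            # (K, F)
    variances: np.ndarray        # (K, F), floored, > 0
    var_floor: float

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if not (self.variances > 0).all():
            raise ValueError("variances must be positive after flooring")


@dataclass(frozen=True)
class CvScheme:
    """Repeated stratified k-fold with random undersampling."""

    n_folds: int = 5
    n_repeats: int = 5
    stratified: bool = True
    undersample: bool = True
    seed: int = 0


@dataclass
class AccuracyMap:
    """Channels x time-centers decoding accuracy for one subject."""

    accuracy: np.ndarray          # (C, T) float, NaN where undefined
    n_used: np.ndarray            # (C, T) float, mean trials tested per repeat
    defined: np.ndarray           # (C, T) bool
    center_time_indices: np.ndarray
    center_times_ms: np.ndarray
    channel_ids: tuple[str, ...]
    variable: str
    subject: object = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (channel, time_ms, accuracy, n_trials)."""
        ch = np.repeat(self.channel_ids, len(self.center_times_ms))
        t = np.tile(self.center_times_ms, len(self.channel_ids))
        return pd.DataFrame(
            {
                "channel": ch,
                "time_ms": t,
                "accuracy": self.accuracy.ravel(),
                "n_trials": self.n_used.ravel(),
                "defined": self.defined.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def fit_gnb(X: np.ndarray, y, var_floor: float | None = None) -> GnbModel:
    """Fit per-class feature means/variances (ML) and class priors.

    ``var_floor`` overrides the default relative floor
    (``1e-9 * mean feature variance``); passing an explicit value makes
    fits comparable across searchlight centers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 trials (variance undefined)")
    means = np.stack([X[y == k].mean(axis=0) for k in classes])
    variances = np.stack([X[y == k].var(axis=0) for k in classes])
    if var_floor is None:
        mean_var = variances.mean()
        var_floor = VAR_FLOOR_REL * mean_var if mean_var > 0 else VAR_FLOOR_ABS
    variances = np.maximum(variances, var_floor)
    return GnbModel(
        classes=classes,
        priors=counts / counts.sum(),
        means=means,
        variances=variances,
        var_floor=float(var_floor),
    )


def log_joint(model: GnbModel, X: np.ndarray) -> np.ndarray:
    """(n, K) array of ``log prior + sum_f log N(x_f; mu, sigma^2)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension does not match the model")
    out = np.empty((X.shape[0], model.classes.size))
    for k in range(model.classes.size):
        mu, var = model.means[k], model.variances[k]
        ll = -0.5 * (np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var)
        out[:, k] = np.log(model.priors[k]) + ll.sum(axis=1)
    return out


def predict_gnb(model: GnbModel, X: np.ndarray) -> np.ndarray:
    """Argmax class per row; ties break to the first (sorted) class."""
    lj = log_joint(model, X)
    return model.classes[np.argmax(lj, axis=1)]


def undersample(y, seed) -> np.ndarray:
    """Indices keeping exactly min-class-count trials of every class.

    Removal within each majority class is uniformly random given ``seed``
    (an int or a ``numpy.random.Generator``); the result is sorted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_keep = counts.min()
    kept = []
    for k in classes:
        idx = np.flatnonzero(y == k)
        if idx.size > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        kept.append(idx)
    return np.sort(np.concatenate(kept))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _repeat_rng(seed: int, repeat: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 211, int(repeat)]))


def _fold_ids(y, n_folds: int, stratified: bool, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..n_folds-1 per trial)."""
    from sklearn.model_selection import KFold, StratifiedKFold

    seed_int = int(rng.integers(2**31 - 1))
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=n_folds, shuffle=True, random_state=seed_int)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds[test_idx] = f
    return folds


def _repeat_plan(y: np.ndarray, scheme: CvScheme, repeat: int):
    """(kept indices, fold ids over kept) for one CV repeat."""
    rng = _repeat_rng(scheme.seed, repeat)
    kept = undersample(y, rng) if scheme.undersample else np.arange(len(y))
    folds = _fold_ids(y[kept], scheme.n_folds, scheme.stratified, rng)
    return kept, folds


def cross_validate(X: np.ndarray, y, scheme: CvScheme) -> float:
    """Pooled accuracy over all folds and repeats of the scheme.

    Raises ``ValueError`` when any class has fewer trials than folds after
    undersampling (callers building maps catch this and mark the cell
    undefined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < scheme.n_folds:
        raise ValueError("insufficient class counts for stratified folds")
    correct = total = 0
    for rep in range(scheme.n_repeats):
        kept, folds = _repeat_plan(y, scheme, rep)
        Xr, yr = X[kept], y[kept]
        for f in range(scheme.n_folds):
            tr, te = folds != f, folds == f
            model = fit_gnb(Xr[tr], yr[tr])
            pred = predict_gnb(model, Xr[te])
            correct += int((pred == yr[te]).sum())
            total += int(te.sum())
    return correct / total


# ---------------------------------------------------------------------------
# accuracy maps
# ---------------------------------------------------------------------------

def decode_map(
    epochs: EpochSet,
    label_variable: str,
    spec: SearchlightSpec,
    scheme: CvScheme,
    graph: NeighborGraph,
    time_stride: int = 1,
    engine: str = "fast",
    labels=None,
    dtype=np.float64,
) -> AccuracyMap:
    """Searchlight CV accuracy at every (channel, time-center) cell.

    ``labels`` overrides the trial-table column (used by permutation
    nulls); ``time_stride`` evaluates every k-th sample.  Both engines
    produce identical maps; ``fast`` factorizes the naive Bayes sums,
    ``exact`` loops cells through :func:`searchlight_features` and is kept
    as the independently-checkable reference.  ``dtype=np.float32`` makes
    the fast engine roughly twice as fast; predictions can differ from the
    double-precision path only at numerically tied cells.
    """
    if labels is None:
        if label_variable not in epochs.trials.columns:
            raise ValueError(f"unknown label variable {label_variable!r}")
        y = epochs.trials[label_variable].to_numpy()
    else:
        y = np.asarray(labels)
        if y.shape[0] != epochs.n_trials:
            raise ValueError("labels length does not match trials")

    w = spec.window_samples(epochs.fs)
    centers = np.arange(0, epochs.n_samples, int(time_stride))
    defined_t = defined_centers(epochs.n_samples, w, spec.alignment)[centers]
    n_ch = epochs.n_channels
    times_ms = epochs.times_ms[centers]

    acc = np.full((n_ch, centers.size), np.nan)
    n_used = np.zeros((n_ch, centers.size))
    defined = np.zeros((n_ch, centers.size), dtype=bool)

    classes, counts = np.unique(y, return_counts=True)
    feasible = classes.size >= 2 and counts.min() >= scheme.n_folds
    if feasible:
        if engine == "fast":
            correct_ct, total_ct = _map_counts_fast(
                epochs, y, spec, scheme, graph, centers, defined_t, dtype
            )
        elif engine == "exact":
            correct_ct, total_ct = _map_counts_exact(
                epochs, y, spec, scheme, graph, centers, defined_t
            )
        else:
            raise ValueError(f"unknown engine {engine!r}")
        ok = total_ct > 0
        acc[ok] = correct_ct[ok] / total_ct[ok]
        n_used = total_ct / scheme.n_repeats
        defined = ok & defined_t[None, :]

    return AccuracyMap(
        accuracy=acc,
        n_used=n_used,
        defined=defined,
        center_time_indices=centers,
        center_times_ms=times_ms,
        channel_ids=tuple(epochs.channel_ids),
        variable=label_variable,
        subject=epochs.info.get("subject"),
        meta={
            "scheme": scheme,
            "spec": spec,
            "engine": engine,
            "time_stride": int(time_stride),
        },
    )


def _global_var_floor(X2: np.ndarray, y_idx: np.ndarray, train: np.ndarray,
                      n_classes: int) -> float:
    """Shared variance floor for one fold: rel. to the mean train variance.

    Computed over all (channel, sample) features and all classes of the
    full training set so that every searchlight center of the fold uses
    the same floor (this is what makes the factorized engine and the
    per-cell reference produce identical numbers).
    """
    variances = []
    for k in range(n_classes):
        sel = train & (y_idx == k)
        variances.append(X2[sel].var(axis=0).mean())
    mean_var = float(np.mean(variances))
    return VAR_FLOOR_REL * mean_var if mean_var > 0 else VAR_FLOOR_ABS


def _map_counts_fast(epochs, y, spec, scheme, graph, centers, defined_t,
                     dtype=np.float64):
    """Pooled (correct, total) counts per cell via the factorized engine."""
    data = epochs.data.astype(dtype, copy=False)
    mask = epochs.missing_mask
    n_ch, n_s = epochs.n_channels, epochs.n_samples
    w = spec.window_samples(epochs.fs)
    classes = np.unique(y)
    k_classes = classes.size
    y_idx_all = np.searchsorted(classes, y)

    # searchlight aggregation operator over channels (sparse: low degree)
    from scipy import sparse as _sparse

    agg_dense = graph.adjacency.astype(float)
    if spec.include_center:
        agg_dense = agg_dense + np.eye(n_ch)
    agg = _sparse.csr_matrix(agg_dense)

    def _agg_channels(arr):
        """(n, C, T) -> (n, C, T) summing each channel's searchlight set."""
        n, c, t = arr.shape
        out = agg @ arr.transpose(1, 0, 2).reshape(c, n * t)
        return out.reshape(c, n, t).transpose(1, 0, 2)

    starts = np.array([window_bounds(c, w, spec.alignment)[0] for c in centers])
    valid_c = defined_t
    sel_starts = starts[valid_c]
    sel_cols = np.flatnonzero(valid_c)

    correct_ct = np.zeros((n_ch, centers.size))
    total_ct = np.zeros((n_ch, centers.size))

    # searchlight channel sets, cached once per map
    sl_cache = {
        ci: searchlight_channels(graph, ci, spec.include_center)
        for ci in range(n_ch)
    }

    # per-trial, per-center "dropped" flags via windowed any + adjacency;
    # depends only on the mask, so computed once for all repeats/folds
    if mask.any():
        win_any = _window_any(mask, w, sel_starts)            # (n, C, Tsel)
        bad_all = _agg_channels(win_any.astype(float)) > 0
    else:
        bad_all = None

    for rep in range(scheme.n_repeats):
        kept, folds = _repeat_plan(y, scheme, rep)
        Xk = data[kept]                      # (n, C, S)
        yk = y_idx_all[kept]
        bad = bad_all[kept] if bad_all is not None else None

        for f in range(scheme.n_folds):
            train = folds != f
            test = folds == f
            n_test = int(test.sum())
            if n_test == 0:
                continue
            floor = _global_var_floor(Xk, yk, train, k_classes)

            # centers whose searchlight contains masked *training* cells
            # cannot use the shared class statistics; handled per cell below
            if bad is not None:
                bad_tr_centers = bad[train].any(axis=0)        # (C, Tsel)
            else:
                bad_tr_centers = None

            # per-(channel, sample) class statistics over the full train set
            Xtr = Xk[train]
            ytr = yk[train]
            cnt = np.bincount(ytr, minlength=k_classes).astype(float)
            onehot = np.zeros((k_classes, Xtr.shape[0]))
            onehot[ytr, np.arange(Xtr.shape[0])] = 1.0
            flat = Xtr.reshape(Xtr.shape[0], -1)
            s1 = onehot @ flat
            s2 = onehot @ (flat * flat)
            mu = s1 / cnt[:, None]
            var = np.maximum(s2 / cnt[:, None] - mu**2, floor)
            log_prior = np.log(cnt / cnt.sum())

            # per-test-trial, per-(channel, sample) log densities, window-summed
            Xte = Xk[test].reshape(n_test, -1)                 # (nt, C*S)
            scores = np.empty((k_classes, n_test, n_ch, sel_starts.size))
            for k in range(k_classes):
                ll = -0.5 * (
                    np.log(2.0 * np.pi * var[k]) + (Xte - mu[k]) ** 2 / var[k]
                )
                ll = ll.reshape(n_test, n_ch, n_s)
                wsum = _window_sum(ll, w, sel_starts)          # (nt, C, Tsel)
                scores[k] = _agg_channels(wsum) + log_prior[k]
            pred = scores.argmax(axis=0)                       # (nt, C, Tsel)
            hit = pred == yk[test][:, None, None]

            if bad is None:
                correct_ct[:, sel_cols] += hit.sum(axis=0)
                total_ct[:, sel_cols] += float(n_test)
            else:
                ok = ~bad[test] & ~bad_tr_centers[None, :, :]
                correct_ct[:, sel_cols] += (hit & ok).sum(axis=0)
                total_ct[:, sel_cols] += ok.sum(axis=0)
                if bad_tr_centers.any():
                    _fallback_cells(
                        Xk, yk, k_classes, spec, graph, floor,
                        train, test, bad, bad_tr_centers,
                        w, sel_starts, sel_cols, correct_ct, total_ct,
                        sl_cache,
                    )
    return correct_ct, total_ct


def _fallback_cells(Xk, yk, k_classes, spec, graph, floor, train, test, bad,
                    bad_tr_centers, w, sel_starts, sel_cols, correct_ct,
                    total_ct, sl_cache):
    """CV counts for centers whose training data contain masked cells.

    Reproduces what the reference engine does at these cells: training
    trials with any masked cell in the searchlight are dropped and the
    class statistics refitted.  Centers sharing the same dropped-trial
    pattern are processed together — the statistics are corrected once per
    pattern and all member cells are scored in one vectorized pass.
    """
    cell_list = np.argwhere(bad_tr_centers)           # (m, 2) of (ci, ti)
    bad_tr = bad[train]                               # (n_train, C, Tsel)
    patterns = bad_tr[:, cell_list[:, 0], cell_list[:, 1]].T  # (m, n_train)
    tr_rows = np.flatnonzero(train)
    Xte_all = Xk[test]                                # (nt, C, S)
    yte = yk[test]
    n_te = yte.size
    bad_te = bad[test]
    n_ch, n_s = Xk.shape[1], Xk.shape[2]

    # full-train sufficient statistics, corrected by subtracting dropped rows
    ytr_all = yk[tr_rows]
    cnt0 = np.bincount(ytr_all, minlength=k_classes).astype(float)
    onehot = np.zeros((k_classes, tr_rows.size))
    onehot[ytr_all, np.arange(tr_rows.size)] = 1.0
    flat_tr = Xk[tr_rows].reshape(tr_rows.size, -1)
    s1_0 = onehot @ flat_tr
    s2_0 = onehot @ (flat_tr**2)

    # group identical dropped-trial patterns (void view: fast unique on rows)
    pat_view = np.ascontiguousarray(patterns).view(
        np.dtype((np.void, patterns.shape[1] * patterns.dtype.itemsize))
    ).ravel()
    _, first, inverse = np.unique(pat_view, return_index=True, return_inverse=True)

    for gi, rep_cell in enumerate(first):
        members = cell_list[inverse == gi]
        cis, tis = members[:, 0], members[:, 1]
        drop = patterns[rep_cell]
        ydrop = ytr_all[drop]
        cnt = cnt0 - np.bincount(ydrop, minlength=k_classes)
        if (cnt < 2).any() or (cnt > 0).sum() < 2:
            continue
        s1 = s1_0.copy()
        s2 = s2_0.copy()
        for row, k in zip(np.flatnonzero(drop), ydrop):
            s1[k] -= flat_tr[row]
            s2[k] -= flat_tr[row] ** 2

        # union of searchlight channels over member cells; restrict the
        # sample range and time centers to what the members actually need
        uniq_ci = np.unique(cis)
        union = np.unique(np.concatenate([sl_cache[ci] for ci in uniq_ci]))
        u_pos = {c: i for i, c in enumerate(union)}
        tis_u, tis_inv = np.unique(tis, return_inverse=True)
        s0 = int(sel_starts[tis_u].min())
        s1_end = int(sel_starts[tis_u].max()) + w

        mu = (s1 / cnt[:, None]).reshape(k_classes, n_ch, n_s)[
            :, union, s0:s1_end
        ]
        var = np.maximum(
            (s2 / cnt[:, None]).reshape(k_classes, n_ch, n_s)[
                :, union, s0:s1_end
            ]
            - mu**2,
            floor,
        )
        log_prior = np.log(cnt / cnt.sum())

        x_u = Xte_all[:, union, s0:s1_end]            # (nt, U, S')
        ll = -0.5 * (
            np.log(2.0 * np.pi * var[:, None]) +
            (x_u[None] - mu[:, None]) ** 2 / var[:, None]
        )                                              # (K, nt, U, S')
        wsum = _window_sum(ll, w, sel_starts[tis_u] - s0)  # (K, nt, U, T')

        # member-wise channel aggregation: weight matrix over the union
        weights = np.zeros((len(members), union.size))
        for mi, ci in enumerate(cis):
            weights[mi, [u_pos[c] for c in sl_cache[ci]]] = 1.0
        agg_scores = np.einsum("mu,knut->knmt", weights, wsum)
        sc = agg_scores[:, :, np.arange(len(members)), tis_inv]  # (K, nt, m)
        sc += log_prior[:, None, None]
        pred = sc.argmax(axis=0)                       # (nt, m)
        hit = pred == yte[:, None]
        ok = ~bad_te[:, cis, tis]
        cols = sel_cols[tis]
        np.add.at(correct_ct, (cis, cols), (hit & ok).sum(axis=0))
        np.add.at(total_ct, (cis, cols), ok.sum(axis=0))


def _window_sum(arr: np.ndarray, w: int, starts: np.ndarray) -> np.ndarray:
    """Sum over [start, start+w) along the last axis for each start."""
    cs = np.concatenate(
        [np.zeros(arr.shape[:-1] + (1,)), np.cumsum(arr, axis=-1)], axis=-1
    )
    return cs[..., starts + w] - cs[..., starts]


def _window_any(arr: np.ndarray, w: int, starts: np.ndarray) -> np.ndarray:
    return _window_sum(arr.astype(float), w, starts) > 0


def _map_counts_exact(epochs, y, spec, scheme, graph, centers, defined_t):
    """Per-cell reference engine: loop centers, fit/predict per fold."""
    n_ch = epochs.n_channels
    classes = np.unique(y)
    correct_ct = np.zeros((n_ch, centers.size))
    total_ct = np.zeros((n_ch, centers.size))
    k_classes = classes.size
    y_idx_all = np.searchsorted(classes, y)

    plans = [_repeat_plan(y, scheme, rep) for rep in range(scheme.n_repeats)]
    # shared per-(repeat, fold) variance floors, identical to the fast engine
    floors = {}
    for rep, (kept, folds) in enumerate(plans):
        Xk = epochs.data[kept]
        yk = y_idx_all[kept]
        for f in range(scheme.n_folds):
            floors[rep, f] = _global_var_floor(Xk, yk, folds != f, k_classes)

    for ci in range(n_ch):
        for ti, defined in enumerate(defined_t):
            if not defined:
                continue
            X_sl, kept_sl = searchlight_features(
                epochs, ci, int(centers[ti]), spec, graph
            )
            if X_sl is None:
                continue
            for rep, (kept, folds) in enumerate(plans):
                sl_pos = {tr: i for i, tr in enumerate(kept_sl)}
                in_both = [
                    (i, sl_pos[tr]) for i, tr in enumerate(kept) if tr in sl_pos
                ]
                if not in_both:
                    continue
                rep_rows = np.array([i for i, _ in in_both])
                sl_rows = np.array([j for _, j in in_both])
                X_rep = X_sl[sl_rows]
                y_rep = y[kept][rep_rows]
                f_rep = folds[rep_rows]
                for f in range(scheme.n_folds):
                    tr = f_rep != f
                    te = f_rep == f
                    if te.sum() == 0:
                        continue
                    tr_classes, tr_counts = np.unique(y_rep[tr], return_counts=True)
                    if tr_classes.size < 2 or tr_counts.min() < 2:
                        continue
                    model = fit_gnb(X_rep[tr], y_rep[tr], var_floor=floors[rep, f])
                    pred = predict_gnb(model, X_rep[te])
                    correct_ct[ci, ti] += int((pred == y_rep[te]).sum())
                    total_ct[ci, ti] += int(te.sum())
    return correct_ct, total_ct
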