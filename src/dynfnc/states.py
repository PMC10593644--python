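"""Connectivity-state clustering and state-transition metrics.

Recurring whole-brain connectivity patterns are estimated in two stages:
exemplar windows (local maxima of the across-pair connectivity variance)
are pooled over all subject-sessions and clustered with k-means (city-block
metric by default, k-means++ seeding, many random restarts, best objective
kept); every window of every subject-session is then assigned to its
nearest centroid.  The number of states is chosen by the elbow of the
within- to between-cluster distance ratio over a candidate range of k.

Four summaries describe each subject-session's state sequence: fractional
time per state, mean dwell time (mean consecutive-run length, in windows),
number of transitions, and the row-stochastic transition-probability
matrix.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .containers import (
    ExemplarSet,
    StateMetrics,
    StateModel,
    StateSequence,
    WindowedFNC,
    pair_labels,
)
from .errors import ArgumentError, InsufficientDataError

_UPDATES = {
    "cityblock": lambda pts: np.median(pts, axis=0),
    "euclidean": lambda pts: pts.mean(axis=0),
}


def select_exemplars(wfncs: Iterable[WindowedFNC]) -> ExemplarSet:
    """Pick high-variance windows as clustering exemplars.

    Per subject-session, the variance of the Fisher-z values across pairs is
    computed at every window and windows at *strict* local maxima of that
    series are kept (endpoints never qualify).  If a session has no strict
    local maximum, its single global-maximum window (lowest index on ties)
    is used instead, so every session contributes at least one exemplar.
    """
    vectors: list[np.ndarray] = []
    provenance: list[tuple[str, str, int]] = []
    any_input = False
    for wf in wfncs:
        any_input = True
        if wf.n_windows < 3:
            raise InsufficientDataError(
                f"{wf.subject}/{wf.session}: {wf.n_windows} windows (< 3) for exemplar selection"
            )
        variance = wf.values.var(axis=1)
        interior = np.arange(1, len(variance) - 1)
        is_max = (variance[interior] > variance[interior - 1]) & (
            variance[interior] > variance[interior + 1]
        )
        picks = interior[is_max]
        if picks.size == 0:
            picks = np.array([int(np.argmax(variance))])
        for w in picks:
            vectors.append(wf.values[w])
            provenance.append((wf.subject, wf.session, int(wf.window_starts[w])))
    if not any_input:
        raise ArgumentError("no windowed FNC supplied")
    return ExemplarSet(vectors=np.stack(vectors), provenance=provenance)


def _kmeans_pp_init(
    X: np.ndarray, k: int, metric: str, rng: np.random.Generator
) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = cdist(X, centroids[:1], metric=metric)[:, 0] ** 2
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
        else:
            centroids[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, cdist(X, centroids[j : j + 1], metric=metric)[:, 0] ** 2)
    return centroids


def _kmeans_single(
    X: np.ndarray,
    k: int,
    metric: str,
    rng: np.random.Generator,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    update = _UPDATES[metric]
    centroids = _kmeans_pp_init(X, k, metric, rng)
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        D = cdist(X, centroids, metric=metric)
        new_labels = D.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if members.shape[0] == 0:
                # re-seed an empty cluster at the worst-fit point
                centroids[j] = X[D.min(axis=1).argmax()]
            else:
                centroids[j] = update(members)
    D = cdist(X, centroids, metric=metric)
    labels = D.argmin(axis=1)
    objective = float(D[np.arange(X.shape[0]), labels].sum())
    return centroids, labels, objective


def cluster_exemplars(
    exemplars: ExemplarSet | np.ndarray,
    k: int,
    n_replicates: int = 150,
    metric: str = "cityblock",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """k-means over exemplar vectors; best of ``n_replicates`` restarts.

    Under the default city-block metric the centroid update is the
    coordinate-wise median (the L1 optimum); under Euclidean it is the mean.
    Returns (centroids, labels, best objective, all replicate objectives).
    """
    X = exemplars.vectors if isinstance(exemplars, ExemplarSet) else np.asarray(exemplars)
    if metric not in _UPDATES:
        raise ArgumentError(f"metric must be one of {sorted(_UPDATES)}")
    if k < 1 or k > X.shape[0]:
        raise ArgumentError(f"k={k} outside [1, {X.shape[0]} exemplars]")
    if n_replicates < 1:
        raise ArgumentError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    objectives: list[float] = []
    for _ in range(n_replicates):
        centroids, labels, obj = _kmeans_single(X, k, metric, rng)
        objectives.append(obj)
        if best is None or obj < best[2]:
            best = (centroids, labels, obj)
    assert best is not None
    return best[0], best[1], best[2], objectives


def cluster_ratio(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray, metric: str) -> float:
    """Within- to between-cluster distance ratio used by the elbow criterion:
    mean distance of points to their own centroid over mean pairwise
    inter-centroid distance."""
    D = cdist(X, centroids, metric=metric)
    within = float(D[np.arange(X.shape[0]), labels].mean())
    between = float(pdist(centroids, metric=metric).mean())
    return within / between


def choose_k_elbow(
    exemplars: ExemplarSet | np.ndarray,
    k_range: Sequence[int] = tuple(range(2, 11)),
    n_replicates: int = 150,
    metric: str = "cityblock",
    seed: int = 0,
) -> StateModel:
    """Scan k over ``k_range`` and pick the elbow of the distance ratio.

    The elbow is operationalized as the interior k maximizing the discrete
    second difference of log ratio(k) — the point of sharpest downward bend
    of the ratio curve.  Curvature is measured on the log scale so that the
    large *relative* drop from badly underfit k values (the ratio can halve
    between k=2 and k=3) does not mask the bend at the true state count.
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ArgumentError("k_range must contain at least 3 values for the second difference")
    X = exemplars.vectors if isinstance(exemplars, ExemplarSet) else np.asarray(exemplars)
    curve: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, float]] = {}
    rng = np.random.default_rng(seed)
    for k in ks:
        sub_seed = int(rng.integers(2**31))
        centroids, labels, obj, _ = cluster_exemplars(
            X, k, n_replicates=n_replicates, metric=metric, seed=sub_seed
        )
        curve[k] = cluster_ratio(X, centroids, labels, metric)
        fits[k] = (centroids, obj)
    log_curve = {k: float(np.log(v)) for k, v in curve.items()}
    second_diff = {
        ks[i]: log_curve[ks[i - 1]] - 2.0 * log_curve[ks[i]] + log_curve[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    best_k = max(second_diff, key=lambda k: (second_diff[k], -k))
    centroids, objective = fits[best_k]
    return StateModel(
        k=best_k,
        centroids=centroids,
        metric=metric,
        elbow_curve=curve,
        n_replicates=n_replicates,
        seed=seed,
        objective=objective,
    )


def assign_windows(
    wfncs: Iterable[WindowedFNC], model: StateModel
) -> list[StateSequence]:
    """Map every window to its nearest centroid (ties -> lowest state index)."""
    out = []
    for wf in wfncs:
        if wf.values.shape[1] != model.centroids.shape[1]:
            raise ArgumentError(
                f"{wf.values.shape[1]} pairs in windows but {model.centroids.shape[1]} "
                "in centroids"
            )
        D = cdist(wf.values, model.centroids, metric=model.metric)
        out.append(
            StateSequence(
                subject=wf.subject,
                session=wf.session,
                states=D.argmin(axis=1),
                window_starts=wf.window_starts.copy(),
            )
        )
    return out


def compute_state_metrics(seq: StateSequence | np.ndarray, k: int) -> StateMetrics:
    """Fractional time, mean dwell, transition count, transition matrix.

    Unvisited states have NaN mean dwell; a state with no outgoing step has
    a NaN transition-matrix row.
    """
    states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
    if states.size == 0:
        raise ArgumentError("empty state sequence")
    if k < int(states.max()) + 1:
        raise ArgumentError(f"k={k} smaller than max state index {int(states.max())}")
    n = states.size
    fractional = np.bincount(states, minlength=k) / n
    # run-length encode
    change = np.flatnonzero(np.diff(states) != 0)
    run_ends = np.append(change, n - 1)
    run_starts = np.insert(change + 1, 0, 0)
    run_states = states[run_starts]
    run_lengths = run_ends - run_starts + 1
    mean_dwell = np.full(k, np.nan)
    for s in range(k):
        lens = run_lengths[run_states == s]
        if lens.size:
            mean_dwell[s] = lens.mean()
    n_transitions = int(change.size)
    counts = np.zeros((k, k))
    np.add.at(counts, (states[:-1], states[1:]), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        transition = np.where(row_sums > 0, counts / row_sums, np.nan)
    return StateMetrics(
        fractional_time=fractional,
        mean_dwell=mean_dwell,
        n_transitions=n_transitions,
        transition_matrix=transition,
    )


def state_mean_fnc(
    wfncs: Iterable[WindowedFNC], sequences: Iterable[StateSequence], k: int
) -> pd.DataFrame:
    """Per subject-session and state, mean windowed FNC over that state's
    windows.  Tidy frame (subject, session, state, one column per pair);
    rows exist only for visited states."""
    seq_by_key = {(s.subject, s.session): s for s in sequences}
    rows = []
    labels = None
    for wf in wfncs:
        labels = labels or wf.labels
        seq = seq_by_key[(wf.subject, wf.session)]
        for s in range(k):
            m = seq.states == s
            if m.any():
                rows.append(
                    {"subject": wf.subject, "session": wf.session, "state": s}
                    | dict(zip(pair_labels(wf.labels), wf.values[m].mean(axis=0)))
                )
    return pd.DataFrame(rows)


def metrics_table(sequences: Iterable[StateSequence], k: int) -> pd.DataFrame:
    """Tidy per-subject-session state metrics (long format)."""
    rows = []
    for seq in sequences:
        m = compute_state_metrics(seq, k)
        base = {"subject": seq.subject, "session": seq.session}
        for s in range(k):
            rows.append(base | {"metric": "fractional_time", "state_from": s,
                                "state_to": np.nan, "value": m.fractional_time[s]})
            rows.append(base | {"metric": "mean_dwell", "state_from": s,
                                "state_to": np.nan, "value": m.mean_dwell[s]})
        rows.append(base | {"metric": "n_transitions", "state_from": np.nan,
                            "state_to": np.nan, "value": float(m.n_transitions)})
        for s in range(k):
            for t in range(k):
                rows.append(base | {"metric": "transition_prob", "state_from": s,
                                    "state_to": t, "value": m.transition_matrix[s, t]})
    return pd.DataFrame(rows)
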