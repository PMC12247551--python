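"""Co-activation-pattern (CAP) brain-state estimation.

Discrete brain states are estimated by pooling every participant's
parcel-level BOLD volumes into one feature matrix and clustering the volumes
with the k-means algorithm under correlation distance, ``d(x, y) = 1 -
r(x, y)`` with ``r`` the sample Pearson correlation across parcels.

The clustering exploits the identity ``1 - r(x, y) = ||x~ - y~||^2 / 2``
for vectors standardized to zero mean and unit Euclidean norm: all volumes
are standardized once, Lloyd iterations run on the standardized points, and
centroids are re-standardized after every mean update so that they remain
valid correlation "prototypes".

Per participant, the fractional occupancy (FO) of a state is the proportion
of that participant's retained volumes assigned to the state.  The two
states with the highest cohort-mean FO are the "high-occupancy" states; a
participant's ``fo_high`` is the arithmetic mean of their FO in those two
states (a ``use_sum`` option is exposed but non-default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcelTimeSeries",
    "BrainStateModel",
    "HighOccupancySelection",
    "build_feature_matrix",
    "corr_distance",
    "standardize_rows",
    "kmeans_corr",
    "fractional_occupancy",
    "occupancy_from_sequences",
    "select_high_occupancy",
    "network_profile",
]


@dataclass
class ParcelTimeSeries:
    """One participant's de-confounded BOLD signal, parcels x volumes."""

    participant_id: str
    data: np.ndarray
    parcellation: str = "unspecified"
    tr: float = 2.5

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 1:
            raise ValueError("data must be a 2-D parcels x volumes array, T >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("data must not contain missing/non-finite values")
        self.data = arr

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class BrainStateModel:
    """Fitted CAP clustering: centroids, assignments and metadata.

    ``centroids`` are standardized (zero mean, unit norm per row);
    ``labels`` take values 1..k aligned with the pooled volume index.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    n_restarts: int
    seed: int | None
    n_iter: int
    converged: bool
    restart_inertias: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class HighOccupancySelection:
    """States ranked by cohort-mean FO plus per-participant fo_high."""

    order: np.ndarray  # state labels (1..k), descending cohort-mean FO
    top_two: tuple[int, int]
    mean_fo: pd.Series  # cohort mean FO per state
    median_fo: pd.Series  # cohort median FO per state
    fo_high: pd.Series  # per participant


def build_feature_matrix(
    series: list[ParcelTimeSeries],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pool volumes across participants into one (parcels x sum T_i) matrix.

    Returns the pooled matrix and an index mapping each column to
    ``(participant_id, time)`` in concatenation order.
    """
    if not series:
        raise ValueError("need at least one time series")
    parc = series[0].parcellation
    p = series[0].n_parcels
    for s in series:
        if s.parcellation != parc or s.n_parcels != p:
            raise ValueError("all series must share one parcellation")
    X = np.concatenate([s.data for s in series], axis=1)
    index = pd.DataFrame(
        {
            "participant_id": np.repeat(
                [s.participant_id for s in series], [s.n_volumes for s in series]
            ),
            "time": np.concatenate([np.arange(s.n_volumes) for s in series]),
        }
    )
    return X, index


def corr_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 minus the sample Pearson correlation; range [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("correlation distance undefined for zero-variance vectors")
    return float(1.0 - (xc @ yc) / (nx * ny))


def standardize_rows(points: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm; errors on zero variance."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError(
            "zero-variance volumes (flat across parcels) cannot be clustered "
            "under correlation distance; remove them upstream"
        )
    return centered / norms


def _restandardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0.0:
        raise FloatingPointError("degenerate centroid (zero variance)")
    return v / n


def _lloyd(
    S: np.ndarray, k: int, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """One k-means run on standardized points; returns labels 0-based."""
    n = S.shape[0]
    centroids = S[np.asarray(init)].copy()
    prev_inertia = np.inf
    labels = np.zeros(n, dtype=np.int64)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # distances: 1 - S @ C.T (rows and centroids are unit-norm, zero-mean);
        # argmin returns the first minimum, so equal distances go to the
        # lowest state index.
        dist = 1.0 - S @ centroids.T
        labels = np.argmin(dist, axis=1)
        inertia = float(dist[np.arange(n), labels].sum())

        new_centroids = centroids.copy()
        for j in range(k):
            members = labels == j
            if not members.any():
                # re-seed from the point currently farthest from its centroid
                far = int(np.argmax(dist[np.arange(n), labels]))
                new_centroids[j] = S[far]
                labels[far] = j
            else:
                new_centroids[j] = _restandardize(S[members].mean(axis=0))
        if abs(prev_inertia - inertia) < tol:
            converged = True
            centroids = new_centroids
            break
        prev_inertia = inertia
        centroids = new_centroids
    # final consistent assignment
    dist = 1.0 - S @ centroids.T
    labels = np.argmin(dist, axis=1)
    inertia = float(dist[np.arange(S.shape[0]), labels].sum())
    return labels, centroids, inertia, it, converged


def kmeans_corr(
    points: np.ndarray,
    k: int = 5,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> BrainStateModel:
    """K-means under correlation distance (rows of ``points`` are volumes).

    Lloyd iterations run on row-standardized points; each restart draws k
    distinct volumes uniformly as initial centroids; the best restart by
    total within-cluster correlation distance (inertia) wins.  Deterministic
    given ``seed``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be 2-D (volumes x parcels)")
    n = pts.shape[0]
    if k < 1 or k > n:
        raise ValueError("need at least k points (volumes) with k >= 1")
    S = standardize_rows(pts)
    rng = np.random.default_rng(seed)
    # On tiny inputs every distinct initial centroid subset is tried
    # deterministically, which in practice reaches the global optimum;
    # otherwise each restart draws k distinct volumes uniformly.
    n_subsets = math.comb(n, k) if n <= 64 else None
    if n_subsets is not None and n_subsets <= max(n_restarts, 64):
        inits = [np.asarray(c) for c in itertools.combinations(range(n), k)]
    else:
        inits = [rng.choice(n, size=k, replace=False) for _ in range(n_restarts)]
    best = None
    inertias = []
    for init in inits:
        labels, centroids, inertia, n_iter, conv = _lloyd(
            S, k, init, max_iter, tol
        )
        inertias.append(inertia)
        if best is None or inertia < best[2] - 1e-15:
            best = (labels, centroids, inertia, n_iter, conv)
    labels, centroids, inertia, n_iter, conv = best
    return BrainStateModel(
        k=k,
        centroids=centroids,
        labels=labels.astype(np.int64) + 1,
        inertia=inertia,
        n_restarts=n_restarts,
        seed=seed,
        n_iter=n_iter,
        converged=conv,
        restart_inertias=np.asarray(inertias),
    )


def fractional_occupancy(
    labels: np.ndarray, index: pd.DataFrame, k: int
) -> pd.DataFrame:
    """Per-participant state occupancy proportions.

    ``FO[s, i]`` is the share of participant i's volumes assigned to state
    s; rows sum to 1.  Returns a DataFrame indexed by participant id with
    columns ``fo_1`` .. ``fo_k`` (participants in first-appearance order).
    """
    labels = np.asarray(labels)
    if labels.size != len(index):
        raise ValueError("labels and index length mismatch")
    if labels.size and (labels.min() < 1 or labels.max() > k):
        raise ValueError("labels must lie in 1..k")
    ids = index["participant_id"].to_numpy()
    order = pd.unique(ids)
    counts = pd.crosstab(ids, labels).reindex(
        index=order, columns=range(1, k + 1), fill_value=0
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every participant needs at least one labeled volume")
    fo = counts.div(totals, axis=0)
    fo.columns = [f"fo_{s}" for s in range(1, k + 1)]
    fo.index.name = "participant_id"
    return fo


def occupancy_from_sequences(
    sequences: list[np.ndarray], ids: list[str], k: int
) -> pd.DataFrame:
    """Occupancy table straight from per-participant label sequences."""
    labels = np.concatenate(sequences)
    index = pd.DataFrame(
        {
            "participant_id": np.repeat(ids, [len(s) for s in sequences]),
            "time": np.concatenate([np.arange(len(s)) for s in sequences]),
        }
    )
    return fractional_occupancy(labels, index, k)


def select_high_occupancy(
    occupancy: pd.DataFrame, use_sum: bool = False
) -> HighOccupancySelection:
    """Rank states by cohort-mean FO and compute per-participant fo_high.

    Ties in the mean are broken toward the lower state index.  ``fo_high``
    is the arithmetic mean of the two top states' FOs (their sum if
    ``use_sum``).
    """
    k = occupancy.shape[1]
    if k < 2:
        raise ValueError("need at least two states")
    means = occupancy.mean(axis=0)
    medians = occupancy.median(axis=0)
    # stable sort on negated means keeps the lower state index first on ties
    order0 = np.argsort(-means.to_numpy(), kind="stable")
    order = order0 + 1
    top = (int(order[0]), int(order[1]))
    cols = [occupancy.columns[top[0] - 1], occupancy.columns[top[1] - 1]]
    fo_high = occupancy[cols].sum(axis=1) if use_sum else occupancy[cols].mean(axis=1)
    fo_high.name = "fo_high"
    return HighOccupancySelection(
        order=order.astype(int),
        top_two=top,
        mean_fo=means,
        median_fo=medians,
        fo_high=fo_high,
    )


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


def network_profile(
    centroids: np.ndarray, network_labels
) -> pd.DataFrame:
    """Cosine similarity of centroid activations/suppressions with networks.

    For state s and network N with binary parcel indicator ``1_N``:
    ``sim_pos = cos(max(c_s, 0), 1_N)`` and ``sim_neg = cos(max(-c_s, 0),
    1_N)``.  An all-zero positive (or negative) part yields similarity 0.
    Returns a tidy frame with one row per (state, network).
    """
    centroids = np.asarray(centroids, dtype=float)
    labels = np.asarray(network_labels)
    if labels.size != centroids.shape[1]:
        raise ValueError("every parcel must carry exactly one network label")
    networks = [n for n in pd.unique(labels)]
    rows = []
    for s in range(centroids.shape[0]):
        c = centroids[s]
        pos = np.maximum(c, 0.0)
        neg = np.maximum(-c, 0.0)
        for net in networks:
            ind = (labels == net).astype(float)
            rows.append(
                {
                    "state": s + 1,
                    "network": net,
                    "sim_pos": _cosine(pos, ind),
                    "sim_neg": _cosine(neg, ind),
                }
            )
    return pd.DataFrame(rows)
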