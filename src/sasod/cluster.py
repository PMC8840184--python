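"""Feature extraction, from-scratch k-means with silhouette model selection,
and the cluster-composition SAS screening rule.

The screen clusters the cohort's breath segments (5 per subject) with
Lloyd's k-means over k = 4..7 (Euclidean distance, best of ``n_init``
restarts per k), keeps the k with the highest mean silhouette
coefficient, labels a cluster SAS-indicative when the majority of its
member segments carry the SAS flag, and calls a subject SAS when at least
one of their segments falls in an SAS-indicative cluster.

The Lloyd iteration and the silhouette are written out in full here — they
are the analysis this toolkit exists to make transparent; scikit-learn is
used only for the estimator base classes (and, in the test-suite, as an
independent cross-check).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin

from .segments import BreathSegment
from .types import SasFlag

__all__ = [
    "FeatureScheme",
    "FeatureVector",
    "ClusterModel",
    "extract_features",
    "BreathKMeans",
    "fit_kmeans",
    "silhouette",
    "SasScreener",
    "select_k_and_decide",
]


class FeatureScheme(str, enum.Enum):
    RMS_ENVELOPE_1S = "RMS_ENVELOPE_1S"
    BAND_ENERGY = "BAND_ENERGY"


@dataclass
class FeatureVector:
    values: np.ndarray
    subject_id: str = ""
    segment_index: int = 0
    sas_flag: SasFlag = SasFlag.UNKNOWN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be a finite 1-D vector")


@dataclass
class ClusterModel:
    """A fitted k-means model over one cohort of feature vectors."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    silhouette: float


_BAND_EDGES_HZ = (50.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0)


def extract_features(
    segment: BreathSegment, scheme: FeatureScheme | str = FeatureScheme.RMS_ENVELOPE_1S
) -> FeatureVector:
    """Deterministic fixed-length features from one segment.

    RMS_ENVELOPE_1S: one RMS value per whole second (15 for a 15-s
    segment), z-normalized within the segment.  BAND_ENERGY: log10
    energies in fixed octave bands below Nyquist, z-normalized.

    An all-zero segment is rejected (z-normalization undefined); a
    non-zero segment with constant features returns the all-zero vector.
    """
    scheme = FeatureScheme(scheme)
    x = segment.samples
    if not np.any(x != 0):
        raise ValueError("all-zero segment: features undefined")
    if scheme is FeatureScheme.RMS_ENVELOPE_1S:
        step = int(round(segment.rate))
        n_sec = x.size // step
        if n_sec < 2:
            raise ValueError("segment too short for per-second features")
        v = np.sqrt(np.mean(x[: n_sec * step].reshape(n_sec, step) ** 2, axis=1))
    else:
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, d=1.0 / segment.rate)
        edges = [e for e in _BAND_EDGES_HZ if e < segment.rate / 2] + [segment.rate / 2]
        v = np.array(
            [
                np.log10(spec[(freqs >= lo) & (freqs < hi)].sum() + 1e-30)
                for lo, hi in zip([0.0] + edges[:-1], edges)
            ]
        )
    sd = v.std()
    # constant (to numerical jitter) feature vectors map to zeros rather
    # than amplifying rounding noise through the z-normalization
    if sd > 1e-9 * max(float(np.abs(v).max()), 1e-300):
        v = (v - v.mean()) / sd
    else:
        v = np.zeros_like(v)
    return FeatureVector(
        values=v,
        subject_id=segment.subject_id,
        sas_flag=segment.sas_flag,
    )


# --- k-means (Lloyd), written in full --------------------------------------

def _kpp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding over a lexicographically sorted view of X.

    Sorting first makes the chosen centroids — hence the fitted model —
    invariant under permutations of the input rows for a fixed seed.
    """
    Xs = X[np.lexsort(X.T[::-1])]
    n = Xs.shape[0]
    centers = [Xs[rng.integers(n)]]
    for _ in range(1, k):
        d2 = cdist(Xs, np.asarray(centers), "sqeuclidean").min(axis=1)
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            probs = np.full(n, 1.0 / n)
        else:
            probs = d2 / total
        centers.append(Xs[rng.choice(n, p=probs)])
    return np.asarray(centers, dtype=np.float64)


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float], int]:
    """One Lloyd run.  Returns (labels, centers, inertia, inertia_path, n_iter).

    ``inertia_path`` records the objective after every assignment step; it
    is non-increasing by construction of the algorithm.
    """
    k = centers.shape[0]
    labels = np.full(X.shape[0], -1)
    path: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centers, "sqeuclidean")
        new_labels = d2.argmin(axis=1)
        path.append(float(d2[np.arange(X.shape[0]), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            return labels, centers, path[-1], path, it
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if members.size:
                centers[j] = members.mean(axis=0)
            else:
                # empty cluster: reseed from the point farthest from its centroid
                far = int(d2[np.arange(X.shape[0]), labels].argmax())
                centers[j] = X[far]
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    path.append(float(d2[np.arange(X.shape[0]), labels].sum()))
    return labels, centers, path[-1], path, max_iter


class BreathKMeans(ClusterMixin, BaseEstimator):
    """Euclidean k-means (Lloyd), best of ``n_init`` seeded restarts.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k (>= 2).
    n_init : int
        Restarts; the model with the lowest inertia is kept.
    max_iter : int
        Lloyd iteration cap per restart.
    random_state : int
        Seed for all restarts.

    Attributes
    ----------
    cluster_centers_ : (k, d) array
    labels_ : (n,) assignment per input row
    inertia_ : float, sum of squared distances to assigned centroids
    inertia_path_ : list of float, objective per iteration of the winning
        restart (non-increasing)
    n_iter_ : iterations used by the winning restart
    """

    def __init__(self, n_clusters: int = 6, n_init: int = 10,
                 max_iter: int = 300, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        k = self.n_clusters
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if X.shape[0] <= k:
            raise ValueError(f"need more than {k} samples to fit k={k}")
        if np.unique(X, axis=0).shape[0] < k:
            raise ValueError(
                f"fewer than k={k} distinct points: clustering degenerate"
            )
        ss = np.random.SeedSequence(self.random_state)
        best = None
        for child in ss.spawn(self.n_init):
            rng = np.random.default_rng(child)
            centers = _kpp_init(X, k, rng)
            labels, centers, inertia, path, n_iter = _lloyd(
                X, centers.copy(), self.max_iter
            )
            if len(np.unique(labels)) < k:
                continue
            if best is None or inertia < best[2]:
                best = (labels, centers, inertia, path, n_iter)
        if best is None:
            raise ValueError("no restart produced k non-empty clusters")
        self.labels_, self.cluster_centers_, self.inertia_, self.inertia_path_, self.n_iter_ = best
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        return cdist(X, self.cluster_centers_, "sqeuclidean").argmin(axis=1)


def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient, O(n^2) pairwise distances.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the other members of i's cluster and b(i) the smallest mean distance
    to another cluster.  Singleton-cluster points contribute 0, as do
    points with a = b = 0.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    s = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(masks[c].sum()) for c in uniq}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue
        a = D[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(D[i, masks[o]].mean() for o in uniq if o != c)
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return float(s.mean())


def fit_kmeans(
    features: list[FeatureVector] | np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """Functional wrapper: fit k-means and score its silhouette."""
    X = _stack(features)
    est = BreathKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return ClusterModel(
        k=k,
        centroids=est.cluster_centers_,
        assignments=est.labels_,
        inertia=est.inertia_,
        silhouette=silhouette(X, est.labels_),
    )


def _stack(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=np.float64)
    X = np.asarray([f.values for f in features], dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("all feature vectors must share one length")
    return X


# --- SAS screening rule ----------------------------------------------------

class SasScreener(ClassifierMixin, BaseEstimator):
    """Cluster-composition SAS screen.

    ``fit(X, y, groups=...)`` clusters the labeled reference cohort for
    each k in ``k_range``, keeps the maximum-silhouette model (ties
    broken toward smaller k), labels each cluster SAS-indicative iff the
    majority of its member segments carry the SAS flag, and calls a
    subject SAS iff at least one of their segments falls in an
    SAS-indicative cluster.

    With ``y=None`` only the clustering is fitted; the decision rule is
    unavailable and per-subject calls are not produced.

    Attributes
    ----------
    k_ : selected number of clusters
    model_ : ClusterModel for the selected k
    silhouette_by_k_ : dict k -> mean silhouette
    indicative_clusters_ : sorted list of SAS-indicative cluster indices
    cluster_table_ : dict k-cluster index -> {"sas": count, "non_sas": count}
    subject_calls_ : dict subject_id -> bool (SAS call), in first-seen order
    """

    def __init__(self, k_range: tuple[int, ...] = (4, 5, 6, 7),
                 n_init: int = 10, random_state: int = 0):
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None, groups=None):
        X = _stack(X)
        models = {}
        sils = {}
        for k in self.k_range:
            m = fit_kmeans(X, k, seed=self.random_state, n_init=self.n_init)
            models[k] = m
            sils[k] = m.silhouette
        # max silhouette, ties toward smaller k (iteration order is ascending)
        best_k = min(sorted(models), key=lambda k: (-sils[k], k))
        self.k_ = best_k
        self.model_ = models[best_k]
        self.silhouette_by_k_ = sils
        if y is None:
            self.indicative_clusters_ = None
            self.subject_calls_ = None
            self.cluster_table_ = None
            return self
        y = np.asarray(y, dtype=bool)
        if y.shape[0] != X.shape[0]:
            raise ValueError("y must provide one SAS flag per segment")
        assign = self.model_.assignments
        table = {}
        indicative = []
        for c in range(best_k):
            in_c = assign == c
            n_sas = int(y[in_c].sum())
            n_non = int(in_c.sum() - n_sas)
            table[c] = {"sas": n_sas, "non_sas": n_non}
            if n_sas > n_non:
                indicative.append(c)
        self.cluster_table_ = table
        self.indicative_clusters_ = indicative
        if groups is not None:
            self.subject_calls_ = self._calls(assign, groups)
        else:
            self.subject_calls_ = None
        return self

    def _calls(self, assign: np.ndarray, groups) -> dict[str, bool]:
        groups = list(groups)
        if len(groups) != assign.shape[0]:
            raise ValueError("groups must provide one subject id per segment")
        counts = {g: groups.count(g) for g in dict.fromkeys(groups)}
        if len(set(counts.values())) > 1:
            raise ValueError("every subject must contribute the same number of segments")
        ind = set(self.indicative_clusters_)
        calls: dict[str, bool] = {}
        for g, c in zip(groups, assign):
            calls[g] = calls.get(g, False) or (int(c) in ind)
        return calls

    def predict(self, X, groups=None):
        """Per-segment (or, with ``groups``, per-subject) SAS calls."""
        if self.indicative_clusters_ is None:
            raise ValueError("decision rule unavailable: fitted without labels")
        X = _stack(X)
        assign = cdist(X, self.model_.centroids, "sqeuclidean").argmin(axis=1)
        seg_calls = np.isin(assign, list(self.indicative_clusters_))
        if groups is None:
            return seg_calls
        calls: dict[str, bool] = {}
        for g, c in zip(groups, seg_calls):
            calls[g] = calls.get(g, False) or bool(c)
        return calls


def select_k_and_decide(
    features: list[FeatureVector] | np.ndarray,
    y=None,
    groups=None,
    k_range: tuple[int, ...] = (4, 5, 6, 7),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[ClusterModel, dict[str, bool] | None, dict | None]:
    """Functional wrapper over :class:`SasScreener`.

    When ``features`` is a list of labeled FeatureVectors, ``y`` and
    ``groups`` default to the vectors' flags and subject ids.  Returns
    (best model, per-subject calls or None, cluster composition table).
    """
    if not isinstance(features, np.ndarray) and y is None:
        flags = [f.sas_flag for f in features]
        if all(fl is not SasFlag.UNKNOWN for fl in flags):
            y = [fl is SasFlag.SAS for fl in flags]
            groups = [f.subject_id for f in features]
    scr = SasScreener(k_range=k_range, n_init=n_init, random_state=seed)
    scr.fit(_stack(features), y=y, groups=groups)
    return scr.model_, scr.subject_calls_, scr.cluster_table_
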