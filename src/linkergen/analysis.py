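"""Post-hoc analysis of generation runs: reward trends, top-k selection,
similarity reporting, and k-medoids diversity clustering of fingerprints.

Clustering is PAM-style alternation (assign points to the nearest medoid,
then move each medoid to the cluster member minimizing within-cluster cost)
on the Jaccard/Tanimoto distance 1 − similarity, with k-medoids++ greedy
seeding. The total cost is non-increasing across iterations and the result is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .chem import BIT_FP_2048, FingerprintSpec, canonical_smiles, morgan_fingerprint, tanimoto
from .errors import ConfigError
from .generator import GenerationLog


def moving_average(series, window: int) -> np.ndarray:
    """Trailing moving average; the first window−1 points average the
    available prefix (so the output has the same length as the input)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - window, 0)
    return (csum[idx] - csum[lo]) / (idx - lo)


def top_k_by_reward(log: GenerationLog, k: int) -> pd.DataFrame:
    """The k highest-reward unique linkers from a generation log.

    Uniqueness is by canonical SMILES (unparseable strings dedup by their raw
    spelling); ties in reward are broken by earlier generation index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    first: dict[str, int] = {}
    rows = []
    for e in log.entries:
        try:
            key = canonical_smiles(e.smiles, lenient=True)
        except Exception:
            key = e.smiles
        if key in first:
            continue
        first[key] = e.index
        rows.append((e.index, e.smiles, key, e.reward, e.predicted_mean, e.passed))
    rows.sort(key=lambda r: (-r[3], r[0]))
    out = pd.DataFrame(
        rows[:k],
        columns=["index", "smiles", "canonical", "reward", "predicted_mean", "passed"],
    )
    return out


def tanimoto_similarity(
    smiles_a: str, smiles_b: str, spec: FingerprintSpec = BIT_FP_2048
) -> float:
    """Tanimoto similarity of two molecules under a fingerprint spec."""
    return tanimoto(morgan_fingerprint(smiles_a, spec), morgan_fingerprint(smiles_b, spec))


def similarity_report(
    candidates: list[str],
    reference_smiles: list[str],
    spec: FingerprintSpec = BIT_FP_2048,
) -> pd.DataFrame:
    """Per-candidate maximum similarity to a reference set, with the nearest
    reference molecule."""
    if not reference_smiles:
        raise ConfigError("similarity report requires a non-empty reference set")
    ref_fps = [morgan_fingerprint(s, spec) for s in reference_smiles]
    rows = []
    for cand in candidates:
        fp = morgan_fingerprint(cand, spec)
        sims = [tanimoto(fp, r) for r in ref_fps]
        best = int(np.argmax(sims))
        rows.append((cand, float(sims[best]), reference_smiles[best]))
    return pd.DataFrame(rows, columns=["candidate", "max_similarity", "nearest_reference"])


# ---------------------------------------------------------------------------
# k-medoids
# ---------------------------------------------------------------------------


def pairwise_jaccard_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 − Tanimoto on fingerprint rows (counts or bits)."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    D = np.empty((n, n))
    for i in range(n):
        mins = np.minimum(X, X[i]).sum(axis=1)
        maxs = np.maximum(X, X[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(maxs > 0, mins / maxs, 0.0)
        D[i] = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return D


class KMedoids(BaseEstimator, ClusterMixin):
    """PAM-style k-medoids on fingerprint vectors.

    Parameters
    ----------
    n_clusters : number of medoids.
    metric : "jaccard" (1 − Tanimoto, default — handles bit and count
        fingerprints) or "euclidean".
    max_iter : cap on assign/update alternations.
    random_state : seeds the k-medoids++ greedy initialization.

    Fitted attributes: ``medoid_indices_``, ``labels_``, ``inertia_`` (total
    cost), ``cost_history_`` (non-increasing), ``n_iter_``.
    """

    def __init__(
        self,
        n_clusters: int = 10,
        metric: str = "jaccard",
        max_iter: int = 100,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.metric = metric
        self.max_iter = max_iter
        self.random_state = random_state

    def _distance_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.metric == "jaccard":
            return pairwise_jaccard_distance(X)
        if self.metric == "euclidean":
            from scipy.spatial.distance import squareform, pdist

            return squareform(pdist(np.asarray(X, dtype=float)))
        raise ConfigError(f"unknown metric {self.metric!r}")

    def _init_medoids(self, D: np.ndarray, rng: np.random.Generator) -> list[int]:
        # k-medoids++ greedy seeding: first medoid minimizes total distance,
        # each next one maximizes its distance to the chosen set (ties by index)
        n = D.shape[0]
        medoids = [int(np.argmin(D.sum(axis=1)))]
        while len(medoids) < self.n_clusters:
            dmin = D[:, medoids].min(axis=1)
            dmin[medoids] = -1.0
            nxt = int(np.argmax(dmin))
            if dmin[nxt] <= 0:
                # duplicate points: fall back to the first unused index
                unused = [i for i in range(n) if i not in medoids]
                nxt = unused[0]
            medoids.append(nxt)
        return medoids

    def fit(self, X, y=None):
        X = np.asarray(X)
        n = X.shape[0]
        if self.n_clusters > n:
            raise ConfigError(
                f"n_clusters={self.n_clusters} exceeds number of samples {n}"
            )
        rng = np.random.default_rng(self.random_state)
        D = self._distance_matrix(X)
        medoids = self._init_medoids(D, rng)

        self.cost_history_ = []
        labels = np.argmin(D[:, medoids], axis=1)
        for it in range(self.max_iter):
            cost = float(D[np.arange(n), [medoids[l] for l in labels]].sum())
            self.cost_history_.append(cost)
            new_medoids = list(medoids)
            for c in range(self.n_clusters):
                members = np.where(labels == c)[0]
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = int(members[int(np.argmin(within))])
            new_labels = np.argmin(D[:, new_medoids], axis=1)
            if new_medoids == medoids and np.array_equal(new_labels, labels):
                break
            medoids, labels = new_medoids, new_labels

        # swap refinement: steepest-descent single-medoid swaps until the
        # assignment is a local optimum (no medoid/non-medoid exchange lowers
        # the total cost)
        for _ in range(self.max_iter):
            cost = float(D[np.arange(n), [medoids[l] for l in labels]].sum())
            best_cost, best_swap = cost, None
            med_arr = np.array(medoids)
            for c in range(self.n_clusters):
                others = np.delete(med_arr, c)
                d_without = (
                    D[:, others].min(axis=1) if others.size else np.full(n, np.inf)
                )
                for o in range(n):
                    if o in medoids:
                        continue
                    swap_cost = float(np.minimum(d_without, D[:, o]).sum())
                    if swap_cost < best_cost - 1e-12:
                        best_cost, best_swap = swap_cost, (c, o)
            if best_swap is None:
                break
            medoids[best_swap[0]] = best_swap[1]
            labels = np.argmin(D[:, medoids], axis=1)
            self.cost_history_.append(best_cost)

        # medoids always belong to their own cluster
        for c, m in enumerate(medoids):
            labels[m] = c
        self.medoid_indices_ = np.array(medoids)
        self.labels_ = labels
        self.inertia_ = float(D[np.arange(n), self.medoid_indices_[labels]].sum())
        self.cost_history_.append(self.inertia_)
        self.n_iter_ = len(self.cost_history_) - 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterAssignment:
    """Result of a k-medoids run: medoid indices, per-item labels, total cost."""

    medoid_indices: np.ndarray
    labels: np.ndarray
    total_cost: float


def kmedoids_cluster(
    fingerprints, k: int, seed: int = 0, metric: str = "jaccard"
) -> ClusterAssignment:
    """Cluster fingerprint vectors into k groups (thin wrapper over KMedoids)."""
    X = np.asarray(fingerprints)
    km = KMedoids(n_clusters=k, metric=metric, random_state=seed).fit(X)
    return ClusterAssignment(km.medoid_indices_, km.labels_, km.inertia_)
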