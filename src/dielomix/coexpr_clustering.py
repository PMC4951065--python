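"""Consensus co-expression clustering of the joint mRNA+protein matrix.

Rows of each data type are z-scored independently and concatenated
column-wise; the consensus matrix is built from repeated PAM (k-medoids,
Euclidean) runs on gene subsamples, final labels come from average-linkage
hierarchical clustering of (1 - consensus), and k is chosen by the
consensus-CDF delta-area heuristic unless fixed. Cluster/pathway enrichment
uses the hypergeometric upper tail with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import pairwise_distances

from dielomix.expression_compare import _zscore_rows


def build_joint_matrix(mrna, protein) -> pd.DataFrame:
    """Row-z-score each data type independently, then concatenate columns."""
    m = mrna.timepoint_means() if hasattr(mrna, "timepoint_means") else mrna
    p = protein.timepoint_means() if hasattr(protein, "timepoint_means") else protein
    genes = m.index.intersection(p.index)
    m, p = m.loc[genes], p.loc[genes]
    mz, m_const = _zscore_rows(m)
    pz, p_const = _zscore_rows(p)
    if (m_const | p_const).any():
        warnings.warn(f"{int((m_const | p_const).sum())} constant rows flagged")
    mz.columns = [f"mrna_{c}" for c in m.columns]
    pz.columns = [f"prot_{c}" for c in p.columns]
    return pd.concat([mz, pz], axis=1)


class PamKMedoids(ClusterMixin, BaseEstimator):
    """Partitioning Around Medoids with deterministic BUILD + SWAP.

    Euclidean distance by default; ties in the greedy BUILD step and in SWAP
    are broken by the lowest point index, so a given input always yields the
    same medoids.
    """

    def __init__(self, n_clusters: int = 2, metric: str = "euclidean", max_iter: int = 100):
        self.n_clusters = n_clusters
        self.metric = metric
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} outside [1, {n}]")
        D = pairwise_distances(X, metric=self.metric)
        medoids: list[int] = []
        # BUILD: greedy, lowest index wins ties
        costs = D.sum(axis=1)
        medoids.append(int(np.argmin(costs)))
        while len(medoids) < k:
            current = D[:, medoids].min(axis=1)
            gains = np.maximum(current[None, :] - D, 0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
        medoids_arr = np.array(sorted(medoids))
        # SWAP: best-improvement passes
        for _ in range(self.max_iter):
            dist_to_med = D[:, medoids_arr]
            order = np.argsort(dist_to_med, axis=1)
            d1 = dist_to_med[np.arange(n), order[:, 0]]
            best_cost = d1.sum()
            improved = False
            best_swap = None
            for mi in range(len(medoids_arr)):
                nearest_is_mi = order[:, 0] == mi
                if len(medoids_arr) > 1:
                    d2 = dist_to_med[np.arange(n), order[:, 1]]
                else:
                    d2 = np.full(n, np.inf)
                base = np.where(nearest_is_mi, d2, d1)
                cand = np.minimum(base[None, :], D)  # candidate h x points
                costs_h = cand.sum(axis=1)
                costs_h[medoids_arr] = np.inf
                h = int(np.argmin(costs_h))
                if costs_h[h] < best_cost - 1e-12:
                    if best_swap is None or costs_h[h] < best_swap[0] - 1e-12:
                        best_swap = (costs_h[h], mi, h)
                        improved = True
            if not improved:
                break
            _, mi, h = best_swap
            medoids_arr[mi] = h
            medoids_arr = np.array(sorted(medoids_arr))
        self.medoid_indices_ = medoids_arr
        self.labels_ = np.argmin(D[:, medoids_arr], axis=1)
        self.inertia_ = float(D[np.arange(n), medoids_arr[self.labels_]].sum())
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _consensus_cdf_area(consensus: np.ndarray) -> float:
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    grid = np.linspace(0, 1, 101)
    cdf = np.searchsorted(vals, grid, side="right") / len(vals)
    return float(np.trapezoid(cdf, grid))


@dataclass
class ConsensusClusteringResult:
    consensus: dict[int, pd.DataFrame]       # k -> gene x gene consensus
    labels: pd.Series                        # final labels at chosen k
    chosen_k: int
    k_trace: pd.DataFrame                    # k, cdf_area, delta_area
    within_cluster_correlation: pd.Series    # cluster -> mean pairwise Pearson


class ConsensusCluster(ClusterMixin, BaseEstimator):
    """Subsampled-PAM consensus clustering with CDF delta-area k selection.

    consensus(i, j) = (# subsamples where i, j co-cluster) / (# subsamples
    containing both); pairs never co-sampled score 0 and the diagonal is 1.
    """

    def __init__(
        self,
        k_range=(2, 3, 4, 5),
        n_iter: int = 100,
        subsample: float = 0.8,
        fixed_k: int | None = None,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.n_iter = n_iter
        self.subsample = subsample
        self.fixed_k = fixed_k
        self.random_state = random_state

    def fit(self, X, y=None):
        values = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(values))
        n = len(values)
        ks = sorted(set(int(k) for k in self.k_range))
        if min(ks) < 2 or max(ks) > n - 1:
            raise ValueError(f"k_range {ks} outside [2, {n - 1}]")
        if n < max(ks) * 3:
            raise ValueError("need at least 3 genes per candidate cluster")
        rng = np.random.default_rng(self.random_state)
        m = max(2, int(round(self.subsample * n)))
        subsamples = [
            np.sort(rng.choice(n, size=m, replace=False)) for _ in range(self.n_iter)
        ]
        self.consensus_ = {}
        areas = []
        for k in ks:
            together = np.zeros((n, n))
            cosampled = np.zeros((n, n))
            for idx in subsamples:
                labels = PamKMedoids(n_clusters=k).fit_predict(values[idx])
                onehot = np.zeros((len(idx), k))
                onehot[np.arange(len(idx)), labels] = 1.0
                co = onehot @ onehot.T
                together[np.ix_(idx, idx)] += co
                cosampled[np.ix_(idx, idx)] += 1.0
            with np.errstate(invalid="ignore", divide="ignore"):
                consensus = np.where(cosampled > 0, together / cosampled, 0.0)
            np.fill_diagonal(consensus, 1.0)
            consensus = 0.5 * (consensus + consensus.T)
            self.consensus_[k] = pd.DataFrame(consensus, index=index, columns=index)
            areas.append(_consensus_cdf_area(consensus))
        deltas = [
            areas[0] if i == 0 else (areas[i] - areas[i - 1]) / areas[i - 1]
            for i in range(len(ks))
        ]
        self.k_trace_ = pd.DataFrame({"k": ks, "cdf_area": areas, "delta_area": deltas})
        if self.fixed_k is not None:
            chosen = int(self.fixed_k)
            if chosen not in self.consensus_:
                raise ValueError(f"fixed_k={chosen} not in k_range")
        else:
            chosen = ks[int(np.argmax(deltas))]
        self.chosen_k_ = chosen
        dist = 1.0 - self.consensus_[chosen].to_numpy()
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(Z, t=chosen, criterion="maxclust")
        self.labels_ = np.asarray(raw) - 1
        self.labels_series_ = pd.Series(self.labels_, index=index, name="cluster")

        # per-cluster mean within-cluster pairwise Pearson correlation
        corr = np.corrcoef(values)
        within = {}
        for c in np.unique(self.labels_):
            members = np.where(self.labels_ == c)[0]
            if len(members) < 2:
                within[c] = float("nan")
                continue
            block = corr[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            within[c] = float(block[iu].mean())
        self.within_cluster_correlation_ = pd.Series(within, name="mean_pairwise_r")
        return self

    def result(self) -> ConsensusClusteringResult:
        return ConsensusClusteringResult(
            consensus=self.consensus_,
            labels=self.labels_series_,
            chosen_k=self.chosen_k_,
            k_trace=self.k_trace_,
            within_cluster_correlation=self.within_cluster_correlation_,
        )


def consensus_cluster(
    joint: pd.DataFrame,
    k_range=(2, 3, 4, 5),
    n_iter: int = 100,
    subsample: float = 0.8,
    fixed_k: int | None = None,
    seed: int | None = None,
) -> ConsensusClusteringResult:
    """Functional wrapper over :class:`ConsensusCluster`."""
    est = ConsensusCluster(
        k_range=k_range,
        n_iter=n_iter,
        subsample=subsample,
        fixed_k=fixed_k,
        random_state=seed,
    )
    return est.fit(joint).result()


def cluster_enrichment(
    labels: pd.Series,
    sets: dict[str, list[str]],
    universe=None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each cluster in each gene set.

    p = P(overlap >= observed) under sampling |cluster| genes from the
    universe containing |set| successes; Bonferroni over all performed tests.
    """
    if universe is None:
        universe = list(labels.index)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    labels = labels[labels.index.isin(universe)]
    rows = []
    for set_id, genes in sets.items():
        members = set(genes) & universe
        if not members:
            continue
        for cluster in sorted(labels.unique()):
            cluster_genes = set(labels.index[labels == cluster])
            overlap = len(cluster_genes & members)
            p = float(
                hypergeom.sf(
                    overlap - 1, len(universe), len(members), len(cluster_genes)
                )
            )
            rows.append(
                {
                    "cluster": cluster,
                    "set_id": set_id,
                    "overlap": overlap,
                    "cluster_size": len(cluster_genes),
                    "set_size": len(members),
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out
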