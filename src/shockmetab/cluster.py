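"""UMAP embedding + DBSCAN density clustering of the QC'd metabolite matrix.

The pipeline projects the per-metabolite z-score matrix to two dimensions
with UMAP (n_neighbors=15, min_dist=0.1, Euclidean — the classic defaults,
pinned explicitly because "default" differs across implementations) and
clusters the embedding with DBSCAN at eps=0.7, minPts=5. The eps choice can
be checked against a k-distance curve (k = minPts − 1) whose knee is located
by the maximum-distance-to-chord rule; the configured eps always wins over
the suggestion, mirroring an analyst's manual pick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .io import CohortTables, RunConfig
from .preprocess import QCResult, qc_filter

#: label given to patients DBSCAN leaves unassigned
NOISE = -1


@dataclass
class EmbeddingParams:
    n_components: int = 2
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    rng_seed: int = 0

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "EmbeddingParams":
        return cls(n_neighbors=cfg.n_neighbors, min_dist=cfg.min_dist,
                   metric=cfg.metric, rng_seed=cfg.rng_seed)


def embed(z_matrix: pd.DataFrame, params: EmbeddingParams | None = None) -> pd.DataFrame:
    """2-D UMAP embedding, deterministic given ``params.rng_seed``.

    Rows are canonical-sorted by patient id before fitting so the result is
    invariant to input row order.
    """
    from umap import UMAP  # deferred: numba JIT import is slow

    params = params or EmbeddingParams()
    z = z_matrix.sort_index()
    n = len(z)
    if n <= params.n_neighbors:
        raise ValueError(
            f"need more patients ({n}) than n_neighbors ({params.n_neighbors}); "
            "reduce n_neighbors")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        coords = UMAP(
            n_components=params.n_components,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            metric=params.metric,
            random_state=params.rng_seed,
        ).fit_transform(z.to_numpy(dtype=np.float64))
    return pd.DataFrame(np.asarray(coords, dtype=np.float64),
                        index=z.index, columns=["umap1", "umap2"])


def k_distance(embedding: pd.DataFrame | np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Sorted k-th-nearest-neighbor distances and a knee-based eps suggestion.

    Returns the ascending curve of each point's distance to its k-th nearest
    neighbor (self excluded) and the curve value at the point of maximum
    perpendicular distance to the chord joining the curve's endpoints.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    X = np.asarray(embedding, dtype=float)
    if k >= len(X):
        raise ValueError(f"k={k} requires more than {k} points")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    curve = np.sort(dist[:, k])
    # distance of each curve point to the chord from first to last point
    n = len(curve)
    x = np.arange(n, dtype=float)
    dx, dy = x[-1] - x[0], curve[-1] - curve[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return curve, float(curve[0])
    d = np.abs(dy * (x - x[0]) - dx * (curve - curve[0])) / norm
    return curve, float(curve[int(np.argmax(d))])


def dbscan_cluster(embedding: pd.DataFrame, eps: float, min_pts: int) -> pd.Series:
    """DBSCAN labels with canonical ids.

    A core point has >= ``min_pts`` neighbors within ``eps`` counting itself.
    Clusters are renumbered 1..K by decreasing size (ties broken by the
    smallest contained patient id); unassigned points get :data:`NOISE`.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    raw = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(
        embedding.to_numpy(dtype=float))
    return _canonical_labels(pd.Series(raw, index=embedding.index))


def _canonical_labels(raw: pd.Series) -> pd.Series:
    """Renumber cluster ids 1..K by decreasing size, smallest member id on ties."""
    out = pd.Series(NOISE, index=raw.index, dtype=int)
    ids = [c for c in raw.unique() if c != -1]
    keyed = sorted(
        ids, key=lambda c: (-int((raw == c).sum()), min(raw.index[raw == c])))
    for new, old in enumerate(keyed, start=1):
        out[raw == old] = new
    return out


@dataclass
class ClusterResults:
    """Fitted stratification: embedding, labels and full provenance."""

    qc: QCResult
    embedding: pd.DataFrame
    labels: pd.Series
    eps: float
    min_pts: int
    k_distance_curve: np.ndarray
    eps_suggested: float
    params: EmbeddingParams
    config: RunConfig
    qc_groups: pd.Series | None = None

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(c for c in self.labels.unique() if c != NOISE)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def cluster_sizes(self) -> pd.Series:
        return self.labels[self.labels != NOISE].value_counts().sort_index()

    def members(self, cluster_id: int) -> set:
        return set(self.labels.index[self.labels == cluster_id])

    def bootstrap_stability(self, n_boot: int | None = None, seed: int | None = None):
        from .stability import bootstrap_stability

        return bootstrap_stability(self, n_boot=n_boot, seed=seed)

    def sensitivity_analysis(self, tables: CohortTables):
        from .stability import sensitivity_recluster

        return sensitivity_recluster(tables, self.config, reference=self)

    def summary(self) -> str:
        sizes = self.cluster_sizes()
        noise = int((self.labels == NOISE).sum())
        lines = [
            "Metabolic phenotype clustering (UMAP + DBSCAN)",
            "=" * 47,
            f"patients:             {len(self.labels)}",
            f"metabolites retained: {len(self.qc.retained)} "
            f"(excluded {len({m for m, _ in self.qc.excluded})})",
            f"eps / min_pts:        {self.eps} / {self.min_pts} "
            f"(k-distance suggestion: {self.eps_suggested:.3f})",
            f"clusters found:       {self.n_clusters}",
        ]
        for cid, size in sizes.items():
            lines.append(f"  cluster {cid}: n = {size}")
        lines.append(f"  noise:     n = {noise}")
        return "\n".join(lines)

    def plot_embedding(self, ax=None):
        """Scatter of the 2-D embedding colored by cluster label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for cid in self.cluster_ids + [NOISE]:
            sel = self.labels == cid
            if not sel.any():
                continue
            name = "noise" if cid == NOISE else f"cluster {cid}"
            ax.scatter(self.embedding.loc[sel, "umap1"],
                       self.embedding.loc[sel, "umap2"], label=name, s=25)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        ax.legend(frameon=False)
        return ax


class MetabolicClusterModel:
    """Unsupervised stratification model over a metabolomics cohort.

    Composes the QC filter, imputation/log/z-score preparation, UMAP
    embedding and DBSCAN clustering; ``fit`` returns a
    :class:`ClusterResults` carrying labels plus full provenance.

    Parameters
    ----------
    tables : CohortTables
    config : RunConfig, optional
    qc_groups : str or Series, optional
        Patient grouping for the QC missingness rule. The default,
        ``"admission_cause"``, uses admission strata, avoiding the
        circularity of grouping by clusters that do not exist yet; a second
        pass with discovered clusters can be requested after fitting.
    """

    def __init__(self, tables: CohortTables, config: RunConfig | None = None,
                 qc_groups: str | pd.Series | None = "admission_cause"):
        self.tables = tables
        self.config = config or RunConfig()
        if isinstance(qc_groups, str):
            qc_groups = tables.clinical[qc_groups]
        self.qc_groups = qc_groups

    def fit(self, seed: int | None = None) -> ClusterResults:
        cfg = self.config
        if seed is not None:
            import dataclasses

            cfg = dataclasses.replace(cfg, rng_seed=seed)
        qc = qc_filter(self.tables, groups=self.qc_groups, cfg=cfg)
        matrix = qc.z_matrix if cfg.scale else qc.matrix
        params = EmbeddingParams.from_config(cfg)
        embedding = embed(matrix, params)
        curve, eps_suggested = k_distance(embedding, k=cfg.min_pts - 1)
        labels = dbscan_cluster(embedding, eps=cfg.eps, min_pts=cfg.min_pts)
        return ClusterResults(
            qc=qc, embedding=embedding, labels=labels,
            eps=cfg.eps, min_pts=cfg.min_pts,
            k_distance_curve=curve, eps_suggested=eps_suggested,
            params=params, config=cfg, qc_groups=self.qc_groups,
        )


def run_clustering(tables: CohortTables, cfg: RunConfig | None = None,
                   qc_groups: str | pd.Series | None = "admission_cause") -> ClusterResults:
    """Functional entry point: QC → impute/log/z → UMAP → DBSCAN."""
    return MetabolicClusterModel(tables, cfg, qc_groups=qc_groups).fit()
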