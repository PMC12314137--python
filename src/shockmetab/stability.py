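"""Cluster robustness: bootstrap Jaccard stability and outlier sensitivity.

Stability follows the clusterwise-bootstrap convention: patients are
resampled with replacement, duplicates collapsed (duplicated points inflate
local density and distort DBSCAN), the embedding + clustering re-run with
fixed eps/minPts, and each original cluster scored by its best Jaccard match
among the bootstrap clusters over the patients common to both sets. Noise
points belong to no cluster and can only lower the score.

The sensitivity analysis removes patients whose maximum absolute z-score
over all metabolites exceeds a threshold (default 5), re-runs the whole
pipeline on the reduced cohort, and cross-tabulates original versus reduced
assignments — the table behind an alluvial plot.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import NOISE, ClusterResults, EmbeddingParams, dbscan_cluster, embed
from .io import CohortTables, RunConfig

_SEED_MOD = 2**31


def jaccard_index(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(a | b)


@dataclass
class StabilityReport:
    per_iteration_jaccard: np.ndarray
    per_cluster_mean_jaccard: dict[int, float]
    mean_jaccard: float
    n_boot: int
    seeds: list[int]

    def summary(self) -> str:
        lines = [
            f"Bootstrap cluster stability ({self.n_boot} iterations)",
            f"mean Jaccard index: {self.mean_jaccard:.3f}",
        ]
        for cid, j in sorted(self.per_cluster_mean_jaccard.items()):
            lines.append(f"  cluster {cid}: {j:.3f}")
        return "\n".join(lines)


def score_iteration(
    orig_clusters: dict[int, set],
    boot_clusters: list[set],
    common: set,
) -> dict[int, float]:
    """Clusterwise bootstrap scores for one iteration.

    Each original cluster is restricted to the patients in ``common`` (the
    unique bootstrap draw); clusters left without members are skipped. The
    score is the maximum Jaccard index against any bootstrap cluster (an
    empty bootstrap partition scores 0).
    """
    scores = {}
    for cid, members in orig_clusters.items():
        restricted = members & common
        if not restricted:
            continue
        scores[cid] = max(
            (jaccard_index(restricted, bc) for bc in boot_clusters), default=0.0)
    return scores


def bootstrap_stability(
    reference: ClusterResults,
    n_boot: int | None = None,
    seed: int | None = None,
    resampler=None,
) -> StabilityReport:
    """Clusterwise bootstrap Jaccard stability of a fitted clustering.

    Each iteration draws a with-replacement sample of patients, reduces it
    to its unique members, re-embeds and re-clusters that subset of the
    reference z-matrix with the reference eps/min_pts, and scores every
    original cluster with at least one sampled member by its maximum Jaccard
    against the bootstrap clusters. Iteration seeds derive deterministically
    from ``seed`` (seed + iteration index) so long runs are reproducible.
    """
    cfg = reference.config
    n_boot = cfg.n_boot if n_boot is None else n_boot
    seed = cfg.rng_seed if seed is None else seed
    orig_clusters = {cid: reference.members(cid) for cid in reference.cluster_ids}
    if not orig_clusters:
        raise ValueError("reference clustering has no clusters (all noise)")
    matrix = reference.qc.z_matrix if cfg.scale else reference.qc.matrix
    patients = np.asarray(matrix.index)

    per_iter = np.empty(n_boot)
    per_cluster_scores: dict[int, list[float]] = {cid: [] for cid in orig_clusters}
    seeds = [(seed + i) % _SEED_MOD for i in range(n_boot)]
    for i, it_seed in enumerate(seeds):
        rng = np.random.default_rng(it_seed)
        draw = (rng.choice(patients, size=len(patients), replace=True)
                if resampler is None else np.asarray(resampler(rng, patients)))
        common = sorted(set(draw))
        boot_labels = _recluster_subset(matrix.loc[common], reference, it_seed)
        boot_clusters = [set(boot_labels.index[boot_labels == c])
                         for c in boot_labels.unique() if c != NOISE]
        scores = score_iteration(orig_clusters, boot_clusters, set(common))
        for cid, s in scores.items():
            per_cluster_scores[cid].append(s)
        per_iter[i] = float(np.mean(list(scores.values()))) if scores else np.nan
    valid = per_iter[~np.isnan(per_iter)]
    return StabilityReport(
        per_iteration_jaccard=per_iter,
        per_cluster_mean_jaccard={
            cid: float(np.mean(v)) if v else float("nan")
            for cid, v in per_cluster_scores.items()},
        mean_jaccard=float(np.mean(valid)),
        n_boot=n_boot,
        seeds=seeds,
    )


def _recluster_subset(z_sub: pd.DataFrame, reference: ClusterResults,
                      it_seed: int) -> pd.Series:
    params = dataclasses.replace(reference.params, rng_seed=int(it_seed))
    if len(z_sub) <= params.n_neighbors:
        params = dataclasses.replace(params, n_neighbors=max(2, len(z_sub) - 1))
    emb = embed(z_sub, params)
    return dbscan_cluster(emb, eps=reference.eps, min_pts=reference.min_pts)


def find_outliers(z_matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Patients whose max |z| over metabolites exceeds ``threshold``.

    Returns a DataFrame indexed by patient_id with columns
    ``worst_metabolite`` and ``max_abs_z``, sorted by max_abs_z descending.
    """
    absz = z_matrix.abs()
    max_abs = absz.max(axis=1)
    worst = absz.idxmax(axis=1)
    sel = max_abs > threshold
    out = pd.DataFrame({
        "worst_metabolite": worst[sel],
        "max_abs_z": max_abs[sel],
    })
    return out.sort_values("max_abs_z", ascending=False)


@dataclass
class SensitivityReport:
    outliers: pd.DataFrame
    labels_original: pd.Series
    labels_reduced: pd.Series
    flow_table: pd.DataFrame  # original × reduced label contingency

    def summary(self) -> str:
        kept = len(self.labels_reduced)
        moved = int(sum(
            self.labels_original.loc[p] != self.labels_reduced.loc[p]
            for p in self.labels_reduced.index))
        return (
            f"Outlier sensitivity analysis\n"
            f"outliers excluded: {len(self.outliers)}\n"
            f"patients retained: {kept}\n"
            f"label changes among retained: {moved}\n"
            f"flow table (rows original, cols reduced):\n{self.flow_table}"
        )


def sensitivity_recluster(
    tables: CohortTables,
    cfg: RunConfig | None = None,
    reference: ClusterResults | None = None,
) -> SensitivityReport:
    """Exclude extreme metabolomic profiles and re-run the pipeline.

    ``reference`` may carry an already-fitted primary clustering; otherwise
    it is fitted here with ``cfg``. The flow table counts retained patients
    by (original label, reduced label); noise is a valid row/column.
    """
    from .cluster import MetabolicClusterModel

    cfg = cfg or RunConfig()
    if reference is None:
        reference = MetabolicClusterModel(tables, cfg).fit()
    outliers = find_outliers(reference.qc.z_matrix, cfg.z_outlier_threshold)
    keep = [p for p in tables.patients if p not in set(outliers.index)]
    if len(keep) < cfg.min_pts + 1:
        raise ValueError(
            f"only {len(keep)} patients remain after outlier exclusion; "
            f"need at least min_pts + 1 = {cfg.min_pts + 1}")
    reduced = MetabolicClusterModel(tables.subset_patients(keep), cfg).fit()
    flow = pd.crosstab(
        reference.labels.loc[keep].rename("original"),
        reduced.labels.loc[keep].rename("reduced"),
    )
    return SensitivityReport(
        outliers=outliers,
        labels_original=reference.labels,
        labels_reduced=reduced.labels,
        flow_table=flow,
    )
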