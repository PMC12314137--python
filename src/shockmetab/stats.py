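"""Between-cluster comparisons: exact r×c Fisher, Kruskal–Wallis, family profiles.

Categorical variables are compared with the Freeman–Halton generalization
of Fisher's exact test: all tables with the observed margins are enumerated
recursively, each scored by its multivariate hypergeometric probability
(computed with log-factorials), and the two-sided p-value sums the
probabilities of tables no more probable than the observed one — the
probability-ordering convention of the classic implementations. Continuous
variables use the tie-corrected Kruskal–Wallis rank test. Metabolite
families are profiled as each patient's mean z-score over the family's
metabolites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import kruskal as _scipy_kruskal

from .io import FAMILIES, CohortTables
from .cluster import NOISE

logger = logging.getLogger(__name__)

#: relative slack when comparing table probabilities for float ties
_TIE_RTOL = 1e-7


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list = None
    col_labels: list = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative integers")
        if self.row_labels is None:
            self.row_labels = list(range(self.counts.shape[0]))
        if self.col_labels is None:
            self.col_labels = list(range(self.counts.shape[1]))


@dataclass
class GroupComparison:
    variable: str
    test: str  # "kruskal_wallis" | "fisher_exact"
    statistic: float
    p_value: float
    pairwise: dict | None = None


def kruskal_wallis(groups, variable: str = "") -> GroupComparison:
    """Tie-corrected Kruskal–Wallis H with chi-square (k−1 df) p-value.

    A degenerate input where every observation is identical yields
    H = 0, p = 1 rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupComparison(variable, "kruskal_wallis", 0.0, 1.0)
    h, p = _scipy_kruskal(*groups)
    return GroupComparison(variable, "kruskal_wallis", float(h), float(p))


def _enumerate_log_probs(counts: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-probability of the observed table and of every margin-feasible table."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    logp_obs = const - gammaln(counts + 1).sum()

    out: list[float] = []
    ncols = len(cols)

    def fill_row(r: int, rem_cols: np.ndarray, acc: float) -> None:
        if r == len(rows) - 1:
            # last row forced by the column margins
            out.append(acc - gammaln(rem_cols + 1).sum())
            return
        target = rows[r]

        def fill_cell(j: int, left: int, rem: np.ndarray, a: float) -> None:
            if j == ncols - 1:
                if left <= rem[j]:
                    rem2 = rem.copy()
                    rem2[j] -= left
                    fill_row(r + 1, rem2, a - gammaln(left + 1))
                return
            hi = min(left, rem[j])
            for v in range(hi + 1):
                rem2 = rem.copy()
                rem2[j] -= v
                fill_cell(j + 1, left - v, rem2, a - gammaln(v + 1))

        fill_cell(0, target, rem_cols, acc)

    fill_row(0, cols.astype(np.int64), const)
    return float(logp_obs), np.asarray(out)


def fisher_exact_rxc(table, variable: str = "") -> GroupComparison:
    """Freeman–Halton exact test for an r×c contingency table.

    Exact enumeration under the multivariate hypergeometric law with the
    observed margins fixed; feasible for total N up to a few hundred on
    small tables. The returned statistic is the observed table probability.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(
        table, dtype=np.int64)
    ct = ContingencyTable(counts) if not isinstance(table, ContingencyTable) else table
    if (ct.counts.sum(axis=1) == 0).any() or (ct.counts.sum(axis=0) == 0).any():
        raise ValueError("test undefined: a row or column margin is zero")
    if ct.counts.shape[0] < 2 or ct.counts.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    logp_obs, logps = _enumerate_log_probs(ct.counts)
    cutoff = logp_obs + np.log1p(_TIE_RTOL)
    p = float(np.exp(logps[logps <= cutoff]).sum())
    return GroupComparison(variable, "fisher_exact",
                           float(np.exp(logp_obs)), min(p, 1.0))


def family_scores(z_matrix: pd.DataFrame, annotations: pd.Series) -> pd.DataFrame:
    """Per-patient family score: mean z-score over the family's metabolites.

    Families with no retained metabolite are dropped with a logged warning.
    """
    unannotated = set(z_matrix.columns) - set(annotations.index)
    if unannotated:
        raise ValueError(f"metabolites without annotation: {sorted(unannotated)}")
    fam = annotations.loc[z_matrix.columns]
    scores = {}
    for family in FAMILIES:
        mets = fam.index[fam == family]
        if len(mets) == 0:
            logger.warning("family %s has no retained metabolites; dropped", family)
            continue
        scores[family] = z_matrix[mets].mean(axis=1)
    return pd.DataFrame(scores, index=z_matrix.index)


@dataclass
class FamilyProfile:
    """Cluster-level family medians and omnibus Kruskal–Wallis p per family."""

    medians: pd.DataFrame  # clusters × families
    omnibus_p: dict[str, float]
    scores: pd.DataFrame  # patients × families

    def summary(self) -> str:
        lines = ["Metabolite-family profiles (median of patient mean z-scores)"]
        lines.append(self.medians.round(2).to_string())
        lines.append("omnibus Kruskal-Wallis p per family:")
        for famname, p in self.omnibus_p.items():
            lines.append(f"  {famname}: {p:.4g}")
        return "\n".join(lines)


def family_profile(z_matrix: pd.DataFrame, annotations: pd.Series,
                   labels: pd.Series) -> FamilyProfile:
    """Family medians per cluster plus an omnibus test across clusters."""
    scores = family_scores(z_matrix, annotations)
    clustered = labels[labels != NOISE]
    ids = sorted(clustered.unique())
    med = pd.DataFrame(
        {f: [scores.loc[clustered.index[clustered == c], f].median() for c in ids]
         for f in scores.columns},
        index=pd.Index(ids, name="cluster"))
    omnibus = {}
    for f in scores.columns:
        groups = [scores.loc[clustered.index[clustered == c], f] for c in ids]
        omnibus[f] = kruskal_wallis(groups, f).p_value if len(ids) >= 2 else float("nan")
    return FamilyProfile(medians=med, omnibus_p=omnibus, scores=scores)


def _pct(n: int, d: int) -> int:
    """Round-half-up integer percent, the 'n (%)' convention of clinical tables."""
    return int(np.floor(100.0 * n / d + 0.5)) if d else 0


def _safe_fisher(counts: np.ndarray, variable: str) -> float:
    sub = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        return 1.0  # degenerate table: no association testable
    return fisher_exact_rxc(sub, variable).p_value


@dataclass
class BaselineTable:
    table: pd.DataFrame  # rendered strings, one row per variable/level
    p_values: dict[str, float]
    pairwise: dict[str, dict[tuple, float]] | None = None

    def summary(self) -> str:
        return self.table.to_string()

    def to_markdown(self) -> str:
        return self.table.to_markdown()


def summarize_baseline(tables: CohortTables, labels: pd.Series,
                       pairwise: bool = False, holm: bool = False) -> BaselineTable:
    """Per-cluster descriptive table with omnibus p-values.

    Categorical variables are rendered ``n (percent)`` with round-half-up
    integer percents and tested with the exact r×c Fisher test; continuous
    variables are rendered ``median (min–max)`` and tested with
    Kruskal–Wallis. Noise-labeled patients are excluded from cluster
    columns but included in the total.
    """
    clin = tables.clinical
    clustered = labels[labels != NOISE]
    ids = sorted(clustered.unique())
    groups = {c: clustered.index[clustered == c] for c in ids}
    cols = [f"Cluster {c} (n={len(groups[c])})" for c in ids] + [
        f"Total (n={len(clin)})"]

    rows, pvals, pair_out = {}, {}, {}
    for var in clin.columns:
        series = clin[var]
        if series.dtype == bool or series.dtype == object:
            levels = ([True] if series.dtype == bool else sorted(series.unique()))
            counts = np.array([[int((series.loc[groups[c]] == lv).sum()) for c in ids]
                               for lv in (series.unique() if series.dtype == object
                                          else [True, False])])
            pvals[var] = _safe_fisher(counts, var)
            for lv in levels:
                cells = [
                    f"{int((series.loc[groups[c]] == lv).sum())} "
                    f"({_pct(int((series.loc[groups[c]] == lv).sum()), len(groups[c]))})"
                    for c in ids
                ]
                cells.append(f"{int((series == lv).sum())} "
                             f"({_pct(int((series == lv).sum()), len(series))})")
                name = var if series.dtype == bool else f"{var}: {lv}"
                rows[name] = cells
            if pairwise:
                pair_out[var] = _pairwise_categorical(series, groups)
        else:
            vals = {c: series.loc[groups[c]].astype(float) for c in ids}
            comp = kruskal_wallis(list(vals.values()), var)
            pvals[var] = comp.p_value
            cells = [f"{v.median():g} ({v.min():g}–{v.max():g})"
                     for v in vals.values()]
            cells.append(f"{series.median():g} ({series.min():g}–{series.max():g})")
            rows[var] = cells
            if pairwise:
                pair_out[var] = {
                    (a, b): kruskal_wallis([vals[a], vals[b]], var).p_value
                    for i, a in enumerate(ids) for b in ids[i + 1:]}
    if pairwise and holm:
        from statsmodels.stats.multitest import multipletests

        for var, d in pair_out.items():
            keys = list(d)
            adj = multipletests([d[k] for k in keys], method="holm")[1]
            pair_out[var] = dict(zip(keys, adj))

    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table["p"] = [
        f"{pvals[v.split(': ')[0]]:.2f}" if v.split(": ")[0] in pvals else ""
        for v in table.index]
    return BaselineTable(table=table, p_values=pvals,
                         pairwise=pair_out if pairwise else None)


def _pairwise_categorical(series: pd.Series, groups: dict) -> dict:
    ids = sorted(groups)
    out = {}
    levels = sorted(series.unique(), key=str)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            counts = np.array([
                [int((series.loc[groups[g]] == lv).sum()) for g in (a, b)]
                for lv in levels])
            out[(a, b)] = _safe_fisher(counts, series.name or "")
    return out
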