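"""Metabolite retention (QC), imputation, log transform and z-scoring.

A metabolite is dropped when it has more than ``qc_missing_frac`` missing
values within any patient group, or when it is detected (measured above the
LOD) in fewer than ``qc_detect_frac`` of all samples. Below-LOD cells are
imputed at half the minimum measured value of that metabolite and missing
cells at the metabolite's median measured value — common targeted-
metabolomics defaults — before a natural-log transform and per-metabolite
z-scoring (sample SD, ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BELOW_LOD, MEASURED, MISSING, CohortTables, RunConfig

REASON_MISSING = "missing_gt_20pct"
REASON_DETECT = "detect_lt_50pct"


@dataclass
class QCResult:
    retained: list[str]
    excluded: list[tuple[str, str]]  # (metabolite, reason)
    matrix: pd.DataFrame  # imputed + log-transformed, patients × retained
    z_matrix: pd.DataFrame  # per-metabolite z-scores of `matrix`


def qc_filter(
    tables: CohortTables,
    groups: pd.Series | None = None,
    cfg: RunConfig | None = None,
) -> QCResult:
    """Apply the retention rules and build the analysis matrices.

    ``groups`` (optional per-patient labels, e.g. admission-cause strata or
    discovered clusters) scopes the missingness rule; without it the whole
    cohort is a single group. The detectability rule always counts over all
    samples.
    """
    cfg = cfg or RunConfig()
    status = tables.status
    if status.shape[1] == 0:
        raise ValueError("cohort contains no metabolites")
    if groups is not None:
        groups = pd.Series(groups)
        missing_in_groups = set(tables.patients) - set(groups.index)
        if missing_in_groups:
            raise ValueError(f"patients without group label: {sorted(map(str, missing_in_groups))}")
        groups = groups.loc[tables.patients]
        group_ids = [g for g in pd.unique(groups)]
    else:
        groups = pd.Series("all", index=tables.patients)
        group_ids = ["all"]

    excluded: list[tuple[str, str]] = []
    retained: list[str] = []
    detect_frac = (status == MEASURED).mean(axis=0)
    for met in sorted(tables.metabolites):
        reasons = []
        for g in group_ids:
            frac_missing = (status.loc[groups == g, met] == MISSING).mean()
            if frac_missing > cfg.qc_missing_frac:
                reasons.append(REASON_MISSING)
                break
        if detect_frac[met] < cfg.qc_detect_frac:
            reasons.append(REASON_DETECT)
        if reasons:
            excluded.extend((met, r) for r in reasons)
        else:
            retained.append(met)

    if retained:
        matrix = impute_and_transform(tables, retained)
        z_matrix = zscore(matrix)
    else:  # every metabolite excluded: empty, but well-formed, matrices
        matrix = pd.DataFrame(index=tables.patients)
        z_matrix = matrix.copy()
    return QCResult(retained=retained, excluded=excluded,
                    matrix=matrix, z_matrix=z_matrix)


def impute_and_transform(tables: CohortTables, retained: list[str]) -> pd.DataFrame:
    """Impute below-LOD (half-minimum) and missing (median) cells, then log.

    Deterministic; raises if a retained metabolite has no measured value at
    all (nothing to anchor the imputation).
    """
    if not retained:
        raise ValueError("retained metabolite list is empty")
    out = {}
    for met in retained:
        col = tables.concentrations[met].astype(float).copy()
        st = tables.status[met]
        measured = col[st == MEASURED]
        if measured.empty:
            raise ValueError(f"metabolite {met!r} has no measured values; cannot impute")
        col[st == BELOW_LOD] = measured.min() / 2.0
        col[st == MISSING] = measured.median()
        out[met] = np.log(col)
    return pd.DataFrame(out, index=tables.patients)


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column standardization to mean 0, sample SD 1 (ddof=1)."""
    sd = matrix.std(axis=0, ddof=1)
    zero_var = sd[sd == 0]
    if not zero_var.empty:
        raise ValueError(
            f"zero-variance metabolite(s), cannot z-score: {list(zero_var.index)}")
    return (matrix - matrix.mean(axis=0)) / sd
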