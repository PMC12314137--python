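"""Input tables, run configuration and report serialization.

The analysis starts from three plain-text tables: a wide patient ×
metabolite concentration matrix (µM, possibly with below-LOD or empty
cells), a metabolite → biochemical-family annotation table following the
six families of a targeted plasma panel, and a per-patient clinical table
(admission cause, severity scores, organ failures, mortality flags).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

#: The six biochemical families of the targeted panel.
FAMILIES = (
    "amino_acids",
    "biogenic_amines",
    "acylcarnitines",
    "glycerophospholipids",
    "sphingolipids",
    "sugars",
)

#: Cell status codes for the concentration matrix.
MEASURED, BELOW_LOD, MISSING = "measured", "below_LOD", "missing"

#: Default spellings accepted for a below-limit-of-detection cell.
DEFAULT_LOD_SENTINELS = ("<LOD", "< LOD", "<lod", "< lod", "LOD")


class CohortValidationError(ValueError):
    """Raised when the three input tables are mutually inconsistent."""


@dataclass
class CohortTables:
    """Validated in-memory cohort.

    Attributes
    ----------
    concentrations : DataFrame, patients × metabolites
        Measured values as floats; below-LOD and missing cells are NaN
        (their nature is recorded in ``status``).
    status : DataFrame, patients × metabolites
        Per-cell code: ``measured``, ``below_LOD`` or ``missing``.
    annotations : Series, metabolite → family
    clinical : DataFrame indexed by patient_id
    """

    concentrations: pd.DataFrame
    status: pd.DataFrame
    annotations: pd.Series
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def patients(self) -> pd.Index:
        return self.concentrations.index

    @property
    def metabolites(self) -> pd.Index:
        return self.concentrations.columns

    def validate(self) -> None:
        conc_ids = list(self.concentrations.index)
        if len(set(conc_ids)) != len(conc_ids):
            dup = sorted({p for p in conc_ids if conc_ids.count(p) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dup}")
        mismatch = set(conc_ids) ^ set(self.clinical.index)
        if mismatch:
            raise CohortValidationError(
                "patient ids differ between concentrations and clinical "
                f"tables: {sorted(map(str, mismatch))}"
            )
        unannotated = set(self.concentrations.columns) - set(self.annotations.index)
        if unannotated:
            raise CohortValidationError(
                f"metabolites without family annotation: {sorted(unannotated)}"
            )
        bad_fam = set(self.annotations.unique()) - set(FAMILIES)
        if bad_fam:
            raise CohortValidationError(
                f"unknown metabolite families {sorted(bad_fam)}; "
                f"allowed families are {list(FAMILIES)}"
            )
        measured = self.concentrations.to_numpy(dtype=float)
        if np.nanmin(measured, initial=0.0) < 0:
            raise CohortValidationError("measured concentrations must be >= 0")

    def subset_patients(self, patients) -> "CohortTables":
        """Return a new cohort restricted to ``patients`` (canonical order kept)."""
        keep = [p for p in self.patients if p in set(patients)]
        return CohortTables(
            concentrations=self.concentrations.loc[keep],
            status=self.status.loc[keep],
            annotations=self.annotations,
            clinical=self.clinical.loc[keep],
        )


@dataclass
class RunConfig:
    """Tunable parameters of the full pipeline.

    Defaults follow the primary analysis: DBSCAN ``eps=0.7`` / ``min_pts=5``
    on a 2-D UMAP embedding, 1000 bootstrap iterations, outlier screening at
    max |z| > 5, metabolite retention at <=20% missing within any patient
    group and >=50% detectability, and logistic-model selection at a 0.10
    univariate screen with 0.05 backward-elimination retention.
    """

    eps: float = 0.7
    min_pts: int = 5
    n_boot: int = 1000
    z_outlier_threshold: float = 5.0
    qc_missing_frac: float = 0.20
    qc_detect_frac: float = 0.50
    screen_alpha: float = 0.10
    keep_alpha: float = 0.05
    rng_seed: int = 0
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    scale: bool = True  # log + z-score before embedding

    def __post_init__(self) -> None:
        if not (0 < self.qc_detect_frac <= 1):
            raise ValueError("qc_detect_frac must be in (0, 1]")
        if not (0 < self.qc_missing_frac < 1):
            raise ValueError("qc_missing_frac must be in (0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_cohort(
    conc_path: str | Path,
    annot_path: str | Path,
    clinical_path: str | Path,
    lod_sentinels: tuple[str, ...] = DEFAULT_LOD_SENTINELS,
) -> CohortTables:
    """Read and validate the three cohort tables.

    Cells equal to one of ``lod_sentinels`` are flagged ``below_LOD``; empty
    cells are ``missing``. Patients are canonicalized by sorting patient_id
    so downstream seeded runs do not depend on file row order.
    """
    raw = _read_table(conc_path)
    pid_col = raw.columns[0]
    raw = raw.set_index(pid_col)
    sentinels = {s.strip().lower() for s in lod_sentinels}

    conc = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    status = pd.DataFrame(MEASURED, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        cells = raw[col].str.strip()
        is_lod = cells.str.lower().isin(sentinels)
        is_missing = cells == ""
        status[col] = np.where(is_lod, BELOW_LOD, np.where(is_missing, MISSING, MEASURED))
        vals = pd.to_numeric(cells.where(~(is_lod | is_missing)), errors="raise")
        conc[col] = vals

    annot = _read_table(annot_path)
    annotations = pd.Series(
        annot.iloc[:, 1].str.strip().values,
        index=annot.iloc[:, 0].str.strip().values,
        name="family",
    )

    clin_raw = _read_table(clinical_path)
    clinical = clin_raw.set_index(clin_raw.columns[0])
    clinical = _coerce_clinical(clinical)

    order = sorted(conc.index)
    return CohortTables(
        concentrations=conc.loc[order],
        status=status.loc[order],
        annotations=annotations,
        clinical=clinical.loc[[p for p in order if p in clinical.index]]
        if set(order) <= set(clinical.index)
        else clinical,
    )


_BOOL_STRINGS = {"true": True, "false": False, "1": True, "0": False,
                 "yes": True, "no": False}


def _coerce_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in clinical.columns:
        cells = clinical[col].astype(str).str.strip()
        lower = cells.str.lower()
        if lower.isin(_BOOL_STRINGS).all():
            out[col] = lower.map(_BOOL_STRINGS)
        else:
            try:
                out[col] = pd.to_numeric(cells)
            except (ValueError, TypeError):
                out[col] = cells
    return pd.DataFrame(out, index=clinical.index)


# ---------------------------------------------------------------------------
# report serialization


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return {
            "__dataframe__": True,
            "index": list(map(_scalar, obj.index)),
            "columns": list(map(_scalar, obj.columns)),
            "data": [[_scalar(v) for v in row] for row in obj.to_numpy()],
        }
    if isinstance(obj, pd.Series):
        return {"__series__": True,
                "index": list(map(_scalar, obj.index)),
                "data": [_scalar(v) for v in obj.to_numpy()]}
    if isinstance(obj, np.ndarray):
        return [_scalar(v) for v in obj.tolist()]
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return _scalar(obj)


def _scalar(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v


def write_report(report: Any, out_path: str | Path) -> None:
    """Serialize any stage report (dataclass / dict / DataFrame) to JSON.

    Floats are written at full precision so a write→read round trip
    reproduces every numeric field exactly.
    """
    payload = _to_jsonable(report)
    with open(out_path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    """Read a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return _revive(json.load(fh))


def _revive(obj: Any) -> Any:
    if isinstance(obj, dict):
        if obj.get("__dataframe__"):
            return pd.DataFrame(obj["data"], index=obj["index"], columns=obj["columns"])
        if obj.get("__series__"):
            return pd.Series(obj["data"], index=obj["index"])
        return {k: _revive(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_revive(v) for v in obj]
    return obj


def write_table(df: pd.DataFrame, out_path: str | Path) -> None:
    """Write a per-patient table as TSV (full float precision)."""
    df.to_csv(out_path, sep="\t", float_format="%.17g")
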