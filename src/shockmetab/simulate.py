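"""Synthetic shock-cohort generator.

Emulates the statistical structure the downstream analysis assumes: three
metabolic phenotypes with family-specific log-concentration shifts
(phenotype A rich in biogenic amines, sugars and sphingolipids; phenotype B
rich in glycerophospholipids and sphingolipids; phenotype C uniformly low),
below-LOD censoring, completely-at-random missingness, cluster-dependent
clinical severity, and hospital mortality drawn from an explicit logistic
model over phenotype, APACHE II and the number of organ failures.

Concentrations are log-normal: metabolomics panels report strictly positive,
right-skewed values, and phenotype effects act multiplicatively, i.e.
additively on the log scale. Metabolites within a family share a latent
patient-level factor so family-level summaries are correlated, as they are
in real panels where one pathway drives many analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binom, norm

from .io import BELOW_LOD, FAMILIES, MEASURED, MISSING, CohortTables

PHENOTYPES = ("A", "B", "C")

#: metabolite-name prefixes per family, echoing targeted-panel nomenclature
_PREFIX = {
    "amino_acids": "AA",
    "biogenic_amines": "BA",
    "acylcarnitines": "AC",
    "glycerophospholipids": "PC",
    "sphingolipids": "SM",
    "sugars": "H",
}


def _default_counts() -> dict[str, int]:
    # 130 metabolites total, families in the proportions of a 186-analyte
    # targeted plasma panel after typical quality filtering
    return {
        "amino_acids": 20,
        "biogenic_amines": 14,
        "acylcarnitines": 15,
        "glycerophospholipids": 65,
        "sphingolipids": 15,
        "sugars": 1,
    }


def _default_shifts() -> dict[tuple[str, str], float]:
    return {
        ("A", "biogenic_amines"): 3.0,
        ("A", "sugars"): 3.0,
        ("A", "sphingolipids"): 2.0,
        ("B", "glycerophospholipids"): 3.0,
        ("B", "sphingolipids"): 2.0,
    }


@dataclass
class MortalityLogit:
    """Hospital-death model used by the generator.

    logit P(death) = intercept + offset[phenotype]
                     + beta_apache2 * (apache2 - apache2_center)/apache2_scale
                     + beta_organ   * (n_organ - organ_center)/organ_scale

    Defaults imply phenotype-level hospital mortality of roughly 54%, 38%
    and 9% for A, B and C respectively given the default covariate
    distributions (see :func:`implied_mortality`).
    """

    intercept: float = -1.85
    offsets: dict[str, float] = field(
        default_factory=lambda: {"A": 1.45, "B": 1.35, "C": 0.0})
    beta_apache2: float = 0.5
    beta_organ: float = 0.5
    apache2_center: float = 25.0
    apache2_scale: float = 5.5
    organ_center: float = 2.4
    organ_scale: float = 1.3

    def linear_predictor(self, phenotype, apache2, n_organ):
        off = np.asarray([self.offsets[p] for p in np.atleast_1d(phenotype)])
        return (
            self.intercept
            + off
            + self.beta_apache2 * (np.asarray(apache2) - self.apache2_center) / self.apache2_scale
            + self.beta_organ * (np.asarray(n_organ) - self.organ_center) / self.organ_scale
        )


@dataclass
class SyntheticCohortSpec:
    """All knobs of the generator; defaults are the study-like conditions."""

    n_patients: int = 60
    cluster_proportions: tuple[float, ...] = (13 / 60, 24 / 60, 23 / 60)
    n_metabolites_per_family: dict[str, int] = field(default_factory=_default_counts)
    family_shift: dict[tuple[str, str], float] = field(default_factory=_default_shifts)
    within_cluster_sd: float = 1.0
    family_loading: float = 0.5
    lod_quantile: float = 0.02
    missing_rate: float = 0.01
    # clinical covariates per phenotype
    apache2_mean: dict[str, float] = field(
        default_factory=lambda: {"A": 29.0, "B": 25.0, "C": 22.0})
    apache2_sd: float = 5.0
    sofa_mean: dict[str, float] = field(
        default_factory=lambda: {"A": 13.0, "B": 13.0, "C": 11.0})
    sofa_sd: float = 3.0
    organ_failure_p: dict[str, float] = field(
        default_factory=lambda: {"A": 0.50, "B": 0.42, "C": 0.33})
    organ_failure_max: int = 6
    septic_p: dict[str, float] = field(
        default_factory=lambda: {"A": 0.54, "B": 0.71, "C": 0.65})
    mortality_logit: MortalityLogit = field(default_factory=MortalityLogit)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if len(self.cluster_proportions) != len(PHENOTYPES):
            raise ValueError(f"expected {len(PHENOTYPES)} phenotype proportions")
        if any(c <= 0 for c in self.n_metabolites_per_family.values()):
            raise ValueError("metabolite counts must be positive")
        for q in (self.lod_quantile, self.missing_rate):
            if not (0 <= q < 1):
                raise ValueError("lod_quantile and missing_rate must be in [0, 1)")
        bad = {f for _, f in self.family_shift} - set(FAMILIES)
        if bad:
            raise ValueError(f"family_shift references unknown families: {sorted(bad)}")
        bad = {p for p, _ in self.family_shift} - set(PHENOTYPES)
        if bad:
            raise ValueError(f"family_shift references unknown phenotypes: {sorted(bad)}")


def default_spec(**overrides) -> SyntheticCohortSpec:
    """The documented default study-like conditions (n=60, 13/24/23 split)."""
    return replace(SyntheticCohortSpec(), **overrides) if overrides else SyntheticCohortSpec()


@dataclass
class SyntheticCohort:
    tables: CohortTables
    true_labels: pd.Series  # patient_id -> phenotype in {"A","B","C"}


def simulate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw one cohort; fully reproducible given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_patients
    patients = pd.Index([f"P{i + 1:03d}" for i in range(n)], name="patient_id")
    labels = rng.choice(PHENOTYPES, size=n, p=spec.cluster_proportions)

    met_names, met_family = [], []
    for fam in FAMILIES:
        count = spec.n_metabolites_per_family.get(fam, 0)
        for j in range(count):
            met_names.append(f"{_PREFIX[fam]}{j + 1:02d}")
            met_family.append(fam)
    annotations = pd.Series(met_family, index=met_names, name="family")
    m = len(met_names)

    baseline = rng.uniform(np.log(0.5), np.log(200.0), size=m)
    lam = spec.family_loading
    factor = {fam: rng.standard_normal(n) for fam in FAMILIES}  # latent per-patient
    noise = rng.standard_normal((n, m))

    logc = np.empty((n, m))
    for j, (name, fam) in enumerate(zip(met_names, met_family)):
        shift = np.array([spec.family_shift.get((lab, fam), 0.0) for lab in labels])
        logc[:, j] = baseline[j] + shift + spec.within_cluster_sd * (
            lam * factor[fam] + np.sqrt(1 - lam**2) * noise[:, j]
        )
    conc = np.exp(logc)

    status = np.full((n, m), MEASURED, dtype=object)
    if spec.lod_quantile > 0:
        lod = np.quantile(conc, spec.lod_quantile, axis=0)
        status[conc < lod[None, :]] = BELOW_LOD
    if spec.missing_rate > 0:
        miss = rng.random((n, m)) < spec.missing_rate
        status[miss] = MISSING
    conc_df = pd.DataFrame(conc, index=patients, columns=met_names)
    conc_df = conc_df.mask(pd.DataFrame(status != MEASURED, index=patients, columns=met_names))
    status_df = pd.DataFrame(status, index=patients, columns=met_names)

    apache2 = np.clip(np.round(rng.normal(
        [spec.apache2_mean[lab] for lab in labels], spec.apache2_sd)), 0, 71).astype(int)
    sofa = np.clip(np.round(rng.normal(
        [spec.sofa_mean[lab] for lab in labels], spec.sofa_sd)), 0, 24).astype(int)
    n_organ = rng.binomial(spec.organ_failure_max,
                           [spec.organ_failure_p[lab] for lab in labels])
    septic = rng.random(n) < np.array([spec.septic_p[lab] for lab in labels])

    lp = spec.mortality_logit.linear_predictor(labels, apache2, n_organ)
    hospital_death = rng.random(n) < expit(lp)
    # ICU death is a subset of hospital death
    icu_death = hospital_death & (rng.random(n) < 0.8)

    clinical = pd.DataFrame(
        {
            "admission_cause": np.where(septic, "septic", "cardiogenic"),
            "apache2": apache2,
            "sofa": sofa,
            "n_organ_failures": n_organ,
            "icu_death": icu_death,
            "hospital_death": hospital_death,
        },
        index=patients,
    )

    tables = CohortTables(
        concentrations=conc_df, status=status_df,
        annotations=annotations, clinical=clinical,
    )
    return SyntheticCohort(tables=tables,
                           true_labels=pd.Series(labels, index=patients, name="phenotype"))


def implied_mortality(spec: SyntheticCohortSpec) -> dict[str, float]:
    """Phenotype-level P(hospital death) implied by the generator's logit.

    Computed by numerically integrating the logistic model over the exact
    covariate distributions (rounded-normal APACHE II, binomial organ
    failures), not by simulation.
    """
    out = {}
    ml = spec.mortality_logit
    for lab in PHENOTYPES:
        ks = np.arange(0, 72)
        pk = norm.cdf(ks + 0.5, spec.apache2_mean[lab], spec.apache2_sd) - norm.cdf(
            ks - 0.5, spec.apache2_mean[lab], spec.apache2_sd)
        pk[0] += norm.cdf(-0.5, spec.apache2_mean[lab], spec.apache2_sd)
        pk[-1] += norm.sf(71.5, spec.apache2_mean[lab], spec.apache2_sd)
        ms = np.arange(0, spec.organ_failure_max + 1)
        pm = binom.pmf(ms, spec.organ_failure_max, spec.organ_failure_p[lab])
        p = 0.0
        for k, pk_ in zip(ks, pk):
            lp = ml.linear_predictor([lab] * len(ms), np.full(len(ms), k), ms)
            p += pk_ * float(np.sum(pm * expit(lp)))
        out[lab] = p
    return out


def write_cohort(cohort: SyntheticCohort, out_dir, lod_sentinel: str = "<LOD") -> dict[str, str]:
    """Write the three analysis input CSVs plus true_labels.tsv to ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = cohort.tables
    rendered = t.concentrations.copy().astype(object)
    rendered = rendered.where(t.status == MEASURED, None)
    rendered[t.status == BELOW_LOD] = lod_sentinel
    rendered[t.status == MISSING] = ""
    paths = {
        "concentrations": str(out / "concentrations.csv"),
        "annotations": str(out / "annotations.csv"),
        "clinical": str(out / "clinical.csv"),
        "true_labels": str(out / "true_labels.tsv"),
    }
    rendered.to_csv(paths["concentrations"])
    t.annotations.rename_axis("metabolite").to_csv(paths["annotations"])
    t.clinical.rename_axis("patient_id").to_csv(paths["clinical"])
    cohort.true_labels.rename_axis("patient_id").to_csv(paths["true_labels"], sep="\t")
    return paths
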