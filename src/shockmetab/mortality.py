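"""In-hospital mortality model with bootstrap internal validation.

The modelling flow mirrors small-sample clinical-prediction practice:
univariate logistic screening (p < 0.1), backward elimination (p < 0.05,
categorical blocks kept or dropped jointly by likelihood-ratio test), a
final maximum-likelihood logistic fit on standardized continuous covariates
with cluster membership as a categorical term, events-per-variable
accounting, and Harrell's optimism bootstrap: each resample refits the
fixed final covariate set, and apparent performance is corrected by the
mean (bootstrap − original) optimism for the c-index and g-index, with the
calibration slope taken as the mean original-data slope of the
resample-fitted linear predictors and Emax as the maximum absolute gap
between apparent and slope-corrected risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, rankdata

from .cluster import NOISE
from .io import CohortTables

_FIT_KW = dict(disp=0, warn_convergence=False)


class SeparationWarningInfo(UserWarning):
    pass


# ---------------------------------------------------------------------------
# elementary metrics


def concordance_index(predicted, outcome) -> float:
    """Probability an event outranks a non-event in predicted risk; ties 0.5."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required for the c-index")
    ranks = rankdata(p)  # midranks handle ties as 0.5
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def gini_mean_difference(values) -> float:
    """Mean |xi − xj| over all unordered pairs (the g-index on a linear predictor)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    i = np.arange(n)
    total = float(np.sum(x * (2 * i - n + 1)))
    return total / (n * (n - 1) / 2.0)


def calibration_metrics(linear_predictor, outcome) -> tuple[float, float]:
    """Logistic recalibration slope and Emax.

    Refits ``outcome ~ a + b * linear_predictor``; Emax is the maximum over
    the observed predictions of |p − expit(a + b·logit(p))|, the largest
    discrepancy between apparent and recalibrated risk.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.ptp(lp) == 0:
        raise ValueError("calibration slope undefined for a constant linear predictor")
    X = sm.add_constant(lp)
    res = sm.Logit(y, X).fit(**_FIT_KW)
    a, b = res.params
    emax = float(np.max(np.abs(expit(lp) - expit(a + b * lp))))
    return float(b), emax


# ---------------------------------------------------------------------------
# design matrix


def _standardize(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=1)
    if sd == 0:
        raise ValueError(f"covariate {col.name!r} is constant; cannot standardize")
    return (col - col.mean()) / sd


def build_design(data: pd.DataFrame, terms: list[str],
                 reference: dict | None = None,
                 standardize: bool = True) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Design matrix (with intercept) and term → column mapping.

    Categorical terms expand to indicator columns for every non-reference
    level (a joint multi-df block); numeric terms are z-scored when
    ``standardize``.
    """
    reference = reference or {}
    cols, term_cols = {}, {}
    for term in terms:
        s = data[term]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.unique(), key=str)
            ref = reference.get(term, levels[0])
            block = []
            for lv in levels:
                if lv == ref:
                    continue
                name = f"{term}[{lv}]"
                cols[name] = (s == lv).astype(float)
                block.append(name)
            term_cols[term] = block
        else:
            x = s.astype(float)
            cols[term] = _standardize(x) if standardize else x
            term_cols[term] = [term]
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "const", 1.0)
    return X, term_cols


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """MLE logistic fit; returns (result, separated_flag)."""
    import warnings as _w

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    separated = False
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        try:
            res = sm.Logit(np.asarray(y, dtype=float), X).fit(
                method="newton", maxiter=100, **_FIT_KW)
        except Exception:
            res = sm.Logit(np.asarray(y, dtype=float), X).fit(
                method="bfgs", maxiter=200, **_FIT_KW)
            separated = True
    for w in caught:
        if issubclass(w.category, (PerfectSeparationWarning, RuntimeWarning)):
            separated = True
    if not separated and np.any(np.abs(res.params) > 15):
        separated = True  # runaway coefficients betray quasi-separation
    return res, separated


# ---------------------------------------------------------------------------
# selection


def univariate_screen(clinical: pd.DataFrame, outcome, alpha: float = 0.10,
                      candidates: list[str] | None = None,
                      ) -> tuple[list[str], list[str]]:
    """Single-covariate logistic screens; keep terms with p < alpha.

    Categorical candidates are judged by the likelihood-ratio p of their
    indicator block. Perfectly separating covariates get an unreliable p;
    they are retained and reported in the returned warning list.
    """
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; nothing to model")
    candidates = list(candidates) if candidates is not None else [
        c for c in clinical.columns]
    kept, flagged = [], []
    for term in candidates:
        X, term_cols = build_design(clinical, [term])
        res, separated = _fit_logit(y, X)
        block = term_cols[term]
        if len(block) == 1:
            p = float(res.pvalues[block[0]])
        else:
            p = _lr_block_p(y, clinical, [term], term)
        if separated:
            flagged.append(term)
            kept.append(term)  # retained, but its p is unreliable
        elif p < alpha:
            kept.append(term)
    return kept, flagged


def _lr_block_p(y, data, terms, dropped_term, reference=None) -> float:
    Xf, _ = build_design(data, terms, reference)
    Xr, _ = build_design(data, [t for t in terms if t != dropped_term], reference)
    full, _ = _fit_logit(y, Xf)
    red, _ = _fit_logit(y, Xr)
    df = Xf.shape[1] - Xr.shape[1]
    lr = 2 * (full.llf - red.llf)
    return float(chi2.sf(max(lr, 0.0), df))


def backward_eliminate(covariates: list[str], clinical: pd.DataFrame, outcome,
                       keep_alpha: float = 0.05,
                       forced: tuple[str, ...] = (),
                       reference: dict | None = None) -> list[str]:
    """Iteratively drop the weakest non-forced term until all p < keep_alpha.

    Single continuous terms use Wald p; categorical blocks use the joint
    likelihood-ratio p and are dropped or kept as a unit. Deterministic:
    ties broken by larger p, then lexicographic term name.
    """
    if not covariates:
        raise ValueError("no covariates to select from")
    y = np.asarray(outcome, dtype=float)
    terms = list(covariates)
    while True:
        X, term_cols = build_design(clinical, terms, reference)
        res, _ = _fit_logit(y, X)
        worst, worst_p = None, -1.0
        for term in terms:
            if term in forced:
                continue
            block = term_cols[term]
            p = (float(res.pvalues[block[0]]) if len(block) == 1
                 else _lr_block_p(y, clinical, terms, term, reference))
            if (p, term) > (worst_p, worst or ""):
                worst, worst_p = term, p
        if worst is None or worst_p < keep_alpha:
            return terms
        terms = [t for t in terms if t != worst]
        if not terms:
            return terms


# ---------------------------------------------------------------------------
# model / results


@dataclass
class ValidationMetrics:
    c_apparent: float
    c_corrected: float
    calibration_slope: float
    emax: float
    g_apparent: float
    g_corrected: float
    n_boot: int
    n_redrawn: int = 0

    def summary(self) -> str:
        return (
            f"Bootstrap internal validation ({self.n_boot} iterations, "
            f"{self.n_redrawn} degenerate resamples redrawn)\n"
            f"  c-index:           {self.c_apparent:.3f} apparent -> "
            f"{self.c_corrected:.3f} corrected\n"
            f"  calibration slope: {self.calibration_slope:.3f}\n"
            f"  Emax:              {self.emax:.3f}\n"
            f"  g-index:           {self.g_apparent:.3f} apparent -> "
            f"{self.g_corrected:.3f} corrected"
        )


class MortalityModel:
    """Multivariable logistic model of in-hospital death.

    Parameters
    ----------
    data : DataFrame
        One row per patient; must contain the outcome column and every
        covariate. Build one from a cohort with :meth:`from_cohort`.
    covariates : list of str
        Model terms; object/categorical columns enter as multi-df blocks.
    outcome : str
        Binary outcome column (default ``hospital_death``).
    reference : mapping, optional
        Reference level per categorical term. For ``cluster`` the default
        is the cluster with the lowest event rate, so odds ratios read as
        risk relative to the most benign phenotype.
    """

    def __init__(self, data: pd.DataFrame,
                 covariates: list[str] = ("cluster", "apache2", "n_organ_failures"),
                 outcome: str = "hospital_death",
                 reference: dict | None = None):
        self.data = data
        self.covariates = list(covariates)
        self.outcome = outcome
        self.reference = dict(reference or {})
        if "cluster" in self.covariates and "cluster" not in self.reference:
            rates = data.groupby("cluster")[outcome].mean()
            self.reference["cluster"] = rates.idxmin()

    @classmethod
    def from_cohort(cls, tables: CohortTables, labels: pd.Series,
                    covariates=("cluster", "apache2", "n_organ_failures"),
                    outcome: str = "hospital_death", **kw) -> "MortalityModel":
        """Join clinical data with cluster labels (noise patients dropped)."""
        clustered = labels[labels != NOISE]
        data = tables.clinical.loc[clustered.index].copy()
        data["cluster"] = clustered.astype(str)
        return cls(data, covariates=covariates, outcome=outcome, **kw)

    def fit(self) -> "MortalityResults":
        y = self.data[self.outcome].astype(float).to_numpy()
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("outcome has a single class; no fit possible")
        X, term_cols = build_design(self.data, self.covariates, self.reference)
        res, separated = _fit_logit(y, X)
        if not res.mle_retvals.get("converged", True) and not separated:
            raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
        return MortalityResults(self, res, X, y, term_cols, separated)

    def select_and_fit(self, candidates: list[str] | None = None,
                       screen_alpha: float = 0.10, keep_alpha: float = 0.05,
                       forced: tuple[str, ...] = ("cluster",)) -> "MortalityResults":
        """Full selection flow: univariate screen, backward elimination, fit."""
        y = self.data[self.outcome]
        screened, flagged = univariate_screen(
            self.data, y, alpha=screen_alpha,
            candidates=candidates or self.covariates)
        for f in forced:
            if f not in screened:
                screened.append(f)
        final = backward_eliminate(screened, self.data, y, keep_alpha=keep_alpha,
                                   forced=forced, reference=self.reference)
        self.covariates = final
        results = self.fit()
        results.screened_in = screened
        results.separation_flagged = flagged
        return results


class MortalityResults:
    """Fitted mortality model: coefficients, EPV and validation utilities."""

    def __init__(self, model: MortalityModel, res, X: pd.DataFrame,
                 y: np.ndarray, term_cols: dict[str, list[str]],
                 separated: bool = False):
        self.model = model
        self._res = res
        self.X = X
        self.y = y
        self.term_cols = term_cols
        self.separated = separated
        self.screened_in: list[str] | None = None
        self.separation_flagged: list[str] = []

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._res.conf_int(alpha)

    @property
    def n_events(self) -> int:
        return int(self.y.sum())

    @property
    def model_df(self) -> int:
        return self.X.shape[1] - 1  # non-intercept columns

    @property
    def epv(self) -> Fraction:
        """Events per variable, kept as an exact rational."""
        return Fraction(self.n_events, self.model_df)

    @property
    def linear_predictor(self) -> np.ndarray:
        return np.asarray(self.X.to_numpy() @ self.params.to_numpy())

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        lp = self.linear_predictor if X is None else np.asarray(
            X.to_numpy() @ self.params.to_numpy())
        return expit(lp)

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        out = pd.DataFrame({
            "coef": self.params,
            "OR": np.exp(self.params),
            "OR_low": np.exp(ci[0]),
            "OR_high": np.exp(ci[1]),
            "p": self.pvalues,
        })
        return out.drop(index="const")

    def validate(self, n_boot: int = 1000, seed: int = 0) -> ValidationMetrics:
        return bootstrap_validate(self, n_boot=n_boot, seed=seed)

    def summary(self) -> str:
        lines = [
            "Logistic model of in-hospital mortality",
            "=" * 48,
            f"n = {len(self.y)}, events = {self.n_events}, "
            f"model df = {self.model_df}, EPV = {float(self.epv):g}",
            "(continuous covariates standardized; categorical reference: "
            f"{self.model.reference})",
            "",
            self.odds_ratios().round(3).to_string(),
        ]
        if self.separated:
            lines.append("WARNING: (quasi-)separation detected; estimates unstable")
        return "\n".join(lines)


def fit_final_model(covariates: list[str], clinical: pd.DataFrame, outcome,
                    reference: dict | None = None) -> MortalityResults:
    """Fit the final standardized logistic model (functional entry point)."""
    data = clinical.copy()
    out_col = outcome if isinstance(outcome, str) else "__outcome__"
    if not isinstance(outcome, str):
        data[out_col] = np.asarray(outcome)
    return MortalityModel(data, covariates=list(covariates), outcome=out_col,
                          reference=reference).fit()


def bootstrap_validate(results: MortalityResults, n_boot: int = 1000,
                       seed: int = 0, resampler=None) -> ValidationMetrics:
    """Harrell's optimism bootstrap for the fixed final model.

    Resamples with replacement, refits the same design, and accumulates
    optimism = metric(resample fit, resample data) − metric(resample fit,
    original data) for the c-index and g-index. Single-class or
    non-convergent resamples are redrawn and counted. ``resampler``
    (callable ``(rng, n) -> index array``) overrides the default
    with-replacement draw, e.g. for degenerate identity resampling.
    """
    X = results.X
    y = results.y
    n = len(y)
    lp_app = results.linear_predictor
    c_app = concordance_index(expit(lp_app), y)
    g_app = gini_mean_difference(lp_app)

    rng = np.random.default_rng(seed % 2**31)
    opt_c, opt_g, slopes, intercepts = [], [], [], []
    failures = 0
    Xv = X.to_numpy()
    for _ in range(n_boot):
        while True:
            if failures > max(n_boot, 20):
                raise RuntimeError(
                    f"more than half of bootstrap resamples failed ({failures})")
            idx = rng.integers(0, n, n) if resampler is None else np.asarray(
                resampler(rng, n))
            yb = y[idx]
            if yb.min() == yb.max():
                failures += 1
                continue
            try:
                res_b, separated = _fit_logit(yb, X.iloc[idx])
            except Exception:
                failures += 1
                continue
            # a (quasi-)separated resample has diverging coefficients: its
            # unbounded linear predictor would dominate the g-index and
            # slope averages, so treat it as non-convergent and redraw
            if separated or not np.all(np.isfinite(res_b.params)):
                failures += 1
                continue
            break
        beta = np.asarray(res_b.params)
        lp_boot = Xv[idx] @ beta
        lp_orig = Xv @ beta
        opt_c.append(concordance_index(expit(lp_boot), yb)
                     - concordance_index(expit(lp_orig), y))
        opt_g.append(gini_mean_difference(lp_boot) - gini_mean_difference(lp_orig))
        if np.ptp(lp_orig) > 0:
            a_i, b_i = sm.Logit(y.astype(float), sm.add_constant(lp_orig)).fit(
                **_FIT_KW).params
            intercepts.append(a_i)
            slopes.append(b_i)
    slope = float(np.mean(slopes))
    a_bar = float(np.mean(intercepts))
    emax = float(np.max(np.abs(expit(lp_app) - expit(a_bar + slope * lp_app))))
    return ValidationMetrics(
        c_apparent=float(c_app),
        c_corrected=float(c_app - np.mean(opt_c)),
        calibration_slope=slope,
        emax=emax,
        g_apparent=float(g_app),
        g_corrected=float(g_app - np.mean(opt_g)),
        n_boot=n_boot,
        n_redrawn=failures,
    )
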