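"""Mortality model: metrics, selection, EPV, recovery and optimism bootstrap."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from shockmetab import (
    MortalityModel,
    backward_eliminate,
    bootstrap_validate,
    calibration_metrics,
    concordance_index,
    gini_mean_difference,
    univariate_screen,
)
from shockmetab.simulate import MortalityLogit, default_spec, simulate_cohort


def _clinical_sim(n, rng, logit=None, offsets=(1.45, 1.35, 0.0)):
    """Clinical-only cohort drawn from the generator's mortality logit."""
    logit = logit or MortalityLogit(offsets={"A": offsets[0], "B": offsets[1],
                                             "C": offsets[2]})
    labels = rng.choice(list("ABC"), size=n, p=[13 / 60, 24 / 60, 23 / 60])
    apache = np.round(rng.normal([{"A": 29, "B": 25, "C": 22}[l] for l in labels], 5.0))
    organ = rng.binomial(6, [{"A": 0.5, "B": 0.42, "C": 0.33}[l] for l in labels])
    lp = logit.linear_predictor(labels, apache, organ)
    death = rng.random(n) < expit(lp)
    return pd.DataFrame({
        "cluster": labels, "apache2": apache,
        "n_organ_failures": organ, "hospital_death": death,
    })


# ---------------------------------------------------------------------------
# elementary metrics


def test_concordance_hand_count_and_limits():
    assert concordance_index([.2, .6, .4, .8], [0, 0, 1, 1]) == 0.75
    assert concordance_index([.1, .2, .8, .9], [0, 0, 1, 1]) == 1.0
    assert concordance_index([.5, .5, .5, .5], [0, 0, 1, 1]) == 0.5
    with pytest.raises(ValueError):
        concordance_index([.1, .2], [1, 1])


def test_concordance_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    p = rng.random(40)
    y = rng.random(40) < p
    if y.all() or not y.any():
        y[0] = ~y[0]
    base = concordance_index(p, y)
    for f in (np.exp, lambda x: x**3 + x, lambda x: 10 * x - 4):
        assert concordance_index(f(p), y) == pytest.approx(base, abs=1e-12)


def test_gini_mean_difference_values_and_scaling():
    assert gini_mean_difference([3.0, 3.0, 3.0]) == 0.0
    assert gini_mean_difference([0.0, 1.0]) == 1.0
    assert gini_mean_difference([0.0, 1.0, 2.0]) == pytest.approx(4 / 3)
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    g = gini_mean_difference(x)
    for c in (-2.5, 0.3, 7.0):
        assert gini_mean_difference(c * x) == pytest.approx(abs(c) * g, rel=1e-12)


def test_calibration_self_refit_identity_and_halving():
    rng = np.random.default_rng(2)
    n = 500
    lp = rng.normal(0, 1.5, n)
    y = rng.random(n) < expit(lp)
    # refit on a model's own ML predictions: slope 1, Emax 0
    import statsmodels.api as sm

    fit = sm.Logit(y.astype(float), sm.add_constant(lp)).fit(disp=0)
    lp_fit = fit.params[0] + fit.params[1] * lp
    slope, emax = calibration_metrics(lp_fit, y)
    assert slope == pytest.approx(1.0, abs=1e-6)
    assert emax == pytest.approx(0.0, abs=1e-6)
    # halving the predictor exactly doubles the slope (reparametrization)
    slope_half, _ = calibration_metrics(lp_fit / 2, y)
    assert slope_half == pytest.approx(2.0, abs=1e-6)
    # anti-predictive predictor: negative slope
    slope_neg, _ = calibration_metrics(-lp_fit, y)
    assert slope_neg == pytest.approx(-1.0, abs=1e-6)
    with pytest.raises(ValueError):
        calibration_metrics(np.zeros(n), y)


# ---------------------------------------------------------------------------
# selection


def test_univariate_screen_vacuous_and_separation():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "x1": rng.normal(size=40),
        "x2": rng.normal(size=40),
    })
    y = rng.random(40) < 0.4
    kept, flagged = univariate_screen(df, y, alpha=1.0)
    assert set(kept) == {"x1", "x2"}
    df["mirror"] = y.astype(float)  # equals the outcome: perfect separation
    kept, flagged = univariate_screen(df, y, alpha=0.1)
    assert "mirror" in flagged and "mirror" in kept


def test_univariate_screen_type_I_rate():
    """A null covariate passes the p<alpha screen in about alpha of draws."""
    rng = np.random.default_rng(4)
    alpha, reps, n = 0.10, 400, 100
    hits = 0
    for _ in range(reps):
        df = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.random(n) < 0.3
        if y.all() or not y.any():
            continue
        kept, _ = univariate_screen(df, y, alpha=alpha)
        hits += "x" in kept
    rate = hits / reps
    se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rate - alpha) < 3 * se


def test_backward_elimination_drops_noise_first():
    rng = np.random.default_rng(5)
    n = 300
    x_true = rng.normal(size=n)
    x_noise = rng.normal(size=n)
    y = rng.random(n) < expit(1.5 * x_true)
    df = pd.DataFrame({"signal": x_true, "noise": x_noise})
    final = backward_eliminate(["signal", "noise"], df, y, keep_alpha=0.05)
    assert final == ["signal"]
    # fixed point: everything already significant stays
    assert backward_eliminate(["signal"], df, y, keep_alpha=0.05) == ["signal"]
    # forcing keeps terms regardless of p
    assert set(backward_eliminate(["signal", "noise"], df, y, keep_alpha=0.05,
                                  forced=("noise", "signal"))) == {"signal", "noise"}


def test_categorical_block_handled_jointly():
    rng = np.random.default_rng(6)
    df = _clinical_sim(400, rng)
    y = df["hospital_death"]
    final = backward_eliminate(["cluster", "apache2", "n_organ_failures"],
                               df, y, keep_alpha=0.05, forced=())
    assert "cluster" in final  # strong planted cluster effect survives


# ---------------------------------------------------------------------------
# final model


def test_epv_exact_rational():
    rng = np.random.default_rng(7)
    df = _clinical_sim(60, rng)
    # force exactly 18 events for the events-per-variable bookkeeping
    death = np.zeros(60, dtype=bool)
    order = np.argsort(-df["apache2"].to_numpy())
    death[order[:18]] = True
    df["hospital_death"] = death
    fit = MortalityModel(df).fit()
    assert fit.model_df == 4  # 2-df cluster block + 2 continuous terms
    assert fit.epv == Fraction(18, 4)
    assert float(fit.epv) == 4.5


def test_zero_events_rejected():
    rng = np.random.default_rng(8)
    df = _clinical_sim(30, rng)
    df["hospital_death"] = False
    with pytest.raises(ValueError):
        MortalityModel(df).fit()


def test_reference_level_is_lowest_risk_cluster():
    rng = np.random.default_rng(9)
    df = _clinical_sim(500, rng)
    fit = MortalityModel(df).fit()
    assert fit.model.reference["cluster"] == "C"
    ors = fit.odds_ratios()
    assert ors.loc["cluster[A]", "OR"] > 1
    assert ors.loc["cluster[B]", "OR"] > 1


def test_parameter_recovery_large_sample():
    """Standardized coefficients recovered within 3 SE of the generating
    logit at n = 5000 (cluster offsets are scale-free; continuous terms
    rescale by sample SD / generator scale)."""
    rng = np.random.default_rng(10)
    df = _clinical_sim(5000, rng)
    fit = MortalityModel(df, reference={"cluster": "C"}).fit()
    truth = {
        "cluster[A]": 1.45,
        "cluster[B]": 1.35,
        "apache2": 0.5 * df["apache2"].std(ddof=1) / 5.5,
        "n_organ_failures": 0.5 * df["n_organ_failures"].std(ddof=1) / 1.3,
    }
    for term, true_val in truth.items():
        est, se = fit.params[term], fit._res.bse[term]
        assert abs(est - true_val) < 3 * se, (term, est, true_val, se)


def test_ci_coverage_near_nominal():
    """95% Wald CIs for the APACHE II coefficient cover the truth at the
    nominal rate (within 3 SE over replicates) at n = 500."""
    rng = np.random.default_rng(11)
    reps, covered, used = 250, 0, 0
    for _ in range(reps):
        df = _clinical_sim(500, rng)
        try:
            fit = MortalityModel(df, reference={"cluster": "C"}).fit()
        except (ValueError, RuntimeError):
            continue
        truth = 0.5 * df["apache2"].std(ddof=1) / 5.5
        lo, hi = fit.conf_int().loc["apache2"]
        used += 1
        covered += lo <= truth <= hi
    rate = covered / used
    se = np.sqrt(0.95 * 0.05 / used)
    assert abs(rate - 0.95) < 3 * se, rate


# ---------------------------------------------------------------------------
# bootstrap validation


def test_identity_resample_gives_zero_optimism():
    rng = np.random.default_rng(12)
    df = _clinical_sim(200, rng)
    fit = MortalityModel(df).fit()
    val = bootstrap_validate(fit, n_boot=1, seed=0,
                             resampler=lambda rng_, n: np.arange(n))
    assert val.c_corrected == pytest.approx(val.c_apparent, abs=1e-12)
    assert val.g_corrected == pytest.approx(val.g_apparent, abs=1e-10)
    assert val.calibration_slope == pytest.approx(1.0, abs=1e-6)
    assert val.emax == pytest.approx(0.0, abs=1e-6)


def test_optimism_vanishes_at_large_n():
    rng = np.random.default_rng(13)
    df = _clinical_sim(100_000, rng)
    fit = MortalityModel(df, reference={"cluster": "C"}).fit()
    val = fit.validate(n_boot=15, seed=1)
    assert abs(val.c_corrected - val.c_apparent) < 0.005
    assert val.calibration_slope == pytest.approx(1.0, abs=0.02)


def test_small_sample_overfitting_direction():
    """At study scale (n=60, ~18 events, 4 df) the corrected c-index falls
    below the apparent one and the calibration slope shrinks below 1."""
    rng = np.random.default_rng(14)
    d_c, slopes = [], []
    seeds_used = 0
    for _ in range(40):
        df = _clinical_sim(60, rng)
        ev = int(df["hospital_death"].sum())
        if ev < 5 or ev > 55:
            continue
        try:
            fit = MortalityModel(df).fit()
            val = fit.validate(n_boot=40, seed=int(rng.integers(2**31)))
        except (ValueError, RuntimeError):
            continue
        seeds_used += 1
        d_c.append(val.c_apparent - val.c_corrected)
        slopes.append(val.calibration_slope)
    assert seeds_used >= 25
    assert np.median(d_c) > 0
    assert np.median(slopes) < 1
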