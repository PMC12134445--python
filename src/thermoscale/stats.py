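"""Regression fits and evaluations for rescaled heating tolerance.

Covers: concordance of the rescaled budget across acclimation temperatures
(log10 scale), observed-vs-estimated prediction regressions, power-law fits
of the budget against normalised heating rate (pooled, per-species, and
random-slopes mixed model), pairwise cross-rate prediction evaluation, and
an activation-energy sensitivity sweep.

All fits run on pandas DataFrames with the canonical column names produced
by :mod:`thermoscale.io` and :mod:`thermoscale.synthetic`:

* paired table: ``species, ta_low, tc_low, ta_high, tc_high, heating_rate``
* rate table:   ``species, ta, heating_rate, tc``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import (
    DEFAULT_CONSTANTS,
    HeatingAssay,
    RescaledTolerance,
    ThermalConstants,
    invert_critical_temperature,
    predict_heating_tolerance,
    rate_transfer,
    rescaled_tolerance,
)

__all__ = [
    "OlsResult",
    "ConcordanceResult",
    "PowerLawFit",
    "PredictionRecord",
    "ols_fit",
    "paired_concordance",
    "evaluate_predictions",
    "fit_power_law_pooled",
    "fit_power_law_by_species",
    "fit_random_slopes",
    "cross_rate_prediction_eval",
    "sensitivity_activation_energy",
    "paired_rescaled_tolerances",
    "predict_paired",
]


@dataclass(frozen=True)
class OlsResult:
    """Slope, intercept, coefficient of determination and sample size of a
    simple ordinary-least-squares regression."""

    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class ConcordanceResult(OlsResult):
    """OLS of log10 high-acclimation budget on log10 low-acclimation budget,
    plus the mean absolute log10 deviation from the identity line."""

    identity_mad: float = float("nan")


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of dt_r(lam) ~ c * lam^{-gamma} on log10-log10 axes.

    ``slope`` is the raw regression slope (negative when the budget falls
    with rate); ``gamma = -slope`` is stored positive under that sign
    convention.  ``scope`` records which estimator produced it.
    """

    prefactor: float
    gamma: float
    slope: float
    scope: Literal["pooled", "pooled-intercepts", "per-species", "random-slopes"]
    r_squared: float
    n: int
    species_id: str | None = None
    warning: str | None = None


@dataclass(frozen=True)
class PredictionRecord:
    """One observed/estimated heating-tolerance pair."""

    species_id: str
    observed: float
    estimated: float
    direction: str


def ols_fit(x: Sequence[float], y: Sequence[float]) -> OlsResult:
    """Simple OLS of y on x via statsmodels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is unidentifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    r2 = float(model.rsquared)
    if not np.isfinite(r2):  # SST == 0 (constant y fitted exactly)
        r2 = 0.0
    return OlsResult(slope=float(slope), intercept=float(intercept),
                     r_squared=r2, n=int(x.size))


def paired_concordance(dtr_low: Sequence[float],
                       dtr_high: Sequence[float]) -> ConcordanceResult:
    """Concordance of the rescaled budget across acclimation temperatures.

    Regresses log10(dt_r at high T_a) on log10(dt_r at low T_a); under
    perfect budget conservation the points sit on the identity line (slope
    1, R^2 = 1, zero mean absolute deviation).
    """
    low = np.asarray(dtr_low, dtype=float)
    high = np.asarray(dtr_high, dtype=float)
    if low.shape != high.shape:
        raise ValueError("paired arrays must have equal length")
    if np.any(low <= 0) or np.any(high <= 0):
        raise ValueError("rescaled tolerances must be positive for log10 analysis")
    if low.size < 2:
        raise ValueError("need at least 2 species pairs")
    base = ols_fit(np.log10(low), np.log10(high))
    mad = float(np.mean(np.abs(np.log10(high) - np.log10(low))))
    return ConcordanceResult(slope=base.slope, intercept=base.intercept,
                             r_squared=base.r_squared, n=base.n,
                             identity_mad=mad)


def evaluate_predictions(records: Iterable[PredictionRecord],
                         log_scale: bool = False) -> OlsResult:
    """OLS of observed heating tolerance (y) on estimated (x).

    ``log_scale=True`` switches both axes to log10.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 prediction records")
    obs = np.array([r.observed for r in records], dtype=float)
    est = np.array([r.estimated for r in records], dtype=float)
    if log_scale:
        if np.any(obs <= 0) or np.any(est <= 0):
            raise ValueError("log10 evaluation requires positive tolerances")
        obs, est = np.log10(obs), np.log10(est)
    return ols_fit(est, obs)


def _prepare_loglog(records: pd.DataFrame) -> pd.DataFrame:
    """Validate and log10-transform a (species, lam, dtr) table, averaging
    duplicate (species, lam) records on the log10 dt_r scale."""
    df = records.copy()
    required = {"species", "lam", "dtr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if np.any(df["lam"] <= 0) or np.any(df["dtr"] <= 0):
        raise ValueError("lam and dtr must be positive")
    df["log_lam"] = np.log10(df["lam"])
    df["log_dtr"] = np.log10(df["dtr"])
    df = (df.groupby(["species", "log_lam"], as_index=False)["log_dtr"]
            .mean())
    return df


def fit_power_law_pooled(records: pd.DataFrame,
                         species_intercepts: bool = True) -> PowerLawFit:
    """Common power-law exponent across species.

    With ``species_intercepts=True`` (default) each species gets its own
    intercept and the slope is shared — species with a single record still
    inform the intercept, not the slope.  With ``False`` a single pooled
    line is fitted.  ``gamma`` is minus the fitted slope; the prefactor is
    10**(mean intercept), i.e. the geometric-mean budget at lam = 1.
    """
    df = _prepare_loglog(records)
    if df["log_lam"].nunique() < 2:
        raise ValueError("need at least 2 distinct rates overall")
    n_species = df["species"].nunique()
    if species_intercepts:
        if len(df) <= n_species:
            raise ValueError(
                "all species are singletons: slope is unidentifiable")
        model = smf.ols("log_dtr ~ log_lam + C(species)", data=df).fit()
        slope = float(model.params["log_lam"])
        # Intercept + mean of species offsets relative to the base level
        mean_intercept = float(model.params["Intercept"]
                               + np.mean([v for k, v in model.params.items()
                                          if k.startswith("C(species)")] or [0.0]))
        scope = "pooled-intercepts"
    else:
        model = smf.ols("log_dtr ~ log_lam", data=df).fit()
        slope = float(model.params["log_lam"])
        mean_intercept = float(model.params["Intercept"])
        scope = "pooled"
    r2 = float(model.rsquared)
    return PowerLawFit(prefactor=10.0 ** mean_intercept, gamma=-slope,
                       slope=slope, scope=scope, r_squared=r2, n=len(df))


def fit_power_law_by_species(records: pd.DataFrame,
                             min_distinct_rates: int = 3
                             ) -> tuple[list[PowerLawFit], pd.DataFrame]:
    """Independent log10-log10 OLS per species.

    Species with fewer than ``min_distinct_rates`` distinct rates are not
    fitted; they are returned in the exclusion report, never silently
    dropped.  Returns ``(fits, exclusions)`` where exclusions is a
    DataFrame with columns ``species, n_distinct_rates, reason``.
    """
    df = _prepare_loglog(records)
    fits: list[PowerLawFit] = []
    excluded = []
    for species, grp in df.groupby("species", sort=True):
        n_rates = grp["log_lam"].nunique()
        if n_rates < min_distinct_rates:
            excluded.append({"species": species, "n_distinct_rates": n_rates,
                             "reason": f"fewer than {min_distinct_rates} distinct rates"})
            continue
        res = ols_fit(grp["log_lam"].to_numpy(), grp["log_dtr"].to_numpy())
        fits.append(PowerLawFit(prefactor=10.0 ** res.intercept,
                                gamma=-res.slope, slope=res.slope,
                                scope="per-species", r_squared=res.r_squared,
                                n=res.n, species_id=str(species)))
    exclusions = pd.DataFrame(excluded,
                              columns=["species", "n_distinct_rates", "reason"])
    return fits, exclusions


def fit_random_slopes(records: pd.DataFrame) -> PowerLawFit:
    """Hierarchical power-law fit: per-species random intercepts and random
    slopes around a fixed-effect slope, by REML.

    On a singular or non-converged fit the estimator falls back to the mean
    of per-species OLS slopes (two-stage estimate) and tags the result with
    a warning.
    """
    df = _prepare_loglog(records)
    per_species_rates = df.groupby("species")["log_lam"].nunique()
    if (per_species_rates >= 2).sum() < 3:
        raise ValueError("need at least 3 species with at least 2 rates each")

    result = None
    warning = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm("log_dtr ~ log_lam", data=df,
                                groups=df["species"],
                                re_formula="~log_lam")
            fitted = model.fit(reml=True, method="lbfgs", maxiter=500)
            cov_re = np.asarray(fitted.cov_re, dtype=float)
            singular = (not fitted.converged
                        or not np.all(np.isfinite(fitted.params))
                        or fitted.scale < 1e-10  # zero residual noise
                        or np.any(np.diag(cov_re) < 1e-10))
            if not singular:
                result = fitted
        except (np.linalg.LinAlgError, ValueError):
            result = None

    if result is not None:
        slope = float(result.fe_params["log_lam"])
        intercept = float(result.fe_params["Intercept"])
        fitted_vals = np.asarray(result.fittedvalues, dtype=float)
        ss_res = float(np.sum((df["log_dtr"].to_numpy() - fitted_vals) ** 2))
        ss_tot = float(np.sum((df["log_dtr"] - df["log_dtr"].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    else:
        fits, _ = fit_power_law_by_species(records, min_distinct_rates=2)
        if not fits:
            raise ValueError("random-slopes fallback found no fittable species")
        slope = float(np.mean([f.slope for f in fits]))
        intercept = float(np.mean([np.log10(f.prefactor) for f in fits]))
        r2 = float("nan")
        warning = "singular mixed-model fit; fell back to mean of per-species slopes"
    return PowerLawFit(prefactor=10.0 ** intercept, gamma=-slope, slope=slope,
                       scope="random-slopes", r_squared=r2, n=len(df),
                       warning=warning)


def cross_rate_prediction_eval(rate_table: pd.DataFrame,
                               gamma_mode: Literal["species", "pooled"] = "species",
                               constants: ThermalConstants = DEFAULT_CONSTANTS,
                               min_distinct_rates: int = 3
                               ) -> tuple[list[PredictionRecord], OlsResult]:
    """Pairwise cross-rate prediction within species.

    For every ordered pair of distinct rates (v1, v2) in a species: the
    budget measured at v1 is transferred to v2 by the power law and
    inverted to a predicted T_c, giving an estimated heating tolerance that
    is regressed (observed on estimated) across all pairs.

    ``gamma_mode="species"`` uses each species' own fitted exponent;
    ``"pooled"`` uses the common species-intercept exponent for everyone.
    """
    df = rate_table.copy()
    df["dtr"] = [
        rescaled_tolerance(HeatingAssay(str(s), ta, tc, v), constants).value
        for s, ta, tc, v in zip(df["species"], df["ta"], df["tc"], df["heating_rate"])
    ]
    df["lam"] = df["heating_rate"] / constants.reference_temp
    loglog = df[["species", "lam", "dtr"]]

    if gamma_mode == "pooled":
        pooled = fit_power_law_pooled(loglog)
        gamma_of = {s: pooled.gamma for s in df["species"].unique()}
    elif gamma_mode == "species":
        fits, _ = fit_power_law_by_species(loglog,
                                           min_distinct_rates=min_distinct_rates)
        gamma_of = {f.species_id: f.gamma for f in fits}
    else:
        raise ValueError(f"unknown gamma_mode: {gamma_mode!r}")

    records: list[PredictionRecord] = []
    # one budget per (species, rate): duplicates averaged on log10 dt_r
    agg = (df.assign(log_dtr=np.log10(df["dtr"]))
             .groupby(["species", "heating_rate"], as_index=False)
             .agg(ta=("ta", "mean"), log_dtr=("log_dtr", "mean")))
    agg["dtr"] = 10.0 ** agg["log_dtr"]
    for species, grp in agg.groupby("species", sort=True):
        gamma = gamma_of.get(species)
        if gamma is None:
            continue
        rows = list(grp.itertuples())
        for a in rows:
            for b in rows:
                if a.heating_rate == b.heating_rate:
                    continue
                budget1 = RescaledTolerance(
                    value=a.dtr, beta_used=constants.beta,
                    lambda_used=a.heating_rate / constants.reference_temp)
                budget2 = rate_transfer(budget1, a.heating_rate, b.heating_rate, gamma)
                tc_pred = invert_critical_temperature(b.ta, b.heating_rate,
                                                      budget2, constants)
                tc_obs = invert_critical_temperature(b.ta, b.heating_rate,
                                                     b.dtr, constants)
                records.append(PredictionRecord(
                    species_id=str(species),
                    observed=tc_obs - b.ta,
                    estimated=tc_pred - b.ta,
                    direction=f"{a.heating_rate}->{b.heating_rate}"))
    if len(records) < 2:
        raise ValueError("not enough rate pairs for evaluation")
    return records, evaluate_predictions(records)


def paired_rescaled_tolerances(paired: pd.DataFrame,
                               constants: ThermalConstants = DEFAULT_CONSTANTS
                               ) -> pd.DataFrame:
    """Per-species rescaled budgets at the low and high acclimation
    temperature (columns ``dtr_low``, ``dtr_high`` appended)."""
    out = paired.copy()
    out["dtr_low"] = [
        rescaled_tolerance(HeatingAssay(str(s), ta, tc, v), constants).value
        for s, ta, tc, v in zip(out["species"], out["ta_low"], out["tc_low"],
                                out["heating_rate"])
    ]
    out["dtr_high"] = [
        rescaled_tolerance(HeatingAssay(str(s), ta, tc, v), constants).value
        for s, ta, tc, v in zip(out["species"], out["ta_high"], out["tc_high"],
                                out["heating_rate"])
    ]
    return out


def predict_paired(paired: pd.DataFrame,
                   direction: Literal["low_to_high", "high_to_low"],
                   constants: ThermalConstants = DEFAULT_CONSTANTS
                   ) -> list[PredictionRecord]:
    """Predict heating tolerance at one acclimation temperature from the
    measured tolerance at the other, assuming a conserved budget."""
    if direction == "low_to_high":
        src_ta, src_tc, dst_ta, dst_tc = "ta_low", "tc_low", "ta_high", "tc_high"
    elif direction == "high_to_low":
        src_ta, src_tc, dst_ta, dst_tc = "ta_high", "tc_high", "ta_low", "tc_low"
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    records = []
    for row in paired.itertuples():
        h1 = getattr(row, src_tc) - getattr(row, src_ta)
        h2_est = predict_heating_tolerance(h1, getattr(row, src_ta),
                                           getattr(row, dst_ta), constants)
        h2_obs = getattr(row, dst_tc) - getattr(row, dst_ta)
        records.append(PredictionRecord(species_id=str(row.species),
                                        observed=h2_obs, estimated=h2_est,
                                        direction=direction))
    return records


def sensitivity_activation_energy(paired: pd.DataFrame,
                                  e_grid: Sequence[float],
                                  constants: ThermalConstants = DEFAULT_CONSTANTS
                                  ) -> pd.DataFrame:
    """Re-run the concordance and prediction pipeline over a grid of
    activation energies.

    The E = 0 row is the unscaled analysis (beta = 0: the budget is the
    plain assay duration).  A flat profile over realistic E demonstrates
    the analysis is insensitive to the exact activation energy.
    """
    rows = []
    for e in e_grid:
        if e < 0:
            raise ValueError(f"activation energy must be non-negative, got {e}")
        consts = constants.with_activation_energy(e)
        with_budgets = paired_rescaled_tolerances(paired, consts)
        conc = paired_concordance(with_budgets["dtr_low"], with_budgets["dtr_high"])
        pred_lh = evaluate_predictions(predict_paired(paired, "low_to_high", consts))
        pred_hl = evaluate_predictions(predict_paired(paired, "high_to_low", consts))
        rows.append({
            "activation_energy": e,
            "beta": consts.beta,
            "concordance_slope": conc.slope,
            "concordance_r2": conc.r_squared,
            "identity_mad": conc.identity_mad,
            "pred_slope_low_to_high": pred_lh.slope,
            "pred_r2_low_to_high": pred_lh.r_squared,
            "pred_slope_high_to_low": pred_hl.slope,
            "pred_r2_high_to_low": pred_hl.r_squared,
        })
    return pd.DataFrame(rows)
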