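"""Closed-form mathematics of metabolically rescaled heating tolerance.

During a ramping assay an ectotherm is heated at a constant rate from its
acclimation temperature ``T_a`` until physiological collapse at the critical
temperature ``T_c``.  Biological rates rise roughly exponentially with
temperature (Arrhenius scaling ~ e^{-E/kT}); near a reference temperature
``T_K`` this is well approximated by ``e^{beta * tau}`` with the
dimensionless temperature ``tau = T_celsius / T_K`` and
``beta = E / (k * T_K)``.

The rescaled heating tolerance ``dt_r`` is the integral of that exponential
rate over the ramp — a cumulative "metabolic currency" spent before
collapse.  For a constant heating rate ``v`` (normalised rate
``lam = v / T_K``) the integral has the closed form

    dt_r = (e^{beta * tau_c} - e^{beta * tau_a}) / (beta * lam)

The central empirical claim this package operationalises is that ``dt_r``
is conserved within a species across acclimation temperatures, which turns
a single measured assay into a predictor of ``T_c`` at any other
acclimation temperature and (via a power law in the heating rate) at any
other ramp speed.

All public interfaces use degrees Celsius, minutes, and °C/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ThermalConstants",
    "HeatingAssay",
    "RescaledTolerance",
    "TemperatureTrajectory",
    "DEFAULT_CONSTANTS",
    "compute_beta",
    "normalize_temperature",
    "from_normalized",
    "heating_tolerance",
    "rescaled_tolerance",
    "rescaled_tolerance_trajectory",
    "predict_heating_tolerance",
    "invert_critical_temperature",
    "rate_transfer",
    "predict_tc_surface",
    "acclimation_response_ratio",
]

#: Boltzmann's constant in eV/K (CODATA).
BOLTZMANN_EV = 8.617333262e-5

#: Reference temperature in Kelvin; tau = T_celsius / T_K is dimensionless.
REFERENCE_TEMP_K = 273.15

#: Default organism-level activation energy in eV.
DEFAULT_ACTIVATION_ENERGY = 0.66


def compute_beta(activation_energy: float = DEFAULT_ACTIVATION_ENERGY,
                 boltzmann: float = BOLTZMANN_EV,
                 reference_temp: float = REFERENCE_TEMP_K) -> float:
    """Dimensionless exponent beta = E / (k * T_K).

    With the defaults (E = 0.66 eV, k = 8.617333262e-5 eV/K,
    T_K = 273.15 K) this is ~28.04.
    """
    if boltzmann <= 0:
        raise ValueError(f"Boltzmann constant must be positive, got {boltzmann}")
    if reference_temp <= 0:
        raise ValueError(f"reference temperature must be positive, got {reference_temp}")
    if activation_energy < 0:
        raise ValueError(f"activation energy must be non-negative, got {activation_energy}")
    return activation_energy / (boltzmann * reference_temp)


@dataclass(frozen=True)
class ThermalConstants:
    """Arrhenius constants and the derived exponent beta.

    Parameters
    ----------
    activation_energy : float
        Organism-level activation energy E in eV.  0.66 eV describes the
        temperature dependence of most biological rates.
    boltzmann : float
        Boltzmann's constant k in eV/K.
    reference_temp : float
        Normalisation temperature T_K in Kelvin (273.15 = ~0 °C); divides
        Celsius temperatures to give the dimensionless tau.
    """

    activation_energy: float = DEFAULT_ACTIVATION_ENERGY
    boltzmann: float = BOLTZMANN_EV
    reference_temp: float = REFERENCE_TEMP_K
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "beta",
            compute_beta(self.activation_energy, self.boltzmann, self.reference_temp),
        )

    def with_activation_energy(self, activation_energy: float) -> "ThermalConstants":
        """Same k and T_K, different E (used by the sensitivity sweep)."""
        return ThermalConstants(activation_energy=activation_energy,
                                boltzmann=self.boltzmann,
                                reference_temp=self.reference_temp)


DEFAULT_CONSTANTS = ThermalConstants()


def normalize_temperature(t_celsius: float,
                          constants: ThermalConstants = DEFAULT_CONSTANTS) -> float:
    """tau = T_celsius / T_K; dimensionless."""
    return t_celsius / constants.reference_temp


def from_normalized(tau: float,
                    constants: ThermalConstants = DEFAULT_CONSTANTS) -> float:
    """Inverse of :func:`normalize_temperature`: T_celsius = tau * T_K."""
    return tau * constants.reference_temp


def heating_tolerance(t_acclimation: float, t_critical: float) -> float:
    """Heating tolerance H = T_c - T_a in °C.

    Raises ``ValueError`` if T_c < T_a (the assay is invalid: the ramp
    never reaches the recorded endpoint).
    """
    if t_critical < t_acclimation:
        raise ValueError(
            f"critical temperature {t_critical} °C below acclimation "
            f"temperature {t_acclimation} °C: invalid assay")
    return t_critical - t_acclimation


@dataclass(frozen=True)
class HeatingAssay:
    """One constant-rate ramping trial.

    Attributes
    ----------
    species_id : str
        Label of the species (or experimental unit).
    acclimation_temp : float
        Starting/holding temperature T_a in °C.
    critical_temp : float
        Endpoint temperature T_c in °C at physiological collapse.
    heating_rate : float
        Constant ramp speed v in °C/min; must be positive.
    """

    species_id: str
    acclimation_temp: float
    critical_temp: float
    heating_rate: float

    def __post_init__(self) -> None:
        if self.heating_rate <= 0:
            raise ValueError(
                f"heating rate must be positive, got {self.heating_rate} °C/min")
        # heating_tolerance raises on T_c < T_a
        heating_tolerance(self.acclimation_temp, self.critical_temp)

    @property
    def tolerance(self) -> float:
        """H = T_c - T_a (°C)."""
        return self.critical_temp - self.acclimation_temp

    @property
    def duration(self) -> float:
        """Unscaled assay duration dt = H / v (min)."""
        return self.tolerance / self.heating_rate

    @property
    def is_degenerate(self) -> bool:
        """True when T_c == T_a (zero-span assay; dt_r = 0, kept but flagged)."""
        return self.critical_temp == self.acclimation_temp

    def normalized_rate(self, constants: ThermalConstants = DEFAULT_CONSTANTS) -> float:
        """lam = v / T_K (min^-1)."""
        return self.heating_rate / constants.reference_temp


@dataclass(frozen=True)
class RescaledTolerance:
    """A rescaled heating tolerance dt_r with the inputs used to compute it.

    ``value`` is in rate-weighted minutes: minutes weighted by the
    dimensionless Arrhenius factor e^{beta * tau}.
    """

    value: float
    beta_used: float
    lambda_used: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"rescaled tolerance must be non-negative, got {self.value}")


@dataclass(frozen=True)
class TemperatureTrajectory:
    """Sampled temperature profile of a (possibly non-linear) ramp.

    ``times`` in minutes, strictly increasing; ``temps`` in °C.  Between
    samples the temperature is treated as piecewise linear.
    """

    times: tuple
    temps: tuple

    def __init__(self, times: Sequence[float], temps: Sequence[float]):
        times = tuple(float(t) for t in times)
        temps = tuple(float(x) for x in temps)
        if len(times) != len(temps):
            raise ValueError("times and temps must have equal length")
        if len(times) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)


def _segment_integral(t0: float, t1: float, temp0: float, temp1: float,
                      constants: ThermalConstants) -> float:
    """Exact integral of e^{beta*tau(t)} over one linear segment."""
    beta = constants.beta
    dt = t1 - t0
    if beta == 0.0:
        return dt
    tau0 = temp0 / constants.reference_temp
    tau1 = temp1 / constants.reference_temp
    if temp1 == temp0:
        return dt * math.exp(beta * tau0)
    # (e^{b*tau1} - e^{b*tau0}) / (b * lam) with lam = (tau1 - tau0) / dt;
    # expm1 keeps accuracy as beta*(tau1 - tau0) -> 0 and the form is valid
    # for cooling segments too (numerator and lam change sign together).
    lam = (tau1 - tau0) / dt
    return math.exp(beta * tau0) * math.expm1(beta * (tau1 - tau0)) / (beta * lam)


def rescaled_tolerance(assay: HeatingAssay,
                       constants: ThermalConstants = DEFAULT_CONSTANTS) -> RescaledTolerance:
    """Rescaled heating tolerance of a constant-rate assay (closed form).

    dt_r = (e^{beta*tau_c} - e^{beta*tau_a}) / (beta * lam); in the
    beta -> 0 limit this reduces to the unscaled duration H / v.
    """
    lam = assay.normalized_rate(constants)
    if assay.is_degenerate:
        value = 0.0
    else:
        value = _segment_integral(0.0, assay.duration,
                                  assay.acclimation_temp, assay.critical_temp,
                                  constants)
    return RescaledTolerance(value=value, beta_used=constants.beta, lambda_used=lam)


def rescaled_tolerance_trajectory(trajectory: TemperatureTrajectory,
                                  constants: ThermalConstants = DEFAULT_CONSTANTS
                                  ) -> RescaledTolerance:
    """dt_r for an arbitrary sampled trajectory.

    The profile is interpolated piecewise-linearly between samples and each
    linear piece is integrated exactly by the constant-rate closed form, so
    the only approximation is the interpolation itself.
    """
    total = 0.0
    for (t0, t1), (x0, x1) in zip(zip(trajectory.times, trajectory.times[1:]),
                                  zip(trajectory.temps, trajectory.temps[1:])):
        total += _segment_integral(t0, t1, x0, x1, constants)
    span = trajectory.times[-1] - trajectory.times[0]
    # mean normalised rate over the trajectory, for provenance only
    lam = ((trajectory.temps[-1] - trajectory.temps[0]) / span
           / constants.reference_temp)
    return RescaledTolerance(value=total, beta_used=constants.beta, lambda_used=lam)


def _log_expm1(x: float) -> float:
    """log(e^x - 1), stable for large x."""
    if x <= 0:
        raise ValueError("log(expm1(x)) requires x > 0")
    if x > 33:  # e^{-x} below double-precision epsilon of 1
        return x + math.log1p(-math.exp(-x))
    return math.log(math.expm1(x))


def predict_heating_tolerance(h1: float, t_a1: float, t_a2: float,
                              constants: ThermalConstants = DEFAULT_CONSTANTS) -> float:
    """Heating tolerance at acclimation temperature ``t_a2`` predicted from
    a measured tolerance ``h1`` at ``t_a1``, assuming the rescaled budget is
    conserved and the constant heating rate is shared (it cancels).

    H2 = (T_K / beta) * ln(1 + e^{beta*(tau_a1 - tau_a2)} * (e^{beta*H1/T_K} - 1))

    Evaluated in log space so large beta or temperature gaps cannot
    overflow.  For beta = 0 the budget is the plain duration and H2 = H1.
    """
    if h1 < 0:
        raise ValueError(f"measured heating tolerance must be non-negative, got {h1}")
    beta = constants.beta
    if beta == 0.0 or h1 == 0.0:
        return h1
    t_k = constants.reference_temp
    a = beta * (t_a1 - t_a2) / t_k + _log_expm1(beta * h1 / t_k)
    return (t_k / beta) * np.logaddexp(0.0, a)


def invert_critical_temperature(t_acclimation: float, heating_rate: float,
                                budget: RescaledTolerance | float,
                                constants: ThermalConstants = DEFAULT_CONSTANTS) -> float:
    """Critical temperature implied by a rescaled budget spent from ``t_acclimation``
    at constant ``heating_rate``.

    T_c = (T_K / beta) * ln(e^{beta*tau_a} + beta * lam * dt_r); this is the
    algebraic inverse of the constant-rate closed form, so composing it with
    :func:`rescaled_tolerance` recovers T_c.
    """
    if heating_rate <= 0:
        raise ValueError(f"heating rate must be positive, got {heating_rate} °C/min")
    value = budget.value if isinstance(budget, RescaledTolerance) else float(budget)
    if value < 0:
        raise ValueError(f"budget must be non-negative, got {value}")
    if value == 0.0:
        return t_acclimation
    beta = constants.beta
    t_k = constants.reference_temp
    lam = heating_rate / t_k
    if beta == 0.0:
        return t_acclimation + heating_rate * value
    return (t_k / beta) * np.logaddexp(beta * t_acclimation / t_k,
                                       math.log(beta * lam * value))


def rate_transfer(budget: RescaledTolerance, v1: float, v2: float,
                  gamma: float) -> RescaledTolerance:
    """Transfer a rescaled budget measured at rate ``v1`` to rate ``v2``.

    Empirically dt_r declines with normalised heating rate as a power law
    dt_r(lam) ~ c * lam^{-gamma}, so dt_r2 = dt_r1 * (lam2 / lam1)^{-gamma}.
    The normalising T_K cancels in the ratio, so raw rates can be used.
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError(f"heating rates must be positive, got v1={v1}, v2={v2}")
    factor = (v2 / v1) ** (-gamma)
    return RescaledTolerance(value=budget.value * factor,
                             beta_used=budget.beta_used,
                             lambda_used=budget.lambda_used * (v2 / v1))


def acclimation_response_ratio(t_acclimation: float, t_critical: float,
                               constants: ThermalConstants = DEFAULT_CONSTANTS) -> float:
    """Local slope dT_c/dT_a under a fixed budget: e^{beta*(tau_a - tau_c)}.

    Strictly inside (0, 1) whenever T_c > T_a and beta > 0 — the model's
    explanation for why acclimation raises heat limits only marginally.
    """
    beta = constants.beta
    t_k = constants.reference_temp
    return math.exp(beta * (t_acclimation - t_critical) / t_k)


def predict_tc_surface(anchor: HeatingAssay,
                       ta_grid: Sequence[float],
                       rate_grid: Sequence[float],
                       gamma: float = 0.76,
                       constants: ThermalConstants = DEFAULT_CONSTANTS):
    """Predicted critical temperature over a grid of acclimation
    temperatures and heating rates, anchored on one measured assay.

    The anchor's budget is computed by the closed form, transferred to each
    grid rate by the power law, and inverted to a T_c at each grid T_a.
    At the anchor's own (T_a, v) the prediction reproduces the anchor's
    T_c exactly.

    Returns a :class:`pandas.DataFrame` with columns
    ``acclimation_temp``, ``heating_rate``, ``predicted_tc``.
    """
    import pandas as pd

    if len(ta_grid) == 0 or len(rate_grid) == 0:
        raise ValueError("grids must be non-empty")
    anchor_budget = rescaled_tolerance(anchor, constants)
    rows = []
    for v in rate_grid:
        budget_v = rate_transfer(anchor_budget, anchor.heating_rate, v, gamma)
        for t_a in ta_grid:
            rows.append({
                "acclimation_temp": t_a,
                "heating_rate": v,
                "predicted_tc": invert_critical_temperature(t_a, v, budget_v, constants),
            })
    return pd.DataFrame(rows, columns=["acclimation_temp", "heating_rate", "predicted_tc"])


def replace_constants(constants: ThermalConstants, **kwargs) -> ThermalConstants:
    """dataclasses.replace that recomputes beta."""
    kwargs.pop("beta", None)
    return replace(constants, **kwargs)
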