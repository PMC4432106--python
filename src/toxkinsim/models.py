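"""Structural population PK models and concentration simulation.

Three structural models are supported, all with first-order oral
absorption from a depot compartment:

* ``ONE_CMT``    — one compartment, linear elimination (CL).
* ``ONE_CMT_MM`` — one compartment, Michaelis–Menten elimination
  (VMAX, KM); solved numerically.
* ``TWO_CMT``    — two compartments, linear elimination (CL, K12, K21).

Unit conventions: all drug amounts are normalized per kg body weight.
Doses are mg/kg, volumes ml/kg, clearances ml/h/kg, VMAX mg/h/kg, and
concentrations therefore mg/ml (so KM in mg/ml is directly comparable).
Time is in hours.

Between-subject variability (BSV) is log-normal: an individual value is
``typical * exp(eta)`` with ``eta ~ Normal(0, omega^2)`` and
``omega = CV% / 100`` (the NONMEM log-scale convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, EstimationError, InputError

__all__ = [
    "ModelId",
    "ModelSpec",
    "PopulationParameters",
    "IndividualParameters",
    "DoseRegimen",
    "model_a_population",
    "model_b_population",
    "model_c_population",
    "population_for",
    "sample_individual_params",
    "predict_concentration",
    "simulate_observations",
    "mm_state_trajectories",
]


class ModelId(str, Enum):
    ONE_CMT = "ONE_CMT"
    ONE_CMT_MM = "ONE_CMT_MM"
    TWO_CMT = "TWO_CMT"


#: structural parameters each model expects, in canonical order
MODEL_PARAMS: dict[ModelId, tuple[str, ...]] = {
    ModelId.ONE_CMT: ("KA", "V", "CL"),
    ModelId.ONE_CMT_MM: ("VMAX", "KM", "KA", "V"),
    ModelId.TWO_CMT: ("KA", "V", "CL", "K12", "K21"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Identity of a structural model; determines the parameter set."""

    model_id: ModelId

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model_id]

    def validate_params(self, values: Mapping[str, float]) -> None:
        missing = [p for p in self.param_names if p not in values]
        if missing:
            raise ConfigurationError(
                f"{self.model_id.value} requires parameters {missing}"
            )


@dataclass
class PopulationParameters:
    """Typical values, BSV (CV%), and proportional residual error.

    ``bsv_cv`` maps parameter name -> CV% on the log-normal scale;
    parameters absent from the map have no between-subject variability.
    ``sigma_prop`` is the proportional residual SD as a fraction
    (0.15 = 15 %).
    """

    theta: dict[str, float]
    bsv_cv: dict[str, float] = field(default_factory=dict)
    sigma_prop: float = 0.15

    def __post_init__(self) -> None:
        for name, value in self.theta.items():
            if not value > 0:
                raise ConfigurationError(f"typical value {name}={value} must be > 0")
        for name, cv in self.bsv_cv.items():
            if name not in self.theta:
                raise ConfigurationError(f"BSV given for unknown parameter {name!r}")
            if cv < 0:
                raise ConfigurationError(f"BSV CV% for {name} must be >= 0")
        if self.sigma_prop < 0:
            raise ConfigurationError("sigma_prop must be >= 0")

    def omega(self, name: str) -> float:
        """Log-scale SD of the random effect on ``name`` (CV%/100)."""
        return self.bsv_cv.get(name, 0.0) / 100.0

    @property
    def random_effect_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.theta if self.bsv_cv.get(n, 0.0) > 0)


@dataclass
class IndividualParameters:
    """One animal's realized parameter values."""

    animal_id: int
    values: dict[str, float]

    def __post_init__(self) -> None:
        for name, value in self.values.items():
            if not value > 0:
                raise ConfigurationError(
                    f"individual value {name}={value} must be > 0"
                )


@dataclass(frozen=True)
class DoseRegimen:
    """Repeat oral bolus dosing into the depot compartment."""

    dose: float  # mg/kg
    n_doses: int = 1
    interval: float = 24.0  # h
    start_time: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ConfigurationError("dose must be >= 0")
        if self.interval <= 0:
            raise ConfigurationError("interval must be > 0")
        if self.n_doses < 1:
            raise ConfigurationError("n_doses must be >= 1")

    def dose_times(self) -> np.ndarray:
        return self.start_time + self.interval * np.arange(self.n_doses)


# ---------------------------------------------------------------------------
# Reference populations (hypothetical NSAID-like rodent compounds)
# ---------------------------------------------------------------------------

def model_a_population(sigma_prop: float = 0.15) -> PopulationParameters:
    """One-compartment linear model: rapid absorption, t1/2 ~ 12.6 h."""
    return PopulationParameters(
        theta={"KA": 13.46, "V": 49.4, "CL": 2.72},
        bsv_cv={"KA": 50.0, "V": 16.0, "CL": 20.0},
        sigma_prop=sigma_prop,
    )


def model_b_population(sigma_prop: float = 0.15) -> PopulationParameters:
    """Michaelis–Menten elimination; saturates at the highest dose so
    dose proportionality breaks down (VMAX/KM matches model A's CL in
    the linear limit)."""
    return PopulationParameters(
        theta={"VMAX": 2.72, "KM": 1.0, "KA": 13.46, "V": 49.4},
        bsv_cv={"VMAX": 20.0, "KA": 50.0, "V": 16.0},
        sigma_prop=sigma_prop,
    )


def model_c_population(
    sigma_prop: float = 0.15, k21: float = 0.053, k21_cv: float = 2.0
) -> PopulationParameters:
    """Two-compartment model with slow absorption and a deep peripheral
    compartment: accumulation approaches steady state only after about
    two weeks of daily dosing.  K21 and its BSV are overridable."""
    return PopulationParameters(
        theta={"KA": 0.55, "V": 49.4, "CL": 2.72, "K12": 0.3, "K21": k21},
        bsv_cv={"KA": 50.0, "V": 16.0, "CL": 20.0, "K21": k21_cv},
        sigma_prop=sigma_prop,
    )


_POPULATION_FACTORY = {
    ModelId.ONE_CMT: model_a_population,
    ModelId.ONE_CMT_MM: model_b_population,
    ModelId.TWO_CMT: model_c_population,
}


def population_for(model_id: ModelId | str, **kwargs) -> PopulationParameters:
    """Reference population parameters for a model family."""
    return _POPULATION_FACTORY[ModelId(model_id)](**kwargs)


# ---------------------------------------------------------------------------
# Individual parameter sampling
# ---------------------------------------------------------------------------

def sample_individual_params(
    pop: PopulationParameters,
    n_animals: int,
    rng: int | np.random.Generator,
    first_id: int = 1,
) -> list[IndividualParameters]:
    """Draw per-animal parameters: typical * exp(eta), eta ~ N(0, omega^2).

    Parameters without BSV are identical across animals.  Reproducible
    for a fixed seed/generator.
    """
    if n_animals < 1:
        raise InputError("n_animals must be >= 1")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = []
    names = list(pop.theta)
    omegas = np.array([pop.omega(n) for n in names])
    etas = gen.standard_normal((n_animals, len(names))) * omegas
    for i in range(n_animals):
        values = {
            name: pop.theta[name] * math.exp(etas[i, j])
            for j, name in enumerate(names)
        }
        out.append(IndividualParameters(animal_id=first_id + i, values=values))
    return out


# ---------------------------------------------------------------------------
# Concentration prediction
# ---------------------------------------------------------------------------

def _phi(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, stable at x -> 0 (removable singularity)."""
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


def one_cmt_superposition(
    times: np.ndarray, dose_times: np.ndarray, dose: float,
    ka: float, v: float, ke: float,
) -> np.ndarray:
    """Multi-dose Bateman profile, stable for any ka vs ke (including
    the ka == ke limit via the phi formulation).

    Uses the symmetric form (e^{-ke d} - e^{-ka d})/(ka - ke)
    = d * e^{-min(ka,ke) d} * phi(|ka - ke| d), which never overflows."""
    delta = times[:, None] - dose_times[None, :]
    active = delta > 0
    d = np.where(active, delta, 0.0)
    m = min(ka, ke)
    term = d * np.exp(-m * d) * _phi(abs(ka - ke) * d)
    term[~active] = 0.0
    return (dose * ka / v) * term.sum(axis=1)


def _two_cmt_macro(ka: float, v: float, cl: float, k12: float, k21: float):
    """Hybrid rate constants and exponential coefficients of the oral
    two-compartment model (central-compartment concentration)."""
    k10 = cl / v
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    # guard removable coincidences that break partial fractions
    eps = 1e-9 * max(ka, alpha, 1.0)
    if abs(ka - alpha) < eps:
        alpha *= 1.0 + 1e-7
    if abs(ka - beta) < eps:
        beta *= 1.0 + 1e-7
    if abs(alpha - beta) < eps:
        beta *= 1.0 - 1e-7
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    cc = (k21 - ka) / ((alpha - ka) * (beta - ka))
    return alpha, beta, ca, cb, cc


def two_cmt_superposition(
    times: np.ndarray, dose_times: np.ndarray, dose: float,
    ka: float, v: float, cl: float, k12: float, k21: float,
) -> np.ndarray:
    alpha, beta, ca, cb, cc = _two_cmt_macro(ka, v, cl, k12, k21)
    delta = times[:, None] - dose_times[None, :]
    active = delta > 0
    d = np.where(active, delta, np.inf)
    term = ca * np.exp(-alpha * d) + cb * np.exp(-beta * d) + cc * np.exp(-ka * d)
    term[~active] = 0.0
    return (dose * ka / v) * term.sum(axis=1)


def _mm_rhs(t, y, ka, v, vmax, km):
    depot, amt = y
    c = amt / v
    return [-ka * depot, ka * depot - vmax * c / (km + c)]


def mm_state_trajectories(
    params: Mapping[str, float],
    regimen: DoseRegimen,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, np.ndarray]:
    """Integrate the Michaelis–Menten model through all dose events,
    returning depot amount, central amount, concentration, cumulative
    eliminated amount, and cumulative AUC at the requested times.

    Observation times that coincide exactly with a dose time are
    evaluated *before* that bolus (pre-dose trough convention).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise InputError("negative observation time")
    ka, v = params["KA"], params["V"]
    vmax, km = params["VMAX"], params["KM"]
    dose_times = regimen.dose_times()
    horizon = max(times.max() if times.size else 0.0, dose_times[-1]) + 1e-9

    def rhs(t, y):
        depot, amt, _, _ = y
        c = amt / v
        elim = vmax * c / (km + c)
        return [-ka * depot, ka * depot - elim, elim, c]

    # integrate piecewise between dose events
    events = [t for t in dose_times if t <= horizon]
    breakpoints = np.unique(np.concatenate([events, [horizon]]))
    y = np.zeros(4)  # depot, central, eliminated, cumulative AUC
    out = {k: np.zeros_like(times) for k in ("depot", "central", "conc", "eliminated", "cum_auc")}
    t_prev = 0.0
    # times before the first dose: everything zero
    for bp_i, t_next in enumerate(breakpoints):
        if t_next > t_prev:
            sel = (times > t_prev) & (times <= t_next)
            t_eval = np.sort(np.unique(times[sel]))
            if y[0] == 0.0 and y[1] == 0.0:
                # nothing in the system: states constant
                sol_vals = {t: y.copy() for t in t_eval}
            else:
                sol = solve_ivp(
                    rhs, (t_prev, t_next), y,
                    t_eval=np.concatenate([t_eval, [t_next]]) if (t_eval.size == 0 or t_eval[-1] < t_next) else t_eval,
                    method="LSODA", rtol=rtol, atol=atol,
                )
                if not sol.success:
                    raise EstimationError(f"MM ODE solve failed: {sol.message}")
                sol_vals = {t: sol.y[:, j] for j, t in enumerate(sol.t)}
                y = sol.y[:, -1].copy()
            for t in t_eval:
                yv = sol_vals[t]
                for k, idx in (("depot", 0), ("central", 1), ("eliminated", 2), ("cum_auc", 3)):
                    out[k][times == t] = yv[idx]
                out["conc"][times == t] = yv[1] / v
            t_prev = t_next
        if t_next in dose_times and regimen.dose > 0:
            y[0] += regimen.dose
    return out


def predict_concentration(
    spec: ModelSpec,
    params: IndividualParameters | Mapping[str, float],
    regimen: DoseRegimen,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Noise-free plasma concentration Cp(t) (mg/ml) at the given times.

    Linear models use closed-form superposition; the Michaelis–Menten
    model is integrated with a stiff-capable adaptive solver.  An
    observation at exactly a dose time is the pre-dose trough.
    """
    values = params.values if isinstance(params, IndividualParameters) else dict(params)
    spec.validate_params(values)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise InputError("negative observation time")
    if regimen.dose == 0:
        return np.zeros_like(times)
    dose_times = regimen.dose_times()
    if spec.model_id is ModelId.ONE_CMT:
        ke = values["CL"] / values["V"]
        return one_cmt_superposition(times, dose_times, regimen.dose,
                                     values["KA"], values["V"], ke)
    if spec.model_id is ModelId.TWO_CMT:
        return two_cmt_superposition(times, dose_times, regimen.dose,
                                     values["KA"], values["V"], values["CL"],
                                     values["K12"], values["K21"])
    states = mm_state_trajectories(values, regimen, times, rtol=rtol, atol=atol)
    return np.maximum(states["conc"], 0.0)


def simulate_observations(
    true_conc: Sequence[float],
    sigma_prop: float,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Apply proportional residual error: obs = Cp * (1 + eps),
    eps ~ N(0, sigma^2).  Zero concentrations stay exactly zero."""
    if sigma_prop < 0:
        raise ConfigurationError("sigma_prop must be >= 0")
    true_conc = np.asarray(true_conc, dtype=float)
    if np.any(true_conc < 0):
        raise InputError("true concentrations must be >= 0")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eps = gen.standard_normal(true_conc.shape) * sigma_prop
    return true_conc * (1.0 + eps)
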