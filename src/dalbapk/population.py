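"""Population-level generative PK model.

Combines typical parameter values with allometric body-weight scaling,
log-normal inter-individual variability (IIV), a proportional residual
error model, and the plasma free fraction, and builds weight-banded
virtual populations for Monte Carlo simulation.

The bundled reference parameterisation (:func:`dalbavancin_reference_model`)
is the published dalbavancin adult model: typical CL 0.0273 L/h,
V1 3.6 L, Q 0.0225 L/h, V2 6.4 L at the reference weight, allometric
exponents 0.75 on clearances and 1.0 on volumes, IIV CVs of 22 / 17.3 /
55.9 / 30.1 % on CL / V1 / Q / V2, proportional residual SD 0.144 and a
7 % free fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .pk import PKParameters, Regimen, _conc_matrix

__all__ = [
    "PopulationModel",
    "VirtualSubject",
    "WeightBand",
    "SimulationConfig",
    "CovariateEffect",
    "dalbavancin_reference_model",
    "allometric_scale",
    "individual_params",
    "sample_population",
    "simulate_observations",
    "population_conc_matrix",
]

PARAM_NAMES = ("cl", "v1", "q", "v2")


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate effect on a structural parameter.

    ``form`` is ``"power"`` (``(cov/center)**coef``) or ``"linear"``
    (``1 + coef*(cov - center)``); ``center`` is normally the dataset
    median of the covariate.  Linear multipliers are floored at 1e-6 to
    keep parameters positive during estimation.
    """

    parameter: str
    covariate: str
    form: Literal["linear", "power"]
    center: float
    coef: float = 0.0

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in ("linear", "power"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    def multiplier(self, value: float) -> float:
        if self.form == "power":
            with np.errstate(over="ignore"):
                m = float(np.power(np.float64(value / self.center), self.coef))
            # clamp so optimiser excursions in the coefficient stay finite
            return float(np.clip(m, 1e-12, 1e12))
        return max(1.0 + self.coef * (value - self.center), 1e-6)


@dataclass(frozen=True)
class PopulationModel:
    """Complete generative population PK model.

    Parameters
    ----------
    theta : PKParameters
        Typical values at the reference weight.
    ref_weight : float
        Allometric reference weight (kg).
    exp_clearance, exp_volume : float
        Fixed allometric exponents applied to (cl, q) and (v1, v2).
    omega_cv : tuple of 4 floats
        Inter-individual variability of (cl, v1, q, v2) expressed as CV
        fractions (0.22 means 22 %).
    resid_b : float
        Proportional residual error SD (fraction of the prediction).
    fu : float
        Free (unbound) fraction of drug in plasma.
    cv_convention : {"lognormal", "identity"}
        How CV maps to the log-scale SD omega: ``sqrt(ln(1+CV^2))``
        (exact for a log-normal) or ``omega = CV`` (the cruder common
        approximation, kept for sensitivity analysis).
    covariate_effects : tuple of CovariateEffect
        Optional extra covariate terms beyond allometric weight.
    """

    theta: PKParameters
    ref_weight: float = 70.0
    exp_clearance: float = 0.75
    exp_volume: float = 1.0
    omega_cv: tuple[float, float, float, float] = (0.22, 0.173, 0.559, 0.301)
    resid_b: float = 0.144
    fu: float = 0.07
    cv_convention: Literal["lognormal", "identity"] = "lognormal"
    covariate_effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.fu <= 1.0:
            raise ValueError(f"free fraction must be in (0, 1], got {self.fu!r}")
        if any(cv < 0.0 for cv in self.omega_cv):
            raise ValueError("omega_cv entries must be >= 0")
        if self.resid_b < 0.0:
            raise ValueError("resid_b must be >= 0")
        if not self.ref_weight > 0.0:
            raise ValueError("ref_weight must be > 0")

    @property
    def omegas(self) -> np.ndarray:
        """Log-scale SDs of the four random effects."""
        cv = np.asarray(self.omega_cv, dtype=float)
        if self.cv_convention == "lognormal":
            return np.sqrt(np.log1p(cv * cv))
        return cv.copy()

    def with_theta(self, theta: PKParameters) -> "PopulationModel":
        return replace(self, theta=theta)


def dalbavancin_reference_model(**overrides) -> PopulationModel:
    """The published adult dalbavancin population model (see module docstring)."""
    kwargs = dict(
        theta=PKParameters(cl=0.0273, v1=3.6, q=0.0225, v2=6.4),
        ref_weight=70.0,
        omega_cv=(0.22, 0.173, 0.559, 0.301),
        resid_b=0.144,
        fu=0.07,
    )
    kwargs.update(overrides)
    return PopulationModel(**kwargs)


@dataclass(frozen=True)
class WeightBand:
    """Half-open body-weight interval [lower, upper) in kg."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper):
            raise ValueError(
                f"need 0 < lower < upper, got [{self.lower}, {self.upper})"
            )

    def contains(self, weight: float) -> bool:
        return self.lower <= weight < self.upper

    @property
    def label(self) -> str:
        return f"{self.lower:g}-{self.upper:g} kg"


#: The three adult weight bands used for the multidose recommendations.
STANDARD_BANDS = (
    WeightBand(40.0, 80.0),
    WeightBand(80.0, 120.0),
    WeightBand(120.0, 200.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Virtual-population simulation settings."""

    n_per_band: int = 2000
    seed: int = 0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_band < 1:
            raise ValueError("n_per_band must be >= 1")
        if not self.grid_step > 0.0:
            raise ValueError("grid_step must be > 0")


@dataclass(frozen=True)
class VirtualSubject:
    """One simulated individual: weight plus log-scale random effects."""

    id: int
    weight: float
    eta: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not self.weight > 0.0:
            raise ValueError("weight must be > 0")


def _covariate_multipliers(
    model: PopulationModel, covariates: dict[str, float] | None
) -> np.ndarray:
    mult = np.ones(4)
    for effect in model.covariate_effects:
        if covariates is None or effect.covariate not in covariates:
            raise ValueError(
                f"model requires covariate {effect.covariate!r} which was "
                "not provided"
            )
        mult[PARAM_NAMES.index(effect.parameter)] *= effect.multiplier(
            covariates[effect.covariate]
        )
    return mult


def scaled_param_array(
    model: PopulationModel,
    weight: float,
    covariates: dict[str, float] | None = None,
) -> np.ndarray:
    """Typical (cl, v1, q, v2) at the given weight, as a plain array."""
    if not weight > 0.0:
        raise ValueError(f"weight must be > 0, got {weight!r}")
    ratio = weight / model.ref_weight
    fc = ratio**model.exp_clearance
    fv = ratio**model.exp_volume
    base = model.theta.as_array() * np.array([fc, fv, fc, fv])
    return base * _covariate_multipliers(model, covariates)


def allometric_scale(
    model: PopulationModel,
    weight: float,
    covariates: dict[str, float] | None = None,
) -> PKParameters:
    """Typical PK parameters at a given body weight.

    Clearances scale as (weight/ref)^0.75 and volumes as (weight/ref)^1
    by default; additional covariate effects, if present on the model, are
    applied multiplicatively.
    """
    cl, v1, q, v2 = scaled_param_array(model, weight, covariates)
    return PKParameters(cl=cl, v1=v1, q=q, v2=v2)


def individual_params(
    model: PopulationModel,
    weight: float,
    eta: Sequence[float],
    covariates: dict[str, float] | None = None,
) -> PKParameters:
    """Individual parameters: allometric typical values times exp(eta)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (4,):
        raise ValueError("eta must be a 4-vector (cl, v1, q, v2)")
    cl, v1, q, v2 = scaled_param_array(model, weight, covariates) * np.exp(eta)
    return PKParameters(cl=cl, v1=v1, q=q, v2=v2)


def _sample_weights(
    rng: np.random.Generator,
    band: WeightBand,
    n: int,
    sampler: str,
) -> np.ndarray:
    if sampler == "uniform":
        return rng.uniform(band.lower, band.upper, size=n)
    if sampler == "lognormal":
        # log-normal centred on the band midpoint (CV 20 %), clipped by
        # rejection so the band bounds stay exact
        mid = 0.5 * (band.lower + band.upper)
        sigma = math.sqrt(math.log(1.0 + 0.2**2))
        out = np.empty(0)
        while out.size < n:
            draw = rng.lognormal(math.log(mid) - 0.5 * sigma**2, sigma, size=2 * n)
            out = np.concatenate([out, draw[(draw >= band.lower) & (draw < band.upper)]])
        return out[:n]
    raise ValueError(f"unknown weight sampler {sampler!r}")


def sample_population(
    model: PopulationModel,
    bands: Sequence[WeightBand],
    config: SimulationConfig,
    weight_sampler: str = "uniform",
) -> list[VirtualSubject]:
    """Draw a weight-banded virtual population.

    Weights are sampled within each band (uniform by default) and etas are
    independent mean-zero normals on the log scale with SDs derived from the
    model's CVs.  Fully reproducible given ``config.seed``.
    """
    bands = list(bands)
    if not bands:
        raise ValueError("at least one weight band is required")
    for i, a in enumerate(bands):
        for b in bands[i + 1 :]:
            if a.lower < b.upper and b.lower < a.upper:
                raise ValueError(f"weight bands overlap: {a.label} and {b.label}")
    rng = np.random.default_rng(config.seed)
    omegas = model.omegas
    subjects: list[VirtualSubject] = []
    next_id = 0
    for band in bands:
        weights = _sample_weights(rng, band, config.n_per_band, weight_sampler)
        etas = rng.normal(0.0, 1.0, size=(config.n_per_band, 4)) * omegas
        for w, eta in zip(weights, etas):
            subjects.append(
                VirtualSubject(id=next_id, weight=float(w), eta=tuple(eta))
            )
            next_id += 1
    return subjects


def population_conc_matrix(
    model: PopulationModel,
    subjects: Sequence[VirtualSubject],
    regimen: Regimen,
    times: np.ndarray,
) -> np.ndarray:
    """True (noise-free) concentration profiles, one row per subject."""
    pm = np.stack(
        [
            scaled_param_array(model, s.weight) * np.exp(np.asarray(s.eta))
            for s in subjects
        ]
    )
    starts, rates, durations = regimen.dose_arrays()
    return _conc_matrix(pm, starts, rates, durations, np.asarray(times, dtype=float))


def simulate_observations(
    params: PKParameters,
    regimen: Regimen,
    times: Sequence[float],
    resid_b: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Noisy observed concentrations under the proportional error model.

    obs = true * (1 + eps) with eps ~ Normal(0, resid_b^2), independent per
    sample.  Negative draws are retained, mirroring untruncated assay noise;
    the estimator must tolerate them.  Used only when emitting synthetic
    observed data or simulating for a VPC — never inside PTA, which works on
    true concentrations.
    """
    from .pk import concentration

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    true = concentration(params, regimen, times)
    eps = rng.normal(0.0, resid_b, size=true.shape) if resid_b > 0 else 0.0
    return true * (1.0 + eps)
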