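"""Deterministic two-compartment IV-infusion kinetics.

Closed-form solutions for a linear two-compartment disposition model with
first-order elimination from the central compartment and zero-order
(constant-rate) infusion input.  Multidose regimens are handled by
superposition.  All other modules build on this layer.

Units: time in hours, amounts in mg, volumes in L, clearances in L/h,
concentrations in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PKParameters",
    "MicroConstants",
    "DoseEvent",
    "Regimen",
    "DegenerateKineticsError",
    "micro_constants",
    "concentration",
    "compartment_amounts",
    "terminal_half_life",
]

#: Default infusion duration in hours (30-minute IV infusion).
DEFAULT_INFUSION_DURATION = 0.5

# Discriminant of the disposition quadratic below this value means the two
# hybrid rate constants are numerically indistinguishable; the biexponential
# form would lose all precision.  Such parameter sets do not occur in the
# modelled clinical ranges, so they are rejected rather than special-cased.
_DEGENERACY_EPS = 1e-12


class DegenerateKineticsError(ValueError):
    """Raised when alpha and beta coincide to within numerical precision."""


@dataclass(frozen=True)
class PKParameters:
    """Structural PK constants for one subject.

    Parameters
    ----------
    cl : float
        Elimination clearance from the central compartment (L/h).
    v1 : float
        Central volume of distribution (L).
    q : float
        Inter-compartmental clearance (L/h).
    v2 : float
        Peripheral volume of distribution (L).
    """

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise ValueError(
                    f"PK parameter {name!r} must be strictly positive and "
                    f"finite, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.cl, self.v1, self.q, self.v2], dtype=float)


@dataclass(frozen=True)
class MicroConstants:
    """First-order micro rate constants and hybrid disposition constants (1/h).

    ``alpha`` and ``beta`` are the (negated) eigenvalues of the disposition
    matrix, with ``alpha > beta > 0``; they satisfy
    ``alpha + beta = k10 + k12 + k21`` and ``alpha * beta = k10 * k21``.
    """

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order IV infusion.

    ``time`` is the start of the infusion (h), ``amount`` the dose (mg) and
    ``duration`` the infusion length (h).
    """

    time: float
    amount: float
    duration: float = DEFAULT_INFUSION_DURATION

    def __post_init__(self) -> None:
        if not self.amount > 0.0:
            raise ValueError(f"dose amount must be > 0, got {self.amount!r}")
        if not self.duration > 0.0:
            raise ValueError(
                f"infusion duration must be > 0, got {self.duration!r}"
            )
        if self.time < 0.0:
            raise ValueError(f"dose time must be >= 0, got {self.time!r}")

    @property
    def rate(self) -> float:
        """Infusion rate (mg/h)."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        """End of infusion (h)."""
        return self.time + self.duration


@dataclass(frozen=True)
class Regimen:
    """Ordered sequence of IV infusions with non-overlapping administration."""

    events: tuple[DoseEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        for prev, nxt in zip(events, events[1:]):
            if nxt.time <= prev.time:
                raise ValueError("dose event times must be strictly increasing")
            if nxt.time < prev.end:
                raise ValueError(
                    f"infusions overlap: dose at {prev.time} h runs until "
                    f"{prev.end} h but next dose starts at {nxt.time} h"
                )

    def __len__(self) -> int:
        return len(self.events)

    @classmethod
    def single(
        cls,
        amount: float,
        time: float = 0.0,
        duration: float = DEFAULT_INFUSION_DURATION,
    ) -> "Regimen":
        return cls((DoseEvent(time=time, amount=amount, duration=duration),))

    @classmethod
    def from_times(
        cls,
        times: Sequence[float],
        amount: float,
        duration: float = DEFAULT_INFUSION_DURATION,
    ) -> "Regimen":
        """Equal doses at the given start times (h)."""
        return cls(
            tuple(DoseEvent(time=t, amount=amount, duration=duration) for t in times)
        )

    def dose_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(start times, rates, durations) as float arrays, for vectorised use."""
        starts = np.array([e.time for e in self.events], dtype=float)
        rates = np.array([e.rate for e in self.events], dtype=float)
        durations = np.array([e.duration for e in self.events], dtype=float)
        return starts, rates, durations


def _hybrid_constants(
    cl: np.ndarray, v1: np.ndarray, q: np.ndarray, v2: np.ndarray,
    allow_degenerate: bool = False,
) -> tuple[np.ndarray, ...]:
    """Vectorised micro/hybrid constants; inputs broadcast elementwise.

    With ``allow_degenerate`` the degenerate entries propagate as NaN
    instead of raising, so batched optimisation callers can penalise and
    back away from such parameter regions.
    """
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    if np.any(disc < _DEGENERACY_EPS):
        if not allow_degenerate:
            raise DegenerateKineticsError(
                "alpha and beta are numerically indistinguishable "
                f"(discriminant < {_DEGENERACY_EPS:g})"
            )
        disc = np.where(disc < _DEGENERACY_EPS, np.nan, disc)
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    # beta computed via the product to avoid cancellation when beta << alpha
    beta = k10 * k21 / alpha
    return k10, k12, k21, alpha, beta


def micro_constants(params: PKParameters) -> MicroConstants:
    """Micro rate constants and hybrid disposition constants for one subject.

    ``alpha`` and ``beta`` are the roots of
    ``s^2 - (k10 + k12 + k21) s + k10 k21 = 0`` with ``alpha >= beta``.
    """
    k10, k12, k21, alpha, beta = _hybrid_constants(
        np.float64(params.cl),
        np.float64(params.v1),
        np.float64(params.q),
        np.float64(params.v2),
    )
    return MicroConstants(
        k10=float(k10), k12=float(k12), k21=float(k21),
        alpha=float(alpha), beta=float(beta),
    )


def _conc_matrix(
    params_matrix: np.ndarray,
    dose_starts: np.ndarray,
    dose_rates: np.ndarray,
    dose_durations: np.ndarray,
    times: np.ndarray,
    allow_degenerate: bool = False,
) -> np.ndarray:
    """Central-compartment concentration for a batch of parameter vectors.

    ``params_matrix`` has shape (B, 4) with columns (cl, v1, q, v2); returns
    an array of shape (B, len(times)).  This batched kernel is the single
    hot path shared by the Monte Carlo engine and the mixed-effects
    estimator.

    For each infusion with rate R over [t0, t0 + T] the central concentration
    contribution at elapsed time tau = t - t0 is, with w = min(max(tau,0), T)
    and u = max(tau - T, 0),

        C = (R / v1) * [ A/alpha (1 - e^{-alpha w}) e^{-alpha u}
                       + B/beta  (1 - e^{-beta  w}) e^{-beta  u} ],
        A = (alpha - k21)/(alpha - beta),  B = (k21 - beta)/(alpha - beta),

    which covers pre-dose (zero), intra-infusion and post-infusion phases in
    one expression.  Contributions superpose across doses.
    """
    pm = np.asarray(params_matrix, dtype=float)
    cl, v1, q, v2 = pm[:, 0], pm[:, 1], pm[:, 2], pm[:, 3]
    _, _, k21, alpha, beta = _hybrid_constants(cl, v1, q, v2, allow_degenerate)
    denom = alpha - beta
    coef_a = ((alpha - k21) / denom / alpha / v1)[:, None]
    coef_b = ((k21 - beta) / denom / beta / v1)[:, None]
    alpha = alpha[:, None]
    beta = beta[:, None]

    t = np.asarray(times, dtype=float)
    out = np.zeros((pm.shape[0], t.size), dtype=float)
    for t0, rate, dur in zip(dose_starts, dose_rates, dose_durations):
        tau = t - t0
        w = np.clip(tau, 0.0, dur)
        u = np.maximum(tau - dur, 0.0)
        out += rate * (
            coef_a * (-np.expm1(-alpha * w)) * np.exp(-alpha * u)
            + coef_b * (-np.expm1(-beta * w)) * np.exp(-beta * u)
        )
    return out


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be a 1-D array")
    if t.size and t[0] < 0.0:
        raise ValueError("times must be >= 0")
    if np.any(np.diff(t) < 0.0):
        raise ValueError("times must be sorted in non-decreasing order")
    return t


def concentration(
    params: PKParameters, regimen: Regimen, times: Sequence[float]
) -> np.ndarray:
    """Total central-compartment concentration (mg/L) at the given times (h).

    Exact closed-form biexponential solution with zero-order infusion input,
    superposed over all dose events.  Zero before the first infusion starts,
    continuous everywhere.
    """
    t = _check_times(np.asarray(times))
    if len(regimen) == 0:
        return np.zeros(t.size, dtype=float)
    starts, rates, durations = regimen.dose_arrays()
    return _conc_matrix(
        params.as_array()[None, :], starts, rates, durations, t
    )[0]


def compartment_amounts(
    params: PKParameters, regimen: Regimen, times: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Drug amounts (mg) in the central and peripheral compartments.

    Closed form for the same model as :func:`concentration`; used mainly for
    mass-balance checking.
    """
    t = _check_times(np.asarray(times))
    if len(regimen) == 0:
        zero = np.zeros(t.size, dtype=float)
        return zero, zero.copy()
    mc = micro_constants(params)
    alpha, beta, k21, k12 = mc.alpha, mc.beta, mc.k21, mc.k12
    denom = alpha - beta
    a1 = np.zeros(t.size, dtype=float)
    a2 = np.zeros(t.size, dtype=float)
    for ev in regimen.events:
        tau = t - ev.time
        w = np.clip(tau, 0.0, ev.duration)
        u = np.maximum(tau - ev.duration, 0.0)
        ea = (-np.expm1(-alpha * w)) * np.exp(-alpha * u) / alpha
        eb = (-np.expm1(-beta * w)) * np.exp(-beta * u) / beta
        a1 += ev.rate * ((alpha - k21) * ea + (k21 - beta) * eb) / denom
        a2 += ev.rate * k12 * (eb - ea) / denom
    return a1, a2


def terminal_half_life(params: PKParameters) -> float:
    """Terminal (beta-phase) half-life, ln(2)/beta, in hours."""
    return math.log(2.0) / micro_constants(params).beta
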