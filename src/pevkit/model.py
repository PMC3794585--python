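"""Deterministic two-state model of position-effect variegation (PEV).

A locus subject to PEV switches between an active (A) and a silenced (S)
epigenetic state once per cell generation, with per-generation conversion
probabilities ``c_sa`` (silent -> active) and ``c_as`` (active -> silent).
The population-level fraction of cells with the active gene, ``Y_A``,
follows the linear recurrence

    Y_A[n] = Y_A[n-1] - Y_A[n-1] * c_as + (1 - Y_A[n-1]) * c_sa

whose solution is geometric approach to the stationary point
``Y* = c_sa / (c_sa + c_as)`` with per-generation retention factor
``lambda = 1 - c_sa - c_as``:

    Y_A[n] = Y* + (Y_A[0] - Y*) * lambda**n

This module provides the recurrence, its closed form, equilibrium
analysis, first-passage times to equilibrium, and the OD600-based
generation count used to time liquid cultures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConversionRates",
    "EquilibriumInfo",
    "Trajectory",
    "step",
    "trajectory",
    "closed_form",
    "equilibrium",
    "generations_to_equilibrium",
    "od_to_generations",
]


def _check_fraction(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ConversionRates:
    """Per-generation conversion probabilities of a variegating locus.

    Parameters
    ----------
    c_sa : float
        Probability per generation of a silent -> active conversion
        (fraction in [0, 1]).
    c_as : float
        Probability per generation of an active -> silent conversion
        (fraction in [0, 1]).

    Rates are stored as fractions; percentages appear only at I/O
    boundaries (see :meth:`from_percent`).
    """

    c_sa: float
    c_as: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_sa", _check_fraction(self.c_sa, "c_sa"))
        object.__setattr__(self, "c_as", _check_fraction(self.c_as, "c_as"))
        if self.c_sa + self.c_as > 1.0:
            warnings.warn(
                "c_sa + c_as > 1: the retention factor is negative and the "
                "approach to equilibrium is oscillatory (still geometric in "
                "|1 - c_sa - c_as|).",
                stacklevel=2,
            )

    @classmethod
    def from_percent(cls, c_sa_pct: float, c_as_pct: float) -> "ConversionRates":
        """Build rates from percent-per-generation values (e.g. 8.0, 6.3)."""
        return cls(c_sa_pct / 100.0, c_as_pct / 100.0)

    @property
    def retention(self) -> float:
        """Per-generation multiplier of the deviation from equilibrium."""
        return 1.0 - self.c_sa - self.c_as

    def as_percent(self) -> tuple[float, float]:
        return (100.0 * self.c_sa, 100.0 * self.c_as)


class EquilibriumInfo:
    """Stationary point of the two-state recurrence.

    ``y_star = c_sa / (c_sa + c_as)`` when at least one rate is positive;
    when both rates are zero every state is frozen and no unique
    equilibrium exists (``exists`` is False and accessing ``y_star``
    raises).
    """

    def __init__(self, rates: ConversionRates) -> None:
        self.rates = rates
        self.retention = rates.retention
        total = rates.c_sa + rates.c_as
        self.exists = total > 0.0
        self._y_star = rates.c_sa / total if self.exists else None

    @property
    def y_star(self) -> float:
        if not self.exists:
            raise ValueError(
                "no unique equilibrium: c_sa = c_as = 0 freezes every state"
            )
        return self._y_star

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.exists:
            return (
                f"EquilibriumInfo(y_star={self._y_star:.6f}, "
                f"retention={self.retention:.6f})"
            )
        return "EquilibriumInfo(exists=False)"


def step(y_a: float, rates: ConversionRates) -> float:
    """One generation of the recurrence.

    Returns ``y_a - y_a * c_as + (1 - y_a) * c_sa``; maps [0, 1] into
    [0, 1] for any valid rates.
    """
    y_a = _check_fraction(y_a, "y_a")
    return y_a - y_a * rates.c_as + (1.0 - y_a) * rates.c_sa


@dataclass(frozen=True)
class Trajectory:
    """Deterministic series of the active-state fraction over generations."""

    y0: float
    rates: ConversionRates
    generations: np.ndarray = field(repr=False)
    y_a: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.generations)

    @property
    def values(self) -> list[tuple[int, float]]:
        return list(zip(self.generations.tolist(), self.y_a.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "frac_active": self.y_a,
                "frac_silent": 1.0 - self.y_a,
            }
        )


def trajectory(y0: float, rates: ConversionRates, n_gens: int) -> Trajectory:
    """Iterate the recurrence ``n_gens`` times from ``y0``.

    The returned trajectory has ``n_gens + 1`` entries, entry 0 being
    ``(0, y0)``.
    """
    y0 = _check_fraction(y0, "y0")
    n_gens = int(n_gens)
    if n_gens < 0:
        raise ValueError(f"n_gens must be >= 0, got {n_gens}")
    ys = np.empty(n_gens + 1)
    ys[0] = y0
    y = y0
    for i in range(1, n_gens + 1):
        y = y - y * rates.c_as + (1.0 - y) * rates.c_sa
        ys[i] = y
    return Trajectory(y0=y0, rates=rates, generations=np.arange(n_gens + 1), y_a=ys)


def closed_form(y0: float, rates: ConversionRates, n):
    """Active fraction after ``n`` generations, by the closed-form solution.

    ``n`` may be a scalar or an array, and may be non-integer (the
    geometric interpolation between integer generations). With both
    rates zero the state is frozen and ``y0`` is returned.
    """
    y0 = _check_fraction(y0, "y0")
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("generation n must be >= 0")
    eq = EquilibriumInfo(rates)
    if not eq.exists:
        out = np.full_like(n_arr, y0)
    else:
        out = eq.y_star + (y0 - eq.y_star) * rates.retention ** n_arr
    if np.isscalar(n) or np.ndim(n) == 0:
        return float(out)
    return out


def equilibrium(rates: ConversionRates) -> EquilibriumInfo:
    """Stationary point and retention factor of the recurrence."""
    return EquilibriumInfo(rates)


def _first_passage(y0: float, y_star: float, lam: float, tol: float) -> int:
    """Smallest n with |Y_n - Y*| <= tol, for one initial condition."""
    dev = abs(y0 - y_star)
    if dev <= tol:
        return 0
    if abs(lam) >= 1.0:
        raise ValueError(
            "never converges: |retention factor| >= 1 with initial deviation "
            f"{dev:.4g} > tol {tol:.4g}"
        )
    if lam > 0.0:
        # |Y_n - Y*| = dev * lam**n exactly; invert the geometric decay.
        n = math.ceil(math.log(tol / dev) / math.log(lam))
        # guard against floating-point edge cases of the ceil
        while n > 0 and dev * lam ** (n - 1) <= tol:
            n -= 1
        while dev * lam**n > tol:
            n += 1
        return n
    # lam <= 0: oscillatory (or one-step) approach; iterate directly.
    d = dev
    n = 0
    while d > tol:
        d *= abs(lam)
        n += 1
    return n


def generations_to_equilibrium(
    rates: ConversionRates,
    tol: float = 0.02,
    y0_set: tuple[float, ...] = (0.0, 1.0),
) -> int:
    """First generation at which every listed start is within ``tol`` of Y*.

    The convention used throughout the package for "equilibrium reached":
    both the all-silent (y0=0) and all-active (y0=1) cultures are within
    2 percentage points of the stationary fraction.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    eq = equilibrium(rates)
    y_star = eq.y_star  # raises if no equilibrium
    lam = rates.retention
    return max(_first_passage(_check_fraction(y0, "y0"), y_star, lam, tol)
               for y0 in y0_set)


def od_to_generations(od_initial: float, od_final: float) -> float:
    """Generations elapsed in a liquid culture, from OD600 readings.

    number of generations = log(final OD600 / initial OD600) / log(2)
    """
    od_initial = float(od_initial)
    od_final = float(od_final)
    if od_initial <= 0 or od_final <= 0:
        raise ValueError("OD600 readings must be positive")
    if od_final < od_initial:
        raise ValueError("final OD600 must be >= initial OD600")
    return math.log2(od_final / od_initial)
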