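"""Synthetic assay data with the statistical structure of the wet assays.

Three generators stand in for the laboratory measurements:

* plating time courses — serial dilutions of a culture are spotted on
  non-selective, uracil-dropout and 5-FOA plates; each plate receives an
  independent aliquot, so colony counts are modeled as independent
  Poisson draws and the reported %FOA^R / %URA+ are ratios of counts.
  Ratios occasionally exceed 100%, just as real plating tables do.
* dual-selection pairs — the same culture genotype established from both
  the all-silent (FOA-selected) and all-active (ura-selected) state.
* FACS clone panels — per-well %GFP+ readouts of single-cell-founded
  mini-cultures, with binomial counting noise over the scored events.

Mutation-driven FOA resistance is not modeled: forward-mutation rates
(~1e-6) are negligible next to epigenetic switching (1e-2 to 1e-3).

A small registry of named rate fixtures covers the parameter sets used
throughout the package's examples and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clones import simulate_panel
from .fitting import FRACTION_CEILING, TimeCourse
from .model import ConversionRates, closed_form

__all__ = [
    "PlatingCounts",
    "FacsWell",
    "FixtureSet",
    "synth_timecourse",
    "synth_dual_selection",
    "synth_facs_panel",
    "fixtures",
    "get_fixture",
]


@dataclass(frozen=True)
class PlatingCounts:
    """Colony counts of one plating (one time point)."""

    n_nonselective: int
    n_ura: int
    n_foa: int

    def __post_init__(self) -> None:
        for name in ("n_nonselective", "n_ura", "n_foa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FacsWell:
    """One mini-culture well as read by FACS."""

    clone_index: int
    true_frac_gfp: float
    observed_frac_gfp: float
    n_events: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.observed_frac_gfp <= 1.0):
            raise ValueError("observed_frac_gfp must be in [0, 1]")
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")


@dataclass(frozen=True)
class FixtureSet:
    name: str
    rates: ConversionRates
    provenance: str


def synth_timecourse(rates: ConversionRates, y0: float, generations,
                     mean_colonies: int = 200, seed: int = 0) -> TimeCourse:
    """Noisy plating time course from the deterministic truth.

    For each generation ``n`` the true active fraction ``y`` comes from
    the closed form; counts are drawn independently as
    Poisson(mean_colonies) for the non-selective plate (redrawn until
    positive), Poisson(mean_colonies * y) for SC-ura and
    Poisson(mean_colonies * (1 - y)) for SC/FOA. Fractions are count
    ratios, truncated at 120% (the documented ceiling of the time-course
    container). Deterministic given ``seed``.
    """
    generations = np.asarray(generations, dtype=float)
    if generations.ndim != 1 or len(generations) == 0:
        raise ValueError("generations must be a non-empty 1D sequence")
    if np.any(generations < 0) or np.any(np.diff(generations) < 0):
        raise ValueError("generations must be sorted and >= 0")
    if mean_colonies < 1:
        raise ValueError("mean_colonies must be >= 1")
    rng = np.random.default_rng(seed)
    y_true = np.atleast_1d(closed_form(y0, rates, generations))
    frac_foa, frac_ura, counts = [], [], []
    for y in y_true:
        n_ns = 0
        while n_ns <= 0:
            n_ns = rng.poisson(mean_colonies)
        n_ura = rng.poisson(mean_colonies * y)
        n_foa = rng.poisson(mean_colonies * (1.0 - y))
        counts.append(PlatingCounts(n_ns, int(n_ura), int(n_foa)))
        frac_ura.append(min(n_ura / n_ns, FRACTION_CEILING))
        frac_foa.append(min(n_foa / n_ns, FRACTION_CEILING))
    origin = "FOA" if y0 < 0.5 else "URA"
    return TimeCourse(
        selection_origin=origin,
        replicate=0,
        generations=generations,
        frac_foa_r=np.array(frac_foa),
        frac_ura=np.array(frac_ura),
        counts=tuple(counts),
    )


def synth_dual_selection(rates: ConversionRates, generations,
                         mean_colonies: int = 200,
                         seed: int = 0) -> tuple[TimeCourse, TimeCourse]:
    """Paired time courses from both selection origins.

    The FOA-origin course starts all-silent (y0 = 0), the URA-origin
    course all-active (y0 = 1); the two use independent sub-seeds
    derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seed_foa, seed_ura = ss.spawn(2)
    course_foa = synth_timecourse(rates, 0.0, generations, mean_colonies,
                                  seed=seed_foa)
    course_ura = synth_timecourse(rates, 1.0, generations, mean_colonies,
                                  seed=seed_ura)
    return course_foa, course_ura


def synth_facs_panel(rates: ConversionRates, n_clones: int, n_gens: int = 15,
                     founder_prob_active: float | None = None,
                     n_events: int = 10_000, seed: int = 0,
                     false_positive_rate: float = 0.0) -> list[FacsWell]:
    """FACS readout of a simulated mini-culture panel.

    True per-well fractions come from the branching clone simulator; the
    observed %GFP+ is Binomial(n_events, p)/n_events per well, where p
    folds in an optional autofluorescence false-positive floor.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not (0.0 <= false_positive_rate <= 1.0):
        raise ValueError("false_positive_rate must be in [0, 1]")
    panel = simulate_panel(n_clones, rates, n_gens,
                           founder_prob_active=founder_prob_active, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    wells = []
    for i, clone in enumerate(panel.clones):
        p = clone.frac_active + (1.0 - clone.frac_active) * false_positive_rate
        observed = rng.binomial(n_events, p) / n_events
        wells.append(FacsWell(clone_index=i, true_frac_gfp=clone.frac_active,
                              observed_frac_gfp=observed, n_events=n_events))
    return wells


_FIXTURES = {
    "wt_tel_VIIL": ((0.080, 0.063),
                    "wild-type W303, URA3 at the VIIL telomere (best fit)"),
    "cac1_tel_VIIL_first50": ((0.0044, 0.0006),
                              "CAF-I cac1 deletion, VIIL telomere, first 50 "
                              "generations (best fit)"),
    "sir1_hmr": ((0.0566, 0.0017),
                 "sir1 deletion, hmr-a1::URA3 locus (best fit)"),
    "fig2A_fast": ((0.15, 0.06), "illustrative fast-switching scenario"),
    "fig2A_slow": ((0.07, 0.03), "illustrative slow-switching scenario"),
    "fig2C_loss": ((0.15, 0.0001), "loss-of-silencing scenario"),
    "fig2C_loss_slow": ((0.07, 0.0001), "loss-of-silencing, slower variant"),
    "fig2D_gain": ((0.03, 0.15), "gain-of-silencing scenario"),
    "fig2D_gain_slow": ((0.03, 0.07), "gain-of-silencing, slower variant"),
    "fig3A_unstable": ((0.15, 0.15), "loss-of-stability scenario"),
    "fig3B_stable": ((0.01, 0.01), "gain-of-stability scenario"),
}


def fixtures() -> list[FixtureSet]:
    """All named rate fixtures used in examples and tests."""
    return [
        FixtureSet(name=name, rates=ConversionRates(*pair), provenance=prov)
        for name, (pair, prov) in _FIXTURES.items()
    ]


def get_fixture(name: str) -> FixtureSet:
    """Look up a fixture by name; unknown names raise with the valid list."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {sorted(_FIXTURES)}"
        )
    pair, prov = _FIXTURES[name]
    return FixtureSet(name=name, rates=ConversionRates(*pair), provenance=prov)
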