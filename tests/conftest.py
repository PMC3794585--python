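import numpy as np
import pytest

from pevkit import ConversionRates, TimeCourse, closed_form


def noiseless_dual_courses(rates: ConversionRates, gens) -> list[TimeCourse]:
    """Exact dual-selection %FOA^R courses from the closed form."""
    gens = np.asarray(gens, dtype=float)
    courses = []
    for y0, origin in ((0.0, "FOA"), (1.0, "URA")):
        y = np.array([closed_form(y0, rates, g) for g in gens])
        courses.append(TimeCourse(selection_origin=origin, replicate=0,
                                  generations=gens, frac_foa_r=1.0 - y))
    return courses


@pytest.fixture
def wt_rates() -> ConversionRates:
    return ConversionRates(0.080, 0.063)


@pytest.fixture
def symmetric_rates() -> ConversionRates:
    return ConversionRates(0.07, 0.07)
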