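"""Published reference values for *Synanthedon bicingulata* in Korea.

The parameter set below is the published two-peaked Weibull fit to 24
pheromone-trap site-year datasets (degree-days at LDT 4 °C from an
October 1 biofix).  The validation table holds the published observed and
model-predicted day-of-year pairs at 10–90 % cumulative occurrence for the
three hold-out monitoring sites (Suncheon, Chuncheon, Gongju), and the
benchmark block holds the Rural Development Administration (RDA) peak
thresholds these predictions are compared against.

These constants let prediction, validation and mapping run out of the box
without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import TwoPeakWeibullParams

__all__ = [
    "REFERENCE_PARAMS",
    "REFERENCE_PARAM_SEM",
    "VALIDATION_PERCENTILE_DAYS",
    "PEAK_DEVIATIONS_DAYS",
    "RdaBenchmark",
    "RDA_BENCHMARK",
]

#: Published parameter estimates (fit on 24 site-years, n = 437 points).
REFERENCE_PARAMS = TwoPeakWeibullParams(
    alpha1=0.4008,
    beta1=1464.09,
    gamma1=-4.9041,
    delta_beta=1829.17,
    gamma2=189.73,
)

#: Published standard errors of the estimates (alpha2 is derived, no SEM).
REFERENCE_PARAM_SEM = {
    "alpha1": 0.0415,
    "beta1": 92.95,
    "gamma1": 1.1323,
    "delta_beta": 78.28,
    "gamma2": 28.75,
}

_VALIDATION_ROWS = [
    # peak, percent, site, observed_doy, predicted_doy
    (1, 10, "Suncheon", 109, 111), (1, 10, "Chuncheon", 130, 124), (1, 10, "Gongju", 134, 128),
    (1, 30, "Suncheon", 122, 133), (1, 30, "Chuncheon", 138, 144), (1, 30, "Gongju", 149, 148),
    (1, 50, "Suncheon", 137, 146), (1, 50, "Chuncheon", 149, 158), (1, 50, "Gongju", 160, 159),
    (1, 70, "Suncheon", 152, 159), (1, 70, "Chuncheon", 163, 171), (1, 70, "Gongju", 167, 171),
    (1, 90, "Suncheon", 162, 174), (1, 90, "Chuncheon", 178, 187), (1, 90, "Gongju", 176, 184),
    (2, 10, "Suncheon", 240, 215), (2, 10, "Chuncheon", 244, 222), (2, 10, "Gongju", 232, 219),
    (2, 30, "Suncheon", 243, 234), (2, 30, "Chuncheon", 248, 236), (2, 30, "Gongju", 245, 237),
    (2, 50, "Suncheon", 244, 243), (2, 50, "Chuncheon", 251, 245), (2, 50, "Gongju", 251, 246),
    (2, 70, "Suncheon", 245, 252), (2, 70, "Chuncheon", 255, 255), (2, 70, "Gongju", 259, 256),
    (2, 90, "Suncheon", 245, 269), (2, 90, "Chuncheon", 265, 271), (2, 90, "Gongju", 273, 274),
]

#: Published observed vs predicted Julian days per peak x percent x site.
VALIDATION_PERCENTILE_DAYS = pd.DataFrame(
    _VALIDATION_ROWS,
    columns=["peak", "percent", "site", "observed_doy", "predicted_doy"],
)

#: Published absolute peak-date deviations (days) at the 50 % occurrence
#: point per validation site, for this model and for the RDA benchmark.
PEAK_DEVIATIONS_DAYS = pd.DataFrame(
    [
        ("Suncheon", "weibull", 9, 1), ("Suncheon", "rda", 2, 1),
        ("Chuncheon", "weibull", 9, 6), ("Chuncheon", "rda", 9, 15),
        ("Gongju", "weibull", 1, 5), ("Gongju", "rda", 17, 13),
    ],
    columns=["site", "model", "first_peak", "second_peak"],
)


@dataclass(frozen=True)
class RdaBenchmark:
    """RDA peak thresholds: fixed CDDs at LDT 8.1 °C from a Jan 1 biofix."""

    first_peak_dd: float = 350.0
    second_peak_dd: float = 1895.0
    ldt: float = 8.1
    biofix_month: int = 1
    biofix_day: int = 1


RDA_BENCHMARK = RdaBenchmark()
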