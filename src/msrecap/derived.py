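"""Life-history summaries derived from fitted or model-averaged rates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np


def mean_age_first_reproduction(alpha1, alpha2, alpha3, alpha4=1.0) -> float:
    """Mean age at first reproduction over ages 1..4.

    AFR = alpha_1 + sum_{n=2..4} n * alpha_n * prod_{i<n} (1 - alpha_i),
    the mean of the age distribution implied by the conditional
    probabilities of starting to breed.  With alpha_4 = 1 the distribution
    is proper; otherwise a warning is raised (some mass never breeds).
    """
    alphas = [float(alpha1), float(alpha2), float(alpha3), float(alpha4)]
    if any(a < 0 or a > 1 for a in alphas):
        raise ValueError("each alpha must be in [0, 1]")
    if alphas[3] != 1.0:
        warnings.warn(
            "alpha at age 4 != 1: the first-breeding age distribution is "
            "not proper and the mean is conditional on ever breeding",
            stacklevel=2,
        )
    afr = alphas[0]
    surv = 1.0
    for n in range(2, 5):
        surv *= 1.0 - alphas[n - 2]
        afr += n * alphas[n - 1] * surv
    return afr


def life_expectancy(phi_ad: float) -> float:
    """Expected further years of life at age 1, -1/ln(phi), for phi in (0,1)."""
    phi_ad = float(phi_ad)
    if not 0.0 < phi_ad < 1.0:
        raise ValueError("life expectancy requires 0 < phi < 1")
    return -1.0 / np.log(phi_ad)


def reproductive_years(life_expectancy_at_1: float, afr: float) -> float:
    """Expected breeding-capable years: life expectancy minus the wait
    from age 1 to first breeding."""
    if afr < 1.0:
        raise ValueError("age at first reproduction is at least 1")
    return float(life_expectancy_at_1) - (float(afr) - 1.0)


def geometric_mean(series) -> float:
    """exp(mean(log(x))) over a series of rates in (0, 1]."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires positive entries")
    return float(np.exp(np.mean(np.log(x))))


@dataclass(frozen=True)
class LifeHistorySummary:
    """Per-species life-history report."""

    species: str
    afr: float
    life_expectancy_ad: float
    reproductive_years: float
    juvenile_survival_geomean: float

    def to_dict(self) -> dict:
        return asdict(self)


def species_summary(
    species: str,
    alphas,
    phi_ad: float,
    phi_juv_series,
) -> LifeHistorySummary:
    """Assemble the standard per-species life-history summary.

    ``alphas`` are the age-1..4 conditional first-breeding probabilities,
    ``phi_juv_series`` the (possibly year-specific) first-year survival
    values whose geometric mean is reported.
    """
    afr = mean_age_first_reproduction(*alphas)
    e1 = life_expectancy(phi_ad)
    return LifeHistorySummary(
        species=species,
        afr=afr,
        life_expectancy_ad=e1,
        reproductive_years=reproductive_years(e1, afr),
        juvenile_survival_geomean=geometric_mean(phi_juv_series),
    )
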