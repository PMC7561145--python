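"""Energy rescaling of pellet counts and carcass-based predation energetics.

Two energetic conversions drive the analysis:

1. **Pellet rescaling.** Summed pellet fractions over-represent bird remains
   (feather and bone survive digestion), so the bird category is divided by
   a correction factor (default 1.7) to make each pellet equivalent to a
   single meal.  Counts are then weighted by the relative energy a meal of
   each category provides: ``s_j = e_j * m / mean_k(e_k * m)``, where ``e_j``
   is energy density (kJ/g) and ``m`` the average meal mass (g).  The scale
   factors average exactly 1 over the six categories, so rescaling preserves
   the overall magnitude of a diet while shifting weight toward
   energy-dense prey.

2. **Carcass energetics.** A predated chick near fledging mass supplies
   ``fledging_mass * carcass_energy_density * digestible_fraction`` kJ
   (2834 kJ at the defaults).  Dividing a breeding pair's daily energetic
   demand by this yields the sufficiency threshold in carcasses/day above
   which predation alone could provision the pair (0.5/d at the defaults,
   to one decimal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from gulldiet.ingest import BIRD_INDEX, CATEGORIES, CarcassVisit

#: Literature-style default energy densities (kJ/g wet mass) per category.
#: Fish/bird/mammal flesh run ~6-8 kJ/g, invertebrates and plant matter much
#: lower, human refuse intermediate.  These are configuration, not data:
#: override them from the energy YAML for a real colony.
DEFAULT_ENERGY_DENSITY: dict[str, float] = {
    "fish": 6.5,
    "plant": 2.0,
    "invertebrate": 3.5,
    "mammal": 7.0,
    "bird": 6.8,
    "garbage": 5.0,
}


@dataclass(frozen=True)
class EnergyConfig:
    """Energetic constants for rescaling and sufficiency computations.

    Parameters
    ----------
    energy_density:
        kJ/g per prey category (all six required).
    meal_size:
        Average meal mass in grams; cancels out of the relative scale
        factors when shared across categories but kept explicit.
    bird_correction:
        Divisor applied to the bird category's summed pellet fractions
        before energy scaling, compensating for over-representation of
        bird remains in pellets.  Default 1.7.
    fledging_mass, carcass_energy_density, digestible_fraction:
        Per-carcass energy model: mass (g) of a chick near fledging, its
        energy density (kJ/g) and the digestible proportion.
    pair_demand:
        Combined daily energetic demand of both pair members (kJ/d).
    """

    energy_density: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENERGY_DENSITY)
    )
    meal_size: float = 100.0
    bird_correction: float = 1.7
    fledging_mass: float = 400.0
    carcass_energy_density: float = 10.9
    digestible_fraction: float = 0.65
    pair_demand: float = 1460.0

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.energy_density]
        if missing:
            raise ValueError(f"energy_density missing categories: {missing}")
        if any(self.energy_density[c] <= 0 for c in CATEGORIES):
            raise ValueError("energy densities must be positive")
        if self.bird_correction < 1:
            raise ValueError("bird_correction must be >= 1")
        if not (0 < self.digestible_fraction <= 1):
            raise ValueError("digestible_fraction must be in (0, 1]")
        for name in ("meal_size", "fledging_mass", "carcass_energy_density", "pair_demand"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scale_factors(self) -> np.ndarray:
        """Relative energy-per-meal scale factors, mean exactly 1."""
        energy = np.array(
            [self.energy_density[c] * self.meal_size for c in CATEGORIES]
        )
        return energy / energy.mean()


@dataclass(frozen=True)
class RescaledProfile:
    """Energy-rescaled diet counts for one pair."""

    territory_id: str
    counts: np.ndarray  # rescaled, CATEGORIES order
    scale_factors: np.ndarray

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def energy_rescale(profile, config: EnergyConfig | None = None) -> RescaledProfile:
    """Rescale a pair's summed pellet counts by relative energetic value.

    The bird correction (division by ``config.bird_correction``) is applied
    to the bird category first, then every category is multiplied by its
    relative energy scale factor.  With ``bird_correction=1`` and equal
    per-category energies the operation is the identity.
    """
    config = config or EnergyConfig()
    if profile.total <= 0:
        raise ValueError(f"cannot rescale empty profile {profile.territory_id}")
    corrected = np.asarray(profile.counts, dtype=float).copy()
    corrected[BIRD_INDEX] = corrected[BIRD_INDEX] / config.bird_correction
    s = config.scale_factors()
    return RescaledProfile(
        territory_id=profile.territory_id,
        counts=corrected * s,
        scale_factors=s,
    )


def carcass_energy(config: EnergyConfig | None = None) -> float:
    """Digestible energy (kJ) per predated carcass."""
    config = config or EnergyConfig()
    return (
        config.fledging_mass
        * config.carcass_energy_density
        * config.digestible_fraction
    )


def sufficiency_threshold(config: EnergyConfig | None = None) -> float:
    """Carcasses/day needed to meet the pair's daily energetic demand.

    ``pair_demand / carcass_energy``; callers typically report it rounded
    to one decimal.
    """
    config = config or EnergyConfig()
    return config.pair_demand / carcass_energy(config)


def visit_kill_rate(visit: CarcassVisit) -> float:
    """Kills/day for one search visit: carcasses found / days since last search.

    Baseline visits anchor the clock but carry no rate; asking for one is a
    caller error.
    """
    if visit.baseline:
        raise ValueError("baseline visit has no kill rate (old remains destroyed)")
    return visit.total_carcasses / visit.days_since_last_search


@dataclass(frozen=True)
class PairSeasonRate:
    territory_id: str
    mean_rate: float  # kills/day, unweighted mean of per-visit rates
    total_rate: float  # total carcasses / total monitored days
    n_visits: int
    meets_demand: bool
    sufficient_data: bool


def pair_season_rate(
    visits: Sequence[CarcassVisit],
    config: EnergyConfig | None = None,
    min_searches: int = 4,
    weighting: str = "visit_mean",
) -> PairSeasonRate:
    """Season-average kill rate for one pair and its sufficiency flag.

    The default statistic is the unweighted mean of per-visit rates (each
    visit's kills/day averaged across the season); ``weighting="total"``
    uses total carcasses over total monitored days instead.  Pairs searched
    fewer than ``min_searches`` times (non-baseline) are flagged
    insufficient and should be excluded from population summaries.
    """
    if weighting not in ("visit_mean", "total"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rated = [v for v in visits if not v.baseline]
    if not rated:
        raise ValueError("no non-baseline visits")
    tid = rated[0].territory_id
    rates = np.array([visit_kill_rate(v) for v in rated])
    days = np.array([v.days_since_last_search for v in rated])
    kills = np.array([v.total_carcasses for v in rated])
    mean_rate = float(rates.mean())
    total_rate = float(kills.sum() / days.sum())
    chosen = mean_rate if weighting == "visit_mean" else total_rate
    tau = sufficiency_threshold(config)
    return PairSeasonRate(
        territory_id=tid,
        mean_rate=mean_rate,
        total_rate=total_rate,
        n_visits=len(rated),
        meets_demand=chosen > tau,
        sufficient_data=len(rated) >= min_searches,
    )


def daily_predatory_impact(visits: Sequence[CarcassVisit]) -> float:
    """Mean kills per pair per day across the monitored season.

    For each pair: total bird carcasses over total monitored days
    (non-baseline visits); the impact is the unweighted mean over pairs.
    """
    by_pair: dict[str, list[CarcassVisit]] = {}
    for v in visits:
        if not v.baseline:
            by_pair.setdefault(v.territory_id, []).append(v)
    if not by_pair:
        raise ValueError("no non-baseline visits")
    per_pair = [
        sum(v.total_carcasses for v in vs) / sum(v.days_since_last_search for v in vs)
        for vs in by_pair.values()
    ]
    return float(np.mean(per_pair))


def extrapolate_colony_impact(
    total_kills: float, sample_fraction: float, n_prey_nests: int | None = None
) -> tuple[float, float | None, float]:
    """Scale observed kills in a studied subsample up to the whole colony.

    Returns ``(colony_kills, pct_nests, raw_colony_kills)`` where
    ``colony_kills`` is rounded to the nearest 100 and ``pct_nests`` (kills
    as a percentage of prey nests, or None if ``n_prey_nests`` is not given)
    to the nearest integer.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    raw = total_kills / sample_fraction
    colony = round(raw / 100) * 100
    pct = None
    if n_prey_nests is not None:
        if n_prey_nests <= 0:
            raise ValueError("n_prey_nests must be positive")
        pct = float(round(colony / n_prey_nests * 100))
    return float(colony), pct, raw
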