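"""Raw diet summaries: per-pair profiles, niche width, seasonal exploitation.

A pair's diet profile accumulates its pellets' fractional compositions: the
count for category *j* is the sum over pellets of the fraction of each pellet
made of *j*, so a pellet that is half fish, half bird contributes 0.5 to
each.  Niche width is simply the number of categories with nonzero count —
a deliberately coarse index that is robust to the fractional bookkeeping.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gulldiet.ingest import BIRD_INDEX, CATEGORIES, CarcassVisit, PelletRecord


@dataclass
class DietProfile:
    """Accumulated diet of one breeding pair.

    ``counts[j]`` is the summed pellet fraction for category ``CATEGORIES[j]``
    and ``total`` their sum (the effective number of pellets accounted for,
    excluding unidentifiable residue).  ``presence_by_visit`` records, per
    visit date, whether any pellet contained bird remains and whether a
    carcass was found — the raw material for seasonal exploitation curves.
    """

    territory_id: str
    counts: np.ndarray
    n_pellets: int
    pellet_category_presence: np.ndarray  # pellets containing each category
    presence_by_visit: list[tuple[_dt.date, bool, bool]] = field(default_factory=list)
    empty: bool = False

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def build_profiles(
    pellets: Sequence[PelletRecord],
    carcasses: Sequence[CarcassVisit] = (),
) -> dict[str, DietProfile]:
    """One :class:`DietProfile` per territory appearing in either table.

    Territories with no pellets get an empty, flagged profile so downstream
    stages can report them rather than silently dropping them.
    """
    by_territory: dict[str, list[PelletRecord]] = {}
    for p in pellets:
        by_territory.setdefault(p.territory_id, []).append(p)
    territories = sorted(
        set(by_territory) | {v.territory_id for v in carcasses}
    )

    profiles: dict[str, DietProfile] = {}
    for tid in territories:
        recs = by_territory.get(tid, [])
        if recs:
            fr = np.array([r.fractions for r in recs], dtype=float)
            counts = fr.sum(axis=0)
            presence = (fr > 0).sum(axis=0)
        else:
            counts = np.zeros(len(CATEGORIES))
            presence = np.zeros(len(CATEGORIES), dtype=int)
        profile = DietProfile(
            territory_id=tid,
            counts=counts,
            n_pellets=len(recs),
            pellet_category_presence=presence,
            empty=not recs,
        )
        # visit-level bird presence: pellets by date, carcasses by date
        pellet_dates: dict[_dt.date, bool] = {}
        for r in recs:
            pellet_dates[r.date] = pellet_dates.get(r.date, False) or (
                r.fractions[BIRD_INDEX] > 0
            )
        carcass_dates = {
            v.date: v.total_carcasses > 0
            for v in carcasses
            if v.territory_id == tid and not v.baseline
        }
        for date in sorted(set(pellet_dates) | set(carcass_dates)):
            profile.presence_by_visit.append(
                (date, pellet_dates.get(date, False), carcass_dates.get(date, False))
            )
        profiles[tid] = profile
    return profiles


def niche_width(profile: DietProfile) -> int:
    """Number of prey categories (0–6) with any recorded use."""
    return int((profile.counts > 0).sum())


def most_common_share(profile: DietProfile) -> tuple[str, float, bool]:
    """The most common prey item and the share of pellets containing it.

    "Contains" means the pellet's fraction for the category is > 0, with no
    minimum-fraction cutoff.  Returns ``(category, proportion, tied)``; ties
    on the presence count are broken by the fixed category order and
    reported via the flag.

    Raises ``ValueError`` on an empty profile.
    """
    if profile.n_pellets == 0 or profile.total == 0:
        raise ValueError(f"most_common_share undefined for empty profile {profile.territory_id}")
    presence = profile.pellet_category_presence
    j = int(np.argmax(presence))  # argmax takes first on ties = fixed order
    tied = int((presence == presence[j]).sum()) > 1
    return CATEGORIES[j], float(presence[j]) / profile.n_pellets, tied


def seasonal_exploitation(
    profiles: dict[str, DietProfile],
    window_days: int | None = None,
) -> pd.DataFrame:
    """Share of pairs exploiting bird prey through the season.

    For each visit date (or calendar bin of ``window_days``), computes the
    proportion of pairs *searched on that date* whose pellets contained bird
    remains, and the proportion with at least one carcass.  Dates with no
    searched pairs are omitted.  Returns a DataFrame with columns
    ``date, n_pairs, pellet_share, carcass_share``.
    """
    rows: list[tuple[_dt.date, bool, bool]] = []
    for profile in profiles.values():
        rows.extend(profile.presence_by_visit)
    if not rows:
        return pd.DataFrame(columns=["date", "n_pairs", "pellet_share", "carcass_share"])
    df = pd.DataFrame(rows, columns=["date", "pellet_bird", "carcass"])
    if window_days:
        origin = df["date"].min()
        df["date"] = df["date"].map(
            lambda d: origin + _dt.timedelta(days=((d - origin).days // window_days) * window_days)
        )
    out = (
        df.groupby("date")
        .agg(
            n_pairs=("pellet_bird", "size"),
            pellet_share=("pellet_bird", "mean"),
            carcass_share=("carcass", "mean"),
        )
        .reset_index()
        .sort_values("date", ignore_index=True)
    )
    return out


def diet_summary(profiles: dict[str, DietProfile]) -> pd.DataFrame:
    """Per-territory table: pellet count, niche width, most-common share."""
    rows = []
    for tid in sorted(profiles):
        p = profiles[tid]
        if p.empty or p.total == 0:
            rows.append(
                {
                    "territory_id": tid,
                    "n_pellets": p.n_pellets,
                    "niche_width": 0,
                    "most_common": "",
                    "most_common_share": np.nan,
                    "tied": False,
                    "empty": True,
                }
            )
            continue
        cat, share, tied = most_common_share(p)
        rows.append(
            {
                "territory_id": tid,
                "n_pellets": p.n_pellets,
                "niche_width": niche_width(p),
                "most_common": cat,
                "most_common_share": share,
                "tied": tied,
                "empty": False,
            }
        )
    return pd.DataFrame(rows)
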