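"""Attack/aggression classification, rates per territory-hour, and timings.

An interaction with an intruding bird counts as a *predatory attack* rather
than territorial aggression when any of four criteria holds: the prey was
chased further into the breeding territory, pursued after a temporary
escape, subjected to a drowning attempt, or an attempt was made to eat it.
Everything else is aggression.  Rates are normalized by observation effort
in territory-hours and reported overall and per stratum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta

from gulldiet.ingest import BehaviorEvent, ObservationEffort

#: Timing bins (minutes since the initial attack): {0}, (0,1], (1,5], (5,inf).
TIMING_BINS: tuple[str, ...] = ("0", "0-1", "1-5", ">5")


def classify_event(event: BehaviorEvent) -> str:
    """``"attack"`` if any predation criterion is met, else ``"aggression"``.

    A kill outcome with all four criteria flags false is internally
    inconsistent (a kill implies an eating or drowning attempt at minimum);
    it is classified as an attack and a warning is emitted.
    """
    is_attack = (
        event.chased_into_territory
        or event.pursued_after_escape
        or event.drowning_attempt
        or event.eating_attempt
    )
    if event.outcome == "kill" and not is_attack:
        warnings.warn(
            f"event at {event.territory_id} ended in a kill but no attack "
            "criterion is set; classifying as attack",
            stacklevel=2,
        )
        return "attack"
    return "attack" if is_attack else "aggression"


def attack_rate(
    events: Sequence[BehaviorEvent],
    efforts: Sequence[ObservationEffort],
    strata: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Attacks and aggressive interactions per territory-hour.

    ``strata`` optionally maps territory_id to a stratum label (e.g.
    treatment group); rates are then reported per stratum plus an
    ``overall`` row.  Columns: ``stratum, hours, attacks, aggressions,
    attack_rate, aggression_rate`` (rates rounded to 2 decimals in the
    ``*_rate_2dp`` columns; full precision kept alongside).
    """
    total_hours = sum(e.hours for e in efforts)
    if total_hours <= 0:
        raise ValueError("total observation effort must be positive")

    def label(tid: str) -> str:
        return (strata or {}).get(tid, "overall")

    hours_by = {}
    for e in efforts:
        hours_by[label(e.territory_id)] = hours_by.get(label(e.territory_id), 0.0) + e.hours
    counts: dict[str, list[int]] = {s: [0, 0] for s in hours_by}
    for ev in events:
        s = label(ev.territory_id)
        if s not in counts:  # event at a territory with unrecorded effort
            raise ValueError(f"no observation effort recorded for stratum {s!r}")
        idx = 0 if classify_event(ev) == "attack" else 1
        counts[s][idx] += 1

    rows = []
    strata_names = sorted(hours_by)
    for s in strata_names:
        att, agg = counts[s]
        rows.append((s, hours_by[s], att, agg))
    if strata:  # add the pooled row
        att = sum(c[0] for c in counts.values())
        agg = sum(c[1] for c in counts.values())
        rows.append(("overall", total_hours, att, agg))
    df = pd.DataFrame(rows, columns=["stratum", "hours", "attacks", "aggressions"])
    df["attack_rate"] = df["attacks"] / df["hours"]
    df["aggression_rate"] = df["aggressions"] / df["hours"]
    df["attack_rate_2dp"] = df["attack_rate"].round(2)
    df["aggression_rate_2dp"] = df["aggression_rate"].round(2)
    return df


def success_rate(
    events: Sequence[BehaviorEvent], ci_level: float = 0.95
) -> tuple[float, int, int, tuple[float, float]]:
    """Proportion of attacks ending in a kill, with an exact binomial CI.

    Returns ``(proportion, kills, attacks, (lo, hi))`` using the
    Clopper-Pearson interval.  Raises if there are no attacks.
    """
    attacks = [e for e in events if classify_event(e) == "attack"]
    if not attacks:
        raise ValueError("success rate undefined: no attacks")
    k = sum(1 for e in attacks if e.outcome == "kill")
    n = len(attacks)
    a = (1 - ci_level) / 2
    lo = 0.0 if k == 0 else float(_beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(_beta.ppf(1 - a, k + 1, n - k))
    return k / n, k, n, (lo, hi)


def timing_bin(minutes: float) -> str:
    """Assign minutes-since-initial-attack to its bin.

    Edges are upper-inclusive: 0 is its own "immediately" bin, then
    (0,1], (1,5], (5,inf).
    """
    if minutes < 0:
        raise ValueError(f"negative minutes: {minutes}")
    if minutes == 0:
        return "0"
    if minutes <= 1:
        return "0-1"
    if minutes <= 5:
        return "1-5"
    return ">5"


def behavior_timing_histogram(events: Sequence[BehaviorEvent]) -> pd.DataFrame:
    """Counts of each behavior label per timing bin (long format).

    Every (label, minutes) observation lands in exactly one bin, so the
    histogram total equals the number of observations.
    """
    rows: list[tuple[str, str]] = []
    for ev in events:
        for label, minutes in ev.behaviors:
            rows.append((label, timing_bin(minutes)))
    df = pd.DataFrame(rows, columns=["behavior", "bin"])
    out = (
        df.groupby(["behavior", "bin"]).size().rename("count").reset_index()
        if len(df)
        else pd.DataFrame(columns=["behavior", "bin", "count"])
    )
    out["bin"] = pd.Categorical(out["bin"], categories=TIMING_BINS, ordered=True)
    return out.sort_values(["behavior", "bin"], ignore_index=True)


def attack_durations(events: Sequence[BehaviorEvent]) -> dict[str, float]:
    """Mean, SD, SE and max of attack durations (minutes).

    Both SD and SE are reported: published "mean ± spread" figures are
    ambiguous between the two, so callers can pick either.
    """
    durations = [
        e.duration_min
        for e in events
        if classify_event(e) == "attack" and e.duration_min is not None
    ]
    if not durations:
        raise ValueError("no attack durations recorded")
    arr = np.asarray(durations, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return {
        "n": float(len(arr)),
        "mean": float(arr.mean()),
        "sd": sd,
        "se": sd / math.sqrt(len(arr)),
        "max": float(arr.max()),
    }
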