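import datetime as dt

import numpy as np
import pytest

from gulldiet import (
    BehaviorEvent,
    CarcassVisit,
    ObservationEffort,
    PelletRecord,
    build_profiles,
)
from gulldiet.simulate import paper_regime, simulate_colony


def pellet(tid="T01", date="2009-06-01", fractions=(1, 0, 0, 0, 0, 0), resid=0.0):
    return PelletRecord(
        territory_id=tid,
        date=dt.date.fromisoformat(date),
        fractions=tuple(float(f) for f in fractions),
        unidentifiable=resid,
    )


def visit(tid="T01", date="2009-06-01", days=6.0, counts=None, baseline=False):
    return CarcassVisit(
        territory_id=tid,
        date=dt.date.fromisoformat(date),
        days_since_last_search=days,
        counts=counts or {},
        baseline=baseline,
    )


def attack_event(tid="T01", outcome="escape", duration=3.0, behaviors=(), **flags):
    defaults = dict(
        chased_into_territory=False,
        pursued_after_escape=False,
        drowning_attempt=False,
        eating_attempt=True,
    )
    defaults.update(flags)
    return BehaviorEvent(
        territory_id=tid,
        start_time=dt.datetime(2015, 7, 5, 10, 0),
        actor="focal_adult",
        behaviors=tuple(behaviors),
        outcome=outcome,
        duration_min=duration,
        **defaults,
    )


def aggression_event(tid="T01"):
    return BehaviorEvent(
        territory_id=tid,
        start_time=dt.datetime(2015, 7, 5, 10, 0),
        actor="intruder",
        outcome="escape",
    )


@pytest.fixture(scope="session")
def colony_2009():
    """One simulated season under the 2009 study regime."""
    return simulate_colony(paper_regime("gull_island_2009", seed=42))


@pytest.fixture(scope="session")
def colony_2015():
    return simulate_colony(paper_regime("gull_island_2015", seed=42))


@pytest.fixture(scope="session")
def profiles_2009(colony_2009):
    return build_profiles(
        colony_2009.tables["pellets"], colony_2009.tables["carcasses"]
    )
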