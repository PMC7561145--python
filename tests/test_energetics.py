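import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gulldiet import (
    EnergyConfig,
    carcass_energy,
    daily_predatory_impact,
    energy_rescale,
    extrapolate_colony_impact,
    pair_season_rate,
    sufficiency_threshold,
    visit_kill_rate,
)
from gulldiet.diet import DietProfile
from gulldiet.ingest import CATEGORIES

from conftest import visit


def profile(counts, tid="T01"):
    return DietProfile(tid, np.asarray(counts, float), 10, np.zeros(6, int))


def config_with_energies(energies, **kw):
    return EnergyConfig(
        energy_density=dict(zip(CATEGORIES, energies)), meal_size=1.0, **kw
    )


class TestRescale:
    def test_scale_factors_relative_to_mean(self):
        cfg = config_with_energies([10, 20, 30, 40, 50, 60])
        s = cfg.scale_factors()
        assert s == pytest.approx(np.array([10, 20, 30, 40, 50, 60]) / 35)
        assert s[0] == pytest.approx(0.2857, abs=1e-4)
        assert s.mean() == pytest.approx(1.0, abs=1e-12)

    def test_bird_correction_before_scaling(self):
        cfg = config_with_energies([1, 1, 1, 1, 1, 1], bird_correction=1.7)
        out = energy_rescale(profile([0, 0, 0, 0, 3.4, 0]), cfg)
        assert out.counts[4] == pytest.approx(2.0)

    def test_identity_limit(self):
        """Equal energies and no bird correction leave counts untouched."""
        cfg = config_with_energies([5, 5, 5, 5, 5, 5], bird_correction=1.0)
        counts = [1.5, 0.5, 2, 0, 3.4, 1]
        out = energy_rescale(profile(counts), cfg)
        assert out.counts.tolist() == counts

    def test_missing_energy_density_rejected(self):
        with pytest.raises(ValueError, match="missing categories"):
            EnergyConfig(energy_density={"fish": 6.5})

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            energy_rescale(profile([0, 0, 0, 0, 0, 0]))

    @given(st.lists(st.floats(0.5, 50), min_size=6, max_size=6))
    @settings(derandomize=True, max_examples=50)
    def test_scale_factor_mean_is_one(self, energies):
        assert config_with_energies(energies).scale_factors().mean() == pytest.approx(
            1.0, abs=1e-9
        )


class TestCarcassEnergetics:
    @pytest.mark.parametrize(
        "mass, dens, digest, expected",
        [(400, 10.9, 0.65, 2834.0), (100, 1.0, 1.0, 100.0), (400, 10.9, 1.0, 4360.0)],
    )
    def test_per_carcass_energy(self, mass, dens, digest, expected):
        cfg = EnergyConfig(
            fledging_mass=mass, carcass_energy_density=dens, digestible_fraction=digest
        )
        assert carcass_energy(cfg) == pytest.approx(expected)

    def test_threshold_examples(self):
        assert sufficiency_threshold(
            EnergyConfig(pair_demand=1000, fledging_mass=2000, carcass_energy_density=1, digestible_fraction=1)
        ) == pytest.approx(0.5)
        cfg = EnergyConfig(pair_demand=2834.0)
        assert sufficiency_threshold(cfg) == pytest.approx(1.0)

    def test_threshold_monotonic(self):
        base = sufficiency_threshold(EnergyConfig())
        assert sufficiency_threshold(EnergyConfig(pair_demand=2000)) > base
        assert sufficiency_threshold(EnergyConfig(fledging_mass=500)) < base


class TestKillRates:
    def test_visit_rate(self):
        assert visit_kill_rate(visit(days=6, counts={"chick": 3})) == 0.5
        assert visit_kill_rate(visit(days=9, counts={})) == 0.0

    def test_baseline_visit_has_no_rate(self):
        with pytest.raises(ValueError, match="baseline"):
            visit_kill_rate(visit(days=0, baseline=True))

    def test_pair_mean_of_visit_rates(self):
        visits = [
            visit(days=4, counts={"chick": 2}),
            visit(days=2, counts={"chick": 1}),
        ]
        r = pair_season_rate(visits, min_searches=2)
        assert r.mean_rate == pytest.approx(0.5)
        assert r.total_rate == pytest.approx(0.5)

    def test_sufficiency_flags(self):
        rich = [visit(days=1, counts={"chick": 1}) for _ in range(4)]
        poor = [visit(days=1, counts={}) for _ in range(4)]
        assert pair_season_rate(rich).meets_demand
        assert not pair_season_rate(poor).meets_demand
        assert pair_season_rate(poor).mean_rate == 0.0

    def test_too_few_searches_flagged(self):
        r = pair_season_rate([visit(days=2, counts={"chick": 1})], min_searches=4)
        assert not r.sufficient_data

    def test_conservation_rates_times_days(self, colony_2009):
        """Per-visit rate x interval recovers the carcass count exactly."""
        for v in colony_2009.tables["carcasses"]:
            if not v.baseline:
                assert visit_kill_rate(v) * v.days_since_last_search == pytest.approx(
                    v.total_carcasses
                )


class TestImpact:
    def test_single_pair(self):
        visits = [visit(days=10, counts={"chick": 4})]
        assert daily_predatory_impact(visits) == pytest.approx(0.4)

    def test_mean_over_pairs(self):
        visits = [
            visit(tid="A", days=10, counts={"chick": 4}),
            visit(tid="B", days=10, counts={}),
        ]
        assert daily_predatory_impact(visits) == pytest.approx(0.2)

    def test_baseline_excluded(self):
        visits = [
            visit(tid="A", days=0, counts={"chick": 99}, baseline=True),
            visit(tid="A", days=10, counts={"chick": 4}),
        ]
        assert daily_predatory_impact(visits) == pytest.approx(0.4)


class TestExtrapolation:
    def test_colony_wide(self):
        colony, pct, raw = extrapolate_colony_impact(292, 0.20, 30000)
        assert (colony, pct) == (1500.0, 5.0)
        assert raw == pytest.approx(1460.0)

    def test_full_sample(self):
        colony, pct, _ = extrapolate_colony_impact(100, 1.0, 1000)
        assert (colony, pct) == (100.0, 10.0)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_colony_impact(100, 0.0, 1000)
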