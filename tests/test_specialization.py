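import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gulldiet import (
    exact_overlap_p,
    monte_carlo_p,
    petraitis_lambda,
    pooled_population,
    population_specialism_summary,
)
from gulldiet.energetics import RescaledProfile
from gulldiet.specialization import overlap_tests


def rescaled(counts, tid="T01"):
    return RescaledProfile(tid, np.asarray(counts, float), np.ones(6))


class TestPooledPopulation:
    def test_pooled_fractions(self):
        pool = pooled_population(
            [rescaled([1, 1, 0, 0, 0, 0]), rescaled([1, 3, 0, 0, 0, 0], "T02")]
        )
        assert pool.q.tolist() == pytest.approx([1 / 3, 2 / 3, 0, 0, 0, 0])

    def test_single_pair_is_own_population(self):
        pool = pooled_population([rescaled([2, 2, 0, 0, 0, 0])])
        assert pool.q.tolist() == pytest.approx([0.5, 0.5, 0, 0, 0, 0])

    def test_order_invariance(self):
        a = [rescaled([1, 2, 3, 0, 0, 0]), rescaled([0, 1, 0, 4, 0, 0], "T02")]
        assert pooled_population(a).q.tolist() == pooled_population(a[::-1]).q.tolist()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pooled_population([rescaled([0] * 6)])


class TestLambda:
    def test_identity_when_diet_matches_population(self):
        lam, W = petraitis_lambda([1, 1], [0.5, 0.5])
        assert (lam, W) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_pure_diet_against_even_population(self):
        lam, W = petraitis_lambda([2, 0], [0.5, 0.5])
        assert lam == pytest.approx(0.25)
        assert W == pytest.approx(0.5)

    def test_unused_population_category_ignored(self):
        lam, _ = petraitis_lambda([3, 0, 0], [0.5, 0.25, 0.25])
        assert lam == pytest.approx(0.5**3)

    def test_impossible_category_gives_zero(self):
        lam, W = petraitis_lambda([1, 1], [1.0, 0.0])
        assert (lam, W) == (0.0, 0.0)

    @given(
        st.lists(st.floats(0.1, 20), min_size=3, max_size=3),
        st.integers(2, 9),
    )
    @settings(derandomize=True, max_examples=50)
    def test_W_standardizes_sample_size(self, counts, scale):
        """Scaling all counts leaves W unchanged (lambda scales as lambda**c)."""
        q = np.array([0.5, 0.3, 0.2])
        lam, W = petraitis_lambda(counts, q)
        lam_s, W_s = petraitis_lambda([c * scale for c in counts], q)
        assert W_s == pytest.approx(W, rel=1e-9)
        assert np.log(lam_s) == pytest.approx(scale * np.log(lam), rel=1e-9)


class TestMonteCarlo:
    def test_exact_enumeration_small_case(self):
        # null outcomes for N=2, q=(.5,.5): (2,0) lam=.25, (0,2) lam=.25, (1,1) lam=1
        assert exact_overlap_p([2, 0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_mc_converges_to_exact(self):
        res = monte_carlo_p([2, 0], [0.5, 0.5], n_replicates=9999, seed=1)
        assert res.p_value == pytest.approx(0.5, abs=0.02)

    def test_matching_diet_has_p_one(self):
        res = monte_carlo_p([3, 3], [0.5, 0.5], n_replicates=999, seed=0)
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self):
        a = monte_carlo_p([5, 1, 0], [0.4, 0.4, 0.2], n_replicates=999, seed=7)
        b = monte_carlo_p([5, 1, 0], [0.4, 0.4, 0.2], n_replicates=999, seed=7)
        assert a.p_value == b.p_value

    def test_p_value_never_zero(self):
        res = monte_carlo_p(
            [30, 0, 0], [0.01, 0.495, 0.495], n_replicates=999, seed=0
        )
        assert res.p_value >= 1 / 1000
        assert res.specialist

    def test_degenerate_observed_category_flagged(self):
        res = monte_carlo_p([1, 1], [1.0, 0.0], n_replicates=999, seed=0)
        assert res.degenerate
        assert res.lam == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_p([0.1, 0.1], [0.5, 0.5], n_replicates=999, seed=0)


class TestSummary:
    def test_counts_significant_pairs(self):
        q = [0.4, 0.4, 0.2, 0, 0, 0]
        rng = np.random.default_rng(3)
        results = []
        for i in range(10):
            counts = rng.multinomial(20, q)
            results.append(
                monte_carlo_p(counts, q, n_replicates=499, seed=rng, territory_id=f"T{i}")
            )
        n_sig, prop, table = population_specialism_summary(results)
        assert n_sig == int(table["specialist"].sum())
        assert prop == n_sig / 10
        assert set(table.columns) >= {"territory_id", "lambda", "W", "p_value"}

    def test_all_p_one_means_none_significant(self):
        results = [
            monte_carlo_p([4, 4], [0.5, 0.5], n_replicates=199, seed=0, territory_id="A")
        ]
        n_sig, prop, _ = population_specialism_summary(results)
        assert (n_sig, prop) == (0, 0.0)


class TestPipeline:
    def test_specialists_detected_against_generalist_pool(self):
        """A strongly divergent pair is flagged; conforming pairs are not."""
        rng = np.random.default_rng(11)
        q = np.array([0.3, 0.25, 0.1, 0.05, 0.2, 0.1])
        profiles = [
            rescaled(rng.multinomial(40, q), f"T{i:02d}") for i in range(12)
        ]
        profiles.append(rescaled([0, 0, 0, 0, 40, 0], "SPEC"))
        results = overlap_tests(profiles, n_replicates=999, seed=5)
        by_id = {r.territory_id: r for r in results}
        assert by_id["SPEC"].specialist
        assert by_id["SPEC"].more_birds_than_population
        n_conform_sig = sum(r.specialist for r in results if r.territory_id != "SPEC")
        assert n_conform_sig <= 2

    def test_leave_one_out_pooling_runs(self):
        rng = np.random.default_rng(4)
        q = np.array([0.5, 0.3, 0.2, 0, 0, 0])
        profiles = [rescaled(rng.multinomial(30, q), f"T{i}") for i in range(5)]
        res = overlap_tests(profiles, n_replicates=199, seed=1, leave_one_out=True)
        assert len(res) == 5

    def test_fdr_option_never_flags_more(self):
        rng = np.random.default_rng(9)
        q = np.array([0.4, 0.3, 0.3, 0, 0, 0])
        profiles = [rescaled(rng.multinomial(25, q), f"T{i}") for i in range(8)]
        raw = overlap_tests(profiles, n_replicates=499, seed=2)
        adj = overlap_tests(profiles, n_replicates=499, seed=2, fdr=True)
        assert sum(r.specialist for r in adj) <= sum(r.specialist for r in raw)
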