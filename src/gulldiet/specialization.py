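"""Likelihood niche-overlap test for individual dietary specialization.

Each pair's diet (category counts ``n``, total ``N``, proportions
``p = n/N``) is compared with the pooled population diet ``q`` through the
likelihood measure

    lambda = prod_{j: n_j > 0} (q_j / p_j)^{n_j},        W = lambda^{1/N}.

``lambda`` is the ratio of the multinomial likelihood of the pair's data
under the population diet to its likelihood under the pair's own (saturated)
proportions, so ``lambda = 1`` when the pair eats exactly like the
population and small values flag divergent (specialized) diets.  ``W``
standardizes for sample size: scaling counts leaves lambda unchanged only
if N is held fixed, while W is the per-observation likelihood ratio.

Significance comes from a Monte-Carlo null: draw the pair's sample size from
the population diet as a multinomial, recompute lambda for each replicate,
and estimate ``P = Pr(lambda_null <= lambda_obs)`` with the add-one
estimator ``(1 + #{lambda_rep <= lambda_obs}) / (R + 1)``, which is never
exactly zero.  An exact enumeration over all multinomial outcomes is
provided for small samples as an oracle for the Monte-Carlo estimate.

All likelihood accumulation is in log space; observed counts may be
non-integer (energy-rescaled pellet fractions), handled through continuous
exponents.  Null replicates use the observed total rounded to the nearest
integer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from gulldiet.ingest import BIRD_INDEX, CATEGORIES
from gulldiet.energetics import RescaledProfile

#: slack for lambda <= lambda_obs comparisons on the log scale
_LOG_TIE_TOL = 1e-9


@dataclass(frozen=True)
class PopulationDiet:
    """Pooled population diet: six proportions summing to 1."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (len(CATEGORIES),) and q.ndim != 1:
            raise ValueError("q must be a 1-D proportion vector")
        if (q < 0).any() or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError(f"q must be non-negative and sum to 1, got {q}")


@dataclass(frozen=True)
class OverlapResult:
    territory_id: str
    lam: float
    W: float
    p_value: float
    n_replicates: int
    N: float
    specialist: bool
    degenerate: bool = False
    more_birds_than_population: bool | None = None


def pooled_population(profiles: Sequence[RescaledProfile]) -> PopulationDiet:
    """Population diet ``q`` from pooled rescaled counts (focal pairs included).

    ``q_j = sum_i n_ij / sum_i N_i`` over all pairs.  For a leave-one-out
    convention, pool the remaining profiles explicitly.
    """
    pooled = np.sum([p.counts for p in profiles], axis=0)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("pooled counts are all zero")
    return PopulationDiet(q=pooled / total)


def _log_lambda(counts: np.ndarray, q: np.ndarray) -> np.ndarray:
    """log lambda for one count vector or a (R, J) matrix of them.

    Rows with n_j > 0 where q_j == 0 come out -inf (lambda = 0).
    """
    n = np.atleast_2d(np.asarray(counts, dtype=float))
    N = n.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.where(n > 0, np.log(q)[None, :], 0.0)
        logp = np.where(n > 0, np.log(n) - np.log(N), 0.0)
    out = np.sum(np.where(n > 0, n * (logq - logp), 0.0), axis=1)
    return out


def petraitis_lambda(
    counts: Sequence[float], q: Sequence[float]
) -> tuple[float, float]:
    """Likelihood measure ``(lambda, W)`` of a diet against population ``q``.

    ``lambda = prod_{j: n_j>0} (q_j/p_j)^{n_j}`` with ``p = n/N`` and real
    exponents allowed; ``W = lambda^{1/N}``.  If a category is used that the
    population never uses (``q_j = 0 < n_j``), lambda and W are 0.
    """
    n = np.asarray(counts, dtype=float)
    q = np.asarray(q, dtype=float)
    N = n.sum()
    if N <= 0:
        raise ValueError("counts must have positive total")
    loglam = float(_log_lambda(n, q)[0])
    lam = float(np.exp(loglam))
    W = float(np.exp(loglam / N))
    return lam, W


def monte_carlo_p(
    counts: Sequence[float],
    q: Sequence[float],
    n_replicates: int = 9999,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    territory_id: str = "",
) -> OverlapResult:
    """Monte-Carlo niche-overlap test of one diet against population ``q``.

    Draws ``n_replicates`` multinomial diets of size ``round(N)`` from ``q``
    and reports the add-one P-value for ``lambda_null <= lambda_obs``.
    Deterministic given an integer seed or Generator.
    """
    if n_replicates < 99:
        raise ValueError("use at least 99 replicates")
    n = np.asarray(counts, dtype=float)
    q = np.asarray(q, dtype=float)
    N = n.sum()
    N_int = int(round(N))
    if N_int <= 0:
        raise ValueError("total count rounds to zero; cannot draw null diets")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    lam, W = petraitis_lambda(n, q)
    loglam_obs = float(_log_lambda(n, q)[0])
    degenerate = not np.isfinite(loglam_obs)

    draws = rng.multinomial(N_int, q, size=n_replicates)
    loglam_null = _log_lambda(draws, q)
    n_le = int(np.sum(loglam_null <= loglam_obs + _LOG_TIE_TOL))
    p_value = (1 + n_le) / (n_replicates + 1)

    more_birds = (
        bool(n[BIRD_INDEX] / N > q[BIRD_INDEX])
        if len(n) == len(CATEGORIES)
        else None
    )
    return OverlapResult(
        territory_id=territory_id,
        lam=lam,
        W=W,
        p_value=p_value,
        n_replicates=n_replicates,
        N=float(N),
        specialist=p_value < alpha,
        degenerate=degenerate,
        more_birds_than_population=more_birds,
    )


def exact_overlap_p(counts: Sequence[float], q: Sequence[float]) -> float:
    """Exact ``Pr(lambda_null <= lambda_obs)`` by full multinomial enumeration.

    Enumerates every composition of ``round(N)`` over the categories and
    sums the multinomial probabilities of outcomes with lambda at or below
    the observed value.  Feasible only for small N and few categories; used
    as the independent check on :func:`monte_carlo_p`.
    """
    n = np.asarray(counts, dtype=float)
    q = np.asarray(q, dtype=float)
    N = int(round(n.sum()))
    if N <= 0:
        raise ValueError("total count rounds to zero")
    J = len(q)
    loglam_obs = float(_log_lambda(n, q)[0])

    total = 0.0
    for combo in itertools.combinations_with_replacement(range(J), N):
        outcome = np.bincount(combo, minlength=J).astype(float)
        if (outcome[q == 0] > 0).any():
            continue  # zero probability under the null
        loglam = float(_log_lambda(outcome, q)[0])
        if loglam <= loglam_obs + _LOG_TIE_TOL:
            logpmf = (
                gammaln(N + 1)
                - gammaln(outcome + 1).sum()
                + np.sum(outcome[outcome > 0] * np.log(q[outcome > 0]))
            )
            total += float(np.exp(logpmf))
    return min(total, 1.0)


def population_specialism_summary(
    results: Sequence[OverlapResult],
    niche_widths: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> tuple[int, float, pd.DataFrame]:
    """Colony-level view of the per-pair overlap tests.

    Returns ``(n_significant, proportion_significant, table)`` where the
    table lists each pair's lambda, W, P, specialist flag, diet direction
    (more or fewer birds than the population) and, when supplied, niche
    width.
    """
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for r in results:
        rows.append(
            {
                "territory_id": r.territory_id,
                "lambda": r.lam,
                "W": r.W,
                "p_value": r.p_value,
                "N": r.N,
                "specialist": r.p_value < alpha,
                "more_birds_than_population": r.more_birds_than_population,
                "niche_width": (niche_widths or {}).get(r.territory_id),
            }
        )
    table = pd.DataFrame(rows).sort_values("p_value", ignore_index=True)
    n_sig = int(table["specialist"].sum())
    return n_sig, n_sig / len(results), table


def overlap_tests(
    profiles: Sequence[RescaledProfile],
    n_replicates: int = 9999,
    seed: int | None = None,
    alpha: float = 0.05,
    leave_one_out: bool = False,
    fdr: bool = False,
) -> list[OverlapResult]:
    """Run the overlap test for every pair against the pooled population.

    ``leave_one_out`` excludes the focal pair from the pooled diet it is
    tested against; ``fdr`` applies a Benjamini-Hochberg correction to the
    specialist calls (raw P-values are still reported).
    """
    rng = np.random.default_rng(seed)
    results = []
    for i, prof in enumerate(profiles):
        pool = (
            pooled_population([p for k, p in enumerate(profiles) if k != i])
            if leave_one_out
            else pooled_population(profiles)
        )
        results.append(
            monte_carlo_p(
                prof.counts,
                pool.q,
                n_replicates=n_replicates,
                seed=rng,
                alpha=alpha,
                territory_id=prof.territory_id,
            )
        )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        results = [
            OverlapResult(
                territory_id=r.territory_id,
                lam=r.lam,
                W=r.W,
                p_value=r.p_value,
                n_replicates=r.n_replicates,
                N=r.N,
                specialist=bool(rej),
                degenerate=r.degenerate,
                more_birds_than_population=r.more_birds_than_population,
            )
            for r, rej in zip(results, reject)
        ]
    return results
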