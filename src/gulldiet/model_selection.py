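"""Binomial-GLM covariate screening with QAICc ranking and model averaging.

The response is per-territory bird-prey frequency in one of two currencies:
pellet mode (pellets containing bird remains out of pellets collected) or
carcass mode (search visits yielding at least one carcass out of visits).
Candidate models are every main-effect subset of the territory covariates
(shoreline access, territory-size class, nearest-neighbor distance,
treatment, hatch date), including the null model, fitted as logit-link
binomial GLMs.

Overdispersion is estimated on the global (all-predictor) model as
``c_hat = Pearson chi^2 / residual df`` and floored at 1; models are ranked

    QAICc = -2 logL / c_hat + 2K + 2K(K+1)/(n - K - 1)

with n = number of territories.  When c_hat is estimated (> 1), K includes
one extra parameter for it.  Akaike weights are computed over the full
candidate set; the relative importance of a predictor is the summed weight
of the models containing it within the Delta <= 2 confidence set,
renormalized by that set's total weight (a full-set unrenormalized variant
is available).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from gulldiet.diet import DietProfile
from gulldiet.ingest import BIRD_INDEX, CarcassVisit, TerritoryCovariates, dichotomize_area

PREDICTORS = ("shoreline", "size_class", "nearest_neighbor", "treatment", "hatch_date")

#: |linear predictor| beyond which a logit fit is treated as separated
#: (fitted probabilities within ~1e-9 of 0/1)
_SEPARATION_CUTOFF = 20.0


@dataclass(frozen=True)
class DispersionEstimate:
    """Overdispersion factor from the global model; used only when > 1."""

    c_hat: float
    source_model: str

    @property
    def effective(self) -> float:
        return max(self.c_hat, 1.0)

    @property
    def estimated(self) -> bool:
        return self.c_hat > 1.0


@dataclass
class CandidateModel:
    terms: tuple[str, ...]
    K: int
    loglik: float
    qaicc: float
    delta: float = np.nan
    weight: float = np.nan
    excluded: bool = False

    @property
    def name(self) -> str:
        return " + ".join(self.terms) if self.terms else "null"


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# responses and design
# ---------------------------------------------------------------------------


def build_responses(
    profiles: dict[str, DietProfile],
    visits: Sequence[CarcassVisit],
    mode: str,
) -> pd.DataFrame:
    """Per-territory (successes, trials) for the chosen response currency.

    ``mode="pellet"``: pellets containing bird remains / pellets collected.
    ``mode="carcass"``: non-baseline visits with >= 1 carcass / visits.
    Territories with zero trials are dropped (reported in the ``dropped``
    attribute of the returned frame).
    """
    rows = []
    dropped = []
    if mode == "pellet":
        for tid in sorted(profiles):
            p = profiles[tid]
            if p.n_pellets == 0:
                dropped.append(tid)
                continue
            rows.append((tid, int(p.pellet_category_presence[BIRD_INDEX]), p.n_pellets))
    elif mode == "carcass":
        by_t: dict[str, list[CarcassVisit]] = {}
        for v in visits:
            if not v.baseline:
                by_t.setdefault(v.territory_id, []).append(v)
        for tid in sorted(by_t):
            vs = by_t[tid]
            rows.append((tid, sum(1 for v in vs if v.total_carcasses > 0), len(vs)))
    else:
        raise ValueError(f"mode must be 'pellet' or 'carcass', got {mode!r}")
    df = pd.DataFrame(rows, columns=["territory_id", "successes", "trials"])
    if (df["successes"] > df["trials"]).any():
        raise ValueError("successes exceed trials")
    df.attrs["dropped"] = dropped
    return df


def covariate_frame(
    territories: Sequence[TerritoryCovariates],
    size_threshold: float | None = None,
) -> pd.DataFrame:
    """Numeric design covariates per territory.

    ``size_class`` dichotomizes the territory area at ``size_threshold``
    (default: the sample mean, the conventional cut).  Treatment and hatch
    date are kept as NaN where undefined; territories missing a requested
    covariate are dropped at fit time, never from diet metrics.
    """
    areas = np.array([t.area for t in territories])
    threshold = size_threshold if size_threshold is not None else float(areas.mean())
    rows = []
    for t, area in zip(territories, areas):
        rows.append(
            {
                "territory_id": t.territory_id,
                "shoreline": float(t.shoreline_access),
                "size_class": float(dichotomize_area(area, threshold) == "large"),
                "nearest_neighbor": t.nearest_neighbor_distance,
                "treatment": {"near": 1.0, "away": 0.0, None: np.nan}[t.treatment],
                "hatch_date": np.nan if t.hatch_date is None else float(t.hatch_date),
                "area": area,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["size_threshold"] = threshold
    return df


# ---------------------------------------------------------------------------
# fitting and information criteria
# ---------------------------------------------------------------------------


def fit_binomial_glm(
    data: pd.DataFrame, terms: Sequence[str]
) -> sm.GLM:
    """Logit-link binomial GLM of (successes, trials) on ``terms``.

    ``data`` needs ``successes``/``trials`` columns plus one numeric column
    per term.  Returns the fitted statsmodels results object.  Fits showing
    signs of complete separation (runaway coefficients) raise
    :class:`FitError`; callers exclude the model with a warning.
    """
    endog = np.column_stack(
        [data["successes"].to_numpy(), (data["trials"] - data["successes"]).to_numpy()]
    )
    exog = sm.add_constant(
        data[list(terms)].to_numpy(dtype=float) if terms else np.empty((len(data), 0)),
        has_constant="add",
    )
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit()
    eta = exog @ result.params
    if not np.all(np.isfinite(result.params)) or np.max(np.abs(eta)) > _SEPARATION_CUTOFF:
        raise FitError(f"separation suspected for terms {tuple(terms)}")
    return result


def estimate_c_hat(global_fit, name: str = "global") -> DispersionEstimate:
    """Overdispersion ``c_hat = Pearson chi^2 / df_resid`` from the global fit.

    Floored at 1 downstream (``effective``); a deviance-based variant is
    ``global_fit.deviance / df_resid`` if preferred.
    """
    df = global_fit.df_resid
    if df <= 0:
        raise ValueError("no residual degrees of freedom for c-hat")
    return DispersionEstimate(c_hat=float(global_fit.pearson_chi2 / df), source_model=name)


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample AIC: ``-2 logL + 2K + 2K(K+1)/(n-K-1)``."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n}, K={K}")
    return -2.0 * loglik + 2 * K + 2 * K * (K + 1) / (n - K - 1)


def qaicc(loglik: float, c_hat: float, K: int, n: int) -> float:
    """Quasi-AICc: ``-2 logL / c_hat + 2K + 2K(K+1)/(n-K-1)``.

    Reduces to :func:`aicc` at ``c_hat = 1``.
    """
    if n <= K + 1:
        raise ValueError(f"QAICc undefined for n={n}, K={K}")
    if c_hat < 1:
        raise ValueError("c_hat is floored at 1; pass the effective value")
    return -2.0 * loglik / c_hat + 2 * K + 2 * K * (K + 1) / (n - K - 1)


# ---------------------------------------------------------------------------
# candidate set, ranking, averaging
# ---------------------------------------------------------------------------


def fit_all_subsets(
    data: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
) -> tuple[list[CandidateModel], DispersionEstimate]:
    """Fit every main-effect subset (incl. null) and rank it by QAICc.

    Rows with a missing value in any requested predictor are dropped before
    fitting so all candidates see the same data.  ``n`` in the small-sample
    correction is the number of territories.
    """
    predictors = [p for p in predictors if data[p].notna().any()]
    data = data.dropna(subset=list(predictors)).reset_index(drop=True)
    n = len(data)
    if n < 3:
        raise ValueError("too few territories after dropping missing covariates")

    global_fit = fit_binomial_glm(data, predictors)
    disp = estimate_c_hat(global_fit)
    extra_k = 1 if disp.estimated else 0

    candidates: list[CandidateModel] = []
    for r in range(len(predictors) + 1):
        for terms in itertools.combinations(predictors, r):
            K = 1 + len(terms) + extra_k
            try:
                fit = fit_binomial_glm(data, terms)
            except FitError as exc:
                warnings.warn(str(exc), stacklevel=2)
                candidates.append(
                    CandidateModel(terms=terms, K=K, loglik=np.nan, qaicc=np.inf, excluded=True)
                )
                continue
            candidates.append(
                CandidateModel(
                    terms=terms,
                    K=K,
                    loglik=float(fit.llf),
                    qaicc=qaicc(float(fit.llf), disp.effective, K, n),
                )
            )
    return candidates, disp


def rank_and_average(
    candidates: Sequence[CandidateModel],
    delta_cut: float = 2.0,
    renormalize_ri: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank candidates, compute Akaike weights and relative importance.

    Weights ``w_m = exp(-Delta_m/2) / sum_k exp(-Delta_k/2)`` over the full
    (non-excluded) candidate set.  Relative importance of a predictor is the
    summed weight of Delta <= ``delta_cut`` models containing it; with
    ``renormalize_ri`` (default) that sum is divided by the confidence
    set's total weight.  Ties at the top are broken toward fewer
    parameters.  Returns ``(ranked models, importance)`` DataFrames.
    """
    usable = [c for c in candidates if not c.excluded]
    if len(usable) < 2:
        raise ValueError("need at least two fitted candidates")
    order = sorted(usable, key=lambda c: (c.qaicc, c.K))
    best = order[0].qaicc
    deltas = np.array([c.qaicc - best for c in order])
    rel = np.exp(-deltas / 2)
    weights = rel / rel.sum()
    for c, d, w in zip(order, deltas, weights):
        c.delta = float(d)
        c.weight = float(w)

    ranked = pd.DataFrame(
        {
            "model": [c.name for c in order],
            "terms": [c.terms for c in order],
            "K": [c.K for c in order],
            "loglik": [c.loglik for c in order],
            "QAICc": [c.qaicc for c in order],
            "delta": [c.delta for c in order],
            "weight": [c.weight for c in order],
        }
    )

    in_set = ranked["delta"] <= delta_cut
    set_weight = float(ranked.loc[in_set, "weight"].sum())
    all_terms = sorted({t for c in usable for t in c.terms})
    rows = []
    for term in all_terms:
        has = ranked["terms"].map(lambda ts: term in ts)
        ri_set = float(ranked.loc[in_set & has, "weight"].sum())
        ri = ri_set / set_weight if renormalize_ri else float(ranked.loc[has, "weight"].sum())
        rows.append({"predictor": term, "relative_importance": ri, "in_confidence_set": bool((in_set & has).any())})
    importance = pd.DataFrame(rows).sort_values(
        "relative_importance", ascending=False, ignore_index=True
    )
    return ranked, importance


def select_models(
    profiles: dict[str, DietProfile],
    visits: Sequence[CarcassVisit],
    territories: Sequence[TerritoryCovariates],
    mode: str,
    predictors: Sequence[str] = PREDICTORS,
    size_threshold: float | None = None,
    delta_cut: float = 2.0,
) -> dict:
    """End-to-end covariate screen: responses, all-subsets QAICc, averaging."""
    responses = build_responses(profiles, visits, mode)
    covars = covariate_frame(territories, size_threshold=size_threshold)
    data = responses.merge(covars, on="territory_id", how="inner")
    candidates, disp = fit_all_subsets(data, predictors=predictors)
    ranked, importance = rank_and_average(candidates, delta_cut=delta_cut)
    return {
        "ranked": ranked,
        "importance": importance,
        "c_hat": disp,
        "n_territories": len(data),
        "data": data,
    }
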