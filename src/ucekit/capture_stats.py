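"""Capture-success modeling: GLMs ranked by AIC, Akaike weights, averaging.

The number of loci recovered per taxon is modeled with Poisson (log link)
GLMs and the mean recovered locus length with Gaussian (identity link)
GLMs, over covariates such as genetic distance to the bait-design genome
(supplied externally, on [0, 1]), read counts, mean read length, and
assembly method.  Candidate models are ranked by AIC; Akaike weights are
``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` with ``d_i = AIC_i - min AIC``.
Model-averaged coefficients are computed over the valid candidate set
(``w_i`` above a threshold, default 0.10) with weights renormalized; terms
absent from a model contribute 0 by default (zero-substitution averaging),
with conditional averaging available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = {"count": "uce_count", "length": "mean_uce_length"}


@dataclass
class CandidateModel:
    """One fitted GLM with its information-criterion bookkeeping."""

    terms: tuple[str, ...]
    family: str  # poisson_log | gaussian_identity
    response: str
    log_likelihood: float
    k: int  # number of estimated mean parameters (incl. intercept)
    aic: float
    params: pd.Series
    bse: pd.Series | None = None  # standard errors of the coefficients
    delta_aic: float | None = None
    weight: float | None = None

    @property
    def formula(self) -> str:
        return " + ".join(self.terms) if self.terms else "1"


def _family(response: str):
    if response == "count":
        return sm.families.Poisson(), "poisson_log"
    if response == "length":
        return sm.families.Gaussian(), "gaussian_identity"
    raise ValueError(f"response must be 'count' or 'length', got {response!r}")


def fit_model_set(
    data: pd.DataFrame,
    response: str,
    term_sets: Sequence[Sequence[str]],
    response_column: str | None = None,
) -> list[CandidateModel]:
    """Fit one GLM per term set by maximum likelihood.

    ``response`` selects the family: ``"count"`` -> Poisson with log link on
    ``uce_count``; ``"length"`` -> Gaussian with identity link on
    ``mean_uce_length`` (override the column with ``response_column``).
    Term sets must be distinct; an empty term set is the intercept-only
    model.  Models that fail to converge are excluded with a warning.
    """
    family, family_name = _family(response)
    col = response_column or RESPONSE_COLUMNS[response]
    if col not in data.columns:
        raise ValueError(f"response column {col!r} not in data")
    if data[data.columns].isna().any().any():
        raise ValueError("missing values in covariate data")
    canon = [tuple(sorted(ts)) for ts in term_sets]
    if len(set(canon)) != len(canon):
        raise ValueError("duplicate term sets")

    models: list[CandidateModel] = []
    for terms in term_sets:
        terms = tuple(terms)
        formula = f"{col} ~ " + (" + ".join(terms) if terms else "1")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = smf.glm(formula, data=data, family=family).fit()
            if not result.converged or not np.isfinite(result.llf):
                raise RuntimeError("did not converge")
        except Exception as exc:  # non-convergence or separation
            warnings.warn(f"model {formula!r} excluded: {exc}")
            continue
        k = int(result.df_model) + 1
        models.append(
            CandidateModel(
                terms=terms,
                family=family_name,
                response=response,
                log_likelihood=float(result.llf),
                k=k,
                aic=2 * k - 2 * float(result.llf),
                params=result.params,
                bse=result.bse,
            )
        )
    logger.info("stage=capstats in=%d out=%d models", len(term_sets), len(models))
    return models


def akaike_weights(models: Sequence[CandidateModel]) -> list[CandidateModel]:
    """Rank models by AIC and attach delta-AIC and Akaike weights.

    Returns the models sorted by ascending AIC; weights sum to 1 and are
    invariant under adding a constant to every AIC.
    """
    if not models:
        raise ValueError("empty model set")
    ranked = sorted(models, key=lambda m: m.aic)
    best = ranked[0].aic
    rel = np.array([np.exp(-(m.aic - best) / 2) for m in ranked])
    weights = rel / rel.sum()
    for m, d, w in zip(ranked, (m.aic - best for m in ranked), weights):
        m.delta_aic = float(d)
        m.weight = float(w)
    return ranked


def model_average(
    models: Sequence[CandidateModel],
    threshold: float = 0.10,
    method: str = "zero_substitution",
) -> pd.DataFrame:
    """Model-averaged coefficients over the valid candidate set (w > threshold).

    Weights are renormalized within the candidate set.  Under
    ``zero_substitution`` a parameter absent from a model contributes 0 to
    the average; under ``conditional`` the average runs only over models
    containing the parameter.
    """
    if method not in ("zero_substitution", "conditional"):
        raise ValueError(f"unknown averaging method {method!r}")
    if any(m.weight is None for m in models):
        raise ValueError("call akaike_weights before model_average")
    candidates = [m for m in models if m.weight > threshold]
    if not candidates:
        raise ValueError(f"no model exceeds the weight threshold {threshold}")
    total = sum(m.weight for m in candidates)
    renorm = [m.weight / total for m in candidates]

    names: list[str] = []
    for m in candidates:
        for p in m.params.index:
            if p not in names:
                names.append(p)
    rows = []
    for name in names:
        if method == "zero_substitution":
            est = sum(w * float(m.params.get(name, 0.0)) for m, w in zip(candidates, renorm))
        else:
            have = [(m, w) for m, w in zip(candidates, renorm) if name in m.params.index]
            wsum = sum(w for _, w in have)
            est = sum(w * float(m.params[name]) for m, w in have) / wsum
        rows.append(
            {
                "parameter": name,
                "estimate": est,
                "n_models": sum(name in m.params.index for m in candidates),
            }
        )
    return pd.DataFrame(rows)


def models_table(models: Sequence[CandidateModel]) -> pd.DataFrame:
    """Model-comparison table (terms, k, lnL, AIC, delta AIC, weight)."""
    return pd.DataFrame(
        {
            "terms": [m.formula for m in models],
            "family": [m.family for m in models],
            "k": [m.k for m in models],
            "lnL": [m.log_likelihood for m in models],
            "AIC": [m.aic for m in models],
            "delta_AIC": [m.delta_aic for m in models],
            "weight": [m.weight for m in models],
        }
    )
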