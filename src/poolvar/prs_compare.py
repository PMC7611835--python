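"""Rare-variant carrier effect versus a common-variant polygenic score.

A genome-wide polygenic score (PRS) is consumed as a precomputed
per-individual value.  The comparison mirrors the standard design: the
score is dichotomised into its top decile versus the lower 90%, the
carrier effect is re-estimated with and without PRS adjustment, and the
trait variance explained by each predictor is the R^2 of the univariate
linear model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_models import EffectEstimate, age_specific_effect


@dataclass
class PRSGrouping:
    indicator: pd.Series   # True for the top decile, indexed by individual_id
    n_top: int
    degenerate: bool = False


def prs_top_decile(scores: pd.Series) -> PRSGrouping:
    """Deterministic top-decile split of a polygenic score.

    The ceil(0.1 N) highest scores form the top group; ties are broken by
    individual id (ascending) so the split is reproducible.  An all-equal
    score vector is flagged degenerate.
    """
    n = len(scores)
    if n < 10:
        raise ValueError("need at least 10 individuals for a decile split")
    k = int(np.ceil(0.1 * n))
    order = pd.DataFrame({"score": scores.to_numpy(), "id": scores.index}).sort_values(
        ["score", "id"], ascending=[False, True], kind="mergesort"
    )
    top = set(order["id"].iloc[:k])
    indicator = pd.Series(scores.index.isin(list(top)), index=scores.index, name="prs_top_decile")
    return PRSGrouping(indicator, k, degenerate=bool(scores.nunique() == 1))


def variance_explained(trait: pd.Series, predictor: pd.Series) -> float:
    """R^2 of the univariate linear model of trait on predictor."""
    df = pd.concat([trait.rename("y"), predictor.rename("x")], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.isclose(df.x.std(ddof=0), 0.0):
        raise ValueError("predictor has zero variance")
    r = np.corrcoef(df.x, df.y)[0, 1]
    return float(r * r)


def adjusted_carrier_effect(data: pd.DataFrame) -> dict:
    """Carrier effect before and after adjusting for the polygenic score.

    ``data`` needs columns value, carrier, prs and sex.  Returns
    'unadjusted' (carrier + sex) and 'adjusted' (carrier + sex + PRS)
    :class:`EffectEstimate` objects plus a collinearity flag raised when
    the carrier indicator and the score are strongly correlated.
    """
    df = data.dropna(subset=["value", "carrier", "prs", "sex"])
    unadj = age_specific_effect(df, covariates=("sex",))
    adj = age_specific_effect(df, covariates=("sex", "prs"))
    r = np.corrcoef(df.carrier.astype(float), df.prs.astype(float))[0, 1] if df.carrier.std() > 0 else 0.0
    return {
        "unadjusted": unadj,
        "adjusted": adj,
        "collinear": bool(abs(r) > 0.95),
    }


def comparison_report(
    data: pd.DataFrame,
    trait_name: str = "BMI",
    age: float = 18.0,
) -> dict:
    """Headline comparison at one age: carrier beta vs top-decile-PRS beta.

    ``data`` is one row per individual with columns value, carrier, prs,
    sex.  The PRS contrast replaces the carrier indicator with the
    top-decile indicator; R^2 is reported for both predictors.
    """
    grouping = prs_top_decile(data.set_index(data.index).prs)
    prs_df = data.copy()
    prs_df["carrier"] = grouping.indicator.to_numpy().astype(int)
    carrier_est = age_specific_effect(data, trait=trait_name, age=age, covariates=("sex",))
    prs_est = age_specific_effect(prs_df, trait=f"{trait_name}~PRS-decile", age=age, covariates=("sex",))
    adj = adjusted_carrier_effect(data)
    return {
        "carrier_beta": carrier_est.beta,
        "carrier_ci": (carrier_est.ci_low, carrier_est.ci_high),
        "prs_top_decile_beta": prs_est.beta,
        "prs_top_decile_ci": (prs_est.ci_low, prs_est.ci_high),
        "carrier_beta_prs_adjusted": adj["adjusted"].beta,
        "r2_carrier": variance_explained(data.value, data.carrier.astype(float)),
        "r2_prs": variance_explained(data.value, data.prs),
        "n": carrier_est.n,
        "n_top_decile": grouping.n_top,
    }
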