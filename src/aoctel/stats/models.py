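"""Multiway ANOVA and linear regression on per-scan study tables.

Covariates (intensity, time, position) are treated as numeric codes, matching
how the study assigns numbers and regresses on them; interaction terms are
products of the coded covariates. No multiple-testing correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["anova_ncsc", "regress", "DEFAULT_ANOVA_TERMS"]

DEFAULT_ANOVA_TERMS = (
    "intensity",
    "time",
    "position",
    "intensity:time",
    "intensity:position",
    "time:position",
    "intensity:time:position",
)


def _base_factors(terms: tuple[str, ...]) -> list[str]:
    seen: list[str] = []
    for term in terms:
        for f in term.split(":"):
            if f not in seen:
                seen.append(f)
    return seen


def _check_design(table: pd.DataFrame, terms: tuple[str, ...], response: str) -> None:
    factors = _base_factors(terms)
    missing = [c for c in factors + [response] if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 distinct values")
    if len(table) <= len(terms) + 1:
        raise ValueError(
            f"n = {len(table)} rows cannot support {len(terms)} model terms"
        )


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    """Reject rank-deficient designs, naming the aliased columns."""
    rank = 0
    aliased = []
    for j in range(design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : j + 1])
        if new_rank == rank:
            aliased.append(names[j])
        rank = new_rank
    if aliased:
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def anova_ncsc(
    table: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_ANOVA_TERMS,
    response: str = "ncsc",
    ss_type: int = 2,
) -> pd.DataFrame:
    """Linear-model ANOVA on numeric coded covariates with interactions.

    Fits ``response ~ term_1 + ... + term_k`` by OLS (interaction terms are
    products of coded covariates) and returns a tidy table with one row per
    term: ``term, df, statistic, p_value``. ``ss_type`` selects the
    sum-of-squares decomposition (2 by default, 1 available for sequential).
    """
    _check_design(table, terms, response)
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=table)
    _check_rank(np.asarray(model.exog), list(model.exog_names))
    fit = model.fit()
    aov = sm.stats.anova_lm(fit, typ=ss_type)
    aov = aov.reset_index().rename(columns={"index": "term"})
    out = pd.DataFrame(
        {
            "term": aov["term"],
            "df": aov["df"],
            "statistic": aov["F"],
            "p_value": aov["PR(>F)"],
        }
    )
    return out[out["term"] != "Residual"].reset_index(drop=True)


def regress(
    table: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...],
    ordinal_logit: bool = False,
) -> pd.DataFrame:
    """OLS regression of ``response`` on numeric predictors.

    Returns a tidy table ``term, coef, se, p_value`` (including the
    intercept). Constant predictors are rejected by name. With
    ``ordinal_logit=True`` an ordered-logit model is fitted instead (useful
    for ordinal injury grades); its table has no intercept rows.
    """
    missing = [c for c in (*predictors, response) if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    for pred in predictors:
        if table[pred].nunique() < 2:
            raise ValueError(f"constant predictor: {pred!r}")
    if ordinal_logit:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        model = OrderedModel(
            table[response].astype(int), table[list(predictors)], distr="logit"
        )
        fit = model.fit(method="bfgs", disp=False)
        rows = [
            {
                "term": name,
                "coef": fit.params[name],
                "se": fit.bse[name],
                "p_value": fit.pvalues[name],
            }
            for name in predictors
        ]
        return pd.DataFrame(rows)
    formula = f"{response} ~ " + " + ".join(predictors)
    model = smf.ols(formula, data=table)
    _check_rank(np.asarray(model.exog), list(model.exog_names))
    fit = model.fit()
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "coef": fit.params.values,
            "se": fit.bse.values,
            "p_value": fit.pvalues.values,
        }
    )
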