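"""Group statistics for entrainment outcomes.

OLS regression families relating dyad- and speaker-level entrainment to
diagnostic group, age, language ability (CELF-5 core score) and non-verbal
IQ; one-way ANOVA group comparisons; and the F-to-Cohen's-d conversion used
for two-group effect sizes.  The diagnostic group is treatment-coded with
ASD as the reference level, so the reported group term is the NT effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .datatypes import ValidationError

log = logging.getLogger(__name__)

CATEGORICAL_TERMS = {
    "group": "C(group, Treatment('ASD'))",
    "gender": "C(gender)",
    "partner_id": "C(partner_id)",
}

OUTCOMES = ("delta_ent", "contribution", "adjusted_contribution", "mean_f0", "f0_iqr")


class SingularDesignError(ValueError):
    """Perfectly collinear design; the message names the aliased terms."""


@dataclass
class ModelSpec:
    """One regression: outcome, predictors, optional interactions, feature k."""

    outcome: str
    predictors: Sequence[str]
    interactions: Sequence[str] = field(default_factory=list)  # e.g. "group:age"
    k: int = 1
    name: str = ""

    def formula(self) -> str:
        terms = [CATEGORICAL_TERMS.get(p, p) for p in self.predictors]
        for inter in self.interactions:
            parts = [CATEGORICAL_TERMS.get(p.strip(), p.strip()) for p in inter.split(":")]
            terms.append(":".join(parts))
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class RegressionResult:
    """Tidy per-term estimates plus model-level fit statistics."""

    name: str
    terms: pd.DataFrame  # columns: term, estimate, se, t, p
    r_squared: float
    adj_r_squared: float
    n: int
    df_resid: int
    formula: str
    n_dropped: int = 0

    def term(self, contains: str) -> pd.Series:
        exact = self.terms[self.terms["term"] == contains]
        if len(exact) == 1:
            return exact.iloc[0]
        hit = self.terms[self.terms["term"].str.contains(contains, regex=False)]
        if ":" not in contains:  # a main-effect query never means an interaction
            hit = hit[~hit["term"].str.contains(":", regex=False)]
        if len(hit) != 1:
            raise KeyError(f"{contains!r} matches {len(hit)} terms in model {self.name!r}")
        return hit.iloc[0]

    def summary_text(self) -> str:
        lines = [f"model {self.name or self.formula}",
                 f"  formula: {self.formula}",
                 f"  n = {self.n} (dropped {self.n_dropped} incomplete rows), "
                 f"residual df = {self.df_resid}",
                 f"  R^2 = {self.r_squared:.3f}, adjusted R^2 = {self.adj_r_squared:.3f}"]
        for _, row in self.terms.iterrows():
            lines.append(
                f"  {row['term']:<28s} b = {row['estimate']:8.3f}  SE = {row['se']:7.3f}"
                f"  t = {row['t']:6.2f}  p = {row['p']:.4f}"
            )
        return "\n".join(lines)


def _clean_term(term: str) -> str:
    return (
        term.replace("C(group, Treatment('ASD'))", "group")
        .replace("C(gender)", "gender")
        .replace("C(partner_id)", "partner_id")
    )


def _check_full_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank == exog.shape[1]:
        return
    aliased, prev_rank = [], 0
    for j in range(exog.shape[1]):
        r = np.linalg.matrix_rank(exog[:, : j + 1])
        if r == prev_rank:
            aliased.append(_clean_term(names[j]))
        prev_rank = r
    raise SingularDesignError(f"design is singular; aliased terms: {aliased}")


def fit_ols(table: pd.DataFrame, spec: ModelSpec) -> RegressionResult:
    """Ordinary least squares with intercept and listwise deletion.

    Incomplete rows (NaN in the outcome or any predictor) are dropped and
    logged.  A rank-deficient design raises SingularDesignError naming the
    aliased terms instead of silently pseudo-inverting.
    """
    columns = [spec.outcome] + [p for p in spec.predictors]
    for inter in spec.interactions:
        columns += [p.strip() for p in inter.split(":")]
    columns = list(dict.fromkeys(columns))
    missing = set(columns) - set(table.columns)
    if missing:
        raise ValidationError(f"table missing columns: {sorted(missing)}")
    data = table[columns].dropna()
    n_dropped = len(table) - len(data)
    if n_dropped:
        log.info("fit_ols %s: dropped %d incomplete rows", spec.name, n_dropped)
    n_terms_max = len(data.columns)
    if len(data) < n_terms_max + 2:
        raise ValidationError(
            f"need at least {n_terms_max + 2} complete rows, have {len(data)}"
        )
    model = smf.ols(spec.formula(), data=data)
    _check_full_rank(model.exog, model.exog_names)
    fit = model.fit()
    terms = pd.DataFrame(
        {
            "term": [_clean_term(t) for t in fit.params.index],
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return RegressionResult(
        name=spec.name,
        terms=terms,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=int(fit.nobs),
        df_resid=int(fit.df_resid),
        formula=spec.formula(),
        n_dropped=n_dropped,
    )


def group_anova(values: Sequence[float], groups: Sequence[str]) -> tuple[float, int, int, float]:
    """One-way two-group ANOVA from sum-of-squares definitions.

    Returns (F, df_between, df_within, p).  Equivalent to the squared
    pooled-variance t statistic for two groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {list(labels)}")
    parts = [values[groups == g] for g in labels]
    if any(len(p) < 2 for p in parts):
        raise ValidationError("each group needs n >= 2")
    grand = values.mean()
    ss_between = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in parts)
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    if ss_within == 0:
        f_stat = 0.0 if ss_between == 0 else np.inf
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), df1, df2, p


def cohens_d_from_f(f_stat: float, n1: int, n2: int, direction_sign: float = 1.0) -> float:
    """Two-sample Cohen's d recovered from a one-way two-group F statistic.

    For two groups F = t^2, and d = t * sqrt(1/n1 + 1/n2), so
    d = sign * sqrt(F) * sqrt(1/n1 + 1/n2).  The sign is supplied by the
    caller since F is direction-blind.
    """
    if f_stat < 0:
        raise ValidationError("F must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    return float(np.sign(direction_sign) or 1.0) * np.sqrt(f_stat) * np.sqrt(1.0 / n1 + 1.0 / n2)


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------

#: the retained final predictor sets per outcome family
FINAL_SPECS = {
    "conversation_level": ModelSpec(
        outcome="delta_ent",
        predictors=["group", "age", "celf_core"],
        interactions=["group:age"],
        name="conversation_level_final",
    ),
    "contribution_level": ModelSpec(
        outcome="contribution",
        predictors=["group", "celf_core"],
        name="contribution_level_final",
    ),
    "adjusted_level": ModelSpec(
        outcome="adjusted_contribution",
        predictors=["group", "celf_core"],
        interactions=["group:age"],
        name="adjusted_level_final",
    ),
}

FULL_PREDICTORS = ["group", "age", "gender", "celf_core", "nonverbal_iq", "partner_id"]


def run_model_family(dataset: pd.DataFrame, family: str, k: int = 1) -> dict[str, RegressionResult]:
    """Fit the final and full models of one outcome family.

    ``dataset`` is the analysis table (one row per dyad per feature k, with
    participant covariates joined).  ``family`` is one of
    conversation_level, contribution_level, adjusted_level, or
    f0_range_family (which re-runs the first three on the f0-IQR feature,
    k = 2).  Each family also fits the full model with gender, non-verbal
    IQ and conversation partner; if the partner factor is aliased in the
    small design it is dropped with a warning.
    """
    if family == "f0_range_family":
        results: dict[str, RegressionResult] = {}
        for sub in ("conversation_level", "contribution_level", "adjusted_level"):
            for name, res in run_model_family(dataset, sub, k=2).items():
                results[f"f0_range_{sub}_{name}"] = res
        return results
    if family not in FINAL_SPECS:
        raise ValidationError(f"unknown model family {family!r}")

    rows = dataset[dataset["k"] == k].copy()
    base = FINAL_SPECS[family]
    final_spec = ModelSpec(
        outcome=base.outcome,
        predictors=list(base.predictors),
        interactions=list(base.interactions),
        k=k,
        name=f"{family}_final_k{k}",
    )
    if base.interactions and "age" not in final_spec.predictors:
        final_spec.predictors = list(final_spec.predictors) + ["age"]
    results = {"final": fit_ols(rows, final_spec)}

    full_spec = ModelSpec(
        outcome=base.outcome,
        predictors=list(FULL_PREDICTORS),
        interactions=["group:age"],
        k=k,
        name=f"{family}_full_k{k}",
    )
    try:
        results["full"] = fit_ols(rows, full_spec)
    except SingularDesignError as err:
        log.warning("%s: full model singular (%s); dropping partner_id", family, err)
        full_spec.predictors = [p for p in FULL_PREDICTORS if p != "partner_id"]
        full_spec.name += "_no_partner"
        try:
            results["full"] = fit_ols(rows, full_spec)
        except ValidationError as err2:
            log.warning("%s: full model omitted (%s)", family, err2)
    except ValidationError as err:
        log.warning("%s: full model omitted (%s)", family, err)
    return results
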