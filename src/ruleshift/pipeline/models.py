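"""The inferential models of the pipeline.

All models follow the same conventions: the observer certainty traces
(GC/CC) are z-scored within participant; trial distance is z-scored
globally (it is a shared design variable); participant-level covariates
(age, IQ proxy) are z-scored across the sample; gender is an unordered
3-level factor; group is coded 1 = patient, 0 = control. Confidence models are linear mixed models with a random
intercept per participant and, where stated, uncorrelated random slopes;
accuracy models are logistic. Task level enters confidence models as a
fixed factor (with only three levels, a level random intercept is not
reliably estimable; see the methods note).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mixed import (
    ModelResult,
    fit_lmm,
    fit_logistic_glmm,
    logistic_fe_bic,
    orthogonal_poly,
    zscore,
    zscore_within,
)
from .shifts import annotate_shift_distance

__all__ = [
    "prepare_trials",
    "lagged_accuracy",
    "select_functional_form",
    "fit_recovery_model",
    "fit_feedback_model",
    "fit_normative_model",
]


def lagged_accuracy(trials: pd.DataFrame) -> pd.Series:
    """Previous-trial accuracy, computed within participant x level.

    The first trial of every level has no lag (NaN): feedback context
    never crosses a level boundary.
    """
    return trials.groupby(["participant_id", "level"], sort=False)["outcome"].shift(1)

_COVARIATES = "age_z + C(gender) + iq_z"

#: complexity rank used to break BIC ties toward the simpler form
_FORM_COMPLEXITY = {"linear": 1, "log": 1, "quadratic": 2}


def prepare_trials(cohort) -> pd.DataFrame:
    """Merge demographics onto the trial log and code model covariates."""
    demo = cohort.demographics.copy()
    demo["group_bin"] = (demo["group"].str.upper() == "OCD").astype(int)
    demo["age_z"] = zscore(demo["age"])
    demo["iq_z"] = zscore(demo["iq"])
    df = cohort.trials.merge(
        demo[["participant_id", "group_bin", "age_z", "iq_z", "gender"]],
        on="participant_id",
    )
    return df.rename(columns={"group_bin": "group"})


def _distance_terms(df: pd.DataFrame, form: str) -> tuple[pd.DataFrame, list[str]]:
    # distance is a shared design variable: scale it globally, never within
    # participant (per-participant scaling would corrupt comparisons between
    # candidate bases and make slopes participant-specific in z units)
    df = df.copy()
    if form == "linear":
        df["d1"] = zscore(df["dist"])
        return df, ["d1"]
    if form == "log":
        df["d1"] = zscore(np.log(df["dist"].astype(float)))
        return df, ["d1"]
    if form == "quadratic":
        basis = orthogonal_poly(df["dist"].to_numpy(), 2)
        df["d1"], df["d2"] = basis[:, 0], basis[:, 1]
        return df, ["d1", "d2"]
    raise ValueError(f"unknown functional form {form!r}")


def select_functional_form(
    cohort,
    outcome: str,
    shift_type: Optional[str] = None,
    candidates: Sequence[str] = ("linear", "quadratic", "log"),
    family: Optional[str] = None,
) -> tuple[str, pd.DataFrame]:
    """Choose the distance functional form by BIC.

    Fits each candidate model of ``outcome`` against post-shift trial
    distance (linear, log, or centred orthogonal quadratic polynomial) and
    returns the lowest-BIC form plus the full BIC table. Ties break toward
    the simpler (fewer-parameter) form, then alphabetically.

    Linear-family candidates are ML-fit mixed models with a random
    intercept per participant; binary outcomes are compared through
    fixed-effects logistic GLMs whose participant terms are identical
    across candidates.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate forms")
    if family is None:
        family = "logistic" if outcome == "outcome" else "linear"
    df = annotate_shift_distance(prepare_trials(cohort))
    df = df[df["dist"] >= 1].dropna(subset=[outcome])
    if shift_type is not None:
        df = df[df["last_shift_type"] == shift_type]

    rows = []
    for form in candidates:
        dat, terms = _distance_terms(df, form)
        rhs = " + ".join(terms)
        if family == "logistic":
            bic = logistic_fe_bic(dat, f"{outcome} ~ {rhs}")
        else:
            res = fit_lmm(dat, f"{outcome} ~ {rhs}", reml=False)
            bic = res.bic
        rows.append(dict(form=form, bic=bic, n_terms=len(terms)))
    table = pd.DataFrame(rows)
    order = table.assign(rank=table["form"].map(_FORM_COMPLEXITY)).sort_values(
        ["bic", "rank", "form"]
    )
    return str(order.iloc[0]["form"]), table


def fit_recovery_model(
    cohort,
    metric: str = "outcome",
    shift_type: str = "ID",
    form: str = "log",
    with_group: bool = False,
) -> ModelResult:
    """Post-shift recovery: metric vs trial distance from the shift.

    ``metric='outcome'`` fits a logistic model of accuracy; ``'confidence'``
    a linear mixed model. With ``with_group`` the group main effect,
    group x distance interactions, and demographic covariates are added.
    """
    family = "logistic" if metric == "outcome" else "linear"
    df = annotate_shift_distance(prepare_trials(cohort))
    df = df[(df["dist"] >= 1) & (df["last_shift_type"] == shift_type)].dropna(
        subset=[metric]
    )
    df, terms = _distance_terms(df, form)
    rhs = " + ".join(terms)
    if with_group:
        inter = " + ".join(f"{t}:group" for t in terms)
        formula = f"{metric} ~ {rhs} + group + {inter} + {_COVARIATES}"
    else:
        formula = f"{metric} ~ {rhs}"
    if family == "logistic":
        return fit_logistic_glmm(df, formula)
    return fit_lmm(df, formula, vc_formula={"d1": "0 + d1"})


def fit_feedback_model(cohort, with_group: bool = True) -> ModelResult:
    """Confidence at t as a function of accuracy at t-1 (feedback sensitivity).

    The accuracy lag is computed within participant x level and never
    crosses a level boundary (first trials of a level are dropped). Random
    structure: intercept plus an uncorrelated random slope of lagged
    accuracy per participant; task level enters as a fixed factor.
    """
    df = prepare_trials(cohort)
    df["acc_lag"] = lagged_accuracy(df)
    df = df.dropna(subset=["acc_lag", "confidence"])
    if with_group:
        formula = (
            "confidence ~ acc_lag + group + acc_lag:group + "
            f"{_COVARIATES} + C(level)"
        )
    else:
        formula = "confidence ~ acc_lag + C(level)"
    return fit_lmm(df, formula, vc_formula={"acc_lag": "0 + acc_lag"})


def fit_normative_model(
    cohort,
    traces: pd.DataFrame,
    spec: str = "joint",
    with_group: bool = True,
    timing: str = "pre",
    compute_vif: bool = True,
) -> ModelResult:
    """Confidence regressed on the Bayes-optimal certainty traces.

    ``spec='joint'``: confidence ~ GC + CC + group + GC x group +
    CC x group + covariates; ``'gc_only'`` drops the CC terms. GC/CC are
    the pre-feedback traces by default (``timing='post'`` switches to the
    post-outcome traces) and are z-scored within participant. Random
    structure: participant intercept plus uncorrelated random slopes for
    each certainty trace. VIFs are computed on the fixed-effects design.
    """
    if spec not in ("joint", "gc_only"):
        raise ValueError(f"unknown model spec {spec!r}")
    if timing not in ("pre", "post"):
        raise ValueError(f"unknown trace timing {timing!r}")
    df = prepare_trials(cohort).merge(
        traces[["participant_id", "level", "trial",
                f"gc_{timing}", f"cc_{timing}"]],
        on=["participant_id", "level", "trial"],
    )
    df = df.rename(columns={f"gc_{timing}": "gc", f"cc_{timing}": "cc"})
    df = df.dropna(subset=["confidence"])
    df["zgc"] = zscore_within(df, "gc")
    df["zcc"] = zscore_within(df, "cc")

    terms = ["zgc"] if spec == "gc_only" else ["zgc", "zcc"]
    rhs = " + ".join(terms)
    vc = {t: f"0 + {t}" for t in terms}
    if with_group:
        inter = " + ".join(f"{t}:group" for t in terms)
        formula = f"confidence ~ {rhs} + group + {inter} + {_COVARIATES}"
    else:
        formula = f"confidence ~ {rhs} + {_COVARIATES}"
    res = fit_lmm(df, formula, vc_formula=vc, compute_vif=compute_vif)
    if res.vif is not None and (res.vif["vif"] >= 10).any():
        res.converged = res.converged  # keep fit; flag via random_structure note
        res.random_structure += ",vif_warning"
    return res
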