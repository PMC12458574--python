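"""Mixed-model fitting utilities shared by the analysis pipeline.

Linear mixed models use statsmodels ``MixedLM`` (ML, not REML, whenever
BICs are compared). Logistic mixed models (binary accuracy outcomes) use
statsmodels' variational-Bayes ``BinomialBayesMixedGLM`` with a random
intercept per participant; its posterior means/SDs are reported as
estimates/SEs with normal-approximation p-values. For BIC-based form
selection with a binary outcome, a fixed-effects logistic GLM (participant
dummies) is used instead, since the variational fit has no likelihood
suitable for BIC.

Singular or non-converged fits are retried down a simplification ladder
(drop random slopes, keep the random intercept) and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelResult",
    "fit_lmm",
    "fit_logistic_glmm",
    "logistic_fe_bic",
    "orthogonal_poly",
    "zscore",
    "zscore_within",
    "design_vif",
]


@dataclass
class ModelResult:
    """Fitted coefficients and diagnostics of one statistical model."""

    formula: str
    family: str  # "linear" | "logistic"
    coef: pd.DataFrame  # columns: term, estimate, se, p
    bic: Optional[float] = None
    converged: bool = True
    simplified: bool = False  # random structure reduced after a singular fit
    vif: Optional[pd.DataFrame] = None
    random_structure: str = ""

    def term(self, name: str) -> pd.Series:
        sub = self.coef[self.coef["term"] == name]
        if sub.empty:
            raise KeyError(f"term {name!r} not in model {self.formula!r}")
        return sub.iloc[0]

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "family": self.family,
            "coefficients": self.coef.to_dict(orient="records"),
            "bic": self.bic,
            "converged": self.converged,
            "simplified": self.simplified,
            "random_structure": self.random_structure,
            "vif": None if self.vif is None else self.vif.to_dict(orient="records"),
        }


def zscore(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x)
    if sd == 0 or np.isnan(sd):
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def zscore_within(df: pd.DataFrame, col: str, by: str = "participant_id") -> pd.Series:
    """Z-score a trial-level column within each participant."""
    return df.groupby(by, sort=False)[col].transform(lambda v: zscore(v))


def orthogonal_poly(x, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis of ``x`` (R ``poly()`` convention).

    Columns are centred, mutually orthogonal and unit-norm; evaluated on
    the observed values, so coefficients scale with sqrt(n) - quadratic
    trend estimates are therefore large in magnitude by construction.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    X = np.vander(xc, degree + 1, increasing=True)
    Q, R = np.linalg.qr(X)
    Z = Q[:, 1:] * np.sign(np.diag(R)[1:])
    norms = np.linalg.norm(Z, axis=0)
    return Z / norms


def _wald_table(names: Sequence[str], est: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({"term": list(names), "estimate": est, "se": se, "p": p})


def fit_lmm(
    data: pd.DataFrame,
    formula: str,
    groups: str = "participant_id",
    re_formula: str = "1",
    vc_formula: Optional[dict] = None,
    reml: bool = False,
    compute_vif: bool = False,
) -> ModelResult:
    """Fit a linear mixed model, simplifying the random structure if needed.

    The ladder on failure: requested structure -> random intercept only.
    A fit counts as failed when it does not converge or produces
    non-finite fixed-effect standard errors.
    """
    attempts = [(re_formula, vc_formula)]
    if re_formula != "1" or vc_formula:
        attempts.append(("1", None))

    last_exc = None
    for i, (re_f, vc_f) in enumerate(attempts):
        # gradient optimisers occasionally land in a spurious optimum with
        # inflated variance components; fit with two optimisers and keep
        # the converged solution with the higher likelihood (allFit-style).
        # Intercept-only models are not multi-modal in practice: accept the
        # first acceptable fit there, keeping powell as a pure fallback.
        simple = re_f == "1" and not vc_f
        best = None
        for method in ("bfgs", "powell"):
            if simple and best is not None:
                break
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    model = smf.mixedlm(
                        formula, data, groups=data[groups],
                        re_formula=re_f, vc_formula=vc_f,
                    )
                    res = model.fit(reml=reml, method=[method])
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            se = np.asarray(res.bse_fe, dtype=float)
            ok = res.converged and np.all(np.isfinite(se)) and np.all(se > 0)
            if ok and (best is None or res.llf > best[1].llf):
                best = (model, res)
        if best is not None:
            model, res = best
            se = np.asarray(res.bse_fe, dtype=float)
            coef = _wald_table(model.exog_names, np.asarray(res.fe_params), se)
            bic = float(res.bic) if not reml else None
            vif = design_vif(data, formula) if compute_vif else None
            return ModelResult(
                formula=formula, family="linear", coef=coef, bic=bic,
                converged=True, simplified=(i > 0), vif=vif,
                random_structure=_describe_re(re_f, vc_f),
            )
    raise RuntimeError(f"mixed model failed to converge: {formula!r} ({last_exc})")


def _describe_re(re_f: str, vc_f: Optional[dict]) -> str:
    parts = [f"re={re_f}"]
    if vc_f:
        parts.append("vc=" + "+".join(sorted(vc_f)))
    return ",".join(parts)


def fit_logistic_glmm(
    data: pd.DataFrame,
    formula: str,
    groups: str = "participant_id",
) -> ModelResult:
    """Variational-Bayes logistic mixed model with a random intercept per group."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    vc_formulas = {"participant": f"0 + C({groups})"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(formula, vc_formulas, data)
        res = model.fit_vb()
    k_fe = len(model.fep_names)
    est = np.asarray(res.fe_mean[:k_fe] if hasattr(res, "fe_mean") else res.params[:k_fe])
    sd = np.asarray(res.fe_sd[:k_fe])
    coef = _wald_table(model.fep_names, est, sd)
    return ModelResult(
        formula=formula, family="logistic", coef=coef, bic=None,
        converged=True, random_structure="re=1 (vb)",
    )


def logistic_fe_bic(data: pd.DataFrame, formula: str,
                    groups: str = "participant_id") -> float:
    """BIC of a fixed-effects logistic GLM (participant dummies).

    Used for comparing candidate functional forms on binary outcomes,
    where the participant terms are constant across candidates.
    """
    full = f"{formula} + C({groups})"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.glm(full, data, family=sm.families.Binomial()).fit()
    k = res.df_model + 1
    return float(-2.0 * res.llf + k * np.log(res.nobs))


def design_vif(data: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Variance inflation factors of the fixed-effects design matrix.

    Reported for continuous terms and interactions only; dummy columns of
    unordered factors are excluded (their pairwise correlation is a coding
    artefact and would need a generalised VIF to interpret).
    """
    from patsy import dmatrices

    _, X = dmatrices(formula, data, return_type="dataframe")
    cols = [c for c in X.columns if c != "Intercept" and not c.startswith("C(")]
    mat = X.to_numpy()
    vifs = []
    for c in cols:
        j = list(X.columns).index(c)
        vifs.append(variance_inflation_factor(mat, j))
    return pd.DataFrame({"term": cols, "vif": vifs})
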