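"""Assortative mating and sexual selection on male traits.

From the inferred mother-father pairs and the candidate-male pool this
module quantifies:

* standardized selection differentials — the mean trait difference (in SD
  units) between successful fathers and all candidate males, by area and
  year, with Welch t-tests;
* logistic selection models on mating success for carapace length (CL),
  claw width (CW) and residual claw width (CW_res), with and without area
  interactions and a quadratic term, ranked by small-sample AICc;
* approximate selection gradients via the Janzen-Stern transformation of
  logistic coefficients, β_avggrad = b · mean[ŵ(1-ŵ)] / w̄, and their
  mean-standardized form β_μ = β_avggrad · mean / SD (absolute traits only);
* the size-assortative mating model: male adjusted CL regressed on female
  CL with an additive or interacting area effect, compared by likelihood
  ratio, plus the within-pair relative size gap.

Candidate males are filtered to CL >= 80 mm (maturity proxy) before any
selection computation, and traits are standardized within each area × year
group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MatedPair",
    "SelectionEstimate",
    "standardize",
    "selection_differential",
    "residual_claw",
    "fit_selection_models",
    "janzen_stern_gradient",
    "mean_standardized_gradient",
    "assortative_model",
    "pair_size_gap",
    "MATURITY_CL_MM",
]

MATURITY_CL_MM = 80.0


@dataclass(frozen=True)
class MatedPair:
    """A female and her inferred mate with back-adjusted male size."""

    mother_id: str
    father_id: str
    female_cl: float
    male_cl_adjusted: float
    male_cw: float | None
    female_area: str
    male_area: str
    year: int

    @property
    def interarea(self) -> bool:
        return self.female_area != self.male_area


def pairs_frame(pairs: list[MatedPair], drop_interarea: bool = True) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "mother_id": [p.mother_id for p in pairs],
            "father_id": [p.father_id for p in pairs],
            "female_cl": [p.female_cl for p in pairs],
            "male_cl": [p.male_cl_adjusted for p in pairs],
            "male_cw": [p.male_cw for p in pairs],
            "area": [p.female_area for p in pairs],
            "year": [p.year for p in pairs],
            "interarea": [p.interarea for p in pairs],
        }
    )
    if drop_interarea:
        df = df.loc[~df["interarea"]].reset_index(drop=True)
    return df


@dataclass(frozen=True)
class SelectionEstimate:
    trait: str  # "CL" | "CW" | "CW_res"
    group: str  # e.g. "reserve:2010" or "reserve:pooled"
    s: float | None = None  # standardized differential
    s_p: float | None = None
    beta: float | None = None  # logistic coefficient (per SD)
    beta_se: float | None = None
    beta_z: float | None = None
    beta_p: float | None = None
    beta_avggrad: float | None = None
    beta_mu: float | None = None  # mean-standardized; absolute traits only


# ---------------------------------------------------------------------------
# Differentials


def standardize(values, group=None) -> np.ndarray:
    """Z-scores, optionally per group: mean 0, sample SD 1 within each group."""
    x = np.asarray(values, dtype=float)
    if group is None:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance: cannot standardize")
        return (x - x.mean()) / sd
    out = np.empty_like(x)
    group = np.asarray(group)
    for g in np.unique(group):
        mask = group == g
        sd = x[mask].std(ddof=1)
        if len(np.unique(x[mask])) < 2 or sd == 0:
            raise ValueError(f"group {g}: zero variance, cannot standardize")
        out[mask] = (x[mask] - x[mask].mean()) / sd
    return out


def selection_differential(z, success) -> tuple[float, float]:
    """Standardized differential S and its two-tailed Welch p-value.

    S = mean z of successful males minus mean z of all candidates; the test
    compares successful against unsuccessful males.  Returns (nan, nan)
    when no male was successful.
    """
    z = np.asarray(z, dtype=float)
    success = np.asarray(success, dtype=bool)
    if len(z) != len(success):
        raise ValueError("z and success must align")
    if not success.any():
        return float("nan"), float("nan")
    s = float(z[success].mean() - z.mean())
    if success.all() or success.sum() < 2 or (~success).sum() < 2:
        return s, float("nan")
    t, p = stats.ttest_ind(z[success], z[~success], equal_var=False)
    return s, float(p)


def residual_claw(cw, cl) -> np.ndarray:
    """OLS residuals of claw width on carapace length (relative claw size)."""
    cw = np.asarray(cw, dtype=float)
    cl = np.asarray(cl, dtype=float)
    if len(cw) < 3:
        raise ValueError("need >= 3 males with both traits")
    X = sm.add_constant(cl)
    return np.asarray(sm.OLS(cw, X).fit().resid)


# ---------------------------------------------------------------------------
# Logistic selection models


def _aicc(fit, n: int) -> float:
    p = fit.df_model + 1
    if n - p - 1 <= 0:
        return float("inf")
    return float(fit.aic + 2 * p * (p + 1) / (n - p - 1))


# Model structures over the standardized traits; "x:area" is the product term.
SELECTION_MODELS: list[tuple[str, list[str]]] = [
    ("CL + CW_res", ["z_cl", "z_cwres"]),
    ("CW_res", ["z_cwres"]),
    ("CL + CW_res x Area", ["z_cl", "z_cwres", "area", "z_cwres:area"]),
    ("CW_res x Area", ["z_cwres", "area", "z_cwres:area"]),
    ("CW", ["z_cw"]),
    ("CW x Area", ["z_cw", "area", "z_cw:area"]),
    ("CL", ["z_cl"]),
    ("CL x Area", ["z_cl", "area", "z_cl:area"]),
    ("Null", []),
]

QUADRATIC_MODELS: list[tuple[str, list[str]]] = [
    ("CL + CL^2", ["z_cl", "z_cl^2"]),
    ("CW + CW^2", ["z_cw", "z_cw^2"]),
]


def _design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(_term(df, a) * _term(df, b))
        else:
            cols.append(_term(df, term))
    return np.column_stack(cols)


def _term(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "area":
        return (df["area"] == "reserve").to_numpy(dtype=float)
    if name.endswith("^2"):
        return df[name[:-2]].to_numpy(dtype=float) ** 2
    return df[name].to_numpy(dtype=float)


def fit_selection_models(
    males: pd.DataFrame,
    include_quadratic: bool = True,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Fit the logistic selection-model set and rank by AICc.

    ``males`` needs columns ``success`` (0/1), ``z_cl``, ``z_cw``,
    ``z_cwres`` and ``area``.  Returns (ranking table, fitted models by
    name).  Models that fail to converge are flagged and ranked last.
    """
    y = males["success"].to_numpy(dtype=float)
    n = len(males)
    multi_area = males["area"].nunique() > 1
    rows = []
    fits: dict[str, object] = {}
    model_set = list(SELECTION_MODELS) + (QUADRATIC_MODELS if include_quadratic else [])
    for name, terms in model_set:
        if not multi_area and any("area" in t for t in terms):
            continue
        X = _design(males, terms)
        converged = True
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True)) and np.all(
                np.isfinite(fit.bse)
            )
        except Exception:
            fit = None
            converged = False
        aicc = _aicc(fit, n) if (fit is not None and converged) else float("inf")
        rows.append(
            {
                "model": name,
                "p": len(terms) + 1,
                "aicc": aicc,
                "converged": converged,
            }
        )
        if fit is not None:
            fits[name] = fit
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    return table, fits


def janzen_stern_gradient(fit, coef_index: int | None = None) -> float | np.ndarray:
    """Approximate selection gradient(s) from a fitted logistic model.

    β_avggrad_j = b_j · mean_i[ŵ_i (1 - ŵ_i)] / w̄, with ŵ the fitted
    success probabilities and w̄ the mean observed success.
    """
    w_hat = np.asarray(fit.predict())
    y = np.asarray(fit.model.endog, dtype=float)
    wbar = y.mean()
    if wbar == 0:
        raise ValueError("no successful individuals: gradient undefined")
    scale = float(np.mean(w_hat * (1 - w_hat)) / wbar)
    coefs = np.asarray(fit.params)[1:]  # drop intercept
    grads = coefs * scale
    if coef_index is not None:
        return float(grads[coef_index])
    return grads


def mean_standardized_gradient(
    beta_avggrad: float, trait_mean: float, trait_sd: float, trait: str = "CL"
) -> float:
    """β_μ = β_avggrad · mean / SD (unstandardized trait scale).

    Only defined for absolute traits (CL, CW); residual claw size has no
    natural zero, so requesting it is an error.
    """
    if trait.upper() in ("CW_RES", "CWRES"):
        raise ValueError("mean-standardized gradient undefined for residual traits")
    if trait_sd <= 0:
        raise ValueError("trait SD must be positive")
    return float(beta_avggrad * trait_mean / trait_sd)


# ---------------------------------------------------------------------------
# Assortative mating


@dataclass(frozen=True)
class AssortativeFit:
    slope: float
    slope_se: float
    area_effect: float | None
    r_squared: float
    lrt_chi2: float | None
    lrt_p: float | None
    n: int
    additive_supported: bool | None


def assortative_model(pairs: pd.DataFrame) -> AssortativeFit:
    """Male adjusted CL on female CL with an area term.

    Fits the interaction model (female CL × area) against the additive one
    and reports the 1-df likelihood-ratio test; inference (slope, area
    effect, R²) comes from the additive model.  With a single area the area
    terms are dropped.
    """
    df = pairs.loc[~pairs.get("interarea", pd.Series(False, index=pairs.index))]
    y = df["male_cl"].to_numpy(dtype=float)
    x = df["female_cl"].to_numpy(dtype=float)
    areas = df["area"].astype(str)
    multi_area = areas.nunique() > 1
    if multi_area and any((areas == a).sum() < 3 for a in areas.unique()):
        raise ValueError("need >= 3 pairs per area")
    if not multi_area and len(df) < 3:
        raise ValueError("need >= 3 pairs")
    if multi_area:
        area_ind = (areas == "reserve").to_numpy(dtype=float)
        X_add = np.column_stack([np.ones_like(x), x, area_ind])
        X_int = np.column_stack([np.ones_like(x), x, area_ind, x * area_ind])
        fit_add = sm.OLS(y, X_add).fit()
        fit_int = sm.OLS(y, X_int).fit()
        lrt = float(2 * (fit_int.llf - fit_add.llf))
        lrt_p = float(stats.chi2.sf(lrt, df=1))
        return AssortativeFit(
            slope=float(fit_add.params[1]),
            slope_se=float(fit_add.bse[1]),
            area_effect=float(fit_add.params[2]),
            r_squared=float(fit_add.rsquared),
            lrt_chi2=lrt,
            lrt_p=lrt_p,
            n=len(df),
            additive_supported=lrt_p > 0.05,
        )
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return AssortativeFit(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        area_effect=None,
        r_squared=float(fit.rsquared),
        lrt_chi2=None,
        lrt_p=None,
        n=len(df),
        additive_supported=None,
    )


def pair_size_gap(pairs: pd.DataFrame, area: str | None = None) -> tuple[float, float, float]:
    """Mean within-pair relative size gap and a Welch test of male vs female CL.

    Gap per pair = (male adjusted CL - female CL) / female CL × 100.
    Returns (mean gap %, Welch t, two-tailed p).
    """
    df = pairs if area is None else pairs.loc[pairs["area"] == area]
    if len(df) < 2:
        raise ValueError("need >= 2 pairs")
    male = df["male_cl"].to_numpy(dtype=float)
    female = df["female_cl"].to_numpy(dtype=float)
    gap = float(np.mean((male - female) / female * 100.0))
    t, p = stats.ttest_ind(male, female, equal_var=False)
    return gap, float(t), float(p)
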