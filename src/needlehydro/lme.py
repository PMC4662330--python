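"""Mixed-effects inference for needle traits, plus the sap-flow t-test.

Each trait is analysed at the needle level with linear mixed-effects
models whose random part is an intercept for each tree and an intercept
for each shoot nested in its tree — the structure induced by the
hierarchical sampling (needles within shoots within trees).  Fixed
effects are canopy position (sun/shade), watering treatment
(control/drought), and their interaction.

Significance of the fixed effects follows the nested-model
likelihood-ratio ladder: each simpler model is compared with the
relevant more complex model by a chi-square LRT on maximum-likelihood
fits (REML likelihoods of models with different fixed effects are not
comparable).  Group means with Wald 95% confidence intervals come from
the REML fit of the full interaction model.  Needle conductivity k_th is
log-transformed before analysis (its distribution is strongly
right-skewed); its group means are reported back-transformed as
geometric means and flagged as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .hydraulics import TRAIT_COLUMNS
from .io import CANOPIES, TREATMENTS

__all__ = [
    "LmeSpec",
    "FitSummary",
    "SapflowTest",
    "DEFAULT_TRANSFORMS",
    "FACTOR_LABELS",
    "fit_trait_model",
    "lrt_ladder",
    "group_means_ci",
    "full_report",
    "sapflow_ttest",
]

#: Fixed-effect structures, keyed by the shorthand used throughout.
_FIXED_FORMULAS = {
    "canopy": "C(canopy)",
    "drought": "C(treatment)",
    "canopy+drought": "C(canopy) + C(treatment)",
    "canopy*drought": "C(canopy) * C(treatment)",
}

#: Default response transforms; only k_th is log-transformed.
DEFAULT_TRANSFORMS: dict[str, str] = {"k_th": "log"}

#: Human-readable factor labels used in the test ladder output.
FACTOR_LABELS = {
    "canopy": "canopy height",
    "drought": "drought",
    "interaction": "drought x canopy height",
}

#: Traits analysed by the full report (the reported trait set; the SI-scale
#: duplicate of k_s is carried in the tables but not analysed twice).
ANALYSIS_TRAITS = [c for c in TRAIT_COLUMNS if c != "k_s_si"]


@dataclass(frozen=True)
class LmeSpec:
    """One trait's model specification."""

    trait: str
    transform: str = "identity"   # 'identity' | 'log'
    fixed: str = "canopy*drought"  # key into the fixed-effect structures

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.fixed not in _FIXED_FORMULAS:
            raise ValueError(f"unknown fixed-effect structure {self.fixed!r}")


@dataclass
class FitSummary:
    """Condensed fit result (one model, one trait)."""

    trait: str
    fixed: str
    transform: str
    reml: bool
    llf: float
    aic: float
    n_obs: int
    n_params: int
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    vc: dict[str, float]
    sigma2: float
    converged: bool
    degenerate: bool = False
    design_info: object | None = field(default=None, repr=False)


def _prepare(df: pd.DataFrame, spec: LmeSpec) -> pd.DataFrame:
    for col in ("canopy", "treatment", "tree_id", "shoot_id", spec.trait):
        if col not in df.columns:
            raise ValueError(f"traits table lacks required column {col!r}")
    for trt in TREATMENTS:
        if df.loc[df["treatment"] == trt, "tree_id"].nunique() < 2:
            raise ValueError(f"need >= 2 trees per plot (treatment {trt!r})")
    shoots_per_tree = df.groupby("tree_id")["shoot_id"].nunique()
    if (shoots_per_tree < 2).any():
        raise ValueError("need >= 2 shoots per tree for the nested random effect")
    out = df[["canopy", "treatment", "tree_id", "shoot_id"]].copy()
    y = df[spec.trait].astype(float)
    if spec.transform == "log":
        if (y <= 0).any():
            raise ValueError(f"log transform of {spec.trait} requires positive values")
        y = np.log(y)
    out["_y"] = y
    return out


def _cell_means(data: pd.DataFrame) -> pd.Series:
    return data.groupby(["canopy", "treatment"], observed=True)["_y"].mean()


def _ols_summary(data: pd.DataFrame, formula: str, spec: LmeSpec, reml: bool,
                 degenerate: bool) -> FitSummary:
    """OLS fallback: the ML solution when all variance components vanish."""
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    ols = sm.OLS(y, X).fit()
    fe = ols.params.copy()
    fe.index = X.columns
    zero_resid = degenerate
    # count the (boundary-zero) variance components so AICs stay comparable
    # with the mixed fits in the same ladder
    k = int(X.shape[1]) + (1 if degenerate else 3)
    return FitSummary(
        trait=spec.trait, fixed=spec.fixed, transform=spec.transform,
        reml=reml, llf=float(ols.llf), aic=float(-2.0 * ols.llf + 2.0 * k),
        n_obs=int(len(data)), n_params=k,
        fe_params=fe,
        fe_cov=ols.cov_params() * (0.0 if zero_resid else 1.0),
        vc={"tree": 0.0, "shoot(tree)": 0.0},
        sigma2=0.0 if zero_resid else float(ols.scale),
        converged=True, degenerate=degenerate,
        design_info=X.design_info,
    )


def fit_trait_model(
    traits: pd.DataFrame,
    spec: LmeSpec,
    reml: bool = False,
) -> FitSummary:
    """Fit one trait's mixed model.

    Maximum likelihood (``reml=False``) is the default because every fit
    that feeds a likelihood-ratio comparison must be ML; the final
    reported model (group means and intervals) uses REML.

    Data in which the random effects and residual variance all vanish
    (e.g. a zero-dispersion simulation) are detected and fitted by
    ordinary least squares with zero variance components, flagged
    ``degenerate`` — the mixed-model likelihood is singular there.
    """
    data = _prepare(traits, spec)
    formula = "_y ~ " + _FIXED_FORMULAS[spec.fixed]

    # degenerate-variance escape hatch: zero residual variance
    resid_var = data.groupby(["canopy", "treatment"], observed=True)["_y"].var(ddof=0)
    scale = float(np.mean(np.square(data["_y"]))) or 1.0
    if float(resid_var.fillna(0.0).max()) <= 1e-16 * scale:
        return _ols_summary(data, formula, spec, reml, degenerate=True)

    model = smf.mixedlm(
        formula, data, groups="tree_id",
        re_formula="1", vc_formula={"shoot": "0 + C(shoot_id)"},
    )
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            try:
                result = model.fit(reml=reml, method=method, maxiter=200)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if result is None:
            raise RuntimeError(f"mixed-model fit failed for {spec.trait} ({spec.fixed})")
        # Near the variance boundary (a component ~0) the quasi-Newton
        # optimiser can report convergence short of the optimum, which
        # corrupts likelihood-ratio differences; polish with direct-search
        # fits (warm-started and from scratch) and keep the best likelihood.
        tau_min = min(float(result.cov_re.iloc[0, 0]),
                      float(result.vcomp[0]) if len(result.vcomp) else np.inf)
        if not result.converged or tau_min < 1e-3 * float(result.scale):
            for start in (result.params_object, None):
                try:
                    polished = model.fit(reml=reml, method="powell", maxiter=500,
                                         start_params=start)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if polished.llf >= result.llf:
                    result = polished
    converged = bool(getattr(result, "converged", False))

    # At the boundary the ML solution collapses to OLS (all variance
    # components zero); if plain OLS attains a higher ML likelihood than the
    # best mixed fit, that OLS solution *is* the maximum-likelihood fit.
    if not reml:
        ols = _ols_summary(data, formula, spec, reml, degenerate=False)
        if ols.llf > result.llf + 1e-9:
            return ols

    k_fe = len(result.fe_params)
    n_params = k_fe + 2 + 1  # fixed effects + tree & shoot variances + residual
    aic = float(-2.0 * result.llf + 2.0 * n_params)
    fe_cov = result.cov_params().iloc[:k_fe, :k_fe]
    vc = {
        "tree": float(result.cov_re.iloc[0, 0]),
        "shoot(tree)": float(result.vcomp[0]) if len(result.vcomp) else 0.0,
    }
    return FitSummary(
        trait=spec.trait, fixed=spec.fixed, transform=spec.transform,
        reml=reml, llf=float(result.llf), aic=aic,
        n_obs=int(result.nobs), n_params=n_params,
        fe_params=result.fe_params, fe_cov=fe_cov,
        vc=vc, sigma2=float(result.scale),
        converged=converged,
        design_info=model.data.design_info,
    )


def _lrt_row(trait: str, factor: str, simple: FitSummary, complex_: FitSummary,
             df: int) -> dict:
    lrt = max(0.0, 2.0 * (complex_.llf - simple.llf))
    return {
        "trait": trait,
        "factor": FACTOR_LABELS[factor],
        "aic_simple": simple.aic,
        "aic_complex": complex_.aic,
        "lrt": lrt,
        "df": df,
        "p": float(stats.chi2.sf(lrt, df)),
        "converged": bool(simple.converged and complex_.converged),
    }


def lrt_ladder(
    traits: pd.DataFrame,
    trait: str,
    transform: str | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test ladder for one trait.

    Three chi-square tests, each comparing a simpler against the relevant
    more complex ML fit (1 df each):

    * canopy height:           (drought)        vs (canopy + drought)
    * drought:                 (canopy)         vs (canopy + drought)
    * drought x canopy height: (canopy+drought) vs (canopy x drought)

    The AIC of both models in each comparison is reported.
    """
    if transform is None:
        transform = DEFAULT_TRANSFORMS.get(trait, "identity")
    fits = {
        fixed: fit_trait_model(traits, LmeSpec(trait, transform, fixed), reml=False)
        for fixed in ("canopy", "drought", "canopy+drought", "canopy*drought")
    }
    rows = [
        _lrt_row(trait, "canopy", fits["drought"], fits["canopy+drought"], 1),
        _lrt_row(trait, "drought", fits["canopy"], fits["canopy+drought"], 1),
        _lrt_row(trait, "interaction", fits["canopy+drought"], fits["canopy*drought"], 1),
    ]
    return pd.DataFrame(rows)


def group_means_ci(
    traits: pd.DataFrame,
    trait: str,
    transform: str | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Model-based group means with Wald confidence intervals.

    REML fit of the full interaction model; each 2x2 cell mean is a
    linear combination of the fixed effects with variance x' V x.  For
    log-transformed traits the back-transformed values are geometric
    means (``scale`` column says which).
    """
    if transform is None:
        transform = DEFAULT_TRANSFORMS.get(trait, "identity")
    fit = fit_trait_model(traits, LmeSpec(trait, transform, "canopy*drought"), reml=True)
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for canopy in CANOPIES:
        for trt in TREATMENTS:
            cell = pd.DataFrame({"canopy": [canopy], "treatment": [trt]})
            x = np.asarray(
                patsy.dmatrix(fit.design_info, cell, return_type="matrix")
            ).ravel()
            mean = float(x @ fit.fe_params.to_numpy())
            se = float(np.sqrt(x @ fit.fe_cov.to_numpy() @ x))
            lo, hi = mean - z * se, mean + z * se
            if transform == "log":
                mean, lo, hi = np.exp(mean), np.exp(lo), np.exp(hi)
            rows.append({
                "trait": trait, "canopy": canopy, "treatment": trt,
                "mean": mean, "ci_lo": lo, "ci_hi": hi,
                "scale": "geometric" if transform == "log" else "arithmetic",
                "converged": fit.converged,
            })
    return pd.DataFrame(rows)


def full_report(
    traits: pd.DataFrame,
    analysis_traits: Sequence[str] = ANALYSIS_TRAITS,
    transforms: Mapping[str, str] = DEFAULT_TRANSFORMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AIC/p-value ladder and group means with CIs for every trait.

    Returns ``(tests, means)``: the per-trait likelihood-ratio ladder and
    the per-trait 2x2 group means table.
    """
    tests = pd.concat(
        [lrt_ladder(traits, t, transforms.get(t, "identity")) for t in analysis_traits],
        ignore_index=True,
    )
    means = pd.concat(
        [group_means_ci(traits, t, transforms.get(t, "identity")) for t in analysis_traits],
        ignore_index=True,
    )
    return tests, means


@dataclass(frozen=True)
class SapflowTest:
    """Two-sample t-test of accumulated per-tree sap-flow totals."""

    t: float
    p: float
    mean_control: float
    mean_drought: float
    percent_reduction: float
    df: int


def sapflow_ttest(
    control: Sequence[float],
    drought: Sequence[float],
) -> SapflowTest:
    """Classical pooled-variance two-sample two-tailed t-test.

    Also reports the percent reduction of the drought-group mean relative
    to control (positive = reduction).
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(drought, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 trees per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):  # zero pooled variance
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    return SapflowTest(
        t=float(t), p=float(p),
        mean_control=float(a.mean()), mean_drought=float(b.mean()),
        percent_reduction=100.0 * (a.mean() - b.mean()) / a.mean(),
        df=len(a) + len(b) - 2,
    )
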