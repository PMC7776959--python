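"""Reciprocal-transplant fitness analysis.

Composite fitness per plant is binary survival times ln(1 + biomass).
Cell (habitat x phenotype) means are standardized within each habitat by
the most-fit phenotype to give relative fitness; the selection
coefficient is one minus relative fitness. Uncertainty comes from a
seeded percentile bootstrap truncated to [0, 1]. Fitness models are
negative-binomial GLMs (log link, dispersion profiled by ML) on the
ln(1 + x) scale — non-integer responses are accepted via the
quasi-likelihood IRLS contract — compared with likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import ContractError, FitError, ValidationError
from .io_core import TransplantTable


@dataclass
class FitnessSummary:
    """Per habitat x phenotype fitness cell.

    ``relative_w`` standardizes the cell's composite fitness by the
    most-fit phenotype in the same habitat; ``s = 1 - relative_w``;
    ``ci`` is a percentile bootstrap interval for ``s`` truncated to
    [0, 1] (None when the bootstrap is skipped).
    """

    habitat: str
    phenotype: str
    n: int
    mean_growth: float
    survival_frac: float
    composite: float
    relative_w: float
    s: float
    ci: tuple[float, float] | None = None


@dataclass
class GlmResult:
    """Fitted GLM with profiled dispersion.

    ``alpha`` is the NB2 dispersion (variance mu + alpha*mu^2; R's
    glm.nb theta is 1/alpha); zero for families without it.
    """

    params: pd.Series
    bse: pd.Series
    alpha: float
    deviance: float
    loglik: float
    formula: str
    df_model: int
    nobs: int


def composite_fitness(T: TransplantTable) -> np.ndarray:
    """Per-plant composite fitness: survived * ln(1 + biomass)."""
    biomass = T.df["biomass"].to_numpy(dtype=float)
    if (biomass < 0).any():
        raise ValidationError("negative biomass")
    surv = T.df["survived"].to_numpy(dtype=float)
    return surv * np.log1p(biomass)


def _habitat_summaries(df: pd.DataFrame, w: np.ndarray):
    """Cell composite-fitness means and habitat-relative fitness."""
    tmp = df.assign(_w=w)
    cells = (tmp.groupby(["habitat", "phenotype"], observed=True)["_w"]
             .agg(["mean", "size"]))
    rel = {}
    for hab in tmp["habitat"].unique():
        sub = cells.loc[hab]
        top = float(sub["mean"].max())
        for phe, row in sub.iterrows():
            rel[(hab, phe)] = (row["mean"] / top) if top > 0 else float("nan")
    return cells, rel


def selection_coefficients(
    T: TransplantTable,
    n_boot: int = 1000,
    seed: int | None = None,
    resample: str = "cell",
) -> list[FitnessSummary]:
    """Selection coefficients per habitat x phenotype with bootstrap CIs.

    Every habitat must contain at least two phenotypes with plants. The
    bootstrap resamples plants within cells (``resample="cell"``,
    default) or within habitats (``"habitat"``); CIs are empirical
    2.5/97.5 percentiles of s, truncated to [0, 1]. A habitat whose best
    cell has zero fitness gets NaN relative fitness and s.
    """
    if resample not in ("cell", "habitat"):
        raise ValidationError(f"unknown resample scheme {resample!r}")
    df = T.df
    for hab, sub in df.groupby("habitat", observed=True):
        if sub["phenotype"].nunique() < 2:
            raise ValidationError(
                f"habitat {hab!r} has <2 phenotypes with plants")
    w = composite_fitness(T)
    cells, rel = _habitat_summaries(df, w)

    boot_s: dict[tuple[str, str], list[float]] = {k: [] for k in rel}
    if n_boot > 0:
        if seed is None:
            raise ValidationError("bootstrap requires a seed")
        rng = np.random.default_rng(seed)
        group_cols = (["habitat", "phenotype"] if resample == "cell"
                      else ["habitat"])
        groups = [(key, idx.to_numpy())
                  for key, idx in df.groupby(group_cols, observed=True).groups.items()]
        for _ in range(n_boot):
            take = np.concatenate([
                idx[rng.integers(0, len(idx), len(idx))] for _, idx in groups])
            bdf = df.loc[take]
            bw = w[take]
            _, brel = _habitat_summaries(bdf, bw)
            for key in boot_s:
                if key in brel:
                    boot_s[key].append(1.0 - brel[key])

    out = []
    grouped = df.groupby(["habitat", "phenotype"], observed=True)
    for (hab, phe), sub in grouped:
        wi = w[sub.index.to_numpy()]
        relw = rel[(hab, phe)]
        s = 1.0 - relw if np.isfinite(relw) else float("nan")
        ci = None
        if n_boot > 0:
            draws = np.array(boot_s[(hab, phe)], dtype=float)
            draws = draws[np.isfinite(draws)]
            if len(draws):
                lo, hi = np.percentile(draws, [2.5, 97.5])
                ci = (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))
        out.append(FitnessSummary(
            habitat=hab, phenotype=phe, n=len(sub),
            mean_growth=float(np.log1p(sub["biomass"].to_numpy(float)).mean()),
            survival_frac=float(sub["survived"].mean()),
            composite=float(wi.mean()),
            relative_w=float(relw), s=float(s), ci=ci,
        ))
    return out


def summaries_to_frame(summaries: list[FitnessSummary]) -> pd.DataFrame:
    rows = []
    for f in summaries:
        rows.append({
            "habitat": f.habitat, "phenotype": f.phenotype, "n": f.n,
            "mean_growth": f.mean_growth, "survival_frac": f.survival_frac,
            "composite": f.composite, "relative_w": f.relative_w, "s": f.s,
            "s_ci_low": f.ci[0] if f.ci else np.nan,
            "s_ci_high": f.ci[1] if f.ci else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# negative-binomial GLM (glm.nb analog)
# ---------------------------------------------------------------------------

def _nb_loglik_alpha(alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    """NB2 log-likelihood in alpha given the mean vector (continuous y OK)."""
    inv = 1.0 / alpha
    return float(np.sum(
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
        + y * np.log(alpha * mu / (1 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    ))


def _profile_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    res = minimize_scalar(
        lambda la: -_nb_loglik_alpha(np.exp(la), y, mu),
        bounds=(np.log(1e-8), np.log(1e6)), method="bounded",
        options={"xatol": 1e-8})
    return float(np.exp(res.x))


def fit_nb_glm(
    data: pd.DataFrame,
    formula: str,
    family: str = "nb",
    max_rounds: int = 30,
    tol: float = 1e-8,
) -> GlmResult:
    """Log-link GLM with negative-binomial variance, dispersion profiled
    by ML (alternating IRLS / alpha steps, matching R's glm.nb).

    Non-integer, nonnegative responses are accepted (quasi-likelihood
    contract). ``family="gamma"`` fits a log-link Gamma GLM instead.
    """
    if family == "gamma":
        model = smf.glm(formula, data=data,
                        family=sm.families.Gamma(sm.families.links.Log()))
        res = model.fit()
        return GlmResult(res.params, res.bse, 0.0, float(res.deviance),
                         float(res.llf), formula, int(res.df_model),
                         int(res.nobs))
    if family != "nb":
        raise ValidationError(f"unknown family {family!r}")

    # initialize alpha from a Poisson fit's method-of-moments residuals
    pois = smf.glm(formula, data=data, family=sm.families.Poisson()).fit()
    y = np.asarray(pois.model.endog, dtype=float)
    if (y < 0).any():
        raise ValidationError("response must be nonnegative")
    mu = np.asarray(pois.fittedvalues, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = float(np.nansum(((y - mu) ** 2 - mu) / mu**2) / len(y))
    alpha = max(mom, 1e-6)
    res = None
    for _ in range(max_rounds):
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            res = smf.glm(formula, data=data, family=fam).fit(
                start_params=res.params if res is not None else None)
        except Exception as exc:
            raise FitError(f"IRLS failed at alpha={alpha:.4g}: {exc}") from exc
        mu = np.asarray(res.fittedvalues, dtype=float)
        new_alpha = _profile_alpha(y, mu)
        if abs(new_alpha - alpha) <= tol * (abs(alpha) + tol):
            alpha = new_alpha
            break
        alpha = new_alpha
    fam = sm.families.NegativeBinomial(alpha=alpha)
    res = smf.glm(formula, data=data, family=fam).fit(start_params=res.params)
    ll = _nb_loglik_alpha(alpha, y, np.asarray(res.fittedvalues, float))
    return GlmResult(res.params, res.bse, alpha, float(res.deviance),
                     ll, formula, int(res.df_model), int(res.nobs))


def lr_interaction_test(full: GlmResult, reduced: GlmResult
                        ) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Returns ``(LR statistic, df, p)`` with p from chi-square. Models must
    be fit to the same observations, and the reduced model's terms must
    be a subset of the full model's.
    """
    if full.nobs != reduced.nobs:
        raise ContractError("models fit to different numbers of observations")
    if not set(reduced.params.index) <= set(full.params.index):
        raise ContractError("reduced model is not nested in full model")
    df = full.df_model - reduced.df_model
    if df < 0:
        raise ContractError("reduced model has more parameters than full")
    lr = 2.0 * (full.loglik - reduced.loglik)
    if df == 0:
        return max(lr, 0.0), 0, 1.0
    lr = max(lr, 0.0)
    return lr, df, float(chi2.sf(lr, df))
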