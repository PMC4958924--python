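"""Pairwise yield-herbicide-weed analyses with linear mixed models.

This stage mirrors the screening analysis that precedes the
hierarchical modelling: per-field responses (yield, richness, weed
frequency) regressed on per-field predictors (total dose, TFI,
richness, weed frequency) with random intercepts for farm — and for
field nested within farm where the data carry replicate observations
per field; with one observation per field the field intercept is
confounded with the residual and the fit silently reduces to the
farm-level structure, recording the reduction in the result tag.

The mixed model is fitted by REML on the marginal Gaussian likelihood,
and the slope test uses the Satterthwaite approximation for the
denominator degrees of freedom: the variance of the slope variance is
obtained by the delta method from the numeric gradient of
Var(beta_hat) with respect to the variance components and the inverse
observed REML information.  AIC values for covariate screening come
from a maximum-likelihood refit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import WeedSurveyDataset

__all__ = [
    "ApplicationRecord",
    "LMMResult",
    "compute_tfi",
    "weed_frequency",
    "pairwise_lmm",
    "aic_screen",
    "run_descriptive_stage",
    "DEFAULT_PANELS",
]


@dataclass(frozen=True)
class ApplicationRecord:
    """One herbicide application on one field."""

    field_id: str
    product: str
    ai_dose_kg_ha: float
    recommended_dose_kg_ha: Optional[float] = None
    week: Optional[int] = None
    spectrum: str = "broad"

    def __post_init__(self) -> None:
        if self.ai_dose_kg_ha < 0:
            raise ValueError("applied dose must be >= 0")


def compute_tfi(applications, field_id: str) -> float:
    """Treatment Frequency Indicator for one field.

    The sum over the field's applications of applied dose divided by
    the product's recommended dose; 0 for untreated fields.  A missing
    recommended dose raises an error naming the product.
    """
    if isinstance(applications, pd.DataFrame):
        rows = applications[applications["field_id"] == field_id]
        records = [
            ApplicationRecord(
                field_id=r.field_id,
                product=r.product,
                ai_dose_kg_ha=r.ai_dose_kg_ha,
                recommended_dose_kg_ha=(
                    None if pd.isna(r.recommended_dose_kg_ha)
                    else r.recommended_dose_kg_ha
                ),
            )
            for r in rows.itertuples()
        ]
    else:
        records = [a for a in applications if a.field_id == field_id]
    total = 0.0
    for rec in records:
        if rec.recommended_dose_kg_ha is None or rec.recommended_dose_kg_ha <= 0:
            raise ValueError(
                f"recommended dose missing for product {rec.product!r} "
                f"on field {field_id!r}"
            )
        total += rec.ai_dose_kg_ha / rec.recommended_dose_kg_ha
    return total


def weed_frequency(observations, field_id: str) -> int:
    """Per-field count of (species x quadrat) presence records."""
    if isinstance(observations, pd.DataFrame):
        rows = observations[
            (observations["field_id"] == field_id)
            & observations["present"].astype(bool)
        ]
        return int(len(rows))
    return sum(
        1 for o in observations if o.field_id == field_id and o.present
    )


# ---------------------------------------------------------------------------
# REML mixed model with Satterthwaite df
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Slope inference for one pairwise relationship."""

    estimate: float
    se: float
    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    aic: float
    loglik_reml: float
    sigma2: dict  # variance components by name
    random_structure: str
    n_obs: int


def _build_z(groups: np.ndarray) -> np.ndarray:
    labels, idx = np.unique(groups, return_inverse=True)
    Z = np.zeros((groups.size, labels.size))
    Z[np.arange(groups.size), idx] = 1.0
    return Z


class _MarginalGaussian:
    """Marginal covariance V = sum_k s2_k Z_k Z_k' + s2_e I and the
    profile (RE)ML criteria over the variance components."""

    def __init__(self, y, X, z_list):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.ZZ = [Z @ Z.T for Z in z_list]
        self.n, self.p = self.X.shape

    def _v(self, theta):
        # theta: (s2_1, ..., s2_k, s2_e) on the natural scale
        V = theta[-1] * np.eye(self.n)
        for s2, ZZ in zip(theta[:-1], self.ZZ):
            V += s2 * ZZ
        return V

    def gls(self, theta):
        V = self._v(theta)
        L = np.linalg.cholesky(V)
        Vi_X = np.linalg.solve(V, self.X)
        Vi_y = np.linalg.solve(V, self.y)
        XtViX = self.X.T @ Vi_X
        C = np.linalg.inv(XtViX)
        beta = C @ (self.X.T @ Vi_y)
        resid = self.y - self.X @ beta
        Vi_r = np.linalg.solve(V, resid)
        logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
        return beta, C, float(resid @ Vi_r), logdet_V, XtViX

    def reml(self, theta):
        beta, C, quad, logdet_V, XtViX = self.gls(theta)
        sign, logdet_X = np.linalg.slogdet(XtViX)
        return -0.5 * (
            logdet_V + logdet_X + quad + (self.n - self.p) * np.log(2 * np.pi)
        )

    def ml(self, theta):
        beta, C, quad, logdet_V, _ = self.gls(theta)
        return -0.5 * (logdet_V + quad + self.n * np.log(2 * np.pi))


def _fit_variances(model: _MarginalGaussian, criterion: str, floor: float):
    k = len(model.ZZ) + 1
    # starting values from the OLS residual variance
    beta0, *_ = np.linalg.lstsq(model.X, model.y, rcond=None)
    resid_var = float(np.var(model.y - model.X @ beta0)) + floor
    x0 = np.log(np.full(k, resid_var / k) + floor)
    fun = model.reml if criterion == "reml" else model.ml

    def neg(log_theta):
        theta = np.exp(np.clip(log_theta, np.log(floor), 50.0)) + 0.0
        return -fun(theta)

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    theta = np.exp(np.clip(res.x, np.log(floor), 50.0))
    return theta, -res.fun


def _satterthwaite_df(model, theta_hat, contrast, floor):
    """Denominator df for a single fixed-effect contrast.

    df = 2 f^2 / (g' A g) with f = Var(c'beta_hat) as a function of the
    variance components, g its numeric gradient and A the inverse
    observed REML information.
    """
    c = np.asarray(contrast, dtype=float)

    def f(theta):
        _, C, *_ = model.gls(theta)
        return float(c @ C @ c)

    k = theta_hat.size
    h = np.maximum(1e-4 * theta_hat, 1e-2 * floor)
    g = np.empty(k)
    for i in range(k):
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[i] += h[i]
        tm[i] = max(tm[i] - h[i], floor)
        g[i] = (f(tp) - f(tm)) / (tp[i] - tm[i])
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            tpp, tpm, tmp, tmm = (theta_hat.copy() for _ in range(4))
            tpp[i] += h[i]; tpp[j] += h[j]
            tpm[i] += h[i]; tpm[j] = max(tpm[j] - h[j], floor)
            tmp[i] = max(tmp[i] - h[i], floor); tmp[j] += h[j]
            tmm[i] = max(tmm[i] - h[i], floor); tmm[j] = max(tmm[j] - h[j], floor)
            di = tpp[i] - tmp[i]
            dj = tpp[j] - tpm[j]
            H[i, j] = H[j, i] = (
                model.reml(tpp) - model.reml(tpm) - model.reml(tmp) + model.reml(tmm)
            ) / (di * dj)
    info = -H
    try:
        A = np.linalg.inv(info)
        denom = float(g @ A @ g)
    except np.linalg.LinAlgError:
        denom = np.nan
    f_hat = f(theta_hat)
    if not np.isfinite(denom) or denom <= 0:
        return float(model.n - model.p)
    return float(2.0 * f_hat**2 / denom)


def pairwise_lmm(
    response: Sequence[float],
    predictor: Sequence[float],
    farm_ids: Sequence,
    field_ids: Optional[Sequence] = None,
    covariate: Optional[Sequence[float]] = None,
    random_structure: str = "nested",
) -> LMMResult:
    """Mixed-model slope of ``response`` on ``predictor``.

    Random intercepts for farm and — when ``random_structure ==
    'nested'`` and fields carry replicate observations — for field
    within farm.  Rows with missing response, predictor or covariate
    are dropped.  Returns the slope, its standard error, the type III
    F test with Satterthwaite denominator df, and the ML-based AIC.
    """
    df = pd.DataFrame({"y": response, "x": predictor, "farm": farm_ids})
    if field_ids is not None:
        df["field"] = field_ids
    if covariate is not None:
        df["cov"] = covariate
    df = df.dropna()
    n = len(df)
    if n < 4:
        raise ValueError("too few complete observations for a mixed model")
    if df["farm"].nunique() < 3:
        raise ValueError("need >= 3 farms for the random-intercept model")

    y = df["y"].to_numpy(dtype=float)
    cols = [np.ones(n), df["x"].to_numpy(dtype=float)]
    if covariate is not None:
        cols.append(df["cov"].to_numpy(dtype=float))
    X = np.column_stack(cols)

    z_list = [_build_z(df["farm"].to_numpy())]
    tag = "farm_intercept"
    if random_structure == "nested" and field_ids is not None:
        counts = df.groupby("field").size()
        if counts.max() > 1:
            z_list.append(_build_z(df["field"].to_numpy()))
            tag = "farm+field_nested"
        else:
            tag = "farm_intercept(field_reduced)"
    elif random_structure not in ("nested", "farm"):
        raise ValueError(f"unknown random_structure {random_structure!r}")

    scale = float(np.var(y)) + 1.0
    floor = 1e-10 * scale
    model = _MarginalGaussian(y, X, z_list)
    theta, ll_reml = _fit_variances(model, "reml", floor)
    beta, C, *_ = model.gls(theta)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    se = float(np.sqrt(max(C[1, 1], floor * 1e-6)))
    df_den = _satterthwaite_df(model, theta, contrast, floor)
    f_stat = float((beta[1] / se) ** 2)
    p = float(stats.f.sf(f_stat, 1, df_den)) if np.isfinite(f_stat) else 1.0

    _, ll_ml = _fit_variances(model, "ml", floor)
    k_params = X.shape[1] + len(theta)
    aic = float(-2.0 * ll_ml + 2.0 * k_params)

    names = ["farm"] + (["field"] if len(z_list) > 1 else []) + ["residual"]
    return LMMResult(
        estimate=float(beta[1]),
        se=se,
        f_stat=f_stat,
        df_num=1.0,
        df_den=df_den,
        p_value=p,
        aic=aic,
        loglik_reml=ll_reml,
        sigma2=dict(zip(names, theta)),
        random_structure=tag,
        n_obs=n,
    )


def aic_screen(base: LMMResult, with_covariate: LMMResult) -> str:
    """Covariate-retention rule: keep the covariate only if it lowers
    the AIC by at least 2; ties and small gains keep the simpler model."""
    if base.n_obs != with_covariate.n_obs:
        raise ValueError("AIC screening requires fits on identical data")
    return "covariate" if base.aic - with_covariate.aic >= 2.0 else "base"


# ---------------------------------------------------------------------------
# the four-panel stage
# ---------------------------------------------------------------------------

DEFAULT_PANELS = (
    ("yield_q_ha", "dose"),
    ("richness", "dose"),
    ("weed_frequency", "dose"),
    ("yield_q_ha", "weed_frequency"),
)


def run_descriptive_stage(
    dataset: WeedSurveyDataset,
    panels: Iterable[tuple] = DEFAULT_PANELS,
    herbicide_indicator: str = "dose_D",
    random_structure: str = "nested",
) -> pd.DataFrame:
    """Run the pairwise mixed-model panels on one survey.

    ``dose`` in a panel resolves to ``herbicide_indicator`` (total
    dose by default, TFI via ``"tfi"``).  Returns one tidy row per
    panel with slope, SE, F, Satterthwaite df, p and AIC.
    """
    fields = dataset.fields.copy()
    fields["richness"] = dataset.richness().to_numpy()
    fields["weed_frequency"] = dataset.weed_frequency().to_numpy()
    fields["dose"] = fields[herbicide_indicator]

    rows = []
    for response, predictor in panels:
        res = pairwise_lmm(
            fields[response],
            fields[predictor],
            fields["farm_id"],
            fields["field_id"],
            random_structure=random_structure,
        )
        rows.append(
            {
                "response": response,
                "predictor": predictor,
                "estimate": res.estimate,
                "se": res.se,
                "F": res.f_stat,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p_value": res.p_value,
                "aic": res.aic,
                "random_structure": res.random_structure,
                "n_obs": res.n_obs,
            }
        )
    return pd.DataFrame(rows)
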