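"""Model families, DIC selection, effectiveness summaries and the
survival / yield-association profiles.

This module orchestrates what a full analysis does with the fitted
variants: fit every member of a family on the same data, pick the
lowest-DIC member (flagging near-ties), summarise the latent
effectiveness hierarchy, build the species x dose survival matrix and
test the effectiveness-yield association.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ModelVariant, survival_probability, treated_intensity
from .datasets import WeedSurveyDataset
from .inference import FitResult, MCMCSettings, PriorSpec, fit_variant

__all__ = [
    "VariantFamily",
    "SelectionResult",
    "EffectivenessSummary",
    "SurvivalProfile",
    "AssociationResult",
    "richness_family",
    "abundance_family",
    "fit_family",
    "select_best",
    "summarize_effectiveness",
    "survival_profile",
    "eta_yield_association",
]

_RICHNESS_MEMBERS = (
    ModelVariant.RICH_BASE,
    ModelVariant.RICH_FARM,
    ModelVariant.RICH_FIELD,
)
_ABUNDANCE_MEMBERS = (
    ModelVariant.AB_BASE,
    ModelVariant.AB_FARM,
    ModelVariant.AB_FIELD,
    ModelVariant.AB_SPEC,
)


@dataclass(frozen=True)
class VariantFamily:
    family: str
    members: tuple

    def __post_init__(self) -> None:
        for m in self.members:
            if m.family != self.family:
                raise ValueError(f"{m} does not belong to family {self.family!r}")


def richness_family() -> VariantFamily:
    return VariantFamily("richness", _RICHNESS_MEMBERS)


def abundance_family() -> VariantFamily:
    return VariantFamily("abundance", _ABUNDANCE_MEMBERS)


def fit_family(
    dataset: WeedSurveyDataset,
    family: VariantFamily,
    priors: Optional[PriorSpec] = None,
    settings: Optional[MCMCSettings] = None,
) -> List[FitResult]:
    """Fit every member of a family on identical data and settings.

    Member seeds are derived deterministically from the master seed, so
    the whole family is reproducible from one integer.
    """
    settings = settings or MCMCSettings()
    fits = []
    for i, member in enumerate(family.members):
        member_seed = int(
            np.random.SeedSequence([settings.seed, i]).generate_state(1)[0]
            % (2**31)
        )
        fits.append(
            fit_variant(
                dataset, member, priors, replace(settings, seed=member_seed)
            )
        )
    return fits


@dataclass
class SelectionResult:
    best: ModelVariant
    table: pd.DataFrame  # variant, dic, p_d, mean_deviance, n_parameters
    indistinguishable: bool
    delta_dic: float


def select_best(fits: Sequence[FitResult]) -> SelectionResult:
    """Lowest-DIC member of one family.

    A gap of less than 2 DIC units between the top two members raises
    the ``indistinguishable`` flag; exact ties resolve toward the
    member with fewer free parameters.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select among")
    families = {f.variant.family for f in fits}
    if len(families) != 1:
        raise ValueError(f"fits mix families: {sorted(families)}")
    table = pd.DataFrame(
        {
            "variant": [f.variant.value for f in fits],
            "dic": [f.dic for f in fits],
            "p_d": [f.p_d for f in fits],
            "mean_deviance": [f.mean_deviance for f in fits],
            "n_parameters": [f.n_free_parameters for f in fits],
        }
    ).sort_values(["dic", "n_parameters"], kind="stable", ignore_index=True)
    delta = float(table.loc[1, "dic"] - table.loc[0, "dic"])
    return SelectionResult(
        best=ModelVariant(table.loc[0, "variant"]),
        table=table,
        indistinguishable=delta < 2.0,
        delta_dic=delta,
    )


# ---------------------------------------------------------------------------
# effectiveness summaries
# ---------------------------------------------------------------------------

@dataclass
class EffectivenessSummary:
    """Posterior summary of the latent effectiveness hierarchy."""

    variant: ModelVariant
    farm_table: pd.DataFrame  # farm_id, mean, q2.5, q97.5
    field_table: Optional[pd.DataFrame]  # farm_id, field_id, mean, q2.5, q97.5
    within_farm_sd: Optional[pd.Series]
    fraction_below: float
    threshold: float

    @property
    def point_estimates(self) -> pd.Series:
        """Posterior-mean effectiveness at the finest available level."""
        if self.field_table is not None:
            return self.field_table.set_index("field_id")["mean"]
        return self.farm_table.set_index("farm_id")["mean"]


def summarize_effectiveness(
    fit: FitResult, threshold: float = 0.2, point: str = "mean"
) -> EffectivenessSummary:
    """Posterior-mean effectiveness tables and the fraction of units
    whose point estimate falls below ``threshold``.

    The fraction is taken over the finest fitted level (field-level
    eta_Ff when present, else farm-level eta_F).  Base variants carry
    no effectiveness and raise.
    """
    chains = fit.chains
    if "logit_eta_farm" not in chains.draws:
        raise ValueError(f"variant {fit.variant} has no effectiveness parameters")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    center = np.mean if point == "mean" else np.median

    eta_F = chains.natural_draws("logit_eta_farm").reshape(-1, len(chains.farm_ids))
    farm_table = pd.DataFrame(
        {
            "farm_id": chains.farm_ids,
            "mean": center(eta_F, axis=0),
            "q2.5": np.quantile(eta_F, 0.025, axis=0),
            "q97.5": np.quantile(eta_F, 0.975, axis=0),
        }
    )
    field_table = None
    within_sd = None
    if "logit_eta_field" in chains.draws:
        eta_Ff = chains.eta_field_draws().reshape(-1, len(chains.field_ids))
        farm_of = [chains.farm_ids[i] for i in chains.field_farm]
        field_table = pd.DataFrame(
            {
                "farm_id": farm_of,
                "field_id": chains.field_ids,
                "mean": center(eta_Ff, axis=0),
                "q2.5": np.quantile(eta_Ff, 0.025, axis=0),
                "q97.5": np.quantile(eta_Ff, 0.975, axis=0),
            }
        )
        within_sd = field_table.groupby("farm_id")["mean"].std(ddof=1)
        points = field_table["mean"].to_numpy()
    else:
        points = farm_table["mean"].to_numpy()
    fraction = float(np.mean(points < threshold))
    return EffectivenessSummary(
        variant=fit.variant,
        farm_table=farm_table,
        field_table=field_table,
        within_farm_sd=within_sd,
        fraction_below=fraction,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# survival profiling
# ---------------------------------------------------------------------------

@dataclass
class SurvivalProfile:
    """Species x dose matrix of persistence probabilities.

    Species are ordered from least to most abundant in the absence of
    herbicide (posterior-mean untreated intensity mu_s); each row is
    non-increasing in dose.
    """

    species: list  # ascending posterior-mean mu_s
    mu_s: np.ndarray
    dose_grid: np.ndarray
    matrix: np.ndarray  # (n_species, n_doses)
    dose_quantile_markers: dict

    def half_survival_dose(self) -> np.ndarray:
        """Smallest grid dose at which survival drops below 0.5 per
        species (inf when it never does)."""
        below = self.matrix < 0.5
        out = np.full(len(self.species), np.inf)
        for i in range(len(self.species)):
            idx = np.argmax(below[i])
            if below[i].any():
                out[i] = self.dose_grid[idx]
        return out


def survival_profile(
    fit: FitResult,
    dose_grid: Sequence[float],
    reference_area_W: float = 4000.0,
    doses_observed: Optional[np.ndarray] = None,
    quantiles: Sequence[float] = (0.9,),
    use_species_params: bool = True,
) -> SurvivalProfile:
    """Posterior survival matrix for an abundance fit.

    For each species the untreated intensity is the posterior mean
    mu_s; the dose response uses the species' own (a_s, b_s, mean
    eta_Ffs over fields) when fitted species-specifically, falling back
    to the shared (a, b) and field-level effectiveness otherwise.
    ``use_species_params=False`` forces the shared dose response (with
    the overall posterior-mean effectiveness) for every species, which
    isolates how the untreated abundance alone orders the survival
    profiles.  Survival at dose D is the probability that at least one
    individual persists in the reference area W.
    """
    dose_grid = np.asarray(list(dose_grid), dtype=float)
    if dose_grid.size == 0:
        raise ValueError("dose grid must be non-empty")
    chains = fit.chains
    if fit.variant.family != "abundance":
        raise ValueError("survival profiling requires an abundance fit")
    species = chains.species_ids
    mu_s = chains.natural_draws("log_mu_s").reshape(-1, len(species)).mean(axis=0)

    shared_a = shared_b = shared_eta = None
    if "log_a" in chains.draws:
        shared_a = float(np.exp(chains.draws["log_a"]).mean())
        shared_b = float(np.exp(chains.draws["log_b"]).mean())
    if "logit_eta_farm" in chains.draws:
        shared_eta = float(chains.eta_field_draws().mean())
    elif "logit_eta_fs" in chains.draws:
        from scipy.special import expit as _expit

        shared_eta = float(_expit(chains.draws["logit_eta_fs"]).mean())
    elif shared_a is not None:
        shared_eta = 1.0  # base variant: dose acts unmodulated

    spec_index = (
        {s: j for j, s in enumerate(chains.spec_species)}
        if use_species_params
        else {}
    )
    if chains.spec_species and use_species_params:
        a_s = np.exp(chains.draws["log_a_s"]).reshape(-1, len(chains.spec_species)).mean(axis=0)
        b_s = np.exp(chains.draws["log_b_s"]).reshape(-1, len(chains.spec_species)).mean(axis=0)
        from scipy.special import expit

        eta_fs = expit(chains.draws["logit_eta_fs"])  # (c, n, f, s)
        eta_s = eta_fs.reshape(-1, *eta_fs.shape[2:]).mean(axis=(0, 1))

    if not use_species_params and shared_a is None:
        # every species carries its own dose response: pool them
        shared_a = float(np.exp(chains.draws["log_a_s"]).mean())
        shared_b = float(np.exp(chains.draws["log_b_s"]).mean())

    rows_a = np.empty(len(species))
    rows_b = np.empty(len(species))
    rows_eta = np.empty(len(species))
    for i, s in enumerate(species):
        if s in spec_index:
            j = spec_index[s]
            rows_a[i], rows_b[i], rows_eta[i] = a_s[j], b_s[j], eta_s[j]
        else:
            if shared_a is None:
                raise ValueError(f"no dose-response parameters for species {s}")
            rows_a[i], rows_b[i], rows_eta[i] = shared_a, shared_b, shared_eta

    order = np.argsort(mu_s, kind="stable")
    lam = treated_intensity(
        mu_s[order][:, None],
        dose_grid[None, :],
        rows_a[order][:, None],
        rows_b[order][:, None],
        rows_eta[order][:, None],
    )
    matrix = survival_probability(lam, reference_area_W)
    markers = {}
    if doses_observed is not None and len(doses_observed):
        markers = {q: float(np.quantile(doses_observed, q)) for q in quantiles}
    return SurvivalProfile(
        species=[species[i] for i in order],
        mu_s=mu_s[order],
        dose_grid=dose_grid,
        matrix=matrix,
        dose_quantile_markers=markers,
    )


# ---------------------------------------------------------------------------
# effectiveness-yield association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    spearman: float
    ci_low: float
    ci_high: float
    p_value: float
    n_fields: int
    smoother: pd.DataFrame  # eta, yield_smoothed


def eta_yield_association(
    effectiveness: EffectivenessSummary,
    fields: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    lowess_frac: float = 0.6,
) -> AssociationResult:
    """Local-regression smoother and rank correlation of yield on
    posterior-mean field effectiveness.

    Fields with missing yields are dropped; the Spearman confidence
    interval is a percentile bootstrap over fields.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    eta = effectiveness.point_estimates
    key = "field_id" if effectiveness.field_table is not None else "farm_id"
    merged = fields[[key, "yield_q_ha"]].copy()
    merged["eta"] = merged[key].map(eta)
    merged = merged.dropna(subset=["eta", "yield_q_ha"])
    if merged["yield_q_ha"].isna().all() or len(merged) == 0:
        raise ValueError("no fields with both effectiveness and yield")
    if len(merged) < 5:
        raise ValueError("need at least 5 fields with effectiveness and yield")
    x = merged["eta"].to_numpy()
    y = merged["yield_q_ha"].to_numpy()
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        if np.ptp(y[idx]) == 0 or np.ptp(x[idx]) == 0:
            boots[i] = 0.0
        else:
            boots[i] = stats.spearmanr(x[idx], y[idx]).statistic
    sm = lowess(y, x, frac=lowess_frac, return_sorted=True)
    return AssociationResult(
        spearman=float(rho),
        ci_low=float(np.quantile(boots, 0.025)),
        ci_high=float(np.quantile(boots, 0.975)),
        p_value=float(p),
        n_fields=len(merged),
        smoother=pd.DataFrame(sm, columns=["eta", "yield_smoothed"]),
    )
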