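"""Bayesian inference for the hierarchical herbicide-weed models.

Seven model variants share one likelihood skeleton.  Richness variants
model observed per-field species richness as Poisson with mean
``mu / (1 + a*eta*D)**b``; abundance variants model per-(field, species)
quadrat-presence counts as Binomial(n_quadrats, 1 - exp(-lambda_s * w))
with ``lambda_s = mu_s / (1 + a*eta*D)**b``.  The effectiveness eta
enters at no level (base), the farm level (eta_F), the field level
(eta_Ff = eta_F * eta_f) or, for the species variant, per
(field, species) (eta_Ffs).

Priors: Normal(0, sd) on log(mu), log(a), log(b) (sd defaults to 10,
read as a standard deviation); Uniform(0, 1) on every effectiveness.

Sampling is adaptive Metropolis-within-Gibbs on unconstrained scales
(log for positive parameters, logit for effectiveness, with the exact
Jacobian in the logit prior).  Parameter blocks whose components touch
disjoint slices of the data (per-farm, per-field, per-species,
per-cell) are proposed and accepted/rejected componentwise in a single
vectorised pass, which makes the 180+-parameter field-level model
tractable without gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, expit, logit as sp_logit

from .core import (
    EffectivenessParams,
    GlobalParams,
    ModelVariant,
    SpeciesParams,
    SurveyDesign,
)
from .datasets import WeedSurveyDataset

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "ChainSet",
    "FitResult",
    "log_prior",
    "log_likelihood",
    "run_mcmc",
    "gelman_rubin",
    "compute_dic",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Priors for the hierarchical models.

    ``log_scale_sd`` is the standard deviation of the Normal(0, sd)
    priors on log(mu), log(a), log(b).  Set ``sd_is_precision`` to read
    the value with the BUGS precision convention instead (sd becomes
    1/sqrt(value)).  Effectiveness priors are fixed Uniform(0, 1).
    """

    log_scale_sd: float = 10.0
    sd_is_precision: bool = False

    def __post_init__(self) -> None:
        if self.log_scale_sd <= 0:
            raise ValueError("log_scale_sd must be > 0")

    @property
    def sd(self) -> float:
        if self.sd_is_precision:
            return 1.0 / math.sqrt(self.log_scale_sd)
        return self.log_scale_sd


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings.

    Defaults follow the full-scale analysis protocol: 3 chains of
    20,000 iterations, the first 10,000 discarded, and a pooled
    posterior sample of 20,000 draws subsampled uniformly from the
    3 x 10,000 retained iterations.
    """

    n_chains: int = 3
    n_iterations: int = 20000
    burn_in: int = 10000
    posterior_sample_size: int = 20000
    thin: int = 1
    seed: int = 0
    target_acceptance: float = 0.44
    initial_step: float = 0.5
    min_fields_for_species_eta: int = 5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")
        retained = self.n_chains * ((self.n_iterations - self.burn_in) // self.thin)
        if self.posterior_sample_size > retained:
            raise ValueError(
                f"posterior_sample_size {self.posterior_sample_size} exceeds "
                f"retained draws {retained}"
            )

    @property
    def n_stored(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# model structure: data layout + likelihood
# ---------------------------------------------------------------------------

def _stable_log_expm1_neg(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(-x)) for x > 0, stable for tiny and large x."""
    with np.errstate(divide="ignore"):
        return np.log(-np.expm1(-np.asarray(x, dtype=float)))


@dataclass
class _Block:
    """One MH update block: a named parameter array on its sampling scale.

    ``kind`` is "log" (Normal prior on the sampling scale) or "logit"
    (Uniform(0,1) prior on the natural scale, Jacobian included).
    ``scope`` says which slices of the unit log-likelihood each
    component touches: "all", "farm", "field", "species" or "cell".
    """

    name: str
    shape: tuple
    kind: str
    scope: str
    labels: list


class _ModelStructure:
    """Index arrays, parameter blocks and likelihood for one variant."""

    def __init__(
        self,
        dataset: WeedSurveyDataset,
        variant: ModelVariant,
        design: SurveyDesign,
        min_fields_for_species_eta: int = 5,
    ):
        self.variant = variant
        self.design = design
        fields_df = dataset.fields
        self.field_ids: list = list(fields_df["field_id"])
        self.farm_ids: list = list(pd.unique(fields_df["farm_id"]))
        farm_index = {f: i for i, f in enumerate(self.farm_ids)}
        self.field_farm = np.array(
            [farm_index[f] for f in fields_df["farm_id"]], dtype=int
        )
        self.dose = fields_df["dose_D"].to_numpy(dtype=float)
        self.n_fields = len(self.field_ids)
        self.n_farms = len(self.farm_ids)

        if variant.family == "richness":
            self.k_rich = dataset.richness().to_numpy(dtype=int)
            self._rich_const = -gammaln(self.k_rich + 1.0).sum() if self.n_fields else 0.0
            self.species_ids: list = []
        else:
            self.species_ids = dataset.species_ids
            summary = dataset.presence_summary()
            k = summary.pivot(index="field_id", columns="species_id", values="k_present")
            k = k.reindex(index=self.field_ids, columns=self.species_ids)
            self.k_mat = k.to_numpy(dtype=float)  # (n_fields, n_species)
            self.n_quadrats = design.quadrats_per_field
            self._binom_const = (
                gammaln(self.n_quadrats + 1.0)
                - gammaln(self.k_mat + 1.0)
                - gammaln(self.n_quadrats - self.k_mat + 1.0)
                if self.k_mat.size
                else np.zeros_like(self.k_mat)
            )
            occ = dataset.species_field_occurrence()
            if variant is ModelVariant.AB_SPEC:
                self.spec_species = [
                    s for s in self.species_ids
                    if occ[s] >= min_fields_for_species_eta
                ]
            else:
                self.spec_species = []
            self.spec_mask = np.array(
                [s in set(self.spec_species) for s in self.species_ids], dtype=bool
            )
        self.n_species = len(self.species_ids)
        self.n_spec = len(getattr(self, "spec_species", []))

        self.blocks = self._build_blocks()

    # -- block layout -------------------------------------------------

    def _build_blocks(self) -> List[_Block]:
        v = self.variant
        blocks: List[_Block] = []
        if v.family == "richness":
            blocks.append(_Block("log_mu", (), "log", "all", ["mu"]))
        else:
            blocks.append(
                _Block(
                    "log_mu_s",
                    (self.n_species,),
                    "log",
                    "species",
                    [f"mu_s[{s}]" for s in self.species_ids],
                )
            )
        # shared dose-response scale/shape: present unless every species
        # carries its own (species variant with no fallback species)
        needs_shared = not (
            v is ModelVariant.AB_SPEC and self.n_spec == self.n_species
        )
        if needs_shared:
            blocks.append(_Block("log_a", (), "log", "all", ["a"]))
            blocks.append(_Block("log_b", (), "log", "all", ["b"]))
        if v is ModelVariant.AB_SPEC:
            blocks.append(
                _Block(
                    "log_a_s",
                    (self.n_spec,),
                    "log",
                    "spec_species",
                    [f"a_s[{s}]" for s in self.spec_species],
                )
            )
            blocks.append(
                _Block(
                    "log_b_s",
                    (self.n_spec,),
                    "log",
                    "spec_species",
                    [f"b_s[{s}]" for s in self.spec_species],
                )
            )
        level = v.eta_level
        if level in ("farm", "field") or (
            v is ModelVariant.AB_SPEC and self.n_spec < self.n_species
        ):
            blocks.append(
                _Block(
                    "logit_eta_farm",
                    (self.n_farms,),
                    "logit",
                    "farm",
                    [f"eta_F[{f}]" for f in self.farm_ids],
                )
            )
        if level == "field" or (
            v is ModelVariant.AB_SPEC and self.n_spec < self.n_species
        ):
            blocks.append(
                _Block(
                    "logit_eta_field",
                    (self.n_fields,),
                    "logit",
                    "field",
                    [f"eta_f[{f}]" for f in self.field_ids],
                )
            )
        if v is ModelVariant.AB_SPEC:
            blocks.append(
                _Block(
                    "logit_eta_fs",
                    (self.n_fields, self.n_spec),
                    "logit",
                    "cell",
                    [
                        f"eta_Ffs[{f},{s}]"
                        for f in self.field_ids
                        for s in self.spec_species
                    ],
                )
            )
        return blocks

    def initial_state(self, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        """Data-scale initialisation, jittered per chain.

        Dose-response and effectiveness parameters start at 0 on their
        sampling scales (a = b = 1, eta = 0.5); the untreated means
        start at moment estimates from the observations themselves
        (mean richness, or the presence-implied per-species intensity),
        which anchors the chains in the dominant posterior basin — the
        weak priors otherwise admit a remote basin with enormous mu
        compensated by an enormous reduction.
        """
        state = {
            b.name: 0.0 + 0.1 * rng.standard_normal(b.shape) for b in self.blocks
        }
        if "log_mu" in state and self.n_fields:
            state["log_mu"] = (
                math.log(max(float(self.k_rich.mean()), 0.5))
                + 0.1 * rng.standard_normal()
            )
        if "log_mu_s" in state and self.n_fields and self.n_species:
            frac = np.clip(
                self.k_mat.mean(axis=0) / self.n_quadrats, 1e-3, 1 - 1e-3
            )
            lam0 = -np.log1p(-frac) / self.design.quadrat_area_w
            state["log_mu_s"] = np.log(lam0) + 0.1 * rng.standard_normal(
                self.n_species
            )
        return state

    # -- effectiveness assembly ---------------------------------------

    def _eta_field_level(self, state) -> np.ndarray:
        """Field-level effectiveness vector for the shared structure."""
        level = self.variant.eta_level
        if level == "none":
            return np.ones(self.n_fields)
        eta_F = expit(state["logit_eta_farm"])[self.field_farm]
        if level == "farm":
            return eta_F
        return eta_F * expit(state["logit_eta_field"])

    # -- unit log-likelihood ------------------------------------------

    def unit_loglik(self, state: Dict[str, np.ndarray]) -> np.ndarray:
        """Per-field (richness) or per-(field, species) (abundance)
        log-likelihood contributions under ``state``."""
        if self.variant.family == "richness":
            if self.n_fields == 0:
                return np.zeros(0)
            mu = np.exp(state["log_mu"])
            a = np.exp(state["log_a"])
            b = np.exp(state["log_b"])
            eta = self._eta_field_level(state)
            with np.errstate(over="ignore"):  # (1+x)^b -> inf gives lam = 0
                lam = mu / (1.0 + a * eta * self.dose) ** b
            with np.errstate(divide="ignore", invalid="ignore"):
                klog = np.where(self.k_rich > 0, self.k_rich * np.log(lam), 0.0)
            return klog - lam - gammaln(self.k_rich + 1.0)
        # abundance families
        if self.n_fields == 0 or self.n_species == 0:
            return np.zeros((self.n_fields, self.n_species))
        mu_s = np.exp(state["log_mu_s"])[None, :]
        return self._abundance_units(state, mu_s)

    def _abundance_units(self, state, mu_s) -> np.ndarray:
        # overflow in (1+x)^b harmlessly yields lam = 0; 0 * log(0) in
        # zero-count cells is repaired below
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if self.variant is ModelVariant.AB_SPEC:
                lam = np.empty((self.n_fields, self.n_species))
                if self.n_spec:
                    a_s = np.exp(state["log_a_s"])[None, :]
                    b_s = np.exp(state["log_b_s"])[None, :]
                    eta_fs = expit(state["logit_eta_fs"])
                    lam[:, self.spec_mask] = mu_s[:, self.spec_mask] / (
                        1.0 + a_s * eta_fs * self.dose[:, None]
                    ) ** b_s
                if self.n_spec < self.n_species:
                    a = np.exp(state["log_a"])
                    b = np.exp(state["log_b"])
                    eta_F = expit(state["logit_eta_farm"])[self.field_farm]
                    eta = eta_F * expit(state["logit_eta_field"])
                    fallback = ~self.spec_mask
                    lam[:, fallback] = mu_s[:, fallback] / (
                        1.0 + a * eta[:, None] * self.dose[:, None]
                    ) ** b
            else:
                a = np.exp(state["log_a"])
                b = np.exp(state["log_b"])
                eta = self._eta_field_level(state)
                lam = mu_s / (1.0 + a * eta[:, None] * self.dose[:, None]) ** b
            x = lam * self.design.quadrat_area_w
            log_p = _stable_log_expm1_neg(x)
            log_1mp = -x
            k = self.k_mat
            ll = self._binom_const + k * log_p + (self.n_quadrats - k) * log_1mp
            if np.any(k == 0):
                ll = np.where(
                    k == 0, self._binom_const + self.n_quadrats * log_1mp, ll
                )
        return ll

    def loglik_full(self, state) -> float:
        return float(np.sum(self.unit_loglik(state)))

    # -- grouping for componentwise acceptance ------------------------

    def group_delta(self, scope: str, delta_units: np.ndarray) -> np.ndarray:
        """Sum the per-unit log-likelihood change over each component's
        slice of the data."""
        if scope == "all":
            return np.array([delta_units.sum()])
        if self.variant.family == "richness":
            if scope == "farm":
                return np.bincount(
                    self.field_farm, weights=delta_units, minlength=self.n_farms
                )
            if scope == "field":
                return delta_units
            raise ValueError(f"scope {scope} undefined for richness models")
        per_field = delta_units.sum(axis=1)
        if scope == "farm":
            return np.bincount(
                self.field_farm, weights=per_field, minlength=self.n_farms
            )
        if scope == "field":
            return per_field
        if scope == "species":
            return delta_units.sum(axis=0)
        if scope == "spec_species":
            return delta_units[:, self.spec_mask].sum(axis=0)
        if scope == "cell":
            return delta_units[:, self.spec_mask]
        raise ValueError(f"unknown scope {scope}")


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _block_log_prior(x: np.ndarray, kind: str, sd: float) -> np.ndarray:
    """Elementwise log prior on the sampling scale."""
    x = np.asarray(x, dtype=float)
    if kind == "log":
        return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
    # Uniform(0,1) on expit(x) plus the logit Jacobian
    return -np.logaddexp(0.0, -x) - np.logaddexp(0.0, x)


def log_prior(
    global_params: GlobalParams,
    eta: EffectivenessParams,
    spec: PriorSpec,
    species_params: Optional[SpeciesParams] = None,
) -> float:
    """Joint log prior density of natural-scale parameters.

    Normal(0, sd) densities evaluated at log(mu), log(a), log(b) (and
    the per-species analogues when given); effectiveness values
    contribute 0 inside (0, 1) and -inf outside (Uniform(0,1) density
    on the natural scale).
    """
    sd = spec.sd
    mu = np.atleast_1d(np.asarray(global_params.mu, dtype=float))
    logs = np.concatenate(
        [np.log(mu), np.log([global_params.a, global_params.b])]
    )
    if species_params is not None:
        extra = [
            np.log(list(m.values()))
            for m in (species_params.mu_s, species_params.a_s, species_params.b_s)
            if m
        ]
        if extra:
            logs = np.concatenate([logs] + extra)
    total = float(np.sum(_block_log_prior(logs, "log", sd)))
    for mapping in (eta.eta_farm, eta.eta_field_component, eta.eta_field_species):
        for v in mapping.values():
            if not 0.0 <= v <= 1.0:
                return -math.inf
            if v in (0.0, 1.0):
                # boundary of the uniform support: density still 1 on
                # the closed interval; logit-scale sampling never lands
                # here, keep 0 contribution
                continue
    return total


def _state_from_params(
    structure: _ModelStructure,
    global_params: GlobalParams,
    eta: EffectivenessParams,
    species_params: Optional[SpeciesParams],
) -> Dict[str, np.ndarray]:
    """Natural-scale parameter objects -> sampling-scale state dict."""
    state: Dict[str, np.ndarray] = {}
    v = structure.variant
    if v.family == "richness":
        state["log_mu"] = np.log(float(np.asarray(global_params.mu)))
    else:
        mu = np.asarray(global_params.mu, dtype=float)
        if species_params is not None:
            mu = np.array([species_params.mu_s[s] for s in structure.species_ids])
        elif mu.ndim == 0:
            mu = np.full(structure.n_species, float(mu))
        state["log_mu_s"] = np.log(mu)
    for b in structure.blocks:
        if b.name == "log_a":
            state["log_a"] = np.log(global_params.a)
        elif b.name == "log_b":
            state["log_b"] = np.log(global_params.b)
        elif b.name == "log_a_s":
            state["log_a_s"] = np.log(
                [species_params.a_s[s] for s in structure.spec_species]
            )
        elif b.name == "log_b_s":
            state["log_b_s"] = np.log(
                [species_params.b_s[s] for s in structure.spec_species]
            )
        elif b.name == "logit_eta_farm":
            state["logit_eta_farm"] = sp_logit(
                np.array([eta.eta_farm[f] for f in structure.farm_ids])
            )
        elif b.name == "logit_eta_field":
            composed = {fid: v_ for (_, fid), v_ in eta.eta_field_component.items()}
            state["logit_eta_field"] = sp_logit(
                np.array([composed[f] for f in structure.field_ids])
            )
        elif b.name == "logit_eta_fs":
            vals = np.array(
                [
                    [
                        eta.eta_field_species[
                            (structure.farm_ids[structure.field_farm[i]], fid, s)
                        ]
                        for s in structure.spec_species
                    ]
                    for i, fid in enumerate(structure.field_ids)
                ]
            )
            state["logit_eta_fs"] = sp_logit(vals)
    return state


def log_likelihood(
    dataset: WeedSurveyDataset,
    global_params: GlobalParams,
    eta: EffectivenessParams,
    variant: ModelVariant,
    design: Optional[SurveyDesign] = None,
    species_params: Optional[SpeciesParams] = None,
    min_fields_for_species_eta: int = 5,
) -> float:
    """Full-data log likelihood of natural-scale parameters.

    Richness variants sum Poisson log-pmfs of observed field richness;
    abundance variants sum Binomial(n_quadrats, presence probability)
    log-pmfs of quadrat-presence counts over every observed species and
    field.  An empty dataset contributes 0.
    """
    design = design or dataset.design
    structure = _ModelStructure(
        dataset, variant, design, min_fields_for_species_eta
    )
    if structure.n_fields == 0 or (
        variant.family == "abundance" and structure.n_species == 0
    ):
        return 0.0
    state = _state_from_params(structure, global_params, eta, species_params)
    return structure.loglik_full(state)


# ---------------------------------------------------------------------------
# chains and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ChainSet:
    """Stored post-burn-in draws for every chain.

    ``draws`` maps block name -> array of shape (n_chains, n_stored,
    *block shape) on the *sampling* scale; ``deviance`` holds
    -2 x log-likelihood per stored draw.
    """

    variant: ModelVariant
    draws: Dict[str, np.ndarray]
    deviance: np.ndarray
    blocks: List[_Block]
    field_ids: list
    farm_ids: list
    species_ids: list
    spec_species: list
    field_farm: np.ndarray
    settings: MCMCSettings
    acceptance: Dict[str, float]

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_stored(self) -> int:
        return self.deviance.shape[1]

    def natural_draws(self, name: str) -> np.ndarray:
        """Draws transformed back to the natural scale."""
        x = self.draws[name]
        return expit(x) if name.startswith("logit_") else np.exp(x)

    def flat_labelled(self) -> Dict[str, np.ndarray]:
        """Map scalar-parameter label -> (n_chains, n_stored) natural-scale
        draws, flattening every block."""
        out: Dict[str, np.ndarray] = {}
        for b in self.blocks:
            nat = self.natural_draws(b.name)
            flat = nat.reshape(self.n_chains, self.n_stored, -1)
            for j, label in enumerate(b.labels):
                out[label] = flat[:, :, j]
        return out

    def eta_field_draws(self) -> np.ndarray:
        """Composed field-level effectiveness eta_Ff = eta_F * eta_f per
        draw, shape (n_chains, n_stored, n_fields)."""
        if "logit_eta_farm" not in self.draws:
            raise ValueError(f"variant {self.variant} has no farm-level eta")
        eta_F = expit(self.draws["logit_eta_farm"])[:, :, self.field_farm]
        if "logit_eta_field" not in self.draws:
            return eta_F
        return eta_F * expit(self.draws["logit_eta_field"])

    def posterior_sample(self, name: str, size: int, seed: int = 0) -> np.ndarray:
        """Uniform subsample of the pooled post-burn-in draws."""
        nat = self.natural_draws(name)
        pooled = nat.reshape(-1, *nat.shape[2:])
        rng = np.random.default_rng(seed)
        idx = rng.choice(pooled.shape[0], size=size, replace=False)
        return pooled[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy chains: one row per chain x iteration x parameter."""
        rows = []
        for label, arr in self.flat_labelled().items():
            for c in range(self.n_chains):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(self.n_stored),
                            "parameter": label,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def gelman_rubin(chains: ChainSet | Dict[str, np.ndarray]) -> Dict[str, float]:
    """Potential scale reduction factor per parameter.

    R_hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n x variance of the chain means.  Constant chains
    (W = B = 0) return 1 by convention.
    """
    labelled = chains.flat_labelled() if isinstance(chains, ChainSet) else chains
    out: Dict[str, float] = {}
    for label, arr in labelled.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("need >= 2 chains to compute R-hat")
        m, n = arr.shape
        if n < 2:
            raise ValueError("need >= 2 draws per chain")
        W = arr.var(axis=1, ddof=1).mean()
        B = n * arr.mean(axis=1).var(ddof=1)
        if W == 0.0:
            out[label] = 1.0
        else:
            out[label] = float(np.sqrt(((n - 1) / n * W + B / n) / W))
    return out


@dataclass
class FitResult:
    """Posterior summaries, diagnostics and DIC for one fitted variant."""

    variant: ModelVariant
    summary: pd.DataFrame  # index: parameter; mean, sd, q2.5, median, q97.5
    rhat: Dict[str, float]
    dic: float
    p_d: float
    mean_deviance: float
    settings: MCMCSettings
    chains: ChainSet

    @property
    def n_free_parameters(self) -> int:
        return int(sum(np.prod(b.shape, dtype=int) for b in self.chains.blocks))

    def posterior_mean(self, label: str) -> float:
        return float(self.summary.loc[label, "mean"])


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _run_single_chain(
    structure: _ModelStructure,
    settings: MCMCSettings,
    sd: float,
    rng: np.random.Generator,
):
    state = structure.initial_state(rng)
    units = structure.unit_loglik(state)
    steps = {
        b.name: (
            np.full(b.shape, settings.initial_step)
            if b.shape
            else np.float64(settings.initial_step)
        )
        for b in structure.blocks
    }
    prior = {
        b.name: _block_log_prior(state[b.name], b.kind, sd) for b in structure.blocks
    }
    block_names = {b.name for b in structure.blocks}
    kinds = {b.name: b.kind for b in structure.blocks}
    # translation moves along the product degeneracies: a (and, through
    # the near-exponential regime, b) trade against the farm logits
    ridge_moves = []
    if "logit_eta_farm" in block_names:
        for scale_name in ("log_a", "log_b"):
            if scale_name in block_names:
                ridge_moves.append(
                    {scale_name: 1.0, "logit_eta_farm": -1.0}
                )
    ridge_steps = [settings.initial_step] * len(ridge_moves)
    # adaptive joint update of the global scalars (correlated ridges
    # among mu, a, b)
    global_names = [
        b.name for b in structure.blocks if b.scope == "all"
    ]
    n_g = len(global_names)
    am_mean = np.zeros(n_g)
    am_cov = np.eye(n_g)
    am_count = 0
    am_scale = 0.5
    n_stored = settings.n_stored
    stored = {
        b.name: np.empty((n_stored,) + b.shape) for b in structure.blocks
    }
    deviance = np.empty(n_stored)
    acc_count = {b.name: 0.0 for b in structure.blocks}
    acc_total = {b.name: 0 for b in structure.blocks}
    store_idx = 0

    for t in range(settings.n_iterations):
        adapt = t < settings.burn_in
        gamma = (t + 1) ** -0.6 if adapt else 0.0
        for b in structure.blocks:
            x = state[b.name]
            prop = x + steps[b.name] * rng.standard_normal(b.shape)
            new_state = dict(state)
            new_state[b.name] = prop
            new_units = structure.unit_loglik(new_state)
            delta_l = structure.group_delta(b.scope, new_units - units)
            new_prior = _block_log_prior(prop, b.kind, sd)
            delta_p = new_prior - prior[b.name]
            if b.scope == "all":
                delta_p = np.array([np.sum(delta_p)])
            log_u = np.log(rng.random(delta_l.shape))
            accept = log_u < delta_l + np.asarray(delta_p).reshape(delta_l.shape)
            if b.scope == "all":
                if accept[0]:
                    state[b.name] = prop
                    prior[b.name] = new_prior
                    units = new_units
            else:
                state[b.name] = np.where(accept, prop, x)
                prior[b.name] = np.where(accept, new_prior, prior[b.name])
                units = _merge_units(structure, b.scope, accept, units, new_units)
            if adapt:
                acc_f = (
                    float(accept[0]) if b.scope == "all" else accept.astype(float)
                )
                steps[b.name] = np.clip(
                    steps[b.name]
                    * np.exp(gamma * (acc_f - settings.target_acceptance)),
                    1e-4,
                    50.0,
                )
            else:
                acc_count[b.name] += float(np.mean(accept))
                acc_total[b.name] += 1
        # symmetric translation moves along the a-eta / b-eta product
        # degeneracies: the componentwise sweep alone crawls along these
        # ridges
        for mi, move in enumerate(ridge_moves):
            delta = ridge_steps[mi] * rng.standard_normal()
            new_state = dict(state)
            for name, coef in move.items():
                new_state[name] = state[name] + coef * delta
            new_units = structure.unit_loglik(new_state)
            dprior = sum(
                np.sum(_block_log_prior(new_state[name], kinds[name], sd))
                - np.sum(prior[name])
                for name in move
            )
            dll = float(np.sum(new_units) - np.sum(units))
            acc = math.log(rng.random()) < dll + dprior
            if acc:
                for name in move:
                    state[name] = new_state[name]
                    prior[name] = _block_log_prior(state[name], kinds[name], sd)
                units = new_units
            if adapt:
                ridge_steps[mi] = float(
                    np.clip(
                        ridge_steps[mi]
                        * math.exp(
                            gamma * (float(acc) - settings.target_acceptance)
                        ),
                        1e-4,
                        50.0,
                    )
                )
        # adaptive-covariance joint update of the global scalars
        if n_g >= 2:
            g = np.array([float(state[name]) for name in global_names])
            if adapt:
                am_count += 1
                w = 1.0 / am_count
                diff = g - am_mean
                am_mean = am_mean + w * diff
                am_cov = (1 - w) * am_cov + w * np.outer(diff, diff)
            try:
                L = np.linalg.cholesky(am_cov + 1e-6 * np.eye(n_g))
            except np.linalg.LinAlgError:
                L = np.eye(n_g)
            prop_g = g + am_scale * (L @ rng.standard_normal(n_g))
            new_state = dict(state)
            for name, v in zip(global_names, prop_g):
                new_state[name] = np.float64(v)
            new_units = structure.unit_loglik(new_state)
            dprior = sum(
                float(
                    _block_log_prior(new_state[name], "log", sd)
                    - _block_log_prior(state[name], "log", sd)
                )
                for name in global_names
            )
            dll = float(np.sum(new_units) - np.sum(units))
            acc = math.log(rng.random()) < dll + dprior
            if acc:
                for name in global_names:
                    state[name] = new_state[name]
                    prior[name] = _block_log_prior(state[name], "log", sd)
                units = new_units
            if adapt:
                am_scale = float(
                    np.clip(
                        am_scale
                        * math.exp(gamma * (float(acc) - 0.3)),
                        1e-4,
                        50.0,
                    )
                )
        if t >= settings.burn_in and (t - settings.burn_in) % settings.thin == 0:
            if store_idx < n_stored:
                for b in structure.blocks:
                    stored[b.name][store_idx] = state[b.name]
                deviance[store_idx] = -2.0 * float(units.sum())
                store_idx += 1
    acceptance = {
        name: acc_count[name] / max(acc_total[name], 1) for name in acc_count
    }
    return stored, deviance, acceptance


def _merge_units(structure, scope, accept, units, new_units):
    """Combine old and new unit log-likelihoods after componentwise
    acceptance: each unit takes the new value iff its component moved."""
    if structure.variant.family == "richness":
        if scope == "farm":
            take = accept[structure.field_farm]
        else:  # field
            take = accept
        return np.where(take, new_units, units)
    if scope == "farm":
        take = accept[structure.field_farm][:, None]
    elif scope == "field":
        take = accept[:, None]
    elif scope == "species":
        take = accept[None, :]
    elif scope == "spec_species":
        take = np.zeros(units.shape, dtype=bool)
        take[:, structure.spec_mask] = accept[None, :]
    elif scope == "cell":
        take = np.zeros(units.shape, dtype=bool)
        take[:, structure.spec_mask] = accept
    else:
        raise ValueError(scope)
    return np.where(take, new_units, units)


def run_mcmc(
    dataset: WeedSurveyDataset,
    variant: ModelVariant,
    priors: Optional[PriorSpec] = None,
    settings: Optional[MCMCSettings] = None,
    design: Optional[SurveyDesign] = None,
) -> ChainSet:
    """Sample the posterior of one model variant.

    Runs ``settings.n_chains`` independent adaptive
    Metropolis-within-Gibbs chains (proposal scales tuned during
    burn-in, frozen afterwards) and stores the post-burn-in draws.
    Fully reproducible: chain RNGs are spawned from ``settings.seed``.
    """
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    design = design or dataset.design
    variant = ModelVariant(variant)
    structure = _ModelStructure(
        dataset, variant, design, settings.min_fields_for_species_eta
    )
    init_state = structure.initial_state(np.random.default_rng(settings.seed))
    init_ll = structure.loglik_full(init_state)
    if not np.isfinite(init_ll):
        raise RuntimeError(
            f"non-finite initial log-likelihood ({init_ll}) for {variant}; "
            "check the dataset for impossible observations"
        )

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    all_stored: Dict[str, list] = {b.name: [] for b in structure.blocks}
    all_dev = []
    acc_accum: Dict[str, float] = {b.name: 0.0 for b in structure.blocks}
    for ss in seeds:
        stored, deviance, acceptance = _run_single_chain(
            structure, settings, priors.sd, np.random.default_rng(ss)
        )
        for name, arr in stored.items():
            all_stored[name].append(arr)
        all_dev.append(deviance)
        for name, rate in acceptance.items():
            acc_accum[name] += rate / settings.n_chains

    return ChainSet(
        variant=variant,
        draws={name: np.stack(arrs) for name, arrs in all_stored.items()},
        deviance=np.stack(all_dev),
        blocks=structure.blocks,
        field_ids=structure.field_ids,
        farm_ids=structure.farm_ids,
        species_ids=structure.species_ids,
        spec_species=getattr(structure, "spec_species", []),
        field_farm=structure.field_farm,
        settings=settings,
        acceptance=acc_accum,
    )


# ---------------------------------------------------------------------------
# DIC and fitting front-end
# ---------------------------------------------------------------------------

def compute_dic(
    chains: ChainSet,
    dataset: WeedSurveyDataset,
    variant: Optional[ModelVariant] = None,
    design: Optional[SurveyDesign] = None,
) -> Tuple[float, float]:
    """Deviance information criterion from stored chains.

    DIC = mean posterior deviance + p_D, with p_D = mean deviance minus
    the deviance at the posterior mean taken on the sampling scale.
    When that plug-in produces a negative p_D — impossible for a valid
    effective-parameter count, and symptomatic of the posterior mean
    falling off the curved (a, b) ridge this model family carries — the
    coordinatewise posterior median is used as the plug-in instead.
    """
    variant = ModelVariant(variant or chains.variant)
    design = design or dataset.design
    if not np.all(np.isfinite(chains.deviance)):
        idx = np.argwhere(~np.isfinite(chains.deviance))[0]
        raise FloatingPointError(
            f"non-finite deviance at chain {idx[0]}, stored draw {idx[1]}"
        )
    structure = _ModelStructure(
        dataset, variant, design, chains.settings.min_fields_for_species_eta
    )
    mean_dev = float(chains.deviance.mean())
    state_mean = {
        name: arr.reshape(-1, *arr.shape[2:]).mean(axis=0)
        for name, arr in chains.draws.items()
    }
    dev_at_mean = -2.0 * structure.loglik_full(state_mean)
    p_d = mean_dev - dev_at_mean
    if p_d < 0.0:
        state_med = {
            name: np.median(arr.reshape(-1, *arr.shape[2:]), axis=0)
            for name, arr in chains.draws.items()
        }
        p_d = mean_dev + 2.0 * structure.loglik_full(state_med)
    return mean_dev + p_d, p_d


def summarize_chains(chains: ChainSet) -> pd.DataFrame:
    """Posterior mean/sd/quantiles per labelled parameter (natural scale)."""
    rows = {}
    for label, arr in chains.flat_labelled().items():
        pooled = arr.reshape(-1)
        rows[label] = {
            "mean": pooled.mean(),
            "sd": pooled.std(ddof=1),
            "q2.5": np.quantile(pooled, 0.025),
            "median": np.quantile(pooled, 0.5),
            "q97.5": np.quantile(pooled, 0.975),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "parameter"
    return out


def fit_variant(
    dataset: WeedSurveyDataset,
    variant: ModelVariant,
    priors: Optional[PriorSpec] = None,
    settings: Optional[MCMCSettings] = None,
    design: Optional[SurveyDesign] = None,
) -> FitResult:
    """Sample one variant and assemble summaries, R-hat and DIC."""
    chains = run_mcmc(dataset, variant, priors, settings, design)
    dic, p_d = compute_dic(chains, dataset)
    return FitResult(
        variant=ModelVariant(variant),
        summary=summarize_chains(chains),
        rhat=gelman_rubin(chains),
        dic=dic,
        p_d=p_d,
        mean_deviance=float(chains.deviance.mean()),
        settings=chains.settings,
        chains=chains,
    )
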