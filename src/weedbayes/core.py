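"""Domain types and the deterministic model mathematics.

The herbicide dose--response at the heart of the package: an untreated
field carries weed richness (or per-species abundance) with Poisson mean
``mu``; a herbicide application of total active-ingredient rate ``D``
(kg/ha), modulated by a latent effectiveness ``eta`` in [0, 1], reduces
that mean to ``mu / (1 + a * eta * D) ** b``.  Presence/absence in a
quadrat of area ``w`` and persistence in a reference area ``W`` follow
from the complete-spatial-randomness (Poisson) assumption.

All functions here are pure and accept scalars or numpy arrays
(broadcasting applies); domain violations raise ``ValueError``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "SurveyDesign",
    "FieldRecord",
    "QuadratObservation",
    "SpeciesPresenceSummary",
    "GlobalParams",
    "SpeciesParams",
    "EffectivenessParams",
    "ModelVariant",
    "DerivedIntensities",
    "reduction_factor",
    "treated_intensity",
    "presence_probability",
    "survival_probability",
    "intensity_from_presence",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyDesign:
    """Geometry of the quadrat sampling scheme.

    Defaults mirror the study design the package emulates: 30 farms,
    5 winter-wheat fields per farm, 10 quadrats of 4 m^2 per field,
    and a 4000 m^2 reference area for survival profiling.
    """

    n_farms: int = 30
    fields_per_farm: int = 5
    quadrats_per_field: int = 10
    quadrat_area_w: float = 4.0
    reference_area_W: float = 4000.0

    def __post_init__(self) -> None:
        if min(self.n_farms, self.fields_per_farm, self.quadrats_per_field) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.quadrat_area_w <= 0 or self.reference_area_W <= 0:
            raise ValueError("quadrat and reference areas must be > 0")

    @property
    def n_fields(self) -> int:
        return self.n_farms * self.fields_per_farm

    @property
    def surveyed_area(self) -> float:
        """Total area surveyed per field (quadrats x quadrat area)."""
        return self.quadrats_per_field * self.quadrat_area_w


@dataclass(frozen=True)
class FieldRecord:
    """Per-field treatment and yield covariates.

    ``dose_D`` is the summed active-ingredient application rate over the
    cultivation period (kg/ha).  Yield and nitrogen may be missing (the
    emulated survey lacked yields for 3 of 30 farms).
    """

    farm_id: str
    field_id: str
    dose_D: float
    tfi: Optional[float] = None
    yield_q_ha: Optional[float] = None
    nitrogen: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dose_D < 0:
            raise ValueError(f"dose_D must be >= 0, got {self.dose_D}")
        if self.tfi is not None and self.tfi < 0:
            raise ValueError(f"tfi must be >= 0, got {self.tfi}")


@dataclass(frozen=True)
class QuadratObservation:
    """A single presence/absence record: species x quadrat x field."""

    field_id: str
    quadrat_index: int
    species_id: str
    present: bool


@dataclass(frozen=True)
class SpeciesPresenceSummary:
    """Quadrat-presence count for one species in one field."""

    field_id: str
    species_id: str
    k_present: int
    n_quadrats: int

    def __post_init__(self) -> None:
        if not 0 <= self.k_present <= self.n_quadrats:
            raise ValueError(
                f"k_present={self.k_present} outside [0, {self.n_quadrats}]"
            )


@dataclass(frozen=True)
class GlobalParams:
    """Shared model parameters: no-treatment mean and dose-response shape.

    ``mu`` is the mean richness (richness models) or a vector of
    per-species mean intensities (abundance models) in the absence of
    treatment; ``a`` (scale) and ``b`` (shape) control the reduction curve.
    """

    mu: np.ndarray | float
    a: float
    b: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.mu) <= 0):
            raise ValueError("mu must be > 0 componentwise")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be > 0")


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species dose-response parameters (species-specific variant)."""

    mu_s: Mapping[str, float]
    a_s: Mapping[str, float]
    b_s: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, m in (("mu_s", self.mu_s), ("a_s", self.a_s), ("b_s", self.b_s)):
            if any(v <= 0 for v in m.values()):
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class EffectivenessParams:
    """The latent effectiveness hierarchy.

    ``eta_farm`` maps farm -> eta_F; ``eta_field_component`` maps
    (farm, field) -> eta_f; the composed field-level effectiveness is
    eta_Ff = eta_F * eta_f.  ``eta_field_species`` maps
    (farm, field, species) -> eta_Ffs.  Exactly one level is populated
    per model variant (the species level may coexist with the field
    level for species falling back to the shared structure).
    """

    eta_farm: dict = field(default_factory=dict)
    eta_field_component: dict = field(default_factory=dict)
    eta_field_species: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.eta_farm, self.eta_field_component, self.eta_field_species):
            for v in m.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"effectiveness value {v} outside [0, 1]")

    @property
    def eta_field(self) -> dict:
        """Composed field-level effectiveness eta_Ff = eta_F * eta_f."""
        return {
            (farm, fld): self.eta_farm.get(farm, 1.0) * v
            for (farm, fld), v in self.eta_field_component.items()
        }


class ModelVariant(str, enum.Enum):
    """The seven hierarchical model variants (two families)."""

    RICH_BASE = "rich_base"
    RICH_FARM = "rich_farm"
    RICH_FIELD = "rich_field"
    AB_BASE = "ab_base"
    AB_FARM = "ab_farm"
    AB_FIELD = "ab_field"
    AB_SPEC = "ab_spec"

    @property
    def family(self) -> str:
        return "richness" if self.value.startswith("rich") else "abundance"

    @property
    def eta_level(self) -> str:
        return {
            "base": "none",
            "farm": "farm",
            "field": "field",
            "spec": "species",
        }[self.value.split("_")[1]]


@dataclass(frozen=True)
class DerivedIntensities:
    """Treated intensities and the probabilities derived from them."""

    lambda_rich: float | np.ndarray
    lambda_s: float | np.ndarray
    p_presence: float | np.ndarray
    survival: float | np.ndarray


# ---------------------------------------------------------------------------
# closed-form model mathematics
# ---------------------------------------------------------------------------

def _validate_dose_response(dose_D, a, b, eta) -> None:
    if np.any(np.asarray(dose_D) < 0):
        raise ValueError("dose_D must be >= 0")
    if np.any(np.asarray(a) <= 0) or np.any(np.asarray(b) <= 0):
        raise ValueError("a and b must be > 0")
    eta = np.asarray(eta)
    if np.any(eta < 0) or np.any(eta > 1):
        raise ValueError("eta must lie in [0, 1]")


def reduction_factor(dose_D, a, b, eta):
    """Fraction of the untreated mean surviving treatment.

    ``1 / (1 + a * eta * dose_D) ** b``: equals 1 iff the effective dose
    ``eta * dose_D`` is zero, and decreases towards 0 with dose, scale
    and effectiveness.  The effectiveness multiplies the dose inside the
    parenthesis (an effective dose), not the factor as a whole.
    """
    _validate_dose_response(dose_D, a, b, eta)
    return (1.0 + np.asarray(a) * np.asarray(eta) * np.asarray(dose_D)) ** (
        -np.asarray(b)
    )


def treated_intensity(mu, dose_D, a, b, eta):
    """Poisson mean after treatment: ``mu / (1 + a*eta*D)**b``."""
    if np.any(np.asarray(mu) <= 0):
        raise ValueError("mu must be > 0")
    return np.asarray(mu) * reduction_factor(dose_D, a, b, eta)


def presence_probability(lambda_s, area):
    """Probability of finding at least one plant in ``area`` m^2.

    Under complete spatial randomness the count in the area is
    Poisson(lambda_s * area), so presence has probability
    ``1 - exp(-lambda_s * area)``.
    """
    lambda_s = np.asarray(lambda_s, dtype=float)
    if np.any(lambda_s < 0):
        raise ValueError("intensity must be >= 0")
    if np.any(np.asarray(area) <= 0):
        raise ValueError("area must be > 0")
    return -np.expm1(-lambda_s * np.asarray(area))


def survival_probability(lambda_s, reference_area_W, complement: bool = True):
    """Probability that a species persists in the reference area.

    With post-treatment intensity ``lambda_s`` the number of surviving
    individuals in ``W`` m^2 is Poisson(W * lambda_s); the species
    persists iff at least one individual remains, probability
    ``1 - exp(-W * lambda_s)`` (the default).  ``complement=False``
    returns the extinction probability ``exp(-W * lambda_s)`` instead
    (the probability of observing zero individuals).
    """
    p = presence_probability(lambda_s, reference_area_W)
    return p if complement else 1.0 - p


def intensity_from_presence(k_present, n_quadrats, quadrat_area_w):
    """ML Poisson intensity from a quadrat presence count.

    With ``k`` of ``n`` independent quadrats of area ``w`` occupied, the
    ML intensity is ``-log(1 - k/n) / w`` plants per m^2.  At the
    saturated boundary ``k == n`` the MLE diverges; a continuity-corrected
    finite value ``-log(1/(2n)) / w`` is returned together with a
    saturation flag.

    Returns
    -------
    (intensity, saturated) : tuple of float/array and bool/array
    """
    k = np.asarray(k_present, dtype=float)
    n = np.asarray(n_quadrats, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_quadrats must be >= 1")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k_present must lie in [0, n_quadrats]")
    if np.any(np.asarray(quadrat_area_w) <= 0):
        raise ValueError("quadrat_area_w must be > 0")
    saturated = k == n
    frac = np.where(saturated, 1.0 - 1.0 / (2.0 * n), k / n)
    intensity = -np.log1p(-frac) / quadrat_area_w
    if np.ndim(k_present) == 0 and np.ndim(n_quadrats) == 0:
        return float(intensity), bool(saturated)
    return intensity, saturated
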