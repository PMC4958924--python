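"""In-memory survey dataset container and aggregation helpers.

A :class:`WeedSurveyDataset` bundles the three tidy tables the analysis
consumes — per-field treatment/yield covariates, per-quadrat species
presence records and (optionally) per-application herbicide records —
together with the sampling design, and exposes the aggregations the
models need: per-field richness and per-(field, species) quadrat
presence counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import SurveyDesign

FIELDS_COLUMNS = ["farm_id", "field_id", "dose_D", "tfi", "yield_q_ha", "nitrogen"]
OBS_COLUMNS = ["field_id", "quadrat_index", "species_id", "present"]
APPLICATIONS_COLUMNS = [
    "field_id",
    "product",
    "ai_dose_kg_ha",
    "recommended_dose_kg_ha",
    "week",
    "spectrum",
]


class DatasetValidationError(ValueError):
    """A table violates the dataset schema or an invariant."""


@dataclass
class WeedSurveyDataset:
    """The three survey tables plus the sampling design.

    ``fields`` has one row per field (farm_id, field_id, dose_D, tfi,
    yield_q_ha, nitrogen; the last three may be NaN).  ``observations``
    is tidy presence/absence: one row per recorded (field, quadrat,
    species) with ``present`` in {0, 1}; absent combinations may simply
    be omitted.  ``applications`` is optional and only needed for the
    treatment-frequency indicator.
    """

    fields: pd.DataFrame
    observations: pd.DataFrame
    design: SurveyDesign = field(default_factory=SurveyDesign)
    applications: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.fields = self.fields.reset_index(drop=True)
        self.observations = self.observations.reset_index(drop=True)
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        for col in ("farm_id", "field_id", "dose_D"):
            if col not in self.fields.columns:
                raise DatasetValidationError(f"fields table lacks column {col!r}")
        for col in OBS_COLUMNS:
            if col not in self.observations.columns:
                raise DatasetValidationError(
                    f"observations table lacks column {col!r}"
                )
        if (self.fields["dose_D"] < 0).any():
            bad = self.fields.index[self.fields["dose_D"] < 0][0]
            raise DatasetValidationError(f"fields row {bad}: dose_D < 0")
        if self.fields.duplicated(["farm_id", "field_id"]).any():
            raise DatasetValidationError("duplicate (farm_id, field_id) rows")
        dup = self.observations.duplicated(["field_id", "quadrat_index", "species_id"])
        if dup.any():
            row = self.observations.index[dup][0]
            raise DatasetValidationError(
                f"observations row {row}: duplicate (field_id, quadrat_index, "
                f"species_id) record"
            )
        unknown = ~self.observations["field_id"].isin(self.fields["field_id"])
        if unknown.any():
            row = self.observations.index[unknown][0]
            raise DatasetValidationError(
                f"observations row {row}: field_id not in fields table"
            )
        q = self.observations["quadrat_index"]
        if ((q < 1) | (q > self.design.quadrats_per_field)).any():
            raise DatasetValidationError(
                f"quadrat_index outside 1..{self.design.quadrats_per_field}"
            )

    # -- aggregation --------------------------------------------------

    @property
    def field_ids(self) -> list:
        return list(self.fields["field_id"])

    @property
    def species_ids(self) -> list:
        """Species ever recorded present, in sorted order."""
        present = self.observations[self.observations["present"].astype(bool)]
        return sorted(present["species_id"].unique())

    def presence_summary(self) -> pd.DataFrame:
        """Per (field, species) quadrat-presence counts.

        One row per field x (species observed anywhere), with
        ``k_present`` in 0..n_quadrats — absences are filled in so the
        binomial likelihood sees every cell.
        """
        present = self.observations[self.observations["present"].astype(bool)]
        counts = (
            present.groupby(["field_id", "species_id"], sort=False)
            .size()
            .rename("k_present")
        )
        idx = pd.MultiIndex.from_product(
            [self.field_ids, self.species_ids], names=["field_id", "species_id"]
        )
        out = counts.reindex(idx, fill_value=0).reset_index()
        out["n_quadrats"] = self.design.quadrats_per_field
        if (out["k_present"] > out["n_quadrats"]).any():
            raise DatasetValidationError("k_present exceeds n_quadrats")
        return out

    def richness(self) -> pd.Series:
        """Observed per-field species richness (distinct species present
        in at least one of the field's quadrats), indexed by field_id."""
        present = self.observations[self.observations["present"].astype(bool)]
        r = present.groupby("field_id")["species_id"].nunique()
        return r.reindex(self.field_ids, fill_value=0).rename("richness")

    def weed_frequency(self) -> pd.Series:
        """Per-field count of (species x quadrat) presence records."""
        present = self.observations[self.observations["present"].astype(bool)]
        f = present.groupby("field_id").size()
        return f.reindex(self.field_ids, fill_value=0).rename("weed_frequency")

    def farm_of_field(self) -> pd.Series:
        return self.fields.set_index("field_id")["farm_id"]

    def species_field_occurrence(self) -> pd.Series:
        """Number of fields in which each species was recorded present."""
        present = self.observations[self.observations["present"].astype(bool)]
        occ = present.groupby("species_id")["field_id"].nunique()
        return occ.reindex(self.species_ids, fill_value=0)


def make_field_table(records) -> pd.DataFrame:
    """Build the fields table from an iterable of FieldRecord."""
    rows = [
        {
            "farm_id": r.farm_id,
            "field_id": r.field_id,
            "dose_D": r.dose_D,
            "tfi": np.nan if r.tfi is None else r.tfi,
            "yield_q_ha": np.nan if r.yield_q_ha is None else r.yield_q_ha,
            "nitrogen": np.nan if r.nitrogen is None else r.nitrogen,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=FIELDS_COLUMNS)
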