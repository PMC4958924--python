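"""CSV dialects, fit persistence and run manifests.

Three tidy UTF-8 comma-separated tables move data in and out of the
package:

* ``survey.csv`` — field_id, quadrat_index, species_id, present (0/1)
* ``applications.csv`` — field_id, product, ai_dose_kg_ha,
  recommended_dose_kg_ha, week, spectrum
* ``yields.csv`` — farm_id, field_id, yield_q_ha, nitrogen

The yields table doubles as the farm-field register; per-field total
dose is the sum of the field's application doses.  Ground truth from
the simulator is written to a separate ``truth.csv`` so that fitting
code cannot accidentally read it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import ModelVariant, SurveyDesign
from .datasets import (
    APPLICATIONS_COLUMNS,
    DatasetValidationError,
    FIELDS_COLUMNS,
    OBS_COLUMNS,
    WeedSurveyDataset,
)
from .inference import ChainSet, FitResult, MCMCSettings, _Block

__all__ = [
    "load_dataset",
    "write_dataset",
    "save_fit",
    "load_chainset",
    "file_checksum",
    "write_manifest",
]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise DatasetValidationError(f"{path}: missing column {c!r}")


def load_dataset(
    survey_path,
    applications_path=None,
    yields_path=None,
    design: Optional[SurveyDesign] = None,
) -> WeedSurveyDataset:
    """Read the CSV tables into a validated dataset.

    The yields table supplies the farm-field register; when absent,
    fields are taken from the survey/applications tables, farm ids are
    inferred from the field-id prefix before the last underscore, and
    yields are marked missing.  Per-field total dose is the sum of the
    field's application doses (0 for untreated fields); TFI is filled
    in where every application carries a recommended dose.
    """
    design = design or SurveyDesign()
    survey_path = Path(survey_path)
    survey = pd.read_csv(survey_path)
    _require_columns(survey, OBS_COLUMNS, survey_path)
    bad = ~survey["present"].isin([0, 1])
    if bad.any():
        row = int(survey.index[bad][0])
        raise DatasetValidationError(
            f"{survey_path}: row {row}, column 'present' must be 0 or 1"
        )

    applications = None
    if applications_path is not None and Path(applications_path).exists():
        applications = pd.read_csv(applications_path)
        _require_columns(
            applications,
            ["field_id", "product", "ai_dose_kg_ha"],
            applications_path,
        )
        if (applications["ai_dose_kg_ha"] < 0).any():
            row = int(
                applications.index[applications["ai_dose_kg_ha"] < 0][0]
            )
            raise DatasetValidationError(
                f"{applications_path}: row {row}, column 'ai_dose_kg_ha' < 0"
            )

    if yields_path is not None and Path(yields_path).exists():
        yields = pd.read_csv(yields_path)
        _require_columns(yields, ["farm_id", "field_id"], yields_path)
        fields = yields.copy()
        if "yield_q_ha" not in fields.columns:
            fields["yield_q_ha"] = np.nan
        if "nitrogen" not in fields.columns:
            fields["nitrogen"] = np.nan
    else:
        ids = set(survey["field_id"])
        if applications is not None:
            ids |= set(applications["field_id"])
        fields = pd.DataFrame({"field_id": sorted(ids)})
        fields["farm_id"] = [
            f.rsplit("_", 1)[0] if "_" in f else f for f in fields["field_id"]
        ]
        fields["yield_q_ha"] = np.nan
        fields["nitrogen"] = np.nan

    if applications is not None:
        dose = applications.groupby("field_id")["ai_dose_kg_ha"].sum()
        fields["dose_D"] = (
            fields["field_id"].map(dose).fillna(0.0).astype(float)
        )
        if "recommended_dose_kg_ha" in applications.columns:
            app = applications.copy()
            app["ratio"] = app["ai_dose_kg_ha"] / app["recommended_dose_kg_ha"]
            ok = app.groupby("field_id")["recommended_dose_kg_ha"].apply(
                lambda s: s.notna().all() and (s > 0).all()
            )
            tfi = app.groupby("field_id")["ratio"].sum()[ok[ok].index]
            fields["tfi"] = fields["field_id"].map(tfi)
        else:
            fields["tfi"] = np.nan
    else:
        fields["dose_D"] = 0.0
        fields["tfi"] = np.nan

    return WeedSurveyDataset(
        fields=fields[FIELDS_COLUMNS],
        observations=survey[OBS_COLUMNS],
        design=design,
        applications=applications,
    )


def write_dataset(dataset: WeedSurveyDataset, outdir) -> dict:
    """Write the dataset tables; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    survey = outdir / "survey.csv"
    dataset.observations[OBS_COLUMNS].to_csv(survey, index=False)
    paths["survey"] = survey
    yields = outdir / "yields.csv"
    dataset.fields[["farm_id", "field_id", "yield_q_ha", "nitrogen"]].to_csv(
        yields, index=False
    )
    paths["yields"] = yields
    if dataset.applications is not None:
        apps = outdir / "applications.csv"
        dataset.applications[APPLICATIONS_COLUMNS].to_csv(apps, index=False)
        paths["applications"] = apps
    return paths


# ---------------------------------------------------------------------------
# fit persistence (chains npz + JSON manifest)
# ---------------------------------------------------------------------------

def save_fit(fit: FitResult, outdir, name: Optional[str] = None) -> dict:
    """Persist a fit: tidy chain CSV, a draws archive and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = name or fit.variant.value
    chains = fit.chains
    paths = {}

    npz_path = outdir / f"{name}_draws.npz"
    np.savez_compressed(
        npz_path,
        deviance=chains.deviance,
        field_farm=chains.field_farm,
        **{f"draw_{k}": v for k, v in chains.draws.items()},
    )
    paths["draws"] = npz_path

    csv_path = outdir / f"{name}_chains.csv"
    chains.to_frame().to_csv(csv_path, index=False)
    paths["chains_csv"] = csv_path

    summary_path = outdir / f"{name}_summary.csv"
    fit.summary.to_csv(summary_path)
    paths["summary"] = summary_path

    manifest = {
        "variant": fit.variant.value,
        "dic": fit.dic,
        "p_d": fit.p_d,
        "mean_deviance": fit.mean_deviance,
        "max_rhat": max(fit.rhat.values()) if fit.rhat else None,
        "n_parameters": fit.n_free_parameters,
        "settings": asdict(fit.settings),
        "blocks": [
            {
                "name": b.name,
                "shape": list(b.shape),
                "kind": b.kind,
                "scope": b.scope,
                "labels": b.labels,
            }
            for b in chains.blocks
        ],
        "field_ids": chains.field_ids,
        "farm_ids": chains.farm_ids,
        "species_ids": chains.species_ids,
        "spec_species": chains.spec_species,
        "acceptance": chains.acceptance,
    }
    manifest_path = outdir / f"{name}_fit.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


def load_chainset(manifest_path) -> ChainSet:
    """Rebuild a ChainSet from a saved fit manifest + draws archive."""
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    name = meta["variant"]
    stem = manifest_path.name.replace("_fit.json", "")
    npz = np.load(manifest_path.parent / f"{stem}_draws.npz")
    draws = {
        k[len("draw_"):]: npz[k] for k in npz.files if k.startswith("draw_")
    }
    blocks = [
        _Block(
            name=b["name"],
            shape=tuple(b["shape"]),
            kind=b["kind"],
            scope=b["scope"],
            labels=b["labels"],
        )
        for b in meta["blocks"]
    ]
    return ChainSet(
        variant=ModelVariant(name),
        draws=draws,
        deviance=npz["deviance"],
        blocks=blocks,
        field_ids=meta["field_ids"],
        farm_ids=meta["farm_ids"],
        species_ids=meta["species_ids"],
        spec_species=meta["spec_species"],
        field_farm=npz["field_farm"],
        settings=MCMCSettings(**meta["settings"]),
        acceptance=meta["acceptance"],
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, seed: int, config: dict, outputs: dict) -> Path:
    """Record seed, resolved configuration and output checksums."""
    outdir = Path(outdir)
    manifest = {
        "master_seed": seed,
        "config": config,
        "outputs": {
            str(k): {"path": str(p), "sha256": file_checksum(p)}
            for k, p in outputs.items()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
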