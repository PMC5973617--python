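"""Readers and writers for the flat experiment CSV schema and configuration.

The canonical interchange format is one CSV row per microcosm with
per-species values pivoted into ``<field>__<speciescode>`` columns::

    microcosm_id, species, detritivores, n_discs_per_species,
    fpom_event_1..k, case_length_1..L, detritivore_final_dm,
    initial_airdry_dm__A, final_dm__A, final_afdm__A, ...

``species`` holds the composition as ``"+"``-joined codes (``A+C+Q``).
A read-only import adapter for the deposited supplementary spreadsheet is
provided (:func:`import_s1_workbook`); it expects the same flat schema on
the first worksheet and fails loudly when per-species mass columns are
absent.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .records import (
    AllometryParams,
    Composition,
    LeachingFactors,
    MicrocosmRecord,
    SchemaError,
    TraitTable,
    ValidationError,
)

__all__ = [
    "read_experiment",
    "write_experiment",
    "records_to_frame",
    "frame_to_records",
    "write_results",
    "read_results",
    "read_traits",
    "write_traits",
    "load_config",
    "save_config",
    "import_s1_workbook",
]

_BASE_COLUMNS = ("microcosm_id", "species", "detritivores", "n_discs_per_species")
_SPECIES_FIELDS = ("initial_airdry_dm", "final_dm", "final_afdm")


def records_to_frame(records: Sequence[MicrocosmRecord]) -> pd.DataFrame:
    """Flatten records into the canonical one-row-per-microcosm table."""
    if not records:
        raise ValidationError("no records to write")
    all_species: list[str] = []
    for r in records:
        for sp in r.composition.species:
            if sp not in all_species:
                all_species.append(sp)
    n_events = max(len(r.fpom_filter_mass) for r in records)
    n_larvae = max(
        (len(r.detritivore_case_lengths) for r in records if r.detritivore_case_lengths),
        default=0,
    )
    rows = []
    for r in records:
        row: dict[str, object] = {
            "microcosm_id": r.microcosm_id,
            "species": "+".join(r.composition.species),
            "detritivores": int(r.detritivores_present),
            "n_discs_per_species": r.n_discs_per_species,
        }
        for i in range(n_events):
            row[f"fpom_event_{i + 1}"] = (
                r.fpom_filter_mass[i] if i < len(r.fpom_filter_mass) else math.nan
            )
        for j in range(n_larvae):
            cls = r.detritivore_case_lengths or ()
            row[f"case_length_{j + 1}"] = cls[j] if j < len(cls) else math.nan
        row["detritivore_final_dm"] = (
            r.detritivore_final_dm if r.detritivore_final_dm is not None else math.nan
        )
        for sp in all_species:
            for fld in _SPECIES_FIELDS:
                row[f"{fld}__{sp}"] = getattr(r, fld).get(sp, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame, validate: bool = True) -> list[MicrocosmRecord]:
    """Inverse of :func:`records_to_frame`; validates every record."""
    missing = [c for c in _BASE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"experiment table missing required columns: {missing}")
    if frame.empty:
        return []
    if frame["microcosm_id"].duplicated().any():
        dupes = frame.loc[frame["microcosm_id"].duplicated(), "microcosm_id"].tolist()
        raise ValidationError(f"duplicate microcosm_id values: {dupes}")
    fpom_cols = sorted(
        (c for c in frame.columns if c.startswith("fpom_event_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    cl_cols = sorted(
        (c for c in frame.columns if c.startswith("case_length_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    records = []
    for _, row in frame.iterrows():
        comp = Composition.parse(str(row["species"]))
        masses: dict[str, dict[str, float]] = {f: {} for f in _SPECIES_FIELDS}
        for sp in comp.species:
            for fld in _SPECIES_FIELDS:
                col = f"{fld}__{sp}"
                if col not in frame.columns:
                    raise SchemaError(
                        f"missing per-species column {col!r} required by "
                        f"composition {comp.label}"
                    )
                val = row[col]
                if pd.isna(val):
                    raise ValidationError(
                        f"{row['microcosm_id']}: missing value in column {col!r}"
                    )
                masses[fld][sp] = float(val)
        fpom = tuple(float(row[c]) for c in fpom_cols if not pd.isna(row[c]))
        det = bool(int(row["detritivores"]))
        case_lengths = None
        final_det_dm = None
        if det:
            case_lengths = tuple(float(row[c]) for c in cl_cols if not pd.isna(row[c]))
            if "detritivore_final_dm" in frame.columns and not pd.isna(
                row["detritivore_final_dm"]
            ):
                final_det_dm = float(row["detritivore_final_dm"])
        rec = MicrocosmRecord(
            microcosm_id=str(row["microcosm_id"]),
            composition=comp,
            detritivores_present=det,
            n_discs_per_species=int(row["n_discs_per_species"]),
            initial_airdry_dm=masses["initial_airdry_dm"],
            final_dm=masses["final_dm"],
            final_afdm=masses["final_afdm"],
            fpom_filter_mass=fpom,
            detritivore_case_lengths=case_lengths,
            detritivore_final_dm=final_det_dm,
            expected_larvae=len(case_lengths) if case_lengths else 3,
        )
        if validate:
            rec.validate()
        records.append(rec)
    return records


def read_experiment(path: str | Path, schema_version: str = "1") -> list[MicrocosmRecord]:
    """Read and validate an experiment CSV (see module docstring for schema)."""
    if schema_version != "1":
        raise SchemaError(f"unknown schema version {schema_version!r}")
    frame = pd.read_csv(path)
    return frame_to_records(frame)


def write_experiment(records: Sequence[MicrocosmRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.12g")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write any result table to CSV; round-trip stable to 1e-9."""
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty result table")
    results.to_csv(path, index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_traits(path: str | Path) -> TraitTable:
    """Read a ``traits.csv`` with columns species, N_pct, P_pct, SLA,
    toughness_kPa, ash_pct."""
    frame = pd.read_csv(path)
    if "species" not in frame.columns:
        raise SchemaError("traits.csv must have a 'species' column")
    return TraitTable(frame.set_index("species"))


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.frame.rename_axis("species").reset_index().to_csv(
        path, index=False, float_format="%.12g"
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML analysis config (leaching factors, allometry, design)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def parse_leaching(cfg: dict) -> LeachingFactors:
    try:
        return LeachingFactors({str(k): float(v) for k, v in cfg["leaching_factors"].items()})
    except KeyError:
        raise SchemaError("config missing 'leaching_factors'") from None


def parse_allometry(cfg: dict) -> AllometryParams:
    allo = cfg.get("allometry", {})
    return AllometryParams(a=float(allo.get("a", 0.0043)), b=float(allo.get("b", 2.8041)))


def import_s1_workbook(path: str | Path, sheet: str | int = 0) -> list[MicrocosmRecord]:
    """Import an Excel workbook holding the experiment in the flat schema.

    The deposited supplementary spreadsheet is mapped onto the canonical
    CSV schema: the worksheet must carry the same columns, including the
    per-species ``<field>__<code>`` mass columns.  If per-species final
    masses are absent (e.g. only mixture totals were stored) the import
    fails loudly rather than guessing.
    """
    frame = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    if isinstance(frame, dict):  # pragma: no cover - sheet_name=None
        frame = next(iter(frame.values()))
    per_species = [c for c in frame.columns if "__" in str(c)]
    if not per_species:
        raise SchemaError(
            "workbook has no per-species '<field>__<code>' columns; cannot "
            "reconstruct per-species masses from totals"
        )
    return frame_to_records(frame)
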