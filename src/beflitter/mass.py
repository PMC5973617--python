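"""Derived per-microcosm quantities.

Litter decomposition is quantified as mass loss: leaching-corrected initial
AFDM minus final AFDM, per species and summed.  In microcosms with
detritivores the loss is additionally normalised by the summed initial
detritivore dry mass (estimated from case lengths via the power-law
allometry), removing variation due to detritivore size.  FPOM production is
the accumulated filter mass over water changes (normalised the same way),
and detritivore growth is the percent change in dry mass over the
incubation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import (
    AllometryParams,
    ConfigurationError,
    DataError,
    LeachingFactors,
    MicrocosmRecord,
    ValidationError,
)

__all__ = [
    "MassLossResult",
    "FpomResult",
    "GrowthResult",
    "allometric_dm",
    "corrected_initial_afdm",
    "mass_loss",
    "fpom_production",
    "detritivore_growth",
    "detritivore_initial_dm",
    "compute_metrics",
    "MassMetrics",
]


@dataclass(frozen=True)
class MassLossResult:
    """Per-species and total litter mass loss (mg AFDM) for one microcosm."""

    corrected_initial_afdm: dict[str, float]
    per_species_loss: dict[str, float]
    total_loss: float
    normalized_loss: float | None
    mass_gain_flag: bool


@dataclass(frozen=True)
class FpomResult:
    total_fpom: float
    normalized_fpom: float | None


@dataclass(frozen=True)
class GrowthResult:
    initial_dm: float
    final_dm: float
    growth_pct: float


def allometric_dm(case_length: float, params: AllometryParams) -> float:
    """Larval dry mass (mg) from case length (mm): a * CL**b."""
    return params.dm(case_length)


def detritivore_initial_dm(record: MicrocosmRecord, params: AllometryParams) -> float:
    """Summed allometric initial dry mass (mg) of all larvae in a microcosm."""
    if not record.detritivores_present:
        raise DataError(f"{record.microcosm_id}: no detritivores in this microcosm")
    assert record.detritivore_case_lengths is not None
    return sum(params.dm(cl) for cl in record.detritivore_case_lengths)


def corrected_initial_afdm(
    record: MicrocosmRecord, factors: LeachingFactors
) -> dict[str, float]:
    """Initial post-leach AFDM per species: air-dry DM x leaching factor."""
    out = {}
    for sp in record.composition.species:
        if sp not in factors:
            raise ConfigurationError(
                f"{record.microcosm_id}: no leaching factor for species {sp!r}"
            )
        out[sp] = record.initial_airdry_dm[sp] * factors[sp]
    return out


def mass_loss(
    record: MicrocosmRecord,
    factors: LeachingFactors,
    allometry: AllometryParams | None = None,
) -> MassLossResult:
    """Leaching-corrected litter mass loss, normalised by detritivore mass
    when detritivores are present.

    Negative per-species losses (apparent mass gain, e.g. handling
    variance) are preserved, not clipped, and raise ``mass_gain_flag``.
    """
    initial = corrected_initial_afdm(record, factors)
    losses = {sp: initial[sp] - record.final_afdm[sp] for sp in record.composition.species}
    total = sum(losses.values())
    normalized = None
    if record.detritivores_present:
        if allometry is None:
            raise ConfigurationError("allometry params needed to normalise by detritivore DM")
        det_dm = detritivore_initial_dm(record, allometry)
        if det_dm <= 0:
            raise DataError(f"{record.microcosm_id}: zero initial detritivore DM")
        normalized = total / det_dm
    return MassLossResult(
        corrected_initial_afdm=initial,
        per_species_loss=losses,
        total_loss=total,
        normalized_loss=normalized,
        mass_gain_flag=any(v < 0 for v in losses.values()),
    )


def fpom_production(
    record: MicrocosmRecord, allometry: AllometryParams | None = None
) -> FpomResult:
    """Accumulated FPOM over water changes, normalised when detritivores
    are present."""
    if len(record.fpom_filter_mass) < 1:
        raise ValidationError(f"{record.microcosm_id}: no FPOM collection events")
    if any(f < 0 for f in record.fpom_filter_mass):
        raise ValidationError(f"{record.microcosm_id}: negative FPOM filter mass")
    total = float(sum(record.fpom_filter_mass))
    normalized = None
    if record.detritivores_present:
        if allometry is None:
            raise ConfigurationError("allometry params needed to normalise by detritivore DM")
        normalized = total / detritivore_initial_dm(record, allometry)
    return FpomResult(total_fpom=total, normalized_fpom=normalized)


def detritivore_growth(record: MicrocosmRecord, params: AllometryParams) -> GrowthResult:
    """Percent change in detritivore dry mass: (final - initial)/initial x 100."""
    if not record.detritivores_present:
        raise DataError(f"{record.microcosm_id}: no detritivores in this microcosm")
    if record.detritivore_final_dm is None:
        raise DataError(f"{record.microcosm_id}: final detritivore DM missing")
    initial = detritivore_initial_dm(record, params)
    final = record.detritivore_final_dm
    return GrowthResult(
        initial_dm=initial,
        final_dm=final,
        growth_pct=(final - initial) / initial * 100.0,
    )


def compute_metrics(
    records: list[MicrocosmRecord],
    factors: LeachingFactors,
    allometry: AllometryParams,
) -> pd.DataFrame:
    """One row per microcosm with all derived responses.

    Columns: identifiers (``mixture``, ``richness``, ``detritivores``),
    total and normalised mass loss and FPOM, growth %, detritivore initial
    DM, the mass-gain flag, and per-species losses in ``mass_loss__<sp>``
    columns (NaN for species absent from the microcosm).
    """
    all_species: list[str] = []
    for r in records:
        for sp in r.composition.species:
            if sp not in all_species:
                all_species.append(sp)
    rows = []
    for rec in records:
        ml = mass_loss(rec, factors, allometry)
        fp = fpom_production(rec, allometry)
        row: dict[str, object] = {
            "microcosm_id": rec.microcosm_id,
            "mixture": rec.composition.label,
            "richness": rec.composition.richness,
            "detritivores": rec.detritivores_present,
            "total_mass_loss": ml.total_loss,
            "normalized_mass_loss": ml.normalized_loss,
            "total_fpom": fp.total_fpom,
            "normalized_fpom": fp.normalized_fpom,
            "mass_gain_flag": ml.mass_gain_flag,
        }
        if rec.detritivores_present:
            gr = detritivore_growth(rec, allometry)
            row["detritivore_initial_dm"] = gr.initial_dm
            row["growth_pct"] = gr.growth_pct
        else:
            row["detritivore_initial_dm"] = None
            row["growth_pct"] = None
        for sp in all_species:
            row[f"mass_loss__{sp}"] = ml.per_species_loss.get(sp)
        rows.append(row)
    return pd.DataFrame(rows)


class MassMetrics(BaseEstimator, TransformerMixin):
    """Stateless transformer from microcosm records to the metrics table.

    Parameters
    ----------
    leaching_factors : LeachingFactors
        Per-species air-dry-DM -> post-leach-AFDM conversion.
    allometry : AllometryParams
        Case-length/dry-mass power law for detritivore initial biomass.
    """

    def __init__(
        self,
        leaching_factors: LeachingFactors | None = None,
        allometry: AllometryParams | None = None,
    ):
        self.leaching_factors = leaching_factors
        self.allometry = allometry

    def fit(self, X: list[MicrocosmRecord], y=None) -> "MassMetrics":
        if self.leaching_factors is None or self.allometry is None:
            raise ConfigurationError("leaching_factors and allometry are required")
        self.n_records_ = len(X)
        return self

    def transform(self, X: list[MicrocosmRecord]) -> pd.DataFrame:
        if self.leaching_factors is None or self.allometry is None:
            raise ConfigurationError("leaching_factors and allometry are required")
        return compute_metrics(X, self.leaching_factors, self.allometry)
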