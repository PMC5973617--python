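"""Domain types for litter-mixture microcosm experiments.

One experimental unit is a :class:`MicrocosmRecord`: a jar seeded with leaf
discs from one or more plant species, with or without leaf-shredding
detritivores, incubated for a fixed number of days with periodic water
changes.  Masses are in mg throughout; times are integer days since the
start of the incubation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BeflitterError",
    "SchemaError",
    "ValidationError",
    "ConfigurationError",
    "DataError",
    "Species",
    "Composition",
    "AllometryParams",
    "LeachingFactors",
    "TraitTable",
    "MicrocosmRecord",
    "TRAIT_COLUMNS",
]


class BeflitterError(Exception):
    """Base class for all package errors."""


class SchemaError(BeflitterError):
    """A table is missing a required column or has a malformed layout."""


class ValidationError(BeflitterError):
    """A record or table violates a domain invariant."""


class ConfigurationError(BeflitterError):
    """A configuration object is incomplete or inconsistent."""


class DataError(BeflitterError):
    """The data cannot support the requested computation (e.g. a mixture
    species with no monoculture replicates)."""


#: Canonical trait columns of a species trait table.  N and P are tissue
#: concentrations in % dry mass, SLA is specific leaf area in mm^2 mg^-1,
#: toughness is the piercing pressure in kPa, ash is % dry mass.
TRAIT_COLUMNS = ("N_pct", "P_pct", "SLA", "toughness_kPa", "ash_pct")


@dataclass(frozen=True)
class Species:
    """A plant species with a short code (e.g. ``"A"``) and display name."""

    code: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("species code must be non-empty")


@dataclass(frozen=True)
class Composition:
    """An ordered set of species codes with their seeded proportions.

    Proportions default to 1/richness (equal disc numbers per species) and
    must sum to one.
    """

    species: tuple[str, ...]
    proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        species = tuple(self.species)
        if len(species) == 0:
            raise ValidationError("a composition needs at least one species")
        if len(set(species)) != len(species):
            raise ValidationError(f"duplicate species in composition {species!r}")
        object.__setattr__(self, "species", species)
        if self.proportions is None:
            props = tuple(1.0 / len(species) for _ in species)
        else:
            props = tuple(float(p) for p in self.proportions)
            if len(props) != len(species):
                raise ValidationError("proportions must match species")
            if any(p <= 0 for p in props):
                raise ValidationError("proportions must be positive")
            if not math.isclose(sum(props), 1.0, abs_tol=1e-9):
                raise ValidationError(f"proportions must sum to 1, got {sum(props)}")
        object.__setattr__(self, "proportions", props)

    @property
    def richness(self) -> int:
        return len(self.species)

    @property
    def label(self) -> str:
        """Compact label: ``"ACQ"`` for single-letter codes, else ``"+"``-joined."""
        if all(len(s) == 1 for s in self.species):
            return "".join(self.species)
        return "+".join(self.species)

    def proportion_of(self, code: str) -> float:
        try:
            return self.proportions[self.species.index(code)]
        except ValueError:
            raise DataError(f"species {code!r} not in composition {self.label}") from None

    @classmethod
    def parse(cls, text: str, proportions: Sequence[float] | None = None) -> "Composition":
        """Parse ``"A+C+Q"`` or, for single-letter codes, ``"ACQ"``."""
        text = text.strip()
        if "+" in text:
            species = tuple(s.strip() for s in text.split("+"))
        else:
            species = tuple(text)
        return cls(species, tuple(proportions) if proportions is not None else None)


@dataclass(frozen=True)
class AllometryParams:
    """Power-law case-length/dry-mass allometry DM = a * CL**b.

    ``a`` is in mg mm^-b, ``b`` dimensionless.
    """

    a: float = 0.0043
    b: float = 2.8041

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("allometry coefficients must be positive")

    def dm(self, case_length: float) -> float:
        """Dry mass (mg) of a larva with case length ``case_length`` (mm)."""
        if case_length <= 0:
            raise ValidationError(f"case length must be positive, got {case_length}")
        return self.a * case_length**self.b

    def case_length(self, dm: float) -> float:
        """Inverse allometry: case length (mm) for a dry mass (mg)."""
        if dm <= 0:
            raise ValidationError(f"dry mass must be positive, got {dm}")
        return (dm / self.a) ** (1.0 / self.b)


@dataclass(frozen=True)
class LeachingFactors:
    """Per-species multiplicative factor mapping pre-leach air-dry DM to
    post-leach AFDM (dimensionless, in (0, 1])."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for code, f in self.factors.items():
            if not (0.0 < f <= 1.0):
                raise ConfigurationError(
                    f"leaching factor for {code!r} must be in (0, 1], got {f}"
                )
        object.__setattr__(self, "factors", dict(self.factors))

    def __getitem__(self, code: str) -> float:
        try:
            return self.factors[code]
        except KeyError:
            raise ConfigurationError(f"no leaching factor for species {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.factors


class TraitTable:
    """Species x trait matrix (rows = species codes, columns = TRAIT_COLUMNS).

    Wraps a :class:`pandas.DataFrame`; all values must be strictly positive
    and the matrix complete.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TRAIT_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"trait table missing columns: {missing}")
        frame = frame.loc[:, list(TRAIT_COLUMNS)].astype(float)
        if len(frame) < 1:
            raise ValidationError("trait table needs at least one species")
        if frame.index.duplicated().any():
            raise ValidationError("duplicate species in trait table")
        if frame.isna().any().any():
            raise ValidationError("trait table has missing cells")
        if (frame <= 0).any().any():
            raise ValidationError("all trait values must be positive")
        self.frame = frame

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, species: Iterable[str]) -> "TraitTable":
        species = list(species)
        missing = [s for s in species if s not in self.frame.index]
        if missing:
            raise DataError(f"species missing from trait table: {missing}")
        return TraitTable(self.frame.loc[species])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TraitTable(species={self.species})"


@dataclass
class MicrocosmRecord:
    """One microcosm: composition, per-species masses, FPOM series and
    detritivore measurements.

    ``initial_airdry_dm``/``final_dm``/``final_afdm`` map species code to
    mass (mg).  ``fpom_filter_mass`` holds one value per water change.
    Detritivore fields are present iff ``detritivores_present``.
    """

    microcosm_id: str
    composition: Composition
    detritivores_present: bool
    n_discs_per_species: int
    initial_airdry_dm: dict[str, float]
    final_dm: dict[str, float]
    final_afdm: dict[str, float]
    fpom_filter_mass: tuple[float, ...]
    detritivore_case_lengths: tuple[float, ...] | None = None
    detritivore_final_dm: float | None = None
    expected_larvae: int = field(default=3, repr=False)

    def validate(self) -> "MicrocosmRecord":
        comp_species = set(self.composition.species)
        for name in ("initial_airdry_dm", "final_dm", "final_afdm"):
            masses = getattr(self, name)
            if set(masses) != comp_species:
                raise ValidationError(
                    f"{self.microcosm_id}: species keys of {name} "
                    f"({sorted(masses)}) do not match composition "
                    f"({sorted(comp_species)})"
                )
            for sp, m in masses.items():
                if m < 0:
                    raise ValidationError(
                        f"{self.microcosm_id}: negative {name} for {sp}: {m}"
                    )
        for sp in self.composition.species:
            if self.final_afdm[sp] > self.final_dm[sp] + 1e-9:
                raise ValidationError(
                    f"{self.microcosm_id}: final AFDM exceeds final DM for {sp}"
                )
        if len(self.fpom_filter_mass) < 1:
            raise ValidationError(f"{self.microcosm_id}: no FPOM collection events")
        if any(f < 0 for f in self.fpom_filter_mass):
            raise ValidationError(f"{self.microcosm_id}: negative FPOM filter mass")
        if self.n_discs_per_species <= 0:
            raise ValidationError(f"{self.microcosm_id}: non-positive disc count")
        if self.detritivores_present:
            if self.detritivore_case_lengths is None or self.detritivore_final_dm is None:
                raise ValidationError(
                    f"{self.microcosm_id}: detritivores present but measurements missing"
                )
            if len(self.detritivore_case_lengths) != self.expected_larvae:
                raise ValidationError(
                    f"{self.microcosm_id}: expected {self.expected_larvae} case "
                    f"lengths, got {len(self.detritivore_case_lengths)}"
                )
            if any(cl <= 0 for cl in self.detritivore_case_lengths):
                raise ValidationError(f"{self.microcosm_id}: non-positive case length")
            if self.detritivore_final_dm < 0:
                raise ValidationError(f"{self.microcosm_id}: negative detritivore DM")
        else:
            if self.detritivore_case_lengths is not None or self.detritivore_final_dm is not None:
                raise ValidationError(
                    f"{self.microcosm_id}: detritivore measurements on a "
                    "no-detritivore microcosm"
                )
        return self
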