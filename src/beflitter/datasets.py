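"""Bundled reference data for the four riparian species of the experiment.

*Alnus glutinosa* (A), *Corylus avellana* (C), *Quercus robur* (Q) and
*Ilex aquifolium* (I): leaf trait means, leaching-correction factors and the
caddisfly case-length/dry-mass allometry.  The species set is open — any
trait table with the canonical columns works throughout the package — these
four simply ship as the default fixture.
"""

from __future__ import annotations

import math

import pandas as pd

from .records import AllometryParams, LeachingFactors, TraitTable

__all__ = [
    "FOUR_SPECIES",
    "four_species_traits",
    "default_leaching_factors",
    "default_allometry",
    "DISC_AREA_MM2",
    "default_disc_mass",
]

FOUR_SPECIES = ("A", "C", "Q", "I")

SPECIES_NAMES = {
    "A": "Alnus glutinosa",
    "C": "Corylus avellana",
    "Q": "Quercus robur",
    "I": "Ilex aquifolium",
}

#: Leaf area of a 12-mm-diameter disc (mm^2).
DISC_AREA_MM2 = math.pi * 6.0**2

_TRAITS = {
    #        N_pct  P_pct   SLA  toughness_kPa  ash_pct
    "A": (3.30, 0.084, 13.28, 1397.0, 5.64),
    "C": (1.48, 0.053, 21.90, 1016.0, 5.66),
    "Q": (1.23, 0.041, 11.50, 2793.0, 4.68),
    "I": (1.58, 0.068, 6.57, 7715.0, 3.93),
}

_LEACHING = {"A": 0.753, "C": 0.843, "Q": 0.844, "I": 0.767}


def four_species_traits() -> TraitTable:
    """Trait means (5 field replicates each) for the four bundled species."""
    frame = pd.DataFrame.from_dict(
        _TRAITS, orient="index",
        columns=["N_pct", "P_pct", "SLA", "toughness_kPa", "ash_pct"],
    )
    return TraitTable(frame)


def default_leaching_factors() -> LeachingFactors:
    """Fraction of air-dry disc mass remaining as AFDM after 48 h leaching."""
    return LeachingFactors(dict(_LEACHING))


def default_allometry() -> AllometryParams:
    """Case-length/dry-mass allometry DM = 0.0043 * CL**2.8041 (r^2 = 0.79)."""
    return AllometryParams(a=0.0043, b=2.8041)


def default_disc_mass(traits: TraitTable | None = None) -> dict[str, float]:
    """Air-dry mass (mg) of one leaf disc per species, as disc area / SLA."""
    traits = traits if traits is not None else four_species_traits()
    return {sp: DISC_AREA_MM2 / traits.frame.loc[sp, "SLA"] for sp in traits.species}
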