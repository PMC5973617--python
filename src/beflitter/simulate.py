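"""Seeded generator of complete litter-mixture microcosm experiments.

The generator emulates the structure of the laboratory design: a full
factorial of species compositions (every non-empty subset of the species
pool; 15 treatments for four species) crossed with detritivore presence,
with replicate microcosms, 48 leaf discs split equally among the species,
a 21-day incubation and water changes on days 7, 14 and 21.

Mechanisms (all per-microcosm, noise-free expectations):

* microbial loss per species: m_i * (1 - exp(-k_i * T)) of the post-leach
  AFDM m_i;
* detritivore consumption: total demand C = gamma^[N>1] * c * B * T, where
  B is initial detritivore biomass, allocated across species proportionally
  to seeded proportion x preference weight (weight = quality trait raised
  to the preference exponent), capped at each species' availability with
  proportional redistribution of any surplus;
* FPOM: f_m of microbial loss plus f_d of consumption (egestion), split
  across water changes proportionally to elapsed time;
* detritivore growth: final DM = B + AE * C - maintenance * B * T.

The complementarity multiplier gamma boosts consumption only in mixtures
(resource partitioning); trait-based preference re-allocates consumption
toward preferred species (selection).  With gamma = 1 and equal
preferences the generated mixtures equal their monoculture expectation
exactly, so every downstream diversity effect is zero by construction.

Observation noise is multiplicative lognormal (unit mean) on final masses
and larval dry masses, and additive truncated-at-zero Gaussian on FPOM
filter masses.  A single seed drives hierarchical per-microcosm substreams,
so adding replicates never changes existing microcosms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .datasets import (
    default_allometry,
    default_disc_mass,
    default_leaching_factors,
    four_species_traits,
)
from .partition import additive_partition, contribution_pct, net_effect_fpom
from .records import (
    AllometryParams,
    Composition,
    ConfigurationError,
    LeachingFactors,
    MicrocosmRecord,
    TraitTable,
)

__all__ = ["SyntheticConfig", "generate_experiment", "ground_truth"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a synthetic microcosm experiment.

    Defaults reproduce the study conditions: four species with the bundled
    trait table, 15 composition treatments x 10 replicates (half with 3
    detritivores), 21 days, water changes on days 7/14/21, ~17.8 mg initial
    detritivore biomass per microcosm, and mechanism strengths that yield
    detritivore-mediated diversity effects with dominant complementarity
    and an Alnus-linked selection effect.
    """

    species: tuple[str, ...] = ("A", "C", "Q", "I")
    traits: TraitTable = field(default_factory=four_species_traits)
    #: per-species microbial decay rate (day^-1)
    k_micro: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.016, "C": 0.010, "Q": 0.007, "I": 0.005}
    )
    #: detritivore consumption rate (mg leaf mg detritivore^-1 day^-1)
    consumption_rate: float = 0.15
    #: trait whose value feeds the preference weights
    preference_trait: str = "N_pct"
    #: preference weight = trait^exponent; 0 = no preference
    preference_exponent: float = 1.0
    #: consumption multiplier applied in mixtures (complementarity)
    gamma: float = 1.3
    #: fraction of microbial loss exported as FPOM
    f_m: float = 0.05
    #: fraction of consumed mass egested as FPOM
    f_d: float = 0.40
    assimilation_efficiency: float = 0.30
    #: maintenance mass-loss rate of detritivores (day^-1)
    maintenance_rate: float = 0.0349
    #: per-species air-dry mass of one leaf disc (mg); default area/SLA
    disc_mass: Mapping[str, float] | None = None
    leaching: LeachingFactors = field(default_factory=default_leaching_factors)
    allometry: AllometryParams = field(default_factory=default_allometry)
    n_discs_total: int = 48
    larvae_per_microcosm: int = 3
    #: mean dry mass (mg) of one larva; 3 x 5.94 ~ 17.8 mg per microcosm
    larva_dm_mean: float = 5.94
    larva_dm_cv: float = 0.12
    #: coefficient of variation of multiplicative mass noise
    mass_cv: float = 0.05
    #: SD (mg) of additive FPOM filter noise
    filter_sd: float = 0.3
    #: replicate microcosms per composition (half receive detritivores)
    replicates: int = 10
    water_change_days: tuple[int, ...] = (7, 14, 21)
    duration: int = 21
    seed: int = 42

    def __post_init__(self) -> None:
        if self.disc_mass is None:
            object.__setattr__(self, "disc_mass", default_disc_mass(self.traits))
        for name in ("consumption_rate", "gamma", "maintenance_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("f_m", "f_d", "assimilation_efficiency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for sp in self.species:
            if sp not in self.k_micro:
                raise ConfigurationError(f"missing k_micro for species {sp!r}")
            if self.k_micro[sp] < 0:
                raise ConfigurationError(f"k_micro[{sp!r}] must be >= 0")
            if sp not in self.disc_mass or self.disc_mass[sp] <= 0:
                raise ConfigurationError(f"invalid disc mass for species {sp!r}")
            if sp not in self.leaching:
                raise ConfigurationError(f"missing leaching factor for {sp!r}")
        if self.preference_trait not in self.traits.frame.columns:
            raise ConfigurationError(
                f"unknown preference trait {self.preference_trait!r}"
            )
        if self.replicates < 1 or self.larvae_per_microcosm < 1:
            raise ConfigurationError("replicates and larvae counts must be >= 1")
        if self.duration <= 0 or not self.water_change_days:
            raise ConfigurationError("need a positive duration and >= 1 water change")
        if max(self.water_change_days) != self.duration:
            raise ConfigurationError("last water change must fall on the final day")

    # -- convenience constructors for the canonical scenarios -------------

    @classmethod
    def paper_like(cls, seed: int = 42, **overrides) -> "SyntheticConfig":
        """Both mechanisms on (default): gamma = 1.3, N-based preference."""
        return cls(seed=seed, **overrides)

    @classmethod
    def null(cls, seed: int = 42, **overrides) -> "SyntheticConfig":
        """No diversity mechanisms: gamma = 1, equal preferences."""
        return cls(seed=seed, gamma=1.0, preference_exponent=0.0, **overrides)

    @classmethod
    def complementarity_only(cls, seed: int = 42, **overrides) -> "SyntheticConfig":
        return cls(seed=seed, gamma=1.3, preference_exponent=0.0, **overrides)

    @classmethod
    def selection_only(cls, seed: int = 42, **overrides) -> "SyntheticConfig":
        return cls(seed=seed, gamma=1.0, preference_exponent=2.0, **overrides)

    def with_noise_off(self) -> "SyntheticConfig":
        return replace(self, larva_dm_cv=0.0, mass_cv=0.0, filter_sd=0.0)

    # -- design ------------------------------------------------------------

    def compositions(self) -> list[Composition]:
        """All non-empty subsets of the species pool, smallest first."""
        comps = []
        for r in range(1, len(self.species) + 1):
            for combo in itertools.combinations(self.species, r):
                comps.append(Composition(tuple(combo)))
        return comps

    def preference_weights(self, species: Sequence[str]) -> dict[str, float]:
        tvals = self.traits.frame[self.preference_trait]
        return {sp: float(tvals.loc[sp]) ** self.preference_exponent for sp in species}


def _allocate_consumption(
    demand: float,
    shares: Mapping[str, float],
    available: Mapping[str, float],
) -> dict[str, float]:
    """Split total demand by shares, capping at availability and
    redistributing any surplus proportionally among uncapped species."""
    species = list(shares)
    consumed = {sp: 0.0 for sp in species}
    remaining = demand
    active = set(species)
    while remaining > 1e-12 and active:
        total_share = sum(shares[sp] for sp in active)
        if total_share <= 0:
            break
        capped = set()
        allocated = 0.0
        for sp in active:
            want = remaining * shares[sp] / total_share
            room = available[sp] - consumed[sp]
            take = min(want, room)
            consumed[sp] += take
            allocated += take
            if take >= room - 1e-12:
                capped.add(sp)
        remaining -= allocated
        active -= capped
        if allocated <= 1e-15:
            break
    return consumed


def _expected_microcosm(
    config: SyntheticConfig, comp: Composition, detritivores: bool, biomass: float
) -> dict:
    """Noise-free expectations for one microcosm: per-species post-leach
    AFDM, microbial loss, consumption, final AFDM; FPOM and growth."""
    t = float(config.duration)
    n_discs = config.n_discs_total // comp.richness
    post_leach = {}
    microbial = {}
    airdry = {}
    for sp in comp.species:
        airdry[sp] = n_discs * config.disc_mass[sp]
        post_leach[sp] = airdry[sp] * config.leaching[sp]
        microbial[sp] = post_leach[sp] * (1.0 - math.exp(-config.k_micro[sp] * t))
    consumed = {sp: 0.0 for sp in comp.species}
    if detritivores and config.consumption_rate > 0:
        boost = config.gamma if comp.richness > 1 else 1.0
        demand = boost * config.consumption_rate * biomass * t
        weights = config.preference_weights(comp.species)
        shares = {
            sp: comp.proportion_of(sp) * weights[sp] for sp in comp.species
        }
        available = {sp: post_leach[sp] - microbial[sp] for sp in comp.species}
        consumed = _allocate_consumption(demand, shares, available)
    final_afdm = {
        sp: post_leach[sp] - microbial[sp] - consumed[sp] for sp in comp.species
    }
    total_consumed = sum(consumed.values())
    fpom_total = config.f_m * sum(microbial.values()) + config.f_d * total_consumed
    growth = None
    final_det_dm = None
    if detritivores:
        final_det_dm = (
            biomass
            + config.assimilation_efficiency * total_consumed
            - config.maintenance_rate * biomass * t
        )
        growth = (final_det_dm - biomass) / biomass * 100.0
    return {
        "n_discs": n_discs,
        "airdry": airdry,
        "post_leach": post_leach,
        "microbial": microbial,
        "consumed": consumed,
        "final_afdm": final_afdm,
        "fpom_total": fpom_total,
        "final_det_dm": final_det_dm,
        "growth_pct": growth,
    }


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    z = rng.standard_normal(size)
    return np.exp(math.sqrt(sigma2) * z - sigma2 / 2.0)


def generate_experiment(
    config: SyntheticConfig, seed: int | None = None
) -> list[MicrocosmRecord]:
    """Generate the full factorial experiment as validated records.

    ``seed`` overrides ``config.seed``.  Substreams are keyed by
    (treatment, arm, replicate) so records are independent of how many
    replicates are requested.
    """
    base_seed = config.seed if seed is None else seed
    n_det = config.replicates // 2
    records: list[MicrocosmRecord] = []
    ash = config.traits.frame["ash_pct"]
    intervals = np.diff((0,) + tuple(config.water_change_days)).astype(float)
    fpom_shares = intervals / intervals.sum()
    for t_idx, comp in enumerate(config.compositions()):
        for rep in range(config.replicates):
            det = rep < n_det
            rep_in_arm = rep if det else rep - n_det
            rng = np.random.default_rng(
                [base_seed, t_idx, int(det), rep_in_arm]
            )
            if det:
                larva_dm = config.larva_dm_mean * _lognormal_factor(
                    rng, config.larva_dm_cv, config.larvae_per_microcosm
                )
                larva_dm = np.atleast_1d(larva_dm)
                biomass = float(larva_dm.sum())
                case_lengths = tuple(
                    float(config.allometry.case_length(dm)) for dm in larva_dm
                )
            else:
                biomass = 0.0
                case_lengths = None
            exp = _expected_microcosm(config, comp, det, biomass)
            final_afdm = {}
            final_dm = {}
            for sp in comp.species:
                noisy = exp["final_afdm"][sp] * float(
                    _lognormal_factor(rng, config.mass_cv)
                )
                final_afdm[sp] = max(noisy, 0.0)
                final_dm[sp] = final_afdm[sp] / (1.0 - float(ash.loc[sp]) / 100.0)
            fpom_events = tuple(
                max(
                    float(
                        exp["fpom_total"] * share
                        + (rng.normal(0.0, config.filter_sd) if config.filter_sd > 0 else 0.0)
                    ),
                    0.0,
                )
                for share in fpom_shares
            )
            final_det_dm = None
            if det:
                final_det_dm = max(
                    exp["final_det_dm"] * float(_lognormal_factor(rng, config.mass_cv)),
                    0.0,
                )
            rec = MicrocosmRecord(
                microcosm_id=f"{comp.label}-{'D' if det else 'N'}{rep_in_arm + 1}",
                composition=comp,
                detritivores_present=det,
                n_discs_per_species=exp["n_discs"],
                initial_airdry_dm=dict(exp["airdry"]),
                final_dm=final_dm,
                final_afdm=final_afdm,
                fpom_filter_mass=fpom_events,
                detritivore_case_lengths=case_lengths,
                detritivore_final_dm=final_det_dm,
                expected_larvae=config.larvae_per_microcosm,
            )
            records.append(rec.validate())
    return records


def ground_truth(config: SyntheticConfig) -> dict:
    """Noise-free expected responses and diversity effects per mixture.

    Evaluates the generator equations at the mean detritivore biomass and
    applies the additive partition to the expected per-species normalised
    losses; these are the recovery targets for the pipeline.
    """
    biomass = config.larva_dm_mean * config.larvae_per_microcosm
    mono_loss: dict[str, float] = {}
    mono_fpom: dict[str, float] = {}
    growth = {}
    for sp in config.species:
        comp = Composition((sp,))
        exp = _expected_microcosm(config, comp, True, biomass)
        mono_loss[sp] = (exp["microbial"][sp] + exp["consumed"][sp]) / biomass
        mono_fpom[sp] = exp["fpom_total"] / biomass
        growth[sp] = exp["growth_pct"]
    mixtures = {}
    for comp in config.compositions():
        if comp.richness < 2:
            continue
        exp = _expected_microcosm(config, comp, True, biomass)
        observed = {
            sp: (exp["microbial"][sp] + exp["consumed"][sp]) / biomass
            for sp in comp.species
        }
        part = additive_partition(
            observed, mono_loss, dict(zip(comp.species, comp.proportions))
        )
        fpom_net = net_effect_fpom(
            exp["fpom_total"] / biomass,
            mono_fpom,
            dict(zip(comp.species, comp.proportions)),
        )
        pct = contribution_pct(part.complementarity, part.selection)
        mixtures[comp.label] = {
            "net": part.net,
            "complementarity": part.complementarity,
            "selection": part.selection,
            "ce_pct": pct[0] if pct else None,
            "se_pct": pct[1] if pct else None,
            "fpom_net": fpom_net,
            "growth_pct": exp["growth_pct"],
            "per_species_loss": {
                sp: exp["microbial"][sp] + exp["consumed"][sp] for sp in comp.species
            },
        }
    return {
        "monoculture_normalized_loss": mono_loss,
        "monoculture_normalized_fpom": mono_fpom,
        "monoculture_growth_pct": growth,
        "mixtures": mixtures,
    }
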