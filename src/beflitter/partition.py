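"""Additive partitioning of net diversity effects on decomposition.

For a mixture of N species with seeded proportions p_i, monoculture mean
responses M_i and per-species observed mixture responses Y_O,i, the
expected response of species i is Y_E,i = p_i * M_i and its relative-yield
deviation is dRY_i = Y_O,i / M_i - p_i.  The net diversity effect

    net = sum(Y_O,i) - sum(Y_E,i)

splits exactly into a complementarity effect and a selection effect:

    CE = N * mean(dRY) * mean(M)
    SE = N * cov(dRY, M)        (population covariance, divide by N)

The population covariance convention is what makes net = CE + SE an exact
identity.  Positive CE indicates synergy shared across species (resource
partitioning or facilitation); positive SE indicates dominance of species
with above-average monoculture performance.

For FPOM production only the net effect is defined, because the
contribution of individual species to the mixture total cannot be
separated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .records import Composition, DataError, ValidationError

__all__ = [
    "MonocultureSummary",
    "PartitionResult",
    "monoculture_summary",
    "additive_partition",
    "contribution_pct",
    "net_effect_fpom",
    "fpom_net_experiment",
    "partition_experiment",
    "summarize_partitions",
    "summarize_fpom_net",
    "net_effect_test",
    "DiversityPartitioner",
]


@dataclass(frozen=True)
class MonocultureSummary:
    """Per-species monoculture mean response with replicate count and SD."""

    mean: dict[str, float]
    n: dict[str, int]
    sd: dict[str, float]
    response: str

    def require(self, species: Sequence[str]) -> None:
        missing = [s for s in species if s not in self.mean]
        if missing:
            raise DataError(
                f"no monoculture replicates for species {missing} "
                f"(response {self.response!r})"
            )


@dataclass(frozen=True)
class PartitionResult:
    """Additive partition of one mixture replicate."""

    species: tuple[str, ...]
    proportions: tuple[float, ...]
    observed: dict[str, float]
    expected: dict[str, float]
    relative_yield: dict[str, float]
    delta_ry: dict[str, float]
    net: float
    complementarity: float
    selection: float


def monoculture_summary(
    metrics: pd.DataFrame,
    response: str = "normalized_mass_loss",
    detritivores: bool = True,
) -> MonocultureSummary:
    """Mean monoculture response per species for the selected arm."""
    mono = metrics[(metrics["richness"] == 1) & (metrics["detritivores"] == detritivores)]
    means: dict[str, float] = {}
    ns: dict[str, int] = {}
    sds: dict[str, float] = {}
    for sp, grp in mono.groupby("mixture"):
        vals = grp[response].astype(float).to_numpy()
        if len(vals) == 0:
            continue
        means[str(sp)] = float(np.mean(vals))
        ns[str(sp)] = int(len(vals))
        sds[str(sp)] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    if not means:
        raise DataError(
            f"no monoculture replicates in the "
            f"{'detritivore' if detritivores else 'no-detritivore'} arm"
        )
    return MonocultureSummary(mean=means, n=ns, sd=sds, response=response)


def additive_partition(
    observed: Mapping[str, float],
    mono: MonocultureSummary | Mapping[str, float],
    proportions: Mapping[str, float] | None = None,
) -> PartitionResult:
    """Partition one mixture replicate into net, complementarity and
    selection effects.

    ``observed`` maps species -> per-species mixture response; ``mono``
    supplies monoculture means; ``proportions`` defaults to 1/N.
    """
    mono_mean = mono.mean if isinstance(mono, MonocultureSummary) else dict(mono)
    species = tuple(observed.keys())
    if len(species) < 2:
        raise ValidationError("additive partitioning needs a mixture of >= 2 species")
    missing = [s for s in species if s not in mono_mean]
    if missing:
        raise DataError(f"no monoculture mean for species {missing}")
    if proportions is None:
        props = {s: 1.0 / len(species) for s in species}
    else:
        props = {s: float(proportions[s]) for s in species}
    m = np.array([mono_mean[s] for s in species], dtype=float)
    if np.any(m <= 0):
        bad = [s for s, v in zip(species, m) if v <= 0]
        raise DataError(f"monoculture mean must be positive for relative yields: {bad}")
    y_o = np.array([float(observed[s]) for s in species])
    p = np.array([props[s] for s in species])
    n = len(species)
    ry_o = y_o / m
    dry = ry_o - p
    y_e = p * m
    net = float(y_o.sum() - y_e.sum())
    ce = float(n * dry.mean() * m.mean())
    se = float(n * (np.mean(dry * m) - dry.mean() * m.mean()))
    return PartitionResult(
        species=species,
        proportions=tuple(p),
        observed={s: float(v) for s, v in zip(species, y_o)},
        expected={s: float(v) for s, v in zip(species, y_e)},
        relative_yield={s: float(v) for s, v in zip(species, ry_o)},
        delta_ry={s: float(v) for s, v in zip(species, dry)},
        net=net,
        complementarity=ce,
        selection=se,
    )


def contribution_pct(ce: float, se: float) -> tuple[float, float] | None:
    """Percent contributions of CE and SE to the net effect, on absolute
    values: CE% = 100|CE| / (|CE| + |SE|).  Returns ``None`` when both are
    zero (undefined)."""
    denom = abs(ce) + abs(se)
    if denom == 0:
        return None
    ce_pct = 100.0 * abs(ce) / denom
    return (ce_pct, 100.0 - ce_pct)


def net_effect_fpom(
    observed_total: float,
    mono: MonocultureSummary | Mapping[str, float],
    proportions: Mapping[str, float] | Sequence[str],
) -> float:
    """Net diversity effect on a total-only response (FPOM): observed
    mixture total minus the proportion-weighted monoculture expectation."""
    mono_mean = mono.mean if isinstance(mono, MonocultureSummary) else dict(mono)
    if isinstance(proportions, Mapping):
        props = dict(proportions)
    else:
        props = {s: 1.0 / len(proportions) for s in proportions}
    missing = [s for s in props if s not in mono_mean]
    if missing:
        raise DataError(f"no monoculture mean for species {missing}")
    expected = sum(p * mono_mean[s] for s, p in props.items())
    return float(observed_total) - float(expected)


def fpom_net_experiment(
    metrics: pd.DataFrame,
    mixtures: Sequence[str] | None = None,
    detritivores: bool = True,
) -> pd.DataFrame:
    """Per-replicate net diversity effect on FPOM production.

    Uses ``normalized_fpom`` in the detritivore arm and ``total_fpom``
    otherwise; no CE/SE split exists for a total-only response.
    """
    response = "normalized_fpom" if detritivores else "total_fpom"
    mono = monoculture_summary(metrics, response=response, detritivores=detritivores)
    arm = metrics[(metrics["detritivores"] == detritivores) & (metrics["richness"] >= 2)]
    if mixtures is not None:
        arm = arm[arm["mixture"].isin(list(mixtures))]
    rows = []
    for mixture, grp in arm.groupby("mixture", sort=False):
        comp = Composition.parse(str(mixture))
        mono.require(comp.species)
        props = dict(zip(comp.species, comp.proportions))
        for _, row in grp.iterrows():
            rows.append(
                {
                    "mixture": mixture,
                    "replicate": row["microcosm_id"],
                    "richness": comp.richness,
                    "fpom_net": net_effect_fpom(float(row[response]), mono, props),
                }
            )
    if not rows:
        raise DataError("no mixture microcosms for the FPOM net effect")
    return pd.DataFrame(rows)


def summarize_fpom_net(
    fpom: pd.DataFrame, mono: MonocultureSummary
) -> pd.DataFrame:
    """Mixture means +- SE of the FPOM net effect with the combined-variance
    Welch test against zero."""
    rows = []
    for mixture, grp in fpom.groupby("mixture", sort=False):
        comp = Composition.parse(str(mixture))
        props = dict(zip(comp.species, comp.proportions))
        expected = sum(p * mono.mean[s] for s, p in props.items())
        observed = grp["fpom_net"].to_numpy(dtype=float) + expected
        est, se, p_val = net_effect_test(observed, mono, props)
        rows.append(
            {
                "mixture": mixture,
                "n": len(grp),
                "fpom_net_mean": est,
                "fpom_net_se": se,
                "fpom_net_p": p_val,
            }
        )
    return pd.DataFrame(rows)


def _per_species_observed(row: pd.Series, species: Sequence[str], response: str) -> dict:
    """Per-species observed responses for one mixture microcosm."""
    out = {}
    for sp in species:
        loss = row.get(f"mass_loss__{sp}")
        if loss is None or pd.isna(loss):
            raise DataError(
                f"{row['microcosm_id']}: missing per-species loss for {sp}"
            )
        loss = float(loss)
        if response == "normalized_mass_loss":
            out[sp] = loss / float(row["detritivore_initial_dm"])
        elif response == "total_mass_loss":
            out[sp] = loss
        else:
            raise ValidationError(
                f"per-species partitioning undefined for response {response!r}"
            )
    return out


def partition_experiment(
    metrics: pd.DataFrame,
    mixtures: Sequence[str] | None = None,
    response: str = "normalized_mass_loss",
    detritivores: bool = True,
    on_means: bool = False,
) -> pd.DataFrame:
    """Additive partition for every replicate of every mixture.

    ``mixtures`` restricts the computation to the named composition labels
    (default: every composition with richness >= 2 in the selected arm).
    ``on_means`` collapses replicates to treatment means before
    partitioning (one row per mixture; same means as per-replicate,
    different spread).

    Returns a long table with columns mixture, replicate (microcosm_id),
    richness, net, complementarity, selection.
    """
    if detritivores is False and response == "normalized_mass_loss":
        response = "total_mass_loss"
    mono = monoculture_summary(metrics, response=response, detritivores=detritivores)
    arm = metrics[(metrics["detritivores"] == detritivores) & (metrics["richness"] >= 2)]
    if mixtures is not None:
        missing = [mx for mx in mixtures if mx not in set(arm["mixture"])]
        if missing:
            raise DataError(f"mixtures absent from the metrics table: {missing}")
        arm = arm[arm["mixture"].isin(list(mixtures))]
    rows = []
    for mixture, grp in arm.groupby("mixture", sort=False):
        comp = Composition.parse(str(mixture))
        mono.require(comp.species)
        if on_means:
            grp = grp.copy()
            num_cols = grp.select_dtypes("number").columns
            mean_row = grp.iloc[0].copy()
            mean_row[num_cols] = grp[num_cols].mean()
            mean_row["microcosm_id"] = f"{mixture}:mean"
            grp = pd.DataFrame([mean_row])
        for _, row in grp.iterrows():
            observed = _per_species_observed(row, comp.species, response)
            res = additive_partition(
                observed, mono, dict(zip(comp.species, comp.proportions))
            )
            rows.append(
                {
                    "mixture": mixture,
                    "replicate": row["microcosm_id"],
                    "richness": comp.richness,
                    "net": res.net,
                    "complementarity": res.complementarity,
                    "selection": res.selection,
                }
            )
    if not rows:
        raise DataError("no mixture microcosms to partition")
    return pd.DataFrame(rows)


def net_effect_test(
    observed: np.ndarray,
    mono: MonocultureSummary,
    proportions: Mapping[str, float],
) -> tuple[float, float, float]:
    """Welch-type test of a mixture's net diversity effect against zero.

    The net effect is the mixture mean minus the proportion-weighted
    monoculture means, so its sampling variance combines both sources:
    s_obs^2 / n_obs + sum(p_i^2 s_i^2 / n_i).  A one-sample t-test across
    mixture replicates alone conditions on the estimated monoculture
    means and is anti-conservative.  Returns (estimate, se, p) with
    Welch-Satterthwaite degrees of freedom.
    """
    observed = np.asarray(observed, dtype=float)
    n_obs = len(observed)
    expected = sum(p * mono.mean[s] for s, p in proportions.items())
    est = float(observed.mean() - expected)
    v_obs = float(observed.var(ddof=1)) / n_obs if n_obs > 1 else np.nan
    v_terms = [v_obs]
    df_terms = [(v_obs, n_obs - 1)]
    for s, p in proportions.items():
        v_i = p**2 * mono.sd[s] ** 2 / mono.n[s]
        v_terms.append(v_i)
        df_terms.append((v_i, max(mono.n[s] - 1, 1)))
    var = float(np.nansum(v_terms))
    if not np.isfinite(var) or var <= 0:
        return est, np.nan, np.nan
    df = var**2 / sum(v**2 / d for v, d in df_terms if np.isfinite(v) and v > 0)
    se = np.sqrt(var)
    p_val = float(2 * stats.t.sf(abs(est) / se, df))
    return est, float(se), p_val


def summarize_partitions(
    per_replicate: pd.DataFrame,
    mono: MonocultureSummary | None = None,
) -> pd.DataFrame:
    """Aggregate replicate-level partitions to mixture means +- SE with
    contribution percentages and p-values against zero.

    CE/SE p-values are one-sample t-tests across mixture replicates
    (conditional on the monoculture means).  When ``mono`` is supplied the
    net-effect test instead uses the combined-variance Welch form of
    :func:`net_effect_test`, which also accounts for monoculture-mean
    sampling error.
    """
    rows = []
    for mixture, grp in per_replicate.groupby("mixture", sort=False):
        row: dict[str, object] = {"mixture": mixture, "n": len(grp)}
        for col, short in (
            ("net", "net"),
            ("complementarity", "ce"),
            ("selection", "se"),
        ):
            vals = grp[col].to_numpy(dtype=float)
            row[f"{short}_mean"] = float(vals.mean())
            row[f"{short}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
            if len(vals) > 1 and vals.std(ddof=1) > 0:
                row[f"{short}_p"] = float(stats.ttest_1samp(vals, 0.0).pvalue)
            else:
                row[f"{short}_p"] = np.nan
        if mono is not None:
            comp = Composition.parse(str(mixture))
            props = dict(zip(comp.species, comp.proportions))
            # reconstruct per-replicate observed mixture totals:
            # net = observed_total - expected, with expected fixed
            expected = sum(p * mono.mean[s] for s, p in props.items())
            observed = grp["net"].to_numpy(dtype=float) + expected
            est, se, p_val = net_effect_test(observed, mono, props)
            row["net_se"] = se
            row["net_p"] = p_val
        pct = contribution_pct(row["ce_mean"], row["se_mean"])
        row["ce_pct"] = pct[0] if pct else np.nan
        row["se_pct"] = pct[1] if pct else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class DiversityPartitioner(BaseEstimator):
    """Estimator wrapper around the additive partition of an experiment.

    Parameters
    ----------
    response : str
        Metrics column to partition; ``"normalized_mass_loss"`` (default,
        detritivore arm) or ``"total_mass_loss"``.
    detritivores : bool
        Which experimental arm to analyse.
    mixtures : sequence of str, optional
        Composition labels to partition (default: all with richness >= 2).
    on_means : bool
        Partition treatment means instead of individual replicates.

    Attributes
    ----------
    monoculture_ : MonocultureSummary
    results_ : DataFrame, replicate-level net/CE/SE
    summary_ : DataFrame, mixture means +- SE with CE%/SE%
    """

    def __init__(
        self,
        response: str = "normalized_mass_loss",
        detritivores: bool = True,
        mixtures: Sequence[str] | None = None,
        on_means: bool = False,
    ):
        self.response = response
        self.detritivores = detritivores
        self.mixtures = mixtures
        self.on_means = on_means

    def fit(self, X: pd.DataFrame, y=None) -> "DiversityPartitioner":
        response = self.response
        if not self.detritivores and response == "normalized_mass_loss":
            response = "total_mass_loss"
        self.monoculture_ = monoculture_summary(
            X, response=response, detritivores=self.detritivores
        )
        self.results_ = partition_experiment(
            X,
            mixtures=self.mixtures,
            response=self.response,
            detritivores=self.detritivores,
            on_means=self.on_means,
        )
        self.summary_ = summarize_partitions(self.results_, mono=self.monoculture_)
        return self
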