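"""End-to-end orchestration: metrics -> partitioning -> trait metrics ->
inference, with CSV/JSON outputs and report figures.

Every output table is regenerable from the experiment CSV plus the
configuration alone; warnings collected along the way (negative losses,
fallback transforms) end up in the JSON summary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import diversity_loss_anova, regress_effect_on_trait
from .io import write_results
from .mass import compute_metrics, corrected_initial_afdm
from .partition import (
    fpom_net_experiment,
    monoculture_summary,
    partition_experiment,
    summarize_fpom_net,
    summarize_partitions,
)
from .records import (
    AllometryParams,
    Composition,
    ConfigurationError,
    LeachingFactors,
    MicrocosmRecord,
    TraitTable,
)
from .traits import mixture_trait_table

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

log = logging.getLogger("beflitter")


@dataclass
class PipelineConfig:
    """Switches and parameters for a full analysis run."""

    leaching: LeachingFactors
    allometry: AllometryParams
    traits: TraitTable
    output_dir: Path | str = "."
    #: which experimental arm to analyse: "detritivores", "none" or "both"
    arm: str = "detritivores"
    #: partition per replicate (default) or on treatment means
    on_means: bool = False
    scale_convention: str = "sample_sd"
    alpha: float = 0.05
    #: mixtures to partition; default: the full mixture plus every
    #: one-species-removed mixture (the focal comparisons of the design)
    focal_mixtures: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("detritivores", "none", "both"):
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        self.output_dir = Path(self.output_dir)


def default_focal_mixtures(records: Sequence[MicrocosmRecord]) -> list[str]:
    """The full-richness mixture plus each mixture missing one species."""
    pool: list[str] = []
    for r in records:
        for sp in r.composition.species:
            if sp not in pool:
                pool.append(sp)
    labels = {r.composition.label: r.composition for r in records}
    n = len(pool)
    focal = [
        lab
        for lab, comp in labels.items()
        if comp.richness in (n, n - 1) and comp.richness >= 2
    ]
    return focal


def _anova_table(
    metrics: pd.DataFrame,
    focal: list[str],
    detritivores: bool,
    alpha: float,
) -> pd.DataFrame:
    responses = (
        ["normalized_mass_loss", "normalized_fpom", "growth_pct"]
        if detritivores
        else ["total_mass_loss", "total_fpom"]
    )
    rows = []
    for lab in focal:
        comp = Composition.parse(lab)
        for response in responses:
            fit, _ = diversity_loss_anova(
                metrics,
                comp.species,
                response,
                detritivores=detritivores,
                alpha=alpha,
            )
            rows.append(
                {
                    "mixture_set": lab,
                    "response": response,
                    "arm": "detritivores" if detritivores else "none",
                    "df_num": fit.df_num,
                    "df_den": fit.df_den,
                    "F": fit.f,
                    "p": fit.p,
                }
            )
    return pd.DataFrame(rows)


def _trait_regressions(
    effects: pd.DataFrame,
    effect_cols: dict[str, str],
    mixture_traits: pd.DataFrame,
    alpha: float,
) -> pd.DataFrame:
    """Table-3-style models: each diversity effect against each trait mean
    and against trait variability, log-transformed where possible."""
    predictors = [
        c
        for c in mixture_traits.columns
        if c not in ("mixture", "richness")
    ]
    merged = effects.merge(mixture_traits, on="mixture", how="left")
    rows = []
    for effect_name, col in effect_cols.items():
        for pred in predictors:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = regress_effect_on_trait(
                    merged[col].to_numpy(dtype=float),
                    merged[pred].to_numpy(dtype=float),
                    log_transform=True,
                )
            rows.append(
                {
                    "effect": effect_name,
                    "predictor": pred,
                    "slope": fit.slope,
                    "F": fit.f,
                    "p": fit.p,
                    "r2": fit.r2,
                    "transform": fit.transform,
                    "significant": fit.p < alpha,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    records: Sequence[MicrocosmRecord], config: PipelineConfig
) -> dict:
    """Execute the full analysis and write stage outputs.

    Returns the result bundle: metrics table, per-arm partition tables and
    summaries, FPOM net effects, mixture trait table, ANOVA table, trait
    regression table, and collected warnings.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []

    metrics = compute_metrics(list(records), config.leaching, config.allometry)
    n_gain = int(metrics["mass_gain_flag"].sum())
    if n_gain:
        collected.append(f"{n_gain} microcosm(s) show apparent mass gain")
    write_results(metrics, outdir / "metrics.csv")

    focal = (
        list(config.focal_mixtures)
        if config.focal_mixtures is not None
        else default_focal_mixtures(records)
    )
    arms = {"detritivores": [True], "none": [False], "both": [True, False]}[config.arm]

    bundle: dict = {
        "metrics": metrics,
        "focal_mixtures": focal,
        "arms": {},
        "warnings": collected,
        "alpha": config.alpha,
    }
    summary_json: dict = {"focal_mixtures": focal, "alpha": config.alpha, "arms": {}}

    # weights for mixture trait means: corrected initial AFDM per species
    weights: dict[str, dict[str, float]] = {}
    for rec in records:
        lab = rec.composition.label
        if lab not in weights:
            weights[lab] = corrected_initial_afdm(rec, config.leaching)
    mixture_traits = mixture_trait_table(
        config.traits,
        [lab for lab in focal],
        weights=weights,
        scale_convention=config.scale_convention,
    )
    write_results(mixture_traits, outdir / "mixture_traits.csv")
    bundle["mixture_traits"] = mixture_traits

    for det in arms:
        arm_name = "detritivores" if det else "none"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            per_rep = partition_experiment(
                metrics, mixtures=focal, detritivores=det, on_means=config.on_means
            )
            loss_resp = "normalized_mass_loss" if det else "total_mass_loss"
            mono_loss = monoculture_summary(metrics, response=loss_resp, detritivores=det)
            summary = summarize_partitions(per_rep, mono=mono_loss)
            fpom = fpom_net_experiment(metrics, mixtures=focal, detritivores=det)
            fpom_resp = "normalized_fpom" if det else "total_fpom"
            mono_fpom = monoculture_summary(metrics, response=fpom_resp, detritivores=det)
            fpom_summary = summarize_fpom_net(fpom, mono_fpom)
            anova = _anova_table(metrics, focal, det, config.alpha)
        collected.extend(str(w.message) for w in caught)
        effects = summary.merge(fpom_summary, on="mixture")
        effect_cols = {
            "net_decomposition": "net_mean",
            "complementarity": "ce_mean",
            "selection": "se_mean",
            "net_fpom": "fpom_net_mean",
        }
        # regress replicate-level effects on mixture-level trait summaries
        rep_effects = per_rep.merge(
            fpom.rename(columns={"fpom_net": "fpom_net_rep"})[
                ["mixture", "replicate", "fpom_net_rep"]
            ],
            on=["mixture", "replicate"],
            how="left",
        )
        rep_cols = {
            "net_decomposition": "net",
            "complementarity": "complementarity",
            "selection": "selection",
            "net_fpom": "fpom_net_rep",
        }
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            trait_models = _trait_regressions(
                rep_effects, rep_cols, mixture_traits, config.alpha
            )
        collected.extend(str(w.message) for w in caught)

        suffix = "" if det else "_nodet"
        write_results(per_rep, outdir / f"partition{suffix}.csv")
        write_results(summary, outdir / f"partition_summary{suffix}.csv")
        write_results(fpom, outdir / f"fpom_net{suffix}.csv")
        write_results(anova, outdir / f"anova{suffix}.csv")
        write_results(trait_models, outdir / f"trait_models{suffix}.csv")

        bundle["arms"][arm_name] = {
            "partition": per_rep,
            "partition_summary": summary,
            "fpom_net": fpom,
            "fpom_net_summary": fpom_summary,
            "anova": anova,
            "trait_models": trait_models,
        }
        summary_json["arms"][arm_name] = {
            "partition_summary": effects.to_dict(orient="records"),
            "anova": anova.to_dict(orient="records"),
            "n_significant_trait_models": int(trait_models["significant"].sum()),
        }

    summary_json["warnings"] = collected
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=2, default=float)
    log.info("pipeline complete: %d microcosms, %d focal mixtures", len(records), len(focal))
    return bundle


def make_report(bundle: dict, outdir: Path | str) -> list[Path]:
    """Render figures (means +- SE with significance letters; stacked
    CE/SE bars) and layout tables from a completed bundle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not bundle or "arms" not in bundle or not bundle["arms"]:
        raise ConfigurationError("empty bundle: run the pipeline first")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = bundle["metrics"]
    arm_name = "detritivores" if "detritivores" in bundle["arms"] else "none"
    det = arm_name == "detritivores"
    arm = bundle["arms"][arm_name]
    paths: list[Path] = []

    responses = (
        [("normalized_mass_loss", "Litter decomposition (mg mg$^{-1}$)"),
         ("normalized_fpom", "FPOM production (mg mg$^{-1}$)"),
         ("growth_pct", "Detritivore growth (%)")]
        if det
        else [("total_mass_loss", "Litter mass loss (mg)"),
              ("total_fpom", "FPOM production (mg)")]
    )
    sub = metrics[metrics["detritivores"] == det]
    for response, label in responses:
        fig, ax = plt.subplots(figsize=(4, 3))
        grp = sub.groupby("richness")[response]
        means, sems = grp.mean(), grp.sem()
        ax.bar(means.index.astype(str), means, yerr=sems, capsize=3, color="#7fb3d5")
        from .inference import diversity_loss_anova

        pool = sorted({s for lab in sub["mixture"] for s in Composition.parse(lab).species})
        try:
            fit, pairwise = diversity_loss_anova(
                metrics, tuple(pool), response, detritivores=det,
                alpha=bundle.get("alpha", 0.05),
            )
            letters = pairwise.attrs["letters"]
            for idx, r in enumerate(means.index):
                ax.text(idx, means.loc[r] + (sems.loc[r] or 0), letters.get(str(r), ""),
                        ha="center", va="bottom")
        except Exception:  # letters are decoration; never fail the report
            pass
        ax.set_xlabel("Species richness")
        ax.set_ylabel(label)
        fig.tight_layout()
        path = outdir / f"fig_{response}.svg"
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)

    summary = arm["partition_summary"]
    fig, ax = plt.subplots(figsize=(4.5, 3))
    x = np.arange(len(summary))
    ax.bar(x, summary["ce_mean"], yerr=summary["ce_se"], capsize=3,
           label="Complementarity", color="#5dade2")
    ax.bar(x, summary["se_mean"], bottom=summary["ce_mean"].where(summary["se_mean"] > 0, 0.0),
           yerr=summary["se_se"], capsize=3, label="Selection", color="#f5b041")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(x, summary["mixture"])
    ax.set_ylabel("Diversity effect")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = outdir / "fig_partition.svg"
    fig.savefig(path)
    plt.close(fig)
    paths.append(path)

    for name in ("anova", "trait_models"):
        path = outdir / f"table_{name}.csv"
        write_results(arm[name], path)
        paths.append(path)
    return paths
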