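"""End-to-end orchestration: simulate -> DE -> meta -> EVE -> selection.

This is the glue the ``run-all`` command and the reproduction script use; each
stage is the corresponding module's public API, chained on one seed, with the
planted truth carried along so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, feeding, meta, selection
from .eve import EVEFitResult, shared_beta_lrt
from .orthogroups import (
    FCMatrix,
    build_fc_matrix,
    fc_dendrogram_signal,
    SignalReport,
    strict_orthologs,
)
from .selection import DEFAULT_CLADE_NAMES, GroupSpec, SelectionEntry
from .simulate import (
    EffectClass,
    FeedingCell,
    SimConfig,
    SimulatedDataset,
    simulate_dataset,
    simulate_feeding,
)
from .trees import smallest_clade_map


def clade_name_map(tree) -> dict[str, str]:
    """Species -> name of its smallest non-trivial containing clade."""
    raw = smallest_clade_map(tree)
    return {
        sp: DEFAULT_CLADE_NAMES.get(cl, "clade_" + "_".join(sorted(cl)))
        for sp, cl in raw.items()
    }


@dataclass
class RunResult:
    config: SimConfig
    seed: int
    dataset: SimulatedDataset
    feeding_records: pd.DataFrame
    de_results: dict[str, dict[str, pd.DataFrame]]
    de_genes: dict[str, set]
    fc: FCMatrix
    signal: SignalReport | None
    eve: EVEFitResult | None
    growth: pd.DataFrame
    success_groups: dict[str, feeding.SuccessGroups]
    meta_tables: dict[str, pd.DataFrame]
    success_selections: list[SelectionEntry] = field(default_factory=list)
    clade_selections: list[SelectionEntry] = field(default_factory=list)
    confound_report: pd.DataFrame = field(default_factory=pd.DataFrame)
    heatmap_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def normalized_per_larva(records: pd.DataFrame, control_diet: str = "control") -> pd.DataFrame:
    """Per-larva rates as % deviation from the species' control-diet mean rate."""
    df = feeding.per_larva_rates(records)
    control_means = (
        df[df["diet"] == control_diet].groupby("species")["rate"].mean()
    )
    out = df[df["diet"] != control_diet].copy()
    cm = out["species"].map(control_means)
    if cm.isna().any() or (cm <= 0).any():
        bad = sorted(out.loc[cm.isna() | (cm <= 0), "species"].unique())
        raise ValueError(f"missing or non-positive control mean for {bad}")
    out["norm_rate"] = 100.0 * (out["rate"] - cm) / cm
    return out


def run_all(
    config: SimConfig | None = None,
    seed: int = 0,
    user_success_groups: Mapping[str, list[set]] | None = None,
    max_eve_ogs: int = 100,
    eve_starts: int = 3,
) -> RunResult:
    """Run the whole synthetic-data pipeline with one seed."""
    config = config if config is not None else SimConfig()
    ds = simulate_dataset(config, seed=seed)
    records = simulate_feeding(config, seed=seed + 1)
    species = list(config.species_names)
    plants = [d for d in config.diets if d != config.control_diet]

    # per-species differential expression (every plant vs control)
    de_results = {
        sp: diffexpr.de_all_contrasts(ds.counts[sp], ds.samples, sp,
                                      control=config.control_diet)
        for sp in species
    }
    de_genes = {sp: diffexpr.select_de_genes(de_results[sp]) for sp in species}

    # strict orthologs -> fold-change matrix -> phylogenetic signal
    strict = strict_orthologs(ds.orthogroups)
    cmap = clade_name_map(ds.tree)
    fc = build_fc_matrix(ds.orthogroups, strict, de_results,
                         contrasts=plants, clade_map=cmap)
    signal = fc_dendrogram_signal(fc) if fc.values.shape[1] >= 2 and len(fc.values) >= 3 else None

    eve_fit = None
    if len(fc.values) >= 10:
        sub = fc.values.iloc[:max_eve_ogs]
        species_of_obs = list(fc.col_meta["species"])
        eve_fit = shared_beta_lrt(
            sub, ds.tree, species_of_obs, seed=seed, n_starts=eve_starts
        )

    # feeding assays -> candidate success groups per plant
    growth = feeding.normalize_to_control(
        feeding.growth_rates(records), control_diet=config.control_diet
    )
    norm = normalized_per_larva(records, control_diet=config.control_diet)
    success_groups: dict[str, feeding.SuccessGroups] = {}
    for plant in plants:
        sub = norm[norm["diet"] == plant]
        pw = feeding.kruskal_dunn(sub, grouping="species", value="norm_rate")
        user = None
        if user_success_groups and plant in user_success_groups:
            user = user_success_groups[plant]
        success_groups[plant] = feeding.candidate_success_groups(
            growth, pw, plant, user_groups=user
        )

    # cross-species meta-analysis per plant
    meta_tables = {
        plant: meta.run_meta(ds.orthogroups, de_results, plant) for plant in plants
    }

    # pattern selections
    clade_groups = selection.clade_groups_from_tree(ds.tree)
    success_selections: list[SelectionEntry] = []
    clade_selections: list[SelectionEntry] = []
    for plant in plants:
        tab = meta_tables[plant]
        for i, grp in enumerate(success_groups[plant].groups):
            spec = GroupSpec(
                name=f"success_{plant}_{i + 1}", species=grp, origin="success",
                plants=(plant,),
            )
            success_selections.append(
                selection.select_pattern_ogs(tab, spec, plant, species)
            )
        for grp in clade_groups:
            clade_selections.append(
                selection.select_pattern_ogs(tab, grp, plant, species)
            )
    confound = selection.overlap_confound_report(success_selections, clade_selections)
    heatmap = selection.write_heatmap_table(
        success_selections + clade_selections, species, confound
    )

    return RunResult(
        config=config,
        seed=seed,
        dataset=ds,
        feeding_records=records,
        de_results=de_results,
        de_genes=de_genes,
        fc=fc,
        signal=signal,
        eve=eve_fit,
        growth=growth,
        success_groups=success_groups,
        meta_tables=meta_tables,
        success_selections=success_selections,
        clade_selections=clade_selections,
        confound_report=confound,
        heatmap_table=heatmap,
    )


def score_against_truth(
    truth: pd.DataFrame,
    success_selections: list[SelectionEntry],
    clade_selections: list[SelectionEntry],
) -> dict:
    """Recovery of planted convergent vs clade orthogroups by the selections.

    Sensitivity = fraction of planted OGs of a class picked up by a selection
    of the matching origin with the matching species set and plant;
    cross-assignment = fraction picked up by a selection of the *other* origin
    with a different species set.
    """
    def tally(label: str, same: list[SelectionEntry], other: list[SelectionEntry]):
        sub = truth[truth["label"] == label]
        total = len(sub)
        hit = cross = 0
        for r in sub.itertuples(index=False):
            planted = frozenset(r.species.split(";"))
            if any(
                s.plant == r.diet and s.group.species == planted and r.og in s.selected
                for s in same
            ):
                hit += 1
            if any(
                s.plant == r.diet
                and s.group.species != planted
                and r.og in s.selected
                for s in other
            ):
                cross += 1
        return {
            "n": total,
            "sensitivity": hit / total if total else np.nan,
            "cross_rate": cross / total if total else np.nan,
        }

    return {
        "convergent": tally("convergent", success_selections, clade_selections),
        "clade": tally("clade", clade_selections, success_selections),
    }


# --------------------------------------------------------------------------
# YAML configuration
# --------------------------------------------------------------------------

def config_from_yaml(path) -> SimConfig:
    """Build a SimConfig from a YAML file; unspecified fields keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimConfig()
    simple = {
        k: raw[k]
        for k in (
            "species_names", "tree_newick", "n_orthogroups", "paralog_rate",
            "missing_rate", "n_replicates", "diets", "control_diet",
            "baseline_logmean", "baseline_logsd", "dispersion_shape",
            "dispersion_rate", "library_factor_range", "effect_log2fc", "seed",
        )
        if k in raw
    }
    for k in ("species_names", "diets", "library_factor_range"):
        if k in simple:
            simple[k] = tuple(simple[k])
    if "effect_classes" in raw:
        simple["effect_classes"] = [
            EffectClass(
                kind=e["kind"], species=tuple(e["species"]), diet=e["diet"],
                count=int(e["count"]),
            )
            for e in raw["effect_classes"]
        ]
    if "feeding_params" in raw:
        params = dict(cfg.feeding_params)
        for e in raw["feeding_params"]:
            params[(e["species"], e["diet"])] = FeedingCell(
                mean_rate=float(e["mean_rate"]),
                sd_rate=float(e["sd_rate"]),
                mean_dev_days=float(e["mean_dev_days"]),
                n_larvae=int(e["n_larvae"]),
            )
        simple["feeding_params"] = params
    return replace(cfg, **simple)
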