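"""Significance-pattern selection: convergence vs shared evolutionary history.

An orthogroup whose member species of a "high herbivore success" group are all
significantly up-regulated on a host plant, while every other species with
data is non-significant, is a candidate convergence signal.  The same
predicate applied to phylogenetic clades instead captures expression shifts
attributable to shared ancestry.  When a success group's species set happens
to equal a clade (e.g. both Spodoptera species topping the maize ranking),
the two explanations cannot be separated and every shared orthogroup is
flagged as confounded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .trees import nontrivial_clades

#: conventional clade names for the default five-species topology
DEFAULT_CLADE_NAMES: dict[frozenset, str] = {
    frozenset({"S_exigua", "S_littoralis"}): "Spodoptera",
    frozenset({"S_exigua", "S_littoralis", "M_brassicae"}): "Noctuinae",
    frozenset({"T_ni", "A_gamma"}): "Plusiinae",
}


@dataclass(frozen=True)
class GroupSpec:
    """A named species set used for pattern selection."""

    name: str
    species: frozenset
    origin: str  # success | clade
    plants: tuple[str, ...] | None = None  # None = applicable to every plant

    def __post_init__(self):
        if len(self.species) < 2:
            raise ValueError("group must contain at least 2 species")
        if self.origin not in ("success", "clade"):
            raise ValueError(f"unknown group origin {self.origin!r}")


def clade_groups_from_tree(
    tree: dendropy.Tree, names: Mapping[frozenset, str] | None = None
) -> list[GroupSpec]:
    """All non-trivial clades (2 <= size < #leaves) as clade-origin groups."""
    if names is None:
        names = DEFAULT_CLADE_NAMES
    groups = []
    for leaves in nontrivial_clades(tree):
        name = names.get(leaves, "clade_" + "_".join(sorted(leaves)))
        groups.append(GroupSpec(name=name, species=leaves, origin="clade"))
    return groups


@dataclass
class SelectionEntry:
    """Outcome of applying the pattern predicate for one (group, plant)."""

    group: GroupSpec
    plant: str
    selected: list[str]
    alpha: float
    direction: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def select_pattern_ogs(
    meta: pd.DataFrame,
    group: GroupSpec,
    plant: str,
    species_universe: Iterable[str],
    alpha: float = 0.05,
    direction: str = "up",
    nonmember_rule: str = "two_sided",
    missing_policy: str = "lenient",
) -> SelectionEntry:
    """Apply the significance-pattern predicate over the meta table.

    An OG is selected iff (i) it is meta-significant (q <= FDR threshold);
    (ii) every group member has adjusted representative p <= ``alpha`` and a
    positive fold-change sign (for ``direction="up"``); and (iii) every
    non-member fails to reach significance: with ``nonmember_rule="two_sided"``
    any significant non-member (either direction) disqualifies the OG, with
    ``"up_only"`` only significant up-regulation does.  Non-members without
    data are skipped under ``missing_policy="lenient"`` and disqualify the OG
    under ``"strict"``.
    """
    universe = list(species_universe)
    if not group.species <= set(universe):
        raise ValueError(
            f"group {group.name} not a subset of the species universe"
        )
    members = sorted(group.species)
    nonmembers = [s for s in universe if s not in group.species]
    selected = []
    for og, r in meta.iterrows():
        if not bool(r["significant"]):
            continue
        ok = True
        for sp in members:
            p = r[f"p_adj_{sp}"]
            sgn = r[f"sign_{sp}"]
            if not np.isfinite(p) or p > alpha:
                ok = False
                break
            if direction == "up" and sgn <= 0:
                ok = False
                break
            if direction == "down" and sgn >= 0:
                ok = False
                break
        if not ok:
            continue
        for sp in nonmembers:
            p = r[f"p_adj_{sp}"]
            if not np.isfinite(p):
                if missing_policy == "strict":
                    ok = False
                    break
                continue
            if p <= alpha:
                if nonmember_rule == "two_sided" or (
                    nonmember_rule == "up_only" and r[f"sign_{sp}"] > 0
                ):
                    ok = False
                    break
        if ok:
            selected.append(og)
    return SelectionEntry(
        group=group,
        plant=plant,
        selected=selected,
        alpha=alpha,
        direction=direction,
        table=meta.loc[selected].copy(),
    )


def overlap_confound_report(
    success_selections: list[SelectionEntry],
    clade_selections: list[SelectionEntry],
) -> pd.DataFrame:
    """Per plant, intersect success- and clade-selected OG sets.

    Shared OGs between a success group and a clade with the *same* species set
    are flagged ``confounded`` — herbivore success and shared ancestry cannot
    be told apart there.
    """
    rows = []
    for s in success_selections:
        for c in clade_selections:
            if s.plant != c.plant:
                continue
            shared = sorted(set(s.selected) & set(c.selected))
            same_set = s.group.species == c.group.species
            for og in shared:
                rows.append(
                    {
                        "plant": s.plant,
                        "success_group": s.group.name,
                        "clade_group": c.group.name,
                        "og": og,
                        "confounded": same_set,
                    }
                )
    return pd.DataFrame(
        rows, columns=["plant", "success_group", "clade_group", "og", "confounded"]
    )


def confounded_ogs(report: pd.DataFrame) -> set[tuple[str, str]]:
    """(plant, og) pairs flagged as confounded."""
    if report.empty:
        return set()
    sub = report[report["confounded"]]
    return {(r.plant, r.og) for r in sub.itertuples(index=False)}


def count_annotations(
    selected_ogs: Iterable[str], annotations: Mapping[str, list[str]]
) -> pd.Series:
    """Multiset label counts over the selected OGs, descending; gaps counted
    under "unannotated"."""
    counter: Counter = Counter()
    for og in selected_ogs:
        labels = annotations.get(og) or []
        if not labels:
            counter["unannotated"] += 1
        else:
            counter.update(labels)
    items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series(
        [v for _, v in items], index=[k for k, _ in items], name="count", dtype=int
    )


def write_heatmap_table(
    selections: list[SelectionEntry],
    species_universe: Iterable[str],
    confound_report: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format table behind the selection heatmaps.

    One row per (plant, group, selected OG, species) with the per-species
    adjusted representative p, fold-change sign, membership and confound flag;
    deterministically ordered by (plant, group, og, species).
    """
    universe = sorted(species_universe)
    conf = confounded_ogs(confound_report) if confound_report is not None else set()
    rows = []
    for sel in sorted(selections, key=lambda s: (s.plant, s.group.name)):
        for og in sorted(sel.selected):
            r = sel.table.loc[og]
            for sp in universe:
                rows.append(
                    {
                        "plant": sel.plant,
                        "group": sel.group.name,
                        "og": og,
                        "species": sp,
                        "p_raw": r[f"p_raw_{sp}"],
                        "p_adj": r[f"p_adj_{sp}"],
                        "sign": int(r[f"sign_{sp}"]),
                        "meta_q": r["q"],
                        "significant": bool(r["significant"]),
                        "in_group": sp in sel.group.species,
                        "selected": True,
                        "confounded": (sel.plant, og) in conf,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "plant", "group", "og", "species", "p_raw", "p_adj", "sign",
            "meta_q", "significant", "in_group", "selected", "confounded",
        ],
    )
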