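"""Orthogroup tables, strict orthologs, and the cross-species fold-change matrix.

An orthogroup (OG) is a set of genes, across several species, descended from a
single gene in their last common ancestor; it may contain paralogs (several
genes from one species) and may lack some species entirely.  This module
consumes the tab-separated orthogroup dialect written by standard orthology
inference tools (header ``Orthogroup\\t<species...>``; one row per OG with
comma-separated gene lists, blank cell = species absent), extracts strict
one-to-one orthologs, assembles the cross-species log2 fold-change matrix, and
reads the phylogenetic signal off a hierarchical clustering of that matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


class OrthogroupParseError(ValueError):
    """Malformed orthogroup table (duplicate OG or gene id); carries a line number."""


@dataclass
class OrthogroupMap:
    """Orthogroup id -> (species -> gene-id list), with a fixed species universe."""

    groups: dict[str, dict[str, list[str]]]
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        self.species = tuple(self.species)

    def genes(self, og: str, sp: str) -> list[str]:
        return self.groups.get(og, {}).get(sp, [])

    def og_ids(self) -> list[str]:
        return list(self.groups)

    def validate(self) -> None:
        """Check gene-id uniqueness within each species and non-empty OGs."""
        seen: dict[str, set[str]] = {sp: set() for sp in self.species}
        for og, per_sp in self.groups.items():
            total = 0
            for sp, genes in per_sp.items():
                if sp not in seen:
                    raise ValueError(f"OG {og}: unknown species {sp!r}")
                for g in genes:
                    if g in seen[sp]:
                        raise ValueError(f"duplicate gene id {g!r} in species {sp}")
                    seen[sp].add(g)
                total += len(genes)
            if total == 0:
                raise ValueError(f"OG {og} has no genes")


def read_orthogroups(path) -> OrthogroupMap:
    """Parse an ``Orthogroups.tsv``-dialect file.

    Raises :class:`OrthogroupParseError` (with a 1-based line number) on a
    duplicate OG id or a duplicate gene id within a species.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise OrthogroupParseError("empty file (line 1): missing header")
    header = lines[0].split("\t")
    species = tuple(s.strip() for s in header[1:])
    groups: dict[str, dict[str, list[str]]] = {}
    seen_genes: dict[str, set[str]] = {sp: set() for sp in species}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        og = cells[0].strip()
        if og in groups:
            raise OrthogroupParseError(f"duplicate orthogroup id {og!r} at line {lineno}")
        per_sp: dict[str, list[str]] = {}
        for sp, cell in zip(species, cells[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()]
            for g in genes:
                if g in seen_genes[sp]:
                    raise OrthogroupParseError(
                        f"duplicate gene id {g!r} for species {sp} at line {lineno}"
                    )
                seen_genes[sp].add(g)
            if genes:
                per_sp[sp] = genes
        groups[og] = per_sp
    return OrthogroupMap(groups=groups, species=species)


def write_orthogroups(og_map: OrthogroupMap, path) -> None:
    """Write the tab-separated dialect; round-trips through :func:`read_orthogroups`."""
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(og_map.species) + "\n")
        for og in og_map.groups:
            cells = [", ".join(og_map.genes(og, sp)) for sp in og_map.species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def strict_orthologs(og_map: OrthogroupMap) -> set[str]:
    """OGs with exactly one gene in every species of the universe (one-to-one)."""
    return {
        og
        for og, per_sp in og_map.groups.items()
        if all(len(per_sp.get(sp, [])) == 1 for sp in og_map.species)
    }


@dataclass
class FCMatrix:
    """log2 fold-change matrix: rows = strict-ortholog OGs, columns = (species, contrast)."""

    values: pd.DataFrame
    col_meta: pd.DataFrame  # index = column labels; columns: species, diet, clade
    n_dropped: int = 0


def build_fc_matrix(
    og_map: OrthogroupMap,
    strict: set[str],
    de_results: Mapping[str, Mapping[str, pd.DataFrame]],
    contrasts: list[str] | None = None,
    clade_map: Mapping[str, str] | None = None,
) -> FCMatrix:
    """Assemble the strict-ortholog log2FC matrix from per-species DE tables.

    ``de_results[species][contrast]`` is a DataFrame indexed by gene id with a
    ``log2FC`` column.  Rows (OGs) whose gene lacks a fold change in any
    (species, contrast) cell — e.g. because the gene was abundance-filtered in
    that species — are dropped and counted in ``n_dropped``.
    """
    if contrasts is None:
        sp0 = og_map.species[0]
        contrasts = list(de_results[sp0])
    cols = [f"{sp}|{c}" for sp in og_map.species for c in contrasts]
    meta = pd.DataFrame(
        {
            "species": [c.split("|")[0] for c in cols],
            "diet": [c.split("|")[1] for c in cols],
        },
        index=cols,
    )
    meta["clade"] = [
        (clade_map or {}).get(sp, sp) for sp in meta["species"]
    ]
    rows = {}
    n_dropped = 0
    for og in sorted(strict):
        vals = []
        ok = True
        for sp in og_map.species:
            gene = og_map.genes(og, sp)[0]
            for c in contrasts:
                tab = de_results[sp][c]
                if gene in tab.index and np.isfinite(tab.at[gene, "log2FC"]):
                    vals.append(float(tab.at[gene, "log2FC"]))
                else:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            rows[og] = vals
        else:
            n_dropped += 1
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return FCMatrix(values=values, col_meta=meta, n_dropped=n_dropped)


@dataclass
class SignalReport:
    """Dendrogram reading of the fold-change matrix: diet signal vs clade signal."""

    verdict: str  # by_diet | by_clade | mixed
    diet_score: float
    clade_score: float
    linkage: np.ndarray
    columns: list[str]
    nearest: dict[str, str]
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "diet_score": float(self.diet_score),
            "clade_score": float(self.clade_score),
            "excluded_columns": list(self.excluded),
            "nearest_neighbor": dict(self.nearest),
        }


def fc_dendrogram_signal(fc: FCMatrix, margin: float = 0.2) -> SignalReport:
    """Cluster the FC-matrix columns and score diet vs clade concordance.

    Columns are clustered hierarchically (distance = 1 - Pearson correlation
    over OGs, complete linkage).  Each column's nearest neighbour under the
    cophenetic distance is found; the diet score is the fraction of columns
    whose nearest neighbour shares the diet, the clade score the fraction
    sharing the clade.  Verdict: ``by_diet`` when diet - clade >= ``margin``,
    ``by_clade`` when <= -``margin``, otherwise ``mixed``.
    """
    X = fc.values.to_numpy(dtype=float)
    cols = list(fc.values.columns)
    sd = X.std(axis=0)
    excluded = [c for c, s in zip(cols, sd) if s == 0.0]
    if excluded:
        warnings.warn(
            f"excluding zero-variance columns from signal clustering: {excluded}"
        )
        keep = [i for i, c in enumerate(cols) if c not in excluded]
        X = X[:, keep]
        cols = [cols[i] for i in keep]
    if len(cols) < 2:
        raise ValueError("need at least 2 usable columns for signal clustering")
    corr = np.corrcoef(X, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    coph = squareform(hierarchy.cophenet(Z))
    nearest: dict[str, str] = {}
    for i, c in enumerate(cols):
        d = coph[i].copy()
        d[i] = np.inf
        nearest[c] = cols[int(np.argmin(d))]  # argmin -> lowest index on ties
    meta = fc.col_meta
    diet_hits = sum(meta.at[c, "diet"] == meta.at[n, "diet"] for c, n in nearest.items())
    clade_hits = sum(
        meta.at[c, "clade"] == meta.at[n, "clade"] for c, n in nearest.items()
    )
    diet_score = diet_hits / len(cols)
    clade_score = clade_hits / len(cols)
    delta = diet_score - clade_score
    verdict = "by_diet" if delta >= margin else "by_clade" if delta <= -margin else "mixed"
    return SignalReport(
        verdict=verdict,
        diet_score=diet_score,
        clade_score=clade_score,
        linkage=Z,
        columns=cols,
        nearest=nearest,
        excluded=excluded,
    )
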