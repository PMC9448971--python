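"""Orthogroup-level cross-species meta-analysis of differential expression.

Each species contributes one representative p-value per orthogroup and
contrast: the smallest raw DE p-value among its paralogs in the group.  The
minimum of m uniform p-values is Beta(1, m)-distributed, so the representative
is corrected to 1 - (1 - p)^m before species are combined Fisher-style
(X2 = -2 sum ln p, chi-square with 2k df over the k contributing species).
Benjamini-Hochberg FDR is then applied once, across orthogroups within the
contrast; orthogroups with data from fewer than two species are excluded from
the FDR and reported with a missing combined p.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .orthogroups import OrthogroupMap

P_FLOOR = 1e-300  # zero p-values are floored before taking logs
FDR_ALPHA = 0.05


def representative_p(
    og_map: OrthogroupMap, og: str, species: str, de_table: pd.DataFrame
) -> tuple[float, int, int] | None:
    """(min raw p, paralog count m, sign of the argmin gene's log2FC), or None.

    Only the species' genes that appear in ``de_table`` with a defined p-value
    count; an absent species (or one whose genes were all filtered out)
    yields None — missingness is data, not an error.
    """
    genes = [g for g in og_map.genes(og, species) if g in de_table.index]
    ps = []
    for g in genes:
        p = de_table.at[g, "pvalue"]
        if np.isfinite(p):
            ps.append((float(p), g))
    if not ps:
        return None
    p_min, g_min = min(ps, key=lambda t: t[0])  # ties -> first gene in OG order
    sign = int(np.sign(de_table.at[g_min, "log2FC"]))
    return p_min, len(ps), sign


def adjust_min_p(p_min: float, m: int) -> float:
    """Order-statistic correction: distribution of the min of m uniform p-values."""
    if m < 1:
        raise ValueError("paralog count m must be >= 1")
    if not (0.0 <= p_min <= 1.0):
        raise ValueError("p_min must be in [0, 1]")
    return 1.0 - (1.0 - p_min) ** m


def fisher_combine(pvalues: list[float]) -> tuple[float, int, float]:
    """Fisher's method: (X2 = -2 sum ln p, df = 2k, combined upper-tail p)."""
    if len(pvalues) < 2:
        raise ValueError("need >= 2 p-values to combine")
    p = np.maximum(np.asarray(pvalues, dtype=float), P_FLOOR)
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    return x2, df, float(stats.chi2.sf(x2, df))


def run_meta(
    og_map: OrthogroupMap,
    de_results: Mapping[str, Mapping[str, pd.DataFrame]],
    contrast: str,
    adjust_paralogs: bool = True,
    fdr_alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Full per-orthogroup meta-analysis for one plant-vs-control contrast.

    Returns a wide DataFrame indexed by OG with per-species columns
    ``p_raw_<sp>``, ``m_<sp>``, ``p_adj_<sp>``, ``sign_<sp>`` plus ``k``,
    ``X2``, ``df``, ``p_comb``, ``q`` and ``significant`` (q <= ``fdr_alpha``).
    ``adjust_paralogs=False`` skips the order-statistic correction (sensitivity
    analysis; anti-conservative for paralog-rich orthogroups).
    """
    rows = {}
    for og in og_map.og_ids():
        row: dict[str, float] = {}
        adjusted = []
        k = 0
        for sp in og_map.species:
            rep = (
                representative_p(og_map, og, sp, de_results[sp][contrast])
                if sp in de_results and contrast in de_results[sp]
                else None
            )
            if rep is None:
                row[f"p_raw_{sp}"] = np.nan
                row[f"m_{sp}"] = 0
                row[f"p_adj_{sp}"] = np.nan
                row[f"sign_{sp}"] = 0
                continue
            p_min, m, sign = rep
            p_adj = adjust_min_p(p_min, m) if adjust_paralogs else p_min
            row[f"p_raw_{sp}"] = p_min
            row[f"m_{sp}"] = m
            row[f"p_adj_{sp}"] = p_adj
            row[f"sign_{sp}"] = sign
            adjusted.append(p_adj)
            k += 1
        row["k"] = k
        if k >= 2:
            x2, df, p_comb = fisher_combine(adjusted)
            row["X2"], row["df"], row["p_comb"] = x2, df, p_comb
        else:
            row["X2"], row["df"], row["p_comb"] = np.nan, 2 * k, np.nan
        rows[og] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "og"
    combinable = table["k"] >= 2
    q = np.full(len(table), np.nan)
    q[combinable.to_numpy()] = bh_adjust(table.loc[combinable, "p_comb"].to_numpy())
    table["q"] = q
    table["significant"] = (table["q"] <= fdr_alpha).fillna(False)
    return table


def meta_long(table: pd.DataFrame, species: tuple[str, ...], contrast: str) -> pd.DataFrame:
    """Long form of the wide meta table: one row per (og, species)."""
    rows = []
    for og, r in table.iterrows():
        for sp in species:
            rows.append(
                {
                    "og": og,
                    "contrast": contrast,
                    "species": sp,
                    "p_raw": r[f"p_raw_{sp}"],
                    "m": int(r[f"m_{sp}"]),
                    "p_adj": r[f"p_adj_{sp}"],
                    "sign": int(r[f"sign_{sp}"]),
                    "X2": r["X2"],
                    "df": int(r["df"]),
                    "p_comb": r["p_comb"],
                    "q": r["q"],
                    "significant": bool(r["significant"]),
                }
            )
    return pd.DataFrame(rows)
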