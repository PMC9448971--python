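"""Larval performance: growth rates, rank tests, control normalization, groups.

Herbivore success is proxied by the larval growth rate (third-instar weight in
mg divided by development time in days).  Diet and species differences are
tested with a Kruskal-Wallis omnibus test followed by Dunn's pairwise post-hoc
test with Bonferroni adjustment; per-plant growth is expressed as the percent
deviation from the species' artificial-diet (control) mean; and candidate
"high herbivore success" species groups (size >= 2) are enumerated per plant
by a deterministic rule over the pairwise significance pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def growth_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Per species x diet growth-rate summaries.

    ``records`` needs columns species, diet, weight_mg, dev_days.  The rate per
    larva is weight / dev_days; the summary holds n, mean and sample SD (n-1
    denominator; reported as 0 with ``single_larva`` flag when n = 1).
    """
    req = {"species", "diet", "weight_mg", "dev_days"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if (records["dev_days"] <= 0).any():
        raise ValueError("dev_days must be strictly positive")
    if (records["weight_mg"] <= 0).any():
        raise ValueError("weight_mg must be strictly positive")
    df = records.copy()
    df["rate"] = df["weight_mg"] / df["dev_days"]
    rows = []
    for (sp, diet), grp in df.groupby(["species", "diet"], sort=True):
        n = len(grp)
        rows.append(
            {
                "species": sp,
                "diet": diet,
                "n": n,
                "mean_rate": float(grp["rate"].mean()),
                "sd_rate": float(grp["rate"].std(ddof=1)) if n > 1 else 0.0,
                "single_larva": n == 1,
            }
        )
    return pd.DataFrame(rows)


def per_larva_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Records with an added per-larva ``rate`` column (mg/day)."""
    df = records.copy()
    df["rate"] = df["weight_mg"] / df["dev_days"]
    return df


@dataclass
class PairwiseTestResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise z / p / Bonferroni-adjusted p."""

    grouping: str
    kw_h: float
    kw_p: float
    pairs: pd.DataFrame  # columns: a, b, z, p_raw, p_adj
    method: str = "asymptotic"

    def p_adj_lookup(self) -> dict[frozenset, float]:
        return {
            frozenset((r.a, r.b)): r.p_adj for r in self.pairs.itertuples(index=False)
        }


def _kw_statistic(values: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(values, return_counts=True)
    tie = 1.0 - (t ** 3 - t).sum() / (n ** 3 - n) if n > 1 else 1.0
    return h / tie if tie > 0 else 0.0


def _exact_kw_p(values: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p for the KW statistic by full enumeration of label
    assignments (small samples only)."""
    n = len(values)
    if n > 12:
        raise ValueError("exact Kruskal-Wallis enumeration limited to n <= 12")
    h_obs = _kw_statistic(values, labels)
    uniq = sorted(np.unique(labels))
    sizes = [int((labels == g).sum()) for g in uniq]
    idx = list(range(n))
    count = 0
    total = 0
    for assign in _multiset_assignments(idx, sizes):
        lab = np.empty(n, dtype=object)
        for g, members in zip(uniq, assign):
            for m in members:
                lab[m] = g
        total += 1
        if _kw_statistic(values, lab) >= h_obs - 1e-12:
            count += 1
    return count / total


def _multiset_assignments(items: list, sizes: list[int]):
    """Yield all partitions of ``items`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(items),)
        return
    first = sizes[0]
    for combo in itertools.combinations(items, first):
        rest = [x for x in items if x not in combo]
        for tail in _multiset_assignments(rest, sizes[1:]):
            yield (combo,) + tail


def kruskal_dunn(
    records: pd.DataFrame,
    grouping: str,
    value: str = "rate",
    method: str = "asymptotic",
) -> PairwiseTestResult:
    """Kruskal-Wallis omnibus + Dunn pairwise post-hoc with Bonferroni.

    ``grouping`` names the factor column (species or diet).  Dunn z statistics
    use rank sums over the pooled sample with tie-corrected variance; raw
    two-sided p-values are Bonferroni-multiplied by the number of pairs
    (capped at 1).  ``method="exact"`` replaces the omnibus chi-square p with a
    full-enumeration permutation p (small n only).
    """
    df = records.dropna(subset=[grouping, value])
    groups = sorted(df[grouping].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = df[value].to_numpy(dtype=float)
    labels = df[grouping].to_numpy()
    n = len(values)
    samples = [values[labels == g] for g in groups]
    if np.ptp(values) == 0:
        kw_h, kw_p = 0.0, 1.0  # every value tied: no evidence of difference
    else:
        kw_h, kw_p = stats.kruskal(*samples)
    if method == "exact":
        kw_p = _exact_kw_p(values, labels)
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    ranks = stats.rankdata(values)
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    _, t = np.unique(values, return_counts=True)
    tie_term = (t ** 3 - t).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "a": a,
                "b": b,
                "z": float(z),
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, p_raw * len(pairs))),
            }
        )
    return PairwiseTestResult(
        grouping=grouping,
        kw_h=float(kw_h),
        kw_p=float(kw_p),
        pairs=pd.DataFrame(rows),
        method=method,
    )


def normalize_to_control(
    summaries: pd.DataFrame, control_diet: str = "control"
) -> pd.DataFrame:
    """Fill ``normalized_pct``: percent deviation from the species' control mean.

    The artificial diet is treated as the neutral, toxin-free baseline; a
    species' performance on a plant is 100 x (mean - control mean) / control
    mean.  Control rows get NaN (the quantity is undefined there).
    """
    out = summaries.copy()
    control = {
        r.species: r.mean_rate
        for r in out[out["diet"] == control_diet].itertuples(index=False)
    }
    pct = []
    for r in out.itertuples(index=False):
        if r.diet == control_diet:
            pct.append(np.nan)
            continue
        cm = control.get(r.species)
        if cm is None:
            raise ValueError(f"no control-diet summary for species {r.species!r}")
        if cm <= 0:
            raise ValueError(f"non-positive control mean for species {r.species!r}")
        pct.append(100.0 * (r.mean_rate - cm) / cm)
    out["normalized_pct"] = pct
    return out


@dataclass
class SuccessGroups:
    """Candidate high-herbivore-success species sets per plant diet."""

    plant: str
    groups: list[frozenset[str]]
    provenance: str = "rule"  # rule | user

    def as_lists(self) -> list[list[str]]:
        return [sorted(g) for g in self.groups]


def candidate_success_groups(
    normalized: pd.DataFrame,
    pairwise: PairwiseTestResult,
    plant: str,
    alpha: float = 0.05,
    user_groups: list[set[str]] | None = None,
) -> SuccessGroups:
    """Enumerate candidate success groups for one plant.

    Deterministic rule over the normalized growth ranking and the cross-species
    Dunn significance matrix (adjusted p > ``alpha`` = "not different"):

    1. rank species by normalized_pct descending;
    2. base group = top species plus every species not significantly different
       from it;
    3. a singleton base is extended with the next-ranked species;
    4. each outside species not significantly different from the lowest-ranked
       base member yields an additional candidate (base + that species).

    User-supplied groups (each of size >= 2) bypass the rule entirely.
    """
    if user_groups is not None:
        groups = []
        for g in user_groups:
            if len(g) < 2:
                raise ValueError("user-supplied groups must have size >= 2")
            groups.append(frozenset(g))
        return SuccessGroups(plant=plant, groups=groups, provenance="user")

    sub = normalized[normalized["diet"] == plant]
    if len(sub) < 2:
        raise ValueError(f"need at least 2 species with data on {plant!r}")
    ranked = list(
        sub.sort_values(["normalized_pct", "species"], ascending=[False, True])[
            "species"
        ]
    )
    padj = pairwise.p_adj_lookup()

    def not_different(a: str, b: str) -> bool:
        return padj.get(frozenset((a, b)), 0.0) > alpha

    top = ranked[0]
    base = [top] + [s for s in ranked[1:] if not_different(s, top)]
    if len(base) == 1:
        base.append(ranked[1])
    base_set = frozenset(base)
    lowest = max(base, key=lambda s: ranked.index(s))
    groups = [base_set]
    for s in ranked:
        if s in base_set:
            continue
        if not_different(s, lowest):
            cand = base_set | {s}
            if cand not in groups:
                groups.append(cand)
    return SuccessGroups(plant=plant, groups=groups, provenance="rule")
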