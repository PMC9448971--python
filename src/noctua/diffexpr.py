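"""Per-species differential expression and expression-profile clustering.

Counts are modelled as negative binomial with Var = mu + phi * mu^2.  The DE
engine is a deliberately small two-group NB Wald test: median-of-ratios size
factors, method-of-moments gene-wise dispersion (floored), per-group mean fit
by Newton iteration on the NB log-likelihood with a log link, and a two-sided
Wald p on the log2 fold change — referred to a t distribution with the
residual degrees of freedom to account for the dispersion being estimated
from few replicates — BH-adjusted across tested genes.  It has no
dispersion or fold-change shrinkage, so its numbers are close to, but not
bit-identical with, heavier DE packages; externally produced DE tables with
the same columns can be substituted anywhere downstream.

The module also carries the abundance filter (>= 10 counts in >= 2 samples),
CPM/TMM normalization, DE-gene gating (|log2FC| >= 2 and padj <= 1e-3 in at
least one contrast), hierarchical clustering of DE-gene profiles with a cut at
50% of the maximum merge height, and diet-specific cluster labelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)

#: minimum per-gene NB dispersion (phi); avoids degenerate Poisson-only fits
MIN_DISPERSION = 1e-8

#: DE gene gate: fold change >= 4 in either direction, FDR <= 1e-3
MIN_ABS_LOG2FC = 2.0
MAX_PADJ = 1e-3

#: a cluster is diet-specific when its top diet mean exceeds the runner-up by
#: this much on the centered log2 scale (~1.5-fold), boundary inclusive
DIET_MARGIN = 0.58


def filter_min_counts(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 2
) -> pd.DataFrame:
    """Keep genes with >= ``min_count`` counts in >= ``min_samples`` samples."""
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (sequencing depth + composition).

    Reference value per gene = geometric mean across samples; genes with a
    zero anywhere are excluded from the reference set; the factor of a sample
    is the median ratio of its counts to the reference.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no reference genes: every gene has a zero count somewhere")
    ref = mat[nonzero]
    log_geo = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    return counts / lib * 1e6


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values cross-sample scaling factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  For each sample, per-gene M (log2
    ratio of depth-scaled counts to the reference) and A (mean log2 abundance)
    values are computed over genes expressed in both; the most extreme 30% of
    M and 5% of A are trimmed from each tail; the factor is 2 to the
    precision-weighted mean of the surviving M values.  Factors are rescaled
    so their product is 1.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    frac = mat / lib
    q75 = np.array([np.quantile(frac[:, j][mat[:, j] > 0], 0.75) if (mat[:, j] > 0).any() else 0 for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        ok = (mat[:, j] > 0) & (mat[:, ref] > 0)
        if ok.sum() < 2:
            continue
        y, r = mat[ok, j], mat[ok, ref]
        pj, pr = y / lib[j], r / lib[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (lib[j] - y) / (lib[j] * y) + (lib[ref] - r) / (lib[ref] * r)
        n = len(M)
        loM, hiM = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        loA, hiA = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rM = stats.rankdata(M, method="ordinal")
        rA = stats.rankdata(A, method="ordinal")
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.sum() == 0 or w[keep].min() <= 0:
            continue
        factors[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm_tmm(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """CPM matrix on TMM-adjusted effective library sizes, plus the factors."""
    factors = tmm_factors(counts)
    lib = counts.sum(axis=0).to_numpy(dtype=float) * factors.to_numpy()
    return counts / lib * 1e6, factors


# --------------------------------------------------------------------------
# negative-binomial Wald differential expression
# --------------------------------------------------------------------------

def _mom_dispersion(
    q: np.ndarray, inv_f: np.ndarray, group_idx: list[np.ndarray]
) -> np.ndarray:
    """Gene-wise method-of-moments dispersion from normalized counts ``q``.

    Within each group: Var(q) ~= mean(q) * mean(1/f) + phi * mean(q)^2.  The
    per-group estimates are df-weighted and floored at MIN_DISPERSION.
    """
    n_genes = q.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for idx in group_idx:
        if len(idx) < 2:
            continue
        qg = q[:, idx]
        m = qg.mean(axis=1)
        s2 = qg.var(axis=1, ddof=1)
        c = np.mean(inv_f[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (s2 - m * c) / np.square(m)
        phi_g = np.where(m > 0, phi_g, 0.0)
        w = len(idx) - 1
        num += w * np.nan_to_num(phi_g)
        den += w
    phi = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return np.maximum(phi, MIN_DISPERSION)


def _fit_group_mean(
    y: np.ndarray, f: np.ndarray, phi: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve of the NB log-link MLE for a single group, vectorized over genes.

    Model: y_s ~ NB(mean = f_s * m, dispersion phi).  Returns (log m, Fisher
    information of log m).  All-zero genes are treated as half a count.
    """
    tot = y.sum(axis=1)
    fsum = f.sum()
    m0 = np.where(tot > 0, tot / fsum, 0.5 / fsum)
    beta = np.log(m0)
    for _ in range(n_iter):
        m = np.exp(beta)
        mu = f[None, :] * m[:, None]
        denom = 1.0 + phi[:, None] * mu
        U = ((y - mu) / denom).sum(axis=1)
        J = (mu * (1.0 + phi[:, None] * y) / denom**2).sum(axis=1)
        step = U / np.maximum(J, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    m = np.exp(beta)
    mu = f[None, :] * m[:, None]
    info = (mu / (1.0 + phi[:, None] * mu)).sum(axis=1)
    return beta, info


def nb_wald_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: str,
    control: str = "control",
    size_factors: pd.Series | None = None,
    min_row_sum: int = 2,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression: ``contrast`` diet vs control.

    ``samples`` must carry sample/diet columns covering the count matrix's
    columns.  Size factors default to median-of-ratios computed on the full
    matrix passed in.  Genes whose total count across the two groups is below
    ``min_row_sum`` are excluded from testing.  Returns a DataFrame indexed by
    gene: baseMean, log2FC, lfcSE, pvalue, padj.
    """
    smap = samples.set_index("sample")["diet"]
    missing = [c for c in counts.columns if c not in smap.index]
    if missing:
        raise ValueError(f"samples table lacks entries for {missing}")
    for cond in (contrast, control):
        if not (smap.loc[list(counts.columns)] == cond).any():
            raise ValueError(f"condition {cond!r} absent from samples")
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    cols_t = [c for c in counts.columns if smap[c] == contrast]
    cols_c = [c for c in counts.columns if smap[c] == control]
    if len(cols_t) < 2 or len(cols_c) < 2:
        raise ValueError("need >= 2 replicates per condition")
    sub = counts[cols_c + cols_t]
    f = size_factors[cols_c + cols_t].to_numpy(dtype=float)
    y = sub.to_numpy(dtype=float)
    tested = y.sum(axis=1) >= min_row_sum
    y = y[tested]
    genes = sub.index[tested]

    idx_c = np.arange(len(cols_c))
    idx_t = np.arange(len(cols_c), len(cols_c) + len(cols_t))
    q = y / f[None, :]
    phi = _mom_dispersion(q, 1.0 / f, [idx_c, idx_t])

    beta_c, info_c = _fit_group_mean(y[:, idx_c], f[idx_c], phi)
    beta_t, info_t = _fit_group_mean(y[:, idx_t], f[idx_t], phi)
    log2fc = (beta_t - beta_c) / LOG2
    se = np.sqrt(1.0 / np.maximum(info_c, 1e-12) + 1.0 / np.maximum(info_t, 1e-12)) / LOG2
    z = np.where(se > 0, log2fc / se, 0.0)
    # Wald statistic referred to a t distribution with the residual degrees of
    # freedom: the plug-in dispersion is estimated from very few replicates and
    # a normal reference is badly anti-conservative at n = 3 + 3
    dof = len(cols_c) + len(cols_t) - 2
    pval = 2.0 * stats.t.sf(np.abs(z), dof)
    padj = bh_adjust(pval)
    return pd.DataFrame(
        {
            "baseMean": q.mean(axis=1),
            "log2FC": log2fc,
            "lfcSE": se,
            "pvalue": pval,
            "padj": padj,
        },
        index=pd.Index(genes, name="gene"),
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_all_contrasts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    species: str,
    control: str = "control",
    apply_filter: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run every plant-vs-control contrast for one species."""
    ssub = samples[samples["species"] == species]
    cols = [c for c in counts.columns if c in set(ssub["sample"])]
    mat = counts[cols]
    if apply_filter:
        mat = filter_min_counts(mat)
    sf = size_factors_median_of_ratios(mat)
    diets = [d for d in ssub["diet"].unique() if d != control]
    return {
        d: nb_wald_de(mat, ssub, d, control=control, size_factors=sf)
        for d in sorted(diets)
    }


def select_de_genes(
    results: Mapping[str, pd.DataFrame],
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
    max_padj: float = MAX_PADJ,
) -> set[str]:
    """Genes passing |log2FC| >= 2 and padj <= 1e-3 in at least one contrast."""
    selected: set[str] = set()
    for tab in results.values():
        hit = (tab["log2FC"].abs() >= min_abs_log2fc) & (tab["padj"] <= max_padj)
        selected |= set(tab.index[hit])
    return selected


# --------------------------------------------------------------------------
# expression-profile clustering of DE genes
# --------------------------------------------------------------------------

@dataclass
class ExpressionClusterSet:
    labels: pd.Series  # gene -> cluster id (1-based)
    profiles: pd.DataFrame  # cluster x sample mean centered-log2 profile
    diet_labels: dict[int, str]  # cluster -> diet or "none"


def center_log2(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), then subtract each gene's median (focus on pattern, not level)."""
    lg = np.log2(expr + 1.0)
    return lg.sub(lg.median(axis=1), axis=0)


def cluster_de_genes(centered: pd.DataFrame, cut_fraction: float = 0.5) -> pd.Series:
    """Hierarchical clustering of gene profiles, cut at 50% of max merge height.

    Distance = 1 - Pearson correlation of the centered profiles, complete
    linkage.  Genes are processed in id order so the partition is independent
    of input row order; zero-variance profiles are treated as uncorrelated
    with everything (distance 1).
    """
    genes = sorted(centered.index)
    if len(genes) == 0:
        raise ValueError("no genes to cluster")
    if len(genes) == 1:
        return pd.Series([1], index=genes, name="cluster")
    X = centered.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    cut = cut_fraction * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    # renumber clusters by first appearance in gene-id order
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return pd.Series(labels, index=genes, name="cluster")


def cluster_profiles(centered: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster mean centered-log2 profile over samples."""
    prof = centered.loc[labels.index].groupby(labels).mean()
    prof.index.name = "cluster"
    return prof


def diet_specific_clusters(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    margin: float = DIET_MARGIN,
) -> dict[int, str]:
    """Label each cluster with the diet it is specifically up-regulated on.

    A cluster is labelled for diet d iff its mean centered-log2 expression
    averaged over d's samples is positive and exceeds the runner-up diet
    average by at least ``margin`` (boundary inclusive); otherwise "none".
    """
    smap = samples.set_index("sample")["diet"]
    diets = sorted(smap.loc[list(profiles.columns)].unique())
    out: dict[int, str] = {}
    for cl in profiles.index:
        means = {
            d: profiles.loc[cl, [c for c in profiles.columns if smap[c] == d]].mean()
            for d in diets
        }
        ordered = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
        (d1, v1), (_, v2) = ordered[0], ordered[1]
        out[int(cl)] = d1 if (v1 > 0 and v1 - v2 >= margin - 1e-12) else "none"
    return out


def cluster_pipeline(
    norm_expr: pd.DataFrame,
    de_genes: set[str],
    samples: pd.DataFrame,
) -> ExpressionClusterSet:
    """Cluster the DE genes of one species and label diet-specific clusters."""
    sub = norm_expr.loc[sorted(de_genes & set(norm_expr.index))]
    centered = center_log2(sub)
    labels = cluster_de_genes(centered)
    profiles = cluster_profiles(centered, labels)
    diet_labels = diet_specific_clusters(profiles, samples)
    return ExpressionClusterSet(labels=labels, profiles=profiles, diet_labels=diet_labels)
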