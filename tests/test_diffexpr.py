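"""Differential expression: filtering, normalization, NB Wald, clustering."""

import numpy as np
import pandas as pd
import pytest

from noctua import (
    bh_adjust,
    cluster_de_genes,
    cpm_tmm,
    diet_specific_clusters,
    filter_min_counts,
    nb_wald_de,
    select_de_genes,
    size_factors_median_of_ratios,
    tmm_factors,
)
from noctua.diffexpr import center_log2, cluster_profiles


def _mat(rows, columns=None):
    df = pd.DataFrame(rows)
    df.index = [f"g{i}" for i in range(len(df))]
    if columns:
        df.columns = columns
    return df


class TestFilterMinCounts:
    def test_boundary_rules(self):
        counts = _mat(
            [
                [10, 10, 0, 0],   # retained: two samples at the threshold
                [9, 500, 0, 0],   # removed: only one sample >= 10
                [0, 0, 0, 0],     # removed: all zero
                [11, 12, 13, 0],  # retained
            ]
        )
        kept = filter_min_counts(counts)
        assert list(kept.index) == ["g0", "g3"]


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = _mat([[5, 5, 5], [9, 9, 9], [100, 100, 100]])
        assert np.allclose(size_factors_median_of_ratios(counts), 1.0)

    def test_doubled_sample_hand_computation(self):
        """Two samples, second exactly twice the first: factors (1/sqrt2, sqrt2)."""
        base = np.array([10, 20, 50, 100, 7])
        counts = _mat(np.column_stack([base, 2 * base]))
        f = size_factors_median_of_ratios(counts)
        assert f.iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert f.iloc[1] == pytest.approx(np.sqrt(2))

    def test_gene_with_zero_excluded_from_reference(self):
        base = np.array([10, 20, 50])
        counts = _mat(np.column_stack([base, 2 * base]))
        counts.loc["g3"] = [1000, 0]  # would skew the median if not excluded
        f = size_factors_median_of_ratios(counts)
        assert f.iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_no_reference_genes_is_an_error(self):
        counts = _mat([[0, 5], [5, 0]])
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(counts)


def _tmm_oracle(counts, ref_j, j):
    """Straight-line re-derivation of the trimmed weighted M-mean for sample j."""
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    ok = (mat[:, j] > 0) & (mat[:, ref_j] > 0)
    y, r = mat[ok, j], mat[ok, ref_j]
    M = np.log2((y / lib[j]) / (r / lib[ref_j]))
    A = 0.5 * np.log2((y / lib[j]) * (r / lib[ref_j]))
    w = (lib[j] - y) / (lib[j] * y) + (lib[ref_j] - r) / (lib[ref_j] * r)
    n = len(M)
    order_m = np.argsort(np.argsort(M, kind="stable"), kind="stable") + 1
    order_a = np.argsort(np.argsort(A, kind="stable"), kind="stable") + 1
    keep = (
        (order_m >= np.floor(n * 0.3) + 1)
        & (order_m <= n - np.floor(n * 0.3))
        & (order_a >= np.floor(n * 0.05) + 1)
        & (order_a <= n - np.floor(n * 0.05))
    )
    return 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))


class TestTMM:
    def test_identical_samples_unit_factors(self):
        counts = _mat(np.tile(np.arange(1, 21)[:, None], (1, 4)))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_removed(self):
        rng = np.random.default_rng(1)
        base = rng.integers(5, 500, size=50)
        counts = _mat(np.column_stack([base, 3 * base]))
        f = tmm_factors(counts)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_constructed_shift_matches_independent_recompute(self):
        """20 genes, 4 strongly up-shifted in sample 2: the factor equals an
        independent straight-line recompute of the trim-and-weight formula."""
        rng = np.random.default_rng(7)
        base = rng.integers(50, 400, size=20)
        shifted = base.copy()
        shifted[:4] = shifted[:4] * 8
        counts = _mat(np.column_stack([base, shifted]))
        f = tmm_factors(counts)
        raw = _tmm_oracle(counts, 0, 1)  # sample 1's q75 fraction is nearest the mean
        expected = np.array([1.0, raw])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f.to_numpy(), expected)

    def test_cpm_tmm_zero_library_rejected(self):
        counts = _mat([[0, 5], [0, 7]])
        with pytest.raises(ValueError):
            cpm_tmm(counts)


def _samples_for(columns, species="sp"):
    rows = []
    for c in columns:
        diet, rep = c.rsplit("_r", 1)
        rows.append({"sample": c, "species": species, "diet": diet,
                     "replicate": int(rep)})
    return pd.DataFrame(rows)


def _two_group_counts(rng, n_genes, mean, phi, fold, n_rep=3, n_null=0):
    """NB counts for a two-group design; the first n_genes rows carry the fold
    change, the remaining n_null rows are unchanged background."""
    cols = [f"control_r{i}" for i in range(1, n_rep + 1)] + [
        f"plant_r{i}" for i in range(1, n_rep + 1)
    ]
    mu = np.full((n_genes + n_null, 2 * n_rep), float(mean))
    mu[:n_genes, n_rep:] *= fold
    n_param = 1.0 / phi
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    return pd.DataFrame(
        counts, index=[f"g{i}" for i in range(n_genes + n_null)], columns=cols
    )


class TestNBWald:
    def test_identical_groups_give_zero_log2fc(self):
        counts = _mat(
            np.tile([[20, 30, 40, 20, 30, 40]], (5, 1)),
            columns=["control_r1", "control_r2", "control_r3",
                     "plant_r1", "plant_r2", "plant_r3"],
        )
        sf = pd.Series(1.0, index=counts.columns)
        res = nb_wald_de(counts, _samples_for(counts.columns), "plant",
                         size_factors=sf)
        assert np.allclose(res["log2FC"], 0.0, atol=1e-8)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(5)
        counts = _two_group_counts(rng, 2000, mean=200, phi=0.1, fold=1.0)
        res = nb_wald_de(counts, _samples_for(counts.columns), "plant")
        frac = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= frac <= 0.08

    def test_planted_fourfold_recovered(self):
        """500 four-fold genes in a mostly-null background: median estimated
        log2FC of the planted genes is 2 within tolerance."""
        rng = np.random.default_rng(6)
        counts = _two_group_counts(rng, 500, mean=500, phi=0.01, fold=4.0,
                                   n_null=1500)
        res = nb_wald_de(counts, _samples_for(counts.columns), "plant")
        planted = res.loc[[f"g{i}" for i in range(500)], "log2FC"]
        assert abs(float(planted.median()) - 2.0) <= 0.2

    def test_missing_condition_rejected(self):
        counts = _mat([[5, 6], [7, 8]], columns=["control_r1", "control_r2"])
        with pytest.raises(ValueError):
            nb_wald_de(counts, _samples_for(counts.columns), "plant")


def _bh_oracle(p):
    """Quadratic-time step-up: q_i = min over j with p_j >= p_i of n*p_j/rank_j."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, n * p[i] / rank_from_top)
        q[i] = min(running, 1.0)
    return q


class TestBH:
    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for n in (1, 5, 100, 1000):
            p = rng.uniform(size=n)
            assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)
        p = np.round(rng.uniform(size=300), 2)  # heavy ties
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


class TestSelectDEGenes:
    def test_gate_boundaries(self):
        tab = pd.DataFrame(
            {
                "log2FC": [2.1, 2.1, -2.5, 1.9],
                "padj": [5e-4, 2e-3, 1e-5, 1e-6],
            },
            index=["a", "b", "c", "d"],
        )
        got = select_de_genes({"plant": tab})
        assert got == {"a", "c"}  # b fails FDR, d fails fold change


class TestClustering:
    def test_two_anticorrelated_blocks_cut_into_two_clusters(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        rows = [x + 0.01 * i for i in range(4)] + [-x + 0.01 * i for i in range(4)]
        centered = pd.DataFrame(rows, index=[f"g{i}" for i in range(8)])
        labels = cluster_de_genes(centered)
        assert labels.nunique() == 2
        assert len(set(labels.iloc[:4])) == 1 and len(set(labels.iloc[4:])) == 1

    def test_single_gene_is_one_cluster(self):
        centered = pd.DataFrame([[0.1, -0.1, 0.0]], index=["g0"])
        labels = cluster_de_genes(centered)
        assert list(labels) == [1]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        centered = pd.DataFrame(
            rng.normal(size=(20, 12)), index=[f"g{i:02d}" for i in range(20)]
        )
        base = cluster_de_genes(centered)
        shuffled = cluster_de_genes(centered.sample(frac=1.0, random_state=9))
        pd.testing.assert_series_equal(base, shuffled)


class TestDietSpecificClusters:
    def _profiles(self, maize, others):
        cols = [f"{d}_r{i}" for d in ("B_oleracea", "N_tabacum", "Z_mays", "control")
                for i in (1, 2, 3)]
        vals = [maize if c.startswith("Z_mays") else others for c in cols]
        return pd.DataFrame([vals], index=pd.Index([1], name="cluster"), columns=cols)

    def _samples(self, profiles):
        return _samples_for(profiles.columns)

    def test_strong_maize_cluster_labelled(self):
        prof = self._profiles(2.0, 0.0)
        assert diet_specific_clusters(prof, self._samples(prof)) == {1: "Z_mays"}

    def test_flat_cluster_is_none(self):
        prof = self._profiles(0.0, 0.0)
        assert diet_specific_clusters(prof, self._samples(prof)) == {1: "none"}

    def test_margin_boundary_inclusive(self):
        prof = self._profiles(0.58, 0.0)
        assert diet_specific_clusters(prof, self._samples(prof)) == {1: "Z_mays"}
        prof2 = self._profiles(0.57, 0.0)
        assert diet_specific_clusters(prof2, self._samples(prof2)) == {1: "none"}


def test_center_log2_profiles_roundtrip():
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(rng.integers(0, 100, size=(6, 4)).astype(float),
                        index=[f"g{i}" for i in range(6)])
    centered = center_log2(expr)
    assert np.allclose(centered.median(axis=1), 0.0)
    labels = cluster_de_genes(centered)
    prof = cluster_profiles(centered, labels)
    assert prof.shape[1] == expr.shape[1]


def test_planted_diet_specific_clusters_recovered():
    """Genes planted up-regulated on one diet (log2FC 2.5) end up in clusters
    labelled with that diet for >= 80% of the selected genes."""
    from noctua.diffexpr import cluster_pipeline, de_all_contrasts

    rng = np.random.default_rng(19)
    diets = ["B_oleracea", "N_tabacum", "Z_mays", "control"]
    cols = [f"sp_{d}_r{i}" for d in diets for i in (1, 2, 3)]
    samples = pd.DataFrame(
        {"sample": cols, "species": "sp",
         "diet": [c.split("_r")[0][3:] for c in cols],
         "replicate": [int(c[-1]) for c in cols]}
    )
    n_per, fold = 25, 2.0 ** 2.5
    mu = np.full((3 * n_per + 75, 12), 500.0)
    for b, d in enumerate(diets[:3]):
        idx = [j for j, c in enumerate(cols) if f"_{d}_" in c]
        mu[np.ix_(range(b * n_per, (b + 1) * n_per), idx)] *= fold
    counts = pd.DataFrame(
        rng.negative_binomial(50.0, 50.0 / (50.0 + mu)),  # dispersion 0.02
        index=[f"g{i:03d}" for i in range(mu.shape[0])], columns=cols,
    )
    de = de_all_contrasts(counts, samples, "sp")
    genes = select_de_genes(de)
    assert len(genes) >= 20
    norm, _ = cpm_tmm(filter_min_counts(counts))
    cs = cluster_pipeline(norm, genes, samples)
    truth = {f"g{i:03d}": diets[i // n_per] for i in range(3 * n_per)}
    planted = [g for g in genes if g in truth]
    hits = sum(cs.diet_labels[cs.labels[g]] == truth[g] for g in planted)
    assert hits / len(planted) >= 0.8
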