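"""Integration metrics against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crossvae import (
    asw_batch,
    batch_strength_unintegrated,
    condition_mixing,
    generate,
    ilisi,
    jaccard_per_type,
    knn_graph,
    leiden_majority_relabel,
    majority_relabel,
    morans_i,
    morans_i_ratio,
    nmi_fixed,
    preset,
    scale_and_overall,
    select_best_setting,
)
from crossvae.metrics import EmbeddingView, gene_group_heterogeneity


def _ring_graph(n):
    """Each node connected to its two ring neighbours, row-normalised."""
    rows, cols = [], []
    for i in range(n):
        rows += [i, i]
        cols += [(i - 1) % n, (i + 1) % n]
    return sp.csr_matrix((np.full(2 * n, 0.5), (rows, cols)), shape=(n, n))


class TestIlisi:
    def test_pure_neighbourhoods_score_zero(self):
        # two distant clusters, one per label
        emb = np.vstack([np.random.default_rng(0).normal(0, 0.1, (20, 2)),
                         np.random.default_rng(1).normal(100, 0.1, (20, 2))])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        assert ilisi(emb, labels, k_neighbors=10) == pytest.approx(0.0)

    def test_exact_fifty_fifty_neighbourhoods_score_one(self):
        # constructed graph where every cell's neighbours split 50/50
        n = 8
        labels = np.array(["a", "b"] * (n // 2))
        graph = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        # neighbourhood of each cell: 3 same-label, 4 other-label -> not exact.
        # Build exact balance instead: neighbours = 2 of each label.
        rows, cols = [], []
        for i in range(n):
            same = [j for j in range(n) if j != i and labels[j] == labels[i]][:2]
            other = [j for j in range(n) if labels[j] != labels[i]][:2]
            for j in same + other:
                rows.append(i)
                cols.append(j)
        graph = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        assert ilisi(None, labels, graph=graph) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(60, 3))
        labels = rng.choice(["x", "y", "z"], 60)
        renamed = np.array({"x": "1", "y": "2", "z": "0"}[l] for l in labels)
        renamed = np.array([{"x": "1", "y": "2", "z": "0"}[l] for l in labels])
        assert ilisi(emb, labels, 15) == pytest.approx(ilisi(emb, renamed, 15))

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="two label"):
            ilisi(np.random.default_rng(0).normal(size=(10, 2)), np.array(["a"] * 10))

    def test_matches_bruteforce_simpson_on_random_graph(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(40, 4))
        labels = rng.choice(["a", "b", "c"], 40)
        k = 7
        got = ilisi(emb, labels, k)
        # brute force: neighbour lists from pairwise distances
        d = np.linalg.norm(emb[:, None] - emb[None], axis=2)
        np.fill_diagonal(d, np.inf)
        vals = []
        for i in range(40):
            nbrs = np.argsort(d[i])[:k]
            p = np.array([(labels[nbrs] == c).mean() for c in ("a", "b", "c")])
            vals.append((1.0 / (p**2).sum() - 1) / 2)
        assert got == pytest.approx(np.mean(vals))


class TestClusterRelabel:
    def test_separable_blobs_recover_truth_exactly(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(10, 0.3, (40, 2))])
        truth = np.array(["t0"] * 40 + ["t1"] * 40)
        derived = leiden_majority_relabel(emb, truth, resolution=2.0, seed=0)
        assert np.array_equal(derived, truth)
        assert nmi_fixed(derived, truth) == pytest.approx(1.0)

    def test_majority_vote_tie_breaks_to_lowest_label(self):
        clusters = np.array(["c1", "c1", "c1", "c1"])
        truth = np.array(["zeta", "alpha", "zeta", "alpha"])
        assert list(majority_relabel(clusters, truth)) == ["alpha"] * 4

    def test_leiden_seed_is_respected(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(120, 4))
        truth = rng.choice(["a", "b"], 120)
        d1 = leiden_majority_relabel(emb, truth, seed=5)
        d2 = leiden_majority_relabel(emb, truth, seed=5)
        assert np.array_equal(d1, d2)


class TestNmiJaccard:
    def test_identical_labelings_nmi_one(self):
        labels = np.array(["a", "b", "a", "c"])
        assert nmi_fixed(labels, labels) == pytest.approx(1.0)

    def test_single_cluster_nmi_zero(self):
        derived = np.array(["x"] * 8)
        truth = np.array(["a", "b"] * 4)
        assert nmi_fixed(derived, truth) == pytest.approx(0.0)

    def test_contingency_matches_entropy_oracle(self):
        # contingency [[3,1],[1,3]]
        derived = np.array(["d0"] * 4 + ["d1"] * 4)
        truth = np.array(["t0"] * 3 + ["t1"] + ["t0"] + ["t1"] * 3)

        def H(p):
            p = np.asarray(p, float)
            p = p[p > 0]
            return -(p * np.log(p)).sum()

        pj = np.array([[3, 1], [1, 3]]) / 8.0
        mi = sum(
            pj[i, j] * np.log(pj[i, j] / (pj[i].sum() * pj[:, j].sum()))
            for i in range(2)
            for j in range(2)
        )
        oracle = mi / ((H([0.5, 0.5]) + H([0.5, 0.5])) / 2)
        assert nmi_fixed(derived, truth) == pytest.approx(oracle)

    def test_jaccard_perfect_and_missing(self):
        truth = np.array(["a", "a", "b", "b"])
        assert jaccard_per_type(truth, truth) == {"a": 1.0, "b": 1.0}
        derived = np.array(["a", "a", "a", "a"])
        assert jaccard_per_type(derived, truth)["b"] == 0.0

    def test_jaccard_one_third(self):
        # intersection 1, union 3 for type a
        truth = np.array(["a", "a", "b"])
        derived = np.array(["a", "b", "a"])
        assert jaccard_per_type(derived, truth)["a"] == pytest.approx(1 / 3)


class TestASW:
    def test_separated_batches_score_high(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 0.05, (30, 2)), rng.normal(5, 0.05, (30, 2))])
        batch = np.array(["b0"] * 30 + ["b1"] * 30)
        ct = np.array(["t"] * 60)
        assert asw_batch(emb, batch, ct) > 0.9

    def test_identically_distributed_batches_score_near_zero(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(200, 2))
        batch = np.array(["b0", "b1"] * 100)
        ct = np.array(["t"] * 200)
        assert abs(asw_batch(emb, batch, ct)) < 0.1

    def test_coincident_points_score_zero_by_convention(self):
        # zero-width silhouette: a(i) = b(i) = 0 for every cell
        emb = np.ones((20, 2))
        batch = np.array(["b0"] * 10 + ["b1"] * 10)
        ct = np.array(["t"] * 20)
        assert asw_batch(emb, batch, ct) == pytest.approx(0.0)

    def test_single_batch_type_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(40, 2))
        batch = np.array(["b0"] * 20 + ["b0"] * 10 + ["b1"] * 10)
        ct = np.array(["only_b0"] * 20 + ["mixed"] * 20)
        with pytest.warns(UserWarning, match="only_b0"):
            val = asw_batch(emb, batch, ct)
        assert np.isfinite(val)


class TestMoransI:
    def test_constant_vector_nan_with_warning(self):
        g = _ring_graph(6)
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(morans_i(np.ones(6), g))

    def test_four_cycle_checkerboard_is_minus_one(self):
        g = _ring_graph(4)
        assert morans_i(np.array([1.0, -1.0, 1.0, -1.0]), g) == pytest.approx(-1.0)

    def test_smooth_ring_signal_is_positive(self):
        n = 30
        vals = np.sin(np.linspace(0, 2 * np.pi, n, endpoint=False))
        assert morans_i(vals, _ring_graph(n)) > 0.5

    def test_permutation_null_expectation(self):
        rng = np.random.default_rng(0)
        n = 40
        g = _ring_graph(n)
        x = rng.normal(size=n)
        null = [morans_i(rng.permutation(x), g) for _ in range(800)]
        assert np.mean(null) == pytest.approx(-1.0 / (n - 1), abs=0.01)

    def test_matches_formula_on_random_graph(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(25, 3))
        w = knn_graph(emb, 4)
        x = rng.normal(size=25)
        xc = x - x.mean()
        expected = (25 / w.sum()) * (xc @ (w @ xc)) / (xc**2).sum()
        assert morans_i(x, w) == pytest.approx(expected)


@pytest.fixture(scope="module")
def grad_ds():
    from crossvae import preprocess

    ds, _ = generate(preset("gradient_rich", n_cells_total=900, n_genes=150, seed=6))
    return preprocess(ds, min_cells=3)


class TestMoransIRatio:

    def test_identity_embedding_gives_exactly_one(self, grad_ds):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(grad_ds.n_cells, 10))
        rep = morans_i_ratio(grad_ds, emb, pre_embedding=emb, min_cells=30)
        assert rep.ratio == pytest.approx(1.0)
        assert np.allclose(rep.per_group["mi_pre"], rep.per_group["mi_post"])

    def test_within_group_shuffling_lowers_ratio(self, grad_ds):
        rng = np.random.default_rng(1)
        from sklearn.decomposition import PCA

        x = grad_ds.dense()
        emb = PCA(n_components=10, random_state=0).fit_transform(
            (x - x.mean(0)) / (x.std(0) + 1e-8)
        )
        shuffled = emb.copy()
        for ct in np.unique(grad_ds.cell_type):
            for smp in np.unique(grad_ds.sample):
                idx = np.flatnonzero((grad_ds.cell_type == ct) & (grad_ds.sample == smp))
                shuffled[idx] = shuffled[rng.permutation(idx)]
        r_same = morans_i_ratio(grad_ds, emb, pre_embedding=emb, min_cells=30).ratio
        r_shuf = morans_i_ratio(grad_ds, shuffled, pre_embedding=emb, min_cells=30).ratio
        assert r_shuf < r_same - 0.2

    def test_gene_count_clamp_respected(self, grad_ds):
        rep = morans_i_ratio(
            grad_ds,
            np.random.default_rng(2).normal(size=(grad_ds.n_cells, 5)),
            min_cells=30,
            keep_genes=(5, 12),
        )
        counts = rep.per_group.groupby(["cell_type", "sample"], observed=True)["gene"].count()
        assert counts.between(5, 12).all()

    def test_doublet_types_excluded(self, grad_ds):
        import dataclasses

        labelled = dataclasses.replace(
            grad_ds,
            cell_type=np.where(grad_ds.cell_type == "type0", "type0+type1", grad_ds.cell_type),
        )
        rep = morans_i_ratio(
            labelled, np.random.default_rng(0).normal(size=(grad_ds.n_cells, 5)), min_cells=30
        )
        assert not any("+" in ct for ct in rep.per_group["cell_type"])

    def test_no_qualifying_group_raises(self, grad_ds):
        with pytest.raises(ValueError, match="at least"):
            morans_i_ratio(grad_ds, np.zeros((grad_ds.n_cells, 3)), min_cells=10_000)


class TestOverallScore:
    def test_dominant_run_scores_one(self):
        runs = pd.DataFrame(
            {
                "morans_i_ratio": [0.9, 0.5],
                "nmi_fixed": [0.8, 0.2],
                "ilisi": [0.7, 0.1],
            }
        )
        out = scale_and_overall(runs)
        assert out["overall"].iloc[0] == pytest.approx(1.0)

    def test_worked_weighting_example(self):
        """scaled MoransI 0.8, NMI 0.6, iLISI 0.5 -> 0.6*0.7 + 0.4*0.5 = 0.62."""
        runs = pd.DataFrame(
            {
                "morans_i_ratio": [0.0, 0.8, 1.0],
                "nmi_fixed": [0.0, 0.6, 1.0],
                "ilisi": [0.0, 0.5, 1.0],
            }
        )
        out = scale_and_overall(runs)
        assert out["overall"].iloc[1] == pytest.approx(0.62)

    def test_degenerate_metric_scales_to_zero(self):
        runs = pd.DataFrame(
            {
                "morans_i_ratio": [0.5, 0.5],
                "nmi_fixed": [0.3, 0.7],
                "ilisi": [0.2, 0.9],
            }
        )
        out = scale_and_overall(runs)
        assert (out["morans_i_ratio_scaled"] == 0.0).all()


class TestBestSetting:
    def _table(self):
        return pd.DataFrame(
            {
                "value": [1.0, 1.0, 1.0, 5.0, 5.0, 5.0],
                "seed": [0, 1, 2, 0, 1, 2],
                "overall": [0.2, 0.5, 0.9, 0.3, 0.4, 0.35],
            }
        )

    def test_best_setting_by_mean_overall(self):
        setting, rep = select_best_setting(self._table(), ["value"])
        assert setting == {"value": 1.0}  # mean 0.533 > 0.35

    def test_representative_is_median_run(self):
        _, rep = select_best_setting(self._table(), ["value"])
        assert rep["overall"] == 0.5

    def test_dominating_setting_selected(self):
        df = self._table()
        df.loc[df["value"] == 5.0, "overall"] = [0.95, 0.96, 0.97]
        setting, rep = select_best_setting(df, ["value"])
        assert setting == {"value": 5.0}
        assert rep["overall"] == 0.96


class TestBatchStrength:
    def test_strong_system_shift_detected(self):
        from crossvae import preprocess

        ds, _ = generate(
            preset("balanced_two_system", n_cells_total=1200, n_genes=150, seed=8)
        )
        table = batch_strength_unintegrated(
            preprocess(ds, min_cells=3), min_cells=20, min_samples_per_system=3
        )
        assert (table["mean_between"] > table["mean_within"]).all()
        assert (table["p_value"] < 0.05).all()

    def test_no_shift_not_significant(self):
        from crossvae import preprocess

        ds, _ = generate(
            preset(
                "balanced_two_system",
                n_cells_total=1200,
                n_genes=150,
                seed=9,
                system_shift_scale=0.0,
                system_type_interaction_scale=0.0,
            )
        )
        table = batch_strength_unintegrated(
            preprocess(ds, min_cells=3), min_cells=20, min_samples_per_system=3
        )
        assert (table["p_value"] > 0.1).all()

    def test_no_qualifying_type_raises(self):
        from crossvae import preprocess

        ds, _ = generate(preset("balanced_two_system", n_cells_total=300, n_genes=80, seed=1))
        with pytest.raises(ValueError, match="qualifies"):
            batch_strength_unintegrated(preprocess(ds, min_cells=3), min_cells=10_000)


class TestConditionMixing:
    def test_mixed_and_separated_extremes(self):
        rng = np.random.default_rng(0)
        n = 80
        system = np.array(["s0", "s1"] * (n // 2))
        emb = np.zeros((n, 2))
        # first half: systems interleaved at identical coordinates (mixed)
        emb[: n // 2] = np.repeat(rng.normal(size=(n // 4, 2)), 2, axis=0)
        # second half: systems far apart (separated)
        emb[n // 2 :] = rng.normal(size=(n // 2, 2))
        emb[n // 2 :][system[n // 2 :] == "s1"] += 500.0
        similar = np.arange(n) < n // 2
        dissimilar = ~similar
        s, d = condition_mixing(emb, system, similar, dissimilar, k_neighbors=6)
        assert s > 0.8
        assert d == pytest.approx(0.0)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            condition_mixing(
                np.zeros((4, 2)),
                np.array(["a", "b", "a", "b"]),
                np.array([True, False, False, False]),
                np.array([False, True, True, True]),
            )


class TestGeneGroupHeterogeneity:
    def test_identical_embedding_gives_identical_scores(self):
        from crossvae import preprocess

        ds, truth = generate(preset("gradient_rich", n_cells_total=600, n_genes=150, seed=5))
        dsp = preprocess(ds, min_cells=3)
        prog = truth.gradient_programs[0]
        genes = [g for g in (f"g{i}" for i in prog.genes) if g in dsp.gene_ids]
        emb = np.random.default_rng(0).normal(size=(dsp.n_cells, 6))
        mask = dsp.cell_type == prog.cell_type
        out1 = gene_group_heterogeneity(dsp, emb, {"prog": genes}, mask=mask)
        out2 = gene_group_heterogeneity(dsp, emb, {"prog": genes}, mask=mask)
        assert out1 == out2

    def test_missing_genes_rejected(self):
        from crossvae import preprocess

        ds, _ = generate(preset("balanced_two_system", n_cells_total=200, n_genes=50, seed=0))
        dsp = preprocess(ds, min_cells=3)
        with pytest.raises(ValueError, match="absent"):
            gene_group_heterogeneity(
                dsp, np.zeros((dsp.n_cells, 3)), {"bad": ["not_a_gene"]}
            )


def test_knn_graph_row_normalised_excludes_self():
    emb = np.random.default_rng(0).normal(size=(30, 3))
    g = knn_graph(emb, 5)
    assert np.allclose(np.asarray(g.sum(axis=1)).ravel(), 1.0)
    assert g.diagonal().sum() == 0.0


def test_embedding_view_subsample_records_seed():
    rng = np.random.default_rng(0)
    view = EmbeddingView(embedding=rng.normal(size=(50, 2)), system=np.array(["a"] * 50))
    sub = view.subsample(max_cells=10, seed=3)
    assert len(sub.embedding) == 10
    assert sub.subsample_seed == 3
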