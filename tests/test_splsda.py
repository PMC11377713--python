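"""(Sparse) PLS-DA: components, sparsity, variance, networks, prediction."""

import numpy as np
import pytest

from triomics.factor_eval import evaluate_factor
from triomics.io import (MultiOmicsSet, OmicsBlock, PeptideEntry, PeptideMap,
                         SampleAnnotation, TargetMap)
from triomics.simulate import SimConfig, simulate_multiomics
from triomics.splsda import (SimilarityEdge, assemble_network,
                             cross_block_similarity, explained_variance,
                             fit_block_splsda, fit_plsda, fit_splsda, predict)


def _block(vals, name="custom"):
    vals = np.asarray(vals, dtype=float)
    return OmicsBlock(name, [f"{name}_f{i}" for i in range(vals.shape[0])],
                      [f"S{j:02d}" for j in range(vals.shape[1])], vals)


def _labels(n1, n2):
    return ["a"] * n1 + ["b"] * n2


def _clouds(rng, n1=12, n2=10, p=10, sep=4.0, noise=0.5):
    X = rng.normal(scale=noise, size=(p, n1 + n2))
    X[:3, :n1] += sep / 2
    X[:3, n1:] -= sep / 2
    return _block(X), _labels(n1, n2)


class TestPlsda:
    def test_separated_clouds_component1_classifies_perfectly(self, rng):
        b, lab = _clouds(rng)
        m = fit_plsda(b, lab, ncomp=2)
        sc = evaluate_factor(m.scores["custom"][:, 0], lab, n_runs=100, seed=0)
        assert sc.mean_accuracy == 1.0

    def test_loadings_unit_norm(self, rng):
        b, lab = _clouds(rng)
        m = fit_plsda(b, lab, ncomp=3)
        norms = np.linalg.norm(m.loadings["custom"], axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-8)

    def test_scores_orthogonal_under_regression_deflation(self, rng):
        b, lab = _clouds(rng, p=15)
        m = fit_plsda(b, lab, ncomp=4)
        T = m.scores["custom"]
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).max()

    def test_rank1_data_one_component_explains_everything(self, rng):
        t = rng.normal(size=12)
        w = rng.normal(size=6)
        b = _block(np.outer(w, t))
        m = fit_plsda(b, _labels(6, 6), ncomp=1)
        assert m.explained_variance["custom"][0] > 99.0

    def test_ncomp_above_rank_rejected(self, rng):
        b = _block(rng.normal(size=(3, 8)))
        with pytest.raises(ValueError):
            fit_plsda(b, _labels(4, 4), ncomp=5)

    def test_component1_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        b, lab = _clouds(rng, p=12)
        m = fit_plsda(b, lab, ncomp=2)
        Y = np.stack([(np.array(lab) == lv).astype(float) for lv in ("a", "b")],
                     axis=1)
        pls = PLSRegression(n_components=2, scale=True).fit(b.values.T, Y)
        c = abs(np.corrcoef(m.scores["custom"][:, 0], pls.x_scores_[:, 0])[0, 1])
        assert c > 0.999


class TestSplsda:
    def test_full_keepx_reduces_to_plsda(self, rng):
        b, lab = _clouds(rng, p=14)
        dense = fit_plsda(b, lab, ncomp=3)
        sparse = fit_splsda(b, lab, ncomp=3, keepX=[14, 14, 14])
        for h in range(3):
            c = abs(np.corrcoef(dense.scores["custom"][:, h],
                                sparse.scores["custom"][:, h])[0, 1])
            assert c > 0.999

    def test_keepx_counts_exact(self, rng):
        b, lab = _clouds(rng, p=20)
        m = fit_splsda(b, lab, ncomp=3, keepX=[5, 2, 20])
        nz = (m.loadings["custom"] != 0).sum(axis=0)
        assert nz.tolist() == [5, 2, 20]

    def test_planted_informative_features_selected(self, rng):
        b, lab = _clouds(rng, p=12, sep=6.0, noise=0.3)
        # features 0-2 carry the separation; keepX=2 must pick among them
        m = fit_splsda(b, lab, ncomp=1, keepX=[2])
        nz = np.where(m.loadings["custom"][:, 0] != 0)[0]
        assert set(nz) <= {0, 1, 2} and len(nz) == 2

    def test_keepx_below_one_rejected(self, rng):
        b, lab = _clouds(rng)
        with pytest.raises(ValueError):
            fit_splsda(b, lab, ncomp=1, keepX=[0])


def _two_block_set(rng, n1=12, n2=10, p1=15, p2=18, sep=4.0):
    n = n1 + n2
    f = np.concatenate([np.full(n1, sep / 2), np.full(n2, -sep / 2)])
    f = f + 0.3 * rng.normal(size=n)
    X1 = 0.4 * rng.normal(size=(p1, n))
    X2 = 0.4 * rng.normal(size=(p2, n))
    X1[:4] += np.outer(rng.uniform(0.8, 1.2, 4), f)
    X2[:5] += np.outer(rng.uniform(0.8, 1.2, 5), f)
    samples = [f"S{j:02d}" for j in range(n)]
    lab = _labels(n1, n2)
    blocks = [OmicsBlock("miRNome", [f"m{i}" for i in range(p1)], samples, X1),
              OmicsBlock("peptidome", [f"p{i}" for i in range(p2)], samples, X2)]
    return MultiOmicsSet(blocks, SampleAnnotation(dict(zip(samples, lab))))


class TestBlockSplsda:
    def test_identical_blocks_share_scores(self, rng):
        ms = _two_block_set(rng)
        X = ms.blocks[0].values
        twin = MultiOmicsSet(
            [ms.blocks[0],
             OmicsBlock("copy", [f"c{i}" for i in range(X.shape[0])],
                        ms.sample_ids, X.copy())], ms.labels)
        m = fit_block_splsda(twin, ncomp=2)
        c = abs(np.corrcoef(m.scores["miRNome"][:, 0], m.scores["copy"][:, 0])[0, 1])
        assert c > 0.999

    def test_design_weight_zero_decouples_to_single_block(self, rng):
        ms = _two_block_set(rng)
        m = fit_block_splsda(ms, ncomp=1, design_weight=0.0)
        for b in ms.blocks:
            single = fit_splsda(b, ms.labels.groups, ncomp=1)
            c = abs(np.corrcoef(m.scores[b.omics_name][:, 0],
                                single.scores[b.omics_name][:, 0])[0, 1])
            assert c > 0.99

    def test_default_five_components_with_keepx_schedule(self):
        mset, _ = simulate_multiomics(SimConfig(seed=11))
        sub = MultiOmicsSet([mset.block("miRNome"), mset.block("peptidome")],
                            mset.labels)
        keepX = {"miRNome": [50, 20, None, None, None],
                 "peptidome": [50, 10, None, None, None]}
        m = fit_block_splsda(sub, ncomp=5, keepX=keepX)
        assert m.ncomp == 5
        nz_m = (m.loadings["miRNome"] != 0).sum(axis=0).tolist()
        nz_p = (m.loadings["peptidome"] != 0).sum(axis=0).tolist()
        assert nz_m == [50, 20, 100, 100, 100]
        assert nz_p == [50, 10, 400, 400, 400]

    def test_single_block_rejected(self, rng):
        ms = _two_block_set(rng)
        solo = MultiOmicsSet([ms.blocks[0]], ms.labels)
        with pytest.raises(ValueError):
            fit_block_splsda(solo, ncomp=1)


class TestExplainedVariance:
    def test_sums_to_100_over_full_rank(self, rng):
        b, lab = _clouds(rng, n1=6, n2=6, p=4)
        m = fit_plsda(b, lab, ncomp=4)
        assert m.explained_variance["custom"].sum() == pytest.approx(100.0,
                                                                     abs=0.1)

    def test_matches_direct_variance_ratio_oracle(self, rng):
        b, lab = _clouds(rng, n1=6, n2=6, p=4)
        m = fit_plsda(b, lab, ncomp=3)
        X0 = m.X0["custom"]
        total = np.sum(X0 ** 2)
        X = X0.copy()
        for h in range(3):
            t = m.scores["custom"][:, h]
            p_load = X.T @ t / (t @ t)
            rec = np.outer(t, p_load)
            ratio = 100.0 * np.sum(rec ** 2) / total
            assert m.explained_variance["custom"][h] == pytest.approx(
                ratio, abs=1e-6)
            X = X - rec

    def test_table_has_cumulative(self, rng):
        b, lab = _clouds(rng)
        tab = explained_variance(fit_plsda(b, lab, ncomp=2))
        assert list(tab.columns) == ["block", "component", "explained_pct",
                                     "cumulative_pct"]
        assert tab["cumulative_pct"].iloc[-1] >= tab["explained_pct"].iloc[-1]


class TestCrossBlockSimilarity:
    def test_feature_equal_to_mean_score_has_similarity_one(self, rng):
        ms = _two_block_set(rng)
        m = fit_block_splsda(ms, ncomp=1)
        tbar = 0.5 * (m.scores["miRNome"][:, 0] + m.scores["peptidome"][:, 0])
        # implant the averaged score as a feature in both blocks
        X1 = np.vstack([ms.blocks[0].values, tbar])
        X2 = np.vstack([ms.blocks[1].values, tbar])
        blocks = [OmicsBlock("miRNome", [*ms.blocks[0].feature_ids, "mt"],
                             ms.sample_ids, X1),
                  OmicsBlock("peptidome", [*ms.blocks[1].feature_ids, "pt"],
                             ms.sample_ids, X2)]
        ms2 = MultiOmicsSet(blocks, ms.labels)
        m2 = fit_block_splsda(ms2, ncomp=1)
        tbar2 = 0.5 * (m2.scores["miRNome"][:, 0] + m2.scores["peptidome"][:, 0])
        edges = cross_block_similarity(m2, ncomp_used=1, threshold=0.95,
                                       selected_only=False)
        pair = [e for e in edges if e.feature_i == "mt" and e.feature_j == "pt"]
        c1 = np.corrcoef(X1[-1], tbar2)[0, 1]
        assert pair and pair[0].similarity == pytest.approx(c1 * c1, abs=1e-9)

    def test_matches_direct_formula_oracle(self, rng):
        ms = _two_block_set(rng, p1=5, p2=5)
        m = fit_block_splsda(ms, ncomp=2)
        edges = cross_block_similarity(m, ncomp_used=2, threshold=0.0,
                                       selected_only=False)
        tbar = 0.5 * (m.scores["miRNome"] + m.scores["peptidome"])
        for e in edges[:10]:
            i = m.feature_ids["miRNome"].index(e.feature_i)
            j = m.feature_ids["peptidome"].index(e.feature_j)
            x = m.X0["miRNome"][:, i]
            z = m.X0["peptidome"][:, j]
            sim = sum(np.corrcoef(x, tbar[:, h])[0, 1] *
                      np.corrcoef(z, tbar[:, h])[0, 1] for h in range(2))
            assert e.similarity == pytest.approx(sim, abs=1e-9)

    def test_threshold_one_empty_on_noise(self, rng):
        ms = _two_block_set(rng)
        m = fit_block_splsda(ms, ncomp=2)
        assert cross_block_similarity(m, threshold=1.0) == []

    def test_single_block_model_rejected(self, rng):
        b, lab = _clouds(rng)
        with pytest.raises(ValueError):
            cross_block_similarity(fit_plsda(b, lab, ncomp=1))

    def test_planted_pairs_dominate_edges(self):
        """In a low-noise regime the 0.80-threshold edges connect planted
        informative cross-block pairs with precision >= 0.8; at default
        noise any surviving edge still links planted features."""
        for cfg, thr in ((SimConfig(seed=2, noise_sd=0.25, effect_size=4.0), 0.80),
                         (SimConfig(seed=2), 0.80)):
            mset, truth = simulate_multiomics(cfg)
            sub = MultiOmicsSet([mset.block("miRNome"),
                                 mset.block("peptidome")], mset.labels)
            m = fit_block_splsda(sub, ncomp=2,
                                 keepX={"miRNome": [50, 20], "peptidome": [50, 10]})
            edges = cross_block_similarity(m, ncomp_used=1, threshold=thr)
            if not edges:
                continue
            inf_m = truth.informative["miRNome"]
            inf_p = truth.informative["peptidome"]
            good = sum(1 for e in edges
                       if e.feature_i in inf_m and e.feature_j in inf_p)
            assert good / len(edges) >= 0.8


class TestAssembleNetwork:
    def test_empty_similarity_keeps_knowledge_edges_only(self):
        net = assemble_network([], target_map=TargetMap({"m1": {"G1"}}),
                               peptide_map=None)
        assert net.empty  # no involved miRNAs -> nothing to attach

    def test_toy_counts_by_hand(self):
        edges = [SimilarityEdge("m1", "miRNome", "p1", "peptidome", 0.9, 1)]
        tm = TargetMap({"m1": {"G1", "G2"}})
        pm = PeptideMap({"p1": PeptideEntry("P9", "G9")})
        net = assemble_network(edges, target_map=tm, peptide_map=pm)
        assert net["type"].value_counts().to_dict() == {
            "similarity": 1, "mirna_target": 2, "peptide_protein": 1}

    def test_alignment_fallback_exact_substring(self):
        edges = [SimilarityEdge("m1", "miRNome", "ACDEFGHIK", "peptidome",
                                0.95, 1)]
        prot = {"PROT1": "MMMACDEFGHIKWWW", "PROT2": "QQQQQQQQQQQQ"}
        net = assemble_network(edges, protein_sequences=prot)
        pp = net[net["type"] == "peptide_protein"]
        assert pp.iloc[0]["target"] == "PROT1"
        assert pp.iloc[0]["weight"] == pytest.approx(1.0)


class TestPredict:
    def test_training_samples_classified_correctly(self, rng):
        ms = _two_block_set(rng, sep=6.0)
        m = fit_block_splsda(ms, ncomp=2)
        pred = predict(m, {n: ms.block(n).values.T for n in m.block_names})
        truth = [ms.labels.groups[s] for s in ms.sample_ids]
        agree = np.mean([p == t for p, t in zip(pred, truth)])
        assert agree == 1.0
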