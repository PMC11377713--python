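"""Joint factorization methods: recovery, monotonicity, symmetry, adapters."""

import numpy as np
import pytest

from triomics.io import MultiOmicsSet, OmicsBlock, SampleAnnotation
from triomics.jdr import (fit_jica, fit_jnmf, fit_mfa, load_factorization,
                          run_all, save_factorization)
from triomics.preprocess import standardize


def _mset(mats, labels=None, names=None):
    n = mats[0].shape[1]
    samples = [f"S{j:02d}" for j in range(n)]
    if labels is None:
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
    names = names or [f"block{i}" for i in range(len(mats))]
    blocks = [OmicsBlock(nm, [f"{nm}_f{i}" for i in range(m.shape[0])],
                         samples, m) for nm, m in zip(names, mats)]
    return MultiOmicsSet(blocks, SampleAnnotation(dict(zip(samples, labels))))


class TestJnmf:
    def test_exact_nonnegative_rank2_recovery(self, rng):
        W = rng.uniform(0.5, 2.0, size=(30, 2))
        F = rng.uniform(0.5, 2.0, size=(12, 2))
        X = W @ F.T
        ms = _mset([X])
        fz = fit_jnmf(ms, k=2, max_iter=3000, tol=1e-12, seed=0)
        rec = fz.W["block0"] @ fz.F.T
        rel = np.linalg.norm(X - rec) / np.linalg.norm(X)
        assert rel < 1e-3

    def test_objective_nonincreasing(self, fzs42):
        fz = next(f for f in fzs42 if f.method == "jnmf")
        tr = np.asarray(fz.objective_trace)
        assert np.all(np.diff(tr) <= 1e-10 * tr[:-1])

    def test_single_block_matches_minimal_nmf_oracle(self, rng):
        """Joint NMF on one block is plain NMF: compare against an
        independent multiplicative-update oracle at matched seed/iterations."""
        X = rng.uniform(0.0, 3.0, size=(20, 10))
        ms = _mset([X])
        iters = 150
        fz = fit_jnmf(ms, k=2, max_iter=iters, tol=0.0, seed=3)

        r = np.random.default_rng(3)
        F = r.uniform(0.1, 1.0, size=(10, 2))
        W = r.uniform(0.1, 1.0, size=(20, 2))
        for _ in range(iters):
            W *= (X @ F) / (W @ (F.T @ F) + 1e-12)
            F *= (X.T @ W) / (F @ (W.T @ W) + 1e-12)
        obj_oracle = float(np.sum((X - W @ F.T) ** 2))
        assert fz.objective_trace[-1] == pytest.approx(obj_oracle, rel=0.02)

    def test_k_too_large_rejected(self, rng):
        ms = _mset([rng.uniform(size=(5, 8))])
        with pytest.raises(ValueError):
            fit_jnmf(ms, k=6)


class TestMfa:
    def test_single_block_equals_pca(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(40, 15))
        ms = _mset([X])
        fz = fit_mfa(ms, k=2)
        pcs = PCA(n_components=2).fit_transform(standardize(ms.blocks[0]).values.T)
        for j in range(2):
            c = abs(np.corrcoef(fz.F[:, j], pcs[:, j])[0, 1])
            assert c > 0.999

    def test_duplicate_blocks_keep_single_block_factors(self, rng):
        X = rng.normal(size=(25, 14))
        one = fit_mfa(_mset([X]), k=2)
        two = fit_mfa(_mset([X, X.copy()], names=["b0", "b1"]), k=2)
        for j in range(2):
            assert abs(np.corrcoef(one.F[:, j], two.F[:, j])[0, 1]) > 0.999

    def test_factor_columns_orthogonal(self, sim42):
        mset, _ = sim42
        fz = fit_mfa(mset, k=2)
        g = fz.F.T @ fz.F
        assert abs(g[0, 1]) < 1e-8 * max(g[0, 0], g[1, 1])

    def test_block_order_invariance(self, sim42):
        mset, _ = sim42
        fw = fit_mfa(mset, k=2)
        rev = MultiOmicsSet(list(reversed(mset.blocks)), mset.labels)
        bw = fit_mfa(rev, k=2)
        C = np.abs(np.corrcoef(fw.F.T, bw.F.T)[:2, 2:])
        # each factor matches one factor of the reversed fit up to sign
        assert np.all(C.max(axis=1) > 0.999)

    def test_rank_guard(self, rng):
        ms = _mset([rng.normal(size=(6, 5))])
        with pytest.raises(ValueError):
            fit_mfa(ms, k=5)


class TestJica:
    def test_planted_source_recovery(self, rng):
        # one bimodal group-like source, one Laplace source, low noise
        n = 60
        s1 = np.where(rng.uniform(size=n) < 0.5, -1.0, 1.0) + 0.05 * rng.normal(size=n)
        s2 = rng.laplace(size=n)
        S = np.stack([s1, s2], axis=1)
        A = rng.normal(size=(50, 2))
        X = A @ S.T + 0.05 * rng.normal(size=(50, n))
        fz = fit_jica(_mset([X]), k=2, seed=0)
        C = np.abs(np.corrcoef(fz.F.T, S.T)[:2, 2:])
        # permutation/sign-free matching
        assert C.max(axis=0).min() > 0.95

    def test_whitened_covariance_identity(self, sim42):
        mset, _ = sim42
        from triomics.jdr import _standardized_concat
        Z, _ = _standardized_concat(mset, scale_blocks=False)
        n = Z.shape[1]
        U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
        Xw = U[:, :2] * np.sqrt(n)
        np.testing.assert_allclose(Xw.T @ Xw / n, np.eye(2), atol=1e-6)

    def test_k1_unit_variance(self, sim42):
        mset, _ = sim42
        fz = fit_jica(mset, k=1, seed=0)
        assert fz.F[:, 0].std() == pytest.approx(1.0, abs=1e-6)

    def test_block_order_invariance(self, sim42):
        mset, _ = sim42
        fw = fit_jica(mset, k=2, seed=0)
        rev = MultiOmicsSet(list(reversed(mset.blocks)), mset.labels)
        bw = fit_jica(rev, k=2, seed=0)
        C = np.abs(np.corrcoef(fw.F.T, bw.F.T)[:2, 2:])
        assert np.all(C.max(axis=1) > 0.99)


class TestRunAllAndAdapters:
    def test_default_three_methods_k2(self, fzs42):
        assert [f.method for f in fzs42] == ["jnmf", "mfa", "jica"]
        assert all(f.k == 2 for f in fzs42)

    def test_unknown_method_named(self, sim42):
        mset, _ = sim42
        with pytest.raises(KeyError, match="nope"):
            run_all(mset, methods=["nope"])

    def test_empty_registry_call(self, sim42):
        mset, _ = sim42
        with pytest.raises(ValueError):
            run_all(mset, methods=[])

    def test_seeded_determinism(self, sim42):
        mset, _ = sim42
        a = run_all(mset, k=2, seed=9)
        b = run_all(mset, k=2, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.F, fb.F)

    def test_save_load_round_trip(self, tmp_path, fzs42):
        fz = fzs42[1]
        save_factorization(fz, tmp_path)
        loaded = load_factorization(
            tmp_path / "mfa_factors.tsv",
            {n: tmp_path / f"mfa_weights_{n}.tsv" for n in fz.W})
        np.testing.assert_allclose(loaded.F, fz.F, atol=1e-9)
        assert loaded.sample_ids == fz.sample_ids
        for n in fz.W:
            np.testing.assert_allclose(loaded.W[n], fz.W[n], atol=1e-9)
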