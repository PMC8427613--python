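import numpy as np
import pandas as pd
import pytest

from cnsig.signatures import (
    CNSignatureModel,
    allocate_max,
    fit_signatures,
    match_signatures,
    quantify_fixed,
    select_rank,
)


def _random_factor_matrix(rng, n=60, m=12, k=3, noise=0.0):
    W0 = rng.dirichlet(np.ones(m) * 0.5, size=k).T  # m x k, columns sum 1
    H0 = rng.dirichlet(np.ones(k) * 0.7, size=n)  # n x k
    scale = rng.uniform(50, 150, size=n)
    M = (H0 * scale[:, None]) @ W0.T
    if noise > 0:
        M = rng.poisson(M).astype(float)
    cols = [f"c{i}" for i in range(m)]
    return (pd.DataFrame(M, index=[f"S{i}" for i in range(n)], columns=cols),
            pd.DataFrame(W0, index=cols, columns=[f"T{j}" for j in range(k)]),
            pd.DataFrame(H0, index=[f"S{i}" for i in range(n)],
                         columns=[f"T{j}" for j in range(k)]))


class TestFitSignatures:
    def test_noiseless_factor_recovery(self):
        rng = np.random.default_rng(0)
        M, W0, _ = _random_factor_matrix(rng)
        res = fit_signatures(M, k=3, n_runs=10, seed=0)
        match = match_signatures(res.W, W0)
        assert (match["cosine"] >= 0.99).all()

    def test_k1_exposures_are_unit(self):
        rng = np.random.default_rng(1)
        M, _, _ = _random_factor_matrix(rng)
        res = fit_signatures(M, k=1, n_runs=3, seed=0)
        assert np.allclose(res.exposures.values, 1.0)

    def test_noisy_recovery_cosine(self):
        rng = np.random.default_rng(2)
        M, W0, _ = _random_factor_matrix(rng, n=200, noise=1.0)
        res = fit_signatures(M, k=3, n_runs=10, seed=0)
        match = match_signatures(res.W, W0)
        assert match["cosine"].mean() >= 0.9

    def test_normalization_invariants(self):
        rng = np.random.default_rng(3)
        M, _, _ = _random_factor_matrix(rng, noise=1.0)
        res = fit_signatures(M, k=4, n_runs=5, seed=0)
        assert np.allclose(res.W.sum(axis=0), 1.0)
        defined = ~res.exposures.isna().any(axis=1)
        assert np.allclose(res.exposures[defined].sum(axis=1), 1.0)
        assert (res.W.values >= 0).all()

    def test_zero_row_flagged_undefined(self):
        rng = np.random.default_rng(4)
        M, _, _ = _random_factor_matrix(rng, n=20)
        M.iloc[5] = 0.0
        res = fit_signatures(M, k=2, n_runs=3, seed=0)
        assert "S5" in res.undefined_samples
        assert res.exposures.loc["S5"].isna().all()
        assert res.allocate_max()["S5"] == "unassigned"

    def test_reconstruction_error_nonincreasing_in_k(self):
        rng = np.random.default_rng(5)
        M, _, _ = _random_factor_matrix(rng, n=50, noise=1.0)
        errs = [fit_signatures(M, k=k, n_runs=4, seed=0).reconstruction_error
                for k in (1, 2, 3, 4)]
        assert all(b <= a + 1e-6 for a, b in zip(errs[:-1], errs[1:]))

    def test_summary_mentions_all_signatures(self):
        rng = np.random.default_rng(6)
        M, _, _ = _random_factor_matrix(rng)
        res = fit_signatures(M, k=3, n_runs=3, seed=0)
        text = res.summary()
        for name in ("Sig1", "Sig2", "Sig3"):
            assert name in text


class TestSelectRank:
    def test_rank1_outer_product_zero_error(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(1, 5, 30)
        v = rng.uniform(0.1, 2, 8)
        M = pd.DataFrame(np.outer(u, v))
        diag = select_rank(M, k_range=range(1, 4), n_runs=4, seed=0)
        assert diag.table.loc[1, "reconstruction_error"] == pytest.approx(0.0, abs=1e-2)

    def test_error_monotone_in_k(self):
        rng = np.random.default_rng(1)
        M, _, _ = _random_factor_matrix(rng, n=40, noise=1.0)
        diag = select_rank(M, k_range=range(1, 6), n_runs=4, seed=0)
        errs = diag.table["reconstruction_error"].to_numpy()
        assert all(b <= a + 0.5 for a, b in zip(errs[:-1], errs[1:]))

    def test_k_exceeding_dimension_raises(self):
        rng = np.random.default_rng(2)
        M, _, _ = _random_factor_matrix(rng, n=6, m=5)
        with pytest.raises(ValueError, match="k_range"):
            select_rank(M, k_range=range(2, 7), n_runs=2, seed=0)


class TestAllocateMax:
    def test_argmax_allocation(self):
        H = pd.DataFrame([[0.1, 0.7, 0.2]], index=["A"], columns=["Sig1", "Sig2", "Sig3"])
        assert allocate_max(H)["A"] == "Sig2"

    def test_tie_goes_to_lowest_index(self):
        H = pd.DataFrame([[0.5, 0.5]], index=["A"], columns=["Sig1", "Sig2"])
        assert allocate_max(H)["A"] == "Sig1"

    def test_invariant_to_row_rescaling(self):
        rng = np.random.default_rng(0)
        H = pd.DataFrame(rng.dirichlet([1, 1, 1], size=20),
                         columns=["Sig1", "Sig2", "Sig3"])
        scaled = H * rng.uniform(0.5, 10, size=(20, 1))
        assert (allocate_max(H) == allocate_max(scaled)).all()

    def test_commutes_with_column_permutation(self):
        rng = np.random.default_rng(1)
        H = pd.DataFrame(rng.dirichlet([1, 1, 1], size=30),
                         columns=["Sig1", "Sig2", "Sig3"])
        perm = ["Sig3", "Sig1", "Sig2"]
        a = allocate_max(H)
        b = allocate_max(H[perm])
        assert (a == b).all()


class TestQuantifyFixed:
    @staticmethod
    def _ref():
        rng = np.random.default_rng(0)
        W = rng.dirichlet(np.ones(10) * 0.5, size=3).T
        return pd.DataFrame(W, index=[f"c{i}" for i in range(10)],
                            columns=["Sig1", "Sig2", "Sig3"])

    def test_pure_signature_sample(self):
        W = self._ref()
        M = pd.DataFrame([3 * W["Sig2"].to_numpy()], index=["A"], columns=W.index)
        H = quantify_fixed(M, W)
        assert H.loc["A"].to_numpy() == pytest.approx([0, 1, 0], abs=1e-9)

    def test_even_mixture(self):
        W = self._ref()
        v = 0.5 * W["Sig1"].to_numpy() + 0.5 * W["Sig2"].to_numpy()
        H = quantify_fixed(pd.DataFrame([v], index=["A"], columns=W.index), W)
        assert H.loc["A"].to_numpy() == pytest.approx([0.5, 0.5, 0.0], abs=1e-6)

    def test_zero_vector_undefined(self):
        W = self._ref()
        H = quantify_fixed(pd.DataFrame([np.zeros(10)], index=["A"], columns=W.index), W)
        assert H.loc["A"].isna().all()

    def test_component_mismatch_raises(self):
        W = self._ref()
        M = pd.DataFrame(np.ones((1, 3)), columns=["x", "y", "z"])
        with pytest.raises(ValueError, match="component labels"):
            quantify_fixed(M, W)
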