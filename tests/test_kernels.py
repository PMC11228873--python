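"""Relationship kernels against brute-force elementwise oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenogp as pg
from phenogp import kernels as kn


def brute_force_grm(X):
    """Elementwise sum oracle: G[i,k] = sum_j xc_ij xc_kj / p."""
    Xc = (X - X.mean(axis=0)) / X.std(axis=0)
    n, p = Xc.shape
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            G[i, k] = sum(Xc[i, j] * Xc[k, j] for j in range(p)) / p
    return G


class TestGenomicRelationship:
    def test_matches_hand_oracle_3x2(self):
        mk = kn.MarkerMatrix(["a", "b", "c"], ["m1", "m2"],
                             np.array([[0, 2], [1, 1], [2, 0]]))
        G = kn.genomic_relationship(mk)
        assert np.allclose(G.to_numpy(), brute_force_grm(mk.X.astype(float)),
                           atol=1e-12)

    def test_trace_identity_and_symmetry(self):
        mk = pg.simulate_markers(25, 120, seed=5)
        G = kn.genomic_relationship(mk).to_numpy()
        assert np.trace(G) / len(G) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_identical_genotypes_identical_rows(self):
        X = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 1, 0]])
        G = kn.genomic_relationship(kn.MarkerMatrix(list("abc"), list("wxyz"), X))
        assert G.iloc[0, 1] == pytest.approx(G.iloc[0, 0])
        assert np.allclose(G.iloc[0], G.iloc[1])

    def test_monomorphic_only_raises(self):
        X = np.ones((3, 4), dtype=int)
        with pytest.raises(kn.DegenerateMarkerError):
            kn.genomic_relationship(kn.MarkerMatrix(list("abc"), list("wxyz"), X))

    def test_monomorphic_columns_dropped_with_warning(self):
        X = np.array([[0, 1], [0, 2], [0, 0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            G = kn.genomic_relationship(kn.MarkerMatrix(list("abc"), ["m1", "m2"], X))
        assert np.trace(G.to_numpy()) / 3 == pytest.approx(1.0)


class TestPhenomicRelationship:
    def test_matches_brute_force_oracle(self, rng):
        R = rng.normal(0, [1, 5, 0.1, 2, 8, 0.5], size=(4, 6))
        P = kn.phenomic_relationship(pd.DataFrame(R))
        Rc = (R - R.mean(0)) / R.std(0)
        expect = np.array(
            [[sum(Rc[i, j] * Rc[k, j] for j in range(6)) / 6 for k in range(4)]
             for i in range(4)]
        )
        assert np.allclose(P, expect, atol=1e-12)

    def test_divisor_is_72_for_full_panel(self, small_scores):
        # indirectly: trace/n == 1 regardless, and the kernel equals
        # RcRc'/n_cols with n_cols = 2 x n_vi
        S = small_scores["until_flowering"]
        P = kn.phenomic_relationship(S)
        assert np.trace(P) / len(P) == pytest.approx(1.0, abs=1e-10)
        Rc = (S - S.mean()) / S.std(ddof=0)
        expect = Rc.to_numpy() @ Rc.to_numpy().T / S.shape[1]
        assert np.allclose(P, expect, atol=1e-10)

    def test_duplicate_rows_identical_kernel_rows(self, rng):
        R = rng.normal(size=(5, 4))
        R[1] = R[0]
        P = kn.phenomic_relationship(pd.DataFrame(R))
        assert np.allclose(P[0], P[1])

    def test_constant_column_dropped_with_warning(self, rng):
        R = rng.normal(size=(6, 4))
        R[:, 2] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            P = kn.phenomic_relationship(pd.DataFrame(R))
        Rc = np.delete(R, 2, axis=1)
        Rc = (Rc - Rc.mean(0)) / Rc.std(0)
        assert np.allclose(P, Rc @ Rc.T / 3, atol=1e-12)


class TestEnvironmentKernel:
    def test_single_environment_all_ones(self):
        rec = pd.DataFrame({"hybrid": list("abc"), "environment": "E"})
        assert np.allclose(kn.environment_kernel(rec), 1.0)

    def test_two_envs_half_blocks(self):
        rec = pd.DataFrame(
            {"hybrid": list("aabb"), "environment": ["E1", "E2", "E1", "E2"]}
        )
        E = kn.environment_kernel(rec)
        assert E[0, 0] == 0.5 and E[0, 2] == 0.5 and E[0, 1] == 0.0

    def test_three_envs_match_incidence_oracle(self):
        rng = np.random.default_rng(2)
        env = rng.choice(["E1", "E2", "E3"], 12)
        rec = pd.DataFrame({"hybrid": [f"h{i}" for i in range(12)], "environment": env})
        Z = pd.get_dummies(rec["environment"], dtype=float).to_numpy()
        assert np.allclose(kn.environment_kernel(rec), Z @ Z.T / 3, atol=1e-12)


class TestInteractionKernel:
    def test_matches_elementwise_loop_oracle(self, rng):
        main = rng.normal(size=(6, 6))
        main = main @ main.T
        env = rng.choice(["A", "B"], 6)
        ind = (env[:, None] == env[None, :]).astype(float)
        K = kn.interaction_kernel(main, ind, 2)
        expect = np.array(
            [[main[i, j] * ind[i, j] / 2 for j in range(6)] for i in range(6)]
        )
        assert np.allclose(K, expect, atol=1e-12)
        # cross-environment pairs annihilated
        assert np.all(K[ind == 0] == 0)

    def test_single_env_indicator_reduces_to_scaled_main(self, rng):
        main = rng.normal(size=(4, 4))
        K = kn.interaction_kernel(main, np.ones((4, 4)), 3)
        assert np.allclose(K, main / 3)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            kn.interaction_kernel(np.eye(3), np.eye(4), 1)


class TestAssembleModel:
    @pytest.fixture()
    def parts(self, small_trial, small_dataset):
        return small_dataset

    @pytest.mark.parametrize(
        "model_id,expected",
        [
            ("M1", {"E", "g", "gxE"}),
            ("M2", {"E", "P1", "P1xE"}),
            ("M3", {"E", "P2", "P2xE"}),
            ("M4", {"E", "g", "P1", "gxE", "P1xE"}),
            ("M5", {"E", "g", "P2", "gxE", "P2xE"}),
            ("M6", {"E", "g", "gxE"}),
        ],
    )
    def test_kernel_lists_per_model(self, parts, model_id, expected):
        ks = parts.kernel_set(model_id)
        assert set(ks.kernels) == expected
        assert ks.multitrait == (model_id == "M6")
        for K in ks.kernels.values():
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_m6_kernels_equal_m1(self, parts):
        k1, k6 = parts.kernel_set("M1"), parts.kernel_set("M6")
        for name in k1.kernels:
            assert np.array_equal(k1.kernels[name], k6.kernels[name])

    def test_record_expansion_restricted_to_env_equals_g(self, parts):
        ks = parts.kernel_set("M1")
        rec = ks.records
        env_mask = (rec["environment"] == rec["environment"].iloc[0]).to_numpy()
        sub = ks.kernels["g"][np.ix_(env_mask, env_mask)]
        hyb = rec.loc[env_mask, "hybrid"]
        expect = parts.G.loc[hyb, hyb].to_numpy()
        assert np.allclose(sub, expect)

    def test_missing_kernel_raises(self, parts):
        with pytest.raises(kn.KernelConfigurationError):
            kn.assemble_model("M4", parts.records, G=parts.G)  # no P1


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n=st.integers(3, 8),
    p=st.integers(2, 10),
    seed=st.integers(0, 1000),
)
def test_grm_trace_property(n, p, seed):
    """trace(G)/n == 1 for any polymorphic dosage matrix."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, p))
    X[:, X.std(axis=0) == 0] = 0
    X[0, X.std(axis=0) == 0] = 1     # force polymorphism
    mk = kn.MarkerMatrix([f"h{i}" for i in range(n)], [f"m{j}" for j in range(p)], X)
    G = kn.genomic_relationship(mk).to_numpy()
    assert np.trace(G) / n == pytest.approx(1.0, abs=1e-10)
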