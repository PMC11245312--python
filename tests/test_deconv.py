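"""Fixed-point deconvolution: the update, convergence, and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statemix import (
    BulkMatrix,
    DeconvolutionModel,
    ReferenceProfile,
    aggregate_states,
    em_step,
    intersect_genes,
    run_deconv,
)
from statemix.errors import InputError

from conftest import grid_search_mle


def random_instance(rng, n_genes, n_states, total=5000):
    A = rng.dirichlet(np.ones(n_genes), size=n_states).T
    truth = rng.dirichlet(np.ones(n_states))
    x = rng.multinomial(total, A @ truth).astype(float)
    ref = ReferenceProfile(
        A=A,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        state_ids=[f"s{i}" for i in range(n_states)],
        state_to_type={f"s{i}": f"s{i}" for i in range(n_states)},
        type_ids=[f"s{i}" for i in range(n_states)],
    )
    bulk = BulkMatrix(
        X=x[:, None], gene_ids=ref.gene_ids, sample_ids=["b"]
    )
    return bulk, ref, x, A


class TestEmStep:
    def test_single_state_returns_one(self):
        A = np.array([[0.3], [0.7]])
        out = em_step(np.array([10.0, 20.0]), A, np.array([1.0]))
        np.testing.assert_allclose(out, [1.0])

    def test_hand_expanded_responsibilities(self, two_state_ref):
        # uniform theta: responsibilities are 0.8/0.2 at gene1, 0.2/0.8 at
        # gene2, so state 1 expects (60*0.8 + 40*0.2)/100 = 0.56 of the reads
        out = em_step(
            np.array([60.0, 40.0]), two_state_ref.A, np.array([0.5, 0.5])
        )
        np.testing.assert_allclose(out, [0.56, 0.44])

    def test_fixed_point_is_stationary(self, two_state_ref):
        theta = np.array([2.0 / 3.0, 1.0 / 3.0])
        out = em_step(np.array([60.0, 40.0]), two_state_ref.A, theta)
        np.testing.assert_allclose(out, theta, atol=1e-12)

    def test_zero_denominator_raises(self):
        A = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(InputError, match="denominator"):
            em_step(np.array([1.0, 5.0]), A, np.array([0.5, 0.5]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_preserves_simplex(self, seed):
        rng = np.random.default_rng(seed)
        G, S = int(rng.integers(2, 10)), int(rng.integers(1, 5))
        A = rng.dirichlet(np.ones(G), size=S).T
        theta = rng.dirichlet(np.ones(S))
        x = rng.integers(0, 50, size=G).astype(float)
        out = em_step(x, A, theta)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class TestRunDeconv:
    def test_exact_recovery_two_state(self, two_gene_bulk, two_state_ref):
        # A @ (2/3, 1/3) = (0.6, 0.4) exactly; grid oracle confirms the MLE
        res = run_deconv(two_gene_bulk, two_state_ref, max_iter=500, tol=1e-12)
        np.testing.assert_allclose(res.theta_state[0], [2 / 3, 1 / 3], atol=1e-6)
        oracle = grid_search_mle(
            two_gene_bulk.X[:, 0], two_state_ref.A, step=1e-4
        )
        np.testing.assert_allclose(res.theta_state[0], oracle, atol=1e-3)

    def test_pure_column_converges_to_vertex(self):
        rng = np.random.default_rng(2)
        A = rng.dirichlet(np.ones(20), size=3).T
        x = 1000.0 * A[:, 1]
        ref = ReferenceProfile(
            A=A,
            gene_ids=[f"g{i}" for i in range(20)],
            state_ids=["s0", "s1", "s2"],
            state_to_type={s: s for s in ["s0", "s1", "s2"]},
            type_ids=["s0", "s1", "s2"],
        )
        bulk = BulkMatrix(X=x[:, None], gene_ids=ref.gene_ids, sample_ids=["b"])
        res = run_deconv(bulk, ref, max_iter=2000, tol=1e-10)
        np.testing.assert_allclose(res.theta_state[0], [0, 1, 0], atol=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_mle(self, seed):
        # random 10-gene / 3-state instances vs brute-force simplex search
        rng = np.random.default_rng(seed)
        bulk, ref, x, A = random_instance(rng, 10, 3)
        res = run_deconv(bulk, ref, max_iter=2000, tol=1e-10)
        oracle = grid_search_mle(x, A, step=0.01)
        assert np.abs(res.theta_state[0] - oracle).max() < 0.02

    def test_loglik_nondecreasing(self, small_dataset):
        from statemix import ref_prepare

        ref = ref_prepare(small_dataset.sc_reference_half)
        res = run_deconv(small_dataset.pseudobulk, ref)
        for trace in res.loglik:
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-7)

    def test_scale_invariance(self, two_state_ref):
        rng = np.random.default_rng(4)
        x = rng.integers(50, 200, size=2).astype(float)
        b1 = BulkMatrix(X=x[:, None], gene_ids=["g1", "g2"], sample_ids=["b"])
        b2 = BulkMatrix(X=37.5 * x[:, None], gene_ids=["g1", "g2"], sample_ids=["b"])
        r1 = run_deconv(b1, two_state_ref, max_iter=500, tol=1e-12)
        r2 = run_deconv(b2, two_state_ref, max_iter=500, tol=1e-12)
        np.testing.assert_allclose(r1.theta_state, r2.theta_state, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        bulk, ref, x, A = random_instance(rng, 8, 3)
        perm = [2, 0, 1]
        ref_p = ReferenceProfile(
            A=A[:, perm],
            gene_ids=ref.gene_ids,
            state_ids=[ref.state_ids[j] for j in perm],
            state_to_type=ref.state_to_type,
            type_ids=ref.type_ids,
        )
        res = run_deconv(bulk, ref, max_iter=500, tol=1e-12)
        res_p = run_deconv(bulk, ref_p, max_iter=500, tol=1e-12)
        np.testing.assert_allclose(
            res_p.theta_state[0], res.theta_state[0][perm], atol=1e-10
        )
        # type fractions are unchanged (types are sorted identically)
        np.testing.assert_allclose(res_p.theta_type, res.theta_type, atol=1e-10)

    def test_all_zero_sample_flagged_uniform(self, two_state_ref):
        X = np.array([[60.0, 0.0], [40.0, 0.0]])
        bulk = BulkMatrix(X=X, gene_ids=["g1", "g2"], sample_ids=["b1", "b2"])
        res = run_deconv(bulk, two_state_ref)
        assert not res.converged[1]
        np.testing.assert_allclose(res.theta_state[1], [0.5, 0.5])
        assert res.converged[0]

    def test_rows_sum_to_one(self, small_dataset):
        from statemix import ref_prepare

        ref = ref_prepare(small_dataset.sc_reference_half)
        res = run_deconv(small_dataset.pseudobulk, ref)
        np.testing.assert_allclose(res.theta_state.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.theta_type.sum(axis=1), 1.0, atol=1e-9)

    def test_log_scale_warning(self, two_state_ref):
        bulk = BulkMatrix(
            X=np.array([[3.0], [8.0]]), gene_ids=["g1", "g2"], sample_ids=["b"]
        )
        with pytest.warns(UserWarning, match="log-scaled"):
            DeconvolutionModel(bulk, two_state_ref)

    def test_summary_mentions_convergence(self, two_gene_bulk, two_state_ref):
        res = run_deconv(two_gene_bulk, two_state_ref)
        text = res.summary()
        assert "converged: 1/1" in text
        assert "k1" in text


class TestIntersectGenes:
    def test_identical_gene_sets_unchanged(self, two_gene_bulk, two_state_ref):
        b, r = intersect_genes(two_gene_bulk, two_state_ref)
        np.testing.assert_allclose(b.X, two_gene_bulk.X)
        np.testing.assert_allclose(r.A, two_state_ref.A)

    def test_bulk_extra_gene_dropped(self, two_state_ref):
        bulk = BulkMatrix(
            X=np.array([[60.0], [40.0], [5.0]]),
            gene_ids=["g1", "g2", "g9"],
            sample_ids=["b"],
        )
        b, r = intersect_genes(bulk, two_state_ref)
        assert b.gene_ids == ["g1", "g2"]
        np.testing.assert_allclose(r.A, two_state_ref.A)

    def test_reference_subset_renormalized(self, two_gene_bulk):
        rng = np.random.default_rng(8)
        A = rng.dirichlet(np.ones(3), size=2).T
        ref = ReferenceProfile(
            A=A,
            gene_ids=["g1", "g2", "g3"],
            state_ids=["s1", "s2"],
            state_to_type={"s1": "k1", "s2": "k2"},
            type_ids=["k1", "k2"],
        )
        _, r = intersect_genes(two_gene_bulk, ref)
        assert r.gene_ids == ["g1", "g2"]
        np.testing.assert_allclose(r.A.sum(axis=0), 1.0, atol=1e-12)

    def test_no_shared_genes_raises(self, two_state_ref):
        bulk = BulkMatrix(
            X=np.array([[1.0]]), gene_ids=["other"], sample_ids=["b"]
        )
        with pytest.raises(InputError, match="shared genes"):
            intersect_genes(bulk, two_state_ref)


class TestAggregateStates:
    def test_identity_map(self):
        theta = np.array([[0.2, 0.8]])
        out, types = aggregate_states(theta, {"a": "a", "b": "b"}, ["a", "b"])
        np.testing.assert_allclose(out, theta)

    def test_grouped_sum(self):
        theta = np.array([[0.2, 0.3, 0.5]])
        out, types = aggregate_states(
            theta, {"s1": "k1", "s2": "k1", "s3": "k2"}, ["s1", "s2", "s3"]
        )
        np.testing.assert_allclose(out, [[0.5, 0.5]])
        assert types == ["k1", "k2"]

    def test_unmapped_state_raises(self):
        with pytest.raises(InputError, match="unmapped"):
            aggregate_states(np.array([[1.0]]), {}, ["s1"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_row_sums_preserved(self, seed):
        rng = np.random.default_rng(seed)
        S, K = int(rng.integers(1, 8)), int(rng.integers(1, 4))
        theta = rng.dirichlet(np.ones(S), size=3)
        mapping = {f"s{j}": f"k{rng.integers(0, K)}" for j in range(S)}
        out, _ = aggregate_states(theta, mapping, list(mapping))
        np.testing.assert_allclose(
            out.sum(axis=1), theta.sum(axis=1), atol=1e-12
        )
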