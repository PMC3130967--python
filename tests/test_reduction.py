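"""PCA whitening/reduction, MDL order selection, two-stage group reduction."""

import numpy as np
import pytest

from groupica.datasets import EpochedDataset, GroupDataset
from groupica.reduction import (
    estimate_order_mdl,
    mdl_criterion,
    pca_reduce,
    reduce_group,
)

from conftest import make_dataset


def covariance_pca_oracle(data, L):
    """Brute-force PCA via eigendecomposition of the covariance matrix."""
    centered = data - data.mean(axis=1, keepdims=True)
    lam, vec = np.linalg.eigh(np.cov(centered))
    order = np.argsort(lam)[::-1]
    return lam[order], vec[:, order[:L]]


class TestPcaReduce:
    def test_diagonal_covariance_eigenvalues(self, rng):
        # rows orthogonal by construction with variances 4 and 1
        t = np.arange(4000)
        data = np.vstack([2.0 * np.sqrt(2) * np.sin(2 * np.pi * t / 100),
                          np.sqrt(2) * np.cos(2 * np.pi * t / 100)])
        r = pca_reduce(data, L=2, whiten=True)
        np.testing.assert_allclose(r.eigenvalues, [4.0, 1.0], rtol=1e-3)
        reduced = r.transform(data)
        np.testing.assert_allclose(reduced.var(axis=1, ddof=1), [1.0, 1.0], rtol=1e-6)

    def test_full_rank_reconstruction_matches_covariance_oracle(self, rng):
        data = rng.standard_normal((8, 1000))
        r = pca_reduce(data, L=8, whiten=True)
        centered = data - data.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(r.dewhitener @ r.reducer @ centered, centered, atol=1e-8)
        lam, _ = covariance_pca_oracle(data, 8)
        np.testing.assert_allclose(r.eigenvalues, lam, rtol=1e-8)

    def test_subspace_matches_covariance_oracle(self, rng):
        data = rng.standard_normal((6, 500))
        r = pca_reduce(data, L=3)
        _, axes = covariance_pca_oracle(data, 3)
        # same principal subspace: projector difference vanishes
        p_ours = r.dewhitener @ r.reducer
        p_oracle = axes @ axes.T
        centered = data - data.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(p_ours @ centered, p_oracle @ centered, atol=1e-8)

    def test_whiteness_invariant(self, rng):
        data = rng.standard_normal((10, 2000)) * rng.uniform(0.5, 3, size=(10, 1))
        r = pca_reduce(data, L=6, whiten=True)
        reduced = r.transform(data)
        cov = reduced @ reduced.T / (reduced.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(6), atol=1e-6)

    def test_reducer_dewhitener_pseudoinverse(self, rng):
        r = pca_reduce(rng.standard_normal((7, 300)), L=4)
        np.testing.assert_allclose(r.reducer @ r.dewhitener, np.eye(4), atol=1e-10)

    def test_variance_retained_monotone_in_L(self, rng):
        data = rng.standard_normal((6, 400))
        fracs = [pca_reduce(data, L).variance_retained for L in range(1, 7)]
        assert np.all(np.diff(fracs) >= -1e-12)
        assert fracs[-1] == pytest.approx(1.0)

    def test_invalid_L(self, rng):
        data = rng.standard_normal((4, 100))
        with pytest.raises(ValueError):
            pca_reduce(data, L=0)
        with pytest.raises(ValueError):
            pca_reduce(data, L=5)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pca_reduce(np.ones((3, 50)), L=1)

    def test_rank_deficient_L_rejected(self, rng):
        row = rng.standard_normal(200)
        data = np.vstack([row, 2 * row, -row, rng.standard_normal(200)])
        with pytest.raises(ValueError, match="rank"):
            pca_reduce(data, L=4)

    def test_deterministic_sign_convention(self, rng):
        data = rng.standard_normal((5, 300))
        a = pca_reduce(data, L=3)
        b = pca_reduce(data.copy(), L=3)
        np.testing.assert_array_equal(a.reducer, b.reducer)
        # largest-magnitude loading of each axis is positive
        axes = a.dewhitener / np.linalg.norm(a.dewhitener, axis=0)
        assert all(axes[np.argmax(np.abs(axes[:, k])), k] > 0 for k in range(3))


class TestMdl:
    def test_recovers_source_count(self, rng):
        # 5 unit-variance sources through a random 10x5 mixing plus weak noise
        n = 20000
        sources = rng.standard_normal((5, n))
        mixing = rng.standard_normal((10, 5))
        data = mixing @ sources + 0.1 * rng.standard_normal((10, n))
        assert estimate_order_mdl(data) == 5

    def test_matches_bruteforce_criterion(self, rng):
        data = rng.standard_normal((6, 800))
        centered = data - data.mean(axis=1, keepdims=True)
        lam = np.sort(np.linalg.eigvalsh(np.cov(centered)))[::-1]
        n = data.shape[1]
        # brute-force evaluation of the criterion at every candidate order
        best, best_val = None, np.inf
        for k in range(1, 6):
            tail = lam[k:]
            val = -(6 - k) * n * (np.mean(np.log(tail)) - np.log(np.mean(tail))) \
                + 0.5 * k * (2 * 6 - k) * np.log(n)
            if val < best_val:
                best, best_val = k, val
        assert estimate_order_mdl(data) == best
        np.testing.assert_allclose(
            mdl_criterion(lam, n)[best - 1], best_val, rtol=1e-12
        )

    def test_isotropic_noise_gives_small_order(self, rng):
        data = rng.standard_normal((10, 50000))
        assert estimate_order_mdl(data) < 5

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="channels"):
            estimate_order_mdl(rng.standard_normal((1, 100)))
        with pytest.raises(ValueError, match="fewer"):
            estimate_order_mdl(rng.standard_normal((5, 100)), effective_samples=3)
        with pytest.raises(ValueError, match="finite"):
            mdl_criterion(np.array([1.0, np.nan, 0.5]), 100)


class TestReduceGroup:
    def test_identical_subjects_span_single_subject_subspace(self, rng):
        data = rng.standard_normal((5, 600))
        subs = [EpochedDataset(f"s{i}", data.copy(), 60, 10) for i in range(2)]
        red = reduce_group(GroupDataset(subs), L=5, N=5)
        # principal angles between row spaces of X and one subject's whitened data
        x1 = red.per_subject[0].transform(data)
        qa, _ = np.linalg.qr(red.X.T)
        qb, _ = np.linalg.qr(x1.T)
        angles = np.linalg.svd(qa.T @ qb, compute_uv=False)
        np.testing.assert_allclose(angles, 1.0, atol=1e-8)

    def test_stacking_identity(self, small_group):
        """Aggregate X equals the group reducer applied to stacked subject data."""
        red = reduce_group(small_group, L=3, N=5)
        stacked = np.vstack([
            r.transform(ds.data) for r, ds in zip(red.per_subject, small_group)
        ])
        np.testing.assert_allclose(red.group_reducer @ stacked, red.X, atol=1e-8)
        np.testing.assert_allclose(red.reduced_stack, stacked, atol=1e-12)

    def test_group_reducer_dewhitener_identity(self, small_group):
        red = reduce_group(small_group, L=3, N=4)
        np.testing.assert_allclose(
            red.group_reducer @ red.group_dewhitener, np.eye(4), atol=1e-10
        )

    def test_partitions_disjoint_and_covering(self, small_group):
        red = reduce_group(small_group, L=3, N=4)
        seen = []
        for s in red.partitions:
            seen.extend(range(*s.indices(3 * len(small_group))))
        assert sorted(seen) == list(range(9))
        assert red.partition(1).shape == (3, 4)

    def test_reconstruction_error_bounded_by_truncation(self, rng):
        """The Eq.-1 factorization loses no more than the discarded eigenvalues."""
        subs = [make_dataset(rng, q=6, samples=50, trials=10, subject_id=f"s{i}")
                for i in range(3)]
        red = reduce_group(GroupDataset(subs), L=6, N=10)
        stacked = red.reduced_stack
        recon = red.group_dewhitener @ red.X
        rel_err = np.linalg.norm(recon - stacked) ** 2 / np.linalg.norm(stacked) ** 2
        # independent bound from a full SVD of the stacked matrix
        sv = np.linalg.svd(stacked - stacked.mean(axis=1, keepdims=True),
                           compute_uv=False)
        bound = (sv[10:] ** 2).sum() / (sv**2).sum()
        assert rel_err <= bound + 1e-9

    def test_paper_configuration_shapes(self, rng):
        subs = [
            EpochedDataset(f"s{i}", rng.standard_normal((63, 640)), 32, 20)
            for i in range(20)
        ]
        red = reduce_group(GroupDataset(subs), L=20, N=20)
        assert red.group_reducer.shape == (20, 400)
        assert red.X.shape == (20, 640)

    def test_dimension_violations(self, small_group):
        with pytest.raises(ValueError, match="exceeds"):
            reduce_group(small_group, L=3, N=10)
        with pytest.raises(ValueError, match="exceeds"):
            reduce_group(small_group, L=5, N=2)
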