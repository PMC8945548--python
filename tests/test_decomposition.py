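"""CP solver: exact recovery, invariants, matching, explained variance."""

import itertools

import numpy as np
import pytest

from braintensor import (
    NascarOptions,
    build_tensor,
    explained_variance,
    match_components,
    nascar_decompose,
)
from braintensor.decomposition import Decomposition, NetworkComponent

from conftest import make_dataset


def _unit(rng, n):
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def _rank1(lam, a, b, c):
    return lam * np.einsum("v,t,s->vts", a, b, c)


def _orthonormal_rows(rng, r, n):
    q, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return q.T


def _decomposition_from_factors(lams, a, b, c):
    comps = [
        NetworkComponent(magnitude=float(l), spatial=a[i], temporal=b[i], subject=c[i])
        for i, l in enumerate(lams)
    ]
    return Decomposition(components=comps, rank_requested=len(comps))


class TestBuildTensor:
    def test_stacks_subjects_in_order(self, rng):
        ds = make_dataset(rng, v=4, t=3, s=2, n_sub=2, grid=(2, 1, 1))
        tens = build_tensor(ds, synced=True)
        assert tens.shape == (4, 3, 2)
        for s in range(2):
            np.testing.assert_array_equal(tens.values[:, :, s], ds.subjects[s])

    def test_single_subject_degenerate(self, rng):
        ds = make_dataset(rng, v=6, t=5, s=1, n_sub=2, grid=(2, 1, 1))
        tens = build_tensor(ds, synced=True)
        assert tens.shape == (6, 5, 1)

    def test_spot_check_random_triples(self, rng):
        ds = make_dataset(rng, v=20, t=15, s=4, n_sub=4, grid=(4, 1, 1))
        tens = build_tensor(ds, synced=True)
        for _ in range(100):
            i, t, s = (
                rng.integers(20), rng.integers(15), rng.integers(4),
            )
            assert tens.values[i, t, s] == ds.subjects[s][i, t]

    def test_unsynced_rejected(self, rng):
        ds = make_dataset(rng)
        with pytest.raises(ValueError, match="synchron|asynchron"):
            build_tensor(ds, synced=False)


class TestNascarDecompose:
    def test_exact_rank1_recovery(self, rng):
        a, b, c = _unit(rng, 30), _unit(rng, 20), _unit(rng, 6)
        x = _rank1(5.0, a, b, c)
        dec = nascar_decompose(x, rank=1, seed=0)
        comp = dec.components[0]
        assert comp.magnitude == pytest.approx(5.0, rel=0.01)
        assert abs(comp.spatial @ a) > 0.999
        assert abs(comp.temporal @ b) > 0.999
        assert abs(comp.subject @ c) > 0.999

    def test_zero_tensor_gives_zero_magnitudes(self):
        dec = nascar_decompose(np.zeros((6, 5, 4)), rank=2, seed=0)
        assert np.all(dec.magnitudes == 0.0)

    def test_noisy_rank3_orthogonal_recovery(self, rng):
        """Orthogonal rank-3 tensor with magnitudes (3,2,1) plus 1% noise:
        all nine factor vectors recovered with congruence >= 0.99 and
        magnitudes within 5%."""
        lams = np.array([3.0, 2.0, 1.0])
        a = _orthonormal_rows(rng, 3, 40)
        b = _orthonormal_rows(rng, 3, 30)
        c = _orthonormal_rows(rng, 3, 10)
        x = np.einsum("r,rv,rt,rs->vts", lams, a, b, c)
        noise = rng.standard_normal(x.shape)
        x = x + noise * np.sqrt(0.01 * x.var() / noise.var())
        dec = nascar_decompose(x, rank=3, seed=1)
        truth = _decomposition_from_factors(lams, a, b, c)
        m = match_components(dec, truth)
        assert (m.congruence >= 0.99).all()
        est_lams = dec.magnitudes[m.assignment]
        np.testing.assert_allclose(est_lams, lams, rtol=0.05)

    def test_fit_history_nonincreasing(self, rng):
        x = rng.standard_normal((20, 15, 5))
        dec = nascar_decompose(x, rank=4, seed=0)
        assert np.all(np.diff(dec.fit_history) <= 1e-12)

    def test_component_invariants(self, rng):
        x = rng.standard_normal((15, 12, 4))
        dec = nascar_decompose(x, rank=3, seed=0)
        assert np.all(np.diff(dec.magnitudes) <= 0)
        for comp in dec.components:
            assert comp.magnitude >= 0
            for f in (comp.spatial, comp.temporal, comp.subject):
                assert np.linalg.norm(f) == pytest.approx(1.0, abs=1e-8)
            assert comp.spatial[np.argmax(np.abs(comp.spatial))] > 0

    def test_vertex_shuffle_invariance_bit_identical(self, rng):
        """Permuting the space axis before decomposition and un-permuting the
        spatial factors afterwards changes nothing, bit for bit."""
        x = rng.standard_normal((40, 20, 5))
        dec0 = nascar_decompose(x, rank=3, seed=2)
        perm = rng.permutation(40)
        dec1 = nascar_decompose(x[perm], rank=3, seed=2)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(40)
        for c0, c1 in zip(dec0.components, dec1.components):
            assert np.array_equal(c0.spatial, c1.spatial[inv])
            assert np.array_equal(c0.temporal, c1.temporal)
            assert np.array_equal(c0.subject, c1.subject)
            assert c0.magnitude == c1.magnitude

    def test_determinism(self, rng):
        x = rng.standard_normal((15, 10, 4))
        d1 = nascar_decompose(x, rank=2, seed=3)
        d2 = nascar_decompose(x, rank=2, seed=3)
        for c1, c2 in zip(d1.components, d2.components):
            assert np.array_equal(c1.spatial, c2.spatial)

    def test_nan_rejected(self):
        x = np.zeros((4, 4, 4))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            nascar_decompose(x, rank=1)

    def test_excessive_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            nascar_decompose(np.zeros((3, 3, 3)), rank=9)


class TestMatchComponents:
    def _truth(self, rng, r=3):
        return _decomposition_from_factors(
            np.arange(r, 0, -1).astype(float),
            _orthonormal_rows(rng, r, 20),
            _orthonormal_rows(rng, r, 15),
            _orthonormal_rows(rng, r, 8),
        )

    def test_exact_match_identity(self, rng):
        truth = self._truth(rng)
        m = match_components(truth, truth)
        np.testing.assert_array_equal(m.assignment, np.arange(3))
        np.testing.assert_allclose(m.congruence, 1.0, atol=1e-12)

    def test_sign_flip_in_two_modes_resolved(self, rng):
        truth = self._truth(rng)
        est = _decomposition_from_factors(
            truth.magnitudes,
            np.array([c.spatial for c in truth.components]) * -1,
            np.array([c.temporal for c in truth.components]) * -1,
            np.array([c.subject for c in truth.components]),
        )
        m = match_components(est, truth)
        np.testing.assert_allclose(m.congruence, 1.0, atol=1e-12)
        assert (m.spatial_sign == -1).all()

    def test_permutation_recovered_vs_exhaustive(self, rng):
        """The greedy assignment agrees with exhaustive search over all
        permutations for a shuffled copy of the truth (R <= 6)."""
        r = 5
        truth = self._truth(rng, r=r)
        perm = rng.permutation(r)
        ta, tb, tc = truth.factor_matrices()
        est = _decomposition_from_factors(
            truth.magnitudes[perm], ta[perm], tb[perm], tc[perm]
        )
        m = match_components(est, truth)
        # exhaustive: maximize total product-congruence over permutations
        def total(assign):
            s = 0.0
            for k, i in enumerate(assign):
                s += (
                    abs(est.components[i].spatial @ ta[k])
                    * abs(est.components[i].temporal @ tb[k])
                    * abs(est.components[i].subject @ tc[k])
                )
            return s

        best = max(itertools.permutations(range(r)), key=total)
        np.testing.assert_array_equal(m.assignment, best)
        assert np.argsort(perm)[0] == m.assignment[0] or perm[m.assignment[0]] == 0

    def test_subset_modes(self, rng):
        truth = self._truth(rng)
        m = match_components(truth, truth, modes=("spatial", "subject"))
        np.testing.assert_array_equal(m.assignment, np.arange(3))
        with pytest.raises(ValueError):
            match_components(truth, truth, modes=("bogus",))


class TestExplainedVariance:
    def test_exact_decomposition_explains_everything(self, rng):
        truth = TestMatchComponents()._truth(rng)
        x = truth.reconstruct()
        assert explained_variance(truth, x) == pytest.approx(1.0, abs=1e-6)

    def test_empty_decomposition_explains_nothing(self, rng):
        truth = TestMatchComponents()._truth(rng)
        x = truth.reconstruct()
        empty = Decomposition(components=[], rank_requested=0)
        assert explained_variance(empty, x) == 0.0

    def test_rank1_truncation_of_orthogonal_rank2(self, rng):
        """For an orthogonal rank-2 tensor with magnitudes (2,1), the rank-1
        truncation explains 4/5 of the variance (by Parseval)."""
        a = _orthonormal_rows(rng, 2, 12)
        b = _orthonormal_rows(rng, 2, 10)
        c = _orthonormal_rows(rng, 2, 6)
        lams = np.array([2.0, 1.0])
        x = np.einsum("r,rv,rt,rs->vts", lams, a, b, c)
        trunc = _decomposition_from_factors(lams[:1], a[:1], b[:1], c[:1])
        assert explained_variance(trunc, x) == pytest.approx(0.8, abs=1e-6)
        # direct residual verification
        resid = x - trunc.reconstruct()
        assert 1 - (resid**2).sum() / (x**2).sum() == pytest.approx(0.8, abs=1e-12)

    def test_zero_tensor_rejected(self, rng):
        truth = TestMatchComponents()._truth(rng)
        with pytest.raises(ValueError):
            explained_variance(truth, np.zeros((20, 15, 8)))
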