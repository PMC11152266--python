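"""Metric suite: analytic oracles, bounds, and invariances."""

import numpy as np
import pytest

from idpdiff.evalsuite import (
    HistogramSpec,
    ensemble_report,
    histogram_divergence,
    mse_c,
    mse_d,
    pca_landscape,
)
from idpdiff.geometry import Ensemble, mirror, pairwise_distances, \
    radius_of_gyration, random_rotation, rigid_transform
from idpdiff.synthdata import ToyModelSpec, generate_toy_sequence, \
    sample_toy_ensemble


@pytest.fixture(scope="module")
def toy_pair():
    seq = generate_toy_sequence(10, 40)
    spec = ToyModelSpec()
    ref = sample_toy_ensemble(seq, 300, spec, seed=41)
    gen = sample_toy_ensemble(seq, 300, spec, seed=42)
    return ref, gen


class TestHistogramDivergence:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(0).normal(size=2000)
        assert histogram_divergence(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kl_matches_closed_form(self):
        # KL(N(0,1) ‖ N(1,1)) = 0.5
        rng = np.random.default_rng(1)
        p = rng.normal(0.0, 1.0, 100_000)
        q = rng.normal(1.0, 1.0, 100_000)
        assert histogram_divergence(p, q) == pytest.approx(0.5, abs=0.02)

    def test_gaussian_kl_error_decreases_with_n(self):
        rng = np.random.default_rng(2)
        errs = []
        for n in (10**3, 10**4, 10**5):
            est = np.mean([
                histogram_divergence(rng.normal(0, 1, n), rng.normal(1, 1, n))
                for _ in range(3)
            ])
            errs.append(abs(est - 0.5))
        assert errs[2] < errs[0]

    def test_disjoint_jsd_is_ln2(self):
        p = np.linspace(0.0, 1.0, 500)
        q = np.linspace(10.0, 11.0, 500)
        assert histogram_divergence(p, q, symmetric=True) \
            == pytest.approx(np.log(2.0), abs=1e-6)

    def test_degenerate_range_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert histogram_divergence(np.ones(10), np.ones(10)) == 0.0


class TestPairScores:
    def test_identity_zero(self, toy_pair):
        ref, _ = toy_pair
        assert mse_c(ref, ref) == 0.0
        assert mse_d(ref, ref) == 0.0

    def test_mse_c_bound_case(self):
        seq = generate_toy_sequence(8, 1)
        compact = Ensemble(seq, np.random.default_rng(0).normal(0, 1, (5, 8, 3)))
        spread = Ensemble(seq, compact.coords * 100.0)
        assert mse_c(compact, spread) == pytest.approx(1.0)

    def test_mse_d_unit_conversion(self, toy_pair):
        # uniformly scaled coordinates change every distance by a known
        # amount in Å; the score must come back in nm²
        ref, _ = toy_pair
        scaled = Ensemble(ref.sequence, ref.coords * 1.05)
        d = pairwise_distances(ref.coords).mean(axis=0)
        iu, ju = np.triu_indices(ref.length, 2)
        expected = np.mean((0.05 * d[iu, ju] * 0.1) ** 2)  # Å → nm
        assert mse_d(ref, scaled) == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_oracle(self, toy_pair):
        ref, gen = toy_pair
        got = mse_c(ref, gen)
        pr = [(pairwise_distances(ref.coords) < 8.0).mean(axis=0)]
        pg = [(pairwise_distances(gen.coords) < 8.0).mean(axis=0)]
        acc = []
        L = ref.length
        for i in range(L):
            for j in range(i + 2, L):
                acc.append((pr[0][i, j] - pg[0][i, j]) ** 2)
        assert got == pytest.approx(np.mean(acc))


class TestEnsembleReport:
    def test_identical_all_zero(self, toy_pair):
        ref, _ = toy_pair
        rep = ensemble_report(ref, ref)
        for v in rep.as_dict().values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_member_order_invariance(self, toy_pair):
        ref, _ = toy_pair
        shuffled = Ensemble(
            ref.sequence,
            ref.coords[np.random.default_rng(3).permutation(ref.n_members)])
        for v in ensemble_report(ref, shuffled).as_dict().values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, toy_pair):
        ref, gen = toy_pair
        rng = np.random.default_rng(4)
        moved = Ensemble(gen.sequence, np.stack([
            rigid_transform(c, random_rotation(rng), rng.normal(0, 5, 3))
            for c in gen.coords
        ]))
        a = ensemble_report(ref, gen).as_dict()
        b = ensemble_report(ref, moved).as_dict()
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_mirrored_ensemble_chiral_probe(self, toy_pair):
        ref, _ = toy_pair
        mirrored = Ensemble(ref.sequence, mirror(ref.coords))
        rep = ensemble_report(ref, mirrored)
        assert rep.MSE_d == pytest.approx(0.0, abs=1e-12)
        assert rep.aKLD_d == pytest.approx(0.0, abs=1e-9)
        assert rep.aKLD_t > 0.1  # torsion distributions flip sign

    def test_bounds(self, toy_pair):
        ref, gen = toy_pair
        rep = ensemble_report(ref, gen)
        assert rep.aJSD_d <= np.log(2.0) and rep.aJSD_t <= np.log(2.0)
        assert min(rep.as_dict().values()) >= 0.0

    def test_subsample_scores_shrink_with_size(self, toy_pair):
        ref, _ = toy_pair
        small = ensemble_report(ref, Ensemble(ref.sequence, ref.coords[:20]))
        large = ensemble_report(ref, Ensemble(ref.sequence, ref.coords[:150]))
        assert large.aKLD_d < small.aKLD_d


class TestPCALandscape:
    def test_loadings_match_covariance_eigendecomposition(self, toy_pair):
        ref, gen = toy_pair
        land = pca_landscape(ref, gen, n_components=5)
        iu, ju = np.triu_indices(ref.length, 2)
        X = pairwise_distances(ref.coords)[:, iu, ju]
        C = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        assert np.allclose(land.explained_variance, evals[order][:5], atol=1e-8)
        for k in range(5):
            v = evecs[:, order[k]]
            dot = np.abs(np.dot(v, land.components[k]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(land.explained_variance) <= 1e-12).all()

    def test_two_conformer_reference(self):
        seq = generate_toy_sequence(8, 2)
        coords = sample_toy_ensemble(seq, 2, ToyModelSpec(), seed=3).coords
        ens = Ensemble(seq, coords)
        land = pca_landscape(ens, ens, n_components=1)
        total = np.cov(
            pairwise_distances(coords)[:, np.triu_indices(8, 2)[0],
                                       np.triu_indices(8, 2)[1]],
            rowvar=False).trace()
        assert land.explained_variance[0] == pytest.approx(total)

    def test_insufficient_members_rejected(self, toy_pair):
        ref, gen = toy_pair
        small = Ensemble(ref.sequence, ref.coords[:4])
        with pytest.raises(Exception):
            pca_landscape(small, gen, n_components=5)
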