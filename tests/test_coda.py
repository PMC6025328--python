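"""Aitchison-geometry primitives: transforms, metric, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from floodrisk import coda
from floodrisk.coda import Composition

from conftest import random_compositions


def parts(min_size=2, max_size=8):
    return st.lists(
        st.floats(min_value=1e-4, max_value=1e4), min_size=min_size, max_size=max_size
    )


class TestClosure:
    def test_basic(self):
        np.testing.assert_allclose(coda.closure([1, 1, 2]), [0.25, 0.25, 0.5])

    def test_idempotent(self):
        x = coda.closure([3.0, 1.0, 7.0])
        np.testing.assert_allclose(coda.closure(x), x, rtol=1e-14)

    def test_kappa(self):
        assert coda.closure([2, 2], kappa=100.0).sum() == pytest.approx(100.0)

    def test_vertex_collapse_of_raw_hazard_shares(self):
        # dominant-part effect: the BaP/gHCH/ppDDT median-HQ triple closes
        # almost entirely onto the BaP vertex
        x = coda.closure([0.152897, 0.000164, 0.000493])
        np.testing.assert_allclose(x, [0.99572, 0.00107, 0.00321], atol=5e-5)

    @pytest.mark.parametrize("bad", [[1.0, 0.0], [1.0, -2.0], [np.nan, 1.0]])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            coda.closure(bad)


class TestGroupStructure:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(parts(3, 6), parts(3, 6), parts(3, 6))
    def test_abelian_group_axioms(self, a, b, c):
        d = min(len(a), len(b), len(c))
        x, y, z = (coda.closure(v[:d]) for v in (a, b, c))
        neutral = np.full(d, 1.0 / d)
        np.testing.assert_allclose(coda.perturb(x, neutral), x, rtol=1e-10)
        np.testing.assert_allclose(coda.perturb(x, coda.power(x, -1)), neutral, rtol=1e-10)
        np.testing.assert_allclose(
            coda.perturb(coda.perturb(x, y), z),
            coda.perturb(x, coda.perturb(y, z)),
            rtol=1e-10,
        )
        np.testing.assert_allclose(coda.perturb(x, y), coda.perturb(y, x), rtol=1e-12)
        np.testing.assert_allclose(coda.power(x, 0.0), neutral, rtol=1e-12)


class TestClrIlr:
    def test_clr_example(self):
        np.testing.assert_allclose(
            coda.clr([0.25, 0.25, 0.5]), [-0.23105, -0.23105, 0.46210], atol=1e-5
        )

    def test_clr_neutral_is_zero(self):
        np.testing.assert_allclose(coda.clr([1 / 3] * 3), np.zeros(3), atol=1e-15)

    def test_ilr_two_parts(self):
        np.testing.assert_allclose(coda.ilr([0.5, 0.5]), [0.0], atol=1e-15)

    def test_ilr_three_part_example(self):
        # balance basis: z1 = sqrt(1/2) ln(x1/x2), z2 = sqrt(2/3) ln(g(x1,x2)/x3)
        # oracle: z2 = sqrt(2/3)*ln(0.25/0.5) = -0.565952
        np.testing.assert_allclose(
            coda.ilr([0.25, 0.25, 0.5]), [0.0, np.sqrt(2 / 3) * np.log(0.5)], atol=1e-12
        )

    def test_basis_is_orthonormal_contrast(self):
        for d in (2, 3, 5, 31):
            psi = coda.ilr_basis(d)
            np.testing.assert_allclose(psi @ psi.T, np.eye(d - 1), atol=1e-12)
            np.testing.assert_allclose(psi.sum(axis=1), 0.0, atol=1e-12)

    def test_ilr_basis_rejects_single_part(self):
        with pytest.raises(ValueError):
            coda.ilr_basis(1)

    def test_roundtrips_and_consistency(self, rng):
        X = random_compositions(rng, 50, 7)
        np.testing.assert_allclose(coda.clr_inv(coda.clr(X)), X, atol=1e-12)
        np.testing.assert_allclose(coda.ilr_inv(coda.ilr(X)), X, atol=1e-12)
        psi = coda.ilr_basis(7)
        np.testing.assert_allclose(coda.ilr(X), coda.clr(X) @ psi.T, atol=1e-12)
        assert np.abs(coda.clr(X).sum(axis=1)).max() < 1e-12

    def test_skbio_clr_cross_check(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        X = random_compositions(rng, 20, 5)
        np.testing.assert_allclose(coda.clr(X), skbio_comp.clr(X), atol=1e-10)
        np.testing.assert_allclose(
            coda.closure(X * 3.7), skbio_comp.closure(X * 3.7), atol=1e-12
        )


class TestDistance:
    def test_isometry(self, rng):
        X = random_compositions(rng, 20, 9)
        for i in range(0, 18, 2):
            x, y = X[i], X[i + 1]
            d = coda.aitchison_distance(x, y)
            assert d == pytest.approx(np.linalg.norm(coda.ilr(x) - coda.ilr(y)), abs=1e-10)
            assert d == pytest.approx(np.linalg.norm(coda.clr(x) - coda.clr(y)), abs=1e-10)

    def test_identity_and_symmetry(self, comp_pair):
        x, y = comp_pair
        assert coda.aitchison_distance(x, x) == 0.0
        assert coda.aitchison_distance(x, y) == pytest.approx(
            coda.aitchison_distance(y, x), rel=1e-14
        )

    def test_perturbation_and_scale_invariance(self, rng):
        x, y, p = random_compositions(rng, 3, 6)
        d = coda.aitchison_distance(x, y)
        assert coda.aitchison_distance(
            coda.perturb(x, p), coda.perturb(y, p)
        ) == pytest.approx(d, rel=1e-10)
        assert coda.aitchison_distance(2.0 * x, y) == pytest.approx(d, rel=1e-10)

    def test_distance_matrix_matches_pairwise(self, rng):
        X = random_compositions(rng, 12, 5)
        D = coda.aitchison_distance_matrix(X)
        assert D.shape == (12, 12)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(
                    coda.aitchison_distance(X[i], X[j]), abs=1e-8
                )


class TestVariationMatrix:
    def test_proportional_parts_have_zero_link(self, rng):
        base = rng.lognormal(size=20)
        X = coda.closure(np.column_stack([base, 3.0 * base, rng.lognormal(size=20)]))
        T = coda.variation_matrix(X)
        assert T[0, 1] == pytest.approx(0.0, abs=1e-20)
        assert T[0, 2] > 0

    def test_symmetric_zero_diagonal(self, rng):
        T = coda.variation_matrix(random_compositions(rng, 15, 6))
        np.testing.assert_allclose(T, T.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(T), 0.0, atol=1e-15)

    def test_two_part_variance_oracle(self):
        # two compositions with log-ratio values {0, 2}: sample variance 2
        X = coda.closure(np.array([[1.0, 1.0], [np.e**2, 1.0]]))
        assert coda.variation_matrix(X)[0, 1] == pytest.approx(2.0, rel=1e-12)

    def test_total_variance_matches_ilr(self, rng):
        X = random_compositions(rng, 40, 8)
        ilr_total = np.var(coda.ilr(X), axis=0, ddof=1).sum()
        assert coda.total_variance(X) == pytest.approx(ilr_total, abs=1e-8)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            coda.variation_matrix(np.array([[0.5, 0.5]]))


class TestCentering:
    def test_single_row_goes_neutral(self):
        xc, center = coda.center_data(np.array([0.7, 0.2, 0.1]))
        np.testing.assert_allclose(xc, 1 / 3, atol=1e-12)
        np.testing.assert_allclose(center, [0.7, 0.2, 0.1], atol=1e-12)

    def test_idempotent_and_distance_preserving(self, rng):
        X = random_compositions(rng, 25, 5)
        Xc, _ = coda.center_data(X)
        Xcc, center2 = coda.center_data(Xc)
        np.testing.assert_allclose(Xcc, Xc, atol=1e-10)
        np.testing.assert_allclose(center2, 0.2, atol=1e-10)
        np.testing.assert_allclose(
            coda.aitchison_distance_matrix(X),
            coda.aitchison_distance_matrix(Xc),
            atol=1e-8,
        )

    def test_geometric_center_is_barycenter(self, rng):
        Xc, _ = coda.center_data(random_compositions(rng, 30, 4))
        gm = coda.closure(np.exp(np.log(Xc).mean(axis=0)))
        np.testing.assert_allclose(gm, 0.25, atol=1e-10)


class TestSubcomposition:
    def test_full_subset_is_identity(self):
        x = coda.closure([1, 2, 3.0])
        np.testing.assert_allclose(
            coda.subcomposition(x, ["a", "b", "c"], ["a", "b", "c"]), x, rtol=1e-14
        )

    def test_subcompositional_dominance(self, rng):
        labels = list("abcdefgh")
        X = random_compositions(rng, 10, 8)
        for i in range(0, 8, 2):
            x, y = X[i], X[i + 1]
            full = coda.aitchison_distance(x, y)
            sub = coda.aitchison_distance(
                coda.subcomposition(x, labels, ["b", "d", "g"]),
                coda.subcomposition(y, labels, ["b", "d", "g"]),
            )
            assert sub <= full + 1e-12

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            coda.subcomposition([0.5, 0.5], ["a", "b"], ["a", "z"])


class TestTernary:
    def test_barycenter(self):
        np.testing.assert_allclose(
            coda.ternary_coords([1 / 3] * 3), [0.5, np.sqrt(3) / 6], atol=1e-12
        )

    def test_vertices(self):
        eps = 1e-9
        v1 = coda.ternary_coords([1 - 2 * eps, eps, eps])
        v2 = coda.ternary_coords([eps, 1 - 2 * eps, eps])
        v3 = coda.ternary_coords([eps, eps, 1 - 2 * eps])
        np.testing.assert_allclose(v1, [0, 0], atol=1e-8)
        np.testing.assert_allclose(v2, [1, 0], atol=1e-8)
        np.testing.assert_allclose(v3, [0.5, np.sqrt(3) / 2], atol=1e-8)

    def test_wrong_dimension(self):
        with pytest.raises(ValueError):
            coda.ternary_coords([0.5, 0.5])


class TestCompositionClass:
    def test_labels_and_ops(self):
        x = Composition(np.array([1.0, 1.0, 2.0]), ("a", "b", "c"))
        assert x.n_parts == 3
        np.testing.assert_allclose(x.parts, [0.25, 0.25, 0.5])
        neutral = Composition.neutral(("a", "b", "c"))
        assert x.perturb(neutral).parts == pytest.approx(x.parts)
        assert x.perturb(x.inverse()).parts == pytest.approx(neutral.parts)
        assert x.distance(x) == 0.0
        sub = x.subcomposition(["a", "c"])
        assert sub.labels == ("a", "c")

    def test_label_mismatch(self):
        x = Composition(np.array([1.0, 1.0]), ("a", "b"))
        y = Composition(np.array([1.0, 1.0]), ("a", "c"))
        with pytest.raises(ValueError):
            x.perturb(y)
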