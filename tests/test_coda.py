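"""Aitchison-geometry unit and property tests for the 4-part simplex."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timecoda import (
    BEHAVIORS,
    InfeasibleReallocationError,
    all_pivot_bases,
    closure,
    geometric_mean_composition,
    ilr,
    ilr_inverse,
    pivot_basis,
    reallocate,
)
from conftest import direct_pivot_ilr, random_compositions

PAPER_MEANS = np.array([447.3, 583.7, 366.0, 42.6])


class TestClosure:
    def test_equal_parts_close_to_quarters(self):
        assert np.allclose(closure([1, 1, 1, 1], kappa=1.0), 0.25)

    def test_preserves_ratios_and_sums_to_kappa(self):
        c = closure(PAPER_MEANS, kappa=1440.0)
        assert np.isclose(c.sum(), 1440.0)
        assert np.allclose(c / c[0], PAPER_MEANS / PAPER_MEANS[0])

    def test_idempotent(self, rng):
        x = random_compositions(rng, 10)
        assert np.allclose(closure(closure(x)), closure(x), atol=1e-12)

    @pytest.mark.parametrize("bad", [[0, 1, 1, 1], [-1, 2, 3, 4],
                                     [np.nan, 1, 1, 1]])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            closure(bad)


class TestPivotBases:
    @pytest.mark.parametrize("pivot", BEHAVIORS)
    def test_rows_orthonormal_and_centred(self, pivot):
        V = pivot_basis(pivot).matrix
        assert np.abs(V @ V.T - np.eye(3)).max() < 1e-12
        assert np.abs(V.sum(axis=1)).max() < 1e-12

    @pytest.mark.parametrize("pivot", BEHAVIORS)
    def test_gram_is_centring_projector(self, pivot):
        V = pivot_basis(pivot).matrix
        G = np.eye(4) - np.full((4, 4), 0.25)
        assert np.abs(V.T @ V - G).max() < 1e-12

    def test_mvpa_pivot_first_row_coefficients(self):
        row = pivot_basis("mvpa").matrix[0]
        assert np.isclose(row[3], np.sqrt(3 / 4))
        assert np.allclose(row[:3], -np.sqrt(1 / 12))

    def test_bases_related_by_orthogonal_rotation(self):
        bases = all_pivot_bases()
        for a in bases:
            for b in bases:
                R = a.matrix @ b.matrix.T
                assert np.abs(R @ R.T - np.eye(3)).max() < 1e-12

    def test_four_distinct_bases(self):
        mats = [b.matrix for b in all_pivot_bases()]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.allclose(mats[i], mats[j])


class TestIlr:
    @pytest.mark.parametrize("pivot", BEHAVIORS)
    def test_equal_composition_maps_to_zero(self, pivot):
        z = ilr(np.full(4, 0.25), pivot_basis(pivot))
        assert np.abs(z).max() < 1e-12

    @pytest.mark.parametrize("pivot_index", range(4))
    def test_matches_direct_pivot_formula(self, pivot_index):
        comp = closure(PAPER_MEANS)
        z = ilr(comp, pivot_basis(pivot_index))
        expected = direct_pivot_ilr(comp, pivot_index)
        assert np.abs(z - expected).max() < 1e-12

    def test_scale_invariant(self, rng):
        x = random_compositions(rng, 20)
        b = pivot_basis("sb")
        assert np.allclose(ilr(x, b), ilr(closure(x, 1.0), b), atol=1e-10)

    def test_norm_equal_across_bases(self, rng):
        x = random_compositions(rng, 20)
        norms = [np.linalg.norm(ilr(x, b), axis=1) for b in all_pivot_bases()]
        for n in norms[1:]:
            assert np.allclose(n, norms[0], atol=1e-10)

    def test_isometry_matches_direct_aitchison_distance(self, rng):
        # Euclidean distance of ILR images vs clr-space distance, computed
        # directly from logs without the contrast matrix.
        x = random_compositions(rng, 30)
        y = random_compositions(rng, 30)
        b = pivot_basis("lpa")
        d_ilr = np.linalg.norm(ilr(x, b) - ilr(y, b), axis=1)
        clr = lambda m: np.log(m) - np.log(m).mean(axis=1, keepdims=True)
        d_ait = np.linalg.norm(clr(x) - clr(y), axis=1)
        assert np.allclose(d_ilr, d_ait, atol=1e-9)

    def test_matches_scikit_bio_reference(self, rng):
        from skbio.stats.composition import ilr as skbio_ilr
        x = closure(random_compositions(rng, 15), 1.0)
        for b in all_pivot_bases():
            ref = skbio_ilr(x, basis=b.matrix)
            assert np.allclose(ilr(x, b), ref, atol=1e-9)

    @given(st.lists(st.floats(-8, 8), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_round_trip_from_coordinates(self, zlist):
        b = pivot_basis("sleep")
        z = np.array(zlist)
        assert np.abs(ilr(ilr_inverse(z, b), b) - z).max() < 1e-9

    @given(st.lists(st.floats(0.5, 1400), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_round_trip_from_compositions(self, parts):
        b = pivot_basis("mvpa")
        comp = closure(parts)
        back = ilr_inverse(ilr(comp, b), b)
        assert np.abs(back - comp).max() < 1e-9

    def test_inverse_rejects_huge_coordinates(self):
        with pytest.raises(ValueError):
            ilr_inverse(np.array([1e4, 0, 0]), pivot_basis(0))


class TestGeometricMean:
    def test_single_composition_is_identity(self):
        c = closure(PAPER_MEANS)
        assert np.allclose(geometric_mean_composition([c]), c, atol=1e-10)

    def test_two_compositions_hand_computed(self):
        a = np.array([400.0, 600.0, 400.0, 40.0])
        b = np.array([500.0, 560.0, 340.0, 40.0])
        raw = np.sqrt(a * b)
        expected = 1440.0 * raw / raw.sum()
        got = geometric_mean_composition(np.vstack([a, b]))
        assert np.allclose(got, expected, atol=1e-9)

    def test_equals_ilr_coordinate_mean_route(self, rng):
        x = random_compositions(rng, 25)
        for b in all_pivot_bases():
            via_ilr = ilr_inverse(ilr(x, b).mean(axis=0), b)
            assert np.abs(geometric_mean_composition(x) - via_ilr).max() < 1e-9


class TestReallocate:
    def test_zero_delta_is_identity(self):
        c = closure(PAPER_MEANS)
        assert np.array_equal(reallocate(c, "sb", "mvpa", 0.0), c)

    def test_moves_minutes_and_conserves_total(self):
        c = closure(PAPER_MEANS)
        r = reallocate(c, "sb", "mvpa", 15.0)
        assert np.isclose(r[1], c[1] - 15) and np.isclose(r[3], c[3] + 15)
        assert np.isclose(r[0], c[0]) and np.isclose(r[2], c[2])
        assert np.isclose(r.sum(), 1440.0)

    def test_inverse_pair_restores_exactly(self, rng):
        # parts bounded below 60 min so the 30-min move stays feasible
        x = closure(rng.uniform(100, 600, size=(5, 4)))
        for c in x:
            r = reallocate(reallocate(c, "sleep", "lpa", 30.0),
                           "lpa", "sleep", 30.0)
            assert np.array_equal(r, c)

    @pytest.mark.parametrize("delta", [45.0, 60.0])
    @pytest.mark.parametrize("to", ["sleep", "sb", "lpa"])
    def test_displacing_more_than_mvpa_reference_is_infeasible(self, to, delta):
        c = closure(PAPER_MEANS)  # MVPA part is 42.6 min
        with pytest.raises(InfeasibleReallocationError):
            reallocate(c, "mvpa", to, delta)

    def test_same_behavior_rejected(self):
        with pytest.raises(ValueError):
            reallocate(closure(PAPER_MEANS), "sb", "sb", 10.0)
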