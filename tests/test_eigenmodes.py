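"""Spectral layers, band partitions and the oscillation-balance indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seiznet import (
    EffectiveNetworkSnapshot,
    complex_spectrum,
    index_time_course,
    layer_measure,
    oscillation_indices,
    partition_layer,
)

from _oracles import straight_line_indices


def random_adjacency(rng, n, density=0.6, scale=1.0):
    A = rng.uniform(0, scale, size=(n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(A, 0.0)
    return A


class TestComplexSpectrum:
    def test_zero_matrix(self):
        spectrum = complex_spectrum(np.zeros((4, 4)))
        assert np.all(spectrum.eigen_moduli == 0)

    def test_rotation_matrix(self):
        spectrum = complex_spectrum(np.array([[0.0, -1.0], [1.0, 0.0]]))
        assert spectrum.eigen_moduli == pytest.approx([1.0, 1.0])
        assert sorted(spectrum.eigen_angles) == pytest.approx([-np.pi / 2, np.pi / 2])

    def test_moduli_match_characteristic_polynomial_roots(self):
        import sympy

        rng = np.random.default_rng(21)
        A = random_adjacency(rng, 4)
        roots = sympy.Matrix(A.tolist()).charpoly().all_roots()
        expected = sorted((abs(complex(r)) for r in roots), reverse=True)
        assert np.allclose(complex_spectrum(A).eigen_moduli, expected, atol=1e-9)

    def test_conjugate_pairs_share_modulus_and_component_moduli(self):
        rng = np.random.default_rng(2)
        spectrum = complex_spectrum(random_adjacency(rng, 6))
        ang = spectrum.eigen_angles
        complex_layers = (np.abs(ang) > 1e-12) & (np.abs(np.abs(ang) - np.pi) > 1e-12)
        moduli = spectrum.eigen_moduli[complex_layers]
        comp = spectrum.component_moduli[complex_layers]
        # conjugates are adjacent after sorting (equal modulus, angle tie-break)
        for k in range(0, moduli.size - 1, 2):
            assert moduli[k] == pytest.approx(moduli[k + 1], abs=1e-9)
            assert np.allclose(comp[k], comp[k + 1], atol=1e-9)

    def test_schur_inequality(self):
        rng = np.random.default_rng(33)
        A = random_adjacency(rng, 7)
        spectrum = complex_spectrum(A)
        assert np.sum(spectrum.eigen_moduli**2) <= np.sum(A**2) + 1e-9


class TestPartitionLayer:
    def test_equal_components_collapse_to_one_weak_module(self):
        part = partition_layer(np.full(5, 0.3), layer_index=2)
        assert part.M == 1 and part.p == 0.0
        assert set(part.labels) == {"weak"}

    def test_hand_worked_band_example(self):
        # moduli {0.1, 0.1, 0.5, 0.9}: AVG=0.4, SD~0.33; bands at 0.73 / 1.06
        part = partition_layer([0.1, 0.1, 0.5, 0.9], layer_index=3)
        assert part.labels.tolist() == ["weak", "weak", "weak", "balance"]
        assert part.M == 2
        assert part.p == pytest.approx((abs(3 - 2) + abs(1 - 2)) / 4)

    def test_sizes_conserve_nodes_and_p_below_one(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            v = rng.uniform(0, 1, size=int(rng.integers(2, 12)))
            part = partition_layer(v, layer_index=2)
            assert part.module_sizes.sum() == v.size
            assert 0.0 <= part.p < 1.0

    def test_first_layer_is_never_partitioned(self):
        with pytest.raises(ValueError):
            partition_layer([0.5, 0.5], layer_index=1)


class TestLayerMeasure:
    def test_zero_stretch_gives_zero(self):
        part = partition_layer([0.2, 0.8], layer_index=2)
        assert layer_measure(0.0, part, N=2) == 0.0

    def test_direct_formula(self):
        part = partition_layer(np.full(4, 0.5), layer_index=2)  # M=1, p=0
        assert layer_measure(2.0, part, N=4) == pytest.approx(0.25)


class TestOscillationIndices:
    def test_zero_matrix_is_balanced_by_convention(self):
        idx = oscillation_indices(complex_spectrum(np.zeros((4, 4))))
        assert idx.H_in == idx.H_se == 0.0 and idx.H_sb_norm == 0.0

    def test_pure_global_mode_gives_plus_one(self):
        # rank-one uniform coupling: one nonzero eigenvalue, the rest zero
        A = np.ones((4, 4)) / 4
        idx = oscillation_indices(complex_spectrum(A))
        assert idx.H_se == pytest.approx(0.0, abs=1e-12)
        assert idx.H_sb_norm == pytest.approx(1.0)

    def test_directed_ring_is_strongly_local(self):
        # N equal-modulus modes: H_se = (N-1) H_in, so hsb = (2-N)/N
        N = 4
        A = np.roll(np.eye(N), 1, axis=1)
        idx = oscillation_indices(complex_spectrum(A))
        assert idx.H_sb_norm == pytest.approx((2 - N) / N)

    def test_matches_straight_line_reimplementation(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            A = random_adjacency(rng, int(rng.integers(3, 9)))
            idx = oscillation_indices(complex_spectrum(A))
            H_in, H_se, hsb = straight_line_indices(A)
            assert idx.H_in == pytest.approx(H_in, abs=1e-12)
            assert idx.H_se == pytest.approx(H_se, abs=1e-10)
            assert idx.H_sb_norm == pytest.approx(hsb, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_bounds_on_random_nonnegative_matrices(self, seed):
        rng = np.random.default_rng(seed)
        A = random_adjacency(rng, int(rng.integers(2, 13)))
        idx = oscillation_indices(complex_spectrum(A))
        assert idx.H_in >= 0 and idx.H_se >= 0
        assert -1.0 <= idx.H_sb_norm <= 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        A = random_adjacency(rng, 6)
        perm = rng.permutation(6)
        B = A[np.ix_(perm, perm)]
        ia = oscillation_indices(complex_spectrum(A))
        ib = oscillation_indices(complex_spectrum(B))
        assert ia.H_in == pytest.approx(ib.H_in, abs=1e-9)
        assert ia.H_se == pytest.approx(ib.H_se, abs=1e-9)
        assert ia.H_sb_norm == pytest.approx(ib.H_sb_norm, abs=1e-9)

    def test_scale_law(self):
        rng = np.random.default_rng(9)
        A = random_adjacency(rng, 5)
        c = 3.7
        ia = oscillation_indices(complex_spectrum(A))
        ic = oscillation_indices(complex_spectrum(c * A))
        assert ic.H_in == pytest.approx(c**2 * ia.H_in)
        assert ic.H_se == pytest.approx(c**2 * ia.H_se)
        assert ic.H_sb_norm == pytest.approx(ia.H_sb_norm, abs=1e-9)


class TestIndexTimeCourse:
    def test_zero_snapshots_give_zero_indices(self):
        snaps = [EffectiveNetworkSnapshot(time=t, A=np.zeros((4, 4))) for t in (10, 20)]
        for idx in index_time_course(snaps):
            assert idx.H_in == idx.H_se == idx.H_sb_norm == 0.0

    def test_node_relabelling_leaves_course_unchanged(self):
        rng = np.random.default_rng(10)
        A = random_adjacency(rng, 5)
        perm = rng.permutation(5)
        a = index_time_course([EffectiveNetworkSnapshot(time=1, A=A)])[0]
        b = index_time_course([EffectiveNetworkSnapshot(time=1, A=A[np.ix_(perm, perm)])])[0]
        assert a.H_sb_norm == pytest.approx(b.H_sb_norm, abs=1e-9)

    def test_global_max_normalization_stays_in_bounds(self):
        rng = np.random.default_rng(12)
        snaps = [
            EffectiveNetworkSnapshot(time=t, A=random_adjacency(rng, 5))
            for t in range(5)
        ]
        course = index_time_course(snaps, hsb_normalization="global_max")
        norms = [abs(ix.H_sb_norm) for ix in course]
        assert max(norms) == pytest.approx(1.0)
        assert all(n <= 1.0 + 1e-12 for n in norms)
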