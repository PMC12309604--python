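"""HILLS parsing, bias summation, FES construction and landscape analysis."""

import math

import numpy as np
import pytest

from sugarstack.fes_analysis import (
    FESGrid,
    HillsFormatError,
    HillsTable,
    KJ_PER_KCAL,
    LineProfile,
    average_replicas,
    barrier_between,
    basin_region,
    bias_potential,
    binding_free_energy,
    fes_from_bias,
    kcal_to_kj,
    kj_to_kcal,
    line_profile,
    make_axis,
    minimax_path_barrier,
    read_hills,
    write_hills,
)


def _hills(n=3, seed=0, gamma=20.0):
    rng = np.random.default_rng(seed)
    return HillsTable(
        time=np.arange(n, dtype=float),
        centers=rng.uniform(-1, 1, (n, 2)),
        sigmas=rng.uniform(0.05, 0.3, (n, 2)),
        heights=rng.uniform(0.0, 1.0, n),
        bias_factor=gamma,
    )


class TestHillsIO:
    def test_round_trip(self, tmp_path):
        table = _hills(10)
        path = tmp_path / "HILLS"
        write_hills(table, path)
        back = read_hills(path)
        assert np.allclose(back.time, table.time)
        assert np.allclose(back.centers, table.centers, rtol=1e-9)
        assert np.allclose(back.sigmas, table.sigmas, rtol=1e-9)
        assert np.allclose(back.heights, table.heights, rtol=1e-9)
        assert back.bias_factor == table.bias_factor
        assert back.cv_names == ("cv1", "cv2")

    def test_literal_three_row_file(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text(
            "#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf\n"
            "1.0 0.5 0.6 0.1 0.2 0.05 20\n"
            "2.0 0.7 0.8 0.1 0.2 0.04 20\n"
            "3.0 0.9 1.0 0.1 0.2 0.03 20\n")
        table = read_hills(path)
        assert len(table) == 3
        assert np.allclose(table.centers[1], [0.7, 0.8])
        assert np.allclose(table.heights, [0.05, 0.04, 0.03])
        assert table.bias_factor == 20.0

    def test_missing_height_column(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text("#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 biasf\n"
                        "1.0 0.5 0.6 0.1 0.2 20\n")
        with pytest.raises(HillsFormatError):
            read_hills(path)

    def test_missing_fields_header(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text("1.0 0.5 0.6 0.1 0.2 0.05 20\n")
        with pytest.raises(HillsFormatError):
            read_hills(path)

    def test_varying_bias_factor_rejected(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text(
            "#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf\n"
            "1.0 0.5 0.6 0.1 0.2 0.05 20\n"
            "2.0 0.7 0.8 0.1 0.2 0.04 10\n")
        with pytest.raises(HillsFormatError):
            read_hills(path)

    def test_columns_mapped_by_name_not_position(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text(
            "#! FIELDS time height d1 d2 sigma_d1 sigma_d2 biasf\n"
            "1.0 0.05 0.5 0.6 0.1 0.2 20\n")
        table = read_hills(path)
        assert table.cv_names == ("d1", "d2")
        assert np.allclose(table.centers[0], [0.5, 0.6])
        assert table.heights[0] == pytest.approx(0.05)

    def test_invariants(self):
        with pytest.raises(ValueError):
            HillsTable(np.array([0.0]), [[0, 0]], [[0.1, -0.1]], [0.1], 20.0)
        with pytest.raises(ValueError):
            HillsTable(np.array([0.0]), [[0, 0]], [[0.1, 0.1]], [-0.1], 20.0)
        with pytest.raises(ValueError):
            HillsTable(np.array([0.0]), [[0, 0]], [[0.1, 0.1]], [0.1], 1.0)


class TestBiasPotential:
    def test_single_hill_closed_form(self):
        table = HillsTable(np.array([1.0]), [[0.0, 0.0]], [[0.1, 0.1]],
                           [0.05], 20.0)
        ax = np.array([-0.1, 0.0, 0.1])
        V = bias_potential(table, ax, ax)
        assert V[1, 1] == pytest.approx(0.05, rel=1e-12)
        assert V[2, 1] == pytest.approx(0.05 * math.exp(-0.5), rel=1e-12)
        assert V[2, 2] == pytest.approx(0.05 * math.exp(-1.0), rel=1e-12)

    def test_linearity(self):
        one = _hills(5, seed=1)
        doubled = HillsTable(np.concatenate([one.time, one.time]),
                             np.concatenate([one.centers, one.centers]),
                             np.concatenate([one.sigmas, one.sigmas]),
                             np.concatenate([one.heights, one.heights]),
                             one.bias_factor)
        ax = make_axis(-2, 2, 0.5)
        assert np.allclose(bias_potential(doubled, ax, ax),
                           2 * bias_potential(one, ax, ax), rtol=1e-12)

    def test_row_permutation_invariance(self):
        table = _hills(20, seed=2)
        perm = np.random.default_rng(0).permutation(20)
        shuffled = HillsTable(table.time[perm], table.centers[perm],
                              table.sigmas[perm], table.heights[perm],
                              table.bias_factor)
        ax = make_axis(-2, 2, 0.5)
        assert np.allclose(bias_potential(table, ax, ax),
                           bias_potential(shuffled, ax, ax), rtol=1e-12)

    def test_matches_brute_force_double_loop(self):
        """Vectorized summation equals the naive loop to 1e-10 relative."""
        table = _hills(100, seed=3)
        ax = make_axis(-2, 2, 0.25)
        V = bias_potential(table, ax, ax)
        brute = np.zeros_like(V)
        for k in range(len(table)):
            for i, x in enumerate(ax):
                for j, y in enumerate(ax):
                    brute[i, j] += table.heights[k] * math.exp(
                        -((x - table.centers[k, 0]) ** 2 / (2 * table.sigmas[k, 0] ** 2)
                          + (y - table.centers[k, 1]) ** 2 / (2 * table.sigmas[k, 1] ** 2)))
        assert np.abs(V - brute).max() <= 1e-10 * np.abs(brute).max()


class TestFesFromBias:
    def test_well_depth_scaling(self):
        """γ=20: a 0.19 kcal/mol bias peak maps to a 0.2 kcal/mol well."""
        ax = np.arange(3.0)
        V = np.zeros((3, 3))
        V[1, 1] = 0.19
        fes = fes_from_bias(V, 20.0, ax, ax, energy_unit="kcal/mol")
        assert fes.values.min() == 0.0
        assert fes.values[1, 1] == 0.0
        assert fes.values[0, 0] == pytest.approx(0.2, rel=1e-12)

    def test_zero_bias_flat(self):
        ax = np.arange(4.0)
        fes = fes_from_bias(np.zeros((4, 4)), 20.0, ax, ax)
        assert np.all(fes.values == 0.0)

    def test_rescaled_convention(self):
        ax = np.arange(3.0)
        V = np.zeros((3, 3))
        V[1, 1] = 1.0
        dep = fes_from_bias(V, 20.0, ax, ax, convention="deposited",
                            energy_unit="kcal/mol")
        res = fes_from_bias(V, 20.0, ax, ax, convention="rescaled",
                            energy_unit="kcal/mol")
        assert dep.values[0, 0] == pytest.approx(20 / 19, rel=1e-12)
        assert res.values[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_kj_conversion_and_gamma_validation(self):
        ax = np.arange(2.0)
        V = np.array([[0.0, KJ_PER_KCAL], [0.0, 0.0]])
        fes = fes_from_bias(V, 2.0, ax, ax, energy_unit="kJ/mol")
        assert fes.values.max() == pytest.approx(2.0, rel=1e-12)
        with pytest.raises(ValueError):
            fes_from_bias(V, 1.0, ax, ax)

    def test_unit_round_trip_exact(self):
        x = np.linspace(0.1, 50, 100)
        assert np.allclose(kj_to_kcal(kcal_to_kj(x)), x, rtol=1e-12, atol=0)


class TestAverageReplicas:
    def test_identical_surfaces(self):
        ax = np.arange(5.0)
        F = np.random.default_rng(0).uniform(0, 3, (5, 5))
        F -= F.min()
        fes = FESGrid(ax, ax, F)
        avg = average_replicas([fes, fes, fes])
        assert np.allclose(avg.values, F, rtol=1e-12)

    def test_additive_constant_removed(self):
        ax = np.arange(5.0)
        F = np.random.default_rng(1).uniform(0, 3, (5, 5))
        F -= F.min()
        reps = [FESGrid(ax, ax, F + c) for c in (0.0, 5.0, -2.0)]
        avg = average_replicas(reps)
        assert np.allclose(avg.values, F, rtol=1e-12)

    def test_pointwise_mean(self):
        ax = np.arange(4.0)
        rng = np.random.default_rng(2)
        surfaces = [rng.uniform(0, 3, (4, 4)) for _ in range(3)]
        reps = [FESGrid(ax, ax, s - s.min()) for s in surfaces]
        manual = np.mean([s - s.min() for s in surfaces], axis=0)
        manual -= manual.min()
        assert np.allclose(average_replicas(reps).values, manual, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = FESGrid(np.arange(4.0), np.arange(4.0), np.zeros((4, 4)))
        b = FESGrid(np.arange(5.0), np.arange(5.0), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            average_replicas([a, b])


class TestBasin:
    def _two_well_grid(self):
        """20×20: wells at (5,5)=0 and (14,14)=0.5 split by a 3 kcal ridge."""
        ax = np.arange(20.0)
        F = np.full((20, 20), 3.0)
        F[2:9, 2:9] = 1.0
        F[5, 5] = 0.0
        F[11:18, 11:18] = 1.2
        F[14, 14] = 0.5
        return FESGrid(ax, ax, F)

    def test_single_well_mask(self):
        ax = np.arange(10.0)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        F = 0.1 * ((xx - 5) ** 2 + (yy - 5) ** 2)
        fes = FESGrid(ax, ax, F)
        mask = basin_region(fes, cutoff=1.5)
        assert np.array_equal(mask, F <= 1.5)

    def test_disconnected_well_excluded(self):
        fes = self._two_well_grid()
        mask = basin_region(fes, cutoff=1.5)
        assert mask[5, 5]
        assert mask[3, 3]
        assert not mask[14, 14]     # below cutoff but across the ridge
        assert not mask[11, 11]

    def test_zero_cutoff_minimum_component(self):
        fes = self._two_well_grid()
        mask = basin_region(fes, cutoff=0.0)
        assert mask.sum() == 1
        assert mask[5, 5]

    def test_connectivity_option(self):
        ax = np.arange(3.0)
        F = np.full((3, 3), 5.0)
        F[0, 0] = 0.0
        F[1, 1] = 1.0
        fes = FESGrid(ax, ax, F)
        assert basin_region(fes, cutoff=1.5, connectivity=8)[1, 1]
        assert not basin_region(fes, cutoff=1.5, connectivity=4)[1, 1]


class TestLineProfile:
    def test_constant_surface(self):
        ax = make_axis(6, 14, 0.1)
        fes = FESGrid(ax, ax, np.full((len(ax), len(ax)), 2.0))
        prof = line_profile(fes, a=-1.1, b=19.4)
        assert np.allclose(prof.values, 2.0, rtol=1e-12)
        assert np.allclose(prof.cv1 * -1.1 + 19.4, prof.cv2, atol=1e-9)

    def test_planar_surface_identity_in_cv2(self):
        ax = make_axis(6, 14, 0.1)
        fes = FESGrid(ax, ax, np.tile(ax, (len(ax), 1)))
        for a, b in ((-1.1, 19.4), (-0.4, 13.4)):
            prof = line_profile(fes, a=a, b=b)
            assert np.allclose(prof.values, prof.cv2, atol=1e-9)

    def test_matches_independent_bilinear_oracle(self, rng):
        ax1 = make_axis(0, 5, 0.25)
        ax2 = make_axis(0, 4, 0.2)
        F = rng.uniform(0, 10, (len(ax1), len(ax2)))
        fes = FESGrid(ax1, ax2, F)
        prof = line_profile(fes, a=0.7, b=0.3, step=0.05)

        def bilinear(x, y):
            i = min(np.searchsorted(ax1, x, "right") - 1, len(ax1) - 2)
            j = min(np.searchsorted(ax2, y, "right") - 1, len(ax2) - 2)
            tx = (x - ax1[i]) / (ax1[i + 1] - ax1[i])
            ty = (y - ax2[j]) / (ax2[j + 1] - ax2[j])
            return ((1 - tx) * (1 - ty) * F[i, j] + tx * (1 - ty) * F[i + 1, j]
                    + (1 - tx) * ty * F[i, j + 1] + tx * ty * F[i + 1, j + 1])

        expected = [bilinear(x, y) for x, y in zip(prof.cv1, prof.cv2)]
        assert np.allclose(prof.values, expected, atol=1e-9)

    def test_line_outside_grid_rejected(self):
        ax = make_axis(6, 14, 0.1)
        fes = FESGrid(ax, ax, np.zeros((len(ax), len(ax))))
        with pytest.raises(ValueError):
            line_profile(fes, a=1.0, b=100.0)
        with pytest.raises(ValueError):
            line_profile(fes, a=0.0, b=10.0)


class TestBarriers:
    def test_w_shaped_profile(self):
        prof = LineProfile(1.0, 0.0, np.arange(5.0),
                           np.array([0.0, 2.0, 4.0, 3.0, 1.0]))
        res = barrier_between(prof, (0, 0.5), (3.5, 4.5))
        assert res.basin_a == 0.0
        assert res.basin_b == 1.0
        assert res.transition == 4.0
        assert res.forward == 4.0
        assert res.reverse == 3.0

    def test_monotone_profile(self):
        prof = LineProfile(1.0, 0.0, np.arange(6.0),
                           np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5]))
        res = barrier_between(prof, (0, 1), (4, 5))
        assert res.transition == pytest.approx(2.0)
        assert res.forward == pytest.approx(2.0)
        assert res.reverse == pytest.approx(0.0)

    def test_double_gaussian_well_matches_scan_oracle(self):
        cv2 = np.arange(0.0, 10.0001, 0.02)
        F = (3.0 - 2.5 * np.exp(-((cv2 - 2.5) ** 2) / 0.5)
             - 3.0 * np.exp(-((cv2 - 7.5) ** 2) / 0.5))
        F -= F.min()
        prof = LineProfile(1.0, 0.0, cv2, F)
        res = barrier_between(prof, (1.5, 3.5), (6.5, 8.5))
        ia = np.argmin(np.where((cv2 >= 1.5) & (cv2 <= 3.5), F, np.inf))
        ib = np.argmin(np.where((cv2 >= 6.5) & (cv2 <= 8.5), F, np.inf))
        assert res.basin_a == pytest.approx(F[ia])
        assert res.basin_b == pytest.approx(F[ib])
        assert res.transition == pytest.approx(F[ia:ib + 1].max())
        assert res.transition >= max(res.basin_a, res.basin_b)

    def test_empty_window_rejected(self):
        prof = LineProfile(1.0, 0.0, np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            barrier_between(prof, (10, 11), (0, 1))


class TestMinimaxPath:
    def test_three_by_three_example(self):
        F = np.array([[0, 5, 9], [9, 5, 9], [9, 5, 0]], float)
        fes = FESGrid(np.arange(3.0), np.arange(3.0), F)
        assert minimax_path_barrier(fes, (0, 0), (2, 2)) == 5.0

    def test_same_cell(self):
        F = np.array([[0, 5, 9], [9, 5, 9], [9, 5, 0]], float)
        fes = FESGrid(np.arange(3.0), np.arange(3.0), F)
        assert minimax_path_barrier(fes, (1, 1), (1, 1)) == 5.0

    def test_bounded_by_any_explicit_path(self, rng):
        F = rng.uniform(0, 10, (15, 15))
        fes = FESGrid(np.arange(15.0), np.arange(15.0), F)
        a, b = (0, 0), (14, 14)
        best = minimax_path_barrier(fes, a, b)
        diagonal = [F[i, i] for i in range(15)]
        assert best <= max(diagonal)

    def test_cell_outside_grid(self):
        fes = FESGrid(np.arange(3.0), np.arange(3.0), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            minimax_path_barrier(fes, (0, 0), (5, 5))


class TestBindingFreeEnergy:
    def test_well_below_plateau(self):
        ax = np.arange(10.0)
        F = np.full((10, 10), 5.0)
        F[2, 2] = 0.0
        fes = FESGrid(ax, ax, F)
        bound = np.zeros((10, 10), bool)
        bound[:4, :4] = True
        unbound = np.zeros((10, 10), bool)
        unbound[6:, 6:] = True
        assert binding_free_energy(fes, bound, unbound) == pytest.approx(-5.0)

    def test_equal_levels_give_zero(self):
        ax = np.arange(4.0)
        fes = FESGrid(ax, ax, np.full((4, 4), 1.0))
        bound = np.zeros((4, 4), bool)
        bound[0, 0] = True
        unbound = np.zeros((4, 4), bool)
        unbound[3, 3] = True
        assert binding_free_energy(fes, bound, unbound) == 0.0

    def test_random_depth_recovered(self, rng):
        depth = float(rng.uniform(1.0, 8.0))
        ax = np.arange(8.0)
        F = np.full((8, 8), depth)
        F[1, 1] = 0.0
        fes = FESGrid(ax, ax, F)
        bound = np.zeros((8, 8), bool)
        bound[:3, :3] = True
        unbound = ~bound
        assert binding_free_energy(fes, bound, unbound) == pytest.approx(-depth)

    def test_mask_validation(self):
        ax = np.arange(4.0)
        fes = FESGrid(ax, ax, np.zeros((4, 4)))
        empty = np.zeros((4, 4), bool)
        full = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            binding_free_energy(fes, empty, full)
        with pytest.raises(ValueError):
            binding_free_energy(fes, full, full)
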