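"""Mean-shift vectors, the approximation chain and mode finding."""

import numpy as np
import pytest

from fmshift import (
    MixtureSpec,
    MsvParams,
    exact_msv,
    exact_square_msv,
    fast_msv,
    find_modes,
    make_point_cloud,
    seek_mode,
)
from conftest import feats_from_points, grid_and_tables


class TestExactMsv:
    def test_single_point_at_centre_is_stationary(self):
        assert np.allclose(exact_msv([[1.0, 1.0]], [1.0, 1.0], h=2.0), 0)

    def test_symmetric_neighbourhood_cancels(self):
        x = np.array([0.5, -0.5])
        d = 0.7
        pts = [x + (d, 0), x - (d, 0), x + (0, d), x - (0, d)]
        assert np.allclose(exact_msv(pts, x, h=1.0), 0, atol=1e-12)

    def test_spherical_membership_hand_case(self):
        # only (0,0) and (2,0) fall inside the radius-2.5 sphere at the origin
        v = exact_msv([(0, 0), (2, 0), (4, 0)], (0, 0), h=2.5)
        assert np.allclose(v, (1.0, 0.0))

    def test_empty_point_list_rejected(self):
        with pytest.raises(ValueError):
            exact_msv([], (0, 0), h=1.0)


class TestExactSquareMsv:
    def test_corner_point_separates_square_from_sphere(self):
        # (h, h) is inside the circumscribing square but outside the sphere
        pts = [(0.0, 0.0), (1.0, 1.0)]
        assert np.allclose(exact_msv(pts, (0, 0), h=1.0), 0)
        assert np.allclose(exact_square_msv(pts, (0, 0), h=1.0), (0.5, 0.5))

    def test_matches_filter_then_average(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(50, 2)) * 3
            x = rng.normal(size=2)
            h = rng.uniform(0.5, 4.0)
            inside = np.abs(pts - x).max(axis=1) <= h
            expect = pts[inside].mean(axis=0) - x if inside.any() else np.zeros(2)
            assert np.allclose(exact_square_msv(pts, x, h), expect)


class TestFastMsv:
    def test_matches_square_msv_on_cell_centre_snapped_points(self, rng):
        # replacing each point by its cell centre, the four-lookup MSV is the
        # square-window MSV computed directly — this is the whole approximation
        for _ in range(20):
            pts = rng.uniform(-5, 5, size=(100, 2))
            e = rng.uniform(0.05, 0.3)
            grid, tables = grid_and_tables(pts, e)
            p = MsvParams(h=40 * e, e=e)
            m, n = grid.occupied_cells()[rng.integers((grid.w > 0).sum())]
            x = grid.c[m, n]
            snapped = np.repeat(
                grid.c.reshape(-1, 2), grid.w.ravel(), axis=0)
            # half-cell margin keeps exactly the cells the four lookups cover,
            # immune to centres landing on the square boundary up to rounding
            expect = exact_square_msv(snapped, x, h=e * (2 * p.h_c + 1))
            assert np.allclose(fast_msv(tables, grid, x, p), expect, atol=1e-9)

    def test_whole_grid_window_gives_centroid_shift(self, rng):
        pts = rng.uniform(0, 2, size=(60, 2))
        e = 0.05
        grid, tables = grid_and_tables(pts, e)
        p = MsvParams(h=1000.0, e=e)  # window covers everything
        x = np.array([0.7, 0.9])
        snapped_mean = (grid.w[..., None] * grid.c).sum(axis=(0, 1)) / grid.n_points
        assert np.allclose(fast_msv(tables, grid, x, p), snapped_mean - x)

    def test_single_occupied_cell_is_stationary(self):
        grid, tables = grid_and_tables([[1.0, 1.0]] * 5 + [[9.0, 9.0]], e=0.1)
        p = MsvParams(h=2.0, e=0.1)
        m, n = 0, 0
        x = grid.c[m, n]
        v, mass = fast_msv(tables, grid, x, p, return_mass=True)
        assert mass == 5 and np.allclose(v, 0, atol=1e-12)


class TestSeekMode:
    def test_isolated_cell_converges_immediately(self):
        grid, tables = grid_and_tables([[0.0, 0.0]] * 4 + [[50.0, 0.0]], e=0.05)
        p = MsvParams(h=1.0, e=0.05)
        res = seek_mode(grid.c[0, 0], tables, grid, p)
        assert res.converged and res.n_iter == 0
        assert np.allclose(res.point, grid.c[0, 0])

    def test_vacuum_window_terminates_at_start(self):
        grid, tables = grid_and_tables([[0.0, 0.0]] * 5 + [[100.0, 0.0]] * 5, e=0.05)
        p = MsvParams(h=2.0, e=0.05)
        start = np.array([50.0, 0.0])  # empty middle, window mass zero
        res = seek_mode(start, tables, grid, p)
        assert res.vacuum and not res.converged
        assert np.allclose(res.point, start)

    def test_converges_into_the_right_basin(self, rng):
        spec = MixtureSpec(means=((0.0, 0.0), (20.0, 0.0)), sigmas=(1.0, 1.0),
                           weights=(0.5, 0.5), n=2000, seed=5)
        pts, lbl = make_point_cloud(spec)
        e = 0.05
        grid, tables = grid_and_tables(pts, e)
        p = MsvParams(h=2.0, e=e)
        res = seek_mode(np.array([1.5, 0.5]), tables, grid, p)
        assert res.converged
        assert np.linalg.norm(res.point - pts[lbl == 0].mean(axis=0)) < p.h


class TestFindModes:
    @staticmethod
    def _mixture(k, n=3000, sep=20.0, seed=9):
        means = tuple((sep * i, 0.5 * sep * (i % 2)) for i in range(k))
        spec = MixtureSpec(means=means, sigmas=(1.0,) * k,
                           weights=(1.0 / k,) * k, n=n, seed=seed)
        return make_point_cloud(spec)

    def test_single_occupied_cell_single_mode(self):
        grid, tables = grid_and_tables([[2.0, 3.0]] * 7 + [[2.4, 3.0]], e=0.5)
        p = MsvParams(h=5.0, e=0.5)
        ms = find_modes(tables, grid, p)
        assert ms.n_modes == 1 and ms.mode_mass[0] == 8

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_recovers_component_count(self, k):
        pts, _ = self._mixture(k)
        e = 0.05
        grid, tables = grid_and_tables(pts, e)
        ms = find_modes(tables, grid, MsvParams(h=2.0, e=e))
        assert ms.n_modes == k
        assert ms.mode_mass.sum() == grid.n_points

    def test_well_separated_equal_blobs_split_mass(self):
        pts, _ = self._mixture(2, n=4000)
        e = 0.05
        grid, tables = grid_and_tables(pts, e)
        ms = find_modes(tables, grid, MsvParams(h=2.0, e=e))
        assert ms.n_modes == 2
        assert np.abs(ms.mode_mass - 2000).max() < 200

    def test_infinite_merge_radius_forces_one_mode(self):
        pts, _ = self._mixture(3)
        e = 0.05
        grid, tables = grid_and_tables(pts, e)
        ms = find_modes(tables, grid,
                        MsvParams(h=2.0, e=e, merge_radius=np.inf))
        assert ms.n_modes == 1

    def test_every_occupied_cell_assigned_and_masses_conserve(self):
        pts, _ = self._mixture(3)
        e = 0.05
        grid, tables = grid_and_tables(pts, e)
        p = MsvParams(h=2.0, e=e)
        ms = find_modes(tables, grid, p)
        occ = grid.w > 0
        assert (ms.cell_mode[occ] >= 0).all() and (ms.cell_mode[~occ] == -1).all()
        assert ms.mode_mass.sum() == grid.n_points
        assert (np.diff(ms.mode_mass) <= 0).all()  # sorted by mass descending
        # surviving modes are pairwise at least merge_radius apart
        d = np.linalg.norm(ms.modes[:, None] - ms.modes[None, :], axis=2)
        assert (d[np.triu_indices(ms.n_modes, 1)] >= p.merge_radius).all()

    def test_deterministic(self):
        pts, _ = self._mixture(3)
        e = 0.05
        grid, tables = grid_and_tables(pts, e)
        a = find_modes(tables, grid, MsvParams(h=2.0, e=e))
        b = find_modes(tables, grid, MsvParams(h=2.0, e=e))
        assert (a.modes == b.modes).all()
        assert (a.cell_mode == b.cell_mode).all()
        assert (a.mode_mass == b.mode_mass).all()


def test_small_window_warns():
    with pytest.warns(UserWarning, match="h < 10 e"):
        MsvParams(h=0.5, e=0.1)
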