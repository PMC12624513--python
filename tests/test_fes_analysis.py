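"""FES estimator, symmetrization, minima, minimax barriers, block profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antiport import fes_analysis as fa
from antiport import metad_engine as me
from antiport import toy_system as ts
from conftest import brute_force_minimax


def _grid_from(values, lo=-1.0, hi=1.0):
    values = np.asarray(values, dtype=float)
    axes = [np.linspace(lo, hi, n) for n in values.shape]
    return fa.FESGrid(axes=axes, values=values - values.min())


class TestFesFromHills:
    def test_empty_hills_all_zero(self):
        bias = me.BiasState(1, 0.5, 10.0)
        grid = fa.fes_from_hills(bias, [np.linspace(-1, 1, 50)])
        assert np.all(grid.values == 0.0)

    def test_single_hill_closed_form(self):
        """One hill of height h at c with gamma = 10: pre-offset F(c) is
        -(10/9) h, so after the min-zero shift F is 0 at c and (10/9) h in
        the far field."""
        h, gamma = 0.9, 10.0
        bias = me.BiasState(2, h, gamma,
                            hills=[me.Hill(0.0, (0.0, 0.0), (0.2, 0.2), h, gamma)])
        axes = [np.linspace(-2, 2, 81)] * 2
        grid = fa.fes_from_hills(bias, axes)
        center = grid.nearest_index((0.0, 0.0))
        corner = (0, 0)
        assert grid.values[center] == pytest.approx(0.0, abs=1e-12)
        assert grid.values[corner] == pytest.approx(gamma / (gamma - 1) * h, rel=1e-6)

    def test_converged_double_well_recovery(self, dw_run, double_well):
        """RMSE of the estimate against the planted profile < 0.5 kT over
        the region below 10 kT."""
        bias, _ = dw_run
        axes = double_well.grid_axes(200)
        grid = fa.fes_from_hills(bias, axes)
        truth = double_well.energy(axes[0][:, None])
        truth -= truth.min()
        mask = truth <= 10.0
        rmse = float(np.sqrt(np.mean((grid.values[mask] - truth[mask]) ** 2)))
        assert rmse < 0.5

    def test_linear_in_hill_heights(self):
        """Pre-offset, the estimator is linear in hill heights at fixed
        centers and widths."""
        gamma = 8.0
        hills1 = [me.Hill(0.0, (0.3,), (0.2,), 0.4, gamma)]
        hills2 = [me.Hill(0.0, (0.3,), (0.2,), 0.8, gamma)]
        axes = [np.linspace(-1, 1, 41)]
        b1 = me.BiasState(1, 0.4, gamma, hills=hills1)
        b2 = me.BiasState(1, 0.8, gamma, hills=hills2)
        f1 = -(gamma / (gamma - 1)) * b1.values(axes[0][:, None])
        f2 = -(gamma / (gamma - 1)) * b2.values(axes[0][:, None])
        np.testing.assert_allclose(2.0 * f1, f2, rtol=1e-12)


class TestSymmetrize:
    def test_symmetric_input_unchanged(self):
        v = np.random.default_rng(0).random((20, 20))
        v = v + v.T
        grid = _grid_from(v)
        out = fa.symmetrize_fes(grid)
        np.testing.assert_allclose(out.values, grid.values, atol=1e-12)

    def test_planar_surface_averages(self):
        xs = np.linspace(-1, 1, 30)
        v = np.broadcast_to(xs[:, None], (30, 30)).copy()  # F = z1
        grid = _grid_from(v)
        out = fa.symmetrize_fes(grid)
        expect = 0.5 * (xs[:, None] + xs[None, :])
        np.testing.assert_allclose(out.values, expect - expect.min(), atol=1e-12)

    def test_exactly_symmetric_and_idempotent(self):
        v = np.random.default_rng(1).random((40, 40)) * 5
        out = fa.symmetrize_fes(_grid_from(v))
        assert float(np.abs(out.values - out.values.T).max()) == 0.0
        again = fa.symmetrize_fes(out)
        np.testing.assert_allclose(again.values, out.values, atol=1e-12)

    def test_non_square_rejected(self):
        v = np.zeros((10, 12))
        grid = fa.FESGrid(axes=[np.linspace(0, 1, 10), np.linspace(0, 1, 12)], values=v)
        with pytest.raises(ValueError, match="identical axes"):
            fa.symmetrize_fes(grid)


class TestFindMinima:
    def test_single_paraboloid(self):
        xs = np.linspace(-1, 1, 41)
        v = xs[:, None] ** 2 + xs[None, :] ** 2
        minima = fa.find_minima(_grid_from(v))
        assert len(minima) == 1
        assert minima.minima[0].location == pytest.approx((0.0, 0.0))

    def test_flat_surface_empty(self):
        minima = fa.find_minima(_grid_from(np.zeros((30, 30))))
        assert len(minima) == 0

    def test_wp_like_recovers_planted_wells(self):
        """Minima inventory matches an exhaustive fine-grid scan of the
        analytic trap-chain landscape."""
        s = ts.make_landscape("wp_like")
        axes = s.grid_axes(100)
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        v = s.energy(pts)
        grid = fa.FESGrid(axes=axes, values=v - v.min())
        minima = fa.find_minima(grid, depth_threshold=1.0)
        cell = float(axes[0][1] - axes[0][0])
        planted = [(1.2, 0.55), (1.2, 0.0), (1.2, -0.55),
                   (0.55, 1.2), (0.0, 1.2), (-0.55, 1.2)]
        assert len(minima) == len(planted)
        locs = minima.locations()
        for p in planted:
            d = np.abs(locs - np.asarray(p)).max(axis=1)
            assert d.min() <= 1.5 * cell

    def test_rank_order_of_planted_depths(self):
        """The three chain wells are recovered deepest-first (M3 < M2 < M1)."""
        s = ts.make_landscape("wp_like")
        axes = s.grid_axes(100)
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        v = s.energy(pts)
        minima = fa.find_minima(fa.FESGrid(axes=axes, values=v - v.min()), 1.0)
        one_side = [m for m in minima if m.location[0] > m.location[1]]
        ordered = sorted(one_side, key=lambda m: m.energy)
        z2 = [m.location[1] for m in ordered]
        assert z2 == sorted(z2)  # deepest well sits lowest along the chain


class TestMepBarrier:
    def test_start_equals_end(self):
        grid = _grid_from(np.random.default_rng(0).random((15, 15)))
        res = fa.mep_barrier(grid, (0.0, 0.0), (0.0, 0.0))
        assert res.saddle_height == 0.0
        assert len(res.nodes) == 1

    def test_flat_surface_zero_barrier(self):
        grid = _grid_from(np.zeros((20, 20)))
        res = fa.mep_barrier(grid, (-1.0, -1.0), (1.0, 1.0))
        assert res.saddle_height == 0.0

    def test_planted_ridge_height(self):
        """Two wells separated by a 5 kT ridge: the minimax saddle equals
        the ridge height over the start well."""
        xs = np.linspace(-1, 1, 21)
        v = np.zeros((21, 21))
        v[:, xs == 0.0] = 5.0  # ridge column at z2 = 0... but path could go around
        v[:, np.abs(xs) > 0.9] = 8.0  # cap the edges so the ridge must be crossed
        v[10, 10] = 5.0
        grid = fa.FESGrid(axes=[xs, xs], values=v)
        res = fa.mep_barrier(grid, (0.0, -0.5), (0.0, 0.5))
        assert res.saddle_height == pytest.approx(5.0)

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(12)
        xs = np.linspace(-1, 1, 20)
        for _ in range(10):
            v = rng.random((20, 20)) * 6.0
            v -= v.min()
            grid = fa.FESGrid(axes=[xs, xs], values=v)
            s, e = (2, 3), (17, 15)
            res = fa.mep_barrier(grid, grid.coords(s), grid.coords(e))
            expect = brute_force_minimax(v, s, e) - v[s]
            assert res.saddle_height == pytest.approx(expect, abs=1e-12)

    def test_reverse_barrier_identity(self):
        """mep(s,e) - mep(e,s) = F(e) - F(s): both directions share the
        minimax level."""
        rng = np.random.default_rng(3)
        xs = np.linspace(-1, 1, 25)
        v = rng.random((25, 25)) * 4.0
        grid = _grid_from(v)
        s, e = (1.0, -0.9), (-0.8, 0.7)
        fwd = fa.mep_barrier(grid, s, e).saddle_height
        rev = fa.mep_barrier(grid, e, s).saddle_height
        fs = grid.values[grid.nearest_index(s)]
        fe = grid.values[grid.nearest_index(e)]
        assert fwd - rev == pytest.approx(fe - fs, abs=1e-12)

    def test_path_nodes_are_grid_neighbors(self):
        grid = _grid_from(np.random.default_rng(5).random((15, 15)))
        res = fa.mep_barrier(grid, (-1.0, -1.0), (1.0, 1.0))
        steps = np.diff(res.nodes, axis=0)
        cell = 2.0 / 14
        assert np.all(np.abs(steps) <= cell + 1e-9)
        assert np.all(np.abs(steps).max(axis=1) > 0)


class TestBlockProfiles:
    def test_default_schedule(self):
        """Defaults: nine blocks of 2,500 kernels."""
        import inspect
        sig = inspect.signature(fa.block_profiles)
        assert sig.parameters["n_blocks"].default == 9
        assert sig.parameters["block_size_kernels"].default == 2500

    def test_saturated_blocks_zero_spread(self):
        """If the bias stops growing after the first block (the deep
        well-tempered limit: later kernels have zero height), every
        checkpoint profile is identical and the spread vanishes."""
        gamma = 10.0
        hills = [me.Hill(float(t), (np.cos(t * 0.7),), (0.3,), 0.5, gamma)
                 for t in range(2500)]
        hills += [me.Hill(2500.0 + t, (0.0,), (0.3,), 0.0, gamma)
                  for t in range(8 * 2500)]
        bias = me.BiasState(1, 0.5, gamma, hills=hills)
        res = fa.block_profiles(bias, [np.linspace(-2, 2, 100)])
        assert len(res.boundaries) == 9
        # identical checkpoints up to summation rounding
        assert float(res.spread.max()) < 1e-10

    def test_converged_run_checkpoints_approach_truth(self, dw_run, double_well):
        """Successive checkpoint profiles drift less and less, and the final
        checkpoint matches the planted profile."""
        bias, _ = dw_run
        n = bias.n_hills
        axes = [np.linspace(-2.5, 2.5, 150)]
        res = fa.block_profiles(bias, axes, n_blocks=8, block_size_kernels=n // 8)
        diffs = [float(np.sqrt(np.mean((res.profiles[i + 1] - res.profiles[i]) ** 2)))
                 for i in range(len(res.profiles) - 1)]
        # early filling moves the estimate a lot; late checkpoints barely
        assert diffs[-1] < diffs[0] / 3
        truth = double_well.energy(axes[0][:, None])
        truth -= truth.min()
        mask = truth <= 10.0
        rmse = float(np.sqrt(np.mean((res.profiles[-1][mask] - truth[mask]) ** 2)))
        assert rmse < 0.5

    def test_invalid_block_counts(self):
        bias = me.BiasState(1, 0.5, 10.0)
        with pytest.raises(ValueError):
            fa.block_profiles(bias, [np.linspace(-1, 1, 10)], n_blocks=0)


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2 ** 31 - 1))
def test_symmetrize_idempotent_property(seed):
    v = np.random.default_rng(seed).random((15, 15)) * 3
    grid = _grid_from(v)
    once = fa.symmetrize_fes(grid)
    twice = fa.symmetrize_fes(once)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
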