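"""NCS operator detection, NCS averaging, solvent flattening, map averaging."""

import numpy as np
import pytest

from conftest import helix_model
from micromr.density_mod import (NcsOperator, _region_mask, average_maps,
                                 density_modify, find_ncs_operators,
                                 ncs_average)
from micromr.model_core import Model, SymmetryOps, UnitCell, superpose
from micromr.rebuild import _rotation_about
from micromr.synthetic import make_standard_fixture, perturb_model
from micromr.xray_core import (DensityMap, compute_map, map_correlation,
                               set_f_calc, sf_fft)

P1 = SymmetryOps.from_name("P1")


def multi_copy_model(n_copies, cell_edge=46.0, n_res=8, seed=0):
    """n identical helix copies placed by known rigid motions in a big cell."""
    rng = np.random.default_rng(seed)
    base = helix_model(n_res)
    coords = base.coords()
    coords -= coords.mean(axis=0)
    chains = {}
    ops = []
    centers = [np.array([10.0, 10, 10]), np.array([32.0, 12, 11]),
               np.array([12.0, 33, 12]), np.array([31.0, 32, 33])]
    R0 = np.eye(3)
    for i in range(n_copies):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = _rotation_about(axis, rng.uniform(0, np.pi)) if i else np.eye(3)
        cid = "ABCD"[i]
        m = Model({cid: [r.copy() for r in base.chains["A"]]})
        m.set_coords(coords @ R.T + centers[i])
        chains[cid] = m.chains[cid]
        if i == 0:
            R0, c0 = R, centers[0]
        else:
            ops.append(NcsOperator(R @ R0.T, centers[i] - R @ R0.T @ c0,
                                   "A", cid))
    cell = UnitCell(cell_edge, cell_edge, cell_edge)
    return Model(chains), cell, ops


class TestFindNcsOperators:
    def test_single_chain_gives_empty_list(self):
        assert find_ncs_operators(helix_model(6)) == []

    def test_exact_two_copy_recovery(self):
        model, cell, true_ops = multi_copy_model(2)
        found = find_ncs_operators(model)
        ab = [o for o in found if o.source_chain == "A"
              and o.target_chain == "B"]
        assert len(ab) == 1
        np.testing.assert_allclose(ab[0].rotation, true_ops[0].rotation,
                                   atol=1e-6)
        np.testing.assert_allclose(ab[0].translation, true_ops[0].translation,
                                   atol=1e-6)
        assert ab[0].rmsd < 1e-9

    def test_four_copies_give_twelve_ordered_ops_with_closure(self):
        model, cell, _ = multi_copy_model(4)
        ops = find_ncs_operators(model)
        assert len(ops) == 12
        get = {(o.source_chain, o.target_chain): o for o in ops}
        ab, bc, ac = get[("A", "B")], get[("B", "C")], get[("A", "C")]
        np.testing.assert_allclose(bc.rotation @ ab.rotation, ac.rotation,
                                   atol=1e-3)
        np.testing.assert_allclose(
            bc.rotation @ ab.translation + bc.translation, ac.translation,
            atol=1e-3)

    def test_divergent_copies_discarded(self):
        model, cell, _ = multi_copy_model(2)
        bad = perturb_model(
            Model({"B": [r.copy() for r in model.chains["B"]]}), 3.5, seed=1)
        model.chains["B"] = bad.chains["B"]
        assert find_ncs_operators(model) == []


class TestNcsAverage:
    def _map_and_model(self, n_copies, noise=0.0, seed=0):
        model, cell, ops = multi_copy_model(n_copies)
        refl = sf_fft(model, cell, P1, 3.0)
        dmap = compute_map(refl, "fc")
        clean = dmap.copy()
        if noise:
            rng = np.random.default_rng(seed)
            dmap = DensityMap(dmap.grid + rng.normal(0, noise,
                                                     dmap.grid.shape), cell)
        ref = Model({"A": [r.copy() for r in model.chains["A"]]})
        return dmap, clean, ref, ops, cell

    def test_identity_only_ops_leave_map_unchanged(self):
        dmap, _, ref, _, cell = self._map_and_model(1)
        ident = [NcsOperator(np.eye(3), np.zeros(3), "A", "A")]
        out = ncs_average(dmap, ident, ref)
        np.testing.assert_array_equal(out.grid, dmap.grid)

    def test_exact_ncs_map_is_fixed_point(self):
        dmap, _, ref, ops, cell = self._map_and_model(4)
        out = ncs_average(dmap, ops, ref)
        region = _region_mask(dmap, ref.coords(), 5.0)
        a, b = dmap.grid[region], out.grid[region]
        cc = np.corrcoef(a, b)[0, 1]
        assert cc > 0.999

    def test_noise_reduced_by_averaging_four_copies(self):
        sigma = 0.5
        dmap, clean, ref, ops, cell = self._map_and_model(4, noise=sigma,
                                                          seed=3)
        out = ncs_average(dmap, ops, ref)
        region = _region_mask(dmap, ref.coords(), 5.0)
        err_before = np.sqrt(((dmap.grid - clean.grid)[region] ** 2).mean())
        err_after = np.sqrt(((out.grid - clean.grid)[region] ** 2).mean())
        assert err_after <= 0.6 * err_before

    def test_empty_ops_rejected(self):
        dmap, _, ref, _, _ = self._map_and_model(1)
        with pytest.raises(ValueError):
            ncs_average(dmap, [], ref)


class TestDensityModify:
    def test_zero_cycles_returns_start_unchanged(self, std_fixture):
        fx = std_fixture
        refl = set_f_calc(fx["refl"], fx["target"], fx["sym"])
        start = compute_map(refl, "two_fo_fc")
        out = density_modify(start, refl, fx["target"], 0.6, n_cycles=0)
        np.testing.assert_array_equal(out.grid, start.grid)

    def test_improves_map_from_perturbed_model(self, std_fixture, true_map):
        fx = std_fixture
        pert = perturb_model(fx["target"], 1.5, seed=11)
        refl = set_f_calc(fx["refl"], pert, fx["sym"])
        start = compute_map(refl, "two_fo_fc")
        out = density_modify(start, refl, pert, 0.6, n_cycles=5)
        assert map_correlation(out, true_map) > \
            map_correlation(start, true_map)

    def test_near_fixed_point_with_perfect_phases(self, std_fixture,
                                                  true_map):
        fx = std_fixture
        refl = set_f_calc(fx["refl"], fx["target"], fx["sym"])
        start = compute_map(refl, "two_fo_fc")
        out = density_modify(start, refl, fx["target"], 0.6, n_cycles=5)
        cc0 = map_correlation(start, true_map)
        cc5 = map_correlation(out, true_map)
        assert cc0 - cc5 < 0.02

    def test_amplitudes_reset_to_f_obs_on_work_and_free_alike(
            self, std_fixture):
        # phase-only modification: output coefficients have |F| = f_obs
        # for every reflection, free or work
        from micromr.xray_core import map_coefficients
        fx = std_fixture
        pert = perturb_model(fx["target"], 1.0, seed=2)
        refl = set_f_calc(fx["refl"], pert, fx["sym"])
        start = compute_map(refl, "two_fo_fc")
        out = density_modify(start, refl, pert, 0.6, n_cycles=2)
        F = map_coefficients(out, refl.hkl)
        np.testing.assert_allclose(np.abs(F), refl.f_obs, rtol=1e-6)

    def test_solvent_fraction_bounds(self, std_fixture):
        fx = std_fixture
        refl = set_f_calc(fx["refl"], fx["target"], fx["sym"])
        start = compute_map(refl, "two_fo_fc")
        with pytest.raises(ValueError):
            density_modify(start, refl, fx["target"], 0.1)


class TestAverageMaps:
    def _noise_map(self, seed, base=None):
        rng = np.random.default_rng(seed)
        grid = rng.normal(0, 1, (12, 12, 12))
        if base is not None:
            grid = base + grid
        return DensityMap(grid, UnitCell(12, 12, 12))

    def test_single_map_standardized_identity(self):
        m = self._noise_map(0)
        out = average_maps([m])
        np.testing.assert_allclose(out.grid, m.standardized().grid)

    def test_map_plus_negation_cancels(self):
        m = self._noise_map(1)
        neg = DensityMap(-m.grid, m.cell)
        out = average_maps([m, neg])
        np.testing.assert_allclose(out.grid, 0.0, atol=1e-12)

    def test_permutation_invariance(self):
        maps = [self._noise_map(s) for s in range(4)]
        a = average_maps(maps)
        b = average_maps(maps[::-1])
        np.testing.assert_allclose(a.grid, b.grid, atol=1e-12)

    def test_averaging_beats_every_input(self):
        rng = np.random.default_rng(9)
        signal = rng.normal(0, 1, (12, 12, 12))
        sig_map = DensityMap(signal, UnitCell(12, 12, 12))
        wins = 0
        for trial in range(5):
            maps = [self._noise_map(100 * trial + s, base=signal)
                    for s in range(4)]
            avg = average_maps(maps)
            cc_avg = map_correlation(avg, sig_map)
            if all(cc_avg > map_correlation(m, sig_map) for m in maps):
                wins += 1
        assert wins == 5

    def test_grid_mismatch_rejected(self):
        a = self._noise_map(0)
        b = DensityMap(np.zeros((8, 8, 8)) + np.arange(8), UnitCell(8, 8, 8))
        with pytest.raises(ValueError):
            average_maps([a, b])
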