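"""Structure factors (dual route), scaling/R, free flags, maps and fit scores."""

import numpy as np
import pytest

from conftest import helix_model
from micromr.model_core import Atom, Model, Residue, SymmetryOps, UnitCell
from micromr.xray_core import (DensityMap, ReflectionSet, assign_free_flags,
                               compute_map, form_factor, map_correlation,
                               r_factor, real_space_fit, scale_and_r,
                               set_f_calc, sf_direct, sf_fft, synthesize_map)

P1 = SymmetryOps.from_name("P1")


def single_atom_model(element="C", xyz=(0.0, 0.0, 0.0), b=10.0):
    return Model({"A": [Residue("ALA", 1, [Atom("CA", element,
                                                np.array(xyz), 1.0, b)])]})


class TestSfDirect:
    def test_atom_at_origin_is_real_positive_damped_form_factor(self):
        cell = UnitCell(10, 10, 10)
        m = single_atom_model(b=10.0)
        hkl = np.array([[1, 0, 0], [2, 1, 0], [3, 2, 1]])
        F = sf_direct(m, cell, P1, hkl)
        stol2 = 0.25 / cell.d_spacing(hkl) ** 2
        expected = form_factor("C", stol2) * np.exp(-10.0 * stol2)
        np.testing.assert_allclose(F.imag, 0, atol=1e-10)
        np.testing.assert_allclose(F.real, expected, rtol=1e-12)

    def test_friedel_symmetry(self):
        cell = UnitCell(12, 14, 16)
        m = helix_model(5)
        hkl = np.array([[1, 2, 3], [2, -1, 4]])
        F = sf_direct(m, cell, P1, hkl)
        Fneg = sf_direct(m, cell, P1, -hkl)
        np.testing.assert_allclose(Fneg, np.conj(F), rtol=1e-12)

    def test_centrosymmetric_pair_hand_expansion(self):
        # atoms at +x and -x: F = 2 f cos(2 pi h.x) exp(-B stol2)
        cell = UnitCell(10, 10, 10)
        x = np.array([1.2, 0.7, -0.4])
        m = Model({"A": [Residue("ALA", 1, [Atom("CA", "C", x, 1.0, 5.0)]),
                         Residue("ALA", 2, [Atom("CA", "C", -x, 1.0, 5.0)])]})
        hkl = np.array([[1, 0, 0], [2, 3, 1]])
        F = sf_direct(m, cell, P1, hkl)
        stol2 = 0.25 / cell.d_spacing(hkl) ** 2
        xfrac = cell.fractionalize(x)
        expected = 2 * form_factor("C", stol2) * np.exp(-5.0 * stol2) \
            * np.cos(2 * np.pi * hkl @ xfrac)
        np.testing.assert_allclose(F.real, expected, rtol=1e-10)
        np.testing.assert_allclose(F.imag, 0, atol=1e-8)

    def test_p21_systematic_absences(self):
        cell = UnitCell(15, 18, 20, 90, 90, 90)
        sym = SymmetryOps.from_name("P21")
        m = helix_model(6)
        hkl = np.array([[0, 1, 0], [0, 3, 0], [0, 2, 0]])
        F = np.abs(sf_direct(m, cell, sym, hkl))
        assert F[0] < 1e-8 and F[1] < 1e-8
        assert F[2] > 1.0

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            sf_direct(single_atom_model("FE"), UnitCell(10, 10, 10), P1,
                      np.array([[1, 0, 0]]))


class TestSfFft:
    def test_matches_direct_summation(self):
        cell = UnitCell(18, 20, 16)
        m = helix_model(8)
        refl = sf_fft(m, cell, P1, 2.5)
        F = sf_direct(m, cell, P1, refl.hkl)
        amp_r = np.abs(np.abs(refl.f_calc) - np.abs(F)).sum() / np.abs(F).sum()
        assert amp_r < 0.005
        dphi = np.abs(np.angle(refl.f_calc * np.conj(F)))
        w = np.abs(F)
        assert np.degrees((dphi * w).sum() / w.sum()) < 2.0

    def test_translation_by_full_cell_is_invisible(self):
        cell = UnitCell(18, 20, 16)
        m = helix_model(6)
        shifted = m.transformed(np.eye(3), np.array([cell.a, 0.0, 0.0]))
        a = sf_fft(m, cell, P1, 3.0)
        b = sf_fft(shifted, cell, P1, 3.0)
        np.testing.assert_allclose(np.abs(a.f_calc), np.abs(b.f_calc),
                                   rtol=1e-6)

    def test_occupancy_linearity(self):
        cell = UnitCell(18, 20, 16)
        m = helix_model(6)
        half = m.copy()
        for _, _, at in half.iter_atoms():
            at.occ = 0.5
        a = sf_fft(m, cell, P1, 3.0)
        b = sf_fft(half, cell, P1, 3.0)
        np.testing.assert_allclose(np.abs(b.f_calc), 0.5 * np.abs(a.f_calc),
                                   rtol=1e-9)

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            sf_fft(helix_model(4), UnitCell(18, 20, 16), P1, 2.5,
                   shape=(8, 8, 8))


class TestScaleAndR:
    def _refl(self, f_obs, f_calc, n_free=3):
        n = len(f_obs)
        hkl = np.array([[i + 1, 0, 0] for i in range(n)])
        free = np.zeros(n, bool)
        free[:n_free] = True
        return ReflectionSet(hkl, UnitCell(50, 50, 50), f_obs=np.asarray(f_obs, float),
                             free_flag=free, f_calc=np.asarray(f_calc, complex))

    def test_exact_match_gives_zero_r_unit_scale(self):
        f = np.linspace(10, 100, 20)
        rep = scale_and_r(self._refl(f, f))
        assert rep.r_work == pytest.approx(0.0, abs=1e-6)
        assert rep.r_free == pytest.approx(0.0, abs=1e-6)
        assert rep.scale == pytest.approx(1.0, rel=1e-4)
        assert abs(rep.b_overall) < 0.01

    def test_global_scale_absorbed(self):
        f = np.linspace(10, 100, 20)
        rep = scale_and_r(self._refl(2.0 * f, f))
        assert rep.r_work == pytest.approx(0.0, abs=1e-6)
        assert rep.scale == pytest.approx(2.0, rel=1e-4)

    def test_r_work_invariant_under_f_obs_scaling(self, std_fixture):
        fx = std_fixture
        refl = set_f_calc(fx["refl"], fx["template"], fx["sym"])
        r1 = scale_and_r(refl).r_work
        scaled = refl.copy()
        scaled.f_obs = scaled.f_obs * 7.3
        assert scale_and_r(scaled).r_work == pytest.approx(r1, abs=1e-9)

    def test_hand_computed_three_reflection_r(self):
        # unscaled R definition on a 3-reflection toy set
        assert r_factor([10.0, 20.0, 30.0], [12.0, 18.0, 33.0]) == \
            pytest.approx(7.0 / 60.0)

    def test_empty_free_set_errors(self):
        f = np.linspace(10, 100, 20)
        refl = self._refl(f, f, n_free=0)
        with pytest.raises(ValueError):
            scale_and_r(refl)


class TestFreeFlags:
    def _refl(self, n=1000):
        rng = np.random.default_rng(0)
        hkl = np.array([[i, j, k] for i in range(12) for j in range(12)
                        for k in range(8)][:n])
        return ReflectionSet(hkl, UnitCell(30, 30, 30),
                             f_obs=rng.uniform(1, 100, n))

    def test_reproducible_under_seed(self):
        refl = self._refl()
        a = assign_free_flags(refl, 0.05, seed=42)
        b = assign_free_flags(refl, 0.05, seed=42)
        np.testing.assert_array_equal(a.free_flag, b.free_flag)

    def test_realized_fraction_close_to_target(self):
        flags = assign_free_flags(self._refl(), 0.05, seed=1).free_flag
        assert 0.04 <= flags.mean() <= 0.06

    def test_different_seeds_differ(self):
        refl = self._refl()
        a = assign_free_flags(refl, 0.05, seed=1).free_flag
        b = assign_free_flags(refl, 0.05, seed=2).free_flag
        assert (a != b).sum() > 0

    def test_too_few_reflections(self):
        refl = ReflectionSet(np.array([[1, 0, 0]]), UnitCell(10, 10, 10),
                             f_obs=np.array([5.0]))
        with pytest.raises(ValueError):
            assign_free_flags(refl, 0.05, 0)


class TestMaps:
    def test_fc_map_peaks_at_atoms(self):
        cell = UnitCell(18, 20, 16)
        m = helix_model(4)
        refl = sf_fft(m, cell, P1, 2.0)
        dmap = compute_map(refl, "fc")
        vals = dmap.interpolate_cart(m.coords())
        assert vals.min() > 2.0 * dmap.grid.std()

    def test_two_fo_fc_equals_fc_when_fobs_is_fcalc(self):
        cell = UnitCell(18, 20, 16)
        m = helix_model(4)
        refl = sf_fft(m, cell, P1, 2.5)
        refl.f_obs = np.abs(refl.f_calc)
        a = compute_map(refl, "two_fo_fc")
        b = compute_map(refl, "fc")
        np.testing.assert_allclose(a.grid, b.grid, atol=1e-6 * b.grid.std())

    def test_parseval(self):
        cell = UnitCell(18, 20, 16)
        m = helix_model(4)
        refl = sf_fft(m, cell, P1, 2.5)
        dmap = compute_map(refl, "fc")
        # both Friedel mates contribute: variance = 2 sum |F|^2 / V^2
        coeffs = np.abs(refl.f_calc) ** 2
        expected = 2 * coeffs.sum() / cell.volume ** 2
        assert dmap.grid.var() == pytest.approx(expected, rel=0.01)

    def test_map_mean_zero(self):
        cell = UnitCell(18, 20, 16)
        refl = sf_fft(helix_model(4), cell, P1, 2.5)
        dmap = compute_map(refl, "fc")
        assert abs(dmap.grid.mean()) < 1e-9 * dmap.grid.std()


class TestMapCorrelation:
    def _map(self, seed=0):
        rng = np.random.default_rng(seed)
        return DensityMap(rng.normal(0, 1, (8, 8, 8)), UnitCell(10, 10, 10))

    def test_self_and_negation(self):
        a = self._map()
        neg = DensityMap(-a.grid, a.cell)
        assert map_correlation(a, a) == pytest.approx(1.0)
        assert map_correlation(a, neg) == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        a, b = self._map(1), self._map(2)
        assert map_correlation(a, b) == pytest.approx(map_correlation(b, a))
        b2 = DensityMap(3.0 * b.grid + 7.0, b.cell)
        assert map_correlation(a, b2) == pytest.approx(map_correlation(a, b))

    def test_constant_map_errors(self):
        a = self._map()
        flat = DensityMap(np.ones((8, 8, 8)), a.cell)
        with pytest.raises(ValueError):
            map_correlation(a, flat)


class TestRealSpaceFit:
    def test_generating_model_beats_shifted_model(self):
        cell = UnitCell(18, 20, 16)
        m = helix_model(5)
        dmap = compute_map(sf_fft(m, cell, P1, 2.5), "fc")
        good = real_space_fit(m, dmap).overall
        shifted = m.transformed(np.eye(3), np.array([3.0, 0.0, 0.0]))
        assert good > 0
        assert good > real_space_fit(shifted, dmap).overall

    def test_invariant_to_map_offset(self):
        cell = UnitCell(18, 20, 16)
        m = helix_model(5)
        dmap = compute_map(sf_fft(m, cell, P1, 2.5), "fc")
        base = real_space_fit(m, dmap).overall
        lifted = DensityMap(dmap.grid + 42.0, cell)
        assert real_space_fit(m, lifted).overall == pytest.approx(base,
                                                                  abs=1e-9)

    def test_matches_brute_force_trilinear_oracle(self):
        rng = np.random.default_rng(3)
        cell = UnitCell(10, 12, 14)
        grid = rng.normal(0, 1, (10, 12, 14))
        dmap = DensityMap(grid, cell)
        m = helix_model(3)
        fit = real_space_fit(m, dmap)
        std = (grid - grid.mean()) / grid.std()

        def brute(p):
            f = cell.fractionalize(p) % 1.0
            x = f * np.array(grid.shape)
            i0 = np.floor(x).astype(int)
            t = x - i0
            v = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((t[0] if dx else 1 - t[0])
                             * (t[1] if dy else 1 - t[1])
                             * (t[2] if dz else 1 - t[2]))
                        v += w * std[(i0[0] + dx) % 10, (i0[1] + dy) % 12,
                                     (i0[2] + dz) % 14]
            return v

        for (cid, res) in m.iter_residues():
            xyz = np.array([a.xyz for a in res.atoms])
            occ = np.array([a.occ for a in res.atoms])
            vals = np.array([brute(p) for p in xyz])
            oracle = (occ * vals).sum() / occ.sum()
            assert fit.residue_scores[(cid, res.seqnum)] == \
                pytest.approx(oracle, abs=1e-10)


class TestReflectionIO:
    def test_text_round_trip(self, tmp_path):
        cell = UnitCell(18, 20, 16)
        refl = sf_fft(helix_model(4), cell, P1, 3.0)
        refl.f_obs = np.abs(refl.f_calc)
        refl.sigma = 0.05 * refl.f_obs
        refl = assign_free_flags(refl, 0.05, 3)
        path = tmp_path / "refl.txt"
        refl.write_text(path)
        back = ReflectionSet.read_text(path, cell)
        np.testing.assert_array_equal(back.hkl, refl.hkl)
        np.testing.assert_allclose(back.f_obs, refl.f_obs, atol=1e-3)
        np.testing.assert_array_equal(back.free_flag, refl.free_flag)

    def test_ccp4_map_round_trip(self, tmp_path):
        cell = UnitCell(18, 20, 16)
        dmap = compute_map(sf_fft(helix_model(4), cell, P1, 3.0), "fc")
        path = tmp_path / "map.ccp4"
        dmap.write_ccp4(path)
        back = DensityMap.read_ccp4(path)
        assert map_correlation(dmap, back) > 0.99999
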