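"""Geometry/density scoring, MC fragment rebuilding, NCS rebuilding,
real-space refinement and model selection."""

import numpy as np
import pytest

from conftest import helix_model
from micromr import peptide
from micromr.model_core import Model, Residue, SymmetryOps, UnitCell, \
    superpose, MAIN_CHAIN_ATOMS
from micromr.density_mod import NcsOperator
from micromr.rebuild import (FragmentLibrary, RebuildParams, ScoreWeights,
                             combined_score, discard_unassigned,
                             geometry_score, make_default_library,
                             metropolis_accept, rebuild_model,
                             rebuild_with_ncs, refine_real_space,
                             select_top_models, _rotation_about)
from micromr.xray_core import DensityMap, compute_map, real_space_fit, sf_fft

P1 = SymmetryOps.from_name("P1")


@pytest.fixture(scope="module")
def helix_in_map():
    """16-residue helix placed in a cell, with its own fc map."""
    n = 16
    m = peptide.build_chain_model(np.full(n, -57.0), np.full(n, -47.0),
                                  np.full(n, 180.0), ["ALA"] * n)
    cell = UnitCell(*(m.coords().max(0) - m.coords().min(0) + 12))
    m.set_coords(m.coords() - m.coords().min(0) + 4.0)
    dmap = compute_map(sf_fft(m, cell, P1, 2.5), "fc")
    return m, cell, dmap


class TestGeometryScore:
    def test_ideal_helix_is_clean(self):
        gs = geometry_score(helix_model(10))
        assert gs.bond_dev < 1e-6
        assert gs.angle_dev < 1e-6
        assert gs.clash == 0
        assert gs.rama_outliers == 0.0

    def test_displaced_atom_detected(self):
        m = helix_model(10)
        m.chains["A"][4].atom("CA").xyz = \
            m.chains["A"][4].atom("CA").xyz + np.array([1.0, 0, 0])
        gs = geometry_score(m)
        assert gs.bond_dev > 0.1

    def test_clash_counted_between_distant_residues(self):
        m = helix_model(10)
        # park residue 9's CB on residue 1's CA
        m.chains["A"][8].atom("CB").xyz = \
            m.chains["A"][0].atom("CA").xyz + np.array([0.5, 0, 0])
        assert geometry_score(m).clash >= 1

    def test_torsion_outlier_detected(self):
        n = 10
        phis = np.full(n, -57.0)
        psis = np.full(n, -47.0)
        phis[5], psis[5] = 150.0, -120.0     # far outside allowed regions
        m = peptide.build_chain_model(phis, psis, np.full(n, 180.0),
                                      ["ALA"] * n)
        assert geometry_score(m).rama_outliers > 0


class TestCombinedScore:
    def test_true_model_beats_displaced(self, helix_in_map):
        m, cell, dmap = helix_in_map
        w = ScoreWeights()
        bad = m.copy()
        bad.chains["A"][7].atom("CA").xyz = \
            bad.chains["A"][7].atom("CA").xyz + np.array([2.0, 0, 0])
        assert combined_score(m, dmap, w) > combined_score(bad, dmap, w)

    def test_geometry_only_score_ignores_map(self, helix_in_map):
        m, cell, dmap = helix_in_map
        w = ScoreWeights(w_geom=1.0, w_dens=0.0)
        other = DensityMap(np.random.default_rng(0).normal(0, 1,
                                                           dmap.grid.shape),
                           cell)
        assert combined_score(m, dmap, w) == \
            pytest.approx(combined_score(m, other, w))

    def test_equals_weighted_component_sum(self, helix_in_map):
        m, cell, dmap = helix_in_map
        w = ScoreWeights(w_geom=0.7, w_dens=1.3)
        three = Model({"A": [r.copy() for r in m.chains["A"][:3]]})
        expected = (w.w_dens * real_space_fit(three, dmap).overall
                    - w.w_geom * geometry_score(three).penalty)
        assert combined_score(three, dmap, w) == pytest.approx(expected)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            ScoreWeights(0.0, 0.0)
        with pytest.raises(ValueError):
            ScoreWeights(-1.0, 1.0)


class TestFragmentLibrary:
    def test_default_library_has_both_lengths(self, frag_lib):
        assert len(frag_lib.by_length(3)) > 20
        assert len(frag_lib.by_length(9)) > 20
        assert len(frag_lib.fragments) >= 100

    def test_every_fragment_complete(self, frag_lib):
        for f in frag_lib.fragments:
            assert len(f.phis) == len(f.psis) == len(f.omegas) == len(f)

    def test_library_without_nine_mers_rejected(self, frag_lib):
        with pytest.raises(ValueError):
            FragmentLibrary(frag_lib.by_length(3)[:5])

    def test_deterministic(self):
        a = make_default_library(seed=0)
        b = make_default_library(seed=0)
        for fa, fb in zip(a.fragments, b.fragments):
            np.testing.assert_array_equal(fa.phis, fb.phis)


class TestMetropolis:
    def test_zero_temperature_accepts_only_improvements(self):
        rng = np.random.default_rng(0)
        deltas = [0.5, 0.0, -1e-9, -0.3, -5.0, 0.1]
        accepted = [metropolis_accept(d, 0.0, rng) for d in deltas]
        assert accepted == [d >= 0 for d in deltas]

    def test_finite_temperature_accepts_at_boltzmann_rate(self):
        rng = np.random.default_rng(1)
        delta, temp = -0.1, 0.1
        rate = np.mean([metropolis_accept(delta, temp, rng)
                        for _ in range(4000)])
        assert rate == pytest.approx(np.exp(delta / temp), abs=0.03)


class TestRebuildModel:
    def test_zero_steps_returns_input(self, helix_in_map, frag_lib):
        m, cell, dmap = helix_in_map
        out = rebuild_model(m, dmap, frag_lib,
                            RebuildParams(n_models=2, n_steps=0, seed=0),
                            ScoreWeights())
        assert len(out) == 2
        for o in out:
            np.testing.assert_array_equal(o.coords(), m.coords())

    def test_same_seed_bitwise_identical(self, helix_in_map, frag_lib):
        m, cell, dmap = helix_in_map
        params = RebuildParams(n_models=2, n_steps=40, seed=7)
        a = rebuild_model(m, dmap, frag_lib, params, ScoreWeights())
        b = rebuild_model(m, dmap, frag_lib, params, ScoreWeights())
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.coords(), mb.coords())

    def test_no_rebuildable_window_rejected(self, helix_in_map, frag_lib):
        m, cell, dmap = helix_in_map
        tiny = Model({"A": [r.copy() for r in m.chains["A"][:3]]})
        with pytest.raises(ValueError):
            rebuild_model(tiny, dmap, frag_lib,
                          RebuildParams(n_models=1, n_steps=5, seed=0),
                          ScoreWeights())

    def test_gap_built_into_true_density(self, helix_in_map, frag_lib):
        m, cell, dmap = helix_in_map
        gap = [8, 9, 10, 11]
        gapped = m.copy()
        gapped.chains["A"] = [r for r in gapped.chains["A"]
                              if r.seqnum not in gap]
        gapped.meta["gaps"] = gap
        gapped.meta["target_seq"] = "A" * 16
        w = ScoreWeights()
        models = rebuild_model(gapped, dmap, frag_lib,
                               RebuildParams(n_models=4, n_steps=120, seed=0),
                               w)
        std = dmap.standardized()
        best = max(models, key=lambda mm: combined_score(mm, std, w, 16))
        built = [r for r in best.chains["A"] if r.seqnum in gap]
        assert len(built) == len(gap)
        truth = {r.seqnum: r for r in m.chains["A"]}
        errs = [np.linalg.norm(a.xyz - truth[r.seqnum].atom(a.name).xyz)
                for r in built for a in r.atoms if a.name in ("N", "CA", "C")]
        assert np.mean(errs) < 2.0


class TestRebuildWithNcs:
    def _two_copy(self):
        base = helix_model(10)
        coords = base.coords() - base.coords().mean(0)
        axis = np.array([0.3, 0.5, 0.81])
        axis /= np.linalg.norm(axis)
        R = _rotation_about(axis, 1.2)
        t = np.array([22.0, 4.0, 6.0])
        chains = {"A": [r.copy() for r in base.chains["A"]],
                  "B": [r.copy() for r in base.chains["A"]]}
        model = Model(chains)
        model.set_coords(np.vstack([coords + 12.0, (coords @ R.T) + 12.0 + t]))
        cell = UnitCell(48, 40, 42)
        op = NcsOperator(R, (12.0 + t) - R @ np.full(3, 12.0), "A", "B")
        dmap = compute_map(sf_fft(model, cell, P1, 3.0), "fc")
        return model, op, dmap

    def test_output_has_exact_ncs(self, frag_lib):
        model, op, dmap = self._two_copy()
        out = rebuild_with_ncs(model, dmap, [op], frag_lib,
                               RebuildParams(n_models=2, n_steps=30, seed=0),
                               ScoreWeights())
        a = np.array([r.atom("CA").xyz for r in out.chains["A"]])
        b = np.array([r.atom("CA").xyz for r in out.chains["B"]])
        np.testing.assert_allclose(a @ op.rotation.T + op.translation, b,
                                   atol=1e-6)

    def test_identity_ops_equal_plain_rebuild(self, frag_lib):
        model, op, dmap = self._two_copy()
        single = Model({"A": [r.copy() for r in model.chains["A"]]})
        params = RebuildParams(n_models=2, n_steps=25, seed=3)
        w = ScoreWeights()
        ident = NcsOperator(np.eye(3), np.zeros(3), "A", "A")
        via_ncs = rebuild_with_ncs(single, dmap, [ident], frag_lib, params, w)
        plain = rebuild_model(single, dmap, frag_lib, params, w)
        std = dmap.standardized()
        best = max(plain, key=lambda m: combined_score(m, std, w))
        np.testing.assert_array_equal(via_ncs.chains["A"][0].atom("CA").xyz,
                                      best.chains["A"][0].atom("CA").xyz)

    def test_unknown_target_chain_rejected(self, frag_lib):
        model, op, dmap = self._two_copy()
        bad = NcsOperator(op.rotation, op.translation, "A", "Z")
        with pytest.raises(ValueError):
            rebuild_with_ncs(model, dmap, [bad], frag_lib,
                             RebuildParams(n_models=1, n_steps=5, seed=0),
                             ScoreWeights())


class TestRefineRealSpace:
    def test_own_map_is_fixed_point(self, helix_in_map):
        m, cell, dmap = helix_in_map
        out = refine_real_space(m, dmap, ScoreWeights(), max_iter=6)
        shifts = np.linalg.norm(out.coords() - m.coords(), axis=1)
        assert shifts.max() < 0.05

    def test_rigid_displacement_recovered(self, helix_in_map):
        m, cell, dmap = helix_in_map
        disp = m.transformed(np.eye(3), np.array([0.5, 0.0, 0.0]))
        out = refine_real_space(disp, dmap, ScoreWeights(), max_iter=6)
        assert superpose(out, m, selection=set(MAIN_CHAIN_ATOMS)).rmsd < 0.2

    def test_score_never_decreases(self, helix_in_map):
        m, cell, dmap = helix_in_map
        w = ScoreWeights()
        rng = np.random.default_rng(5)
        noisy = m.copy()
        for _, _, a in noisy.iter_atoms():
            a.xyz = a.xyz + rng.normal(0, 0.4, 3)
        out = refine_real_space(noisy, dmap, w, max_iter=5)
        std = dmap.standardized()
        assert combined_score(out, std, w) >= combined_score(noisy, std, w)


class TestSelection:
    def test_top_n_is_permutation_when_n_equals_len(self, helix_in_map):
        from micromr.synthetic import simulate_fobs, perturb_model
        m, cell, dmap = helix_in_map
        refl = simulate_fobs(m, cell, P1, 3.0, 0.0, seed=0)
        models = [m.copy(), perturb_model(m, 1.0, seed=1),
                  perturb_model(m, 2.0, seed=2)]
        out = select_top_models(models, refl, P1, n=3)
        assert len(out) == 3
        assert {id(x) for x in out} == {id(x) for x in models}

    def test_true_model_first(self, helix_in_map):
        from micromr.synthetic import simulate_fobs, perturb_model
        m, cell, dmap = helix_in_map
        refl = simulate_fobs(m, cell, P1, 3.0, 0.0, seed=0)
        bad = perturb_model(m, 3.0, seed=4)
        out = select_top_models([bad, m], refl, P1, n=1)
        assert out[0] is m

    def test_n_larger_than_models_warns(self, helix_in_map):
        from micromr.synthetic import simulate_fobs
        m, cell, dmap = helix_in_map
        refl = simulate_fobs(m, cell, P1, 3.0, 0.0, seed=0)
        with pytest.warns(UserWarning):
            out = select_top_models([m], refl, P1, n=2)
        assert len(out) == 1


class TestDiscardUnassigned:
    def test_unk_chain_removed_assigned_kept(self):
        m = helix_model(6)
        unk = helix_model(4, chain="U", resname="UNK")
        m.chains["U"] = unk.chains["U"]
        out = discard_unassigned(m)
        assert set(out.chains) == {"A"}
        assert out.n_residues == 6

    def test_all_assigned_unchanged(self):
        m = helix_model(6)
        out = discard_unassigned(m)
        assert set(out.chains) == {"A"}
        np.testing.assert_array_equal(out.coords(), m.coords())
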