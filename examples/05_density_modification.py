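"""Solvent flattening improves a model-phased map.

Phases from a 1.5 Å-perturbed model are biased toward that model.  Cycles of
solvent flattening with phase recombination (amplitudes always reset to the
observed values) pull the map toward the true density; the improvement is
measured as Pearson correlation to the map of the known true structure.
"""

from micromr import (compute_map, density_modify, make_standard_fixture,
                     map_correlation, perturb_model, set_f_calc)

fx = make_standard_fixture(seed=0)
target, cell, sym, refl = fx["target"], fx["cell"], fx["sym"], fx["refl"]
true_map = compute_map(set_f_calc(refl, target, sym), "fc")

pert = perturb_model(target, 1.5, seed=42)
refl_fc = set_f_calc(refl, pert, sym)
start = compute_map(refl_fc, "two_fo_fc")
print(f"start: 2Fo-Fc map phased by the 1.5 Å-perturbed model, "
      f"CC to truth {map_correlation(start, true_map):.3f}")

for cycles in (1, 3, 5):
    dm = density_modify(start, refl_fc, pert, solvent_fraction=0.6,
                        n_cycles=cycles)
    print(f"after {cycles} flattening cycle(s): "
          f"CC to truth {map_correlation(dm, true_map):.3f}")
print("Each cycle flattens the solvent region, recombines phases with the "
      "starting set (weight 0.5) and resets amplitudes to F_obs.")
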