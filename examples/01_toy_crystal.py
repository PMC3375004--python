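"""Generate the standard synthetic toy crystal and inspect it.

Builds a 30-residue helix-turn-helix target in a P1 cell, simulates observed
amplitudes at 2.5 Å with 5% relative noise, and derives a perturbed homolog
template (30% sequence identity, ~1.5 Å main-chain rmsd) with its alignment
— the complete input set for a molecular-replacement experiment with a known
answer.
"""

from micromr import make_standard_fixture, scale_and_r, set_f_calc

fx = make_standard_fixture(seed=0)
cell, refl = fx["cell"], fx["refl"]
print(f"cell: {cell.a:.1f} x {cell.b:.1f} x {cell.c:.1f} Å  "
      f"({fx['sym'].name}, volume {cell.volume:.0f} Å^3)")
print(f"target: {fx['target'].n_residues} residues, "
      f"sequence {fx['sequence']}")
print(f"reflections to 2.5 Å: {len(refl)} "
      f"({int(refl.free_flag.sum())} free)")
print(f"template: {fx['template'].n_residues} residues, "
      f"alignment identity {fx['alignment'].identity:.2f}")

rep = scale_and_r(set_f_calc(refl, fx["target"], fx["sym"]))
print(f"true model vs simulated data: R_work {rep.r_work:.3f}, "
      f"R_free {rep.r_free:.3f}")
print("(R ~ 0.04 is the floor set by the 5% amplitude noise; "
      "any rebuilt model is judged against it)")
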