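"""Edit a homolog template to the target sequence and enumerate copy numbers.

Aligned residues are renamed and renumbered to the target, side chains are
pruned to the atoms both residue types share (CB kept unless the target is
glycine), and unaligned target positions are recorded as gaps for later loop
building.  The Matthews relation then says how many copies of the target
could occupy the cell.
"""

from micromr import edit_template, enumerate_copies, make_standard_fixture
from micromr.template_prep import sequence_mass

fx = make_standard_fixture(seed=0)
aln = fx["alignment"]
print(f"alignment: {len(aln.pairs)} aligned columns, "
      f"identity {aln.identity:.2f}, target gaps at {aln.gap_positions}")

edited = edit_template(fx["template"], aln)
print(f"edited template: {edited.n_residues} residues "
      f"(target numbering, target residue types)")
first = edited.chains["A"][0]
print(f"  e.g. residue {first.seqnum} {first.resname}: "
      f"{[a.name for a in first.atoms]}")

mass = sequence_mass(fx["sequence"])
hyps = enumerate_copies(fx["cell"], fx["sym"], mass)
print(f"target mass {mass:.0f} Da; plausible copy numbers "
      "(ordered by closeness of solvent fraction to 50%):")
for h in hyps:
    print(f"  n = {h.n_copies}: solvent fraction {h.solvent_fraction:.2f}")
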