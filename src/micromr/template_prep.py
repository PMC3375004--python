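"""Template preparation: alignment parsing, sequence editing, copy-number and
multimer enumeration.

The alignment interface is a paired-FASTA dialect: exactly two records of
equal aligned length, target first, '-' for gaps.  Template columns are
counted in ungapped template positions (1-based, file order of the template's
residues); target columns in ungapped target positions (1-based).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

from .model_core import AA1TO3, MAIN_CHAIN_ATOMS, Model, Residue, SymmetryOps, UnitCell

# Matthews-relation constant: protein occupies 1.23 Da/Å^3 of cell volume
MATTHEWS_CONST = 1.23
SOLVENT_WINDOW = (0.20, 0.80)

# average residue masses (Da) for sequence-based Matthews estimates
RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.20, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
    "X": 110.0,
}


def sequence_mass(seq: str) -> float:
    """Mass (Da) of a 1-letter protein sequence (plus one water)."""
    return sum(RESIDUE_MASS.get(c, 110.0) for c in seq.upper()) + 18.02


def residue_topology() -> dict:
    """Side-chain heavy atoms per residue type, tree order (packaged table)."""
    with resources.files("micromr.data").joinpath("residue_topology.json").open() as fh:
        table = json.load(fh)
    return {k: v for k, v in table.items() if not k.startswith("_")}


@dataclass
class Alignment:
    target_seq: str        # ungapped target sequence
    template_seq: str      # template row as aligned (with gaps)
    target_aln: str        # target row as aligned (with gaps)
    pairs: list            # (target_pos, template_pos), both 1-based ungapped
    identity: float

    def target_position_of(self, template_pos: int) -> int | None:
        for tp, mp in self.pairs:
            if mp == template_pos:
                return tp
        return None

    @property
    def gap_positions(self) -> list:
        """Target positions (1-based) with no aligned template residue."""
        aligned = {tp for tp, _ in self.pairs}
        return [i for i in range(1, len(self.target_seq) + 1) if i not in aligned]


@dataclass
class CopyNumberHypothesis:
    n_copies: int
    solvent_fraction: float
    uses_multimer: bool = False


def parse_alignment(path_or_text) -> Alignment:
    """Parse a paired-FASTA alignment (target record first)."""
    if hasattr(path_or_text, "read") or "\n" not in str(path_or_text):
        records = list(SeqIO.parse(str(path_or_text), "fasta"))
    else:
        import io
        records = list(SeqIO.parse(io.StringIO(path_or_text), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 records, got {len(records)}")
    tgt, tpl = str(records[0].seq).upper(), str(records[1].seq).upper()
    if len(tgt) != len(tpl):
        raise ValueError(f"aligned lengths differ ({len(tgt)} vs {len(tpl)})")
    pairs, matches = [], 0
    ti = mi = 0
    for a, b in zip(tgt, tpl):
        if a != "-":
            ti += 1
        if b != "-":
            mi += 1
        if a != "-" and b != "-":
            pairs.append((ti, mi))
            matches += a == b
    if not pairs:
        raise ValueError("alignment has zero aligned columns")
    return Alignment(tgt.replace("-", ""), tpl, tgt, pairs, matches / len(pairs))


def edit_template(template: Model, aln: Alignment) -> Model:
    """Edit a (single-chain) template to the target sequence.

    Aligned residues are kept, renamed to the target residue type and
    renumbered to target numbering; side chains are pruned to the atoms of
    the target residue's topology (N, CA, C, O always kept; CB kept unless
    the target residue is glycine); unaligned template residues are dropped.
    Target positions with no template residue are recorded in
    ``model.meta['gaps']``.
    """
    topo = residue_topology()
    cid = next(iter(template.chains))
    residues = template.chains[cid]
    out = []
    for target_pos, template_pos in aln.pairs:
        if template_pos > len(residues):
            raise ValueError(
                f"alignment references template residue {template_pos}, "
                f"but template has only {len(residues)}")
        src = residues[template_pos - 1]
        target_aa = aln.target_seq[target_pos - 1]
        target_name = AA1TO3.get(target_aa, "UNK")
        allowed = set(MAIN_CHAIN_ATOMS) | set(topo[target_name])
        atoms = [a.copy() for a in src.atoms if a.name in allowed]
        if not any(a.name == "CA" for a in atoms):
            raise ValueError(f"template residue {template_pos} has no CA")
        out.append(Residue(target_name, target_pos, atoms))
    model = Model({"A": out}, label="edited_template")
    model.meta["gaps"] = aln.gap_positions
    model.meta["target_seq"] = aln.target_seq
    return model


def enumerate_copies(cell: UnitCell, sym: SymmetryOps,
                     target_mass: float) -> list:
    """Plausible copy numbers by the Matthews relation.

    Vm = V / (|ops| * n * mass); solvent = 1 - 1.23 / Vm.  Hypotheses with
    solvent fraction inside [0.20, 0.80] are returned, ordered by closeness
    of the solvent fraction to 0.50.
    """
    if target_mass <= 0:
        raise ValueError("target mass must be positive")
    out = []
    n = 1
    while True:
        vm = cell.volume / (len(sym) * n * target_mass)
        solvent = 1.0 - MATTHEWS_CONST / vm
        if solvent < SOLVENT_WINDOW[0]:
            break
        if solvent <= SOLVENT_WINDOW[1]:
            out.append(CopyNumberHypothesis(n, solvent))
        n += 1
    if not out:
        warnings.warn("no admissible copy number (cell too small for target)")
    return sorted(out, key=lambda h: abs(h.solvent_fraction - 0.5))


def build_multimers(edited: Model, template_assembly_count: int,
                    hypotheses: list) -> list:
    """Search models to try: the monomer always; the template's own multimer
    whenever some hypothesis' copy number is a multiple of the assembly size."""
    if template_assembly_count < 1:
        raise ValueError("assembly count must be >= 1")
    n_chains = len(edited.chains)
    if template_assembly_count > n_chains:
        raise ValueError(
            f"assembly count {template_assembly_count} exceeds the "
            f"{n_chains} chain(s) present")
    first = next(iter(edited.chains))
    monomer = Model({first: [r.copy() for r in edited.chains[first]]},
                    label=(edited.label or "template") + ":monomer")
    monomer.meta = dict(edited.meta)
    models = [monomer]
    if template_assembly_count > 1 and any(
            h.n_copies % template_assembly_count == 0 for h in hypotheses):
        multimer = edited.copy()
        multimer.label = (edited.label or "template") + f":{template_assembly_count}mer"
        models.append(multimer)
    return models
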