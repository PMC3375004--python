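"""Coordinate data model, PDB I/O, crystal geometry and superposition.

Coordinates are stored orthogonal (Cartesian, Å).  Crystallographic symmetry
is applied in fractional coordinates through the cell orthogonalization
matrix, following PDB conventions.  The hierarchy is deliberately small:
``Model`` -> chains (dict keyed by chain id) -> ordered ``Residue`` lists ->
ordered ``Atom`` lists.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import gemmi
import numpy as np

STANDARD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "UNK",
}

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

ATOMIC_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}


def model_mass(model: "Model") -> float:
    """Mass (Da) of the atoms actually present, occupancy-weighted."""
    return sum(ATOMIC_MASS.get(a.element, 12.0) * a.occ
               for _, _, a in model.iter_atoms())


class PDBParseError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occ: float = 1.0
    b: float = 20.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not (0.0 <= self.occ <= 1.0):
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.b < 0:
            raise ValueError(f"negative B-factor {self.b}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.xyz.copy(), self.occ, self.b)


@dataclass
class Residue:
    resname: str
    seqnum: int
    atoms: list = field(default_factory=list)

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate atom names in residue {self.seqnum}")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.resname, self.seqnum, [a.copy() for a in self.atoms])


@dataclass
class Model:
    chains: dict = field(default_factory=dict)
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for cid, residues in self.chains.items():
            nums = [r.seqnum for r in residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(
                    f"residue numbers not strictly increasing in chain {cid}")

    def copy(self) -> "Model":
        m = Model({cid: [r.copy() for r in res] for cid, res in self.chains.items()},
                  self.label)
        m.meta = _copy.deepcopy(self.meta)
        return m

    def iter_atoms(self):
        for cid, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom

    def iter_residues(self):
        for cid, residues in self.chains.items():
            for res in residues:
                yield cid, res

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def coords(self, atom_names=None) -> np.ndarray:
        """All atom positions (optionally restricted by atom name) as (n, 3)."""
        out = [a.xyz for _, _, a in self.iter_atoms()
               if atom_names is None or a.name in atom_names]
        if not out:
            return np.zeros((0, 3))
        return np.array(out)

    def set_coords(self, xyz: np.ndarray, atom_names=None) -> None:
        i = 0
        for _, _, a in self.iter_atoms():
            if atom_names is None or a.name in atom_names:
                a.xyz = np.asarray(xyz[i], dtype=float)
                i += 1
        if i != len(xyz):
            raise ValueError("coordinate count mismatch")

    def centroid(self, atom_names=None) -> np.ndarray:
        return self.coords(atom_names).mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Model":
        """Return a copy with x' = R @ x + t applied to every atom."""
        m = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for _, _, a in m.iter_atoms():
            a.xyz = R @ a.xyz + t
        return m

    def merged(self, other: "Model") -> "Model":
        """Combine chains of two models; other's chains renamed on collision."""
        m = self.copy()
        alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
        for cid, residues in other.chains.items():
            new_id = cid
            if new_id in m.chains:
                new_id = next(c for c in alphabet if c not in m.chains)
            m.chains[new_id] = [r.copy() for r in residues]
        return m


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must be in (0, 180)")
        g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        if g.volume <= 0:
            raise ValueError("cell volume must be positive")
        self._orth = np.array(g.orth.mat.tolist())
        self._frac = np.array(g.frac.mat.tolist())
        self._volume = g.volume

    @property
    def volume(self) -> float:
        return self._volume

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> orthogonal: x_cart = M @ x_frac."""
        return self._orth

    @property
    def frac_matrix(self) -> np.ndarray:
        return self._frac

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self._orth.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, float) @ self._frac.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) for integer Miller index rows."""
        svec = np.atleast_2d(np.asarray(hkl, float)) @ self._frac
        s = np.linalg.norm(svec, axis=1)
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), np.inf)


_BUILTIN_GROUPS = {"P1": "P 1", "P21": "P 1 21 1", "P212121": "P 21 21 21"}


@dataclass
class SymmetryOps:
    name: str
    ops: list  # list of (3x3 int rotation acting on fractional coords, frac translation)

    def __post_init__(self):
        self.ops = [(np.asarray(R, float), np.asarray(t, float)) for R, t in self.ops]
        if not any(np.allclose(R, np.eye(3)) and np.allclose(t % 1.0, 0)
                   for R, t in self.ops):
            raise ValueError("identity operator missing")

    def __len__(self):
        return len(self.ops)

    @classmethod
    def from_name(cls, name: str) -> "SymmetryOps":
        key = name.replace(" ", "").replace("(", "").replace(")", "").upper()
        if key not in _BUILTIN_GROUPS:
            raise ValueError(
                f"space group {name!r} is not built in (built-ins: P1, P21, P212121); "
                "supply explicit operators instead")
        sg = gemmi.SpaceGroup(_BUILTIN_GROUPS[key])
        den = float(gemmi.Op.DEN)
        ops = [(np.array(op.rot, float) / den, np.array(op.tran, float) / den)
               for op in sg.operations()]
        return cls(key, ops)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition; returns (R, t) with ref ≈ R @ mob + t."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - cm, reference - cr
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # guard against degenerate (collinear / coplanar with ambiguity) input
    if S[1] < 1e-8 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) coordinates: superposition ill-defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def _matched_pairs(mobile: Model, reference: Model, selection=None):
    ref_index = {}
    for cid, res in reference.iter_residues():
        for a in res.atoms:
            if selection is None or a.name in selection:
                ref_index[(cid, res.seqnum, a.name)] = a.xyz
    mob, ref = [], []
    for cid, res in mobile.iter_residues():
        for a in res.atoms:
            if selection is not None and a.name not in selection:
                continue
            key = (cid, res.seqnum, a.name)
            if key in ref_index:
                mob.append(a.xyz)
                ref.append(ref_index[key])
    return np.array(mob), np.array(ref)


def superpose(mobile: Model, reference: Model, selection=None) -> SuperpositionResult:
    """Kabsch superposition over atoms paired by (chain, seqnum, atom name)."""
    mob, ref = _matched_pairs(mobile, reference, selection)
    if len(mob) < 3:
        raise ValueError(f"need >= 3 matched atoms, got {len(mob)}")
    R, t = kabsch(mob, ref)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(R, t, rmsd, len(mob))


def main_chain_rmsd(mobile: Model, reference: Model) -> float:
    return superpose(mobile, reference, selection=set(MAIN_CHAIN_ATOMS)).rmsd


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)

def read_structure(path):
    """Read a PDB file -> (Model, UnitCell | None, space-group label | None)."""
    try:
        st = gemmi.read_pdb(str(path))
    except Exception as exc:  # gemmi reports the offending line
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models in file")
    chains = {}
    for chain in st[0]:
        residues = []
        for res in chain:
            if res.seqid.icode not in ("", " ", "\x00"):
                raise PDBParseError(
                    f"{path}: insertion code {res.seqid.icode!r} at residue "
                    f"{chain.name}/{res.seqid.num} not supported")
            by_name = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                else:
                    # altloc collapse: highest occupancy wins, ties by altloc letter
                    key_new = (-at.occ, at.altloc or "~")
                    key_old = (-prev.occ, prev.altloc or "~")
                    if key_new < key_old:
                        by_name[at.name] = at
            atoms = [Atom(at.name, at.element.name or at.name[:1],
                          np.array([at.pos.x, at.pos.y, at.pos.z]),
                          min(max(at.occ, 0.0), 1.0), max(at.b_iso, 0.0))
                     for at in by_name.values()]
            if atoms:
                residues.append(Residue(res.name, res.seqid.num, atoms))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise PDBParseError(f"{path}: empty model (no ATOM/HETATM records)")
    model = Model(chains, label=str(path))
    cell = None
    if st.cell.a > 1.0 and st.cell.volume > 2.0:  # gemmi default dummy cell is 1,1,1
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = st.spacegroup_hm if st.spacegroup_hm and st.spacegroup_hm != "P 1" else (
        st.spacegroup_hm or None)
    return model, cell, sg


def read_model(path) -> Model:
    return read_structure(path)[0]


def write_model(model: Model, path, cell: UnitCell | None = None,
                spacegroup: str | None = None) -> None:
    """Write PDB-format coordinates (fixed columns, 3-decimal positions)."""
    if not model.chains or model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = model.label or "micromr"
    if cell is not None:
        st.cell = gemmi.UnitCell(cell.a, cell.b, cell.c,
                                 cell.alpha, cell.beta, cell.gamma)
    if spacegroup:
        st.spacegroup_hm = _BUILTIN_GROUPS.get(
            spacegroup.replace(" ", "").upper(), spacegroup)
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        gc = gemmi.Chain(cid)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.resname
            gr.seqid = gemmi.SeqId(res.seqnum, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = a.occ
                ga.b_iso = a.b
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def apply_symmetry(frac_point: np.ndarray, sym: SymmetryOps) -> np.ndarray:
    """All symmetry images of a fractional point, reduced mod 1."""
    p = np.asarray(frac_point, float)
    return np.array([(R @ p + t) % 1.0 for R, t in sym.ops])
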