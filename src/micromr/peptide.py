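"""Ideal-geometry polypeptide backbone construction and torsion utilities.

Backbones are built by sequential natural-extension (NeRF-style) atom
placement from phi/psi/omega torsions with ideal bond lengths and angles
(Engh-Huber-like values).  Only heavy main-chain atoms plus CB are handled;
side chains beyond CB are outside the scope of the rebuilding engine.
"""

from __future__ import annotations

import numpy as np

from .model_core import Atom, Model, Residue

# ideal bond lengths (Å)
BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.530}
# ideal bond angles (degrees)
ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
         "CA-C-O": 120.8, "N-CA-CB": 110.5, "C-CA-CB": 110.1}
CB_IMPROPER = 122.6      # dihedral(C, N, CA, CB) for L-amino acids
ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise 3-vector cross product (much faster than np.cross here)."""
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def dihedral_rows(a, b, c, d) -> np.ndarray:
    """Signed dihedral angles (degrees) for rows of four (n, 3) arrays."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = _cross_rows(b1, b2)
    n2 = _cross_rows(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = _cross_rows(n1, b2n)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    return np.degrees(np.arctan2(y, x))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in degrees."""
    return float(dihedral_rows(np.asarray(a)[None], np.asarray(b)[None],
                               np.asarray(c)[None], np.asarray(d)[None])[0])


def bond_angle(a, b, c) -> float:
    u, v = a - b, c - b
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Position D bonded to c with given b-c-D angle and a-b-c-D torsion."""
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.cos(tor) * np.sin(ang),
                               -np.sin(tor) * np.sin(ang)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omegas, anchor=None, psi_prev: float = 140.0):
    """Build (N, CA, C) triples for n residues from torsions.

    ``anchor`` is an optional (N, CA, C) triple of the residue immediately
    before the built stretch; ``psi_prev`` is that residue's psi, which
    positions the first built N.  phi of residue i uses phis[i], omega of
    the i-th peptide bond omegas[i] (omegas[0] links anchor to residue 0).
    """
    n = len(phis)
    out = np.zeros((n, 3, 3))
    if anchor is None:
        N = np.array([0.0, 0.0, 0.0])
        CA = N + np.array([BOND["N-CA"], 0.0, 0.0])
        ang = np.radians(ANGLE["N-CA-C"])
        C = CA + BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        out[0] = (N, CA, C)
        start = 1
        prev = (N, CA, C)
        # residue 0's phi is undefined without an anchor; psi applies below
    else:
        prev = tuple(np.asarray(x, float) for x in anchor)
        start = 0
    for i in range(start, n):
        pN, pCA, pC = prev
        psi = psi_prev if (i == 0 and anchor is not None) else psis[i - 1]
        N = place_atom(pN, pCA, pC, BOND["C-N"], ANGLE["CA-C-N"], psi)
        CA = place_atom(pCA, pC, N, BOND["N-CA"], ANGLE["C-N-CA"], omegas[i])
        C = place_atom(pC, N, CA, BOND["CA-C"], ANGLE["N-CA-C"], phis[i])
        out[i] = (N, CA, C)
        prev = (N, CA, C)
    return out


def place_oxygen(N, CA, C, next_N=None, psi: float = 140.0) -> np.ndarray:
    if next_N is not None:
        return place_atom(next_N, CA, C, BOND["C-O"], ANGLE["CA-C-O"], 180.0)
    return place_atom(N, CA, C, BOND["C-O"], ANGLE["CA-C-O"], psi - 180.0)


def place_cb(N, CA, C) -> np.ndarray:
    return place_atom(C, N, CA, BOND["CA-CB"], ANGLE["N-CA-CB"], CB_IMPROPER)


def chain_from_backbone(triples, resnames, seqnums, b_factor: float = 20.0,
                        with_cb: bool = True) -> list:
    """Residue list (N, CA, C, O, CB) from (n, 3, 3) backbone triples."""
    residues = []
    n = len(triples)
    for i, (name, num) in enumerate(zip(resnames, seqnums)):
        N, CA, C = triples[i]
        next_N = triples[i + 1][0] if i + 1 < n else None
        atoms = [Atom("N", "N", N, 1.0, b_factor),
                 Atom("CA", "C", CA, 1.0, b_factor),
                 Atom("C", "C", C, 1.0, b_factor),
                 Atom("O", "O", place_oxygen(N, CA, C, next_N), 1.0, b_factor)]
        if with_cb and name != "GLY":
            atoms.append(Atom("CB", "C", place_cb(N, CA, C), 1.0, b_factor))
        residues.append(Residue(name, num, atoms))
    return residues


def build_chain_model(phis, psis, omegas, sequence3, chain_id: str = "A",
                      b_factor: float = 20.0) -> Model:
    triples = build_backbone(phis, psis, omegas)
    residues = chain_from_backbone(triples, sequence3,
                                   list(range(1, len(sequence3) + 1)), b_factor)
    return Model({chain_id: residues})


def extract_torsions(residues) -> tuple:
    """(phi, psi, omega) arrays for an ordered residue list; NaN where undefined."""
    n = len(residues)
    co = [{a.name: a.xyz for a in r.atoms} for r in residues]
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    linked = np.array([residues[i].seqnum == residues[i - 1].seqnum + 1
                       and all(k in co[i] for k in ("N", "CA", "C"))
                       and all(k in co[i - 1] for k in ("N", "CA", "C"))
                       for i in range(1, n)], bool) if n > 1 else np.zeros(0, bool)
    idx = np.flatnonzero(linked) + 1
    if len(idx):
        Cm = np.array([co[i - 1]["C"] for i in idx])
        CAm = np.array([co[i - 1]["CA"] for i in idx])
        N = np.array([co[i]["N"] for i in idx])
        CA = np.array([co[i]["CA"] for i in idx])
        C = np.array([co[i]["C"] for i in idx])
        phi[idx] = dihedral_rows(Cm, N, CA, C)
        omega[idx] = dihedral_rows(CAm, Cm, N, CA)
        Np = np.array([co[i - 1]["N"] for i in idx])
        psi[idx - 1] = dihedral_rows(Np, CAm, Cm, N)
    return phi, psi, omega
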