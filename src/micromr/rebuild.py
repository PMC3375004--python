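"""Density-guided Monte-Carlo fragment rebuilding, real-space refinement and
the convergence-controlled autobuild loop.

The score that drives every move trades a physical-plausibility surrogate
(bond/angle deviations, steric clashes, backbone-torsion outliers) against
the fit of the model to a standardized density map:

    score = w_dens * density_fit - w_geom * (bond_dev + angle_dev/50
                                             + clash + 2 * rama_outliers)

Window proposals replace the phi/psi/omega torsions of a 3- or 9-residue
stretch with a fragment from the torsion library, rebuild the stretch with
ideal geometry, close internal windows onto the downstream anchor by cyclic
coordinate descent (closure rmsd <= 0.5 Å required) and are accepted by a
Metropolis criterion.  Loops of up to ``max_loop_len`` residues are built
into annotated gaps the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from . import peptide
from .density_mod import density_modify, find_ncs_operators
from .model_core import AA1TO3, Model, Residue, SymmetryOps, model_mass
from .peptide import ANGLE, BOND, build_backbone, dihedral, place_cb, place_oxygen
from .xray_core import DensityMap, RFactorReport, ReflectionSet, compute_map, \
    real_space_fit, scale_and_r, set_f_calc, sf_direct

CLASH_DISTANCE = 2.4
CLOSURE_RMSD_MAX = 0.5
CLOSURE_RMSD_GOOD = 0.25
CCD_MAX_PASSES = 40
BACKBONE_NAMES = ("N", "CA", "C", "O", "CB")


# ---------------------------------------------------------------------------
# Score weights and fragment library


@dataclass
class ScoreWeights:
    w_geom: float = 1.0
    w_dens: float = 1.0

    def __post_init__(self):
        if self.w_geom < 0 or self.w_dens < 0 or (self.w_geom == 0 and
                                                  self.w_dens == 0):
            raise ValueError("weights must be >= 0 and not both zero")


@dataclass
class RebuildParams:
    n_models: int = 20
    n_steps: int = 300
    temperature: float = 0.05
    max_loop_len: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


@dataclass
class Fragment:
    phis: np.ndarray
    psis: np.ndarray
    omegas: np.ndarray
    tag: str = ""

    def __post_init__(self):
        self.phis = np.asarray(self.phis, float)
        self.psis = np.asarray(self.psis, float)
        self.omegas = np.asarray(self.omegas, float)
        if not (len(self.phis) == len(self.psis) == len(self.omegas)):
            raise ValueError("incomplete fragment torsions")

    def __len__(self):
        return len(self.phis)


@dataclass
class FragmentLibrary:
    fragments: list

    def __post_init__(self):
        lengths = {len(f) for f in self.fragments}
        if not {3, 9} <= lengths:
            raise ValueError("library must contain both 3- and 9-residue fragments")
        self._by_len = {}
        for f in self.fragments:
            self._by_len.setdefault(len(f), []).append(f)

    def by_length(self, length: int) -> list:
        if length not in self._by_len:
            raise ValueError(f"no fragments of length {length} in library")
        return self._by_len[length]


_CANONICAL = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 130.0),
    "ppII": (-75.0, 145.0),
    "turn": (-80.0, 0.0),
}


def make_default_library(seed: int = 0, n_jitter: int = 12) -> FragmentLibrary:
    """Deterministic synthetic torsion library (~200 entries).

    Canonical helix/strand/ppII/turn 3-mers and 9-mers plus Gaussian-jittered
    variants (sigma 12 degrees on phi/psi, 3 on omega) and a few mixed 9-mers.
    """
    rng = np.random.default_rng(seed)
    frags = []
    for length in (3, 9):
        for tag, (phi, psi) in _CANONICAL.items():
            base = Fragment(np.full(length, phi), np.full(length, psi),
                            np.full(length, 180.0), tag)
            frags.append(base)
            for _ in range(n_jitter):
                frags.append(Fragment(
                    base.phis + rng.normal(0, 12, length),
                    base.psis + rng.normal(0, 12, length),
                    base.omegas + rng.normal(0, 3, length), tag + "-j"))
    # mixed 9-mers: random concatenations of canonical triples
    kinds = list(_CANONICAL.values())
    for _ in range(40):
        picks = [kinds[rng.integers(len(kinds))] for _ in range(3)]
        phi = np.concatenate([np.full(3, p) for p, _ in picks])
        psi = np.concatenate([np.full(3, s) for _, s in picks])
        frags.append(Fragment(phi + rng.normal(0, 8, 9),
                              psi + rng.normal(0, 8, 9),
                              np.full(9, 180.0) + rng.normal(0, 3, 9), "mixed"))
    return FragmentLibrary(frags)


# ---------------------------------------------------------------------------
# Geometry scoring


@dataclass
class GeometryScore:
    bond_dev: float
    angle_dev: float
    clash: int
    rama_outliers: float

    @property
    def penalty(self) -> float:
        return self.bond_dev + self.angle_dev / 50.0 + self.clash \
            + 2.0 * self.rama_outliers


# broad allowed (phi, psi) regions: right-handed alpha, beta/ppII, left alpha
def _rama_allowed(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    a = (phi >= -180) & (phi <= -20) & (psi >= -120) & (psi <= 60)
    b = (phi >= -180) & (phi <= -20) & ((psi > 60) | (psi < -150))
    l = (phi >= 20) & (phi <= 100) & (psi >= -60) & (psi <= 100)
    return a | b | l


def _bond_angle_terms(model: Model):
    """Lists of (xyz_i, xyz_j, l0) bonds and (a, b, c, theta0) angles."""
    bonds, angles = [], []
    for cid, residues in model.chains.items():
        for i, res in enumerate(residues):
            co = {a.name: a.xyz for a in res.atoms}
            if "N" in co and "CA" in co:
                bonds.append((co["N"], co["CA"], BOND["N-CA"]))
            if "CA" in co and "C" in co:
                bonds.append((co["CA"], co["C"], BOND["CA-C"]))
            if "C" in co and "O" in co:
                bonds.append((co["C"], co["O"], BOND["C-O"]))
            if "CA" in co and "CB" in co:
                bonds.append((co["CA"], co["CB"], BOND["CA-CB"]))
            if all(k in co for k in ("N", "CA", "C")):
                angles.append((co["N"], co["CA"], co["C"], ANGLE["N-CA-C"]))
            if all(k in co for k in ("CA", "C", "O")):
                angles.append((co["CA"], co["C"], co["O"], ANGLE["CA-C-O"]))
            if all(k in co for k in ("N", "CA", "CB")):
                angles.append((co["N"], co["CA"], co["CB"], ANGLE["N-CA-CB"]))
            if i + 1 < len(residues) and residues[i + 1].seqnum == res.seqnum + 1:
                cn = {a.name: a.xyz for a in residues[i + 1].atoms}
                if "C" in co and "N" in cn:
                    bonds.append((co["C"], cn["N"], BOND["C-N"]))
                    if "CA" in co:
                        angles.append((co["CA"], co["C"], cn["N"], ANGLE["CA-C-N"]))
                    if "CA" in cn:
                        angles.append((co["C"], cn["N"], cn["CA"], ANGLE["C-N-CA"]))
    return bonds, angles


def geometry_score(model: Model) -> GeometryScore:
    bonds, angles = _bond_angle_terms(model)
    bond_dev = angle_dev = 0.0
    if bonds:
        P = np.array([b[0] for b in bonds])
        Q = np.array([b[1] for b in bonds])
        L0 = np.array([b[2] for b in bonds])
        d = np.sqrt(((P - Q) ** 2).sum(axis=1))
        bond_dev = float(np.sqrt(np.mean((d - L0) ** 2)))
    if angles:
        A = np.array([a[0] for a in angles])
        B = np.array([a[1] for a in angles])
        C = np.array([a[2] for a in angles])
        T0 = np.array([a[3] for a in angles])
        u, v = A - B, C - B
        cosang = (u * v).sum(axis=1) / np.sqrt(
            (u ** 2).sum(axis=1) * (v ** 2).sum(axis=1))
        th = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        angle_dev = float(np.sqrt(np.mean((th - T0) ** 2)))
    # clashes: non-bonded heavy-atom pairs closer than 2.4 Å; pairs within the
    # same or sequence-adjacent residue are covalently connected and excluded
    xyz, resid = [], []
    for ci, (cid, residues) in enumerate(model.chains.items()):
        for res in residues:
            for a in res.atoms:
                xyz.append(a.xyz)
                resid.append((ci, res.seqnum))
    clash = 0
    if len(xyz) > 1:
        tree = cKDTree(np.array(xyz))
        for i, j in tree.query_pairs(CLASH_DISTANCE):
            ci, ni = resid[i]
            cj, nj = resid[j]
            if ci == cj and abs(ni - nj) <= 1:
                continue
            clash += 1
    # torsion outliers over residues with defined phi and psi
    n_def, n_out = 0, 0
    for cid, residues in model.chains.items():
        phi, psi, _ = peptide.extract_torsions(residues)
        ok = ~np.isnan(phi) & ~np.isnan(psi)
        n_def += ok.sum()
        n_out += (~_rama_allowed(phi[ok], psi[ok])).sum()
    rama = n_out / n_def if n_def else 0.0
    return GeometryScore(bond_dev, angle_dev, int(clash), float(rama))


def combined_score(model: Model, dmap: DensityMap, w: ScoreWeights,
                   n_total: int | None = None) -> float:
    """Density fit vs geometry trade-off; higher is better; deterministic.

    With ``n_total`` the density term is averaged over that many target
    positions, counting unbuilt residues as zero fit, so that building a
    well-fitting loop into a gap raises the score (completeness-aware form
    used inside the Monte-Carlo rebuilder).  Without it the density term is
    the plain per-residue mean.
    """
    if model.n_atoms == 0:
        raise ValueError("empty model")
    dens = real_space_fit(model, dmap).overall
    if n_total is not None and n_total > 0:
        dens *= model.n_residues / n_total
    geom = geometry_score(model).penalty
    return w.w_dens * dens - w.w_geom * geom


def _target_length(model: Model) -> int | None:
    seq = model.meta.get("target_seq")
    return len(seq) if seq else None


# ---------------------------------------------------------------------------
# CCD closure and window proposals


def _rotation_about(axis_unit: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    ux, uy, uz = axis_unit
    c, s = np.cos(theta), np.sin(theta)
    mc = 1.0 - c
    return np.array([
        [c + ux * ux * mc, ux * uy * mc - uz * s, ux * uz * mc + uy * s],
        [uy * ux * mc + uz * s, c + uy * uy * mc, uy * uz * mc - ux * s],
        [uz * ux * mc - uy * s, uz * uy * mc + ux * s, c + uz * uz * mc]])


def _rodrigues(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
               theta: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    return (points - origin) @ _rotation_about(u, theta).T + origin


def _ccd_close(W: np.ndarray, pred: np.ndarray, targets: np.ndarray,
               anchor_ca: np.ndarray, anchor_c: np.ndarray):
    """Cyclic coordinate descent closing a rebuilt window onto fixed targets.

    W: (3L, 3) window backbone atoms [N0, CA0, C0, N1, ...]; pred: (3, 3)
    predicted downstream anchor atoms (move rigidly with the chain end);
    targets: (3, 3) their fixed current positions.  Degrees of freedom are
    the anchor psi and each window residue's phi/psi.
    """
    L = len(W) // 3
    dofs = [("prev", anchor_ca, anchor_c, 0)]
    for i in range(L):
        dofs.append(("phi", 3 * i, 3 * i + 1, 3 * i + 2))
        dofs.append(("psi", 3 * i + 1, 3 * i + 2, 3 * (i + 1)))
    rms = np.inf
    for it in range(CCD_MAX_PASSES):
        for kind, a_ref, b_ref, start in dofs:
            if kind == "prev":
                o, b = a_ref, b_ref
            else:
                o, b = W[a_ref], W[b_ref]
            u = b - o
            u = u / np.sqrt(u @ u)
            v = pred - o                      # (3, 3)
            z = np.outer(v @ u, u)
            rv = v - z                        # radial components
            d = targets - o - z
            # optimal rotation: maximize sum cos(t) rv.d + sin(t) (u x rv).d
            uxrv = peptide._cross_rows(np.broadcast_to(u, rv.shape), rv)
            theta = np.arctan2((uxrv * d).sum(), (rv * d).sum())
            if abs(theta) < 1e-3:
                continue
            R = _rotation_about(u, theta)
            if start < len(W):
                W[start:] = (W[start:] - o) @ R.T + o
            pred[:] = (pred - o) @ R.T + o
        new_rms = float(np.sqrt(((pred - targets) ** 2).sum(axis=1).mean()))
        if new_rms < CLOSURE_RMSD_GOOD:
            return new_rms
        if it >= 3 and rms - new_rms < 5e-3:
            return new_rms        # stalled
        rms = new_rms
    return rms


def _segments(residues) -> list:
    """Maximal runs of consecutive seqnums, as index lists."""
    segs, cur = [], [0]
    for i in range(1, len(residues)):
        if residues[i].seqnum == residues[i - 1].seqnum + 1:
            cur.append(i)
        else:
            segs.append(cur)
            cur = [i]
    segs.append(cur)
    return [s for s in segs if residues]


def _res_coords(res) -> dict:
    return {a.name: a.xyz for a in res.atoms}


def _set_backbone(res: Residue, N, CA, C, O, CB=None) -> None:
    """Replace a residue's atoms with the rebuilt backbone (side chains beyond
    CB are dropped for rebuilt residues)."""
    from .model_core import Atom
    b = float(np.mean([a.b for a in res.atoms])) if res.atoms else 20.0
    atoms = [Atom("N", "N", N, 1.0, b), Atom("CA", "C", CA, 1.0, b),
             Atom("C", "C", C, 1.0, b), Atom("O", "O", O, 1.0, b)]
    if CB is not None and res.resname != "GLY":
        atoms.append(Atom("CB", "C", CB, 1.0, b))
    res.atoms = atoms


def _apply_window(cand_res, seg, ws, triples, next_n):
    """Write rebuilt backbone triples into candidate residues ws..ws+L-1."""
    L = len(triples)
    # anchor O follows the (possibly moved) first window N
    prev = cand_res[seg[ws - 1]]
    co_prev = _res_coords(prev)
    o_at = prev.atom("O")
    if o_at is not None:
        o_at.xyz = place_oxygen(co_prev["N"], co_prev["CA"], co_prev["C"],
                                next_N=triples[0][0])
    for k in range(L):
        N, CA, C = triples[k]
        nn = triples[k + 1][0] if k + 1 < L else next_n
        O = place_oxygen(N, CA, C, next_N=nn)
        CB = place_cb(N, CA, C)
        _set_backbone(cand_res[seg[ws + k]], N, CA, C, O, CB)


def _propose_window(model: Model, dmap, lib: FragmentLibrary, rng,
                    windows_restrict=None):
    """One fragment-insertion candidate; returns a new Model or None."""
    choices = []
    for cid, residues in model.chains.items():
        for seg in _segments(residues):
            for L in (3, 9):
                # window needs an upstream in-segment anchor
                for ws in range(1, len(seg) - L + 1):
                    if windows_restrict is not None:
                        nums = {residues[seg[ws + k]].seqnum for k in range(L)}
                        if not (nums & windows_restrict.get(cid, set())):
                            continue
                    choices.append((cid, tuple(seg), ws, L))
    if not choices:
        return None
    cid, seg, ws, L = choices[rng.integers(len(choices))]
    frag = lib.by_length(L)[rng.integers(len(lib.by_length(L)))]
    residues = model.chains[cid]
    prev = _res_coords(residues[seg[ws - 1]])
    first = _res_coords(residues[seg[ws]])
    psi_prev = dihedral(prev["N"], prev["CA"], prev["C"], first["N"])
    triples = build_backbone(frag.phis, frag.psis, frag.omegas,
                             anchor=(prev["N"], prev["CA"], prev["C"]),
                             psi_prev=psi_prev)
    internal = ws + L <= len(seg) - 1
    if internal:
        nxt = _res_coords(residues[seg[ws + L]])
        targets = np.array([nxt["N"], nxt["CA"], nxt["C"]])
        last = _res_coords(residues[seg[ws + L - 1]])
        phi_next = dihedral(last["C"], nxt["N"], nxt["CA"], nxt["C"])
        pN = place_atom_chain(triples[-1], frag.psis[-1])
        pCA = peptide.place_atom(triples[-1][1], triples[-1][2], pN,
                                 BOND["N-CA"], ANGLE["C-N-CA"], 180.0)
        pC = peptide.place_atom(triples[-1][2], pN, pCA,
                                BOND["CA-C"], ANGLE["N-CA-C"], phi_next)
        pred = np.array([pN, pCA, pC])
        W = triples.reshape(-1, 3).copy()
        rms = _ccd_close(W, pred, targets, prev["CA"], prev["C"])
        if rms > CLOSURE_RMSD_MAX:
            return None
        triples = W.reshape(-1, 3, 3)
        next_n = targets[0]
    else:
        next_n = None
    cand = model.copy()
    _apply_window(cand.chains[cid], list(seg), ws, triples, next_n)
    return cand


def place_atom_chain(triple, psi):
    N, CA, C = triple
    return peptide.place_atom(N, CA, C, BOND["C-N"], ANGLE["CA-C-N"], psi)


def _gap_runs(model: Model):
    gaps = sorted(model.meta.get("gaps", []))
    runs, cur = [], []
    for g in gaps:
        if cur and g == cur[-1] + 1:
            cur.append(g)
        else:
            if cur:
                runs.append(cur)
            cur = [g]
    if cur:
        runs.append(cur)
    return runs


def _propose_loop(model: Model, lib: FragmentLibrary, params, rng):
    """Build one annotated gap (<= max_loop_len residues) into the model."""
    runs = [r for r in _gap_runs(model) if len(r) <= params.max_loop_len]
    if not runs:
        return None
    run = runs[rng.integers(len(runs))]
    target_seq = model.meta.get("target_seq", "")
    cid = next(iter(model.chains))
    residues = model.chains[cid]
    nums = [r.seqnum for r in residues]
    if run[0] - 1 not in nums:        # no upstream anchor: N-terminal gap, skip
        return None
    ai = nums.index(run[0] - 1)
    prev = _res_coords(residues[ai])
    L = len(run)
    torsions = []
    while len(torsions) < L:
        frag = lib.by_length(3)[rng.integers(len(lib.by_length(3)))]
        torsions.extend(zip(frag.phis, frag.psis, frag.omegas))
    torsions = torsions[:L]
    phis = np.array([t[0] for t in torsions])
    psis = np.array([t[1] for t in torsions])
    omegas = np.array([t[2] for t in torsions])
    psi_prev = float(rng.uniform(-180, 180))
    triples = build_backbone(phis, psis, omegas,
                             anchor=(prev["N"], prev["CA"], prev["C"]),
                             psi_prev=psi_prev)
    has_next = run[-1] + 1 in nums
    if has_next:
        nxt = _res_coords(residues[nums.index(run[-1] + 1)])
        targets = np.array([nxt["N"], nxt["CA"], nxt["C"]])
        pN = place_atom_chain(triples[-1], psis[-1])
        pCA = peptide.place_atom(triples[-1][1], triples[-1][2], pN,
                                 BOND["N-CA"], ANGLE["C-N-CA"], 180.0)
        pC = peptide.place_atom(triples[-1][2], pN, pCA,
                                BOND["CA-C"], ANGLE["N-CA-C"], -120.0)
        pred = np.array([pN, pCA, pC])
        W = triples.reshape(-1, 3).copy()
        rms = _ccd_close(W, pred, targets, prev["CA"], prev["C"])
        if rms > CLOSURE_RMSD_MAX:
            return None
        triples = W.reshape(-1, 3, 3)
    cand = model.copy()
    cres = cand.chains[cid]
    from .model_core import Atom
    new_res = []
    for k, pos in enumerate(run):
        aa = AA1TO3.get(target_seq[pos - 1], "ALA") if pos <= len(target_seq) \
            else "ALA"
        N, CA, C = triples[k]
        if k + 1 < L:
            nn = triples[k + 1][0]
        elif has_next:
            nn = targets[0]
        else:
            nn = None
        O = place_oxygen(N, CA, C, next_N=nn, psi=psis[k])
        atoms = [Atom("N", "N", N), Atom("CA", "C", CA), Atom("C", "C", C),
                 Atom("O", "O", O)]
        if aa != "GLY":
            atoms.append(Atom("CB", "C", place_cb(N, CA, C)))
        new_res.append(Residue(aa, pos, atoms))
    merged = sorted(cres + new_res, key=lambda r: r.seqnum)
    cand.chains[cid] = merged
    cand.meta["gaps"] = [g for g in cand.meta.get("gaps", []) if g not in run]
    return cand


def metropolis_accept(delta: float, temperature: float, rng) -> bool:
    """Metropolis criterion on a score where higher is better; at zero
    temperature only improving moves pass."""
    if delta >= 0:
        return True
    if temperature <= 0:
        return False
    return bool(rng.random() < np.exp(delta / temperature))


def rebuild_model(model: Model, dmap: DensityMap, lib: FragmentLibrary,
                  params: RebuildParams, w: ScoreWeights,
                  windows_restrict=None) -> list:
    """Monte-Carlo fragment rebuilding; returns the end models of
    ``params.n_models`` independent seeded trajectories."""
    if all(len(seg) < 4 for residues in model.chains.values()
           for seg in _segments(residues)) and not _gap_runs(model):
        raise ValueError("no rebuildable window (segments shorter than 4)")
    std = dmap.standardized()
    n_total = _target_length(model)
    out = []
    for traj in range(params.n_models):
        rng = np.random.default_rng(params.seed + traj)
        current = model.copy()
        cur_score = combined_score(current, std, w, n_total)
        for _ in range(params.n_steps):
            buildable_gaps = [r for r in _gap_runs(current)
                              if len(r) <= params.max_loop_len]
            if buildable_gaps and rng.random() < 0.3:
                cand = _propose_loop(current, lib, params, rng)
            else:
                cand = _propose_window(current, std, lib, rng, windows_restrict)
            if cand is None:
                continue
            try:
                cand_score = combined_score(cand, std, w, n_total)
            except ValueError:
                continue
            if metropolis_accept(cand_score - cur_score, params.temperature,
                                 rng):
                current, cur_score = cand, cand_score
        out.append(current)
    return out


def rebuild_with_ncs(model: Model, dmap: DensityMap, ops: list,
                     lib: FragmentLibrary, params: RebuildParams,
                     w: ScoreWeights) -> Model:
    """Rebuild one reference copy and replicate it through the NCS operators,
    yielding a model with exact (idealized) non-crystallographic symmetry."""
    ref_chain = ops[0].source_chain if ops and ops[0].source_chain else \
        next(iter(model.chains))
    for op in ops:
        if op.target_chain and op.target_chain not in model.chains:
            raise ValueError(f"operator targets unknown chain {op.target_chain}")
    ref = Model({ref_chain: [r.copy() for r in model.chains[ref_chain]]})
    ref.meta = dict(model.meta)
    candidates = rebuild_model(ref, dmap, lib, params, w)
    std = dmap.standardized()
    n_total = _target_length(ref)
    best = max(candidates,
               key=lambda m: combined_score(m, std, w, n_total))
    out = model.copy()
    out.chains[ref_chain] = [r.copy() for r in best.chains[ref_chain]]
    for op in ops:
        tgt = op.target_chain
        if not tgt or tgt == ref_chain:
            continue
        replica = [r.copy() for r in best.chains[ref_chain]]
        for res in replica:
            for a in res.atoms:
                a.xyz = op.apply(a.xyz)[0]
        out.chains[tgt] = replica
    return out


# ---------------------------------------------------------------------------
# Real-space refinement


def _density_field(grid: np.ndarray, cell=None, blur_b: float = 0.0):
    """Sampler returning interpolated values and the exact (band-limited)
    spectral gradient of the map, both trilinearly interpolated.

    With ``blur_b`` > 0 the map is first convolved with a Gaussian of that
    B-value (Å^2).  Sampling a map blurred by the atomic profile at atom
    centers is the matched-filter overlap of model and map density, whose
    maximum for a model-generated map lies at the generating atom positions
    rather than at the (termination-shifted) raw-map peaks."""
    import scipy.fft
    from scipy.ndimage import map_coordinates
    n = np.array(grid.shape)
    C = scipy.fft.fftn(grid)
    if blur_b > 0.0 and cell is not None:
        idx = [scipy.fft.fftfreq(grid.shape[ax]) * grid.shape[ax]
               for ax in range(3)]
        H = np.stack(np.meshgrid(*idx, indexing="ij"), axis=-1)
        s2 = ((H @ cell.frac_matrix) ** 2).sum(axis=-1)
        C = C * np.exp(-blur_b * s2 / 4.0)
    dgrids = []
    for ax in range(3):
        shape = [1, 1, 1]
        shape[ax] = -1
        f = (2j * np.pi * scipy.fft.fftfreq(grid.shape[ax])).reshape(shape)
        dgrids.append(scipy.fft.ifftn(C * f).real * grid.shape[ax])  # d/dfrac

    def sample(frac: np.ndarray):
        coords = (frac % 1.0).T * n[:, None]
        vals = map_coordinates(grid, coords, order=1, mode="grid-wrap")
        gfrac = np.stack([map_coordinates(dg, coords, order=1,
                                          mode="grid-wrap")
                          for dg in dgrids], axis=1)
        return vals, gfrac

    return sample


def refine_real_space(model: Model, dmap: DensityMap, w: ScoreWeights,
                      max_iter: int = 5, sym: SymmetryOps | None = None) -> Model:
    """Real-space least-squares coordinate refinement with geometry restraints.

    Each round computes the band-limited model density on the map grid and a
    least-squares residual map; atoms then move (quasi-Newton, max 0.5 Å per
    atom per round) down a force field given by the residual blurred with a
    typical atomic profile, with harmonic bond/angle and soft-clash
    restraints.  The residual is identically zero when the map is the
    model's own synthesis, so such a model is a fixed point.  Snapshots are
    ranked by residual sum of squares; the returned model never scores below
    the input under the combined score (ascent guarantee).
    """
    import scipy.fft
    std = dmap.standardized()
    shape = std.grid.shape
    cell = dmap.cell
    if sym is None:
        sym = SymmetryOps.from_name("P1")
    # reciprocal-space helpers: |s|^2 per FFT index and the map's band mask
    idxf = [scipy.fft.fftfreq(shape[ax]) * shape[ax] for ax in range(3)]
    H = np.stack(np.meshgrid(*idxf, indexing="ij"), axis=-1)
    s2 = ((H @ cell.frac_matrix) ** 2).sum(axis=-1)
    Cmap = scipy.fft.fftn(std.grid)
    band = np.abs(Cmap) > 1e-6 * np.abs(Cmap).max()
    band[0, 0, 0] = False

    def residual_field(m: Model):
        """(ssr, value grid, d/dfrac grids) of the profile-blurred residual."""
        from .xray_core import sample_density
        bmin = min(a.b for _, _, a in m.iter_atoms())
        blur = max(0.0, 60.0 - bmin)
        rho = sample_density(m, cell, sym, shape, blur)
        Cm = scipy.fft.fftn(rho) * np.exp(blur * s2 / 4.0) * band
        rho_m = scipy.fft.ifftn(Cm).real
        denom = (rho_m * rho_m).sum()
        k = (std.grid * rho_m).sum() / denom if denom > 0 else 0.0
        R = std.grid - k * rho_m
        ssr = float((R * R).sum())
        CR = scipy.fft.fftn(R) * np.exp(-25.0 * s2 / 4.0)
        vals = scipy.fft.ifftn(CR).real
        dgrids = []
        for ax in range(3):
            sh = [1, 1, 1]
            sh[ax] = -1
            f = (2j * np.pi * scipy.fft.fftfreq(shape[ax])).reshape(sh)
            dgrids.append(scipy.fft.ifftn(CR * f).real * shape[ax])
        return ssr, vals, dgrids

    def interp(grids, frac):
        from scipy.ndimage import map_coordinates
        coords = (frac % 1.0).T * np.array(shape)[:, None]
        return [map_coordinates(g, coords, order=1, mode="grid-wrap")
                for g in grids]

    work = model.copy()
    atoms = [a for _, _, a in work.iter_atoms()]
    index = {id(a): i for i, a in enumerate(atoms)}
    occ = np.array([a.occ for a in atoms])
    frac_mat = dmap.cell.frac_matrix
    n_atoms = len(atoms)

    def current_terms():
        bonds, angles = [], []
        for cid, residues in work.chains.items():
            for i, res in enumerate(residues):
                co = {a.name: a for a in res.atoms}
                for x, y, l0 in (("N", "CA", BOND["N-CA"]),
                                 ("CA", "C", BOND["CA-C"]),
                                 ("C", "O", BOND["C-O"]),
                                 ("CA", "CB", BOND["CA-CB"])):
                    if x in co and y in co:
                        bonds.append((index[id(co[x])], index[id(co[y])], l0))
                for x, y, z, t0 in (("N", "CA", "C", ANGLE["N-CA-C"]),
                                    ("CA", "C", "O", ANGLE["CA-C-O"]),
                                    ("N", "CA", "CB", ANGLE["N-CA-CB"])):
                    if x in co and y in co and z in co:
                        angles.append((index[id(co[x])], index[id(co[y])],
                                       index[id(co[z])], np.radians(t0)))
                if i + 1 < len(residues) and \
                        residues[i + 1].seqnum == res.seqnum + 1:
                    cn = {a.name: a for a in residues[i + 1].atoms}
                    if "C" in co and "N" in cn:
                        bonds.append((index[id(co["C"])], index[id(cn["N"])],
                                      BOND["C-N"]))
                        if "CA" in co:
                            angles.append((index[id(co["CA"])],
                                           index[id(co["C"])],
                                           index[id(cn["N"])],
                                           np.radians(ANGLE["CA-C-N"])))
        return bonds, angles

    bonds, angles = current_terms()
    bi = np.array([[b[0], b[1]] for b in bonds]) if bonds else np.zeros((0, 2), int)
    bl = np.array([b[2] for b in bonds])
    # surrogate weights chosen so per-atom geometry and density forces are
    # comparable near the optimum (official score uses rms/mean terms)
    KB, KA, KC = 30.0, 20.0, 2.0
    n_bonds = max(len(bonds), 1)
    n_angles = max(len(angles), 1)
    best = work.copy()
    best_ssr = np.inf
    start_score = combined_score(work, std, w)
    x_cur = np.array([a.xyz for a in atoms]).ravel()

    for _ in range(max_iter):
        x0 = x_cur.copy()
        ssr, rvals, rgrads = residual_field(work)
        if ssr < best_ssr - 1e-9 * max(best_ssr, 1.0):
            best = work.copy()
            best_ssr = ssr
        elif np.isfinite(best_ssr):
            break          # residual no longer shrinking
        # soft-clash candidate pairs, fixed for this round
        pts = x0.reshape(-1, 3)
        tree = cKDTree(pts)
        resid = []
        for ci, (cid, residues) in enumerate(work.chains.items()):
            for res in residues:
                resid.extend([(ci, res.seqnum)] * len(res.atoms))
        cpairs = [(i, j) for i, j in tree.query_pairs(3.0)
                  if not (resid[i][0] == resid[j][0]
                          and abs(resid[i][1] - resid[j][1]) <= 1)]
        cpairs = np.array(cpairs, int) if cpairs else np.zeros((0, 2), int)

        def objective(x):
            p = x.reshape(-1, 3)
            g = np.zeros_like(p)
            frac = p @ frac_mat.T
            vals = interp([rvals], frac)[0]
            gfrac = np.stack(interp(rgrads, frac), axis=1)
            # moving into positive residual (density not yet explained by
            # the model) lowers the objective
            E = -w.w_dens * (occ * vals).sum() / n_atoms
            g -= w.w_dens * (occ[:, None] * (gfrac @ frac_mat)) / n_atoms
            if len(bi):
                kb = w.w_geom * KB / n_bonds
                dvec = p[bi[:, 0]] - p[bi[:, 1]]
                d = np.linalg.norm(dvec, axis=1)
                dev = d - bl
                E += kb * (dev ** 2).sum()
                gb = kb * 2 * (dev / d)[:, None] * dvec
                np.add.at(g, bi[:, 0], gb)
                np.add.at(g, bi[:, 1], -gb)
            ka = w.w_geom * KA / n_angles
            for ia, ib, ic, t0 in angles:
                u = p[ia] - p[ib]
                v = p[ic] - p[ib]
                nu, nv = np.linalg.norm(u), np.linalg.norm(v)
                ct = np.clip((u @ v) / (nu * nv), -1 + 1e-9, 1 - 1e-9)
                th = np.arccos(ct)
                st = np.sqrt(1 - ct * ct)
                dth_da = (ct * u / nu - v / nv) / (nu * st)
                dth_dc = (ct * v / nv - u / nu) / (nv * st)
                dev = th - t0
                E += ka * dev ** 2
                g[ia] += ka * 2 * dev * dth_da
                g[ic] += ka * 2 * dev * dth_dc
                g[ib] -= ka * 2 * dev * (dth_da + dth_dc)
            if len(cpairs):
                kc = w.w_geom * KC
                dvec = p[cpairs[:, 0]] - p[cpairs[:, 1]]
                d = np.linalg.norm(dvec, axis=1)
                viol = np.maximum(0.0, 2.6 - d)
                E += kc * (viol ** 2).sum()
                gc = -kc * 2 * (viol / d)[:, None] * dvec
                np.add.at(g, cpairs[:, 0], gc)
                np.add.at(g, cpairs[:, 1], -gc)
            return E, g.ravel()

        bounds = [(xi - 0.5, xi + 0.5) for xi in x0]
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 25})
        x_new = res.x
        for a, xyz in zip(atoms, x_new.reshape(-1, 3)):
            a.xyz = xyz.copy()
        x_cur = x_new
        if np.abs(x_new - x0).max() < 1e-3:
            ssr, _, _ = residual_field(work)
            if ssr < best_ssr:
                best = work.copy()
            break
    final_ssr, _, _ = residual_field(work)
    if final_ssr < best_ssr:
        best = work.copy()
    # ascent guarantee: never return a model that scores below the input
    # under the reported combined score
    if combined_score(best, std, w) < start_score:
        return model.copy()
    return best


# ---------------------------------------------------------------------------
# Autobuild iteration and model selection


@dataclass
class AutobuildResult:
    model: Model
    map: DensityMap
    report: RFactorReport
    history: list = field(default_factory=list)


def _solvent_fraction_estimate(model: Model, refl: ReflectionSet,
                               sym: SymmetryOps) -> float:
    vm = refl.cell.volume / (len(sym) * max(model_mass(model), 1.0))
    return float(np.clip(1.0 - 1.23 / vm, 0.2, 0.8))


def autobuild_iterate(model: Model, refl: ReflectionSet, sym: SymmetryOps,
                      lib: FragmentLibrary, params: RebuildParams,
                      w: ScoreWeights, r_tol: float = 0.005,
                      max_cycles: int = 5,
                      dm_cycles: int = 3) -> AutobuildResult:
    """Iterate {map -> density modify -> rebuild worst residues -> refine ->
    prune} until R_work stops changing; keep the lowest-R_work model/map."""
    if refl.free_flag is None:
        raise ValueError("autobuild needs free flags")
    current = model.copy()
    history = []
    snapshots = []
    rising = 0
    for cycle in range(max_cycles):
        refl_fc = set_f_calc(refl, current, sym)
        report = scale_and_r(refl_fc)
        map2 = compute_map(refl_fc, "two_fo_fc")
        ops = find_ncs_operators(current)
        solv = _solvent_fraction_estimate(current, refl, sym)
        first_chain = next(iter(current.chains))
        center = Model({first_chain: [r.copy()
                                      for r in current.chains[first_chain]]})
        dm = density_modify(map2, refl_fc, current, solv, n_cycles=dm_cycles,
                            ops=[o for o in ops
                                 if o.source_chain == first_chain] or None,
                            mask_center=center)
        history.append({"cycle": cycle, "r_work": report.r_work,
                        "r_free": report.r_free})
        snapshots.append((report, current.copy(), dm))
        if len(history) >= 2:
            prev_r = history[-2]["r_work"]
            if abs(report.r_work - prev_r) < r_tol:
                break
            rising = rising + 1 if report.r_work > prev_r else 0
            if rising >= 3:
                warnings.warn("R_work rising for 3 cycles; stopping")
                break
        if cycle == max_cycles - 1:
            break
        # rebuild the worst-fitting 20% of residues against the modified map
        fit = real_space_fit(current, dm)
        vals = np.array(list(fit.residue_scores.values()))
        thr = np.quantile(vals, 0.2)
        restrict = {}
        for (cid, num), v in fit.residue_scores.items():
            if v <= thr:
                restrict.setdefault(cid, set()).add(num)
        try:
            cands = rebuild_model(current, dm, lib, params, w,
                                  windows_restrict=restrict)
            std = dm.standardized()
            current = max(cands, key=lambda m: combined_score(m, std, w))
        except ValueError:
            pass
        current = refine_real_space(current, dm, w)
        # prune residues far below the typical density fit
        fit = real_space_fit(current, dm)
        vals = np.array(list(fit.residue_scores.values()))
        cut = vals.mean() - 2.0 * vals.std()
        pruned = current.copy()
        for cid in list(pruned.chains):
            keep = [r for r in pruned.chains[cid]
                    if fit.residue_scores[(cid, r.seqnum)] >= cut]
            if len(keep) >= 3:
                pruned.chains[cid] = keep
        current = pruned
    best_i = int(np.argmin([s[0].r_work for s in snapshots]))
    report, bmodel, bmap = snapshots[best_i]
    return AutobuildResult(bmodel, bmap, report, history)


def select_top_models(models: list, refl: ReflectionSet, sym: SymmetryOps,
                      n: int = 2) -> list:
    """Top-n models by the common rescoring criterion (stable order)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(models):
        warnings.warn(f"asked for {n} models, only {len(models)} available")
        n = len(models)
    scores = []
    for m in models:
        F = sf_direct(m, refl.cell, sym, refl.hkl)
        scores.append(float(np.corrcoef(refl.f_obs ** 2, np.abs(F) ** 2)[0, 1]))
    order = sorted(range(len(models)), key=lambda i: -scores[i])
    return [models[i] for i in order[:n]]


def discard_unassigned(model: Model, target_seq: str = "") -> Model:
    """Drop chains whose residues are all UNK (not assignable to sequence)."""
    out = model.copy()
    for cid in list(out.chains):
        if all(r.resname == "UNK" for r in out.chains[cid]):
            del out.chains[cid]
    return out
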