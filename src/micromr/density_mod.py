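"""Density modification: solvent flattening with phase recombination, NCS
operator detection, NCS map averaging and multi-map averaging.

The scheme is classical phase-improvement: amplitudes are always reset to the
observed values, only phases move, through a fixed-weight recombination of
the modified map's transform with the starting transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model_core import Model, kabsch
from .xray_core import DensityMap, ReflectionSet, map_coefficients, synthesize_map

NCS_MAX_RMSD = 2.0
NCS_MIN_IDENTITY = 0.9
SOLVENT_ATOM_RADIUS = 4.0   # grid points farther than this from any atom start as solvent
NCS_REGION_RADIUS = 5.0


@dataclass
class NcsOperator:
    rotation: np.ndarray
    translation: np.ndarray
    source_chain: str = ""
    target_chain: str = ""
    rmsd: float = 0.0

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.atleast_2d(xyz) @ self.rotation.T + self.translation

    def inverse_apply(self, xyz: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(xyz) - self.translation) @ self.rotation

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "source_chain": self.source_chain,
                "target_chain": self.target_chain, "rmsd": self.rmsd}

    @classmethod
    def from_dict(cls, d: dict) -> "NcsOperator":
        return cls(np.array(d["rotation"]), np.array(d["translation"]),
                   d.get("source_chain", ""), d.get("target_chain", ""),
                   d.get("rmsd", 0.0))


def find_ncs_operators(model: Model) -> list:
    """CA-superposition operators for every ordered pair of matching chains.

    Chains match if their sequences agree at >= 90% of shared residue
    numbers; operators with defining rmsd > 2 Å are discarded.
    """
    chains = {}
    for cid, residues in model.chains.items():
        chains[cid] = {r.seqnum: r for r in residues if r.atom("CA") is not None}
    ops = []
    ids = list(chains)
    for src in ids:
        for dst in ids:
            if src == dst:
                continue
            shared = sorted(set(chains[src]) & set(chains[dst]))
            if len(shared) < 3:
                continue
            same = sum(chains[src][n].resname == chains[dst][n].resname
                       for n in shared)
            if same / len(shared) < NCS_MIN_IDENTITY:
                continue
            a = np.array([chains[src][n].atom("CA").xyz for n in shared])
            b = np.array([chains[dst][n].atom("CA").xyz for n in shared])
            try:
                R, t = kabsch(a, b)
            except ValueError:
                continue
            rmsd = float(np.sqrt(((a @ R.T + t - b) ** 2).sum(axis=1).mean()))
            if rmsd <= NCS_MAX_RMSD:
                ops.append(NcsOperator(R, t, src, dst, rmsd))
    return ops


def _region_mask(dmap: DensityMap, atoms_xyz: np.ndarray, radius: float) -> np.ndarray:
    """Boolean grid mask of points within `radius` Å of any atom (periodic)."""
    shape = dmap.grid.shape
    n = np.array(shape)
    idx = np.indices(shape).reshape(3, -1).T
    pts_cart = dmap.cell.orthogonalize(idx / n)
    frac = dmap.cell.fractionalize(np.atleast_2d(atoms_xyz)) % 1.0
    shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                  indexing="ij")).reshape(3, -1).T
    images = (frac[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tree = cKDTree(dmap.cell.orthogonalize(images))
    d, _ = tree.query(pts_cart, k=1)
    return (d <= radius).reshape(shape)


def ncs_average(dmap: DensityMap, ops: list, mask_center: Model,
                radius: float = NCS_REGION_RADIUS) -> DensityMap:
    """Average density over NCS copies within the mask_center copy's region.

    ``ops`` must map the mask_center copy onto the other copies.  The region
    is the union of `radius`-Å spheres around the mask_center atoms; the
    averaged values are written back to every copy's region.  Points mapped
    outside the cell wrap periodically.
    """
    if not ops:
        raise ValueError("ncs_average needs at least one operator")
    # identity operators contribute nothing to the average: drop them, and
    # with none left the map is unchanged exactly
    ops = [op for op in ops
           if not (np.allclose(op.rotation, np.eye(3), atol=1e-9)
                   and np.allclose(op.translation, 0.0, atol=1e-9))]
    if not ops:
        return dmap.copy()
    atoms = mask_center.coords()
    ref_mask = _region_mask(dmap, atoms, radius)
    n = np.array(dmap.grid.shape)
    ref_idx = np.argwhere(ref_mask)
    P = dmap.cell.orthogonalize(ref_idx / n)
    vals = dmap.interpolate_cart(P, order=3).astype(float)
    for op in ops:
        vals += dmap.interpolate_cart(op.apply(P), order=3)
    vals /= (1 + len(ops))
    averaged_ref = dmap.copy()
    averaged_ref.grid[tuple(ref_idx.T)] = vals
    out = averaged_ref.copy()
    for op in ops:
        copy_mask = _region_mask(dmap, op.apply(atoms), radius)
        cidx = np.argwhere(copy_mask)
        Q = dmap.cell.orthogonalize(cidx / n)
        out.grid[tuple(cidx.T)] = averaged_ref.interpolate_cart(
            op.inverse_apply(Q), order=3)
    return out


def solvent_mask(dmap: DensityMap, model: Model,
                 solvent_fraction: float) -> np.ndarray:
    """Solvent region: far-from-model points, trimmed/grown by density ranking
    so that exactly round(solvent_fraction * N) points are solvent."""
    base = ~_region_mask(dmap, model.coords(), SOLVENT_ATOM_RADIUS)
    target = round(solvent_fraction * dmap.grid.size)
    flat = dmap.grid.ravel()
    mask = base.ravel().copy()
    n_now = int(mask.sum())
    if n_now > target:
        # too much solvent: return the highest-density solvent points to protein
        idx = np.flatnonzero(mask)
        drop = idx[np.argsort(flat[idx])[::-1][: n_now - target]]
        mask[drop] = False
    elif n_now < target:
        # grow: lowest-density protein-region points become solvent
        idx = np.flatnonzero(~mask)
        add = idx[np.argsort(flat[idx])[: target - n_now]]
        mask[add] = True
    return mask.reshape(dmap.grid.shape)


def density_modify(start_map: DensityMap, refl: ReflectionSet, model: Model,
                   solvent_fraction: float, n_cycles: int = 5,
                   ops: list | None = None, mask_center: Model | None = None,
                   recomb_weight: float = 0.5) -> DensityMap:
    """Solvent flattening + optional NCS averaging with phase recombination.

    Per cycle: flatten the solvent region to its mean, NCS-average if
    operators are given, then rebuild the map from coefficients whose phases
    are those of w*F_mod + (1-w)*F_start and whose amplitudes are the
    observed ones.  Work and free reflections are treated identically
    (phase-only modification).
    """
    if not 0.2 <= solvent_fraction <= 0.8:
        raise ValueError("solvent fraction outside [0.2, 0.8]")
    if n_cycles == 0:
        return start_map.copy()
    F_start = map_coefficients(start_map, refl.hkl)
    current = start_map.copy()
    prev_masks = []
    for _ in range(n_cycles):
        mask = solvent_mask(current, model, solvent_fraction)
        if len(prev_masks) >= 2 and np.array_equal(mask, prev_masks[-2]) \
                and not np.array_equal(mask, prev_masks[-1]):
            warnings.warn("solvent mask oscillating; stopping early")
            break
        prev_masks = (prev_masks + [mask])[-2:]
        mod = current.copy()
        mod.grid[mask] = mod.grid[mask].mean()
        if ops:
            center = mask_center if mask_center is not None else model
            mod = ncs_average(mod, ops, center)
        F_mod = map_coefficients(mod, refl.hkl)
        F_comb = recomb_weight * F_mod + (1 - recomb_weight) * F_start
        coeffs = refl.f_obs * np.exp(1j * np.angle(F_comb))
        current = synthesize_map(refl.hkl, coeffs, refl.cell,
                                 shape=start_map.grid.shape)
    return current


def average_maps(maps: list) -> DensityMap:
    """Pointwise mean of standardized maps (all on identical grids)."""
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].grid.shape
    for m in maps[1:]:
        if m.grid.shape != shape:
            raise ValueError("map grids differ")
    grids = [m.standardized().grid for m in maps]
    return DensityMap(np.mean(grids, axis=0), maps[0].cell)
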