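"""Molecular replacement: rotation-grid + translation search against observed
amplitudes, sequential multi-copy placement with fixed-model support, and
common-criterion rescoring.

The translation-function target is the classic correlation score: Pearson
correlation between F_obs^2 and |F_calc|^2 of the (fixed + shifted search)
model.  Orientations are sampled on a uniform zyz Euler grid with the polar
redundancy deduplicated.  In polar directions (e.g. every direction in P1,
the screw axis in P21) amplitudes are invariant under origin shifts, so
translation components along them are resolved by the documented
lexicographic tie-break: among placements whose scores agree to 1e-9, the
smallest fractional offset wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_core import Model, SymmetryOps, UnitCell
from .xray_core import ReflectionSet, _atom_amplitudes, _atom_arrays, scale_and_r, \
    sf_direct

MAX_TRANSLATION_POINTS = 64 ** 3
SCORE_TIE_TOL = 1e-9


@dataclass
class Placement:
    rotation: tuple          # zyz Euler angles, degrees
    translation: np.ndarray  # fractional triplet in [0, 1)
    score: float
    n_copy_index: int = 0

    def __post_init__(self):
        self.translation = np.asarray(self.translation, float) % 1.0


@dataclass
class MrSolution:
    placements: list
    combined_model: Model
    score: float
    r_after_placement: float
    hypothesis: object = None
    search_model_label: str = ""
    partial: bool = False


def euler_zyz_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix R = Rz(alpha) @ Ry(beta) @ Rz(gamma), angles in degrees."""
    a, b, g = np.radians([alpha, beta, gamma])

    def rz(t):
        return np.array([[np.cos(t), -np.sin(t), 0],
                         [np.sin(t), np.cos(t), 0], [0, 0, 1]])

    def ry(t):
        return np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0],
                         [-np.sin(t), 0, np.cos(t)]])

    return rz(a) @ ry(b) @ rz(g)


def euler_grid(step_deg: float) -> list:
    """Uniform zyz Euler grid; beta in [0, 180], polar redundancy removed."""
    alphas = np.arange(0.0, 360.0, step_deg)
    betas = np.arange(0.0, 180.0 + 1e-9, step_deg)
    gammas = np.arange(0.0, 360.0, step_deg)
    grid = []
    for b in betas:
        if b in (0.0, 180.0):
            grid.extend((a, b, 0.0) for a in alphas)
        else:
            grid.extend((a, b, g) for a in alphas for g in gammas)
    return grid


def rotation_angle_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Angle of the relative rotation between two rotation matrices."""
    c = (np.trace(R1 @ R2.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def translation_grid(grid_step: float) -> np.ndarray:
    n = round(1.0 / grid_step)
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1 evenly")
    if n ** 3 > MAX_TRANSLATION_POINTS:
        raise ValueError(f"translation grid {n}^3 exceeds the desk budget "
                         f"({MAX_TRANSLATION_POINTS} points); override by "
                         "calling the scorer directly")
    ax = np.arange(n) / n
    I, J, K = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([I.ravel(), J.ravel(), K.ravel()], axis=1)


def _partial_sfs(model: Model, cell: UnitCell, sym: SymmetryOps, refl):
    """Per-symmetry-op partial structure factors of a model at t = 0.

    F(h; t) = sum_s Fs(h) * exp(2 pi i (h^T R_s) . t), so each op's partial
    Fs and its rotated index set (h^T R_s) are enough to score any shift.
    """
    hkl = refl.hkl
    stol2 = refl.stol2
    xyz, occ, b, elems = _atom_arrays(model)
    xf = cell.fractionalize(xyz)
    famp = _atom_amplitudes(elems, occ, b, stol2)
    Fs, h_rots = [], []
    for R, t in sym.ops:
        h_rot = hkl @ R
        phase = np.exp(2j * np.pi * (xf @ h_rot.T))
        Fs.append(np.exp(2j * np.pi * (hkl @ t)) * (famp * phase).sum(axis=0))
        h_rots.append(h_rot)
    return Fs, h_rots


def _pearson_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector x with every column of Y."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    num = xc @ Yc
    den = np.linalg.norm(xc) * np.linalg.norm(Yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, -1.0)


def _score_shifts(Fs, phase_t, F_fixed, target):
    """Scores for every translation grid point given per-op partial SFs."""
    F_tot = F_fixed[:, None] + sum(F[:, None] * pt for F, pt in zip(Fs, phase_t))
    return _pearson_columns(target, np.abs(F_tot) ** 2)


def _rank_placements(scores: np.ndarray, tgrid: np.ndarray):
    """Descending score, ties (to 1e-9) broken by lexicographic offset."""
    q = np.round(scores / SCORE_TIE_TOL).astype(np.int64)
    order = np.lexsort((tgrid[:, 2], tgrid[:, 1], tgrid[:, 0], -q))
    return order


def translation_search(oriented: Model, refl: ReflectionSet, cell: UnitCell,
                       sym: SymmetryOps, grid_step: float = 1 / 8,
                       fixed: Model | None = None, n_top: int = 10) -> list:
    """Grid translation search for an already-oriented model."""
    tgrid = translation_grid(grid_step)
    Fs, h_rots = _partial_sfs(oriented, cell, sym, refl)
    phase_t = [np.exp(2j * np.pi * (hr @ tgrid.T)) for hr in h_rots]
    F_fixed = (sf_direct(fixed, cell, sym, refl.hkl) if fixed is not None
               else np.zeros(len(refl), complex))
    scores = _score_shifts(Fs, phase_t, F_fixed, refl.f_obs ** 2)
    order = _rank_placements(scores, tgrid)[:n_top]
    return [Placement(rotation=(0.0, 0.0, 0.0), translation=tgrid[i],
                      score=float(scores[i])) for i in order]


def run_mr(search_models: list, refl: ReflectionSet, cell: UnitCell,
           sym: SymmetryOps, hypotheses: list, rot_step: float = 15.0,
           fixed: Model | None = None, grid_step: float = 1 / 8,
           score_floor: float = 0.0) -> list:
    """Full MR: Euler grid x translation grid, sequential copy placement.

    Each placed copy joins the fixed set before the next copy is searched.
    Returns one MrSolution per (search model, hypothesis) combination that
    clears the score floor, ranked by score.
    """
    if not search_models or not hypotheses:
        raise ValueError("need at least one search model and one hypothesis")
    tgrid = translation_grid(grid_step)
    target = refl.f_obs ** 2
    orientations = euler_grid(rot_step)
    # translation phase factors depend only on the symmetry ops and the grid
    h_rots_fixed = [refl.hkl @ R for R, _ in sym.ops]
    phase_t = [np.exp(2j * np.pi * (hr @ tgrid.T)) for hr in h_rots_fixed]
    solutions = []
    for smodel in search_models:
        centered = smodel.transformed(np.eye(3), -smodel.centroid())
        for hyp in hypotheses:
            combined = fixed.copy() if fixed is not None else None
            placements = []
            partial = False
            for copy_idx in range(hyp.n_copies):
                F_fixed = (sf_direct(combined, cell, sym, refl.hkl)
                           if combined is not None
                           else np.zeros(len(refl), complex))
                # with one symmetry op and nothing fixed, amplitudes are
                # invariant under translation: score once, tie-break to 0
                degenerate = len(sym) == 1 and combined is None
                best = None
                for euler in orientations:
                    R = euler_zyz_matrix(*euler)
                    oriented = centered.transformed(R, np.zeros(3))
                    Fs, _ = _partial_sfs(oriented, cell, sym, refl)
                    if degenerate:
                        sc = float(np.corrcoef(target,
                                               np.abs(Fs[0]) ** 2)[0, 1])
                        cand = (sc, euler, tgrid[0])
                    else:
                        scores = _score_shifts(Fs, phase_t, F_fixed, target)
                        i = _rank_placements(scores, tgrid)[0]
                        cand = (float(scores[i]), euler, tgrid[i])
                    if best is None or cand[0] > best[0] + SCORE_TIE_TOL:
                        best = cand
                score, euler, tvec = best
                if score < score_floor:
                    partial = True
                    warnings.warn(
                        f"copy {copy_idx + 1}: best score {score:.3f} below "
                        f"floor {score_floor}; stopping placement")
                    break
                R = euler_zyz_matrix(*euler)
                placed = centered.transformed(R, cell.orthogonalize(tvec))
                combined = placed if combined is None else combined.merged(placed)
                placements.append(Placement(euler, tvec, score, copy_idx))
            if not placements:
                continue
            refl_fc = refl.copy()
            refl_fc.f_calc = sf_direct(combined, cell, sym, refl.hkl)
            r_work = scale_and_r(refl_fc).r_work if refl.free_flag is not None \
                else float("nan")
            solutions.append(MrSolution(
                placements, combined, placements[-1].score, r_work,
                hypothesis=hyp, search_model_label=smodel.label,
                partial=partial))
    solutions.sort(key=lambda s: -s.score)
    if not solutions:
        warnings.warn("no MR solution above the score floor")
    return solutions


def rescore_solutions(solutions: list, refl: ReflectionSet, cell: UnitCell,
                      sym: SymmetryOps, b_inflate: float = 20.0) -> list:
    """Re-rank solutions under one common criterion.

    All combined models get the same B-factor inflation (the stand-in for a
    fixed assumed template rmsd: larger assumed rmsd <-> larger inflation)
    and are scored by the same squared-amplitude correlation used as the
    translation-function target, so with b_inflate = 0 the rescored value of
    a single-model solution reproduces its search score.  Pearson
    correlation is invariant to an overall scale, so no k fit is needed.
    """
    if not solutions:
        return []
    rescored = []
    for sol in solutions:
        infl = sol.combined_model.copy()
        for _, _, a in infl.iter_atoms():
            a.b += b_inflate
        F = sf_direct(infl, cell, sym, refl.hkl)
        score = float(np.corrcoef(refl.f_obs ** 2, np.abs(F) ** 2)[0, 1])
        rescored.append((score, sol))
    rescored.sort(key=lambda pair: -pair[0])
    out = []
    for score, sol in rescored:
        sol.score = score
        out.append(sol)
    return out
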