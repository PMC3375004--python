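"""Synthetic toy crystals: ideal-geometry targets, perturbed templates,
homolog sequences/alignments and simulated amplitudes.

Everything is generated from a seed, so every pipeline stage is testable
offline with a known ground truth.  The template-divergence and
sequence-identity regimes mirror challenging real molecular-replacement
cases (main-chain rmsd around 1-2 Å, identities down to ~20-30%), at toy
size.  Perturbations are smooth (low-frequency torsion modulation), not
i.i.d. atomic noise, so rigid placement of a perturbed template remains
meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import peptide
from .model_core import AA1TO3, AA3TO1, MAIN_CHAIN_ATOMS, Model, SymmetryOps, \
    UnitCell, kabsch, superpose
from .template_prep import Alignment, parse_alignment
from .xray_core import ReflectionSet, assign_free_flags, sf_fft

HELIX = (-57.0, -47.0)
TURN_POOL = [(-80.0, 0.0), (-90.0, 10.0), (-60.0, -30.0), (70.0, 30.0)]
_SEQ_ALPHABET = "ACDEFGHIKLMNQRSTVWY"   # proline excluded from random sequences
PROTEIN_VOLUME_PER_DA = 1.0 / 1.23      # Å^3 per Da at zero solvent


@dataclass
class FixtureSpec:
    n_res: int = 30
    fold: str = "helix-turn-helix"
    spacegroup: str = "P1"
    n_copies: int = 1
    d_min: float = 2.5
    noise_frac: float = 0.05
    perturb_rmsd: float = 1.5
    identity: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.d_min < 1.5:
            raise ValueError("d_min below 1.5 Å is outside the toy regime")
        if self.perturb_rmsd < 0:
            raise ValueError("perturb_rmsd must be >= 0")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")


def _random_sequence(n: int, rng) -> str:
    return "".join(_SEQ_ALPHABET[i]
                   for i in rng.integers(len(_SEQ_ALPHABET), size=n))


def _fold_torsions(spec: FixtureSpec, rng):
    """Backbone torsions for the requested fold.

    For helix-turn-helix, several seeded turn variants are tried and the most
    compact clash-free one kept, so the two helices actually pack back on
    each other rather than extending."""
    n = spec.n_res
    omegas = np.full(n, 180.0)
    if spec.fold == "helix":
        return np.full(n, HELIX[0]), np.full(n, HELIX[1]), omegas
    if spec.fold != "helix-turn-helix":
        raise ValueError(f"unknown fold {spec.fold!r}")
    t0 = n // 2 - 2
    best = None
    for _ in range(300):
        phis = np.full(n, HELIX[0])
        psis = np.full(n, HELIX[1])
        for k in range(4):
            if rng.random() < 0.5:
                phi, psi = TURN_POOL[rng.integers(len(TURN_POOL))]
                phi += rng.normal(0, 15)
                psi += rng.normal(0, 15)
            elif rng.random() < 0.8:
                phi = rng.uniform(-150, -45)
                psi = rng.uniform(-70, 180)
            else:
                phi = rng.uniform(40, 90)
                psi = rng.uniform(-40, 80)
            phis[t0 + k] = phi
            psis[t0 + k] = psi
        triples = peptide.build_backbone(phis, psis, omegas)
        ca = triples[:, 1, :]
        vol = float(np.prod(ca.max(axis=0) - ca.min(axis=0)))
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        if d[sep > 3].min() < 4.2:
            continue
        if best is None or vol < best[0]:
            best = (vol, phis, psis)
    if best is None:
        raise RuntimeError("no clash-free compact turn found")
    return best[1], best[2], omegas


def _min_periodic_distance(a: np.ndarray, b: np.ndarray, cell: UnitCell) -> float:
    fa = cell.fractionalize(a)
    fb = cell.fractionalize(b)
    d = fa[:, None, :] - fb[None, :, :]
    d -= np.round(d)
    cart = d.reshape(-1, 3) @ cell.orth_matrix.T
    return float(np.sqrt((cart ** 2).sum(axis=1).min()))


def make_target(spec: FixtureSpec, centroid_frac=(0.25, 0.25, 0.25)):
    """Build an ideal toy target placed in a cell sized for ~50% solvent.

    Returns (Model, UnitCell, SymmetryOps); ground-truth bookkeeping (pose,
    NCS generators, sequence) is stored in ``model.meta['truth']``.
    """
    last_err = None
    for attempt in range(10):
        try:
            return _make_target_once(spec, centroid_frac, spec.seed + 101 * attempt)
        except RuntimeError as err:
            last_err = err
    raise RuntimeError(f"could not pack fixture: {last_err}")


def _make_target_once(spec: FixtureSpec, centroid_frac, seed):
    rng = np.random.default_rng(seed)
    seq1 = _random_sequence(spec.n_res, rng)
    seq3 = [AA1TO3[c] for c in seq1]
    phis, psis, omegas = _fold_torsions(spec, rng)
    chain = peptide.build_chain_model(phis, psis, omegas, seq3, "A")
    base = chain.coords()
    base = base - base.mean(axis=0)
    sym = SymmetryOps.from_name(spec.spacegroup)

    from .model_core import model_mass
    mass = model_mass(chain)
    v_target = 2.0 * mass * PROTEIN_VOLUME_PER_DA * spec.n_copies * len(sym)
    span = base.max(axis=0) - base.min(axis=0)
    edges = (span + 3.0) * (spec.n_copies * len(sym)) ** (1 / 3)
    factor = max(1.0, (v_target / np.prod(edges)) ** (1 / 3))
    cell = UnitCell(*(edges * factor))

    model = Model({"A": [r.copy() for r in chain.chains["A"]]})
    model.set_coords(base + cell.orthogonalize(np.asarray(centroid_frac)))
    ncs_ops = []
    alphabet = "BCDEFGH"
    for i in range(spec.n_copies - 1):
        for _ in range(25):
            # random rotation via QR of a Gaussian matrix
            q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            shift_frac = rng.uniform(0.3, 0.7, size=3)
            coords = (base @ q.T) + cell.orthogonalize(
                (np.asarray(centroid_frac) + shift_frac) % 1.0)
            ok = all(_min_periodic_distance(coords, other.coords(), cell) > 3.0
                     for other in [model])
            if ok:
                break
        else:
            raise RuntimeError("cannot place NCS copy without clashes")
        cid = alphabet[i]
        copy_model = Model({cid: [r.copy() for r in chain.chains["A"]]})
        copy_model.set_coords(coords)
        model.chains[cid] = copy_model.chains[cid]
        ref_coords = np.array([a.xyz for r in model.chains["A"] for a in r.atoms])
        R_ab, t_ab = kabsch(ref_coords, coords)
        ncs_ops.append({"rotation": R_ab.tolist(), "translation": t_ab.tolist(),
                        "source_chain": "A", "target_chain": cid})
    # check packing against crystallographic mates
    coords_all = model.coords()
    for R, t in sym.ops[1:]:
        fa = model_coords_sym(coords_all, cell, R, t)
        if _min_periodic_distance(coords_all, fa, cell) < 2.4:
            raise RuntimeError("clash with symmetry mate")
    if spec.n_copies == 1 and _self_periodic_clash(coords_all, cell):
        raise RuntimeError("clash with periodic image")
    model.meta["truth"] = {
        "centroid_frac": list(centroid_frac),
        "sequence": seq1,
        "ncs_ops": ncs_ops,
        "spec": asdict(spec),
    }
    return model, cell, sym


def model_coords_sym(coords, cell, R, t):
    return (cell.fractionalize(coords) @ R.T + t) @ cell.orth_matrix.T


def _self_periodic_clash(coords: np.ndarray, cell: UnitCell,
                         cutoff: float = 2.4) -> bool:
    f = cell.fractionalize(coords)
    for shift in ((1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1),
                  (0, 1, 1), (1, 1, 1), (1, -1, 0), (1, 0, -1), (0, 1, -1)):
        d = f[:, None, :] - (f + np.asarray(shift))[None, :, :]
        cart = d.reshape(-1, 3) @ cell.orth_matrix.T
        if np.sqrt((cart ** 2).sum(axis=1).min()) < cutoff:
            return True
    return False


def simulate_fobs(model: Model, cell: UnitCell, sym: SymmetryOps,
                  d_min: float, noise_frac: float = 0.05,
                  seed: int = 0) -> ReflectionSet:
    """Simulated observed amplitudes: |F_calc| with relative Gaussian noise,
    sigma = noise_frac * f_obs, 5% free flags."""
    refl = sf_fft(model, cell, sym, d_min)
    rng = np.random.default_rng(seed)
    amp = np.abs(refl.f_calc)
    f_obs = np.clip(amp * (1.0 + rng.normal(0, noise_frac, len(amp))), 0, None)
    out = ReflectionSet(refl.hkl, cell, f_obs=f_obs,
                        sigma=noise_frac * f_obs)
    out = assign_free_flags(out, 0.05, seed)
    return out


def perturb_model(model: Model, perturb_rmsd: float, seed: int = 0,
                  tol: float = 0.10) -> Model:
    """Smoothly perturb a model to a target main-chain rmsd (±10%).

    Backbone torsions are modulated by a low-frequency field plus small
    jitter, the chain rebuilt with ideal geometry and superposed back onto
    the input, and the modulation amplitude rescaled until the achieved
    main-chain rmsd is within tolerance of the target.
    """
    if perturb_rmsd == 0:
        return model.copy()
    rng = np.random.default_rng(seed)
    out = model.copy()
    for cid, residues in model.chains.items():
        n = len(residues)
        phi, psi, omega = peptide.extract_torsions(residues)
        # fill undefined ends with canonical values for rebuilding
        phi[np.isnan(phi)] = HELIX[0]
        psi[np.isnan(psi)] = HELIX[1]
        omega[np.isnan(omega)] = 180.0
        i = np.arange(n)
        fields = []
        for _ in range(2):  # one field for phi, one for psi
            coeff = rng.normal(0, 1, 3)
            phase = rng.uniform(0, 2 * np.pi, 3)
            f = sum(c * np.sin(2 * np.pi * (k + 1) * i / n + p)
                    for k, (c, p) in enumerate(zip(coeff, phase)))
            fields.append(f + rng.normal(0, 0.3, n))
        amp = 2.0 * perturb_rmsd
        achieved = None
        for _ in range(20):
            triples = peptide.build_backbone(phi + amp * fields[0],
                                             psi + amp * fields[1], omega)
            names3 = [r.resname for r in residues]
            nums = [r.seqnum for r in residues]
            cand = Model({cid: peptide.chain_from_backbone(triples, names3, nums)})
            ref = Model({cid: [r.copy() for r in residues]})
            sup = superpose(cand, ref, selection=set(MAIN_CHAIN_ATOMS))
            achieved = sup.rmsd
            if abs(achieved - perturb_rmsd) <= tol * perturb_rmsd:
                cand = cand.transformed(sup.rotation, sup.translation)
                out.chains[cid] = cand.chains[cid]
                break
            amp *= np.clip(perturb_rmsd / max(achieved, 1e-6), 0.3, 3.0)
        else:
            raise RuntimeError(
                f"could not reach target rmsd {perturb_rmsd} "
                f"(achieved {achieved:.2f})")
    return out


def make_homolog(seq: str, identity: float, seed: int = 0):
    """Derive a homolog sequence at the requested identity plus 0-2 short
    deletions; returns (homolog_sequence, Alignment)."""
    rng = np.random.default_rng(seed)
    L = len(seq)
    deleted = set()
    if identity < 1.0 and L >= 12:
        for _ in range(int(rng.integers(0, 3))):
            dlen = int(rng.integers(1, 3))
            start = int(rng.integers(3, L - 3 - dlen))
            span = set(range(start, start + dlen))
            if not span & deleted:
                deleted |= span
    aligned = [i for i in range(L) if i not in deleted]
    n_sub = round((1.0 - identity) * len(aligned))
    sub_pos = set(rng.choice(aligned, size=n_sub, replace=False)) if n_sub else set()
    template_row = []
    for i in range(L):
        if i in deleted:
            template_row.append("-")
        elif i in sub_pos:
            others = [c for c in _SEQ_ALPHABET if c != seq[i]]
            template_row.append(others[rng.integers(len(others))])
        else:
            template_row.append(seq[i])
    text = f">target\n{seq}\n>template\n{''.join(template_row)}\n"
    aln = parse_alignment(text)
    return "".join(template_row).replace("-", ""), aln


def make_template_model(true_model: Model, aln: Alignment,
                        perturb_rmsd: float, seed: int = 0) -> Model:
    """Perturbed, homolog-renamed, renumbered template for one target chain."""
    cid = next(iter(true_model.chains))
    single = Model({cid: [r.copy() for r in true_model.chains[cid]]})
    perturbed = perturb_model(single, perturb_rmsd, seed) if perturb_rmsd > 0 \
        else single
    residues = perturbed.chains[cid]
    template_ungapped = aln.template_seq.replace("-", "")
    # template residue mp corresponds to target position tp; the template model
    # keeps only its own residues, numbered 1..m in file order
    kept = {mp: tp for tp, mp in aln.pairs}
    new_residues = []
    for mp in range(1, len(template_ungapped) + 1):
        tp = kept.get(mp)
        if tp is None:
            continue
        src = residues[tp - 1].copy()
        src.resname = AA1TO3.get(template_ungapped[mp - 1], "UNK")
        src.seqnum = mp
        new_residues.append(src)
    tmpl = Model({"A": new_residues}, label="synthetic_template")
    return tmpl


def make_standard_fixture(seed: int = 0, spec: FixtureSpec | None = None,
                          centroid_frac=(0.25, 0.25, 0.25)) -> dict:
    """The standard end-to-end fixture: target, cell, symmetry, amplitudes,
    perturbed homolog template and alignment, with ground truth attached."""
    if spec is None:
        spec = FixtureSpec(seed=seed)
    target, cell, sym = make_target(spec, centroid_frac)
    refl = simulate_fobs(target, cell, sym, spec.d_min, spec.noise_frac,
                         seed=spec.seed + 11)
    seq = target.meta["truth"]["sequence"]
    _, aln = make_homolog(seq, spec.identity, seed=spec.seed + 23)
    template = make_template_model(target, aln, spec.perturb_rmsd,
                                   seed=spec.seed + 37)
    return {"spec": spec, "target": target, "cell": cell, "sym": sym,
            "refl": refl, "alignment": aln, "template": template,
            "sequence": seq}


def write_fixture(fixture: dict, outdir) -> None:
    """Write target.pdb, template.pdb, alignment.fasta, refl.txt, truth.json."""
    import os
    from .model_core import write_model
    os.makedirs(outdir, exist_ok=True)
    cell = fixture["cell"]
    sg = fixture["sym"].name
    write_model(fixture["target"], os.path.join(outdir, "target.pdb"),
                cell=cell, spacegroup=sg)
    write_model(fixture["template"], os.path.join(outdir, "template.pdb"))
    aln = fixture["alignment"]
    with open(os.path.join(outdir, "alignment.fasta"), "w") as fh:
        fh.write(f">target\n{aln.target_aln}\n>template\n{aln.template_seq}\n")
    fixture["refl"].write_text(os.path.join(outdir, "refl.txt"))
    with open(os.path.join(outdir, "sequence.fasta"), "w") as fh:
        fh.write(f">target\n{fixture['sequence']}\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(fixture["target"].meta["truth"], fh, indent=1)
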