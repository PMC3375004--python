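"""Structure factors, amplitude scaling, R-factors, map synthesis and map/model fit.

Two independent structure-factor routes are provided: direct summation over
atoms (``sf_direct``, exact within float tolerance) and Gaussian density
sampling + FFT (``sf_fft``).  The FFT route is the production path; the direct
sum is its oracle.

Conventions
-----------
* F(h) = sum_sym sum_atoms f_elem(s) * occ * exp(-B s^2/4) * exp(2 pi i h.(Rx+t))
  with s = 1/d and four-Gaussian-plus-constant form factors (IT92 table).
* Map synthesis: rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x), both Friedel
  mates included; F(000) is never part of a ReflectionSet, so maps are
  mean-zero by construction.
* Grid spacing d_min/3 per axis (rounded up to an FFT-friendly size).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import gemmi
import numpy as np
import scipy.fft
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize_scalar

from .model_core import Model, SymmetryOps, UnitCell

SUPPORTED_ELEMENTS = ("C", "N", "O", "S")

# minimum effective Gaussian width (Å^2) used when sampling density for the
# FFT route; wider Gaussians alias less on the d_min/3 grid and the blur is
# removed exactly in reciprocal space afterwards
_BLUR_TARGET = 80.0
_DENSITY_TOL = 1e-8


def _it92(element: str):
    if element not in SUPPORTED_ELEMENTS:
        raise ValueError(f"no form factors packaged for element {element!r} "
                         f"(supported: {SUPPORTED_ELEMENTS})")
    t = gemmi.Element(element).it92
    return np.array(t.a), np.array(t.b), float(t.c)


def form_factor(element: str, stol2: np.ndarray) -> np.ndarray:
    """Scattering factor f(s) at stol2 = (sin theta / lambda)^2 = 1/(4 d^2)."""
    a, b, c = _it92(element)
    return (a[None, :] * np.exp(-np.outer(stol2, b))).sum(axis=1) + c


# ---------------------------------------------------------------------------
# Reflection container


@dataclass
class RFactorReport:
    r_work: float
    r_free: float
    scale: float
    b_overall: float


@dataclass
class ReflectionSet:
    hkl: np.ndarray            # (n, 3) int
    cell: UnitCell
    f_obs: np.ndarray | None = None
    sigma: np.ndarray | None = None
    free_flag: np.ndarray | None = None
    f_calc: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, int)
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != len(self.hkl):
            raise ValueError("duplicate Miller indices")
        if self.f_obs is not None:
            self.f_obs = np.asarray(self.f_obs, float)
            if (self.f_obs < 0).any():
                raise ValueError("negative observed amplitudes")

    def __len__(self):
        return len(self.hkl)

    @property
    def d_spacing(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def d_min(self) -> float:
        return float(self.d_spacing.min())

    @property
    def stol2(self) -> np.ndarray:
        return 0.25 / self.d_spacing ** 2

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            self.hkl.copy(), self.cell,
            None if self.f_obs is None else self.f_obs.copy(),
            None if self.sigma is None else self.sigma.copy(),
            None if self.free_flag is None else self.free_flag.copy(),
            None if self.f_calc is None else self.f_calc.copy())

    @classmethod
    def generate(cls, cell: UnitCell, d_min: float) -> "ReflectionSet":
        """All Friedel-unique reflections with d >= d_min (000 excluded)."""
        inv_d_max = 1.0 / d_min
        astar = np.linalg.norm(cell.frac_matrix, axis=1)
        hmax = np.floor(inv_d_max / astar).astype(int)
        h, k, l = np.meshgrid(*(np.arange(-m, m + 1) for m in hmax), indexing="ij")
        hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
        d = cell.d_spacing(hkl)
        keep = d >= d_min - 1e-9
        # one hemisphere: l > 0, or l == 0 and k > 0, or l == k == 0 and h > 0
        hh, kk, ll = hkl.T
        hemi = (ll > 0) | ((ll == 0) & (kk > 0)) | ((ll == 0) & (kk == 0) & (hh > 0))
        return cls(hkl[keep & hemi], cell)

    def write_text(self, path) -> None:
        if self.f_obs is None:
            raise ValueError("no observed amplitudes to write")
        sig = self.sigma if self.sigma is not None else np.zeros(len(self))
        free = self.free_flag if self.free_flag is not None else np.zeros(len(self), bool)
        with open(path, "w") as fh:
            fh.write("#  h   k   l        F      SIGF  FREE\n")
            for (h, k, l), f, s, fl in zip(self.hkl, self.f_obs, sig, free):
                fh.write(f"{h:4d}{k:4d}{l:4d} {f:12.4f} {s:9.4f} {int(fl):5d}\n")

    @classmethod
    def read_text(cls, path, cell: UnitCell) -> "ReflectionSet":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: expected 'h k l F [SIGF] [FREE]'")
                rows.append([float(x) for x in parts[:6]] + [0.0] * (6 - len(parts)))
        arr = np.array(rows)
        return cls(arr[:, :3].astype(int), cell, f_obs=arr[:, 3],
                   sigma=arr[:, 4], free_flag=arr[:, 5].astype(bool))

    @classmethod
    def read_mtz(cls, path, f_col="FP", sig_col="SIGFP", free_col="FreeR_flag"):
        mtz = gemmi.read_mtz_file(str(path))
        cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c,
                        mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
        cols = {c.label: np.array(c) for c in mtz.columns}
        hkl = np.stack([cols["H"], cols["K"], cols["L"]], axis=1).astype(int)
        free = cols[free_col].astype(int) == 0 if free_col in cols else None
        return cls(hkl, cell, f_obs=cols[f_col],
                   sigma=cols.get(sig_col), free_flag=free)


def assign_free_flags(refl: ReflectionSet, fraction: float = 0.05,
                      seed: int = 0) -> ReflectionSet:
    """Reproducible pseudo-random cross-validation (free) flags."""
    if not 0 < fraction < 0.5:
        raise ValueError("free fraction must be in (0, 0.5)")
    n = len(refl)
    if n < 10:
        raise ValueError("fewer than 10 reflections")
    rng = np.random.default_rng(seed)
    flags = np.zeros(n, bool)
    flags[rng.permutation(n)[:max(1, round(n * fraction))]] = True
    out = refl.copy()
    out.free_flag = flags
    return out


# ---------------------------------------------------------------------------
# Structure factors


def sf_direct(model: Model, cell: UnitCell, sym: SymmetryOps,
              hkl: np.ndarray) -> np.ndarray:
    """Direct-summation complex structure factors at the given Miller indices."""
    hkl = np.asarray(hkl, int)
    d = cell.d_spacing(hkl)
    stol2 = 0.25 / d ** 2
    xyz, occ, b, elems = _atom_arrays(model)
    xf = cell.fractionalize(xyz)
    F = np.zeros(len(hkl), complex)
    famp = _atom_amplitudes(elems, occ, b, stol2)        # (natom, nrefl)
    for R, t in sym.ops:
        h_rot = hkl @ R                                   # h^T R, (nrefl, 3)
        phase = np.exp(2j * np.pi * (xf @ h_rot.T))       # (natom, nrefl)
        phase_t = np.exp(2j * np.pi * (hkl @ t))          # (nrefl,)
        F += phase_t * (famp * phase).sum(axis=0)
    return F


def _atom_arrays(model: Model):
    xyz, occ, b, elems = [], [], [], []
    for _, _, a in model.iter_atoms():
        xyz.append(a.xyz)
        occ.append(a.occ)
        b.append(a.b)
        elems.append(a.element)
    return np.array(xyz), np.array(occ), np.array(b), elems


def _atom_amplitudes(elems, occ, b, stol2):
    """(natom, nrefl) array of occ * f_elem(s) * exp(-B stol2)."""
    uniq = sorted(set(elems))
    f_by_elem = {e: form_factor(e, stol2) for e in uniq}
    f = np.stack([f_by_elem[e] for e in elems])
    return occ[:, None] * f * np.exp(-np.outer(b, stol2))


def grid_shape_for(cell: UnitCell, d_min: float) -> tuple:
    edges = (cell.a, cell.b, cell.c)
    return tuple(scipy.fft.next_fast_len(int(np.ceil(3.0 * e / d_min)))
                 for e in edges)


def sample_density(model: Model, cell: UnitCell, sym: SymmetryOps,
                   shape: tuple, blur: float) -> np.ndarray:
    """Gaussian atom density on a periodic fractional grid (blurred by `blur` Å^2)."""
    shape = tuple(shape)
    n = np.array(shape)
    rho = np.zeros(shape)
    orth = cell.orth_matrix
    frac_rows = np.linalg.norm(cell.frac_matrix, axis=1)
    xyz, occ, bfac, elems = _atom_arrays(model)
    xf = cell.fractionalize(xyz)
    coeffs = {}
    for e in set(elems):
        a, b, c = _it92(e)
        coeffs[e] = (np.append(a, c), np.append(b, 0.0))
    for (R, t) in sym.ops:
        xf_sym = xf @ R.T + t
        for x0, o, B, e in zip(xf_sym, occ, bfac, elems):
            a_all, b_all = coeffs[e]
            b_eff = b_all + B + blur
            r_cut = np.sqrt(b_eff.max() * np.log(1.0 / _DENSITY_TOL)) / (2 * np.pi)
            m = np.ceil(r_cut * frac_rows * n).astype(int)
            i0 = np.round(x0 * n).astype(int)
            axes = [i0[k] + np.arange(-m[k], m[k] + 1) for k in range(3)]
            fr = [axes[k] / n[k] - x0[k] for k in range(3)]
            I, J, K = np.meshgrid(*fr, indexing="ij")
            dfrac = np.stack([I, J, K], axis=-1)
            dcart = dfrac @ orth.T
            r2 = (dcart ** 2).sum(axis=-1)
            dens = np.zeros_like(r2)
            for ai, bi in zip(a_all, b_eff):
                dens += ai * (4 * np.pi / bi) ** 1.5 * np.exp(-4 * np.pi ** 2 * r2 / bi)
            dens *= o
            idx = np.ravel_multi_index(
                np.meshgrid(*(axes[k] % n[k] for k in range(3)), indexing="ij"),
                shape)
            np.add.at(rho.ravel(), idx.ravel(), dens.ravel())
    return rho


def sf_fft(model: Model, cell: UnitCell, sym: SymmetryOps,
           d_min: float, shape: tuple | None = None) -> ReflectionSet:
    """FFT-route structure factors to d_min; returns a ReflectionSet with f_calc."""
    if shape is None:
        shape = grid_shape_for(cell, d_min)
    spacing = max(e / s for e, s in zip((cell.a, cell.b, cell.c), shape))
    if d_min <= 2 * spacing:
        raise ValueError(f"grid too coarse for d_min={d_min} (spacing {spacing:.2f})")
    _, _, bfac, _ = _atom_arrays(model)
    blur = max(0.0, _BLUR_TARGET - float(bfac.min()))
    rho = sample_density(model, cell, sym, shape, blur)
    Fgrid = cell.volume * scipy.fft.ifftn(rho)
    refl = ReflectionSet.generate(cell, d_min)
    h, k, l = refl.hkl.T
    F = Fgrid[h % shape[0], k % shape[1], l % shape[2]]
    F = F * np.exp(blur * refl.stol2)        # remove sampling blur exactly
    refl.f_calc = F
    return refl


def set_f_calc(refl: ReflectionSet, model: Model, sym: SymmetryOps,
               method: str = "fft") -> ReflectionSet:
    """Attach f_calc for `model` to a copy of `refl` (fft route by default)."""
    out = refl.copy()
    if method == "direct":
        out.f_calc = sf_direct(model, refl.cell, sym, refl.hkl)
    else:
        calc = sf_fft(model, refl.cell, sym, refl.d_min)
        index = {tuple(h): i for i, h in enumerate(calc.hkl)}
        out.f_calc = calc.f_calc[[index[tuple(h)] for h in refl.hkl]]
    return out


# ---------------------------------------------------------------------------
# Scaling and R factors


def _fit_scale(f_obs, f_abs, stol2, mask=None):
    """Fit k, B minimizing sum (f_obs - k exp(-B stol2) f_abs)^2 on `mask`."""
    if mask is None:
        mask = np.ones(len(f_obs), bool)
    fo, fa, s2 = f_obs[mask], f_abs[mask], stol2[mask]

    def k_for(B):
        m = np.exp(-B * s2) * fa
        denom = (m * m).sum()
        return (fo * m).sum() / denom if denom > 0 else 0.0

    def loss(B):
        k = k_for(B)
        return ((fo - k * np.exp(-B * s2) * fa) ** 2).sum()

    res = minimize_scalar(loss, bounds=(-100.0, 300.0), method="bounded")
    B = float(res.x)
    return float(k_for(B)), B


def r_factor(f_obs: np.ndarray, f_model: np.ndarray) -> float:
    """R = sum |f_obs - f_model| / sum f_obs."""
    f_obs = np.asarray(f_obs, float)
    denom = f_obs.sum()
    if denom <= 0:
        raise ValueError("empty or zero f_obs")
    return float(np.abs(f_obs - np.asarray(f_model, float)).sum() / denom)


def scale_and_r(refl: ReflectionSet) -> RFactorReport:
    """Overall k/B fit on the work set; R on work and free sets separately."""
    if refl.f_obs is None or refl.f_calc is None:
        raise ValueError("scale_and_r needs both f_obs and f_calc")
    if refl.free_flag is None:
        raise ValueError("scale_and_r needs free flags")
    work = ~refl.free_flag
    free = refl.free_flag
    if work.sum() == 0 or free.sum() == 0:
        raise ValueError("empty work or free set")
    f_abs = np.abs(refl.f_calc)
    k, B = _fit_scale(refl.f_obs, f_abs, refl.stol2, work)
    scaled = k * np.exp(-B * refl.stol2) * f_abs
    return RFactorReport(r_factor(refl.f_obs[work], scaled[work]),
                         r_factor(refl.f_obs[free], scaled[free]), k, B)


def scaled_f_calc_amplitudes(refl: ReflectionSet) -> np.ndarray:
    """|f_calc| put on the f_obs scale with an overall k/B fit (all reflections)."""
    f_abs = np.abs(refl.f_calc)
    k, B = _fit_scale(refl.f_obs, f_abs, refl.stol2)
    return k * np.exp(-B * refl.stol2) * f_abs


def amplitude_correlation(refl: ReflectionSet) -> float:
    """Pearson correlation of f_obs with scaled |f_calc| (model-selection score)."""
    scaled = scaled_f_calc_amplitudes(refl)
    return float(np.corrcoef(refl.f_obs, scaled)[0, 1])


# ---------------------------------------------------------------------------
# Density maps


@dataclass
class DensityMap:
    grid: np.ndarray
    cell: UnitCell

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        if min(self.grid.shape) < 2:
            raise ValueError("map grid needs >= 2 divisions per axis")

    @property
    def shape(self):
        return self.grid.shape

    @property
    def spacing(self) -> tuple:
        return tuple(e / s for e, s in zip((self.cell.a, self.cell.b, self.cell.c),
                                           self.grid.shape))

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.cell)

    def standardized(self) -> "DensityMap":
        sd = self.grid.std()
        if sd == 0:
            raise ValueError("zero-variance map")
        return DensityMap((self.grid - self.grid.mean()) / sd, self.cell)

    def interpolate_frac(self, frac: np.ndarray, order: int = 1) -> np.ndarray:
        """Periodic interpolation at fractional positions (n, 3); trilinear
        by default, cubic spline with order=3."""
        frac = np.atleast_2d(np.asarray(frac, float))
        coords = (frac % 1.0).T * np.array(self.grid.shape)[:, None]
        return map_coordinates(self.grid, coords, order=order,
                               mode="grid-wrap")

    def interpolate_cart(self, cart: np.ndarray, order: int = 1) -> np.ndarray:
        return self.interpolate_frac(self.cell.fractionalize(cart), order)

    def write_ccp4(self, path) -> None:
        g = gemmi.FloatGrid(*self.grid.shape)
        g.set_unit_cell(gemmi.UnitCell(self.cell.a, self.cell.b, self.cell.c,
                                       self.cell.alpha, self.cell.beta,
                                       self.cell.gamma))
        g.spacegroup = gemmi.SpaceGroup("P 1")
        arr = np.array(g, copy=False)
        arr[...] = self.grid
        m = gemmi.Ccp4Map()
        m.grid = g
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))

    @classmethod
    def read_ccp4(cls, path) -> "DensityMap":
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
        cell = m.grid.unit_cell
        return cls(np.array(m.grid), UnitCell(cell.a, cell.b, cell.c,
                                              cell.alpha, cell.beta, cell.gamma))


def synthesize_map(hkl: np.ndarray, coeffs: np.ndarray, cell: UnitCell,
                   shape: tuple | None = None, d_min: float | None = None) -> DensityMap:
    """Fourier synthesis rho(x) = (1/V) sum_h F e^{-2 pi i h.x} (+Friedel mates)."""
    hkl = np.asarray(hkl, int)
    if shape is None:
        if d_min is None:
            d_min = float(cell.d_spacing(hkl).min())
        shape = grid_shape_for(cell, d_min)
    G = np.zeros(shape, complex)
    h, k, l = hkl.T
    G[h % shape[0], k % shape[1], l % shape[2]] = coeffs
    G[(-h) % shape[0], (-k) % shape[1], (-l) % shape[2]] = np.conj(coeffs)
    rho = scipy.fft.fftn(G).real / cell.volume
    return DensityMap(rho, cell)


def compute_map(refl: ReflectionSet, kind: str = "two_fo_fc",
                shape: tuple | None = None) -> DensityMap:
    """Map synthesis with fc phases: kind in {fo, two_fo_fc, fc}."""
    if refl.f_calc is None:
        raise ValueError("compute_map needs phases (f_calc missing)")
    phase = np.exp(1j * np.angle(refl.f_calc))
    if kind == "fc":
        if refl.f_obs is not None:
            coeffs = scaled_f_calc_amplitudes(refl) * phase
        else:
            coeffs = refl.f_calc
    elif kind in ("fo", "two_fo_fc"):
        if refl.f_obs is None:
            raise ValueError(f"kind={kind} needs f_obs")
        scaled_fc = scaled_f_calc_amplitudes(refl)
        amp = refl.f_obs if kind == "fo" else 2.0 * refl.f_obs - scaled_fc
        coeffs = amp * phase
    else:
        raise ValueError(f"unknown map kind {kind!r}")
    return synthesize_map(refl.hkl, coeffs, refl.cell, shape=shape)


def map_coefficients(dmap: DensityMap, hkl: np.ndarray) -> np.ndarray:
    """Inverse of synthesize_map: complex coefficients of a real map at hkl."""
    hkl = np.asarray(hkl, int)
    Fgrid = dmap.cell.volume * scipy.fft.ifftn(dmap.grid)
    h, k, l = hkl.T
    s = dmap.grid.shape
    return Fgrid[h % s[0], k % s[1], l % s[2]]


def map_correlation(a: DensityMap, b: DensityMap) -> float:
    if a.grid.shape != b.grid.shape:
        raise ValueError("map grids differ")
    x, y = a.grid.ravel(), b.grid.ravel()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance map")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class RealSpaceFit:
    overall: float
    residue_scores: dict       # (chain id, seqnum) -> score


def real_space_fit(model: Model, dmap: DensityMap) -> RealSpaceFit:
    """Occupancy-weighted mean map value per residue (map standardized first)."""
    std = dmap.standardized()
    scores = {}
    for cid, res in model.iter_residues():
        if not res.atoms:
            raise ValueError(f"empty residue {cid}/{res.seqnum}")
        xyz = np.array([a.xyz for a in res.atoms])
        occ = np.array([a.occ for a in res.atoms])
        vals = std.interpolate_cart(xyz)
        scores[(cid, res.seqnum)] = float((occ * vals).sum() / occ.sum())
    overall = float(np.mean(list(scores.values())))
    return RealSpaceFit(overall, scores)
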