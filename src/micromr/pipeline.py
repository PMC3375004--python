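"""Six-step orchestration: template editing, optional geometry-only
pre-refinement, molecular replacement, refinement + density modification,
density-guided rebuilding with map averaging, and iterative autobuilding.

Entry points: ``run_pipeline`` on a ``PipelineConfig`` (alignment mode or
placed-model mode), or ``run_steps_456`` to drive the map/rebuild/autobuild
stages directly from an already-placed model.  All randomness derives from
the single config seed through fixed per-stage offsets.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .density_mod import average_maps, density_modify, find_ncs_operators
from .model_core import Model, SymmetryOps, UnitCell, read_structure, write_model
from .mr_search import rescore_solutions, run_mr
from .rebuild import AutobuildResult, FragmentLibrary, RebuildParams, ScoreWeights, \
    autobuild_iterate, combined_score, make_default_library, rebuild_model, \
    rebuild_with_ncs, refine_real_space, select_top_models
from .template_prep import edit_template, enumerate_copies, parse_alignment, \
    sequence_mass
from .xray_core import DensityMap, ReflectionSet, compute_map, map_correlation, \
    scale_and_r, set_f_calc

N_MAPS_TO_AVERAGE = 4     # density-modified maps from the top-scoring rebuilds


@dataclass
class PipelineConfig:
    mode: str = "from_alignment"          # or "from_placed_model"
    reflections: str = ""
    sequence: str = ""
    alignment: str = ""
    template: str = ""
    placed_model: str = ""
    truth_model: str = ""                 # optional: track map CC to a known answer
    cell: list | None = None              # [a, b, c, alpha, beta, gamma]
    spacegroup: str = "P1"
    seed: int = 0
    output_dir: str = "micromr_out"
    pre_refine: bool = False
    rot_step: float = 30.0
    grid_step: float = 0.125
    b_inflate: float = 20.0
    score_floor: float = 0.0
    max_hypotheses: int = 2
    n_models: int = 6
    n_steps: int = 150
    temperature: float = 0.05
    max_loop_len: int = 8
    w_geom: float = 1.0
    w_dens: float = 1.0
    r_tol: float = 0.005
    max_outer_cycles: int = 3
    autobuild_cycles: int = 4
    dm_cycles: int = 3
    top_k: int = 2

    def __post_init__(self):
        if self.mode not in ("from_alignment", "from_placed_model"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "from_alignment":
            if self.placed_model:
                raise ValueError("placed_model given in alignment mode")
            if not (self.alignment and self.template):
                raise ValueError("alignment mode needs alignment and template")
        else:
            if self.alignment or self.template:
                raise ValueError("alignment/template given in placed-model mode")
            if not self.placed_model:
                raise ValueError("placed-model mode needs placed_model")
        if not self.reflections:
            raise ValueError("reflections file required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def weights(self) -> ScoreWeights:
        return ScoreWeights(self.w_geom, self.w_dens)

    def rebuild_params(self, seed_offset: int = 0) -> RebuildParams:
        return RebuildParams(self.n_models, self.n_steps, self.temperature,
                             self.max_loop_len, self.seed + seed_offset)


@dataclass
class RunResult:
    best_model: Model
    best_map: DensityMap
    report: object
    history: list = field(default_factory=list)
    events: list = field(default_factory=list)
    status: str = "ok"


class _Log:
    def __init__(self):
        self.events = []

    def add(self, stage, **info):
        self.events.append({"stage": stage, "time": round(time.time(), 3),
                            **info})


def _flat_map(cell: UnitCell, shape=(24, 24, 24), seed: int = 0) -> DensityMap:
    """Uninformative map (seeded noise) for modelling without density."""
    rng = np.random.default_rng(seed)
    return DensityMap(rng.normal(0, 1, shape), cell)


def _truth_map(config: PipelineConfig, refl: ReflectionSet,
               sym: SymmetryOps) -> DensityMap | None:
    if not config.truth_model:
        return None
    truth, _, _ = read_structure(config.truth_model)
    return compute_map(set_f_calc(refl, truth, sym), "fc")


def run_steps_456(model: Model, refl: ReflectionSet, sym: SymmetryOps,
                  config: PipelineConfig, lib: FragmentLibrary | None = None,
                  log: _Log | None = None, truth_map: DensityMap | None = None,
                  seed_offset: int = 4000):
    """One pass of refinement + density modification (4), density-guided
    rebuilding with map averaging (5) and iterative autobuilding (6)."""
    log = log or _Log()
    lib = lib or make_default_library()
    w = config.weights()

    def dm_map_for(m: Model):
        rf = set_f_calc(refl, m, sym)
        report = scale_and_r(rf)
        m2 = compute_map(rf, "two_fo_fc")
        ops = find_ncs_operators(m)
        first = next(iter(m.chains))
        solv = _solvent_estimate(m, refl, sym)
        dm = density_modify(
            m2, rf, m, solv, n_cycles=config.dm_cycles,
            ops=[o for o in ops if o.source_chain == first] or None,
            mask_center=Model({first: [r.copy() for r in m.chains[first]]}))
        return dm, report, ops

    # --- step 4: refine the placed model, build a density-modified map
    dm, report0, ops = dm_map_for(model)
    entry = AutobuildResult(model.copy(), dm, report0, [])
    history = [{"stage": "step4_start", "r_work": report0.r_work,
                "r_free": report0.r_free,
                "map_cc": map_correlation(dm, truth_map) if truth_map else None}]
    current = refine_real_space(model, dm, w)
    dm, report, ops = dm_map_for(current)
    log.add("step4_refine_dm", r_work=report.r_work, r_free=report.r_free)

    # --- step 5: density-guided rebuilding, map averaging, rebuild again
    params = config.rebuild_params(seed_offset)
    ncs = [o for o in ops if o.source_chain == next(iter(current.chains))]
    if ncs:
        models = [rebuild_with_ncs(current, dm, ncs, lib, params, w)]
    else:
        models = rebuild_model(current, dm, lib, params, w)
    tops = select_top_models(models, refl, sym, min(N_MAPS_TO_AVERAGE,
                                                    len(models)))
    dms = []
    for m in tops:
        mdm, _, _ = dm_map_for(refine_real_space(m, dm, w))
        dms.append(mdm)
    avg = average_maps(dms)
    if truth_map is not None:
        log.add("step5_avg_map", map_cc=map_correlation(avg, truth_map))
    rebuilt = [refine_real_space(m, avg, w) for m in
               select_top_models(tops, refl, sym, min(config.top_k, len(tops)))]
    log.add("step5_rebuild", n_models=len(models), n_averaged=len(dms))

    # --- step 6: autobuild each candidate, keep the lowest R_work
    # (the entry state is itself a candidate: rebuilding must never lose an
    # already-good model, matching the lowest-R-value selection rule)
    results = [entry]
    for i, m in enumerate(rebuilt):
        res = autobuild_iterate(m, refl, sym, lib,
                                config.rebuild_params(seed_offset + 100 + i),
                                w, r_tol=config.r_tol,
                                max_cycles=config.autobuild_cycles,
                                dm_cycles=config.dm_cycles)
        results.append(res)
        log.add("step6_autobuild", candidate=i, r_work=res.report.r_work,
                cycles=len(res.history))
    best = min(results, key=lambda r: r.report.r_work)
    for res in results:
        for h in res.history:
            history.append({"stage": "step6", **h})
    history.append({
        "stage": "best", "r_work": best.report.r_work,
        "r_free": best.report.r_free,
        "map_cc": map_correlation(best.map, truth_map) if truth_map else None})
    return best, history


def _solvent_estimate(model: Model, refl: ReflectionSet,
                      sym: SymmetryOps) -> float:
    from .model_core import model_mass
    vm = refl.cell.volume / (len(sym) * max(model_mass(model), 1.0))
    return float(np.clip(1.0 - 1.23 / vm, 0.2, 0.8))


def _load_inputs(config: PipelineConfig):
    cell = sgname = None
    model_path = config.placed_model or config.template
    model, pdb_cell, pdb_sg = read_structure(model_path)
    if config.cell:
        cell = UnitCell(*config.cell)
    elif pdb_cell is not None:
        cell = pdb_cell
    else:
        raise ValueError("no unit cell: set config.cell or a CRYST1 record")
    sgname = config.spacegroup or pdb_sg or "P1"
    sym = SymmetryOps.from_name(sgname)
    if config.reflections.endswith(".mtz"):
        refl = ReflectionSet.read_mtz(config.reflections)
    else:
        refl = ReflectionSet.read_text(config.reflections, cell)
    if refl.free_flag is None or not refl.free_flag.any():
        from .xray_core import assign_free_flags
        refl = assign_free_flags(refl, 0.05, config.seed + 17)
    return model, cell, sym, refl


def run_pipeline(config: PipelineConfig) -> RunResult:
    log = _Log()
    lib = make_default_library()
    w = config.weights()
    model, cell, sym, refl = _load_inputs(config)
    truth_map = _truth_map(config, refl, sym)
    history = []
    placed = None

    if config.mode == "from_alignment":
        # --- step 1: edit the template to the target sequence
        aln = parse_alignment(config.alignment)
        edited = edit_template(model, aln)
        log.add("step1_edit", n_res=edited.n_residues,
                identity=aln.identity, gaps=len(edited.meta.get("gaps", [])))
        # --- step 2 (optional): geometry-only remodelling, no density
        if config.pre_refine:
            flat = _flat_map(cell, seed=config.seed + 2000)
            geom_w = ScoreWeights(w_geom=1.0, w_dens=0.0)
            cands = rebuild_model(edited, flat, lib,
                                  config.rebuild_params(2000), geom_w)
            edited = max(cands, key=lambda m: combined_score(m, flat, geom_w))
            log.add("step2_prerefine", n_candidates=len(cands))
        else:
            log.add("step2_skipped")
        # --- step 3: molecular replacement over copy-number hypotheses
        mass = sequence_mass(aln.target_seq)
        hyps = enumerate_copies(cell, sym, mass)[:config.max_hypotheses]
        if not hyps:
            raise ValueError("no admissible copy-number hypothesis")
        sols = run_mr([edited], refl, cell, sym, hyps,
                      rot_step=config.rot_step, grid_step=config.grid_step,
                      score_floor=config.score_floor)
        if not sols:
            return RunResult(edited, _flat_map(cell), None, history,
                             log.events, status="mr_failed")
        sols = rescore_solutions(sols, refl, cell, sym, config.b_inflate)
        top = sols[0]
        log.add("step3_mr", score=top.score, r=top.r_after_placement,
                n_copies=len(top.placements), partial=top.partial)
        if top.partial and len(top.placements) > 0:
            # partial solution: placed part becomes the fixed model
            more = run_mr([edited], refl, cell, sym,
                          [h for h in hyps if h.n_copies > len(top.placements)]
                          or hyps, rot_step=config.rot_step,
                          grid_step=config.grid_step, fixed=top.combined_model,
                          score_floor=config.score_floor)
            if more:
                top = more[0]
                log.add("step3_mr_fixed_retry", score=top.score)
        placed = top.combined_model
        placed.meta = dict(edited.meta)
    else:
        placed = model
        log.add("placed_model_input", n_res=placed.n_residues)

    # --- steps 4-6, iterated until R_work stops changing
    best = None
    for outer in range(config.max_outer_cycles):
        res, hist = run_steps_456(placed, refl, sym, config, lib, log,
                                  truth_map, seed_offset=4000 + 500 * outer)
        for h in hist:
            history.append({"outer": outer, **h})
        if best is None or res.report.r_work < best.report.r_work:
            best = res
        log.add("outer_cycle", outer=outer, r_work=res.report.r_work)
        entry_r = hist[0]["r_work"]
        if abs(res.report.r_work - entry_r) < config.r_tol:
            break
        placed = res.model

    result = RunResult(best.model, best.map, best.report, history, log.events)
    _write_outputs(result, config, cell, sym)
    return result


def _write_outputs(result: RunResult, config: PipelineConfig,
                   cell: UnitCell, sym: SymmetryOps) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    write_model(result.best_model, os.path.join(out, "best_model.pdb"),
                cell=cell, spacegroup=sym.name)
    result.best_map.write_ccp4(os.path.join(out, "best_map.ccp4"))
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump({"r_work": result.report.r_work,
                   "r_free": result.report.r_free,
                   "scale": result.report.scale,
                   "b_overall": result.report.b_overall,
                   "status": result.status,
                   "history": result.history}, fh, indent=1, default=str)
    with open(os.path.join(out, "log.jsonl"), "w") as fh:
        for ev in result.events:
            fh.write(json.dumps(ev, default=str) + "\n")
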