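# micromr

Desk-scale molecular replacement and density-guided model rebuilding for
protein crystallography, verifiable end-to-end on synthetic toy crystals.

Solving a crystal structure by molecular replacement (MR) places a homologous
template structure in the unit cell by optimizing the agreement between
measured structure-factor amplitudes |F_obs(h)| and those calculated from the
placed template, then uses the template's phases to compute an electron
density map and rebuilds a new model into that map.  The method fails in two
ways when the template is too far from the target (main-chain rmsd beyond
roughly 1.5–2 Å): the correct placement may not be found, and a correctly
placed template may give a map too biased to rebuild.  `micromr` implements,
at toy scale, the combined strategy that addresses both failure modes:
template editing from a sequence alignment, rigid-body placement scored
against amplitudes, solvent flattening and NCS averaging to improve phases,
Monte-Carlo fragment rebuilding driven by a physical-plausibility score
augmented with a density-fit term,

    score = w_dens * <rho_map at atoms> - w_geom * (bond_dev + angle_dev/50
                                                    + clash + 2 * rama_out)

and a convergence-controlled autobuild loop that iterates map calculation,
rebuilding, real-space refinement and pruning until the R value

    R = sum_h | |F_obs| - k e^{-B s^2/4} |F_calc| | / sum_h |F_obs|

stops changing, keeping the lowest-R model and its density-modified map.

Every stage is exercised against synthetic toy crystals with a known answer:
ideal-geometry helical folds in P1/P2₁/P2₁2₁2₁ cells, simulated amplitudes
with controlled noise, templates perturbed to a prescribed main-chain rmsd,
and homolog sequences at a prescribed identity.  Nothing is downloaded;
every number below is reproducible from a seed.

## Worked example

```python
from micromr import (make_standard_fixture, perturb_model, set_f_calc,
                     scale_and_r, compute_map, map_correlation,
                     run_steps_456, PipelineConfig)
from micromr.model_core import main_chain_rmsd

fx = make_standard_fixture(seed=0)            # 30-res helix-turn-helix, P1,
target, sym, refl = fx["target"], fx["sym"], fx["refl"]   # 2.5 Å, 5% noise

pert = perturb_model(target, 1.5, seed=1000)  # the "distant template"
refl_fc = set_f_calc(refl, pert, sym)
print(scale_and_r(refl_fc).r_work)            # 0.450  -- placed-template R

cfg = PipelineConfig(mode="from_placed_model", placed_model="x",
                     reflections="x")         # paths unused when run directly
true_map = compute_map(set_f_calc(refl, target, sym), "fc")
best, history = run_steps_456(pert, refl, sym, cfg, truth_map=true_map)
print(round(best.report.r_work, 3))                    # 0.350
print(round(main_chain_rmsd(best.model, target), 3))   # 1.044
print(round(map_correlation(best.map, true_map), 3))   # 0.843
```

One pass of refinement, density modification, fragment rebuilding, map
averaging and autobuilding takes the placed 1.5 Å-perturbed template from
R 0.450 to 0.350, its main-chain rmsd to the true structure from 1.48 to
1.04 Å, and the map correlation to the true map from 0.66 to 0.84 — the
rebuild-clears-the-map mechanism the package exists to demonstrate.

The `examples/` directory holds one short script per capability (toy
crystals, dual-route structure factors, template editing, MR recovery,
density modification, gap rebuilding, the full pipeline); each prints the
numbers it computes and what they mean.  A thin CLI is also installed:

```
micromr synth --seed 2 --out fixture/      # write a toy crystal + run.yaml
micromr run --config fixture/run.yaml      # full pipeline
micromr score model.pdb refl.txt           # R factors of a model
```

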