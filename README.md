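# szest

Simulation and analysis toolkit for structurally enhanced Bayesian perimetry:
ZEST and S-ZEST adaptive threshold strategies on a fovea-centred 10-2 visual
field grid, with priors individualized from ganglion-cell-layer (GCL)
thickness, spatial likelihood enhancement, simulated observers, a cohort
simulation harness, and test–retest/agreement statistics. Everything runs on
synthetic eyes — no hardware, no clinical data.

## What's inside

| module | role |
|---|---|
| `szest.grid` | 10-2 grid construction, fovea–disc rotation, ganglion-cell displacement, neighbour graphs |
| `szest.structfunc` | thickness maps, GCL sampling, structure–function prediction and fitting |
| `szest.priors` | discrete normal/abnormal mixture priors over 0–40 dB |
| `szest.engine` | the adaptive loop: cdf likelihood (asymptotes 0.03/0.97), posterior-mean stimulus choice, SD ≤ 1.5 dB termination, spatial flattened updates |
| `szest.observer` | Gaussian psychometric observers with sensitivity-dependent slope; reliable (5%) and unreliable (20%) presets |
| `szest.synth` | synthetic cohorts: healthy + glaucoma eyes with SF-consistent GCL maps |
| `szest.fovea` | fovea localization by zero-normalized cross-correlation; affine coordinate mapping |
| `szest.analysis` | simulation harness, MAE/presentation summaries with 2.5/97.5% quantiles, Bland–Altman with subject bootstrap |

Caveats: the structure–function model (linear in log10 thickness), the
abnormality-weight logistic, the displacement curve and the foveal template
are documented stand-ins for material not published in the source study
(supplementary equations, third-party model code, a 30-scan average
template); each sits behind a pluggable parameter object so fitted versions
can be substituted.

## CLI

```bash
szest make-cohort --healthy 21 --glaucoma 32 --severity-mix 5,8,19 --seed 1 --out scratch/cohort
szest run-test --eye scratch/cohort/glaucoma_000 --strategy szest --spatial on --seed 1 --out scratch/run
szest simulate --cohort scratch/cohort --conditions zest:off,szest:on --reps 50 --seed 1 --out scratch/sim
szest analyze --results scratch/sim/raw.tsv --mode summary
szest detect-fovea --map MAP.tsv --template TEMPLATE.tsv
```

All files are delimited text; thickness maps carry a 3-line `#` header
(origin, pixel size).

## Minimal API example

```python
import szest

eyes = szest.gen_cohort(szest.CohortSpec(n_healthy=2, n_glaucoma=3, seed=0))
eye = eyes[-1]
grid, graph, priors, cfg = szest.prepare_strategy(eye, "structural", spatial=True)
result = szest.run_test(eye, grid, graph, priors, szest.RELIABLE, cfg, seed=1)
print(result.n_presentations, szest.mae(result, eye.true_thresholds))
```
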