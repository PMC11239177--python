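# dendrodomains

Analysis of how functional synapses organize into co-active domains on
developing cortical dendrites, from concurrent dendritic calcium imaging and
somatic voltage-clamp data.

During the second postnatal week, layer 2/3 pyramidal cells in mouse visual
cortex receive spontaneous synaptic input in compound barrages. Calcium
imaging of a dendrite during somatic voltage clamp localizes individual
transmission events to synapses along that dendrite, and the somatic current
reports the global input barrages. This package implements the full analysis
chain over such data, plus a seeded synthetic-data generator that provides
ground truth for every stage:

1. **Event and barrage detection** — calcium transients are fluorescence
   increases ≥ 2× the trace noise level lasting ≥ 2 frames; barrages are
   compound inward currents ≥ 10 pA, merged when separated by < 3 s, with
   charge Q = ∫(baseline − I) dt in pC.
2. **Synapse activity table** — per-synapse transmission frequency *f*
   (min⁻¹), the 0.03 min⁻¹ functional-synapse filter, and high-activity
   classification (top 20th percentile of *f* within each age group).
3. **Spatial statistics** — a shuffle test for non-random placement: "empty"
   candidate positions fill the dendrite at the typical minimal
   inter-synapse spacing (4 µm), synapses are redistributed over real +
   empty positions (100 shuffles), and observed vs null proximal/distal
   nearest-neighbor geodesic distances are compared with a
   Kolmogorov–Smirnov test.
4. **Domain segmentation** — high-activity synapses ≤ 10 µm apart anchor a
   common domain (single linkage); normal synapses join their nearest anchor
   within 10 µm; extents are padded 5 µm beyond an outermost anchor with no
   nearby member, so a lone high-activity synapse defines a 10 µm domain.
5. **Co-activity** — for a synapse and a comparison group,
   C = (# barrages co-active with ≥ 1 group member) / (# active barrages) /
   |group|, with groups for ≤ 10 µm neighbors, same-domain partners, other
   domains, and outside-domain synapses.
6. **Trends** — the Mann–Kendall score S = Σ_{i<j} sign(f_j − f_i) over the
   per-recording frequencies, and an OLS regression of S on local
   co-activity over synapses with f ≥ 0.6 min⁻¹.

All distances are geodesics along the reconstructed dendrite (µm), never
through space.

## Worked example

```python
from dendrodomains import (PipelineConfig, generate_cohort, run_pipeline)

cohort = generate_cohort(seed=1, n_per_group=6)   # 6 young + 6 old dendrites
bundle = run_pipeline([e for e, _ in cohort], PipelineConfig(seed=1),
                      out_dir="results/pipeline")
print(bundle.stats["coactivity_within_vs_other_experiment"])
```

On this cohort the analysis chain reproduces the study's qualitative
structure from the generator's ground truth (printed by the drivers under
`analysis/`, run in order):

```
event recall 1.000, precision 0.987 (74 strong true events)
barrage windows: 22 detected / 22 true, interval Jaccard 0.950
age_regression/mean_f: slope 0.093/day, p = 0.0000
membership recovery vs ground truth: Jaccard 0.836
within-domain vs other-domain co-activity, per experiment (n=7):
    0.228 vs 0.118, Wilcoxon p = 0.0312
Mann-Kendall score inside vs outside domains: +5.73 vs +0.41, p = 0.0226
```

That is: rendered signals round-trip through detection almost losslessly;
mean transmission frequency rises with postnatal day; inferred domain
membership matches the generative truth; synapses are more co-active with
their own domain than with other domains; and synapses inside domains tend
to potentiate while those outside tend to stagnate or depress.

The command-line interface exposes the same stages
(`dendrodomains simulate|detect|shuffle-test|run-all ...`).

## Layout

- `src/dendrodomains/` — the library: `morphology`, `detection`,
  `activity`, `spatial`, `domains`, `coactivity`, `synthetic`, `pipeline`,
  `io`, `cli`.
- `analysis/01…06` — numbered drivers that simulate the study cohort and
  run each analysis stage, writing tables under `results/`.
- `tests/` — unit, property and end-to-end acceptance tests (synthetic
  ground truth throughout; no data downloads).
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and limitations.
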