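# Methods

## Data model

An *experiment* is one dendrite imaged during somatic voltage clamp: a
geometric tree (nodes with 3D positions, positive edge lengths in µm), a set
of synapses at edge-local positions with spine/shaft labels, a series of
recordings (3 min each), per-synapse transmission events (onset, duration in
frames, peak ΔF amplitude), and somatic barrages (window, peak, charge).
Every distance is the geodesic along the tree; positions use half-open
edge-local coordinates, with ties at branch points resolved to the parent
edge. Unbranched dendrites can be built directly from a single arc length.
The paper-equivalent image-space path measurements coincide with tree
geodesics for points on one dendrite; the tree version is deterministic and
testable, which is why it is used here.

## Detection

**ΔF events.** The noise level of a trace is 1.4826 × MAD of its first
differences divided by √2 (differencing removes slow drift and inflates
white noise by √2; transients touch only a small fraction of the
differences, so the estimator is robust to them — verified to stay within
[0.9, 1.2] of truth with 5% contaminated frames). An event is a run of at
least two consecutive frames at least 2σ above the trace median; its
amplitude is the peak ΔF above that baseline, its offset the last
supra-threshold frame. A per-frame accept mask lets callers emulate manual
curation (e.g. movement rejection). Note an intrinsic property of the
2σ/2-frame rule on white noise: about 0.9 spurious 2-frame runs per 1800
frames per trace. These were removed by manual review in the original
workflow; here they remain (they are 2 frames long by construction, so any
analysis of ≥ 3-frame transients is unaffected) and the round-trip
validation quantifies precision within the ≥ 3-frame class.

**Barrages.** The somatic current baseline is a running 20th percentile
over 10 s blocks (inward = negative; the deflection is analysed as a
positive signal). Because a barrage is a *compound* current, detection
operates on a 0.05 s smoothed envelope so single EPSC-scale blips cannot
trigger it. Candidate regions exceed 10 pA; each region's window extends
outward to the crossings at 10% of its peak, tolerating envelope dips
shorter than 0.6 s (far below the 3 s separation rule, so windows never
bridge distinct barrages); windows closer than 3 s merge. Charge is
trapezoidal ∫(baseline − I) dt over the window in pC. Events associate to
the barrage whose window (± 0.2 s tolerance, for clock jitter between the
two acquisition streams) contains their onset; with several candidates the
nearest onset wins, ties to the earlier barrage. Event amplitudes are
z-scored per synapse (sample SD; synapses with < 2 events or zero spread
get z = 0).

## Activity table

f = events / recorded minutes (min⁻¹), per recording and overall (the
overall value is the duration-weighted mean of the per-recording values).
Synapses below 0.03 min⁻¹ are excluded from all functional statistics.
High-activity = f at or above the 80th percentile (linear-interpolation
quantile, ties included) of all synapses pooled over the dendrites of the
same age group (P8–10 vs P12–13); per-dendrite and per-day grouping are
config options.

## Shuffle test

Empty candidate positions fill the dendrite between real synapses: nodes
without a synapse within half the spacing receive a candidate, and every
inter-anchor gap of length g gets ⌈g/s⌉ − 1 equally spaced candidates
(s = 4 µm, the typical minimal inter-synapse distance; candidates closer
than s/2 to a real synapse are dropped). Each of 100 shuffles redistributes
the synapses uniformly without replacement over real + empty positions;
proximal and distal nearest-neighbor geodesic distances are pooled across
shuffles and compared with the observed ones by a two-sample KS test
("proximal" on branched trees = the neighbor whose path from the focal
synapse starts toward the root). Two p-value modes exist: the default pools
all shuffles into one null sample (scipy `ks_2samp`); the "rank" mode uses
the permutation rank of the observed KS statistic among the per-shuffle
statistics.

Calibration: the test presumes data with the stated minimal inter-synapse
spacing. Against placements drawn from its own null model (uniform draws
from candidate slots at 4 µm spacing) the rank mode with an explicit
candidate set is exchangeable by construction and rejects at 0.045 for
α = 0.05 over 200 dendrites; the pooled mode is conservative under the
discrete candidate geometry (heavy ties; rejection ~0.01–0.02). Against
placements that ignore the minimal spacing (continuous uniform), the test
is anticonservative — sub-spacing nearest-neighbor distances are impossible
under the null — so it should not be applied to data whose resolution
admits them. Power against half-dendrite clustering (20 synapses on half of
a 150 µm dendrite) is ≈ 1.0 in either mode.

## Domains

Single-linkage clustering of high-activity synapses at 10 µm (chains of
≤ 10 µm links join; a complete-linkage option exists for sensitivity
analysis). Normal synapses join the domain of their nearest anchor if
within 10 µm — this subsumes the ≤ 20 µm between-domain tie-break rule and
extends it to all distances. A domain's span is the minimal subtree covering
its synapses; each outermost anchor with no normal member within 5 µm
contributes 5 µm of padding along its open direction, clipped at tips and
branch points, with overlapping paddings of adjacent domains split at the
midpoint. A single-anchor domain with no members therefore has extent
exactly 10 µm. Metrics per dendrite: domains per 100 µm, covered fraction
(capped at 1), % of synapses inside domains.

## Co-activity and trends

C(focal, group) = (# barrages in which focal and ≥ 1 group member both have
an event) / (# barrages in which focal is active) / |group| ∈ [0, 1];
undefined (excluded) when the group is empty or the focal synapse never
fires inside a barrage. Out-of-barrage events never contribute. The
alternative event-count ratio (focal events over group events within the
focal synapse's active barrages, normalized by group size) is available as
`method="event_ratio"`; it is unbounded and undefined for silent groups,
which is why the bounded fraction is primary. Comparison groups: ≤ 10 µm
neighbors ("local"), same-domain partners, all other-domain synapses,
outside synapses.

The Mann–Kendall score S = Σ_{i<j} sign(f_j − f_i) over the experiment's
recording sequence (ties contribute 0; |S| ≤ n(n−1)/2); it is reported raw,
not normalized to tau, since zero has the natural reading "no change". The
trend–co-activity relation is an OLS regression of S on local C over
synapses with f ≥ 0.6 min⁻¹; a constant-C design degenerates with a warning.

Group statistics follow the study's conventions: two-sided Student's
t-tests for low-n per-experiment comparisons, Mann–Whitney U for unpaired
and Wilcoxon signed-rank for paired non-normal samples, OLS with 95% CI for
per-experiment regressions on postnatal day. No multiple-testing correction
is applied by default, matching per-comparison reporting.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, with
every latent exposed as ground truth. Defaults (the study-like conditions):

| parameter | default | basis |
| --- | --- | --- |
| dendrite length | 150 µm, unbranched | typical imaged stretch |
| recordings | 10 × 3 min | many 3-min recordings per experiment |
| frame rate / current sampling | 10 Hz / 10 kHz | acquisition range |
| domain density | young 1.2, old 2.5 / 100 µm | development of domain density |
| domain extent | ~19–23 ± 4 µm | domain extent range |
| synapses per domain | young 4, old 5.5 (Poisson, ≥ 2) | 3→6 over development |
| background synapse density | 2 / 100 µm | sparse non-domain synapses |
| high-release fraction | 0.20 of placed synapses | top-20% definition |
| release propensity | lognormal σ = 0.4; anchors ×4.5 (σ = 0.3) | long-tailed frequencies |
| barrage rate / gaps / durations | 3 min⁻¹ / ≥ 3 s / 1.2–3 s | barrage statistics |
| recruitment | P(domain recruited) = 0.35·scale·size | within-domain co-activity |
| firing given recruitment | 0.2 × propensity | event rates |
| background firing / out-of-barrage | 0.02 per barrage × scale·size / 0.1 min⁻¹ | ~⅔ of events in barrages |
| young/old frequency scale | 0.4 / 1.0 | mean f ≈ 0.2 / 0.55 min⁻¹ |
| amplitude coupling | amp ∝ size^0.5 × lognormal(0.25) | amplitude grows with barrage size |
| trends | fraction 0.6, magnitude 0.8, coupled | potentiation inside domains |

Placement: domain centers uniform along the tree; each domain gets one
high-release anchor at its center (the largest domains a second, a few
µm away, since high-activity synapses cluster near each other); members are
placed within 10 µm of an anchor, keeping generative membership consistent
with the assignment rules; background synapses are uniform. Part of the
high-release budget ("lone" anchors) is placed without partners: these fire
out of sync — background-level inside barrages plus an elevated
out-of-barrage rate (0.25 min⁻¹ × propensity) — and under coupled trends
they always depress, while synapses with domain partners potentiate and
background synapses depress at the trend fraction. Barrage sizes are
lognormal (σ = 0.4, floor 0.6); size scales recruitment and background
firing, so larger barrages carry more events and more charge, and event
amplitudes scale with size^β.

Rendering: ΔF = events convolved with a rise/decay indicator kernel
(0.1 s / 0.6 s) plus Gaussian noise (σ = 0.15 against default amplitudes
≈ 1, i.e. ≈ 6σ events); somatic current = one 8 pA, 20 ms-decay EPSC per
event — including the unimaged majority of inputs, drawn at 40 s⁻¹ × size
during each barrage with 35% of them front-loaded into the first 12% of the
window (the fast-rising compound onset) — plus 1 pA noise.

What the generator does *not* emulate: imaging artifacts (drift, movement,
bleaching, neuropil contamination), ROI segmentation errors, spatially
correlated noise, z-foreshortening of distances, electrotonic filtering of
EPSCs, and any biological mechanism behind the trends. Passing tests
therefore validate the analysis chain's logic and statistical behavior on
data with the assumed structure, not robustness to real-world imaging
artifacts.

## Problem sizes and numerical choices

Tests and drivers use seeded cohorts of 12–20 dendrites (6–10 per age
group) for recovery checks, 200 dendrites for shuffle-test calibration, and
a 64-dendrite cohort with full trend injection (fraction 1.0, magnitude
1.6, all spare anchors lone, background 4 / 100 µm) for the
trend–co-activity slope: at the default presets the slope is positive in
expectation but its sign is noise-dominated at study-sized cohorts (a
handful of depressing high-activity loners against ~10% co-activity
spread), so the coupling demonstration uses conditions where the coupled
populations are both well represented. Relatedly, at small cohorts the
near-vs-far comparison around high-activity synapses can invert when lone
high-release synapses dominate the "far" group; the elevated-neighborhood
property is demonstrated under paired-anchor conditions.

Determinism: every stochastic step draws from `numpy.random.default_rng`
seeded from the experiment/config seed; identical seeds give bit-identical
tables, and the whole pipeline replays byte-identically. Degenerate inputs
(constant traces, empty groups, single synapses, missing anchors) return
explicit empties, warnings, or raise with the offending stage named.

## Known limitations

- The pooled-KS shuffle mode inherits `ks_2samp`'s tie handling and is
  conservative on discrete candidate sets; use the rank mode when
  calibration matters.
- Domain padding on branched trees is clipped at branch points rather than
  split across child branches; extents on heavily branched trees are
  therefore conservative.
- The event detector applies the 2σ/2-frame rule without any surrogate for
  full manual review; ≥ 3-frame analyses are unaffected, but raw event
  counts include short noise runs at the documented rate.
- Frequencies assume recordings are homogeneous within themselves; within-
  recording nonstationarity is not modeled.
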