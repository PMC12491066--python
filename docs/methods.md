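# Methods

## Melt-curve scoring

A paDSF well pairs one dye with one sample and records fluorescence in six
excitation/emission channels (470/520, 515/545, 535/580, 565/605, 630/670,
660/705 nm) over a 25–95 °C ramp at 1 °C per cycle (71 points). Counter
screens use three control well types: dye alone (*no-protein*), dye +
polyanion inducer (*polyanion-only*), and dye + monomeric protein
(*monomer*).

Each curve is summarized by f_max, f_min and T(f_max) from the **raw**
curve, and Δf from the control-subtracted curve. The scoring rules mention
subtraction only for Δf, so the extrema are deliberately read raw; Δf is
the amplitude (max − min) of the subtracted series, the standard DSF
reading — `summarize_curve(delta_mode="max")` switches to the maximum of
the subtracted series instead. Ties in the maximum resolve to the lowest
temperature. Control pairing: fibril wells subtract the polyanion-only
control sharing their dye and inducer; monomer wells subtract the
no-protein control. This is the only pairing in which the subtraction
removes exactly the fluorescence the sample well contains beyond its
protein.

The rule table (first match wins, descending):

| score | f_max | f_min | Δf | T(f_max) |
|---|---|---|---|---|
| 10 | > 1000 | > −1000 | > 2500 | < 55 °C |
| 8 | > 1000 | > −2000 | 1500 ≤ Δf ≤ 2500 | < 55 °C |
| 5 | > 1000 | > −2000 | 1000 ≤ Δf < 1500 | < 55 °C |
| 3 | > 2000 | > −2000 | > 2000 | 55 ≤ T ≤ 70 °C |
| 1 | > 2000 | > −2000 | > 2000 | > 70 °C |
| 0 | — | — | — | — |

Band endpoints are chosen so the rules partition without holes against the
adjacent strict inequalities: Δf exactly 2500 scores 8 (the 10-rule needs
strictly more), T exactly 70 scores 3 (the 1-rule needs strictly more).
With the half-open alternative those boundary summaries would fall through
to 0, and the score would not be monotone in Δf. All thresholds live in
`ScoringThresholds` and can be overridden from YAML.

The well score is the maximum over the six channel scores (hits surface in
different channels for different dyes; the winning channel is recorded).
Two replicate well scores add to a 0–20 cumulative score; `triage_hits`
selects dyes whose best cumulative score reaches the hit cutoff (default
20) and excludes those whose monomer counter-screen well score reaches the
monomer cutoff (default 5) in either replicate. Manual curation is an
explicit input list, never inferred. Dyes whose no-protein control already
exceeds 1,000 RFU at ramp start are flagged as potential bright-dye
artefacts but never auto-removed. `hit_rate` uses exact rational
arithmetic with half-up rounding to one decimal.

For abbreviated plate-reader screens without a ramp, `sd_activity_call`
implements the endpoint rule: active when the fibril mean is at least k
(default 3) monomer standard deviations above the monomer mean, boundary
inclusive; zero monomer variance is rejected rather than silently treated
as infinitely sensitive.

Heatmap ordering (`cluster_order`) uses agglomerative clustering with
average linkage on Euclidean distances of the dye × sample cumulative
score matrix, identifiers pre-sorted for deterministic tie-breaks.

## Spectral discrimination

The default acquisition grid pairs excitations 470–670 nm (20-nm steps)
with contiguous 20-nm emission windows from 10 nm above each excitation up
to 780 nm (110 channels), plus a 405-nm sweep from 420 to 780 nm
(18 channels): 128 channels total.

Segmentation thresholds the maximum-intensity projection across channels
(max preserves particles bright in few channels): a pixel is foreground
when it exceeds the local mean over a square window (side = 1/8 of the
image side) scaled by 1 + *sensitivity*; 8-connected components under
`min_area` (default 10 px) are dropped. The default sensitivity is 0. On
noisy images a strictly positive sensitivity is required: with additive
background noise roughly half of all background pixels exceed their local
mean, and at 8-connectivity that fraction percolates into one giant
component. The discrimination tests run at sensitivity 0.5 for this
reason.

Per-particle profiles are channel means over mask pixels, normalized to
sum to one (pure spectral shape, invariant to brightness and laser power;
unit-norm normalization would differ only by a per-profile constant).
PCA is mean-centered with component signs fixed so the largest-magnitude
loading is positive, making embeddings reproducible. The discrimination
score is the resubstitution accuracy of a quadratic discriminant (per-class
means/covariances, empirical priors) on the first two components; a
stratified cross-validation mode is available behind a flag. Before the
fit, coordinates are rescaled to unit pooled within-class variance — QDA
accuracy is equivariant under a common feature rescaling, and this keeps
the fit independent of intensity units (the pipeline is exactly invariant
under scaling all images by c > 0) and of the between-class separation.
Genuinely singular class covariances raise an error suggesting
`reg_param`. Per-inducer accuracies average arithmetically into the
overall discrimination score.

## Kinetics

Traces are min–max normalized ("fraction of total signal"), the only
rescaling that yields exactly [0, 1] endpoints; constant traces are
rejected. t50 is the first upward 0.5-crossing, linearly interpolated
between bracketing samples; an optional 3-point moving-median pre-filter
(off by default) suppresses single-sample spikes. Early/late calls against
a reference reporter use an explicit tolerance (default 2 h) because such
conclusions are otherwise qualitative. Curves that never reach 0.5 raise —
a deliberate stop: a flat curve may mean the dye inhibits aggregation, and
that needs a human decision, not a number.

## Tanimoto diversity

The similarity statistic operates on bit sets; fingerprint generation is
delegated to RDKit (Morgan, radius 2, 2048 bits by default) at the
interface boundary, because fingerprint type and length are an interface
choice. Histograms tile [0, 1] with width-0.1 bins, last bin right-closed
so identity pairs are counted once.

## Synthetic data

The generators emulate the screen design — by default 306 dyes against 26
fibril samples (2 protein variants × 13 polyanion inducers) with the three
control types, two biological replicates, six channels and the 71-point
ramp — not the photophysics of real dyes. A binder's melt signature is a
logistic decay (amplitude 3,000 RFU, midpoint 45 °C, width 4 °C, baseline
200 RFU) in one dye-specific response channel, so the fluorescence maximum
sits at ramp start; at zero noise these parameters map active wells to
score 10 and everything else to 0, which the oracle-closure test verifies
archetype by archetype. Bright artefacts sit flat at 6,000 RFU in every
well including the dye-alone control. The default archetype mix is mostly
inert (90%) with 2% of each interesting behavior, echoing low real-world
hit rates; recovery tests use a richer mix so every archetype is present
at small n. Noise is i.i.d. Gaussian per point drawn from per-well named
substreams, so enlarging a dataset never perturbs existing wells and the
same seed reproduces byte-identical CSVs.

Spectral stacks place non-overlapping Gaussian blobs (σ = 2.5 px, peak
1,000) on a jittered grid; channel intensities follow a bivariate Gaussian
response (width 60 nm) over (excitation, emission-center) wavelengths,
shifted along both axes for class B. Reference masks use the 1/e²
beam-waist support (r = 2σ), the standard optics spot-size convention.
Kinetic traces are logistic with recorded midpoint.

What passing tests do and do not show: planted-truth recovery at zero
noise demonstrates the pipeline's logic, not robustness to instrument
drift, well-to-well gain variation, or dyes whose real melt signatures
differ from a clean logistic decay; the spectral generator omits
autofluorescent background structure and particle overlap. Conclusions
about real screens still require the controls and replicates the scoring
stage is built around.

## Problem sizes

Tests and the acceptance script run at desk scale as the package's own
choice: screens of 10–24 dyes × 4 conditions, spectral stacks of 96×96 px
with 12 particles per class over 10 seeds, kinetics at 0.25–0.5 h
sampling. All stages scale linearly in wells, pixels × channels, and
timepoints respectively; the full 306 × 26 design runs with the same code
paths.
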