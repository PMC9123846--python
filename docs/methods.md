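# Methods

`dbsnet` implements a normative-connectome mapping chain for deep-brain-
stimulation (DBS) target networks: seed-to-voxel functional connectivity
across a multi-subject resting-state cohort, group-level statistical
thresholding, seizure-outcome-weighted efficacy mapping, multi-seed overlap
node extraction, and weighted graph centrality analysis. A synthetic
resting-state phantom with planted covariance structure stands in for a real
normative dataset so that every stage can be validated by parameter
recovery.

## Synthetic phantom

The phantom emulates the acquisition geometry of a 3 T normative
resting-state cohort: T = 124 time points at TR = 3 s, 3 x 3 x 3 mm voxels,
signal band-limited below 0.08 Hz. Each latent network k carries an
independent signal s_k(t), drawn fresh per subject as white Gaussian noise,
low-pass filtered, and re-standardised to unit sample variance (times an
optional `signal_sd`). A voxel in a region with loadings a_vk observes

    x_v(t) = sum_k a_vk s_k(t) + sigma eps_v(t),

with i.i.d. white Gaussian eps of standard deviation `noise_sd`; voxels
outside all regions are pure noise. Because the latents are exactly
unit-variance, the population seed-to-voxel correlation for a
single-network voxel is the closed form

    rho = a sigma_s / sqrt(a^2 sigma_s^2 + sigma^2),

which the recovery tests check directly (a = sigma_s = sigma = 1 gives
rho = 1/sqrt(2) ~ 0.707). In the closed-form checks the latent signal
itself serves as the noiseless seed time course; in pipeline-level phantoms
seeds are multi-voxel regions with strong loadings, whose mean time course
approximates the latent to within a fraction of a percent.

The low-pass filter is a zero-phase FFT brick wall: every discrete-frequency
bin above the cutoff is zeroed. Its stopband attenuation at removed bins is
total (the only residual energy is spectral leakage of off-bin components;
an 0.15 Hz sinusoid sampled at TR = 3 s retains < 5% of its variance), the
DC component is preserved exactly, and the operation is exactly linear.

What the phantom does **not** emulate: hemodynamic response shape,
physiological noise, head motion, spatial smoothing, or spatial noise
autocorrelation — noise is i.i.d. per voxel per time point. Passing
recovery tests therefore demonstrate correctness of the statistical chain
under the stated generative model, not robustness to the artefact structure
of real fMRI. One run per subject is generated; multi-run acquisition would
be combined by averaging Fisher-z maps across runs.

## Seed-to-voxel mapping and thresholding

Per subject, the seed time course is the arithmetic mean of the seed
voxels' series, and the r-map its voxelwise Pearson correlation. Group
inference Fisher-z transforms each subject's r-map (|r| = 1 clamped to
1 - 1e-7) and applies a voxelwise one-sample t test of the z values against
zero, df = n - 1. An alternative scheme — average the Fisher-z maps across
subjects, back-transform, and convert with t = r sqrt(n-2)/sqrt(1-r^2) —
is available behind `AnalysisConfig.group_stat="average_r"`; the
per-subject t is the default because it is the standard construction for
normative-connectome group maps.

The |t| cutoff defaults to the published whole-brain value 5.1; setting
`t_threshold: null` derives it as the two-tailed Bonferroni quantile
t(1 - alpha/(2 m), df) for m = `brain_voxel_count` tests (default 67 000,
approximately an in-brain 3 mm grid; at alpha = 0.05, df = 999 this gives
4.98, consistent with 5.1). Zero-variance voxels yield r = 0 with a QC
count rather than an error, so masked or edge regions never abort a run.
Family-wise error control is validated on all-null phantoms; suprathreshold
voxels are counted outside the seed itself, since seed-member voxels
correlate with their own mean by construction.

## Outcome pooling and efficacy map

Per-study percent seizure reductions are pooled into one mean per target by
a simple (unweighted) average; study medians are accepted as means without
distributional correction, and a patient-count-weighted average is
available as `pooling_weighting="by_n"`. The published review reports only
per-target summaries (23 ANT studies, 330 patients, mean 59.6%; 8 CMT
studies, 90 patients, 69.3%; 13 HC studies, 107 patients, 64.6%); the
bundled `synthetic_study_records()` list is a deterministic synthetic
stand-in constructed to match those summaries exactly under simple
averaging, which is why simple weighting is the default convention.

The efficacy map assigns each binarised target map its pooled seizure
reduction as a weight and combines voxelwise. Where maps overlap, the
default `mean` mode divides the weighted sum by the number of covering
maps, keeping values interpretable as percent improvement (a voxel covered
by all three established targets scores (59.6 + 69.3 + 64.6)/3 = 64.5);
`sum` mode reports the raw weighted sum.

## Overlap nodes

The common network territory is the voxelwise AND of the binarised target
maps. Discrete nodes are maximal connected components under a 26-neighbour
3-D connectivity (6-neighbour available), dropping components below
`min_component_voxels` (default 5, ~135 mm^3 at 3 mm) to suppress speckle
while keeping small subcortical nodes. Labelling is deterministic:
descending size, ties broken by lexicographically smallest voxel index.
Seed regions and overlap components are merged into one disjoint atlas with
seeds taking precedence over component voxels they overlap — seeds are the
anchored anatomy. Regions enter the graph at native size; no size
normalisation across regions is applied.

## Graph analysis

The region-by-region matrix is built from per-subject Pearson correlations
of region-mean time courses, Fisher-z averaged across subjects and
back-transformed. Hierarchical clustering uses complete linkage on
Euclidean distances between matrix rows (the default of the heatmap tools
commonly used for such matrices), cut at `n_clusters` (default 5).

The graph keeps an undirected edge for every pair with r > 0, weight r;
anticorrelated pairs carry no edge, following standard practice for
weighted brain-graph analysis. The display cutoff (default 0.3; 0.2 is the
other value in circulation for this analysis) flags edges for rendering
only and never affects computation. Shortest paths use edge length 1/weight
(`one_minus` gives 1 - weight); betweenness is reported unnormalised as
pair counts with fractional credit over tied shortest paths, closeness as
(n_c - 1) over the summed shortest distances within a node's component
(disconnected graphs are analysed per component and flagged). Both are also
reported as z-scores, (x - mean)/sample sd, which makes the normalisation
convention irrelevant for rankings; a constant vector z-scores to zeros.

Correctness of both centralities is established against an exhaustive
brute-force enumeration of all simple paths on random connected weighted
graphs with up to 8 nodes — an oracle that shares no code with the
shortest-path implementation.

## Pipeline, determinism, problem sizes

`run_pipeline` executes seedmap -> efficacy -> overlap -> graphnet, writes
NIfTI volumes, delimited-text tables, an edge list and GraphML, and records
a YAML run manifest (config echo, input checksums, per-stage outputs and QC
flags). Grids must match exactly in shape and to 1e-4 mm in affine; there
is no resampling. All randomness flows from the phantom's `rng_seed`, so a
fixed seed and config reproduce outputs bit-identically; a completed run
whose fingerprint (config + input checksums) matches is returned from the
manifest rather than recomputed. Caching is at run granularity — per-stage
resume was not worth the complexity in a single-process pipeline.

Validation problem sizes were chosen so the whole suite runs on one CPU in
minutes: null-control family-wise error uses 200 phantoms of 12^3 voxels
with 50 subjects; closed-form recovery uses 100 subjects; hub recovery 50
phantoms of 6 regions with 20 subjects; overlap recovery one 14^3 phantom
with 100 subjects at planted rho = 0.5; the centrality oracle 500 random
graphs. These are deliberately smaller than a real 1000-subject connectome
at ~2 mm resolution; the statistical chain is scale-free, but real-data
effect sizes and dependence structure are not represented.

## Known limitations

- The phantom's noise is spatially and temporally white; real resting-state
  noise is neither, so the Bonferroni count on real data must reflect the
  effective number of independent tests chosen by the analyst.
- Anatomical node identification (assigning overlap components to named
  structures) is out of scope; components are labelled by size order.
- The per-study outcome list is synthetic (see above); only the per-target
  pooled summaries are anchored to published values.
- No nuisance regression, motion handling, smoothing or registration:
  inputs must already be on a shared grid.
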