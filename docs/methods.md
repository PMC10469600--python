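# Methods

This note documents the procedures the package implements, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Experimental design enumeration

A reporter panel is a table of genes, each tagged with the phenotype its
promoter reports on and an optional exclusion flag. The built-in panel has
15 *B. subtilis* genes spanning specialized metabolites, matrix, motility,
sporulation, competence, protease and cannibalism programs; *sunA*
(sublancin) is excluded by default because its reporter strain alters
colony morphology, leaving 14 active genes. The loader ships an alias map
(`aprF→aprE`, `comG→comGA`, `comQ→comQX`, `skf→skfA`, `skfAA→srfAA`)
normalizing alternate spellings seen in strain tables.

The dual-reporter design over n active genes is all n(n−1)/2 unordered
pairs, each built in two color orientations (which gene drives YPet vs
mTurq), i.e. n(n−1) strain configurations — 91 pairs and 182 strains for
n = 14. Ordering is deterministic: pairs lexicographic by gene name,
orientation 1 assigning the lexicographically smaller gene to YPet.

## Colony radial profiling

**Masking.** Both agar and colony are near-uniform in brightfield, so the
Laplacian-of-Gaussian response (σ = 2 px by default) concentrates at the
colony edge. The |LoG| response is thresholded by Otsu's method (avoiding
a magic constant), closed morphologically and hole-filled to a solid
footprint, then trimmed to the LoG **zero crossing**: the signed response
flips sign exactly at the intensity step, so band pixels carrying the agar
side's sign are removed. This places the boundary at sub-pixel accuracy
regardless of band width and works for either contrast polarity (the agar
side is identified by comparing mean intensities). The largest 8-connected
component ≥ 100 px is kept; smaller specks raise `NoColonyFound`, as do
constant images.

**Radial coordinate.** Every frame pixel gets
p = 100·‖x − c‖/R̄ where c is the mask centroid and R̄ the mean Euclidean
distance from c to the traced boundary, so the *average* colony edge sits
at 100% (an irregular boundary spans values below and above 100).
Distances for all pixels are computed up front; at typical frame sizes
(≤ 1388×1040) the full field is a few MB and simpler than restricting to
a colony margin.

**Binning.** Distances are rounded to the nearest multiple of the bin
resolution and each channel's mean is taken per unique rounded value.
The default resolution is 1% of radius — equivalently, rounding the
edge-normalized distance ratio to two decimals; finer grids would leave
most bins empty at practical image sizes. Bins beyond 120% are dropped;
keeping 100–120% reports the background fluorescence just beyond the
colony edge, a useful per-image reference level.

**Normalization.** Profiles can be displayed on a shared axis by dividing
each channel by a constant. The default is the channel's peak bin mean
over bins ≤ 100% (peak inside the colony = 1.0); a fixed per-channel
constant is accepted for cross-image comparability. The constant is
always recorded with the profile.

## Flow-cytometry gating and co-expression

**Gates.** The detection limit per channel is the empirical quantile
(default 0.999) of a non-fluorescent wild-type control, computed as an
order statistic (inverted-CDF definition), so gates are always observed
intensities. Controls under 1,000 events are rejected. No compensation or
transform is applied before gating: the YPet/mTurquoise2 pair has minimal
spectral overlap and thresholding is scale-equivariant. The quantile is a
config parameter; sensitivity analysis is one config change.

**Quadrants.** An event is positive in a channel iff its intensity is
*strictly* above the gate; an event exactly on the threshold is negative.
The tie rule is load-bearing because empirical quantiles land on observed
values. The four populations are neither / mTurq-only / YPet-only / both;
counts always sum to n. Samples under 24,000 events are summarized but
flagged `qc_pass=False`.

**Aggregation.** Per-gene percent expressing uses YPet only
(100·(YPet-only + both)/n), averaged over every strain in which the gene
carries the YPet reporter, with the min/max range reported — YPet's
sensitivity is superior to mTurq against cellular background. The
pairwise co-expression matrix entry is the maximum of 100·n_both/n over
the pair's two orientations (controlling for fluorophore expression-level
differences); provenance records both orientations' values and which
supplied the max. Unmeasured pairs are missing (NaN), never zero.

**Relationship labels.** A pair is classified from the coverage
c = p_both/min(pA, pB) and the independence ratio r = p_both/(pA·pB):
`distinct` if c < 0.1 (or pA·pB = 0), else `anticorrelated` if r < 0.5,
else `overlapping` if c > 0.8, else `partial`. Coverage is tested before
the ratio so a vanishing overlap reads as distinct rather than
anticorrelated. The category names are standard; the cutoffs are this
package's defaults and live in configuration, not code.

## Voxel-wise Pearson correlation

Stacks are tiled into cubes of 10 px per side (≈ 0.80 µm at the default
0.08 µm/px; both configurable). Trailing partial voxels are dropped
rather than padded — correlations over unequal pixel counts would not be
comparable — and the drop is visible in the output grid. Per voxel,
r = Σ(I₁−Ī₁)(I₂−Ī₂) / √(Σ(I₁−Ī₁)² Σ(I₂−Ī₂)²) over its 10³ pixels, placed
at the voxel's arithmetic centroid (reported in pixels and µm).
Correlations use raw intensities with no background subtraction.

Exclusions: a voxel is `no_fluorescence` when fewer than 10% of its
pixels exceed the background threshold in at least one channel (a voxel
where only one reporter fluoresces still carries usable signal);
`constant_channel` when either channel has zero variance. The background
threshold defaults to mean + 2 sd of a user-designated no-signal region.
The excluded set grows monotonically with the threshold. Single-plane
(2D) inputs are accepted; voxels then become in-plane squares.
Cross-sections extract one voxel plane with NaN at exclusions and are
rendered with a diverging scale (yellow = +1, dark blue = −1), axes
annotated Center → End.

## Synthetic data

The generators emulate the statistical structure each pipeline assumes,
with ground truth always returned alongside the data, and all randomness
driven by a spec seed (same seed → bit-identical output).

- **Colonies**: a disk of mean radius R with low-order Fourier boundary
  perturbation (modes 2–5, peak amplitude 5% of R by default — real
  colonies are not circles); brightfield contrast agar 30,000 / colony
  12,000 counts; fluorescence = background + f(p) inside the footprint,
  where f is uniform, center-peaked, edge-peaked, or a Gaussian ring in
  percent-of-radius; additive Gaussian noise (default sd 100 counts);
  quantized to unsigned 16-bit. The default frame is 1388×1040 px,
  matching stereomicroscope acquisition; tests and the acceptance script
  use 256–512 px frames, which exercise identical code at lower cost.
  Ground truth includes the footprint mask, the percent field and the
  noise-free binned profile.
- **Stacks**: pixelwise bivariate draws ch₁ = μ₁+σ₁z₁,
  ch₂ = μ₂+σ₂(ρz₁+√(1−ρ²)z₂) realize an arbitrary per-pixel target
  correlation field ρ(z,y,x), with an optional near-zero background
  region. Marginals are Gaussian (truncated at zero) rather than
  log-normal: the analysis is specified on the raw intensity scale, and a
  nonlinear marginal transform would not preserve the target ρ the
  recovery tests compare against. Stacks stay floating-point in memory so
  exact-correlation constructions remain exact; they are quantized to
  16-bit on TIFF export.
- **Flow**: a four-component mixture over the quadrants with per-channel
  log-normal intensities (flow distributions are heavy-tailed): off-state
  location ln(150), log-sd 0.35, with positives shifted by ln(10) — a 10×
  brighter positive cluster, comfortably separable yet overlapping enough
  for the tie and threshold rules to matter. True cluster labels ride
  along with each sample. Event counts default to 24,000 per strain and
  100,000 for controls.

Not emulated: optics (PSF, attenuation with depth), spectral overlap
(empirically negligible for this fluorophore pair), cell-scale intensity
texture, scatter parameters and doublets in flow, or biofilm growth
itself. Passing recovery tests therefore demonstrates correctness of the
measurement pipeline, not robustness to those real-data effects.

## Orchestration

A YAML config names the panel, inputs and parameters; all defaults (1%
bins, 120% cutoff, 0.999 gate quantile, 24,000-event floor, 10 px voxels)
are configuration, never hard-coded in the stages. Unreadable inputs are
skipped per-sample with a reason in the run report; the run fails only
when nothing succeeds. Deterministic stages write byte-identical CSVs on
rerun. Every figure (heatmap ordered by panel gene order, profile panels
on the shared 0–120% axis, correlation sections on the diverging scale)
is a view of numbers that also exist in a CSV.

## Problem sizes and limitations

The test suite and acceptance script run on one CPU in well under a
minute using 300–384 px colony frames, 20×50×50-voxel stacks and
24,000-event flow samples — sizes at which binomial/Monte-Carlo error
bands (3 SE) are tight enough to detect real defects. Known limitations:
one colony per image (no multi-colony detection), no flat-field
correction, no mixture-model gating (control-threshold gating only), no
image registration (channels are assumed co-registered), and FCS binary
files are not parsed — flow input is CSV event tables.
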