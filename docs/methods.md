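# Methods

This note documents the measurement model implemented by `nucleopunct`,
the choices made where the underlying workflow left them open, and what
the synthetic benchmark does and does not establish.

## The measurement chain

The pipeline quantifies punctate fluorescence signals inside cell
nuclei after non-viral plasmid (pDNA) delivery: Galectin-9 (Gal9)
puncta, pDNA hybridization signals, and SC35-marked nuclear speckles,
plus the object-based colocalization between them.

**Nucleus segmentation.** Nuclei come from the Hoechst channel:
Gaussian smoothing (default sigma 2 px), a global Otsu threshold, hole
filling, and 8-connected labelling. Objects touching the image border
are flagged and excluded from all downstream counts. Each object is
gated on equivalent diameter (default 150–600 px, inclusive; a
configuration switch interprets the window as area instead, since pixel
windows of this kind are quoted both ways in practice) and on form
factor 4πA/P² (default 0.70–1.00, inclusive). The form-factor gate is
what removes out-of-focus, jagged, and touching/merged nuclei — merged
blobs are deliberately *not* split by watershed; they fail the
circularity gate instead. This is a documented limitation: in fields
with many abutting nuclei the gate discards rather than rescues them.

**Perimeter estimator.** The form factor uses the 4-direction Crofton
perimeter (as implemented in scikit-image). The common weighted
boundary-pixel estimator biases the perimeter of rasterized disks high,
which pushes disk form factors to ≈0.90 and would make a 0.98-level
circularity check unattainable for genuinely circular objects. The
Crofton estimator is unbiased for disks across the 150–600 px range
(values land at 1.00 ± 0.01 and are clipped at 1.0), scores a 3:1
ellipse at ≈0.67 (below the 0.70 gate), and agrees with the analytic
4πA/P² of a 4:1 ellipse (Ramanujan perimeter) to within 0.01.

**Ring partition.** Each retained nucleus is split into an *edge* band
and an *inner* core by the Euclidean distance transform: inner pixels
are those whose distance to the boundary exceeds `edge_fraction`
(default 0.2) of the maximum interior distance. For a disk this puts
1 − (1 − f)² of the area in the edge band. Edge and inner tile the mask
exactly by construction; `edge_fraction = 0` makes the whole nucleus
inner.

**Intensity thresholds.** The original workflow thresholded puncta
manually against untransfected controls. Here the rule is
reproducible: pool the non-nuclear pixels of the channel over the
negative-control stacks (nuclear pixels masked by Otsu on the control's
Hoechst plane) and set threshold = mean + k·SD with k = 3 by default.
The SD is the population SD — this is a calibration constant, not an
inference. A fixed manual threshold per channel remains available in
the configuration. Background subtraction is pixelwise
max(plane − mean, 0); detection thresholds the *raw* plane at the model
threshold and additionally gates each component's mean raw intensity
against the same threshold, so the subtracted plane is available for
export but never changes which objects are found.

**Punctum detection.** Pixels strictly above the threshold form
8-connected components; components are kept when their equivalent
diameter (4A/π)^½ lies inside the channel's inclusive window — pDNA
4–40 px, Gal9 0.5–2 μm (≈10.4–41.7 px at the default 0.048 μm/px),
SC35 0.5–3 μm. The SC35 window is this package's choice: nuclear
speckles are conventionally sub-micron to a few microns across, and the
source workflow treats SC35 as a *signal* (see below), so the window
only matters in punctum-pairing mode. Overlapping spots that merge into
one out-of-window component are an accepted failure mode at high
density; no per-spot watershed is attempted. Each punctum is assigned
to a nucleus and region (edge / inner / cytoplasm) by its centroid —
the partition sets are disjoint, so the assignment is unambiguous.

**Colocalization.** Gal9 is always the reference: a Gal9 punctum is
colocalized with a partner channel when the partner signal covers at
least 30 % of the *Gal9* punctum area (inclusive, configurable). The
partner signal is by default the thresholded mask of the partner
channel; a stricter punctum-vs-punctum mode (union of the partner's
detected in-window puncta) is provided. Triple colocalization is the
conjunction of the pDNA and SC35 calls. The per-condition summary
reports the mean ± SEM of the per-cell colocalized-punctum fraction
(cells with zero Gal9 puncta cannot contribute a fraction; they are
skipped and surfaced in a QC column), plus the fraction of cells with
at least one colocalized punctum as a secondary metric, since published
"% colocalization" figures are quoted under both conventions.

**Flow metrics.** Events are gated by inclusive rectangular
forward/side-scatter windows. eTE is the percentage of gated events
with green intensity strictly above the positive cut; expression level
is the geometric mean of green intensity among positives; apparent
expression is (eTE/100) · expression · viability, with eTE entering as
a fraction so fold-comparisons are scale-consistent (the three factors
are always reported alongside). The positive cut defaults to the
99.5th percentile of an untransfected control's green intensities.
Cell-cycle fractions partition an EdU histogram at two thresholds:
G0/G1 ≤ low < early S ≤ high < late S.

**Statistics.** Two groups: Mann–Whitney U, exact two-sided p (from
the exact U null distribution) when n·m ≤ 200 and the pooled sample is
tie-free, otherwise the normal approximation with midrank-tie and
continuity corrections; the result records which path ran. Three or
more groups: one-way ANOVA, then Tukey HSD for every pair regardless of
the ANOVA outcome. Outliers: a single, non-iterated pass removing
values more than two *sample* (n−1) standard deviations from the group
mean — the sample-SD convention is pinned by tests. Summaries are mean
± SEM (sample SD/√n; blank at n = 1). Stars use strict inequalities at
0.05 / 0.01 / 0.001 / 0.0001. All-zero within-group variance with
unequal means yields a flagged degenerate ANOVA result rather than an
exception.

## The synthetic benchmark

Because the raw microscopy and flow data behind the original study are
not deposited, correctness is established by parameter recovery on
synthetic scenes with exact ground truth.

**What a scene contains.** Non-overlapping rotated ellipses (nuclei)
rejection-sampled away from the border; per-nucleus punctum counts
drawn Poisson with mean proportional to nucleus area (normalized to the
configured means at the mid-range diameter — uniform means would
over-crowd the smallest nuclei); puncta placed on edge/inner partition
pixels with a configured edge-placement probability and hard minimum
separations (2·PSF σ + 3 px between mask edges) so that blurred masks
of distinct objects neither merge within a channel nor touch across
channels. A planted colocalization pair places a partner disk at the
analytic lens-area offset for a target overlap drawn U(0.6, 0.9)
(partner radius raised to the Gal9 radius when the target is otherwise
unreachable), then backs the offset off in half-pixel steps until the
rasterized pre-blur overlap also meets the target — so the recorded
planted fraction is a guaranteed lower bound. Rendering: hard disks /
filled ellipses → Gaussian PSF blur (default σ 1.5 px) → constant
background (100) + zero-mean Gaussian noise (SD 10). The default
punctum amplitude of 200 gives a peak SNR of 20. A matched negative
control renders the same nuclei with empty puncta channels.

**Default conditions.** 2048×2048 px at 0.048 μm/px (chosen so the
600 px size bound corresponds to ≈29 μm), 10 nuclei of 10–16 μm
equivalent diameter with axis ratios 1–1.5, ~12 Gal9, ~12 pDNA and ~6
SC35 puncta per nucleus, planted diameters inside each channel's
detection window. Recovery/acceptance runs use 20-nucleus 2560² scenes
so each carries ≥200 Gal9 puncta — the scale of the published
per-figure cell counts (n ≈ 20 cells per condition). These problem
sizes keep a full benchmark run to a few seconds per scene.

**What the generator does not emulate.** Poisson (shot) noise and
camera gain, realistic PSF tails, intensity heterogeneity within and
between puncta, diffuse nucleoplasmic Gal9 background, touching
nuclei, out-of-focus blur gradients, and autofluorescence texture.
Passing recovery tests therefore demonstrates that the measurement
chain is correct *given its model assumptions* (well-separated,
disk-like objects over additive Gaussian noise), not that it is robust
to every pathology of real micrographs. The additive-Gaussian choice is
deliberate: it is sufficient to stress thresholding, and the noise
model is a single isolated function for users who need more.

**Numerical conventions.** Coordinates are 0-based (row, col); masks
are pixel-centre rasterizations; all size gates and the 30 % rule are
inclusive at both bounds; intensities are never rescaled on I/O;
thresholds use strict `>`; every random draw flows through one
`numpy.random.Generator` seeded explicitly, and reruns are bit-identical
(asserted in tests down to the bytes of the output CSVs).

**Degenerate inputs.** Blank or constant planes segment to zero nuclei
(not an error); empty detection results are valid; a scene whose
objects cannot be placed in 10 000 attempts fails loudly rather than
silently biasing density; empty groups/tables raise `ValueError`s at
the statistics and flow layers.

## Reference checks

The independent oracles used in the test suite: the circle–circle
lens-area formula against pixel-counted overlap; Ramanujan's ellipse
perimeter against the Crofton form factor; the annulus identity
1 − (1 − f)² for the ring partition; full enumeration of all label
assignments for the exact Mann–Whitney p (exhaustive for n, m ≤ 5);
the hand-computed F = 3.0 on (2, 6) df for the three-group worked
example; and binomial recovery of the planted positive fraction for
eTE (±1 percentage point at 10⁵ events).
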