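# Methods

## Phantom model

A phantom is a 2-D field of areal concentrations (µg/cm²) on a raster grid
(default 100 nm pitch, 200 ms dwell). The filament is a horizontal chain of
axis-aligned elliptical vegetative cells (semi-axes 3.0 × 2.3 µm) touching
at septa with a 0.2 µm gap, plus one round heterocyst of equal area placed
mid-chain. Each cell carries a uniform cytosolic concentration per element
and a Cl-bearing envelope, modeled as the band between the cell ellipse and
the same ellipse grown by the envelope thickness (345 nm by default).

Cluster families, all placed by rejection sampling inside their cell with a
≥ 2-px separation between regions (largest families placed first, with a
per-cell restart if a configuration cannot be completed):

* **P/K cores** (polyphosphate-body analogues): filled disks with K and P
  raised above cytosol; equivalent-diameter distribution 0.99 ± 0.48 µm.
  1–2 per vegetative cell sit peripherally and are wrapped by a **Ca-rich
  disk** of 1.8× the core area at 1.337 µg/cm² total Ca; another 1–2 sit
  interior with a small **Fe satellite** — an irregular aggregate grown by
  seeded Eden-type random-walk accretion, confined to the core's exclusion
  disk, with its own area distribution (0.050 ± 0.095 µm²).
* **Ca-only disks** (0–1 per vegetative cell, area 0.310 µm² mean) and
  **Fe-only blobs** (1–2 per cell, both cell types, same Fe area
  distribution). The heterocyst never receives P/K clusters.

Size distributions are truncated normals (truncation at 2 px, and at an
upper bound that keeps regions placeable inside a cell), *moment-matched*:
the underlying Gaussian location is solved numerically so the
post-truncation expectation equals the nominal mean. For the Fe areas the
naive truncated normal would realize a mean of ≈ 0.11 µm² instead of
0.050 µm²; moment matching keeps the generator's ground truth equal to its
nominal parameters. Distributions are therefore right-skewed for Fe, which
matches the broad dispersion such clusters show.

The registry records every painted region (pixels, area, per-element mean
concentration, family, cell); an analytic mass ledger accumulated during
painting lets tests assert exact mass conservation of the maps.

### Forward models

*Count maps*: counts ~ Poisson(conc × sensitivity(Z) × dwell), with
sensitivity(Z) = flux_scale · exp(0.05·(Z−19)) counts per (µg/cm²·ms) — a
smooth, injective stand-in for the fluorescence-yield × detection-efficiency
product that a real instrument calibrates empirically.

*Spectra*: per pixel, expected counts per 20 eV bin over 0–10 keV are a
smooth exponential continuum plus, per element, an EMG at the Kα energy
with area conc·sensitivity·dwell and a Kβ companion at the catalog ratio;
Poisson noise on top. The same unit-area profiles serve simulation and
fitting, so quantification accuracy is limited by noise, stripping and
overlap — not by shape mismatch (a deliberate property of a self-consistency
phantom; see Limitations).

## Spectral quantification

The EMG line shape is f(x) = (A/2τ)·exp(σ²/2τ² − (x−µ)/τ)·
erfc((σ/τ − (x−µ)/σ)/√2), normalized to area A, evaluated in the
numerically stable erfcx form. Defaults σ = 65 eV, τ = 50 eV, shared by all
lines of a spectrum (detector properties); the Kα/Kβ energies and Kβ/Kα
area ratios for Z = 13–30 ship as an editable catalog.

Background is estimated by SNIP-style peak stripping: in the √counts
(variance-stabilizing) domain, each bin is clipped to the mean of its
symmetric neighbours with a window decreasing linearly from 40 bins to 1
over 24 passes. Clipping is restricted to bins where the full window fits;
clamped-edge clipping would erode monotone spectrum ends and break
idempotency on peak-free inputs.

Fitting solves per-pixel amplitudes of the unit-area element profiles by
least squares (nonnegative for single spectra; for cubes, one shared normal
system solved for all pixels with negative amplitudes clamped at zero).
Three smooth nuisance columns (constant, linear, nominal continuum shape)
absorb the stripping residual: min-clipping estimators sit slightly below
the true noise floor of counting data and would otherwise bias every peak
area high by a roughly uniform offset (observed at ≈ +0.03 µg/cm²-equivalent
before the fix). Sensitivities come from fitted areas of a thin-film
standard with certified densities — sensitivity = area/(density × live
time) — with log-linear interpolation in Z for uncalibrated elements. The
default standard (S/Ca/Fe/Cu) is synthetic: a real analysis must supply its
own certified composition, which is why it is an input everywhere.

## Segmentation

All thresholding operates on raw concentrations (display percentile
clipping — 98th, or 99.9th for cluster emphasis — is export-only), making
the stage equivariant under positive rescaling.

`kmeans_1d` computes the *globally optimal* two-class split by scanning all
ordered splits of the sorted values with prefix sums; the optimum is itself
a Lloyd fixed point, and a property test checks equality with an exhaustive
oracle on every random instance. For k > 2, Lloyd iterations run from
deterministic initials (interior percentiles plus the maximum, anchoring
the top class on the bright tail).

Intensity maps of these filaments are **trimodal**, not bimodal: off-cell
background, cytosol, clusters — and within the cytoplasm, vegetative vs
heterocyst cytosol (Fe differs 3.5-fold). A plain 2-class split therefore
mis-segments: on the K field it separates clusters from everything else
(cytoplasm Jaccard ≈ 0.1), and on in-cell Fe it can classify the entire
heterocyst as one giant cluster. Both stages consequently use a 3-class
split: the cytoplasm threshold is the midpoint of the two *lowest*
centroids; the cluster threshold takes the cluster side of the *largest
centroid gap* (if the top two centroids are mutually closer than to the
bottom one, both upper classes are clusters — the bimodal case whose bright
mode was split). With these rules the cytoplasm mask reaches Jaccard ≈ 1.0
against truth and cluster recovery ≈ 0.8–1.0 per region.

The fixed-threshold alternative defaults to cytosol mean + 3 SD (cytosol =
cytoplasm minus the k-means cluster class, so clusters do not inflate the
estimate). The consensus core is the intersection of the two methods'
masks; the symmetric difference is reported as the boundary-uncertainty
band. ROIs are 8-connected components (minimum 2 px) labeled in row-major
discovery order with tight half-open bounding boxes.

## Cluster and group statistics

Areas are n_pixels × (step/1000)² µm² (0.01 µm² per pixel at 100 nm);
equivalent diameter 2·√(A/π). Region concentrations subtract the median of
the off-cytoplasm pixels (the ice/substrate blank) and clamp at zero.
Per-ROI Pearson correlations use all pixels of the ROI's bounding box so
anti-colocalization remains detectable; a pooled all-ROI reduction is
emitted alongside, since either convention is defensible. Overlap is
reported both as |A∩B|/min(|A|,|B|) (primary — reads through systematic
size differences between elements) and Jaccard. Family classification is
purely geometric: a P/K core requires ≥ 0.5 overlap_min against both the P
and K cluster masks (per connected component, so a small Fe aggregate fully
inside a large core still scores 1); Ca/Fe association uses the same
criterion, Ca winning ties as the geometrically larger wrapper. No chemical
identity is implied by the tags.

t-tests: pooled-variance Student's form is the default, Welch by flag; the
one-sided p (alternative mean(a) > mean(b)) is emitted with the two-sided
one, since "not significantly larger" phrasing implies a one-sided
question. Both variants are validated against a 10⁴-permutation oracle.
Violin summaries use linear-interpolation quartiles and Q1/Q3 ∓/± 1.5×IQR
fences.

## Tomography

Scan rows are independent 2-D problems (as acquired by raster-scanned XRF
tomography), reconstructed slice by slice without 3-D regularization. The
projector is pixel-driven with bilinear detector interpolation,
materialized as a sparse matrix; the back projector is its exact transpose
(adjoint identity holds to ~1e-15), and per-pixel weights sum to 1 whenever
the projection lands on the detector, giving per-angle mass conservation —
note the detector must span the slice diagonal for that to hold for
off-center mass. SIRT uses inverse row/column sums as weights, masking
zeros, with optional (default-on) nonnegativity clamping; 100 iterations by
default. The missing-wedge preset is 51 equally spaced angles from −82° to
70° (3.04° spacing), i.e. a 28° wedge: disk-phantom correlation drops from
≈ 0.99 (full 180°) to ≈ 0.97–0.99 with mild directional streaks, and a
Ca shell around a K core remains radially resolved.

## Problem sizes and defaults

The preset filament is 7 cells on a 96 × 480 field (100 nm pixels): large
enough for ~50 cluster regions and clean off-cell statistics, small enough
that the full spectral route (46k pixels × 500 bins) runs in well under a
minute. Pooled size statistics use 20 independent filaments (≈ 360 P/K
cores, ≈ 390 Fe clusters). Tomography demonstrations use 64×64 slices.
Cytosolic S, Cl and P levels and all in-cluster P/K/Fe boosts are free
choices at plausible trace levels (the study constrains only K/Ca/Fe
cytosol, Ca-cluster concentration, and the size distributions); the Ca
cluster concentration is deterministic at its nominal mean, with per-pixel
spread arising from counting noise rather than a per-cluster draw, so that
fixed-seed recovery measures pipeline fidelity rather than sampling noise.

## What the phantom does and does not show

Passing recovery tests shows the chain is *self-consistent and unbiased
under its own forward model* at realistic counting statistics. Real data
additionally contain detector artifacts the phantom omits (escape and
pile-up peaks, L-lines of heavy trace elements, self-absorption in thick
ice, scan jitter and drift), non-uniform cytosol, partial-volume boundary
pixels (clusters here are rasterized as whole pixels), and cell-to-cell
biological variability beyond the two cell types. Fixed Kβ/Kα ratios and a
single (σ, τ) per spectrum are assumptions real fits share, but their
misspecification — invisible here by construction — adds systematic error
on real spectra. Tomography omits self-absorption of the fluorescence
signal, the dominant artifact source in real XRF nanotomography of
low-energy lines; low-count behaviour is characterized, not corrected.
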