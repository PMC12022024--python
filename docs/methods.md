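# Methods

This note documents the models, procedures and numerical choices behind
`paintplus`, and what the synthetic-data generator does and does not
emulate.

## Multi-cycle acquisition model and registration

The pipeline models a two-cycle staining–elution screen: cycle 1 carries
DNA, RNA and Mito channels; after elution, cycle 2 carries ER, Golgi,
Actin and Lyso, with the Mito signal persisting into cycle 2 as the shared
reference. Cycle-2 stacks are aligned to cycle 1 on that reference, in two
modes:

* **Translation-only** (`register_translation`): integer shift maximizing
  the normalized cross-correlation (NCC) over the image overlap, default
  search window ±50 px. The NCC over every candidate shift is computed
  exactly with six FFT correlations (the sliding sums of a, b, ab, a², b²
  and the overlap size), so the search equals an exhaustive scan at FFT
  cost; a brute-force implementation is retained as the reference oracle.
  Optional quadratic peak interpolation provides subpixel shifts behind a
  flag; it is off by default because the acquisition contract is integer
  lateral shifts.
* **Similarity** (`register_similarity`): coarse-to-fine grid over scale
  (±5%, coarse step 1%) and rotation (±5°, coarse step 1°), translation
  solved by NCC at each grid point; the coarse pass runs on 2× downsampled
  images and the refinement pass at full resolution with steps of 0.25%
  and 0.25°. Translations up to 50% of the image width are admitted.

NCC is computed on mean-subtracted values over the overlap only, making it
invariant to intensity offset and gain. QC is a step function of the NCC:
≥ 0.8 accepted, [0.5, 0.8) flagged for manual review, < 0.5 excluded; the
thresholds are "below x" rules, so the boundary values are kept. Applying
a transform fills uncovered pixels with zeros and moves the valid-area
mask with the same parameters (nearest-neighbour for the mask); integer
translations use exact array shifts, everything else bilinear warping.
Trimming crops both cycles to the bounding box of the mask intersection.
Coordinates are (row, col), 0-based; a reported shift is the cycle-2 →
cycle-1 displacement. Per-field results are independent of processing
order.

The two translation bounds (50 px for the on-instrument mode, 50% of the
width for the stitcher) are deliberately exposed as two modes rather than
reconciled into one.

## Segmentation and cell regions

Nuclei: Gaussian presmooth (σ 1), Otsu threshold, hole filling,
distance-transform watershed seeded at local maxima (minimum peak distance
7 px), minimum nucleus area 50 px². Cells: marker-controlled watershed on
a merged channel (pixelwise max of min-max-scaled RNA, Mito cycle 1 and
Mito cycle 2 — the merge operator is this package's choice, as is the
band geometry below), masked to the Otsu foreground; each cell keeps its
seed nucleus's label; nuclei outside the foreground are dropped with a
warning. Border-touching cells are flagged and excluded from feature
extraction.

Derived regions: cytoplasm = cell ∖ nucleus; ring = a 3-px dilation band
just outside the nucleus clipped to the cell; membrane = a 2-px erosion
band just inside the cell boundary. Nucleolus spots are detected in the
RNA channel as local maxima of a difference-of-Gaussians band-pass (σ 1.0
/ 4.0) inside the 1-px-eroded nucleus, thresholded 20% of the in-nucleus
dynamic range above the in-nucleus median; pixels outside the nucleus are
filled with the in-nucleus median before filtering so the nuclear envelope
itself produces no band-pass response. Spot masks are the watershed basins
of the maxima. On synthetic fields at the default signal-to-noise the
exact-count accuracy exceeds 95%.

Illumination correction divides by a quadratic polynomial surface fitted
to a lightly denoised copy of the image and rescales to preserve the
global mean; a low-order surface captures lamp gradients and vignetting
and, unlike a large Gaussian, has no edge bias and cannot imprint
individual cells.

## Feature catalog

Features are named `<channel>_<region>_<family>_<stat>`. Per configured
channel × region: intensity mean/median/sum/sd/q05/q95; shape
area/perimeter/roundness (4πA/P²)/axis ratio on the nucleus and cell
masks; texture as grey-level co-occurrence contrast, correlation and
entropy (distance 1, 4-direction average, 32 levels, quantized over the
in-mask range) plus gradient energy; position centroid and nucleus–cell
displacement. The catalog is deliberately compact (~120 columns with the
default config) and versioned through the config; the column set depends
only on the config, never on the data. Mito features of a registered
stack come from the cycle-2 Mito image (the cycle-1 Mito may carry
cross-excitation from the RNA stain).

## Standardization and gating

Cell-level robust z uses the plate's pooled solvent-control cells; the
1.4826 factor appears once, in the denominator — a dedicated test guards
against applying it twice. Features with zero control MAD on any plate
are removed (and logged). Well profiles are per-well medians of cell
z-scores with no further rescaling. Well-population features are
standardized at the well level only: the absolute cell number with the
robust z form against control wells, the three nucleolus-count fractions
(1–2, 3–4, 5+) with a plain z-score because of their discrete support.
Missing cell-level values are dropped before medians, not imputed.

PercentCells is 100 × well cell count / median control-well count,
per biological replicate; the median (not mean) control reference is the
robust choice and is recorded in output metadata. A compound ×
concentration is cytotoxic iff its median PercentCells falls strictly
below 53% (the boundary value itself is non-cytotoxic). Flags propagate
to all wells of the condition.

Replicate variability follows the Diff chain: per-well Diff = well z −
all-replicate median of its condition; MedianDiff, SumDiff = ΣΣ|Diff| and
SumResp = ΣΣ|z| aggregate per technical (TRep), biological (BRep) or all
(AllRep) replicate grouping, and RelSumDiff = SumDiff / SumResp, which is
invariant to feature rescaling. Replicate correlations are Pearson
correlations of the concatenated feature × condition median profiles,
computed after removing cytotoxic concentrations.

## Concentration-response modeling

Responses per series are the medians of well z over the three technical
replicates, one point per biological replicate × concentration. The five
families are f(x)=0 (cnst), a·x (poly1), b₁x+b₂x² (poly2), a·xᵖ with
p ∈ [0.3, 8] (pow), and tp/(1+(ga/x)ᵖ) with ga bounded to the tested
range × [0.1, 10] and p ∈ [0.3, 8] (hill). cnst, poly1 and poly2 are
closed-form least squares; pow profiles its linear coefficient and
optimizes p on a bounded scalar search; hill runs bounded trust-region
least squares on (tp, log₁₀ ga, p) with 5 seeded restarts. Model
selection is AIC with Gaussian likelihood and profiled variance; ties go
to fewer parameters, then the fixed order cnst < poly1 < pow < poly2 <
hill. Under a constant-zero truth at realistic noise this yields a
constant-model selection rate near 72% — AIC trades some parsimony for
power — but the operative error rate, the fraction of null series
classified as active (OK), is well under 10%.

BMR = 1.349 × 1.4826 × MAD of the feature's control-well scores
(≈ one interquartile range of Gaussian data). The BMC solves
|f(x)| = BMR — responses are signed and both directions count — by
log-spaced bracketing (2048 points) plus bisection to relative tolerance
1e-6, bracketed between lowest-tested/√10 and the highest non-cytotoxic
concentration. Classification: no crossing → NA; crossing above the
highest non-cytotoxic tested concentration → HIGH (inactive); crossing
below the lowest tested → LOW with log₁₀ BMC set half a log below the
lowest tested concentration; otherwise OK. Gating requires ≥ 4
non-cytotoxic concentrations and ≥ 3 biological replicates. For
downstream use, NA records become the global maximum tested concentration
(proportion profiles) or the compound's own maximum non-cytotoxic
concentration (correlation analyses). Bootstrap confidence intervals on
the BMC are out of scope.

## Reporting

Features map deterministically to categories — (channel, region, analysis
family) triples parsed from the feature name; malformed names are
collected into one error rather than dropped. Proportion-BMC profiles
test, per feature, each compound's log₁₀ BMC one-sided (lower tail)
against the across-compound mean/SD (t = (x−m)/s, df = n−1); the exact
grouping of this test was an open design point and the one-sample
construction is this package's documented choice. Accumulation lists keep
categories where at least 30% of member features respond (class OK or
LOW; the 30% boundary is inclusive) and rank them by the median BMC of
the responding members. The normalized magnitude of a feature is the
maximum |aggregated z| over the non-cytotoxic concentration range —
absolute value, so negative responses register. Profile similarity uses
Spearman correlation of the compound profiles at each compound's highest
non-cytotoxic concentration, optionally excluding Lyso features;
clustering is average-linkage on 1 − ρ cut into k flat clusters (k
configurable, default 6). Constant profiles get missing correlations and
isolate into their own cluster. The CV-vs-cell-number analysis resamples
n cells with replacement per well and plate, takes per-feature medians,
computes the CV of those medians per well across plates, and reports the
median over wells and features; the whole resample repeats `n_draws`
times (default 8) and the median over repetitions is reported, which
suppresses Monte-Carlo jitter without biasing the n-dependence.

## Synthetic data: what it emulates, what it does not

The plate generator reproduces the reference-design combinatorics: 384
wells, 15 compounds × 8 half-log dilutions × 3 technical blocks + 24
solvent controls, with the compound sequence rotated between blocks (a
deterministic stand-in for "alternating order") and control positions
scattered per block by the seed. The feature-table generator draws
per-cell values as log-normal baselines plus a planted concentration
effect plus additive Gaussian noise; the Gaussian component carries the
configured MAD (σ = MAD/0.6745) and the log-normal shape is kept small
(0.2 × σ/median) so the sample MAD stays within a few percent of the
target. Cell counts decline sigmoidally (hill, slope 2) with a
per-compound cytotoxicity EC50. Effects are hill curves whose direction
is a fixed property of the feature (a parity hash of the name), shared by
every compound hitting that channel — compounds with the same mode of
action move a feature the same way, which is what makes mode-of-action
profiles correlate.

The default ground truth emulates a reference compound plate: 13 active
compounds in five signature groups — two lysosomotropic (strong Lyso,
weak ER), two actin disruptors (strong Actin, weak Golgi), two
mitochondrial inhibitors (strong Mito, weak DNA), a three-compound
secretory-pathway group (ER/Golgi) and a four-compound nucleic-acid group
(DNA/RNA) — plus two inactive negative controls; two compounds carry
finite cytotoxicity EC50s (30 and 10 µM). Strong effects top out at 6–8
control MADs, weak secondaries at 2–4; per-compound AC50s are drawn
log-uniformly from 0.3–3 µM. The ~120-feature roster (7 stats × 2–3
regions × 7 channels plus shape features) is a desk-scale stand-in for
the hundreds of features commercial analysis software produces; the
secondary channels within each group are shared so that same-group rank
correlations (~0.6) dominate between-group correlations (~0.1–0.3), as
they do in real screens where a mode of action spans many correlated
features.

The image generator places non-overlapping elliptical cells by
Poisson-disc sampling, renders nucleus, cytoplasm, 1–6 nucleolus spots
and granular organelle texture per channel, and produces cycle-2 images
by warping the noiseless scene with a known similarity transform before
adding independent noise. Default fields are 512×512 at a 16-bit
intensity scale; tests use 128–256 px fields, which leaves the same
geometry at lower cost.

Not emulated: photorealistic optics, dye spectra, bleed-through, elution
chemistry, plate-position (edge) effects, segmentation errors in the
feature table (the statistical generator plants features directly), and
feature–feature correlation beyond the shared planted effects. Passing
tests therefore demonstrate that the analysis contract is implemented
correctly and is recoverable under controlled noise — not that the
pipeline is robust to optical artifacts or staining variability in real
images.

## Problem sizes and determinism

The default synthetic screen is 384 wells × 4 biological replicates × 100
cells/well with ~120 features — large enough for stable control MAD
estimates and meaningful replicate structure at desk scale. Simulation
studies use 100 fields (registration recovery), 500 simulated features
(BMC recovery, noise SD 0.5) and 100 seeds (cluster recovery). All
randomness flows through seeded `numpy` generators; the pipeline records
the seed, config hash and package version in its run log, and rerunning
an unchanged configuration reuses cached stage outputs and reproduces
byte-identical tables.
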