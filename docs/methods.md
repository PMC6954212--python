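# Methods

## Problem setting

A coccal bacterium (~1 µm diameter) is fixed, resin-embedded, cut into
consecutive ~50 nm sections, and immunogold-labelled: each gold particle
marks one antibody-accessible copy of the target protein on a section
surface. Tracing the sections in a reconstruction tool and re-stacking them
yields a 3D point cloud of gold coordinates. The analysis question is which
generative geometry that cloud supports: protein spread through the volume,
over a spherical (membrane-proximal) surface, or concentrated in one or two
ring structures.

Three physical distortions separate the observed cloud from the true
protein positions, and all three are modelled explicitly:

1. **Slab quantisation.** A mark carries only its section index; its z
   coordinate is known to one slab. Extraction places it at the slab
   mid-plane (`z = (index + 0.5) × thickness`), which minimises the
   worst-case error; a top-of-section convention is also exposed because
   labelling happens on a cut face.
2. **Surface accessibility.** Antibodies cannot penetrate resin, so only
   epitopes within a small capture depth of a cut face can be labelled.
3. **Linkage error.** The primary+secondary antibody complex offsets the
   gold particle from the epitope by tens of nm. Visualised as a 40
   nm-diameter uncertainty sphere per mark; modelled statistically as a
   random displacement with 65 nm mean magnitude.

## Section-plane geometry

A spherical shell of radius *r* cut by a plane at distance *s* from the
cell centre appears in-plane at radius x = √(r² − s²). Two shell/plane
pairs (r₁, s₁), (r₂, s₂) bound the wall signal in a slab; the blur extent
is reported as the width D = |x₂ − x₁| (the signed radii stay available as
x₁/x₂, since which pair is "inner" is a labelling choice left to the
caller). The average wall position is estimated as the midpoint
(x₁ + x₂)/2 — the unbiased convention absent further information about the
intensity profile across the blur. `wall_band` sweeps the same formula over
a slab to give the annulus where wall signal can appear; a slab beyond the
inner shell's reach returns inner radius 0 (a cap section shows a filled
disc, not an annulus).

## K function and envelopes

The estimator is the standard conditioned-on-n pair-count form

    K̂(r) = V / (n(n−1)) · Σ_{i≠j} 1(d_ij ≤ r) · e_ij ,

with e_ij = 1 (uncorrected) or the translation edge correction
e_ij = V / Π_k (L_k − |Δ_k|) for an axis-aligned box with sides L_k
(intensity λ̂ = n/V; note some implementations normalise by n²/V rather
than n(n−1)/V, a 1/n relative difference). The default r-grid runs from 0
to min(shortest window side / 4, 500 nm) in 100 steps: the quarter-side cap
is the usual validity heuristic for the correction, and 500 nm is the cell
radius scale beyond which K carries no subcellular information.

Envelopes are pointwise empirical quantile bands: m simulations from a null
model (default m = 999, level 0.95, so at least ⌈2/(1−level)−1⌉ = 39 sims
are required), all estimated on one common box window with the observed
pattern's n. Simulated points jittered outside the window are dropped,
exactly as data outside the window would be — this keeps the data and the
simulations exchangeable, which is what gives the band its nominal
pointwise coverage. Classification computes the fraction of the r-grid at
which the data K̂ lies inside each model's band; the best-supported model
attains the maximum (ties broken by the supplied model order, which lists
simpler geometries first), and models above a configurable 0.95 fraction
are flagged compatible. No p-value is computed: the report is a band
containment profile, not a test statistic.

## Null models and jitter

Four generative geometries, each an i.i.d. sample of n points followed by
linkage jitter:

- `csr_ball` — uniform in a ball (complete spatial randomness in the cell);
- `sphere` — uniform on a sphere surface (membrane-associated);
- `ring` — uniform on a circle with given centre, radius, plane normal;
- `two_rings` — two parallel circles offset ±separation/2 along the
  normal, each point assigned by a fair coin (keeping the process i.i.d.
  on the union manifold; a fixed split is available via two ring calls).

Jitter modes: `gaussian` (default) draws isotropic 3D Gaussian
displacements with per-axis σ = mean/(2√(2/π)), so the expected norm equals
the stated 65 nm mean (chi₃ mean = 2σ√(2/π)); `fixed` displaces by exactly
the mean in a uniform random direction. Only the mean displacement is
physically known, so both calibrations are provided and tested.

Model parameters are fitted from data when not supplied: sphere centre by
the algebraic least-squares sphere fit (exact on noiseless sphere samples),
radius as the median distance; ball radius as the median distance ×
2^(1/3), the exact inverse of the uniform-ball radial median; ring plane
normal from the smallest-variance principal axis with the median in-plane
distance as radius; two rings by splitting at the median projection,
refining the threshold to the midpoint of the group means, then fitting one
plane per group exactly (so a noiseless two-ring sample returns its exact
separation). Envelope width is conditioned on the observed n, the standard
matched-null construction.

## Synthetic experiments

`generate_experiment` forward-simulates the full chain: epitopes drawn from
a null geometry; each assigned to the slab containing it; detectable iff
within `capture_depth` (default 10 nm) of the slab's nearer cut face;
detectable epitopes labelled with probability `labeling_prob` (default
0.7); labelled positions displaced by the linkage jitter; the gold mark
emitted in its section with only (u, v) pixel coordinates, as real data
carries. Cell-wall annuli from `wall_band` are written as traced contours
so parsers see realistic files. For epitopes roughly uniform in z within a
slab the detected fraction is labeling_prob × min(1, 2·capture_depth /
thickness); the tests check this against an exact integral of the ball's
z-density. Neither the capture depth nor the labelling efficiency is
measurable from the reconstruction itself — both are configuration with
stated defaults, and the statistical guarantees are exercised across
labelling probabilities 0.5–1.0.

The default configuration sections a 500 nm-radius cell into 21 × 50 nm
slabs (the column must cover the cell). The bundled single-cell preset
follows an entire small coccus — radius 300 nm, so it fits the 13 × 50 nm
column — with a surface-associated (sphere) distribution of 600 epitopes
and a fixed seed.

What the generator deliberately does not emulate: micrograph pixel images
and electron optics, stain contrast, antibody binding chemistry and
steric competition between neighbouring labels, rod-shaped or dividing
cells, and section compression or alignment error (transforms in generated
fixtures are identities; the parser supports general affine transforms and
is tested on them separately). Passing tests therefore demonstrate the
statistical machinery under the declared geometric model, not robustness
to those acquisition artefacts.

## Numerical choices

- All world coordinates in nm; pixel coordinates convert via the series'
  pixel size. Right-handed axes, z increasing with 0-based section index.
- Pattern/window containment tolerance 1e-9 nm; manifold membership of
  un-jittered samples is exact to the same tolerance.
- Windows for simulated patterns: bounding box of the generating geometry
  padded by 4 × jitter mean (≥ 1 nm, keeping degenerate planar geometries
  at zero jitter three-dimensional), expanded further if a displaced point
  escapes.
- Quantiles via linear interpolation (`numpy.quantile` default); with
  m = 199 the realised pointwise coverage of a 95% band is ~0.95 with mild
  inflation at large r where K̂ curves are strongly correlated across
  distances.
- K̂ at coincident points: a pair at distance 0 would count at r = 0;
  duplicate coordinates are degenerate input and not special-cased.
- Ties in the best-model argmax resolve to the first model supplied.
- Exported PLY meshes store float32 vertices (ASCII); geometry checks on
  them use a 1e-3 nm tolerance.

## Problem sizes in the shipped checks

The statistical suite uses: 100 replicates × 199-simulation bands at
n = 200 for envelope coverage; 20 seeds per geometry at n = 300 (direct
patterns) and 5 seeds per geometry at 600 epitopes (full pipeline) with
99-simulation bands for model recovery; 10⁵ draws for jitter calibration;
500 CSR simulations for the closed-form check of the estimator, compared
on 50–75 nm ≤ r ≤ side/4 where the Monte-Carlo error of that many
simulations is below the 5% comparison band.

## Known limitations

- The translation correction requires a box window; ball windows are
  analysed on their enclosing box (the pattern is unchanged; the empty
  corners slightly inflate V and hence K̂ uniformly, which cancels in
  band-containment comparisons because envelopes use the same window).
- Band containment across candidate models is not a calibrated selection
  procedure; with strongly overlapping geometries (e.g. one ring vs two
  rings closer than the jitter scale) the fractions can tie and the
  reported best model follows the supplied order.
- The surface-accessibility model is binary (within capture depth or not);
  real epitope exposure is graded and antigen-dependent.
- Non-affine (polynomial) section transforms are rejected, not
  approximated.
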