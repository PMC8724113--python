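# Methods

## Shape model

Boundary geometry is modelled as a point-distribution model (PDM) over
corresponded landmarks.  Correspondence exploits the left-to-right
ordering of retinal boundaries: each curve gets 51 landmarks per B-scan
— the first at column 0, the last at column W−1, the middle one (0-based
index 25) pinned to the foveal column, and the remaining points evenly
spaced within each half.  Landmark depths are read off the dense surface
by linear interpolation.  The foveal column, when not supplied, is the
column of minimum total retinal thickness (z_K − z_1) on the central
B-scan.

Training shapes are aligned by generalized Procrustes analysis with the
full similarity group (rotation, translation, isotropic scale).  The
reference starts as the first shape and is replaced by the iterated mean;
iteration stops when the mean moves by less than 1e-8 (Frobenius) or
after 50 rounds.  Each aligned shape is the similarity transform of its
*original* minimizing summed squared distance to the current mean, so the
returned transforms map raw inputs directly into the model frame.

The PDM uses the 1/N-normalized covariance of the aligned shape vectors.
Eigenpairs are computed from the thin SVD of the centred N × D data
matrix (the dual formulation) rather than by assembling the D × D
covariance — for the default geometry D = 3 × 9 × 969 ≈ 26k, while the
spectrum has rank at most N − 1; the eigenpairs are identical, and the
unit tests verify this against an explicitly assembled covariance on
small instances.  The retained mode count t is the smallest number of
leading components whose cumulative eigenvalue share reaches the
configured variance fraction (default 0.94), capped at min(N − 1, D); t
is therefore data-dependent.  Degenerate spectra are handled
deterministically: eigenvalues are kept in descending order with a
stable sort, and each mode's sign is fixed so its first component above
1e-12 is positive.  A training set of identical shapes yields one
zero-variance mode by convention.

Coefficient handling distinguishes two cases.  Random draws are
b_i ~ N(0, σ_i) independently per mode; in constrained (healthy) mode
each coefficient is redrawn until it falls within ±3√σ_i, which
preserves the truncated-Gaussian distribution.  Explicitly supplied
coefficients are instead *clipped* to the limit (with a warning), giving
deterministic behaviour for user requests.  Unconstrained mode — used
for DME, where edema legitimately drives boundaries outside the healthy
range — passes coefficients through unchanged.  Whether the underlying
population samples its modes independently is not identifiable from a
PCA model; independence is assumed.

Inversion is the least-squares projection b = Pᵀ(x − x̄); with
orthonormal modes this makes sample → project an exact roundtrip, which
the parameter-recovery tests exploit.

## Surface reconstruction

Sampled landmark vectors are turned back into dense surfaces by monotone
cubic (PCHIP) interpolation through each curve's 51 landmarks, evaluated
at every column.  Monotone cubics avoid the overshoot a natural spline
would introduce at the foveal pit.  Landmark abscissae are sorted and
nudged to be strictly increasing (sampling can jitter the x coordinates
slightly).  Non-crossing is then enforced by a cumulative-max projection
from the innermost surface down — cheap, order-preserving, and applied
after *every* sampling or reconstruction step, so no pipeline output can
violate the ordering invariant.  Depths are clamped into [0, H).

Round-tripping extract → reconstruct is exact at integral landmark
columns; at fractional columns the linear read-off of the cubic curve
introduces a sub-voxel discrepancy (well under 1 voxel on smooth
anatomy), which the tests bound explicitly.

## Rendering

Layer appearance is a per-layer mean brightness μ_k estimated over a
seeded random fraction (default 0.5) of training B-scans, pooled across
volumes; re-drawing the subset per synthetic volume is what produces
brightness diversity across outputs.  Voxel ownership is half-open: a
voxel on boundary k belongs to the layer below it, [z_k, z_{k+1}).
Vitreous and sub-retinal voxels are left empty and later composited
per A-scan from a reference volume, each band axially resampled (linear)
to the target extents.  Intensities are float in [0, 1] end to end;
quantization happens only on export (8/16-bit TIFF with the scale
recorded in a JSON sidecar).

Speckle is modelled as multiplicative Gaussian noise,
I′ = clip(I·(1 + η), 0, 1) with η ~ N(0, σ²) — the standard surrogate
for OCT's signal-proportional speckle, not a coherent-scattering
simulation.  σ is deliberately unfixed: data sets are meant to be
generated across a range of noise levels (0–0.2 covers visually clean to
heavily speckled; the CLI default is 0.05).

## Vasculature

A vessel's lateral footprint is a multiplicative intensity profile
across a window (≈1 at the edges, a dip at the centre), modelled by a 1D
PDM over training profiles — the same PCA machinery, without Procrustes
(profiles share a fixed window).  At render time a sampled profile is
normalized so its edge baseline is exactly 1; a unit-baseline
multiplicative profile matches any host region's brightness by
construction, which is how "normalize to the host region" is realized
here.  Columns under a vessel are multiplied by the dark profile
d(x) < 1 from the vessel-bearing surface (default: surface 2, the
NFL/vessel layer) down through the outer retina and choroid, and by a
derived bright factor 1 + g·(1 − d(x)) (gain g = 0.5) between the ILM
and the vessel layer.  The bright factor's form is a modeling choice —
no closed form exists for the inner-retinal brightening — chosen so
bright and dark contrast scale together.  This yields the expected
en-face signature: vessels dark in outer-layer projections, bright in
inner-layer ones, asserted per placement in the tests.

Because this package runs data-free, placements come from a seeded
spatial model rather than shadow detection on real scans: vessel tracks
avoid a configurable foveal avascular zone, keep a minimum lateral
separation, and persist across adjacent B-scans with small jitter
(continuity of real vasculature).  File-based placements can be supplied
instead.

## DME synthesis

The 2D DME model spans 9 boundary curves (the eight standard interfaces
plus a manually added choroidal 9th) per B-scan and is sampled
unconstrained.  For each synthesized boundary set the most similar
reference B-scan is selected by mean-centred SSD on the first boundary
(ILM); mean-centring removes axial placement differences, and ties go to
the lowest index.  A single best reference is used (no blending).
Texture is transferred column-wise: per column and per axial band
(vitreous, the eight retinal layers, the choroid band below the 9th
boundary) the reference's intensity profile is linearly resampled to the
new band's thickness.  The fluid mask travels with the same per-column
axial map using nearest-neighbour sampling, which preserves binarity;
transferred fluid is finally clipped to the open region between
boundaries 1 and 8, the invariant every scene must satisfy.  A library
with a single usable reference degenerates gracefully to a model whose
mean is that reference (one zero-variance mode), so b = 0 reproduces it.

## Evaluation

Thickness maps are surface differences z_k − z_j per (B-scan, column),
reported in µm when voxel spacing is known.  Projections are mean
intensity over [z_j, z_k) per A-scan, NaN where the band is empty.

GLCM features quantize the region to n_levels (default 8) equal-width
bins over its own range, count *ordered* pixel pairs at one offset
(default (0, 1), asymmetric), normalize to p(i, j), and evaluate energy
Σp², contrast Σ(i−j)²p, homogeneity Σp/(1+(i−j)²) and the normalized
correlation.  A constant region has a single-cell GLCM: energy and
homogeneity 1, contrast 0, correlation undefined (NaN, not an error).
An optional mask restricts counting to pairs wholly inside a retinal
layer, which is how per-layer features (defaults: layers 1, 3, 5) are
computed.  A brute-force double-loop oracle in the tests pins the
implementation to 1e-12.

The two-sample Kolmogorov–Smirnov statistic is the supremum ECDF gap
with the asymptotic p-value (scipy's `ks_2samp`, asymptotic mode, behind
this module's interface), plus matched empirical quantiles for Q-Q
plots.  Group comparison reports per-layer mean ± SD of per-volume mean
thickness with a Welch two-sample t-test (the layer → surface-pair map —
total macula 1–9, RNFL 1–2, GCIPL 2–3, RPE 8–9 — is configuration, as is
the test), and per-feature K-S statistics across per-image GLCM values.
Welch's test is a choice: the comparison needs no equal-variance
assumption, and the test calibration (type-I error ≈ 5% on null phantom
groups) is itself asserted in the suite.

## Phantom data

Phantoms are parametric-analytic rather than resampled from scans, so
ground truth exists in closed form.  Layer thicknesses are generated as
positive fields — normative base thickness (anchored to macular anatomy:
RNFL ≈ 30 µm, GCIPL ≈ 77 µm, RPE ≈ 55 µm, total ≈ 310 µm at 3.87
µm/voxel) × exp(smooth low-order polynomial perturbation) × a foveal
thinning factor that collapses inner layers at a Gaussian pit — and
accumulated upward from a smooth outer (BM) surface, so ordering holds
by construction and is still verified on every output.  All randomness
(perturbation fields, base jitter, pit-centre jitter) scales with the
perturbation amplitude; a zero-amplitude configuration emits identical
volumes, which pins the zero-variance behaviour of the shape model.
DME references replace the pit with a central dome, thicken the central
layers, and carve 1–3 ellipsoidal hyporeflective pockets strictly inside
the retina, with masks consistent by construction.

What the phantoms do *not* emulate: real speckle statistics and texture
within layers (layers are piecewise-constant before noise), pathology
other than dome + fluid pockets, vessel tortuosity, and scanner-specific
artifacts.  Tests passing on phantoms therefore demonstrate the
correctness of the machinery — landmark bookkeeping, PCA algebra,
invariant enforcement, transfer maps, statistics — not that synthetic
output is indistinguishable from any particular device's scans.

## Problem sizes and tolerances

The test suite runs on scaled-down rasters (typically 5 B-scans of
64 × 128, 15 landmarks per curve) chosen so the whole suite completes in
seconds while exercising identical code paths; the landmark-arithmetic
and acceptance computations use the full 19-B-scan, 51-point layout.
Key tolerances: orthonormality and eigen-oracle agreement 1e-8–1e-9;
GLCM/K-S oracle agreement 1e-12; parameter recovery 1e-6; surface
roundtrip < 1 voxel; Monte-Carlo moment checks at the 1–10% level
appropriate to their sample sizes.
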