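# Methods

`layermet` re-implements, as a tested pipeline, the image-analysis chain
used to map mechanics and metabolism across an expanding MDCKII
epithelial monolayer: Peredox redox-sensor calibration and conversion,
TCSPC lifetime fitting, nuclei tracking, Voronoi morphometrics,
traction force microscopy, and layer-aligned spatial profiling.
Because the study's raw images are not available, a synthetic-data
generator reproduces the *form* of every raw input with known ground
truth, so each stage — and the whole chain — is verifiable.

## Peredox calibration and NAD+/NADH conversion

The Peredox-NLS sensor reports cytoplasmic NADH occupancy in its green
(T-Sapphire) channel and normalizes expression with a red (mCherry)
channel; the red/green ratio rises with NADH.  During calibration,
media with known lactate:pyruvate ratio X clamp the cytoplasmic redox
state through the lactate dehydrogenase equilibrium

    K = [Pyr][NADH][H+] / ([Lac][NAD+]),   K = 1.1e-11,  pH 7.4,

so X = [H+] / (K · NAD+/NADH).  The normalized per-cell fluorescence
response follows a Hill curve

    F(X) = 1 + A / (1 + (B/X)^1.7),

fitted per cell by bounded nonlinear least squares with the Hill
coefficient fixed.  Composing the two relations converts fluorescence
to NAD+/NADH and back; the inverse is

    X = B / (A/(F−1) − 1)^(1/1.7),   NAD+/NADH = [H+] / (K X).

Design points:

- **Normalization anchor.** The lowest-X (pyruvate-dominant) titration
  step drives the sensor to its low-NADH state and maps to F = 1,
  matching the model's lower asymptote.
- **Ratio semantics.** Per-cell ratio is the ratio of channel means
  over the nucleus mask, not the mean of pixel ratios — robust to
  pixel-level zeros in the green channel.
- **Out-of-range values.** F at or beyond the asymptotes (1, 1+A) is
  clipped into an ε-interior (ε = 10⁻³·A) and flagged; flagged cells
  are carried with a quality code, never dropped silently.
- **Order of operations.** Layer composites are formed in
  fluorescence-ratio units and converted to NAD+/NADH afterwards; the
  conversion is nonlinear and does not commute with averaging.
- **Asymmetric errors.** The layer-to-layer SD is added to/subtracted
  from the mean ratio *before* conversion, so redox error bars are
  asymmetric by construction.

The titration cohort simulator draws per-cell true (A, B) from normal
distributions truncated at A > 0.05, B > 1 (the midpoint is a positive
concentration ratio), evaluates the Hill curve at 7 steps spanning
X = 0.1–400, applies 2 % multiplicative noise plus a log-normal
expression scale, and re-fits.  With the reported population values
(A = 1.04 ± 0.24, B = 44.13 ± 26.08) the mean fitted parameters
reproduce the population means within two standard errors at n = 200.

## FLIM decay fitting

NADH autofluorescence decays are modeled as

    I(t) = α₁ exp(−t/τ₁) + α₂ exp(−t/τ₂) + C,   α₁ + α₂ = 1,

with the fast component interpreted as free and the slow as
enzyme-bound NADH; τm = α₁τ₁ + α₂τ₂.  The exponential mixture is
convolved with the instrument response by discrete *linear* convolution
(no circular wrap: photons must not re-enter the pre-pulse region) and
compared with the photon histogram by multi-start bounded least squares
(bounds 0 ≤ αᵢ ≤ 1, 0.02 ≤ τᵢ ≤ 100 ns; 5 seeded random restarts by
default, best residual kept; components reported ordered τ₁ ≤ τ₂; R²
against the fitted histogram).

- **Temporal window.** The acquisition window is not stated with the
  256-bin histogram depth; a 12.5 ns window (80 MHz Ti:Sapphire pulse
  period, 48.8 ps raw bins) is adopted as the config default.
- **Binning.** Photon counts are aggregated 4→1 in time (256→64 bins,
  exactly count-conserving) and over a moving spatial window (radius 2
  px default, summation not averaging) to raise per-decay photon
  counts.  The window radius is configurable; the source text for the
  spatial window size is ambiguous, so no particular value is asserted.
- **Binned forward model.** Fitting binned histograms against a model
  convolved on the *coarse* grid with a re-binned IRF distorts the fast
  component badly (the IRF width is comparable to one coarse bin).  The
  fit therefore evaluates the model on the acquisition grid, convolves
  with the acquisition-resolution IRF, and aggregates to the coarse
  bins — the exact forward model of the binned measurement.
- **Quality gates.** Decays under 500 photons are skipped with a code
  (the threshold is this package's choice).  Unweighted least squares
  is the default; at the photon counts produced by binning the
  precision target (median |Δτm|/τm < 2 % at 5000 photons/pixel) is met
  with margin.
- **Dye validation.** A two-component decay at τ₁ = 0.11 ns,
  τ₂ = 0.70 ns under the 311-ps-FWHM Gaussian IRF (Rhodamine-B
  standard) is recovered within ±0.003/±0.01 ns from Poisson draws;
  the validation uses 2×10⁵ photons per decay and 32 replicates
  (cuvette-style photon budgets; the amplitude mix is set to
  α₁ = 0.5, as the source reports only the lifetimes).

## Nuclei tracking

Nuclei are detected in the red channel with a Laplacian-of-Gaussian
band-pass at the expected nucleus scale, peak extraction with a minimum
separation, and marker-based watershed on the smoothed image —
deliberately not a raw intensity threshold, so dim and bright nuclei
are treated alike.  Centroids are intensity-weighted (sub-pixel,
< 0.3 px error on rendered blobs).  Two equal Gaussian blobs merge into
a single intensity maximum below 2σ separation; that is the detector's
physical resolution limit (the split test uses 2.5σ).

Linking advects each live track's last position by a dense optical-flow
field and matches predictions to detections by a globally minimum-cost
assignment (Hungarian) gated at 1.5× the expected per-frame
displacement; unmatched detections open tracks, unmatched tracks end
(no gap closing or division handling).  Speed is the mean inter-frame
displacement magnitude, in µm/h; tracks shorter than 2 frames are
excluded from speed statistics.

The dense flow (and the bead displacement measurement below) uses
locally normalized block cross-correlation (`match_template`) with a
separable Gaussian three-point sub-pixel peak fit.  Plain windowed
correlation carries a triangular-envelope bias (~σ²/N toward zero) that
the local normalization removes; rigid test shifts are recovered to
±0.01 px (flow) and ±0.005 px mean (beads).

## Voronoi morphometrics

Cell footprints are proxied by the Voronoi cells of nuclear centroids.
Each polygon is built by clipping the domain rectangle against the
perpendicular bisectors of the cell's Voronoi ridge neighbors
(Sutherland–Hodgman), which handles unbounded edge regions exactly.
Area, perimeter and centroid come from the shoelace closed forms;
aspect ratio is the axis ratio of the ellipse sharing the polygon's
second central moments (the standard region-property definition).
Cells touching the domain or free boundary are flagged and excluded
from shape statistics near the open edge, where Voronoi cells are
artifacts of the clipping rectangle.  The shape index p/√A is exported
as a derived column; no jamming phase calls are made.

## Traction force microscopy

Bead displacements between the stressed and relaxed (post-trypsin)
images are measured by the windowed correlator above (32 px windows,
50 % overlap), after removing a whole-field rigid stage shift.
Windows with peak correlation below 0.6 are masked and filled by
nearest-neighbor interpolation.

Tractions follow from the elastic half-space (Boussinesq) surface
Green's tensor in Fourier space,

    û(k) = G(k) t̂(k),
    G(k) = 1/(μk³) [ (1−ν)k² + νk_y²,  −νk_x k_y ;
                     −νk_x k_y,  (1−ν)k² + νk_x² ],

inverted per wavevector with Tikhonov regularization
(Gᵀ G + λ²I) t̂ = Gᵀ û; λ is a dimensionless fraction of the softest
Green's mode.  Choices:

- ν = 0.5 (incompressible polyacrylamide, standard in traction
  microscopy; the source states only the 9.6 kPa shear modulus).
- The 100 µm gel is treated as a half-space: cellular-wavelength
  displacement fields decay well within the gel thickness.
- Grids must have square *cells* but may be rectangular in extent
  (the imaged strip is ~13:1); the per-wavevector operator is agnostic
  to the grid aspect, and a square grid over the long axis would be
  mostly empty.
- The k = 0 (rigid) mode is excluded; recovered fields are
  automatically force-balanced (net/total < 1 %).
- Regularization default λ = 0.05, fixed by an L-curve sweep on
  synthetic bead pairs; the measured displacement field is additionally
  Gaussian-smoothed by one traction cell before inversion.  Noise-free
  round trips at λ → 0 are exact to machine precision (< 2 % required).

Per-cell traction is the mean traction magnitude interpolated under
each cell footprint; footprints smaller than one traction grid cell are
flagged.

## Spatial profiling

Per-cell quantities are linearly interpolated onto a regular grid
(35 px ≈ 11 µm at 0.325 µm/px — typical cell spacing in the dense
layer); nodes outside the cells' convex hull are missing.  Each imaged
strip spans two advancing fronts; fields are split at the layer's
center of mass and mirrored so both fronts advance toward +x.  Layers
are aligned by their centers (offsets rounded to the grid — no
interpolation smoothing), averaged pixel-wise ignoring missing data,
collapsed over y, and binned in ~260 µm x-bins.  The trace SD is the
layer-to-layer dispersion of per-layer bin means; bins with fewer than
3 contributing layers report missing SD.  Uptake (2-NBDG-style) images
are normalized twice: by the pre-release layer-center reference
intensity, and by mean cell area from the tessellation, giving a
dimensionless per-cell uptake index that is 1 at the reference.

## Synthetic monolayer

The generator is a phenomenological emulation, not a mechanistic
jamming model.  A confluent strip expands symmetrically about its
center; both fronts advance at the prescribed edge speed, and cells are
advected by a front-relative velocity field decaying exponentially into
the bulk (decay length 150 µm default), leaving a jammed core and a
flowing margin.  Every gradient the pipeline must resolve is prescribed
the same way (edge vs bulk value, exponential decay): NAD+/NADH
(60→250, the physiologic decade range), free-NADH fraction α₁
(0.85→0.70 with τ₁ = 0.4 ns, τ₂ = 2.5 ns), speed (20→1 µm/h), Voronoi
aspect ratio (2.0→1.1, realized by stretching the seeding lattice), and
traction magnitude (120→20 Pa, pointing toward the layer center and
mirror-symmetric so the net force vanishes).  These default magnitudes
are chosen to be realistic for an expanding MDCK monolayer on a
9.6 kPa gel; they are configuration, not claims about the biology —
neither the functional forms nor the constants are measurements.

Rendering: nuclei are 2D Gaussian blobs (σ = 3 px) with log-normal red
amplitudes; the green amplitude is set so red/green equals the
fluorescence ratio implied by the cell's true redox (the sensor's
ratiometric design).  TCSPC stacks draw Poisson counts around the
IRF-convolved expected curve, normalized to the photon budget, with a
constant background defaulting to 1 % of peak.  Bead pairs render
seeded random beads displaced by the bilinearly interpolated forward
solution of the prescribed traction field.  Uptake images follow a
caller-supplied x-profile inside the layer mask.

What the generator does *not* emulate — real nuclear texture, shading
and dark-field structure, mitosis and apoptosis, out-of-focus light,
mask errors from machine-learning segmentation, finite gel thickness —
bounds what passing tests show: the pipeline's numerics and contracts
are verified, not its robustness to every artifact of real microscopy.

## Problem sizes and determinism

Default test problem sizes (a 1600×120 µm strip with 900 cells and 6
frames for the end-to-end check; 16×16 FLIM fields; 200-cell titration
cohorts; 32-replicate dye validation) keep the full suite comfortably
within a desktop budget while leaving every recovery check
statistically meaningful.  All stochastic stages take explicit seeds;
identical configuration and seeds reproduce outputs exactly, and run
manifests record both.

## Known limitations

- Lifetime fitting is unweighted least squares by default (matching
  the described procedure); at very low photon counts a Poisson
  likelihood would be more efficient.
- Linking has no gap closing: a missed detection splits a track.
- The traction inversion is unconstrained; constrained or
  boundary-element variants (and finite-thickness kernels) are out of
  scope, with the config carrying a hook for the latter.
- Uptake/dye analysis consumes masks as inputs; no pixel-classification
  segmentation is included.
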