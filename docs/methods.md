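# Methods

This note records the models, parameter choices and numerical conventions
behind `clxmreg`, and what the synthetic benchmark does and does not show.

## Coordinate and transform conventions

All geometry is in physical nanometres. Positions are `(x, y)` with `x` the
column index and `y` the row index; `nm = index × pixel_size_nm`, measured
at pixel centres, origin at the centre of pixel (0, 0). The parametric
affine maps *moving* (FM) coordinates into the *reference* (SXT) frame:

    p' = R(θ) · diag(sx, sy) · (p − c) + c + t

with the pivot `c` at the reference landmark centroid. The family
`R·diag(sx,sy)` is not closed under composition or inversion when θ ≠ 0 and
sx ≠ sy; inverses are therefore returned as exact general affines (matrix +
offset), and only the forward parameters are serialised. The thin-plate
warp is always fitted and applied *after* the affine and models only
residual displacements; image resampling uses inverse mapping with
bilinear interpolation, inverting the (small, smooth) warp by fixed-point
iteration `p ← q − d(p)` (4 iterations, accurate to ≪ 1 nm for the ≤150 nm
distortions it models).

SXT is the fixed reference and FM the moving modality: registration then
happens on the finer 29 nm grid and the high-resolution data is never
resampled. The ground-truth transform of the generator points the same way
(FM→SXT), so estimated and true parameters are directly comparable; a
consequence is that a ground-truth translation of +x shifts the rendered FM
content by −x.

## Segmentation

Preprocessing is Gaussian smoothing (default σ = 2 px of the grid being
segmented) followed by CLAHE (clip limit 0.01, tile 64 px — chosen so a flat
field stays flat while faint droplet rims are lifted to segmentable
contrast), output min–max scaled to [0, 1]. Thresholding is a *global* Otsu
on the preprocessed image, with dark (SXT) objects inverted first; polarity
defaults to bright for FM, dark for SXT, and for unknown modalities the
minority pixel class above/below the threshold is taken as foreground.
Morphological cleanup is an opening with a radius-1 disc followed by binary
hole filling — the minimal instantiation that turns ring-like absorption
droplets into solid segments before centroiding. Components are kept when
their equivalent radius `√(area/π)` lies in 150–1500 nm, bracketing the
droplet population (a few hundred nm up to a micron) with margin. Centroids
are unweighted (binary) centres of mass in nm.

Droplet pairs whose blob supports merge under the 250 nm FM PSF cannot be
split by global thresholding; they appear as one oversized component. This
is a resolution limit of the method, not an artefact: the benchmark's
matching gate simply leaves such components unmatched.

## Registration

The coarse stage cross-correlates the binary masks (not intensities — the
modalities have unrelated contrast) with subpixel refinement via the
upsampled cross-power spectrum. Pure phase normalisation is brittle for
sparse binary scenes that also differ by rotation and scale, so both the
phase-normalised and plain correlation peaks are evaluated and the
candidate with the lower mean matched-centroid distance wins; the choice is
deterministic and cost-driven.

The refinement alternates mutual-nearest-neighbour matching with
derivative-free simplex minimisation of the mean squared pair distance over
(tx, ty, θ, sx, sy), started from the best of a 3×3 translation jitter grid
(±150 nm). The match gate starts at 2 µm and shrinks to 3× the current RMS
residual (floor 300 nm). Scale is bounded to [0.8, 1.25] and rotation to
±15° — generous for two detectors on a shared cryo-stage — enforced by
penalty. Convergence: relative cost change < 1e-4 between ICP iterations,
cap 30 outer iterations (a `ConvergenceError` carries the best estimate).
Fewer than 3 gated pairs at any point raises a degenerate-geometry error.

The warp stage fits a thin-plate spline (`r² log r`, scipy RBF with a
degree-1 polynomial part) to the matched residuals; λ = 0 by default, i.e.
exact interpolation at the controls, as "interpolation" implies. With < 3
or collinear controls it degrades to a pure translation by the mean
residual; collinear controls with λ = 0 are rejected with a hint to
regularise.

## Leave-one-out accuracy

Each moving-side segment is erased from the moving mask only; PCC + affine
(never the warp — the spline would interpolate the held-out point from its
fold-mates and void the statistic) are recomputed from the edited binary
masks; the erased segment's centroid is mapped through the refitted
transform and compared with its matched reference centroid. Correspondences
are frozen by one full-data matching before the protocol so folds cannot
relabel landmarks. Folds without a reference match or with degenerate
geometry are flagged and excluded from the summary (arithmetic mean ±
sample standard deviation, n−1). At least 4 moving landmarks are required
so every fold keeps the 3 an affine needs.

## Resolution metrics

FRC: images are mean-subtracted *before* the (default Hann) window — this
makes the curve exactly invariant to shared affine intensity rescalings —
zero-padded to square if needed, and correlated over 1-bin-wide rings up to
Nyquist, using the real part of the cross-spectrum. The resolution is the
first downward crossing of the fixed 0.25 threshold (DC ring excluded),
located by linear interpolation and reported as full pitch `1/f`; curves
that never cross are flagged Nyquist-limited (full pitch = 2 px), curves
already below threshold at the first ring are flagged degenerate. The
half-bit criterion is deliberately not the default, to match the fixed-
threshold convention used for soft X-ray instrument characterisation.

Noise-independent halves come from summing even- vs odd-indexed frames per
tilt; the two halves conserve the total signal exactly. The depth profile
runs the per-slice FRC of two half reconstructions and reports full pitch
against signed distance from the focal slice (the slice with minimal full
pitch); the z-step defaults to the in-plane pixel size (isotropic voxels).

FWHM: profiles are sampled bilinearly at a uniform step; the baseline is
the median of the two 10% end regions, the extremum is the peak/dip
(or whichever is farther from baseline, for `auto`), and the two half-level
crossings flanking the extremum are linearly interpolated.

## Synthetic generator

The generator emulates the study conditions: droplets of radii 200–1000 nm
with ≥ 2 µm centre separation in a 30×30 µm field (default 15), rendered at
120 nm/px with a Gaussian PSF of σ 250 nm in FM (bright blobs, amplitude 1
on a 0.05 background) and at 29 nm/px in SXT (rings by default: rim at 0.25,
core at 0.55 against a 0.85 transmission background; the inner 70% of the
radius is core). The inter-modality ground truth is an affine with
|t| ≤ 2 µm, |θ| ≤ 3°, scales 0.97–1.03 plus a thin-plate displacement field
from 5–10 random control points, rescaled so its maximum over the field
never exceeds 150 nm. Noise is additive Gaussian applied last (σ = 0.05 in
both channels; optional Poisson scaling), which puts the faintest droplet
at a contrast-to-noise ratio of about 5 — segmentation is reliable but not
trivial. Rendering is anti-aliased by 4× supersampling and box averaging,
keeping noise-free centroid bias well under a pixel. The stack renderer
assigns each droplet's full cross-section to one slice round-robin so the
minimum-intensity projection reproduces the 2D render exactly.

Deliberately *not* modelled: zone-plate optics and partial coherence, depth
of field, Radon-projection tilt geometry, autofluorescence background,
droplet polydispersity in shape. Passing the synthetic benchmark therefore
shows the *algorithmic* chain is correct and accurate under realistic
geometry, sampling and noise — it does not certify performance on
instrument data with uncorrected optical artefacts.

## Benchmark problem sizes

The accuracy benchmark pools the leave-one-out errors of ten seeds of the
default generator (≈ 150 landmark folds, each fold a full PCC + affine
refit on 1034² masks); it runs in a few minutes on one CPU. The affine
recovery suite uses twenty affine-only seeds. These sizes give sub-10 nm
standard errors on the reported means while staying desk-scale.

## Known limitations

- Merged (sub-PSF-separation) droplets are detected as one component; no
  watershed splitting is attempted, staying faithful to the plain
  Otsu-plus-morphology segmentation the workflow defines.
- The leave-one-out statistic shares landmarks between folds, so one
  grossly corrupted landmark inflates neighbouring folds somewhat (its own
  fold remains the clear outlier).
- 2D only: the SXT stack is min-projected before registration; no 3D–3D or
  mutual-information registration.
- TIFF and MRC2014 only; pixel sizes are honoured from metadata or must be
  given explicitly — they are never guessed.
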