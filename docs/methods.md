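# Methods

## Model and assumptions

The coordinate system assumes that the four LSCC landmarks (anterior and
posterior canal–vestibule junctions, left and right) are (i) identifiable
in both cone-beam CT and T2 MRI, and (ii) approximately coplanar, with the
left and right canals lying roughly on one common plane. The construction
never requires exact planarity: landmarks are orthogonally projected onto
the total-least-squares plane before any axis is defined, so small
off-plane deviations perturb the frame smoothly rather than invalidating
it. The planarity report quantifies the residual assumption directly
(median landmark vs its projection, per coordinate).

The plane fit is orthogonal (total) least squares — centroid plus the
smallest principal direction of the centered points — not a z-on-(x,y)
regression. Since the landmarks are subsequently projected *orthogonally*
onto the plane, only the orthogonal-residual fit makes the two steps
consistent. The normal's sign is fixed deterministically
(z ≥ 0, ties broken by y ≥ 0 then x ≥ 0).

The world convention throughout is LPS-like (+x right→left,
+y anterior→posterior, +z inferior→superior, right-handed, mm). NIfTI
files (conventionally RAS) are converted at the I/O boundary by negating
the x and y rows of the affine.

### Tilt sense

The final 20° rotation of the y/z axes about x̂ is "counter-clockwise"
only relative to a viewing direction; we define it as the right-hand-rule
positive rotation about +x̂ (which points right→left). For the
anatomically sensible configuration this tips the frame's xy plane from
the canal plane toward the Reid horizontal. The angle is a signed
parameter (`tilt_degrees`, default +20), so the opposite convention is one
sign flip away.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `tilt_degrees` | +20 | degrees | canal plane sits ≈20° from the Reid horizontal; sign = right-hand rule about +x̂ |
| output spacing | 0.2604 | mm, isotropic | the coarser in-plane acquisition spacing; avoids upsampling MR far beyond native resolution |
| interpolation | trilinear | — | bounded (output range ⊆ input range); nearest and cubic available |
| fill value | 0 | intensity | out-of-field voxels after rotation |
| voxel→mm convention | world = index × spacing | — | differences in quantized tables are then exact voxel-size multiples; a half-voxel-center offset is available for interoperability |
| ICC form reported | single-measure ICC(A,1) | — | both forms are computed and emitted; reports default to the stricter single-measure form |
| "worst" rater pair | lowest ICC(A,1) | — | the alternative (highest mean difference) is selectable via `criterion="mean_diff"` |

Difference summaries use absolute differences (mean, sample SD with
ddof = 1, max): they describe selection scatter, not signed bias;
Bland–Altman carries the signed-bias information instead.

### ICC details

Two-way random effects, absolute agreement. With n subjects × k
measurements and mean squares MSR (rows), MSC (columns), MSE (residual):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

The p-value tests H₀: ICC = 0 with F = MSR/MSE on (n−1, (n−1)(k−1)) df;
the general absolute-agreement test's Satterthwaite denominator collapses
to MSE at a null value of zero. Zero-total-variance matrices are perfect
agreement by definition and return r = 1, p = 0 with a `degenerate` flag
rather than NaN (0/0). Intra-rater analysis treats a rater's two attempts
as the k = 2 measurements of the same model.

## What the synthetic generator emulates — and what it does not

`PhantomSpec` defaults describe a realistic adult geometry and the study
design the statistics assume:

- canal radius of curvature 3 mm; inter-labyrinth separation 64 mm; SSCC
  probes 4 mm superior to the canal plane (typical adult labyrinth
  dimensions);
- canal plane tilted 20° from the world horizontal about x;
- 20 patients × 2 modalities × 3 raters × 2 attempts;
- per-patient head pose scatter (SD 3 mm / 4°), per-scan repositioning
  between a patient's CT and MR (SD 2 mm / 2°), plus a fixed systematic
  MR scanner pose (4°, [1.5, −1, 2] mm);
- selection jitter: isotropic Gaussian, SD 0.1 mm per axis (on the order
  of one CT voxel, matching expert-level repeatability); per-rater and
  per-axis SDs are configurable — real raters show larger right–left (X)
  scatter, and tests exercise the anisotropic path;
- quantization: every selection is rounded to the nearest voxel of the
  modality grid (CT 0.15 mm isotropic; MR 0.2604/0.2604/0.3 mm), which is
  why simulated difference tables contain exact voxel-size multiples.

The phantom volumes render each side as the lateral half-arc of a torus
whose endpoints are exactly the two landmarks, a vestibule ellipsoid whose
surface passes through them, and an SSCC knob at the probe point; CT-like
contrast is dark lumen in bright bone, MR-like is bright fluid on dark
background.

Deliberately **not** modelled: anatomical shape variation between
patients (pose varies, shape does not), partial-volume and MR
susceptibility/motion artifacts, intensity inhomogeneity, rater-specific
systematic bias (only zero-mean jitter), and non-planarity of real canals.
Passing tests therefore demonstrate correctness of the geometry and
statistics under the stated measurement model — not that human raters
achieve any particular reliability on clinical images.

## Numerical choices

- Orthonormality/determinant of rotations validated at 1e-10; plane
  normals unit to 1e-12; projections onto the plane verified to 1e-10.
  These are fixed constants, not configuration.
- Degenerate landmark configurations (collinear points, coincident side
  or anterior/posterior midpoints, swapped left/right labels) raise
  errors; silent repair would mask data-entry mistakes in clinical
  tables. The CLI maps malformed input to exit code 2 and degenerate
  geometry to exit code 3.
- Frame comparisons use the Frobenius identity ‖Ra−Rb‖_F = 2√2·sin(θ/2)
  for the rotation angle, which keeps full precision near θ = 0 where
  arccos-of-trace loses digits.
- Resampling composes the output-grid→frame→world→input-voxel affines
  into a single `scipy.ndimage.affine_transform` call; the frame origin
  maps to the output grid's geometric center ((dims−1)/2 in index
  space). Trilinear interpolation is the default because it cannot
  overshoot the input intensity range; cubic can.
- The median (componentwise, mean-of-middle-two for even counts) is used
  to pool repeated selections before frame construction, damping
  outliers without favouring any rater.

## Problem sizes used in the validation suite

Oracle-equivalence and equivariance checks run on 1000 and 500 random
landmark sets; ICC is checked against explicit ANOVA sums on 200 random
20×2 and 20×3 matrices; parameter recovery uses 100 seeds × 20 patients
per jitter level σ ∈ {0.2, 0.1, 0.05, 0} mm; the intra-rater calibration
uses 200 seeds (50 in the acceptance script). Image-level tests use a
scaled-down phantom (16 mm ear separation, 0.5–0.7 mm grids) so volumes
stay small; the acceptance script's jitter-free co-registration check uses
the full-size phantom at acquisition spacing.

One empirical subtlety: frame error decreases with jitter σ only while σ
dominates the quantization scale Δ/√12 ≈ 0.043 mm. At and below that
scale the error saturates at the voxel-quantization floor, and sub-voxel
jitter acts as dither that can nudge the quantized-median error
marginally *below* the σ = 0 value. The recovery tests therefore assert
strict decrease over {0.2, 0.1, 0.05} and floor attainment at σ = 0,
rather than a strict ordering between two statistically indistinguishable
floor values.

## Known limitations

- Rigid registration only: no deformable or intensity-based refinement,
  no automatic landmark detection — landmark tables are the input.
- Frames are only as good as the landmarks; four points give no
  redundancy beyond the plane projection, so a gross mislabel produces a
  grossly wrong frame (hence the strict validation instead of repair).
- Reliability tables for real clinical data can only be recomputed
  from an expert coordinate-selection workbook, which no package can
  ship; the full recomputation pipeline
  (`read_landmark_table(coordinates="voxel")` → `evaluate_study`) is in
  place and tested on synthetic tables of identical structure.
- NIfTI only (no DICOM series); first-sheet-only XLSX reading.
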