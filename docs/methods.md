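# Methods

## Forward model of a 2D multi-slice acquisition

A thick-slice MR stack is modelled as the composition of a through-plane
slice profile and plane sampling. The slice profile is a 1D Gaussian along
the slice-normal axis with standard deviation equal to the slice thickness
`t` in mm (σ = t as stated, not FWHM = t; the kernel is truncated at 4σ and
renormalised to unit sum so constant images are preserved exactly). Planes
are then sampled at the slice distance `d` with a random phase offset
U(0, d) — real stacks are not anchored at the volume edge. Per view,
`t ~ U(3, 8)` mm and `d ~ U(t, t + 4)` mm, giving the 3–12 mm through-plane
envelope of routinely acquired follow-up scans; the two views use distinct
slice axes drawn from {sagittal, coronal, axial}.

On top of the clean degradation the simulator applies, in order: a rigid
inter-view perturbation of the HR frame (rotation U(±2°), translation
U(±2 mm) per axis), per-slice in-plane motion (2D shifts ~ N(0, 1 mm²),
applied to a stack with probability 0.3), Rician noise (σ = 2% of the 99th
intensity percentile), brightness/gamma augmentation
(`v → clip(v + b, 0, 1)^γ`, b ~ U(±0.1), γ ~ U(0.75, 1.33)) and blanking of
one randomly chosen view with probability 0.1. These magnitudes are
config-exposed defaults chosen as conservative values for routine pediatric
head imaging; the artifact *families* are fixed, their sizes are not
canonical. Intensities are windowed to [0, 1] by the 1st–99th percentile
range before augmentation so that gamma is well defined on raw-scaled
images.

Because the two views are misregistered against each other and the
within-stack motion perturbs each view again, there is no single canonical
HR frame. The simulator therefore emits four HR targets per example: the
identity frame, each view's rigid frame, and the geodesic half-way frame
(rotation slerp, mean translation). The training loss scores a prediction
against the closest target (minimum-L1), letting the network commit to one
consistent frame instead of averaging frames into blur. The per-example L1
uses the mean (not sum) of absolute differences so the loss is
patch-size-invariant; the batch reduces by mean.

## Network

The network follows the densely connected super-resolution pattern: initial
3³ convolution, `num_blocks` dense blocks of `units_per_block` units (each
unit: per-channel batch normalisation with affine parameters → ELU → 3³
convolution emitting `growth_rate` features, input = concatenation of all
earlier features in the block), a 1³ compression convolution after each
block, and a final 1³ convolution to one channel. Spatial extent is
preserved everywhere, so the net is fully convolutional over patch size.

Two wiring constants are free in this pattern. They are fixed to
`init_features = 8 × growth` and `compress_to = 2 × growth`, which gives
248,017 trainable parameters — rounding to the published 248K — for the
reference configuration (growth 8, 8 blocks, 4 units, 2 input channels).
An enumeration over the standard variants (initial feature counts, halving
vs fixed compression, cross-block dense wiring, bottleneck units, final 3³
vs 1³) shows this is the variant consistent with that count; cross-block
(multi-level) dense wiring is not.

The output adds the mean of the two input channels to the convolutional
path (a parameter-free global residual): the network predicts the
correction to the linearly fused input rather than the image itself. At
desk scale this is the difference between learning a useful deconvolution
in minutes and spending the whole budget approximating the identity; with
the final convolution zeroed the network reduces exactly to linear fusion,
which the tests exploit as an analytic surrogate for the patch-aggregation
arithmetic.

Whole volumes are reconstructed by tiling overlapping 40³ patches (default
stride 20 mm, i.e. 50% overlap) and averaging overlaps with per-voxel
weights that sum to one; volumes smaller than a patch are reflect-padded
and cropped back. If the native in-plane resolution is finer than 1 mm,
inputs are resampled to 1 mm for inference and the output resampled back.

## Training

Per HR volume, `patches_per_image` random 40³ patches are cropped, each
given a random orientation from the 24-element right-angle rotation group
(arbitrary-angle rotation would break the perpendicular-stack geometry),
degraded into a simulated pair, and upsampled back onto the patch grid as
the 2-channel input. At full scale, 256 patches × 80 volumes = 20,480
examples. Optimisation is Adam (default lr 1e-4 full scale; 1e-2 at desk
scale) with cosine learning-rate decay to zero, batch size 8, a 10%
validation split, and the best-validation state retained. The batch order
is shuffled once from the seed and reused across epochs, making runs
bit-reproducible and a zero learning rate provably a no-op.

## Geometry conventions

World coordinates are RAS, voxel-center based, all distances in mm. Array
axes carry labels named after the slice orientation whose normal they are
(x → sagittal, y → coronal, z → axial). Resampling covers the same
voxel-center extent (`n_out = floor(extent/spacing) + 1`); out-of-grid
samples clamp to the edge value. Interpolation kernels: linear, nearest,
and Lanczos with a = 3 (the standard choice; the windowed-sinc weights are
renormalised to unit sum, which preserves constants and makes half-spacing
resampling exact on affine fields — the property the baseline tests use).
Rigid registration is a pluggable contract (anything maximising a
normalised-correlation similarity may substitute); the default backend is
SimpleITK's Euler 6-DOF transform with the correlation metric over a
3-level multiresolution pyramid, which recovers 2 mm / 2° perturbations on
phantoms to well under 0.5 mm.

## Baselines and metrics

The interpolation-fusion baseline resamples both views to the isotropic
grid (linear or Lanczos), optionally registers view 2 to view 1, z-scores
each view within its head mask, averages voxelwise, and rescales to view
1's statistics (the averaging-in-normalised-units choice; a blanked view is
excluded). PSNR is `10·log10(max(ref)²/MSE)` with the peak taken inside the
evaluation mask when one is supplied; identical images are reported as
unbounded (+inf), not a number. SSIM is computed in 2D slice by slice
(Gaussian window σ = 1.5, K1 = 0.01, K2 = 0.03, population covariance,
data range = reference range) and averaged per orientation and across the
three orientations. NRMSE normalises by the reference intensity range. The
head mask thresholds at half the Otsu level (dark tissue — skull, CSF,
vitreous — must stay inside), closes with a 3 mm ball, keeps the largest
connected component and fills holes. Surface distances use 6-connectivity
boundaries and pool both directions symmetrically: mDTA is the pooled mean,
95HD the pooled 95th percentile — the common radiotherapy-QA convention;
DSC is `2|A∩B|/(|A|+|B|)`.

## Phantoms

The phantom emulates a T1 head at 1 mm isotropic (default 160³): bright
scalp (0.75) over dark skull (0.12), CSF (0.22), a bright brain ellipsoid
(0.62) with dark ventricles, two dark eye spheres (12 mm radius at full
size), a brainstem cylinder, two hippocampal arcs and two optic-nerve tubes
of ≤ 4 mm diameter — thin enough that thick-slice degradation measurably
destroys them, mirroring the clinical finding that optic-nerve contours
suffer most. A smooth multiplicative inhomogeneity field (±8%) and light
texture noise break piecewise constancy. Geometry scales with the grid so
smaller desk-scale phantoms stay proportioned; per-seed jitter moves
positions by ±5 mm and radii by ±10%. The phantom does **not** model
gyral/sulcal texture, k-space artifacts, bias fields of realistic shape, or
pathology, so passing tests demonstrate the pipeline's mechanics and the
method ordering on piecewise-smooth anatomy, not clinical performance.

## Desk-scale experiment sizes

The ordering experiments (`orthosr.experiments`) are sized for minutes on
one CPU, chosen as the package's reference desk scale: 4 training phantoms
of 96³ cropped to the head bounding box (so the small corpus is spent on
anatomy, not empty air), 50 patches each (200 examples) at patch size 16,
the reduced network (growth 4, 4 blocks, 2 units, init 16, compress 8), 20
epochs of cosine Adam at lr 1e-2; evaluation on 20 held-out 40³ patches
centred on head voxels from 2 unseen phantoms at the follow-up profile
(d = 7 mm, t = 5 mm) — centring inside the head mirrors the head-masked
reporting convention for whole images. The desk-scale corpus is degraded
without artifacts: the evaluation condition is artifact-free, and within a
minutes-long budget the artifact stack teaches intensity corrections that
are wrong for clean inputs; the artifacts keep their own unit and property
tests, and full-scale training defaults keep them on.

The contour experiment mirrors the clinical protocol's shape: one simple
auto-contourer (an intensity-band segmenter with morphological closing,
restricted to a region of interest) runs on the reference volume and on
each method's reconstruction, and the reconstruction-derived contour is
compared with the reference-derived one by mDTA. A blurrier reconstruction
smears the structure's intensity signature and displaces the recovered
contour, which is exactly the failure mode the distance metrics measure.

## Known limitations

* The desk-scale margins are modest (fractions of a dB); the experiment
  demonstrates ordering, not the magnitude of the full-scale gains.
* The contour surrogate is sensitive to the training draw: across desk
  training seeds the visual ordering is stable, but the band segmenter can
  fail on an occasional reconstruction (one of three seeds in our runs),
  so the contour ordering is reported for the reference desk model rather
  than aggregated across seeds.
* The registration contract is validated on phantoms with simulated rigid
  motion only; deformable motion is out of scope.
* Lanczos resampling clamps at edges rather than windowing, which can ring
  near high-contrast borders at extreme upsampling factors.
* The numpy network trains small configurations quickly but is not suited
  to the full-scale (multi-GPU, days-long) training regime.
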