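# Methods

## The problem

Cone-beam CT acquires 2D X-ray projections of a patient from many gantry
angles and reconstructs the 3D map of linear attenuation coefficients
mu(x) (mm^-1).  Classical analytic reconstruction (FDK filtered
backprojection) needs dense angular sampling; coordinate-network
("neural-field") approaches instead fit a continuous function mu(x)
directly to the projections by differentiable physics, which degrades far
more gracefully under sparse views and permits extraction at any
resolution.  `mufield` implements both routes end to end on synthetic
phantoms, with four interchangeable input encodings for the neural field,
so the two families can be compared under identical, fully controlled
acquisition conditions.

## Forward model

A point source at distance `sad` from the rotation axis and a flat-panel
detector at distance `sdd` rotate about +z.  For each detector pixel a ray
is cast and the transmitted intensity follows Beer–Lambert:

    I = I0 * exp(-p),      p = integral of mu along the ray,

discretized with a strictly uniform midpoint rule, `p = sum_i mu(x_i) *
delta` with `delta = (t_far - t_near) / n`.  Uniform (rather than
importance-weighted) sampling is deliberate: in transmission imaging every
region of the anatomy contributes to every ray, so there is no surface to
concentrate samples on.  Volumes are sampled trilinearly between voxel
centers; the edge value is held across the outer half-voxel (voxels are
cells, not points) and positions beyond the volume faces contribute 0.

Supervision is in line-integral space, `p = -ln(I/I0)`, which is linear in
mu and much better conditioned than raw intensity; intensity supervision
exists behind a flag since either convention is defensible.

## Field variants

All variants map a world position (never a view direction — attenuation is
isotropic) through an encoder and a ReLU MLP with 128 channels per layer to
a softplus output, guaranteeing mu >= 0 at every training stage:

| variant | encoder                                   | layers | skip | lr    |
|---------|-------------------------------------------|--------|------|-------|
| vanilla | Fourier, L = 10 frequencies               | 8      | 5    | 5e-4  |
| mip     | integrated Fourier over conical frustums  | 8      | 5    | 5e-4  |
| ingp    | multiresolution hash grid, 2^20-row table | 4      | 3    | 1e-3  |
| pixel   | Fourier + 3 pixel-aligned reference views | 3      | 2    | 5e-4  |

The skip connection concatenates the raw encoded input to the given
(1-based) layer's input.  Softplus was chosen over a shifted exponential
for the output nonlinearity because its gradient is bounded; hidden
activation is ReLU.  Initialization is fan-in uniform, fully seeded, with
one deliberate exception: the output bias starts at softplus^-1(0.01), so
the initial field sits at the soft-tissue attenuation scale (~0.01 mm^-1).
A head left at its natural softplus(0) ~ 0.7 over-predicts line integrals
by ~40x, and the violent first updates drive the pre-activation into the
dead softplus tail — the Fourier-encoded variants then never recover.
This single scalar is the difference between the 8-layer variants training
reliably and collapsing to mu = 0.

Variant-specific notes:

* **mip.** Under cone-beam X-ray geometry the natural cone radius is the
  detector pixel footprint back-projected through the source: the radius
  grows as `r(t) = du * t / sdd`.  Each ray segment becomes a conical
  frustum whose exact first and second moments (along-ray mean/variance and
  radial variance) feed the integrated encoding: every frequency-k feature
  is damped by `exp(-0.5 * (2^k pi)^2 * var)`.  Zero variance reproduces
  the plain encoding exactly.
* **ingp.** Per level, the enclosing grid cell's 8 corners are hashed with
  the XOR spatial hash (primes 1, 2654435761, 805459861) modulo the table
  size, or indexed densely when the level's full vertex grid fits in the
  table; corner features are trilinearly blended and levels concatenated.
  The level resolutions grow geometrically from `base_resolution` to
  `finest_resolution`.  Defaults: 8 levels, 2 features per level, base 16,
  `log2_hashmap_size = 20`; the finest resolution tracks the scene's
  largest dimension.  (Lowering the base below 16 to add coarser levels
  was evaluated for small scenes and consistently *hurt* sparse-view
  recovery — fitting capacity at mid frequencies matters more than a
  coarse prior — so the base stays at 16 everywhere.)
* **pixel.** Each 3D sample is projected into 3 fixed reference views,
  bilinearly samples a feature map per view, and the per-view features are
  averaged (points projecting off-panel contribute zeros).  The feature
  extractor is a contract — any image-to-feature-map function with a
  stated downsampling factor; the default is a small conv stack (two 3x3
  conv + pool stages, then a 1-channel-to-128 head, downsample 4) trained
  jointly with the field.  A pretrained backbone can be dropped in but
  nothing requires one.

## Differentiation engine

The networks are small, so the package carries its own reverse-mode
autodiff over NumPy arrays (`mufield.autodiff`): a tape of (parent,
gradient-closure) pairs per tensor, walked in reverse topological order,
with exactly the op set the fields need — dense affine layers, ReLU,
softplus, exp, concatenation, reductions, an embedding gather whose
backward scatter-adds via per-column `bincount`, a fused
gather-blend-reduce for the hash tables, and an im2col conv2d/avg-pool
pair for the feature extractor.  Gradients are only ever taken with
respect to parameters; sample positions and interpolation weights enter as
constants, which keeps both the op set and the tape small.  All training
math is float32; the test-suite validates every op against central finite
differences in float64.  Optimization is plain Adam (beta = 0.9/0.999,
eps = 1e-8, no schedule).

## Training loop

Each iteration draws `batch_rays` rays uniformly at random over all
training pixels (all views pooled), renders them differentiably with the
same midpoint rule as the simulator, and minimizes the mean squared error
against the measured line integrals.  Every `eval_every` iterations the
held-out views (default 2, evenly spaced) are rendered and their mean PSNR
recorded; training stops early once that metric changes by less than 1%
for 3 consecutive evaluations, or at `max_iterations` (default 30,000
single-batch iterations — the batch-iteration reading of a training
"epoch", since a literal epoch over 50 x 512^2 rays x 30K passes is not
meaningful at any scale).

## FDK baseline

Feldkamp–Davis–Kress filtered backprojection, implemented from first
principles for full-scan circular trajectories: detector coordinates are
rescaled to the isocenter plane (`u' = u*sad/sdd`), cosine-weighted by
`sad/sqrt(sad^2+u'^2+v'^2)`, each row convolved (zero-padded FFT, power-of-
two length) with the exact discrete Ram-Lak kernel — `h(0) = 1/(4 du'^2)`,
odd taps `-1/(pi k du')^2` — optionally Hann-apodized, and backprojected
with magnification weight `(sad/L)^2` and angular weight `delta_theta/2`.
The spatial-domain kernel (rather than a sampled `|f|` ramp) keeps the DC
level right, which is what makes the homogeneous-cylinder interior mean
land within a few percent.  Negative voxels are clamped to zero (counted
and logged); a `clamp_negative=False` escape hatch exists because the
pre-clamp operator is exactly linear in the projections and is tested as
such.  No short-scan (Parker) weighting: full 360-degree data is assumed.

## Phantoms

Four archetypes emulate the structural regimes of clinical CT targets:
thin high-contrast rods (extremity bone), an arc of dense tooth-like
superellipsoids (dental), adjacent organ blobs within ~20% of their
surround (abdominal soft tissue), and fine low-contrast branching
filaments (pulmonary vessels).  All are analytic primitives rasterized
onto the grid; the only randomness is primitive placement/size through the
seed, so phantoms are bit-reproducible.  mu is capped at 0.1 mm^-1 and
scaled (soft tissue ~0.02 mm^-1) so typical line integrals land in
[0.5, 5], keeping `exp(-p)` well conditioned.  What these phantoms do NOT
emulate: anatomical texture, polychromatic beam hardening, scatter, or
detector physics — tests passing on them demonstrate correct geometry,
physics, optimization and reconstruction machinery, not clinical-grade
image quality.

## Metrics

* **PSNR** `10 log10(range^2/MSE)`, with identical inputs reported as the
  99 dB cap rather than infinity; `data_range` defaults to the ground-truth
  maximum and is recorded in the report.
* **3D SSIM** with a Gaussian window (sigma 1.5, 11-wide support,
  truncate 3.5 — the 2D standard lifted to 3D), K1/K2 = 0.01/0.03,
  reflect boundaries, mean over all voxels.  Volumes narrower than the
  window are rejected with a pointer at the uniform-7^3 fallback.
* **GMSD** rescales to [0, 255], 2x mean-pools, takes Prewitt gradient
  magnitudes and reports the standard deviation of the gradient-magnitude
  similarity map (c = 170).  The defining formulation is 2D, so volumes
  are scored per axial slice and averaged; an isotropic 3D-Prewitt mode
  exists behind a flag (it is also the permutation-stable variant — the
  slice-wise default is intentionally axis-anchored).

## Experiment runner and problem sizes

`run_experiment` chains phantom -> DRR -> per-variant training -> volume
extraction / FDK -> one metrics table, with per-stage seeds derived via
`SeedSequence(seed, spawn_key=(stage,))`, stage logging, resume, and
best/worst flags per metric column.  All neural variants in a comparison
share the same samples-per-ray and ray batch, so sampling budgets stay
aligned.  The full profile mirrors the publication-scale acquisition
(50 views over 360 degrees, 512^2 detector, 30K iterations); the tiny
profile (32^3 phantom, 32^2 detector, 20 views, batch 256, 32 samples/ray,
2,000 iterations) is the package's desk-scale configuration, sized for a
single CPU.  The sparse-view recovery study uses a 64^2 detector — finer
than the volume, matching the proportions of publication-scale
acquisitions — because with 32^2 views the 20-view ray set under-determines
the 32^3 voxels and recovery is limited by the null space rather than by
the method; 1,200 iterations at 32 samples/ray suffice there.

## Known limitations

* Monochromatic, noiseless physics; additive Gaussian noise on line
  integrals is available but is a statistical stand-in, not a physics
  model.
* The hash table uses dense Adam updates (exact, but wasteful for very
  large tables); no CUDA-style performance engineering is attempted.
* Desk-scale metric values are far below publication-scale ones — with
  32^2-pixel views the detector resolves about 2 mm at the isocenter, so
  volumetric PSNR in the low 20s dB is the expected regime for the tiny
  profile, not a defect.
* Pixel-variant checkpoints persist the MLP and extractor weights but not
  the reference images; after reloading, queries need the reference views
  re-bound (the trainer does this automatically at the end of training).
* Grids are assumed aligned; there is no registration before comparison.
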