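# Methods

## The problem

2D classification of single-particle cryo-EM data groups particle images
of similar projection view so they can be averaged into high-SNR class
images. Because individual particles are recorded at very low SNR
(often 0.01–0.05 as a variance ratio), the in-plane alignment step inside
classification is error-prone, and poor initial alignments propagate into
poor classes. `cryoprepro` implements a pre-processor that improves the
*starting point* of classification without altering the data handed to
the classifier: it estimates alignment parameters on denoised surrogate
particles and applies them to the untouched originals.

## 2SDR denoising

Each image `X_i` (H×W) is kept as a matrix. Stage 1 computes shared
orthonormal row and column bases `U` (H×p0) and `V` (W×q0) as the top
eigenvectors of the mode-wise scatter matrices `Σ_i X_i X_iᵀ` and
`Σ_i X_iᵀ X_i`, and reduces each image to a core `C_i = Uᵀ X_i V`
(a HOSVD-style multilinear reduction; the stage is not centered). Stage 2
vectorizes the cores and fits an ordinary PCA with `r` components (this
stage is centered; covariance uses the 1/(n−1) convention, which affects
only reported eigenvalue scale). The denoised image is
`U · unvec(mean + compsᵀ c_i) · Vᵀ`.

Defaults `(p0, q0, r) = (25, 25, 50)` are the standard working
configuration for cryo-EM particles; ranks are fixed, not adaptively
selected. Cost: the stage-1 eigenproblems are H×H and W×W regardless of
n, and stage-2 PCA sees only p0·q0-dimensional vectors — this is what
makes the method fast compared to PCA on vectorized images.

Numerical conventions: eigenvectors are produced in descending eigenvalue
order with the largest-magnitude entry of each column made positive, so
repeated fits are bit-identical; eigenvalue ties keep solver order. With
full ranks (`p0=H, q0=W, r=n−1`) the pipeline reconstructs the input
exactly (to float tolerance), which the tests assert; with `p0=q0=H` it
reduces to plain PCA on vectorized images.

## Reference-free alignment

The aligner is the classic two-stage scheme: (1) average all particles
into one reference; (2) for each particle, exhaustively search in-plane
rotation ψ and integer shifts (dx, dy) for the pose maximizing the masked
normalized cross-correlation with the reference; re-average under the new
poses and repeat. No external template enters, so poses carry one global
gauge freedom (a common pose applied to all particles changes nothing);
all accuracy statements are therefore gauge-fixed (see below).

Conventions, used consistently everywhere:

- pose = rotate CCW by ψ about the image center, then shift by (dx, dy);
  composition is ψ = ψ₁+ψ₂ (mod 360), d = R(ψ₂)d₁ + d₂;
- scoring mask: raised-cosine disc of radius H/2 − max_shift (falloff
  2 px), which also guarantees the FFT shift search (all shifts scored at
  once per rotation) is *exactly* equivalent to transforming and scoring
  each pose individually — no circular wrap can reach the mask support;
- interpolation: bilinear during search (speed), cubic spline for final
  output (quality); out-of-field pixels take the image's edge-mean value;
  sampling coordinates are rounded at the 1e-9 level so that exact
  quarter-turn poses do not fall off the grid through 1e-16 trigonometric
  round-off;
- tie-break: poses within 1e-9 of the peak correlation count as tied and
  are resolved deterministically (smallest |ψ|, then smallest shift norm,
  then lexicographic), so the fast searcher and a naive every-pose scorer
  agree exactly, including ties;
- defaults: angular step 3°, max_shift = ⌊0.1·H⌋ px, shift step 1 px;
- mirror search is off by default; a grid flag enables it for retrieval
  (the candidate is also scored x-flipped). The iterative aligner does
  not track mirror poses.

Degenerate inputs: a zero-variance image or reference under the mask is
rejected; poses whose masked variance vanishes can never win the search.

## The pre-processing workflow

1. Denoise the stack with 2SDR.
2. Three reference-free iterations on the denoised stack.
3. Apply the resulting poses to the *original* images (this intermediate
   stack seeds the next step only).
4. Two further iterations on the re-positioned originals (a fresh
   reference-free run; the reference restarts from their average).
5. Compose both parameter sets per particle and transform the original
   images **once** (cubic interpolation) — the output seen by a
   downstream classifier is the original data under a single resampling.

The denoised stack is discarded after step 2; denoised pixels never reach
the output. Reverting the composed pose recovers the input to within
interpolation error, and input/output pixel histograms agree up to
interpolation smoothing — the sense in which the pre-processor is
lossless.

## Synthetic data

The generator emulates particles of a rigid macromolecule: projections of
a 3D phantom at a fixed set of views (Fibonacci-lattice directions with a
deterministic in-plane twist; view 0 is the identity, where projection is
the exact axis sum), given uniform random in-plane rotation, sub-pixel
shifts, CTF modulation and white Gaussian noise calibrated so that
var(signal)/var(noise) equals the target SNR. Ground truth (view id, ψ,
dx, dy, defocus) is recorded per particle.

- Phantom: 24 anisotropic Gaussian blobs (widths 3–8% of the box) inside
  a sphere of radius 0.45·box, deterministic from a seed. Blob scale was
  chosen so that distinct views correlate at ~0.85–0.95 under the best
  relative pose: similar enough that retrieval is hard (the regime where
  a pre-processor is worth having), distinct enough to be identifiable.
  The phantom seed is separate from the replicate seed — replicates image
  the same specimen under new noise, poses and defocus.
- CTF: `CTF(s) = −[√(1−A²)·sin χ + A·cos χ]`,
  `χ(s) = π λ Δf s² − (π/2) Cs λ³ s⁴`, underfocus positive, relativistic
  electron wavelength from the accelerating voltage; defaults 300 kV,
  Cs = 2.7 mm, A = 0.07. No envelope decay is applied. At s = 0 the CTF
  equals −A (the contrast sign is not flipped to protein-white).
- Noise is added after the CTF, i.i.d. per pixel (white). Real detector
  noise is colored and real micrographs carry structured background; the
  generator does not emulate either.
- Defocus is drawn uniformly from a configurable range; the benchmark
  conditions use 1.5–2.0 μm.

What passing tests on this generator do **not** show: performance on real
micrographs with colored noise, structural heterogeneity, contamination,
or picking errors — the generator models none of these.

## Evaluation

- `estimate_snr(noisy, signal) = var(signal)/var(noisy − signal)`,
  pooled over the stack.
- Retrieval: "most resembling" = highest masked normalized
  cross-correlation over the exhaustive pose grid (the same objective a
  fast rotational matcher optimizes, searched directly); a retrieved
  particle is a true positive when it shares the query's ground-truth
  view id.
- Alignment error: the single global gauge pose (rotation by circular
  mean, then least-squares shift) is fitted from estimated to true poses;
  medians and RMS of the per-particle residuals are reported. Generative
  poses (projection → particle) are inverted before comparison.

## Benchmark conditions and problem sizes

The seeded benchmark experiments (`cryoprepro.benchmarks`) use sizes a
single CPU handles in seconds per replicate, chosen once:

- SNR gain: 200 particles, 64×64, 8 views, SNR 0.05, default ranks.
- Alignment head-to-head: 150 particles, 64×64, single view, SNR 0.05,
  shift range ±3 px; full workflow (3+2 iterations) versus the same
  five-iteration budget spent directly on the raw stack; 6° angular step,
  max shift 4 px.
- Retrieval: 160 particles, 6 views (≈27 per view, so the 20-nearest
  retrieval depth stays below the per-view membership), k = 20, five
  query particles, SNR 0.05 and 0.01, defocus 1.5–2.0 μm.

## Known limitations

- The pre-processor's benefits are strongest with many particles, where
  the stage-2 eigenbasis is well estimated. At benchmark-scale stacks
  (order 10²), denoising reliably raises measured SNR and improves
  alignment accuracy, but the *retrieval-ordering* advantage (denoised
  retrieval finding more same-view neighbours than raw retrieval) does
  not reproduce: exhaustive NCC on raw 64×64 images is already close to
  the information limit, and every 2SDR reconstruction shares the PCA
  mean component, which inflates correlations of weak-signal candidates
  with any query and dilutes view ranking. With thousands of particles
  the eigenbasis is far better estimated and reconstructions are
  signal-dominated; the package exposes the experiment so larger runs can
  probe that regime.
- The iterative aligner estimates poses on a discrete grid; accuracy is
  bounded below by the grid steps.
- Mirror (flip) poses are searched only in retrieval, not tracked through
  the iterative aligner or pose composition.
- The simulation draws views from a discrete set; continuous orientation
  sampling (and the angular-distance true-positive definition it needs)
  is supported only through the configurable view count.
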