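# cryoprepro

A lossless pre-processor for cryo-EM 2D classification.

Single-particle cryo-EM records each particle at very low signal-to-noise
(SNR 0.01–0.05 as a variance ratio), and the in-plane alignment buried
inside 2D classification is the step that suffers most. `cryoprepro`
inserts between particle picking and classification: it denoises the
particle stack with a fast two-stage dimension reduction (2SDR), extracts
in-plane alignment parameters from the denoised surrogates by iterative
reference-free alignment, and then applies those parameters to the
**untouched original particles**. The classifier receives the original
data, better positioned, under exactly one interpolation — denoised
pixels never reach the output.

## Method in brief

**2SDR denoiser.** Each image `X_i` is kept as a matrix. Stage 1 (HOSVD)
finds shared orthonormal bases `U` (H×p₀), `V` (W×q₀) from the mode-wise
scatter matrices `Σᵢ XᵢXᵢᵀ`, `Σᵢ XᵢᵀXᵢ` and reduces each image to the
core `Cᵢ = Uᵀ Xᵢ V`. Stage 2 vectorizes the cores and applies PCA with
`r` components. Reconstruction `U·unvec(μ + Wᵀcᵢ)·Vᵀ` is the denoised
image. Defaults: `(p₀, q₀, r) = (25, 25, 50)`, fixed ranks.

**Reference-free alignment.** Average all particles into a reference;
exhaustively search each particle's rotation ψ and shift (dx, dy) for
the maximum masked normalized cross-correlation against it; re-average
and iterate. Three iterations run on the denoised stack, the poses are
transferred to the originals, and two further iterations fine-tune the
re-positioned originals. The two pose sets are composed per particle
(ψ = ψ₁+ψ₂, d = R(ψ₂)d₁ + d₂) and applied once.

**Simulation & evaluation.** A synthetic-data module generates
CTF-modulated projections of a deterministic 3D phantom with known view,
pose and defocus per particle, noise calibrated to a stated SNR; the
evaluation module measures SNR, performs rotation/translation-invariant
k-nearest-particle retrieval with true-positive counting, and computes
gauge-fixed alignment-error statistics.

See `docs/methods.md` for conventions, parameters and limitations.

## Worked example

```python
from cryoprepro import (SimulationSpec, simulate_dataset, denoise,
                        TwoSDRConfig, run_prepro, estimate_snr)
from cryoprepro.prepro import PreproConfig
from cryoprepro.align import SearchGrid

spec = SimulationSpec(size=64, n_views=6, n_particles=150, snr=0.05, seed=7)
stack, clean, truth = simulate_dataset(spec)
print(f"simulated {stack.n} particles, SNR = {estimate_snr(stack, clean):.4f}")

den, _ = denoise(stack, TwoSDRConfig().clipped(stack.n, stack.box, stack.box))
print(f"denoised SNR            = {estimate_snr(den, clean):.4f}")

cfg = PreproConfig(grid=SearchGrid(max_shift=4, angular_step=6.0),
                   twosdr=TwoSDRConfig().clipped(stack.n, stack.box, stack.box))
repositioned, total, report = run_prepro(stack, cfg)
print("mean peak cc, denoised alignment :", [round(c, 3) for c in report["mean_cc_denoised"]])
print("mean peak cc, fine-tuning        :", [round(c, 3) for c in report["mean_cc_refine"]])
```

Output:

```
simulated 150 particles, SNR = 0.0501
denoised SNR            = 0.4956
mean peak cc, denoised alignment : [0.453, 0.709, 0.719]
mean peak cc, fine-tuning        : [0.439, 0.452]
```

Reading it: denoising raised the measured SNR roughly tenfold
(0.050 → 0.496); during alignment of the denoised stack the mean peak
correlation against the evolving reference climbed from 0.45 to 0.72 as
the poses converged; the fine-tuning iterations on the re-positioned
*originals* score lower (≈0.45) because they correlate raw noisy pixels,
which is expected — the output stack is the original data, only re-posed.
`repositioned` and `total` are what a downstream classifier and its
metadata table would consume.

## Command line

```
prepro simulate --size 64 --views 6 --n 150 --snr 0.05 --seed 7 \
                --out sim.mrcs --truth truth.star
prepro run --in sim.mrcs --out repositioned.mrcs --params total.star \
           --p0 25 --q0 25 --r 50 --iters-denoised 3 --iters-refine 2 \
           --angular-step 6 --max-shift 4 --report report.json
prepro denoise --in sim.mrcs --out denoised.mrcs
prepro align --in sim.mrcs --iters 3 --params-out params.star
prepro tp-rate --stack sim.mrcs --truth truth.star --k 20 --denoise
```

Stacks are MRC2014 (mode 2) files; parameter tables are single-loop STAR
files with 1-based particle index, ψ in degrees, shifts in pixels and a
mirror flag.

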