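# Methods

## Model and procedure

The codec treats image compression as codebook design. For `vq_direct`
mode an H×W image is edge-replicated to multiples of the block side b = 4,
cut row-major into N = ⌈H/4⌉·⌈W/4⌉ flattened 16-vectors, and quantized
against an M×16 codebook; the stream stores the codebook (float32), one
⌈log₂M⌉-bit index per block, and a 22-byte header. For `ann_vq` mode,
8×8 blocks normalized to [0,1] pass through a 64→p→64 logistic
autoencoder; the p-dimensional hidden activations (p = 16 by default) are
quantized instead, and the network weights are stored in-stream so the
decoder can run the output half. Decoding is deterministic and involves no
random numbers.

Codebook search runs in two stages. The hybrid GA→PSO optimizer explores
ℝ^{M·k} with the reconstruction PSNR as fitness (internally −PSNR is
minimized via its monotone MSE twin, with a finite sentinel for exact
reconstruction so the arithmetic never sees infinities). The GA half uses
random non-replacement pairing, single-point (or per-neuron, for network
genomes) crossover, per-coordinate Gaussian mutation clamped to bounds,
and wins-based selection: each member of the shuffled parent+offspring
pool duels ⌈0.1·2P⌉ distinct random opponents and the P highest win
counts survive (ties by fitness, then index). The PSO half starts from the
GA's final population with zero velocities, pbest at the start positions,
and strict-improvement pbest/gbest updates. Both halves stop early when
the best fitness improves by less than 1e-5 over 50 consecutive
generations. The strided codebook — every ⌊N/M⌋-th training vector — is
injected into the initial GA population, so the search starts no worse
than the classical initialization.

The optimizer's winner is then polished by generalized-Lloyd iterations
under the city-block distortion: nearest-codeword assignment alternates
with per-coordinate **median** updates (the exact L1 centroid; a mean
update optimizes squared error, which is not the distortion this coder
reports). Cells that lose all members are reseeded from the training
vector currently farthest from its codeword — a deterministic repair that
recovers missing prototypes instead of hoping a random redraw lands in
the uncovered cluster. Because a single Lloyd basin can be poor, the
polish is run from several starts — the optimizer's winner, the strided
seed, and three greedy farthest-point seeds — and the lowest-distortion
result is kept. The returned codebook therefore never has higher
distortion than the strided seed (elitism), and on training sets whose
distinct-vector count is ≤ M it reaches zero distortion exactly.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| block side b | 4 (direct), 8 (autoencoder) | px | 16-dim vectors keep VQ tractable; 64-px blocks feed the 64-input net |
| codebook size M | 16 | codewords | 4 bits/block ≈ 0.25 bpp payload at b=4 |
| hidden width p | 16 | units | 4× bottleneck on 64-px blocks; allowed set {2,4,8,16,32,64} |
| population P | 50 (30 in codec defaults) | solutions | 50 is the reference setting; 30 keeps per-image search fast |
| iteration budget T | 100 (40 in codec defaults) | generations | split ⌊T/2⌋ GA / ⌈T/2⌉ PSO |
| opponents fraction q | 0.10 | — | each candidate duels 10 % of the mixed pool |
| stagnation | 1e-5 over 50 generations | fitness units | early stop on plateaus |
| inertia w, c1, c2 | 0.729, 1.49445, 1.49445 | — | constriction-style PSO coefficients |
| vmax | 0.5 | fraction of bound width | velocity clamp |
| mutation | rate 0.1, σ = 0.05–0.1 of bound width | — | per-coordinate Gaussian, clamped |
| learning rate α | 0.5–1.0 | — | per-sample logistic backprop on [0,1] data |
| BP epochs | 60 (codec), 100+ (library) | — | refinement after weight evolution |

SSIM uses K1 = 0.01, K2 = 0.03, L = 255 and is computed globally (one
window over the whole image, population 1/n variances); a sliding-window
implementation is used only as a cross-check in the tests. SNR and NMSE
are signal-power ratios (no standard reference formula accompanies those
names in compression tables; the definitions are printed in the CLI
help).

## Numerical choices

- Pixel ordering is row-major everywhere; blocks are flattened row-major.
- Padding replicates edge pixels, avoiding artificial block-boundary
  energy; reassembly crops, rounds half-up, clamps to [0,255].
- Luma conversion uses integer-rounded BT.601 weights.
- Nearest-codeword ties go to the lowest index; pbest/gbest updates
  require strict improvement; boundary handling is clamping.
- The L1 distance uses absolute values (a signed sum is not a metric).
- Strided initialization uses floor division and 0-based indexing.
- PSNR of an identical pair is +inf (a sentinel, not a cap); inside the
  optimizer the equivalent fitness is capped finite.
- Genome packing is v_ji row-major, v_oj, w_jk row-major, w_ok; a hidden
  node's incoming slice is its v_ji column plus bias (n+1 entries), the
  unit swapped by node crossover.
- Weight init for plain backprop is uniform [−0.5, 0.5]; GenPSO weight
  evolution searches [−1, 1] per coordinate.
- The backprop fitness during weight evolution is evaluated on a fixed
  seed-chosen subset of ≤ 512 blocks; reported losses always use the full
  set.

## What the synthetic phantoms exercise — and what they do not

The generator produces gradients (smooth shading), soft-edged ellipse
phantoms (curved boundaries and flat interiors, loosely Shepp-Logan-like),
block-prototype mosaics with controlled Gaussian noise (the only family
with an analytic codebook ground truth), and uniform noise (the
incompressible control). Mosaics make codebook recovery checkable: with
σ = 0 the four prototypes are literally the optimal codebook and the
trained distortion must hit zero; with σ = 2 each recovered codeword must
sit within 3σ/√(cluster size) of its prototype. Ellipse phantoms drive
the quality-ordering study: at a matched payload of 1/16 bit per pixel
(direct VQ with M = 2 vs autoencoder+VQ with M = 16), the
autoencoder-fronted pipeline beats direct VQ, which beats a random
codebook, in median PSNR over five seeds.

Passing these tests shows the optimization and coding machinery is
correct and that the pipeline ordering holds on images with smooth
anatomy-like structure. It does **not** show clinical adequacy: real
radiographs have modality-specific noise spectra, fine texture, and much
larger dimensions than the 64–256 px phantoms used here, and no claim
about diagnostic quality is made. Problem sizes in the tests and the
acceptance script (128×128 phantoms, populations of 20–30, budgets of
30–40 iterations, five-seed medians) are the package's own choice of a
desk-scale study; all knobs accept larger values.

## Known limitations

- The codec is per-image: codebook and network are trained on the image
  being compressed and shipped with it, so side information dominates at
  small image sizes (both total-stream and payload-only ratios are
  reported for this reason).
- Fixed-length indices; no entropy coding, progressive decoding, region
  of interest, or lossless mode.
- The autoencoder is a single hidden layer with plain per-sample
  backprop — no momentum, batching, or adaptive rates — by design, to
  keep the training rules exactly the classic ones stated above.
- GenPSO is single-threaded and fully deterministic under a seed; there
  is no parallel-island or adaptive-parameter variant.
- 16-bit and color inputs are out of scope (color is reduced to luma on
  read; deeper data is rejected).
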