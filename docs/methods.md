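# Methods

## Model

The package restores motion-corrupted magnitude MR images `y` toward
their motion-free counterparts `x` with a conditional diffusion model
whose forward process is built around the residual `r = y − x` rather
than pure noise. The transition and marginal kernels are

    q(x_t | x_{t−1}, y) = N(x_t ; x_{t−1} + α_t r, γ² α_t I),
    q(x_t | x, y)       = N(x_t ; x + β_t r,       γ² β_t I),

with `α_t = β_t − β_{t−1}` and the convention `β_0 = 0` (hence
`α_1 = β_1`). The reverse posterior given the clean image is Gaussian
with

    mean = (β_{t−1}/β_t) x_t + (α_t/β_t) x,
    var  = γ² (β_{t−1}/β_t) α_t ;

the residual cancels, so sampling never needs `r`. A denoiser
`f(x_t, y, √β_t)` estimating `x` is plugged into the posterior mean at
each of N reverse steps; the chain is initialized at
`x_N ~ N(y, γ² β_N I)`. With `β_0 = 0` the final step has zero variance
and mean equal to the denoiser output, so the sampler with a perfect
denoiser is an exact inverse — this is asserted bit-for-bit in the
tests, and it also means end-to-end quality is bounded by the quality of
the final low-noise denoiser call.

## Schedule

`β_t` interpolates geometrically between `β_1` and `β_N`:

    β_t = β_1 (β_N/β_1)^{w_t},  w_t = ((t−1)/(N−1))^p .

Defaults: `γ = 2`, `β_1 = (0.04/γ)² = 4·10⁻⁴` (so the first state is
statistically indistinguishable from the clean image: its noise std is
`γ√β_1 = 0.04` on images scaled to [0, 1]), `β_N = 0.999`, `p = 0.3`,
N = 20 for training and N = 4 for sampling. Smaller `p` front-loads the
noise. The exponent form is the only continuous reading that attains
both stated endpoints exactly; the endpoints are pinned after the
`exp/log` evaluation so they hold to the last bit. Two float-precision
facts are tolerated deliberately: (a) at extreme growth rates (p = 10
with N ≳ 50) the first increment (~10⁻¹⁷ relative) underflows to a tie,
so construction rejects only *decreasing* sequences; (b) re-summing the
increments reproduces `β` bit-exactly for the default schedules but can
be one ulp off for other (N, p); tests assert exactness where it holds
and ≤ 2 ulp elsewhere.

## Denoiser

`f` is a channels-last U-net over the 2-channel stack (x_t, y):
a 3×3-conv stem, one residual block per resolution level (GroupNorm,
SiLU, two 3×3 convs, FiLM-style additive conditioning from the noise
embedding), stride-2 conv downsampling, nearest-neighbour upsampling
with skip concatenation, and — at the two lowest-resolution levels — a
pair of windowed self-attention blocks (non-shifted + cyclically shifted
windows, learned per-window positional bias, channel LayerNorm, 2× MLP).
The scalar noise level enters as sinusoidal features of `log √β_t`
through a 2-layer MLP. Conditioning on the *continuous* level rather
than the step index is what lets a model trained under the 20-step
schedule serve the 4-step sampler, whose β values differ; the sampler's
four query levels (0.02, 0.33, 0.64, 1.00) lie inside the training range.
The network output is added to a learned linear combination of its two
input channels (initialized to pass x_t through), a useful inductive
bias because at low noise the identity is nearly correct.

Two presets ship: `tiny` (base 16 channels, depth 3, window 4, 2 heads,
~3·10⁵ parameters) — the test and selftest default — and `paper`
(base 64, depth 4, window 8, 4 heads) for users with more compute. The
published architecture's exact widths/depths are not recoverable from
its description; these presets are declared stand-ins. Input grids must
be divisible by `2^(depth−1)` and by the window size at the attention
levels (32/64/96 all work for `tiny`).

The network runs in float32 numpy; gradients come from `autograd`
reverse mode. The 3×3 convolution is registered as a custom primitive
(sliding-window GEMM forward; col2im adjoint) because the generic
slice-gradient path is an order of magnitude slower. Optimization is
Adam (β = 0.9/0.999, ε = 10⁻⁸) with base learning rate 2·10⁻³, a cosine
anneal to a tenth of it, and an exponential moving average of the
weights (decay 0.995) swapped in at the end of training — the optimizer
family, decay shape and weight averaging that diffusion training
conventionally uses, rescaled to desk-size batches (batch 2) and step
counts (2000). Training draws `t ~ Uniform{1..N}` per
batch element, forms `x_t` from the marginal, and minimizes
`mean((f−x)²) + mean(|f−x|)` with equal weights; `l2_only=True` drops
the second term (the ablation switch). Non-finite losses or outputs
abort with a diagnostic.

## Motion simulator

Corruption operates on the centered 2-D FFT of the (real, non-negative)
magnitude image. A slab plan draws widths uniformly from {3..7} until
the severity preset's line budget (minor 7, moderate 10, heavy 15) is
met — the last slab is truncated so the total is exact — and places the
slabs disjointly, uniformly over all feasible packings (via the
bijection between packings and k-subsets of an (m+k)-set). Each slab
carries one rigid motion: rotation uniform in ±7°, in-plane translation
uniform in ±5 mm per axis (converted to pixels by the grid spacing),
applied about the image center in a single bilinear resample with zero
fill. The slab's phase-encode lines are overwritten with the moved
image's lines; the corrupted image is the magnitude of the inverse FFT.

Design choices where the protocol is underspecified: slabs are disjoint
(overlap behaviour is unstated); placement may include the k-space
center (an `exclude_center` flag exists, default off); one motion per
slab (piecewise-constant trajectory); the additive acquisition-noise
term is not simulated by default (a Gaussian `noise_std` flag exists);
the phase-encode axis defaults to rows and is configurable; 3-D volumes
are corrupted slice by slice.

One consequence of the magnitude output is worth stating precisely: the
corrupted *image's* spectrum is not the assembled acquisition k-space —
taking the magnitude discards the imaginary part that the (now
non-Hermitian) spectrum produces, perturbing every line slightly. Exact
line accounting (`count_perturbed_lines`, the acceptance script, and the
line-count tests) therefore compares the assembled acquisition k-space
against the clean spectrum, where untouched lines are bit-identical by
construction and the perturbed-line count is exactly the preset budget.

## Phantoms and what passing tests do and do not show

The phantom generator emulates the gross intensity layout of a
T1-weighted brain slice — bright outer annulus (fat/skull analogue, so
ghosting is visible outside the head), mid-intensity parenchyma with a
smooth modulation, dark ventricle-like and brighter elliptical
inclusions — in [0, 1] on grids of 64 (default) or 128. It is seeded and
deterministic. It does *not* model anatomy, partial-volume texture,
coil-sensitivity shading, Rician noise, or slice-to-slice correlation;
consequently the desk-scale experiments demonstrate that the machinery
learns and inverts this corruption class on structured images, not that
the shipped `tiny` network generalizes to clinical data. On 128×128
phantoms the corrupted-baseline severity averages (NMSE ≈ 0.8/1.4/3.2 %
for minor/moderate/heavy) sit close to the corrupted baselines reported
for real T1 data, which suggests the corruption operator is calibrated
sensibly; at the 64×64 default the same absolute line budgets corrupt a
4× larger fraction of k-space, so baselines are harsher and per-draw
variance is large — severity ordering is therefore asserted on averages
over ≥ 50 phantoms, never single draws.

## Numerical choices and degenerate inputs

Step indexing is 1-based (t = 1..N) with β_0 the only index-0 element.
The core sampler returns its raw float output; the pipeline and CLI clip
restored slices into the [0, 1] normalization range before scoring or
rescaling, since magnitude images are non-negative and values beyond the
per-slice maximum are sampling overshoot.
Schedules are precomputed and immutable. All stochastic operations take
an explicit `numpy.random.Generator`; a single pipeline seed derives
per-stage children, so every artifact is reproducible bit-for-bit
(fixture digests are asserted equal across reruns). The identity rigid
motion returns the input array bit-exactly (no resampling). PSNR returns
an infinity sentinel at zero MSE; NMSE rejects an identically zero
reference; Pearson rejects zero-variance inputs; SSIM uses the standard
11×11 Gaussian window (σ = 1.5, K1 = 0.01, K2 = 0.03) via scikit-image
and is cross-checked in the tests against a directly written
implementation of the defining formula. PSNR/SSIM default their data
range to the per-pair reference maximum, and NMSE is reported in
percent. Metrics are computed per slice and aggregated as mean ± std per
severity level.

## Problem sizes

The shipped experiment sizes are chosen so the full suite runs on one
CPU: phantoms 64×64, 20 phantoms × 3 severities (36 training pairs, 12
held-out), `tiny` denoiser, 2000 training steps at batch 2, 4-step
sampling, Monte-Carlo checks with 3000 pooled chains (16×16) and 10⁵
scalar draws. These sizes are the package's desk-scale defaults, not
statements about the method's ceiling; the `paper` preset and the
pipeline config expose the larger knobs.

## Known limitations

Rigid in-plane motion only (no through-plane, non-rigid, B0 or
susceptibility effects); zero-phase objects (raw phase unavailable in
magnitude inputs); no multi-coil model; no learned schedules; the
training objective is the simplified x-prediction loss, not the full
variational bound; and the `tiny` preset is deliberately far below the
capacity one would use on clinical data.
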