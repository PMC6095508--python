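# Methods

## Model

An image **I** ∈ ℝ^(Nx×Ny) of 8-bit intensities is represented block-wise.
The partition uses square blocks of side N_b (default 16); images whose
sides are not multiples of N_b are mirror-padded (edge-inclusive
reflection, `numpy.pad(mode="symmetric")`) to the next multiple and
cropped after reassembly. A `partial-blocks` policy (smaller edge blocks,
with dictionaries built at the matching lengths) is available but not the
default.

Each block is approximated by orthogonal matching pursuit over a
separable 2D dictionary: the tensor product of two identical 1D
dictionaries, so that atom selection reduces to the argmax of
|Dxᵀ R Dy| over the cross-correlation matrix of the residual. The
implementation maintains, per block:

* the selected atoms A_n (as vectors),
* a Gram–Schmidt orthogonalised set W_n spanning them, with one
  re-orthogonalisation pass applied to every new W (one pass suffices to
  keep pairwise Frobenius inner products below 1e−8 at the block sizes
  used; the pass count is configurable),
* the biorthogonal (dual) set B_n, updated recursively, from which the
  least-squares coefficients are recomputed at termination as
  c(n) = ⟨B_n, I⟩_F.

The residual is downdated by projection on the newest orthogonal
direction, which makes the per-iteration cost O(N²k) for an N×N block.
Stopping: squared-Frobenius residual < ρ, an atom-count cap (default: the
block pixel count), a numerically zero selection score (≤ 1e−12 relative
to the block norm), or a new direction with ‖W‖_F < 1e−12 — the last
guards the division by ‖W‖² when an atom is numerically dependent on the
span; the pursuit then stops without adding it and reports the reason.
Argmax ties resolve to the smallest (ℓx, ℓy) in row-major order, fixing
the streams bit-for-bit across runs.

## Dictionaries

Per direction, the mixed dictionary is the ordered union of

1. a redundant cosine dictionary: atom n has components
   cos(π(2i−1)(n−1)/(2M)), i = 1..N, unit-normalised, n = 1..M;
2. a redundant sine dictionary: components sin(π(2i−1)n/(2M));
3. translates (stride 1, full support only — clipped translates are
   excluded) of short prototype pulses.

M defaults to 2N per trigonometric family. The prototype families differ
by domain: pixel-intensity blocks use an impulse and the discrete hats
(1,2,1)/‖·‖ and (1,2,3,2,1)/‖·‖; wavelet-coefficient blocks use an
impulse and the oscillating pulses (1,−1)/√2 and (1,−2,1)/‖·‖. These
defaults are this package's choice of smooth-bump versus oscillatory
prototypes for the two domains; a config hook loads arbitrary prototype
vectors from a text file (one whitespace-separated prototype per line)
when a specific prototype set must be replicated. For N = 16 the mixed
pixel dictionary has 106 atoms (64 trigonometric + 42 translates), mutual
coherence 0.94, and full rank N.

A practical consequence of that coherence: greedy pursuit cannot
guarantee exact support recovery of arbitrary sparse combinations.
Empirically, 5-atom blocks drawn uniformly from the 16×16 mixed
dictionary are exactly recovered in roughly 4 out of 5 seeds; failures
select a coherent neighbour first and then need extra atoms. The
recovered coefficients are always least-squares optimal on whatever
support is selected (they match a pseudo-inverse oracle to ~1e−14).

## Wavelet-domain path

In wavelet mode the (padded) image is transformed as a whole before
partitioning — CDF 9/7 (`bior4.4`), 3 levels, periodised boundaries, via
PyWavelets — and the inverse transform is applied after the blocks are
reassembled at decode time. Periodisation keeps the coefficient array the
same shape as the image (padded sides are multiples of 16, hence of
2³) and reconstruction exact to machine precision. The residual budget is
applied to transform coefficients; since CDF 9/7 is biorthogonal, not
orthogonal, coefficient-domain error only approximates pixel-domain MSE,
so achieved PSNR is always re-measured in pixel space and the Δ-tuning
loop absorbs the discrepancy. The family and depth are configurable.

## Quality budget and rate control

A global PSNR target converts to a uniform per-block budget
ρ_q = n_pixels(q) · 255² · 10^(−(target+margin)/10). The margin (default
0.75 dB) buys headroom for the quality later lost to quantisation.
Because the pursuit stops at the first iteration *under* budget, the
unquantised approximation typically overshoots the adjusted target by
up to ~1 dB.

Quantisation: m = ⌈(|c| − θ)/Δ⌉ for |c| ≥ θ, with θ = 1.3Δ; coefficients
below θ, or exactly at it (⌈0⌉ = 0), are dropped together with their
atoms — magnitude 0 is not representable in the coefficient stream while
keeping unique index recovery. Decoding uses the mid-bin level
Δm + (θ − Δ/2), so every surviving magnitude is reconstructed within Δ/2.
Dropping never adds coefficients, so the sparsity ratio never decreases
under quantisation.

Rate control bisects Δ geometrically (Δ is a scale parameter) until the
decoded PSNR is within ±0.1 dB of the target or 40 iterations. The
initial bracket [1e−4, 10] is widened geometrically (×4, capped at 1e5)
when the decoded PSNR at the upper end still exceeds the target, which
happens on very sparse content: few, large coefficients make quantisation
noise weak at any fixed Δ. An unreachable target (even the unquantised
approximation falls short) is reported via `converged=False` with the
best achieved code, never raised. Rate-control PSNR is evaluated on the
un-rounded decoded array; final decoding to an image clips to [0, 255]
and rounds, which costs well under 0.5 dB at the qualities of interest.

## Streams and container

Index pairs linearise as o = (ℓx − 1)·My + ℓy (recorded in the header, so
containers are self-describing). Per block, sorted indices are stored as
a first value plus positive differences; 0 separates blocks (Q − 1
separators; an empty block contributes an empty segment). Magnitudes and
sign bits (0 = +, 1 = −) are plain concatenations in index order. The
HDF5 layout is `/streams/{st_ind, st_cf, st_sg}` plus `/header`
attributes (Δ, θ-factor, geometry, domain, dictionary configuration and
its hash, maximum valid index, stream metadata). Streams take the
smallest unsigned width (8/16/32/64) that holds their maximum; signs are
packed 8 per byte. Optional deflate (levels 1–9) is off by default: the
scheme deliberately contains no entropy-coding stage, and bits-per-pixel
is accounted as 8 × (stream payload bytes)/(Nx·Ny). Decoding validates
separator count, stream-length consistency and index bounds, raising a
container-corruption error otherwise.

## Metrics

PSNR uses the 8-bit peak (2⁸−1)², with an infinite sentinel at MSE = 0.
MSSIM delegates to scikit-image's `structural_similarity` with the
standard parameters — 11 × 11 Gaussian window, σ = 1.5, K1 = 0.01,
K2 = 0.03, dynamic range 255, no pre-downsampling — and is cross-checked
in the tests against an explicit windowed-loop implementation (agreement
to 1e−6; window choice matters only in the fourth decimal). The global
sparsity ratio is pixels over stored coefficients; the per-block map of
k_q (inverse local sparsity) is exported as an 8-bit PNG (rescaled to
0–255, brightest = least sparse) and as a numeric text grid.

## Synthetic data

The phantom generator supplies the study inputs; all phantoms are seeded
and bitwise reproducible.

* `atoms`: every 16 × 16 block is an exact combination of 5 distinct
  separable dictionary atoms (defaults), coefficient magnitudes uniform
  in [1, 2] with random signs (signs are randomised so the sign-bit
  stream is actually exercised); the generating decompositions are
  returned as ground truth. These test exact recovery and the codec path;
  their pixel values live on the coefficient scale, not the 8-bit scale.
* `smooth`: a seeded mixture of six low-frequency 2D cosines (up to 3
  cycles per side) scaled into [20, 235], with optional additive Gaussian
  noise. This emulates the smooth large-scale structure of radiographs —
  it does *not* contain sharp anatomical edges, film grain, collimation
  borders or annotations, so passing tests speak to the pipeline's
  correctness and to broad rate/sparsity trends, not to clinical
  image quality.
* `mixed`: atoms blocks in the top half, smooth content in the bottom.

Default problem sizes in the tests and the acceptance script — 128 × 128
phantoms (64 blocks), 100 recovery seeds, 50 oracle blocks, 100 round-trip
phantoms, 20 domain-trend seeds — are chosen so the whole suite completes
in well under a minute while every block-level code path (padding, empty
blocks, both domains, all stream dtypes) is exercised.

## Known limitations

* Exact support recovery degrades with dictionary coherence (see above);
  this is a property of greedy pursuit, not of the implementation.
* Blocks larger than ~24 × 24 make full OMP2D expensive; dedicated
  large-block solvers are out of scope here.
* The per-block budget is uniform; no bit allocation across blocks is
  attempted, matching the scheme's design.
* bits-per-pixel counts stream payload only (headers are excluded), and
  no entropy coding is applied, so reported rates are upper bounds on
  what the same streams would cost after a lossless coding stage.
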