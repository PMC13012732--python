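# Methods

This note documents the models, algorithms and numerical choices behind the
package, and what its synthetic-data experiments do and do not show.

## Contact maps and preprocessing

A `ContactMap` is a symmetric n×n matrix of non-negative interaction values
for one chromosome at a fixed bin size; bins are 0-based and genomic
intervals half-open (BED convention). Input asymmetric beyond a 1e-6
relative tolerance is rejected; smaller asymmetry is averaged away.

**KR balancing.** `kr_normalize` implements Knight–Ruiz matrix balancing
(inner–outer Newton iteration with a conjugate-gradient inner solve) and
returns a diagonal scaling x with `diag(x)·A·diag(x)` having unit row sums
on unmasked bins. Bins with fewer than `min_nonzeros` nonzero entries
(default 1% of n, at least 1) are masked before balancing because the
iteration diverges on near-empty rows. The test oracle is an independent
symmetric Sinkhorn fixed-point iteration.

**Coverage downsampling.** Low-coverage maps are produced by binomial
thinning of raw integer counts on the upper triangle (each read retained
independently with probability r), mirrored to preserve symmetry —
the read-level model of shallow sequencing. Thinning therefore precedes
normalization in the canonical pipeline; both maps are KR-balanced
independently afterwards. A deterministic scalar mode
(`downsample(..., mode="scale")`) exists for comparison when only
normalized values are available.

**Dynamic range.** Balanced maps are rescaled to a count-like total
(`prepare_map`), clipped at 255 and divided by 255, so network inputs lie
in [0, 1]. When a low-coverage map is prepared for comparison or
enhancement against deeper data, it is rescaled to the matched total
(its own total divided by the retention ratio) — standard sequencing-depth
normalization, so paired maps share a dynamic range. The clip ceiling is
configurable; 255 follows common practice in Hi-C restoration pipelines.

**Tiling.** Maps are split into non-overlapping `patch_size`×`patch_size`
(default 40×40) tiles; trailing bins that do not fill a tile are dropped
and reported. An optional diagonal band keeps only tiles with
|row0 − col0| ≤ band; re-assembly averages (i, j) and (j, i) where both are
covered, mirrors where only one is, and flags uncovered cells. The default
chromosome split assigns 2/6/10/12 to validation and 4/14/16/20 to test.

## The S6 selective scan

The continuous system h' = A h + B x, y = C h is discretized by the
zeroth-order hold: Ā = exp(ΔA), B̄ = (ΔA)⁻¹(exp(ΔA) − I)·ΔB. For diagonal A
these are elementwise closed forms using φ(x) = (eˣ − 1)/x (series-expanded
near 0). The recurrence h_t = Ā h_{t−1} + B̄ x_t with h₀ = 0 is evaluated
sequentially; in the time-invariant case it equals the causal convolution
with kernel K̄ = (CB̄, CĀB̄, …), verified to 1e-5 relative tolerance over
random stable systems (float accumulation over T steps motivates the
tolerance).

In the selective scan, B, C and Δ are per-step linear functions of the
input token. **The decay A is likewise input-dependent by default**,
parameterized A = −exp(W_A x + b_A) so it is strictly negative (stable);
the projection is zero-initialized, so A = −1 at the start of training and
input dependence is learned. The standard alternative — a static learned
A = −exp(A_log), as in mainstream Mamba implementations — ships behind
`input_dependent_a=False`. Δ positivity comes from a softplus with bias
initialized so initial timescales lie in [0.001, 0.1] per channel. A
learned per-channel skip D·x_t is added to the scan output. The state size
`d_state` defaults to 16 (8 or 4 in desk-scale configurations).

**Implementation.** The trainable scan is a fused primitive with an
analytic backward pass. With numba present it is an exact sequential JIT
kernel (float64); otherwise a chunked cumulative-sum formulation is used,
h_t = exp(S_t)(h_in + Σ_{r≤t} exp(−S_r)·B̄_r x_r) with S the running sum of
ΔA, chunk length 64, and ΔA floored at −8 per step (a decay below e⁻⁸ is
numerically indistinguishable from a reset). The two paths agree to
float32 rounding, and both are tested against an independent step-by-step
interpreter of the selective-scan algorithm.

## Network architecture

Input 3×3 convolution lifts the 1-channel patch to C = 32 channels (E₁).
Each encoder stage applies two holistic scan blocks then a 2×2 stride-2
convolution doubling channels (E₂: 2C at H/2, E₃/bottleneck: 4C at H/4).
The decoder mirrors with 2×2 transposed convolutions, concatenates the
matching encoder features, and fuses with a 1×1 convolution back to the
stage width. A final 3×3 convolution (small-scale init, 0.1× Glorot)
projects to one channel, and the input patch is added as a global residual
so the network starts near the identity and learns a correction — standard
restoration practice; both the residual and the fusion scheme are package
design choices where the architecture description leaves the operator
unspecified.

The holistic scan block is pre-norm residual, Transformer style:
x ← x + SS2D(LN(x)); x ← x + LEFN(LN(x)). SS2D's four path orders are
fixed as row-major, reversed row-major, column-major, reversed
column-major; each path has its own input/output linear projections at
d_inner = channels and its own scan parameters (the "minimal" variant). A
gated variant (input projection to 2×channels with a SiLU gate) is
available via `ss2d_variant="gated"`. LEFN is 1×1 → GELU → 3×3 → GELU →
1×1 → GELU with channel expansion factor `lefn_expansion` (default 1; with
full 3×3 convolutions larger expansions dominate the compute budget).
`use_ss2d`/`use_lefn` switch one branch off for ablation probes.

**MACs accounting.** `count_macs` mirrors the forward pass analytically:
convolutions cost out-elements·k²·C_in·C_out (one kernel tap per output for
the 2×2 stride-2 transposed convolution), linear projections in·out per
position, and the scan is counted op-by-op per (step, channel, state):
B/C/Δ/A projections as linears, 4 multiplies for the ZOH discretization,
3 for the recurrence and readout, 1 per channel for the D skip. Norms,
activations, biases and residual additions are excluded. Under this
convention the default configuration costs 39.15 GMACs on a 320×320 input,
and the count is exactly linear in pixel count (every layer is
convolutional or per-position).

**Effective receptive field.** The probe averages |∂y_center/∂x| over ≥16
standard-normal inputs and max-normalizes. At initialization the scan
network places measurable gradient mass (>1e-6 of the maximum) at all four
input corners; the LEFN-only control is exactly zero there, since its
receptive field is a finite convolutional radius (~19 pixels at the probe
scale).

## Training

`HiCMambaModel.fit` minimizes patch-level L1 with Adam (batch 64, lr 1e-4,
β = (0.9, 0.999) by default), shuffling with a seeded generator, clipping
gradients at global norm 1.0 (configurable off), evaluating validation
L1 each epoch, keeping the best-validation checkpoint, and early-stopping
after 10 non-improving epochs. Epoch count and the selection criterion are
package choices (the training protocol they extend specifies optimizer,
batch size and learning rate but not these). Everything is reproducible
bit-for-bit given the seed. Checkpoints are single-file archives of named
weight arrays plus a JSON config snapshot.

## Synthetic data

`generate_pair` draws counts from a Poisson (optionally negative-binomial)
model around λ_ij ∝ (|i−j|+1)^(−α) with α = 1 (canonical contact-probability
decay), multiplied by a TAD enrichment when both bins fall in the same
planted block and by 2-D Gaussian loop bumps (width 1 bin); λ is scaled so
the expected upper-triangle total equals `total_reads`. The standard
fixture is a 400-bin (4 Mb at 10 kb) chromosome with 3 TADs
(enrichment 2–3), 12 loops (strength 6) and 2M reads — chosen so the
high-coverage map has clearly resolvable structure while its 1/16 thinning
is visibly degraded, the regime the enhancement task targets. The
generator emulates distance decay, domains, focal peaks and sampling
noise; it does not emulate A/B compartment checkerboards (beyond the
metric tests' toy), mappability/GC bias, translocations, or
inter-chromosomal contacts — so passing tests demonstrate the machinery
and the learning direction, not performance on real genomes.

## Desk-scale experiments

`experiments.denoising_improvement` runs the full pipeline on one standard
fixture: thinning at 1/16, KR balancing, depth normalization, clip/scale,
diagonal-band tiling (10 diagonal 40×40 tiles; 7 train, 3 held out), and
50 epochs of the tiny configuration (C = 8, d_state = 4, batch 8,
lr 1e-3). The tiny width, small state, diagonal band and raised learning
rate are sizings for a single CPU; the diagonal band also concentrates
training where Hi-C signal (and the planted structure) lives, mirroring
the near-diagonal focus of patch-based enhancement pipelines. Across seeds
0–9 the held-out PCC against the target improves over the raw input in
10/10 runs (typical gains 0.02–0.04 absolute).

## Metrics

Pixel inclusion for PCC/SRCC: upper triangle, optional distance band,
masked bins excluded; per-chromosome values aggregate by unweighted mean.
The random-walk concordance score row-normalizes each map to a transition
matrix (zero rows stay zero), takes t = 3 steps by default, and returns
1 − d/2 with d the mean L1 row difference over non-empty rows. The
spectral score compares the first 20 normalized-Laplacian eigenvectors
with per-pair sign alignment, mapped to [0, 1] via 1 − Sd/(n_eigen·√2).
The compartment score correlates the leading eigenvectors (PC1) of the
observed/expected correlation matrices in absolute value; PC1 orientation
is not anchored to GC content or gene density (no external tracks at this
scale), a known limitation — the absolute value makes the score
orientation-free but cannot label which compartment is "A". Expected
values per diagonal are means over unmasked pixels; empty diagonals are
skipped. These definitions follow the cited methods' conventions but are
this package's own implementations; exact numeric parity with the original
tools' defaults is not claimed.

## Structure statistics

Loop matching: a predicted loop is validated when a reference loop on the
same chromosome has both anchor midpoints within ±1 bin (closed interval;
tolerance configurable — reported proportions depend on it, so it is
surfaced prominently in the API). Boundary support uses ±1 bin closed
intervals likewise. The two-cell-line weighted score W_l^s =
P_l^s / Σ_l' P_l'^s with P_l^s = A_l^s/N_l is computed in exact rational
arithmetic, so Σ_l W_l^s = 1 holds exactly; zero denominators are flagged
missing rather than scored 0. Distance-matched non-loop controls are drawn
with a seeded generator to have the identical multiset of anchor distances
while avoiding all true loops; intensity comparisons use a Mann–Whitney
rank test (normal approximation), flagged underpowered below 3
observations per group.

## Degenerate inputs and tie-breaks

Zero-variance pixel sets make correlations undefined: reported as missing,
never 0. Constant matrices have no leading-eigenvector direction: error.
Eigenvector sign ambiguity is handled by per-pair alignment (spectral
score) or absolute correlation (compartment score); degenerate eigenvalue
multiplicities can still make eigenvector comparisons basis-dependent,
which is why the spectral score is tested through identities and
perturbations rather than closed-form toy spectra.

## Known limitations

- Full-scale benchmark numbers require deep real Hi-C data and GPU-scale
  training; this package demonstrates correctness and learning direction
  at desk scale only.
- The sequential scan is O(T) per layer but interpreter-bound in its numpy
  fallback; numba is strongly recommended.
- Multi-resolution coolers, `.hic` binary files and inter-chromosomal maps
  are out of scope.
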