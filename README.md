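# hicmamba

Resolution enhancement of Hi-C chromatin contact maps with a selective
state-space-model (SSM) UNet, plus the surrounding toolchain: Knight–Ruiz
matrix balancing, coverage downsampling, patch tiling, reproducibility
metrics (PCC, SRCC, distance-stratified PCC, random-walk concordance,
spectral score, compartment score), and 3D-genome structure validation
statistics for chromatin loops and TAD boundaries.

## The problem

Hi-C measures genome-wide interaction frequencies between pairs of genomic
bins, yielding a symmetric contact matrix per chromosome. Deeply sequenced
(high-coverage) maps resolve fine structures — topologically associating
domains (TADs) and point-to-point chromatin loops — but most datasets are
shallow, and the resulting sparse, noisy maps blur those structures. This
package trains an image-restoration network to predict the high-coverage
map from a low-coverage one, processing the matrix as non-overlapping
40×40 patches.

## The model

The network is a UNet auto-encoder whose stages are built from *holistic
scan blocks*, pre-norm residual blocks combining:

- **SS2D** (2-D selective scan): the feature map is flattened along four
  traversal paths (row-major, reversed row-major, column-major, reversed
  column-major); each path is processed by an independent S6 selective-scan
  state-space model and the four restored maps are summed. The S6 recurrence
  is the zeroth-order-hold discretization of `h'(t) = A h(t) + B x(t)`,
  `y(t) = C h(t)`:

      Ā = exp(ΔA),  B̄ = (ΔA)⁻¹(exp(ΔA) − I)·ΔB,
      h_t = Ā h_{t−1} + B̄ x_t,  y_t = C h_t,

  with A, B, C and the timescale Δ produced per step by learned linear maps
  of the input (selective scan). In the time-invariant case the scan equals a
  causal convolution with kernel `K̄ = (CB̄, CĀB̄, …, CĀ^{T−1}B̄)`, which the
  test suite uses as an oracle. The scan gives a *global* receptive field at
  cost linear in the number of pixels.
- **LEFN** (locally-enhanced feedforward): a 1×1 → 3×3 → 1×1 convolution
  stack with GELU activations, supplying the local receptive field the
  sequential scan lacks.

Training minimizes the mean absolute error (L1) between enhanced and target
patches with Adam (defaults: batch 64, lr 1e-4, β₁ = 0.9, β₂ = 0.999);
chromosomes 2/6/10/12 validate, 4/14/16/20 test, the rest train. The default
width is C = 32 with two blocks per encoder stage, decoder stage and
bottleneck. An analytic multiply-accumulate counter reports the forward-pass
cost (≈39 GMACs at 320×320 for the default configuration, scaling linearly
with pixel count), and an input-gradient probe visualizes the effective
receptive field.

Everything — the scan, the network, backpropagation, Adam — is implemented
in numpy (`hicmamba.nn`), with numba-JIT kernels accelerating the scan when
available. No GPU is needed at the package's desk scale.

## Worked example

Train the tiny configuration on one synthetic 400-bin chromosome (4 Mb at
10 kb bins) with planted TADs and loops, thinned to 1/16 coverage:

```python
from hicmamba.synthetic import standard_spec, generate_pair
from hicmamba.model import prepare_map, HiCMambaModel, TrainConfig
from hicmamba.network import NetworkConfig
from hicmamba.preprocess import clip_and_scale, tile_patches

spec = standard_spec(seed=0)                       # 3 TADs, 12 loops
high, low, loops, bounds = generate_pair(spec, ratio=1/16)
high_s = clip_and_scale(prepare_map(high), 255.0)  # KR balance, clip, scale
low_s = clip_and_scale(prepare_map(low, target_total=low.values.sum()*16), 255.0)
patches, _ = tile_patches(low_s, high_s, patch_size=40, max_distance_bins=0)
res = HiCMambaModel(patches[:7], patches[7:],
                    NetworkConfig(base_channels=8, d_state=4),
                    TrainConfig(batch_size=8, lr=1e-3, epochs=50, seed=0)).fit()
print(res.summary())
```

prints

```
HiCMamba enhancement model
==========================================
base channels (C):      8
blocks per stage:       2
d_state:                4
SS2D variant:           minimal
parameters:             94393
epochs run:             50
best epoch:             46
final train L1:         0.087108
best validation L1:     0.083387
validation PCC (best):  0.9334
```

On the three held-out diagonal patches the raw low-coverage input correlates
with the high-coverage target at PCC 0.931; the enhanced prediction reaches
0.949 (seed 0; across seeds 0–9 the improvement holds in 10/10 runs, e.g.
0.894 → 0.930, 0.926 → 0.962). `res.enhance(map)` applies the model to a
whole contact map (tile → forward → assemble), and
`hicmamba.metrics.evaluate_pair` scores any two maps with all five metrics.

The same pipeline is scriptable:

```sh
hicmamba simulate --out fixtures --seed 0
hicmamba preprocess --input fixtures/high_r16.txt --format dense --ratio 0.0625 \
    --seed 0 --out patches.npz
hicmamba train --patches patches.npz --base-channels 8 --d-state 4 --out model.npz
hicmamba enhance --checkpoint model.npz --input fixtures/low_r16.txt --out enhanced.txt
hicmamba evaluate --pred enhanced.txt --target fixtures/high_r16.txt --out report.json
hicmamba count-macs --input-side 320
```

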