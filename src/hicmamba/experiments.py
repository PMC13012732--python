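"""Self-contained desk-scale experiments on synthetic fixtures.

These drive the full pipeline (simulate -> preprocess -> fit -> enhance
-> evaluate) at sizes a single CPU handles in seconds-to-minutes, and
are what the test suite runs.  The denoising experiment trains the
network on one synthetic chromosome and asks whether enhancement
increases the pixel-level Pearson correlation with the high-coverage
target on held-out patches, compared to the raw low-coverage input —
the directional, scaled-down analogue of full-scale benchmarking.
"""

from __future__ import annotations

import numpy as np

from .metrics import pcc
from .model import HiCMambaModel, TrainConfig, prepare_map
from .network import NetworkConfig
from .preprocess import clip_and_scale, tile_patches
from .synthetic import standard_spec, generate_pair

#: desk-scale training configuration: C=8 network, small state, diagonal
#: patches only, 50 short epochs — sized for a single CPU
TINY_NET = dict(base_channels=8, d_state=4, patch_size=40)
TINY_TRAIN = dict(batch_size=8, lr=1e-3, epochs=50, early_stop_patience=10)


def denoising_improvement(seed: int, ratio: float = 1 / 16,
                          n_bins: int = 400, band_bins: int = 0,
                          n_holdout: int = 3, max_value: float = 255.0,
                          net_kw: dict | None = None,
                          train_kw: dict | None = None) -> dict:
    """Train on one synthetic map; compare held-out PCC before/after.

    The low-coverage map is depth-normalized to the high-coverage total
    (its own total divided by the retention ratio) before clipping and
    scaling, so both maps share a dynamic range.  Returns the held-out
    PCC of the raw input and of the enhanced prediction against the
    target, and the improvement flag.
    """
    spec = standard_spec(seed=seed, n_bins=n_bins)
    high, low, _loops, _bounds = generate_pair(spec, ratio)
    high_s = clip_and_scale(prepare_map(high), max_value)
    low_s = clip_and_scale(
        prepare_map(low, target_total=low.values.sum() / ratio), max_value)
    patches, _ = tile_patches(low_s, high_s, patch_size=40,
                              max_distance_bins=band_bins)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patches))
    held = [patches[i] for i in order[:n_holdout]]
    train = [patches[i] for i in order[n_holdout:]]
    ncfg = NetworkConfig(**{**TINY_NET, **(net_kw or {})})
    tcfg = TrainConfig(seed=seed, **{**TINY_TRAIN, **(train_kw or {})})
    res = HiCMambaModel(train, held, ncfg, tcfg).fit()
    x = np.stack([p.low for p in held])[:, None].astype(np.float32)
    y = np.stack([p.high for p in held])
    pred = res.predict_patches(x)[:, 0]
    pcc_low = pcc(x[:, 0].ravel(), y.ravel())
    pcc_enh = pcc(pred.ravel(), y.ravel())
    return {"seed": seed, "pcc_low": pcc_low, "pcc_enhanced": pcc_enh,
            "improved": pcc_enh > pcc_low, "results": res}


def denoising_improvement_rate(seeds, **kw) -> dict:
    """Run :func:`denoising_improvement` over several seeds."""
    runs = [denoising_improvement(s, **kw) for s in seeds]
    for r in runs:
        r.pop("results")
    return {"runs": runs,
            "n_improved": sum(r["improved"] for r in runs),
            "n_total": len(runs)}


__all__ = ["denoising_improvement", "denoising_improvement_rate",
           "TINY_NET", "TINY_TRAIN"]
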