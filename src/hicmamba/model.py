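"""Model/Results interface for training and whole-map enhancement.

:class:`HiCMambaModel` is constructed from paired low/high-coverage
patches; :meth:`HiCMambaModel.fit` minimizes the mean-absolute (L1)
reconstruction error with Adam and returns a :class:`HiCMambaResults`
carrying the fitted weights, the per-epoch training log, a ``summary()``
table, checkpoint save/load, and whole-map :meth:`HiCMambaResults.enhance`
(tile -> forward -> assemble -> inverse scaling).

Training is fully reproducible given the seed: deterministic weight
initialization, data order and (binomial thinning upstream) fixtures.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .contact import ContactMap
from .network import HiCMambaNet, NetworkConfig, l1_loss
from .nn.autograd import Tensor
from .nn.layers import Adam, DTYPE
from .preprocess import (PatchPair, tile_patches, assemble_patches,
                         clip_and_scale, kr_normalize, rescale_to_total)
from .metrics import pcc


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam, constant learning rate)."""

    batch_size: int = 64
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 100
    seed: int = 0
    device: str = "cpu"
    checkpoint_dir: str | None = None
    early_stop_patience: int = 10
    grad_clip_norm: float | None = 1.0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 < self.beta1 < self.beta2 < 1):
            raise ValueError("require 0 < beta1 < beta2 < 1")


@dataclass
class TrainLog:
    """Per-epoch losses and the best-checkpoint pointer."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_pcc: list = field(default_factory=list)
    best_epoch: int = -1
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _stack(patches: list[PatchPair], which: str) -> np.ndarray:
    arrs = []
    for p in patches:
        v = getattr(p, which)
        if v is None:
            raise ValueError(f"patch lacks {which!r} values")
        arrs.append(v)
    return np.stack(arrs)[:, None].astype(DTYPE)


class HiCMambaModel:
    """Enhancement network specified by patch data and configurations."""

    def __init__(self, train_patches: list[PatchPair],
                 val_patches: list[PatchPair] | None = None,
                 net_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not train_patches:
            raise ValueError("need at least one training patch")
        self.net_config = net_config or NetworkConfig()
        self.train_config = train_config or TrainConfig()
        self.x_train = _stack(train_patches, "low")
        self.y_train = _stack(train_patches, "high")
        if val_patches:
            self.x_val = _stack(val_patches, "low")
            self.y_val = _stack(val_patches, "high")
        else:
            self.x_val = self.y_val = None

    def _eval_loss(self, net: HiCMambaNet, x: np.ndarray, y: np.ndarray,
                   batch: int) -> tuple[float, float | None]:
        losses, preds = [], []
        for a in range(0, len(x), batch):
            out = net(Tensor(x[a:a + batch])).data
            preds.append(out)
            losses.append(np.abs(out - y[a:a + batch]).mean() * (len(out)))
        pred = np.concatenate(preds)
        loss = float(sum(losses) / len(x))
        corr = pcc(pred.ravel(), y.ravel())
        return loss, corr

    def fit(self, verbose: bool = False) -> "HiCMambaResults":
        """Train with Adam on the L1 objective; early-stop on validation loss."""
        tc, nc = self.train_config, self.net_config
        net = HiCMambaNet(nc, seed=tc.seed)
        opt = Adam(net.parameters(), lr=tc.lr, beta1=tc.beta1, beta2=tc.beta2,
                   clip_norm=tc.grad_clip_norm)
        rng = np.random.default_rng(tc.seed + 1)
        log = TrainLog(seed=tc.seed)
        n = len(self.x_train)
        batch = min(tc.batch_size, n)
        best_val = np.inf
        best_state = net.state_dict()
        since_best = 0
        for epoch in range(tc.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for a in range(0, n, batch):
                idx = order[a:a + batch]
                net.zero_grad()
                pred = net(Tensor(self.x_train[idx]))
                loss = l1_loss(pred, Tensor(self.y_train[idx]))
                lval = float(loss.data)
                if not np.isfinite(lval):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch offset {a} (lr={tc.lr}, batch={batch})")
                loss.backward()
                opt.step()
                ep_loss += lval * len(idx)
            log.train_loss.append(ep_loss / n)
            if self.x_val is not None:
                vl, vp = self._eval_loss(net, self.x_val, self.y_val, batch)
            else:
                vl, vp = log.train_loss[-1], None
            log.val_loss.append(vl)
            log.val_pcc.append(vp)
            if vl < best_val:
                best_val = vl
                best_state = net.state_dict()
                log.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
            if verbose:
                print(f"epoch {epoch}: train {log.train_loss[-1]:.5f} "
                      f"val {vl:.5f}")
            if tc.early_stop_patience and since_best >= tc.early_stop_patience:
                break
        net.load_state_dict(best_state)
        return HiCMambaResults(weights=best_state, net_config=nc,
                               train_config=tc, log=log)


class HiCMambaResults:
    """Fitted weights plus diagnostics; supports enhancement and I/O."""

    def __init__(self, weights: dict, net_config: NetworkConfig,
                 train_config: TrainConfig | None = None,
                 log: TrainLog | None = None):
        self.weights = weights
        self.net_config = net_config
        self.train_config = train_config
        self.log = log
        self._net: HiCMambaNet | None = None

    @property
    def net(self) -> HiCMambaNet:
        if self._net is None:
            self._net = HiCMambaNet(self.net_config, seed=0)
            self._net.load_state_dict(self.weights)
        return self._net

    def predict_patches(self, x: np.ndarray, batch: int = 16) -> np.ndarray:
        """Forward (N,1,H,W) scaled patches in inference mode."""
        outs = []
        for a in range(0, len(x), batch):
            outs.append(self.net(Tensor(x[a:a + batch].astype(DTYPE))).data)
        return np.concatenate(outs)

    def enhance(self, map_low: ContactMap, band_bins: int | None = None,
                max_value: float = 255.0, already_scaled: bool = False
                ) -> ContactMap:
        """Whole-map enhancement: tile, forward each patch, re-assemble.

        The map is clipped/scaled exactly as during training (unless
        ``already_scaled``), enhanced patch-wise, assembled (uncovered
        off-band cells stay zero), rescaled to the original dynamic
        range and clamped at zero.  Deterministic in inference mode.
        """
        ps = self.net_config.patch_size
        work = map_low if already_scaled else clip_and_scale(map_low, max_value)
        patches, _ = tile_patches(work, patch_size=ps,
                                  max_distance_bins=band_bins)
        x = _stack(patches, "low")
        pred = np.maximum(self.predict_patches(x), 0.0)  # clamp at zero
        out_patches = [PatchPair(low=pred[k, 0], row0=p.row0, col0=p.col0,
                                 chrom=p.chrom)
                       for k, p in enumerate(patches)]
        assembled, _cov = assemble_patches(out_patches, n=work.n,
                                           chrom=map_low.chrom,
                                           bin_size=map_low.bin_size,
                                           offset=map_low.offset)
        vals = np.maximum(assembled.values * max_value, 0.0)
        return ContactMap(chrom=map_low.chrom, bin_size=map_low.bin_size,
                          values=vals, offset=map_low.offset,
                          is_normalized=map_low.is_normalized)

    def summary(self) -> str:
        n_params = sum(v.size for v in self.weights.values())
        lines = [
            "HiCMamba enhancement model",
            "=" * 42,
            f"base channels (C):      {self.net_config.base_channels}",
            f"blocks per stage:       {self.net_config.blocks_per_stage}",
            f"d_state:                {self.net_config.d_state}",
            f"SS2D variant:           {self.net_config.ss2d_variant}",
            f"parameters:             {n_params}",
        ]
        if self.log is not None:
            lines += [
                f"epochs run:             {len(self.log.train_loss)}",
                f"best epoch:             {self.log.best_epoch}",
                f"final train L1:         {self.log.train_loss[-1]:.6f}",
                f"best validation L1:     {min(self.log.val_loss):.6f}",
            ]
            vp = [p for p in self.log.val_pcc if p is not None]
            if vp:
                lines.append(f"validation PCC (best):  {max(vp):.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {
            "net_config": self.net_config.to_dict(),
            "train_config": asdict(self.train_config) if self.train_config else None,
            "log": self.log.to_dict() if self.log else None,
            "schema": 1,
        }
        np.savez_compressed(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.weights)

    @classmethod
    def load(cls, path) -> "HiCMambaResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            weights = {k: z[k] for k in z.files if k != "__meta__"}
        nc = NetworkConfig.from_dict(meta["net_config"])
        tc = TrainConfig(**meta["train_config"]) if meta.get("train_config") else None
        log = TrainLog(**meta["log"]) if meta.get("log") else None
        return cls(weights=weights, net_config=nc, train_config=tc, log=log)


# -- functional wrappers ----------------------------------------------------

def train(train_patches, val_patches, net_cfg: NetworkConfig,
          tr_cfg: TrainConfig) -> tuple[dict, TrainLog]:
    """Train on patch pairs; returns (weights, log)."""
    res = HiCMambaModel(train_patches, val_patches, net_cfg, tr_cfg).fit()
    return res.weights, res.log


def enhance(map_low: ContactMap, weights: dict, net_cfg: NetworkConfig,
            band_bins: int | None = None, max_value: float = 255.0
            ) -> ContactMap:
    """Whole-map enhancement from a weight dictionary."""
    return HiCMambaResults(weights, net_cfg).enhance(map_low, band_bins,
                                                     max_value)


def prepare_map(cmap: ContactMap, kr: bool = True, tol: float = 1e-6,
                target_total: float | None = None) -> ContactMap:
    """Canonical normalization before clipping/scaling.

    KR-balances the map, then rescales the balanced matrix to
    ``target_total`` (default: the map's own raw total, keeping the
    dynamic range count-like).  When preparing a low-coverage map for a
    model trained on deeper data, pass the high-coverage total (or the
    low total divided by the coverage ratio) — sequencing-depth
    normalization, so paired maps share a dynamic range.
    """
    if not kr:
        if target_total is None:
            return cmap
        return rescale_to_total(cmap, target_total)
    total = cmap.values.sum() if target_total is None else target_total
    normed, _x = kr_normalize(cmap, tol=tol)
    return rescale_to_total(normed, total)


__all__ = ["TrainConfig", "TrainLog", "HiCMambaModel", "HiCMambaResults",
           "train", "enhance", "prepare_map"]
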