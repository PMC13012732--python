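"""Preprocessing pipeline for contact maps.

Implements Knight-Ruiz (KR) matrix balancing, binomial read thinning
(coverage downsampling), clipping/min-max scaling, non-overlapping
square tiling into patches, patch re-assembly, and the
chromosome-based train/validation/test split.

The canonical training pipeline thins raw integer counts first and KR-
normalizes the high- and low-coverage maps independently afterwards;
thinning of already-normalized values (scalar scaling with Poisson-like
resampling disabled) is available through ``downsample(..., mode="scale")``
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactMap


# ---------------------------------------------------------------------------
# KR balancing

def _bnewt(A: np.ndarray, tol: float, max_outer: int,
           delta: float = 0.1, Delta: float = 3.0) -> tuple[np.ndarray, float]:
    """Knight-Ruiz balancing: find positive x with x * (A x) = 1 per row.

    Inner-outer Newton scheme with a conjugate-gradient inner loop,
    following the bnewt pseudocode of the KR method.  Returns (x, final
    residual); raises on non-convergence within ``max_outer`` outer steps.
    """
    n = A.shape[0]
    e = np.ones(n)
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    x = e.copy()
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise RuntimeError(
                f"KR balancing did not converge: residual {np.sqrt(rout):.3g} "
                f"after {max_outer} outer iterations")
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / np.sqrt(rout))
    return x, float(np.sqrt(rout))


def kr_normalize(cmap: ContactMap, tol: float = 1e-6, max_iter: int = 100,
                 min_nonzeros: int | None = None
                 ) -> tuple[ContactMap, np.ndarray]:
    """Knight-Ruiz balance a raw-count map to uniform row sums.

    Bins with fewer than ``min_nonzeros`` nonzero entries (default 1% of
    n, at least 1) are masked (zeroed) before balancing — KR diverges on
    near-empty rows.  Returns the balanced map (row sums within ``tol``
    of 1 on unmasked bins) and the diagonal scaling vector ``x`` such
    that scaled = diag(x) @ values @ diag(x); masked bins carry x = 0.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = cmap.n
    if min_nonzeros is None:
        min_nonzeros = max(1, int(round(0.01 * n)))
    A = cmap.values
    nonzeros = (A > 0).sum(axis=1)
    keep = nonzeros >= min_nonzeros
    if not keep.any():
        raise ValueError("all bins masked before balancing")
    sub = A[np.ix_(keep, keep)]
    x_sub, _res = _bnewt(sub, tol=tol, max_outer=max_iter)
    x = np.zeros(n)
    x[keep] = x_sub
    scaled = (x[:, None] * A) * x[None, :]
    mask = frozenset(int(i) for i in np.nonzero(~keep)[0]) | cmap.mask
    out = cmap.copy_with(scaled, is_normalized=True, mask=mask)
    return out, x


# ---------------------------------------------------------------------------
# coverage downsampling

def downsample(cmap: ContactMap, ratio: float, seed: int,
               mode: str = "binomial") -> ContactMap:
    """Simulate lower sequencing coverage at the given read-retention ratio.

    ``binomial`` (default) thins each upper-triangle integer count c to a
    Binomial(c, ratio) draw, mirrored to preserve symmetry — the
    read-level model of shallow sequencing.  ``scale`` multiplies values
    by the ratio deterministically (applicable to normalized maps).
    """
    if not (0 < ratio <= 1):
        raise ValueError("ratio must be in (0, 1]")
    if mode == "scale":
        return cmap.copy_with(cmap.values * ratio)
    if mode != "binomial":
        raise ValueError(f"unknown mode {mode!r}")
    v = cmap.values
    if not np.allclose(v, np.round(v)):
        raise ValueError("binomial thinning requires integer counts")
    if ratio == 1.0:
        return cmap.copy_with(v.copy())
    counts = np.round(v).astype(np.int64)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(cmap.n)
    thinned = rng.binomial(counts[iu], ratio)
    out = np.zeros_like(counts)
    out[iu] = thinned
    out = out + np.triu(out, 1).T
    return cmap.copy_with(out.astype(float))


def clip_and_scale(cmap: ContactMap, max_value: float = 255.0) -> ContactMap:
    """Clip values to [0, max_value] and divide by max_value (range [0, 1])."""
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    return cmap.copy_with(np.clip(cmap.values, 0, max_value) / max_value)


def rescale_to_total(cmap: ContactMap, total: float) -> ContactMap:
    """Rescale so the matrix sum equals ``total`` (used after KR balancing)."""
    s = cmap.values.sum()
    if s == 0:
        return cmap.copy_with(cmap.values.copy())
    return cmap.copy_with(cmap.values * (total / s))


# ---------------------------------------------------------------------------
# tiling

@dataclass
class PatchPair:
    """Aligned low/high-coverage square sub-matrices of one contact map."""

    low: np.ndarray
    row0: int
    col0: int
    chrom: str
    high: np.ndarray | None = None

    def __post_init__(self):
        self.low = np.asarray(self.low, dtype=float)
        if self.low.ndim != 2 or self.low.shape[0] != self.low.shape[1]:
            raise ValueError("patch must be square")
        ps = self.low.shape[0]
        if self.high is not None:
            self.high = np.asarray(self.high, dtype=float)
            if self.high.shape != self.low.shape:
                raise ValueError("low/high patches must share shape")
        if self.row0 % ps or self.col0 % ps:
            raise ValueError("patch origin must be a multiple of the patch size")

    @property
    def patch_size(self) -> int:
        return self.low.shape[0]


def tile_patches(low: ContactMap, high: ContactMap | None = None,
                 patch_size: int = 40,
                 max_distance_bins: int | None = None
                 ) -> tuple[list[PatchPair], int]:
    """Split map(s) into non-overlapping patch_size x patch_size tiles.

    Trailing bins that do not fill a full patch are dropped; the number
    of dropped bins is returned alongside the patch list.  With
    ``max_distance_bins`` set, only tiles with |row0 - col0| within the
    band are kept (the band is symmetric, so tiles come in mirror pairs).
    """
    n = low.n
    if patch_size > n:
        raise ValueError("patch_size exceeds matrix size")
    if high is not None and high.n != n:
        raise ValueError("low/high maps must share size")
    k = n // patch_size
    dropped = n - k * patch_size
    patches = []
    for bi in range(k):
        for bj in range(k):
            r, c = bi * patch_size, bj * patch_size
            if max_distance_bins is not None and abs(r - c) > max_distance_bins:
                continue
            patches.append(PatchPair(
                low=low.values[r:r + patch_size, c:c + patch_size].copy(),
                high=None if high is None else
                high.values[r:r + patch_size, c:c + patch_size].copy(),
                row0=r, col0=c, chrom=low.chrom))
    return patches, dropped


def assemble_patches(patches: list[PatchPair], n: int, field: str = "low",
                     chrom: str | None = None, bin_size: int = 1,
                     offset: int = 0) -> tuple[ContactMap, np.ndarray]:
    """Place patches back into an n x n map (inverse of tiling).

    Cells not covered by any patch are zero; the returned boolean mask
    flags covered cells.  The output is symmetrized: where both (i, j)
    and (j, i) are covered their values are averaged, where only one
    side is covered it is mirrored.
    """
    if not patches:
        raise ValueError("no patches to assemble")
    acc = np.zeros((n, n))
    cov = np.zeros((n, n), dtype=bool)
    for p in patches:
        ps = p.patch_size
        vals = getattr(p, field)
        if vals is None:
            raise ValueError(f"patch at ({p.row0},{p.col0}) lacks {field!r} values")
        if p.row0 + ps > n or p.col0 + ps > n:
            raise ValueError("patch exceeds matrix bounds")
        if cov[p.row0:p.row0 + ps, p.col0:p.col0 + ps].any():
            raise ValueError("overlapping patches")
        acc[p.row0:p.row0 + ps, p.col0:p.col0 + ps] = vals
        cov[p.row0:p.row0 + ps, p.col0:p.col0 + ps] = True
    both = cov & cov.T
    sym = np.where(both, (acc + acc.T) / 2.0,
                   np.where(cov, acc, acc.T))
    covered = cov | cov.T
    cmap = ContactMap(chrom=chrom or patches[0].chrom, bin_size=bin_size,
                      values=sym, offset=offset)
    return cmap, covered


# ---------------------------------------------------------------------------
# chromosome split

DEFAULT_VAL = frozenset({"2", "6", "10", "12"})
DEFAULT_TEST = frozenset({"4", "14", "16", "20"})


def _stem(label: str) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


@dataclass
class SplitSpec:
    """Disjoint train/validation/test chromosome lists."""

    train_chroms: list
    val_chroms: list
    test_chroms: list

    def __post_init__(self):
        sets = [set(self.train_chroms), set(self.val_chroms), set(self.test_chroms)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"chromosomes in multiple splits: {sorted(overlap)}")


def make_split(all_chroms, val_chroms=None, test_chroms=None) -> SplitSpec:
    """Chromosome-based dataset split.

    Default: chromosomes 2, 6, 10 and 12 validate, 4, 14, 16 and 20
    test, the remainder trains (labels matched on their numeric stem, so
    'chr2' and '2' both hit the default validation set).  User-supplied
    lists override the defaults and must not overlap.
    """
    labels = [str(c) for c in all_chroms]
    if len(set(labels)) != len(labels):
        raise ValueError("chromosome labels must be unique")
    if val_chroms is None and test_chroms is None:
        val = [c for c in labels if _stem(c) in DEFAULT_VAL]
        test = [c for c in labels if _stem(c) in DEFAULT_TEST]
    else:
        val = [str(c) for c in (val_chroms or [])]
        test = [str(c) for c in (test_chroms or [])]
        unknown = (set(val) | set(test)) - set(labels)
        if unknown:
            raise ValueError(f"unknown chromosomes: {sorted(unknown)}")
    train = [c for c in labels if c not in set(val) | set(test)]
    return SplitSpec(train_chroms=train, val_chroms=val, test_chroms=test)


__all__ = ["kr_normalize", "downsample", "clip_and_scale", "rescale_to_total",
           "PatchPair", "tile_patches", "assemble_patches", "SplitSpec",
           "make_split", "DEFAULT_VAL", "DEFAULT_TEST"]
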