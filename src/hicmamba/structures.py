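"""Downstream 3D-genome structure validation statistics.

Operates on chromatin-loop calls (BEDPE, two anchors per record) and
TAD-boundary / ChIP-seq-peak intervals (BED): anchor-midpoint loop
matching, matched/predicted proportions, boundary support by peaks, the
two-cell-line structure weighted score

    P_l^s = A_l^s / N_l,      W_l^s = P_l^s / (P_l1^s + P_l2^s),

the partition of predicted loops by which reference sets support them,
distance-matched non-loop sampling, and pixel-intensity comparison
between loop classes.

Coordinates are 0-based half-open (BED convention), in bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# containers

@dataclass
class LoopSet:
    """Chromatin loops as paired anchors, upper-triangle oriented."""

    chrom: list
    a1_start: np.ndarray
    a1_end: np.ndarray
    a2_start: np.ndarray
    a2_end: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.chrom = [str(c) for c in self.chrom]
        for name in ("a1_start", "a1_end", "a2_start", "a2_end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if np.any(self.a1_end <= self.a1_start) or np.any(self.a2_end <= self.a2_start):
            raise ValueError("malformed anchor interval")
        # enforce anchor1 upstream of anchor2
        swap = self.a1_start > self.a2_start
        if swap.any():
            for a, b in (("a1_start", "a2_start"), ("a1_end", "a2_end")):
                va, vb = getattr(self, a).copy(), getattr(self, b).copy()
                va[swap], vb[swap] = vb[swap], va[swap].copy()
                setattr(self, a, va)
                setattr(self, b, vb)

    def __len__(self):
        return len(self.chrom)

    def midpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return ((self.a1_start + self.a1_end) // 2,
                (self.a2_start + self.a2_end) // 2)

    def subset(self, idx) -> "LoopSet":
        idx = np.asarray(idx)
        return LoopSet(chrom=[self.chrom[i] for i in np.nonzero(idx)[0]]
                       if idx.dtype == bool else [self.chrom[i] for i in idx],
                       a1_start=self.a1_start[idx], a1_end=self.a1_end[idx],
                       a2_start=self.a2_start[idx], a2_end=self.a2_end[idx],
                       source=self.source)


@dataclass
class BoundarySet:
    """TAD-boundary (or peak) intervals with BED semantics, sorted per chrom."""

    chrom: list
    start: np.ndarray
    end: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.chrom = [str(c) for c in self.chrom]
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.end <= self.start):
            raise ValueError("malformed interval (start must precede end)")
        order = np.lexsort((self.start, np.asarray(self.chrom)))
        self.chrom = [self.chrom[i] for i in order]
        self.start = self.start[order]
        self.end = self.end[order]

    def __len__(self):
        return len(self.chrom)


def read_bedpe(path, source: str = "") -> LoopSet:
    """Read loops from BEDPE; columns 1-6 are authoritative, extras ignored."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("BEDPE requires at least 6 columns")
    if str(df.iloc[0, 0]) != str(df.iloc[0, 3]):
        raise ValueError("inter-chromosomal loops are not supported")
    return LoopSet(chrom=df[0].tolist(), a1_start=df[1], a1_end=df[2],
                   a2_start=df[4], a2_end=df[5], source=source)


def write_bedpe(loops: LoopSet, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(loops)):
            fh.write(f"{loops.chrom[i]}\t{loops.a1_start[i]}\t{loops.a1_end[i]}\t"
                     f"{loops.chrom[i]}\t{loops.a2_start[i]}\t{loops.a2_end[i]}\n")


def read_bed(path, source: str = "") -> BoundarySet:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    return BoundarySet(chrom=df[0].tolist(), start=df[1], end=df[2], source=source)


def write_bed(bs: BoundarySet, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(bs)):
            fh.write(f"{bs.chrom[i]}\t{bs.start[i]}\t{bs.end[i]}\n")


# ---------------------------------------------------------------------------
# loop matching

def _match_mask(pred: LoopSet, ref: LoopSet, tol_bp: int) -> np.ndarray:
    """Boolean mask over predicted loops: matched by some reference loop.

    A predicted loop matches when a reference loop on the same chromosome
    has both anchor midpoints within tol_bp (closed interval); each
    predicted loop is counted at most once.
    """
    p1, p2 = pred.midpoints()
    r1, r2 = ref.midpoints()
    ref_chrom = np.asarray(ref.chrom)
    matched = np.zeros(len(pred), dtype=bool)
    for i in range(len(pred)):
        sel = ref_chrom == pred.chrom[i]
        if not sel.any():
            continue
        hit = (np.abs(r1[sel] - p1[i]) <= tol_bp) & (np.abs(r2[sel] - p2[i]) <= tol_bp)
        matched[i] = bool(hit.any())
    return matched


def match_loops(pred: LoopSet, ref: LoopSet, tol_bins: int = 1,
                bin_size: int = 10000) -> tuple[int, LoopSet]:
    """Count predicted loops validated by the reference set.

    Returns (matched count, unmatched predicted loops).  Tolerance is
    tol_bins * bin_size on each anchor midpoint.
    """
    m = _match_mask(pred, ref, tol_bins * bin_size)
    return int(m.sum()), pred.subset(~m)


def proportion(matched: int, predicted: int) -> float:
    """100 * matched / predicted, to one decimal (the 'proportion' metric)."""
    if predicted < 1:
        raise ValueError("predicted count must be >= 1")
    if not (0 <= matched <= predicted):
        raise ValueError("matched must lie in [0, predicted]")
    return round(100.0 * matched / predicted, 1)


def match_boundaries(pred: BoundarySet, peaks: BoundarySet,
                     tol_bp: int = 10000) -> tuple[int, float]:
    """Boundaries supported by a peak within +-tol_bp (closed intervals).

    A boundary [s, e) is supported if some same-chromosome peak
    intersects [s - tol_bp, e + tol_bp]; returns (matched, proportion).
    """
    if len(pred) == 0:
        raise ValueError("empty boundary set")
    peaks_chrom = np.asarray(peaks.chrom)
    matched = 0
    for i in range(len(pred)):
        sel = peaks_chrom == pred.chrom[i]
        if not sel.any():
            continue
        lo = pred.start[i] - tol_bp
        hi = pred.end[i] + tol_bp
        hit = (peaks.start[sel] <= hi) & (peaks.end[sel] >= lo)
        if hit.any():
            matched += 1
    return matched, proportion(matched, len(pred))


# ---------------------------------------------------------------------------
# structure weighted score

@dataclass
class StructureScoreInputs:
    """Counts A[l][s] of l-specific structures hitting s-specific features."""

    A: dict            # A[l][s] -> int
    N: dict            # N[l] -> int

    def __post_init__(self):
        for l, n in self.N.items():
            if n < 1:
                raise ValueError(f"N[{l}] must be >= 1")
            for s, a in self.A[l].items():
                if not (0 <= a <= n):
                    raise ValueError(f"A[{l}][{s}] outside [0, N[{l}]]")


@dataclass
class WeightedScoreTable:
    """Exact-rational proportions P[l][s] and weighted scores W[l][s].

    W[l][s] is None (flagged missing) where the denominator
    sum_l P[l][s] is zero.  For integer inputs the identity
    sum_l W[l][s] == 1 holds exactly in rational arithmetic.
    """

    P: dict = field(default_factory=dict)
    W: dict = field(default_factory=dict)

    def as_float(self) -> dict:
        return {l: {s: (None if w is None else float(w))
                    for s, w in row.items()} for l, row in self.W.items()}


def structure_weighted_score(inputs: StructureScoreInputs) -> WeightedScoreTable:
    """Cell-type specificity of regulator-associated structures.

    P[l][s] = A[l][s] / N[l]; W[l][s] = P[l][s] / sum_l' P[l'][s].
    Computed in exact rational arithmetic.
    """
    lines = list(inputs.N)
    features = sorted({s for l in lines for s in inputs.A[l]})
    P = {l: {s: Fraction(int(inputs.A[l][s]), int(inputs.N[l]))
             for s in features} for l in lines}
    W = {}
    for l in lines:
        W[l] = {}
        for s in features:
            denom = sum(P[l2][s] for l2 in lines)
            W[l][s] = None if denom == 0 else P[l][s] / denom
    return WeightedScoreTable(P=P, W=W)


# ---------------------------------------------------------------------------
# loop-support partition and intensity control

def support_partition(pred: LoopSet, set1: LoopSet, set2: LoopSet,
                      tol_bins: int = 1, bin_size: int = 10000) -> dict:
    """Fractions of predicted loops supported by set1 only, set2 only,
    both, or neither; the four fractions sum to 1."""
    if len(pred) == 0:
        raise ValueError("empty predicted loop set")
    tol = tol_bins * bin_size
    m1 = _match_mask(pred, set1, tol)
    m2 = _match_mask(pred, set2, tol)
    n = len(pred)
    return {
        "only1": float((m1 & ~m2).sum() / n),
        "only2": float((~m1 & m2).sum() / n),
        "both": float((m1 & m2).sum() / n),
        "neither": float((~m1 & ~m2).sum() / n),
    }


def _loop_bins(loops: LoopSet, cmap) -> tuple[np.ndarray, np.ndarray]:
    m1, m2 = loops.midpoints()
    i = (m1 - cmap.offset) // cmap.bin_size
    j = (m2 - cmap.offset) // cmap.bin_size
    return i.astype(np.int64), j.astype(np.int64)


def sample_matched_nonloops(cmap, loops: LoopSet, seed: int,
                            tol_bins: int = 1, max_tries: int = 1000) -> LoopSet:
    """Distance-matched non-loop control pixels.

    Draws exactly len(loops) pixel pairs whose multiset of anchor
    distances (in bins) equals that of the input loops, none within
    ``tol_bins`` (Chebyshev, in bins) of any input loop.  Deterministic
    given the seed.
    """
    n = cmap.n
    li, lj = _loop_bins(loops, cmap)
    rng = np.random.default_rng(seed)
    out_i, out_j = [], []
    taken = set()
    for d in (lj - li):
        d = int(d)
        if d >= n:
            raise ValueError("loop distance exceeds map size")
        for attempt in range(max_tries):
            i = int(rng.integers(0, n - d))
            j = i + d
            near = (np.abs(li - i) <= tol_bins) & (np.abs(lj - j) <= tol_bins)
            if not near.any() and (i, j) not in taken:
                taken.add((i, j))
                out_i.append(i)
                out_j.append(j)
                break
        else:
            raise RuntimeError(f"no eligible non-loop pixel at distance {d} bins")
    bs = cmap.bin_size
    off = cmap.offset
    out_i, out_j = np.array(out_i), np.array(out_j)
    return LoopSet(chrom=[cmap.chrom] * len(out_i),
                   a1_start=off + out_i * bs, a1_end=off + (out_i + 1) * bs,
                   a2_start=off + out_j * bs, a2_end=off + (out_j + 1) * bs,
                   source="matched-nonloop")


def intensity_comparison(cmap, validated: LoopSet, unvalidated: LoopSet,
                         controls: LoopSet) -> dict:
    """Pixel-intensity summary per loop class.

    Returns mean/median per set plus a rank-based two-sample comparison
    (Mann-Whitney U, normal approximation) between the unvalidated
    predictions and the distance-matched controls; the test is flagged
    underpowered when either sample has fewer than three observations.
    """
    def intensities(ls: LoopSet) -> np.ndarray:
        if len(ls) == 0:
            raise ValueError("empty loop set")
        i, j = _loop_bins(ls, cmap)
        if np.any(i < 0) or np.any(j >= cmap.n):
            raise ValueError("loop coordinates outside the contact map")
        return cmap.values[i, j]

    out = {}
    sets = {"validated": validated, "unvalidated": unvalidated,
            "controls": controls}
    vals = {}
    for name, ls in sets.items():
        v = intensities(ls)
        vals[name] = v
        out[name] = {"n": int(v.size), "mean": float(v.mean()),
                     "median": float(np.median(v))}
    if min(vals["unvalidated"].size, vals["controls"].size) < 3:
        out["test"] = {"underpowered": True}
    else:
        res = stats.mannwhitneyu(vals["unvalidated"], vals["controls"],
                                 alternative="greater", method="asymptotic")
        out["test"] = {"underpowered": False, "U": float(res.statistic),
                       "pvalue": float(res.pvalue)}
    return out


__all__ = ["LoopSet", "BoundarySet", "read_bedpe", "write_bedpe", "read_bed",
           "write_bed", "match_loops", "proportion", "match_boundaries",
           "StructureScoreInputs", "WeightedScoreTable",
           "structure_weighted_score", "support_partition",
           "sample_matched_nonloops", "intensity_comparison"]
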