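"""Reproducibility and similarity metrics for contact-map pairs.

Local agreement: Pearson (PCC) and Spearman (SRCC) correlations over
the included pixels, and PCC stratified by genomic distance.  Global
structure: a random-walk concordance score (GenomeDISCO-style), a
Laplacian-eigenvector spectral score (HiC-Spector-style), and the A/B
compartment score (correlation of the leading eigenvectors of the
observed/expected correlation matrices).

Pixel inclusion for the correlation metrics: upper triangle, optionally
restricted to a diagonal band, excluding masked bins; per-chromosome
values are aggregated by an unweighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .contact import ContactMap


def _as_values(a) -> np.ndarray:
    return a.values if isinstance(a, ContactMap) else np.asarray(a, dtype=float)


def _included_pixels(a: ContactMap | np.ndarray, b: ContactMap | np.ndarray,
                     band_bins: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    va, vb = _as_values(a), _as_values(b)
    if va.shape != vb.shape:
        raise ValueError("maps must share shape")
    if va.ndim == 1:
        return va, vb
    n = va.shape[0]
    i, j = np.triu_indices(n)
    keep = np.ones(i.size, dtype=bool)
    if band_bins is not None:
        keep &= (j - i) <= band_bins
    masked = set()
    for m in (a, b):
        if isinstance(m, ContactMap):
            masked |= set(m.mask)
    if masked:
        marr = np.array(sorted(masked))
        keep &= ~np.isin(i, marr) & ~np.isin(j, marr)
    return va[i[keep], j[keep]], vb[i[keep], j[keep]]


def pcc(a, b, band_bins: int | None = None) -> float | None:
    """Pearson correlation over the included pixels; None if undefined."""
    x, y = _included_pixels(a, b, band_bins)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def srcc(a, b, band_bins: int | None = None) -> float | None:
    """Spearman rank correlation (mid-ranks for ties) over included pixels."""
    x, y = _included_pixels(a, b, band_bins)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.spearmanr(x, y).statistic)


def distance_stratified_pcc(pred, target, bin_edges,
                            bin_size: int | None = None
                            ) -> list[tuple[tuple[float, float], float | None]]:
    """PCC per genomic-distance stratum.

    Pixels are grouped by |i - j| * bin_size into [lo, hi) strata given
    by consecutive ``bin_edges``; strata with fewer than two pixels or
    zero variance are reported as None.
    """
    vp, vt = _as_values(pred), _as_values(target)
    if vp.shape != vt.shape:
        raise ValueError("maps must share shape")
    edges = list(bin_edges)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if bin_size is None:
        bin_size = pred.bin_size if isinstance(pred, ContactMap) else 1
    n = vp.shape[0]
    i, j = np.triu_indices(n)
    dist = (j - i) * bin_size
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi)
        x, y = vp[i[sel], j[sel]], vt[i[sel], j[sel]]
        if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
            out.append(((lo, hi), None))
        else:
            out.append(((lo, hi), float(stats.pearsonr(x, y).statistic)))
    return out


# ---------------------------------------------------------------------------
# random-walk concordance (GenomeDISCO-style)

def _transition(v: np.ndarray) -> np.ndarray:
    rs = v.sum(axis=1, keepdims=True)
    t = np.divide(v, rs, out=np.zeros_like(v), where=rs > 0)
    return t


def genomedisco(a, b, t_steps: int = 3) -> float:
    """Concordance of t-step random walks on the two contact graphs.

    Rows are normalized to transition matrices (zero rows stay zero),
    raised to the ``t_steps``-th power, and compared by the mean L1 row
    difference d over rows that are nonzero in at least one map; the
    score is 1 - d/2 (1 iff the smoothed matrices coincide).
    """
    va, vb = _as_values(a), _as_values(b)
    if va.shape != vb.shape:
        raise ValueError("maps must share shape")
    ta, tb = _transition(va), _transition(vb)
    pa, pb = ta.copy(), tb.copy()
    for _ in range(t_steps - 1):
        pa = pa @ ta
        pb = pb @ tb
    rows = (va.sum(axis=1) > 0) | (vb.sum(axis=1) > 0)
    if not rows.any():
        return 1.0
    d = np.abs(pa[rows] - pb[rows]).sum(axis=1).mean()
    return float(1.0 - d / 2.0)


# ---------------------------------------------------------------------------
# spectral score (HiC-Spector-style)

def _laplacian_eigvecs(v: np.ndarray, k: int) -> np.ndarray:
    deg = v.sum(axis=1)
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
    L = np.eye(v.shape[0]) - inv_sqrt[:, None] * v * inv_sqrt[None, :]
    w, vecs = np.linalg.eigh(L)
    order = np.argsort(w)
    return vecs[:, order[:k]]


def hic_spector(a, b, n_eigen: int = 20) -> float:
    """Spectral reproducibility from normalized-Laplacian eigenvectors.

    Sums, over the ``n_eigen`` leading (smallest-eigenvalue) eigenvector
    pairs, the Euclidean distance after per-pair sign alignment, and maps
    the total to [0, 1] via 1 - Sd / (n_eigen * sqrt(2)).
    """
    va, vb = _as_values(a), _as_values(b)
    if va.shape != vb.shape:
        raise ValueError("maps must share shape")
    n = va.shape[0]
    if n_eigen >= n:
        raise ValueError("n_eigen must be smaller than the matrix size")
    ua = _laplacian_eigvecs(va, n_eigen)
    ub = _laplacian_eigvecs(vb, n_eigen)
    sd = 0.0
    for k in range(n_eigen):
        d1 = np.linalg.norm(ua[:, k] - ub[:, k])
        d2 = np.linalg.norm(ua[:, k] + ub[:, k])
        sd += min(d1, d2)
    return float(np.clip(1.0 - sd / (n_eigen * np.sqrt(2.0)), 0.0, 1.0))


# ---------------------------------------------------------------------------
# compartment score

def _oe(v: np.ndarray, mask: set) -> tuple[np.ndarray, np.ndarray]:
    n = v.shape[0]
    keep = np.array([i not in mask for i in range(n)])
    oe = np.zeros_like(v)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        sel = keep[i] & keep[j]
        if not sel.any():
            continue
        mean = v[i[sel], j[sel]].mean()
        if mean > 0:
            oe[i[sel], j[sel]] = v[i[sel], j[sel]] / mean
            oe[j[sel], i[sel]] = oe[i[sel], j[sel]]
    return oe, keep


def compartment_pc1(cmap: ContactMap | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenvector of the observed/expected correlation matrix.

    Returns (pc1, keep) where ``keep`` flags the unmasked bins with
    defined values; pc1 entries on dropped bins are 0.  Orientation of
    the eigenvector is arbitrary.
    """
    v = _as_values(cmap)
    mask = set(cmap.mask) if isinstance(cmap, ContactMap) else set()
    oe, keep = _oe(v, mask)
    sub = oe[np.ix_(keep, keep)]
    sd = sub.std(axis=1)
    good = sd > 0
    if good.sum() < 2:
        raise ValueError("matrix too degenerate for compartment analysis")
    corr = np.corrcoef(sub[good][:, good])
    w, vecs = np.linalg.eigh(corr)
    lead = vecs[:, -1]
    pc1 = np.zeros(v.shape[0])
    idx = np.nonzero(keep)[0][good]
    pc1[idx] = lead
    final_keep = np.zeros(v.shape[0], dtype=bool)
    final_keep[idx] = True
    return pc1, final_keep


def compartment_score(pred, target) -> float:
    """|Pearson correlation| of the two PC1 vectors on shared unmasked bins."""
    vp = _as_values(pred)
    if vp.shape[0] < 10:
        raise ValueError("map too small for observed/expected computation")
    p1, k1 = compartment_pc1(pred)
    p2, k2 = compartment_pc1(target)
    keep = k1 & k2
    if keep.sum() < 2:
        raise ValueError("no shared bins with defined PC1")
    x, y = p1[keep], p2[keep]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant PC1; no leading eigenvector direction")
    return float(abs(stats.pearsonr(x, y).statistic))


# ---------------------------------------------------------------------------
# report

@dataclass
class MetricReport:
    """Per-chromosome metric values with unweighted-mean aggregation."""

    per_chrom: dict = field(default_factory=dict)
    stratified: dict = field(default_factory=dict)

    def add(self, chrom: str, values: dict) -> None:
        self.per_chrom[chrom] = values

    def aggregate(self) -> dict:
        keys = {k for v in self.per_chrom.values() for k in v}
        out = {}
        for k in sorted(keys):
            vals = [v[k] for v in self.per_chrom.values()
                    if v.get(k) is not None]
            out[k] = float(np.mean(vals)) if vals else None
        return out

    def to_dict(self) -> dict:
        return {"per_chrom": self.per_chrom, "aggregate": self.aggregate(),
                "stratified": self.stratified}


def evaluate_pair(pred: ContactMap, target: ContactMap,
                  band_bins: int | None = None, t_steps: int = 3,
                  n_eigen: int = 20, strata_edges=None) -> dict:
    """All five metrics for one pred/target pair (None where undefined)."""
    out = {
        "pcc": pcc(pred, target, band_bins),
        "srcc": srcc(pred, target, band_bins),
        "genomedisco": genomedisco(pred, target, t_steps),
        "hic_spector": hic_spector(pred, target, min(n_eigen, pred.n - 1)),
    }
    try:
        out["compartment"] = compartment_score(pred, target)
    except ValueError:
        out["compartment"] = None
    if strata_edges is not None:
        out["stratified_pcc"] = [
            {"lo": lo, "hi": hi, "pcc": v}
            for (lo, hi), v in distance_stratified_pcc(pred, target, strata_edges)
        ]
    return out


__all__ = ["pcc", "srcc", "distance_stratified_pcc", "genomedisco",
           "hic_spector", "compartment_pc1", "compartment_score",
           "MetricReport", "evaluate_pair"]
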