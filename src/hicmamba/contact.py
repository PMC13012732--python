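"""Contact-map container and readers/writers.

A :class:`ContactMap` holds the symmetric n x n interaction-frequency
matrix of one chromosome at a fixed bin size, together with the genomic
coordinate of bin 0 and a set of masked (too-sparse) bins.  Supported
on-disk formats: whitespace-delimited dense text, a compressed-array
archive with keys {values, chrom, bin_size, offset}, and
single-resolution cooler files (read through h5py).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SYMMETRY_TOL = 1e-6


@dataclass
class ContactMap:
    """Symmetric per-chromosome Hi-C contact matrix.

    ``values[i][j]`` is the interaction frequency between bins i and j;
    bins are 0-based, bin i covers genomic interval
    [offset + i*bin_size, offset + (i+1)*bin_size) (half-open).
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    offset: int = 0
    is_normalized: bool = False
    mask: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if v.shape[0] < 1:
            raise ValueError("contact matrix must have side length >= 1")
        if np.any(v < 0):
            raise ValueError("contact matrix must be non-negative")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > SYMMETRY_TOL * max(1.0, np.abs(v).max()):
            raise ValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance")
        if asym > 0:
            v = (v + v.T) / 2.0
        self.values = v
        self.mask = frozenset(int(i) for i in self.mask)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy_with(self, values: np.ndarray, **kw) -> "ContactMap":
        args = dict(chrom=self.chrom, bin_size=self.bin_size, values=values,
                    offset=self.offset, is_normalized=self.is_normalized,
                    mask=self.mask)
        args.update(kw)
        return ContactMap(**args)


# ---------------------------------------------------------------------------
# readers / writers

def _read_dense(path) -> np.ndarray:
    arr = np.loadtxt(path, dtype=float)
    return np.atleast_2d(arr)


def _read_npz(path, chrom, bin_size):
    with np.load(path, allow_pickle=False) as z:
        values = z["values"]
        chrom_f = str(z["chrom"]) if "chrom" in z else chrom
        bin_f = int(z["bin_size"]) if "bin_size" in z else bin_size
        offset = int(z["offset"]) if "offset" in z else 0
    return values, chrom_f, bin_f, offset


def _read_cooler(path, chrom, bin_size):
    import h5py

    with h5py.File(path, "r") as f:
        if "resolutions" in f:
            raise ValueError("multi-resolution coolers are not supported")
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["chroms/name"][:]]
        if chrom not in names:
            raise KeyError(f"chromosome {chrom!r} not in cooler file")
        code = names.index(chrom)
        bins_chrom = f["bins/chrom"][:]
        starts = f["bins/start"][:]
        idx = np.nonzero(bins_chrom == code)[0]
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        if bin_size is None:
            bin_size = int(f.attrs.get("bin-size",
                                       starts[lo + 1] - starts[lo] if hi - lo > 1 else 0))
        offset = int(starts[lo])
        n = hi - lo
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:]
        sel = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        mat = np.zeros((n, n))
        np.add.at(mat, (b1[sel] - lo, b2[sel] - lo), cnt[sel])
        mat = mat + np.triu(mat, 1).T  # cooler stores the upper triangle
    return mat, bin_size, offset


def read_contact_matrix(path, format: str, chrom: str = "chr1",
                        bin_size: int | None = None) -> ContactMap:
    """Read a per-chromosome contact matrix.

    ``format`` is one of ``dense`` (whitespace-delimited text), ``npz``
    (archive with keys values/chrom/bin_size/offset) or ``cooler``
    (single-resolution HDF5).  Input asymmetric beyond a 1e-6 relative
    tolerance is an error; smaller asymmetry is symmetrized by averaging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    offset = 0
    if format == "dense":
        values = _read_dense(path)
    elif format == "npz":
        values, chrom, bin_size, offset = _read_npz(path, chrom, bin_size)
    elif format == "cooler":
        values, bin_size, offset = _read_cooler(path, chrom, bin_size)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ContactMap(chrom=chrom, bin_size=bin_size or 1, values=values,
                      offset=offset)


def write_contact_matrix(cmap: ContactMap, path, format: str) -> None:
    path = Path(path)
    if format == "dense":
        np.savetxt(path, cmap.values, fmt="%.8g")
    elif format == "npz":
        np.savez_compressed(path, values=cmap.values, chrom=cmap.chrom,
                            bin_size=cmap.bin_size, offset=cmap.offset)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_bed_mask(path, chrom: str, bin_size: int, n: int,
                  offset: int = 0) -> frozenset:
    """Bins overlapped by BED intervals on ``chrom`` (half-open, 0-based)."""
    masked = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0] != chrom:
                continue
            start, end = int(parts[1]) - offset, int(parts[2]) - offset
            lo = max(0, start // bin_size)
            hi = min(n, -(-end // bin_size))
            masked.update(range(lo, hi))
    return frozenset(masked)


__all__ = ["ContactMap", "read_contact_matrix", "write_contact_matrix",
           "read_bed_mask", "SYMMETRY_TOL"]
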