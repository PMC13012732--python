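"""Seeded generator of Hi-C-like contact maps.

Emulates the statistical structure of real intra-chromosomal maps:
power-law contact-probability decay with genomic distance, planted TAD
blocks (contiguous intervals with enriched internal contacts), planted
loops (focal 2-D Gaussian bumps off the diagonal), Poisson (optionally
negative-binomial) read counts, and binomial thinning to produce a
paired low-coverage map.  Ground-truth loop and boundary annotations
are returned alongside, so enhancement and validation statistics can be
tested end-to-end without external downloads.

Expected intensity of pixel (i, j):

    lambda_ij ∝ (|i-j| + 1)^(-decay_exponent)
                * enrichment   if i, j fall in the same TAD
                * (1 + sum_k strength_k * exp(-((i-a_k)^2 + (j-b_k)^2)
                                              / (2 width_k^2)))

scaled so the expected upper-triangle total equals ``total_reads``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .contact import ContactMap, write_contact_matrix
from .preprocess import downsample
from .structures import LoopSet, BoundarySet, write_bedpe, write_bed


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic chromosome map.

    ``tads`` is a list of (start_bin, end_bin, enrichment >= 1) blocks;
    ``loops`` a list of (bin_i, bin_j, strength, width_bins) bumps with
    i < j.  ``noise`` > 0 switches Poisson counts to negative binomial
    with variance lambda * (1 + noise).
    """

    n_bins: int = 400
    bin_size: int = 10000
    total_reads: int = 2_000_000
    decay_exponent: float = 1.0
    tads: list = field(default_factory=list)
    loops: list = field(default_factory=list)
    noise: float = 0.0
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self):
        for t in self.tads:
            s, e, enr = t
            if not (0 <= s < e <= self.n_bins):
                raise ValueError(f"TAD {t} outside [0, n_bins)")
            if enr < 1:
                raise ValueError("TAD enrichment must be >= 1")
        for lp in self.loops:
            i, j, strength, width = lp
            if not (0 <= i < j < self.n_bins):
                raise ValueError(f"loop {lp} anchors must satisfy 0 <= i < j < n")
            if strength < 0 or width <= 0:
                raise ValueError("loop strength must be >= 0 and width > 0")


def expected_intensity(spec: SyntheticSpec) -> np.ndarray:
    """Per-pixel expected counts lambda (symmetric, upper-tri sum = total)."""
    n = spec.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = (dist + 1.0) ** (-spec.decay_exponent)
    for s, e, enr in spec.tads:
        inside = (idx >= s) & (idx < e)
        lam[np.ix_(inside, inside)] *= enr
    if spec.loops:
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        bump = np.zeros((n, n))
        for a, b, strength, width in spec.loops:
            g = np.exp(-((ii - a) ** 2 + (jj - b) ** 2) / (2.0 * width ** 2))
            g = g + np.exp(-((ii - b) ** 2 + (jj - a) ** 2) / (2.0 * width ** 2))
            bump += strength * g
        lam *= 1.0 + bump
    upper = np.triu(lam).sum()
    if upper <= 0:
        raise ValueError("zero total intensity; infeasible spec")
    return lam * (spec.total_reads / upper)


def truth_annotations(spec: SyntheticSpec) -> tuple[LoopSet, BoundarySet]:
    """Planted loops (anchor bins as 1-bin intervals) and TAD boundaries."""
    bs, off = spec.bin_size, 0
    if spec.loops:
        ii = np.array([lp[0] for lp in spec.loops])
        jj = np.array([lp[1] for lp in spec.loops])
        loops = LoopSet(chrom=[spec.chrom] * len(ii),
                        a1_start=off + ii * bs, a1_end=off + (ii + 1) * bs,
                        a2_start=off + jj * bs, a2_end=off + (jj + 1) * bs,
                        source="truth")
    else:
        loops = LoopSet(chrom=[], a1_start=[], a1_end=[], a2_start=[], a2_end=[])
    bounds = sorted({t[0] for t in spec.tads} | {t[1] for t in spec.tads})
    if bounds:
        barr = np.array(bounds)
        boundaries = BoundarySet(chrom=[spec.chrom] * len(bounds),
                                 start=barr * bs, end=(barr + 1) * bs,
                                 source="truth")
    else:
        boundaries = BoundarySet(chrom=[], start=[], end=[])
    return loops, boundaries


def generate_pair(spec: SyntheticSpec, ratio: float
                  ) -> tuple[ContactMap, ContactMap, LoopSet, BoundarySet]:
    """Draw a high-coverage count map and its binomially thinned pair.

    Counts are Poisson (negative binomial when ``spec.noise`` > 0) around
    the expected intensity; the low map retains each read independently
    with probability ``ratio``.  Deterministic given ``spec.seed``.
    """
    if not (0 < ratio <= 1):
        raise ValueError("ratio must be in (0, 1]")
    lam = expected_intensity(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    iu = np.triu_indices(n)
    lam_u = lam[iu]
    if spec.noise > 0:
        r = np.maximum(lam_u / spec.noise, 1e-9)
        p = r / (r + lam_u)
        counts_u = rng.negative_binomial(r, p)
    else:
        counts_u = rng.poisson(lam_u)
    high = np.zeros((n, n))
    high[iu] = counts_u
    high = high + np.triu(high, 1).T
    high_map = ContactMap(chrom=spec.chrom, bin_size=spec.bin_size, values=high)
    low_map = downsample(high_map, ratio, seed=spec.seed + 1)
    loops, boundaries = truth_annotations(spec)
    return high_map, low_map, loops, boundaries


def standard_spec(seed: int = 0, n_bins: int = 400) -> SyntheticSpec:
    """The standard small fixture: 3 TADs and 12 loops on a 400-bin map."""
    scale = n_bins / 400
    tads = [(int(40 * scale), int(120 * scale), 2.5),
            (int(150 * scale), int(230 * scale), 3.0),
            (int(260 * scale), int(370 * scale), 2.0)]
    anchors = [(45, 115), (60, 100), (155, 225), (170, 210), (185, 200),
               (265, 365), (280, 340), (300, 330), (50, 180), (100, 270),
               (200, 320), (130, 250)]
    loops = [(int(i * scale), int(j * scale), 6.0, 1.0) for i, j in anchors]
    return SyntheticSpec(n_bins=n_bins, tads=tads, loops=loops, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixture_suite(out_dir, seed: int = 0, n_bins: int = 400,
                       ratios=(1 / 16, 1 / 100)) -> dict:
    """Write the standard fixture suite and a manifest of files and hashes.

    For each ratio, the high/low maps are written as dense text, truth
    loops as BEDPE and TAD boundaries as BED; the manifest records the
    generating parameters, seeds and a SHA-256 per file, so a
    regenerated suite can be verified byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = standard_spec(seed=seed, n_bins=n_bins)
    files = {}
    for ratio in ratios:
        tag = f"r{int(round(1 / ratio))}"
        high, low, loops, bounds = generate_pair(spec, ratio)
        paths = {
            f"high_{tag}.txt": lambda p, m=high: write_contact_matrix(m, p, "dense"),
            f"low_{tag}.txt": lambda p, m=low: write_contact_matrix(m, p, "dense"),
            f"loops_{tag}.bedpe": lambda p, l=loops: write_bedpe(l, p),
            f"boundaries_{tag}.bed": lambda p, b=bounds: write_bed(b, p),
        }
        for name, writer in paths.items():
            path = out / name
            writer(path)
            files[name] = _sha256(path)
    manifest = {"spec": asdict(spec), "ratios": list(ratios), "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


__all__ = ["SyntheticSpec", "expected_intensity", "truth_annotations",
           "generate_pair", "standard_spec", "make_fixture_suite"]
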