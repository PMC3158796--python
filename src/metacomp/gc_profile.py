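"""Per-read GC content, dataset GC profiles, mode detection, and GC splits.

The GC histogram of a shotgun dataset is a cheap community fingerprint:
marine oligotrophic samples show a single low-GC peak, soils a high-GC
peak, and some freshwater communities a distinctive bimodal profile with
nearly equal peaks (around 45% and 65%).  ``detect_peaks`` finds such
modes by Gaussian smoothing plus prominence-filtered local maxima, and
``split_by_gc`` partitions a dataset at a GC threshold for per-fraction
analyses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from metacomp.sequence_io import Read, ReadSet


@dataclass
class GCProfile:
    """Histogram of per-read GC percentages over contiguous bins on [0, 100]."""

    bin_edges: np.ndarray  # length n_bins + 1, covering [0, 100]
    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have one more entry than counts")
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("counts must sum to n_total")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("bin_start\tcount\n")
            for lo, c in zip(self.bin_edges[:-1], self.counts):
                fh.write(f"{float(lo)!r}\t{int(c)}\n")


def gc_content(sequence: str) -> float:
    """GC percentage: ``100 × (G + C) / (A + C + G + T)``.

    N bases are excluded from numerator and denominator; case-insensitive.
    Raises on a sequence with no A/C/G/T bases.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("sequence has no non-N bases; GC content undefined")
    return 100.0 * gc / acgt


def gc_values(rs: ReadSet) -> np.ndarray:
    """Vector of per-read GC percentages."""
    return np.array([gc_content(r.sequence) for r in rs.reads])


def gc_histogram(rs: ReadSet, bin_width: float = 1.0) -> GCProfile:
    """Bin per-read GC into fixed-width, half-open bins ``[lo, hi)`` covering
    [0, 100] (the last bin is closed).  ``bin_width`` must divide 100."""
    if len(rs) == 0:
        raise ValueError("cannot profile an empty ReadSet")
    n_bins = 100.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 100")
    edges = np.linspace(0.0, 100.0, int(round(n_bins)) + 1)
    counts, _ = np.histogram(gc_values(rs), bins=edges)
    return GCProfile(bin_edges=edges, counts=counts, n_total=len(rs))


def detect_peaks(profile: GCProfile, bandwidth: float = 2.0,
                 min_prominence: float = 0.05) -> list[tuple[float, float]]:
    """Detect modes of a GC profile.

    The count histogram is smoothed with a Gaussian kernel of the given
    bandwidth (in GC percentage points) and local maxima with prominence
    of at least ``min_prominence`` times the smoothed maximum are reported
    as ``(mode_percent, height)`` pairs, sorted by ascending mode.  May
    return an empty list (e.g. a flat profile).
    """
    bin_width = float(profile.bin_edges[1] - profile.bin_edges[0])
    smoothed = gaussian_filter1d(profile.counts.astype(float),
                                 sigma=bandwidth / bin_width, mode="nearest")
    if smoothed.max() <= 0:
        return []
    idx, _props = find_peaks(smoothed, prominence=min_prominence * smoothed.max())
    centers = profile.bin_centers
    return sorted((float(centers[i]), float(smoothed[i])) for i in idx)


def split_by_gc(rs: ReadSet, threshold: float = 50.0) -> tuple[ReadSet, ReadSet]:
    """Partition a ReadSet into low-GC and high-GC subsets at a threshold.

    Reads with GC below the threshold go low, above go high; reads exactly
    at the threshold go to the low side (tie rule, so the two sides always
    partition the input).  Order is preserved.
    """
    if not 0.0 < threshold < 100.0:
        raise ValueError("threshold must be strictly between 0 and 100")
    low: list[Read] = []
    high: list[Read] = []
    for r in rs.reads:
        (low if gc_content(r.sequence) <= threshold else high).append(r)
    return (ReadSet(label=f"{rs.label}_lowGC", reads=low),
            ReadSet(label=f"{rs.label}_highGC", reads=high))
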