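"""SPO11-oligo maps, hotspots, and the signal-processing primitives shared by
the simulator and the breakpoint statistics.

A SPO11-oligo map gives per-base counts (reads or RPM) of sequenced
SPO11-bound oligonucleotides over a genomic window; it is the
nucleotide-resolution picture of where meiotic double-strand breaks form.
Hotspots are narrow intervals of concentrated signal; breakpoint and oligo
profiles are compared after Hann smoothing and local normalization.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpoOligoMap",
    "Hotspot",
    "SignalProfile",
    "hann_kernel",
    "smooth_hann",
    "local_normalize",
    "flip_and_average",
    "call_hotspot",
    "read_bedgraph",
    "write_bedgraph",
    "read_hotspot_bed",
    "write_hotspot_bed",
]


@dataclass
class SpoOligoMap:
    """Per-base SPO11-oligo counts over a reference window.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based start of the window.
    counts : ndarray
        One non-negative value per base pair.
    total_reads : int, optional
        Library size; enables RPM (reads per million) conversion.
    """

    chrom: str
    start: int
    counts: np.ndarray
    total_reads: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.counts.size

    def rpm(self) -> np.ndarray:
        """Counts scaled to reads per million; identity when no library size."""
        if self.total_reads is None:
            return self.counts.copy()
        return self.counts * 1e6 / self.total_reads

    def slice(self, left: int, right: int) -> np.ndarray:
        """Counts over genomic interval [left, right)."""
        if not (self.start <= left < right <= self.end):
            raise ValueError(f"[{left}, {right}) outside map window")
        return self.counts[left - self.start : right - self.start]


@dataclass
class Hotspot:
    """A SPO11 hotspot: center, bounds, and total oligo signal (strength)."""

    chrom: str
    center: int
    left: int
    right: int
    strength: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.left < self.center < self.right):
            raise ValueError("require left < center < right")


@dataclass
class SignalProfile:
    """A signal on a grid of positions relative to an anchor (hotspot center)."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")


def hann_kernel(width: int) -> np.ndarray:
    """Hann window w[n] = sin^2(pi*n/(width-1)), n = 0..width-1, normalized
    to sum 1. width=1 is the identity kernel. Endpoints are zero for
    width >= 2, so the effective support is width-2."""
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be a positive odd integer")
    if width == 1:
        return np.ones(1)
    n = np.arange(width)
    w = np.sin(np.pi * n / (width - 1)) ** 2
    return w / w.sum()


def smooth_hann(values: np.ndarray, width: int) -> np.ndarray:
    """Smooth with a normalized Hann kernel; the kernel is truncated and
    renormalized at the edges so output length equals input length."""
    values = np.asarray(values, dtype=float)
    if width > values.size:
        raise ValueError("width must not exceed signal length")
    kernel = hann_kernel(width)
    num = np.convolve(values, kernel, mode="same")
    # weight actually under the (truncated) kernel at each position
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def local_normalize(values: np.ndarray, window: int = 3001) -> np.ndarray:
    """Divide the signal at each base pair by the mean signal within a
    centered window (default 3001 bp), truncated at the edges.

    Windows with zero mean yield 0 with a warning.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    h = window // 2
    n = values.size
    cum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    means = (cum[hi] - cum[lo]) / (hi - lo)
    out = np.zeros_like(values)
    ok = means > 0
    if not ok.all():
        warnings.warn(
            "zero-mean window(s) in local_normalize; emitting 0 there",
            stacklevel=2,
        )
    out[ok] = values[ok] / means[ok]
    return out


def flip_and_average(
    profiles: list[SignalProfile], flip_flags: list[bool]
) -> SignalProfile:
    """Mirror flagged profiles about position 0, then average pointwise.

    Used to combine left- and right-hotspot profiles of a pair onto a common
    orientation before cross-hotspot averaging. All profiles must share one
    anchor-relative grid; flipping requires the grid to be symmetric.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if len(profiles) != len(flip_flags):
        raise ValueError("one flip flag per profile required")
    grid = profiles[0].positions
    for p in profiles[1:]:
        if not np.array_equal(p.positions, grid):
            raise ValueError("profiles must share the same position grid")
    stack = []
    for p, flip in zip(profiles, flip_flags):
        if flip:
            if not np.array_equal(-grid[::-1], grid):
                raise ValueError("flipping requires a symmetric position grid")
            stack.append(p.values[::-1])
        else:
            stack.append(p.values)
    return SignalProfile(grid.copy(), np.mean(stack, axis=0))


def call_hotspot(
    spo_map: SpoOligoMap,
    bounds: tuple[int, int],
    smooth_width: int = 151,
    name: str = "",
) -> Hotspot:
    """Call a hotspot within genomic bounds.

    The center is the argmax of the Hann-smoothed signal within the bounds
    (leftmost maximum on ties; smoothing is computed over the whole map so
    edge truncation inside the bounds does not bias the peak). Strength is
    the raw count sum within the bounds, independent of smoothing width.
    """
    left, right = bounds
    seg = spo_map.slice(left, right)
    if seg.size == 0 or not np.any(seg > 0):
        raise ValueError("no signal within bounds")
    smoothed = smooth_hann(spo_map.counts, min(smooth_width, spo_map.counts.size | 1))
    sseg = smoothed[left - spo_map.start : right - spo_map.start]
    center = left + int(np.argmax(sseg))
    if center == left:  # keep left < center < right strict
        center = left + 1 if right - left > 1 else left
    return Hotspot(
        chrom=spo_map.chrom,
        center=center,
        left=left,
        right=right,
        strength=float(seg.sum()),
        name=name,
    )


# ---------------------------------------------------------------------------
# I/O: bedGraph and BED6


def read_bedgraph(path) -> SpoOligoMap:
    """Read a 4-column bedGraph (chrom, start, end, value; 0-based half-open)
    or a 2-column TSV (position, value) into a per-base map."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 4:
        chrom = str(df.iloc[0, 0])
        start = int(df[1].min())
        end = int(df[2].max())
        counts = np.zeros(end - start)
        for _, row in df.iterrows():
            counts[int(row[1]) - start : int(row[2]) - start] = float(row[3])
    elif df.shape[1] == 2:
        chrom = "chrU"
        pos = df[0].astype(int).to_numpy()
        start, end = int(pos.min()), int(pos.max()) + 1
        counts = np.zeros(end - start)
        counts[pos - start] = df[1].astype(float).to_numpy()
    else:
        raise ValueError("expected bedGraph (4 cols) or position/value TSV (2 cols)")
    return SpoOligoMap(chrom=chrom, start=start, counts=counts)


def write_bedgraph(spo_map: SpoOligoMap, path, values: np.ndarray | None = None) -> None:
    """Write per-base values as bedGraph, merging equal-valued runs."""
    v = spo_map.counts if values is None else np.asarray(values, dtype=float)
    rows = []
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[j + 1] == v[i]:
            j += 1
        rows.append((spo_map.chrom, spo_map.start + i, spo_map.start + j + 1, v[i]))
        i = j + 1
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_hotspot_bed(path) -> list[Hotspot]:
    """Read hotspots from BED6 (name = id, score = strength); the center is
    thickStart when columns 7 is present, else the interval midpoint."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for _, row in df.iterrows():
        left, right = int(row[1]), int(row[2])
        center = int(row[6]) if df.shape[1] > 6 else (left + right) // 2
        out.append(
            Hotspot(
                chrom=str(row[0]),
                center=center,
                left=left,
                right=right,
                strength=float(row[4]) if df.shape[1] > 4 else 0.0,
                name=str(row[3]) if df.shape[1] > 3 else "",
            )
        )
    return out


def write_hotspot_bed(hotspots: list[Hotspot], path) -> None:
    rows = [
        (h.chrom, h.left, h.right, h.name or f"hs{i}", h.strength, "+", h.center)
        for i, h in enumerate(hotspots)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
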