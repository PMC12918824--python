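"""Statistical comparison of end-joining spectra across genotypes.

Breakpoints are expressed relative to hotspot centers (positive to the
right; left-hotspot profiles of a pair are flipped before cross-pair
averaging). The module covers: the chance-microhomology model for junctions
in random DNA, exact 2x2 contingency tests, spread (Brown-Forsythe Levene)
and shift (Wilcoxon rank-sum) comparisons of breakpoint distributions,
center-window fractions, deletion-size stratification with kernel-density
size curves, strength-adjusted well-assay frequencies, and classification of
junction insertions against candidate source hotspots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .hotspots import Hotspot, SignalProfile, smooth_hann
from .junctions import revcomp
from .simulate import AssayResult, DeletionEvent

__all__ = [
    "BreakpointSet",
    "ContingencyTable2x2",
    "SizeStrata",
    "microhomology_chance",
    "fisher_exact",
    "spread_test",
    "shift_test",
    "center_window_fraction",
    "stratify_sizes",
    "adjusted_frequency",
    "classify_insertions",
    "breakpoint_profile",
]


@dataclass
class BreakpointSet:
    """Breakpoints of one genotype's events, relative to a hotspot center."""

    genotype: str
    events: list[DeletionEvent]
    center: int = 0

    @property
    def left_positions(self) -> np.ndarray:
        return np.array([e.left_bp - self.center for e in self.events])

    @property
    def right_positions(self) -> np.ndarray:
        return np.array([e.right_bp - self.center for e in self.events])

    @property
    def positions(self) -> np.ndarray:
        """Both breakpoints of every event, center-relative."""
        return np.concatenate([self.left_positions, self.right_positions])


@dataclass
class ContingencyTable2x2:
    cells: np.ndarray  # 2x2 non-negative ints
    row_labels: tuple[str, str] = ("a", "b")
    col_labels: tuple[str, str] = ("hit", "miss")

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        if self.cells.shape != (2, 2) or (self.cells < 0).any():
            raise ValueError("need a 2x2 table of non-negative counts")
        if self.cells.sum() == 0:
            raise ValueError("empty table")


def microhomology_chance(x: int) -> float:
    """Probability that a junction in random DNA shows a maximal
    microhomology of exactly x bp: P(x) = (x+1) (1/4)^x (3/4)^2.

    The microhomology can extend left and right of the junction; a total of
    x matching bases splits into (x+1) left/right combinations, each run
    terminated by a mismatch on both sides.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    return (x + 1) * 0.25**x * 0.75**2


def fisher_exact(table: ContingencyTable2x2 | list | np.ndarray) -> float:
    """Two-sided Fisher's exact p: the sum of hypergeometric probabilities,
    over all tables with the observed margins, that do not exceed the
    observed table's probability."""
    cells = table.cells if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    ContingencyTable2x2(cells)  # validates
    return float(sps.fisher_exact(cells, alternative="two-sided").pvalue)


def spread_test(*groups: np.ndarray) -> tuple[float, float]:
    """Brown-Forsythe Levene test (absolute deviations from the group
    median) for unequal spread of breakpoint positions. Returns (W, p).
    Degenerate all-identical groups yield p = 1 with a warning."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 3 for g in groups):
        raise ValueError("need >= 2 groups with n >= 3 each")
    if all(np.ptp(g) == 0 for g in groups):
        warnings.warn("all groups are constant; spread test is degenerate", stacklevel=2)
        return 0.0, 1.0
    stat, p = sps.levene(*groups, center="median")
    return float(stat), float(p)


def shift_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney, normal approximation with tie
    correction) for a location shift between two breakpoint sets. Returns
    (median(b) - median(a), p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 in each set")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(np.median(b) - np.median(a)), float(res.pvalue)


def center_window_fraction(positions: np.ndarray, half_width: int = 100) -> float:
    """Fraction of breakpoints within +/- half_width bp of the hotspot
    center (the conventional 200-bp center window)."""
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("empty breakpoint set")
    return float(np.mean(np.abs(positions) <= half_width))


DEFAULT_SIZE_EDGES = (1, 11, 18, 25, 46, 76, 200, np.inf)


@dataclass
class SizeStrata:
    """Events partitioned by net deletion size. Default edges isolate the
    ~13-bp (11-17) and ~21-bp (18-24) very-small classes, the ~30-bp and
    ~60-bp double-cut classes, and the >= 200 bp tail."""

    edges: tuple = DEFAULT_SIZE_EDGES
    bins: dict = field(default_factory=dict)  # label -> list of events

    @property
    def labels(self) -> list[str]:
        return list(self.bins)

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.bins.items()}


def _bin_label(lo, hi) -> str:
    return f">={int(lo)}" if np.isinf(hi) else f"{int(lo)}-{int(hi) - 1}"


def stratify_sizes(
    events: list[DeletionEvent],
    edges: tuple = DEFAULT_SIZE_EDGES,
    center: int = 0,
    smooth_width: int = 21,
    kde_bandwidth: float = 2.0,
) -> tuple[SizeStrata, dict]:
    """Bin events by net deletion size and emit per-bin summaries.

    Returns (strata, per-bin dict of {breakpoint profile (Hann-smoothed
    counts on a center-relative grid), size-density curve (Gaussian KDE,
    2-bp bandwidth)}). Empty bins are present with count 0.
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    strata = SizeStrata(edges=edges)
    for lo, hi in zip(edges, edges[1:]):
        strata.bins[_bin_label(lo, hi)] = []
    for e in events:
        size = e.size
        if size < edges[0]:
            raise ValueError(f"event size {size} below first edge")
        for lo, hi in zip(edges, edges[1:]):
            if lo <= size < hi:
                strata.bins[_bin_label(lo, hi)].append(e)
                break
    summaries = {}
    for label, evs in strata.bins.items():
        if not evs:
            summaries[label] = {"profile": None, "size_density": None}
            continue
        bs = BreakpointSet(genotype=label, events=evs, center=center)
        summaries[label] = {
            "profile": breakpoint_profile(bs.positions, smooth_width=smooth_width),
            "size_density": _size_kde([e.size for e in evs], kde_bandwidth),
        }
    return strata, summaries


def _size_kde(sizes, bandwidth: float):
    sizes = np.asarray(sizes, dtype=float)
    grid = np.arange(max(1.0, sizes.min() - 10), sizes.max() + 11)
    dens = np.exp(-0.5 * ((grid[:, None] - sizes[None, :]) / bandwidth) ** 2)
    dens = dens.sum(axis=1) / (sizes.size * bandwidth * np.sqrt(2 * np.pi))
    return grid, dens


def breakpoint_profile(
    positions: np.ndarray, half_span: int | None = None, smooth_width: int = 21
) -> SignalProfile:
    """Per-base breakpoint counts on a center-relative grid, Hann-smoothed
    (default 21-bp filter)."""
    positions = np.asarray(positions, dtype=int)
    if half_span is None:
        half_span = int(max(100, np.abs(positions).max() + 50))
    grid = np.arange(-half_span, half_span + 1)
    counts = np.zeros(grid.size)
    inb = np.abs(positions) <= half_span
    np.add.at(counts, positions[inb] + half_span, 1)
    width = min(smooth_width, counts.size if counts.size % 2 else counts.size - 1)
    return SignalProfile(grid, smooth_hann(counts, width))


def adjusted_frequency(
    assay: AssayResult,
    pair: tuple[Hotspot, Hotspot],
    reference_pair: tuple[Hotspot, Hotspot],
) -> float:
    """Observed well-assay frequency adjusted for hotspot strength.

    The expected double-cutting weight of a pair is the product of its two
    hotspot strengths (independent cutting); the adjusted frequency scales
    the observed frequency by reference-pair weight over this pair's weight,
    so the reference pair's adjusted frequency equals its observed one.
    """
    w = pair[0].strength * pair[1].strength
    w_ref = reference_pair[0].strength * reference_pair[1].strength
    if w <= 0 or w_ref <= 0:
        raise ValueError("hotspot strengths must be positive")
    return assay.frequency * (w_ref / w)


def classify_insertions(
    events: list[DeletionEvent],
    ref: str,
    source_hotspots: list[tuple[Hotspot, tuple[int, int]]] | None = None,
    min_len: int = 15,
    flank: int = 400,
) -> dict:
    """Classify junction insertions as none / ectopic / inverted.

    Inserted sequences >= min_len bp are searched (exact and reverse-
    complement) within the supplied candidate source-hotspot windows; hits
    are annotated with the source hotspot and the distance of the insert
    midpoint from its center. Local inverted insertions are detected as
    reverse-complement matches to sequence flanking (within `flank` bp of)
    the deletion. Unmappable inserts are reported unclassified and excluded
    from source statistics.
    """
    source_hotspots = source_hotspots or []
    counts = {"none": 0, "ectopic": 0, "inverted": 0, "unclassified": 0}
    sources = []  # (event index, hotspot name, midpoint distance, orientation)
    for i, e in enumerate(events):
        ins = e.insertion.seq if e.insertion else ""
        if not ins:
            counts["none"] += 1
            continue
        if len(ins) < min_len:
            counts["unclassified"] += 1
            continue
        # local inverted: revcomp match near the deletion
        lo = max(0, e.left_bp - flank)
        hi = min(len(ref), e.right_bp + flank)
        if ref[lo:hi].find(revcomp(ins)) != -1:
            counts["inverted"] += 1
            continue
        hit = None
        for hs, (wlo, whi) in source_hotspots:
            window = ref[wlo:whi]
            for ori, probe in (("+", ins), ("-", revcomp(ins))):
                p = window.find(probe)
                if p != -1:
                    mid = wlo + p + len(ins) // 2
                    hit = (i, hs.name, mid - hs.center, ori)
                    break
            if hit:
                break
        if hit:
            counts["ectopic"] += 1
            sources.append(hit)
        else:
            counts["unclassified"] += 1
    return {"counts": counts, "sources": sources}
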