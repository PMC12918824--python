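"""Ground-truth simulation of SPO11 double-cut mutagenesis and its readouts.

Generates (i) cut sites drawn from SPO11-oligo maps, (ii) double cuts with
the ~10-bp spacing periodicity and ~21-bp minimum observed for co-oriented
SPO11 complexes, (iii) end-joining junctions under an unresected (NHEJ-like)
or resected (MMEJ-like) repair model, (iv) ectopic and inverted insertions of
double-cut fragments, and the two assay readouts: the limiting-dilution
nested-PCR well screen and amplicon paired-end deep sequencing with PCR
duplication and substitution errors.

Every stochastic operation takes an explicit seed or numpy Generator;
pipeline-level seeds are derived deterministically per stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .hotspots import SpoOligoMap
from .junctions import canonicalize_deletion, insertion_junction_mh, revcomp

__all__ = [
    "DoubleCut",
    "Insertion",
    "DeletionEvent",
    "RepairModel",
    "SpacingModel",
    "AssayResult",
    "FastqRead",
    "derive_seed",
    "sample_cut_sites",
    "make_double_cut",
    "join_ends",
    "make_insertion_event",
    "simulate_well_assay",
    "simulate_amplicon_reads",
    "random_reference",
    "make_oligo_map",
]


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from a master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class DoubleCut:
    """Two SPO11 cleavages on one chromatid releasing the fragment between
    them. Each cut leaves a 2-nt 5' overhang."""

    chromatid: int
    left_cut: int
    right_cut: int
    fragment: str = ""
    overhang: int = 2

    @property
    def spacing(self) -> int:
        return self.right_cut - self.left_cut


@dataclass
class Insertion:
    """Insertion captured at a deletion junction: an ectopic double-cut
    fragment from another hotspot, or a locally inverted segment."""

    kind: str  # "ectopic" | "inverted"
    seq: str
    source: str = ""  # source hotspot name (ectopic)
    source_interval: tuple[int, int] | None = None
    orientation: str = "+"
    junction_mh: int = 0  # inverted insertions: mh at exactly one junction


@dataclass
class DeletionEvent:
    """A joined double cut: deleted interval [left_bp, right_bp) in 0-based
    coordinates, canonicalized to leftmost placement against the reference,
    with observed junction microhomology and optional insertion."""

    chrom: str
    left_bp: int
    right_bp: int
    mh_len: int
    mh_seq: str
    insertion: Insertion | None = None
    genotype: str = ""
    drawn_mh: int = 0
    resected: bool = False
    tag: str = ""

    @property
    def size(self) -> int:
        return self.right_bp - self.left_bp

    def apply(self, ref: str) -> str:
        """The joined molecule sequence."""
        ins = self.insertion.seq if self.insertion else ""
        return ref[: self.left_bp] + ins + ref[self.right_bp :]


@dataclass
class SpacingModel:
    """Distance between the two DSBs of a double cut: a mixture on the
    ~10-bp lattice (21, 31, 41, ...) with per-component Gaussian jitter
    (sd 1.5 bp, truncated at +/-4), reflecting the steric periodicity of
    adjacent SPO11 complexes."""

    lattice: tuple[int, ...] = (21, 31, 41, 51, 61, 71, 81)
    weights: tuple[float, ...] = (0.25, 0.35, 0.25, 0.08, 0.04, 0.02, 0.01)
    jitter_sd: float = 1.5
    jitter_max: int = 4
    min_spacing: int = 21

    def __post_init__(self) -> None:
        if len(self.lattice) != len(self.weights):
            raise ValueError("lattice and weights must match")
        w = np.asarray(self.weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights must have positive mass")
        self.weights = tuple(w / w.sum())

    def sample(self, rng: np.random.Generator, max_tries: int = 100) -> int:
        for _ in range(max_tries):
            base = rng.choice(self.lattice, p=self.weights)
            if self.jitter_sd > 0:
                j = rng.normal(0, self.jitter_sd)
                j = int(round(np.clip(j, -self.jitter_max, self.jitter_max)))
            else:
                j = 0
            s = int(base) + j
            if s >= self.min_spacing:
                return s
        raise RuntimeError("spacing resampling exceeded retry bound")


@dataclass
class RepairModel:
    """End-joining model.

    unresected: junction at the cut positions; the drawn 0-2 bp offset models
    annealing of the 2-nt 5' overhangs (otherwise treated as filled in before
    ligation). Observed microhomology is whatever the flanks share by chance.

    resected: resection lengths per end drawn from a gamma distribution
    (mean ~1100 nt in mouse meiosis); the junction is placed at a shared
    k-mer (k drawn from the microhomology distribution) found within the
    resected flanks, widening the deletion (MMEJ).
    """

    mode: str = "unresected"
    mh_probs: dict[int, float] = field(default_factory=dict)
    resection_mean: float = 1100.0
    resection_shape: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in ("unresected", "resected"):
            raise ValueError("mode must be 'unresected' or 'resected'")
        if not self.mh_probs:
            self.mh_probs = (
                {0: 0.5, 1: 0.3, 2: 0.2}
                if self.mode == "unresected"
                else {1: 0.22, 2: 0.20, 3: 0.16, 4: 0.14, 5: 0.10,
                      6: 0.07, 7: 0.05, 8: 0.03, 9: 0.02, 10: 0.01}
            )
        tot = sum(self.mh_probs.values())
        if not np.isclose(tot, 1.0):
            self.mh_probs = {k: v / tot for k, v in self.mh_probs.items()}
        if self.mode == "unresected" and max(self.mh_probs) > 2:
            raise ValueError("unresected mode allows microhomology <= 2 bp")

    @classmethod
    def unresected(cls) -> "RepairModel":
        return cls(mode="unresected")

    @classmethod
    def resected(cls) -> "RepairModel":
        return cls(mode="resected")

    def sample_mh(self, rng: np.random.Generator) -> int:
        ks = sorted(self.mh_probs)
        ps = np.array([self.mh_probs[k] for k in ks])
        return int(rng.choice(ks, p=ps / ps.sum()))

    def sample_resection(self, rng: np.random.Generator) -> int:
        scale = self.resection_mean / self.resection_shape
        return max(1, int(round(rng.gamma(self.resection_shape, scale))))


@dataclass
class AssayResult:
    """Nested-PCR well screen: each well seeded with ~16,000 haploid genome
    equivalents; the per-genome deletion frequency is positives over total
    genomes screened."""

    wells: int
    genomes_per_well: int
    positives: list = field(default_factory=list)  # (well index, event or None)

    @property
    def total_genomes(self) -> int:
        return self.wells * self.genomes_per_well

    @property
    def frequency(self) -> float:
        return len(self.positives) / self.total_genomes

    @classmethod
    def from_positives(cls, n_events: int, wells: int, genomes_per_well: int = 16000):
        return cls(wells, genomes_per_well, [(i % wells, None) for i in range(n_events)])


# ---------------------------------------------------------------------------
# Cut-site and double-cut sampling


def sample_cut_sites(spo_map: SpoOligoMap, n: int, seed) -> np.ndarray:
    """Draw n cut positions from the map's counts treated as a probability
    distribution over base pairs. Reproducible under seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    total = spo_map.counts.sum()
    if total <= 0:
        raise ValueError("cannot sample from an all-zero map")
    rng = _rng(seed)
    p = spo_map.counts / total
    idx = rng.choice(spo_map.counts.size, size=n, p=p)
    return spo_map.start + idx


def make_double_cut(
    spo_map: SpoOligoMap,
    spacing_model: SpacingModel | None = None,
    seed=None,
    ref: str | None = None,
    chromatid: int = 0,
) -> DoubleCut:
    """Place a double cut: the left cut drawn from the oligo map, the spacing
    from the lattice mixture model."""
    spacing_model = spacing_model or SpacingModel()
    rng = _rng(seed)
    left = int(sample_cut_sites(spo_map, 1, rng)[0])
    spacing = spacing_model.sample(rng)
    right = left + spacing
    frag = ""
    if ref is not None:
        if right > len(ref):
            right = len(ref)
        frag = ref[left:right]
    return DoubleCut(chromatid=chromatid, left_cut=left, right_cut=right, fragment=frag)


# ---------------------------------------------------------------------------
# End joining


def _find_shared_kmers(ref: str, lo1: int, hi1: int, lo2: int, hi2: int, k: int):
    """(i, j) pairs with ref[i:i+k] == ref[j:j+k], i+k <= hi1, j in [lo2, hi2-k]."""
    table: dict[str, list[int]] = {}
    for i in range(max(lo1, 0), hi1 - k + 1):
        table.setdefault(ref[i : i + k], []).append(i)
    pairs = []
    for j in range(lo2, min(hi2, len(ref)) - k + 1):
        for i in table.get(ref[j : j + k], ()):
            pairs.append((i, j))
    return pairs


def join_ends(
    cut: DoubleCut | tuple[int, int],
    ref: str,
    repair: RepairModel,
    seed=None,
    chrom: str = "chrU",
    genotype: str = "",
) -> DeletionEvent:
    """Join the two DSB ends flanking a deleted interval, producing a
    canonicalized DeletionEvent (ground truth for recovery tests).

    Accepts a DoubleCut or a plain (left_cut, right_cut) pair (e.g. two DSBs
    at adjacent hotspots).
    """
    rng = _rng(seed)
    if isinstance(cut, DoubleCut):
        lc, rc = cut.left_cut, cut.right_cut
    else:
        lc, rc = cut
    if not (0 < lc < rc <= len(ref)):
        raise ValueError("cut positions outside reference")
    tag = ""
    if repair.mode == "unresected":
        m = repair.sample_mh(rng)
        m = min(m, rc - lc - 1)
        left_bp, right_bp = lc, rc - m  # overhang annealing retains m bases
        drawn = m
        resected = False
    else:
        k = repair.sample_mh(rng)
        r_left = repair.sample_resection(rng)
        r_right = repair.sample_resection(rng)
        lo1, hi1 = max(0, lc - r_left), lc
        lo2, hi2 = rc, min(len(ref), rc + r_right)
        pairs = _find_shared_kmers(ref, lo1, hi1, lo2, hi2, k) if k >= 1 else []
        if pairs:
            i, j = pairs[rng.integers(len(pairs))]
            left_bp, right_bp = i + k, j + k
        else:
            left_bp, right_bp = lc, rc
            tag = "no_mh_fallback"
        drawn = k
        resected = True
    left_bp, right_bp, mh = canonicalize_deletion(ref, left_bp, right_bp)
    return DeletionEvent(
        chrom=chrom,
        left_bp=left_bp,
        right_bp=right_bp,
        mh_len=len(mh),
        mh_seq=mh,
        genotype=genotype,
        drawn_mh=drawn,
        resected=resected,
        tag=tag,
    )


def make_insertion_event(
    event: DeletionEvent,
    ref: str,
    donor: DoubleCut | None = None,
    kind: str = "ectopic",
    orientation: str | None = None,
    source: str = "",
    seed=None,
    max_tries: int = 50,
) -> DeletionEvent:
    """Attach an insertion to a deletion event.

    ectopic: the released fragment of a double cut at another hotspot is
    ligated into the junction in either orientation; donors overlapping the
    deletion interval are rejected.

    inverted: a segment local to the deletion is reinserted in inverted
    orientation; the returned event carries microhomology (>= 1 bp) at
    exactly one of the two insertion junctions.
    """
    rng = _rng(seed)
    L, R = event.left_bp, event.right_bp
    if kind == "ectopic":
        if donor is None:
            raise ValueError("ectopic insertion requires a donor double cut")
        if donor.left_cut < R and donor.right_cut > L:
            raise ValueError("donor fragment overlaps the deletion interval")
        ori = orientation or ("+" if rng.random() < 0.5 else "-")
        frag = donor.fragment or ref[donor.left_cut : donor.right_cut]
        seq = frag if ori == "+" else revcomp(frag)
        ins = Insertion(
            kind="ectopic",
            seq=seq,
            source=source,
            source_interval=(donor.left_cut, donor.right_cut),
            orientation=ori,
        )
        return replace(event, insertion=ins)
    if kind != "inverted":
        raise ValueError("kind must be 'ectopic' or 'inverted'")
    # inverted: sample local segments from the deleted interval until the
    # reverse-complement shows >= 1 bp junction microhomology at exactly one side
    span = R - L
    for attempt in range(max_tries):
        ln = int(rng.integers(10, max(11, min(60, span))))
        if ln >= span:
            ln = max(1, span - 1)
        a = L + int(rng.integers(0, span - ln + 1))
        seq = revcomp(ref[a : a + ln])
        lm, rm = insertion_junction_mh(ref, L, R, seq)
        if (lm >= 1) != (rm >= 1):
            ins = Insertion(
                kind="inverted",
                seq=seq,
                source_interval=(a, a + ln),
                orientation="-",
                junction_mh=max(lm, rm),
            )
            return replace(event, insertion=ins)
    raise RuntimeError("could not construct an inverted insertion with one-sided microhomology")


# ---------------------------------------------------------------------------
# Well assay


def simulate_well_assay(
    event_rate: float, wells: int, genomes_per_well: int = 16000, seed=None
) -> AssayResult:
    """Poisson well screen: per-well event counts ~ Poisson(rate x genomes);
    the frequency estimator is total events / total genomes."""
    if event_rate < 0:
        raise ValueError("rate must be >= 0")
    rng = _rng(seed)
    counts = rng.poisson(event_rate * genomes_per_well, size=wells)
    positives = [(w, None) for w in range(wells) for _ in range(int(counts[w]))]
    return AssayResult(wells=wells, genomes_per_well=genomes_per_well, positives=positives)


# ---------------------------------------------------------------------------
# Amplicon sequencing


@dataclass
class FastqRead:
    name: str
    seq: str
    qual: str


_BASES = np.frombuffer(b"ACGT", dtype="S1")
BASE_Q = 33  # Phred baseline assigned to correct bases
ERROR_Q = 12  # Phred assigned at substituted positions


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, str]:
    """Substitution errors at the given per-base rate; returns (seq, qual)
    with errored positions flagged by a low quality score."""
    n = len(seq)
    qual = np.full(n, BASE_Q + 33, dtype=np.uint8)
    if rate > 0:
        hits = np.nonzero(rng.random(n) < rate)[0]
        if hits.size:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            for i in hits:
                choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
                arr[i] = bytes([choices[rng.integers(3)]])
            qual[hits] = ERROR_Q + 33
            seq = arr.tobytes().decode()
    return seq, qual.tobytes().decode("latin1")


def _pcr_copies(n_molecules: int, cycles: int, efficiency: float, rng) -> np.ndarray:
    """Galton-Watson amplification: each copy duplicates with probability
    `efficiency` per cycle."""
    copies = np.ones(n_molecules, dtype=np.int64)
    for _ in range(cycles):
        copies = copies + rng.binomial(copies, efficiency)
    return copies


def simulate_amplicon_reads(
    molecules: list[tuple[str, str, str]],
    seed=None,
    pcr_cycles: int = 22,
    efficiency: float = 0.9,
    error_rate: float = 1e-3,
    read_len: int = 300,
    depth: int | None = None,
    min_per_molecule: int = 1,
) -> list[tuple[FastqRead, FastqRead]]:
    """Simulate paired-end sequencing of PCR-amplified molecules.

    molecules: (molecule_id, event_id, sequence) triples; sequences span the
    amplicon (primer to primer). Each molecule is amplified by a branching
    process over `pcr_cycles` cycles, the pool is sampled to `depth` read
    pairs (default: 3 per molecule, with a guaranteed floor of
    `min_per_molecule` pairs each so every input molecule is observed), and
    300-bp paired reads are taken from
    the two amplicon ends with substitution errors at `error_rate`. Read
    names encode molecule and event ids for truth tracking.
    """
    if not molecules:
        return []
    for _, _, seq in molecules:
        if len(seq) < 20:
            raise ValueError("molecule shorter than the minimum primer span")
    rng = _rng(seed)
    depth = depth if depth is not None else 3 * len(molecules)
    copies = _pcr_copies(len(molecules), pcr_cycles, efficiency, rng)
    p = copies / copies.sum()
    base = np.repeat(np.arange(len(molecules)), min_per_molecule)
    extra = max(0, depth - base.size)
    picks = np.concatenate([base, rng.choice(len(molecules), size=extra, p=p)])
    out = []
    for ridx, mi in enumerate(picks):
        mid, eid, seq = molecules[mi]
        rl = min(read_len, len(seq))
        name = f"{mid}|{eid}|rd{ridx}"
        s1, q1 = _apply_errors(seq[:rl], error_rate, rng)
        s2, q2 = _apply_errors(revcomp(seq[-rl:]), error_rate, rng)
        out.append((FastqRead(name + "/1", s1, q1), FastqRead(name + "/2", s2, q2)))
    return out


def write_fastq(reads: list[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# Synthetic references and oligo maps


def random_reference(length: int, seed) -> str:
    rng = _rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_oligo_map(
    chrom: str,
    start: int,
    length: int,
    center: int,
    peak_offsets: tuple[int, ...] = (0, 34, 55),
    peak_weights: tuple[float, ...] = (0.55, 0.25, 0.20),
    peak_sd: float = 2.0,
    total_signal: float = 1000.0,
    floor: float = 0.01,
    seed=None,
) -> SpoOligoMap:
    """A hotspot-shaped SPO11-oligo map: a major peak at the center with
    secondary peaks offset by the characteristic ~34/~55-bp spacings, over a
    low uniform floor."""
    pos = np.arange(start, start + length)
    sig = np.zeros(length)
    for off, w in zip(peak_offsets, peak_weights):
        sig += w * np.exp(-0.5 * ((pos - (center + off)) / peak_sd) ** 2)
    sig = sig / sig.sum() * total_signal * (1 - floor)
    sig += total_signal * floor / length
    if seed is not None:
        rng = _rng(seed)
        sig = rng.poisson(sig).astype(float)
    return SpoOligoMap(chrom=chrom, start=start, counts=sig)
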