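"""Amplicon microdeletion junction caller.

From paired 300-bp FASTQ reads to validated, deduplicated deletion junction
calls per amplicon:

1. merge overlapping read pairs into single molecule-spanning reads;
2. infer apparent amplicons ab initio from read outer endpoints;
3. collapse reads into unique sequences per amplicon, keeping the best base
   quality seen at each position;
4. align each unique sequence to its amplicon (global, affine gaps) so
   large deletions appear as single deletion operations;
5. extract deletion operations >= 10 bp, pairing nearby insertions for
   net-size accounting;
6. discard balanced-indel artifacts (net deletion < 10 bp) that arise when a
   low-quality read segment fails to align;
7. infer microhomologous or inserted bases at each junction, canonicalized
   to the leftmost placement;
8. collapse identical alignment paths (potential PCR duplicates of one input
   molecule) into unique molecular events;
9. apply mean-base-quality and mapping-confidence filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import islice

import numpy as np
from Bio import Align

from .junctions import canonicalize_junction, revcomp
from .simulate import FastqRead

logger = logging.getLogger(__name__)

__all__ = [
    "AmpliconDef",
    "MergedRead",
    "AlignmentPath",
    "DeletionCandidate",
    "JunctionCall",
    "merge_pairs",
    "read_fastq",
    "infer_amplicons",
    "collapse_unique",
    "make_aligner",
    "align_to_amplicon",
    "extract_deletions",
    "filter_artifact_indels",
    "infer_junction_bases",
    "dedup_paths",
    "apply_quality_filters",
    "call_amplicons",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class AmpliconDef:
    """An amplicon reference interval (0-based half-open) with its sequence."""

    name: str
    chrom: str
    start: int
    end: int
    seq: str
    primer_len: int = 20

    def __post_init__(self) -> None:
        if self.seq and len(self.seq) != self.end - self.start:
            raise ValueError("sequence length must equal end - start")
        if self.end - self.start < 2 * self.primer_len:
            raise ValueError("amplicon shorter than its primers")


@dataclass
class MergedRead:
    """A read pair merged into a single molecule-spanning read."""

    seq: str
    qual: np.ndarray  # numeric Phred per base
    pair_id: str
    status: str = "merged"  # "merged" | "unmerged"

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError("quality length must equal sequence length")


@dataclass
class UniqueSeq:
    seq: str
    qual: np.ndarray  # best (max) quality per position over the group
    group_size: int
    rep_id: str
    amplicon: str = ""


@dataclass
class AlignmentPath:
    """Ordered alignment of a read against one amplicon reference: aligned
    segments plus the gap operations between them."""

    amplicon: str
    score: float
    map_conf: float
    segments: list  # [(t_start, t_end, q_start, q_end)] amplicon-local
    ops: list  # [("D"|"I", t_pos, length, q_pos, inserted_seq)]


@dataclass
class DeletionCandidate:
    """A deletion operation >= min size with any paired nearby insertion."""

    amplicon: str
    del_start: int  # amplicon-local reference coords
    del_end: int
    del_len: int
    ins_len: int
    ins_seq: str
    read_id: str


@dataclass
class JunctionCall:
    """A validated junction: canonicalized deleted interval, net size,
    microhomology or inserted bases, and quality/duplicate metadata."""

    amplicon: str
    chrom: str
    left_bp: int  # genomic, leftmost-canonical
    right_bp: int
    del_len: int
    ins_len: int
    net: int
    mh_len: int
    mh_seq: str
    ins_seq: str
    mean_baseq: float
    map_conf: float
    group_size: int
    read_id: str
    multiplicity: int = 1  # reads collapsed into this unique event
    n_molecules: int = 1  # unique sequences sharing this path


# ---------------------------------------------------------------------------
# FASTQ and read merging


def read_fastq(path) -> list[FastqRead]:
    reads = []
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln]
    if len(lines) % 4:
        raise ValueError(f"malformed FASTQ {path}: line count not a multiple of 4")
    for i in range(0, len(lines), 4):
        if not lines[i].startswith("@") or lines[i + 2][:1] != "+":
            raise ValueError(f"malformed FASTQ {path} at record {i // 4}")
        seq, qual = lines[i + 1], lines[i + 3]
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ {path} at record {i // 4}: length mismatch")
        reads.append(FastqRead(lines[i][1:], seq, qual))
    return reads


def _qnum(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("latin1"), dtype=np.uint8).astype(int) - 33


def _overlap_candidates(s1: str, s2: str, anchor: int = 20) -> list[int]:
    """Candidate offsets of s2 within s1 from exact anchor matches."""
    cands = set()
    for a_ofs in (0, anchor):  # second anchor tolerates an error in the first
        if len(s2) >= a_ofs + anchor:
            probe = s2[a_ofs : a_ofs + anchor]
            p = s1.find(probe)
            while p != -1:
                if p - a_ofs >= 0:
                    cands.add(p - a_ofs)
                p = s1.find(probe, p + 1)
    return sorted(cands)


def merge_pairs(
    r1: FastqRead,
    r2: FastqRead,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.10,
) -> MergedRead:
    """Merge a read pair by its best ungapped overlap.

    r2 is reverse-complemented, slid along r1, and the overlap with the best
    (matches - mismatches) score among placements with >= min_overlap bases
    and <= 10% mismatches is taken; the consensus uses the higher-quality
    base at each disagreement. Pairs with no acceptable overlap are returned
    with status "unmerged" and are excluded from calling.
    """
    s1, q1 = r1.seq, _qnum(r1.qual)
    s2 = revcomp(r2.seq)
    q2 = _qnum(r2.qual)[::-1].copy()
    n1, n2 = len(s1), len(s2)
    a1 = np.frombuffer(s1.encode(), dtype="S1")
    a2 = np.frombuffer(s2.encode(), dtype="S1")

    offsets = _overlap_candidates(s1, s2)
    if not offsets:  # fall back to a full scan
        offsets = list(range(0, n1 - min_overlap + 1))
    best = None
    for o in offsets:
        ov = min(n1 - o, n2)
        if ov < min_overlap:
            continue
        mism = int((a1[o : o + ov] != a2[:ov]).sum())
        if mism > max_mismatch_frac * ov:
            continue
        score = (ov - mism) - mism
        if best is None or score > best[0]:
            best = (score, o, ov, mism)
    if best is None:
        return MergedRead(seq=s1, qual=q1, pair_id=r1.name, status="unmerged")
    _, o, ov, _ = best
    # consensus over [o, o+ov); r1 prefix before, r2 tail after
    cons = list(s1[:o])
    qcons = list(q1[:o])
    for i in range(ov):
        if s1[o + i] == s2[i]:
            cons.append(s1[o + i])
            qcons.append(max(q1[o + i], q2[i]))
        elif q2[i] > q1[o + i]:
            cons.append(s2[i])
            qcons.append(q2[i])
        else:
            cons.append(s1[o + i])
            qcons.append(q1[o + i])
    cons.extend(s2[ov:])
    qcons.extend(q2[ov:])
    return MergedRead(
        seq="".join(cons), qual=np.array(qcons), pair_id=r1.name, status="merged"
    )


# ---------------------------------------------------------------------------
# Amplicon inference and read assignment


def _locate_endpoints(seq: str, ref: str, anchor: int = 20) -> tuple[int, int] | None:
    """Outer (start, end) of a read on the reference from exact anchor
    matches at the read's ends; a second anchor position tolerates a
    sequencing error within the terminal anchor."""
    start = end = None
    for ofs in (0, anchor):
        p = ref.find(seq[ofs : ofs + anchor])
        if p != -1 and ref.find(seq[ofs : ofs + anchor], p + 1) == -1:
            start = p - ofs
            break
    for ofs in (0, anchor):
        probe = seq[len(seq) - anchor - ofs : len(seq) - ofs]
        p = ref.find(probe)
        if p != -1 and ref.find(probe, p + 1) == -1:
            end = p + anchor + ofs
            break
    if start is None or end is None or not (0 <= start < end <= len(ref)):
        return None
    return start, end


def infer_amplicons(
    merged: list[MergedRead],
    ref: str,
    chrom: str = "chrU",
    ref_start: int = 0,
    tol: int = 5,
    min_reads: int = 10,
    primer_len: int = 20,
) -> list[AmpliconDef]:
    """Ab initio amplicon identification: cluster the outer (start, end)
    endpoints of merged reads with +/- tol tolerance; clusters supported by
    >= min_reads reads become amplicons. Reads whose ends cannot be located
    on the reference are excluded."""
    clusters: list[list] = []  # [start0, end0, [starts], [ends]]
    for m in merged:
        if m.status != "merged":
            continue
        loc = _locate_endpoints(m.seq, ref)
        if loc is None:
            continue
        s, e = loc
        for c in clusters:
            if abs(s - c[0]) <= tol and abs(e - c[1]) <= tol:
                c[2].append(s)
                c[3].append(e)
                break
        else:
            clusters.append([s, e, [s], [e]])
    out = []
    for i, c in enumerate(sorted(clusters, key=lambda c: (c[0], c[1]))):
        if len(c[2]) < min_reads:
            continue
        s = int(np.median(c[2]))
        e = int(np.median(c[3]))
        out.append(
            AmpliconDef(
                name=f"amp{i + 1}",
                chrom=chrom,
                start=ref_start + s,
                end=ref_start + e,
                seq=ref[s:e],
                primer_len=primer_len,
            )
        )
    if not out:
        logger.warning("no amplicon clusters with >= %d reads", min_reads)
    return out


def assign_to_amplicons(
    merged: list[MergedRead],
    amplicons: list[AmpliconDef],
    ref: str,
    ref_start: int = 0,
    tol: int = 5,
) -> dict[str, list[MergedRead]]:
    """Assign merged reads to amplicons by matching outer endpoints within
    tolerance. A read with an internal deletion still carries both amplicon
    ends, so endpoints are unaffected by the event itself."""
    by_amp: dict[str, list[MergedRead]] = {a.name: [] for a in amplicons}
    for m in merged:
        if m.status != "merged":
            continue
        loc = _locate_endpoints(m.seq, ref)
        if loc is None:
            continue
        s, e = loc[0] + ref_start, loc[1] + ref_start
        for a in amplicons:
            if abs(s - a.start) <= tol and abs(e - a.end) <= tol:
                by_amp[a.name].append(m)
                break
    return by_amp


def collapse_unique(reads: list[MergedRead], amplicon: str = "") -> list[UniqueSeq]:
    """Group exactly identical sequences, keeping the elementwise maximum
    base quality over the group and the group size (PCR duplicates of one
    molecule collapse here when error-free)."""
    groups: dict[str, UniqueSeq] = {}
    for m in reads:
        u = groups.get(m.seq)
        if u is None:
            groups[m.seq] = UniqueSeq(
                seq=m.seq, qual=m.qual.copy(), group_size=1, rep_id=m.pair_id,
                amplicon=amplicon,
            )
        else:
            np.maximum(u.qual, m.qual, out=u.qual)
            u.group_size += 1
    return list(groups.values())


# ---------------------------------------------------------------------------
# Alignment


def make_aligner() -> Align.PairwiseAligner:
    """Affine-gap aligner for merged amplicon reads: match +1, mismatch -4,
    gap open -6, gap extend -0.5. Merged reads span the amplicon primer to
    primer, so the alignment is global on both sequences; the mild gap
    extension keeps large deletions as single contiguous deletion
    operations rather than split or end-shifted paths."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -4
    al.open_gap_score = -6
    al.extend_gap_score = -0.5
    return al


_ALIGNER = make_aligner()


def _path_from_alignment(aln, amplicon: AmpliconDef, seq: str) -> tuple[list, list]:
    tb, qb = aln.aligned
    segments = [(int(t0), int(t1), int(q0), int(q1)) for (t0, t1), (q0, q1) in zip(tb, qb)]
    ops = []
    for k in range(1, len(segments)):
        t_prev, q_prev = segments[k - 1][1], segments[k - 1][3]
        t_next, q_next = segments[k][0], segments[k][2]
        dlen = t_next - t_prev
        ilen = q_next - q_prev
        if dlen > 0:
            ops.append(("D", t_prev, dlen, q_prev, ""))
        if ilen > 0:
            ops.append(("I", t_next, ilen, q_prev, seq[q_prev:q_next]))
    return segments, ops


def align_to_amplicon(
    seq: str,
    amplicon: AmpliconDef,
    competitors: list[AmpliconDef] | None = None,
    min_score: float = 10.0,
    max_conf: float = 60.0,
) -> AlignmentPath | None:
    """Align a unique sequence to its amplicon reference.

    Mapping confidence (0-60) is the scaled margin (2x, capped at 60)
    between the best score and the best competitor-amplicon score; a
    sequence with two equal-score placements within the amplicon gets
    confidence 0. Unique full-length alignments score 60. Below min_score the sequence is
    unaligned and excluded downstream.
    """
    alns = _ALIGNER.align(amplicon.seq, seq)
    score = alns.score
    if score < min_score:
        return None
    spans = set()
    first = None
    for a in islice(alns, 8):
        if first is None:
            first = a
        tb = a.aligned[0]
        if len(tb):
            spans.add((int(tb[0][0]), int(tb[-1][1])))
    if first is None:
        return None
    if len(spans) > 1:
        conf = 0.0
    else:
        second = None
        for comp in competitors or ():
            if comp.name == amplicon.name:
                continue
            s = _ALIGNER.score(comp.seq, seq)
            second = s if second is None else max(second, s)
        conf = (
            max_conf
            if second is None
            else float(np.clip(2.0 * (score - second), 0, max_conf))
        )
    segments, ops = _path_from_alignment(first, amplicon, seq)
    return AlignmentPath(
        amplicon=amplicon.name, score=float(score), map_conf=conf,
        segments=segments, ops=ops,
    )


# ---------------------------------------------------------------------------
# Junction extraction and filtering


def extract_deletions(
    path: AlignmentPath, min_del: int = 10, pair_window: int = 30, read_id: str = ""
) -> list[DeletionCandidate]:
    """Candidates from deletion operations >= min_del bp; insertion
    operations within pair_window bp on the read are paired with the
    deletion for net-size accounting."""
    cands = []
    for kind, tpos, length, qpos, _ in path.ops:
        if kind != "D" or length < min_del:
            continue
        ins_len = 0
        ins_seq = ""
        for k2, t2, l2, q2, s2 in path.ops:
            if k2 == "I" and abs(q2 - qpos) <= pair_window:
                ins_len += l2
                if q2 == qpos:  # insertion at the junction itself
                    ins_seq = s2
        cands.append(
            DeletionCandidate(
                amplicon=path.amplicon, del_start=tpos, del_end=tpos + length,
                del_len=length, ins_len=ins_len, ins_seq=ins_seq, read_id=read_id,
            )
        )
    return cands


def filter_artifact_indels(
    cands: list[DeletionCandidate], min_net: int = 10
) -> tuple[list[DeletionCandidate], list[DeletionCandidate]]:
    """Retain candidates with net deletion (deletion - paired insertion)
    >= min_net bp; balanced indels, the signature of a low-quality read
    segment failing to align, are discarded. Returns (retained, discarded)."""
    kept, dropped = [], []
    for c in cands:
        if c.del_len - c.ins_len >= min_net:
            kept.append(c)
        else:
            dropped.append(c)
            logger.debug(
                "discarding balanced indel del=%d ins=%d (%s)",
                c.del_len, c.ins_len, c.read_id,
            )
    return kept, dropped


def infer_junction_bases(
    cand: DeletionCandidate, amplicon: AmpliconDef
) -> tuple[int, int, str, str]:
    """Canonical (left, right, ins_seq, mh_seq) for a candidate, amplicon-
    local. Microhomology is the maximal junction slide; junctions with
    inserted bases matching neither flank report those bases verbatim and
    microhomology 0."""
    return canonicalize_junction(amplicon.seq, cand.del_start, cand.del_end, cand.ins_seq)


def build_calls(
    unique: UniqueSeq,
    path: AlignmentPath,
    cands: list[DeletionCandidate],
    amplicon: AmpliconDef,
) -> list[JunctionCall]:
    calls = []
    for c in cands:
        left, right, ins, mh = infer_junction_bases(c, amplicon)
        calls.append(
            JunctionCall(
                amplicon=amplicon.name,
                chrom=amplicon.chrom,
                left_bp=amplicon.start + left,
                right_bp=amplicon.start + right,
                del_len=c.del_len,
                ins_len=c.ins_len,
                net=c.del_len - c.ins_len,
                mh_len=len(mh),
                mh_seq=mh,
                ins_seq=ins,
                mean_baseq=float(unique.qual.mean()),
                map_conf=path.map_conf,
                group_size=unique.group_size,
                read_id=unique.rep_id,
            )
        )
    return calls


def dedup_paths(calls_per_read: list[list[JunctionCall]]) -> list[JunctionCall]:
    """Collapse reads with identical alignment paths — same amplicon and
    same ordered junction list (coordinates + inserted bases) — into one
    unique molecular event each: identical reads may be PCR duplicates of a
    single input molecule (conservative rule). Keeps the best-quality
    representative; multiplicity counts reads, n_molecules counts unique
    sequences."""
    groups: dict[tuple, list[list[JunctionCall]]] = {}
    for calls in calls_per_read:
        if not calls:
            continue
        key = (
            calls[0].amplicon,
            tuple((c.left_bp, c.right_bp, c.ins_seq) for c in calls),
        )
        groups.setdefault(key, []).append(calls)
    out = []
    for group in groups.values():
        best = max(group, key=lambda cs: (cs[0].mean_baseq, cs[0].map_conf))
        mult = sum(cs[0].group_size for cs in group)
        for c in best:
            out.append(replace(c, multiplicity=mult, n_molecules=len(group)))
    return out


def apply_quality_filters(
    calls: list[JunctionCall],
    min_mean_baseq: float = 25.0,
    min_map_conf: float = 55.0,
) -> tuple[list[JunctionCall], list[tuple[JunctionCall, str]]]:
    """Retain calls whose representative read has mean base quality >= 25
    and mapping confidence >= 55 (0-60 scale). Returns (kept, rejected with
    reason)."""
    kept, rejected = [], []
    for c in calls:
        if c.mean_baseq < min_mean_baseq:
            rejected.append((c, "base_quality"))
        elif c.map_conf < min_map_conf:
            rejected.append((c, "map_conf"))
        else:
            kept.append(c)
    for c, reason in rejected:
        logger.debug("rejected call at %d-%d: %s", c.left_bp, c.right_bp, reason)
    return kept, rejected


# ---------------------------------------------------------------------------
# End-to-end calling


def call_amplicons(
    pairs: list[tuple[FastqRead, FastqRead]],
    ref: str,
    amplicons: list[AmpliconDef] | None = None,
    chrom: str = "chrU",
    ref_start: int = 0,
    min_net: int = 10,
    min_mean_baseq: float = 25.0,
    min_map_conf: float = 55.0,
    min_amplicon_reads: int = 10,
) -> tuple[list[JunctionCall], dict]:
    """Full caller: FASTQ pairs to validated unique junction calls.

    When no amplicon definitions are supplied they are inferred ab initio
    from read outer endpoints. Returns (calls, stage-count log).
    """
    merged = [merge_pairs(r1, r2) for r1, r2 in pairs]
    ok = [m for m in merged if m.status == "merged"]
    log = {"pairs_in": len(pairs), "merged": len(ok), "unmerged": len(merged) - len(ok)}
    if amplicons is None:
        amplicons = infer_amplicons(
            ok, ref, chrom=chrom, ref_start=ref_start, min_reads=min_amplicon_reads
        )
    log["amplicons"] = len(amplicons)
    by_amp = assign_to_amplicons(ok, amplicons, ref, ref_start=ref_start)
    log["assigned"] = sum(len(v) for v in by_amp.values())
    amap = {a.name: a for a in amplicons}
    per_read_calls: list[list[JunctionCall]] = []
    n_unique = n_aligned = n_cand = n_artifact = 0
    for name, reads in by_amp.items():
        amp = amap[name]
        uniques = collapse_unique(reads, amplicon=name)
        n_unique += len(uniques)
        for u in uniques:
            path = align_to_amplicon(u.seq, amp, competitors=amplicons)
            if path is None:
                continue
            n_aligned += 1
            cands = extract_deletions(path, min_del=min_net, read_id=u.rep_id)
            n_cand += len(cands)
            kept, dropped = filter_artifact_indels(cands, min_net=min_net)
            n_artifact += len(dropped)
            calls = build_calls(u, path, kept, amp)
            if calls:
                per_read_calls.append(calls)
    unique_events = dedup_paths(per_read_calls)
    kept, rejected = apply_quality_filters(
        unique_events, min_mean_baseq=min_mean_baseq, min_map_conf=min_map_conf
    )
    log.update(
        unique_seqs=n_unique,
        aligned=n_aligned,
        candidates=n_cand,
        artifact_discards=n_artifact,
        unique_events=len(unique_events),
        quality_discards=len(rejected),
        calls=len(kept),
    )
    return kept, log


def calls_to_frame(calls: list[JunctionCall]):
    """Junction-call table (one row per junction)."""
    import pandas as pd

    rows = [
        dict(
            amplicon=c.amplicon, chrom=c.chrom, left_bp=c.left_bp, right_bp=c.right_bp,
            del_len=c.del_len, ins_len=c.ins_len, net=c.net, mh_len=c.mh_len,
            mh_seq=c.mh_seq, ins_seq=c.ins_seq, mean_baseq=round(c.mean_baseq, 2),
            map_conf=c.map_conf, reads=c.multiplicity, group_size=c.group_size,
            read_id=c.read_id,
        )
        for c in calls
    ]
    cols = [
        "amplicon", "chrom", "left_bp", "right_bp", "del_len", "ins_len", "net",
        "mh_len", "mh_seq", "ins_seq", "mean_baseq", "map_conf", "reads",
        "group_size", "read_id",
    ]
    return pd.DataFrame(rows, columns=cols)
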