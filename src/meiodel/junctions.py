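"""Junction canonicalization and microhomology inference.

A deletion junction can often be placed at several equivalent positions when
the two flanks share sequence (microhomology): the deleted interval can slide
by the length of the shared bases without changing the joined molecule. Both
the simulator's ground truth and the caller's output are canonicalized to the
LEFTMOST placement so that coordinates compare exactly.

Microhomology at a deletion junction is the longest sequence that is
simultaneously a suffix of the retained left flank and a prefix of the
resumed right flank — equivalently, the maximal range over which the
junction can slide.
"""

from __future__ import annotations

__all__ = [
    "revcomp",
    "slide_left",
    "microhomology_at",
    "canonicalize_deletion",
    "canonicalize_junction",
    "insertion_junction_mh",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def slide_left(ref: str, left: int, right: int) -> tuple[int, int]:
    """Shift a deleted interval [left, right) to its leftmost equivalent
    placement: while the base before the deletion equals the last deleted
    base, the junction can slide one step left."""
    while left > 0 and ref[left - 1] == ref[right - 1]:
        left -= 1
        right -= 1
    return left, right


def microhomology_at(ref: str, left: int, right: int) -> str:
    """Microhomology of the junction deleting [left, right): the longest m
    with ref[left:left+m] == ref[right:right+m] (how far the junction can
    slide right from this placement). At the leftmost placement this is the
    full microhomology."""
    m = 0
    n = len(ref)
    # m may exceed the deletion size: in a repeat run the junction slides
    # further than the deletion is long (the comparison self-overlaps)
    while right + m < n and ref[left + m] == ref[right + m]:
        m += 1
    return ref[left : left + m]


def canonicalize_deletion(ref: str, left: int, right: int) -> tuple[int, int, str]:
    """Return (left, right, microhomology) at the leftmost placement."""
    if not (0 <= left < right <= len(ref)):
        raise ValueError(f"deletion [{left}, {right}) outside reference")
    left, right = slide_left(ref, left, right)
    return left, right, microhomology_at(ref, left, right)


def canonicalize_junction(
    ref: str, left: int, right: int, ins: str = ""
) -> tuple[int, int, str, str]:
    """Canonical form (left, right, ins, microhomology) of a junction that
    deletes [left, right) and inserts `ins`, preserving the joined molecule
    ref[:left] + ins + ref[right:].

    Inserted bases that merely continue a flank are absorbed into the flanks
    (minimal insert); a pure deletion is then slid to its leftmost placement.
    Microhomology and inserted bases are mutually exclusive by construction.
    """
    if not (0 <= left <= right <= len(ref)):
        raise ValueError(f"junction [{left}, {right}) outside reference")
    # absorb insert bases identical to the adjoining reference
    while ins and left < right and ins[0] == ref[left]:
        ins = ins[1:]
        left += 1
    while ins and left < right and ins[-1] == ref[right - 1]:
        ins = ins[:-1]
        right -= 1
    if ins:
        return left, right, ins, ""
    if left == right:
        return left, right, "", ""
    left, right, mh = canonicalize_deletion(ref, left, right)
    return left, right, "", mh


def insertion_junction_mh(ref: str, left: int, right: int, ins: str) -> tuple[int, int]:
    """Microhomology lengths at the two junctions of an insertion placed in a
    deletion of [left, right): bases shared between the insert's ends and the
    retained flanks (insert prefix vs left-flank suffix; insert suffix vs
    right-flank start), assignable to either side."""
    lm = 0
    for k in range(1, min(len(ins), left) + 1):
        if ins[:k] == ref[left - k : left]:
            lm = k
    rm = 0
    for k in range(1, min(len(ins), len(ref) - right) + 1):
        if ins[-k:] == ref[right : right + k]:
            rm = k
    return lm, rm
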