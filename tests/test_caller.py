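"""Amplicon junction caller: read merging, amplicon inference, alignment,
junction extraction, artifact filtering, deduplication, quality filters,
and the end-to-end caller against simulated truth."""

import numpy as np
import pytest

from meiodel.caller import (
    AlignmentPath,
    AmpliconDef,
    JunctionCall,
    align_to_amplicon,
    apply_quality_filters,
    assign_to_amplicons,
    call_amplicons,
    collapse_unique,
    dedup_paths,
    extract_deletions,
    filter_artifact_indels,
    infer_amplicons,
    infer_junction_bases,
    merge_pairs,
    read_fastq,
)
from meiodel.junctions import canonicalize_deletion, revcomp
from meiodel.simulate import (
    FastqRead,
    RepairModel,
    derive_seed,
    random_reference,
    simulate_amplicon_reads,
)


def make_pair(seq, read_len=300, q1=None, q2=None):
    q1 = q1 or chr(33 + 35) * min(read_len, len(seq))
    q2 = q2 or chr(33 + 35) * min(read_len, len(seq))
    return (
        FastqRead("p/1", seq[:read_len], q1[: min(read_len, len(seq))]),
        FastqRead("p/2", revcomp(seq[-read_len:]), q2[: min(read_len, len(seq))]),
    )


class TestReadFastq:
    def test_malformed_rejected(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nII\n")  # qual length mismatch
        with pytest.raises(ValueError):
            read_fastq(p)
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n")  # truncated record
        with pytest.raises(ValueError):
            read_fastq(p)


class TestMergePairs:
    def test_perfect_overlap_reconstructs_molecule(self):
        seq = random_reference(560, 21)
        r1, r2 = make_pair(seq)
        m = merge_pairs(r1, r2)
        assert m.status == "merged"
        assert m.seq == seq
        assert len(m.qual) == 560

    def test_no_overlap_unmerged(self):
        seq = random_reference(700, 22)  # 2x300 reads leave a 100-bp gap
        r1, r2 = make_pair(seq)
        m = merge_pairs(r1, r2)
        assert m.status == "unmerged"

    def test_disagreement_takes_higher_quality_base(self):
        seq = random_reference(560, 23)
        r1, r2 = make_pair(seq)
        # corrupt one overlap base on r1 with low quality; r2 keeps truth
        pos = 150  # inside the 40-bp overlap [260, 300) of r1? use a
        # position covered by both reads: overlap region is [260, 300)
        pos = 280
        bad = "G" if seq[pos] != "G" else "T"
        s1 = r1.seq[:pos] + bad + r1.seq[pos + 1 :]
        q1 = r1.qual[:pos] + chr(33 + 5) + r1.qual[pos + 1 :]
        m = merge_pairs(FastqRead(r1.name, s1, q1), r2)
        assert m.status == "merged"
        assert m.seq == seq  # consensus restored the true base
        # and symmetrically: corrupt r2's copy instead
        rpos = 560 - 1 - pos  # position in r2 (reverse-complemented read)
        bad2 = revcomp(bad)
        s2 = r2.seq[:rpos] + bad2 + r2.seq[rpos + 1 :]
        q2 = r2.qual[:rpos] + chr(33 + 5) + r2.qual[rpos + 1 :]
        m2 = merge_pairs(r1, FastqRead(r2.name, s2, q2))
        assert m2.seq == seq

    def test_merged_length_with_deletion(self):
        ref = random_reference(560, 24)
        mol = ref[:200] + ref[260:]  # 60-bp deletion -> 500-bp molecule
        m = merge_pairs(*make_pair(mol))
        assert m.status == "merged"
        assert m.seq == mol


class TestAmpliconInference:
    def wt_reads(self, toy, n_per_amp=12, seed=1):
        mols = []
        for a in toy.amplicons:
            for j in range(n_per_amp):
                mols.append((f"{a.name}:wt{j}", "none", toy.ref[a.start : a.end]))
        pairs = simulate_amplicon_reads(mols, seed=seed, error_rate=0.0, depth=len(mols))
        return [merge_pairs(r1, r2) for r1, r2 in pairs]

    def test_recovers_all_four_amplicons(self, toy):
        merged = self.wt_reads(toy)
        amps = infer_amplicons(merged, toy.ref, chrom=toy.chrom)
        spans = {(a.start, a.end) for a in amps}
        assert spans == {(a.start, a.end) for a in toy.amplicons}

    def test_min_reads_threshold(self, toy):
        merged = self.wt_reads(toy, n_per_amp=3)
        assert infer_amplicons(merged, toy.ref, min_reads=10) == []
        assert len(infer_amplicons(merged, toy.ref, min_reads=3)) == 4

    def test_foreign_reads_excluded(self, toy):
        merged = self.wt_reads(toy) + [
            merge_pairs(*make_pair(random_reference(560, 77)))
        ]
        amps = infer_amplicons(merged, toy.ref)
        assert len(amps) == 4

    def test_assignment_matches_spans(self, toy):
        merged = self.wt_reads(toy)
        by_amp = assign_to_amplicons(merged, toy.amplicons, toy.ref)
        counts = {k: len(v) for k, v in by_amp.items()}
        assert counts == {a.name: 12 for a in toy.amplicons}


class TestCollapseUnique:
    def mread(self, seq, qual, pid="r"):
        from meiodel.caller import MergedRead

        return MergedRead(seq=seq, qual=np.asarray(qual), pair_id=pid)

    def test_identical_reads_collapse(self):
        reads = [self.mread("ACGT", [30, 30, 30, 30], f"r{i}") for i in range(50)]
        uniq = collapse_unique(reads)
        assert len(uniq) == 1
        assert uniq[0].group_size == 50

    def test_distinct_sequences_stay_separate(self):
        reads = [self.mread("ACGT", [30] * 4), self.mread("ACGA", [30] * 4)]
        assert len(collapse_unique(reads)) == 2

    def test_quality_is_elementwise_max(self):
        reads = [self.mread("ACGT", [10, 40, 10, 40]), self.mread("ACGT", [40, 10, 40, 10])]
        uniq = collapse_unique(reads)
        assert list(uniq[0].qual) == [40, 40, 40, 40]


def mk_amplicon(seq, name="ampX", start=0):
    return AmpliconDef(
        name=name, chrom="c", start=start, end=start + len(seq), seq=seq
    )


class TestAlignment:
    def test_identity_alignment(self):
        amp = mk_amplicon(random_reference(560, 31))
        path = align_to_amplicon(amp.seq, amp)
        assert path is not None
        assert path.ops == []
        assert path.map_conf == 60.0
        assert path.segments == [(0, 560, 0, 560)]

    def test_planted_deletion_single_op(self):
        ref = random_reference(560, 32)
        amp = mk_amplicon(ref)
        mol = ref[:250] + ref[310:]  # 60-bp deletion
        path = align_to_amplicon(mol, amp)
        dels = [op for op in path.ops if op[0] == "D"]
        assert len(dels) == 1
        _, tpos, length, _, _ = dels[0]
        assert length == 60
        # the op's placement is junction-equivalent to the planted one
        assert canonicalize_deletion(ref, tpos, tpos + length) == canonicalize_deletion(
            ref, 250, 310
        )

    def test_garbage_sequence_unaligned(self):
        amp = mk_amplicon(random_reference(560, 33))
        assert align_to_amplicon(random_reference(560, 34), amp) is None

    def test_ambiguous_placement_gets_zero_confidence(self):
        unit = random_reference(300, 35)
        amp = mk_amplicon(unit + unit)
        path = align_to_amplicon(unit, amp)
        assert path is not None
        assert path.map_conf == 0.0

    def test_competitor_margin_confidence(self, toy):
        a1, a2 = toy.amplicons[0], toy.amplicons[1]
        path = align_to_amplicon(a1.seq, a1, competitors=[a1, a2])
        assert path is not None
        # oracle: confidence = 2x score margin over the best competitor
        from meiodel.caller import make_aligner

        al = make_aligner()
        margin = al.score(a1.seq, a1.seq) - al.score(a2.seq, a1.seq)
        assert path.map_conf == pytest.approx(min(60.0, 2.0 * margin))
        assert path.map_conf >= 55.0


class TestExtractAndFilter:
    def path_with(self, ops):
        return AlignmentPath(amplicon="a", score=0, map_conf=60, segments=[], ops=ops)

    def test_small_deletion_ignored(self):
        path = self.path_with([("D", 100, 9, 100, "")])
        assert extract_deletions(path, min_del=10) == []

    def test_large_deletion_kept(self):
        path = self.path_with([("D", 100, 15, 100, "")])
        (c,) = extract_deletions(path, min_del=10)
        assert (c.del_start, c.del_end, c.del_len, c.ins_len) == (100, 115, 15, 0)

    def test_adjacent_insertion_paired(self):
        path = self.path_with([("D", 100, 30, 100, ""), ("I", 130, 28, 100, "A" * 28)])
        (c,) = extract_deletions(path, min_del=10)
        assert c.ins_len == 28
        assert c.ins_seq == "A" * 28

    def test_distant_insertion_not_paired(self):
        path = self.path_with([("D", 100, 30, 100, ""), ("I", 300, 28, 200, "A" * 28)])
        (c,) = extract_deletions(path, min_del=10)
        assert c.ins_len == 0

    def test_artifact_filter_arithmetic(self):
        path = self.path_with(
            [("D", 100, 30, 100, ""), ("I", 130, 28, 100, "A" * 28), ("D", 300, 40, 272, "")]
        )
        cands = extract_deletions(path, min_del=10)
        kept, dropped = filter_artifact_indels(cands, min_net=10)
        # the insertion pairs only with the adjacent deletion (net 2 < 10);
        # the distant deletion keeps its full net size of 40
        assert [c.del_len for c in dropped] == [30]
        assert [(c.del_len, c.ins_len, c.del_len - c.ins_len) for c in kept] == [(40, 0, 40)]

    def test_end_to_end_balanced_indel_discarded(self):
        # a low-quality segment failing to align shows up as deletion +
        # nearby insertion with small net size; the filter must remove it
        ref = random_reference(560, 36)
        amp = mk_amplicon(ref)
        mol = ref[:250] + random_reference(25, 99) + ref[280:]  # del 30 / ins 25
        path = align_to_amplicon(mol, amp)
        cands = extract_deletions(path, min_del=10)
        assert cands, "expected a deletion candidate from the balanced indel"
        kept, dropped = filter_artifact_indels(cands, min_net=10)
        assert kept == []
        assert len(dropped) == 1


class TestJunctionInference:
    def test_documented_microhomology_case(self):
        from meiodel.caller import DeletionCandidate

        seq = "CCTTAGCAGCGATT" + random_reference(60, 41)
        amp = mk_amplicon(seq)
        cand = DeletionCandidate(
            amplicon="ampX", del_start=7, del_end=10, del_len=3,
            ins_len=0, ins_seq="", read_id="r",
        )
        left, right, ins, mh = infer_junction_bases(cand, amp)
        assert (left, right) == (4, 7)
        assert mh == "AGC"
        assert ins == ""

    def test_matches_canonicalization_oracle(self, rng):
        for _ in range(100):
            seq = "".join(np.array(list("AC"))[rng.integers(0, 2, 80)]) + random_reference(40, 42)
            amp = mk_amplicon(seq)
            left = int(rng.integers(5, 60))
            right = int(rng.integers(left + 1, 80))
            from meiodel.caller import DeletionCandidate

            cand = DeletionCandidate(
                amplicon="ampX", del_start=left, del_end=right,
                del_len=right - left, ins_len=0, ins_seq="", read_id="r",
            )
            l, r, ins, mh = infer_junction_bases(cand, amp)
            assert (l, r, mh) == canonicalize_deletion(seq, left, right)


def mk_call(left=100, right=160, ins="", baseq=35.0, conf=60.0, group=1, amp="amp1"):
    return JunctionCall(
        amplicon=amp, chrom="c", left_bp=left, right_bp=right,
        del_len=right - left, ins_len=len(ins), net=right - left - len(ins),
        mh_len=0, mh_seq="", ins_seq=ins, mean_baseq=baseq, map_conf=conf,
        group_size=group, read_id="r",
    )


class TestDedupAndQuality:
    def test_identical_paths_collapse_with_multiplicity(self):
        groups = [
            [mk_call(baseq=30.0, group=2)],
            [mk_call(baseq=38.0, group=1)],
            [mk_call(baseq=34.0, group=4)],
        ]
        out = dedup_paths(groups)
        assert len(out) == 1
        assert out[0].multiplicity == 7
        assert out[0].n_molecules == 3
        assert out[0].mean_baseq == 38.0  # best representative kept

    def test_distinct_junctions_not_collapsed(self):
        out = dedup_paths([[mk_call(left=100)], [mk_call(left=101)]])
        assert len(out) == 2

    def test_same_junction_different_amplicons_kept_apart(self):
        out = dedup_paths([[mk_call(amp="amp1")], [mk_call(amp="amp2")]])
        assert len(out) == 2

    def test_quality_filters(self):
        calls = [
            mk_call(baseq=35.0, conf=60.0),
            mk_call(baseq=24.9, conf=60.0),
            mk_call(baseq=35.0, conf=54.9),
            mk_call(baseq=20.0, conf=0.0),
        ]
        kept, rejected = apply_quality_filters(calls)
        assert len(kept) == 1
        reasons = sorted(r for _, r in rejected)
        assert reasons == ["base_quality", "base_quality", "map_conf"]


class TestCallAmplicons:
    def simulate_cohort(self, toy, n_events=40, error_rate=0.0, seed=0):
        from meiodel.pipeline import molecules_for_events, simulate_microdeletion_cohort

        events = simulate_microdeletion_cohort(
            toy, n_events, RepairModel.unresected(), seed, genotype="unresected"
        )
        mols = molecules_for_events(toy, events, n_wt=12, seed=seed)
        pairs = simulate_amplicon_reads(
            mols, seed=derive_seed(seed, "reads"), error_rate=error_rate,
            depth=3 * len(mols),
        )
        return events, mols, pairs

    def test_error_free_recovery_and_log_arithmetic(self, toy):
        from meiodel.pipeline import evaluate_recovery

        events, mols, pairs = self.simulate_cohort(toy)
        calls, log = call_amplicons(pairs, toy.ref, amplicons=toy.amplicons, chrom=toy.chrom)
        rec = evaluate_recovery(toy, events, calls)
        assert rec["recovery"] == 1.0
        assert rec["n_false"] == 0
        # RunLog arithmetic invariants
        assert log["merged"] + log["unmerged"] == log["pairs_in"]
        assert log["assigned"] <= log["merged"]
        assert log["unique_seqs"] >= log["aligned"]
        assert log["calls"] == log["unique_events"] - log["quality_discards"]
        assert log["calls"] == len(calls)

    def test_dedup_returns_molecule_count_error_free(self, toy):
        # error-free PCR duplicates of one molecule are identical sequences;
        # dedup must return exactly one event per event-carrying molecule
        events, mols, pairs = self.simulate_cohort(toy, n_events=30)
        calls, _ = call_amplicons(pairs, toy.ref, amplicons=toy.amplicons, chrom=toy.chrom)
        n_event_mols = sum(1 for _, eid, _ in mols if eid != "none")
        assert sum(c.n_molecules for c in calls) == n_event_mols
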