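"""Adapter trimming and all-best-hit sequential alignment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_best_placements
from conftest import make_ref
from trfage.aligner import (
    REJECTED, ReadRecord, ReferenceSet, align_all_best, read_fastq, read_sam,
    sequential_align, trim_adapter, write_sam,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        insert = "ACGTACGTACGTACGTACGT"  # 20 nt
        read = ReadRecord("r1", insert + ADAPTER)
        out = trim_adapter(read, ADAPTER)
        assert out.sequence == insert

    def test_short_insert_rejected(self):
        insert = "ACGTACGTACGTAC"  # 14 nt
        assert trim_adapter(ReadRecord("r1", insert + ADAPTER), ADAPTER) is REJECTED

    def test_read_without_adapter_kept(self):
        seq = "GCATGCATGCATGCATGCAT"
        out = trim_adapter(ReadRecord("r1", seq), ADAPTER)
        assert out.sequence == seq

    def test_adapter_prefix_at_three_prime_end(self):
        insert = "ACGCACGCACGCACGCACGC"
        read = ReadRecord("r1", insert + ADAPTER[:8])
        assert trim_adapter(read, ADAPTER).sequence == insert

    def test_error_tolerance(self):
        insert = "ACGCACGCACGCACGCACGC"
        noisy = ADAPTER[:9] + "A" + ADAPTER[10:]  # 1 error in 21 < 10%
        assert trim_adapter(ReadRecord("r1", insert + noisy), ADAPTER).sequence == insert
        assert trim_adapter(
            ReadRecord("r1", insert + noisy), ADAPTER, max_error_rate=0.0
        ).sequence != insert


class TestAlignAllBest:
    def test_prefix_of_one_reference(self, toy_refs):
        refs = ReferenceSet(toy_refs)
        read = ReadRecord("r1", toy_refs[2].sequence[:18])
        hits = align_all_best(read, refs)
        assert len(hits) == 1
        assert (hits[0].ref_id, hits[0].start, hits[0].mismatch_count) == ("Gly_GCC", 0, 0)

    def test_shared_prefix_multimaps(self, toy_refs):
        refs = ReferenceSet(toy_refs)
        read = ReadRecord("r1", toy_refs[0].sequence[:20])
        hits = align_all_best(read, refs)
        assert {h.ref_id for h in hits} == {"Ala_AGC", "Ala_AGC_2"}
        assert all(h.n_best_hits == 2 and h.mismatch_count == 0 for h in hits)

    def test_single_mismatch_reported_with_triple(self, toy_refs):
        refs = ReferenceSet(toy_refs)
        src = toy_refs[2].sequence
        seq = src[5:25]
        seq = seq[:7] + ("A" if seq[7] != "A" else "C") + seq[8:]
        hits = align_all_best(ReadRecord("r1", seq), refs, v=2)
        oracle = brute_force_best_placements(
            seq, {r.ref_id: r.sequence for r in toy_refs}, 2)
        assert {(h.ref_id, h.start, h.mismatch_count) for h in hits} == oracle
        (hit,) = [h for h in hits if h.ref_id == "Gly_GCC"]
        assert hit.mismatches == [(12, src[12], seq[7])]

    def test_n_counts_as_mismatch_to_everything(self, toy_refs):
        refs = ReferenceSet(toy_refs)
        seq = toy_refs[2].sequence[:20]
        seq = seq[:4] + "N" + seq[5:]
        hits = align_all_best(ReadRecord("r1", seq), refs, v=2)
        assert hits and all(h.mismatch_count == 1 for h in hits)

    def test_no_placement_within_v(self, toy_refs):
        refs = ReferenceSet(toy_refs)
        assert align_all_best(ReadRecord("r1", "A" * 20), refs, v=2) == []


class TestSequentialAlign:
    def test_perfect_match_priority_within_family(self):
        # copy B differs from copy A by one base inside the fragment
        base = "GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTCCCACGCGGGAGACCCGGGTTCGATTCCCGGCCAATGCACCA"
        seq_b = base[:40] + "T" + base[41:]
        refs = [make_ref("A", base), make_ref("B", seq_b)]
        read = ReadRecord("r1", seq_b[30:55])  # contains the divergent base
        alignments, unaligned = sequential_align([read], refs)
        assert [a.ref_id for a in alignments] == ["B"]
        assert alignments[0].mismatch_count == 0 and alignments[0].round == 0

    def test_three_mismatches_unalignable(self, toy_refs):
        seq = toy_refs[2].sequence[:20]
        bad = "TTT" + seq[3:]
        assert bad[:3] != seq[:3]
        alignments, unaligned = sequential_align([ReadRecord("r1", bad)], toy_refs)
        if alignments:  # only acceptable if some other placement beat 3 mismatches
            assert all(a.mismatch_count <= 2 for a in alignments)
        else:
            assert [r.read_id for r in unaligned] == ["r1"]

    def test_empty_input(self, toy_refs):
        assert sequential_align([], toy_refs) == ([], [])

    def test_output_order_canonical(self, toy_refs):
        reads = [ReadRecord(f"r{i}", toy_refs[i % 3].sequence[:20]) for i in range(6)]
        fwd, _ = sequential_align(reads, toy_refs)
        rev, _ = sequential_align(reads[::-1], toy_refs)
        key = lambda a: (a.read_id, a.ref_id, a.start, a.mismatch_count)
        assert [key(a) for a in fwd] == [key(a) for a in rev]

    def test_round_equals_mismatch_count_and_end_start_consistency(self, toy_refs):
        rng = np.random.default_rng(0)
        reads = []
        for i in range(40):
            src = toy_refs[rng.integers(0, 3)].sequence
            s = int(rng.integers(0, len(src) - 16))
            frag = list(src[s:s + 16])
            for _ in range(rng.integers(0, 3)):
                p = int(rng.integers(0, 16))
                frag[p] = "ACGT"[rng.integers(0, 4)]
            reads.append(ReadRecord(f"r{i}", "".join(frag)))
        alignments, _ = sequential_align(reads, toy_refs)
        for a in alignments:
            assert a.round == a.mismatch_count == len(a.mismatches)
            assert a.end - a.start == len(a.read_seq)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence_random_instances(self, seed):
        """Placement sets equal exhaustive minimal-mismatch enumeration."""
        rng = np.random.default_rng(seed)
        n_refs = int(rng.integers(1, 6))
        ref_seqs = {
            f"R{i}": "".join(rng.choice(list("ACGT"), int(rng.integers(25, 60))))
            for i in range(n_refs)
        }
        refs = [make_ref(rid, seq[:-3] + "CCA") for rid, seq in ref_seqs.items()]
        ref_seqs = {r.ref_id: r.sequence for r in refs}
        reads = []
        for i in range(int(rng.integers(1, 25))):
            if rng.random() < 0.6:
                src = ref_seqs[f"R{int(rng.integers(0, n_refs))}"]
                s = int(rng.integers(0, len(src) - 15))
                frag = list(src[s:s + 15 + int(rng.integers(0, 6))][:len(src) - s])
                for _ in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(frag)))
                    frag[p] = "ACGTN"[rng.integers(0, 5)]
                seq = "".join(frag)
            else:
                seq = "".join(rng.choice(list("ACGT"), 16))
            reads.append(ReadRecord(f"r{i}", seq))
        alignments, unaligned = sequential_align(reads, refs)
        got = {}
        for a in alignments:
            got.setdefault(a.read_id, set()).add((a.ref_id, a.start, a.mismatch_count))
        for read in reads:
            expected = brute_force_best_placements(read.sequence, ref_seqs, 2)
            assert got.get(read.read_id, set()) == expected

    def test_adding_reference_never_increases_round(self, toy_refs):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(30):
            src = toy_refs[rng.integers(0, 3)].sequence
            s = int(rng.integers(0, len(src) - 16))
            frag = list(src[s:s + 16])
            if rng.random() < 0.5:
                frag[rng.integers(0, 16)] = "ACGT"[rng.integers(0, 4)]
            reads.append(ReadRecord(f"r{i}", "".join(frag)))
        small, _ = sequential_align(reads, toy_refs[:2])
        full, _ = sequential_align(reads, toy_refs)
        round_small = {a.read_id: a.round for a in small}
        round_full = {a.read_id: a.round for a in full}
        for read_id, r in round_small.items():
            assert round_full[read_id] <= r


class TestSamIO:
    def test_sam_round_trip(self, toy_refs, tmp_path):
        rng = np.random.default_rng(1)
        reads = []
        for i in range(20):
            src = toy_refs[rng.integers(0, 3)].sequence
            s = int(rng.integers(0, len(src) - 18))
            frag = list(src[s:s + 18])
            if rng.random() < 0.4:
                frag[rng.integers(0, 18)] = "ACGT"[rng.integers(0, 4)]
            reads.append(ReadRecord(f"r{i}", "".join(frag)))
        alignments, _ = sequential_align(reads, toy_refs)
        path = tmp_path / "out.sam"
        write_sam(alignments, toy_refs, path)
        loaded = read_sam(path, toy_refs)
        key = lambda a: (a.read_id, a.ref_id, a.start, a.end, a.mismatch_count,
                         a.round, a.n_best_hits, tuple(a.mismatches))
        assert sorted(map(key, loaded)) == sorted(map(key, alignments))

    def test_fastq_reader(self, tmp_path):
        path = tmp_path / "x.fastq"
        path.write_text("@r1 extra\nACGT\n+\nIIII\n@r2\nggtt\n+\nIIII\n")
        reads = read_fastq(path)
        assert [(r.read_id, r.sequence) for r in reads] == [("r1", "ACGT"), ("r2", "GGTT")]
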