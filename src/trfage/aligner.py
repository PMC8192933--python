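"""Adapter trimming and sequential all-best-hit alignment.

Short tRNA fragments are aligned to the mature reference set ungapped,
end-to-end, on the sense strand only.  Alignment is sequential: a read is
first placed only if it matches some reference perfectly; reads that fail are
retried allowing one, then two mismatches.  Every placement achieving the
read's minimal mismatch count is reported ("all best hits"), so homologous
copies share multi-mapped reads instead of one copy absorbing them at random.

The sequential discipline is what makes downstream mismatch analysis sound:
a read identical to one member of a homologous family is never reported as a
mismatched alignment to another member, so per-site mismatch fractions
reflect RNA editing or genuine mutations, not family-internal divergence.

The reference set totals a few tens of kilobases, so placement is exact
brute force over every (reference, offset) pair, vectorized with numpy
sliding windows; no heuristics, no seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .reference_builder import MatureReference

MIN_READ_LENGTH = 15
REJECTED = "REJECTED"

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# N never equals anything, including another N: encode read N as 5, ref N as 4
_READ_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}


@dataclass
class ReadRecord:
    read_id: str
    sequence: str


@dataclass
class AlignmentRecord:
    """One read placement on a mature reference (0-based half-open)."""

    read_id: str
    ref_id: str
    start: int
    end: int
    mismatch_count: int
    mismatches: list[tuple[int, str, str]]  # (ref_pos, ref_base, read_base)
    round: int
    n_best_hits: int
    read_seq: str = ""


class ReferenceSet:
    """Mature references with pre-encoded arrays for window comparison."""

    def __init__(self, references: Sequence[MatureReference]):
        self.references = sorted(references, key=lambda r: r.ref_id)
        self.by_id = {r.ref_id: r for r in self.references}
        self._encoded = {
            r.ref_id: np.array([_ENCODE[b] for b in r.sequence], dtype=np.int8)
            for r in self.references
        }

    def __len__(self) -> int:
        return len(self.references)

    def encoded(self, ref_id: str) -> np.ndarray:
        return self._encoded[ref_id]


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
    min_length: int = MIN_READ_LENGTH,
) -> ReadRecord | str:
    """Remove a 3' sequencing adapter; reject reads left shorter than 15 nt.

    The best occurrence of the adapter (or of an adapter prefix reaching the
    read's 3' end) with per-overlap error rate <= ``max_error_rate`` is
    removed; everything from the adapter start onward is discarded.  Among
    admissible occurrences the one with the most matching bases wins (ties
    to the leftmost), so a long true adapter hit beats a chance short one.
    A read with no admissible occurrence is kept unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    best: tuple[int, int] | None = None  # (matches, -position)
    best_pos = None
    for i in range(len(seq) - min_overlap + 1):
        overlap = min(len(adapter), len(seq) - i)
        errors = sum(1 for a, b in zip(seq[i:i + overlap], adapter[:overlap]) if a != b)
        if errors <= max_error_rate * overlap:
            key = (overlap - errors, -i)
            if best is None or key > best:
                best, best_pos = key, i
    if best_pos is not None:
        trimmed = seq[:best_pos]
        return ReadRecord(read.read_id, trimmed) if len(trimmed) >= min_length else REJECTED
    return read if len(seq) >= min_length else REJECTED


def _placements_for_seq(
    seq: str, refs: ReferenceSet, v: int
) -> tuple[int, list[tuple[str, int]]]:
    """(min mismatch count, [(ref_id, start), ...]) for placements <= v.

    Returns ``(v + 1, [])`` when no placement achieves <= v mismatches.
    """
    enc = np.array([_READ_ENCODE.get(b, 5) for b in seq], dtype=np.int8)
    m = len(enc)
    best = v + 1
    hits: list[tuple[str, int]] = []
    for ref in refs.references:
        ref_arr = refs.encoded(ref.ref_id)
        if m > len(ref_arr):
            continue
        windows = sliding_window_view(ref_arr, m)
        counts = (windows != enc).sum(axis=1)
        local = int(counts.min())
        if local < best:
            best = local
            hits = [(ref.ref_id, int(p)) for p in np.flatnonzero(counts == local)]
        elif local == best and best <= v:
            hits.extend((ref.ref_id, int(p)) for p in np.flatnonzero(counts == local))
    if best > v:
        return v + 1, []
    return best, hits


def _mismatch_list(seq: str, ref_seq: str, start: int) -> list[tuple[int, str, str]]:
    return [
        (start + i, ref_seq[start + i], b)
        for i, b in enumerate(seq)
        if b != ref_seq[start + i]
    ]


def align_all_best(
    read: ReadRecord, refs: ReferenceSet, v: int = 2, round_number: int | None = None
) -> list[AlignmentRecord]:
    """All placements of one read achieving its minimal mismatch count <= v."""
    best, hits = _placements_for_seq(read.sequence, refs, v)
    if not hits:
        return []
    hits.sort()
    out = []
    for ref_id, start in hits:
        ref_seq = refs.by_id[ref_id].sequence
        out.append(AlignmentRecord(
            read_id=read.read_id,
            ref_id=ref_id,
            start=start,
            end=start + len(read.sequence),
            mismatch_count=best,
            mismatches=_mismatch_list(read.sequence, ref_seq, start),
            round=round_number if round_number is not None else best,
            n_best_hits=len(hits),
            read_seq=read.sequence,
        ))
    return out


def sequential_align(
    reads: Iterable[ReadRecord],
    refs: ReferenceSet | Sequence[MatureReference],
    max_mismatches: int = 2,
) -> tuple[list[AlignmentRecord], list[ReadRecord]]:
    """Perfect-match-first alignment of a library.

    Each read is attempted at 0 mismatches; failures are retried at 1, then 2
    (up to ``max_mismatches``).  A read placed in round r therefore has no
    placement anywhere with fewer than r mismatches.  Output order is
    canonical (read_id, ref_id, start), independent of input order.
    """
    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs)
    reads = list(reads)
    # identical sequences share placements; align each distinct sequence once
    placements_cache: dict[str, tuple[int, list[tuple[str, int]]]] = {}
    alignments: list[AlignmentRecord] = []
    unaligned: list[ReadRecord] = []
    for read in reads:
        cached = placements_cache.get(read.sequence)
        if cached is None:
            cached = _placements_for_seq(read.sequence, refs, max_mismatches)
            cached[1].sort()
            placements_cache[read.sequence] = cached
        best, hits = cached
        if not hits:
            unaligned.append(read)
            continue
        for ref_id, start in hits:
            ref_seq = refs.by_id[ref_id].sequence
            alignments.append(AlignmentRecord(
                read_id=read.read_id,
                ref_id=ref_id,
                start=start,
                end=start + len(read.sequence),
                mismatch_count=best,
                mismatches=_mismatch_list(read.sequence, ref_seq, start),
                round=best,
                n_best_hits=len(hits),
                read_seq=read.sequence,
            ))
    alignments.sort(key=lambda a: (a.read_id, a.ref_id, a.start))
    unaligned.sort(key=lambda r: r.read_id)
    return alignments, unaligned


# ---------------------------------------------------------------------------
# FASTQ / SAM I/O

def read_fastq(path: str | Path) -> list[ReadRecord]:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append(ReadRecord(header[1:].split()[0], seq.upper()))
    return reads


def _md_tag(aln: AlignmentRecord, ref_seq: str) -> str:
    md = []
    run = 0
    for i in range(aln.start, aln.end):
        read_base = aln.read_seq[i - aln.start]
        if read_base == ref_seq[i]:
            run += 1
        else:
            md.append(str(run))
            md.append(ref_seq[i])
            run = 0
    md.append(str(run))
    return "".join(md)


def write_sam(
    alignments: Sequence[AlignmentRecord],
    refs: ReferenceSet | Sequence[MatureReference],
    path: str | Path,
) -> None:
    """Write placements as SAM: all hits primary, NM and MD tags set."""
    import pysam

    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.ref_id, "LN": r.length} for r in refs.references],
    }
    tid = {r.ref_id: i for i, r in enumerate(refs.references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.read_seq
            seg.flag = 0
            seg.reference_id = tid[aln.ref_id]
            seg.reference_start = aln.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{aln.end - aln.start}M"
            seg.set_tag("NM", aln.mismatch_count)
            seg.set_tag("MD", _md_tag(aln, refs.by_id[aln.ref_id].sequence))
            seg.set_tag("XR", aln.round)
            seg.set_tag("XH", aln.n_best_hits)
            out.write(seg)


def read_sam(path: str | Path, refs: ReferenceSet | Sequence[MatureReference]) -> list[AlignmentRecord]:
    """Read ungapped SAM records back into alignment records."""
    import pysam

    if not isinstance(refs, ReferenceSet):
        refs = ReferenceSet(refs)
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            if any(op != 0 for op, _ in seg.cigartuples):
                raise ValueError(f"{seg.query_name}: only ungapped records supported")
            ref_id = seg.reference_name
            ref_seq = refs.by_id[ref_id].sequence
            seq = seg.query_sequence.upper()
            start = seg.reference_start
            mism = _mismatch_list(seq, ref_seq, start)
            out.append(AlignmentRecord(
                read_id=seg.query_name,
                ref_id=ref_id,
                start=start,
                end=start + len(seq),
                mismatch_count=len(mism),
                mismatches=mism,
                round=seg.get_tag("XR") if seg.has_tag("XR") else len(mism),
                n_best_hits=seg.get_tag("XH") if seg.has_tag("XH") else 1,
                read_seq=seq,
            ))
    return out


def write_read_report(alignments: Sequence[AlignmentRecord], path: str | Path) -> None:
    """Per-read TSV of alignment round and number of co-reported hits."""
    seen: dict[str, tuple[int, int]] = {}
    for aln in alignments:
        seen.setdefault(aln.read_id, (aln.round, aln.n_best_hits))
    with open(path, "w") as fh:
        fh.write("read_id\tround\tn_best_hits\n")
        for read_id in sorted(seen):
            r, n = seen[read_id]
            fh.write(f"{read_id}\t{r}\t{n}\n")
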