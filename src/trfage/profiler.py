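"""Coverage and base-composition profiling over mature tRNA references.

A pileup here is per-reference: an integer depth track plus a 4xL matrix of
A/C/G/T counts from the aligned read bases.  Multi-mapped reads contribute one
count to every reported placement by default (each best hit is primary); an
optional fractional mode weights each placement by 1/n_best_hits.  N bases
count toward depth but not toward base counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import AlignmentRecord
from .reference_builder import MatureReference

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASE_ORDER = "ACGT"


@dataclass
class CoverageProfile:
    ref_id: str
    depth: np.ndarray          # float (integer-valued unless fractional mode)
    base_counts: np.ndarray    # 4 x L, rows A,C,G,T

    @property
    def length(self) -> int:
        return len(self.depth)


def pileup(
    alignments: Iterable[AlignmentRecord],
    references: Sequence[MatureReference],
    fractional: bool = False,
) -> dict[str, CoverageProfile]:
    """Accumulate per-position depth and read-base counts per reference."""
    profiles = {
        r.ref_id: CoverageProfile(
            r.ref_id,
            np.zeros(r.length, dtype=float),
            np.zeros((4, r.length), dtype=float),
        )
        for r in references
    }
    for aln in alignments:
        prof = profiles[aln.ref_id]
        w = 1.0 / aln.n_best_hits if fractional else 1.0
        prof.depth[aln.start:aln.end] += w
        for i, base in enumerate(aln.read_seq):
            row = BASE_INDEX.get(base)
            if row is not None:
                prof.base_counts[row, aln.start + i] += w
    return profiles


def base_composition_at(
    profiles: Mapping[str, CoverageProfile],
    sites: Iterable[tuple[str, int]],
) -> pd.DataFrame:
    """A/C/G/T counts at named (ref_id, position) sites.

    Sites on references without coverage come back as zero rows; aggregate
    across sites by summing rows (e.g. all wobble positions of one library).
    """
    rows = []
    for ref_id, pos in sites:
        prof = profiles.get(ref_id)
        if prof is None or not (0 <= pos < prof.length):
            counts = np.zeros(4)
        else:
            counts = prof.base_counts[:, pos]
        rows.append({"ref_id": ref_id, "position": pos,
                     **{b: counts[i] for b, i in BASE_INDEX.items()}})
    return pd.DataFrame(rows, columns=["ref_id", "position", *BASE_ORDER])


def count_interval_overlaps(
    placements: Iterable[tuple[str, int, int]],
    intervals: Sequence[tuple[str, int, int]],
    mode: str = "any",
) -> list[int]:
    """Per-interval count of placements overlapping it.

    ``mode='any'`` counts >= 1-base overlap; ``mode='contained'`` counts only
    placements lying fully inside the interval.  Intervals and placements are
    (ref_id, start, end), half-open.  The partial count is any - contained.
    """
    if mode not in {"any", "contained"}:
        raise ValueError(f"unknown mode {mode!r}")
    counts = [0] * len(intervals)
    by_ref: dict[str, list[tuple[int, int, int]]] = {}
    for idx, (ref, s, e) in enumerate(intervals):
        by_ref.setdefault(ref, []).append((s, e, idx))
    for ref, ps, pe in placements:
        for s, e, idx in by_ref.get(ref, ()):
            if mode == "any":
                if ps < e and pe > s:
                    counts[idx] += 1
            else:
                if ps >= s and pe <= e:
                    counts[idx] += 1
    return counts


def normalize_abundance(
    raw: pd.DataFrame, library_totals: Mapping[str, float]
) -> pd.DataFrame:
    """Reads-per-million table from raw counts.

    ``raw`` has one column per age label; totals are per-library aligned-read
    counts.  A zero or missing total is an error, not a silent zero.
    """
    rpm = raw.astype(float).copy()
    for col in rpm.columns:
        total = library_totals.get(col)
        if not total:
            raise ValueError(f"library {col!r} has no aligned reads to normalize by")
        rpm[col] = rpm[col] * 1e6 / total
    return rpm


def write_profiles(profiles: Mapping[str, CoverageProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\tposition\tdepth\tA\tC\tG\tT\n")
        for ref_id in sorted(profiles):
            prof = profiles[ref_id]
            for pos in range(prof.length):
                if prof.depth[pos] == 0:
                    continue
                counts = "\t".join(f"{prof.base_counts[i, pos]:g}" for i in range(4))
                fh.write(f"{ref_id}\t{pos}\t{prof.depth[pos]:g}\t{counts}\n")
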