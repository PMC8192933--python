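"""Enrichment-region calling, tRF classification and age trends.

A tRF shows up as a contiguous high-coverage interval on a mature reference.
Regions are called per age library as maximal runs above a fraction of the
reference's coverage maximum, ranked by abundance, and the top percentile per
library is kept (union over libraries).  Each region is classified by where
it sits on the mature tRNA — 5' end, 3' end (with or without the terminal
CCA) or middle — and given a linear age trend.

Because tRNA genes come in near-identical copies, an apparent enrichment on
one reference can be a shadow of a larger fragment from a homologous copy
that multi-mapped reads project onto both.  The homology filter removes a
candidate exactly when a homologous reference carries a called region that
properly contains the candidate's sequence content; a fragment that exists
"as is" (same content, same extent) on its homologs is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .aligner import AlignmentRecord
from .profiler import CoverageProfile
from .reference_builder import MatureReference


class RegionType(str, Enum):
    FIVE_PRIME = "FIVE_PRIME"
    THREE_PRIME = "THREE_PRIME"
    MIDDLE = "MIDDLE"


class Trend(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    FLAT = "FLAT"


@dataclass
class EnrichmentRegion:
    ref_id: str
    start: int
    end: int
    abundance: dict[str, float] = field(default_factory=dict)   # age -> mean depth
    read_count: dict[str, int] = field(default_factory=dict)    # age -> overlapping reads
    rpm: dict[str, float] = field(default_factory=dict)
    type: RegionType | None = None
    has_cca: bool = False
    passes_filter: bool = True
    trend: Trend | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def call_candidate_regions(
    profile: CoverageProfile,
    theta: float = 0.5,
    min_gap: int = 3,
    min_length: int = 10,
) -> list[EnrichmentRegion]:
    """Maximal runs of positions with depth >= theta * max depth.

    Runs separated by gaps shorter than ``min_gap`` are merged; runs shorter
    than ``min_length`` are dropped.  A flat-zero profile yields no regions.
    """
    peak = profile.depth.max() if profile.length else 0
    if peak <= 0:
        return []
    above = profile.depth >= theta * peak
    runs: list[list[int]] = []
    pos = 0
    L = profile.length
    while pos < L:
        if above[pos]:
            end = pos
            while end < L and above[end]:
                end += 1
            if runs and pos - runs[-1][1] < min_gap:
                runs[-1][1] = end
            else:
                runs.append([pos, end])
            pos = end
        else:
            pos += 1
    return [
        EnrichmentRegion(profile.ref_id, s, e)
        for s, e in runs
        if e - s >= min_length
    ]


def region_abundance(region: EnrichmentRegion, profile: CoverageProfile) -> float:
    """Mean depth over the region in one library's profile."""
    return float(profile.depth[region.start:region.end].mean())


def select_top_percent(
    regions: Sequence[EnrichmentRegion],
    abundances: Sequence[float],
    pct: float = 1.0,
) -> list[EnrichmentRegion]:
    """Regions at or above the (100 - pct) abundance percentile of one library.

    Ties at the threshold are all kept.
    """
    if not regions:
        return []
    threshold = np.percentile(np.asarray(abundances, dtype=float), 100 - pct)
    return [r for r, a in zip(regions, abundances) if a >= threshold]


def classify_region(
    region: EnrichmentRegion, ref: MatureReference, d5: int = 3, d3: int = 3
) -> EnrichmentRegion:
    """Assign 5'/3'/middle type and the terminal-CCA flag.

    A region starting within ``d5`` of the 5' end is 5'; one ending within
    ``d3`` of the 3' end (CCA included) is 3'; near-full-length regions take
    the closer end, ties going 5'.  ``has_cca`` means the region runs through
    the final mature base.
    """
    L = ref.length
    near5 = region.start <= d5
    near3 = region.end >= L - d3
    if near5 and near3:
        rtype = RegionType.FIVE_PRIME if region.start <= L - region.end else RegionType.THREE_PRIME
    elif near5:
        rtype = RegionType.FIVE_PRIME
    elif near3:
        rtype = RegionType.THREE_PRIME
    else:
        rtype = RegionType.MIDDLE
    region.type = rtype
    region.has_cca = rtype is RegionType.THREE_PRIME and region.end == L
    return region


def homology_map_from_alignments(
    alignments: Iterable[AlignmentRecord],
) -> dict[str, set[str]]:
    """References sharing at least one multi-mapped read are homologs."""
    by_read: dict[str, set[str]] = {}
    for aln in alignments:
        by_read.setdefault(aln.read_id, set()).add(aln.ref_id)
    homologs: dict[str, set[str]] = {}
    for refs in by_read.values():
        if len(refs) < 2:
            continue
        for r in refs:
            homologs.setdefault(r, set()).update(refs - {r})
    return homologs


def homology_filter(
    candidate: EnrichmentRegion,
    regions_by_ref: Mapping[str, Sequence[EnrichmentRegion]],
    references: Mapping[str, MatureReference],
    homology_map: Mapping[str, set[str]],
) -> bool:
    """True iff the candidate survives the false-positive filter.

    The candidate fails when any homologous reference carries a called region
    strictly larger than the candidate whose sequence contains the
    candidate's sequence content — i.e. the candidate is a sub-fragment
    shadow of a bigger enrichment elsewhere.  Equal-extent identical
    enrichments on homologs are fine (the fragment exists "as is").
    """
    cand_seq = references[candidate.ref_id].sequence[candidate.start:candidate.end]
    for other_ref in homology_map.get(candidate.ref_id, ()):
        other_seq = references[other_ref].sequence
        for region in regions_by_ref.get(other_ref, ()):
            if region.length <= candidate.length:
                continue
            if cand_seq in other_seq[region.start:region.end]:
                return False
    return True


def age_trend(
    rpm: Sequence[float], days: Sequence[float], r_threshold: float = 0.8
) -> Trend:
    """UP/DOWN/FLAT from a least-squares fit of abundance on age.

    UP needs a positive slope with Pearson r >= ``r_threshold`` (DOWN the
    mirror image); anything weaker — including a constant series, whose
    correlation is undefined — is FLAT.
    """
    rpm = np.asarray(rpm, dtype=float)
    days = np.asarray(days, dtype=float)
    if len(rpm) < 3 or np.allclose(rpm, rpm[0]):
        return Trend.FLAT
    fit = stats.linregress(days, rpm)
    if fit.slope > 0 and fit.rvalue >= r_threshold:
        return Trend.UP
    if fit.slope < 0 and fit.rvalue <= -r_threshold:
        return Trend.DOWN
    return Trend.FLAT


def _reciprocal_overlap(a: EnrichmentRegion, b: EnrichmentRegion) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / max(a.length, b.length)


def merge_across_ages(
    selected_per_age: Mapping[str, Sequence[EnrichmentRegion]],
    min_reciprocal_overlap: float = 0.5,
) -> list[EnrichmentRegion]:
    """Union of per-library selections, deduplicated.

    Same-reference regions from different libraries with reciprocal overlap
    >= the threshold are considered the same fragment; the widest interval
    becomes the representative.
    """
    merged: list[EnrichmentRegion] = []
    for age in sorted(selected_per_age):
        for region in selected_per_age[age]:
            match = None
            for existing in merged:
                if existing.ref_id == region.ref_id and \
                        _reciprocal_overlap(existing, region) >= min_reciprocal_overlap:
                    match = existing
                    break
            if match is None:
                merged.append(EnrichmentRegion(region.ref_id, region.start, region.end))
            elif region.length > match.length:
                match.start, match.end = region.start, region.end
    merged.sort(key=lambda r: (r.ref_id, r.start, r.end))
    return merged


def call_trfs(
    profiles_by_age: Mapping[str, Mapping[str, CoverageProfile]],
    references: Sequence[MatureReference],
    alignments_by_age: Mapping[str, Sequence[AlignmentRecord]],
    days_by_age: Mapping[str, float],
    theta: float = 0.5,
    pct: float = 1.0,
    min_gap: int = 3,
    min_length: int = 10,
    d5: int = 3,
    d3: int = 3,
    r_threshold: float = 0.8,
    rank_by: str = "mean_depth",
    library_totals: Mapping[str, int] | None = None,
) -> list[EnrichmentRegion]:
    """Full tRF calling across an age series.

    Per library: call candidate regions on every reference, keep the top
    ``pct`` percent by abundance (mean depth by default, supporting read
    count with ``rank_by='read_count'``).  The per-library selections are
    unified, annotated with per-age abundance/RPM, classified, filtered
    against homologous shadows, and given an age trend.

    ``library_totals`` sets the per-library RPM denominator (total reads in
    the library); without it the number of distinct aligned reads is used.
    """
    ref_by_id = {r.ref_id: r for r in references}
    ages = sorted(profiles_by_age, key=lambda a: days_by_age[a])

    candidates_by_age: dict[str, list[EnrichmentRegion]] = {}
    regions_by_ref_by_age: dict[str, dict[str, list[EnrichmentRegion]]] = {}
    for age in ages:
        regions: list[EnrichmentRegion] = []
        by_ref: dict[str, list[EnrichmentRegion]] = {}
        for ref_id, profile in profiles_by_age[age].items():
            called = call_candidate_regions(profile, theta, min_gap, min_length)
            regions.extend(called)
            if called:
                by_ref[ref_id] = called
        regions_by_ref_by_age[age] = by_ref
        if rank_by == "read_count":
            placements = [(a.ref_id, a.start, a.end) for a in alignments_by_age[age]]
            from .profiler import count_interval_overlaps
            abund = [float(c) for c in count_interval_overlaps(
                placements, [(r.ref_id, r.start, r.end) for r in regions])]
        else:
            abund = [region_abundance(r, profiles_by_age[age][r.ref_id]) for r in regions]
        candidates_by_age[age] = select_top_percent(regions, abund, pct)

    final = merge_across_ages(candidates_by_age)

    if library_totals is None:
        totals = {age: len({a.read_id for a in alignments_by_age[age]}) for age in ages}
    else:
        totals = dict(library_totals)
    from .profiler import count_interval_overlaps
    for age in ages:
        placements = [(a.ref_id, a.start, a.end) for a in alignments_by_age[age]]
        counts = count_interval_overlaps(
            placements, [(r.ref_id, r.start, r.end) for r in final])
        for region, c in zip(final, counts):
            region.read_count[age] = c
            region.abundance[age] = region_abundance(
                region, profiles_by_age[age][region.ref_id])
            region.rpm[age] = c * 1e6 / totals[age] if totals[age] else 0.0

    # homology: union of per-age multi-mapping graphs
    homology: dict[str, set[str]] = {}
    for age in ages:
        for ref_id, others in homology_map_from_alignments(alignments_by_age[age]).items():
            homology.setdefault(ref_id, set()).update(others)

    # regions visible to the filter: every called region in any library
    all_regions_by_ref: dict[str, list[EnrichmentRegion]] = {}
    for age in ages:
        for ref_id, regions in regions_by_ref_by_age[age].items():
            all_regions_by_ref.setdefault(ref_id, []).extend(regions)

    days = [days_by_age[a] for a in ages]
    for region in final:
        classify_region(region, ref_by_id[region.ref_id], d5, d3)
        region.passes_filter = homology_filter(
            region, all_regions_by_ref, ref_by_id, homology)
        region.trend = age_trend([region.rpm[a] for a in ages], days, r_threshold)
    return final


def write_trf_table(
    regions: Sequence[EnrichmentRegion], ages: Sequence[str], path: str | Path
) -> None:
    """BED-like TSV of called tRFs with per-age RPM, trend and filter status."""
    with open(path, "w") as fh:
        rpm_cols = "\t".join(f"rpm_{a}" for a in ages)
        fh.write(f"ref_id\tstart\tend\ttype\thas_cca\t{rpm_cols}\ttrend\tpasses_filter\n")
        for r in regions:
            rpms = "\t".join(f"{r.rpm.get(a, 0.0):.3f}" for a in ages)
            fh.write(
                f"{r.ref_id}\t{r.start}\t{r.end}\t{r.type.value}\t"
                f"{int(r.has_cca)}\t{rpms}\t{r.trend.value}\t{int(r.passes_filter)}\n"
            )
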