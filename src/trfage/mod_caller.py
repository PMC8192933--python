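"""RNA-modification and mutation calling from mismatch signatures.

Reverse transcription converts RNA base modifications into characteristic
mismatch patterns in sequencing reads.  Two signatures dominate in tRNAs:

* A-to-I editing at the anticodon wobble position (canonical position 34) —
  inosine pairs like G, so nearly every read shows A->G at that site;
* m1A (N1-methyladenosine), canonical at position 58 in the T-loop — the
  methyl group blocks Watson-Crick pairing, and the reverse transcriptase
  misincorporates any of the four bases, giving a mixed-base pile.

A genuine genomic mutation instead shows one consistent alternate base at a
site with no special identity, stable across every library.  Because the
aligner places perfectly matching reads before mismatched ones, mismatch
piles cannot arise from family-internal sequence differences, which is what
makes these calls interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiler import BASE_INDEX, BASE_ORDER, CoverageProfile
from .reference_builder import MatureReference


class ModCall:
    A_TO_I = "A_TO_I"
    M1A_LIKE = "M1A_LIKE"
    DE_NOVO_MUTATION = "DE_NOVO_MUTATION"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class CandidateSite:
    ref_id: str
    position: int
    ref_base: str
    depth: float                 # non-N covered depth (sum of base counts)
    base_counts: np.ndarray      # length 4, A/C/G/T, summed over libraries
    mismatch_fraction: float
    per_age_counts: dict[str, np.ndarray]


@dataclass
class ModificationCall:
    site: CandidateSite
    call: str
    neighbor_3p: str             # base 3' of the site on the reference


def t_loop_window(ref: MatureReference) -> tuple[int, int]:
    """Default T-loop window in mature coordinates: [L-22, L-14).

    Derived from canonical position 58 of a 76-nt tRNA carrying its CCA.
    """
    return max(0, ref.length - 22), max(0, ref.length - 14)


def mismatch_profile(
    profiles_by_age: Mapping[str, CoverageProfile],
    ref: MatureReference,
    min_depth: float = 20,
    min_fraction: float = 0.1,
) -> list[CandidateSite]:
    """Sites with enough coverage and >= ``min_fraction`` non-reference bases.

    Counts are pooled across libraries for the site summary; the per-library
    breakdown is kept for the classification and stability checks.
    """
    lengths = {p.length for p in profiles_by_age.values()}
    if lengths != {ref.length}:
        raise ValueError(f"{ref.ref_id}: profile/reference length mismatch")
    pooled = sum(p.base_counts for p in profiles_by_age.values())
    sites = []
    for pos in range(ref.length):
        counts = pooled[:, pos]
        depth = counts.sum()
        if depth < min_depth:
            continue
        ref_base = ref.sequence[pos]
        ref_row = BASE_INDEX.get(ref_base)
        if ref_row is None:
            continue
        fraction = 1.0 - counts[ref_row] / depth
        if fraction < min_fraction:
            continue
        sites.append(CandidateSite(
            ref_id=ref.ref_id,
            position=pos,
            ref_base=ref_base,
            depth=float(depth),
            base_counts=counts.copy(),
            mismatch_fraction=float(fraction),
            per_age_counts={
                age: p.base_counts[:, pos].copy() for age, p in profiles_by_age.items()
            },
        ))
    return sites


def classify_site(
    site: CandidateSite,
    ref: MatureReference,
    mixed_min_fraction: float = 0.05,
    de_novo_min_fraction: float = 0.9,
) -> ModificationCall:
    """Apply the signature rules in order; first match wins.

    1. reference A at the anticodon wobble position with G the dominant
       alternate -> A_TO_I;
    2. site inside the T-loop window with >= 3 base identities each carrying
       >= ``mixed_min_fraction`` of the depth -> M1A_LIKE;
    3. a single alternate base at >= ``de_novo_min_fraction`` of depth in
       every library -> DE_NOVO_MUTATION;
    4. otherwise AMBIGUOUS.
    """
    counts = site.base_counts
    ref_row = BASE_INDEX[site.ref_base]
    alt_counts = [counts[i] for i in range(4) if i != ref_row]
    call = ModCall.AMBIGUOUS

    if (
        site.ref_base == "A"
        and ref.anticodon_pos is not None
        and site.position == ref.anticodon_pos
        and counts[BASE_INDEX["G"]] == max(alt_counts)
        and counts[BASE_INDEX["G"]] > 0
    ):
        call = ModCall.A_TO_I
    else:
        lo, hi = t_loop_window(ref)
        n_identities = int((counts >= mixed_min_fraction * site.depth).sum())
        if lo <= site.position < hi and n_identities >= 3:
            call = ModCall.M1A_LIKE
        else:
            top_alt_row = int(np.argmax([c if i != ref_row else -1 for i, c in enumerate(counts)]))
            consistent = True
            for age_counts in site.per_age_counts.values():
                depth = age_counts.sum()
                if depth == 0:
                    continue
                if age_counts[top_alt_row] < de_novo_min_fraction * depth:
                    consistent = False
                    break
            if consistent and counts[top_alt_row] >= de_novo_min_fraction * site.depth:
                call = ModCall.DE_NOVO_MUTATION

    pos3 = site.position + 1
    neighbor = ref.sequence[pos3] if pos3 < ref.length else "."
    return ModificationCall(site=site, call=call, neighbor_3p=neighbor)


def call_modifications(
    profiles_by_age: Mapping[str, Mapping[str, CoverageProfile]],
    references: Sequence[MatureReference],
    min_depth: float = 20,
    min_fraction: float = 0.1,
) -> list[ModificationCall]:
    """Candidate-site discovery + classification over a reference set.

    References whose anticodon position is unresolved are excluded, since the
    wobble rule cannot be applied to them.
    """
    calls = []
    for ref in references:
        if ref.anticodon_pos is None:
            continue
        per_ref = {
            age: profs[ref.ref_id]
            for age, profs in profiles_by_age.items()
            if ref.ref_id in profs
        }
        if not per_ref:
            continue
        for site in mismatch_profile(per_ref, ref, min_depth, min_fraction):
            calls.append(classify_site(site, ref))
    return calls


def compare_across_ages(
    calls: Sequence[ModificationCall],
    ages: Sequence[str],
    max_range: float = 0.2,
) -> pd.DataFrame:
    """Per-site mismatch fraction across ages and a stability flag.

    A site is flagged when the spread (max - min) of its per-age mismatch
    fractions exceeds ``max_range``.  Libraries without coverage at the site
    contribute a missing value and never cause a flag by themselves.
    """
    rows = []
    for mc in calls:
        site = mc.site
        fractions = {}
        for age in ages:
            counts = site.per_age_counts.get(age)
            depth = counts.sum() if counts is not None else 0
            if depth == 0:
                fractions[age] = np.nan
            else:
                fractions[age] = 1.0 - counts[BASE_INDEX[site.ref_base]] / depth
        observed = [f for f in fractions.values() if not np.isnan(f)]
        spread = (max(observed) - min(observed)) if observed else np.nan
        rows.append({
            "ref_id": site.ref_id,
            "position": site.position,
            "call": mc.call,
            **{f"fraction_{a}": fractions[a] for a in ages},
            "range": spread,
            "flagged": bool(observed and spread > max_range),
        })
    return pd.DataFrame(rows)


def write_modification_table(
    calls: Sequence[ModificationCall], ages: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        count_cols = "\t".join(
            f"{b}_{a}" for a in ages for b in BASE_ORDER
        )
        fh.write(f"ref_id\tposition\tref_base\t{count_cols}\tcall\tneighbor_3p\n")
        for mc in sorted(calls, key=lambda m: (m.site.ref_id, m.site.position)):
            site = mc.site
            counts = "\t".join(
                f"{site.per_age_counts.get(a, np.zeros(4))[BASE_INDEX[b]]:g}"
                for a in ages for b in BASE_ORDER
            )
            fh.write(
                f"{site.ref_id}\t{site.position}\t{site.ref_base}\t{counts}\t"
                f"{mc.call}\t{mc.neighbor_3p}\n"
            )
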