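"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive (pure-Python enumeration or textbook
closed forms) and shares no code with the package internals.
"""

from __future__ import annotations

import math


def base_mismatch(a: str, b: str) -> bool:
    """N never matches anything, including another N."""
    return a == "N" or b == "N" or a != b


def brute_force_best_placements(
    seq: str, ref_seqs: dict[str, str], v: int
) -> set[tuple[str, int, int]]:
    """All (ref_id, start, mismatches) achieving the minimal mismatch count <= v."""
    scored = []
    for ref_id, ref_seq in ref_seqs.items():
        for start in range(len(ref_seq) - len(seq) + 1):
            mm = sum(
                1 for a, b in zip(seq, ref_seq[start:start + len(seq)])
                if base_mismatch(a, b)
            )
            if mm <= v:
                scored.append((ref_id, start, mm))
    if not scored:
        return set()
    best = min(mm for _, _, mm in scored)
    return {(r, s, mm) for r, s, mm in scored if mm == best}


def brute_force_overlap_counts(
    placements: list[tuple[str, int, int]],
    intervals: list[tuple[str, int, int]],
    contained: bool,
) -> list[int]:
    out = []
    for ref, s, e in intervals:
        n = 0
        for pref, ps, pe in placements:
            if pref != ref:
                continue
            if contained:
                n += ps >= s and pe <= e
            else:
                n += max(ps, s) < min(pe, e)
        out.append(n)
    return out


def pearson_r(xs: list[float], ys: list[float]) -> float:
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def naive_average_linkage(dist: list[list[float]], k: int) -> list[set[int]]:
    """Agglomerative average linkage by direct repeated merging."""
    clusters: list[set[int]] = [{i} for i in range(len(dist))]
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = sum(dist[a][b] for a in clusters[i] for b in clusters[j]) / (
                    len(clusters[i]) * len(clusters[j])
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def find_runs(depth: list[float], threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of positions with depth >= threshold (no merging)."""
    runs = []
    start = None
    for i, d in enumerate(depth):
        if d >= threshold and start is None:
            start = i
        elif d < threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(depth)))
    return runs
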