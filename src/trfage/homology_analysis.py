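"""Homology grouping of tRNA references and copy-number/abundance correlation.

tRNA genes form multicopy families whose members span anticodons and even
amino acids, so grouping by anticodon undercounts the effective genomic
dosage behind a fragment pool.  Here unique mature sequences are clustered on
a pairwise percent-identity matrix (average-linkage agglomerative on
distance = 100 - identity); a homology group's copy number is the total
number of genomic loci encoding any member.  Abundance summed per group is
then correlated (Pearson) against group copy number, per age.

The cluster count k is chosen by scanning a range: partitions that mix amino
acids inside one group are inadmissible, and among admissible k the one
maximizing the mean per-age correlation wins (ties to the smallest k).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .reference_builder import MatureReference


@dataclass
class HomologyGroup:
    group_id: str
    member_ref_ids: list[str]
    total_copy_number: int
    amino_acids: set[str]


@dataclass
class CorrelationResult:
    R: float
    p: float
    n: int
    slope: float
    intercept: float
    degenerate: bool = False  # constant input: R reported as 0


@dataclass
class ClusterConfig:
    k: int
    linkage: str = "average"
    k_table: pd.DataFrame | None = None  # k vs per-age R scan


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity between two sequences.

    Scored with match +1 / mismatch -1 / gap -2; identity is 100 x (matched
    columns) / (columns where both sequences have a residue), so terminal
    gaps from length differences do not dilute the identity.  End gaps are
    scored like internal ones: leaving them free lets unrelated sequences
    reach 100% over a short chance overlap, which would collapse homology
    clustering.  Arguments are ordered canonically before aligning so the
    result is exactly symmetric even when optimal alignments tie.
    """
    if seq_a == seq_b:
        return 100.0
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aligner = _pairwise_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    paired = counts.identities + counts.mismatches
    if paired == 0:
        return 0.0
    return 100.0 * counts.identities / paired


def percent_identity_matrix(references: Sequence[MatureReference]) -> pd.DataFrame:
    """Symmetric ref-by-ref percent-identity matrix, rows sorted by ref_id."""
    refs = sorted(references, key=lambda r: r.ref_id)
    n = len(refs)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = percent_identity(refs[i].sequence, refs[j].sequence)
    ids = [r.ref_id for r in refs]
    return pd.DataFrame(mat, index=ids, columns=ids)


def load_identity_matrix(path: str | Path) -> pd.DataFrame:
    """Ingest an externally produced square percent-identity TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("identity matrix rows and columns must match")
    order = sorted(df.index)
    return df.loc[order, order]


def cluster_homology(
    identity: pd.DataFrame,
    references: Sequence[MatureReference],
    k: int,
    method: str = "average",
) -> list[HomologyGroup]:
    """Cut an agglomerative tree on distance = 100 - identity at k clusters."""
    if not 1 <= k <= len(identity):
        raise ValueError(f"k={k} out of range for {len(identity)} references")
    ref_by_id = {r.ref_id: r for r in references}
    order = sorted(identity.index)
    dist = 100.0 - identity.loc[order, order].to_numpy()
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(linkage(squareform(dist, checks=False), method=method),
                      t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for ref_id, label in zip(order, labels):
        groups.setdefault(int(label), []).append(ref_id)
    out = []
    for i, label in enumerate(sorted(groups, key=lambda l: groups[l][0]), start=1):
        members = sorted(groups[label])
        out.append(HomologyGroup(
            group_id=f"HG{i:03d}",
            member_ref_ids=members,
            total_copy_number=sum(ref_by_id[m].copy_number for m in members),
            amino_acids={ref_by_id[m].amino_acid for m in members},
        ))
    return out


def correlate_copy_number(
    copy_numbers: Sequence[float], abundances: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation of abundance against genomic copy number.

    Points enter untransformed.  A constant vector on either axis makes the
    correlation undefined; that is reported as R = 0 with the degenerate flag
    set rather than NaN.
    """
    x = np.asarray(copy_numbers, dtype=float)
    y = np.asarray(abundances, dtype=float)
    n = len(x)
    if n < 3 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(R=0.0, p=1.0, n=n, slope=0.0, intercept=float(y.mean()) if n else 0.0,
                                 degenerate=True)
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(R=float(r), p=float(p), n=n,
                             slope=float(fit.slope), intercept=float(fit.intercept))


def group_abundance(
    groups: Sequence[HomologyGroup], abundance: pd.DataFrame
) -> pd.DataFrame:
    """Sum per-reference abundance (refs x ages) into groups x ages."""
    rows = {}
    for g in groups:
        members = [m for m in g.member_ref_ids if m in abundance.index]
        rows[g.group_id] = abundance.loc[members].sum() if members else \
            pd.Series(0.0, index=abundance.columns)
    return pd.DataFrame(rows).T


def correlate_groups_per_age(
    groups: Sequence[HomologyGroup], abundance: pd.DataFrame
) -> dict[str, CorrelationResult]:
    """Per-age copy-number correlation over homology groups."""
    ab = group_abundance(groups, abundance)
    copy_numbers = [g.total_copy_number for g in groups]
    return {
        age: correlate_copy_number(copy_numbers, ab[age].to_numpy())
        for age in abundance.columns
    }


def is_pure(groups: Sequence[HomologyGroup]) -> bool:
    """No group mixes two amino acids."""
    return all(len(g.amino_acids) <= 1 for g in groups)


def select_cluster_number(
    identity: pd.DataFrame,
    references: Sequence[MatureReference],
    abundance: pd.DataFrame,
    k_range: Sequence[int],
    method: str = "average",
    strict_purity: bool = False,
) -> ClusterConfig:
    """Scan k, keep amino-acid-pure partitions, maximize mean per-age R.

    ``strict_purity`` additionally requires each amino acid to be confined to
    a single cluster (the stronger reading of 'all amino acids in separate
    clusters'); the default only forbids mixed clusters.  Emits the full
    k-vs-R table; raises if no k in the range is admissible.
    """
    rows = []
    best: tuple[float, int] | None = None
    violations = {}
    for k in k_range:
        groups = cluster_homology(identity, references, k, method)
        pure = is_pure(groups)
        if pure and strict_purity:
            first_cluster: dict[str, str] = {}
            for g in groups:
                for aa in g.amino_acids:
                    if aa in first_cluster and first_cluster[aa] != g.group_id:
                        pure = False
                    first_cluster.setdefault(aa, g.group_id)
        per_age = correlate_groups_per_age(groups, abundance)
        mean_r = float(np.mean([c.R for c in per_age.values()]))
        rows.append({"k": k, "pure": pure, "mean_R": mean_r,
                     **{f"R_{age}": c.R for age, c in per_age.items()}})
        if not pure:
            mixed = [g.group_id for g in groups if len(g.amino_acids) > 1]
            violations[k] = mixed
            continue
        # strictly-better-only keeps the smallest k on ties; the epsilon stops
        # float jitter from breaking exact ties between equivalent partitions
        if best is None or mean_r > best[0] + 1e-9:
            best = (mean_r, k)
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError(
            f"no admissible cluster number in range; purity violations: {violations}"
        )
    return ClusterConfig(k=best[1], linkage=method, k_table=table)


def write_groups(groups: Sequence[HomologyGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\ttotal_copy_number\tamino_acids\tmember_ref_ids\n")
        for g in groups:
            fh.write(
                f"{g.group_id}\t{g.total_copy_number}\t"
                f"{','.join(sorted(g.amino_acids))}\t{','.join(g.member_ref_ids)}\n"
            )


def write_correlations(
    correlations: Mapping[str, CorrelationResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("age\tR\tp\tn\tslope\tintercept\tdegenerate\n")
        for age, c in correlations.items():
            fh.write(
                f"{age}\t{c.R:.6f}\t{c.p:.3e}\t{c.n}\t{c.slope:.6f}\t"
                f"{c.intercept:.6f}\t{int(c.degenerate)}\n"
            )
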