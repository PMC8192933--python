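"""Synthetic stand-in for the C. elegans genomic tRNA gene census.

This module builds, deterministically, an artificial tRNA gene annotation with
the census structure reported for the C. elegans genome by the genomic tRNA
database: 820 annotated regions of which 605 carry an amino-acid label (600
after excluding flagged pseudogenes), collapsing to 178 unique mature
sequences over 48 anticodons covering the 20 standard amino acids, with 32
intronic regions, a 24-locus proline-TGG family (plus 9 highly homologous
pseudo regions), 25 identical lysine-CTT copies and 17 identical alanine-AGC
copies.

The *sequences* are synthetic: random tRNA-length DNA with a per-amino-acid
backbone so that genes sharing an amino acid are homologous and genes sharing
an anticodon are near-identical, mirroring the homology structure of a real
multicopy tRNA gene complement.  Counts and family structure are exact; use
this set to exercise the reference builder and the homology analysis where
the real annotation is not at hand.
"""

from __future__ import annotations

import numpy as np

from ..reference_builder import TRNAGeneRecord

_SEED = 104729  # fixed: this dataset is a constant, not a simulation

BASES = np.array(list("ACGT"))

#: (amino acid, anticodon) pairs — 48 anticodons over 20 amino acids
ANTICODONS: list[tuple[str, str]] = [
    ("Ala", "AGC"), ("Ala", "CGC"), ("Ala", "TGC"),
    ("Arg", "ACG"), ("Arg", "CCG"), ("Arg", "CCT"), ("Arg", "TCT"), ("Arg", "TCG"),
    ("Asn", "GTT"),
    ("Asp", "GTC"),
    ("Cys", "GCA"),
    ("Gln", "CTG"), ("Gln", "TTG"),
    ("Glu", "CTC"), ("Glu", "TTC"),
    ("Gly", "CCC"), ("Gly", "GCC"), ("Gly", "TCC"),
    ("His", "GTG"),
    ("Ile", "AAT"), ("Ile", "GAT"), ("Ile", "TAT"),
    ("Leu", "AAG"), ("Leu", "CAA"), ("Leu", "CAG"), ("Leu", "TAA"), ("Leu", "TAG"),
    ("Lys", "CTT"), ("Lys", "TTT"),
    ("Met", "CAT"),
    ("Phe", "GAA"),
    ("Pro", "AGG"), ("Pro", "CGG"), ("Pro", "TGG"),
    ("Ser", "AGA"), ("Ser", "CGA"), ("Ser", "GCT"), ("Ser", "TGA"),
    ("Thr", "AGT"), ("Thr", "CGT"), ("Thr", "TGT"),
    ("Trp", "CCA"),
    ("Tyr", "GTA"),
    ("Val", "AAC"), ("Val", "CAC"), ("Val", "TAC"), ("Val", "GAC"),
    ("Gly", "ACC"),
]

ANTICODON_OFFSET = 33  # first anticodon base, spliced gene coordinates
INTRON_AFTER = 38      # canonical intron insertion point, 3' of the anticodon

N_UNIQUE = 178
N_FUNCTIONAL = 600
N_FLAGGED_DECODING = 5   # amino-acid-labelled but pseudogene-flagged
N_NON_DECODING = 215     # regions labelled Pseudo/Undet
N_INTRON_GENES = 32
N_PRO_TGG_HOMOLOG_PSEUDO = 9

# (anticodon key, unique-sequence copy numbers) pinned to the published
# family structure; everything else is allocated pseudo-randomly.
_PINNED: dict[tuple[str, str], list[int]] = {
    ("Pro", "TGG"): [20, 4],          # 24 loci
    ("Lys", "CTT"): [25, 2, 1],       # 25 identical copies in the top family
    ("Ala", "AGC"): [17, 2],          # 17 identical copies
}

CHROMS = ["I", "II", "III", "IV", "V", "X"]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, n_mut: int, protect: range) -> str:
    arr = np.array(list(seq))
    positions = [i for i in range(len(seq)) if i not in protect]
    for pos in rng.choice(positions, size=n_mut, replace=False):
        alternatives = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alternatives[rng.integers(0, 3)]
    return "".join(arr)


def _allocate(rng: np.random.Generator) -> dict[tuple[str, str], list[int]]:
    """Copy numbers per unique sequence, per anticodon; totals exact."""
    free = [key for key in ANTICODONS if key not in _PINNED]
    pinned_uniques = sum(len(v) for v in _PINNED.values())
    pinned_copies = sum(sum(v) for v in _PINNED.values())

    n_extra_uniques = N_UNIQUE - len(free) - pinned_uniques
    weights = rng.dirichlet(np.full(len(free), 0.8))
    extra_uniques = rng.multinomial(n_extra_uniques, weights)

    alloc: dict[tuple[str, str], list[int]] = {k: list(v) for k, v in _PINNED.items()}
    unique_slots: list[tuple[str, str]] = []
    for key, extra in zip(free, extra_uniques):
        alloc[key] = [1] * (1 + int(extra))
        unique_slots.extend([key] * (1 + int(extra)))

    n_extra_copies = N_FUNCTIONAL - pinned_copies - len(unique_slots)
    copy_weights = rng.dirichlet(np.full(len(unique_slots), 0.5))
    extra_copies = rng.multinomial(n_extra_copies, copy_weights)
    cursor: dict[tuple[str, str], int] = {k: 0 for k in alloc}
    for key, extra in zip(unique_slots, extra_copies):
        alloc[key][cursor[key]] += int(extra)
        cursor[key] += 1
    return alloc


def celegans_synthetic_gene_set() -> tuple[list[TRNAGeneRecord], dict[str, str]]:
    """Build the synthetic gene table and its genome.

    Returns the annotated records (sense-oriented sequences) and a
    ``chrom -> sequence`` genome in which every locus is embedded at its
    annotated coordinates (minus-strand loci reverse-complemented).
    """
    rng = np.random.default_rng(_SEED)
    alloc = _allocate(rng)

    # per-amino-acid backbone, per-anticodon consensus, per-unique sequence
    aa_backbone: dict[str, str] = {}
    seen: set[str] = set()
    uniques: list[tuple[str, str, str, list[int]]] = []  # aa, anticodon, seq, copies
    for (aa, anticodon), copies in ((k, alloc[k]) for k in ANTICODONS):
        if aa not in aa_backbone:
            length = int(rng.integers(70, 91))
            aa_backbone[aa] = _random_seq(rng, length)
        backbone = aa_backbone[aa]
        protect = range(ANTICODON_OFFSET, ANTICODON_OFFSET + 3)
        consensus = (
            backbone[:ANTICODON_OFFSET] + anticodon + backbone[ANTICODON_OFFSET + 3:]
        )
        consensus = _mutate(rng, consensus, 4, protect)
        for i, copy_number in enumerate(copies):
            seq = consensus
            while i > 0 or seq in seen:
                seq = _mutate(rng, consensus, int(rng.integers(1, 7)), protect)
                if seq not in seen:
                    break
            seen.add(seq)
            uniques.append((aa, anticodon, seq, [copy_number]))

    # expand uniques into genomic loci
    loci: list[dict] = []
    for serial, (aa, anticodon, seq, copies) in enumerate(uniques):
        for c in range(copies[0]):
            loci.append({
                "amino_acid": aa, "anticodon": anticodon, "spliced": seq,
                "is_pseudogene": False, "unique_serial": serial,
            })
    assert len(loci) == N_FUNCTIONAL

    # amino-acid-labelled pseudogenes: degenerate copies of real uniques
    for i in range(N_FLAGGED_DECODING):
        aa, anticodon, seq, _ = uniques[int(rng.integers(0, len(uniques)))]
        loci.append({
            "amino_acid": aa, "anticodon": anticodon,
            "spliced": _mutate(rng, seq, 3, range(0)),
            "is_pseudogene": True, "unique_serial": -1,
        })

    # non-decoding regions: 9 homologs of the big Pro-TGG family + the rest
    pro_seq = next(seq for aa, ac, seq, _ in uniques if (aa, ac) == ("Pro", "TGG"))
    for i in range(N_NON_DECODING):
        if i < N_PRO_TGG_HOMOLOG_PSEUDO:
            label, seq = "Pseudo", _mutate(rng, pro_seq, 6, range(0))
        else:
            label = "Undet" if i % 8 == 0 else "Pseudo"
            seq = _random_seq(rng, int(rng.integers(60, 86)))
        loci.append({
            "amino_acid": label, "anticodon": "NNN", "spliced": seq,
            "is_pseudogene": True, "unique_serial": -1,
        })
    assert len(loci) == N_FUNCTIONAL + N_FLAGGED_DECODING + N_NON_DECODING == 820

    # introns: 32 functional genes carry one intron 3' of the anticodon
    functional_idx = [i for i, l in enumerate(loci) if not l["is_pseudogene"]]
    intron_idx = set(rng.choice(functional_idx, size=N_INTRON_GENES, replace=False).tolist())

    # lay loci onto chromosomes in a shuffled deterministic order
    order = rng.permutation(len(loci))
    genome_parts: dict[str, list[str]] = {c: [_random_seq(rng, 50)] for c in CHROMS}
    genome_pos: dict[str, int] = {c: 50 for c in CHROMS}
    records: list[TRNAGeneRecord] = []
    for rank, idx in enumerate(order):
        locus = loci[idx]
        spliced = locus["spliced"]
        if idx in intron_idx:
            ilen = int(rng.integers(11, 21))
            intron_seq = _random_seq(rng, ilen)
            gene_seq = spliced[:INTRON_AFTER] + intron_seq + spliced[INTRON_AFTER:]
            introns = [(INTRON_AFTER, INTRON_AFTER + ilen)]
        else:
            gene_seq = spliced
            introns = []
        chrom = CHROMS[rank % len(CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        start = genome_pos[chrom]
        end = start + len(gene_seq)
        genomic = gene_seq if strand == "+" else _revcomp(gene_seq)
        flank = _random_seq(rng, int(rng.integers(30, 61)))
        genome_parts[chrom].extend([genomic, flank])
        genome_pos[chrom] = end + len(flank)
        decoding = locus["amino_acid"] not in {"Pseudo", "Undet"}
        records.append(TRNAGeneRecord(
            gene_id=f"trna-{rank + 1:04d}",
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            amino_acid=locus["amino_acid"],
            anticodon=locus["anticodon"],
            anticodon_start=ANTICODON_OFFSET if decoding else None,
            introns=introns,
            is_pseudogene=locus["is_pseudogene"],
            gene_seq=gene_seq,
        ))
    genome = {c: "".join(parts) for c, parts in genome_parts.items()}
    return records, genome


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
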