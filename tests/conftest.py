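from __future__ import annotations

import pytest

from trfage.reference_builder import MatureReference, TRNAGeneRecord


def make_gene(
    gene_id: str,
    seq: str,
    introns=(),
    anticodon_start: int | None = None,
    aa: str = "Ala",
    anticodon: str = "AGC",
    pseudo: bool = False,
    chrom: str = "chr1",
    start: int = 0,
    strand: str = "+",
) -> TRNAGeneRecord:
    return TRNAGeneRecord(
        gene_id=gene_id, chrom=chrom, start=start, end=start + len(seq),
        strand=strand, amino_acid=aa, anticodon=anticodon,
        anticodon_start=anticodon_start, introns=list(introns),
        is_pseudogene=pseudo, gene_seq=seq,
    )


def make_ref(
    ref_id: str,
    sequence: str,
    n_copies: int = 1,
    anticodon_pos: int | None = None,
    aa: str = "Ala",
    anticodon: str = "AGC",
) -> MatureReference:
    return MatureReference(
        ref_id=ref_id,
        sequence=sequence,
        member_gene_ids=[f"{ref_id}_g{i}" for i in range(n_copies)],
        amino_acid=aa,
        anticodon=anticodon,
        anticodon_pos=anticodon_pos,
    )


@pytest.fixture
def toy_refs() -> list[MatureReference]:
    """Two 40-nt references sharing a 20-nt 5' prefix, plus an unrelated one."""
    shared = "ACGTACGTGGATCCAAGGTT"
    return [
        make_ref("Ala_AGC", shared + "CAGTGGTAGAGCATTCCCCA"),
        make_ref("Ala_AGC_2", shared + "TTTTGGGACCACGAGATCCA"),
        make_ref("Gly_GCC", "GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACCCA", aa="Gly", anticodon="GCC"),
    ]
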