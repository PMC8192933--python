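"""Mature tRNA reference construction.

Genomic tRNA loci are turned into the reference set actually present in the
cell: introns are spliced out, the post-transcriptionally added 3'-CCA
trinucleotide is appended, pseudogenes are dropped, and byte-identical mature
sequences are collapsed into a single reference that remembers every genomic
copy it represents.  Fragment abundance downstream is interpreted per unique
mature sequence, with the genomic copy number carried along for the
copy-number/abundance analysis.

Coordinates are 0-based half-open everywhere; minus-strand loci are stored
sense-oriented (already reverse-complemented).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

#: amino-acid labels that mark a region as not a decoding tRNA gene
NON_DECODING_LABELS = frozenset({"Pseudo", "Undet"})

CCA = "CCA"


@dataclass
class TRNAGeneRecord:
    """One genomic tRNA locus with its structural annotation.

    ``gene_seq`` is the sense strand of the tRNA (reverse-complemented for
    minus-strand loci), so all gene-relative offsets (``anticodon_start``,
    ``introns``) read left-to-right along the transcript.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    amino_acid: str
    anticodon: str
    anticodon_start: int | None
    introns: list[tuple[int, int]]
    is_pseudogene: bool
    gene_seq: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.gene_seq and len(self.gene_seq) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.gene_seq)} does not "
                f"match interval length {self.end - self.start}"
            )
        for ivl_start, ivl_end in self.introns:
            if not (0 <= ivl_start < ivl_end <= len(self.gene_seq)):
                raise ValueError(f"{self.gene_id}: intron {ivl_start}-{ivl_end} out of bounds")

    @property
    def is_decoding(self) -> bool:
        """True for regions annotated with a standard amino acid."""
        return self.amino_acid not in NON_DECODING_LABELS


@dataclass
class MatureReference:
    """One unique mature tRNA sequence and the genomic copies behind it."""

    ref_id: str
    sequence: str
    member_gene_ids: list[str]
    amino_acid: str
    anticodon: str
    anticodon_pos: int | None

    def __post_init__(self) -> None:
        if not self.sequence.endswith(CCA):
            raise ValueError(f"{self.ref_id}: mature sequence must end in CCA")

    @property
    def copy_number(self) -> int:
        return len(self.member_gene_ids)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _parse_introns(text: str) -> list[tuple[int, int]]:
    if not text or text in {".", "-"}:
        return []
    out = []
    for chunk in text.split(","):
        s, _, e = chunk.partition("-")
        out.append((int(s), int(e)))
    return out


def _format_introns(introns: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in introns) if introns else "."


ANNOTATION_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand", "amino_acid",
    "anticodon", "anticodon_start", "introns", "is_pseudogene",
]


def parse_gene_set(
    annotation: str | Path,
    sequences: str | Path | Mapping[str, str],
) -> list[TRNAGeneRecord]:
    """Parse a tab-separated tRNA gene annotation plus genomic sequence.

    ``sequences`` is a genome FASTA path or a mapping ``chrom -> sequence``;
    the genomic slice of each locus is extracted and reverse-complemented for
    minus-strand loci so that every record stores the sense sequence.

    Inconsistencies between the annotated anticodon and the sequence at
    ``anticodon_start`` are kept but flagged; duplicate gene ids are rejected.
    """
    if not isinstance(sequences, Mapping):
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(sequences), "fasta")}

    records: list[TRNAGeneRecord] = []
    seen: set[str] = set()
    with open(annotation) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in ANNOTATION_COLUMNS if c not in col]
        if missing:
            raise ValueError(f"annotation is missing columns: {missing}")
        for line in fh:
            row = line.rstrip("\n").split("\t")
            gene_id = row[col["gene_id"]]
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r} in annotation")
            seen.add(gene_id)
            chrom = row[col["chrom"]]
            start, end = int(row[col["start"]]), int(row[col["end"]])
            strand = row[col["strand"]]
            genomic = sequences[chrom][start:end]
            gene_seq = reverse_complement(genomic) if strand == "-" else genomic
            ac_start_raw = row[col["anticodon_start"]]
            anticodon_start = None if ac_start_raw in {"", ".", "NA"} else int(ac_start_raw)
            rec = TRNAGeneRecord(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                amino_acid=row[col["amino_acid"]],
                anticodon=row[col["anticodon"]],
                anticodon_start=anticodon_start,
                introns=_parse_introns(row[col["introns"]]),
                is_pseudogene=row[col["is_pseudogene"]] in {"1", "true", "True", "yes"},
                gene_seq=gene_seq,
            )
            if anticodon_start is not None and not _anticodon_in_intron(rec):
                observed = gene_seq[anticodon_start:anticodon_start + 3]
                if observed != rec.anticodon:
                    log.warning(
                        "%s: annotated anticodon %s != sequence %s at offset %d",
                        gene_id, rec.anticodon, observed, anticodon_start,
                    )
                    rec.flags.append("anticodon_mismatch")
            records.append(rec)
    return records


def _anticodon_in_intron(gene: TRNAGeneRecord) -> bool:
    assert gene.anticodon_start is not None
    return any(s <= gene.anticodon_start < e for s, e in gene.introns)


def write_gene_set(
    genes: Iterable[TRNAGeneRecord],
    genome: Mapping[str, str],
    annotation_path: str | Path,
    genome_path: str | Path,
) -> None:
    """Write the annotation TSV + genome FASTA pair that parse_gene_set reads."""
    with open(annotation_path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for g in genes:
            fh.write("\t".join([
                g.gene_id, g.chrom, str(g.start), str(g.end), g.strand,
                g.amino_acid, g.anticodon,
                "." if g.anticodon_start is None else str(g.anticodon_start),
                _format_introns(g.introns),
                "1" if g.is_pseudogene else "0",
            ]) + "\n")
    with open(genome_path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def build_mature_sequence(gene: TRNAGeneRecord) -> str:
    """Splice out introns and append the 3'-CCA of the mature tRNA."""
    introns = sorted(gene.introns)
    for (s1, e1), (s2, e2) in zip(introns, introns[1:]):
        if s2 < e1:
            raise ValueError(f"{gene.gene_id}: overlapping introns {(s1, e1)} and {(s2, e2)}")
    pieces = []
    cursor = 0
    for s, e in introns:
        pieces.append(gene.gene_seq[cursor:s])
        cursor = e
    pieces.append(gene.gene_seq[cursor:])
    return "".join(pieces) + CCA


def map_anticodon_position(gene: TRNAGeneRecord) -> int | None:
    """Mature-coordinate offset of the first anticodon base.

    With an annotated gene-relative offset this subtracts the introns that lie
    entirely upstream.  Without one, the anticodon is located by exact string
    match in the spliced sequence within the canonical window (offsets 30-40);
    ``None`` means the position could not be resolved and the reference is
    excluded from modification calling.
    """
    if gene.anticodon_start is not None:
        if _anticodon_in_intron(gene):
            return None
        return gene.anticodon_start - sum(
            e - s for s, e in gene.introns if e <= gene.anticodon_start
        )
    spliced = build_mature_sequence(gene)[:-len(CCA)]
    hit = spliced.find(gene.anticodon, 30, 40 + len(gene.anticodon))
    return hit if hit != -1 else None


def deduplicate(genes: Iterable[TRNAGeneRecord]) -> list[MatureReference]:
    """Collapse non-pseudogene loci into unique mature references.

    References are named ``<AA>_<anticodon>`` with a ``_<n>`` serial for
    isodecoders sharing amino acid and anticodon, serials assigned by
    lexicographic order of the mature sequence so ids are stable across runs
    and input orderings.
    """
    by_seq: dict[str, list[TRNAGeneRecord]] = {}
    for g in genes:
        if g.is_pseudogene:
            continue
        by_seq.setdefault(build_mature_sequence(g), []).append(g)

    groups = []
    for seq, members in by_seq.items():
        members = sorted(members, key=lambda g: g.gene_id)
        rep = members[0]
        groups.append((rep.amino_acid, rep.anticodon, seq, members))

    serial: Counter[tuple[str, str]] = Counter()
    refs = []
    for aa, ac, seq, members in sorted(groups, key=lambda t: (t[0], t[1], t[2])):
        serial[(aa, ac)] += 1
        n = serial[(aa, ac)]
        ref_id = f"{aa}_{ac}" if n == 1 else f"{aa}_{ac}_{n}"
        refs.append(MatureReference(
            ref_id=ref_id,
            sequence=seq,
            member_gene_ids=[g.gene_id for g in members],
            amino_acid=aa,
            anticodon=ac,
            anticodon_pos=map_anticodon_position(members[0]),
        ))
    return refs


def anticodon_census(genes: Iterable[TRNAGeneRecord]) -> dict[str, int]:
    """Genomic copy count per anticodon over non-pseudogene genes."""
    census: Counter[str] = Counter(
        g.anticodon for g in genes if not g.is_pseudogene and g.is_decoding
    )
    return dict(census)


def summarize_gene_set(genes: Sequence[TRNAGeneRecord]) -> dict[str, int]:
    """Census of a gene set: region, gene, intron, and unique-sequence counts.

    Both the raw amino-acid-annotated gene count and the pseudogene-filtered
    count are reported, since annotation sources disagree on whether flagged
    pseudogenes with amino-acid labels count as tRNA genes.
    """
    decoding = [g for g in genes if g.is_decoding]
    functional = [g for g in decoding if not g.is_pseudogene]
    refs = deduplicate(genes)
    return {
        "n_regions": len(genes),
        "n_trna_genes": len(decoding),
        "n_non_pseudogene_genes": len(functional),
        "n_unique_mature": len(refs),
        "n_anticodons": len(anticodon_census(genes)),
        "n_intronic_regions": sum(len(g.introns) for g in decoding),
    }


def write_reference_fasta(refs: Iterable[MatureReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.ref_id}\n{r.sequence}\n")


def write_reference_index(refs: Iterable[MatureReference], path: str | Path) -> None:
    """TSV index: ref_id, amino acid, anticodon, mature anticodon offset,
    copy number and member gene ids."""
    with open(path, "w") as fh:
        fh.write("ref_id\tamino_acid\tanticodon\tanticodon_pos\tcopy_number\tmember_gene_ids\n")
        for r in refs:
            pos = "." if r.anticodon_pos is None else str(r.anticodon_pos)
            fh.write(
                f"{r.ref_id}\t{r.amino_acid}\t{r.anticodon}\t{pos}\t"
                f"{r.copy_number}\t{','.join(r.member_gene_ids)}\n"
            )


def load_references(fasta_path: str | Path, index_path: str | Path) -> list[MatureReference]:
    """Load a mature reference set written by the two writers above."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    refs = []
    with open(index_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            ref_id = row[col["ref_id"]]
            pos = row[col["anticodon_pos"]]
            refs.append(MatureReference(
                ref_id=ref_id,
                sequence=seqs[ref_id],
                member_gene_ids=row[col["member_gene_ids"]].split(","),
                amino_acid=row[col["amino_acid"]],
                anticodon=row[col["anticodon"]],
                anticodon_pos=None if pos == "." else int(pos),
            ))
    return refs
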