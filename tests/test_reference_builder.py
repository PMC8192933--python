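"""Mature reference construction: splicing, CCA addition, deduplication."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings, strategies as st

from conftest import make_gene
from trfage.reference_builder import (
    anticodon_census, build_mature_sequence, deduplicate, map_anticodon_position,
    parse_gene_set, summarize_gene_set, write_gene_set, write_reference_fasta,
    write_reference_index, load_references,
)


def _write_toy_set(tmp_path, genes, genome):
    ann, fa = tmp_path / "genes.tsv", tmp_path / "genome.fa"
    write_gene_set(genes, genome, ann, fa)
    return ann, fa


class TestParseGeneSet:
    def test_toy_table_preserves_pseudogene_flag(self, tmp_path):
        seq = "GGGAAACCCTTTGGGAAACCC"
        genome = {"chr1": "A" * 10 + seq + "T" * 10}
        genes = [
            make_gene("g1", seq, start=10),
            make_gene("g2", seq, start=10, aa="Gly", anticodon="GCC"),
            make_gene("g3", seq, start=10, pseudo=True),
        ]
        ann, fa = _write_toy_set(tmp_path, genes, genome)
        parsed = parse_gene_set(ann, fa)
        assert len(parsed) == 3
        assert [g.is_pseudogene for g in parsed] == [False, False, True]
        assert all(g.gene_seq == seq for g in parsed)

    def test_minus_strand_locus_stored_sense_oriented(self, tmp_path):
        sense = "GGGCCCATTGCGATCGTTAA"
        genome = {"chr1": "ACGT" + reverse_complement(sense) + "ACGT"}
        gene = make_gene("g1", sense, start=4, strand="-")
        ann, fa = _write_toy_set(tmp_path, [gene], genome)
        parsed = parse_gene_set(ann, fa)
        assert parsed[0].gene_seq == sense

    def test_empty_table(self, tmp_path):
        ann, fa = _write_toy_set(tmp_path, [], {"chr1": "ACGT"})
        assert parse_gene_set(ann, fa) == []

    def test_duplicate_gene_id_rejected(self, tmp_path):
        seq = "GGGAAACCCTTTGGGAAACCC"
        genome = {"chr1": seq}
        genes = [make_gene("g1", seq), make_gene("g1", seq)]
        ann, fa = tmp_path / "a.tsv", tmp_path / "g.fa"
        with open(ann, "w") as fh:
            fh.write("gene_id\tchrom\tstart\tend\tstrand\tamino_acid\tanticodon\t"
                     "anticodon_start\tintrons\tis_pseudogene\n")
            for g in genes:
                fh.write(f"{g.gene_id}\tchr1\t0\t{len(seq)}\t+\tAla\tAGC\t.\t.\t0\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_gene_set(ann, {"chr1": seq})

    def test_anticodon_sequence_inconsistency_flagged_not_dropped(self, tmp_path):
        seq = "GGGAAACCCTTTGGGAAACCC"
        gene = make_gene("g1", seq, anticodon_start=0, anticodon="TTT")
        ann, fa = _write_toy_set(tmp_path, [gene], {"chr1": seq})
        parsed = parse_gene_set(ann, fa)
        assert len(parsed) == 1
        assert "anticodon_mismatch" in parsed[0].flags


class TestMatureSequence:
    @pytest.mark.parametrize("seq,introns,expected", [
        ("GGGAAACCC", [], "GGGAAACCCCCA"),
        ("GGGAAACCC", [(3, 6)], "GGGCCCCCA"),
        ("GGGAAACCC", [(0, 3), (6, 9)], "AAACCA"),
    ])
    def test_splice_and_cca(self, seq, introns, expected):
        assert build_mature_sequence(make_gene("g", seq, introns)) == expected

    def test_intronless_length_arithmetic(self):
        gene = make_gene("g", "A" * 72)
        assert len(build_mature_sequence(gene)) == 75

    def test_overlapping_introns_error(self):
        gene = make_gene("g", "GGGAAACCC", [(2, 6), (4, 8)])
        with pytest.raises(ValueError, match="overlapping"):
            build_mature_sequence(gene)

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_splice_round_trip(self, data):
        """Mature sequence minus CCA equals the concatenated exonic slices."""
        n = data.draw(st.integers(40, 100))
        seq = "".join(data.draw(st.sampled_from("ACGT")) for _ in range(n))
        cuts = sorted(data.draw(
            st.lists(st.integers(0, n), min_size=0, max_size=6, unique=True)))
        introns = [(cuts[i], cuts[i + 1]) for i in range(0, len(cuts) - 1, 2)
                   if cuts[i] < cuts[i + 1]]
        gene = make_gene("g", seq, introns)
        mature = build_mature_sequence(gene)
        exonic = []
        cursor = 0
        for s, e in introns:
            exonic.append(seq[cursor:s])
            cursor = e
        exonic.append(seq[cursor:])
        assert mature == "".join(exonic) + "CCA"


class TestAnticodonPosition:
    @pytest.mark.parametrize("introns,expected", [
        ([], 33),
        ([(10, 20)], 23),
        ([(40, 55)], 33),
        ([(10, 20), (40, 55)], 23),
    ])
    def test_upstream_introns_shift_offset(self, introns, expected):
        seq = "A" * 80
        gene = make_gene("g", seq, introns, anticodon_start=33, anticodon="AAA")
        assert map_anticodon_position(gene) == expected

    def test_unannotated_anticodon_found_by_search(self):
        seq = "T" * 33 + "AGC" + "T" * 40
        gene = make_gene("g", seq, anticodon_start=None, anticodon="AGC")
        assert map_anticodon_position(gene) == 33

    def test_unfindable_anticodon_is_none(self):
        gene = make_gene("g", "T" * 76, anticodon_start=None, anticodon="AGC")
        assert map_anticodon_position(gene) is None


class TestDeduplicate:
    def test_identical_copies_collapse(self):
        seq_a, seq_b = "GGGAAACCC", "GGGTTTCCC"
        genes = [make_gene("g1", seq_a), make_gene("g2", seq_a),
                 make_gene("g3", seq_b, aa="Gly", anticodon="GCC")]
        refs = deduplicate(genes)
        assert sorted(r.copy_number for r in refs) == [1, 2]
        assert all(r.sequence.endswith("CCA") for r in refs)

    def test_all_pseudogene_input_empty(self):
        genes = [make_gene("g1", "GGGAAACCC", pseudo=True)]
        assert deduplicate(genes) == []

    def test_copy_number_conservation_and_order_independence(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(8)]
        genes = [
            make_gene(f"g{i}", seqs[rng.integers(0, len(seqs))])
            for i in range(30)
        ]
        refs = deduplicate(genes)
        assert sum(r.copy_number for r in refs) == len(genes)
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        refs2 = deduplicate(shuffled)
        assert [(r.ref_id, r.sequence, sorted(r.member_gene_ids)) for r in refs] == \
               [(r.ref_id, r.sequence, sorted(r.member_gene_ids)) for r in refs2]

    def test_deduplicate_idempotent_ref_ids(self):
        genes = [make_gene("g1", "GGGAAACCC"), make_gene("g2", "GGGTTTCCC")]
        ids1 = [r.ref_id for r in deduplicate(genes)]
        ids2 = [r.ref_id for r in deduplicate(genes)]
        assert ids1 == ids2
        assert ids1[0] != ids1[1]  # serials disambiguate shared AA+anticodon


class TestCensusAndRoundTrip:
    def test_anticodon_census_toy(self):
        genes = [make_gene(f"g{i}", "GGGAAACCC", anticodon="TGG") for i in range(3)]
        genes.append(make_gene("g3", "GGGTTTCCC", anticodon="GTC"))
        genes.append(make_gene("g4", "GGGTTTCCC", anticodon="GTC", pseudo=True))
        census = anticodon_census(genes)
        assert census == {"TGG": 3, "GTC": 1}
        assert sum(census.values()) == sum(
            1 for g in genes if not g.is_pseudogene and g.is_decoding)

    def test_anticodon_census_empty(self):
        assert anticodon_census([]) == {}

    def test_reference_fasta_index_round_trip(self, tmp_path):
        genes = [make_gene("g1", "GGGAAACCC"), make_gene("g2", "GGGTTTCCC")]
        refs = deduplicate(genes)
        write_reference_fasta(refs, tmp_path / "r.fa")
        write_reference_index(refs, tmp_path / "r.tsv")
        loaded = load_references(tmp_path / "r.fa", tmp_path / "r.tsv")
        assert [(r.ref_id, r.sequence, r.copy_number) for r in loaded] == \
               [(r.ref_id, r.sequence, r.copy_number) for r in refs]


class TestPackagedCensus:
    def test_synthetic_celegans_counts(self):
        """The packaged gene table carries the published census structure."""
        from trfage.datasets import celegans_synthetic_gene_set

        genes, genome = celegans_synthetic_gene_set()
        summary = summarize_gene_set(genes)
        assert summary == {
            "n_regions": 820,
            "n_trna_genes": 605,
            "n_non_pseudogene_genes": 600,
            "n_unique_mature": 178,
            "n_anticodons": 48,
            "n_intronic_regions": 32,
        }
        census = anticodon_census(genes)
        assert census["TGG"] == 24  # proline-TGG family
        copy_numbers = {r.copy_number for r in deduplicate(genes)}
        assert {25, 17, 20} <= copy_numbers  # Lys-CTT, Ala-AGC, big Pro-TGG

    def test_synthetic_celegans_genome_round_trip(self, tmp_path):
        """Written annotation + genome re-parse to the same sense sequences."""
        from trfage.datasets import celegans_synthetic_gene_set

        genes, genome = celegans_synthetic_gene_set()
        write_gene_set(genes, genome, tmp_path / "g.tsv", tmp_path / "g.fa")
        parsed = parse_gene_set(tmp_path / "g.tsv", tmp_path / "g.fa")
        assert len(parsed) == len(genes)
        for a, b in zip(genes, parsed):
            assert a.gene_seq == b.gene_seq
            assert a.introns == b.introns
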