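# trfage

Quantifying tRNA-derived fragments (tRFs) in aging small-RNA sequencing
series, with the two confounders that make naive tRF analysis unreliable
handled explicitly: tRNA genes exist as families of identical and
near-identical genomic copies, and mature tRNAs carry modified bases that
show up as systematic mismatches in reads.

It is written for people analysing small-RNA-seq libraries over an age (or
other condition) course who want per-fragment abundance calls that are not
artifacts of multi-mapping or RNA modification.

## What it does

1. **Mature reference construction.** Genomic tRNA loci are spliced
   (introns removed), the post-transcriptional 3′-CCA is appended,
   pseudogenes are dropped, and byte-identical mature sequences are collapsed
   into unique references that remember their genomic copy number.
2. **Sequential all-best-hit alignment.** Reads are placed ungapped,
   end-to-end, sense-strand only: first requiring a perfect match, then
   retrying failures at one and two mismatches (`v = 0, 1, 2`). *All*
   placements achieving a read's minimal mismatch count are reported, so
   homologous copies share multi-mapped reads. The perfect-match-first
   discipline guarantees that a read identical to one family member is never
   reported as a mismatched alignment to another — the mismatches that
   remain are RNA editing or genuine mutations, not family-internal
   divergence.
3. **Profiling and tRF calling.** Per-reference depth and base-composition
   pileups; enrichment regions called as maximal runs with depth ≥ θ·max
   (default θ = 0.5), top-percentile selection per library, classification
   into 5′ / 3′ (± terminal CCA) / middle fragments, and a homology filter
   that removes a candidate exactly when a homologous reference carries a
   strictly larger enrichment containing the candidate's sequence. Per-age
   abundance (reads per million) gets a linear age trend (UP/DOWN/FLAT at
   |r| ≥ 0.8).
4. **Modification calling.** Mismatch piles are classified by signature:
   A→G at the anticodon wobble position (position 34) → A-to-I editing;
   mixed-base misincorporation in the T-loop window → m1A-like; one
   consistent alternate base in every library → de novo mutation.
5. **Copy-number coupling.** Unique references are clustered into homology
   groups on a pairwise percent-identity matrix (average linkage on
   100 − identity); the cluster number k is scanned, discarding partitions
   that mix amino acids, and per-age Pearson correlation between group copy
   number and fragment abundance is reported.
6. **Synthetic data.** A first-class simulator produces gene families,
   age-series FASTQ libraries (fragment counts ∝ copy_number × (1 + s·day),
   Poisson-sampled) and ground-truth tables, so the whole pipeline is
   testable end to end without downloads. A packaged synthetic stand-in for
   the *C. elegans* genomic tRNA census (820 regions, 605 genes, 178 unique
   mature sequences, 48 anticodons) exercises the reference builder at
   realistic scale.

## Worked example

One command simulates an 8-family gene set with four age libraries
(days 0, 5, 8, 12) and runs every stage:

```bash
trfage demo --seed 1 --outdir demo-run
```

The run prints:

```
gene set: {'n_regions': 118, 'n_trna_genes': 118, 'n_non_pseudogene_genes': 118,
           'n_unique_mature': 8, 'n_anticodons': 8, 'n_intronic_regions': 61}
called 5 tRF regions (5 pass the homology filter)
copy-number correlation day0: R=1.000 p=1.40e-10
copy-number correlation day5: R=0.999 p=1.25e-09
copy-number correlation day8: R=1.000 p=2.82e-11
copy-number correlation day12: R=1.000 p=2.53e-10
```

118 simulated loci across 8 families collapse to 8 unique mature
references; 5 enrichment
regions are called and all survive the homology filter; because simulated
fragment counts are proportional to family copy number, the per-age
copy-number correlation is ≈ 1. `demo-run/trfs.tsv` holds the called
fragments, e.g.

```
ref_id   start  end  type         has_cca  rpm_day0    ...  trend  passes_filter
Arg_ACG  53     86   THREE_PRIME  0        158828.499  ...  FLAT   1
Asp_GTC  30     60   MIDDLE       0        195437.905  ...  FLAT   1
```

(the trends are FLAT here because every simulated family grows at the same
rate, so library-relative abundance is constant — see `docs/methods.md`).

Individual stages are available as `trfage build-ref / simulate / align /
profile / call-trfs / call-mods / cluster / correlate / run-all`; `run-all`
takes a YAML config naming the annotation, genome FASTA, and per-age FASTQ
files.

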