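# Methods

## The problem

tRNA-derived fragments (tRFs) are small RNAs cleaved from mature tRNAs,
mostly at the single-stranded loops; halves produced at the anticodon loop
are 30–35 nt. Two properties of tRNA biology defeat generic small-RNA
quantification. First, tRNA genes occur as multicopy families — many copies
are byte-identical, others differ by a few bases — so a read's genomic
origin is ambiguous, and an aligner that reports one arbitrary best hit
distributes a family's reads unpredictably over its members. Second, mature
tRNAs differ from their genes: introns are spliced out, a CCA trinucleotide
is added at the 3′ end, and modified bases (inosine at the anticodon wobble
position, N1-methyladenosine in the T-loop) reverse-transcribe as
mismatches. Aligning against genomic sequence therefore loses 3′-CCA reads,
splice-junction reads and heavily modified reads, and miscounts everything
shared between homologs.

## Reference model

A unique mature reference is the equivalence class of non-pseudogene loci
whose spliced sequence plus CCA is byte-identical; its copy number is the
class size. Coordinates are 0-based half-open throughout; SAM output is the
only place 1-based coordinates appear. Loci annotated without an anticodon
offset have the anticodon located by exact match within mature offsets
30–40; when that fails the reference is excluded from modification calling
(its anticodon position is unknown) but kept for everything else. Histidine
G−1 addition and other 5′ maturation edits are not modeled. Reference ids
are `<AA>_<anticodon>` with a serial suffix for isodecoders, serials
assigned by lexicographic order of the mature sequence, so ids are stable
across runs and input orderings.

## Alignment

Placements are ungapped, end-to-end, and sense-strand only — a tRF is a
contiguous piece of a mature tRNA, so antisense or gapped placements would
be artifacts (a deliberate tightening relative to general-purpose aligners
whose defaults search both strands). The reference set is tens of kilobases,
so search is exact brute force over every (reference, offset) pair using
numpy sliding-window comparisons; there are no seeds or heuristics to
introduce mapping bias. `N` mismatches every base. Alignment is sequential:
round 0 places reads with a perfect match somewhere; failures retry at one,
then two mismatches. All placements achieving the read's minimal mismatch
count are reported as primary ("all best hits"), and each placement counts 1
in downstream tallies (an optional fractional mode weights by 1/n_hits,
default off). Equivalently: placements are minimal-mismatch sets with a
cap of 2, which is what the brute-force oracle in the test suite checks
exactly.

Adapter trimming removes the best-scoring occurrence of the 3′ adapter (or
an adapter prefix reaching the read end) with per-overlap error rate ≤ 0.1
(configurable; minimum overlap 3, most-matching-bases occurrence wins);
trimmed reads shorter than 15 nt are discarded.

## tRF calling

Enrichment regions are maximal runs of positions with depth ≥ θ · (reference
maximum), θ = 0.5 by default; runs separated by < 3 nt merge and runs
< 10 nt are dropped. These defaults are calibrated to half-molecule-scale
fragments; all are configurable. Region abundance is mean depth (supporting
read count available), ranked per library, and the top 1% (configurable;
ties kept) selected per library, with the union over libraries as the final
candidate set — same-reference selections with reciprocal overlap ≥ 0.5 are
treated as the same fragment, widest interval kept. Classification: a region
starting within 3 nt of the 5′ end is FIVE_PRIME, ending within 3 nt of the
3′ end (CCA included) THREE_PRIME, else MIDDLE; near-full-length regions take
the closer end (ties 5′); `has_cca` means the region runs through the final
base.

The homology false-positive filter: multi-mapped reads from a long fragment
on one family member project a shorter shadow enrichment onto homologs that
share only part of the fragment's sequence. A candidate fails the filter iff
some homologous reference (by default: any reference sharing a multi-mapped
read with it) carries a called region strictly larger than the candidate
whose sequence contains the candidate's sequence. A fragment present "as is"
(equal extent) on homologs passes — it is the same fragment, legitimately
multi-mapped. A candidate that is the unique largest enrichment in its
homology set can never be removed.

Age trends: least-squares regression of per-age RPM on day; UP requires
positive slope and Pearson r ≥ 0.8, DOWN the mirror image, everything else
(including constant series, whose r is undefined) FLAT. RPM denominators are
whole-library read totals when available — tRF abundance is meaningful
relative to the whole small-RNA population, and relative-to-tRNA-only
normalization cancels uniform growth.

## Modification calling

Candidate sites have pooled non-N depth ≥ 20 and mismatch fraction ≥ 0.1.
Rules apply in order: (1) reference A at the anticodon wobble position with
G the dominant alternate → A-to-I (inosine pairs like G); (2) a site in the
T-loop window with ≥ 3 base identities each ≥ 5% of depth → m1A-like (the
methyl group makes reverse transcriptase misincorporate any base); (3) a
single alternate ≥ 90% of depth in every library → de novo mutation;
(4) otherwise ambiguous. The T-loop window defaults to mature positions
[L−22, L−14), derived from canonical position 58 of a 76-nt CCA-bearing
tRNA. The base 3′ of each called site is recorded (m1A misincorporation is
context-dependent) but not used for classification. The thresholds are this
package's choices; published analyses state none. Cross-age stability
reports each site's per-library mismatch-fraction spread and flags sites
exceeding 0.2; libraries without coverage contribute missing values, never
flags.

## Homology grouping and copy-number correlation

Pairwise percent identity uses global alignment (match +1, mismatch −1, gap
−2, end gaps penalized like internal ones) with identity = 100 × matched
columns / columns where both sequences have a residue, computed with
Biopython's pairwise aligner; argument order is canonicalized so the matrix
is exactly symmetric. End gaps are deliberately not free: with free end
gaps, two unrelated sequences can align a short chance overlap perfectly and
score 100% identity, which collapses clustering. An externally produced
square identity matrix can be ingested instead.

Groups come from average-linkage agglomerative clustering on distance =
100 − identity, cut at k clusters. k is scanned over a range; partitions
placing two amino acids in one cluster are inadmissible (a stricter mode
additionally requires each amino acid confined to a single cluster), and
among admissible k the mean per-age Pearson R of group copy number versus
group abundance is maximized, ties to the smallest k (an epsilon guard keeps
float jitter from breaking exact ties between equivalent partitions — with
abundance exactly proportional to copy number every refinement of the true
partition scores R = 1). Correlations use raw counts (log mode behind a
flag); a constant vector on either axis makes R undefined and is reported as
0 with a degenerate flag.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
multicopy families (identical copies by default, near-identical at a
configurable per-base divergence), optional introns and pseudogenes, mature
lengths 70–90 nt before CCA, fragments per family of one of four types
(5′, 3′ with CCA, 3′ without CCA, middle) with boundaries jittered by a
discretized Gaussian (σ = 1 nt — ragged cleavage at single-stranded loops),
A→G at the wobble position at 0.97 penetrance, a mixed-spectrum
misincorporation site at mature position L−19 (inside the T-loop window),
optional planted mutations at full penetrance, a 3′ adapter appended before
truncation to a 50-nt instrument read, and uniform-random background reads.
Per-family expected counts follow depth_per_copy × copy_number ×
(1 + s·day), Poisson-sampled; s defaults to 0.11, matching the roughly
2.3-fold rise in tRNA-aligned reads per million over a 12-day adult course
observed in aged nematode libraries. Identical (config, seed) pairs give
byte-identical output. Constant quality strings are written; the pipeline
never reads qualities.

What the simulator does **not** model: sequencing errors beyond planted
edits, ligation and size-selection bias, pre-tRNA leader/trailer fragments,
and biological between-animal variation. Passing tests on synthetic data
therefore demonstrate algorithmic correctness under the assumed model, not
robustness to every artifact of real libraries.

A separate packaged dataset (`trfage.datasets.synthetic_celegans`) is a
deterministic synthetic stand-in for the *C. elegans* genomic tRNA census —
820 regions, 605 amino-acid-annotated genes (600 after pseudogene
filtering), 178 unique mature sequences over 48 anticodons and 20 amino
acids, 32 intronic regions, a 24-copy proline-TGG family with 9 homologous
pseudo regions, 25 identical lysine-CTT and 17 identical alanine-AGC copies.
Family structure and counts are exact; the sequences themselves are random
tRNA-length DNA with per-amino-acid homology structure.

## Problem sizes and numerical choices

The acceptance checks run at sizes chosen for statistical reliability on a
single CPU: 1,000 random instances for aligner-oracle equivalence, 10⁵
reads for perfect-match priority, 1,000× wobble depth for editing-rate
recovery (binomial noise ≈ ±1%), 20 families at 200× with 5% background for
fragment recovery, and 150 families at low per-copy depth with 12 replicate
libraries per age for the copy-number correlation. The replicate averaging
matters: a single library's Pearson R at adjacent ages differs by less than
its sampling noise, so the systematic rise of R with age (deeper libraries →
smaller relative Poisson noise) is only reliably monotone in the
replicate-averaged estimate. Uniform growth across families also means
library-relative abundance is flat by construction; age trends in real data
reflect differential growth against a large non-tRNA background, which the
demo does not attempt to fake.

## Known limitations

Indels are not modeled anywhere (alignment is mismatch-only, matching the
`-v`-style alignment mode the approach is built around). Reads longer than a
reference never align to it. The homology filter compares called regions
only — an enrichment absent from a homolog because it fell below the calling
threshold there cannot veto a candidate. Modification calls at sites covered
only by multi-mapped reads inherit whatever placement ambiguity remains
after perfect-match prioritization.
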