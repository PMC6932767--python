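# Methods

## Scope and model

`editprofile` analyzes targeted amplicon sequencing of edited loci. Input
reads are assumed to be merged, single-end amplicon reads already aligned to
a reference fragment (preprocessing, merging and alignment are a user-run
upstream step); the unit of analysis is the read, and the unit of reporting
is the allele — the canonical set of variants observed on one molecule.

A read is **analyzable** when the union of reference intervals covered by
its alignment records contains the configured *analysis window*, a
sub-interval of the region around the cut site(s). For a split read whose
two records flank a deletion, the deleted interval counts as covered by the
junction — otherwise no large deletion could ever be analyzable. All
denominators (allele frequencies, class proportions) are analyzable reads;
unmapped, secondary and duplicate-flagged records are excluded up front.

### Variant calling

Each record's CIGAR is walked against the reference: mismatching bases in
`M`/`=`/`X` runs become SNPs (query `N` never calls a SNP — absence of
evidence), `I` runs insertions, `D` runs deletions. Soft/hard clips emit
nothing at this stage. Indels are left-aligned (VCF convention) to the
smallest reference coordinate producing the identical molecule, with two
bounds: a shift never crosses the region start, and never crosses another
variant of the same read — sliding a junction deletion through its junction
insertion point, or through a SNP, would change the molecule the set
describes. Left alignment makes the canonical allele name a pure function
of the molecule, so identical edits reported at different aligner
placements collapse to one allele.

Allele names are region-relative and 1-based: `"<s>-<e>del"`, `"<s>ins<seq>"`,
`"<s><ref>><alt>"`, joined by `;` in positional order; the empty set is
`WT`. The naming is invertible (`parse_allele_name`).

### Chimeric split-read reassembly

Records are grouped by read name (the SA tag is not required). In a group
of two records on one chromosome and strand, each record's query interval
is derived from its clip lengths: query start = left soft+hard clip, query
end = start + aligned length. Three cases follow:

- disjoint query intervals with a gap: the uncovered query bases are the
  **junction insertion** (taken from whichever record stores them — soft
  clips retain sequence, so a hard-clipped supplementary is covered by the
  primary);
- abutting intervals: a clean junction deletion;
- overlapping intervals (**junction microhomology**): the overlap is
  assigned to the upstream record and the downstream record's first *h*
  aligned query bases are trimmed (converted to clip, its start advanced
  over the reference they consumed). Together with left alignment of the
  resulting deletion this makes the call invariant to how many homologous
  bases the aligner extended into either side.

The merged variant set is: intra-record variants from both (trimmed)
records, plus one deletion `[upstream_end+1, downstream_start−1]`, plus the
junction insertion if present — then normalized exactly like a gapped call,
which is what makes gapped and split representations of one molecule
provably equivalent (asserted over the full 5–120 bp deletion and 1–120 bp
junction-insertion grids in the acceptance tests).

Groups outside this model — three or more records, mixed strands or
chromosomes, records overlapping on the reference after trimming, a mate
outside the configured region — are not guessed at: the read is kept in the
analyzable denominator and reported as its own `ERROR` class, with an
all-not-applicable impact profile.

### Classification

With a donor template configured (either an explicit variant list or a
full-region template sequence diffed against the reference at load time):

- empty variant set → `WT`
- set == template set → `HDR` (perfect match only)
- set ⊋ template set → `HDR-NHEJ`
- anything else non-empty (including partial template matches) → `NHEJ`.

`HDR` and `HDR-NHEJ` are never merged anywhere in the outputs. When
`ignore_snp` is enabled, SNPs are stripped before naming and classification
*except* template variants, so a SNP knock-in template remains detectable.
Reporting filters (`cutoff` percent, `ignore_single`) suppress alleles from
the reported table but never change denominators or class proportions.

### Coding-impact annotation

The allele's variants are applied to the region sequence to build the
mutant molecule, with a monotone coordinate map between reference and
mutant positions; minus-strand regions are reverse-complemented (map
reflected) before any codon logic, which makes annotation strand-symmetric
by construction. Twelve three-state metrics (true / false / not-applicable)
are scored:

| flag | meaning |
|---|---|
| WT | mutant CDS identical to the reference CDS |
| FS | net indel length inside the CDS not a multiple of 3 |
| SNP | any single-base substitution present |
| ATG | start codon destroyed (deleted, interrupted, or no longer `ATG`) |
| CODING | start codon intact and translation of the mutant reaches an in-frame stop |
| STOP | stop codon destroyed |
| PSTOP | first in-frame stop strictly upstream of the original stop (evaluated on the mutant molecule, so frameshift-created stops count) |
| SM / LG | small / large indel present (threshold `small_indel_max`) |
| UTR | indel wholly outside the CDS but inside the region |
| CRYPTIC | a qualifying cryptic ORF distinct from the normal CDS exists |
| ERROR | no determination possible (unresolvable group, overlapping variants) |

plus the mutant coding-sequence length in bases, stop codon included: the
normal-start ORF when CODING, else the longest qualifying cryptic ORF, else 0.

"Net indel length inside the CDS" counts the deleted bases intersected with
the CDS span and the full length of insertions whose insertion point lies
inside the CDS — the quantity that actually determines the downstream
reading frame. Consequently `WT=true` (an identical coding sequence) forces
FS/ATG/STOP/PSTOP false, while SNP/SM/LG may still be true for UTR-only
edits; the WT flag is about the coding sequence, not the whole amplicon.

The cryptic-ORF scan walks the mutant region sequence on the coding strand
only: every `ATG` is translated to its in-frame stop inside the region, and
ORFs of at least `min_cryptic_codons` codons (stop included) are reported,
excluding the normal reading frame three ways — the ORF starting at the
surviving normal start, any ORF identical to the reference CDS, and
in-frame internal ATGs nested inside the translated primary ORF (those are
internal methionines, not cryptic starts). This reproduces the classic
two-guide knockout signature where deleting the start codon exposes a
cryptic ATG one base downstream and a truncated-but-open C-terminal frame
(`cryptic_start_analog` constructs exactly this situation and the
acceptance suite asserts the flags and the one-base offset).

### Base-edit quantification

For regions flagged `base_edit`, every analyzable read contributes its
aligned base to each window position (M runs), `del` for deleted positions
(including resolved chimeric junctions); insertions consume no reference
position. Conversion rate at a position = count(to_base) / (depth −
count(N)): `N` is removed from the denominator (no evidence), deletions are
kept (a deleted base is evidence of a non-conversion outcome, and hiding
indel reads in a base-edit experiment would overstate purity). The logo
matrix renormalizes A/C/G/T to column sums of 1, dropping zero-depth
positions with a warning, columns ordered along the coding strand. Counting
is allele-agnostic by design.

## The simulator

The bundled generator is the package's test bench and defines the
conditions the validation runs under:

- random reference fragments with a planted single-exon gene model (ATG,
  non-stop codons, terminal stop). Background coding-strand ATGs are
  scrubbed by default so the unedited fragment has no cryptic ORF and the
  CRYPTIC flag reflects only what an edit creates;
- event grids mirroring the validation designs: one deletion of every size
  5–120 bp centered on the cut site (50 reads each), and a 120-bp deletion
  with 1–120 uniformly drawn scrambled bases inserted at the junction;
- class mixtures with *exact* per-class counts (largest-remainder rounding,
  not multinomial draws), default 60/25/10/5 percent WT/NHEJ/HDR/HDR-NHEJ,
  so recovery can be asserted exactly;
- NHEJ outcomes drawn from a configurable menu of small indels (1–10 bp
  deletions, 1–6 bp insertions), large deletions (30–120 bp, optionally
  with junction insertions) and SNPs near the cut site;
- base-edit mode: independent per-position conversion draws at stated
  probabilities (validation uses 0.50 on-target and 0.05 at two bystander
  positions, 2000 reads — recovery asserted within three binomial standard
  errors);
- alignment emission in two modes: one gapped record per read with the
  exact M/I/D CIGAR, or the split representation (primary + 0x800
  supplementary with complementary soft or hard clips) for reads whose
  deletion reaches `split_threshold` (default 30 bp, roughly where real
  aligners stop producing gapped records; configurable so equivalence can
  be swept).

Simulated reads span the whole region, carry no sequencing errors by
default (an optional uniform substitution rate exists), no quality
structure, no PCR duplicates, and the split representation is always the
ideal two-record form. Passing tests therefore demonstrate the *algorithm*
— reassembly, naming, classification, annotation, counting — not robustness
to noisy alignments, ambiguous mappings or aligner idiosyncrasies beyond
clip conventions.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `cutoff` | 0 | % of analyzable reads | report everything unless asked |
| `ignore_snp` | false | — | strip background SNPs/noise from allele naming |
| `ignore_single` | false | — | suppress singleton alleles from reports |
| `small_indel_max` | 25 | bp | SM/LG boundary; well below typical two-guide distances |
| `min_cryptic_codons` | 25 | codons | below ~25 codons a spurious ORF is likely noise |
| `min_mapq` | 0 | — | no MAPQ filter by default; amplicon mappings are unambiguous |
| `keep_duplicates` | false | — | duplicate-flagged records excluded; flag to keep |
| `split_threshold` (simulator) | 30 | bp | deletion size emitted as split pair |

Problem sizes in the test and acceptance runs (116 deletion sizes and 120
insertion sizes at 50 reads each, 1000-read mixtures, 2000-read base-edit
samples) are the validation designs themselves; the full pipeline runs in
seconds at these sizes on one core.

## Numerical and policy choices

- Coordinates: 1-based inclusive in every file and report; 0-based
  half-open internally; conversion only at I/O boundaries. Gene-table rows
  written high-to-low (common for minus-strand loci) are normalized on load.
- Minus-strand regions are stored on forward coordinates; strand is
  consulted only for translation and display.
- Ties and ordering: alleles sort by descending count then name; segments
  by (read name, supplementary flag, position); batch cells by (sample,
  gene) — output is byte-stable under any worker count because cells are
  pure functions gathered in sorted order.
- Adjacent `D` and `I` at one locus remain separate DEL and INS variants
  (no `delins` collapsing); the junction insertion is placed at the
  upstream segment's last base, matching the I-before-D gapped convention.
- Degenerate inputs: zero analyzable reads yields an empty summary (error
  at the summarize level, empty tables at the batch level); zero-depth logo
  columns are dropped with a warning; a reads-past-reference alignment is a
  bounds error that marks the read ERROR rather than silently truncating.
- ERROR reads stay in the analyzable denominator as their own class and
  pseudo-allele, so allele counts always sum to analyzable reads.

## Limitations

Single-exon gene models only (no GFF/GTF, no splicing); no inversions,
duplications, translocations or ≥3-record chimeras (reported as ERROR, not
guessed); no quality-weighted calling, diploid genotyping or phasing; no
statistical testing of editing versus control samples; FASTQ emission
exists for optional end-to-end runs through an external aligner but the
pipeline's contract is pre-aligned BAM.
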