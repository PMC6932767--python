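# editprofile

Batch profiling of genome-editing outcomes from targeted amplicon
sequencing. Given a reference fragment, per-sample alignments (BAM) and a
table of edited loci, `editprofile` calls the variants carried by every
read, reassembles chimeric split reads caused by large deletions, classifies
reads as WT / NHEJ / HDR / HDR-NHEJ, annotates the likely coding consequence
of each allele (frameshifts, start/stop codon loss, premature stops, cryptic
open reading frames), and quantifies base-editor efficiency per position.

## Why allele-level profiling

Designer nucleases (CRISPR/Cas9, TALENs, ZFNs) create double-strand breaks
that are repaired by error-prone non-homologous end joining (NHEJ) or by
template-guided homology-directed repair (HDR). Aggregated "percent edited"
summaries are enough to rank guides, but genotype–phenotype work on edited
cell lines and embryos needs the *alleles*: an in-frame deletion or a
truncated-but-functional protein is a very different outcome from a null.
Two situations are handled that trip up simpler pipelines:

- **Large deletions between two guides.** When the deleted span exceeds what
  the aligner will represent as a gapped alignment, the read comes back as a
  *chimeric/split* pair — a primary record mapping one side with the rest
  clipped (soft `S` or hard `H`), plus a supplementary record (flag 0x800)
  mapping the clipped part. `editprofile` groups records by read name, does
  clip-length arithmetic on the query, and reassembles the pair into a
  single junction event: one deletion, plus any scrambled bases inserted at
  the junction (query bases covered by neither record). Junction
  microhomology is trimmed and the event left-aligned, so split and gapped
  representations of the same molecule yield the identical allele.
- **HDR vs. HDR+NHEJ.** HDR is counted only for reads whose variant set
  *perfectly* matches the donor-template edit; template-plus-extra-variants
  reads are reported separately as HDR-NHEJ, and everything else non-WT is
  NHEJ. Tools that fold HDR-NHEJ into HDR overstate the usable knock-in
  rate.

For base-editor experiments, efficiency is quantified per reference
position (conversion of individual bases) rather than per allele, because
bystander positions near the on-target base may be edited independently;
outputs include a per-position count matrix, conversion rates, and a
sequence-logo position-frequency matrix.

Variant calling itself walks the alignment CIGAR: `M` runs are compared
base-by-base for SNPs, `I`/`D` runs become insertions/deletions, indels in
repeat context are left-aligned, and each read's canonical, sorted variant
set is the allele (named e.g. `2-183del`, `7G>A;12insTT`, or `WT`).

## Worked example

The bundled simulator writes a complete synthetic experiment — reference,
gene table, truth table, and an indexed BAM in which every large deletion is
emitted as a split primary/supplementary pair:

```
$ editprofile simulate --out demo --seed 7 --n-reads 500
wrote fixture set under demo (500 reads)
$ editprofile profile --config demo/config.json
sim x gene1: 500 analyzable reads, 74 alleles
```

`demo/files/output/sim/gene1.classes.csv` then holds the class summary:

```
class,count,proportion
WT,375,0.75
NHEJ,125,0.25
HDR,0,0.0
HDR-NHEJ,0,0.0
ERROR,0,0.0
```

i.e. 500 analyzable reads of which 75% are unedited and 25% carry NHEJ
repair outcomes (the simulated mixture). The allele table pairs each allele
with its coding-impact profile; the first rows:

```
allele,count,frequency,class,...,FS,...,SM,...,cds_length
WT,375,0.75,WT,...,FALSE,...,FALSE,...,300
246-254del,9,0.018,NHEJ,...,FALSE,...,TRUE,...,291
246-253del,7,0.014,NHEJ,...,TRUE,...,TRUE,...,198
```

Read: the 9-bp deletion `246-254del` is in-frame (FS false, 291-bp mutant
CDS), while the 8-bp `246-253del` shifts the frame and truncates the coding
sequence to 198 bp at a premature stop. `editprofile plot` renders the
allele alignment, the allele × metric impact grid, and base-edit sequence
logos, each with its underlying CSV.

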