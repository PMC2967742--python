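# Methods

## Problem setting and model

`l1scout` detects germline insertions of the full-length LINE-1 (L1)
retrotransposon that are present in an individual but absent from the
reference genome, using only short single-end reads. The method rests on a
single structural fact: the active human L1 lineage carries a conserved
14-mer, `GGGGAGGAGCCAAG`, at the extreme 5' end of its 5' UTR. Because no
element sequence lies 5' of it, a read containing the 14-mer necessarily
spans the 5' insertion junction; everything 5' of the 14-mer within such a
read is genomic flank. This converts junction discovery into an exact
substring search plus a flank-placement problem — tractable even at 48-nt
read length, where alignment-based mobile-element detection is unreliable.

Deliberate consequences of anchoring on the 5'-most 14-mer:

* only **full-length** (promoter-retaining, potentially active) insertions
  are discoverable; 5'-truncated copies — the majority of genomic L1s — are
  invisible to the search and out of scope;
* an element whose first 14 bases deviate by even one substitution is
  missed; exactness buys specificity at a known sensitivity cost;
* element **deletions** relative to the reference are not considered.

## Discovery

1. Every read is scanned for exact occurrences of the signature and its
   reverse complement; overlapping occurrences are all recorded. A read
   with multiple hits contributes its leftmost plus-strand hit, else its
   rightmost minus-strand hit (a 48-nt read cannot support two junctions).
2. The flank (read sequence 5' of the element, oriented so its 3' end abuts
   the element's 5' end) must be at least `min_flank` = 25 bp, otherwise the
   read is discarded as unplaceable.
3. Placement uses an exact k-mer index of the reference (seed = the flank's
   junction-proximal 22-mer; 22 mirrors the word size of the original
   external-aligner workflow) extended to a full-flank comparison with
   `max_placement_mismatches` (default 0) tolerated mismatches, both
   strands. Exactly one placement → accepted; zero → unplaced; more than
   one → discarded as non-unique. "Unique in the genome" is thus
   operationalized as uniqueness under this mapper at the configured
   tolerance.
4. Coordinate convention (fixed here because published tables rarely state
   one): the **site position is the 1-based reference base immediately 5'
   of the insert on the plus strand**. A plus-placed flank ending at p
   gives (p, `+`); a minus-placed flank starting at q gives (q − 1, `-`),
   the element pointing toward decreasing coordinates. With error-free
   reads every recovered site is exact to the base; tests tolerate no
   off-by-one.
5. Junctions whose reference continuation is itself the signature are
   elements already present in the reference and are excluded; reads
   supporting the same (contig, position, orientation) merge into one site.

## Genotyping and trio analysis

For each site and sample, reads are re-examined against the junction:

* **insertion evidence** — the read contains the junction-proximal 25 bp of
  the site flank (either strand) and continues into the element: the
  continuation must match a prefix of the signature over at least 7 bases
  (the marker `GGGGAGG`). Anchoring on the junction-proximal 25-mer rather
  than the full stored flank (up to 34 nt) keeps the required read span at
  32 nt, preserving sensitivity in 48-nt reads;
* **reference evidence** — the continuation instead matches the reference
  (≥ 7 bases, ≤ 1 mismatch);
* **poly-A evidence** — at the *opposite* junction, a read anchored by
  ≥ 12 reference bases whose insert-side segment is a run of ≥ 10 bases
  that are A up to ≤ 1 exception (T-run on the plus strand for
  minus-orientation elements) **and** that disagrees with the aligned
  reference at ≥ 50% of the run's positions. The inconsistency clause stops
  genomic A-tracts from counting as tails. The thresholds (10/1/50%) are
  this package's choices: long enough to be rare by chance in a 48-nt read,
  lenient enough for one sequencing error.

Calls: `+/-` if both insertion and reference reads are seen; `Y` if only
insertion reads; `N` if only reference reads; `?/?` if neither. `N` means
"no insertion evidence among junction-spanning reads", not a validated
homozygous-reference genotype, and `Y` means "present, possibly homozygous";
the report therefore always carries the raw tallies
(`n_signature, n_polyA, n_reference`) per sample so users can judge. A
`min_reads` bar (default 1, matching shallow pilot-style coverage) flags
rather than withholds low-evidence calls.

Trio verdicts: a child-positive site is *inherited* if a parent shows any
insertion evidence, a *de-novo candidate* only if **both** parents are `N`
(positive evidence of absence); a `?/?` parent leaves the site *unresolved*
— absence of reads is never promoted to absence of the allele. The poly-A
rule is a per-sample switch, default all samples; `--paper-mode` restricts
it to the parents, reproducing the original asymmetric usage. A targeted
rescue search (10–15 bp of unique flank + the first 7 element bases)
recovers sub-threshold junction reads at apparent de-novo loci.

## Annotation, set comparison, in-silico PCR

Gene context uses the single junction coordinate as a point: intragenic iff
it falls within a gene span (1-based inclusive; BED6 input converted at the
boundary); when several genes overlap, all are reported and the first by
start is primary; sense iff element orientation equals gene strand.
`compare_site_sets` partitions a call set against an independent list by
(contig, position). `insilico_pcr` places primers by exact match and
returns all product lengths ≤ 5 kb; printed product sizes from the original
wet-lab validation are *not* recomputed, since that would require the exact
reference build and element allele, both external.

## The synthetic trio generator

The generator emulates the study conditions the method targets, not a
sequencing platform:

| parameter | default | rationale |
|---|---|---|
| `genome_len`, `n_contigs` | 100 kb, 2 | large enough that 25-bp flanks and 22-mer seeds are effectively unique; small enough for seconds-scale runs |
| `gc` | 0.41 | human-like base composition |
| `n_sites` | 20 | same order as the published call set (22) |
| `cassette_len` | 6000 | full-length L1 is ~6 kb |
| `polyA_len` | 30 | typical young-insertion tail scale |
| `tsd_len` | 0 | keeps positional checks exact; > 0 shifts the observable `-` junction and truth records both coordinates |
| `read_len` | 48 | the short-read regime the method was designed for |
| `coverage` | 30 | diploid depth; reads per sample = coverage × haplotype-pair length / (2 × read length) |
| `error_rate` | 0 | substitutions optional; detection is exact-match |
| `de_novo_fraction` | 0 | germline-only by default |

The cassette is a **synthetic stand-in** for a real L1 consensus: the
signature, a random body resampled until the signature occurs exactly once
on either strand, the reverse complement of the element-internal validation
oligo embedded at offset 300, and a poly-A tail. A real L1 FASTA may be
substituted. The reference is random sequence rejected-sampled to be
signature-free.

Parental genotypes per site are drawn het 0.5 / hom 0.25 / absent 0.25 and
transmitted Mendelianly; non-de-novo sites are redrawn until the child
carries at least one allele, because sites are ascertained through the
child exactly as in a proband-first study design (this makes the truth set
fully discoverable from child reads and yields a child homozygote fraction
of ~1/3, matching the published call set's 8 of 22). Everything is a pure
function of the config including the seed: identical configs give
byte-identical FASTA/FASTQ/truth files.

What the simulator does **not** model — hence what passing tests do not
show about real data: sequence divergence within the signature, 5'-truncated
and inverted insertions, paired ends, indel or quality-structured errors,
repetitive reference context (real genomes have far more non-unique flanks),
and GC or mappability coverage biases.

## Numerical and degenerate-case choices

* Alphabet `{A,C,G,T,N}`; anything else is an error, never silently
  N-masked (masking would hide simulator bugs). Lowercase is uppercased on
  read.
* Coordinates are 1-based inclusive everywhere internally; BED converts at
  the I/O boundary.
* Qualities are parsed (Sanger +33) but never used by detection; an
  optional mean-quality read filter exists and is off by default.
* A minus-placed flank starting at contig position 1 leaves no junction
  base and is dropped; contigs shorter than the seed contribute nothing to
  the index.
* Ties in primary-gene selection break by (start, end, name).
* Site identity is the triple (contig, position, orientation); merging
  keeps the longest observed flank for reporting.

## Expected performance and known limitations

At the default conditions, a heterozygous junction expects
10 × coverage/(2 × read_len) ≈ 3.1 reads carrying both a ≥ 25-bp flank and
the full 14-mer, so single-site recovery is Poisson-limited (~4–8% of
heterozygous sites draw zero qualifying reads per run); genome-wide
recovery on the default 20-site trio is typically 85–100% with zero false
positives, and genotype concordance on recovered sites is ≈ 100%. Raising
coverage or read length moves recovery to ~100%. The problem sizes used
throughout the test suite (20 kb–100 kb genomes, 6–20 sites, 30–60×) were
chosen to make each run a few seconds to ~half a minute on one core while
keeping per-site read support in the realistic shallow-coverage regime.

The genotyper's tail-junction anchoring assumes `tsd_len` = 0; with a
nonzero target-site duplication the poly-A anchor would sit `tsd_len` bases
away from the assumed junction, so poly-A sensitivity degrades (signature
and reference evidence are unaffected). Family assignment of detected
elements, truncated-insert discovery, and statistical genotype likelihoods
are out of scope.
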