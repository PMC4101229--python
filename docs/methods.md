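# Methods

`captureseq` reimplements, as a tested and reusable pipeline, the analysis
used to characterise an unsequenced genome by hybridisation capture of
regions matching an EST/transcript catalogue: probes are designed on
expressed-sequence contigs, captured genomic fragments are sequenced as
medium-length single-end reads, and the read set is quality-filtered,
mapped, de novo assembled, and mined for gene structure (introns) and
single-nucleotide variation, with RNA-seq used as orthogonal evidence.
Because the organism of interest has no reference genome, every stage is
validated on synthetic data with machine-readable truth.

## Probe design

Transcript contigs strictly longer than 750 bp are selected as capture
targets; short sequences of special interest (for example antimicrobial
peptide transcripts) can be forced in by id and are flagged. 120-mer probes
are tiled from the 5' end every 60 bp, which gives every interior position
(at least one probe length from each end) exactly 2x probe coverage. When
the last regular start does not land on `length - 120`, one terminal probe
anchored at the 3' end is appended so the probe union covers the whole
contig; published probe counts for this kind of design are not derivable
from the tiling arithmetic alone, so full-coverage tiling is adopted as the
defensible reading of "2x coverage". Probes containing an N are emitted but
flagged, letting users exclude them without changing counts.

## Read quality control

The filter chain is fixed and logged: adapter trimming, then mean-quality,
then length, then N-count, then exact-duplicate removal, then
microsatellite-repeat exclusion.

- Adapter trimming removes the longest read 3'-suffix matching an adapter
  prefix over at least 8 bases with at most 10% mismatches.
- The quality rule "above Q20" is interpreted as the arithmetic mean Phred
  score strictly above 20; a minimum-per-base reading would discard nearly
  every read with a low-quality tail. The alternative is exposed as
  `quality_mode="min"`.
- Length must be strictly greater than 50 nt and at most one N is allowed
  ("fewer than 2 Ns").
- Duplicates are exact full-sequence copies, collapsed to the first
  occurrence; clonality is reported as `(n_input - n_unique)/n_input`.
  Deduplication happens before mapping (where in the original workflow it
  happened is not documented; doing it first makes every downstream count
  duplicate-free).
- The repeat filter removes reads whose best alignment to the repeat
  library is *accepted* under the same mapping thresholds as target
  mapping, so only reads that are mostly repeat are excluded.

## Read mapping

The mapper is a transparent stand-in for a proprietary workbench mapper:
the published acceptance parameters, not the engine, define on-target
status. Scoring is match +1, mismatch -2, gap -3 per base (equivalently
mismatch/insertion/deletion costs 2/3/3 against a unit match), and an
alignment is accepted iff at least 50% of the read aligns (length fraction)
and at least 80% of the aligned read bases match (similarity). Candidate
loci are nominated by shared k-mers (default k = 13) on both strands,
clustered by diagonal; each cluster's window is aligned by a numba-compiled
Smith-Waterman with deterministic tie-breaks (first best cell in row-major
order; diagonal preferred over gaps in traceback). Among accepted
candidates the highest-scoring wins; ties break by reference id then
leftmost start, and reads with several distinct best placements are flagged
ambiguous (counted once toward the tie-broken assignment by default,
droppable via `ambiguous="drop"`).

Seeding is a speed heuristic: a borderline-acceptable alignment whose
longest exact match is shorter than k is invisible to it. `map_read`
therefore falls back to a full scan of every reference for a strand with no
seed hits, and offers `exhaustive=True`, which aligns against every
reference in full and makes the accept/reject decision exact. The oracle
test compares the exhaustive decision against an independent Biopython
`PairwiseAligner` under the same scoring; instances where co-optimal
alignments disagree about the thresholds are excluded, because there the
decision is a property of the traceback tie-break rather than of the rule.

Capture efficiency is the percentage of high-quality reads with an accepted
alignment to a selected target; per-target mean depth is aligned read bases
divided by target length, and the coverage-class histogram bins
(0, (0,1], (1,5], (5,10], (10,50], >50) are configuration defaults.

qPCR enrichment folds are computed per matched dilution as
`E**(mean Ct_raw - mean Ct_enriched)` with amplification efficiency E = 2,
geometric-mean-aggregated across dilutions, and additionally reported in a
signed convention (-1/fold for depletion) so that, e.g., an 867-fold
depletion prints as -867.

## De novo assembly

A greedy overlap-layout-consensus assembler repeatedly merges the pair of
sequences with the longest suffix-prefix overlap of at least 40 bp at 95%
identity or better, both strands considered, ties broken by higher identity
then lexicographic id. Candidate overlaps are nominated by shared k-mers
and verified by direct (mismatch-only) comparison on the implied diagonal;
containments are absorbed. Consensus is per-column majority over base
counts (ties resolved in fixed A<C<G<T order); contig orientation is set by
the first merge. Contigs shorter than 200 bp are discarded — the minimum
adopted from the observed contig range of the study this emulates — and
unmerged reads are reported separately as singletons. N50/N75 use the
cumulative-length definition (length of the contig at which the
longest-first cumulative sum first reaches 50%/75% of the total).

## Gene structure from RNA-seq back-mapping

RNA-seq reads are mapped onto genomic contigs with the same mapper. Since
RNA-seq reads derive from spliced transcripts, introns receive no coverage:
internal zero-depth runs of at least `min_gap` = 100 bp become intron
segments (100 bp matching the smallest intron observed in the motivating
study; the threshold is configuration-exposed), zero-depth runs touching a
contig end become unresolved flanks (never introns), and sub-threshold gaps
are absorbed into exons. Segments always partition the contig.

Contigs whose uncovered span is at least 250 bp are intron candidates.
Each candidate is locally aligned to every transcript target by iterative
masked Smith-Waterman: the best local alignment is recorded as an HSP, its
contig span is masked, and the process repeats, so each contig locus
contributes exactly one HSP ("one high-scoring segment pair" per locus);
both contig orientations are tried and the better one kept. A pair of
query-adjacent HSPs to the same transcript whose transcript intervals are
adjacent within a 10 bp tolerance (absorbing alignment-end fraying)
brackets a fully sequenced intron; the call is complete because both
flanking exons are present in the same contig. Splice motifs (GT..AG) are
annotated but never used as a filter.

## SNP calling and concordance

Pileups are built from accepted alignments after collapsing reads with an
identical mapping locus (reference, start, strand, aligned read length) —
a guard against PCR amplification artefacts. Deletions contribute nothing
and inserted read bases are skipped. A biallelic call is emitted iff depth
is at least 10 and the most frequent non-reference base reaches at least
35% of the locally aligned reads, both boundaries inclusive; columns where
a second alternate also clears the threshold are flagged multiallelic but
still report only the top alternate. Transitions are A<->G and C<->T;
everything else is a transversion, and transitions + transversions always
equals the number of calls. SNP frequency is reported as
`100 * n_snps / total contig bp` with the denominator printed alongside
(the original figure's denominator is not derivable from its printed
totals). Genomic and transcriptomic call sets are intersected on exact
(contig, position, alternate) equality when both are in contig
coordinates; calls made in transcript coordinates are first lifted through
HSP alignment columns, with unmappable positions excluded and counted.

## Synthetic data: what it emulates and what it does not

The generator builds one gene per contig (intergenic flanks of 300-800 bp,
1-4 exons of 150-400 bp separated by introns of 150-600 bp), plants
heterozygous SNPs at a default rate of 0.7% per bp — the variation
frequency scale reported for the highly polymorphic bivalve genome this
emulates — each on exactly one haplotype, and inserts tandem 2-6 bp
microsatellite tracts into intergenic flanks as a repeat library. Capture
reads are single-end, normal-length (mean 250 bp, sd 50), drawn from both
haplotypes with equal probability; reads overlapping probe-covered
(exonic) intervals are sampled at the on-target depth and elsewhere at the
off-target depth, with substitution errors (default 0.5%), a 36% clonal
duplicate fraction (exact copies of earlier reads), and a full library
adapter appended to 20% of reads. Qualities are a constant Q30 with error
positions assigned random Q in [2, 15], so the Q20 filter exercises both
branches. RNA-seq reads are 75 bp, exon-only, drawn uniformly from
transcripts at the requested depth.

Not emulated: flowgram-style homopolymer error structure, paired-end or
strand-specific protocols, population-level variation (one diploid
individual), gene families and paralogy, and realistic coverage biases
(GC, mappability). Passing recovery tests therefore demonstrates the
correctness of the threshold logic and of the truth-recovery machinery
under clean conditions, not performance on real 454/Illumina data.

## Problem sizes and numerical choices in the validation suite

The recovery studies run on an 8-gene genome (~20 kb). For SNP recovery,
reads are mapped to the known genomic contigs so that truth coordinates
compare directly; de novo assembly fidelity is validated separately (an
error-free 2 kb region tiled at 15x is reconstructed to within one read
length of its ends, and contig reads realign at >= 95% identity). The
capture depth of the SNP study is chosen from the binomial structure of a
heterozygous pileup: the alternate count at depth d is Binomial(d, 1/2),
so the 35% threshold misses a site with probability ~Phi(-0.3 sqrt(d));
an effective post-deduplication exonic depth around 60x keeps that below
1% per site, which a 0.95 recall bound requires. Duplicate removal (36%)
and partial read/exon overlap dilute nominal on-target depth by a factor
of roughly `0.64 * L_exon / (L_exon + L_read)`, hence a nominal on-target
depth of 250x in that study. Intron recovery uses error-free RNA-seq at
25x, the regime in which the coverage-gap signal is unambiguous.

## Known limitations

- The greedy assembler is quadratic in the worst case and intended for the
  tens-of-kilobase validation scale, not for hundreds of thousands of
  reads.
- The mapper reports no mapping quality; ambiguity is a binary flag.
- Indels are not called; multi-allelic sites report only the top
  alternate.
- The intron caller requires both flanking exons in one contig; partial
  (flank-truncated) introns are visible only as unresolved coverage gaps.
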