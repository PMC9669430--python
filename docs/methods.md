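# Methods notes

This note records the models, parameter choices and numerical conventions
behind lncflow, and what the synthetic benchmark does and does not
demonstrate.

## Coordinate and matching conventions

All genomic coordinates are 1-based closed intervals (GTF convention),
everywhere, including internally; a single convention avoids off-by-one
drift between filtering, classification and cis-distance logic. The gap
between two intervals is the number of bases strictly between them (zero
when they overlap or touch), so "distance < 100 kb" means a gap of at most
99,999 bp.

"Known mRNA" removal uses exact structure matching: identical intron chain
on the same chromosome and strand for multi-exon transcripts, exact exon
interval for single-exon ones. Exact matching is conservative (a candidate
differing by a single splice boundary is kept) and, unlike fuzzy overlap
rules, has an unambiguous truth value in tests. The length filter applies
to the spliced length with a strict `< 200` comparison, so a 200-nt
transcript survives.

## Coding potential

Trained coding-potential classifiers (CPC's SVM, CNCI's codon usage
model) are deliberately replaced by a transparent composite of two classic
features:

- **Longest ORF** — the longest ATG…stop reading frame on the sense
  strand, stop codon included, ties resolved to the smallest start.
- **Fickett TESTCODE** — the published position-asymmetry and composition
  lookup tables with their weights; scores are higher for coding-like
  sequence, with the classic interpretation ≥ 0.95 coding and ≤ 0.74
  noncoding.

A transcript is *coding* iff ORF ≥ 300 nt (the canonical ORF-length
heuristic for lncRNA definition) **or** Fickett ≥ 0.95 with ORF coverage
≥ 0.5 (captures short transcripts that are mostly reading frame). All
three thresholds are configuration parameters. This composite is a
stand-in with the same intent as the trained tools, not a reconstruction
of them; on data where coding potential is ambiguous (short ORFs with
coding-like composition) it will disagree with them.

Positional classification is total and exclusive by a fixed precedence
(exonic sense overlap ≻ antisense ≻ intronic ≻ intergenic), since a
transcript can satisfy several definitions at once and only aggregate
class counts are reported downstream. Promoter- or UTR-associated
subclasses are not emitted; they would require TSS/UTR annotation finer
than the pipeline's inputs.

## Expression and differential testing

FPKM uses the column sums of the provided count matrix as the per-sample
totals, keeping the computation self-contained and reproducible; the
conservation identity Σᵢ FPKMᵢⱼ·Lᵢ·Nⱼ/10⁹ = Nⱼ is enforced in tests to
1e-12 relative tolerance. Sample correlation and the t statistics operate
on log₂(FPKM+1); the pseudocount of 1 bounds log fold changes for
zero-count features and is applied on the FPKM scale.

The default test is a **pooled-variance two-sample t** on log₂(FPKM+1).
With three replicates per group the Welch–Satterthwaite correction is
markedly conservative (empirical size ≈ 0.034 at nominal 0.05 in the null
simulations below), whereas the pooled t is nearly exact for the balanced
design with similar group dispersions this pipeline targets (empirical
size ≈ 0.049). Welch (`welch_logfpkm`) remains available for unbalanced
designs, and a negative-binomial Wald test with per-feature moment
dispersion (`nb_wald`) supports single-replicate groups, at the cost of
poorer small-sample calibration. FDR control is Benjamini–Hochberg
step-up; calls require both q < 0.05 and |FC| ≥ 2 by default, mirroring
field convention.

A pilot of the calling pipeline at planted log₂FC = 2, base means in
[200, 1000], dispersion 0.05 and 3 vs 3 replicates measured recovery of
planted features at 0.87–0.92 across seeds; the repository's recovery
floor was frozen at 0.85 from that pilot.

## Integration

Cis-target prediction is strand-agnostic and window-based: a coding gene
is a candidate cis target when its span overlaps the lncRNA's or lies
within a strict < 100 kb gap. Overlap always qualifies, regardless of the
window parameter. Homology to miRNA precursors uses Smith–Waterman local
alignment at the nucleotide level (match +2, mismatch −1, linear gap −2);
identity is matches over alignment columns and coverage is the aligned
fraction of the precursor, with 0.9/0.9 default cut-offs. Ties on the
optimal score resolve to the lowest end coordinates and the traceback
prefers substitutions over gaps, making hits deterministic. Network edges
connect a DEL to a DEM whenever the DEM's gene is a cis target of the
DEL; concordance compares call signs only, not magnitudes.

## Enrichment

Over-representation only (upper-tail hypergeometric), against the
*expressed* background — every feature that entered differential testing
— rather than the whole genome; the background is switchable. Terms that
are empty after intersection with the background are skipped and noted.
BH correction runs across the tested terms; top-k selection sorts by
p-value with term-id tie-breaks for determinism.

## The synthetic benchmark

The generator emulates the target study shape: two groups of three
replicates, a three-chromosome genome (600 kb each) with 300 coding genes
(three 300-bp exons, 500-bp introns), six lncRNAs of each positional
class, six sub-200-nt fragments, six coding contaminants with planted
630-nt ORFs, four cis pairs at exact gaps (5 kb, 20 kb, 50 kb, 99,999 bp)
with forced differential expression (three concordant, one discordant),
and nine 80-nt precursors embedded verbatim in designated lncRNAs.

Counts are negative binomial with variance m + αm² (dispersion α = 0.02
by default, appropriate for near-isogenic biological replicates), feature
base means lognormal around 300 (mRNA) and 30 (lncRNA) — a 10× gap so the
mRNA-vs-lncRNA expression contrast is reproduced — and planted fold
changes of 2³ on 5% of features. Force-planted features (cis pairs,
precursor hosts) are anchored at base mean ≥ 500 so their recovery at
n = 3 is essentially deterministic. The planted DE mass is kept small
relative to the 300-gene background on purpose: FPKM normalises by total
counts, so a simulation in which planted effects dominate the library
induces compositional fold-change shifts in every other feature — a real
property of FPKM-based analysis that the defaults avoid rather than
model. The paper-scale configuration (tens of thousands of transcripts,
real read depths) is emulated at this reduced size as the package's own
choice of benchmark scale.

Construction guarantees replace probabilistic arguments wherever a test
needs exactness: planted lncRNA sequences contain no ATG (longest ORF 0),
contaminant ORFs are built from A/C-only codons (no internal stop or
spurious start anywhere), and precursor junctions are padded with `CC` so
no reading frame can cross into an embedded copy while the copy stays
verbatim. Minus-strand transcripts are written into the genome as reverse
complements, and designed sequences are written after the random
background so re-extraction from the emitted FASTA reproduces them
exactly.

What passing tests show: the algorithms implement their definitions
(validated against brute-force oracles), boundary rules are exact, the
statistics are calibrated under the simulator's null, and planted signals
are recovered. What they do not show: performance on real assemblies with
isoform complexity, fragmented transcripts, ambiguous bases, trained
coding-potential model behaviour, or realistic miRNA-precursor divergence
— the simulator plants verbatim embeddings, so the precursor scan's
sensitivity to diverged homologs is untested.

## Degenerate inputs and numerical details

Zero-total samples make FPKM undefined and raise an error naming the
sample. Zero-variance samples yield missing (NaN) correlations, with the
diagonal pinned at 1. Features that are constant in both groups get
p = 1 (equal means) or 0 (different means) instead of NaN from the t
statistic. The BH implementation is the step-up definition via a reverse
cumulative minimum; q-values are capped at 1. Hypergeometric p-values
come from the exact survival function, never a normal approximation. All
randomness flows from a single integer seed fanned out to fixed
per-purpose streams (genome/assembly design, counts, gene sets), so any
stage is reproducible in isolation and the CLI's `--seed` determines
every output byte.
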