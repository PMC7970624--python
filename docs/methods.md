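# Methods

## Disruption construct design

**Guide enumeration and selection.** Every NGG-adjacent 20-mer on both
strands of a target CDS is a candidate. Hard filters — GC ≤ 0.50 and maximum
homopolymer run ≤ 3 — are never relaxed: high-GC guides and homopolymer runs
degrade both Cas9 activity and synthesis fidelity. Position in the CDS is a
*preference*: guides cutting in the first quarter are preferred (a short
truncated peptide minimises residual function and post-translational
interference), with documented fallback tiers to the first half, then the
whole CDS; the tier used is recorded per gene. Within a tier the comparator
is: greatest off-target distance, then earliest cut site, then
lexicographically smallest protospacer — a total order, so design is a pure
function of its inputs and repeated runs are byte-identical. "Nucleotide
repeat" is read as homopolymer run (the stricter and more common reading;
di-/tri-nucleotide motif repeats are not filtered). The off-target criterion
is the minimum Hamming distance from the protospacer to every *other*
PAM-adjacent 20-mer in the supplied genome, computed by exhaustive scan
(vectorised; practical to tens of megabases). One exact genomic occurrence is
treated as the guide's own locus; a second exact occurrence scores distance
0. Without a genome the criterion is skipped and flagged unknown. Windows
overlapping ambiguous bases (N) are disqualified — there is no defensible
design over unknown sequence.

**Frameshift donor.** The 165 bp donor is `71 nt left arm + 22 nt
replacement + 72 nt right arm` (165 − 22 = 143 is odd; the extra base goes
downstream by convention), centred on the 23 nt protospacer+PAM span. The
replacement is constructed deterministically: delete the protospacer base
immediately 5′ of the PAM (the 1 bp frameshift), keep the PAM's N, flip the
PAM's GG to CC (no NGG, so no re-cut), and — if the shifted frame does not
already terminate early — rewrite up to four seed bases (protospacer
positions 16–19) minimally, preferring TAA, then TAG, then TGA stops and
then lexicographic order among equally small rewrites. A design is accepted
only if the first stop codon of the edited frame falls within the
replacement or ≤ 10 codons downstream of it **and** before 50 % of the
original protein length, and if the edited locus contains no ≤ 2-mismatch
match to the protospacer next to an intact NGG on either strand. Each donor
is validated through the in-silico HDR routine before being emitted; genes
whose best guide cannot yield a compliant donor fall through to the next
ranked guide, and genes with no workable guide are reported undesignable
with the failing criteria.

**In-silico HDR** splices the donor into a locus by locating each homology
arm exactly once (ambiguous or missing arms are errors) and replacing the
intervening span, reporting the net length change, the first stop of the
edited frame, and re-cuttability. The deletion donor (two 75 nt flanks
immediately outside the ORF, 150 bp total) uses the same machinery with an
empty replacement, so "applying the donor removes the ORF exactly" is a
checkable post-condition.

**Fragment assembly.** Core = guide (20) + scaffold (79) + SUP4 terminator
(36) + donor (165) = 300 nt, wrapped in 43 nt of synthesis adaptors. The
79 nt scaffold is the canonical chimeric tracr scaffold plus a 3 nt linker;
the terminator and adaptor sequences are package defaults (the adaptors are
synthetic placeholders), all overridable via `DesignRules`/YAML — only the
length arithmetic is load-bearing, and it is enforced with explicit error
messages. The core re-parses unambiguously into its four parts because the
constant parts are verified on parse.

## Synthetic screen model

The generator emulates the *data shape* of a sorted-pool screen, not its
biology. Member abundance is log-normal (σ = 1.5 by default, matching the
orders-of-magnitude read-count skew reported for real disruption libraries)
and drawn **once** per library: the plasmid pool is a fixed physical object,
so all samples share the same composition expectation. Sorted conditions
multiply spiked members by their fold-change and renormalise. Each replicate
applies independent log-normal jitter (σ = 0.2, biological replicate
variability of separate cultures/PCRs) before multinomial read sampling.
Setting both sigmas to 0 degenerates to uniform, noiseless sampling — useful
in tests. Reads are `barcode + amplicon` with i.i.d. per-base errors
(defaults 5 % substitution, 3 % insertion, 3 % deletion, long-read-like),
reverse-complemented with probability ½; qualities are constant
placeholders. Not modelled: homopolymer-length error bias, read truncation,
chimeras, quality-score realism. Consequently, passing tests demonstrate the
pipeline's correctness and error-tolerance under a well-specified error
model, not performance on any particular sequencing chemistry.

`simulate_counts` draws the multinomial counts directly (equivalent to
error-free sequencing plus perfect assignment), which is how statistic-level
properties are exercised at 10⁵ reads × 1000 genes in seconds.

## Quantification

Demultiplexing matches each sample barcode against both read ends by edit
distance (threshold 4 ≈ 0.15 × barcode length); a plain Hamming prefix
comparison would lose most reads to indel register shifts at realistic indel
rates. Barcode sets whose pairwise Hamming distance is ≤ 2× the threshold
are rejected up front. Assignment aligns every member amplicon as an infix
of the read (and of its reverse complement) with edlib and counts the read
for the uniquely closest member within 0.15 × member length (≈ 3× the
default total error rate, keeping random cross-member hits rare); ties are
ambiguous and counted nowhere; everything else is unassigned. The identity
`assigned + ambiguous + unassigned = total` holds per sample and is enforced.
Representation QC reports dropouts (zero-read members), min/max, fold-range
and the Gini coefficient of the count distribution.

## Screen statistic

Frequencies use a 0.5 pseudocount per cell (members with zero reads exist in
real libraries; the ratio statistic needs finiteness; 0.5 is the standard
continuity correction). The enrichment score is the ratio of mean sorted to
mean control frequency, computed per replicate and averaged — per-replicate
frequencies are also reported so the pooled alternative can be derived from
the output. Replicates are compared with the classic two-tailed Student's
*t*-test (pooled variance). The pooled-variance flavour is deliberate: with
triplicate pools, Welch's degrees-of-freedom estimate is noisy enough to
make the test materially conservative (empirical type-I ≈ 0.033 at nominal
0.05 on null data), whereas the pooled test is near-exactly calibrated
(≈ 0.048, verified in the acceptance suite); with equal group sizes it is
also robust to mild variance inequality. Zero-variance identical groups
return p = 1. Benjamini–Hochberg correction is applied across genes within
each contrast. Ranking is by log2 score, descending for Max contrasts and
ascending for Min contrasts, ties broken by gene id; shortlist sizes are a
parameter (uneven per-direction presets are supported). Differential-count
analysis in the DESeq2 style is intentionally not reimplemented; the counts
TSV exports directly to such external tools.

## Problem sizes and numerical choices

The test and acceptance suites run on synthetic sets sized for quick,
convincing coverage: 50–411 genes of 300–900 nt for design properties,
2 × 10³ noisy reads on a 50-member library for assignment fidelity, and
10⁵ reads × 200–1000 genes (count-level) for statistic calibration and
fold-4 spike recovery over 20 seeds. Seeds are fixed everywhere; the design
path contains no randomness at all. Floating-point tolerances: frequency
normalisation to 1e-12, t-test agreement with an independent implementation
to 1e-10.

## Known limitations

- Guide efficiency is rule-based only; no thermodynamic or learned activity
  scores, and no cloning/junction simulation or verification-primer design.
- Off-target distance is Hamming on PAM-adjacent 20-mers, ignoring
  bulge-mediated off-targets and non-NGG PAMs.
- The GFF3 convenience reader handles single-exon CDS features only; the
  canonical input is the tabular annotation.
- Multi-exon genes, alternative genetic codes, and genome-scale alignment
  are out of scope; the mapping-free assignment presumes the full member
  sequence set is known, which is exactly true for a synthesised library.
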