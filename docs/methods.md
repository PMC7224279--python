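# Methods

This note documents the models implemented in `circsponge`, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical conventions.

## Coordinates and splice signals

Intervals are 0-based half-open internally; reports render
`contig:start..end` with a 1-based inclusive start, the convention circRNA
catalogues print.  A circle's genomic span is `[start, end)`; on `+` the
acceptor is `start` and the donor `end`, reversed on `-`.  Canonical splice
signals are checked on the annotated strand: GT immediately 3′ of the donor
and AG immediately 5′ of the acceptor.  On the `+` strand of the genome this
reads `AG[circle]GT` for a `+` junction and `AC[circle]CT` for a `-`
junction (the reverse complements, swapped).

## Synthetic study generator

The generator's defaults are the study conditions every recovery and
calibration claim is made under: 40 samples, 75 bp single-end reads, three
100 kb contigs, 24 genes with 5–12 exons (exons 150–350 nt, introns
400–900 nt; the first/last two exons in transcript order are 5′/3′ UTR, the
rest CDS), and 26 planted circles (12 CDS + 4 5′UTR + 4 3′UTR + 3 intronic
+ 3 intergenic).

- **Exonic circles** use 1–10 consecutive same-feature internal exons of one
  gene, so their junctions reuse the gene's own GT/AG intron boundaries.
  Terminal exons are excluded (no flanking intron, hence no splice signal).
- **Intronic and intergenic circles** are carved out of introns or
  gene-free gaps (150–300 nt) and have GT/AG flanks written into the
  genome; without this they would be invisible to a caller that demands a
  splice signal, and the planted-truth invariant (every junction canonical)
  would not hold.
- **Abundance**: per-circle expected BSJ read count is log-normal
  (ln-mean 3.0, ln-sd 0.7, floored at 5 expected reads so every planted
  circle is detectable by design) with per-sample log-normal variation
  (ln-sd 0.4).  Realized read counts are Poisson.  Per-sample raw totals
  default to 20,000 reads — real sperm libraries are three orders of
  magnitude deeper, so synthetic CPM values are correspondingly larger; all
  downstream statistics are scale-free in this respect.
- **Reads**: linear background fragments are sampled uniformly from
  annotated exonic transcript sequence (no expression model — only BSJ
  reads matter downstream); BSJ reads place the junction uniformly at least
  20 nt (the anchor length) from both read ends.  Substitution errors at
  rate 0.001; base qualities constant Phred 37, with an option to inject
  low-quality (Phred 30) samples so the quality filter is exercisable.
  Paired-end mode rotates a fragment around the junction and reports both
  mates; support is counted per fragment.
- **miRNAs**: 20 random 20–24 nt sequences; 10 are sponged, each by one
  exonic circle from a distinct host gene.  The reverse complement of the
  miRNA's first 13 nt — covering the seed (positions 2–8) plus 3′
  supplementary pairing, as strong natural sites have — is written into the
  circle's spliced sequence, and the miRNA's log2 abundance is coupled to
  the circle's log2 abundance with coefficient −1 plus Gaussian noise
  (sd 0.58 log2 units), giving a true correlation near −0.7.  The 13 nt
  planted site (rather than the 7 nt seed minimum) is what makes planted
  sites clear the alignment-score threshold reliably while shuffled
  controls do not.
- **Phenotypes**: trait = intercept + farm + age-class + season-year
  effects + Σ(coefficient × centred log2 abundance) + Gaussian noise;
  motile % clipped to [0, 100].  Boar ages are uniform on 9–54 months and
  age classes are age tertiles.  Causal circles are assigned round-robin
  across traits with the coefficient sized for a planted circ–trait
  correlation of 0.6 given the trait noise and abundance spread.

Everything is deterministic under the config seed (byte-identical FASTA /
FASTQ / TSV outputs; the on-disk manifest stores file names, not paths, for
this reason).

What the generator does **not** emulate: RNA degradation and the highly
fragmented, low-input nature of real sperm libraries; linear-transcript
expression structure; adapter contamination; indel sequencing errors;
multi-mapping repeat context; isoform complexity within genes.  Passing
recovery tests therefore demonstrate the correctness of the algorithms
under the stated model, not the field performance of the pipeline on real
libraries.

## Junction caller

Terminal anchors (20 nt) of each read — and of its reverse complement — are
looked up in an exact k-mer index of the `+` strand.  A hit pair in
head-to-tail order (right anchor strictly upstream of and non-overlapping
the left anchor) triggers extension of both anchors toward the read
interior with at most 1 total mismatch; the breakpoint is the split with the
fewest mismatches.  Breakpoints without a canonical splice signal are
discarded (unless `require_canonical_splice` is off), and a read is dropped
as ambiguous unless exactly one junction remains — this resolves the
frequent one-off breakpoint tie at junction-flank homology, because the
shifted split lands inside the GT/AG dinucleotides.  The strand is read off
the signal pattern.

Numerical/semantic choices: anchors are exact (mismatches live only in the
extension); junction quality is the mean base quality in a ±10 nt window
around the breakpoint, and a candidate's score is the minimum over its
supporting reads; a read counts toward *unique* support only when both its
anchors have exactly one genomic hit (both strands counted); paired mates
probe junctions independently but count once per fragment; junctions merge
across samples by exact coordinate equality (breakpoints are base-precise
under the extension rule, so no fuzzy window is needed); the default
multi-sample threshold is ceil(0.75 × n), i.e. 30 of 40.  The span cap
(1 Mb) discards pathological head-to-tail pairs across distant loci.

The "Phred ≥ 35" stringency rule is interpreted as a base-quality summary
of the junction window; the threshold and window are parameters, so a
different quality interpretation can be plugged in.

## Catalogue

CPM = count / raw_total × 10⁶ per sample; mean and SD CPM are computed over
*all* catalogue samples, counting undetected as 0 (SD with ddof = 1).
Classification is by co-location, strand-blind (as interval-overlap
co-location tools behave by default): no overlapping gene → intergenic;
gene but no exon overlap → intronic; otherwise exonic, sub-classed by the
feature type (CDS/5′UTR/3′UTR) covering the largest share of the circle's
overlap, ties broken CDS > 3′UTR > 5′UTR.  The host gene is the gene with
the largest bp overlap (ties alphabetical).  Exon count and spliced length
use the host gene's annotated exons fully contained in the span; if none is
contained, touched exons clipped to the span are used.  Hotspot genes have
≥ 5 distinct exonic isoforms.  Catalogue comparison requires both
catalogues on one assembly and matches junctions within a boundary
tolerance (default 0 nt); cross-assembly input is undetectable and is the
caller's responsibility.

## Sponge network

Abundances are stabilized as log2(x + 1) before correlation.  PCIT follows
the trio-elimination rule described in the README; numerical guards: |r| is
clamped below 1 − 10⁻¹², ratio terms with |direct r| < 10⁻¹² are skipped
from the tolerance mean, and with fewer than three features no trio exists
so every edge survives.  PCIT runs on the combined circRNA + miRNA matrix;
only circ–miR edges are exported.

The target scan is an ungapped, position-weighted complementarity scan
(match +5, mismatch −4, G:U wobble +1 outside the seed, seed positions 2–8
weighted ×2, threshold 50) of the reversed-complement miRNA against the
circle sequence extended by (miRNA length − 1) nt of its own start, so
junction-spanning sites are visible; positions are reported modulo the
circle length.  A hit additionally requires a perfect Watson–Crick seed at
miRNA positions 2–7.  This is a deliberate approximation of
thermodynamics-aware target predictors: no free-energy term and no gap
moves (gaps would blur the position bookkeeping that the seed requirement
relies on, and seed-anchored sites are well approximated ungapped).  With
these scores a planted 13 nt site scores ≈ 84 ± 12 and shuffled controls
with a chance seed match pass the threshold < 20% of the time, which the
intersection with PCIT-negative edges reduces to a ≤ 0.5% false-pair rate
in practice.

A final edge requires all three: PCIT survival, negative Pearson r, and at
least one target site.  No post-PCIT correlation-magnitude cutoff is
applied beyond the sign requirement.

## Association

Fixed-effect correction is OLS on dummy-coded factors (first level
reference); a rank-deficient design raises an error naming the aliased
columns rather than silently dropping them.  The Pearson screen uses the
two-sided t transform with n − 2 df and applies **no multiple-testing
correction** by default, matching the screening character of the analysis;
`bh_fdr` is available for callers who want adjusted p-values.  Constant
abundance vectors yield r = NaN and are never flagged.  Whether raw CPM or
log2 CPM is screened is a flag (`log2=False` default).

The Wilcoxon rank-sum test uses the exact null distribution when the pooled
sample is ≤ 20 and tie-free, and the tie-corrected normal approximation
otherwise.  The age comparison splits at 24 months by default (configurable)
and supports an extreme-groups mode comparing the k youngest and k oldest
samples (default k = 4).  "Abundance" per sample is summarized as mean CPM
over catalogue circRNAs.

## Problem sizes

The test suite and `scripts/acceptance.py` run the read-level study at its
default size (40 samples × 20,000 reads, 26 circles), the network stage at
50 circles × 20 miRNAs × 40 samples with 10 planted sponge pairs, oracle
comparisons on ≤ 50 kb genomes and ≤ 15-feature correlation matrices, and
the screen calibration on 1,000 null pairs plus 200 power replicates.

## Known limitations

- The caller requires both anchors to match exactly; a substitution inside
  an anchor loses that read (not the junction, given enough support).
- Circles with genomic span shorter than the read length are undetectable
  by construction (the head-to-tail gate requires non-overlapping anchors),
  and circles with terminal exons shorter than read − anchor length lose
  reads whose extension crosses an internal splice.
- Classification trusts the annotation; host-transcript choice is the gene
  model itself (one transcript per gene in the synthetic annotation).
- The target scan has no thermodynamic filter; its score threshold was set
  against the planted-site/shuffled-control separation described above, not
  against experimental binding data.
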