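# Methods

## Signal model

A modified nucleotide interferes with reverse transcription in two ways that
survive into mapped sequencing data. First, the enzyme may arrest: cDNA
synthesis terminates and the resulting read's 5′ end lies one position 3′ of
the modified base (reads are synthesised 3′→5′ along the tRNA, anchored at
the CCA end by the library chemistry). Second, the enzyme may read through
while inserting a non-templated base, leaving a mismatch at the modified
position itself. Different chemistries produce characteristic combinations:
1-methyladenosine gives strong arrest with A→T/A→G mismatches; inosine is a
clean A→G mismatch with no arrest; N2-methylguanosines give G mismatches
with arrest; dihydrouridine and 2′-O-methylations give weak signals. The
caller detects sites from either channel and a classifier maps the observed
signature, together with positional prior knowledge, to ranked candidate
identities.

Because reads are 3′-anchored, coverage is non-increasing toward the 5′ end
and the arrest fraction at *n*, `stop(n+1)/cov(n+1)`, is identically
`1 − cov(n)/cov(n+1)`. Both forms are computed and their equality is
asserted on simulated data; the stop-fraction form is primary and the
read-through ratio is exposed as a debug column.

## Reference construction and coordinates

Gene annotations arrive as a TSV (id, contig, 1-based inclusive coordinates,
strand, isotype, anticodon, intron intervals relative to the gene, origin)
plus a genome FASTA. Maturation is: splice introns, then append CCA unless
the spliced sequence already ends in CCA (conditional appending avoids
CCACCA artifacts for genomically encoded tails). Genes with identical mature
sequences are merged into clusters — reads cannot distinguish them — with
nuclear and mitochondrial genes always kept apart, even on sequence
coincidence, because their modification biology differs. Cluster ids are
deterministic (`isotype-anticodon-ordinal`, ordinals by lexicographic mature
sequence; `mt-` prefix for mitochondrial). Intron intervals are accepted
anywhere inside the gene, including its edges, provided they are sorted,
non-overlapping and leave a non-empty product. All TSV coordinates are
1-based; BED output is 0-based half-open.

## Standard-position numbering

Sprinzl labels are assigned by global affine-gap alignment of each mature
sequence to a packaged 76-column cloverleaf consensus. Scoring: +2 for the
invariant base at 15 strongly conserved columns (U8, A14, G18, G19, A21,
U33, G53, U54, U55, C56, A58, C61, C74–A76), −1 for any other base there;
non-conserved columns accept any base at +1 with a +0.5 bonus for the
consensus base — the bonus pins insertions to the column where the extra
base actually sits instead of letting them drift through runs of equally
scored columns. Gap open 5, extend 1 (mitochondrial template: 3/0.5, since
mt-tRNAs commonly shorten the D- or T-arm and must not be penalised into
unfittability). The terminal CCA is anchored onto columns 74–76; when the
anticodon is known and found within 8 nt of its canonical offset, its
triplet is anchored onto 34–36 and the flanks are aligned independently.
Traceback ties prefer matches over gaps, giving leftmost gap placement.
Insertions after column 17 are labelled 17a…, after column 20 → 20a, 20b,
20b1…; insertions in the variable-arm region (after columns 44–47) → e1…eN;
elsewhere a generic letter suffix is used. Alignments scoring below a floor
(default 20; 10 mitochondrial) are flagged unfittable and those clusters are
reported by raw coordinate only. This template-alignment design replaces a
database-search step (best-hit alignment against a tRNA sequence database)
with a self-contained equivalent: the highest-scoring fit defines the
numbering either way.

## Read retention and the mapping contract

Raw reads are 3′-quality-trimmed at Q25 using the BWA-style partial-sum
rule (cut where the running sum of `cutoff − q` from the 3′ end is
maximal), then kept when the trimmed length is 8–95 nt. Whether the
published "quality cutoff" meant trimming or mean-quality filtering is not
decidable from the text; trimming is the cited trimmer's semantics and the
cutoff is exposed in config. The mapping itself is external; the package
documents its contract (minimum accuracy 80%, i.e. `floor(0.2·L)`
mismatches for an L-nt read, computed exactly over rationals to avoid float
floor artifacts) and removes precursor-tRNA reads: any alignment reaching
≥ k nt (default k = 1, the strictest consistent rule) outside the mature
interval of a precursor contig is excluded.

## Pileup and calling

Profiles count, per reference position: coverage (aligned bases plus
deletions), 5′-most-aligned-base stops, and base composition. Secondary and
supplementary records and reads tagged multi-mapped (NH > 1) are dropped —
only uniquely mapped reads contribute — soft-clipped bases are ignored (the
5′-most *aligned* base defines the stop), insertions do not consume
reference positions, N calls are discarded, and duplicate reads are not
collapsed. Deletions count toward coverage but never toward mismatches, and
indels are not modification evidence.

Mismatch confidence is the one-sided exact binomial tail
`P(X ≥ k | cov, ε)`, Phred-scaled and capped at 1000, with ε = 0.01 by
default. This stands in for a variant caller's Phred-scaled site quality
with identical threshold semantics (Q ≥ 20 ⇔ p ≤ 0.01) while being exact
and deterministic; tests verify the decision boundary against a brute-force
`math.comb` enumeration for every coverage ≤ 30. No multiple-testing
correction is applied: the thresholds are the published operating point and
candidate counts per cluster are small.

The arrest caller emits position *n* when `RTa(n) ≥ 0.20` (inclusive) and
`cov(n+1) ≥ 10`. The artifact filter codifies a manual curation step: an
arrest call at *p* is suppressed when a stronger arrest call exists at *q*
with `q < p ≤ q+3`, `RTa(p) < RTa(q)`, and *p* shows mismatches that stay
below the confidence threshold — the echo pattern of the TGIRT enzyme.
Window, relative-strength and mismatch conditions are all configurable;
suppression flags calls but never deletes them, and filtering happens after
thresholding. Finally the two channels are merged by (cluster, position)
with evidence flags OR-ed.

## Classification

A signature rule specifies reference base, whether arrest is required,
forbidden or optional, the admissible dominant mismatch targets, and an
intensity class (weak/strong split at RTa 0.4, configurable; no numeric
boundary is published, so this is a declared convention). Candidates
compatible with the observed call are ranked: identities also catalogued at
the same Sprinzl label in other species come first, then
signature-only matches; ambiguous sets (m2G|m22G at G10/G26, the A37
hypermodification family) are preserved rather than forced to a single
code. Calls matching no rule receive `unknown` with the observed mismatch
signature attached — classification never drops a call. The packaged
signature table and position catalogue are curated reconstructions of
published RT-signature collections; both are plain TSVs with per-row
provenance and can be replaced by the user.

## Time-course aggregation

The per-position distribution sums stops and coverage over *qualifying*
clusters and reports their ratio per sample — a coverage-weighted mean,
which is the only reading consistent with normalising over all reads
(an unweighted mean of per-cluster ratios would let a 10-read cluster
outvote a 10 000-read one). A cluster qualifies at a label when it reaches
the 20% threshold there in **at least one** sample, and the same cluster
set is then summed at every time point so values are comparable across the
course; per-sample qualification would change the summand set between time
points and confound dynamics with set membership. The presence matrix
counts clusters with unsuppressed calls per (label, reference base,
sample) and is monotone under threshold relaxation. The
expression-independence check uses Spearman rank correlation (read totals
are heavy-tailed; only a monotone association claim is made) between
cluster read totals and cluster arrest intensity at each qualifying label,
two-sided p-values, reported as missing below 4 clusters.

## Simulator

The generator emulates CCA-anchored tRNA-seq: mature sequences are drawn by
mutating ~12 non-conserved, non-anticodon columns of the cloverleaf
consensus (so template fitting always succeeds, as for real tRNAs),
gene copies are assigned by a Dirichlet-skewed multiplicity vector summing
to the configured total (defaults: 70 distinct sequences, 15 of them
mitochondrial, over 421 genes — the cardinality of the motivating
dataset), ~15% of nuclear genes receive an intron one base 3′ of the
anticodon (the canonical location), and genes are embedded on either strand
of a toy genome with 50 nt flanks. Each read starts at the 3′ end and
walks 5′-ward; at each planted site it terminates with the site's stop
probability (5′ end = site+1) or else substitutes a base per the site's
mismatch spectrum; every emitted base carries a uniform background error
(default 0.001; 0.005 in the recovery conditions). Reads are written both
as FASTQ and as a truth-aligned SAM so no aligner is needed in tests.
Per-sample streams are seeded via CRC32 of the sample id mixed with the
master seed — process-invariant, unlike Python's string hash. Constant Q40
qualities by default. RT "jumps" (skipped positions) and PCR duplicates are
not modelled; real error profiles are not instrument-shaped. Passing tests
therefore demonstrate correctness of the counting, calling and aggregation
machinery under the stated generative model, not robustness to alignment
artifacts, paralog cross-mapping, or structured sequencing error.

## Problem sizes and numerical choices

The recovery suite plants ≥ 200 sites over 60 clusters at 600 reads per
cluster with stop probabilities 0.3–0.7, mismatch fractions 0.2–0.8 and
≥ 8 nt spacing; with the caller's assumed error rate (0.01) at twice the
simulated background (0.005), null positions essentially never reach
Phred 20, giving sensitivity ≥ 0.95 at FDR ≤ 0.05. Calling the caller with
an assumed rate *equal* to the truth would, by construction of the p ≤ 0.01
operating point, call ~1% of null positions. Intensity estimates are
validated within 3 binomial standard errors at depth 2000. The expression
null uses 100 replicates of 15 clusters. Boundary bisections use
synthetic pileups at coverage 10 000 (intensity) and coverage sweeps
20–5000 (confidence). All thresholds are compared inclusively
(≥ 0.20, ≥ 10 reads, ≥ Phred 20), matching the published wording
"greater or equal".

## Known limitations

Sprinzl numbering of severely degenerate mitochondrial tRNAs (missing
arms) may be flagged unfittable rather than forced; such clusters remain
analyzable by raw coordinate. The artifact filter is a codified
approximation of a manual curation step and its exact published pattern is
not recoverable. Identity assignments are hypotheses: signature plus
homologous-position evidence, not chemical proof — distinguishing e.g.
pseudouridine, m7G or m5C requires treated libraries or mass spectrometry.
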