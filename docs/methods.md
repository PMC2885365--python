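# Methods

This note documents the models and procedures `mirprof` implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic fixtures do and do not demonstrate.

## Coordinates and formats

All genomic intervals are 0-based half-open internally. GFF3 input
(1-based closed) is converted on read; BED-style output stays half-open.
FASTA/FASTQ go through Biopython; because Biopython silently drops
whitespace inside sequence lines, FASTA reading first scans raw lines and
rejects embedded whitespace as malformed. Tag files are two-column TSVs
(sequence, frequency); an optional header line is accepted only when
neither column parses as data, so a malformed first record is still an
error. `N` bases are accepted on input but never match anything in the
mismatch matcher — not even another `N` — which is the conservative choice
for an elimination cascade whose early hits are removed permanently.

## Adapter trimming and collapsing

Delivered reads have a fixed length (33/35 nt here), so the 3' adapter
appears in full when the insert is short and as a prefix fragment when the
insert is long. Trimming cuts at the leftmost full-adapter occurrence,
else at the longest read suffix equal to an adapter prefix of at least
`min_prefix` nt. `min_prefix` defaults to 5: shorter suffixes match by
chance once per ~4⁵ reads, which at library scale would chip real 3' ends
off thousands of inserts. Matching is exact — no data here motivate an
adapter error model. A consequence worth knowing: an insert whose own 3'
end happens to equal the start of the adapter is trimmed one or more bases
short; this ambiguity is intrinsic to end-trimming, not to this
implementation.

Collapsing sums frequencies of identical trimmed inserts and orders the
library by descending frequency (ties lexicographic), assigning ids in
that order, so identical inputs give byte-identical processed FASTA. The
length filter keeps inserts of ≥ 11 nt (strictly longer than 10),
configurable via `min_len`. Singletons are kept: a frequency-1 sequence
can be a real low-abundance transcript, and downstream family evidence
(isomiRs, stars) is how it earns belief.

## The elimination cascade and the mismatch matcher

Tags are annotated by ordered elimination: mature miRNAs first, then other
ncRNAs (precursors, sn/sno/sca, tRNA), rRNA/mRNA, exons. Counting known
miRNAs first matters — any broader set would absorb them. A tag's category
is the first set it hits; hits are removed before the next round, so the
output is a partition of the library.

The matcher reports every ungapped full-tag alignment with Hamming
distance ≤ 2 (substitutions only; an indel model would change what
"matches a known miRNA" means). Seeding: split the tag into 3 segments —
with at most 2 mismatches at least one segment is exact (pigeonhole) — and
look up each segment's k-prefix in a k-mer index, then verify the full
alignment. k = min(8, ⌊min tag length/3⌋) keeps the guarantee exact at
every tag length the length filter admits. Reference matching is
sense-strand only (references are transcript sequences); genome matching
of leftover tags is exact on both strands. Within a stage the best hit is
fewest mismatches, ties to the lexicographically smallest reference id;
frequency is never split across references (there is no defensible
apportioning rule at this depth), but every within-stage hit is kept in a
multi-mapping report.

Genome hits fully inside an intron are intronic, hits outside all genes
intergenic; anything touching an exon or straddling a gene boundary is
discarded — those reads belonged to the exon stage.

## Normalization and differential expression

TPM = count / total clone count × 10⁶, with the total clone count the
summed frequency of all unique trimmed sequences in the library (not just
miRNA-derived ones). Tag-level TPM therefore sums to exactly 10⁶ per
sample.

Differential calls intersect two routes:

**Moderated statistic.** The two-class unpaired SAM-style score
d = (x̄₂ − x̄₁)/(s + s₀), with s the pooled standard error and s₀ a fudge
factor chosen by the standard search: over candidate percentiles of s,
pick the s₀ minimizing the coefficient of variation of the d spread
(MAD/0.64) across percentile windows of s; below 50 features the search is
unstable and s₀ = median(s) is used instead. The statistic is computed on
log2(TPM + 0.5): expression spans orders of magnitude and on the raw scale
the score's spread grows with abundance, producing a heavy null tail no
single s₀ can moderate; log scale is the standard input for t-like scores
on expression data and makes a k-fold change an additive shift. q-values
come from sample-label permutations (all relabelings when there are at
most 1000, else 500 sampled with the given seed): for each observed |d|
cut, q = median over permutations of the number of permuted scores beyond
the cut, divided by the observed count beyond it, capped at 1 and
monotonized so q never decreases as |d| grows. With fewer than 3 samples
per group the permutation set is degenerate (the original 2-normals-vs-1-
tumor design has 3 relabelings); the tool runs but warns.

**Fold change.** A miRNA is up if tumor TPM exceeds 2.5× the TPM of
*every* normal sample, down in the mirrored case; strictly greater than,
per the rule's wording. miRNAs under 10 TPM in all compared samples are
ignored. Ratios use max(TPM, 0.5) — half the smallest meaningful singleton
scale in a ~1M-read library — to avoid division by zero. A multi-sample
tumor group is summarized by its mean TPM before the per-normal
comparison.

The final set is the intersection at q ≤ 0.05, with direction taken from
the fold change; a sign conflict between the two routes excludes the
feature and is reported. Calibration on null 3v3 negative-binomial
matrices yields ≤ 0.1% false calls. Recovery of planted 4-fold effects is
about 90% under the generator's default dispersion (0.05, BCV ≈ 0.22):
the loss comes entirely from the every-normal fold-change requirement —
with three normals, the chance that at least one is drawn above
tumor-mean/2.5 for a true 4-fold effect is ≈ 11%. That is a property of
the rule under that noise level, not of the implementation; SAM alone
recovers 100%.

## Novel miRNA discovery

Each exact genomic hit is extended by 70 nt on both sides (clamped at
chromosome ends; minus-strand windows extracted reverse-complemented with
the read span re-measured on the extracted strand), giving ~162-nt
candidate precursors for a 22-nt read.

**Folding.** The built-in folder maximizes nested base pairs
(Watson–Crick + G·U wobble, minimum loop 3) by dynamic programming, with a
deterministic traceback (pairing the interval ends is preferred over
bifurcation; bifurcations split at the smallest k). It is not a
thermodynamic model: it was chosen because it is dependency-free,
oracle-testable by exhaustive enumeration, and sufficient for the stem
geometry this filter needs; a free-energy folder can be plugged in through
the external-classifier adapter. Non-ACGU characters are forced unpaired.

**Arm location.** Terminal stem-loops are read off the structure: each
innermost pair is extended outward through enclosing pairs, tolerating
interior bulges of up to 6 nt per side (typical of real precursors;
without a cap, a long unpaired stretch would be swallowed as one giant
"bulge" and two unrelated helices would merge into one apparent stem). The
dominant stem-loop is the one whose stem pairing involves the read most.
The read is classified by where its bases sit: on the 5' or 3' strand of
the stem's pairs (an arm call requires a majority of the read to actually
pair within the stem), in the terminal loop, spanning, or unpaired — the
window-scanning caveat that a fold may not involve the read at all is an
explicit reject. Acceptance requires an arm location and ≥ 14 stem pairs
(a 22-nt read with a near-full-length helix; configurable), and, when
external classifiers are configured, at least 2 accepting votes (failed
adapters are recorded and excluded from the denominator).

## Families, naming, clusters

Accepted candidates whose windows overlap by ≥ 1 nt on the same strand
share a precursor; this is also how redundancy across samples is removed —
per-sample windows around the same hairpin rarely agree to the base, so
requiring identical coordinates would leave duplicates. Within a family
the most abundant member (ties lexicographic by sequence) is the mature
miRNA; same-arm others are isomiRs — defined positionally (same arm,
≥ 50% overlap with the representative) because end variation from
DROSHA/DICER slippage, not substitution, is what generates them;
opposite-arm members are stars. Naming is deterministic in locus order:
`jnuhsa-N` with star `jnuhsa-N*` when the representative exceeds 5× the
best opposite-arm frequency (or has no opposite arm), else
`jnuhsa-N-5p`/`-3p`. The 5× dominance ratio operationalizes "clearly
predominant" and is configurable.

Seed kinship links a novel mature to known miRNAs sharing nucleotides 2–8
exactly. Genomic clustering chains loci (known and novel, strand-agnostic)
whose end-to-start gap is ≤ 20 kb, transitively (single linkage — the
natural reading of a fixed-distance neighbour rule, and the one that
matches connected components of the gap graph); clusters are labeled
known-only, mixed, or novel-only.

## Target refinement

Prediction-program votes arrive as a table over a configured 11-program
universe; a pair survives with ≥ 5 programs. "Inverse correlation" is
sign opposition, not a correlation coefficient — with one tumor line per
comparison there is nothing to correlate: miRNA down & gene up by more
than 1.5-fold, or the mirror. Gene symbols are matched case-insensitively
after whitespace stripping; no alias resolution. Reports: genes targeted
by ≥ 3 differential miRNAs, and intronic-miRNA/host-gene concordance
(both_up / both_down / discordant, with the concordant fraction).

## The synthetic fixtures

The generator emulates the study conditions: a 60-kb toy genome with 4
intron-containing genes; 20 perfect-stem hairpins (30-bp stem, 8-nt loop —
a 68-nt precursor, inside the 60–120-nt human range) planted alternately
in intergenic and intronic space; 5 large-loop decoy hairpins whose
sequenced read sits in the loop; 50 known-miRNA sequences and 30 decoys
each for the ncRNA and rRNA/mRNA classes (exon decoys come from the gene
model), all registered in reference sets so every cascade stage has true
hits. Species are 18–30 nt; each hairpin expresses a mature (log-uniform
50–3000 copies), 0–3 isomiRs (shifted ends, lower abundance), and with
probability 0.6 a star (log-uniform 1–50) — matching the observed pattern
that matures predominate and stars are low-abundance. Reads are delivered
at 33/35 nt with the real platform adapter; species long enough that a
33-nt read would leave a sub-`min_prefix` adapter remnant go into 35-nt
reads so the ground-truth counts stay well-defined, and planted species
never end in the adapter's first base for the same reason. Hairpins are
placed ≥ 200 nt apart (more than twice the 70-nt flank) so distinct
planted precursors cannot share a candidate window. Count matrices for DE
calibration are negative binomial, mean log-uniform 10–1000 (planted
features 100–1000), dispersion 0.05.

What passing on these fixtures does **not** show: robustness to
sequencing error (not modeled), bulged or G·U-rich real precursor stems
(a `bulge_rate` option exists for stress tests but defaults to 0),
cross-mapping between paralogous miRNA families, or thermodynamic
stability of predicted hairpins. One realistic artifact is reproduced
faithfully: a perfect inverted repeat matches the genome on both strands,
so every planted hairpin also yields a mirror-image family on the
opposite strand, exactly as real data would.

## Problem sizes

Default test and acceptance runs use 5 reference sequences of 2–5 kb ×
250 tags for the matcher oracle, 220 sequences of ≤ 25 nt for the folding
oracle, one ~45k-read library for the end-to-end run, 10 × (1000 features,
3v3) matrices for DE calibration, and 100 random locus sets for the
clustering oracle — sizes at which the independent oracles (brute-force
Hamming scan, exhaustive structure enumeration, graph connected
components) are themselves fast and exact.
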