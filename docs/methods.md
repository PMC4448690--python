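# Methods

This note documents the models and procedures `stresslnc` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions chosen where the design was open.

## Coordinates and transcript models

All internal coordinates are 0-based half-open. GTF I/O converts from/to
1-based inclusive, BED12 is natively 0-based half-open; both round-trip
bit-exactly. A transcript is an ordered, non-overlapping exon chain on one
strand; TSS/TES are strand-aware span endpoints. Transcripts shorter than
200 nt (spliced) are parsed and retained but never treated as lncRNA
candidates — the 200 nt bound is a classification gate, not a parsing gate.

Gene loci are the connected components of the "shares ≥ 1 bp of same-strand
exonic overlap" relation (the minimum overlap is configurable,
`merge_loci(..., min_overlap_bp=)`). The locus representative is the member
with the highest RPKM in any experimental condition; ties are broken by
longer spliced length and then lexicographic transcript id, so results are
identical across runs and input orderings.

## Expression filters

RPKM is `count × 10⁹ / (length_nt × library_size)`. A feature is *detected*
in a sample when it has > 10 reads and > 1 RPKM there. A treated-vs-control
comparison calls *up* when RPKM(treated)/RPKM(control) > 1.5 and the
treated sample passes detection; *down* mirrors the rule with the filter on
the control side (the mirrored filter is a package choice; only the
treated-side rule is forced by the design being reproduced, and the
thresholds are all exposed). When either side of a ratio is 0, a
pseudocount of 0.1 RPKM is added to both sides — this avoids infinite fold
changes and is configurable. A feature is up overall when any treated
comparison (time point × compartment) calls it up, matching the
"at least one time-point" convention of the study design. Report
percentages round half-up to one decimal.

The intron/exon quadrant analysis places each intron-containing gene by
the sign pair of (log2 exonic fold change, log2 intronic fold change):
quadrant I = both up, II = exonic down/intronic up, III = both down,
IV = exonic up/intronic down; a zero log fold change counts as "up" so the
quadrants partition all eligible genes. "Altered" means |log2 fc| ≥
log2 1.5 on either axis. Intron-less genes are excluded and logged.
Intronic RPKM is computed over the concatenated intronic length of a gene.

Up-vs-down gene structure (genomic span length, exon number) is compared
with the two-sided Mann–Whitney–Wilcoxon test from scipy.

## Positional lncRNA classification

Classes, in precedence order (first match wins):

1. **overlapping** — the lncRNA genomic span shares ≥ 1 bp with a coding
   gene span (partner = largest overlap; ties by gene id). Genomic (not
   exonic) overlap is used; the cartoon geometry being reproduced depicts
   whole gene bodies.
2. **promoter_associated** — the lncRNA TSS lies within (inner, outer] bp
   *upstream* of a coding TSS, measured on the coding gene's strand axis;
   default window (0, 5000]. Partner = smallest |distance|. Antisense
   orientation makes the call a paancRNA. Distances are signed, negative
   upstream of the anchor.
3. **terminal_associated** — likewise within (inner, outer] bp *downstream*
   of a coding TES; default (0, 5000].
4. **distal** — no coding gene span within 5 kb (`distal_min_gap_bp`) of
   the lncRNA span, or no gene on the chromosome.
5. **proximity fallback** — a lncRNA within 5 kb of a gene but outside both
   windows (possible only with shrunken windows or unusual geometry) is
   assigned promoter- or terminal-associated by which side of the nearest
   gene's axis its TSS falls on. This makes classification total and
   deterministic; the brute-force test oracle implements the same tree.

The published window notation for the promoter/terminal classes is
internally inconsistent with the observed −0.5 to −1.5 kb antisense peak,
so both window bounds are configuration (`ClassWindows`), with the
defaults above. Orientation is concurrent/opposite by strand equality with
the partner. Nearest-gene ties break by distance then gene id.

True symmetries, verified by property tests: translation invariance
(shifting all coordinates), and mirror invariance (reflecting coordinates
*and* flipping strands). Flipping strands alone is not a symmetry of the
rules — it exchanges upstream and downstream, hence promoter- and
terminal-associated calls — so the suite tests the full mirror instead.

## PolII traveling ratio and metaprofiles

The traveling ratio (pausing/stalling index) of a gene is the mean per-bp
coverage over the promoter window, default offsets −30 to +300 around the
TSS (331 bp, strand-oriented), divided by the mean over the remaining gene
body (+301 to the TES). Genes shorter than the window are skipped with a
reason; zero body coverage yields NA (not +∞) so summary statistics stay
finite. A minimum gene length (600 bp in the original analysis of antisense
transcripts) is a caller-supplied filter. Per-bp mean density is used in
both regions; TR is invariant to global rescaling of the track.

Metaprofiles average coverage in fixed-width bins (default 50 bp) over
symmetric windows around anchors; minus-strand windows are reversed before
averaging (half-open reversal maps genomic offset +k to profile offset
−k−1), windows beyond chromosome bounds are NaN-padded and counted, and
profiles are reported both raw and RPM-normalised
(× 10⁶ / total mapped reads). Coverage I/O is dense per-bp arrays with
bedGraph read/write; text bedGraph keeps tests dependency-light.

## Polysome-array pipeline

Samples are (state ∈ {stress, control}) × (pool ∈ {Total, None, Low,
High}) × replicate (three replicates by default). Processing: optional
background correction, log2, quantile normalisation (every column forced
to the identical sorted multiset; idempotent by construction). Background
modes: "none", "subtract" (column 5th percentile + offset, floored), and
"normexp" — a maximum-likelihood fit of the normal + exponential
convolution (background B ~ N(μ, σ²), signal S ~ Exp(α)), replacing each
intensity by E[S | X = x] plus an offset (default 50, the common practice
for stabilising low-intensity variance). The normexp fit is validated by
signal recovery on data simulated from the model.

Replicate QC: average-linkage hierarchical clustering at 1 − Pearson
distance over samples; a replicate in a ≥ 3-replicate group is dropped when
it shares no flat cluster (cut at a configurable distance, default 0.15)
with any sibling; groups of two are skipped with a warning, and removal
never reduces a group below two.

Contrasts are per-probe stress-minus-control log2 mean differences per pool
(RT, RN, RL, RH); the Total contrast carries a two-sample t-test p-value
(Welch by default; pooled-variance optional). Probes with p ≥ 0.1 are
excluded; significant probes are transcriptionally high / low / no-change
at a 1.5-fold cut applied as |RT| ≥ log2 1.5 (identical to the
signed-linear ±1.5 convention). The D rule uses log2 units by default
(the matrix is log2-transformed before analysis), with the signed-linear
alternative available: D1 = |RN−RL|, D2 = |RL−RH|, D3 = |RN−RH|; a probe is
translationally regulated when any D ≥ 1 (non-strict, matching the rule's
parenthetical definition), and its trend is the pool with the highest
ratio, ties resolved High > Low > None (deterministic; the tie order is a
package choice). Probe-to-transcript collapse, where wanted, is the
per-transcript median. Fraction enrichment is percent of the pool sum.

## Sequence features

The longest-ORF search scans the three sense-strand frames for ATG…stop
spans (transcripts are stranded); ties go to the 5′-most start; codons
containing N never match. The default minimum is 1 codon so the search is
total; the coding-potential screen (`score_transcript_orfs`) applies the
conventional 10-codon minimum. CBI follows the Bennetzen–Hall form,
CBI = (N_opt − N_rand)/(N_tot − N_rand), over codons of amino acids with
≥ 2 synonyms and ≥ 1 declared optimal codon; N_rand is the expectation
under uniform synonymous usage; no degenerate codons → NA. The bundled
human optimal-codon set is a default, not a constant of the method, and
every call accepts a replacement.

PWM scanning uses log2 odds against a uniform background; both strands are
scanned and hits ≥ threshold are counted greedily left-to-right without
overlap. Motifs parse from MEME minimal format via Biopython.
Co-occurrence summaries report, per motif, total hits, promoters with ≥ 1
hit, mean hits per hit-carrying promoter (reported to 1 decimal) and the
percent of the promoter universe (2 decimals), plus the percent of
promoters containing every motif simultaneously (1 decimal) — the rounding
conventions of the printed summaries they reproduce. The promoter region
convention for this analysis is the 1 kb window 0.5–1.5 kb upstream of the
coding partner's TSS.

## Synthetic data: what it emulates, and what it does not

`generate_annotation` lays out one synthetic chromosome: coding genes with
enforced spacing (30 kb minimum gap, so class windows cannot collide),
up-regulated genes drawn short and exon-poor (1–3 kb, 1–3 exons,
immediate-early-like) and down-regulated genes long and exon-rich
(6–15 kb, 4–12 exons); lncRNAs placed inside their intended class windows
(promoter/terminal TSS offsets drawn from the 0.5–1.5 kb peak region),
~90% mono-exonic; distal lncRNAs in a zone > 5 kb from every gene. The
chromosome auto-sizes to the layout. Planted classes are re-verified by the
classifier at generation time, so a placement collision is an error, never
silent truth corruption.

`simulate_counts` draws negative-binomial counts (dispersion 0.1 by
default) with planted fold changes of 3 (up) and 1/3 (down) applied at both
time points, across nucleus and cytosol compartments. Per-class up
fractions default to the observed class table (distal 65.1%, overlapping
65.9%, terminal 70.7%, promoter 75.9%) and are planted as exact counts
(round(f·n)), not Bernoulli draws, so recovery error measures the pipeline,
not planting noise. 70% of coding genes go down; 30% of intron-bearing
genes get a 2× intronic up-shift. Library size is the configured depth
(10⁷) rather than the column sum: the simulated features are a small subset
of a full library, and using the subset sum as the depth would introduce a
composition bias that the genome-scale normalisation does not have.
Baseline expected counts are log-normal (median 200).

`simulate_coverage` gives every gene uniform body coverage (5 reads/bp)
plus a promoter pileup: a paused-PolII peak at TSS+100 (σ 150, amplitude
12) and two divergent lobes at ±1 kb (σ 300, amplitude 0.6), all
Poisson-sampled. The 30-min track scales coverage inside the
promoter-proximal zone (−1200 to +300 on the gene axis) by the pausing
gain; the zone contains the whole traveling-ratio promoter window and no
gene body, so the expected TR ratio equals the gain exactly; the 2-h track
reverts to control intensity. The downstream (+1 kb) lobe is part of the
static architecture and is not amplified — a simplification that keeps the
gain identifiable from the TR alone.

`simulate_polysome_arrays` plants, per transcript, a transcriptional class
(Total effect ±log2 3; "no-change" transcripts get a small real effect of
|log2| = 0.4, inside the 1.5-fold band — a zero effect would make the
p < 0.1 gate exclude them at random, which would test nothing about the
caller) and, for the regulated 60%, a trend with a pairwise contrast spread
of 2 log2 units; lncRNAs shift mostly into the High pool, mRNAs into the
None pool. Two probes per transcript, triplicate arrays, Gaussian log2
noise (σ 0.1). The recovery analysis computes contrasts on the log2 of the
emitted matrix directly; the emitted arrays are already comparable by
construction, and quantile normalisation is exercised by its own property
suite rather than inside the recovery loop.

What the generator does **not** emulate: read-level alignment artefacts,
isoform mixtures within loci, sequence-content realism beyond what PWM
scans need, batch effects or array spatial artefacts, and genome-scale
transcript censuses. Passing recovery tests therefore demonstrates that the
pipeline's rules and statistics are implemented correctly and are
identifiable under realistic noise — not that the pipeline would reproduce
any genome-scale census from raw sequencing data.

## Problem sizes and determinism

The test and acceptance runs use desk-scale sizes chosen as the package's
own defaults: 100–2,000 genes, up to 2,000 lncRNAs of a class, 1,200 array
probes, 1,000 random layouts for classifier/oracle equivalence, a 21³ grid
for the D rule. Every stochastic component is a pure function of
(config, seed); generators derive independent child streams per stage so
adding one stage never perturbs another.

## Known limitations

- The detection gate ("> 10 reads, > 1 RPKM") is applied to treated
  samples ("any treated sample" policy); a control-side or either-side
  policy is a one-line configuration away but changes the detected
  denominator.
- The normexp fit uses Nelder–Mead on the exact likelihood; for very small
  arrays (< ~200 probes) the parameter estimates are noisy and the
  "subtract" mode is more robust.
- The traveling ratio is undefined (NA) for genes with zero body coverage
  and is sensitive to the promoter-window convention for genes shorter
  than ~1 kb.
- The quadrant convention places zero log fold changes in the "up"
  half-plane; genes exactly at the boundary are rare in real data but this
  matters for noiseless synthetic input.
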