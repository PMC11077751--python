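# Methods

This note documents the models, the synthetic data the package is
validated on, the numerical choices, and the limits of what the tests
demonstrate.

## Site calling and the filter cascade

Reads are gapless alignments (read id, chromosome, 1-based start, strand,
bases in genomic-forward orientation, sample). Coordinates are 1-based
closed throughout. The pileup accumulates base counts on the **transcript
strand** — bases of minus-strand fragments are complemented — so an
A-to-I event is always the mismatch class "AG" regardless of the genomic
strand of the gene. Only read offsets `[12, L−2)` counted along the
biological read direction contribute ("read-end trimming"); for a
minus-strand read the biological start is its genomic right end. Reads
shorter than the trim window contribute nothing and are logged, not
errors.

Candidates are positions with ≥ 1 alternative-base read. The cascade then
runs per time point, in order:

1. **Both replicates** — the (position, mismatch type) must be detected
   (≥ 1 alt read) in every replicate of the time point.
2. **Trimming** — applied at pileup construction.
3. **SNP and splice-proximity** — positions present in the known-variant
   set, and intronic positions 1–4 nt from an annotated exon/intron
   boundary, are removed. Exonic positions adjacent to the boundary are
   retained.
4. **Multiallelic** — a position with more than one alternative base in
   *any* sample of the time point is removed. Raw candidate evidence is
   used rather than only replicate-concordant alleles: a second allele
   that happens to miss one replicate is still evidence the position is a
   genomic variant or artifact, and the concordance-first ordering lets
   exactly such sites through.
5. **Support** — pooled over replicates: editing level ≥ 0.02, coverage
   ≥ 10 reads, ≥ 3 edited reads. A strict mode applies the thresholds per
   replicate instead.

A site "present at a time point" means it survived the full cascade
there; presence across time points defines the prevalence groups f1–f5.
The cascade asserts its own monotonicity (each stage's survivors are a
subset of the previous stage's) and that every survivor satisfies the
support thresholds.

Per-time-point editing level is the pooled-count ratio
`EL_t = Σ edited / Σ covered` over replicates, weighting replicates by
coverage; a mean-of-ratios mode exists. When pileup coverage is supplied,
a covered-but-unedited time point yields EL = 0 — absence of editing at a
covered position is a measurement, not missingness; EL is left undefined
only where pooled coverage is below the floor (default 10).

Region annotation assigns CDS (split into synonymous/nonsynonymous by
recomputing the codon with the substituted base on the coding strand),
5'/3' UTR, intron, ncRNA or intergenic; positions whose overlapping
transcripts disagree on the class are excluded as ambiguous.

Deliberately **not** implemented: homopolymer and paralog filters used by
some editing pipelines — the cascade implements exactly the five steps
above; base qualities (synthetic reads carry none; a quality-floor hook
is the natural extension point for real data).

## Differential editing

Each replicate's (edited, non-edited) pair at a site is one beta-binomial
draw, k ~ BetaBinomial(n, α, β). Groups (time points) are fitted
separately and pooled by maximum likelihood and compared by

    LLR = 2[ℓ(group1) + ℓ(group2) − ℓ(pooled)].

Optimisation runs in (logit mean, log concentration) coordinates with
bounded L-BFGS-B and an analytic gradient; the concentration is capped at
10⁶ (the quasi-binomial limit) and method-of-moments estimates seed the
search. Group fits are additionally started from the pooled optimum, so
the LLR is non-negative by construction; values in (−10⁻⁶, 0) from
optimiser tolerance are clipped to 0. Zero-coverage replicates are
dropped from the likelihood, not imputed.

**Degrees of freedom.** The classical count is 2 (the alternative fits
one extra (α, β) pair). With duplicate designs, however, the
concentration is pinned at the binomial boundary in both null and
alternative fits, so only the mean contributes an effective degree of
freedom: in 1,000 null simulations at coverage 50, EL 0.2 and 2+2
samples, the LLR's 95th percentile is 3.73 (chi-square(1): 3.84;
chi-square(2): 5.99), and referring to chi-square(2) yields a type-I
error of 0.009 at nominal 0.05 versus 0.046 with chi-square(1). The
default is therefore df = 1, with df = 2 available by argument.
Significance is p ≤ 0.05 per comparison with no multiple-testing
correction, matching the per-pair reporting convention; a BH option
exists.

## Temporal patterns

Profiles (site × time point EL) are row-z-scored; constant or incomplete
rows are dropped. The fuzzifier is the Schwämmle–Jensen (2010) empirical
function of the matrix dimensions,

    m(N, D) = 1 + (1418/N + 22.05)·D⁻²
            + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134),

about 2.06 at the default scale (≈2,000 × 5). Fuzzy c-means with c = 6
alternates centre and membership updates minimising Σ u^m‖x−v‖²; a site
coincident with a centre takes membership 1 there (the limit rule); the
objective is asserted non-increasing every iteration and convergence is
an absolute objective change below 10⁻⁶. Because single k-means++-seeded
runs can stall in local minima that merge the two post-eye-opening
clusters, 8 restarts are run and the lowest-objective solution kept;
seeded runs are bit-reproducible. Clusters are renumbered by the time
index of each centre's peak (ties: earlier secondary peak, then original
index; the reordering is idempotent). Hard assignments are argmax
memberships, with the membership value retained.

## Splicing

PSI is reported on the 0–100 scale. The coverage filter keeps an event
when inclusion+exclusion reaches 25 reads (IR) or 15 reads (other types)
in at least ⌈20% of samples⌉. IR events with boundary read counts are
additionally screened by a two-sided binomial test of the two counts
against 0.5 (imbalance indicates mis-assigned reads). Differential
splicing between groups: ΔPSI is the difference of group means over
defined PSIs; the range statistic is the signed gap between the groups'
PSI sets — min(g₂)−max(g₁) when ΔPSI > 0, mirrored otherwise — and an
event is significant iff |ΔPSI| ≥ 15 and range ≥ 5. Event *discovery* is
input, not computed: the module owns the PSI arithmetic and filters.

## Translational efficiency

Genes with total count < 10 across all samples are discarded. Size
factors are plain median-of-ratios against the per-gene geometric-mean
reference (genes with any zero excluded from the reference), computed
separately per library type since RNA-seq and Ribo-seq library
compositions differ; a joint mode exists. No geometric-mean-1 rescaling
is applied afterwards — the raw factors already sit near 1 for comparable
libraries, and rescaling would break the exact absorption of a
per-sample scaling constant into that sample's factor. Expression is
length-corrected by CDS length in kb. TE averages replicate expression
per time point before the Ribo/RNA ratio; entries with zero RNA are left
missing.

Differential TE fits, per gene, a negative-binomial GLM (log link, size
factors as offsets) with design `library type + time + library:time` over
the two time points of a comparison, and Wald-tests the interaction
coefficient — the log TE fold change. The gene-wise dispersion is a
method-of-moments estimate from a Poisson pre-fit's means, with squared
residuals inflated by n/(n−4) for the four fitted mean parameters, and
floored at 10⁻⁸; there is no shrinkage or empirical-Bayes moderation,
a deliberate simplification. Significance: |log2FC| ≥ 1 and BH-adjusted
p ≤ 0.05. At the default benchmark (planted log2FC = 2, mean count 200,
2+2+2+2 samples) the test reaches ~0.85 power with the mean estimate
within 0.07 of truth and ~2% null calls.

## Integration

The editing×splicing association is a two-sided Fisher exact test on the
2×2 gene-presence table; a stratified mode bins genes by transcript-length
deciles and combines strata with a Mantel-Haenszel test (a stand-in for
length-confounding control — the exact normalisation used for the
original figure is not specified anywhere authoritative).

Each site in a gene with both editing and splicing is paired to the
same-gene event minimising the distance to the event's alternative
segment (0 when inside; ties broken IR > EX > Alt3 > Alt5 > MIC, then
smaller event id — a documented package convention). Pearson r between
the EL and PSI trajectories is computed on time points where both are
defined (≥ 3 required); strength categories partition |r| with ≥ on the
lower bound (Strong ≥ 0.7, Moderate ≥ 0.5, Weak ≥ 0.3, else None), and
"significantly strong" is |r| ≥ 0.7 with p ≤ 0.05. Pair summaries use the
Wilcoxon rank-sum test (via the exact-capable Mann–Whitney U) on
distances of positive vs negative pairs and a contingency test of event
type by correlation sign, plus a joint fuzzy clustering of the z-scored
EL and PSI trajectories of strong pairs into 6 groups.

Gene classes AS&ES / AS&Non-ES / Non-AS&ES / Non-AS&Non-ES summarise
translatable-transcript counts (mean ± normal CI) and TE (pairwise
rank-sum tests). dTE genes are partitioned by differential-splicing /
differential-editing status ("dEL genes" = genes with ≥ 1 differentially
edited site; "dPSI genes" = genes with ≥ 1 significant event), with
up/down fractions per group. ADAR correlation relates per-time-point site
counts and shared-site mean EL to normalised ADAR-gene expression at the
RNA and Ribo level (≥ 3 time points required; constant series flagged).

## The synthetic dataset

The generator's defaults are the package's study conditions: 200
multi-exon genes on one chromosome (3–5 exons of 150–400 nt, introns
400–900 nt, 10% non-coding, CDS divisible by 3), 5 time points
(E13/P0/P6/P21/P42) × 2 replicates, 2,000 true A-to-I sites at ~50 reads
per replicate per site, read length 50. Sites are planted ≥ 110 nt apart
so reads supporting different sites never overlap.

Six editing-level trajectory families echo the developmental shapes: a
post-eye-opening plateau (0.02, 0.05, 0.10, 0.50, 0.52), a gradual rise
to the last time point (0.03, 0.06, 0.12, 0.28, 0.55), and four
single-time-point spikes (0.45 at one time point, 0.01 elsewhere), each
jittered per site with N(0, 0.02). Edited read counts are
Binomial(coverage, EL_t). The −1 neighbour of a planted site is
G-depleted and the +1 neighbour G-enriched by ±0.15 around the 0.25
background, emulating the ADAR substrate preference.

Contaminant classes (fractions of the true-site count) and the filter
that removes each: SNPs at known-variant positions with mismatch 0.5 or
1.0 (4%, SNP filter); multiallelic positions with two alt bases (3%,
multiallelic filter); low-support sites violating exactly one support
rule — EL ≈ 0.015 at deep coverage, pooled depth ≤ 8, or exactly 2
pooled edited reads (4%, support filter); sites 1–4 nt into an intron
(2%, splice-proximity filter); read-end artifacts whose mismatches sit
only in the trimmed read regions (2%, trimming); and replicate-1-only
signal (3%, both-replicates filter). A uniform 2×10⁻⁴ per-base
sequencing-error background generates non-A-to-I mismatches; errors are
excluded at planted contaminant positions so each class remains removable
by exactly its intended filter.

Paired splicing events (240 sites, half positive, half negative) get PSI
trajectories constructed so the z-space sample correlation with the
site's EL trajectory is exactly ±0.95 before counting noise
(inclusion ~ Binomial(Poisson(50), PSI/100)); positive pairs are placed
0–200 nt from their site and negative pairs 600–1500 nt (clamped to the
gene), planting the "positively correlated pairs are closer" structure.
Counts are negative-binomial with variance μ + αμ² (α = 0.05), gene
baselines log-normal around 200, size factors uniform on [0.75, 1.3]; 40
dTE genes change TE by 2^±2 at one random adjacent boundary, with the
down direction more likely in genes that also carry splicing and editing
(0.88 / ~0.67 / 0.5), echoing the buffering pattern. The Adarb1 (ADAR2)
expression trajectory is proportional to the planted per-time-point
active-site count, so editing activity and ADAR2 expression are coupled.

What the simulator does **not** model: mapping ambiguity and alignment
error, base-quality structure, indels, overlapping genes and multi-isoform
ambiguity at scale, FASTQ-level error profiles, P-site offsets, library
GC/length biases, and any real developmental biology — time points are
labels with an ordinal index. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
generative assumptions, not performance on real sequencing data.

## Problem sizes and determinism

The default end-to-end run (2,000 sites, 10 samples, ~1.2 M reads)
completes in about a minute on one CPU; calibration measurements use
2,000 null simulations for the editing test and 300 simulations for the
splicing and TE benchmarks. All randomness flows from a single root seed:
the simulator derives per-stage seeds from it, fuzzy c-means restarts are
seeded deterministically, and rerunning with the same seed reproduces
byte-identical outputs (hashed in the pipeline manifest).
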