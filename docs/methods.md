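# Methods

This note documents the models implemented in `bacrnaseq`, the parameters
that matter, the synthetic data used to validate them, and the numerical
choices made where the design was genuinely open.

## Read alignment

The genome (single replicon, alphabet ACGTN after sanitization) is indexed
with an FM-index: suffix array by prefix doubling, Burrows–Wheeler
transform, cumulative symbol counts C, an occurrence table sampled at a
configurable stride (dense by default, which allows backward search over
thousands of reads to be vectorized), and suffix-array samples at stride 4
recovered by LF-walking. Exact matching of a read of length m costs O(m)
rank operations. `N` never matches anything, in the index or in a read.

Reads without an exact match (either orientation) enter seed-and-extend.
For an edit budget k = ⌈k_frac·m⌉ (k_frac = 0.15), the read is partitioned
into s equal non-overlapping seeds; any alignment with ≤ s−1 edits must
contain an error-free seed, so exact seed hits enumerate all candidate
loci. Instead of jumping directly to s = k+1 (which for short seeds floods
the candidate list), s escalates from 2 upward and stops as soon as the
best penalty found is provably unbeatable: an alignment with ≥ s edits
costs at least s × (minimum per-edit cost in this read), so once
best < s·min_cost the search is complete. Seeds with more than 200 exact
occurrences are deferred to later (longer-seed) levels. Candidate windows
(locus ± k) are scored by a banded dynamic program (numba-compiled) that
fills only entries within k of the alignment diagonal: mismatch costs
min(Phred, 30), insertion/deletion cost 30, matches cost 0; ties are broken
by fewer edits, then leftmost placement. All placements attaining the
minimum penalty are reported, each with weight 1/n_optimal; alignment is
therefore deterministic and free of random tie-breaking.

Reads shorter than 12 nt are counted as unaligned. SAM export (optional)
reconstructs CIGAR strings by an unbanded traceback; secondary placements
carry flag 256, unmapped reads flag 4, and edit counts the NM tag.

## Coverage and transcript boundaries

Per-nucleotide, per-strand coverage accumulates alignment weights over each
alignment's reference span. For forward-stranded protocols the alignment
orientation is the transcribed strand ('rev' flips it); unstranded
libraries pool into a single track consulted by both strands' analyses.

Transcript seeds are (a) annotated genes and (b) maximal runs of at least
w = 10 nt with coverage ≥ T on the strand, outside same-strand genes, with
T = max(2, ⌈genome-wide mean coverage⌉) — the max(2, ·) floor keeps novel
calls conservative in shallow data. Each seed is extended outward in
windows of 5 nt. The window's (rounded) read mass x_r is classified
transcript-vs-background by comparing Poisson(x_r; step·λ) against the
background probability of x_r summed over a step-nt window, modeled as a
sum of iid geometrics, i.e. negative binomial with size = step and success
probability p_bg. λ is the mean coverage of the original seed and is not
refitted during extension (refitting lets a seed drift into its
neighbour). p_bg comes from method of moments on coverage antisense to
annotated coding genes: a geometric on {0,1,2,…} with mean μ_bg has
p = 1/(1+μ_bg); with no CDS annotated, the sub-threshold genome-wide mean
substitutes. Ties in the likelihood comparison extend (a window exactly as
likely under the transcript model is kept). Extension halts at the genome
edge, at an adjacent seed, or at the first background call; flanking
zero-coverage positions gained by extension are then trimmed (the original
seed is never shrunk).

Extended seeds that overlap always merge; abutting seeds merge when their
mean coverages are within a factor 2 of each other — a deliberately simple
stand-in for a similarity test, adequate because extension already stops at
coverage discontinuities. Transcripts containing annotated genes report
strand-aware 5′/3′ UTR lengths measured from the outermost member genes;
unannotated transcripts are `novel-antisense` when at least half their span
lies under opposite-strand genes, else `novel-intergenic`.

## Quantification and normalization

A read contributes its weight to every transcript on the matching strand
whose span contains the read's midpoint; midpoint assignment prevents
double counting where transcripts abut. Each sample is normalized by the
upper quartile of its non-zero transcript counts — the order statistic at
rank ⌈0.75·n′⌉ without interpolation — and scaling factors are anchored at
the geometric mean of the per-sample quartiles so they are dimensionless
and symmetric. Expression is K·count/((length/1000)·UQ) with K = 1000; the
measure is invariant under rescaling a sample's counts.

## Differential expression

With replicates, per-condition sample means and variances (one point per
gene per condition) feed the mean–variance smoothing; without, the two
conditions act as surrogate replicates of a pooled condition — variability
is then overestimated and conclusions deliberately weaker. Mixed designs
(one condition unreplicated) fall back to surrogate mode.

The variance trend is lowess (tricube weights, span 0.3) of sample variance
on sample mean, interpolated between fitted points, extended quadratically
beyond the largest observed mean, and floored at μ(1+10⁻⁸) so the negative
binomial is defined. Robustness iterations are disabled on purpose:
per-gene sample variances from few replicates are strongly right-skewed,
and down-weighting the (legitimate) large values pulls the curve ~40%
below the true conditional mean, which destroys type-I error control.
When true replicates exist, the test uses max(fitted, per-gene) variance —
the conservative sharing rule — so a gene whose own spread exceeds the
trend is never tested with the smaller trend variance. With fewer than five
positive-mean genes a method-of-moments quadratic v(μ) = μ + aμ² replaces
the lowess fit.

The exact test conditions on S = R1 + R2. Null means are split
proportionally to replicate counts, μ_i = n_i·q0 with q0 = (R1+R2)/(n1+n2),
and the sum over n_i replicates has variance n_i·v(q0). Each split (x, S−x)
is scored as the product of two negative binomial pmfs (Poisson when the
variance does not exceed the mean); the two-sided P-value is the normalized
sum of split probabilities not exceeding the observed one, with terms summed
in sorted order so that swapping the conditions gives bit-identical results.
S = 0 yields P = 1. Benjamini–Hochberg adjustment (statsmodels) yields
q-values; the default significance cutoff is q < 0.01. Non-integer
normalized sums are rounded for the enumeration.

Known limitation: the variance trend is a regression on the *observed*
mean, which is correlated with the observed variance; the fitted curve
therefore sits a few percent below the true mean–variance relation
(errors-in-variables attenuation). The conservative sharing rule absorbs
this in practice — null calibration and FDR are verified in the acceptance
suite — but individual points of the curve can be 10–20% off, so accuracy
claims about the curve are made on interval averages, not single points.

## Operon prediction

For adjacent same-strand gene pairs the prior probability of
co-transcription is 1 − D/P (D = maximal same-strand runs, P = adjacent
same-strand pairs), clamped to [0.05, 0.95] for degenerate annotations.
Two features enter a naive Bayes posterior:

- **Intergenic distance** d = downstream start − upstream stop − 1
  (negative when genes overlap). Class likelihoods are Epanechnikov KDEs
  (Silverman bandwidth rescaled for that kernel, h = 2.34σn^{−1/5}) over
  same-strand vs opposite-strand adjacent distances. Because both
  estimates have compact support, a query outside a class's training range
  is censored to the range boundary — an extrapolated ratio would reflect
  only which class happened to reach further — and the opposite-strand
  density is reflected at its empirical minimum to undo kernel boundary
  bias at the hard spacing floor that independent transcription units keep.
- **Expression correlation** ρ: Pearson correlation of per-sample-centered
  log expression (centering removes sample-level common modes, e.g.
  residual normalization error, that otherwise correlate *every* pair).
  With fewer than three samples the feature is inert. Class densities are
  KDEs on proxy labels — overlapping same-strand pairs as positives,
  opposite-strand pairs as negatives — reflected at ±1 and mixed with a
  10% uniform component: the proxy sets are small, and a raw KDE's hard
  zeros would veto any correlation value it happened not to cover.

Pairs with posterior above 0.5 chain into maximal multi-gene operons; each
operon reports its weakest pair posterior. Densities are floored at 10⁻⁹.

## Synthetic data

`simdata` generates complete, ground-truthed experiments: an iid random
genome at a chosen GC; genes laid out in transcription units of geometric
size (mean 2.5 genes — giving a co-transcription base rate near 0.75 among
same-strand pairs, the range annotated enterobacterial genomes show);
within-operon gaps with a 25% overlap component (translational coupling)
and a gamma-shaped remainder, mean 20 nt, capped below the between-unit
floor; between-unit gaps of 60 nt (terminator + promoter footprint) plus an
exponential tail, mean 150 nt; consecutive units keep the strand with
probability 1/2. Expression is drawn per operon from a mixed law — with
probability 1/2 exponential (mean θ = 200), else Pareto(α = 1.5) truncated
at 100θ — giving the heavy upper tail real libraries show; member genes
share one abundance exactly. Optional per-operon log-normal condition
factors (condition_sd, default 0) create correlated variation across
conditions; differential expression is planted per operon so abundance
sharing survives in every condition. Transcripts extend operons by
exponential 5′ UTRs (mean 25 nt, the transcription-start-site jitter scale)
and 3′ tails (mean 15 nt). Reads (length ≥ 20, default 72 nt) are drawn per
transcript with Poisson counts proportional to abundance × length, start
positions uniform within the transcript (uniform fragmentation),
strand-specific orientation, and each base flipped with probability
10^(−q/10) at its Phred quality (default 30) — so the quality-aware
aligner is tested against the exact error process it models.
`simulate_model_coverage` instead draws per-nucleotide coverage directly
from the boundary model's assumptions (Poisson inside transcripts,
geometric background), which is the right substrate for testing the
extension rule in isolation.

What the generator does **not** emulate: positional and GC bias,
PCR duplicates, paired ends, rRNA carry-over, and condition-dependent
operon structure. Passing tests therefore demonstrate correctness of the
algorithms under their own model assumptions, not robustness to every
artifact of real libraries.

## Validation problem sizes

The acceptance suite and `scripts/acceptance.py` use desk-scale problems
chosen to keep each check well-powered: exhaustive FM-index/naive-scan
equivalence on fifty 2 kb genomes; 5000 reads with planted q30 mismatches
on 50 kb; transcript-boundary recovery at 20× on 200 kb (120 genes) and
novel-call specificity on a 2 Mb annotated-only simulation; the exact test
against brute-force enumeration on 200 random instances (S ≤ 200);
differential expression on 2000 genes with 2+2 replicates, dispersion
0.05, and 400 direction-balanced 4-fold changes pooled over three runs
(pooling reduces the quantization of the empirical FDR, which with ~400
discoveries moves in steps of ~0.25%); operon pairs pooled over six
300-gene genomes with 4 conditions × 2 replicates and condition_sd = 1.2
(strongly contrasting conditions, as chosen in practice to elicit
regulation); and a full two-condition pipeline on 100 kb with ~200k reads,
checked for byte-identical reruns.
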