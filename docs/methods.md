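# Methods

This note documents the statistical model behind `sifcall`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Coordinate system and QC

All coordinates are 0-based half-open (BED convention). A genome is
digested in silico by a literal forward-strand scan for a palindromic
recognition motif (HindIII `A^AGCTT`, MboI/DpnII `^GATC` as presets);
degenerate (IUPAC) sites and methylation-sensitive digestion are out of
scope. Fragments tile each chromosome with no gaps, so position-to-fragment
lookup is a single `searchsorted` on the cut boundaries.

Read pairs are deduplicated on the full (chrom, pos, strand) signature of
both ends before any counting, since PCR duplicates directly inflate USF
scores. Ligation classes: both ends in the same fragment → self-ligation;
ends in immediately adjacent fragments (index offset exactly 1) →
re-ligation; anything else, including all inter-chromosomal pairs → valid.
Strand-orientation refinements (dangling-end detection) are deliberately
omitted; the adjacency rule is a documented package choice, since standard
pipelines vary. Calling is intra-chromosomal by default because the
distance-decay background is undefined across chromosomes; a flag admits
inter-chromosomal records with the background filter bypassed.

## Mixture model

USF scores are modeled as ω₁Pois(λ₁) + ω₂Pois(λ₂). EM runs in log space on
the unique-score representation (the likelihood depends on data only
through score multiplicities), with:

| parameter | default | rationale |
|---|---|---|
| init λ₁, λ₂ | 25th / 90th score percentile (λ₁ ≥ 0.5) | random ligations dominate Hi-C libraries, so the low component starts in the bulk |
| init ω | (0.9, 0.1) | same consideration |
| tol | 1e-6 on log-likelihood | stable to well below the resolution of any downstream decision |
| max_iter | 1000 | |
| bootstrap rounds | 50 | enough for quartile-based inner fences to be meaningful |
| Np (null resampling) | 100 000 | stabilizes FP densities to ~3 decimals over typical score ranges |

Label switching is resolved by sorting λ ascending after convergence. The
all-identical-scores case is reported as a degenerate fit (λ₁ = λ₂, initial
weights retained). BIC (p = 2k − 1 free parameters) is exposed as a k = 1
vs k = 2 diagnostic only; calling always uses k = 2.

The bootstrap resamples M observations with replacement, refits, and per
parameter discards round estimates outside the inner fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] before averaging; trimming is per-parameter,
and averaged weights are renormalized to sum to one.

## Distance decay and background likelihood

The empirical ligation probability versus genomic distance is binned
logarithmically (50 bins per decade from 1 kb by default). The power law is
fitted by least squares on log10(density) vs log10(distance), where density
is the bin probability divided by bin width: with logarithmic bins, fitting
raw per-bin probability of a d^α law would recover α + 1, so the
density form is the binning-invariant one. Below the fitted range the
probability plateaus at its d_min value, mirroring the short-range
flattening of contact frequency.

The background likelihood of a fragment pair (F_i, F_j) multiplies, over a
window of K = 5 fragments on each side of F_j (truncated at chromosome
ends, excluding F_j), the terms (1 − E)^|k−j| · P(F_i, F_j), with P
evaluated at the fragment-midpoint distance. The exponent is the absolute
index offset — a signed offset would make the product explode for
left-side neighbors — and P is constant across the product. The window is
applied around F_j only, so the likelihood is deliberately asymmetric in
its two anchors; tests assert the asymmetry rather than hiding it.
Digestion efficiency E defaults to 0.7 (typical Hi-C digests run 60–80%
efficient); a diagnostic estimator (fraction of read ends within 500 bp of
a cut site) is provided but never substituted silently. Records whose
likelihood exceeds the threshold are removed as linear-closeness
artifacts; the default threshold is data-adaptive, the 99th percentile of
the likelihood over records at fragment offset > 20, because no principled
fixed value exists across libraries.

## Calling

TP_d is the Poisson density at the proximate mean λ₂; FP_d is the
normalized histogram of Np scores resampled uniformly from the observed
score multiset of the background-filtered records (so linear-closeness
artifacts do not inflate the null). FDR_d = FP_d/(FP_d + TP_d) is applied
as a step function over integer scores; scores above the support inherit
the last defined value (conservative tail). A record is called when
score > FTR (strict) and FDR_score < cutoff; defaults FTR = 1,
FDR < 0.1. Calls adjacent on both anchors (index offset exactly 1 on each
side) with equal scores merge transitively, like ChIP-seq peak summits;
the merged anchor interval spans the member fragments and its length is
the reported per-side resolution.

A global Benjamini–Hochberg procedure is intentionally not offered: with a
single library there is no replication to support p-value-based inference,
which is the reason the local-FDR route exists.

## Annotation and evaluation

Promoter windows are strand-aware (−5 kb/+1 kb of the TSS, mirrored for
minus-strand genes); distal windows are ±100 kb of any TSS outside every
promoter window. Anchor membership is tested by anchor midpoint so an
anchor sits in at most one promoter; ties break by nearest TSS then gene
id. The distal end's "closest gene" minimizes |midpoint − TSS| over all
genes. Loop-set comparison uses reciprocal anchor overlap with symmetric
slack and is one-to-many aware, so the two "common" counts of a Venn
partition may differ. APA sums (2w+1)×(2w+1) submatrices centered on loop
bin pairs, excluding loops within 2w bins of the diagonal, and reports the
central pixel over the mean of the w×w lower-left corner block (the corner
farthest from the diagonal); the other corner ratios are diagnostics. ROC
evaluation consumes a caller-supplied universe of putative loops, labels
them by reference overlap, predicts by overlap with the called set at a
sweeping score threshold, and integrates by trapezoid with (0,0) and
(1,1) endpoints.

## Synthetic world

The generator produces one chromosome of geometric-length fragments
(default 1000 fragments, mean 4 kb — a 6-cutter's scale), 50 planted loops
at fragment offset ≥ 50 with counts ~ Pois(λ₂ = 8), a power-law background
(α = −1) whose counts are Pois(λ₁ = 1) per touched pair, and
self-/re-ligation artifacts at rates 0.10/0.05. The total read budget
defaults to 4000 pairs, which leaves random-ligation records at ~97% of
the USF table — the regime the mixture model assumes. Background
separations are sampled distance-first and placed uniformly in the
feasible span, so the realized distance marginal is exactly d^α; draws at
fragment offset ≤ 1 are rejected because they would masquerade as QC
artifacts. All randomness flows from one explicit seed.

What the generator does **not** emulate: fragment-level biases (GC,
mappability, length), TAD/compartment structure, inter-chromosomal
contacts (available behind a flag but not in the default world), and the
coupling of digestion efficiency to near-diagonal counts (artifact rates
are set directly instead). A green end-to-end test therefore establishes
the statistical machinery, not robustness to real-library bias.

## Known limitations

* Observed USF scores are zero-truncated (a pair with no reads is never
  seen), but the mixture likelihood is untruncated, exactly as printed.
  On the default synthetic world this biases λ̂₂ upward by roughly 0.9
  and shifts the local-FDR score cutoff up by one in about half of the
  replicates; the end-to-end planted-loop sensitivity averages 0.789
  (empirical FDR 0.096) over 100 replicates, with ~0.80 the ceiling even
  when oracle mixture parameters are substituted. A truncation-aware EM
  would remove the bias but would no longer maximize the stated
  likelihood, so it is not implemented.
* The FDR → single-score-cutoff mapping some descriptions imply is not
  assumed; the general per-score gate reproduces the worked eight-fragment
  example either way. "Weak interactions" (scores close to but below the
  FTR) are reported only as a diagnostic label.
* The background-likelihood reading (offset exponent, constant P,
  high-likelihood removal) is one of several consistent with its terse
  definition; it is isolated behind `BackgroundConfig` so alternatives can
  be swapped without touching the caller.
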