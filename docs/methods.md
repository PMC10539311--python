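# Methods

This note documents the statistical models implemented in `chartographer`,
the choices made where the methods literature leaves the design open, and
what the synthetic-data tests do and do not establish about real data.

## Data model

A *contact* is one RNA-DNA proximity-ligation event: an RNA-side mapping
position (the transcript's locus of origin) joined to a DNA-side genomic
position. Contacts live in pairs-style text files (1-based on disk, 0-based
in memory, RNA side first) and are aggregated into sparse RNA x genomic-bin
count matrices over either uniform tilings (100 kb / 1 Mb) or explicit
window lists (e.g. gene-proximal regulatory regions). For a cis contact the
*travel distance* is delta = (DNA position) - (RNA position); trans contacts
have no travel distance.

## Delocalization scores

For RNA *i* with `N_i` total contacts, let `K_i` be its *far* contacts:
off-chromosome contacts in trans mode, or cis contacts with |delta| > D in
cis mode (D defaults to 1 Mb, overridable to 10 Mb; |delta| = D counts as
near). The null model is beta-binomial,

    E[K_i | N_i]   = pi_i N_i
    var[K_i | N_i] = pi_i (1 - pi_i) N_i (1 + (N_i - 1) gamma)
    logit(pi_i)    = eta_chr(i) + eta_expr ln N_i

with chromosome-specific intercepts (no global intercept), a log-expression
slope, and a shared intraclass-correlation overdispersion gamma in [0, 1).
The model is fitted by joint maximum likelihood on mRNAs only (RNAs with
fewer than 50 total contacts are dropped), the premise being that mRNAs have
no specific chromatin targets, so their spread calibrates expression,
chromosome and sample biases. Optimization uses L-BFGS-B on
(eta, logit gamma) initialized from a binomial GLM plus method-of-moments
gamma, with random restarts and a Nelder-Mead polish for the flat
binomial-limit direction; standard errors come from the numerical Hessian.

The fitted null doubles as an empirical-Bayes prior: gamma is the
beta-binomial ICC, so the implied Beta mixing distribution has concentration
`alpha + beta = 1/gamma - 1` and mean `pi_model,i`. The conjugate update
with the observed counts gives the shrunken rate `pi_post,i`, and the
calibrated score is the log2 odds ratio

    Delta_i = [logit(pi_post,i) - logit(pi_model,i)] / ln 2

(a natural-log variant is available via `base='ln'`). The tail probability
compares the posterior against the prior at the RNA's own covariates:
`p_deloc,i = P(prior draw >= posterior draw)`, computed by deterministic
quadrature (vectorized Gauss-Legendre over the posterior support where the
density is bounded, adaptive quadrature to 1e-8 otherwise, Monte-Carlo
fallback flagged in the log). Small values indicate delocalization; the
complement reads out ultralocalization. Per cell state, replicate p-values
are combined with Fisher's method (df = 2 x replicates, p floored at
1e-300), BH-corrected across RNAs within each (state, side) family, and RNAs
declared delocalized / ultralocalized at FDR 0.05. Under the null this
screen reads out approximately the 5% tails of the mRNA score distribution;
the calibration test verifies the empirical CDF of p at 0.05 stays in
[0.03, 0.07] for 2,000 RNAs with N_i >= 500.

The raw (uncalibrated) score — the log2 far/near contact *density* ratio
using summed chromosome or window lengths — is computed for reference but
not used for classification.

## Generative contact model

Conditional on the per-RNA per-chromosome contact totals, an RNA transcribed
at positions {r_k} contacts bin j of its own chromosome with multinomial
probability

    p_j propto b_j * sum_k rho(d_j - r_k)

and bins of a trans chromosome with probability proportional to b_j alone,
renormalized within each chromosome because the totals are conditioned per
chromosome. The distance kernel rho is the empirical per-bp density of mRNA
travel distances over log-spaced bins (25 per decade from 100 bp up to the
longest chromosome), mixed with a uniform floor of weight 1e-3 so empty and
beyond-range bins stay positive, and normalized to integrate to one. The
DNA-locus bias b_j is the trans-chromosomal mRNA coverage per bin plus a
pseudocount of 0.5, normalized to sum one. Kernel evaluation uses |delta| at
bin midpoints against the gene midpoint by default; per-read source
positions can be supplied for exact convolution at small scales. Simulated
model maps draw one multinomial realization per RNA per chromosome, so
observed and simulated per-chromosome totals agree exactly by construction.

## Differential testing in interactome space

Rows are (RNA, locus) interactions, columns are samples; interactions with
fewer than 10 reads in fewer than 2 of the designated filter samples are
excluded. Size factors are median-of-ratios against row geometric means,
estimated on a designated row subset (all-positive rows only) and rescaled
to geometric mean one.

The engine is a self-contained moderated negative-binomial GLM, not a
DESeq2 wrapper; it is validated by its calibration and recovery properties
rather than by matching another implementation's numbers:

- per-row dispersion by method of moments on size-factor-normalized counts
  within design cells, floored at 1e-8, then shrunk 50/50 toward the 10%-
  trimmed mean dispersion of rows in the same base-mean stratum (about 20
  quantile strata);
- batched IRLS with a log link, log size factors as offsets, and a weak
  normal prior (sd 5 on the natural-log scale) on non-intercept
  coefficients. The prior leaves well-populated cells untouched but keeps
  estimates and Wald standard errors finite when a design cell is all zero,
  where the unpenalized Wald statistic degenerates (Hauck-Donner effect);
- a Wald test on the coefficient of interest against a t reference with
  4x residual degrees of freedom. The normal reference is anticonservative
  with two replicates per condition; the factor 4 reflects the quartered
  variance of the 50/50-shrunk dispersion estimate. Type-I error at
  alpha = 0.05 is verified to lie in [0.03, 0.07] on null simulations;
- BH correction across rows, and LFC shrinkage toward zero under a normal
  prior whose scale is the empirical SD of the raw log2 fold changes.

Three analyses are built on this engine, each using treatment coding with
explicit reference levels and re-fitting after relabeling to switch the
reference state (rather than recombining coefficients):

1. **Observed vs model** (`cell + observedORmodel + cell:observedORmodel`):
   interactions whose shrunken LFC(observed/model) exceeds log2(1.3) at
   adjusted p < 0.05 are flagged as not explained by the proximity model
   (candidate type III / affinity-driven contacts). The threshold is
   configurable (a linear-scale 1.3 variant exists).
2. **Relocalization** (`cell + mapType + cell:mapType`): observed maps are
   compared against *expression-only* maps in which every bin of RNA i
   carries the constant N_i; a significant interaction coefficient flags
   state dynamics not explained by RNA abundance.
3. **Chromatin association** (`cell + sequencing + cell:sequencing`):
   gene-level ChAR-seq vs total RNA-seq counts; the shrunken `sequencing`
   coefficient is the chromatin-association score, genes are labeled
   enriched/depleted at adjusted p < 0.05 beyond +-log2(3) (the fold-scale
   reading of the threshold is exposed via `min_fold`), and the interaction
   coefficient with its adjusted p reports state differences in association.
   Genes under 10 combined counts are excluded; size factors use rows with
   at least 50 combined counts.

## UTL classification

Each unannotated transcribed locus gets four tags — dominant
transposable-element family and TE-score (dominant family's reads over all
reads, unlabeled included; ties break lexicographically and are logged),
nearest active cis-regulatory element within +-300 bp of the 5' end,
readthrough (5' end within the strand-oriented window [3' end - 200 bp,
3' end + 100 bp] of a same-strand gene; "+" is downstream in the gene's
transcription direction), and antisense (>= 10% of the UTL length
overlapping an opposite-strand gene body). The final class is the first
match of: tRNA-derived (tRNA, score > 10%) > snRNA-derived (small-RNA
family, score > 10%) > readthrough > CRE-derived(subtype) > repeat-derived
(score > 50%) > antisense > intergenic. Readthrough requires the same
strand by default (readthrough continues the gene's transcription); an
any-strand flag exists.

## caRNA-gene network and enrichment

The proximal regulatory region (PRR) of a gene is the 100 kb window from
10 kb upstream of its TSS to 90 kb downstream in the transcription
direction, reflected for "-" strand genes and clipped (flagged) at
chromosome ends. The interactome counts each RNA's contacts inside each
PRR; a contact inside two overlapping PRRs counts once per gene. Edges are
non-stable differential contacts signed against the target gene's expression
class: positive when the contact is up in the state where the gene is up,
negative when crossed, neutral when the gene is stable.

Positive-edge enrichment is the observed positive fraction over its
expectation under a null that permutes gene DE labels across genes
(label counts preserved), averaged over 1,000 permutations. The 95% CI comes
from 10,000 bootstrap resamples of edges; each resample recomputes both the
positive fraction and the permutation-expected null fraction on the
resampled edge set (via joint class-x-label category counts), so the CI
reflects the finite-sample noise of the label marginals as well — without
this the CI undercovers a planted fold. Significance is the CI excluding
fold 1. Metagene profiles average an RNA's contacts in windows around
feature centers, normalized by the RNA's genome-wide mean per-bin count so
background is 1.

## Synthetic data generator

The generator draws data from the same structure the analysis assumes, with
planted ground truth, at a desk scale chosen to run in seconds: 3
chromosomes x 30 Mb, 500 RNAs (300 mRNA / 100 lncRNA / 50 ncRNA / 50 UTL),
2e5 contacts per sample, two states (ES, DE) x two replicates, paired
RNA-seq at the same depth with two replicates per state.

- Expression weights are log-normal (mu 0, sigma 1); per-sample totals N_i
  are multinomial at the configured depth. 30% of RNAs get a state
  log2-fold-change of magnitude 1.5-3; DE labels derive from |LFC| > 1.
- The trans split is N_trans ~ BetaBin(N_i, pi_i, gamma) with
  logit pi_i = eta_chr + eta_expr ln N_i + planted offset (defaults
  eta_chr ~ logit(0.15-0.17), eta_expr 0, gamma 0.02). XIST-like RNAs
  multiply the trans odds by 1e-3 (not exactly 0, avoiding degenerate
  likelihoods) and carry a positive cis offset.
- The cis near/far split at the threshold D is likewise beta-binomial around
  the kernel-implied far fraction p0 (computed from the gene midpoint with
  chromosome-end truncation), with planted cis offsets added on the logit
  scale. Contacts are then placed from the kernel *conditioned on the
  class* via exact inverse-CDF sampling, so with gamma = 0 and no offsets
  the unconditional placement law is exactly the kernel mixture (verified
  by a probability-integral-transform KS test at n = 1e5). This RNA-level
  overdispersion in cis is what makes the fitted cis null have gamma > 0
  and the empirical-Bayes screen informative.
- The kernel is a truncated power law (|delta| + delta0)^-alpha with
  alpha = 2, delta0 = 10 kb and a 2% uniform floor — a ~100-fold density
  drop 100 kb from the locus, the scale of decay seen in real contact maps.
  Source positions are uniform within the gene body (emulating
  fragmentation). An optional log-normal per-bin DNA bias is applied by
  rejection; trans contacts choose bins proportional to the bias.
- Planted type III peaks reroute 5% of a boosted-expression RNA's cis
  contacts into a 100 kb window 1-3 Mb from its locus; planted
  relocalization reroutes 10% into window A in ES and window B in DE at
  constant abundance. The 10x expression boost puts >= 200 contacts in the
  planted windows at default depth, the regime in which detection is
  asserted.
- RNA-seq weights divide the ChAR weights by each gene's
  chromatin-enrichment factor (log-normal, sigma 0.5 in log2, with 10 genes
  planted at 8x), so the ChAR:RNA-seq abundance ratio recovers the factor.

What the generator does **not** emulate: 3D genome structure (TADs,
compartments, loops), so long-range deviations driven by chromatin folding
are absent; read-level sequence artifacts, mappability and blacklist
effects; realistic chromosome counts or human-genome scale; dependence
between contacts of one RNA beyond the class split. Passing tests therefore
establish internal statistical correctness and calibration of the methods
under their own assumptions — not that real libraries satisfy those
assumptions.

## Numerical choices and degenerate inputs

Rates are clipped to [1e-12, 1 - 1e-12] before logits; gamma = 0 degrades
the EB prior to a documented pseudo-count-1 prior; zero near- or
far-density raw scores become NaN and are excluded from ranking; all-zero
interaction rows return NA results; unknown chromosomes in binning are
counted as unassigned with a warning rather than raising; Fisher p-values
are floored at 1e-300; probability vectors are validated to 1e-12.
Optimizer convergence is declared at log-likelihood changes below 1e-8 with
up to 3 random restarts.

## Problem sizes used in tests

The test and acceptance suites use 2,000-RNA cohorts for GLM recovery and
calibration, 5,000 rows for NB type-I error, 5,000 edges x 50 repeats for
bootstrap coverage, 1e5 contacts for distribution-law and I/O checks, and
the default 2e5-contacts-per-sample dataset for end-to-end screens — sizes
chosen so the full suite completes in about a minute while keeping binomial
standard errors small relative to the asserted tolerances.
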