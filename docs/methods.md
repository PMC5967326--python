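# Methods

This note documents the models, the defaults and the numerical choices
behind `lungsig`, and what the synthetic-data tests do and do not
establish about real cohorts.

## Mutation catalog

SNVs are strand-collapsed onto the pyrimidine basis: a purine-reference
substitution is reverse-complemented (base and 3-mer context) before
indexing, so each biological event maps to exactly one of 96 channels.
Channel order is the COSMIC-style lexicographic layout — substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G) major, then 5′ and 3′ base in
(A, C, G, T) order — chosen so catalogs and profiles can be compared
column-by-column with published signature tables. Coordinates are 1-based
inclusive internally; BEDPE's 0-based half-open starts are converted once
at the parsing boundary. Mutations whose reference 3-mer contains an
ambiguous base have no defined channel and are excluded with a logged
count, as are duplicate calls at the same (sample, chrom, pos) — keeping
the first, since a double-counted call would bias the catalog.

## Signature extraction

The factorization objective is the generalized KL divergence
D(V‖WH) = Σ V log(V/WH) − V + WH, i.e. the Poisson log-likelihood of the
count catalog up to a constant. Optimization uses the classical
multiplicative updates, which are monotone in D (asserted by test);
convergence is declared when the relative change in D over 10 iterations
falls below `tol` (default 1e-8) or after `max_iter` (default 5000)
iterations. Because the objective is non-convex, the best of `restarts`
(default 20) uniform-random initializations is kept; each restart's RNG
derives from a `SeedSequence` child of the user seed, so results are
reproducible bit-for-bit. Profiles are rescaled to column sum 1 with the
inverse rescale applied to exposures, leaving the reconstruction
unchanged; an exposure is then denominated in events.

Exact KL-NMF factorizations are not unique in general; recovery tests use
either separable fixtures (each signature has a near-pure sample) or
cosine/correlation criteria rather than elementwise equality.

**Rank selection.** For each candidate rank all restarts are matched to
the best-fit solution by greedy maximum-cosine assignment (adequate at
rank ≤ 5). A signature's reproducibility is its mean matched cosine
across restarts; the rank's stability is the *minimum* reproducibility
over its signatures, so a single unstable component disqualifies the
rank. A rank is also disqualified when its best solution contains two
near-duplicate profiles (pairwise cosine > 0.95) — the characteristic
overfitting mode on degenerate catalogs, where extra components converge
to copies of a real signature and are individually "stable". The chosen
rank is the largest stable, distinct candidate. The reported table keeps
the per-rank divergence, the min-based stability, the mean matched cosine
and the max inter-signature cosine.

**Dominance** uses the strict inequality: a sample is dominant for a
signature only when its contribution (exposure share) exceeds 0.5, so a
50/50 tie is "none". Contribution is exposure-normalized; with
column-normalized profiles this coincides with the share of mutations
attributed.

## Rearrangement catalog and attribution

Only intra-chromosomal events carry a segment size, so translocations are
excluded from the 15 categories (they still contribute breakpoints to
hotspot detection). Size bins are half-open on the right; events below
1 kb are kept in the smallest bin with a logged count rather than
dropped, preserving the conservation invariant (catalog total = number of
intra events). The clustered/non-clustered split used by some
breast-cancer classification schemes is deliberately not applied: the
catalog here is 15 categories, not 32.

Per-event attribution multiplies the signature's category probability by
the sample's exposure and normalizes over signatures. The normalized
posterior — rather than the raw product — is thresholded at 0.5, because
the raw product is not a probability and a fixed threshold on it would
mean different things in samples with different event counts.

## Hotspot detection

IMD is the distance from a breakpoint to its predecessor on the sorted
chromosome; the first breakpoint of each chromosome has no IMD and is
excluded from segment means. PCF operates on log10(IMD) to stabilize the
variance across the several orders of magnitude an IMD spans; the
segmentation is the exact dynamic-program minimizer of
Σ_segments SSE + γ·(#segments) subject to a k_min segment length
(O(n²) per chromosome with prefix sums), verified against brute-force
enumeration for all sequences of length ≤ 15. Defaults γ = 8, k_min = 8;
a third parameter `i = 2` is carried in the configuration for
compatibility but has no role in the exact DP.

A segment qualifies as a hotspot when (a) its mean IMD is at most half
the genome-wide mean IMD — i.e. breakpoint density at least twice the
genome-wide level; a literal "average IMD two times greater" would select
rearrangement deserts, the opposite of clustering, so the density reading
is used — and (b) its observed breakpoint count exceeds the summed
expectation of all background bins overlapping the segment. Summing whole
overlapping bins (rather than pro-rating by overlap) makes criterion (b)
conservative for sub-bin segments. "Genome-wide level" is the mean of all
defined IMDs (the paper-scale choice between mean and median is not
determined by the definition; the mean is used throughout). The negative
binomial tail probability P(X ≥ observed) of each qualifying segment is
reported with a BH q-value across segments; it is reported, not used as a
filter, since the hotspot definition is (a) ∧ (b).

The background is an NB2 regression (log link, Var = μ + αμ²) of per-bin
breakpoint counts on z-normalized feature tracks over non-overlapping
0.5-Mb bins, fitted by maximum likelihood through `statsmodels`; when the
dispersion estimate collapses or the NB fit fails, a Poisson GLM is used
instead (logged). Bins with undefined features are dropped from both
fitting and calling. Real feature tracks (replication timing, DNase,
fragile sites, histone marks) are user-supplied per-bin TSVs; the
synthetic generator fabricates three stand-in tracks (a smooth
periodic "timing" track, a blocky "repeats" track, white noise).

## Cohort statistics

* **Cochran–Armitage.** Standard score-weighted trend statistic with the
  null variance, referred to the normal; groups default to 10 equal-size
  quantiles of a signature's contribution with integer scores 1..10,
  matching a 10-patient top group in a 92-sample cohort. Calibration is
  tested (type-I error within [0.03, 0.07] at α = 0.05 over 2000 null
  simulations) and the asymptotic p is cross-checked against a
  permutation oracle.
* **Fisher exact.** Two-sided p by the minimum-likelihood rule (sum of
  hypergeometric probabilities of tables no more probable than observed,
  with a 1 + 1e-7 relative tolerance against floating-point ties, the
  mainstream-software convention). The odds ratio is the conditional MLE:
  the root of E_ψ[a] = a_obs under the Fisher noncentral hypergeometric
  distribution, found by bisection on log ψ in log-space weights; zero
  cells yield 0 or ∞.
* **Wilcoxon rank-sum** delegates to `scipy.stats.mannwhitneyu`: exact
  null when m + n ≤ 20 with no ties, tie-corrected normal approximation
  otherwise; the rank-sum statistic W = U + m(m+1)/2 is reported.
* **Spearman partial correlation.** All variables are midrank-transformed;
  ranked x and y are residualized on the ranked covariates (with
  intercept) by least squares and the residual Pearson r is referred to a
  t distribution with n − 2 − #covariates df. With no covariates this is
  plain Spearman (verified against `scipy.stats.spearmanr` to 1e-12).
  Binary covariates (histology) are coded 0/1; multi-level covariates
  one-hot.
* **BH FDR** wraps `statsmodels.stats.multitest.multipletests`.
* **SPM** is the cosine between a gene's cross-cell-type expression
  profile and the one-hot profile of the target type, x_t/‖x‖₂; the > 0.9
  cutoff defines type-specific gene sets. All-zero genes are flagged NaN.

## Synthetic cohorts: what they emulate

Default ground truth: three mutational profiles — APOBEC-like (C>T/C>G at
TpC), smoking-like (broad C>A with a mild 3′ preference), and a diffuse
profile dominated by C>T and T>C with its TpC C>T contexts held at
background so the three profiles are mutually separated (pairwise cosine
≤ 0.3, the well-separated regime the recovery claims are stated for) —
and three rearrangement profiles with RS1 (large deletions/inversions)
and RS2 (large duplications) above 1 Mb and RS3 below 1 Mb. These shapes
echo the biology they stand in for; they are generator parameters, not
estimates of any published signature.

Per-sample exposures are Dirichlet(0.8) proportions of the per-sample
event total (defaults: 92 samples, 2000 mutations, 126 rearrangements —
the cohort size and median rearrangement count of the motivating study);
concentration 0.8 yields dominant-signature patients at a realistic rate
(~27% per signature). Mutations are placed at uniformly chosen reference
sites carrying the required trinucleotide context on either strand,
without site reuse within a sample, so the catalog rebuilt from the
emitted VCFs equals the drawn channel counts exactly. Rearrangement sizes
are log-uniform within the drawn size bin; left breakpoints are uniform
except in hotspot intervals, whose sampling weight is multiplied by the
stated intensity.

Phenotypes: driver status is Bernoulli with logit = −2.5 + 5·c₃ in the
diffuse signature's contribution c₃ (≈8% at c₃ = 0 rising to ≈92% at
c₃ = 1, ≈30% at the mean contribution — the effect-size regime of the
motivating cohort); each of 6 fusion carriers falls in the top
contribution decile with probability 4.6 × the decile share, putting half
the fusions there in expectation; TIL abundances are linear in
contributions plus truncated Gaussian noise, with B-cell and CD4 T-cell
tracks coupled to the diffuse signature.

What passing tests on these cohorts do **not** show: real catalogs have
correlated noise, sub-clonal structure, mappability artifacts and
signatures far closer in cosine than 0.3; real feature tracks are
heavy-tailed and mutually correlated; real rearrangement calls carry
caller-specific breakpoint uncertainty. Recovery numbers here certify the
estimator under its own model, not performance on such data.

## Problem sizes and determinism

Tests and the acceptance script run the study-scale cohort (92 × 2000)
for recovery, 10 replicate cohorts for rank selection, 5000 bins for
background recovery, 20 replicates of a 200-Mb genome (400 bins, ~1300
breakpoints, 5 planted clusters of 30 breakpoints in 50 kb) for hotspot
recall/precision, 2000 null simulations for trend-test calibration and
100 replicates for power — sizes at which every stochastic criterion is
stable across seeds while the whole suite completes in well under a
minute of NMF time. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` children; reruns are bit-identical.

## Known limitations

* KL-NMF with multiplicative updates can stall near saddle points; the
  restart mechanism mitigates but does not eliminate this, and rank
  selection inherits the restarts' coverage.
* The greedy cosine matcher is not the Hungarian algorithm; at rank ≤ 5
  with separated profiles they coincide, but at higher ranks optimal
  assignment should replace it.
* The hotspot criterion has no multiplicity control by construction (the
  q-value is reported only); on feature-driven backgrounds ~1 spurious
  segment per 200-Mb genome replicate passes both criteria.
* The conditional-MLE odds ratio is undefined when the support of the
  a-cell is a single point (degenerate margins); it is flagged NaN.
* Panel-of-normals and segmental-duplication filtering happen upstream of
  this package's inputs and are not reproduced.
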