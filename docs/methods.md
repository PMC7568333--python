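# Methods

`pterochron` implements, at desk scale, the computational pipeline of a
pteropod phylogenomic dating study: filtering cross-contaminated transcript
tables, assembling an ortholog supermatrix, ranking genes by informativeness,
Bayesian relaxed-clock divergence dating on a fixed topology with
soft-bounded fossil calibrations, and fossil diversity-through-time curves.
A synthetic-data module generates inputs carrying the statistical structure
each stage assumes, so the whole pipeline is testable without external
downloads. This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Contamination filter

Multiplexed libraries on a shared sequencing lane exchange reads through
index hopping. The filter works purely on relative expression. For a
transcript of a focal dataset, its *contaminant enrichment* is the maximum,
over lane-mate datasets carrying the same transcript id, of the lane-mate
TPM divided by the focal TPM (lane-mates lacking the transcript contribute
0; a zero focal TPM against any positive lane-mate TPM counts as infinite
enrichment). Two criteria are applied independently:

1. enrichment strictly greater than `fold_threshold` (default 2);
2. estimated read count strictly below `min_count` (default 2; counts are
   fractional estimates and compared as real numbers).

The union is excluded; a transcript failing both is attributed to criterion
1 so the two exclusion fractions can be reported separately, as medians
across datasets. Aggregation over multiple lane-mates uses the maximum (the
worst-case reading) rather than the sum; this is a parameter. TPMs are taken
from the input table and never recomputed — quantification is upstream of
this package.

## Supermatrix assembly

Gene selection keeps single-copy orthologs present in at least
`min_outgroup` outgroup taxa (default 1) and at least
`ceil(min_ingroup_frac x |ingroup|)` ingroup taxa (default half; `ceil`
because "at least half" of an odd roster must round up). Column trimming
first drops columns whose non-gap fraction falls below `min_nongap_frac`
(default 0.15) and then columns whose similarity falls below
`min_similarity` (default 0.001), where similarity is the frequency of the
modal residue among non-gap residues — a simple, monotone conservation proxy
standing in for the original trimming tool's unpublished statistic.
Concatenation pads taxa missing from a gene with `-` and reports a missing
fraction that counts both padding and internal gaps over the full taxa x
columns grid, the conventional bookkeeping for supermatrix missing data.
Columns are 0-based half-open internally; reports are 1-based inclusive.

Gene informativeness is the mean bootstrap support of the gene's own tree:
neighbor joining on pairwise distances corrected under the 20-state
equal-rates model (d = -(19/20) ln(1 - 20p/19), capped at 10 substitutions
per site for saturated pairs), with supports from `n_boot` (default 100)
column resamples. Distance/NJ trees replace per-gene maximum-likelihood
trees deliberately: the selection *procedure* — rank genes by mean support,
take the top k (default 200), ties broken by taxon count then gene id — is
preserved at a small fraction of the cost, and externally computed scores
can be substituted. Genes with fewer than four taxa are reported unscored.

## Relaxed clocks

Three rate processes are supported, with rates in substitutions/site/Myr:

* **UGAM** — independent gamma branch rates, mean `mean_rate`, shape `1/nu`.
* **Lognormal autocorrelated** — geometric Brownian motion of the rate along
  root-to-tip paths, infinitesimal variance `sigma2` per Myr, drift
  `-sigma2/2` so the rate's expectation is preserved. Rates live on nodes;
  a branch's rate is the arithmetic mean of its endpoint rates (the
  Thorne–Kishino convention).
* **CIR** — the mean-reverting square-root diffusion
  `dr = theta (mu_r - r) dt + sigma sqrt(r) dW`, with exact noncentral
  chi-square transitions and stationary distribution
  Gamma(2 theta mu_r / sigma2, scale sigma2 / (2 theta)). The Feller
  condition `2 theta mu_r >= sigma2` is enforced so the process cannot
  reach zero. Node rates, branch rate = endpoint mean, as above.

Simulator defaults: `mean_rate = 0.01`/site/Myr (about 1.3 substitutions per
site root-to-tip on a 130-Ma tree, typical of transcriptome-scale amino-acid
data); CIR `theta = 0.03`/Myr and `sigma2 = 6e-5`, i.e. a stationary rate CV
of ~32% and an autocorrelation time of ~33 Myr. The autocorrelation time
matters: a reversion rate much faster than the tree depth makes branch rates
effectively independent, and node ages then lose the identifiability that
autocorrelated clocks provide — an early default with a 1-Myr relaxation
time made interior ages unrecoverable by construction and was replaced.

The CIR transition density is evaluated through the exponentially scaled
Bessel function; where that underflows (extreme hyperparameter proposals)
the leading ascending-series term `q log(x/2) - lgamma(q+1)` is used, so the
log-density degrades gracefully instead of overflowing.

## Node-age priors

The root age always carries a gamma prior moment-matched to a mean and SD
(default 150 +- 70 Ma). Interior ages follow one of:

* **uniform** — flat over the order-constrained simplex given the root;
* **birth–death** — the reconstructed-process speciation-time kernel
  f(t) = rho lam r^2 e^{-rt} / (rho lam + (lam(1-rho) - mu) e^{-rt})^2,
  r = lam - mu, i.i.d. across interior nodes conditioned below the root age;
  lam and mu carry exponential hyperpriors (mean 0.01/Myr) and are sampled;
  the sampling fraction rho is fixed at 1 by default. With mu = 0 this
  kernel is a truncated exponential in node *age* — pure-birth trees are
  tippy, and increasingly so at higher lam.
* **Dirichlet** — symmetric Dirichlet on the proportions of the internode
  gaps obtained by sorting all internal ages; at concentration 1 it
  coincides with the uniform prior.

## Soft-bounded fossil calibrations

A calibration attaches a fossil minimum age `m` to the crown (MRCA) node of
a named taxon set, with prior mass `soft_mass` (default 5%) below the bound.
Nine calibrations cover the pteropod clades (a: *Diacria* 7.2 Ma, b:
*Cavolinia*+*Diacavolinia*+*Diacria* 28.1, c: *Cavolinia*+*Diacavolinia*
16, d: Cavolinioidea 47.8, e: *Limacina* 47.8, f: *Heliconoides* sp. 72.1,
g: Pseudothecosomata 16, h: Gymnosomata 23, i: root/*Akera*), and six
schemes s1–s6 vary the root minimum (163.1 Ma, 133 Ma, or absent) and
whether the *Heliconoides* fossil calibrates Euthecosomata or Limacinoidea
— nine calibrations under s1–s4, eight under s5–s6.

The prior construction makes "5% below the bound" an exact property rather
than an aspiration. Multiplying a base prior by per-node soft-bound factors
— the standard approach — lets the tree's order constraints truncate the
factors, so the realised prior mass below each bound drifts from its nominal
value. Instead, with the uniform interior prior the joint age prior is built
top-down as a chain of normalised conditionals:

* a calibrated **root** keeps its gamma density, reweighted so mass
  `soft_mass` lies below the minimum and the gamma tail — which anchors the
  absolute time scale — lies above;
* every other calibrated node has a two-piece density conditional on its
  nearest calibrated ancestor's age (or a fixed prior age cap, default 250
  Ma, when it has none and the root is uncalibrated): a power-law ramp below
  `m` whose log-density decreases monotonically to -inf at age zero, and a
  flat plateau above, continuous at the bound wherever the continuity
  exponent stays above 1;
* uncalibrated nodes (the root included, via a truncated gamma) are uniform
  between the oldest calibrated age in their subtree and their parent's age.

Because each conditional integrates to one, the calibrated skeleton's
marginals are unaffected by everything sampled after it. One residual
distortion remains — a nested calibration spends all its mass below `m`
whenever its ancestor happens to be younger than `m` — and is removed by a
one-time Monte-Carlo adjustment of the conditional masses at prior
construction (300,000 skeleton draws under a fixed internal seed that is
part of the prior's definition). The construction is exercised by prior-only
MCMC: every calibration in every scheme shows an empirical violation
probability of 0.05 to within Monte-Carlo error.

Under the birth–death and Dirichlet priors, calibrations enter as
multiplicative factors in the conventional way; the soft mass is then
approximate, which is documented behaviour, not a defect.

## Likelihood

Felsenstein pruning over unique site patterns, with 20-state
equal-exchangeability ("Poisson") or LG exchangeabilities and empirical
frequencies, rate matrices normalised to one expected substitution per unit
branch length, optional discrete-gamma site rates (equal-probability
categories carrying their bin means; default shape 0.8, 4 categories), and
per-node rescaling against underflow. Branch expected substitutions are
branch rate x branch duration. The engine supports transactional path
updates: a move that changes a few branches recomputes only the partials on
the affected root paths, and a rejection restores them; an invariant test
keeps the incremental state byte-consistent with a fresh full evaluation.
The implementation is checked against closed forms (two-taxon equal-rates
probability (1/20)(1/20 + (19/20)e^{-20 nu/19})) and against brute-force
summation over all internal state assignments on four taxa.

The original study's CAT-GTR site-heterogeneous mixture is out of scope;
Poisson/LG with discrete gamma is the engine's ceiling, which is why
full-data headline ages would be reproduced only approximately.

## MCMC

Metropolis-within-Gibbs over node ages (uniform slides between the oldest
child and the parent), the root age (multiplicative), node/branch rates
(multiplicative), clock hyperparameters, the gamma shape, and birth–death
hyperparameters. Step windows adapt toward ~30% acceptance during burn-in
and are frozen afterwards, preserving detailed balance for retained samples.
Runs are deterministic given the configuration seed.

The slow direction of this posterior is the rate-time product: the
likelihood constrains branch lengths, so the absolute scale is informed only
by the calibrations and the root prior. A dedicated joint rescale move
multiplies all ages by c and divides all rates by c — leaving every branch
length, and hence the likelihood, exactly invariant — while transforming the
clock parameters so the rate-prior density is invariant too (CIR:
`mu_r/c, sigma2/c^2, theta/c`; lognormal: `mu_r/c, sigma2/c`; UGAM:
`mu_r/c`). Acceptance is then governed by the age prior and hyperpriors
alone. The move is likelihood-free and therefore cheap; it runs many times
per sweep, as does the root move. The CIR reversion rate `theta`
consequently becomes a sampled quantity and carries a lognormal prior
centred on its configured value (log-SD 0.7).

Hyperpriors: exponential on the clock mean rate (mean 0.01/site/Myr), on the
clock variance parameter (mean 0.05), on the gamma shape (mean 1), and on
the birth–death rates (mean 0.01/Myr). Initial states are drawn from the
calibrated prior construction (valid under every mode); initialisation fails
with an explicit error after bounded attempts if a calibration's minimum is
not below the age cap.

Posterior summaries report per-node means, 2.5–97.5% credibility intervals,
and autocorrelation-based effective sample sizes (a root ESS below 50 raises
a convergence warning, not an error). The annotated chronogram carries
posterior means; where means violate parent > child (they may — means are
not a sampled state) children are nudged just below their parent.

## Cross-validation

Genes are shuffled into k folds (default 10) with a seeded permutation. For
each clock/age-prior configuration the sampler fits the training folds; the
posterior means of per-branch expected substitutions and of the gamma shape
form a plug-in estimate at which the held-out fold's log-likelihood is
evaluated; fold scores sum to the configuration's score. Plug-in scoring is
cheap and deterministic per seed, and bounds the posterior-predictive
held-out likelihood from below (Jensen); it ranks configurations, it does
not estimate marginal likelihoods.

## Synthetic data

* **Chronograms** — forward birth–death simulation (defaults: speciation
  0.05, extinction 0.02 per lineage per Myr) stopped inside the holding
  interval where the extant count first reaches n, extinct subtrees pruned,
  rejection until n survivors, then uniform rescaling of all ages so the
  root hits the target (default 28 taxa, 140 Ma). Mean rescaled node ages of
  pure-birth simulations match a direct Monte-Carlo of the exponential
  waiting-time construction.
* **Alignments** — sites evolved state-by-state down the tree under
  Poisson or LG, optional discrete-gamma site rates (shape 0.8, 4
  categories), per-gene whole-taxon deletion with probability
  `missing_prob` (resampled if a draw would empty the gene). Pairwise
  identities match the equal-rates closed form within binomial error.
* **Expression tables** — per dataset, log-normal true abundances (log-mean
  1, log-SD 1.5), log-normal transcript lengths, multinomial read counts
  (default 2 x 10^6 reads over 2,000 transcripts); each transcript leaks a
  binomial fraction c (default 0.05) of its reads into every lane-mate as a
  distinct row with the originating id, mirroring how an assembler would
  recover leaked reads; TPMs recomputed per dataset from final counts sum to
  10^6; ground-truth origin labels retained for scoring.
* **Fossil records** — per clade, species with contiguous stage ranges
  (geometric durations), recorded per lived-through stage with that stage's
  preservation probability; Recent occurrences always recorded. A bundled
  stage table (Tithonian to Recent, bounds in Ma) ships as replaceable CSV.

What passing synthetic tests do **not** show: the generators are
homogeneous where real data are not (no compositional heterogeneity across
sites or taxa, no alignment error, no within-gene occupancy structure, no
assembly artefacts), so recovery results bound what the method can do under
its own assumptions, not its robustness to their violation.

## Simulation-study design

The credibility-interval coverage study runs 28-taxon replicates under the
CIR clock with nested soft minimum-age calibrations placed on five deep and
three mid-depth nodes plus the root, minima at 80% of the true node age —
emulating fossils that postdate the divergences they calibrate. Data per
replicate are 4 genes x 100 amino acids with 10% per-gene taxon deletion,
and chains run 3,000 sweeps (900 burn-in) over 3 replicates; these sizes
keep the default suite at desk scale while leaving the posterior clearly
data-informed.
Chains are convergence-gated: a run whose root-age effective sample size
falls below 20 is discarded and repeated with a fresh chain seed (data and
priors unchanged, at most two attempts) — the standard dating-MCMC
workflow of checking sampler diagnostics and rerunning stuck chains; the
gate never consults the simulated truth.
Pooled over replicates, at least 90% of true interior ages should fall in
their 95% credibility intervals; per-interval ESS is modest at this chain
length, which widens the binomial tolerance but does not bias coverage.

## Fossil curves

Observed diversity counts distinct accepted species per stage; range-through
counts every species in all stages between its first and last occurrence.
Synonym and doubtful records never contribute; stage spans
("Chattian–Burdigalian") expand to one record per spanned stage before
counting; species identity is the trimmed verbatim binomial — taxonomy
curation is the database's job. Interval summaries (median/total/mean over a
stage set, even-length medians as midpoint averages) and a per-clade +
pooled report with the Thanetian-to-Ypresian step highlighted complete the
module.

## Known limitations

* Site-heterogeneous mixtures (CAT-GTR) are not implemented; LG+Gamma4 is
  the ceiling.
* Topology is always fixed; there is no co-estimation, tip-dating, or
  fossilized birth–death process.
* The exact soft-mass construction applies to the uniform interior prior;
  birth–death and Dirichlet priors use multiplicative factors with
  approximate soft mass.
* Cross-validation is plug-in, not posterior-predictive.
* The NJ-bootstrap informativeness score is a proxy; ML-based scores can be
  supplied externally but are not computed here.
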