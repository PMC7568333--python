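# pterochron

Phylogenomic divergence dating of pteropods (sea butterflies and sea
angels), packaged as a reusable, testable pipeline. Pteropods are
holoplanktonic gastropods whose thin aragonitic shells preserve poorly, so
their fossil record alone badly underestimates the age of the group;
molecular dating from transcriptome-scale data, anchored by fossil minimum
ages with soft bounds, places their major divergences in the Cretaceous.
`pterochron` implements the computations such a study needs, end to end:

* **Contamination filtering** of multiplexed transcript expression tables:
  index hopping on shared Illumina lanes leaks reads between samples, so a
  transcript more than 2-fold TPM-enriched in a lane-mate, or supported by
  fewer than 2 estimated reads, is excluded from its dataset.
* **Supermatrix assembly**: single-copy ortholog selection by taxon
  occupancy (at least one outgroup taxon and at least half the ingroup),
  gap/conservation column trimming, concatenation with missing-data
  bookkeeping, and per-gene informativeness ranking by mean bootstrap
  support of neighbor-joining gene trees.
* **Bayesian relaxed-clock dating** on a fixed topology: three rate
  processes (uncorrelated gamma multipliers, lognormal autocorrelated, and
  the mean-reverting CIR diffusion `dr = theta (mu - r) dt + sigma sqrt(r) dW`),
  three node-age priors (uniform, birth–death, Dirichlet), a gamma root
  prior (150 ± 70 Ma), and nine fossil calibrations in six alternative
  schemes (s1–s6), each a soft minimum-age bound carrying exactly 5% prior
  mass below the fossil age. Likelihoods are Felsenstein pruning under
  Poisson or LG+Γ amino-acid models; inference is Metropolis-within-Gibbs
  with a likelihood-invariant time/rate rescale move; model choice uses
  k-fold held-out likelihood.
* **Fossil diversity curves**: species-level occurrences binned on a
  stage-resolved geologic timescale, observed and range-through diversity
  per clade, and interval summaries.
* **Synthetic data** for every stage: birth–death chronograms, relaxed-clock
  rates, amino-acid alignments with per-gene taxon occupancy, multi-lane
  expression tables with injected cross-contamination (ground truth
  retained), and stage-binned fossil records with preservation bias.

The scientific core is the calibrated prior: node ages are built top-down so
that each calibrated clade's age has, conditionally on its nearest
calibrated ancestor, a two-piece density — a power-law ramp below the fossil
minimum carrying exactly the soft mass, a plateau above — while the root
keeps a gamma prior reweighted around its own bound. The 5%-below-the-bound
contract is then a theorem about the prior, checked empirically by
prior-only MCMC.

## Worked example

Run the end-to-end demo on synthetic data (a 12-taxon chronogram, 8 genes,
a contaminated 4-dataset expression table, dating with three soft
calibrations, and a fossil record):

```bash
pterochron demo --seed 42 --out demo_run --iters 800
```

which logs one JSON line per stage to stderr, e.g.

```
{"stage": "demo", ... "stages": ["simulate", "filter", "matrix", "rank", "date", "fossil"], "out": "demo_run"}
```

and leaves `demo_run/` with the simulated inputs, the filter report, the
supermatrix (`supermatrix.phy`, `partitions.csv`), gene scores, the MCMC
chain (`chain.csv`), posterior node summaries, an annotated chronogram
(`chronogram_posterior.nwk` with `[&mean=...,CrI={...}]` comments), the
diversity curves, and `manifest.json` with SHA-256 checksums of every
artifact — rerunning with the same seed reproduces the checksums byte for
byte.

Individual stages are also exposed (`pterochron simulate|filter|matrix|rank|
date|cv|fossil`); for instance

```bash
pterochron filter --table expression.csv --fold 2 --min-count 2 --out report.csv
```

writes a per-transcript decision table (`kept` / `excluded` with the
criterion and the enrichment ratio), and

```bash
pterochron date --genes genes/ --tree topology.nwk --scheme s4 \
    --clades clades.json --clock CIR --ageprior uniform \
    --iters 20000 --seed 1 --out dating/
```

dates a topology under calibration scheme s4 (root *Akera* minimum at 133
Ma, *Heliconoides* sp. on Limacinoidea), echoing the fully resolved
configuration next to the outputs.

As a library:

```python
from pterochron.example import pteropod_demo_tree
from pterochron.clockdating import (build_calibration_set, run_mcmc,
                                    NodeAgePriorSpec)
from pterochron.formats import RunConfig

tree, clades = pteropod_demo_tree()          # 28-taxon demo topology
cals = build_calibration_set("s4", tree, clades)
cfg = RunConfig(seed=1, iterations=40_000, burn_in=2_000, thinning=1,
                age_prior="uniform")
chain = run_mcmc(tree, cfg, calibrations=cals, prior_only=True,
                 age_prior=NodeAgePriorSpec(kind="uniform"))
for node, cal in chain.calibrations.items():
    frac = (chain.samples[f"age_{node}"] < cal.min_age).mean()
    print(cal.label, cal.min_age, round(float(frac), 3))
```

prints, for each of the nine s4 calibrations, the prior probability of
violating its fossil minimum — each close to the nominal 0.05:

```
a 7.2 0.049
b 28.1 0.059
c 16.0 0.052
d 47.8 0.058
e 47.8 0.049
f 72.1 0.049
g 16.0 0.057
h 23.0 0.049
i 133.0 0.048
```

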