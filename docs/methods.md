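# Methods

## Model

A sample's Y chromosome is haploid and fully linked, so conditional on its
haplogroup the model treats sites as independent. The generative picture
is a finite mixture: haplogroup l is drawn from a prior P(H\*<sub>·l</sub>),
the allele g at site i is drawn from the haplogroup's allele distribution
H\*<sub>il</sub> = {H\*<sub>ilg</sub>}, and the read data enter only
through the genotype likelihood G<sub>ijg</sub> = P(reads | g). The
per-sample likelihood of haplogroup l is the product over sites of
∑<sub>g</sub> G<sub>ijg</sub> H\*<sub>ilg</sub>, and assignment is the
posterior over whichever haplogroup set is active (major clades, leaves,
or all nodes). Likelihoods are defined up to a positive per-vector
constant; every downstream quantity is invariant to rescaling, and a
missing observation is the vector {1,1}, which contributes a constant
factor and cannot move a posterior.

At marker sites the allele distributions are fixed by the phylogeny:
degenerate at leaves, descendant-leaf proportions at internal nodes
(unweighted leaf counting — the tree carries no branch lengths, and none
are modelled). The marker table must be pre-normalized to the forward
strand with an explicit derived-allele flag; curating or orienting marker
lists against a reference genome is a one-time upstream step, not part of
the method.

## EM over the cohort

Allele distributions at non-marker sites (the *free rows* of H\*,
initialized {0.5,0.5}) and the haplogroup prior are parameters, fitted by
EM with two latent variables per sample: its haplogroup and its allele at
each site. The E-step computes responsibilities r<sub>jl</sub> — exactly
the assignment posterior. The M-step sets each free row to the
responsibility-weighted average of soft genotypes,

H\*<sub>il1</sub> ← (c + ∑<sub>j</sub> r<sub>jl</sub> q<sub>jil1</sub>) / (2c + ∑<sub>j</sub> r<sub>jl</sub>),  q<sub>jilg</sub> ∝ G<sub>ijg</sub> H\*<sub>ilg</sub>,

and the prior to smoothed responsibility proportions
(∑<sub>j</sub> r<sub>jl</sub> + c/A)/(M + c) over the A active nodes.
Marker rows are never modified. The soft genotype q is the posterior of
the latent allele under the current parameters — the standard EM
treatment; a likelihood-only variant (q ∝ G<sub>ijg</sub>) is available
behind `EMConfig.soft_genotype="likelihood"` for sensitivity analysis.

**Pseudocount.** c is a per-allele Dirichlet-style weight. Its fixed point
against k concordant covered carriers is (c+k)/(2c+k): with c = 0.5 a
haplogroup needs ≥ 5 covered carriers before a free row can exceed 0.9, so
in cohorts of a few samples per haplogroup no private allele could ever be
learned confidently. The default is c = 0.1: one concordant covered sample
reaches ≈ 0.92, while probabilities still never hit exact 0/1 (one
erroneous read cannot irreversibly poison a profile, and no prior entry
can reach an unrecoverable zero). c is exposed in `EMConfig` and on the
CLI.

**Convergence.** The observed-data log-likelihood
∑<sub>j</sub> log ∑<sub>l</sub> P(G<sub>·j</sub>|H\*<sub>·l</sub>)P(H\*<sub>·l</sub>)
is recorded each iteration; the run stops when the improvement falls below
`tol` (default 1e-6, absolute) or at `max_iters` (default 100). The trace
must be non-decreasing up to 1e-8 slack — the update is an exact (MAP-)EM
step, so a larger decrease indicates a defect and raises in strict mode.
Responsibilities and parameters returned together are mutually consistent
(the E-step of the final parameters).

## Numerical choices

* All products are log-space sums; posteriors are formed by log-sum-exp.
  A naive product underflows near N ≈ 10³ sites.
* Input likelihoods are floored at ε = 1e-10 (configurable): a sample
  contradicting a degenerate marker keeps a finite log-likelihood of
  N·log ε instead of −∞. The floor is far below any per-read error rate
  and cannot alter a MAP call. −∞ likelihoods are still permitted per
  node (a truly excluded haplogroup); an error is raised only if a
  sample excludes *every* active node, which requires disabling the floor.
* MAP ties are broken by preorder node order and flagged
  (`AssignmentResult.tie`), so runs are deterministic and testable.
* Diploid-coded VCFs (e.g. consortium pilot data) are accepted: 3-value
  PL/GL arrays use the two homozygous entries; heterozygous GT calls on
  the Y are treated as missing data, since they signal mapping artifacts
  in pseudo-autosomal or paralogous regions and the model is strictly
  haploid.
* Fine-level posteriors are never silently renormalized into major
  clades; `rollup_major` is an explicit report that sums leaf posteriors
  within each configured clade.
* In the M-step a 0/0 soft-genotype (impossible data under a hard
  parameter value, only reachable with c = 0) falls back to the current
  parameter; a haplogroup with zero total responsibility and c = 0 keeps
  its rows and warns.

## Marker discovery

After convergence, a free row is reported as a candidate novel marker for
haplogroup l when the probability of one allele is ≥ `min_prob` (0.95),
the same allele's probability in every *informed* competitor is ≤
`max_other` (0.05), and the effective support ∑<sub>j</sub> r<sub>jl</sub>
is ≥ `min_support` (2.0). A competitor below the support threshold has no
samples in the cohort; its free-row value is still the uninformative 0.5
and says nothing about exclusivity in the population studied, so it is
excluded from the veto. Marker rows can never be reported. All three
thresholds are reporting choices exposed as function arguments and CLI
flags; raising any of them can only shrink the candidate list.

Discovery presumes the haplogroup profiles were actually learnable: in a
cohort where a haplogroup's carriers are mostly uncovered at a site, its
free-row value remains intermediate and correctly blocks (or fails to
reach) the thresholds. Candidate reports are therefore most useful on
cohorts with at least a handful of covered carriers per haplogroup.

## Synthetic data

The generator emulates the regime the method targets: a population of M
haploid samples drawn from the leaves of a known tree and sequenced at
low coverage. Defaults (the study conditions used throughout the tests):
a 20-leaf random bifurcating tree, 3 markers per non-root branch, 5
clade-private free sites per leaf, 30 haplogroup-independent noise sites
(allele frequency 0.5 per sample), M = 40 drawn uniformly over leaves,
Poisson read depth with mean 1.5, per-read error 0.005. The depth values
bracket the low-coverage population-sequencing regime (≈ 1.7x typical,
0.6x in the downsampled experiments). Reads are site-independent;
linkage needs no modelling because the model conditions on the haplogroup
and the locus does not recombine. Likelihoods are phred-quantized exactly
as written to VCF, so the in-memory matrix and a VCF round-trip agree to
the quantization. Everything is deterministic from a single seed via
spawned per-stage generators.

What the generator does *not* emulate: realistic coalescent branch
lengths or haplogroup frequencies, context-dependent error profiles,
mapping artifacts (the source of real heterozygous Y calls), recurrent or
back mutations, multi-allelic sites, and multifurcating trees (the parser
accepts them; the simulator only emits bifurcating ones). Passing tests
therefore demonstrate correctness of the inference given the model's own
assumptions, not robustness to these real-data effects.

A planted private site is *observable* when at least one carrier sample
has at least one read showing the planted allele; recovery rates are
reported over observable sites, since a variant with zero supporting
reads is unrecoverable by any method (at M = 40 over 20 leaves, roughly
13% of leaves receive no samples at all).

## Evaluation experiments

`yhap.benchmarks` fixes three seeded experiments used by both the test
suite and `scripts/acceptance.py`:

* **Recovery** (defaults above, 1.5x): fine-level MAP accuracy after EM
  and the fraction of observable planted sites whose learned probability
  exceeds 0.9.
* **Pooling** (same design at 0.6x): mean posterior on the true
  haplogroup with vs without EM, and accuracy among MAP ≥ 0.9 calls.
* **Calibration** (500 samples, 1 marker/branch, 1.0x, per-read error
  0.2, no EM): empirical accuracy per MAP-posterior bin
  [0.5–0.7), [0.7–0.9), [0.9–1.0]. The noisy read regime is deliberate:
  at realistic error rates a single read is nearly decisive, posteriors
  are bimodal (≈ 1/k ties and ≈ 1) and the middle bins are structurally
  empty; heavy per-read noise produces graded evidence so that binned
  calibration measures something.

Problem sizes were chosen so the whole suite and the acceptance script
each run in seconds on one core.

## Known limitations

* EM polarizes posteriors. On cohorts where marker data alone already
  assign nearly everyone (dense marker sets), the mean posterior on the
  truth is near its ceiling and a single confidently wrong pooled call
  can make the *mean* pooling gain slightly negative for a particular
  cohort, even though high-confidence accuracy stays high. The gain
  should be read as a distributional statement across cohorts.
* A marker may only be placed on a single node; recurrent mutations on
  the real tree must be pre-filtered (duplicated positions are rejected
  by default).
* The prior-update smoothing and the soft-genotype definition are
  modelling choices where several defensible variants exist; both are
  exposed as configuration rather than hard-coded.
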