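# yhap

Probabilistic assignment of Y-chromosome haplogroups from low-coverage
sequencing or genotyping data, with EM pooling across a population sample.

## The problem

The Y chromosome is haploid and non-recombining, so every Y lineage belongs
to exactly one clade of a known phylogeny — a *haplogroup* — defined by
bi-allelic SNP markers (major clades A–T, finer labels below them). With
deep genotyping the assignment is a lookup; with low-coverage sequencing
(≈0.5–2 reads per site) most markers of any one sample are simply not
covered, and hard lookups fail. `yhap` treats assignment as Bayesian
inference over genotype *likelihoods*, and additionally pools reads across
samples that the model infers to share a haplogroup — no sample alone needs
adequate coverage.

## The model

Let T be a rooted haplogroup tree with L labelled nodes and let
**H** be the N<sub>ref</sub>×L matrix whose entry **H**<sub>il</sub> =
{H<sub>ilg</sub>} is the probability that a chromosome from the clade below
node l carries allele g ∈ {ref, alt} at marker site i: degenerate {0,1} or
{1,0} at leaves, the proportion of descendant leaves carrying each allele
at internal nodes. Given per-sample haploid genotype likelihoods
**G**<sub>ij</sub> = {G<sub>ijg</sub>} (from VCF PL/GL fields, or 0/1 from
hard calls), the likelihood of sample j under haplogroup l is

P(G<sub>·j</sub> | H<sub>·l</sub>) = ∏<sub>i</sub> ∑<sub>g</sub> G<sub>ijg</sub> H<sub>ilg</sub>

and the posterior over a chosen haplogroup set (major clades, all leaves,
or all nodes) follows by Bayes' rule with a uniform prior. Sites observed
in **G** but absent from the marker table enter an augmented matrix **H\***
with uninformative rows {0.5, 0.5}; these rows, together with the
haplogroup prior, are then fitted by expectation–maximization over the
whole cohort. The EM learns which non-marker alleles are characteristic of
each haplogroup, which both sharpens assignment at low depth and — when a
free row converges to a degenerate distribution exclusive to one
haplogroup — nominates candidate novel markers.

All arithmetic is in log space with log-sum-exp normalization; a
configurable epsilon floor (default 1e-10) keeps contradicted hypotheses
finite.

## Worked example

```bash
python examples/em_pooling.py
```

```
EM converged after 68 iterations (log-likelihood -1792.8 -> -425.8)
mean posterior on the true haplogroup, markers only : 0.9992
mean posterior on the true haplogroup, with pooling : 1.0000
high-confidence calls (MAP >= 0.9): 40/40, accuracy 1.000
```

This simulates 40 haploid samples from a 20-leaf haplogroup tree at 0.6x
mean depth, assigns them from markers alone, then re-assigns after EM
pooling. The two means are the average posterior mass each sample places
on its true haplogroup — pooling recovers the information that no single
sample's reads contain. `examples/assign_cohort.py` shows plain
assignment and `examples/discover_markers.py` shows novel-marker
discovery (it recovers all 10 planted clade-private variants).

The same pipeline is available from the shell:

```bash
yhap simulate --seed 7 --out-dir sim
yhap assign --vcf sim/cohort.vcf --tree sim/tree.nwk --markers sim/markers.tsv --out run
yhap discover --vcf sim/cohort.vcf --tree sim/tree.nwk --markers sim/markers.tsv --out candidates.tsv
```

`assign` writes a per-sample posterior table (`assignments.tsv`), the
fitted **H\*** matrix, the learned prior, the EM log-likelihood trace and
a JSON run summary.

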