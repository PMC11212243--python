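# mdprio

Rare-variant recurrence and network-propagation gene prioritization for
sequenced disease cohorts.

## The problem

Cohort sequencing studies of complex diseases often lack a matched
control population, ruling out conventional gene burden testing. `mdprio`
implements an alternative prioritization strategy built for exactly that
setting (its motivating use case is Ménière's disease, an inner-ear
disorder studied by whole-genome sequencing of a patient cohort):

1. **Unusually frequent variants (UFVs).** Annotated cohort variants are
   reduced to rare (reference allele frequency ≤ 5% in every panel),
   non-benign, protein-altering variants whose cohort allele frequency
   AF = AC/(2N) exceeds 1.3× their expected (gnomAD-style) frequency —
   or which are absent from the reference panel entirely ("novel").
2. **Recurrence.** Genes are scored by the number of *distinct* UFVs they
   harbour; genes with ≥ 4 UFVs form the highly recurrent set.
3. **Network propagation.** Genes carrying UFVs seed a random walk with
   restart over a confidence-weighted protein-interaction network
   (STRING-style edge list). With symmetric normalization
   W̃ = D^(−1/2) W D^(−1/2), scores solve

   F = α W̃ F + (1 − α) S,  0 < α < 1,

   where S is the seed vector (per-gene UFV mutation counts, normalized
   to sum 1). Observed scores are calibrated against an **empirical
   null**: each patient keeps their observed mutation count, but every
   mutation is reassigned to a uniformly random network gene; many
   replicates yield per-gene null moments and hence z-scores
   z = (F − μ₀)/σ₀. Genes with z > 3 form the network set, and the
   **recurrence ∩ network** intersection is the high-priority candidate
   set.
4. **Validation.** Hypergeometric gene-set enrichment (GMT collections,
   Benjamini–Hochberg correction), diagnostic-panel recovery curves
   (cumulative fraction of the cohort carrying ≥ 1 qualifying variant in
   the top-k genes versus the Hardy–Weinberg expectation
   1 − Π(1 − qᵥ)² for a general-population control), and cell-type
   expression-percentile comparisons (Wilcoxon rank-sum per cell type)
   in a labeled single-cell expression matrix.

A fully self-contained synthetic-data module generates cohorts,
networks, gene sets and expression atlases with planted disease genes,
so the entire pipeline is testable without any external downloads.

## Worked example

```python
from mdprio import (
    PropagationConfig, SimulationConfig, cohort_allele_frequency,
    filter_rare_damaging, gene_recurrence, prioritize, ufv_filter,
)
from mdprio.network import network_scores_from_ufvs
from mdprio.simulate import make_truth, simulate_cohort, simulate_network

# filtering arithmetic on a single variant: 52 alleles in 511 samples
af = cohort_allele_frequency(52, 511)
print(round(100 * af, 1), round(af / 0.039, 1))   # -> 5.1 1.3

# a synthetic cohort of 511 patients, 2000 genes, 50 planted disease
# genes with 2-fold-inflated variants forming a connected network module
cfg = SimulationConfig(rng_seed=1)
truth = make_truth(cfg)
variants, _ = simulate_cohort(cfg, truth)
network = simulate_network(cfg, truth)

ufvs = ufv_filter(filter_rare_damaging(variants), cfg.n_samples)
recurrence = gene_recurrence(ufvs, cfg.n_samples)
scores, _ = network_scores_from_ufvs(
    ufvs, network, PropagationConfig(n_null=1000, rng_seed=2))
sets = prioritize(recurrence, scores)
for name in ("recurrence", "network", "intersection"):
    hits = len(sets[name] & truth.disease_genes)
    print(name, len(sets[name]), round(hits / len(sets[name]), 3))
```

Output:

```
5.1 1.3
recurrence 133 0.18
network 213 0.16
intersection 79 0.278
```

133 genes reach ≥ 4 UFVs but only 18% of them are planted disease genes;
intersecting with the propagation z > 3 set shrinks the list to 79 genes
and raises precision to 28% — the combination of recurrence and network
evidence is more specific than either criterion alone (a random set of
79 genes would hit 2.5%).

There is also a CLI mirroring each stage
(`mdprio simulate | filter | recurrence | netprop | enrich | panel |
expression | run`); `mdprio run --config run.yaml` executes the whole
pipeline and writes a manifest.

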