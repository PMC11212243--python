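# Methods

This note documents the models and procedures `mdprio` implements, the
parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Variant filtering

The cohort variant table carries one row per distinct variant with its
cohort allele count, carrier sample ids, reference-panel allele
frequencies and deleteriousness-predictor labels. Two successive filters
apply:

- **Rare & damaging.** A variant is removed when its allele frequency in
  *any* supplied reference panel exceeds `common_af_max` (default 0.05,
  strict inequality), when *any* configured predictor labels it benign
  (OR semantics across predictors; the predictor list is configurable),
  or when its consequence is not protein-altering. The protein-altering
  classes are missense, nonsense, frameshift and in-frame indels,
  nonstop and splice-site; unknown consequence strings map to `other`
  with a warning, and a missing consequence is an error.
- **Unusually frequent (UFV).** A surviving variant is retained when its
  cohort allele frequency AF = AC/(2N) — the diploid convention —
  exceeds `ratio_min` (default 1.3, strict) times its expected
  frequency in one designated reference panel, or when it is novel
  (absent from the panel). A recorded reference frequency of exactly 0
  is treated as novel with a warning. The ratio uses allele frequency
  (not carrier frequency) on both sides.

A variant-level binomial upper-tail p-value
(`variant_count_pvalue`) is provided as a comparator for the ratio
filter; the pipeline itself filters by the observed/expected ratio.

Boundary conventions are deliberate: a variant at exactly 5% reference
frequency survives the rarity filter; a variant at exactly 1.3-fold is
removed by the UFV filter.

## Recurrence

Per gene, `n_ufv` counts *distinct* UFVs (not allele occurrences) and
`n_samples` the union of carrier sets. Genes with `n_ufv ≥ recur_min`
(default 4) form the highly recurrent set. Each variant maps to exactly
one gene symbol; multi-gene annotations must be resolved upstream.
Ranking (for reports and panels) is by `n_ufv`, ties by `n_samples`,
then symbol.

## Network propagation and the empirical null

The interaction network is an undirected, confidence-weighted edge list
(STRING-style 0–1000 integer confidences are auto-detected and rescaled
to fractions). The propagation operator is random walk with restart on
the symmetric degree-normalized adjacency
W̃ = D^(−1/2) W D^(−1/2) (weighted degrees; isolated nodes keep zero
rows):

    F ← α · W̃ · F + (1 − α) · S

iterated until the L1 change drops below `tol` (default 1e-6; for α < 1
the fixed point is unique because the spectral radius of αW̃ is below
1, and equals (1−α)(I−αW̃)⁻¹S). Defaults α = 0.5 and symmetric
normalization are declared design choices; both the restart weight and
the seeding mode are configurable.

**Seeds.** Each gene's seed weight is its total UFV mutation count
across patients (one count per carried UFV), normalized to sum 1;
binary seeding (`seed_mode="binary"`) is available. Seed genes absent
from the network are dropped with a warning and reported in a sidecar
list; such genes can enter prioritization only through recurrence.

**Null ensemble.** Each replicate preserves every patient's observed
mutation count and reassigns each mutation to a gene drawn uniformly
(with replacement) from the network's node set; seeds are rebuilt
exactly as for the observed cohort and propagated. Because patients are
independent and uniform, a replicate's pooled seed counts equal
total-mutation-count iid uniform draws, which is how the implementation
realizes them. Per-gene means and SDs accumulate through a Welford
(one-pass) update; replicate *r* uses the independent stream
`default_rng([rng_seed, r])`, so the ensemble is reproducible and
independent of batch size. The default ensemble size is 10⁴ replicates;
z-ranks are already stable at 10³ (Spearman ρ > 0.95 on 200-gene
synthetic instances, checked in the test suite), so desk-scale analyses
use 300–1000 replicates.

z = (observed − null mean)/null SD; genes with zero null SD are flagged
undefined and sort last. The three candidate sets are `recurrence`
(n_ufv ≥ 4), `network` (z > 3) and their intersection.

## Enrichment

Upper-tail hypergeometric test of query/annotation overlap within a
declared universe; effect sizes as log(observed/expected overlap) and
the log odds ratio of the 2×2 table with a Haldane 0.5 correction when
any cell is empty. Benjamini–Hochberg adjustment is applied within each
query across a collection's sets (BH is the only multiple-testing
procedure in the package). The default testing universe is the
intersection of the collection's universe with the genes under study
(e.g. all genes with ≥ 1 variant), to avoid annotation-coverage bias;
this is configurable. An optional bootstrap SD of log(obs/exp)
(resampling the query with replacement, default 1000 draws) supports
error bars on enrichment plots. Threshold sensitivity re-derives the
three gene sets over grids of `ratio_min`, `recur_min` and `z_min` and
re-tests enrichment at every grid point; network scores are held fixed
across the grid because the propagation itself does not depend on the
thresholds.

## Panel evaluation

For genes ranked by recurrence, the observed curve is the cumulative
fraction of the cohort carrying ≥ 1 qualifying variant (any zygosity)
in the top-k genes. The control curve assumes independent variants in
Hardy–Weinberg equilibrium: a control individual escapes the panel with
probability Π(1 − qᵥ)² over the panel's variants, qᵥ the reference
allele frequency. Novel variants contribute q = 0, making the control
(false-positive) estimate conservative. Note an intrinsic ascertainment
effect: because UFVs are *selected* for high observed/expected ratio,
the observed curve exceeds the control expectation even for neutral
variants; calibration experiments therefore use cohort-independent
variant lists (see below).

## Expression specificity

Within each cell type, every gene's mean expression is converted to a
fractional rank (average ranks for ties, divided by the number of
genes). Percentiles are invariant to monotone per-cell-type transforms,
so raw versus log-normalized means do not change the result. Prioritized
genes are compared against the baseline (all genes with ≥ 1 cohort
variant, which contains the prioritized set) with a two-sided Wilcoxon
rank-sum test per cell type, BH correction across cell types, and
significance tiers FDR < 0.001/0.01/0.05/ns. Sets smaller than 3 genes
skip the test with NaN. Heatmap-style "relative average expression" is
per-gene min-max scaling of cell-type means to [0, 1] (flat genes map
to 0).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at desk scale:

- **Cohort** (defaults): 511 diploid individuals; 2000 genes, 50 of
  them disease genes; Poisson(5) candidate variants per gene; underlying
  population frequencies from a truncated Pareto(α = 1) law on
  [5×10⁻⁴, 0.05] (heavy-tailed toward rare); 10% of variants novel.
  Genotypes are two independent Bernoulli draws per individual at the
  variant's frequency, multiplied by `fold` (default 2.0) in disease
  genes and capped at 1. Only variants observed in ≥ 1 individual are
  emitted unless `include_unobserved` is set (calibration experiments
  need the ascertainment-free table). Nuisance variants — common,
  benign-labelled, non-protein-altering — are planted at 5%/10%/5% to
  exercise the filters. Consequence categories follow the spectrum
  typical of a filtered WGS cohort (≈ 90% missense; indel classes set
  the variant type, giving ≈ 97.7% SNP / 2% DEL / 0.3% INS).
- **Network**: Erdős–Rényi background (edge probability 0.005, i.e.
  mean degree 10 at 2000 genes) plus a planted module — a random
  spanning tree over the disease genes (guaranteeing connectivity) and
  extra internal edges at `module_factor` (default 10) times the
  background probability. Confidences are uniform on (0.2, 1].
- **Gene sets**: background inclusion at rate set-size/universe;
  disease genes enter designated "relevant" sets at 5× that rate.
- **Expression atlas**: 8 cell types × 30 cells; per-gene log-normal
  baseline means, Poisson counts; disease genes up-shifted by
  exp(effect size) (default e¹) in 2 designated cell types.

All generators are deterministic given `rng_seed`; each component draws
from its own derived stream (`default_rng([rng_seed, k])`).

What the generator does **not** emulate: linkage disequilibrium,
relatedness, population stratification, gene length/mutability
covariation beyond Poisson variant counts, scale-free network topology,
annotation-ontology structure, or single-cell dropout/batch effects.
Passing recovery tests therefore demonstrate that the pipeline's logic
and calibration behave as designed under its own model assumptions —
not that real cohorts satisfy those assumptions.

## Calibration and recovery experiments (test suite)

- **Oracle equivalence**: iterative propagation matches the dense
  linear solve to < 1e-8 on networks up to 200 nodes; hypergeometric
  p-values match exhaustive enumeration over all query draws on
  universes up to 25 genes; BH matches the reference implementation in
  statsmodels.
- **Null calibration**: on no-signal cohorts (fold 1, no module,
  50-gene networks, 500-replicate nulls, 8 cohorts) mean gene z is
  within ±0.1; on fold-1 cohorts with the ascertainment-free table and
  no novel variants, observed and Hardy–Weinberg control curves agree
  within Monte-Carlo error.
- **Recovery**: at the default planted configuration, the intersection
  set's precision against the planted disease genes exceeds both the
  recurrence-only set and a size-matched random set in ≥ 95% of 50
  replicates (300-replicate nulls keep the suite fast; the z-rank
  stability result above justifies the reduced ensemble).

Problem sizes in these experiments (gene counts, replicate counts,
ensemble sizes) are the package's chosen desk-scale defaults; all are
configurable upward.

## Degenerate inputs and tie-breaking

Empty edge sets yield a zero operator (propagation then returns the
normalized seed vector); seed vectors with no positive network weight
are an error; duplicate edges keep the larger confidence; self-loops are
dropped with a warning. Gene ordering ties break lexicographically
everywhere so outputs are fully deterministic.

## Limitations

- No burden testing (by design: the setting assumes no control cohort);
  the observed/expected ratio filter is sensitive to small-count noise
  at very rare frequencies, which is why recurrence and network
  evidence are combined downstream.
- The Hardy–Weinberg control model ignores LD between panel variants
  and underestimates the false-positive rate for panels of UFVs (the
  selection effect described above).
- The propagation variant (restart parameter, normalization) is a
  declared default, not a uniquely determined choice; both are exposed
  in `PropagationConfig`.
- Genes absent from the interaction network receive no z-score and can
  be prioritized only via recurrence.
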