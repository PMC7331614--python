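# Methods

## Model and assumptions

`metaboprop` prioritizes candidate disease genes for a single patient by
combining two sources of evidence: (i) patient-specific differential
abundance of metabolites relative to a control population, aggregated
per gene through the gene→metabolite annotation map, and (ii) the
topology of a weighted gene–gene functional-linkage network, through
which metabolic evidence diffuses to genes that lack direct
annotations. The underlying assumptions are the standard ones of
guilt-by-association methods: genes close in the functional network
participate in related biochemistry, so a perturbation caused by gene
*g* disturbs metabolites annotated to *g*'s neighborhood even when *g*
itself has no measurable metabolites (membrane transporters, channels,
regulators). The method makes no attempt to model reaction
stoichiometry or flux; the network is treated purely as a smoothing
operator.

## Pipeline stages

### Abundance → z-scores → DAMs

Raw feature tables (features × samples, one patient plus ≥ 2 controls,
one biofluid per table) pass through:

1. **Median scaling** — each sample is rescaled so its median detected
   intensity equals the grand median of per-sample medians.
2. **Imputation** — missing values take the feature's minimum detected
   intensity (detection-limit censoring assumption).
3. **Prevalence filter** — features detected in < 10% of samples are
   dropped; the boundary is inclusive (exactly 10% is kept).
4. **log₂(x + 1) transform**, then **linear baseline normalization**:
   the baseline profile bᵢ is the per-feature median across samples and
   each sample *j* is multiplied by βⱼ = mean(b)/mean(y·ⱼ), making every
   run a scalar multiple of the shared baseline. One pass equalizes all
   per-sample means; a second pass therefore applies a single global
   scalar shared by all samples — not the identity — which downstream
   z-scores are invariant to.
5. **z-scoring** — z = (x_patient − mean)/sd with the sample (n−1)
   standard deviation over all samples *including* the patient (a
   leave-patient-out mode is a flag). Zero-variance features are
   dropped with a warning. Curated inputs (metabolite-ID × z TSV)
   bypass all of the above.

DAMs are metabolites with |z| ≥ 2 (inclusive, both signs; threshold
configurable). When positive- and negative-ionization tables are
merged, duplicate metabolite IDs keep the largest-magnitude z.

### Feature → metabolite annotation

Observed m/z values are matched to metabolite monoisotopic masses
within a ppm tolerance (default 15 ppm, inclusive, denominator = the
theoretical candidate mass). Two adduct conventions are exposed because
upstream pipelines differ: `neutral` (m/z already deconvoluted to
neutral mass) and `protonation` ([M+H]⁺ / [M−H]⁻, ± 1.007276 Da).
Default is `neutral` for the bundled synthetic data; raw positive/
negative-mode ESI data should use `protonation`. All qualifying
identities are retained (identity ambiguity is deliberately passed
through to enrichment rather than resolved). Before enrichment,
features matching no metabolite and features flagged as non-base
isotopes (`[M+1]`, `[M+2]`, … in a CAMERA-style isotope column) are
removed.

### Enrichment seeds

The metabolite universe is the measured metabolites annotated to at
least one gene. Per gene: one-sided over-representation p-value from
the hypergeometric upper tail (scipy), Benjamini–Hochberg FDR across
tested genes (statsmodels) — reported, but scoring uses the unadjusted
p. Genes with no annotated measured metabolite are reported untested.

Two seed transforms:

* `neglog` (default): raw = −log₂(p)·|z|ₘₐₓ — monotone increasing in
  enrichment strength and in the strongest metabolite signal.
* `eq3_literal`: raw = −log₂(2 + p)·|z|ₘₐₓ — a published variant,
  retained for strict reproduction. Its raw values lie in
  [−1.585·|z|ₘₐₓ, −|z|ₘₐₓ] and *decrease* as |z|ₘₐₓ grows, so after
  scaling it inverts the z ordering; this non-monotonicity is why it is
  not the default.

Scaling to [0, 1] is per patient over genes with k ≥ 1: `neglog` raw
scores (non-negative) are divided by their maximum, preserving strict
positivity of every enriched gene; `eq3_literal` raw scores (negative)
are min–max scaled. If all k ≥ 1 raws coincide each scales to 1. Genes
with k = 0 receive exactly 0.

### Propagation

Zhou-style label spreading on w′ᵢⱼ = wᵢⱼ/√(dᵢdⱼ):
f⁽ʳ⁾ = λW′f⁽ʳ⁻¹⁾ + (1−λ)y, initialized at f⁽⁰⁾ = y. Since the spectral
radius of W′ is ≤ 1 and λ < 1, the iteration contracts to
f\* = (1−λ)(I−λW′)⁻¹y from any start; the initialization choice is for
reproducibility only. Parameters: λ = 0.99 (heavy smoothing — the
regime in which neighborhood evidence dominates the retained seed),
convergence when the L∞ change ≤ 1e−6 (small enough that candidate
rankings on all bundled fixtures are stable well below one rank),
max 10 000 iterations with a hard error carrying the last iterate.
`propagate_exact` performs the dense resolvent solve and is guarded to
2 000 nodes; it serves as the oracle in the test suite, never as the
production path. Seeds naming genes absent from the network are
ignored with a warning (propagation is defined only on the network);
network genes without seeds get y = 0.

### Ranking, benchmark, fusion

Candidates are ranked by descending score with competition (min) ranks
— conservative for a top-k criterion — and percentile 100·rank/N;
candidates missing from the score table get score 0 and sort last. The
permutation benchmark embeds the n causative genes in 1000 random sets
of 300 genes (drawing 300 − n without replacement from the network
universe minus the causative genes, fully seeded) and records the
per-gene median rank.

The fused score is C = scale(p·E) + scale((1−p)·M): E and M are first
min–max scaled over the candidate list, multiplied by the prior weights,
and the two products are min–max scaled again before summing (a
constant term scales to 0, so the fusion degenerates exactly to
phenotype-only at p ≡ 1 and propagation-only at p ≡ 0). The prior p is
computed per decile bin of the percentage of a gene's first-degree
neighbors carrying metabolite annotations (bins [0,10), …, [90,100]):
p_b is the fraction of network genes in bin b whose full-network
propagated percentile is ≤ 20. Priors are computed per patient from
that patient's own propagation result, keeping the tool applicable to
a single patient; where the "scale between 0 and 1" step applies
(inputs, products, or both) was genuinely open — the
inputs-then-products pipeline above is the package's reading and is
what the degeneracy tests pin down.

## Synthetic data: what it emulates, what it does not

The generator produces a STRING-like network (integer combined scores
uniform in [150, 999]; Erdős–Rényi or Barabási–Albert topology), an
HMDB-like annotation map, and per-patient z-score or raw feature
tables. Defaults define the simulated study: 500 genes at mean degree
≈ 10; 50% of genes annotated with 1–8 metabolites drawn from a shared
pool (pool size ≈ 0.6 × total slots, so pathway neighbors share
substrates); 20 control samples for raw tables; background z ~ N(0, 1);
planted metabolites shifted by ±3 z-units, giving each a ≈ 84% chance
of crossing the DAM threshold against a ≈ 4.6% background rate. Three
planting modes: `direct` (the causative gene's own metabolites shift),
`neighbor-only` (the causative gene is unannotated; all annotated
first neighbors — required ≥ 3 — shift), `null` (an unrelated gene
shifts). Direct-mode causative genes are drawn from genes with ≥ 3
annotated metabolites, mirroring benchmark cohorts restricted to
disorders with detectable biomarkers; with a single-metabolite gene the
planted signal is statistically indistinguishable from the background
false-DAM rate.

What the synthetic data does **not** emulate: correlated metabolite
covariance (background z-scores are independent), retention-time or
batch structure, adduct/isotope envelopes beyond a verbatim flag
column, annotation errors, and the heavy-tailed degree–annotation
coupling of the real STRING/HMDB overlap. Passing tests therefore
demonstrate correctness of the computations and the qualitative
neighborhood-rescue behavior, not clinical-grade sensitivity on real
cohorts.

Raw-table generation inverts the z-score construction on the log₂
scale (control intensities 2^N(μᵢ, 1), patient 2^(μᵢ + zᵢ)), so the
raw route recovers the planted z-scores up to sampling noise; the
raw-vs-curated equivalence test feeds the raw route's own derived
z-table through the curated route, isolating the annotation and
filtering stages as the only difference.

## Numerical choices and degenerate inputs

* Fisher p clipped to ≤ 1 against floating-point tail sums; k = 0 gives
  p = 1 exactly.
* ppm comparison carries a 1e−9 ppm guard so decimally-exact boundary
  cases (e.g. 15.000 ppm) are not lost to binary representation.
* Normalization: isolated nodes keep zero rows (no normalized edges);
  duplicate A–B/B–A rows merge keeping the max weight; self-loops are
  rejected (or dropped when created by alias collapse).
* Empty DAM sets are valid (all seeds 0, propagation returns all
  zeros); an all-tied permutation ranking is flagged as degenerate
  rather than hidden.
* STRING combined scores are used unscaled: the symmetric normalization
  is invariant to any global weight scale (tested).

## Problem sizes in the bundled experiments

The test suite and `scripts/acceptance.py` use 50-patient cohorts on
500-gene networks, random propagation-oracle graphs up to 500 nodes,
exhaustive Fisher enumeration up to a 12-metabolite universe, and the
full 1000 × 300 permutation protocol on 500–2000-gene universes; these
sizes exercise every code path while keeping a full run in seconds to
minutes on one CPU.

## Known limitations

* Gene identity is by symbol; the alias map is a plain two-column
  translation with max-weight collision handling, not a full ID
  service.
* Adduct handling is ± one proton only; multimers, sodiated adducts and
  in-source fragments are out of scope.
* The physical-interaction filter trusts a binding/physical channel
  column in the edge list; it does not recompute channel evidence.
* Bin priors for the fusion are per patient; pooled-cohort priors would
  need an external loop.
* ME = 0 genes are unrecoverable by the enrichment score alone by
  construction; that is the gap propagation exists to fill, and the
  neighbor-only experiments quantify it on synthetic data only.
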