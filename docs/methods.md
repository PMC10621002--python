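# Methods

## Scope and data model

The pipeline operates on per-sample gene quantification tables (estimated
counts and effective lengths, as produced by pseudoalignment tools),
gene→MAG membership with biotype (CDS/rRNA/tRNA) and marker-family
annotation, sample metadata (treatment/control with replicates), and a
set of target MAG ids. All tables are TSV; networks export to GraphML,
GEXF, or an edge-list TSV. Identifiers are case-sensitive exact strings.
Genes without a MAG assignment are kept for gene-level statistics but
never enter MAG aggregation.

## MAG-level TPM

TPM_i = (q_i/l_i) / Σ_j (q_j/l_j) × 10⁶, where q_i and l_i are the sums
of estimated counts and effective lengths over MAG *i*'s coding genes.
Noncoding RNAs (rRNA, tRNA) are excluded from numerator and denominator:
ribosomal transcripts are orders of magnitude more abundant than mRNA and
would otherwise dominate every profile. Aggregating counts and lengths
*before* forming the rate is deliberately different from summing per-gene
TPMs (a regression test pins the distinction). Per sample the MAG TPM
vector sums to 10⁶ whenever any MAG is expressed; a sample with no counts
yields a zero column with a warning rather than a division error.

For display (network node size) the mean log10 TPM over the treatment
samples is used, with zeros floored at 10⁻² TPM (configurable) so silent
MAGs stay representable. MAGs expressed nowhere remain nodes; constant
profiles can never form edges.

## Differential expression

log-CPM: log2((count + 0.5) / (library + 1) × 10⁶) with library size the
per-sample total of estimated counts; no TMM normalization or precision
weights (out of scope by design — counts feed the model directly). The
moderated t follows the standard empirical-Bayes linear-model treatment:
per gene, b = mean(treatment) − mean(control), pooled residual variance
s² on d_g = n − 2 df; across genes, s² is modeled as s₀²·F(d_g, d₀) and
(d₀, s₀²) estimated by moment-matching log s² (digamma/trigamma
relations, Newton inversion of the trigamma function); then
s²_post = (d₀s₀² + d_g s²)/(d₀ + d_g), t = b/(u·s_post) with
u = √(1/n_t + 1/n_c), and a two-sided p on d₀ + d_g df (normal when d₀ is
infinite). Zero-variance genes are excluded from the moment fit; if every
gene is constant the prior df is set to +∞ with a warning. The
implementation agrees with Bioconductor limma's `lmFit`+`eBayes` to
machine precision on identical input, which the test suite checks via
Rscript.

With the duplicated-microcosm design (2 vs 2) each gene has only 2
residual df; the stage emits a warning that adjusted significance then
rests almost entirely on the moderation. `d0` and `s02` can be overridden
(0 = classical pooled t; ∞ = full shrinkage), which the closed-form limit
tests exercise.

Enriched genes: log2 fold change > 0 (an optional minimum fold change is
exposed), BH-adjusted p < α (default 0.05), biotype CDS. rRNA/tRNA genes
are never enriched regardless of their statistics.

## Coexpression network

Spearman correlation uses average ranks for ties and the t-approximation
p = 2·P(T_{n−2} > |ρ|·√((n−2)/(1−ρ²))), with p = 0 at |ρ| = 1 and an
undefined (flagged, never an edge) result for constant profiles. The
t-approximation rather than the exact permutation law is a deliberate and
consequential choice: with n = 4 samples the exact two-sided p of even a
perfect correlation is 2/24 ≈ 0.083, which can never clear α = 0.05 — the
approximation is the only reading under which significant edges exist at
such n, at the cost of optimistic p-values there. With four samples, only
ρ = 1 (identical rank order) can form an edge; users should treat n = 4
networks as rank-coincidence graphs and prefer more samples when they can.

Benjamini–Hochberg is the exact step-up construction (sorted
min-over-tail of m·p/j, capped at 1), applied once over all unordered
pairs of the profile pool. By default the pool is the union of MAG
profiles and enriched-gene profiles ("union"); a "mag" option restricts
the family to MAG–MAG pairs. Edges are MAG–MAG only, one-sided positive:
ρ > 0.8 (anti-correlation never joins) and adjusted p < α. Gene profiles
never become nodes. The target neighborhood is the set of non-target MAGs
with a direct edge to at least one target, annotated "all" or "subset"
according to how many targets they touch.

A practical note on the BH family: when the union pool contains a large
block of genuinely correlated profiles (hundreds of co-enriched genes),
the step-up threshold rises toward the raw α, so the *marginal* MAG–MAG
edge behaves as if barely adjusted. That is correct FDR behavior for the
whole family, but for quantifying the false-edge rate among MAG pairs the
"mag" family is the right instrument, and the validation below uses it.

## Role assignment

A marker-family leaf is satisfied for a MAG iff the MAG carries ≥ 1 gene
of that family with estimated count ≥ 1 (configurable) in at least 2
samples (per-rule configurable), all samples pooled across conditions.
Rules are AND/OR trees over leaves; the built-in registry encodes seven
roles (acetate/H₂ producer, corrinoid transporter, CO metabolizer,
corrinoid assembler/salvager — one role with two display names —
cobyrinate a,c-diamide producer, DMB producer, RP producer). Fractional
counts below the threshold never count as expression. Every granted role
records its evidence (gene, family, samples expressed), and replaying the
evidence re-derives the grant (tested). Mapping annotation products or
KEGG orthologs to family labels is the upstream annotator's concern; an
example mapping ships in `magcoex/data/example_family_mapping.yaml`.

## Summaries

Role composition over a reference set (typically the target neighborhood)
uses the *full* reference set as the percentage denominator — not only
the members holding some role — rounded half-up to one decimal for
display with full precision retained internally. The expression fraction
of a role is 100 × (Σ mean-treatment TPM of correlated holders)/(Σ over
all holders); it is invariant to global TPM rescaling and undefined
(flagged NaN) when the role has no expression.

## Synthetic communities

The generator emulates the emulated study design: 160 MAGs, 2 treatment +
2 control samples, 20–60 genes per MAG, negative-binomial counts
(gamma–Poisson, dispersion 0.2) with mean = MAG latent abundance ×
lognormal gene weight (log-sd 1, median ≈ 100 counts) × sample depth.
Latent structure:

* **Target block** (default 10 MAGs including the 3 targets): one shared
  trajectory — lognormal replicate-bottle noise (log-sd 0.3) times a 2⁴
  condition effect in treatment — scaled per MAG; strictly co-monotone by
  construction. Its baseline scale is 0.08× a typical MAG, keeping the
  bloom a modest share of community expression so the compositional
  (closed-sum) coupling it imposes on everyone else stays small.
* **Anti block** (default 10 competitor MAGs): independent volatile
  trajectories (log-sd 0.7) rejection-sampled to Spearman ≤ 0 against the
  target trajectory.
* **Background MAGs**: per-MAG treatment response (log2 fold change ~
  Normal(0, 1)) on top of their own replicate noise. Communities respond
  broadly to an amendment; this is what makes the default network dense
  (typically ~155/160 MAGs have at least one edge at n = 4) and gives
  genes homogeneous residual variances, so empirical-Bayes moderation
  behaves as designed.
* rRNA/tRNA genes (5% of genes, counts inflated 50×) make the noncoding
  exclusion consequential; marker genes (mean ≈ 80 counts) are planted
  per role so role assignment has exact ground truth.

Dispersion 0 means the deterministic noise-free limit: counts equal their
(fractional) means, as pseudoalignment counts are fractional anyway; this
makes rank-preservation and block-clique properties exact rather than
probabilistic. All randomness derives from one seed; identical configs
give byte-identical files.

What the generator does **not** emulate: sequencing error, mapping
ambiguity, genome incompleteness/contamination, within-MAG operon
structure, compositional interactions beyond the closed TPM sum, and
temporal dynamics. Passing tests therefore demonstrate correctness of the
statistical machinery on data satisfying its assumptions, not performance
on real sediment metatranscriptomes.

## Validation designs and problem sizes

* **Normalization**: 500 randomized small communities (3–8 MAGs, mixed
  dispersions including 0) check the 10⁶ per-sample TPM sum to 1e-6
  relative tolerance.
* **Oracle equivalence**: Spearman vs explicit rank-then-Pearson (and
  scipy) on 200 tied integer vectors, |Δρ| < 1e-12; BH vs the literal
  min-over-tail construction (and statsmodels), bitwise, on 100 random
  p-vectors.
* **Network recovery**: the noise-free check runs the full 160-MAG, 2×2
  default with dispersion 0 — the planted block must form its complete
  45-edge clique with no edge into the competitor block. The
  moderate-dispersion check uses 20 seeds at 6 samples per condition with
  condition-neutral backgrounds and the MAG-only BH family: more samples
  because n = 4 admits only ρ = 1 edges (rank coarseness) and chance rank
  coincidences (1/24 per pair) would swamp any false-edge bound;
  condition-neutral backgrounds because backgrounds with real responses
  carry true unplanted correlations that would be miscounted as errors.
  Under that design mean planted-edge recall is ≈ 0.95 and the unplanted
  fraction ≈ 0.045 — the BH FDR guarantee observed end to end.
* **Moderated-t calibration**: d₀ = 0 matches the classical pooled t and
  d₀ = ∞ the closed-form limit, both to 1e-9; five 2000-gene null
  simulations (no planted effect) each reject at 0.05 within three
  binomial standard errors of one experiment (±0.0146). The rate on
  log-CPM of negative-binomial counts sits slightly above 0.05 on average
  (~0.053–0.058, matched exactly by limma on the same matrices) — an
  inherent property of unweighted log-CPM moderation, which is why the
  per-experiment band is the meaningful check.
* **Role soundness**: on the noise-free default community every planted
  role is recovered and nothing else is granted.

All simulation sizes were chosen so the whole suite runs in well under a
minute on one CPU while keeping every check at full method scale (the
160-MAG community is simulated outright, never subsampled).

## Known limitations

TPM is compositional: a genuine bloom depresses every other MAG's TPM,
which can induce (anti-)correlations with no ecological meaning — the
generator keeps the planted bloom small partly to expose what remains.
The t-approximation p-values are optimistic at very small n. The BH
family choice materially changes edge counts and is exposed rather than
hidden. Role assignment is presence/expression logic, not pathway
completeness scoring. Networks are static; temporal designs are out of
scope.
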