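# Methods

## Model and assumptions

The package operates on per-study gene-level summaries: a two-sided
p-value and a direction of regulation per gene, as exported by study
browsers when raw expression data are unavailable. The conversion
*z* = Φ⁻¹(1 − *p*) (up) / Φ⁻¹(*p*) (down) treats each study's p-value as
exact and its direction as reliable; under a true null and valid p-values
the deviates are standard normal, so the Stouffer combination
Σ*z*/√*N* is again standard normal regardless of how many studies measured
the gene. The combination assumes independence across studies — shared
samples or platforms between studies would inflate the combined |Z|.

Two algebraic consequences the pipeline relies on, both enforced by tests:
the combination is permutation-invariant and scales as √*N* for concordant
evidence, and the nested two-table averaging gives effective weights
(¼, ¼, ½) to (level-1 contrast, normal-vs-localized prostate,
localized-vs-metastatic) for genes present at every stage.

### Group balancing

Cancer types contribute different study counts and sample sizes, which
directly scale |Z|. Before the bone-vs-non-bone contrast, each type's
combined table is multiplied by `target / mean|Z|_type`, where the target
is the unweighted mean over types of the per-type mean |Z|. Balancing runs
jointly across all four types (one common target), and the balanced
per-type tables are averaged — not Stouffer-combined — within each side,
so each cancer type contributes equally to its side regardless of how many
studies it brought. Prostate-level combinations are not balanced: they are
a single tissue, and rescaling a single group is a no-op by construction.

### Missing-gene policy

Platforms overlap only partially, so every pairwise operation needs a
policy for one-sided genes. The contrast defaults to `intersect` (a
difference requires both sides; dropped counts are logged), the level-2/3
averages default to `carry` (keep the available value), mirroring how
partially overlapping platforms are usually pooled: losing a gene from the
final table merely because one side's platforms missed it would discard
evidence, whereas a one-sided *difference* would be biased. Both policies
are switchable per call.

### Ranking and hubs

Candidates are the k = 250 largest and smallest signed level-3 scores;
boundary ties break lexicographically by symbol for reproducibility. Hub
selection works on the subnetwork induced by the top candidates (nodes
with at least one internal edge): a gene is a hub if its subnetwork degree
is ≥ 5 and its local connectivity is ≥ 2× its overall connectivity.
"Connectivity" is normalized as degree/(network size − 1) so the local and
overall quantities are comparable densities; a raw-degree ratio is
available via `normalized=False`. Edges are undirected and simple —
regulation and binding interactions are collapsed, since direction plays
no role in the criterion.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *consumed* granularity of multi-study
meta-analysis inputs rather than raw arrays. For each study, per-gene
two-sample t-statistics are drawn from the noncentral t with
noncentrality `effect·sqrt(n1·n2/(n1+n2))` and `n1+n2−2` degrees of
freedom, giving two-sided p-values whose sharpness scales with sample size
exactly as in a real t-test; the reported direction is the sign of the
drawn statistic (a zero statistic counts as "up", a deterministic
tie-break). Platforms are seeded uniform subsamples of the gene universe
(fractions 0.6–1.0), so contributing-study counts vary per gene.

The default scenario plants three independent effect layers over 10,000
genes, 100 genes each at standardized effect 1.0, half up and half down
(odd counts resolve toward up): a tumor signature shared by all cancer
types (cancelled by the level-1 subtraction), a bone-metastasis-specific
signature carried by breast, lung and prostate, and a metastasis signature
in the localized-vs-metastatic contrast. Five studies per role with
per-class sample sizes drawn from ranges typical of published cohorts
(normal-vs-tumor: 3–41 vs 7–64; localized-vs-metastatic: 23–64 vs 5–25).
A composite "advanced vs benign" effect map (bone + metastasis layers)
drives the simulated 9-case/5-control validation experiment.

Interactomes wire each planted hub to at least `hub_degree_min` partners,
drawn from the planted signature genes with probability 0.9 so hub
neighborhoods fall inside top-candidate lists, plus uniform background
edges. Expression matrices are Gaussian log-intensities with a group-mean
shift equal to the planted effect.

Deliberately not emulated: probe-level noise and normalization artifacts,
batch effects, correlated genes (effects are planted independently),
dependent studies, and p-value miscalibration in the source studies.
Passing tests therefore demonstrate that the pipeline recovers planted
signal under clean, independent summaries — not that it is robust to
correlated or biased inputs.

## Numerical choices

- p-values are clamped into [1e-15, 1 − 1e-15] on ingest (with a logged
  count) so Φ⁻¹ stays finite; no realistic p moves materially.
- The Stouffer denominator is √N. The method's standard form divides by
  √N, and the √N scaling law is pinned by tests; the denominator lives in
  one function should a variant ever be needed.
- p-values are used exactly as supplied (no halving): sidedness of the
  source studies is taken at face value, with the direction flag carrying
  the sign.
- A group with mean |Z| = 0 cannot be balanced and raises a dedicated
  error rather than producing infinite factors.
- Genes with zero pooled variance in the expression t-test get p = 1 with
  a warning; their log-ratio is still reported.
- The Fisher r-to-z comparison assumes independent samples. When two
  correlations share a vector (as in comparing per-type correlations
  against the same prostate table) the statistic is approximate; the
  dependent-correlation covariance is not computable from summary inputs,
  so the independent-samples form is used and documented as such.
- Master seeds fan out through `numpy.random.SeedSequence` so adding or
  reordering components does not couple their streams; all derived seeds
  stay below 2³¹.

## Problem sizes

The test suite runs the full pipeline at 10,000 genes for the recovery
checks (50 seeded replicates for the enrichment trend) and scales
unit-level Monte-Carlo checks down to 100–500 replicates at 400–4,000
genes; one full-size replicate takes well under a second, the whole suite
about half a minute.

## Known limitations

- The per-gene combination weights studies only through their p-values;
  no effect-size or random-effects modeling (out of scope by design).
- Balancing equalizes mean |Z| across cancer types but cannot correct
  within-type heterogeneity between studies.
- Hub selection depends on the interactome's completeness; missing edges
  in sparsely annotated regions depress both degree criteria.
- With `carry` averaging, a gene measured only in late levels receives a
  halved single-source score rather than a principled reweighting; its
  provenance is visible through `n_studies`.
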