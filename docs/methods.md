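# Methods

This note documents the statistical procedures implemented in `crosspath`,
the design choices made where the method is genuinely open, and what the
synthetic cohort does and does not emulate.

## Differential screen

Features (mRNAs and miRNAs) are compared between tumor and normal samples
with the unpaired Student *t*-test (pooled variance; Welch available via
`welch=True`). A feature is differential when all three hold: BH FDR < 0.01,
|log₂FC| > 2 and raw *P* < 0.05; each threshold is configurable. The two
molecule classes are corrected separately (they are screened as separate
datasets with very different feature counts).

Scale conventions: expression is stored linear. The *t*-test runs on
log2(x+1)-transformed values by default (`test_scale="log2"`) because linear
abundances are heavy-tailed and a raw-scale *t* loses most of its power;
`test_scale="linear"` reproduces the textbook behaviour on small hand
examples. Fold change is the ratio of linear group means (pseudocount 1e-9
guards zero expression); `fc_on_log` switches to the difference of log2
means. Degenerate features (zero variance in both groups, equal means) get
p = 1 by convention.

## Co-expression modules and risk factors

Differential mRNAs and miRNAs are clustered jointly on log2 scale. The
unsigned soft-threshold adjacency |cor|^β (default β = 6; `signed` uses
((1+cor)/2)^β) is converted to topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), and average-
linkage clustering of 1 − TOM is cut at a fixed dendrogram height.

The default cut height is **0.9**. A fixed cut at 0.25 — the value usually
quoted for eigengene *merging* — is not meaningful on a TOM-dissimilarity
dendrogram: even near-perfect modules (within-module correlation 0.8 at
β = 6) sit at within-module TOM dissimilarity ≈ 0.6–0.8, while cross-module
merges happen near 1.0, so 0.9 separates the two regimes (the
`cutreeStatic` convention). Clusters smaller than `min_module_size` (10)
form a grey pool that never contributes risk factors.

Each module's eigengene (first principal component of the standardized
member submatrix, sign-oriented along mean member expression) is correlated
with the phenotype (tumor = 1). Risk factors are the members of the
phenotype-correlated module(s): `module_select="top"` takes the single
module with maximal |r| among those with p < 0.05, `"all-significant"`
(the pipeline default) takes the union over all passing modules — with
strong planted effects several modules are genuinely cancer-correlated, and
published per-cancer risk-factor counts (hundreds to thousands) are only
reachable with more than one module.

A scale-free soft-power criterion (`pick_soft_power`) is provided: smallest
β whose log-log degree-frequency fit reaches R² ≥ 0.8, falling back to 6.
The pipeline fixes β = 6 by default; block-structured cohorts are not
scale-free, so the criterion is only advisory there.

## Pathway reconstruction and risk pathways

A miRNA is attached to a pathway when its targets are over-represented
among the pathway's mRNAs: with N background mRNAs, M pathway mRNAs,
n in-universe targets and m in-pathway targets, the upper tail P(X ≥ m) of
the hypergeometric distribution is compared to α = 0.05, and edges are
added to the in-pathway targets only. P(X ≥ m) (= 1 − Σ_{k≤m−1}) is the
over-representation convention; the strict tail P(X > m) — which would let
a perfect overlap reach p = 0 — is available as `tail="gt"`. The tail is
evaluated by `scipy.stats.hypergeom.sf` (log-space internally) and is
verified against exact rational enumeration in the tests.

Risk pathways use the same tail with mixed counts: M = pathway mRNAs +
attached miRNAs, n = risk mRNAs + risk miRNAs, N = the mRNA+miRNA
expression universe (both sets mix the two kinds, so the background must
too). Raw p < 0.05 is thresholded without multiplicity correction, matching
the screening convention this method family uses; `apply_bh=True` enables
BH.

## Crosstalk

For risk pathways i, j, every cross-pathway feature pair (a ∈ i, b ∈ j,
a ≠ b) carrying an interaction edge — PPI for mRNA–mRNA, a miRNA→target
edge for mixed pairs; miRNA–miRNA pairs have no interaction source and are
not scored — contributes

CS(a,b) = −(ln P(a) + ln P(b) + ln P(a,b)),

with P(a), P(b) the raw differential t-test p-values (not FDR: the score is
defined directly on the test) and P(a,b) the two-sided Pearson correlation
p-value across all samples by default (`correlation_samples="tumor"`
restricts to tumors). p-values are clamped to [1e-300, 1], so CS ∈
[0, ≈2072] and all crosstalk totals are finite and nonnegative. A feature
shared by both pathways never pairs with itself but may pair with other
members of the opposite pathway; unordered pairs are counted once per
pathway pair. Correlations are memoized across pathway pairs.

## Drug perturbation

DS(d) = 1 − Crosstalk_d/Crosstalk_s, clipped to [0, 1], where Crosstalk_d
is the network total after deleting the drug's mRNA and miRNA targets from
every risk pathway. Deletion never adds interacting pairs, so the reduced
total is computed exactly by filtering the full network's recorded
contributions. Drugs with DS > 0.01 pass the single screen.

**Cascade removal** (default on): an attached miRNA whose in-pathway target
mRNAs are all deleted is deleted from that pathway too (to fixpoint).
Without the cascade, removal kills a fixed union of nonnegative CS terms,
so DS is provably subadditive — DS(T₁∪T₂) ≤ DS(T₁)+DS(T₂) — and the
combination rule below could only ever be met with equality. The cascade is
the explicit mechanism by which two drugs can jointly silence a miRNA
neither silences alone, making strict superadditivity possible; it is this
package's modelling choice for how "greater than the sum" scores arise.

Pairs of passing drugs are scored on the union of their target sets and
selected when DS_combo ≥ DS₁ + DS₂ − 1e-9 (`criterion="gt"` demands strict
excess). Results are ranked by DS_combo; affected pathway pairs (crosstalk
before/after) are recorded per combination.

## Survival validation

Tumor samples are clustered by K-means (k = 2, 10 restarts, seeded) on the
per-feature z-scored expression of the combination's target signature —
by default the targets appearing in the combination's affected pathway
pairs (`survival_scope="all"` uses every target). The two groups are
compared by the two-group log-rank test (lifelines); the group with the
smaller median Kaplan–Meier survival is labelled high-risk (the method
defines no orientation, so it is assigned post hoc). p < 0.05 is read as
survival relevance of the target signature.

## Synthetic cohort

The generator emulates the statistical structure of a TCGA-style cohort
plus curated interaction resources on a desk scale (defaults: 40 tumor +
40 normal samples, 500 mRNAs, 50 miRNAs, 20 pathways, 12 drugs):

* **Expression** is log-normal: log2 values are
  μ_i + l_i·f_k(sample) + d_i·1[tumor] + σ·ε, exponentiated to linear.
  30% of features are differential with |d| = 3 (log2); most belong to one
  of 4 modules driven by shared latent factors scaled so the within-module
  correlation is 0.8 (the phenotype shift contributes, the factor supplies
  the rest); a 15% "solo" fraction is differential but unclustered, with
  doubled noise. Module miRNAs load negatively (l = −1, opposite shift), so
  planted miRNA→target edges carry negative correlation.
* **Pathways**: 8 of 20 are risk pathways drawing 75% of their members from
  one module; the rest draw from non-differential mRNAs. Bridge PPI edges
  connect designated risk-pathway pairs between differential members — the
  planted crosstalk. 600 background PPI edges are random.
* **Drugs**: one pathway-attached miRNA's in-pathway targets are split
  between DRUG01 and DRUG02 (the planted superadditive pair: only their
  union orphans the miRNA, whose additional cross-pathway target edges are
  its cascade payload); DRUG03/DRUG04 hit bridges of two disjoint modules
  and are exactly additive (background PPI edges between their target sets,
  or between the two cascade halves, are rejected during generation, making
  these properties structural); DRUG05 is a strong single drug; the rest
  carry small random target sets.
* **Survival** is exponential with median 800 days and log-linear rate in
  the mean z-scored expression of the planted combination signature
  (β = 1.0), censored administratively at 3000 days.

Identical config + seed is byte-identical. What the generator does *not*
emulate: batch effects, copy-number confounding, count noise, realistic
KEGG topology, hub-dominated PPI degree distributions, or competing risks —
so passing tests demonstrate correctness of the pipeline's logic under its
own model assumptions, not performance on real cohorts.

## Numerical choices and degenerate inputs

* Hypergeometric bounds are validated; out-of-range (N, M, n, m) raise.
* Constant expression vectors: correlation r = 0, p = 1 (warned); constant
  features in adjacency get zero correlation.
* p-value clamp 1e-300 in CS; DS clipped to [0, 1]; combination tolerance
  1e-9 absorbs float cancellation in the ≥ comparison.
* All serialized JSON is key-sorted; matrices are written with %.17g and
  read with round-trip float parsing, so writer→reader cycles are exact and
  reruns are byte-identical.
* Problem sizes in the test and acceptance runs (5 seeds of the default
  cohort; 100–200 random fixtures for the oracle and subadditivity checks;
  1000 replicates for calibration) keep the full suite under a minute while
  leaving the binomial calibration bands (0.03–0.07 at nominal 0.05) tight.

## Known limitations

* The crosstalk score has no significance model; scores are comparable
  within a cohort, not across cohorts of different size.
* Only 2-drug combinations are screened; no dose, toxicity or
  pharmacokinetics.
* Module detection uses a static cut, not dynamic tree cut or eigengene
  merging; very unbalanced module sizes may need a different `cut_height`.
* With `cascade=False` the selection rule admits only (numerically) additive
  pairs — by design, see the subadditivity law above.
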