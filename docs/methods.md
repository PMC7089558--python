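# Methods

## Instrument model

The PAT 2.0 register ships as a JSON resource with 57 scored items across the
seven subscales (8 structure/resources, 4 social support, 15 child problems,
8 family problems, 3 caregiver stress, 4 family beliefs, 15 sibling
problems). 38 of these are *network items* — the nodes of the item-level
network; the sibling scale and four further items (three structure/resources,
one child problems) are scored but not part of the network. Ids and labels of
the 38 network items follow the published instrument; the remaining ids and
labels are package-assigned placeholders, flagged as such in the resource,
because the instrument itself is proprietary. The generic variant
(`PAT2.0_GEN`) removes item 9 (and would remove 15g/15i, which are not among
the scored items registered here); both variants share one scoring code path
driven entirely by the catalog.

Scoring choices that the instrument's public description leaves open:

* **Total score** = unweighted sum of the seven subscale scores — the only
  rule consistent with the documented 0–7 range for seven 0–1 subscales.
* **Risk bands**: the published partition prints "<1 / 1.0–1.9 / >2", which
  leaves (1.9, 2.0) and the point 2.0 unassigned; we use the contiguous,
  exhaustive reading [0,1) / [1,2) / [2,7], right-continuous at both
  cutpoints.
* **Inapplicable sibling scale**: families without siblings score 0 on
  sibling problems (flagged on the score card), keeping everyone on the 0–7
  scale. An entirely missing non-sibling subscale makes the total undefined
  rather than silently prorated.
* **Dichotomisation boundary**: the pipeline ingests already-dichotomized
  responses (0/1/missing). The instrument's raw-response-to-risk mapping is
  per-item and proprietary, so it is explicitly out of scope.

## Synthetic cohort generator

The generator emulates the three study cohorts (leukemia n=90, epilepsy n=42,
asthma n=63) with a latent-threshold (multivariate probit) model: family *f*
draws a latent vector **z** ~ N(0, **R**) and answers item *i* with risk iff
z<sub>i</sub> > Φ⁻¹(1 − p<sub>i</sub>). Expected subscale score = mean item
prevalence, an exact identity used throughout the tests.

Calibration, in order:

1. **Subscale means** — every item on a subscale starts at the published
   subscale mean. Two means are not published and are set by residual so the
   means sum to the published totals: leukemia structure/support 0.05/0.04
   (total 1.44) and epilepsy sibling 0.05 (total 1.0). The published asthma
   means sum to 0.922 against a printed total of 0.90; the printed subscale
   values are kept.
2. **Item anchors** — published item prevalences are imposed (change-mood
   0.80/0.50/0.60 for leukemia/epilepsy/asthma, distractibility 0.80 for
   epilepsy, excessive worry 0.58 and prolonged sadness 0.24 for leukemia)
   and the free items on the same subscale are renormalised,
   (m·μ − Σanchors)/(m − k), so subscale and total means are preserved
   exactly in expectation.
3. **Dependence** — **R** is block-structured: one within-subscale
   correlation per subscale, solved (bivariate-normal orthant identity +
   Brent root-finding) so the model-implied subscale-score SD matches the
   published SD; 0.4 where no SD is published; 0.3 between the subscale
   pairs each disease's network is described as connecting tightly; 0.05
   background. Negative eigenvalues are clipped at 1e-8 and the diagonal
   renormalised; because that repair pulls strongly negative within-block
   values toward zero, a short fixed-point iteration re-adjusts the inputs so
   the *repaired* blocks land on their targets up to global PSD feasibility.
   The published asthma sibling SD (0.26 at mean 0.008) exceeds the maximum
   attainable for a [0,1] variable and is treated as a printing error (the
   solved correlation clamps at its upper bound).
4. **Sibling scale** — 80% of families are sampled as having siblings;
   per-item sibling prevalence is the published cohort-level mean divided by
   that rate (inapplicable families score 0), and sibling items form their
   own latent block, independent of the 38 network items.

One seeded generator drives a cohort, consumed family-by-family in a fixed
order, so output is byte-for-byte reproducible. Prevalences of 0 or 1 are
legal and yield constant columns, which the network stage excludes as
zero-variance nodes.

**What the generator does *not* emulate**: covariates (age, sex, site),
longitudinal T0→T1 change, item-specific prevalence variation beyond the
published anchors, and any joint structure beyond second moments. Passing
tests therefore demonstrate that the pipeline recovers what the published
tables encode — not that it would reproduce every statistic of the real
cohorts (see "Known limitations").

## Network estimation

Pearson correlation on 0/1 items (= phi coefficient) over pairwise-complete
observations; per-edge complete-pair counts are recorded and edges with fewer
than 3 complete pairs are unestimable. Two-sided p-values come from
*t* = *r*√((m−2)/(1−r²)) with df = m−2. A tetrachoric estimator (the latent
correlation under the same threshold model, solved from the 2×2 table with a
0.5 continuity correction on empty cells) is available as an option, but phi
is the default: product-moment correlation is what standard desktop network
tools compute on exported 0/1 data. Zero-variance items are excluded and
listed on the results object.

Thresholding: significance (retain p < α, α = 0.05 uncorrected, by design —
the reduced graphs are descriptive, not inferential) and proportional (retain
⌈f·E⌉ edges of largest |r|, default f = 0.2; ties broken by node-pair order
for reproducibility). Both can be chained; they are idempotent and never add
edges. Negative correlations keep their sign as metadata while magnitude
drives thresholding, strength and path lengths — the usual symptom-network
convention.

Layout: Fruchterman–Reingold implemented directly with a central gravity
term (default 10, mirroring common desktop settings), seeded initial
positions and linear cooling over 200 iterations. Desktop gravity/speed
settings do not map one-to-one onto any textbook FR variant, so only the
qualitative property is contractual (and tested): high-strength nodes sit
nearer the layout centroid than weakly connected ones.

## Graph metrics

Betweenness uses edge lengths 1/|r| and is normalised by (n−1)(n−2)/2;
closeness is Wasserman–Faust component-scaled with isolated nodes at 0 —
a convention is mandatory because the estimated networks are disconnected.
Diameter and average path length are unweighted hop metrics on the largest
connected component. The clustering coefficient is the mean binary local
transitivity with degree<2 nodes contributing 0. Modularity is the value of
the partition found by deterministic greedy (Clauset–Newman–Moore)
maximisation — the desktop tools' Louvain is stochastic with an unrecorded
resolution, so a deterministic stand-in keeps runs comparable; it is NaN on
an edgeless graph. All of these are checked against closed forms and an
exhaustive path-enumeration oracle on small random graphs.

## Cluster analysis

k-means (k = 2, 20 seeded restarts keeping the lowest within-cluster sum of
squares) on subscale scores z-scored across the pooled cohort; zero-variance
subscales contribute 0. Rows are sorted by family id before fitting so the
solution is invariant to input order. Labels are canonicalised by the raw
family-beliefs centroid (cluster 2 = high beliefs). The silhouette score is
reported, with a k ∈ {2, 3, 4} diagnostic helper. The original analysis ran
in a closed-source statistics package whose exact procedure and distance
settings are unrecorded; k-means on standardized profiles is the
reproducible reconstruction, with k fixed at 2 (the published solution).

## Problem sizes and numerical choices

Replicate-averaged checks use 200 cohorts per disease for calibration
recovery and 100 pooled replicates for cluster recovery — large enough that
Monte-Carlo error is well below the tolerances (the grand-mean SE of the
leukemia total is ≈ 0.004), small enough for interactive runs. Marginal
recovery is tested at n = 10⁴ with ±2 binomial-SE bands. Centrality
correctness is tested on 500 random graphs of ≤ 8 nodes against the
brute-force oracle. PSD clipping threshold 1e-8; Brent tolerance 1e-4 on
correlations; proportional-threshold ties resolved lexicographically.

## Known limitations

* The published per-item centrality figures and global network
  characteristics of the real cohorts derive from unavailable patient data;
  the package reproduces the *machinery* (verified against oracles), not
  those specific numbers. The published global-characteristics table is also
  internally inconsistent (average degree 3.2 on 38 nodes implies density
  0.086, not the printed 0.094, consistent with zero-variance items having
  been dropped).
* Under the fully calibrated generator, the pooled two-cluster solution
  assigns ~63% of simulated leukemia families to the high-beliefs cluster
  versus the published 90% (epilepsy ~75% vs 83%, asthma ~81% vs 82%). A
  supervised linear classifier on the same simulated features reaches only
  ~81% leukemia-vs-rest accuracy, so the published marginal moments do not
  encode enough separation for 90% unsupervised recovery: the real cohorts'
  cluster structure rests on joint, within-family patterns the publication
  does not print. The package reports what the calibrated model actually
  yields rather than tuning dependence parameters to force the published
  shares.
* The latent-threshold model is exchangeable within subscale blocks; real
  item-level heterogeneity (beyond the anchored items) is not represented.
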