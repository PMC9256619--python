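# Methods

`droughtnet` implements a three-level analysis of microbial community
stability under drought and rewetting — community composition, all
pairwise correlations, and co-occurrence networks — together with the
artifact checks that guard the network level, and a synthetic-data
generator that emulates the underlying field design so every stage can be
tested end to end without sequencing data.

## Study design assumed by the pipeline

Two irrigation treatments (control; pre-flowering drought) with six
replicate plots each, sampled weekly over 17 weeks in four plant
compartments (leaf, root, rhizosphere, soil), with paired bacterial (16S)
and fungal (ITS) OTU tables per sample. Drought runs over weeks 3–8;
watering resumes in week 9.

Samples are split into two analysis windows that decouple time from
treatment. The drought window is weeks 3–8 (36 communities = 6 plots × 6
weeks per treatment and compartment). For the correlation and network
analyses the rewetting window is weeks 10–17 (48 communities = 6 plots × 8
weeks): watering resumes during week 9, so week 9 communities were sampled
before rewetting could act, and including it would give nine time points
where the design calls for eight. The resilience statistics, by contrast,
evaluate every week 9–17 against the week-8 baseline, because the per-week
recovery trajectory — including the not-yet-recovered week 9 — is the
quantity of interest there.

Early-season fungal leaf samples (weeks 1–8) are excluded from fungal
analyses; in the source material the fungal fraction of leaf reads is too
low early in the season to quantify the mycobiome.

## Preparation

Tables are rarefied once, before window splitting, to a common depth
(default 10,000 reads) by exact without-replacement subsampling (a
multivariate hypergeometric draw per sample); samples below the depth are
dropped and logged. Correlation/network datasets additionally drop taxa
occurring in fewer than 8 communities of that dataset (window × treatment
× compartment), applied per dataset because each network is built
separately. Fungal tables are analyzed at OTU level and, for the
stability statistics, also aggregated to family level, to control for the
coarser taxonomic resolution of ITS versus 16S.

## Stability: resistance and resilience

From the Bray–Curtis dissimilarity matrix of a compartment's communities,
same-week sample pairs are partitioned into within-group pairs
(control–control and drought–drought) and between-group pairs
(control–drought).

*Resistance*, per drought week: a two-sided Welch t-test of between-pair
versus within-pair dissimilarities; Bonferroni adjustment over the weeks
tested within one compartment × kingdom × resolution; a week is flagged
"affected by drought" when the adjusted p < 0.05 **and** the between mean
exceeds the within mean. Pair dissimilarities at a week share samples, so
they are not independent; the test ignores this (matching the procedure it
implements) and every row carries a `dependent_pairs` caveat flag. The
null calibration test shows the directional, Bonferroni-adjusted
family-wise flag stays at or below its nominal rate under the generator's
null despite the dependence.

*Resilience*, per recovery week t: with d_p(t) = BC of between-pair p
minus the week-t within mean, the matched-pair resilience is
R_p(t) = d_p(8) − d_p(t), positive when the drought community moved back
toward controls; R may exceed the baseline gap (overshoot is allowed).
Pairs are matched on (control plot, drought plot) identity.

*Kingdom contrasts*: bacteria versus fungi compared by Welch t-test on the
per-pair statistics (d_p for resistance, R_p for resilience) over the
intersection of plot pairs. Both per-week rows and window-pooled rows are
reported; per-week directions at n = 36 pairs are noisy, so the pooled row
(all drought weeks; or the last three recovery weeks, where the
fast-recovering kingdom has plateaued) is the headline readout of the
asymmetry.

*Dual resolution*: a fungal result is "robust" if the significance flag
(and, when significant, the direction) agrees between OTU- and
family-level analyses; non-robust weeks are flagged and excluded from
headline output.

## All-correlation analysis

Spearman ρ (mid-rank Pearson; p from the t approximation on n − 2 df) over
all taxon pairs of one window × treatment × compartment dataset, BH-FDR
adjusted over all pairs of that dataset. Pairs are classed BB, FF or BF by
endpoint kingdoms. Summaries report the combined mean ρ, the positive
mean, the negative mean × (−1) for comparability, and the fraction of
positive pairs (ρ = 0 counts as non-positive).

The treatment contrast is a stratified permutation test rather than a
linear mixed-effect model fit: the observed effect per link class (and
pooled over all pairs, class "ALL") is the treatment-minus-control
difference in mean ρ, fraction positive, and positive-mean; the null
distribution permutes treatment labels across communities within each
compartment stratum and recomputes everything, preserving group sizes and
the dependence structure of the pair set; two-sided
p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1). The full ρ distributions are
exported so a mixed model can be fitted externally if desired. Defaults:
999 permutations.

Compositional closure matters here: relative abundances sum to one, so a
coherent positive block is partly offset by induced negative correlations
between the block and the rest of the table. The positive-mean statistic
isolates block-type signals cleanly; the pooled fraction-positive is the
stress-gradient readout.

## Co-occurrence networks

Edges are correlations with ρ > 0.6 (strict) and q < 0.05; vertices are
edge endpoints only, so vertex counts respond to edge loss. Modules come
from greedy modularity maximization (Clauset–Newman–Moore, via networkx)
on the unweighted graph, with nodes pre-sorted for deterministic
tie-breaking; Q is the standard modularity of that partition (a weighted
variant using ρ is available behind a flag). Per node, the within-module
degree z-score Zi (z of the node's intra-module degree against its module,
population SD; Zi = 0 with a flag when the module has zero spread) and the
participation coefficient Pi = 1 − Σ_t (κ_it/k_i)². Role thresholds follow
the Guimerà–Amaral convention as used in pollination-network ecology:
module hub Zi > 2.5, connector Pi > 0.62, network hub both, else
peripheral.

Network comparisons (treatment − control at identical thresholds) report
per-class edge deltas with a disrupted/enhanced/unchanged call by sign,
plus modularity and role-count changes. Guild/phylum edge composition
reports proportions of edges within versus between annotation groups,
optionally restricted to the "new" edges of a comparison. AMF subnetworks
keep edges from arbuscular-mycorrhizal fungi to other fungi (network A)
and to bacteria (network B); AMF–AMF edges belong to neither and are
counted separately.

## Artifact checks

*Temporal autocorrelation*: six independent 'taxa', each six replicate
Gaussian random walks (start 0, standard-normal increments — the walk
distribution is a design choice) of six (drought) or eight (rewetting)
weekly points; replicate × week observations are pooled per taxon exactly
as the real analysis pools plots × weeks; all 15 pairs are tested against
the network edge criteria with BH over the 15 (FDR-adjusted, for
consistency with the edge criteria). The median significant count over 20
iterations is ≤ 1, so the criteria are essentially immune to
autocorrelation artifacts at this design size.

*Spatial attribution*: for each network edge, the partial Spearman
correlation of the two taxa controlling for plot coordinates (ranks
residualized on ranked x, y with intercept; t approximation on n − 4 df);
an edge is "spatially driven" when it met the criteria marginally but its
partial correlation does not (BH over the tested edges). Partial rank
correlation is the operational definition here; the interface is isolated
so a distance-matrix regression could be slotted in.

## Synthetic data generator

A latent-Gaussian copula: per sample, a standard-normal latent vector
receives (i) equicorrelated blocks — each block a taxon subset, target
latent correlation, link class, and an activity condition (always /
unstressed / stressed, optionally compartment-restricted), where
"stressed" means a drought-treatment sample during drought weeks; (ii) a
shared stress factor with equal loadings on a fixed random subset of taxa,
active only in stressed samples. Log abundance = per-taxon log-normal
baseline (SD 1.0) + 0.8 × latent + drought shift + optional spatial
gradient; counts are multinomial per kingdom at a log-normal library size
(median 25,000, log-SD 0.15 — so rarefaction at 10,000 never drops samples
by default). The drought shift is a kingdom-level loading times a fixed
per-taxon response direction, active during drought weeks and decaying as
exp(−r·(week − 8)) afterwards.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| bacterial / fungal drought shift | 1.2 / 0.6 (log-scale) | fungi half as responsive: the community-level asymmetry under test |
| bacterial / fungal recovery rate | 0.8 / 0.15 per week | bacteria essentially recovered by week ~11; fungi retain ~25% of their shift at week 17 |
| blocks | BB 8 taxa ρ 0.85 and BF 6 taxa ρ 0.90, active when unstressed; FF 6 taxa ρ 0.85, stressed-only, rhizosphere | strong associations that drought destroys (BB, BF) or creates (FF); ρ chosen so rank correlations survive the double multinomial attenuation and clear the 0.6 edge threshold |
| stress factor | loading 0.9 on 40% of taxa | pairwise latent correlation 0.9²/(1+0.9²) ≈ 0.45 — raises the positive-correlation fraction under drought while staying below the strong-edge threshold |
| taxa | 200 bacteria, 100 fungi | typical post-filter richness scale; tests use smaller tables |
| spatial gradient | 2.0 (when spatial taxa requested) | strong enough that a purely spatial pair enters the network and is flagged |

Tight blocks (ρ ≥ 0.6) are placed on taxa with elevated baselines so the
planted correlations survive read noise; diffuse blocks are left at their
drawn baselines to avoid inflating closure feedback. Plot coordinates
follow a randomized-block grid (treatments alternating across 16 × 8 m
cells), so position is not confounded with treatment — a confounded layout
would make treatment effects look spatial.

What the generator does **not** emulate: temporal autocorrelation within a
plot's series (samples are independent given their condition),
phylogenetic structure, read-level artifacts (chimeras, primer bias),
taxon-specific extraction efficiencies, and realistic zero inflation
beyond what the multinomial induces. Passing recovery tests therefore
show that the pipeline detects these effect types at field-realistic
design sizes — not that real data contain them.

## Numerical choices and degenerate inputs

- Rarefaction is a per-sample multivariate hypergeometric draw from a
  single seeded generator; identical seed ⇒ identical table.
- Bray–Curtis on a pair of all-zero samples is undefined → rejected with
  the sample ids; a zero-variance resistance test reports p = 1 with a
  degenerate flag.
- Spearman records for taxa with fewer than two distinct values are
  dropped and logged; datasets need ≥ 4 samples.
- BH-FDR enforces step-up monotonicity and caps at 1 (statsmodels
  `fdr_bh`, verified against a hand-written oracle).
- Greedy modularity requires ≥ 1 edge; node order is fixed by sorting, so
  results are reproducible across runs.
- ρ = 0.6 exactly is *not* an edge (strict inequality), and ρ = 0 pairs
  count as non-positive.
- Permutation p-values use the add-one estimator, so they are never 0.

## Problem sizes used by the test suite

The acceptance checks run the full pipeline at 60 bacterial + 40 fungal
taxa over the complete 4-compartment design for 20 seeds (parameter
recovery), and single-compartment null datasets of 24 + 12 taxa for 100
seeds with 999 permutations each (calibration). These sizes keep the
planted-effect signal-to-noise at the level of the full design while the
whole suite completes in minutes on one CPU; the generator's *effect*
parameters are always the defaults above.

## Known limitations

- The t-tests on pair dissimilarities inherit the dependence caveat; a
  permutation analog would be exact but is not what the implemented
  procedure specifies.
- The stratified permutation contrast replaces a mixed-model t-test; it
  preserves the grouping structure but does not estimate variance
  components.
- Fast-greedy modularity is order-dependent in general; determinism here
  comes from fixed node ordering, not from a canonical optimum.
- Partial rank correlation on coordinates captures linear spatial trends
  only; patchy spatial structure would need a distance-matrix approach.
- BIOM input is not supported; tables are TSV (samples × taxa).
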