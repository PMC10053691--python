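# Methods

This note documents the models and numerical choices behind
`phyloassembly`: the two-statistic null-model framework for
partitioning community assembly processes, the per-taxon phyloscore and
its phylofactorization, the downstream ecology statistics, and the
synthetic metacommunity generator used to verify every stage.

## Phylogenetic turnover: βMNTD and βNTI

For a sample pair (k, m) over a shared taxon pool with cophenetic
(patristic) distances d_ij, the between-sample mean nearest taxon
distance is

    βMNTD = ½ [ Σ_{i∈k} f_ik · min_{j∈m} d_ij  +  Σ_{j∈m} f_jm · min_{i∈k} d_ij ]

with f the within-sample relative abundances (presence weighting is an
option). Under the default conspecific handling (`include`) a taxon
present in both samples has nearest-taxon distance zero; under
`exclude` the minimum is taken over the other sample's taxa minus the
taxon itself and the weights are renormalized over taxa that retain a
candidate (a taxon whose only potential neighbour is itself is
dropped from that side).

βNTI is the z-score of the observed βMNTD against a null distribution
obtained by shuffling the tip labels of the phylogeny across the
regional pool: the permutation randomizes *which* taxa carry the
observed abundances while preserving the distribution of phylogenetic
distances and the pair's co-occurrence pattern. The z-score uses the
sample standard deviation (ddof = 1) of the null replicates; the
default is 999 replicates, and a zero null standard deviation raises an
error rather than returning an arbitrary value. Within one analysis
group all pairs share a single permutation stream, which also serves
the phyloscore nulls, so the two statistics are internally consistent.

The regional pool for the shuffle is the full aligned analysis dataset
(all ASVs of the study tree), not the taxa observed within one group.
This matters: under homogeneous selection a group's own observed taxa
collapse onto the selected clades, and a shuffle restricted to them has
no contrast left — the same reason empirical studies hand the complete
study tree to the randomization.

Pairs are enumerated lexicographically by sample identifier within each
analysis group (floodplain × stream type); pairs containing an empty
sample are skipped.

## Compositional turnover: Bray–Curtis and RC_Bray

Bray–Curtis dissimilarity is 1 − 2·Σ min(a_i, b_i)/(Σa + Σb) on the
observed integer counts (no rarefaction; each sample's total is
preserved). The abundance-based Raup–Crick null assembles each
community afresh: taxa are drawn without replacement with probability
proportional to their occupancy frequency in the group until the
sample's observed richness is reached (implemented by Gumbel-top-k,
which is equivalent to sequential weighted sampling); each drawn taxon
receives one individual and the remaining N − richness individuals are
distributed multinomially in proportion to the pool's mean relative
abundances. This construction preserves each sample's richness and
total count exactly in every replicate. With the observed Bray–Curtis
ranked against the null values (ties at half weight),

    RC_Bray = 2 · (#{null < obs} + ½·#{null = obs}) / n_reps − 1  ∈ [−1, 1].

One set of null assemblies is drawn per sample (from a per-sample seed
substream) and shared by all pairs involving that sample, which keeps
the metric symmetric under argument swap and the cost linear in the
number of samples. Counts are processed in a canonical (sorted) sample
order so results are invariant to the caller's row order down to the
last bit.

A property worth knowing: RC_Bray is a rank statistic and is uniformly
distributed only for communities assembled by its own null process.
Samples that are multinomial draws from one static pool come out near
−1 (they are more similar than the membership-randomizing null — the
mass-effect signature the framework labels homogenizing dispersal), and
strongly overdispersed communities come out near +1. Calibration tests
therefore draw their communities from the null assembly process itself;
the neutral-drift scenario is used for βNTI calibration, where the
tip-shuffle null is insensitive to these compositional details.

## Process classification

The two-step decision rule, with strict inequalities so that boundary
values fall to the stochastic interior:

| condition                       | process                 |
|---------------------------------|-------------------------|
| βNTI < −2                       | homogeneous selection   |
| βNTI > +2                       | variable selection      |
| else RC_Bray < −0.95            | homogenizing dispersal  |
| else RC_Bray > +0.95            | dispersal limitation    |
| otherwise                       | drift                   |

RC_Bray is computed only for pairs with |βNTI| ≤ 2 unless a full
computation is forced. Group summaries report per-process counts and
proportions (summing to one).

## Phyloscores and phylofactorization

For each pair and each ASV present in exactly one of the two
communities, the observed nearest-taxon distance is the minimum
patristic distance to the other community's taxa; its phyloscore is the
z-score of that distance against the same tip-shuffle null used for
βNTI. An ASV's total phyloscore sums its phyloscores over all scored
pairs; cells with zero null spread are dropped and counted. Shared
taxa are not scored — including them would pin their scores at zero
distance and add no information.

Phylofactorization walks the edges of the phylogeny. Each edge splits
the current bin of taxa into a candidate clade and its outgroup, and a
two-sample contrast on total phyloscores scores the split. The edge
with the largest |statistic| is accepted as a factor if its p-value,
Bonferroni-adjusted by the number of edges tested in that step, is
below α (default 0.001); the clade is then frozen and the remainder
stays an active bin. Freezing extracted clades keeps factors disjoint.
Candidate clades need `min_clade` members (default 2, so detection is
unconstrained) and at least two taxa per side with non-degenerate
variance; the display rule of reporting only clades with more than 20
members is applied at output time, with all factors retained in a
diagnostics table.

The default contrast is Student's pooled-variance t. Welch's t is
available but deliberately not the default: as a max-|t| selection
objective it degenerates, because a two-tip clade with near-identical
scores has near-zero within-clade variance and an unboundedly inflated
statistic, so factorization extracts minuscule subclades instead of the
planted clade. The pooled-variance statistic is dominated by outgroup
variance and does not reward tiny near-constant clades. A rank-based
option (Mann–Whitney, converted to its normal-approximation z so the
statistic is signed and magnitude-comparable) is also provided.

Clades whose mean total phyloscore is below the outgroup's
(direction "lower") are the clades under homogeneous selection (HoS);
"higher" factors are reported separately. Consensus taxonomy is the
deepest rank at which at least 80% (configurable) of a clade's
classified members share one name. HoS ASV sets from the two stream
types of a floodplain are partitioned into shared / exclusive /
none categories with percentages of the HoS union.

## Ecology of HoS clades

Per sample, the richness fraction (share of observed ASVs belonging to
any HoS clade) and abundance fraction (summed relative abundance of
HoS ASVs) are computed; both are invariant to column order and count
rescaling. Stream-type comparisons use Welch's t-test by default with
a Wilcoxon fallback under degenerate variance. Chlorophyll-a models
are ordinary least squares of each contribution on the sediment
chlorophyll a concentration, per floodplain, reporting slope, p-value
and adjusted R². Genus-level analysis aggregates HoS ASVs at the genus
rank (ASVs without a genus are dropped and counted), orders samples by
ascending chlorophyll a, keeps the 30 most abundant genera, and
computes Spearman correlations with Benjamini–Hochberg correction
across genera per floodplain. The chronosequence rerun repeats the
full turnover/classification pipeline per upstream/downstream region
subgroup (subgroups with fewer than two samples are skipped with a
warning) and compares environmental variables between regions by
Mann–Whitney tests with BH correction.

## Synthetic metacommunity generator

The generator emulates the shape of the survey — three floodplains ×
two stream types, sites split into upstream/downstream regions, a
chlorophyll-a covariate — with planted assembly processes and full
ground truth.

**Phylogeny and traits.** Pure-birth (Yule) trees; the study generator
uses the ultrametric variant, whose early waiting times put long
branches at the deep splits, so a Brownian niche trait is strongly
clade-structured. Regional pool abundances are lognormal(0, 1).

**Selection scenarios.** Sites sample N individuals (default 150) with
weights mixing a Gaussian filter on the niche trait with a neutral
mass-effect term, the two components normalized separately so the mix
parameter m is the realized immigrant share (default 0.05). The niche
width is 0.25 pool-trait standard deviations. The filter targets
planted clades carrying a stem trait innovation: each planted clade's
trait mean is moved onto a common niche value 3 sd above the pool mean
(convergent adaptation). Without the shift, Brownian trait values
collide across clades and a Gaussian filter selects a phylogenetically
scattered set, which the nearest-taxon statistics correctly do not
read as clustering. Planted clades are the phylogenetically tightest
mid-size clades of the tree (smallest mean within-clade distance,
holding 4–12% of tips each, mutually disjoint). Site-level lognormal
noise (sd 1.2) on the pool weights turns over the identity of locally
dominant clade members between sites — the within-clade microdiversity
turnover that gives the nearest-taxon statistics their signal.

In the default study every group is under homogeneous selection, with
nested targets: each floodplain has one floodplain-wide clade selected
in both of its stream types, and each stream type one stream-specific
clade shared across floodplains (five disjoint clades in total). This
mirrors the shared/exclusive clade structure the pipeline is meant to
resolve and keeps the study-wide pool phylogenetically diverse, which
the tip-shuffle null requires. Variable selection gives every site its
own optimum, spread over quantiles of the trait axis.

**Stochastic scenarios.** Neutral drift follows Sloan's neutral
community model: site compositions are Dirichlet-distributed around
the pool with concentration N·m (migration m = 0.3, a
literature-typical value), then observed by multinomial sampling.
Plain multinomial resampling of a static pool is deliberately not used
for drift — it is a pure mass effect and produces compositional
similarity below any drift expectation. Dispersal limitation assigns
taxa to disjoint site-specific subpools with neutral assembly within
each; homogenizing dispersal resamples every site from one realized
source community. These constructions are one reasonable choice among
several; they are labelled by their truth label in the output manifest.

**Covariate coupling.** Chlorophyll a is lognormal around a scale of
2 µg/g with a log-scale contribution `coupling × standardized
planted-clade abundance` (default coupling −0.8, noise sd 0.4):
greener sites carry less of the selected clades. A site-level
dispersal-mix gradient (`mix_span`) creates the ecological variation
in clade dominance that the coupling acts on; it defaults to zero in
the study generator (where the focus is process recovery) and is
switched on (0.6) in the covariate-recovery configuration. Bacterial
abundances are lognormal around 10⁸ cells/g.

**What the generator does not emulate.** Sequencing noise, chimeras,
compositional artifacts of relative-abundance data, spatial
autocorrelation along the floodplain, seasonal structure, and real
SILVA taxonomy (lineages are derived from the simulated tree's own
clade structure by depth cuts, which is sufficient to exercise the
consensus-taxonomy logic). Passing tests on these data show the
statistics behave as designed under their own model assumptions; they
do not certify behaviour under real-data artifacts.

## Problem sizes and determinism

Verification runs use trees of 100–1024 tips, 4–21 sites per group,
and 99–999 null replicates, chosen so each check exercises the regime
it is about (e.g. 999 replicates and ≥200 pairs for null calibration;
a 1024-tip pool for planted-process recovery so communities stay
sparse relative to the pool, as in real surveys). All randomness
derives from a single master seed through named, collision-resistant
substreams (CRC-hashed labels into a `SeedSequence` spawn key), so
stage-level reruns reproduce pipeline runs bit for bit, and two runs
with the same configuration produce identical numeric outputs.

## Known limitations

- βNTI needs the analysis tree to extend beyond any single group's
  selected taxa; on a dataset whose pool is a single clade the null
  has no contrast and z-scores shrink toward zero.
- RC_Bray is uniformly distributed only under its own null assembly
  process; interpreting mid-range values as "drift" inherits that
  model choice (see above).
- The Bonferroni adjustment within a factorization step is
  conservative given the strong dependence of edge contrasts; the
  planted-clade tests show it costs little power at the scales used.
- Consensus taxonomy resolves ties toward the more frequent name and
  returns "Unclassified" only when no member carries any
  classification.
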