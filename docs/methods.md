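# Methods

This note documents the statistical procedures implemented in
`hybridbiome`, the choices made where the methodology was genuinely open,
and what the synthetic-data validation does and does not demonstrate.

## Study design assumed by the pipeline

The pipeline compares four populations: a clonal hybrid lineage sampled at
two sites, each syntopic with one of its progenitor species (maternal
progenitor at site 1, paternal at site 2), for one body site per table
(gut and skin data are two independent runs). Preprocessing removes taxa
not identified as Bacteria or Archaea, drops samples with fewer than
10,000 reads (strictly lower; a 10,000-read sample is kept), and rarefies
every sample to a common depth — by default the minimum retained sample
sum, configurable because the appropriate depth is a property of each
dataset. Rarefaction is without replacement (multivariate hypergeometric);
implementations of rarefaction differ on this point across tools and
versions, and the choice matters only at depths close to the sample total.

## Bootstrap assemblages and the 83.4% CI rule

Population-level traits (multisite β, γ, core and unique-core diversity)
have no per-host replicate, so uncertainty is estimated by resampling from
an incidence-based bootstrap assemblage (Chao2 family):

* undetected richness `Q0 = ((T−1)/T)·Q1²/(2Q2)` when `Q2 > 0`, else the
  bias-corrected form `((T−1)/T)·Q1(Q1−1)/2`;
* coverage deficit `(Q1/U)·[(T−1)Q1/((T−1)Q1+2Q2)]`;
* observed detection probabilities `π_i = (Y_i/T)(1 − λ(1−Y_i/T)^T)`, with
  `λ` chosen so total shrinkage equals the deficit; each of `round(Q0)`
  anonymous undetected taxa receives an equal share of the deficit.

The exact inflation constant for the undetected component is the one
under-specified piece of the published framework; the implementation
follows the iNEXT-style incidence bootstrap above and keeps the estimate
fixed (one assemblage per population, `round(Q0)` anonymous taxa in every
replicate, not re-drawn). Phylogenetic bootstrap metrics use
observed-taxa-only assemblages, because anonymous taxa have no placement
on the tree; taxon-count metrics use the full assemblage. In validation
runs the undetected component is small (a handful of taxa against
hundreds observed).

From each assemblage, B = 500 pseudo-populations of N = 15 hosts are drawn
(each taxon independently present with its `π_i`). The 83.4% interval is
formed from order statistics `round(0.166·B)` and `round(0.834·B)` — the
83rd and 417th of 500 — and two populations are called different when
their intervals are disjoint (touching endpoints overlap). Under
approximate normality with comparable variances this corresponds to a
pairwise test at roughly α = 0.05; the calibration run
(`calibration.ci_overlap_calibration`, two samples from one community,
γ-richness, 1000 replicate pairs) measures the realised rate, which lands
near 4–7% under the generator's default conditions.

Replicates with an undefined ratio (empty core ⇒ percent unique core
undefined) are recorded as missing and dropped before order statistics;
the effective replicate count is reported.

## Diversity metrics

Richness counts presences. Shannon uses the natural log; Simpson is the
Gini–Simpson form `1 − Σ p²`. Faith's PD is the rooted form (branch
lengths of the minimal subtree connecting the community to the root),
computed on a precomputed branch index and cross-checked against
scikit-bio in the tests. Rao's quadratic entropy `Σ d_ij p_i p_j` requires
an ultrametric tree; `ultrametricize_mpl` resolves multichotomies and
applies mean-path-length dating (node age = mean path length to descendant
tips, bottom-up; negative branch lengths are clamped to zero with a
warning). Multisite β is the Baselga-family multiple-site Jaccard
dissimilarity; for N = 2 it provably reduces to pairwise Jaccard (used as
an oracle test), and the phylogenetic variant replaces taxa by
branch-length-weighted branch segments.

Core membership uses `ceil(f·n)` hosts with a floor of one — 8 of 15 hosts
at f = 0.5, and f = 0 meaning "present on at least one host" (the full
microbiota). Unique cores are asymmetric by design: a progenitor's unique
core excludes every other population's core, while a hybrid's excludes
only the two progenitor cores, so novelty shared by both hybrid
populations still counts as hybrid novelty.

## Ordination and triangle statistics

Distance matrices: Jaccard and unweighted UniFrac on incidence; Euclidean,
Bray–Curtis and weighted UniFrac on relative abundances (UniFrac via
scikit-bio). PCoA is classical Gower-centred eigendecomposition; axes with
non-positive eigenvalues are dropped and their magnitude logged (no
Cailliez correction — the simplest defensible treatment; distances used
here are near-Euclidean after embedding). Triangle statistics are computed
in the space of min(20, axes covering > 95% variance) coordinates, per
subsample of 12 hosts per group, 50 subsamples by default; position and
height are normalised by the inter-progenitor centroid distance and are
invariant to rigid motions of the space (tested to 1e-8).

Null models: (i) progenitor nulls — subsamples of one progenitor treated
as the hybrid group; (ii) pooled-progenitor null — subsamples from both
progenitors combined; (iii) incidence pseudo-hybrids — for a random parent
pair, taxa on both parents are kept and exactly `round(m/2)` (round half
up) of the `m` single-parent taxa are kept, making pseudo-hybrid richness
deterministic given the pair; (iv) abundance pseudo-hybrids — the
arithmetic mean of the parents' relative-abundance vectors. Pseudo-hybrid
individuals are embedded in the same PCoA as the real samples so all
groups share one space.

Comparisons between observed and null triangle statistics use a two-sided
Mann–Whitney U on per-subsample values. Subsamples reuse individuals, so
this is a heuristic stand-in for an exact test (the published comparison
function is not described in detail); it is labelled as such in outputs,
and the per-axis PCoA comparisons use host-level Mann–Whitney tests that
do not have this caveat.

## The 4H index

Set form and branch-length form share one partition (intersection / union
/ gain / loss over `Ω = H ∪ P1 ∪ P2`); the branch form weights branch
segments by length, with segment-level presence defined by descendant-tip
presence and the root stem excluded from all totals. The four components
sum to one by construction (asserted at 1e-9). Bootstrap runs draw 100
subsamples of 12 hosts per group at core threshold 0 by default, with the
hybrid group taken from site 1 only, site 2 only, or pooled.

The null plane is an **operational** construction (the published source
does not specify one): the cloud of 4H points of incidence-null
pseudo-hybrid groups, plus the affine 2-plane through the cloud fitted by
SVD. Null hybrids carry no taxa outside the progenitor pool, so their gain
is zero up to core-threshold sampling effects — a property the tests
verify. The retention-bias test statistic is
`intersection/(intersection+union)` — the fraction of progenitor-derived
hybrid material shared with both progenitors — with a one-sided empirical
p-value against the null cloud, floored at `1/(n_null+1)`. Because the
p-value compares one statistic against individual null points, the
calibration run generates its "observed" group by the same null mechanism
(one pseudo-hybrid group per run) so that the statistic is exchangeable
with the null points; averaging many observed subsamples first would
concentrate p near 0.5 by construction and is not a valid calibration.

## Outcome classification

T requires significance against both progenitors and a value strictly
outside the progenitor range; I requires significance against both and a
value strictly inside; everything else is C, annotated with the
progenitor(s) the hybrid is statistically indistinguishable from. A hybrid
value exactly equal to a progenitor value with both tests significant is
classified C with that progenitor — equality is not "more extreme" — which
keeps transgressive counts conservative. Direction glyphs: '^' above both
central values, 'v' below both, '-' between, '0' equal to a progenitor
value. When both tests are non-significant the annotation is "both"
regardless of which median is closer; this reproduces the published
outcome codes, though the published legend never states the rule
explicitly. Significance sources are wired per trait family: rank tests
(Kruskal–Wallis, then pairwise Mann–Whitney with Benjamini–Hochberg, run
only when the omnibus rejects) for per-host traits, disjoint 83.4% CIs for
bootstrap traits, per-axis Mann–Whitney for ordination axes, and null-model
comparisons for triangle statistics.

`datasets.py` carries the published outcome codes for the whiptail system
as data; re-encoding them as comparisons and tallying reproduces the
published per-family counts exactly (the two published total percentages
that differ from exact rounding by 0.01 — 42.30 vs 11/26 = 42.31 and 38.47
vs 10/26 = 38.46 — appear to be printing artifacts; counts match exactly).

## The synthetic-data generator

`simulate_populations` emulates the sampling design: four populations
(two sites × hybrid/progenitor), 15 hosts each by default, one body site
per table, integer read counts at a configurable depth (default 20,000,
within the 10⁴–10⁵ range typical of such studies), and a random binary
tree with exponential branch lengths over all pool taxa (default 300: 120
shared, 60 per progenitor-exclusive pool, 60 novel). The hybrid taxon pool
is assembled once (clonal lineage): each shared taxon kept with
`p_keep_shared`, each exclusive taxon with `p_keep_exclusive`, each novel
taxon gained with `p_gain`; the realised pools and their exact 4H
fractions are recorded as ground truth. Per-taxon, per-population
occupancies are Beta(2, 2) by default — chosen to produce the high
interindividual turnover (multisite β near 1) seen in squamate gut/skin
communities — with an optional logit shift on a taxon subset at one site
to emulate location effects (off by default). Counts are multinomial over
present taxa with log-normal relative-abundance weights, so incidence and
abundance layers are consistent and absent taxa have exactly zero counts.

What the generator does **not** emulate: sequencing error, chimeras,
compositional biases of library preparation, taxonomy-assignment error,
phylogenetic signal in occupancy (occupancies are i.i.d. across the tree),
or the real sites' parameter values. Passing validation therefore shows
that the estimators recover what they claim under a faithful sampling
design — not that any biological conclusion about a real system is
reproduced.

## Problem sizes used in validation

Chosen to exercise the estimators at the study's sampling design while
keeping runs quick: CI calibration uses 1000 replicate pairs at 180 taxa,
T = 15, B = 500; retention calibration 200 runs with null clouds of 100
branch-length 4H points at 120 taxa; 4H recovery and the gain sweep use
the full generator defaults (300 taxa, 15 hosts/population, keep
probabilities (1, 0.5, 0.2), occupancy 0.95) with 60–100 subsamples;
progenitor-null positions use 10–20 simulated datasets with UniFrac PCoA.
At occupancy 0.95 and f = 0, per-taxon detection over 12 subsampled hosts
is essentially certain, so 4H recovery error is dominated by pool
assembly, not sampling — near-zero recovery error is expected there, and
the gain sweep provides the complementary dose–response check.

## Known limitations

* The disjoint-CI rule is only approximately a 5% test; its realised level
  depends on the trait and the community (the calibration run reports it
  for γ-richness under the generator's conditions).
* The triangle comparison p-values inherit subsample pseudo-replication.
* The null plane and the retention test are operational definitions.
* Genus-level analyses are supported through one pooling operation
  (`pool_to_rank`); per-rank method variants are not re-specified.
* No plotting beyond coordinate tables (triangle and quaternary
  coordinates are emitted as TSV for external plotting tools).
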