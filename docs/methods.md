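# Methods

This note records the models implemented in `clonetrace`, the
assumptions behind them, the defaults that matter, and what the
synthetic-data tests do and do not establish.

## Cancer cell fractions and clustering

A somatic mutation observed with variant allele fraction VAF in a
sample of purity ρ, at a locus with tumor total copy number CN_t,
normal copy number CN_n (2 on autosomes) and mutation multiplicity m,
is carried by a fraction

    CCF = VAF · [ρ·CN_t + (1−ρ)·CN_n] / (ρ·m)

of the tumor cells. CCFs are clipped to [0, 2]: values above ~1.2
indicate a mis-specified copy-number context and are preserved (not
discarded) so they remain visible downstream. Zero sequencing depth
yields a missing value, never CCF 0. Multiplicity is estimated per
variant by pooling reads across samples
(`round(pooled alt / pooled expected per-copy coverage)`, floored at
1, capped at the tumor copy number); per-sample rounding proved far
too noisy at typical 70–120x depth.

Clustering fits a finite mixture over the joint CCF space of all
samples: component j has a latent CCF vector θ_j, and the alt count of
mutation i in sample s is beta-binomial with mean
`depth · clip(θ_js · conv_is, e, 1)` where `conv_is` is the expected
VAF per unit CCF (from purity, copy number, multiplicity) and
`e = 10⁻³` is a sequencing-error floor that keeps genuinely absent
mutations (whose few alt reads are errors) from destabilising the fit.
The beta-binomial precision τ = 500 inflates the binomial variance by
roughly `depth/τ`; a pure binomial likelihood is so sharp at WGS depth
that it resolves noise-level CCF wobble into spurious components
(trunk splitting). EM is initialised from k-means++ centres on the
CCF matrix, model selection is by BIC over 1..8 components, and
components attracting fewer than 5 mutations are dissolved as outlier
sinks with their members reassigned. Everything is deterministic under
a seed. The pipeline additionally folds together fitted components
whose CCFs differ by less than 0.2 in *every* sample — at that
separation the components are statistically indistinguishable and
their evolutionary order is not identifiable.

Artifact filtering is a conjunction: a cluster is excluded from
phylogeny reconstruction only if its per-sample CCFs are all below
0.2 *and* its trinucleotide spectrum has cosine ≥ 0.9 to a known
artifact profile. A clonal cluster with an odd spectrum, or a low-CCF
cluster with a clock-like spectrum, is never removed. The package
ships two built-in spectra: the analytic CpG>TpG clock profile
(uniform over the four N[C>T]G channels) and a synthetic, C>A-heavy
"artifact-like" profile used for injection and filtering tests; the
latter is deterministic and is not a catalog signature.

## Clone-tree reconstruction

Two multi-sample constraints define feasibility: *dominance* (a
parent's cumulative CCF is at least each child's, within tolerance, in
every sample) and the *sum rule* (children's CCFs sum to at most the
parent's, within tolerance, per sample). The default tolerance is 0.1
CCF, accommodating curve-fitted median noise; it is exposed in every
entry point. The root must reach CCF ≥ 0.95 in all tumor samples
(truncal/MRCA cluster); its absence is an error, as is any cluster no
candidate parent can dominate.

Among feasible trees the builder returns a canonical one: clusters are
placed in decreasing order of total CCF (ties: more SNVs, then id),
and each takes the smallest-CCF dominating cluster with remaining
sum-rule capacity (same tie-breaks). Preferring the smallest feasible
parent yields the deepest, maximally linear topology consistent with
the data — the convention matches the long descendant chains seen in
real multisample reconstructions. The search is an exact depth-first
backtracking over all parent assignments, so the result is the
lexicographically minimal feasible tree under that preference; the
test suite verifies this against exhaustive enumeration on random
instances. Note that with tolerance 0.1 the canonical tree need not
equal the generating topology even on noiseless data: a near-sibling
within tolerance can legitimately be preferred as a parent. Ambiguity
of that kind is a property of the data, not of the search.

Cluster curation follows two rules. Clusters whose CCFs are within
`ccf_distance` in all but at most one sample are merged (counts
summed, CCFs count-weighted; iterated to a fixpoint, closest pair
first, which makes the result order-independent). Clusters below 0.5
CCF in every sample are excluded from the TD-rate regression — their
event assignments are too uncertain — but stay in the tree.

Somatic events (CNAs, SVs, TDs) are hard-assigned to the cluster with
the nearest CCF vector (Euclidean, missing samples excluded pairwise;
exact ties resolve to the more ancestral cluster). Tandem duplications
are duplication-type SVs with both breakpoints on one chromosome and
span `|pos2 − pos1| < 5 Mb` (1-based breakpoints).

## Molecular-clock timing

Clock-like CpG>TpG (SBS1) mutations accumulate approximately linearly
with age; advanced tumors accelerate the rate. The model is a
piecewise-constant clock anchored to the patient's age at
prostatectomy T: the root-to-leaf path with the largest SBS1 total
(the anchor path, N mutations; ties broken by SNV total then id)
spans [0, T], with a change point t_a after which the rate is k-fold
higher (default k = 5, matching pan-cancer estimates for prostate
tumors). Conservation of the anchor fixes the pre-change rate
r = N/(t_a + k(T − t_a)), and cumulative count n maps to age n/r
below r·t_a, else t_a + (n − r·t_a)/(k·r). The map is continuous,
strictly increasing, and sends N to T for every t_a.

t_a is unknown: 10,000 draws are taken uniformly from the
`window_years = 15` years before sampling (roughly a quarter of the
patients' age). A draw is rejected unless every sample-private
cluster (detected at CCF ≥ 0.01 in exactly one sample) emerges at or
after t_a — private mutations are assumed to accrue at the
accelerated rate. Cluster emergence is dated at the *end* of its
branch (all branch mutations accrued); dating at the branch start
would shift every age earlier by the branch's own span and is not
implemented. Non-anchor clusters use the cumulative SBS1 count along
their own root path rescaled by the anchor rate. Ages are summarised
as the median and the 2.5/97.5 percentiles over accepted draws —
percentiles, not a normal approximation, because the intervals are
strongly asymmetric near T.

These intervals propagate change-point uncertainty only. For clusters
whose count approaches N the interval collapses while Poisson noise
in the counts themselves persists, so such intervals under-cover the
truth. `ClockModel(count_resampling=True)` therefore additionally
draws one Poisson replicate of every branch count per accepted draw (a
parametric bootstrap cumulated along each root path, with the anchor
leaf re-pinned to T by construction). The default is off: the plain
mapping is the simpler model and keeps the k = 1 limit exactly equal
to the linear clock age = T·n/N; calibration tests and the acceptance
recomputation use the resampling variant, which is what the measured
≥ 90% coverage refers to.

TD-phenotype dating: ordinary least squares of cumulative TD count on
cumulative SBS1 count across in-scope clusters (two-sided t-test on
the slope, ≥ 3 clusters required). With truncal counts N_T (SBS1) and
D_T (TD) and fitted slope β, the onset sits at SBS1 coordinate
n₀ = max(0, N_T − D_T/β), i.e. after n₀/N_T of the truncal
mutations, and its age is the piecewise map of n₀ summarised over
accepted draws.

## Anatomic tracing

Samples carry a site class (prostate, seminal_vesicle, lymph_node)
and laterality (L/R/midline). Extraprostatic samples are metastatic
compartments. Two cluster sets are distinguished deliberately:

* **metastatic-capable** — non-truncal clusters whose cumulative CCF
  reaches 0.01 in any extraprostatic sample. Ancestors of metastatic
  subclones belong here: their mutations ride along in every
  metastatic cell.
* **seeding** — non-truncal clusters with a *resident* population
  (surface = CCF minus children's CCFs ≥ 0.01) in a metastatic
  sample. Each resident population must have migrated at least once,
  so the set size is the minimum number of seeding events. An
  ancestor fully accounted for by its descendants implies no separate
  migration and is not counted; with cumulative CCFs it would always
  be counted, which is why presence-counting cannot reproduce minimum
  event tallies on nested clusters.

Because seminal-vesicle invasion blurs the prostate→node tally, the
trace report carries both counts (all-extraprostatic and
lymph-node-only). Routes list, per (cluster, metastatic sample), the
upstream samples containing the cluster (prostate and SV for node
metastases, prostate for SV samples); the verdict is ipsilateral if
all sources share the metastasis' side, contralateral if none does,
ambiguous-bilateral otherwise. A cluster with no source anywhere is a
met-private lineage and routes through its nearest sourced ancestor —
the migration must have preceded the within-met divergence. The
anatomic origin is the primary sample with the largest truncal-only
(root surface) fraction; samples within 0.02 of the top are reported
jointly rather than pretending to resolve them.

## Drivers and druggability

Events matched against the driver catalog count as putatively
oncogenic only when the catalog direction is known and the observed
effect is consistent (loss in a suppressor, gain in an oncogene);
direction-unknown events are mapped but excluded from coverage
denominators. Index-lesion coverage is the fraction of oncogenic
events whose cluster is detectable (CCF ≥ 0.01) in the declared index
samples — monotone in the index set by construction. Druggability
tiers order targets by expected durability: (1) truncal druggable,
(2) metastatic-capable subclonal, (3) other subclonal; eligibility
requires a protein-altering variant, copy gain or homozygous loss,
with loss of heterozygosity additionally accepted for TP53. The
bundled drug–gene table is a small synthetic snapshot for tests and
examples, not a database export. CNA burden is the fraction of
autosomal segment length whose total copy number differs from the
sample's rounded ploidy; groups of ≥ 3 samples are compared by a
two-sided Mann–Whitney U test.

## The synthetic generator

`simulate_clone_tree` draws a topology by sequential uniform parent
attachment, then ages: the MRCA completes at
accel_age + U(0.25, 0.55)·(T − accel_age) and every subclone emerges
between its parent and T, with the deepest leaf anchored to T exactly.
Placing all subclonal expansions after the change point is a modelling
commitment, not a convenience: the timing model assumes private
mutations accrue at the accelerated rate, and multisample prostate
case histories date the observed clonal expansions to the last years
before prostatectomy. Branch SBS1 counts are Poisson with the
piecewise-clock intensity (base rate 4 mutations/year — truncal
totals in the low hundreds, the scale of prostate WGS), non-clock
SNVs at 3× the SBS1 intensity, TDs at td_per_sbs1 = 2 per SBS1
mutation beyond the onset point (default after 75% of the truncal
clock mass). CCFs are stick-broken under each parent, so the sum rule
holds exactly; sample presence is a random subtree prune
(keep-probability 0.7) restricted in metastatic samples to a
descent-closed metastatic lineage set; purity is U(0.5, 0.9), depth
Poisson(70), alt counts binomial with a 10⁻³ error floor, and a
N(0, 0.02) CCF jitter models residual dispersion. A single
`numpy` Generator seeded from the config drives every draw, so
outputs are bit-reproducible.

What the generator does *not* emulate: germline variation, alignment
artifacts, subclonal copy number (CN context is clonal, 90% diploid /
10% single gain), signature mixtures beyond clock + one artifact
spectrum, spatially correlated CCFs, or realistic per-chromosome
mutation placement. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the stated generative
assumptions, not robustness to every failure mode of real WGS data.

## Numerical choices and degenerate inputs

* CCF clip at 2.0; cluster CCF cap 1.2 inside the EM.
* EM convergence: relative log-likelihood change < 10⁻⁶, ≤ 200
  iterations; BIC with k·m + (k−1) parameters.
* `n_clusters = 1` simulations produce a root-only tree with
  emergence age 0 and the whole history on the truncal branch.
* Zero accepted change-point draws raise an error advising a wider
  window rather than returning an empty interval.
* Exact ties throughout (anchor path, parent choice, event
  assignment) resolve by SNV count then lexical id, making every
  result order-independent and reproducible.
* Pipeline outputs carry no timestamps; reruns with one seed are
  byte-identical.

## Known limitations

* Hard event assignment ignores assignment uncertainty; an event
  equidistant between clusters silently goes to the ancestor.
* The backtracking tree search is exponential in the worst case;
  fine at the ≤ 15-cluster scale of multisample reconstructions, not
  intended for hundreds of clusters.
* The clock anchors the SBS1-richest path to the sampling age; if the
  true anchor lineage were undersampled, all ages shift accordingly.
* Clusters indistinguishable within 0.2 CCF in every sample are
  merged by the pipeline; genuinely distinct but tightly nested
  clones below that resolution are reported as one.
* The bundled GP5/GP12 tables are curated cluster-level summaries for
  worked examples and regression tests, not raw data.
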