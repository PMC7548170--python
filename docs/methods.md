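# Methods

This note documents the models implemented in `barcodescope`, the
assumptions behind them, the numerical choices made where the underlying
methods are under-specified, and what the synthetic-data experiments do and
do not demonstrate.

## Genetic distances

Pairwise divergence uses the Kimura 2-parameter correction
`K = -½ ln(1 - 2P - Q) - ¼ ln(1 - 2Q)`, with P and Q the proportions of
transition and transversion differences over compared sites. Only columns
where both sequences carry an unambiguous base (A/C/G/T) are compared;
under the default *pairwise deletion* policy this set is determined per
pair, under *complete deletion* any column gapped or ambiguous in any
sequence is dropped for all pairs. K2P distances are reported as
proportions or as percent (K2P% = 100 K, shown to one decimal in summary
tables). The model saturates when `1 - 2P - Q ≤ 0` or `1 - 2Q ≤ 0`; such
pairs raise an error naming the offending sequences rather than returning
a truncated value. JC69, raw p-distance and integer base-pair differences
are available under the same interface, plus a fixed-ratio K80 variant
that splits an observed difference proportion into transition and
transversion parts according to a supplied ts/tv ratio before applying the
K2P formula (used where a transition bias is imposed on the correction
rather than estimated per pair).

## Populations and contrasts

Specimens are grouped into populations when their site names match or
their collection points lie within a linking radius (default 5 km,
strict `<`), reflecting the limited dispersal of the study organisms. The
pairwise criterion is closed under single linkage so that "same
population" is an equivalence relation; a strict-pairwise mode (greedy
clique refinement in deterministic insertion order) is available for
comparison. Population coordinates are the arithmetic mean of member
coordinates, and between-population geography uses the haversine
great-circle distance on a sphere of radius 6371 km.

For every species and unordered pair of populations that both contain the
species, the contrast table records the *maximum* K2P% over all
cross-population pairs of individuals (a deliberately extreme-value
statistic: it captures the deepest lineage divergence rather than the
average), the centroid-to-centroid distance in km, and the larger of the
two sample sizes (`n_max`), which controls for the fact that larger
samples reach deeper into the coalescent. Region pairs map to contrast
classes EUEU, EUIB, EUIT and IBIB; Italy–Italy and Iberia–Italy pairs are
labelled `other` and excluded from the models, since too few such
comparisons exist to estimate their effects. The country→region map
defaults to Spain/Portugal → IB, Italy → IT, everything else in Europe
(including the Balkans) → EU, and is configurable.

## GMYC

The generalized mixed Yule–coalescent model views an ultrametric
single-locus gene tree as generated by species-level diversification above
a transition and within-species coalescence below it. Ordering the n−1
branching events by age (ties broken by a stable sort on (age, preorder
index)), interval *i* of duration `x_i` has total branching rate

    b_i = λ_div · k_i^{p_div} + λ_coal · Σ_j [m_ij (m_ij − 1)]^{p_coal}

where `k_i` counts species-level lineages crossing the interval and
`m_ij` gene lineages inside delimited unit *j*. Each interval ends with an
event and contributes `ln b_i − b_i x_i`; zero-length intervals (tied
ages) contribute only the event term. The event term uses the *total*
rate, i.e. the likelihood is `Π_i b_i e^{−b_i x_i}`; published
parametrizations differ in whether the event term uses the component that
actually branched, and the component-specific alternative is available
behind a flag. The null model is a single coalescent over all lineages,
`b_i = λ [n_i(n_i − 1)]^p`, which is exactly the labeling with no
speciation node; because that labeling is included among the candidates,
the fitted mixed-model likelihood can never fall below the null and the
likelihood-ratio statistic is non-negative by construction.

Fitting maximizes over the two rates (log-parametrized, bounds ±20 in log
space) and two exponents (bounds [0, 10], the conventional search interval
for these scaling parameters) with L-BFGS-B using analytic gradients,
three starts per candidate (one moment-based, two seeded perturbations)
and convergence tolerance 1e−8. The single-threshold fit scans the
midpoints between consecutive distinct node ages (plus an all-speciation
and the all-coalescent candidate). The multiple-threshold fit starts from
the single-threshold labeling and repeatedly applies the best strictly
improving move, where a move relabels one node together with the minimal
consequent relabels that keep the labeling consistent (promoting a node
promotes its non-speciation ancestors; demoting a node demotes its
speciation descendants); it terminates at a local optimum, and on small
trees it attains the global optimum found by exhaustive enumeration of all
consistent labelings. Like the method it implements, it tends to
over-split relative to the single-threshold solution on data with
heterogeneous within-species depths. The LR test uses χ² with 3 degrees
of freedom by default (two extra rate/exponent parameters plus the
threshold), configurable to 2. Entity counts, not likelihood values, are
the comparable output across GMYC implementations, since parametrizations
differ.

Input trees must be ultrametric (tip-depth spread checked against a
tolerance, default 1e−6 when parsing Newick); a UPGMA builder (node age =
half the merge height) provides a deterministic ultrametric tree where no
externally inferred chronogram is supplied. UPGMA trees are a convenience
for end-to-end runs, not a substitute for proper time-tree inference.

## Barcode-gap partitioning

Given all pairwise distances and a prior `P_max` on the maximum
intraspecific divergence, θ is the mean of distances strictly below the
prior and the limit `L = −ln(0.05) · θ` is the 95% quantile of an
exponential with mean θ — below L, an apparent gap carries more than a 5%
risk of being intraspecific under a panmictic coalescent, so gaps there
are ignored. The exact derivation of this limit in the original method is
not published; the exponential pairwise-coalescence quantile adopted here
is documented and configurable.

Gap detection ranks the distances and computes windowed slopes
`s_i = (d_{i+w} − d_i)/w` with a dynamic window `w = max(10, ⌈0.01 m⌉)`
(shrunk to ⌊m/2⌋ with a warning for short lists). Among windows whose top
reaches above L, the peak-slope window marks the candidate region; within
it, the largest single consecutive jump whose midpoint exceeds L is the
candidate gap, accepted only if its width exceeds X times the largest
consecutive jump among the sub-limit distances (the intraspecific
baseline). Requiring only the window *top* (not its base) to clear L is
deliberate: the barcode gap starts among intraspecific distances below L
and ends among interspecific ones above it. Comparing the single largest
jump (rather than the window span) against the baseline keeps uniformly
spaced distances from triggering spurious acceptances. When fewer than
two distances fall below L no baseline exists and no gap is reported,
with the reason logged.

The initial partition single-links sequences with distances strictly
below the gap position; recursive partitioning re-applies the whole
procedure inside each group (recomputing θ and L from the group's own
distances, same prior) until nothing splits, so the recursive group count
never falls below the initial one. The default prior grid is 10
logarithmic steps in [0.005, 0.05] with relative gap widths
X ∈ {0.5, 1.0, 1.5, 2.0}, under JC69 and fixed-ratio K80 (ts/tv 2 and 4).

## MOTU clustering

MOTU clustering takes a cutoff in raw base-pair differences — no
substitution model — counted over sites where both sequences have an
unambiguous base. Sequences with more than `min_len` (default 500)
informative bases enter; a pair is compared only when its mutual overlap
covers at least 90% of the shorter sequence. Clusters are connected
components of the graph linking pairs with differences ≤ cutoff, so no
member of one MOTU is within the cutoff of a member of another; counts
are non-increasing in the cutoff and partitions nest. The identity
prefilter some implementations use for speed is unnecessary here — all
pairs are computed exactly, which is result-identical by design. Note the
asymmetric edge semantics: gap-based partitions link strictly *below* the
gap position, MOTUs link at differences *at or below* the cutoff (honoring
the "closer than the cutoff" exclusion guarantee).

## Latitude trends and the divergence mixed model

Species richness along latitude derives from per-species range limits: a
species counts at every grid latitude between its southern and northern
records (integer-degree grid by default). Barcode counts bin each record
to its rounded integer latitude. Trends are ordinary least squares of
degree 1 or 2 with the model F-test against intercept-only; a concave
quadratic peaks at `−b/2c`. Under the printed noise level of the barcode
counts (σ ≈ 5 per latitude over a 26-point grid) simulation puts the
vertex estimate within 1° of truth in about 86% of replicates — the
peak's precision, not just the fit's significance, should be read with
that in mind.

The divergence model is a linear mixed model
`max_div = β₀ + β₁·1[contrast] + β₂·geo_km + β₃·n_max + u_species + ε`
with a species random intercept, fitted by maximum likelihood (not REML)
so that the σ_u² = 0 boundary nests ordinary least squares exactly; when
the boundary beats the interior optimum — or the mixed fit degenerates —
the OLS solution is reported with σ_u² = 0, which is the MLE in that
case. REML is available by flag. Covariates without variation are dropped
with a warning. Per-term Wald F statistics use 1 and n − rank denominator
degrees of freedom. For the EUEU-vs-IBIB comparison the spatial range is
capped at 1,000 km, matching the maximum extent of Iberian
inter-population distances, so the two contrast classes overlap in
distance.

## Synthetic data

The generators produce data with exactly the structure the analyses
assume, making every stage testable offline.

- `simulate_species_tree`: a Yule species tree (forward simulation at rate
  λ, default 1.0 per lineage per time unit) with an independent
  constant-size coalescent genealogy grafted within each species. θ is the
  mean pairwise coalescence time (default 0.05; recovery experiments use
  0.001 against a guard that keeps every speciation at least 0.5 time
  units old, a split-to-coalescent ratio comfortably above the ≥ 20×
  regime where single-threshold delimitation is expected to work).
  Genealogies that would outgrow their species stem are shrunk
  proportionally to fit — a truncation, not an exact conditioned
  coalescent, rare in the intended regime. `violate_threshold` multiplies
  one species' θ to break the speciation-before-coalescence assumption.
- `evolve_alignment`: site-independent K2P evolution with uniform base
  frequencies (the model's own assumption), total rate per site per time
  `rate`, and instantaneous transition/transversion rate ratio `kappa`
  (default 4; expected transition:transversion *count* ratio ≈ κ/2 at low
  divergence). Branch transition probabilities use the closed-form K80
  solution, so estimated K2P distance is consistent for 2 × time × rate.
- `simulate_geography` and `simulate_refugium_dataset`: populations placed
  uniformly in disjoint per-region bounding boxes; population sample sizes
  vary (1 to 2·n−1, mean n = 3). All EU and IT populations draw haplotypes
  from a 'shallow' lineage; Iberian populations split between 'shallow'
  and a 'deep' lineage diverging `refugium_effect` (default 1.0) time
  units earlier, so Iberia-Iberia pairs span a divergence matched-distance
  northern pairs cannot. Species subtrees join on a caterpillar backbone
  at 2.5–4× the deepest within-species age, keeping pooled between-species
  divergence finite under K2P (~10–16% at the defaults).
- `make_gap_dataset` plants an exact barcode gap by flipping disjoint
  site blocks: per-species blocks guarantee interspecific distances above
  `inter_min`, per-individual blocks keep intraspecific distances below
  `intra_max` (with a 0.8 margin absorbing the model correction); the
  construction is verified after building and errors when the alignment
  is too short.

What the generators do *not* emulate: codon structure (synthetic sequences
are not stop-free, so the numt screen flags them — it is validated on
constructed coding sequences instead), isolation-by-distance within
lineages (the refugium experiments test the contrast effect, not the
distance slope), rate heterogeneity across sites and lineages, ambiguity
codes and missing data, and non-neutral or structured coalescence.
Passing tests therefore show the estimators recover the effects they
target under the stated generative assumptions — not robustness to the
full messiness of real barcode data.

## Problem sizes and determinism

Simulation experiments use 100 seeded replicates at modest sizes — species
trees of 5 species × 4 tips, refugium datasets of 4 species across 12
populations, mixed-model designs of 15 species × 40 rows — chosen so each
experiment completes in seconds while leaving comfortable margins over
its acceptance threshold. Every generator and fit that uses randomness
takes an explicit seed; identical seeds reproduce trees, alignments and
tables byte for byte, and the pipeline writes the hash of its
configuration into every output table.

## Known limitations

- GMYC likelihood values are not comparable across implementations with
  different rate parametrizations; entity counts are.
- The multiple-threshold search is a greedy local search; on rugged
  likelihood surfaces it can stop short of the global optimum (it is
  guaranteed never to fall below its single-threshold start).
- The barcode-gap windowing details (window size, acceptance rule) follow
  the documented choices above where the original method leaves them
  unspecified; absolute group counts at aggressive priors can differ from
  other implementations while the qualitative prior-response curve is
  preserved.
- The per-population centroid is used for geographic distances; with very
  scattered populations this differs from specimen-to-specimen distance.
- The numt screen checks forward frames by default (barcodes are stored in
  coding orientation); reverse-complement screening is behind a flag.
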