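# barcodescope

Geographic structure in DNA-barcode divergence and single-locus species
delimitation.

DNA barcoding identifies specimens by comparing a standard marker (~658 bp
of mitochondrial COI) against reference libraries, using the separation
between intra- and interspecific divergence. Reference libraries, however,
are geographically biased: in Europe most barcodes come from central and
northern countries, while the southern peninsulas (Iberia, Italy, the
Balkans) — Pleistocene glacial refugia that concentrate genetic diversity —
are undersampled. Pairs of populations that include a southern refugium
then show systematically higher intraspecific divergence than
matched-distance northern pairs, and refugial lineages can exceed the
identification threshold against northern references or even be delimited
as separate putative species.

`barcodescope` implements the full analysis chain for quantifying this
effect and delimiting units from single-locus data:

- **Sequence handling** (`seqio`): FASTA alignment and metadata I/O,
  haplotype collapsing by exact string identity, and a numt screen that
  translates each sequence in the three forward frames under the
  invertebrate mitochondrial code and flags sequences with no stop-free
  frame.
- **Distances** (`distances`): Kimura 2-parameter divergence
  `K = -½ ln(1 - 2P - Q) - ¼ ln(1 - 2Q)` with P and Q the transition and
  transversion proportions (pairwise or complete deletion); haversine
  great-circle distances; grouping of specimens into populations by shared
  site name or proximity below 5 km (single-linkage closure); and the
  per-species contrast table of maximum cross-population divergence,
  labelled EUEU / EUIB / EUIT / IBIB by the unordered region pair.
- **GMYC** (`gmyc`): the generalized mixed Yule–coalescent model. On an
  ultrametric gene tree, inter-event interval *i* has branching rate
  `b_i = λ_div k_i^{p_div} + λ_coal Σ_j [m_ij(m_ij - 1)]^{p_coal}` with
  `k_i` species lineages and `m_ij` gene lineages in unit *j*, giving
  `ln L = Σ_i (ln b_i − b_i x_i)`. Single-threshold fits scan every age
  threshold; the multiple-threshold fit hill-climbs over consistent node
  labelings from the single-threshold solution; a likelihood-ratio test
  against the single-coalescent null uses χ² with 3 df. A UPGMA builder
  provides deterministic ultrametric input trees.
- **Distance-based delimitation** (`distance_delim`): barcode-gap
  partitioning with a prior `P_max` on intraspecific divergence, gap
  limit `L = −ln(0.05)·θ`, slope-based gap detection on ranked distances
  and recursive re-partitioning; and single-linkage MOTU clustering on raw
  base-pair differences with a cutoff sweep.
- **Geostatistics** (`geostats`): species richness and barcode counts along
  a latitudinal grid with OLS trend fits and the quadratic vertex
  (`−b/2c`); and the divergence mixed model
  `max_div ~ contrast + geo_km + n_max + (1 | species)` fitted by ML.
- **Synthetic data** (`synthetic_data`): Yule species trees with grafted
  coalescent genealogies, K2P sequence evolution with transition bias,
  refugial population geography, and alignments with an exactly planted
  barcode gap — so every stage is testable without downloads.
- **Pipeline** (`pipeline`, CLI `barcodescope`): config-driven end-to-end
  orchestration writing CSV/JSON reports.

## Worked example

```python
import barcodescope as bs

# simulate a 5-species gene tree: deep species splits, shallow coalescences
tree, truth = bs.simulate_species_tree(
    n_species=5, theta=0.001, n_per_species=4, seed=42, min_split_age=0.5
)
fit = bs.fit_gmyc_single(tree, seed=42)
print(f"delimited entities: {fit.n_entities} (true species: {truth.n_species})")
print(f"threshold age: {fit.threshold:.4f}")
print(f"lnL GMYC {fit.lnL_gmyc:.2f} vs null {fit.lnL_null:.2f} "
      f"(LR = {fit.lr:.2f}, p = {fit.p_value:.2e})")

# evolve sequences, plant populations, test the refugium contrast
aln, specimens, sim = bs.simulate_refugium_dataset(n_species=4, seed=42)
dms = {sp: bs.distance_matrix(aln.subset(ids), scale="percent")
       for sp, ids in sim.partition.items()}
pops = bs.assign_populations(specimens, radius_km=5.0)
rows = bs.contrast_table(dms, pops, specimens)
lmm = bs.fit_divergence_lmm(rows, ("EUEU", "IBIB"), max_geo_km=1000.0)
beta = lmm.fixed_effects["contrast"]
f, p = lmm.f_tests["contrast"]
print(f"IBIB vs EUEU contrast: +{beta:.2f} K2P% (F = {f:.1f}, p = {p:.2e})")
```

prints

```
delimited entities: 5 (true species: 5)
threshold age: 0.2599
lnL GMYC 122.98 vs null 104.91 (LR = 36.15, p = 6.97e-08)
IBIB vs EUEU contrast: +1.42 K2P% (F = 23.2, p = 1.06e-05)
```

The GMYC fit recovers the five planted species exactly, placing the
threshold between the deepest coalescence and the youngest speciation, and
the likelihood-ratio test firmly rejects the single-coalescent null. In
the refugium simulation, pairs of Iberian populations are on average 1.4
K2P% more divergent than matched European pairs after controlling for
geographic distance and sample size — the undersampled-hotspot signature
the package is built to measure.

The same workflow runs from the shell:

```bash
barcodescope run config.yaml        # full pipeline from a YAML config
barcodescope gmyc --tree t.nwk --mode single
barcodescope abgd --alignment aln.fasta --prior 0.01 --gapwidth 1.5
barcodescope motu --alignment aln.fasta --cutoffs 3:23
```

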