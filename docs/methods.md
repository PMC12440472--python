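# Methods

## Coordinate conventions

Variant panels and array manifests carry 1-based positions (build Hg19), as
such tables are printed. Probe designs and target regions use 0-based
half-open intervals (BED). The single bridge between the two: a variant at
1-based position *p* lies in interval [*s*, *e*) iff *s* ≤ *p* − 1 < *e*.
Chromosome labels are normalized by stripping a leading `chr` prefix, so
mixed-dialect inputs compare equal. Strand is ignored throughout; all
coordinates are forward-strand.

## Direct coverage

A panel variant is directly covered by a platform when its (chromosome,
position) is a member of the platform's manifest; matching by rsID alone is
available as an explicit fallback for manifests that list identifiers
without coordinates, but position matching is primary because identifiers
drift across dbSNP builds. Percent coverage is
covered·100 / total over the panel.

## LD model and tag discovery

All LD quantities are computed from phased haplotypes by direct counting —
no EM or composite-genotype estimator is needed, and unphased input is
rejected at the VCF reader rather than phased or imputed. For two biallelic
loci, D = p_AB − p_A·p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)), and
D′ = |D|/D_max with D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A p_B, (1−p_A)(1−p_B)) for D < 0. LD at a monomorphic site is
undefined and raises an error — it is never silently reported as zero.

Tag discovery for a target variant scans the assayed (manifest) sites
within ±`window_kb` (default 250 kb, the conventional tag-search window) and
returns those with r² ≥ `r2_min` (default 0.8, the accepted cutoff for
strong linkage in pharmacogenomics), ordered by r² descending then position
ascending so output is deterministic. The target self-tags at r² = 1 when
it is itself assayed, which guarantees LD-adjusted coverage ≥ direct
coverage variant-wise. A target absent from the haplotype panel is
*unassessable* — reported distinctly from "assessed, no tags found".

Three aggregation modes handle multiple population panels: `pooled` (the
default) stacks all haplotypes into one panel before computing r², which
corresponds to running the tag search once on a merged dataset;
`per_population_any` and `per_population_all` run the search per panel and
require a hit in at least one, or every, panel that assays the variant.

### Numerical choices

* The r²-vs-threshold comparison uses an absolute tolerance of 1e-9. This
  absorbs float rounding of values that are exactly the threshold as
  rationals (haplotype counts give rational r²; on any realistic panel size
  no attainable rational falls strictly within 1e-9 of a threshold, so the
  tolerance never admits a genuinely sub-threshold tag).
* The r² denominator is grouped per site, (p_A(1−p_A))·(p_B(1−p_B)), making
  the result bit-identical under swapping the two sites.
* r² and D′ are clipped to [0, 1] to remove last-ulp overshoot.
* Percentages are rounded only at presentation, half-up to two decimals;
  internal comparisons use integer counts.

## Enrichment coverage

For each target region the covered-base fraction is |union of probe
intervals ∩ region| / |region|, computed with an interval tree so
overlapping or book-ended probes never double-count. A region is
high-covered when its fraction is ≥ the threshold (default 0.90,
inclusive). Per-gene aggregation reports high/low region counts and the
percent high; the overall figure is Σ high / Σ regions. Target regions are
caller-supplied; a convenience builder derives one region per panel variant
(position ± 100 bp flank by default) for designs whose region definitions
are not published.

## Synthetic data generator

The simulator exists to give the pipeline inputs with *exact, controllable*
LD ground truth, so it uses a copy-with-flip block model rather than a
coalescent: sites within a block are copies of a founder column (founder
MAF ~ Uniform over `maf_range`, default 0.05–0.5, resampled if fixed), each
copy perturbed by independent per-haplotype allele flips; founder columns
of different blocks are independent, so cross-block r² vanishes in
expectation (mean sample r² ≈ 1/n_haplotypes). Sites are evenly spaced
(`site_spacing_bp`, default 2 kb) on one chromosome.

The flip rate ε is calibrated to the target within-block r² by numerically
inverting the closed-form expectation for a flipped pair: with marginal
frequency m = p + ε(1−2p) and E[X₁X₂] = p(1−ε)² + (1−p)ε², the correlation
is (E[X₁X₂] − m²)/(m(1−m)) and the target is its square. The inversion
(Brent's method on ε ∈ [0, ½]) is exact at the endpoints — ε = 0 gives
r² = 1, ε = ½ gives 0 — and accurate to solver tolerance in between;
realized sample r² then scatters around the target with binomial noise.
`within_block_r` is interpreted as the target pairwise r² between sites of
a block (at the value 1 used for exact-recovery validation, target
correlation and target r² coincide).

A complete simulated study (`simulate_study`) allocates one block per panel
variant (the variant plus `sites_per_block − 1` candidate proxies, default
3 sites per block) and realizes a designed (n_direct, n_taggable,
n_untagged) manifest: direct variants are placed verbatim; taggable
variants get their closest in-window non-panel proxy with r² above
threshold (an error if none exists — e.g. single-site blocks); untagged
variants get nothing. Defaults are 34 variants, 500 diploid samples (1000
haplotypes) and design (18, 12, 4), the multi-platform shape of a
well-covered genotyping array on this panel. With `within_block_r = 1` the
pipeline recovers the designed counts exactly for every seed; at lower
within-block r² the recovery is exact up to panel-estimation noise of r²
around the threshold.

Probe tilings (`simulate_probes`) cover each region within one base of a
requested fraction (a fraction strictly between 0 and 1 on a 1-base region
is rejected as unrepresentable); covered spans of ≥ 4 bases are split into
two book-ended probes to exercise union arithmetic.

What the simulator deliberately does **not** emulate: genealogical LD decay
with distance, recombination maps, realistic allele-frequency spectra,
population structure and admixture, genotyping error, and the
paralog/homology artifacts that plague *CYP2D6* assays in practice.
Passing tests on synthetic data therefore demonstrate the correctness of
the counting, tagging and aggregation machinery — not that any particular
real array achieves a given coverage; real-data conclusions always flow
through the packaged empirical matrix or user-supplied manifests and VCFs.

## Packaged fixtures

`adme_core_panel.tsv` holds the 34-variant CYP2C8/CYP2D6/CYP3A4/CYP3A5
chloroquine-pathway panel (gene, rsID, Hg19 position).
`platform_coverage_matrix.tsv` holds its published 0/1 direct and LD
coverage over Omni 1S/2.5S/2.5/5 and Axiom, keyed by rsID (the published
table is rsID-indexed). Column summaries of this matrix reproduce the
published per-platform percentages; its two all-zero rows (rs72549352 and
rs72549357, both *CYP2D6*) are the variants no platform captures even with
LD. The matrix is reproduced verbatim, including one published
inconsistency: the accompanying narrative names rs72549353 among the
uncovered variants while the table's all-zero rows are rs72549352 and
rs72549357; the count of two is consistent and is what this package
asserts.

## Rounding edge case

Half-up rounding to two decimals matches every published genotyping
percentage (e.g. 18/34 → 52.94, 30/34 → 88.24). For the enrichment overall
figure, 33/34 = 97.0588…% rounds to 97.06 under the same rule, whereas the
published figure appears truncated to 97.05; the package applies the single
consistent rule and reports 97.06.

## Known limitations

* LD is biallelic-SNP only; multi-allelic sites are skipped at the reader.
* No lift-over: all inputs must share one genome build.
* Star-allele and structural-variant calling (the other half of *CYP2D6*
  pharmacogenomics) are out of scope; coverage is assessed per SNP/indel
  position only.
* VCF reading requires phased GT fields; sites with any missing genotype
  are skipped, not imputed (counts of all skips are surfaced).
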