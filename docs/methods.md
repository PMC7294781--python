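# Methods

## Coordinates and gene models

All coordinates are 0-based half-open (BED convention); GTF input (1-based
closed) is converted on read. A gene with several transcripts is collapsed
to the outermost TSS/TES and the union of exon/CDS intervals, matching the
single-TSS/TES definitions used throughout the analysis. Derived regions:

- **promoter** — TSS to `promoter_bp` upstream (default 3,000 bp), strictly
  upstream (not centred on the TSS), clipped at chromosome bounds;
- **gene body** — TSS to TES (the full span, both strands);
- **metagene bins** — the span from 5 kb upstream of the TSS to 5 kb
  downstream of the TES tiled with 100 contiguous bins, ordered in
  transcription direction; any bp remainder is spread one bp at a time over
  the leading bins, so bin widths differ by at most 1 bp.

Position classification uses the precedence **CDS > UTR > intron >
promoter > intergenic** (configurable). The choice matters only where a
promoter overlaps a neighbouring gene's body; giving body sub-categories
priority keeps the gene-body occupancy breakdown internally consistent.
A sweep-based piecewise decomposition (`category_segments`) makes
whole-chromosome classification O(intervals log intervals); it is tested
base-by-base against the single-position classifier.

## Tags

A *tag* is a read reduced to one base. Alignment records (SAM/BAM) use the
strand-aware 5′ end and are subject to the MAPQ ≥ 5 filter; plain BED
intervals carry no MAPQ and are reduced to midpoints. Both reduction modes
are selectable. Duplicates at an identical (chrom, position, strand) are
collapsed to a single tag. Counting in regions is half-open; overlapping
regions each receive a tag (no fractional assignment), which makes the
per-region "total read count" contract exact and oracle-testable.

## Domain calling and consensus

The domain caller tiles the genome with fixed 1 kb windows and keeps
windows whose tag count exceeds the global Poisson upper tail
(`P(X ≥ c) < 1e-3`, λ = genome-wide tags per window), merging kept windows
closer than 1 kb. This is intentionally minimal — no local background, no
fragment-shift model — because domain detection is plumbing here, not the
contribution; externally produced peak BEDs are accepted in its place.

Consensus regions are maximal runs of bases covered by peaks from ≥ 2
distinct samples (per-base semantics; support = maximal per-base sample
count in the run). An any-overlap union mode exists for comparability with
overlap-voting consensus tools; the per-base default is the definition the
oracle tests verify.

## The statistical chain

1. **TMM factors.** Reference = sample whose 75th-percentile count
   fraction is closest to the mean. Per sample vs reference, over rows
   positive in both: M and A values, two-sided trims (30% on M, 5% on A by
   rank), weighted mean of M with inverse delta-method-variance weights,
   factor `2^mean`, all factors centred to product 1. Verified against an
   independent transcription of the formula and against Bioconductor
   edgeR's `calcNormFactors` (agreement ≤ 1e-8; the factors are frozen in
   the test suite). Note the precision weights depend on absolute counts,
   so TMM is invariant to rescaling a column only up to those weights
   (empirically ~1e-3 relative).
2. **Common dispersion.** Default `moments`: per row and group,
   `max(0, (s² − x̄)/x̄²)` on effective-library-scaled counts, combined
   across groups by degrees of freedom and across rows by a 10% two-sided
   trimmed mean. The trim guards the mean against the heavy right tail of
   per-row estimates at 6 + 6 samples. A profile-likelihood estimator
   (group means profiled out, φ maximized numerically) is available; both
   recover φ = 0.1 within [0.07, 0.13] at 2,000 rows in the seeded checks.
3. **Exact test.** Counts are scaled to the geometric-mean effective
   library size and rounded half-even to pseudo-counts. Group sums of n
   iid NB(μ, φ) variables are NB(nμ, φ/n); conditional on the total S the
   null split distribution is computed exactly (Binomial(S, n_A/n) when
   φ = 0) and the two-sided p-value sums all splits with probability at
   most the observed one (tolerance factor 1 + 1e-10 on the comparison).
   Agrees with full enumeration to 1e-10 and with edgeR's `exactTest` to
   ~1e-13 (checked during development). `log2FC` uses prior-count 0.5 on
   the per-sample group means to avoid infinities at zero counts.
4. **Permutation cutoff.** Relabelings of the samples into groups of the
   original sizes; the identity labeling is excluded, and for equal group
   sizes its label-swap as well, since it reproduces the observed
   grouping's |log2FC| vector exactly. Distinct splits are drawn without
   replacement first (6 vs 6 has C(12,6) − 2 = 922), then with
   replacement up to `n_permutations` (default 1,000); the realized
   distinct count is logged. Per relabeling the per-row |log2FC| is
   computed exactly as in the test; the pooled values give the cutoff.
   Two modes: **literal** (default) takes the 10th-percentile quantile of
   the pool — a very permissive threshold that mostly removes
   near-zero-fold rows; **upper-tail** takes the 90th percentile — the
   conventional null-tail choice. Both are exposed because the literal
   reading and the conventional one differ materially; outputs record the
   mode used.
5. **Calling.** `passes ⇔ (p < α) ∧ (|log2FC| > cutoff)`, both strict.
   Raw p-values by default (no multiple-testing correction), matching the
   `p < .05` convention of the target analysis; Benjamini–Hochberg is
   available behind a flag. The absolute (unsigned) fold-change scale is
   used for the cutoff.

## DMG/DEG logic

Method 1 maps each passing DMR to every gene whose body it overlaps by
≥ 1 bp (a flag extends mapping to promoters). Method 2 runs the chain on
promoter and gene-body matrices independently. The DMG set is the union;
per-gene direction comes from the most significant supporting call
(smallest p, ties by larger |log2FC|, then lexicographic region id), and a
conflict flag records sign disagreement between supporting calls. DEGs use
the identical chain on transcript counts; "up" means higher in the case
group.

## Integration

- Inverse sets: among genes called on both sides, set (a) = expression up ∧
  mark down, set (b) = the mirror; concordant genes remain only in the
  common-epigenome (DMG ∩ DEG) set.
- Expression stratification: genes ranked by cross-sample mean normalized
  expression (stable tie-break by gene id), genes < 5 kb excluded, top and
  bottom 1,000 selected (shrinking with a warning on small gene universes);
  profiles are computed on tags pooled across samples by default.
- Mark/expression correlation: Spearman rank correlation of per-gene mean
  normalized gene-body occupancy vs mean normalized expression (promoter
  mode available).
- Change clustering: Ward linkage on Euclidean distances over per-gene
  (Δmark, ΔmRNA) vectors; leaf order is deterministic under fixed input
  order; exported as Newick.
- Cell-type partition: plain set intersection of the common-epigenome set
  with user-supplied marker lists, split by expression direction. Marker
  lists are an input, not a computation.

## The simulator

`SimulationConfig` emulates the study design the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 6 | samples per group (6 disease vs 6 control) |
| `dispersion` | 0.1 | NB dispersion φ, typical for bulk tissue counts |
| `baseline_logmean_range` | (5, 8) | per-region log2 mean count, uniform |
| `frac_chip_effect` / `frac_rna_effect` | 0.3 | fraction of genes with a planted mark / expression effect |
| `frac_inverse_coupled` | 0.5 | fraction of the smaller affected set carrying both effects with opposite signs |
| `effect_log2fc` | 2.0 | planted effect magnitude, split ±Δ/2 between groups |
| `level_rho` | −0.5 | Gaussian-copula correlation between baseline mark and expression intensity |
| `library_size_cv` | 0.1 | log-normal spread of per-sample depth factors |
| `gene_length_range` | 2–50 kb | so both sub-5 kb (profile-excluded) and long genes exist |

Counts follow `NB(s_k · μ_g · 2^{±Δ_g/2}, φ)`. The ±Δ/2 split keeps
overall abundance comparable between groups. The negative `level_rho`
default encodes the defining property of a repressive mark — highly
expressed genes carry less of it — which is what the stratified profiles
and the correlation analysis measure. The 30% effect fractions give the
planted-truth benchmarks balanced true/null classes; with a raw `p < .05`
rule the achievable false-discovery rate is bounded below by the
null-to-true ratio, so a sparse-effect configuration would measure that
arithmetic rather than the method. Tags are single bases placed uniformly
within their region (counts and tags therefore round-trip exactly when
background is zero) plus an optional uniform genomic background.

One master seed drives everything; per-stage generators are derived by
hashing `seed:stage`, so adding a stage never perturbs another stage's
draws, and fixed seeds give bit-identical datasets.

**What the simulator does not emulate:** mappability and GC bias,
fragment-length structure, chromatin-input background, overlapping genes,
alternative promoters, and cell-type mixture. Passing tests therefore
demonstrate the correctness of the statistics and the plumbing under the
model's assumptions, not robustness to those real-data artifacts.

## Problem sizes

The seeded checks run at deliberately desk-scale sizes: 2,000 rows for
null calibration, 5 × 1,000 rows for planted-effect recovery, 400-gene
synthetic genomes for the end-to-end workflow, 1,000 permutations
throughout. These sizes keep each property estimable (binomial error on a
type-I rate at 2,000 rows is ±0.5% at 1σ) while the whole suite stays
fast.

## Numerical choices

- Pseudo-count rounding: numpy half-even; fixed so reruns are identical.
- Quantiles: numpy linear interpolation.
- p-value comparison tolerance in the exact test: `≤ p_obs · (1 + 1e-10)`
  guards against float noise when summing equal-probability splits.
- Degenerate inputs: all-constant matrices give φ = 0 and cutoff 0; empty
  tag sets give empty peak sets; an all-zero row gives p = 1.
- Outputs carry no timestamps and use fixed float formatting, so equal
  configs give byte-identical result trees.

## Known limitations

- The common-dispersion model ignores mean-dispersion trends; strongly
  heteroskedastic data would need tagwise shrinkage, which is out of scope.
- The domain caller's global background over-calls in copy-number-variable
  or low-mappability genomes; substitute external peak BEDs there.
- Direction attribution by minimum p is a convention; genes with genuinely
  mixed regional behaviour are flagged (`dmg_conflict`) rather than
  resolved.
- With 6 vs 6 samples the permutation null is built from at most 922
  distinct relabelings; the cutoff's Monte-Carlo error is correspondingly
  larger than the nominal 1,000 permutations suggest.
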