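# Methods

## The generative model

The simulator (`dronehap.simulate`) emulates the data-generating process of a
drone-cohort sequencing study at the *genotype* level — the post-variant-
calling table of per-site, per-drone calls — not at the read level.

**Queen.** The reference assembly is i.i.d. sequence at a configurable GC
content (default 0.375) over a configurable karyotype
(`GenomeSpec.bumblebee_like`: 18 chromosomes whose lengths taper linearly from
1.5× to 0.5× the mean, a deterministic stand-in for a real karyotype's size
spread). Assembly gaps are explicit `N` runs. The queen is heterozygous at a
Bernoulli-per-bp rate (default 0.26%, the colony diversity of the system this
package targets); at each heterozygous site one haplotype carries the
reference base, the other a uniformly drawn alternative, with random
haplotype assignment per site.

**Meiosis.** Crossover counts per chromosome are Poisson with mean
`rate × L_Mb / 100` (default 8.73 cM/Mb), positions uniform unless a
piecewise-constant hotspot map is supplied. There is no crossover
interference: the Poisson null is the simplest model consistent with what the
analysis assumes, and the pipeline never exploits interference. Noncrossover
tracts arrive at `nco_rate_per_gamete` (default 0.7) with geometric lengths
(mean 300 bp) — geometric is the standard gene-conversion tract model, and no
tract-length data exist for this system, so the default is a convention that
keeps simulated tracts well under the 10-kb calling rule, not a calibrated
value. A fraction of crossovers (default 3/606) carry an adjacent conversion
tract on the donor side. Converted heterozygous sites with one A/T and one
G/C allele resolve toward G/C with probability `gc_bias` (default 23/36, the
observed conversion split); other sites take the donor haplotype's allele.

**Mutation.** De novo counts are Poisson(μ × non-gap length) per gamete
(default μ = 3.58 × 10⁻⁹/bp), positions uniform over non-gap sequence and
resampled off queen-heterozygous sites so truth stays unambiguous. The
spectrum defaults are read directly off the observed study counts:
`p_transition = 1.0` (23/23 substitutions were transitions),
`p_gc_to_at_given_transition = 20/23` (implemented by resampling the site
until the origin base class matches, i.e. G/C sites mutate faster), and
`indel_fraction = 2/25` with indels < 20 bp.

**Observation.** Each (site, drone) call receives Poisson depth (mean 26, the
study's coverage regime), a binomial strand split, and a genotype quality
from a configurable family (default Normal(60, 10) clipped to [1, 99]).
Missing calls (default 2%) are emitted with sub-threshold depth — real
no-calls are low-coverage sites, which keeps the callable denominator and the
detection channel consistent. "Heterozygous" artifacts in the haploid samples
(default 0.1%) model the mapping/copy-number noise marker rule 1 removes.
Genotype errors (default rate 0) come with exponentially distributed low
quality and mostly single-strand support — exactly the signal the mutation
filters strip; the default is zero because the validated residual
false-positive rate of the post-alignment genotype channel this table
represents is negligible, and nonzero error rates are exercised in unit
tests rather than in the recovery conditions.

**What the generator does not emulate,** and hence what passing tests do not
show about real data: read-level errors and realignment artifacts (only their
genotype-level shadow), locus-specific missingness and depth (everything is
i.i.d. across sites), copy-number variation beyond the H-artifact channel,
linkage structure in queen heterozygosity, hotspot fine structure (uniform
crossover placement by default), and crossover interference. Recovery results
certify the *inference machinery*, not the upstream variant calling.

## Pipeline numerics and conventions

* Coordinates are 0-based half-open internally and in BED; genotype/phase
  TSVs and VCF are 1-based.
* Marker rules apply in the fixed order artifact → biallelic → quality/call
  rate, with each dropped site attributed to the first failing rule. Missing
  calls never count against the biallelic rule (rule 3 polices missingness).
  An optional `min_carriers_per_allele` (pipeline default 2) requires each of
  the two genotypes in ≥ 2 drones, which keeps drone-unique alleles
  (candidate mutations) out of the marker map — otherwise every true mutation
  site doubles as a "marker" and would surface as a spurious one-marker
  conversion tract.
* Phasing ties (equal votes, or no drone called at both markers) bridge to
  the nearest earlier informative marker within `max_bridge` (50) markers of
  the same phase set; failing that, a new phase set starts — linkage is never
  fabricated. Haplotype 0 carries the reference (else alphabetically smaller)
  allele at the first marker of each phase set; all downstream quantities are
  invariant to per-phase-set label swaps.
* Block span is measured between first and last *marker* positions;
  breakpoints are localized to the inter-marker interval — the resolution the
  marker map affords. Chromosome-terminal short blocks count as crossovers
  (one flank only); this is configurable.
* Shared-crossover grouping requires the exact flanking-marker pair;
  near-identical intervals are not grouped (conservative and reproducible).
  The double-CO exclusion window defaults to 700 kb, covering the observed
  ~100–700 kb artifact separations. Breakpoint intervals overlapping assembly
  gaps are annotated, not excluded.
* The hotspot call is a parameter (≥ 5× the genome-mean window rate over
  500-kb windows) — "hotspot" has no canonical numeric definition.
* The mutation caller's two haplotype-aware safeguards address the one true
  genotype-level degeneracy: a drone that locally carries a queen haplotype
  no sib shares is site-by-site indistinguishable from a run of mutations.
  `hap_support_ok` demands another drone that shares the carrier's flanking
  haplotype yet lacks the allele (impossible for a queen-heterozygous site);
  the cluster filter rejects > 2 same-drone candidates within 100 kb as one
  haplotype block rather than many independent mutations. Together with the
  gap-proximity and homopolymer flags these deterministically replace the
  study-style manual review.
* Exact Poisson intervals are Garwood: `low = χ²(α/2, 2k)/2` (0 at k = 0),
  `high = χ²(1−α/2, 2k+2)/2`; they agree with brute-force tail inversion to
  better than 10⁻⁴ for k ≤ 50.
* Per-drone count dispersion uses the (n−1)-denominator sample variance. With
  the row total fixed, the equal-probability multinomial null then has mean
  variance exactly `total/n` (= 0.719 at 23 mutations over 32 drones); no
  callable-site weighting is needed to reproduce that value, though a
  weighted null is available.
* All Monte-Carlo tests use `p = (n+1)/(m+1)` with "as extreme or more
  extreme" (≥) one-sided extremity; every randomization takes an explicit
  seed and reproduces exactly. The conversion-bias test reports the
  randomization p plus both the one- and two-sided exact binomial p (23:13
  toward GC gives 0.066 one-sided, 0.132 two-sided); which null the original
  analyses randomized is under-specified, so neither is privileged.
* The proximity test conditions on the mutation carrier's *own* events
  (mutation–meiosis coupling); a pooled-breakpoint variant sits behind a
  flag.
* Partial Spearman correlations come from the inverse rank-correlation
  matrix; constant or collinear inputs raise `UndefinedResultError` rather
  than returning a conventional value.
* `merge_rank_correlate` bins rank-ordered windows into 21–25 groups whose
  sizes differ by at most one and reports the raw per-window Spearman
  alongside, since binned regression p-values do not mean what raw ones do.

## Problem sizes

The test suite and acceptance script run the recovery analyses on a 50 Mb,
18-chromosome genome with colonies of 22 + 10 drones — the full study design
at roughly a quarter of the genome, with the mutation rate scaled up by the
same factor so the expected mutation count (~25) is preserved. Interval
coverage is checked over 200 replicate mutation-channel colonies; Monte-Carlo
calibration uses 500 repetitions of 199–399-replicate tests. These sizes are
the package's chosen balance between statistical resolution and a test suite
that runs in about a minute.

## Known limitations

* Genotype-level only: no realignment, no read-level spike-ins; the spike-in
  estimator resamples the empirical observation channel instead.
* Phasing assumes a single queen per colony and no selection among drones.
* A locally unique queen haplotype spanning a whole chromosome end could
  still masquerade as clustered mutations if it carried fewer than three
  markers; at realistic marker densities this is vanishingly rare.
* The indel model is minimal (geometric lengths, no homopolymer slippage
  bias), adequate for exercising the < 20 bp rule and the rate arithmetic,
  not for indel-spectrum inference.
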