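# Methods

This note documents the models implemented in `yeastpop`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Synthetic populations

The generator (`yeastpop.simulate`) draws a population of isolate
genomes on the 16 real *S. cerevisiae* chromosome lengths (12.07 Mb
total). All randomness flows from one named `numpy.random.Generator`
per stage, each seeded from `(config.seed, stage index)`, so a
`(config, seed)` pair reproduces every output byte for byte.

**Ploidy and aneuploidy.** Ploidy is drawn per isolate from
`{1n: 2%, 2n: 87%, 3n: 7%, 4n: 3%, 5n: 1%}`, matching a predominantly
diploid natural collection with ~11% polyploids. Each chromosome
deviates from the baseline by ±1 copy with probability 3% (roughly the
per-chromosome aneuploidy frequency observed in natural collections).
Thirty percent of isolates carry one segmental duplication of 30–80 kb
at chromosome CN + 1.

**Sites and clade structure.** Polymorphic sites form a genome-wide
Poisson pool at twice the per-isolate heterozygosity rate (default
3 het/kb, inside the 0.63–6.56/kb range seen in natural isolates).
Isolates are heterozygous at a pool site with probability 1/2 outside
their LOH tracts and never inside them, so realized het density equals
the configured rate exactly before masking. Homozygous-alternate
genotypes carry a two-level clade structure (four clades; clade-
discriminating sites at 80% alt frequency within the clade versus 2%
outside, plus a 3% genome-wide background), which makes distance
matrices and kinship non-trivial.

**LOH tracts** are placed per chromosome by an alternating renewal
process: exponential tract lengths (mean 240 kb) and exponential
heterozygous gaps whose mean is set so the expected genome fraction
under LOH equals the target (default 0.5). The chain starts in its
stationary phase — inside a tract with probability equal to the target
fraction — so the expectation is exact despite truncation at chromosome
ends. With these defaults an isolate carries ~25 tracts covering ~50%
of its genome, the scale reported for natural heterozygous isolates.

**Coverage and allele depths.** Window depths (1 kb) are
negative-binomial with mean `mean_depth × CN / ploidy` (dispersion
parameter 10, i.e. strongly overdispersed relative to Poisson, which is
what forces the callers to be median-based) and segmental duplications
raise the local mean. At a heterozygous site carrying a of CN alternate
copies (a uniform on 1..CN−1), the alternate depth is binomial(DP,
a/CN).

**FACS readouts.** G1 is drawn at the midpoint of the interval for
which both G1 and G2 = 2·G1 fall inside the ploidy's classification
ranges, plus Gaussian jitter (default SD 8, clipped to the feasible
interval); G2 is 2·G1 plus jitter clipped into its range. With zero
jitter the values round-trip exactly through classification.

**Phenotypes.** y = causal + polygenic + noise. Causal sites (default
5) are drawn among sites with MAF ≥ 0.1 with N(0,1) effect sizes; a
polygenic term over 500 random sites takes a 30% share of the genetic
variance. Components are empirically standardized and mixed so the
genetic variance fraction equals h² (default 0.5) by construction.

**Assemblies.** For the pangenome stage a miniature reference embeds
the core ORFs (lengths 300–1,500 bp, multiples of 3) between random
spacers; each isolate's contigs are exact reference chunks (3–8 kb)
with that isolate's variable ORFs inserted at least 250 bp apart, so no
187–249 bp reference sliver can be stranded between insertions.

**What is not emulated:** reads and sequencing error, mapping
artifacts, indels inside duplicated sequence, recombination maps,
GC-coverage bias, and real linkage structure (sites are exchangeable
given the clade model). Tests passing on these populations therefore
demonstrate the correctness and calibration of the algorithms under the
stated signal models, not robustness to alignment artifacts in real
data.

## Ploidy, aneuploidy, segmental duplications

FACS classification is a pure lookup against the five printed (G1, G2)
range pairs; the ranges of adjacent ploidies share boundary values, and
a readout matching two ploidies is reported ambiguous rather than
resolved by precedence. Peak finding uses a Gaussian KDE (Silverman
bandwidth) after removing saturated events (value 1000); the two
highest modes must be separated by ≥15% of the value range and the
minor mode must reach ≥20% of the major mode's density, otherwise the
readout is flagged ambiguous.

Copy number is CN = round(ratio × ploidy) with
ratio = median(full-width window depths)/genome median; a deviation of
more than 0.25 copies from the snapped integer flags the call
low-confidence (0.25 is half the spacing between adjacent copy states
in ratio units at ploidy 2). Terminal short windows are kept but
excluded from medians. Calls are invariant under global depth
rescaling.

Segmental duplications: per-window copy estimates are smoothed with a
running median of 15 windows — at the default overdispersion a single
1-kb window has a copy-number SD near 1, so unsmoothed thresholding is
meaningless — then maximal runs deviating by ≥0.4 copies are taken,
nearby same-level runs split by noise dips are merged (gap ≤ 10
windows), boundaries are refitted on the unsmoothed signal by a CUSUM-
style changepoint criterion, and runs shorter than 20 kb are dropped.
Boundary precision depends directly on depth and dispersion: at 200×
near-Poisson coverage boundaries land within one window; at 50× with
dispersion 10 they can be off by several windows, which mirrors why
such calls are usually confirmed by eye.

Ploidy assignment lets an unambiguous FACS label win unless the
genome-wide allele-balance modes contradict it while supporting a
different ploidy (→ ambiguous with both evidence flags). Without FACS,
the smallest candidate ploidy (2..5) whose k/CN modes explain ≥60% of
het sites within a ±0.08 band is chosen; the band is tighter than the
per-chromosome validation band (±0.12) because consecutive ploidies
share modes (e.g. 1/2 belongs to both 2n and 4n) and the tighter band
is what separates 1/4-3/4 patterns from 1/3-2/3 ones at 50× depth.

## Variant filtering

Pipeline order is fixed: depth floor → zygosity classification → het
cleanup/allele-balance. The depth floor is inclusive (≥50×, or ≥10×
for previously sequenced external isolates). The 5% zygosity threshold
counts heterozygous calls among an isolate's called variant sites.
The allele-balance filter keeps a het site iff
min_k |alt fraction − k/CN| ≤ 0.12, with CN taken from the chromosome
call or from a segmental-duplication interval overlapping the site.
The ±0.12 band is a fixed, reproducible stand-in for thresholds that
would otherwise be read off each collection's empirical allele-balance
distributions; at DP = 50 the binomial tail outside the band is ~12%,
falling below 2% by DP ≈ 100, and the test suite asserts agreement with
the exact binomial-tail oracle rather than a round number. Multi-allelic
sites stay in the matrix but are flagged and excluded from biallelic
analyses (distances, diversity, association). Missing genotypes are
explicit and excluded from MAF denominators.

## Loss of heterozygosity

A segment must be longer than 50 kb with fewer than 10 het sites per
50 kb. Strict mode (default) enforces the density cap on every 50-kb
sub-window at 1-kb steps; loose mode requires only the segment-wide
average and merges neighbouring strict segments while the merged
average passes. Segment edges move to the midpoint between the
qualifying window run's edge and the nearest flanking het site, clipped
at chromosome ends; maximal qualifying runs can overlap through a
shared sparse stretch, in which case the later segment is trimmed at
the earlier one's end. Two consequences of the rule worth knowing:
the density cap grants up to ~3.3 kb of slack into a 3 het/kb flank (a
50-kb edge window may legally contain 9 flanking hets), and tracts at
or below 50 kb are invisible by definition — recovery of planted tracts
is therefore assessed against tracts longer than the rule's minimum.

Heterozygosity is reported per kb of the non-LOH genome. SNP distances
are means over co-called biallelic sites of |dosage difference|/2
(dosage 0/1/2), so a het-vs-hom difference counts half of a hom-vs-hom
one; pairs' missing sites are dropped pairwise, never imputed.

## Pangenome

The extraction cascade operates on 12-column tabular local alignments
(identity > 95% only): contigs under 100 bp with any aligned part, or
whose ≤200-bp aligned block leaves less than 75 bp of flank, are
discarded whole; 200–1,500-bp blocks are excised; longer blocks are cut
into 250-bp segments, each re-aligned and removed if it matches at
>95% identity over ≥187 bp. Retained pieces of a contig separated by
under 100 bp are merged; across isolates, pieces are sorted by
decreasing length and any piece aligning at >95% identity (≥100 bp)
to an already-kept longer piece is dropped. Merging is applied once,
after filtering, and de-duplication compares retained sequences whole.
Note the shorter-sequence elimination can drop genuinely novel material
when a piece shares one ORF with a longer multi-ORF piece; this is the
rule's literal behaviour.

The aligner is pluggable. The built-in k-mer aligner (15-mer seeds
grouped by diagonal, co-diagonal chaining, exact-match extension,
Hamming identity) handles the simulator's indel-free sequences;
production data should use a real local aligner and feed its tabular
output in.

ORF families are connected components of the similarity graph
(identity > 95% over ≥ 75% of the smaller sequence, single best block
per pair); the representative is the highest-degree non-dubious
reference ORF, then the highest-degree reference ORF, then the
highest-degree member, ties broken lexicographically. Copy number is
ORF median depth over the median of per-chromosome median depths
(per haploid genome, hence 0.5 for a hemizygous diploid locus);
presence requires ≥0.2 copies. Clade contrasts compare the two groups'
distributions of per-clade median copy numbers with a two-sided
rank-sum test, which removes clade-size bias.

## Diversity statistics

π is the mean pairwise difference per site over called alleles (each
diploid isolate contributes two alleles; a consensus mode collapses
each isolate to one sequence, het counted as carrying the alternate,
for compatibility with one-sequence-per-isolate pipelines — which of
the two matches any given legacy run is deliberately left to the
caller). θ_w = S/(a₁L); Tajima's D uses the standard variance constants
and is undefined at S = 0 and at n = 2 (where the constants vanish).
Windows are 10-kb non-overlapping, 0-based half-open, terminal windows
reported at true length; sites with >20% missingness are excluded, and
each window's n is the modal called-allele count of its sites. r² is
the squared Pearson correlation of mean-imputed allele-count vectors
(composite LD on unphased genotypes) for intra-chromosomal pairs within
25 kb, averaged in 100-bp bins; the half-length is the midpoint of the
first bin at or below half the maximum bin mean.

## Mixed-model association

Variance components are estimated by REML: with K = USUᵀ the model
rotates to independent observations with variances σ²_g(s_i + δ),
δ = σ²_e/σ²_g; the restricted likelihood is profiled over σ²_g and
maximized over log δ on a 33-point grid over [−8, 8] followed by
bounded refinement. h² = σ²_g/(σ²_g + σ²_e) = 1/(1 + δ). When K is
numerically proportional to the identity the components are
unidentifiable and the fit is flagged. Kinship is ZZᵀ/m with markers
centred by 2p and scaled by √(2p(1−p)); missing genotypes are
mean-imputed for kinship and association only, never for diversity
statistics.

Markers are tested by likelihood ratio in the rotated model with the
null δ re-used per trait (the fast single-decomposition approximation);
the statistic n·log(RSS₀/RSS₁) is χ²(1) under the null and reduces
exactly to the OLS likelihood ratio when K = I. λ divides the median
observed statistic by 0.456, the conventional null median of χ²(1) in
the association literature; the exactly computed median is 0.45494
(0.455 at three decimals), a 0.2% difference that is immaterial for
calibration but worth stating since the convention is a rounding of
this value. Permutation thresholds permute the phenotype vector against
fixed genotypes and kinship rows, re-fit δ per permutation, record each
genome-wide minimum p, and take the (fwer·n_perm)-th lowest minimum
literally (5th of 100) without interpolation; the seed is mandatory.
Variance explained by selected markers is the increase in the REML
genetic-variance fraction when the selected markers join the kinship
markers, mirroring how associated markers are folded back into the
similarity matrix.

## Problem sizes used in the checks

The calibration checks run at desk scale: λ on 200 isolates × 5,000
markers; permutation FWER over 200 null traits on 200 × 500 genotypes
with 100 permutations each; LOH oracle checks on 100 default-condition
isolates; ploidy/CN recovery on the default 50-isolate population;
Tajima's D over 200 neutral coalescent replicates (n = 20, 10 kb);
pangenome checks on ≤200 ORFs and 8 assemblies; heritability recovery
at n = 300 with 250 markers (the marker count keeps the GRM's
off-diagonal variance high enough that a single REML estimate has a
standard error near 0.08 — with thousands of markers on 300 isolates
the estimate is unbiased but far noisier).

## Known limitations

* Segdup boundary precision degrades quickly with coverage
  overdispersion (see above); calls are exact on clean signal only.
* The extraction cascade's shorter-sequence de-duplication can discard
  novel sequence that co-occurs on a piece with shared material.
* The LOH rule cannot see tracts ≤ 50 kb and systematically includes a
  few kilobases of het-dense flank; both follow from the rule itself.
* `classify_facs` treats boundary-overlapping range pairs as ambiguous;
  collections with many readouts on range edges will need the manual
  review the ranges were designed to trigger.
* The generator's sites are exchangeable given clade membership; LD
  decay on simulated data reflects the planted correlation structure
  of the test at hand, not a recombination map.
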