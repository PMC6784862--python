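# yeastpop

Population genomics of *Saccharomyces cerevisiae* isolate collections.

Large surveys of natural yeast isolates combine several bespoke analyses
that are usually scattered across one-off scripts: assigning each
isolate's ploidy from flow-cytometry DNA content, sequencing coverage
and allele balance; calling chromosome-level aneuploidies and segmental
duplications; filtering variant calls with ploidy-aware allele-balance
rules; mapping loss-of-heterozygosity (LOH) tracts; building the
pangenome's presence/absence and copy-number matrices; computing
population diversity statistics; and running permutation-calibrated
mixed-model association between genetic variants and quantitative
phenotypes. `yeastpop` packages these procedures as a tested, reusable
library with a built-in synthetic-data generator, so every stage can be
exercised end to end — with a known ground truth — without any sequence
download.

## The methods in brief

* **Ploidy and aneuploidy.** FACS G1/G2 fluorescence peaks are classified
  against fixed per-ploidy ranges (e.g. haploid: G1 ∈ [39, 181],
  G2 ∈ [148, 255]). Coverage is binned into 1-kb non-overlapping windows
  and each chromosome's copy number is CN = round(ratio × ploidy) where
  ratio = median window depth / genome median. At a heterozygous site on a
  CN-copy chromosome the alternate-allele fraction clusters at k/CN
  (k = 1..CN−1), which validates or contradicts the other two signals.
* **Variant filtering.** Depth floor of 50× (10× for previously sequenced
  isolates); isolates with < 5% heterozygous calls are treated as
  homozygous and their residual het calls removed; het sites whose allele
  balance falls outside a band around the k/CN modes are rejected;
  per-gene frameshift = summed signed indel lengths not divisible by 3.
* **LOH.** Regions longer than 50 kb with fewer than 10 heterozygous
  sites per 50 kb (enforced on every 50-kb sub-window at 1-kb steps) are
  called LOH; heterozygosity levels are computed on the LOH-masked
  genome; SNP distances half-weight heterozygous differences.
* **Pangenome.** Non-reference material is extracted from de novo
  assembly contigs by a filtering cascade over >95%-identity alignments
  (whole-contig drops, block excision for 200–1,500 bp, 250-bp
  re-alignment segmentation above 1,500 bp, piece merging, cross-isolate
  de-duplication). ORFs collapse into families as connected components of
  a >95%-identity / ≥75%-coverage similarity graph; per-ORF copy number
  is ORF median depth / median of per-chromosome median depths.
* **Diversity.** π, Watterson's θ_w = S/(a₁L), Tajima's D with the
  standard variance constants, folded site-frequency spectra, and r²
  decay in 100-bp distance bins with the half-length of LD.
* **GWAS.** Phenotypes are growth ratios to the control condition,
  quantile-normalized to N(0,1) scores. The mixed model
  y = μ + g + e, g ~ N(0, σ²_g K) with kinship K = ZZᵀ/m over
  standardized genotypes is fit by REML via the spectral decomposition of
  K; markers are tested by likelihood ratio in the rotated model;
  genomic inflation λ = median(χ²)/0.456; family-wise thresholds come
  from 100 phenotype permutations (5th lowest genome-wide minimum
  p-value); heritability and marker-explained variance come from the
  null-model variance components.

## Worked example

```python
import numpy as np
from yeastpop.simulate import (SimulationConfig, simulate_population,
                               simulate_coverage, simulate_facs)
from yeastpop.ploidy import (FacsReadout, classify_facs, assign_ploidy,
                             call_chromosome_copy_numbers)
from yeastpop.loh import detect_loh, loh_fraction_and_count

config = SimulationConfig(seed=7, n_isolates=20)
genotypes, truth = simulate_population(config)
coverage, depths = simulate_coverage(genotypes, truth, config)
facs = simulate_facs(truth, config)

i, iso = 2, truth.isolates[2]
label = classify_facs(FacsReadout(facs.loc[i, "g1"], facs.loc[i, "g2"]))
het = depths[iso].query("code == 1")
call = assign_ploidy(iso, label, (het["alt_depth"] / het["dp"]).to_numpy())
print(f"{iso}: ploidy {call.ploidy}n")

chrom_calls = call_chromosome_copy_numbers(coverage[iso], call.ploidy)
print("aneuploid:", [(c.chromosome, c.copy_number) for c in chrom_calls if c.aneuploid])

lengths = dict(zip(truth.chromosomes, config.chromosome_lengths))
het_pos = {ch: np.sort(genotypes.pos[(genotypes.chrom_idx == c) & (genotypes.codes[:, i] == 1)])
           for c, ch in enumerate(truth.chromosomes)}
segments = detect_loh(het_pos, lengths)
frac, n_seg = loh_fraction_and_count(segments, sum(config.chromosome_lengths))
print(f"LOH: {n_seg} segments covering {100 * frac:.1f}% of the genome")
```

prints

```
iso002: ploidy 2n
aneuploid: [('chr12', 1)]
LOH: 22 segments covering 51.2% of the genome
```

meaning isolate `iso002` is a diploid carrying a chromosome-12 monosomy,
and 22 detected LOH segments cover 51.2% of its genome — against a
planted truth of 52.0% for that isolate.

A thin command-line interface covers the common batch steps:
`yeastpop simulate`, `yeastpop ploidy`, `yeastpop loh`,
`yeastpop diversity`, `yeastpop ld` and `yeastpop gwas` (see
`yeastpop --help`).

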