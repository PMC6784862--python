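"""Seeded synthetic populations of yeast-like isolate genomes.

The generator emulates the statistical structure of a natural
*S. cerevisiae* isolate collection: a 16-chromosome 12-Mb genome, a
clade-structured population with ploidies 1n-5n, chromosome-level
aneuploidies and segmental duplications, long loss-of-heterozygosity
(LOH) tracts, core/variable ORF content, overdispersed sequencing
coverage, binomially sampled allele depths at heterozygous sites,
per-ploidy FACS G1/G2 readouts and quantitative phenotypes with a chosen
narrow-sense heritability.  Every draw comes from one named
``numpy.random.Generator`` so a (config, seed) pair reproduces output
byte-for-byte, and a full truth set is returned for downstream testing.

It does not simulate reads, sequencing error or recombination maps; see
the methods note for what this implies for the tests built on it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ploidy import FACS_RANGES, CoverageProfile

#: S. cerevisiae chromosome lengths (bp), chrI-chrXVI (R64 assembly scale).
YEAST_CHROMOSOME_LENGTHS: tuple[int, ...] = (
    230_218, 813_184, 316_620, 1_531_933, 576_874, 270_161, 1_090_940,
    562_643, 439_888, 745_751, 666_816, 1_078_177, 924_431, 784_333,
    1_091_291, 948_066,
)

#: G1 intervals from which FACS values are drawn so that both G1 and
#: G2 = 2*G1 land inside the classification ranges of FACS_RANGES.
_FEASIBLE_G1 = {
    1: (74.0, 127.5),
    2: (147.5, 250.0),
    3: (250.0, 350.0),
    4: (350.0, 452.5),
    5: (455.0, 499.5),
}

_BASES = np.array(list("ACGT"))

# Segmental-duplication planting rate/size (module policy, not config).
_SEGDUP_RATE = 0.3
_SEGDUP_LEN = (30_000, 80_000)
_N_CLADES = 4


@dataclass
class SimulationConfig:
    """Study conditions of a simulated isolate collection.

    Defaults are scaled to a realistic S. cerevisiae collection: a
    12-Mb/16-chromosome genome, a predominantly diploid population with
    ~12% polyploids and ~3% aneuploid chromosomes, LOH tracts of mean
    240 kb covering half the genome of heterozygous isolates, and
    3 heterozygous sites per kb outside LOH.
    """

    n_isolates: int = 50
    chromosome_lengths: tuple[int, ...] = YEAST_CHROMOSOME_LENGTHS
    ploidy_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.02, 2: 0.87, 3: 0.07, 4: 0.03, 5: 0.01}
    )
    aneuploidy_rate: float = 0.03
    loh_tract_length: float = 240_000.0
    loh_genome_fraction: float = 0.5
    het_rate: float = 3.0  # het sites per kb outside LOH
    n_core_orfs: int = 60
    n_variable_orfs: int = 60
    variable_orf_presence: float = 0.5
    mean_depth: float = 50.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    h2: float = 0.5
    n_causal: int = 5
    facs_jitter: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_isolates < 1:
            raise ValueError("n_isolates must be >= 1")
        if not self.chromosome_lengths or any(
            L <= 0 for L in self.chromosome_lengths
        ):
            raise ValueError("chromosome_lengths must all be > 0")
        probs = np.array(list(self.ploidy_distribution.values()))
        if (probs < 0).any() or (probs > 1).any() or not np.isclose(probs.sum(), 1):
            raise ValueError("ploidy_distribution must be probabilities summing to 1")
        if any(p not in range(1, 6) for p in self.ploidy_distribution):
            raise ValueError("ploidy_distribution keys must be in 1..5")
        for name in ("aneuploidy_rate", "loh_genome_fraction", "variable_orf_presence", "h2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.loh_tract_length <= 0:
            raise ValueError("loh_tract_length must be > 0")
        if self.het_rate < 0:
            raise ValueError("het_rate must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if self.facs_jitter < 0:
            raise ValueError("facs_jitter must be >= 0")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(len(self.chromosome_lengths))]


@dataclass
class TruthSet:
    """Planted ground truth of one simulated population."""

    isolates: list[str]
    chromosomes: list[str]
    chromosome_lengths: tuple[int, ...]
    ploidy: np.ndarray  # (n,)
    chromosome_cn: np.ndarray  # (n, n_chrom)
    clade: np.ndarray  # (n,) clade index
    loh_tracts: list[list[tuple[int, int, int]]]  # per isolate: (chrom_idx, start, end)
    segdups: list[list[tuple[int, int, int, int]]]  # (chrom_idx, start, end, cn)
    orf_ids: list[str] = field(default_factory=list)
    orf_is_core: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    orf_copy: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    causal_sites: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    causal_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    h2: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for tracts in self.loh_tracts:
            for c, s, e in tracts:
                if not (0 <= s < e <= self.chromosome_lengths[c]):
                    raise ValueError("LOH tract outside its chromosome")
        for dups in self.segdups:
            for c, s, e, cn in dups:
                if not (0 <= s < e <= self.chromosome_lengths[c]) or cn < 0:
                    raise ValueError("invalid segmental duplication")
        if (self.chromosome_cn < 0).any():
            raise ValueError("copy numbers must be non-negative")

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, np.generic):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not serializable: {type(o)}")

        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, default=_default))


@dataclass
class PopulationGenotypes:
    """Biallelic site-by-isolate genotype-class matrix.

    ``codes`` holds 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing, one
    row per site (sorted by chromosome then position, 0-based) and one
    column per isolate.
    """

    chrom_idx: np.ndarray  # (n_sites,)
    pos: np.ndarray  # (n_sites,) 0-based
    ref: np.ndarray  # (n_sites,) single bases
    alt: np.ndarray
    codes: np.ndarray  # (n_sites, n_isolates) int8
    isolates: list[str]
    chromosomes: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def dosage(self) -> np.ndarray:
        """Alt-allele count per genotype (float, NaN for missing)."""
        d = self.codes.astype(float)
        d[self.codes < 0] = np.nan
        return d


def _stream_rng(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng([seed, label])


def _place_loh_tracts(
    rng: np.random.Generator, length: int, mean_tract: float, fraction: float
) -> list[tuple[int, int]]:
    """Alternating-renewal placement of LOH tracts along one chromosome.

    Exponential tract lengths (mean ``mean_tract``) alternate with
    exponential heterozygous gaps whose mean is chosen so the expected
    genome fraction under LOH equals ``fraction``; the chain starts in
    its stationary phase (inside a tract with probability ``fraction``)
    so the expectation holds exactly despite end truncation, and tracts
    are truncated at chromosome ends.
    """
    if fraction <= 0:
        return []
    if fraction >= 1:
        return [(0, length)]
    mean_gap = mean_tract * (1 - fraction) / fraction
    tracts = []
    x = 0.0
    if rng.random() < fraction:  # stationary start: already inside a tract
        x = rng.exponential(mean_tract)
        tracts.append((0, int(min(x, length))))
        x += rng.exponential(mean_gap)
    else:
        x = rng.exponential(mean_gap)
    while x < length:
        start = x
        x += rng.exponential(mean_tract)
        tracts.append((int(start), int(min(x, length))))
        x += rng.exponential(mean_gap)
    return [(s, e) for s, e in tracts if e > s]


def simulate_population(
    config: SimulationConfig,
) -> tuple[PopulationGenotypes, TruthSet]:
    """Draw a clade-structured population and its full truth set.

    Sites come from a genome-wide pool at twice the per-isolate het rate;
    an isolate is heterozygous at a pool site outside its LOH tracts with
    probability 1/2, so realized het density matches ``het_rate``.
    Hom-alt genotypes carry the clade structure: each clade owns a set of
    discriminating sites at elevated alt frequency, plus a genome-wide
    background of shared and private homozygous variants.
    """
    config.validate()
    rng = _stream_rng(config.seed, 1)
    n = config.n_isolates
    n_chrom = len(config.chromosome_lengths)
    isolates = [f"iso{i:03d}" for i in range(n)]

    ploidy_labels = np.array(sorted(config.ploidy_distribution))
    probs = np.array([config.ploidy_distribution[p] for p in ploidy_labels])
    ploidy = rng.choice(ploidy_labels, size=n, p=probs)

    cn = np.repeat(ploidy[:, None], n_chrom, axis=1).astype(int)
    aneu = rng.random((n, n_chrom)) < config.aneuploidy_rate
    direction = np.where(rng.random((n, n_chrom)) < 0.5, 1, -1)
    direction[cn + direction < 1] = 1  # never drop below one copy
    cn[aneu] += direction[aneu]

    segdups: list[list[tuple[int, int, int, int]]] = []
    for i in range(n):
        dups = []
        if rng.random() < _SEGDUP_RATE:
            c = int(rng.integers(n_chrom))
            L = int(rng.integers(*_SEGDUP_LEN))
            L = min(L, config.chromosome_lengths[c] - 1)
            start = int(rng.integers(0, config.chromosome_lengths[c] - L))
            dups.append((c, start, start + L, cn[i, c] + 1))
        segdups.append(dups)

    clade = rng.integers(_N_CLADES, size=n)

    # site pool
    pool_rate = 2.0 * config.het_rate / 1000.0  # per bp
    chrom_idx_parts, pos_parts = [], []
    for c, L in enumerate(config.chromosome_lengths):
        k = rng.poisson(pool_rate * L)
        p = np.unique(rng.integers(0, L, size=k))
        pos_parts.append(p)
        chrom_idx_parts.append(np.full(len(p), c))
    pos = np.concatenate(pos_parts)
    chrom_idx = np.concatenate(chrom_idx_parts).astype(np.int32)
    n_sites = len(pos)

    ref_i = rng.integers(4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4

    # clade-discriminating sites (30% of pool) and background hom-alt
    site_clade = np.where(
        rng.random(n_sites) < 0.3, rng.integers(_N_CLADES, size=n_sites), -1
    )
    hom_p = np.full((n_sites, n), 0.03)
    disc = site_clade >= 0
    hom_p[disc, :] = 0.02
    same = site_clade[:, None] == clade[None, :]
    hom_p[same] = 0.8

    het = rng.random((n_sites, n)) < 0.5
    het[:, ploidy == 1] = False

    loh_tracts: list[list[tuple[int, int, int]]] = []
    for i in range(n):
        tracts_i: list[tuple[int, int, int]] = []
        if ploidy[i] >= 2:
            for c, L in enumerate(config.chromosome_lengths):
                for s, e in _place_loh_tracts(
                    rng, L, config.loh_tract_length, config.loh_genome_fraction
                ):
                    tracts_i.append((c, s, e))
        loh_tracts.append(tracts_i)
        for c, s, e in tracts_i:
            inside = (chrom_idx == c) & (pos >= s) & (pos < e)
            het[inside, i] = False

    hom = rng.random((n_sites, n)) < hom_p
    codes = np.zeros((n_sites, n), dtype=np.int8)
    codes[hom] = 2
    codes[het] = 1  # het wins so realized het density is exact

    genotypes = PopulationGenotypes(
        chrom_idx=chrom_idx,
        pos=pos.astype(np.int64),
        ref=_BASES[ref_i],
        alt=_BASES[alt_i],
        codes=codes,
        isolates=isolates,
        chromosomes=config.chromosome_names,
    )
    truth = TruthSet(
        isolates=isolates,
        chromosomes=config.chromosome_names,
        chromosome_lengths=tuple(config.chromosome_lengths),
        ploidy=ploidy.astype(int),
        chromosome_cn=cn,
        clade=clade,
        loh_tracts=loh_tracts,
        segdups=segdups,
        h2=config.h2,
        seed=config.seed,
    )
    truth.validate()
    return genotypes, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, size_param: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_coverage(
    genotypes: PopulationGenotypes,
    truth: TruthSet,
    config: SimulationConfig,
) -> tuple[dict[str, CoverageProfile], dict[str, pd.DataFrame]]:
    """Draw window coverage tracks and per-site allele depths.

    Window depths are negative-binomial with mean
    ``mean_depth * CN / ploidy`` (segmental duplications raise CN
    locally).  At heterozygous sites the alt depth is binomial with
    success probability a/CN for a true alt copy count a drawn uniformly
    from 1..CN-1.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = _stream_rng(config.seed, 2)
    w = 1000
    profiles: dict[str, CoverageProfile] = {}
    allele_depths: dict[str, pd.DataFrame] = {}
    lengths = dict(zip(truth.chromosomes, truth.chromosome_lengths))
    for i, iso in enumerate(truth.isolates):
        ploidy = int(truth.ploidy[i])
        windows: dict[str, np.ndarray] = {}
        site_mean = np.empty(genotypes.n_sites)
        for c, chrom in enumerate(truth.chromosomes):
            L = truth.chromosome_lengths[c]
            n_win = -(-L // w)
            mean = np.full(n_win, config.mean_depth * truth.chromosome_cn[i, c] / ploidy)
            site_cn = np.full(L // w + 1, truth.chromosome_cn[i, c], dtype=float)
            for dc, ds, de, dcn in truth.segdups[i]:
                if dc == c:
                    mean[ds // w : -(-de // w)] = config.mean_depth * dcn / ploidy
                    site_cn[ds // w : de // w + 1] = dcn
            windows[chrom] = _nb_draw(rng, mean, config.depth_dispersion).astype(float)
            on_c = genotypes.chrom_idx == c
            site_mean[on_c] = config.mean_depth * site_cn[
                np.minimum(genotypes.pos[on_c] // w, len(site_cn) - 1)
            ] / ploidy
        profile = CoverageProfile(
            windows=windows, window_size=w, chromosome_lengths=lengths
        )
        full = np.concatenate(
            [profile.full_width_depths(ch) for ch in truth.chromosomes]
        )
        profile.genome_median = float(np.median(full))
        profiles[iso] = profile

        # allele depths at this isolate's variant sites
        called = genotypes.codes[:, i] != 0
        dp = np.maximum(
            _nb_draw(rng, site_mean[called], config.depth_dispersion), 1
        )
        code = genotypes.codes[called, i]
        cn_site = np.maximum(
            truth.chromosome_cn[i, genotypes.chrom_idx[called]], 2
        )
        a = 1 + (rng.random(called.sum()) * (cn_site - 1)).astype(int)
        frac = np.where(code == 1, a / cn_site, 1.0)
        alt_dp = rng.binomial(dp, frac)
        allele_depths[iso] = pd.DataFrame(
            {
                "chrom": np.asarray(truth.chromosomes)[genotypes.chrom_idx[called]],
                "pos": genotypes.pos[called],
                "code": code,
                "dp": dp,
                "ref_depth": dp - alt_dp,
                "alt_depth": alt_dp,
            }
        )
    return profiles, allele_depths


def simulate_facs(truth: TruthSet, config: SimulationConfig) -> pd.DataFrame:
    """Draw per-isolate (G1, G2) FACS peak values.

    G1 is the midpoint of the ploidy's feasible interval plus Gaussian
    jitter (clipped into the interval); G2 is 2*G1 plus jitter, clipped
    into the ploidy's G2 classification range.  With zero jitter the
    values round-trip exactly through FACS classification.
    """
    if not np.all((truth.ploidy >= 1) & (truth.ploidy <= 5)):
        raise ValueError("ploidy must be in 1..5")
    rng = _stream_rng(config.seed, 3)
    g1s, g2s = [], []
    for p in truth.ploidy:
        lo, hi = _FEASIBLE_G1[int(p)]
        g1 = np.clip((lo + hi) / 2 + rng.normal(0, config.facs_jitter or 1e-12), lo, hi)
        g2lo, g2hi = FACS_RANGES[int(p)][1]
        g2hi = min(g2hi, 999.0)
        g2 = np.clip(2 * g1 + rng.normal(0, config.facs_jitter or 1e-12), g2lo, g2hi)
        if int(p) == 5:
            g2 = max(g2, 906.0)
        g1s.append(float(g1))
        g2s.append(float(g2))
    return pd.DataFrame({"isolate": truth.isolates, "g1": g1s, "g2": g2s})


def simulate_phenotypes(
    genotypes: PopulationGenotypes,
    config: SimulationConfig,
    truth: TruthSet,
) -> pd.DataFrame:
    """Simulate a quantitative trait with heritability ``config.h2``.

    y = causal effects + polygenic term + environmental noise, with the
    genetic (causal + polygenic) and noise components empirically scaled
    to variance fractions h2 and 1 - h2.  Causal sites are drawn among
    sites with minor-allele frequency >= 0.1; the polygenic term takes a
    30% share of the genetic variance when causal sites are present.
    """
    config.validate()
    rng = _stream_rng(config.seed, 4)
    n = len(truth.isolates)
    dosage = genotypes.dosage()
    dosage = np.nan_to_num(dosage, nan=0.0)
    freq = dosage.mean(axis=1) / 2
    maf = np.minimum(freq, 1 - freq)
    candidates = np.flatnonzero(maf >= 0.1)
    if config.n_causal > len(candidates):
        raise ValueError(
            f"n_causal={config.n_causal} exceeds {len(candidates)} eligible markers"
        )
    if config.h2 > 0 and genotypes.n_sites == 0:
        raise ValueError("h2 > 0 requires at least one marker")

    def _std(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    causal = rng.choice(candidates, size=config.n_causal, replace=False) \
        if config.n_causal else np.empty(0, int)
    effects = rng.normal(size=config.n_causal)
    causal_part = _std(effects @ dosage[causal]) if config.n_causal else np.zeros(n)

    m_poly = min(500, genotypes.n_sites)
    poly_sites = rng.choice(genotypes.n_sites, size=m_poly, replace=False)
    poly_part = _std(rng.normal(size=m_poly) @ dosage[poly_sites]) if m_poly else np.zeros(n)

    share = 0.3 if config.n_causal else 1.0
    genetic = np.sqrt(1 - share) * causal_part + np.sqrt(share) * poly_part
    genetic = _std(genetic) if genetic.std() > 0 else genetic
    noise = _std(rng.normal(size=n))
    y = np.sqrt(config.h2) * genetic + np.sqrt(1 - config.h2) * noise

    truth.causal_sites = causal
    truth.causal_effects = effects
    truth.h2 = config.h2
    return pd.DataFrame({"isolate": truth.isolates, "value": y})


def simulate_orf_content(
    truth: TruthSet, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant per-isolate ORF copy numbers and derived median coverages.

    Core ORFs are present in every isolate (copy 1 per haploid genome,
    occasionally 2); variable ORFs are present with probability
    ``variable_orf_presence``.  Returns (per-ORF median coverage table,
    per-chromosome median coverage table), the inputs of the pangenome
    copy-number stage.  Truth copy numbers are stored on ``truth``.
    """
    rng = _stream_rng(config.seed, 5)
    n = len(truth.isolates)
    n_orfs = config.n_core_orfs + config.n_variable_orfs
    orf_ids = [f"CORE{i:04d}" for i in range(config.n_core_orfs)] + [
        f"VAR{i:04d}" for i in range(config.n_variable_orfs)
    ]
    is_core = np.arange(n_orfs) < config.n_core_orfs
    copy = np.zeros((n, n_orfs))
    copy[:, is_core] = rng.choice([1.0, 2.0], p=[0.95, 0.05], size=(n, config.n_core_orfs))
    present = rng.random((n, config.n_variable_orfs)) < config.variable_orf_presence
    var_copy = rng.choice([1.0, 2.0, 3.0], p=[0.85, 0.1, 0.05], size=present.shape)
    copy[:, ~is_core] = np.where(present, var_copy, 0.0)

    # hemizygous calls in diploids give 0.5-copy values
    hemi = (rng.random((n, n_orfs)) < 0.05) & (copy == 1.0) & (truth.ploidy[:, None] == 2)
    copy[hemi] = 0.5

    orf_cov = _nb_draw(
        rng, np.maximum(copy * config.mean_depth, 0.01), config.depth_dispersion
    ).astype(float)
    chrom_cov = _nb_draw(
        rng,
        np.full((n, len(truth.chromosomes)), config.mean_depth * 20),
        config.depth_dispersion * 20,
    ).astype(float) / 20.0

    truth.orf_ids = orf_ids
    truth.orf_is_core = is_core
    truth.orf_copy = copy
    orf_df = pd.DataFrame(orf_cov, index=truth.isolates, columns=orf_ids)
    chrom_df = pd.DataFrame(chrom_cov, index=truth.isolates, columns=truth.chromosomes)
    return orf_df, chrom_df


def simulate_hwe_markers(
    n_isolates: int,
    n_markers: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> pd.DataFrame:
    """Unlinked biallelic markers under Hardy-Weinberg equilibrium.

    Allele frequencies are uniform over ``maf_range`` and genotypes are
    independent binomial(2, p) draws — the null genotype model used for
    association-calibration experiments.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf_range, n_markers)
    x = rng.binomial(1, p, (n_isolates, n_markers)) + rng.binomial(
        1, p, (n_isolates, n_markers)
    )
    return pd.DataFrame(
        x.astype(float),
        index=[f"iso{i:03d}" for i in range(n_isolates)],
        columns=[f"m{j}" for j in range(n_markers)],
    )


# ---------------------------------------------------------------------------
# assembly-level simulation for the pangenome extraction stage


@dataclass
class AssemblySimulation:
    """Reference sequence, per-isolate contigs and planted novel ORFs."""

    reference: dict[str, str]
    contigs: dict[str, dict[str, str]]  # isolate -> contig id -> seq
    core_orfs: dict[str, str]  # id -> sequence (embedded in the reference)
    novel_orfs: dict[str, str]  # id -> sequence (absent from the reference)
    presence: pd.DataFrame  # isolates x novel ORF ids (bool)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(4, size=length)])


def simulate_assemblies(
    config: SimulationConfig,
    n_isolates: int | None = None,
    ref_chunk: tuple[int, int] = (3000, 8000),
) -> AssemblySimulation:
    """Build a miniature reference plus de-novo-assembly-like contigs.

    The reference embeds the core ORFs separated by random spacers;
    each isolate's contigs are exact reference chunks with that
    isolate's variable (novel) ORFs inserted mid-chunk, emulating what a
    de novo assembly of a strain carrying non-reference material looks
    like to the extraction cascade.
    """
    rng = _stream_rng(config.seed, 6)
    n = n_isolates if n_isolates is not None else config.n_isolates
    core = {
        f"CORE{i:04d}": _random_seq(rng, int(rng.integers(100, 500)) * 3)
        for i in range(config.n_core_orfs)
    }
    novel = {
        f"VAR{i:04d}": _random_seq(rng, int(rng.integers(100, 500)) * 3)
        for i in range(config.n_variable_orfs)
    }
    parts = []
    for seq in core.values():
        parts.append(_random_seq(rng, int(rng.integers(200, 800))))
        parts.append(seq)
    parts.append(_random_seq(rng, 500))
    ref_seq = "".join(parts)
    reference = {"ref01": ref_seq}

    isolates = [f"iso{i:03d}" for i in range(n)]
    presence = pd.DataFrame(
        rng.random((n, len(novel))) < config.variable_orf_presence,
        index=isolates,
        columns=list(novel),
    )
    contigs: dict[str, dict[str, str]] = {}
    for iso in isolates:
        # chop the reference into chunks
        bounds = [0]
        while bounds[-1] < len(ref_seq):
            bounds.append(min(bounds[-1] + int(rng.integers(*ref_chunk)), len(ref_seq)))
        chunks = [ref_seq[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        mine = [o for o in novel if presence.loc[iso, o]]
        targets = rng.integers(len(chunks), size=len(mine))
        inserts: dict[int, list[tuple[int, str]]] = {}
        for orf, t in zip(mine, targets):
            # insertion points in original chunk coordinates, kept either
            # coincident or >= 250 bp apart so a later insertion never
            # splits an earlier ORF nor strands a 187-249 bp ref sliver
            taken = [a for a, _ in inserts.get(int(t), [])]
            for _ in range(20):
                at = int(rng.integers(500, max(len(chunks[t]) - 500, 501)))
                if all(abs(at - a) >= 250 for a in taken):
                    break
            else:
                at = taken[0]
            inserts.setdefault(int(t), []).append((at, orf))
        for t, placed in inserts.items():
            chunk = chunks[t]
            parts, prev = [], 0
            for at, orf in sorted(placed):
                at = min(at, len(chunk))
                parts.append(chunk[prev:at])
                parts.append(novel[orf])
                prev = at
            parts.append(chunk[prev:])
            chunks[t] = "".join(parts)
        contigs[iso] = {f"{iso}_ctg{j:03d}": c for j, c in enumerate(chunks)}
    return AssemblySimulation(
        reference=reference,
        contigs=contigs,
        core_orfs=core,
        novel_orfs=novel,
        presence=presence,
    )


# ---------------------------------------------------------------------------
# fixture emission


def emit_fixtures(
    outdir: str | Path,
    config: SimulationConfig,
    genotypes: PopulationGenotypes,
    truth: TruthSet,
    coverage: dict[str, CoverageProfile] | None = None,
    allele_depths: dict[str, pd.DataFrame] | None = None,
    facs: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    assemblies: AssemblySimulation | None = None,
) -> dict[str, Path]:
    """Write the simulated dataset as standard text files.

    Emits a multi-sample VCF 4.2 (GT/DP/AD), a window coverage TSV
    (isolate, chrom, window_start, depth; 0-based half-open), FACS and
    phenotype TSVs, per-isolate assembly FASTAs and the truth JSON.
    Regeneration from the same (config, seed) is byte-identical.
    """
    from . import io as _io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    vcf_path = out / "population.vcf"
    _io.write_population_vcf(vcf_path, genotypes, truth, allele_depths)
    written["vcf"] = vcf_path

    if coverage is not None:
        rows = []
        for iso, profile in coverage.items():
            for chrom, depths in profile.windows.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "isolate": iso,
                            "chrom": chrom,
                            "window_start": np.arange(len(depths)) * profile.window_size,
                            "depth": depths,
                        }
                    )
                )
        cov_path = out / "coverage.tsv"
        pd.concat(rows).to_csv(cov_path, sep="\t", index=False)
        written["coverage"] = cov_path
    if facs is not None:
        facs_path = out / "facs.tsv"
        facs.to_csv(facs_path, sep="\t", index=False)
        written["facs"] = facs_path
    if phenotypes is not None:
        ph_path = out / "phenotypes.tsv"
        phenotypes.to_csv(ph_path, sep="\t", index=False)
        written["phenotypes"] = ph_path
    if assemblies is not None:
        asm_dir = out / "assemblies"
        asm_dir.mkdir(exist_ok=True)
        _io.write_fasta(asm_dir / "reference.fasta", assemblies.reference)
        for iso, ctgs in assemblies.contigs.items():
            _io.write_fasta(asm_dir / f"{iso}.fasta", ctgs)
        written["assemblies"] = asm_dir
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    written["truth"] = truth_path
    return written
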