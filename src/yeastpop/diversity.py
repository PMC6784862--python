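"""Windowed diversity statistics and linkage-disequilibrium decay.

Computes the classical summaries of segregating variation: the average
pairwise nucleotide diversity pi, Watterson's estimator theta_w
(S / (a1 L)), Tajima's D (with the standard 1989 variance constants),
the folded site-frequency spectrum, and binned r^2 decay with its
half-length (the distance at which mean r^2 falls to half its maximum).

By default diploid genotypes contribute two alleles each ("allele"
mode); the "consensus" mode collapses each isolate to one sequence
(heterozygous genotypes count as carrying the alternate allele), which
reproduces analyses run on one representative sequence per isolate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PopulationGenotypes

MISSINGNESS_MAX = 0.2


@dataclass
class WindowDiversity:
    chromosome: str
    start: int
    end: int
    n: int  # number of sequences
    S: int  # segregating sites
    pi: float  # per site
    theta_w: float  # per site
    tajimas_d: float  # NaN when S == 0


@dataclass
class SFS:
    histogram: np.ndarray  # counts of minor-allele counts 1..floor(n/2)
    singleton_fraction: float
    maf: np.ndarray  # per polymorphic site


def _allele_counts(
    genotypes: PopulationGenotypes, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, total called alleles) per site."""
    d = genotypes.dosage()
    biallelic = getattr(genotypes, "biallelic", None)
    if biallelic is not None:
        d = d[np.asarray(biallelic)]
    called = np.isfinite(d)
    if mode == "allele":
        alt = np.nansum(d, axis=1)
        tot = 2 * called.sum(axis=1)
    elif mode == "consensus":
        alt = np.nansum(d >= 1, axis=1).astype(float)
        tot = called.sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return alt, tot


def sfs(genotypes: PopulationGenotypes, mode: str = "allele") -> SFS:
    """Folded site-frequency spectrum over called alleles.

    A singleton is a site whose minor allele is observed exactly once.
    Invariant under swapping ref/alt labels at any site.
    """
    alt, tot = _allele_counts(genotypes, mode)
    minor = np.minimum(alt, tot - alt)
    poly = (minor > 0) & (tot > 0)
    minor = minor[poly].astype(int)
    maf = minor / tot[poly]
    n_max = int(tot.max()) // 2 if len(tot) else 0
    hist = np.bincount(minor, minlength=n_max + 1)[1:]
    frac = float((minor == 1).mean()) if minor.size else 0.0
    return SFS(histogram=hist, singleton_fraction=frac, maf=maf)


def nucleotide_diversity(alt: np.ndarray, tot: np.ndarray, length: int) -> float:
    """pi per site: mean pairwise difference over all allele pairs.

    For each site with x alt alleles of n called, the pairwise
    difference fraction is x (n - x) / C(n, 2); summed over sites and
    divided by the window length.
    """
    if length <= 0:
        raise ValueError("window length must be positive")
    n = tot
    ok = n >= 2
    x = alt[ok]
    n = n[ok]
    per_site = x * (n - x) / (n * (n - 1) / 2)
    return float(per_site.sum() / length)


def watterson_theta(S: int, n: int, length: int) -> float:
    """theta_w per site = S / (a1 L), a1 = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("need at least two sequences")
    if length <= 0:
        raise ValueError("window length must be positive")
    a1 = np.sum(1.0 / np.arange(1, n))
    return float(S / (a1 * length))


def tajimas_d(pi_total: float, S: int, n: int) -> float:
    """Tajima's D with the standard variance constants.

    ``pi_total`` is the un-normalized (per-window, not per-site) mean
    pairwise difference count.  Returns NaN for S == 0.
    """
    if S == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # degenerate at n = 2, where the variance constants vanish
        return float("nan")
    return float((pi_total - S / a1) / np.sqrt(var))


def windowed_diversity(
    genotypes: PopulationGenotypes,
    window: int = 10_000,
    chromosome_lengths: dict[str, int] | None = None,
    mode: str = "allele",
) -> list[WindowDiversity]:
    """pi, theta_w and Tajima's D in non-overlapping windows.

    Sites with more than 20% missing genotypes are excluded.  The
    sample size n per window is the modal number of called alleles of
    its sites (windows differ only through missingness).  Terminal
    partial windows are reported with their true length.
    """
    alt, tot = _allele_counts(genotypes, mode)
    biallelic = getattr(genotypes, "biallelic", None)
    keep = np.ones(len(alt), dtype=bool)
    pos = genotypes.pos
    chrom_idx = genotypes.chrom_idx
    if biallelic is not None:
        mask = np.asarray(biallelic)
        pos = pos[mask]
        chrom_idx = chrom_idx[mask]
    full_n = tot.max(initial=0)
    keep &= tot >= (1 - MISSINGNESS_MAX) * full_n
    results = []
    for c, chrom in enumerate(genotypes.chromosomes):
        on_c = (chrom_idx == c) & keep
        if chromosome_lengths and chrom in chromosome_lengths:
            chrom_len = chromosome_lengths[chrom]
        elif on_c.any():
            chrom_len = int(pos[chrom_idx == c].max()) + 1
        else:
            continue
        for start in range(0, chrom_len, window):
            end = min(start + window, chrom_len)
            in_w = on_c & (pos >= start) & (pos < end)
            length = end - start
            if not in_w.any():
                results.append(
                    WindowDiversity(chrom, start, end, int(full_n), 0, 0.0, 0.0, float("nan"))
                )
                continue
            a, t = alt[in_w], tot[in_w]
            seg = (a > 0) & (a < t)
            S = int(seg.sum())
            n = int(np.bincount(t.astype(int)).argmax())
            pi = nucleotide_diversity(a, t, length)
            th = watterson_theta(S, n, length) if n >= 2 else 0.0
            D = tajimas_d(pi * length, S, n) if S > 0 and n >= 2 else float("nan")
            results.append(WindowDiversity(chrom, start, end, n, S, pi, th, D))
    return results


@dataclass
class LDBin:
    distance_lo: int
    distance_hi: int
    mean_r2: float
    pair_count: int

    @property
    def midpoint(self) -> float:
        return (self.distance_lo + self.distance_hi) / 2


@dataclass
class LDDecay:
    bins: list[LDBin]
    half_length: float  # NaN when undefined
    empty: bool = False


def ld_decay(
    genotypes: PopulationGenotypes,
    maf_min: float = 0.05,
    bin_width: int = 100,
    max_dist: int = 25_000,
) -> LDDecay:
    """Binned r^2 decay over intra-chromosomal site pairs.

    r^2 is the squared Pearson correlation of (mean-imputed) allele
    count vectors; pairs farther apart than ``max_dist`` are skipped
    and sites with minor-allele frequency below ``maf_min`` excluded.
    The half-length is the midpoint of the first bin whose mean r^2
    drops to half of the maximum bin mean.
    """
    d = genotypes.dosage()
    biallelic = getattr(genotypes, "biallelic", None)
    pos = genotypes.pos
    chrom_idx = genotypes.chrom_idx
    if biallelic is not None:
        mask = np.asarray(biallelic)
        d, pos, chrom_idx = d[mask], pos[mask], chrom_idx[mask]
    mean = np.nanmean(d, axis=1)
    inds = np.where(np.isnan(d), mean[:, None], d)
    p = mean / 2
    maf = np.minimum(p, 1 - p)
    keep = (maf > maf_min) & (np.nanstd(inds, axis=1) > 0)
    inds, pos, chrom_idx = inds[keep], pos[keep], chrom_idx[keep]

    n_bins = max_dist // bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    z = inds - inds.mean(axis=1, keepdims=True)
    norms = np.sqrt((z**2).sum(axis=1))
    for c in np.unique(chrom_idx):
        on_c = chrom_idx == c
        zp, pp, nn = z[on_c], pos[on_c], norms[on_c]
        order = np.argsort(pp)
        zp, pp, nn = zp[order], pp[order], nn[order]
        for i in range(len(pp) - 1):
            j_hi = np.searchsorted(pp, pp[i] + max_dist, side="right")
            if j_hi <= i + 1:
                continue
            dists = pp[i + 1 : j_hi] - pp[i]
            r = (zp[i + 1 : j_hi] @ zp[i]) / (nn[i + 1 : j_hi] * nn[i])
            bins = np.minimum(dists // bin_width, n_bins - 1).astype(int)
            np.add.at(sums, bins, r**2)
            np.add.at(counts, bins, 1)
    if counts.sum() == 0:
        return LDDecay(bins=[], half_length=float("nan"), empty=True)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = [
        LDBin(i * bin_width, (i + 1) * bin_width, float(means[i]), int(counts[i]))
        for i in range(n_bins)
        if counts[i] > 0
    ]
    peak = np.nanmax(means)
    half = float("nan")
    for b in bins:
        if b.mean_r2 <= peak / 2:
            half = b.midpoint
            break
    return LDDecay(bins=bins, half_length=half)
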