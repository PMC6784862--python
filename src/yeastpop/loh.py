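"""Loss-of-heterozygosity segmentation and heterozygosity accounting.

An LOH segment is a region longer than 50 kb in which heterozygous
sites are depleted below 10 per 50 kb.  In the default (strict) mode
the density rule is enforced on every 50-kb sub-window slid at 1-kb
steps; the looser variant requires only the segment-wide average to
pass.  Segment boundaries are refined to the midpoint between the het
sites bounding the qualifying region (clipped to chromosome ends).

The module also computes LOH-masked heterozygosity levels and the
half-weighted SNP distance matrix in which a heterozygous difference
counts half of a homozygous one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PopulationGenotypes

WINDOW = 50_000
MAX_HET = 10  # a window with >= MAX_HET het sites disqualifies
STEP = 1_000


@dataclass
class LOHSegment:
    chromosome: str
    start: int  # 0-based half-open
    end: int
    het_count: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HeterozygosityStats:
    het_sites: int
    callable_length: int  # non-LOH bp
    het_per_kb: float
    undefined: bool = False


def _window_het_counts(het: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Het counts of 50-kb windows at 1-kb start steps (fully inside)."""
    starts = np.arange(0, max(length - WINDOW, 0) + 1, STEP)
    hi = np.searchsorted(het, starts + WINDOW, side="left")
    lo = np.searchsorted(het, starts, side="left")
    return starts, hi - lo


def window_passes(het: np.ndarray, start: int, end: int) -> bool:
    """Brute-force strict check: every 1-kb-stepped 50-kb sub-window of
    [start, end) holds fewer than MAX_HET het sites."""
    if end - start <= WINDOW:
        lo = np.searchsorted(het, start)
        hi = np.searchsorted(het, end)
        return hi - lo < MAX_HET
    for s in range(start, end - WINDOW + 1, STEP):
        lo = np.searchsorted(het, s)
        hi = np.searchsorted(het, s + WINDOW)
        if hi - lo >= MAX_HET:
            return False
    return True


def detect_loh(
    het_positions: dict[str, np.ndarray],
    chromosome_lengths: dict[str, int],
    strict: bool = True,
) -> list[LOHSegment]:
    """Detect LOH segments on each chromosome of one heterozygous isolate.

    ``het_positions`` maps chromosome to the sorted heterozygous site
    positions (0-based).  Returns segments longer than 50 kb satisfying
    the density rule, non-overlapping and sorted.
    """
    segments: list[LOHSegment] = []
    for chrom, het in het_positions.items():
        if chrom not in chromosome_lengths:
            raise ValueError(f"unknown chromosome length for {chrom}")
        length = chromosome_lengths[chrom]
        het = np.asarray(het)
        if het.size and (het.min() < 0 or het.max() >= length):
            raise ValueError(f"het position outside {chrom}")
        if length <= WINDOW:
            continue
        starts, counts = _window_het_counts(het, length)
        good = counts < MAX_HET
        if not good.any():
            continue
        # maximal runs of good windows
        edges = np.flatnonzero(np.diff(good.astype(int)))
        run_starts = np.concatenate([[0], edges + 1])
        run_ends = np.concatenate([edges + 1, [len(good)]])
        bounds: list[tuple[int, int]] = []
        for rs, re in zip(run_starts, run_ends):
            if not good[rs]:
                continue
            raw_start = int(starts[rs])
            raw_end = int(min(starts[re - 1] + WINDOW, length))
            seg = _refine_boundaries(het, raw_start, raw_end, length)
            if seg is None:
                continue
            start, end = seg
            if strict and not window_passes(het, start, end):
                start, end = raw_start, raw_end  # fall back to grid bounds
            bounds.append((start, end))
        # maximal qualifying runs may overlap through a shared sparse
        # stretch; trim the latter at the former's end
        bounds.sort()
        trimmed: list[tuple[int, int]] = []
        for start, end in bounds:
            if trimmed and start < trimmed[-1][1]:
                start = trimmed[-1][1]
            if end > start:
                trimmed.append((start, end))
        if not strict:
            trimmed = _merge_by_average(het, trimmed)
        for start, end in trimmed:
            if end - start > WINDOW:
                n_inside = int(np.searchsorted(het, end) - np.searchsorted(het, start))
                segments.append(LOHSegment(chrom, start, end, n_inside))
    segments.sort(key=lambda s: (s.chromosome, s.start))
    return segments


def _avg_ok(het: np.ndarray, start: int, end: int) -> bool:
    inside = np.searchsorted(het, end) - np.searchsorted(het, start)
    return inside / max(end - start, 1) * WINDOW < MAX_HET


def _merge_by_average(
    het: np.ndarray, bounds: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Loose mode: greedily merge neighbouring segments (gap included)
    while the merged segment-wide density stays below the 10/50-kb cap."""
    merged: list[tuple[int, int]] = []
    for start, end in bounds:
        if merged and _avg_ok(het, merged[-1][0], end):
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return [b for b in merged if _avg_ok(het, *b)]


def _refine_boundaries(
    het: np.ndarray, raw_start: int, raw_end: int, length: int
) -> tuple[int, int] | None:
    """Move each edge of a qualifying window run to the midpoint between
    that edge and the nearest flanking het site outside the run; without
    a flanking het the segment is clipped to the chromosome end."""
    left_flank = np.searchsorted(het, raw_start) - 1
    start = 0 if left_flank < 0 else (int(het[left_flank]) + raw_start) // 2 + 1
    right_flank = np.searchsorted(het, raw_end, side="left")
    end = length if right_flank >= len(het) else (int(het[right_flank]) + raw_end) // 2
    if end <= start:
        return None
    return max(start, 0), min(end, length)


def mask_loh(records: pd.DataFrame, segments: list[LOHSegment]) -> pd.DataFrame:
    """Remove het records inside LOH segments; other records untouched."""
    if not segments:
        return records.copy()
    drop = pd.Series(False, index=records.index)
    het = records["code"] == 1
    for seg in segments:
        drop |= (
            het
            & (records["chrom"] == seg.chromosome)
            & (records["pos"] >= seg.start)
            & (records["pos"] < seg.end)
        )
    return records[~drop]


def heterozygosity_level(
    masked_records: pd.DataFrame,
    genome_length: int,
    segments: list[LOHSegment],
) -> HeterozygosityStats:
    """Het sites per kb of the non-LOH (callable) genome."""
    loh_total = sum(s.length for s in segments)
    callable_length = genome_length - loh_total
    het_sites = int((masked_records["code"] == 1).sum())
    if callable_length <= 0:
        return HeterozygosityStats(het_sites, 0, float("nan"), undefined=True)
    return HeterozygosityStats(
        het_sites, callable_length, het_sites / (callable_length / 1000)
    )


def loh_fraction_and_count(
    segments: list[LOHSegment], genome_length: int
) -> tuple[float, int]:
    """(fraction of the genome under LOH, number of segments)."""
    return sum(s.length for s in segments) / genome_length, len(segments)


def snp_distance_matrix(
    genotypes: PopulationGenotypes, as_percent: bool = True
) -> pd.DataFrame:
    """Half-weighted pairwise SNP distances.

    Per pair, the mean over co-called biallelic sites of
    |dosage_a - dosage_b| / 2 (dosage 0/1/2), i.e. heterozygous
    differences count half of homozygous ones; reported as percentage
    of non-identical bases by default.  Pairs without co-called sites
    get NaN.
    """
    biallelic = getattr(genotypes, "biallelic", None)
    d = genotypes.dosage()
    if biallelic is not None:
        d = d[np.asarray(biallelic)]
    n = len(genotypes.isolates)
    out = np.zeros((n, n))
    called = np.isfinite(d)
    for a in range(n):
        for b in range(a + 1, n):
            co = called[:, a] & called[:, b]
            if not co.any():
                out[a, b] = out[b, a] = np.nan
                continue
            diff = np.abs(d[co, a] - d[co, b]) / 2
            out[a, b] = out[b, a] = diff.mean()
    if as_percent:
        out = out * 100
    return pd.DataFrame(out, index=genotypes.isolates, columns=genotypes.isolates)
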