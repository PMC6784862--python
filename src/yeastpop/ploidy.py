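"""Ploidy, aneuploidy and segmental-duplication calling.

Ploidy of a natural isolate is assigned by combining three evidence
sources:

1. flow-cytometry DNA content (G1/G2 fluorescence peak positions,
   classified against fixed per-ploidy ranges),
2. sequencing coverage in 1-kb non-overlapping windows (the ratio of a
   chromosome's median window depth to the genome-wide median scales with
   chromosome copy number), and
3. the allele-balance ratio at heterozygous sites, whose modes sit at
   k/CN for a chromosome at copy number CN.

Chromosome copy numbers that differ from the baseline ploidy are reported
as aneuploidies; sub-chromosomal runs of windows at a deviating copy
number are reported as segmental duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

#: Closed (G1, G2) fluorescence ranges per ploidy, in FL2-A units.
#: The 5n G2 range is open-ended ("over 905"); FACS saturation is at 1000.
FACS_RANGES: dict[int, tuple[tuple[float, float], tuple[float, float]]] = {
    1: ((39.0, 181.0), (148.0, 255.0)),
    2: ((145.0, 265.0), (295.0, 500.0)),
    3: ((245.0, 355.0), (500.0, 700.0)),
    4: ((295.0, 500.0), (700.0, 905.0)),
    5: ((395.0, 605.0), (905.0, float("inf"))),
}

FACS_SATURATION = 1000.0

#: |ratio * ploidy - CN| above this marks a low-confidence copy-number call.
CN_SNAP_TOLERANCE = 0.25

#: Allele-balance residual tolerance around the k/CN modes.
AB_TOLERANCE = 0.12


@dataclass
class FacsReadout:
    """G1/G2 density-peak positions of a propidium-iodide FACS profile."""

    g1_value: float
    g2_value: float
    ambiguous: bool = False


@dataclass
class CoverageProfile:
    """Fixed-width window depths per chromosome plus the genome median.

    ``windows`` maps chromosome name to an array of mean depths for
    consecutive non-overlapping windows (0-based, half-open).  The
    terminal window of each chromosome may be shorter than
    ``window_size``; it is retained but excluded from all medians.
    """

    windows: dict[str, np.ndarray]
    window_size: int = 1000
    chromosome_lengths: dict[str, int] = field(default_factory=dict)
    genome_median: float = 0.0

    def full_width_depths(self, chrom: str) -> np.ndarray:
        """Depths of the full-width windows of ``chrom``."""
        d = np.asarray(self.windows[chrom], dtype=float)
        length = self.chromosome_lengths.get(chrom)
        if length is not None and length % self.window_size != 0 and len(d) > 1:
            return d[:-1]
        return d


@dataclass
class ChromosomeCall:
    chromosome: str
    coverage_ratio: float
    copy_number: int
    aneuploid: bool
    low_confidence: bool = False
    allele_balance_support: str = "no_data"  # consistent | inconsistent | no_data


@dataclass
class SegmentalDuplication:
    chromosome: str
    start: int  # 0-based, half-open, snapped to window bounds
    end: int
    copy_number: int


@dataclass
class PloidyCall:
    isolate: str
    ploidy: int | None  # None == ambiguous
    facs_evidence: bool = False
    coverage_evidence: bool = False
    allele_balance_evidence: bool = False
    conflict: bool = False


def classify_facs(readout: FacsReadout) -> int | None:
    """Classify a FACS readout into a ploidy label (1-5) or ``None``.

    A pure lookup against :data:`FACS_RANGES`: the readout must fall in
    both the G1 and the G2 range of exactly one ploidy; readouts matching
    zero or more than one ploidy are ambiguous (``None``).
    """
    if readout.g1_value <= 0 or readout.g2_value <= 0:
        raise ValueError("FACS G1/G2 values must be positive")
    matches = [
        p
        for p, ((g1lo, g1hi), (g2lo, g2hi)) in FACS_RANGES.items()
        if g1lo <= readout.g1_value <= g1hi and g2lo <= readout.g2_value <= g2hi
    ]
    if len(matches) == 1:
        return matches[0]
    return None


def find_facs_peaks(events: pd.DataFrame, min_events: int = 100) -> FacsReadout:
    """Locate the two main density peaks (G1 and G2 populations).

    ``events`` has columns ``fl2a`` and ``fsch``.  Events saturating
    either channel (value equal to 1000) are removed first.  Peaks are
    the two highest modes of a Gaussian KDE (Silverman bandwidth) of the
    FL2-A values; with fewer than two separable modes the readout is
    flagged ambiguous.
    """
    ok = (events["fl2a"] < FACS_SATURATION) & (events["fsch"] < FACS_SATURATION)
    values = events.loc[ok, "fl2a"].to_numpy(dtype=float)
    if values.size < min_events:
        raise ValueError(
            f"only {values.size} unsaturated events (need >= {min_events})"
        )
    if np.ptp(values) == 0:
        return FacsReadout(float(values[0]), float(values[0]), ambiguous=True)
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    if len(interior) < 2:
        # fall back to boundary maxima before declaring ambiguity
        peaks = interior.tolist()
        for j in (0, len(grid) - 1):
            if (j == 0 and dens[0] > dens[1]) or (
                j == len(grid) - 1 and dens[-1] > dens[-2]
            ):
                peaks.append(j)
        interior = np.array(sorted(peaks), dtype=int)
    if len(interior) < 2:
        m = float(grid[int(np.argmax(dens))])
        return FacsReadout(m, m, ambiguous=True)
    # two dominant, well-separated modes; spurious shoulder bumps have
    # negligible density or sit next to the main peak
    order = interior[np.argsort(dens[interior])[::-1]]
    top = order[0]
    min_sep = 0.15 * (grid[-1] - grid[0])
    second = next(
        (j for j in order[1:] if abs(grid[j] - grid[top]) >= min_sep), None
    )
    if second is None or dens[second] < 0.2 * dens[top]:
        m = float(grid[top])
        return FacsReadout(m, m, ambiguous=True)
    g1, g2 = sorted((float(grid[top]), float(grid[second])))
    return FacsReadout(g1, g2)


def window_coverage(
    track: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    window_size: int = 1000,
) -> CoverageProfile:
    """Bin a depth track into non-overlapping windows.

    ``track`` is tabular with columns ``chrom``, ``pos`` (0-based) and
    ``depth``; per-base and pre-binned tracks are both accepted (depths
    are averaged within each window).  The genome median is the median
    depth over all full-width windows.
    """
    if track.empty:
        raise ValueError("empty depth track")
    windows: dict[str, np.ndarray] = {}
    for chrom, length in chromosome_lengths.items():
        n_win = -(-length // window_size)  # ceil
        sub = track[track["chrom"] == chrom]
        sums = np.zeros(n_win)
        counts = np.zeros(n_win)
        if not sub.empty:
            idx = (sub["pos"].to_numpy() // window_size).astype(int)
            if idx.max() >= n_win:
                raise ValueError(f"track position beyond length of {chrom}")
            np.add.at(sums, idx, sub["depth"].to_numpy(dtype=float))
            np.add.at(counts, idx, 1)
        with np.errstate(invalid="ignore"):
            windows[chrom] = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    profile = CoverageProfile(
        windows=windows,
        window_size=window_size,
        chromosome_lengths=dict(chromosome_lengths),
    )
    full = np.concatenate(
        [profile.full_width_depths(c) for c in chromosome_lengths]
    )
    profile.genome_median = float(np.median(full))
    return profile


def call_chromosome_copy_numbers(
    profile: CoverageProfile,
    ploidy: int,
    snap_tolerance: float = CN_SNAP_TOLERANCE,
) -> list[ChromosomeCall]:
    """Call per-chromosome copy number from coverage ratios.

    ratio = median(window depths) / genome median;  CN = round(ratio * ploidy).
    Calls whose ratio deviates from the snapped integer by more than
    ``snap_tolerance`` (in copy units) are flagged low-confidence.
    Invariant under global depth rescaling.
    """
    if ploidy < 1:
        raise ValueError("baseline ploidy must be >= 1")
    if profile.genome_median <= 0:
        raise ValueError("genome median depth is zero; isolate not callable")
    calls = []
    for chrom in profile.windows:
        med = float(np.median(profile.full_width_depths(chrom)))
        ratio = med / profile.genome_median
        cn = max(int(round(ratio * ploidy)), 0)
        calls.append(
            ChromosomeCall(
                chromosome=chrom,
                coverage_ratio=ratio,
                copy_number=cn,
                aneuploid=cn != ploidy,
                low_confidence=abs(ratio * ploidy - cn) > snap_tolerance,
            )
        )
    return calls


def _ab_consistent(fracs: np.ndarray, cn: int, tolerance: float) -> bool:
    if cn < 2:
        return False
    modes = np.arange(1, cn) / cn
    resid = np.min(np.abs(fracs[:, None] - modes[None, :]), axis=1)
    return float(np.mean(resid <= tolerance)) >= 0.6


def validate_with_allele_balance(
    het_alt_fractions: dict[str, np.ndarray],
    calls: list[ChromosomeCall],
    min_het_sites: int = 20,
    tolerance: float = AB_TOLERANCE,
) -> list[ChromosomeCall]:
    """Score each copy-number call against heterozygous allele balance.

    A chromosome at copy number CN should show alt-allele fractions
    clustered at k/CN (k = 1..CN-1).  A call is ``consistent`` when at
    least 60% of its het sites sit within ``tolerance`` of the nearest
    mode, ``inconsistent`` otherwise, and ``no_data`` with fewer than
    ``min_het_sites`` heterozygous sites.
    """
    for call in calls:
        fracs = np.asarray(het_alt_fractions.get(call.chromosome, ()), dtype=float)
        if fracs.size < min_het_sites:
            call.allele_balance_support = "no_data"
        elif _ab_consistent(fracs, call.copy_number, tolerance):
            call.allele_balance_support = "consistent"
        else:
            call.allele_balance_support = "inconsistent"
    return calls


def detect_segmental_duplications(
    profile: CoverageProfile,
    calls: list[ChromosomeCall],
    ploidy: int,
    min_segment: int = 20_000,
    deviation: float = 0.4,
    smooth: int = 15,
) -> list[SegmentalDuplication]:
    """Find sub-chromosomal runs of windows at a deviating copy number.

    A window's copy estimate is depth / genome_median * ploidy.  The
    per-window estimates are smoothed with a running median of
    ``smooth`` windows (single-window depths are far too noisy at
    realistic overdispersion to threshold directly); maximal runs of
    consecutive windows deviating from the chromosome copy number by at
    least ``deviation`` copies in one direction and spanning at least
    ``min_segment`` bp are reported.  Boundaries are then refined on the
    unsmoothed signal: the interval is grown or trimmed window by window
    according to whether the raw copy estimate lies closer to the
    segment level than to the chromosome level, and snapped to window
    bounds.
    """
    if profile.genome_median <= 0:
        raise ValueError("genome median depth is zero")
    from scipy.ndimage import median_filter

    cn_by_chrom = {c.chromosome: c.copy_number for c in calls}
    min_windows = max(min_segment // profile.window_size, 1)
    found = []
    for chrom in profile.windows:
        cn = cn_by_chrom[chrom]
        copies = profile.full_width_depths(chrom) / profile.genome_median * ploidy
        if len(copies) < 2:
            continue
        smoothed = median_filter(copies, size=min(smooth, len(copies)), mode="nearest")
        dev = smoothed - cn
        state = np.where(dev >= deviation, 1, np.where(dev <= -deviation, -1, 0))
        boundaries = np.flatnonzero(np.diff(state)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(state)]])
        candidates: list[tuple[int, int, int]] = []
        for s, e in zip(starts, ends):
            if state[s] == 0 or e - s < 3:
                continue
            seg_cn = max(int(round(np.median(copies[s:e]))), 0)
            if seg_cn == cn:
                continue
            mid = (seg_cn + cn) / 2
            closer = (copies > mid) if seg_cn > cn else (copies < mid)
            s, e = int(s), int(e)
            # changepoint boundary fit: place each edge to maximize
            # segment-level windows inside and chromosome-level outside
            span = smooth + 10
            cum = np.concatenate([[0], np.cumsum(closer.astype(int))])
            lo, hi = max(s - span, 0), min(e + span, len(copies))
            right = np.arange(max(s + 1, e - span), hi + 1)
            e = int(right[np.argmax(2 * cum[right] - right)])
            left = np.arange(lo, min(e - 1, s + span) + 1)
            s = int(left[np.argmax(left - 2 * cum[left])])
            candidates.append((s, e, seg_cn))
        # merge candidate runs at the same level split by short noise dips
        candidates.sort()
        merged: list[list[int]] = []
        for s, e, seg_cn in candidates:
            if merged and seg_cn == merged[-1][2] and s - merged[-1][1] <= 10:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e, seg_cn])
        for s, e, seg_cn in merged:
            if e - s < min_windows:
                continue
            found.append(
                SegmentalDuplication(
                    chromosome=chrom,
                    start=int(s * profile.window_size),
                    end=int(e * profile.window_size),
                    copy_number=seg_cn,
                )
            )
    return found


def _ploidy_from_allele_balance(
    all_fracs: np.ndarray,
    candidates: tuple[int, ...] = (2, 3, 4, 5),
    tolerance: float = 0.08,
    min_sites: int = 50,
) -> int | None:
    """Smallest candidate ploidy whose k/CN modes explain the genome-wide
    het allele-balance distribution."""
    if all_fracs.size < min_sites:
        return None
    for p in candidates:
        if _ab_consistent(all_fracs, p, tolerance):
            return p
    return None


def assign_ploidy(
    isolate: str,
    facs_label: int | None,
    het_alt_fractions: np.ndarray | None = None,
) -> PloidyCall:
    """Combine FACS and allele-balance evidence into one ploidy call.

    An unambiguous FACS label wins unless the genome-wide allele-balance
    modes are inconsistent with it while supporting a different ploidy,
    in which case the call is ambiguous with both evidence flags set.
    Without FACS the allele-balance consensus is used alone.
    """
    fracs = (
        np.asarray(het_alt_fractions, dtype=float)
        if het_alt_fractions is not None
        else np.empty(0)
    )
    ab_ploidy = _ploidy_from_allele_balance(fracs)
    if facs_label is None and ab_ploidy is None:
        if fracs.size == 0 and het_alt_fractions is None:
            raise ValueError("no evidence source provided")
        return PloidyCall(isolate, None)
    if facs_label is not None:
        if ab_ploidy is None:
            return PloidyCall(isolate, facs_label, facs_evidence=True)
        facs_ok = fracs.size == 0 or facs_label == 1 or _ab_consistent(
            fracs, facs_label, AB_TOLERANCE
        )
        if facs_ok:
            return PloidyCall(
                isolate,
                facs_label,
                facs_evidence=True,
                allele_balance_evidence=ab_ploidy == facs_label,
            )
        return PloidyCall(
            isolate,
            None,
            facs_evidence=True,
            allele_balance_evidence=True,
            conflict=True,
        )
    return PloidyCall(isolate, ab_ploidy, allele_balance_evidence=True)
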