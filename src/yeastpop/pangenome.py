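"""Pangenome construction: non-reference extraction, ORF families,
copy-number and presence/absence matrices.

The pangenome of an isolate collection is the non-redundant union of
reference ORFs and the ORFs carried on non-reference material found in
de novo assemblies.  Non-reference sequence is recovered by a filtering
cascade over local alignments of each assembly against the reference;
redundant ORFs are collapsed into families via a similarity graph; and
per-ORF copy numbers (per haploid genome) are estimated as the ratio of
the ORF's median read coverage to the genome-wide median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .align import AlignmentRecord, KmerAligner, best_pair_block, candidate_pairs

IDENTITY_MIN = 95.0  # percent, "greater than 95%"
SEGMENT_LEN = 250
SEGMENT_MATCH_MIN = 187  # 75% of the segment length
MERGE_GAP = 100
PRESENCE_THRESHOLD = 0.2  # copies per haploid genome


@dataclass
class ORF:
    orf_id: str
    sequence: str
    source: str = "non-reference"  # "reference" | "non-reference"
    dubious: bool = False


@dataclass
class ORFCatalog:
    orfs: dict[str, ORF]
    families: dict[str, list[str]] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)

    @property
    def representative_ids(self) -> list[str]:
        return sorted(self.representatives.values())


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def extract_nonreference(
    contigs: dict[str, str],
    alignments: list[AlignmentRecord],
    realign: Callable[[str], list[AlignmentRecord]],
    deduplicate: bool = True,
) -> dict[str, str]:
    """Recover non-reference sequence from assembly contigs.

    ``alignments`` are contig-vs-reference records; only those with
    identity above 95% take part.  The cascade per contig:

    * a contig shorter than 100 bp with any aligned part, or one whose
      aligned block is at most 200 bp while the contig is shorter than
      the block plus 75 bp, is discarded whole;
    * aligned blocks of 200-1,500 bp are excised, keeping the flanks;
    * longer blocks are cut into 250-bp segments which are re-aligned
      individually (via ``realign``); a segment matching the reference
      at over 95% identity across at least 187 bp is excised, the rest
      is kept.

    Retained pieces of the same contig separated by fewer than 100 bp
    are merged keeping the spanning sequence.  Finally, retained
    sequences are deduplicated across the whole set: sorted by
    decreasing length, and any sequence aligning at over 95% identity
    to an already-kept longer one is dropped.

    Returns a mapping ``"<contig>|<start>-<end>" -> sequence``.
    """
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        if rec.query not in contigs:
            raise ValueError(f"alignment references unknown contig {rec.query!r}")
        if rec.identity > IDENTITY_MIN:
            by_contig.setdefault(rec.query, []).append(rec)

    pieces: dict[str, str] = {}
    for name, seq in contigs.items():
        blocks = by_contig.get(name, [])
        if not blocks:
            pieces[f"{name}|0-{len(seq)}"] = seq
            continue
        if len(seq) < 100:
            continue
        if any(
            r.qend - r.qstart <= 200 and len(seq) < (r.qend - r.qstart) + 75
            for r in blocks
        ):
            continue
        cut: list[tuple[int, int]] = []
        for r in blocks:
            blen = r.qend - r.qstart
            if 200 <= blen <= 1500:
                cut.append((r.qstart, r.qend))
            elif blen > 1500:
                for s in range(r.qstart, r.qend, SEGMENT_LEN):
                    e = min(s + SEGMENT_LEN, r.qend)
                    hits = realign(seq[s:e])
                    if any(
                        h.identity > IDENTITY_MIN and h.length >= SEGMENT_MATCH_MIN
                        for h in hits
                    ):
                        cut.append((s, e))
        cut = _merge_intervals(cut)
        kept: list[tuple[int, int]] = []
        prev = 0
        for s, e in cut + [(len(seq), len(seq))]:
            if s > prev:
                kept.append((prev, s))
            prev = max(prev, e)
        # merge retained pieces separated by small excised gaps
        merged: list[tuple[int, int]] = []
        for s, e in kept:
            if merged and s - merged[-1][1] < MERGE_GAP:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        for s, e in merged:
            if e > s:
                pieces[f"{name}|{s}-{e}"] = seq[s:e]

    if not deduplicate:
        return pieces
    order = sorted(pieces, key=lambda k: (-len(pieces[k]), k))
    shared = candidate_pairs(pieces)
    neighbours: dict[str, set[str]] = {}
    for a, b in shared:
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)
    kept_ids: list[str] = []
    kept_set: set[str] = set()
    for name in order:
        dup = False
        for other in neighbours.get(name, ()):
            if other not in kept_set:
                continue
            block = best_pair_block(pieces[name], pieces[other])
            if block is not None and block.identity > IDENTITY_MIN and block.length >= 100:
                dup = True
                break
        if not dup:
            kept_ids.append(name)
            kept_set.add(name)
    return {k: pieces[k] for k in kept_ids}


def collapse_orfs(
    orfs: dict[str, ORF],
    edges: list[tuple[str, str]] | None = None,
) -> ORFCatalog:
    """Collapse similar ORFs into families with one representative each.

    An edge joins two ORFs aligning at over 95% identity across at
    least 75% of the smaller sequence; connected components of the
    resulting graph are the families.  If ``edges`` is not given they
    are computed with the built-in aligner.  The representative is the
    most central (highest-degree) non-dubious reference ORF, then the
    most central reference ORF, then the most central non-reference
    ORF; ties break lexicographically by id.  Idempotent: collapsing
    the representatives again yields singleton families.
    """
    if edges is None:
        edges = similarity_edges({k: o.sequence for k, o in orfs.items()})
    g = nx.Graph()
    g.add_nodes_from(orfs)
    g.add_edges_from(e for e in edges if e[0] in orfs and e[1] in orfs)
    catalog = ORFCatalog(orfs=dict(orfs))
    for comp in nx.connected_components(g):
        members = sorted(comp)
        fam_id = f"fam_{members[0]}"
        catalog.families[fam_id] = members

        def rank(oid: str) -> tuple:
            o = orfs[oid]
            tier = (
                0 if (o.source == "reference" and not o.dubious)
                else 1 if o.source == "reference"
                else 2
            )
            return (tier, -g.degree[oid], oid)

        catalog.representatives[fam_id] = min(members, key=rank)
    return catalog


def similarity_edges(
    seqs: dict[str, str],
    identity_min: float = IDENTITY_MIN,
    coverage_min: float = 0.75,
) -> list[tuple[str, str]]:
    """Pairs aligning at > ``identity_min`` % over >= ``coverage_min``
    of the smaller sequence (single best block per pair)."""
    out = []
    for a, b in sorted(candidate_pairs(seqs)):
        small = min(len(seqs[a]), len(seqs[b]))
        query, subject = (a, b) if len(seqs[a]) <= len(seqs[b]) else (b, a)
        block = best_pair_block(seqs[query], seqs[subject])
        if (
            block is not None
            and block.identity > identity_min
            and block.length >= coverage_min * small
        ):
            out.append((a, b))
    return out


def orf_copy_number(
    orf_coverage: pd.DataFrame,
    chromosome_coverage: pd.DataFrame,
) -> pd.DataFrame:
    """Copy number per haploid genome for every isolate x ORF.

    ``orf_coverage`` holds the median read depth of each ORF per
    isolate (rows) and ``chromosome_coverage`` the median depth of each
    nuclear chromosome; the copy number is the ORF depth divided by the
    median of the per-chromosome medians.  Non-integer values arise
    naturally (e.g. 0.5 for a hemizygous ORF in a diploid).  Isolates
    with zero genome coverage are dropped and listed in
    ``.attrs['excluded']``.  Invariant under global depth rescaling.
    """
    genome = chromosome_coverage.median(axis=1)
    bad = genome[genome <= 0].index.tolist()
    ok = genome.index.difference(bad)
    cnv = orf_coverage.loc[ok].div(genome.loc[ok], axis=0)
    cnv.attrs["excluded"] = bad
    return cnv


def presence_absence(
    cnv: pd.DataFrame, threshold: float = PRESENCE_THRESHOLD
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Presence calls plus the core/variable partition.

    An ORF is present in an isolate when its copy number reaches
    ``threshold``; core ORFs are present in every isolate, the rest are
    variable.  core + variable = all ORFs.
    """
    presence = (cnv >= threshold).astype(int)
    core = [c for c in presence.columns if presence[c].all()]
    variable = [c for c in presence.columns if c not in set(core)]
    return presence, core, variable


def orf_content_distance(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise count of ORFs present in exactly one of the two isolates."""
    x = presence.to_numpy(dtype=float)
    ones = x @ (1 - x).T
    d = ones + ones.T
    return pd.DataFrame(
        d.astype(int), index=presence.index, columns=presence.index
    )


@dataclass
class CladeContrast:
    clade_medians: pd.DataFrame  # clades x ORFs
    statistic: float
    p_value: float


def clade_cnv_contrast(
    cnv: pd.DataFrame,
    clade_of_isolate: pd.Series,
    group_of_clade: dict,
) -> CladeContrast:
    """Compare ORF copy numbers between two clade groups.

    To avoid sample-size bias the copy number of each ORF is first
    summarized as its median within each clade; the distributions of
    clade medians in the two groups are then compared with a two-sided
    rank-sum (Mann-Whitney) test.
    """
    groups = sorted(set(group_of_clade.values()))
    if len(groups) != 2:
        raise ValueError("exactly two clade groups required")
    clade_medians = cnv.groupby(clade_of_isolate).median()
    missing = [g for g in groups if not any(
        group_of_clade[c] == g for c in clade_medians.index
    )]
    if missing:
        raise ValueError(f"group(s) without clades: {missing}")
    pooled = {
        g: clade_medians.loc[
            [c for c in clade_medians.index if group_of_clade[c] == g]
        ].to_numpy().ravel()
        for g in groups
    }
    a, b = pooled[groups[0]], pooled[groups[1]]
    if np.array_equal(np.sort(a), np.sort(b)):
        return CladeContrast(clade_medians, float("nan"), 1.0)
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return CladeContrast(clade_medians, float(stat), float(p))
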