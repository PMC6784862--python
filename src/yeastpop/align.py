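"""K-mer-seeded local alignment for synthetic sequences.

The pangenome pipeline consumes standard 12-column tabular alignment
records from any local aligner; this module provides a small built-in
aligner adequate for sequences without indels (exact or
substitution-diverged copies, which is what the simulator plants).
Seeds are exact k-mer matches grouped by diagonal; co-diagonal seeds
within a gap limit are chained into one block, the block ends are
extended while bases match, and identity is the Hamming identity over
the block span.

Records use 0-based half-open coordinates internally; use
:func:`records_to_blast6` for the 1-based inclusive BLAST convention.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BLAST6_COLUMNS

DEFAULT_K = 15


@dataclass
class AlignmentRecord:
    query: str
    subject: str
    identity: float  # percent
    length: int
    qstart: int  # 0-based half-open
    qend: int
    sstart: int
    send: int

    @property
    def matches(self) -> int:
        return int(round(self.identity / 100 * self.length))


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _kmer_index(seq: str, k: int, step: int = 1, max_hits: int = 50) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(0, len(seq) - k + 1, step):
        index[seq[i : i + k]].append(i)
    return {km: v for km, v in index.items() if len(v) <= max_hits}


def _chain_and_score(
    qa: np.ndarray,
    sa: np.ndarray,
    qname: str,
    sname: str,
    seeds_by_diag: dict[int, list[int]],
    k: int,
    max_gap: int,
    min_len: int,
) -> list[AlignmentRecord]:
    records = []
    for diag, qps in seeds_by_diag.items():
        qps = sorted(qps)
        chains: list[tuple[int, int]] = []
        cs, ce = qps[0], qps[0] + k
        for q in qps[1:]:
            if q <= ce + max_gap:
                ce = q + k
            else:
                chains.append((cs, ce))
                cs, ce = q, q + k
        chains.append((cs, ce))
        for qs, qe in chains:
            # extend while bases match exactly
            while qs > 0 and qs - diag > 0 and qa[qs - 1] == sa[qs - diag - 1]:
                qs -= 1
            while qe < len(qa) and qe - diag < len(sa) and qa[qe] == sa[qe - diag]:
                qe += 1
            length = qe - qs
            if length < min_len:
                continue
            matches = int((qa[qs:qe] == sa[qs - diag : qe - diag]).sum())
            records.append(
                AlignmentRecord(
                    query=qname,
                    subject=sname,
                    identity=100.0 * matches / length,
                    length=length,
                    qstart=qs,
                    qend=qe,
                    sstart=qs - diag,
                    send=qe - diag,
                )
            )
    # drop blocks fully contained in a longer one on a nearby diagonal
    records.sort(key=lambda r: -r.length)
    kept: list[AlignmentRecord] = []
    for r in records:
        if not any(o.qstart <= r.qstart and r.qend <= o.qend for o in kept):
            kept.append(r)
    return kept


class KmerAligner:
    """Aligns queries against a fixed set of subject sequences."""

    def __init__(
        self,
        subjects: dict[str, str],
        k: int = DEFAULT_K,
        max_gap: int = 200,
        min_len: int = 30,
    ):
        self.k = k
        self.max_gap = max_gap
        self.min_len = min_len
        self.subjects = subjects
        self._bytes = {name: _as_bytes(s) for name, s in subjects.items()}
        self._index = {name: _kmer_index(s, k) for name, s in subjects.items()}

    def align(self, query: str, qname: str = "query", seed_step: int = 1) -> list[AlignmentRecord]:
        qa = _as_bytes(query)
        out: list[AlignmentRecord] = []
        for sname, index in self._index.items():
            seeds: dict[int, list[int]] = defaultdict(list)
            for i in range(0, len(query) - self.k + 1, seed_step):
                for spos in index.get(query[i : i + self.k], ()):
                    seeds[i - spos].append(i)
            if seeds:
                out.extend(
                    _chain_and_score(
                        qa, self._bytes[sname], qname, sname, seeds,
                        self.k, self.max_gap, self.min_len,
                    )
                )
        return out


def best_pair_block(a: str, b: str, k: int = DEFAULT_K) -> AlignmentRecord | None:
    """Best local block between two sequences (query = a, subject = b)."""
    aligner = KmerAligner({"b": b}, k=k)
    recs = aligner.align(a, "a")
    if not recs:
        return None
    return max(recs, key=lambda r: r.matches)


def candidate_pairs(
    seqs: dict[str, str], k: int = DEFAULT_K, step: int = 4
) -> set[tuple[str, str]]:
    """Pairs of sequences sharing at least one sampled k-mer.

    A cheap prefilter: unrelated random sequences essentially never
    share a 15-mer, so only these candidates need full alignment.
    """
    index: dict[str, list[str]] = defaultdict(list)
    for name, seq in seqs.items():
        seen = set()
        for i in range(0, len(seq) - k + 1, step):
            km = seq[i : i + k]
            if km not in seen:
                index[km].append(name)
                seen.add(km)
    pairs: set[tuple[str, str]] = set()
    for names in index.values():
        if len(names) < 2:
            continue
        for i, x in enumerate(names):
            for y in names[i + 1 :]:
                pairs.add((x, y) if x < y else (y, x))
    return pairs


def records_to_blast6(records: list[AlignmentRecord]) -> pd.DataFrame:
    """Convert to the 12-column BLAST tabular layout (1-based inclusive)."""
    rows = []
    for r in records:
        mismatch = r.length - r.matches
        rows.append(
            (
                r.query, r.subject, round(r.identity, 2), r.length, mismatch, 0,
                r.qstart + 1, r.qend, r.sstart + 1, r.send, 0.0, 2.0 * r.matches,
            )
        )
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def blast6_to_records(df: pd.DataFrame) -> list[AlignmentRecord]:
    """Parse 12-column tabular records (1-based inclusive, possibly on
    the reverse strand) into internal 0-based half-open records."""
    out = []
    for row in df.itertuples(index=False):
        qs, qe = sorted((int(row.qstart), int(row.qend)))
        ss, se = sorted((int(row.sstart), int(row.send)))
        out.append(
            AlignmentRecord(
                query=str(row.qseqid),
                subject=str(row.sseqid),
                identity=float(row.pident),
                length=int(row.length),
                qstart=qs - 1,
                qend=qe,
                sstart=ss - 1,
                send=se,
            )
        )
    return out
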