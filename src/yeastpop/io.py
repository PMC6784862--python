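"""File I/O: VCF 4.2 (pysam), FASTA (Biopython), BED and tabular formats.

Coordinates are 0-based half-open everywhere in memory; VCF positions
are converted to/from 1-based on the way through pysam.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import PopulationGenotypes, TruthSet

_CODE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}


def write_population_vcf(
    path: str | Path,
    genotypes: "PopulationGenotypes",
    truth: "TruthSet",
    allele_depths: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write a multi-sample VCF with GT, DP and AD per sample."""
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, length in zip(truth.chromosomes, truth.chromosome_lengths):
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allele depths")
    for iso in genotypes.isolates:
        header.add_sample(iso)

    depth_lookup: dict[str, dict[tuple[str, int], tuple[int, int, int]]] = {}
    if allele_depths:
        for iso, df in allele_depths.items():
            depth_lookup[iso] = {
                (c, int(p)): (int(d), int(r), int(a))
                for c, p, d, r, a in zip(
                    df["chrom"], df["pos"], df["dp"], df["ref_depth"], df["alt_depth"]
                )
            }
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in range(genotypes.n_sites):
            chrom = genotypes.chromosomes[genotypes.chrom_idx[s]]
            rec = vcf.new_record(
                contig=chrom,
                start=int(genotypes.pos[s]),
                alleles=(str(genotypes.ref[s]), str(genotypes.alt[s])),
            )
            for j, iso in enumerate(genotypes.isolates):
                code = int(genotypes.codes[s, j])
                rec.samples[iso]["GT"] = _CODE_TO_GT[code]
                hit = depth_lookup.get(iso, {}).get((chrom, int(genotypes.pos[s])))
                if hit is not None:
                    dp, rd, ad = hit
                    rec.samples[iso]["DP"] = dp
                    rec.samples[iso]["AD"] = (rd, ad)
            vcf.write(rec)


def read_population_vcf(path: str | Path) -> "PopulationGenotypes":
    """Read a multi-sample VCF back into a genotype-class matrix."""
    from .simulate import PopulationGenotypes

    with pysam.VariantFile(str(path)) as vcf:
        isolates = list(vcf.header.samples)
        chromosomes = list(vcf.header.contigs)
        chrom_to_idx = {c: i for i, c in enumerate(chromosomes)}
        chrom_idx, pos, ref, alt, codes = [], [], [], [], []
        for rec in vcf:
            chrom_idx.append(chrom_to_idx[rec.chrom])
            pos.append(rec.start)
            ref.append(rec.ref)
            alt.append(rec.alts[0] if rec.alts else ".")
            row = []
            for iso in isolates:
                gt = rec.samples[iso]["GT"]
                if gt is None or gt[0] is None:
                    row.append(-1)
                else:
                    row.append(int(sum(gt) > 0) + int(all(a and a > 0 for a in gt)))
            codes.append(row)
    return PopulationGenotypes(
        chrom_idx=np.array(chrom_idx, dtype=np.int32),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref),
        alt=np.array(alt),
        codes=np.array(codes, dtype=np.int8),
        isolates=isolates,
        chromosomes=chromosomes,
    )


def read_vcf_records(path: str | Path, sample: str) -> pd.DataFrame:
    """Per-sample variant records (chrom, pos, ref, alt, dp, ad, class)."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            s = rec.samples[sample]
            gt = s.get("GT")
            if gt is None or gt[0] is None:
                code = -1
            else:
                code = int(sum(a > 0 for a in gt if a is not None) > 0) + int(
                    all(a and a > 0 for a in gt)
                )
            ad = s.get("AD") or (None, None)
            rows.append(
                (
                    rec.chrom,
                    rec.start,
                    rec.ref,
                    rec.alts[0] if rec.alts else ".",
                    s.get("DP"),
                    ad[0],
                    ad[1] if len(ad) > 1 else None,
                    code,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "dp", "ref_depth", "alt_depth", "code"],
    )


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    """BED (0-based half-open): needs chrom/start/end columns; extras kept."""
    cols = ["chrom", "start", "end"] + [
        c for c in intervals.columns if c not in ("chrom", "start", "end")
    ]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Parse 12-column BLAST tabular output (outfmt 6 column order)."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")


def write_blast_tabular(path: str | Path, records: pd.DataFrame) -> None:
    records[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
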