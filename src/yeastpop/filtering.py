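"""Post-calling SNP/indel filters and the population genotype matrix.

The filter pipeline mirrors how a large isolate collection is cleaned
after per-sample variant calling:

1. depth: a site needs >= 50x in newly sequenced isolates (10x for
   previously sequenced external ones);
2. zygosity: an isolate with < 5% heterozygous calls among its variant
   sites is treated as homozygous and its residual het calls are
   removed as false positives;
3. allele balance (ABHet): in heterozygous isolates a het site must
   show an alt fraction near one of the k/CN modes implied by the copy
   number of its chromosome (or segmental-duplication region).

Records are DataFrames with columns chrom, pos, ref, alt, dp,
ref_depth, alt_depth and code (0 hom-ref / 1 het / 2 hom-alt /
-1 missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PopulationGenotypes


@dataclass
class FilterConfig:
    min_depth_primary: int = 50
    min_depth_external: int = 10
    het_fraction_threshold: float = 0.05
    abhet_tolerance: float = 0.12

    def validate(self) -> None:
        if min(self.min_depth_primary, self.min_depth_external) <= 0:
            raise ValueError("depth thresholds must be positive")
        if not 0 < self.het_fraction_threshold < 1:
            raise ValueError("het_fraction_threshold must be in (0, 1)")
        if self.abhet_tolerance <= 0:
            raise ValueError("abhet_tolerance must be positive")


def filter_by_depth(
    records: pd.DataFrame,
    is_external: bool = False,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Keep records at or above the depth floor (inclusive boundary).

    Records without a depth value are dropped; the count of such drops
    is stored in ``.attrs['missing_dp']``.
    """
    config = config or FilterConfig()
    floor = config.min_depth_external if is_external else config.min_depth_primary
    dp = pd.to_numeric(records["dp"], errors="coerce")
    out = records[dp >= floor].copy()
    out.attrs["missing_dp"] = int(dp.isna().sum())
    return out


def classify_zygosity(
    records: pd.DataFrame,
    threshold: float = 0.05,
) -> tuple[str, pd.DataFrame]:
    """Classify an isolate and clean its het calls if homozygous.

    The isolate is ``heterozygous`` iff its het fraction among called
    variant sites is at least ``threshold``; otherwise it is
    ``homozygous`` and every het call is removed as a false positive.
    An isolate with zero called sites is homozygous (degenerate case).
    """
    called = records[records["code"] > 0]
    if len(called) == 0:
        return "homozygous", records.copy()
    het_fraction = float((called["code"] == 1).mean())
    if het_fraction < threshold:
        return "homozygous", records[records["code"] != 1].copy()
    return "heterozygous", records.copy()


def abhet_filter(
    records: pd.DataFrame,
    copy_numbers: dict[str, int],
    tolerance: float = 0.12,
    region_cn: list[tuple[str, int, int, int]] | None = None,
) -> pd.DataFrame:
    """Drop het records whose allele balance contradicts the local CN.

    A het record survives iff min_k |alt_fraction - k/CN| <= tolerance
    for k in 1..CN-1, where CN comes from the chromosome call or, inside
    a segmental duplication interval from ``region_cn``
    (chrom, start, end, cn), from that region.  Records on chromosomes
    with no known CN pass through with ``abhet_unscored=True``.
    Non-het records are untouched.
    """
    out = records.copy()
    out["abhet_unscored"] = False
    het = out["code"] == 1
    if not het.any():
        return out
    cn = out["chrom"].map(copy_numbers)
    if region_cn:
        for chrom, start, end, rcn in region_cn:
            inside = (out["chrom"] == chrom) & (out["pos"] >= start) & (out["pos"] < end)
            cn[inside] = rcn
    unscored = het & cn.isna()
    out.loc[unscored, "abhet_unscored"] = True
    scored = het & cn.notna()
    if not scored.any():
        return out
    total = out.loc[scored, "ref_depth"] + out.loc[scored, "alt_depth"]
    frac = out.loc[scored, "alt_depth"] / total.replace(0, np.nan)
    cns = cn[scored].astype(int)
    ok = np.zeros(scored.sum(), dtype=bool)
    for i, (f, c) in enumerate(zip(frac, cns)):
        if not np.isfinite(f) or c < 2:
            continue
        ks = np.arange(1, c) / c
        ok[i] = np.min(np.abs(f - ks)) <= tolerance
    keep = pd.Series(True, index=out.index)
    keep.loc[scored] = ok
    return out[keep]


def annotate_frameshift(indel_lengths_by_gene: dict[str, list[int]]) -> dict[str, bool]:
    """Flag genes whose summed signed indel lengths are not a multiple of 3.

    Insertions are positive, deletions negative; a gene frameshifts when
    the net length change modulo 3 is non-zero.
    """
    return {g: sum(ls) % 3 != 0 for g, ls in indel_lengths_by_gene.items()}


def build_matrix(
    records_by_isolate: dict[str, pd.DataFrame],
    chromosomes: list[str] | None = None,
) -> PopulationGenotypes:
    """Assemble filtered per-isolate records into a population matrix.

    Sites are the union over isolates; an isolate with no record at a
    site is hom-ref (joint-calling convention).  A position with
    conflicting REF alleles across isolates is rejected.  Sites with
    more than one ALT allele across isolates are kept but flagged
    non-biallelic (``.biallelic``); per-site MAF over called alleles is
    exposed via :meth:`PopulationGenotypes.dosage`-based helpers.
    """
    isolates = list(records_by_isolate)
    frames = []
    for iso, df in records_by_isolate.items():
        sub = df[df["code"] > 0][["chrom", "pos", "ref", "alt", "code"]].copy()
        sub["isolate"] = iso
        frames.append(sub)
    allrec = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "code", "isolate"]
    )
    refs = allrec.groupby(["chrom", "pos"])["ref"].nunique()
    conflicts = refs[refs > 1]
    if len(conflicts):
        sites = ", ".join(f"{c}:{p}" for c, p in conflicts.index[:10])
        raise ValueError(f"conflicting REF alleles at: {sites}")

    if chromosomes is None:
        chromosomes = sorted(allrec["chrom"].unique())
    chrom_to_idx = {c: i for i, c in enumerate(chromosomes)}
    sites = (
        allrec[["chrom", "pos", "ref"]]
        .drop_duplicates(["chrom", "pos"])
        .assign(ci=lambda d: d["chrom"].map(chrom_to_idx))
        .sort_values(["ci", "pos"])
        .reset_index(drop=True)
    )
    site_index = {
        (c, p): i for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))
    }
    n_alts = allrec.groupby(["chrom", "pos"])["alt"].nunique()
    alt_of = allrec.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])["alt"]

    codes = np.zeros((len(sites), len(isolates)), dtype=np.int8)
    for j, iso in enumerate(isolates):
        df = records_by_isolate[iso]
        for _, row in df.iterrows():
            idx = site_index.get((row["chrom"], row["pos"]))
            if idx is not None:
                codes[idx, j] = row["code"]
    geno = PopulationGenotypes(
        chrom_idx=sites["ci"].to_numpy(dtype=np.int32),
        pos=sites["pos"].to_numpy(dtype=np.int64),
        ref=sites["ref"].to_numpy(),
        alt=np.array(
            [alt_of.loc[(c, p)] for c, p in zip(sites["chrom"], sites["pos"])]
        ),
        codes=codes,
        isolates=isolates,
        chromosomes=chromosomes,
    )
    geno.biallelic = np.array(
        [n_alts.loc[(c, p)] == 1 for c, p in zip(sites["chrom"], sites["pos"])]
    )
    return geno


def site_maf(genotypes: PopulationGenotypes) -> np.ndarray:
    """Minor-allele frequency per site over called alleles."""
    d = genotypes.dosage()
    called = np.isfinite(d)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=1) / (2 * called.sum(axis=1))
    return np.minimum(p, 1 - p)


def singleton_fraction(genotypes: PopulationGenotypes) -> float:
    """Fraction of polymorphic sites whose minor allele appears once."""
    d = genotypes.dosage()
    alt = np.nansum(d, axis=1)
    total = 2 * np.isfinite(d).sum(axis=1)
    minor = np.minimum(alt, total - alt)
    poly = minor > 0
    if not poly.any():
        return 0.0
    return float((minor[poly] == 1).mean())
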