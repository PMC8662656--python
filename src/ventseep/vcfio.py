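"""Readers/writers for the text formats the pipeline touches.

VCF v4.2 with FORMAT ``GT:DP:GQ`` (via pysam), two-column population
maps, and TSV genotype matrices.  Coordinates are VCF convention:
1-based, inclusive.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .demography import MISSING, GenotypeMatrix
from .filtering import VariantRecord

_GT_CODES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | os.PathLike,
) -> None:
    """Write records as uncompressed VCF v4.2 with GT:DP:GQ."""
    header = pysam.VariantHeader()
    header.add_line('##source=ventseep')
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                         ("Description", "Genotype")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                         ("Description", "Read depth")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "GQ"), ("Number", "1"), ("Type", "Integer"),
                         ("Description", "Genotype quality")]
    )
    scaffolds: dict[str, int] = {}
    for r in records:
        scaffolds[r.scaffold] = max(scaffolds.get(r.scaffold, 0), r.pos + 1000)
    for name, length in scaffolds.items():
        header.contigs.add(name, length=length)
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(records, key=lambda r: (r.scaffold, r.pos)):
            rec = vf.new_record(
                contig=r.scaffold,
                start=r.pos - 1,            # pysam start is 0-based
                alleles=tuple([r.ref] + list(r.alt)),
            )
            for i, s in enumerate(samples):
                g = int(r.gt[i])
                rec.samples[s]["GT"] = _GT_CODES.get(g, (None, None))
                if r.dp is not None:
                    rec.samples[s]["DP"] = int(r.dp[i])
                if r.gq is not None:
                    rec.samples[s]["GQ"] = int(r.gq[i])
            vf.write(rec)


def read_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF into VariantRecords; returns (records, sample names).

    Genotypes become alt-allele counts; any genotype carrying an allele
    index above 1 (a non-biallelic call) is encoded missing, and sites
    without DP or GQ carry ``None`` there so the filter stage can refuse
    them with its documented error.
    """
    records = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            n = len(samples)
            gt = np.full(n, MISSING, dtype=np.int8)
            dp = np.zeros(n, dtype=np.int32)
            gq = np.zeros(n, dtype=np.int32)
            has_dp = has_gq = False
            for i, s in enumerate(samples):
                sm = rec.samples[s]
                alleles = sm.get("GT", (None,))
                if alleles is not None and None not in alleles:
                    if len(alleles) != 2:
                        raise ValueError(
                            f"non-diploid genotype at {rec.chrom}:{rec.pos}"
                        )
                    if max(alleles) <= 1:
                        gt[i] = sum(alleles)
                if "DP" in sm and sm["DP"] is not None:
                    dp[i] = int(sm["DP"])
                    has_dp = True
                if "GQ" in sm and sm["GQ"] is not None:
                    gq[i] = int(sm["GQ"])
                    has_gq = True
            records.append(
                VariantRecord(
                    scaffold=rec.chrom,
                    pos=rec.pos,            # pysam .pos is 1-based
                    ref=rec.ref,
                    alt=[a for a in (rec.alts or [])],
                    gt=gt,
                    dp=dp if has_dp else None,
                    gq=gq if has_gq else None,
                )
            )
    return records, samples


def matrix_to_records(gm: GenotypeMatrix) -> list[VariantRecord]:
    """Convert a genotype matrix to records (no DP/GQ decoration)."""
    out = []
    for j in range(gm.n_loci):
        out.append(
            VariantRecord(
                scaffold=str(gm.loci["scaffold"].iloc[j]),
                pos=int(gm.loci["pos"].iloc[j]),
                ref=str(gm.loci["ref"].iloc[j]) if "ref" in gm.loci else "A",
                alt=[str(gm.loci["alt"].iloc[j])] if "alt" in gm.loci else ["G"],
                gt=gm.genotypes[:, j].copy(),
            )
        )
    return out


def write_popmap(popmap: pd.DataFrame, path: str | os.PathLike) -> None:
    popmap[["sample_id", "group"]].to_csv(path, sep="\t", index=False, header=False)


def read_popmap(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"])
    return df


def write_genotype_tsv(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        gm.genotypes.T,
        index=pd.MultiIndex.from_frame(gm.loci[["scaffold", "pos"]]),
        columns=gm.individuals,
    )
    df.to_csv(path, sep="\t")


def matrix_from_vcf(
    vcf_path: str | os.PathLike, popmap_path: str | os.PathLike
) -> GenotypeMatrix:
    from .filtering import records_to_matrix

    records, samples = read_vcf(vcf_path)
    popmap = read_popmap(popmap_path)
    return records_to_matrix(records, samples, popmap)
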