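"""File-format I/O: VCF, BED, population maps, Q matrices, manifests.

VCF reading goes through pysam; writing is plain VCFv4.2 text emitted
directly so that identical inputs yield byte-identical files (checksum
determinism is part of the simulator contract).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from arabpop.core import MISSING, GenotypeMatrix, QMatrix

_DIP_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_HAP_GT = {0: "0", 1: "1", MISSING: "."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as uncompressed VCFv4.2 with GT-only records."""
    lut = _DIP_GT if gm.ploidy == 2 else _HAP_GT
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=arabpop\n")
        seen = dict.fromkeys(gm.chrom)
        for c in seen:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        gt = gm.gt
        for j in range(gm.n_sites):
            calls = "\t".join(lut[int(g)] for g in gt[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | os.PathLike, ploidy: int | None = None) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a GenotypeMatrix.

    Ploidy is inferred from the first genotype call unless given explicitly.
    """
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    inferred = ploidy
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alt.append(rec.alts[0])
        row = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            alleles = rec.samples[s]["GT"]
            if inferred is None:
                inferred = len(alleles)
            if alleles is None or any(a is None for a in alleles):
                row[i] = MISSING
            else:
                row[i] = sum(alleles)
        rows.append(row)
    vf.close()
    if inferred is None:
        inferred = 2
    gt = (np.vstack(rows).T if rows
          else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples=samples, chrom=np.array(chrom, dtype=object),
                          pos=np.array(pos), ref=np.array(ref, dtype=object),
                          alt=np.array(alt, dtype=object), gt=gt, ploidy=inferred)


@dataclass
class BedInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    name: str | None = None


def read_bed(path: str | os.PathLike) -> list[BedInterval]:
    """Parse a BED3+ file; malformed lines are fatal with their line number."""
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates")
            if start < 0 or end < start:
                raise ValueError(f"malformed BED line {lineno}: bad interval [{start},{end})")
            out.append(BedInterval(parts[0], start, end,
                                   parts[3] if len(parts) > 3 else None))
    return out


def read_population_map(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def write_population_map(labels: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s, p in labels.items():
            fh.write(f"{s}\t{p}\n")


def read_qmatrix(path: str | os.PathLike) -> QMatrix:
    df = pd.read_csv(path, sep="\t")
    comps = [c for c in df.columns if c != "sample"]
    return QMatrix(samples=df["sample"].astype(str).tolist(), components=comps,
                   q=df[comps].to_numpy(float))


def write_qmatrix(qm: QMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(qm.q, columns=qm.components)
    df.insert(0, "sample", qm.samples)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Array-site manifest: chrom/pos TSV (with or without a header)."""
    with open(path) as fh:
        first = fh.readline()
    has_header = first.lower().startswith("chrom")
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None,
                     names=None if has_header else ["chrom", "pos"])
    df.columns = ["chrom", "pos"] + list(df.columns[2:])
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    return df[["chrom", "pos"]]


def write_manifest(chrom, pos, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\n")
        for c, p in zip(chrom, pos):
            fh.write(f"{c}\t{p}\n")
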