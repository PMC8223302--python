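"""Genotype matrix container with VCF / HapMap text round trips.

SNPs are biallelic and additively coded 0/1/2 (count of the alternate
allele).  Coordinates are 1-based and positions are kept strictly
increasing within each chromosome, the convention shared by VCF, HapMap
and GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive genotype matrix.

    Attributes
    ----------
    matrix : (n_individuals, n_snps) int8 array with entries in {0,1,2}
        (-1 marks missing).
    snp_ids, chrom, pos : per-SNP identifier, chromosome label and
        1-based position.
    accessions : per-individual accession ids.
    """

    matrix: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    accessions: np.ndarray
    ref: np.ndarray = field(default=None)
    alt: np.ndarray = field(default=None)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.accessions = np.asarray(self.accessions)
        if self.ref is None:
            self.ref = np.full(self.n_snps, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_snps, "T", dtype=object)
        if self.matrix.shape != (len(self.accessions), len(self.snp_ids)):
            raise ValueError("matrix shape does not match accession/SNP ids")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Sample minor-allele frequency per SNP (missing entries ignored)."""
        m = np.ma.masked_equal(self.matrix, -1)
        p = m.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.matrix[:, idx], self.snp_ids[idx], self.chrom[idx],
            self.pos[idx], self.accessions, self.ref[idx], self.alt[idx],
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(snp_id)
        return int(hits[0])

    def column(self, snp_id: str) -> np.ndarray:
        return self.matrix[:, self.snp_index(snp_id)].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.accessions, columns=self.snp_ids)


_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with GT fields only."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=itrait\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(gm.accessions.astype(str))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j in range(gm.n_snps):
            gts = "\t".join(_GT_CODES[int(g)] for g in gm.matrix[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.snp_ids[j]}\t{gm.ref[j]}\t"
                f"{gm.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accessions = np.asarray(vcf.samples)
    rows, ids, chrom, pos, ref, alt = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        g = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2 and 3=missing
        g[g == 3] = -1
        rows.append(g)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    matrix = np.stack(rows, axis=1) if rows else np.empty((len(accessions), 0), np.int8)
    return GenotypeMatrix(matrix, np.asarray(ids, object), np.asarray(chrom, object),
                          np.asarray(pos), accessions,
                          np.asarray(ref, object), np.asarray(alt, object))


_HMP_HEADER = ("rs#\talleles\tchrom\tpos\tstrand\tassembly#\tcenter\tprotLSID\t"
               "assayLSID\tpanelLSID\tQCcode")


def write_hapmap(gm: GenotypeMatrix, path) -> None:
    """Write HapMap-format text (diploid letter pairs, NN for missing)."""
    with open(path, "w") as fh:
        fh.write(_HMP_HEADER + "\t" + "\t".join(gm.accessions.astype(str)) + "\n")
        for j in range(gm.n_snps):
            r, a = str(gm.ref[j]), str(gm.alt[j])
            code = {0: r + r, 1: r + a, 2: a + a, -1: "NN"}
            gts = "\t".join(code[int(g)] for g in gm.matrix[:, j])
            fh.write(f"{gm.snp_ids[j]}\t{r}/{a}\t{gm.chrom[j]}\t{gm.pos[j]}\t"
                     f"+\tNA\tNA\tNA\tNA\tNA\tNA\t{gts}\n")


def read_hapmap(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    accessions = np.asarray(df.columns[11:])
    ids = df["rs#"].to_numpy(object)
    chrom = df["chrom"].to_numpy(object)
    pos = df["pos"].astype(np.int64).to_numpy()
    ref = df["alleles"].str.split("/").str[0].to_numpy(object)
    alt = df["alleles"].str.split("/").str[1].to_numpy(object)
    mat = np.empty((len(accessions), len(ids)), dtype=np.int8)
    for j in range(len(ids)):
        r, a = ref[j], alt[j]
        code = {r + r: 0, r + a: 1, a + r: 1, a + a: 2, "NN": -1}
        mat[:, j] = [code[g] for g in df.iloc[j, 11:]]
    return GenotypeMatrix(mat, ids, chrom, pos, accessions, ref, alt)
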