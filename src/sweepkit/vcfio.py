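"""VCF reading and writing for the genotype model (GT field only).

Reading is backed by cyvcf2; only biallelic SNP records are loaded, and
multiallelic or indel records are skipped with a counted warning.  Writing
emits minimal VCF 4.2 with phased (``0|1``) or unphased (``0/1``) GT values
and is byte-deterministic for a given matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class ReadReport:
    n_loaded: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_non_snp: int = 0


def read_vcf(path: str, return_report: bool = False):
    """Load a VCF into a :class:`GenotypeMatrix`.

    ``./.`` and ``.|.`` (and half-calls) are treated as missing; ``0/1``
    records are accepted but clear the matrix-wide phased flag.
    Multiallelic and non-SNP records are skipped and counted.
    """
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    report = ReadReport()
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    allele_rows: list[np.ndarray] = []
    phased = True
    chrom_lengths: dict[str, int] = {}
    try:
        chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header has no contig lengths
        pass
    for rec_no, var in enumerate(vcf, start=1):
        try:
            if len(var.ALT) != 1:
                report.n_skipped_multiallelic += 1
                continue
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                report.n_skipped_non_snp += 1
                continue
            gts = np.array(var.genotypes, dtype=object)  # rows: [a0, a1, phased]
            a = np.empty((len(samples), 2), dtype=np.int8)
            for s, g in enumerate(gts):
                a0, a1 = int(g[0]), int(g[1])
                if a0 < 0 or a1 < 0:
                    a[s] = MISSING
                else:
                    a[s, 0], a[s, 1] = a0, a1
                    if not g[2]:
                        phased = False
            chroms.append(var.CHROM)
            positions.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            allele_rows.append(a)
            report.n_loaded += 1
        except Exception as exc:
            raise ValueError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc
    if report.n_skipped_multiallelic or report.n_skipped_non_snp:
        log.info(
            "read_vcf: skipped %d multiallelic and %d non-SNP records",
            report.n_skipped_multiallelic,
            report.n_skipped_non_snp,
        )
    alleles = (
        np.stack(allele_rows, axis=1)
        if allele_rows
        else np.empty((len(samples), 0, 2), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        alleles=alleles,
        phased=phased,
        chrom_lengths={c: l for c, l in chrom_lengths.items() if c in set(chroms)},
    )
    return (gm, report) if return_report else gm


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write the matrix as minimal VCF 4.2 (GT only)."""
    sep = "|" if gm.phased else "/"
    miss = f".{sep}."
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in gm.chromosomes():
            fh.write(f"##contig=<ID={c},length={gm.chromosome_length(c)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        a = gm.alleles
        for j in range(gm.n_variants):
            gts = []
            for s in range(gm.n_samples):
                a0, a1 = a[s, j]
                gts.append(miss if a0 == MISSING else f"{a0}{sep}{a1}")
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
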