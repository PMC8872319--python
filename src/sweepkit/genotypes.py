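"""Core genotype data model shared by all analysis stages.

A :class:`GenotypeMatrix` holds phased (or unphased) diploid genotypes for
``S`` samples at ``V`` biallelic SNPs as an ``(S, V, 2)`` array of allele
codes, ``0`` = REF, ``1`` = ALT, ``-1`` = missing.  Positions are 1-based
and strictly increasing within each chromosome; variants are stored grouped
by chromosome in chromosome order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Phased biallelic genotypes for S samples x V variants x 2 haplotypes."""

    samples: list[str]
    chrom: np.ndarray          # (V,) str
    pos: np.ndarray            # (V,) int64, 1-based
    ref: np.ndarray            # (V,) str, single base
    alt: np.ndarray            # (V,) str, single base
    alleles: np.ndarray        # (S, V, 2) int8 in {-1, 0, 1}
    phased: bool = True
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (S, V, 2)")
        if self.alleles.shape[0] != len(self.samples):
            raise ValueError("sample count mismatch")
        if self.alleles.shape[1] != len(self.pos):
            raise ValueError("variant count mismatch")
        bad = ~np.isin(self.alleles, (-1, 0, 1))
        if bad.any():
            raise ValueError("allele codes must be in {-1, 0, 1}")
        # missing genotypes must mask both haplotype entries
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("missing genotypes must mask both haplotypes")
        for _, sl in self.chromosome_slices():
            p = self.pos[sl]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_samples

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def chromosome_slices(self):
        """Yield ``(chrom, slice)`` pairs covering the variant axis."""
        if len(self.chrom) == 0:
            return
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                yield self.chrom[start], slice(start, i)
                start = i

    def chromosome_length(self, chrom: str) -> int:
        """Declared length if known, else the last SNP position."""
        if chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        mask = self.chrom == chrom
        if not mask.any():
            raise KeyError(chrom)
        return int(self.pos[mask].max())

    # ------------------------------------------------------------- derived views
    def missing_mask(self) -> np.ndarray:
        """(S, V) boolean mask of missing genotypes."""
        return self.alleles[:, :, 0] == MISSING

    def haplotypes(self) -> np.ndarray:
        """(2S, V) haplotype matrix; haplotypes of sample s are rows 2s, 2s+1."""
        S, V, _ = self.alleles.shape
        return self.alleles.transpose(0, 2, 1).reshape(2 * S, V)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (ref_count, alt_count) over non-missing alleles."""
        a = self.alleles
        alt = (a == 1).sum(axis=(0, 2))
        ref = (a == 0).sum(axis=(0, 2))
        return ref, alt

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-variant (hom_ref, het, hom_alt) counts over called genotypes."""
        a = self.alleles
        called = a[:, :, 0] != MISSING
        s = a.sum(axis=2)
        hom_ref = ((s == 0) & called).sum(axis=0)
        het = ((s == 1) & called).sum(axis=0)
        hom_alt = ((s == 2) & called).sum(axis=0)
        return hom_ref, het, hom_alt

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given variant indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            alleles=self.alleles[:, index, :],
            phased=self.phased,
            chrom_lengths=dict(self.chrom_lengths),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            alleles=self.alleles.copy(),
            phased=self.phased,
            chrom_lengths=dict(self.chrom_lengths),
        )


def window_index(pos: np.ndarray, window_size: int) -> np.ndarray:
    """Index of the non-overlapping window containing each 1-based position.

    Windows tile each chromosome from position 1: window ``w`` covers
    ``[w*window_size + 1, (w+1)*window_size]``.
    """
    return (np.asarray(pos, dtype=np.int64) - 1) // window_size


def window_bounds(n_windows: int, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based inclusive (start, end) arrays for the first ``n_windows`` windows."""
    idx = np.arange(n_windows, dtype=np.int64)
    return idx * window_size + 1, (idx + 1) * window_size
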