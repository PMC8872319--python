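import numpy as np
import pytest

from sweepkit.genotypes import GenotypeMatrix

BASES = np.array(["A", "C", "G", "T"], dtype=object)


def random_matrix(
    rng: np.random.Generator,
    n_samples: int = 6,
    n_variants: int = 15,
    chrom: str = "chr1",
    span: int = 100_000,
    missing_rate: float = 0.0,
    phased: bool = True,
) -> GenotypeMatrix:
    """Small random matrix for oracle comparisons."""
    pos = np.sort(rng.choice(span, size=n_variants, replace=False)) + 1
    alleles = rng.integers(0, 2, size=(n_samples, n_variants, 2)).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((n_samples, n_variants)) < missing_rate
        alleles[miss] = -1
    ref = rng.choice(4, size=n_variants)
    alt = (ref + 1) % 4
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n_samples)],
        chrom=np.full(n_variants, chrom, dtype=object),
        pos=pos,
        ref=BASES[ref],
        alt=BASES[alt],
        alleles=alleles,
        phased=phased,
        chrom_lengths={chrom: span},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def matrix_from_haplotypes(hap, pos, chrom="chr1", chrom_length=None, phased=True):
    """Build a matrix from an explicit (2S, V) haplotype array."""
    hap = np.asarray(hap, dtype=np.int8)
    n_hap, V = hap.shape
    assert n_hap % 2 == 0
    S = n_hap // 2
    pos = np.asarray(pos, dtype=np.int64)
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(S)],
        chrom=np.full(V, chrom, dtype=object),
        pos=pos,
        ref=np.full(V, "A", dtype=object),
        alt=np.full(V, "C", dtype=object),
        alleles=hap.reshape(S, 2, V).transpose(0, 2, 1).copy(),
        phased=phased,
        chrom_lengths={chrom: chrom_length or int(pos.max())},
    )
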