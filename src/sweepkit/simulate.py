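"""Synthetic phased genotype data with known ground truth.

Two neutral generation modes are provided:

* *mosaic*: a small pool of founder haplotypes carries independent sites
  whose derived-allele count follows the neutral site-frequency spectrum
  (P(k) proportional to 1/k); each sample haplotype is a mosaic copy of the
  founders with template switches at a per-bp rate, which produces
  distance-dependent linkage disequilibrium.
* *independent sites*: every site is drawn independently with derived count
  among the 2S sample haplotypes proportional to 1/k; useful for
  calibrating frequency-spectrum statistics (Tajima's D) where LD is a
  nuisance.

Hard selective sweeps and autozygous (ROH) tracts are injected by haplotype
copying, and missingness/genotype errors can be layered on top.  All
randomness flows from explicit seeds; identical seeds give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

_BASES = np.array(["A", "C", "G", "T"], dtype=object)


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int
    chrom_length: int
    target_snp_count: int
    n_chromosomes: int = 1
    founder_haplotypes: int = 20
    switch_rate: float = 1e-5
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.founder_haplotypes < 2:
            raise ValueError("founder_haplotypes must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.genotype_error_rate < 1:
            raise ValueError("genotype_error_rate must be in [0, 1)")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.target_snp_count > self.chrom_length:
            raise ValueError(
                f"target_snp_count ({self.target_snp_count}) exceeds the "
                f"{self.chrom_length} distinct positions available"
            )


@dataclass(frozen=True)
class SweepTruth:
    chrom: str
    start: int
    end: int
    carrier_fraction: float


@dataclass(frozen=True)
class RohTruth:
    sample: str
    chrom: str
    start: int
    end: int


def _sfs_counts(rng: np.random.Generator, n_alleles: int, n_sites: int) -> np.ndarray:
    """Derived-allele counts k in 1..n_alleles-1 with P(k) proportional to 1/k."""
    k = np.arange(1, n_alleles)
    w = 1.0 / k
    return rng.choice(k, size=n_sites, p=w / w.sum())


def _sample_positions(rng: np.random.Generator, chrom_length: int, n: int) -> np.ndarray:
    pos = rng.choice(chrom_length, size=n, replace=False) + 1
    pos.sort()
    return pos.astype(np.int64)


def simulate_neutral(config: SimulationConfig, mode: str = "mosaic") -> GenotypeMatrix:
    """Generate a phased neutral dataset with no missing genotypes.

    Parameters
    ----------
    config
        Simulation parameters; determinism is guaranteed per seed.
    mode
        ``"mosaic"`` (founder-copying, realistic LD) or
        ``"independent"`` (every site independent, no LD).
    """
    if mode not in ("mosaic", "independent"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    S = config.n_samples
    n_hap = 2 * S
    chroms, positions, hap_blocks = [], [], []
    refs, alts = [], []
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        V = config.target_snp_count
        pos = _sample_positions(rng, config.chrom_length, V)
        if mode == "independent":
            hap = np.zeros((n_hap, V), dtype=np.int8)
            counts = _sfs_counts(rng, n_hap, V)
            for j in range(V):
                carriers = rng.choice(n_hap, size=counts[j], replace=False)
                hap[carriers, j] = 1
        else:
            K = config.founder_haplotypes
            founders = np.zeros((K, V), dtype=np.int8)
            counts = _sfs_counts(rng, K, V)
            for j in range(V):
                carriers = rng.choice(K, size=counts[j], replace=False)
                founders[carriers, j] = 1
            gaps = np.diff(pos)
            p_switch = 1.0 - np.exp(-config.switch_rate * gaps)
            hap = np.empty((n_hap, V), dtype=np.int8)
            for h in range(n_hap):
                switch = rng.random(V - 1) < p_switch
                # template index per segment between switches
                seg = np.concatenate(([0], np.cumsum(switch)))
                templates = rng.integers(0, K, size=seg[-1] + 1)
                hap[h] = founders[templates[seg], np.arange(V)]
        ref = rng.choice(4, size=V)
        alt = (ref + rng.integers(1, 4, size=V)) % 4
        chroms.append(np.full(V, name, dtype=object))
        positions.append(pos)
        hap_blocks.append(hap)
        refs.append(_BASES[ref])
        alts.append(_BASES[alt])
    hap_all = np.concatenate(hap_blocks, axis=1)
    alleles = hap_all.reshape(S, 2, -1).transpose(0, 2, 1)
    return GenotypeMatrix(
        samples=[f"S{i + 1}" for i in range(S)],
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        ref=np.concatenate(refs),
        alt=np.concatenate(alts),
        alleles=np.ascontiguousarray(alleles),
        phased=True,
        chrom_lengths={f"chr{c + 1}": config.chrom_length for c in range(config.n_chromosomes)},
    )


def inject_sweep(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    carrier_fraction: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SweepTruth]:
    """Copy one donor haplotype over ``carrier_fraction`` of all haplotypes.

    Copying is restricted to SNPs inside ``[start, end]`` on ``chrom``
    (1-based inclusive), creating locally reduced diversity, an excess of
    low-frequency variants at the edges, and one long shared haplotype.
    """
    if not 0 < carrier_fraction <= 1:
        raise ValueError("carrier_fraction must be in (0, 1]")
    if start < 1 or end > gm.chromosome_length(chrom) or start > end:
        raise ValueError("sweep region outside chromosome bounds")
    sites = np.flatnonzero((gm.chrom == chrom) & (gm.pos >= start) & (gm.pos <= end))
    if len(sites) == 0:
        raise ValueError("sweep region contains no SNPs")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    hap = out.haplotypes()
    n_hap = hap.shape[0]
    n_carriers = max(2, int(carrier_fraction * n_hap))
    donor = rng.integers(0, n_hap)
    others = np.delete(np.arange(n_hap), donor)
    recipients = rng.choice(others, size=n_carriers - 1, replace=False)
    hap[recipients[:, None], sites[None, :]] = hap[donor, sites]
    out.alleles = np.ascontiguousarray(
        hap.reshape(out.n_samples, 2, -1).transpose(0, 2, 1)
    )
    return out, SweepTruth(chrom=chrom, start=start, end=end, carrier_fraction=carrier_fraction)


def inject_roh(
    gm: GenotypeMatrix, sample: str, chrom: str, start: int, end: int
) -> tuple[GenotypeMatrix, RohTruth]:
    """Overwrite haplotype 2 of ``sample`` with haplotype 1 over the region."""
    if sample not in gm.samples:
        raise ValueError(f"unknown sample {sample!r}")
    if start < 1 or end > gm.chromosome_length(chrom) or start > end:
        raise ValueError("ROH region outside chromosome bounds")
    s = gm.samples.index(sample)
    sites = np.flatnonzero((gm.chrom == chrom) & (gm.pos >= start) & (gm.pos <= end))
    out = gm.copy()
    out.alleles[s, sites, 1] = out.alleles[s, sites, 0]
    return out, RohTruth(sample=sample, chrom=chrom, start=start, end=end)


def inject_missing_and_errors(
    gm: GenotypeMatrix, missing_rate: float, error_rate: float, seed: int = 0
) -> GenotypeMatrix:
    """Set genotypes missing at ``missing_rate`` and flip remaining alleles
    at ``error_rate``, both independently per entry; deterministic per seed."""
    if not 0 <= missing_rate < 1 or not 0 <= error_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    S, V, _ = out.alleles.shape
    if missing_rate > 0:
        miss = rng.random((S, V)) < missing_rate
        out.alleles[miss] = MISSING
    if error_rate > 0:
        flip = rng.random((S, V, 2)) < error_rate
        ok = out.alleles != MISSING
        sel = flip & ok
        out.alleles[sel] = 1 - out.alleles[sel]
    return out


def write_sweep_truth_bed(truths: list[SweepTruth], path: str) -> None:
    """Write sweep truth intervals as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for t in truths:
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\tsweep_cf={t.carrier_fraction:g}\n")


def write_roh_truth_table(truths: list[RohTruth], path: str) -> None:
    """Write ROH truth as TSV: sample, chrom, start, end (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\n")
        for t in truths:
            fh.write(f"{t.sample}\t{t.chrom}\t{t.start}\t{t.end}\n")
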