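"""Windowed nucleotide diversity, Tajima's D, and runs of homozygosity.

Windows are non-overlapping, anchored at position 1 on every chromosome;
the final partial window is retained.  Window-level pi divides the summed
per-site diversity by the window length (VCFtools ``--window-pi``
convention); Tajima's D uses average pairwise differences without the
length division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, window_bounds, window_index


# --------------------------------------------------------------------- pi / D
def site_pi(ref_count: int, alt_count: int) -> float:
    """Per-site diversity: fraction of haplotype pairs that differ.

    Returns NaN when fewer than two non-missing alleles are available.
    """
    n = ref_count + alt_count
    if n < 2:
        return float("nan")
    return ref_count * alt_count / (n * (n - 1) / 2)


def _site_pi_vector(gm: GenotypeMatrix) -> np.ndarray:
    ref, alt = gm.allele_counts()
    n = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, ref * alt / np.maximum(n * (n - 1) / 2, 1e-300), np.nan)
    return pi


def windowed_pi(gm: GenotypeMatrix, window_size: int) -> pd.DataFrame:
    """Per-window pi = (sum of site diversities) / window_size.

    Windows with no SNPs get pi 0 and ``empty`` True.  Columns: chrom,
    start, end, n_snps, pi, empty.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    pi_site = _site_pi_vector(gm)
    rows = []
    for chrom, sl in gm.chromosome_slices():
        pos = gm.pos[sl]
        n_windows = int(np.ceil(gm.chromosome_length(chrom) / window_size))
        widx = window_index(pos, window_size)
        counts = np.bincount(widx, minlength=n_windows)
        sums = np.bincount(widx, weights=np.nan_to_num(pi_site[sl]), minlength=n_windows)
        starts, ends = window_bounds(n_windows, window_size)
        ends[-1] = min(ends[-1], gm.chromosome_length(chrom))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_snps": counts,
                    "pi": sums / window_size,
                    "empty": counts == 0,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "pi", "empty"])
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class TajimaConstants:
    """Normalization constants for Tajima's D with n haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def windowed_tajima_d(gm: GenotypeMatrix, window_size: int) -> pd.DataFrame:
    """Per-window Tajima's D; windows with no segregating sites are NaN.

    S counts segregating sites among non-missing alleles; the pairwise
    estimator sums per-site mean pairwise differences.  Window-level
    constants use n = 2 x sample count.
    """
    const = tajima_constants(gm.n_haplotypes)
    pi_site = _site_pi_vector(gm)
    ref, alt = gm.allele_counts()
    seg = (ref > 0) & (alt > 0)
    rows = []
    for chrom, sl in gm.chromosome_slices():
        pos = gm.pos[sl]
        n_windows = int(np.ceil(gm.chromosome_length(chrom) / window_size))
        widx = window_index(pos, window_size)
        n_snps = np.bincount(widx, minlength=n_windows)
        S = np.bincount(widx, weights=seg[sl].astype(float), minlength=n_windows)
        pi_hat = np.bincount(widx, weights=np.nan_to_num(pi_site[sl]), minlength=n_windows)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = const.e1 * S + const.e2 * S * (S - 1)
            d = np.where(S > 0, (pi_hat - S / const.a1) / np.sqrt(np.maximum(var, 1e-300)), np.nan)
        starts, ends = window_bounds(n_windows, window_size)
        ends[-1] = min(ends[-1], gm.chromosome_length(chrom))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_snps": n_snps,
                    "n_segregating": S.astype(int),
                    "pi_hat": pi_hat,
                    "tajima_d": d,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_snps", "n_segregating", "pi_hat", "tajima_d"]
        )
    return pd.concat(rows, ignore_index=True)


def window_stats(gm: GenotypeMatrix, window_size: int) -> pd.DataFrame:
    """Joined per-window table with n_snps, pi and tajima_d."""
    pi = windowed_pi(gm, window_size)
    td = windowed_tajima_d(gm, window_size)
    out = pi[["chrom", "start", "end", "n_snps", "pi", "empty"]].copy()
    out["tajima_d"] = td["tajima_d"].to_numpy()
    return out


# ------------------------------------------------------------------------ ROH
@dataclass(frozen=True)
class RohParams:
    """Consecutive-method run detection parameters (detectRUNS-style defaults)."""

    min_snp: int = 15
    min_length_bps: int = 1_000
    max_gap: int = 1_000_000
    max_opposite: int = 0
    max_missing: int = 1

    def __post_init__(self) -> None:
        if min(self.min_snp, self.min_length_bps, self.max_gap, self.max_opposite, self.max_missing) < 0:
            raise ValueError("ROH parameters must be nonnegative")


@dataclass(frozen=True)
class RohSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _runs_one_track(pos: np.ndarray, state: np.ndarray, params: RohParams):
    """Consecutive scan over one sample/chromosome track.

    ``state``: 0 homozygous, 1 heterozygous, 2 missing.  A run accumulates
    homozygous calls, tolerating up to max_opposite heterozygotes and
    max_missing missing calls; a gap > max_gap or an exceeded allowance
    closes the run at its last homozygous SNP.
    """
    runs = []
    cur: list[int] = []  # indices in current candidate, trimmed to end homozygous
    n_het = n_miss = 0

    def flush():
        nonlocal cur, n_het, n_miss
        while cur and state[cur[-1]] != 0:
            cur.pop()
        if cur:
            n_snps = cur[-1] - cur[0] + 1
            start, end = int(pos[cur[0]]), int(pos[cur[-1]])
            if n_snps >= params.min_snp and end - start + 1 >= params.min_length_bps:
                runs.append((start, end, n_snps))
        cur, n_het, n_miss = [], 0, 0

    for i in range(len(pos)):
        if cur and pos[i] - pos[cur[-1]] > params.max_gap:
            flush()
        st = state[i]
        if st == 0:
            cur.append(i)
        elif st == 1:
            if not cur:
                continue
            if n_het + 1 > params.max_opposite:
                flush()
            else:
                n_het += 1
                cur.append(i)
        else:
            if not cur:
                continue
            if n_miss + 1 > params.max_missing:
                flush()
            else:
                n_miss += 1
                cur.append(i)
    flush()
    return runs


def detect_roh(gm: GenotypeMatrix, params: RohParams = RohParams()) -> pd.DataFrame:
    """Detect runs of homozygosity per sample with the consecutive method.

    Returns a table with columns sample, chrom, start, end, n_snps, length;
    run coordinates span the first to last SNP of the run.
    """
    a = gm.alleles
    rows = []
    for chrom, sl in gm.chromosome_slices():
        pos = gm.pos[sl]
        for s, name in enumerate(gm.samples):
            g = a[s, sl, :]
            state = np.where(
                g[:, 0] < 0, 2, np.where(g[:, 0] == g[:, 1], 0, 1)
            ).astype(np.int8)
            for start, end, n_snps in _runs_one_track(pos, state, params):
                rows.append((name, chrom, start, end, n_snps, end - start + 1))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "n_snps", "length"])


ROH_CLASSES = ((0, 2_000_000), (2_000_000, 4_000_000), (4_000_000, 8_000_000), (8_000_000, None))


def snp_covered_length(gm: GenotypeMatrix) -> int:
    """Sum over chromosomes of (last SNP pos - first SNP pos + 1)."""
    total = 0
    for _, sl in gm.chromosome_slices():
        pos = gm.pos[sl]
        total += int(pos[-1] - pos[0] + 1)
    return total


def froh(rohs: pd.DataFrame, gm: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample F_ROH and per-length-class summary.

    F_ROH(sample) = total ROH length / SNP-covered autosome length.  The
    class summary reports ROH counts, percentage of all ROH, and the
    population-level class F_ROH (class length / (samples x genome length))
    for classes 0-2, 2-4, 4-8 and >8 Mb.
    """
    L = snp_covered_length(gm)
    per_sample = []
    for name in gm.samples:
        tot = int(rohs.loc[rohs["sample"] == name, "length"].sum()) if len(rohs) else 0
        per_sample.append((name, tot, tot / L if L else float("nan")))
    sample_df = pd.DataFrame(per_sample, columns=["sample", "roh_length", "froh"])

    n_total = len(rohs)
    class_rows = []
    for lo, hi in ROH_CLASSES:
        label = f"{lo // 1_000_000}-{hi // 1_000_000}Mb" if hi else f">{lo // 1_000_000}Mb"
        if len(rohs):
            sel = (rohs["length"] >= lo) & ((rohs["length"] < hi) if hi else True)
            count = int(sel.sum())
            length = int(rohs.loc[sel, "length"].sum())
        else:
            count, length = 0, 0
        pct = 100.0 * count / n_total if n_total else 0.0
        class_froh = length / (gm.n_samples * L) if L else float("nan")
        class_rows.append((label, count, pct, class_froh))
    class_df = pd.DataFrame(class_rows, columns=["roh_class", "n_roh", "pct", "froh"])
    return sample_df, class_df
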