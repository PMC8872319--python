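"""Pairwise linkage disequilibrium, LD-decay profiling and LD-based Ne.

r-squared is computed from phased haplotype counts over pairwise-complete
haplotypes.  Historical effective population size follows the classic
inversion of E[r2] = 1/(alpha + 4*N*c): per distance bin,
Ne = (1/(4c)) * (1/r2_adj - alpha), dated to t = 1/(2c) generations, with
physical distance mapped to recombination rate by a configurable mapping
function (1 cM/Mb absent a genetic map).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

MORGAN_PER_BP = 1e-8  # 1 cM/Mb


def haplotype_r2(gm: GenotypeMatrix, i: int, j: int) -> float:
    """r2 between variants i and j from phased haplotype frequencies.

    NaN when either site is monomorphic among pairwise-complete haplotypes.
    """
    if not gm.phased:
        raise ValueError("haplotype r2 requires phased genotypes")
    if gm.chrom[i] != gm.chrom[j]:
        raise ValueError("r2 is defined within a chromosome only")
    hap = gm.haplotypes()
    x, y = hap[:, i].astype(float), hap[:, j].astype(float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if len(x) == 0:
        return float("nan")
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = (x * y).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _pairwise_r2(hap: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """Vectorised r2 for many site pairs; NaN where undefined."""
    out = np.empty(len(idx_i))
    for lo in range(0, len(idx_i), chunk):
        hi = min(lo + chunk, len(idx_i))
        x = hap[:, idx_i[lo:hi]].astype(np.float64)
        y = hap[:, idx_j[lo:hi]].astype(np.float64)
        ok = (x >= 0) & (y >= 0)
        n = ok.sum(axis=0)
        x = np.where(ok, x, 0.0)
        y = np.where(ok, y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = x.sum(axis=0) / n
            pb = y.sum(axis=0) / n
            pab = (x * y).sum(axis=0) / n
            d = pab - pa * pb
            denom = pa * (1 - pa) * pb * (1 - pb)
            r2 = np.where(denom > 0, d * d / denom, np.nan)
        r2 = np.where(n >= 2, r2, np.nan)
        out[lo:hi] = r2
    return out


def collect_pairs(
    gm: GenotypeMatrix,
    max_dist: int,
    max_pairs: int = 2_000_000,
    min_maf: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """All intra-chromosomal site pairs within max_dist, with distance and r2.

    Pairs are uniformly subsampled to ``max_pairs`` (seeded) to bound cost.
    """
    if not gm.phased:
        raise ValueError("LD analysis requires phased genotypes")
    hap = gm.haplotypes()
    keep_site = np.ones(gm.n_variants, dtype=bool)
    if min_maf > 0:
        ref, alt = gm.allele_counts()
        tot = np.maximum(ref + alt, 1)
        maf = np.minimum(ref, alt) / tot
        keep_site = maf >= min_maf
    ii, jj = [], []
    for _, sl in gm.chromosome_slices():
        pos = gm.pos[sl]
        base = sl.start
        sites = np.flatnonzero(keep_site[sl])
        p = pos[sites]
        # two-pointer enumeration of pairs within max_dist
        right = np.searchsorted(p, p + max_dist, side="right")
        for a in range(len(sites)):
            b = right[a]
            if b > a + 1:
                ii.append(np.full(b - a - 1, base + sites[a]))
                jj.append(base + sites[a + 1 : b])
    if not ii:
        raise ValueError("no site pairs within max_dist")
    idx_i = np.concatenate(ii)
    idx_j = np.concatenate(jj)
    if len(idx_i) > max_pairs:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(idx_i), size=max_pairs, replace=False)
        sel.sort()
        idx_i, idx_j = idx_i[sel], idx_j[sel]
    dist = gm.pos[idx_j] - gm.pos[idx_i]
    r2 = _pairwise_r2(hap, idx_i, idx_j)
    return pd.DataFrame(
        {"chrom": gm.chrom[idx_i], "pos_i": gm.pos[idx_i], "pos_j": gm.pos[idx_j], "dist": dist, "r2": r2}
    )


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 1_000_000,
    bin_width: int = 10_000,
    r2_threshold: float = 0.2,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float | None]:
    """Mean r2 per distance bin plus the threshold-crossing decay distance.

    Bins partition (0, max_dist].  The decay distance is the upper edge of
    the first bin whose mean r2 drops below ``r2_threshold`` with no bin at
    or above the threshold among the next 5 (smoothing guard); ``None``
    when LD never decays below the threshold within max_dist.
    """
    pairs = collect_pairs(gm, max_dist=max_dist, max_pairs=max_pairs, seed=seed)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    bin_idx = np.clip(np.searchsorted(edges, pairs["dist"], side="left") - 1, 0, len(edges) - 2)
    table = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:]})
    grp = pairs.groupby(bin_idx)["r2"]
    table["n_pairs"] = grp.size().reindex(range(len(edges) - 1), fill_value=0).to_numpy()
    table["mean_r2"] = grp.mean().reindex(range(len(edges) - 1)).to_numpy()
    mean_r2 = table["mean_r2"].to_numpy()
    below = ~(mean_r2 >= r2_threshold)  # NaN (empty bin) counts as below
    decay_distance = None
    for b in range(len(below)):
        if below[b] and np.isfinite(mean_r2[b]) and below[b + 1 : b + 6].all():
            decay_distance = float(table["bin_end"].iloc[b])
            break
    return table, decay_distance


def _map_distance(d_morgans: np.ndarray, mapping: str) -> np.ndarray:
    if mapping == "linear":
        return d_morgans
    if mapping == "haldane":
        return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
    if mapping == "sved":
        # Closed form of the original Sved mapping not restated upstream;
        # aliased to Haldane pending a verbatim source.
        log.warning("mapping 'sved' aliased to 'haldane'")
        return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
    raise ValueError(f"unknown mapping {mapping!r}")


def ne_from_binned_pairs(
    dist_bp: np.ndarray,
    r2: np.ndarray,
    n_samples: int,
    n_bins: int = 20,
    mapping: str = "sved",
    mutation_alpha: float = 2.2,
    sample_size_correction: str = "1/2n",
) -> pd.DataFrame:
    """Ne trajectory from raw (distance, r2) pairs, binned by distance.

    Per bin: mean distance d (Morgans at 1 cM/Mb), c = mapping(d),
    r2_adj = mean r2 - correction, Ne = (1/(4c)) * (1/r2_adj - alpha),
    t = 1/(2c).  Bins where r2_adj <= 0 or Ne <= 0 are left NaN.
    """
    dist_bp = np.asarray(dist_bp, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    ok = np.isfinite(r2)
    dist_bp, r2 = dist_bp[ok], r2[ok]
    if sample_size_correction == "1/2n":
        corr = 1.0 / (2 * n_samples)
    elif sample_size_correction == "1/n":
        corr = 1.0 / n_samples
    elif sample_size_correction == "none":
        corr = 0.0
    else:
        raise ValueError(f"unknown correction {sample_size_correction!r}")
    edges = np.linspace(dist_bp.min(), dist_bp.max(), n_bins + 1)
    edges[-1] += 1  # include right endpoint
    bin_idx = np.digitize(dist_bp, edges) - 1
    rows = []
    for b in range(n_bins):
        sel = bin_idx == b
        n_pairs = int(sel.sum())
        if n_pairs == 0:
            continue
        d_m = dist_bp[sel].mean() * MORGAN_PER_BP
        c = float(_map_distance(np.array([d_m]), mapping)[0])
        r2_adj = r2[sel].mean() - corr
        if r2_adj > 0 and c > 0:
            ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - mutation_alpha)
            ne = ne if ne > 0 else float("nan")
        else:
            ne = float("nan")
        rows.append((dist_bp[sel].mean(), n_pairs, c, r2_adj, ne, 1.0 / (2.0 * c)))
    return pd.DataFrame(
        rows, columns=["mean_dist_bp", "n_pairs", "c", "r2_adj", "ne", "generations"]
    )


def estimate_ne(
    gm: GenotypeMatrix,
    n_bins: int = 20,
    mapping: str = "sved",
    mutation_alpha: float = 2.2,
    max_dist: int = 1_000_000,
    min_maf: float = 0.05,
    max_pairs: int = 2_000_000,
    sample_size_correction: str = "1/2n",
    seed: int = 0,
) -> pd.DataFrame:
    """LD-based historical Ne trajectory for a phased genotype matrix."""
    pairs = collect_pairs(gm, max_dist=max_dist, max_pairs=max_pairs, min_maf=min_maf, seed=seed)
    if n_bins < 2:
        raise ValueError("need at least 2 distance bins")
    return ne_from_binned_pairs(
        pairs["dist"].to_numpy(),
        pairs["r2"].to_numpy(),
        n_samples=gm.n_samples,
        n_bins=n_bins,
        mapping=mapping,
        mutation_alpha=mutation_alpha,
        sample_size_correction=sample_size_correction,
    )
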