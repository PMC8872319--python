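"""Extended haplotype homozygosity and the integrated haplotype score.

Per core SNP, EHH curves are traced for the carriers of each allele by
refining haplotype groups SNP-by-SNP outward until the curve falls below a
cutoff (or a guard trips: maximum extension, inter-SNP gap, chromosome
edge).  iHH integrates each curve trapezoidally over physical distance;
unstandardized iHS = ln(iHH_ancestral / iHH_derived) with ancestral = REF,
standardized within derived-allele-frequency bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, window_bounds, window_index

log = logging.getLogger(__name__)


@dataclass
class EhhSide:
    offsets: np.ndarray          # bp, nonnegative, increasing, starts at 0
    ehh: np.ndarray              # values in [0, 1], ehh[0] == 1
    truncated: bool              # True if the curve never fell below cutoff


@dataclass
class EhhCurve:
    core: int
    allele: int
    left: EhhSide
    right: EhhSide

    @property
    def truncated(self) -> bool:
        return self.left.truncated or self.right.truncated


def _group_homozygosity(groups: np.ndarray) -> float:
    """Sum over groups of C(k,2) / C(K,2)."""
    K = len(groups)
    _, counts = np.unique(groups, return_counts=True)
    return float((counts * (counts - 1)).sum() / (K * (K - 1)))


def _trace_side(
    hap: np.ndarray,
    pos: np.ndarray,
    carriers: np.ndarray,
    core: int,
    step: int,
    cutoff: float,
    max_extend: int,
    max_gap: int,
) -> EhhSide:
    offsets = [0.0]
    values = [1.0]
    groups = np.zeros(len(carriers), dtype=np.int64)
    j = core
    truncated = True
    while True:
        nxt = j + step
        if nxt < 0 or nxt >= hap.shape[1]:
            break  # chromosome edge
        gap = abs(int(pos[nxt]) - int(pos[j]))
        if gap > max_gap:
            break
        offset = abs(int(pos[nxt]) - int(pos[core]))
        if offset > max_extend:
            break
        a = hap[carriers, nxt].astype(np.int64)
        groups = groups * 3 + (a + 1)  # missing (-1) splits as its own value
        _, groups = np.unique(groups, return_inverse=True)
        e = _group_homozygosity(groups)
        offsets.append(float(offset))
        values.append(e)
        j = nxt
        if e < cutoff:
            truncated = False
            break
    return EhhSide(offsets=np.array(offsets), ehh=np.array(values), truncated=truncated)


def ehh(
    gm_or_hap,
    core: int,
    allele: int,
    cutoff: float = 0.05,
    max_extend: int = 1_000_000,
    max_gap: int = 200_000,
    _pos: np.ndarray | None = None,
) -> EhhCurve | None:
    """EHH curve around ``core`` for carriers of ``allele``.

    Accepts a phased :class:`GenotypeMatrix` (the core's chromosome is
    extracted automatically) or a raw (H, V) haplotype array plus ``_pos``.
    Returns ``None`` when fewer than 2 carriers exist.
    """
    if isinstance(gm_or_hap, GenotypeMatrix):
        gm = gm_or_hap
        if not gm.phased:
            raise ValueError("EHH requires phased genotypes")
        for chrom, sl in gm.chromosome_slices():
            if sl.start <= core < sl.stop:
                hap = gm.haplotypes()[:, sl]
                pos = gm.pos[sl]
                core = core - sl.start
                break
        else:
            raise IndexError(core)
    else:
        hap, pos = gm_or_hap, _pos
    carriers = np.flatnonzero(hap[:, core] == allele)
    if len(carriers) < 2:
        return None
    left = _trace_side(hap, pos, carriers, core, -1, cutoff, max_extend, max_gap)
    right = _trace_side(hap, pos, carriers, core, +1, cutoff, max_extend, max_gap)
    return EhhCurve(core=core, allele=allele, left=left, right=right)


def ihh(curve: EhhCurve) -> float | None:
    """Trapezoidal integral of EHH over bp offset, summed over both sides.

    Each side integrates out to the first sample point below the cutoff
    (no interpolated crossing).  Returns ``None`` for truncated curves.
    """
    if curve.truncated:
        return None
    total = 0.0
    for side in (curve.left, curve.right):
        total += float(np.trapezoid(side.ehh, side.offsets))
    return total


@dataclass
class IhsScanConfig:
    maf: float = 0.05
    cutoff: float = 0.05
    max_extend: int = 1_000_000
    max_gap: int = 200_000
    n_bins: int = 20
    min_bin_records: int = 20


def ihs_unstandardized(
    gm: GenotypeMatrix,
    config: IhsScanConfig = IhsScanConfig(),
    engine: str = "compiled",
) -> pd.DataFrame:
    """Per-SNP unstandardized iHS = ln(iHH_ancestral / iHH_derived).

    Cores outside the derived-frequency band [maf, 1-maf] are not scored;
    cores whose curves are truncated or degenerate are skipped and counted.
    The compiled engine and the pure-Python reference (``engine="python"``)
    produce identical tables.  Columns: chrom, pos, freq, ihh_a, ihh_d, ihs_u.
    """
    if not gm.phased:
        raise ValueError("iHS requires phased genotypes")
    ref, alt = gm.allele_counts()
    tot = np.maximum(ref + alt, 1)
    daf = alt / tot
    rows = []
    n_skipped = 0
    full_hap = gm.haplotypes()
    for chrom, sl in gm.chromosome_slices():
        hap = full_hap[:, sl]
        pos = gm.pos[sl]
        scoreable = (daf[sl] >= config.maf) & (daf[sl] <= 1 - config.maf)
        if engine == "compiled":
            from ._ihs_kernel import scan_chromosome

            ihh_ref, ihh_alt = scan_chromosome(
                np.ascontiguousarray(hap),
                pos,
                scoreable,
                config.cutoff,
                config.max_extend,
                config.max_gap,
            )
        elif engine == "python":
            ihh_ref = np.full(len(pos), np.nan)
            ihh_alt = np.full(len(pos), np.nan)
            for j in np.flatnonzero(scoreable):
                vals = []
                for a in (0, 1):
                    curve = ehh(hap, j, a, config.cutoff, config.max_extend, config.max_gap, _pos=pos)
                    vals.append(None if curve is None else ihh(curve))
                if all(v is not None and v > 0 for v in vals):
                    ihh_ref[j], ihh_alt[j] = vals
        else:
            raise ValueError(f"unknown engine {engine!r}")
        for j in np.flatnonzero(scoreable):
            if np.isfinite(ihh_ref[j]) and np.isfinite(ihh_alt[j]):
                rows.append(
                    (chrom, int(pos[j]), float(daf[sl.start + j]),
                     float(ihh_ref[j]), float(ihh_alt[j]),
                     float(np.log(ihh_ref[j] / ihh_alt[j])))
                )
            else:
                n_skipped += 1
    if n_skipped:
        log.info("ihs_unstandardized: skipped %d cores (truncated or degenerate)", n_skipped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "freq", "ihh_a", "ihh_d", "ihs_u"])


def _merge_small_bins(bin_of: np.ndarray, n_bins: int, min_records: int) -> np.ndarray:
    """Merge occupied frequency bins with < min_records into their nearest
    occupied neighbour (by bin index; ties to the left)."""
    bins = sorted(set(bin_of.tolist()))
    counts = {b: int((bin_of == b).sum()) for b in bins}
    merged = {b: b for b in bins}
    while len(counts) > 1:
        small = [b for b, c in counts.items() if c < min_records]
        if not small:
            break
        b = min(small, key=lambda x: counts[x])
        others = [o for o in counts if o != b]
        nearest = min(others, key=lambda o: (abs(o - b), o))
        counts[nearest] += counts.pop(b)
        for k, v in merged.items():
            if v == b:
                merged[k] = nearest
    return np.array([merged[b] for b in bin_of])


def ihs_standardize(records: pd.DataFrame, n_bins: int = 20, min_bin_records: int = 20) -> pd.DataFrame:
    """Z-score iHS within derived-allele-frequency bins.

    Frequencies are cut into ``n_bins`` equal-width bins on [0, 1]; bins
    with fewer than ``min_bin_records`` records are merged with their
    nearest neighbour.  Adds columns ``freq_bin`` and ``ihs_std``.
    """
    if len(records) == 0:
        raise ValueError("no iHS records to standardize")
    out = records.copy()
    bin_of = np.clip((out["freq"].to_numpy() * n_bins).astype(int), 0, n_bins - 1)
    bin_of = _merge_small_bins(bin_of, n_bins, min_bin_records)
    out["freq_bin"] = bin_of
    std = np.empty(len(out))
    for b in np.unique(bin_of):
        sel = bin_of == b
        vals = out.loc[sel, "ihs_u"].to_numpy()
        if len(vals) < 2 or vals.std(ddof=0) == 0:
            raise ValueError(f"degenerate frequency bin {b}: cannot standardize")
        std[sel] = (vals - vals.mean()) / vals.std(ddof=0)
    out["ihs_std"] = std
    return out


def windowed_abs_ihs(records: pd.DataFrame, window_size: int = 100_000, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-window mean |standardized iHS|; windows with no scored SNP are NaN.

    Windows use the same position-1-anchored tiling as the diversity
    statistics.  ``chrom_lengths`` extends the tiling beyond the last
    scored SNP when provided.
    """
    rows = []
    for chrom in dict.fromkeys(records["chrom"]):
        sub = records[records["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        length = (chrom_lengths or {}).get(chrom, int(pos.max()))
        n_windows = int(np.ceil(length / window_size))
        widx = window_index(pos, window_size)
        counts = np.bincount(widx, minlength=n_windows)
        sums = np.bincount(widx, weights=np.abs(sub["ihs_std"].to_numpy()), minlength=n_windows)
        starts, ends = window_bounds(n_windows, window_size)
        with np.errstate(invalid="ignore"):
            mean_abs = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "n_snps": counts, "mean_abs_ihs": mean_abs}
            )
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "mean_abs_ihs"])
    return pd.concat(rows, ignore_index=True)
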