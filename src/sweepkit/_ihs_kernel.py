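"""Compiled inner loops for the genome-wide iHS scan.

The pure-Python EHH tracer in :mod:`sweepkit.ihs` stays the reference
implementation; these kernels reproduce it exactly (asserted in the test
suite) and exist only to make whole-chromosome scans fast.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def _side_ihh(hap, pos, carriers, core, step, cutoff, max_extend, max_gap):
    """Trapezoidal iHH for one side; returns (integral, truncated)."""
    K = carriers.shape[0]
    n_pairs = K * (K - 1) / 2.0
    group = np.zeros(K, dtype=np.int64)
    comb = np.empty(K, dtype=np.int64)
    ehh_prev = 1.0
    off_prev = 0.0
    total = 0.0
    V = hap.shape[1]
    j = core
    while True:
        nxt = j + step
        if nxt < 0 or nxt >= V:
            return total, True
        gap = pos[nxt] - pos[j]
        if gap < 0:
            gap = -gap
        if gap > max_gap:
            return total, True
        off = pos[nxt] - pos[core]
        if off < 0:
            off = -off
        if off > max_extend:
            return total, True
        for t in range(K):
            comb[t] = group[t] * 3 + hap[carriers[t], nxt] + 1
        su = np.sort(comb)
        same = 0.0
        run = 1
        for t in range(1, K):
            if su[t] == su[t - 1]:
                run += 1
            else:
                same += run * (run - 1) / 2.0
                run = 1
        same += run * (run - 1) / 2.0
        e = same / n_pairs
        for t in range(K):
            group[t] = np.searchsorted(su, comb[t])
        total += (ehh_prev + e) / 2.0 * (off - off_prev)
        ehh_prev = e
        off_prev = float(off)
        j = nxt
        if e < cutoff:
            return total, False


@nb.njit(cache=True)
def scan_chromosome(hap, pos, scoreable, cutoff, max_extend, max_gap):
    """iHH for both core alleles at every scoreable site of one chromosome.

    Returns (ihh_ref, ihh_alt); NaN where a record is undefined (fewer than
    2 carriers of either allele, or a truncated EHH curve).
    """
    H, V = hap.shape
    ihh_ref = np.full(V, np.nan)
    ihh_alt = np.full(V, np.nan)
    for j in range(V):
        if not scoreable[j]:
            continue
        vals = np.empty(2)
        ok = True
        for allele in range(2):
            K = 0
            for h in range(H):
                if hap[h, j] == allele:
                    K += 1
            if K < 2:
                ok = False
                break
            carriers = np.empty(K, dtype=np.int64)
            c = 0
            for h in range(H):
                if hap[h, j] == allele:
                    carriers[c] = h
                    c += 1
            left, tl = _side_ihh(hap, pos, carriers, j, -1, cutoff, max_extend, max_gap)
            right, tr = _side_ihh(hap, pos, carriers, j, 1, cutoff, max_extend, max_gap)
            if tl or tr:
                ok = False
                break
            vals[allele] = left + right
        if ok and vals[0] > 0 and vals[1] > 0:
            ihh_ref[j] = vals[0]
            ihh_alt[j] = vals[1]
    return ihh_ref, ihh_alt
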