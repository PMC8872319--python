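"""SNP quality control: exact Hardy-Weinberg test and threshold filters.

Variants are removed when call rate < ``call_rate_min``, minor allele
frequency < ``maf_min``, or exact HWE p-value < ``hwe_p_min`` (all strict
inequalities).  Criteria are attributed in the order call rate, MAF, HWE so
the removal counts partition the removed set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    n_retained: int

    def __post_init__(self) -> None:
        total = self.removed_call_rate + self.removed_maf + self.removed_hwe + self.n_retained
        if total != self.n_input:
            raise ValueError("filter report counts do not sum to input count")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("criterion\tcount\n")
            fh.write(f"input\t{self.n_input}\n")
            fh.write(f"removed_call_rate\t{self.removed_call_rate}\n")
            fh.write(f"removed_maf\t{self.removed_maf}\n")
            fh.write(f"removed_hwe\t{self.removed_hwe}\n")
            fh.write(f"retained\t{self.n_retained}\n")


def _levene_haldane_logprobs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of each attainable heterozygote count.

    Conditional on ``n`` diploid individuals and ``n_minor`` copies of the
    minor allele, heterozygote counts share the parity of ``n_minor``:

        P(h) = n! / (hom_major! h! hom_minor!) * 2^h / [ (2n)! / (n_minor! n_major! ) ]
    """
    n_major = 2 * n - n_minor
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    valid = hom_major >= 0
    hs, hom_minor, hom_major = hs[valid], hom_minor[valid], hom_major[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hs + 1)
        - gammaln(hom_minor + 1)
        + hs * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(n_major + 1))
    )
    return hs, logp


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (Levene-Haldane distribution).

    Returns the sum of probabilities of all heterozygote configurations no
    more probable than the observed one, conditional on the allele counts.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one individual required")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    hs, logp = _levene_haldane_logprobs(n, n_minor)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hs == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the three QC filters; removal is strict-inequality on each threshold."""
    V = gm.n_variants
    called = ~gm.missing_mask()
    call_rate = called.sum(axis=0) / max(gm.n_samples, 1)
    ref, alt = gm.allele_counts()
    tot = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, np.minimum(ref, alt) / np.maximum(tot, 1), 0.0)
    fail_cr = call_rate < call_rate_min
    fail_maf = maf < maf_min
    hom_ref, het, hom_alt = gm.genotype_counts()
    keep = ~(fail_cr | fail_maf)
    fail_hwe = np.zeros(V, dtype=bool)
    for j in np.flatnonzero(keep):
        if hwe_exact_test(int(hom_ref[j]), int(het[j]), int(hom_alt[j])) < hwe_p_min:
            fail_hwe[j] = True
    removed_cr = int(fail_cr.sum())
    removed_maf = int((fail_maf & ~fail_cr).sum())
    removed_hwe = int(fail_hwe.sum())
    retained_idx = np.flatnonzero(~(fail_cr | fail_maf | fail_hwe))
    report = FilterReport(
        n_input=V,
        removed_call_rate=removed_cr,
        removed_maf=removed_maf,
        removed_hwe=removed_hwe,
        n_retained=len(retained_idx),
    )
    if len(retained_idx) == 0:
        log.warning("filter_variants removed every variant")
    return gm.take_variants(retained_idx), report
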