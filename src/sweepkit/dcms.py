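"""De-correlated composite of multiple signals (DCMS).

Per-window statistics are converted to genome-wide rank p-values with a
configurable tail per statistic, combined as a weighted sum of logits where
each statistic's weight is the reciprocal of its summed absolute
correlation with all statistics, calibrated against a robust normal fit
(Huber location, MAD scale), and windows with upper-tail p below a fixed
threshold are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr
from sklearn.covariance import MinCovDet

log = logging.getLogger(__name__)

#: sweep-consistent tail per statistic: depressed diversity, negative D,
#: elevated haplotype homozygosity
DEFAULT_TAILS = {"pi": "lower", "tajima_d": "lower", "mean_abs_ihs": "upper"}


def rank_pvalues(values: np.ndarray, tail: str) -> np.ndarray:
    """Genome-wide rank-based p-values with inclusive tie handling.

    lower tail: p_i = #{j : v_j <= v_i} / N; upper: p_i = #{j : v_j >= v_i} / N,
    over the N non-missing values.  Missing in, missing out.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    x = v[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 non-missing values")
    s = np.sort(x)
    if tail == "lower":
        p = np.searchsorted(s, x, side="right") / len(x)
    elif tail == "upper":
        p = (len(x) - np.searchsorted(s, x, side="left")) / len(x)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    out[ok] = p
    return out


def robust_correlation(
    stat_matrix: np.ndarray,
    mcd_alpha: float = 0.75,
    sample_rows: int = 50_000,
    seed: int = 0,
) -> np.ndarray:
    """Robust correlation of the statistics via the FAST-MCD estimator.

    Complete-case rows are subsampled (seeded) to at most ``sample_rows``;
    the reweighted MCD covariance is rescaled to a correlation matrix.
    Falls back to Spearman rank correlation if MCD fails.
    """
    X = np.asarray(stat_matrix, dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    T = X.shape[1]
    if X.shape[0] < 10 * T:
        raise ValueError("need at least 10 complete rows per statistic")
    rng = np.random.default_rng(seed)
    if X.shape[0] > sample_rows:
        X = X[rng.choice(X.shape[0], size=sample_rows, replace=False)]
    try:
        mcd = MinCovDet(
            support_fraction=mcd_alpha,
            random_state=np.random.RandomState(rng.integers(2**31 - 1)),
        ).fit(X)
        cov = mcd.covariance_
        sd = np.sqrt(np.diag(cov))
        if not np.all(sd > 0):
            raise np.linalg.LinAlgError("degenerate MCD covariance")
        corr = cov / np.outer(sd, sd)
    except Exception as exc:
        log.warning("MCD failed (%s); falling back to Spearman correlation", exc)
        corr = spearmanr(X).statistic
        corr = np.atleast_2d(corr)
        if corr.shape != (T, T):
            corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return corr


def dcms_scores(p_matrix: np.ndarray, correlation: np.ndarray) -> np.ndarray:
    """DCMS_i = sum_t ln((1-p_it)/p_it) / sum_s |r_st|, complete rows only.

    p-values are clamped to [1/(2N), 1 - 1/(2N)] before the logit (when
    N >= 2 rows; the band is degenerate otherwise); rows with any missing
    p get NaN.
    """
    P = np.asarray(p_matrix, dtype=float)
    R = np.asarray(correlation, dtype=float)
    if P.ndim != 2 or R.shape != (P.shape[1], P.shape[1]):
        raise ValueError("p-matrix columns must align with the correlation matrix")
    N = P.shape[0]
    if N >= 2:
        lo = 1.0 / (2 * N)
        Pc = np.clip(P, lo, 1 - lo)
    else:
        Pc = P
    weights = 1.0 / np.abs(R).sum(axis=0)
    scores = (np.log((1 - Pc) / Pc) * weights).sum(axis=1)
    scores[~np.isfinite(P).all(axis=1)] = np.nan
    return scores


def _huber_location(x: np.ndarray, tuning: float = 1.345, tol: float = 1e-8, max_iter: int = 200) -> tuple[float, float]:
    """Intercept-only Huber M-estimate of location with fixed MAD scale."""
    med = np.median(x)
    sigma = 1.4826 * np.median(np.abs(x - med))
    if sigma == 0:
        raise ValueError("zero MAD: degenerate scores")
    mu = med
    for _ in range(max_iter):
        r = (x - mu) / sigma
        w = np.minimum(1.0, tuning / np.maximum(np.abs(r), 1e-300))
        mu_new = float(np.sum(w * x) / np.sum(w))
        if abs(mu_new - mu) < tol:
            mu = mu_new
            break
        mu = mu_new
    return mu, float(sigma)


@dataclass
class DcmsResult:
    table: pd.DataFrame          # per-window p per statistic, dcms, p_value, significant
    correlation: np.ndarray
    mu: float
    sigma: float
    threshold: float


def dcms_calibrate(scores: np.ndarray, threshold: float = 0.01) -> tuple[np.ndarray, float, float]:
    """Upper-tail normal p-values for DCMS scores under a robust fit.

    Location by intercept-only Huber M-estimation (tuning 1.345), scale by
    normalized MAD; p_i = 1 - Phi((score_i - mu)/sigma).
    """
    s = np.asarray(scores, dtype=float)
    ok = np.isfinite(s)
    if ok.sum() < 50:
        raise ValueError("need at least 50 scores to calibrate")
    mu, sigma = _huber_location(s[ok])
    p = np.full(s.shape, np.nan)
    p[ok] = norm.sf((s[ok] - mu) / sigma)
    return p, mu, sigma


def dcms_scan(
    stats: pd.DataFrame,
    columns: tuple[str, ...] = ("pi", "tajima_d", "mean_abs_ihs"),
    tails: dict[str, str] | None = None,
    mcd_alpha: float = 0.75,
    sample_rows: int = 50_000,
    threshold: float = 0.01,
    seed: int = 0,
) -> DcmsResult:
    """Full composite scan over a per-window statistics table.

    ``stats`` must carry chrom/start/end plus the statistic columns.
    Windows missing any statistic receive no DCMS p-value (untested).
    """
    tails = {**DEFAULT_TAILS, **(tails or {})}
    P = np.column_stack(
        [rank_pvalues(stats[c].to_numpy(), tails.get(c, "lower")) for c in columns]
    )
    corr = robust_correlation(stats[list(columns)].to_numpy(), mcd_alpha, sample_rows, seed)
    scores = dcms_scores(P, corr)
    pvals, mu, sigma = dcms_calibrate(scores, threshold)
    table = stats[["chrom", "start", "end"]].copy()
    for t, c in enumerate(columns):
        table[f"p_{c}"] = P[:, t]
    table["dcms"] = scores
    table["p_value"] = pvals
    table["significant"] = pvals < threshold
    return DcmsResult(table=table, correlation=corr, mu=mu, sigma=sigma, threshold=threshold)
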