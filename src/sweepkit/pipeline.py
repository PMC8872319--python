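"""End-to-end window scan: diversity + iHS statistics -> DCMS calls."""

from __future__ import annotations

import pandas as pd

from . import dcms as dcms_mod
from . import diversity, ihs as ihs_mod
from .genotypes import GenotypeMatrix


def window_statistics(
    gm: GenotypeMatrix,
    window_size: int,
    ihs_config: ihs_mod.IhsScanConfig = ihs_mod.IhsScanConfig(),
) -> pd.DataFrame:
    """Per-window pi, Tajima's D and mean |iHS| on one tiling."""
    stats = diversity.window_stats(gm, window_size)
    records = ihs_mod.ihs_standardize(
        ihs_mod.ihs_unstandardized(gm, ihs_config),
        n_bins=ihs_config.n_bins,
        min_bin_records=ihs_config.min_bin_records,
    )
    wihs = ihs_mod.windowed_abs_ihs(records, window_size, gm.chrom_lengths)
    return stats.merge(
        wihs[["chrom", "start", "mean_abs_ihs"]], on=["chrom", "start"], how="left"
    )


def scan(
    gm: GenotypeMatrix,
    window_size: int = 100_000,
    threshold: float = 0.01,
    seed: int = 0,
    ihs_config: ihs_mod.IhsScanConfig = ihs_mod.IhsScanConfig(),
    mcd_alpha: float = 0.75,
    sample_rows: int = 50_000,
) -> dcms_mod.DcmsResult:
    """Compute all three window statistics and run the DCMS composite scan."""
    stats = window_statistics(gm, window_size, ihs_config)
    return dcms_mod.dcms_scan(
        stats, mcd_alpha=mcd_alpha, sample_rows=sample_rows, threshold=threshold, seed=seed
    )
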