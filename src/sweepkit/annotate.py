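"""Sweep-region assembly and gene/QTL interval annotation.

Significant windows are extended upstream and downstream (by the LD-decay
distance or a fixed amount), merged when the extended intervals overlap or
bookend, and intersected with gene/QTL features under a 1-bp inclusive
overlap rule.  All public coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    windows: list[tuple[int, int]] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    qtls: list[str] = field(default_factory=list)


def extend_and_merge(
    windows: pd.DataFrame,
    extension: int,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SweepRegion]:
    """Extend each window by ``extension`` bp both ways, clamp, and merge.

    ``windows`` needs chrom/start/end columns (1-based inclusive,
    non-overlapping).  Overlapping or bookended extended intervals on the
    same chromosome are merged; member windows are recorded.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    chrom_lengths = chrom_lengths or {}
    regions: list[SweepRegion] = []
    df = windows.sort_values(["chrom", "start"], kind="stable")
    for _, row in df.iterrows():
        chrom = row["chrom"]
        start = max(1, int(row["start"]) - extension)
        end = int(row["end"]) + extension
        if chrom in chrom_lengths:
            end = min(end, chrom_lengths[chrom])
        member = (int(row["start"]), int(row["end"]))
        last = regions[-1] if regions else None
        if last is not None and last.chrom == chrom and start <= last.end + 1:
            last.end = max(last.end, end)
            last.windows.append(member)
        else:
            regions.append(SweepRegion(chrom=chrom, start=start, end=end, windows=[member]))
    return regions


def overlap_features(regions: list[SweepRegion], features: pd.DataFrame) -> tuple[list[SweepRegion], int]:
    """Attach overlapping feature identifiers to each region.

    ``features`` columns: chrom, start, end (1-based inclusive), id, cls
    ('gene' or 'qtl').  A feature is reported iff it shares >= 1 bp with
    the region.  Returns the annotated regions and the count of distinct
    overlapping genes.
    """
    known = {r.chrom for r in regions}
    unknown = sorted(set(features["chrom"]) - known)
    if unknown:
        log.warning("features on chromosomes without regions skipped: %s", ", ".join(map(str, unknown)))
    all_genes: set[str] = set()
    for r in regions:
        sub = features[
            (features["chrom"] == r.chrom)
            & (features["start"] <= r.end)
            & (features["end"] >= r.start)
        ]
        r.genes = sorted(sub.loc[sub["cls"] == "gene", "id"])
        r.qtls = sorted(sub.loc[sub["cls"] == "qtl", "id"])
        all_genes.update(r.genes)
    return regions, len(all_genes)


def read_bed_features(path: str, cls: str) -> pd.DataFrame:
    """BED (0-based half-open) -> feature table (1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            name = parts[3] if len(parts) > 3 else f"{cls}_{ln}"
            rows.append((parts[0], int(parts[1]) + 1, int(parts[2]), name, cls))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "cls"])


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene records from a GFF3 file (feature type 'gene' only)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: GFF3 line needs 9 fields")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"gene_{ln}"
            rows.append((parts[0], int(parts[3]), int(parts[4]), name, "gene"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "cls"])


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    """Flatten regions to a 1-based inclusive report table."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_windows": len(r.windows),
                "genes": ",".join(r.genes),
                "qtls": ",".join(r.qtls),
            }
            for r in regions
        ]
    )
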