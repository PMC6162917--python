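"""Attribution of SAG reads against a binned metagenome.

Each primary, non-duplicate alignment of a SAG read is placed in exactly
one of four categories relative to a focal MAG: the read maps to a contig
of the focal bin (IN_MAG), to a long (>= 1 kb) contig that was subject to
binning but sits in another bin (LONG_NON_MAG), to a short contig that was
never binned (SHORT), or nowhere (UNMAPPED).  Base-coverage on the
LONG_NON_MAG contigs over base-coverage on all binned contigs is the
false-negative binning rate: the share of genome signal the binning
wrongly excluded from the focal MAG.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_compare import union_length
from .io import AlignmentRecord, BinTable, logger


class Category(str, enum.Enum):
    IN_MAG = "IN_MAG"
    LONG_NON_MAG = "LONG_NON_MAG"
    SHORT = "SHORT"
    UNMAPPED = "UNMAPPED"


def primary_unique(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep one primary, non-duplicate record per read (first wins)."""
    seen: set[str] = set()
    kept = []
    for rec in records:
        if not rec.primary or rec.duplicate or rec.read_id in seen:
            continue
        seen.add(rec.read_id)
        kept.append(rec)
    return kept


def categorize_read(
    record: AlignmentRecord,
    bins: BinTable,
    focal_bin: str,
    min_length: int = 1000,
) -> Category:
    """Place one primary alignment record in its attribution category."""
    if not record.mapped:
        return Category.UNMAPPED
    if record.target_id not in bins:
        raise ValueError(f"contig {record.target_id!r} absent from the bin table")
    if bins.bin_of(record.target_id) == focal_bin:
        return Category.IN_MAG
    if bins.length_of(record.target_id) >= min_length:
        return Category.LONG_NON_MAG
    return Category.SHORT


def covered_bases(
    records: Iterable[AlignmentRecord], contig_subset: set[str] | None = None
) -> int:
    """Target bases covered by >= 1 aligned operation, via interval union."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        if not rec.mapped:
            continue
        if contig_subset is not None and rec.target_id not in contig_subset:
            continue
        per_contig.setdefault(rec.target_id, []).append(rec.target_interval())
    return sum(union_length(ivs) for ivs in per_contig.values())


def fn_binning_rate(
    records: Iterable[AlignmentRecord],
    bins: BinTable,
    focal_bin: str,
    min_length: int = 1000,
    denominator: str = "binned",
) -> float:
    """False-negative binning rate for one SAG / focal-MAG pair.

    Numerator: bases covered by SAG reads on long non-focal binned
    contigs.  Denominator: bases covered on all binned contigs
    (``denominator="binned"``, the headline definition) or on the focal
    MAG's contigs only (``denominator="mag"``, the supplementary variant).
    """
    records = list(records)
    non_mag = {
        c for c, (length, b) in bins.contigs.items()
        if b is not None and b != focal_bin and length >= min_length
    }
    mag = {c for c, (_, b) in bins.contigs.items() if b == focal_bin}
    num = covered_bases(records, non_mag)
    if denominator == "binned":
        den = covered_bases(records, non_mag | mag)
    elif denominator == "mag":
        den = covered_bases(records, mag)
    else:
        raise ValueError(f"denominator must be 'binned' or 'mag', got {denominator!r}")
    if den == 0:
        logger.warning("fn_binning_rate: zero covered bases in denominator; returning 0")
        return 0.0
    return num / den


@dataclass
class AttributionSummary:
    """Category tallies and FN rate for one (SAG, focal MAG) pair."""

    sag_id: str
    focal_bin: str
    counts: dict[Category, int]
    covered: dict[Category, int]
    fn_rate: float

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[Category, float]:
        total = self.total_reads
        return {c: 100.0 * n / total if total else 0.0 for c, n in self.counts.items()}


def attribute_pair(
    records: Iterable[AlignmentRecord],
    bins: BinTable,
    sag_id: str,
    focal_bin: str,
    min_length: int = 1000,
) -> AttributionSummary:
    """Categorize one SAG's deduplicated primary records against one MAG."""
    records = primary_unique(records)
    counts = {c: 0 for c in Category}
    by_cat: dict[Category, list[AlignmentRecord]] = {c: [] for c in Category}
    for rec in records:
        cat = categorize_read(rec, bins, focal_bin, min_length)
        counts[cat] += 1
        by_cat[cat].append(rec)
    covered = {c: covered_bases(by_cat[c]) for c in Category}
    rate = fn_binning_rate(records, bins, focal_bin, min_length)
    return AttributionSummary(sag_id, focal_bin, counts, covered, rate)


def summarize_pairs(
    record_sets: Mapping[tuple[str, str], Iterable[AlignmentRecord]],
    bins: BinTable,
    min_length: int = 1000,
) -> tuple[list[AttributionSummary], pd.DataFrame]:
    """Per-pair summaries plus across-pair medians/means of each category.

    ``record_sets`` maps (sag_id, focal_bin) to that SAG's alignment
    records against the metagenome the focal MAG came from.
    """
    summaries = [
        attribute_pair(records, bins, sag_id, focal_bin, min_length)
        for (sag_id, focal_bin), records in record_sets.items()
    ]
    if not summaries:
        raise ValueError("no (SAG, MAG) pairs to summarize")
    rows = []
    for s in summaries:
        pct = s.percentages
        rows.append(
            {
                "sag_id": s.sag_id,
                "focal_bin": s.focal_bin,
                "total_reads": s.total_reads,
                **{f"pct_{c.value}": pct[c] for c in Category},
                **{f"covered_{c.value}": s.covered[c] for c in Category},
                "fn_rate": s.fn_rate,
            }
        )
    table = pd.DataFrame(rows)
    stat_cols = [f"pct_{c.value}" for c in Category] + ["fn_rate"]
    agg = pd.DataFrame(
        {
            "median": table[stat_cols].median(),
            "mean": table[stat_cols].mean(),
        }
    )
    return summaries, pd.concat(
        [table, agg.T.assign(sag_id=["median", "mean"], focal_bin="-")],
        ignore_index=True,
    )


def write_attribution(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
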