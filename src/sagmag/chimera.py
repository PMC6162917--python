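"""Detection of MDA inversion-chimera reads from soft-clipped alignments.

A read becomes a chimera candidate when some primary alignment carries at
least 20 soft-clipped bases while its aligned region still spans at least
half the read with no more than two mismatches — a conservative signature
of an inversion joint inside the read.  Candidates are pooled across all
samples the read was mapped to, deduplicated, and rescued (removed) if any
sample aligns the read near-full-length (>= 95 % of its length, fewer than
five mismatches), which a genuine inversion chimera cannot achieve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io import AlignmentRecord, BinTable, logger
from .read_attribution import Category, categorize_read, primary_unique


def _clip(record: AlignmentRecord, mode: str) -> int:
    if mode == "total":
        return record.clipped_bases
    if mode == "single":
        return record.max_single_clip
    raise ValueError(f"clip_mode must be 'total' or 'single', got {mode!r}")


def is_chimera_candidate(
    record: AlignmentRecord,
    min_clip: int = 20,
    match_fraction: float = 0.5,
    max_mismatches: int = 2,
    clip_mode: str = "total",
) -> bool:
    """Does one mapped primary alignment look like an inversion joint?"""
    if not record.mapped:
        return False
    subs = record.substitutions
    if subs is None:
        logger.warning("record %s has no mismatch count; skipped as candidate", record.read_id)
        return False
    return (
        _clip(record, clip_mode) >= min_clip
        and record.aligned_query_bases >= match_fraction * record.read_length
        and subs <= max_mismatches
    )


def is_nonchimeric_mapping(
    record: AlignmentRecord,
    min_fraction: float = 0.95,
    max_mismatches: int = 5,
) -> bool:
    """Near-full-length mapping that rules a read out as chimeric."""
    if not record.mapped:
        return False
    subs = record.substitutions
    if subs is None:
        logger.warning("record %s has no mismatch count; not a rescue", record.read_id)
        return False
    return (
        record.aligned_query_bases >= min_fraction * record.read_length
        and subs < max_mismatches
    )


@dataclass
class ChimeraCallSet:
    """Pooled chimera calls across samples."""

    candidate_reads: set[str]
    rescued_reads: set[str]
    chimeric_reads: set[str]
    candidate_samples: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chimeric_reads != self.candidate_reads - self.rescued_reads:
            raise ValueError("chimeric_reads must equal candidates minus rescued")


def call_chimeras(
    sample_records: Mapping[str, Iterable[AlignmentRecord]],
    min_clip: int = 20,
    match_fraction: float = 0.5,
    max_mismatches: int = 2,
    nonchimeric_fraction: float = 0.95,
    nonchimeric_max_mismatches: int = 5,
    clip_mode: str = "total",
) -> ChimeraCallSet:
    """Pool per-sample candidates, deduplicate, and apply any-sample rescue."""
    candidates: set[str] = set()
    rescued: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for sample, records in sample_records.items():
        for rec in primary_unique(records):
            if is_chimera_candidate(rec, min_clip, match_fraction, max_mismatches, clip_mode):
                if rec.read_id not in candidates:
                    provenance[rec.read_id] = []
                candidates.add(rec.read_id)
                provenance[rec.read_id].append(sample)
            if is_nonchimeric_mapping(rec, nonchimeric_fraction, nonchimeric_max_mismatches):
                rescued.add(rec.read_id)
    rescued &= candidates
    calls = ChimeraCallSet(
        candidate_reads=candidates,
        rescued_reads=rescued,
        chimeric_reads=candidates - rescued,
        candidate_samples=provenance,
    )
    logger.info(
        "call_chimeras: %d candidates, %d rescued, %d chimeric",
        len(candidates), len(rescued), len(calls.chimeric_reads),
    )
    return calls


@dataclass
class ChimeraStats:
    """Downstream statistics of the chimera call set."""

    chimeric_fraction: float
    softclip_vs_sag_chimeric: float
    softclip_vs_sag_other: float
    edge_fraction_chimeric: float
    edge_fraction_other: float
    category_distribution: dict[str, float]

    def as_dict(self) -> dict[str, float | dict[str, float]]:
        return {
            "chimeric_fraction": self.chimeric_fraction,
            "softclip_vs_sag_chimeric": self.softclip_vs_sag_chimeric,
            "softclip_vs_sag_other": self.softclip_vs_sag_other,
            "edge_fraction_chimeric": self.edge_fraction_chimeric,
            "edge_fraction_other": self.edge_fraction_other,
            "category_distribution": self.category_distribution,
        }


def _is_edge_alignment(record: AlignmentRecord, contig_length: int) -> bool:
    """Soft-clipped alignment flush with a contig boundary (either end)."""
    if not record.mapped:
        return False
    start, end = record.target_interval()
    if record.left_clip > 0 and start == 0:
        return True
    if record.right_clip > 0 and end == contig_length:
        return True
    return False


def chimera_stats(
    calls: ChimeraCallSet,
    sag_records: Iterable[AlignmentRecord],
    meta_records: Iterable[AlignmentRecord],
    bins: BinTable,
    focal_bin: str,
    contig_lengths: Mapping[str, int],
    total_reads: int | None = None,
    min_clip: int = 20,
    min_length: int = 1000,
) -> ChimeraStats:
    """Soft-clip, contig-edge and category statistics of the chimera calls.

    ``sag_records``: the reads aligned against the SAG's own contigs
    (``contig_lengths`` gives those contigs' lengths); ``meta_records``:
    the same reads against the binned metagenome, used to re-run the
    four-way attribution restricted to chimeric reads.
    """
    sag_records = primary_unique(sag_records)
    meta_records = primary_unique(meta_records)
    all_reads = {r.read_id for r in sag_records} | {r.read_id for r in meta_records}
    n_total = total_reads if total_reads is not None else len(all_reads)
    chimeric = calls.chimeric_reads

    def _softclip_fraction(read_set: set[str]) -> float:
        recs = [r for r in sag_records if r.read_id in read_set]
        if not recs:
            return 0.0
        n = sum(1 for r in recs if r.mapped and r.clipped_bases >= min_clip)
        return n / len(recs)

    def _edge_fraction(read_set: set[str]) -> float:
        recs = [r for r in sag_records if r.read_id in read_set and r.mapped]
        if not recs:
            return 0.0
        n = sum(1 for r in recs if _is_edge_alignment(r, contig_lengths[r.target_id]))
        return n / len(recs)

    others = all_reads - chimeric
    dist: dict[str, float] = {}
    chim_meta = [r for r in meta_records if r.read_id in chimeric]
    if chim_meta:
        counts = {c: 0 for c in Category}
        for rec in chim_meta:
            counts[categorize_read(rec, bins, focal_bin, min_length)] += 1
        dist = {c.value: 100.0 * n / len(chim_meta) for c, n in counts.items()}
    return ChimeraStats(
        chimeric_fraction=len(chimeric) / n_total if n_total else 0.0,
        softclip_vs_sag_chimeric=_softclip_fraction(chimeric),
        softclip_vs_sag_other=_softclip_fraction(others),
        edge_fraction_chimeric=_edge_fraction(chimeric),
        edge_fraction_other=_edge_fraction(others),
        category_distribution=dist,
    )


def write_calls(path: str | Path, calls: ChimeraCallSet) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tsamples\n")
        for rid in sorted(calls.candidate_reads):
            status = "rescued" if rid in calls.rescued_reads else "chimeric"
            fh.write(f"{rid}\t{status}\t{','.join(calls.candidate_samples.get(rid, []))}\n")
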