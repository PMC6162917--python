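"""Shared data containers, file formats and configuration.

Everything the pipeline exchanges on disk is plain text: FASTA for
sequences, SAM for read alignments, TSV for tables, JSON for the
configuration and run summaries.  Readers are lossless with respect to
the fields the pipeline consumes; SAM flag semantics (unmapped,
secondary, duplicate) are honoured via pysam.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger("sagmag")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Alignment records
# ---------------------------------------------------------------------------

#: CIGAR operations that consume query bases
_QUERY_OPS = frozenset("MIS")
#: CIGAR operations that consume reference bases
_REF_OPS = frozenset("MD")


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-vs-contig alignment (a minimal SAM line).

    ``position`` is the 1-based leftmost target coordinate.  ``cigar`` is a
    tuple of ``(op, length)`` pairs over M/I/D/S/H.  ``mismatches`` carries
    the NM-style edit count and may be ``None`` when the tag is absent.
    """

    read_id: str
    mapped: bool
    read_length: int
    primary: bool = True
    duplicate: bool = False
    target_id: str | None = None
    position: int | None = None
    cigar: tuple[tuple[str, int], ...] | None = None
    mismatches: int | None = None

    def __post_init__(self) -> None:
        if self.mapped:
            if self.target_id is None or self.position is None or self.cigar is None:
                raise ValueError(f"mapped record {self.read_id!r} missing target/position/cigar")
            if self.position < 1:
                raise ValueError(f"record {self.read_id!r}: position must be >= 1")
            consumed = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if consumed != self.read_length:
                raise ValueError(
                    f"record {self.read_id!r}: cigar consumes {consumed} query bases, "
                    f"read_length is {self.read_length}"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def aligned_query_bases(self) -> int:
        """Query bases inside the aligned (M) region."""
        return sum(n for op, n in self.cigar or () if op == "M")

    @property
    def clipped_bases(self) -> int:
        """Total clipped query bases (soft + hard, both ends)."""
        return sum(n for op, n in self.cigar or () if op in "SH")

    @property
    def max_single_clip(self) -> int:
        return max((n for op, n in self.cigar or () if op in "SH"), default=0)

    @property
    def left_clip(self) -> int:
        cig = self.cigar or ()
        return cig[0][1] if cig and cig[0][0] in "SH" else 0

    @property
    def right_clip(self) -> int:
        cig = self.cigar or ()
        return cig[-1][1] if cig and cig[-1][0] in "SH" else 0

    @property
    def reference_span(self) -> int:
        """Target bases covered by the alignment (M + D)."""
        return sum(n for op, n in self.cigar or () if op in _REF_OPS)

    @property
    def substitutions(self) -> int | None:
        """Mismatch count net of indels (NM minus inserted+deleted bases)."""
        if self.mismatches is None:
            return None
        indel = sum(n for op, n in self.cigar or () if op in "ID")
        return max(self.mismatches - indel, 0)

    def target_interval(self) -> tuple[int, int]:
        """0-based half-open covered interval on the target."""
        if not self.mapped:
            raise ValueError("unmapped record has no target interval")
        start = self.position - 1
        return start, start + self.reference_span


def cigar_to_string(cigar: Iterable[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in "MIDSH":
                raise ValueError(f"unsupported CIGAR {text!r}")
            ops.append((ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"truncated CIGAR {text!r}")
    return tuple(ops)


_PYSAM_OPS = "MIDNSHP=X"


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read a SAM file into :class:`AlignmentRecord` objects.

    Unmapped, secondary/supplementary and duplicate flags are honoured;
    secondary records are kept but marked non-primary so callers can filter.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            primary = not (seg.is_secondary or seg.is_supplementary)
            if seg.is_unmapped:
                length = seg.query_length or (len(seg.query_sequence) if seg.query_sequence else 0)
                records.append(
                    AlignmentRecord(
                        read_id=seg.query_name,
                        mapped=False,
                        read_length=length,
                        primary=primary,
                        duplicate=seg.is_duplicate,
                    )
                )
                continue
            cigar = tuple(
                (_PYSAM_OPS[op], n) for op, n in (seg.cigartuples or ()) if _PYSAM_OPS[op] in "MIDSH"
            )
            length = sum(n for op, n in cigar if op in _QUERY_OPS)
            nm = seg.get_tag("NM") if seg.has_tag("NM") else None
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    mapped=True,
                    read_length=length,
                    primary=primary,
                    duplicate=seg.is_duplicate,
                    target_id=seg.reference_name,
                    position=seg.reference_start + 1,
                    cigar=cigar,
                    mismatches=nm,
                )
            )
    return records


def write_sam(
    path: str | Path,
    records: Sequence[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    sequences: Mapping[str, str] | None = None,
) -> None:
    """Write records as plain-text SAM with @SQ headers and NM:i tags."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in reference_lengths:
            fh.write(f"@SQ\tSN:{name}\tLN:{reference_lengths[name]}\n")
        for rec in records:
            flag = 0
            if not rec.mapped:
                flag |= 4
            if not rec.primary:
                flag |= 256
            if rec.duplicate:
                flag |= 1024
            seq = sequences.get(rec.read_id, "*") if sequences else "*"
            if seq == "*" and not rec.mapped and rec.read_length:
                # SEQ is the only carrier of an unmapped read's length
                seq = "N" * rec.read_length
            if rec.mapped:
                fields = [
                    rec.read_id,
                    str(flag),
                    rec.target_id,
                    str(rec.position),
                    "60",
                    cigar_to_string(rec.cigar),
                    "*",
                    "0",
                    "0",
                    seq,
                    "*",
                ]
                if rec.mismatches is not None:
                    fields.append(f"NM:i:{rec.mismatches}")
            else:
                fields = [rec.read_id, str(flag), "*", "0", "0", "*", "*", "0", "0", seq, "*"]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Bin table
# ---------------------------------------------------------------------------


@dataclass
class BinTable:
    """Contig lengths and bin membership.

    Contigs shorter than ``min_binned_length`` were never subject to binning
    and carry ``bin_id = None``.
    """

    contigs: dict[str, tuple[int, str | None]] = field(default_factory=dict)
    min_binned_length: int = 1000

    def add(self, contig_id: str, length: int, bin_id: str | None) -> None:
        if length <= 0:
            raise ValueError(f"contig {contig_id!r}: length must be > 0")
        if bin_id is not None and length < self.min_binned_length:
            raise ValueError(
                f"contig {contig_id!r}: binned but shorter than {self.min_binned_length}"
            )
        self.contigs[contig_id] = (length, bin_id)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.contigs

    def length_of(self, contig_id: str) -> int:
        return self.contigs[contig_id][0]

    def bin_of(self, contig_id: str) -> str | None:
        return self.contigs[contig_id][1]

    def is_binned(self, contig_id: str) -> bool:
        return self.contigs[contig_id][1] is not None

    def bins(self) -> set[str]:
        return {b for _, b in self.contigs.values() if b is not None}

    def contigs_in_bin(self, bin_id: str) -> list[str]:
        return [c for c, (_, b) in self.contigs.items() if b == bin_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig_id\tbin_id\tlength\n")
            for contig_id, (length, bin_id) in self.contigs.items():
                fh.write(f"{contig_id}\t{bin_id if bin_id is not None else '-'}\t{length}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, min_binned_length: int = 1000) -> "BinTable":
        table = cls(min_binned_length=min_binned_length)
        df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "bin_id": str})
        for col in ("contig_id", "bin_id", "length"):
            if col not in df.columns:
                raise ValueError(f"bin table {path}: missing column {col!r}")
        for row in df.itertuples(index=False):
            bin_id = None if row.bin_id in ("-", "", None) or pd.isna(row.bin_id) else row.bin_id
            table.add(row.contig_id, int(row.length), bin_id)
        return table


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping (uppercased)."""
    sequences: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0]
            if name in sequences:
                raise ValueError(f"{path}: duplicate sequence id {name!r}")
            sequences[name] = seq.upper()
    if not sequences:
        raise ValueError(f"{path}: no sequences found")
    return sequences


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignment blocks (coords-style TSV)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentBlock:
    """One block of a genome-vs-genome alignment, 0-based half-open."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start or self.target_end <= self.target_start:
            raise ValueError("alignment block intervals must be non-empty")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("block identity must lie in [0, 100]")

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start


_BLOCK_COLUMNS = ["query_id", "target_id", "qstart", "qend", "tstart", "tend", "pct_identity"]


def read_blocks(path: str | Path) -> list[AlignmentBlock]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"block table {path}: missing column {missing[0]!r}")
    return [
        AlignmentBlock(
            str(r.query_id), str(r.target_id),
            int(r.qstart), int(r.qend), int(r.tstart), int(r.tend),
            float(r.pct_identity),
        )
        for r in df.itertuples(index=False)
    ]


def write_blocks(path: str | Path, blocks: Iterable[AlignmentBlock]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_BLOCK_COLUMNS) + "\n")
        for b in blocks:
            fh.write(
                f"{b.query_id}\t{b.target_id}\t{b.query_start}\t{b.query_end}"
                f"\t{b.target_start}\t{b.target_end}\t{b.identity:.4f}\n"
            )


# ---------------------------------------------------------------------------
# Count tables (SCG markers, COG categories)
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a genome x feature count TSV (first column = genome_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"count table {path}: negative counts")
    return df.astype(int)


def write_count_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="genome_id")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All numeric thresholds of the comparison pipeline in one place.

    Defaults are the published operating points of each stage: 15-mer
    sketches of 100,000 hashes and a 0.1 clustering cutoff; a 1 kb binning
    threshold; chimera candidacy at >=20 soft-clipped bases, an aligned
    region of at least half the read and at most 2 mismatches, with rescue
    by any >=95 %-aligned, <5-mismatch mapping; a 5 % aligned-fraction
    split for the contamination screen with 100-base coverage accounting
    capped at 3x the median; 139/36-gene marker sets; 99,999 ANOSIM
    permutations.
    """

    sketch_k: int = 15
    sketch_size: int = 100_000
    cluster_cutoff: float = 0.1
    binning_min_length: int = 1000
    min_softclip: int = 20
    clip_mode: str = "total"  # or "single": largest single clip
    chimera_match_fraction: float = 0.5
    chimera_max_mismatches: int = 2
    nonchimeric_fraction: float = 0.95
    nonchimeric_max_mismatches: int = 5
    split_threshold: float = 0.05
    coverage_read_length: int = 100
    coverage_cap_multiplier: float = 3.0
    pc_outlier_quantile: float = 0.975
    low_coverage_fraction: float = 0.1
    marker_set: str = "scg139"
    approval_min_unique: int = 30
    approval_max_multicopy: int = 2
    duplicate_min_element: int = 100
    duplicate_min_contig: int = 1000
    n_permutations: int = 99_999
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
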