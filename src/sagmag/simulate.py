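"""Synthetic community generator with a full ground-truth manifest.

Builds everything the comparison pipeline consumes, with every artifact
class planted and labelled:

* source genomes, each with a distinct order-``markov_order`` Markov
  composition so tetranucleotide signatures separate genomes;
* a metagenome contig pool tiling the genomes, with a fraction of sub-1-kb
  contigs (excluded from binning), a fraction of long contigs assigned to a
  wrong bin (planted binning false negatives), and a fraction of each
  genome left without any contig (assembly gaps);
* one SAG per selected genome: multiple-displacement-amplification-like
  segment amplification (heavy-tailed Gamma weights), zero-coverage dropout
  intervals, inversion-chimera reads, and foreign-composition contaminant
  contigs drawn from genomes outside the community (hence at low
  metagenome coverage);
* alignment records of SAG reads versus the metagenome and versus the
  SAG's own contigs, consistent with the truth (substitution-free, with
  soft clips where a chimera arm or a contig boundary forces one);
* marker-gene (SCG) and COG-category count tables.

A single integer seed determines every output byte.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AlignmentBlock,
    AlignmentRecord,
    BinTable,
    logger,
    write_blocks,
    write_count_table,
    write_fasta,
    write_sam,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: COG functional categories used by the synthetic annotation tables
COG_CATEGORIES = list("JAKLBDYVTMNZWUOCGEFHIPQRS")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Configuration and truth manifest
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the synthetic community.

    Defaults describe a small five-genome community whose focal SAG carries
    roughly 20,000 reads (depth 10x over a 200-kb genome at 100-base
    reads), 5 % misbinned long contigs, 20 % amplification dropout and 2 %
    inversion chimeras.
    """

    n_genomes: int = 5
    genome_length: int = 200_000
    markov_order: int = 3
    contig_len_range: tuple[int, int] = (1000, 5000)
    short_contig_fraction: float = 0.1
    misbin_rate: float = 0.05
    metagenome_coverage: float = 0.92
    sag_dropout: float = 0.2
    sag_read_length: int = 100
    sag_depth: float = 10.0
    chimera_rate: float = 0.02
    contam_contig_count: int = 4
    contam_coverage_fraction: float = 0.05
    meta_read_depth: float = 20.0
    n_foreign_genomes: int = 2
    n_sags: int | None = None  # None: one SAG per genome
    n_read_sags: int = 1  # reads simulated for the first n SAGs
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "short_contig_fraction",
            "misbin_rate",
            "metagenome_coverage",
            "chimera_rate",
            "contam_coverage_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 <= self.sag_dropout < 1.0:
            raise ValueError(f"sag_dropout must lie in [0, 1), got {self.sag_dropout}")
        if self.n_genomes < 1:
            raise ValueError(f"n_genomes must be >= 1, got {self.n_genomes}")
        if self.markov_order < 0:
            raise ValueError(f"markov_order must be >= 0, got {self.markov_order}")
        cmin, cmax = self.contig_len_range
        if not 0 < cmin <= cmax:
            raise ValueError(f"contig_len_range must satisfy 0 < min <= max, got {self.contig_len_range}")
        if self.genome_length < 10 * cmax:
            raise ValueError(
                f"genome_length must be >= 10 x contig_len_range max ({10 * cmax}), got {self.genome_length}"
            )
        if self.sag_read_length < 100:
            raise ValueError(f"sag_read_length must be >= 100, got {self.sag_read_length}")
        if self.misbin_rate > 0 and self.n_genomes < 2:
            raise ValueError("misbin_rate > 0 requires n_genomes >= 2 (no wrong bin exists)")
        if self.contam_contig_count > 0 and self.n_foreign_genomes < 1:
            raise ValueError("contam_contig_count > 0 requires n_foreign_genomes >= 1")


@dataclass
class TruthManifest:
    """Ground truth of a simulated community; the oracle for every screen."""

    contig_source: dict[str, str] = field(default_factory=dict)
    contig_bin_truth: dict[str, str] = field(default_factory=dict)
    contig_interval: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    misbinned: set[str] = field(default_factory=set)
    read_source: dict[str, tuple[str, tuple[int, int]]] = field(default_factory=dict)
    chimeric_reads: set[str] = field(default_factory=set)
    chimera_arms: dict[str, tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=dict)
    contaminant_contigs: set[str] = field(default_factory=set)
    contaminant_reads: set[str] = field(default_factory=set)
    contam_read_origin: dict[str, tuple[str, int]] = field(default_factory=dict)
    dropout_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    sag_contig_interval: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["misbinned"] = sorted(self.misbinned)
        data["chimeric_reads"] = sorted(self.chimeric_reads)
        data["contaminant_contigs"] = sorted(self.contaminant_contigs)
        data["contaminant_reads"] = sorted(self.contaminant_reads)
        with open(path, "w") as fh:
            json.dump(data, fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            contig_source=data["contig_source"],
            contig_bin_truth=data["contig_bin_truth"],
            contig_interval={k: tuple(v) for k, v in data["contig_interval"].items()},
            misbinned=set(data["misbinned"]),
            read_source={k: (v[0], tuple(v[1])) for k, v in data["read_source"].items()},
            chimeric_reads=set(data["chimeric_reads"]),
            chimera_arms={k: (tuple(v[0]), tuple(v[1])) for k, v in data["chimera_arms"].items()},
            contaminant_contigs=set(data["contaminant_contigs"]),
            contaminant_reads=set(data["contaminant_reads"]),
            contam_read_origin={k: tuple(v) for k, v in data["contam_read_origin"].items()},
            dropout_intervals=[tuple(v) for v in data["dropout_intervals"]],
            sag_contig_interval={k: tuple(v) for k, v in data["sag_contig_interval"].items()},
        )


# ---------------------------------------------------------------------------
# Genome simulation (Markov composition models)
# ---------------------------------------------------------------------------


def markov_transitions(rng: np.random.Generator, order: int, alpha: float = 1.0) -> np.ndarray:
    """Dirichlet-sampled transition rows, one per 4**order context."""
    n_ctx = 4**order
    return rng.dirichlet(np.full(4, alpha), size=n_ctx)


def generate_markov_genome(
    rng: np.random.Generator,
    length: int,
    order: int,
    transitions: np.ndarray | None = None,
) -> str:
    """Generate one sequence from a Markov chain over {A,C,G,T}.

    With ``transitions=None`` a fresh Dirichlet-sampled model is drawn from
    ``rng``; passing explicit rows (e.g. uniform 0.25s) makes the
    composition exactly controllable.
    """
    if transitions is None:
        transitions = markov_transitions(rng, order)
    n_ctx = 4**order
    if transitions.shape != (n_ctx, 4):
        raise ValueError(f"transitions must have shape ({n_ctx}, 4)")
    cum_rows = [row.tolist() for row in np.cumsum(transitions, axis=1)]
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    ctx = 0
    mask = n_ctx - 1
    for i in range(length):
        b = bisect_right(cum_rows[ctx], u[i])
        if b > 3:
            b = 3
        out[i] = b
        ctx = ((ctx << 2) | b) & mask
    return bytes(_BASES[out]).decode()


def simulate_genomes(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Simulate ``n_genomes`` community genomes with distinct compositions."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return {
        f"G{i + 1:02d}": generate_markov_genome(rng, config.genome_length, config.markov_order)
        for i in range(config.n_genomes)
    }


def simulate_foreign_genomes(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Extra genomes outside the community: sources for SAG contamination."""
    return {
        f"X{i + 1:02d}": generate_markov_genome(rng, config.genome_length, config.markov_order)
        for i in range(config.n_foreign_genomes)
    }


# ---------------------------------------------------------------------------
# Metagenome simulation
# ---------------------------------------------------------------------------


def simulate_metagenome(
    genomes: Mapping[str, str],
    config: SimConfig,
    rng: np.random.Generator,
    truth: TruthManifest | None = None,
) -> tuple[dict[str, str], BinTable, TruthManifest]:
    """Tile genomes into contigs, bin the long ones, plant misbinning.

    Contigs >= 1 kb are assigned to their source bin except a
    ``misbin_rate`` fraction sent to a uniformly chosen wrong bin (recorded
    in ``truth.misbinned``); shorter contigs carry no bin.  A
    ``1 - metagenome_coverage`` fraction of each genome receives no contig
    at all, standing in for metagenome assembly gaps.
    """
    if not genomes:
        raise ValueError("genomes must be nonempty")
    config.validate()
    if truth is None:
        truth = TruthManifest()
    genome_ids = list(genomes)
    bin_ids = {g: f"bin{i + 1:02d}" for i, g in enumerate(genome_ids)}
    contigs: dict[str, str] = {}
    bins = BinTable()
    counter = 0
    cmin, cmax = config.contig_len_range
    for g in genome_ids:
        seq = genomes[g]
        length = len(seq)
        pos = 0
        while pos < length:
            if rng.random() < config.short_contig_fraction:
                clen = int(rng.integers(200, 1000))
            else:
                clen = int(rng.integers(cmin, cmax + 1))
            clen = min(clen, length - pos)
            # absorb a genome tail that would be shorter than the minimum
            if length - pos - clen < cmin:
                clen = length - pos
            end = pos + clen
            covered = rng.random() < config.metagenome_coverage
            if covered:
                cid = f"mc{counter:06d}"
                counter += 1
                contigs[cid] = seq[pos:end]
                truth.contig_source[cid] = g
                truth.contig_bin_truth[cid] = bin_ids[g]
                truth.contig_interval[cid] = (g, pos, end)
                if end - pos >= 1000:
                    assigned = bin_ids[g]
                    if rng.random() < config.misbin_rate:
                        others = [bin_ids[x] for x in genome_ids if x != g]
                        assigned = others[int(rng.integers(len(others)))]
                        truth.misbinned.add(cid)
                    bins.add(cid, end - pos, assigned)
                else:
                    bins.add(cid, end - pos, None)
            pos = end
    logger.info(
        "simulate_metagenome: %d contigs (%d binned, %d misbinned planted)",
        len(contigs), sum(1 for c in contigs if bins.is_binned(c)), len(truth.misbinned),
    )
    return contigs, bins, truth


# ---------------------------------------------------------------------------
# SAG simulation (MDA artifacts)
# ---------------------------------------------------------------------------


@dataclass
class SagSample:
    sag_id: str
    genome_id: str
    contigs: dict[str, str]
    reads: dict[str, str]
    meta_read_counts: dict[str, int]


def simulate_sag(
    sag_id: str,
    genome_id: str,
    genome: str,
    foreign_genomes: Mapping[str, str],
    config: SimConfig,
    rng: np.random.Generator,
    truth: TruthManifest | None = None,
    with_reads: bool = True,
) -> tuple[SagSample, TruthManifest]:
    """Simulate one SAG: dropout, uneven amplification, chimeras, contaminants.

    The genome is partitioned into 2-10 kb amplification segments.  Random
    segments totalling ``sag_dropout`` of the genome are dropped (zero
    coverage); the rest receive independent Gamma(0.3) amplification
    weights and reads are placed multinomially.  A ``chimera_rate``
    fraction of reads joins a forward arm to the reverse complement of a
    segment within 5 kb.  ``contam_contig_count`` contigs from foreign
    genomes are spliced into the assembly at random positions, together
    with low-depth reads drawn from them.  Per-contig metagenome read
    counts are emitted with contaminants at ``contam_coverage_fraction``
    of the community depth.
    """
    config.validate()
    if config.sag_dropout >= 1.0:
        raise ValueError(f"sag_dropout must be < 1, got {config.sag_dropout}")
    if truth is None:
        truth = TruthManifest()
    length = len(genome)
    read_len = config.sag_read_length

    # amplification segments
    segments: list[tuple[int, int]] = []
    pos = 0
    while pos < length:
        seglen = int(rng.integers(2000, 10_001))
        end = min(pos + seglen, length)
        segments.append((pos, end))
        pos = end

    # dropout: accumulate shuffled segments until the target is reached
    target = config.sag_dropout * length
    dropped: set[int] = set()
    total = 0
    for idx in rng.permutation(len(segments)):
        if total >= target:
            break
        dropped.add(int(idx))
        s, e = segments[idx]
        total += e - s
    for idx in sorted(dropped):
        s, e = segments[idx]
        truth.dropout_intervals.append((genome_id, s, e))

    # SAG contigs: maximal runs of kept segments
    genuine: list[tuple[int, int]] = []
    run_start: int | None = None
    for i, (s, e) in enumerate(segments):
        if i in dropped:
            if run_start is not None:
                genuine.append((run_start, segments[i - 1][1]))
                run_start = None
        elif run_start is None:
            run_start = s
    if run_start is not None:
        genuine.append((run_start, segments[-1][1]))

    # contaminant contigs from foreign genomes
    foreign_ids = list(foreign_genomes)
    contam: list[tuple[str, int, int]] = []
    for _ in range(config.contam_contig_count):
        fg = foreign_ids[int(rng.integers(len(foreign_ids)))]
        clen = int(rng.integers(2000, 8001))
        fstart = int(rng.integers(0, len(foreign_genomes[fg]) - clen + 1))
        contam.append((fg, fstart, fstart + clen))

    # splice contaminants into the contig order, then name sequentially
    entries: list[tuple[str, object]] = [("genuine", iv) for iv in genuine]
    for item in contam:
        pos_ins = int(rng.integers(0, len(entries) + 1))
        entries.insert(pos_ins, ("contam", item))
    contigs: dict[str, str] = {}
    for i, (kind, item) in enumerate(entries):
        cid = f"{sag_id}_c{i:03d}"
        if kind == "genuine":
            s, e = item  # type: ignore[misc]
            contigs[cid] = genome[s:e]
            truth.sag_contig_interval[cid] = (genome_id, s, e)
        else:
            fg, fs, fe = item  # type: ignore[misc]
            contigs[cid] = foreign_genomes[fg][fs:fe]
            truth.contaminant_contigs.add(cid)
            truth.contig_source[cid] = fg
            truth.contig_interval[cid] = (fg, fs, fe)

    # metagenome read counts per SAG contig (coverage substrate for the
    # contamination screen): community depth for genuine contigs, a small
    # fraction of it for contaminants
    meta_counts: dict[str, int] = {}
    for cid, seq in contigs.items():
        depth = config.meta_read_depth
        if cid in truth.contaminant_contigs:
            depth *= config.contam_coverage_fraction
        lam = len(seq) / 100.0 * depth
        meta_counts[cid] = int(rng.poisson(lam))

    reads: dict[str, str] = {}
    if with_reads:
        kept = [seg for i, seg in enumerate(segments) if i not in dropped]
        usable = np.array([e - s if e - s >= read_len else 0 for s, e in kept], dtype=float)
        weights = rng.gamma(0.3, 1.0, size=len(kept)) * usable
        if weights.sum() == 0:
            raise ValueError("no amplifiable segment remains after dropout")
        n_reads = int(round(config.sag_depth * length / read_len))
        counts = rng.multinomial(n_reads, weights / weights.sum())
        chim_flags = rng.random(n_reads) < config.chimera_rate
        ridx = 0
        for (s, e), cnt in zip(kept, counts):
            if cnt == 0:
                continue
            starts = rng.integers(s, e - read_len + 1, size=cnt)
            for p in starts:
                p = int(p)
                rid = f"{sag_id}_r{ridx:06d}"
                if chim_flags[ridx]:
                    b = int(rng.integers(20, read_len - 19))
                    arm2_len = read_len - b
                    delta = int(rng.integers(-5000, 5001))
                    q = min(max(p + delta, 0), length - arm2_len)
                    reads[rid] = genome[p : p + b] + reverse_complement(genome[q : q + arm2_len])
                    truth.chimeric_reads.add(rid)
                    truth.chimera_arms[rid] = ((p, p + b), (q, q + arm2_len))
                    longer = (p, p + b) if b >= arm2_len else (q, q + arm2_len)
                    truth.read_source[rid] = (genome_id, longer)
                else:
                    reads[rid] = genome[p : p + read_len]
                    truth.read_source[rid] = (genome_id, (p, p + read_len))
                ridx += 1
        # low-depth reads from contaminant contigs (carried-over foreign DNA)
        for cid in sorted(truth.contaminant_contigs):
            if not cid.startswith(f"{sag_id}_"):
                continue
            seq = contigs[cid]
            n_c = max(1, int(round(len(seq) / read_len)))
            fg, fs, _ = truth.contig_interval[cid]
            for p in rng.integers(0, len(seq) - read_len + 1, size=n_c):
                p = int(p)
                rid = f"{sag_id}_r{ridx:06d}"
                ridx += 1
                reads[rid] = seq[p : p + read_len]
                truth.read_source[rid] = (fg, (fs + p, fs + p + read_len))
                truth.contaminant_reads.add(rid)
                truth.contam_read_origin[rid] = (cid, p)
    sample = SagSample(sag_id, genome_id, contigs, reads, meta_counts)
    logger.info(
        "simulate_sag %s: %d contigs (%d contaminant), %d reads (%d chimeric)",
        sag_id, len(contigs), sum(1 for c in contigs if c in truth.contaminant_contigs),
        len(reads), sum(1 for r in reads if r in truth.chimeric_reads),
    )
    return sample, truth


# ---------------------------------------------------------------------------
# Alignment emission
# ---------------------------------------------------------------------------


class _ContigIndex:
    """Locate the contig overlapping a genome interval (per source genome)."""

    def __init__(self, intervals: Mapping[str, tuple[str, int, int]]):
        self._by_genome: dict[str, tuple[list[int], list[tuple[str, int, int]]]] = {}
        per_genome: dict[str, list[tuple[str, int, int]]] = {}
        for cid, (g, s, e) in intervals.items():
            per_genome.setdefault(g, []).append((cid, s, e))
        for g, items in per_genome.items():
            items.sort(key=lambda x: x[1])
            self._by_genome[g] = ([s for _, s, _ in items], items)

    def best_overlap(self, genome: str, start: int, end: int) -> tuple[str, int, int, int] | None:
        """Contig with the largest overlap of [start, end); ties to leftmost."""
        if genome not in self._by_genome:
            return None
        starts, items = self._by_genome[genome]
        lo = bisect_right(starts, start) - 1
        best: tuple[str, int, int, int] | None = None
        i = max(lo, 0)
        while i < len(items) and items[i][1] < end:
            cid, cs, ce = items[i]
            ov = min(end, ce) - max(start, cs)
            if ov > 0 and (best is None or ov > best[3]):
                best = (cid, cs, ce, ov)
            i += 1
        return best


def _clipped_record(
    rid: str, read_len: int, aligned: tuple[int, int], is_prefix: bool,
    cid: str, contig_start: int,
) -> AlignmentRecord:
    """Alignment of one read arm; the other arm is soft-clipped."""
    arm_len = aligned[1] - aligned[0]
    clip = read_len - arm_len
    if clip == 0:
        cigar: tuple[tuple[str, int], ...] = (("M", arm_len),)
    elif is_prefix:
        cigar = (("M", arm_len), ("S", clip))
    else:
        cigar = (("S", clip), ("M", arm_len))
    return AlignmentRecord(
        read_id=rid, mapped=True, read_length=read_len,
        target_id=cid, position=aligned[0] - contig_start + 1,
        cigar=cigar, mismatches=0,
    )


def emit_alignments(
    truth: TruthManifest,
    read_ids: Sequence[str],
    contig_intervals: Mapping[str, tuple[str, int, int]],
    read_lengths: Mapping[str, int],
    contam_targets: bool = False,
) -> list[AlignmentRecord]:
    """Emit one primary alignment (or unmapped record) per read.

    Non-chimeric reads fully inside a contig of their source genome align
    end to end; reads spanning a contig boundary align to the contig
    holding the majority of the read with the remainder soft-clipped;
    reads over regions without a contig are unmapped.  Chimeric reads
    align their longer arm (falling back to the shorter) with the other
    arm soft-clipped.  With ``contam_targets`` the target set includes the
    SAG's own contaminant contigs, so contaminant-derived reads map there;
    otherwise (the metagenome side) they are unmapped.
    """
    index = _ContigIndex(contig_intervals)
    records: list[AlignmentRecord] = []
    for rid in read_ids:
        read_len = read_lengths[rid]
        if rid in truth.contaminant_reads:
            if contam_targets:
                cid, offset = truth.contam_read_origin[rid]
                records.append(
                    AlignmentRecord(
                        read_id=rid, mapped=True, read_length=read_len,
                        target_id=cid, position=offset + 1,
                        cigar=(("M", read_len),), mismatches=0,
                    )
                )
            else:
                records.append(AlignmentRecord(read_id=rid, mapped=False, read_length=read_len))
            continue
        genome, _ = truth.read_source[rid]
        if rid in truth.chimeric_reads:
            arm1, arm2 = truth.chimera_arms[rid]
            order = [(arm1, True), (arm2, False)]
            order.sort(key=lambda a: a[0][1] - a[0][0], reverse=True)
            placed = False
            for arm, is_prefix in order:
                hit = index.best_overlap(genome, arm[0], arm[1])
                if hit is not None and hit[1] <= arm[0] and arm[1] <= hit[2]:
                    records.append(
                        _clipped_record(rid, read_len, arm, is_prefix, hit[0], hit[1])
                    )
                    placed = True
                    break
            if not placed:
                records.append(AlignmentRecord(read_id=rid, mapped=False, read_length=read_len))
            continue
        start, end = truth.read_source[rid][1]
        hit = index.best_overlap(genome, start, end)
        if hit is None or 2 * hit[3] < read_len:
            records.append(AlignmentRecord(read_id=rid, mapped=False, read_length=read_len))
            continue
        cid, cs, ce, _ = hit
        ov_s, ov_e = max(start, cs), min(end, ce)
        left_clip = ov_s - start
        right_clip = end - ov_e
        cigar: list[tuple[str, int]] = []
        if left_clip:
            cigar.append(("S", left_clip))
        cigar.append(("M", ov_e - ov_s))
        if right_clip:
            cigar.append(("S", right_clip))
        records.append(
            AlignmentRecord(
                read_id=rid, mapped=True, read_length=read_len,
                target_id=cid, position=ov_s - cs + 1,
                cigar=tuple(cigar), mismatches=0,
            )
        )
    return records


def emit_sag_mag_blocks(
    truth: TruthManifest,
    sag: SagSample,
    bins: BinTable,
    focal_bin: str,
) -> list[AlignmentBlock]:
    """Truth-emitted alignment blocks of SAG contigs versus the focal MAG."""
    blocks: list[AlignmentBlock] = []
    mag_contigs = [
        (cid, truth.contig_interval[cid])
        for cid in bins.contigs_in_bin(focal_bin)
        if truth.contig_interval[cid][0] == sag.genome_id
    ]
    for cid in sag.contigs:
        if cid in truth.contaminant_contigs:
            continue
        g, s, e = truth.sag_contig_interval[cid]
        for mcid, (mg, ms, me) in mag_contigs:
            ov_s, ov_e = max(s, ms), min(e, me)
            if ov_e > ov_s:
                blocks.append(
                    AlignmentBlock(cid, mcid, ov_s - s, ov_e - s, ov_s - ms, ov_e - ms, 100.0)
                )
    return blocks


# ---------------------------------------------------------------------------
# Annotation tables (SCG markers, COG categories)
# ---------------------------------------------------------------------------


def marker_set(size: int) -> list[str]:
    """Generic identifiers for a named single-copy-gene set."""
    return [f"scg{size}_{i + 1:03d}" for i in range(size)]


def simulate_marker_table(
    genome_labels: Mapping[str, str],
    set_size: int,
    rng: np.random.Generator,
    mag_presence: float = 0.93,
    sag_presence: float = 0.5,
    duplicate_prob: float = 0.03,
) -> pd.DataFrame:
    """Plant SCG presence/absence per genome (role "MAG" or "SAG")."""
    markers = marker_set(set_size)
    rows = {}
    for label, role in genome_labels.items():
        p = mag_presence if role == "MAG" else sag_presence
        present = rng.random(set_size) < p
        extra = (rng.random(set_size) < duplicate_prob) & present
        rows[label] = present.astype(int) + extra.astype(int)
    return pd.DataFrame.from_dict(rows, orient="index", columns=markers)


def simulate_cog_table(
    genome_source: Mapping[str, tuple[str, str]],
    rng: np.random.Generator,
    mag_genes: int = 2500,
    sag_genes: int = 1200,
) -> pd.DataFrame:
    """COG-category counts; genomes of one source share a category profile.

    ``genome_source`` maps label -> (source genome id, role).  Each source
    genome receives a Dirichlet-sampled category profile, so SAG/MAG pairs
    from the same organism have similar functional profiles while
    organisms differ.
    """
    sources = sorted({src for src, _ in genome_source.values()})
    profiles = {src: rng.dirichlet(np.full(len(COG_CATEGORIES), 5.0)) for src in sources}
    rows = {}
    for label, (src, role) in genome_source.items():
        n = mag_genes if role == "MAG" else sag_genes
        rows[label] = rng.multinomial(n, profiles[src])
    return pd.DataFrame.from_dict(rows, orient="index", columns=COG_CATEGORIES)


# ---------------------------------------------------------------------------
# Whole-community orchestration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCommunity:
    config: SimConfig
    genomes: dict[str, str]
    foreign_genomes: dict[str, str]
    metagenome_contigs: dict[str, str]
    bins: BinTable
    bin_of_genome: dict[str, str]
    sags: list[SagSample]
    truth: TruthManifest
    meta_alignments: dict[str, list[AlignmentRecord]]
    sag_alignments: dict[str, list[AlignmentRecord]]
    mag_blocks: dict[str, list[AlignmentBlock]]
    marker_table_139: pd.DataFrame
    marker_table_36: pd.DataFrame
    cog_table: pd.DataFrame


def simulate_community(config: SimConfig) -> SyntheticCommunity:
    """Run the full generator from one seed; every output is deterministic."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genomes = simulate_genomes(config, rng)
    foreign = simulate_foreign_genomes(config, rng)
    truth = TruthManifest()
    contigs, bins, truth = simulate_metagenome(genomes, config, rng, truth)
    genome_ids = list(genomes)
    bin_of_genome = {g: f"bin{i + 1:02d}" for i, g in enumerate(genome_ids)}

    n_sags = config.n_sags if config.n_sags is not None else config.n_genomes
    sags: list[SagSample] = []
    meta_aln: dict[str, list[AlignmentRecord]] = {}
    sag_aln: dict[str, list[AlignmentRecord]] = {}
    mag_blocks: dict[str, list[AlignmentBlock]] = {}
    for i in range(n_sags):
        g = genome_ids[i % len(genome_ids)]
        sag_id = f"S{i + 1:02d}"
        sample, truth = simulate_sag(
            sag_id, g, genomes[g], foreign, config, rng, truth,
            with_reads=i < config.n_read_sags,
        )
        sags.append(sample)
        mag_blocks[sag_id] = emit_sag_mag_blocks(truth, sample, bins, bin_of_genome[g])
        if sample.reads:
            rids = sorted(sample.reads)
            lengths = {r: len(sample.reads[r]) for r in rids}
            meta_aln[sag_id] = emit_alignments(
                truth, rids, truth.contig_interval, lengths, contam_targets=False
            )
            own_intervals = {
                cid: iv for cid, iv in truth.sag_contig_interval.items()
                if cid.startswith(f"{sag_id}_")
            }
            sag_aln[sag_id] = emit_alignments(
                truth, rids, own_intervals, lengths, contam_targets=True
            )

    labels = {bin_of_genome[g]: "MAG" for g in genome_ids}
    labels.update({s.sag_id: "SAG" for s in sags})
    marker139 = simulate_marker_table(labels, 139, rng)
    marker36 = simulate_marker_table(labels, 36, rng)
    source_map = {bin_of_genome[g]: (g, "MAG") for g in genome_ids}
    source_map.update({s.sag_id: (s.genome_id, "SAG") for s in sags})
    cogs = simulate_cog_table(source_map, rng)
    return SyntheticCommunity(
        config=config, genomes=genomes, foreign_genomes=foreign,
        metagenome_contigs=contigs, bins=bins, bin_of_genome=bin_of_genome,
        sags=sags, truth=truth, meta_alignments=meta_aln, sag_alignments=sag_aln,
        mag_blocks=mag_blocks, marker_table_139=marker139,
        marker_table_36=marker36, cog_table=cogs,
    )


def mag_sequences(community: SyntheticCommunity, bin_id: str) -> dict[str, str]:
    """Contig sequences of one MAG (the contigs assigned to its bin)."""
    return {
        cid: community.metagenome_contigs[cid]
        for cid in community.bins.contigs_in_bin(bin_id)
    }


def write_community(community: SyntheticCommunity, outdir: str | Path) -> None:
    """Write every community artifact as plain text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genomes.fasta", community.genomes)
    write_fasta(out / "metagenome_contigs.fasta", community.metagenome_contigs)
    community.bins.to_tsv(out / "bins.tsv")
    community.truth.to_json(out / "truth.json")
    meta_lengths = {c: len(s) for c, s in community.metagenome_contigs.items()}
    counts_rows = []
    for sag in community.sags:
        write_fasta(out / f"{sag.sag_id}_contigs.fasta", sag.contigs)
        if sag.reads:
            write_fasta(out / f"{sag.sag_id}_reads.fasta", sag.reads)
            write_sam(
                out / f"{sag.sag_id}_vs_metagenome.sam",
                community.meta_alignments[sag.sag_id], meta_lengths,
            )
            own_lengths = {c: len(s) for c, s in sag.contigs.items()}
            write_sam(
                out / f"{sag.sag_id}_vs_self.sam",
                community.sag_alignments[sag.sag_id], own_lengths,
            )
        write_blocks(out / f"{sag.sag_id}_vs_mag_blocks.tsv", community.mag_blocks[sag.sag_id])
        for cid, cnt in sag.meta_read_counts.items():
            counts_rows.append((sag.sag_id, cid, cnt))
    with open(out / "meta_read_counts.tsv", "w") as fh:
        fh.write("sag_id\tcontig_id\tread_count\n")
        for sag_id, cid, cnt in counts_rows:
            fh.write(f"{sag_id}\t{cid}\t{cnt}\n")
    write_count_table(out / "markers_139.tsv", community.marker_table_139)
    write_count_table(out / "markers_36.tsv", community.marker_table_36)
    write_count_table(out / "cogs.tsv", community.cog_table)
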