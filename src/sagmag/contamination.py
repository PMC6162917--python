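"""Composition + coverage screen for contaminant SAG contigs.

SAG contigs are profiled by canonical tetranucleotide frequencies (each
4-mer collapsed with its reverse complement into one of 136 classes, so
assembly strand is irrelevant) and projected onto the first two principal
components.  Contigs are split on whether at least 5 % of their length
aligns to the matching MAG; within the non-aligning set, a contig is
flagged as a likely contaminant when it is a robust outlier in PC space
relative to the aligning contigs, or when its estimated metagenome
coverage (100 bases assumed per mapped read, capped at three times the
median) is far below the SAG's typical coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genome_compare import union_length
from .io import AlignmentBlock, logger

# ---------------------------------------------------------------------------
# Canonical tetranucleotide classes
# ---------------------------------------------------------------------------


def _rc_code(code: int, k: int = 4) -> int:
    rc = 0
    for i in range(k):
        rc = (rc << 2) | (3 - ((code >> (2 * i)) & 3))
    return rc


def _build_classes() -> tuple[np.ndarray, list[str]]:
    canon_of: dict[int, int] = {}
    names: list[str] = []
    index = np.empty(256, dtype=np.int64)
    bases = "ACGT"
    for code in range(256):
        canon = min(code, _rc_code(code))
        if canon not in canon_of:
            canon_of[canon] = len(names)
            names.append("".join(bases[(canon >> (2 * i)) & 3] for i in (3, 2, 1, 0)))
        index[code] = canon_of[canon]
    return index, names


#: class index for each raw 4-mer code; 136 canonical class names
_CLASS_INDEX, TETRA_CLASSES = _build_classes()
N_TETRA_CLASSES = len(TETRA_CLASSES)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class TetraProfile:
    contig_id: str
    frequencies: np.ndarray  # length 136, sums to 1
    n_windows: int


def tetra_profile(sequence: str, contig_id: str = "") -> TetraProfile:
    """Sliding-window canonical tetranucleotide frequencies of a contig."""
    arr = _CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]
    n = len(arr) - 3
    if n < 1:
        raise ValueError(f"sequence too short for tetranucleotide profile ({len(arr)} bases)")
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(4):
        col = arr[i : i + n]
        codes = (codes << 2) | (col & 3)
        bad |= col >= 4
    codes = codes[~bad]
    if codes.size == 0:
        raise ValueError("no ACGT-only tetranucleotide window in sequence")
    counts = np.bincount(_CLASS_INDEX[codes], minlength=N_TETRA_CLASSES).astype(float)
    return TetraProfile(contig_id, counts / counts.sum(), int(codes.size))


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------


def pca_project(profiles: Sequence[TetraProfile] | np.ndarray) -> np.ndarray:
    """First two principal-component scores of the profile matrix.

    Columns are centred; axes are ordered by descending eigenvalue and the
    sign of each axis is fixed so its largest-magnitude loading is
    positive.  With rank < 2 the second coordinate is zero (warned).
    """
    if not isinstance(profiles, np.ndarray):
        matrix = np.vstack([p.frequencies for p in profiles])
    else:
        matrix = np.asarray(profiles, dtype=float)
    if matrix.shape[0] < 3:
        raise ValueError(f"PCA needs >= 3 profiles, got {matrix.shape[0]}")
    centred = matrix - matrix.mean(axis=0)
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    coords = np.zeros((matrix.shape[0], 2))
    rank = int((svals > 1e-12 * max(svals[0], 1e-300)).sum())
    if rank < 2:
        logger.warning("pca_project: profile matrix has rank < 2; second coordinate is 0")
    for axis in range(min(2, rank)):
        loading = vt[axis]
        if loading[np.argmax(np.abs(loading))] < 0:
            loading = -loading
        coords[:, axis] = centred @ loading
    return coords


# ---------------------------------------------------------------------------
# Alignment split and coverage
# ---------------------------------------------------------------------------


def split_by_alignment(
    contig_lengths: Mapping[str, int],
    blocks: Iterable[AlignmentBlock],
    threshold: float = 0.05,
) -> tuple[set[str], set[str], dict[str, float]]:
    """Split SAG contigs on MAG-aligned fraction (non-aligning: < threshold).

    Blocks from several MAGs may be passed together; aligned intervals are
    unioned per contig before the split.
    """
    per_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for b in blocks:
        if b.query_id in per_contig:
            per_contig[b.query_id].append((b.query_start, b.query_end))
    fractions = {
        c: union_length(ivs) / contig_lengths[c] for c, ivs in per_contig.items()
    }
    nonaligning = {c for c, f in fractions.items() if f < threshold}
    return set(contig_lengths) - nonaligning, nonaligning, fractions


def coverage_estimate(
    read_counts: Mapping[str, int],
    contig_lengths: Mapping[str, int],
    read_length: int = 100,
    cap_multiplier: float = 3.0,
) -> tuple[dict[str, float], dict[str, float], float]:
    """Per-contig fold coverage assuming ``read_length`` bases per read.

    Returns raw coverages, coverages capped at ``cap_multiplier`` times the
    median raw coverage, and the median itself.
    """
    coverage = {
        c: read_length * read_counts.get(c, 0) / contig_lengths[c] for c in contig_lengths
    }
    median = float(np.median(list(coverage.values()))) if coverage else 0.0
    cap = cap_multiplier * median
    capped = {c: min(v, cap) for c, v in coverage.items()}
    return coverage, capped, median


# ---------------------------------------------------------------------------
# Contaminant flagging
# ---------------------------------------------------------------------------


def _robust_distance2(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Squared distance from the reference set's median, per-axis scaled by
    1.4826 x MAD (a robust standard-deviation estimate)."""
    center = np.median(reference, axis=0)
    mad = np.median(np.abs(reference - center), axis=0)
    scale = 1.4826 * mad
    fallback = reference.std(axis=0, ddof=1) if reference.shape[0] > 1 else np.ones(2)
    scale = np.where(scale > 1e-12, scale, np.where(fallback > 1e-12, fallback, 1.0))
    z = (coords - center) / scale
    return (z**2).sum(axis=1)


def flag_contaminants(
    profiles: Sequence[TetraProfile],
    contig_lengths: Mapping[str, int],
    blocks: Iterable[AlignmentBlock],
    read_counts: Mapping[str, int],
    split_threshold: float = 0.05,
    read_length: int = 100,
    cap_multiplier: float = 3.0,
    pc_outlier_quantile: float = 0.975,
    low_coverage_fraction: float = 0.1,
) -> pd.DataFrame:
    """Full contamination report for one SAG.

    A contig is flagged iff it aligns to the MAG over less than
    ``split_threshold`` of its length AND it is either a robust PC-space
    outlier relative to the aligning contigs (squared robust distance above
    the chi-square(2) quantile) or its coverage is below
    ``low_coverage_fraction`` of the median coverage.
    """
    order = [p.contig_id for p in profiles]
    if set(order) != set(contig_lengths):
        raise ValueError("profiles and contig_lengths must cover the same contigs")
    coords = pca_project(profiles)
    aligning, nonaligning, fractions = split_by_alignment(
        contig_lengths, blocks, split_threshold
    )
    coverage, capped, median_cov = coverage_estimate(
        read_counts, contig_lengths, read_length, cap_multiplier
    )
    idx = {c: i for i, c in enumerate(order)}
    aligning_idx = [idx[c] for c in order if c in aligning]
    use_pc = len(aligning_idx) >= 3
    if use_pc:
        dist2 = _robust_distance2(coords, coords[aligning_idx])
        pc_cut = chi2.ppf(pc_outlier_quantile, df=2)
    else:
        logger.warning(
            "flag_contaminants: only %d aligning contigs; PC-outlier rule skipped",
            len(aligning_idx),
        )
        dist2 = np.full(len(order), np.nan)
        pc_cut = np.inf
    rows = []
    for c in order:
        i = idx[c]
        pc_outlier = use_pc and dist2[i] > pc_cut
        low_cov = coverage[c] < low_coverage_fraction * median_cov
        flagged = (c in nonaligning) and (pc_outlier or low_cov)
        rows.append(
            {
                "contig_id": c,
                "length": contig_lengths[c],
                "aligned_fraction_pct": 100.0 * fractions[c],
                "below_split": c in nonaligning,
                "pc1": coords[i, 0],
                "pc2": coords[i, 1],
                "robust_dist2": dist2[i],
                "coverage": coverage[c],
                "capped_coverage": capped[c],
                "flagged": flagged,
            }
        )
    report = pd.DataFrame(rows)
    logger.info(
        "flag_contaminants: %d/%d contigs flagged (median coverage %.2f)",
        int(report["flagged"].sum()), len(report), median_cov,
    )
    return report
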