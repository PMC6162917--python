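"""Genome sketching, Mash-style distances and genome clustering.

Genomes are reduced to bottom-k MinHash sketches of their canonical
15-mers; the Jaccard index estimated from two merged sketches gives the
Mash distance d = -(1/k) * ln(2j / (1 + j)), and single-linkage clustering
at a distance cutoff (default 0.1, i.e. roughly 90 % estimated identity)
groups SAGs with their matching MAGs.  Identity and aligned-fraction
summaries are computed from externally produced (or truth-emitted)
alignment blocks; whole-genome alignment itself is not reimplemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import AlignmentBlock, logger

# ---------------------------------------------------------------------------
# Interval unions (shared by several modules)
# ---------------------------------------------------------------------------


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for s, e in ivs:
        if cur_s is None or s > cur_e:
            if cur_s is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# Canonical k-mer hashing
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit codes of canonical k-mers (min of forward and reverse
    complement; numeric order equals lexicographic order under A<C<G<T).
    Windows containing non-ACGT symbols are skipped."""
    arr = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        col = arr[i : i + n].astype(np.uint64)
        fwd = (fwd << np.uint64(2)) | col
        rev |= (np.uint64(3) - col) << np.uint64(2 * i)
    bad = (arr >= 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    window_bad = cs[k:] - cs[:-k]
    canon = np.minimum(fwd, rev)
    return canon[window_bad == 0]


def _mix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit mixer (splitmix64 finalizer); seed-stable across runs."""
    z = x.astype(np.uint64, copy=True)
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def canonical_kmer_hashes(sequences: Iterable[str], k: int) -> np.ndarray:
    """Sorted distinct 64-bit hashes of all canonical k-mers."""
    parts = [_canonical_kmer_codes(seq, k) for seq in sequences]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    codes = np.unique(np.concatenate(parts))
    return np.unique(_mix64(codes))


# ---------------------------------------------------------------------------
# MinHash sketches and the Mash distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MinHashSketch:
    """Bottom-``sketch_size`` hash sketch of a genome's canonical k-mers."""

    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted, strictly increasing uint64

    def __post_init__(self) -> None:
        if len(self.hashes) > self.sketch_size:
            raise ValueError("sketch holds more hashes than sketch_size")
        if len(self.hashes) > 1 and not (np.diff(self.hashes.astype(np.int64)) != 0).all():
            raise ValueError("sketch hashes must be distinct")


def sketch_genome(
    sequences: Iterable[str] | Mapping[str, str], k: int = 15, sketch_size: int = 100_000
) -> MinHashSketch:
    """Sketch a genome (one or more sequences) into its bottom hashes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    else:
        sequences = list(sequences)
    if not sequences:
        raise ValueError("sequences must be nonempty")
    hashes = canonical_kmer_hashes(sequences, k)
    if hashes.size == 0:
        raise ValueError(f"no valid {k}-mers: all sequences shorter than k or non-ACGT")
    return MinHashSketch(k=k, sketch_size=sketch_size, hashes=hashes[:sketch_size])


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash distance between two sketches.

    The Jaccard index is estimated from the bottom ``sketch_size`` hashes
    of the merged sketch; j = 0 is reported as the cap value 1.0.
    """
    if a.k != b.k:
        raise ValueError(f"sketch k mismatch: {a.k} != {b.k}")
    size = min(a.sketch_size, b.sketch_size)
    union = np.union1d(a.hashes, b.hashes)
    bottom = union[: min(size, len(union))]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    j = np.isin(bottom, shared, assume_unique=True).sum() / len(bottom)
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / a.k)


def exact_jaccard_distance(
    seqs_a: Iterable[str] | Mapping[str, str],
    seqs_b: Iterable[str] | Mapping[str, str],
    k: int = 15,
) -> float:
    """Mash-formula distance from the *true* Jaccard of full k-mer sets."""
    if isinstance(seqs_a, Mapping):
        seqs_a = list(seqs_a.values())
    if isinstance(seqs_b, Mapping):
        seqs_b = list(seqs_b.values())
    ha = canonical_kmer_hashes(seqs_a, k)
    hb = canonical_kmer_hashes(seqs_b, k)
    inter = np.intersect1d(ha, hb, assume_unique=True).size
    union = ha.size + hb.size - inter
    j = inter / union if union else 0.0
    if j == 0.0:
        return 1.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / k)


# ---------------------------------------------------------------------------
# Distance matrices and single-linkage clustering
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = v

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def pairwise_mash_distances(sketches: Mapping[str, MinHashSketch]) -> DistanceMatrix:
    labels = list(sketches)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for jx in range(i + 1, n):
            d = mash_distance(sketches[labels[i]], sketches[labels[jx]])
            values[i, jx] = values[jx, i] = d
    return DistanceMatrix(labels, values)


@dataclass
class GenomeCluster:
    cluster_id: str
    members: list[tuple[str, str]]  # (genome label, role "SAG" | "MAG")

    @property
    def sags(self) -> list[str]:
        return [m for m, role in self.members if role == "SAG"]

    @property
    def mags(self) -> list[str]:
        return [m for m, role in self.members if role == "MAG"]

    @property
    def is_matched(self) -> bool:
        return bool(self.sags) and bool(self.mags)


def single_linkage_clusters(
    distances: DistanceMatrix,
    cutoff: float = 0.1,
    roles: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[GenomeCluster]:
    """Connected components of the graph with edges where d < cutoff.

    Equivalent to cutting a single-linkage dendrogram at the cutoff.  The
    comparison is strict by default (a tie at exactly the cutoff does not
    merge); pass ``strict=False`` for <=.  Clusters are ordered and
    labelled by their smallest member label.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    adj = (
        (distances.values < cutoff) if strict else (distances.values <= cutoff)
    ) & ~np.eye(len(distances.labels), dtype=bool)
    n_comp, assignment = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for label, comp in zip(distances.labels, assignment):
        groups.setdefault(int(comp), []).append(label)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    clusters = []
    for i, members in enumerate(ordered):
        tagged = [(m, (roles or {}).get(m, "MAG")) for m in sorted(members)]
        clusters.append(GenomeCluster(cluster_id=f"cluster{i + 1:02d}", members=tagged))
    logger.info(
        "single_linkage_clusters: %d clusters at cutoff %s (%d matched)",
        len(clusters), cutoff, sum(c.is_matched for c in clusters),
    )
    return clusters


def write_clusters(path: str | Path, clusters: Sequence[GenomeCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgenome\trole\n")
        for cluster in clusters:
            for member, role in cluster.members:
                fh.write(f"{cluster.cluster_id}\t{member}\t{role}\n")


def read_clusters(path: str | Path) -> list[GenomeCluster]:
    clusters: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cluster_id"):
            raise ValueError(f"{path}: missing cluster table header")
        for line in fh:
            cluster_id, member, role = line.rstrip("\n").split("\t")
            clusters.setdefault(cluster_id, []).append((member, role))
    return [GenomeCluster(cid, members) for cid, members in clusters.items()]


# ---------------------------------------------------------------------------
# Alignment-block summaries
# ---------------------------------------------------------------------------


def block_identity_summary(blocks: Sequence[AlignmentBlock]) -> tuple[float, float]:
    """Length-weighted mean and standard deviation of block identities."""
    if not blocks:
        raise ValueError("cannot summarize an empty block collection")
    weights = np.array([b.query_length for b in blocks], dtype=float)
    idents = np.array([b.identity for b in blocks], dtype=float)
    mean = float(np.average(idents, weights=weights))
    var = float(np.average((idents - mean) ** 2, weights=weights))
    return mean, math.sqrt(var)


def aligned_fraction(
    blocks: Sequence[AlignmentBlock], genome_length: int, side: str = "query"
) -> float:
    """Percentage of the genome covered by the union of aligned intervals."""
    if side not in ("query", "target"):
        raise ValueError(f"side must be 'query' or 'target', got {side!r}")
    intervals = []
    for b in blocks:
        s, e = (b.query_start, b.query_end) if side == "query" else (b.target_start, b.target_end)
        if s < 0 or e > genome_length:
            raise ValueError(f"block interval [{s}, {e}) outside genome of length {genome_length}")
        intervals.append((s, e))
    return 100.0 * union_length(intervals) / genome_length


def aligned_fraction_total(
    blocks: Sequence[AlignmentBlock],
    contig_lengths: Mapping[str, int],
    side: str = "query",
) -> float:
    """Aligned percentage over a multi-contig genome (union per contig)."""
    if side not in ("query", "target"):
        raise ValueError(f"side must be 'query' or 'target', got {side!r}")
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        if side == "query":
            per_contig.setdefault(b.query_id, []).append((b.query_start, b.query_end))
        else:
            per_contig.setdefault(b.target_id, []).append((b.target_start, b.target_end))
    covered = 0
    for cid, ivs in per_contig.items():
        if cid not in contig_lengths:
            raise ValueError(f"block references unknown contig {cid!r}")
        covered += union_length(ivs)
    total = sum(contig_lengths.values())
    return 100.0 * covered / total if total else 0.0
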