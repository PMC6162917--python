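"""Shared fixtures and independent oracle implementations.

The oracle functions here recompute quantities by deliberately naive
routes (bitmaps, brute-force enumeration, direct formulas) so the tests
compare the package's optimized paths against independent arithmetic.
"""

from __future__ import annotations

import numpy as np
import pytest

from sagmag.io import BinTable
from sagmag.simulate import SimConfig, TruthManifest, simulate_community

# ---------------------------------------------------------------------------
# Communities (session-scoped; simulation is deterministic per seed)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def community():
    """The default five-genome community with one ~20k-read focal SAG."""
    return simulate_community(SimConfig(seed=11))


@pytest.fixture(scope="session")
def big_read_community():
    """A single-focal-SAG community with ~50,000 reads for chimera tests."""
    return simulate_community(
        SimConfig(seed=13, genome_length=250_000, sag_depth=20.0, n_sags=1)
    )


# ---------------------------------------------------------------------------
# Truth-side placement oracle (brute-force loops over contig intervals)
# ---------------------------------------------------------------------------


def _meta_contigs_of_genome(truth: TruthManifest, bins: BinTable, genome: str):
    out = [
        (cid, s, e)
        for cid, (g, s, e) in truth.contig_interval.items()
        if g == genome and cid in bins.contigs
    ]
    out.sort(key=lambda x: x[1])
    return out


def truth_read_placement(
    truth: TruthManifest, bins: BinTable, read_id: str, read_length: int
) -> tuple[str, int, int] | None:
    """Where the read's alignment should land: (contig, start, end) or None.

    Brute-force re-derivation of the emission rules from the manifest
    alone: chimeras place their longer arm (falling back to the shorter)
    where fully contained; ordinary reads place on the contig holding the
    majority of the read, clipped to the overlap; otherwise unmapped.
    """
    if read_id in truth.contaminant_reads:
        return None
    genome = truth.read_source[read_id][0]
    contigs = _meta_contigs_of_genome(truth, bins, genome)
    if read_id in truth.chimeric_reads:
        arm1, arm2 = truth.chimera_arms[read_id]
        for s, e in sorted([arm1, arm2], key=lambda a: a[1] - a[0], reverse=True):
            for cid, cs, ce in contigs:
                if cs <= s and e <= ce:
                    return cid, s - cs, e - cs
        return None
    s, e = truth.read_source[read_id][1]
    best, best_ov = None, 0
    for cid, cs, ce in contigs:
        ov = min(e, ce) - max(s, cs)
        if ov > best_ov:
            best, best_ov = (cid, cs, ce), ov
    if best is None or 2 * best_ov < read_length:
        return None
    cid, cs, ce = best
    return cid, max(s, cs) - cs, min(e, ce) - cs


def truth_read_category(
    truth: TruthManifest, bins: BinTable, read_id: str, read_length: int, focal_bin: str
) -> str:
    placement = truth_read_placement(truth, bins, read_id, read_length)
    if placement is None:
        return "UNMAPPED"
    cid = placement[0]
    if bins.bin_of(cid) == focal_bin:
        return "IN_MAG"
    if bins.length_of(cid) >= 1000:
        return "LONG_NON_MAG"
    return "SHORT"


def truth_fn_ratio(
    truth: TruthManifest, bins: BinTable, read_ids, read_lengths, focal_bin: str
) -> float:
    """FN binning base ratio from per-position bitmaps of truth placements."""
    bitmaps: dict[str, np.ndarray] = {}
    for rid in read_ids:
        placement = truth_read_placement(truth, bins, rid, read_lengths[rid])
        if placement is None:
            continue
        cid, s, e = placement
        if cid not in bitmaps:
            bitmaps[cid] = np.zeros(bins.length_of(cid), dtype=bool)
        bitmaps[cid][s:e] = True
    num = den = 0
    for cid, bm in bitmaps.items():
        bin_id = bins.bin_of(cid)
        if bin_id is None:
            continue
        covered = int(bm.sum())
        den += covered
        if bin_id != focal_bin and bins.length_of(cid) >= 1000:
            num += covered
    return num / den if den else 0.0


# ---------------------------------------------------------------------------
# Small numeric oracles
# ---------------------------------------------------------------------------


def bitmap_union_length(intervals, size: int) -> int:
    bm = np.zeros(size, dtype=bool)
    for s, e in intervals:
        bm[s:e] = True
    return int(bm.sum())


def brute_force_components(matrix: np.ndarray, cutoff: float) -> list[frozenset[int]]:
    """Connected components of the threshold graph by exhaustive BFS."""
    n = matrix.shape[0]
    unvisited = set(range(n))
    comps = []
    while unvisited:
        seed_node = min(unvisited)
        stack, comp = [seed_node], set()
        unvisited.discard(seed_node)
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in list(unvisited):
                if matrix[u, v] < cutoff:
                    unvisited.discard(v)
                    stack.append(v)
        comps.append(frozenset(comp))
    return comps


def direct_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width, computed point by point from definitions."""
    scores = []
    for i in range(len(points)):
        same = [j for j in range(len(points)) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = np.inf
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(len(points)) if labels[j] == other]
            b = min(b, np.mean([np.linalg.norm(points[i] - points[j]) for j in members]))
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def brute_force_repeats(contigs: dict[str, str], min_element: int, min_contig: int):
    """Quadratic maximal-exact-repeat search via per-diagonal run scanning."""
    found = set()
    eligible = {c: s for c, s in contigs.items() if len(s) >= min_contig}
    names = sorted(eligible)
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            ca, cb = names[ai], names[bi]
            a = np.frombuffer(eligible[ca].encode(), dtype=np.uint8)
            b = np.frombuffer(eligible[cb].encode(), dtype=np.uint8)
            eq = a[:, None] == b[None, :]
            for off in range(-len(b) + 1, len(a)):
                diag = np.diagonal(eq, offset=-off)
                padded = np.concatenate([[False], diag, [False]]).astype(np.int8)
                edges = np.flatnonzero(np.diff(padded))
                for s, e in zip(edges[::2], edges[1::2]):
                    if e - s >= min_element:
                        a_start = s + max(off, 0)
                        b_start = s + max(-off, 0)
                        found.add((ca, a_start, a_start + (e - s), cb, b_start, b_start + (e - s)))
    return found


def direct_poisson_dissimilarity(xi, xj) -> float:
    """Scalar, term-by-term evaluation of the Poisson dissimilarity."""
    ti, tj = float(sum(xi)), float(sum(xj))
    mean_total = (ti + tj) / 2.0
    si, sj = ti / mean_total, tj / mean_total
    total = 0.0
    for a, c in zip(xi, xj):
        n_hat = (a + c) / (si + sj)
        for x, s in ((a, si), (c, sj)):
            term = s * n_hat - x
            if x > 0:
                term += x * np.log(x / (s * n_hat))
            total += term
    return total
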