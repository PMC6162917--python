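"""Sketching, Mash distances, clustering and block summaries."""

import numpy as np
import pytest

from conftest import bitmap_union_length, brute_force_components
from sagmag.genome_compare import (
    DistanceMatrix,
    _mix64,
    aligned_fraction,
    block_identity_summary,
    canonical_kmer_hashes,
    exact_jaccard_distance,
    mash_distance,
    single_linkage_clusters,
    sketch_genome,
    union_length,
)
from sagmag.io import AlignmentBlock
from sagmag.simulate import generate_markov_genome, reverse_complement


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# Sketching
# ---------------------------------------------------------------------------


def test_sketch_is_strand_invariant_and_deterministic():
    rng = np.random.default_rng(0)
    seq = _random_seq(rng, 3000)
    s1 = sketch_genome([seq], k=15, sketch_size=1000)
    s2 = sketch_genome([seq], k=15, sketch_size=1000)
    s3 = sketch_genome([reverse_complement(seq)], k=15, sketch_size=1000)
    assert np.array_equal(s1.hashes, s2.hashes)
    assert np.array_equal(s1.hashes, s3.hashes)


def test_full_size_sketch_equals_brute_force_kmer_set():
    """At sketch_size >= #distinct k-mers the sketch is the full hashed set
    of canonical k-mers, checked against a direct string-set build."""
    rng = np.random.default_rng(1)
    seq = _random_seq(rng, 10_000)
    k = 15
    canon = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        canon.add(min(kmer, reverse_complement(kmer)))
    codes = {b: i for i, b in enumerate("ACGT")}
    ints = np.array(
        sorted({sum(codes[b] << (2 * (k - 1 - j)) for j, b in enumerate(m)) for m in canon}),
        dtype=np.uint64,
    )
    expected = np.unique(_mix64(ints))
    sketch = sketch_genome([seq], k=k, sketch_size=len(seq))
    assert np.array_equal(sketch.hashes, expected)


def test_sketch_skips_ambiguous_windows_and_rejects_short_input():
    hashes_clean = canonical_kmer_hashes(["ACGTACGTACGTACGTACGT"], 15)
    hashes_n = canonical_kmer_hashes(["ACGTACGTACGTACGTACGTNACGTACG"], 15)
    assert set(hashes_n) <= set(canonical_kmer_hashes(["ACGTACGTACGTACGTACGTACGTACG"], 15))
    assert len(hashes_clean) > 0
    with pytest.raises(ValueError, match="shorter than k"):
        sketch_genome(["ACGT"], k=15)


# ---------------------------------------------------------------------------
# Mash distance
# ---------------------------------------------------------------------------


def test_mash_distance_limits_and_symmetry():
    rng = np.random.default_rng(2)
    a = sketch_genome([_random_seq(rng, 2000)], sketch_size=500)
    b = sketch_genome([_random_seq(rng, 2000)], sketch_size=500)
    assert mash_distance(a, a) == 0.0
    assert mash_distance(a, b) == mash_distance(b, a)
    disjoint = sketch_genome(["A" * 100], sketch_size=10)
    assert mash_distance(a, disjoint) == 1.0
    with pytest.raises(ValueError, match="mismatch"):
        mash_distance(a, sketch_genome([_random_seq(rng, 2000)], k=11))


def test_sketch_distance_tracks_exact_jaccard():
    rng = np.random.default_rng(3)
    a = generate_markov_genome(rng, 50_000, 0)
    b = a[:30_000] + generate_markov_genome(rng, 20_000, 0)
    d_exact = exact_jaccard_distance([a], [b])
    d_est = mash_distance(
        sketch_genome([a], sketch_size=5000), sketch_genome([b], sketch_size=5000)
    )
    assert abs(d_exact - d_est) <= 0.01


def test_sketch_error_shrinks_with_sketch_size():
    rng = np.random.default_rng(4)
    errors = {size: [] for size in (100, 1000, 5000)}
    for rep in range(3):
        a = generate_markov_genome(rng, 50_000, 0)
        b = a[: 25_000] + generate_markov_genome(rng, 25_000, 0)
        d_exact = exact_jaccard_distance([a], [b])
        for size in errors:
            d = mash_distance(
                sketch_genome([a], sketch_size=size), sketch_genome([b], sketch_size=size)
            )
            errors[size].append(abs(d - d_exact))
    means = [np.mean(errors[size]) for size in (100, 1000, 5000)]
    assert means[2] <= means[1] <= means[0]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _matrix(values):
    n = len(values)
    return DistanceMatrix([chr(65 + i) for i in range(n)], np.array(values, dtype=float))


def test_all_distant_genomes_stay_singletons():
    m = _matrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    clusters = single_linkage_clusters(m, 0.1)
    assert all(len(c.members) == 1 for c in clusters)


def test_chaining_merges_transitively():
    m = _matrix([[0, 0.05, 0.5], [0.05, 0, 0.05], [0.5, 0.05, 0]])
    clusters = single_linkage_clusters(m, 0.1)
    assert len(clusters) == 1
    assert [g for g, _ in clusters[0].members] == ["A", "B", "C"]


def test_tie_at_cutoff_does_not_merge_by_default():
    m = _matrix([[0, 0.1], [0.1, 0]])
    assert len(single_linkage_clusters(m, 0.1)) == 2
    assert len(single_linkage_clusters(m, 0.1, strict=False)) == 1


def test_clusters_match_brute_force_components():
    rng = np.random.default_rng(5)
    for _ in range(30):
        n = int(rng.integers(2, 13))
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = DistanceMatrix([f"g{i:02d}" for i in range(n)], v)
        cutoff = float(rng.uniform(0.05, 0.95))
        ours = {frozenset(g for g, _ in c.members) for c in single_linkage_clusters(m, cutoff)}
        expected = {
            frozenset(f"g{i:02d}" for i in comp)
            for comp in brute_force_components(v, cutoff)
        }
        assert ours == expected


def test_raising_cutoff_never_splits_clusters():
    rng = np.random.default_rng(6)
    v = rng.random((10, 10))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    m = DistanceMatrix([f"g{i}" for i in range(10)], v)
    previous = None
    for cutoff in (0.2, 0.4, 0.6, 0.8):
        clusters = {frozenset(g for g, _ in c.members) for c in single_linkage_clusters(m, cutoff)}
        if previous is not None:
            for small in previous:
                assert any(small <= big for big in clusters)
        previous = clusters


# ---------------------------------------------------------------------------
# Block summaries
# ---------------------------------------------------------------------------


def _block(qs, qe, ident, query="q", target="t"):
    return AlignmentBlock(query, target, qs, qe, qs, qe, ident)


def test_block_identity_weighted_moments():
    assert block_identity_summary([_block(0, 100, 100.0)]) == (100.0, 0.0)
    mean, _ = block_identity_summary([_block(0, 100, 98.0), _block(100, 200, 100.0)])
    assert mean == pytest.approx(99.0)
    rng = np.random.default_rng(7)
    blocks = [
        _block(int(s), int(s + w), float(ident))
        for s, w, ident in zip(rng.integers(0, 1000, 20), rng.integers(10, 500, 20),
                               rng.uniform(90, 100, 20))
    ]
    w = np.array([b.query_length for b in blocks], dtype=float)
    x = np.array([b.identity for b in blocks])
    mean, sd = block_identity_summary(blocks)
    assert mean == pytest.approx((w * x).sum() / w.sum())
    assert sd == pytest.approx(np.sqrt((w * (x - mean) ** 2).sum() / w.sum()))
    with pytest.raises(ValueError, match="empty"):
        block_identity_summary([])


def test_aligned_fraction_union_semantics():
    assert aligned_fraction([], 1000) == 0.0
    blocks = [_block(0, 500, 100.0), _block(250, 750, 100.0)]
    assert aligned_fraction(blocks, 1000) == pytest.approx(75.0)
    with pytest.raises(ValueError, match="outside"):
        aligned_fraction([_block(0, 2000, 100.0)], 1000)


def test_union_length_matches_bitmap():
    rng = np.random.default_rng(8)
    for _ in range(20):
        ivs = []
        for _ in range(int(rng.integers(1, 15))):
            s = int(rng.integers(0, 900))
            ivs.append((s, s + int(rng.integers(1, 100))))
        assert union_length(ivs) == bitmap_union_length(ivs, 1000)
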