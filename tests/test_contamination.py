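"""Tetranucleotide profiles, PCA projection and the contamination flag."""

import numpy as np
import pytest

from sagmag.contamination import (
    N_TETRA_CLASSES,
    TETRA_CLASSES,
    coverage_estimate,
    flag_contaminants,
    pca_project,
    split_by_alignment,
    tetra_profile,
)
from sagmag.io import AlignmentBlock
from sagmag.simulate import reverse_complement


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_homopolymer_concentrates_in_one_class():
    profile = tetra_profile("AAAAAA")
    assert profile.n_windows == 3
    nz = np.flatnonzero(profile.frequencies)
    assert len(nz) == 1 and TETRA_CLASSES[nz[0]] == "AAAA"
    assert profile.frequencies[nz[0]] == 1.0


def test_profile_is_strand_invariant_and_matches_sliding_tally():
    rng = np.random.default_rng(0)
    seq = _random_seq(rng, 10_000)
    fwd = tetra_profile(seq)
    rev = tetra_profile(reverse_complement(seq))
    assert np.allclose(fwd.frequencies, rev.frequencies)
    assert abs(fwd.frequencies.sum() - 1.0) < 1e-9

    # brute-force position-by-position tally into canonical classes
    counts = dict.fromkeys(TETRA_CLASSES, 0)
    for i in range(len(seq) - 3):
        w = seq[i : i + 4]
        counts[min(w, reverse_complement(w))] += 1
    expected = np.array([counts[c] for c in TETRA_CLASSES], dtype=float)
    assert np.array_equal(np.round(fwd.frequencies * fwd.n_windows), expected)


def test_profile_skips_ambiguous_windows_and_rejects_short_sequences():
    with_n = tetra_profile("ACGTNACGTACGT")
    assert with_n.n_windows == 6  # 10 windows, 4 of them contain the N
    with pytest.raises(ValueError, match="short"):
        tetra_profile("ACG")


def test_pca_duplicates_collapse_and_small_rank_is_isometric():
    rng = np.random.default_rng(1)
    base = rng.dirichlet(np.ones(N_TETRA_CLASSES), size=3)
    coords = pca_project(np.vstack([base, base[0]]))
    assert np.allclose(coords[0], coords[3])
    # 3 points span <= 2 dimensions after centring: distances preserved
    pc = pca_project(base)
    for i in range(3):
        for j in range(i + 1, 3):
            assert np.linalg.norm(pc[i] - pc[j]) == pytest.approx(
                np.linalg.norm(base[i] - base[j]), abs=1e-9
            )


def test_pca_two_component_error_equals_trailing_eigenvalues():
    rng = np.random.default_rng(2)
    matrix = rng.random((12, N_TETRA_CLASSES))
    centred = matrix - matrix.mean(axis=0)
    coords = pca_project(matrix)
    evals = np.sort(np.linalg.eigvalsh(centred.T @ centred))[::-1]
    total = (centred**2).sum()
    explained = (coords**2).sum()
    assert total - explained == pytest.approx(evals[2:].sum(), rel=1e-8)


def test_split_by_alignment_threshold_is_strict():
    lengths = {"a": 1000, "b": 1000, "c": 10_000}
    blocks = [
        AlignmentBlock("a", "m", 0, 50, 0, 50, 100.0),       # exactly 5 %
        AlignmentBlock("c", "m", 0, 300, 0, 300, 100.0),     # union 4 %
        AlignmentBlock("c", "m", 200, 400, 200, 400, 100.0),
    ]
    aligning, nonaligning, fractions = split_by_alignment(lengths, blocks)
    assert "a" in aligning  # 5.0 % is not < 5 %
    assert "b" in nonaligning  # no blocks at all
    assert "c" in nonaligning and fractions["c"] == pytest.approx(0.04)


def test_coverage_estimate_and_cap():
    cov, capped, median = coverage_estimate(
        {"a": 50, "b": 0}, {"a": 1000, "b": 500}
    )
    assert cov["a"] == 5.0 and cov["b"] == 0.0
    cov, capped, median = coverage_estimate(
        {"a": 10, "b": 20, "c": 100}, {"a": 1000, "b": 1000, "c": 1000}
    )
    assert median == 2.0
    assert capped == {"a": 1.0, "b": 2.0, "c": 6.0}


def test_cap_preserves_uncapped_values_and_median():
    rng = np.random.default_rng(3)
    counts = {f"c{i}": int(rng.integers(0, 60)) for i in range(15)}
    lengths = {c: 1000 for c in counts}
    cov, capped, median = coverage_estimate(counts, lengths)
    n_capped = sum(1 for c in cov if cov[c] > 3 * median)
    for c in cov:
        if cov[c] <= 3 * median:
            assert capped[c] == cov[c]
    if n_capped < len(cov) / 2:
        assert np.median(list(capped.values())) == median


def _screen(community, sag):
    blocks = community.mag_blocks[sag.sag_id]
    profiles = [tetra_profile(s, cid) for cid, s in sag.contigs.items()]
    return flag_contaminants(
        profiles, {c: len(s) for c, s in sag.contigs.items()}, blocks, sag.meta_read_counts
    )


def test_planted_contaminants_flagged_with_high_precision(community):
    tp = fp = fn = 0
    for sag in community.sags:
        report = _screen(community, sag)
        flagged = set(report[report.flagged].contig_id)
        planted = {c for c in community.truth.contaminant_contigs
                   if c.startswith(sag.sag_id + "_")}
        tp += len(flagged & planted)
        fp += len(flagged - planted)
        fn += len(planted - flagged)
    assert tp / (tp + fn) >= 0.8
    assert tp / (tp + fp) >= 0.8


def test_screen_is_strand_invariant(community):
    sag = community.sags[0]
    base = _screen(community, sag)
    flipped_contigs = dict(sag.contigs)
    target = sorted(community.truth.contaminant_contigs & set(sag.contigs))[0]
    flipped_contigs[target] = reverse_complement(flipped_contigs[target])
    profiles = [tetra_profile(s, cid) for cid, s in flipped_contigs.items()]
    flipped = flag_contaminants(
        profiles, {c: len(s) for c, s in flipped_contigs.items()},
        community.mag_blocks[sag.sag_id], sag.meta_read_counts,
    )
    assert np.array_equal(base["flagged"].to_numpy(), flipped["flagged"].to_numpy())
    assert np.allclose(base["pc1"].to_numpy(), flipped["pc1"].to_numpy())


def test_uniform_single_genome_sag_has_no_flags():
    rng = np.random.default_rng(4)
    genome = _random_seq(rng, 60_000)
    contigs = {f"c{i}": genome[i * 5000 : (i + 1) * 5000] for i in range(12)}
    blocks = [AlignmentBlock(c, "mag", 0, 5000, 0, 5000, 100.0) for c in contigs]
    counts = {c: 1000 for c in contigs}
    report = flag_contaminants(
        [tetra_profile(s, c) for c, s in contigs.items()],
        {c: 5000 for c in contigs}, blocks, counts,
    )
    assert not report["flagged"].any()


def test_high_coverage_typical_contaminant_is_not_flagged():
    """A non-aligning contig with ordinary composition and coverage passes."""
    rng = np.random.default_rng(5)
    genome = _random_seq(rng, 60_000)
    contigs = {f"c{i}": genome[i * 5000 : (i + 1) * 5000] for i in range(12)}
    blocks = [AlignmentBlock(c, "mag", 0, 5000, 0, 5000, 100.0)
              for c in list(contigs)[:-1]]  # last contig does not align
    counts = {c: 1000 for c in contigs}
    report = flag_contaminants(
        [tetra_profile(s, c) for c, s in contigs.items()],
        {c: 5000 for c in contigs}, blocks, counts,
    )
    last = report[report.contig_id == "c11"].iloc[0]
    assert last["below_split"] and not last["flagged"]


def test_separation_of_contaminants_in_pc_space(community):
    sag = community.sags[0]
    profiles = [tetra_profile(s, cid) for cid, s in sag.contigs.items()]
    coords = pca_project(profiles)
    order = [p.contig_id for p in profiles]
    is_contam = np.array([c in community.truth.contaminant_contigs for c in order])
    genuine = coords[~is_contam]
    contam = coords[is_contam]
    within = np.mean([np.linalg.norm(a - b) for i, a in enumerate(genuine)
                      for b in genuine[i + 1:]])
    between = np.mean([np.linalg.norm(a - b) for a in contam for b in genuine])
    assert between > within
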