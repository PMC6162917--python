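"""Generator contracts: determinism, planted rates, emission rules."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

from conftest import direct_silhouette
from sagmag.contamination import tetra_profile
from sagmag.io import BinTable
from sagmag.simulate import (
    SimConfig,
    TruthManifest,
    emit_alignments,
    generate_markov_genome,
    reverse_complement,
    simulate_community,
    simulate_genomes,
    simulate_metagenome,
    simulate_sag,
)


def test_same_seed_reproduces_every_output_byte():
    a = simulate_community(SimConfig(seed=5, genome_length=60_000, contig_len_range=(1000, 4000)))
    b = simulate_community(SimConfig(seed=5, genome_length=60_000, contig_len_range=(1000, 4000)))
    assert a.genomes == b.genomes
    assert a.metagenome_contigs == b.metagenome_contigs
    assert a.bins.contigs == b.bins.contigs
    assert a.sags[0].reads == b.sags[0].reads
    assert a.truth == b.truth
    assert a.meta_alignments == b.meta_alignments
    assert a.cog_table.equals(b.cog_table)


@pytest.mark.parametrize(
    "field, value",
    [
        ("misbin_rate", 1.5),
        ("sag_dropout", 1.0),
        ("short_contig_fraction", -0.1),
        ("sag_read_length", 50),
        ("genome_length", 10_000),
        ("n_genomes", 0),
    ],
)
def test_invalid_config_rejected_naming_field(field, value):
    config = dataclasses.replace(SimConfig(), **{field: value})
    with pytest.raises(ValueError, match=field):
        config.validate()


def test_misbin_with_single_genome_rejected():
    with pytest.raises(ValueError, match="misbin_rate"):
        SimConfig(n_genomes=1, misbin_rate=0.1).validate()


def test_uniform_order0_model_gives_flat_tetranucleotide_spectrum():
    """Under uniform base probabilities every 4-mer frequency approaches
    1/256 within 3 binomial standard errors."""
    rng = np.random.default_rng(0)
    seq = generate_markov_genome(rng, 500_000, 0, transitions=np.full((1, 4), 0.25))
    codes = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros(256, dtype=int)
    arr = [codes[b] for b in seq]
    for i in range(len(arr) - 3):
        counts[(arr[i] << 6) | (arr[i + 1] << 4) | (arr[i + 2] << 2) | arr[i + 3]] += 1
    n = counts.sum()
    p = 1 / 256
    se = np.sqrt(n * p * (1 - p))
    assert np.all(np.abs(counts - n * p) <= 3.5 * se)


def test_genome_windows_cluster_by_source_in_tetra_space():
    """5-kb windows of two simulated genomes separate by source genome
    (positive silhouette on canonical tetranucleotide profiles)."""
    config = SimConfig(n_genomes=2, genome_length=100_000, misbin_rate=0.0)
    genomes = simulate_genomes(config)
    points, labels = [], []
    for gi, (g, seq) in enumerate(genomes.items()):
        for w in range(0, len(seq) - 5000, 5000):
            points.append(tetra_profile(seq[w : w + 5000]).frequencies)
            labels.append(gi)
    score = direct_silhouette(np.array(points), np.array(labels))
    assert score > 0


def test_metagenome_planted_rates_and_forced_cases():
    config = SimConfig(seed=3, genome_length=120_000)
    genomes = simulate_genomes(config)
    rng = np.random.default_rng(1)

    no_misbin = dataclasses.replace(config, misbin_rate=0.0)
    _, _, truth = simulate_metagenome(genomes, no_misbin, rng)
    assert truth.misbinned == set()

    no_short = dataclasses.replace(config, short_contig_fraction=0.0)
    contigs, _, _ = simulate_metagenome(genomes, no_short, np.random.default_rng(2))
    assert all(len(s) >= 1000 for s in contigs.values())


def test_misbin_count_within_binomial_interval():
    config = SimConfig(seed=9, genome_length=600_000, misbin_rate=0.05)
    genomes = simulate_genomes(config)
    _, bins, truth = simulate_metagenome(genomes, config, np.random.default_rng(9))
    n_long = sum(1 for c, (length, b) in bins.contigs.items() if length >= 1000)
    lo, hi = binom.ppf([0.005, 0.995], n_long, 0.05)
    assert lo <= len(truth.misbinned) <= hi


def test_sag_dropout_and_chimera_plants(big_read_community):
    config = SimConfig(seed=21, genome_length=200_000, sag_dropout=0.3)
    genomes = simulate_genomes(config)
    g = list(genomes)[0]
    rng = np.random.default_rng(4)
    _, truth = simulate_sag("S01", g, genomes[g], {"X01": genomes[list(genomes)[1]]},
                            config, rng, with_reads=False)
    dropout = sum(e - s for _, s, e in truth.dropout_intervals)
    assert 0.3 * 200_000 <= dropout < 0.3 * 200_000 + 10_000

    # chimera plant count ~ Binomial(n_reads, 0.02)
    big = big_read_community
    n_reads = len(big.sags[0].reads) - len(big.truth.contaminant_reads)
    lo, hi = binom.ppf([0.005, 0.995], n_reads, 0.02)
    assert lo <= len(big.truth.chimeric_reads) <= hi

    with pytest.raises(ValueError, match="sag_dropout"):
        simulate_sag("S02", g, genomes[g], {},
                     dataclasses.replace(config, sag_dropout=1.0), rng)


def test_zero_chimera_rate_plants_no_chimeras():
    c = simulate_community(SimConfig(seed=6, genome_length=60_000,
                                     contig_len_range=(1000, 4000), chimera_rate=0.0))
    assert c.truth.chimeric_reads == set()


def _toy_truth():
    truth = TruthManifest()
    truth.contig_interval = {"c1": ("G", 0, 5000), "c2": ("G", 5000, 10_000)}
    bins = BinTable()
    bins.add("c1", 5000, "binA")
    bins.add("c2", 5000, "binA")
    return truth, bins


def test_emit_full_containment_has_no_clip():
    truth, _ = _toy_truth()
    truth.read_source = {"r1": ("G", (100, 250))}
    (rec,) = emit_alignments(truth, ["r1"], truth.contig_interval, {"r1": 150})
    assert rec.mapped and rec.cigar == (("M", 150),) and rec.position == 101


def test_emit_chimeric_read_aligns_longer_arm_with_soft_clip():
    truth, _ = _toy_truth()
    truth.chimeric_reads = {"r1"}
    truth.chimera_arms = {"r1": ((1000, 1090), (2000, 2060))}
    truth.read_source = {"r1": ("G", (1000, 1090))}
    (rec,) = emit_alignments(truth, ["r1"], truth.contig_interval, {"r1": 150})
    assert rec.cigar == (("M", 90), ("S", 60)) and rec.position == 1001


def test_emit_boundary_read_clips_minority_side():
    truth, _ = _toy_truth()
    truth.read_source = {"r1": ("G", (4910, 5060))}  # 90 bases on c1, 60 on c2
    (rec,) = emit_alignments(truth, ["r1"], truth.contig_interval, {"r1": 150})
    assert rec.target_id == "c1"
    assert rec.cigar == (("M", 90), ("S", 60))


def test_every_read_gets_exactly_one_record(community):
    sag = community.sags[0]
    records = community.meta_alignments[sag.sag_id]
    assert sorted(r.read_id for r in records) == sorted(sag.reads)
    own = community.sag_alignments[sag.sag_id]
    assert sorted(r.read_id for r in own) == sorted(sag.reads)
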