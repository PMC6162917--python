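# Methods

This note documents the models, parameter choices and numerical
conventions behind `sagmag`, and what its synthetic-data tests do and do
not establish about real data.

## The synthetic community model

The generator is first-class, tested code: it is the substrate every
downstream screen is validated on, so its assumptions matter.

**Genome composition.**  Each genome is an order-3 Markov chain over
{A,C,G,T} with Dirichlet(1)-sampled transition rows.  This guarantees
distinct tetranucleotide signatures between genomes — the feature the
contamination screen exploits — while remaining featureless at larger
scales (no genes, no repeats, no GC skew structure).

**Metagenome assembly.**  Genomes are tiled into contigs with lengths
uniform on `contig_len_range` (default 1–5 kb); a `short_contig_fraction`
(default 0.1) of draws come from 200–999 bases and are never binned.  A
genome tail shorter than the minimum long-contig length is absorbed into
the final contig, so with `short_contig_fraction = 0` every contig is
≥ 1 kb.  Each tiled segment is retained with probability
`metagenome_coverage` (default 0.92); dropped segments model assembly
gaps and are the main source of unmapped SAG reads.  Long contigs are
assigned to their source bin except a `misbin_rate` fraction (default
0.05) sent to a uniformly chosen wrong bin — the planted binning false
negatives.

**MDA artifacts.**  The SAG's genome is partitioned into 2–10 kb
amplification segments.  Segments totalling `sag_dropout` (default 0.2)
of the genome are dropped entirely (zero coverage); the rest receive
independent Gamma(shape 0.3) amplification weights and reads are placed
multinomially — a two-parameter caricature of the extremely uneven
coverage of multiple displacement amplification.  A `chimera_rate`
(default 0.02) fraction of reads joins a forward arm (20 to L−20 bases)
to the reverse complement of a segment within 5 kb: inversion joins only,
the dominant chimera class of MDA.  Contaminant contigs (default 4 per
SAG, 2–8 kb) are drawn from genomes *outside* the community, so their
composition is foreign and their metagenome coverage genuinely low
(`contam_coverage_fraction = 0.05` of the community depth); low-depth
reads from them are included among the SAG reads.

**Alignment emission.**  Alignments are emitted directly from the truth
rather than by running a mapper: full-length matches for reads inside
one contig, majority-side placement with the remainder soft-clipped for
boundary-spanning reads, longer-arm placement with the other arm
soft-clipped for chimeras, unmapped otherwise.  All emitted alignments
are substitution-only (NM counts carry no indel component), which makes
the mismatch accounting in the chimera rules exact.  Coordinates are
0-based half-open internally and 1-based at the SAM boundary.

**Default scale.**  Five 200-kb genomes, one focal SAG with ~20,000
100-base reads (depth 10×); the full-read configuration used by the
acceptance script simulates reads for all five SAGs (~100,000 reads).
The FN-rate monotonicity test uses 600-kb genomes (~200 long contigs per
genome) so that planted misbin rates of 0.02 produce enough misbinned
contigs for the ordering to be a property of the method rather than of
sampling noise.  Sketch-fidelity checks use 50-kb genome pairs with a
5,000-hash sketch, where the binomial error of the Jaccard estimate is
comfortably below the 0.01 tolerance.

**What passing tests do not show.**  The generator has no indels, no
sequencing errors, no quality scores, no strain heterogeneity, no
repeats, no conserved genes shared between genomes, and chimeras are
pure inversions with clean breakpoints.  Screens that are near-perfect
here (chimera precision ~1, contamination recall ~1) will degrade on
real data, where mapping noise blurs every one of these margins; the
tests establish correctness of the logic, not field performance.

## Stage-by-stage choices

**Sketching.**  Canonical k-mer = lexicographic minimum of a k-mer and
its reverse complement (numeric minimum under 2-bit A<C<G<T encoding);
windows containing non-ACGT symbols are skipped.  The hash is the
splitmix64 finalizer over the 2-bit code — fixed, seed-free, and
platform-stable, so sketches are reproducible across runs and machines.
The Jaccard index is estimated from the bottom `sketch_size` hashes of
the merged sketch.  j = 0 is reported as the cap distance 1.0 (keeps
matrices finite; such pairs never merge in clustering, which is the
behaviour that matters).

**Clustering.**  Connected components of the d < cutoff graph, which is
exactly a single-linkage dendrogram cut.  The comparison is strict (<) —
a tie at exactly the 0.1 cutoff does not merge — and configurable, since
either convention is defensible.  Clusters are ordered and labelled by
smallest member id so output is deterministic.

**Attribution.**  Only primary, non-duplicate alignments count, one per
read.  Contigs of exactly 1,000 bases are treated as binned (≥ 1 kb).
The FN rate's denominator is covered bases on *all* binned contigs; a
variant with the focal MAG's contigs alone as denominator is available
(`denominator="mag"`), since both definitions exist in practice.  An
optional pre-filter keeping only reads that also map to the SAG's own
assembly is off by default.

**Chimera screen.**  "At least 20 soft-clipped bases" is read as the
total over both ends (a `single` mode uses the largest clip instead).
The soft-clip statistic downstream uses the same ≥ 20 constant as the
candidate rule.  Mismatches are the NM value minus inserted/deleted
bases, i.e. substitutions; records without NM are skipped with a
warning, never counted as candidates.  "Aligned over an edge" is
formalized as a soft-clipped alignment flush with position 1 or with the
contig's final position.  In the pipeline the SAG-self alignments are
passed to `call_chimeras` as an additional sample: reads that merely
span a metagenome contig boundary map full-length to their own contig
and are rescued, exactly the role multiple metagenome samples play when
available.

**Contamination screen.**  Frequencies (not raw counts) over the 136
canonical tetranucleotide classes, so contig length and strand are
irrelevant; PCA is computed per SAG on all its contigs, axes sign-fixed
by their largest-magnitude loading.  The flag itself is a formalization
of what is usually a visual call: a contig must fail the < 5 % aligned
split AND be either a robust PC outlier (squared distance from the
aligning set's median, per axis scaled by 1.4826×MAD, above the
chi-square(2) 0.975 quantile) or have coverage below 10 % of the median.
With fewer than three aligning contigs the PC rule is skipped (warned)
and coverage alone decides.  All thresholds sit in `PipelineConfig`.

**QC.**  The approval rule reads "at most 2 in more than a single copy"
as bounding the *number of multi-copy markers*; the alternative reading
(no marker above 2 copies) is available as `rule="max_copies"`.  Marker
tables arrive precomputed (HMM search is out of scope); the generator
plants presence/absence directly.  Duplicated elements are found by
anchoring on shared 100-mers and extending to maximal length, reported
once per contig pair at maximal extent only (no nested reporting);
matches are forward-strand exact — reverse-complement duplications are a
known omission.

**Functional statistics.**  Size factors are pairwise (each pair
normalized to its own mean total count), matching the transcript-count
dissimilarity this follows; a global-size-factor mode would change
values but not orderings on fixed composition.  ANOSIM uses average
ranks on ties and the add-one permutation p-value, so p is never 0 and
is reproducible bit-for-bit for a given seed.  The R statistic is
cross-checked against an independent implementation in the test suite.
NMDS ordination is deliberately not implemented; the statistic of record
is ANOSIM on the distance matrix.

## Degenerate inputs and tie-breaks

Empty block lists raise (identity summary) or yield 0 % (aligned
fraction).  Zero-sum count rows are excluded with a warning before
normalization or distance computation.  A zero denominator in the FN
rate returns 0 with a warning.  Ties in read placement (a read exactly
straddling two contigs) go to the leftmost contig; equal-length chimera
arms place the forward arm.  Unmapped reads written to SAM carry an
N-run sequence so their length survives the round trip.

## Known limitations

Whole-genome alignment is not reimplemented: identity/aligned-fraction
summaries consume alignment blocks from an external aligner or from the
synthetic truth.  The chimera screen detects, but does not localize or
repair, breakpoints.  The contamination screen is composition+coverage
only — no database lookups — and inherits PCA's blindness to
contaminants that are compositionally similar to the host.  ANOSIM
p-values at 99,999 permutations are sampled, not exhaustive, except on
toy problems where enumeration is feasible (and tested).
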