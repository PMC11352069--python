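# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `satdyn`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself recompute.

## The quantities being estimated

A satellite family is represented by a circular monomer consensus.  Its
**abundance** is the fraction of sampled sequence (read bp for unassembled
genomes, assembly bp otherwise) that aligns to that consensus; at uniform
read sampling this is an unbiased estimate of the family's genomic
occupancy.  Its **divergence** profile is the distribution of per-hit Kimura
2-parameter distances from the consensus, binned at 1%:

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)) * 100

with `P` and `Q` the transition/transversion proportions over ungapped
alignment columns.  Gap columns are excluded; hits where `1-2P-Q <= 0` or
`1-2Q <= 0` (saturation) are discarded with a warning.  A low-divergence
peak in the (family x bin) landscape indicates a recent amplification burst;
a broad high-divergence profile indicates old, decaying copies.

**Gain/loss classification.** Within one species, family abundances and
bp-weighted mean divergences are standardized independently across families
(sample standard deviation, n−1).  A family is a *gain* iff its abundance
z-score is strictly positive, irrespective of the divergence z-score, and a
*loss* otherwise; `z_abundance = 0` (measure-zero) maps to loss because gain
requires a strictly positive value.  Families with `z_abundance > 1` and
`z_divergence < 0` are flagged *highly abundant and homogenized* — many
near-identical copies, the signature of recent concerted amplification.
Standardization is within-species; standardizing a family across species is
a different question and is not what per-species gain counts require.

## Alignment engine

Local alignment is affine-gap Smith–Waterman (match +2, mismatch −3,
gap open −5, gap extend −2; a gap of length L costs `open + (L−1)·extend`).
Hits must reach score ≥ 40 and length ≥ 30 bp and stay below 45% Kimura
divergence — the ceiling sits just above the most diverged satellite copies
that remain recognisably alignable.  All values are configurable
(`ScoringScheme`).

The engine computes the optimal end cell with a linear-memory forward pass,
bounds the optimal start with a reverse pass, and runs a full traceback DP
only on the resulting rectangle.  Tie handling is fully deterministic and
documented (best cell: highest score, then smallest query, then smallest
target index; traceback prefers diagonal over target-gap over query-gap, and
closing a gap over extending it), so an independent full-matrix DP reproduces
the *identical* alignment — the test suite and the reproduction script verify
score and span equality on random instances.  A seeded diagonal-band
heuristic was considered and rejected as the default: without a seeding
stage a band is ill-defined for local alignment against a longer tandemized
target, and a seeded band cannot guarantee the optimum that the oracle
comparison demands.  The numba-compiled full DP meets the runtime budget
without approximation.

**Circularity.** Monomers are circular, so each consensus is *tandemized*
(repeated `ceil(L/monomer)+1` times) before alignment; any window of an
array then aligns contiguously regardless of rotation.  For long queries
(assembly windows) the tandemized target is capped at 1200 bp and arrays are
recovered as tilings of consecutive hits via iterative best-hit removal
(find the optimum, record it, recurse into the unmasked flanks), then merged
into intervals downstream.  Uncapped targets would make the DP quadratic in
window length for no accuracy gain; windowed-vs-unwindowed equality is
tested on toys.

**Hit resolution.** Candidate hits from all families and strands compete
greedily by decreasing score; a hit is discarded if it overlaps already
accepted hits by more than 10% of its own length.  This mirrors standard
repeat-masking practice and is simple enough to test against the oracle.

**Known estimator bias.** A maximum-score alignment systematically shaves
mismatches relative to the true homologous path (it may realign through
gaps or trim divergent edges), so the estimated Kimura divergence of highly
diverged families sits 1–2 pp below the realized Kimura distance of the
planted copies; the Kimura correction itself inflates the distance above
the raw substitution rate by a similar amount at 15–20% divergence.
Validation therefore reports both comparisons: the headline metric compares
estimated Kimura divergence to the planted substitution rate, and the
Kimura-truth comparison is kept as a diagnostic.

## Synthetic genomes

The generator emulates the data regime in which satellitomes are profiled:
a genome carrying head-to-tail satellite arrays, sequenced at 0.01–0.5×
with 150 bp paired-end reads (insert 350 bp).

- Monomer copies are mutated **independently from the consensus** (star
  phylogeny): per-site substitution with probability equal to the family's
  divergence rate, transitions chosen with odds `ts_tv_ratio : 1 : 1`
  against the two transversion classes (default 2), and indel events at a
  per-site rate (default 0.002 in validation) with lengths uniform on 1–5 bp.
  The star phylogeny makes mean divergence directly controlled — landscapes
  measure divergence-from-consensus, not a copy genealogy.
- Each family's bp budget (`occupancy x genome length`) is split over 1–10
  arrays planted at random non-overlapping loci; array orientation is
  uniform, so both strands are exercised.
- Reads are uniform over the genome; read 2 is the reverse complement of the
  fragment 3′ end; per-base errors are uniform substitutions (default 0.001
  in validation); qualities are constant because the pipeline never uses
  them.
- The truth table records planted bp, realized occupancy, realized Kimura
  divergence and every array interval; conservation (planted + background =
  genome length) holds exactly by construction.

What the generator does *not* emulate: copy genealogies and gradual
homogenization (bursts are emulated by mixing low- and high-divergence
arrays), GC-dependent coverage bias, PCR duplicates, quality-dependent
errors, and interspersed transposable elements.  Passing recovery tests
therefore demonstrate correctness of the quantification machinery under the
stated generative model, not robustness to every artefact of real libraries.

## Validation experiments and problem sizes

The reference recovery experiment plants ten families in a 10 Mb genome —
occupancies geometric from 0.2% to 5%, substitution divergences linear from
2% to 20%, monomer lengths 120–350 bp — and profiles 0.1× coverage
(3333 read pairs, ~1 Mb of read bp).  Metrics: Spearman correlation between
true and estimated abundance; relative abundance error for families ≥ 0.5%
of the genome; divergence error for families with ≥ 100 hits.

At this coverage a 0.6–0.9% family is covered by only ~40–60 hits, so its
relative abundance error is sampling-noise-dominated (binomial s.d. 13–16%);
the maximum over the qualifying families fluctuates accordingly between
seeds, and the reference experiment is seed-fixed.  Errors shrink as
1/sqrt(hits) and show no directional bias.

The homogenization-flag experiment constructs 20-family species (15
background families, abundance U(0.2, 0.6)% and divergence U(10, 20)%; 5
amplified families, abundance U(1.5, 2.0)% and divergence U(2, 6)% — a
doubled-occupancy, halved-divergence regime) and counts the seeds in which
all five amplified families are flagged.

## Other design choices

- **Superfamily thresholds**: identity ≥ 0.70 over ≥ 0.50 of the shorter
  monomer, best over strands and rotations (shorter consensus doubled).  The
  tools this step descends from do not publish their thresholds; these
  defaults are explicit and configurable.  The higher-scoring strand is used
  for the evidence record, since score scales with both aligned length and
  identity and cannot be outranked by a short spurious high-identity
  fragment.
- **Tandem calls**: exact k-mer self-matches (k = 12, forward strand only —
  monomers within an array are co-oriented), period = smallest offset whose
  multiples hold ≥ 50% of off-diagonal matches.  A minimum of 10 matches is
  required: with ~0.7 expected chance 12-mer collisions in a 5 kb random
  sequence, a single collision must not trigger a call.  "Recent burst" is
  operationalized as landscape mode ≤ 5% divergence (configurable); the
  term is otherwise qualitative.
- **Nomenclature**: families are named `<Spc>SatNN` by decreasing abundance,
  two digits to 99 and three from 100; ties go to the longer monomer, then
  input order.  Low-confidence families stay in the library, flagged.
- **Abundance denominator**: total sampled read bp for read profiling (the
  genome proxy for unassembled species), assembly or chromosome bp
  otherwise.  Both conventions are stated on every output.
- **Landscape filter**: families at or below 0.2% of the genome are dropped
  from landscapes by default, matching the descriptive convention for
  "highly abundant" families.
- **Chromosome-specific** families: ≥ 90% of assembly-wide bp on one
  chromosome ("solely" needs a cutoff to be testable).
- **Subsampling**: reservoir sampling of read pairs (mates together, order
  preserved), so the full FASTQ never resides in memory; default 3 million
  pairs.
- **Coordinates**: 0-based half-open everywhere; BED-compatible.
- **Exact Spearman p**: full permutation enumeration for n ≤ 9 (the
  cross-species comparisons have 8–9 observations, where the
  t-approximation is unreliable); two-sided throughout.  The bundled survey
  table carries one printed correlation labelled Pearson but reported with
  the rank-correlation symbol rs; both methods are exposed.

## Limitations

- Greedy overlap resolution is not globally optimal for dense multi-family
  overlaps; cross-window conflicts in assembly masking are resolved per
  window.
- No CpG-aware Kimura correction; no interspersed-TE masking — the library
  defines what is a satellite.
- The E. pallidus satellite percentage is absent from the bundled survey
  table (not printed in the source survey), so survey-wide correlations use
  the eight species with both values.
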