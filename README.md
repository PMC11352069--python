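# satdyn — satellite-DNA abundance, divergence and evolutionary dynamics

`satdyn` quantifies the **satellitome** — the complete set of satellite-DNA
(tandem-repeat) families in a genome — from low-coverage (0.01–0.5×)
paired-end reads or from a chromosome-level assembly, and characterizes how
families are amplified, homogenized or lost.  It is written for researchers
studying repeat evolution in non-model organisms (insects especially), where
satellite content is profiled from a few million raw reads rather than a
finished assembly.

The pipeline covers:

- **Masking**: tandem-aware affine-gap Smith–Waterman alignment of reads or
  assembly windows against a library of circular monomer consensuses, on both
  strands, with greedy overlap resolution.  Monomer circularity is handled by
  tandemizing each consensus so any window of an array aligns contiguously.
- **Divergence**: per-hit Kimura 2-parameter distance over ungapped columns,
  `K = −½·ln((1−2P−Q)·√(1−2Q)) × 100`, with `P`/`Q` the transition and
  transversion proportions.
- **Landscapes**: aligned bp per (family, 1% divergence bin), rescaled to
  percent of genome — a divsum-style table whose low-divergence peaks mark
  recent amplification bursts.
- **Gain/loss dynamics**: per-family abundance and mean divergence are
  standardized across the species' families (`z = (x − x̄)/s`, sample s.d.);
  `z_abundance > 0` classifies a family as a *gain* (any divergence sign),
  `z_abundance < 0` as a *loss*, and `z_abundance > 1` with
  `z_divergence < 0` flags a *highly abundant, homogenized* family.
- **Superfamilies**: all-to-all consensus comparison (both strands, all
  circular rotations) with identity/coverage thresholds; connected components
  define superfamilies.
- **Tandem confirmation**: self-dotplot k-mer periodicity, the computational
  analogue of inspecting ring-shaped cluster dot plots.
- **Chromosomal distribution**: windowed masking of an assembly, merged
  per-chromosome satellite percentages and chromosome-specific families.
- **Synthetic truth**: a generator that plants tandem arrays with known
  occupancy and divergence and samples paired-end reads, so every stage is
  validated against exact ground truth.

## Worked example

The numbered scripts under `analysis/` run the package end to end and write
their tables to `results/`.  `analysis/01_survey_descriptives.py`
summarizes the bundled nine-species tettigoniid satellitome survey:

```
                          variable  n   min   max      mean  median
 repeatome_percent (Tettigoniidae)  8 52.00  92.0 66.750000   61.00
satellite_percent (printed values)  8  5.65  17.2 11.120000   11.15
     n_families (all nine species)  9 10.00 246.0 67.333333   37.00

satellite abundance vs family count: rho=0.90, p=0.005 (n=8, exact_permutation)
```

The eight Tettigoniidae repeatome percentages span 52–92% of the genome and
average 67% (rounded); satellite content spans 5.65–17.2%; and species with
more satellite families carry a larger satellite fraction (the p-value is an
exact permutation test — at n ≤ 9 the t-approximation is unreliable).

`analysis/02_simulate_and_profile.py` plants ten families (0.2–5% occupancy,
2–20% divergence) in a 10 Mb genome, profiles 0.1× coverage of 150 bp reads,
and scores the estimates against the planted truth:

```
Spearman(true, estimated abundance): 1.000
max relative abundance error over families >= 0.5% of the genome: 11.1%
max |estimated Kimura - planted substitution divergence| over families with >= 100 hits: 1.58 pp
1106 read hits over 999900 sampled bp
```

Abundance ranks are recovered perfectly and per-family occupancies to within
read-sampling error.  `analysis/03_landscape_gainloss.py` and
`analysis/04_chromosome_distribution.py` continue with landscapes, z-score
classification, and per-chromosome profiles:

```
chr1: 97960 bp, satellite 6.24%
chr2: 116680 bp, satellite 21.29% (chromosome-specific: SimSat02)
chr3: 97960 bp, satellite 6.25%
chr2-specific family: planted 10.80% of the chromosome, recovered 10.80%
```

A `satdyn` CLI wraps the same functions (`satdyn simulate`, `satdyn mask`,
`satdyn landscape`, `satdyn gainloss`, `satdyn chromdist`-equivalent via
`mask --assembly`, `satdyn correlate`, `satdyn tandemcheck`, `satdyn run`).

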