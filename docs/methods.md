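# Methods

## Problem and model

An introgression sub-line is homozygous background (cultivated) genome
everywhere except one contiguous donor (wild) segment. Because the line is
homozygous and the parents are fixed, every position where the parents
differ is a diagnostic site: the line's allele there reveals local ancestry.
The package operationalizes three consequences of that model:

1. **Per-gene ancestry.** Variants called against the background reference
   accumulate in donor-derived sequence and vice versa. A gene is assigned
   to the parent it resembles *less* in the opposite callset: donor iff
   `n_vs_background > n_vs_donor`, background iff the reverse, with both a
   strict inequality (ties are never guessed) and a minimum evidence count.
2. **Breakpoints as open intervals.** Between the last diagnostic position
   supporting one ancestry and the first supporting the other, the data say
   nothing; breakpoints are therefore reported as open uncertainty
   intervals, never as point estimates.
3. **A single crossover inside a border gene** splits its diagnostic sites
   into a donor-supporting prefix and a background-supporting suffix; the
   best split is the one maximizing concordance, equivalent to minimizing
   misclassified sites, which tolerates isolated sequencing errors better
   than a first-discordant-site rule.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_mean_depth` | 5 | reads | depth filter below which calls are noise-dominated |
| `require_homozygous` | true | — | the line is homozygous; heterozygous calls are artifacts |
| `min_informative` | 2 | variants | one stray call (the ~1% spurious regime) must not flip a gene |
| `max_bridged_unknowns` | 3 | genes | unexpressed genes interleaved in a block are bridged, then confirmed by markers |
| `evalue_threshold` | 1e-10 | — | regional protein-search significance cutoff |
| `fdr_threshold` | 0.05 | — | DEG significance, strict inequality |
| `min_run` | 3 | sites | a crossover claim needs ≥3 concordant sites on each side |
| `cut_placement` | midpoint | — | merge cut inside the uncertainty interval; `last_donor` / `first_background` anchor to the bounding evidence instead |

Percentages in reports are rounded to one decimal; underlying fractions are
kept at full precision.

## The synthetic-data generator

The generator emulates the statistical structure of the emulated experiment,
not its sequences: two parental genomes derived from a common ancestor
sequence with substitutions at `snp_rate` (default 0.007/bp) and indels at
`indel_rate` (default 0.00175/bp, geometric lengths capped at 50 bp) — an
~80:20 SNP:indel mixture giving ~17 variants per 1.8 kb gene, the published
regime; non-overlapping plus-strand genes with a fixed
5'UTR–CDS–3'UTR layout; species-specific and duplicated genes planted
outside the introgression; one homozygous donor block whose upper crossover
falls at a fixed point inside the last block gene's 3'UTR; variant calls
emitted only for expressed genes (dropout configurable), with spurious
singleton calls at `variant_error_rate` per bp, at most one per gene so
noise can never mimic a block.

Two floors are part of the generator contract, fixed at design time: every
shared gene's CDS carries at least 4 substitutions (in the emulated study
every wild gene was diagnosable; genes without expressed divergence are the
dropout/marker path, not the SNP path), and the chimeric border gene carries
exactly 6 substitutions + 3 indels in its background-derived tail — the
published residual divergence — with ≥12 CDS and ≥4 3'UTR substitutions on
the donor side so the planted chimera is always identifiable. The floors are
inactive when both rates are zero, preserving the zero-divergence identity.
Indels never span feature boundaries, which keeps lift-over arithmetic
exact. All draws come from fixed, documented `numpy` streams keyed by the
seed (`[seed]` generation, `[seed,1]` planting/dropout, `[seed,2]`/`[seed,3]`
the two callsets, `[seed,4]` DEG tables), so identical configs are
byte-identical.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level error models and mapping artifacts
(variants appear exactly at planted differences), heterozygosity beyond a
spurious fraction, overlapping or multi-isoform gene models, recombination
hotspots, and the two-namespace gene-id problem (shared genes carry one id
in both annotations; real data needs an ortholog map before the
two-reference merge).

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere (GFF3/VCF native); the one
  interval primitive is `interval_span(a, b) = b − a + 1`.
- Best-hit ties break by score then lexicographic subject id, and are
  logged; the underlying search is silent on ties.
- One-to-many (duplication) typing precedes BBH extraction, so a duplicated
  copy that is also a mutual best hit stays with its group — this is what
  reproduces the printed relationship table.
- The built-in protein aligner is Biopython's affine-gap local
  `PairwiseAligner` (BLOSUM62, open 11 / extend 1) with a Karlin–Altschul
  e-value proxy (λ = 0.267, K = 0.041); it is a desk-scale stand-in and the
  supported path for real data is ingesting an external 12-column hit table.
- Collinearity uses a patience longest-increasing-subsequence over rank
  pairs (O(n log n), deterministic); on the packaged homology table it keeps
  the 24-pair consistent subset and reports the five-pair tail run as the
  single translocated block — the same event the source describes as the
  second donor segment embedded in the first.
- Donor genes are clustered into segments by coordinate gaps > 300 kb, which
  cleanly separates the published 23- and 16-gene segments (intra-segment
  gaps there are ≤ 75 kb, the inter-segment gap ~672 kb).
- CAPS fragment patterns are compared as exact length multisets; a
  heterozygous pattern is the union of the parental multisets. Primer
  matching is exact (markers are designed on known sequence).
- Degenerate inputs: empty variant sets give zero-count purity reports;
  a zero-gene introgression span returns the background unchanged; a
  donor-free call set raises "no introgression detected" rather than
  returning an empty interval.
- The region used to intersect the common-DEG table is
  chr7:59,085,047–59,695,592 in the coordinate system that table prints
  (start as printed for the replaced span, end at the 3' end of the last
  replaced gene in that system); the homology-table endpoints are in a newer
  assembly and are kept as a separate constant.
- The homology table prints one BBH row with no named background partner;
  the fixture preserves the empty field and flags it, and the synthetic
  hit-structure fixture uses an explicitly labelled placeholder id so
  typing can still reproduce the printed relation. Gene accounting counts
  distinct named ids only (39 donor, 33 background).

## Problem sizes

Defaults are two 120 kb chromosomes with 20 genes each; statistical
properties (ancestry recovery, noisy-accuracy, breakpoint containment) are
measured over 100 independent seeds, property tests over 200–1000 random
instances, and brute-force cross-checks on instances ≤ 10 genes / ≤ 50
sites, where exhaustive search is exact. At these sizes the full suite and
the acceptance script each run in well under a minute.

## Known limitations

- Single-crossover model per border gene; double crossovers inside one gene
  are out of scope.
- The marker resolver needs parent-conserved unique primer sites within
  400 bp flanks; genes in highly diverged or repetitive surroundings come
  back unresolved rather than mis-genotyped.
- `run_all` assumes shared gene ids between the two annotations (see above).
- Strict mode expects one introgression; multi-block lines must set
  `strict_single_block=False` and interpret per-block intervals themselves.
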