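# Methods

## Model

The detection principle is that coding DNA, translated in the right
frame, inherits weak but *spatially coherent* homology: many distinct
protein clusters descended from a common ancestor align over the same
stretch of the translated query. Non-coding DNA produces weak alignments
too, but they scatter — they are chance matches to unrelated clusters at
unrelated positions. The per-position count of distinct aligning
clusters (the accumulation profile) therefore separates the two regimes
far below the significance threshold of any individual alignment.

The pipeline is deterministic given its inputs and seeds:

- **Region extraction.** Exon intervals from GFF3 are merged across all
  genes and strands per chromosome; every gap between consecutive merged
  blocks becomes one scan unit. A gap inside the exon span of a single
  transcript is an intron, anything else intergenic. Chromosome termini
  are excluded unless requested (`include_termini`): the scan is defined
  *between* exons, and termini are often assembly artefacts. Coordinates
  are 0-based half-open internally; GFF3 is converted on read.
- **Translation.** Six frames (1–3 forward at offsets 0/1/2, 4–6 on the
  reverse complement read 5′→3′), standard genetic code, trailing partial
  codons dropped. Stop codons become `X` — one residue per codon, so
  coordinate arithmetic stays exact — and so does any codon containing N,
  even where the ambiguity would resolve (an uncalled base cannot support
  an alignment). Residue↔genome mapping is closed-form in both
  directions and round-trips exactly.
- **Search.** Queries are SEG-masked, then locally aligned
  (Smith–Waterman, affine gaps, first gap residue charged open+extend)
  against every cluster representative. Suboptimal alignments are found
  by splitting the query around each reported alignment, so HSPs never
  overlap on the query. Hits are kept when bit score ≥ threshold and
  E ≤ cap, ordered deterministically (bit score desc, subject id,
  q_start) and truncated to the per-query cap. Precomputed hits in the
  12-column tabular format pass through the identical filter, so an
  external engine can substitute for the internal aligner at scale.
- **Profiling and peaks.** Counting is per *distinct cluster* by default
  (a switch enables raw per-HSP counting): redundant HSPs from one
  cluster carry no extra evidence, and the count is then bounded by
  database size. Peaks are maximal runs of positions ≥ cutoff;
  significance attaches to the run, height is the run maximum. `≥` vs
  `>` at exactly the cutoff is switchable (`strict`); `merge_gap`
  (default 0) bridges short dips, `min_length` (default 1) drops short
  runs — no smoothing is applied by default.
- **Null calibration.** Controls are uniform nucleotide permutations of
  the real regions (composition-preserving, coding-signal-destroying); a
  character-reversal control is also provided. The cutoff is the stated
  quantile (default maximum) of per-control maximum heights, plus one:
  the smallest height no null sequence reached. The expected
  true-positive fraction of a real scan with N significant calls and N₀
  on the shuffled set is 1 − N₀/N; a control count exceeding the real
  count raises an error rather than clamping, since it means the null is
  noisier than the signal.
- **Frameshift reconstruction.** Peak peptides on one strand are ordered
  5′→3′, stripped of `X`, and concatenated. Adjacent peaks in different
  frames typically overlap by a few codons (weak alignments run past the
  shift point), so `trim_peak_overlaps` trims downstream peaks to whole
  codons first; `concatenate_peaks` itself refuses overlapping input.

## Parameters

| parameter | default | rationale |
|---|---|---|
| substitution matrix | BLOSUM90 | favours short, high-identity footprints over long diffuse similarity |
| gap open / extend | 10 / 1 | a standard supported combination for BLOSUM90; configurable |
| λ, K (gapped) | 0.290, 0.0750 | published gapped Karlin–Altschul values for BLOSUM90 10/1, shipped in `data/ka_params.json` |
| bit-score threshold | 30 | the trained operating point separating accumulation in coding vs non-coding sequence; 28 admits too much noise, 40 keeps only conventionally findable genes |
| E-value cap | 200,000 | admits the weak alignments the method feeds on |
| max hits / query | 10,000 | bounds runtime and memory at genome scale |
| SEG window, locut, hicut | 12, 2.2, 2.5 | standard low-complexity trigger/extension entropies (bits) |
| effective search space | m·n | query length × total database residues, per query |
| peak cutoff | 70 (genome scale); calibrated per run otherwise | empirical null: tallest shuffled-control accumulation + 1. 70 is the UniRef50-scale value; small databases calibrate much lower |
| count mode | distinct clusters | redundancy-free evidence; per-HSP counting available behind a switch |

## The synthetic benchmark

`simulate` builds the self-contained study used by the tests and the
acceptance script: a 200-cluster database in 20 families, each family
descended from a random ancestor with members 5–15% diverged (the first
12 residues kept invariant, so every family shares an exact 8-mer), and
a genome in which ten implants — back-translated family members at 20%
divergence, with stop codons injected, +1 frameshifts inserted, or
truncated to terminal/internal fragments — are planted between dummy
single-exon genes, spread over all six frames. Globally homologous
families (rather than a single conserved block in random flanks) were
chosen because fragments of a split protein must each retain family
homology for frameshift signatures to form, and because global homology
at ~90% identity within a family is the more realistic picture of a
50%-identity clustering.

What the generator does **not** emulate: codon bias (back-translation
uses uniform synonymous codons — irrelevant to a protein-level search),
real intron/exon structure, repeat content, base-composition
heterogeneity, and the long-tailed family-size and domain-architecture
distributions of real databases. Passing tests therefore demonstrate the
machinery — translation, scoring, accumulation, calibration,
reconstruction — under a clean signal model, not the false-positive
landscape of a real genome, where the empirical cutoff does the heavy
lifting.

At this benchmark's scale (200 clusters, family size 10, regions of a
few hundred bp) implant peaks reach height ≈ 10 (one count per family
member) while 50 shuffled controls accumulate nothing at bit ≥ 30, so
the calibrated cutoff is 1–3 rather than 70; the separation between
signal and null, not the absolute cutoff, is the scale-invariant
property. Problem sizes throughout (10 implants, 50 controls, 80–120 aa
proteins) were chosen as the smallest study at which every event class
is represented and family accumulation is unambiguous.

## Numerical and design notes

- Raw scores are integers; bit scores use `(λS − ln K)/ln 2`. The
  internal aligner's scores are validated against an exhaustive
  affine-gap DP oracle in the test suite.
- The bit threshold is applied to bit scores, not raw scores: raw 63 is
  the smallest score reaching 30 bits under the default scheme.
- SEG masking applies to the query only, mirroring standard search
  engines; masked residues score as the matrix's X column. Masking is
  computed on the unmasked sequence, making it idempotent.
- Degenerate inputs: regions shorter than one codon translate to six
  empty peptides with a warning; empty databases and duplicate record
  ids are errors; a real scan with zero significant peaks makes the
  true-positive fraction undefined (reported as such, not as a number).
- Ties: peaks at exactly the cutoff are significant by default
  (`strict=False`); hit ordering breaks bit-score ties by subject id
  then query start, so outputs are byte-stable across runs.

## Known limitations

- The internal aligner is exact Smith–Waterman with no heuristic
  seeding; it is meant for the self-contained benchmark and small
  databases. Genome-scale searches should use an external engine and
  the tabular-hit import path.
- Intron/intergenic labelling relies on GFF3 `Parent` attributes of exon
  features; annotations without them label every gap intergenic.
- No p-value model for peak heights is provided — significance is
  purely the empirical shuffle calibration, as designed.
- Trans-spliced annotations, UTR inference and transcript reconstruction
  are out of scope.
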