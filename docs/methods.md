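# Methods

This note records the model, the defaults, and the design decisions behind
`ilsom`, in enough detail to reproduce or criticize them.

## Data model

A *pattern* is the per-genotype profile of one molecular entity
(transcript or metabolite): `P` log ratios of an introgression line (IL)
against the control genotype. Patterns carry a validity mask; an IL
without enough significantly detected replicates is a **pseudo-zero** —
stored as an explicit missing value (NaN in memory, `0` plus a mask entry
on disk), excluded from normalization, distances and means, and never
imputed. A dataset is *inversion-closed* when every pattern has a twin
with negated values and the same mask; closure is what allows one
Euclidean map to expose anti-correlated (cross) relations.

## Preprocessing

* **Replicate averaging.** Per (entity, IL), the value is
  `log10(mean(replicate ratios))` when at least `min_replicates = 2`
  replicates are present, else a pseudo-zero. The mean is taken before the
  log (mean-then-log of the measurement ratios), and base 10 is the
  microarray convention; both are configurable.
* **Spot filter (transcripts).** Spots with quality flags (poor, negative,
  empty, not expressed in both channels) are excluded outright; a spot is
  *non-expressed* iff `foreground_mean < background_mean +
  2·background_sd`, strictly. Inputs are assumed already print-tip-Lowess
  normalized; that correction is upstream of this package.
* **Metabolite magnitude filter.** A metabolite is kept iff its maximum
  absolute valid log ratio strictly exceeds `0.1`. The criterion is
  sign-free (down-accumulation is as informative as up-) and applied to
  the per-entity maximum; transcripts never pass through it.
* **Unit normalization.** `x_i = logR_i / sqrt(Σ_j logR_j²)` over valid
  components, so the valid sum of squares is exactly 1 (contract enforced
  to 1e-10 in the tests). The square root in the denominator is what makes
  the stated unit-energy property hold; dividing by the raw sum of squares
  would not normalize. All-zero or all-missing vectors are rejected and
  must be dropped upstream.
* **Inversion augmentation.** Each original gains a negated twin,
  interleaved original/inverted; augmentation is idempotent on closed
  data, and twins share the validity mask.

## SOM training

* **Topology.** Rectangular lattice by default (hexagonal available);
  units numbered 1-based, column-major (`unit = (row−1) + rows·(col−1) +
  1`). When no size is given, a square grid with roughly `5·√N` units is
  used (the usual map-size heuristic).
* **Initialization.** PCA: codebooks on the grid spanned by the first two
  principal components, centered on the data mean, stretched to one
  standard deviation per component, with component signs fixed
  deterministically (largest-magnitude loading positive). This makes
  training reproducible and independent of pattern input order. For
  inversion-closed data the mean is exactly zero and the initial codebook
  is antisymmetric under 180° grid rotation. Rank-deficient data collapse
  the second axis to zero with a warning. Random (data-sampling)
  initialization is available behind a seed.
* **Batch updates.** Per epoch: assign all patterns to BMUs (masked
  Euclidean distance, summed over valid components; ties break to the
  lowest unit index), then replace every codebook by the Gaussian-weighted
  per-component mean over valid entries, `g_ij = exp(−δ_ij²/2r²)`. A unit
  component receiving zero total weight keeps its previous value (only
  possible at radius 0). At radius 0 one epoch is exactly one k-means
  Lloyd step with `rows·cols` centers — the test suite checks this against
  an independent Lloyd implementation.
* **Radius schedule.** Linear decay from `max(rows, cols)/4` to 1 over
  `n_epochs = 50` epochs; any explicit non-increasing schedule can be
  supplied. These defaults are package choices; they are exposed in
  `SomConfig`.
* **Symmetry.** Batch updates preserve the codebook antisymmetry of
  inversion-closed data (grid distances are invariant under 180° rotation),
  so `bmu(−x)` lands at the rotated image of `bmu(x)` up to floating-point
  drift and exact ties; `symmetry_report` measures the realized fraction.

## Map analysis

* **Vn pooling.** The visualization neighborhood pools all units within
  Chebyshev (square-ring) radius `Vn` on the grid before counting kinds;
  pooling is monotone — it can turn a single-kind unit mixed, never the
  reverse. Two patterns "share a Vn neighborhood" when some unit's pool
  contains both BMUs, i.e. their BMUs are within Chebyshev distance
  `2·Vn`; this is the criterion used for planted-group co-location.
* **Cohesion.** `C̄_j = (1/|Ω_j|) Σ ‖x − w_j‖²`. With pseudo-zeros the
  squared distance is summed over valid components and rescaled by
  `P / n_valid`, so members with different missingness contribute on a
  comparable scale; on fully valid data this is exactly the plain formula.
  Empty units have no cohesion (absent, not 0). The global compactness
  averages `C̄_j` over *nonempty* units — empty units have no defined
  `C̄_j` to average.
* **3-color maps.** Per genotype dimension and nonempty unit, with `μ, σ`
  the mean and *population* standard deviation of the valid member values:
  green if any value exceeds `μ + σ`, else gray if any value falls below
  `μ − σ`, else white; empty units white. Green is tested first. The
  strict comparisons carry a tiny relative tolerance (1e-9) because some
  configurations sit mathematically *on* the boundary — for a two-member
  unit the maximum equals `μ + σ` identically — and must not be decided by
  rounding noise; such exact-boundary units are white. The classification
  is invariant under positive per-genotype rescaling.
* **Mirror position.** The 180° image of grid position `(r, c)` is
  `(rows+1−r, cols+1−c)`.
* **Chromosome subsetting.** IL names carry their chromosome before the
  first dash (`"12-1-1"` → chromosome 12); subsetting restricts genotype
  columns only and is intended for the per-IL 3-color views (per-dimension
  statistics are unaffected by dropping other dimensions).

## Annotation

Lookups are local tab-separated tables (transcript probe → At / SGN-U /
description; metabolite → KEGG compound + pathways), case-insensitive on
keys, last-wins on duplicates. Keeping the tables local makes the package
network-free and the linkage testable; users export their own tables from
the annotation databases. The bundled tables are synthetic examples
(invented identifiers) that document the schema. Annotation never alters
membership: reports are identical with and without it, apart from the
annotation lines.

## File formats

The `.data` family is whitespace-delimited text (decimal points, no locale
handling): first row `P`, optional genotype-name row (detected by a
non-numeric first token), then `P` values per row followed by a trailing
label, `(inv)` (case-insensitive) marking inverted twins whose printed
values must equal the negated original. Values are written in fixed
notation with 6 significant digits, which bounds round-trip precision;
pseudo-zeros are written as `0` and recovered from the `ilexp` masks.
Companion files (`ilexp` masks, `nonormsq`/`nolowess` un-normalized
values) share the layout with one row per *original* entity of their
component and are found by the naming convention; every companion is
optional, and a lone main file loads with all-true validity. The
main file alone cannot distinguish transcripts from metabolites (labels
are free-form), so kinds come from the component companions when present
and default to transcript otherwise. Trained maps serialize to a
tab-separated codebook (unit, grid position, weights at full `repr`
precision) under a config header and reload bit-exactly.

## Synthetic data generator

The generator emulates the shape of an IL fruit-profiling study: `P = 21`
chromosome-tagged lines spanning chromosomes 1, 2, 3, 5, 8, 10, 11 and 12
(four lines on chromosome 12), 200 transcripts and 40 metabolites by
default, 4 technical replicates, and `G = 8` planted co-regulated groups.
Group latent profiles are orthonormal random directions; a member's
profile is `amplitude · sign · unit(√ρ·latent + √(1−ρ)·noise)` with
within-group correlation `ρ = 0.9` and amplitude 1 (log10 units — a
several-fold change at the strongest ILs, typical of contrasting
introgressions). Half of each component is spread over the groups (so
every group mixes kinds); the rest is unstructured background. A quarter
of the groups are *cross-relation* groups whose metabolites follow the
negated profile. Replicate ratios are `10^(logR + N(0, 0.05))` with
per-replicate dropout at rate 0.05, which produces pseudo-zeros through
the two-replicate validity rule. All randomness flows from one seed.

What the generator does **not** emulate: chip spatial artifacts and
print-tip effects (inputs start at replicate ratios), correlated noise
across entities beyond group membership, heavy-tailed measurement error,
batch effects, and non-orthogonal (overlapping) regulatory programs.
Passing the recovery tests therefore shows the pipeline is sound on
well-separated co-regulation with realistic noise and missingness — not
that real IL datasets are this clean.

## Problem sizes in the test suite

The suite trains maps of 36–144 units on datasets of 100–480 patterns
(seconds per run): brute-force oracles use ≤ 16 units and ≤ 50 patterns,
the Lloyd equivalence uses a 3×3 map for 10 epochs, the symmetry check a
10-genotype, 100-entity panel, and planted-group recovery the default
generator conditions above. These sizes were chosen as the smallest at
which the checked properties are non-trivial.

## Known limitations

* Batch SOM with PCA initialization is deterministic but not globally
  optimal; different map sizes or schedules give different partitions, and
  no automatic cluster-boundary detection is attempted (neuron-level
  reading with Vn pooling is the intended mode).
* The masked-distance convention (sum over valid components, no
  rescaling in BMU search) slightly favors patterns with more missing
  components lying closer to all codebooks; with the low missingness the
  validity rule produces this is negligible, but heavily censored data
  would need a rescaled distance.
* `chromosome_subset` restricts columns of unit-normalized patterns; the
  restricted vectors are no longer unit-energy and are meant for display,
  not re-training.
* The hexagonal lattice affects only the neighborhood distances; Vn
  pooling and mirror positions are defined on the rectangular index grid.
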