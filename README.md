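# ilsom

Self-organizing-map clustering and visualization of transcript and
metabolite profiles from introgression-line (IL) panels.

## The problem

Crosses between a crop and a wild relative yield panels of introgression
lines, each carrying one exotic chromosome segment in an otherwise uniform
background. Profiling transcripts and metabolites across such a panel gives
every molecular entity a *genotype-indexed* pattern: a vector of log ratios
(IL vs. the control genotype), one per line. Entities that rise and fall
together across the panel are candidates for shared regulation
(guilt-by-association) — and the interesting relationships often connect
*different* data types (a transcript with a metabolite) or run in opposite
directions (a transcript up where a metabolite is down).

`ilsom` clusters these patterns on a two-dimensional self-organizing map
(SOM) and provides the analysis layer for reading the result: which neurons
mix data types, how tight each neuron is, which neurons respond in a given
IL or chromosome, and where the measurements were too sparse to trust.

## The model

Each entity's per-IL log ratio vector `logR` is scaled to unit energy,

    x_i = logR_i / sqrt( Σ_j logR_j² )        (sum over valid ILs)

so clustering compares *shapes* of genotype responses, not amplitudes. The
training set holds every pattern **and its sign-inverted twin** `-x`, which
lets a plain Euclidean SOM group anti-correlated profiles: an up-regulated
transcript lands next to the inverted copy of a down-accumulated metabolite
(a *cross relation*).

The map is a `rows × cols` lattice of neurons with weight vectors `w_j`,
trained with the **batch** algorithm: per epoch, every pattern `x` is
assigned to its best-matching unit (BMU, smallest Euclidean `‖x − w_j‖`),
then every weight vector is replaced by the neighborhood-weighted mean

    w_j ← Σ_x g(bmu(x), j) · x / Σ_x g(bmu(x), j),
    g_ij = exp( −δ_ij² / 2r² ),

with `δ_ij` the grid distance and `r` a non-increasing radius schedule.
Initial codebooks are laid out on the plane of the first two principal
components, so training is deterministic and independent of input order.
Missing measurements ("pseudo-zeros": ILs without enough detected
replicates) are carried explicitly and skipped per-component in every
distance and mean — never imputed.

Cluster quality is the intracluster variance per neuron,

    C̄_j = (1/|Ω_j|) Σ_{x ∈ Ω_j} ‖x − w_j‖²,

with the global compactness `C̄` its average over occupied neurons; values
near 0 mean tight nodes.

## Worked example

Generate a synthetic IL panel (21 lines, 200 transcripts, 40 metabolites,
8 planted co-regulated groups, replicate dropout), train a map, and query
it:

```sh
$ ilsom synth --outdir data --seed 5
wrote data/omesom1_-_20100101T1200_-oToM.data

$ ilsom create data/omesom1_-_20100101T1200_-oToM.data --rows 12 --cols 12 --outdir model
trained 12x12 map on 480 patterns (200 transcripts, 40 metabolites, P=21)
quantization error 0.6184, global compactness 0.6140
model written to model/model.tsv

$ ilsom search met_001 --data data/omesom1_-_20100101T1200_-oToM.data --model model/model.tsv
unit 43	original
unit 102	inverted
```

The 480 patterns are the 240 surviving entities plus their inverted twins.
The quantization error (mean pattern-to-BMU distance) and the global
compactness are on the scale of the unit-normalized patterns. Note the two
hits for `met_001`: its original pattern sits in unit 43 = grid position
(7, 4), its inverted twin in unit 102 = (6, 9) — exactly the 180°-rotated
mirror position on the 12 × 12 grid, the "triangular" symmetry an
inversion-closed training set produces.

Other subcommands: `map` (composition view: red = transcripts only, blue =
metabolites only, black = mixed, optionally pooled over a neighborhood
radius `--vn`), `detail <unit>` (member curves, `--raw` for un-normalized
values, missing points circled), `three-colors` (per-IL green/gray/white
deviation maps, `--chromosome 12` to restrict to one chromosome's lines),
`cohesion`, `pseudo-zeros`, and `annotate` (local lookup tables linking
probe codes to At/SGN-U ids and metabolites to KEGG compounds/pathways).
Every image is written together with a tab-separated table carrying the
exact numbers.

The same functionality is available as a library (`ilsom.io`,
`ilsom.preprocess`, `ilsom.som`, `ilsom.analysis`, `ilsom.annotate`,
`ilsom.viz`, `ilsom.synthetic`).

## Input format

The main `.data` file is whitespace-delimited text: first row the number of
genotypes `P`, an optional second row naming the ILs (chromosome-tagged
names like `12-1-1`), then one row per pattern (`P` values followed by the
label; `label(inv)` marks inverted twins). Companion files found by naming
convention next to the main file supply expressed-IL masks (`ilexp`) and
un-normalized values (`nonormsq` / `nolowess`); see `ilsom/io.py` for the
templates. All companions are optional.

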