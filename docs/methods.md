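# Methods

This note documents the models, conventions and numerical choices
behind `barcode_eval`, and what the synthetic-data studies do and do
not demonstrate.

## Distances

Both distance models use **pairwise deletion**: a site contributes to a
pair only when both residues are unambiguous nucleotides (A/C/G/T);
gaps and IUPAC ambiguity codes are excluded per pair. Complete deletion
(drop any column containing a gap or ambiguity anywhere) is available
as an option; pairwise deletion is the default because it matches the
default of the distance software ecosystem barcode studies typically
use, and wastes far fewer sites under heavy, locus-specific missingness.

The K2P distance is `d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)` with P the
transition and Q the transversion proportion. When `1−2P−Q ≤ 0` or
`1−2Q ≤ 0` the correction is undefined (substitutional saturation).
Saturated pairs are never silently dropped: they are recorded in
`DistanceMatrix.undefined_pairs`, excluded from gap extrema, and cause
specimens to be excluded (greedily, fewest first, with a logged roster)
before tree building. `k2p ≥ p` holds on every defined pair, and the
two converge as divergence → 0; both properties are asserted in tests.

Distances are stored as proportions and rendered as percent with two
decimals only in report writers; all comparisons (gap flags, minima,
maxima) use full float precision.

## Barcode gap

Per species: `D_intra` = maximum defined conspecific distance (undefined
for singletons, reported N/A), `D_NN` = minimum defined distance to any
heterospecific specimen, with the nearest species recorded and ties
broken lexicographically. D_NN is defined over individual specimen
pairs, not species centroids. The per-species gap criterion is the
**strict** inequality `D_NN > D_intra`; the locus-level verdict is
`min D_NN > max D_intra` over the locus (no overlap of the two clouds).
Singleton species contribute to other species' D_NN but have no gap
verdict of their own.

## Neighbour joining

Classic agglomeration: join the pair minimising
`Q(i,j) = (m−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, limb lengths
`l_i = ½·d(i,j) + (r_i − r_j)/(2(m−2))`, reduced distances
`d(u,k) = ½·(d(i,k)+d(j,k)−d(i,j))`. Exactness on additive matrices
(topology and path lengths) is the correctness oracle, checked on
random additive 4–8-taxon instances and against a least-squares brute
force over the three quartet topologies; an independent NJ
implementation (scikit-bio) serves as a cross-check in the test suite.

Determinism: ties in Q are broken by the smallest (row, column) index
pair (row-major argmin), so degenerate inputs (e.g. an all-zero matrix)
give a reproducible topology. Negative limb lengths — possible on
non-additive data — are clamped to zero for output, with the raw
deficit logged; clamping never triggers on additive input.

## Bootstrap and monophyly

Supports are attached to the full-data tree (not a consensus):
alignment columns are resampled with replacement, the tree is rebuilt
per replicate, and an internal edge's support is 100 × the frequency of
its tip bipartition among retained replicates. Replicates whose
resampled distance matrix contains an undefined pair are dropped and
counted (warning above 10%). All bipartitions are canonicalised as the
tip set not containing the lexicographically smallest tip, making
supports invariant to rooting and label order.

A species with ≥ 2 tips is monophyletic iff some edge's removal splits
the tips into exactly that species versus the rest (pendant edges
included, so a species comprising all but one tip is handled).
Singletons are trivially monophyletic with support N/A. One convention
extends the support rule: when the complement of a species is a single
tip, the defining split is present in every possible tree on those
tips, so its support is reported as 100 rather than N/A. The reporting
threshold (default 70%, strict `>`) flags well-supported species but
never alters verdicts.

Externally built trees (e.g. maximum-likelihood trees from dedicated
software) can be imported as Newick, with internal node labels read as
supports, and fed to the same monophyly test; ML inference itself is
deliberately out of scope.

## Multilocus combinations

Combinations use the **shared-specimen intersection** (specimens
sequenced at every member locus), not a missing-as-gaps supermatrix:
with dropout as heavy and structured as real PCR success tables, a
supermatrix would mix species-level absence with sequence signal. Loci
are concatenated in sorted order with a retained partition map
(provenance only; distances are unpartitioned). Subsets with fewer than
3 shared specimens or 2 species are skipped with a logged reason; these
viability floors are configurable. Results are independent of locus
input order. Arity up to 6 is supported; analyses of published studies
typically stop at 5 of 6 loci.

## Synthetic data

The generator is the package's study stand-in, and its defaults encode
the case-study conditions:

* **Substitution process**: K2P itself (κ-weighted two-rate process),
  matched to the analysis model so that design divergences are
  recoverable in expectation by the K2P estimator — parameter-recovery
  tests are then exact in expectation rather than model-misspecified.
  κ defaults to 2.0, a typical plant transition/transversion ratio.
* **Structure**: a uniform-random root sequence evolves down a species
  tree (branch lengths in expected substitutions/site); each specimen
  then receives a private terminal branch of `intraspecific_scale/2`,
  i.e. within-species variation is a star with expected pairwise
  divergence `intraspecific_scale` (default 0.005). Per-locus rate
  multipliers scale all branches alike, so divergence *ratios* are
  locus-invariant.
* **Dropout**: specimen-level Bernoulli per (locus, species),
  independent across loci, mirroring per-locus PCR success structure.
* **Indels**: off by default; when enabled, inserted as species-shared
  gap runs so matrices remain valid alignments without re-alignment.

The bundled case-study fixture (`case_study_fixture`) uses twelve grass
species with the published specimen counts (66 total, 5 invasive), the
published per-locus aligned lengths, and the published PCR success
rates as dropout probabilities. The species tree places the two
*Nassella* congeners at nominal divergence 0.01 — twice the
intraspecific scale, deliberately unresolvable — and every other
species pair at ≥ 0.1, with terminal stems ≥ 0.05. Plastid loci get
rate multipliers 0.35–0.6 and nuclear loci 1.0–1.2, echoing the
divergence ranges the real loci display.

**What the simulations do not emulate**: real intraspecific structure
(e.g. apomictic lineages with intraspecific divergence of several
percent), rate variation among sites, alignment error, and — notably —
the real study's disproportionately higher *nuclear* divergence of the
*Nassella* pair (the real ETS locus resolves them at ~3% while the
plastid loci do not; under proportional locus rates our fixture keeps
them unresolved at every locus). Passing recovery tests therefore
demonstrates the correctness of the analysis chain under its own model
assumptions, not barcoding performance on real grasses.

## Validation studies

`validation.monophyly_recovery` simulates the case-study fixture under
per-run seeds and measures, over (run, locus, species) instances, how
often a species designed ≥ 10× the intraspecific scale away from every
other species present at the locus is recovered monophyletic with
bootstrap support > 70%. With 100 runs of 100 replicates the observed
rate is ≥ 95% (in practice ~100%). `validation.gap_recovery` measures
detection of a designed two-species gap (divergence 10× the
intraspecific scale): near-certain; with no designed gap, detection
falls to chance. Replicate counts (100 bootstrap replicates in the
studies, versus the 1000 used for real-data reports) were chosen as the
smallest sizes at which support estimates are stable enough for a 70%
threshold.

## Determinism

Every stochastic step (simulation, bootstrap, combination analyses)
draws from `numpy.random.default_rng` seeded from a single configured
seed; loci, species and specimens are always processed in sorted or
listed order. Identical config + seed yields byte-identical FASTA,
truth JSON, `summary.json` and Newick outputs. JSON is written with
sorted keys; Newick children are ordered by smallest descendant tip
label.

## Known limitations

* The indel-event count is convention-dependent; the default counts
  distinct maximal gap runs keyed by (start, end) coordinates, with a
  per-sequence-run alternative. Published indel counts rarely state
  their convention, so cross-study comparison of this one statistic is
  approximate.
* NJ is O(n³) in dense NumPy; comfortable for hundreds of specimens,
  not for thousands.
* The gap analysis assumes the species assignments in the metadata are
  correct; it flags overlap but cannot distinguish misidentification
  from genuine shared variation.
* K2P saturation handling excludes pairs rather than imputing; under
  extreme divergence (observed in real spacer loci above ~40%) D_NN
  minima are unaffected but tree rosters shrink, and the logs should be
  consulted.
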