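# Methods

This note documents the models and procedures implemented in `idrscape`,
the parameters that matter, the design choices made where conventions
were genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## IDR definition and segmentation

A disorder track assigns each residue a score in [0, 1]; scores come
from an external predictor (ingested as a `protein_id / position /
score` TSV, with the predictor mode kept as free-text metadata, e.g.
IUPRED2A "short" vs "long") or from the bundled scorer below. An IDR is
operationalized as:

- every residue scores ≥ `threshold` (default 0.5), except that
  interior runs of sub-threshold residues of length ≤ `max_gap`
  (default 10) are tolerated;
- the segment begins and ends on above-threshold residues (a tolerated
  gap never dangles at an edge — an IDR bounded by ordered residues is
  not extended by sub-threshold tails);
- total length ≥ `min_len` (default 30; 20 and 40 are standard
  variants, and the set of segments at 40 is always a subset of that at
  30, which is a subset of that at 20).

"Tolerated stretches" are read as *runs*: each maximal interior
sub-threshold run must be ≤ `max_gap`; the total number of exceptional
residues is not separately bounded, but is reported per segment together
with a confidence score `1 − n_exceptional/length`. This is the simplest
monotone, bounded penalty that equals 1 exactly for clean segments;
because `n_exceptional` is reported alongside, alternative penalties can
be recomputed from the output. Confidence is descriptive only — no
filtering is applied to it.

The implementation marks above-threshold residues, merges maximal
above-threshold runs across bridgeable gaps (left to right; merge
eligibility depends only on gap lengths, so the result is independent of
scan direction), then length-filters. Two segments separated by a gap
longer than `max_gap` are always reported separately. Equivalence with a
brute-force oracle — enumerate every interval satisfying the invariants,
keep the maximal ones — is asserted exhaustively for all two-level
tracks up to length 12 and on 1,000 random tracks up to length 50
(problem sizes chosen to keep the exhaustive check exact and the whole
suite fast; the oracle is O(L³)).

Per-protein **IDR content** is 100 × (sum of segment lengths)/L, and
cohort summaries report, per group: mean, SD (n−1), median and quartiles
(linear interpolation between order statistics) of content; the fraction
of proteins with ≥ 1 IDR at `min_len` ∈ {20, 30, 40} (re-segmented per
variant); and the fraction with content ≥ 25%.

## Bundled disorder scorer

The bundled scorer is a sliding-window mean (default window 21, odd,
truncated at the termini rather than padded — no phantom residues) of a
per-residue disorder-propensity table. The shipped table is the TOP-IDP
scale (Campen et al., *Protein Pept. Lett.* 15:956–963, 2008) rescaled
linearly to [0, 1]. This scorer exists so that the pipeline runs
end-to-end without external predictors; it is explicitly **not** a
reimplementation of IUPRED's pairwise-energy estimation, nor of
catGRANULE or PScore. Cohort-level percentages computed from it are
therefore not comparable to ones computed from real predictor tracks;
for production analyses users should ingest real IUPRED2A (or
equivalent) tracks.

## Composition analytics

- k-mer spectra (k ∈ {1, 2, 3}) use overlapping windows with stride 1,
  counted within each region independently: windows never span region
  boundaries, so dipeptides bridging an ordered gap between two IDRs are
  never counted. Regions shorter than k contribute zero windows
  (warning, not error). Frequencies always sum to 1 when any window
  exists, and the total window count is Σ(ℓ − k + 1) over regions with
  ℓ ≥ k.
- Pooling across a group is residue-weighted (counts summed over all
  IDRs), so long IDRs contribute proportionally more; an IDR-weighted
  average can be formed from the per-IDR tables.
- The reduced alphabet partitions the 20 standard residues into six
  physico-chemical classes (aromatic YWF; positively charged RKH; polar
  uncharged NQ; negatively charged DE; small/flexible GSPATC;
  hydrophobic ILVM); mapping then counting commutes with counting then
  mapping for single residues.
- `top_kmers` sorts by frequency descending with lexicographic
  tie-breaking, so ranked lists are reproducible.
- Residue-set shares (e.g. Arg+Gly over an RGG box) are computed over
  1-based, both-ends-inclusive windows and reported to one decimal.
  Boundary conventions matter at small window sizes: for the FMRP RGG
  box the inclusive 527–552 window gives 84.6% while interior-exclusive
  variants give 83.3% — when comparing against externally reported
  integers the convention must be fixed explicitly, and the package
  reports both in its acceptance output.

## Reference sequences

`idrscape/data/reference_sequences_synthetic.fasta` bundles offline
reconstructions of the canonical sequences of human FMRP (UniProt
Q06787, 632 aa) and SAM68 (Q07666, 443 aa) for worked examples and
tests. They are labelled *synthetic* because they were written down
without database access and are not byte-verified against UniProt: both
match the canonical lengths, FMRP contains the canonical RGG-box
sequence at 527–552, and SAM68's 283–363 subregion reproduces the known
61.7% Pro/Gly/Arg share exactly. Regional shares outside the validated
regions (e.g. FMRP 466–563) may deviate by a few points from values
computed on the true canonical sequence; production analyses should use
sequences fetched from UniProt.

## LLPS classification

Classification is threshold-based on externally computed predictor
scores: catGRANULE ≥ 1.0, PScore ≥ 2.5, and ≥ 25% IDR content as a
parallel criterion. Boundary inclusivity (score = threshold → positive)
is a documented choice; thresholds are configurable. Proteins lacking a
score for a method are excluded from that method's denominator (logged);
a group with no scores for a method is an error rather than a silent
zero. Membership fractions against curated lists are reported per list
plus a union row and a per-list maximum, since "found in LLPS
databases" can reasonably mean either. The pi-contact share (residues
with aromatic Y/F/W/H, amide Q/N, carboxyl E/D or guanidinium R side
chains) is a descriptive composition statistic related to the physics
PScore models, not a substitute for it.

## Group statistics

One-way fixed-effects ANOVA (between/within mean squares; error on zero
total variance) followed by Tukey–Kramer over all pairs:

q_ij = |x̄ᵢ − x̄ⱼ| / √((MSW/2)(1/nᵢ + 1/nⱼ)),

with p-values from scipy's studentized-range distribution (numerical,
tolerance well below 1e-6; no table lookup). With equal n this reduces
to classical Tukey HSD, which is asserted in tests, as is agreement
with scipy's ANOVA and statsmodels' Tukey HSD to 1e-6–1e-8 on seeded
datasets. Groups of size 1 are excluded with a logged warning; a
variance ratio > 10 between groups logs a heteroscedasticity warning
but applies no correction (plain ANOVA is the contract). Raw values
(not transformed percentages) are compared by default.

## Synthetic cohort generator

The generator emulates exactly the features the analysis consumes:

- **Architecture**: each protein is a concatenation of folded-like and
  IDR blocks; lengths are lognormal (median 450 aa, clipped to
  150–2500); proteins with enough planted disorder get one or two IDR
  blocks with internal folded spacers ≥ 30 residues so planted IDRs
  stay separable at `max_gap` 10.
- **Composition**: residues are drawn i.i.d. within a block — folded
  blocks from an average globular background, IDR blocks from biased
  vectors placing ~80% of mass on G/S/R/P (Reader-like) or ~76% on
  E/K/R/S (Enzyme-like); the combined-interactome group uses their
  midpoint. An optional motif mode overwrites a stated fraction of IDR
  residues with literal k-mer copies (e.g. "RS", "GG") to make
  top-k-mer recovery tests sharp.
- **Tracks**: piecewise-constant at 0.8 (IDR) / 0.2 (folded) plus
  Gaussian noise (default SD 0.05), clipped to [0, 1].
- **Targets**: per-group IDR-content distributions are Normal(48, 25)
  for Readers, Normal(17, 14) for Enzymes and Normal(29, 26) for the
  rest (percent, clipped to [0, 95]); LLPS propensity scores are Normal
  with fixed SDs (0.75 catGRANULE, 1.5 PScore) and means placed so the
  configured fractions (67/59% Readers, 31/17% Enzymes, 30/21% others)
  fall above the thresholds.

These defaults are the package's standard study conditions; the default
analysis cohort is 113 Readers + 93 Enzymes + 200 others (the script
problem size chosen so every stage runs in seconds).

What the synthetic tests show: the segmenter recovers planted intervals
(mean Jaccard ≈ 0.99 at noise SD 0.1), group means/biases/fractions are
recovered within Monte-Carlo error, and the statistics layer orders the
groups correctly. What they do not show: real disorder predictors
produce autocorrelated, sequence-dependent tracks rather than two-level
noise; real IDR compositions are not i.i.d. (they contain motif grammar
and charge patterning); and real interactome percentages depend on the
exact accession lists and predictor versions used. Passing tests
therefore validate the pipeline's algebra and contracts, not any
biological claim about a particular interactome.

## Degenerate inputs and numerical choices

- Tracks must match sequence lengths exactly and scores must lie in
  [0, 1]; violations are errors naming protein and position, never
  silent clipping.
- Non-standard residues (X/B/Z/U/O/J/*): default policy strips them
  with a warning for composition work; `reject` and `keep-as-unknown`
  (counts toward length, belongs to no composition class) are
  available. Stripping must not be combined with externally supplied
  tracks, since it would shift coordinates.
- Empty groups are errors in group-wise operations; groups with zero
  IDR residues produce warning rows in composition reports.
- All percentages are reported to one decimal; confidence to six.
- Determinism: identical configuration (including seeds) produces
  byte-identical output tables; the run manifest records a
  configuration hash, row counts and SHA-256 digests.
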