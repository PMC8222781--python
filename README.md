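# idrscape

Analytics for intrinsically disordered regions (IDRs) in protein
interactome cohorts: disorder-track segmentation, low-complexity
composition and k-mer analysis, liquid–liquid phase separation (LLPS)
propensity classification, and group-level statistics. It is aimed at
researchers characterizing cohorts of nucleic-acid-binding proteins —
e.g. an R-loop interactome split into *Readers* (KH/RRM domain proteins),
*Enzymes* (helicases/hydrolases) and the remaining combined interactome —
where the question is how prevalent IDRs are in each group, what their
sequence composition looks like, and whether the groups differ in their
propensity to phase separate.

## What it computes

**IDR segmentation.** Given a per-residue disorder score track
*s*₁…*s*_L ∈ [0,1] (e.g. from IUPRED2A), an IDR is a maximal segment of
≥ *m* residues with *sᵢ* ≥ θ, tolerating interior sub-threshold runs of
≤ *g* residues (defaults θ = 0.5, *m* = 30, *g* = 10; variants *m* = 20,
40). Segments begin and end on above-threshold residues. Each segment
carries a confidence

> c = 1 − *n*ₑₓ⁄ℓ,

where *n*ₑₓ counts exceptional (sub-threshold) residues and ℓ is the
segment length. A protein's **IDR content** is 100 × (residues inside
IDRs)/L. The segmenter is verified exhaustively against a brute-force
maximal-valid-segment oracle.

**Composition.** Residue, dipeptide and tripeptide spectra over IDRs
(overlapping windows, stride 1, never crossing segment boundaries), a
six-class reduced alphabet (1 aromatic YWF, 2 positive RKH, 3 polar NQ,
4 negative DE, 5 small/flexible GSPATC, 6 hydrophobic ILVM),
residue-set shares of arbitrary regions (e.g. the Arg+Gly share of an
RGG box), and reproducible top-k-mer rankings.

**LLPS classification.** A protein is LLPS-positive when an external
predictor score meets its critical threshold (catGRANULE ≥ 1.0,
PScore ≥ 2.5, boundary inclusive) or holds ≥ 25% IDR content; the
package reports per-group positive percentages and LLPS-database
membership fractions (per list, union, and maximum).

**Group statistics.** One-way ANOVA with Tukey–Kramer post-hoc tests
(studentized-range p-values; Kramer adjustment for unequal group sizes)
and boxplot summaries, checked against scipy/statsmodels references.

**Synthetic cohorts.** A generator plants modular proteins (alternating
folded-like and IDR blocks), group-specific IDR composition biases
(Reader-like G/S/R/P-rich vs Enzyme-like E/K/R/S-rich), disorder tracks
high over planted IDRs with clipped Gaussian noise, and propensity
scores calibrated to target positive fractions — so the whole pipeline
is testable against known ground truth without any downloads.

## Worked example

The bundled reference sequences (`idrscape/data/`) include
reconstructions of two canonical IDR-bearing R-loop readers, FMRP
(UniProt Q06787) and SAM68 (Q07666):

```bash
$ idrscape compose src/idrscape/data/reference_sequences_synthetic.fasta \
      --protein-id SAM68_HUMAN_synthetic --region 283-363 --residues PGR
SAM68_HUMAN_synthetic   283-363 PGR     61.7
```

— 61.7% of the 81-residue SAM68 C-IDR subregion is Pro/Gly/Arg, the
low-complexity signature of that region. The FMRP RGG box (residues
527–552) gives an Arg+Gly share of 84.6% over the inclusive window.

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (113 Readers, 93 Enzymes, 200 further combined-
interactome proteins, seed 1). `python analysis/02_segment_idrs.py`
prints:

```
combined_only: n= 200  content  28.3 +/- 23.5%   >=1 IDR30: 76%
       enzyme: n=  93  content  15.4 +/- 14.0%   >=1 IDR30: 68%
       reader: n= 113  content  47.0 +/- 26.1%   >=1 IDR30: 94%
```

i.e. the pipeline recovers the planted group structure: Readers carry
roughly three times the disordered content of Enzymes, and nearly all
Readers contain a ≥30-residue IDR. `analysis/03_idr_composition.py`
shows the planted composition biases in the recovered IDRs (Reader top
dipeptides GG, GR, SG, RG, GS vs Enzyme EK, EE, RE, KK, KE), and
`analysis/05_group_comparison.py` confirms the groups separate
(IDR-content ANOVA p ≈ 5 × 10⁻²¹, all pairs significant by
Tukey–Kramer; by LLPS propensity the Readers differ from both other
groups while Enzymes vs combined interactome do not).

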