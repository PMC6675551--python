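# Methods

`neopept` reimplements, as a tested library, the computational core of an
MS-driven neoepitope screen in a syngeneic mouse tumor model: candidate
generation from somatic variants, immunopeptidome identification filters,
targeted-MS validation logic, in-vivo tumor-control scoring, and
structural comparison of WT/mutant peptide–MHC models. This note records
the models, parameter choices and conventions behind each stage, and what
the synthetic test data do and do not establish.

## Mutant search space (`variantdb`)

Somatic single-nucleotide variants are consumed at protein coordinates
(protein id, 1-based position, ref/alt residue, read coverage, TPM).
Applying a variant whose stated reference residue disagrees with the
proteome raises an error rather than skipping the record: silently dropped
variants would shrink the mutant search space without shrinking the decoy
space, biasing downstream FDR estimates.

Each variant yields a mutation-centered window of the mutated protein
spanning `flank` residues on each side (default `flank = 15`, so windows
are at most 31 aa, truncated only at protein termini). The windows are
concatenated after the reference proteome into a FASTA search database
with headers `neo|<protein_id>|p.<ref><pos><alt>`; duplicate windows
arising from distinct variants are kept as separate records so provenance
survives. Candidate epitopes are all 8–11-mers of a window whose span
includes the mutated residue, each paired with the wild-type k-mer at the
same coordinates; an interior mutation therefore yields exactly k
candidates per length k (38 for lengths 8–11), fewer near termini.
Proteins containing nonstandard residues (X, B, Z, U) are excluded from
window building with a logged warning.

## MHC motif scoring and DAI (`mhc_binding`)

Quantitative binding predictions are outside this package's scope: IC50
values (nM) enter through a TSV injection interface and are never
computed here. What the package provides is a transparent position-weight
scoring of candidate peptides against the BALB/c H-2 alleles, sufficient
to assign a presenting allele by anchor compatibility:

* **Kd** — Tyr/Phe at P2, Leu/Ile/Val at the C-terminus;
* **Dd** — Gly at P2, Pro at P3, Leu/Ile/Phe at the C-terminus, with a
  tolerant P5 secondary anchor (Phe preferred; Arg/Ile/Gly tolerated);
* **Ld** — Pro at P2, Phe/Leu/Met at the C-terminus.

Weights are log-odds-style values stored in a YAML table (primary anchors
2.0, preferred secondary residues ≤ 1.5) and editable without code
change. A peptide is assigned to the best-scoring allele only when its
score exceeds the runner-up by a margin (default 1.0) and exceeds an
acceptance floor (default 0, i.e. at least one anchor must match); ties
and sub-floor peptides are left unassigned. This is deliberately a
coarse, auditable filter, not an affinity model.

The Differential Agretopic Index is fixed as
`DAI = ln(IC50_wt) − ln(IC50_mut)`, so mutations that improve binding
(lower mutant IC50) score positive. IC50 tiers use half-open intervals:
strong < 50 nM ≤ intermediate < 500 ≤ weak < 5000 ≤ very weak.

## Immunopeptidome filtering (`peptidome`)

**Target–decoy FDR.** The peptide-level filter retains targets with score
≥ t\*, where t\* is the smallest observed score such that
`#decoys(≥t) / #targets(≥t) ≤ fdr` (default 5%). The threshold search
scans the union of observed scores and keeps ties together; decoys are
never returned; an all-decoy input is an error. Retention is monotone in
the FDR level.

**Length filter.** 8–25 aa inclusive, the window appropriate for MHC-I
elution searches with unspecific enzyme digestion.

**Intensity normalization.** Per sample, intensities are log2-transformed
(a flag disables the transform for pre-logged input), the median q2 is
subtracted, and residuals are scaled asymmetrically: positive residuals
divided by q3 − q2, negative by q2 − q1. Quartiles are computed by linear
interpolation on sorted values — the convention is stated because the
upstream description names none. Fixed points of the map: q2 → 0 (values
exactly at the median map to 0 by convention, avoiding the division
branch ambiguity), q1 → −1, q3 → +1. A zero quartile spread is an error.
Missing intensities pass through untouched.

**Neoepitope calls.** A retained peptide is flagged iff it is a substring
of some long peptide, its span covers the mutated offset, and it occurs
nowhere in the reference proteome. The last condition means
mutation-covering peptides that coincidentally match a reference
substring elsewhere are excluded — they are not tumor-specific — and in
particular a wild-type counterpart can never be flagged.

## PRM validation (`prm`)

Masses are monoisotopic throughout (proton 1.007276 Da, water
18.010565 Da; residue masses from the standard amino-acid table). The
shipped label table covers full ¹³C/¹⁵N substitution of K, R, L, P, V and
F (e.g. ¹³C₆¹⁵N₄-Arg = +10.00827 Da); arbitrary labels are accepted as
(residue, delta) pairs. The heavy precursor shift is the label delta
times the residue's occurrence count, and a fragment carries the shift
iff its span contains the labeled residue — so b/y ions not spanning the
label have identical light and heavy m/z, a useful internal control.

XICs are extracted by summing signals within ±0.02 m/z of the target per
time point. Co-elution is scored per fragment as the Pearson correlation
of the light and heavy traces after linear interpolation onto the union
of their time grids (the gridding convention is this package's choice).
The verdict is `validated` iff at least `min_fragments` (default 3)
fragments reach r ≥ 0.9, the apexes of the summed traces align within
0.2 min, and the spectral contrast (normalized dot product of the
per-fragment intensity vectors at the two apexes) reaches 0.9. These
thresholds are conventional targeted-proteomics practice rather than
values fixed by the source study, and all live in the function signature
/ config. Flat (all-zero) traces are excluded from correlation with a
record in the report. The heavy-only QC check passes when the strongest
signal at any light m/z is at most 1% of the heavy apex.

## Tumor Control Index (`tumor_control`)

Growth input is the average of two perpendicular tumor diameters (mm)
per mouse per day, day 0 being tumor challenge. The TCI integrates three
aspects of tumor control, each 0–10, total ≤ 30. The published index is
defined by reference rather than printed formulas, so the decomposition
below is this package's documented convention, constrained by the 0–30
bound and by the monotonicity each component must satisfy:

* **rejection** = 10 iff the tumor is below the detection floor (1 mm)
  at the final observation and has remained below it since the first
  undetectable day — a durable complete response; otherwise 0;
* **inhibition** = 10 × clamp(1 − AUC(curve)/AUC(control mean), 0, 1),
  AUC being the trapezoidal area of diameter over days, curves first
  interpolated to the control's day grid;
* **stability** = 10 × the fraction of observation days whose diameter
  lies within ±20% of the diameter on the first day a measurable tumor
  appeared, undetectable days counting as stable.

A never-detectable curve scores 10 on all three components (total 30,
the maximum); a curve identical to the control mean scores 0 inhibition
and 0 rejection. The detection floor and stability band are arguments
with the defaults above. Truncated curves (early euthanasia) contribute
over their observed days only, via the interpolation rule.

Group comparisons follow the standard design for this assay: one-way
ANOVA with Dunnett's test against the control group for TCI totals,
Tukey's all-pairs test for AUCs (scipy implementations), and two-sample
comparisons by a two-tailed t test. Adjusted p-values are reported.

## Structural metrics (`structure`)

Models arrive as standard PDB coordinates (first MODEL only; waters,
heteroatoms and hydrogens dropped by default; malformed ATOM records
raise an error naming the line). Two models are compared by first
superposing the mutant on the WT via a least-squares (Kabsch) fit of the
MHC-chain backbone atoms (N, CA, C, O) — the peptide is excluded from
the fit — then computing the peptide RMSD over matched atoms with no
re-fitting, so the value measures peptide movement within the groove.
`backbone` matches N/CA/C/O per residue; `common_heavy` matches the
heavy-atom names shared by the two residues at each position, which
handles WT/mutant pairs differing at the substituted residue.

SASA uses Shrake–Rupley sampling: each atom's sphere at (vdW radius +
1.4 Å probe) is covered with a golden-spiral lattice (default 960
points, giving isolated-sphere areas within 1% of the analytic value),
and a point is accessible when outside every neighbor's extended sphere.
Radii: C 1.70, N 1.55, O 1.52, S 1.80 Å (configurable table). The
peptide's **exposed hydrophobic surface** is its SASA summed over apolar
atoms — carbon and sulfur atoms with no nitrogen or oxygen within
covalent-bond distance (1.9 Å heavy-atom cutoff) — computed in the
full-complex context so groove-buried surface is excluded. The
operational hydrophobicity rule is stated because published exposed-area
figures rarely define one; WT/mutant pairs should therefore be compared
through the relative change (A_mut − A_wt)/A_wt rather than absolute
areas.

Salt bridges are basic-N/acidic-O contacts (Arg NE/NH1/NH2, Lys NZ,
optionally His; Asp OD1/OD2, Glu OE1/OE2; free N/OXT termini) within
4.0 Å, reported once per residue pair at the minimum distance.

## Synthetic data (`synthetic`)

Every input class is generated, since no raw data accompany the original
study. One global seed fans out to independent named streams, so adding
draws to one generator never perturbs another. Defaults describe a
small-scale but structurally faithful screen:

* proteome of 200 random canonical proteins (80–400 aa) with 40 planted
  variants that satisfy the reference-match invariant by construction;
* PSM lists of 300 targets (Gaussian scores, mean 80, sd 10) and 300
  decoys (mean 30, sd 10) with log-normal intensities (log2 mean 20,
  sd 2) and 10 planted mutation-covering neoepitopes, truth labels
  returned alongside;
* PRM traces as Gaussian peaks (σ 0.15 min) at a 30-min apex over a
  ±2 min scheduled window with 1% multiplicative noise; the light
  channel can be shifted or scaled to construct failing cases;
* growth curves for 5-mouse groups observed every third day to day 24:
  non-rejecting mice follow logistic growth to ~15 mm with 0.4 mm
  measurement noise; rejecting mice show a complete response (no
  palpable tumor at any measurement), matching the phenotype that
  defines the maximum TCI;
* toy peptide–MHC models as idealized extended chains (N/CA/C/O/CB per
  residue, 3.8 Å CA spacing) with an untouched scaffold chain, so
  superposition is exact and peptide RMSD equals the injected
  perturbation.

What passing tests on these data show: the filters, scores and metrics
implement their definitions exactly, at the stated tolerances. What they
do not show: performance on real spectra (no chimeric spectra, retention
drift, interference or missing values), real binding prediction
accuracy, or biological validity of any specific neoepitope call.

## Numerical conventions and limitations

* Quartiles and percentiles: numpy linear interpolation.
* FDR threshold search is O(n²) over unique scores — fine at
  immunopeptidome scale, not optimized for proteome-wide PSM lists.
* Trace correlation needs ≥ 2 union time points and non-constant
  signals; degenerate fragments are excluded, not imputed.
* TCI component constants (floor 1 mm, band ±20%) are conventions; only
  the bound (≤ 30), the component extremes, and monotonicity are
  test-enforced facts.
* SASA is sampled, not analytic: areas carry ~1% sampling error at the
  default 960 points; exactly coincident atoms are a degenerate input
  (each sphere counted) — real structures never contain them.
* The motif tables are anchor heuristics; allele assignment should be
  read as "motif-compatible", not as a binding prediction.
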