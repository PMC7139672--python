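# Methods

This note records the models, conventions, numerical choices, and known
limitations behind each part of the toolkit.

## Construct model and residue numbering

A `ProteinConstruct` stores the N-terminal tag, the mature enzyme
sequence, and the coding ORF, and validates at construction that the ORF
translates (standard genetic code) to tag + mature followed by exactly
one stop codon. Two addressing schemes are supported: construct
numbering (1-based over the full protein) and mature numbering (mature
residue 1 = construct residue `tag_length + 1`, tag residues −tag_length…−1,
no index 0). The packaged BSLA reference construct has a 23-residue
pelB-derived tag and a 181-residue mature lipase (204 residues, 615-nt
ORF); all region definitions and variant names in the package use mature
numbering, which matches the numbering of the BSLA crystal structure.

## Variability profiling

Superposition is Cα-only: region calling needs backbone-level
variability, and full-atom superposition would add noise from side-chain
conformers without changing region boundaries. Residue correspondence
between the reference and each ensemble member is supplied externally
(matching residue numbers, or an aligned FASTA); the package deliberately
does not implement multiple structure alignment — its contribution is
what happens *after* alignment.

The rigid superposition is the closed-form Kabsch solution (SVD of the
cross-covariance, determinant-corrected to a proper rotation). Inputs
with fewer than three pairs, or rank-deficient (collinear/coincident)
point sets, are rejected because the optimal rotation is then
under-determined. The test suite cross-checks against an independent
quaternion-eigenvalue (Horn) implementation.

Per reference residue, the profile records the quadratic mean (RMS, not
the arithmetic mean of distances) of Cα deviations over the members
mapping that residue, plus a coverage count; unmapped residues carry NaN
rather than 0 Å so that "no information" can never read as "conserved".

By default each member is superposed on **all** of its mapped residues.
This is the right default for heterogeneous real ensembles, but it means
a uniformly displaced loop partially contaminates the global fit: with
n_loop of n residues displaced by d, the best-fit translation absorbs
roughly n_loop·d/n, so the loop reads slightly below d and the core
slightly above 0. When a rigid core is known — as in the synthetic
fixtures — `variability_profile(..., fit_residues=core)` performs
core-referenced superposition, the standard practice for measuring loop
excursions, and recovers a constructed displacement exactly (to 1e-6 in
the in-memory tests; to the 3-decimal coordinate precision, ~1e-3 Å,
after a PDB round trip).

Region calling scans for maximal runs of consecutive residues with
RMSD ≥ threshold and coverage ≥ min_coverage, keeping runs of at least
min_length. There is no field-standard threshold for "highly variable";
the shipped default of 2.0 Å is a convention, always user-overridable
and echoed into every output header. Runs that touch the exclusion set
(catalytic stretches; for BSLA, regions around D133 and H156 plus S77)
are returned flagged `excluded` rather than silently dropped. No
secondary-structure (coil) filter is applied; the exclusion set and
threshold stand in for it.

## Library design

The deleted block defaults to the *middle rule*: within a region of
length L, a deletion of size k starts at 1-based region offset
⌊(L−k)/2⌋ + 1. For the six packaged BSLA regions this reproduces five of
the six published layouts; library 4 (region 90–94) was designed with
the block one position to the right of the rule, so its config entry
carries an explicit `deleted_override: [92, 93]`. The override mechanism
is general — any hand-shifted block that leaves a flank on both sides is
accepted.

Deletion size is a parameter (default 2: an even-length deletion keeps
the register of downstream residue orientations, whereas a single
deletion flips it — disruptive in a small single-domain enzyme). The
degenerate codon is NNK by default but any IUPAC triplet is accepted.

Variant nomenclature orders tokens by position: left junction
substitution, one Δ token per deleted wildtype residue, right junction
substitution; a junction that retains the wildtype residue drops the new
letter (`F41` rather than `F41F`). A strict inverse parser validates all
wildtype letters against the construct.

### Primers

Primer pairs use the fully overlapping (classic QuickChange) dialect:
the forward primer is left homology arm + NNK + NNK + right homology
arm on the coding strand with the deleted codons absent, and the reverse
primer is the exact reverse complement. The two-step
separate-forward/reverse-primer PCR protocol the strategy is normally
run with is compatible with fully complementary primers, and the dialect
makes the reverse sequence a pure function of the forward one.

Arms grow one nucleotide at a time from `min_arm` (default 15 nt) until
the arm's melting temperature reaches `tm_target` (default 60 °C) or
`max_arm` (default 45 nt) is hit, which warns. Arm Tm uses unified
nearest-neighbour thermodynamics for arms ≥ 14 nt and the Wallace
2(A+T)+4(G+C) rule below that (NN initiation terms dominate very short
sequences and the rule of thumb is the conventional choice there).
Degenerate positions never enter a Tm computation by construction. The
nearest-neighbour route delegates to Biopython's `Tm_NN` (unified
Allawi–SantaLucia parameter set, entropy salt correction); the test
suite re-derives it from a hand-summed ΔH/ΔS table. No hairpin or
self-dimer screening is attempted.

## NNK combinatorics and coverage

NNK expands to 32 codons: all 20 amino acids (Leu/Arg/Ser keep 3 codons,
several 2, the rest 1) plus the single stop TAG. A two-NNK junction has
1024 codon pairs; 63 contain a stop, leaving 31² = 961 codon pairs over
400 ordered amino-acid pairs.

Clone sampling is modelled as uniform over expanded codons, independent
across the two positions — ideal synthesis; no codon-usage, synthesis,
or transformation bias, which is documented rather than modelled.
Statistics default to conditioning on clones without a stop at either
junction (stop clones are inactive by construction); both conditioned
and unconditioned glycine-pair nulls are reported (1 − (29/31)² ≈ 0.1249
and 1 − (30/32)² ≈ 0.1211) since the convention used for the informal
"random chance" comparison is not fixed by the data.

Expected distinct pairs after n clones is the coupon-collector sum
Σ_pairs (1 − (1 − p_pair)^n); the expected stop-clone fraction is
1 − (31/32)². Full-coverage probability has no convenient closed form
over non-uniform pairs and is estimated by seeded Monte Carlo with a
binomial standard error; every report records its seed and repetition
count. The default screening depth used in examples is 3000 clones per
library, at which the analytic expectation is ≈ 393 of 400 pairs.

## Screening statistics

Screening tables are (library, ordered pair, active/inactive) rows.
Entries are counted **as listed**: duplicate pairs are independent
sequenced clones, and the packaged BSLA table keeps its printed repeats
(including an identical inactive list shared by two libraries, kept as
printed). A `distinct` mode collapses duplicates per (library, pair)
but is not the default, because as-listed counting is what the headline
prevalence figures (49% / 11%) are defined over. Fractions are stored at
full precision; percent display rounds half-up to an integer.

Enrichment formalizes the active-vs-inactive comparison as a two-sided
Fisher exact test on the presence/absence × active/inactive table
(scipy), with the Haldane–Anscombe +0.5 correction applied to the odds
ratio when a cell is zero. The test suite verifies the p-value against
exhaustive hypergeometric enumeration — all tables with total N ≤ 20
exhaustively (~10⁴ tables, chosen to keep the suite fast) plus a seeded
random sample of tables with margins ≤ 30.

## Kinetics

Absorbance slopes (A/min) convert to specific rates via Lambert–Beer:
rate = slope/(ε·ℓ) [M/min] × V[µL] (M·µL = µmol) ÷ mass[mg]. Defaults
are the microtiter assay constants ℓ = 0.58 cm (165 µL/well),
ε = 7194 M⁻¹cm⁻¹ for p-nitrophenol at the assay pH, and a 120 ng/reaction
enzyme loading (the standardized wildtype amount; always override for
other preparations).

Michaelis–Menten fitting is unweighted nonlinear least squares of
v = Vmax·S/(Km+S) on pooled replicate points (a weighted option would be
easy to add; unweighted pooling is the default because plate-reader
replicate structure rarely justifies more). Initialization: Vmax₀ = max
observed rate, Km₀ = concentration whose rate is nearest Vmax₀/2.
Positivity is enforced by optimizing (log Vmax, log Km)
(Levenberg–Marquardt, tolerances 1e-15); standard errors come from the
Jacobian at the optimum and transfer to the natural scale by the delta
method (se(V) = V·se(log V)). Non-convergence raises an error carrying
the solver diagnostics — never a silent partial result. Fitted values
are labelled *observed* Vmax/Km deliberately: no correction is applied
for substrate availability artifacts at high nominal concentrations of
poorly soluble long-chain esters, so values are comparative, not
absolute kinetic constants.

Fluorogenic assays report RFU/min over the "linear range", which has no
standard definition; the package uses the longest prefix of the time
series whose OLS fit has R² ≥ 0.99 (configurable). An exactly constant
prefix counts as linear with slope 0 (R² is undefined there).

The synthetic generator draws v(S)·(1 + CV·z), z ~ N(0,1) i.i.d. —
multiplicative Gaussian noise matching the roughly constant CV of
plate-reader rate measurements. It reproduces the assay's concentration
series (0.06–1.875 mM, plus 2.5 mM for the octanoate substrate) by
default and is deterministic under a seed. What it does *not* emulate:
substrate-solubility saturation, pipetting covariance across a plate,
replicate batch effects, or background hydrolysis — so fit-recovery
tests demonstrate estimator correctness, not robustness to those real
effects.

## Problem sizes in the test suite

The noisy-fit calibration study runs 200 seeded simulations (5% CV,
3 replicates) and requires both generating parameters inside 3 reported
SEs in ≥ 95% of runs. Coverage calibration compares the analytic
expectation with an 80-replicate seeded simulation at n = 600 clones
within 3 standard errors. Kabsch-vs-quaternion agreement is checked on
300 random point sets of 3–10 points at 1e-8.

## Known limitations

- Structural alignment (and hence the original 25-structure BSLA
  ensemble analysis) is out of scope; region boundaries for BSLA ship as
  a curated config, and synthetic ensembles exercise the profiling code.
- Primer design performs no thermodynamic simulation beyond arm Tm; no
  hairpin/dimer checks.
- The clone-sampling model is ideal; real NNK libraries show synthesis
  and transformation bias.
- Kinetics covers the hyperbolic (observed) model only — no interfacial
  activation, inhibition, or enzyme quantification from gels.
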