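# Methods

This note documents the models, conventions and numerical choices behind
`idpchar`, in the order the pipeline uses them.

## Residue property tables

All numeric scales live in versioned TSV files under `idpchar/data/` and are
exposed only through `idpchar.properties.get_scale`; every analysis in the
package reads from this single registry.

- **Average residue masses** (Da): isotope-abundance-weighted masses of each
  residue as incorporated in a chain; peptide Mw adds one water
  (18.01524 Da).  Average, not monoisotopic, masses are used throughout —
  the convention of standard pI/Mw calculators.
- **Bjellqvist pKa set**: side-chain pKas for D/E/C/Y (acidic) and H/K/R
  (basic), terminal-group pKas with residue-specific N-terminal amine
  overrides (e.g. Met 7.00, Pro 8.36) and side-chain overrides for D/E in
  the C-terminal position.  This is the set used by the standard
  web calculators, and it is required to reproduce their two-decimal pI
  output.
- **Kyte–Doolittle indices** for hydropathy smoothing (positive =
  hydrophobic).
- **Wimley–White whole-residue octanol scale** (kcal/mol, water→octanol,
  hydrophobic negative), with neutral and charged variants for D, E, H, K
  and R.  Three groups of entries deserve comment.  (1) The published
  whole-residue values cover the charged forms of D/E/K/R and both forms of
  H; they are transcribed as printed.  (2) The published scale contains no
  free-terminal contributions.  The charged N- and C-terminal constants are
  a *calibration point*: their sum (+7.72 kcal/mol) is fixed against the
  documented behaviour of the standard partitioning calculator for this
  scale on the reference peptide, and split evenly between the two ends
  because only the sum is observable.  (3) Neutral K/R variants and neutral
  termini are estimates kept only to complete the variant set and satisfy
  the charged-more-hydrophilic ordering; no reported quantity depends on
  them.
- **Disorder propensity**: per-residue fractional composition difference
  (C_disordered − C_ordered)/C_ordered between disordered-protein and
  folded-structure databases.  The source publication plots but does not
  tabulate the values, so the table is a transcription of the standard
  composition-bias profile; analyses and tests rely only on its robust
  features (signs: P/E/S/Q/K/G/D/R disorder-promoting, W/C/F/I/Y/V/L/N/M/T/A/H
  order-promoting), not on third-decimal values.
- **214-nm extinction coefficients**: the composition method for peptide
  concentration by far-UV absorbance — one 923 M⁻¹cm⁻¹ term per backbone
  amide plus per-side-chain terms, with a reduced value for an N-terminal
  proline.  Published instrument readings use unpublished refinements; the
  composition sum is expected to land within a couple of percent.

`validate_tables()` re-checks every registry invariant (20-residue
coverage, finiteness, positive masses, variant completeness, sign
structure, variant ordering) and reports rather than raises.

## Titration, pI and charge conventions

Two charge conventions are deliberately kept side by side.  The *integer*
convention (K/R = +1, D/E = −1, His = 0, termini ±1) is the
physiological-pH bookkeeping used when counting charges or placing a
sequence on the diagram of states.  The *Henderson–Hasselbalch* convention
assigns partial charges from the pKa set.  The two disagree visibly near
neutral pH whenever a group titrates there: for the reference peptide the
N-terminal Met amine (pKa 7.00) carries only +0.28 at pH 7.4, so the HH
net charge is +2.36 against the integer +3.  Both numbers are correct
under their own convention and both are reported.

The isoelectric point is the unique zero of the HH net-charge curve
(strictly decreasing in pH); it is found by bisection on [0, 14] to
|q| < 10⁻⁴ and reported to two decimals, matching the reference
calculator's output format.

## Diagram-of-states classification

f⁺ and f⁻ are the fractions of K/R and D/E over the full chain length.
Region rules: R1 if f⁺ < 0.25 and f⁻ < 0.25; R2 if 0.25 ≤ FCR ≤ 0.35 and
|NCPR| ≤ 0.35; R3 if FCR > 0.35 and |NCPR| ≤ 0.35; R4 if f⁻ > 0.35 and
f⁺ ≤ 0.35; R5 if f⁺ > 0.35 and f⁻ ≤ 0.35, applied in that order.  These
are the standard published thresholds; sequences near boundaries are
assigned by rule order.

## Hydropathy windows and transmembrane rules

Profiles are centered, unweighted window means (default window 5) over a
whole-residue scale — by default the Wimley–White octanol values with
charged side chains, so negative means hydrophobic.  No padding is used:
positions where the window overhangs the chain are reported as undefined
(NaN) with an explicit `defined_flag` in TSV output.  Transmembrane
candidacy requires a maximal run of qualifying window positions at least
as long as thickness/rise (30 Å bilayer: 20 residues for a helix at
1.5 Å/residue, 9 for a strand at 3.3 Å/residue), rounded to the nearest
integer.  Positions are 0-based in code and 1-based in all reports.

## Partitioning free energy

ΔG is the sum of whole-residue octanol transfer free energies under an
ionization convention (default: His neutral, K/R/D/E charged) plus the
charged free-terminal contributions; positive totals oppose partitioning.
The partitioning–folding coupling correction subtracts 0.4 kcal/mol per
residue, applied to the *whole* chain length — the convention implied by
the reference arithmetic (a 33-residue chain gains exactly 13.2 kcal/mol).
Whether only folding residues should count is not defined by the source;
the per-residue constant is exposed for sensitivity analysis.

## Synthetic ensembles

The generator replaces an atomistic MD trajectory with an idealized
backbone model:

- **Geometry**: fixed ideal bond lengths (N–CA 1.458 Å, CA–C 1.525 Å,
  C–N 1.329 Å, C=O 1.231 Å), fixed angles (111.2°/116.2°/121.7°, CA–C–O
  120.8°) and trans peptide bonds (ω = 180°).  Chains are built by the
  standard internal-coordinate (NeRF) construction; the first residue sits
  in a canonical frame, so identical dihedrals give identical coordinates
  on every platform.
- **Ramachandran basins**: helix (−57, −47), PPII (−75, +145), β
  (−120, +130) with 8–10° Gaussian spread, and a broad coil basin
  ((−85, +75), σ = (35°, 70°)).  The default mixture — PPII 0.40, β 0.25,
  helix 0.05, coil 0.30 — emulates the qualitative composition of a
  PPII-rich, β-containing, essentially helix-free disordered peptide.
- **Segment persistence**: basins are drawn per contiguous segment with
  geometric lengths (mean 6 residues), not independently per residue.
  Independent draws would make isolated single-residue "helices" common,
  and the classifier (correctly) refuses to call a secondary structure on
  a single residue; with short persistence the assigned fractions recover
  the mixture weights to within a few percent, which is what real chains'
  local cooperativity produces.  The expected residue fraction per basin
  still equals the mixture weight.
- **Excluded volume**: frames with any nonbonded CA pair (|i−j| ≥ 3)
  closer than 3.0 Å are rejected and resampled; sampling aborts if the
  rejection rate exceeds 99%.
- **Randomness**: one documented generator family
  (`numpy.random.default_rng`), with the seed threaded explicitly through
  every stochastic operation and recorded in the ensemble provenance.

Freely-jointed chains (i.i.d. uniform bond directions, default bond
3.8 Å) provide exact reference statistics: ⟨R_ee²⟩ = (N−1)b²,
⟨R_g²⟩ = b²(N²−1)/6N, and ⟨R_ee²⟩/⟨R_g²⟩ = 6N/(N+1) → 6.

What the generator does **not** emulate: side chains (all analyses are
defined on backbone atoms; distance maps use backbone-atom minima, a
documented fidelity reduction relative to all-atom minimum-distance maps),
force-field energetics, solvent, sequence-dependent basin preferences, and
long-range correlations beyond excluded volume.  Tests that pass on these
ensembles therefore validate the *analysis machinery* — estimator
correctness, closed-form consistency, round-trip recovery — not any claim
about the real peptide's ensemble.

Ensembles round-trip through multi-model PDB (MODEL/ENDMDL, chain A,
1-based residues) via biotite at the format's 3-decimal coordinate
precision; single-frame ensembles are written as plain PDB without MODEL
records, and CA-only files are read back as coarse ensembles that refuse
backbone-only analyses with an explicit capability error.

## Ensemble observables

- **R_g** is computed over all sites with mass weighting by default
  (atomic masses of N/CA/C/O; residue masses for CA-only chains — equal
  for the poly-G FJC, so closed forms apply) and uniform weighting as an
  option; scattering-facing comparisons use uniform weights to match the
  unit-form-factor Debye curve.  **R_ee** is the first-to-last CA
  distance.  Coordinates are Å internally; reports convert R_g/R_ee to nm.
- **Secondary structure** is assigned from (φ, ψ) windows: E first
  (φ ∈ (−180, −90), ψ ∈ (90, 180] ∪ [−180, −170)), then H
  (φ ∈ (−100, −30), ψ ∈ (−80, −5)), then P (φ ∈ (−110, −40),
  ψ ∈ (120, 180)); H/E/P require runs of ≥ 2 consecutive residues
  (singletons become coil); unassigned residues at a chain reversal
  (CA(i)–CA(i+3) < 7 Å) become turns; chain termini are coil.  The
  windows are centered on the canonical basin values and validated by
  generator round trips, not against any external classifier; they are a
  reduced-granularity substitute for hydrogen-bond-energy classifiers
  extended with PPII detection.
- **Clustering** is the greedy neighbor-count algorithm: repeatedly take
  the frame with the most neighbours within the RMSD cutoff as the next
  representative, assign and remove it with its neighbours.  Ties go to
  the lowest frame index (the algorithm's source is silent on ties).
  RMSD uses backbone N/CA/C (CA for coarse chains) after Kabsch
  superposition with a proper rotation; collinear selections are rejected
  as degenerate.
- **Convergence diagnostics**: normalized autocorrelation (ACF(0) ≡ 1,
  defined as zero beyond lag 0 for constant series) and block-averaged
  standard errors over doubling block sizes.
- **PCA** superposes all frames onto the iteratively refined ensemble-mean
  structure before diagonalizing the coordinate covariance.

## Scattering analysis

The Debye sum uses unit point scatterers at CA positions (per-residue
weights optional): a deliberate reduction of continuum/atomic form-factor
calculations, adequate because all in-repo validation is
internal-consistency based (I(0) = N² exactly; the small-q expansion
reproduces the coordinate R_g).  The Guinier fit iterates weighted least
squares of ln I on q², starting from the lowest 15 points (configurable)
and shrinking from the high-q side until q_max·R_g ≤ 0.8 — the limit
appropriate for flexible chains — and R_g is stable within 1%; positive
slopes are an error, not a number.  P(r) is the normalized histogram
(default bin 0.5 Å) of all distinct inter-site distances pooled over
frames; D_max is the upper edge of the last occupied bin.  With the
self-pairs excluded, the second-moment identity R_g² = ∫r²P dr/2 carries
a factor N/(N−1) — about 1.5% at N = 33, within one bin width for every
chain size used here.  No uncertainty model is attached to real-space
estimates beyond bin-width granularity.

## CD spectra

Mean residue molar ellipticity is θ_obs·mrw/(10·l·c) with metadata
(path length cm, concentration g/mL, mrw Da) carried on the spectrum and
the inverse conversion exact.  The mean residue weight defaults to the
per-bond convention Mw/(N−1), the common CD practice, with Mw/N exposed.
Basis decomposition solves min‖Σ w_k B_k − y‖² on the probability simplex
(SLSQP with analytic gradient, ftol 10⁻¹⁴); basis spectra are linearly
interpolated onto the target grid and an explicit fit range restricts the
window, since published fits use different wavelength ranges in different
contexts.  This is a generic constrained decomposition: it does not
reproduce any proprietary basis-set algorithm's percentages.

## Problem sizes and determinism

The validation suite runs at sizes chosen to make statistical bands sharp
while keeping the whole suite interactive: freely-jointed chains at
N = 50 with 5000 frames (3-standard-error bands on both closed forms),
basin round trips at 500 frames (±0.05 on fractions), Guinier/P(r)
self-consistency on 100-frame ensembles with 80-point low-q grids, and
exhaustive clustering/rotation-search oracles on ≤ 8-frame toys.  All
stochastic stages are seeded; reports embed the package version, a
configuration hash and the seeds, and reruns with identical configuration
are bit-identical for deterministic stages.

## Known limitations

- The terminal octanol constants are calibrated as a sum; their split
  between N- and C-terminus is conventional.
- The disorder-propensity table is a transcription of a plotted scale;
  treat third decimals as decorative.
- The dihedral-window classifier has coarser label granularity than
  hydrogen-bond-based classifiers (no 3₁₀/π helices, bridges or bends) and
  its windows are validated only by generator round trips.
- Distance and contact maps are backbone-only in synthetic ensembles; side
  chain contacts (e.g. cation–π pairs) are invisible by construction.
- The generator's ensembles are stand-ins: parameter-recovery tests
  validate estimators, not the conformational ensemble of any real
  peptide.
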