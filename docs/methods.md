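# Methods

`tbmkit` implements the candidate-to-validation workflow for the
TMEM55B-binding motif (TBM), a short linear motif through which cytosolic
adaptor proteins (RILPL1, JIP3, JIP4, WDR81, OCRL, TBC1D9B and likely
others) engage the tandem RING-like domains of the lysosomal membrane
protein TMEM55B.  This note records the models implemented, the defaults
and why, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was open.

## Motif model

The strict consensus is **E-x-(G/A)-x-E-A** (length 6); the relaxed
consensus **(E/Q)-x-(G/A)-x-E** (length 5) admits a glutamine first anchor
and drops the position-6 constraint entirely.  The relaxed form exists
because the validated OCRL motif has Q at position 1 and T at position 6;
dropping position 6 (rather than enumerating "small" residues there) is the
minimal relaxation consistent with that validated outlier.  Anchors are
motif positions 1 and 5; position 5 is always glutamate in both patterns.

Coordinates are 1-based, inclusive, in native protein numbering: a peptide
record carries a `start_residue` offset so that scan output lines up with
mutagenesis labels (E398 of RILPL1, E897 of JIP3, ...).  Overlapping
matches are all reported — no suppression rule exists for this motif and
downstream filters are the right place to deduplicate.  An `X` in a
sequence never satisfies a constrained position and always satisfies a
wildcard, so unknown residues cannot create anchor matches.

The optional PSSM uses natural-log odds against a uniform 1/20 background
(no composition model is asserted for so small a motif set); pseudocounts
are additive per column.  `X` scores zero (background).

## Context filter

A functional TBM must sit in flexible, surface-exposed polypeptide —
binding is dominated by backbone hydrogen bonds, which a rigid or buried
segment cannot donate — and shows some conservation at its anchors.  Three
independent evidence tracks produce a verdict:

* **Structured** (`fail_structured`): more than half of the hit's residues
  are annotated H or E *and* confidently so (pLDDT ≥ `plddt_min` when a
  pLDDT track is present).  pLDDT is the per-residue confidence of a
  predicted model, conventionally stored in the coordinate B-factor
  column; values below ~70 double as a disorder proxy, which is why a
  low-confidence helix annotation does not reject a hit.
* **Buried** (`fail_buried`): mean relative solvent accessibility over the
  hit below `rsasa_min`.
* **Non-conserved** (`fail_nonconserved`): mean conservation of the two
  anchor columns below `cons_min`.  Only anchors are tested because the
  motif tolerates substitutions at its x positions by definition.

Defaults: `plddt_min = 70` (the conventional "confident" cutoff),
`rsasa_min = 0.25` (standard buried/exposed boundary), `cons_min = 0.5`
(mid-scale on the entropy-based score).  The source criteria are
qualitative; these defaults are exposed, not asserted as anyone's
measured values.  Missing tracks yield `no_data` notes, never failures —
absence of evidence does not reject a candidate.

Conservation is `1 − H/log₂20` per alignment column, with `H` the Shannon
entropy of non-gap residues; gaps are excluded rather than treated as a
21st symbol (standard practice), columns where the reference is gapped are
skipped, and columns with no non-reference residues are flagged as having
no data.  The sequence-only flexibility score is the FoldIndex-form
foldability index `I = 2.785⟨H⟩ − |⟨q⟩| − 1.151` over a 21-residue window
(Kyte–Doolittle hydropathy rescaled to [0, 1]; D/E = −1, K/R = +1),
truncated at the termini; negative values flag disorder-prone residues.

## Single-site ITC model

Binding heats follow the 1:1 mass-action model.  For total titrand `M_t`
(receptor, in the cell), total titrant `X_t` and `n` sites, the complex
concentration is the physical quadratic root

    [PL] = ((n·M_t + X_t + K_d) − √((n·M_t + X_t + K_d)² − 4·n·M_t·X_t)) / 2

evaluated in the numerically stable rationalized form (the naive form
cancels catastrophically at high affinity).

**Dilution bookkeeping** uses the perfusion-cell convention of the ITC200
instrument family: the cell volume is fixed, each injection displaces an
equal volume of pre-injection contents (which leaves the sensed volume),
then both total concentrations update.  The heat of injection *i* is the
enthalpy of the change in complex moles inside the cell, normalized per
mole injected, plus a constant dilution baseline `q_dil`.  Summed
un-normalized heats therefore equal ΔH times the total complex ever formed
— which approaches `n·[cell]·V₀·ΔH` only when saturation is reached before
significant displacement, the regime the conservation test uses.

**Concentration convention.** The published methods prose and the
thermodynamics table disagree about what was in the syringe; the table's
arrows (e.g. 0.45 mM → 0.06 mM) put the concentrated peptide in the
syringe, which is the convention implemented and used in all presets.

**Fitting** minimizes squared residuals over (n, log K_d, ΔH, q_dil) with
`scipy.optimize.least_squares`; K_d is log-parameterized for positivity and
reported on the natural scale.  Default initialization: n = 1, ΔH = first
injection heat, K_d = [cell]/10, q_dil = last injection heat.  Standard
errors come from the linearized covariance `s²(JᵀJ)⁻¹` at the optimum
(delta method for K_d); an ill-conditioned JᵀJ (flat isotherm, K_d
unidentifiable) yields infinite errors and a warning rather than an
exception, as does non-convergence.  A Wiseman c-value (`n·[cell]/K_d`)
outside [1, 1000] attaches an interpretability warning.  Simulation-based
calibration at the preset conditions (c ≈ 96, 0.1 kcal/mol heat noise)
shows these 1σ errors are well calibrated: about 68% of replicates fall
within one reported SE of the generating K_d, and the median relative K_d
error is ≈4%.

**Thermodynamics**: ΔG = RT ln K_d (standard state 1 M,
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹) and ΔS = 1000(ΔH − ΔG)/T in cal/(K·mol).
The experiment temperature is not stated with the published table; the
package default is **T = 293.15 K**, which reproduces every printed ΔS
within ±0.8 cal/(K·mol) (worst row: OCRL-PH run (i), 8.32 derived vs 8.6
printed).  At 298.15 K the derived values shift by ~0.2–0.4 cal/(K·mol)
and several rows move outside that band, supporting the 20 °C choice.  The
temperature is a configurable argument everywhere.

## Interface geometry

Contacts use hydrogen-free distance criteria because the relevant crystal
structures (1.55–1.76 Å) are deposited without hydrogens: a hydrogen bond
is any nitrogen→oxygen pair across the two selections within 3.5 Å
(classified backbone/sidechain/mixed by atom names; an optional
backbone-only mode restricts to amide N and carbonyl O/OXT); a salt bridge
is a Glu/Asp carboxylate oxygen within 4.0 Å of an Arg NE/NH1/NH2 or Lys
NZ.  Histidine is excluded from the basic set by default (protonation
unknown at crystallization pH) behind an opt-in flag.  Author residue
numbering is the public coordinate system throughout, so detected contacts
read like the literature labels (E398–R151).  Note a salt bridge always
doubles as a sidechain N→O contact under these definitions; backbone-only
mode exists partly to keep the two reports disjoint.

Superposition is the Kabsch algorithm: centroid shift, SVD of the
covariance, determinant-corrected rotation so the transform is always
proper (mirror inputs superpose with a positive-determinant rotation and a
correspondingly larger RMSD).  Fewer than three point pairs, or collinear
points (second singular value < 1e−8 of the first), raise an error because
the rotation is underdetermined.

PDB reading/writing is delegated to gemmi behind a thin contract: first
model only, altloc blank-or-'A', fixed-column pre-validation so malformed
coordinate fields fail with a line number.

## Enrichment statistics

The IP-enrichment recipe mirrors the Perseus workflow used for
DIA proteomics: quantile normalization, left-censored imputation, Welch
t-tests, permutation FDR.

* **Quantile normalization** maps every column onto the row-wise mean of
  the per-column quantile functions; missing values stay missing and are
  bridged by rank interpolation on a common grid.  The operation is
  idempotent.  Caveat: rows that hold the same rank in every column become
  constant by construction; downstream tests treat resulting zero-variance
  rows as carrying no evidence (t = 0, p = 1) rather than letting 0/0
  propagate.
* **Imputation** draws each missing entry from
  `Normal(m − 1.8·s, (0.3·s)²)` per column, with `m`, `s` the observed
  column mean and SD — the down-shifted-normal model appropriate for
  left-censored (abundance-dependent) missingness.
* **Testing** is a two-sided Welch t-test per protein (unequal variances;
  the pooled-variance variant is available behind a switch).  The log2
  fold change is second group minus first, groups ordered by first
  appearance among the columns.
* **Permutation FDR**: for each observed |t| threshold, the estimated FDR
  is the median over label permutations of the count of permuted |t| at or
  above the threshold, divided by the observed count.  All distinct label
  assignments are enumerated when ≤ 500 exist (e.g. C(8,4) = 70 for a
  4 + 4 design), otherwise 1000 seeded Monte-Carlo draws.  Q-values are
  monotonized with a running **maximum** from the strictest threshold: a
  protein's q is the worst estimated FDR over all thresholds at least as
  strict as its own.  With few distinct permutations the raw plug-in
  estimate is integer-granular and noisy; taking the running minimum from
  the lenient side (the other common convention) lets those noisy dips
  propagate to all stronger hits and measurably inflates the realized FDR
  at small sample sizes, so the conservative direction is used.
  Benjamini–Hochberg adjustment is available as an alternative
  (`method="bh"`).

## Synthetic data

One integer seed drives one `numpy.random.default_rng` stream per
generator, with draws in fixed order, so every artifact regenerates
byte-identically.

* **Proteome**: proteins alternate structured blocks (30–60 residues,
  order-promoting composition biased to I/L/V/F/A/W/Y, annotated H or E,
  pLDDT ~ N(92, 3), rSASA ~ U(0, 0.2)) and linkers (20–40 residues,
  disorder-promoting composition biased to D/E/S/T/P/G, annotated C,
  pLDDT ~ N(45, 8), rSASA ~ U(0.35, 0.9)).  Implants place consensus
  instances (20% as the glutamine-anchored relaxed variant) inside
  linkers with a margin; decoys place the same strings inside structured
  blocks while keeping structured annotations.  Defaults: 60 proteins,
  25 implants, 25 decoys.
* **MSA**: rows mutate the reference independently per column at rate
  1 − conservation (separately for designated anchor columns), with gaps
  at 2% in non-reference rows.
* **Isotherms**: presets carry the published run-(i) syringe/cell
  concentrations and fitted parameters per interactor; the injection
  scheme is 19 × 2 µL into a 200 µL cell with 0.1 kcal/mol Gaussian heat
  noise by default.
* **Toy complex**: a 6-residue extended peptide over a minimal receptor,
  with three backbone N···O bonds drawn uniformly in [2.8, 3.2] Å, one
  Glu–Arg bridge in the same range, and a control lysine placed > 6 Å from
  everything.  The generator self-checks that no unintended backbone
  donor–acceptor or acid–base pair falls within the detection cutoffs plus
  a 0.3 Å margin, so construction truth and detection must agree exactly.
* **Intensities**: protein-level log2 means ~ N(25, 2), within-group noise
  SD 0.5 (a realistic DIA-scale replicate CV), 25 of 500 proteins spiked
  by 2 log2 units in the case group of a 4 + 4 design, and left-censored
  missingness (logistic in the noisy intensity, calibrated to a 10%
  overall rate, floor of two observed values per column).

What the generators deliberately do **not** emulate: homologous sequence
families and real domain architectures; correlated noise, batch effects or
peptide-to-protein roll-up in the intensity matrices; real rotamer
chemistry in the toy coordinates; baseline drift or first-injection
artifacts in the isotherms.  Passing tests therefore demonstrate
correctness of the algorithms under their stated models, not performance
on any real proteome, spectrum or titration.

## Problem sizes and determinism

The shipped tests and the acceptance script run entirely on synthetic or
in-package data at desk scale: 200 simulate-and-refit ITC replicates, 50
spike-in matrices of 500 × 8 for the FDR study, a 4000-row global-null
matrix for type-I error, a 60-protein proteome for the screen.  All
stochastic tests fix seeds; hypothesis profiles are derandomized.

## Known limitations

* The scanner is consensus/PSSM-based; no positional weighting beyond the
  shipped patterns, no homology search, no motif-database integration.
* The context filter consumes annotations; it computes neither secondary
  structure nor solvent accessibility from coordinates.
* The ITC model is strictly 1:1; multi-site or sequential schemes (e.g. a
  dimeric partner binding two receptors) are out of scope, as is raw
  power-trace integration.
* Salt-bridge/H-bond detection is distance-only by design; no angular term
  is applied by default.
* C-terminal location of a motif (as in RILPL1, whose TBM ends the
  protein) is recorded via coordinates but not scored — no data exist on
  whether terminal context modulates binding.
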