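# tbmkit

Discovery and biophysical validation of the **TMEM55B-binding motif
(TBM)** — the short linear motif `E-x-(G/A)-x-E-A` through which cytosolic
adaptor proteins (RILPL1, JIP3, JIP4, WDR81, OCRL, ...) bind the tandem
RING-like domains of the lysosomal membrane protein TMEM55B.  Binding is
dominated by backbone hydrogen bonds and anchored by two glutamates (motif
positions 1 and 5), so a functional TBM must sit in flexible,
surface-exposed polypeptide.

The package is aimed at structural bioinformaticians and biophysicists who
want to screen sequences for TBM candidates and validate them the way the
motif was characterized experimentally:

* **`tbmkit.motif`** — consensus scanning (strict and relaxed patterns) in
  native protein numbering, plus an optional log-odds PSSM.
* **`tbmkit.context`** — the three candidate criteria: anchor-column
  conservation (Shannon-entropy MSA scores), flexibility (FoldIndex-form
  disorder score, pLDDT), and surface exposure (rSASA); motif matches
  inside inaccessible helices/strands are rejected.
* **`tbmkit.itc`** — the single-site (1:1) titration calorimetry model:
  closed-form complex concentration, isotherm simulation with
  perfusion-cell dilution bookkeeping, nonlinear least-squares fitting of
  (N, K_d, ΔH, baseline), and ΔG/ΔS derivation
  (ΔG = RT ln K_d, ΔS = 1000(ΔH − ΔG)/T).
* **`tbmkit.structure`** — PDB parsing (via gemmi), hydrogen-bond and
  salt-bridge detection with hydrogen-free distance criteria, interface
  residues, and Kabsch SVD superposition with reflection correction.
* **`tbmkit.enrichment`** — Perseus-style IP-enrichment statistics:
  quantile normalization, left-censored Gaussian imputation (width 0.3,
  down-shift 1.8), Welch t-tests, permutation-based FDR.
* **`tbmkit.synth`** — seeded generators for every input (proteomes with
  implanted motifs and structured decoys, MSAs, isotherms, toy complexes,
  intensity matrices) with ground-truth tables.

## Worked example

Scan the validated peptides and derive binding entropies:

```python
from tbmkit import STRICT_TBM, scan_motif, derive_thermo
from tbmkit.fasta import ProteinRecord

rec = ProteinRecord(id="RILPL1", sequence="GYTEQGQEALQHL", start_residue=391)
hit = scan_motif(rec, STRICT_TBM)[0]
print(hit.matched_sequence, hit.anchor1_residue, hit.anchor2_residue)
# EQGQEA 394 398

thermo = derive_thermo(kd=590e-9, dh=-12.1, temperature=293.15)
print(round(thermo.dg, 2), round(thermo.ds, 2))
# -8.36 -12.77
```

The scan places the motif at residues 394–399 with anchor glutamates E394
and E398 — the residues whose mutation to lysine abolishes TMEM55B binding
in co-immunoprecipitation assays.  The derived entropy −12.77 cal/(K·mol)
for the measured K_d = 590 nM, ΔH = −12.1 kcal/mol titration matches the
published −12.7 at 20 °C.

Longer narrative scripts live in `examples/` (one per capability:
`scan_tbm_peptides.py`, `itc_thermodynamics.py`, `interface_geometry.py`,
`differential_enrichment.py`, `proteome_screen.py`); each prints the
numbers it computes and a line on what they mean.  A thin CLI exposes the
same stages (`tbmkit scan | context | pssm | itc-sim | itc-fit | thermo |
iface | superpose | diffexp | synth`; see `tbmkit --help`).

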