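"""Published reference data for TBM-bearing TMEM55B interactors.

Two small tables are shipped as package data:

* :data:`TBM_PEPTIDES` — the synthesized TBM peptides used for pulldowns,
  ITC and co-crystallization, with their native residue ranges.
* :func:`itc_thermodynamics` — measured single-site ITC parameters
  (Kd, ΔH, ΔS, N) for TMEM55B binding to each interactor's TBM, one row per
  titration run.  Row labels give syringe → cell concentrations in mM.

These are inputs for worked examples and consistency checks (e.g. verifying
that ΔS follows from Kd and ΔH at the assumed experiment temperature); the
package never treats them as fitted output.
"""

from __future__ import annotations

import pandas as pd

from .fasta import ProteinRecord

#: Validated TBM peptides (untagged sequences, native numbering).
#: ``pattern`` names the consensus that recognizes each peptide: the OCRL
#: TBM has a glutamine first anchor and a non-alanine position 6, so only
#: the relaxed consensus matches it.
TBM_PEPTIDES: dict[str, dict] = {
    "RILPL1": {"sequence": "GYTEQGQEALQHL", "start": 391, "pattern": "strict"},
    "JIP3": {"sequence": "SQSTEEATEATEVPD", "start": 889, "pattern": "strict"},
    "JIP4": {"sequence": "TAEEATEATEG", "start": 887, "pattern": "strict"},
    "WDR81": {"sequence": "DDLEQATEALDS", "start": 657, "pattern": "strict"},
    "OCRL": {"sequence": "VQEAEETLLID", "start": 65, "pattern": "relaxed"},
}


def tbm_peptide_records() -> list[ProteinRecord]:
    """The validated TBM peptides as :class:`ProteinRecord` objects."""
    return [
        ProteinRecord(id=name, sequence=d["sequence"], start_residue=d["start"])
        for name, d in TBM_PEPTIDES.items()
    ]


# protein, run, syringe_mM, cell_mM, kd_nM, kd_err_pct, dh_kcal, dh_err_pct,
# ds_cal, n_sites
_ITC_ROWS = [
    ("RILPL1", "i", 0.45, 0.060, 590, 7, -12.1, 5, -12.7, 0.95),
    ("RILPL1", "ii", 0.30, 0.040, 1000, 22, -13.6, 22, -19.0, 0.87),
    ("RILPL1", "iii", 0.45, 0.045, 680, 23, -11.4, 5, -10.7, 0.87),
    ("OCRL-PH", "i", 0.30, 0.015, 1700, 50, -5.3, 10, 8.6, 0.69),
    ("OCRL-PH", "ii", 0.35, 0.030, 900, 26, -5.9, 3, 7.6, 0.86),
    ("OCRL-PH", "iii", 0.50, 0.050, 460, 100, -6.7, 10, 6.0, 0.68),
    ("WDR81", "i", 0.30, 0.040, 20, 27, -9.0, 1, 4.4, 0.94),
    ("WDR81", "ii", 0.20, 0.020, 33, 20, -9.1, 1, 3.2, 1.1),
    ("WDR81", "iii", 0.20, 0.020, 12, 92, -8.7, 2, 6.4, 1.1),
    ("JIP3", "i", 0.30, 0.030, 127, 47, -8.2, 3, 3.4, 1.2),
    ("JIP3", "ii", 0.30, 0.030, 126, 22, -9.3, 1, -0.2, 0.99),
    ("JIP3", "iii", 0.30, 0.030, 103, 35, -9.3, 2, 0.2, 1.1),
    ("JIP4", "i", 0.40, 0.030, 2900, 11, -8.9, 2, -5.1, 1.0),
    ("JIP4", "ii", 0.40, 0.030, 2200, 13, -9.7, 8, -7.1, 0.91),
    ("JIP4", "iii", 0.40, 0.030, 3100, 37, -8.7, 10, -4.5, 0.78),
]

_ITC_COLUMNS = [
    "protein", "run", "syringe_mM", "cell_mM", "kd_nM", "kd_err_pct",
    "dh_kcal_per_mol", "dh_err_pct", "ds_cal_per_K_mol", "n_sites",
]


def itc_thermodynamics() -> pd.DataFrame:
    """Measured ITC thermodynamics of TMEM55B–TBM interactions (one row per run)."""
    return pd.DataFrame(_ITC_ROWS, columns=_ITC_COLUMNS)
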