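"""Scan the five validated TBM peptides and report their anchor glutamates.

The TBM consensus is E-x-(G/A)-x-E-A; its two glutamate anchors (motif
positions 1 and 5) mediate sequence-specific recognition of TMEM55B.  The
OCRL peptide carries a glutamine first anchor and a threonine at position
6, so it matches only the relaxed consensus (E/Q)-x-(G/A)-x-E.
"""

from tbmkit import RELAXED_TBM, STRICT_TBM, scan_motif
from tbmkit.datasets import tbm_peptide_records

for record in tbm_peptide_records():
    strict = scan_motif(record, STRICT_TBM)
    relaxed = scan_motif(record, RELAXED_TBM)
    hits = strict or relaxed
    label = "strict" if strict else "relaxed only"
    for hit in hits:
        print(
            f"{record.id:8s} {record.sequence:16s} {label:12s} "
            f"motif {hit.matched_sequence} at {hit.start}-{hit.end}, "
            f"anchors {hit.anchor1_residue}/{hit.anchor2_residue}"
        )

print()
print("The anchor-2 residue numbers are the glutamates whose mutation to")
print("lysine abolishes TMEM55B binding (e.g. E398 of RILPL1).")
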