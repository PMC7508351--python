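"""Classify predicted proteins into confidence classes from database evidence.

A protein is judged on completeness (start and stop codon) and significant
hits (E-value < 1e-10, subject coverage > 80%) in three databases: UniMag
(validated Magnoliophyta proteins), Fab (legume proteins) and PTREP
(transposon-associated proteins).
"""

from symisle.confidence import DatabaseHit, ProteinEvidence, classify_batch

strong = dict(evalue=1e-30, subject_coverage=0.95, query_coverage=0.92)

proteins = [
    ProteinEvidence("validated_kinase", True, unimag=DatabaseHit(**strong)),
    ProteinEvidence("legume_specific", True, fab=DatabaseHit(1e-18, 0.9, 0.85)),
    ProteinEvidence("truncated_model", False, fab=DatabaseHit(1e-12, 0.88, 0.5)),
    ProteinEvidence("orphan_orf", True),
    ProteinEvidence("retroelement", True, ptrep=DatabaseHit(1e-40, 0.99, 0.99)),
    ProteinEvidence("fragment_no_hits", False),
]

table, counts = classify_batch(proteins)
print(table.to_string(index=False))
print("\nper-class totals:", {k: v for k, v in counts.items() if v})
# HC = complete with database support, LC = incomplete-but-supported or
# complete-but-orphan, REPEAT = transposon-dominated evidence; an incomplete
# protein with no hits anywhere stays UNCLASSIFIED.
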