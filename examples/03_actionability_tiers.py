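"""Assign clinical-utility tiers to a handful of annotated alterations.

Tier 1 = established utility in the patient's cancer type (somatic S,
resistance R, germline G, diagnosis change D); tier 2 = investigational or
off-label rationale; tier 3 = biological relevance only.
"""

from oncoprofile import Alteration, KnowledgeBase, KnowledgeBaseEntry, assign_tier

kb = KnowledgeBase(
    [
        KnowledgeBaseEntry("KB01", "ERBB2", "amplification", "breast", "FDA_APPROVED_BENEFIT"),
        KnowledgeBaseEntry("KB02", "ERBB2", "amplification", "ANY", "INVESTIGATIONAL_OR_OFF_LABEL"),
        KnowledgeBaseEntry(
            "KB03", "BRCA2", "mutation", "ANY", "BIOLOGICAL_ONLY",
            germline_risk="HIGH_PENETRANT", germline_therapeutic=True,
        ),
        KnowledgeBaseEntry("KB04", "TP53", "ANY", "ANY", "BIOLOGICAL_ONLY"),
    ]
)

cases = [
    ("HER2+ breast cancer", Alteration("P1", "ERBB2", "amplification", "somatic", cancer_type="breast")),
    ("HER2 amp in a CUP", Alteration("P2", "ERBB2", "amplification", "somatic", cancer_type="CUP")),
    ("germline BRCA2 carrier", Alteration("P3", "BRCA2", "mutation", "germline", "pathogenic", "prostate")),
    ("TP53 mutation", Alteration("P4", "TP53", "mutation", "somatic", cancer_type="lung")),
]

for label, alt in cases:
    call = assign_tier(alt, kb)
    star = "*" if call.germline_therapeutic_flag else ""
    print(f"{label:28s} -> tier {call.tier} {call.subcategory}{star}")

print("\nThe same HER2 amplification is tier 1 in its approved indication but")
print("tier 2 (off-label rationale) in a cancer of unknown primary; the BRCA2")
print("germline hit is tier 1 G with the therapeutic (G1*) flag for PARP inhibition.")
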