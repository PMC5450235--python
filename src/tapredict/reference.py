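"""Reference constants from the published TA-protein targeting study.

These are experimental design inputs and reported values from the
mutagenesis work this package models: the ACBD5 TMD-tail peptide series
used for binding assays (C-terminal Asn removed for peptide synthesis;
restore it for charge analysis of the native tail), the FALDH isoform
values, the published tail-charge group means, and AGADIR helical
propensities quoted for the GDAP1 mutant series (reference data only —
this package never computes helicity).
"""

from __future__ import annotations

#: ACBD5 TMD-tail peptides (synthesized form, terminal Asn removed).
ACBD5_TMD_T_PEPTIDES: dict[str, str] = {
    "WT": "SPGVLTFAIIWPFIAQWLVYLYYQRRRRKL",
    "MUT1": "SPGVLTFAIIWPFIAQWLVYLYYQRARAKL",
    "MUT2": "SPGVLTFAIIWPFIAQWLVYLYYQAAAAKL",
}

#: Residue removed from the native C-terminus to facilitate synthesis.
ACBD5_RESTORED_CTERM = "N"

#: Reported net tail charges (pH 7, 1 dp) for the ACBD5 series.
ACBD5_TAIL_CHARGES: dict[str, float] = {"WT": 4.9, "MUT1": 2.9, "MUT2": 0.9}

#: Annotated TMD of the ACBD5 TMD-tail construct (1-based, inclusive,
#: within the Asn-restored peptide): the 23-residue hydrophobic block.
ACBD5_TMD_SPAN = (1, 23)

#: FALDH isoforms: shared highly hydrophobic TMD, divergent tails.
FALDH_TMD_GRAVY = 2.4
FALDH_TAIL_CHARGE = {"FALDH-PO": 9.1, "FALDH-ER": -1.1}

#: Published mean ± s.e.m. net tail charge per localization group.
GROUP_TAIL_CHARGE = {
    "PO": (6.03, 1.03),
    "PO_MITO": (2.5, 0.43),
    "MITO": (1.12, 0.41),
    "ER": (0.21, 0.3),
}

#: AGADIR helical propensity values quoted for GDAP1 tail variants
#: (external algorithm; stored for reference, never computed here).
GDAP1_AGADIR = {"WT": 1.05, "MUT4": 0.73, "MUT5": 0.57, "MUT6": 0.48}
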