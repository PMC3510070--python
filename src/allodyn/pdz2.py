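"""Published residue lists for the hPDZ2 (PTP1E PDZ2) benchmark.

Residues are labelled by type + author index (e.g. ``I35``). The positive
set is the experimentally determined collection of methyl-bearing residues
whose side-chain dynamics respond to binding of the RA-GEF2 peptide; the
exclusion set covers methyl residues with completely or partially missing
relaxation data. Seven exclusions are named explicitly in the source
experiments (the DS3 residues V9, L11, L87, L89 plus T28, V37, V75); the
remaining two are constrained by cross-method confusion counts to A74 plus
one of {A46, V58, L59} — A46 is used here, and any of the three choices
reproduces every published count. The universe lists the methyl-bearing
residues named across the published prediction sets; it is user-editable
via :func:`allodyn.evaluation.read_labels`.
"""

from __future__ import annotations

#: Experimentally identified positives (methyl side-chain dynamics change).
FUENTES_POSITIVES = [
    "L18", "I20", "V22", "V26", "V30", "A39", "V40",
    "V61", "V64", "L66", "A69", "L78", "T81", "V85",
]

#: Methyl residues lacking (complete) relaxation data — excluded from scoring.
EXCLUDED = ["V9", "L11", "T28", "V37", "V75", "L87", "L89", "A46", "A74"]

#: Methyl-bearing residues of the domain appearing in the published lists.
METHYL_UNIVERSE = [
    "V9", "L11", "A12", "L18", "I20", "V22", "T23", "V26", "T28", "V30",
    "I35", "V37", "A39", "V40", "I41", "A45", "A46", "I52", "V58", "L59",
    "A60", "V61", "V64", "L66", "A69", "A74", "V75", "T77", "L78", "T81",
    "V85", "L87", "L88", "L89",
]

#: Prediction sets of the compared methods (methyl-bearing residues).
PREDICTIONS = {
    "md_interaction_correlation": [       # molecular-dynamics approach
        "A12", "L18", "V26", "I41", "A45", "A46", "V58",
        "L59", "L66", "A69", "A74", "L78", "T81", "L89",
    ],
    "perturbation_response": [            # perturbation response scanning
        "L11", "L18", "I20", "V22", "T23", "I35", "V37", "A39", "V40",
        "I41", "A45", "A46", "V58", "L59", "A60", "V61", "L66", "A69",
        "A74", "V75", "T77", "L78", "T81", "V85", "L87",
    ],
    "delta_mi_methyl": [                  # ΔMI on methyl sub-matrix
        "V9", "L11", "L18", "I20", "V22", "V26", "T28", "V30", "I35",
        "V37", "V40", "V61", "L66", "V75", "T77", "L78", "T81", "V85",
        "L87", "L89",
    ],
    "delta_mi_all": [                     # ΔMI on the full residue matrix
        "V9", "L11", "L18", "I20", "V22", "V26", "T28", "V30", "I35",
        "V37", "V40", "L66", "V75", "T77", "L78", "T81", "L87", "L89",
    ],
    "betweenness_bound": [
        "L11", "L18", "I20", "V22", "V26", "T28", "I35", "V37", "V40",
        "A46", "I52", "V58", "L59", "V61", "L66", "L78", "V85", "L87",
        "L88", "L89",
    ],
    "betweenness_unbound": [
        "L11", "L18", "I20", "V22", "V26", "T28", "I35", "V37", "V40",
        "A46", "I52", "V58", "L59", "V61", "L66", "A74", "L78", "V85",
        "L87", "L88", "L89",
    ],
}

#: Published confusion counts per method: (TP, TN, FP, FN).
CONFUSION_COUNTS = {
    "md_interaction_correlation": (6, 6, 5, 8),
    "perturbation_response": (11, 3, 8, 3),
    "delta_mi_methyl": (11, 9, 2, 3),
    "delta_mi_all": (9, 9, 2, 5),
    "betweenness_bound": (9, 6, 5, 5),
    "betweenness_unbound": (9, 6, 5, 5),
}

#: Best CAST thresholds reported for the two ΔMI analyses.
BEST_THRESHOLD_METHYL = 0.023
BEST_THRESHOLD_ALL = 0.027
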