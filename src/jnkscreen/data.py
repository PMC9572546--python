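"""Bundled reference data for worked examples.

``TOP5_CANDIDATES`` is the published consensus-analysis table for the five
top-ranked natural-product candidates from the original JNK1 screen: the
docking binding free energy (kcal/mol, AutoDock Vina) and the two ensemble
confidences per compound, together with the scores reported alongside them.
``KINASE_ASSAY`` holds the published kinase-assay inhibition readouts for
the three purchased candidates at the five highest tested concentrations.

These rows are *inputs* for the consensus and dose–response worked
examples; the ``reported_*`` fields are the published values the package's
own computation is compared against.
"""

from __future__ import annotations

#: Co-crystallized ligand affinity used as the docking-score reference (kcal/mol).
REFERENCE_LIGAND_ENERGY_KCAL = -10.6

#: Consensus-analysis inputs and published scores for the top five candidates.
TOP5_CANDIDATES: list[dict] = [
    {"name": "Lariciresinol", "cas_number": "27003-73-2",
     "docking_energy_kcal": -9.282, "conf_voting": 0.855, "conf_stacking": 0.861,
     "reported_s_dock": 0.873, "reported_s_ml": 0.858, "reported_s_total": 0.866},
    {"name": "Nigracin", "cas_number": "18463-25-7",
     "docking_energy_kcal": -9.229, "conf_voting": 0.829, "conf_stacking": 0.838,
     "reported_s_dock": 0.868, "reported_s_ml": 0.834, "reported_s_total": 0.851},
    {"name": "Tricin", "cas_number": "520-32-1",
     "docking_energy_kcal": -9.007, "conf_voting": 0.830, "conf_stacking": 0.836,
     "reported_s_dock": 0.847, "reported_s_ml": 0.833, "reported_s_total": 0.840},
    {"name": "4'-Demethylepipodophyllotoxin", "cas_number": "6559-91-7",
     "docking_energy_kcal": -8.856, "conf_voting": 0.826, "conf_stacking": 0.859,
     "reported_s_dock": 0.833, "reported_s_ml": 0.842, "reported_s_total": 0.838},
    {"name": "Ophiopogonanone E", "cas_number": "588706-66-5",
     "docking_energy_kcal": -8.802, "conf_voting": 0.844, "conf_stacking": 0.846,
     "reported_s_dock": 0.828, "reported_s_ml": 0.845, "reported_s_total": 0.837},
]

#: Published ranking of the five candidates by total consensus score.
TOP5_RANKING = [c["name"] for c in TOP5_CANDIDATES]

#: Kinase-assay percent inhibition at the five highest concentrations (µM),
#: plus the published IC50 outcome ("censored" = reported as > 50 µM).
KINASE_ASSAY: dict[str, dict] = {
    "Lariciresinol": {
        "concentrations_um": [50.0, 25.0, 12.5, 6.25, 3.125],
        "inhibition_percent": [15.1, 11.6, 9.0, 7.2, 5.6],
        "reported_ic50_um": None, "censored": True},
    "Tricin": {
        "concentrations_um": [50.0, 25.0, 12.5, 6.25, 3.125],
        "inhibition_percent": [75.4, 61.8, 47.2, 34.8, 25.9],
        "reported_ic50_um": 17.68, "censored": False},
    "4'-Demethylepipodophyllotoxin": {
        "concentrations_um": [50.0, 25.0, 12.5, 6.25, 3.125],
        "inhibition_percent": [10.2, 7.9, 5.7, 3.3, 1.9],
        "reported_ic50_um": None, "censored": True},
}
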