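"""Published group-mean outcomes of the rat varus-loading study.

These printed values are *inputs* to the package: the reporting stage
reproduces the published delta arithmetic from them, and the calibration
stage scales the nominal synthetic geometry so that the specimen-specific
contact model reproduces the published medial contact area at 100 % varus.

Units: peak pressures in MPa, contact areas and area changes in mm^2.
"""

from __future__ import annotations

import pandas as pd

# Peak contact pressure group means per (varus level %, model type, compartment).
PRINTED_PEAK_PRESSURE = pd.DataFrame(
    [
        (0, "sample_fea", 1.77, 1.66),
        (0, "ssam_fea", 1.80, 1.64),
        (0, "experiment_sim", 1.77, 1.77),
        (50, "sample_fea", 2.06, 1.45),
        (50, "ssam_fea", 2.15, 1.42),
        (50, "experiment_sim", 2.05, 1.45),
        (100, "sample_fea", 2.30, 1.25),
        (100, "ssam_fea", 2.35, 1.21),
        (100, "experiment_sim", 2.40, 1.10),
    ],
    columns=["varus_level", "model_type", "medial", "lateral"],
)

# Contact-area changes relative to the neutral (0 %) condition.
PRINTED_AREA_INCREASE_MEDIAL = pd.DataFrame(
    [
        (50, "sample_fea", 0.63),
        (50, "ssam_fea", 0.92),
        (50, "experiment_sim", 0.66),
        (100, "sample_fea", 1.07),
        (100, "ssam_fea", 1.28),
        (100, "experiment_sim", 1.11),
    ],
    columns=["varus_level", "model_type", "delta_mm2"],
)

PRINTED_AREA_DECREASE_LATERAL = pd.DataFrame(
    [
        (100, "sample_fea", 1.37),
        (100, "ssam_fea", 1.17),
        (100, "experiment_sim", 1.42),
    ],
    columns=["varus_level", "model_type", "delta_mm2"],
)

# Absolute contact areas quoted at 100 % varus (medial, lateral), mm^2.
PRINTED_AREA_100 = {
    "sample_fea": (8.3, 5.3),
    "ssam_fea": (8.5, 5.1),
}

# Headline aggregates quoted in the study summary.  The pressure aggregates
# are consistent with the two FEA model types only (the experimental medial
# increase, 2.40 - 1.77 = 0.63 MPa, exceeds the quoted 0.55 MPa maximum);
# the area aggregates span all three model types.  The quoted maximum
# lateral area decrease (1.76 mm^2) is NOT reproducible from the printed
# per-model decreases (max 1.42 mm^2); the reporting stage computes both and
# flags the discrepancy.
PRINTED_MAX_MEDIAL_PRESSURE_INCREASE = 0.55
PRINTED_MAX_LATERAL_PRESSURE_DECREASE = 0.43
PRINTED_MAX_MEDIAL_AREA_INCREASE = 1.28
PRINTED_MAX_LATERAL_AREA_DECREASE_QUOTED = 1.76

FEA_MODEL_TYPES = ("sample_fea", "ssam_fea")
ALL_MODEL_TYPES = ("sample_fea", "ssam_fea", "experiment_sim")


def printed_pressure_records() -> pd.DataFrame:
    """Printed Table-of-means pressures as long-format knee-level records.

    Each group mean becomes a single record (knee_id ``group_mean``) so the
    reporting stage can reproduce the printed table verbatim.
    """
    rows = []
    for _, r in PRINTED_PEAK_PRESSURE.iterrows():
        for side in ("medial", "lateral"):
            rows.append(
                {
                    "knee_id": "group_mean",
                    "model_type": r["model_type"],
                    "varus_level": int(r["varus_level"]),
                    "compartment": side,
                    "peak_pressure": float(r[side]),
                    "contact_area": float("nan"),
                }
            )
    return pd.DataFrame(rows)
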