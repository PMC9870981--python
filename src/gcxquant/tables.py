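"""Published group-level summary statistics used as reference inputs.

These are the printed endpoint summaries — mean, sample SD, and group size —
of the six-arm mouse hemorrhage/resuscitation study this package models:
glycocalyx index (GCXI, μm) for ~40-μm and ~60-μm arteries, plasma
syndecan-1 (ng/mL), and the blood-gas panel (pH, pCO2/pO2 mmHg, base excess
mEq/L, lactate mmol/L, hemoglobin g/dL). Group C is the untreated control;
the other arms differ in the type and order of the two resuscitation fluids
(NS = normal saline, ALB = 5% albumin, HES = hydroxyethyl starch 130/0.4).

They serve two roles: defaults for the cohort simulator, and direct inputs
to the summary-statistics ANOVA/Dunnett layer.
"""

from __future__ import annotations

GROUPS = ("C", "NS-NS", "NS-ALB", "ALB-NS", "NS-HES", "HES-NS")

CONTROL_GROUP = "C"

#: endpoint -> group -> (mean, sample SD, n)
ENDPOINT_SUMMARIES: dict[str, dict[str, tuple[float, float, int]]] = {
    "gcxi_40um": {
        "C": (5.69, 1.99, 7),
        "NS-NS": (3.69, 0.91, 7),
        "NS-ALB": (3.31, 1.04, 8),
        "ALB-NS": (3.40, 1.15, 8),
        "NS-HES": (2.96, 0.53, 8),
        "HES-NS": (3.28, 0.66, 6),
    },
    "gcxi_60um": {
        "C": (4.93, 1.45, 10),
        "NS-NS": (3.76, 0.80, 9),
        "NS-ALB": (3.77, 0.80, 8),
        "ALB-NS": (4.04, 1.27, 7),
        "NS-HES": (3.28, 1.07, 10),
        "HES-NS": (4.82, 0.88, 8),
    },
    "syndecan1": {
        "C": (2.54, 0.69, 9),
        "NS-NS": (7.70, 5.71, 7),
        "NS-ALB": (3.00, 0.92, 5),
        "ALB-NS": (5.99, 3.04, 6),
        "NS-HES": (2.11, 0.44, 6),
        "HES-NS": (2.76, 1.33, 8),
    },
    "pH": {
        "C": (7.172, 0.058, 10),
        "NS-NS": (6.980, 0.070, 8),
        "NS-ALB": (7.068, 0.052, 8),
        "ALB-NS": (7.037, 0.069, 7),
        "NS-HES": (7.088, 0.051, 8),
        "HES-NS": (7.077, 0.055, 8),
    },
    "pCO2": {
        "C": (83.0, 11.73, 10),
        "NS-NS": (85.3, 9.85, 8),
        "NS-ALB": (82.7, 7.19, 8),
        "ALB-NS": (86.0, 12.10, 7),
        "NS-HES": (85.0, 9.96, 8),
        "HES-NS": (87.9, 8.41, 8),
    },
    "pO2": {
        "C": (46.1, 18.23, 10),
        "NS-NS": (42.3, 9.04, 8),
        "NS-ALB": (37.6, 5.78, 8),
        "ALB-NS": (35.7, 7.70, 7),
        "NS-HES": (43.0, 12.47, 8),
        "HES-NS": (47.8, 11.45, 8),
    },
    "BE": {
        "C": (1.8, 1.48, 10),
        "NS-NS": (-11.5, 4.21, 8),
        "NS-ALB": (-6.1, 3.44, 8),
        "ALB-NS": (-7.4, 4.04, 7),
        "NS-HES": (-4.4, 1.77, 8),
        "HES-NS": (-4.5, 2.00, 8),
    },
    "lactate": {
        "C": (0.8, 0.51, 10),
        "NS-NS": (4.2, 0.99, 8),
        "NS-ALB": (2.9, 1.34, 8),
        "ALB-NS": (3.9, 1.37, 6),
        "NS-HES": (1.8, 1.71, 8),
        "HES-NS": (1.2, 0.56, 8),
    },
    "Hb": {
        "C": (13.7, 1.06, 10),
        "NS-NS": (6.5, 1.36, 8),
        "NS-ALB": (4.3, 1.45, 8),
        "ALB-NS": (7.3, 0.98, 6),
        "NS-HES": (5.6, 1.18, 8),
        "HES-NS": (6.7, 0.56, 8),
    },
}

ENDPOINT_UNITS = {
    "gcxi_40um": "um",
    "gcxi_60um": "um",
    "syndecan1": "ng/mL",
    "pH": "",
    "pCO2": "mmHg",
    "pO2": "mmHg",
    "BE": "mEq/L",
    "lactate": "mmol/L",
    "Hb": "g/dL",
}

#: published per-comparison significance marks vs control
#: ("**": p <= 0.01, "*": p <= 0.05, "": not significant)
PUBLISHED_FLAGS: dict[str, dict[str, str]] = {
    "gcxi_40um": {"NS-NS": "**", "NS-ALB": "**", "ALB-NS": "**", "NS-HES": "**", "HES-NS": "**"},
    "gcxi_60um": {"NS-NS": "*", "NS-ALB": "*", "ALB-NS": "", "NS-HES": "**", "HES-NS": ""},
    "syndecan1": {"NS-NS": "**", "NS-ALB": "", "ALB-NS": "", "NS-HES": "", "HES-NS": ""},
    "pH": {"NS-NS": "**", "NS-ALB": "**", "ALB-NS": "**", "NS-HES": "*", "HES-NS": "**"},
    "pCO2": {"NS-NS": "", "NS-ALB": "", "ALB-NS": "", "NS-HES": "", "HES-NS": ""},
    "pO2": {"NS-NS": "", "NS-ALB": "", "ALB-NS": "", "NS-HES": "", "HES-NS": ""},
    "BE": {"NS-NS": "**", "NS-ALB": "**", "ALB-NS": "**", "NS-HES": "**", "HES-NS": "**"},
    "lactate": {"NS-NS": "**", "NS-ALB": "**", "ALB-NS": "**", "NS-HES": "", "HES-NS": ""},
    "Hb": {"NS-NS": "**", "NS-ALB": "**", "ALB-NS": "**", "NS-HES": "**", "HES-NS": "**"},
}

#: loose survival defaults for the simulator. The published seven-day
#: mortality wording is internally inconsistent, so only the three explicit
#: percentages are used (control capped below 1 to keep the hazard finite);
#: unstated groups default to 0.9. These are free parameters, not findings.
REFERENCE_WEEKLY_DEATH_PROB: dict[str, float] = {
    "C": 0.99,
    "NS-NS": 0.20,
    "NS-ALB": 0.90,
    "ALB-NS": 0.90,
    "NS-HES": 0.60,
    "HES-NS": 0.90,
}


def reference_cohort() -> dict[str, dict[str, tuple[float, float, int]]]:
    """Group -> endpoint -> (mean, sd, n), reshaped from ENDPOINT_SUMMARIES."""
    out: dict[str, dict[str, tuple[float, float, int]]] = {g: {} for g in GROUPS}
    for endpoint, per_group in ENDPOINT_SUMMARIES.items():
        for group, stats in per_group.items():
            out[group][endpoint] = stats
    return out
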