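"""Published reference numbers packaged as annotated fixtures.

These values are inputs and cross-checks, never calibration ground truth:
the study's reported stage-endpoint figures depend on unpublished model
equations and integration settings, so they cannot be reproduced here.
"""

from __future__ import annotations

__all__ = [
    "TENNESSEE_ESRD_2021",
    "esrd_treated_total",
    "STAGE_BIAS_CHANGES",
    "REPORTED_ENDPOINTS_2022",
]

#: American Kidney Fund counts for Tennessee, 2021.
TENNESSEE_ESRD_2021 = {
    "untreated": 15_662,  # ESRD without dialysis or transplant
    "dialysis": 11_495,
    "transplant": 4_167,
}


def esrd_treated_total() -> int:
    """Dialysis plus transplant counts — the worked-example arithmetic."""
    return TENNESSEE_ESRD_2021["dialysis"] + TENNESSEE_ESRD_2021["transplant"]


#: Base → altered bias level per stage. Stage 1 is printed both as
#: 0.8→1.3 (narrative) and 0.8→1.33 (summary table); both are carried.
STAGE_BIAS_CHANGES = {
    "1": {"base": 0.8, "altered": 1.3, "altered_table": 1.33},
    "2": {"base": 0.08, "altered": 1.55},
    "3": {"base": 0.16, "altered": 1.32},
    "4": {"base": 0.073, "altered": 1.151},
    "5": {"base": 0.152, "altered": 0.275},
    "esrd": {"base": 0.33, "altered": 0.72},
}

#: Reported 2022 progression/incidence endpoints under the altered biases.
#: The stage-3 and stage-4 entries are typographically ambiguous in the
#: source ("26, 5000" and "25, 1000"); they are kept verbatim as strings
#: and never parsed.
REPORTED_ENDPOINTS_2022 = {
    "1": 1_240_000.0,  # progression to stage 2 ("1.24 M")
    "2": 310_000.0,  # progression to stage 3
    "3": "26, 5000",  # progression to stage 4 (ambiguous)
    "4": "25, 1000",  # progression to stage 5 (ambiguous)
    "5": 1_000.0,  # progression to ESRD
    "esrd": 650.0,  # death incidence
}
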