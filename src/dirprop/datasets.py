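"""Bundled reference data.

Gross-tumour-volume measurements (cm^3) for a 17-patient longitudinal lung
cohort: volumes delineated on the pre-treatment scan and on a repeat scan
taken during the second week of treatment.  Used by the volume-change
statistics and the acceptance report.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LUNG_COHORT_PATIENTS",
    "LUNG_COHORT_GTV_PRE_CM3",
    "LUNG_COHORT_GTV_MID_CM3",
]

LUNG_COHORT_PATIENTS = tuple(range(1, 18))

LUNG_COHORT_GTV_PRE_CM3 = (
    15.8, 150.5, 96.6, 39.4, 32.9, 7.9, 55.8, 59.6, 158.6,
    18.7, 115.7, 17.9, 3.1, 182.1, 46.3, 10.9, 66.6,
)

LUNG_COHORT_GTV_MID_CM3 = (
    14.5, 106.2, 111.4, 39.0, 26.4, 7.8, 47.0, 65.7, 120.9,
    17.2, 104.3, 17.3, 2.9, 148.8, 56.9, 10.3, 65.5,
)
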