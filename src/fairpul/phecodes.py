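"""ICD-10-CM → phecode mapping resources.

Phecodes are curated groupings of ICD codes into clinically meaningful
phenotypes. Real analyses use the published ICD-10-CM phecode map; this
module ships a small synthetic map (one row per ICD code, maximum-granularity
match) covering the codes emitted by :mod:`fairpul.synthetic`, and helpers
shared by the preparation pipeline.

The disease of interest is Alzheimer's disease: diagnosis ICD codes are the
G30 family, which map to phecode 290.11. The dementia exclusion range
290–292.99 covers related neurocognitive phenotypes (dementias, mild
cognitive impairment, memory loss) that disqualify a patient from serving as
a reliable negative.
"""

from __future__ import annotations

import pandas as pd

#: Phecode assigned to the disease diagnosis codes (G30*). Never a feature.
DISEASE_PHECODE = "290.11"

#: Inclusive phecode range excluded when selecting reliable negatives.
EXCLUSION_RANGE = (290.0, 292.99)

_DEFAULT_MAP_ROWS = [
    # disease codes
    ("G30", "290.11", "Alzheimer's disease"),
    ("G30.0", "290.11", "Alzheimer's disease with early onset"),
    ("G30.1", "290.11", "Alzheimer's disease with late onset"),
    ("G30.8", "290.11", "Other Alzheimer's disease"),
    ("G30.9", "290.11", "Alzheimer's disease, unspecified"),
    # related neurocognitive codes (dementia exclusion range 290-292.99)
    ("F01.50", "290.16", "Vascular dementia without behavioral disturbance"),
    ("F01.51", "290.16", "Vascular dementia with behavioral disturbance"),
    ("F02.81", "290.1", "Dementia in other diseases with behavioral disturbance"),
    ("F03", "290.1", "Unspecified dementia"),
    ("F03.90", "290.1", "Unspecified dementia without behavioral disturbance"),
    ("F03.91", "290.1", "Unspecified dementia with behavioral disturbance"),
    ("G31.84", "292.2", "Mild cognitive impairment"),
    ("G31.85", "292.6", "Other cerebral degeneration"),
    ("R41.3", "292.3", "Memory loss"),
    # neuropsychiatric / functional codes outside the exclusion range
    ("F32.9", "296.22", "Major depressive disorder, single episode"),
    ("G47.00", "327", "Insomnia, unspecified"),
    ("R26.81", "781", "Unsteadiness on feet"),
    ("W19", "970", "Unspecified fall"),
    # vascular / metabolic risk factors
    ("I10", "401.1", "Essential hypertension"),
    ("I15.9", "401", "Secondary hypertension, unspecified"),
    ("E78.5", "272.1", "Hyperlipidemia, unspecified"),
    ("E11.9", "250.2", "Type 2 diabetes mellitus without complications"),
    ("E11.40", "250.24", "Type 2 diabetes with neurological complications"),
    ("E11.21", "250.22", "Type 2 diabetes with renal complications"),
    # background comorbidity noise
    ("M54.5", "760", "Low back pain"),
    ("K21.9", "530.11", "Gastro-esophageal reflux disease"),
    ("N39.0", "591", "Urinary tract infection"),
    ("J06.9", "465", "Acute upper respiratory infection"),
    ("H52.4", "367", "Presbyopia"),
]


def default_phecode_map() -> pd.DataFrame:
    """Synthetic one-to-one ICD-10-CM → phecode map as a DataFrame.

    Columns: ``icd10cm``, ``phecode``, ``description``. Each ICD maps to at
    most one phecode; parent codes (e.g. ``G30``, ``F03``) are present so the
    truncation-based maximum-granularity match is exercised by descendants
    absent from the map.
    """
    return pd.DataFrame(_DEFAULT_MAP_ROWS, columns=["icd10cm", "phecode", "description"])


def in_exclusion_range(phecode: str) -> bool:
    """Whether a phecode falls in the dementia exclusion range."""
    try:
        value = float(phecode)
    except (TypeError, ValueError):
        return False
    lo, hi = EXCLUSION_RANGE
    return lo <= value <= hi
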