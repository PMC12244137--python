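"""Shared cohort-table conventions.

A cohort table is a pandas DataFrame with one row per subject. The four
outcome columns hold regional serotonin-4-receptor binding potentials
(BP_ND, unitless, cerebellum reference); hormones are plasma
concentrations in nM; dose is injected tracer mass per kg bodyweight
(μg/kg). Estradiol values at or below the assay's lower limit of
quantification (LOQ) are left-censored: the stored value is the LOQ and
``estradiol_censored`` is 1.
"""

from __future__ import annotations

REGIONS = ("neostriatum", "hippocampus", "amygdala", "prefrontal")
BP_COLUMNS = tuple(f"bp_{r}" for r in REGIONS)

GROUP_HC = "HC"
GROUP_MDD = "MDD"

SCANNER_HRRT = "HRRT"
SCANNER_GE = "GE"

#: covariates adjusted for in every measurement equation
COVARIATES = ("age", "dose", "scanner")

HAMD_COLUMNS = tuple(f"hamd_{i}" for i in range(1, 18))

#: Bech core-depression subscale (HAMD6): depressed mood, guilt, work and
#: interests, retardation, psychic anxiety, general somatic symptoms.
HAMD6_ITEMS = (1, 2, 7, 8, 10, 13)

#: vegetative items: initial / middle / delayed insomnia,
#: gastrointestinal somatic symptoms, loss of weight.
VEGETATIVE_ITEMS = (4, 5, 6, 12, 16)

#: maximum score per HAMD-17 item (items 1-based)
HAMD_ITEM_MAX = {
    1: 4, 2: 4, 3: 4, 4: 2, 5: 2, 6: 2, 7: 4, 8: 4, 9: 4,
    10: 4, 11: 4, 12: 2, 13: 2, 14: 2, 15: 2, 16: 2, 17: 2,
}

MANDATORY_COLUMNS = (
    ("id", "group", "age", "dose", "scanner")
    + BP_COLUMNS
    + ("testosterone", "estradiol", "estradiol_censored")
)
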