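"""State space of the CKD stock-and-flow model.

The model tracks the Chilean population aged 40+ with reduced kidney
function across six mutually exclusive states: CKD stages 3a, 3b, 4 and 5
(KDIGO eGFR bands), end-stage kidney disease on renal replacement
treatment (ESKD), and death (absorbing).  Within each CKD stage the stock
is subdivided into three progression classes tied to comorbidity:

* ``slow``   - no diabetes (eGFR decline 1.4 ml/min/1.73m2 per year)
* ``medium`` - diabetes without increased albuminuria (3 ml/min/1.73m2/yr)
* ``fast``   - diabetes with increased albuminuria (5 ml/min/1.73m2/yr)

Because the class assignment is a function of diabetes status, the
diabetic sub-stock of a stage is exactly ``medium + fast``.
"""

STAGES = ("3a", "3b", "4", "5")
CLASSES = ("slow", "medium", "fast")
ESKD = "ESKD"
DEAD = "Dead"
STATES = STAGES + (ESKD, DEAD)

# KDIGO eGFR bands (ml/min/1.73m2), half-open [lower, upper).  Stage 3a's
# upper bound is 60 (the eGFR<60 cut), even though a discrete histogram of
# CKD eGFR values tops out at 59.
STAGE_BOUNDS = {
    "3a": (45.0, 60.0),
    "3b": (30.0, 45.0),
    "4": (15.0, 30.0),
    "5": (0.0, 15.0),
}

# Five-year age bands of the 40+ population for which all-cause mortality
# rates are configured (per 1000 per year).
AGE_BANDS = (
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74",
    "75-79", "80-84", "85-89", "90-94", "95-99", "100+",
)
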