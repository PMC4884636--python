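"""Published inverse-Gompertz parameter estimates for the SEER lymph-node-
positive prostate cancer cohort (radical prostatectomy, diagnoses 1988+).

These are the reference fits for the three %LN+ strata of the whole LN+
cohort and of the subcohort of white, grade III patients without
radiotherapy. They serve as fixtures: evaluating the inflection point
ln(b2)/b3 on them reproduces the published stratum inflection points, and
the model value at 10 years for the >=40% stratum reproduces the published
71% 10-year relative survival.
"""

#: (b1, b2, b3) with b3 in 1/years, keyed by cohort then %LN+ stratum.
PUBLISHED_FITS: dict[str, dict[str, tuple[float, float, float]]] = {
    "whole": {
        "<10%": (1.985, 9.016, 0.082),
        "10-40%": (0.337, 6.15, 0.189),
        ">=40%": (0.469, 4.51, 0.222),
    },
    "white_gIII_noRT": {
        "<10%": (0.513, 4.64, 0.096),
        "10-40%": (0.579, 5.22, 0.151),
        ">=40%": (0.616, 4.0, 0.203),
    },
}
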