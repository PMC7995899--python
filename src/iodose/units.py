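"""Unit conventions and physical constants.

Internal time unit is the day (transfer coefficients are day^-1, matching
biokinetic convention); every user-facing time or time-integrated activity
coefficient is in hours (TIACs print as MBq·h/MBq = h).  All conversions go
through this module so the convention lives in exactly one place.
"""

import numpy as np

LN2 = float(np.log(2.0))

HOURS_PER_DAY = 24.0
SECONDS_PER_HOUR = 3600.0

#: CODATA: 1 MeV in joule.
MEV_TO_J = 1.602176634e-13


def hours_to_days(t_hours):
    return np.asarray(t_hours, dtype=float) / HOURS_PER_DAY


def days_to_hours(t_days):
    return np.asarray(t_days, dtype=float) * HOURS_PER_DAY
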