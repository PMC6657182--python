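"""Lung-cancer-screening eligibility verdicts for merged profiles.

Eligibility = current smoker, or former smoker who quit within 15 years,
with >= 30 pack years. Missing status or missing pack years yield a
missing-data verdict rather than a guess.
"""

import datetime as dt

from smokereg import SmokingProfile, SmokingStatus, assess_eligibility

ref = dt.date(2016, 4, 1)
cases = [
    SmokingProfile("a", SmokingStatus.CURRENT, pack_years_nlp=35),
    SmokingProfile("b", SmokingStatus.FORMER, pack_years_nlp=40),  # no quit date
    SmokingProfile("c", SmokingStatus.FORMER, pack_years_nlp=50,
                   cessation_date=dt.date(1996, 1, 1)),
    SmokingProfile("d", SmokingStatus.CURRENT),  # no pack years
    SmokingProfile("e", SmokingStatus.NEVER),
    SmokingProfile("f", SmokingStatus.UNKNOWN),
]

for p in cases:
    r = assess_eligibility(p, reference_date=ref)
    print(p.patient_id, r.verdict.value, f"({r.reason.value})")

# a: eligible; b: eligible (former smokers without a recorded quit date are
# assumed recently quit); c: not eligible (quit 20 years before reference);
# d/f: missing data; e: not eligible (never smoker).
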