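"""Extract smoking behaviors from a handful of clinical notes.

Trains the status classifier on synthetic phrasings, then runs all three
extractors (status, pack years, cessation date) on small hand-written notes.
"""

import datetime as dt

from smokereg import ClinicalNote, extract_profiles, make_training_corpus, train

model = train(make_training_corpus(80, seed=1), seed=1)

notes = [
    ClinicalNote("n1", "p1", dt.date(2016, 4, 1),
                 "Patient is a current smoker. Smokes 2 packs per day for 20 years."),
    ClinicalNote("n2", "p2", dt.date(2016, 4, 1),
                 "Former smoker, quit smoking in 2005. 30 pack year history of tobacco use."),
    ClinicalNote("n3", "p3", dt.date(2016, 4, 1),
                 "Blood pressure stable. Continue lisinopril."),
]

for profile in extract_profiles(notes, model):
    print(profile.patient_id, profile.status_nlp.value,
          "pack_years:", profile.pack_years_nlp,
          "quit:", profile.cessation_date)

# p1: current with 40 pack years (2 ppd x 20 yr product);
# p2: former, 30 stated pack years, quit 2005-01-01 (year resolution);
# p3: unknown — no hotspot token, so no smoking information to classify.
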