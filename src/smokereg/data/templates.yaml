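# Phrasing templates for the synthetic clinical-note generator.
# Three sets: "unambiguous" phrasings carry one clear class cue each and
# round-trip exactly through the extractors; "varied" adds hedged clinical
# shorthand; "adversarial" mixes in trap-prone wording. Placeholders:
# {freq} frequency phrase, {years} duration, {py} pack-year total,
# {year} quit year, {n} years-ago count, {verb} smokes/smoked.

status_sentences:
  unambiguous:
    current:
      - "Patient is a current smoker."
      - "Currently smoking every day."
      - "Active smoker, current tobacco use."
    former:
      - "Patient is a former smoker."
      - "Former tobacco user."
      - "Ex smoker, tobacco free at this time."
    never:
      - "Patient has never smoked."
      - "Never smoker."
      - "Denies any tobacco use, lifelong never smoker."
    smoker_temporality_unknown:
      - "Smoker, temporality not documented."
      - "Positive smoking history, details unclear."
      - "Tobacco use positive."
  varied:
    current:
      - "Tobacco: current."
      - "Still smoking despite counseling."
      - "Ongoing cigarette use reported."
    former:
      - "Tobacco: former."
      - "Remote smoking history, none recently."
      - "Prior cigarette use, abstinent at present."
    never:
      - "Tobacco: never."
      - "No history of smoking whatsoever."
      - "Nonsmoker for life, denies tobacco."
    smoker_temporality_unknown:
      - "Tobacco use: yes."
      - "Smoking noted in chart, timing unclear."
      - "Positive for cigarette use, unspecified."
  adversarial:
    current:
      - "Patient is a current smoker."
      - "Still smoking; advised that if you currently smoke you should quit."
    former:
      - "Patient is a former smoker."
      - "Former smoker; counseled to stop smoking permanently."
    never:
      - "Patient has never smoked."
      - "Never smoker; reviewed handout stating if you currently smoke call the quitline."
    smoker_temporality_unknown:
      - "Smoker, temporality not documented."
      - "Tobacco use positive per intake form."

packyear_sentences:
  product:
    - "{verb} {freq} for {years} years."
    - "Smoking history: {freq} for {years} years."
    - "Tobacco use of {freq} over {years} years."
  stated:
    - "Has a {py} pack year smoking history."
    - "{py} pack year history of tobacco use."
    - "Cigarette use totaling {py} pack years."

quit_sentences:
  absolute:
    - "Quit smoking in {year}."
    - "Stopped smoking in {year}."
    - "Patient quit all tobacco in {year}."
  relative:
    - "Quit smoking {n} years ago."
    - "Stopped all tobacco use {n} years ago."

no_info_sentences:
  - "Blood pressure stable on current regimen."
  - "Continue lisinopril 10 mg daily."
  - "Follow up in 6 months for routine labs."
  - "Denies chest pain or shortness of breath."
  - "A1c improved since last visit."
  - "Knee pain managed conservatively with PT."
  - "Screening colonoscopy discussed and scheduled."
  - "Influenza vaccine administered today."

distractors:
  - "If you currently smoke, please ask about cessation resources."
  - "Stop aspirin 7 days before the procedure."
  - "Metoprolol 25 mg qd."
  - "Packed red blood cells transfused without complication."
  - "Patients who smoke should receive an annual flu shot."
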