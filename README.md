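# smokereg

Tools for building and validating a **smokers' registry** from electronic
health record (EHR) sources. The package is aimed at clinical-informatics
teams who need to turn unstructured and semi-structured smoking
documentation into a per-patient record usable for cessation outreach and
lung-cancer-screening identification — and to quantify how much they can
trust it.

## What it does

1. **Extraction from free-text notes** (rule-based NLP):
   - *Smoking status* — five classes (current / former / smoker-temporality-
     unknown / never / unknown). Token windows of ±5 words around "hotspot"
     roots (`smok`, `cig`, `tobac`, `nicoti`) are concatenated per note and
     classified by a multi-class linear SVM; a note with no hotspot is
     *unknown* by rule.
   - *Pack-year history* — sentences carrying a pack-year stem (`cig`,
     `smok`, `pk`, `ppd`, `pack`, `pak`, `pkyr`) are parsed for one or two
     numbers (numerals or words). Two numbers give frequency × duration
     (cigarette frequencies converted at 20 cigarettes/pack); one number is
     routed by its unit cue to a stated total, a bare frequency, or a bare
     duration. A heuristic filter drops stated totals below 5 pack years,
     which usually encode partial histories.
   - *Cessation date* — quit-cue sentences (`quit`, `qd`, `stop`) gated on a
     smoking root, with absolute and relative ("quit 10 years ago") dates
     normalized to ISO form at day/month/year resolution.
2. **Registry merging** — discordant statuses resolve to the worst label
   (current > former > smoker-temporality-unknown > never > unknown);
   discordant pack years to the highest estimate.
3. **Screening eligibility** — the guideline phenotype: current smoker, or
   former smoker who quit within 15 years, with ≥ 30 pack years; explicit
   missing-data verdicts otherwise.
4. **Agreement statistics** — concordance, Cohen's kappa with linear or
   quadratic (Fleiss–Cohen) weights

   κ_w = (Σ w_ij p_ij − Σ w_ij r_i c_j) / (1 − Σ w_ij r_i c_j),
   w_ij = 1 − (|i−j|/(k−1))^q,

   large-sample confidence intervals, table collapsing, PPV/NPV/sensitivity/
   specificity, and pack-year correlation.
5. **Synthetic corpora** — a seeded generator emulating all three record
   sources (notes, semi-structured fields, questionnaire) with gold labels,
   since real registry data cannot be shared.

## Worked example

```python
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
for p in extract_profiles(notes, model):
    print(p.patient_id, p.status_nlp.value, p.pack_years_nlp, p.cessation_date)
```

prints

```
p1 current 40.0 None
p2 former 30.0 2005-01-01
p3 unknown None None
```

— p1's 40 pack years is the 2 ppd × 20 yr product, p2's quit year is
normalized to January 1 at year resolution, and p3 is *unknown* because the
note contains no smoking-related token at all.

The `examples/` directory holds one short script per capability (extraction,
agreement statistics, simulation + validation, eligibility), and the
`smokereg` command exposes the same workflow from the shell:

```bash
smokereg run --out run1 --seed 11 --n-patients 1504
```

writes the simulated inputs, trained model, merged registry, eligibility
verdicts, validation statistics, and a JSON run report under `run1/`.

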