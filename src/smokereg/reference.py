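"""Published validation cross-tabulations and the analyses run on them.

The package ships the cross-tabulations from an external-questionnaire
validation study of an EHR smokers' registry (1,504 patients): the 3×5
status table (questionnaire current/former/never against the merged-EHR
five-class label), the 3×3 screening-eligibility table, and the 74-record
comparison of semi-structured "current" codes against the NLP label. These
let the full statistics layer run — and be checked against the study's
printed numbers — without any protected data.

Two documented restrictions reconstruct the study's analysis sets:

* the multi-class agreement analysis drops the uninformative "unknown" EHR
  column and the three smoker-temporality-unknown records, leaving the
  square current/former/never table (n = 400);
* the ever/never analysis drops only the unknown column (n = 403), folding
  smoker-temporality-unknown into "ever";
* the current-smoker comparison likewise sets aside its single
  smoker-temporality-unknown record (52/73 concordant), matching the
  study's printed 71.2%.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .agreement import (
    AgreementResult,
    ContingencyTable,
    ScreeningMetrics,
    WeightScheme,
    cohens_kappa,
    collapse_table,
    concordance,
    restrict_table,
    screening_metrics,
)

STATUS_ORDERING = ("current", "former", "never")


def _load() -> dict:
    with resources.files("smokereg.data").joinpath("validation_tables.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


def _table(block: dict) -> ContingencyTable:
    return ContingencyTable(
        tuple(block["row_labels"]),
        tuple(block["col_labels"]),
        np.asarray(block["counts"], dtype=float),
    )


def status_table() -> ContingencyTable:
    """Questionnaire status (rows) × merged-EHR five-class status (columns)."""
    return _table(_load()["status"])


def eligibility_table() -> ContingencyTable:
    """Questionnaire eligibility × EHR eligibility, including missing-data."""
    return _table(_load()["eligibility"])


def current_smoker_table() -> ContingencyTable:
    """Semi-structured 'current' records × NLP label (74 records)."""
    return _table(_load()["current_smoker"])


def status_table_three_class() -> ContingencyTable:
    """The square current/former/never restriction (n = 400)."""
    return restrict_table(status_table(), STATUS_ORDERING)


def status_table_ever_never() -> ContingencyTable:
    """The ever/never collapse over classifiable EHR records (n = 403)."""
    t = status_table()
    return collapse_table(
        t,
        row_groups={"ever": ("current", "former"), "never": ("never",)},
        col_groups={
            "ever": ("current", "former", "smoker_temporality_unknown"),
            "never": ("never",),
        },
    )


def combined_status_agreement() -> tuple[AgreementResult, AgreementResult]:
    """(concordance, quadratic-weighted kappa) on the n=400 three-class table."""
    t = status_table_three_class()
    return (
        concordance(t),
        cohens_kappa(t, WeightScheme.QUADRATIC, ordering=STATUS_ORDERING),
    )


def ever_never_agreement() -> tuple[AgreementResult, AgreementResult]:
    """(concordance, unweighted kappa) on the n=403 ever/never table."""
    t = status_table_ever_never()
    return (concordance(t), cohens_kappa(t, WeightScheme.NONE))


def current_smoker_concordance() -> AgreementResult:
    """Concordance for current-smoker codes, STU record set aside (52/73)."""
    t = collapse_table(
        current_smoker_table(),
        row_groups={"current": ("current",)},
        col_groups={l: (l,) for l in ("current", "former", "never")},
    )
    return concordance(t, pairing={"current": "current"})


def screening_metrics_combined() -> ScreeningMetrics:
    """PPV/NPV/sensitivity/specificity over records classifiable in both
    sources (the 2×2 block of the eligibility table)."""
    t = restrict_table(eligibility_table(), ("eligible", "not_eligible"))
    return screening_metrics(t)
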