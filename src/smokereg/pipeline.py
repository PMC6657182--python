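"""End-to-end workflow: extract → merge → assess → validate.

This module wires the extraction stages into per-patient registry profiles
and reproduces the validation workflow against a questionnaire reference:
status agreement (multi-class and ever/never), pack-year correlation, and
screening-eligibility metrics. It also hosts the file-based stage runner
behind the command-line interface, which writes a JSON run report with
record counts at every stage (records in = records out + excluded, with
reasons).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io as reg_io
from .agreement import (
    ContingencyTable,
    WeightScheme,
    cohens_kappa,
    collapse_table,
    concordance,
    kappa_ci,
    pearson_correlation,
    restrict_table,
    screening_metrics,
)
from .cessation import note_cessation_date
from .classify import DEFAULT_SEED, StatusModel, classify_note, train
from .hotspots import DEFAULT_ROOTS
from .io import ClinicalNote, QuestionnaireRecord, SemiStructuredRecord
from .merge import (
    EligibilityResult,
    Reason,
    SmokingProfile,
    Verdict,
    assess_eligibility,
    build_profile,
)
from .packyears import PackYearConfig, note_pack_years
from .simulate import GeneratorConfig, generate_corpus, make_training_corpus
from .status import SmokingStatus


@dataclass
class PipelineConfig:
    roots: tuple[str, ...] = DEFAULT_ROOTS
    packyear: PackYearConfig = field(default_factory=PackYearConfig)
    cessation_gate: bool = True
    threshold: float = 30.0
    inclusive_threshold: bool = True
    quit_window_years: int = 15
    assume_recent_quit: bool = True
    seed: int = DEFAULT_SEED


def extract_profile(
    note: ClinicalNote,
    model: Optional[StatusModel],
    config: PipelineConfig = PipelineConfig(),
    semi: Optional[SemiStructuredRecord] = None,
) -> SmokingProfile:
    """Run all three extractors on one note and merge with a coded record."""
    status = classify_note(model, note, config.roots)
    pack_years = note_pack_years(note.text, config.packyear)
    cess = note_cessation_date(
        note.text, note.note_date, require_smoking_root=config.cessation_gate
    )
    return build_profile(
        patient_id=note.patient_id,
        status_nlp=status,
        pack_years_nlp=pack_years,
        cessation_date=None if cess is None else cess.date,
        semi=semi,
    )


def extract_profiles(
    notes: Sequence[ClinicalNote],
    model: Optional[StatusModel],
    semi_records: Sequence[SemiStructuredRecord] = (),
    config: PipelineConfig = PipelineConfig(),
) -> list[SmokingProfile]:
    by_patient = {r.patient_id: r for r in semi_records}
    return [
        extract_profile(n, model, config, semi=by_patient.get(n.patient_id))
        for n in notes
    ]


def questionnaire_eligibility(
    q: QuestionnaireRecord, *, threshold: float = 30.0, inclusive: bool = True
) -> Verdict:
    """Reference eligibility from self-report; all former smokers are taken
    as recently quit (no cessation dates exist on the questionnaire side)."""
    if q.status is None:
        return Verdict.MISSING_DATA
    if q.status is SmokingStatus.NEVER:
        return Verdict.NOT_ELIGIBLE
    py = q.pack_years
    if py is None:
        return Verdict.MISSING_DATA
    meets = py >= threshold if inclusive else py > threshold
    return Verdict.ELIGIBLE if meets else Verdict.NOT_ELIGIBLE


_FIVE_CLASS = ("current", "former", "never", "smoker_temporality_unknown", "unknown")
_THREE_CLASS = ("current", "former", "never")


def validate_registry(
    profiles: Sequence[SmokingProfile],
    questionnaire: Sequence[QuestionnaireRecord],
    note_dates: Optional[dict[str, dt.date]] = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Agreement report of the merged registry against the questionnaire.

    Returns a JSON-serializable dict with the status cross-tabulation, the
    three-class (quadratic-weighted kappa) and ever/never (unweighted kappa)
    agreement, pack-year correlation over patients with history in both
    sources, and the 2×2 screening metrics over patients classifiable in
    both.
    """
    q_by_pid = {q.patient_id: q for q in questionnaire}
    pairs_status: list[tuple[str, str]] = []
    pairs_py: list[tuple[float, float]] = []
    elig_pairs: list[tuple[str, str]] = []
    for p in profiles:
        q = q_by_pid.get(p.patient_id)
        if q is None or q.status is None:
            continue
        pairs_status.append((q.status.value, p.status_merged.value))
        if q.pack_years is not None and p.pack_years_merged is not None:
            pairs_py.append((p.pack_years_merged, q.pack_years))
        ref = questionnaire_eligibility(
            q, threshold=config.threshold, inclusive=config.inclusive_threshold
        )
        ehr = assess_eligibility(
            p,
            threshold=config.threshold,
            inclusive=config.inclusive_threshold,
            quit_window_years=config.quit_window_years,
            assume_recent_quit=config.assume_recent_quit,
            reference_date=(note_dates or {}).get(p.patient_id),
        )
        elig_pairs.append((ref.value, ehr.verdict.value))

    status_table = ContingencyTable.from_pairs(pairs_status, _THREE_CLASS, _FIVE_CLASS)
    report: dict = {
        "n_compared": len(pairs_status),
        "status_table": {
            "row_labels": list(status_table.row_labels),
            "col_labels": list(status_table.col_labels),
            "counts": status_table.counts.astype(int).tolist(),
        },
    }

    three = restrict_table(status_table, _THREE_CLASS)
    if three.n > 0:
        conc = concordance(three)
        kap = cohens_kappa(three, WeightScheme.QUADRATIC, ordering=_THREE_CLASS)
        lo, hi = kappa_ci(three, kap, ordering=_THREE_CLASS)
        report["three_class"] = {
            "n": conc.n,
            "concordance": conc.statistic,
            "weighted_kappa": kap.statistic,
            "kappa_ci": [lo, hi],
        }
    ever = collapse_table(
        status_table,
        row_groups={"ever": ("current", "former"), "never": ("never",)},
        col_groups={
            "ever": ("current", "former", "smoker_temporality_unknown"),
            "never": ("never",),
        },
    )
    if ever.n > 0:
        conc = concordance(ever)
        kap = cohens_kappa(ever, WeightScheme.NONE)
        report["ever_never"] = {
            "n": conc.n,
            "concordance": conc.statistic,
            "kappa": kap.statistic,
        }
    if len(pairs_py) >= 2:
        report["pack_years"] = {
            "n": len(pairs_py),
            "pearson_r": pearson_correlation(pairs_py),
        }
    elig_table = ContingencyTable.from_pairs(
        elig_pairs,
        ("eligible", "not_eligible", "missing_data"),
        ("eligible", "not_eligible", "missing_data"),
    )
    report["eligibility_table"] = {
        "labels": ["eligible", "not_eligible", "missing_data"],
        "counts": elig_table.counts.astype(int).tolist(),
    }
    two = restrict_table(elig_table, ("eligible", "not_eligible"))
    if two.n > 0:
        m = screening_metrics(two)
        report["screening"] = {
            "n": int(two.n),
            "ppv": m.ppv, "npv": m.npv,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
        }
    return report


def recovery_metrics(
    profiles: Sequence[SmokingProfile],
    gold: Sequence,
    *,
    tol: float = 1e-9,
) -> dict:
    """Parameter-recovery rates of the pipeline against simulator gold.

    Status accuracy and the UNKNOWN fraction are over all patients;
    pack-year exact recovery is over smokers whose note carried quantities;
    cessation-year recovery is over former smokers with an informative note.
    """
    by_pid = {p.patient_id: p for p in profiles}
    n = status_ok = unknown = 0
    py_n = py_ok = 0
    cess_n = cess_ok = 0
    for g in gold:
        p = by_pid[g.patient_id]
        n += 1
        if p.status_merged is SmokingStatus.UNKNOWN:
            unknown += 1
        if g.note_has_info:
            if p.status_merged is g.true_status:
                status_ok += 1
            if g.true_pack_years is not None:
                py_n += 1
                if (
                    p.pack_years_merged is not None
                    and abs(p.pack_years_merged - g.true_pack_years) <= tol
                ):
                    py_ok += 1
            if g.true_quit_date is not None:
                cess_n += 1
                if (
                    p.cessation_date is not None
                    and p.cessation_date.year == g.true_quit_date.year
                ):
                    cess_ok += 1
    return {
        "n": n,
        "n_with_info": sum(1 for g in gold if g.note_has_info),
        "status_accuracy": status_ok / max(1, sum(1 for g in gold if g.note_has_info)),
        "unknown_fraction": unknown / max(1, n),
        "pack_year_exact_recovery": py_ok / py_n if py_n else None,
        "cessation_year_recovery": cess_ok / cess_n if cess_n else None,
    }


# ---------------------------------------------------------------------------
# File-based stage runner (CLI backend)


class StageError(RuntimeError):
    pass


STAGES = ("simulate", "train", "extract", "merge", "eligibility", "validate")


def _require_artifact(path: Path, stage: str, producer: str) -> None:
    if not path.exists():
        raise StageError(
            f"stage {stage!r} requires missing artifact {path.name!r} "
            f"(produced by {producer!r})"
        )


def run_pipeline(
    outdir,
    stages: Sequence[str] = STAGES,
    *,
    generator: Optional[GeneratorConfig] = None,
    config: PipelineConfig = PipelineConfig(),
    train_per_class: int = 120,
) -> dict:
    """Run the requested stages in order, writing artifacts under ``outdir``
    and returning the run report (also written as ``report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "notes": outdir / "notes.csv",
        "semi": outdir / "semi_structured.csv",
        "questionnaire": outdir / "questionnaire.csv",
        "gold": outdir / "gold.jsonl",
        "model": outdir / "model.json",
        "registry": outdir / "registry.csv",
        "eligibility": outdir / "eligibility.csv",
        "stats": outdir / "validation.json",
    }
    report: dict = {"schema_version": 1, "stages": {}}

    for stage in stages:
        if stage == "simulate":
            gen = generator or GeneratorConfig(seed=config.seed)
            corpus = generate_corpus(gen)
            reg_io.write_notes(corpus.notes, paths["notes"])
            reg_io.write_semistructured(corpus.semi_records, paths["semi"])
            reg_io.write_questionnaire(corpus.questionnaire, paths["questionnaire"])
            with open(paths["gold"], "w", encoding="utf-8") as fh:
                for g in corpus.gold:
                    d = dataclasses.asdict(g)
                    d["true_status"] = g.true_status.value
                    d["true_quit_date"] = (
                        None if g.true_quit_date is None else g.true_quit_date.isoformat()
                    )
                    fh.write(json.dumps(d) + "\n")
            report["stages"]["simulate"] = {
                "n_patients": len(corpus.gold),
                "n_notes": len(corpus.notes),
                "n_semi_records": len(corpus.semi_records),
                "n_questionnaire": len(corpus.questionnaire),
            }
        elif stage == "train":
            examples = make_training_corpus(train_per_class, seed=config.seed)
            model = train(examples, seed=config.seed)
            model.save(paths["model"])
            report["stages"]["train"] = {
                "n_examples": len(examples),
                "training_accuracy": model.metadata["training_accuracy"],
            }
        elif stage == "extract":
            _require_artifact(paths["notes"], stage, "simulate")
            _require_artifact(paths["model"], stage, "train")
            notes = reg_io.read_notes(paths["notes"]).records
            model = StatusModel.load(paths["model"])
            profiles = extract_profiles(notes, model, (), config)
            reg_io.write_registry(profiles, paths["registry"])
            counts = {s.value: 0 for s in SmokingStatus}
            for p in profiles:
                counts[p.status_nlp.value] += 1
            report["stages"]["extract"] = {
                "n_notes": len(notes),
                "status_counts": counts,
                "n_pack_years": sum(1 for p in profiles if p.pack_years_nlp is not None),
                "n_cessation_dates": sum(1 for p in profiles if p.cessation_date is not None),
            }
        elif stage == "merge":
            _require_artifact(paths["registry"], stage, "extract")
            _require_artifact(paths["semi"], stage, "simulate")
            profiles = reg_io.read_registry(paths["registry"]).records
            semi = reg_io.read_semistructured(paths["semi"]).records
            by_pid = {r.patient_id: r for r in semi}
            merged = [
                dataclasses.replace(
                    p,
                    status_semi=by_pid[p.patient_id].status if p.patient_id in by_pid else None,
                    pack_years_semi=by_pid[p.patient_id].pack_years if p.patient_id in by_pid else None,
                    semi_source=p.patient_id in by_pid,
                )
                for p in profiles
            ]
            reg_io.write_registry(merged, paths["registry"])
            report["stages"]["merge"] = {
                "n_profiles": len(merged),
                "n_with_semi": sum(1 for p in merged if p.semi_source),
            }
        elif stage == "eligibility":
            _require_artifact(paths["registry"], stage, "merge")
            profiles = reg_io.read_registry(paths["registry"]).records
            dates = _note_dates(paths["notes"])
            rows = []
            tally = {v.value: 0 for v in Verdict}
            for p in profiles:
                r = assess_eligibility(
                    p,
                    threshold=config.threshold,
                    inclusive=config.inclusive_threshold,
                    quit_window_years=config.quit_window_years,
                    assume_recent_quit=config.assume_recent_quit,
                    reference_date=dates.get(p.patient_id),
                )
                tally[r.verdict.value] += 1
                rows.append(
                    {"patient_id": p.patient_id, "verdict": r.verdict.value, "reason": r.reason.value}
                )
            with open(paths["eligibility"], "w", newline="", encoding="utf-8") as fh:
                import csv as _csv

                w = _csv.DictWriter(fh, fieldnames=("patient_id", "verdict", "reason"))
                w.writeheader()
                w.writerows(rows)
            report["stages"]["eligibility"] = {"n": len(rows), "verdicts": tally}
        elif stage == "validate":
            _require_artifact(paths["registry"], stage, "merge")
            _require_artifact(paths["questionnaire"], stage, "simulate")
            profiles = reg_io.read_registry(paths["registry"]).records
            questionnaire = reg_io.read_questionnaire(paths["questionnaire"]).records
            stats = validate_registry(
                profiles, questionnaire, _note_dates(paths["notes"]), config
            )
            paths["stats"].write_text(json.dumps(stats, indent=2), encoding="utf-8")
            report["stages"]["validate"] = {
                "n_compared": stats["n_compared"],
                "three_class": stats.get("three_class"),
                "ever_never": stats.get("ever_never"),
                "screening": stats.get("screening"),
            }
        else:
            raise StageError(f"unknown stage: {stage!r}")

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    return report


def _note_dates(notes_path: Path) -> dict[str, dt.date]:
    if not Path(notes_path).exists():
        return {}
    return {
        n.patient_id: n.note_date for n in reg_io.read_notes(notes_path).records
    }
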