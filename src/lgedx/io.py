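"""Cohort CSV round-tripping and the end-to-end evaluation report.

CSV schema (one row per patient, comma-separated, UTF-8, header required):
``id, diagnosis, lv_seg_01..lv_seg_17, rv_seg_18..rv_seg_24, atrial,
valvular, papillary, moderator_band, whales_tail, junctional_only,
genotype_positive``.  LV cells hold a transmurality token ("" = no LGE,
"subepi", "mid", "subendo", "transmural"); RV cells and flags are 0/1;
genotype_positive may be blank for unknown.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .classifiers import (
    DecisionTree,
    PaduaCategory,
    any_lv_lge,
    any_rv_lge,
    classify_patient,
    default_paper_tree,
    padua_category,
    padua_lv_criterion,
    padua_rv_criterion,
    tree_from_json,
)
from .metrics import (
    TestMethod,
    compare_binary,
    confusion_table,
    diagnostic_metrics,
    printed_threshold,
)
from .segments import (
    Cohort,
    Diagnosis,
    LVSegment,
    MiscLGEFlags,
    NON_ARVC,
    PatientRecord,
    RVSegment,
    SegmentalLGEMap,
    Transmurality,
    extract_features,
    validate_patient,
)

logger = logging.getLogger("lgedx")

_LV_COLS = [f"lv_seg_{i:02d}" for i in range(1, 18)]
_RV_COLS = [f"rv_seg_{i}" for i in range(18, 25)]
_FLAG_COLS = ["atrial", "valvular", "papillary", "moderator_band", "whales_tail"]
COLUMNS = (
    ["id", "diagnosis"]
    + _LV_COLS
    + _RV_COLS
    + _FLAG_COLS
    + ["junctional_only", "genotype_positive"]
)

_TOKEN_TO_TRANS = {t.value: t for t in Transmurality}


class CohortParseError(ValueError):
    """CSV did not parse into a valid cohort; message lists row numbers."""


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    rows = []
    for p in cohort:
        row: dict[str, object] = {"id": p.id, "diagnosis": p.diagnosis.value}
        for i, col in enumerate(_LV_COLS, start=1):
            t = p.lge.lv.get(LVSegment(i))
            row[col] = "" if t is None else t.value
        for i, col in zip(range(18, 25), _RV_COLS):
            row[col] = int(bool(p.lge.rv.get(RVSegment(i), False)))
        for col in _FLAG_COLS:
            row[col] = int(getattr(p.lge.misc, col))
        row["junctional_only"] = int(p.lge.junctional_only_septal_lge)
        row["genotype_positive"] = (
            "" if p.genotype_positive is None else int(p.genotype_positive)
        )
        rows.append(row)
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_cohort(path: Union[str, Path]) -> Cohort:
    """Parse and validate a cohort CSV; every problem row is reported."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"missing column(s): {', '.join(missing)}")
    errors: list[str] = []
    patients: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        pid = row["id"].strip()
        if pid in seen_ids:
            errors.append(f"row {rowno}: duplicate id {pid!r}")
        seen_ids.add(pid)
        try:
            dx = Diagnosis(row["diagnosis"].strip())
        except ValueError:
            errors.append(f"row {rowno}: unknown diagnosis {row['diagnosis']!r}")
            continue
        lv: dict[LVSegment, Transmurality] = {}
        ok = True
        for i, col in enumerate(_LV_COLS, start=1):
            token = row[col].strip()
            if token != row[col]:
                logger.info("row %d: trimmed whitespace in %s", rowno, col)
            if not token:
                continue
            if token not in _TOKEN_TO_TRANS:
                errors.append(f"row {rowno}: malformed transmurality {row[col]!r} in {col}")
                ok = False
                continue
            lv[LVSegment(i)] = _TOKEN_TO_TRANS[token]
        rv: set[RVSegment] = set()
        for i, col in zip(range(18, 25), _RV_COLS):
            token = row[col].strip()
            if token not in ("0", "1"):
                errors.append(f"row {rowno}: {col} must be 0/1, got {row[col]!r}")
                ok = False
            elif token == "1":
                rv.add(RVSegment(i))
        flags = {}
        for col in _FLAG_COLS + ["junctional_only"]:
            token = row[col].strip()
            if token not in ("0", "1"):
                errors.append(f"row {rowno}: {col} must be 0/1, got {row[col]!r}")
                ok = False
                token = "0"
            flags[col] = token == "1"
        geno_token = row["genotype_positive"].strip()
        if geno_token not in ("", "0", "1"):
            errors.append(f"row {rowno}: genotype_positive must be 0/1/blank")
            ok = False
        geno = None if geno_token == "" else geno_token == "1"
        if not ok:
            continue
        patient = PatientRecord(
            id=pid,
            diagnosis=dx,
            lge=SegmentalLGEMap.from_positive(
                lv=lv,
                rv=rv,
                misc=MiscLGEFlags(**{f: flags[f] for f in _FLAG_COLS}),
                junctional_only_septal_lge=flags["junctional_only"],
            ),
            genotype_positive=geno,
        )
        violations = validate_patient(patient)
        if violations:
            errors.extend(f"row {rowno}: {v}" for v in violations)
        else:
            patients.append(patient)
    if errors:
        raise CohortParseError("; ".join(errors))
    return Cohort(tuple(patients))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    cohort_path: Optional[str] = None
    seed: int = 0
    alpha: float = 0.05
    ci_method: str = "wilson"
    chi2_method: str = "auto"
    tree_path: Optional[str] = None
    out_dir: str = "lgedx-out"
    genotype_positive_only: bool = False
    verbosity: int = 0


def _metrics_block(cohort: Cohort, preds: dict[str, bool], alpha: float) -> dict:
    table = confusion_table(cohort, preds)
    dm = diagnostic_metrics(table, alpha=alpha)
    per_diff = {}
    for dx in NON_ARVC:
        t = confusion_table(cohort, preds, restrict_to=[Diagnosis.ARVC, dx])
        m = diagnostic_metrics(t, alpha=alpha)
        per_diff[dx.value] = None if m.specificity is None else m.specificity
    k_arvc = sum(
        preds[p.id] for p in cohort if p.diagnosis is Diagnosis.ARVC
    )
    n_arvc = sum(1 for p in cohort if p.diagnosis is Diagnosis.ARVC)
    k_non = sum(preds[p.id] for p in cohort if p.diagnosis is not Diagnosis.ARVC)
    n_non = len(cohort) - n_arvc
    comparison = None
    if 0 < n_arvc and 0 < n_non:
        res = compare_binary(k_arvc, n_arvc, k_non, n_non, TestMethod.AUTO)
        comparison = {
            "test": res.test_name.value,
            "statistic": res.statistic,
            "p_value": res.p_value,
        }
    return {
        "confusion": dataclasses.asdict(table),
        "metrics": {
            "sensitivity": dm.sensitivity,
            "specificity": dm.specificity,
            "accuracy": dm.accuracy,
            "ppv": dm.ppv,
            "npv": dm.npv,
        },
        "metrics_percent": dm.as_percent(),
        "ci": dm.ci,
        "specificity_vs_differential": per_diff,
        "prevalence": {
            "ARVC": {"count": int(k_arvc), "n": int(n_arvc)},
            "non_ARVC": {"count": int(k_non), "n": int(n_non)},
        },
        "arvc_vs_non_arvc": comparison,
    }


def evaluate_cohort(
    cohort: Cohort,
    tree: Optional[DecisionTree] = None,
    alpha: float = 0.05,
) -> dict:
    """Diagnostic evaluation of the four LGE classifiers and the decision
    tree on a cohort, with ARVC as the positive class throughout.

    Returns a JSON-serializable dict: 2x2 tables, metric sets with Wilson
    CIs, per-differential specificities, Padua-LV prevalence per diagnosis,
    the four-way Padua category partition, and ARVC-vs-non-ARVC comparison
    p-values with the per-report Bonferroni threshold.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    tree = tree or default_paper_tree()
    feats = {p.id: extract_features(p) for p in cohort}
    preds = {
        "any_rv_lge": {p.id: any_rv_lge(feats[p.id]) for p in cohort},
        "any_lv_lge": {p.id: any_lv_lge(feats[p.id]) for p in cohort},
        "padua_rv": {p.id: padua_rv_criterion(p) for p in cohort},
        "decision_tree": {
            p.id: classify_patient(tree, p) is Diagnosis.ARVC for p in cohort
        },
    }
    out: dict = {
        "n": len(cohort),
        "group_sizes": {d.value: n for d, n in cohort.group_sizes().items()},
        "classifiers": {
            name: _metrics_block(cohort, pred, alpha) for name, pred in preds.items()
        },
    }
    # LV-LGE per Padua: prevalence per diagnosis (no gold standard for
    # left-dominant disease, so no sens/spec)
    prev = {}
    sizes = cohort.group_sizes()
    for dx in Diagnosis:
        group = [p for p in cohort if p.diagnosis is dx]
        if not group:
            continue
        k = sum(padua_lv_criterion(p) for p in group)
        prev[dx.value] = {"count": int(k), "n": sizes[dx]}
    out["padua_lv_prevalence"] = prev
    cats = {cat.value: 0 for cat in PaduaCategory}
    for p in cohort:
        cats[padua_category(p).value] += 1
    out["padua_category_counts"] = cats
    m = len(preds)
    out["bonferroni"] = {
        "alpha": alpha,
        "m_comparisons": m,
        "threshold_printed": printed_threshold(alpha, m),
    }
    return out


def _report_markdown(report: dict) -> str:
    lines = ["# LGE diagnostic evaluation", ""]
    lines.append(f"Patients: {report['n']}  ")
    lines.append("Group sizes: " + ", ".join(
        f"{k} {v}" for k, v in report["group_sizes"].items()) + "")
    lines.append("")
    lines.append("| classifier | tp | fp | fn | tn | sens % | spec % | acc % | ppv % | npv % | p (ARVC vs non) |")
    lines.append("|---|---|---|---|---|---|---|---|---|---|---|")
    for name, block in report["classifiers"].items():
        t = block["confusion"]
        pct = block["metrics_percent"]
        comp = block["arvc_vs_non_arvc"]
        p_txt = "-" if comp is None else f"{comp['p_value']:.3f}"
        cells = [str(pct[k]) if pct[k] is not None else "-" for k in
                 ("sensitivity", "specificity", "accuracy", "ppv", "npv")]
        lines.append(
            f"| {name} | {t['tp']} | {t['fp']} | {t['fn']} | {t['tn']} | "
            + " | ".join(cells) + f" | {p_txt} |"
        )
    lines.append("")
    lines.append("Four-way Padua partition (both / LV only / RV only / neither): "
                 + " / ".join(str(report["padua_category_counts"][k])
                              for k in ("both", "lv_only", "rv_only", "neither")))
    lines.append("")
    lines.append("LV-LGE per Padua prevalence: " + ", ".join(
        f"{dx} {d['count']}/{d['n']}" for dx, d in report["padua_lv_prevalence"].items()))
    lines.append("")
    b = report["bonferroni"]
    lines.append(
        f"Bonferroni: alpha {b['alpha']}, m = {b['m_comparisons']}, "
        f"printed threshold {b['threshold_printed']}")
    return "\n".join(lines) + "\n"


def run_evaluate(config: RunConfig) -> dict:
    """Read a cohort, evaluate, and write JSON + Markdown reports and a
    reproducibility manifest into the output directory."""
    if config.cohort_path is None:
        raise ValueError("config.cohort_path is required")
    cohort = read_cohort(config.cohort_path)
    if config.genotype_positive_only:
        cohort = cohort.subset(genotype_positive=True)
    tree = None
    if config.tree_path:
        tree = tree_from_json(Path(config.tree_path).read_text())
    report = evaluate_cohort(cohort, tree=tree, alpha=config.alpha)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "evaluation.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "evaluation.md").write_text(_report_markdown(report))
    manifest = {
        "package": "lgedx",
        "version": __version__,
        "command": "evaluate",
        "config": dataclasses.asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote evaluation to %s", out)
    return report
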