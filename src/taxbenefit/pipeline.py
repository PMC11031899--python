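"""End-to-end experiment orchestration.

One call (or one shell command) reproduces the full design: simulate a
cohort -> PFS-threshold labels -> outcome-stratified 80:20 split -> fit the
four classifiers on the training split -> AUROC / threshold metrics with
bootstrap CIs -> Kaplan-Meier + log-rank validation of the predicted strata
on the validation split -> baseline-characteristics tables -> artifacts on
disk.

A single global seed fans out to per-stage seeds through a fixed
``SeedSequence([global_seed, stage_offset])`` scheme, so any stage can be
re-run in isolation with the same stream it saw inside the full run.
"""

from __future__ import annotations

import csv
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import yaml

from . import __version__
from .cohort_synth import (
    PATIENT_CSV_COLUMNS,
    VARIANT_CSV_COLUMNS,
    CohortConfig,
    EffectSpec,
    Patient,
    generate_cohort,
)
from .evaluation import MetricsReport, evaluate_scores, roc_curve
from .features import (
    EXCLUDED,
    BaselineTable,
    build_feature_set,
    build_variant_vocabulary,
    stratified_split,
    summarize_cohort,
)
from .models import MODEL_KINDS, FittedModel, ModelSpec, fit_classifier, predict_proba
from .survival import SurvivalComparison, compare_predicted_groups

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "stage_seed",
    "run_experiment",
    "load_cohort",
    "write_report",
]

_STAGE_OFFSETS = {
    "cohort": 1,
    "split": 2,
    "random_forest": 3,
    "logistic_regression": 4,
    "ann": 5,
    "ann_with_ge": 6,
    "bootstrap": 7,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([global_seed, _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class ExperimentConfig:
    """Everything one experiment run depends on."""

    cohort: CohortConfig
    t_resistant: float = 3.0
    t_sensitive: float = 6.0
    validation_fraction: float = 0.2
    model_kinds: tuple[str, ...] = MODEL_KINDS
    decision_threshold: float = 0.5
    bootstrap_n: int = 2000
    ci_level: float = 0.95
    vocabulary_policy: str = "train_only"  # or "all_patients"
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if not 0 < self.t_resistant <= self.t_sensitive:
            raise ValueError("label thresholds must satisfy 0 < t_resistant <= t_sensitive")
        if self.vocabulary_policy not in ("train_only", "all_patients"):
            raise ValueError("vocabulary_policy must be 'train_only' or 'all_patients'")
        for kind in self.model_kinds:
            if kind not in MODEL_KINDS:
                raise ValueError(f"unknown model kind {kind!r}")

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["cohort"]["clinical_prevalences"] = dict(
            payload["cohort"]["clinical_prevalences"]
        )
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text())
        cohort_payload = payload.pop("cohort")
        effect = cohort_payload.pop("effect_spec", None)
        if effect is not None:
            effect["beta_clinical"] = tuple(effect.get("beta_clinical", ()))
            effect["beta_variant"] = tuple(effect.get("beta_variant", ()))
            effect["beta_variant_os"] = tuple(effect.get("beta_variant_os", ()))
            effect["gamma_pairs"] = tuple(
                tuple(pair) for pair in effect.get("gamma_pairs", ())
            )
            cohort_payload["effect_spec"] = EffectSpec(**effect)
        if cohort_payload.get("variant_prevalences") is not None:
            cohort_payload["variant_prevalences"] = tuple(
                cohort_payload["variant_prevalences"]
            )
        payload["cohort"] = CohortConfig(**cohort_payload)
        payload["model_kinds"] = tuple(payload.get("model_kinds", MODEL_KINDS))
        return cls(**payload)


@dataclass
class ExperimentReport:
    """Everything the run computed, recomputable from config + seed."""

    config: ExperimentConfig
    n_total: int
    n_labeled: int
    n_excluded: int
    n_train: int
    n_validation: int
    train_metrics: dict[str, MetricsReport]
    validation_metrics: dict[str, MetricsReport]
    validation_scores: dict[str, np.ndarray]
    validation_labels: np.ndarray
    train_scores: dict[str, np.ndarray]
    train_labels: np.ndarray
    survival_comparisons: dict[str, dict[str, SurvivalComparison]]
    baseline_train_vs_validation: BaselineTable
    baseline_sensitive_vs_resistant: BaselineTable
    models: dict[str, FittedModel] = field(repr=False, default_factory=dict)
    provenance: dict = field(default_factory=dict)


def run_experiment(config: ExperimentConfig, log=None) -> ExperimentReport:
    """Execute every stage in order; deterministic given the global seed."""
    config.validate()

    def _log(msg: str) -> None:
        if log:
            print(msg, file=log)

    cohort_cfg = CohortConfig(
        **{**config.cohort.__dict__, "seed": stage_seed(config.seed, "cohort")}
    )
    _log("stage: simulate cohort")
    cohort = generate_cohort(cohort_cfg)

    _log("stage: label and split")
    all_features = build_feature_set(
        cohort, t_resistant=config.t_resistant, t_sensitive=config.t_sensitive
    )
    labeled = [i for i, lab in enumerate(all_features.labels) if lab != EXCLUDED]
    if not labeled:
        raise RuntimeError("labeling stage: no patient received a definite label")
    y_labeled = (np.array([all_features.labels[i] for i in labeled]) == "sensitive").astype(int)
    split = stratified_split(
        y_labeled, config.validation_fraction, seed=stage_seed(config.seed, "split")
    )
    train_idx = [labeled[i] for i in split.train_indices]
    val_idx = [labeled[i] for i in split.validation_indices]
    assert not set(train_idx) & set(val_idx)

    # Feature layout: vocabulary from training patients only by default, so no
    # validation information leaks into the fitted models.
    if config.vocabulary_policy == "train_only":
        vocab = build_variant_vocabulary([cohort[i] for i in train_idx])
    else:
        vocab = build_variant_vocabulary(cohort)
    features = build_feature_set(
        cohort,
        vocab=vocab,
        t_resistant=config.t_resistant,
        t_sensitive=config.t_sensitive,
        restrict_to_vocabulary=True,
    )

    models: dict[str, FittedModel] = {}
    train_metrics: dict[str, MetricsReport] = {}
    validation_metrics: dict[str, MetricsReport] = {}
    train_scores: dict[str, np.ndarray] = {}
    validation_scores: dict[str, np.ndarray] = {}
    survival_comparisons: dict[str, dict[str, SurvivalComparison]] = {}
    y_train = features.binary_labels(train_idx)
    y_val = features.binary_labels(val_idx)
    boot_seed = stage_seed(config.seed, "bootstrap")
    for kind in config.model_kinds:
        _log(f"stage: fit {kind}")
        spec = ModelSpec(kind=kind, seed=stage_seed(config.seed, kind))
        model = fit_classifier(spec, features, train_idx)
        models[kind] = model
        s_train = predict_proba(model, features, train_idx)
        s_val = predict_proba(model, features, val_idx)
        train_scores[kind] = s_train
        validation_scores[kind] = s_val
        train_metrics[kind] = evaluate_scores(
            s_train, y_train, config.decision_threshold,
            config.bootstrap_n, config.ci_level, boot_seed,
        )
        validation_metrics[kind] = evaluate_scores(
            s_val, y_val, config.decision_threshold,
            config.bootstrap_n, config.ci_level, boot_seed,
        )
        survival_comparisons[kind] = {
            endpoint: compare_predicted_groups(
                model, features, cohort, val_idx, endpoint, config.decision_threshold
            )
            for endpoint in ("pfs", "os")
        }

    _log("stage: baseline tables")
    baseline_split = summarize_cohort(
        [[cohort[i] for i in train_idx], [cohort[i] for i in val_idx]],
        ("train", "validation"),
    )
    sens = [cohort[i] for i in train_idx if features.labels[i] == "sensitive"]
    res = [cohort[i] for i in train_idx if features.labels[i] == "resistant"]
    baseline_outcome = summarize_cohort([sens, res], ("sensitive", "resistant"))

    provenance = {
        "package_version": __version__,
        "global_seed": config.seed,
        "stage_seeds": {k: stage_seed(config.seed, k) for k in _STAGE_OFFSETS},
        "vocabulary_policy": config.vocabulary_policy,
        "vocabulary_size": len(vocab),
        "python": sys.version.split()[0],
    }
    return ExperimentReport(
        config=config,
        n_total=len(cohort),
        n_labeled=len(labeled),
        n_excluded=len(cohort) - len(labeled),
        n_train=len(train_idx),
        n_validation=len(val_idx),
        train_metrics=train_metrics,
        validation_metrics=validation_metrics,
        validation_scores=validation_scores,
        validation_labels=y_val,
        train_scores=train_scores,
        train_labels=y_train,
        survival_comparisons=survival_comparisons,
        baseline_train_vs_validation=baseline_split,
        baseline_sensitive_vs_resistant=baseline_outcome,
        models=models,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Cohort CSV round-trip
# ---------------------------------------------------------------------------

def load_cohort(patient_csv, variant_csv) -> list[Patient]:
    """Read the documented patient + long-format variant CSV pair.

    Strict on headers, duplicate patient ids, and variant rows referencing
    unknown patients; round-trips byte-for-byte with the cohort writers.
    """
    with open(patient_csv, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != PATIENT_CSV_COLUMNS:
            raise ValueError(
                f"patient CSV header mismatch: expected {PATIENT_CSV_COLUMNS}, "
                f"got {tuple(reader.fieldnames or ())}"
            )
        rows = list(reader)
    seen: set[str] = set()
    variant_sets: dict[str, set[str]] = {}
    for row in rows:
        pid = row["patient_id"]
        if pid in seen:
            raise ValueError(f"duplicate patient_id {pid!r}")
        seen.add(pid)
        variant_sets[pid] = set()
    with open(variant_csv, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != VARIANT_CSV_COLUMNS:
            raise ValueError(
                f"variant CSV header mismatch: expected {VARIANT_CSV_COLUMNS}, "
                f"got {tuple(reader.fieldnames or ())}"
            )
        for row in reader:
            pid = row["patient_id"]
            if pid not in variant_sets:
                raise ValueError(f"variant row references unknown patient_id {pid!r}")
            variant_sets[pid].add(row["variant_id"])
    return [
        Patient(
            patient_id=row["patient_id"],
            age_years=int(row["age_years"]),
            sex=row["sex"],
            histology=row["histology"],
            clinical_setting=row["clinical_setting"],
            prior_gastrectomy=int(row["prior_gastrectomy"]),
            prior_trastuzumab=int(row["prior_trastuzumab"]),
            first_line_duration=row["first_line_duration"],
            variant_ids=frozenset(variant_sets[row["patient_id"]]),
            pfs_months=float(row["pfs_months"]),
            pfs_event=int(row["pfs_event"]),
            os_months=float(row["os_months"]),
            os_event=int(row["os_event"]),
        )
        for row in rows
    ]


def write_report(report: ExperimentReport, out_dir) -> list[Path]:
    """Emit the run's artifacts: metrics JSON, baseline tables and ROC / KM
    curves as CSV, the config, and a human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    metrics_payload = {
        "n_total": report.n_total,
        "n_labeled": report.n_labeled,
        "n_excluded": report.n_excluded,
        "n_train": report.n_train,
        "n_validation": report.n_validation,
        "train": {k: m.as_dict() for k, m in report.train_metrics.items()},
        "validation": {k: m.as_dict() for k, m in report.validation_metrics.items()},
        "survival": {
            kind: {
                endpoint: {
                    "medians": cmp.medians,
                    "group_sizes": cmp.group_sizes,
                    "logrank_statistic": cmp.logrank_statistic,
                    "p_value": cmp.p_value,
                    "test_defined": cmp.test_defined,
                }
                for endpoint, cmp in per_kind.items()
            }
            for kind, per_kind in report.survival_comparisons.items()
        },
        "provenance": report.provenance,
    }
    path = out / "metrics.json"
    path.write_text(json.dumps(metrics_payload, indent=2, allow_nan=True))
    written.append(path)

    for name, table in (
        ("baseline_train_vs_validation.csv", report.baseline_train_vs_validation),
        ("baseline_sensitive_vs_resistant.csv", report.baseline_sensitive_vs_resistant),
    ):
        path = out / name
        table.to_csv(path)
        written.append(path)

    for kind, scores in report.validation_scores.items():
        curve = roc_curve(scores, report.validation_labels)
        path = out / f"roc_validation_{kind}.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fpr", "tpr", "threshold"])
            for f, t, th in zip(curve.fpr, curve.tpr, curve.thresholds):
                writer.writerow([repr(float(f)), repr(float(t)), repr(float(th))])
        written.append(path)

    for kind, per_kind in report.survival_comparisons.items():
        for endpoint, cmp in per_kind.items():
            for group, curve in cmp.curves.items():
                if curve is None:
                    continue
                path = out / f"km_{endpoint}_{kind}_{group}.csv"
                with open(path, "w", newline="") as fh:
                    writer = csv.writer(fh)
                    writer.writerow(["time", "survival", "n_at_risk", "n_events"])
                    for t, s, nr, ne in zip(
                        curve.event_times, curve.survival_prob,
                        curve.n_at_risk, curve.n_events,
                    ):
                        writer.writerow([repr(float(t)), repr(float(s)), int(nr), int(ne)])
                written.append(path)

    path = out / "config.yaml"
    report.config.to_yaml(path)
    written.append(path)

    lines = [
        f"taxbenefit experiment (seed {report.config.seed})",
        f"  cohort: {report.n_total} patients, {report.n_labeled} labeled "
        f"({report.n_excluded} excluded), train {report.n_train} / "
        f"validation {report.n_validation}",
        "  validation metrics:",
    ]
    for kind in report.config.model_kinds:
        m = report.validation_metrics[kind]
        lines.append(
            f"    {kind:20s} AUROC {m.auroc:.3f} "
            f"(95% CI {m.auroc_ci[0]:.3f}-{m.auroc_ci[1]:.3f})  "
            f"sens {m.sensitivity:.3f}  spec {m.specificity:.3f}  "
            f"acc {m.accuracy:.3f}  F1 {m.f1:.3f}"
        )
    lines.append("  predicted-strata survival (validation):")
    for kind in report.config.model_kinds:
        for endpoint in ("pfs", "os"):
            cmp = report.survival_comparisons[kind][endpoint]
            med = {
                g: ("NA" if m is None else f"{m:.2f}") for g, m in cmp.medians.items()
            }
            p = "NA" if not cmp.test_defined else f"{cmp.p_value:.3f}"
            lines.append(
                f"    {kind:20s} {endpoint.upper():3s} median "
                f"{med['predicted_sensitive']} vs {med['predicted_resistant']} mo, "
                f"log-rank P={p}"
            )
    path = out / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written
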