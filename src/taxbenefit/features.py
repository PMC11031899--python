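"""Turn a cohort into supervised-learning inputs and baseline tables.

Labeling follows the PFS-threshold rule of the study design: patients with an
observed or censored PFS beyond six months are *paclitaxel-sensitive*;
patients progressing before three months are *paclitaxel-resistant*; patients
between the thresholds, or censored too early to classify, are *excluded*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_synth import CLINICAL_FEATURE_NAMES, Patient

__all__ = [
    "SENSITIVE",
    "RESISTANT",
    "EXCLUDED",
    "VariantVocabulary",
    "FeatureSet",
    "SplitResult",
    "BaselineTable",
    "assign_label",
    "build_clinical_features",
    "build_variant_vocabulary",
    "build_variant_matrix",
    "build_feature_set",
    "stratified_split",
    "summarize_cohort",
    "categorical_balance_test",
    "percentage",
]

SENSITIVE = "sensitive"
RESISTANT = "resistant"
EXCLUDED = "excluded"


def assign_label(
    pfs_months: float,
    pfs_event: int,
    t_resistant: float = 3.0,
    t_sensitive: float = 6.0,
) -> str:
    """Classify one patient's paclitaxel response from PFS.

    Strictly more than ``t_sensitive`` months progression-free (event or
    censored — either way survival past the threshold is observed) is
    *sensitive*; an observed progression strictly before ``t_resistant``
    months is *resistant*.  Everything else — intermediate PFS, or censoring
    before the resistant threshold (outcome indeterminate) — is *excluded*.
    """
    if pfs_months < 0:
        raise ValueError("pfs_months must be non-negative")
    if not 0 < t_resistant <= t_sensitive:
        raise ValueError("thresholds must satisfy 0 < t_resistant <= t_sensitive")
    if pfs_months > t_sensitive:
        return SENSITIVE
    if pfs_months < t_resistant and pfs_event == 1:
        return RESISTANT
    return EXCLUDED


def build_clinical_features(
    patient: Patient, age_cutoff_young: int = 40
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Fixed-order binary clinical vector.

    Encoding: young-onset (age < cutoff), male sex, intestinal histology
    (mixed type is folded into diffuse upstream), prior trastuzumab, and two
    dummies for the three-level first-line-duration category (mid = reference).
    """
    if patient.sex not in ("male", "female"):
        raise ValueError(f"unknown sex value: {patient.sex!r}")
    histology = patient.histology
    if histology == "mixed":
        histology = "diffuse"
    if histology not in ("intestinal", "diffuse"):
        raise ValueError(f"unknown histology value: {patient.histology!r}")
    if patient.first_line_duration not in ("lt3", "mid", "ge6"):
        raise ValueError(
            f"unknown first_line_duration value: {patient.first_line_duration!r}"
        )
    vec = np.array(
        [
            1.0 if patient.age_years < age_cutoff_young else 0.0,
            1.0 if patient.sex == "male" else 0.0,
            1.0 if histology == "intestinal" else 0.0,
            float(patient.prior_trastuzumab),
            1.0 if patient.first_line_duration == "lt3" else 0.0,
            1.0 if patient.first_line_duration == "ge6" else 0.0,
        ]
    )
    return vec, CLINICAL_FEATURE_NAMES


@dataclass(frozen=True)
class VariantVocabulary:
    """Ordered variant identifier -> contiguous 0-based index mapping."""

    variant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant identifiers must be unique")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def index(self) -> dict[str, int]:
        return {vid: i for i, vid in enumerate(self.variant_ids)}


def _vocab_sort_key(variant_id: str) -> tuple[str, str]:
    gene = variant_id.rsplit("_", 1)[0] if "_" in variant_id else variant_id
    return (gene, variant_id)


def build_variant_vocabulary(cohort: Iterable[Patient]) -> VariantVocabulary:
    """Vocabulary over every variant observed in >= 1 patient.

    Ordering is lexicographic by gene then identifier, so the mapping is
    deterministic regardless of patient order.
    """
    observed = set()
    for p in cohort:
        observed.update(p.variant_ids)
    return VariantVocabulary(tuple(sorted(observed, key=_vocab_sort_key)))


def build_variant_matrix(
    cohort: Sequence[Patient], vocab: VariantVocabulary
) -> np.ndarray:
    """n x V binary presence matrix; out-of-vocabulary variants are an error."""
    index = vocab.index
    mat = np.zeros((len(cohort), len(vocab)))
    for i, p in enumerate(cohort):
        unknown = sorted(v for v in p.variant_ids if v not in index)
        if unknown:
            raise KeyError(
                f"patient {p.patient_id} carries variants outside the "
                f"vocabulary: {unknown}"
            )
        for v in p.variant_ids:
            mat[i, index[v]] = 1.0
    return mat


@dataclass
class FeatureSet:
    """Aligned model inputs for one cohort (rows share patient order)."""

    clinical_matrix: np.ndarray
    clinical_names: tuple[str, ...]
    variant_sets: list[frozenset[int]]
    variant_matrix: np.ndarray
    labels: list[str]
    vocabulary: VariantVocabulary

    def __post_init__(self) -> None:
        n = self.clinical_matrix.shape[0]
        if not (
            len(self.variant_sets) == self.variant_matrix.shape[0] == len(self.labels) == n
        ):
            raise ValueError("FeatureSet fields disagree on the number of patients")

    @property
    def n_patients(self) -> int:
        return self.clinical_matrix.shape[0]

    def binary_labels(self, indices: Sequence[int]) -> np.ndarray:
        """1 = sensitive, 0 = resistant; excluded patients are not allowed."""
        out = np.empty(len(indices))
        for j, i in enumerate(indices):
            lab = self.labels[i]
            if lab == EXCLUDED:
                raise ValueError(f"patient row {i} is label-excluded")
            out[j] = 1.0 if lab == SENSITIVE else 0.0
        return out


def build_feature_set(
    cohort: Sequence[Patient],
    vocab: VariantVocabulary | None = None,
    t_resistant: float = 3.0,
    t_sensitive: float = 6.0,
    age_cutoff_young: int = 40,
    restrict_to_vocabulary: bool = False,
) -> FeatureSet:
    """Assemble the full FeatureSet for a cohort.

    When ``vocab`` is supplied (e.g. built on the training split only),
    ``restrict_to_vocabulary=True`` silently drops out-of-vocabulary variants
    instead of raising — the policy used for validation patients whose
    variants were never seen in training.
    """
    if vocab is None:
        vocab = build_variant_vocabulary(cohort)
    work = cohort
    if restrict_to_vocabulary:
        known = set(vocab.variant_ids)
        work = [
            Patient(
                **{
                    **p.__dict__,
                    "variant_ids": frozenset(v for v in p.variant_ids if v in known),
                }
            )
            for p in cohort
        ]
    clinical = np.vstack(
        [build_clinical_features(p, age_cutoff_young)[0] for p in work]
    ) if work else np.zeros((0, len(CLINICAL_FEATURE_NAMES)))
    matrix = build_variant_matrix(work, vocab)
    index = vocab.index
    sets = [frozenset(index[v] for v in p.variant_ids) for p in work]
    labels = [
        assign_label(p.pfs_months, p.pfs_event, t_resistant, t_sensitive) for p in work
    ]
    return FeatureSet(clinical, CLINICAL_FEATURE_NAMES, sets, matrix, labels, vocab)


@dataclass(frozen=True)
class SplitResult:
    train_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]


def stratified_split(
    labels: Sequence[int] | np.ndarray,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> SplitResult:
    """Outcome-stratified random train/validation partition.

    The validation set has exactly ``ceil(n * fraction)`` members; per-class
    validation counts are allocated by largest remainder of
    ``class_count * fraction`` (ties broken toward the larger class), so class
    proportions are preserved to within one patient.
    """
    y = np.asarray(labels)
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must lie in (0, 1)")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("stratified_split requires at least two classes")
    n = len(y)
    val_n = math.ceil(n * validation_fraction)
    quotas = {c: int(np.sum(y == c)) * validation_fraction for c in classes}
    counts = {c: int(math.floor(quotas[c])) for c in classes}
    deficit = val_n - sum(counts.values())
    order = sorted(
        classes,
        key=lambda c: (quotas[c] - counts[c], int(np.sum(y == c))),
        reverse=True,
    )
    for c in order[:deficit]:
        counts[c] += 1
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(y == c)
        perm = rng.permutation(members)
        val_idx.extend(perm[: counts[c]].tolist())
    val = sorted(val_idx)
    train = sorted(set(range(n)) - set(val))
    return SplitResult(tuple(train), tuple(val))


def percentage(count: int, total: int) -> float:
    """count/total as a percentage, rounded half-away-from-zero to 1 decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    x = 100.0 * count / total
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


def categorical_balance_test(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Between-group balance test for one categorical characteristic.

    Returns the Pearson chi-square statistic (no continuity correction,
    df = c - 1) and its upper-tail p-value.  For a 2x2 table with any expected
    count below 5 the p-value is replaced by Fisher's exact test (the
    statistic reported stays the Pearson one).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x c contingency table")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("degenerate margin: a row or column sums to zero")
    res = stats.chi2_contingency(t, correction=False)
    statistic, p_value, expected = float(res[0]), float(res[1]), res[3]
    if t.shape == (2, 2) and np.any(expected < 5):
        p_value = float(stats.fisher_exact(t.astype(int))[1])
    return statistic, p_value


_CHARACTERISTICS: tuple[tuple[str, ...], ...] = (
    ("age_group", "lt40", "40_69", "ge70"),
    ("sex", "male", "female"),
    ("histology", "intestinal", "diffuse"),
    ("clinical_setting", "initially_metastatic", "recurrent"),
    ("prior_gastrectomy", "yes", "no"),
    ("prior_trastuzumab", "yes", "no"),
    ("first_line_duration", "lt3", "mid", "ge6"),
)


def _level_of(p: Patient, characteristic: str) -> str:
    if characteristic == "age_group":
        return "lt40" if p.age_years < 40 else ("ge70" if p.age_years >= 70 else "40_69")
    if characteristic == "sex":
        return p.sex
    if characteristic == "histology":
        return "diffuse" if p.histology == "mixed" else p.histology
    if characteristic == "clinical_setting":
        return p.clinical_setting
    if characteristic == "prior_gastrectomy":
        return "yes" if p.prior_gastrectomy else "no"
    if characteristic == "prior_trastuzumab":
        return "yes" if p.prior_trastuzumab else "no"
    if characteristic == "first_line_duration":
        return p.first_line_duration
    raise KeyError(characteristic)


@dataclass
class BaselineTable:
    """Baseline-characteristics table for one or two cohort subsets."""

    table: pd.DataFrame
    group_names: tuple[str, ...]
    age_summaries: tuple[str, ...]  # "median (min-max)" per group

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [
            f"Baseline characteristics ({' vs '.join(self.group_names)})",
            *(
                f"  median age, {g}: {s}"
                for g, s in zip(self.group_names, self.age_summaries)
            ),
            self.table.to_string(index=False),
        ]
        return "\n".join(lines)


def summarize_cohort(
    subsets: Sequence[Sequence[Patient]],
    group_names: Sequence[str] | None = None,
) -> BaselineTable:
    """Counts and one-decimal percentages per characteristic, Table-1 style.

    With two subsets a balance-test p-value is attached per characteristic
    (chi-square over the full level contingency, Fisher fallback for sparse
    2x2 tables).
    """
    if not 1 <= len(subsets) <= 2 or any(len(s) == 0 for s in subsets):
        raise ValueError("expected one or two non-empty subsets")
    names = tuple(group_names) if group_names else tuple(
        f"group_{i + 1}" for i in range(len(subsets))
    )
    rows = []
    for spec in _CHARACTERISTICS:
        characteristic, levels = spec[0], spec[1:]
        counts = [
            {lvl: sum(1 for p in s if _level_of(p, characteristic) == lvl) for lvl in levels}
            for s in subsets
        ]
        p_value = None
        if len(subsets) == 2:
            tab = np.array([[counts[g][lvl] for lvl in levels] for g in range(2)])
            keep = tab.sum(axis=0) > 0
            if keep.sum() >= 2:
                p_value = categorical_balance_test(tab[:, keep])[1]
        for lvl in levels:
            row: dict[str, object] = {"characteristic": characteristic, "level": lvl}
            for g, (name, s) in enumerate(zip(names, subsets)):
                row[f"n_{name}"] = counts[g][lvl]
                row[f"pct_{name}"] = percentage(counts[g][lvl], len(s))
            if len(subsets) == 2:
                row["p_value"] = p_value
            rows.append(row)
    ages = tuple(
        f"{np.median([p.age_years for p in s]):g} "
        f"({min(p.age_years for p in s)}-{max(p.age_years for p in s)})"
        for s in subsets
    )
    return BaselineTable(pd.DataFrame(rows), names, ages)
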