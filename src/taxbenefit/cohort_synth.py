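"""Synthetic advanced-gastric-cancer (AGC) cohorts for second-line paclitaxel studies.

The real study cohort is not public, so this module generates cohorts with the
statistical structure the downstream analysis assumes: binary clinical
covariates, per-patient sets of pathogenic variants drawn from a fixed panel
(73 SNVs + 29 CNVs across 87 genes by default), and PFS/OS survival times with
administrative censoring.  Outcomes are driven by a planted "benefit score"
that acts multiplicatively on the exponential survival medians
(accelerated-time form), so classifiers downstream have a recoverable signal
whose shape — additive, or purely interaction-based — is under the caller's
control via :class:`EffectSpec`.

Baseline medians default to 2.70 months (PFS) and 13.28 months (OS), the
calibration anchors of the simulated disease setting.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CLINICAL_FEATURE_NAMES",
    "DEFAULT_CLINICAL_PREVALENCES",
    "CohortConfig",
    "EffectSpec",
    "Patient",
    "VariantPanel",
    "build_panel",
    "default_variant_prevalences",
    "benefit_score",
    "sample_variant_profile",
    "sample_survival",
    "generate_cohort",
    "write_patient_csv",
    "write_variant_csv",
    "interaction_effect_config",
    "additive_effect_config",
]

LN2 = math.log(2.0)

#: Canonical order of the binary clinical model features (matches the feature
#: encoder in :mod:`taxbenefit.features`).
CLINICAL_FEATURE_NAMES = (
    "young_onset",
    "male",
    "intestinal_histology",
    "prior_trastuzumab",
    "duration_lt3",
    "duration_ge6",
)

#: Marginal prevalences of the generated covariates.  Taken from the pooled
#: baseline-characteristics table of the study population (n=288): 65.6% male,
#: 16.7% prior trastuzumab, 82.3% of ages outside the young-onset band, etc.
DEFAULT_CLINICAL_PREVALENCES: Mapping[str, float] = {
    "young_onset": 13 / 288,        # age < 40 years
    "age_ge70": 88 / 288,           # shapes the age distribution only
    "male": 189 / 288,
    "intestinal_histology": 185 / 288,
    "initially_metastatic": 192 / 288,
    "prior_gastrectomy": 146 / 288,
    "prior_trastuzumab": 48 / 288,
    "duration_lt3": 73 / 288,
    "duration_ge6": 106 / 288,
}


def default_variant_prevalences(n_variants: int) -> np.ndarray:
    """Per-variant carrier probabilities, geometrically decaying 0.40 -> 0.01.

    Real pathogenic-variant panels are strongly skewed (a few hot genes such
    as TP53 carried by a large fraction of patients, a long tail of rare
    alterations); a geometric decay reproduces that shape and gives a mean
    mutation burden of roughly 11 variants per patient for a 102-variant panel.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    if n_variants == 1:
        return np.array([0.4])
    return np.geomspace(0.4, 0.01, n_variants)


@dataclass(frozen=True)
class EffectSpec:
    """Planted association between covariates and the latent benefit score.

    The score for a patient is

        beta0 + beta_clinical . x  +  sum_{v in S} beta_variant[v]
              + sum_{(j,k) in gamma_pairs, {j,k} subset S} gamma_pairs[(j,k)]

    where ``x`` is the binary clinical vector (order of
    :data:`CLINICAL_FEATURE_NAMES`) and ``S`` the patient's variant index set.
    ``beta_variant_os`` drives an analogous score for the post-progression
    part of overall survival.  An all-zero spec yields outcomes independent of
    every covariate.
    """

    beta0: float = 0.0
    beta_clinical: tuple[float, ...] = (0.0,) * len(CLINICAL_FEATURE_NAMES)
    beta_variant: tuple[float, ...] = ()
    gamma_pairs: tuple[tuple[int, int, float], ...] = ()
    beta_variant_os: tuple[float, ...] = ()

    @classmethod
    def null(cls, n_variants: int) -> "EffectSpec":
        """Spec with every coefficient zero (no covariate-outcome association)."""
        zeros = (0.0,) * n_variants
        return cls(beta_variant=zeros, beta_variant_os=zeros)

    def validate(self, n_variants: int) -> None:
        if len(self.beta_clinical) != len(CLINICAL_FEATURE_NAMES):
            raise ValueError(
                f"beta_clinical must have length {len(CLINICAL_FEATURE_NAMES)}"
            )
        for arr, name in ((self.beta_variant, "beta_variant"),
                          (self.beta_variant_os, "beta_variant_os")):
            if arr and len(arr) != n_variants:
                raise ValueError(f"{name} must have length {n_variants} (panel size)")
        for j, k, _ in self.gamma_pairs:
            for idx in (j, k):
                if not 0 <= idx < n_variants:
                    raise ValueError(
                        f"gamma_pairs references unknown variant index {idx}"
                    )


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to draw one synthetic cohort deterministically."""

    n_patients: int
    n_genes: int = 87
    n_snv: int = 73
    n_cnv: int = 29
    variant_prevalences: tuple[float, ...] | None = None
    clinical_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_PREVALENCES)
    )
    effect_spec: EffectSpec | None = None
    baseline_pfs_median_months: float = 2.70
    baseline_os_median_months: float = 13.28
    censoring_rate: float = 0.2
    seed: int = 0

    @property
    def n_variants(self) -> int:
        return self.n_snv + self.n_cnv

    def resolved_prevalences(self) -> np.ndarray:
        if self.variant_prevalences is None:
            return default_variant_prevalences(self.n_variants)
        return np.asarray(self.variant_prevalences, dtype=float)

    def resolved_effect_spec(self) -> EffectSpec:
        return self.effect_spec if self.effect_spec is not None else EffectSpec.null(
            self.n_variants
        )

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name in ("n_genes", "n_snv", "n_cnv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        prev = self.resolved_prevalences()
        if prev.shape != (self.n_variants,):
            raise ValueError(
                f"variant_prevalences must have length {self.n_variants}"
            )
        if np.any((prev <= 0) | (prev >= 1)):
            raise ValueError("variant prevalences must lie strictly in (0, 1)")
        for key, p in self.clinical_prevalences.items():
            if not 0 < p < 1:
                raise ValueError(f"clinical prevalence {key!r}={p} not in (0, 1)")
        if self.baseline_pfs_median_months <= 0 or self.baseline_os_median_months <= 0:
            raise ValueError("baseline survival medians must be positive")
        if self.baseline_os_median_months <= self.baseline_pfs_median_months:
            raise ValueError("baseline OS median must exceed baseline PFS median")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        self.resolved_effect_spec().validate(self.n_variants)


@dataclass(frozen=True)
class VariantPanel:
    """The fixed variant panel: identifiers, host genes and SNV/CNV classes."""

    variant_ids: tuple[str, ...]
    genes: tuple[str, ...]
    classes: tuple[str, ...]  # "SNV" or "CNV", parallel to variant_ids

    def __len__(self) -> int:
        return len(self.variant_ids)


def build_panel(config: CohortConfig) -> VariantPanel:
    """Assign the n_snv + n_cnv variants to genes round-robin.

    With the 102-variant / 87-gene default the first 15 genes carry both an
    SNV and a CNV, mimicking real panels where hot genes accumulate several
    alteration types.
    """
    gene_names = [f"GENE{g + 1:03d}" for g in range(config.n_genes)]
    ids, genes, classes = [], [], []
    for v in range(config.n_variants):
        gene = gene_names[v % config.n_genes]
        cls = "SNV" if v < config.n_snv else "CNV"
        ids.append(f"{gene}_{cls}")
        genes.append(gene)
        classes.append(cls)
    if len(set(ids)) != len(ids):
        raise ValueError(
            "panel shape yields duplicate variant identifiers; "
            "need n_snv <= n_genes and n_cnv <= n_genes"
        )
    return VariantPanel(tuple(ids), tuple(genes), tuple(classes))


@dataclass
class Patient:
    """One simulated subject: covariates, variant set, survival outcomes."""

    patient_id: str
    age_years: int
    sex: str                      # "male" | "female"
    histology: str                # "intestinal" | "diffuse"
    clinical_setting: str         # "initially_metastatic" | "recurrent"
    prior_gastrectomy: int
    prior_trastuzumab: int
    first_line_duration: str      # "lt3" | "mid" | "ge6"
    variant_ids: frozenset[str]
    pfs_months: float
    pfs_event: int
    os_months: float
    os_event: int

    def __post_init__(self) -> None:
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be non-negative")
        if self.pfs_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValueError("event flags must be 0 or 1")
        if self.pfs_event and self.os_event and self.os_months < self.pfs_months:
            raise ValueError("observed OS cannot precede observed PFS")


def benefit_score(
    clinical_vec: Sequence[float],
    variant_indices: Iterable[int],
    spec: EffectSpec,
) -> float:
    """Latent benefit score for one patient (deterministic)."""
    variant_set = frozenset(int(v) for v in variant_indices)
    n_variants = len(spec.beta_variant)
    for v in variant_set:
        if v < 0 or (spec.beta_variant and v >= n_variants):
            raise IndexError(f"unknown variant index {v}")
    score = spec.beta0
    score += float(np.dot(spec.beta_clinical, np.asarray(clinical_vec, dtype=float)))
    if spec.beta_variant:
        score += sum(spec.beta_variant[v] for v in variant_set)
    for j, k, gamma in spec.gamma_pairs:
        if j in variant_set and k in variant_set:
            score += gamma
    return score


def _os_score(variant_indices: Iterable[int], spec: EffectSpec) -> float:
    if not spec.beta_variant_os:
        return 0.0
    return sum(spec.beta_variant_os[v] for v in frozenset(variant_indices))


def sample_variant_profile(config: CohortConfig, rng: np.random.Generator) -> frozenset[int]:
    """Draw one patient's variant index set, each variant independently."""
    prev = config.resolved_prevalences()
    return frozenset(np.flatnonzero(rng.random(len(prev)) < prev).tolist())


@lru_cache(maxsize=64)
def _post_progression_median(pfs_median: float, os_median: float) -> float:
    """Baseline median of the post-progression exponential.

    OS is the sum PFS + PP of two independent exponentials (hypoexponential),
    whose median is *not* the sum of the two medians.  The PP median is
    therefore calibrated so that the marginal OS median of a baseline
    (score 0) patient equals ``os_median`` exactly.
    """
    l1 = LN2 / pfs_median

    def os_survival(l2: float) -> float:
        if abs(l1 - l2) < 1e-12:
            return math.exp(-l1 * os_median) * (1 + l1 * os_median)
        return (l2 * math.exp(-l1 * os_median) - l1 * math.exp(-l2 * os_median)) / (
            l2 - l1
        )

    return brentq(lambda m2: os_survival(LN2 / m2) - 0.5, 1e-6, 1e6)


@lru_cache(maxsize=64)
def _censoring_horizon(censoring_rate: float, os_median: float) -> float:
    """Upper end c_max of the Uniform(0, c_max) administrative censoring time.

    Chosen so a baseline (score 0) patient is censored with probability
    ``censoring_rate``: for OS ~ Exp(rate lam) and C ~ U(0, c),
    P(OS > C) = (1 - exp(-lam c)) / (lam c); solve for c.
    """
    lam = LN2 / os_median
    target = censoring_rate

    def f(x: float) -> float:
        return (1.0 - math.exp(-x)) / x - target

    x = brentq(f, 1e-9, 1e6)
    return x / lam


def sample_survival(
    score: float,
    score_os: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[float, int, float, int]:
    """Draw (pfs_months, pfs_event, os_months, os_event) for one patient.

    PFS is exponential with median ``baseline_pfs_median * exp(score)``; OS is
    PFS plus an independent exponential post-progression time whose baseline
    median is calibrated so the marginal OS median equals
    ``baseline_os_median`` (see :func:`_post_progression_median`), scaled by
    ``exp(score_os)``.  A single administrative censoring time truncates both
    endpoints consistently.
    """
    if config.baseline_pfs_median_months <= 0 or config.baseline_os_median_months <= 0:
        raise ValueError("baseline survival medians must be positive")
    pfs_median = config.baseline_pfs_median_months * math.exp(score)
    pp_median = _post_progression_median(
        config.baseline_pfs_median_months, config.baseline_os_median_months
    ) * math.exp(score_os)
    pfs = rng.exponential(pfs_median / LN2)
    os_time = pfs + rng.exponential(pp_median / LN2)
    if config.censoring_rate <= 0:
        # one rng draw regardless, so coefficient changes never shift the stream
        rng.random()
        return pfs, 1, os_time, 1
    c_max = _censoring_horizon(config.censoring_rate, config.baseline_os_median_months)
    c = rng.uniform(0.0, c_max)
    if c < pfs:
        return c, 0, c, 0
    if c < os_time:
        return pfs, 1, c, 0
    return pfs, 1, os_time, 1


def _draw_age(prevs: Mapping[str, float], rng: np.random.Generator) -> int:
    """Piecewise-uniform age with the configured young-onset and >=70 mass."""
    u = rng.random()
    if u < prevs["young_onset"]:
        return int(rng.integers(25, 40))
    if u < prevs["young_onset"] + prevs["age_ge70"]:
        return int(rng.integers(70, 92))
    return int(rng.integers(40, 70))


def clinical_feature_vector(patient: "Patient", age_cutoff_young: int = 40) -> np.ndarray:
    """Binary model-feature vector in :data:`CLINICAL_FEATURE_NAMES` order."""
    return np.array(
        [
            1.0 if patient.age_years < age_cutoff_young else 0.0,
            1.0 if patient.sex == "male" else 0.0,
            1.0 if patient.histology == "intestinal" else 0.0,
            float(patient.prior_trastuzumab),
            1.0 if patient.first_line_duration == "lt3" else 0.0,
            1.0 if patient.first_line_duration == "ge6" else 0.0,
        ]
    )


def generate_cohort(config: CohortConfig) -> list[Patient]:
    """Generate ``config.n_patients`` patients; identical seed => identical cohort."""
    config.validate()
    panel = build_panel(config)
    spec = config.resolved_effect_spec()
    prevs = config.clinical_prevalences
    rng = np.random.default_rng(config.seed)
    patients: list[Patient] = []
    for i in range(config.n_patients):
        age = _draw_age(prevs, rng)
        sex = "male" if rng.random() < prevs["male"] else "female"
        histology = (
            "intestinal" if rng.random() < prevs["intestinal_histology"] else "diffuse"
        )
        setting = (
            "initially_metastatic"
            if rng.random() < prevs["initially_metastatic"]
            else "recurrent"
        )
        gastrectomy = int(rng.random() < prevs["prior_gastrectomy"])
        trastuzumab = int(rng.random() < prevs["prior_trastuzumab"])
        u = rng.random()
        if u < prevs["duration_lt3"]:
            duration = "lt3"
        elif u < prevs["duration_lt3"] + prevs["duration_ge6"]:
            duration = "ge6"
        else:
            duration = "mid"
        variant_idx = sample_variant_profile(config, rng)
        clin_vec = np.array(
            [
                1.0 if age < 40 else 0.0,
                1.0 if sex == "male" else 0.0,
                1.0 if histology == "intestinal" else 0.0,
                float(trastuzumab),
                1.0 if duration == "lt3" else 0.0,
                1.0 if duration == "ge6" else 0.0,
            ]
        )
        score = benefit_score(clin_vec, variant_idx, spec)
        score_os = _os_score(variant_idx, spec)
        pfs, pfs_event, os_time, os_event = sample_survival(score, score_os, config, rng)
        patients.append(
            Patient(
                patient_id=f"P{i + 1:05d}",
                age_years=age,
                sex=sex,
                histology=histology,
                clinical_setting=setting,
                prior_gastrectomy=gastrectomy,
                prior_trastuzumab=trastuzumab,
                first_line_duration=duration,
                variant_ids=frozenset(panel.variant_ids[v] for v in variant_idx),
                pfs_months=pfs,
                pfs_event=pfs_event,
                os_months=os_time,
                os_event=os_event,
            )
        )
    return patients


PATIENT_CSV_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "histology",
    "clinical_setting",
    "prior_gastrectomy",
    "prior_trastuzumab",
    "first_line_duration",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
)

VARIANT_CSV_COLUMNS = ("patient_id", "gene", "variant_id", "variant_class", "pathogenicity")


def write_patient_csv(cohort: Sequence[Patient], path) -> None:
    """One row per patient; survival times serialized with 17 significant digits
    so a write -> load -> write cycle is byte-identical."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENT_CSV_COLUMNS)
        for p in cohort:
            writer.writerow(
                [
                    p.patient_id,
                    p.age_years,
                    p.sex,
                    p.histology,
                    p.clinical_setting,
                    p.prior_gastrectomy,
                    p.prior_trastuzumab,
                    p.first_line_duration,
                    repr(float(p.pfs_months)),
                    p.pfs_event,
                    repr(float(p.os_months)),
                    p.os_event,
                ]
            )


def write_variant_csv(cohort: Sequence[Patient], path) -> None:
    """Long-format variant table; variant identifiers are ``<gene>_<class>``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(VARIANT_CSV_COLUMNS)
        for p in cohort:
            for vid in sorted(p.variant_ids):
                gene, cls = vid.rsplit("_", 1)
                writer.writerow([p.patient_id, gene, vid, cls, "pathogenic"])


# ---------------------------------------------------------------------------
# Canonical planted-signal scenarios
# ---------------------------------------------------------------------------

def interaction_effect_config(
    n_patients: int = 2000,
    seed: int = 0,
    gamma: float = 1.5,
    censoring_rate: float = 0.0,
) -> CohortConfig:
    """Cohort whose benefit signal is purely pairwise-epistatic.

    Eight signal variants (panel indices 0-7) are given prevalence 0.5 and
    joined in a cycle of eight pairs with alternating-sign interaction
    coefficients +/- ``gamma``.  Each signal variant then sits in exactly one
    positive and one negative pair with equal-prevalence partners, so every
    single-variant marginal effect cancels: a main-effects model sees no
    signal, while a model able to represent variant co-occurrence can recover
    it.  All additive variant and clinical coefficients are zero.
    """
    base = CohortConfig(n_patients=n_patients, seed=seed, censoring_rate=censoring_rate)
    prev = base.resolved_prevalences().copy()
    cycle = list(range(8))
    prev[cycle] = 0.5
    pairs = tuple(
        (cycle[i], cycle[(i + 1) % len(cycle)], gamma if i % 2 == 0 else -gamma)
        for i in range(len(cycle))
    )
    spec = replace(EffectSpec.null(base.n_variants), gamma_pairs=pairs)
    return replace(
        base, variant_prevalences=tuple(prev.tolist()), effect_spec=spec
    )


def additive_effect_config(
    n_patients: int = 2000,
    seed: int = 0,
    beta: float = 0.8,
    censoring_rate: float = 0.0,
) -> CohortConfig:
    """Cohort with a purely additive variant signal of the same scale.

    Panel indices 0-9 get prevalence 0.5 and alternating main effects
    +/- ``beta``; no interactions.  A linear model is well specified here, so
    it serves as the matched control for the epistatic scenario.
    """
    base = CohortConfig(n_patients=n_patients, seed=seed, censoring_rate=censoring_rate)
    prev = base.resolved_prevalences().copy()
    signal = list(range(10))
    prev[signal] = 0.5
    beta_variant = [0.0] * base.n_variants
    for i, v in enumerate(signal):
        beta_variant[v] = beta if i % 2 == 0 else -beta
    spec = replace(EffectSpec.null(base.n_variants), beta_variant=tuple(beta_variant))
    return replace(
        base, variant_prevalences=tuple(prev.tolist()), effect_spec=spec
    )
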