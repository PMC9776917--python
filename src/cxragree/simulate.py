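"""Synthetic multi-rater, two-round annotation generator.

Emulates the design of a reader study in which six radiologists (two each
at novice, intermediate and experienced level) annotate 100 chest X-ray
cases twice, with a wash-out period between rounds.  A latent truth — a set
of true leaf findings per case — is drawn from per-finding prevalences;
each simulated rater then reads every case with four behavioral dials:

sensitivity
    probability of detecting each true finding.
specificity
    per-finding true-negative probability; false positives on absent leaf
    findings arise at rate 1 − specificity.
granularity
    probability of reporting a detected finding at its true leaf label;
    otherwise an ancestor within the same top-level branch is reported,
    chosen uniformly along the path to the subtree root.  Low granularity
    reproduces the documented tendency of less experienced readers to fall
    back on broad labels (reporting an infection as an infiltrate, or as
    decreased translucency).
over_annotation_rate
    Poisson mean of spurious extra labels per case, drawn from the
    annotatable labels with prevalence-smoothed weights; emulates the
    over-annotating behavior reported for intermediate readers.
rescore_flip
    probability that a label's used/not-used decision independently flips
    in the second round (test–retest noise).

'Normal' is never simulated directly: a rater reports it exactly when they
report nothing else on a case, in either round.  Every positive label is
emitted as duplicate frontal and lateral records with dummy bounding boxes,
so the case-level collapse step is exercised.

The numeric defaults in :func:`default_study_config` are illustrative: the
real per-level operating points are unknowable, so they are chosen to land
the expected frequency table in the study's reported order of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ontology import LabelScheme, fig1_lung_scheme
from .store import AnnotationRecord

__all__ = [
    "RaterProfile",
    "TruthTable",
    "simulate",
    "default_study_config",
    "expected_label_count",
]

NORMAL = "Normal"
_DUMMY_BBOX = (10.0, 10.0, 50.0, 50.0)
_SMOOTHING = 0.005  # additive prevalence smoothing for spurious-label weights


@dataclass(frozen=True)
class RaterProfile:
    """Behavioral parameters of one simulated rater."""

    rater_id: str
    experience: str  # novice | intermediate | experienced
    sensitivity: float
    specificity: float
    granularity: float
    over_annotation_rate: float = 0.0
    rescore_flip: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "granularity", "rescore_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.over_annotation_rate < 0:
            raise ValueError("over_annotation_rate must be >= 0")
        if self.experience not in ("novice", "intermediate", "experienced"):
            raise ValueError(f"unknown experience level {self.experience!r}")


@dataclass
class TruthTable:
    """Latent per-case true leaf findings and the prevalences used."""

    cases: list[str]
    findings: list[set[str]]
    prevalences: dict[str, float]

    def indicator(self, label: str) -> np.ndarray:
        """0/1 vector over cases: label among the true findings.

        'Normal' is true exactly on cases with an empty finding set.
        """
        if label == NORMAL:
            return np.array([0 if f else 1 for f in self.findings], dtype=np.uint8)
        return np.array([1 if label in f else 0 for f in self.findings], dtype=np.uint8)


def _over_weights(scheme: LabelScheme, prevalences: dict[str, float]) -> dict[str, float]:
    """Prevalence-smoothed spurious-label weights over annotatable labels."""
    weights = {}
    for lab in scheme.labels:
        if lab == NORMAL:
            continue
        desc_leaves = [d for d in scheme.descendants(lab) if scheme.is_leaf(d)]
        if desc_leaves:
            base = float(np.mean([prevalences.get(d, 0.0) for d in desc_leaves]))
        else:
            base = prevalences.get(lab, 0.0)
        weights[lab] = base + _SMOOTHING
    return weights


def simulate(
    scheme: LabelScheme,
    profiles: list[RaterProfile],
    prevalences: dict[str, float],
    n_cases: int,
    rounds: int = 2,
    seed: int | None = 0,
) -> tuple[list[AnnotationRecord], TruthTable]:
    """Generate annotation records for all raters, cases and rounds.

    Deterministic given the seed: the same call yields byte-identical
    records.  Raises on empty profiles, on prevalences for unknown or
    non-leaf labels, and on a prevalence supplied for 'Normal' (which is
    derived, never drawn).
    """
    if not profiles:
        raise ValueError("need at least one rater profile")
    if rounds not in (1, 2):
        raise ValueError("rounds must be 1 or 2")
    leaves = set(scheme.leaves())
    for lab, p in prevalences.items():
        if lab == NORMAL:
            raise ValueError("'Normal' is derived from an empty finding set; "
                             "do not assign it a prevalence")
        if lab not in leaves:
            raise ValueError(f"prevalence given for unknown leaf {lab!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {lab!r} outside [0, 1]")

    rng = np.random.default_rng(seed)
    cases = [f"case_{i + 1:03d}" for i in range(n_cases)]
    finding_leaves = [lab for lab in scheme.labels
                      if lab in prevalences and lab != NORMAL]

    truth_sets: list[set[str]] = []
    for _ in cases:
        truth_sets.append(
            {f for f in finding_leaves if rng.random() < prevalences[f]}
        )
    truth = TruthTable(cases=cases, findings=truth_sets, prevalences=dict(prevalences))

    weights = _over_weights(scheme, prevalences)
    weight_labels = list(weights)
    wvec = np.array([weights[w] for w in weight_labels])
    wvec = wvec / wvec.sum()
    flippable = [lab for lab in scheme.labels if lab != NORMAL]

    records: list[AnnotationRecord] = []
    for profile in profiles:
        for i, case in enumerate(cases):
            reported: set[str] = set()
            # detection of true findings, at leaf or ancestor level
            for f in (lab for lab in finding_leaves if lab in truth_sets[i]):
                if rng.random() >= profile.sensitivity:
                    continue
                ancestors = scheme.ancestors(f)
                if not ancestors or rng.random() < profile.granularity:
                    reported.add(f)
                else:
                    reported.add(ancestors[rng.integers(0, len(ancestors))])
            # false positives on absent leaf findings
            for f in finding_leaves:
                if f not in truth_sets[i] and rng.random() > profile.specificity:
                    reported.add(f)
            # over-annotation: spurious labels across the whole scheme
            k = rng.poisson(profile.over_annotation_rate)
            for _ in range(k):
                reported.add(weight_labels[rng.choice(len(weight_labels), p=wvec)])

            per_round = [reported]
            if rounds == 2:
                second = {
                    lab
                    for lab in flippable
                    if (lab in reported) != (rng.random() < profile.rescore_flip)
                }
                per_round.append(second)

            for rnd, labels in enumerate(per_round, start=1):
                emitted = labels if labels else {NORMAL}
                for lab in (l for l in scheme.labels if l in emitted):
                    for projection in ("frontal", "lateral"):
                        records.append(
                            AnnotationRecord(
                                case_id=case,
                                rater_id=profile.rater_id,
                                round=rnd,
                                projection=projection,
                                label=lab,
                                bbox=_DUMMY_BBOX,
                            )
                        )
    return records, truth


def default_study_config() -> tuple[list[RaterProfile], dict[str, float]]:
    """Profiles and prevalences emulating the six-reader study.

    Two raters per experience level; granularity rises and over-annotation
    peaks at intermediate level, matching the reported behavioral contrast.
    Prevalences are set so expected per-rater label counts over 100 cases
    fall in the order of magnitude of the study's frequency table (pleural
    effusion in the tens, tuberculosis at most one or two).
    """
    profiles = [
        RaterProfile("Novice 1", "novice", 0.65, 0.995, 0.30, 0.3, 0.06),
        RaterProfile("Novice 2", "novice", 0.70, 0.995, 0.45, 0.2, 0.05),
        RaterProfile("Intermediate 1", "intermediate", 0.80, 0.995, 0.65, 0.8, 0.05),
        RaterProfile("Intermediate 2", "intermediate", 0.80, 0.995, 0.70, 1.0, 0.05),
        RaterProfile("Experienced 1", "experienced", 0.85, 0.997, 0.95, 0.2, 0.04),
        RaterProfile("Experienced 2", "experienced", 0.85, 0.997, 0.95, 0.2, 0.04),
    ]
    prevalences = {
        "Pneumothorax": 0.10,
        "Cyst/Bullae": 0.03,
        "Emphysema": 0.02,
        "Infection": 0.20,
        "Abscess": 0.01,
        "Tuberculosis": 0.01,
        "Malignant": 0.06,
        "Fibrosis": 0.02,
        "Chronic Lung Changes": 0.03,
        "Stasis/Edema": 0.09,
        "Costophrenic Angle Blunting": 0.15,
        "Pleural Effusion": 0.35,
        "Atelectasis": 0.25,
        "Pleural Thickening/Changes": 0.05,
        "Former Operation in Lung Tissue": 0.03,
    }
    return profiles, prevalences


def expected_label_count(
    scheme: LabelScheme,
    profile: RaterProfile,
    prevalences: dict[str, float],
    label: str,
    n_cases: int,
) -> float:
    """Analytic expected positive-case count for one *leaf* label.

    Combines the detection, false-positive and over-annotation routes;
    contributions from other findings reported at ancestor level do not
    reach a leaf, so the expression is exact for leaves.
    """
    if not scheme.is_leaf(label) or label == NORMAL:
        raise ValueError("expected count is closed-form for non-Normal leaves only")
    p = prevalences.get(label, 0.0)
    g_eff = profile.granularity if scheme.ancestors(label) else 1.0
    base = p * profile.sensitivity * g_eff + (1.0 - p) * (1.0 - profile.specificity)
    weights = _over_weights(scheme, prevalences)
    w_norm = weights[label] / sum(weights.values())
    p_over = 1.0 - math.exp(-profile.over_annotation_rate * w_norm)
    return n_cases * (1.0 - (1.0 - base) * (1.0 - p_over))
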