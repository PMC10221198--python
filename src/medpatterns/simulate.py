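"""Synthetic two-phase binary medication panels from a latent-class truth.

The generator draws subjects from a fully specified latent class / latent
transition model: a phase-1 class from the prevalence vector pi, a phase-2
class from the row of the transition matrix tau belonging to the phase-1
class, and item indicators as independent Bernoulli draws from the
phase-specific class profile rho.  Optional comorbidity flags are Bernoulli
draws whose probability depends only on the subject's latent class, which is
what makes class membership and self-reported disease associated downstream.

A named default scenario emulates a COPDGene-like two-phase cohort: 5564
subjects, 27 medication categories, four classes (low medication;
HTN/CVD + Hychol; HTN/CVD + T2D + Hychol; Hychol) with published class sizes,
the published signature item-response probabilities, a graded per-class
background for unlisted items, and the published cross-phase transition
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import IndicatorMatrix
from .errors import ValidationError

#: 27 chronic-disease medication categories (COPD and cancer treatments are
#: deliberately absent from the panel).
MEDICATION_CATEGORIES: tuple[str, ...] = (
    "ACEi",
    "ARB",
    "beta_blocker",
    "calcium_channel_blocker",
    "diuretic",
    "antiplatelet",
    "anticoagulant",
    "nitrate",
    "antiarrhythmic",
    "statin",
    "other_lipid_lowering",
    "biguanide",
    "sulfonylurea",
    "insulin",
    "other_diabetes_med",
    "thyroid_hormone",
    "proton_pump_inhibitor",
    "h2_blocker",
    "ssri_snri",
    "other_antidepressant",
    "anxiolytic",
    "anticonvulsant",
    "opioid_analgesic",
    "nsaid",
    "systemic_corticosteroid",
    "bisphosphonate",
    "antihistamine",
)


def _check_prob(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if (arr < 0).any() or (arr > 1).any() or not np.isfinite(arr).all():
        raise ValidationError(f"{name} entries must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class GenerativeTruth:
    """Fully specified generating model for a two-phase binary panel."""

    n_subjects: int
    class_prevalence: np.ndarray  # pi, (K,)
    item_response_p1: np.ndarray  # rho1, (K, J)
    item_response_p2: np.ndarray  # rho2, (K, J)
    transition_matrix: np.ndarray  # tau, (K, K) row-stochastic
    comorbidity_link: Mapping[str, np.ndarray] = field(default_factory=dict)
    item_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be a positive integer")
        pi = _check_prob("class_prevalence", self.class_prevalence)
        if pi.ndim != 1:
            raise ValidationError("class_prevalence must be a vector")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"class_prevalence must sum to 1 within 1e-12 (got {pi.sum()!r})"
            )
        k = pi.shape[0]
        rho1 = _check_prob("item_response_p1", self.item_response_p1)
        rho2 = _check_prob("item_response_p2", self.item_response_p2)
        if rho1.ndim != 2 or rho1.shape[0] != k:
            raise ValidationError(f"item_response_p1 must be {k} x J")
        if rho2.shape != rho1.shape:
            raise ValidationError("item_response_p2 must match item_response_p1")
        tau = _check_prob("transition_matrix", self.transition_matrix)
        if tau.shape != (k, k):
            raise ValidationError(f"transition_matrix must be {k} x {k}")
        if np.abs(tau.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValidationError(
                "transition_matrix rows must each sum to 1 within 1e-12"
            )
        names = self.item_names
        if names is None:
            names = tuple(f"item_{j + 1:02d}" for j in range(rho1.shape[1]))
        names = tuple(str(n) for n in names)
        if len(names) != rho1.shape[1]:
            raise ValidationError(
                f"item_names has {len(names)} entries for J={rho1.shape[1]} items"
            )
        link = {
            str(m): _check_prob(f"comorbidity_link[{m!r}]", v)
            for m, v in dict(self.comorbidity_link).items()
        }
        for m, v in link.items():
            if v.shape != (k,):
                raise ValidationError(
                    f"comorbidity_link[{m!r}] must have one probability per class"
                )
        object.__setattr__(self, "class_prevalence", pi)
        object.__setattr__(self, "item_response_p1", rho1)
        object.__setattr__(self, "item_response_p2", rho2)
        object.__setattr__(self, "transition_matrix", tau)
        object.__setattr__(self, "item_names", names)
        object.__setattr__(self, "comorbidity_link", link)

    @property
    def n_classes(self) -> int:
        return int(self.class_prevalence.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.item_response_p1.shape[1])


def _subject_ids(n: int) -> np.ndarray:
    return np.array([f"S{i + 1:06d}" for i in range(n)])


def _draw_items(
    rng: np.random.Generator, rho: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    n = classes.shape[0]
    return (rng.random((n, rho.shape[1])) < rho[classes]).astype(np.int8)


def _draw_classes(
    rng: np.random.Generator, probs: np.ndarray, n: int
) -> np.ndarray:
    return rng.choice(probs.shape[0], size=n, p=probs)


def generate_cross_sectional(
    truth: GenerativeTruth, *, phase: int = 1
) -> tuple[IndicatorMatrix, np.ndarray]:
    """Draw one phase of data: class c ~ pi, then item j ~ Bernoulli(rho_cj).

    Returns the indicator matrix and the true class labels.  The stream is a
    deterministic function of ``truth.seed`` and ``phase``.
    """
    if phase not in (1, 2):
        raise ValidationError("phase must be 1 or 2")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 10 + phase]))
    rho = truth.item_response_p1 if phase == 1 else truth.item_response_p2
    classes = _draw_classes(rng, truth.class_prevalence, truth.n_subjects)
    values = _draw_items(rng, rho, classes)
    data = IndicatorMatrix(_subject_ids(truth.n_subjects), truth.item_names, values)
    return data, classes


def generate_longitudinal(
    truth: GenerativeTruth,
) -> tuple[IndicatorMatrix, IndicatorMatrix, np.ndarray, np.ndarray]:
    """Draw the two-phase panel for one cohort of subjects.

    Phase-1 class ~ pi; phase-2 class ~ tau[phase-1 class, :]; items are
    drawn from the phase-specific rho.  Subject identifiers are identical
    and aligned across the two matrices.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 20]))
    n, k = truth.n_subjects, truth.n_classes
    c1 = _draw_classes(rng, truth.class_prevalence, n)
    c2 = np.empty(n, dtype=np.int64)
    for c in range(k):
        idx = np.flatnonzero(c1 == c)
        if idx.size:
            c2[idx] = _draw_classes(rng, truth.transition_matrix[c], idx.size)
    y1 = _draw_items(rng, truth.item_response_p1, c1)
    y2 = _draw_items(rng, truth.item_response_p2, c2)
    ids = _subject_ids(n)
    return (
        IndicatorMatrix(ids, truth.item_names, y1),
        IndicatorMatrix(ids, truth.item_names, y2),
        c1,
        c2,
    )


def generate_comorbidity_flags(
    true_classes: np.ndarray,
    comorbidity_link: Mapping[str, np.ndarray],
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw 0/1 self-reported comorbidity flags given latent classes.

    Flag for subject i and comorbidity m ~ Bernoulli(link_m[class_i]); one
    column per comorbidity.
    """
    classes = np.asarray(true_classes)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 30]))
    cols = {}
    for m, link in comorbidity_link.items():
        link = _check_prob(f"comorbidity_link[{m!r}]", link)
        if classes.max(initial=0) >= link.shape[0]:
            raise ValidationError(
                f"comorbidity_link[{m!r}] has {link.shape[0]} entries but class "
                f"labels reach {int(classes.max())}"
            )
        cols[str(m)] = (rng.random(classes.shape[0]) < link[classes]).astype(np.int8)
    return pd.DataFrame(cols)


def copdgene_like_truth(
    n_subjects: int = 5564, seed: int = 0
) -> GenerativeTruth:
    """The default COPDGene-like two-phase scenario.

    Four classes per phase (in canonical descending-prevalence order at
    phase 1): LC0 low medication, LC1 HTN/CVD + Hychol predominant,
    LC2 HTN/CVD + T2D + Hychol predominant, LC3 Hychol predominant — note the
    Hychol class (index 3) is the second largest.  Signature item-response
    probabilities are set per phase; unlisted items sit at a small per-class
    background probability, graded by the class's overall medication burden
    and kept below the 0.06 low-medication floor.  The transition matrix
    holds the published cross-phase row percentages, row-normalized.
    """
    j = len(MEDICATION_CATEGORIES)
    idx = {name: i for i, name in enumerate(MEDICATION_CATEGORIES)}
    pi = np.array([0.5640, 0.1240, 0.0460, 0.2660])
    pi = pi / pi.sum()

    # Per-class background for unlisted items, graded by multimorbidity
    # burden (heavier-medication classes use modestly more of everything).
    # A single flat background would leave the low-medication and the
    # Hychol-only classes differing in one item alone, which makes their
    # prevalences non-identifiable (a two-component mixture on a single
    # Bernoulli item collapses to one Bernoulli).  All backgrounds stay
    # below the 0.06 floor that defines a low-medication profile, except
    # where a signature probability overrides them.
    background = np.array([0.008, 0.05, 0.05, 0.05])
    rho1 = np.tile(background[:, None], (1, j))
    rho1[1, idx["ACEi"]] = 0.9768
    rho1[1, idx["antiplatelet"]] = 0.4052
    rho1[1, idx["diuretic"]] = 0.4131
    rho1[1, idx["statin"]] = 0.5581
    rho1[1, idx["calcium_channel_blocker"]] = 0.15
    rho1[1, idx["beta_blocker"]] = 0.20
    rho1[1, idx["proton_pump_inhibitor"]] = 0.15
    rho1[2, idx["biguanide"]] = 0.7244
    rho1[2, idx["statin"]] = 0.7320
    rho1[2, idx["ACEi"]] = 0.4545
    rho1[2, idx["antiplatelet"]] = 0.4650
    rho1[2, idx["sulfonylurea"]] = 0.4034
    rho1[2, idx["insulin"]] = 0.20
    rho1[2, idx["proton_pump_inhibitor"]] = 0.15
    rho1[3, idx["statin"]] = 0.4721
    rho1[3, idx["other_lipid_lowering"]] = 0.25
    rho1[3, idx["proton_pump_inhibitor"]] = 0.18
    rho1[3, idx["nsaid"]] = 0.15
    rho1[3, idx["antihistamine"]] = 0.12
    rho1[3, idx["ssri_snri"]] = 0.12
    rho1[3, idx["thyroid_hormone"]] = 0.10

    rho2 = np.tile(background[:, None], (1, j))
    rho2[1, idx["ACEi"]] = 0.4115
    rho2[1, idx["antiplatelet"]] = 0.6670
    rho2[1, idx["beta_blocker"]] = 0.9817
    rho2[1, idx["statin"]] = 0.7906
    rho2[1, idx["diuretic"]] = 0.20
    rho2[1, idx["proton_pump_inhibitor"]] = 0.18
    rho2[2, idx["ACEi"]] = 0.5169
    rho2[2, idx["antiplatelet"]] = 0.4046
    rho2[2, idx["biguanide"]] = 0.7411
    rho2[2, idx["statin"]] = 0.6983
    rho2[2, idx["insulin"]] = 0.22
    rho2[2, idx["proton_pump_inhibitor"]] = 0.16
    rho2[3, idx["statin"]] = 0.5043
    rho2[3, idx["other_lipid_lowering"]] = 0.25
    rho2[3, idx["proton_pump_inhibitor"]] = 0.18
    rho2[3, idx["nsaid"]] = 0.15
    rho2[3, idx["antihistamine"]] = 0.12
    rho2[3, idx["ssri_snri"]] = 0.12
    rho2[3, idx["thyroid_hormone"]] = 0.10

    tau = np.array(
        [
            [0.6364, 0.0303, 0.0424, 0.2909],
            [0.1159, 0.2029, 0.1449, 0.5362],
            [0.0941, 0.2275, 0.5255, 0.1529],
            [0.1924, 0.1296, 0.0560, 0.6219],
        ]
    )
    tau = tau / tau.sum(axis=1, keepdims=True)

    # Class-conditional probabilities of self-reported disease, chosen so
    # each flag tracks the diseases its class's medications treat.
    link = {
        "hypertension": np.array([0.15, 0.85, 0.80, 0.30]),
        "diabetes": np.array([0.05, 0.12, 0.85, 0.08]),
        "high_cholesterol": np.array([0.15, 0.65, 0.75, 0.70]),
        "cardiovascular_disease": np.array([0.05, 0.55, 0.45, 0.15]),
    }
    return GenerativeTruth(
        n_subjects=n_subjects,
        class_prevalence=pi,
        item_response_p1=rho1,
        item_response_p2=rho2,
        transition_matrix=tau,
        comorbidity_link=link,
        item_names=MEDICATION_CATEGORIES,
        seed=seed,
    )


def truth_to_dict(truth: GenerativeTruth) -> dict:
    """Plain-python representation, suitable for YAML/JSON provenance."""
    return {
        "n_subjects": int(truth.n_subjects),
        "seed": int(truth.seed),
        "item_names": list(truth.item_names),
        "class_prevalence": truth.class_prevalence.tolist(),
        "item_response_p1": truth.item_response_p1.tolist(),
        "item_response_p2": truth.item_response_p2.tolist(),
        "transition_matrix": truth.transition_matrix.tolist(),
        "comorbidity_link": {
            m: v.tolist() for m, v in truth.comorbidity_link.items()
        },
    }


def truth_from_dict(d: Mapping) -> GenerativeTruth:
    return GenerativeTruth(
        n_subjects=int(d["n_subjects"]),
        class_prevalence=np.asarray(d["class_prevalence"], dtype=float),
        item_response_p1=np.asarray(d["item_response_p1"], dtype=float),
        item_response_p2=np.asarray(d["item_response_p2"], dtype=float),
        transition_matrix=np.asarray(d["transition_matrix"], dtype=float),
        comorbidity_link={
            m: np.asarray(v, dtype=float)
            for m, v in dict(d.get("comorbidity_link", {})).items()
        },
        item_names=tuple(d["item_names"]) if d.get("item_names") else None,
        seed=int(d.get("seed", 0)),
    )
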