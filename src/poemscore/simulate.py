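"""Synthetic vessel-field annotations and simulated rater studies.

No public deposit of the study's sublingual video material exists, so the
whole pipeline is exercised on synthetic clip annotations that emulate
the material's statistical shape: 10-40 vessel segments per clip, flow
categories drawn from a severity-tilted mixture, within-clip
heterogeneity as a second flow regime one severity band away, and rater
noise as one-step ordinal confusion of the per-clip grade.

Severity tilt (``severity`` in [0, 1]) maps to category probabilities
(absent, intermittent, sluggish, continuous) by piecewise-linear
interpolation through four simplex knots::

    severity 0    -> (0.00, 0.00, 0.00, 1.00)   all continuous
    severity 1/3  -> (0.02, 0.08, 0.15, 0.75)
    severity 2/3  -> (0.20, 0.15, 0.15, 0.50)
    severity 1    -> (1.00, 0.00, 0.00, 0.00)   all absent

The knots make the endpoints degenerate, keep the expected stopped
fraction (1 - P(continuous) under the default stopped set) strictly
increasing in severity, and place it exactly at the grading band edges
(0.25, 0.50) at the band knots (1/3, 2/3), so the severity axis sweeps
the whole grading ladder at an even pace.

A fraction ``heterogeneity_level`` of a clip's segments forms a second
flow regime one severity band (1/3) away — toward worse flow for mild
clips, toward better flow for severe ones — with categories drawn
conditional on differing from the main regime's modal category. The
mixing weight therefore directly controls the deviant-segment fraction
that the heterogeneity rule counts, producing the patchy fields the rule
is meant to catch.

All randomness flows through :func:`numpy.random.default_rng` seeded from
the :class:`SimulationSpec`, so an identical spec object reproduces
identical annotations byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DomainError
from .scoring import DEFAULT_CONFIG, assess_clip, compute_poem
from .types import (
    ClipAnnotation,
    ClipAssessment,
    FlowCategory,
    FlowGrade,
    Heterogeneity,
    RatingMatrix,
    ScoringConfig,
    SegmentAnnotation,
    SequenceAssessment,
)

_CATEGORIES = (
    FlowCategory.ABSENT,
    FlowCategory.INTERMITTENT,
    FlowCategory.SLUGGISH,
    FlowCategory.CONTINUOUS,
)

_SEVERITY_KNOTS = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
_PROB_KNOTS = np.array(
    [
        [0.00, 0.00, 0.00, 1.00],
        [0.02, 0.08, 0.15, 0.75],
        [0.20, 0.15, 0.15, 0.50],
        [1.00, 0.00, 0.00, 0.00],
    ]
)

#: Width of one severity band; the heterogeneous sub-regime sits this far away.
SEVERITY_BAND = 1.0 / 3.0

# Ordinal clip states used for rater noise, worst to best.
_CLIP_STATES = (
    (FlowGrade.CRITICALLY_IMPAIRED, Heterogeneity.PRESENT),
    (FlowGrade.IMPAIRED, Heterogeneity.PRESENT),
    (FlowGrade.NORMAL, Heterogeneity.PRESENT),
    (FlowGrade.NORMAL, Heterogeneity.ABSENT),
)
# representative stopped fractions for reconstructed (perturbed) states
_STATE_FRACTIONS = (0.75, 0.375, 0.10, 0.10)


class SimulationSpec(BaseModel):
    """Parameters of a synthetic rater study.

    Defaults mirror the validation design: five sequences of four clips
    scored by 32 raters, severities spanning the full dysfunction range.
    """

    model_config = ConfigDict(frozen=True)

    n_segments_min: int = Field(default=10, ge=6)
    n_segments_max: int = Field(default=40, ge=6)
    severity: float = Field(default=1.0, ge=0, le=1)
    heterogeneity_level: float = Field(default=0.3, ge=0, le=1)
    field_width_um: float = Field(default=1000.0, gt=0)
    field_height_um: float = Field(default=750.0, gt=0)
    n_sequences: int = Field(default=5, ge=1)
    n_raters: int = Field(default=32, ge=1)
    rater_noise: float = Field(default=0.1, ge=0, le=0.5)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "SimulationSpec":
        if self.n_segments_min > self.n_segments_max:
            raise ValueError(
                f"n_segments_min ({self.n_segments_min}) > n_segments_max "
                f"({self.n_segments_max})"
            )
        return self


def category_probabilities(severity: float) -> np.ndarray:
    """(absent, intermittent, sluggish, continuous) weights for a severity."""
    if not 0 <= severity <= 1:
        raise DomainError(f"severity must be in [0, 1], got {severity}")
    probs = np.array(
        [np.interp(severity, _SEVERITY_KNOTS, _PROB_KNOTS[:, j]) for j in range(4)]
    )
    return probs / probs.sum()


def _second_regime(severity: float) -> float:
    """Severity of the heterogeneous sub-regime, one band away."""
    if severity < 0.5:
        return min(1.0, severity + SEVERITY_BAND)
    return max(0.0, severity - SEVERITY_BAND)


def _random_polyline(
    rng: np.random.Generator, width: float, height: float
) -> tuple[tuple[float, float], ...]:
    """Short, gently curved 3-point centerline inside the field."""
    margin = 1.0
    x0 = rng.uniform(margin, width - margin)
    y0 = rng.uniform(margin, height - margin)
    theta = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(50.0, 250.0)
    bend = rng.normal(0.0, 0.25)
    pts = [np.array([x0, y0])]
    for i, ang in enumerate((theta, theta + bend)):
        step = (length / 2.0) * np.array([np.cos(ang), np.sin(ang)])
        pts.append(pts[-1] + step)
    arr = np.clip(np.array(pts), [0.0, 0.0], [width, height])
    # clamping at the border can collapse points; nudge duplicates apart
    out: list[tuple[float, float]] = [tuple(arr[0])]
    for p in arr[1:]:
        if tuple(p) != out[-1]:
            out.append(tuple(p))
    if len(out) < 2:
        out.append((min(width, out[0][0] + 1.0), out[0][1]))
        if out[1] == out[0]:
            out[1] = (out[0][0] - 1.0, out[0][1])
    return tuple(out)


def simulate_clip(
    spec: SimulationSpec,
    severity: float | None = None,
    heterogeneity_level: float | None = None,
    seed: int | None = None,
    clip_id: str = "clip",
) -> ClipAnnotation:
    """One synthetic clip annotation, deterministic given spec and seed."""
    severity = spec.severity if severity is None else severity
    het = spec.heterogeneity_level if heterogeneity_level is None else heterogeneity_level
    if not 0 <= severity <= 1:
        raise DomainError(f"severity must be in [0, 1], got {severity}")
    if not 0 <= het <= 1:
        raise DomainError(f"heterogeneity_level must be in [0, 1], got {het}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    n = int(rng.integers(spec.n_segments_min, spec.n_segments_max + 1))
    n_het = int(round(het * n))
    probs_main = category_probabilities(severity)
    # the sub-regime draws only categories different from the main regime's
    # modal one, so the mixing weight maps onto the deviant fraction
    probs_alt = category_probabilities(_second_regime(severity)).copy()
    probs_alt[int(np.argmax(probs_main))] = 0.0
    probs_alt /= probs_alt.sum()
    cats_main = rng.choice(4, size=n - n_het, p=probs_main)
    cats_alt = rng.choice(4, size=n_het, p=probs_alt)
    cats = np.concatenate([cats_main, cats_alt])
    rng.shuffle(cats)

    # capillary-dominated calibre mix, lognormal around ~8 µm
    diameters = np.clip(rng.lognormal(mean=np.log(8.0), sigma=0.35, size=n), 3.0, 30.0)

    segments = tuple(
        SegmentAnnotation(
            segment_id=f"{clip_id}-s{i:03d}",
            polyline=_random_polyline(rng, spec.field_width_um, spec.field_height_um),
            diameter_um=float(diameters[i]),
            flow_category=_CATEGORIES[int(cats[i])],
        )
        for i in range(n)
    )
    return ClipAnnotation(
        clip_id=clip_id,
        field_width_um=spec.field_width_um,
        field_height_um=spec.field_height_um,
        segments=segments,
    )


@dataclass(frozen=True)
class SimulatedSequence:
    sequence_id: str
    severity: float
    heterogeneity_level: float
    clips: tuple[ClipAnnotation, ...]
    truth: SequenceAssessment


@dataclass(frozen=True)
class SimulatedStudy:
    """A full synthetic rater study."""

    spec: SimulationSpec
    sequences: tuple[SimulatedSequence, ...]
    ratings: RatingMatrix | None
    expert: pd.Series  # ground-truth score per sequence


def _clip_state_index(assessment: ClipAssessment) -> int:
    return _CLIP_STATES.index((assessment.flow_grade, assessment.heterogeneity))


def _state_assessment(clip_id: str, state: int) -> ClipAssessment:
    grade, het = _CLIP_STATES[state]
    return ClipAssessment(
        clip_id=clip_id,
        stopped_fraction=_STATE_FRACTIONS[state],
        flow_grade=grade,
        heterogeneity=het,
    )


def _perturb_state(state: int, rng: np.random.Generator, noise: float) -> int:
    """One-step ordinal confusion with probability ``noise``; ends move inward."""
    if rng.random() >= noise:
        return state
    if state == 0:
        return 1
    if state == len(_CLIP_STATES) - 1:
        return state - 1
    return state + (1 if rng.random() < 0.5 else -1)


def simulate_sequences(
    spec: SimulationSpec, config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[SimulatedSequence, ...]:
    """Synthetic sequences with ground-truth scores.

    Sequence severities are evenly spaced over [0, ``spec.severity``]
    (one value when ``n_sequences`` is 1); each sequence's heterogeneity
    level is drawn uniformly on [0, ``spec.heterogeneity_level``] and
    shared by its four clips.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_sequences == 1:
        severities = np.array([spec.severity])
    else:
        severities = np.linspace(0.0, spec.severity, spec.n_sequences)
    sequences = []
    for i, sev in enumerate(severities):
        het = float(rng.uniform(0.0, spec.heterogeneity_level))
        seq_id = f"seq{i:03d}"
        clips = tuple(
            simulate_clip(
                spec,
                severity=float(sev),
                heterogeneity_level=het,
                seed=int(rng.integers(0, 2**31 - 1)),
                clip_id=f"{seq_id}-c{j}",
            )
            for j in range(4)
        )
        truth = compute_poem([assess_clip(c, config) for c in clips], sequence_id=seq_id)
        sequences.append(
            SimulatedSequence(
                sequence_id=seq_id,
                severity=float(sev),
                heterogeneity_level=het,
                clips=clips,
                truth=truth,
            )
        )
    return tuple(sequences)


def simulate_study(
    spec: SimulationSpec, config: ScoringConfig = DEFAULT_CONFIG
) -> SimulatedStudy:
    """Simulate sequences plus a noisy rater panel and the expert reference.

    Each simulated rater sees every clip's true grade/heterogeneity state
    and, with probability ``rater_noise`` per clip, confuses it with an
    adjacent state on the ordinal ladder (critically impaired < impaired
    < normal+heterogeneity < normal) before the four-clip aggregation.
    The expert is noiseless, so expert scores equal ground truth.
    """
    if spec.n_raters < 2:
        raise DomainError("a rater-agreement study needs at least 2 raters")
    sequences = simulate_sequences(spec, config)
    rng = np.random.default_rng(spec.seed + 1)

    items = [s.sequence_id for s in sequences]
    raters = [f"rater{r:02d}" for r in range(spec.n_raters)]
    scores = np.zeros((len(items), len(raters)), dtype=int)
    for j in range(spec.n_raters):
        for i, seq in enumerate(sequences):
            perturbed = []
            for a in seq.truth.clip_assessments:
                state = _perturb_state(_clip_state_index(a), rng, spec.rater_noise)
                perturbed.append(_state_assessment(a.clip_id, state))
            scores[i, j] = compute_poem(perturbed, sequence_id=seq.sequence_id).poem_score

    ratings = RatingMatrix.from_arrays(items, raters, scores) if len(items) >= 2 else None
    expert = pd.Series(
        {s.sequence_id: s.truth.poem_score for s in sequences}, name="expert", dtype=int
    )
    return SimulatedStudy(spec=spec, sequences=sequences, ratings=ratings, expert=expert)
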