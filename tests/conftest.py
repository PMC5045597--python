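"""Shared fixtures: programmatic clip builders and assessment shorthands."""

from __future__ import annotations

import pytest
from hypothesis import settings

from poemscore import (
    ClipAnnotation,
    ClipAssessment,
    FlowCategory,
    FlowGrade,
    Heterogeneity,
    ScoringConfig,
    SegmentAnnotation,
)

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


def make_segment(
    segment_id: str,
    category: FlowCategory,
    x: float = 100.0,
    y: float = 100.0,
    length: float = 100.0,
    diameter: float = 8.0,
) -> SegmentAnnotation:
    """Horizontal straight segment centred at (x, y)."""
    return SegmentAnnotation(
        segment_id=segment_id,
        polyline=((x - length / 2, y), (x + length / 2, y)),
        diameter_um=diameter,
        flow_category=category,
    )


def make_clip(
    categories,
    clip_id: str = "clip",
    width: float = 1000.0,
    height: float = 750.0,
    diameter: float = 8.0,
) -> ClipAnnotation:
    """Clip whose segments carry the given flow categories, laid out on a grid."""
    segments = []
    for i, cat in enumerate(categories):
        x = 100.0 + 80.0 * (i % 10)
        y = 50.0 + 60.0 * (i // 10)
        segments.append(
            make_segment(f"s{i:03d}", FlowCategory(cat), x=x, y=y, diameter=diameter)
        )
    return ClipAnnotation(
        clip_id=clip_id, field_width_um=width, field_height_um=height, segments=tuple(segments)
    )


_STATES = {
    "critical": (FlowGrade.CRITICALLY_IMPAIRED, Heterogeneity.PRESENT, 0.75),
    "impaired": (FlowGrade.IMPAIRED, Heterogeneity.PRESENT, 0.375),
    "het": (FlowGrade.NORMAL, Heterogeneity.PRESENT, 0.10),
    "normal": (FlowGrade.NORMAL, Heterogeneity.ABSENT, 0.10),
}

#: ordered worst -> best, for monotonicity checks
STATE_ORDER = ("critical", "impaired", "het", "normal")


def assessment(state: str, clip_id: str = "clip") -> ClipAssessment:
    grade, het, frac = _STATES[state]
    return ClipAssessment(
        clip_id=clip_id, stopped_fraction=frac, flow_grade=grade, heterogeneity=het
    )


def assessments(*states: str) -> list[ClipAssessment]:
    return [assessment(s, clip_id=f"clip{i}") for i, s in enumerate(states)]


@pytest.fixture
def default_config() -> ScoringConfig:
    return ScoringConfig()
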