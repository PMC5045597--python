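"""Point-of-care microcirculation (POEM) grading.

A clip is graded by the fraction of vessel segments whose flow is
sluggish/stopped: normal below 25 %, impaired between 25 % and 50 %
inclusive, critically impaired above 50 %. For clips with normal flow,
heterogeneity is present when strictly more than five segments show flow
different from the remainder; impaired and critically impaired clips carry
heterogeneity by definition. Exactly four clips from one patient/time
point combine into the overall 1-5 ordinal score:

* two or more critically impaired clips -> score 1;
* otherwise two or more impaired-or-worse clips -> score 2;
* otherwise (three or more normal clips) the score is set by the number
  of heterogeneous clips H: score 3 if H = 4, score 4 if H in {2, 3},
  score 5 if H <= 1.

The rule for a sequence with exactly one critically impaired and one
impaired clip is not covered by the published wording; here a critically
impaired clip counts toward the impaired tally (the most conservative
reading of the severity ordering), so such sequences score 2.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence

from .errors import ArityError, DomainError, EmptyClipError
from .types import (
    ClipAnnotation,
    ClipAssessment,
    FlowGrade,
    Heterogeneity,
    ScoringConfig,
    SequenceAssessment,
    sequence_label,
)

DEFAULT_CONFIG = ScoringConfig()


def stopped_fraction(clip: ClipAnnotation, config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Fraction of segments in view whose flow is sluggish/stopped.

    Each segment has weight 1 regardless of its length; the grading counts
    vessel segments, not vessel length.
    """
    if clip.n_segments == 0:
        raise EmptyClipError(clip.clip_id)
    stopped = sum(1 for s in clip.segments if s.flow_category in config.stopped_categories)
    return stopped / clip.n_segments


def classify_clip_flow(fraction: float, config: ScoringConfig = DEFAULT_CONFIG) -> FlowGrade:
    """Band a stopped fraction into normal / impaired / critically impaired.

    The bands are ``< normal_upper`` (strict), ``[normal_upper,
    critical_lower]`` (closed) and ``> critical_lower`` (strict): exactly
    25 % and exactly 50 % are impaired.
    """
    if not 0 <= fraction <= 1:
        raise DomainError(f"stopped fraction must be in [0, 1], got {fraction}")
    if fraction < config.normal_upper:
        return FlowGrade.NORMAL
    if fraction <= config.critical_lower:
        return FlowGrade.IMPAIRED
    return FlowGrade.CRITICALLY_IMPAIRED


def deviant_count(clip: ClipAnnotation) -> int:
    """Number of segments whose flow differs from the modal category.

    ``n - max(category counts)`` is independent of how plurality ties are
    broken, so no tie rule is needed.
    """
    if clip.n_segments == 0:
        raise EmptyClipError(clip.clip_id)
    counts = Counter(s.flow_category for s in clip.segments)
    return clip.n_segments - max(counts.values())


def detect_heterogeneity(
    clip: ClipAnnotation, config: ScoringConfig = DEFAULT_CONFIG
) -> Heterogeneity:
    """Present iff strictly more than ``het_deviant_threshold`` (default 5)
    segments demonstrate flow different from the remainder."""
    if deviant_count(clip) > config.het_deviant_threshold:
        return Heterogeneity.PRESENT
    return Heterogeneity.ABSENT


def assess_clip(clip: ClipAnnotation, config: ScoringConfig = DEFAULT_CONFIG) -> ClipAssessment:
    """Grade one clip: flow band plus heterogeneity.

    Heterogeneity is evaluated only for clips with normal flow; impaired
    and critically impaired clips are heterogeneous by definition.
    """
    fraction = stopped_fraction(clip, config)
    grade = classify_clip_flow(fraction, config)
    if grade is FlowGrade.NORMAL:
        het = detect_heterogeneity(clip, config)
    else:
        het = Heterogeneity.PRESENT
    return ClipAssessment(
        clip_id=clip.clip_id,
        stopped_fraction=fraction,
        flow_grade=grade,
        heterogeneity=het,
    )


def compute_poem(
    assessments: Sequence[ClipAssessment], sequence_id: str = "sequence"
) -> SequenceAssessment:
    """Combine exactly four clip assessments into the overall score."""
    assessments = tuple(assessments)
    if len(assessments) != 4:
        raise ArityError(
            f"the overall score is derived from exactly four clips, got {len(assessments)}"
        )
    n_critical = sum(1 for a in assessments if a.flow_grade is FlowGrade.CRITICALLY_IMPAIRED)
    n_impaired = sum(1 for a in assessments if a.flow_grade is FlowGrade.IMPAIRED)
    n_het = sum(1 for a in assessments if a.heterogeneity is Heterogeneity.PRESENT)

    if n_critical >= 2:
        score = 1
    elif n_critical + n_impaired >= 2:
        score = 2
    elif n_het == 4:
        score = 3
    elif n_het >= 2:
        score = 4
    else:
        score = 5

    return SequenceAssessment(
        sequence_id=sequence_id,
        clip_assessments=assessments,
        poem_score=score,
        label=sequence_label(score),
    )


def assess_sequence(
    clips: Iterable[ClipAnnotation],
    sequence_id: str = "sequence",
    config: ScoringConfig = DEFAULT_CONFIG,
) -> SequenceAssessment:
    """Grade four clips end-to-end and combine them into the overall score."""
    return compute_poem([assess_clip(c, config) for c in clips], sequence_id=sequence_id)
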