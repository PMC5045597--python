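"""Traditional offline consensus microcirculatory parameters.

Computed from the same segment-level annotations as the point-of-care
grade, following the consensus small-vessel conventions:

* **TVD** (total vessel density): total small-vessel centerline length per
  field area, mm/mm^2, using a 20 µm diameter cutoff by default.
* **PVD** (perfused vessel density): as TVD, summing only perfused
  segments (sluggish or continuous flow by default).
* **PPV** (proportion of perfused vessels): perfused / all small-vessel
  segments, per segment count.
* **MFI** (microcirculatory flow index, quadrant method): the field is
  split into four equal quadrants; each segment belongs to the quadrant
  containing its centerline's arc-length midpoint; each non-empty quadrant
  scores the flow score (absent 0 ... continuous 3) of its predominant
  category, ties broken toward the lower score; MFI is the mean over
  non-empty quadrants.
* **MHI** (microcirculatory heterogeneity index): (max - min) / mean of
  the clip MFIs of one patient/time point.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence

import numpy as np

from .errors import DomainError, EmptyClipError, UndefinedValueError
from .types import (
    FLOW_SCORES,
    ClipAnnotation,
    ConsensusParams,
    FlowCategory,
    SegmentAnnotation,
    SequenceHeterogeneity,
)

#: Flow categories counted as perfused (configurable per call).
DEFAULT_PERFUSED: frozenset[FlowCategory] = frozenset(
    {FlowCategory.SLUGGISH, FlowCategory.CONTINUOUS}
)

#: Consensus small-vessel diameter cutoff, µm.
DEFAULT_SMALL_VESSEL_MAX_DIAMETER_UM = 20.0


def flow_score(category: FlowCategory) -> int:
    """Ordinal flow score: absent 0, intermittent 1, sluggish 2, continuous 3."""
    try:
        return FLOW_SCORES[FlowCategory(category)]
    except (KeyError, ValueError):
        raise DomainError(f"unknown flow category: {category!r}") from None


def polyline_length_um(segment: SegmentAnnotation) -> float:
    """Centerline arc length in µm."""
    pts = np.asarray(segment.polyline, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _small_segments(
    clip: ClipAnnotation, cutoff_um: float
) -> list[SegmentAnnotation]:
    return [s for s in clip.segments if s.diameter_um <= cutoff_um]


def _field_area_mm2(clip: ClipAnnotation) -> float:
    area_um2 = clip.field_width_um * clip.field_height_um
    if area_um2 <= 0:
        raise DomainError(f"clip {clip.clip_id!r}: field area must be positive")
    return area_um2 / 1e6


def total_vessel_density(
    clip: ClipAnnotation,
    small_vessel_max_diameter_um: float = DEFAULT_SMALL_VESSEL_MAX_DIAMETER_UM,
) -> float:
    """TVD in mm/mm^2: small-vessel centerline length over field area."""
    length_mm = sum(
        polyline_length_um(s) for s in _small_segments(clip, small_vessel_max_diameter_um)
    ) / 1e3
    return length_mm / _field_area_mm2(clip)


def perfused_vessel_density(
    clip: ClipAnnotation,
    perfused_categories: frozenset[FlowCategory] = DEFAULT_PERFUSED,
    small_vessel_max_diameter_um: float = DEFAULT_SMALL_VESSEL_MAX_DIAMETER_UM,
) -> float:
    """PVD in mm/mm^2: perfused small-vessel length over field area."""
    length_mm = (
        sum(
            polyline_length_um(s)
            for s in _small_segments(clip, small_vessel_max_diameter_um)
            if s.flow_category in perfused_categories
        )
        / 1e3
    )
    return length_mm / _field_area_mm2(clip)


def proportion_perfused(
    clip: ClipAnnotation,
    perfused_categories: frozenset[FlowCategory] = DEFAULT_PERFUSED,
    small_vessel_max_diameter_um: float = DEFAULT_SMALL_VESSEL_MAX_DIAMETER_UM,
) -> float:
    """PPV: perfused small-vessel segments over all small-vessel segments."""
    small = _small_segments(clip, small_vessel_max_diameter_um)
    if not small:
        raise UndefinedValueError(
            f"clip {clip.clip_id!r}: no segments under the "
            f"{small_vessel_max_diameter_um} µm cutoff; PPV undefined"
        )
    perfused = sum(1 for s in small if s.flow_category in perfused_categories)
    return perfused / len(small)


def _segment_midpoint(segment: SegmentAnnotation) -> tuple[float, float]:
    """Point at half the centerline arc length."""
    pts = np.asarray(segment.polyline, dtype=float)
    step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(step)])
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half, side="right") - 1)
    i = min(i, len(step) - 1)
    t = 0.0 if step[i] == 0 else (half - cum[i]) / step[i]
    p = pts[i] + t * (pts[i + 1] - pts[i])
    return float(p[0]), float(p[1])


def mfi_quadrant(clip: ClipAnnotation) -> float:
    """Quadrant-method MFI: mean predominant flow score over non-empty quadrants.

    Empty quadrants are excluded from the mean rather than scored 0, so a
    sparse field is not penalized for bare quadrants.
    """
    if clip.n_segments == 0:
        raise EmptyClipError(clip.clip_id)
    half_w = clip.field_width_um / 2.0
    half_h = clip.field_height_um / 2.0
    quadrants: dict[int, Counter] = {}
    for seg in clip.segments:
        x, y = _segment_midpoint(seg)
        q = (1 if x >= half_w else 0) + (2 if y >= half_h else 0)
        quadrants.setdefault(q, Counter())[seg.flow_category] += 1
    scores = []
    for counts in quadrants.values():
        top = max(counts.values())
        # predominant category by count; ties broken toward the lower score
        score = min(FLOW_SCORES[c] for c, n in counts.items() if n == top)
        scores.append(score)
    return float(np.mean(scores))


def mhi(clip_mfis: Sequence[float]) -> float:
    """Heterogeneity index across one time point's clip MFIs: (max-min)/mean."""
    values = np.asarray(clip_mfis, dtype=float)
    if values.size < 2:
        raise DomainError(f"MHI needs at least two clip MFIs, got {values.size}")
    mean = values.mean()
    if mean <= 0:
        raise UndefinedValueError("MHI undefined: mean MFI is zero")
    return float((values.max() - values.min()) / mean)


def consensus_params(
    clip: ClipAnnotation,
    perfused_categories: frozenset[FlowCategory] = DEFAULT_PERFUSED,
    small_vessel_max_diameter_um: float = DEFAULT_SMALL_VESSEL_MAX_DIAMETER_UM,
) -> ConsensusParams:
    """TVD, PVD, PPV and MFI for one clip."""
    return ConsensusParams(
        clip_id=clip.clip_id,
        tvd=total_vessel_density(clip, small_vessel_max_diameter_um),
        pvd=perfused_vessel_density(clip, perfused_categories, small_vessel_max_diameter_um),
        ppv=proportion_perfused(clip, perfused_categories, small_vessel_max_diameter_um),
        mfi=mfi_quadrant(clip),
    )


def sequence_heterogeneity(
    clips: Sequence[ClipAnnotation], sequence_id: str = "sequence"
) -> SequenceHeterogeneity:
    """MHI across the four clips of one patient/time point."""
    if len(clips) != 4:
        raise DomainError(f"a sequence has exactly four clips, got {len(clips)}")
    mfis = tuple(mfi_quadrant(c) for c in clips)
    return SequenceHeterogeneity(sequence_id=sequence_id, mhi=mhi(mfis), mfi_per_clip=mfis)
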