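"""Domain types for sublingual video-microscopy annotation and grading.

Geometry is in micrometres (µm) with the image convention: origin at the
top-left corner, y increasing downward. A *vessel segment* is an
individually distinguishable stretch of microvessel, annotated with a
centerline polyline, a diameter and one of four ordinal flow categories
(the semi-quantitative flow vocabulary used for the microcirculatory flow
index: absent < intermittent < sluggish < continuous).
"""

from __future__ import annotations

import enum

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InputValidationError

SCHEMA_VERSION = "1"


class FlowCategory(str, enum.Enum):
    """Ordinal flow category of a single vessel segment."""

    ABSENT = "absent"
    INTERMITTENT = "intermittent"
    SLUGGISH = "sluggish"
    CONTINUOUS = "continuous"

    @classmethod
    def parse(cls, value: str) -> "FlowCategory":
        """Parse a category name, tolerant of case and surrounding space."""
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise InputValidationError(
                f"unknown flow category {value!r}; expected one of {valid}"
            ) from None


#: Flow-score mapping of the semi-quantitative (Boerma-style) MFI scale.
FLOW_SCORES: dict[FlowCategory, int] = {
    FlowCategory.ABSENT: 0,
    FlowCategory.INTERMITTENT: 1,
    FlowCategory.SLUGGISH: 2,
    FlowCategory.CONTINUOUS: 3,
}


class FlowGrade(str, enum.Enum):
    """Per-clip overall flow grade from the stopped-segment fraction."""

    NORMAL = "normal"
    IMPAIRED = "impaired"
    CRITICALLY_IMPAIRED = "critically_impaired"


class Heterogeneity(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"


#: Ordinal-score -> label mapping of the 5-point grading table.
POEM_LABELS: dict[int, str] = {
    1: "critically impaired",
    2: "impaired",
    3: "normal with marked heterogeneity",
    4: "normal with mild heterogeneity",
    5: "normal with no heterogeneity",
}


class SegmentAnnotation(BaseModel):
    """One annotated vessel segment."""

    model_config = ConfigDict(frozen=True)

    segment_id: str
    polyline: tuple[tuple[float, float], ...] = Field(min_length=2)
    diameter_um: float = Field(gt=0)
    flow_category: FlowCategory

    @model_validator(mode="after")
    def _check_polyline(self) -> "SegmentAnnotation":
        for a, b in zip(self.polyline, self.polyline[1:]):
            if a == b:
                raise ValueError(
                    f"segment {self.segment_id!r}: consecutive polyline "
                    f"points must be distinct (got repeated {a})"
                )
        return self


class ClipAnnotation(BaseModel):
    """A single video clip's worth of segment annotations.

    ``segments`` may be empty at construction time; scoring operations
    reject empty clips with a distinct :class:`~poemscore.errors.EmptyClipError`.
    """

    model_config = ConfigDict(frozen=True)

    clip_id: str
    field_width_um: float = Field(gt=0)
    field_height_um: float = Field(gt=0)
    segments: tuple[SegmentAnnotation, ...] = ()

    @model_validator(mode="after")
    def _check_in_field(self) -> "ClipAnnotation":
        for seg in self.segments:
            for x, y in seg.polyline:
                if not (0 <= x <= self.field_width_um and 0 <= y <= self.field_height_um):
                    raise ValueError(
                        f"clip {self.clip_id!r} segment {seg.segment_id!r}: "
                        f"point ({x}, {y}) outside field "
                        f"[0, {self.field_width_um}] x [0, {self.field_height_um}]"
                    )
        return self

    @property
    def n_segments(self) -> int:
        return len(self.segments)


class ScoringConfig(BaseModel):
    """Thresholds of the grading rules.

    ``normal_upper`` / ``critical_lower`` are the stopped-fraction band
    edges (normal strictly below 25 %, critically impaired strictly above
    50 %, the closed band in between impaired). ``het_deviant_threshold``
    is the strictly-greater deviant-segment count for heterogeneity.
    ``stopped_categories`` defines which flow categories count as
    sluggish/stopped; intermittent flow is stopped part of the time and is
    counted by default.
    """

    model_config = ConfigDict(frozen=True)

    normal_upper: float = 0.25
    critical_lower: float = 0.50
    het_deviant_threshold: int = Field(default=5, ge=0)
    stopped_categories: frozenset[FlowCategory] = frozenset(
        {FlowCategory.ABSENT, FlowCategory.INTERMITTENT, FlowCategory.SLUGGISH}
    )

    @model_validator(mode="after")
    def _check_bands(self) -> "ScoringConfig":
        if not (0 < self.normal_upper <= self.critical_lower < 1):
            raise ValueError(
                "band thresholds must satisfy 0 < normal_upper <= critical_lower < 1 "
                f"(got {self.normal_upper}, {self.critical_lower})"
            )
        return self


class ClipAssessment(BaseModel):
    """Flow grade and heterogeneity of one clip.

    Heterogeneity is universally present in impaired and critically
    impaired clips, so a non-normal grade forces ``heterogeneity=present``.
    """

    model_config = ConfigDict(frozen=True)

    clip_id: str
    stopped_fraction: float = Field(ge=0, le=1)
    flow_grade: FlowGrade
    heterogeneity: Heterogeneity

    @model_validator(mode="after")
    def _check_het(self) -> "ClipAssessment":
        if self.flow_grade is not FlowGrade.NORMAL and self.heterogeneity is not Heterogeneity.PRESENT:
            raise ValueError(
                f"clip {self.clip_id!r}: heterogeneity must be present when "
                f"flow grade is {self.flow_grade.value}"
            )
        return self


class SequenceAssessment(BaseModel):
    """Four clip assessments and the overall 1-5 ordinal score."""

    model_config = ConfigDict(frozen=True)

    sequence_id: str
    clip_assessments: tuple[ClipAssessment, ...] = Field(min_length=4, max_length=4)
    poem_score: int = Field(ge=1, le=5)
    label: str

    @model_validator(mode="after")
    def _check_label(self) -> "SequenceAssessment":
        expected = POEM_LABELS[self.poem_score]
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} does not match score {self.poem_score} "
                f"({expected!r})"
            )
        return self


class ConsensusParams(BaseModel):
    """Per-clip consensus parameters (small-vessel conventions)."""

    model_config = ConfigDict(frozen=True)

    clip_id: str
    tvd: float = Field(ge=0, description="total vessel density, mm/mm^2")
    pvd: float = Field(ge=0, description="perfused vessel density, mm/mm^2")
    ppv: float = Field(ge=0, le=1, description="proportion of perfused vessels")
    mfi: float = Field(ge=0, le=3, description="microcirculatory flow index")

    @model_validator(mode="after")
    def _check_densities(self) -> "ConsensusParams":
        if self.pvd > self.tvd + 1e-12:
            raise ValueError(f"PVD ({self.pvd}) cannot exceed TVD ({self.tvd})")
        return self


class SequenceHeterogeneity(BaseModel):
    """Per-sequence (time point) heterogeneity index over four clip MFIs."""

    model_config = ConfigDict(frozen=True)

    sequence_id: str
    mhi: float = Field(ge=0)
    mfi_per_clip: tuple[float, float, float, float]


class ICCResult(BaseModel):
    """Two-way intraclass correlation estimate with its F-based 95 % CI.

    Single-measures estimates lie in (-1, 1] and that range is enforced;
    the average-measures (Spearman-Brown stepped-up) forms are unbounded
    on anti-reliable data, where negative variance components push the
    estimator outside [-1, 1].
    """

    model_config = ConfigDict(frozen=True)

    estimate: float
    ci_low: float
    ci_high: float
    flavor: str  # "consistency" | "agreement"
    measures: str = "single"  # "single" | "average"
    f_value: float
    df1: float
    df2: float

    @model_validator(mode="after")
    def _check_ci(self) -> "ICCResult":
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"estimate {self.estimate}"
            )
        if self.measures == "single" and not (-1 < self.estimate <= 1):
            raise ValueError(
                f"single-measures ICC must lie in (-1, 1], got {self.estimate}"
            )
        return self


class RegressionResult(BaseModel):
    """Ordinary least-squares summary for score-vs-parameter regressions."""

    model_config = ConfigDict(frozen=True)

    r_squared: float = Field(ge=0, le=1)
    p_value: float = Field(ge=0, le=1)
    slope: float
    intercept: float


class RatingMatrix:
    """Complete items x raters matrix of ordinal 1-5 scores.

    Thin wrapper over a :class:`pandas.DataFrame` (items as index, raters
    as columns) enforcing completeness and the 1-5 score range. Incomplete
    matrices are rejected: the validation design is complete (every rater
    scores every sequence).
    """

    def __init__(self, scores: pd.DataFrame):
        if scores.shape[0] < 2 or scores.shape[1] < 2:
            raise InputValidationError(
                f"rating matrix needs >=2 items and >=2 raters, got {scores.shape}"
            )
        if scores.isna().any().any():
            raise InputValidationError("rating matrix has missing cells")
        values = scores.to_numpy()
        if not ((values == values.astype(int)) & (values >= 1) & (values <= 5)).all():
            raise InputValidationError("all scores must be integers in 1..5")
        self._scores = scores.astype(int)

    @classmethod
    def from_arrays(cls, items, raters, scores) -> "RatingMatrix":
        return cls(pd.DataFrame(scores, index=list(items), columns=list(raters)))

    @property
    def scores(self) -> pd.DataFrame:
        return self._scores

    @property
    def items(self) -> list:
        return list(self._scores.index)

    @property
    def raters(self) -> list:
        return list(self._scores.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._scores.shape

    def to_long(self) -> pd.DataFrame:
        """Long form with columns item, rater, score."""
        long = self._scores.rename_axis("item").reset_index().melt(
            id_vars="item", var_name="rater", value_name="score"
        )
        return long

    def __eq__(self, other) -> bool:
        return isinstance(other, RatingMatrix) and self._scores.equals(other._scores)

    def __repr__(self) -> str:
        n, k = self.shape
        return f"RatingMatrix({n} items x {k} raters)"


def sequence_label(poem_score: int) -> str:
    """Table label for an overall score ∈ {1..5}."""
    try:
        return POEM_LABELS[int(poem_score)]
    except KeyError:
        raise InputValidationError(f"POEM score must be in 1..5, got {poem_score}") from None
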