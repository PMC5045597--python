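"""Readers and writers for the package's plain-text interchange formats.

Clip annotations travel as CSV (one row per vessel segment) or JSON (one
object per clip). The CSV dialect is UTF-8, comma-separated, header row
required, ``.`` decimal separator; the polyline is a semicolon-separated
list of ``x,y`` pairs in µm (origin top-left, y increasing downward).
JSON is the lossless canonical form. Columns::

    clip_id, segment_id, diameter_um, flow_category, polyline
    [, field_width_um, field_height_um]

Field dimensions default to the simulator's 1000 x 750 µm field when the
optional columns are absent. Flow categories are normalized to lower
case on read.

Rating matrices are CSV with the item id in the first column and one
column per rater; expert scores are two-column CSV (item id, score).
A sequence manifest is JSON naming a sequence id and exactly four clip
annotation files.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from collections.abc import Iterable, Sequence

import pandas as pd
import pydantic

from .errors import ArityError, InputValidationError
from .types import (
    SCHEMA_VERSION,
    ClipAnnotation,
    FlowCategory,
    RatingMatrix,
    SegmentAnnotation,
)

DEFAULT_FIELD_WIDTH_UM = 1000.0
DEFAULT_FIELD_HEIGHT_UM = 750.0

_CSV_COLUMNS = [
    "clip_id",
    "segment_id",
    "diameter_um",
    "flow_category",
    "polyline",
    "field_width_um",
    "field_height_um",
]


def _parse_polyline(text: str, row: int) -> tuple[tuple[float, float], ...]:
    points = []
    for pair in str(text).split(";"):
        pair = pair.strip()
        if not pair:
            continue
        parts = pair.split(",")
        if len(parts) != 2:
            raise InputValidationError(
                f"row {row}: field 'polyline': malformed pair {pair!r} "
                "(expected 'x,y' pairs separated by ';')"
            )
        try:
            points.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise InputValidationError(
                f"row {row}: field 'polyline': non-numeric coordinate in {pair!r}"
            ) from None
    return tuple(points)


def _format_polyline(polyline: Sequence[tuple[float, float]]) -> str:
    return ";".join(f"{x:g},{y:g}" for x, y in polyline)


def _build_clip(
    clip_id: str,
    width: float,
    height: float,
    segments: list[SegmentAnnotation],
    row: int | None = None,
) -> ClipAnnotation:
    try:
        return ClipAnnotation(
            clip_id=clip_id,
            field_width_um=width,
            field_height_um=height,
            segments=tuple(segments),
        )
    except pydantic.ValidationError as exc:
        where = f"row {row}: " if row is not None else ""
        raise InputValidationError(f"{where}clip {clip_id!r}: {exc}") from None


def read_clips(path: str | Path) -> list[ClipAnnotation]:
    """Read clip annotations from a ``.csv`` or ``.json`` file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_clips_json(path)
    return _read_clips_csv(path)


def _read_clips_csv(path: Path) -> list[ClipAnnotation]:
    order: list[str] = []
    grouped: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InputValidationError(f"{path}: empty file, header row required")
        required = {"clip_id", "segment_id", "diameter_um", "flow_category", "polyline"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise InputValidationError(f"{path}: missing columns {sorted(missing)}")
        for row_no, row in enumerate(reader, start=2):  # header is row 1
            clip_id = (row["clip_id"] or "").strip()
            if not clip_id:
                raise InputValidationError(f"row {row_no}: field 'clip_id': empty")
            width = float(row.get("field_width_um") or DEFAULT_FIELD_WIDTH_UM)
            height = float(row.get("field_height_um") or DEFAULT_FIELD_HEIGHT_UM)
            try:
                diameter = float(row["diameter_um"])
            except (TypeError, ValueError):
                raise InputValidationError(
                    f"row {row_no}: field 'diameter_um': not a number "
                    f"({row['diameter_um']!r})"
                ) from None
            try:
                category = FlowCategory.parse(row["flow_category"])
            except InputValidationError as exc:
                raise InputValidationError(f"row {row_no}: field 'flow_category': {exc}") from None
            polyline = _parse_polyline(row["polyline"], row_no)
            try:
                segment = SegmentAnnotation(
                    segment_id=(row["segment_id"] or "").strip(),
                    polyline=polyline,
                    diameter_um=diameter,
                    flow_category=category,
                )
            except pydantic.ValidationError as exc:
                raise InputValidationError(f"row {row_no}: {exc}") from None
            if clip_id not in grouped:
                order.append(clip_id)
                grouped[clip_id] = {"width": width, "height": height, "segments": [], "row": row_no}
            grouped[clip_id]["segments"].append(segment)
    if not grouped:
        raise InputValidationError(f"{path}: no annotation rows")
    return [
        _build_clip(cid, g["width"], g["height"], g["segments"], row=g["row"])
        for cid, g in ((cid, grouped[cid]) for cid in order)
    ]


def _read_clips_json(path: Path) -> list[ClipAnnotation]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    records = payload["clips"] if isinstance(payload, dict) else payload
    clips = []
    for rec in records:
        segments = []
        for seg in rec.get("segments", []):
            try:
                segments.append(
                    SegmentAnnotation(
                        segment_id=seg["segment_id"],
                        polyline=tuple((float(x), float(y)) for x, y in seg["polyline"]),
                        diameter_um=seg["diameter_um"],
                        flow_category=FlowCategory.parse(seg["flow_category"]),
                    )
                )
            except (KeyError, TypeError, pydantic.ValidationError) as exc:
                raise InputValidationError(
                    f"clip {rec.get('clip_id')!r} segment {seg.get('segment_id')!r}: {exc}"
                ) from None
        clips.append(
            _build_clip(
                rec["clip_id"],
                rec.get("field_width_um", DEFAULT_FIELD_WIDTH_UM),
                rec.get("field_height_um", DEFAULT_FIELD_HEIGHT_UM),
                segments,
            )
        )
    return clips


def write_clips(clips: Iterable[ClipAnnotation], path: str | Path) -> None:
    """Write clip annotations to ``.csv`` or ``.json`` (by extension)."""
    path = Path(path)
    clips = list(clips)
    if path.suffix.lower() == ".json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "clips": [
                {
                    "clip_id": c.clip_id,
                    "field_width_um": c.field_width_um,
                    "field_height_um": c.field_height_um,
                    "segments": [
                        {
                            "segment_id": s.segment_id,
                            "diameter_um": s.diameter_um,
                            "flow_category": s.flow_category.value,
                            "polyline": [[x, y] for x, y in s.polyline],
                        }
                        for s in c.segments
                    ],
                }
                for c in clips
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for c in clips:
            for s in c.segments:
                writer.writerow(
                    [
                        c.clip_id,
                        s.segment_id,
                        repr(s.diameter_um),
                        s.flow_category.value,
                        ";".join(f"{x!r},{y!r}" for x, y in s.polyline),
                        repr(c.field_width_um),
                        repr(c.field_height_um),
                    ]
                )


def read_ratings(path: str | Path) -> RatingMatrix:
    """Rating matrix CSV: first column item id, one column per rater."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise InputValidationError(
            f"{path}: expected an item-id column plus >=2 rater columns"
        )
    df = df.set_index(df.columns[0])
    return RatingMatrix(df)


def write_ratings(matrix: RatingMatrix, path: str | Path) -> None:
    matrix.scores.rename_axis("item").to_csv(path)


def read_expert_scores(path: str | Path) -> pd.Series:
    """Expert scores CSV: item id, score."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InputValidationError(f"{path}: expected columns item id, score")
    series = df.set_index(df.columns[0]).iloc[:, 0]
    if not series.map(lambda v: float(v).is_integer() and 1 <= v <= 5).all():
        raise InputValidationError(f"{path}: expert scores must be integers in 1..5")
    return series.astype(int)


def write_expert_scores(expert: pd.Series, path: str | Path) -> None:
    expert.rename("score").rename_axis("item").to_csv(path)


def read_manifest(path: str | Path) -> tuple[str, list[ClipAnnotation]]:
    """Sequence manifest JSON: sequence id plus exactly four clip files.

    Clip file paths are resolved relative to the manifest's directory.
    Each referenced file must contain exactly one clip.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    try:
        sequence_id = manifest["sequence_id"]
        clip_files = manifest["clip_files"]
    except (KeyError, TypeError):
        raise InputValidationError(
            f"{path}: manifest must contain 'sequence_id' and 'clip_files'"
        ) from None
    if len(clip_files) != 4:
        raise ArityError(
            f"{path}: a sequence manifest must reference exactly four clips, "
            f"got {len(clip_files)}"
        )
    clips = []
    for ref in clip_files:
        file_clips = read_clips(path.parent / ref)
        if len(file_clips) != 1:
            raise InputValidationError(
                f"{path}: clip file {ref!r} must contain exactly one clip, "
                f"got {len(file_clips)}"
            )
        clips.append(file_clips[0])
    return sequence_id, clips
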