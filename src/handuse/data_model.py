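"""Domain types and on-disk format for annotated egocentric task sequences.

A *task sequence* is one subject performing one task: an ordered stack of
colour frames plus per-frame, per-hand annotations (bounding box, binary
hand mask, interaction and role labels).  Hands are identified by clinical
side — ``more_affected`` / ``less_affected`` — rather than image left/right,
because the clinical side is the reporting unit throughout the pipeline.

On disk a task is a directory::

    <task_root>/
      meta.yaml                      # subject_id, task_id, fps, flags, size
      frames/frame_00000.png         # 3-channel colour frames
      masks/<side>_00000.png         # single-channel 0/255 hand masks
      annotations.csv                # frame_index, side, x, y, w, h,
                                     #   interacting, role (empty = absent)

Coordinates are 0-based, half-open: a box occupies columns ``[x, x+w)`` and
rows ``[y, y+h)``.  All label cells left empty mean "unlabeled", never a
sentinel number.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

__all__ = [
    "Side",
    "Role",
    "BoundingBox",
    "HandMask",
    "HandObservation",
    "TaskSequence",
    "Dataset",
    "read_task_sequence",
    "write_task_sequence",
    "read_dataset",
    "write_dataset",
]

#: Default analysis resolution (width, height) in pixels.
DEFAULT_FRAME_SIZE = (640, 360)

ANNOTATION_COLUMNS = ["frame_index", "side", "x", "y", "w", "h", "interacting", "role"]


class Side(str, enum.Enum):
    """Clinical hand side relative to the stroke lesion."""

    MORE_AFFECTED = "more_affected"
    LESS_AFFECTED = "less_affected"


class Role(str, enum.Enum):
    """Hand role within an interaction.

    A stabilizer is statically in contact with an object, keeping the
    hand-object contact area constant; a manipulator moves an object with
    the contact area changing over time.
    """

    STABILIZER = "stabilizer"
    MANIPULATOR = "manipulator"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open ``[x, x+w) × [y, y+h)``."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive extent, got w={self.w}, h={self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    def intersection_area(self, other: "BoundingBox") -> int:
        iw = min(self.x2, other.x2) - max(self.x, other.x)
        ih = min(self.y2, other.y2) - max(self.y, other.y)
        return max(iw, 0) * max(ih, 0)

    def clipped(self, frame_size: tuple[int, int]) -> "BoundingBox":
        """Clip to a ``(width, height)`` frame; raises if nothing remains."""
        fw, fh = frame_size
        x1, y1 = max(self.x, 0), max(self.y, 0)
        x2, y2 = min(self.x2, fw), min(self.y2, fh)
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"box {self} does not intersect frame {frame_size}")
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)

    def expanded(self, factor: float, frame_size: tuple[int, int]) -> "BoundingBox":
        """Scale about the centre by ``factor`` and clip to the frame."""
        if factor < 1.0:
            raise ValueError("expansion factor must be >= 1")
        cx = self.x + self.w / 2.0
        cy = self.y + self.h / 2.0
        nw, nh = self.w * factor, self.h * factor
        x1 = int(round(cx - nw / 2.0))
        y1 = int(round(cy - nh / 2.0))
        return BoundingBox(x1, y1, max(int(round(nw)), 1), max(int(round(nh)), 1)).clipped(frame_size)

    def scaled(self, sx: float, sy: float) -> "BoundingBox":
        """Rescale coordinates (used when resampling a sequence)."""
        x1 = int(round(self.x * sx))
        y1 = int(round(self.y * sy))
        x2 = int(round(self.x2 * sx))
        y2 = int(round(self.y2 * sy))
        return BoundingBox(x1, y1, max(x2 - x1, 1), max(y2 - y1, 1))

    def slices(self) -> tuple[slice, slice]:
        """(row_slice, col_slice) for numpy indexing."""
        return slice(self.y, self.y2), slice(self.x, self.x2)


class HandMask:
    """Binary hand segmentation raster with the frame's dimensions."""

    def __init__(self, raster: np.ndarray):
        raster = np.asarray(raster)
        if raster.ndim != 2:
            raise ValueError("mask raster must be 2-D")
        self.raster = raster.astype(bool)

    @property
    def area(self) -> int:
        """Number of hand pixels."""
        return int(self.raster.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    def tight_box(self) -> BoundingBox:
        """Smallest box containing every mask pixel."""
        rows = np.flatnonzero(self.raster.any(axis=1))
        cols = np.flatnonzero(self.raster.any(axis=0))
        if rows.size == 0:
            raise ValueError("empty mask has no bounding box")
        return BoundingBox(
            int(cols[0]), int(rows[0]), int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1)
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HandMask) and np.array_equal(self.raster, other.raster)


@dataclass
class HandObservation:
    """One hand in one frame.

    ``interacting`` is tri-state: True/False when labeled, None when the
    frame is unannotated for this hand (e.g. the hand is < 50 % visible).
    A role may only be present on interacting frames.
    """

    frame_index: int
    side: Side
    box: Optional[BoundingBox] = None
    mask: Optional[HandMask] = None
    interacting: Optional[bool] = None
    role: Optional[Role] = None

    def __post_init__(self) -> None:
        if self.role is not None and self.interacting is not True:
            raise ValueError(
                f"frame {self.frame_index} {self.side.value}: role labels are only "
                "defined within interactions"
            )


@dataclass
class TaskSequence:
    """Ordered frames plus per-frame per-hand observations for one task."""

    subject_id: str
    task_id: str
    fps: float
    frames: list[np.ndarray]
    observations: dict[tuple[int, Side], HandObservation] = field(default_factory=dict)
    is_no_interaction_task: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_size(self) -> tuple[int, int]:
        """(width, height) of the frames."""
        h, w = self.frames[0].shape[:2]
        return (w, h)

    def get(self, frame_index: int, side: Side) -> Optional[HandObservation]:
        return self.observations.get((frame_index, side))

    def iter_side(self, side: Side) -> Iterator[HandObservation]:
        """Observations for one hand in frame order."""
        for i in range(self.n_frames):
            obs = self.observations.get((i, side))
            if obs is not None:
                yield obs

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.frames:
            raise ValueError("sequence has no frames")
        fw, fh = self.frame_size
        for frame_index, frame in enumerate(self.frames):
            if frame.ndim != 3 or frame.shape[2] != 3:
                raise ValueError(f"frame {frame_index} is not 3-channel colour")
            if frame.shape[:2] != (fh, fw):
                raise ValueError(f"frame {frame_index} size differs from frame 0")
        for (frame_index, side), obs in self.observations.items():
            if not (0 <= frame_index < self.n_frames):
                raise ValueError(f"observation frame index {frame_index} out of range")
            if obs.frame_index != frame_index or obs.side != side:
                raise ValueError("observation key disagrees with its contents")
            if obs.mask is not None and obs.mask.shape != (fh, fw):
                raise ValueError(
                    f"frame {frame_index}: mask shape {obs.mask.shape} does not match "
                    f"frame shape {(fh, fw)}"
                )
            if obs.box is not None:
                obs.box.clipped((fw, fh))  # raises if disjoint from the frame
            if self.is_no_interaction_task and obs.interacting is True:
                raise ValueError(
                    f"frame {frame_index}: interaction label inside a no-interaction task"
                )


@dataclass
class Dataset:
    """A cohort of task sequences plus per-subject metadata."""

    sequences: list[TaskSequence]
    subjects: dict[str, dict] = field(default_factory=dict)

    def validate(self) -> None:
        keys = [(s.subject_id, s.task_id) for s in self.sequences]
        if len(keys) != len(set(keys)):
            raise ValueError("(subject_id, task_id) pairs must be unique")

    @property
    def subject_ids(self) -> list[str]:
        out: list[str] = []
        for seq in self.sequences:
            if seq.subject_id not in out:
                out.append(seq.subject_id)
        return out

    def by_subject(self, subject_id: str) -> list[TaskSequence]:
        return [s for s in self.sequences if s.subject_id == subject_id]


# ---------------------------------------------------------------------------
# serialisation helpers

def _label_to_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, Role):
        return value.value
    return str(value)


def _cell_to_bool(cell: str) -> Optional[bool]:
    if cell == "":
        return None
    if cell not in ("true", "false"):
        raise ValueError(f"bad interacting cell {cell!r}")
    return cell == "true"


def write_task_sequence(seq: TaskSequence, root: Path | str) -> None:
    """Write a task sequence in the documented directory layout."""
    seq.validate()
    root = Path(root)
    (root / "frames").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(exist_ok=True)

    fw, fh = seq.frame_size
    meta = {
        "subject_id": seq.subject_id,
        "task_id": seq.task_id,
        "fps": float(seq.fps),
        "is_no_interaction_task": bool(seq.is_no_interaction_task),
        "n_frames": seq.n_frames,
        "width": fw,
        "height": fh,
    }
    (root / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))

    for i, frame in enumerate(seq.frames):
        iio.imwrite(root / "frames" / f"frame_{i:05d}.png", frame.astype(np.uint8))

    rows = []
    for (frame_index, side) in sorted(seq.observations, key=lambda k: (k[0], k[1].value)):
        obs = seq.observations[(frame_index, side)]
        box = obs.box
        rows.append(
            {
                "frame_index": frame_index,
                "side": side.value,
                "x": "" if box is None else box.x,
                "y": "" if box is None else box.y,
                "w": "" if box is None else box.w,
                "h": "" if box is None else box.h,
                "interacting": _label_to_cell(obs.interacting),
                "role": _label_to_cell(obs.role),
            }
        )
        if obs.mask is not None:
            mask_png = (obs.mask.raster.astype(np.uint8)) * 255
            iio.imwrite(root / "masks" / f"{side.value}_{frame_index:05d}.png", mask_png)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(root / "annotations.csv", index=False)


def _resize_sequence(seq: TaskSequence, target_size: tuple[int, int]) -> TaskSequence:
    """Rescale frames, masks and boxes to ``(width, height)``."""
    fw, fh = seq.frame_size
    tw, th = target_size
    if (fw, fh) == (tw, th):
        return seq
    sx, sy = tw / fw, th / fh
    frames = [
        (resize(f, (th, tw, 3), preserve_range=True, anti_aliasing=True)).astype(np.uint8)
        for f in seq.frames
    ]
    observations = {}
    for key, obs in seq.observations.items():
        mask = obs.mask
        if mask is not None:
            scaled = resize(mask.raster.astype(float), (th, tw), order=0, preserve_range=True)
            mask = HandMask(scaled > 0.5)
        box = obs.box.scaled(sx, sy).clipped((tw, th)) if obs.box is not None else None
        observations[key] = HandObservation(
            frame_index=obs.frame_index,
            side=obs.side,
            box=box,
            mask=mask,
            interacting=obs.interacting,
            role=obs.role,
        )
    return TaskSequence(
        subject_id=seq.subject_id,
        task_id=seq.task_id,
        fps=seq.fps,
        frames=frames,
        observations=observations,
        is_no_interaction_task=seq.is_no_interaction_task,
    )


def read_task_sequence(
    root: Path | str, target_size: Optional[tuple[int, int]] = None
) -> TaskSequence:
    """Read a task directory written by :func:`write_task_sequence`.

    Parameters
    ----------
    root:
        Task directory.
    target_size:
        Optional (width, height); when given and different from the stored
        resolution, frames, masks and boxes are rescaled proportionally
        (nearest-integer box coordinates).

    Frames missing from the numbered stack are a hard error; a mask whose
    dimensions differ from its frame is a hard error naming the frame.
    Hands without a row in the annotation table are unlabeled.
    """
    root = Path(root)
    meta = yaml.safe_load((root / "meta.yaml").read_text())
    n_frames = int(meta["n_frames"])
    fw, fh = int(meta["width"]), int(meta["height"])

    frames = []
    for i in range(n_frames):
        path = root / "frames" / f"frame_{i:05d}.png"
        if not path.exists():
            raise FileNotFoundError(f"missing frame {i}: {path}")
        frames.append(np.asarray(iio.imread(path)))

    table = pd.read_csv(root / "annotations.csv", dtype=str, keep_default_na=False)
    observations: dict[tuple[int, Side], HandObservation] = {}
    for _, row in table.iterrows():
        frame_index = int(row["frame_index"])
        side = Side(row["side"])
        box = None
        if row["x"] != "":
            box = BoundingBox(int(row["x"]), int(row["y"]), int(row["w"]), int(row["h"]))
        mask = None
        mask_path = root / "masks" / f"{side.value}_{frame_index:05d}.png"
        if mask_path.exists():
            raster = np.asarray(iio.imread(mask_path))
            if raster.shape != (fh, fw):
                raise ValueError(
                    f"frame {frame_index} ({side.value}): mask shape {raster.shape} "
                    f"does not match frame shape {(fh, fw)}"
                )
            mask = HandMask(raster > 127)
        role_cell = row["role"]
        observations[(frame_index, side)] = HandObservation(
            frame_index=frame_index,
            side=side,
            box=box,
            mask=mask,
            interacting=_cell_to_bool(row["interacting"]),
            role=None if role_cell == "" else Role(role_cell),
        )

    seq = TaskSequence(
        subject_id=str(meta["subject_id"]),
        task_id=str(meta["task_id"]),
        fps=float(meta["fps"]),
        frames=frames,
        observations=observations,
        is_no_interaction_task=bool(meta["is_no_interaction_task"]),
    )
    if target_size is not None:
        seq = _resize_sequence(seq, target_size)
    seq.validate()
    return seq


def write_dataset(dataset: Dataset, root: Path | str) -> None:
    """Write every sequence under ``root/<subject>/<task>/`` plus a manifest."""
    dataset.validate()
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for seq in dataset.sequences:
        rel = Path(seq.subject_id) / seq.task_id
        write_task_sequence(seq, root / rel)
        entries.append(str(rel))
    manifest = {"sequences": entries, "subjects": dataset.subjects}
    (root / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_dataset(root: Path | str, target_size: Optional[tuple[int, int]] = None) -> Dataset:
    root = Path(root)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    sequences = [read_task_sequence(root / rel, target_size) for rel in manifest["sequences"]]
    dataset = Dataset(sequences=sequences, subjects=manifest.get("subjects", {}))
    dataset.validate()
    return dataset
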