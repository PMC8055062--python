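"""Deterministic generator of annotated egocentric-like scenes.

The generator replaces two things that cannot ship with the package: the
study's videos, and the pretrained detection/segmentation networks whose
outputs (boxes, masks) the feature stages consume.  It plants exactly the
signals the feature families are built to detect:

* **colour** — during an interaction a distinctly-coloured object patch sits
  in the pixels surrounding the hand;
* **motion** — a manipulated object moves rigidly with its hand, so flow in
  the hand's surround matches the hand and differs from the background;
  non-interacting hands wave against a static background;
* **shape** — hands in contact with anything take a different (rotated)
  ellipse pose, so the HOG descriptor of the crop changes;
* **size change** — stabilizer hands keep a constant mask area while
  manipulator hands' areas fluctuate frame to frame.

Difficulty is also plantable: a *rest-contact* block puts a hand in
static contact with a full-size object without using it — visually a
stabilizer, semantically (and by label) not an interaction, exactly the
functional-purpose distinction that makes the real problem hard.

Hands are filled ellipses with internal texture that translates rigidly
with the hand (so dense flow has structure to track); objects are textured
rectangles; the background is a static smoothed-noise texture.  Gaussian
pixel noise is added after compositing.  Everything is driven by one seed:
the same config always produces bit-identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb
from skimage.draw import ellipse as draw_ellipse

from .data_model import (
    BoundingBox,
    Dataset,
    HandMask,
    HandObservation,
    Role,
    Side,
    TaskSequence,
)

__all__ = ["SceneConfig", "CohortConfig", "generate_task", "generate_cohort", "corrupt_boxes"]


@dataclass
class SceneConfig:
    """Parameters of one synthetic task.

    Hues are degrees in [0, 360).  ``interaction_segments`` is a list of
    ``(start_frame, end_frame, side, role)`` tuples with half-open frame
    ranges; segments for the same side must not overlap.  A config with no
    segments describes a no-interaction (hand-waving) task.
    """

    seed: int = 0
    n_frames: int = 150
    fps: float = 30.0
    frame_size: tuple[int, int] = (640, 360)  # (width, height)
    background_hue: float = 110.0
    hand_hue: float = 25.0
    object_hue: float = 215.0
    interaction_segments: list[tuple[int, int, Side, Role]] = field(default_factory=list)
    hand_speed: Optional[float] = None  # px/frame; default 0.02 * width
    area_jitter_manipulator: float = 0.25
    noise_sigma: float = 4.0  # std of additive pixel noise, 8-bit units
    object_scale: float = 1.0  # relative size of the object patch (difficulty dial)
    object_saturation: float = 0.85
    object_value: float = 0.62
    #: non-functional contact: blocks in which a hand rests statically on a
    #: full-size object without using it — visually identical to a
    #: stabilizer but labeled non-interacting (a hand resting on an object
    #: is not a functional interaction).  The second difficulty dial.
    rest_contact_segments: list[tuple[int, int, Side]] = field(default_factory=list)
    interaction_fraction_target: Optional[float] = None
    subject_id: str = "S0"
    task_id: str = "task0"
    #: hands that wave when the task has no segments at all
    waving_sides: tuple[Side, ...] = (Side.MORE_AFFECTED, Side.LESS_AFFECTED)

    def validate(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        hues = (self.background_hue, self.hand_hue, self.object_hue)
        if len({round(h, 6) for h in hues}) != 3:
            raise ValueError("background, hand and object hues must be pairwise distinct")
        per_side: dict[Side, list[tuple[int, int]]] = {}
        for start, end, side, role in self.interaction_segments:
            if not (0 <= start < end <= self.n_frames):
                raise ValueError(f"segment [{start}, {end}) outside [0, {self.n_frames})")
            if not isinstance(role, Role):
                raise ValueError(f"bad role {role!r}")
            per_side.setdefault(side, []).append((start, end))
        for start, end, side in self.rest_contact_segments:
            if not (0 <= start < end <= self.n_frames):
                raise ValueError(f"rest segment [{start}, {end}) outside [0, {self.n_frames})")
            per_side.setdefault(side, []).append((start, end))
        for side, spans in per_side.items():
            spans = sorted(spans)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping segments for {side.value}")


@dataclass
class CohortConfig:
    """Parameters of a synthetic multi-subject cohort.

    Each subject contributes ``tasks_per_subject`` bimanual interaction
    tasks (each hand interacts once per task, swapping stabilizer and
    manipulator roles halfway through its block) and, when enabled, two
    no-interaction tasks in which one hand waves in the air.  Per-subject
    ground-truth interaction fractions are spread monotonically across
    ``interaction_fraction_range`` for the less-affected hand, with the
    more-affected hand scaled down by ``more_affected_scale`` (stroke
    survivors use the more-affected hand less).

    When ``difficulty_inverse_to_fraction`` is set, low-use subjects are
    also the hardest to score: their object patches shrink
    (``object_scale_range``), their object hue drifts towards the
    background (``object_hue_range``), their pixel noise grows
    (``noise_sigma_range``), and — decisively — a growing share of their
    non-interaction time (up to ``max_rest_contact_fraction`` of each
    task) is spent in rest-contact blocks that are visually identical to
    stabilizer interactions.  This plants a positive F1-versus-
    interaction-percentage relation whose sign the correlation analysis
    must recover.
    """

    seed: int = 0
    n_subjects: int = 9
    tasks_per_subject: int = 6
    include_no_interaction_tasks: bool = True
    interaction_fraction_range: tuple[float, float] = (0.12, 0.35)
    more_affected_scale: float = 0.75
    n_frames: int = 120
    fps: float = 30.0
    frame_size: tuple[int, int] = (128, 72)
    difficulty_inverse_to_fraction: bool = True
    noise_sigma_range: tuple[float, float] = (2.0, 4.5)
    object_scale_range: tuple[float, float] = (0.35, 1.0)
    object_hue_range: tuple[float, float] = (165.0, 215.0)
    max_rest_contact_fraction: float = 0.14

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects for cross-validation")
        if self.tasks_per_subject < 1:
            raise ValueError("tasks_per_subject must be positive")
        lo, hi = self.interaction_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("interaction_fraction_range must satisfy 0 < low <= high < 1")


# ---------------------------------------------------------------------------
# rendering internals


def _texture(rng: np.random.Generator, shape: tuple[int, int], smooth: float, amp: float) -> np.ndarray:
    """Static smoothed-noise field in [-amp, amp]."""
    t = gaussian_filter(rng.standard_normal(shape), smooth)
    t /= max(np.abs(t).max(), 1e-9)
    return t * amp


def _segment_for(config: SceneConfig, side: Side, frame: int):
    for start, end, s, role in config.interaction_segments:
        if s == side and start <= frame < end:
            return start, end, role
    return None


def _resting_contact(config: SceneConfig, side: Side, frame: int) -> bool:
    return any(
        s == side and start <= frame < end
        for start, end, s in config.rest_contact_segments
    )


def generate_task(config: SceneConfig) -> TaskSequence:
    """Render one annotated task sequence from its config.

    Ground truth is exact by construction: interaction labels follow the
    configured segments, role labels exist only inside segments, masks are
    the rendered hand ellipses and boxes are their tight bounds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    W, H = config.frame_size
    speed = config.hand_speed if config.hand_speed is not None else 0.02 * W

    # static background texture (HSV)
    bg_h = (config.background_hue / 360.0 + _texture(rng, (H, W), 4.0, 0.02)) % 1.0
    bg_s = np.clip(0.40 + _texture(rng, (H, W), 4.0, 0.10), 0, 1)
    bg_v = np.clip(0.55 + _texture(rng, (H, W), 3.0, 0.18), 0, 1)

    # hand geometry: vertical ellipses, proportional to the frame
    rx = max(0.055 * W, 5.0)
    ry = 1.8 * rx
    homes = {
        Side.MORE_AFFECTED: (0.30 * W, 0.62 * H),
        Side.LESS_AFFECTED: (0.70 * W, 0.62 * H),
    }
    wave_amp = 0.12 * W
    # per-hand rigid internal texture (value channel), translated with the hand
    hand_tex = {side: _texture(rng, (H, W), 1.5, 0.22) for side in Side}
    obj_tex = _texture(rng, (H, W), 1.2, 0.25)
    wave_phase0 = {side: rng.uniform(0, 2 * np.pi) for side in Side}
    # per-frame area jitter for manipulator hands
    jitter = {
        side: 1.0 + config.area_jitter_manipulator * rng.uniform(-1, 1, size=config.n_frames)
        for side in Side
    }

    is_waving_task = len(config.interaction_segments) == 0
    frames: list[np.ndarray] = []
    observations: dict[tuple[int, Side], HandObservation] = {}

    obj_w = 1.6 * rx * config.object_scale  # object rectangle ~ hand scale
    obj_h = 1.4 * rx * config.object_scale

    for t in range(config.n_frames):
        h = bg_h.copy()
        s = bg_s.copy()
        v = bg_v.copy()
        per_side_state = {}

        for side in Side:
            hx, hy = homes[side]
            seg = _segment_for(config, side, t)
            resting_contact = seg is None and _resting_contact(config, side, t)
            if seg is not None:
                start, end, role = seg
                if role == Role.STABILIZER:
                    cx, cy = hx, hy - 0.08 * H  # static contact
                    scale = 1.0
                else:
                    # manipulator: the hand follows the same waving path as
                    # a non-interacting hand (movement alone must not give
                    # the interaction away); the object rides along and the
                    # mask area fluctuates
                    phase = wave_phase0[side] + (speed / wave_amp) * t
                    cx = hx + wave_amp * np.sin(phase)
                    cy = hy + 0.3 * wave_amp * np.sin(0.7 * phase)
                    scale = float(np.sqrt(jitter[side][t]))
                # grasp pose: ellipse rotated to horizontal
                axes = (ry * scale, rx * scale)
                interacting = True
            elif resting_contact:
                # appearance-identical to a stabilizer: static contact with
                # a full-size object, constant area — but non-functional,
                # hence labeled non-interacting
                cx, cy = hx, hy - 0.08 * H
                scale = 1.0
                axes = (ry, rx)
                interacting = False
            else:
                if is_waving_task and side not in config.waving_sides:
                    cx, cy = hx, hy  # resting hand
                    scale = 1.0
                else:
                    phase = wave_phase0[side] + (speed / wave_amp) * t
                    cx = hx + wave_amp * np.sin(phase)
                    cy = hy + 0.3 * wave_amp * np.sin(0.7 * phase)
                    # waving hands flicker too, so area change alone does
                    # not give the manipulator away
                    scale = float(np.sqrt(jitter[side][t]))
                axes = (rx * scale, ry * scale)
                interacting = False

            # keep the ellipse inside the frame
            cx = float(np.clip(cx, axes[0] + 1, W - axes[0] - 2))
            cy = float(np.clip(cy, axes[1] + 1, H - axes[1] - 2))
            per_side_state[side] = (cx, cy, axes, seg, resting_contact)

        # draw objects first (hands occlude them at the contact edge)
        for side in Side:
            cx, cy, axes, seg, resting_contact = per_side_state[side]
            if seg is None and not resting_contact:
                continue
            sign = -1.0 if side == Side.MORE_AFFECTED else 1.0
            # patch sits just beyond the hand's current horizontal extent,
            # inside the surround ring rather than occluded by the hand
            edge = 1.15 * axes[0]
            patch_w, patch_h = obj_w, obj_h
            ox, oy = cx + sign * edge, cy
            x1 = int(np.clip(round(ox - patch_w / 2), 0, W - 2))
            x2 = int(np.clip(round(ox + patch_w / 2), x1 + 1, W - 1))
            y1 = int(np.clip(round(oy - patch_h / 2), 0, H - 2))
            y2 = int(np.clip(round(oy + patch_h / 2), y1 + 1, H - 1))
            tex = np.roll(obj_tex, (int(round(oy - homes[side][1])), int(round(ox - homes[side][0]))), axis=(0, 1))
            h[y1:y2, x1:x2] = config.object_hue / 360.0
            s[y1:y2, x1:x2] = config.object_saturation
            v[y1:y2, x1:x2] = np.clip(config.object_value + tex[y1:y2, x1:x2], 0.05, 1.0)

        for side in Side:
            cx, cy, axes, _, _ = per_side_state[side]
            rr, cc = draw_ellipse(cy, cx, axes[1], axes[0], shape=(H, W))
            mask = np.zeros((H, W), dtype=bool)
            mask[rr, cc] = True
            tex = np.roll(
                hand_tex[side],
                (int(round(cy - homes[side][1])), int(round(cx - homes[side][0]))),
                axis=(0, 1),
            )
            h[mask] = config.hand_hue / 360.0
            s[mask] = 0.70
            v[mask] = np.clip(0.66 + tex[mask], 0.05, 1.0)

            hand_mask = HandMask(mask)
            obs_seg = per_side_state[side][3]
            observations[(t, side)] = HandObservation(
                frame_index=t,
                side=side,
                box=hand_mask.tight_box(),
                mask=hand_mask,
                interacting=obs_seg is not None,
                role=obs_seg[2] if obs_seg is not None else None,
            )

        rgb = hsv2rgb(np.stack([h, s, v], axis=-1)) * 255.0
        rgb += rng.normal(0.0, config.noise_sigma, size=rgb.shape)
        frames.append(np.clip(rgb, 0, 255).astype(np.uint8))

    seq = TaskSequence(
        subject_id=config.subject_id,
        task_id=config.task_id,
        fps=config.fps,
        frames=frames,
        observations=observations,
        is_no_interaction_task=is_waving_task,
    )
    seq.validate()
    return seq


# ---------------------------------------------------------------------------
# cohorts


def _place_rest_segment(
    n_frames: int,
    occupied: list[tuple[int, int]],
    length: int,
    rng: np.random.Generator,
) -> Optional[tuple[int, int]]:
    """Place a rest-contact block in the largest free gap of a task."""
    if length < 8:
        return None
    gaps = []
    busy = sorted(occupied)
    cursor = 4
    for a, b in busy:
        if a - cursor >= 8:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if n_frames - 4 - cursor >= 8:
        gaps.append((cursor, n_frames - 4))
    if not gaps:
        return None
    lo, hi = max(gaps, key=lambda g: g[1] - g[0])
    length = min(length, hi - lo - 2)
    if length < 8:
        return None
    start = int(rng.integers(lo + 1, hi - length))
    return start, start + length


def _task_seed(cohort_seed: int, subject_idx: int, task_idx: int) -> int:
    ss = np.random.SeedSequence([cohort_seed, subject_idx, task_idx])
    return int(ss.generate_state(1)[0])


def generate_cohort(config: CohortConfig) -> Dataset:
    """Generate a full cohort: subjects × (interaction + no-interaction tasks).

    Interaction tasks alternate bilateral (both hands interact, one as
    stabilizer and one as manipulator) and unilateral.  Segment lengths are
    sized so each subject's per-side ground-truth interaction percentage
    lands near its planted target; per-subject hand hue and background hue
    are jittered so subjects look different (a subject-specific appearance
    signal that subject-aware cross-validation can exploit).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.interaction_fraction_range
    n = config.n_subjects
    n_wave = 2 if config.include_no_interaction_tasks else 0
    n_tasks_total = config.tasks_per_subject + n_wave

    sequences: list[TaskSequence] = []
    subjects: dict[str, dict] = {}
    sig_lo, sig_hi = config.noise_sigma_range

    for si in range(n):
        subject_id = f"S{si:02d}"
        u = si / (n - 1) if n > 1 else 0.5
        frac_less = lo + (hi - lo) * u
        frac_more = frac_less * config.more_affected_scale
        obj_lo, obj_hi = config.object_scale_range
        hue_lo, hue_hi = config.object_hue_range
        if config.difficulty_inverse_to_fraction:
            # low-use subjects get smaller, duller (background-closer hue)
            # objects in noisier footage: a monotone difficulty gradient
            noise_sigma = sig_hi - (sig_hi - sig_lo) * u
            object_scale = obj_lo + (obj_hi - obj_lo) * u
            object_hue = hue_lo + (hue_hi - hue_lo) * u
            rest_fraction = config.max_rest_contact_fraction * (1.0 - u)
        else:
            noise_sigma = 0.5 * (sig_lo + sig_hi)
            object_scale = 0.5 * (obj_lo + obj_hi)
            object_hue = 0.5 * (hue_lo + hue_hi)
            rest_fraction = 0.0
        subjects[subject_id] = {
            "affected_image_side": "left",
            "target_fraction_more_affected": round(frac_more, 4),
            "target_fraction_less_affected": round(frac_less, 4),
            "noise_sigma": round(noise_sigma, 3),
        }
        hand_hue = 25.0 + rng.uniform(-12, 12)
        background_hue = 110.0 + rng.uniform(-15, 15)

        # every interaction task is bimanual: spreading each side's
        # interaction budget over all tasks keeps per-task fractions
        # moderate, which the smoothing + per-task normalization needs
        # every interaction task is bimanual; the last one is an "anchor"
        # task whose long interaction block (58 % of the task) keeps a
        # role track longer than half the smoothing window, so role
        # post-processing has at least one non-degenerate track per
        # subject.  The remaining tasks carry the variable fractions that
        # spread interaction percentages across subjects.
        anchor_ti = config.tasks_per_subject - 1
        anchor_frac = 0.58
        n_variable = max(config.tasks_per_subject - 1, 1)

        targets = {Side.MORE_AFFECTED: frac_more, Side.LESS_AFFECTED: frac_less}
        for ti in range(config.tasks_per_subject):
            segments = []
            for k, side in enumerate(Side):
                if ti == anchor_ti and config.tasks_per_subject > 1:
                    frac = anchor_frac
                else:
                    # size the variable tasks so the subject-level fraction
                    # (over tasks_per_subject + waving tasks) hits the target
                    base = (targets[side] * n_tasks_total - anchor_frac) / n_variable
                    frac = float(np.clip(base * rng.uniform(0.85, 1.15), 0.05, 0.5))
                total_len = max(int(round(frac * config.n_frames)), 16)
                total_len = min(total_len, config.n_frames - 24)
                # each hand swaps role mid-block, so role truth tracks vary
                # within the task (one constant role per task would collapse
                # to a degenerate track after min-max normalization); the
                # block is contiguous to keep the smoothed interaction truth
                # track well-conditioned
                first = Role.STABILIZER if (ti + k) % 2 == 0 else Role.MANIPULATOR
                second = Role.MANIPULATOR if first == Role.STABILIZER else Role.STABILIZER
                half = total_len // 2
                span = 2 * half
                start = int(rng.integers(4, max(config.n_frames - span - 4, 5)))
                segments.append((start, start + half, side, first))
                segments.append((start + half, start + span, side, second))
            rest_segments = []
            if rest_fraction > 0:
                for side in Side:
                    target = rest_fraction * config.n_frames * float(rng.uniform(0.8, 1.2))
                    span = _place_rest_segment(
                        config.n_frames,
                        [(a, b) for a, b, sd, _ in segments if sd == side],
                        int(round(target)),
                        rng,
                    )
                    if span is not None:
                        rest_segments.append((span[0], span[1], side))
            scfg = SceneConfig(
                seed=_task_seed(config.seed, si, ti),
                n_frames=config.n_frames,
                fps=config.fps,
                frame_size=config.frame_size,
                hand_hue=hand_hue,
                background_hue=background_hue,
                interaction_segments=segments,
                noise_sigma=noise_sigma,
                object_scale=object_scale,
                object_hue=object_hue,
                rest_contact_segments=rest_segments,
                subject_id=subject_id,
                task_id=f"task{ti:02d}",
            )
            sequences.append(generate_task(scfg))

        for wi in range(n_wave):
            waving = (Side.MORE_AFFECTED,) if wi == 0 else (Side.LESS_AFFECTED,)
            scfg = SceneConfig(
                seed=_task_seed(config.seed, si, config.tasks_per_subject + wi),
                n_frames=config.n_frames,
                fps=config.fps,
                frame_size=config.frame_size,
                hand_hue=hand_hue,
                background_hue=background_hue,
                interaction_segments=[],
                noise_sigma=noise_sigma,
                object_scale=object_scale,
                object_hue=object_hue,
                subject_id=subject_id,
                task_id=f"wave{wi}",
                waving_sides=waving,
            )
            sequences.append(generate_task(scfg))

    dataset = Dataset(sequences=sequences, subjects=subjects)
    dataset.validate()
    return dataset


def corrupt_boxes(
    seq: TaskSequence,
    shift: float = 0.0,
    scale: float = 1.0,
    drop_rate: float = 0.0,
    seed: int = 0,
) -> dict[tuple[int, Side], BoundingBox]:
    """Produce "predicted" boxes by perturbing ground-truth boxes.

    Stands in for an imperfect hand detector so IoU-based detection
    evaluation can be exercised: each box is shifted by up to ``shift``
    pixels per axis (uniform), scaled about its centre by ``scale``, and
    dropped entirely with probability ``drop_rate``.
    """
    rng = np.random.default_rng(seed)
    fw, fh = seq.frame_size
    out: dict[tuple[int, Side], BoundingBox] = {}
    for key, obs in seq.observations.items():
        if obs.box is None:
            continue
        if rng.uniform() < drop_rate:
            continue
        b = obs.box
        dx, dy = rng.uniform(-shift, shift, size=2)
        cx, cy = b.x + b.w / 2 + dx, b.y + b.h / 2 + dy
        w, h = max(b.w * scale, 1), max(b.h * scale, 1)
        box = BoundingBox(
            int(round(cx - w / 2)), int(round(cy - h / 2)), int(round(w)), int(round(h))
        )
        try:
            out[key] = box.clipped((fw, fh))
        except ValueError:
            continue  # corrupted box left the frame entirely
    return out
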