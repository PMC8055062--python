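"""Region-contrast feature extraction for hand-object interaction analysis.

For each annotated hand instance (one hand in one frame) the frame is split
into three nested regions around the hand's bounding box:

* **hand** — segmentation-mask pixels inside the box;
* **surround** — the box expanded about its centre (default factor 1.5),
  minus the hand pixels;
* **background** — everything outside the expanded box.

Four feature families are computed from these regions:

colour (6)
    Bhattacharyya distances between per-channel HSV histograms, for the
    hand-vs-surround and surround-vs-background pairings.  An object held
    by the hand puts unusual colours into the surround.
motion (60)
    Bin-wise differences of dense-optical-flow magnitude and direction
    histograms (15 normalized bins each) for the same two region pairings.
    A manipulated object moves with the hand, so the surround's flow
    matches the hand's and differs from the background's.
shape (60)
    A HOG descriptor of the resized box crop (40×72 px, 16×16-px cells,
    2×2-cell blocks, 9 unsigned orientation bins → 108 raw values),
    projected onto 60 principal components fitted on training data only.
size change (10)
    Forward differences of the hand-mask pixel count over the next 10
    frames, normalized by the current frame's count.  Distinguishes a
    stabilizing hand (constant contact area) from a manipulating one.

Conventions fixed for bit-reproducibility: flow is reported as (dx, dy)
with +dx rightward and +dy downward in image coordinates; the direction
histogram's bin 0 starts at angle 0 (east) and proceeds counter-clockwise
(angle = atan2(-dy, dx) mod 2π); magnitude histograms span [0, m99] where
m99 is the 99th-percentile magnitude over the whole frame, values above
m99 clipped into the top bin.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import hog as skimage_hog
from skimage.registration import optical_flow_ilk
from skimage.transform import resize

from .data_model import BoundingBox, HandMask, Side, TaskSequence

__all__ = [
    "FeatureConfig",
    "RegionPartition",
    "ShapeProjection",
    "RawInstanceFeatures",
    "partition_regions",
    "bhattacharyya_distance",
    "colour_features",
    "dense_flow",
    "motion_features",
    "hog_shape",
    "fit_shape_projection",
    "size_change_feature",
    "extract_task_features",
    "extract_instances",
    "assemble_features",
    "assemble_from_raw",
    "feature_schema",
    "schema_hash",
]

logger = logging.getLogger(__name__)

#: HOG crop geometry: (height, width) after resizing the box crop.
HOG_CROP_SHAPE = (72, 40)
HOG_RAW_LENGTH = 108  # 3 blocks × 4 cells × 9 orientations for the crop above


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable feature-extraction parameters (defaults are the pipeline's)."""

    expansion: float = 1.5
    hsv_bins: int = 32
    flow_bins: int = 15
    pca_components: int = 60
    size_change_horizon: int = 10
    flow_num_warp: int = 2
    flow_radius: int = 7

    def to_dict(self) -> dict:
        return {
            "expansion": self.expansion,
            "hsv_bins": self.hsv_bins,
            "flow_bins": self.flow_bins,
            "pca_components": self.pca_components,
            "size_change_horizon": self.size_change_horizon,
        }


def feature_schema(stage: str, config: FeatureConfig = FeatureConfig()) -> list[tuple[str, int]]:
    """Ordered (family, length) slices of the assembled feature row."""
    if stage == "interaction":
        return [("colour", 6), ("motion", 4 * config.flow_bins), ("shape", config.pca_components)]
    if stage == "role":
        return [
            ("motion", 4 * config.flow_bins),
            ("shape", config.pca_components),
            ("size_change", config.size_change_horizon),
        ]
    raise ValueError(f"unknown stage {stage!r}")


def schema_hash(stage: str, config: FeatureConfig = FeatureConfig()) -> str:
    payload = {"stage": stage, "schema": feature_schema(stage, config), **config.to_dict()}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# regions


@dataclass
class RegionPartition:
    """Boolean membership rasters for the hand / surround / background split."""

    hand: np.ndarray
    surround: np.ndarray
    background: np.ndarray

    @property
    def hand_empty(self) -> bool:
        return not self.hand.any()

    def counts(self) -> tuple[int, int, int]:
        return int(self.hand.sum()), int(self.surround.sum()), int(self.background.sum())


def partition_regions(
    frame_size: tuple[int, int],
    box: BoundingBox,
    mask: HandMask,
    expansion: float = 1.5,
) -> RegionPartition:
    """Split the frame into hand / surround / background pixel sets.

    The three sets are pairwise disjoint and cover the frame exactly:
    hand = mask ∩ box, surround = expanded box minus hand, background =
    frame minus expanded box.  An empty hand set (mask misses the box) is
    allowed but flagged via :attr:`RegionPartition.hand_empty`.
    """
    fw, fh = frame_size
    box = box.clipped(frame_size)
    expanded = box.expanded(expansion, frame_size)

    in_box = np.zeros((fh, fw), dtype=bool)
    in_box[box.slices()] = True
    in_expanded = np.zeros((fh, fw), dtype=bool)
    in_expanded[expanded.slices()] = True

    hand = mask.raster & in_box
    surround = in_expanded & ~hand
    background = ~in_expanded
    return RegionPartition(hand=hand, surround=surround, background=background)


# ---------------------------------------------------------------------------
# colour


def _hist_from_indices(idx: np.ndarray, bins: int) -> np.ndarray:
    """Normalized histogram from precomputed bin indices (uniform if empty)."""
    if idx.size == 0:
        return np.full(bins, 1.0 / bins)
    return np.bincount(idx, minlength=bins) / idx.size


def _bin_indices(values: np.ndarray, bins: int, upper: float) -> np.ndarray:
    """Map values in [0, upper] to integer bins 0..bins-1 (top edge closed)."""
    return np.clip((values * (bins / upper)).astype(np.int32), 0, bins - 1)


def bhattacharyya_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Bhattacharyya distance ``sqrt(1 − Σ sqrt(h1·h2))`` between two
    normalized histograms.

    0 for identical histograms, 1 for disjoint supports.  Inputs must
    already be normalized (sum 1); this function refuses to normalize
    implicitly.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError("histograms must have the same number of bins")
    for h in (h1, h2):
        if np.any(h < 0) or abs(h.sum() - 1.0) > 1e-6:
            raise ValueError("histograms must be normalized to sum 1")
    bc = float(np.sum(np.sqrt(h1 * h2)))
    return float(np.sqrt(max(0.0, 1.0 - min(bc, 1.0))))


def colour_features(
    frame_hsv: np.ndarray, partition: RegionPartition, n_bins: int = 32
) -> np.ndarray:
    """Six HSV-histogram Bhattacharyya distances.

    Order: (H, S, V) hand-vs-surround, then (H, S, V) surround-vs-background.
    ``frame_hsv`` is the frame already converted to HSV with channels in
    [0, 1].  Empty regions (e.g. a box covering the whole frame leaves no
    background) are represented by uniform histograms and logged.
    """
    return _colour_from_indices(_bin_indices(frame_hsv, n_bins, 1.0), partition, n_bins)


def _colour_from_indices(
    hsv_idx: np.ndarray, partition: RegionPartition, n_bins: int
) -> np.ndarray:
    out = np.empty(6)
    hists: dict[str, list[np.ndarray]] = {}
    for name, region in (("hand", partition.hand), ("surround", partition.surround), ("background", partition.background)):
        pix = hsv_idx[region]
        if pix.size == 0:
            logger.debug("empty %s region: uniform histograms substituted", name)
        hists[name] = [_hist_from_indices(pix[:, c], n_bins) for c in range(3)]
    for c in range(3):
        out[c] = bhattacharyya_distance(hists["hand"][c], hists["surround"][c])
        out[3 + c] = bhattacharyya_distance(hists["surround"][c], hists["background"][c])
    return out


# ---------------------------------------------------------------------------
# motion


def dense_flow(
    prev: np.ndarray, curr: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Dense optical flow between consecutive frames.

    Returns an (H, W, 2) array of per-pixel displacements ``(dx, dy)``
    describing content motion from ``prev`` to ``curr`` (+dx rightward,
    +dy downward).  The algorithm is pluggable behind this contract; the
    default is iterative Lucas-Kanade dense flow.
    """
    if prev.shape != curr.shape:
        raise ValueError("frames must share dimensions")
    g0 = rgb2gray(prev) if prev.ndim == 3 else prev.astype(float)
    g1 = rgb2gray(curr) if curr.ndim == 3 else curr.astype(float)
    v = optical_flow_ilk(
        g0, g1, radius=config.flow_radius, num_warp=config.flow_num_warp
    )
    return np.stack([v[1], v[0]], axis=-1)


def _flow_bin_indices(flow: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel magnitude and direction bin indices for one flow field.

    Magnitude bins span [0, m99] (99th-percentile magnitude over the
    frame, larger values clipped into the top bin); direction bins span
    [0, 2π) with angle = atan2(−dy, dx).
    """
    mag = np.hypot(flow[..., 0], flow[..., 1])
    m_max = float(np.percentile(mag, 99))
    if m_max <= 0:
        m_max = 1.0
    direction = np.arctan2(-flow[..., 1], flow[..., 0]) % (2 * np.pi)
    return (
        _bin_indices(np.clip(mag, 0.0, m_max), n_bins, m_max),
        _bin_indices(direction, n_bins, 2 * np.pi),
    )


def _motion_from_indices(
    mag_idx: np.ndarray, dir_idx: np.ndarray, partition: RegionPartition, n_bins: int
) -> np.ndarray:
    hists = {}
    for name, region in (("hand", partition.hand), ("surround", partition.surround), ("background", partition.background)):
        hists[name] = (
            _hist_from_indices(mag_idx[region], n_bins),
            _hist_from_indices(dir_idx[region], n_bins),
        )
    (mh, dh), (ms, ds), (mb, db) = hists["hand"], hists["surround"], hists["background"]
    return np.concatenate([mh - ms, dh - ds, ms - mb, ds - db])


def motion_features(
    flow: np.ndarray, partition: RegionPartition, n_bins: int = 15
) -> np.ndarray:
    """Bin-wise flow-histogram differences between the region pairs.

    Order: magnitude(hand − surround), direction(hand − surround),
    magnitude(surround − background), direction(surround − background);
    each block has ``n_bins`` values, 60 in total with the default 15 bins.
    """
    mag_idx, dir_idx = _flow_bin_indices(flow, n_bins)
    return _motion_from_indices(mag_idx, dir_idx, partition, n_bins)


# ---------------------------------------------------------------------------
# shape


def hog_shape(frame: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Raw HOG descriptor of the resized box crop.

    The crop is resized to 40×72 (width × height); cells are 16×16 px,
    blocks 2×2 cells with one-cell stride, 9 unsigned orientation bins,
    L2-Hys block normalization.  With 2×4 whole cells this gives 1×3
    blocks × 4 cells × 9 orientations = 108 values.
    """
    if box.w < 2 or box.h < 2:
        raise ValueError("degenerate box: need at least 2×2 pixels for gradients")
    crop = frame[box.slices()]
    gray = rgb2gray(crop) if crop.ndim == 3 else crop.astype(float)
    resized = resize(gray, HOG_CROP_SHAPE, anti_aliasing=True)
    vec = skimage_hog(
        resized,
        orientations=9,
        pixels_per_cell=(16, 16),
        cells_per_block=(2, 2),
        block_norm="L2-Hys",
        feature_vector=True,
    )
    assert vec.shape == (HOG_RAW_LENGTH,)
    return vec


@dataclass
class ShapeProjection:
    """Mean-centred PCA projection of raw HOG vectors."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, raw_length), orthonormal rows

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def raw_length(self) -> int:
        return self.components.shape[1]

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(raw)
        if raw.shape[1] != self.raw_length:
            raise ValueError("raw HOG length does not match the fitted projection")
        return (raw - self.mean) @ self.components.T


def fit_shape_projection(raw_hogs: np.ndarray, n_components: int = 60) -> ShapeProjection:
    """Fit the PCA that reduces raw HOG vectors to ``n_components`` values.

    Must be fitted on training-fold data only; the cross-validation
    harnesses do this per fold.  Requires strictly more samples than
    components.
    """
    from sklearn.decomposition import PCA

    raw_hogs = np.asarray(raw_hogs, dtype=float)
    if raw_hogs.ndim != 2:
        raise ValueError("expected a 2-D array of raw HOG vectors")
    if raw_hogs.shape[0] <= n_components:
        raise ValueError(
            f"PCA needs more than {n_components} training vectors, got "
            f"{raw_hogs.shape[0]}; configure a smaller component count for toy runs"
        )
    pca = PCA(n_components=n_components, svd_solver="covariance_eigh")
    pca.fit(raw_hogs)
    return ShapeProjection(mean=pca.mean_.copy(), components=pca.components_.copy())


# ---------------------------------------------------------------------------
# size change


def size_change_feature(areas: np.ndarray, t: int, horizon: int = 10) -> np.ndarray:
    """Normalized forward differences of the hand-mask area.

    ``[(areas[t+k+1] − areas[t+k]) / areas[t] for k in 0..horizon-1]``;
    differences reaching past the end of the sequence contribute 0.
    """
    areas = np.asarray(areas, dtype=float)
    if not (0 <= t < areas.size):
        raise ValueError("frame index out of range")
    if areas[t] <= 0:
        raise ValueError(f"no hand pixels at frame {t}; skip instances without a mask")
    out = np.zeros(horizon)
    for k in range(horizon):
        if t + k + 1 < areas.size:
            out[k] = (areas[t + k + 1] - areas[t + k]) / areas[t]
    return out


# ---------------------------------------------------------------------------
# per-task extraction


@dataclass
class RawInstanceFeatures:
    """Pre-PCA features for every includable instance of one hand in one task.

    Label encoding: ``interacting`` 1/0 with −1 for unlabeled frames;
    ``role`` 1 = manipulator, 0 = stabilizer, −1 = no role label.
    """

    subject_id: str
    task_id: str
    side: Side
    is_no_interaction_task: bool
    frame_indices: np.ndarray
    colour: np.ndarray  # (n, 6)
    motion: np.ndarray  # (n, 60)
    hog_raw: np.ndarray  # (n, 108)
    size_change: np.ndarray  # (n, 10)
    interacting: np.ndarray  # (n,) int8
    role: np.ndarray  # (n,) int8

    @property
    def n_instances(self) -> int:
        return self.frame_indices.size


def extract_task_features(
    seq: TaskSequence, config: FeatureConfig = FeatureConfig()
) -> dict[Side, RawInstanceFeatures]:
    """Extract raw features for both hands of one task in a single pass.

    HSV conversion and dense flow are computed once per frame and shared
    between hands.  The first frame of a task has a zero flow field (its
    motion features are zeros; the row is retained).  Frames missing a box
    or mask for a hand are excluded for that hand and logged.
    """
    fw, fh = seq.frame_size
    per_side: dict[Side, dict[str, list]] = {
        side: {k: [] for k in ("idx", "colour", "motion", "hog", "interacting", "role")}
        for side in Side
    }
    areas = {side: np.zeros(seq.n_frames) for side in Side}
    for side in Side:
        for t in range(seq.n_frames):
            obs = seq.get(t, side)
            if obs is not None and obs.mask is not None:
                areas[side][t] = obs.mask.area

    prev_frame: Optional[np.ndarray] = None
    for t, frame in enumerate(seq.frames):
        # per-frame work shared between the two hands: HSV bin indices and
        # flow magnitude/direction bin indices are computed once
        hsv_idx = _bin_indices(rgb2hsv(frame), config.hsv_bins, 1.0)
        if prev_frame is None:
            flow = np.zeros((fh, fw, 2))
        else:
            flow = dense_flow(prev_frame, frame, config)
        prev_frame = frame
        mag_idx, dir_idx = _flow_bin_indices(flow, config.flow_bins)

        for side in Side:
            obs = seq.get(t, side)
            if obs is None or obs.box is None or obs.mask is None:
                if obs is not None:
                    logger.debug(
                        "%s/%s frame %d %s: missing box or mask, instance excluded",
                        seq.subject_id, seq.task_id, t, side.value,
                    )
                continue
            partition = partition_regions((fw, fh), obs.box, obs.mask, config.expansion)
            if partition.hand_empty:
                logger.debug(
                    "%s/%s frame %d %s: empty hand region, instance excluded",
                    seq.subject_id, seq.task_id, t, side.value,
                )
                continue
            acc = per_side[side]
            acc["idx"].append(t)
            acc["colour"].append(_colour_from_indices(hsv_idx, partition, config.hsv_bins))
            acc["motion"].append(_motion_from_indices(mag_idx, dir_idx, partition, config.flow_bins))
            acc["hog"].append(hog_shape(frame, obs.box))
            acc["interacting"].append(
                -1 if obs.interacting is None else int(obs.interacting)
            )
            acc["role"].append(-1 if obs.role is None else int(obs.role.value == "manipulator"))

    out = {}
    for side in Side:
        acc = per_side[side]
        idx = np.asarray(acc["idx"], dtype=int)
        size_change = np.zeros((idx.size, config.size_change_horizon))
        for r, t in enumerate(idx):
            if areas[side][t] > 0:
                size_change[r] = size_change_feature(
                    areas[side], t, config.size_change_horizon
                )
        out[side] = RawInstanceFeatures(
            subject_id=seq.subject_id,
            task_id=seq.task_id,
            side=side,
            is_no_interaction_task=seq.is_no_interaction_task,
            frame_indices=idx,
            colour=np.asarray(acc["colour"]).reshape(idx.size, 6),
            motion=np.asarray(acc["motion"]).reshape(idx.size, 4 * config.flow_bins),
            hog_raw=np.asarray(acc["hog"]).reshape(idx.size, HOG_RAW_LENGTH),
            size_change=size_change,
            interacting=np.asarray(acc["interacting"], dtype=np.int8),
            role=np.asarray(acc["role"], dtype=np.int8),
        )
    return out


def extract_instances(
    seq: TaskSequence, side: Side, config: FeatureConfig = FeatureConfig()
) -> RawInstanceFeatures:
    """Raw features for one hand of one task (see :func:`extract_task_features`)."""
    return extract_task_features(seq, config)[side]


def assemble_from_raw(
    raw: RawInstanceFeatures,
    stage: str,
    projection: ShapeProjection,
    config: FeatureConfig = FeatureConfig(),
    families: Optional[list[str]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the final feature matrix for one (task, hand).

    Returns ``(X, frame_indices, labels)`` with labels encoded as in
    :class:`RawInstanceFeatures` (−1 = unlabeled, excluded from training
    and metrics by the harnesses).  ``families`` optionally restricts the
    matrix to a subset of feature families (used by the ablation study).
    """
    blocks = {
        "colour": raw.colour,
        "motion": raw.motion,
        "shape": projection.apply(raw.hog_raw) if raw.n_instances else np.zeros((0, projection.n_components)),
        "size_change": raw.size_change,
    }
    schema = feature_schema(stage, config)
    selected = [name for name, _ in schema if families is None or name in families]
    if not selected:
        raise ValueError(f"no feature families selected from {families!r}")
    X = np.concatenate([blocks[name] for name in selected], axis=1) if raw.n_instances else np.zeros((0, 0))
    if stage == "interaction":
        labels = raw.interacting.copy()
        keep = np.ones(raw.n_instances, dtype=bool)
    else:
        labels = raw.role.copy()
        keep = raw.role >= 0  # role rows exist only where a role is labeled
    return X[keep], raw.frame_indices[keep], labels[keep]


def assemble_features(
    seq: TaskSequence,
    side: Side,
    stage: str,
    projection: ShapeProjection,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract and assemble the feature matrix for one hand of one task."""
    raw = extract_instances(seq, side, config)
    return assemble_from_raw(raw, stage, projection, config)
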