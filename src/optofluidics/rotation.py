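"""Rotational-behavior quantification from pose-keypoint tracks.

A mouse's heading is summarized per video frame by a body vector running
from the "back" (centroid of the two hind legs and the tail base) to the
"head" (centroid of the snout and both ears).  One frame is selected per
time bin (default 0.5 s); the signed angle between consecutive body
vectors,

    theta = degrees( atan2(x1*y2 - y1*x2, x1*x2 + y1*y2) ),

is the per-bin rotation.  Signed angles in (-180, 180] make the turning
direction explicit, so left and right totals and their ratio are well
defined; a per-bin rotation of 180 deg or more is aliased by construction
and cannot be recovered.

Pose tables use the DeepLabCut CSV dialect: three header rows
(scorer / bodyparts / coords) with x, y, likelihood per bodypart.  Image
coordinates have y growing downward; with the default ``y_down=True`` a
positive theta means a left (counter-clockwise as seen in the video) turn.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KEYPOINTS",
    "HEAD_PARTS",
    "BACK_PARTS",
    "PoseTrack",
    "BodyVectorSeries",
    "RotationSeries",
    "PoseSchemaError",
    "read_pose_csv",
    "filter_confidence",
    "compute_body_vectors",
    "frame_rotation_angle",
    "rotation_angles",
    "summarize_rotation",
    "quantify_rotation",
]

KEYPOINTS = ("snout", "ear_left", "ear_right", "leg_left", "leg_right", "tail_base")
HEAD_PARTS = ("snout", "ear_left", "ear_right")
BACK_PARTS = ("leg_left", "leg_right", "tail_base")


class PoseSchemaError(ValueError):
    """Pose CSV does not follow the expected three-row-header dialect."""


@dataclass
class PoseTrack:
    """Per-frame keypoint coordinates with likelihoods for one animal.

    ``data`` has MultiIndex columns (bodypart, coord) with coords
    x, y, likelihood for each canonical bodypart; rows are frames.
    """

    data: pd.DataFrame
    fps: float = 25.0

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("pose track must contain at least one frame")
        missing = [p for p in KEYPOINTS if p not in self.data.columns.levels[0]]
        if missing:
            raise PoseSchemaError(f"missing required bodyparts: {missing}")
        lk = self.data.loc[:, (slice(None), "likelihood")].to_numpy(dtype=float)
        finite = lk[np.isfinite(lk)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("likelihoods must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class BodyVectorSeries:
    """One body vector per time bin; invalid bins carry NaN and valid=False."""

    table: pd.DataFrame  # bin_t_s, head_x, head_y, back_x, back_y, vx, vy, valid
    bin_s: float

    @property
    def vectors(self) -> np.ndarray:
        return self.table[["vx", "vy"]].to_numpy()


@dataclass
class RotationSeries:
    """Per-bin signed rotation angles plus cumulative and directional totals.

    Positive theta = left turn (counter-clockwise in the video view).
    ``lr_ratio`` is +inf when no rightward rotation occurred.
    """

    table: pd.DataFrame  # bin_t_s, theta_deg, cum_deg, valid
    total_deg: float
    left_deg: float
    right_deg: float
    lr_ratio: float
    n_valid_bins: int

    def summary(self) -> dict:
        return {
            "total_deg": self.total_deg,
            "left_deg": self.left_deg,
            "right_deg": self.right_deg,
            "lr_ratio": self.lr_ratio,
            "n_valid_bins": self.n_valid_bins,
        }


def read_pose_csv(
    path,
    aliases: dict[str, str] | None = None,
    fps: float = 25.0,
) -> PoseTrack:
    """Read a DeepLabCut-dialect pose CSV.

    Expects three header rows (scorer / bodyparts / coords) and per-bodypart
    x, y, likelihood columns.  ``aliases`` maps file bodypart names to the
    canonical roles in :data:`KEYPOINTS`; extra bodyparts are ignored with
    a warning.
    """
    try:
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise PoseSchemaError(f"not a three-header-row pose CSV: {exc}") from exc
    if raw.columns.nlevels != 3:
        raise PoseSchemaError("expected scorer/bodyparts/coords header rows")
    coords_level = {c.lower() for c in raw.columns.get_level_values(2)}
    if not {"x", "y", "likelihood"} <= coords_level:
        raise PoseSchemaError(
            "third header row must contain x, y and likelihood columns"
        )
    raw.columns = pd.MultiIndex.from_arrays(
        [raw.columns.get_level_values(1), raw.columns.get_level_values(2).str.lower()]
    )
    aliases = aliases or {}
    rename = {name: aliases.get(name, name) for name in raw.columns.levels[0]}
    raw = raw.rename(columns=rename, level=0)
    present = set(raw.columns.get_level_values(0))
    missing = [p for p in KEYPOINTS if p not in present]
    if missing:
        raise PoseSchemaError(f"missing required bodyparts: {missing}")
    extras = sorted(present - set(KEYPOINTS))
    if extras:
        warnings.warn(f"ignoring extra bodyparts: {extras}", stacklevel=2)
    data = raw.loc[:, [(p, c) for p in KEYPOINTS for c in ("x", "y", "likelihood")]]
    data = data.astype(float).reset_index(drop=True)
    return PoseTrack(data, fps=fps)


def filter_confidence(track: PoseTrack, p_cutoff: float = 0.6) -> PoseTrack:
    """Mask keypoints whose likelihood falls below ``p_cutoff``.

    Masked keypoints become NaN; downstream centroids are taken over the
    remaining members of each group.
    """
    data = track.data.copy()
    for part in KEYPOINTS:
        bad = data[(part, "likelihood")] < p_cutoff
        data.loc[bad, (part, "x")] = np.nan
        data.loc[bad, (part, "y")] = np.nan
    return PoseTrack(data, fps=track.fps)


def _centroid(data: pd.DataFrame, parts: tuple[str, ...]) -> np.ndarray:
    xs = data.loc[:, [(p, "x") for p in parts]].to_numpy(dtype=float)
    ys = data.loc[:, [(p, "y") for p in parts]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.stack([np.nanmean(xs, axis=1), np.nanmean(ys, axis=1)], axis=1)


def compute_body_vectors(track: PoseTrack, bin_s: float = 0.5) -> BodyVectorSeries:
    """One back-to-head body vector per time bin.

    The first frame at/after each bin start represents the bin.  Bins whose
    head or back centroid has no valid member are flagged invalid.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n = track.n_frames
    duration = n / track.fps
    n_bins = max(1, int(math.floor(duration / bin_s + 1e-9)))
    frames = np.minimum(
        np.ceil(np.arange(n_bins) * bin_s * track.fps - 1e-9).astype(int), n - 1
    )
    sub = track.data.iloc[frames]
    head = _centroid(sub, HEAD_PARTS)
    back = _centroid(sub, BACK_PARTS)
    v = head - back
    valid = np.isfinite(v).all(axis=1) & (np.linalg.norm(v, axis=1) > 0)
    table = pd.DataFrame(
        {
            "bin_t_s": np.arange(n_bins) * bin_s,
            "frame": frames,
            "head_x": head[:, 0],
            "head_y": head[:, 1],
            "back_x": back[:, 0],
            "back_y": back[:, 1],
            "vx": v[:, 0],
            "vy": v[:, 1],
            "valid": valid,
        }
    )
    return BodyVectorSeries(table, bin_s)


def frame_rotation_angle(v1, v2) -> float:
    """Signed angle from ``v1`` to ``v2`` in degrees, range (-180, 180].

    degrees(atan2(x1*y2 - y1*x2, x1*x2 + y1*y2)); positive is
    counter-clockwise in standard (y-up) axes.
    """
    x1, y1 = float(v1[0]), float(v1[1])
    x2, y2 = float(v2[0]), float(v2[1])
    if (x1 == 0.0 and y1 == 0.0) or (x2 == 0.0 and y2 == 0.0):
        raise ValueError("body vectors must be non-zero")
    ang = math.degrees(math.atan2(x1 * y2 - y1 * x2, x1 * x2 + y1 * y2))
    if ang <= -180.0:
        ang = 180.0
    return ang


def rotation_angles(series: BodyVectorSeries, y_down: bool = True) -> pd.DataFrame:
    """Per-bin signed rotation between consecutive valid body vectors.

    With ``y_down`` (image coordinates), the sign is flipped so that a
    positive angle is a left turn as seen in the video.  A bin following an
    invalid bin gets NaN; the cumulative sum carries forward unchanged over
    invalid bins.
    """
    tab = series.table
    n = len(tab)
    theta = np.full(n, np.nan)
    sign = -1.0 if y_down else 1.0
    last_valid = None
    for k in range(n):
        if not tab["valid"].iloc[k]:
            continue
        v = (tab["vx"].iloc[k], tab["vy"].iloc[k])
        if last_valid is not None:
            theta[k] = sign * frame_rotation_angle(last_valid, v)
        last_valid = v
    cum = np.nancumsum(theta)
    out = pd.DataFrame(
        {
            "bin_t_s": tab["bin_t_s"],
            "theta_deg": theta,
            "cum_deg": cum,
            "valid": np.isfinite(theta),
        }
    )
    return out


def summarize_rotation(angles: pd.DataFrame) -> RotationSeries:
    """Directional totals from a per-bin angle table.

    total = final cumulative signed rotation; left = sum of positive bins;
    right = |sum of negative bins|; their ratio is +inf when right is zero.
    """
    valid = angles["valid"].to_numpy(dtype=bool)
    if not valid.any():
        raise ValueError("no valid rotation bins to summarize")
    theta = angles["theta_deg"].to_numpy()
    left = float(np.nansum(np.where(theta > 0, theta, 0.0)))
    right = float(abs(np.nansum(np.where(theta < 0, theta, 0.0))))
    ratio = left / right if right > 0 else math.inf
    return RotationSeries(
        table=angles,
        total_deg=float(angles["cum_deg"].iloc[-1]),
        left_deg=left,
        right_deg=right,
        lr_ratio=ratio,
        n_valid_bins=int(valid.sum()),
    )


def quantify_rotation(
    track: PoseTrack,
    p_cutoff: float = 0.6,
    bin_s: float = 0.5,
    y_down: bool = True,
) -> RotationSeries:
    """Full pipeline: confidence filter, body vectors, angles, summary."""
    filtered = filter_confidence(track, p_cutoff)
    vectors = compute_body_vectors(filtered, bin_s)
    angles = rotation_angles(vectors, y_down=y_down)
    return summarize_rotation(angles)
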