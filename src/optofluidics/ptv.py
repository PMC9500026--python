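"""Micro-particle tracking velocimetry (micro-PTV) pipeline.

Recovers Lagrangian tracer trajectories from grayscale image stacks and
turns them into an Eulerian velocity field and a channel flow-rate
estimate.  Processing stages mirror standard micro-PTV practice:

1. sub-pixel spot detection (intensity-weighted centroids);
2. frame-to-frame linking by minimum total squared displacement
   (Hungarian assignment with a hard displacement gate);
3. gap closing: re-joining track ends to starts across dropouts of up to
   three frames;
4. trajectory smoothing with fourth-order (cubic) least-squares B-splines,
   whose analytic derivatives give the Lagrangian velocities;
5. grid averaging into an Eulerian field and a flow-rate fit against the
   analytic square-duct profile.

Coordinate convention: origin at the channel corner, ``x`` streamwise,
``y`` across the channel, units micrometres; the time of frame ``k`` is
``k / frame_rate``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline
from scipy.optimize import linear_sum_assignment
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .duct import midplane_profile

__all__ = [
    "ImagingSpec",
    "TrajectorySet",
    "EulerianField",
    "FlowRateEstimate",
    "detect_particles",
    "link_frames",
    "link_detections",
    "close_gaps",
    "smooth_tracks",
    "to_eulerian",
    "estimate_flow_rate",
    "flow_rate_series",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


@dataclass(frozen=True)
class ImagingSpec:
    """Camera and optics parameters of the tracer movie."""

    frame_rate: float = 640.0  # Hz
    pixel_size: float = 0.64  # um / pixel
    field_of_view: tuple[float, float] = (500.0, 30.0)  # (x, y) um

    def __post_init__(self) -> None:
        if min(self.frame_rate, self.pixel_size, *self.field_of_view) <= 0:
            raise ValueError("imaging parameters must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (rows, cols) = (y, x) in pixels."""
        return (
            int(round(self.field_of_view[1] / self.pixel_size)),
            int(round(self.field_of_view[0] / self.pixel_size)),
        )


@dataclass
class TrajectorySet:
    """Lagrangian tracks as a tidy table plus the linking parameters used.

    ``tracks`` columns: track_id, frame, t_s, x_um, y_um and, after
    smoothing, u_um_s, v_um_s and a ``smoothed`` flag.
    """

    tracks: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_tracks(self) -> int:
        return int(self.tracks["track_id"].nunique()) if len(self.tracks) else 0

    def lengths(self) -> pd.Series:
        return self.tracks.groupby("track_id").size()

    def to_csv(self, path) -> None:
        self.tracks.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectorySet":
        return cls(pd.read_csv(path))


@dataclass
class EulerianField:
    """Cell-averaged velocities on a fixed grid; empty cells are NaN with
    count 0, never silently zero-filled."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    u: np.ndarray  # shape (ny, nx), um/s
    v: np.ndarray
    counts: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[1:] + self.x_edges[:-1])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[1:] + self.y_edges[:-1])

    def to_frame(self) -> pd.DataFrame:
        yy, xx = np.meshgrid(self.y_centers, self.x_centers, indexing="ij")
        return pd.DataFrame(
            {
                "x_um": xx.ravel(),
                "y_um": yy.ravel(),
                "u_um_s": self.u.ravel(),
                "v_um_s": self.v.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass
class FlowRateEstimate:
    """Flow-rate fit result; ``flow_rate`` in m^3/s."""

    flow_rate: float
    coverage: float
    low_confidence: bool


# ---------------------------------------------------------------------------
# detection


def detect_particles(
    stack: np.ndarray,
    spec: ImagingSpec,
    threshold: float | None = None,
    subtract_background: bool = True,
    min_area: int = 2,
) -> pd.DataFrame:
    """Sub-pixel particle detection on a grayscale stack.

    The per-pixel temporal median serves as the background estimate when
    ``subtract_background`` is set.  Connected regions above ``threshold``
    (default: median + 5 MAD-sigma of the corrected stack) are reduced to
    intensity-weighted centroids.  Returns a table with columns
    frame, x_um, y_um, mass; frames with no spots simply contribute no rows.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    work = stack - np.median(stack, axis=0) if subtract_background else stack
    if threshold is None:
        # robust noise floor of the (signed) residual; spots are rare so the
        # median/MAD reflect the background
        med = float(np.median(work))
        mad = float(np.median(np.abs(work - med)))
        threshold = med + 5.0 * 1.4826 * mad
        if mad == 0.0:
            threshold = 0.5 * float(work.max()) if work.size else 0.0
    work = np.clip(work, 0.0, None)
    rows = []
    for k, frame in enumerate(work):
        lbl = sk_label(frame > threshold)
        for region in regionprops(lbl, intensity_image=frame):
            if region.area < min_area:
                continue
            r, c = region.centroid_weighted
            rows.append(
                {
                    "frame": k,
                    "x_um": c * spec.pixel_size,
                    "y_um": r * spec.pixel_size,
                    "mass": float(region.image_intensity.sum()),
                }
            )
    det = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "mass"])
    fov_x, fov_y = spec.field_of_view
    return det[(det["x_um"] <= fov_x) & (det["y_um"] <= fov_y)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# linking


def link_frames(
    d_t: np.ndarray, d_t1: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    """One-to-one assignment between detections of consecutive frames.

    Minimizes total squared displacement with a hard gate ``max_disp``;
    each unmatched detection incurs a ``max_disp**2`` birth/death cost
    (standard linear-assignment particle-tracking formulation).  Returns
    matched index pairs (i in d_t, j in d_t1).
    """
    a = np.atleast_2d(np.asarray(d_t, dtype=float))
    b = np.atleast_2d(np.asarray(d_t1, dtype=float))
    n = 0 if a.size == 0 else a.shape[0]
    m = 0 if b.size == 0 else b.shape[0]
    if n == 0 or m == 0:
        return []
    gate2 = float(max_disp) ** 2
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    cost = np.full((n + m, n + m), np.inf)
    cost[:n, :m] = np.where(d2 <= gate2, d2, np.inf)
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), gate2, np.inf)
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), gate2, np.inf)
    cost[n:, m:] = 0.0
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if i < n and j < m]


def link_detections(
    detections: pd.DataFrame,
    max_disp: float,
    frame_rate: float = 640.0,
) -> TrajectorySet:
    """Link a detection table frame by frame into raw tracks (no gaps)."""
    if len(detections) == 0:
        return TrajectorySet(
            pd.DataFrame(columns=TRACK_COLUMNS), {"max_disp": max_disp}
        )
    det = detections.sort_values(["frame"]).reset_index(drop=True)
    frames = range(int(det["frame"].min()), int(det["frame"].max()) + 1)
    by_frame = {int(f): g for f, g in det.groupby("frame")}
    next_id = 0
    active: dict[int, tuple[float, float]] = {}  # track_id -> last (x, y)
    records: list[tuple] = []

    prev_ids: list[int] = []
    prev_xy = np.empty((0, 2))
    for f in frames:
        g = by_frame.get(f)
        xy = (
            g[["x_um", "y_um"]].to_numpy() if g is not None else np.empty((0, 2))
        )
        pairs = link_frames(prev_xy, xy, max_disp) if len(prev_ids) else []
        matched_j = {j: prev_ids[i] for i, j in pairs}
        new_ids = []
        for j in range(xy.shape[0]):
            tid = matched_j.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
            new_ids.append(tid)
            records.append((tid, f, f / frame_rate, xy[j, 0], xy[j, 1]))
        prev_ids, prev_xy = new_ids, xy
    tracks = pd.DataFrame(records, columns=TRACK_COLUMNS)
    return TrajectorySet(tracks, {"max_disp": max_disp, "frame_rate": frame_rate})


# ---------------------------------------------------------------------------
# gap closing


def close_gaps(
    trajectories: TrajectorySet,
    max_gap: int = 3,
    max_disp: float | None = None,
) -> TrajectorySet:
    """Re-join track ends to later track starts across short dropouts.

    A join requires 1..``max_gap`` missing frames between the end and the
    start and a displacement within ``max_disp * (gap + 1)``.  Ambiguities
    are resolved by minimum squared displacement; exact ties go to the
    earliest candidate (smallest start frame, then smallest track id).
    Positions inside the gap are left unfilled; spline smoothing spans them.
    """
    tracks = trajectories.tracks
    if max_disp is None:
        max_disp = trajectories.metadata.get("max_disp")
        if max_disp is None:
            raise ValueError("max_disp not given and absent from metadata")
    if len(tracks) == 0:
        return TrajectorySet(tracks.copy(), dict(trajectories.metadata))

    firsts = tracks.loc[tracks.groupby("track_id")["frame"].idxmin()]
    lasts = tracks.loc[tracks.groupby("track_id")["frame"].idxmax()]
    firsts = firsts.set_index("track_id")
    lasts = lasts.set_index("track_id")

    candidates = []
    for end_id, erow in lasts.iterrows():
        for start_id, srow in firsts.iterrows():
            if start_id == end_id:
                continue
            gap = int(srow["frame"]) - int(erow["frame"]) - 1
            if gap < 1 or gap > max_gap:
                continue
            d2 = (srow["x_um"] - erow["x_um"]) ** 2 + (
                srow["y_um"] - erow["y_um"]
            ) ** 2
            if d2 <= (max_disp * (gap + 1)) ** 2:
                candidates.append((d2, int(srow["frame"]), start_id, end_id))
    candidates.sort()

    parent = {tid: tid for tid in firsts.index}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    end_used: set = set()
    start_used: set = set()
    successor: dict = {}
    for _d2, _sf, start_id, end_id in candidates:
        if end_id in end_used or start_id in start_used:
            continue
        if find(end_id) == find(start_id):
            continue
        parent[find(start_id)] = find(end_id)
        end_used.add(end_id)
        start_used.add(start_id)
        successor[end_id] = start_id

    label = {tid: find(tid) for tid in firsts.index}
    # name each merged chain after its earliest segment
    root_name = {}
    for tid, root in label.items():
        first_frame = int(firsts.loc[tid, "frame"])
        if root not in root_name or first_frame < root_name[root][0]:
            root_name[root] = (first_frame, tid)
    merged = tracks.copy()
    merged["track_id"] = merged["track_id"].map(
        lambda t: root_name[label[t]][1]
    )
    merged = merged.sort_values(["track_id", "frame"]).reset_index(drop=True)
    meta = dict(trajectories.metadata)
    meta.update({"max_gap": max_gap, "n_joins": len(successor)})
    return TrajectorySet(merged, meta)


# ---------------------------------------------------------------------------
# smoothing and velocities


def _fit_spline(t: np.ndarray, x: np.ndarray, k: int, knot_spacing: int):
    interior = t[k + 1 : len(t) - k - 1 : knot_spacing]
    while len(interior):
        try:
            return LSQUnivariateSpline(t, x, interior, k=k)
        except ValueError:
            interior = interior[: len(interior) - 1]
    return LSQUnivariateSpline(t, x, [], k=k)


def smooth_tracks(
    trajectories: TrajectorySet,
    spline_order: int = 4,
    knot_spacing: int = 5,
) -> TrajectorySet:
    """Least-squares B-spline smoothing and analytic velocity estimation.

    ``spline_order`` is the B-spline order (degree + 1); the default of 4
    fits cubics, which reproduce straight-line motion exactly.  Interior
    knots are placed every ``knot_spacing`` samples.  Tracks shorter than
    ``spline_order + 1`` points are passed through unsmoothed (flagged
    ``smoothed = False``) with finite-difference velocities.
    """
    if spline_order < 2:
        raise ValueError("spline_order must be >= 2")
    k = spline_order - 1
    out = []
    for tid, g in trajectories.tracks.groupby("track_id"):
        g = g.sort_values("frame").copy()
        t = g["t_s"].to_numpy()
        n = len(g)
        if n >= spline_order + 1 and np.ptp(t) > 0:
            sx = _fit_spline(t, g["x_um"].to_numpy(), k, knot_spacing)
            sy = _fit_spline(t, g["y_um"].to_numpy(), k, knot_spacing)
            g["x_um"] = sx(t)
            g["y_um"] = sy(t)
            g["u_um_s"] = sx.derivative()(t)
            g["v_um_s"] = sy.derivative()(t)
            g["smoothed"] = True
        else:
            if n >= 2 and np.ptp(t) > 0:
                g["u_um_s"] = np.gradient(g["x_um"].to_numpy(), t)
                g["v_um_s"] = np.gradient(g["y_um"].to_numpy(), t)
            else:
                g["u_um_s"] = 0.0
                g["v_um_s"] = 0.0
            g["smoothed"] = False
        out.append(g)
    if not out:
        cols = TRACK_COLUMNS + ["u_um_s", "v_um_s", "smoothed"]
        return TrajectorySet(pd.DataFrame(columns=cols), dict(trajectories.metadata))
    meta = dict(trajectories.metadata)
    meta.update({"spline_order": spline_order, "knot_spacing": knot_spacing})
    return TrajectorySet(pd.concat(out, ignore_index=True), meta)


# ---------------------------------------------------------------------------
# Eulerian field and flow rate


def to_eulerian(
    trajectories: TrajectorySet,
    x_edges: np.ndarray | None = None,
    y_edges: np.ndarray | None = None,
    spec: ImagingSpec | None = None,
) -> EulerianField:
    """Cell-average track velocities on a fixed grid.

    Default grid: 10 um (streamwise) x 1 um (cross-channel) cells over the
    imaging field of view.
    """
    if spec is None:
        spec = ImagingSpec()
    if x_edges is None:
        x_edges = np.arange(0.0, spec.field_of_view[0] + 1e-9, 10.0)
    if y_edges is None:
        y_edges = np.arange(0.0, spec.field_of_view[1] + 1e-9, 1.0)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    ny, nx = len(y_edges) - 1, len(x_edges) - 1
    u_sum = np.zeros((ny, nx))
    v_sum = np.zeros((ny, nx))
    counts = np.zeros((ny, nx), dtype=int)
    tr = trajectories.tracks
    if len(tr) and "u_um_s" in tr.columns:
        xi = np.searchsorted(x_edges, tr["x_um"].to_numpy(), side="right") - 1
        yi = np.searchsorted(y_edges, tr["y_um"].to_numpy(), side="right") - 1
        ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
        ok &= np.isfinite(tr["u_um_s"].to_numpy())
        np.add.at(u_sum, (yi[ok], xi[ok]), tr["u_um_s"].to_numpy()[ok])
        np.add.at(v_sum, (yi[ok], xi[ok]), tr["v_um_s"].to_numpy()[ok])
        np.add.at(counts, (yi[ok], xi[ok]), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(counts > 0, u_sum / np.maximum(counts, 1), np.nan)
        v = np.where(counts > 0, v_sum / np.maximum(counts, 1), np.nan)
    return EulerianField(x_edges, y_edges, u, v, counts)


def _q_fit(u: np.ndarray, y: np.ndarray, w: np.ndarray, side_a_um: float,
           n_terms: int) -> float:
    """Weighted least-squares flow rate (um^3/s) from midplane samples."""
    phi = midplane_profile(y, 1.0, side_a_um, n_terms)
    denom = float(np.sum(w * phi * phi))
    if denom == 0.0:
        return 0.0
    return float(np.sum(w * u * phi) / denom)


def estimate_flow_rate(
    field: EulerianField,
    side_a_um: float = 30.0,
    n_terms: int = 50,
) -> FlowRateEstimate:
    """Volumetric flow rate from an Eulerian midplane field.

    Fits the observed cell velocities to the analytic square-duct midplane
    profile by count-weighted least squares (the fit is linear in Q).
    Coverage below 50% of cells flags the estimate as low-confidence.
    """
    sampled = field.counts > 0
    coverage = float(sampled.mean()) if sampled.size else 0.0
    if not sampled.any():
        return FlowRateEstimate(0.0, 0.0, True)
    yy = np.broadcast_to(field.y_centers[:, None], field.u.shape)
    q_um3_s = _q_fit(
        field.u[sampled], yy[sampled], field.counts[sampled].astype(float),
        side_a_um, n_terms,
    )
    return FlowRateEstimate(q_um3_s * 1e-18, coverage, coverage < 0.5)


def flow_rate_series(
    trajectories: TrajectorySet,
    side_a_um: float = 30.0,
    n_terms: int = 50,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-frame flow-rate estimate (m^3/s) from Lagrangian velocities.

    For each frame, the streamwise velocities of all tracked particles are
    fit to the analytic midplane profile; frames with fewer than
    ``min_samples`` particles are reported as NaN.
    """
    tr = trajectories.tracks
    if "u_um_s" not in tr.columns:
        raise ValueError("run smooth_tracks first (velocities required)")
    rows = []
    for f, g in tr.groupby("frame"):
        g = g[np.isfinite(g["u_um_s"])]
        if len(g) < min_samples:
            q = np.nan
        else:
            q = _q_fit(
                g["u_um_s"].to_numpy(),
                g["y_um"].to_numpy(),
                np.ones(len(g)),
                side_a_um,
                n_terms,
            ) * 1e-18
        rows.append({"frame": int(f), "t_s": float(g["t_s"].iloc[0]) if len(g) else np.nan,
                     "q_m3_s": q, "n": len(g)})
    return pd.DataFrame(rows)
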