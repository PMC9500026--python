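"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here with the
generating parameters recorded in a machine-readable truth record, so the
whole pipeline is testable without measured data:

* pump flow profiles (optionally noisy) standing in for measured temporal
  flow curves;
* tracer image stacks (640 fps, 0.64 um/px, 30 x 500 um field) of
  0.86-um-scale fluorescent particles advected by a square-duct flow,
  for the micro-PTV pipeline;
* pose-keypoint tracks (25 fps, DeepLabCut CSV dialect) of a mouse
  turning at a commanded angular rate, with Gaussian keypoint noise and
  likelihood-tagged dropouts;
* qNMR peak-integral tables for a first-order photolysis series with a
  maleic-acid internal standard.

A single seed fans out into independent per-scenario substreams, so adding
one scenario never perturbs another's draws.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .duct import midplane_profile
from .ptv import ImagingSpec
from .pump import DriveWaveform, FlowProfile, PumpSystem, integrate_pump_ode
from .qnmr import ReferenceStandard, reference_concentration

__all__ = [
    "substream",
    "gen_flow_profile",
    "gen_particle_stack",
    "gen_pose_track",
    "write_pose_csv",
    "gen_nmr_series",
]

_SCENARIOS = {"flow_profile": 0, "particle_stack": 1, "pose_track": 2, "nmr_series": 3}


def substream(seed: int, scenario: str) -> np.random.Generator:
    """Independent random stream for one scenario derived from the global seed."""
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(_SCENARIOS[scenario],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# flow profiles


def gen_flow_profile(
    seed: int,
    system: PumpSystem | None = None,
    drive: DriveWaveform | None = None,
    noise_m3_s: float = 0.0,
    valve=None,
    dt: float | None = None,
) -> tuple[FlowProfile, dict]:
    """Pump-model flow profile plus optional additive measurement noise.

    The truth record holds the noiseless profile and the generating
    parameters.  With ``noise_m3_s = 0`` the output equals the pump-model
    output exactly.
    """
    system = system or PumpSystem()
    drive = drive or DriveWaveform()
    clean = integrate_pump_ode(system, drive, dt=dt, valve=valve)
    rng = substream(seed, "flow_profile")
    noisy_q = clean.flow_rate + (
        rng.normal(0.0, noise_m3_s, size=clean.flow_rate.shape)
        if noise_m3_s > 0
        else 0.0
    )
    noisy = FlowProfile(
        time=clean.time.copy(),
        pressure=clean.pressure.copy(),
        gas_volume=clean.gas_volume.copy(),
        flow_rate=np.asarray(noisy_q),
        delivered_volume=clean.delivered_volume.copy(),
    )
    truth = {
        "scenario": "flow_profile",
        "seed": seed,
        "noise_m3_s": noise_m3_s,
        "peak_flow_m3_s": clean.peak_flow_rate,
        "total_delivered_m3": clean.total_delivered,
        "drive": {
            "period_s": drive.period,
            "duty_cycle": drive.duty_cycle,
            "peak_current_a": drive.peak_current,
            "duration_s": drive.duration,
        },
    }
    return noisy, truth


# ---------------------------------------------------------------------------
# tracer image stacks


def gen_particle_stack(
    seed: int,
    flow_time: np.ndarray,
    flow_rate: np.ndarray,
    n_frames: int = 300,
    n_tracers: int = 20,
    spec: ImagingSpec | None = None,
    side_a_um: float = 30.0,
    psf_sigma_px: float = 1.0,
    amplitude: float = 800.0,
    background: float = 100.0,
    poisson_noise: bool = True,
    wall_margin_um: float = 2.0,
    n_terms: int = 50,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Synthetic tracer movie advected by a square-duct flow.

    ``flow_time``/``flow_rate`` (s, m^3/s) define the pulsatile flow; each
    tracer sits at a fixed cross-channel position ``y`` (laminar flow) and
    is advected along ``x`` by the local midplane duct velocity.  Tracers
    leaving the field of view are recycled at the inlet under a fresh track
    id.  Spots are rendered as isotropic Gaussians (sigma in pixels) on a
    constant background with optional Poisson noise.

    Returns (uint16 stack, truth track table, truth record).  Truth columns
    match the PTV pipeline: track_id, frame, t_s, x_um, y_um, u_um_s.
    """
    spec = spec or ImagingSpec()
    rng = substream(seed, "particle_stack")
    ny, nx = spec.shape
    fov_x, fov_y = spec.field_of_view
    dt_frame = 1.0 / spec.frame_rate

    q_um3 = np.interp(
        np.arange(n_frames) * dt_frame, flow_time, flow_rate
    ) * 1e18  # m^3/s -> um^3/s

    ys = rng.uniform(wall_margin_um, side_a_um - wall_margin_um, size=n_tracers)
    xs = rng.uniform(0.0, fov_x, size=n_tracers)
    ids = np.arange(n_tracers)
    next_id = n_tracers

    def u_of(y: np.ndarray, q: float) -> np.ndarray:
        return midplane_profile(y, q, side_a_um, n_terms)

    stack = np.empty((n_frames, ny, nx), dtype=np.uint16)
    truth_rows = []
    half = max(3, int(math.ceil(4 * psf_sigma_px)))
    for f in range(n_frames):
        u = u_of(ys, q_um3[f])
        img = np.full((ny, nx), background, dtype=float)
        for j in range(n_tracers):
            cx = xs[j] / spec.pixel_size
            cy = ys[j] / spec.pixel_size
            c0, r0 = int(round(cx)), int(round(cy))
            rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, ny))
            cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, nx))
            if rr.size and cc.size:
                gy = np.exp(-0.5 * ((rr - cy) / psf_sigma_px) ** 2)
                gx = np.exp(-0.5 * ((cc - cx) / psf_sigma_px) ** 2)
                img[np.ix_(rr, cc)] += amplitude * np.outer(gy, gx)
            truth_rows.append(
                (ids[j], f, f * dt_frame, xs[j], ys[j], u[j])
            )
        if poisson_noise:
            img = rng.poisson(img).astype(float)
        stack[f] = np.clip(img, 0, 65535).astype(np.uint16)
        # advect to the next frame (trapezoidal in the frame-sampled flow)
        if f + 1 < n_frames:
            q_mid = 0.5 * (q_um3[f] + q_um3[f + 1])
            xs = xs + u_of(ys, q_mid) * dt_frame
            for j in range(n_tracers):
                if xs[j] > fov_x or xs[j] < 0.0:
                    xs[j] = xs[j] % fov_x
                    ys[j] = rng.uniform(wall_margin_um, side_a_um - wall_margin_um)
                    ids[j] = next_id
                    next_id += 1
    truth = pd.DataFrame(
        truth_rows, columns=["track_id", "frame", "t_s", "x_um", "y_um", "u_um_s"]
    )
    record = {
        "scenario": "particle_stack",
        "seed": seed,
        "n_frames": n_frames,
        "n_tracers": n_tracers,
        "peak_flow_m3_s": float(np.max(q_um3)) * 1e-18,
        "frame_rate": spec.frame_rate,
        "pixel_size_um": spec.pixel_size,
        "psf_sigma_px": psf_sigma_px,
        "side_a_um": side_a_um,
    }
    return stack, truth, record


# ---------------------------------------------------------------------------
# pose tracks


#: Rigid body template in cm, body frame: +forward, +right-of-animal.
BODY_TEMPLATE_CM = {
    "snout": (3.0, 0.0),
    "ear_left": (1.0, -1.0),
    "ear_right": (1.0, 1.0),
    "leg_left": (-2.0, -1.0),
    "leg_right": (-2.0, 1.0),
    "tail_base": (-3.0, 0.0),
}


def gen_pose_track(
    seed: int,
    omega_deg_s: float | Callable[[float], float] = 90.0,
    duration_s: float = 12.0,
    fps: float = 25.0,
    noise_px: float = 2.0,
    dropout_p: float = 0.2,
    bin_s: float = 0.5,
    tail_s: float = 1.0,
    px_per_cm: float = 20.0,
    center_px: tuple[float, float] = (640.0, 360.0),
    frame_size: tuple[int, int] = (1280, 720),
) -> tuple[pd.DataFrame, dict]:
    """Pose track of a rigid mouse template turning at rate ``omega_deg_s``.

    ``omega_deg_s`` (deg/s, positive = left turn, i.e. counter-clockwise in
    the video view) may be a constant or a function of time; per-bin
    rotation must stay below 180 deg or the request is refused (aliasing).
    A stationary tail of ``tail_s`` seconds is appended so that binned
    quantification covers the full commanded rotation.  Keypoints get
    isotropic Gaussian noise (``noise_px``); with probability ``dropout_p``
    a keypoint is replaced by a uniform random position with likelihood
    below 0.5 (a detection failure).

    Returns a DeepLabCut-style wide table (see :func:`write_pose_csv`) and
    a truth record whose ``total_deg`` is the integral of omega.
    """
    rng = substream(seed, "pose_track")
    omega = omega_deg_s if callable(omega_deg_s) else (lambda t: float(omega_deg_s))
    n_active = int(round(duration_s * fps))
    n_total = n_active + int(round(tail_s * fps))
    dt = 1.0 / fps

    # heading psi(t): cumulative integral of omega over the active span
    psi = np.zeros(n_total)
    total = 0.0
    for k in range(1, n_total):
        t_mid = (k - 0.5) * dt
        w = omega(t_mid) if t_mid < duration_s else 0.0
        total += w * dt
        psi[k] = total
    # aliasing refusal: per-bin rotation must stay below 180 deg
    bin_frames = max(1, int(round(bin_s * fps)))
    per_bin = np.abs(np.diff(psi[::bin_frames]))
    if per_bin.size and per_bin.max() >= 180.0:
        raise ValueError(
            f"commanded rotation reaches {per_bin.max():.1f} deg per {bin_s} s bin; "
            "per-bin rotation must stay below 180 deg to be recoverable"
        )

    parts = list(BODY_TEMPLATE_CM)
    columns = {}
    w_px, h_px = frame_size
    for part in parts:
        fwd, right = BODY_TEMPLATE_CM[part]
        # visual-CCW-positive heading in image coordinates (y down)
        ang = np.radians(psi)
        fx, fy = np.cos(ang), -np.sin(ang)
        rx, ry = np.sin(ang), np.cos(ang)
        x = center_px[0] + px_per_cm * (fwd * fx + right * rx)
        y = center_px[1] + px_per_cm * (fwd * fy + right * ry)
        x = x + rng.normal(0.0, noise_px, size=n_total)
        y = y + rng.normal(0.0, noise_px, size=n_total)
        like = rng.uniform(0.9, 1.0, size=n_total)
        drop = rng.uniform(size=n_total) < dropout_p
        x[drop] = rng.uniform(0, w_px, size=int(drop.sum()))
        y[drop] = rng.uniform(0, h_px, size=int(drop.sum()))
        like[drop] = rng.uniform(0.0, 0.5, size=int(drop.sum()))
        columns[(part, "x")] = x
        columns[(part, "y")] = y
        columns[(part, "likelihood")] = like
    table = pd.DataFrame(columns)
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    truth = {
        "scenario": "pose_track",
        "seed": seed,
        "total_deg": float(psi[-1]),
        "duration_s": duration_s,
        "tail_s": tail_s,
        "fps": fps,
        "noise_px": noise_px,
        "dropout_p": dropout_p,
    }
    return table, truth


def write_pose_csv(table: pd.DataFrame, path, scorer: str = "synthetic") -> None:
    """Write a pose table in the DeepLabCut CSV dialect (three header rows:
    scorer / bodyparts / coords, with a leading frame-index column)."""
    parts = table.columns.get_level_values(0)
    coords = table.columns.get_level_values(1)
    out = table.copy()
    out.columns = pd.MultiIndex.from_arrays(
        [[scorer] * len(parts), parts, coords],
        names=["scorer", "bodyparts", "coords"],
    )
    out.index.name = None
    out.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# qNMR photolysis series


def gen_nmr_series(
    seed: int,
    k_per_min: float = 0.1,
    times_min: Sequence[float] = (0.0, 1.0, 5.0, 10.0, 30.0),
    c0_mM: float = 10.0 * 10.0 / 600.0,
    standard: ReferenceStandard | None = None,
    released_t0_mM: float = 0.0,
    noise: float = 0.0,
    integral_per_proton_per_mM: float = 1000.0,
    caged_peak: tuple[str, float, int] = ("c", 3.49, 2),
    released_peak: tuple[str, float, int] = ("d", 3.68, 2),
    ref_peak_ppm: float = 6.27,
) -> tuple[pd.DataFrame, dict]:
    """Peak-integral table for a first-order photolysis series.

    Default concentrations follow the tube preparation: 10 ul of 10 mM
    caged stock diluted to 0.6 ml (0.1667 mM) with the maleic-acid internal
    standard at 0.0667 mM.  Integrals are per-proton-proportional to
    concentration with multiplicative Gaussian noise of relative scale
    ``noise``.  Returns a tidy table (sample_id, time_min, peak_label,
    ppm, n_protons, integral) and a truth record.
    """
    if k_per_min < 0:
        raise ValueError("k_per_min must be >= 0")
    rng = substream(seed, "nmr_series")
    standard = standard or ReferenceStandard()
    ref_mM = reference_concentration(standard)
    rows = []
    c_label, c_ppm, c_protons = caged_peak
    r_label, r_ppm, r_protons = released_peak
    for idx, t in enumerate(times_min):
        decay = math.exp(-k_per_min * t)
        caged = (c0_mM - released_t0_mM) * decay
        released = released_t0_mM + (c0_mM - released_t0_mM) * (1.0 - decay)
        for label, ppm, npro, conc in (
            (c_label, c_ppm, c_protons, caged),
            (r_label, r_ppm, r_protons, released),
            ("ref", ref_peak_ppm, standard.n_protons, ref_mM),
        ):
            integral = conc * npro * integral_per_proton_per_mM
            if noise > 0:
                integral *= max(0.0, 1.0 + rng.normal(0.0, noise))
            rows.append(
                {
                    "sample_id": f"t{idx}",
                    "time_min": float(t),
                    "peak_label": label,
                    "ppm": ppm,
                    "n_protons": npro,
                    "integral": integral,
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "scenario": "nmr_series",
        "seed": seed,
        "k_per_min": k_per_min,
        "c0_mM": c0_mM,
        "ref_mM": ref_mM,
        "released_t0_mM": released_t0_mM,
        "noise": noise,
    }
    return table, truth
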