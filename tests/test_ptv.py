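"""Micro-PTV pipeline: detection, linking, gap closing, smoothing, fields."""

import itertools

import numpy as np
import pandas as pd
import pytest

from optofluidics import ptv
from optofluidics.duct import midplane_profile

SPEC = ptv.ImagingSpec()


def render_frame(spots, shape=(47, 782), sigma_px=1.0, amplitude=500.0):
    """Gaussian spots at (x_um, y_um) positions on a zero background."""
    img = np.zeros(shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for x_um, y_um in spots:
        cx, cy = x_um / SPEC.pixel_size, y_um / SPEC.pixel_size
        img += amplitude * np.exp(
            -0.5 * (((rr - cy) / sigma_px) ** 2 + ((cc - cx) / sigma_px) ** 2)
        )
    return img


def brute_force_assignment_cost(a, b, gate):
    """Exhaustive minimum of the gated linking objective: sum of squared
    displacements of matched pairs plus gate^2 per unmatched detection."""
    gate2 = gate**2
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    n = a.shape[0] if a.size else 0
    m = b.shape[0] if b.size else 0
    best = [np.inf]

    def rec(i, used, cost):
        if cost >= best[0]:
            return
        if i == n:
            best[0] = min(best[0], cost + (m - len(used)) * gate2)
            return
        rec(i + 1, used, cost + gate2)  # a_i unmatched
        for j in range(m):
            if j in used:
                continue
            d2 = float(((a[i] - b[j]) ** 2).sum())
            if d2 <= gate2:
                rec(i + 1, used | {j}, cost + d2)

    rec(0, frozenset(), 0.0)
    return best[0]


def linking_cost(a, b, pairs, gate):
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    matched = sum(float(((a[i] - b[j]) ** 2).sum()) for i, j in pairs)
    n_un = (a.shape[0] - len(pairs)) + (b.shape[0] - len(pairs))
    return matched + n_un * gate**2


class TestDetection:
    def test_subpixel_centroid(self):
        stack = render_frame([(10.25, 3.50)])[None]
        det = ptv.detect_particles(stack, SPEC, threshold=25.0,
                                   subtract_background=False)
        assert len(det) == 1
        tol = 0.1 * SPEC.pixel_size
        assert det["x_um"].iloc[0] == pytest.approx(10.25, abs=tol)
        assert det["y_um"].iloc[0] == pytest.approx(3.50, abs=tol)

    def test_blank_frame_empty(self):
        stack = np.zeros((2, 47, 782))
        det = ptv.detect_particles(stack, SPEC, threshold=10.0,
                                   subtract_background=False)
        assert len(det) == 0

    def test_two_spots_matched_to_truth(self):
        truth = [(50.0, 10.0), (200.0, 20.0)]
        stack = render_frame(truth)[None]
        det = ptv.detect_particles(stack, SPEC, threshold=25.0,
                                   subtract_background=False)
        assert len(det) == 2
        found = det[["x_um", "y_um"]].to_numpy()
        for tx, ty in truth:
            d = np.hypot(found[:, 0] - tx, found[:, 1] - ty).min()
            assert d < 0.1

    def test_background_subtraction_removes_static_signal(self):
        rng = np.random.default_rng(0)
        bg = rng.uniform(90, 110, size=(47, 782))
        frames = []
        for x in (30.0, 40.0, 50.0):
            frames.append(bg + render_frame([(x, 15.0)]))
        det = ptv.detect_particles(np.array(frames), SPEC, threshold=50.0)
        assert len(det) == 3
        assert np.allclose(sorted(det["x_um"]), [30, 40, 50], atol=0.3)


class TestLinking:
    def test_single_particle_unique_pair(self):
        pairs = ptv.link_frames([[5.0, 5.0]], [[6.0, 5.2]], max_disp=3.0)
        assert pairs == [(0, 0)]

    def test_displacement_beyond_gate_unmatched(self):
        pairs = ptv.link_frames([[5.0, 5.0]], [[50.0, 5.0]], max_disp=3.0)
        assert pairs == []

    def test_three_crossing_particles_match_enumeration(self):
        a = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        b = np.array([[2.0, 1.0], [12.0, -1.0], [18.0, 0.5]])
        pairs = ptv.link_frames(a, b, max_disp=6.0)
        best = min(
            (
                sum(((a[i] - b[p[i]]) ** 2).sum() for i in range(3)),
                p,
            )
            for p in itertools.permutations(range(3))
        )
        assert sorted(pairs) == [(i, best[1][i]) for i in range(3)]

    @pytest.mark.parametrize("trial", range(20))
    def test_equals_brute_force_up_to_six_particles(self, trial):
        """Hungarian solution equals exhaustive enumeration for all
        instances with <= 6 particles (including unequal counts)."""
        rng = np.random.default_rng(200 + trial)
        n, m = rng.integers(1, 7, size=2)
        a = rng.uniform(0, 30, size=(n, 2))
        b = a[rng.integers(0, n, size=m)] + rng.normal(0, 2.0, size=(m, 2))
        gate = 6.0
        pairs = ptv.link_frames(a, b, max_disp=gate)
        ours = linking_cost(a, b, pairs, gate)
        brute = brute_force_assignment_cost(a, b, gate)
        assert ours == pytest.approx(brute, rel=1e-12)


def make_linear_tracks(dropout_frames=(), n=30, vx=2.0, fps=640.0):
    rows = []
    for f in range(n):
        if f in dropout_frames:
            continue
        rows.append({"frame": f, "x_um": 5.0 + vx * f, "y_um": 10.0, "mass": 1.0})
    return pd.DataFrame(rows)


class TestGapClosing:
    def test_short_dropout_merged(self):
        det = make_linear_tracks(dropout_frames=(10, 11))
        raw = ptv.link_detections(det, max_disp=4.0)
        assert raw.n_tracks == 2
        closed = ptv.close_gaps(raw)
        assert closed.n_tracks == 1

    def test_long_dropout_not_merged(self):
        det = make_linear_tracks(dropout_frames=(10, 11, 12, 13))
        raw = ptv.link_detections(det, max_disp=4.0)
        closed = ptv.close_gaps(raw, max_gap=3)
        assert closed.n_tracks == 2

    def test_no_dropout_identity(self):
        det = make_linear_tracks()
        raw = ptv.link_detections(det, max_disp=4.0)
        closed = ptv.close_gaps(raw)
        pd.testing.assert_frame_equal(
            closed.tracks.reset_index(drop=True), raw.tracks.reset_index(drop=True)
        )

    def test_track_count_never_increases_and_no_shared_detections(self):
        rng = np.random.default_rng(5)
        rows = []
        for p in range(4):
            x0, y0 = rng.uniform(0, 100), rng.uniform(5, 25)
            for f in range(25):
                if rng.uniform() < 0.15:
                    continue
                rows.append({"frame": f, "x_um": x0 + 2.0 * f + 30 * p,
                             "y_um": y0, "mass": 1.0})
        det = pd.DataFrame(rows)
        raw = ptv.link_detections(det, max_disp=4.0)
        closed = ptv.close_gaps(raw)
        assert closed.n_tracks <= raw.n_tracks
        assert not closed.tracks.duplicated(["track_id", "frame"]).any()
        assert len(closed.tracks) == len(raw.tracks)


class TestSmoothing:
    def test_linear_track_velocity_exact(self):
        det = make_linear_tracks(n=50, vx=2.0)
        tracks = ptv.smooth_tracks(ptv.link_detections(det, max_disp=4.0))
        u = tracks.tracks["u_um_s"]
        assert np.allclose(u, 2.0 * 640.0, rtol=1e-6)
        assert np.allclose(tracks.tracks["v_um_s"], 0.0, atol=1e-6)

    def test_noisy_linear_track_small_bias(self):
        rng = np.random.default_rng(11)
        n, vx = 100, 2.0
        det = make_linear_tracks(n=n, vx=vx)
        sigma = 0.5 * SPEC.pixel_size
        det["x_um"] += rng.normal(0, sigma, size=n)
        det["y_um"] += rng.normal(0, sigma, size=n)
        tracks = ptv.smooth_tracks(ptv.link_detections(det, max_disp=5.0))
        mean_u = tracks.tracks["u_um_s"].mean()
        assert abs(mean_u - vx * 640.0) / (vx * 640.0) < 0.02

    def test_parabolic_track_acceleration_sign(self):
        rows = [
            {"frame": f, "x_um": 0.05 * f**2, "y_um": 10.0, "mass": 1.0}
            for f in range(40)
        ]
        tracks = ptv.smooth_tracks(
            ptv.link_detections(pd.DataFrame(rows), max_disp=10.0)
        )
        u = tracks.tracks["u_um_s"].to_numpy()
        assert np.all(np.diff(u) > 0)  # accelerating throughout

    def test_short_track_passed_through_flagged(self):
        det = make_linear_tracks(n=3)
        tracks = ptv.smooth_tracks(ptv.link_detections(det, max_disp=4.0))
        assert not tracks.tracks["smoothed"].any()
        assert np.allclose(tracks.tracks["u_um_s"], 2.0 * 640.0, rtol=1e-6)


class TestEulerianField:
    def make_uniform_tracks(self, u0=1000.0, n=200):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "track_id": np.arange(n),
                "frame": np.zeros(n, dtype=int),
                "t_s": np.zeros(n),
                "x_um": rng.uniform(0, 500, n),
                "y_um": rng.uniform(0, 30, n),
                "u_um_s": np.full(n, u0),
                "v_um_s": np.zeros(n),
            }
        )
        return ptv.TrajectorySet(df)

    def test_uniform_flow_cells(self):
        field = ptv.to_eulerian(self.make_uniform_tracks(u0=1234.0))
        sampled = field.counts > 0
        assert np.allclose(field.u[sampled], 1234.0)
        assert np.isnan(field.u[~sampled]).all()

    def test_counts_conserve_samples(self):
        tracks = self.make_uniform_tracks(n=150)
        field = ptv.to_eulerian(tracks)
        assert field.counts.sum() == 150

    def test_empty_tracks_empty_field(self):
        empty = ptv.TrajectorySet(pd.DataFrame(columns=ptv.TRACK_COLUMNS))
        field = ptv.to_eulerian(empty)
        assert field.counts.sum() == 0
        assert np.isnan(field.u).all()


class TestFlowRateEstimate:
    def duct_sampled_tracks(self, q_m3_s, n=400, seed=9):
        rng = np.random.default_rng(seed)
        y = rng.uniform(1.0, 29.0, n)
        u = midplane_profile(y, q_m3_s * 1e18, 30.0)
        df = pd.DataFrame(
            {
                "track_id": np.arange(n),
                "frame": np.zeros(n, dtype=int),
                "t_s": np.zeros(n),
                "x_um": rng.uniform(0, 500, n),
                "y_um": y,
                "u_um_s": u,
                "v_um_s": np.zeros(n),
            }
        )
        return ptv.TrajectorySet(df)

    def test_round_trip_within_five_percent(self):
        q = 2e-12
        field = ptv.to_eulerian(self.duct_sampled_tracks(q))
        est = ptv.estimate_flow_rate(field)
        assert est.flow_rate == pytest.approx(q, rel=0.05)

    def test_zero_field_zero_rate(self):
        tracks = self.duct_sampled_tracks(0.0)
        est = ptv.estimate_flow_rate(ptv.to_eulerian(tracks))
        assert est.flow_rate == 0.0

    def test_linearity_in_velocity(self):
        tracks = self.duct_sampled_tracks(1e-12)
        q1 = ptv.estimate_flow_rate(ptv.to_eulerian(tracks)).flow_rate
        tracks.tracks["u_um_s"] *= 2.0
        q2 = ptv.estimate_flow_rate(ptv.to_eulerian(tracks)).flow_rate
        assert q2 == pytest.approx(2 * q1, rel=1e-9)

    def test_low_coverage_flagged(self):
        tracks = self.duct_sampled_tracks(1e-12, n=5)
        est = ptv.estimate_flow_rate(ptv.to_eulerian(tracks))
        assert est.low_confidence
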