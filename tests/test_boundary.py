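"""Boundary extraction: difference image, edges, geometry, traces."""

import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from colonychirality import (
    BoundaryTrace,
    ColonyImagePair,
    CurationHint,
    SyntheticColonySpec,
    assemble_traces,
    clean_traces,
    detect_edges,
    difference_image,
    extract_traces,
    fit_center,
    generate_boundaries,
    render_colony,
    smooth_trace,
    to_polar,
)
from colonychirality.boundary import ColonyGeometry, PolarPoints

from conftest import gt_points_px


class TestDifferenceImage:
    def test_identical_channels_give_zero(self):
        img = np.random.default_rng(0).uniform(0, 100, (32, 32))
        pair = ColonyImagePair(img, img)
        assert np.allclose(difference_image(pair), 0.0)

    def test_channel_swap_negates(self):
        rng = np.random.default_rng(1)
        pair = ColonyImagePair(rng.uniform(0, 50, (16, 16)),
                               rng.uniform(0, 80, (16, 16)))
        assert np.allclose(difference_image(pair.swapped()),
                           -difference_image(pair))

    def test_sign_flips_at_ground_truth_boundaries(self, noiseless_colony):
        spec, bounds, pair = noiseless_colony
        diff = difference_image(pair)
        # walk a ring at mid-radius: the sign changes exactly n_sectors
        # times, each within a couple of pixels of a true boundary angle
        c = (spec.image_px - 1) / 2.0
        r_um = 0.6 * spec.r_max
        phis = np.linspace(-np.pi, np.pi, 4000, endpoint=False)
        px = (c + r_um * np.cos(phis) / spec.pixel_size).astype(int)
        py = (c + r_um * np.sin(phis) / spec.pixel_size).astype(int)
        sign = np.sign(diff[py, px])
        changes = phis[np.nonzero(sign[1:] != sign[:-1])[0]]
        s = np.tan(np.deg2rad(spec.theta_true))
        true_angles = np.array([
            np.mod(b.phi0 + s * np.log(r_um / spec.r_i) + np.pi, 2 * np.pi)
            - np.pi for b in bounds
        ])
        ang_tol = 3 * spec.pixel_size / r_um
        for ch in changes:
            d = np.abs(np.angle(np.exp(1j * (true_angles - ch))))
            assert d.min() < ang_tol

    def test_dimension_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            ColonyImagePair(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDetectEdges:
    def test_vertical_step_detected_within_one_pixel(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        mask = detect_edges(img, sigma=2.0)
        ys, xs = np.nonzero(mask)
        assert len(xs) > 0
        assert np.all(np.abs(xs - 31.5) <= 1.5)

    def test_constant_image_yields_empty_mask(self):
        assert not detect_edges(np.full((32, 32), 3.7)).any()

    def test_edges_lie_near_ground_truth_boundaries(self, noiseless_colony):
        spec, bounds, pair = noiseless_colony
        mask = detect_edges(difference_image(pair), sigma=2.0)
        ys, xs = np.nonzero(mask)
        c = (spec.image_px - 1) / 2.0
        r_px = np.hypot(xs - c, ys - c)
        R = spec.r_max / spec.pixel_size
        keep = (r_px > 0.25 * R) & (r_px < 0.95 * R)  # sector-boundary zone
        tree = cKDTree(gt_points_px(bounds, spec))
        d, _ = tree.query(np.column_stack([xs[keep], ys[keep]]))
        assert np.mean(d <= 2.0) >= 0.90


class TestFitCenter:
    def test_exact_circle_recovered_to_machine_precision(self):
        t = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        pts = np.column_stack([50 + 40 * np.cos(t), 60 + 40 * np.sin(t)])
        g = fit_center(pts)
        assert abs(g.cx - 50) < 1e-6
        assert abs(g.cy - 60) < 1e-6
        assert abs(g.R - 40) < 1e-6

    def test_three_points_give_circumcenter(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
        g = fit_center(pts)
        # closed-form circumcenter oracle
        ax, ay = pts[0]
        bx, by = pts[1]
        cx, cy = pts[2]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        assert abs(g.cx - ux) < 1e-9
        assert abs(g.cy - uy) < 1e-9

    def test_noisy_rim_center_within_half_pixel_median(self):
        rng = np.random.default_rng(0)
        errs = []
        t = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        for _ in range(100):
            pts = np.column_stack([
                100 + 70 * np.cos(t) + rng.normal(0, 0.5, 20),
                80 + 70 * np.sin(t) + rng.normal(0, 0.5, 20),
            ])
            g = fit_center(pts)
            errs.append(np.hypot(g.cx - 100, g.cy - 80))
        assert np.median(errs) < 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_center(np.array([[0, 0], [1, 1]]))
        with pytest.raises(ValueError):
            fit_center(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))


class TestToPolar:
    def test_reference_axis_definition(self):
        mask = np.zeros((40, 40), dtype=bool)
        g = ColonyGeometry(cx=15, cy=20, R=18)
        mask[20, 25] = True  # (x=cx+10, y=cy)
        pts = to_polar(mask, g)
        assert pts.r[0] == pytest.approx(10.0)
        assert pts.phi[0] == pytest.approx(0.0)

    def test_round_trip_reproduces_pixel_coordinates(self):
        rng = np.random.default_rng(2)
        mask = rng.random((50, 50)) < 0.1
        g = ColonyGeometry(cx=24.3, cy=25.7, R=20)
        pts = to_polar(mask, g)
        x = g.cx + pts.r * np.cos(pts.phi)
        y = g.cy + pts.r * np.sin(pts.phi)
        assert np.all(np.hypot(x - pts.x, y - pts.y) <= 0.5)
        assert np.all(pts.r <= np.hypot(50, 50))


class TestAssembleTraces:
    def test_two_separated_spirals_yield_two_traces(self):
        # dense points along two spirals half a turn apart
        u = np.linspace(0, 1.5, 300)
        r = 40 * np.exp(u)
        xy = []
        for phi0 in (0.0, np.pi):
            phi = phi0 + 0.15 * u
            xy.append(np.column_stack([150 + r * np.cos(phi),
                                       150 + r * np.sin(phi)]))
        pts_xy = np.vstack(xy)
        pts = PolarPoints(
            x=pts_xy[:, 0], y=pts_xy[:, 1],
            r=np.hypot(pts_xy[:, 0] - 150, pts_xy[:, 1] - 150),
            phi=np.arctan2(pts_xy[:, 1] - 150, pts_xy[:, 0] - 150),
        )
        traces = assemble_traces(pts, max_link=3.0)
        assert len(traces) == 2
        assert sorted(len(t) for t in traces) == [300, 300]

    def test_single_point_becomes_singleton_trace(self):
        pts = PolarPoints(x=np.array([5.0]), y=np.array([5.0]),
                          r=np.array([1.0]), phi=np.array([0.3]))
        traces = assemble_traces(pts)
        assert len(traces) == 1 and len(traces[0]) == 1

    def test_points_beyond_max_link_stay_separate(self):
        pts = PolarPoints(x=np.array([0.0, 10.0]), y=np.array([0.0, 0.0]),
                          r=np.array([1.0, 2.0]), phi=np.array([0.0, 0.1]))
        assert len(assemble_traces(pts, max_link=3.0)) == 2

    def test_phi_unwrapped_along_chain(self):
        # chain crossing the -pi/pi discontinuity
        phis = np.linspace(np.pi - 0.2, np.pi + 0.2, 40)
        pts = PolarPoints(
            x=100 + 50 * np.cos(phis), y=100 + 50 * np.sin(phis),
            r=np.full(40, 50.0), phi=np.arctan2(np.sin(phis), np.cos(phis)),
        )
        traces = assemble_traces(pts, max_link=2.0)
        assert len(traces) == 1
        assert np.all(np.abs(np.diff(traces[0].phi)) < 0.5)


class TestCleanTraces:
    def test_all_points_inside_r_min_gives_empty_set_with_warning(self):
        tr = BoundaryTrace(np.linspace(1, 9, 30), np.zeros(30))
        with pytest.warns(UserWarning):
            ts = clean_traces([tr], r_min=20.0)
        assert len(ts) == 0

    def test_split_hint_partitions_trace(self):
        tr = BoundaryTrace(np.linspace(10, 50, 60), np.zeros(60),
                           colony_id="c", trace_id=0)
        hint = CurationHint(colony_id="c", trace_id=0, action="split",
                            index=25)
        ts = clean_traces([tr], r_min=0.0, min_points=5, hints=[hint])
        assert sorted(len(t) for t in ts.traces) == [25, 35]

    def test_drop_hint_removes_trace(self):
        tr = BoundaryTrace(np.linspace(10, 50, 60), np.zeros(60),
                           colony_id="c", trace_id=1)
        hint = CurationHint(colony_id="c", trace_id=1, action="drop")
        with pytest.warns(UserWarning):
            ts = clean_traces([tr], r_min=0.0, min_points=5, hints=[hint])
        assert len(ts) == 0

    def test_radial_reversal_chain_is_split_into_two_boundaries(self):
        # out-and-back chain: two sides of a pinched-off sector
        r = np.concatenate([np.linspace(100, 200, 80),
                            np.linspace(200, 100, 80)[1:]])
        phi = np.concatenate([np.zeros(80), np.full(79, 0.05)])
        ts = clean_traces([BoundaryTrace(r, phi)], r_min=0.0, min_points=10,
                          turn_tolerance=5.0, min_radial_aspect=None)
        assert len(ts) == 2

    def test_circumferential_fragment_is_discarded(self):
        # an arc at nearly constant radius is not a sector boundary
        phi = np.linspace(0, 0.8, 120)
        r = 500 + np.random.default_rng(0).normal(0, 0.5, 120)
        with pytest.warns(UserWarning):
            ts = clean_traces([BoundaryTrace(r, phi)], r_min=0.0,
                              min_points=10, turn_tolerance=None)
        assert len(ts) == 0

    def test_noiseless_colony_recovers_one_trace_per_sector(
            self, noiseless_colony, noiseless_traceset):
        spec, _, _ = noiseless_colony
        assert len(noiseless_traceset) == spec.n_sectors


class TestSmoothTrace:
    def test_constant_trace_is_fixed_point(self):
        tr = BoundaryTrace(np.linspace(10, 20, 30), np.full(30, 1.3))
        assert np.allclose(smooth_trace(tr, 11).phi, 1.3)

    def test_linear_profile_slope_preserved_everywhere(self):
        r = np.geomspace(10, 100, 50)
        phi = 0.2 * np.log(r / 10)
        sm = smooth_trace(BoundaryTrace(r, phi), 11)
        assert np.all(np.abs(sm.phi - phi) < 1e-6)

    def test_alternating_noise_attenuated_by_window(self):
        n = 41
        delta = 0.3
        phi = delta * (-1.0) ** np.arange(n)
        sm = smooth_trace(BoundaryTrace(np.linspace(1, 2, n), phi), 3)
        interior = sm.phi[1:-1]
        assert np.allclose(np.abs(interior), delta / 3, atol=1e-12)

    def test_invalid_window_rejected(self):
        tr = BoundaryTrace(np.linspace(1, 2, 20), np.zeros(20))
        with pytest.raises(ValueError):
            smooth_trace(tr, 0)


class TestPipelineProperties:
    def test_extracted_traces_follow_ground_truth_spirals(
            self, noiseless_colony, noiseless_traceset):
        spec, bounds, _ = noiseless_colony
        tree = cKDTree(gt_points_px(bounds, spec))
        c = (spec.image_px - 1) / 2.0
        devs = []
        for tr in noiseless_traceset.traces:
            r_px = tr.r / spec.pixel_size
            x = c + r_px * np.cos(tr.phi)
            y = c + r_px * np.sin(tr.phi)
            d, _ = tree.query(np.column_stack([x, y]))
            devs.append(d)
        rms = np.sqrt(np.mean(np.concatenate(devs) ** 2))
        assert rms <= 2.0

    def test_channel_swap_leaves_trace_geometry_unchanged(self, noiseless_colony):
        _, _, pair = noiseless_colony
        ts1 = extract_traces(pair, colony_id="a")
        ts2 = extract_traces(pair.swapped(), colony_id="a")
        pts1 = np.sort(np.concatenate([t.r for t in ts1.traces]))
        pts2 = np.sort(np.concatenate([t.r for t in ts2.traces]))
        assert np.array_equal(pts1, pts2)

    def test_rotating_image_preserves_chirality_slope(self, noiseless_colony):
        from colonychirality import ChiralityModel

        spec, _, pair = noiseless_colony
        rot = ColonyImagePair(np.rot90(pair.yfp), np.rot90(pair.cfp),
                              pair.pixel_size)
        win = (0.4 * spec.r_max, 0.9 * spec.r_max)
        t1 = ChiralityModel(extract_traces(pair, colony_id="a")).fit(
            n_boot=50, seed=0, window=win)
        t2 = ChiralityModel(extract_traces(rot, colony_id="b")).fit(
            n_boot=50, seed=0, window=win)
        assert abs(t1.theta_deg - t2.theta_deg) < 0.2
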