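import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from vertasm.corners import (
    InitializationError,
    detect_candidates,
    detect_corners,
    estimate_geometry,
    filter_angle,
    filter_isolated,
    find_corner_sequence,
    reduce_window,
)


class TestEstimateGeometry:
    def test_five_vertebrae(self):
        g = estimate_geometry([0, 0], [0, 24], 5)
        assert g.alpha == pytest.approx(4.0)
        assert g.beta == pytest.approx(1.0)

    def test_single_vertebra(self):
        g = estimate_geometry([0, 0], [0, 4], 1)
        assert g.alpha == pytest.approx(4.0)
        assert g.beta == pytest.approx(1.0)

    @pytest.mark.parametrize("n", range(1, 11))
    @pytest.mark.parametrize("d", [10, 50, 137, 500])
    def test_identities_hold_exactly(self, n, d):
        g = estimate_geometry([0.0, 0.0], [0.0, float(d)], n)
        assert g.alpha == pytest.approx(4 * g.beta, abs=1e-12)
        assert n * g.alpha + (n - 1) * g.beta == pytest.approx(d, abs=1e-9)

    def test_coincident_anchors_rejected(self):
        with pytest.raises(ValueError):
            estimate_geometry([5, 5], [5, 5], 3)


class TestReduceWindow:
    def test_window_arithmetic(self):
        img = np.zeros((200, 200))
        win, off = reduce_window(img, [10, 10], [10, 100], margin_px=20)
        assert off.tolist() == [0, 0]
        assert win.shape == (121, 31)

    def test_offset_maps_back_to_original(self):
        img = np.arange(10000.0).reshape(100, 100)
        win, off = reduce_window(img, [50, 40], [55, 70], margin_px=5)
        assert win[0, 0] == img[int(off[1]), int(off[0])]

    def test_full_image_clicks_return_whole_image(self):
        img = np.zeros((50, 60))
        win, off = reduce_window(img, [0, 0], [59, 49], margin_px=5)
        assert win.shape == img.shape
        assert off.tolist() == [0, 0]

    def test_reversed_clicks_swapped_with_warning(self):
        img = np.zeros((100, 100))
        with pytest.warns(RuntimeWarning):
            win, off = reduce_window(img, [10, 80], [10, 20], margin_px=0)
        assert win.shape[0] == 61

    def test_identical_clicks_rejected(self):
        with pytest.raises(ValueError):
            reduce_window(np.zeros((10, 10)), [3, 3], [3, 3])


def rect_image(h=80, w=80, top=20, bottom=60, left=20, right=60, blur=1.0):
    img = np.full((h, w), 50.0)
    img[top:bottom, left:right] = 200.0
    return gaussian_filter(img, blur)


class TestDetectCandidates:
    def test_rectangle_corners_found(self):
        img = rect_image()
        edges, cands, _ = detect_candidates(img)
        # corner foreground pixels of the filled block
        truth = np.array(
            [[20.0, 20.0], [20.0, 59.0], [59.0, 20.0], [59.0, 59.0]]
        )
        for t in truth:
            d = np.linalg.norm(cands - t, axis=1).min()
            assert d <= 2.0

    def test_constant_image_yields_nothing(self):
        edges, cands, _ = detect_candidates(np.full((40, 40), 77.0))
        assert not edges.any()
        assert len(cands) == 0

    def test_candidate_count_monotone_in_threshold(self):
        img = rect_image()
        counts = [
            len(detect_candidates(img, response_rel=r)[1])
            for r in (0.001, 0.01, 0.1, 0.5)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFilterIsolated:
    def test_candidate_off_contour_removed(self):
        img = rect_image()
        edges, _, _ = detect_candidates(img)
        out = filter_isolated(np.array([[5.0, 5.0]]), edges, reach_px=20)
        assert len(out) == 0

    def test_candidate_on_long_contour_kept(self):
        img = rect_image()
        edges, _, _ = detect_candidates(img)
        out = filter_isolated(np.array([[20.0, 40.0]]), edges, reach_px=20)
        assert len(out) == 1

    def test_output_subset_of_input(self, rng):
        img = rect_image()
        edges, cands, _ = detect_candidates(img)
        noise = rng.uniform(0, 79, (10, 2))
        allc = np.vstack([cands, noise])
        out = filter_isolated(allc, edges, reach_px=20)
        assert len(out) <= len(allc)
        for p in out:
            assert np.linalg.norm(allc - p, axis=1).min() < 1e-12

    def test_spine_fixture_keeps_true_corners_drops_noise(self, synthetic_spine):
        """All 2N true anterior corners survive; a good share of
        off-contour decoys is removed."""
        sp = synthetic_spine
        win, off = reduce_window(sp.image, sp.anchor_top, sp.anchor_bottom)
        edges, _, _ = detect_candidates(win)
        g = estimate_geometry(sp.anchor_top, sp.anchor_bottom, 5)
        true_c = sp.corners - off
        rng = np.random.default_rng(7)
        # decoys away from the body contours (anterior edge is at x ~ 25)
        noise = np.column_stack([
            rng.uniform(0, 4, 30), rng.uniform(0, win.shape[0] - 1, 30)
        ])
        kept_true = filter_isolated(true_c, edges, reach_px=g.alpha)
        kept_noise = filter_isolated(noise, edges, reach_px=g.alpha)
        assert len(kept_true) == len(true_c)
        assert len(kept_noise) <= 0.7 * len(noise)


def synth_contour(kind, size=61, angle_deg=90):
    """Edge map with a single polyline vertex of the given angle at the
    centre; returns (edge_map, vertex_xy)."""
    edges = np.zeros((size, size), bool)
    c = size // 2
    if kind == "line":
        edges[c, :] = True
        return edges, np.array([c, c], float)
    half = np.deg2rad(angle_deg / 2)
    for r in range(c):
        dx = int(round(r * np.sin(half)))
        dy = int(round(r * np.cos(half)))
        edges[c - dy, c - dx] = True
        edges[c - dy, c + dx] = True
    return edges, np.array([c, c], float)


class TestFilterAngle:
    def test_collinear_removed(self):
        edges, v = synth_contour("line")
        out = filter_angle(v[None], edges, neighbor_dist_px=15)
        assert len(out) == 0

    def test_right_angle_kept(self):
        edges, v = synth_contour("corner", angle_deg=90)
        out = filter_angle(v[None], edges, neighbor_dist_px=15)
        assert len(out) == 1

    def test_needle_corner_removed(self):
        edges, v = synth_contour("corner", angle_deg=5)
        out = filter_angle(v[None], edges, neighbor_dist_px=15)
        assert len(out) == 0

    def test_isolated_candidate_removed(self):
        edges, v = synth_contour("corner", angle_deg=90)
        out = filter_angle(np.array([[2.0, 2.0]]), edges, neighbor_dist_px=15)
        assert len(out) == 0

    def test_output_subset_of_input(self, rng):
        edges, v = synth_contour("corner", angle_deg=90)
        cands = np.vstack([v, rng.uniform(0, 60, (8, 2))])
        out = filter_angle(cands, edges, neighbor_dist_px=15)
        for p in out:
            assert np.linalg.norm(cands - p, axis=1).min() < 1e-12


def exhaustive_shortest_sequence(cands, l1, l2n, geom):
    """Brute-force oracle: enumerate every alternating 2N-sequence that
    satisfies the step windows and monotone progression; return the one
    with minimal path length (None if none exists)."""
    two_n = 2 * geom.n_vertebrae
    axis = (l2n - l1) / np.linalg.norm(l2n - l1)

    def ok_step(a, b, upper):
        d = np.linalg.norm(b - a)
        if upper:
            lo, hi = geom.alpha - geom.delta_alpha, geom.alpha + geom.delta_alpha
        else:
            lo, hi = geom.beta - geom.delta_beta, geom.beta + geom.delta_beta
        return lo < d < hi and (b - l1) @ axis > (a - l1) @ axis + 1e-12

    best = [np.inf, None]

    def recurse(pts, used):
        # exhaustive: every feasible prefix is extended by every candidate
        if len(pts) == two_n - 1:
            full = pts + [l2n]
            length = sum(
                np.linalg.norm(full[i + 1] - full[i]) for i in range(two_n - 1)
            )
            if length < best[0] - 1e-12:
                best[0], best[1] = length, full
            return
        upper = (len(pts) - 1) % 2 == 0
        for j in range(len(cands)):
            if j in used:
                continue
            if ok_step(pts[-1], cands[j], upper):
                recurse(pts + [cands[j]], used | {j})

    recurse([l1], frozenset())
    return best[0], best[1]


def random_instance(rng, n_vert):
    """True corner chain with jitter plus decoys, <= 15 candidates."""
    alpha, beta = 20.0, 5.0
    ys = []
    for v in range(n_vert):
        ys += [v * (alpha + beta), v * (alpha + beta) + alpha]
    truth = np.column_stack([np.zeros(2 * n_vert), ys])
    truth[1:-1] += rng.uniform(-1.5, 1.5, (2 * n_vert - 2, 2))
    l1, l2n = truth[0], truth[-1]
    geom = estimate_geometry(l1, l2n, n_vert)
    n_decoys = int(rng.integers(3, 15 - (2 * n_vert - 2) + 1))
    decoys = np.column_stack([
        rng.uniform(-10, 10, n_decoys),
        rng.uniform(0, ys[-1], n_decoys),
    ])
    cands = np.vstack([truth[1:-1], decoys])
    return cands[rng.permutation(len(cands))], l1, l2n, geom


class TestFindCornerSequence:
    def test_ideal_candidates_returned_in_order(self):
        geom = estimate_geometry([0, 0], [0, 120], 5)
        ys = []
        for v in range(5):
            ys += [v * (geom.alpha + geom.beta),
                   v * (geom.alpha + geom.beta) + geom.alpha]
        truth = np.column_stack([np.zeros(10), ys])
        seq = find_corner_sequence(truth[1:-1], truth[0], truth[-1], geom)
        np.testing.assert_allclose(seq.points, truth, atol=1e-12)
        assert seq.types == ["upper", "lower"] * 5

    def test_no_feasible_step_raises(self):
        geom = estimate_geometry([0, 0], [0, 120], 5)
        with pytest.raises(InitializationError):
            find_corner_sequence(np.array([[500.0, 500.0]]), [0, 0], [0, 120], geom)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_vert = int(rng.integers(2, 6))
        cands, l1, l2n, geom = random_instance(rng, n_vert)
        oracle_len, oracle_seq = exhaustive_shortest_sequence(cands, l1, l2n, geom)
        if oracle_seq is None:
            with pytest.raises(InitializationError):
                find_corner_sequence(cands, l1, l2n, geom)
            return
        seq = find_corner_sequence(cands, l1, l2n, geom)
        assert seq.path_length == pytest.approx(oracle_len, abs=1e-9)
        np.testing.assert_allclose(seq.points, oracle_seq, atol=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_returned_sequence_satisfies_all_windows(self, trial):
        rng = np.random.default_rng(2000 + trial)
        cands, l1, l2n, geom = random_instance(rng, 3)
        try:
            seq = find_corner_sequence(cands, l1, l2n, geom)
        except InitializationError:
            return
        axis = (l2n - l1) / np.linalg.norm(l2n - l1)
        for i in range(len(seq.points) - 2):  # final appended step unchecked
            d = np.linalg.norm(seq.points[i + 1] - seq.points[i])
            if i % 2 == 0:  # upper -> lower
                assert geom.alpha - geom.delta_alpha < d < geom.alpha + geom.delta_alpha
            else:
                assert geom.beta - geom.delta_beta < d < geom.beta + geom.delta_beta
        prog = (seq.points - l1) @ axis
        assert np.all(np.diff(prog[:-1]) > 0)


class TestFullPipeline:
    def test_detected_corners_close_to_truth(self, synthetic_spine):
        sp = synthetic_spine
        seq, diag = detect_corners(
            sp.image, sp.anchor_top, sp.anchor_bottom, 5
        )
        err = np.linalg.norm(seq.points - sp.corners, axis=1)
        assert err.max() <= 3.0
        # counts never increase along the filter pipeline
        assert (
            diag["n_harris"]
            >= diag["n_after_isolated_filter"]
            >= diag["n_after_angle_filter"]
        )
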