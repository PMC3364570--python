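"""Circular Hough transform: edge maps, voting, selection, multiresolution."""

import numpy as np
import pytest
from skimage.draw import disk

from ivusseg.contourlet import contourlet_decompose
from ivusseg.metrics import md_rmd
from ivusseg.hough import (
    CircleParam,
    EdgeMap,
    InitConstraints,
    ParabolaParam,
    cht_accumulate,
    circle_contour,
    edge_map,
    estimate_lumen_center,
    find_circles,
    multiresolution_initialize,
    select_lumen_circle,
    select_media_circle,
)


def ring_image(shape, center, radius, arc_deleted=0.0):
    """Binary 1-px ring, optionally with a fraction of its arc removed."""
    img = np.zeros(shape)
    t = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
    if arc_deleted:
        t = t[t > 2 * np.pi * arc_deleted]
    rr = np.clip(np.round(center[1] + radius * np.sin(t)).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(center[0] + radius * np.cos(t)).astype(int), 0, shape[1] - 1)
    img[rr, cc] = 1.0
    return img


def edges_from_binary(img):
    grad = np.zeros_like(img)
    return EdgeMap(img > 0.5, grad, grad)


class TestTypes:
    def test_circle_invariants(self):
        with pytest.raises(ValueError):
            CircleParam(10, 10, -1.0)
        with pytest.raises(ValueError):
            CircleParam(10, 10, 5.0, score=-1)

    def test_parabola_invariants(self):
        with pytest.raises(ValueError):
            ParabolaParam(a=0.0, h=0, k=0, theta=0.0)
        with pytest.raises(ValueError):
            ParabolaParam(a=1.0, h=0, k=0, theta=7.0)

    def test_constraints_invariants(self):
        with pytest.raises(ValueError):
            InitConstraints(r_min=40, r_max=15)


class TestEdgeMap:
    def test_ideal_disk_gives_thin_ring(self):
        img = np.zeros((128, 128))
        rr, cc = disk((64, 64), 30)
        img[rr, cc] = 1.0
        em = edge_map(img, sigma=1.5)
        ys, xs = np.nonzero(em.mask)
        radii = np.hypot(ys - 64, xs - 64)
        assert abs(radii.mean() - 30) < 1.5
        assert em.n_edges > 100

    def test_constant_image_empty(self):
        em = edge_map(np.full((64, 64), 0.5))
        assert em.n_edges == 0

    def test_noisy_disk_ring_dominates(self, rng):
        img = np.zeros((128, 128))
        rr, cc = disk((64, 64), 30)
        img[rr, cc] = 1.0
        img += 0.05 * rng.normal(size=img.shape)
        em = edge_map(img, sigma=2.0)
        ys, xs = np.nonzero(em.mask)
        radii = np.hypot(ys - 64, xs - 64)
        near_ring = np.abs(radii - 30) < 3
        assert near_ring.mean() > 0.5


class TestAccumulator:
    def test_single_ring_peak_at_truth(self):
        img = ring_image((100, 100), (50, 50), 30)
        acc = cht_accumulate(edges_from_binary(img), InitConstraints(15, 40, 25))
        ri, y, x = np.unravel_index(np.argmax(acc), acc.shape)
        assert (x, y, 15 + ri) == (50, 50, 30)

    def test_two_concentric_rings_two_maxima(self):
        img = ring_image((120, 120), (60, 60), 20) + ring_image((120, 120), (60, 60), 35)
        cands = find_circles(
            cht_accumulate(edges_from_binary(img), InitConstraints(15, 40, 25)),
            InitConstraints(15, 40, 25),
        )
        found = {(round(c.x_c), round(c.y_c), round(c.r)) for c in cands[:2]}
        assert found == {(60, 60, 20), (60, 60, 35)}

    def test_occluded_ring_recovered_and_matches_bruteforce(self):
        """25% of the arc removed (guide-wire surrogate): the peak stays at
        the true parameters; cross-checked by exhaustively scoring every
        (centre, radius) on a small instance."""
        img = ring_image((64, 64), (32, 32), 20, arc_deleted=0.25)
        cons = InitConstraints(15, 25, 25)
        acc = cht_accumulate(edges_from_binary(img), cons)
        ri, y, x = np.unravel_index(np.argmax(acc), acc.shape)
        assert (x, y, 15 + ri) == (32, 32, 20)

        ys, xs = np.nonzero(img)
        best, best_score = None, -1
        for r in range(15, 26):
            for cy in range(20, 45):
                for cx in range(20, 45):
                    d = np.hypot(ys - cy, xs - cx)
                    score = np.sum(np.abs(d - r) <= 0.5) / r
                    if score > best_score:
                        best, best_score = (cx, cy, r), score
        assert best == (32, 32, 20)

    def test_empty_edge_map_raises(self):
        with pytest.raises(ValueError, match="no edges"):
            cht_accumulate(edges_from_binary(np.zeros((32, 32))),
                           InitConstraints(5, 10, 5))

    def test_skimage_cross_check(self):
        """Our accumulator peak agrees with scikit-image's Hough circle
        transform on the same edge map."""
        from skimage.transform import hough_circle, hough_circle_peaks

        img = ring_image((100, 100), (47, 53), 28)
        cons = InitConstraints(20, 35, 25)
        acc = cht_accumulate(edges_from_binary(img), cons)
        ri, y, x = np.unravel_index(np.argmax(acc), acc.shape)

        radii = np.arange(20, 36)
        h = hough_circle(img > 0.5, radii)
        _, cxs, cys, rads = hough_circle_peaks(h, radii, total_num_peaks=1)
        assert (cxs[0], cys[0], rads[0]) == (x, y, 20 + ri)


class TestSelection:
    def test_lumen_nearest_center(self):
        cands = [CircleParam(50, 50, 20, 90), CircleParam(80, 80, 25, 95)]
        sel = select_lumen_circle(cands, (52, 49))
        assert (sel.x_c, sel.y_c) == (50, 50)

    def test_lumen_single_candidate(self):
        c = CircleParam(10, 10, 5, 1)
        assert select_lumen_circle([c], (0, 0)) is c

    def test_lumen_tie_breaks_by_score(self):
        cands = [CircleParam(40, 50, 20, 40), CircleParam(60, 50, 20, 70)]
        sel = select_lumen_circle(cands, (50, 50))
        assert sel.score == 70

    def test_lumen_empty_raises(self):
        with pytest.raises(ValueError, match="no lumen"):
            select_lumen_circle([], (0, 0))

    def test_media_constraint_violation_raises(self):
        lumen = CircleParam(50, 50, 20, 10)
        far = [CircleParam(120, 120, 30, 50)]
        with pytest.raises(ValueError, match="media"):
            select_media_circle(far, lumen, InitConstraints(15, 40, 25))

    def test_media_larger_contrast_wins(self):
        """Two concentric candidates: the one sitting on the stronger
        intensity step is selected."""
        band = np.zeros((200, 200))
        yy, xx = np.mgrid[0:200, 0:200]
        rho = np.hypot(yy - 100, xx - 100)
        band[rho >= 55] = 0.15   # weak step at 55
        band[rho >= 90] = 0.70   # strong step at 90
        lumen = CircleParam(100, 100, 30, 10)
        cands = [CircleParam(100, 100, 55, 50), CircleParam(100, 100, 90, 50)]
        sel = select_media_circle(cands, lumen, InitConstraints(15, 95, 25), band)
        assert sel.r == 90


class TestLumenCenter:
    def test_dark_disk_centroid(self):
        img = np.full((192, 192), 0.6)
        rr, cc = disk((96, 96), 40)
        img[rr, cc] = 0.05
        ac = estimate_lumen_center(img)
        assert np.hypot(ac.x - 96, ac.y - 96) < 5
        assert ac.confidence == 1.0

    def test_uniform_image_falls_back_to_center(self):
        ac = estimate_lumen_center(np.full((100, 100), 0.5))
        assert (ac.x, ac.y) == (49.5, 49.5)
        assert ac.confidence == 0.0

    def test_offcenter_lumen(self):
        img = np.full((384, 384), 0.55)
        rr, cc = disk((200, 170), 40)  # (row, col)
        img[rr, cc] = 0.08
        ac = estimate_lumen_center(img)
        assert np.hypot(ac.x - 170, ac.y - 200) < 10


class TestMultiresolution:
    def test_clean_phantom_recovery(self, clean_phantom):
        """Detected circles match the best-fit circles of the (Fourier-
        perturbed) true interfaces on a noise-free phantom."""
        ph = clean_phantom
        coeffs = contourlet_decompose(ph.image, 3, (2, 2, 3))
        init = multiresolution_initialize(coeffs, InitConstraints(),
                                          image=ph.image)
        for circ, truth in ((init.lumen_circle, ph.lumen_truth),
                            (init.media_circle, ph.media_truth)):
            center = truth.mean(axis=0)
            r_fit = np.hypot(*(truth - center).T).mean()
            assert np.hypot(circ.x_c - center[0], circ.y_c - center[1]) < 5.0
            assert abs(circ.r - r_fit) < 3.0
            # the initial contour itself hugs the perturbed interface
            assert md_rmd(circle_contour(circ), truth).MD < 3.5

    def test_speckled_phantom_within_five_px(self, default_phantom):
        ph = default_phantom
        coeffs = contourlet_decompose(ph.image, 3, (2, 2, 3))
        init = multiresolution_initialize(coeffs, InitConstraints(),
                                          image=ph.image)
        spec = ph.spec
        c = (spec.image_size - 1) / 2.0
        cx, cy = c + spec.center_offset[0], c + spec.center_offset[1]
        for circ, r_true in ((init.lumen_circle, spec.lumen_radius),
                             (init.media_circle, spec.media_radius)):
            assert np.hypot(circ.x_c - cx, circ.y_c - cy) < 5.0
            assert abs(circ.r - r_true) < 5.0

    def test_lumen_strictly_inside_media(self):
        from ivusseg.simulator import batch

        for ph in batch(3, seed=21):
            coeffs = contourlet_decompose(ph.image, 3, (2, 2, 3))
            init = multiresolution_initialize(coeffs, InitConstraints(),
                                              image=ph.image)
            l, m = init.lumen_circle, init.media_circle
            assert l.center_distance(m) + l.r < m.r

    def test_contours_closed_polygons(self, clean_phantom):
        coeffs = contourlet_decompose(clean_phantom.image, 3, (2, 2, 3))
        lumen, media = multiresolution_initialize(coeffs, InitConstraints(),
                                                  image=clean_phantom.image)
        for poly in (lumen, media):
            assert poly.shape[1] == 2 and len(poly) >= 8

    def test_reconstructed_image_fallback(self, clean_phantom):
        """Without an explicit frame, a_0 is rebuilt from the coefficients
        and detection proceeds identically."""
        coeffs = contourlet_decompose(clean_phantom.image, 3, (2, 2, 3))
        a = multiresolution_initialize(coeffs, InitConstraints(),
                                       image=clean_phantom.image)
        b = multiresolution_initialize(coeffs, InitConstraints())
        assert np.hypot(a.media_circle.x_c - b.media_circle.x_c,
                        a.media_circle.y_c - b.media_circle.y_c) < 1.0
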