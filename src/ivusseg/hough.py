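"""Circular-Hough initialization of the lumen and media-adventitia contours.

The two vessel interfaces in a cross-sectional IVUS frame are roughly
circular, so initial contours are recovered as circles by a voting circular
Hough transform (CHT) on Canny edge maps. Detection runs coarse-to-fine
over the approximation (low-pass) bands of the contourlet pyramid: the
coarsest band is nearly speckle-free, so a reliable pair of circles found
there seeds a restricted search window at each finer level.

Selection logic: the lumen circle is the accumulator candidate whose centre
is nearest an approximate lumen centre (dark blood-pool centroid); the
media-adventitia circle is then chosen among candidates concentric with the
lumen (centre distance <= D_c) and larger than it, scoring accumulator
votes together with the mean intensity-gradient magnitude along the circle;
finally the lumen selection is re-run once with its radius capped at half
the media radius.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import canny
from skimage.filters import threshold_otsu

__all__ = [
    "CircleParam",
    "ParabolaParam",
    "EdgeMap",
    "InitConstraints",
    "InitResult",
    "edge_map",
    "cht_accumulate",
    "find_circles",
    "estimate_lumen_center",
    "select_lumen_circle",
    "select_media_circle",
    "multiresolution_initialize",
    "circle_contour",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CircleParam:
    """A circle hypothesis (x_c, y_c, r) with its accumulator score."""

    x_c: float
    y_c: float
    r: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("circle radius must be positive")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    def center_distance(self, other: "CircleParam") -> float:
        return math.hypot(self.x_c - other.x_c, self.y_c - other.y_c)


@dataclass(frozen=True)
class ParabolaParam:
    """Rotated parabola ((x-h)sin t - (y-k)cos t)^2 = a((x-h)cos t + (y-k)sin t).

    Offered as an optional arc refinement of the circular fit; unused by the
    default pipeline.
    """

    a: float
    h: float
    k: float
    theta: float

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("curvature constant a must be nonzero")
        if not 0 <= self.theta < 2 * math.pi:
            raise ValueError("theta must lie in [0, 2*pi)")


@dataclass
class EdgeMap:
    """Binary Canny edges plus the retained gradient fields of the source."""

    mask: np.ndarray
    grad_mag: np.ndarray
    grad_orient: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.shape != self.grad_mag.shape:
            raise ValueError("edge mask and gradient grids must share a shape")
        self.mask = self.mask.astype(bool)

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class InitConstraints:
    """Search constraints: radius range and max centre separation D_c."""

    r_min: float = 15.0
    r_max: float = 40.0
    d_c: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.r_min < self.r_max:
            raise ValueError("need 0 < r_min < r_max")
        if self.d_c < 0:
            raise ValueError("D_c must be >= 0")


def fit_parabola_arcs(edges: EdgeMap, circle: CircleParam,
                      band_px: float = 4.0) -> tuple[ParabolaParam, ParabolaParam]:
    """Optional post-fit: vertical-axis parabolas through the upper and
    lower arcs of a detected circle (off by default in the pipeline).

    Edge points within ``band_px`` of the circle are split into upper and
    lower halves (image y grows downward) and each half is fitted by least
    squares to (x - h)^2 = a (y - k).
    """
    ys, xs = np.nonzero(edges.mask)
    d = np.hypot(ys - circle.y_c, xs - circle.x_c)
    near = np.abs(d - circle.r) <= band_px
    out = []
    for upper in (True, False):
        sel = near & ((ys < circle.y_c) if upper else (ys >= circle.y_c))
        if sel.sum() < 5:
            raise ValueError("too few edge points on the arc for a parabola fit")
        x, y = xs[sel].astype(float), ys[sel].astype(float)
        c2, c1, c0 = np.polyfit(x, y, 2)
        if abs(c2) < 1e-12:
            raise ValueError("arc is degenerate (no curvature)")
        a = 1.0 / c2
        h = -c1 / (2.0 * c2)
        k = c0 - c1**2 / (4.0 * c2)
        theta = np.pi / 2 if c2 > 0 else 3 * np.pi / 2
        out.append(ParabolaParam(a=abs(a), h=float(h), k=float(k), theta=theta))
    return tuple(out)


class ApproxCenter(NamedTuple):
    x: float
    y: float
    confidence: float


def edge_map(image, low_thr: float = 0.90, high_thr: float = 0.98,
             sigma: float = 1.5) -> EdgeMap:
    """Canny edge detection with hysteresis thresholds given as quantiles
    of the gradient-magnitude distribution; gradients are retained for
    later circle scoring.

    Quantile thresholds keep the edge density bounded on speckled frames:
    thresholds relative to the maximum gradient collapse when a single
    bright artifact (the ring-down halo) dominates the gradient range.
    """
    if not 0 <= low_thr < high_thr <= 1:
        raise ValueError("need 0 <= low_thr < high_thr <= 1 (quantiles)")
    img = np.asarray(image, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(img, sigma)
    gy, gx = np.gradient(smoothed)
    mag = np.hypot(gx, gy)
    orient = np.arctan2(gy, gx)
    if float(mag.max()) < 1e-12:
        logger.warning("edge_map: constant image, returning empty edge map")
        return EdgeMap(np.zeros(img.shape, dtype=bool), mag, orient)
    mask = canny(img, sigma=sigma, low_threshold=low_thr,
                 high_threshold=high_thr, use_quantiles=True)
    return EdgeMap(mask, mag, orient)


def _ring_kernel(r: int) -> np.ndarray:
    n = r + 1
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    dist = np.hypot(yy, xx)
    return (np.abs(dist - r) <= 0.5).astype(np.float64)


def cht_accumulate(edges: EdgeMap, constraints: InitConstraints) -> np.ndarray:
    """Vote for circle centres: accumulator of shape (n_radii, H, W).

    Each edge point votes for every centre at distance r from it (the dual
    of drawing radius-r circles around edge points). Votes on each radius
    plane are normalized by the ring perimeter pixel count, so a complete
    ideal circle scores ~1 regardless of its radius.
    """
    if edges.n_edges == 0:
        raise ValueError("no edges to vote")
    mask = edges.mask.astype(np.float64)
    radii = np.arange(int(round(constraints.r_min)),
                      int(round(constraints.r_max)) + 1)
    acc = np.empty((radii.size,) + mask.shape, dtype=np.float64)
    for i, r in enumerate(radii):
        ring = _ring_kernel(int(r))
        acc[i] = fftconvolve(mask, ring / ring.sum(), mode="same")
    np.clip(acc, 0.0, None, out=acc)
    return acc


def find_circles(acc: np.ndarray, constraints: InitConstraints,
                 n_max: int = 20, rel_threshold: float = 0.5) -> list[CircleParam]:
    """Peak-pick the smoothed accumulator into circle candidates.

    Votes are smoothed with a 3x3x3 box; peaks are local maxima above
    ``rel_threshold`` of the global maximum, non-max suppressed within a
    (3 radii, 5 px, 5 px) neighbourhood, returned sorted by score.
    """
    sm = ndimage.uniform_filter(acc, size=3, mode="nearest")
    peak = sm.max()
    if peak <= 0:
        return []
    local_max = sm == ndimage.maximum_filter(sm, size=(3, 5, 5), mode="nearest")
    strong = local_max & (sm > rel_threshold * peak)
    r0 = int(round(constraints.r_min))
    cands = [
        CircleParam(x_c=float(x), y_c=float(y), r=float(r0 + ri),
                    score=float(sm[ri, y, x]))
        for ri, y, x in zip(*np.nonzero(strong))
    ]
    cands.sort(key=lambda c: -c.score)
    return cands[:n_max]


def estimate_lumen_center(band, exclude_radius: float | None = None,
                          search_radius: float | None = None) -> ApproxCenter:
    """Approximate the lumen centre as the centroid of the dark blood pool.

    The band is thresholded at its Otsu level inside a central search disk
    (the blood pool always surrounds the catheter at the frame centre, and
    the restriction keeps elongated dark structures such as the guide-wire
    shadow from dragging the estimate away); among dark connected
    components that overlap the central third of the frame (a disk of
    catheter radius around the exact centre excluded), the one with the
    lowest mean intensity wins and its intensity-weighted centroid is
    returned. Degenerate inputs fall back to the frame centre with zero
    confidence.
    """
    img = np.asarray(band, dtype=np.float64)
    h, w = img.shape
    center = ApproxCenter(x=(w - 1) / 2.0, y=(h - 1) / 2.0, confidence=0.0)
    if img.max() - img.min() < 1e-12:
        logger.warning("estimate_lumen_center: uniform band, using frame centre")
        return center
    if exclude_radius is None:
        exclude_radius = max(2.0, min(h, w) / 48.0)
    if search_radius is None:
        search_radius = min(h, w) / 4.0
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - center.y, xx - center.x)
    roi = dist <= search_radius
    thr = threshold_otsu(img[roi])
    dark = (img < thr) & roi & (dist > exclude_radius)
    labels, n = ndimage.label(dark)
    if n == 0:
        return center
    central = np.zeros_like(dark)
    central[h // 3:(2 * h) // 3, w // 3:(2 * w) // 3] = True
    min_area = max(9, (h * w) // 2000)
    best, best_mean = None, np.inf
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area or not (comp & central).any():
            continue
        m = float(img[comp].mean())
        if m < best_mean:
            best, best_mean = comp, m
    if best is None:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        best = labels == (1 + int(np.argmax(sizes)))
    weight = (img[best].max() - img[best]) + 1e-12
    cy = float(np.average(yy[best], weights=weight))
    cx = float(np.average(xx[best], weights=weight))
    return ApproxCenter(x=cx, y=cy, confidence=1.0)


def select_lumen_circle(candidates: list[CircleParam], approx_center) -> CircleParam:
    """Candidate whose centre is nearest the approximate lumen centre.

    Ties (to 1e-6 px) break by higher accumulator score, then smaller radius.
    """
    if not candidates:
        raise ValueError("no lumen circle found")
    ax, ay = float(approx_center[0]), float(approx_center[1])
    return min(
        candidates,
        key=lambda c: (round(math.hypot(c.x_c - ax, c.y_c - ay), 6), -c.score, c.r),
    )


def radial_contrast(band: np.ndarray, c: CircleParam,
                    delta: float | None = None, n: int = 72) -> float:
    """Median intensity step across a circle (just outside minus just inside).

    Robust (median over angles) measure of the "change in intensity" at a
    candidate boundary: both vessel interfaces are darker inside than
    outside, so true circles score a large positive contrast while circles
    fitted to speckle score near zero.
    """
    d = delta if delta is not None else max(1.5, 0.15 * c.r)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    outer = ndimage.map_coordinates(
        band, [c.y_c + (c.r + d) * np.sin(t), c.x_c + (c.r + d) * np.cos(t)],
        order=1, mode="nearest")
    inner = ndimage.map_coordinates(
        band, [c.y_c + (c.r - d) * np.sin(t), c.x_c + (c.r - d) * np.cos(t)],
        order=1, mode="nearest")
    return float(np.median(outer - inner))


def _score_candidates(candidates: list[CircleParam], band: np.ndarray,
                      w_votes: float = 0.5, delta: float | None = None,
                      ) -> CircleParam:
    vmax = max(c.score for c in candidates) + 1e-12
    contrasts = {id(c): max(radial_contrast(band, c, delta), 0.0) for c in candidates}
    cmax = max(contrasts.values()) + 1e-12
    return max(
        candidates,
        key=lambda c: w_votes * c.score / vmax
        + (1.0 - w_votes) * contrasts[id(c)] / cmax,
    )


def select_media_circle(candidates: list[CircleParam], lumen: CircleParam,
                        constraints: InitConstraints,
                        band: np.ndarray | None = None) -> CircleParam:
    """Select the media-adventitia circle given the lumen circle.

    Feasible candidates lie within D_c of the lumen centre and are larger
    than the lumen; candidates that fully contain the lumen circle are
    preferred. The winner maximizes an equal-weight combination of
    normalized accumulator votes and radial intensity contrast across the
    circle on ``band`` (the intensity step at a boundary), falling back to
    votes alone when no band is supplied.
    """
    near = [
        c for c in candidates
        if c.center_distance(lumen) <= constraints.d_c + 1e-9
    ]
    larger = [c for c in near if c.r > lumen.r]
    contained = [c for c in larger if c.center_distance(lumen) + lumen.r < c.r]
    # prefer candidates that contain the lumen circle, but a first-pass
    # "lumen" can itself be the media circle, so fall back to any
    # concentric candidate and let the subsequent capped lumen re-search
    # restore the ordering
    pool = contained or larger or near
    if not pool:
        raise ValueError(
            "no media-adventitia candidate satisfies the constraints; "
            f"consider widening r_min/r_max ({constraints.r_min}, {constraints.r_max}) "
            f"or D_c ({constraints.d_c})"
        )
    if band is None:
        return max(pool, key=lambda c: (c.score, -c.center_distance(lumen)))
    return _score_candidates(pool, band)


def circle_contour(circle: CircleParam, n: int = 360) -> np.ndarray:
    """Rasterize a circle as a closed CCW polygon of (x, y) points."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([circle.x_c + circle.r * np.cos(t),
                            circle.y_c + circle.r * np.sin(t)])


@dataclass
class InitResult:
    """Initial contours plus the circles and per-level detection trace."""

    lumen: np.ndarray
    media: np.ndarray
    lumen_circle: CircleParam
    media_circle: CircleParam
    per_level: list[dict]

    def __iter__(self):
        # allow `lumen, media = multiresolution_initialize(...)`
        return iter((self.lumen, self.media))


def _scale_circle(c: CircleParam, s: float) -> CircleParam:
    return CircleParam(x_c=c.x_c * s, y_c=c.y_c * s, r=c.r * s, score=c.score)


def _smooth_acc(acc: np.ndarray) -> np.ndarray:
    return ndimage.uniform_filter(acc, size=3, mode="nearest")


def _window_peaks(sm: np.ndarray, r0: int, center: tuple[float, float],
                  win: float, r_lo: float, r_hi: float,
                  n_max: int = 10) -> list[CircleParam]:
    """Local accumulator maxima restricted to a centre box and radius range."""
    n_r, h, w = sm.shape
    i0 = max(0, int(np.ceil(r_lo)) - r0)
    i1 = min(n_r - 1, int(np.floor(r_hi)) - r0)
    if i1 < i0:
        return []
    cx, cy = center
    y0, y1 = max(0, int(cy - win)), min(h - 1, int(np.ceil(cy + win)))
    x0, x1 = max(0, int(cx - win)), min(w - 1, int(np.ceil(cx + win)))
    if y1 < y0 or x1 < x0:
        return []
    sub = sm[i0:i1 + 1, y0:y1 + 1, x0:x1 + 1]
    if sub.size == 0 or sub.max() <= 0:
        return []
    local = sub == ndimage.maximum_filter(sub, size=(3, 5, 5), mode="nearest")
    strong = local & (sub > 0.3 * sub.max())
    cands = [
        CircleParam(x_c=float(x0 + x), y_c=float(y0 + y), r=float(r0 + i0 + ri),
                    score=float(sub[ri, y, x]))
        for ri, y, x in zip(*np.nonzero(strong))
    ]
    cands.sort(key=lambda c: -c.score)
    return cands[:n_max]


LOG_FLOOR = 0.02  # intensity floor before log compression


def _votes_at(sm: np.ndarray, r0: int, c: CircleParam) -> float:
    """Smoothed accumulator value interpolated at an arbitrary circle."""
    v = ndimage.map_coordinates(
        sm, [[c.r - r0], [c.y_c], [c.x_c]], order=1, mode="nearest")
    return max(0.0, float(v[0]))


def _log_band(band: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(band, 0.0) + LOG_FLOOR)


def _outer_brightness(band: np.ndarray, c: CircleParam, n: int = 72) -> float:
    """Median intensity just outside a circle (its enclosing layer)."""
    d = max(2.0, 0.1 * c.r)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    vals = ndimage.map_coordinates(
        band, [c.y_c + (c.r + d) * np.sin(t), c.x_c + (c.r + d) * np.cos(t)],
        order=1, mode="nearest")
    return float(np.median(vals))


def _quality(c: CircleParam, band: np.ndarray) -> float:
    """Cross-level comparable circle quality: perimeter-normalized votes
    plus (twice) the positive radial intensity contrast on the linear band."""
    return c.score + 2.0 * max(radial_contrast(band, c), 0.0)


def _refine_circle(circle: CircleParam, level: int, pyramid, sigma_fine: float,
                   trace: list[dict]) -> CircleParam:
    """Cascade a circle from ``level`` down to level 0 with gated searches.

    At each finer level the circle is rescaled x2 and a tightly windowed
    accumulator search (centre +-2.5 px, radius +-2 px, log-compressed
    band) may replace it when the peak's votes beat the seed's own
    interpolated accumulator support by 10%.
    """
    c = circle
    for j in range(level - 1, -1, -1):
        c = _scale_circle(c, 2.0)
        band = _log_band(pyramid[j])
        sigma = sigma_fine if j == 0 else 1.0
        em = edge_map(band, sigma=sigma)
        if em.n_edges == 0:
            continue
        r_lo = max(2.0, c.r - 2.0)
        cj = InitConstraints(r_lo, c.r + 2.0, 25.0)
        sm = _smooth_acc(cht_accumulate(em, cj))
        r0 = int(round(cj.r_min))
        peaks = _window_peaks(sm, r0, (c.x_c, c.y_c), 2.5, cj.r_min, cj.r_max,
                              n_max=4)
        accepted = False
        if peaks:
            best = _score_candidates(peaks, band)
            if best.score > 1.1 * _votes_at(sm, r0, c):
                c = best
                accepted = True
        trace.append({"level": j, "refined": accepted,
                      "circle": c, "fallback": not accepted})
    return c


def multiresolution_initialize(coeffs, constraints: InitConstraints,
                               image=None) -> InitResult:
    """Multiresolution CHT over the low-pass pyramid of a decomposition.

    The radius range (r_min, r_max) and the centre-separation bound D_c
    apply at every pyramid level in that level's own pixels, so each level
    detects vessel interfaces at its natural scale: for a typical 384 px
    frame the media-adventitia circle (radius ~90 px) falls inside the
    range on the level-2 band and the lumen (radius <= media/2) on the
    level-1 band.

    Detection pass (levels J..1): on each band, accumulator peaks near the
    approximate lumen centre (dark blood-pool centroid) are scored by
    perimeter-normalized votes plus radial intensity contrast. The
    media-adventitia circle is the best-quality candidate across levels
    (the media/adventitia interface is the strongest circular edge); the
    lumen circle is then the best candidate whose full-resolution radius
    is at most half the media radius — the capped re-search — and whose
    centre lies within D_c (full-resolution) of the media centre, with
    concentric probe circles added at the level where the capped radius
    sits inside the search range. Both circles are finally cascaded to
    level 0 by tightly windowed, evidence-gated accumulator searches on
    log-compressed bands (log compression equalizes the multiplicative
    speckle across layers so weak boundary edges survive quantile
    thresholding at fine scales). Failures fall back to the coarser
    estimate with a warning rather than aborting.

    ``image`` optionally supplies the full-resolution frame a_0; if
    omitted it is reconstructed from the coefficients.
    """
    from .contourlet import contourlet_reconstruct, lowpass_pyramid

    if image is None:
        image = contourlet_reconstruct(coeffs)
    pyramid = lowpass_pyramid(image, coeffs)
    J = coeffs.levels
    trace: list[dict] = []
    r0 = int(round(constraints.r_min))
    r_hi = int(round(constraints.r_max))

    # detection pass: same pixel-range at every level
    detections: list[tuple[int, CircleParam, float]] = []
    for j in range(J, 0, -1):
        band = pyramid[j]
        if min(band.shape) < 2 * constraints.r_min:
            trace.append({"level": j, "skipped": True, "fallback": False})
            continue
        em = edge_map(band, sigma=1.0)
        info = {"level": j, "shape": band.shape, "fallback": False}
        if em.n_edges == 0:
            info["fallback"] = True
            trace.append(info)
            continue
        sm = _smooth_acc(cht_accumulate(em, constraints))
        ac = estimate_lumen_center(band)
        peaks = _window_peaks(sm, r0, (ac.x, ac.y), constraints.d_c,
                              r0, r_hi, n_max=8)
        for p in peaks:
            detections.append((j, p, _quality(p, band)))
        info["n_candidates"] = len(peaks)
        trace.append(info)

    if detections:
        # among strong candidates, the media-adventitia circle is the one
        # whose outside is brightest (the adventitia is the most echogenic
        # layer); quality alone cannot separate it from the lumen circle,
        # which is often the stronger accumulator peak
        qmax = max(q for _, _, q in detections)
        r_cap = 0.55 * min(image.shape)
        eligible = [
            (j, c, q) for j, c, q in detections
            if q >= 0.5 * qmax and c.r * 2.0 ** j <= r_cap
        ] or detections
        j_m, med_c, _ = max(
            eligible,
            key=lambda t: max(radial_contrast(pyramid[t[0]], t[1]), 0.0)
            * _outer_brightness(pyramid[t[0]], t[1]),
        )
        med_level = j_m
    else:
        logger.warning("no circle detected at any level; using geometric fallback")
        med_level = min(2, J)
        ac = estimate_lumen_center(pyramid[med_level])
        med_c = CircleParam(ac.x, ac.y, 0.9 * constraints.r_max, 0.0)
    med = _scale_circle(med_c, 2.0 ** med_level)  # full-resolution frame

    # lumen: capped radius (<= media/2), centre within D_c of the media centre
    lum_pool = [
        (j, c, q) for j, c, q in detections
        if c.r * 2.0 ** j <= med.r / 2.0 + 1e-9
        and math.hypot(c.x_c * 2.0 ** j - med.x_c,
                       c.y_c * 2.0 ** j - med.y_c) <= constraints.d_c
        and not (j == med_level and c is med_c)
    ]
    # concentric probes at the level where the capped radius fits the range
    j_probe = next(
        (j for j in range(J, 0, -1)
         if constraints.r_min <= med.r / 2.0 / 2.0 ** j <= constraints.r_max),
        None,
    )
    if j_probe is not None:
        band = pyramid[j_probe]
        s = 2.0 ** j_probe
        em = edge_map(band, sigma=1.0)
        if em.n_edges:
            sm = _smooth_acc(cht_accumulate(em, constraints))
            for rr in np.arange(r0, min(r_hi, med.r / 2.0 / s) + 1e-9, 1.0):
                c = CircleParam(med.x_c / s, med.y_c / s, float(rr),
                                _votes_at(sm, r0,
                                          CircleParam(med.x_c / s,
                                                      med.y_c / s, float(rr))))
                lum_pool.append((j_probe, c, _quality(c, band)))
    if lum_pool:
        lum_level, lum_c, _ = max(lum_pool, key=lambda t: t[2])
    else:
        logger.warning("no lumen candidate under the media/2 radius cap; "
                       "using a concentric fallback")
        lum_level = med_level
        s = 2.0 ** lum_level
        lum_c = CircleParam(med.x_c / s, med.y_c / s,
                            max(2.0, med.r / 2.5 / s), 0.0)

    # cascade both circles to full resolution with gated refinement
    med = _refine_circle(med_c, med_level, pyramid, sigma_fine=1.5, trace=trace)
    lum = _refine_circle(lum_c, lum_level, pyramid, sigma_fine=1.5, trace=trace)
    # enforce strict containment of the final pair
    gap = lum.center_distance(med) + lum.r - med.r
    if gap > -1.0:
        new_r = med.r - lum.center_distance(med) - 2.0
        if new_r < 2.0:
            lum = CircleParam(med.x_c, med.y_c, max(2.0, med.r - 4.0), lum.score)
        else:
            logger.warning("shrinking lumen radius %.1f -> %.1f to stay inside "
                           "the media circle", lum.r, new_r)
            lum = CircleParam(lum.x_c, lum.y_c, new_r, lum.score)
    if lum.center_distance(med) + lum.r >= med.r:
        raise ValueError(
            f"initialization inconsistent: lumen circle {lum} not strictly "
            f"inside media circle {med}"
        )
    return InitResult(
        lumen=circle_contour(lum),
        media=circle_contour(med),
        lumen_circle=lum,
        media_circle=med,
        per_level=trace,
    )
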