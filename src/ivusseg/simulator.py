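"""Synthetic IVUS phantom generator with known ground-truth contours.

Images are synthesized in polar coordinates around the catheter (frame
centre), mimicking ultrasonic image formation: a radial layer map — dark
blood-filled lumen, echolucent intima/media band, bright adventitia — is
multiplied by Rayleigh-distributed speckle that is spatially correlated in
the polar domain, a bright exponentially decaying ring-down halo is added
around the catheter, a guide-wire shadow attenuates one angular sector
beyond the wire position, and the result is scan-converted to the
Cartesian grid by bilinear interpolation. The ring-down halo and the
guide-wire shadow are the two catheter artifacts merged into the model.

The speckle field is the magnitude of a correlated complex Gaussian field,
so its single-pixel distribution is exactly Rayleigh even at nonzero
correlation length. ``speckle_scale`` interpolates between the noise-free
layer image (0) and fully developed speckle (1).

The two interface contours are low-order Fourier perturbations of circles
around a vessel centre that may be offset from the catheter; they are the
exact curves used to build the layer map, so segmentation error against
them is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "Phantom", "generate", "batch"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; fixed seed gives a bitwise-identical image."""

    image_size: int = 384
    # vessel geometry (pixels / radians); radii measured from the vessel
    # centre. Defaults model a diseased coronary segment at ~37 px/mm:
    # media-adventitia radius ~2.4 mm, lumen narrowed to under half of it
    # by plaque (consistent with a media/lumen radius ratio > 2).
    center_offset: tuple[float, float] = (3.5, -2.5)  # vessel centre - frame centre
    lumen_radius: float = 41.0
    lumen_amplitudes: tuple[float, ...] = (2.2, 1.1)   # harmonics m = 2, 3
    lumen_phases: tuple[float, ...] = (0.6, 2.0)
    media_radius: float = 92.0
    media_amplitudes: tuple[float, ...] = (2.6, 1.2)
    media_phases: tuple[float, ...] = (1.9, 0.8)
    # layer mean echogenicities (unit intensity scale)
    lumen_level: float = 0.08
    media_level: float = 0.25
    adventitia_level: float = 0.55
    # speckle
    speckle_scale: float = 1.0
    corr_r: float = 1.2       # correlation length along the beam (polar px)
    corr_theta: float = 1.2   # correlation length across beams (polar px)
    # catheter artifacts
    catheter_radius: float = 7.0
    catheter_level: float = 0.03
    ringdown_amp: float = 0.9
    ringdown_decay: float = 4.0
    wire_angle: float = 0.8          # sector centre (rad)
    wire_width: float = 0.30         # full sector width (rad)
    wire_attenuation: float = 0.2    # multiplicative shadow factor
    wire_radius: float = 9.0         # shadow starts beyond this radius
    seed: int = 0
    harmonics: tuple[int, ...] = (2, 3)
    n_truth_points: int = 360

    def radius_profile(self, which: str, theta: np.ndarray) -> np.ndarray:
        """r(theta) of the lumen or media interface around the vessel centre."""
        if which == "lumen":
            base, amps, phases = self.lumen_radius, self.lumen_amplitudes, self.lumen_phases
        elif which == "media":
            base, amps, phases = self.media_radius, self.media_amplitudes, self.media_phases
        else:
            raise ValueError(f"unknown interface {which!r}")
        r = np.full_like(theta, float(base))
        for m, a, p in zip(self.harmonics, amps, phases):
            r += a * np.cos(m * theta + p)
        return r

    def __post_init__(self) -> None:
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        r_l = self.radius_profile("lumen", t)
        r_m = self.radius_profile("media", t)
        if (r_m - r_l).min() < 5.0:
            raise ValueError("media-lumen gap below 5 px somewhere")
        off = float(np.hypot(*self.center_offset))
        if r_m.max() + off >= self.image_size / 2 - 5:
            raise ValueError("media contour too close to the frame border")
        if off + self.catheter_radius + 1 >= r_l.min():
            raise ValueError("catheter not strictly inside the lumen")
        if not 0 <= self.wire_attenuation <= 1:
            raise ValueError("wire_attenuation must lie in [0, 1]")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")


@dataclass
class Phantom:
    """A synthesized frame with its exact ground-truth contours."""

    image: np.ndarray
    lumen_truth: np.ndarray
    media_truth: np.ndarray
    spec: PhantomSpec
    polar_image: np.ndarray | None = None
    polar_layer: np.ndarray | None = None


def _truth_contour(spec: PhantomSpec, which: str) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, spec.n_truth_points, endpoint=False)
    r = spec.radius_profile(which, t)
    cx = (spec.image_size - 1) / 2.0 + spec.center_offset[0]
    cy = (spec.image_size - 1) / 2.0 + spec.center_offset[1]
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def _speckle_field(rng: np.random.Generator, shape: tuple[int, int],
                   corr_r: float, corr_theta: float) -> np.ndarray:
    """Unit-mean Rayleigh field, correlated in the polar domain.

    Magnitude of a complex Gaussian field whose components are smoothed
    (wrapping in the angular axis), so the marginal stays exactly Rayleigh.
    """
    re = rng.standard_normal(shape)
    im = rng.standard_normal(shape)
    if corr_r > 0 or corr_theta > 0:
        re = ndimage.gaussian_filter(re, (corr_r, corr_theta), mode=("nearest", "wrap"))
        im = ndimage.gaussian_filter(im, (corr_r, corr_theta), mode=("nearest", "wrap"))
    amp = np.hypot(re, im)
    return amp / amp.mean()


def generate(spec: PhantomSpec, keep_polar: bool = False) -> Phantom:
    """Synthesize one phantom (see module docstring for the model)."""
    size = spec.image_size
    rng = np.random.default_rng(spec.seed)
    n_r = int(size / np.sqrt(2.0)) + 8
    n_t = 720
    r = np.arange(n_r, dtype=np.float64)[:, None]
    theta = (2 * np.pi / n_t) * np.arange(n_t, dtype=np.float64)[None, :]

    # Cartesian position of each polar sample, relative to the vessel centre
    px = r * np.cos(theta) - spec.center_offset[0]
    py = r * np.sin(theta) - spec.center_offset[1]
    rho = np.hypot(px, py)
    psi = np.arctan2(py, px)
    r_lum = spec.radius_profile("lumen", psi)
    r_med = spec.radius_profile("media", psi)

    layer = np.full((n_r, n_t), spec.adventitia_level)
    layer[rho < r_med] = spec.media_level
    layer[rho < r_lum] = spec.lumen_level
    layer_id = np.full((n_r, n_t), 2, dtype=np.int8)
    layer_id[rho < r_med] = 1
    layer_id[rho < r_lum] = 0

    speckle = _speckle_field(rng, (n_r, n_t), spec.corr_r, spec.corr_theta)
    polar = layer * np.clip(1.0 + spec.speckle_scale * (speckle - 1.0), 0.0, None)

    # catheter dead zone and ring-down halo (coherent, unspeckled)
    in_cath = r < spec.catheter_radius
    polar = np.where(np.broadcast_to(in_cath, polar.shape), spec.catheter_level, polar)
    ringdown = spec.ringdown_amp * np.exp(
        -np.maximum(r - spec.catheter_radius, 0.0) / spec.ringdown_decay
    )
    polar = polar + np.where(np.broadcast_to(~in_cath, polar.shape), ringdown, 0.0)

    # guide-wire shadow sector
    dtheta = np.angle(np.exp(1j * (theta - spec.wire_angle)))
    in_sector = np.abs(dtheta) <= spec.wire_width / 2.0
    shadow = np.broadcast_to(in_sector, polar.shape) & np.broadcast_to(
        r > spec.wire_radius, polar.shape
    )
    polar = np.where(shadow, polar * spec.wire_attenuation, polar)

    # scan conversion: bilinear polar -> Cartesian
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    rr = np.hypot(xx - c, yy - c)
    tt = np.mod(np.arctan2(yy - c, xx - c), 2 * np.pi)
    polar_wrapped = np.concatenate([polar, polar[:, :1]], axis=1)
    img = ndimage.map_coordinates(
        polar_wrapped,
        [np.clip(rr, 0, n_r - 1), tt / (2 * np.pi / n_t)],
        order=1, mode="nearest",
    )
    img = np.clip(img, 0.0, 1.0)

    return Phantom(
        image=img,
        lumen_truth=_truth_contour(spec, "lumen"),
        media_truth=_truth_contour(spec, "media"),
        spec=spec,
        polar_image=polar if keep_polar else None,
        polar_layer=layer_id if keep_polar else None,
    )


def batch(n: int, base_spec: PhantomSpec | None = None, seed: int = 0,
          ) -> list[Phantom]:
    """A reproducible cohort of ``n`` phantoms with jittered geometry.

    Per-item seeds and geometry jitter derive deterministically from the
    batch seed. The cohort models diseased coronary segments: lumen base
    radius uniform in [38, 44] px, media-adventitia in [2*lumen + 6, 96] px
    — the factor-2 margin keeps the initialization's lumen radius cap
    (half the media radius) above the true lumen radius.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        lumen_r = rng.uniform(38.0, 44.0)
        media_r = rng.uniform(max(2 * lumen_r + 6.0, 88.0), 96.0)
        off_r = rng.uniform(0.0, 5.0)
        off_a = rng.uniform(0.0, 2 * np.pi)
        spec = replace(
            base,
            lumen_radius=float(lumen_r),
            media_radius=float(media_r),
            center_offset=(float(off_r * np.cos(off_a)), float(off_r * np.sin(off_a))),
            lumen_amplitudes=(float(rng.uniform(1.0, 3.0)), float(rng.uniform(0.5, 1.5))),
            lumen_phases=(float(rng.uniform(0, 2 * np.pi)), float(rng.uniform(0, 2 * np.pi))),
            media_amplitudes=(float(rng.uniform(1.0, 3.0)), float(rng.uniform(0.5, 1.5))),
            media_phases=(float(rng.uniform(0, 2 * np.pi)), float(rng.uniform(0, 2 * np.pi))),
            wire_angle=float(rng.uniform(0, 2 * np.pi)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate(spec))
    return out
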