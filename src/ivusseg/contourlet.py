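"""Contourlet decomposition: Laplacian pyramid + directional filter bank.

The multiscale stage is a Laplacian pyramid (LP) built with the biorthogonal
CDF 9/7 filter pair; synthesis is the standard LP reconstruction
``a_{j-1} = b_j + expand(a_j)``, which inverts the analysis exactly in double
precision regardless of the filters.

The directional stage is a nonsubsampled directional filter bank: each detail
band is split in the 2-D frequency plane into ``2^l`` antipodal wedge pairs by
smooth raised-cosine angular windows that form an exact partition of unity.
Subbands are full-resolution and real; reconstruction is their pointwise sum.
This lattice-free construction keeps perfect reconstruction exact and makes
per-level pooling of filtered subbands a plain sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.ndimage import convolve1d

__all__ = [
    "ContourletCoeffs",
    "lp_decompose",
    "lp_reconstruct",
    "dfb_decompose",
    "dfb_reconstruct",
    "contourlet_decompose",
    "contourlet_reconstruct",
    "lowpass_pyramid",
]

MIN_BAND = 8  # coarsest LP band must be at least this size per axis


def _cdf97_filters() -> tuple[np.ndarray, np.ndarray]:
    """Return (analysis lowpass h, synthesis lowpass g) CDF 9/7 filters.

    h is normalized to unit DC gain; g to gain 2 so that zero-upsampling
    followed by filtering preserves constants (both polyphase sums equal 1).
    """
    w = pywt.Wavelet("bior4.4")
    h = np.trim_zeros(np.asarray(w.dec_lo, dtype=np.float64))
    g = np.trim_zeros(np.asarray(w.rec_lo, dtype=np.float64))
    h = h / h.sum()
    g = 2.0 * g / g.sum()
    return h, g


_H, _G = _cdf97_filters()


def _as_image(image) -> np.ndarray:
    a = np.asarray(image, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def _sep_filter(a: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = convolve1d(a, kernel, axis=0, mode="mirror")
    return convolve1d(out, kernel, axis=1, mode="mirror")


def _pad_even(a: np.ndarray) -> np.ndarray:
    """Mirror-pad by one row/col where needed so both dims are even."""
    ph = a.shape[0] % 2
    pw = a.shape[1] % 2
    if ph or pw:
        a = np.pad(a, ((0, ph), (0, pw)), mode="reflect")
    return a


def _reduce(a: np.ndarray) -> np.ndarray:
    """One LP analysis step: lowpass filter and decimate by 2 per axis."""
    return _sep_filter(_pad_even(a), _H)[::2, ::2]


def _expand(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """One LP synthesis step: zero-upsample to 2x and interpolate with g."""
    up = np.zeros((2 * a.shape[0], 2 * a.shape[1]), dtype=np.float64)
    up[::2, ::2] = a
    out = _sep_filter(up, _G)
    return out[: shape[0], : shape[1]]


def lp_decompose(image, levels: int) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """J-level Laplacian pyramid analysis.

    Returns ``(approximations a_1..a_J, details b_1..b_J)`` where
    ``b_j = a_{j-1} - expand(a_j)`` and ``a_0`` is the input image.
    """
    a = _as_image(image)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h, w = a.shape
    for j in range(1, levels + 1):
        if min(h, w) // 2 < MIN_BAND:
            raise ValueError(
                f"image of shape {a.shape} too small for a {levels}-level pyramid: "
                f"level {j} band would fall below {MIN_BAND}x{MIN_BAND}"
            )
        h, w = (h + 1) // 2, (w + 1) // 2
    approx: list[np.ndarray] = []
    details: list[np.ndarray] = []
    cur = a
    for _ in range(levels):
        nxt = _reduce(cur)
        details.append(cur - _expand(nxt, cur.shape))
        approx.append(nxt)
        cur = nxt
    return approx, details


def lp_reconstruct(a_J, details: list[np.ndarray]) -> np.ndarray:
    """Invert :func:`lp_decompose`; exact for untouched coefficients."""
    cur = _as_image(a_J)
    for j in range(len(details) - 1, -1, -1):
        b = np.asarray(details[j], dtype=np.float64)
        if tuple((s + 1) // 2 for s in b.shape) != cur.shape:
            raise ValueError(
                f"detail at level {j + 1} has shape {b.shape}, inconsistent "
                f"with the approximation of shape {cur.shape}"
            )
        cur = b + _expand(cur, b.shape)
    return cur


def _angular_windows(shape: tuple[int, int], n_dirs: int) -> np.ndarray:
    """Smooth angular windows tiling the frequency plane into wedge pairs.

    Returns an array (n_dirs, H, W) of nonnegative masks summing to 1 at
    every frequency. Wedge k is centred on angle ``k*pi/n_dirs`` (mod pi);
    transitions are raised-cosine over half a sector width, so adjacent
    windows overlap smoothly and the tiling is exact.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    theta = np.mod(np.arctan2(fy, fx), np.pi)  # antipodal identification
    sector = np.pi / n_dirs
    t = sector / 4.0  # half transition width
    masks = np.empty((n_dirs,) + shape, dtype=np.float64)
    for k in range(n_dirs):
        d = np.mod(theta - k * sector + np.pi / 2.0, np.pi) - np.pi / 2.0
        u = (np.abs(d) - (sector / 2.0 - t)) / (2.0 * t)
        masks[k] = np.cos(0.5 * np.pi * np.clip(u, 0.0, 1.0)) ** 2
    masks /= masks.sum(axis=0)  # exact partition of unity
    return masks


def dfb_decompose(detail, levels: int) -> list[np.ndarray]:
    """Split a band into ``2^levels`` directional subbands (full resolution)."""
    a = _as_image(detail)
    if levels < 1:
        raise ValueError("directional levels must be >= 1")
    n = 2**levels
    if min(a.shape) < MIN_BAND:
        raise ValueError(f"band of shape {a.shape} too small for a DFB split")
    masks = _angular_windows(a.shape, n)
    spec = np.fft.fft2(a)
    return [np.fft.ifft2(spec * masks[k]).real for k in range(n)]


def dfb_reconstruct(subbands: list[np.ndarray]) -> np.ndarray:
    """Invert :func:`dfb_decompose`: the subbands sum back to the band."""
    if not subbands:
        raise ValueError("no subbands to reconstruct from")
    shapes = {np.asarray(s).shape for s in subbands}
    if len(shapes) != 1:
        raise ValueError(f"subband shapes disagree: {sorted(shapes)}")
    out = np.zeros(shapes.pop(), dtype=np.float64)
    for s in subbands:
        out += np.asarray(s, dtype=np.float64)
    return out


@dataclass
class ContourletCoeffs:
    """Coefficients of a contourlet decomposition.

    ``bandpass[j-1][k]`` is the k-th directional subband of pyramid level j
    (levels ordered fine to coarse, directions in wedge order, wedge k
    centred on angle k*pi/2^{l_j} in the frequency plane).
    """

    lowpass: np.ndarray
    bandpass: list[list[np.ndarray]] = field(default_factory=list)
    levels: int = 0
    dfb_levels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.levels != len(self.bandpass):
            raise ValueError("levels inconsistent with bandpass list")
        if len(self.dfb_levels) != self.levels:
            raise ValueError("dfb_levels must have one entry per pyramid level")
        for j, (subs, l) in enumerate(zip(self.bandpass, self.dfb_levels), start=1):
            if len(subs) != 2**l:
                raise ValueError(
                    f"level {j}: expected {2 ** l} directional subbands, got {len(subs)}"
                )

    @property
    def n_subbands(self) -> int:
        return sum(len(s) for s in self.bandpass)


def contourlet_decompose(image, levels: int, dfb_levels) -> ContourletCoeffs:
    """Full contourlet analysis: LP stage, then a DFB on every detail band."""
    dfb_levels = tuple(int(l) for l in dfb_levels)
    if len(dfb_levels) != levels:
        raise ValueError(
            f"need one DFB level per pyramid level: got {len(dfb_levels)} for J={levels}"
        )
    approx, details = lp_decompose(image, levels)
    bandpass = [dfb_decompose(b, l) for b, l in zip(details, dfb_levels)]
    return ContourletCoeffs(
        lowpass=approx[-1], bandpass=bandpass, levels=levels, dfb_levels=dfb_levels
    )


def contourlet_reconstruct(coeffs: ContourletCoeffs) -> np.ndarray:
    """Invert :func:`contourlet_decompose` (exact for untouched coefficients)."""
    details = [dfb_reconstruct(subs) for subs in coeffs.bandpass]
    return lp_reconstruct(coeffs.lowpass, details)


def lowpass_pyramid(image, coeffs: ContourletCoeffs) -> list[np.ndarray]:
    """Return the approximation sequence ``[a_0, a_1, ..., a_J]``.

    ``a_0`` is the input image itself; coarser members come from the LP
    stage of ``coeffs`` (recomputed from the stored coefficients so the
    sequence is consistent with them).
    """
    a = _as_image(image)
    out = [a]
    cur = a
    for _ in range(coeffs.levels):
        cur = _reduce(cur)
        out.append(cur)
    return out
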