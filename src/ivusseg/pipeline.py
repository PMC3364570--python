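"""End-to-end orchestration: decompose, initialize, despeckle, evolve, score.

The full method on one frame:

1. contourlet decomposition of the input (J pyramid levels, per-level
   directional splits);
2. coarse-to-fine circular-Hough initialization of the two contours on the
   low-pass bands;
3. anisotropic diffusion of every band-pass directional subband, per-level
   pooling and reconstruction into the despeckled frame I';
4. two independent reinitialization-free level sets evolved on I' from the
   initial circles;
5. optional MD/RMD scoring against reference contours.

The ``traditional`` baseline shares every stage except despeckling (the
level set runs on the raw frame), so the measured difference isolates the
contourlet-domain filtering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contourlet import contourlet_decompose
from .diffusion import ADParams, despeckle_coeffs
from .hough import InitConstraints, InitResult, multiresolution_initialize
from .levelset import LevelSetParams, segment
from .metrics import ContourComparison, md_rmd
from .simulator import Phantom, batch

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "run",
    "benchmark",
    "read_image",
    "write_result",
    "read_contour_csv",
    "write_contour_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All method parameters with the published defaults.

    Pyramid depth J=3 with directional splits (2, 2, 3); Hough radius range
    (15, 40) px and centre-separation bound D_c = 25 px at full resolution;
    remaining numerics per the module defaults.
    """

    levels: int = 3
    dfb_levels: tuple[int, ...] = (2, 2, 3)
    hough: InitConstraints = field(default_factory=InitConstraints)
    diffusion: ADParams = field(default_factory=ADParams)
    levelset: LevelSetParams = field(default_factory=LevelSetParams)
    nu_lumen: float = -0.3
    nu_media: float = 1.0
    # radial bias applied to the detected circles before evolution: the
    # lumen seed is deflated and the media seed inflated so that each
    # balloon force (expansion / shrink) pushes the contour TOWARD its
    # boundary from a known side — a circle through the middle of a
    # boundary would otherwise be dragged through the echolucent band on
    # the side that starts inside it
    init_bias_lumen: float = -4.0
    init_bias_media: float = 6.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "hough" in d and isinstance(d["hough"], dict):
            d["hough"] = InitConstraints(**d["hough"])
        if "diffusion" in d and isinstance(d["diffusion"], dict):
            d["diffusion"] = ADParams(**d["diffusion"])
        if "levelset" in d and isinstance(d["levelset"], dict):
            d["levelset"] = LevelSetParams(**d["levelset"])
        if "dfb_levels" in d:
            d["dfb_levels"] = tuple(d["dfb_levels"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class SegmentationResult:
    """Final contours plus the initialization and per-stage diagnostics."""

    lumen: np.ndarray
    media: np.ndarray
    initial: InitResult
    diagnostics: dict
    lumen_eval: ContourComparison | None = None
    media_eval: ContourComparison | None = None


def run(image, config: PipelineConfig | None = None,
        lumen_ref=None, media_ref=None, baseline: bool = False,
        ) -> SegmentationResult:
    """Segment one frame (or a :class:`Phantom`, whose truths become the
    references). ``baseline=True`` skips despeckling ('traditional' method)."""
    config = config or PipelineConfig()
    if isinstance(image, Phantom):
        if lumen_ref is None:
            lumen_ref = image.lumen_truth
        if media_ref is None:
            media_ref = image.media_truth
        image = image.image
    img = np.asarray(image, dtype=np.float64)
    diagnostics: dict = {"baseline": baseline}

    t0 = time.perf_counter()
    coeffs = contourlet_decompose(img, config.levels, config.dfb_levels)
    diagnostics["t_decompose"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    init = multiresolution_initialize(coeffs, config.hough, image=img)
    diagnostics["t_initialize"] = time.perf_counter() - t0
    diagnostics["init_fallbacks"] = sum(l["fallback"] for l in init.per_level)

    if baseline:
        work = img
        diagnostics["t_despeckle"] = 0.0
    else:
        t0 = time.perf_counter()
        work = despeckle_coeffs(coeffs, config.diffusion)
        diagnostics["t_despeckle"] = time.perf_counter() - t0

    from .hough import CircleParam, circle_contour

    lc, mc = init.lumen_circle, init.media_circle
    lumen0 = circle_contour(CircleParam(
        lc.x_c, lc.y_c, max(3.0, lc.r + config.init_bias_lumen), lc.score))
    media0 = circle_contour(CircleParam(
        mc.x_c, mc.y_c, mc.r + config.init_bias_media, mc.score))

    t0 = time.perf_counter()
    lumen, media, seg_diag = segment(
        work, lumen0, media0, config.levelset,
        nu_lumen=config.nu_lumen, nu_media=config.nu_media,
    )
    diagnostics["t_levelset"] = time.perf_counter() - t0
    diagnostics["segmentation"] = seg_diag

    result = SegmentationResult(
        lumen=lumen, media=media, initial=init, diagnostics=diagnostics
    )
    if lumen_ref is not None:
        result.lumen_eval = md_rmd(lumen, lumen_ref)
    if media_ref is not None:
        result.media_eval = md_rmd(media, media_ref)
    return result


def benchmark(n: int = 20, seed: int = 0, config: PipelineConfig | None = None,
              base_spec=None, methods: tuple[str, ...] = ("proposed", "traditional"),
              ) -> dict:
    """Cohort evaluation on a seeded phantom batch.

    Runs the requested methods on the same ``n`` phantoms and returns mean
    MD (px) and RMD (%) per border and method, plus the per-image table.
    """
    config = config or PipelineConfig()
    phantoms = batch(n, base_spec=base_spec, seed=seed)
    per_image: list[dict] = []
    for i, ph in enumerate(phantoms):
        row: dict = {"index": i, "seed": ph.spec.seed}
        for method in methods:
            res = run(ph, config, baseline=(method == "traditional"))
            row[method] = {
                "lumen": {"MD": res.lumen_eval.MD, "RMD": res.lumen_eval.RMD},
                "media": {"MD": res.media_eval.MD, "RMD": res.media_eval.RMD},
            }
        per_image.append(row)
        logger.info("phantom %d/%d done", i + 1, n)
    summary: dict = {"n": n, "seed": seed, "per_image": per_image}
    for method in methods:
        summary[method] = {
            border: {
                stat: float(np.mean([row[method][border][stat] for row in per_image]))
                for stat in ("MD", "RMD")
            }
            for border in ("lumen", "media")
        }
    return summary


# ---------------------------------------------------------------------------
# I/O plumbing


def read_image(path) -> np.ndarray:
    """Read a single-frame grayscale image (PNG/TIFF/DICOM) as float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim == 3:
            raise ValueError(f"{path}: multi-frame DICOM not supported")
        arr = arr.astype(np.float64)
        if arr.max() > arr.min():
            arr = (arr - arr.min()) / (arr.max() - arr.min())
        if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
            arr = 1.0 - arr
        return arr
    import imageio.v3 as iio

    raw = iio.imread(path)
    arr = raw[..., :3].mean(axis=-1) if raw.ndim == 3 else raw
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame 2-D image")
    arr = arr.astype(np.float64)
    if np.issubdtype(raw.dtype, np.integer):
        arr /= np.iinfo(raw.dtype).max
    elif arr.max() > 1.0:
        arr /= arr.max()
    return arr


def write_contour_csv(contour: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(contour, dtype=np.float64),
               delimiter=",", header="x,y", comments="")


def read_contour_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1)


def write_result(result: SegmentationResult, out_dir, image=None,
                 overlay: bool = True, stem: str = "frame") -> None:
    """Write contour CSVs, a diagnostics JSON and (optionally) an overlay PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_contour_csv(result.lumen, out / f"{stem}_lumen.csv")
    write_contour_csv(result.media, out / f"{stem}_media.csv")
    diag = {"diagnostics": _jsonable(result.diagnostics)}
    if result.lumen_eval is not None:
        diag["lumen"] = {"MD": result.lumen_eval.MD, "RMD": result.lumen_eval.RMD}
    if result.media_eval is not None:
        diag["media"] = {"MD": result.media_eval.MD, "RMD": result.media_eval.RMD}
    (out / f"{stem}_diagnostics.json").write_text(json.dumps(diag, indent=2))
    if overlay and image is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(np.asarray(image), cmap="gray", vmin=0, vmax=1)
        for contour, color, label in (
            (result.initial.lumen, "cyan", "initial"),
            (result.initial.media, "cyan", None),
            (result.lumen, "lime", "lumen"),
            (result.media, "red", "media-adventitia"),
        ):
            c = np.vstack([contour, contour[:1]])
            ax.plot(c[:, 0], c[:, 1], color=color, lw=1.0, label=label)
        ax.legend(loc="lower right", fontsize=7)
        ax.set_axis_off()
        fig.savefig(out / f"{stem}_overlay.png", dpi=150, bbox_inches="tight")
        plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
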