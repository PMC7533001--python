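"""End-to-end analysis: one image in, the three hair-loss features out.

``analyze_image`` preprocesses an image three ways (one branch per
feature), estimates the hair count by grid-line selection, the follicle
count by skeleton-endpoint clustering, and the mean thickness by the
contour-eigenvalue chain (fed with the GLS hair count). Results
serialize to JSON with fixed field order so identical inputs and seeds
give byte-identical output.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import follicle as fol
from . import gls
from . import thickness as thick
from .preprocess import PreprocessParams, preprocess

log = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "HLFResult",
    "load_image",
    "analyze_image",
    "batch_analyze",
    "write_result",
    "read_result",
    "relative_report",
]

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp")


@dataclass(frozen=True)
class AnalysisConfig:
    """All pipeline knobs in one place; see the module docs for meaning."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    n_grid: int = 8
    ratio_constant: float = 2.0
    follicle_seed: int = 0
    kmeans_max_iter: int = 10
    selection: str = "min_loss"
    gamma: float = 0.01
    alpha: float = 0.15
    p_norm: float | None = None
    s_scale: float | None = None


@dataclass
class HLFResult:
    """The hair-loss feature triple plus provenance.

    ``thickness_um`` is None when undefined (no hairs / no contours).
    ``timings`` (seconds per stage) are diagnostic only and are not
    serialized, keeping output JSON deterministic.
    """

    hair_count: float
    follicle_count: int
    thickness_um: float | None
    image: str
    params: dict
    follicle_loss: float = 0.0
    follicle_k: int = 0
    area: int = 0
    e_p: float | None = None
    lambda_bar: float | None = None
    timings: dict = field(default_factory=dict, compare=False)


def load_image(path: str | Path) -> np.ndarray:
    """Decode PNG/JPEG/BMP into an RGB uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _sig6(x: float | None):
    if x is None:
        return None
    return float(f"{float(x):.6g}")


def analyze_image(
    source: str | Path | np.ndarray,
    config: AnalysisConfig | None = None,
    debug_dir: str | Path | None = None,
) -> HLFResult:
    """Run the full pipeline on an image file or RGB array."""
    config = config or AnalysisConfig()
    if isinstance(source, (str, Path)):
        img = load_image(source)
        name = str(source)
    else:
        img = np.asarray(source)
        name = "<array>"

    timings: dict[str, float] = {}
    stages: dict[str, dict] = {b: {} for b in ("gls", "follicle", "thickness")}

    t0 = time.perf_counter()
    masks = {b: preprocess(img, config.preprocess, branch=b, stages=stages[b]) for b in stages}
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    hair = gls.estimate_hair_count(masks["gls"], n_grid=config.n_grid, ratio_constant=config.ratio_constant)
    timings["gls"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    skel = fol.skeletonize(masks["follicle"])
    endpoints = fol.detect_endpoints(skel)
    sol = fol.select_cluster_count(
        endpoints,
        rng_seed=config.follicle_seed,
        max_iter=config.kmeans_max_iter,
        selection=config.selection,
        gamma=config.gamma,
    )
    n_follicles = fol.count_follicles(sol)
    timings["follicle"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tparams = thick.ThicknessParams(
        alpha=config.alpha,
        erosion_size=config.preprocess.erosion_size,
        side=config.preprocess.resize_side,
        p=config.p_norm,
        s=config.s_scale,
    )
    est, _ = thick.thickness_from_mask(masks["thickness"], hair.h, tparams)
    timings["thickness"] = time.perf_counter() - t0

    result = HLFResult(
        hair_count=hair.h,
        follicle_count=n_follicles,
        thickness_um=est.t,
        image=name,
        params={
            "n_grid": config.n_grid,
            "ratio_constant": config.ratio_constant,
            "threshold": config.preprocess.threshold,
            "alpha": config.alpha,
            "follicle_seed": config.follicle_seed,
            "selection": config.selection,
        },
        follicle_loss=sol.loss,
        follicle_k=sol.k,
        area=est.area,
        e_p=est.e_p,
        lambda_bar=est.lambda_bar,
        timings=timings,
    )
    if debug_dir is not None:
        _dump_debug(Path(debug_dir), img, stages, masks, skel, endpoints, config)
    return result


def _result_dict(res: HLFResult) -> dict:
    return {
        "hair_count": _sig6(res.hair_count),
        "follicle_count": int(res.follicle_count),
        "thickness_um": _sig6(res.thickness_um),
        "area": int(res.area),
        "e_p": _sig6(res.e_p),
        "lambda_bar": _sig6(res.lambda_bar),
        "follicle_loss": _sig6(res.follicle_loss),
        "follicle_k": int(res.follicle_k),
        "image": res.image,
        "params": res.params,
    }


def write_result(res: HLFResult, path: str | Path, force: bool = False) -> Path:
    """Serialize a result to JSON; refuses to overwrite unless ``force``."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    path.write_text(json.dumps(_result_dict(res), indent=2) + "\n")
    return path


def read_result(path: str | Path) -> HLFResult:
    d = json.loads(Path(path).read_text())
    return HLFResult(
        hair_count=d["hair_count"],
        follicle_count=d["follicle_count"],
        thickness_um=d["thickness_um"],
        image=d["image"],
        params=d["params"],
        follicle_loss=d["follicle_loss"],
        follicle_k=d["follicle_k"],
        area=d["area"],
        e_p=d["e_p"],
        lambda_bar=d["lambda_bar"],
    )


def batch_analyze(
    directory: str | Path,
    config: AnalysisConfig | None = None,
    jsonl_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> tuple[list[HLFResult], list[str]]:
    """Analyze every readable image in a directory.

    Unreadable files are logged and skipped; their paths are returned so
    callers can signal partial failure. Optionally writes JSON-lines and
    CSV summaries.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not paths:
        raise ValueError(f"no images found in {directory}")
    results: list[HLFResult] = []
    failures: list[str] = []
    for p in paths:
        try:
            results.append(analyze_image(p, config))
        except Exception as exc:  # noqa: BLE001 - batch contract: log and continue
            log.error("failed on %s: %s", p, exc)
            failures.append(str(p))
    if jsonl_path is not None:
        with open(jsonl_path, "w") as fh:
            for r in results:
                fh.write(json.dumps(_result_dict(r)) + "\n")
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image", "hair_count", "follicle_count", "thickness_um"])
            for r in results:
                w.writerow([r.image, _sig6(r.hair_count), r.follicle_count, _sig6(r.thickness_um)])
    return results, failures


def relative_report(baseline: HLFResult, target: HLFResult) -> dict:
    """Target/baseline ratios of the three features.

    Comparing a healthy region (e.g. occipital scalp) against a
    suspected hair-loss region gives microscope-independent relative
    indicators; ratios are None where undefined.
    """

    def ratio(a, b):
        if a is None or b is None or b == 0:
            return None
        return _sig6(a / b)

    return {
        "hair_count_ratio": ratio(target.hair_count, baseline.hair_count),
        "follicle_count_ratio": ratio(target.follicle_count, baseline.follicle_count),
        "thickness_ratio": ratio(target.thickness_um, baseline.thickness_um),
    }


def _save_gray(path: Path, arr: np.ndarray) -> None:
    Image.fromarray(np.asarray(arr).astype(np.uint8)).save(path)


def _dump_debug(out: Path, img, stages, masks, skel, endpoints, config) -> None:
    """Write every intermediate image of the three branches as PNG."""
    out.mkdir(parents=True, exist_ok=True)
    g = stages["gls"]
    _save_gray(out / "gray.png", g["gray"])
    _save_gray(out / "stretched.png", g["stretched"])
    _save_gray(out / "smoothed.png", g["smoothed"])
    for b in ("follicle", "thickness"):
        _save_gray(out / f"eroded_{b}.png", stages[b]["eroded"])
    for b, m in masks.items():
        _save_gray(out / f"binary_{b}.png", m.mask.astype(np.uint8) * 255)
    _save_gray(out / "skeleton.png", skel.mask.astype(np.uint8) * 255)

    # overlays on the grayscale image
    base = np.stack([g["gray"]] * 3, axis=-1).astype(np.uint8)
    grid = gls.grid_positions(masks["gls"].side, config.n_grid)
    overlay = base.copy()
    overlay[grid.rows, :] = (0, 180, 0)
    overlay[:, grid.cols] = (0, 180, 0)
    Image.fromarray(overlay).save(out / "grid_overlay.png")

    overlay = base.copy()
    overlay[skel.mask] = (255, 255, 0)
    for r, c in endpoints.pixel_coords:
        r0, r1 = max(0, r - 2), min(overlay.shape[0], r + 3)
        c0, c1 = max(0, c - 2), min(overlay.shape[1], c + 3)
        overlay[r0:r1, c0:c1] = (255, 0, 0)
    Image.fromarray(overlay).save(out / "endpoints_overlay.png")

    overlay = base.copy()
    contours = thick.detect_contours(masks["thickness"])
    for cont in contours.contours:
        overlay[cont[:, 0], cont[:, 1]] = (0, 120, 255)
    Image.fromarray(overlay).save(out / "contours_overlay.png")
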