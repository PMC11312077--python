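"""Per-image analysis reports, CSV export and batch processing.

``analyze_pair`` ties the two channel pipelines together: CLAHE + multi-scale
droplet detection on the Nile Red channel, blur/threshold/contour counting on
the DAPI channel, and the image-level ratio droplets-per-cell.  ``run_batch``
maps that over a directory of paired files and writes one CSV row per pair;
per-image failures are logged and skipped, never fatal to the batch.

Droplets-per-cell is an image-level ratio (total droplets / total nuclei),
not an assignment of droplets to individual cells: the two channels are
analysed independently, so no droplet–cell correspondence exists.
"""

from __future__ import annotations

import csv
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

from .droplets import (
    DetectionConfig,
    SizeClassRule,
    detect_droplets,
    render_mask,
    summarize,
)
from .image import GrayImage, clahe, load_image
from .nuclei import NucleiConfig, count_nuclei

__all__ = ["AnalysisReport", "BatchSummary", "analyze_pair", "write_csv", "run_batch"]

logger = logging.getLogger("lipidquant")

CSV_COLUMNS = (
    "image_id",
    "n_droplets",
    "n_cells",
    "droplets_per_cell",
    "mean_diameter_um",
    "sd_diameter_um",
    "cv_percent",
    "pct_small",
    "pct_medium",
    "pct_large",
)


@dataclass(frozen=True)
class AnalysisReport:
    """One image pair's quantification.  ``None`` marks undefined values
    (e.g. droplets_per_cell when no cells were counted); they serialise as
    empty CSV fields."""

    image_id: str
    n_droplets: int
    n_cells: int
    droplets_per_cell: float | None
    mean_diameter_um: float | None
    sd_diameter_um: float | None
    cv_percent: float | None
    pct_small: float | None
    pct_medium: float | None
    pct_large: float | None
    config_fingerprint: str = ""


@dataclass(frozen=True)
class BatchSummary:
    n_analyzed: int
    n_failed: int
    images_per_minute: float
    csv_path: Path


def _fingerprint(det_cfg: DetectionConfig, nuc_cfg: NucleiConfig, rule: SizeClassRule) -> str:
    return (
        f"det({det_cfg.min_diameter_um},{det_cfg.max_diameter_um},{det_cfg.n_scales},"
        f"{det_cfg.response_threshold},{det_cfg.overlap_suppression},"
        f"{det_cfg.smoothing_sigma_px},{det_cfg.refine_diameters})|"
        f"nuc({nuc_cfg.blur_sigma_px},{nuc_cfg.threshold},{nuc_cfg.min_area_px})|"
        f"rule({rule.small_max_um},{rule.large_min_um})"
    )


def analyze_pair(
    droplet_img: GrayImage,
    nuclei_img: GrayImage,
    det_cfg: DetectionConfig = DetectionConfig(),
    nuc_cfg: NucleiConfig = NucleiConfig(),
    rule: SizeClassRule = SizeClassRule(),
    image_id: str = "",
    clip_limit: float = 0.03,
) -> AnalysisReport:
    """Quantify one two-channel pair.

    The droplet channel runs CLAHE → detection (diameters measured on the
    pre-equalization intensities) → summary; the nuclei channel runs the
    counting pipeline.  A pair with zero counted cells yields a report with
    ``droplets_per_cell`` undefined and a warning, not an error.
    """
    if droplet_img.microns_per_pixel != nuclei_img.microns_per_pixel:
        raise ValueError(
            f"calibration mismatch: droplet channel {droplet_img.microns_per_pixel} "
            f"µm/px vs nuclei channel {nuclei_img.microns_per_pixel} µm/px"
        )
    equalized = clahe(droplet_img, clip_limit=clip_limit)
    droplets = detect_droplets(equalized, det_cfg, measurement_image=droplet_img)
    summary = summarize(droplets, rule)
    nuclei = count_nuclei(nuclei_img, nuc_cfg)

    if nuclei.n_cells > 0:
        droplets_per_cell: float | None = summary.n_droplets / nuclei.n_cells
    else:
        droplets_per_cell = None
        warnings.warn(
            f"image {image_id or '<unnamed>'}: no cells counted; "
            "droplets_per_cell is undefined",
            stacklevel=2,
        )
    return AnalysisReport(
        image_id=image_id,
        n_droplets=summary.n_droplets,
        n_cells=nuclei.n_cells,
        droplets_per_cell=droplets_per_cell,
        mean_diameter_um=summary.mean_diameter_um,
        sd_diameter_um=summary.sd_diameter_um,
        cv_percent=summary.cv_percent,
        pct_small=summary.pct_small,
        pct_medium=summary.pct_medium,
        pct_large=summary.pct_large,
        config_fingerprint=_fingerprint(det_cfg, nuc_cfg, rule),
    )


def _fmt(value: float | int | None) -> str:
    if value is None:
        return ""
    if isinstance(value, int):
        return str(value)
    return f"{value:.4f}"


def write_csv(reports: list[AnalysisReport], path: str | Path) -> Path:
    """Write reports as RFC 4180 CSV with a fixed column order; numbers carry
    four decimals and undefined values are empty fields."""
    path = Path(path)
    try:
        fh = open(path, "w", newline="")
    except OSError as exc:
        raise OSError(f"cannot write CSV to {path}: {exc}") from exc
    with fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rep in reports:
            writer.writerow(
                [
                    rep.image_id,
                    rep.n_droplets,
                    rep.n_cells,
                    _fmt(rep.droplets_per_cell),
                    _fmt(rep.mean_diameter_um),
                    _fmt(rep.sd_diameter_um),
                    _fmt(rep.cv_percent),
                    _fmt(rep.pct_small),
                    _fmt(rep.pct_medium),
                    _fmt(rep.pct_large),
                ]
            )
    return path


def find_pairs(
    input_dir: Path,
    droplet_suffix: str,
    nuclei_suffix: str,
) -> tuple[dict[str, tuple[Path, Path]], list[Path]]:
    """Pair channel files by shared stem: ``<id><droplet_suffix>.<ext>`` with
    ``<id><nuclei_suffix>.<ext>``.  Returns (pairs by id, unmatched files)."""
    exts = {".tif", ".tiff", ".png"}
    droplet_files: dict[str, Path] = {}
    nuclei_files: dict[str, Path] = {}
    unmatched: list[Path] = []
    for path in sorted(input_dir.iterdir()):
        if path.suffix.lower() not in exts:
            continue
        stem = path.stem
        if stem.endswith(droplet_suffix):
            droplet_files[stem.removesuffix(droplet_suffix)] = path
        elif stem.endswith(nuclei_suffix):
            nuclei_files[stem.removesuffix(nuclei_suffix)] = path
        else:
            unmatched.append(path)
    pairs = {
        key: (droplet_files[key], nuclei_files[key])
        for key in sorted(droplet_files.keys() & nuclei_files.keys())
    }
    unmatched += [droplet_files[k] for k in droplet_files.keys() - pairs.keys()]
    unmatched += [nuclei_files[k] for k in nuclei_files.keys() - pairs.keys()]
    return pairs, sorted(unmatched)


def run_batch(
    input_dir: str | Path,
    output_csv: str | Path,
    microns_per_pixel: float,
    det_cfg: DetectionConfig = DetectionConfig(),
    nuc_cfg: NucleiConfig = NucleiConfig(),
    rule: SizeClassRule = SizeClassRule(),
    clip_limit: float = 0.03,
    droplet_suffix: str = "_droplets",
    nuclei_suffix: str = "_nuclei",
    mask_dir: str | Path | None = None,
    droplet_records_dir: str | Path | None = None,
) -> BatchSummary:
    """Analyse every matched channel pair in ``input_dir``.

    One CSV row per pair, rows sorted by image id (output is independent of
    directory iteration order).  Per-image failures are logged and skipped.
    When ``mask_dir`` is given, each pair's white-on-black detection mask is
    written there as an 8-bit PNG; ``droplet_records_dir`` additionally gets
    one per-droplet CSV per image (consumable by ``lipidquant evaluate``).
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise OSError(f"input directory {input_dir} does not exist")
    pairs, unmatched = find_pairs(input_dir, droplet_suffix, nuclei_suffix)
    for path in unmatched:
        logger.warning("skipping unmatched file %s", path)
    if not pairs:
        raise OSError(
            f"no channel pairs (*{droplet_suffix}/*{nuclei_suffix}) found in {input_dir}"
        )

    t_start = time.monotonic()
    reports: list[AnalysisReport] = []
    n_failed = 0
    for image_id, (droplet_path, nuclei_path) in pairs.items():
        try:
            droplet_img = load_image(droplet_path, microns_per_pixel)
            nuclei_img = load_image(nuclei_path, microns_per_pixel)
            report = analyze_pair(
                droplet_img,
                nuclei_img,
                det_cfg,
                nuc_cfg,
                rule,
                image_id=image_id,
                clip_limit=clip_limit,
            )
            if mask_dir is not None or droplet_records_dir is not None:
                equalized = clahe(droplet_img, clip_limit=clip_limit)
                droplets = detect_droplets(equalized, det_cfg, measurement_image=droplet_img)
                if mask_dir is not None:
                    mask = render_mask(droplets, droplet_img.shape, microns_per_pixel)
                    _write_mask_png(Path(mask_dir) / f"{image_id}_mask.png", mask.pixels)
                if droplet_records_dir is not None:
                    _write_droplet_records(
                        Path(droplet_records_dir) / f"{image_id}_droplets.csv", droplets
                    )
            reports.append(report)
        except Exception:
            n_failed += 1
            logger.exception("analysis failed for image pair %s", image_id)
    reports.sort(key=lambda r: r.image_id)
    csv_path = write_csv(reports, output_csv)
    elapsed_min = (time.monotonic() - t_start) / 60.0
    ipm = len(reports) / elapsed_min if elapsed_min > 0 else float("inf")
    logger.info(
        "analyzed %d pair(s), %d failure(s): %.1f images per minute",
        len(reports),
        n_failed,
        ipm,
    )
    return BatchSummary(
        n_analyzed=len(reports),
        n_failed=n_failed,
        images_per_minute=ipm,
        csv_path=csv_path,
    )


def _write_droplet_records(path: Path, droplets) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["center_row_px", "center_col_px", "diameter_um", "diameter_px", "size_class", "response"]
        )
        for rec in droplets:
            writer.writerow(
                [
                    f"{rec.center_row_px:.2f}",
                    f"{rec.center_col_px:.2f}",
                    f"{rec.diameter_um:.4f}",
                    f"{rec.diameter_px:.4f}",
                    rec.size_class,
                    f"{rec.response:.4f}",
                ]
            )


def _write_mask_png(path: Path, mask) -> None:
    import numpy as np
    import imageio.v3 as iio

    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))
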