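"""Seeded synthetic two-channel micrographs with known ground truth.

The generator emulates the features of Nile Red / DAPI micrographs that the
quantification pipelines actually key on:

* a dark background with additive Gaussian noise;
* bright circular droplets with soft (Gaussian-blurred) edges whose **peak
  intensity increases with diameter** — larger droplets are more hydrophobic
  and absorb more of the lipophilic dye, the confound that breaks
  single-window contrast analysis;
* diffuse elliptical nuclei blobs in the second channel.

Droplets are placed by rejection sampling with pairwise centre separation of
at least the sum of radii + 2 px.  Setting ``pair_large_gap_px`` places
large-class droplets in near-touching pairs (separation = sum of radii + gap),
emulating the clusters of large droplets in which the single-contrast
workflow loses them; all separations still respect the 2 px minimum.

:func:`match_detections` scores a detection list against ground truth by
greedy one-to-one centre matching and reports precision, recall, mean
absolute diameter error and per-size-class recall.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .droplets import DropletRecord, SizeClassRule, classify_size
from .image import GrayImage

__all__ = [
    "UniformDiameters",
    "BimodalDiameters",
    "SceneSpec",
    "DropletTruth",
    "NucleusTruth",
    "SceneTruth",
    "MatchReport",
    "generate_scene",
    "match_detections",
    "write_scene",
    "read_truth_csv",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class UniformDiameters:
    """Droplet diameters drawn uniformly from [min_um, max_um]."""

    min_um: float = 0.5
    max_um: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.min_um <= self.max_um):
            raise ValueError(f"need 0 < min_um <= max_um, got ({self.min_um}, {self.max_um})")

    def sample(self, rng: np.random.Generator, n: int, floor_um: float) -> np.ndarray:
        lo = max(self.min_um, floor_um)
        return rng.uniform(lo, max(self.max_um, lo), size=n)


@dataclass(frozen=True)
class BimodalDiameters:
    """Mixture of two normal diameter modes; ``mixing`` is the probability of
    the small mode.  Draws below ``floor_um`` are redrawn."""

    small_mean_um: float = 1.2
    large_mean_um: float = 5.0
    sd_um: float = 0.25
    mixing: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.small_mean_um < self.large_mean_um):
            raise ValueError("need 0 < small_mean_um < large_mean_um")
        if self.sd_um <= 0:
            raise ValueError(f"sd_um must be > 0, got {self.sd_um}")
        if not (0.0 <= self.mixing <= 1.0):
            raise ValueError(f"mixing must lie in [0, 1], got {self.mixing}")

    def sample(self, rng: np.random.Generator, n: int, floor_um: float) -> np.ndarray:
        means = np.where(
            rng.random(n) < self.mixing, self.small_mean_um, self.large_mean_um
        )
        d = rng.normal(means, self.sd_um)
        for _ in range(100):
            bad = d < floor_um
            if not bad.any():
                break
            d[bad] = rng.normal(means[bad], self.sd_um)
        return np.maximum(d, floor_um)


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterisation of one synthetic two-channel scene.

    ``intensity_base``/``intensity_gain`` define the droplet intensity law
    ``peak = base + gain × diameter_um`` (clipped to ≤ 1): with a positive
    gain, brightness is coupled to size as in real Nile Red staining.
    ``droplet_edge_softness_px`` is the Gaussian σ applied to the rendered
    droplet field (an idealised point-spread blur).  Nuclei are rendered as
    rotated anisotropic Gaussian blobs of characteristic σ
    ``nucleus_radius_px`` and axis ratio up to ``nucleus_ellipticity``.
    """

    height_px: int = 512
    width_px: int = 512
    microns_per_pixel: float = 0.2
    n_droplets: int = 50
    diameter_distribution: UniformDiameters | BimodalDiameters = field(
        default_factory=UniformDiameters
    )
    intensity_base: float = 0.25
    intensity_gain: float = 0.09  # per µm of diameter
    droplet_edge_softness_px: float = 1.0
    pair_large_gap_px: float | None = None
    n_nuclei: int = 5
    nucleus_radius_px: float = 8.0
    nucleus_ellipticity: float = 1.5
    nucleus_peak: float = 0.8
    background_level: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("image dimensions must be positive")
        if not (self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be > 0")
        if self.n_droplets < 0 or self.n_nuclei < 0:
            raise ValueError("object counts must be >= 0")
        if not (0.0 <= self.background_level < 1.0):
            raise ValueError("background_level must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.intensity_gain < 0:
            raise ValueError("intensity_gain must be >= 0")
        if self.droplet_edge_softness_px < 0:
            raise ValueError("droplet_edge_softness_px must be >= 0")
        if self.pair_large_gap_px is not None and self.pair_large_gap_px < 2.0:
            raise ValueError("pair_large_gap_px must be >= 2 (the minimum separation)")
        if self.nucleus_radius_px <= 0 or self.nucleus_ellipticity < 1.0:
            raise ValueError("nucleus_radius_px must be > 0 and ellipticity >= 1")


@dataclass(frozen=True)
class DropletTruth:
    center_row_px: float
    center_col_px: float
    diameter_um: float
    peak_intensity: float


@dataclass(frozen=True)
class NucleusTruth:
    center_row_px: float
    center_col_px: float
    sigma_major_px: float
    sigma_minor_px: float
    orientation_rad: float


@dataclass(frozen=True)
class SceneTruth:
    """Every generated object of a scene, plus the spec and seed that made it."""

    droplets: tuple[DropletTruth, ...]
    nuclei: tuple[NucleusTruth, ...]
    spec: SceneSpec
    seed: int


@dataclass(frozen=True)
class MatchReport:
    """Detection-vs-truth score.  ``precision`` is ``None`` when there are no
    detections, ``recall`` when there is no truth, class recalls when the
    class is empty in truth, and the diameter error when nothing matched."""

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float | None
    recall: float | None
    mean_abs_diameter_error_px: float | None
    recall_small: float | None
    recall_medium: float | None
    recall_large: float | None


def _peak_intensity(spec: SceneSpec, diameter_um: float) -> float:
    return min(1.0, spec.intensity_base + spec.intensity_gain * diameter_um)


def _in_bounds(r: float, c: float, margin: float, h: int, w: int) -> bool:
    return margin <= r <= h - 1 - margin and margin <= c <= w - 1 - margin


def _place_droplets(
    rng: np.random.Generator, spec: SceneSpec, diameters_um: np.ndarray
) -> list[tuple[float, float, float]]:
    """Rejection-sample droplet centres; returns (row, col, radius_px) aligned
    with ``diameters_um``.  Large-class droplets are paired when
    ``pair_large_gap_px`` is set."""
    h, w = spec.height_px, spec.width_px
    radii = diameters_um / (2.0 * spec.microns_per_pixel)
    order = np.argsort(-radii)

    groups: list[tuple[int, ...]] = []
    if spec.pair_large_gap_px is not None:
        rule = SizeClassRule()
        large = [int(i) for i in order if diameters_um[i] > rule.large_min_um]
        rest = [int(i) for i in order if diameters_um[i] <= rule.large_min_um]
        groups.extend(tuple(large[k : k + 2]) for k in range(0, len(large), 2))
        groups.extend((i,) for i in rest)
    else:
        groups.extend((int(i),) for i in order)

    placed: dict[int, tuple[float, float]] = {}
    placed_arr: list[tuple[float, float, float]] = []  # (r, c, radius)

    def ok(r: float, c: float, rad: float, extra: list[tuple[float, float, float]]) -> bool:
        for pr, pc, prad in placed_arr + extra:
            if math.hypot(pr - r, pc - c) < rad + prad + 2.0:
                return False
        return True

    for group in groups:
        rad0 = radii[group[0]]
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            margin0 = rad0 + 3.0
            if 2 * margin0 >= min(h, w):
                break
            r0 = rng.uniform(margin0, h - 1 - margin0)
            c0 = rng.uniform(margin0, w - 1 - margin0)
            if len(group) == 1:
                if ok(r0, c0, rad0, []):
                    placed[group[0]] = (r0, c0)
                    placed_arr.append((r0, c0, rad0))
                    break
            else:
                rad1 = radii[group[1]]
                theta = rng.uniform(0.0, 2.0 * math.pi)
                sep = rad0 + rad1 + spec.pair_large_gap_px
                r1 = r0 + sep * math.sin(theta)
                c1 = c0 + sep * math.cos(theta)
                if (
                    _in_bounds(r1, c1, rad1 + 3.0, h, w)
                    and ok(r0, c0, rad0, [])
                    and ok(r1, c1, rad1, [(r0, c0, rad0)])
                ):
                    placed[group[0]] = (r0, c0)
                    placed[group[1]] = (r1, c1)
                    placed_arr.append((r0, c0, rad0))
                    placed_arr.append((r1, c1, rad1))
                    break
        else:
            raise RuntimeError(
                f"could not place droplet of radius {rad0:.1f} px after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts — request fewer or smaller "
                f"droplets, or a larger scene"
            )
        if group[0] not in placed:
            raise RuntimeError(
                f"scene of {h}×{w} px cannot hold a droplet of radius {rad0:.1f} px"
            )
    return [(placed[i][0], placed[i][1], float(radii[i])) for i in range(len(diameters_um))]


def _render_droplet_field(
    spec: SceneSpec,
    placements: list[tuple[float, float, float]],
    peaks: np.ndarray,
) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    canvas = np.zeros((h, w), dtype=float)
    for (r, c, rad), peak in zip(placements, peaks):
        # Anti-aliased hard disk: per-pixel coverage ramp of 1 px at the rim.
        lo_r = max(0, int(math.floor(r - rad - 2)))
        hi_r = min(h, int(math.ceil(r + rad + 3)))
        lo_c = max(0, int(math.floor(c - rad - 2)))
        hi_c = min(w, int(math.ceil(c + rad + 3)))
        rows = np.arange(lo_r, hi_r)[:, None]
        cols = np.arange(lo_c, hi_c)[None, :]
        rho = np.hypot(rows - r, cols - c)
        coverage = np.clip(rad - rho + 0.5, 0.0, 1.0)
        patch = canvas[lo_r:hi_r, lo_c:hi_c]
        np.maximum(patch, peak * coverage, out=patch)
    if spec.droplet_edge_softness_px > 0:
        canvas = ndi.gaussian_filter(canvas, spec.droplet_edge_softness_px, mode="constant")
    return canvas


def _render_nuclei_field(
    spec: SceneSpec, nuclei: list[NucleusTruth]
) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    canvas = np.zeros((h, w), dtype=float)
    for nuc in nuclei:
        s_maj, s_min, phi = nuc.sigma_major_px, nuc.sigma_minor_px, nuc.orientation_rad
        ext = 4.0 * s_maj
        lo_r = max(0, int(math.floor(nuc.center_row_px - ext)))
        hi_r = min(h, int(math.ceil(nuc.center_row_px + ext + 1)))
        lo_c = max(0, int(math.floor(nuc.center_col_px - ext)))
        hi_c = min(w, int(math.ceil(nuc.center_col_px + ext + 1)))
        rows = np.arange(lo_r, hi_r)[:, None] - nuc.center_row_px
        cols = np.arange(lo_c, hi_c)[None, :] - nuc.center_col_px
        u = rows * math.cos(phi) + cols * math.sin(phi)
        v = -rows * math.sin(phi) + cols * math.cos(phi)
        q = (u / s_maj) ** 2 + (v / s_min) ** 2
        patch = canvas[lo_r:hi_r, lo_c:hi_c]
        np.maximum(patch, spec.nucleus_peak * np.exp(-0.5 * q), out=patch)
    return canvas


def _place_nuclei(rng: np.random.Generator, spec: SceneSpec) -> list[NucleusTruth]:
    h, w = spec.height_px, spec.width_px
    nuclei: list[NucleusTruth] = []
    for _ in range(spec.n_nuclei):
        ratio = rng.uniform(1.0, spec.nucleus_ellipticity)
        s_maj = spec.nucleus_radius_px * math.sqrt(ratio)
        s_min = spec.nucleus_radius_px / math.sqrt(ratio)
        phi = rng.uniform(0.0, math.pi)
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            margin = 3.0 * s_maj
            if 2 * margin >= min(h, w):
                raise RuntimeError(
                    f"scene of {h}×{w} px cannot hold a nucleus of σ {s_maj:.1f} px"
                )
            r = rng.uniform(margin, h - 1 - margin)
            c = rng.uniform(margin, w - 1 - margin)
            # Non-overlapping means disjoint *thresholded supports*: a blob's
            # support at a mid-level threshold reaches ~1.6 σ (plus counting
            # blur), so separation of 2 σ per blob keeps supports disjoint
            # even for majors pointing at each other.
            if all(
                math.hypot(n.center_row_px - r, n.center_col_px - c)
                >= 2.0 * (s_maj + n.sigma_major_px) + 4.0
                for n in nuclei
            ):
                nuclei.append(NucleusTruth(r, c, s_maj, s_min, phi))
                break
        else:
            raise RuntimeError(
                f"could not place nucleus after {_MAX_PLACEMENT_ATTEMPTS} attempts — "
                f"request fewer or smaller nuclei"
            )
    return nuclei


def generate_scene(spec: SceneSpec) -> tuple[GrayImage, GrayImage, SceneTruth]:
    """Generate the droplet channel, the nuclei channel and their ground truth.

    Deterministic for a fixed ``spec`` (including its seed): the same spec
    yields bit-identical channels and truth.
    """
    rng = np.random.default_rng(spec.seed)
    floor_um = 2.0 * spec.microns_per_pixel  # nothing below 2 px diameter
    diameters = spec.diameter_distribution.sample(rng, spec.n_droplets, floor_um)
    placements = _place_droplets(rng, spec, diameters)
    peaks = np.array([_peak_intensity(spec, d) for d in diameters])
    droplet_field = _render_droplet_field(spec, placements, peaks)

    nuclei = _place_nuclei(rng, spec)
    nuclei_field = _render_nuclei_field(spec, nuclei)

    droplet_px = spec.background_level + droplet_field
    nuclei_px = spec.background_level + nuclei_field
    if spec.noise_sd > 0:
        droplet_px = droplet_px + rng.normal(0.0, spec.noise_sd, droplet_px.shape)
        nuclei_px = nuclei_px + rng.normal(0.0, spec.noise_sd, nuclei_px.shape)
    droplet_px = np.clip(droplet_px, 0.0, 1.0)
    nuclei_px = np.clip(nuclei_px, 0.0, 1.0)

    truth = SceneTruth(
        droplets=tuple(
            DropletTruth(r, c, float(d), float(p))
            for (r, c, _rad), d, p in zip(placements, diameters, peaks)
        ),
        nuclei=tuple(nuclei),
        spec=spec,
        seed=spec.seed,
    )
    mpp = spec.microns_per_pixel
    return (
        GrayImage(droplet_px, mpp),
        GrayImage(nuclei_px, mpp),
        truth,
    )


def match_detections(
    truth: SceneTruth,
    detections: list[DropletRecord],
    tol_px: float = 3.0,
    rule: SizeClassRule = SizeClassRule(),
) -> MatchReport:
    """Greedy one-to-one matching of detections to true droplets.

    Candidate pairs within ``tol_px`` centre distance are matched in order of
    ascending distance; unmatched truth becomes false negatives, unmatched
    detections false positives.  Per-class recall is computed on the *true*
    diameters under ``rule``.
    """
    if not (tol_px > 0):
        raise ValueError(f"tol_px must be > 0, got {tol_px}")
    mpp = truth.spec.microns_per_pixel
    nt, nd = len(truth.droplets), len(detections)
    pairs: list[tuple[float, int, int]] = []
    for i, t in enumerate(truth.droplets):
        for j, det in enumerate(detections):
            dist = math.hypot(
                t.center_row_px - det.center_row_px, t.center_col_px - det.center_col_px
            )
            if dist <= tol_px:
                pairs.append((dist, i, j))
    pairs.sort()
    matched_t: dict[int, int] = {}
    used_d: set[int] = set()
    for _dist, i, j in pairs:
        if i in matched_t or j in used_d:
            continue
        matched_t[i] = j
        used_d.add(j)

    tp = len(matched_t)
    fp = nd - tp
    fn = nt - tp
    diam_errors = [
        abs(truth.droplets[i].diameter_um / mpp - detections[j].diameter_px)
        for i, j in matched_t.items()
    ]

    class_tot = {"small": 0, "medium": 0, "large": 0}
    class_hit = {"small": 0, "medium": 0, "large": 0}
    for i, t in enumerate(truth.droplets):
        k = classify_size(t.diameter_um, rule)
        class_tot[k] += 1
        if i in matched_t:
            class_hit[k] += 1

    def _recall(k: str) -> float | None:
        return class_hit[k] / class_tot[k] if class_tot[k] > 0 else None

    return MatchReport(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=tp / nd if nd > 0 else None,
        recall=tp / nt if nt > 0 else None,
        mean_abs_diameter_error_px=float(np.mean(diam_errors)) if diam_errors else None,
        recall_small=_recall("small"),
        recall_medium=_recall("medium"),
        recall_large=_recall("large"),
    )


def write_scene(
    out_dir: str | Path,
    stem: str,
    droplet_channel: GrayImage,
    nuclei_channel: GrayImage,
    truth: SceneTruth,
) -> tuple[Path, Path, Path]:
    """Write a scene as a 16-bit TIFF pair plus a truth-table CSV (one row per
    object).  Returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    drop_path = out_dir / f"{stem}_droplets.tif"
    nuc_path = out_dir / f"{stem}_nuclei.tif"
    truth_path = out_dir / f"{stem}_truth.csv"
    for path, img in ((drop_path, droplet_channel), (nuc_path, nuclei_channel)):
        tifffile.imwrite(path, np.round(img.pixels * 65535.0).astype(np.uint16))
    with open(truth_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "type",
                "center_row_px",
                "center_col_px",
                "diameter_um",
                "sigma_major_px",
                "sigma_minor_px",
                "peak_intensity",
                "seed",
            ]
        )
        for d in truth.droplets:
            writer.writerow(
                [
                    "droplet",
                    f"{d.center_row_px:.4f}",
                    f"{d.center_col_px:.4f}",
                    f"{d.diameter_um:.4f}",
                    "",
                    "",
                    f"{d.peak_intensity:.4f}",
                    truth.seed,
                ]
            )
        for n in truth.nuclei:
            writer.writerow(
                [
                    "nucleus",
                    f"{n.center_row_px:.4f}",
                    f"{n.center_col_px:.4f}",
                    "",
                    f"{n.sigma_major_px:.4f}",
                    f"{n.sigma_minor_px:.4f}",
                    "",
                    truth.seed,
                ]
            )
    return drop_path, nuc_path, truth_path


def read_truth_csv(path: str | Path, spec: SceneSpec | None = None) -> SceneTruth:
    """Reload a truth table written by :func:`write_scene`.  A ``spec`` may be
    supplied to carry the calibration; otherwise defaults are assumed."""
    droplets: list[DropletTruth] = []
    nuclei: list[NucleusTruth] = []
    seed = 0
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            seed = int(row["seed"])
            if row["type"] == "droplet":
                droplets.append(
                    DropletTruth(
                        float(row["center_row_px"]),
                        float(row["center_col_px"]),
                        float(row["diameter_um"]),
                        float(row["peak_intensity"]),
                    )
                )
            else:
                nuclei.append(
                    NucleusTruth(
                        float(row["center_row_px"]),
                        float(row["center_col_px"]),
                        float(row["sigma_major_px"]),
                        float(row["sigma_minor_px"]),
                        0.0,
                    )
                )
    if spec is None:
        spec = SceneSpec(n_droplets=len(droplets), n_nuclei=len(nuclei), seed=seed)
    return SceneTruth(tuple(droplets), tuple(nuclei), spec, seed)
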