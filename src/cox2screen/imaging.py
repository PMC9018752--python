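"""Segmentation masks and per-well aggregation for two-channel well images.

Two masks are computed per field, mirroring a live-cell imager's analysis
definition:

* **GFP-object mask** -- white top-hat background subtraction (disc radius
  10 um), fixed intensity threshold (0.2 GCU), connected components, area
  filter strictly > 80 um^2.  The per-object readout is the mean subtracted
  intensity over the object's pixels; the per-well readout is the unweighted
  mean over objects.
* **Confluence mask** -- local-texture segmentation of the phase-like
  channel (standard-deviation filter over a 10 um window), components
  strictly > 250 um^2 to exclude cell debris, reported as percent of the
  field area.

The texture algorithm is this package's own; only the threshold constants
and area filters follow the published analysis definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "SegmentationParams",
    "GFPObject",
    "tophat",
    "detect_gfp_objects",
    "well_gfp_mean",
    "confluence_percent",
    "segment_timelapse",
]


@dataclass(frozen=True)
class SegmentationParams:
    um_per_px: float = 2.0
    tophat_radius_um: float = 10.0
    gcu_threshold: float = 0.2
    gfp_min_area_um2: float = 80.0          # strict >
    confluence_min_area_um2: float = 250.0  # strict >
    connectivity: int = 8                   # 4 or 8
    texture_window_um: float = 10.0
    texture_threshold: float = 0.05
    # measure object means on the subtracted image (the quantity the
    # threshold was applied to); set False to measure on the raw image
    mean_on_subtracted: bool = True

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        for name in ("tophat_radius_um", "gcu_threshold", "gfp_min_area_um2",
                     "confluence_min_area_um2", "texture_window_um",
                     "texture_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SegmentationParams.{name} must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def tophat_radius_px(self) -> int:
        return int(round(self.tophat_radius_um / self.um_per_px))

    @property
    def px_area_um2(self) -> float:
        return self.um_per_px ** 2

    @property
    def _skimage_connectivity(self) -> int:
        return 2 if self.connectivity == 8 else 1


@dataclass(frozen=True)
class GFPObject:
    """One connected GFP+ component (a cell or small cluster of cells)."""

    label: int
    area_um2: float
    mean_gcu: float
    centroid_um: tuple[float, float]  # (x right, y down), origin top-left


def tophat(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """White top-hat background subtraction with a disc structuring element.

    Removes background structures larger than the disc (image minus its
    morphological opening); the result is >= 0 everywhere.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    r = params.tophat_radius_px
    if r < 1:
        raise ValueError(
            f"top-hat radius {params.tophat_radius_um} um is < 1 px at "
            f"{params.um_per_px} um/px")
    return morphology.white_tophat(image, footprint=morphology.disk(r))


def detect_gfp_objects(image: np.ndarray, params: SegmentationParams,
                       raw_image: np.ndarray | None = None) -> list[GFPObject]:
    """Detect GFP+ objects in a background-subtracted image.

    Pixels >= the GCU threshold form the mask; connected components at the
    configured connectivity are kept when their area is strictly greater
    than the minimum object area.  Object means are measured on ``image``
    (the subtracted one) unless the parameters select the raw image, in
    which case ``raw_image`` must be given.
    """
    image = np.asarray(image, dtype=float)
    if params.mean_on_subtracted:
        meas = image
    else:
        if raw_image is None:
            raise ValueError("raw_image required when mean_on_subtracted=False")
        meas = np.asarray(raw_image, dtype=float)
    mask = image >= params.gcu_threshold
    labels = measure.label(mask, connectivity=params._skimage_connectivity)
    objects = []
    for region in measure.regionprops(labels, intensity_image=meas):
        area = region.area * params.px_area_um2
        if area <= params.gfp_min_area_um2:
            continue
        cy, cx = region.centroid
        objects.append(GFPObject(
            label=int(region.label),
            area_um2=float(area),
            mean_gcu=float(region.intensity_mean),
            centroid_um=(float(cx * params.um_per_px),
                         float(cy * params.um_per_px)),
        ))
    return objects


def well_gfp_mean(objects: list[GFPObject]) -> float:
    """Unweighted mean of per-object mean intensities; 0.0 for no objects.

    With multiple fields per well, pass the pooled object list.  The
    zero-object convention keeps 'no signal' finite; downstream fold changes
    apply a control floor.
    """
    if not objects:
        return 0.0
    return float(np.mean([o.mean_gcu for o in objects]))


def _local_std(image: np.ndarray, window_px: int) -> np.ndarray:
    m = ndimage.uniform_filter(image, size=window_px, mode="reflect")
    m2 = ndimage.uniform_filter(image * image, size=window_px, mode="reflect")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def confluence_percent(phase_image: np.ndarray, params: SegmentationParams) -> float:
    """Percent of the field covered by textured (cell-occupied) area.

    The standard-deviation filter fires inside speckled cell bodies and in a
    halo of ~half a window around their edges; the mask is eroded by that
    halo before the debris area filter is applied.
    """
    phase_image = np.asarray(phase_image, dtype=float)
    if phase_image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    window_px = max(3, int(round(params.texture_window_um / params.um_per_px)))
    std = _local_std(phase_image, window_px)
    mask = std > params.texture_threshold
    halo = window_px // 2
    if halo >= 1 and mask.any() and not mask.all():
        mask = morphology.erosion(mask, footprint=morphology.disk(halo))
    labels = measure.label(mask, connectivity=params._skimage_connectivity)
    if labels.max():
        areas = np.bincount(labels.ravel())[1:] * params.px_area_um2
        keep = np.flatnonzero(areas > params.confluence_min_area_um2) + 1
        mask = np.isin(labels, keep)
    return float(100.0 * mask.sum() / mask.size)


def segment_timelapse(manifest: pd.DataFrame, params: SegmentationParams, *,
                      gain_gcu_per_count: float = 1e-3) -> pd.DataFrame:
    """Segment a rendered/acquired image set into a per-well time-series table.

    ``manifest`` needs columns plate, well, time_h, channel ('phase' or
    'green'), path and um_per_px.  Returns one row per (plate, well, time)
    with confluence_pct, gfp_mean_gcu and n_gfp_objects, sorted by plate,
    well, time.  Missing time points are simply absent (never interpolated).
    """
    import tifffile

    required = {"plate", "well", "time_h", "channel", "path", "um_per_px"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")

    rows = []
    for (plate, well), well_df in manifest.groupby(["plate", "well"], sort=True):
        scales = well_df["um_per_px"].unique()
        if len(scales) != 1:
            raise ValueError(
                f"inconsistent pixel scale for well {plate}/{well}: {scales}")
        p = params if scales[0] == params.um_per_px else \
            SegmentationParams(**{**params.__dict__, "um_per_px": float(scales[0])})
        for t, t_df in well_df.groupby("time_h", sort=True):
            images = {}
            for _, rec in t_df.iterrows():
                try:
                    images[rec["channel"]] = tifffile.imread(rec["path"]).astype(float) \
                        * gain_gcu_per_count
                except (OSError, ValueError) as exc:
                    raise OSError(f"cannot read image {rec['path']!r}: {exc}") from exc
            n_obj = 0
            gfp = 0.0
            if "green" in images:
                sub = tophat(images["green"], p)
                objects = detect_gfp_objects(sub, p, raw_image=images["green"])
                n_obj = len(objects)
                gfp = well_gfp_mean(objects)
            conf = confluence_percent(images["phase"], p) if "phase" in images else np.nan
            rows.append((plate, well, float(t), conf, gfp, n_obj))
    out = pd.DataFrame(rows, columns=["plate", "well", "time_h",
                                      "confluence_pct", "gfp_mean_gcu",
                                      "n_gfp_objects"])
    return out.sort_values(["plate", "well", "time_h"], ignore_index=True)
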