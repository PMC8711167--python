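"""Plaque segmentation in spectral lambda stacks.

Plaques are detected on the total-intensity projection (sum over all channels
of all dyes) by Otsu or fixed thresholding, connected-component labeling, and
an area filter; false-positive objects (e.g. plaque-associated NFTs) are
removed via a file-driven exclusion list or ROI polygons rather than
interactively, so the manual curation step is reproducible.  Per-plaque
spectra are the channel-wise mean intensities over each label's pixels.

Analysis is 2-D on the single optical plane per field of view.  Pixel
coordinates are 0-based row-major (row, col).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .spectra import EmissionSpectrum


@dataclass
class LambdaStack:
    """Per-dye spectral volumes sharing one image plane."""

    per_dye_volumes: dict[str, np.ndarray]  # dye -> (n_channels, H, W)
    channel_wavelengths: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.channel_wavelengths = np.asarray(self.channel_wavelengths, dtype=float)
        shapes = {v.shape[1:] for v in self.per_dye_volumes.values()}
        if len(shapes) > 1:
            raise ValueError(f"dye volumes have mismatched image shapes: {shapes}")
        for dye, vol in self.per_dye_volumes.items():
            if vol.shape[0] != self.channel_wavelengths.size:
                raise ValueError(
                    f"dye {dye!r}: {vol.shape[0]} channels but "
                    f"{self.channel_wavelengths.size} wavelengths"
                )

    @property
    def image_shape(self) -> tuple[int, int]:
        return next(iter(self.per_dye_volumes.values())).shape[1:]


@dataclass
class SegmentationParams:
    threshold_method: str = "otsu"  # "otsu" or "fixed"
    fixed_threshold: float | None = None
    min_area_px: int = 50
    max_area_px: int = 50000
    connectivity: int = 8  # 4 or 8

    def __post_init__(self) -> None:
        if not 0 < self.min_area_px <= self.max_area_px:
            raise ValueError("require 0 < min_area_px <= max_area_px")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")


@dataclass
class PlaqueMaskSet:
    """Disjoint plaque labels: 0 background, k > 0 plaque k."""

    label_image: np.ndarray
    areas: dict[int, int] = field(default_factory=dict)
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        return sorted(self.areas)

    @property
    def n_labels(self) -> int:
        return len(self.areas)


@dataclass
class ExclusionSet:
    """Labels and/or ROI polygons (rows of (row, col) vertices) to remove."""

    excluded_label_ids: frozenset[int] = frozenset()
    roi_polygons: tuple[np.ndarray, ...] = ()


def project_total_intensity(stack: LambdaStack) -> np.ndarray:
    """Pixel-wise sum over all channels of all dyes."""
    return sum(vol.sum(axis=0) for vol in stack.per_dye_volumes.values())


def _relabel_raster_order(labels: np.ndarray, keep: list[int]) -> PlaqueMaskSet:
    """Renumber surviving labels 1..K by raster order of each label's first pixel."""
    flat = labels.ravel()
    first_pixel = {}
    for lab in keep:
        first_pixel[lab] = int(np.flatnonzero(flat == lab)[0])
    ordered = sorted(keep, key=lambda lab: first_pixel[lab])
    out = np.zeros_like(labels, dtype=np.int32)
    areas: dict[int, int] = {}
    centroids: dict[int, tuple[float, float]] = {}
    for new, old in enumerate(ordered, start=1):
        mask = labels == old
        out[mask] = new
        areas[new] = int(mask.sum())
        rr, cc = np.nonzero(mask)
        centroids[new] = (float(rr.mean()), float(cc.mean()))
    return PlaqueMaskSet(label_image=out, areas=areas, centroids=centroids)


def segment_plaques(image: np.ndarray, params: SegmentationParams) -> PlaqueMaskSet:
    """Threshold -> connected components -> area filter -> stable relabel."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)) or np.any(image < 0):
        raise ValueError("image must be finite and nonnegative")
    if params.threshold_method == "fixed":
        thresh = float(params.fixed_threshold)
    else:
        if np.ptp(image) == 0:
            return PlaqueMaskSet(label_image=np.zeros(image.shape, dtype=np.int32))
        thresh = float(threshold_otsu(image))
    binary = image > thresh
    conn = 1 if params.connectivity == 4 else 2
    raw = cc_label(binary, connectivity=conn)
    keep = [
        int(p.label)
        for p in regionprops(raw)
        if params.min_area_px <= p.area <= params.max_area_px
    ]
    if not keep:
        return PlaqueMaskSet(label_image=np.zeros(image.shape, dtype=np.int32))
    return _relabel_raster_order(raw, keep)


def apply_exclusions(masks: PlaqueMaskSet, excl: ExclusionSet) -> PlaqueMaskSet:
    """Remove excluded labels and labels overlapped > 50% by any exclusion ROI."""
    drop: set[int] = set()
    for lab in excl.excluded_label_ids:
        if lab in masks.areas:
            drop.add(int(lab))
        else:
            warnings.warn(f"exclusion references unknown label {lab}; ignored",
                          stacklevel=2)
    shape = masks.label_image.shape
    for poly in excl.roi_polygons:
        poly = np.asarray(poly, dtype=float)
        roi = polygon2mask(shape, poly)
        for lab in masks.labels:
            if lab in drop:
                continue
            overlap = int(np.count_nonzero(roi & (masks.label_image == lab)))
            if overlap > 0.5 * masks.areas[lab]:
                drop.add(lab)
    keep = [lab for lab in masks.labels if lab not in drop]
    if not keep:
        return PlaqueMaskSet(label_image=np.zeros(shape, dtype=np.int32))
    return _relabel_raster_order(masks.label_image, keep)


def extract_plaque_spectra(
    stack: LambdaStack, masks: PlaqueMaskSet
) -> dict[int, dict[str, EmissionSpectrum]]:
    """Channel-wise mean intensity over each label's pixels, per dye."""
    if masks.label_image.shape != stack.image_shape:
        raise ValueError("mask shape does not match stack image shape")
    out: dict[int, dict[str, EmissionSpectrum]] = {}
    for lab in masks.labels:
        mask = masks.label_image == lab
        if not mask.any():
            warnings.warn(f"label {lab} has zero area; excluded", stacklevel=2)
            continue
        per_dye = {}
        for dye, vol in stack.per_dye_volumes.items():
            mean_spec = vol[:, mask].mean(axis=1)
            per_dye[dye] = EmissionSpectrum(
                dye=dye,
                wavelengths=stack.channel_wavelengths,
                intensities=np.clip(mean_spec, 0.0, None),
            )
        out[lab] = per_dye
    return out


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O

def write_lambda_stack(stack: LambdaStack, directory, prefix: str = "stack") -> None:
    """One multi-page TIFF per dye plus a JSON wavelength sidecar."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for dye, vol in stack.per_dye_volumes.items():
        tifffile.imwrite(directory / f"{prefix}_{dye}.tif", vol.astype(np.float32))
    sidecar = {
        "dyes": sorted(stack.per_dye_volumes),
        "channel_wavelengths_nm": stack.channel_wavelengths.tolist(),
        "pixel_size_um": stack.pixel_size_um,
    }
    (directory / f"{prefix}_channels.json").write_text(json.dumps(sidecar, indent=2))


def read_lambda_stack(directory, prefix: str = "stack") -> LambdaStack:
    from pathlib import Path

    directory = Path(directory)
    sidecar = json.loads((directory / f"{prefix}_channels.json").read_text())
    volumes = {
        dye: tifffile.imread(directory / f"{prefix}_{dye}.tif").astype(float)
        for dye in sidecar["dyes"]
    }
    return LambdaStack(
        per_dye_volumes=volumes,
        channel_wavelengths=np.asarray(sidecar["channel_wavelengths_nm"]),
        pixel_size_um=sidecar.get("pixel_size_um"),
    )


def write_label_tiff(masks: PlaqueMaskSet, path) -> None:
    tifffile.imwrite(path, masks.label_image.astype(np.uint16))
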