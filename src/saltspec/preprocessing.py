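"""Flat-field correction, illumination audit, plant segmentation, masking.

The platform illuminates each pot with narrow-band LEDs whose field is not
perfectly uniform (vignetting); every raw band image is therefore normalized
by a white-reference frame of a gray-painted plate and a dark-current frame:

    R = (S - D) / (W - D) * 100

giving percent-scale images comparable across the field.  The plant region of
interest is a mask segmented from the corrected far-red fluorescence band
(F740), where chlorophyll emission gives the strongest plant/background
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import (
    BandMismatchError,
    MaskError,
    SaltSpecError,
    SegmentationError,
    ShapeMismatchError,
    UndefinedStatisticError,
)
from .imaging_io import BandImage, SampleRecord


@dataclass
class ReferenceSet:
    """Paired white-reference and dark-current frames per band."""

    white: dict[str, BandImage]
    dark: dict[str, BandImage]

    def __post_init__(self) -> None:
        if set(self.white) != set(self.dark):
            raise SaltSpecError("white and dark frames must cover the same band set")
        for label in self.white:
            if self.white[label].shape != self.dark[label].shape:
                raise ShapeMismatchError(f"white/dark shape mismatch for {label}")

    def usable(self, band_label: str) -> bool:
        """Band usable iff white - dark is positive somewhere in the field."""
        w = self.white[band_label].pixels.astype(float)
        d = self.dark[band_label].pixels.astype(float)
        return bool(np.any(w - d > 0))


@dataclass
class PlantMask:
    """Boolean plant region of interest; one connected component after cleanup."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise MaskError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def correct_flat_field(sample: BandImage, refs: ReferenceSet) -> BandImage:
    """Flat-field-correct one band to a percent scale.

    Output pixels are ``(S - D) / (W - D) * 100``, clipped below at 0.  Pixels
    where the reference dynamic ``W - D`` is non-positive are set to 0 and
    tallied in the output's ``meta['invalid_px']``.
    """
    label = sample.band_label
    if label not in refs.white:
        raise BandMismatchError(f"reference set has no band {label}")
    white, dark = refs.white[label], refs.dark[label]
    if sample.shape != white.shape:
        raise ShapeMismatchError(
            f"sample {sample.shape} vs reference {white.shape} for band {label}"
        )
    s = sample.pixels.astype(np.float64)
    w = white.pixels.astype(np.float64)
    d = dark.pixels.astype(np.float64)
    denom = w - d
    valid = denom > 0
    out = np.zeros_like(s)
    np.divide(s - d, denom, out=out, where=valid)
    out *= 100.0
    np.clip(out, 0.0, None, out=out)
    out[~valid] = 0.0
    return BandImage(
        pixels=out,
        band_label=label,
        role="sample",
        exposure_ms=sample.exposure_ms,
        meta={"invalid_px": int((~valid).sum()), "scale": "percent"},
    )


def correct_sample(record: SampleRecord, refs: ReferenceSet) -> SampleRecord:
    """Flat-field-correct every band of a sample record."""
    corrected = {
        label: correct_flat_field(band, refs) for label, band in record.bands.items()
    }
    return SampleRecord(
        pot_id=record.pot_id,
        view_index=record.view_index,
        period_days=record.period_days,
        class_label=record.class_label,
        bands=corrected,
    )


def uniformity_cv(image: BandImage, field_mask: PlantMask) -> float:
    """Coefficient of variation (%) of masked pixels: 100 * sd / mean.

    Population (n-denominator) standard deviation.
    """
    if field_mask.area_px == 0:
        raise MaskError("uniformity_cv requires a non-empty mask")
    if image.shape != field_mask.shape:
        raise ShapeMismatchError("image/mask shape mismatch")
    vals = image.pixels[field_mask.pixels].astype(np.float64)
    mean = vals.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined: masked mean is zero")
    return float(100.0 * vals.std(ddof=0) / mean)


def segment_plant(f740: BandImage, *, min_area_px: int = 1) -> PlantMask:
    """Segment the plant from the corrected far-red fluorescence band.

    Otsu threshold, keep the largest connected component, fill holes.
    """
    px = f740.pixels.astype(np.float64)
    if px.min() == px.max():
        raise SegmentationError("constant image: no foreground/background contrast")
    thresh = threshold_otsu(px)
    fg = px > thresh
    if not fg.any():
        raise SegmentationError("empty foreground after Otsu threshold")
    labels = cc_label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    mask = labels == largest
    mask = ndi.binary_fill_holes(mask)
    if mask.sum() < min_area_px:
        raise SegmentationError("largest component below minimum area")
    return PlantMask(pixels=mask)


def otsu_threshold_bruteforce(values: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive between-class-variance maximization over histogram bins.

    Independent reference for Otsu's criterion: evaluates every candidate
    threshold and returns the bin center maximizing the between-class
    variance.
    """
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    best, best_t = -np.inf, centers[0]
    for i in range(1, n_bins):
        w0, w1 = p[:i].sum(), p[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[:i] * centers[:i]).sum() / w0
        mu1 = (p[i:] * centers[i:]).sum() / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
        if between > best:
            best, best_t = between, (edges[i - 1] + edges[i]) / 2
    return float(best_t)


def mean_in_mask(image: BandImage | np.ndarray, mask: PlantMask) -> float:
    """Arithmetic mean of pixels inside the plant mask."""
    px = image.pixels if isinstance(image, BandImage) else np.asarray(image)
    if mask.area_px == 0:
        raise MaskError("mean_in_mask requires a non-empty mask")
    if px.shape != mask.shape:
        raise ShapeMismatchError("image/mask shape mismatch")
    return float(px[mask.pixels].mean())


def average_views(values) -> float:
    """Per-plant statistic: arithmetic mean over the (up to 4) view values."""
    values = list(values)
    if not values:
        raise SaltSpecError("average_views requires at least one view")
    return float(np.mean(values))
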