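"""Fluorescence ratios, vegetation and simple-ratio indices, fused stacks.

Scalar features per plant view are ratios and linear combinations of masked
band means; per-pixel index images use the same recipes with an epsilon-guarded
division.  The fused 30-channel stack combines, in a fixed order:

    3 fluorescence bands (F520, F690, F740; F440 is excluded for poor SNR),
    3 fluorescence ratio images (F520/F690, F520/F740, F690/F740),
    11 reflectance bands (R460..R910),
    2 vegetation-index images (GR, PSRI),
    11 selected simple-ratio (SR) images.

NDVI is kept as a scalar feature but not stacked: unlike GR and PSRI it does
not separate the classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    MaskError,
    SaltSpecError,
    ShapeMismatchError,
    UndefinedStatisticError,
    VocabularyError,
)
from .imaging_io import (
    BAND_VOCABULARY,
    FeatureTable,
    META_COLUMNS,
    REFLECTANCE_BANDS,
    SampleRecord,
    band_wavelength,
)
from .preprocessing import PlantMask, mean_in_mask

#: Band roles in the vegetation-index formulas.  The index definitions cite
#: blue at 450 nm, but the platform's nearest LED is 460 nm.
VI_BANDS = {"blue": "R460", "green": "R520", "red": "R660", "nir": "R780"}

#: Fluorescence bands used for analysis (F440 excluded: bad SNR).
ANALYSIS_FLUOR_BANDS = ("F520", "F690", "F740")

#: Fluorescence ratio pairs, numerator/denominator, in stack order.
FLUOR_RATIO_PAIRS = (("F520", "F690"), ("F520", "F740"), ("F690", "F740"))


@dataclass(frozen=True)
class IndexDefinition:
    """A named ratio of linear combinations of band reflectances.

    ``numerator`` and ``denominator`` are tuples of (coefficient, band_label)
    terms; the index value is the ratio of the two weighted sums.
    """

    name: str
    numerator: tuple[tuple[float, str], ...]
    denominator: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        for _, band in (*self.numerator, *self.denominator):
            if band not in BAND_VOCABULARY:
                raise VocabularyError(f"index {self.name!r} references unknown band {band!r}")

    def evaluate(self, spectrum: dict[str, float]) -> float:
        """Evaluate on per-band scalars; raises if the denominator is zero."""
        num = sum(c * spectrum[b] for c, b in self.numerator)
        den = sum(c * spectrum[b] for c, b in self.denominator)
        if den == 0:
            raise UndefinedStatisticError(f"index {self.name!r}: zero denominator")
        return num / den

    def evaluate_image(self, bands: dict[str, np.ndarray], mask: np.ndarray,
                       eps_frac: float = 1e-6) -> np.ndarray:
        """Per-pixel index inside the mask, 0 outside (epsilon-guarded)."""
        num = sum(c * bands[b].astype(np.float64) for c, b in self.numerator)
        den = sum(c * bands[b].astype(np.float64) for c, b in self.denominator)
        ref = np.abs(den[mask]).mean() if mask.any() else 1.0
        eps = eps_frac * (ref if ref > 0 else 1.0)
        out = num / (den + np.where(den >= 0, eps, -eps))
        out[~mask] = 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "numerator": [[c, b] for c, b in self.numerator],
            "denominator": [[c, b] for c, b in self.denominator],
        }


def sr_index(band_a: str, band_b: str) -> IndexDefinition:
    """Simple-ratio index R_a / R_b."""
    return IndexDefinition(
        name=f"{band_a}/{band_b}",
        numerator=((1.0, band_a),),
        denominator=((1.0, band_b),),
    )


def vegetation_index_definition(which: str, gr_variant: str = "printed") -> IndexDefinition:
    """GR, PSRI or NDVI as an :class:`IndexDefinition`.

    GR defaults to the printed form (2G - R - B)/(2R + G + B); the common
    green-leaf-index reading (2G - R - B)/(2G + R + B) is available as
    ``gr_variant='green_leaf_index'``.
    """
    b, g, r, nir = VI_BANDS["blue"], VI_BANDS["green"], VI_BANDS["red"], VI_BANDS["nir"]
    if which == "GR":
        if gr_variant == "printed":
            den = ((2.0, r), (1.0, g), (1.0, b))
        elif gr_variant == "green_leaf_index":
            den = ((2.0, g), (1.0, r), (1.0, b))
        else:
            raise SaltSpecError(f"unknown gr_variant {gr_variant!r}")
        return IndexDefinition("GR", ((2.0, g), (-1.0, r), (-1.0, b)), den)
    if which == "PSRI":
        return IndexDefinition("PSRI", ((1.0, r), (-1.0, g)), ((1.0, nir),))
    if which == "NDVI":
        return IndexDefinition("NDVI", ((1.0, nir), (-1.0, r)), ((1.0, nir), (1.0, r)))
    raise SaltSpecError(f"unknown vegetation index {which!r}")


def vegetation_index(spectrum: dict[str, float], which: str,
                     gr_variant: str = "printed") -> float:
    """Scalar GR / PSRI / NDVI from per-band reflectance scalars."""
    return vegetation_index_definition(which, gr_variant).evaluate(spectrum)


def fluorescence_ratio_image(a: "BandImageLike", b: "BandImageLike", mask: PlantMask,
                             *, eps_frac: float = 1e-6, return_tally: bool = False):
    """Pixelwise a/(b + eps) inside the mask, 0 outside.

    eps is ``eps_frac`` of b's masked mean, guarding near-zero denominators;
    pixels where b is (near) zero are counted in an optional saturation tally.
    """
    pa = a.pixels if hasattr(a, "pixels") else np.asarray(a, dtype=float)
    pb = b.pixels if hasattr(b, "pixels") else np.asarray(b, dtype=float)
    if pa.shape != pb.shape or pa.shape != mask.shape:
        raise ShapeMismatchError("ratio-image inputs must share shape")
    if mask.area_px == 0:
        raise MaskError("fluorescence_ratio_image requires a non-empty mask")
    m = mask.pixels
    b_mean = pb[m].mean()
    eps = eps_frac * (b_mean if b_mean > 0 else 1.0)
    out = np.zeros(pa.shape, dtype=np.float64)
    out[m] = pa[m] / (pb[m] + eps)
    if return_tally:
        saturated = int((pb[m] <= eps).sum())
        return out, saturated
    return out


def enumerate_sr_indices(bands=REFLECTANCE_BANDS) -> list[IndexDefinition]:
    """All unordered band pairs as SR indices, shorter wavelength on top.

    n bands yield n(n-1)/2 definitions; the 11 platform reflectance bands
    give 55.
    """
    bands = list(bands)
    if len(set(bands)) != len(bands):
        raise SaltSpecError("duplicate band labels")
    bands = sorted(bands, key=band_wavelength)
    return [sr_index(a, b) for a, b in itertools.combinations(bands, 2)]


#: Channel-name order of the fused stack, given the 11 selected SR names.
def fused_channel_names(selected_sr_names) -> list[str]:
    return [
        *ANALYSIS_FLUOR_BANDS,
        *[f"{a}/{b}" for a, b in FLUOR_RATIO_PAIRS],
        *REFLECTANCE_BANDS,
        "GR", "PSRI",
        *selected_sr_names,
    ]


@dataclass
class FusedStack:
    """Ordered 30-channel image for one sample; pixels outside the mask are 0."""

    channels: np.ndarray           # (30, H, W)
    channel_names: list[str]
    mask: PlantMask
    pot_id: str = ""
    view_index: int = 0
    period_days: int = 5
    class_label: str = "control"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3:
            raise SaltSpecError("FusedStack channels must be (C, H, W)")
        if self.channels.shape[0] != len(self.channel_names):
            raise SaltSpecError("channel count does not match channel_names")
        if self.channels.shape[1:] != self.mask.shape:
            raise ShapeMismatchError("stack/mask shape mismatch")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]

    def masked_pixels(self) -> np.ndarray:
        """(n_masked, C) matrix of in-mask pixel spectra."""
        return self.channels[:, self.mask.pixels].T


def assemble_fused_stack(sample: SampleRecord, mask: PlantMask,
                         selected_sr: list[IndexDefinition],
                         gr_variant: str = "printed") -> FusedStack:
    """Build the fixed-order 30-channel stack for one corrected sample."""
    if len(selected_sr) != 11:
        raise SaltSpecError(f"expected 11 selected SR indices, got {len(selected_sr)}")
    needed = [*ANALYSIS_FLUOR_BANDS, *REFLECTANCE_BANDS]
    for band in needed:
        if band not in sample.bands:
            raise VocabularyError(f"missing band {band}")
    m = mask.pixels
    grids: list[np.ndarray] = []
    band_px = {b: sample.bands[b].pixels.astype(np.float64) for b in needed}
    for b in ANALYSIS_FLUOR_BANDS:
        g = band_px[b].copy()
        g[~m] = 0.0
        grids.append(g)
    for a, b in FLUOR_RATIO_PAIRS:
        grids.append(fluorescence_ratio_image(sample.bands[a], sample.bands[b], mask))
    for b in REFLECTANCE_BANDS:
        g = band_px[b].copy()
        g[~m] = 0.0
        grids.append(g)
    for vi in ("GR", "PSRI"):
        grids.append(vegetation_index_definition(vi, gr_variant).evaluate_image(band_px, m))
    for idx in selected_sr:
        grids.append(idx.evaluate_image(band_px, m))
    names = fused_channel_names([idx.name for idx in selected_sr])
    return FusedStack(
        channels=np.stack(grids),
        channel_names=names,
        mask=mask,
        pot_id=sample.pot_id,
        view_index=sample.view_index,
        period_days=sample.period_days,
        class_label=sample.class_label,
    )


def build_feature_table(samples_and_masks, gr_variant: str = "printed") -> FeatureTable:
    """Per-(pot, view, period) scalar features from corrected samples.

    Features: 3 fluorescence means, 3 fluorescence ratios, 11 reflectance
    means, GR, PSRI, NDVI, and all 55 SR scalars — every ratio computed on
    masked band means (per-plant means are the reported quantities).
    """
    samples_and_masks = list(samples_and_masks)
    if not samples_and_masks:
        raise SaltSpecError("build_feature_table requires at least one sample")
    sr_defs = enumerate_sr_indices()
    rows = []
    for sample, mask in samples_and_masks:
        means = {
            b: mean_in_mask(sample.bands[b], mask)
            for b in (*ANALYSIS_FLUOR_BANDS, *REFLECTANCE_BANDS)
        }
        row: dict = {
            "pot_id": sample.pot_id,
            "view_index": sample.view_index,
            "period_days": sample.period_days,
            "class_label": sample.class_label,
        }
        for b in ANALYSIS_FLUOR_BANDS:
            row[b] = means[b]
        for a, b in FLUOR_RATIO_PAIRS:
            row[f"{a}/{b}"] = means[a] / means[b]
        for b in REFLECTANCE_BANDS:
            row[b] = means[b]
        for vi in ("GR", "PSRI", "NDVI"):
            row[vi] = vegetation_index(means, vi, gr_variant)
        for idx in sr_defs:
            row[idx.name] = idx.evaluate(means)
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


def correlation_matrix(table: FeatureTable, columns=None) -> pd.DataFrame:
    """Pearson correlation matrix over the named feature columns."""
    if columns is None:
        columns = table.feature_names
    if len(table) < 3:
        raise SaltSpecError("correlation requires at least 3 rows")
    sub = table.df[list(columns)].astype(float)
    zero_var = [c for c in sub.columns if sub[c].std(ddof=0) == 0]
    if zero_var:
        raise UndefinedStatisticError(f"zero-variance columns: {zero_var}")
    return sub.corr(method="pearson")
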