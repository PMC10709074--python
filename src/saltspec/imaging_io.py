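"""On-disk artifacts: multiband sample containers, masks, feature tables, config.

A sample lives on disk as a multi-page TIFF (one page per band, in the
controlled vocabulary order) next to a JSON sidecar carrying band labels,
exposures and pot/view/period/class metadata.  Raw digital numbers are stored
as 16-bit unsigned pages; percent-reflectance / corrected images as 32-bit
float pages.  Feature tables are plain CSV with the four metadata columns
first.  Run configuration is YAML validated against a nested schema of
defaults.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigSchemaError, FormatError, SaltSpecError, VocabularyError

# ---------------------------------------------------------------------------
# Band vocabulary
# ---------------------------------------------------------------------------

#: Fluorescence emission bands (UV-excited), central wavelength in nm.
FLUORESCENCE_BANDS: tuple[str, ...] = ("F440", "F520", "F690", "F740")

#: Narrow-band reflectance channels, 460-910 nm.
REFLECTANCE_BANDS: tuple[str, ...] = (
    "R460", "R520", "R590", "R660", "R710", "R730",
    "R760", "R780", "R820", "R850", "R910",
)

#: Full controlled vocabulary, in canonical storage order.
BAND_VOCABULARY: tuple[str, ...] = FLUORESCENCE_BANDS + REFLECTANCE_BANDS

#: Acquisition exposure times (ms) used by the platform, per band.
DEFAULT_EXPOSURE_MS: dict[str, float] = {
    "F440": 350.0, "F520": 250.0, "F690": 100.0, "F740": 100.0,
    "R460": 500.0, "R520": 100.0, "R590": 100.0, "R660": 50.0,
    "R710": 80.0, "R730": 80.0, "R760": 40.0, "R780": 40.0,
    "R820": 50.0, "R850": 50.0, "R910": 50.0,
}

BAND_ROLES = ("sample", "reference", "dark")
CLASS_LABELS = ("control", "salt")
PERIODS_DAYS = (5, 10, 17)
VIEW_INDICES = (0, 1, 2, 3)

META_COLUMNS = ("pot_id", "view_index", "period_days", "class_label")


def band_wavelength(label: str) -> int:
    """Central wavelength in nm encoded in a band label (e.g. 'R710' -> 710)."""
    return int(label[1:])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BandImage:
    """One 2-D intensity grid with band identity and acquisition role.

    ``pixels`` holds digital numbers (raw capture) or percent reflectance /
    fluorescence (after flat-field correction).  All values must be finite and
    non-negative.
    """

    pixels: np.ndarray
    band_label: str
    role: str = "sample"
    exposure_ms: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise SaltSpecError(f"BandImage pixels must be 2-D, got ndim={self.pixels.ndim}")
        if self.band_label not in BAND_VOCABULARY:
            raise VocabularyError(f"unknown band label {self.band_label!r}")
        if self.role not in BAND_ROLES:
            raise SaltSpecError(f"unknown role {self.role!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise SaltSpecError(f"non-finite pixels in band {self.band_label}")
        if np.any(self.pixels < 0):
            raise SaltSpecError(f"negative pixels in band {self.band_label}")
        if self.exposure_ms is None:
            self.exposure_ms = DEFAULT_EXPOSURE_MS[self.band_label]
        if self.exposure_ms <= 0:
            raise SaltSpecError("exposure_ms must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SampleRecord:
    """All bands captured for one (pot, view, period) plus its metadata."""

    pot_id: str
    view_index: int
    period_days: int
    class_label: str
    bands: dict[str, BandImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view_index not in VIEW_INDICES:
            raise SaltSpecError(f"view_index must be in {VIEW_INDICES}")
        if self.period_days not in PERIODS_DAYS:
            raise SaltSpecError(f"period_days must be in {PERIODS_DAYS}")
        if self.class_label not in CLASS_LABELS:
            raise SaltSpecError(f"class_label must be in {CLASS_LABELS}")
        for label in self.bands:
            if label not in BAND_VOCABULARY:
                raise VocabularyError(f"unknown band label {label!r}")
        # normalize band order to the controlled vocabulary order
        self.bands = {
            label: self.bands[label] for label in BAND_VOCABULARY if label in self.bands
        }

    @property
    def missing_bands(self) -> tuple[str, ...]:
        return tuple(b for b in BAND_VOCABULARY if b not in self.bands)

    def band(self, label: str) -> BandImage:
        if label not in self.bands:
            raise VocabularyError(f"band {label!r} not present in sample {self.pot_id}")
        return self.bands[label]


class FeatureTable:
    """Samples x named scalar features with pot/view/period/class metadata.

    Thin validated wrapper over a :class:`pandas.DataFrame`; the four metadata
    columns always precede the feature columns.
    """

    def __init__(self, df: pd.DataFrame):
        if list(df.columns[: len(META_COLUMNS)]) != list(META_COLUMNS):
            missing = [c for c in META_COLUMNS if c not in df.columns]
            if missing:
                raise FormatError(f"missing metadata columns: {missing}")
            df = df[[*META_COLUMNS, *[c for c in df.columns if c not in META_COLUMNS]]]
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise FormatError(f"duplicate feature names: {dups}")
        if len(df) and df.duplicated(subset=["pot_id", "view_index", "period_days"]).any():
            raise FormatError("duplicate (pot, view, period) rows")
        feats = df.drop(columns=list(META_COLUMNS))
        if len(df) and not np.all(np.isfinite(feats.to_numpy(dtype=float))):
            raise FormatError("non-finite feature values")
        self.df = df.reset_index(drop=True)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    @property
    def metadata(self) -> pd.DataFrame:
        return self.df[list(META_COLUMNS)]

    @property
    def class_labels(self) -> np.ndarray:
        return self.df["class_label"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def select(self, rows) -> "FeatureTable":
        return FeatureTable(self.df.loc[rows].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Sample container read/write
# ---------------------------------------------------------------------------

_TIFF_NAME = "bands.tif"
_SIDECAR_NAME = "sample.json"


def write_sample(record: SampleRecord, path: str | Path) -> None:
    """Write a sample as a multi-page TIFF + JSON sidecar under ``path``.

    Integer digital numbers are stored as uint16 pages; floating-point
    (percent-scale) images as float32 pages with a declared unit scale factor
    in the sidecar.
    """
    if not record.bands:
        raise SaltSpecError("cannot write a sample with no bands")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pages, entries = [], []
    for label, band in record.bands.items():
        px = band.pixels
        if np.issubdtype(px.dtype, np.integer) and px.max(initial=0) <= np.iinfo(np.uint16).max:
            page = px.astype(np.uint16)
            stored = "uint16"
        else:
            page = px.astype(np.float32)
            stored = "float32"
        pages.append(page)
        entries.append(
            {
                "band_label": label,
                "role": band.role,
                "exposure_ms": band.exposure_ms,
                "stored_dtype": stored,
                "scale": 1.0,
            }
        )
    with tifffile.TiffWriter(path / _TIFF_NAME) as writer:
        for page in pages:
            writer.write(page)  # one page per band, dtype preserved per page
    sidecar = {
        "pot_id": record.pot_id,
        "view_index": record.view_index,
        "period_days": record.period_days,
        "class_label": record.class_label,
        "bands": entries,
    }
    (path / _SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))


def read_sample(path: str | Path) -> SampleRecord:
    """Read a sample container written by :func:`write_sample`."""
    path = Path(path)
    sidecar_path = path / _SIDECAR_NAME
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {_SIDECAR_NAME} in {path}")
    sidecar = json.loads(sidecar_path.read_text())
    with tifffile.TiffFile(path / _TIFF_NAME) as tif:
        pages = [p.asarray() for p in tif.pages]
    entries = sidecar["bands"]
    if len(entries) != len(pages):
        raise FormatError("sidecar band count does not match TIFF page count")
    bands: dict[str, BandImage] = {}
    for entry, page in zip(entries, pages):
        label = entry["band_label"]
        if label not in BAND_VOCABULARY:
            raise VocabularyError(f"unknown band label {label!r} in sidecar")
        scale = entry.get("scale", 1.0)
        px = np.asarray(page) if scale == 1.0 else np.asarray(page) * scale
        bands[label] = BandImage(
            pixels=px, band_label=label, role=entry["role"], exposure_ms=entry["exposure_ms"]
        )
    return SampleRecord(
        pot_id=sidecar["pot_id"],
        view_index=sidecar["view_index"],
        period_days=sidecar["period_days"],
        class_label=sidecar["class_label"],
        bands=bands,
    )


# ---------------------------------------------------------------------------
# Mask read/write (single-page 8-bit, 0/255)
# ---------------------------------------------------------------------------

def write_mask(mask_pixels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.where(mask_pixels, 255, 0).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


# ---------------------------------------------------------------------------
# Feature table read/write
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.df.to_csv(Path(path), index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(Path(path))
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Schema of known configuration keys with their defaults.  Nested sections
#: map to dotted keys (e.g. ``pca.retain``).
DEFAULT_CONFIG: dict = {
    "bands": {
        "reflectance": list(REFLECTANCE_BANDS),
        "fluorescence": list(FLUORESCENCE_BANDS),
        "blue": "R460",        # platform has no 450 nm LED; nearest band
        "green": "R520",
        "red": "R660",
        "nir": "R780",
    },
    "preprocessing": {
        "normalize_by_exposure": False,
        "mask_band": "F740",
    },
    "features": {
        "gr_variant": "printed",  # or "green_leaf_index"
    },
    "relief": {
        "k_neighbors": 10,
        "top_k": 5,
    },
    "pca": {
        "retain": None,             # None -> choose by variance threshold
        "variance_threshold": 0.95,
    },
    "split": {
        "n_train_pots": 152,
        "seed": 0,
    },
    "train": {
        "batch_size": 64,        # per the comparison table; 128 in the methods text
        "learning_rate": 0.01,
        "optimizer": "adam",
        "max_epochs": 30,
        "seed": 0,
        "flip_x": True,
        "flip_y": True,
        "scale_range": [0.75, 1.25],
        "shift_within_frame": True,
    },
    "network": {
        "variant": "B2",
        "profile": "full",       # "desk" selects the reduced test profile
        "n_classes": 2,
    },
}


def _merge_config(defaults: dict, overrides: Mapping, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        dotted = f"{prefix}{key}"
        if key not in out:
            raise ConfigSchemaError(f"unknown configuration key {dotted!r}")
        if isinstance(out[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigSchemaError(f"configuration section {dotted!r} must be a mapping")
            out[key] = _merge_config(out[key], value, prefix=dotted + ".")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML run configuration, validate keys and fill defaults.

    ``None`` or an empty file yields the full default configuration.  Unknown
    keys raise :class:`ConfigSchemaError` naming the offending dotted key.
    """
    overrides: Mapping = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigSchemaError("configuration root must be a mapping")
        overrides = loaded
    return _merge_config(DEFAULT_CONFIG, overrides)
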