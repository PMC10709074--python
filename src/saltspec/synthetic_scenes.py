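"""Seeded synthetic multiband plant scenes for exercising the full pipeline.

The study's own images are not deposited, so every stage is driven by a
generative stand-in: leaf-blob "plants" imaged through a vignetted
illumination field, with white-reference and dark-current frames, the full
pot / view / period structure (by default 102 control + 101 salt pots, 4
views, days 5/10/17) and a per-band, per-period multiplicative class-effect
table that realises the reported effect directions — the F520/F690
fluorescence ratio of stressed plants 1.085x (day 10) and 1.192x (day 17)
that of controls, depressed green/yellow reflectance, elevated near-infrared
reflectance, GR falling and PSRI rising under salt.

The raw-image model: a band's true leaf signal is a percent-of-reference
level t, and the captured digital numbers are

    S = D + (t/100) * (W - D) * (1 + noise)

with W carrying the radial vignette, so flat-field correction exactly
removes the injected non-uniformity.  Blobs are overlapping ellipses — no
botanical realism, just enough structure for masking, per-band statistics
and class separability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import SaltSpecError
from .imaging_io import (
    BAND_VOCABULARY,
    BandImage,
    SampleRecord,
)
from .preprocessing import ReferenceSet

PERIOD_DEFAULTS = (5, 10, 17)


def default_leaf_signal() -> dict[str, float]:
    """Control-class leaf signal per band, percent of the white reference."""
    return {
        "F440": 2.0,   # weak blue fluorescence (poor SNR in the real system)
        "F520": 8.0, "F690": 20.0, "F740": 30.0,
        "R460": 5.0, "R520": 12.0, "R590": 10.0, "R660": 6.0,
        "R710": 30.0, "R730": 45.0, "R760": 52.0, "R780": 55.0,
        "R820": 56.0, "R850": 57.0, "R910": 55.0,
    }


def default_class_effects() -> dict[tuple[str, int], float]:
    """Multiplicative salt-stress factor on the leaf signal per (band, period).

    Chosen so that dataset-level F520/F690 ratios of stressed vs. control
    plants are ~1.085 at day 10 and ~1.192 at day 17, F520/F740 rises while
    F690/F740 falls, green/yellow reflectance drops, near-infrared rises,
    and consequently GR falls and PSRI rises under salt.  Bands without a
    reported effect keep factor 1.
    """
    effects: dict[tuple[str, int], float] = {
        (band, period): 1.0 for band in BAND_VOCABULARY for period in PERIOD_DEFAULTS
    }
    effects.update({
        ("F520", 5): 1.12, ("F520", 10): 1.085 * 0.90, ("F520", 17): 1.192 * 0.80,
        ("F690", 5): 1.05, ("F690", 10): 0.90, ("F690", 17): 0.80,
        ("F740", 5): 1.05, ("F740", 10): 0.93, ("F740", 17): 0.85,
        ("R520", 5): 0.98, ("R520", 10): 0.93, ("R520", 17): 0.90,
        ("R590", 5): 0.98, ("R590", 10): 0.92, ("R590", 17): 0.89,
        ("R780", 5): 1.02, ("R780", 10): 1.06, ("R780", 17): 1.09,
        ("R820", 5): 1.02, ("R820", 10): 1.06, ("R820", 17): 1.09,
        ("R850", 5): 1.02, ("R850", 10): 1.06, ("R850", 17): 1.09,
        ("R910", 5): 1.02, ("R910", 10): 1.06, ("R910", 17): 1.09,
    })
    return effects


@dataclass
class SceneConfig:
    """Generator parameters; the defaults are the study conditions."""

    frame_size: int = 96
    n_blobs: tuple[int, int] = (3, 6)
    blob_axis_frac: tuple[float, float] = (0.08, 0.16)
    leaf_signal: dict[str, float] = dc_field(default_factory=default_leaf_signal)
    background_signal: float = 0.8        # percent of reference, off-plant
    noise_sd_frac: float = 0.03           # multiplicative, fraction of signal
    additive_noise: bool = False
    vignette_strength: float = 0.25       # radial falloff fraction, center->corner
    white_level: float = 30000.0          # white-reference DN at frame center
    dark_level: float = 100.0
    ref_noise_sd_frac: float = 0.005
    class_effects: dict[tuple[str, int], float] = dc_field(
        default_factory=default_class_effects
    )
    n_pots_control: int = 102
    n_pots_salt: int = 101
    views_per_pot: int = 4
    periods: tuple[int, ...] = PERIOD_DEFAULTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.vignette_strength < 1:
            raise SaltSpecError("vignette_strength must be in [0, 1)")
        if any(v <= 0 for v in self.leaf_signal.values()):
            raise SaltSpecError("leaf signals must be positive")
        for band in self.leaf_signal:
            for period in self.periods:
                if (band, period) not in self.class_effects:
                    raise SaltSpecError(f"class_effects missing ({band}, {period})")
        if any(f <= 0 for f in self.class_effects.values()):
            raise SaltSpecError("class-effect factors must be positive")


def _sub_seed(config_seed: int, *parts) -> np.random.Generator:
    """Deterministic per-entity RNG from the dataset seed and string parts."""
    tokens = [str(config_seed)] + [str(p) for p in parts]
    digest = zlib.crc32("/".join(tokens).encode())
    return np.random.default_rng(np.random.SeedSequence([config_seed & 0x7FFFFFFF, digest]))


def vignette_field(frame_size: int, strength: float) -> np.ndarray:
    """Radial illumination falloff: 1 at center, 1 - strength at the corners."""
    idx = np.arange(frame_size)
    cy = cx = (frame_size - 1) / 2.0
    rr, cc = np.meshgrid(idx, idx, indexing="ij")
    r2 = (rr - cy) ** 2 + (cc - cx) ** 2
    return 1.0 - strength * r2 / r2.max()


def generate_reference_frames(config: SceneConfig) -> ReferenceSet:
    """White (vignetted flat) and dark-current frames for every band."""
    rng = _sub_seed(config.seed, "references")
    vig = vignette_field(config.frame_size, config.vignette_strength)
    white, dark = {}, {}
    for band in BAND_VOCABULARY:
        w = config.white_level * vig
        d = np.full_like(vig, config.dark_level)
        if config.ref_noise_sd_frac > 0:
            w = w * (1 + config.ref_noise_sd_frac * rng.standard_normal(vig.shape))
            d = d * (1 + config.ref_noise_sd_frac * rng.standard_normal(vig.shape))
        white[band] = BandImage(np.clip(w, 0, None), band, role="reference")
        dark[band] = BandImage(np.clip(d, 0, None), band, role="dark")
    return ReferenceSet(white=white, dark=dark)


def _plant_support(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Union of random overlapping ellipses around the frame center."""
    n = config.frame_size
    n_blobs = int(rng.integers(config.n_blobs[0], config.n_blobs[1] + 1))
    idx = np.arange(n)
    rr, cc = np.meshgrid(idx, idx, indexing="ij")
    support = np.zeros((n, n), dtype=bool)
    lo, hi = config.blob_axis_frac
    for _ in range(n_blobs):
        a = rng.uniform(lo, hi) * n
        b = rng.uniform(lo, hi) * n
        if max(a, b) * 2 > n:
            raise SaltSpecError("blob axis exceeds frame size")
        cy = rng.uniform(0.3, 0.7) * n
        cx = rng.uniform(0.3, 0.7) * n
        theta = rng.uniform(0, np.pi)
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        support |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return support


def generate_plant_sample(config: SceneConfig, class_label: str, period: int,
                          pot_id: str, view: int) -> SampleRecord:
    """One raw multiband sample; deterministic in (seed, pot, view, period)."""
    rng = _sub_seed(config.seed, "sample", pot_id, view, period)
    geom_rng = _sub_seed(config.seed, "geometry", pot_id, view)
    support = _plant_support(config, geom_rng)
    vig = vignette_field(config.frame_size, config.vignette_strength)
    bands: dict[str, BandImage] = {}
    for band in BAND_VOCABULARY:
        t = np.full(vig.shape, config.background_signal)
        factor = (config.class_effects[(band, period)]
                  if class_label == "salt" else 1.0)
        t[support] = config.leaf_signal[band] * factor
        noise = rng.standard_normal(vig.shape)
        if config.additive_noise:
            t = t + config.noise_sd_frac * 100.0 * noise
        else:
            t = t * (1 + config.noise_sd_frac * noise)
        dn = config.dark_level + (t / 100.0) * (config.white_level * vig - config.dark_level)
        dn = np.clip(np.round(dn), 0, 65535).astype(np.uint16)
        bands[band] = BandImage(dn, band, role="sample")
    return SampleRecord(
        pot_id=pot_id, view_index=view, period_days=period,
        class_label=class_label, bands=bands,
    )


@dataclass
class SyntheticDataset:
    """Lazy view over a generated dataset: metadata now, images on demand."""

    config: SceneConfig
    references: ReferenceSet
    metadata: pd.DataFrame

    def sample(self, pot_id: str, view: int, period: int) -> SampleRecord:
        row = self.metadata[
            (self.metadata.pot_id == pot_id)
            & (self.metadata.view_index == view)
            & (self.metadata.period_days == period)
        ]
        if row.empty:
            raise SaltSpecError(f"no such sample ({pot_id}, {view}, {period})")
        return generate_plant_sample(
            self.config, row.iloc[0].class_label, period, pot_id, view
        )

    def __len__(self) -> int:
        return len(self.metadata)

    def __iter__(self):
        for row in self.metadata.itertuples():
            yield generate_plant_sample(
                self.config, row.class_label, row.period_days, row.pot_id, row.view_index
            )

    def pot_labels(self) -> dict[str, str]:
        return dict(
            self.metadata.drop_duplicates("pot_id")[["pot_id", "class_label"]].to_numpy()
        )


def generate_dataset(config: SceneConfig) -> SyntheticDataset:
    """Full pot/view/period dataset with reference frames and metadata.

    Images are generated lazily (each sample is deterministic in its
    identifiers), so metadata-level operations never materialise pixels.
    """
    refs = generate_reference_frames(config)
    rows = []
    pots = (
        [(f"C{i + 1:03d}", "control") for i in range(config.n_pots_control)]
        + [(f"S{i + 1:03d}", "salt") for i in range(config.n_pots_salt)]
    )
    for pot_id, label in pots:
        for period in config.periods:
            for view in range(config.views_per_pot):
                rows.append({
                    "pot_id": pot_id, "view_index": view,
                    "period_days": period, "class_label": label,
                })
    metadata = pd.DataFrame(rows, columns=["pot_id", "view_index", "period_days", "class_label"])
    return SyntheticDataset(config=config, references=refs, metadata=metadata)
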