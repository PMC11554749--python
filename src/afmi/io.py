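"""On-disk formats and the canonical 47-channel table.

One imaged field of view is stored as a multi-page TIFF (one page per spectral
channel) plus a JSON sidecar carrying the channel table, the processing stage
and any per-channel calibration gains.  Cell masks are 16-bit label TIFFs on
the same pixel grid (0 = background).  Per-cell assay labels, reference
spectra and feature tables travel as plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelSpec",
    "SpectralCube",
    "MaskImage",
    "ReferenceSpectra",
    "FormatError",
    "ValidationError",
    "N_CHANNELS",
    "EXCITATION_CENTERS_NM",
    "EMISSION_FILTERS",
    "default_channel_table",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "read_reference_spectra",
    "write_reference_spectra",
]


class FormatError(ValueError):
    """A file does not match the expected on-disk dialect."""


class ValidationError(ValueError):
    """Record content violates a domain constraint."""


#: The 18 LED excitation centers (nm), each with a ±5 nm halfwidth.
EXCITATION_CENTERS_NM: tuple[float, ...] = (
    358, 371, 377, 381, 385, 391, 397, 400, 403, 406,
    412, 418, 430, 437, 451, 457, 469, 476,
)
EXCITATION_HALFWIDTH_NM: float = 5.0

#: The 5 emission filters: (center-or-cutoff nm, kind, halfwidth nm).
EMISSION_FILTERS: tuple[tuple[float, str, float], ...] = (
    (414.0, "bandpass", 23.0),
    (451.0, "bandpass", 53.0),
    (575.0, "bandpass", 29.5),
    (594.0, "longpass", 0.0),
    (675.0, "bandpass", 33.5),
)

N_CHANNELS: int = 47

#: Minimum gap between the excitation center and the lower edge of an
#: emission band for the pair to be considered physically usable.
GUARD_BAND_NM: float = 10.0

CYCLE_PHASES = ("G1", "S", "G2", "M")
STAGES = ("raw", "preprocessed", "calibrated")


@dataclass(frozen=True)
class ChannelSpec:
    """One excitation/emission combination of the multispectral acquisition."""

    channel_id: int
    excitation_center_nm: float
    excitation_halfwidth_nm: float
    emission_kind: str  # "bandpass" | "longpass"
    emission_center_or_cutoff_nm: float
    emission_halfwidth_nm: float
    exposure_s: Optional[float] = None

    def __post_init__(self) -> None:
        if not (300.0 <= self.excitation_center_nm <= 700.0):
            raise ValidationError(
                f"excitation center {self.excitation_center_nm} nm out of [300, 700]"
            )
        if self.excitation_halfwidth_nm < 0 or self.emission_halfwidth_nm < 0:
            raise ValidationError("halfwidths must be >= 0")
        if self.emission_kind not in ("bandpass", "longpass"):
            raise ValidationError(f"unknown emission kind {self.emission_kind!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSpec":
        return cls(**d)


def _emission_lower_edge_nm(filt: tuple[float, str, float]) -> float:
    center, kind, halfwidth = filt
    return center if kind == "longpass" else center - halfwidth


def default_channel_table() -> list[ChannelSpec]:
    """The canonical 47-channel table.

    The instrument's own channel list is configuration (the exact subset of
    excitation x filter pairs is an acquisition parameter); this default picks
    pairs deterministically.  A filter is eligible for an excitation when its
    band lower edge (cutoff for longpass) sits more than ``GUARD_BAND_NM``
    above the excitation center.  Pairs are then taken round-robin — every
    excitation's first eligible filter, then every excitation's second, and so
    on — until 47 pairs are collected, which guarantees all 18 excitations and
    all 5 filters appear.  The table is in acquisition order: emission filter
    major, excitation ascending within each filter, so spectra are piecewise
    smooth in channel index (one smooth excitation scan per filter block).
    """
    eligible: dict[float, list[tuple[float, str, float]]] = {
        ex: [
            f
            for f in EMISSION_FILTERS
            if _emission_lower_edge_nm(f) > ex + GUARD_BAND_NM
        ]
        for ex in EXCITATION_CENTERS_NM
    }
    pairs: list[tuple[float, tuple[float, str, float]]] = []
    rank = 0
    while len(pairs) < N_CHANNELS:
        added = False
        for ex in EXCITATION_CENTERS_NM:
            filters = eligible[ex]
            if rank < len(filters):
                pairs.append((ex, filters[rank]))
                added = True
                if len(pairs) == N_CHANNELS:
                    break
        if not added:  # pragma: no cover - 90 candidate pairs >> 47
            raise RuntimeError("ran out of eligible excitation/filter pairs")
        rank += 1
    pairs.sort(key=lambda p: (p[1][0], p[0]))
    return [
        ChannelSpec(
            channel_id=i,
            excitation_center_nm=float(ex),
            excitation_halfwidth_nm=EXCITATION_HALFWIDTH_NM,
            emission_kind=kind,
            emission_center_or_cutoff_nm=float(center),
            emission_halfwidth_nm=float(halfwidth),
        )
        for i, (ex, (center, kind, halfwidth)) in enumerate(pairs)
    ]


@dataclass
class SpectralCube:
    """One field of view: an H x W x C intensity grid plus channel metadata."""

    pixels: np.ndarray
    channels: list[ChannelSpec]
    field_id: str = ""
    pixel_size_um: Optional[float] = None
    stage: str = "raw"
    #: Ordered record of applied preprocessing steps.
    history: tuple[str, ...] = ()
    #: Free-form numerical metadata (background levels, gains, clip counts).
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.pixels.ndim != 3:
            raise ValidationError("cube pixels must be 3-D (H, W, C)")
        if self.pixels.shape[2] != len(self.channels):
            raise ValidationError(
                f"{self.pixels.shape[2]} pages vs {len(self.channels)} channel specs"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("cube contains non-finite pixels")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate channel_id in channel table")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def replace(self, **kw) -> "SpectralCube":
        """Functional update (pixels are not copied unless passed)."""
        return dataclasses.replace(self, **kw)


@dataclass
class MaskImage:
    """Integer label image on the cube's pixel grid; 0 is background."""

    labels: np.ndarray
    field_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("mask must be integer-typed")
        if self.labels.min() < 0:
            raise ValidationError("mask labels must be >= 0")

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class ReferenceSpectra:
    """Water blank and calibration-fluid spectra used for spectral calibration."""

    water_mean: np.ndarray
    calib_measured: np.ndarray
    calib_reference: np.ndarray

    def __post_init__(self) -> None:
        self.water_mean = np.asarray(self.water_mean, dtype=np.float64)
        self.calib_measured = np.asarray(self.calib_measured, dtype=np.float64)
        self.calib_reference = np.asarray(self.calib_reference, dtype=np.float64)
        n = len(self.water_mean)
        if len(self.calib_measured) != n or len(self.calib_reference) != n:
            raise ValidationError("reference spectra length mismatch")
        if np.any(self.water_mean < 0):
            raise ValidationError("water blank must be non-negative")
        if np.any(self.calib_measured <= 0) or np.any(self.calib_reference <= 0):
            raise ValidationError("calibration spectra must be positive")


# ---------------------------------------------------------------------------
# cubes


def write_cube(cube: SpectralCube, path_stack, path_meta) -> None:
    """Write a cube as a float32 multi-page TIFF + JSON sidecar."""
    data = np.moveaxis(cube.pixels, 2, 0).astype(np.float32)
    tifffile.imwrite(str(path_stack), data, photometric="minisblack")
    sidecar = {
        "field_id": cube.field_id,
        "stage": cube.stage,
        "pixel_size_um": cube.pixel_size_um,
        "history": list(cube.history),
        "meta": {k: _jsonify(v) for k, v in cube.meta.items()},
        "channels": [c.to_dict() for c in cube.channels],
    }
    Path(path_meta).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_cube(path_stack, path_meta) -> SpectralCube:
    """Read a cube written by :func:`write_cube` (page k -> channel_id k)."""
    try:
        data = tifffile.imread(str(path_stack))
    except (OSError, tifffile.TiffFileError) as e:
        raise FormatError(f"cannot read TIFF stack {path_stack}: {e}") from e
    sidecar = json.loads(Path(path_meta).read_text())
    channels = [ChannelSpec.from_dict(d) for d in sidecar["channels"]]
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(channels):
        raise FormatError(
            f"stack has {data.shape[0]} pages but sidecar lists "
            f"{len(channels)} channels"
        )
    return SpectralCube(
        pixels=np.moveaxis(data, 0, 2).astype(np.float64),
        channels=channels,
        field_id=sidecar.get("field_id", ""),
        pixel_size_um=sidecar.get("pixel_size_um"),
        stage=sidecar.get("stage", "raw"),
        history=tuple(sidecar.get("history", ())),
        meta=sidecar.get("meta", {}),
    )


def _jsonify(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


# ---------------------------------------------------------------------------
# masks


def write_mask(mask: MaskImage, path) -> None:
    labels = mask.labels
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("cell IDs exceed 16-bit range")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_mask(path, field_id: str = "") -> MaskImage:
    try:
        labels = tifffile.imread(str(path))
    except (OSError, tifffile.TiffFileError) as e:
        raise FormatError(f"cannot read mask {path}: {e}") from e
    return MaskImage(labels=labels.astype(np.int64), field_id=field_id)


# ---------------------------------------------------------------------------
# label CSVs

_REQUIRED_LABEL_COLS = ("cell_id", "field_id")
_OPTIONAL_LABEL_COLS = (
    "stro1",
    "alp",
    "senescent",
    "cycle_phase",
    "dapi_total",
    "line_id",
    "passage",
    "doublings_remaining",
)
_BINARY_COLS = ("stro1", "alp", "senescent")


def read_labels(path) -> pd.DataFrame:
    """Read per-cell assay labels, validating enumerations."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_LABEL_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"label CSV missing required columns {missing}")
    if "cycle_phase" in df.columns:
        vals = df["cycle_phase"].dropna()
        bad = vals[~vals.isin(CYCLE_PHASES)]
        if len(bad):
            raise ValidationError(
                "invalid cycle_phase values "
                f"{sorted(bad.unique())} in rows {list(bad.index)}"
            )
    for col in _BINARY_COLS:
        if col in df.columns:
            vals = df[col].dropna()
            bad = vals[~vals.isin([0, 1, True, False])]
            if len(bad):
                raise ValidationError(
                    f"column {col!r} must be 0/1; offending rows {list(bad.index)}"
                )
    return df


def write_labels(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reference spectra CSVs


def write_reference_spectra(refs: ReferenceSpectra, path) -> None:
    pd.DataFrame(
        {
            "channel_id": np.arange(len(refs.water_mean)),
            "water_mean": refs.water_mean,
            "calib_measured": refs.calib_measured,
            "calib_reference": refs.calib_reference,
        }
    ).to_csv(path, index=False)


def read_reference_spectra(path) -> ReferenceSpectra:
    df = pd.read_csv(path)
    for col in ("water_mean", "calib_measured", "calib_reference"):
        if col not in df.columns:
            raise FormatError(f"reference spectra CSV missing column {col!r}")
    df = df.sort_values("channel_id") if "channel_id" in df.columns else df
    return ReferenceSpectra(
        water_mean=df["water_mean"].to_numpy(),
        calib_measured=df["calib_measured"].to_numpy(),
        calib_reference=df["calib_reference"].to_numpy(),
    )
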