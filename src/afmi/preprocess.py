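"""Raw-cube preprocessing: cosmic rays, denoising, background, flat field,
spectral calibration.

The pipeline order is fixed and enforced through the cube's ``history`` tag:

    cosmic_rays -> denoise -> background -> flatten -> calibrate

Every stage preserves the cube shape and channel order and leaves pixel
values finite and non-negative.  Denoising is a generic low-rank + wavelet
scheme: per-pixel spectra of a field are well approximated by a handful of
endmember fluorophores, so truncating the pixel x channel matrix to a small
rank removes most spectrally unstructured noise; residual spatial noise is
soft-thresholded in a 2-D wavelet basis per channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view

from .io import MaskImage, ReferenceSpectra, SpectralCube

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "PipelineOrderError",
    "CalibrationError",
    "remove_cosmic_rays",
    "denoise_lowrank",
    "subtract_background",
    "flatten_field",
    "smooth_reference",
    "smooth_references",
    "calibrate",
    "preprocess_cube",
]

#: Scale factor turning a median absolute deviation into a robust SD.
MAD_TO_SD = 1.4826


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was applied out of order."""


class CalibrationError(ValueError):
    """Spectral calibration is undefined (non-positive denominator)."""


@dataclass
class PreprocessConfig:
    cosmic_ray_zscore: float = 8.0
    denoise_rank: int = 8
    denoise_wavelet_levels: int = 2
    flatfield_poly_degree: int = 2
    #: CDF 9/7 biorthogonal wavelet (PyWavelets naming).
    wavelet_name: str = "bior4.4"
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.cosmic_ray_zscore <= 0:
            raise ValueError("cosmic_ray_zscore must be > 0")
        if self.denoise_rank < 1:
            raise ValueError("denoise_rank must be >= 1")


def _require(cube: SpectralCube, step: str, predecessor: str | None) -> None:
    if predecessor is None:
        if cube.stage != "raw":
            raise PipelineOrderError(f"{step} expects a raw cube, got {cube.stage}")
    elif predecessor not in cube.history:
        raise PipelineOrderError(
            f"{step} requires {predecessor!r} first; history={cube.history}"
        )


# ---------------------------------------------------------------------------
# cosmic rays


def remove_cosmic_rays(
    cube: SpectralCube, config: PreprocessConfig | None = None
) -> tuple[SpectralCube, int]:
    """Replace isolated single-pixel spikes by the local spatial median.

    A pixel is a spike when it exceeds the median of its 3x3 spatial
    neighbourhood (same channel, edge-replicated) by more than
    ``cosmic_ray_zscore`` robust SDs (1.4826 x MAD) of that neighbourhood.
    Returns the cleaned cube and the spike count.
    """
    config = config or PreprocessConfig()
    _require(cube, "remove_cosmic_rays", None)
    out = cube.pixels.copy()
    n_spikes = 0
    for k in range(cube.n_channels):
        img = cube.pixels[:, :, k]
        padded = np.pad(img, 1, mode="edge")
        win = sliding_window_view(padded, (3, 3)).reshape(img.shape + (9,))
        med = np.median(win, axis=-1)
        mad = np.median(np.abs(win - med[..., None]), axis=-1)
        spikes = img > med + config.cosmic_ray_zscore * MAD_TO_SD * mad
        out[:, :, k][spikes] = med[spikes]
        n_spikes += int(spikes.sum())
    log.info("removed %d cosmic-ray pixels", n_spikes)
    new = cube.replace(
        pixels=out, stage="preprocessed", history=cube.history + ("cosmic_rays",)
    )
    new.meta = dict(cube.meta, cosmic_ray_count=n_spikes)
    return new, n_spikes


# ---------------------------------------------------------------------------
# denoising


def _universal_soft_threshold(detail_arrays: list[np.ndarray], n: int) -> float:
    """Universal threshold with sigma from the finest detail band's MAD."""
    finest = detail_arrays[-1]
    sigma = np.median(np.abs(finest)) / 0.6745
    return sigma * np.sqrt(2.0 * np.log(max(n, 2)))


def denoise_lowrank(
    cube: SpectralCube, config: PreprocessConfig | None = None
) -> SpectralCube:
    """Spectral low-rank truncation followed by per-channel wavelet shrinkage."""
    config = config or PreprocessConfig()
    _require(cube, "denoise_lowrank", "cosmic_rays")
    if config.denoise_rank > cube.n_channels:
        raise ValueError(
            f"denoise_rank {config.denoise_rank} > n_channels {cube.n_channels}"
        )
    h, w, c = cube.shape
    flat = cube.pixels.reshape(-1, c)
    if config.denoise_rank < c:
        u, s, vt = np.linalg.svd(flat, full_matrices=False)
        r = config.denoise_rank
        flat = (u[:, :r] * s[:r]) @ vt[:r]
    out = flat.reshape(h, w, c).copy()

    if config.denoise_wavelet_levels > 0:
        wav = pywt.Wavelet(config.wavelet_name)
        max_level = pywt.dwtn_max_level((h, w), wav)
        level = min(config.denoise_wavelet_levels, max_level)
        if level > 0:
            for k in range(c):
                coeffs = pywt.wavedec2(out[:, :, k], wav, level=level)
                details = [a for triple in coeffs[1:] for a in triple]
                thr = _universal_soft_threshold([details[-1]], h * w)
                shrunk = [coeffs[0]] + [
                    tuple(pywt.threshold(a, thr, mode="soft") for a in triple)
                    for triple in coeffs[1:]
                ]
                rec = pywt.waverec2(shrunk, wav)
                out[:, :, k] = rec[:h, :w]

    clipped = int((out < 0).sum())
    if clipped:
        log.info("denoise clipped %d negative pixels to 0", clipped)
    np.clip(out, 0.0, None, out=out)
    new = cube.replace(pixels=out, history=cube.history + ("denoise",))
    new.meta = dict(cube.meta, denoise_clipped=clipped)
    return new


# ---------------------------------------------------------------------------
# background


def _fit_illumination(
    pixels: np.ndarray, bg_pixels: np.ndarray, config: PreprocessConfig
) -> list[list[float] | None]:
    """Per-channel polynomial fit to the smoothed background illumination.

    The smoothing is a normalised convolution over background pixels only,
    so bright cell interiors do not bleed into the estimate.  Channels with
    a degenerate (constant) background get ``None``.
    """
    from scipy.ndimage import gaussian_filter

    h, w, c = pixels.shape
    yn, xn = _norm_grid(h, w)
    design_bg = _poly2d_design(
        yn[bg_pixels], xn[bg_pixels], config.flatfield_poly_degree
    )
    sigma = max(min(h, w) / 16.0, 1.0)
    weight = gaussian_filter(bg_pixels.astype(float), sigma)
    weight = np.maximum(weight, config.epsilon)
    coeffs: list[list[float] | None] = []
    for k in range(c):
        est = gaussian_filter(np.where(bg_pixels, pixels[:, :, k], 0.0), sigma) / weight
        values = est[bg_pixels]
        if np.ptp(values) == 0 and config.flatfield_poly_degree > 0:
            coeffs.append(None)
            continue
        coef, *_ = np.linalg.lstsq(design_bg, values, rcond=None)
        coeffs.append([float(v) for v in coef])
    return coeffs


def _norm_grid(h: int, w: int):
    yy, xx = np.mgrid[0:h, 0:w]
    yn = (yy - (h - 1) / 2) / max((h - 1) / 2, 1)
    xn = (xx - (w - 1) / 2) / max((w - 1) / 2, 1)
    return yn, xn


def subtract_background(
    cube: SpectralCube, mask: MaskImage, config: PreprocessConfig | None = None
) -> SpectralCube:
    """Subtract the per-channel median of background (mask==0) pixels.

    The illumination surface of the *pre-subtraction* image is fitted here
    (and stored in the cube metadata) because zero-clipping makes it
    unrecoverable afterwards; :func:`flatten_field` consumes it.
    """
    config = config or PreprocessConfig()
    _require(cube, "subtract_background", "denoise")
    bg_pixels = mask.labels == 0
    if not bg_pixels.any():
        raise ValueError("mask has no background pixels; background undefined")
    levels = np.median(cube.pixels[bg_pixels], axis=0)
    coeffs = _fit_illumination(cube.pixels, bg_pixels, config)
    out = cube.pixels - levels[None, None, :]
    clipped = int((out < 0).sum())
    np.clip(out, 0.0, None, out=out)
    if clipped:
        log.info("background subtraction clipped %d pixels to 0", clipped)
    new = cube.replace(pixels=out, history=cube.history + ("background",))
    new.meta = dict(
        cube.meta,
        background_levels=levels.tolist(),
        background_clipped=clipped,
        illumination_coeffs=coeffs,
        illumination_degree=config.flatfield_poly_degree,
    )
    return new


# ---------------------------------------------------------------------------
# flat field


def _poly2d_design(y: np.ndarray, x: np.ndarray, degree: int) -> np.ndarray:
    cols = [
        (x**i) * (y**j)
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
    ]
    return np.stack(cols, axis=-1)


def flatten_field(
    cube: SpectralCube, mask: MaskImage, config: PreprocessConfig | None = None
) -> SpectralCube:
    """Divide out smooth illumination non-uniformity.

    Per channel, the illumination estimate is a lightly smoothed version of
    the pre-subtraction image (the recorded background levels are added
    back), a 2-D polynomial surface is fitted to its background pixels,
    normalised to mean 1, and the cube is divided by it.
    """
    config = config or PreprocessConfig()
    _require(cube, "flatten_field", "background")
    h, w, c = cube.shape
    bg_pixels = mask.labels == 0
    if not bg_pixels.any():
        raise ValueError("mask has no background pixels; flat field undefined")

    stored_degree = cube.meta.get("illumination_degree")
    if (
        "illumination_coeffs" in cube.meta
        and stored_degree == config.flatfield_poly_degree
    ):
        coeffs = cube.meta["illumination_coeffs"]
    else:
        # reconstruct the pre-subtraction image from the recorded levels
        bg = np.asarray(cube.meta.get("background_levels", np.zeros(c)), dtype=float)
        coeffs = _fit_illumination(
            cube.pixels + bg[None, None, :], bg_pixels, config
        )

    yn, xn = _norm_grid(h, w)
    design_full = _poly2d_design(yn.ravel(), xn.ravel(), config.flatfield_poly_degree)
    out = cube.pixels.copy()
    skipped = []
    for k in range(c):
        if coeffs[k] is None:
            skipped.append(k)
            continue
        surface = (design_full @ np.asarray(coeffs[k])).reshape(h, w)
        surface = np.clip(surface, config.epsilon, None)
        surface /= surface.mean()
        out[:, :, k] = cube.pixels[:, :, k] / np.maximum(surface, config.epsilon)
    if skipped:
        warnings.warn(
            f"flat-field fit degenerate for channels {skipped}; left unchanged",
            stacklevel=2,
        )
    new = cube.replace(pixels=out, history=cube.history + ("flatten",))
    new.meta = dict(cube.meta, flatten_skipped=skipped)
    return new


# ---------------------------------------------------------------------------
# reference smoothing and calibration


def smooth_reference(
    spectrum: np.ndarray, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Wavelet-smooth a per-channel reference spectrum (CDF biorthogonal)."""
    config = config or PreprocessConfig()
    x = np.asarray(spectrum, dtype=np.float64)
    if x.size < 8:
        warnings.warn("spectrum shorter than 8; smoothing skipped", stacklevel=2)
        return x.copy()
    wav = pywt.Wavelet(config.wavelet_name)
    level = min(2, pywt.dwt_max_level(x.size, wav))
    coeffs = pywt.wavedec(x, wav, level=level, mode="symmetric")
    thr = _universal_soft_threshold([coeffs[-1]], x.size)
    shrunk = [coeffs[0]] + [
        pywt.threshold(d, thr, mode="soft") for d in coeffs[1:]
    ]
    rec = pywt.waverec(shrunk, wav, mode="symmetric")
    return rec[: x.size]


def smooth_references(
    refs: ReferenceSpectra,
    channels=None,
    config: PreprocessConfig | None = None,
) -> ReferenceSpectra:
    """Wavelet-smooth reference spectra, one emission-filter block at a time.

    A spectrum over the 47 channels is only piecewise smooth: within one
    emission filter's excitation scan it varies gently, but it jumps at
    filter boundaries.  Smoothing per contiguous filter block avoids
    spreading those jumps; blocks shorter than 8 channels are left as is.
    """
    config = config or PreprocessConfig()

    def per_block(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if channels is None:
            return smooth_reference(x, config)
        out = x.copy()
        start = 0
        key = [
            (c.emission_center_or_cutoff_nm, c.emission_kind) for c in channels
        ]
        for i in range(1, len(key) + 1):
            if i == len(key) or key[i] != key[start]:
                if i - start >= 8:
                    out[start:i] = smooth_reference(x[start:i], config)
                start = i
        return out

    return ReferenceSpectra(
        water_mean=np.clip(per_block(refs.water_mean), 0.0, None),
        calib_measured=np.clip(per_block(refs.calib_measured), 1e-12, None),
        calib_reference=np.clip(per_block(refs.calib_reference), 1e-12, None),
    )


def calibrate(
    cube: SpectralCube,
    refs: ReferenceSpectra,
    config: PreprocessConfig | None = None,
) -> SpectralCube:
    """Convert instrument units to reference-fluorophore units.

    gain_k = calib_reference_k / (calib_measured_k - water_mean_k); channel k
    is multiplied by gain_k.  The gains are recorded in the cube metadata.
    """
    config = config or PreprocessConfig()
    _require(cube, "calibrate", "flatten")
    denom = refs.calib_measured - refs.water_mean
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise CalibrationError(
            f"calibration undefined for channels {bad.tolist()} "
            "(measured - water <= 0)"
        )
    gains = refs.calib_reference / denom
    out = cube.pixels * gains[None, None, :]
    new = cube.replace(
        pixels=out, stage="calibrated", history=cube.history + ("calibrate",)
    )
    new.meta = dict(cube.meta, gains=gains.tolist())
    return new


def preprocess_cube(
    cube: SpectralCube,
    mask: MaskImage,
    refs: ReferenceSpectra,
    config: PreprocessConfig | None = None,
    smooth_refs: bool = True,
) -> SpectralCube:
    """Run the full preprocessing chain on one raw field."""
    config = config or PreprocessConfig()
    cube, _ = remove_cosmic_rays(cube, config)
    cube = denoise_lowrank(cube, config)
    cube = subtract_background(cube, mask, config)
    cube = flatten_field(cube, mask, config)
    if smooth_refs:
        refs = smooth_references(refs, cube.channels, config)
    return calibrate(cube, refs, config)
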