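"""Synthetic multispectral MSC populations with known ground truth.

No public imaging dataset exists for this assay, so every pipeline stage is
exercised on simulated data whose generative structure matches the
analysis's assumptions: per-cell 47-channel signatures composed from three
endmember fluorophores (an NAD(P)H-like blue emitter, an FAD-like green
emitter and a broad lipofuscin-like red emitter), class-dependent spectral
shifts, a monotone aging drift in doublings-remaining with large
within-passage heterogeneity, hypertrophic morphology in old/senescent
cells, Poisson + Gaussian read noise, single-pixel cosmic-ray spikes and a
smooth multiplicative flat-field ramp.

Two paths are provided: a fast path emitting per-cell feature tables
directly (for the modeling / growth-potential stages) and an image path
rendering full cubes + masks (for preprocessing / feature extraction).
The endmember curves are smooth synthetic shapes loosely guided by the
fluorophores' published excitation/emission maxima; they carry no claim of
photophysical accuracy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .io import (
    ChannelSpec,
    MaskImage,
    ReferenceSpectra,
    SpectralCube,
    default_channel_table,
)

__all__ = [
    "Scenario",
    "SimulatedCells",
    "status_scenario",
    "aging_scenario",
    "null_aging_scenario",
    "simulate_cells",
    "render_field",
    "simulate_references",
    "simulate_passage_log",
    "DOUBLING_CLASSES",
]

#: 24 doubling-remaining class values in 0..28, with gaps at the high end
#: (fast-growing early passages are spectrally similar, and not every line
#: reaches the highest values).
DOUBLING_CLASSES: tuple[int, ...] = tuple(range(20)) + (21, 23, 25, 28)


@dataclass
class Scenario:
    """All dials of the generator; the seed fixes every output bit-exactly."""

    name: str = "default"
    seed: int = 0
    population: str = "status"  # "status" (assay labels) | "aging"
    n_channels: int = 47

    # --- status population -------------------------------------------------
    n_cells: int = 300
    senescent_fraction: float = 1 / 3
    stro1_fraction: float = 0.5
    alp_fraction: float = 0.3
    cycle_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)  # G1/S/G2

    # --- aging population --------------------------------------------------
    cells_per_class: int = 100
    doubling_classes: tuple[int, ...] = DOUBLING_CLASSES
    #: total relative drift over the 28-doubling lifespan in the most
    #: affected channels
    aging_amplitude: float = 0.6
    #: per-channel cell heterogeneity equals the drift accumulated over this
    #: many doublings
    het_doublings: float = 8.0
    #: shared "metabolic age" jitter (doublings RMS) along the drift
    age_jitter_sd: float = 4.0

    # --- spectral variability ----------------------------------------------
    cell_cv: float = 0.15  # per-channel cell-to-cell relative SD (status)
    measurement_cv: float = 0.02  # fast-path measurement noise
    n_lines: int = 3
    line_effect_sd: float = 0.05  # per-line per-channel relative offsets
    senescence_shift_sd: float = 1.0  # in units of the within-class SD
    senescence_channels: tuple[int, ...] = tuple(range(37, 47))
    stro1_shift_sd: float = 0.6
    stro1_channels: tuple[int, ...] = tuple(range(0, 8))
    alp_shift_sd: float = 0.5
    alp_channels: tuple[int, ...] = tuple(range(12, 20))
    cycle_shift_sd: float = 0.8
    cycle_channels: tuple[int, ...] = tuple(range(4, 12))
    #: one line may carry an extra shift (line-heterogeneity power checks)
    shifted_line: Optional[int] = None
    line_shift_sd: float = 3.0
    line_shift_channels: tuple[int, ...] = tuple(range(20))

    # --- morphology ---------------------------------------------------------
    base_radius_px: float = 7.0
    hypertrophy_factor: float = 1.6
    pixel_size_um: float = 0.5
    area_cv: float = 0.25

    # --- imaging / rendering -----------------------------------------------
    field_shape: tuple[int, int] = (128, 128)
    cells_per_field: int = 6
    background_level: float = 0.05  # instrument units, relative to mean signal
    flat_field_amplitude: float = 0.2  # ramp spans 1 +/- amplitude
    gain_sd: float = 0.15  # lognormal SD of per-channel gains
    water_level: float = 0.05
    ref_noise_sd: float = 0.0  # relative noise on measured calibration fluid
    poisson_photons: float = 10000.0  # photons per intensity unit
    read_noise_sd: float = 0.01
    cosmic_ray_rate: float = 2e-5  # spikes per pixel per channel
    cosmic_ray_amplitude: float = 30.0  # in units of the channel maximum
    cosmic_ray_count: Optional[int] = None  # exact override
    speckle_sd: float = 0.3
    speckle_scale_px: float = 2.0

    def __post_init__(self) -> None:
        if self.cell_cv < 0 or self.measurement_cv < 0 or self.line_effect_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.aging_amplitude < 0 or self.age_jitter_sd < 0:
            raise ValueError("aging dials must be >= 0")
        if self.population not in ("status", "aging"):
            raise ValueError(f"unknown population {self.population!r}")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def status_scenario(**kw) -> Scenario:
    return Scenario(name=kw.pop("name", "status"), population="status", **kw)


def aging_scenario(**kw) -> Scenario:
    return Scenario(name=kw.pop("name", "aging"), population="aging", **kw)


def null_aging_scenario(**kw) -> Scenario:
    """Aging population with every age-linked effect switched off (no
    spectral drift, no hypertrophy): downstream recovery must be at chance."""
    kw.setdefault("aging_amplitude", 0.0)
    kw.setdefault("hypertrophy_factor", 1.0)
    return Scenario(name=kw.pop("name", "null-aging"), population="aging", **kw)


# ---------------------------------------------------------------------------
# endmember spectra


def _emission_nm(ch: ChannelSpec) -> float:
    if ch.emission_kind == "longpass":
        return ch.emission_center_or_cutoff_nm + 40.0
    return ch.emission_center_or_cutoff_nm


def endmember_matrix(channels: list[ChannelSpec]) -> np.ndarray:
    """(3, n_channels) responses of the NADH-, FAD- and lipofuscin-like
    endmembers in each excitation/emission channel."""
    ex = np.array([c.excitation_center_nm for c in channels])
    em = np.array([_emission_nm(c) for c in channels])

    def gauss2(ex0, sx, em0, sm):
        return np.exp(-0.5 * ((ex - ex0) / sx) ** 2) * np.exp(
            -0.5 * ((em - em0) / sm) ** 2
        )

    nadh = gauss2(351.0, 45.0, 450.0, 55.0)
    fad = gauss2(450.0, 50.0, 535.0, 60.0)
    lipo = gauss2(420.0, 85.0, 600.0, 95.0)
    return np.stack([nadh, fad, lipo])


def _base_spectrum(E: np.ndarray) -> np.ndarray:
    base = np.array([1.0, 0.7, 0.3]) @ E
    return base / base.mean()


def _aging_direction(E: np.ndarray) -> np.ndarray:
    """Relative per-channel drift of an aging cell: lipofuscin accumulates,
    the FAD:NAD(P)H balance shifts oxidised."""
    base = np.array([1.0, 0.7, 0.3]) @ E
    drift = np.array([-0.7, 0.5, 1.0]) @ E
    u = drift / base
    return u / np.abs(u).max()


# ---------------------------------------------------------------------------
# populations


@dataclass
class SimulatedCells:
    """Ground-truth population: metadata, true spectra, fast-path features."""

    cells: pd.DataFrame  # one row per cell, META_COLUMNS subset
    spectra: np.ndarray  # (n_cells, n_channels) true signatures
    features: pd.DataFrame  # metadata + noisy channel means + morphology
    channels: list[ChannelSpec]
    passage_log: Optional[pd.DataFrame]
    scenario_hash: str

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _line_offsets(scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    off = rng.normal(0.0, scenario.line_effect_sd, (scenario.n_lines, scenario.n_channels))
    if scenario.shifted_line is not None:
        shift = np.zeros(scenario.n_channels)
        shift[list(scenario.line_shift_channels)] = (
            scenario.line_shift_sd * scenario.cell_cv
        )
        off[scenario.shifted_line] += shift
    return off


def _morphology_features(
    radii: np.ndarray, scenario: Scenario, rng: np.random.Generator
) -> pd.DataFrame:
    px = scenario.pixel_size_um
    area = np.pi * radii**2 * px**2 * np.exp(rng.normal(0, scenario.area_cv, len(radii)))
    ecc = rng.uniform(0.3, 0.85, len(radii))
    circ = rng.uniform(0.75, 0.98, len(radii))
    return pd.DataFrame(
        {
            "morph_area_um2": area,
            "morph_eccentricity": ecc,
            "morph_circularity": circ,
        }
    )


def _dapi_totals(phases: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    m = 1000.0
    mean = np.where(phases == "G1", m, np.where(phases == "S", 1.5 * m, 2.0 * m))
    return rng.normal(mean, 0.05 * mean)


def simulate_cells(scenario: Scenario) -> SimulatedCells:
    """Generate a ground-truth population under the scenario's dials."""
    rng = np.random.default_rng(scenario.seed)
    channels = default_channel_table()[: scenario.n_channels]
    E = endmember_matrix(channels)
    base = _base_spectrum(E)
    line_off = _line_offsets(scenario, rng)

    if scenario.population == "status":
        sim = _simulate_status(scenario, rng, base, line_off)
    else:
        sim = _simulate_aging(scenario, rng, base, E, line_off)
    cells, spectra, radii, passage_log = sim

    meas = spectra * (1.0 + rng.normal(0, scenario.measurement_cv, spectra.shape))
    feat = pd.DataFrame(
        meas, columns=[f"ch{k:02d}_mean" for k in range(scenario.n_channels)]
    )
    morph = _morphology_features(radii, scenario, rng)
    features = pd.concat(
        [cells.reset_index(drop=True), feat, morph], axis=1
    )
    return SimulatedCells(
        cells=cells,
        spectra=spectra,
        features=features,
        channels=channels,
        passage_log=passage_log,
        scenario_hash=scenario.hash(),
    )


def _simulate_status(scenario, rng, base, line_off):
    n = scenario.n_cells
    n_sen = int(round(n * scenario.senescent_fraction))
    senescent = np.zeros(n, dtype=int)
    senescent[:n_sen] = 1
    stro1 = (rng.uniform(size=n) < scenario.stro1_fraction).astype(int)
    alp = (rng.uniform(size=n) < scenario.alp_fraction).astype(int)
    g1, s, _ = scenario.cycle_fractions
    u = rng.uniform(size=n)
    phases = np.where(u < g1, "G1", np.where(u < g1 + s, "S", "G2"))
    lines = np.arange(n) % scenario.n_lines

    shift = np.zeros((n, scenario.n_channels))
    for flag, sd, chans in (
        (senescent, scenario.senescence_shift_sd, scenario.senescence_channels),
        (stro1, scenario.stro1_shift_sd, scenario.stro1_channels),
        (alp, scenario.alp_shift_sd, scenario.alp_channels),
    ):
        delta = np.zeros(scenario.n_channels)
        delta[list(chans)] = sd * scenario.cell_cv
        shift += np.outer(flag, delta)
    cycling = (phases != "G1").astype(int)
    delta = np.zeros(scenario.n_channels)
    delta[list(scenario.cycle_channels)] = scenario.cycle_shift_sd * scenario.cell_cv
    shift += np.outer(cycling, delta)

    rel = (
        1.0
        + line_off[lines]
        + shift
        + rng.normal(0, scenario.cell_cv, (n, scenario.n_channels))
    )
    spectra = np.clip(base[None, :] * rel, 0.0, None)

    radii = np.where(
        senescent == 1,
        scenario.base_radius_px * scenario.hypertrophy_factor,
        scenario.base_radius_px,
    ).astype(float)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "field_id": [
                f"F{(i // scenario.cells_per_field):03d}" for i in range(n)
            ],
            "line_id": [f"L{i}" for i in lines],
            "passage": np.full(n, 3),
            "doublings_remaining": np.full(n, np.nan),
            "stro1": stro1,
            "alp": alp,
            "senescent": senescent,
            "cycle_phase": phases,
            "dapi_total": _dapi_totals(phases, rng),
        }
    )
    return cells, spectra, radii, None


def _simulate_aging(scenario, rng, base, E, line_off):
    classes = np.asarray(sorted(scenario.doubling_classes, reverse=True))
    u = _aging_direction(E)
    drift_per_doubling = scenario.aging_amplitude / 28.0
    het = np.abs(u) * drift_per_doubling * scenario.het_doublings

    passage_log = simulate_passage_log(scenario)
    passage_of_class = {c: i + 1 for i, c in enumerate(classes)}

    rows, spectra, radii = [], [], []
    cid = 0
    for c in classes:
        for j in range(scenario.cells_per_class):
            line = (cid + j) % scenario.n_lines
            c_eff = c + rng.normal(0, scenario.age_jitter_sd)
            age_frac = np.clip((28.0 - c_eff) / 28.0, 0.0, 1.2)
            rel = (
                1.0
                + u * scenario.aging_amplitude * age_frac
                + line_off[line]
                + rng.normal(0, het, scenario.n_channels)
            )
            spectra.append(np.clip(base * rel, 0.0, None))
            hyper = 1.0 + (scenario.hypertrophy_factor - 1.0) * np.clip(
                (28.0 - c) / 28.0, 0, 1
            )
            radii.append(scenario.base_radius_px * hyper)
            rows.append(
                {
                    "line_id": f"L{line}",
                    "passage": passage_of_class[c],
                    "doublings_remaining": int(c),
                    "senescent": int(c == 0 and rng.uniform() < 0.9),
                }
            )
        cid += scenario.cells_per_class
    cells = pd.DataFrame(rows)
    n = len(cells)
    cells.insert(0, "field_id", [f"F{(i // scenario.cells_per_field):03d}" for i in range(n)])
    cells.insert(0, "cell_id", np.arange(1, n + 1))
    cells["stro1"] = (rng.uniform(size=n) < scenario.stro1_fraction).astype(int)
    cells["alp"] = (rng.uniform(size=n) < scenario.alp_fraction).astype(int)
    phases = np.where(
        cells["doublings_remaining"] > 0,
        np.where(rng.uniform(size=n) < 0.7, "G1", "S"),
        "G1",
    )
    cells["cycle_phase"] = phases
    cells["dapi_total"] = _dapi_totals(phases, rng)
    return cells, np.asarray(spectra), np.asarray(radii, dtype=float), passage_log


def simulate_passage_log(scenario: Scenario) -> pd.DataFrame:
    """Per-line cumulative-doubling logs, monotone with decelerating
    increments up to line-specific arrest totals.

    Lines arrest at distinct totals in [28.05, 29.8]; the imaging passages
    are placed so that round(arrest - cumulative) reproduces the scenario's
    doubling classes exactly.
    """
    classes = np.asarray(sorted(scenario.doubling_classes, reverse=True))
    rows = []
    for i in range(scenario.n_lines):
        arrest = 28.05 + 1.75 * i / max(scenario.n_lines - 1, 1)
        for p, c in enumerate(classes, start=1):
            rows.append(
                {
                    "line_id": f"L{i}",
                    "passage": p,
                    "cumulative_doublings": round(arrest - float(c), 3),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# references


def simulate_references(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> tuple[ReferenceSpectra, np.ndarray]:
    """Reference spectra pair plus the ground-truth per-channel gains.

    calib_measured = calib_reference / gains + water (+ optional noise), so
    applying the calibration formula to these references recovers ``gains``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([scenario.seed, 7]))
    channels = default_channel_table()[: scenario.n_channels]
    E = endmember_matrix(channels)
    # NADH + riboflavin-like calibration fluid: smooth positive spectrum
    ref = np.array([1.0, 0.9, 0.0]) @ E + 0.2
    gains = np.exp(
        scenario.gain_sd * _smooth_unit_noise(scenario.n_channels, rng)
    )
    water = np.full(scenario.n_channels, scenario.water_level * ref.mean())
    measured = ref / gains + water
    if scenario.ref_noise_sd > 0:
        measured = measured * (
            1.0 + rng.normal(0, scenario.ref_noise_sd, scenario.n_channels)
        )
    refs = ReferenceSpectra(
        water_mean=water, calib_measured=measured, calib_reference=ref
    )
    return refs, gains


def _binary_opening_cross(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_opening, generate_binary_structure

    return binary_opening(mask, generate_binary_structure(2, 1))


def _smooth_unit_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    x = gaussian_filter1d(rng.normal(size=n), 3.0, mode="nearest")
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# rendering


def render_field(
    sim: SimulatedCells,
    indices: np.ndarray,
    scenario: Scenario,
    gains: np.ndarray,
    field_id: str = "F000",
    rng: np.random.Generator | None = None,
) -> tuple[SpectralCube, MaskImage, dict]:
    """Draw the given cells into one raw field of view.

    Cells are rotated ellipses with intracellular speckle; the instrument
    records (signal/gain + background) x flat-field ramp with Poisson photon
    noise, Gaussian read noise and cosmic-ray spikes.  Returns the raw cube,
    the true mask and a ground-truth dict (spike coordinates, per-cell
    signatures, ramp, background).
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([scenario.seed, 11]))
    h, w = scenario.field_shape
    c = scenario.n_channels
    indices = np.asarray(indices)

    # --- cell shapes, then placement by rejection sampling ----------------
    axes = []  # (a, b, theta) per cell; area preserved, a is the major axis
    for i in indices:
        area = sim.features["morph_area_um2"].iloc[i]
        r = np.sqrt(area / np.pi) / scenario.pixel_size_um
        ecc = sim.features["morph_eccentricity"].iloc[i]
        b = r * (1 - 0.5 * ecc)
        axes.append((r**2 / b, b, rng.uniform(0, np.pi)))
    centers = []
    for a, _, _ in axes:
        placed = False
        for _ in range(300):
            cy = rng.uniform(a + 2, h - a - 2)
            cx = rng.uniform(a + 2, w - a - 2)
            if all(
                np.hypot(cy - oy, cx - ox) >= a + oa + 2
                for (oy, ox), (oa, _, _) in zip(centers, axes[: len(centers)])
            ):
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {len(indices)} cells in a {h}x{w} field; "
                "use fewer cells per field"
            )

    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int64)
    signal = np.zeros((h, w, c))
    for i, (cy, cx), (a, b, theta) in zip(indices, centers, axes):
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(theta) - dx * np.sin(theta)
        rx = dy * np.sin(theta) + dx * np.cos(theta)
        inside = (ry / a) ** 2 + (rx / b) ** 2 <= 1.0
        # rasterising an ellipse can leave single-pixel protrusions at the
        # major-axis tips; a cross opening removes that degenerate geometry
        inside = _binary_opening_cross(inside)
        cell_id = int(sim.cells["cell_id"].iloc[i])
        mask[inside] = cell_id
        speckle = np.exp(
            gaussian_filter(
                rng.normal(0, scenario.speckle_sd, (h, w)),
                scenario.speckle_scale_px,
            )
        )
        speckle /= speckle[inside].mean()
        signal[inside] += (
            speckle[inside, None] * sim.spectra[i][None, :]
        )

    background = scenario.background_level * sim.spectra.mean() / gains
    ramp = 1.0 + scenario.flat_field_amplitude * (xx / max(w - 1, 1) - 0.5) * 2.0
    field = (signal / gains[None, None, :] + background[None, None, :]) * ramp[
        :, :, None
    ]

    if scenario.poisson_photons > 0:
        field = rng.poisson(field * scenario.poisson_photons) / scenario.poisson_photons
    if scenario.read_noise_sd > 0:
        field = field + rng.normal(0, scenario.read_noise_sd, field.shape)
    field = np.clip(field, 0.0, None)

    # cosmic rays: isolated single-pixel spikes
    if scenario.cosmic_ray_count is not None:
        n_spikes = scenario.cosmic_ray_count
    else:
        n_spikes = int(rng.poisson(scenario.cosmic_ray_rate * h * w * c))
    flat_idx = rng.choice(h * w * c, size=n_spikes, replace=False)
    sy, sx, sc = np.unravel_index(flat_idx, (h, w, c))
    for y0, x0, k0 in zip(sy, sx, sc):
        field[y0, x0, k0] += scenario.cosmic_ray_amplitude * max(
            field[:, :, k0].max(), 1e-3
        )

    cube = SpectralCube(
        pixels=field,
        channels=sim.channels,
        field_id=field_id,
        pixel_size_um=scenario.pixel_size_um,
        stage="raw",
    )
    truth = {
        "spike_coords": list(zip(sy.tolist(), sx.tolist(), sc.tolist())),
        "cell_indices": indices.tolist(),
        "background": background,
        "ramp": ramp,
        "gains": gains,
    }
    return cube, MaskImage(labels=mask, field_id=field_id), truth
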