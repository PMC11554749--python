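"""Per-cell feature extraction and assay gating.

A cell is a labelled region of the mask applied to a calibrated cube.  Three
feature families are computed:

* **intensity** — per channel: mean, median, SD, skewness, excess kurtosis,
  10th and 90th percentiles of the masked pixels (7 x 47 = 329 features),
  plus mean-intensity ratios for a configured subset of channel pairs;
* **texture** — per channel: grey-level co-occurrence statistics (16 levels
  quantised over the cell's own range, offsets (0,1),(1,0),(1,1),(1,-1)
  averaged, symmetric, normalised, masked pixels only): contrast,
  correlation, energy, homogeneity, entropy (5 x 47 = 235 features);
* **morphology** — area, perimeter, equivalent diameter, axis lengths,
  eccentricity, solidity, extent, circularity.

Degenerate conventions: a zero-variance pixel population has skewness and
kurtosis 0; a single-grey-level cell has contrast 0, correlation 0,
energy 1, homogeneity 1, entropy 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .io import MaskImage, SpectralCube

log = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "feature_catalog",
    "GLCM_OFFSETS",
    "extract_intensity_features",
    "extract_texture_features",
    "extract_morphology_features",
    "extract_cell_features",
    "extract_field_features",
    "gate_dna_content",
    "gate_stain_positivity",
    "clean_and_assemble",
    "META_COLUMNS",
    "feature_columns",
]

#: Identifier / label columns of an assembled feature table.
META_COLUMNS = (
    "cell_id",
    "field_id",
    "line_id",
    "passage",
    "doublings_remaining",
    "stro1",
    "alp",
    "senescent",
    "cycle_phase",
    "dapi_total",
)

GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
GLCM_LEVELS = 16

_INTENSITY_STATS = ("mean", "median", "sd", "skew", "kurt", "p10", "p90")
_TEXTURE_STATS = ("contrast", "correlation", "energy", "homogeneity", "entropy")
_MORPH_NAMES = (
    "area_um2",
    "perimeter_um",
    "equiv_diameter_um",
    "major_axis_um",
    "minor_axis_um",
    "eccentricity",
    "solidity",
    "extent",
    "circularity",
)


@dataclass
class FeatureConfig:
    n_channels: int = 47
    #: Channel indices whose pairwise mean ratios are emitted (redox-style).
    ratio_channels: tuple[int, ...] = (1, 16, 30, 40)
    glcm_levels: int = GLCM_LEVELS
    glcm_offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS
    families: tuple[str, ...] = ("intensity", "texture", "morphology", "ratio")


def feature_catalog(config: FeatureConfig | None = None) -> pd.DataFrame:
    """Full ordered feature catalog (name, family, channels, definition)."""
    config = config or FeatureConfig()
    rows = []
    if "intensity" in config.families:
        for k in range(config.n_channels):
            for s in _INTENSITY_STATS:
                rows.append((f"ch{k:02d}_{s}", "intensity", str(k), s))
    if "texture" in config.families:
        for k in range(config.n_channels):
            for s in _TEXTURE_STATS:
                rows.append((f"ch{k:02d}_glcm_{s}", "texture", str(k), f"glcm_{s}"))
    if "morphology" in config.families:
        for name in _MORPH_NAMES:
            rows.append((f"morph_{name}", "morphology", "", name))
    if "ratio" in config.families:
        for a, b in _ratio_pairs(config):
            rows.append(
                (f"ratio_ch{a:02d}_ch{b:02d}", "ratio", f"{a},{b}", "mean_ratio")
            )
    return pd.DataFrame(rows, columns=["name", "family", "channels", "definition"])


def _ratio_pairs(config: FeatureConfig):
    chans = config.ratio_channels
    return [(chans[i], chans[j]) for i in range(len(chans)) for j in range(i + 1, len(chans))]


# ---------------------------------------------------------------------------
# intensity


def _cell_pixels(cube: SpectralCube, mask: MaskImage, cell_id: int) -> np.ndarray:
    sel = mask.labels == cell_id
    if not sel.any():
        raise ValueError(f"cell {cell_id} not present in mask")
    return cube.pixels[sel]  # (n_pixels, n_channels)


def extract_intensity_features(
    cube: SpectralCube,
    mask: MaskImage,
    cell_id: int,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    config = config or FeatureConfig()
    px = _cell_pixels(cube, mask, cell_id)
    n = px.shape[0]
    out: dict[str, float] = {}
    mean = px.mean(axis=0)
    sd = px.std(axis=0, ddof=1) if n > 1 else np.zeros(px.shape[1])
    median = np.median(px, axis=0)
    p10 = np.percentile(px, 10, axis=0)
    p90 = np.percentile(px, 90, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(px, axis=0, bias=False) if n > 2 else np.zeros(px.shape[1])
        kurt = (
            stats.kurtosis(px, axis=0, bias=False) if n > 3 else np.zeros(px.shape[1])
        )
    skew = np.where(sd > 0, np.nan_to_num(skew), 0.0)
    kurt = np.where(sd > 0, np.nan_to_num(kurt), 0.0)
    for k in range(px.shape[1]):
        out[f"ch{k:02d}_mean"] = float(mean[k])
        out[f"ch{k:02d}_median"] = float(median[k])
        out[f"ch{k:02d}_sd"] = float(sd[k])
        out[f"ch{k:02d}_skew"] = float(skew[k])
        out[f"ch{k:02d}_kurt"] = float(kurt[k])
        out[f"ch{k:02d}_p10"] = float(p10[k])
        out[f"ch{k:02d}_p90"] = float(p90[k])
    if "ratio" in config.families:
        for a, b in _ratio_pairs(config):
            if a >= px.shape[1] or b >= px.shape[1]:
                continue
            denom = mean[b] if mean[b] != 0 else np.finfo(float).tiny
            out[f"ratio_ch{a:02d}_ch{b:02d}"] = float(mean[a] / denom)
    return out


# ---------------------------------------------------------------------------
# texture


def _glcm(
    quant: np.ndarray,
    valid: np.ndarray,
    offsets: tuple[tuple[int, int], ...],
    levels: int,
) -> np.ndarray | None:
    """Averaged symmetric normalised co-occurrence matrix over offsets.

    ``quant`` is the integer-quantised bounding-box image; ``valid`` marks
    pixels belonging to the cell.  Pairs where either pixel is outside the
    cell are ignored.
    """
    mats = []
    h, w = quant.shape
    for dy, dx in offsets:
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ys2 = slice(max(0, dy), min(h, h + dy))
        xs2 = slice(max(0, dx), min(w, w + dx))
        ok = valid[ys, xs] & valid[ys2, xs2]
        if not ok.any():
            continue
        a = quant[ys, xs][ok]
        b = quant[ys2, xs2][ok]
        counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(
            levels, levels
        ).astype(float)
        counts = counts + counts.T  # symmetric
        mats.append(counts / counts.sum())
    if not mats:
        return None
    return np.mean(mats, axis=0)


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((p * (ii - jj) ** 2).sum())
    pi = p.sum(axis=1)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    if var > 0:
        correlation = float((p * (ii - mu) * (jj - mu)).sum() / var)
    else:
        correlation = 0.0
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


def extract_texture_features(
    cube: SpectralCube,
    mask: MaskImage,
    cell_id: int,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    config = config or FeatureConfig()
    sel = mask.labels == cell_id
    if not sel.any():
        raise ValueError(f"cell {cell_id} not present in mask")
    ys, xs = np.nonzero(sel)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    valid = sel[y0:y1, x0:x1]
    out: dict[str, float] = {}
    degenerate = {
        "contrast": 0.0,
        "correlation": 0.0,
        "energy": 1.0,
        "homogeneity": 1.0,
        "entropy": 0.0,
    }
    for k in range(cube.n_channels):
        img = cube.pixels[y0:y1, x0:x1, k]
        vals = img[valid]
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            st = degenerate
        else:
            quant = np.minimum(
                ((img - lo) / (hi - lo) * config.glcm_levels).astype(int),
                config.glcm_levels - 1,
            )
            p = _glcm(quant, valid, config.glcm_offsets, config.glcm_levels)
            st = degenerate if p is None else _glcm_stats(p)
        for s, v in st.items():
            out[f"ch{k:02d}_glcm_{s}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# morphology


def extract_morphology_features(
    mask: MaskImage, cell_id: int, pixel_size_um: float = 1.0
) -> dict[str, float]:
    sel = (mask.labels == cell_id).astype(np.uint8)
    if not sel.any():
        raise ValueError(f"cell {cell_id} not present in mask")
    props = measure.regionprops(sel)[0]
    px = pixel_size_um
    area = props.area * px**2
    perimeter = props.perimeter * px
    circularity = 4 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    return {
        "morph_area_um2": float(area),
        "morph_perimeter_um": float(perimeter),
        "morph_equiv_diameter_um": float(props.equivalent_diameter_area * px),
        "morph_major_axis_um": float(props.axis_major_length * px),
        "morph_minor_axis_um": float(props.axis_minor_length * px),
        "morph_eccentricity": float(props.eccentricity),
        "morph_solidity": float(props.solidity),
        "morph_extent": float(props.extent),
        "morph_circularity": float(circularity),
    }


def extract_cell_features(
    cube: SpectralCube,
    mask: MaskImage,
    cell_id: int,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """All configured feature families for one cell."""
    config = config or FeatureConfig()
    out: dict[str, float] = {}
    if "intensity" in config.families or "ratio" in config.families:
        out.update(extract_intensity_features(cube, mask, cell_id, config))
    if "texture" in config.families:
        out.update(extract_texture_features(cube, mask, cell_id, config))
    if "morphology" in config.families:
        out.update(
            extract_morphology_features(
                mask, cell_id, cube.pixel_size_um or 1.0
            )
        )
    return out


def extract_field_features(
    cube: SpectralCube, mask: MaskImage, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature rows for every cell in one field, in cell-id order."""
    config = config or FeatureConfig()
    rows = []
    for cid in mask.cell_ids():
        row = {"cell_id": int(cid), "field_id": cube.field_id}
        row.update(extract_cell_features(cube, mask, int(cid), config))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assay gating


def gate_dna_content(
    dapi_totals: np.ndarray,
    thresholds: tuple[float, float] = (1.25, 1.75),
    fallback_mode: float | None = None,
) -> tuple[np.ndarray, float]:
    """Assign cell-cycle phases from total DNA stain intensity.

    The G1 mode ``m`` is the peak of a kernel density estimate of the totals;
    cells <= 1.25 m are G1, (1.25 m, 1.75 m] are S, > 1.75 m are G2.  M phase
    is only assigned via explicit override labels.  Returns (phases, m).
    """
    x = np.asarray(dapi_totals, dtype=float)
    if np.any(x <= 0):
        raise ValueError("DAPI totals must be positive")
    if x.size < 30:
        warnings.warn("fewer than 30 cells; DNA gating may be unreliable", stacklevel=2)
    try:
        kde = stats.gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 512)
        m = float(grid[np.argmax(kde(grid))])
    except (np.linalg.LinAlgError, ValueError):
        if fallback_mode is not None:
            m = float(fallback_mode)
        else:
            m = float(np.median(x))
        warnings.warn(
            "DNA-content density estimate failed; falling back to "
            f"mode={m:.3g}",
            stacklevel=2,
        )
    lo, hi = thresholds
    phases = np.where(x <= lo * m, "G1", np.where(x <= hi * m, "S", "G2"))
    return phases, m


def gate_stain_positivity(
    stain_totals: np.ndarray,
    background: float,
    areas: np.ndarray,
    threshold_rule: tuple = ("otsu",),
) -> tuple[np.ndarray, float]:
    """Classify cells as stain-positive from background/area-normalised scores.

    score = (total - background * area) / area; positive iff score exceeds
    the threshold (absolute, or Otsu's threshold on the score distribution).
    Returns (positives, threshold).
    """
    totals = np.asarray(stain_totals, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if background < 0:
        raise ValueError("background must be >= 0")
    if np.any(areas <= 0):
        raise ValueError("cell areas must be positive")
    scores = (totals - background * areas) / areas
    if threshold_rule[0] == "absolute":
        thr = float(threshold_rule[1])
    elif threshold_rule[0] == "otsu":
        if np.ptp(scores) == 0:
            warnings.warn(
                "all scores identical; degenerate threshold, all negative",
                stacklevel=2,
            )
            return np.zeros(len(scores), dtype=bool), float(scores[0])
        thr = _otsu_exact(scores)
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return scores > thr, thr


def _otsu_exact(scores: np.ndarray) -> float:
    """Otsu's threshold computed exactly over the sorted samples.

    Unlike the histogram version, this cannot place the threshold inside a
    cluster because of binning granularity: the between-class variance is
    maximised over all n-1 sample splits and the threshold is the midpoint
    of the optimal gap.
    """
    order = np.sort(scores)
    n = len(order)
    cum = np.cumsum(order)
    k = np.arange(1, n)
    mu0 = cum[:-1] / k
    mu1 = (cum[-1] - cum[:-1]) / (n - k)
    crit = k * (n - k) * (mu0 - mu1) ** 2
    best = int(np.argmax(crit))
    return float((order[best] + order[best + 1]) / 2.0)


# ---------------------------------------------------------------------------
# assembly


def clean_and_assemble(
    features: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    corr_threshold: float = 0.95,
) -> pd.DataFrame:
    """Join features with labels, drop non-finite rows, de-correlate features.

    Of each feature pair with |Pearson r| > ``corr_threshold`` the
    lower-variance member is removed (tie: the lexicographically larger name
    goes), scanning pairs in catalog column order, so the result is
    deterministic.
    """
    df = features.copy()
    if labels is not None:
        overlap = set(df.columns) & set(labels.columns) - {"cell_id", "field_id"}
        if overlap:
            raise ValueError(f"join key collision on columns {sorted(overlap)}")
        dup = labels.duplicated(subset=["field_id", "cell_id"])
        if dup.any():
            raise ValueError("duplicate (field_id, cell_id) keys in labels")
        df = df.merge(labels, on=["field_id", "cell_id"], how="left")

    feat_cols = feature_columns(df)
    finite = np.isfinite(df[feat_cols].to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.info("dropped %d cells with non-finite feature values", n_dropped)
        df = df.loc[finite].reset_index(drop=True)

    x = df[feat_cols].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1) if len(df) > 1 else np.zeros(x.shape[1])
    var = sd**2
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False) if len(df) > 1 else np.eye(x.shape[1])
    corr = np.nan_to_num(corr, nan=0.0)
    removed: set[int] = set()
    for i in range(len(feat_cols)):
        if i in removed:
            continue
        for j in range(i + 1, len(feat_cols)):
            if j in removed:
                continue
            if abs(corr[i, j]) > corr_threshold:
                if var[i] > var[j]:
                    removed.add(j)
                elif var[j] > var[i]:
                    removed.add(i)
                    break
                else:  # tie on variance: keep lexicographically smaller name
                    removed.add(j if feat_cols[i] < feat_cols[j] else i)
                    if feat_cols[i] > feat_cols[j]:
                        break
    if removed:
        log.info("correlation filter removed %d features", len(removed))
    keep = [c for idx, c in enumerate(feat_cols) if idx not in removed]
    meta = [c for c in df.columns if c not in feat_cols]
    return df[meta + keep]


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Columns of a table that are features rather than identifiers/labels."""
    return [c for c in df.columns if c not in META_COLUMNS]
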