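"""CIELAB saturation analysis linking image color to surface geometry.

The chromatic translucent stimulus carries two kinds of 3-D information: a
shading-like structure in the weakly scattered (G, B) bands and a
curvature-linked structure in the deeply scattered band.  This module
quantifies how both manifest in chromatic saturation,

    saturation = sqrt(a*^2 + b*^2) / L*,

the radius of a pixel's (a*, b*) chroma coordinate relative to its lightness.
Images are converted from 8-bit sRGB to CIELAB (D65, 2 degree observer),
downsampled to the 67x67 analysis grid, joined per pixel with the shape-index
map, and summarised with Spearman rank correlations and ordinary
least-squares R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surface_geometry import ShapeIndexMap, classify_region

__all__ = [
    "LabImage",
    "SaturationMap",
    "srgb_to_lab",
    "saturation_map",
    "downsample_image",
    "build_pixel_table",
    "spearman_rho",
    "regression_r2",
    "saturation_geometry_report",
]

#: Pixels darker than this L* are excluded from the saturation statistic.
LIGHTNESS_FLOOR = 1.0

ANALYSIS_RESOLUTION = 67


@dataclass(frozen=True)
class LabImage:
    L: np.ndarray
    a: np.ndarray
    b: np.ndarray
    whitepoint: str = "D65/2deg"


@dataclass(frozen=True)
class SaturationMap:
    saturation: np.ndarray
    mask: np.ndarray


def srgb_to_lab(image: np.ndarray) -> LabImage:
    """8-bit (or [0,1] float) sRGB -> CIELAB 1976, D65 2-degree observer."""
    from skimage.color import rgb2lab

    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (ny, nx, 3) image")
    if img.dtype.kind in "ui":
        img = img.astype(float) / 255.0
    lab = rgb2lab(img)
    return LabImage(lab[..., 0], lab[..., 1], lab[..., 2])


def saturation_map(lab: LabImage,
                   lightness_floor: float = LIGHTNESS_FLOOR) -> SaturationMap:
    """saturation = sqrt(a*^2 + b*^2)/L*; near-black pixels are masked."""
    mask = lab.L >= lightness_floor
    chroma = np.sqrt(lab.a**2 + lab.b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(mask, chroma / np.where(mask, lab.L, 1.0), 0.0)
    return SaturationMap(s, mask)


def downsample_image(image: np.ndarray,
                     target: int = ANALYSIS_RESOLUTION) -> np.ndarray:
    """Block-mean downsampling to ``target`` x ``target`` (channels kept)."""
    from skimage.measure import block_reduce
    from skimage.transform import resize

    img = np.asarray(image, dtype=float)
    ny, nx = img.shape[:2]
    if ny < target or nx < target:
        raise ValueError("source image smaller than the target resolution")
    if ny == target and nx == target:
        return img
    by, bx = ny // target, nx // target
    if ny == by * target and nx == bx * target:
        block = (by, bx) + (1,) * (img.ndim - 2)
        return block_reduce(img, block, np.mean)
    # non-integer factor: area-style resample
    out_shape = (target, target) + img.shape[2:]
    return resize(img, out_shape, order=1, anti_aliasing=True,
                  preserve_range=True)


def _normalize_range(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def build_pixel_table(stimulus, shape_map: ShapeIndexMap,
                      elevation=None) -> pd.DataFrame:
    """Per-pixel rows of saturation, lightness, normalized G/B, shape index.

    ``stimulus`` is a RenderedStimulus whose sRGB grid matches the shape-index
    grid.  G and B are min-max normalized to [0, 1] over valid pixels.  Rows
    where the saturation or shape-index mask is false are dropped.
    """
    srgb = stimulus.srgb
    if srgb.shape[:2] != shape_map.s.shape:
        raise ValueError(
            f"stimulus grid {srgb.shape[:2]} != geometry grid "
            f"{shape_map.s.shape}; downsample first"
        )
    lab = srgb_to_lab(srgb)
    sat = saturation_map(lab)
    valid = sat.mask & shape_map.mask
    region = classify_region(shape_map)
    g = srgb[..., 1].astype(float)[valid]
    b = srgb[..., 2].astype(float)[valid]
    table = pd.DataFrame(
        {
            "saturation": sat.saturation[valid],
            "lightness": lab.L[valid],
            "g_norm": _normalize_range(g),
            "b_norm": _normalize_range(b),
            "shape_index": shape_map.s[valid],
            "region": region.classes[valid],
        }
    )
    if elevation is not None:
        table["elevation"] = elevation
    return table


def spearman_rho(x, y):
    """Spearman rank correlation; returns NaN when either input is constant."""
    from scipy.stats import spearmanr

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must be equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(spearmanr(x, y).statistic)


def regression_r2(response, predictors) -> float:
    """R^2 of an OLS fit with intercept; NaN on a rank-deficient design."""
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = np.column_stack([np.asarray(p, dtype=float) for p in predictors])
    if len(y) < X.shape[1] + 2:
        raise ValueError("need at least predictors + 2 rows")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return float("nan")
    return float(sm.OLS(y, design).fit().rsquared)


def gb_concat_correlation(table: pd.DataFrame) -> float:
    """rho(saturation, concatenated normalized G and B intensities).

    The G and B vectors are individually range-normalized and concatenated;
    the saturation vector is duplicated against them.
    """
    gb = np.concatenate([table["g_norm"].values, table["b_norm"].values])
    sat = np.tile(table["saturation"].values, 2)
    return spearman_rho(sat, gb)


def analyze_table(table: pd.DataFrame) -> dict:
    """All correlation-report fields for one stimulus table."""
    sat = table["saturation"].values
    return {
        "rho_sat_gb": gb_concat_correlation(table),
        "rho_sat_shape_index": spearman_rho(sat, table["shape_index"].values),
        "rho_sat_lightness": spearman_rho(sat, table["lightness"].values),
        "r2_gb_shape": regression_r2(
            sat,
            [table["g_norm"].values, table["b_norm"].values,
             table["shape_index"].values],
        ),
        "r2_lightness_shape": regression_r2(
            sat, [table["lightness"].values, table["shape_index"].values]
        ),
        "n_pixels": len(table),
    }


def saturation_geometry_report(stimuli, shape_map: ShapeIndexMap,
                               elevations=None) -> pd.DataFrame:
    """Per-elevation saturation/geometry correlation report.

    ``stimuli`` are chromatic renders at (typically three) illumination
    elevations on the shape-index grid.  Returns one row per stimulus with
    Spearman correlations of saturation against the concatenated G/B
    intensities, the shape index and lightness, plus the R^2 of saturation
    on (G, B, shape index) and on (lightness, shape index).
    """
    if elevations is None:
        elevations = [s.illumination.elevation_deg for s in stimuli]
    rows = []
    for stim, elev in zip(stimuli, elevations):
        table = build_pixel_table(stim, shape_map, elevation=elev)
        rec = analyze_table(table)
        rec["elevation"] = elev
        rows.append(rec)
    return pd.DataFrame(rows).set_index("elevation")
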