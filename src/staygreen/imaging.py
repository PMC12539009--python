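"""From calibrated reflectance to per-plot band medians and vegetation indices.

Bands are keyed by their nominal centre wavelength in nm.  The dual 10-band
camera provides 475 (blue), 560 (green), 668 (red), 717 (red edge), 740 and
842 nm (near-IR); the 5-band MX model lacks the 740 nm band, so the
senescence index PSRI = (red/blue) - near-IR uses the 740 nm band on the
dual camera and falls back to 842 nm on the MX.

The indices:
    NDVI = (R842 - R668) / (R842 + R668)
    NDRE = (R842 - R717) / (R842 + R717)
    PSRI = R668 / R475 - R_nir        (camera-dependent NIR band)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .errors import (CalibrationError, ConfigurationError, ExtractionError,
                     UndefinedCorrelationError)
from .raster import GridTransform

BLUE, GREEN, RED, RED_EDGE, NIR740, NIR842 = 475, 560, 668, 717, 740, 842

#: reflectance kept within (0, 1.5]: small >1 overshoot from calibration is
#: tolerated and clipped with a warning rather than rejected
REFLECTANCE_MAX = 1.5


@dataclass(frozen=True)
class CameraModel:
    """Camera identity fixing which NIR band PSRI uses."""

    name: str                 # "dual-10-band" or "mx-5-band"
    nir_band_for_psri: int

    def __post_init__(self):
        if self.name not in ("dual-10-band", "mx-5-band"):
            raise ConfigurationError(f"unknown camera model {self.name!r}")


DUAL = CameraModel("dual-10-band", NIR740)
MX = CameraModel("mx-5-band", NIR842)


def camera_from_name(name: str) -> CameraModel:
    return {"dual": DUAL, "dual-10-band": DUAL, "mx": MX, "mx-5-band": MX}[name]


# ---------------------------------------------------------------------------
# empirical line calibration
# ---------------------------------------------------------------------------

def empirical_line_calibrate(panel_dn, panel_reflectance, scene_dn):
    """Empirical-line reflectance calibration against reference panels.

    Fits the per-band affine map DN = gain * rho + offset to the reference
    panels by least squares, inverts it and applies it to the scene.

    Returns (calibrated scene, gain, offset, panel residuals).  Calibrated
    values are clipped into [0, REFLECTANCE_MAX]; clipping is reported via a
    RuntimeWarning, not an error.
    """
    dn = np.asarray(panel_dn, dtype=float)
    rho = np.asarray(panel_reflectance, dtype=float)
    if dn.shape != rho.shape or dn.size < 2:
        raise CalibrationError("need >= 2 reference panels per band")
    if np.ptp(rho) == 0:
        raise CalibrationError("panel reflectances must be distinct")
    gain, offset = np.polyfit(rho, dn, 1)
    if gain == 0:
        raise CalibrationError("degenerate panels: zero gain")
    residuals = dn - (gain * rho + offset)
    scene = np.asarray(scene_dn, dtype=float)
    calibrated = (scene - offset) / gain
    n_clip = int(np.sum((calibrated < 0) | (calibrated > REFLECTANCE_MAX)))
    if n_clip:
        import warnings
        warnings.warn(f"{n_clip} calibrated value(s) outside [0, {REFLECTANCE_MAX}]"
                      " were clipped", RuntimeWarning, stacklevel=2)
        calibrated = np.clip(calibrated, 0.0, REFLECTANCE_MAX)
    return calibrated, float(gain), float(offset), residuals


# ---------------------------------------------------------------------------
# zonal medians
# ---------------------------------------------------------------------------

def extract_plot_medians(raster: np.ndarray, transform: GridTransform,
                         polygons: dict, min_coverage_px: int = 50) -> pd.DataFrame:
    """Median reflectance over pixels whose centre falls inside each polygon.

    Missing pixels (NaN) are excluded; plots with fewer than
    ``min_coverage_px`` valid pixels are flagged ``excluded`` and carry no
    value (mirrors the removal of poorly covered plots).  A polygon falling
    outside the raster extent raises an extraction error naming the plot.
    """
    arr = np.asarray(raster, dtype=float)
    xs, ys = transform.pixel_centers(arr.shape)
    x0, x1 = transform.origin_x, transform.origin_x + arr.shape[1] * transform.pixel_size
    y1, y0 = transform.origin_y, transform.origin_y - arr.shape[0] * transform.pixel_size
    rows = []
    for pid, poly in polygons.items():
        minx, miny, maxx, maxy = poly.bounds
        if minx < x0 - 1e-9 or maxx > x1 + 1e-9 or miny < y0 - 1e-9 or maxy > y1 + 1e-9:
            raise ExtractionError(f"plot {pid!r} lies outside the raster extent")
        ci = np.where((xs > minx) & (xs < maxx))[0]
        ri = np.where((ys > miny) & (ys < maxy))[0]
        if len(ci) and len(ri):
            gx, gy = np.meshgrid(xs[ci], ys[ri])
            inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
            vals = arr[np.ix_(ri, ci)].ravel()[inside]
            vals = vals[~np.isnan(vals)]
        else:
            vals = np.array([])
        if len(vals) < min_coverage_px:
            rows.append({"plot_id": pid, "value": np.nan,
                         "n_valid_px": len(vals), "excluded": True})
        else:
            rows.append({"plot_id": pid, "value": float(np.median(vals)),
                         "n_valid_px": len(vals), "excluded": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vegetation indices
# ---------------------------------------------------------------------------

def compute_index(bands, index: str, camera: CameraModel = DUAL):
    """Evaluate NDVI, NDRE or PSRI on a band set (scalars or arrays).

    ``bands`` maps centre wavelength (nm) -> reflectance.  PSRI uses the
    camera-specific NIR band.  Missing bands raise a configuration error;
    zero blue reflectance under PSRI raises a division error.
    """
    index = index.upper()
    def get(wl):
        if wl not in bands:
            raise ConfigurationError(f"index {index} requires the {wl} nm band")
        return np.asarray(bands[wl], dtype=float)

    if index == "NDVI":
        nir, red = get(NIR842), get(RED)
        return _maybe_scalar((nir - red) / (nir + red), bands[NIR842])
    if index == "NDRE":
        nir, re_ = get(NIR842), get(RED_EDGE)
        return _maybe_scalar((nir - re_) / (nir + re_), bands[NIR842])
    if index == "PSRI":
        red, blue, nir = get(RED), get(BLUE), get(camera.nir_band_for_psri)
        if np.any(blue == 0):
            raise ZeroDivisionError("PSRI undefined: blue reflectance is zero")
        return _maybe_scalar(red / blue - nir, bands[RED])
    raise ConfigurationError(f"unknown index {index!r}")


def _maybe_scalar(value, template):
    return float(value) if np.isscalar(template) or np.ndim(template) == 0 else value


# ---------------------------------------------------------------------------
# index vs SPAD
# ---------------------------------------------------------------------------

def index_spad_correlation(index_values: pd.Series, spad_values: pd.Series,
                           groups: pd.Series | None = None,
                           conf: float = 0.95) -> pd.DataFrame:
    """Pearson correlation of an index with SPAD, pooled and per N level.

    Returns a table with group, n, r, p and Fisher-z confidence interval.
    """
    df = pd.DataFrame({"index": index_values, "spad": spad_values}).dropna()
    sets = [("pooled", df)]
    if groups is not None:
        for g, sub in df.groupby(groups.reindex(df.index)):
            sets.append((str(g), sub))
    rows = []
    for name, sub in sets:
        if len(sub) < 3:
            raise ConfigurationError(f"group {name!r}: need >= 3 paired observations")
        x, y = sub["index"].values, sub["spad"].values
        if np.std(x) == 0 or np.std(y) == 0:
            raise UndefinedCorrelationError(f"group {name!r}: zero variance")
        r, p = stats.pearsonr(x, y)
        if len(sub) > 3 and abs(r) < 1:
            z = np.arctanh(r)
            half = stats.norm.ppf(0.5 + conf / 2) / math.sqrt(len(sub) - 3)
            lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
        else:
            lo = hi = float(r)
        rows.append({"group": name, "n": len(sub), "r": float(r), "p": float(p),
                     "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)
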