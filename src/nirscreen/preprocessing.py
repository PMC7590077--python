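"""Scan-wise spectral preprocessing: SNV, Savitzky-Golay derivative, ROI.

Handheld diffuse-reflectance NIR spectra of powders carry two dominant
nuisance effects: additive baseline offsets (vial positioning, scanner
electronics) and multiplicative intensity changes (particle-size scatter).
Standard normal variate (SNV) normalisation — centre each spectrum and
scale it to unit standard deviation — removes both exactly, because any
``a*x + b`` (a > 0) maps to the same normalised vector.

Because the 740-1070 nm window is information-poor, a Savitzky-Golay
derivative is then applied to sharpen compound-specific features: a local
polynomial is least-squares fitted in a sliding window (19 points by
default) and its first or second derivative evaluated at the centre, a
single fused convolution.  Half-window edge points, where the fit is not
supported, are dropped.  Optionally the spectrum is cropped to the
cocaine-selective region of interest: 839-939 nm for first-derivative
data, 839-914 nm for second-derivative data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectral_core import LabeledLibrary, WavelengthGrid

__all__ = [
    "PreprocessConfig",
    "DegenerateSpectrumError",
    "snv",
    "savgol_derivative",
    "derived_grid",
    "select_roi",
    "preprocess_library",
    "preprocess_values",
]

#: ROI bounds (nm, inclusive) per derivative order.
ROI_BOUNDS_NM = {1: (839.0, 939.0), 2: (839.0, 914.0)}


class DegenerateSpectrumError(ValueError):
    """A flat-line (zero-variance) scan cannot be SNV-normalised."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing variant selector.

    Parameters
    ----------
    derivative_order:
        1 or 2.  First derivative is the default working variant for
        full-spectrum screening; the second derivative emphasises finer
        features at the cost of noise.
    sg_window:
        Odd Savitzky-Golay window length in grid points (default 19).
    sg_polyorder:
        Degree of the local polynomial (default 3, supports both
        derivative orders).
    roi_enabled:
        Crop to the cocaine-selective window after the derivative.
    snv_ddof:
        Delta degrees of freedom of the SNV standard deviation (1 =
        sample SD).
    """

    derivative_order: int = 1
    sg_window: int = 19
    sg_polyorder: int = 3
    roi_enabled: bool = False
    snv_ddof: int = 1

    def __post_init__(self) -> None:
        if self.derivative_order not in (1, 2):
            raise ValueError("derivative_order must be 1 or 2")
        if self.sg_window % 2 != 1 or self.sg_window < self.sg_polyorder + 1:
            raise ValueError("sg_window must be odd and >= sg_polyorder + 1")
        if self.sg_polyorder < self.derivative_order:
            raise ValueError("sg_polyorder must be >= derivative_order")
        if self.snv_ddof not in (0, 1):
            raise ValueError("snv_ddof must be 0 or 1")

    @property
    def roi_bounds_nm(self) -> tuple[float, float]:
        return ROI_BOUNDS_NM[self.derivative_order]

    @property
    def half_window(self) -> int:
        return (self.sg_window - 1) // 2

    @property
    def tag(self) -> str:
        """Fingerprint recorded in ``LabeledLibrary.preprocess_tag``."""
        roi = "-roi" if self.roi_enabled else ""
        return (
            f"snv-d{self.derivative_order}"
            f"-w{self.sg_window}-p{self.sg_polyorder}{roi}"
        )


def snv(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum.

    Output has mean 0 and standard deviation 1 (``ddof`` controls the
    denominator; 1 gives the sample SD).  Affine-invariant:
    ``snv(a*x + b) == snv(x)`` for any a > 0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("snv needs a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("snv input contains non-finite values")
    sd = x.std(ddof=ddof)
    if sd == 0.0:
        raise DegenerateSpectrumError("zero-variance (flat-line) spectrum")
    return (x - x.mean()) / sd


def savgol_derivative(
    values: np.ndarray, config: PreprocessConfig, step_nm: float = 1.0
) -> np.ndarray:
    """Fused Savitzky-Golay smoothing + derivative, interior points only.

    Fits a degree-``sg_polyorder`` polynomial in each ``sg_window``-point
    window and evaluates its ``derivative_order``-th derivative (units per
    nm) at the centre.  The ``(sg_window - 1) / 2`` points at each edge,
    where the window would run off the spectrum, are dropped rather than
    extrapolated; on the full 331-point grid this leaves 313 points
    covering 749-1061 nm.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[-1] < config.sg_window:
        raise ValueError(
            f"spectrum length {x.shape[-1]} shorter than "
            f"sg_window {config.sg_window}"
        )
    out = savgol_filter(
        x,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.derivative_order,
        delta=step_nm,
        axis=-1,
        mode="interp",
    )
    h = config.half_window
    return out[..., h:-h] if h else out


def derived_grid(grid: WavelengthGrid, config: PreprocessConfig) -> WavelengthGrid:
    """Grid remaining after edge truncation (and ROI crop, if enabled)."""
    h = config.half_window
    g = WavelengthGrid(
        start_nm=grid.start_nm + h * grid.step_nm,
        end_nm=grid.end_nm - h * grid.step_nm,
        step_nm=grid.step_nm,
    )
    if config.roi_enabled:
        lo, hi = config.roi_bounds_nm
        mask = (g.wavelengths >= lo) & (g.wavelengths <= hi)
        if not mask.any():
            raise ValueError("ROI does not intersect the derivative grid")
        waves = g.wavelengths[mask]
        g = WavelengthGrid(start_nm=waves[0], end_nm=waves[-1], step_nm=g.step_nm)
    return g


def select_roi(
    values: np.ndarray, grid: WavelengthGrid, config: PreprocessConfig
) -> np.ndarray:
    """Crop to the region of interest (inclusive bounds); identity if off."""
    if not config.roi_enabled:
        return np.asarray(values, dtype=float)
    x = np.asarray(values, dtype=float)
    if x.shape[-1] != grid.n_points:
        raise ValueError("values length does not match grid")
    lo, hi = config.roi_bounds_nm
    mask = (grid.wavelengths >= lo) & (grid.wavelengths <= hi)
    if not mask.any():
        raise ValueError(
            f"ROI [{lo}, {hi}] nm does not intersect grid "
            f"{grid.start_nm}-{grid.end_nm} nm"
        )
    return x[..., mask]


def preprocess_library(
    library: LabeledLibrary, config: PreprocessConfig
) -> LabeledLibrary:
    """Apply SNV -> Savitzky-Golay derivative -> optional ROI per scan.

    Returns a new library with the transformed matrix, the shrunken grid,
    and ``preprocess_tag`` set to ``config.tag``.  Row order and metadata
    alignment are preserved.  Flat-line scans are reported by scan_id.
    """
    if library.preprocess_tag != "raw":
        raise ValueError(
            f"library already preprocessed (tag={library.preprocess_tag!r})"
        )
    mat = library.matrix
    sds = mat.std(axis=1, ddof=config.snv_ddof)
    flat = np.nonzero(sds == 0.0)[0]
    if flat.size:
        ids = library.scan_ids[flat].tolist()
        raise DegenerateSpectrumError(f"flat-line scan(s): {ids}")
    normed = (mat - mat.mean(axis=1, keepdims=True)) / sds[:, None]
    deriv = savgol_derivative(normed, config, step_nm=library.grid.step_nm)
    h = config.half_window
    interior = WavelengthGrid(
        start_nm=library.grid.start_nm + h * library.grid.step_nm,
        end_nm=library.grid.end_nm - h * library.grid.step_nm,
        step_nm=library.grid.step_nm,
    )
    out = select_roi(deriv, interior, config)
    return library.with_matrix(out, derived_grid(library.grid, config), config.tag)


def preprocess_values(
    values: np.ndarray, grid: WavelengthGrid, config: PreprocessConfig
) -> np.ndarray:
    """Preprocess a single raw spectrum the same way as a library row."""
    x = snv(np.asarray(values, dtype=float), ddof=config.snv_ddof)
    d = savgol_derivative(x, config, step_nm=grid.step_nm)
    h = config.half_window
    interior = WavelengthGrid(
        start_nm=grid.start_nm + h * grid.step_nm,
        end_nm=grid.end_nm - h * grid.step_nm,
        step_nm=grid.step_nm,
    )
    return select_roi(d, interior, config)
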