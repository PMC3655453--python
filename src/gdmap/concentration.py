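"""T1 -> contrast-agent concentration conversion and its error analysis.

The linear relaxivity model relates the longitudinal rate to concentration:

    1/T1 = 1/T1_0 + r1 * C,

with T1 the observed (post-delivery) relaxation time, T1_0 the native tissue
value, and r1 the relaxivity of the agent.  With T1 in ms, the Gd-DTPA
relaxivity consistent with the worked numbers throughout this package is
r1 = 0.0038 mM^-1 ms^-1.  (The same figure is often quoted with s^-1 units;
``r1_from_per_second`` converts an s-based value explicitly.)

The model is trusted between roughly 0.1 and 5 mM: below that range noise in
T1 dominates, above ~10-50 mM a paramagnetic-to-superparamagnetic transition
corrupts spatial encoding and the affected voxels surface as NA rather than
as a concentration.

When a single representative ("isotropic") T1_0 replaces a registered
precontrast map, the spread of native T1 propagates into an asymmetric
concentration error; ``sensitivity_analysis`` quantifies it by recomputing
the curve with T1_0 at the mean and one SD either side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import T1Map
from .threshold_segment import ContrastRegion, SymmetricHistogramStats

__all__ = [
    "ConcentrationMap",
    "SensitivityCurve",
    "t1_to_concentration",
    "map_concentration",
    "sensitivity_analysis",
    "fit_relaxivity",
    "r1_from_per_second",
]

DEFAULT_R1 = 0.0038  # mM^-1 ms^-1


def r1_from_per_second(r1_per_mM_s: float) -> float:
    """Convert a relaxivity quoted in mM^-1 s^-1 to mM^-1 ms^-1."""
    return r1_per_mM_s / 1000.0


@dataclass(frozen=True)
class ConcentrationMap:
    """Voxel-wise contrast concentration (mM) over a segmented region.

    ``conc`` is NaN outside the region and at NA voxels.  ``na_mask`` marks
    voxels whose T1 was NA (cement or superparamagnetic artifact).
    ``below_range`` / ``above_range`` flag defined voxels outside the
    calibration range; ``clamped`` flags voxels whose raw value was negative
    (T1 above T1_0) and was clamped to zero.
    """

    conc: np.ndarray
    na_mask: np.ndarray
    below_range: np.ndarray
    above_range: np.ndarray
    clamped: np.ndarray
    region_mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    t1_0_ms: float = float("nan")
    r1_mM_per_ms: float = DEFAULT_R1

    @property
    def shape(self):
        return self.conc.shape

    def defined(self) -> np.ndarray:
        return np.isfinite(self.conc)


def t1_to_concentration(t1, t1_0: float, r1: float = DEFAULT_R1):
    """Concentration in mM from observed T1 and native T1_0 (both ms).

    Negative raw values (T1 > T1_0) clamp to zero; NaN (NA) propagates.
    Accepts scalars or arrays.
    """
    if t1_0 <= 0 or r1 <= 0:
        raise ValueError("t1_0 and r1 must be positive")
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1[np.isfinite(t1)] <= 0):
        raise ValueError("t1 must be positive where defined")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (1.0 / t1 - 1.0 / t1_0) / r1
    out = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0))
    return float(out) if out.ndim == 0 else out


def concentration_to_t1(conc, t1_0: float, r1: float = DEFAULT_R1):
    """Invert the relaxivity relation: the T1 produced by concentration ``conc``."""
    conc = np.asarray(conc, dtype=float)
    out = 1.0 / (1.0 / t1_0 + r1 * conc)
    return float(out) if out.ndim == 0 else out


def map_concentration(
    region: ContrastRegion,
    t1_map: T1Map,
    stats: SymmetricHistogramStats,
    r1: float = DEFAULT_R1,
    valid_range_mM: tuple[float, float] = (0.1, 5.0),
) -> ConcentrationMap:
    """Convert the segmented region of a T1 map to concentrations.

    The tissue-specific native value used is ``stats.peak_t1``.  NA voxels in
    the region are carried into ``na_mask`` with undefined concentration.
    An empty region yields an all-undefined map with a warning.
    """
    if region.mask.shape != t1_map.shape:
        raise ValueError("region and T1 map geometry mismatch")
    rmask = region.mask.mask
    if not rmask.any():
        import warnings

        warnings.warn("contrast region is empty", stacklevel=2)
    shape = t1_map.shape
    conc = np.full(shape, np.nan)
    inside_defined = rmask & t1_map.defined()
    conc[inside_defined] = t1_to_concentration(t1_map.t1[inside_defined], stats.peak_t1, r1)
    raw = np.full(shape, np.nan)
    raw[inside_defined] = (1.0 / t1_map.t1[inside_defined] - 1.0 / stats.peak_t1) / r1
    lo, hi = valid_range_mM
    defined = np.isfinite(conc)
    return ConcentrationMap(
        conc=conc,
        na_mask=rmask & t1_map.na_mask,
        below_range=defined & (conc < lo),
        above_range=defined & (conc > hi),
        clamped=defined & np.isfinite(raw) & (raw < 0),
        region_mask=rmask,
        spacing=t1_map.spacing,
        origin=t1_map.origin,
        t1_0_ms=stats.peak_t1,
        r1_mM_per_ms=r1,
    )


@dataclass(frozen=True)
class SensitivityCurve:
    """Concentration vs T1 under the mean and +/- 1 SD native-T1 arms (mM)."""

    t1_grid: np.ndarray
    conc_central: np.ndarray
    conc_upper: np.ndarray  # computed with T1_0 = mean + sd
    conc_lower: np.ndarray  # computed with T1_0 = mean - sd (clamped at 0)

    @property
    def upper_error(self) -> np.ndarray:
        return self.conc_upper - self.conc_central

    @property
    def lower_error(self) -> np.ndarray:
        return self.conc_central - self.conc_lower


def sensitivity_analysis(
    t1_grid, t1_0_mean: float, t1_0_sd: float, r1: float = DEFAULT_R1
) -> SensitivityCurve:
    """Propagate native-T1 spread into the concentration estimate.

    Evaluates the relaxivity relation on ``t1_grid`` with T1_0 set to the
    mean, mean + SD and mean - SD.  A larger assumed T1_0 yields a larger
    concentration for the same observed T1, so the +SD arm is the upper
    curve.  Grid values at or above ``mean - SD`` give a clamped-zero lower
    curve; the relative error shrinks as T1 decreases (concentration grows).
    """
    t1_grid = np.atleast_1d(np.asarray(t1_grid, dtype=float))
    if t1_0_sd <= 0 or t1_0_sd >= t1_0_mean:
        raise ValueError("need 0 < t1_0_sd < t1_0_mean")
    central = t1_to_concentration(t1_grid, t1_0_mean, r1)
    upper = t1_to_concentration(t1_grid, t1_0_mean + t1_0_sd, r1)
    lower = t1_to_concentration(t1_grid, t1_0_mean - t1_0_sd, r1)
    return SensitivityCurve(t1_grid, np.atleast_1d(central), np.atleast_1d(upper), np.atleast_1d(lower))


def render_overlay(
    conc: ConcentrationMap,
    anatomy,
    slice_index: int,
    path,
    vmax_mM: float = 1.0,
) -> None:
    """Render one slice of a concentration map over its T1-weighted anatomy.

    Concentration uses a 0..``vmax_mM`` color scale; NA voxels render white,
    anatomy in greyscale underneath.  Written as PNG.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.asarray(anatomy.data)[:, :, slice_index], cmap="gray")
    sl = conc.conc[:, :, slice_index]
    overlay = np.ma.masked_invalid(sl)
    im = ax.imshow(overlay, cmap="jet", vmin=0.0, vmax=vmax_mM, alpha=0.7)
    na = conc.na_mask[:, :, slice_index]
    if na.any():
        ax.imshow(np.ma.masked_where(~na, na), cmap="gray_r", vmin=0, vmax=1, alpha=0.9)
    fig.colorbar(im, ax=ax, label="concentration (mM)")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def fit_relaxivity(pairs) -> tuple[float, float, float]:
    """Ordinary least squares of 1/T1 on concentration over calibration vials.

    Parameters
    ----------
    pairs:
        Sequence of ``(concentration_mM, t1_ms)``; at least 2 distinct
        concentrations (3+ spanning the calibration range recommended).

    Returns
    -------
    (r1, intercept, r_squared):
        Slope in mM^-1 ms^-1, intercept in ms^-1 (= 1/T1_0), and R^2.
    """
    pairs = [(float(c), float(t)) for c, t in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration pairs")
    conc = np.array([p[0] for p in pairs])
    rate = 1.0 / np.array([p[1] for p in pairs])
    if np.unique(conc).size < 2:
        raise ValueError("all calibration concentrations are equal; slope undefined")
    slope, intercept = np.polyfit(conc, rate, 1)
    pred = slope * conc + intercept
    sstot = ((rate - rate.mean()) ** 2).sum()
    ssres = ((rate - pred) ** 2).sum()
    r2 = 1.0 if sstot == 0 else 1.0 - ssres / sstot
    return float(slope), float(intercept), float(r2)
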