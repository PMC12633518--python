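"""Regional kinetic feature extraction.

For every region the feature vector has four entries: SUV at three time
points (defaults 1.25, 13.5 and 50 minutes post-injection) and the
blood-to-brain influx rate K1 from a single irreversible one-tissue
compartment model driven by the image-derived input function.

Conventions:

* frame times are frame midpoints; TAC interpolation is linear between
  midpoints and exact at them;
* the irreversible model has no efflux (k2 = 0), so the fit is a
  one-parameter least-squares regression through the origin of the tissue
  curve against the running plasma integral;
* the plasma integral is a trapezoid rule on the union of the IDIF sample
  times and the frame midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FrameSchedule, InputFunction, ScanRecord, TimeActivityCurve

__all__ = [
    "KineticsConfig",
    "RegionFeatureVector",
    "interpolate_to_grid",
    "compute_suv",
    "plasma_integral",
    "estimate_k1",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("suv_1p25", "suv_13p5", "suv_50", "k1")


@dataclass(frozen=True)
class KineticsConfig:
    """Settings for feature extraction."""

    suv_times_minutes: tuple[float, ...] = (1.25, 13.5, 50.0)
    k1_fit_window_minutes: tuple[float, float] = (0.0, 50.0)
    idif_integration: str = "trapezoid"

    def __post_init__(self) -> None:
        if self.idif_integration != "trapezoid":
            raise ValueError("only trapezoid IDIF integration is supported")


@dataclass(frozen=True)
class RegionFeatureVector:
    """The 4 regional features (pre-standardization)."""

    roi_id: str
    suv_1p25: float
    suv_13p5: float
    suv_50: float
    k1: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"ROI {self.roi_id!r}: non-finite feature value")
        if self.k1 < 0:
            raise ValueError(f"ROI {self.roi_id!r}: negative K1")

    def as_array(self) -> np.ndarray:
        return np.array([self.suv_1p25, self.suv_13p5, self.suv_50, self.k1], dtype=float)


def interpolate_to_grid(
    tac: TimeActivityCurve, schedule: FrameSchedule, grid_minutes
) -> np.ndarray:
    """Linearly interpolate frame-midpoint TAC samples onto ``grid_minutes``."""
    grid = np.atleast_1d(np.asarray(grid_minutes, dtype=float))
    mid = schedule.midpoints
    lo, hi = mid[0], mid[-1]
    bad = grid[(grid < lo) | (grid > hi)]
    if bad.size:
        raise ValueError(
            f"grid point {bad[0]:g} min outside interpolation support "
            f"[{lo:g}, {hi:g}] min"
        )
    return np.interp(grid, mid, tac.values)


def compute_suv(
    tac: TimeActivityCurve,
    schedule: FrameSchedule,
    dose_mbq: float,
    weight_kg: float,
    t_minutes: float,
) -> float:
    """SUV(t) = C(t)[kBq/mL] / (dose[kBq] / weight[g]); tissue density 1 g/mL."""
    if dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    c = float(interpolate_to_grid(tac, schedule, [t_minutes])[0])
    dose_kbq = dose_mbq * 1000.0
    weight_g = weight_kg * 1000.0
    return c / (dose_kbq / weight_g)


def plasma_integral(idif: InputFunction, times) -> np.ndarray:
    """Running integral of the input function, evaluated at ``times``.

    Trapezoid rule on the union of the IDIF samples and the query times;
    the curve is taken as 0 before its first sample if that is after t=0.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    t = idif.times
    c = idif.concentrations
    if t[0] > 0.0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    union = np.unique(np.concatenate([t, times]))
    if union[-1] > t[-1]:
        raise ValueError(
            f"input function (ends {t[-1]:g} min) does not cover requested time "
            f"{union[-1]:g} min"
        )
    cu = np.interp(union, t, c)
    cumulative = np.concatenate(
        [[0.0], np.cumsum(0.5 * (cu[1:] + cu[:-1]) * np.diff(union))]
    )
    return np.interp(times, union, cumulative)


def estimate_k1(
    tac: TimeActivityCurve,
    schedule: FrameSchedule,
    idif: InputFunction,
    fit_window_minutes: tuple[float, float] = (0.0, 50.0),
) -> float:
    """K1 of the irreversible one-tissue model, C_T(t) = K1 * int_0^t C_p.

    Least squares through the origin over frames whose midpoints fall in the
    fit window; the estimate is clipped at 0.
    """
    mid = schedule.midpoints
    w0, w1 = fit_window_minutes
    mask = (mid >= w0) & (mid <= w1)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 frames in fit window [{w0:g}, {w1:g}] min, got {int(mask.sum())}"
        )
    x = plasma_integral(idif, mid[mask])
    y = tac.values[mask]
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("degenerate input function: all-zero plasma integral over the fit window")
    k1 = float(np.dot(x, y) / sxx)
    return max(k1, 0.0)


def extract_features(
    scan: ScanRecord,
    config: KineticsConfig | None = None,
    registry=None,
) -> list[RegionFeatureVector]:
    """One feature vector per registry ROI, in registry order."""
    from .registry import build_default_registry

    config = config or KineticsConfig()
    registry = registry or build_default_registry()
    if scan.schedule is None or scan.idif is None:
        raise ValueError(f"scan {scan.scan_id!r} lacks a schedule or IDIF")
    scan.validate_against_registry(registry)

    last_mid = scan.schedule.midpoints[-1]
    for t in config.suv_times_minutes:
        if t > last_mid:
            raise ValueError(
                f"scan {scan.scan_id!r}: SUV time t={t:g} min exceeds scan support "
                f"({last_mid:g} min)"
            )

    out: list[RegionFeatureVector] = []
    for name in registry.names:
        tac = scan.tacs[name]
        suvs = [
            compute_suv(tac, scan.schedule, scan.dose_mbq, scan.weight_kg, t)
            for t in config.suv_times_minutes
        ]
        k1 = estimate_k1(tac, scan.schedule, scan.idif, config.k1_fit_window_minutes)
        out.append(RegionFeatureVector(name, suvs[0], suvs[1], suvs[2], k1))
    return out


def feature_frame(scans, config: KineticsConfig | None = None, registry=None):
    """Feature table for a cohort: MultiIndex (scan_id, roi) x 4 features."""
    import pandas as pd

    rows = {}
    for scan in scans:
        for fv in extract_features(scan, config=config, registry=registry):
            rows[(scan.scan_id, fv.roi_id)] = fv.as_array()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index = pd.MultiIndex.from_tuples(df.index, names=["scan_id", "roi"])
    return df
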