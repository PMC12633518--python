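"""Core domain types for dynamic-PET scans.

All times are minutes post-injection; activity concentrations are kBq/mL.
TACs are assumed decay-corrected upstream — no decay correction is applied
anywhere in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "TimeActivityCurve", "InputFunction", "ScanRecord"]

SEX_LEVELS = ("M", "F")
GENOTYPE_LEVELS = ("HAB", "MAB", "NA")


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing: start/end of each frame in minutes."""

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size < 1:
            raise ValueError("frame_start and frame_end must be equal-length 1-D arrays with >= 1 frame")
        if start[0] < 0:
            raise ValueError("frame_start[0] must be >= 0")
        if np.any(start >= end):
            raise ValueError("every frame must satisfy frame_start < frame_end")
        if np.any(start[1:] < end[:-1]):
            raise ValueError("frames must be sorted and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.frame_start, other.frame_start) and np.array_equal(
            self.frame_end, other.frame_end
        )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Regional activity concentration per frame (kBq/mL)."""

    roi_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("TAC values must be 1-D")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"TAC for {self.roi_id!r} contains non-finite values")
        if np.any(values < 0):
            # small negatives occur in reconstructed PET; warn rather than fail
            warnings.warn(
                f"TAC for {self.roi_id!r} contains negative values "
                f"(min {values.min():.4g} kBq/mL)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class InputFunction:
    """Plasma/blood tracer concentration curve (image-derived)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or t.shape != c.shape or t.size < 2:
            raise ValueError("input function needs matching 1-D times/concentrations with >= 2 samples")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("input-function times must be strictly increasing and start at >= 0")
        if not np.all(np.isfinite(c)):
            raise ValueError("input-function concentrations must be finite")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InputFunction):
            return NotImplemented
        return np.array_equal(self.times, other.times) and np.array_equal(
            self.concentrations, other.concentrations
        )


@dataclass
class ScanRecord:
    """One PET scan: regional TACs, frame schedule, input function, covariates."""

    scan_id: str
    subject_id: str
    tracer: str
    batch: str
    dose_mbq: float
    weight_kg: float
    age: float
    sex: str
    genotype: str
    diagnosis: str
    session: str
    tacs: dict[str, TimeActivityCurve] = field(default_factory=dict)
    schedule: FrameSchedule | None = None
    idif: InputFunction | None = None

    def __post_init__(self) -> None:
        if self.dose_mbq <= 0:
            raise ValueError(f"scan {self.scan_id!r}: non-positive dose ({self.dose_mbq})")
        if self.weight_kg <= 0:
            raise ValueError(f"scan {self.scan_id!r}: non-positive weight ({self.weight_kg})")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"scan {self.scan_id!r}: sex must be one of {SEX_LEVELS}")
        if self.genotype not in GENOTYPE_LEVELS:
            raise ValueError(f"scan {self.scan_id!r}: genotype must be one of {GENOTYPE_LEVELS}")
        if self.schedule is not None:
            for roi, tac in self.tacs.items():
                if tac.values.size != self.schedule.n_frames:
                    raise ValueError(
                        f"scan {self.scan_id!r}, ROI {roi!r}: TAC length "
                        f"{tac.values.size} != {self.schedule.n_frames} frames"
                    )

    @property
    def dose_over_weight(self) -> float:
        """Injected dose over body weight, MBq/kg."""
        return self.dose_mbq / self.weight_kg

    def validate_against_registry(self, registry) -> None:
        """Check every registry ROI has exactly one TAC."""
        missing = [n for n in registry.names if n not in self.tacs]
        if missing:
            raise ValueError(
                f"scan {self.scan_id!r}: missing TAC for ROI(s) {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        extra = [n for n in self.tacs if n not in registry]
        if extra:
            raise ValueError(f"scan {self.scan_id!r}: TACs for unknown ROI(s) {extra[:5]}")
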