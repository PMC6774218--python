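"""Core in-memory containers for traces, images and extracted features.

Conventions
-----------
* ERG time is in milliseconds from record start; sample ``i`` sits at
  ``i * 1000 / sampling_rate``.  Voltages are in microvolts.
* OCT images are stored rows = axial depth (row 0 = vitreous side),
  columns = lateral position; the axial pixel pitch is in micrometres.
* Boundary positions are axial row coordinates (sub-pixel floats allowed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError


@dataclass
class ErgTrace:
    """A uniformly sampled ERG voltage recording.

    Parameters
    ----------
    samples : array of μV values
    sampling_rate : Hz
    flash_time : ms from record start at which the flash is delivered
    label : protocol tag, ``"dim-STR"`` or ``"bright-flash"``
    """

    samples: np.ndarray
    sampling_rate: float
    flash_time: float
    label: str = "bright-flash"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidParameterError("trace needs >= 2 samples in 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("trace contains non-finite samples")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if not (0 <= self.flash_time < self.duration_ms):
            raise InvalidParameterError(
                f"flash_time {self.flash_time} ms outside record "
                f"[0, {self.duration_ms}) ms"
            )

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return self.samples.size * 1000.0 / self.sampling_rate

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms

    @property
    def flash_index(self) -> int:
        """First sample index at or after the flash."""
        return int(np.ceil(self.flash_time / self.dt_ms - 1e-9))

    def copy_with(self, samples: np.ndarray, label: str | None = None) -> "ErgTrace":
        return ErgTrace(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            flash_time=self.flash_time,
            label=self.label if label is None else label,
        )


@dataclass
class ErgFeatures:
    """Scalar ERG parameters of one recording session (one animal/eye).

    ``a_amp`` is signed (negative by convention); ``op_total`` is the exact
    sum of ``op_amps``.
    """

    a_amp: float
    b_amp: float
    pstr_amp: float
    op_amps: tuple[float, float, float]
    a_trough_time: float = float("nan")
    b_peak_time: float = float("nan")

    @property
    def op_total(self) -> float:
        return float(sum(self.op_amps))

    def as_dict(self) -> dict[str, float]:
        return {
            "a_amp": self.a_amp,
            "b_amp": self.b_amp,
            "pstr_amp": self.pstr_amp,
            "op1": self.op_amps[0],
            "op2": self.op_amps[1],
            "op3": self.op_amps[2],
            "op_total": self.op_total,
            "a_trough_time": self.a_trough_time,
            "b_peak_time": self.b_peak_time,
        }


@dataclass
class BScan:
    """One OCT B-scan cross-section.

    ``onh_cols`` optionally marks the lateral column interval
    ``(lo, hi)`` (half-open) occupied by the optic nerve head; those
    columns are excluded from thickness averaging.
    """

    image: np.ndarray
    axial_px_um: float
    onh_cols: tuple[int, int] | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or min(self.image.shape) < 32:
            raise InvalidParameterError("B-scan must be 2-D and >= 32x32 px")
        if not np.all(np.isfinite(self.image)):
            raise InvalidParameterError("B-scan contains non-finite pixels")
        if np.any(self.image < 0):
            raise InvalidParameterError("B-scan intensities must be >= 0")
        if self.axial_px_um <= 0:
            raise InvalidParameterError("axial_px_um must be positive")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass
class BoundarySet:
    """Per-column axial positions of the three traced interfaces.

    Ordered top-to-bottom: ILM (top of GCL), INL/OPL interface, RPE base.
    """

    ilm: np.ndarray
    inl_opl: np.ndarray
    rpe_base: np.ndarray
    corrected_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=float)
        self.inl_opl = np.asarray(self.inl_opl, dtype=float)
        self.rpe_base = np.asarray(self.rpe_base, dtype=float)
        if not (self.ilm.shape == self.inl_opl.shape == self.rpe_base.shape):
            raise InvalidParameterError("boundary arrays differ in shape")
        self.validate_ordering()

    def validate_ordering(self) -> None:
        if not (np.all(self.ilm < self.inl_opl) and np.all(self.inl_opl < self.rpe_base)):
            bad = np.flatnonzero(
                ~((self.ilm < self.inl_opl) & (self.inl_opl < self.rpe_base))
            )
            raise InvalidParameterError(
                f"boundary ordering ILM < INL/OPL < RPE violated at columns {bad[:5]}"
            )

    @property
    def width(self) -> int:
        return self.ilm.size

    def as_array(self) -> np.ndarray:
        """(3, width) array ordered top-to-bottom."""
        return np.vstack([self.ilm, self.inl_opl, self.rpe_base])


@dataclass
class ThicknessResult:
    """Averaged, intensity-normalized thickness of one eye (5 B-scans)."""

    inner_um: float
    outer_um: float
    inner_norm_intensity: float = float("nan")
    outer_norm_intensity: float = float("nan")
    corrected_fraction: float = 0.0
    n_scans_used: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "inner_um": self.inner_um,
            "outer_um": self.outer_um,
            "inner_norm_intensity": self.inner_norm_intensity,
            "outer_norm_intensity": self.outer_norm_intensity,
            "corrected_fraction": self.corrected_fraction,
            "n_scans_used": self.n_scans_used,
        }


@dataclass
class NorTrial:
    """Exploration times (seconds) of one novel-object-recognition trial."""

    novel: float
    familiar: float
    animal_id: str = ""
    age_months: float = float("nan")

    def __post_init__(self) -> None:
        if self.novel < 0 or self.familiar < 0:
            raise InvalidParameterError("exploration times must be >= 0")
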