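"""Core containers for flash-series spectro-kinetic data.

A step-scan flash experiment produces, for each of ``n_flashes`` saturating
laser flashes applied to a dark-adapted sample, a time course of absorbance
changes at every wavenumber of the probed spectral window.  The central
container is :class:`FlashSeriesDataset`, a (flash x time x wavenumber) array
with validated axes.  Time is in microseconds with 0 at the flash (pre-flash
samples carry negative times); wavenumbers are stored ascending in cm^-1;
absorbance changes are in OD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, ValidationError

#: Canonical ordering of the four S-state transitions of the Kok cycle.
TRANSITIONS = ("S0->S1", "S1->S2", "S2->S3", "S3->S0")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid with the flash instant at time zero.

    Parameters
    ----------
    dt:
        Sampling interval in microseconds (6 us in the default protocol).
    n_samples:
        Total number of samples per flash.
    t0_index:
        Index of the sample taken at the flash instant; samples before it
        carry negative times.
    """

    dt: float
    n_samples: int
    t0_index: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0 <= self.t0_index < self.n_samples:
            raise ValidationError(
                f"t0_index {self.t0_index} outside [0, {self.n_samples})"
            )

    @property
    def pre_flash_samples(self) -> int:
        return self.t0_index

    @property
    def times(self) -> np.ndarray:
        """Time axis in microseconds, strictly increasing, 0 at the flash."""
        return (np.arange(self.n_samples) - self.t0_index) * self.dt


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending wavenumber axis (cm^-1).

    Readers that encounter a descending axis must reverse both the axis and
    the associated data before constructing the grid; use
    :meth:`from_values` to obtain the required permutation.
    """

    values: np.ndarray
    instrument_range: tuple[float, float] = (800.0, 4000.0)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValidationError("wavenumber values must be a non-empty 1D array")
        if vals.size > 1 and not np.all(np.diff(vals) > 0):
            raise ValidationError("wavenumber grid must be strictly ascending")
        lo, hi = self.instrument_range
        if vals[0] < lo or vals[-1] > hi:
            raise ValidationError(
                f"wavenumbers [{vals[0]}, {vals[-1]}] outside instrument "
                f"range [{lo}, {hi}]"
            )

    @classmethod
    def from_values(cls, values, instrument_range=(800.0, 4000.0)):
        """Build a grid from possibly descending input.

        Returns ``(grid, order)`` where ``order`` indexes the original values
        into ascending order (apply it to the wavenumber axis of the data).
        """
        vals = np.asarray(values, dtype=float)
        if vals.size > 1 and np.all(np.diff(vals) < 0):
            order = np.arange(vals.size)[::-1]
        else:
            order = np.arange(vals.size)
        return cls(vals[order], instrument_range), order

    def __len__(self):
        return self.values.size

    def __eq__(self, other):
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self):  # frozen dataclass with array field
        return hash((self.values.tobytes(), self.instrument_range))


@dataclass
class SpectrumVector:
    """A spectrum on a wavenumber grid; supports grid-checked arithmetic."""

    wavenumbers: WavenumberGrid
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.wavenumbers),):
            raise DimensionError(
                f"spectrum length {vals.shape} does not match grid "
                f"({len(self.wavenumbers)},)"
            )
        self.values = vals

    def _check_grid(self, other: "SpectrumVector"):
        if self.wavenumbers != other.wavenumbers:
            raise ValidationError(
                "spectra are on different wavenumber grids; resample first"
            )

    def __add__(self, other):
        self._check_grid(other)
        return SpectrumVector(self.wavenumbers, self.values + other.values)

    def __sub__(self, other):
        self._check_grid(other)
        return SpectrumVector(self.wavenumbers, self.values - other.values)

    def __mul__(self, factor: float):
        return SpectrumVector(self.wavenumbers, self.values * float(factor))

    __rmul__ = __mul__


@dataclass
class FlashSeriesDataset:
    """3D (flash x time x wavenumber) absorbance-change array with axes.

    ``flash_spacing`` is the time between consecutive flashes in
    milliseconds (700 ms in the default IR protocol).
    """

    data: np.ndarray
    time: TimeGrid
    wavenumbers: WavenumberGrid
    flash_spacing: float = 700.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise DimensionError(f"data must be 3D, got shape {arr.shape}")
        n_flashes, n_t, n_wn = arr.shape
        if n_flashes < 1:
            raise ValidationError("dataset must contain at least one flash")
        if n_t != self.time.n_samples:
            raise DimensionError(
                f"time axis has {self.time.n_samples} samples but data has {n_t}"
            )
        if n_wn != len(self.wavenumbers):
            raise DimensionError(
                f"wavenumber axis has {len(self.wavenumbers)} points but data "
                f"has {n_wn}"
            )
        bad = np.argwhere(~np.isfinite(arr))
        if bad.size:
            raise ValidationError(
                f"non-finite values at indices {bad[:5].tolist()}"
                + ("..." if len(bad) > 5 else "")
            )
        if self.flash_spacing <= 0:
            raise ValidationError("flash_spacing must be positive")
        self.data = arr

    @property
    def n_flashes(self) -> int:
        return self.data.shape[0]

    def flash(self, n: int) -> np.ndarray:
        """Time x wavenumber array of flash ``n`` (0-based)."""
        return self.data[n]


@dataclass
class TransitionSeries:
    """Per-transition time x wavenumber arrays on shared axes.

    ``data`` has shape (4, n_samples, n_wavenumbers) ordered as
    :data:`TRANSITIONS`.
    """

    data: np.ndarray
    time: TimeGrid
    wavenumbers: WavenumberGrid
    residual_norm: float = 0.0
    condition_number: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        expected = (4, self.time.n_samples, len(self.wavenumbers))
        if arr.shape != expected:
            raise DimensionError(
                f"transition data shape {arr.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("transition series contains non-finite values")
        self.data = arr

    def transition(self, name: str) -> np.ndarray:
        """Time x wavenumber array for one transition, e.g. ``\"S3->S0\"``."""
        try:
            idx = TRANSITIONS.index(name)
        except ValueError:
            raise KeyError(
                f"unknown transition {name!r}; expected one of {TRANSITIONS}"
            ) from None
        return self.data[idx]
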