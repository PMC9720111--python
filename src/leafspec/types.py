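"""Core domain types shared across the pipeline.

The central objects are a wavelength grid, a measured leaf spectrum
(paired reflectance/transmittance), and the leaf biophysical parameter
vector of the generalized plate model: a structure parameter ``n``
(effective number of stacked plates), pigment contents per unit leaf
area, the xanthophyll de-epoxidation fraction ``cx``, and the water and
dry-matter terms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Fit window used for model inversion (nm). Spectra may be acquired from
#: 340 nm but only this window enters the least-squares objective.
FIT_WINDOW: tuple[float, float] = (400.0, 900.0)

#: Tolerance on R+T exceeding 1 before a record is rejected as a
#: calibration failure.
CALIBRATION_TOLERANCE: float = 0.01


class CalibrationError(ValueError):
    """Reflectance + transmittance exceeds 1 beyond tolerance."""


class GridMismatchError(ValueError):
    """Two spectral objects do not share the same wavelength grid."""


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True, eq=False)
class SpectralGrid:
    """Strictly increasing wavelength grid in nanometres (>= 340 nm)."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("grid must be a 1-D array with at least 2 wavelengths")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < 340.0:
            raise ValueError("wavelengths below the 340 nm acquisition limit")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:  # frozen dataclass with custom eq
        return hash((self.wavelengths.size, float(self.wavelengths[0]), float(self.wavelengths[-1])))

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of wavelengths inside the closed interval [lo, hi]."""
        return (self.wavelengths >= lo) & (self.wavelengths <= hi)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi


def default_grid() -> SpectralGrid:
    """Canonical internal grid: 400-900 nm at 1 nm spacing."""
    return SpectralGrid(np.arange(400.0, 901.0, 1.0))


@dataclass(frozen=True)
class LeafSpectrum:
    """Paired reflectance/transmittance fractions on a grid.

    Invariant: 0 <= R, 0 <= T and R + T <= 1 elementwise (energy
    conservation of a passive slab).
    """

    grid: SpectralGrid
    reflectance: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        t = np.asarray(self.transmittance, dtype=float)
        if r.shape != (len(self.grid),) or t.shape != (len(self.grid),):
            raise GridMismatchError("R/T arrays do not conform to the grid length")
        if np.any(r < 0) or np.any(t < 0):
            raise ValueError("negative reflectance or transmittance")
        if np.any(r + t > 1.0 + 1e-9):
            raise ValueError("R + T exceeds 1: not a passive leaf spectrum")
        object.__setattr__(self, "reflectance", r)
        object.__setattr__(self, "transmittance", t)

    @property
    def absorptance(self) -> np.ndarray:
        return 1.0 - self.reflectance - self.transmittance


SIDES = ("left", "right", "averaged")


@dataclass
class MeasuredSpectrumRecord:
    """A measured leaf spectrum with sample identity and treatment metadata.

    ``side`` records which side of the midrib the ~1 cm^2 spot was taken
    from; bench protocol measures both sides and averages them.
    Metadata keys in use: ``cultivar``, ``pfd``, ``spectrum`` (B15/B40),
    ``day``, ``leaf``.
    """

    sample_id: str
    side: str
    grid: SpectralGrid
    reflectance: np.ndarray
    transmittance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        r = np.asarray(self.reflectance, dtype=float)
        t = np.asarray(self.transmittance, dtype=float)
        if r.shape != (len(self.grid),) or t.shape != (len(self.grid),):
            raise GridMismatchError("R/T arrays do not conform to the grid length")
        if np.any((r < 0) | (r > 1)) or np.any((t < 0) | (t > 1)):
            raise ValueError("reflectance/transmittance outside [0, 1]")
        if np.any(r + t > 1.0 + CALIBRATION_TOLERANCE):
            raise CalibrationError(
                "R + T > 1 beyond tolerance %.3g: white-standard calibration suspect"
                % CALIBRATION_TOLERANCE
            )
        self.reflectance = r
        self.transmittance = t

    def as_spectrum(self) -> LeafSpectrum:
        # A calibrated record may exceed R+T=1 by the small calibration
        # tolerance; renormalize those channels onto the passive boundary.
        r, t = self.reflectance.copy(), self.transmittance.copy()
        s = r + t
        over = s > 1.0
        if np.any(over):
            r[over] /= s[over]
            t[over] /= s[over]
        return LeafSpectrum(self.grid, r, t)


@dataclass
class LeafBiophysics:
    """Plate-model parameter vector.

    Parameters
    ----------
    n : float
        Leaf structure parameter, the effective number of stacked
        elementary plates (dimensionless, >= 1).
    cab, ccar, canth : float
        Total chlorophyll a+b, total carotenoid and anthocyanin content
        per leaf area (ug cm^-2).
    cx : float
        Zeaxanthin(+antheraxanthin) fraction of the total xanthophyll
        pool, (Z+A)/(Z+A+V), in [0, 1]. Shifts the carotenoid
        absorption between the violaxanthin- and zeaxanthin-dominated
        end members.
    cbrown : float
        Brown pigment content (arbitrary units, >= 0).
    cw : float
        Equivalent water thickness (cm).
    cm : float
        Dry matter per area (g cm^-2); doubles as leaf mass per area.
    """

    n: float = 1.5
    cab: float = 35.0
    ccar: float = 7.0
    canth: float = 0.0
    cx: float = 0.3
    cbrown: float = 0.0
    cw: float = 0.01
    cm: float = 0.004

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("structure parameter n must be >= 1")
        for name in ("cab", "ccar", "canth", "cbrown", "cw", "cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cx <= 1.0:
            raise ValueError("cx must lie in [0, 1]")

    @property
    def chl_car_ratio(self) -> float:
        return self.cab / self.ccar if self.ccar > 0 else float("nan")

    def as_dict(self) -> Mapping[str, float]:
        return {
            "n": self.n, "cab": self.cab, "ccar": self.ccar,
            "canth": self.canth, "cx": self.cx, "cbrown": self.cbrown,
            "cw": self.cw, "cm": self.cm,
        }
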