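"""Light-adapted chlorophyll *a* fluorescence quenching indices.

Indices are computed from four trace level summaries (instrument
counts) extracted upstream by the imaging fluorometer protocol:

- ``f_m_lss``: steady-state maximum fluorescence in light (F_M'),
- ``f_t_lss``: steady-state fluorescence in light (F_t),
- ``f_p``: peak fluorescence of the initial Kautsky phase,
- ``f_m_d3``: instantaneous maximum fluorescence during dark relaxation.

    QY (phiPSII) = (F_M' - F_t) / F_M'      steady-state PSII quantum yield
    Rfd          = (F_P - F_t) / F_t        fluorescence-decline vitality index
    qE           = (F_M_D3 - F_M') / F_M_D3 energy-dependent quenching
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FluorTrace",
    "FluorIndices",
    "compute_indices",
    "vitality_classification",
    "RFD_CRITICAL",
    "RFD_HIGH",
]

#: Rfd below this indicates impaired photosynthetic activity.
RFD_CRITICAL = 1.0
#: Rfd at or above this indicates high photosynthetic efficiency.
RFD_HIGH = 3.0


@dataclass
class FluorTrace:
    """Level summaries of one light-adapted fluorescence trace."""

    f_m_lss: float
    f_t_lss: float
    f_p: float
    f_m_d3: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if min(self.f_m_lss, self.f_t_lss, self.f_p, self.f_m_d3) < 0:
            raise ValueError("fluorescence levels must be non-negative")


@dataclass
class FluorIndices:
    """Quenching indices; an index is NaN (and flagged) if its denominator is zero."""

    qy: float
    rfd: float
    qe: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def compute_indices(trace: FluorTrace) -> FluorIndices:
    """QY, Rfd and qE for one trace; zero denominators flag the single index."""
    flags: list[str] = []
    if trace.f_m_lss > 0:
        qy = (trace.f_m_lss - trace.f_t_lss) / trace.f_m_lss
    else:
        qy, _ = math.nan, flags.append("QY undefined: F_M_Lss = 0")
    if trace.f_t_lss > 0:
        rfd = (trace.f_p - trace.f_t_lss) / trace.f_t_lss
    else:
        rfd, _ = math.nan, flags.append("Rfd undefined: F_t_Lss = 0")
    if trace.f_m_d3 > 0:
        qe = (trace.f_m_d3 - trace.f_m_lss) / trace.f_m_d3
    else:
        qe, _ = math.nan, flags.append("qE undefined: F_M_D3 = 0")
    return FluorIndices(qy=qy, rfd=rfd, qe=qe, flags=tuple(flags))


def vitality_classification(
    rfd: float, critical: float = RFD_CRITICAL, high: float = RFD_HIGH
) -> str:
    """Classify an Rfd value: ``below_critical`` (< 1), ``high`` (>= 3), else ``normal``.

    Values reaching the high threshold are read as indicating high
    photosynthetic efficiency; both thresholds are configurable.
    """
    if not math.isfinite(rfd):
        raise ValueError("Rfd must be finite")
    if rfd < critical:
        return "below_critical"
    if rfd >= high:
        return "high"
    return "normal"
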