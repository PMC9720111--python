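"""Spectrophotometric pigment assay of 95%-ethanol leaf extracts.

Absorbances at 470, 649 and 664 nm (1 cm pathlength, blank-corrected)
are converted to chlorophyll a, chlorophyll b and total carotenoid
concentrations with the standard 95%-ethanol linear equations

    c_a   = 13.36 A664 - 5.19 A649
    c_b   = 27.43 A649 - 8.12 A664
    c_car = (1000 A470 - 2.13 c_a - 97.64 c_b) / 209

(ug mL^-1), then to contents per unit dry mass via extract volume and
sample mass. Extraction replicates are averaged after conversion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "AssayRecord",
    "PigmentContent",
    "extract_concentrations",
    "content_per_dry_mass",
    "summarize_replicates",
]

#: Linear assay coefficients keyed by solvent system. Only 95% ethanol
#: ships; other solvents can be registered by adding an entry.
SOLVENT_COEFFICIENTS = {
    "ethanol95": {
        "ca": (13.36, -5.19),       # * (A664, A649)
        "cb": (-8.12, 27.43),       # * (A664, A649)
        "car": (2.13, 97.64, 209.0),  # (1000*A470 - c1*ca - c2*cb) / c3
    }
}

#: Concentrations more negative than this (ug/mL) invalidate a replicate.
NEGATIVE_CONC_TOLERANCE = -0.01

#: Absorbance above which the detector linear range is doubtful.
LINEAR_RANGE_LIMIT = 1.2


class AssayError(ValueError):
    """A replicate produced physically impossible concentrations."""


@dataclass
class AssayRecord:
    """One extraction replicate: absorbance triplet plus mass/volume."""

    sample_id: str
    a470: float
    a649: float
    a664: float
    extract_volume_ml: float = 2.3
    dry_mass_mg: float = 2.0
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if min(self.a470, self.a649, self.a664) < 0:
            raise ValueError("absorbances must be non-negative")
        if self.extract_volume_ml <= 0 or self.dry_mass_mg <= 0:
            raise ValueError("extract volume and dry mass must be positive")


@dataclass
class PigmentContent:
    """Mass-based pigment contents (mg per g dry weight)."""

    sample_id: str
    chl_a: float
    chl_b: float
    chl_total: float
    car_total: float
    chl_car_ratio: float
    n_replicates: int = 1
    flags: tuple[str, ...] = field(default_factory=tuple)


def extract_concentrations(
    a470: float, a649: float, a664: float, solvent: str = "ethanol95"
) -> tuple[float, float, float]:
    """Pigment concentrations (ug mL^-1) from an absorbance triplet.

    Raises :class:`AssayError` if any concentration falls below the
    negative-concentration tolerance; warns above the linear range.
    """
    if min(a470, a649, a664) < 0:
        raise ValueError("absorbances must be non-negative")
    if max(a470, a649, a664) > LINEAR_RANGE_LIMIT:
        warnings.warn(
            "absorbance above ~%.1f: outside the detector linear range"
            % LINEAR_RANGE_LIMIT,
            stacklevel=2,
        )
    c = SOLVENT_COEFFICIENTS[solvent]
    ca = c["ca"][0] * a664 + c["ca"][1] * a649
    cb = c["cb"][0] * a664 + c["cb"][1] * a649
    ccar = (1000.0 * a470 - c["car"][0] * ca - c["car"][1] * cb) / c["car"][2]
    if min(ca, cb, ccar) < NEGATIVE_CONC_TOLERANCE:
        raise AssayError(
            f"negative pigment concentration (ca={ca:.3g}, cb={cb:.3g}, "
            f"ccar={ccar:.3g} ug/mL): assay invalid"
        )
    return ca, cb, ccar


def content_per_dry_mass(conc_ug_ml: float, volume_ml: float, mass_mg: float) -> float:
    """Content in mg per g dry weight from a concentration in ug mL^-1.

    conc * volume / mass has units ug/mg, numerically equal to mg/g.
    """
    if volume_ml <= 0 or mass_mg <= 0:
        raise ValueError("volume and mass must be positive")
    return conc_ug_ml * volume_ml / mass_mg


def summarize_replicates(records: list[AssayRecord]) -> PigmentContent:
    """Mean pigment contents across extraction replicates of one sample.

    Replicates yielding impossible (negative) concentrations are dropped
    and flagged; the summary averages the remainder. A zero carotenoid
    content flags the chl/car ratio as undefined (NaN).
    """
    if not records:
        raise ValueError("at least one replicate required")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(f"replicates span multiple samples: {sorted(sample_ids)}")
    flags: list[str] = []
    per_rep: list[tuple[float, float, float]] = []
    for rec in records:
        try:
            ca, cb, ccar = extract_concentrations(rec.a470, rec.a649, rec.a664)
        except AssayError:
            flags.append(f"replicate {rec.replicate_id} invalid")
            continue
        per_rep.append(
            tuple(
                content_per_dry_mass(c, rec.extract_volume_ml, rec.dry_mass_mg)
                for c in (ca, cb, ccar)
            )
        )
    if not per_rep:
        raise AssayError("all replicates invalid")
    k = len(per_rep)
    chl_a = sum(v[0] for v in per_rep) / k
    chl_b = sum(v[1] for v in per_rep) / k
    car = sum(v[2] for v in per_rep) / k
    if car > 0:
        ratio = (chl_a + chl_b) / car
    else:
        ratio = float("nan")
        flags.append("chl/car undefined: zero carotenoid content")
    return PigmentContent(
        sample_id=records[0].sample_id,
        chl_a=chl_a,
        chl_b=chl_b,
        chl_total=chl_a + chl_b,
        car_total=car,
        chl_car_ratio=ratio,
        n_replicates=k,
        flags=tuple(flags),
    )
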