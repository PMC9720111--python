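"""Synthetic study generator.

Emulates the statistical structure of the growth-chamber experiment —
2 cultivars (green, anthocyanin-free; red, anthocyanin-bearing) x
2 photon flux densities (160, 240 umol m^-2 s^-1) x 2 spectra (B15,
B40 blue fraction) x 3 sampling days (1, 7, 14) with replicate leaves —
so every pipeline stage runs without any measured data. For each leaf
it draws a true parameter vector (baseline x treatment multipliers x
replicate scatter), renders a reflectance/transmittance spectrum with
the plate model plus multiplicative noise, derives assay absorbances by
inverting the wet-chemistry linear equations from the true mass-based
contents, and draws fluorescence levels whose Rfd and qE rise with time
and blue fraction. Ground truth is stored for every record.

Treatment-effect multipliers are a *calibration* mirroring the
directions and magnitudes reported for the real experiment (e.g. +13%
chlorophyll under 160WB40 at day 1, +12% under 240WB40; anthocyanin
stimulation up to +50% at 160 and +19% at 240 in the red cultivar;
chl/car drifting up over days at 160 and down at 240), not ground
truth about lettuce.

Also builds the synthetic :class:`~leafspec.radiative_transfer.AbsorptionLibrary`
(Gaussian absorption bands at literature-plausible centers) that the
packaged tests and examples run against.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radiative_transfer import AbsorptionLibrary, forward_model
from .types import (
    ConfigurationError,
    LeafBiophysics,
    MeasuredSpectrumRecord,
    default_grid,
)
from .wet_chemistry import SOLVENT_COEFFICIENTS

__all__ = [
    "SyntheticDesign",
    "SyntheticCohort",
    "build_synthetic_library",
    "sample_biophysics",
    "generate_cohort",
    "generate_ratio_straddle_batch",
    "default_effects",
    "default_baselines",
]


def build_synthetic_library(seed: int = 0) -> AbsorptionLibrary:
    """Synthetic specific-absorption library on the 400-900 nm 1 nm grid.

    Gaussian bands at literature-plausible centers: chlorophyll
    dominant in the red (~680 nm) with Soret-region bands (~430/460
    nm), carotenoid end members in the blue-green with the zeaxanthin
    member red-shifted 12.5 nm against the violaxanthin member,
    anthocyanin in the green (~550 nm), a brown-pigment term decaying
    from the blue, a water tail rising toward 900 nm (negligible
    in-window) and a small broad dry-matter term. Deterministic given
    ``seed`` (the seed jitters band centers/amplitudes by <1%).
    """
    grid = default_grid()
    wl = grid.wavelengths
    rng = np.random.default_rng(seed)

    def gauss(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((wl - center) / width) ** 2)

    def jc(center: float) -> float:
        return center + rng.uniform(-0.5, 0.5)

    def ja(amp: float) -> float:
        return amp * (1.0 + rng.uniform(-0.02, 0.02))

    k_ab = (
        ja(0.065) * gauss(jc(680.0), 21.0)
        + ja(0.042) * gauss(jc(430.0), 18.0)
        + ja(0.020) * gauss(jc(462.0), 24.0)
        + ja(0.008) * gauss(jc(600.0), 45.0)
    )
    car_centers = [jc(448.0), jc(474.0), jc(424.0)]
    car_amps = [ja(0.036), ja(0.040), ja(0.014)]
    car_widths = [16.0, 17.0, 14.0]
    z_shift = 12.5  # de-epoxidized pool absorbs red-shifted
    k_car_v = sum(a * gauss(c, w) for a, c, w in zip(car_amps, car_centers, car_widths))
    k_car_z = sum(
        a * gauss(c + z_shift, w) for a, c, w in zip(car_amps, car_centers, car_widths)
    )
    k_anth = ja(0.032) * gauss(jc(548.0), 32.0)
    k_brown = 0.02 * np.exp(-(wl - 400.0) / 160.0)
    k_w = 1.0 * np.exp((wl - 900.0) / 45.0)
    k_m = 6.0 * np.exp(-(wl - 400.0) / 260.0)
    n_refr = 1.45 - 0.05 * (wl - 400.0) / 500.0
    return AbsorptionLibrary(
        grid=grid, n_refr=n_refr, k_ab=k_ab, k_car_v=k_car_v, k_car_z=k_car_z,
        k_anth=k_anth, k_brown=k_brown, k_w=k_w, k_m=k_m,
    )


def default_baselines() -> dict[str, LeafBiophysics]:
    """Cultivar baseline parameter vectors (chl/car ratios inside 4.4-6.4)."""
    return {
        "green": LeafBiophysics(
            n=1.6, cab=32.0, ccar=32.0 / 5.6, canth=0.0, cx=0.30,
            cbrown=0.0, cw=0.009, cm=0.0038,
        ),
        "red": LeafBiophysics(
            n=1.5, cab=38.0, ccar=38.0 / 5.0, canth=4.0, cx=0.35,
            cbrown=0.0, cw=0.010, cm=0.0042,
        ),
    }


def default_effects() -> dict[str, dict[tuple[int, str, int], float]]:
    """Treatment multipliers keyed (pfd, spectrum, day); unlisted cells are 1.

    Calibration targets: +13%/+12% chlorophyll under B40 at day 1
    (160/240), +15% carotenoids at day 1, anthocyanin stimulation up to
    +50% (160) and +19% (240) in the red cultivar, chl/car rising over
    days at 160 and declining at 240, and the zeaxanthin fraction
    lowered by B40 at 160 but raised at 240.
    """
    return {
        "cab": {
            (160, "B40", 1): 1.13, (240, "B40", 1): 1.12,
            (240, "B15", 7): 1.03, (240, "B40", 7): 1.05,
            (240, "B15", 14): 1.06, (240, "B40", 14): 1.06,
            (160, "B15", 14): 1.03, (160, "B40", 14): 1.05,
        },
        "ccar": {
            (160, "B40", 1): 1.15, (160, "B40", 7): 1.07,
            (240, "B40", 1): 1.15,
            (240, "B15", 7): 1.06, (240, "B40", 7): 1.08,
            (240, "B15", 14): 1.12, (240, "B40", 14): 1.14,
            (160, "B15", 14): 0.96, (160, "B40", 14): 0.97,
        },
        "canth": {
            (160, "B40", 1): 1.15, (160, "B40", 7): 1.35, (160, "B40", 14): 1.50,
            (240, "B40", 1): 1.08, (240, "B40", 7): 1.14, (240, "B40", 14): 1.19,
            (240, "B15", 7): 1.05, (240, "B15", 14): 1.10,
        },
        "cx": {
            (160, "B40", 1): 0.88, (160, "B40", 7): 0.85, (160, "B40", 14): 0.82,
            (240, "B40", 1): 1.15, (240, "B40", 7): 1.25, (240, "B40", 14): 1.35,
        },
    }


@dataclass
class SyntheticDesign:
    """Factorial design plus effect calibration and noise model."""

    cultivars: tuple[str, ...] = ("green", "red")
    pfds: tuple[int, ...] = (160, 240)
    spectra: tuple[str, ...] = ("B15", "B40")
    days: tuple[int, ...] = (1, 7, 14)
    replicates: int = 3
    baselines: dict[str, LeafBiophysics] = field(default_factory=default_baselines)
    effects: dict[str, dict] = field(default_factory=default_effects)
    # replicate scatter (lognormal sd): a common leaf-size factor on all
    # pigments, a small independent factor on cab that perturbs the
    # chl/car ratio, and structural scatter
    common_sd: float = 0.08
    ratio_sd: float = 0.02
    cx_sd: float = 0.03
    n_sd: float = 0.04
    cwcm_sd: float = 0.05
    # truth ratios span the interior of the laboratory-observed 4.4-6.4
    # band so that assay noise keeps *measured* ratios inside it
    ratio_truncation: tuple[float, float] = (4.8, 6.0)
    # measurement noise
    rt_noise_sd: float = 0.01          # multiplicative, on R and T
    absorbance_noise_sd: float = 0.005  # additive, per individual reading
    #: each stored absorbance is the mean of this many readings of the
    #: combined extract (the bench protocol reads in triplicates)
    reading_replicates: int = 3
    fluor_noise_sd: float = 0.02        # multiplicative, on trace levels
    max_clip_fraction: float = 0.05
    chl_a_fraction: float = 0.75
    extract_volume_ml: float = 2.3
    assay_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for cultivar, base in self.baselines.items():
            if not 4.4 < base.chl_car_ratio < 6.4:
                raise ConfigurationError(
                    f"baseline chl/car of {cultivar} outside (4.4, 6.4)"
                )
        for pigment, table in self.effects.items():
            for key, mult in table.items():
                if mult <= 0:
                    raise ConfigurationError(f"multiplier {pigment}{key} must be > 0")

    def cells(self):
        for cultivar in self.cultivars:
            for pfd in self.pfds:
                for spectrum in self.spectra:
                    for day in self.days:
                        yield (cultivar, pfd, spectrum, day)

    def multiplier(self, pigment: str, pfd: int, spectrum: str, day: int) -> float:
        return self.effects.get(pigment, {}).get((pfd, spectrum, day), 1.0)

    def lma(self, cultivar: str, pfd: int) -> float:
        """Treatment-level leaf mass per area (g cm^-2): baseline dry
        matter, slightly higher under the higher PFD."""
        return self.baselines[cultivar].cm * (1.05 if pfd == 240 else 1.0)


@dataclass
class SyntheticCohort:
    """One simulated measurement campaign with stored ground truth."""

    design: SyntheticDesign
    library: AbsorptionLibrary
    truth: pd.DataFrame
    spectra: list[MeasuredSpectrumRecord]
    assays: pd.DataFrame
    fluorescence: pd.DataFrame
    lma: pd.DataFrame
    clip_fraction: float

    def __len__(self) -> int:
        return len(self.spectra)


def generate_ratio_straddle_batch(
    n: int = 50,
    seed: int = 42,
    lib: AbsorptionLibrary | None = None,
    noise_sd: float = 0.01,
) -> tuple[list[MeasuredSpectrumRecord], list[LeafBiophysics]]:
    """Leaves whose true chl/car ratios straddle the admissible 4.4-6.4 band.

    True ratios are drawn uniformly in [3.5, 7.5], the other parameters
    over physiological ranges; spectra carry multiplicative noise of sd
    ``noise_sd``. Used to exercise the inversion's ratio-constraint
    behavior on both feasible and infeasible truths.
    """
    lib = lib or build_synthetic_library(seed)
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for i in range(n):
        rho = rng.uniform(3.5, 7.5)
        cab = rng.uniform(25.0, 55.0)
        p = LeafBiophysics(
            n=rng.uniform(1.2, 2.4), cab=cab, ccar=cab / rho,
            canth=rng.uniform(0.0, 6.0), cx=rng.uniform(0.1, 0.9),
            cbrown=0.0, cw=rng.uniform(0.005, 0.02),
            cm=rng.uniform(0.002, 0.008),
        )
        truths.append(p)
        r, t, _ = _noisy_spectrum(forward_model(p, lib), rng, noise_sd)
        records.append(
            MeasuredSpectrumRecord(
                sample_id=f"straddle-{i:02d}", side="averaged", grid=lib.grid,
                reflectance=r, transmittance=t,
                metadata={"true_ratio": rho},
            )
        )
    return records, truths


def _lognormal(rng: np.random.Generator, sd: float) -> float:
    """Unit-mean lognormal factor (exactly 1 when sd = 0)."""
    if sd == 0:
        return 1.0
    return float(rng.lognormal(-0.5 * sd * sd, sd))


def sample_biophysics(
    design: SyntheticDesign,
    cell: tuple[str, int, str, int],
    rng: np.random.Generator,
) -> LeafBiophysics:
    """Draw one leaf's true parameters for a treatment cell.

    baseline x cell multipliers x unit-mean lognormal replicate scatter,
    with anthocyanin forced to zero for the green cultivar, the drawn
    chl/car ratio truncated to the design's admissible interval, and cx
    clipped to [0, 1].
    """
    cultivar, pfd, spectrum, day = cell
    if cultivar not in design.baselines:
        raise ValueError(f"unknown cultivar {cultivar!r}")
    base = design.baselines[cultivar]
    size = _lognormal(rng, design.common_sd)  # common leaf-level factor
    cab = base.cab * design.multiplier("cab", pfd, spectrum, day) * size
    ccar = base.ccar * design.multiplier("ccar", pfd, spectrum, day) * size
    cab *= _lognormal(rng, design.ratio_sd)
    lo, hi = design.ratio_truncation
    ratio = cab / ccar
    if ratio < lo:
        cab = ccar * lo
    elif ratio > hi:
        cab = ccar * hi
    if cultivar == "green":
        canth = 0.0
    else:
        canth = (
            base.canth * design.multiplier("canth", pfd, spectrum, day)
            * _lognormal(rng, design.common_sd)
        )
    cx = base.cx * design.multiplier("cx", pfd, spectrum, day)
    if design.cx_sd > 0:
        cx += rng.normal(0.0, design.cx_sd)
    cx = float(np.clip(cx, 0.0, 1.0))
    n = max(1.0, base.n * _lognormal(rng, design.n_sd))
    cw = base.cw * _lognormal(rng, design.cwcm_sd)
    cm = design.lma(cultivar, pfd) * _lognormal(rng, design.cwcm_sd)
    return LeafBiophysics(
        n=n, cab=cab, ccar=ccar, canth=canth, cx=cx,
        cbrown=base.cbrown, cw=cw, cm=cm,
    )


def _noisy_spectrum(
    spec, rng: np.random.Generator, sd: float
) -> tuple[np.ndarray, np.ndarray, int]:
    r = spec.reflectance * (1.0 + sd * rng.standard_normal(spec.reflectance.size))
    t = spec.transmittance * (1.0 + sd * rng.standard_normal(spec.transmittance.size))
    r = np.clip(r, 0.0, 1.0)
    t = np.clip(t, 0.0, 1.0)
    s = r + t
    over = s > 1.0
    n_clipped = int(np.count_nonzero(over))
    if n_clipped:
        scale = np.where(over, s, 1.0)
        r = r / scale
        t = t / scale
    return r, t, n_clipped


def _assay_absorbances(
    ca: float, cb: float, ccar: float
) -> tuple[float, float, float]:
    """Invert the 95%-ethanol assay equations: concentrations -> absorbances."""
    co = SOLVENT_COEFFICIENTS["ethanol95"]
    # [ca, cb] = M @ [A664, A649] with M = [[13.36, -5.19], [-8.12, 27.43]]
    m11, m12 = co["ca"]
    m21, m22 = co["cb"]
    det = m11 * m22 - m12 * m21
    a664 = (m22 * ca - m12 * cb) / det
    a649 = (m11 * cb - m21 * ca) / det
    a470 = (co["car"][2] * ccar + co["car"][0] * ca + co["car"][1] * cb) / 1000.0
    return a470, a649, a664


def _fluor_targets(
    cultivar: str, pfd: int, spectrum: str, day: int
) -> tuple[float, float, float]:
    """(QY, Rfd, qE) targets: Rfd and qE rise with day, blue fraction and PFD;
    the green cultivar at the lower PFD barely responds to blue."""
    qy = 0.55
    rfd = {1: 1.45, 7: 2.0, 14: 2.6}[day]
    qe = {1: 0.12, 7: 0.20, 14: 0.27}[day]
    if spectrum == "B40" and day >= 7:
        muted = cultivar == "green" and pfd == 160
        rfd += 0.05 if muted else 0.35
        qe += 0.01 if muted else 0.06
    if pfd == 240 and day >= 7:
        rfd += 0.15 + (0.10 if day == 14 else 0.0)
    return qy, rfd, qe


def generate_cohort(
    design: SyntheticDesign | None = None,
    lib: AbsorptionLibrary | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Simulate one full campaign; bit-identical for identical seed/config."""
    design = design or SyntheticDesign()
    seed = design.seed if seed is None else seed
    lib = lib or build_synthetic_library(seed)
    rng = np.random.default_rng(seed)

    truth_rows, spectra, assay_rows, fluor_rows = [], [], [], []
    n_clipped = 0
    n_channels = 0
    for cell in design.cells():
        cultivar, pfd, spectrum, day = cell
        for rep in range(1, design.replicates + 1):
            sid = f"{cultivar}-{pfd}{spectrum}-d{day}-r{rep}"
            p = sample_biophysics(design, cell, rng)
            meta = {
                "cultivar": cultivar, "pfd": pfd, "spectrum": spectrum,
                "day": day, "replicate": rep,
            }
            truth_rows.append(
                {"sample_id": sid, **meta, **p.as_dict(),
                 "chl_car_ratio": p.chl_car_ratio,
                 "lma": design.lma(cultivar, pfd)}
            )
            clean = forward_model(p, lib)
            r, t, nc = _noisy_spectrum(clean, rng, design.rt_noise_sd)
            n_clipped += nc
            n_channels += r.size
            spectra.append(
                MeasuredSpectrumRecord(
                    sample_id=sid, side="averaged", grid=lib.grid,
                    reflectance=r, transmittance=t, metadata=dict(meta),
                )
            )
            # assay: true mass-based contents (per-leaf dry matter), then
            # absorbances through the inverted linear system plus noise
            chl_mgg = p.cab / p.cm / 1000.0
            car_mgg = p.ccar / p.cm / 1000.0
            for arep in range(1, design.assay_replicates + 1):
                mass = rng.uniform(1.6, 2.8)
                vol = design.extract_volume_ml
                ca = design.chl_a_fraction * chl_mgg * mass / vol
                cb = (1.0 - design.chl_a_fraction) * chl_mgg * mass / vol
                ccar = car_mgg * mass / vol
                a470, a649, a664 = _assay_absorbances(ca, cb, ccar)
                # stored absorbance = mean over the reading triplicate
                noise = rng.normal(
                    0.0, design.absorbance_noise_sd,
                    size=(design.reading_replicates, 3),
                ).mean(axis=0)
                assay_rows.append(
                    {"sample_id": sid, "replicate": arep,
                     "A470": max(a470 + noise[0], 0.0),
                     "A649": max(a649 + noise[1], 0.0),
                     "A664": max(a664 + noise[2], 0.0),
                     "extract_volume_ml": vol, "dry_mass_mg": mass,
                     **meta}
                )
            qy, rfd, qe = _fluor_targets(cultivar, pfd, spectrum, day)
            f_t = 500.0
            levels = np.array(
                [f_t / (1.0 - qy), f_t, f_t * (1.0 + rfd), (f_t / (1.0 - qy)) / (1.0 - qe)]
            )
            levels = levels * (
                1.0 + design.fluor_noise_sd * rng.standard_normal(4)
            )
            fluor_rows.append(
                {"sample_id": sid, "f_m_lss": levels[0], "f_t_lss": levels[1],
                 "f_p": levels[2], "f_m_d3": levels[3], **meta}
            )

    clip_fraction = n_clipped / n_channels if n_channels else 0.0
    if clip_fraction > design.max_clip_fraction:
        raise ConfigurationError(
            f"noise clipping rate {clip_fraction:.1%} exceeds "
            f"{design.max_clip_fraction:.0%}: noise model infeasible"
        )
    lma_rows = [
        {"cultivar": c, "pfd": f, "lma_g_cm2": design.lma(c, f)}
        for c in design.cultivars
        for f in design.pfds
    ]
    return SyntheticCohort(
        design=design,
        library=lib,
        truth=pd.DataFrame(truth_rows),
        spectra=spectra,
        assays=pd.DataFrame(assay_rows),
        fluorescence=pd.DataFrame(fluor_rows),
        lma=pd.DataFrame(lma_rows),
        clip_fraction=clip_fraction,
    )
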