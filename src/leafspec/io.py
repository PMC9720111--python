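"""Reading and writing spectra, coefficient libraries, assay and trace tables.

Spectral files are plain CSV. The combined dialect has a header
``wavelength_nm,reflectance,transmittance``; the two-column instrument
dialect is one file per quantity with wavelength in the first column
and the value in the second (header optional). Reflectance is assumed
already calibrated against the white reflective standard; no
calibration model is applied here.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fluorescence import FluorTrace
from .radiative_transfer import AbsorptionLibrary
from .types import (
    GridMismatchError,
    MeasuredSpectrumRecord,
    SpectralGrid,
)
from .wet_chemistry import AssayRecord

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "resample_record",
    "average_sides",
    "read_library",
    "write_library",
    "read_assays",
    "read_fluorescence",
    "ExperimentDesign",
    "DesignReport",
    "validate_design",
    "DEFAULT_STUDY_DESIGN",
]

LIBRARY_COLUMNS = [
    "wavelength_nm", "n_refr", "K_ab", "K_car_V", "K_car_Z",
    "K_anth", "K_brown", "K_w", "K_m",
]


def _read_two_column(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, value)")
    df = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    df = df.dropna()  # drops a header row, if any
    if df.empty:
        raise ValueError(f"{path}: no numeric rows")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def read_spectrum(
    path,
    dialect: str = "combined",
    transmittance_path=None,
    sample_id: str | None = None,
    side: str = "averaged",
    metadata: dict | None = None,
) -> MeasuredSpectrumRecord:
    """Read one measured spectrum.

    ``dialect="combined"``: one 3-column CSV with header
    ``wavelength_nm,reflectance,transmittance``. ``dialect="two-column"``:
    ``path`` is the reflectance file and ``transmittance_path`` the
    transmittance file, each wavelength/value. Non-monotone wavelengths,
    missing columns, values outside [0, 1] and R+T > 1 beyond the
    calibration tolerance are rejected (the record constructor raises
    :class:`~leafspec.types.CalibrationError` for the latter).
    """
    path = Path(path)
    file_meta: dict = {}
    if dialect == "combined":
        file_meta = _read_comment_metadata(path)
        df = pd.read_csv(path, comment="#")
        missing = {"wavelength_nm", "reflectance", "transmittance"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        wl = df["wavelength_nm"].to_numpy(float)
        r = df["reflectance"].to_numpy(float)
        t = df["transmittance"].to_numpy(float)
    elif dialect == "two-column":
        if transmittance_path is None:
            raise ValueError("two-column dialect needs a transmittance file")
        wl, r = _read_two_column(path)
        wl_t, t = _read_two_column(transmittance_path)
        if not np.array_equal(wl, wl_t):
            raise GridMismatchError("R and T files have different wavelength grids")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return MeasuredSpectrumRecord(
        sample_id=sample_id or file_meta.pop("sample_id", path.stem),
        side=side if side != "averaged" else file_meta.pop("side", "averaged"),
        grid=SpectralGrid(wl),
        reflectance=r,
        transmittance=t,
        metadata={**file_meta, **(metadata or {})},
    )


def _read_comment_metadata(path) -> dict:
    """Parse leading ``# key=value`` comment lines into a metadata dict."""
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            value = value.strip()
            try:
                parsed: object = int(value)
            except ValueError:
                try:
                    parsed = float(value)
                except ValueError:
                    parsed = value
            meta[key.strip()] = parsed
    return meta


def write_spectrum(record: MeasuredSpectrumRecord, path) -> None:
    """Write a record in the combined CSV dialect (8 significant digits).

    Sample identity, side and metadata are preserved as ``# key=value``
    comment lines ahead of the header.
    """
    with open(path, "w") as fh:
        fh.write(f"# sample_id={record.sample_id}\n# side={record.side}\n")
        for key, value in record.metadata.items():
            fh.write(f"# {key}={value}\n")
        pd.DataFrame(
            {
                "wavelength_nm": record.grid.wavelengths,
                "reflectance": record.reflectance,
                "transmittance": record.transmittance,
            }
        ).to_csv(fh, index=False, float_format="%.8g")


def resample_record(
    record: MeasuredSpectrumRecord, grid: SpectralGrid
) -> MeasuredSpectrumRecord:
    """Linear interpolation onto a target grid (exact on shared nodes).

    The target must lie inside the acquired range; spacing above 5 nm is
    rejected to protect the fit against undersampled absorption bands.
    """
    wl = grid.wavelengths
    if not record.grid.covers(wl[0], wl[-1]):
        raise ValueError("target grid extends beyond the acquired range")
    if np.max(np.diff(wl)) > 5.0 + 1e-9:
        raise ValueError("resampled spacing must be <= 5 nm")
    return MeasuredSpectrumRecord(
        sample_id=record.sample_id,
        side=record.side,
        grid=grid,
        reflectance=np.interp(wl, record.grid.wavelengths, record.reflectance),
        transmittance=np.interp(wl, record.grid.wavelengths, record.transmittance),
        metadata=dict(record.metadata),
    )


def average_sides(
    left: MeasuredSpectrumRecord, right: MeasuredSpectrumRecord
) -> MeasuredSpectrumRecord:
    """Arithmetic mean of the two midrib-side measurements of one leaf."""
    if left.grid != right.grid:
        raise GridMismatchError("cannot average records on different grids")
    if left.sample_id != right.sample_id:
        raise ValueError("cannot average records of different samples")
    return MeasuredSpectrumRecord(
        sample_id=left.sample_id,
        side="averaged",
        grid=left.grid,
        reflectance=(left.reflectance + right.reflectance) / 2.0,
        transmittance=(left.transmittance + right.transmittance) / 2.0,
        metadata={**right.metadata, **left.metadata},
    )


def read_library(path) -> AbsorptionLibrary:
    df = pd.read_csv(path, comment="#")
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return AbsorptionLibrary(
        grid=SpectralGrid(df["wavelength_nm"].to_numpy(float)),
        n_refr=df["n_refr"].to_numpy(float),
        k_ab=df["K_ab"].to_numpy(float),
        k_car_v=df["K_car_V"].to_numpy(float),
        k_car_z=df["K_car_Z"].to_numpy(float),
        k_anth=df["K_anth"].to_numpy(float),
        k_brown=df["K_brown"].to_numpy(float),
        k_w=df["K_w"].to_numpy(float),
        k_m=df["K_m"].to_numpy(float),
    )


def write_library(lib: AbsorptionLibrary, path) -> None:
    pd.DataFrame(
        dict(
            zip(
                LIBRARY_COLUMNS,
                [lib.grid.wavelengths, lib.n_refr, lib.k_ab, lib.k_car_v,
                 lib.k_car_z, lib.k_anth, lib.k_brown, lib.k_w, lib.k_m],
            )
        )
    ).to_csv(path, index=False, float_format="%.8g")


def read_assays(path) -> list[AssayRecord]:
    """Read an assay CSV: sample_id,replicate,A470,A649,A664,extract_volume_ml,dry_mass_mg."""
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "A470", "A649", "A664"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            AssayRecord(
                sample_id=str(row["sample_id"]),
                a470=float(row["A470"]),
                a649=float(row["A649"]),
                a664=float(row["A664"]),
                extract_volume_ml=float(row.get("extract_volume_ml", 2.3)),
                dry_mass_mg=float(row.get("dry_mass_mg", 2.0)),
                replicate_id=int(row.get("replicate", 1)),
            )
        )
    return records


def read_fluorescence(path) -> list[FluorTrace]:
    """Read a fluorescence CSV: sample_id,f_m_lss,f_t_lss,f_p,f_m_d3."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    required = ["sample_id", "f_m_lss", "f_t_lss", "f_p", "f_m_d3"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        FluorTrace(
            sample_id=str(row[cols["sample_id"]]),
            f_m_lss=float(row[cols["f_m_lss"]]),
            f_t_lss=float(row[cols["f_t_lss"]]),
            f_p=float(row[cols["f_p"]]),
            f_m_d3=float(row[cols["f_m_d3"]]),
        )
        for _, row in df.iterrows()
    ]


# --------------------------------------------------------------------------
# experiment design


@dataclass
class ExperimentDesign:
    """Factorial design of the growth experiment.

    ``spectra`` maps a spectrum label to its waveband percentages
    (keys ``blue``, ``green``, ``red``, ``far_red``) plus, optionally,
    the nominal white total (``white_label_total``) and its
    green:red:far-red breakdown (``white_bracket``) as printed on a
    treatment-code table.
    """

    growing_area_m2: float = 0.27
    plants_per_area: int = 12
    cultivars: tuple[str, ...] = ("green", "red")
    pfd_levels: tuple[int, ...] = (160, 240)
    spectra: dict = field(default_factory=dict)
    days: tuple[int, ...] = (1, 7, 14)

    @property
    def plant_density(self) -> float:
        """Plants per m^2."""
        return self.plants_per_area / self.growing_area_m2


@dataclass
class DesignReport:
    plant_density: float
    band_totals: dict
    flags: tuple[str, ...]

    def as_text(self) -> str:
        lines = [f"plant density: {self.plant_density:.1f} plants m^-2"]
        for label, total in self.band_totals.items():
            lines.append(f"{label}: waveband total {total:g}%")
        for flag in self.flags:
            lines.append(f"FLAG: {flag}")
        return "\n".join(lines)


def validate_design(design: ExperimentDesign) -> DesignReport:
    """Report plant density and per-spectrum band sums; flag inconsistencies.

    Flags (never raises): waveband percentages not summing to 100, and a
    nominal white total that disagrees with the sum of its bracketed
    green:red:far-red components.
    """
    flags: list[str] = []
    band_totals: dict[str, float] = {}
    for label, bands in design.spectra.items():
        total = sum(
            bands.get(k, 0.0) for k in ("blue", "green", "red", "far_red")
        )
        band_totals[label] = total
        if abs(total - 100.0) > 1e-9:
            flags.append(f"{label}: waveband percentages sum to {total:g}, not 100")
        if "white_label_total" in bands and "white_bracket" in bands:
            bracket_sum = sum(bands["white_bracket"])
            if abs(bracket_sum - bands["white_label_total"]) > 1e-9:
                flags.append(
                    f"{label}: white total {bands['white_label_total']:g} "
                    f"inconsistent with bracket sum {bracket_sum:g}"
                )
    return DesignReport(
        plant_density=design.plant_density,
        band_totals=band_totals,
        flags=tuple(flags),
    )


#: The study layout: 0.27 m^2 growing areas with 12 plants each, two
#: PFDs, and the two spectra as printed on the treatment-code table
#: (the B15 white total is nominally 75 although its bracketed
#: components sum to 85 — validate_design flags this).
DEFAULT_STUDY_DESIGN = ExperimentDesign(
    spectra={
        "B15": {
            "blue": 15, "green": 40, "red": 29, "far_red": 16,
            "white_label_total": 75, "white_bracket": (40, 29, 16),
        },
        "B40": {
            "blue": 40, "green": 35, "red": 16, "far_red": 9,
            "white_label_total": 60, "white_bracket": (35, 16, 9),
        },
    }
)
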