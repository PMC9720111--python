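"""Downstream study computations.

Covers the unit bridge between optically estimated (area-based) and
assay-measured (mass-based) pigment contents, grouped Pearson
correlation of the two, pigment-ratio time series by treatment cell,
and pooled-PFD growth-effect percentages from a treatment-mean table.
Only descriptive summaries are computed here; inferential statistics
are intentionally out of scope.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "area_to_mass",
    "mass_to_area",
    "grouped_correlation",
    "pigment_ratio_series",
    "pfd_effect_summary",
]


def area_to_mass(content_area, lma):
    """Convert ug cm^-2 to mg per g dry weight via leaf mass per area.

    ``content_area / lma`` is ug per g; dividing by 1000 gives mg/g.
    LMA is typically known at the treatment level only.
    """
    lma = np.asarray(lma, dtype=float)
    if np.any(lma <= 0):
        raise ValueError("leaf mass per area must be positive")
    return np.asarray(content_area, dtype=float) / lma / 1000.0


def mass_to_area(content_mass, lma):
    """Inverse of :func:`area_to_mass` (mg g^-1 to ug cm^-2)."""
    lma = np.asarray(lma, dtype=float)
    if np.any(lma <= 0):
        raise ValueError("leaf mass per area must be positive")
    return np.asarray(content_mass, dtype=float) * lma * 1000.0


def _pearson_with_line(x: np.ndarray, y: np.ndarray) -> dict:
    n = x.size
    row = {"n": int(n), "r": np.nan, "slope": np.nan, "intercept": np.nan, "flag": ""}
    if n < 3:
        row["flag"] = "fewer than 3 pairs"
        return row
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        row["flag"] = "constant vector: r undefined"
        return row
    res = stats.linregress(x, y)
    row.update(r=res.rvalue, slope=res.slope, intercept=res.intercept)
    return row


def grouped_correlation(
    modelled: pd.DataFrame,
    measured: pd.DataFrame,
    value: str,
    group_by: str | None = None,
    on: str = "sample_id",
) -> pd.DataFrame:
    """Pearson r (plus regression line) between modelled and measured values.

    Both tables must carry ``on`` and ``value`` columns; grouping
    factors are taken from the modelled table. Returns one row per
    group level plus an ``overall`` row pooling all pairs; groups with
    a constant vector or fewer than 3 pairs are flagged with r = NaN.
    """
    merged = modelled.merge(
        measured[[on, value]], on=on, suffixes=("_modelled", "_measured")
    )
    if merged.empty:
        raise ValueError("no sample_id overlap between modelled and measured tables")
    x = merged[f"{value}_modelled"].to_numpy(float)
    y = merged[f"{value}_measured"].to_numpy(float)
    rows = [{"group": "overall", **_pearson_with_line(x, y)}]
    if group_by is not None:
        for level, sub in merged.groupby(group_by, sort=True):
            rows.append(
                {
                    "group": f"{group_by}={level}",
                    **_pearson_with_line(
                        sub[f"{value}_modelled"].to_numpy(float),
                        sub[f"{value}_measured"].to_numpy(float),
                    ),
                }
            )
    return pd.DataFrame(rows)


def pigment_ratio_series(
    estimates: pd.DataFrame,
    numerator: str,
    denominator: str,
    group_by: list[str],
) -> pd.DataFrame:
    """Group mean/sd/n of a per-sample pigment ratio (e.g. ANT/CHL) over cells.

    Samples with a zero denominator get a NaN ratio and are counted in
    the ``n_undefined`` column of their group.
    """
    df = estimates.copy()
    den = df[denominator].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, df[numerator].to_numpy(float) / den, np.nan)
    df["_ratio"] = ratio
    out = (
        df.groupby(group_by, sort=True)["_ratio"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    undef = (
        df.assign(_undef=np.isnan(ratio))
        .groupby(group_by, sort=True)["_undef"]
        .sum()
        .reset_index(name="n_undefined")
    )
    return out.merge(undef, on=group_by)


def pfd_effect_summary(
    treatment_means: pd.DataFrame,
    traits: list[str] | None = None,
    pfd_col: str = "pfd",
    cultivar_col: str = "cultivar",
) -> pd.DataFrame:
    """Percent change of pooled treatment means between the two PFD levels.

    Within each PFD the two spectral treatments are pooled by the
    arithmetic mean of their treatment means; the effect is reported as
    ``100 * (pooled_high - pooled_low) / pooled_high`` rounded to the
    nearest integer percent — i.e. the change is expressed relative to
    the higher-PFD pooled mean, the convention that reproduces the
    study-style growth percentages from a treatment-mean table.
    """
    pfds = sorted(treatment_means[pfd_col].unique())
    if len(pfds) != 2:
        raise ValueError("exactly two PFD levels required")
    lo_pfd, hi_pfd = pfds
    if traits is None:
        traits = [
            c
            for c in treatment_means.columns
            if c not in (pfd_col, cultivar_col, "spectrum")
            and np.issubdtype(treatment_means[c].dtype, np.number)
        ]
    n_spectra = (
        treatment_means["spectrum"].nunique()
        if "spectrum" in treatment_means.columns
        else 1
    )
    rows = []
    for cultivar, sub in treatment_means.groupby(cultivar_col, sort=True):
        for trait in traits:
            cell_lo = sub.loc[sub[pfd_col] == lo_pfd, trait]
            cell_hi = sub.loc[sub[pfd_col] == hi_pfd, trait]
            if (
                len(cell_lo) != n_spectra
                or len(cell_hi) != n_spectra
                or cell_lo.isna().any()
                or cell_hi.isna().any()
            ):
                raise ValueError(
                    f"missing treatment cell for {cultivar}/{trait}"
                )
            pooled_lo = float(cell_lo.mean())
            pooled_hi = float(cell_hi.mean())
            pct = 100.0 * (pooled_hi - pooled_lo) / pooled_hi
            rows.append(
                {
                    cultivar_col: cultivar,
                    "trait": trait,
                    f"pooled_{lo_pfd}": pooled_lo,
                    f"pooled_{hi_pfd}": pooled_hi,
                    "percent_change": int(round(pct)),
                }
            )
    return pd.DataFrame(rows)
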