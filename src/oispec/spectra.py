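"""Hemoglobin absorption spectra and tissue optical properties.

The imaging system illuminates the cortex at four wavelengths (495, 559,
575 and 587 nm by default) and the spectroscopic inversion needs the molar
extinction of oxy- and deoxy-hemoglobin at each of them.  This module
houses the extinction table, interpolation, and the conversion from a
tissue baseline state (total hemoglobin and oxygen saturation) to an
absorption coefficient usable by photon transport.

Conventions
-----------
Tabulated extinction is decadic (base-10), units cm^-1 M^-1.  The
absorption coefficient handed to Monte-Carlo transport is natural-log
(mu_a = ln(10) * sum eps_i * c_i), units cm^-1, concentrations in mol/L.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default imaging wavelengths (nm).
IMAGING_WAVELENGTHS_NM: tuple[float, ...] = (495.0, 559.0, 575.0, 587.0)

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class ExtinctionTable:
    """Wavelength-indexed molar extinction of HbO2 and Hb.

    Parameters
    ----------
    wavelength_nm
        Strictly increasing wavelengths, nm.
    eps_hbo, eps_hbr
        Molar extinction of oxy-/deoxy-hemoglobin, cm^-1 M^-1.
    log_base10
        True if the tabulated values are decadic extinction coefficients
        (the usual convention); the absorption coefficient then carries
        an ln(10) factor.
    source
        Free-text provenance of the table.
    """

    wavelength_nm: np.ndarray
    eps_hbo: np.ndarray
    eps_hbr: np.ndarray
    log_base10: bool = True
    source: str = "unknown"

    def __post_init__(self):
        w = np.asarray(self.wavelength_nm, dtype=float)
        o = np.asarray(self.eps_hbo, dtype=float)
        r = np.asarray(self.eps_hbr, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValidationError("extinction table needs >= 2 wavelength rows")
        if not (w.shape == o.shape == r.shape):
            raise ValidationError("extinction table columns have mismatched lengths")
        if np.any(w <= 0):
            raise ValidationError("wavelengths must be positive")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(o <= 0) or np.any(r <= 0):
            raise ValidationError("extinction values must be positive")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "eps_hbo", o)
        object.__setattr__(self, "eps_hbr", r)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def covers(self, wavelength_nm: float) -> bool:
        lo, hi = self.range_nm
        return lo <= wavelength_nm <= hi


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous-tissue optical parameters for photon transport.

    mu_a : absorption coefficient, cm^-1 (natural log)
    mu_s : scattering coefficient, cm^-1
    g    : scattering anisotropy (Henyey-Greenstein), -1 < g < 1
    n    : refractive index
    """

    mu_a: float
    mu_s: float
    g: float = 0.9
    n: float = 1.4

    def __post_init__(self):
        if self.mu_a < 0:
            raise ValidationError("mu_a must be >= 0")
        if self.mu_s <= 0:
            raise ValidationError("mu_s must be > 0")
        if not (-1.0 < self.g < 1.0):
            raise ValidationError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValidationError("refractive index must be >= 1")


@dataclass(frozen=True)
class BaselineState:
    """Assumed tissue baseline: total hemoglobin and oxygen saturation.

    Under 100% oxygen the pipeline assumes 100 uM total hemoglobin at 70%
    saturation; the air baseline is re-estimated from the gas-transition
    record per animal.
    """

    hbt_uM: float
    so2: float
    condition: str = "oxygen"

    def __post_init__(self):
        if self.hbt_uM < 0:
            raise ValidationError("hbt_uM must be >= 0")
        if not (0.0 <= self.so2 <= 1.0):
            raise ValidationError("so2 must lie in [0, 1]")

    @property
    def hbo_uM(self) -> float:
        return self.so2 * self.hbt_uM

    @property
    def hbr_uM(self) -> float:
        # complement, so hbo + hbr == hbt exactly up to float rounding
        return (1.0 - self.so2) * self.hbt_uM


#: The paper-convention oxygen baseline: 100 uM Hbt at 70% saturation.
DEFAULT_OXYGEN_BASELINE = BaselineState(100.0, 0.70, "oxygen")


def load_extinction_table(source=None) -> ExtinctionTable:
    """Load an extinction table from a TSV file (or the bundled default).

    The file must be tab-separated with a ``wavelength_nm  eps_hbo
    eps_hbr`` header, ``#`` comments allowed, and must cover 450-650 nm
    including all four imaging wavelengths.

    Parameters
    ----------
    source
        Path to a TSV file, or None for the bundled synthetic spectra.
    """
    if source is None:
        ref = importlib.resources.files("oispec.data") / "hb_extinction_synthetic.tsv"
        with importlib.resources.as_file(ref) as p:
            return load_extinction_table(p)
    try:
        df = pd.read_csv(source, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError) as e:
        raise ValidationError(f"cannot read extinction table {source!r}: {e}") from e
    required = {"wavelength_nm", "eps_hbo", "eps_hbr"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"extinction table missing columns: {sorted(missing)}"
        )
    table = ExtinctionTable(
        wavelength_nm=df["wavelength_nm"].to_numpy(float),
        eps_hbo=df["eps_hbo"].to_numpy(float),
        eps_hbr=df["eps_hbr"].to_numpy(float),
        source=str(source),
    )
    for w in IMAGING_WAVELENGTHS_NM:
        if not table.covers(w):
            raise ValidationError(
                f"extinction table does not cover imaging wavelength {w:g} nm "
                f"(table range {table.range_nm[0]:g}-{table.range_nm[1]:g} nm)"
            )
    return table


def extinction_at(table: ExtinctionTable, wavelength_nm: float) -> tuple[float, float]:
    """Linearly interpolated (eps_hbo, eps_hbr) at a wavelength.

    Exact at tabulated rows; raises outside the tabulated range.
    """
    lo, hi = table.range_nm
    if not (lo <= wavelength_nm <= hi):
        raise ValidationError(
            f"wavelength {wavelength_nm:g} nm outside table range [{lo:g}, {hi:g}]"
        )
    o = float(np.interp(wavelength_nm, table.wavelength_nm, table.eps_hbo))
    r = float(np.interp(wavelength_nm, table.wavelength_nm, table.eps_hbr))
    return o, r


def absorption_coefficient(
    state: BaselineState, wavelength_nm: float, table: ExtinctionTable
) -> float:
    """Natural-log absorption coefficient mu_a (cm^-1) of a tissue state.

    mu_a = ln(10) * (eps_hbo * c_hbo + eps_hbr * c_hbr) for a decadic
    table, concentrations in mol/L.  Linear in hbt_uM at fixed so2.
    """
    eps_o, eps_r = extinction_at(table, wavelength_nm)
    c_hbo = state.hbo_uM * 1e-6
    c_hbr = state.hbr_uM * 1e-6
    mu = eps_o * c_hbo + eps_r * c_hbr
    if table.log_base10:
        mu *= LN10
    return float(mu)
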