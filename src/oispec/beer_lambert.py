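"""Modified Beer-Lambert inversion: attenuation movies to hemoglobin movies.

For each wavelength the attenuation change relative to a baseline window,
``dA(lambda, t, p) = -ln(I / I0_bar)``, is modelled as

    dA(lambda) = ln(10) * [eps_hbo(lambda) dC_hbo + eps_hbr(lambda) dC_hbr] * L(lambda)

with L(lambda) the Monte-Carlo mean photon path length.  With four
wavelengths and two unknowns the system is overdetermined and solved
pixel-by-pixel by ordinary (unweighted) least squares.  Concentration
changes may be negative (Hbr washout is the signal); nothing is clipped.

Total hemoglobin is defined as dHbt = dHbo + dHbr element-wise, and
fractional movies are 1 + dC/C_baseline relative to the assumed baseline
state.  Dead pixels (non-positive intensity inside the analysis region)
are excluded, propagated as NaN, and counted — never interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .montecarlo import PathLengthTable
from .spectra import LN10, BaselineState, ExtinctionTable, extinction_at

log = logging.getLogger(__name__)

#: Condition-number guard for the 4x2 spectral design matrix.
MAX_DESIGN_CONDITION = 1e8


@dataclass(frozen=True)
class AttenuationStack:
    """Per-wavelength attenuation-change movies.

    values : array (n_wavelengths, n_frames, ny, nx), natural-log dA.
    dead_mask : boolean (ny, nx), True where the pixel is unusable.
    """

    values: np.ndarray
    wavelengths_nm: tuple[float, ...]
    frame_rate_hz: float
    dead_mask: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4:
            raise ValidationError("attenuation stack must be (wavelength, t, y, x)")
        if v.shape[0] != len(self.wavelengths_nm):
            raise ValidationError("wavelength axis does not match wavelength list")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConcentrationMovies:
    """Hemoglobin concentration-change movies plus fractional versions.

    d_hbo/d_hbr/d_hbt : (n_frames, ny, nx) in uM; d_hbt == d_hbo + d_hbr
    exactly.  fractional_x = 1 + d_x / baseline_x (unitless).
    """

    d_hbo: np.ndarray
    d_hbr: np.ndarray
    d_hbt: np.ndarray
    fractional_hbo: np.ndarray
    fractional_hbr: np.ndarray
    fractional_hbt: np.ndarray
    baseline: BaselineState
    frame_rate_hz: float
    dead_mask: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.d_hbt.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def compute_attenuation(
    intensities: np.ndarray,
    baseline_window: tuple[int, int],
    wavelengths_nm: tuple[float, ...],
    frame_rate_hz: float,
) -> AttenuationStack:
    """Attenuation change relative to the baseline-window mean intensity.

    Parameters
    ----------
    intensities
        Dark-corrected counts, shape (n_wavelengths, n_frames, ny, nx).
    baseline_window
        Half-open frame interval [i0, i1) averaged to give I0 per pixel
        per wavelength.

    Pixels with non-positive intensity at any frame/wavelength are
    flagged dead (NaN everywhere) and counted in the log.
    """
    inten = np.asarray(intensities, dtype=float)
    if inten.ndim != 4:
        raise ValidationError("intensities must be (wavelength, t, y, x)")
    i0, i1 = baseline_window
    if not (0 <= i0 < i1 <= inten.shape[1]):
        raise ValidationError(
            f"baseline window [{i0}, {i1}) outside record of {inten.shape[1]} frames"
        )
    dead = np.any(inten <= 0.0, axis=(0, 1))
    n_dead = int(dead.sum())
    if n_dead:
        log.info("compute_attenuation: %d dead pixel(s) excluded", n_dead)
    ref = inten[:, i0:i1].mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        da = -np.log(inten / ref)
    da[:, :, dead] = np.nan
    return AttenuationStack(
        values=da,
        wavelengths_nm=tuple(float(w) for w in wavelengths_nm),
        frame_rate_hz=float(frame_rate_hz),
        dead_mask=dead,
    )


def design_matrix(
    table: ExtinctionTable, paths: PathLengthTable
) -> tuple[np.ndarray, tuple[float, ...]]:
    """Spectral design matrix M (n_wavelengths x 2) in dA-per-uM units.

    M[i] = ln(10) * [eps_hbo(l_i), eps_hbr(l_i)] * L(l_i) * 1e-6, so that
    dA = M @ (dC_hbo_uM, dC_hbr_uM).
    """
    wl = paths.wavelengths_nm
    rows = []
    for w in wl:
        eps_o, eps_r = extinction_at(table, w)
        L = paths.path_cm(w)
        scale = (LN10 if table.log_base10 else 1.0) * L * 1e-6
        rows.append([eps_o * scale, eps_r * scale])
    M = np.asarray(rows, dtype=float)
    if np.linalg.matrix_rank(M) < 2 or np.linalg.cond(M) > MAX_DESIGN_CONDITION:
        raise ConfigurationError(
            f"spectral design matrix is (near-)collinear at wavelengths {wl}; "
            "HbO2 and Hb cannot be separated"
        )
    return M, wl


def unmix_pixel(
    dA: np.ndarray, table: ExtinctionTable, paths: PathLengthTable
) -> tuple[float, float]:
    """Least-squares (dHbo_uM, dHbr_uM) for one pixel's dA vector."""
    dA = np.asarray(dA, dtype=float)
    M, wl = design_matrix(table, paths)
    if dA.shape != (M.shape[0],):
        raise ValidationError(
            f"expected {M.shape[0]} attenuation values, got shape {dA.shape}"
        )
    sol, *_ = np.linalg.lstsq(M, dA, rcond=None)
    return float(sol[0]), float(sol[1])


def unmix_stack(
    att: AttenuationStack,
    table: ExtinctionTable,
    paths: PathLengthTable,
    baseline: BaselineState,
) -> ConcentrationMovies:
    """Unmix a whole attenuation stack into concentration movies.

    Applies the per-pixel least-squares solve to every (frame, pixel) via
    the pseudoinverse of the shared design matrix.  Dead pixels stay NaN.
    """
    if baseline.hbt_uM <= 0 or not (0.0 < baseline.so2 < 1.0):
        raise ValidationError(
            "fractional movies need a baseline with hbt > 0 and 0 < so2 < 1"
        )
    if tuple(att.wavelengths_nm) != tuple(paths.wavelengths_nm):
        raise ConfigurationError(
            f"attenuation wavelengths {att.wavelengths_nm} do not match "
            f"path-length table {paths.wavelengths_nm}"
        )
    M, _ = design_matrix(table, paths)
    pinv = np.linalg.pinv(M)  # (2, n_wavelengths)
    W, T, ny, nx = att.values.shape
    flat = att.values.reshape(W, -1)
    sol = pinv @ flat  # (2, T*ny*nx)
    d_hbo = sol[0].reshape(T, ny, nx)
    d_hbr = sol[1].reshape(T, ny, nx)
    d_hbt = d_hbo + d_hbr
    return ConcentrationMovies(
        d_hbo=d_hbo,
        d_hbr=d_hbr,
        d_hbt=d_hbt,
        fractional_hbo=1.0 + d_hbo / baseline.hbo_uM,
        fractional_hbr=1.0 + d_hbr / baseline.hbr_uM,
        fractional_hbt=1.0 + d_hbt / baseline.hbt_uM,
        baseline=baseline,
        frame_rate_hz=att.frame_rate_hz,
        dead_mask=att.dead_mask,
    )


def estimate_air_baseline(
    transition_movies: ConcentrationMovies,
    oxygen_baseline: BaselineState,
    settle_window_s: tuple[float, float],
    roi_mask: np.ndarray | None = None,
) -> BaselineState:
    """Air-breathing baseline from the oxygen-to-air transition record.

    The post-switch settle window is averaged on the ROI-mean
    concentration-change series; the air totals are the oxygen baseline
    plus those mean shifts:

        hbt_air = hbt_O2 + <dHbt>,  so2_air = (hbo_O2 + <dHbo>) / hbt_air

    Parameters
    ----------
    settle_window_s
        Half-open time interval [t0, t1) in seconds, after the switch.
    roi_mask
        Boolean pixel mask to average over; whole frame if None.
    """
    t0, t1 = settle_window_s
    rate = transition_movies.frame_rate_hz
    i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
    if not (0 <= i0 < i1 <= transition_movies.n_frames):
        raise ValidationError(
            f"settle window [{t0:g}, {t1:g}) s outside record of "
            f"{transition_movies.n_frames / rate:g} s"
        )
    if roi_mask is None:
        roi_mask = ~transition_movies.dead_mask
    else:
        roi_mask = np.asarray(roi_mask, dtype=bool) & ~transition_movies.dead_mask
    if not roi_mask.any():
        raise ValidationError("empty ROI for air-baseline estimation")
    d_hbt = np.nanmean(transition_movies.d_hbt[i0:i1][:, roi_mask])
    d_hbo = np.nanmean(transition_movies.d_hbo[i0:i1][:, roi_mask])
    hbt_air = oxygen_baseline.hbt_uM + float(d_hbt)
    if hbt_air <= 0:
        raise ValidationError("estimated air Hbt is non-positive")
    so2_air = (oxygen_baseline.hbo_uM + float(d_hbo)) / hbt_air
    so2_air = min(max(so2_air, 0.0), 1.0)
    return BaselineState(hbt_uM=hbt_air, so2=so2_air, condition="air")
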