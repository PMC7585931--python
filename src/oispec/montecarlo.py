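"""Monte-Carlo estimation of remitted-photon mean path lengths.

The modified Beer-Lambert inversion needs, for every imaging wavelength,
the mean geometric path length L(lambda) travelled in tissue by photons
that return to the camera.  We estimate it by simulating photon transport
through a homogeneous semi-infinite tissue slab: pencil beam at normal
incidence, exponential step sampling at mu_t = mu_a + mu_s,
Henyey-Greenstein scattering, implicit-capture weighting (weight
multiplied by the single-scattering albedo at each interaction) with
Russian-roulette termination, and detection of every photon that
re-crosses the entry surface, regardless of exit angle or position.
Refractive-index mismatch at the surface is ignored.

The reported path length is the weight-weighted mean of the detected
photons' total travelled path, which is the differential-path-length role
L(lambda) plays in the inversion.

Randomness comes from a splitmix64 counter generator with one
independent, deterministic stream per photon (stream i is seeded by
scrambling ``seed XOR (i+1)*PRIME``), so results are bit-reproducible and
a naive re-implementation following the same draw protocol reproduces
them exactly.  Draw order per step: (1) step length; (2) roulette draw
only when the weight is below threshold; (3) two scattering draws.  The
exit step consumes no draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit, uint64

from .errors import ConfigurationError, DegenerateDataError, ValidationError
from .spectra import (
    BaselineState,
    ExtinctionTable,
    OpticalProperties,
    absorption_coefficient,
)

_GOLDEN = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB
_STREAM_PRIME = 0xD2B74407B1CE6E93
_WAVELENGTH_PRIME = 0xA24BAED4963EE407

#: Russian-roulette parameters: terminate below this weight with 10% survival.
ROULETTE_WEIGHT_MIN = 1e-4
ROULETTE_SURVIVAL = 0.1
#: Hard cap on interactions per photon (binds only for near-zero absorption).
MAX_STEPS = 1_000_000


def _mix64(x: int) -> int:
    """splitmix64 finalizer (pure python, for seed derivation)."""
    x &= 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * _MIX1) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * _MIX2) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def photon_stream_seed(seed: int, photon_index: int) -> int:
    """Initial splitmix64 state of photon ``photon_index``'s stream."""
    return _mix64((seed ^ ((photon_index + 1) * _STREAM_PRIME)) & 0xFFFFFFFFFFFFFFFF)


def wavelength_subseed(seed: int, k: int) -> int:
    """Deterministic per-wavelength master-seed splitting rule."""
    return _mix64((seed ^ ((k + 1) * _WAVELENGTH_PRIME)) & 0xFFFFFFFFFFFFFFFF)


@njit(fastmath=False)
def _mc_kernel(mu_a, mu_s, g, n_photons, seed, max_steps, wmin, psurv):
    """Transport n_photons through the half-space; returns weighted sums.

    Returns (sum_w, sum_wL, sum_wL2, sum_w2, n_detected) over detected
    photons, accumulated in photon order.
    """
    golden = uint64(_GOLDEN)
    m1 = uint64(_MIX1)
    m2 = uint64(_MIX2)
    sprime = uint64(_STREAM_PRIME)
    inv53 = 1.0 / 9007199254740992.0

    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t

    sum_w = 0.0
    sum_wl = 0.0
    sum_wl2 = 0.0
    sum_w2 = 0.0
    n_det = 0

    for i in range(n_photons):
        # per-photon stream: scrambled (seed ^ (i+1)*PRIME)
        x = uint64(seed) ^ (uint64(i + 1) * sprime)
        x = (x ^ (x >> uint64(30))) * m1
        x = (x ^ (x >> uint64(27))) * m2
        state = x ^ (x >> uint64(31))

        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        path = 0.0
        detected = False

        for _step in range(max_steps):
            state = state + golden
            t = state
            t = (t ^ (t >> uint64(30))) * m1
            t = (t ^ (t >> uint64(27))) * m2
            t = t ^ (t >> uint64(31))
            u = (t >> uint64(11)) * inv53
            s = -math.log(1.0 - u) / mu_t

            if uz < 0.0 and z + uz * s < 0.0:
                # partial step to the surface; photon remitted
                path += z / (-uz)
                detected = True
                break

            z += uz * s
            path += s
            w *= albedo

            if w < wmin:
                state = state + golden
                t = state
                t = (t ^ (t >> uint64(30))) * m1
                t = (t ^ (t >> uint64(27))) * m2
                t = t ^ (t >> uint64(31))
                u = (t >> uint64(11)) * inv53
                if u < psurv:
                    w /= psurv
                else:
                    break

            # Henyey-Greenstein deflection + uniform azimuth
            state = state + golden
            t = state
            t = (t ^ (t >> uint64(30))) * m1
            t = (t ^ (t >> uint64(27))) * m2
            t = t ^ (t >> uint64(31))
            u1 = (t >> uint64(11)) * inv53
            state = state + golden
            t = state
            t = (t ^ (t >> uint64(30))) * m1
            t = (t ^ (t >> uint64(27))) * m2
            t = t ^ (t >> uint64(31))
            u2 = (t >> uint64(11)) * inv53

            if g == 0.0:
                cost = 2.0 * u1 - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            if cost > 1.0:
                cost = 1.0
            elif cost < -1.0:
                cost = -1.0
            sint = math.sqrt(1.0 - cost * cost)
            phi = 2.0 * math.pi * u2
            cosp = math.cos(phi)
            sinp = math.sin(phi)

            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                nuz = -den * sint * cosp + uz * cost
                ux = nux
                uy = nuy
                uz = nuz

        if detected:
            sum_w += w
            sum_wl += w * path
            sum_wl2 += w * path * path
            sum_w2 += w * w
            n_det += 1

    return sum_w, sum_wl, sum_wl2, sum_w2, n_det


@dataclass(frozen=True)
class PathLengthEstimate:
    """Mean remitted-photon path length at one wavelength."""

    wavelength_nm: float
    mean_path_cm: float
    se_path_cm: float
    n_launched: int
    n_detected: int
    seed: int

    def __post_init__(self):
        if self.n_detected > self.n_launched:
            raise ValidationError("n_detected cannot exceed n_launched")
        if self.n_detected > 0 and self.mean_path_cm <= 0:
            raise ValidationError("mean path must be positive when photons detected")
        if self.se_path_cm < 0:
            raise ValidationError("standard error must be >= 0")


@dataclass(frozen=True)
class ScatterModel:
    """Per-wavelength scattering model: power-law reduced scattering.

    mu_s'(lambda) = musp_500 * (lambda/500 nm)^(-power), mu_s = mu_s'/(1-g).
    Defaults are literature-typical for cortical tissue in the visible
    band (mu_s' ~ 20 cm^-1 at 500 nm, power ~ 1.2, g = 0.9, n = 1.4).
    """

    musp_500_cm: float = 20.0
    power: float = 1.2
    g: float = 0.9
    n: float = 1.4

    def mu_s(self, wavelength_nm: float) -> float:
        musp = self.musp_500_cm * (wavelength_nm / 500.0) ** (-self.power)
        return musp / (1.0 - self.g)

    def optics(self, mu_a: float, wavelength_nm: float) -> OpticalProperties:
        return OpticalProperties(
            mu_a=mu_a, mu_s=self.mu_s(wavelength_nm), g=self.g, n=self.n
        )


@dataclass(frozen=True)
class PathLengthTable:
    """One PathLengthEstimate per imaging wavelength, sharing a baseline."""

    entries: tuple[PathLengthEstimate, ...]
    baseline: BaselineState

    def __post_init__(self):
        wl = [e.wavelength_nm for e in self.entries]
        if len(set(wl)) != len(wl):
            raise ValidationError("duplicate wavelengths in path-length table")

    @property
    def wavelengths_nm(self) -> tuple[float, ...]:
        return tuple(e.wavelength_nm for e in self.entries)

    def path_cm(self, wavelength_nm: float) -> float:
        for e in self.entries:
            if e.wavelength_nm == wavelength_nm:
                return e.mean_path_cm
        raise ValidationError(f"no path length for {wavelength_nm:g} nm")

    def paths_cm(self) -> np.ndarray:
        return np.array([e.mean_path_cm for e in self.entries])


def simulate_remittance_pathlength(
    props: OpticalProperties,
    n_photons: int,
    seed: int,
    wavelength_nm: float = float("nan"),
    max_steps: int = MAX_STEPS,
) -> PathLengthEstimate:
    """Estimate the mean remitted path length for one set of optics.

    Runs the implicit-capture random walk described in the module
    docstring.  Identical (props, n_photons, seed) give bit-identical
    results.

    Raises
    ------
    DegenerateDataError
        If no photon is remitted (all absorbed/terminated at depth).
    """
    if n_photons < 1:
        raise ValidationError("n_photons must be >= 1")
    sw, swl, swl2, sw2, n_det = _mc_kernel(
        props.mu_a,
        props.mu_s,
        props.g,
        n_photons,
        np.uint64(seed & 0xFFFFFFFFFFFFFFFF),
        max_steps,
        ROULETTE_WEIGHT_MIN,
        ROULETTE_SURVIVAL,
    )
    if n_det == 0 or sw <= 0.0:
        raise DegenerateDataError(
            f"no remitted photons out of {n_photons} "
            f"(mu_a={props.mu_a:g}, mu_s={props.mu_s:g})"
        )
    mean = swl / sw
    var = max(swl2 / sw - mean * mean, 0.0)
    n_eff = sw * sw / sw2
    se = math.sqrt(var / n_eff) if n_eff > 0 else 0.0
    return PathLengthEstimate(
        wavelength_nm=wavelength_nm,
        mean_path_cm=mean,
        se_path_cm=se,
        n_launched=n_photons,
        n_detected=n_det,
        seed=seed,
    )


_table_cache: dict = {}


def pathlength_table(
    baseline: BaselineState,
    wavelengths: tuple[float, ...],
    table: ExtinctionTable,
    scatter_model: ScatterModel | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
) -> PathLengthTable:
    """Per-wavelength path lengths for a given baseline tissue state.

    mu_a at each wavelength follows from the baseline via the extinction
    table; each wavelength runs an independent simulation with a
    deterministically derived sub-seed, so the table is reproducible
    wavelength by wavelength.  Results are cached per
    (baseline, wavelengths, scatter model, n_photons, seed).
    """
    if scatter_model is None:
        scatter_model = ScatterModel()
    wavelengths = tuple(float(w) for w in wavelengths)
    for w in wavelengths:
        if not table.covers(w):
            raise ConfigurationError(f"extinction table does not cover {w:g} nm")
    key = (baseline, wavelengths, scatter_model, n_photons, seed, id(table))
    hit = _table_cache.get(key)
    if hit is not None:
        return hit
    entries = []
    for k, w in enumerate(wavelengths):
        mu_a = absorption_coefficient(baseline, w, table)
        props = scatter_model.optics(mu_a, w)
        est = simulate_remittance_pathlength(
            props, n_photons, wavelength_subseed(seed, k), wavelength_nm=w
        )
        entries.append(est)
    out = PathLengthTable(entries=tuple(entries), baseline=baseline)
    _table_cache[key] = out
    return out
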