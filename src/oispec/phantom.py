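"""Synthetic imaging phantom: the stand-in for a real cranial-window session.

This module generates complete multispectral imaging sessions with known
ground truth.  A session follows the eight-experiment protocol used in
the study (2 s and 16 s whisker stimulation under oxygen and air, two gas
transitions, and a hypercapnia challenge), and the phantom composes, per
pixel and per frame:

* compartmentalised baseline hemodynamics (artery / vein / parenchyma
  inside a circular cranial window; 100 uM Hbt at 70% saturation under
  oxygen by default),
* stimulus-evoked responses built from gamma-variate kernels convolved
  with the stimulus train — artery leads vein, Hbr washes out with a lag,
  and under air the arterial Hbt response carries a post-stimulus
  undershoot that is absent under oxygen,
* gas-transition baseline shifts (logistic ramp between the oxygen and
  air states) and a hypercapnia excursion,
* for acute sessions, a cortical-spreading-depression-like baseline
  perturbation: a damped oscillation recovering exponentially toward
  baseline, larger in the AD-like group than the WT-like group,
* camera shot noise and a dark offset, plus dark frames for the
  inter-experiment gaps.

The forward model maps concentrations to intensities through the same
modified Beer-Lambert relation the inversion assumes, so with noise
disabled the analysis pipeline must reproduce the injected movies
exactly; every simulated session carries its injected compartment time
courses so any stage can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .montecarlo import PathLengthTable
from .spectra import LN10, BaselineState, ExtinctionTable, extinction_at

DEFAULT_FRAME_RATE_HZ = 8.0
DEFAULT_PIXEL_UM = 75.0

STIM_KINDS = ("stim2s_oxygen", "stim2s_air", "stim16s_air", "stim16s_oxygen")
GAS_KINDS = ("gas_to_air", "gas_to_oxygen", "hypercapnia")


# --------------------------------------------------------------------------
# protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment within a session."""

    exp_id: str
    kind: str
    total_length_s: float
    n_trials: int = 0
    trial_length_s: float = 0.0
    stim_onset_s: float = 0.0
    stim_duration_s: float = 0.0
    stim_rate_hz: float = 0.0
    gas_switch_s: float = float("nan")
    gas_duration_s: float = float("nan")

    def __post_init__(self):
        if self.kind not in STIM_KINDS + GAS_KINDS:
            raise ValidationError(f"unknown experiment kind {self.kind!r}")
        if self.is_stim:
            if self.n_trials < 1:
                raise ValidationError("stimulation experiment needs n_trials >= 1")
            if abs(self.n_trials * self.trial_length_s - self.total_length_s) > 1e-9:
                raise ValidationError(
                    f"{self.exp_id}: total_length_s must equal "
                    "n_trials * trial_length_s"
                )
            if not self.stim_onset_s + self.stim_duration_s < self.trial_length_s:
                raise ValidationError(
                    f"{self.exp_id}: stimulus must end before the trial does"
                )

    @property
    def is_stim(self) -> bool:
        return self.kind in STIM_KINDS

    @property
    def breathing(self) -> str:
        """Breathing condition at the start of the record."""
        if self.kind in ("stim2s_oxygen", "stim16s_oxygen", "gas_to_air",
                         "hypercapnia"):
            return "oxygen"
        return "air"

    @property
    def baseline_window_s(self) -> tuple[float, float]:
        """Interval whose mean defines I0: pre-stimulus for stimulation
        records, pre-switch for gas records."""
        if self.is_stim:
            return (0.0, self.stim_onset_s)
        return (0.0, self.gas_switch_s)


@dataclass(frozen=True)
class Protocol:
    """Ordered experiment list plus the inter-experiment dark-frame gap."""

    experiments: tuple[ExperimentSpec, ...]
    inter_experiment_gap_s: float = 180.0

    def __post_init__(self):
        ids = [e.exp_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValidationError("experiment ids must be unique")

    def __getitem__(self, exp_id: str) -> ExperimentSpec:
        for e in self.experiments:
            if e.exp_id == exp_id:
                return e
        raise KeyError(exp_id)

    @property
    def total_stim_trials(self) -> int:
        return sum(e.n_trials for e in self.experiments if e.is_stim)

    def session_offsets_s(self) -> dict[str, float]:
        """Start time of each experiment on the session clock (with gaps)."""
        out, t = {}, 0.0
        for e in self.experiments:
            out[e.exp_id] = t
            t += e.total_length_s + self.inter_experiment_gap_s
        return out

    @property
    def session_length_s(self) -> float:
        n = len(self.experiments)
        return (sum(e.total_length_s for e in self.experiments)
                + self.inter_experiment_gap_s * max(n - 1, 0))


def default_protocol() -> Protocol:
    """The full eight-experiment session.

    Exp1/2: oxygen, 30 x 25 s trials, 2 s whisker stimulation at 5 Hz
    starting 5 s into each trial (750 s each).  Exp3: oxygen-to-air
    transition at 105 s (750 s).  Exp4: as Exp1 under air.  Exp5: air,
    15 x 70 s trials, 16 s stimulation from 10 s (1050 s).  Exp6:
    air-to-oxygen transition at 105 s (750 s).  Exp7: as Exp5 under
    oxygen.  Exp8: hypercapnia from 250 s for 250 s, then 250 s recovery
    (750 s).
    """
    stim2 = dict(n_trials=30, trial_length_s=25.0, stim_onset_s=5.0,
                 stim_duration_s=2.0, stim_rate_hz=5.0, total_length_s=750.0)
    stim16 = dict(n_trials=15, trial_length_s=70.0, stim_onset_s=10.0,
                  stim_duration_s=16.0, stim_rate_hz=5.0, total_length_s=1050.0)
    return Protocol(experiments=(
        ExperimentSpec("exp1", "stim2s_oxygen", **stim2),
        ExperimentSpec("exp2", "stim2s_oxygen", **stim2),
        ExperimentSpec("exp3", "gas_to_air", total_length_s=750.0,
                       gas_switch_s=105.0),
        ExperimentSpec("exp4", "stim2s_air", **stim2),
        ExperimentSpec("exp5", "stim16s_air", **stim16),
        ExperimentSpec("exp6", "gas_to_oxygen", total_length_s=750.0,
                       gas_switch_s=105.0),
        ExperimentSpec("exp7", "stim16s_oxygen", **stim16),
        ExperimentSpec("exp8", "hypercapnia", total_length_s=750.0,
                       gas_switch_s=250.0, gas_duration_s=250.0),
    ))


def reduced_protocol(n_trials_2s: int = 4, n_trials_16s: int = 3,
                     gas_length_s: float = 240.0, gas_switch_s: float = 60.0,
                     hc_length_s: float = 300.0) -> Protocol:
    """Desk-scale session with the same structure but fewer/shorter records.

    Keeps trial geometry (25 s / 70 s trials, same stimulus timing) so
    epoching and response shapes are unchanged; only counts and gas
    record lengths shrink.
    """
    stim2 = dict(n_trials=n_trials_2s, trial_length_s=25.0, stim_onset_s=5.0,
                 stim_duration_s=2.0, stim_rate_hz=5.0,
                 total_length_s=25.0 * n_trials_2s)
    stim16 = dict(n_trials=n_trials_16s, trial_length_s=70.0, stim_onset_s=10.0,
                  stim_duration_s=16.0, stim_rate_hz=5.0,
                  total_length_s=70.0 * n_trials_16s)
    hc_sw = hc_length_s / 3.0
    return Protocol(experiments=(
        ExperimentSpec("exp1", "stim2s_oxygen", **stim2),
        ExperimentSpec("exp2", "stim2s_oxygen", **stim2),
        ExperimentSpec("exp3", "gas_to_air", total_length_s=gas_length_s,
                       gas_switch_s=gas_switch_s),
        ExperimentSpec("exp4", "stim2s_air", **stim2),
        ExperimentSpec("exp5", "stim16s_air", **stim16),
        ExperimentSpec("exp6", "gas_to_oxygen", total_length_s=gas_length_s,
                       gas_switch_s=gas_switch_s),
        ExperimentSpec("exp7", "stim16s_oxygen", **stim16),
        ExperimentSpec("exp8", "hypercapnia", total_length_s=hc_length_s,
                       gas_switch_s=hc_sw, gas_duration_s=hc_sw),
    ), inter_experiment_gap_s=60.0)


def experiment_events(exp: ExperimentSpec) -> pd.DataFrame:
    """Event log for one experiment, times relative to record start.

    Columns: time_s, kind, value.  Stimulation records carry
    stim_train_on/off plus individual stim_pulse events at the deflection
    rate; gas records carry a single gas_switch (and for hypercapnia a
    gas_switch back).
    """
    rows = []
    if exp.is_stim:
        for k in range(exp.n_trials):
            on = k * exp.trial_length_s + exp.stim_onset_s
            rows.append((on, "stim_train_on", ""))
            n_pulses = int(round(exp.stim_duration_s * exp.stim_rate_hz))
            for j in range(n_pulses):
                rows.append((on + j / exp.stim_rate_hz, "stim_pulse", ""))
            rows.append((on + exp.stim_duration_s, "stim_train_off", ""))
    elif exp.kind == "gas_to_air":
        rows.append((exp.gas_switch_s, "gas_switch", "air"))
    elif exp.kind == "gas_to_oxygen":
        rows.append((exp.gas_switch_s, "gas_switch", "oxygen"))
    else:  # hypercapnia
        rows.append((exp.gas_switch_s, "gas_switch", "co2_on"))
        rows.append((exp.gas_switch_s + exp.gas_duration_s, "gas_switch",
                     "co2_off"))
    return pd.DataFrame(rows, columns=["time_s", "kind", "value"])


# --------------------------------------------------------------------------
# phantom geometry and parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentResponse:
    """Gamma-variate evoked-response parameters for one compartment.

    Amplitudes are the plateau change (uM) a sustained stimulus drives;
    a 2 s train reaches a fraction of it.  The undershoot lobe applies to
    Hbt under the air condition only.
    """

    hbt_amp_uM: float
    hbr_amp_uM: float  # negative: washout
    latency_s: float
    tau_s: float = 1.0
    alpha: float = 3.0
    hbr_extra_lag_s: float = 1.0
    hbr_tau_s: float = 2.0
    undershoot_frac: float = 0.0
    undershoot_delay_s: float = 2.0
    undershoot_tau_s: float = 5.0


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: signal-scaled Gaussian shot noise + dark offset."""

    shot_scale: float = 1.0
    dark_offset: float = 100.0
    dark_sd: float = 2.0
    enabled: bool = True


@dataclass(frozen=True)
class Phantom:
    """Compartment masks plus the forward-model parameters."""

    shape: tuple[int, int]
    pixel_um: float
    window_mask: np.ndarray
    artery_mask: np.ndarray
    vein_mask: np.ndarray
    parenchyma_mask: np.ndarray
    active_mask: np.ndarray
    baseline_oxygen: BaselineState
    baseline_air: BaselineState
    responses: dict
    noise: NoiseModel
    i0_counts: float = 3000.0
    gas_tau_s: float = 10.0
    hypercapnia_hbt_gain: float = 0.15
    hypercapnia_so2_gain: float = 0.08
    seed: int = 0

    def __post_init__(self):
        a, v, p = self.artery_mask, self.vein_mask, self.parenchyma_mask
        if (a & v).any() or (a & p).any() or (v & p).any():
            raise ValidationError("compartment masks must be pairwise disjoint")
        if not a.any() or not v.any():
            raise ValidationError("artery and vein masks must be non-empty")

    @property
    def background_mask(self) -> np.ndarray:
        return ~self.window_mask

    def baseline(self, breathing: str) -> BaselineState:
        return self.baseline_oxygen if breathing == "oxygen" else self.baseline_air

    @property
    def window_diameter_mm(self) -> float:
        rows = np.where(self.window_mask.any(axis=1))[0]
        return (rows[-1] - rows[0] + 1) * self.pixel_um / 1000.0


DEFAULT_RESPONSES = {
    "artery": CompartmentResponse(hbt_amp_uM=8.0, hbr_amp_uM=-4.0,
                                  latency_s=0.2, undershoot_frac=0.5),
    "vein": CompartmentResponse(hbt_amp_uM=5.0, hbr_amp_uM=-5.0,
                                latency_s=1.2, undershoot_frac=0.15),
    "parenchyma": CompartmentResponse(hbt_amp_uM=5.0, hbr_amp_uM=-3.0,
                                      latency_s=0.6, undershoot_frac=0.1),
}


def _curve_mask(shape, pts, width_px):
    """Rasterise a polyline as a thick curve (distance threshold)."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = np.zeros(shape, dtype=bool)
    dense = []
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        n = max(int(np.hypot(y1 - y0, x1 - x0) * 2), 2)
        t = np.linspace(0, 1, n)
        dense.append(np.column_stack([y0 + t * (y1 - y0), x0 + t * (x1 - x0)]))
    dense = np.concatenate(dense)
    for y, x in dense:
        mask |= (yy - y) ** 2 + (xx - x) ** 2 <= width_px ** 2
    return mask


def make_phantom(
    shape: tuple[int, int] = (184, 184),
    pixel_um: float = DEFAULT_PIXEL_UM,
    seed: int = 0,
    baseline_oxygen: BaselineState | None = None,
    baseline_air: BaselineState | None = None,
    responses: dict | None = None,
    noise: NoiseModel | None = None,
    vessel_width_px: float | None = None,
) -> Phantom:
    """Draw a cranial-window phantom: branching artery, draining vein,
    parenchyma inside a circular window, and an off-centre activated
    region through which both vessels run.  Deterministic given seed.
    """
    ny, nx = shape
    if ny < 32 or nx < 32:
        raise ConfigurationError("phantom grid must be at least 32x32")
    rng = np.random.default_rng(seed)
    cy, cx = ny / 2.0, nx / 2.0
    r_win = 0.46 * min(ny, nx)
    yy, xx = np.mgrid[0:ny, 0:nx]
    window = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_win ** 2

    # activated whisker region: off-centre disc inside the window
    ay, ax = cy - 0.10 * ny, cx + 0.08 * nx
    r_act = 0.22 * min(ny, nx)
    active = ((yy - ay) ** 2 + (xx - ax) ** 2 <= r_act ** 2) & window

    w = vessel_width_px if vessel_width_px is not None else max(min(ny, nx) / 40.0, 1.5)
    jit = lambda s: rng.uniform(-s, s)  # noqa: E731

    # artery: enters left, runs through the active region, one branch
    trunk = [(cy + 0.30 * ny + jit(2), cx - r_win),
             (cy + 0.10 * ny + jit(2), cx - 0.25 * nx),
             (ay + 0.05 * ny + jit(2), ax - 0.05 * nx),
             (ay - 0.15 * ny + jit(2), ax + 0.10 * nx)]
    branch = [trunk[2],
              (ay + 0.18 * ny + jit(2), ax + 0.15 * nx)]
    artery = (_curve_mask(shape, trunk, w) | _curve_mask(shape, branch, 0.8 * w))

    # vein: enters top-right, drains past the active region
    vpts = [(cy - r_win, cx + 0.25 * nx + jit(2)),
            (ay - 0.05 * ny + jit(2), ax + 0.18 * nx),
            (ay + 0.25 * ny + jit(2), ax + 0.02 * nx),
            (cy + 0.40 * ny + jit(2), cx + 0.15 * nx)]
    vein = _curve_mask(shape, vpts, 1.2 * w)

    artery &= window
    vein &= window & ~artery
    parenchyma = window & ~artery & ~vein
    if not artery.any() or not vein.any():
        raise ConfigurationError("grid too small to place both vessels")

    return Phantom(
        shape=shape,
        pixel_um=pixel_um,
        window_mask=window,
        artery_mask=artery,
        vein_mask=vein,
        parenchyma_mask=parenchyma,
        active_mask=active,
        baseline_oxygen=baseline_oxygen or BaselineState(100.0, 0.70, "oxygen"),
        baseline_air=baseline_air or BaselineState(95.0, 0.62, "air"),
        responses=dict(responses or DEFAULT_RESPONSES),
        noise=noise or NoiseModel(),
        seed=seed,
    )


# --------------------------------------------------------------------------
# condition / scenario
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSpec:
    """Scenario: group (WT-like / AD-like) x session kind (chronic / acute).

    Chronic sessions have no baseline perturbation and full-sized evoked
    responses in both groups (the study's preserved-response result).
    Acute sessions start during recovery from an electrode-insertion
    CSD-like event: a damped oscillatory baseline dip, larger in the
    AD-like group, together with scaled-down evoked responses.
    """

    group: str  # "WT-like" | "AD-like"
    session_kind: str  # "chronic" | "acute"
    csd_amplitude: float = 0.0  # fractional baseline dip at session start
    csd_recovery_tau_s: float = 600.0
    csd_period_s: float = 120.0
    evoked_scale: float = 1.0

    def __post_init__(self):
        if self.group not in ("WT-like", "AD-like"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.session_kind not in ("chronic", "acute"):
            raise ValidationError(f"unknown session kind {self.session_kind!r}")
        if self.session_kind == "chronic" and self.csd_amplitude != 0.0:
            raise ValidationError("chronic sessions must have csd_amplitude 0")
        if not (0.0 <= self.csd_amplitude < 1.0):
            raise ValidationError("csd_amplitude must lie in [0, 1)")

    @classmethod
    def default(cls, group: str, session_kind: str) -> "ConditionSpec":
        if session_kind == "chronic":
            return cls(group=group, session_kind="chronic")
        if group == "WT-like":
            return cls(group=group, session_kind="acute",
                       csd_amplitude=0.10, evoked_scale=0.85)
        return cls(group=group, session_kind="acute",
                   csd_amplitude=0.20, evoked_scale=0.55)


def csd_perturbation(condition: ConditionSpec, length_s: float,
                     rate_hz: float, t0_s: float = 0.0) -> np.ndarray:
    """Fractional baseline multiplier m(t) for a CSD-like perturbation.

    m(t) = 1 - A cos(2 pi t / P) exp(-t / tau): an initial
    vasoconstriction dip alternating with overshoot, recovering
    exponentially toward 1.  Chronic conditions return all ones.
    ``t0_s`` offsets the evaluation (session time of the record start).
    """
    n = int(round(length_s * rate_hz))
    t = t0_s + np.arange(n) / rate_hz
    if condition.csd_amplitude == 0.0:
        return np.ones(n)
    return 1.0 - condition.csd_amplitude * np.cos(
        2.0 * np.pi * t / condition.csd_period_s
    ) * np.exp(-t / condition.csd_recovery_tau_s)


# --------------------------------------------------------------------------
# evoked time courses
# --------------------------------------------------------------------------

def _gamma_kernel(t: np.ndarray, latency_s: float, tau_s: float,
                  alpha: float) -> np.ndarray:
    """Unit-area gamma-variate kernel delayed by ``latency_s``."""
    ts = t - latency_s
    h = np.where(ts > 0, np.power(np.clip(ts, 0, None), alpha - 1.0)
                 * np.exp(-ts / tau_s), 0.0)
    area = h.sum() * (t[1] - t[0]) if t.size > 1 else 1.0
    return h / area if area > 0 else h


def stimulus_regressor(events: pd.DataFrame, length_s: float,
                       rate_hz: float) -> np.ndarray:
    """Boxcar drive: 1 between each stim_train_on and stim_train_off."""
    n = int(round(length_s * rate_hz))
    r = np.zeros(n)
    ons = events.loc[events["kind"] == "stim_train_on", "time_s"].to_numpy()
    offs = events.loc[events["kind"] == "stim_train_off", "time_s"].to_numpy()
    for on, off in zip(ons, offs):
        r[int(round(on * rate_hz)):int(round(off * rate_hz))] = 1.0
    return r


def evoked_timecourse(
    events: pd.DataFrame,
    params: CompartmentResponse,
    condition: ConditionSpec,
    breathing: str,
    length_s: float,
    rate_hz: float = DEFAULT_FRAME_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Evoked (dHbt, dHbr) series (uM) for one compartment.

    Gamma-variate impulse responses convolved with the stimulus boxcar;
    Hbr is negative-going with an extra lag.  Under air an additional
    slow negative lobe produces the post-stimulus Hbt undershoot; under
    oxygen the Hbt response is non-negative.  Amplitudes are scaled by
    ``condition.evoked_scale``.
    """
    n = int(round(length_s * rate_hz))
    r = stimulus_regressor(events, length_s, rate_hz)
    if not r.any():
        return np.zeros(n), np.zeros(n)
    dt = 1.0 / rate_hz
    tk = np.arange(0, 40.0, dt)
    scale = condition.evoked_scale

    h = _gamma_kernel(tk, params.latency_s, params.tau_s, params.alpha)
    hbt = params.hbt_amp_uM * scale * np.convolve(r, h)[:n] * dt
    if breathing == "air" and params.undershoot_frac > 0:
        hu = _gamma_kernel(tk, params.latency_s + params.undershoot_delay_s,
                           params.undershoot_tau_s, 2.0)
        hbt -= (params.hbt_amp_uM * params.undershoot_frac * scale
                * np.convolve(r, hu)[:n] * dt)

    hr = _gamma_kernel(tk, params.latency_s + params.hbr_extra_lag_s,
                       params.hbr_tau_s, params.alpha)
    hbr = params.hbr_amp_uM * scale * np.convolve(r, hr)[:n] * dt
    return hbt, hbr


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def _logistic(t, center, tau):
    return 1.0 / (1.0 + np.exp(-(t - center) / tau))


def _baseline_trajectory(exp: ExperimentSpec, phantom: Phantom,
                         t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(hbt(t), so2(t)) of the unperturbed baseline for one record."""
    b0 = phantom.baseline(exp.breathing)
    hbt = np.full_like(t, b0.hbt_uM)
    so2 = np.full_like(t, b0.so2)
    tau = phantom.gas_tau_s
    if exp.kind in ("gas_to_air", "gas_to_oxygen"):
        b1 = phantom.baseline("air" if exp.kind == "gas_to_air" else "oxygen")
        s = _logistic(t, exp.gas_switch_s + 4.0 * tau, tau)
        hbt = b0.hbt_uM + (b1.hbt_uM - b0.hbt_uM) * s
        so2 = b0.so2 + (b1.so2 - b0.so2) * s
    elif exp.kind == "hypercapnia":
        ramp = (_logistic(t, exp.gas_switch_s + 2.0 * tau, tau)
                - _logistic(t, exp.gas_switch_s + exp.gas_duration_s
                            + 2.0 * tau, tau))
        hbt = b0.hbt_uM * (1.0 + phantom.hypercapnia_hbt_gain * ramp)
        so2 = np.clip(b0.so2 + phantom.hypercapnia_so2_gain * ramp, 0.0, 0.99)
    return hbt, so2


@dataclass
class ExperimentTruth:
    """Injected ground truth for one simulated experiment."""

    exp_id: str
    breathing: str
    baseline_window_s: tuple[float, float]
    #: list of (pixel mask, c_hbo(t) uM, c_hbr(t) uM) effective compartments
    components: list
    evoked: dict  # compartment -> (d_hbt, d_hbr) in uM
    csd_multiplier: np.ndarray

    def concentration_movie(self) -> tuple[np.ndarray, np.ndarray]:
        """Absolute (c_hbo, c_hbr) movies (t, y, x) in uM."""
        mask0 = self.components[0][0]
        n_t = self.components[0][1].size
        hbo = np.zeros((n_t,) + mask0.shape)
        hbr = np.zeros_like(hbo)
        for mask, co, cr in self.components:
            hbo[:, mask] = co[:, None]
            hbr[:, mask] = cr[:, None]
        return hbo, hbr

    def fractional_hbt_movie(self, baseline: BaselineState,
                             rate_hz: float) -> np.ndarray:
        """Injected fractional Hbt movie relative to the baseline-window
        mean, on the same convention the inversion reports."""
        hbo, hbr = self.concentration_movie()
        hbt = hbo + hbr
        i0, i1 = (int(round(s * rate_hz)) for s in self.baseline_window_s)
        ref = hbt[i0:i1].mean(axis=0, keepdims=True)
        return 1.0 + (hbt - ref) / baseline.hbt_uM


@dataclass
class SessionRecording:
    """A simulated (or loaded) imaging session."""

    intensities: dict  # exp_id -> float32 array (wavelength, t, y, x)
    dark_frames: dict  # gap_id -> float32 array (y, x)
    events: pd.DataFrame  # exp_id, time_s (relative), session_time_s, kind, value
    wavelengths_nm: tuple[float, ...]
    frame_rate_hz: float
    protocol: Protocol
    condition: ConditionSpec | None = None
    phantom: Phantom | None = None
    truth: dict | None = None  # exp_id -> ExperimentTruth
    meta: dict = field(default_factory=dict)

    def experiment_events(self, exp_id: str) -> pd.DataFrame:
        return self.events[self.events["exp_id"] == exp_id].reset_index(drop=True)


def simulate_session(
    phantom: Phantom,
    protocol: Protocol,
    condition: ConditionSpec,
    table: ExtinctionTable,
    paths: PathLengthTable,
    seed: int = 0,
    wavelengths_nm: tuple[float, ...] | None = None,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    experiments: tuple[str, ...] | None = None,
) -> SessionRecording:
    """Forward-simulate a full session of multispectral intensities.

    Per experiment the per-compartment concentration series are composed
    (baseline trajectory x CSD multiplier + evoked responses in the
    activated region), mapped to attenuation via the modified
    Beer-Lambert relation with the supplied extinction table and path
    lengths, exponentiated onto a smooth per-pixel illumination profile,
    and degraded by shot noise plus a dark offset.  Dark frames are
    emitted for each inter-experiment gap and the exact event log is
    returned.  Fully seeded and bit-reproducible.

    Parameters
    ----------
    experiments
        Optional subset of experiment ids to simulate (protocol order
        and session-clock offsets are preserved).
    """
    wl = tuple(wavelengths_nm or paths.wavelengths_nm)
    if tuple(paths.wavelengths_nm) != wl:
        raise ConfigurationError(
            f"path-length wavelengths {paths.wavelengths_nm} do not match {wl}"
        )
    for w in wl:
        if not table.covers(w):
            raise ConfigurationError(f"extinction table does not cover {w:g} nm")
    rng = np.random.default_rng(seed)
    ny, nx = phantom.shape

    # smooth illumination profile, per wavelength intensity scale
    yy, xx = np.mgrid[0:ny, 0:nx]
    profile = 1.0 - 0.3 * (((yy - ny / 2) / ny) ** 2 + ((xx - nx / 2) / nx) ** 2)
    i0 = phantom.i0_counts * profile

    eps = np.array([extinction_at(table, w) for w in wl])  # (W, 2)
    L = np.array([paths.path_cm(w) for w in wl])
    coef = LN10 * 1e-6 * eps * L[:, None]  # (W, 2): dA per uM

    offsets = protocol.session_offsets_s()
    comp_masks = {
        "artery": phantom.artery_mask,
        "vein": phantom.vein_mask,
        "parenchyma": phantom.parenchyma_mask,
    }

    intensities: dict[str, np.ndarray] = {}
    truth: dict[str, ExperimentTruth] = {}
    ev_rows = []

    wanted = set(experiments) if experiments is not None else None
    for exp in protocol.experiments:
        if wanted is not None and exp.exp_id not in wanted:
            continue
        n_t = int(round(exp.total_length_s * frame_rate_hz))
        t = np.arange(n_t) / frame_rate_hz
        events = experiment_events(exp)
        for _, row in events.iterrows():
            ev_rows.append((exp.exp_id, row.time_s,
                            offsets[exp.exp_id] + row.time_s, row.kind,
                            row.value))

        base_hbt, base_so2 = _baseline_trajectory(exp, phantom, t)
        m = csd_perturbation(condition, exp.total_length_s, frame_rate_hz,
                             t0_s=offsets[exp.exp_id])
        hbt_b = base_hbt * m
        so2_b = np.clip(base_so2 * (1.0 + 0.5 * (m - 1.0)), 0.0, 1.0)
        c_hbo_b = so2_b * hbt_b
        c_hbr_b = (1.0 - so2_b) * hbt_b

        components = []
        evoked = {}
        for name, mask in comp_masks.items():
            if exp.is_stim:
                d_hbt, d_hbr = evoked_timecourse(
                    events, phantom.responses[name], condition, exp.breathing,
                    exp.total_length_s, frame_rate_hz)
            else:
                d_hbt = np.zeros(n_t)
                d_hbr = np.zeros(n_t)
            evoked[name] = (d_hbt, d_hbr)
            act = mask & phantom.active_mask
            inact = mask & ~phantom.active_mask
            if inact.any():
                components.append((inact, c_hbo_b.copy(), c_hbr_b.copy()))
            if act.any():
                components.append((act, c_hbo_b + (d_hbt - d_hbr),
                                   c_hbr_b + d_hbr))

        # reference attenuation: record-start nominal baseline
        b0 = phantom.baseline(exp.breathing)
        a_ref = coef @ np.array([b0.hbo_uM, b0.hbr_uM])  # (W,)

        # float32 emulates camera counts; noise-free (verification) runs
        # keep full precision so round trips are exact
        dtype = np.float32 if phantom.noise.enabled else np.float64
        movie = np.empty((len(wl), n_t, ny, nx), dtype=dtype)
        movie[:] = i0[None, None].astype(dtype)
        # background pixels stay at i0; tissue pixels attenuate
        for mask, co, cr in components:
            a = coef @ np.stack([co, cr])  # (W, T)
            rel = np.exp(-(a - a_ref[:, None]))  # (W, T)
            movie[:, :, mask] = (i0[mask][None, None, :]
                                 * rel[:, :, None]).astype(dtype)
        if phantom.noise.enabled:
            nm = phantom.noise
            shot = rng.standard_normal(movie.shape).astype(np.float32)
            movie += shot * (nm.shot_scale * np.sqrt(np.clip(movie, 0, None)))
            movie += nm.dark_offset
            movie += (nm.dark_sd
                      * rng.standard_normal(movie.shape).astype(np.float32))
            np.clip(movie, 0.0, None, out=movie)
        intensities[exp.exp_id] = movie
        truth[exp.exp_id] = ExperimentTruth(
            exp_id=exp.exp_id,
            breathing=exp.breathing,
            baseline_window_s=exp.baseline_window_s,
            components=components,
            evoked=evoked,
            csd_multiplier=m,
        )

    dark = {}
    n_gaps = max(len(protocol.experiments) - 1, 1)
    for k in range(n_gaps):
        nm = phantom.noise
        frame = np.full((ny, nx), nm.dark_offset, dtype=np.float32)
        if nm.enabled:
            frame += nm.dark_sd * rng.standard_normal((ny, nx)).astype(np.float32)
        dark[f"gap{k + 1}"] = frame

    events_df = pd.DataFrame(
        ev_rows, columns=["exp_id", "time_s", "session_time_s", "kind", "value"])
    return SessionRecording(
        intensities=intensities,
        dark_frames=dark,
        events=events_df,
        wavelengths_nm=wl,
        frame_rate_hz=frame_rate_hz,
        protocol=protocol,
        condition=condition,
        phantom=phantom,
        truth=truth,
        meta={"seed": seed, "group": condition.group,
              "session_kind": condition.session_kind,
              "pixel_um": phantom.pixel_um},
    )


# --------------------------------------------------------------------------
# electrophysiology phantom
# --------------------------------------------------------------------------

LFP_RATE_HZ = 6000.0
LFP_N_CHANNELS = 16
LFP_CHANNEL_SPACING_UM = 100.0


def simulate_lfp(
    protocol: Protocol,
    condition: ConditionSpec,
    seed: int = 0,
    rate_hz: float = LFP_RATE_HZ,
    n_channels: int = LFP_N_CHANNELS,
    experiments: tuple[str, ...] | None = None,
    evoked_uV: float = 400.0,
):
    """Synthetic 16-channel field-potential record for a protocol.

    Experiments are laid back-to-back on the neural clock (gaps carry no
    samples).  Each whisker deflection adds a stimulus-locked biphasic
    field potential (negative peak ~8 ms, positive rebound ~25 ms) with a
    depth profile largest on the middle channels; evoked amplitude is the
    same for every group — the study's neural null result — and pink
    noise is added per channel.  Returns a ``neural.NeuralRecord``.

    Notes
    -----
    The CSD-like baseline perturbation is a hemodynamic scenario and does
    not alter the injected neural amplitude.
    """
    from .neural import NeuralRecord  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    segs = []
    pulse_times = []
    t_off = 0.0
    wanted = set(experiments) if experiments is not None else None
    for exp in protocol.experiments:
        if wanted is not None and exp.exp_id not in wanted:
            continue
        n = int(round(exp.total_length_s * rate_hz))
        seg = np.zeros((n_channels, n), dtype=np.float32)
        # pink-ish noise: white + integrated white, per channel
        white = rng.standard_normal((n_channels, n)).astype(np.float32)
        slow = np.cumsum(rng.standard_normal((n_channels, n)), axis=1)
        slow = (slow - slow.mean(axis=1, keepdims=True)).astype(np.float32)
        slow /= max(np.abs(slow).max(), 1e-9)
        seg += 20.0 * white + 30.0 * slow

        ev = experiment_events(exp)
        pulses = ev.loc[ev["kind"] == "stim_pulse", "time_s"].to_numpy()
        if pulses.size:
            tk = np.arange(0, 0.06, 1.0 / rate_hz)
            kernel = (-np.exp(-((tk - 0.008) / 0.004) ** 2)
                      + 0.45 * np.exp(-((tk - 0.025) / 0.010) ** 2))
            ch = np.arange(n_channels)
            depth = np.exp(-((ch - (n_channels - 1) / 2.0) / 4.0) ** 2)
            wave = (evoked_uV * depth[:, None] * kernel[None, :]).astype(np.float32)
            for p in pulses:
                s0 = int(round(p * rate_hz))
                s1 = min(s0 + kernel.size, n)
                seg[:, s0:s1] += wave[:, : s1 - s0]
        segs.append(seg)
        pulse_times.extend(t_off + pulses)
        t_off += exp.total_length_s

    samples = np.concatenate(segs, axis=1) if segs else np.zeros((n_channels, 0),
                                                                 np.float32)
    return NeuralRecord(
        samples=samples,
        rate_hz=rate_hz,
        channel_spacing_um=LFP_CHANNEL_SPACING_UM,
        events_s=np.asarray(pulse_times, dtype=float),
        meta={"seed": seed, "group": condition.group},
    )


# --------------------------------------------------------------------------
# cohort-level magnitude generator (for the statistics stage)
# --------------------------------------------------------------------------

def simulate_cohort_magnitudes(
    n_per_group: int,
    seed: int,
    session_kind: str = "chronic",
    levels: tuple[str, ...] = ("exp1", "exp2", "exp4", "exp5", "exp7"),
    subject_sd: float = 0.05,
    noise_sd: float = 0.002,
    group_scales: tuple[float, float] | None = None,
    protocol: Protocol | None = None,
) -> pd.DataFrame:
    """Per-subject mean response magnitudes for a two-group cohort.

    For each stimulation experiment the parenchymal evoked fractional
    response is computed once from the phantom response model and its
    stimulation-window mean taken as the condition's base magnitude.
    Each subject then scales every magnitude by an individual gain
    (1 + N(0, subject_sd)) times its group's evoked scale, plus
    measurement noise N(0, noise_sd).  Under ``session_kind='chronic'``
    both groups share scale 1 (null difference); under ``'acute'`` the
    default scales follow ``ConditionSpec.default`` (AD-like deficit).

    Returns a long table with columns subject, group, level, species,
    magnitude (fractional units), balanced and complete.
    """
    proto = protocol or default_protocol()
    rng = np.random.default_rng(seed)
    if group_scales is None:
        if session_kind == "chronic":
            group_scales = (1.0, 1.0)
        else:
            group_scales = (
                ConditionSpec.default("WT-like", "acute").evoked_scale,
                ConditionSpec.default("AD-like", "acute").evoked_scale,
            )

    base = BaselineState(100.0, 0.70)
    neutral = ConditionSpec("WT-like", "chronic")
    params = DEFAULT_RESPONSES["parenchyma"]
    base_mag = {}
    for lvl in levels:
        exp = proto[lvl]
        ev = experiment_events(exp)
        d_hbt, d_hbr = evoked_timecourse(ev, params, neutral, exp.breathing,
                                         exp.trial_length_s, DEFAULT_FRAME_RATE_HZ)
        i0 = int(round(exp.stim_onset_s * DEFAULT_FRAME_RATE_HZ))
        i1 = int(round((exp.stim_onset_s + exp.stim_duration_s)
                       * DEFAULT_FRAME_RATE_HZ))
        d_hbo = d_hbt - d_hbr
        base_mag[lvl] = {
            "Hbt": d_hbt[i0:i1].mean() / base.hbt_uM,
            "Hbo": d_hbo[i0:i1].mean() / base.hbo_uM,
            "Hbr": d_hbr[i0:i1].mean() / base.hbr_uM,
        }

    rows = []
    for gi, (gname, gscale) in enumerate(
            zip(("WT-like", "AD-like"), group_scales)):
        for si in range(n_per_group):
            subj = f"{'wt' if gi == 0 else 'ad'}{si + 1:02d}"
            gain = gscale * (1.0 + subject_sd * rng.standard_normal())
            for lvl in levels:
                for sp in ("Hbt", "Hbo", "Hbr"):
                    mag = (base_mag[lvl][sp] * gain
                           + noise_sd * rng.standard_normal())
                    rows.append((subj, gname, lvl, sp, mag))
    return pd.DataFrame(
        rows, columns=["subject", "group", "level", "species", "magnitude"])
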