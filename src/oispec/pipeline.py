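"""Session orchestration: dark correction, epoching, ROI selection,
response magnitudes, and session concatenation.

The analysis of one imaging session runs: dark-correct each experiment's
intensity stack -> attenuation relative to the experiment's baseline
window -> Beer-Lambert unmixing -> whisker-region ROI from the 16 s
oxygen experiment (pixels whose stimulation-window mean exceeds the
pre-stimulus baseline by 1.5 SD) -> per-experiment trial averages and
mean response magnitudes -> vessel compartments by PCA -> concatenated
whole-session time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import compartments as _compartments
from .beer_lambert import (
    ConcentrationMovies,
    compute_attenuation,
    estimate_air_baseline,
    unmix_stack,
)
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    StageError,
    ValidationError,
)
from .montecarlo import PathLengthTable
from .phantom import SessionRecording
from .spectra import BaselineState, ExtinctionTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialTensor:
    """Stimulus-aligned epochs: (n_trials, n_frames, ...) with a time axis
    relative to stimulus onset (negative = pre-stimulus)."""

    values: np.ndarray
    time_axis_s: np.ndarray
    n_trials: int

    def __post_init__(self):
        if self.values.shape[0] != self.n_trials:
            raise ValidationError("trial axis does not match n_trials")
        if self.time_axis_s[0] >= 0:
            raise ValidationError("epoch must include a pre-stimulus interval")


@dataclass(frozen=True)
class RoiMask:
    """Activated-region mask with its selection metadata."""

    pixels: np.ndarray
    k_sd: float
    source_experiment: str

    def __post_init__(self):
        if not self.pixels.any():
            raise ValidationError("ROI mask must be non-empty")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


def dark_correct(stack: np.ndarray, dark_frame: np.ndarray) -> np.ndarray:
    """Subtract a dark image from an intensity stack, clamping at zero.

    ``stack`` is (wavelength, t, y, x); the dark frame is (y, x).  The
    number of clamped samples is logged.
    """
    stack = np.asarray(stack, dtype=float)
    dark_frame = np.asarray(dark_frame, dtype=float)
    if dark_frame.shape != stack.shape[-2:]:
        raise ConfigurationError(
            f"dark frame shape {dark_frame.shape} does not match image "
            f"grid {stack.shape[-2:]}"
        )
    out = stack - dark_frame[None, None]
    n_clamped = int((out < 0).sum())
    if n_clamped:
        log.info("dark_correct: clamped %d negative sample(s)", n_clamped)
        np.clip(out, 0.0, None, out=out)
    return out


def nearest_dark_frame(recording: SessionRecording, exp_id: str) -> np.ndarray:
    """The temporally nearest inter-experiment dark frame for an experiment."""
    if not recording.dark_frames:
        raise ConfigurationError("recording has no dark frames")
    exp_ids = [e.exp_id for e in recording.protocol.experiments]
    idx = exp_ids.index(exp_id)
    n_gaps = len(recording.dark_frames)
    gap = min(max(idx, 1), n_gaps)  # gap k sits after experiment k
    return recording.dark_frames[f"gap{gap}"]


def epoch_trials(data: np.ndarray, onsets_s: np.ndarray, pre_s: float,
                 post_s: float, rate_hz: float) -> TrialTensor:
    """Epoch a series or movie on stimulus-train onsets.

    ``data`` has time as its first axis.  Each epoch covers
    [onset - pre_s, onset + post_s); epochs overrunning the record are
    excluded with a log entry, and an error is raised if all are.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    if onsets_s.size == 0:
        raise ValidationError("no stimulus onsets to epoch on")
    n_pre = int(round(pre_s * rate_hz))
    n_post = int(round(post_s * rate_hz))
    n_total = data.shape[0]
    epochs = []
    n_skipped = 0
    for on in onsets_s:
        c = int(round(on * rate_hz))
        if c - n_pre < 0 or c + n_post > n_total:
            n_skipped += 1
            continue
        epochs.append(data[c - n_pre:c + n_post])
    if n_skipped:
        log.info("epoch_trials: excluded %d trial(s) outside record", n_skipped)
    if not epochs:
        raise ValidationError("all trials fall outside the record")
    values = np.stack(epochs)
    time_axis = (np.arange(-n_pre, n_post) + 0.0) / rate_hz
    return TrialTensor(values=values, time_axis_s=time_axis,
                       n_trials=len(epochs))


def trial_average(tensor: TrialTensor) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation over trials."""
    if tensor.n_trials < 2:
        raise ValidationError("trial SD undefined for fewer than 2 trials")
    return tensor.values.mean(axis=0), tensor.values.std(axis=0, ddof=1)


def select_whisker_roi(
    hbt_trial_avg: TrialTensor,
    stim_window_s: tuple[float, float],
    prestim_window_s: tuple[float, float] | None = None,
    k_sd: float = 1.5,
    window_mask: np.ndarray | None = None,
    source_experiment: str = "exp7",
) -> RoiMask:
    """Activated-region pixels from the trial-averaged Hbt movie.

    A pixel is included iff its stimulation-window mean exceeds its
    pre-stimulus mean by ``k_sd`` pre-stimulus standard deviations.
    Pixels with zero pre-stimulus SD (or NaN) are excluded with a log
    entry; an empty result raises a no-activation error.

    Parameters
    ----------
    hbt_trial_avg
        TrialTensor of the trial-averaged movie (n_trials=1 tensors are
        accepted: pass the average wrapped with a leading axis) or the
        raw trial tensor, which is averaged here.
    stim_window_s, prestim_window_s
        Intervals on the epoch time axis (0 = stimulus onset); the
        pre-stimulus window defaults to everything before onset.
    """
    t = hbt_trial_avg.time_axis_s
    movie = hbt_trial_avg.values.mean(axis=0)
    if movie.ndim != 3:
        raise ValidationError("ROI selection needs a (t, y, x) movie")
    if prestim_window_s is None:
        prestim_window_s = (float(t[0]), 0.0)
    pre = (t >= prestim_window_s[0]) & (t < prestim_window_s[1])
    stim = (t >= stim_window_s[0]) & (t < stim_window_s[1])
    if not pre.any() or not stim.any():
        raise ValidationError("empty stimulation or pre-stimulus window")
    mean_pre = movie[pre].mean(axis=0)
    sd_pre = movie[pre].std(axis=0, ddof=1)
    mean_stim = movie[stim].mean(axis=0)
    usable = np.isfinite(mean_pre) & np.isfinite(mean_stim) & (sd_pre > 0)
    n_zero = int((~usable).sum())
    if n_zero:
        log.info("select_whisker_roi: %d pixel(s) excluded (zero SD or NaN)",
                 n_zero)
    mask = usable & (mean_stim > mean_pre + k_sd * sd_pre)
    if window_mask is not None:
        mask &= window_mask
    if not mask.any():
        raise DegenerateDataError(
            f"no pixels exceed the pre-stimulus baseline by {k_sd} SD"
        )
    return RoiMask(pixels=mask, k_sd=k_sd, source_experiment=source_experiment)


def roi_timeseries(movie: np.ndarray, mask: RoiMask | np.ndarray) -> np.ndarray:
    """Unweighted ROI-mean series of a (t, y, x) movie (NaNs excluded)."""
    pixels = mask.pixels if isinstance(mask, RoiMask) else np.asarray(mask, bool)
    if not pixels.any():
        raise ValidationError("empty ROI mask")
    return np.nanmean(movie[:, pixels], axis=1)


def response_magnitude(fractional_series: np.ndarray,
                       stim_window: tuple[int, int]) -> float:
    """Mean fractional deviation from baseline over the stimulation window.

    ``stim_window`` is a half-open frame interval; the series is a
    fractional (baseline = 1) time course.
    """
    i0, i1 = stim_window
    series = np.asarray(fractional_series, dtype=float)
    if not (0 <= i0 < i1 <= series.shape[0]):
        raise ValidationError(
            f"stimulation window [{i0}, {i1}) outside series of "
            f"{series.shape[0]} frames"
        )
    return float(np.nanmean(series[i0:i1]) - 1.0)


@dataclass(frozen=True)
class ConcatenatedSeries:
    """Whole-session series on the session clock with annotated gaps."""

    values: np.ndarray
    times_s: np.ndarray
    segments: tuple  # (exp_id, start_index, end_index) per experiment
    frame_rate_hz: float

    @property
    def gap_mask(self) -> np.ndarray:
        m = np.ones(self.values.shape[0], dtype=bool)
        for _, i0, i1 in self.segments:
            m[i0:i1] = False
        return m


def concatenate_session(
    series_by_exp: dict[str, np.ndarray],
    protocol,
    frame_rate_hz: float,
) -> ConcatenatedSeries:
    """Join per-experiment series on the session clock.

    Inter-experiment gaps are represented as NaN runs (marked, never
    interpolated); experiments appear in protocol order at their session
    offsets.
    """
    offsets = protocol.session_offsets_s()
    n_total = int(round(protocol.session_length_s * frame_rate_hz))
    values = np.full(n_total, np.nan)
    segments = []
    for exp in protocol.experiments:
        if exp.exp_id not in series_by_exp:
            continue
        s = np.asarray(series_by_exp[exp.exp_id], dtype=float)
        expected = int(round(exp.total_length_s * frame_rate_hz))
        if s.shape[0] != expected:
            raise ValidationError(
                f"{exp.exp_id}: series length {s.shape[0]} does not match "
                f"{expected} frames at {frame_rate_hz:g} Hz"
            )
        i0 = int(round(offsets[exp.exp_id] * frame_rate_hz))
        values[i0:i0 + expected] = s
        segments.append((exp.exp_id, i0, i0 + expected))
    if not segments:
        raise ValidationError("no experiments to concatenate")
    times = np.arange(n_total) / frame_rate_hz
    return ConcatenatedSeries(values=values, times_s=times,
                              segments=tuple(segments),
                              frame_rate_hz=frame_rate_hz)


# --------------------------------------------------------------------------
# orchestrator
# --------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Everything the session analysis needs beyond the recording."""

    table: ExtinctionTable
    paths: PathLengthTable
    oxygen_baseline: BaselineState = BaselineState(100.0, 0.70, "oxygen")
    k_sd: float = 1.5
    roi_source_experiment: str = "exp7"
    compartment_quantile: float = 0.8
    #: settle window for the air-baseline estimate, as fractions of the
    #: gas-record length (well after the switch, before the record end)
    settle_fraction: tuple[float, float] = (0.6, 0.95)
    estimate_air: bool = True


@dataclass
class ExperimentResult:
    exp_id: str
    kind: str
    baseline_used: BaselineState
    roi_series: dict  # species -> fractional ROI series
    trial_mean: dict | None  # species -> (mean, sd) epochs, ROI series
    time_axis_s: np.ndarray | None
    magnitudes: dict | None  # species -> mean fractional response


@dataclass
class SessionResult:
    roi: RoiMask
    air_baseline: BaselineState | None
    experiments: dict  # exp_id -> ExperimentResult
    artery_mask: np.ndarray | None
    vein_mask: np.ndarray | None
    compartment_series: dict  # exp_id -> {compartment: {species: series}}
    concatenated_hbt: ConcatenatedSeries
    stage_log: list
    meta: dict = field(default_factory=dict)


_SPECIES = ("Hbt", "Hbo", "Hbr")


def _fractional(movies: ConcentrationMovies, species: str) -> np.ndarray:
    return {"Hbt": movies.fractional_hbt, "Hbo": movies.fractional_hbo,
            "Hbr": movies.fractional_hbr}[species]


def run_session(recording: SessionRecording,
                config: AnalysisConfig) -> SessionResult:
    """Run the full analysis of one session recording.

    Stage order: dark correction and unmixing of the oxygen-to-air
    record to estimate the air baseline; the ROI-source experiment to
    select the activated region; then every experiment's ROI series,
    trial averages and response magnitudes; vessel compartments by PCA
    on the ROI-source movies; and the concatenated session Hbt series.
    Failures are re-raised tagged with the stage name.
    """
    stage_log: list[str] = []
    proto = recording.protocol
    rate = recording.frame_rate_hz
    window_mask = (recording.phantom.window_mask
                   if recording.phantom is not None else None)

    def movies_for(exp_id: str, baseline: BaselineState) -> ConcentrationMovies:
        exp = proto[exp_id]
        if exp_id not in recording.intensities:
            raise ValidationError(f"recording has no data for {exp_id}")
        corrected = dark_correct(recording.intensities[exp_id],
                                 nearest_dark_frame(recording, exp_id))
        if window_mask is not None:
            # outside the cranial window there is no tissue signal; keep
            # the pixels but they carry baseline intensity only
            pass
        w0, w1 = exp.baseline_window_s
        att = compute_attenuation(
            corrected, (int(round(w0 * rate)), int(round(w1 * rate))),
            recording.wavelengths_nm, rate)
        return unmix_stack(att, config.table, config.paths, baseline)

    # ---- air baseline from the oxygen-to-air transition -------------
    air_baseline: BaselineState | None = None
    gas_id = next((e.exp_id for e in proto.experiments
                   if e.kind == "gas_to_air"
                   and e.exp_id in recording.intensities), None)
    if config.estimate_air and gas_id is not None:
        try:
            gas_movies = movies_for(gas_id, config.oxygen_baseline)
            exp = proto[gas_id]
            f0, f1 = config.settle_fraction
            settle = (f0 * exp.total_length_s, f1 * exp.total_length_s)
            if settle[0] <= exp.gas_switch_s:
                raise ValidationError("settle window precedes the gas switch")
            air_baseline = estimate_air_baseline(
                gas_movies, config.oxygen_baseline, settle,
                roi_mask=window_mask)
            stage_log.append(
                f"air_baseline: {air_baseline.hbt_uM:.2f} uM, "
                f"so2 {air_baseline.so2:.3f} (from {gas_id})")
            del gas_movies
        except Exception as e:  # noqa: BLE001
            raise StageError("air_baseline", e) from e

    def baseline_for(exp) -> BaselineState:
        if exp.breathing == "air" and air_baseline is not None:
            return air_baseline
        return config.oxygen_baseline

    # ---- ROI from the 16 s oxygen experiment -------------------------
    roi_id = config.roi_source_experiment
    try:
        roi_exp = proto[roi_id] if roi_id in [e.exp_id for e in
                                              proto.experiments] else None
        if roi_exp is None or roi_id not in recording.intensities:
            raise ValidationError(f"ROI source experiment {roi_id!r} missing")
        roi_movies = movies_for(roi_id, baseline_for(roi_exp))
        onsets = recording.experiment_events(roi_id)
        onsets = onsets.loc[onsets["kind"] == "stim_train_on",
                            "time_s"].to_numpy()
        tens = epoch_trials(roi_movies.fractional_hbt, onsets,
                            pre_s=roi_exp.stim_onset_s,
                            post_s=roi_exp.trial_length_s - roi_exp.stim_onset_s,
                            rate_hz=rate)
        roi = select_whisker_roi(
            tens, stim_window_s=(0.0, roi_exp.stim_duration_s),
            k_sd=config.k_sd, window_mask=window_mask,
            source_experiment=roi_id)
        stage_log.append(f"roi: {roi.n_pixels} pixel(s) from {roi_id}")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("roi", e) from e

    # ---- vessel compartments on the ROI-source movies ----------------
    artery_mask = vein_mask = None
    try:
        stim_reg = np.zeros(roi_movies.n_frames)
        for on in onsets:
            i0 = int(round(on * rate))
            i1 = int(round((on + roi_exp.stim_duration_s) * rate))
            stim_reg[i0:i1] = 1.0
        hbt_map = _compartments.first_principal_map(
            roi_movies.d_hbt, roi.pixels, stimulus_regressor=stim_reg)
        hbr_map = _compartments.first_principal_map(
            roi_movies.d_hbr, roi.pixels, stimulus_regressor=-stim_reg)
        artery_mask, vein_mask = _compartments.vessel_masks(
            hbt_map, hbr_map, roi, quantile=config.compartment_quantile)
        stage_log.append(
            f"compartments: artery {int(artery_mask.sum())} px, "
            f"vein {int(vein_mask.sum())} px")
    except Exception as e:  # noqa: BLE001
        raise StageError("compartments", e) from e

    # ---- per-experiment analysis -------------------------------------
    results: dict[str, ExperimentResult] = {}
    comp_series: dict[str, dict] = {}
    concat_input: dict[str, np.ndarray] = {}
    for exp in proto.experiments:
        if exp.exp_id not in recording.intensities:
            continue
        try:
            movies = (roi_movies if exp.exp_id == roi_id
                      else movies_for(exp.exp_id, baseline_for(exp)))
            roi_series = {sp: roi_timeseries(_fractional(movies, sp), roi)
                          for sp in _SPECIES}
            concat_input[exp.exp_id] = roi_series["Hbt"]
            trial_mean = None
            time_axis = None
            mags = None
            if exp.is_stim:
                ev = recording.experiment_events(exp.exp_id)
                ons = ev.loc[ev["kind"] == "stim_train_on", "time_s"].to_numpy()
                trial_mean = {}
                mags = {}
                for sp in _SPECIES:
                    tens = epoch_trials(
                        roi_series[sp], ons, pre_s=exp.stim_onset_s,
                        post_s=exp.trial_length_s - exp.stim_onset_s,
                        rate_hz=rate)
                    mean, sd = trial_average(tens)
                    trial_mean[sp] = (mean, sd)
                    time_axis = tens.time_axis_s
                    i0 = int(round(exp.stim_onset_s * rate))
                    i1 = int(round((exp.stim_onset_s + exp.stim_duration_s)
                                   * rate))
                    mags[sp] = response_magnitude(mean, (i0, i1))
                comp_series[exp.exp_id] = _compartments.compartment_series(
                    movies, {"artery": artery_mask, "vein": vein_mask})
            results[exp.exp_id] = ExperimentResult(
                exp_id=exp.exp_id, kind=exp.kind,
                baseline_used=movies.baseline, roi_series=roi_series,
                trial_mean=trial_mean, time_axis_s=time_axis, magnitudes=mags)
            if exp.exp_id != roi_id:
                del movies
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(exp.exp_id, e) from e

    try:
        concatenated = concatenate_session(concat_input, proto, rate)
    except Exception as e:  # noqa: BLE001
        raise StageError("concatenate", e) from e

    return SessionResult(
        roi=roi, air_baseline=air_baseline, experiments=results,
        artery_mask=artery_mask, vein_mask=vein_mask,
        compartment_series=comp_series, concatenated_hbt=concatenated,
        stage_log=stage_log,
        meta=dict(recording.meta, k_sd=config.k_sd,
                  roi_source=config.roi_source_experiment))
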