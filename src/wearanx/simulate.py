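"""Synthetic multimodal wearable recordings with controllable anxiety physiology.

The generator emulates a two-device setup: a chest garment recording ECG
(256 Hz), respiration (128 Hz) and 3-axis acceleration (64 Hz), and a wrist
device recording blood volume pulse (64 Hz), electrodermal activity (4 Hz),
skin temperature (4 Hz) and 3-axis acceleration (32 Hz).  Every subject has a
ground-truth physiological profile; the anxious state shifts heart rate,
RR-interval variability, respiration rate, skin-conductance response rate and
skin temperature by additive deltas, so downstream feature extraction and
classification can be validated against known structure.

Cohorts come in three subsets mirroring increasingly uncontrolled conditions:
``calibration`` (seated, fixed environment), ``in_lab`` (seated / standing /
walking, fixed environment) and ``in_the_wild`` (variable activity, extra
channel noise, class imbalance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidParameterError, InvalidPlanError
from .preprocess import NoiseSpec, add_gaussian_noise

__all__ = [
    "AnxietyDeltas",
    "SubjectProfile",
    "ConditionInterval",
    "Channel",
    "MultimodalRecording",
    "CohortConfig",
    "CHANNEL_RATES",
    "DEVICE_TAG",
    "generate_ecg",
    "generate_eda",
    "generate_resp",
    "generate_acc",
    "generate_temp",
    "generate_bvp",
    "generate_session",
    "generate_cohort",
    "build_plan",
]

# Sampling rates, Hz.  Chest rates follow the smart-shirt convention
# (ECG 256, RESP 128, ACC 64); wrist rates follow public E4 documentation
# (BVP 64, EDA 4, TEMP 4, ACC 32) and are echoed in recording metadata so
# they stay overridable.
CHANNEL_RATES: dict[str, float] = {
    "ECG": 256.0,
    "RESP": 128.0,
    "ACC_C_x": 64.0,
    "ACC_C_y": 64.0,
    "ACC_C_z": 64.0,
    "BVP": 64.0,
    "EDA": 4.0,
    "TEMP": 4.0,
    "ACC_w_x": 32.0,
    "ACC_w_y": 32.0,
    "ACC_w_z": 32.0,
}

DEVICE_TAG: dict[str, str] = {
    "ECG": "chest",
    "RESP": "chest",
    "ACC_C_x": "chest",
    "ACC_C_y": "chest",
    "ACC_C_z": "chest",
    "BVP": "wrist",
    "EDA": "wrist",
    "TEMP": "wrist",
    "ACC_w_x": "wrist",
    "ACC_w_y": "wrist",
    "ACC_w_z": "wrist",
}

ANXIOUS_CONDITIONS = {"cold_pressor", "tsst", "stroop_seated", "stroop_walking"}
CONDITION_ACTIVITY = {
    "relaxation": "seated",
    "cold_pressor": "seated",
    "tsst": "standing",
    "stroop_seated": "seated",
    "stroop_walking": "walking",
    "wild": "variable",
}

_STAI_MIN, _STAI_CUTOFF, _STAI_MAX = 6, 11, 24
_RR_LO, _RR_HI = 0.3, 2.0  # physiological truncation of RR draws, s


@dataclass
class AnxietyDeltas:
    """Additive shifts applied in the anxious state.

    Defaults are placeholder effect sizes of plausible magnitude for acute
    anxiety (sympathetic activation: HR up, HRV down, breathing faster, more
    skin-conductance responses, peripheral skin temperature down through
    vasoconstriction); they are configuration, not empirical claims.
    """

    hr_delta: float = 12.0        # beats/min, > 0
    sdnn_delta: float = -0.015    # s, < 0
    resp_delta: float = 4.0       # breaths/min, > 0
    scr_delta: float = 4.0        # responses/min, > 0
    temp_delta: float = -0.5      # degC


@dataclass
class SubjectProfile:
    """Ground-truth baseline physiology of one simulated subject."""

    baseline_hr: float = 70.0    # beats/min
    sdnn: float = 0.05           # RR-interval standard deviation, s
    resp_rate: float = 14.0      # breaths/min
    ie_ratio: float = 0.8        # inhale/exhale duration ratio
    eda_tonic: float = 2.0       # microsiemens
    scr_rate: float = 3.0        # skin-conductance responses / min
    temp_base: float = 33.0      # degC (wrist skin)
    deltas: AnxietyDeltas = field(default_factory=AnxietyDeltas)

    def __post_init__(self) -> None:
        if not (40.0 <= self.baseline_hr <= 180.0):
            raise InvalidParameterError(f"baseline_hr {self.baseline_hr} outside [40, 180]")
        if self.sdnn < 0:
            raise InvalidParameterError("sdnn must be >= 0")
        if not (6.0 <= self.resp_rate <= 40.0):
            raise InvalidParameterError(f"resp_rate {self.resp_rate} outside [6, 40]")
        if self.ie_ratio <= 0:
            raise InvalidParameterError("ie_ratio must be > 0")
        if self.scr_rate < 0:
            raise InvalidParameterError("scr_rate must be >= 0")
        for name in ("baseline_hr", "sdnn", "resp_rate", "ie_ratio", "eda_tonic",
                     "scr_rate", "temp_base"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def in_state(self, anxious: bool) -> "SubjectProfile":
        """Profile with anxiety deltas applied (clipped to valid ranges)."""
        if not anxious:
            return self
        d = self.deltas
        return replace(
            self,
            baseline_hr=float(np.clip(self.baseline_hr + d.hr_delta, 40.0, 180.0)),
            sdnn=max(self.sdnn + d.sdnn_delta, 0.0),
            resp_rate=float(np.clip(self.resp_rate + d.resp_delta, 6.0, 40.0)),
            scr_rate=max(self.scr_rate + d.scr_delta, 0.0),
            temp_base=self.temp_base + d.temp_delta,
        )


@dataclass
class ConditionInterval:
    """A contiguous block of one experimental condition within a session."""

    start_s: float
    end_s: float
    condition: str
    stai_y6: int = _STAI_MIN
    anxious_truth: int = 0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise InvalidParameterError("interval end_s must exceed start_s")
        if self.condition not in CONDITION_ACTIVITY:
            raise InvalidParameterError(f"unknown condition {self.condition!r}")
        if not (_STAI_MIN <= self.stai_y6 <= _STAI_MAX):
            raise InvalidParameterError("stai_y6 outside [6, 24]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Channel:
    samples: np.ndarray
    fs: float


@dataclass
class MultimodalRecording:
    """Per-channel sampled series plus annotations and generator ground truth."""

    channels: dict[str, Channel]
    annotations: list[ConditionInterval]
    true_beats_s: np.ndarray | None = None
    subject_id: str = "S00"
    device_tag: dict[str, str] = field(default_factory=lambda: dict(DEVICE_TAG))
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.annotations[-1].end_s if self.annotations else 0.0


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort."""

    n_subjects: int = 10
    subset: str = "calibration"  # calibration | in_lab | in_the_wild
    session_duration_s: float = 1800.0
    wild_anxious_frac: float = 0.1934  # anxious-time fraction in the wild
    label_noise: float = 0.05          # probability a STAI score crosses the cutoff
    wild_noise_snr: float | None = 20.0  # extra channel noise in the wild (linear SNR)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.subset not in ("calibration", "in_lab", "in_the_wild"):
            raise InvalidParameterError(f"unknown subset {self.subset!r}")
        if not (0.0 < self.wild_anxious_frac < 1.0):
            raise InvalidParameterError("wild_anxious_frac must lie in (0, 1)")


def _check_duration_fs(duration_s: float, fs: float, min_fs: float) -> int:
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be > 0")
    if fs < min_fs:
        raise InvalidParameterError(f"fs must be >= {min_fs} Hz")
    return int(round(duration_s * fs))


def _draw_rr(profile: SubjectProfile, duration_s: float, state: bool,
             rng: np.random.Generator) -> np.ndarray:
    """RR intervals i.i.d. normal(60/hr, sdnn) truncated to [0.3, 2.0] s."""
    p = profile.in_state(state)
    if p.baseline_hr <= 0:
        raise InvalidParameterError("heart rate must be positive")
    mean_rr = 60.0 / p.baseline_hr
    sd = p.sdnn
    n_max = int(duration_s / _RR_LO) + 2
    if sd == 0.0:
        return np.full(n_max, mean_rr)
    rr = rng.normal(mean_rr, sd, size=n_max)
    bad = (rr < _RR_LO) | (rr > _RR_HI)
    while bad.any():  # rejection sampling keeps the distribution truncated-normal
        rr[bad] = rng.normal(mean_rr, sd, size=int(bad.sum()))
        bad = (rr < _RR_LO) | (rr > _RR_HI)
    return rr


def _render_bumps(t: np.ndarray, fs: float, centers: np.ndarray,
                  amps: np.ndarray, sigma_s: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bumps, each rendered only on its +/-5 sigma support."""
    out = np.zeros_like(t)
    n = t.size
    for c, a, s in zip(centers, amps, sigma_s):
        lo = max(0, int((c - 5 * s) * fs))
        hi = min(n, int((c + 5 * s) * fs) + 1)
        if lo >= hi:
            continue
        seg = t[lo:hi] - c
        out[lo:hi] += a * np.exp(-0.5 * (seg / s) ** 2)
    return out


def generate_ecg(profile: SubjectProfile, duration_s: float, fs: float = 256.0,
                 state: bool = False, seed: int = 0, *,
                 noise_std: float = 0.01, wander_amp: float = 0.05,
                 wander_freq: float = 0.2, qrs_width_s: float = 0.01,
                 qrs_amp: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic single-lead ECG: QRS Gaussian template train plus baseline
    wander and white measurement noise.

    Returns ``(series, true_beats_s)``; beat times are exact ground truth.
    The QRS template is a Gaussian bump of sigma ``qrs_width_s`` (~40 ms full
    width); morphology realism is out of scope — only the peak structure
    matters downstream.
    """
    n = _check_duration_fs(duration_s, fs, 64.0)
    rng = np.random.default_rng(seed)
    rr = _draw_rr(profile, duration_s, state, rng)
    # half-interval phase offset keeps every beat apex strictly inside the
    # sampled record (a beat at exactly duration_s would be unobservable)
    beats = np.cumsum(rr) - rr[0] / 2.0
    beats = beats[beats <= duration_s]
    t = np.arange(n) / fs
    series = _render_bumps(t, fs, beats, np.full(beats.size, qrs_amp),
                           np.full(beats.size, qrs_width_s))
    if wander_amp:
        series += wander_amp * np.sin(2 * np.pi * wander_freq * t)
    if noise_std:
        series += rng.normal(0.0, noise_std, n)
    return series, beats


def generate_bvp(profile: SubjectProfile, duration_s: float, fs: float = 64.0,
                 state: bool = False, seed: int = 0, *,
                 noise_std: float = 0.01) -> np.ndarray:
    """Blood volume pulse sharing the ECG RR sequence for the same seed.

    Each beat is a systolic bump plus a smaller, delayed dicrotic bump, so
    the dominant spectral frequency equals the heart rate in Hz.
    """
    n = _check_duration_fs(duration_s, fs, 16.0)
    rng = np.random.default_rng(seed)
    rr = _draw_rr(profile, duration_s, state, rng)  # same draw order as ECG
    beats = np.cumsum(rr) - rr[0] / 2.0
    beats = beats[beats <= duration_s]
    t = np.arange(n) / fs
    systolic = _render_bumps(t, fs, beats + 0.20, np.full(beats.size, 1.0),
                             np.full(beats.size, 0.06))
    dicrotic = _render_bumps(t, fs, beats + 0.45, np.full(beats.size, 0.3),
                             np.full(beats.size, 0.08))
    series = systolic + dicrotic
    if noise_std:
        series += rng.normal(0.0, noise_std, n)
    return series


_SCR_RISE_S, _SCR_DECAY_S = 0.5, 4.0


def generate_eda(profile: SubjectProfile, duration_s: float, fs: float = 4.0,
                 state: bool = False, seed: int = 0, *,
                 noise_std: float = 0.01, drift_amp: float = 0.1,
                 scr_amp: float = 0.3,
                 return_events: bool = False):
    """Electrodermal activity: tonic level + slow drift + Poisson SCR train.

    Each skin-conductance response is a bi-exponential pulse (rise ~0.5 s,
    decay 4 s, peak ~1 s after onset) of amplitude ``scr_amp`` microsiemens.
    The series is clipped at zero (conductance cannot be negative).
    """
    n = _check_duration_fs(duration_s, fs, 2.0)
    p = profile.in_state(state)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    series = np.full(n, p.eda_tonic)
    if drift_amp:
        phase = rng.uniform(0, 2 * np.pi)
        series += drift_amp * np.sin(2 * np.pi * 0.003 * t + phase)
    # Poisson SCR event times via exponential gaps.
    rate_per_s = p.scr_rate / 60.0
    events = []
    if rate_per_s > 0:
        t_ev = rng.exponential(1.0 / rate_per_s)
        while t_ev < duration_s:
            events.append(t_ev)
            t_ev += rng.exponential(1.0 / rate_per_s)
    events_arr = np.asarray(events)
    if events_arr.size:
        # bi-exponential kernel normalized to peak scr_amp
        tau = np.arange(0, int(8 * _SCR_DECAY_S * fs)) / fs
        kernel = np.exp(-tau / _SCR_DECAY_S) - np.exp(-tau / _SCR_RISE_S)
        kernel *= scr_amp / kernel.max()
        for ev in events_arr:
            lo = int(ev * fs)
            hi = min(n, lo + kernel.size)
            series[lo:hi] += kernel[: hi - lo]
    if noise_std:
        series += rng.normal(0.0, noise_std, n)
    series = np.clip(series, 0.0, None)
    if return_events:
        return series, events_arr
    return series


def generate_resp(profile: SubjectProfile, duration_s: float, fs: float = 128.0,
                  state: bool = False, seed: int = 0, *,
                  amp: float = 1.0, jitter_cv: float = 0.05,
                  noise_std: float = 0.005, return_cycles: bool = False):
    """Respiration as a lung-volume-like waveform with inhale/exhale asymmetry.

    Each breath rises from trough to peak over the inhale (duration fraction
    ``ie_ratio / (1 + ie_ratio)`` of the cycle) and falls back over the
    exhale, as half-cosine segments; cycle durations are jittered with
    coefficient of variation ``jitter_cv``.  With ``return_cycles=True`` the
    ground-truth ``(t_start, t_peak, t_end)`` of each breath is returned too.
    """
    n = _check_duration_fs(duration_s, fs, 8.0)
    p = profile.in_state(state)
    if p.ie_ratio <= 0:
        raise InvalidParameterError("ie_ratio must be > 0")
    rng = np.random.default_rng(seed)
    mean_T = 60.0 / p.resp_rate
    in_frac = p.ie_ratio / (1.0 + p.ie_ratio)
    series = np.zeros(n)
    cycles: list[tuple[float, float, float]] = []
    t0 = 0.0
    while t0 < duration_s:
        T = mean_T if jitter_cv == 0 else float(
            np.clip(rng.normal(mean_T, jitter_cv * mean_T), 0.4 * mean_T, 2.5 * mean_T))
        t_in = T * in_frac
        i0 = int(round(t0 * fs))
        i_pk = min(int(round((t0 + t_in) * fs)), n)
        i1 = min(int(round((t0 + T) * fs)), n)
        tt = np.arange(i0, i_pk) / fs
        series[i0:i_pk] = -amp * np.cos(np.pi * (tt - t0) / t_in)
        tt = np.arange(i_pk, i1) / fs
        if i1 > i_pk:
            series[i_pk:i1] = amp * np.cos(np.pi * (tt - t0 - t_in) / (T - t_in))
        cycles.append((t0, t0 + t_in, t0 + T))
        t0 += T
    if noise_std:
        series += rng.normal(0.0, noise_std, n)
    if return_cycles:
        return series, cycles
    return series


_ACTIVITIES = ("seated", "standing", "walking", "variable")


def _activity_component(activity: str, t: np.ndarray, rng: np.random.Generator,
                        base_noise: float, walk_freq: float,
                        walk_amp: float) -> np.ndarray:
    """Zero-gravity activity acceleration, shape (3, n), in g."""
    n = t.size
    if activity == "seated":
        return rng.normal(0.0, base_noise, (3, n))
    if activity == "standing":
        sway = 0.01 * np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 2 * np.pi))
        out = rng.normal(0.0, 1.5 * base_noise, (3, n))
        out[0] += sway
        return out
    if activity == "walking":
        phase = rng.uniform(0, 2 * np.pi)
        step = walk_amp * np.sin(2 * np.pi * walk_freq * t + phase)
        harm = 0.3 * walk_amp * np.sin(4 * np.pi * walk_freq * t + phase)
        out = rng.normal(0.0, 5 * base_noise, (3, n))
        out[2] += step + harm
        out[0] += 0.4 * step
        return out
    raise InvalidParameterError(f"unknown activity {activity!r}")


def generate_acc(activity: str, duration_s: float, fs: float = 64.0,
                 seed: int = 0, *, gravity_axis: str = "z",
                 base_noise: float = 0.01, walk_freq: float = 2.0,
                 walk_amp: float = 0.3,
                 mean_dwell_s: float = 30.0) -> np.ndarray:
    """3-axis accelerometer trace in g, shape ``(3, n)``.

    Gravity is a constant unit vector along ``gravity_axis`` ('z' for the
    chest device, 'x' tilted for the wrist).  ``variable`` alternates seated /
    standing / walking regimes on exponential dwell times.
    """
    if activity not in _ACTIVITIES:
        raise InvalidParameterError(f"unknown activity {activity!r}")
    n = _check_duration_fs(duration_s, fs, 16.0)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if activity == "variable":
        comp = np.zeros((3, n))
        i0 = 0
        while i0 < n:
            regime = str(rng.choice(["seated", "standing", "walking"]))
            dwell = max(int(rng.exponential(mean_dwell_s) * fs), int(2 * fs))
            i1 = min(n, i0 + dwell)
            comp[:, i0:i1] = _activity_component(
                regime, t[i0:i1], rng, base_noise, walk_freq, walk_amp)
            i0 = i1
    else:
        comp = _activity_component(activity, t, rng, base_noise, walk_freq, walk_amp)
    g = np.zeros((3, 1))
    if gravity_axis == "z":
        g[2, 0] = 1.0
    elif gravity_axis == "x":
        # wrist resting pose: gravity mostly along x, slightly tilted
        g[:, 0] = np.array([0.95, 0.20, 0.24])
        g /= np.linalg.norm(g)
    else:
        raise InvalidParameterError("gravity_axis must be 'x' or 'z'")
    return g + comp


def generate_temp(profile: SubjectProfile, duration_s: float, fs: float = 4.0,
                  state: bool = False, seed: int = 0, *,
                  drift_std: float = 0.005, noise_std: float = 0.01) -> np.ndarray:
    """Skin temperature: base level (shifted when anxious) + random-walk drift."""
    n = _check_duration_fs(duration_s, fs, 1.0)
    p = profile.in_state(state)
    rng = np.random.default_rng(seed)
    series = np.full(n, p.temp_base)
    if drift_std:
        series += np.cumsum(rng.normal(0.0, drift_std / math.sqrt(fs), n))
    if noise_std:
        series += rng.normal(0.0, noise_std, n)
    return series


def _validate_plan(plan: list[ConditionInterval]) -> float:
    if not plan:
        raise InvalidPlanError("empty session plan")
    t = plan[0].start_s
    if t != 0.0:
        raise InvalidPlanError("plan must start at t = 0")
    for iv in plan:
        if iv.start_s < t - 1e-9:
            raise InvalidPlanError("plan intervals overlap or are unordered")
        if abs(iv.start_s - t) > 1e-6:
            raise InvalidPlanError("plan intervals must be contiguous")
        t = iv.end_s
    return t


def _sample_stai(anxious: bool, rng: np.random.Generator, label_noise: float) -> int:
    flip = rng.random() < label_noise
    anxious = bool(anxious) != flip
    if anxious:
        return int(rng.integers(_STAI_CUTOFF, 21))
    return int(rng.integers(_STAI_MIN, _STAI_CUTOFF))


def generate_session(profile: SubjectProfile, plan: list[ConditionInterval],
                     seed: int = 0, *, label_noise: float = 0.05,
                     extra_noise_snr: float | None = None,
                     subject_id: str = "S00",
                     rates: dict[str, float] | None = None) -> MultimodalRecording:
    """Render a full multi-channel session from a condition plan.

    Channels are generated interval-by-interval in the interval's anxiety
    state and concatenated.  STAI Y6 scores are sampled consistently with the
    ground-truth state except with probability ``label_noise``, where they
    cross the cutoff (supports sub-ceiling classification accuracy).
    """
    _validate_plan(plan)
    rates = dict(CHANNEL_RATES if rates is None else rates)
    ss = np.random.SeedSequence(seed)
    stai_rng = np.random.default_rng(ss.spawn(1)[0])
    annotations: list[ConditionInterval] = []
    parts: dict[str, list[np.ndarray]] = {name: [] for name in rates}
    beats_all: list[np.ndarray] = []
    for idx, iv in enumerate(plan):
        anx = bool(iv.anxious_truth) if iv.condition == "wild" \
            else iv.condition in ANXIOUS_CONDITIONS
        child = np.random.SeedSequence(seed, spawn_key=(idx + 1,))
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in child.spawn(6)]
        dur = iv.duration_s
        ecg, beats = generate_ecg(profile, dur, rates["ECG"], anx, seeds[0])
        parts["ECG"].append(ecg)
        beats_all.append(beats + iv.start_s)
        parts["BVP"].append(generate_bvp(profile, dur, rates["BVP"], anx, seeds[0]))
        parts["RESP"].append(generate_resp(profile, dur, rates["RESP"], anx, seeds[1]))
        parts["EDA"].append(generate_eda(profile, dur, rates["EDA"], anx, seeds[2]))
        parts["TEMP"].append(generate_temp(profile, dur, rates["TEMP"], anx, seeds[3]))
        activity = CONDITION_ACTIVITY[iv.condition]
        acc_c = generate_acc(activity, dur, rates["ACC_C_x"], seeds[4], gravity_axis="z")
        acc_w = generate_acc(activity, dur, rates["ACC_w_x"], seeds[5], gravity_axis="x")
        for ax, name in enumerate(("ACC_C_x", "ACC_C_y", "ACC_C_z")):
            parts[name].append(acc_c[ax])
        for ax, name in enumerate(("ACC_w_x", "ACC_w_y", "ACC_w_z")):
            parts[name].append(acc_w[ax])
        annotations.append(ConditionInterval(
            iv.start_s, iv.end_s, iv.condition,
            stai_y6=_sample_stai(anx, stai_rng, label_noise),
            anxious_truth=int(anx)))
    channels = {name: Channel(np.concatenate(chunks), rates[name])
                for name, chunks in parts.items()}
    if extra_noise_snr is not None:
        for k, (name, ch) in enumerate(channels.items()):
            spec = NoiseSpec(snr_linear=extra_noise_snr, seed=seed * 131 + k)
            channels[name] = Channel(add_gaussian_noise(ch.samples, spec), ch.fs)
    return MultimodalRecording(
        channels=channels,
        annotations=annotations,
        true_beats_s=np.concatenate(beats_all) if beats_all else None,
        subject_id=subject_id,
        meta={"seed": seed, "label_noise": label_noise,
              "extra_noise_snr": extra_noise_snr, "rates": rates},
    )


# ---------------------------------------------------------------------------
# session plans

# Calibration alternates guided relaxation with a cold-pressor block in a
# 58/42 duty cycle, matching the reported calibration class balance.
_CAL_CYCLE = (("relaxation", 290.0), ("cold_pressor", 210.0))
# The in-lab session cycles relaxation with three anxiety-induction tasks
# (social stress standing, seated and walking Stroop), ~41% anxious time.
_LAB_CYCLE = (("relaxation", 290.0), ("tsst", 210.0),
              ("relaxation", 290.0), ("stroop_seated", 210.0),
              ("relaxation", 290.0), ("stroop_walking", 210.0))
_MIN_INTERVAL_S = 60.0


def _cycle_plan(cycle, duration_s: float) -> list[ConditionInterval]:
    plan, t, i = [], 0.0, 0
    while t < duration_s - 1e-9:
        cond, d = cycle[i % len(cycle)]
        d = min(d, duration_s - t)
        plan.append(ConditionInterval(t, t + d, cond))
        t += d
        i += 1
    return plan


def _wild_plan(duration_s: float, anxious_frac: float,
               rng: np.random.Generator) -> list[ConditionInterval]:
    durs = []
    total = 0.0
    while total < duration_s - 1e-9:
        d = min(float(rng.uniform(200.0, 400.0)), duration_s - total)
        durs.append(d)
        total += d
    target = anxious_frac * total
    order = rng.permutation(len(durs))
    anx = np.zeros(len(durs), bool)
    acc = 0.0
    for j in order:  # greedy fill toward the anxious-time target
        if acc + durs[j] <= target:
            anx[j] = True
            acc += durs[j]
    for j in order:  # one optional overshoot if it lands closer to the target
        if not anx[j] and abs(acc + durs[j] - target) < abs(acc - target):
            anx[j] = True
            acc += durs[j]
            break
    plan, t = [], 0.0
    for j, d in enumerate(durs):
        plan.append(ConditionInterval(t, t + d, "wild", anxious_truth=int(anx[j])))
        t += d
    return plan


def build_plan(subset: str, duration_s: float, *, wild_anxious_frac: float = 0.1934,
               rng: np.random.Generator | None = None) -> list[ConditionInterval]:
    """Standard session plan for a subset."""
    if duration_s < _MIN_INTERVAL_S:
        raise InvalidParameterError("session_duration_s too short for a plan")
    if subset == "calibration":
        return _cycle_plan(_CAL_CYCLE, duration_s)
    if subset == "in_lab":
        return _cycle_plan(_LAB_CYCLE, duration_s)
    if subset == "in_the_wild":
        rng = np.random.default_rng(0) if rng is None else rng
        return _wild_plan(duration_s, wild_anxious_frac, rng)
    raise InvalidParameterError(f"unknown subset {subset!r}")


def _draw_profile(rng: np.random.Generator) -> SubjectProfile:
    """Between-subject variability around population-typical values."""
    return SubjectProfile(
        baseline_hr=float(np.clip(rng.normal(70.0, 7.0), 50.0, 110.0)),
        sdnn=float(np.clip(rng.normal(0.05, 0.01), 0.02, 0.12)),
        resp_rate=float(np.clip(rng.normal(14.0, 2.0), 8.0, 24.0)),
        ie_ratio=float(np.clip(rng.normal(0.8, 0.1), 0.4, 1.5)),
        eda_tonic=float(np.clip(rng.lognormal(np.log(2.0), 0.3), 0.3, 15.0)),
        scr_rate=float(np.clip(rng.normal(3.0, 1.0), 0.5, 8.0)),
        temp_base=float(rng.normal(33.0, 0.5)),
    )


def generate_cohort(config: CohortConfig,
                    base_profile: SubjectProfile | None = None
                    ) -> list[MultimodalRecording]:
    """Generate one recording per subject under the configured subset.

    Deterministic under a fixed config: identical ``(config, seed)`` yields
    bit-identical recordings.
    """
    rng = np.random.default_rng(config.seed)
    recordings = []
    for i in range(config.n_subjects):
        profile = base_profile if base_profile is not None else _draw_profile(rng)
        plan = build_plan(config.subset, config.session_duration_s,
                          wild_anxious_frac=config.wild_anxious_frac, rng=rng)
        session_seed = int(rng.integers(0, 2 ** 31))
        rec = generate_session(
            profile, plan, seed=session_seed,
            label_noise=config.label_noise,
            extra_noise_snr=config.wild_noise_snr if config.subset == "in_the_wild" else None,
            subject_id=f"S{i:02d}")
        rec.meta["subset"] = config.subset
        rec.meta["profile"] = profile
        recordings.append(rec)
    return recordings
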