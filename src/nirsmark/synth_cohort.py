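"""Synthetic labeled fNIRS cohorts with known ground truth.

Generates jittered event schedules and raw dual-wavelength intensity
recordings through the same forward modified Beer-Lambert model that
:mod:`nirsmark.optics_preproc` inverts, so the full downstream pipeline is
testable without external data and supports exact round-trip checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma_fn

from nirsmark.optics_preproc import OpticalConfig, compute_dpf, mbll_forward

__all__ = [
    "CONDITIONS",
    "EventSchedule",
    "GroundTruth",
    "RawRecording",
    "NoiseParams",
    "EffectSpec",
    "canonical_hrf",
    "generate_schedule",
    "simulate_subject",
    "generate_cohort",
]

CONDITIONS = ("Font", "LowComplexity", "HighComplexity")
N_CHANNELS = 16
#: Channels 1-8 (0-based 0-7) are the synthetic left hemisphere.
LEFT_CHANNELS = tuple(range(8))
RIGHT_CHANNELS = tuple(range(8, 16))


@dataclass(frozen=True)
class EventSchedule:
    """Trial onsets/durations/conditions plus the total recording length."""

    events: tuple[tuple[float, float, str], ...]  # (onset_s, duration_s, condition)
    total_duration_s: float

    def __post_init__(self) -> None:
        onsets = [e[0] for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        if any(e[2] not in CONDITIONS for e in self.events):
            raise ValueError(f"conditions must be in {CONDITIONS}")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def onsets(self, condition: str | None = None) -> np.ndarray:
        return np.array(
            [e[0] for e in self.events if condition is None or e[2] == condition]
        )

    def count(self, condition: str) -> int:
        return sum(1 for e in self.events if e[2] == condition)


@dataclass
class GroundTruth:
    """Per-subject generative parameters kept for parameter-recovery tests."""

    group: str  # "healthy" | "tbi"
    amplitude: np.ndarray  # (16, 3) uM, columns ordered by CONDITIONS
    latency: np.ndarray  # (16, 3) s
    width: np.ndarray  # (16, 3) dimensionless HRF time-scale factor
    artifact_trials: frozenset[int] = frozenset()
    hbr_ratio: float = 1.0 / 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("amplitude", "latency", "width"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_CHANNELS, len(CONDITIONS)):
                raise ValueError(f"{name} must be ({N_CHANNELS}, {len(CONDITIONS)})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)

    @classmethod
    def null(cls, group: str = "healthy") -> "GroundTruth":
        z = np.zeros((N_CHANNELS, len(CONDITIONS)))
        return cls(group=group, amplitude=z.copy(), latency=z.copy(),
                   width=np.ones_like(z))


@dataclass
class RawRecording:
    """Raw dual-wavelength intensity recording for one subject.

    ``intensity`` has shape (16 channels, 2 wavelengths, samples) in strictly
    positive detector units.  The latent concentration series used by the
    forward model are retained (``latent_hbo``/``latent_hbr``, uM) to support
    inversion round-trip tests; real acquisitions would not carry them.
    """

    subject_id: str
    age: float
    group: str
    fs: float
    intensity: np.ndarray
    schedule: EventSchedule
    wavelengths: tuple[float, float] = (730.0, 850.0)
    latent_hbo: np.ndarray | None = None
    latent_hbr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must be (channels, 2 wavelengths, time)")
        if np.any(self.intensity <= 0):
            raise ValueError("intensity must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]


@dataclass(frozen=True)
class NoiseParams:
    """Additive nuisance components of the latent concentration model."""

    white_sd: float = 0.03  # uM
    drift_slope_range: tuple[float, float] = (-3e-4, 3e-4)  # uM/s
    osc_freqs: tuple[float, ...] = (0.02, 0.04, 0.08)  # Hz, inside 0.01-0.1
    osc_amp_range: tuple[float, float] = (0.01, 0.05)  # uM
    mayer_freq: float = 0.1  # Hz
    mayer_amp: float = 0.03  # uM
    resp_freq: float = 0.25  # Hz
    resp_amp: float = 0.02  # uM
    artifact_amp: float = 2.0  # uM spike magnitude on artifact trials
    hbr_noise_sd: float = 0.01  # uM, independent HbR noise

    @classmethod
    def silent(cls) -> "NoiseParams":
        """All nuisance terms off (clean forward model)."""
        return cls(
            white_sd=0.0,
            drift_slope_range=(0.0, 0.0),
            osc_amp_range=(0.0, 0.0),
            mayer_amp=0.0,
            resp_amp=0.0,
            artifact_amp=0.0,
            hbr_noise_sd=0.0,
        )


@dataclass(frozen=True)
class EffectSpec:
    """Group- and channel-dependent response parameters for cohort generation.

    The healthy group's left-hemisphere channels get ``healthy_left_gain``
    times the base amplitude; the TBI group's amplitudes are scaled by the
    per-condition ``tbi_amplitude_scale`` and its HRF widened by
    ``tbi_width_factor``.
    """

    base_amplitude: dict = field(
        default_factory=lambda: {
            "Font": 0.2,
            "LowComplexity": 0.4,
            "HighComplexity": 0.6,
        }
    )
    healthy_left_gain: float = 1.5
    tbi_amplitude_scale: dict = field(
        default_factory=lambda: {
            "Font": 0.9,
            "LowComplexity": 0.7,
            "HighComplexity": 0.5,
        }
    )
    tbi_width_factor: float = 1.3
    amplitude_jitter_sd: float = 0.05  # uM, per channel x condition
    subject_gain_sd: float = 0.2  # per-subject global response gain spread
    latency_jitter_sd: float = 0.3  # s
    artifact_trial_rate: float = 0.05
    age_healthy: tuple[float, float] = (30.8, 8.06)  # mean, sd (years)
    age_tbi: tuple[float, float] = (37.8, 11.6)
    age_bounds: tuple[float, float] = (18.0, 55.0)

    @classmethod
    def null(cls, amplitude: float = 0.0) -> "EffectSpec":
        """Identical generative distributions for both groups."""
        amps = {c: amplitude for c in CONDITIONS}
        return cls(
            base_amplitude=amps,
            healthy_left_gain=1.0,
            tbi_amplitude_scale={c: 1.0 for c in CONDITIONS},
            tbi_width_factor=1.0,
            amplitude_jitter_sd=0.0,
            subject_gain_sd=0.0,
            latency_jitter_sd=0.0,
            artifact_trial_rate=0.0,
        )


def canonical_hrf(
    t: np.ndarray, latency: float = 0.0, width: float = 1.0
) -> np.ndarray:
    """Double-gamma hemodynamic impulse response, peak-normalized to 1.

    Peak near 6 s and undershoot near 16 s at ``width=1``; ``latency`` shifts
    and ``width`` stretches the time axis.  Zero for t < latency.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    t = np.asarray(t, dtype=float)
    ts = np.maximum(t - latency, 0.0) / width
    a1, b1, a2, b2, c = 6.0, 1.0, 16.0, 1.0, 1.0 / 6.0

    def _g(x, a, b):
        return b**a * x ** (a - 1) * np.exp(-b * x) / _gamma_fn(a)

    h = _g(ts, a1, b1) - c * _g(ts, a2, b2)
    peak = _g(np.array([a1 - 1.0]), a1, b1)[0] - c * _g(np.array([a1 - 1.0]), a2, b2)[0]
    return h / peak


def generate_schedule(
    n_font: int,
    n_low: int,
    n_high: int,
    seed: int,
    *,
    trial_duration_s: float = 5.0,
    isi_range_s: tuple[float, float] = (5.0, 7.0),
    initial_rest_s: float = 10.0,
    final_rest_s: float = 10.0,
    total_duration_s: float | None = None,
) -> EventSchedule:
    """Randomly ordered trial schedule with jittered inter-stimulus intervals.

    Trials last ``trial_duration_s`` (default 5 s) and consecutive trials are
    separated by gaps drawn uniformly from ``isi_range_s`` (default [5, 7] s).
    Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If the requested counts cannot fit in ``total_duration_s``; the
        message states the required minimum duration.
    """
    if min(n_font, n_low, n_high) < 0:
        raise ValueError("trial counts must be >= 0")
    n = n_font + n_low + n_high
    rng = np.random.default_rng(seed)
    conditions = (
        ["Font"] * n_font + ["LowComplexity"] * n_low + ["HighComplexity"] * n_high
    )
    rng.shuffle(conditions)
    isis = rng.uniform(isi_range_s[0], isi_range_s[1], size=max(n - 1, 0))

    onsets = []
    t = initial_rest_s
    for i in range(n):
        onsets.append(t)
        t += trial_duration_s
        if i < n - 1:
            t += isis[i]
    min_duration = t + final_rest_s
    if total_duration_s is None:
        total_duration_s = min_duration
    elif total_duration_s < min_duration:
        raise ValueError(
            f"{n} trials need at least {min_duration:.1f} s "
            f"(requested {total_duration_s:.1f} s)"
        )
    events = tuple(
        (float(o), float(trial_duration_s), c) for o, c in zip(onsets, conditions)
    )
    return EventSchedule(events=events, total_duration_s=float(total_duration_s))


def _latent_concentrations(
    schedule: EventSchedule,
    truth: GroundTruth,
    noise: NoiseParams,
    fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(schedule.total_duration_s * fs))
    t = np.arange(n) / fs
    cond_idx = {c: j for j, c in enumerate(CONDITIONS)}

    hbo = np.zeros((N_CHANNELS, n))
    for ch in range(N_CHANNELS):
        for ev_i, (onset, _dur, cond) in enumerate(schedule.events):
            j = cond_idx[cond]
            amp = truth.amplitude[ch, j]
            if amp == 0.0 and ev_i not in truth.artifact_trials:
                continue
            hbo[ch] += amp * canonical_hrf(
                t - onset, latency=truth.latency[ch, j], width=truth.width[ch, j]
            )

    # nuisance terms: slow oscillations, Mayer wave, respiration, drift, noise
    for ch in range(N_CHANNELS):
        for f in noise.osc_freqs:
            a = rng.uniform(*noise.osc_amp_range)
            hbo[ch] += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        hbo[ch] += noise.mayer_amp * np.sin(
            2 * np.pi * noise.mayer_freq * t + rng.uniform(0, 2 * np.pi)
        )
        hbo[ch] += noise.resp_amp * np.sin(
            2 * np.pi * noise.resp_freq * t + rng.uniform(0, 2 * np.pi)
        )
        hbo[ch] += rng.uniform(*noise.drift_slope_range) * t
    hbo += rng.normal(0.0, noise.white_sd, size=hbo.shape) if noise.white_sd else 0.0

    hbr = -truth.hbr_ratio * hbo
    if noise.hbr_noise_sd:
        hbr = hbr + rng.normal(0.0, noise.hbr_noise_sd, size=hbr.shape)

    # artifact trials: additive spikes plus sign-flipped HbO/HbR coupling
    for ev_i in sorted(truth.artifact_trials):
        if ev_i >= schedule.n_events:
            raise ValueError("artifact index outside the event list")
        onset, dur, _ = schedule.events[ev_i]
        lo = int(round(onset * fs))
        hi = min(int(round((onset + dur + 6.0) * fs)), n)
        if lo >= n:
            continue
        seg = slice(lo, hi)
        spike = noise.artifact_amp * np.abs(
            np.sin(2 * np.pi * 0.4 * t[seg] + rng.uniform(0, 2 * np.pi))
        )
        hbo[:, seg] += spike
        hbr[:, seg] = +truth.hbr_ratio * hbo[:, seg] + spike
    return hbo, hbr


def simulate_subject(
    schedule: EventSchedule,
    truth: GroundTruth,
    noise: NoiseParams | None = None,
    *,
    subject_id: str = "sub-01",
    age: float = 30.0,
    fs: float = 2.0,
    baseline_intensity: float = 1000.0,
    optical_config: OpticalConfig | None = None,
    seed: int | None = None,
) -> RawRecording:
    """Forward-simulate one subject's raw dual-wavelength recording.

    Latent per-channel HbO is a sum of trial-locked HRFs plus oscillation,
    drift and noise terms; HbR is ``-hbr_ratio * HbO`` plus independent
    noise.  Latent concentrations are pushed through the modified
    Beer-Lambert forward model to intensities ``I = I0 * base^(-dOD)``.
    """
    if baseline_intensity <= 0:
        raise ValueError("baseline intensity must be > 0")
    noise = noise or NoiseParams()
    config = optical_config or OpticalConfig()
    rng = np.random.default_rng(seed if seed is not None else truth.seed)

    hbo, hbr = _latent_concentrations(schedule, truth, noise, fs, rng)
    dpf = [compute_dpf(w, age) for w in config.wavelengths]
    dod_lo, dod_hi = mbll_forward(hbo, hbr, dpf[0], dpf[1], config)
    base = 10.0 if config.od_log_base == 10 else np.e
    intensity = baseline_intensity * np.stack(
        [base**(-dod_lo), base**(-dod_hi)], axis=1
    )
    return RawRecording(
        subject_id=subject_id,
        age=age,
        group=truth.group,
        fs=fs,
        intensity=intensity,
        schedule=schedule,
        wavelengths=tuple(config.wavelengths),
        latent_hbo=hbo,
        latent_hbr=hbr,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    return float(np.clip(mean, *bounds))


def _subject_truth(
    group: str, effects: EffectSpec, schedule: EventSchedule, rng: np.random.Generator
) -> GroundTruth:
    amp = np.zeros((N_CHANNELS, len(CONDITIONS)))
    lat = np.zeros_like(amp)
    wid = np.ones_like(amp)
    # global response gain shared across channels: dominant source of
    # between-subject feature variability
    gain = (
        max(rng.normal(1.0, effects.subject_gain_sd), 0.1)
        if effects.subject_gain_sd
        else 1.0
    )
    for j, cond in enumerate(CONDITIONS):
        base = effects.base_amplitude.get(cond, 0.0)
        for ch in range(N_CHANNELS):
            a = base
            if group == "healthy" and ch in LEFT_CHANNELS:
                a *= effects.healthy_left_gain
            if group == "tbi":
                a *= effects.tbi_amplitude_scale.get(cond, 1.0)
            a += rng.normal(0.0, effects.amplitude_jitter_sd) if effects.amplitude_jitter_sd else 0.0
            amp[ch, j] = max(a * gain, 0.0)
            lat[ch, j] = abs(rng.normal(0.0, effects.latency_jitter_sd)) if effects.latency_jitter_sd else 0.0
            wid[ch, j] = effects.tbi_width_factor if group == "tbi" else 1.0
    n_art = rng.binomial(schedule.n_events, effects.artifact_trial_rate)
    artifacts = frozenset(
        int(i) for i in rng.choice(schedule.n_events, size=n_art, replace=False)
    ) if n_art else frozenset()
    return GroundTruth(
        group=group, amplitude=amp, latency=lat, width=wid, artifact_trials=artifacts
    )


def generate_cohort(
    n_healthy: int,
    n_tbi: int,
    effects: EffectSpec | None = None,
    seed: int = 0,
    *,
    noise: NoiseParams | None = None,
    schedule: EventSchedule | None = None,
    n_font: int = 33,
    n_low: int = 33,
    n_high: int = 33,
    fs: float = 2.0,
    optical_config: OpticalConfig | None = None,
) -> tuple[list[RawRecording], list[GroundTruth]]:
    """Generate a labeled cohort of raw recordings plus its ground truth.

    All subjects share one event schedule (drawn from ``seed``) unless an
    explicit ``schedule`` is passed.  Ages are drawn per group from truncated
    normal distributions.  Bit-identical for a fixed seed.
    """
    effects = effects or EffectSpec()
    noise = noise or NoiseParams()
    if schedule is None:
        schedule = generate_schedule(n_font, n_low, n_high, seed=seed)
    recordings: list[RawRecording] = []
    truths: list[GroundTruth] = []
    groups = ["healthy"] * n_healthy + ["tbi"] * n_tbi
    for i, group in enumerate(groups):
        rng = np.random.default_rng([seed, i])
        age_mean, age_sd = (
            effects.age_healthy if group == "healthy" else effects.age_tbi
        )
        age = _truncated_normal(rng, age_mean, age_sd, effects.age_bounds)
        truth = _subject_truth(group, effects, schedule, rng)
        truth.seed = int(rng.integers(0, 2**31 - 1))
        rec = simulate_subject(
            schedule,
            truth,
            noise,
            subject_id=f"sub-{i + 1:02d}",
            age=age,
            fs=fs,
            optical_config=optical_config,
            seed=truth.seed,
        )
        recordings.append(rec)
        truths.append(truth)
    return recordings, truths
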