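"""Raw intensity -> HbO/HbR concentration changes.

Fixed stage order: normalize -> delta-OD -> MBLL inversion -> low-pass ->
piecewise detrend.  Every stage is a pure function of its inputs and config,
and channel-wise independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "OpticalConfig",
    "HemoSignals",
    "compute_dpf",
    "intensity_to_delta_od",
    "mbll_forward",
    "mbll_invert",
    "lowpass_filter",
    "detrend_piecewise",
    "preprocess_recording",
]

#: Molar extinction coefficients in cm^-1 * uM^-1 (base-10 convention),
#: rows indexed by wavelength (730, 850 nm), columns by chromophore
#: (HbO, HbR).  Compiled-table values; stored explicitly so the forward
#: and inverse paths always share one source of truth.
DEFAULT_EXTINCTION = np.array(
    [
        [4.46e-4, 1.1022e-3],  # 730 nm
        [1.058e-3, 6.9132e-4],  # 850 nm
    ]
)


@dataclass(frozen=True)
class OpticalConfig:
    """Optical geometry and signal-conditioning settings.

    Attributes
    ----------
    source_detector_distance:
        Emitter-detector separation in cm.
    extinction_matrix:
        2x2 array, ``eps[wavelength][chromophore]`` in cm^-1 * uM^-1, row
        order matching ``wavelengths``, column order (HbO, HbR).
    od_log_base:
        ``10`` for the standard optical-density convention or ``"e"`` for
        natural log.  Forward and inverse paths share the value, so round
        trips hold under either.
    baseline_window_s:
        ``(start, end)`` seconds of the recording used as the intensity
        normalization baseline.
    lowpass_cutoff_hz, lowpass_order:
        Butterworth low-pass parameters.
    zero_phase:
        Forward-backward filtering when True (keeps trial latencies
        unbiased); single-pass causal IIR when False.
    detrend_segment_s:
        Length of the independent piecewise-linear detrending segments.
    """

    source_detector_distance: float = 2.5
    extinction_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXTINCTION.copy()
    )
    wavelengths: tuple[float, float] = (730.0, 850.0)
    od_log_base: int | str = 10
    baseline_window_s: tuple[float, float] = (0.0, 10.0)
    lowpass_cutoff_hz: float = 0.1
    lowpass_order: int = 10
    zero_phase: bool = True
    detrend_segment_s: float = 60.0

    def __post_init__(self) -> None:
        eps = np.asarray(self.extinction_matrix, dtype=float)
        if eps.shape != (2, 2):
            raise ValueError("extinction_matrix must be 2x2")
        if not np.all(np.isfinite(eps)) or abs(np.linalg.det(eps)) < 1e-30:
            raise ValueError("extinction_matrix is singular or non-finite")
        if self.source_detector_distance <= 0:
            raise ValueError("source_detector_distance must be > 0")
        if self.od_log_base not in (10, "e"):
            raise ValueError("od_log_base must be 10 or 'e'")
        object.__setattr__(self, "extinction_matrix", eps)

    def with_(self, **kw) -> "OpticalConfig":
        return replace(self, **kw)


@dataclass
class HemoSignals:
    """Per-channel HbO/HbR concentration-change series in uM."""

    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray  # (n_channels, n_samples)
    fs: float
    retained: np.ndarray | None = None  # bool per channel, set by QC
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("HbO and HbR shapes differ")
        if self.retained is None:
            self.retained = np.ones(self.hbo.shape[0], dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]


# Five-term general DPF fit coefficients (age in years, wavelength in nm).
_DPF_COEF = (223.3, 0.05624, 0.8493, -5.723e-7, 0.001245, -0.9025)


def compute_dpf(wavelength: float, age: float) -> float:
    """Differential pathlength factor as a function of wavelength and age.

    Evaluates the published general five-term fit
    ``a + b*age**c + d*lam**3 + e*lam**2 + f*lam``.

    Parameters
    ----------
    wavelength:
        In nm; valid domain [690, 900].
    age:
        In years; valid domain (0, 100].
    """
    if not 690.0 <= wavelength <= 900.0:
        raise ValueError(
            f"wavelength {wavelength} nm outside the valid domain [690, 900] nm"
        )
    if not 0.0 < age <= 100.0:
        raise ValueError(f"age {age} y outside the valid domain (0, 100] y")
    a, b, c, d, e, f = _DPF_COEF
    return a + b * age**c + d * wavelength**3 + e * wavelength**2 + f * wavelength


def intensity_to_delta_od(
    intensity: np.ndarray,
    baseline_window: tuple[int, int],
    log_base: int | str = 10,
) -> np.ndarray:
    """Optical-density change: negative log of baseline-normalized intensity.

    ``dOD(t) = -log(I(t) / mean(I[baseline]))``; zero wherever the intensity
    equals its baseline mean.

    Parameters
    ----------
    intensity:
        Strictly positive trace (any leading axes, time last).
    baseline_window:
        Half-open sample range ``(start, stop)`` for the baseline mean.
    """
    intensity = np.asarray(intensity, dtype=float)
    bad = intensity <= 0
    if np.any(bad):
        idx = tuple(int(i[0]) for i in np.nonzero(bad))
        raise ValueError(f"non-positive intensity at index {idx}")
    lo, hi = baseline_window
    if hi <= lo or hi > intensity.shape[-1]:
        raise ValueError(f"empty or out-of-range baseline window {baseline_window}")
    baseline = intensity[..., lo:hi].mean(axis=-1, keepdims=True)
    ratio = intensity / baseline
    if log_base == 10:
        return -np.log10(ratio)
    return -np.log(ratio)


def _mbll_matrix(
    dpf_low: float, dpf_high: float, config: OpticalConfig
) -> np.ndarray:
    d = config.source_detector_distance
    eps = config.extinction_matrix
    return eps * (d * np.array([[dpf_low], [dpf_high]]))


def mbll_forward(
    hbo: np.ndarray,
    hbr: np.ndarray,
    dpf_low: float,
    dpf_high: float,
    config: OpticalConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Map concentration changes (uM) to per-wavelength delta-OD.

    ``dOD_lam = (eps[lam,HbO]*dHbO + eps[lam,HbR]*dHbR) * d * DPF_lam``.
    Exact forward counterpart of :func:`mbll_invert`; used by the synthetic
    cohort generator.
    """
    A = _mbll_matrix(dpf_low, dpf_high, config)
    conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)])
    dod = A @ conc.reshape(2, -1)
    return dod[0].reshape(np.shape(hbo)), dod[1].reshape(np.shape(hbr))


def mbll_invert(
    delta_od_low: np.ndarray,
    delta_od_high: np.ndarray,
    dpf_low: float,
    dpf_high: float,
    config: OpticalConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the 2x2 modified Beer-Lambert system per sample for (HbO, HbR)."""
    lo = np.asarray(delta_od_low, dtype=float)
    hi = np.asarray(delta_od_high, dtype=float)
    if lo.shape != hi.shape:
        raise ValueError("delta-OD series must have equal shape")
    A = _mbll_matrix(dpf_low, dpf_high, config)
    conc = np.linalg.solve(A, np.stack([lo.ravel(), hi.ravel()]))
    return conc[0].reshape(lo.shape), conc[1].reshape(hi.shape)


def _lowpass_sos(fs: float, cutoff: float, order: int) -> np.ndarray:
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} Hz must exceed twice the cutoff {cutoff} Hz")
    return _sig.butter(order, cutoff, btype="low", fs=fs, output="sos")


def lowpass_filter(
    x: np.ndarray,
    fs: float,
    cutoff: float = 0.1,
    order: int = 10,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth IIR low-pass (DC gain 1, -3 dB at the cutoff per pass).

    ``zero_phase=True`` applies the filter forward and backward (squared
    magnitude, no phase lag); ``False`` gives the causal single-pass IIR.
    """
    x = np.asarray(x, dtype=float)
    sos = _lowpass_sos(fs, cutoff, order)
    if zero_phase:
        # sosfiltfilt needs > padlen samples for its edge reflection
        padlen = 3 * (2 * sos.shape[0] + 1)
        if x.shape[-1] <= padlen:
            raise ValueError(
                f"signal length {x.shape[-1]} too short; need > {padlen} samples"
            )
        return _sig.sosfiltfilt(sos, x, axis=-1)
    if x.shape[-1] < 2:
        raise ValueError("signal length must be >= 2 samples")
    return _sig.sosfilt(sos, x, axis=-1)


def lowpass_gain(freq: float, cutoff: float = 0.1, order: int = 10) -> float:
    """Closed-form analog Butterworth magnitude |H| = 1/sqrt(1+(f/fc)^2n)."""
    return 1.0 / np.sqrt(1.0 + (freq / cutoff) ** (2 * order))


def detrend_piecewise(
    x: np.ndarray, fs: float, segment_length_s: float = 60.0
) -> np.ndarray:
    """Remove an independently fitted least-squares line per contiguous segment.

    The trace is cut into ``segment_length_s``-long pieces; a trailing
    remainder shorter than a segment is folded into the last one so every
    fitted piece has >= 2 samples.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    seg = int(round(segment_length_s * fs))
    if seg < 2:
        raise ValueError("segment length must span at least 2 samples")
    if n < 2:
        raise ValueError("signal too short to detrend (need >= 2 samples)")
    bounds = list(range(0, n, seg))
    if n - bounds[-1] < 2 and len(bounds) > 1:
        bounds.pop()  # fold short tail into the previous segment
    out = np.empty_like(x)
    for i, lo in enumerate(bounds):
        hi = bounds[i + 1] if i + 1 < len(bounds) else n
        t = np.arange(hi - lo, dtype=float)
        piece = x[..., lo:hi]
        coef = np.polynomial.polynomial.polyfit(t, piece.reshape(-1, hi - lo).T, 1)
        fit = np.polynomial.polynomial.polyval(t, coef).reshape(piece.shape)
        out[..., lo:hi] = piece - fit
    return out


def preprocess_recording(recording, config: OpticalConfig | None = None) -> HemoSignals:
    """Full pipeline: normalize -> delta-OD -> MBLL -> low-pass -> detrend.

    Parameters
    ----------
    recording:
        A :class:`nirsmark.synth_cohort.RawRecording` (or any object with
        ``intensity`` shaped (channels, 2, time), ``fs`` and ``age``).
    """
    config = config or OpticalConfig()
    fs = recording.fs
    lo_s, hi_s = config.baseline_window_s
    window = (int(round(lo_s * fs)), int(round(hi_s * fs)))
    dpf = [compute_dpf(w, recording.age) for w in config.wavelengths]

    intensity = np.asarray(recording.intensity, dtype=float)
    dod = intensity_to_delta_od(intensity, window, config.od_log_base)
    hbo, hbr = mbll_invert(dod[:, 0, :], dod[:, 1, :], dpf[0], dpf[1], config)

    def _condition(sig: np.ndarray) -> np.ndarray:
        filtered = lowpass_filter(
            sig,
            fs,
            cutoff=config.lowpass_cutoff_hz,
            order=config.lowpass_order,
            zero_phase=config.zero_phase,
        )
        return detrend_piecewise(filtered, fs, config.detrend_segment_s)

    provenance = {
        "baseline_window_s": list(config.baseline_window_s),
        "od_log_base": str(config.od_log_base),
        "lowpass_cutoff_hz": config.lowpass_cutoff_hz,
        "lowpass_order": config.lowpass_order,
        "zero_phase": config.zero_phase,
        "detrend_segment_s": config.detrend_segment_s,
        "dpf": {str(w): d for w, d in zip(config.wavelengths, dpf)},
        "source_detector_distance_cm": config.source_detector_distance,
    }
    return HemoSignals(
        hbo=_condition(hbo), hbr=_condition(hbr), fs=fs, provenance=provenance
    )
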