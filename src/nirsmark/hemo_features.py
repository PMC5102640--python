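"""Activity-curve detection and the 11 hemodynamic features.

Ten scalar features are computed from a channel's block-averaged HbO trial
(mean, variance, skewness, kurtosis, activity-curve slopes/area/width/peak/
start time); the spectral feature is a small vector of DFT coefficient
magnitudes taken from the full-length filtered HbO series, where the
0.01-0.1 Hz band is actually resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "FEATURE_NAMES",
    "SCALAR_FEATURES",
    "ActivityCurve",
    "FeatureVector",
    "SubjectFeatures",
    "detect_activity_curve",
    "compute_features",
    "compute_hdft",
    "aggregate_subject",
    "temporal_table",
    "spatiotemporal_table",
]

SCALAR_FEATURES = ("HM", "HV", "HK", "HS", "CSL", "CSR", "CA", "CF", "CP", "CAS")
#: The 11 feature names; HDFT is a single (vector-valued) element.
FEATURE_NAMES = SCALAR_FEATURES + ("HDFT",)

DEFAULT_HDFT_BAND = (0.01, 0.1)
DEFAULT_HDFT_TARGETS = (0.02, 0.05, 0.09)


@dataclass
class ActivityCurve:
    """Boundaries of the positive HbO deflection in an averaged trial."""

    start_index: int
    peak_index: int
    end_index: int
    fs: float
    peak_amplitude: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.start_index <= self.peak_index <= self.end_index:
            raise ValueError("need start <= peak <= end")

    @property
    def start_time_s(self) -> float:
        return self.start_index / self.fs

    @property
    def peak_time_s(self) -> float:
        return self.peak_index / self.fs

    @property
    def end_time_s(self) -> float:
        return self.end_index / self.fs


@dataclass
class FeatureVector:
    HM: float
    HV: float
    HK: float
    HS: float
    CSL: float
    CSR: float
    CA: float
    CF: float
    CP: float
    CAS: float
    HDFT: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def as_dict(self) -> dict[str, float]:
        """Flat mapping with HDFT expanded to HDFT_1..HDFT_k."""
        d = {name: float(getattr(self, name)) for name in SCALAR_FEATURES}
        for i, v in enumerate(np.atleast_1d(self.HDFT), start=1):
            d[f"HDFT_{i}"] = float(v)
        return d


@dataclass
class SubjectFeatures:
    """Temporal (channel-averaged) and per-channel feature sets for a subject."""

    subject_id: str
    group: str
    temporal: FeatureVector
    spatiotemporal: dict[int, FeatureVector]  # 0-based channel -> vector
    n_channels: int = 16


def detect_activity_curve(avg_hbo: np.ndarray, fs: float) -> ActivityCurve:
    """Locate the activity curve: peak, start and end of the deflection.

    Peak is the argmax (first occurrence on ties).  Scanning away from the
    peak, a boundary is the first sample that is non-positive or a local
    minimum, whichever comes first; the window edge if neither exists.  An
    all-non-positive signal yields a degenerate curve collapsed onto the
    peak (flagged, not raised).
    """
    x = np.asarray(avg_hbo, dtype=float)
    if x.size < 5:
        raise ValueError("window too short (need >= 5 samples)")
    peak = int(np.argmax(x))
    if x[peak] <= 0 or x.max() == x.min():
        return ActivityCurve(peak, peak, peak, fs, float(x[peak]), degenerate=True)

    def _boundary(direction: int) -> int:
        i = peak + direction
        while 0 <= i < x.size:
            if x[i] <= 0:
                return i
            prev, nxt = i - direction, i + direction
            if 0 <= nxt < x.size and x[i] <= x[nxt] and x[i] <= x[prev]:
                return i  # local minimum
            i += direction
        return 0 if direction < 0 else x.size - 1

    start = _boundary(-1) if peak > 0 else peak
    end = _boundary(+1) if peak < x.size - 1 else peak
    return ActivityCurve(start, peak, end, fs, float(x[peak]))


def _fwhm(x: np.ndarray, curve: ActivityCurve, fs: float) -> float:
    """Full width at half max by linear interpolation of the crossings
    nearest the peak; clips to the window edge when a crossing is absent."""
    if curve.degenerate or curve.peak_amplitude <= 0:
        return 0.0
    half = curve.peak_amplitude / 2.0
    peak = curve.peak_index

    def _cross(direction: int) -> float:
        i = peak
        while 0 <= i + direction < x.size:
            j = i + direction
            if x[j] < half:
                # interpolate between i (>= half) and j (< half)
                frac = (x[i] - half) / (x[i] - x[j])
                return i + direction * frac
            i = j
        return 0.0 if direction < 0 else float(x.size - 1)

    left = _cross(-1)
    right = _cross(+1)
    return (right - left) / fs


def compute_features(
    avg_hbo: np.ndarray,
    fs: float,
    curve: ActivityCurve | None = None,
    hdft: np.ndarray | None = None,
) -> FeatureVector:
    """All scalar features of an averaged HbO trial (plus attached HDFT).

    Moments use the population (1/n) convention: HV is the biased variance,
    HS Fisher skewness g1, HK excess kurtosis g2.  Slopes are signed rise
    and fall rates of the activity curve; CA is the trapezoidal integral of
    the signal between the curve boundaries; degenerate (zero-duration)
    curves give zero slopes, area and width.
    """
    x = np.asarray(avg_hbo, dtype=float)
    if curve is None:
        curve = detect_activity_curve(x, fs)
    hm = float(np.mean(x))
    constant = x.max() == x.min()  # avoid float-noise moments on flat input
    hv = 0.0 if constant else float(np.mean((x - hm) ** 2))
    if hv == 0.0:
        hs = hk = 0.0
    else:
        hs = float(_stats.skew(x, bias=True))
        hk = float(_stats.kurtosis(x, fisher=True, bias=True))

    s, p, e = curve.start_index, curve.peak_index, curve.end_index
    csl = (x[p] - x[s]) / ((p - s) / fs) if p > s else 0.0
    csr = (x[e] - x[p]) / ((e - p) / fs) if e > p else 0.0
    ca = float(np.trapezoid(x[s:e + 1], dx=1.0 / fs)) if e > s else 0.0
    cf = _fwhm(x, curve, fs)
    cp = float(x[p])
    cas = curve.start_time_s
    return FeatureVector(
        HM=hm, HV=hv, HK=hk, HS=hs, CSL=float(csl), CSR=float(csr),
        CA=ca, CF=float(cf), CP=cp, CAS=float(cas),
        HDFT=np.zeros(3) if hdft is None else np.asarray(hdft, dtype=float),
    )


def compute_hdft(
    hbo: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_HDFT_BAND,
    target_freqs: tuple[float, ...] = DEFAULT_HDFT_TARGETS,
    n_coeff: int = 3,
) -> np.ndarray:
    """DFT coefficient magnitudes |c_n| at the in-band bins nearest the targets.

    ``c_n = sum_k x[k] exp(-2 pi i k n / N)``; bin n sits at frequency
    ``n * fs / N``.  The input must be the full-length continuous HbO
    series — the low band edge is only resolvable when the series spans at
    least two periods of it.
    """
    x = np.asarray(hbo, dtype=float)
    n = x.size
    min_len = int(np.ceil(2.0 / band[0] * fs))
    if n < min_len:
        raise ValueError(
            f"series of {n} samples cannot resolve {band[0]} Hz; "
            f"need >= {min_len} samples at fs={fs}"
        )
    targets = tuple(target_freqs)[:n_coeff]
    if len(targets) < n_coeff:
        raise ValueError("need one target frequency per coefficient")
    spectrum = np.fft.fft(x)
    freqs = np.arange(n) * fs / n
    half = n // 2 + 1
    mags = np.empty(n_coeff)
    for i, f in enumerate(targets):
        if not band[0] <= f <= band[1]:
            raise ValueError(f"target {f} Hz outside the band {band}")
        bin_i = int(np.argmin(np.abs(freqs[:half] - f)))
        mags[i] = np.abs(spectrum[bin_i])
    return mags


def aggregate_subject(
    per_channel: dict[int, FeatureVector],
    retained_channels: np.ndarray,
    *,
    subject_id: str = "sub-01",
    group: str = "unknown",
) -> SubjectFeatures:
    """Channel-averaged (temporal) plus per-channel (spatio-temporal) sets.

    The temporal vector is the elementwise mean over retained channels only
    (HDFT averaged bin-wise); dropped channels appear in no average and are
    simply absent from ``spatiotemporal``.
    """
    retained = np.asarray(retained_channels, dtype=bool)
    idx = [ch for ch in sorted(per_channel) if retained[ch]]
    if not idx:
        raise ValueError(f"subject {subject_id} has no retained channels")
    means = {
        name: float(np.mean([getattr(per_channel[ch], name) for ch in idx]))
        for name in SCALAR_FEATURES
    }
    hdft = np.mean([per_channel[ch].HDFT for ch in idx], axis=0)
    temporal = FeatureVector(**means, HDFT=hdft)
    return SubjectFeatures(
        subject_id=subject_id,
        group=group,
        temporal=temporal,
        spatiotemporal={ch: per_channel[ch] for ch in idx},
        n_channels=retained.size,
    )


def temporal_table(subjects: list[SubjectFeatures]) -> pd.DataFrame:
    """One row per subject: subject, group, HM..CAS, HDFT_1..k."""
    rows = []
    for s in subjects:
        row = {"subject": s.subject_id, "group": s.group}
        row.update(s.temporal.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def spatiotemporal_table(subjects: list[SubjectFeatures]) -> pd.DataFrame:
    """Long format: subject, group, channel (1-based), feature, value.

    Dropped channels are emitted with NaN values so the missingness pattern
    is explicit.
    """
    rows = []
    for s in subjects:
        for ch in range(s.n_channels):
            fv = s.spatiotemporal.get(ch)
            flat = fv.as_dict() if fv is not None else None
            names = (
                flat.keys()
                if flat is not None
                else FeatureVector(*([0.0] * 10)).as_dict().keys()
            )
            for name in names:
                rows.append(
                    {
                        "subject": s.subject_id,
                        "group": s.group,
                        "channel": ch + 1,
                        "feature": name,
                        "value": flat[name] if flat is not None else np.nan,
                    }
                )
    return pd.DataFrame(rows)
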