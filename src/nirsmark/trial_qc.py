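"""Event-locked trial extraction, three-criterion rejection, pruning, averaging.

A trial is retained only if, over its 11-s post-onset window, (1) HbO and
HbR are negatively correlated, (2) mean HbO exceeds mean HbR, and (3) mean
HbO is positive.  Channels losing >= 80% of their trials are dropped;
subjects with no surviving channel are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nirsmark.optics_preproc import HemoSignals
from nirsmark.synth_cohort import EventSchedule, N_CHANNELS

__all__ = [
    "Trial",
    "TrialSet",
    "extract_trials",
    "trial_passes",
    "prune_channels_subjects",
    "block_average",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 11.0
DEFAULT_REJECT_THRESHOLD = 0.80


@dataclass
class Trial:
    """One event-locked HbO/HbR segment with its QC verdict."""

    channel: int
    event_index: int
    condition: str
    hbo: np.ndarray
    hbr: np.ndarray
    qc: dict = field(default_factory=dict)
    retained: bool = False


@dataclass
class TrialSet:
    """All trials of one subject, grouped per channel, plus QC state."""

    subject_id: str
    group: str
    fs: float
    trials: list[list[Trial]]  # outer index = channel
    channel_retained: np.ndarray | None = None
    subject_retained: bool = True
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        if self.channel_retained is None:
            self.channel_retained = np.ones(len(self.trials), dtype=bool)

    @property
    def n_channels(self) -> int:
        return len(self.trials)

    def rejected_fraction(self, channel: int) -> float:
        ts = self.trials[channel]
        if not ts:
            return 1.0
        return sum(not t.retained for t in ts) / len(ts)

    def retained_trials(self, channel: int) -> list[Trial]:
        return [t for t in self.trials[channel] if t.retained]


def trial_passes(
    trial: Trial, positivity_mode: str = "mean"
) -> dict:
    """Apply the three screening criteria to one trial (in place).

    - ``anticorrelation``: Pearson r(HbO, HbR) < 0 (strict).
    - ``oxy_dominance``: mean(HbO) > mean(HbR).
    - ``positivity``: mean(HbO) > 0 (``positivity_mode="mean"``), or every
      sample > 0 (``"all_samples"``).

    Zero-variance HbO or HbR makes the correlation undefined; the trial is
    rejected with ``qc["degenerate"] = True`` rather than raising.
    """
    if positivity_mode not in ("mean", "all_samples"):
        raise ValueError("positivity_mode must be 'mean' or 'all_samples'")
    hbo, hbr = trial.hbo, trial.hbr
    mean_hbo = float(np.mean(hbo))
    mean_hbr = float(np.mean(hbr))
    degenerate = np.std(hbo) == 0.0 or np.std(hbr) == 0.0
    r = float("nan") if degenerate else float(np.corrcoef(hbo, hbr)[0, 1])
    qc = {
        "anticorrelation": (not degenerate) and r < 0.0,
        "oxy_dominance": mean_hbo > mean_hbr,
        "positivity": (
            mean_hbo > 0.0 if positivity_mode == "mean" else bool(np.all(hbo > 0.0))
        ),
        "degenerate": bool(degenerate),
        "r": r,
        "mean_hbo": mean_hbo,
        "mean_hbr": mean_hbr,
    }
    trial.qc = qc
    trial.retained = (
        qc["anticorrelation"] and qc["oxy_dominance"] and qc["positivity"]
    )
    return qc


def extract_trials(
    hemo: HemoSignals,
    schedule: EventSchedule,
    condition: str | tuple[str, ...] | None = "HighComplexity",
    window_s: float = DEFAULT_WINDOW_S,
    *,
    subject_id: str = "sub-01",
    group: str = "unknown",
    apply_qc: bool = True,
    positivity_mode: str = "mean",
) -> TrialSet:
    """Cut event-locked windows from every channel and QC each trial.

    Windows are ``[onset, onset + window_s)``, half-open, 0-based, onset
    sample included.  Events whose window would overrun the recording are
    skipped with a logged warning.  ``apply_qc=False`` marks every trial
    retained (the no-rejection control analysis).
    """
    if isinstance(condition, str):
        condition = (condition,)
    selected = [
        (i, ev)
        for i, ev in enumerate(schedule.events)
        if condition is None or ev[2] in condition
    ]
    if not selected:
        raise ValueError(f"no events with condition {condition}")
    n_win = int(round(window_s * hemo.fs))
    trials: list[list[Trial]] = [[] for _ in range(hemo.n_channels)]
    for ev_i, (onset, _dur, cond) in selected:
        lo = int(round(onset * hemo.fs))
        if lo + n_win > hemo.n_samples:
            logger.warning(
                "skipping trial %d (%s at %.1f s): window overruns the recording",
                ev_i, cond, onset,
            )
            continue
        for ch in range(hemo.n_channels):
            t = Trial(
                channel=ch,
                event_index=ev_i,
                condition=cond,
                hbo=hemo.hbo[ch, lo:lo + n_win].copy(),
                hbr=hemo.hbr[ch, lo:lo + n_win].copy(),
            )
            if apply_qc:
                trial_passes(t, positivity_mode=positivity_mode)
            else:
                t.retained = True
                t.qc = {"skipped": True}
            trials[ch].append(t)
    return TrialSet(
        subject_id=subject_id, group=group, fs=hemo.fs, trials=trials,
        window_s=window_s,
    )


def prune_channels_subjects(
    trialsets: list[TrialSet],
    reject_threshold: float = DEFAULT_REJECT_THRESHOLD,
) -> tuple[list[TrialSet], dict]:
    """Drop channels at >= threshold rejection and subjects with no channel.

    Mutates ``channel_retained``/``subject_retained`` on each TrialSet and
    returns ``(retained subjects, report)``.  The report carries a per-
    subject/channel retention table and a cohort-level histogram counting,
    per channel, how many retained subjects kept that channel.
    """
    rows = []
    kept: list[TrialSet] = []
    for ts in trialsets:
        retained = np.zeros(ts.n_channels, dtype=bool)
        for ch in range(ts.n_channels):
            frac = ts.rejected_fraction(ch)
            retained[ch] = frac < reject_threshold  # drop iff frac >= threshold
            rows.append(
                {
                    "subject": ts.subject_id,
                    "group": ts.group,
                    "channel": ch + 1,
                    "n_trials": len(ts.trials[ch]),
                    "n_retained": len(ts.retained_trials(ch)),
                    "rejected_fraction": frac,
                    "channel_retained": bool(retained[ch]),
                }
            )
        ts.channel_retained = retained
        ts.subject_retained = bool(retained.any())
        if ts.subject_retained:
            kept.append(ts)
    table = pd.DataFrame(rows)
    histogram = {}
    if not table.empty:
        kept_tbl = table[
            table["subject"].isin([ts.subject_id for ts in kept])
            & table["channel_retained"]
        ]
        for pop in sorted(table["group"].unique()):
            counts = (
                kept_tbl[kept_tbl["group"] == pop]
                .groupby("channel")["subject"].nunique()
            )
            histogram[pop] = {
                ch: int(counts.get(ch, 0)) for ch in range(1, N_CHANNELS + 1)
            }
    report = {
        "reject_threshold": reject_threshold,
        "n_subjects_in": len(trialsets),
        "n_subjects_retained": len(kept),
        "dropped_subjects": [
            ts.subject_id for ts in trialsets if not ts.subject_retained
        ],
        "table": table,
        "channel_histogram": histogram,
    }
    return kept, report


def block_average(
    trialset: TrialSet, channel: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean HbO/HbR across this channel's retained trials only."""
    if trialset.channel_retained is not None and not trialset.channel_retained[channel]:
        raise ValueError(
            f"channel {channel} of {trialset.subject_id} was dropped by QC"
        )
    kept = trialset.retained_trials(channel)
    if not kept:
        raise ValueError(
            f"channel {channel} of {trialset.subject_id} has no retained trials"
        )
    hbo = np.mean([t.hbo for t in kept], axis=0)
    hbr = np.mean([t.hbr for t in kept], axis=0)
    return hbo, hbr
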