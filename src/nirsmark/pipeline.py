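"""Glue: raw recordings -> preprocessed signals -> QC'd trials -> feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from nirsmark import hemo_features, optics_preproc, trial_qc
from nirsmark.optics_preproc import HemoSignals, OpticalConfig
from nirsmark.synth_cohort import EventSchedule, RawRecording


def preprocess_cohort(
    recordings: list[RawRecording], config: OpticalConfig | None = None
) -> list[HemoSignals]:
    """Run the optical preprocessing pipeline on every recording."""
    return [optics_preproc.preprocess_recording(rec, config) for rec in recordings]


def condition_features(
    subjects: list[tuple[str, str, HemoSignals, EventSchedule]],
    condition: str | tuple[str, ...] = "HighComplexity",
    *,
    window_s: float = trial_qc.DEFAULT_WINDOW_S,
    reject_threshold: float = trial_qc.DEFAULT_REJECT_THRESHOLD,
    apply_qc: bool = True,
    hdft_targets: tuple[float, ...] = hemo_features.DEFAULT_HDFT_TARGETS,
    n_hdft: int = 3,
) -> tuple[list[hemo_features.SubjectFeatures], dict]:
    """Trial extraction + QC + pruning + averaging + feature extraction.

    Parameters
    ----------
    subjects:
        Tuples ``(subject_id, group, hemo_signals, schedule)``.
    apply_qc:
        ``False`` reproduces the no-rejection control analysis: every trial
        is kept and no channel/subject is pruned.

    Returns
    -------
    (subject feature sets, QC report)
    """
    trialsets = [
        trial_qc.extract_trials(
            hemo, schedule, condition, window_s,
            subject_id=sid, group=group, apply_qc=apply_qc,
        )
        for sid, group, hemo, schedule in subjects
    ]
    if apply_qc:
        kept, report = trial_qc.prune_channels_subjects(trialsets, reject_threshold)
    else:
        kept, report = trialsets, {"reject_threshold": None, "table": None}
    hemo_by_id = {sid: hemo for sid, _g, hemo, _s in subjects}

    out: list[hemo_features.SubjectFeatures] = []
    for ts in kept:
        hemo = hemo_by_id[ts.subject_id]
        per_channel: dict[int, hemo_features.FeatureVector] = {}
        for ch in range(ts.n_channels):
            if not ts.channel_retained[ch] or not ts.retained_trials(ch):
                continue
            avg_hbo, _avg_hbr = trial_qc.block_average(ts, ch)
            hdft = hemo_features.compute_hdft(
                hemo.hbo[ch], hemo.fs, target_freqs=hdft_targets, n_coeff=n_hdft
            )
            per_channel[ch] = hemo_features.compute_features(
                avg_hbo, ts.fs, hdft=hdft
            )
        if not per_channel:
            continue
        retained = np.zeros(ts.n_channels, dtype=bool)
        retained[list(per_channel)] = True
        out.append(
            hemo_features.aggregate_subject(
                per_channel, retained, subject_id=ts.subject_id, group=ts.group
            )
        )
    return out, report


def cohort_temporal_table(
    recordings: list[RawRecording],
    condition: str | tuple[str, ...] = "HighComplexity",
    config: OpticalConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Raw recordings straight to the temporal (channel-averaged) feature table."""
    hemos = preprocess_cohort(recordings, config)
    subjects = [
        (rec.subject_id, rec.group, hemo, rec.schedule)
        for rec, hemo in zip(recordings, hemos)
    ]
    feats, _report = condition_features(subjects, condition, **kwargs)
    return hemo_features.temporal_table(feats)
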