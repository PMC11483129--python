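"""Performance metrics of the synchronization-continuation task.

Four standard measures summarize rhythmic tapping per subject, modality
and target interval:

* absolute asynchrony -- mean unsigned stimulus-tap time difference
  during synchronization (phase accuracy);
* constant error -- mean produced interval minus target (period
  accuracy), per epoch;
* temporal variability -- SD (n-1 denominator) of produced intervals
  (period precision), per epoch;
* lag-1 autocorrelation -- of the within-trial produced-interval series
  during synchronization, averaged across trials (negative values
  indicate error correction).

A trial is valid when every produced interval deviates from the target
by less than 30% of the target during synchronization and less than 40%
during continuation; metrics are computed on valid trials only.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .tapping_sim import TappingSession, Trial

__all__ = [
    "pair_taps", "absolute_asynchrony", "constant_error",
    "temporal_variability", "lag1_autocorrelation", "validate_trial",
    "summarize_subject", "BehavioralSummary", "summary_to_frame",
]

METRIC_NAMES = (
    "mean_abs_asynchrony", "constant_error_sync", "constant_error_cont",
    "temporal_variability_sync", "temporal_variability_cont",
    "lag1_autocorr", "n_valid_trials",
)


@dataclass
class BehavioralSummary:
    """Per (modality, target) metric cells for one subject."""

    subject_id: int
    cells: dict  # {(modality, target_ms): {metric: value}}

    def value(self, modality: str, target_ms: float, metric: str):
        return self.cells.get((modality, float(target_ms)), {}).get(metric, np.nan)


def pair_taps(stimulus_onsets, tap_onsets, target_ms: float):
    """Match taps to stimuli: nearest within half a target interval.

    Each tap is assigned to its nearest stimulus; when several taps claim
    the same stimulus the closest wins; a tap exactly on the half-target
    boundary goes to the earlier stimulus.  Returns
    ``(pairs, unmatched_stimuli, unmatched_taps)`` where pairs is a list
    of (stimulus, tap) tuples in stimulus order.
    """
    stim = np.asarray(stimulus_onsets, float)
    taps = np.asarray(tap_onsets, float)
    if len(stim) == 0 or len(taps) == 0:
        return [], list(stim), list(taps)
    half = target_ms / 2.0

    # nearest stimulus per tap; ties go to the earlier stimulus
    j = np.searchsorted(stim, taps)
    cand_lo = np.clip(j - 1, 0, len(stim) - 1)
    cand_hi = np.clip(j, 0, len(stim) - 1)
    d_lo = np.abs(taps - stim[cand_lo])
    d_hi = np.abs(taps - stim[cand_hi])
    nearest = np.where(d_hi < d_lo, cand_hi, cand_lo)  # tie -> earlier
    dist = np.minimum(d_lo, d_hi)

    best_tap = {}
    for t_idx in range(len(taps)):
        s = int(nearest[t_idx])
        if dist[t_idx] > half:
            continue
        if s not in best_tap or dist[t_idx] < dist[best_tap[s]]:
            best_tap[s] = t_idx
    pairs = [(stim[s], taps[t]) for s, t in sorted(best_tap.items())]
    matched_taps = set(best_tap.values())
    un_stim = [stim[s] for s in range(len(stim)) if s not in best_tap]
    un_taps = [taps[t] for t in range(len(taps)) if t not in matched_taps]
    return pairs, un_stim, un_taps


def absolute_asynchrony(pairs) -> float:
    """Mean unsigned tap-stimulus difference; NaN when there are no pairs."""
    if not pairs:
        return np.nan
    a = np.array([tap - s for s, tap in pairs])
    return float(np.mean(np.abs(a)))


def constant_error(produced_intervals, target: float) -> float:
    """Mean produced interval minus the target; NaN for an empty list."""
    x = np.asarray(produced_intervals, float)
    if x.size == 0:
        return np.nan
    return float(np.mean(x) - target)


def temporal_variability(produced_intervals) -> float:
    """Sample standard deviation (n-1) of the produced intervals."""
    x = np.asarray(produced_intervals, float)
    if x.size == 0:
        return np.nan
    if x.size == 1:
        return 0.0
    return float(np.std(x, ddof=1))


def lag1_autocorrelation(trial_interval_series) -> float:
    """Mean across trials of the lag-1 sample autocorrelation.

    Per trial: r1 = sum (x_t - xbar)(x_{t+1} - xbar) / sum (x_t - xbar)^2
    with the trial mean subtracted.  Zero-variance trials are skipped.
    """
    rs = []
    for series in trial_interval_series:
        x = np.asarray(series, float)
        if len(x) < 3:
            raise ValueError("each interval series needs length >= 3")
        xc = x - x.mean()
        denom = np.sum(xc * xc)
        if denom == 0:
            continue
        rs.append(float(np.sum(xc[:-1] * xc[1:]) / denom))
    return float(np.mean(rs)) if rs else np.nan


def validate_trial(trial: Trial, sync_tol: float = 0.30,
                   cont_tol: float = 0.40):
    """Per-epoch validity: every produced interval within tol * target.

    Returns ``(sync_valid, cont_valid)``.
    """
    t = trial.target_ms
    sync_ok = bool(np.all(np.abs(trial.sync_intervals - t) < sync_tol * t))
    cont_ok = bool(np.all(np.abs(trial.cont_intervals - t) < cont_tol * t))
    return sync_ok, cont_ok


def summarize_subject(session: TappingSession, sync_tol: float = 0.30,
                      cont_tol: float = 0.40) -> BehavioralSummary:
    """All SCT metrics per (modality, target) cell, on valid trials only.

    A trial enters a cell when both its epochs pass the validity filter
    (as in the task's correct-trial criterion); the count of retained
    trials is kept alongside the metrics.  Cells with no valid trial are
    reported missing with a warning.
    """
    cells = {}
    for key, trials in session.by_cell().items():
        valid = [t for t in trials
                 if all(validate_trial(t, sync_tol, cont_tol))]
        if not valid:
            warnings.warn(f"no valid trials in cell {key}", stacklevel=2)
            cells[key] = {m: np.nan for m in METRIC_NAMES}
            cells[key]["n_valid_trials"] = 0
            continue
        asyncs, sync_iv, cont_iv, series = [], [], [], []
        for t in valid:
            pairs, _, _ = pair_taps(t.stimulus_onsets, t.sync_taps, t.target_ms)
            asyncs.append(absolute_asynchrony(pairs))
            sync_iv.append(t.sync_intervals)
            cont_iv.append(t.cont_intervals)
            series.append(t.sync_intervals)
        sync_all = np.concatenate(sync_iv)
        cont_all = np.concatenate(cont_iv)
        cells[key] = {
            "mean_abs_asynchrony": float(np.nanmean(asyncs)),
            "constant_error_sync": constant_error(sync_all, key[1]),
            "constant_error_cont": constant_error(cont_all, key[1]),
            "temporal_variability_sync": temporal_variability(sync_all),
            "temporal_variability_cont": temporal_variability(cont_all),
            "lag1_autocorr": lag1_autocorrelation(series),
            "n_valid_trials": len(valid),
        }
    return BehavioralSummary(subject_id=session.subject_id, cells=cells)


SYNC_METRICS = ("mean_abs_asynchrony", "constant_error_sync",
                "temporal_variability_sync", "lag1_autocorr")


def behavior_matrix(summaries, modalities=("auditory", "visual"),
                    targets=(550.0, 650.0, 750.0, 850.0, 950.0),
                    metrics=SYNC_METRICS) -> pd.DataFrame:
    """Subjects x variables matrix of synchronization-phase SCT metrics.

    Columns are named ``<modality>_<target>_<metric>``, one row per
    subject, in subject order.
    """
    cols, data = [], []
    for mod in modalities:
        for tgt in targets:
            for m in metrics:
                cols.append(f"{mod}_{int(tgt)}_{m}")
    for s in summaries:
        row = []
        for mod in modalities:
            for tgt in targets:
                for m in metrics:
                    row.append(s.value(mod, tgt, m))
        data.append(row)
    return pd.DataFrame(data, columns=cols,
                        index=[s.subject_id for s in summaries])


def summary_to_frame(summaries) -> pd.DataFrame:
    """Tidy table (subject, modality, target_ms, metric, value)."""
    rows = []
    for s in summaries:
        for (mod, tgt), metrics in sorted(s.cells.items()):
            for m, v in metrics.items():
                rows.append((s.subject_id, mod, tgt, m, v))
    return pd.DataFrame(rows, columns=["subject", "modality", "target_ms",
                                       "metric", "value"])
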