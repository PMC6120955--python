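"""Sound-cued lever-pull task: trial detection, metrics, selection.

The task: after a tone cue, the mouse must pull a lever 5 mm within 1 s
and hold it past the threshold for 400 ms to earn a reward.  Trials are
detected from the lever-position time series; per-trial metrics (pull
speed, lever-trajectory correlation, reaction time, time since the last
reward) feed both the learning-curve summaries and the behavioral
clustering, and the selection rule (successful, no pre-pull, reaction
time 100-500 ms) picks the trials used for population analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlations import pearson_rows


class BehaviorError(ValueError):
    """Invalid behavior log or trial parameters."""


@dataclass(frozen=True)
class BehaviorLog:
    """Lever position (mm) sampled at ``rate`` Hz plus event timestamps (s)."""

    lever_mm: np.ndarray
    rate: float
    cue_times: np.ndarray
    reward_times: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise BehaviorError("sampling rate must be positive")
        dur = self.lever_mm.size / self.rate
        for name in ("cue_times", "reward_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.size and (t.min() < 0 or t.max() > dur):
                raise BehaviorError(f"{name} outside the recording")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.lever_mm.size) / self.rate


def detect_trials(
    log: BehaviorLog,
    pull_threshold_mm: float = 5.0,
    hold_s: float = 0.4,
    window_s: float = 1.0,
    pre_pull_fraction: float = 0.2,
) -> pd.DataFrame:
    """Per-cue trial outcomes from the lever trace.

    A cue is successful when the lever crosses ``pull_threshold_mm``
    within ``window_s`` of cue onset and stays continuously beyond the
    threshold for at least ``hold_s``.  The pull onset is the last
    sample below the noise floor (3x the s.d. of the second before the
    cue) preceding the threshold crossing; a pre-pull flag marks trials
    with a sub-threshold excursion (> ``pre_pull_fraction`` of the
    threshold) between the cue and the successful pull onset.
    """
    x = np.asarray(log.lever_mm, dtype=float)
    t = log.times
    dt = 1.0 / log.rate
    cues = np.sort(np.asarray(log.cue_times, dtype=float))
    if np.any(np.diff(cues) < window_s):
        raise BehaviorError("overlapping cue windows")
    hold_n = int(round(hold_s * log.rate))

    rows = []
    for cue in cues:
        i_cue = int(np.searchsorted(t, cue))
        i_win = min(int(np.searchsorted(t, cue + window_s)), x.size)
        above = x >= pull_threshold_mm
        success = False
        pull_onset = np.nan
        cross = None
        # first crossing inside the response window that holds long enough
        for i in range(i_cue, i_win):
            if above[i] and (i == 0 or not above[i - 1]):
                j = i
                while j < x.size and above[j]:
                    j += 1
                if (j - i) >= hold_n:
                    success = True
                    cross = i
                    break
        if cross is not None:
            # noise floor from the second before the cue
            base = x[max(0, i_cue - int(log.rate)):i_cue]
            floor = 3.0 * base.std() if base.size else 0.0
            k = cross
            while k > i_cue and x[k - 1] > floor:
                k -= 1
            pull_onset = t[k]
        pre_pull = False
        if success:
            seg = x[i_cue:int(round(pull_onset / dt))]
            # exclude the rising flank itself; look for an earlier bump
            if seg.size:
                pre_pull = bool(np.any(seg > pre_pull_fraction * pull_threshold_mm))
        rt = pull_onset - cue if success else np.nan
        rows.append(
            {
                "cue_time": cue,
                "success": success,
                "pull_onset": pull_onset,
                "reaction_time": rt,
                "pre_pull": pre_pull,
            }
        )
    return pd.DataFrame(rows)


def _trajectory_snippets(
    log: BehaviorLog, onsets: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    n = int(round((window[1] - window[0]) * log.rate))
    offsets = np.arange(n) / log.rate + window[0]
    snippets = np.empty((onsets.size, n))
    for i, onset in enumerate(onsets):
        snippets[i] = np.interp(
            onset + offsets, log.times, log.lever_mm
        )
    return snippets


def lever_correlation(
    log: BehaviorLog,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.5, 2.0),
):
    """Per-trial CC of the lever trajectory against the session template.

    The template is the mean trajectory of all successful trials over
    ``window`` (s, relative to pull onset); the session value is the
    mean of the per-trial CCs.  Two windows are conventional: (-0.5,
    2.0) s for learning curves and (-0.43, 1.85) s for the behavioral
    cluster analysis.  Returns ``(per_trial_cc, session_mean)`` with
    NaN for unsuccessful trials.
    """
    ok = trials["success"].to_numpy(dtype=bool)
    onsets = trials.loc[ok, "pull_onset"].to_numpy(dtype=float)
    if onsets.size < 2:
        raise BehaviorError("need at least 2 successful trials")
    snippets = _trajectory_snippets(log, onsets, window)
    template = snippets.mean(axis=0)
    ccs = pearson_rows(snippets, template[None, :])[:, 0]
    per_trial = np.full(len(trials), np.nan)
    per_trial[ok] = ccs
    return per_trial, float(np.nanmean(ccs))


def pull_speed(
    log: BehaviorLog, trials: pd.DataFrame, half_window_s: float = 0.1
) -> np.ndarray:
    """Maximum lever slope (mm/s) within ±``half_window_s`` of pull onset."""
    out = np.full(len(trials), np.nan)
    t = log.times
    x = np.asarray(log.lever_mm, dtype=float)
    for i, onset in enumerate(trials["pull_onset"]):
        if not np.isfinite(onset):
            continue
        if onset - half_window_s < t[0] or onset + half_window_s > t[-1]:
            continue  # flagged: window outside the recording
        lo = int(np.searchsorted(t, onset - half_window_s))
        hi = int(np.searchsorted(t, onset + half_window_s))
        seg = x[lo:hi + 1]
        if seg.size >= 2:
            out[i] = float(np.max(np.diff(seg)) * log.rate)
    return out


def time_from_previous_reward(
    trials: pd.DataFrame, reward_times: np.ndarray
) -> np.ndarray:
    """Pull onset minus the latest reward before it (NaN without one)."""
    rewards = np.sort(np.asarray(reward_times, dtype=float))
    out = np.full(len(trials), np.nan)
    for i, onset in enumerate(trials["pull_onset"]):
        if not np.isfinite(onset):
            continue
        k = int(np.searchsorted(rewards, onset)) - 1
        if k >= 0:
            out[i] = onset - rewards[k]
    return out


def select_trials(
    trials: pd.DataFrame,
    rt_bounds_s: tuple[float, float] = (0.1, 0.5),
) -> pd.DataFrame:
    """Apply the trial-selection rule used for the population analysis.

    Selected = successful, no pre-pull, and reaction time within
    ``rt_bounds_s`` (inclusive).  Adds a ``selected`` column.
    """
    rt = trials["reaction_time"]
    selected = (
        trials["success"].astype(bool)
        & ~trials["pre_pull"].astype(bool)
        & (rt >= rt_bounds_s[0])
        & (rt <= rt_bounds_s[1])
    )
    return trials.assign(selected=selected.fillna(False))


def annotate_trials(
    log: BehaviorLog,
    trials: pd.DataFrame,
    lever_corr_window: tuple[float, float] = (-0.5, 2.0),
) -> pd.DataFrame:
    """Attach all per-trial behavioral metrics and the selection flag."""
    trials = trials.copy()
    per_trial_cc, _session = lever_correlation(log, trials, lever_corr_window)
    trials["lever_correlation"] = per_trial_cc
    trials["lever_pull_speed"] = pull_speed(log, trials)
    trials["time_from_prev_reward"] = time_from_previous_reward(
        trials, log.reward_times
    )
    return select_trials(trials)
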