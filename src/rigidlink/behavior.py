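"""Behavioral scoring.

Turns bistable-percept timelines and task-switching (TS) trial logs into
per-subject indices:

* perceptual stability = mean across runs of the per-run **median** clear
  percept duration (durations are long-tailed, so the median is the
  representative statistic; the final run-truncated percept is excluded
  because right-censoring would bias it),
* cognitive rigidity = mean across runs of the per-run median task
  repetition (run) length, after removing unclassifiable trials,
* RT for task repetition / switching and the switch cost (means; RTs are
  treated as normal), plus response accuracy in instructed mode.

Aggregation order is fixed: per-run statistic first, then the mean across
runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PerceptTimeline",
    "TrialRecord",
    "SubjectBehavior",
    "percept_durations",
    "median_percept_duration",
    "classify_trial",
    "classify_trials",
    "repetition_runs",
    "median_repetition_length",
    "rt_metrics",
    "score_cohort",
]

CLEAR_LABELS = ("up", "down")


@dataclass(frozen=True)
class PerceptTimeline:
    """One run's percept reports: (onset_s, label) with strictly
    increasing onsets in [0, run_length_s)."""

    subject_id: str
    run_index: int
    events: tuple[tuple[float, str], ...]
    run_length_s: float = 90.0

    def __post_init__(self):
        onsets = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.run_length_s):
            raise ValueError("onsets must lie in [0, run_length_s)")


@dataclass(frozen=True)
class TrialRecord:
    """One TS trial; ``figures`` is a 4-tuple of (shape_id,
    brightness_level, is_target_shape)."""

    run_index: int
    trial_index: int
    mode: str
    cue: str
    figures: tuple[tuple[str, float, bool], ...]
    choice_index: int | None
    rt_ms: float

    def target_shape_index(self) -> int:
        flags = [i for i, f in enumerate(self.figures) if f[2]]
        if len(flags) != 1:
            raise ValueError("exactly one figure must be the target shape")
        return flags[0]

    def brightest_index(self) -> int:
        levels = [f[1] for f in self.figures]
        top = max(levels)
        idx = [i for i, v in enumerate(levels) if v == top]
        if len(idx) != 1:
            raise ValueError("brightness levels must have a unique maximum")
        return idx[0]


@dataclass(frozen=True)
class SubjectBehavior:
    subject_id: str
    median_percept_duration_s: float
    median_repetition_length: float
    rt_repeat_ms: float
    rt_switch_ms: float
    switch_cost_ms: float
    accuracy: float | None
    unclassifiable_fraction: float


# ---------------------------------------------------------------------------
# percept scoring


def percept_durations(events, run_length_s: float = 90.0) -> list[float]:
    """Durations of clear (up/down) percepts in one run.

    Each clear percept lasts from its onset to the next event onset; the
    final percept (truncated by the run end) is dropped, as are mixed
    intervals. ``events`` is a sequence of (onset_s, label) or a
    PerceptTimeline / DataFrame with onset_s + label columns.
    """
    if isinstance(events, PerceptTimeline):
        run_length_s = events.run_length_s
        events = events.events
    if isinstance(events, pd.DataFrame):
        events = list(zip(events["onset_s"], events["label"]))
    events = list(events)
    out: list[float] = []
    for (t0, lab), (t1, _lab1) in zip(events, events[1:]):
        if t1 <= t0:
            raise ValueError("event onsets must be strictly increasing")
        if lab in CLEAR_LABELS:
            out.append(t1 - t0)
    return out


def median_percept_duration(per_run_durations: list[list[float]]) -> float:
    """Per-run median of clear durations, then the mean across runs."""
    medians = [float(np.median(d)) for d in per_run_durations if len(d) > 0]
    if not medians:
        raise ValueError("no clear percept durations in any run; subject unusable")
    return float(np.mean(medians))


# ---------------------------------------------------------------------------
# task inference


def classify_trial(trial: TrialRecord) -> str:
    """Retrospective task inference for one trial: 'shape' if the chosen
    figure is the target shape, 'brightness' if it is the uniquely
    brightest, else (or on timeout) 'unclassifiable'."""
    target = trial.target_shape_index()
    brightest = trial.brightest_index()
    if target == brightest:
        raise ValueError("stimulus invariant violated: target shape is also brightest")
    if trial.choice_index is None or trial.choice_index < 0:
        return "unclassifiable"
    if trial.choice_index == target:
        return "shape"
    if trial.choice_index == brightest:
        return "brightness"
    return "unclassifiable"


def classify_trials(trials: pd.DataFrame) -> np.ndarray:
    """Vectorized classify_trial over a generator-format trial table
    (circle_index / bright_index / choice_index columns)."""
    choice = trials["choice_index"].to_numpy()
    circle = trials["circle_index"].to_numpy()
    bright = trials["bright_index"].to_numpy()
    if np.any(circle == bright):
        raise ValueError("stimulus invariant violated: target shape is also brightest")
    out = np.full(len(trials), "unclassifiable", dtype=object)
    out[choice == circle] = "shape"
    out[choice == bright] = "brightness"
    out[choice < 0] = "unclassifiable"
    return out


# ---------------------------------------------------------------------------
# repetition runs


def repetition_runs(labels) -> list[int]:
    """Maximal run-length encoding of a task-label stream (unclassifiable
    labels must already be removed); the run lengths sum to the stream
    length."""
    labels = [l for l in labels]
    if any(l == "unclassifiable" for l in labels):
        raise ValueError("remove unclassifiable labels before run-length encoding")
    runs: list[int] = []
    for lab, prev in zip(labels, [None] + labels[:-1]):
        if lab == prev:
            runs[-1] += 1
        else:
            runs.append(1)
    return runs


def median_repetition_length(per_run_labels: list[list[str]]) -> float:
    """Per-run median run length, then the mean across runs."""
    medians = []
    for labels in per_run_labels:
        if len(labels) == 0:
            raise ValueError("a run with zero classified trials cannot be scored")
        medians.append(float(np.median(repetition_runs(labels))))
    return float(np.mean(medians))


# ---------------------------------------------------------------------------
# reaction times


def rt_metrics(
    per_run_trials: list[pd.DataFrame], instructed: bool = False
) -> dict[str, float]:
    """Mean repeat RT, mean switch RT, switch cost, and (instructed mode)
    accuracy; per-run means are averaged across runs, like every other
    behavioral index.

    Unclassifiable/timeout trials are excluded; each classified trial is
    a repeat or switch relative to the previous *classified* trial of its
    run, and the first classified trial of a run is neither. Runs lacking
    a pool (e.g. no switch trial) drop out of that pool's average.
    """
    repeat_means: list[float] = []
    switch_means: list[float] = []
    n_correct = 0
    n_scored = 0
    for run in per_run_trials:
        labels = classify_trials(run)
        keep = labels != "unclassifiable"
        rts = run["rt_ms"].to_numpy()[keep]
        labs = labels[keep]
        if instructed:
            cues = run["cue"].to_numpy()[keep]
            n_correct += int(np.sum(labs == cues))
            n_scored += len(labs)
        if len(labs) < 2:
            continue
        is_switch = labs[1:] != labs[:-1]
        if np.any(~is_switch):
            repeat_means.append(float(np.mean(rts[1:][~is_switch])))
        if np.any(is_switch):
            switch_means.append(float(np.mean(rts[1:][is_switch])))
    if not repeat_means or not switch_means:
        raise ValueError("need at least one repeat and one switch trial for RT metrics")
    out = {
        "rt_repeat_ms": float(np.mean(repeat_means)),
        "rt_switch_ms": float(np.mean(switch_means)),
    }
    out["switch_cost_ms"] = out["rt_switch_ms"] - out["rt_repeat_ms"]
    if instructed:
        out["accuracy"] = n_correct / n_scored if n_scored else float("nan")
    return out


# ---------------------------------------------------------------------------
# cohort-level scoring


def _per_run_medians(events: pd.DataFrame, run_length_s: float) -> list[float]:
    out = []
    for _, run_df in events.groupby("run", sort=True):
        d = percept_durations(run_df, run_length_s)
        if d:
            out.append(float(np.median(d)))
    return out


def score_subject(
    percept_events: pd.DataFrame,
    trials: pd.DataFrame,
    run_length_s: float = 90.0,
    subject_id: str = "",
) -> SubjectBehavior:
    """Score one subject from generator-format tables (all runs)."""
    medians = _per_run_medians(percept_events, run_length_s)
    if not medians:
        raise ValueError(f"subject {subject_id}: no clear percepts in any run")
    percept_med = float(np.mean(medians))

    spont = trials[trials["mode"] == "spontaneous"]
    rep_medians = []
    n_uncls = 0
    n_all = 0
    spont_runs = []
    for _, run_df in spont.groupby("run", sort=True):
        labels = classify_trials(run_df)
        kept = [l for l in labels if l != "unclassifiable"]
        n_uncls += len(labels) - len(kept)
        n_all += len(labels)
        if len(kept) == 0:
            raise ValueError(f"subject {subject_id}: a run with zero classified trials")
        rep_medians.append(float(np.median(repetition_runs(kept))))
        spont_runs.append(run_df)
    rep_med = float(np.mean(rep_medians))
    spont_rt = rt_metrics(spont_runs, instructed=False)

    return SubjectBehavior(
        subject_id=subject_id,
        median_percept_duration_s=percept_med,
        median_repetition_length=rep_med,
        rt_repeat_ms=spont_rt["rt_repeat_ms"],
        rt_switch_ms=spont_rt["rt_switch_ms"],
        switch_cost_ms=spont_rt["switch_cost_ms"],
        accuracy=None,
        unclassifiable_fraction=n_uncls / n_all if n_all else float("nan"),
    )


def score_cohort(cohort) -> pd.DataFrame:
    """Per-subject behavior table for a CohortDataset (or any object with
    percept_events / trials / subjects frames). Adds instructed-mode RT
    metrics and accuracy next to the spontaneous indices."""
    rows = []
    run_length = cohort.spec.run_length_s if hasattr(cohort, "spec") else 90.0
    trials_by_subject = dict(tuple(cohort.trials.groupby("subject", sort=False)))
    for sid, sub_events in cohort.percept_events.groupby("subject", sort=False):
        sub_trials = trials_by_subject[sid]
        sb = score_subject(sub_events, sub_trials, run_length, subject_id=sid)
        instr_runs = [
            run_df
            for _, run_df in sub_trials[sub_trials["mode"] == "instructed"].groupby(
                "run", sort=True
            )
        ]
        instr = rt_metrics(instr_runs, instructed=True)
        rows.append(
            {
                "subject": sid,
                "median_percept_duration_s": sb.median_percept_duration_s,
                "median_repetition_length": sb.median_repetition_length,
                "rt_repeat_ms": sb.rt_repeat_ms,
                "rt_switch_ms": sb.rt_switch_ms,
                "switch_cost_ms": sb.switch_cost_ms,
                "unclassifiable_fraction": sb.unclassifiable_fraction,
                "instr_rt_repeat_ms": instr["rt_repeat_ms"],
                "instr_rt_switch_ms": instr["rt_switch_ms"],
                "instr_switch_cost_ms": instr["switch_cost_ms"],
                "instr_accuracy": instr["accuracy"],
            }
        )
    table = pd.DataFrame(rows)
    return table.merge(cohort.subjects, on="subject", how="left")
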