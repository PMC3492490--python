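"""State-space velocity: a quantitative measure of behavioural-state
instability.

Velocity is the Euclidean distance between two consecutive state-space
points divided by the epoch length. Low velocities mark consolidated sleep
with stable spectra; high velocities mark transitions and within-state
fluctuations. A heuristic cutoff splits epochs into slow (stable) and fast
(transitional) states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral import StateTrajectory


@dataclass
class VelocitySeries:
    """Nonnegative state-space speeds, one per consecutive epoch pair."""

    values: np.ndarray
    epoch_length: float
    channel: str = ""
    smoothed_window: int = 0

    def __len__(self) -> int:
        return len(self.values)


def velocity_series(traj: StateTrajectory | np.ndarray, epoch_length: float | None = None,
                    channel: str = "", smoothed_window: int = 0) -> VelocitySeries:
    """v_i = ||p_{i+1} - p_i||_2 / epoch_length.

    Accepts a :class:`StateTrajectory` or a raw (n, 2) point array (then
    ``epoch_length`` is required). Length of the result is n_points - 1.
    """
    if isinstance(traj, StateTrajectory):
        points = traj.points
        epoch_length = traj.epoch_length
        channel = traj.channel
        smoothed_window = traj.smoothing_window
    else:
        points = np.asarray(traj, dtype=float)
        if epoch_length is None:
            raise ValueError("epoch_length required for raw point arrays")
    if len(points) < 2:
        raise ValueError("need at least 2 trajectory points")
    steps = np.diff(points, axis=0)
    v = np.linalg.norm(steps, axis=1) / epoch_length
    return VelocitySeries(values=v, epoch_length=epoch_length, channel=channel,
                          smoothed_window=smoothed_window)


def resolve_cutoff(v: np.ndarray, cutoff) -> float:
    """Resolve an absolute cutoff or a percentile spec like ``"p75"``."""
    if isinstance(cutoff, str):
        if not (cutoff.startswith("p") and cutoff[1:].replace(".", "", 1).isdigit()):
            raise ValueError(f"bad cutoff spec {cutoff!r}; use a number or 'pNN'")
        return float(np.percentile(v, float(cutoff[1:])))
    cutoff = float(cutoff)
    if cutoff < 0:
        raise ValueError("absolute velocity cutoff must be nonnegative")
    return cutoff


def split_slow_fast(v: VelocitySeries | np.ndarray, cutoff="p75") -> tuple[np.ndarray, np.ndarray]:
    """Partition epoch pairs into slow (v < cutoff) and fast (the rest).

    ``cutoff`` is an absolute speed or a percentile of this recording's own
    velocity distribution (default the 75th). Ties at the cutoff count as
    fast. Returns boolean masks (slow, fast) that partition the series.
    """
    values = v.values if isinstance(v, VelocitySeries) else np.asarray(v, dtype=float)
    thr = resolve_cutoff(values, cutoff)
    slow = values < thr
    return slow, ~slow


def velocity_stage_labels(labels: np.ndarray) -> np.ndarray:
    """Align a per-epoch label sequence to velocity entries.

    Velocity entry i spans epochs i and i+1 and is assigned the label of the
    *arrival* epoch i+1, so speed at a transition is attributed to the stage
    being entered.
    """
    labels = np.asarray(labels, dtype=object)
    return labels[1:]


def stage_velocity_stats(
    velocities_by_subject: dict,
    labels_by_subject: dict,
    compare: list[tuple[str, str]] | None = None,
) -> dict:
    """Per-stage velocity means with between-subject SEM and paired tests.

    Parameters
    ----------
    velocities_by_subject : dict of subject id -> VelocitySeries or array
    labels_by_subject : dict of subject id -> per-epoch stage labels
        (length n_epochs; aligned internally to the n_epochs - 1 velocity
        entries via :func:`velocity_stage_labels`).
    compare : stage pairs for paired two-sided t-tests across subjects.

    Returns ``{"per_stage": {stage: {"mean", "sem", "n_subjects"}},
    "tests": {(a, b): {"t", "p", "n"}}}``. A stage with no epochs for a
    subject is a missing value for that subject. A constant nonzero paired
    difference across subjects is reported as t = +/-inf, p = 0.
    """
    subject_means: dict[str, dict] = {}
    all_stages: list[str] = []
    for sid, v in velocities_by_subject.items():
        values = v.values if isinstance(v, VelocitySeries) else np.asarray(v, float)
        lab = velocity_stage_labels(labels_by_subject[sid])
        if len(lab) != len(values):
            raise ValueError(f"subject {sid}: labels not aligned to velocities")
        means = {}
        for s in set(lab):
            means[s] = float(np.mean(values[lab == s]))
            if s not in all_stages:
                all_stages.append(s)
        subject_means[sid] = means

    per_stage = {}
    for s in all_stages:
        vals = np.array([m[s] for m in subject_means.values() if s in m])
        per_stage[s] = {
            "mean": float(vals.mean()),
            "sem": float(stats.sem(vals)) if len(vals) > 1 else float("nan"),
            "n_subjects": int(len(vals)),
        }

    tests = {}
    for a, b in compare or []:
        pairs = np.array(
            [(m[a], m[b]) for m in subject_means.values() if a in m and b in m]
        )
        if len(pairs) < 2:
            tests[(a, b)] = {"t": float("nan"), "p": float("nan"), "n": len(pairs)}
            continue
        d = pairs[:, 0] - pairs[:, 1]
        if np.allclose(d.std(ddof=1), 0.0):
            # degenerate: identical difference in every subject
            t = 0.0 if np.allclose(d.mean(), 0) else float(np.sign(d.mean())) * np.inf
            p = 1.0 if t == 0.0 else 0.0
        else:
            t, p = stats.ttest_rel(pairs[:, 0], pairs[:, 1])
        tests[(a, b)] = {"t": float(t), "p": float(p), "n": int(len(pairs))}

    return {"per_stage": per_stage, "tests": tests}
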