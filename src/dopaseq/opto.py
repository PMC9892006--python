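"""Closed-loop stimulation effects: excess target counts, learner
classification, specificity in time and kinematic similarity, post-stimulation
dynamics, and learning scores.

All quantities compare stimulation-day sessions with baseline-day sessions
from the same animal.  The workhorse is the excess-count series: target
counts in non-overlapping 30-s bins, cumulatively summed, with the average of
the baseline sessions' cumulative counts subtracted off.
"""

from __future__ import annotations

import warnings

import numpy as np

from .stats import transition_entropy

__all__ = [
    "excess_target_counts",
    "classify_learners",
    "temporal_adjacency_effect",
    "velocity_similarity_effect",
    "post_stim_dynamics",
    "opto_learning_score",
    "velocity_quartile_effect",
    "syllable_count_changes",
]


def _binned_counts(session, syllable: int, window_s: float, frame_rate_hz: float) -> np.ndarray:
    win = int(round(window_s * frame_rate_hz))
    n_bins = max(1, session.n_frames // win)
    onsets = np.asarray(session.onset_frames)[np.asarray(session.labels) == syllable]
    bins = np.minimum(onsets // win, n_bins - 1)
    return np.bincount(bins, minlength=n_bins).astype(float)


def excess_target_counts(
    stim_sessions, baseline_sessions, target: int,
    window_s: float = 30.0, frame_rate_hz: float = 30.0,
) -> np.ndarray:
    """Cumulative excess target counts: stimulation-session cumulative counts
    minus the mean of the baseline sessions' cumulative counts, per 30-s bin,
    averaged over stimulation sessions."""
    if len(stim_sessions) < 1 or len(baseline_sessions) < 2:
        raise ValueError("need >= 1 stim and >= 2 baseline sessions")
    stim = [np.cumsum(_binned_counts(s, target, window_s, frame_rate_hz))
            for s in stim_sessions]
    base = [np.cumsum(_binned_counts(s, target, window_s, frame_rate_hz))
            for s in baseline_sessions]
    n = min(min(len(c) for c in stim), min(len(c) for c in base))
    if len({len(c) for c in stim + base}) > 1:
        warnings.warn("session durations differ; truncating to the shortest")
    stim_mean = np.mean([c[:n] for c in stim], axis=0)
    base_mean = np.mean([c[:n] for c in base], axis=0)
    return stim_mean - base_mean


def classify_learners(mouse_means: np.ndarray, control_values: np.ndarray) -> np.ndarray:
    """A mouse is a learner iff its mean excess exceeds (strictly) the maximum
    mean excess over no-opsin control animals."""
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size < 1:
        raise ValueError("need at least 1 control value")
    return np.asarray(mouse_means, dtype=float) > control_values.max()


def syllable_count_changes(
    stim_sessions, baseline_sessions, n_syllables: int,
    window_s: float = 30.0, frame_rate_hz: float = 30.0,
) -> np.ndarray:
    """Terminal cumulative excess counts for every syllable (the same 30-s-bin
    machinery as the target), one value per syllable."""
    out = np.zeros(n_syllables)
    for s in range(n_syllables):
        out[s] = excess_target_counts(
            stim_sessions, baseline_sessions, s, window_s, frame_rate_hz
        )[-1]
    return out


def _mean_offset_to_target(labels: np.ndarray, target: int, max_offset: int = 10) -> dict:
    """Per non-target syllable: mean signed syllable-step distance to the
    nearest target instance, restricted to |offset| <= max_offset."""
    t_idx = np.flatnonzero(labels == target)
    out = {}
    if t_idx.size == 0:
        return out
    for s in np.unique(labels):
        if s == target:
            continue
        s_idx = np.flatnonzero(labels == s)
        pos = np.searchsorted(t_idx, s_idx)
        cand = []
        for i, p in zip(s_idx, pos):
            choices = []
            if p < t_idx.size:
                choices.append(i - t_idx[p])  # negative: syllable before target
            if p > 0:
                choices.append(i - t_idx[p - 1])  # positive: after target
            if choices:
                off = min(choices, key=abs)
                if abs(off) <= max_offset:
                    cand.append(off)
        if cand:
            out[int(s)] = float(np.mean(cand))
    return out


def temporal_adjacency_effect(
    stim_sessions, baseline_sessions, target: int, n_syllables: int,
    max_offset: int = 10, window_s: float = 30.0, frame_rate_hz: float = 30.0,
) -> dict:
    """Change in counts above baseline for non-target syllables, binned by
    their mean signed temporal offset to the nearest target instance
    (21 bins, -10..+10 syllables), frequency-weighted within bin."""
    changes = syllable_count_changes(stim_sessions, baseline_sessions,
                                     n_syllables, window_s, frame_rate_hz)
    all_labels = np.concatenate([np.asarray(s.labels) for s in stim_sessions])
    freq = np.bincount(all_labels, minlength=n_syllables).astype(float)
    freq /= freq.sum()
    offsets = _mean_offset_to_target(all_labels, target, max_offset)
    edges = np.linspace(-max_offset, max_offset, 2 * max_offset + 2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = np.full(centers.size, np.nan)
    weights_per_bin = np.zeros(centers.size)
    for b in range(centers.size):
        members = [s for s, off in offsets.items()
                   if edges[b] <= off < edges[b + 1]]
        if not members:
            continue
        w = freq[members]
        w = w / w.sum()
        weights_per_bin[b] = w.sum()
        profile[b] = float(np.sum(w * changes[members]))
    return {"offset_bins": centers, "profile": profile,
            "bin_weights": weights_per_bin, "per_syllable_offset": offsets,
            "per_syllable_change": changes}


def velocity_similarity_effect(
    stim_sessions, baseline_sessions, target: int, n_syllables: int,
    n_bins: int = 9, window_s: float = 30.0, frame_rate_hz: float = 30.0,
) -> dict:
    """Count changes binned by each syllable's velocity difference from the
    target (instance-z-scored velocities per session)."""
    changes = syllable_count_changes(stim_sessions, baseline_sessions,
                                     n_syllables, window_s, frame_rate_hz)
    vels = np.full(n_syllables, np.nan)
    per_session = []
    for s in stim_sessions + baseline_sessions:
        if s.kinematics is None:
            continue
        labels = np.asarray(s.labels)
        onsets = np.asarray(s.onset_frames)
        v2d = s.kinematics.velocity_2d
        ends = np.append(onsets[1:], len(v2d))
        inst_v = np.array([v2d[a:b].mean() for a, b in zip(onsets, ends)])
        sd = inst_v.std()
        inst_z = (inst_v - inst_v.mean()) / (sd if sd > 0 else 1.0)
        row = np.full(n_syllables, np.nan)
        for syl in np.unique(labels):
            row[syl] = inst_z[labels == syl].mean()
        per_session.append(row)
    if not per_session:
        raise ValueError("velocities unavailable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vels = np.nanmean(per_session, axis=0)
    diff = vels - vels[target]
    lim = np.nanmax(np.abs(np.delete(diff, target))) or 1.0
    edges = np.linspace(-lim, lim, n_bins + 1)
    edges[-1] += 1e-9
    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = np.full(n_bins, np.nan)
    for b in range(n_bins):
        members = [s for s in range(n_syllables)
                   if s != target and np.isfinite(diff[s])
                   and edges[b] <= diff[s] < edges[b + 1]]
        if members:
            profile[b] = float(np.mean(changes[members]))
    return {"velocity_diff_bins": centers, "profile": profile,
            "per_syllable_velocity_diff": diff, "per_syllable_change": changes}


def post_stim_dynamics(
    sessions,
    metrics=("entropy", "velocity_2d", "angular", "height", "acceleration"),
    bin_syllables: int = 5, n_bins: int = 6, min_catch: int = 10,
) -> dict:
    """Post-onset behavioural metrics in five-syllable bins, pre-onset value
    subtracted, z-scored per bin against the catch-trial distribution."""
    stim_vals = {m: [[] for _ in range(n_bins)] for m in metrics}
    catch_vals = {m: [[] for _ in range(n_bins)] for m in metrics}
    n_catch_total = 0
    for s in sessions:
        if s.stim is None or s.stim.phase != "stimulation":
            continue
        labels = np.asarray(s.labels)
        onsets = np.asarray(s.onset_frames)
        target_steps = np.flatnonzero(labels == s.stim.target)
        kin = s.kinematics
        for flags, store in ((s.stim.stim_instance_flags, stim_vals),
                             (s.stim.catch_instance_flags, catch_vals)):
            events = target_steps[flags]
            if store is catch_vals:
                n_catch_total += events.size
            for t0 in events:
                pre_a, pre_b = max(0, t0 - bin_syllables), t0
                for b in range(n_bins):
                    a = t0 + b * bin_syllables
                    z = a + bin_syllables
                    if z + 1 > labels.size or pre_b - pre_a < 2:
                        continue
                    for m in metrics:
                        post = _bin_metric(m, labels, onsets, kin, a, z)
                        pre = _bin_metric(m, labels, onsets, kin, pre_a, pre_b)
                        if np.isfinite(post) and np.isfinite(pre):
                            store[m][b].append(post - pre)
    if n_catch_total < min_catch:
        raise ValueError("too few catch trials")
    out = {}
    for m in metrics:
        zrow = np.full(n_bins, np.nan)
        for b in range(n_bins):
            cv = np.asarray(catch_vals[m][b])
            sv = np.asarray(stim_vals[m][b])
            if cv.size >= 2 and sv.size >= 1 and cv.std(ddof=1) > 0:
                zrow[b] = (sv.mean() - cv.mean()) / cv.std(ddof=1)
        out[m] = zrow
    return out


def _bin_metric(metric, labels, onsets, kin, a, b):
    if metric == "entropy":
        seg = labels[a: b + 1]
        if seg.size < 3:
            return np.nan
        H = transition_entropy(seg, n_syllables=labels.max() + 1)
        return float(np.nanmean(H))
    if kin is None:
        return np.nan
    series = {"velocity_2d": kin.velocity_2d, "angular": kin.angular_velocity,
              "height": kin.height_velocity, "acceleration": kin.acceleration}[metric]
    f0 = onsets[a]
    f1 = onsets[b] if b < onsets.size else len(series)
    if f1 <= f0:
        return np.nan
    return float(np.mean(series[f0:f1]))


def opto_learning_score(
    stim_counts: float, baseline_counts: float, nonstim_day_pairs,
) -> dict:
    """z-scored log2 fold change of target counts on stimulation vs baseline
    days, normalized by the distribution of log2 fold changes over all pairs
    of non-stimulation days."""
    if len(nonstim_day_pairs) < 2:
        raise ValueError("need at least 2 non-stimulation day pairs")
    smoothed = False

    def lfc(a, b):
        nonlocal smoothed
        if a <= 0 or b <= 0:
            smoothed = True
            a, b = a + 1.0, b + 1.0
        return np.log2(a / b)

    obs = lfc(float(stim_counts), float(baseline_counts))
    null = np.array([lfc(float(a), float(b)) for a, b in nonstim_day_pairs])
    sd = null.std(ddof=1)
    score = (obs - null.mean()) / sd if sd > 0 else np.nan
    return {"score": float(score), "log2fc": float(obs),
            "null_mean": float(null.mean()), "null_sd": float(sd),
            "smoothed": smoothed}


def velocity_quartile_effect(
    pre_sessions, stim_sessions, target: int, arm: str = "high",
    min_stimulations: int = 50,
) -> dict:
    """Velocity-contingent stimulation: change in the target syllable's mean
    velocity after stimulating only its fastest (top-quartile) or slowest
    (bottom-quartile) instances."""
    if arm not in ("high", "low"):
        raise ValueError("arm must be 'high' or 'low'")

    def target_velocities(sessions):
        vals = []
        for s in sessions:
            if s.kinematics is None:
                continue
            labels = np.asarray(s.labels)
            onsets = np.asarray(s.onset_frames)
            v2d = s.kinematics.velocity_2d
            ends = np.append(onsets[1:], len(v2d))
            for lab, a, b in zip(labels, onsets, ends):
                if lab == target and b > a:
                    vals.append(v2d[a:b].mean())
        return np.asarray(vals, dtype=float)

    n_stim = sum(
        int(s.stim.stim_instance_flags.sum())
        for s in stim_sessions if s.stim is not None
    )
    if n_stim < min_stimulations:
        return {"excluded": True, "n_stimulations": n_stim, "shift": np.nan}
    pre = target_velocities(pre_sessions)
    post = target_velocities(stim_sessions)
    if pre.size == 0 or post.size == 0:
        raise ValueError("no target instances with velocity")
    return {"excluded": False, "n_stimulations": n_stim,
            "shift": float(post.mean() - pre.mean()),
            "quartile_thresholds": (float(np.percentile(pre, 25)),
                                    float(np.percentile(pre, 75))),
            "arm": arm}
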