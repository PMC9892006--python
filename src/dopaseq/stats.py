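"""Statistics linking syllable-instance dopamine peaks to usage, sequencing
and kinematics.

The central container is the *syllable peak table*: one row per syllable
instance with the dopamine peak (max z-scored fluorescence from syllable
onset to 300 ms after onset, i.e. 10 samples at 30 Hz) and behavioural
covariates.  On top of it:

* expanding-bin correlations between an instance's peak and its syllable's
  usage / velocity / sequence entropy over the following n syllables
  (n = 5..400), z-scored against dopamine shuffles and averaged over five
  within-session time segments;
* exponential-decay fits (bootstrap tau distributions) to those curves;
* the 3-minute-window cross-correlation between syllable-associated dopamine
  and usage of the same syllable;
* Huber-regression summaries with repeated cross-validation and shuffle
  p-values;
* movement-initiation changepoints and kinematic partialing;
* the "endogenous dopamine influence" index (s.d. across bin sizes of the
  shuffle-z-scored correlation curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import signal as sps
from sklearn.linear_model import HuberRegressor
from sklearn.model_selection import KFold

__all__ = [
    "CorrelationCurve",
    "DecayFit",
    "extract_syllable_peaks",
    "peak_table_from_sessions",
    "timewarp_traces",
    "aligned_average_z",
    "transition_matrix",
    "transition_entropy",
    "expanding_bin_correlation",
    "fit_decay_tau",
    "cross_correlation_usage",
    "huber_regression_cv",
    "movement_initiations",
    "partial_out_kinematics",
    "endo_da_influence",
]

PEAK_WINDOW_FRAMES = 10  # onset .. onset + 300 ms at 30 Hz, onset inclusive
DEFAULT_BIN_SIZES = (5, 10, 25, 50, 100, 200, 300, 400)


# ---------------------------------------------------------------------------
# peak table
# ---------------------------------------------------------------------------

def extract_syllable_peaks(session, zscored: np.ndarray) -> pd.DataFrame:
    """One row per syllable instance with the 300-ms-window dopamine peak.

    The window is frames [onset, onset + 9] (10 samples at 30 Hz), truncated
    at the end of the trace.
    """
    z = np.asarray(zscored, dtype=float)
    onsets = np.asarray(session.onset_frames, dtype=int)
    if onsets.size and onsets.max() >= z.shape[0]:
        raise ValueError("onsets beyond the end of the trace")
    peaks = np.array([
        z[o: min(o + PEAK_WINDOW_FRAMES, z.shape[0])].max() for o in onsets
    ])
    vel = np.full(onsets.size, np.nan)
    if session.kinematics is not None:
        v2d = session.kinematics.velocity_2d
        ends = np.append(onsets[1:], len(v2d))
        vel = np.array([v2d[a:b].mean() if b > a else np.nan
                        for a, b in zip(onsets, ends)])
    df = pd.DataFrame({
        "mouse": session.mouse,
        "session": session.session,
        "instance_index": np.arange(onsets.size),
        "syllable": np.asarray(session.labels, int),
        "onset_frame": onsets,
        "duration_frames": np.asarray(session.durations_frames, int),
        "peak": peaks,
        "velocity": vel,
    })
    return _add_normalized_peaks(df)


def _add_normalized_peaks(df: pd.DataFrame) -> pd.DataFrame:
    def _z(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    df = df.copy()
    df["peak_z_session"] = df.groupby(["mouse", "session"])["peak"].transform(_z)
    df["peak_norm_mouse_syllable"] = df.groupby(["mouse", "syllable"])["peak"].transform(_z)
    return df


def peak_table_from_sessions(sessions, use_truth: bool = True) -> pd.DataFrame:
    """Stack per-session peak tables.  With ``use_truth`` the generator's
    ground-truth amplitudes stand in for measured peaks (they are already in
    z-units); otherwise the processed photometry z-trace is used."""
    frames = []
    for s in sessions:
        if use_truth:
            onsets = np.asarray(s.onset_frames, int)
            vel = np.full(onsets.size, np.nan)
            if s.kinematics is not None:
                v2d = s.kinematics.velocity_2d
                ends = np.append(onsets[1:], len(v2d))
                vel = np.array([v2d[a:b].mean() if b > a else np.nan
                                for a, b in zip(onsets, ends)])
            frames.append(pd.DataFrame({
                "mouse": s.mouse, "session": s.session,
                "instance_index": np.arange(s.n_steps),
                "syllable": s.labels, "onset_frame": onsets,
                "duration_frames": s.durations_frames,
                "peak": s.da_amplitudes, "velocity": vel,
            }))
        else:
            if s.photometry is None or s.photometry.zscored is None:
                raise ValueError("session lacks processed photometry")
            frames.append(extract_syllable_peaks(s, s.photometry.zscored))
    return _add_normalized_peaks(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# waveform utilities
# ---------------------------------------------------------------------------

def timewarp_traces(traces, target_len: int = 25) -> np.ndarray:
    """Linearly interpolate each per-instance trace onto ``target_len`` points."""
    out = np.empty((len(traces), target_len))
    grid = np.linspace(0.0, 1.0, target_len)
    for i, tr in enumerate(traces):
        tr = np.asarray(tr, dtype=float)
        if tr.size < 2:
            raise ValueError("each trace needs at least 2 samples")
        out[i] = np.interp(grid, np.linspace(0.0, 1.0, tr.size), tr)
    return out


def aligned_average_z(
    trace: np.ndarray,
    event_frames: np.ndarray,
    rate: float = 30.0,
    window_s: float = 10.0,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Event-aligned average waveform, doubly z-scored.

    Stage 1: each trial is z-scored within its +/- ``window_s`` window.
    Stage 2: the trial average is z-scored against the mean/s.d. of
    ``n_shuffles`` averages in which each trial is independently circularly
    permuted.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles for the null")
    trace = np.asarray(trace, dtype=float)
    half = int(round(window_s * rate))
    events = np.asarray(event_frames, dtype=int)
    events = events[(events >= half) & (events + half < trace.shape[0])]
    if events.size < 2:
        raise ValueError("need at least 2 events with full windows")
    trials = np.stack([trace[e - half: e + half + 1] for e in events])
    mu = trials.mean(axis=1, keepdims=True)
    sd = trials.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    trials = (trials - mu) / sd
    avg = trials.mean(axis=0)
    rng = np.random.default_rng(seed)
    width = trials.shape[1]
    null = np.empty((n_shuffles, width))
    for k in range(n_shuffles):
        shifts = rng.integers(1, width, size=trials.shape[0])
        null[k] = np.mean(
            [np.roll(trials[i], shifts[i]) for i in range(trials.shape[0])], axis=0
        )
    nm, nsd = null.mean(axis=0), null.std(axis=0)
    nsd[nsd == 0] = 1.0
    return (avg - nm) / nsd


# ---------------------------------------------------------------------------
# transitions and entropy
# ---------------------------------------------------------------------------

def transition_matrix(labels: np.ndarray, n_syllables: int | None = None,
                      normalize: bool = True) -> np.ndarray:
    """Empirical syllable-to-syllable transition matrix (diagonal is zero
    because the data contain no self-transitions)."""
    labels = np.asarray(labels, dtype=int)
    K = int(labels.max()) + 1 if n_syllables is None else int(n_syllables)
    M = np.zeros((K, K))
    np.add.at(M, (labels[:-1], labels[1:]), 1.0)
    if normalize:
        rows = M.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            M = np.where(rows > 0, M / rows, np.nan)
    return M


def transition_entropy(labels_or_matrix, n_syllables: int | None = None) -> np.ndarray:
    """Shannon entropy (nats) of each syllable's outgoing transition
    distribution; NaN for syllables with no outgoing transitions."""
    arr = np.asarray(labels_or_matrix, dtype=float)
    if arr.ndim == 1:
        P = transition_matrix(arr.astype(int), n_syllables, normalize=True)
    else:
        rows = np.nansum(arr, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            P = np.where(rows > 0, arr / rows, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    H = terms.sum(axis=1)
    H[np.isnan(P).all(axis=1)] = np.nan
    return H


# ---------------------------------------------------------------------------
# expanding-bin correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCurve:
    """Correlation between instance peaks and a forward-aggregated outcome,
    as a function of the aggregation bin size."""

    bin_sizes: np.ndarray
    r_raw: np.ndarray
    r_z: np.ndarray
    n_shuffles: int
    segments: int = 5
    segment_curves: np.ndarray | None = None  # rows: session x segment

    def __post_init__(self):
        self.bin_sizes = np.asarray(self.bin_sizes, dtype=int)
        if np.any(np.diff(self.bin_sizes) <= 0):
            raise ValueError("bin_sizes must be strictly increasing")
        if np.any(np.abs(np.asarray(self.r_raw)[~np.isnan(self.r_raw)]) > 1 + 1e-12):
            raise ValueError("|r| must not exceed 1")


def _forward_counts(labels: np.ndarray, n: int) -> np.ndarray:
    """count of labels[t] among labels[t+1 .. t+n]; NaN where the window
    overruns the sequence."""
    T = labels.shape[0]
    out = np.full(T, np.nan)
    if T <= n:
        return out
    K = labels.max() + 1
    onehot = np.zeros((T + 1, K))
    onehot[np.arange(1, T + 1), labels] = 1.0
    cum = np.cumsum(onehot, axis=0)  # cum[t] = counts of labels[:t]
    t = np.arange(T - n)
    out[: T - n] = cum[t + 1 + n, labels[t]] - cum[t + 1, labels[t]]
    return out


def _forward_mean(x: np.ndarray, n: int) -> np.ndarray:
    """mean of x[t+1 .. t+n]; NaN where the window overruns."""
    T = x.shape[0]
    out = np.full(T, np.nan)
    if T <= n:
        return out
    c = np.concatenate([[0.0], np.cumsum(np.nan_to_num(x))])
    cnt = np.concatenate([[0.0], np.cumsum(~np.isnan(x))])
    t = np.arange(T - n)
    num = c[t + 1 + n] - c[t + 1]
    den = cnt[t + 1 + n] - cnt[t + 1]
    with np.errstate(invalid="ignore"):
        out[: T - n] = np.where(den > 0, num / den, np.nan)
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _segment_bounds(T: int, segments: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, T, segments + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(segments)]


def _entropy_bin_r(labels: np.ndarray, peaks: np.ndarray, n: int,
                   n_bins: int = 20, restrict: int | None = None) -> float:
    """Sequence-randomness mode: peaks binned per syllable into ``n_bins``
    equal-width amplitude bins; outgoing transitions over the following n
    syllables pooled per bin; conditional entropy per bin correlated with the
    bin level."""
    T = labels.shape[0]
    if T <= n + 1:
        return np.nan
    K = labels.max() + 1
    bin_of = np.full(T, -1)
    which = np.unique(labels) if restrict is None else [restrict]
    for s in which:
        idx = np.flatnonzero(labels == s)
        p = peaks[idx]
        lo, hi = np.nanmin(p), np.nanmax(p)
        if not np.isfinite(lo) or hi <= lo:
            continue
        b = np.clip(((p - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
        bin_of[idx] = b
    mats = np.zeros((n_bins, K, K))
    for t in range(T - n):
        b = bin_of[t]
        if b < 0:
            continue
        seg = labels[t: t + n + 1]
        np.add.at(mats[b], (seg[:-1], seg[1:]), 1.0)
    levels, ents = [], []
    for b in range(n_bins):
        tot = mats[b].sum()
        if tot < 2:
            continue
        rows = mats[b].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = mats[b] / rows[:, None]
            terms = np.where(P > 0, -P * np.log(P), 0.0)
        H_rows = terms.sum(axis=1)
        w = rows / rows.sum()
        levels.append((b + 0.5) / n_bins)
        ents.append(float(np.sum(w[rows > 0] * H_rows[rows > 0])))
    return _pearson(np.asarray(levels, float), np.asarray(ents, float))


def _per_syllable_r(lab, pk, outcome_arr, restrict):
    """Correlation computed within syllable, then averaged across syllables —
    removes the static cross-syllable dopamine-level differences so the curve
    reflects moment-to-moment fluctuations only."""
    syls = [restrict] if restrict is not None else np.unique(lab)
    rs = [_pearson(pk[lab == s], outcome_arr[lab == s]) for s in syls]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(rs)) if len(rs) else np.nan


def _curve_for_session(labels, peaks, velocity, outcome, bin_sizes, segments,
                       restrict: int | None = None):
    rows = []
    for a, b in _segment_bounds(labels.shape[0], segments):
        lab, pk = labels[a:b], peaks[a:b]
        vel = velocity[a:b] if velocity is not None else None
        r_bins = []
        for n in bin_sizes:
            if outcome == "counts":
                r = _per_syllable_r(lab, pk, _forward_counts(lab, n), restrict)
            elif outcome == "velocity":
                r = _per_syllable_r(lab, pk, _forward_mean(vel, n), restrict)
            elif outcome == "autocorr":
                r = _per_syllable_r(lab, pk, _forward_mean(pk, n), restrict)
            elif outcome == "entropy":
                r = _entropy_bin_r(lab, pk, n, restrict=restrict)
            else:
                raise ValueError(f"unknown outcome: {outcome}")
            r_bins.append(r)
        rows.append(r_bins)
    return np.asarray(rows, dtype=float)


def expanding_bin_correlation(
    table: pd.DataFrame,
    outcome: str = "counts",
    bin_sizes=DEFAULT_BIN_SIZES,
    n_shuffles: int = 100,
    segments: int = 5,
    seed: int = 0,
    peak_col: str = "peak",
    shuffle: str = "circular",
    restrict_syllable: int | None = None,
) -> CorrelationCurve:
    """Expanding-bin correlation curve, shuffle-z-scored.

    ``shuffle='circular'`` circularly shifts the peak column within session
    (preserving autocorrelation); ``'permute'`` fully permutes it.
    """
    bin_sizes = np.asarray(bin_sizes, dtype=int)
    rng = np.random.default_rng(seed)
    sessions = [
        (g["syllable"].to_numpy(int), g[peak_col].to_numpy(float),
         g["velocity"].to_numpy(float) if "velocity" in g else None)
        for _, g in table.groupby(["mouse", "session"], sort=True)
    ]

    def one_pass(peak_fn):
        rows = []
        for lab, pk, vel in sessions:
            rows.append(_curve_for_session(lab, peak_fn(pk), vel, outcome,
                                           bin_sizes, segments,
                                           restrict=restrict_syllable))
        return np.vstack(rows)

    obs_rows = one_pass(lambda p: p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_raw = np.nanmean(obs_rows, axis=0)
        null = np.empty((n_shuffles, bin_sizes.size))
        for k in range(n_shuffles):
            if shuffle == "circular":
                fn = lambda p: np.roll(p, int(rng.integers(1, max(2, p.shape[0]))))
            else:
                fn = lambda p: rng.permutation(p)
            null[k] = np.nanmean(one_pass(fn), axis=0)
        nm, nsd = np.nanmean(null, axis=0), np.nanstd(null, axis=0, ddof=1)
    nsd = np.where(nsd > 0, nsd, np.nan)
    return CorrelationCurve(
        bin_sizes=bin_sizes, r_raw=r_raw, r_z=(r_raw - nm) / nsd,
        n_shuffles=n_shuffles, segments=segments, segment_curves=obs_rows,
    )


# ---------------------------------------------------------------------------
# decay fits
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    """Bootstrap distribution of the exponential decay constant tau."""

    tau_samples: np.ndarray
    n_boot: int
    non_identifiable: bool = False
    n_dropped: int = 0

    @property
    def tau_median(self) -> float:
        return float(np.median(self.tau_samples)) if self.tau_samples.size else np.nan


def _fit_one_decay(n: np.ndarray, r: np.ndarray, with_offset: bool) -> float:
    ok = ~np.isnan(r)
    n, r = n[ok].astype(float), r[ok]
    if n.size < 3:
        raise RuntimeError("too few points")
    a0 = r[0] - (r[-1] if with_offset else 0.0)
    if a0 == 0:
        a0 = 1e-3
    tau0 = max(n[min(len(n) - 1, np.searchsorted(-(r - r[-1]), -(a0 / np.e)))], n[0])
    if with_offset:
        f = lambda x, a, tau, c: a * np.exp(-x / tau) + c
        p0, bounds = (a0, tau0, r[-1]), ([-np.inf, 1e-6, -np.inf], [np.inf, 1e6, np.inf])
    else:
        f = lambda x, a, tau: a * np.exp(-x / tau)
        p0, bounds = (a0, tau0), ([-np.inf, 1e-6], [np.inf, 1e6])
    popt, _ = optimize.curve_fit(f, n, r, p0=p0, bounds=bounds, maxfev=2000)
    return float(popt[1])


def fit_decay_tau(curve: CorrelationCurve, n_boot: int = 1000, seed: int = 0,
                  with_offset: bool = True, max_drop_frac: float = 0.2) -> DecayFit:
    """Bootstrap exponential-decay fits a*exp(-n/tau) (+ offset) to the curve.

    Resamples the per-segment curves with replacement when the curve carries
    them (the usual case); with a single row, residuals are resampled instead.
    A constant curve is flagged non-identifiable.  Fails if more than
    ``max_drop_frac`` of the resampled fits do not converge.
    """
    if curve.bin_sizes.size < 3:
        raise ValueError("need at least 3 bin sizes")
    rows = curve.segment_curves
    if rows is None:
        rows = curve.r_raw[None, :]
    rng = np.random.default_rng(seed)
    mean_r = np.nanmean(rows, axis=0)
    if np.nanstd(mean_r) < 1e-12:
        return DecayFit(np.array([]), n_boot, non_identifiable=True)
    resid = None
    if rows.shape[0] == 1:
        try:
            tau_hat = _fit_one_decay(curve.bin_sizes, mean_r, with_offset)
        except RuntimeError:
            tau_hat = None
        resid = np.zeros_like(mean_r)  # residual bootstrap fallback below
    taus, dropped = [], 0
    for _ in range(n_boot):
        if rows.shape[0] > 1:
            pick = rng.integers(0, rows.shape[0], size=rows.shape[0])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                r = np.nanmean(rows[pick], axis=0)
        else:
            r = mean_r + rng.permutation(resid)
        try:
            taus.append(_fit_one_decay(curve.bin_sizes, r, with_offset))
        except (RuntimeError, ValueError):
            dropped += 1
    if dropped > max_drop_frac * n_boot:
        raise RuntimeError(f"{dropped}/{n_boot} bootstrap decay fits failed")
    return DecayFit(np.asarray(taus), n_boot, n_dropped=dropped)


# ---------------------------------------------------------------------------
# cross-correlation, regression, kinematics
# ---------------------------------------------------------------------------

def cross_correlation_usage(
    table: pd.DataFrame,
    lags=range(-5, 6),
    window_s: float = 180.0,
    frame_rate_hz: float = 30.0,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Lagged correlation between 3-minute-binned syllable-associated dopamine
    and 3-minute-binned usage of the same syllable, z-scored vs shuffles."""
    lags = np.asarray(list(lags), dtype=int)
    win = window_s * frame_rate_hz
    rng = np.random.default_rng(seed)

    def collect(peak_perm: bool):
        pairs = {lag: ([], []) for lag in lags}
        for _, g in table.groupby(["mouse", "session"], sort=True):
            w = (g["onset_frame"].to_numpy() // win).astype(int)
            nw = w.max() + 1
            if nw < 2:
                continue
            pk = g["peak"].to_numpy(float)
            if peak_perm:
                pk = rng.permutation(pk)
            for s in np.unique(g["syllable"]):
                m = g["syllable"].to_numpy() == s
                counts = np.bincount(w[m], minlength=nw).astype(float)
                sums = np.bincount(w[m], weights=pk[m], minlength=nw)
                with np.errstate(invalid="ignore"):
                    mean_pk = np.where(counts > 0, sums / counts, np.nan)
                # standardize within syllable across windows so pooled pairs
                # reflect fluctuations, not static cross-syllable levels
                if np.nanstd(mean_pk) > 0:
                    mean_pk = (mean_pk - np.nanmean(mean_pk)) / np.nanstd(mean_pk)
                if counts.std() > 0:
                    counts = (counts - counts.mean()) / counts.std()
                for lag in lags:
                    if lag >= 0:
                        a, b = mean_pk[: nw - lag], counts[lag:]
                    else:
                        a, b = mean_pk[-lag:], counts[: nw + lag]
                    pairs[lag][0].extend(a)
                    pairs[lag][1].extend(b)
        return np.array([
            _pearson(np.asarray(pairs[lag][0]), np.asarray(pairs[lag][1]))
            for lag in lags
        ])

    r = collect(False)
    null = np.array([collect(True) for _ in range(n_shuffles)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        nm, nsd = np.nanmean(null, axis=0), np.nanstd(null, axis=0, ddof=1)
    nsd = np.where(nsd > 0, nsd, np.nan)
    return {"lags": lags, "r": r, "r_z": (r - nm) / nsd, "n_shuffles": n_shuffles}


def huber_regression_cv(
    x: np.ndarray, y: np.ndarray,
    folds: int = 5, repeats: int = 100, n_shuffles: int = 1000, seed: int = 0,
) -> dict:
    """Huber regression of y on x with repeated K-fold cross-validation.

    Returns the mean held-out Pearson r over repeats and a shuffle p-value
    (fraction of shuffled-y fits with held-out r >= observed).
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 2 * folds:
        raise ValueError("need at least 2*folds points")
    if x.std() == 0:
        raise ValueError("degenerate x: zero variance")
    rng = np.random.default_rng(seed)

    def heldout_r(yy, n_rep):
        rs = []
        for rep in range(n_rep):
            kf = KFold(folds, shuffle=True, random_state=int(rng.integers(2**31)))
            pred = np.empty_like(yy)
            for tr, te in kf.split(x):
                m = HuberRegressor().fit(x[tr], yy[tr])
                pred[te] = m.predict(x[te])
            rs.append(_pearson(pred, yy))
        return float(np.nanmean(rs))

    r_obs = heldout_r(y, repeats)
    null = np.array([heldout_r(rng.permutation(y), 1) for _ in range(n_shuffles)])
    p = float((np.sum(null >= r_obs) + 1) / (n_shuffles + 1))
    return {"r": r_obs, "p": p, "null": null}


def movement_initiations(velocity_2d: np.ndarray, rate: float = 30.0) -> np.ndarray:
    """Changepoints from stillness to movement.

    z-score -> 50-point boxcar -> first difference (per second) -> cube ->
    peak finding with height 1, width 1, prominence 1.
    """
    v = np.asarray(velocity_2d, dtype=float)
    if v.shape[0] <= 50:
        raise ValueError("trace must be longer than the 50-point boxcar")
    sd = v.std()
    z = (v - v.mean()) / (sd if sd > 0 else 1.0)
    smooth = np.convolve(z, np.ones(50) / 50.0, mode="same")
    score = (np.diff(smooth) * rate) ** 3
    peaks, _ = sps.find_peaks(score, height=1.0, width=1.0, prominence=1.0)
    return peaks


def partial_out_kinematics(
    dlight: np.ndarray, covariates: dict, target: np.ndarray,
    n_boot: int = 1000, seed: int = 0,
) -> dict:
    """Residualize dlight on the covariates (OLS), correlate the residual
    with the target, and compare to a circular-shift null band."""
    y = np.asarray(dlight, dtype=float)
    tgt = np.asarray(target, dtype=float)
    cols, names = [np.ones_like(y)], ["intercept"]
    for name, c in covariates.items():
        c = np.asarray(c, dtype=float)
        if c.shape != y.shape:
            raise ValueError("covariate length mismatch")
        X_try = np.column_stack(cols + [c])
        if np.linalg.matrix_rank(X_try) <= len(cols):
            warnings.warn(f"dropping collinear covariate {name!r}")
            continue
        cols.append(c)
        names.append(name)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    r = _pearson(resid, tgt)
    rng = np.random.default_rng(seed)
    null = np.array([
        _pearson(resid, np.roll(tgt, int(rng.integers(1, y.shape[0]))))
        for _ in range(n_boot)
    ])
    lo, hi = np.nanpercentile(null, [2.5, 97.5])
    p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_boot + 1))
    return {"r": r, "null_band": (float(lo), float(hi)), "p": p,
            "covariates_used": names[1:]}


def endo_da_influence(
    table: pd.DataFrame,
    outcome: str = "counts",
    per: str = "mouse",
    bin_sizes=DEFAULT_BIN_SIZES,
    n_shuffles: int = 100,
    segments: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Endogenous-dopamine influence index: the s.d. across bin sizes of the
    shuffle-z-scored expanding-bin correlation, per mouse (or mouse x
    syllable)."""
    if per not in ("mouse", "mouse_syllable"):
        raise ValueError("per must be 'mouse' or 'mouse_syllable'")
    rows = []
    for mouse, g in table.groupby("mouse", sort=True):
        restricts = [None] if per == "mouse" else np.unique(g["syllable"])
        for s in restricts:
            curve = expanding_bin_correlation(
                g, outcome=outcome, bin_sizes=bin_sizes,
                n_shuffles=n_shuffles, segments=segments, seed=seed,
                restrict_syllable=None if s is None else int(s),
            )
            rec = {"mouse": mouse, "influence": float(np.nanstd(curve.r_z, ddof=1))}
            if s is not None:
                rec["syllable"] = int(s)
            rows.append(rec)
    return pd.DataFrame(rows)
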