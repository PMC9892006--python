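"""Fiber-photometry preprocessing for two-channel dopamine-sensor recordings.

Pipeline (in the order a session is processed):

1. :func:`compute_dff` — ΔF/F0 against a sliding 10th-percentile baseline
   (5-s window), applied to the signal and the reference channel alike.
2. :func:`subtract_reference` — "active referencing": the reference channel is
   low-passed (2nd-order Butterworth, 3 Hz, zero-phase), robustly fit to the
   signal channel (RANSAC OLS for slope and bias), and subtracted.  This
   removes motion/mechanical artifacts shared across excitation wavelengths.
3. :func:`sliding_zscore` — z-scoring with a 20-s sliding window removes slow
   trends (bleaching) and puts transients in z-units.
4. :func:`qc_pass` — session inclusion: max %ΔF/F0 above 1.5 and
   signal-reference Pearson correlation below 0.6.
5. :func:`detect_transients` — thresholded local-maximum transient detection.

All operations are pure; each records itself in the trace's provenance list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.linear_model import LinearRegression, RANSACRegressor

__all__ = [
    "PhotometryTrace",
    "TransientEvents",
    "QCRecord",
    "compute_dff",
    "subtract_reference",
    "sliding_zscore",
    "qc_pass",
    "detect_transients",
    "downsample_to_frames",
    "preprocess",
]


@dataclass
class PhotometryTrace:
    """Two-channel fluorescence time series with processing provenance."""

    sampling_rate_hz: float
    raw_signal: np.ndarray
    raw_reference: np.ndarray
    dff_signal: np.ndarray | None = None
    dff_reference: np.ndarray | None = None
    referenced: np.ndarray | None = None
    zscored: np.ndarray | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.raw_signal = np.asarray(self.raw_signal, dtype=float)
        self.raw_reference = np.asarray(self.raw_reference, dtype=float)
        if self.raw_signal.shape != self.raw_reference.shape:
            raise ValueError("signal and reference must have the same length")

    @property
    def n_samples(self) -> int:
        return self.raw_signal.shape[0]

    def log(self, op: str, **params) -> None:
        self.provenance.append({"op": op, **params})


@dataclass
class TransientEvents:
    """Detected dopamine transients: peak sample indices and z amplitudes."""

    peak_frames: np.ndarray
    amplitudes: np.ndarray
    threshold: float
    rate_hz: float

    def __post_init__(self):
        self.peak_frames = np.asarray(self.peak_frames, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.peak_frames) <= 0):
            raise ValueError("peak_frames must be strictly increasing")
        if self.amplitudes.size and np.any(self.amplitudes < self.threshold):
            raise ValueError("all amplitudes must reach the detection threshold")


@dataclass
class QCRecord:
    passed: bool
    max_pct_dff: float
    signal_reference_r: float
    max_pct_threshold: float
    corr_threshold: float


def compute_dff(
    raw: np.ndarray, rate: float, window_s: float = 5.0, percentile: float = 10.0
) -> np.ndarray:
    """ΔF/F0 with F0 the sliding-window percentile of the raw trace.

    The window is centred and truncated at the edges.  Raises if the baseline
    estimate is non-positive anywhere (degenerate for a fluorescence trace).
    """
    raw = np.asarray(raw, dtype=float)
    win = int(round(window_s * rate))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    f0 = (
        pd.Series(raw)
        .rolling(win, center=True, min_periods=1)
        .quantile(percentile / 100.0)
        .to_numpy()
    )
    if np.any(f0 <= 0):
        raise ValueError("degenerate baseline: sliding percentile is non-positive")
    return (raw - f0) / f0


def subtract_reference(
    signal_dff: np.ndarray,
    reference_dff: np.ndarray,
    rate: float,
    corner_hz: float = 3.0,
    residual_threshold_mads: float = 1.0,
    max_trials: int = 100,
    random_state: int = 0,
) -> tuple[np.ndarray, dict]:
    """Low-pass, robustly rescale, and subtract the reference channel.

    Returns the referenced trace and a fit record (slope, intercept, flag).
    A constant reference cannot be fit; the signal is returned unchanged with
    ``degenerate=True`` in the record.
    """
    x = np.asarray(signal_dff, dtype=float)
    ref = np.asarray(reference_dff, dtype=float)
    if x.shape != ref.shape:
        raise ValueError("signal and reference must have equal length")
    sos = sps.butter(2, corner_hz, btype="low", fs=rate, output="sos")
    ref_lp = sps.sosfiltfilt(sos, ref)
    if np.std(ref_lp) < 1e-10 * max(1.0, np.abs(ref_lp).max()):
        warnings.warn("constant reference channel; skipping reference subtraction")
        return x.copy(), {"slope": 0.0, "intercept": 0.0, "degenerate": True}
    resid_scale = np.median(np.abs(ref_lp - np.median(ref_lp)))
    est = RANSACRegressor(
        estimator=LinearRegression(),
        residual_threshold=max(residual_threshold_mads * resid_scale, 1e-12),
        max_trials=max_trials,
        random_state=random_state,
    )
    est.fit(ref_lp[:, None], x)
    slope = float(est.estimator_.coef_[0])
    intercept = float(est.estimator_.intercept_)
    fitted = slope * ref_lp + intercept
    return x - fitted, {"slope": slope, "intercept": intercept, "degenerate": False}


def sliding_zscore(trace: np.ndarray, rate: float, window_s: float = 20.0) -> np.ndarray:
    """Sliding z-score (centred window, single-sample step, edge-truncated).

    The window is forced odd so centring is exactly symmetric.
    """
    x = np.asarray(trace, dtype=float)
    win = int(round(window_s * rate))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    if win % 2 == 0:
        win += 1
    s = pd.Series(x).rolling(win, center=True, min_periods=2)
    mu = s.mean().to_numpy()
    sd = s.std(ddof=1).to_numpy()
    out = np.zeros_like(x)
    ok = np.nan_to_num(sd) > 0
    if not ok.all():
        warnings.warn("zero within-window s.d.; emitting 0 at affected samples")
    out[ok] = (x[ok] - mu[ok]) / sd[ok]
    return out


def qc_pass(
    dff_signal: np.ndarray,
    dff_reference: np.ndarray,
    max_pct_threshold: float = 1.5,
    corr_threshold: float = 0.6,
) -> QCRecord:
    """Session inclusion gate: large enough transients, low enough reference
    contamination."""
    x = np.asarray(dff_signal, dtype=float)
    ref = np.asarray(dff_reference, dtype=float)
    max_pct = float(np.max(100.0 * x))
    if np.std(x) == 0 or np.std(ref) == 0:
        r = 1.0 if np.array_equal(x, ref) else 0.0
    else:
        r = float(np.corrcoef(x, ref)[0, 1])
    passed = (max_pct > max_pct_threshold) and (r < corr_threshold)
    return QCRecord(passed, max_pct, r, max_pct_threshold, corr_threshold)


def detect_transients(
    z: np.ndarray, rate: float, threshold: float = 2.0, min_separation_s: float = 0.167
) -> TransientEvents:
    """Local maxima above ``threshold`` (z), at least ``min_separation_s`` apart."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(z, dtype=float)
    distance = max(1, int(round(min_separation_s * rate)))
    peaks, props = sps.find_peaks(z, height=threshold, distance=distance)
    duration_s = z.shape[0] / rate
    return TransientEvents(
        peak_frames=peaks,
        amplitudes=props.get("peak_heights", np.empty(0)),
        threshold=threshold,
        rate_hz=len(peaks) / duration_s if duration_s > 0 else 0.0,
    )


def downsample_to_frames(
    trace: np.ndarray, rate_in: float, rate_out: float = 30.0
) -> np.ndarray:
    """Anti-aliased resampling onto the behaviour frame base."""
    if rate_in < rate_out:
        raise ValueError("rate_in must be >= rate_out")
    if rate_in == rate_out:
        return np.asarray(trace, dtype=float).copy()
    from fractions import Fraction

    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    return sps.resample_poly(np.asarray(trace, dtype=float), frac.numerator,
                             frac.denominator, padtype="line")


def preprocess(
    trace: PhotometryTrace,
    dff_window_s: float = 5.0,
    dff_percentile: float = 10.0,
    z_window_s: float = 20.0,
) -> PhotometryTrace:
    """Full chain: ΔF/F0 on both channels, reference subtraction, sliding
    z-score.  Mutates and returns the trace; every stage is logged."""
    rate = trace.sampling_rate_hz
    trace.dff_signal = compute_dff(trace.raw_signal, rate, dff_window_s, dff_percentile)
    trace.dff_reference = compute_dff(trace.raw_reference, rate, dff_window_s, dff_percentile)
    trace.log("compute_dff", window_s=dff_window_s, percentile=dff_percentile)
    trace.referenced, fit = subtract_reference(trace.dff_signal, trace.dff_reference, rate)
    trace.log("subtract_reference", **fit)
    trace.zscored = sliding_zscore(trace.referenced, rate, z_window_s)
    trace.log("sliding_zscore", window_s=z_window_s)
    return trace
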