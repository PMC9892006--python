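"""Encoding models: predicting dopamine from behaviour.

Two complementary models:

* **Binned encoding** — per (mouse, syllable) behavioural features (counts,
  entropy, velocity) aggregated at a set of bin sizes (5..1600 syllables),
  z-scored per mouse, ZCA-whitened, and fed to a Bayesian linear regression
  (normal prior on the coefficients, prior on the noise scale; analytic
  posterior approximation) predicting the mean dopamine peak.  A separate
  model per lag quantifies the temporal relationship; feature subsets are
  evaluated at their best lags (kinematics/entropy: 10 steps, counts: 100).

* **Kernel encoding** — instantaneous dopamine predicted by convolving each
  frame-rate behavioural feature with a learned kernel over lags -2..+2 s
  (121 taps at 30 Hz) and summing across features; weights minimize a Huber
  loss with mild L2 regularization; evaluation is twofold cross-validation by
  session with the target smoothed by a 60-sample (2-s) boxcar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import BayesianRidge, HuberRegressor

__all__ = [
    "zca_whiten",
    "BinnedEncodingModel",
    "BinnedEncodingResults",
    "KernelEncodingModel",
    "KernelEncodingResults",
    "binned_feature_table",
    "fit_binned_per_lag",
    "fit_feature_subsets",
    "BIN_SIZES",
    "BEST_LAGS",
]

BIN_SIZES = (5, 10, 25, 50, 100, 200, 300, 400, 800, 1600)
KERNEL_HALF_S = 2.0  # kernels span -2 s .. +2 s
# bin sizes (syllable steps) at which each feature family predicts best
BEST_LAGS = {"counts": 100, "entropy": 10, "velocity": 10}


def zca_whiten(features: np.ndarray, ridge: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase component analysis whitening.

    Returns (whitened, transform) where transform = C^{-1/2} is symmetric and
    the whitened columns have identity covariance.  A rank-deficient
    covariance is ridge-regularized with a warning.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 rows")
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    if w.min() <= ridge * max(w.max(), 1.0):
        warnings.warn("rank-deficient feature covariance; ridge-regularizing")
        w = w + ridge * max(w.max(), 1.0)
    W = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    return Xc @ W, W


# ---------------------------------------------------------------------------
# binned Bayesian encoding
# ---------------------------------------------------------------------------

@dataclass
class BinnedEncodingResults:
    """Posterior summaries and held-out performance of the binned model."""

    coef_mean: np.ndarray
    coef_sd: np.ndarray
    sigma: float
    heldout_r: float
    feature_names: list
    per_lag: dict | None = None  # bin size -> heldout r
    per_subset: dict | None = None  # feature name -> heldout r at best lag

    def summary(self) -> str:
        lines = [
            "Binned Bayesian encoding model (dopamine peak ~ behaviour)",
            "==========================================================",
            f"held-out r: {self.heldout_r:.3f}   noise sd: {self.sigma:.3f}",
        ]
        for n, m, s in zip(self.feature_names, self.coef_mean, self.coef_sd):
            lines.append(f"  {n:>12s}: {m:+.3f} +/- {s:.3f}")
        if self.per_lag:
            lines.append("per-lag held-out r: " + ", ".join(
                f"{k}:{v:.2f}" for k, v in self.per_lag.items()))
        return "\n".join(lines)


class BinnedEncodingModel:
    """Bayesian linear regression of dopamine peaks on whitened behavioural
    features.

    Parameters
    ----------
    X : (n, p) feature matrix (already aggregated per mouse/syllable/bin)
    y : (n,) mean dopamine peak (z-units)
    feature_names : optional list of p names
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, feature_names=None,
                 whiten: bool = True):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must align")
        if self.X.shape[0] < self.X.shape[1] + 2:
            raise ValueError("need at least p + 2 rows")
        self.feature_names = list(feature_names) if feature_names is not None \
            else [f"x{i}" for i in range(self.X.shape[1])]
        self.whiten = whiten

    def _design(self, X):
        if not self.whiten:
            return X - X.mean(axis=0), np.eye(X.shape[1])
        return zca_whiten(X)

    def fit(self, folds: int = 5, seed: int = 0) -> BinnedEncodingResults:
        Xw, W = self._design(self.X)
        est = BayesianRidge(fit_intercept=True)
        est.fit(Xw, self.y)
        coef_sd = np.sqrt(np.diag(est.sigma_))
        # held-out predictive r
        rng = np.random.default_rng(seed)
        idx = rng.permutation(self.X.shape[0])
        bounds = np.linspace(0, idx.size, folds + 1).astype(int)
        pred = np.empty_like(self.y)
        for f in range(folds):
            te = idx[bounds[f]: bounds[f + 1]]
            tr = np.setdiff1d(idx, te)
            m = BayesianRidge(fit_intercept=True)
            Xtr, Wtr = self._design(self.X[tr])
            m.fit(Xtr, self.y[tr])
            Xte = (self.X[te] - self.X[tr].mean(axis=0)) @ Wtr
            pred[te] = m.predict(Xte)
        if pred.std() > 0 and self.y.std() > 0:
            r = float(np.corrcoef(pred, self.y)[0, 1])
        else:
            r = 0.0
        return BinnedEncodingResults(
            coef_mean=est.coef_, coef_sd=coef_sd,
            sigma=float(np.sqrt(1.0 / est.alpha_)),
            heldout_r=r, feature_names=self.feature_names,
        )

    @classmethod
    def from_table(cls, table, feature_cols, outcome_col="peak_mean",
                   zscore_within="mouse"):
        """Build from a long-format DataFrame; features z-scored within mouse."""
        df = table.copy()
        for c in feature_cols:
            if zscore_within:
                df[c] = df.groupby(zscore_within)[c].transform(
                    lambda x: (x - x.mean()) / (x.std(ddof=0) or 1.0))
        return cls(df[list(feature_cols)].to_numpy(float),
                   df[outcome_col].to_numpy(float), feature_names=feature_cols)


def binned_feature_table(peak_table, bin_sizes=BIN_SIZES):
    """Aggregate the syllable peak table into the binned-feature table.

    One row per (mouse, syllable, bin_size) with the syllable's mean forward
    counts, forward mean velocity, pooled forward transition entropy, and the
    mean dopamine peak as the outcome.
    """
    import pandas as pd

    from .stats import _forward_counts, _forward_mean  # shared aggregation

    rows = []
    for (mouse, session), g in peak_table.groupby(["mouse", "session"], sort=True):
        labels = g["syllable"].to_numpy(int)
        peaks = g["peak"].to_numpy(float)
        vel = g["velocity"].to_numpy(float) if "velocity" in g else np.full(labels.size, np.nan)
        K = labels.max() + 1
        for n in bin_sizes:
            cts = _forward_counts(labels, n)
            vfw = _forward_mean(vel, n)
            for s in np.unique(labels):
                idx = np.flatnonzero(labels == s)
                idx = idx[idx + n < labels.size]
                if idx.size == 0:
                    continue
                M = np.zeros((K, K))
                for t in idx:
                    seg = labels[t: t + n + 1]
                    np.add.at(M, (seg[:-1], seg[1:]), 1.0)
                rsum = M.sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    P = M / rsum[:, None]
                    terms = np.where(P > 0, -P * np.log(P), 0.0)
                H = float(np.sum(rsum / rsum.sum() * terms.sum(axis=1)))
                rows.append({
                    "mouse": mouse, "session": session, "syllable": int(s),
                    "bin_size": int(n), "counts": float(np.nanmean(cts[idx])),
                    "velocity": float(np.nanmean(vfw[idx])), "entropy": H,
                    "peak_mean": float(np.nanmean(peaks[idx])),
                })
    df = pd.DataFrame(rows)
    # average across sessions -> one row per mouse x syllable x bin size
    return (df.groupby(["mouse", "syllable", "bin_size"], as_index=False)
              [["counts", "velocity", "entropy", "peak_mean"]].mean())


def fit_binned_per_lag(table, feature_cols=("counts", "entropy", "velocity"),
                       folds: int = 5, seed: int = 0) -> dict:
    """A separate Bayesian model at each bin size (features whitened within
    lag); returns bin_size -> BinnedEncodingResults."""
    out = {}
    for n, g in table.groupby("bin_size", sort=True):
        model = BinnedEncodingModel.from_table(g, list(feature_cols))
        out[int(n)] = model.fit(folds=folds, seed=seed)
    return out


def fit_feature_subsets(table, best_lags: dict | None = None,
                        folds: int = 5, seed: int = 0) -> dict:
    """Each feature fed in separately at its best bin size; returns
    feature -> BinnedEncodingResults."""
    best_lags = best_lags or BEST_LAGS
    out = {}
    for feat, lag in best_lags.items():
        g = table[table["bin_size"] == lag]
        if g.empty:
            raise ValueError(f"bin size {lag} missing from the table")
        model = BinnedEncodingModel.from_table(g, [feat])
        out[feat] = model.fit(folds=folds, seed=seed)
    return out


# ---------------------------------------------------------------------------
# convolution-kernel encoding
# ---------------------------------------------------------------------------

@dataclass
class KernelEncodingResults:
    """Per-feature convolution kernels over lags -2..+2 s and held-out r."""

    kernels: np.ndarray  # (n_features, n_taps), centred at lag 0
    lags_frames: np.ndarray
    feature_names: list
    heldout_r: float
    intercept: float = 0.0

    def best_lag(self, feature: int | str) -> int:
        i = feature if isinstance(feature, int) else self.feature_names.index(feature)
        return int(self.lags_frames[np.argmax(np.abs(self.kernels[i]))])

    def summary(self) -> str:
        lines = [
            "Convolution-kernel encoding model (instantaneous dopamine)",
            "==========================================================",
            f"held-out r: {self.heldout_r:.3f}   taps per kernel: {self.lags_frames.size}",
        ]
        for i, n in enumerate(self.feature_names):
            lines.append(f"  {n:>12s}: peak |weight| at lag {self.best_lag(i):+d} frames")
        return "\n".join(lines)


def _lagged_design(features: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Design matrix with one column per (feature, lag): column value at time
    t is feature[t - lag] (zero-padded)."""
    T, F = features.shape
    X = np.zeros((T, F * lags.size))
    for i in range(F):
        for j, lag in enumerate(lags):
            col = np.zeros(T)
            if lag >= 0:
                col[lag:] = features[: T - lag, i] if lag > 0 else features[:, i]
            else:
                col[:lag] = features[-lag:, i]
            X[:, i * lags.size + j] = col
    return X


class KernelEncodingModel:
    """Jointly fit per-feature convolution kernels mapping behaviour to the
    (smoothed) dopamine trace under a Huber loss.

    Parameters
    ----------
    sessions : list of (features (T, F), dlight (T,)) pairs
    rate_hz : frame rate (default 30)
    standardize : z-score each feature column within session before fitting
    """

    def __init__(self, sessions, rate_hz: float = 30.0, smooth_samples: int = 60,
                 l2: float = 1e-4, standardize: bool = True,
                 feature_names=None, half_window_s: float = KERNEL_HALF_S):
        if len(sessions) < 2:
            raise ValueError("need at least 2 sessions for twofold CV")
        half = int(round(half_window_s * rate_hz))
        self.lags_frames = np.arange(-half, half + 1)
        self.rate_hz = rate_hz
        self.smooth_samples = smooth_samples
        self.l2 = l2
        self.sessions = []
        F = None
        for feats, y in sessions:
            feats = np.asarray(feats, dtype=float)
            y = np.asarray(y, dtype=float)
            if feats.ndim != 2 or feats.shape[0] != y.shape[0]:
                raise ValueError("features must be (T, F) aligned to dlight")
            F = feats.shape[1] if F is None else F
            if standardize:
                mu, sd = feats.mean(axis=0), feats.std(axis=0)
                sd[sd == 0] = 1.0
                feats = (feats - mu) / sd
            if smooth_samples > 1:
                y = np.convolve(y, np.ones(smooth_samples) / smooth_samples, mode="same")
            self.sessions.append((feats, y))
        self.n_features = F
        self.feature_names = list(feature_names) if feature_names is not None \
            else [f"f{i}" for i in range(F)]

    def _stack(self, idx):
        X = np.vstack([_lagged_design(self.sessions[i][0], self.lags_frames)
                       for i in idx])
        y = np.concatenate([self.sessions[i][1] for i in idx])
        return X, y

    def _fit_coef(self, idx):
        X, y = self._stack(idx)
        if np.allclose(y, 0):
            return np.zeros(X.shape[1]), 0.0
        est = HuberRegressor(alpha=self.l2, max_iter=500, fit_intercept=True)
        est.fit(X, y)
        return est.coef_, float(est.intercept_)

    def fit(self, folds: int = 2, seed: int = 0) -> KernelEncodingResults:
        n = len(self.sessions)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        bounds = np.linspace(0, n, folds + 1).astype(int)
        preds, actuals = [], []
        for f in range(folds):
            te = perm[bounds[f]: bounds[f + 1]]
            tr = np.setdiff1d(perm, te)
            coef, b0 = self._fit_coef(tr)
            for i in te:
                Xte = _lagged_design(self.sessions[i][0], self.lags_frames)
                preds.append(Xte @ coef + b0)
                actuals.append(self.sessions[i][1])
        pred = np.concatenate(preds)
        act = np.concatenate(actuals)
        r = 0.0
        if pred.std() > 0 and act.std() > 0:
            r = float(np.corrcoef(pred, act)[0, 1])
        coef, b0 = self._fit_coef(range(n))
        kernels = coef.reshape(self.n_features, self.lags_frames.size)
        return KernelEncodingResults(
            kernels=kernels, lags_frames=self.lags_frames,
            feature_names=self.feature_names, heldout_r=r, intercept=b0,
        )
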