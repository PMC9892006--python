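"""Trailing exponentially-weighted dopamine sums shared by the sequence models.

The dopamine-dependent sequence model scores candidate next syllables with a
ratio of two trailing sums over the last ``window`` syllable steps:

* a per-syllable *usage* sum  A_i(t) = sum_n da_{t-n} exp(-n/tau_a) [s_{t-n} = i]
* a global *randomness* sum   B(t)   = sum_n da_{t-n} exp(-n/tau_b)

Both the generator and the fitted decoding model need these quantities, either
for a whole recorded sequence at once (fitting) or one step at a time
(simulation).  Batch computation uses truncated convolutions; the online
stepper uses the exact sliding recursion, so both paths agree to float
precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["trailing_sums", "SequenceStepper", "decode_logits"]


def _lag_kernel(tau: float, window: int) -> np.ndarray:
    # kernel[j] = exp(-(j+1)/tau): lag n = j+1, n = 1..window
    return np.exp(-np.arange(1, window + 1, dtype=float) / tau)


def trailing_sums(
    labels: np.ndarray,
    da: np.ndarray,
    n_syllables: int,
    tau_a: float,
    tau_b: float,
    window: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch A (T, K), B (T,) and the normalizer S (T,) for a full sequence.

    A[t, i] and B[t] use only steps strictly before t (partial sums at
    t < window, no padding).  S[t] = sum_{n=1..min(t, window)} exp(-n/tau_b)
    is the guard scale for the denominator clamp.
    """
    labels = np.asarray(labels, dtype=int)
    da = np.asarray(da, dtype=float)
    T = labels.shape[0]
    if da.shape[0] != T:
        raise ValueError("labels and da must have equal length")
    ka = _lag_kernel(tau_a, window)
    kb = _lag_kernel(tau_b, window)

    def _lagconv(x: np.ndarray, k: np.ndarray) -> np.ndarray:
        # out[t] = sum_{n>=1} x[t-n] k[n-1]
        full = np.convolve(x, k)
        out = np.zeros(T)
        out[1:] = full[: T - 1]
        return out

    B = _lagconv(da, kb)
    A = np.zeros((T, n_syllables))
    for i in range(n_syllables):
        A[:, i] = _lagconv(da * (labels == i), ka)

    n_avail = np.minimum(np.arange(T), window)
    # closed-form partial geometric sum of exp(-n/tau_b)
    q = np.exp(-1.0 / tau_b)
    S = q * (1.0 - q**n_avail) / (1.0 - q)
    return A, B, S


class SequenceStepper:
    """Online sliding-window update of the trailing sums during simulation.

    push(label, da) appends one emitted syllable instance; A/B/S then reflect
    the history available to the *next* choice.
    """

    def __init__(self, n_syllables: int, tau_a: float, tau_b: float, window: int):
        self.K = int(n_syllables)
        self.tau_a = float(tau_a)
        self.tau_b = float(tau_b)
        self.window = int(window)
        self._da_ring = np.zeros(self.window)
        self._lab_ring = np.full(self.window, -1, dtype=int)
        self._t = 0
        self.A = np.zeros(self.K)
        self.B = 0.0
        self.S = 0.0
        self._ea = np.exp(-1.0 / self.tau_a)
        self._eb = np.exp(-1.0 / self.tau_b)
        self._ea_w = np.exp(-(self.window + 1.0) / self.tau_a)
        self._eb_w = np.exp(-(self.window + 1.0) / self.tau_b)
        self._eb_wS = np.exp(-(self.window + 1.0) / self.tau_b)

    def push(self, label: int, da: float) -> None:
        slot = self._t % self.window
        old_da = self._da_ring[slot]
        old_lab = self._lab_ring[slot]
        dropping = self._t >= self.window
        self.A *= self._ea
        self.A[label] += da * self._ea
        self.B = self._eb * (self.B + da)
        self.S = self._eb * (self.S + 1.0)
        if dropping:
            self.A[old_lab] -= old_da * self._ea_w
            self.B -= old_da * self._eb_w
            self.S -= self._eb_wS
        self._da_ring[slot] = da
        self._lab_ring[slot] = label
        self._t += 1


def decode_logits(
    A: np.ndarray,
    B: np.ndarray,
    S: np.ndarray | float,
    alpha_a: float,
    alpha_b: float,
    guard_frac: float = 0.05,
) -> np.ndarray:
    """Model logits alpha_a * A / clamp(alpha_b * B).

    The denominator acts as a choice temperature, so it is floored at
    eps = guard_frac * alpha_b * S (S is the dopamine-free value of the
    trailing sum): z-scored dopamine hovering near or below zero can neither
    blow the ratio up nor flip the sign of the usage coupling.  At t = 0
    (empty history, S = 0) the logits are defined as zero (uniform choice).
    """
    den = alpha_b * np.asarray(B, dtype=float)
    eps = guard_frac * alpha_b * np.asarray(S, dtype=float)
    den = np.maximum(den, eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = alpha_a * np.asarray(A, dtype=float) / np.expand_dims(den, -1) \
            if np.ndim(A) > 1 else alpha_a * np.asarray(A, dtype=float) / den
    return np.where(np.isfinite(out), out, 0.0)
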