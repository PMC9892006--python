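"""Synthetic sessions with the statistical structure the analyses assume.

A session is a sequence of behavioural syllables (discrete, sub-second,
no self-transitions) with a dopamine transient amplitude attached to every
instance.  The sequence itself is generated from the dopamine-dependent
sequence model (see :mod:`dopaseq.decoding`) mixed with a first-order Markov
prior, so the couplings the downstream fits estimate are planted quantities:

* syllables whose recent instances carried high dopamine are used more over a
  ~``tau_a`` (default 100) syllable-step horizon (usage coupling,
  ``alpha_a_true``);
* high recent global dopamine sharpens/flattens choices over a ~``tau_b``
  (default 10) step horizon (randomness coupling, ``alpha_b_true``).

Fluorescence is rendered as bi-exponential transients (rise 67 ms, decay
100 ms) riding a bleaching baseline, with artifacts shared into a scaled
reference channel, so the photometry chain can be exercised end-to-end.
Kinematics are piecewise per-syllable velocity templates plus smoothed noise.
Closed-loop stimulation sessions flag target detections for "stimulation"
with probability ``stim_prob`` (default 0.75) and add ``extra_da`` z-units of
dopamine on stimulated instances before sequence generation continues.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ._seqkernel import SequenceStepper, decode_logits
from .photometry import PhotometryTrace

__all__ = [
    "GenerativeParams",
    "SessionBundle",
    "StimSchedule",
    "KinematicSeries",
    "make_generative_params",
    "simulate_syllable_sequence",
    "render_photometry",
    "simulate_kinematics",
    "simulate_session",
    "simulate_closed_loop_experiment",
]

# log-normal sigma reproducing the reported duration spread (median 400 ms,
# s.d. 636 ms): solve sd^2 = m^2 e^{s^2}(e^{s^2}-1) for s.
_DURATION_SIGMA = 0.88


@dataclass
class GenerativeParams:
    """Ground-truth parameters of the synthetic session generator."""

    n_syllables: int
    base_transitions: np.ndarray
    syllable_da_mean: np.ndarray
    syllable_da_sd: np.ndarray
    alpha_a_true: float = 1.0
    alpha_b_true: float = 1.0
    tau_a: float = 100.0
    tau_b: float = 10.0
    history_window: int = 250
    duration_median_ms: float = 400.0
    duration_dispersion: float = _DURATION_SIGMA
    frame_rate_hz: float = 30.0
    transient_rise_ms: float = 67.0
    transient_decay_ms: float = 100.0
    transient_dff_per_z: float = 0.01
    bleach_tau_s: float = 2400.0
    noise_sd: float = 0.001
    artifact_rate_hz: float = 0.02
    artifact_amp: float = 0.02
    reference_gain: float = 0.7
    reference_offset: float = 0.05
    velocity_templates: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        K = self.n_syllables
        if K < 2:
            raise ValueError("need at least 2 syllables")
        self.base_transitions = np.asarray(self.base_transitions, dtype=float)
        if self.base_transitions.shape != (K, K):
            raise ValueError("base_transitions must be K x K")
        if np.any(np.abs(self.base_transitions.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("base_transitions rows must sum to 1")
        if np.any(np.diag(self.base_transitions) != 0):
            raise ValueError("base_transitions diagonal must be exactly 0")
        self.syllable_da_mean = np.broadcast_to(
            np.asarray(self.syllable_da_mean, dtype=float), (K,)
        ).copy()
        self.syllable_da_sd = np.broadcast_to(
            np.asarray(self.syllable_da_sd, dtype=float), (K,)
        ).copy()
        if np.any(self.syllable_da_sd < 0):
            raise ValueError("syllable_da_sd must be >= 0")
        if self.velocity_templates is None:
            self.velocity_templates = np.linspace(30.0, 150.0, K)
        self.velocity_templates = np.broadcast_to(
            np.asarray(self.velocity_templates, dtype=float), (K,)
        ).copy()
        for name in (
            "alpha_b_true", "tau_a", "tau_b", "history_window",
            "duration_median_ms", "duration_dispersion", "frame_rate_hz",
            "transient_rise_ms", "transient_decay_ms", "bleach_tau_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha_a_true < 0 or self.noise_sd < 0 or self.artifact_rate_hz < 0:
            raise ValueError("alpha_a_true, noise_sd, artifact_rate_hz must be >= 0")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


@dataclass
class StimSchedule:
    """Closed-loop stimulation bookkeeping for one session."""

    target: int
    stim_instance_flags: np.ndarray  # over target instances, in order
    catch_instance_flags: np.ndarray
    phase: str  # baseline | stimulation | post
    stim_prob: float = 0.75
    extra_da: float = 0.0

    def __post_init__(self):
        self.stim_instance_flags = np.asarray(self.stim_instance_flags, dtype=bool)
        self.catch_instance_flags = np.asarray(self.catch_instance_flags, dtype=bool)
        if self.stim_instance_flags.shape != self.catch_instance_flags.shape:
            raise ValueError("stim and catch flags must align")
        if np.any(self.stim_instance_flags & self.catch_instance_flags):
            raise ValueError("an instance cannot be both stim and catch")


@dataclass
class KinematicSeries:
    """Frame-rate kinematic channels aligned to the photometry frame base."""

    velocity_2d: np.ndarray  # mm / s
    angular_velocity: np.ndarray  # rad / s
    height_velocity: np.ndarray  # mm / s
    acceleration: np.ndarray  # mm / s^2

    def __post_init__(self):
        n = len(self.velocity_2d)
        for name in ("angular_velocity", "height_velocity", "acceleration"):
            if len(getattr(self, name)) != n:
                raise ValueError("all kinematic channels must share one frame base")

    @property
    def n_frames(self) -> int:
        return len(self.velocity_2d)


@dataclass
class SessionBundle:
    """One simulated (or loaded) experiment."""

    labels: np.ndarray
    onset_frames: np.ndarray
    durations_frames: np.ndarray
    da_amplitudes: np.ndarray
    photometry: PhotometryTrace | None = None
    kinematics: KinematicSeries | None = None
    stim: StimSchedule | None = None
    truth: GenerativeParams | None = None
    mouse: str = "m0"
    session: str = "s0"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.onset_frames = np.asarray(self.onset_frames, dtype=int)
        self.durations_frames = np.asarray(self.durations_frames, dtype=int)
        self.da_amplitudes = np.asarray(self.da_amplitudes, dtype=float)
        n = len(self.labels)
        if not (len(self.onset_frames) == len(self.da_amplitudes) == n):
            raise ValueError("labels, onsets and amplitudes must align")
        if np.any(np.diff(self.onset_frames) <= 0):
            raise ValueError("onset_frames must be strictly increasing")
        if np.any(self.labels[1:] == self.labels[:-1]):
            raise ValueError("self-transitions are not allowed")

    @property
    def n_steps(self) -> int:
        return len(self.labels)

    @property
    def n_frames(self) -> int:
        return int(self.onset_frames[-1] + self.durations_frames[-1])


def make_generative_params(
    K: int, seed: int = 0, dirichlet_concentration: float = 1.0, **overrides
) -> GenerativeParams:
    """Default parameter set: Dirichlet base transitions (diagonal removed,
    rows renormalized), per-syllable dopamine means spanning -1..+1 z with
    unit s.d."""
    if K < 2:
        raise ValueError("need at least 2 syllables")
    rng = np.random.default_rng(seed)
    T = rng.dirichlet(np.full(K, dirichlet_concentration), size=K)
    np.fill_diagonal(T, 0.0)
    T = T / T.sum(axis=1, keepdims=True)
    defaults = dict(
        n_syllables=K,
        base_transitions=T,
        syllable_da_mean=np.linspace(-1.0, 1.0, K),
        syllable_da_sd=np.ones(K),
        seed=seed,
    )
    defaults.update(overrides)
    return GenerativeParams(**defaults)


def _rollout(
    params: GenerativeParams,
    n_steps: int,
    rng: np.random.Generator,
    stim_target: int | None = None,
    stim_prob: float = 0.75,
    extra_da: float = 0.0,
):
    """Core generative rollout.  Returns labels, da amplitudes, and per-step
    stim flags (all False unless a stimulation target is given)."""
    K = params.n_syllables
    with np.errstate(divide="ignore"):
        log_prior = np.log(params.base_transitions)
    stepper = SequenceStepper(K, params.tau_a, params.tau_b, params.history_window)
    labels = np.empty(n_steps, dtype=int)
    da = np.empty(n_steps)
    stim_flags = np.zeros(n_steps, dtype=bool)
    prev = int(rng.integers(K))
    labels[0] = prev
    for t in range(n_steps):
        if t > 0:
            logits = log_prior[prev] + decode_logits(
                stepper.A, stepper.B, stepper.S, params.alpha_a_true, params.alpha_b_true
            )
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            lab = int(rng.choice(K, p=p))
            labels[t] = lab
        lab = int(labels[t])
        amp = rng.normal(params.syllable_da_mean[lab], params.syllable_da_sd[lab])
        if stim_target is not None and lab == stim_target:
            if rng.random() < stim_prob:
                amp += extra_da
                stim_flags[t] = True
        da[t] = amp
        stepper.push(lab, amp)
        prev = lab
    return labels, da, stim_flags


def simulate_syllable_sequence(
    params: GenerativeParams, n_steps: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Syllable labels and per-instance dopamine amplitudes (z-units)."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    labels, da, _ = _rollout(params, n_steps, rng)
    return labels, da


def _draw_durations(params: GenerativeParams, n: int, rng: np.random.Generator) -> np.ndarray:
    med_s = params.duration_median_ms / 1000.0
    dur_s = rng.lognormal(np.log(med_s), params.duration_dispersion, size=n)
    return np.maximum(1, np.rint(dur_s * params.frame_rate_hz).astype(int))


def _biexp_kernel(params: GenerativeParams) -> np.ndarray:
    """Unit-peak bi-exponential transient kernel sampled at the frame rate."""
    tr = params.transient_rise_ms / 1000.0
    td = params.transient_decay_ms / 1000.0
    dt = 1.0 / params.frame_rate_hz
    t = np.arange(0.0, 6.0 * (tr + td), dt)
    k = np.exp(-t / td) - np.exp(-t / tr)
    peak = k.max()
    if peak <= 0:  # degenerate tr == td
        k = (t / td) * np.exp(1.0 - t / td)
        peak = k.max()
    return k / peak


def render_photometry(
    labels: np.ndarray,
    onset_frames: np.ndarray,
    da_amplitudes: np.ndarray,
    params: GenerativeParams,
    n_frames: int,
    seed: int | None = None,
) -> PhotometryTrace:
    """Render demodulated two-channel fluorescence.

    signal   = baseline * (1 + transients + artifacts) + white noise
    reference = reference_gain * baseline * (1 + artifacts) + offset + noise

    Each instance contributes a bi-exponential transient scaled by its
    amplitude (z-units -> fractional ΔF via ``transient_dff_per_z``), locked
    to the syllable onset (the kernel starts at the onset frame and peaks
    ~80 ms later, inside the 300-ms window the peak extraction uses).
    Artifacts are Poisson-timed biphasic bumps shared by both channels; the
    baseline is a mono-exponential bleach.
    """
    onset_frames = np.asarray(onset_frames, dtype=int)
    da_amplitudes = np.asarray(da_amplitudes, dtype=float)
    if onset_frames.size and (onset_frames.min() < 0 or onset_frames.max() >= n_frames):
        raise IndexError("onsets out of range")
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    fps = params.frame_rate_hz
    t = np.arange(n_frames) / fps
    baseline = np.exp(-t / params.bleach_tau_s)

    impulses = np.zeros(n_frames)
    if onset_frames.size:
        np.add.at(impulses, onset_frames, da_amplitudes * params.transient_dff_per_z)
    transients = np.convolve(impulses, _biexp_kernel(params))[:n_frames]

    artifacts = np.zeros(n_frames)
    n_art = rng.poisson(params.artifact_rate_hz * n_frames / fps)
    if n_art > 0 and params.artifact_amp != 0:
        width = 0.4  # s; slow enough to survive the 3 Hz reference low-pass
        tk = np.arange(-3 * width, 3 * width, 1.0 / fps)
        bump = -tk / width * np.exp(0.5 - tk**2 / (2 * width**2))  # biphasic
        art_imp = np.zeros(n_frames)
        pos = rng.integers(0, n_frames, size=n_art)
        np.add.at(art_imp, pos, params.artifact_amp * rng.choice([-1.0, 1.0], n_art))
        artifacts = np.convolve(art_imp, bump)[len(tk) // 2 : len(tk) // 2 + n_frames]

    signal = baseline * (1.0 + transients + artifacts) + rng.normal(0, params.noise_sd, n_frames)
    reference = (
        params.reference_gain * baseline * (1.0 + artifacts)
        + params.reference_offset
        + rng.normal(0, params.noise_sd, n_frames)
    )
    trace = PhotometryTrace(fps, signal, reference)
    trace.log("render_photometry", n_frames=n_frames)
    return trace


def simulate_kinematics(
    labels: np.ndarray,
    onset_frames: np.ndarray,
    params: GenerativeParams,
    n_frames: int,
    seed: int | None = None,
    noise_sd_mm_s: float = 10.0,
) -> KinematicSeries:
    """Piecewise per-syllable velocity templates plus smoothed noise."""
    from scipy.ndimage import gaussian_filter1d

    labels = np.asarray(labels, dtype=int)
    onset_frames = np.asarray(onset_frames, dtype=int)
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    fps = params.frame_rate_hz
    v = np.zeros(n_frames)
    if labels.size:
        ends = np.append(onset_frames[1:], n_frames)
        for lab, a, b in zip(labels, onset_frames, ends):
            v[a:b] = params.velocity_templates[lab]

    def smoothed(scale):
        if scale == 0:
            return np.zeros(n_frames)
        return gaussian_filter1d(rng.normal(0, scale, n_frames), sigma=0.3 * fps)

    velocity_2d = v + smoothed(noise_sd_mm_s)
    angular = smoothed(0.02 * noise_sd_mm_s)
    height = smoothed(0.3 * noise_sd_mm_s)
    acceleration = np.gradient(velocity_2d) * fps
    return KinematicSeries(velocity_2d, angular, height, acceleration)


def simulate_session(
    params: GenerativeParams,
    n_steps: int = 2000,
    seed: int | None = None,
    mouse: str = "m0",
    session: str = "s0",
    render: bool = True,
    stim_target: int | None = None,
    stim_prob: float = 0.75,
    extra_da: float = 0.0,
    phase: str = "baseline",
) -> SessionBundle:
    """Generate one full session (sequence, photometry, kinematics)."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    base_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    labels, da, stim_flags = _rollout(
        params, n_steps, rng,
        stim_target=stim_target if phase == "stimulation" else None,
        stim_prob=stim_prob, extra_da=extra_da,
    )
    durations = _draw_durations(params, n_steps, rng)
    onsets = np.concatenate([[0], np.cumsum(durations)[:-1]])
    n_frames = int(onsets[-1] + durations[-1])
    photometry = kinematics = None
    if render:
        photometry = render_photometry(labels, onsets, da, params, n_frames, seed=base_seed + 10_001)
        kinematics = simulate_kinematics(labels, onsets, params, n_frames, seed=base_seed + 10_002)
    stim = None
    if stim_target is not None:
        on_target = labels == stim_target
        stim = StimSchedule(
            target=stim_target,
            stim_instance_flags=stim_flags[on_target],
            catch_instance_flags=~stim_flags[on_target],
            phase=phase,
            stim_prob=stim_prob,
            extra_da=extra_da if phase == "stimulation" else 0.0,
        )
    return SessionBundle(
        labels, onsets, durations, da,
        photometry=photometry, kinematics=kinematics, stim=stim,
        truth=params, mouse=mouse, session=session,
    )


def simulate_closed_loop_experiment(
    params: GenerativeParams,
    target: int,
    extra_da: float,
    seed: int | None = None,
    n_steps: int = 3000,
    stim_prob: float = 0.75,
    render: bool = False,
    mouse: str = "m0",
) -> list[SessionBundle]:
    """Three-day closed-loop schedule: 2 baseline, 2 stimulation, 2 post
    sessions.  On stimulation sessions each target detection is stimulated
    with probability ``stim_prob`` and stimulated instances carry ``extra_da``
    additional dopamine before sequence generation continues."""
    if not (0 <= target < params.n_syllables):
        raise ValueError("target must be a valid syllable ID")
    base_seed = params.seed if seed is None else seed
    phases = ["baseline", "baseline", "stimulation", "stimulation", "post", "post"]
    out = []
    for k, phase in enumerate(phases):
        out.append(
            simulate_session(
                params, n_steps=n_steps, seed=base_seed * 1000 + k,
                mouse=mouse, session=f"{phase}{k % 2}", render=render,
                stim_target=target, stim_prob=stim_prob,
                extra_da=extra_da, phase=phase,
            )
        )
    return out
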