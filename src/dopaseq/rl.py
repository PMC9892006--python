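"""Q-learning agents over syllable transitions with dopamine as reward.

The agent treats syllables as states, transitions as actions, and the
syllable-associated dopamine peak as the reward delivered at each observed
transition.  The Q-table is initialized uniform with the diagonal fixed at 0
(no self-transitions) and updated with the standard temporal-difference rule

    Q(s_t, a_t) <- Q(s_t, a_t) + alpha [ r_{t+1} + gamma max_a Q(s_{t+1}, a) - Q(s_t, a_t) ]

(``reward`` mode), or with the observed dopamine standing in for the whole
bracketed reward-prediction-error term (``rpe`` mode):  Q <- Q + alpha r.
Actions are scored with a softmax policy p(a|s) = exp(Q_s(a)/tau) / sum_b
exp(Q_s(b)/tau) over the non-self actions.  The *dynamic* variant makes the
temperature time-dependent: when the reward crosses a threshold lambda it is
kicked up by nu and relaxes exponentially (constant tau_decay) back to
tau_baseline, transiently increasing choice randomness after large dopamine.

Fitting is likelihood-based: the agent is fed recorded sessions, scores the
log-probability of each observed action, and updates on the observed
dopamine; free parameters are chosen by grid search on held-out likelihood.
The learned Q-table is compared with the empirical transition matrix by
row-z-scored Pearson correlation against time-shuffled-dopamine nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stats import transition_matrix

__all__ = [
    "RLParams",
    "RLResults",
    "QLearningModel",
    "q_update",
    "softmax_policy",
    "run_agent",
    "evaluate_qtable",
    "qtable_shuffle_null",
    "lag_shift_analysis",
    "grid_search_compare",
    "free_running_mode",
    "restrict_to_top_syllables",
]


@dataclass
class RLParams:
    """Agent parameters; stated ranges enforced at construction."""

    alpha: float = 0.1  # learning rate, (0, 1]
    gamma: float = 0.0  # discount factor, [0, 1) (reward mode only)
    temperature: float = 1.0  # softmax temperature (static variant)
    tau_baseline: float = 1.0
    tau_decay: float = 10.0  # steps
    nu: float = 0.0  # temperature kick at threshold crossing
    lam: float = 2.0  # reward threshold, z-units
    reward_mode: str = "reward"  # reward | rpe
    variant: str = "reinforcement_only"  # reinforcement_only | dynamic
    q_init: float = 1.0  # uniform off-diagonal initialization

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")
        if self.temperature <= 0 or self.tau_baseline <= 0 or self.tau_decay <= 0:
            raise ValueError("temperatures and tau_decay must be positive")
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if self.reward_mode not in ("reward", "rpe"):
            raise ValueError("reward_mode must be 'reward' or 'rpe'")
        if self.variant not in ("reinforcement_only", "dynamic"):
            raise ValueError("variant must be 'reinforcement_only' or 'dynamic'")


def init_qtable(K: int, value: float = 1.0) -> np.ndarray:
    Q = np.full((K, K), float(value))
    np.fill_diagonal(Q, 0.0)
    return Q


def q_update(Q: np.ndarray, s: int, a: int, r: float, params: RLParams) -> np.ndarray:
    """One temporal-difference (or RPE-substitution) update, in place."""
    if not np.isfinite(r):
        raise ValueError("reward must be finite")
    if params.reward_mode == "reward":
        target = r + params.gamma * Q[a].max()
        Q[s, a] += params.alpha * (target - Q[s, a])
    else:
        Q[s, a] += params.alpha * r
    return Q


def softmax_policy(Q_row: np.ndarray, temperature: float,
                   exclude: int | None = None) -> np.ndarray:
    """Softmax over actions; the current state (``exclude``) gets probability
    zero (no self-transitions).  Invariant to adding a constant to Q_row."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    q = np.asarray(Q_row, dtype=float) / temperature
    mask = np.ones(q.shape[0], dtype=bool)
    if exclude is not None:
        mask[exclude] = False
    z = q[mask] - q[mask].max()
    p = np.zeros(q.shape[0])
    e = np.exp(z)
    p[mask] = e / e.sum()
    return p


def _as_label_da(session):
    if hasattr(session, "labels"):
        return np.asarray(session.labels, int), np.asarray(session.da_amplitudes, float)
    labels, da = session
    return np.asarray(labels, int), np.asarray(da, float)


def restrict_to_top_syllables(sessions, k: int = 10):
    """Keep the k most frequent syllables, relabelled 0..k-1; out-of-set
    instances are dropped and any self-transition created by the dropping is
    merged (first instance kept)."""
    all_labels = np.concatenate([_as_label_da(s)[0] for s in sessions])
    top = np.sort(np.argsort(np.bincount(all_labels))[::-1][:k])
    remap = {int(s): i for i, s in enumerate(top)}
    out = []
    for s in sessions:
        labels, da = _as_label_da(s)
        keep = np.isin(labels, top)
        lab = np.array([remap[int(x)] for x in labels[keep]])
        amp = da[keep]
        dedup = np.concatenate([[True], lab[1:] != lab[:-1]])
        out.append((lab[dedup], amp[dedup]))
    return out, top


@dataclass
class RLResults:
    """Learned Q-table plus per-step action log-likelihoods."""

    params: RLParams
    qtable: np.ndarray
    logliks: np.ndarray  # one per scored transition
    temperature_trace: np.ndarray
    n_syllables: int

    @property
    def total_loglik(self) -> float:
        return float(self.logliks.sum())

    def evaluate(self, empirical: np.ndarray) -> float:
        return evaluate_qtable(self.qtable, empirical)

    def summary(self) -> str:
        return "\n".join([
            "Q-learning agent over syllable transitions",
            "==========================================",
            f"variant: {self.params.variant}   reward mode: {self.params.reward_mode}",
            f"alpha: {self.params.alpha}   gamma: {self.params.gamma}   "
            f"temperature: {self.params.temperature}",
            f"transitions scored: {self.logliks.size}   "
            f"total log-likelihood: {self.total_loglik:.2f}",
            f"mean temperature: {self.temperature_trace.mean():.3f}",
        ])


class QLearningModel:
    """Q-learning agent fed recorded sessions (statsmodels-style wrapper).

    ``fit()`` runs the agent over the data with the given parameters and
    returns :class:`RLResults`; ``fit_grid`` grid-searches free parameters by
    held-out likelihood.
    """

    def __init__(self, sessions, params: RLParams | None = None,
                 n_syllables: int | None = None):
        self.sessions = [_as_label_da(s) for s in sessions]
        self.params = params or RLParams()
        if n_syllables is None:
            n_syllables = int(max(l.max() for l, _ in self.sessions)) + 1
        self.K = n_syllables
        for labels, _ in self.sessions:
            if labels.max() >= self.K or labels.min() < 0:
                raise ValueError("unknown syllable in sequence")

    def fit(self, params: RLParams | None = None, session_idx=None) -> RLResults:
        params = params or self.params
        idx = range(len(self.sessions)) if session_idx is None else session_idx
        Q = init_qtable(self.K, params.q_init)
        lls, temps = [], []
        for i in idx:
            labels, da = self.sessions[i]
            last_cross = None
            for t in range(len(labels) - 1):
                s, a = int(labels[t]), int(labels[t + 1])
                r = float(da[t + 1])
                if params.variant == "dynamic":
                    if float(da[t]) >= params.lam:
                        last_cross = t
                    if last_cross is None or params.nu == 0:
                        tau = params.tau_baseline
                    else:
                        tau = params.nu * np.exp(-(t - last_cross) / params.tau_decay) \
                            + params.tau_baseline
                else:
                    tau = params.temperature
                p = softmax_policy(Q[s], tau, exclude=s)
                lls.append(np.log(max(p[a], 1e-300)))
                temps.append(tau)
                q_update(Q, s, a, r, params)
        return RLResults(params, Q, np.asarray(lls), np.asarray(temps), self.K)

    def fit_grid(self, alpha_grid=(0.01, 0.05, 0.1, 0.3), gamma_grid=(0.0, 0.5, 0.9),
                 temp_grid=(0.1, 0.5, 1.0, 2.0), reward_mode: str = "reward",
                 folds: int = 2, seed: int = 0) -> dict:
        """Grid search by held-out log-likelihood (K-fold over sessions)."""
        n = len(self.sessions)
        if n < folds:
            raise ValueError("need at least `folds` sessions")
        if reward_mode == "rpe":
            gamma_grid = (0.0,)  # discount enters the reward model only
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        bounds = np.linspace(0, n, folds + 1).astype(int)
        best, best_ll = None, -np.inf
        for alpha in alpha_grid:
            for gamma in gamma_grid:
                for temp in temp_grid:
                    p = replace(self.params, alpha=alpha, gamma=gamma,
                                temperature=temp, reward_mode=reward_mode,
                                variant="reinforcement_only")
                    ll = 0.0
                    for f in range(folds):
                        test = perm[bounds[f]: bounds[f + 1]]
                        ll += self.fit(p, session_idx=test).total_loglik
                    if ll > best_ll:
                        best, best_ll = p, ll
        return {"params": best, "heldout_loglik": best_ll}


def run_agent(sessions, params: RLParams, n_syllables: int | None = None) -> RLResults:
    """Functional form of :meth:`QLearningModel.fit`."""
    return QLearningModel(sessions, params, n_syllables).fit()


def _row_z_offdiag(M: np.ndarray) -> np.ndarray:
    K = M.shape[0]
    out = []
    for i in range(K):
        row = np.delete(M[i], i)
        if np.isnan(row).any():
            out.append(np.full(K - 1, np.nan))
            continue
        sd = row.std()
        out.append((row - row.mean()) / sd if sd > 0 else row * 0.0)
    return np.concatenate(out)


def evaluate_qtable(Q: np.ndarray, empirical: np.ndarray) -> float:
    """Pearson correlation between row-z-scored off-diagonal entries of the
    Q-table and the empirical transition matrix."""
    if Q.shape != empirical.shape:
        raise ValueError("Q and empirical matrix must have matching shape")
    a = _row_z_offdiag(np.asarray(Q, float))
    b = _row_z_offdiag(np.asarray(empirical, float))
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _shuffled_sessions(sessions, rng, mode: str = "within"):
    out = []
    for s in sessions:
        labels, da = _as_label_da(s)
        out.append((labels, rng.permutation(da)))
    return out


def qtable_shuffle_null(sessions, params: RLParams, n_shuffles: int = 100,
                        seed: int = 0) -> dict:
    """Shuffle test: observed Q-table/empirical-matrix correlation against
    agents fit with time-shuffled dopamine."""
    model = QLearningModel(sessions, params)
    empirical = transition_matrix(
        np.concatenate([l for l, _ in model.sessions]), model.K
    )
    r_obs = model.fit().evaluate(empirical)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuf = _shuffled_sessions(model.sessions, rng)
        null[k] = QLearningModel(shuf, params, model.K).fit().evaluate(empirical)
    p = float((np.sum(null >= r_obs) + 1) / (n_shuffles + 1))
    return {"r": r_obs, "null": null, "p": p,
            "exceeds_95pct": bool(r_obs > np.percentile(null, 95))}


def lag_shift_analysis(sessions, params: RLParams, lags) -> dict:
    """Q-table/empirical correlation after shifting dopamine by each lag
    (within session)."""
    model = QLearningModel(sessions, params)
    empirical = transition_matrix(
        np.concatenate([l for l, _ in model.sessions]), model.K
    )
    lags = np.asarray(list(lags), dtype=int)
    rs = np.empty(lags.size)
    for j, lag in enumerate(lags):
        shifted = []
        for labels, da in model.sessions:
            if abs(int(lag)) >= labels.shape[0]:
                raise ValueError("|lag| must be smaller than the session length")
            shifted.append((labels, np.roll(da, int(lag))))
        rs[j] = QLearningModel(shifted, params, model.K).fit().evaluate(empirical)
    return {"lags": lags, "r": rs}


def grid_search_compare(sessions, alpha_grid=(0.01, 0.05, 0.1, 0.3),
                        gamma_grid=(0.0, 0.5, 0.9), temp_grid=(0.1, 0.5, 1.0, 2.0),
                        reward_modes=("reward", "rpe"), folds: int = 2,
                        n_shuffles: int = 10, n_boot: int = 50, seed: int = 0) -> dict:
    """Grid search per reward mode; held-out log-likelihoods z-scored against
    between-session dopamine shuffles, bootstrapped over sessions."""
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    rng = np.random.default_rng(seed)
    base = [_as_label_da(s) for s in sessions]
    K = int(max(l.max() for l, _ in base)) + 1

    def heldout(sess_list, mode, params=None):
        m = QLearningModel(sess_list, RLParams(), K)
        if params is None:
            res = m.fit_grid(alpha_grid, gamma_grid, temp_grid, mode,
                             folds=folds, seed=seed)
            return res["params"], res["heldout_loglik"]
        n = len(sess_list)
        perm = np.random.default_rng(seed).permutation(n)
        bounds = np.linspace(0, n, folds + 1).astype(int)
        ll = sum(
            m.fit(params, session_idx=perm[bounds[f]: bounds[f + 1]]).total_loglik
            for f in range(folds)
        )
        return params, ll

    def between_session_shuffle(sess_list, rng):
        # pool dopamine across experiments and deal it back out
        pool = np.concatenate([d for _, d in sess_list])
        pool = rng.permutation(pool)
        out, k = [], 0
        for labels, d in sess_list:
            out.append((labels, pool[k: k + d.shape[0]]))
            k += d.shape[0]
        return out

    results = {}
    for mode in reward_modes:
        best, ll_obs = heldout(base, mode)
        null = np.array([
            heldout(between_session_shuffle(base, rng), mode, params=best)[1]
            for _ in range(n_shuffles)
        ])
        boot = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, len(base), size=len(base))
            boot[b] = heldout([base[i] for i in pick], mode, params=best)[1]
        sd = null.std(ddof=1)
        results[mode] = {
            "best_params": best,
            "heldout_loglik": ll_obs,
            "z": float((ll_obs - null.mean()) / sd) if sd > 0 else np.nan,
            "z_boot": (boot - null.mean()) / sd if sd > 0 else np.full(n_boot, np.nan),
        }
    return results


def free_running_mode(params: RLParams, da_pools, n_steps: int, seed: int = 0,
                      start: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-loop simulation: the agent selects its own actions and reward is
    drawn from the per-action empirical dopamine pools."""
    K = len(da_pools)
    pools = [np.asarray(p, dtype=float) for p in da_pools]
    if any(p.size == 0 for p in pools):
        raise ValueError("every action needs a non-empty dopamine pool")
    rng = np.random.default_rng(seed)
    Q = init_qtable(K, params.q_init)
    labels = np.empty(n_steps, dtype=int)
    da = np.empty(n_steps)
    s = int(start)
    last_cross = None
    for t in range(n_steps):
        if params.variant == "dynamic" and last_cross is not None and params.nu > 0:
            tau = params.nu * np.exp(-(t - last_cross) / params.tau_decay) + params.tau_baseline
        elif params.variant == "dynamic":
            tau = params.tau_baseline
        else:
            tau = params.temperature
        p = softmax_policy(Q[s], tau, exclude=s)
        a = int(rng.choice(K, p=p))
        r = float(rng.choice(pools[a]))
        if params.variant == "dynamic" and r >= params.lam:
            last_cross = t
        q_update(Q, s, a, r, params)
        labels[t] = a
        da[t] = r
        s = a
    return labels, da, Q
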