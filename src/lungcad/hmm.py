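"""Discrete-observation hidden Markov models for nodule classification.

An HMM over N hidden states and M observation symbols is characterized
by three stochastic arrays: the initial distribution π (π_i = probability
of starting in state i), the transition matrix A (a_ij = probability of
moving from state i to state j), and the observation matrix B
(b_j(k) = probability of emitting symbol k in state j).  The state
sequence is hidden; only the emitted symbols are observed.

Training uses Baum–Welch (EM) re-estimation: π̂_i is the expected
frequency of being in state i at time 1; â_ij the expected number of
i→j transitions over the expected number of transitions out of i; and
b̂_j(k) the expected number of times in state j while observing symbol k
over the expected number of times in state j.  Multiple training
sequences are, by default, concatenated into a single observation
sequence before re-estimation; a statistically cleaner per-sequence
accumulation mode is also provided (concatenation inserts spurious
transitions across sequence boundaries).

Forward/backward recursions are scaled per step so likelihoods of long
sequences stay representable; the log-likelihood is recovered from the
scale factors.

Classification is maximum-likelihood over a set of labeled models: the
observation sequence is scored under each model's forward recursion and
assigned to the argmax label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np

__all__ = [
    "HMMParams",
    "TrainResult",
    "init_params",
    "forward",
    "backward",
    "baum_welch",
    "sample",
    "classify",
]

_ROW_TOL = 1e-9
_FLOOR = 1e-12


@dataclass
class HMMParams:
    """π, A, B of a discrete HMM with N states and M symbols."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.pi)

    @property
    def n_symbols(self) -> int:
        return self.B.shape[1]

    def validate(self) -> None:
        N = len(self.pi)
        if self.A.shape != (N, N):
            raise ValueError(f"A must be {N}x{N}, got {self.A.shape}")
        if self.B.ndim != 2 or self.B.shape[0] != N:
            raise ValueError(f"B must have {N} rows, got {self.B.shape}")
        for name, arr in (("pi", self.pi), ("A", self.A), ("B", self.B)):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
        if abs(self.pi.sum() - 1.0) > _ROW_TOL:
            raise ValueError("pi must sum to 1")
        for name, arr in (("A", self.A), ("B", self.B)):
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > _ROW_TOL):
                raise ValueError(f"rows of {name} must sum to 1")

    def to_json(self, label: str | None = None) -> str:
        d = {"n_states": self.n_states, "n_symbols": self.n_symbols,
             "pi": self.pi.tolist(), "A": self.A.tolist(), "B": self.B.tolist()}
        if label is not None:
            d["label"] = label
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> tuple["HMMParams", str | None]:
        d = json.loads(text)
        return cls(pi=np.array(d["pi"]), A=np.array(d["A"]),
                   B=np.array(d["B"])), d.get("label")


@dataclass
class TrainResult:
    """Baum–Welch output: final parameters plus the likelihood trace."""

    params: HMMParams
    loglik_trace: list[float]
    n_iter: int
    converged: bool


def init_params(n_states: int, n_symbols: int, seed: int = 0,
                eps: float = 0.05) -> HMMParams:
    """Uniform rows with seeded jitter of size ``eps``, renormalized.

    Baum–Welch converges only to a local optimum and its fixed point
    depends heavily on the starting model; the jitter breaks the symmetry
    of the exactly-uniform (degenerate saddle) initialization.
    """
    rng = np.random.default_rng(seed)

    def rows(shape):
        w = np.full(shape, 1.0) + rng.uniform(-eps, eps, size=shape)
        w = np.clip(w, 1e-6, None)
        return w / w.sum(axis=-1, keepdims=True)

    return HMMParams(pi=rows(n_states), A=rows((n_states, n_states)),
                     B=rows((n_states, n_symbols)))


def _check_obs(params: HMMParams, obs) -> np.ndarray:
    obs = np.asarray(obs, dtype=int)
    if obs.ndim != 1 or len(obs) == 0:
        raise ValueError("observation sequence must be nonempty and 1-D")
    if np.any(obs < 0) or np.any(obs >= params.n_symbols):
        raise ValueError(
            f"symbols must lie in [0, {params.n_symbols}); got range "
            f"[{obs.min()}, {obs.max()}]")
    return obs


def forward(params: HMMParams, obs) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward recursion.

    Returns ``(alpha_hat, scales, loglik)`` where each row of
    ``alpha_hat`` sums to 1, ``scales[t]`` is the normalizer
    P(o_t | o_1..t−1), and ``loglik = Σ log scales``.  A structurally
    impossible sequence yields ``-inf``, not an exception.
    """
    obs = _check_obs(params, obs)
    T, N = len(obs), params.n_states
    alpha = np.zeros((T, N))
    scales = np.zeros(T)
    a = params.pi * params.B[:, obs[0]]
    for t in range(T):
        if t > 0:
            a = (alpha[t - 1] @ params.A) * params.B[:, obs[t]]
        scales[t] = a.sum()
        if scales[t] == 0.0:
            # impossible continuation: likelihood is exactly zero
            scales[t:] = 0.0
            return alpha, scales, -np.inf
        alpha[t] = a / scales[t]
    return alpha, scales, float(np.sum(np.log(scales)))


def backward(params: HMMParams, obs, scales: np.ndarray) -> np.ndarray:
    """Scaled backward recursion sharing the forward scale factors.

    ``beta_hat[t] = beta[t] / Π_{s>t} scales[s]``, so the posterior
    identity Σ_i alpha_hat[t,i]·beta_hat[t,i] = 1 holds at every t
    (base case beta_hat[T−1] = 1).
    """
    obs = _check_obs(params, obs)
    T, N = len(obs), params.n_states
    beta = np.zeros((T, N))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        if scales[t + 1] == 0.0:
            beta[t] = 0.0
            continue
        beta[t] = (params.A @ (params.B[:, obs[t + 1]] * beta[t + 1])) / scales[t + 1]
    return beta


def _expectations(params: HMMParams, obs: np.ndarray):
    """E-step posteriors: gamma (T×N), xi summed over t ((N×N)), loglik."""
    alpha, scales, ll = forward(params, obs)
    if not np.isfinite(ll):
        raise ValueError("training sequence has zero probability under the model")
    beta = backward(params, obs, scales)
    gamma = alpha * beta
    T = len(obs)
    xi_sum = np.zeros((params.n_states, params.n_states))
    for t in range(T - 1):
        xi_sum += (alpha[t][:, None] * params.A
                   * (params.B[:, obs[t + 1]] * beta[t + 1])[None, :]) / scales[t + 1]
    return gamma, xi_sum, ll


def _floor_rows(mat: np.ndarray) -> np.ndarray:
    mat = np.maximum(mat, _FLOOR)
    return mat / mat.sum(axis=-1, keepdims=True)


def baum_welch(init: HMMParams, sequences, max_iter: int = 200,
               tol: float = 1e-6, mode: str = "concat") -> TrainResult:
    """Baum–Welch re-estimation of π, A, B on one or more symbol sequences.

    ``mode="concat"`` (default) joins all sequences into one observation
    stream before re-estimation; ``mode="separate"`` accumulates the
    E-step statistics per sequence, avoiding the spurious cross-boundary
    transitions concatenation introduces.  On single-sequence input both
    modes are identical.

    Stops when the log-likelihood improves by less than ``tol`` or after
    ``max_iter`` iterations.  Re-estimated rows are floored at 1e-12 and
    renormalized so degenerate data cannot produce NaNs; the likelihood
    trace is non-decreasing (up to that floor's perturbation).
    """
    if mode not in ("concat", "separate"):
        raise ValueError("mode must be 'concat' or 'separate'")
    if isinstance(sequences, (list, tuple)):
        seqs = [_check_obs(init, s) for s in sequences]
    else:
        seqs = [_check_obs(init, sequences)]
    if not seqs:
        raise ValueError("need at least one training sequence")
    if mode == "concat" and len(seqs) > 1:
        seqs = [np.concatenate(seqs)]

    params = HMMParams(pi=init.pi.copy(), A=init.A.copy(), B=init.B.copy())
    trace: list[float] = []
    converged = False
    n_iter = 0
    M = params.n_symbols
    for n_iter in range(1, max_iter + 1):
        pi_acc = np.zeros(params.n_states)
        a_num = np.zeros((params.n_states, params.n_states))
        a_den = np.zeros(params.n_states)
        b_num = np.zeros((params.n_states, M))
        ll_total = 0.0
        for obs in seqs:
            gamma, xi_sum, ll = _expectations(params, obs)
            ll_total += ll
            pi_acc += gamma[0]
            a_num += xi_sum
            a_den += gamma[:-1].sum(axis=0)
            for k in range(M):
                b_num[:, k] += gamma[obs == k].sum(axis=0)
        trace.append(ll_total)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        new_pi = _floor_rows(pi_acc / len(seqs))
        new_A = _floor_rows(a_num / np.maximum(a_den, _FLOOR)[:, None])
        new_B = _floor_rows(b_num / np.maximum(b_num.sum(axis=1), _FLOOR)[:, None])
        params = HMMParams(pi=new_pi, A=new_A, B=new_B)
    return TrainResult(params=params, loglik_trace=trace,
                       n_iter=n_iter, converged=converged)


def sample(params: HMMParams, T: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw a symbol sequence (and its hidden state path) from the model."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    N, M = params.n_states, params.n_symbols
    states = np.zeros(T, dtype=np.int64)
    obs = np.zeros(T, dtype=np.int64)
    states[0] = rng.choice(N, p=params.pi)
    obs[0] = rng.choice(M, p=params.B[states[0]])
    for t in range(1, T):
        states[t] = rng.choice(N, p=params.A[states[t - 1]])
        obs[t] = rng.choice(M, p=params.B[states[t]])
    return obs, states


def classify(models: dict[str, HMMParams], obs) -> tuple[str, dict[str, float]]:
    """Maximum-likelihood call over labeled models.

    Scores the sequence under each model's forward recursion; ties go to
    the first label in sorted order.  Requires at least two models and a
    nonempty sequence (no evidence, no call).
    """
    if len(models) < 2:
        raise ValueError("need at least two labeled models")
    obs = np.asarray(obs, dtype=int)
    if obs.size == 0:
        raise ValueError("cannot classify an empty observation sequence")
    sym_counts = {p.n_symbols for p in models.values()}
    if len(sym_counts) != 1:
        raise ValueError("all models must share the same symbol alphabet")
    logliks = {}
    for label in sorted(models):
        _, _, ll = forward(models[label], obs)
        logliks[label] = ll
    best = max(sorted(logliks), key=lambda lab: logliks[lab])
    return best, logliks
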