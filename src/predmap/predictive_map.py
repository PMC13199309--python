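"""Successor-feature layer: linear predictive read-out with TD learning.

The predictive map holds a square matrix ``M`` over sparse-layer units and
reads out ``p_h = Mᵀ·s_h``. With the sparse code ``s_h`` playing the role of
the feature vector φ(s), the converged read-out approximates the successor
features ψ(s) = E[Σ_t γᵗ φ(s_t) | s₀ = s]: the discounted expected future
activity of every unit given the present one. M adapts online with the
TD(0) rule

    M ← M + η · s_h,t · (s_h,t + γ·p_h,t+1 − p_h,t)ᵀ,

where both read-outs use the pre-update M. With one-hot features on a
finite Markov chain this converges to the classical successor
representation (I − γP)⁻¹, which :func:`analytic_sr` provides in closed
form as the validation oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SuccessorFeatures", "predict", "td_update_matrix", "analytic_sr"]


def predict(M, s_h):
    """Predictive read-out p_h = Mᵀ·s_h (dense even for sparse s_h)."""
    return np.asarray(M, dtype=float).T @ np.asarray(s_h, dtype=float)


def td_update_matrix(M, s_t, s_next, gamma, eta):
    """One TD(0) update of the successor-feature matrix; returns new M.

    Both bootstrap read-outs use the incoming (pre-update) M. The outer
    product touches only rows where ``s_t`` is active, which is exploited
    for sparse codes.
    """
    M = np.asarray(M, dtype=float)
    s_t = np.asarray(s_t, dtype=float)
    s_next = np.asarray(s_next, dtype=float)
    active = np.flatnonzero(s_t != 0.0)
    if active.size == 0:
        return M
    p_t = M.T @ s_t
    p_next = M.T @ s_next
    delta = s_t + gamma * p_next - p_t           # (N_h,)
    M = M.copy()
    M[active, :] += eta * np.outer(s_t[active], delta)
    return M


def analytic_sr(P, gamma):
    """Closed-form successor representation (I − γP)⁻¹ of a Markov chain.

    ``P`` must be row-stochastic and ``gamma < 1``; row sums of the result
    equal 1/(1−γ).
    """
    P = np.asarray(P, dtype=float)
    if not (0 <= gamma < 1):
        raise ValueError("gamma must be in [0, 1)")
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("P must be row-stochastic")
    n = P.shape[0]
    M = np.linalg.inv(np.eye(n) - gamma * P)
    assert np.all(np.isfinite(M))
    return M


class SuccessorFeatures:
    """Sklearn-style online successor-feature estimator.

    Parameters
    ----------
    gamma : float
        Discount factor in [0, 1).
    eta : float
        TD learning rate.
    init_scale : float
        M is initialized to ``init_scale·I`` — a neutral start that still
        produces nonzero read-outs for the first TD targets.

    Attributes
    ----------
    M_ : ndarray (n_features, n_features)
    n_features_in_ : int
    n_updates_ : int
    """

    def __init__(self, gamma=0.95, eta=0.05, init_scale=0.1):
        self.gamma = gamma
        self.eta = eta
        self.init_scale = init_scale

    def get_params(self, deep=True):
        return {"gamma": self.gamma, "eta": self.eta, "init_scale": self.init_scale}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def initialize(self, n_features):
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")
        self.M_ = self.init_scale * np.eye(n_features)
        self.n_features_in_ = n_features
        self.n_updates_ = 0
        return self

    def predict(self, s_h):
        """Read-out p_h = M_ᵀ·s_h for one code or a batch of row codes."""
        s_h = np.asarray(s_h, dtype=float)
        if s_h.ndim == 1:
            return predict(self.M_, s_h)
        return s_h @ self.M_          # rows: (M, N) @ (N, N) — Mᵀ applied rowwise

    def td_update(self, s_t, s_next):
        """Online TD(0) update from one consecutive activity pair."""
        if not hasattr(self, "M_"):
            self.initialize(np.asarray(s_t).shape[-1])
        self.M_ = td_update_matrix(self.M_, s_t, s_next, self.gamma, self.eta)
        self.n_updates_ += 1
        return self

    def fit(self, X, y=None, episode_ids=None):
        """Online pass over a trajectory of row features.

        ``episode_ids`` (optional, aligned with rows) suppresses updates
        across episode boundaries: transitions through a reset are not part
        of the environment's dynamics.
        """
        X = np.asarray(X, dtype=float)
        self.initialize(X.shape[1])
        for t in range(len(X) - 1):
            if episode_ids is not None and episode_ids[t] != episode_ids[t + 1]:
                continue
            self.td_update(X[t], X[t + 1])
        return self
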