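"""Non-negative sparse coding of entorhinal inputs (place-cell layer).

The layer represents each entorhinal input vector ``s_e`` with a sparse
non-negative code ``s_h`` minimizing

    G(A, s_h) = ||s_e − A·s_h||²₂ + β·||s_h||₁,   A ≥ 0, s_h ≥ 0,

where ``A`` is a non-negative dictionary with unit-L2-norm columns. Codes
are computed with the discretized locally competitive algorithm (LCA):

    u ← u + (1/τ)·(−u + Aᵀs_e − (AᵀA − I)·s_h),   s_h = max(u − β, 0),

and the dictionary adapts with a Hebbian residual rule
``A ← max(A + η·(s_e − A·s_h)·s_hᵀ, 0)`` followed by column normalization.
Trained on spatial input trajectories this produces localized, place-cell-
like tuning whose field density follows the structure of the inputs.
"""

from __future__ import annotations

import numpy as np

from .environments import step_random_walk, wrap_position

__all__ = [
    "NonNegativeSparseCoding",
    "nsc_cost",
    "lca_settle",
    "update_basis",
    "train_sparse_layer",
]


def nsc_cost(A, s_h, s_e, beta):
    """Sparse-coding cost: squared reconstruction error plus L1 penalty."""
    resid = np.asarray(s_e, dtype=float) - np.asarray(A, dtype=float) @ np.asarray(s_h, dtype=float)
    return float(resid @ resid + beta * np.sum(np.abs(s_h)))


def lca_settle(s_e, A, beta, tau=10.0, n_iter=50, u0=None, gram=None):
    """Run ``n_iter`` discrete LCA updates; returns (u, s_h).

    ``gram`` may carry a precomputed ``AᵀA − I`` (used when the dictionary
    is frozen); otherwise the recurrent term is computed as
    ``Aᵀ(A·s_h) − s_h`` without forming the Gram matrix.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    A = np.asarray(A, dtype=float)
    b = A.T @ np.asarray(s_e, dtype=float)
    u = np.zeros(A.shape[1]) if u0 is None else np.array(u0, dtype=float)
    s = np.maximum(u - beta, 0.0)
    inv_tau = 1.0 / tau
    for _ in range(n_iter):
        if gram is not None:
            inhib = gram @ s
        else:
            inhib = A.T @ (A @ s) - s
        u = u + inv_tau * (-u + b - inhib)
        s = np.maximum(u - beta, 0.0)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("LCA produced non-finite membrane potentials")
    return u, s


def lca_settle_batch(S_e, A, beta, tau=10.0, n_iter=200):
    """Settle many inputs simultaneously from a zero start (frozen dictionary).

    ``S_e`` has shape (M, N_e); returns codes of shape (M, N_h). Used for
    batched map evaluation and offline re-analysis.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(S_e, dtype=float) @ A                       # (M, N_h)
    G = A.T @ A - np.eye(A.shape[1])
    U = np.zeros_like(B)
    S = np.maximum(U - beta, 0.0)
    inv_tau = 1.0 / tau
    for _ in range(n_iter):
        U += inv_tau * (-U + B - S @ G)
        np.maximum(U - beta, 0.0, out=S)
    return S


def update_basis(A, s_e, s_h, eta, rng=None):
    """Hebbian residual update, clip at zero, renormalize columns.

    Only columns with nonzero code participate (the outer product vanishes
    elsewhere). Columns whose norm collapses to ~0 after clipping are
    re-initialized to small positive noise (dead-unit rescue) when an
    ``rng`` is supplied, otherwise left untouched.
    """
    A = np.asarray(A, dtype=float)
    s_h = np.asarray(s_h, dtype=float)
    active = np.flatnonzero(s_h > 0)
    if active.size == 0 or eta == 0:
        return A
    resid = np.asarray(s_e, dtype=float) - A[:, active] @ s_h[active]
    cols = np.maximum(A[:, active] + eta * np.outer(resid, s_h[active]), 0.0)
    norms = np.linalg.norm(cols, axis=0)
    dead = norms < 1e-12
    if np.any(dead) and rng is not None:
        cols[:, dead] = rng.uniform(0.01, 1.0, size=(A.shape[0], int(dead.sum())))
        norms[dead] = np.linalg.norm(cols[:, dead], axis=0)
    ok = norms >= 1e-12
    cols[:, ok] /= norms[ok]
    A = A.copy()
    A[:, active] = cols
    return A


class NonNegativeSparseCoding:
    """Sklearn-style online sparse-coding estimator.

    Parameters
    ----------
    n_components : int
        Number of units in the layer (N_h).
    beta : float
        Sparsity threshold of the LCA soft threshold (dimensionless when
        ``normalize_input`` is on).
    tau : float
        LCA time constant (update gain 1/τ per inner iteration).
    n_lca_iter : int
        Inner LCA iterations per presented input (warm-started).
    eta : float
        Dictionary learning rate.
    normalize_input : {"fixed", "sample", "none"}
        Input scaling before coding. "fixed" (default) divides every input
        by one global scale — the mean input norm estimated at
        initialization — so that β and downstream learning rates are
        calibrated on unit-scale vectors while *relative* input drive across
        positions is preserved (salient locations such as objects or reward
        zones have stronger drive and attract more dictionary atoms).
        "sample" normalizes each vector to unit norm (destroys the drive
        gradient); "none" uses raw activities.
    warm_start_membrane : bool
        Carry the membrane potential u across consecutive inputs.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    components_ : ndarray of shape (n_features, n_components)
        The dictionary A (non-negative, unit-norm columns).
    membrane_ : ndarray of shape (n_components,)
        Current membrane state u.
    frozen : bool
        When True, ``step`` never updates the dictionary and uses a cached
        Gram matrix for speed.
    """

    def __init__(self, n_components=400, beta=0.3, tau=10.0, n_lca_iter=50,
                 eta=0.01, normalize_input="fixed", warm_start_membrane=True,
                 recycle_dead_units=True, recycle_ema=0.002,
                 recycle_threshold=0.02, random_state=None):
        self.n_components = n_components
        self.beta = beta
        self.tau = tau
        self.n_lca_iter = n_lca_iter
        self.eta = eta
        self.normalize_input = normalize_input
        self.warm_start_membrane = warm_start_membrane
        self.recycle_dead_units = recycle_dead_units
        self.recycle_ema = recycle_ema
        self.recycle_threshold = recycle_threshold
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep=True):
        return {
            "n_components": self.n_components, "beta": self.beta,
            "tau": self.tau, "n_lca_iter": self.n_lca_iter, "eta": self.eta,
            "normalize_input": self.normalize_input,
            "warm_start_membrane": self.warm_start_membrane,
            "recycle_dead_units": self.recycle_dead_units,
            "recycle_ema": self.recycle_ema,
            "recycle_threshold": self.recycle_threshold,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- state ------------------------------------------------------------
    def _rng(self):
        if not hasattr(self, "_rng_"):
            self._rng_ = np.random.default_rng(self.random_state)
        return self._rng_

    def initialize(self, n_features):
        rng = self._rng()
        A = rng.uniform(0.01, 1.0, size=(n_features, self.n_components))
        A /= np.linalg.norm(A, axis=0)
        if not hasattr(self, "scale_"):
            self.scale_ = 1.0
        self._set_dictionary(A)
        self.membrane_ = np.zeros(self.n_components)
        self.n_features_in_ = n_features
        self.frozen = False
        return self

    def initialize_from_samples(self, S):
        """Seed dictionary columns from (normalized) input samples.

        Dense random positive columns are nearly collinear in high
        dimension, which makes a handful of units win the competition
        everywhere; seeding each column with an actual input vector gives
        every unit a distinct initial tuning, from which learning spreads
        fields across the environment.
        """
        S = np.asarray(S, dtype=float)
        if S.shape[0] != self.n_components:
            raise ValueError("need exactly n_components sample rows")
        self.scale_ = float(np.linalg.norm(S, axis=1).mean()) or 1.0
        S = self._prep(S)
        A = np.maximum(S.T.copy(), 0.0)
        A /= np.linalg.norm(A, axis=0)
        self._set_dictionary(A)
        self.membrane_ = np.zeros(self.n_components)
        self.n_features_in_ = A.shape[0]
        self.frozen = False
        return self

    def _set_dictionary(self, A):
        self.components_ = A
        # Gram cache AᵀA − I, kept in sync with the dictionary
        self._gram = A.T @ A - np.eye(A.shape[1])

    def _refresh_gram(self, cols):
        A = self.components_
        new = A.T @ A[:, cols]
        self._gram[:, cols] = new
        self._gram[cols, :] = new.T
        self._gram[cols, cols] = np.einsum("ij,ij->j", A[:, cols], A[:, cols]) - 1.0

    def _prep(self, s_e):
        s_e = np.asarray(s_e, dtype=float)
        mode = self.normalize_input
        if mode is True:        # backward-compatible alias
            mode = "sample"
        if mode == "sample":
            nrm = np.linalg.norm(s_e, axis=-1, keepdims=s_e.ndim > 1)
            if s_e.ndim == 1:
                nrm = float(nrm)
                if nrm > 0:
                    s_e = s_e / nrm
            else:
                s_e = np.divide(s_e, np.where(nrm > 0, nrm, 1.0))
        elif mode == "fixed":
            s_e = s_e / getattr(self, "scale_", 1.0)
        elif mode not in ("none", False, None):
            raise ValueError(f"unknown normalize_input mode {mode!r}")
        return s_e

    def freeze(self):
        """Stop dictionary learning (Gram cache stays valid)."""
        self.frozen = True
        return self

    def reset_membrane(self):
        self.membrane_[:] = 0.0

    # -- core online step -------------------------------------------------
    def step(self, s_e, learn=None):
        """Settle the LCA on one input; optionally update the dictionary.

        Returns the sparse code s_h. ``learn`` defaults to ``not frozen``.
        """
        if not hasattr(self, "components_"):
            self.initialize(np.asarray(s_e).shape[-1])
        if learn is None:
            learn = not self.frozen
        if learn and self.frozen:
            raise RuntimeError("estimator is frozen; cannot learn")
        s_e = self._prep(s_e)
        u0 = self.membrane_ if self.warm_start_membrane else None
        u, s_h = lca_settle(s_e, self.components_, self.beta, tau=self.tau,
                            n_iter=self.n_lca_iter, u0=u0, gram=self._gram)
        self.membrane_ = u
        if learn:
            changed = np.flatnonzero(s_h > 0)
            if changed.size:
                self.components_ = update_basis(
                    self.components_, s_e, s_h, self.eta, rng=self._rng()
                )
                self._refresh_gram(changed)
            self._recycle(s_e, s_h)
        return s_h

    def _recycle(self, s_e, s_h):
        """Reassign one long-inactive unit to the current input.

        Units whose activity trace falls far below the population mean have
        lost the competition everywhere; re-seeding them with the present
        input reallocates capacity to where the inputs actually live — the
        standard dead-atom treatment in online dictionary learning.
        """
        if not self.recycle_dead_units or self.eta == 0:
            return  # η=0 means a deliberately frozen dictionary
        if not hasattr(self, "activity_ema_"):
            self.activity_ema_ = np.full(self.n_components, np.mean(s_h) + 1e-3)
        ema = self.activity_ema_
        ema += self.recycle_ema * (s_h - ema)
        mean = ema.mean()
        nrm = np.linalg.norm(s_e)
        if mean <= 0 or nrm == 0:
            return
        worst = int(np.argmin(ema))
        if ema[worst] < self.recycle_threshold * mean:
            self.components_[:, worst] = s_e / nrm
            self._refresh_gram(np.array([worst]))
            ema[worst] = mean
            self.membrane_[worst] = 0.0

    # -- batch API ---------------------------------------------------------
    def fit(self, X, y=None):
        """One online pass over the rows of X (inputs in presentation order)."""
        X = np.asarray(X, dtype=float)
        self.scale_ = float(np.linalg.norm(X, axis=1).mean()) or 1.0
        self.initialize(X.shape[1])
        for row in X:
            self.step(row, learn=True)
        return self

    def transform(self, X, n_iter=200):
        """Sparse codes for rows of X, each settled from a zero start."""
        if not hasattr(self, "components_"):
            raise RuntimeError("estimator is not fitted")
        X = self._prep(np.atleast_2d(np.asarray(X, dtype=float)))
        return lca_settle_batch(X, self.components_, self.beta,
                                tau=self.tau, n_iter=n_iter)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def cost(self, s_e):
        """Current-code sparse-coding cost of one (normalized) input."""
        s_e = self._prep(s_e)
        s_h = np.maximum(self.membrane_ - self.beta, 0.0)
        return nsc_cost(self.components_, s_h, s_e, self.beta)


def train_sparse_layer(env, ec, coder, n_steps, rng, speed=0.1,
                       start=None, record_cost_every=50):
    """Train the sparse layer under uniform-random exploration.

    The agent takes ``n_steps`` random-walk steps in ``env``; at each step
    the entorhinal input is coded (warm-started LCA) and the dictionary is
    updated. Returns ``(coder, cost_history)`` where the history holds
    (step, cost) pairs sampled every ``record_cost_every`` steps.
    """
    if start is None:
        pos = np.full(env.ndim, env.L / 2.0) if env.ndim == 2 else np.array(env.L / 2.0)
    else:
        pos = wrap_position(start, env.L)
    if not hasattr(coder, "components_"):
        # seed dictionary columns from inputs at candidate locations drawn
        # with probability ∝ input energy: reconstruction-error minimization
        # allocates capacity to where the input power lives, so the initial
        # allocation should too (salient regions get more atoms)
        n_cand = 10 * coder.n_components
        if env.ndim == 2:
            cand = rng.uniform(0.0, env.L, size=(n_cand, 2))
        else:
            cand = rng.uniform(0.0, env.L, size=n_cand)
        S_cand = ec.encode(cand)
        w = np.sum(S_cand**2, axis=1)
        pick = rng.choice(n_cand, size=coder.n_components, replace=False,
                          p=w / w.sum())
        coder.initialize_from_samples(S_cand[pick])
    costs = []
    for t in range(n_steps):
        s_e = ec.encode(pos if env.ndim == 2 else float(pos))
        s_h = coder.step(s_e, learn=True)
        if record_cost_every and t % record_cost_every == 0:
            costs.append((t, nsc_cost(coder.components_, s_h, coder._prep(s_e), coder.beta)))
        pos = step_random_walk(pos, env.L, rng, speed=speed)
    return coder, np.array(costs)
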