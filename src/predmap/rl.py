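"""Actor–critic reinforcement learning on top of the predictive map.

The critic is *not* a trained network: the state value is the inner product
``V(x) = p_hᵀ·R`` between the predictive read-out and a reward vector ``R``
learned by the exponential trace ``R ← R + α·(r·s_h − R)``. Only R and the
successor matrix M adapt on the critic side; the TD error

    δ = r + γ·V(x') − V(x)

drives both the actor's policy gradient and (through the environment loop)
the successor-feature learning.

Two actors are provided, both small multilayer perceptrons written directly
in numpy with explicit backward passes (their gradients are verified against
finite differences in the test suite):

* :class:`Actor2D` — LayerNorm input → hidden SiLU layer → 32-way softmax
  directional weights; the mean displacement is the population vector
  ``μ = d_max·Σ_k w_k·(cos θ_k, sin θ_k)`` and the executed displacement is
  sampled per axis from N(μ, σ²) then clipped to [−2·d_max, 2·d_max].
* :class:`Actor1D` — LayerNorm input → hidden ReLU layer → tanh output,
  affinely rescaled to a mean step μ ∈ [d_min, d_max]; the step is sampled
  from N(μ, σ²) and clipped below at d_min (motion is always forward).

The policy-gradient loss is E = −log π(d|x)·δ with the Gaussian log-density
of the *unclipped* sample; clipping is environment-side saturation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "update_reward_vector",
    "state_value",
    "td_error",
    "Actor2D",
    "Actor1D",
    "SGD",
    "Adam",
    "policy_gradient_step",
]


def update_reward_vector(R, r_scalar, s_h, alpha):
    """Online exponential-trace update of the reward vector."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    R = np.asarray(R, dtype=float)
    return R + alpha * (r_scalar * np.asarray(s_h, dtype=float) - R)


def state_value(p_h, R):
    """State value V = p_hᵀ·R."""
    return float(np.dot(np.asarray(p_h, dtype=float), np.asarray(R, dtype=float)))


def td_error(r_scalar, v_next, v_now, gamma):
    """TD(0) error δ = r + γ·V(next) − V(now); pass v_next=0 at terminals."""
    return float(r_scalar + gamma * v_next - v_now)


# ---------------------------------------------------------------------------
# numpy MLP actors with explicit backward passes
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


def _layernorm_forward(x, g, b):
    mu = x.mean()
    xc = x - mu
    var = np.mean(xc * xc)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_backward(dy, g, cache):
    xhat, inv = cache
    dg = dy * xhat
    db = dy.copy()
    dxhat = dy * g
    n = xhat.size
    dx = inv * (dxhat - dxhat.mean() - xhat * np.mean(dxhat * xhat))
    # note: mean over all n elements; var computed with 1/n
    del n
    return dx, dg, db


def _silu(h):
    s = 1.0 / (1.0 + np.exp(-h))
    return h * s, s


def _silu_backward(dh_out, h, s):
    return dh_out * (s * (1.0 + h * (1.0 - s)))


class _ActorBase:
    """Shared parameter/initialization plumbing for the numpy actors."""

    def __init__(self, n_inputs, n_hidden, n_outputs, rng):
        self.n_inputs = n_inputs
        self.n_hidden = n_hidden
        self.params = {
            "ln_g": np.ones(n_inputs),
            "ln_b": np.zeros(n_inputs),
            "W1": rng.normal(0.0, 1.0 / np.sqrt(n_inputs), size=(n_hidden, n_inputs)),
            "b1": np.zeros(n_hidden),
            "W2": rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=(n_outputs, n_hidden)),
            "b2": np.zeros(n_outputs),
        }

    def zero_like_params(self):
        return {k: np.zeros_like(v) for k, v in self.params.items()}


class Actor2D(_ActorBase):
    """Population-vector policy over 32 evenly spaced movement directions."""

    def __init__(self, n_inputs, n_hidden=128, n_directions=32,
                 d_max=0.1, sigma=0.02, rng=None):
        rng = np.random.default_rng() if rng is None else rng
        super().__init__(n_inputs, n_hidden, n_directions, rng)
        self.n_directions = n_directions
        self.d_max = d_max
        self.sigma = sigma
        theta = 2.0 * np.pi * np.arange(n_directions) / n_directions
        self.directions = np.column_stack([np.cos(theta), np.sin(theta)])  # (K, 2)

    def forward(self, s_h):
        """Directional weights w (softmax) and population-vector mean μ."""
        p = self.params
        y0, ln_cache = _layernorm_forward(np.asarray(s_h, dtype=float), p["ln_g"], p["ln_b"])
        h1 = p["W1"] @ y0 + p["b1"]
        a1, sig1 = _silu(h1)
        z = p["W2"] @ a1 + p["b2"]
        z = z - z.max()
        ez = np.exp(z)
        w = ez / ez.sum()
        mu = self.d_max * (w @ self.directions)              # (2,)
        cache = {"ln": ln_cache, "y0": y0, "h1": h1, "sig1": sig1,
                 "a1": a1, "w": w}
        return w, mu, cache

    def act(self, s_h, rng):
        """Sample a displacement; returns (displacement, info dict)."""
        w, mu, cache = self.forward(s_h)
        sample = rng.normal(mu, self.sigma)                  # pre-clip
        disp = np.clip(sample, -2.0 * self.d_max, 2.0 * self.d_max)
        log_prob = -0.5 * np.sum((sample - mu) ** 2) / self.sigma**2 \
            - np.log(2.0 * np.pi * self.sigma**2)
        info = {"mu": mu, "sample": sample, "log_prob": log_prob, "cache": cache}
        return disp, info

    def grad_loss(self, info, delta):
        """Gradients of E = −log π(sample)·δ w.r.t. all parameters."""
        p = self.params
        cache = info["cache"]
        w, mu = cache["w"], info["mu"]
        # dE/dmu = −δ · d log π/dμ = −δ · (sample − μ)/σ²
        dmu = -delta * (info["sample"] - mu) / self.sigma**2          # (2,)
        dw = self.d_max * (self.directions @ dmu)                     # (K,)
        dz = w * (dw - np.dot(dw, w))                                 # softmax
        grads = {}
        grads["W2"] = np.outer(dz, cache["a1"])
        grads["b2"] = dz
        da1 = p["W2"].T @ dz
        dh1 = _silu_backward(da1, cache["h1"], cache["sig1"])
        grads["W1"] = np.outer(dh1, cache["y0"])
        grads["b1"] = dh1
        dy0 = p["W1"].T @ dh1
        dx, dg, db = _layernorm_backward(dy0, p["ln_g"], cache["ln"])
        grads["ln_g"] = dg
        grads["ln_b"] = db
        return grads

    def loss(self, s_h, sample, delta):
        """E = −log π(sample|s_h)·δ, recomputed from scratch (for checks)."""
        _, mu, _ = self.forward(s_h)
        log_prob = -0.5 * np.sum((sample - mu) ** 2) / self.sigma**2 \
            - np.log(2.0 * np.pi * self.sigma**2)
        return -log_prob * delta


class Actor1D(_ActorBase):
    """Forward-only Gaussian step policy on the 1D track."""

    def __init__(self, n_inputs, n_hidden=128, d_min=0.01, d_max=0.1,
                 sigma=0.01, rng=None):
        rng = np.random.default_rng() if rng is None else rng
        super().__init__(n_inputs, n_hidden, 1, rng)
        self.d_min = d_min
        self.d_max = d_max
        self.sigma = sigma

    def forward(self, s_h):
        p = self.params
        y0, ln_cache = _layernorm_forward(np.asarray(s_h, dtype=float), p["ln_g"], p["ln_b"])
        h1 = p["W1"] @ y0 + p["b1"]
        a1 = np.maximum(h1, 0.0)
        z = float((p["W2"] @ a1 + p["b2"])[0])
        t = np.tanh(z)
        mu = self.d_min + 0.5 * (t + 1.0) * (self.d_max - self.d_min)
        cache = {"ln": ln_cache, "y0": y0, "h1": h1, "a1": a1, "t": t}
        return mu, cache

    def act(self, s_h, rng):
        mu, cache = self.forward(s_h)
        sample = rng.normal(mu, self.sigma)
        disp = max(sample, self.d_min)       # forward motion only
        log_prob = -0.5 * (sample - mu) ** 2 / self.sigma**2 \
            - 0.5 * np.log(2.0 * np.pi * self.sigma**2)
        info = {"mu": mu, "sample": sample, "log_prob": log_prob, "cache": cache}
        return disp, info

    def grad_loss(self, info, delta):
        p = self.params
        cache = info["cache"]
        mu = info["mu"]
        dmu = -delta * (info["sample"] - mu) / self.sigma**2
        dt = dmu * 0.5 * (self.d_max - self.d_min)
        dz = dt * (1.0 - cache["t"] ** 2)
        grads = {}
        grads["W2"] = dz * cache["a1"][None, :]
        grads["b2"] = np.array([dz])
        da1 = dz * p["W2"][0]
        dh1 = da1 * (cache["h1"] > 0)
        grads["W1"] = np.outer(dh1, cache["y0"])
        grads["b1"] = dh1
        dy0 = p["W1"].T @ dh1
        dx, dg, db = _layernorm_backward(dy0, p["ln_g"], cache["ln"])
        grads["ln_g"] = dg
        grads["ln_b"] = db
        return grads

    def loss(self, s_h, sample, delta):
        mu, _ = self.forward(s_h)
        log_prob = -0.5 * (sample - mu) ** 2 / self.sigma**2 \
            - 0.5 * np.log(2.0 * np.pi * self.sigma**2)
        return -log_prob * delta


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, lr=1e-3):
        self.lr = lr

    def step(self, params, grads):
        for k, g in grads.items():
            params[k] -= self.lr * g


class Adam:
    """Adam optimizer (diagonal adaptive moments)."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def policy_gradient_step(actor, info, delta, optimizer):
    """One gradient step on E = −log π·δ; δ is treated as a constant."""
    if delta == 0.0:
        return actor
    grads = actor.grad_loss(info, delta)
    for g in grads.values():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite policy gradient (delta={delta}, mu={info['mu']})"
            )
    optimizer.step(actor.params, grads)
    return actor
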