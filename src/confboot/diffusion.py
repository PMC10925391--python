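"""Variance-exploding score-based diffusion in low-dimensional Euclidean space.

The forward process is the VE SDE ``dx = g(t) dw`` with ``g(t)^2 = d sigma^2/dt``
and a geometric noise schedule ``sigma(t) = sigma_min^(1-t) * sigma_max^t`` on
``t in [0, 1]``.  Its transition kernel is Gaussian,
``p_0t(x_t | x_0) = N(x_0, sigma(t)^2 I)``, which gives the closed-form
conditional score used by denoising score matching (DSM).  Generation runs the
reverse SDE ``dx = -g(t)^2 s_theta(x, t; d) dt + g(t) dw`` (time reversed) with
Euler--Maruyama.

The score model here is a small fully-connected network written directly in
numpy: the pose, a log-noise-level embedding and the conditioning context are
concatenated and mapped through two tanh hidden layers; the network predicts
the scaled noise, and the score is the network output divided by ``sigma(t)``.
This noise-prediction parametrization keeps the regression target O(1) at
every noise level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NoiseSchedule",
    "WeightFn",
    "ScoreMLP",
    "AnalyticGaussianScore",
    "sigma_of_t",
    "perturb",
    "conditional_score",
    "dsm_loss",
    "reverse_sample",
    "train_score_model",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Geometric VE noise schedule on normalized time ``t in [0, 1]``."""

    sigma_min: float = 0.1
    sigma_max: float = 16.0
    t_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma_min < self.sigma_max):
            raise ValueError(
                f"require 0 < sigma_min < sigma_max, got {self.sigma_min}, {self.sigma_max}"
            )
        if self.t_max != 1.0:
            raise ValueError("time is normalized; t_max must be 1")

    def sigma(self, t):
        return sigma_of_t(self, t)

    def g_squared(self, t):
        """Diffusion coefficient ``g(t)^2 = d sigma^2(t) / dt``."""
        log_ratio = math.log(self.sigma_max / self.sigma_min)
        return 2.0 * log_ratio * self.sigma(t) ** 2


def sigma_of_t(schedule: NoiseSchedule, t):
    """Noise level at time ``t``: geometric interpolation between the bounds."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError(f"t must lie in [0, 1], got {t}")
    out = schedule.sigma_min ** (1.0 - t) * schedule.sigma_max**t
    return float(out) if out.ndim == 0 else out


def perturb(x0, t, schedule: NoiseSchedule, rng: np.random.Generator):
    """Draw ``x(t) ~ N(x0, sigma(t)^2 I)`` from the forward transition kernel."""
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    sig = np.asarray(sigma_of_t(schedule, t))
    if sig.ndim and x0.ndim > sig.ndim:
        sig = sig[..., None]
    return x0 + sig * rng.standard_normal(x0.shape)


def conditional_score(x_t, x0, t, schedule: NoiseSchedule):
    """Score of the transition kernel, ``grad_x log p_0t(x_t | x_0) = -(x_t - x0)/sigma(t)^2``."""
    x_t = np.asarray(x_t, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    sig = np.asarray(sigma_of_t(schedule, t))
    return -(x_t - x0) / (sig**2 if sig.ndim == 0 else sig[..., None] ** 2)


@dataclass(frozen=True)
class WeightFn:
    """Time-weighting profile for score-matching losses.

    kinds
    -----
    ``sigma_sq``
        lambda(t) = scale * sigma(t)^2 — the standard VE/likelihood weighting
        used for plain DSM pretraining; under the noise-prediction
        parametrization every noise level contributes equally.
    ``train_weight``
        lambda(t) = scale * (1 - t) * sigma(t)^2 — down-ramps the *effective*
        (variance-normalized) weight with t; used for the real-data half of a
        bootstrapping update so ground-truth complexes dominate the fine
        (small-t) denoising steps.
    ``buffer_weight``
        lambda'(t) = scale * t * sigma(t)^2 — the mirror ramp; buffer feedback
        dominates the coarse (large-t) steps where the pocket is chosen.
    ``constant``
        lambda(t) = scale.
    """

    kind: str = "sigma_sq"
    scale: float = 1.0

    _KINDS = ("sigma_sq", "train_weight", "buffer_weight", "constant")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")

    def __call__(self, t, schedule: NoiseSchedule):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return self.scale * np.ones_like(t)
        sig2 = np.asarray(sigma_of_t(schedule, t)) ** 2
        if self.kind == "sigma_sq":
            return self.scale * sig2
        if self.kind == "train_weight":
            return self.scale * (1.0 - t) * sig2
        return self.scale * t * sig2


# ---------------------------------------------------------------------------
# score models


class AnalyticGaussianScore:
    """Exact score of the VE-diffused Gaussian ``N(mu, sigma0^2 I)``.

    At time t the marginal is ``N(mu, (sigma0^2 + sigma(t)^2) I)``, so the
    score is ``-(x - mu) / (sigma0^2 + sigma(t)^2)``.  Used as an oracle to
    validate the reverse-SDE sampler independently of any training.
    """

    def __init__(self, mu, sigma0: float, schedule: NoiseSchedule):
        self.mu = np.atleast_1d(np.asarray(mu, dtype=float))
        self.sigma0 = float(sigma0)
        self.schedule = schedule
        self.dim = self.mu.shape[0]

    def score(self, x, t, d=None):
        sig2 = np.asarray(sigma_of_t(self.schedule, t)) ** 2
        var = self.sigma0**2 + sig2
        x = np.asarray(x, dtype=float)
        return -(x - self.mu) / (var if np.ndim(var) == 0 else var[..., None])


def _time_features(sig, schedule: NoiseSchedule):
    """Embed the noise level on a normalized log scale (plus a sin warp)."""
    lo, hi = math.log(schedule.sigma_min), math.log(schedule.sigma_max)
    u = (np.log(sig) - lo) / (hi - lo)
    return np.stack([u, np.sin(math.pi * u)], axis=-1)


class ScoreMLP:
    """Two-hidden-layer tanh network predicting the scaled noise.

    ``s_theta(x, t; d) = net([x, time_emb(t), d]) / sigma(t)``.  The network
    is deterministic given its parameters; initialization is seeded.
    """

    def __init__(
        self,
        dim: int,
        context_dim: int,
        hidden: int = 128,
        seed: int = 0,
    ):
        self.dim = int(dim)
        self.context_dim = int(context_dim)
        self.hidden = int(hidden)
        n_in = self.dim + 2 + self.context_dim
        rng = np.random.default_rng(seed)
        scale1 = 1.0 / math.sqrt(n_in)
        scale2 = 1.0 / math.sqrt(hidden)
        self.params = {
            "W1": rng.normal(0.0, scale1, size=(n_in, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0.0, scale2, size=(hidden, hidden)),
            "b2": np.zeros(hidden),
            "W3": np.zeros((hidden, self.dim)),  # zero-init: initial score is 0
            "b3": np.zeros(self.dim),
        }

    def copy(self) -> "ScoreMLP":
        out = ScoreMLP.__new__(ScoreMLP)
        out.dim, out.context_dim, out.hidden = self.dim, self.context_dim, self.hidden
        out.params = {k: v.copy() for k, v in self.params.items()}
        return out

    # -- forward ------------------------------------------------------------

    def _features(self, x, sig, d, schedule):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        sig = np.broadcast_to(np.asarray(sig, dtype=float), (n,))
        tf = _time_features(sig, schedule)
        if d is None:
            d = np.zeros((n, self.context_dim))
        d = np.broadcast_to(np.atleast_2d(np.asarray(d, dtype=float)), (n, self.context_dim))
        return np.concatenate([x, tf, d], axis=1)

    def _net(self, feats):
        p = self.params
        h1 = np.tanh(feats @ p["W1"] + p["b1"])
        h2 = np.tanh(h1 @ p["W2"] + p["b2"])
        out = h2 @ p["W3"] + p["b3"]
        return out, (feats, h1, h2)

    def score(self, x, t, d=None, schedule: NoiseSchedule | None = None):
        """Evaluate ``s_theta(x, t; d)``; accepts a single pose or a batch."""
        if schedule is None:
            schedule = self._default_schedule
        single = np.asarray(x).ndim == 1
        sig = np.asarray(sigma_of_t(schedule, t), dtype=float)
        feats = self._features(x, sig, d, schedule)
        out, _ = self._net(feats)
        s = out / (sig.reshape(-1, 1) if sig.ndim else float(sig))
        return s[0] if single else s

    # schedule is attached once by the trainer so that `score(x, t, d)`
    # matches the three-argument contract used by the sampler
    _default_schedule: NoiseSchedule = NoiseSchedule()

    def attach_schedule(self, schedule: NoiseSchedule) -> None:
        self._default_schedule = schedule

    # -- backward -----------------------------------------------------------

    def _backward(self, cache, dout):
        """Gradient of sum(dout * net_out) w.r.t. parameters."""
        feats, h1, h2 = cache
        p = self.params
        grads = {}
        grads["W3"] = h2.T @ dout
        grads["b3"] = dout.sum(axis=0)
        dh2 = (dout @ p["W3"].T) * (1.0 - h2**2)
        grads["W2"] = h1.T @ dh2
        grads["b2"] = dh2.sum(axis=0)
        dh1 = (dh2 @ p["W2"].T) * (1.0 - h1**2)
        grads["W1"] = feats.T @ dh1
        grads["b1"] = dh1.sum(axis=0)
        return grads


# ---------------------------------------------------------------------------
# DSM objective


def _dsm_terms(model, x0, d, schedule, weight, rng, time_alpha: float = 1.0):
    """Sample (t, noise) per item and return per-item weighted residuals.

    Returns (loss, grads).  Per item i the contribution is
    ``w(t_i) * || s(x_i(t_i), t_i; d_i) - (-eps_i / sigma_i) / sigma_i ||^2``
    computed in noise-prediction space: with s = net/sigma the residual is
    ``(net_i + eps_i)`` and the effective weight ``w(t_i)/sigma_i^2``.

    ``time_alpha`` reshapes the time-sampling density to ``t^(alpha-1)``
    (alpha = 1 is the default uniform draw; alpha > 1 concentrates training
    on the high-noise end).
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    n = x0.shape[0]
    t = rng.uniform(0.0, 1.0, size=n)
    if time_alpha != 1.0:
        t = t ** (1.0 / time_alpha)
    sig = sigma_of_t(schedule, t)
    eps = rng.standard_normal(x0.shape)
    x_t = x0 + sig[:, None] * eps
    w_eff = weight(t, schedule) / sig**2

    feats = model._features(x_t, sig, d, schedule)
    net, cache = model._net(feats)
    resid = net + eps  # net target is -eps... sign: score target -(x_t-x0)/sig^2 = -eps/sig
    per_item = w_eff * np.sum(resid**2, axis=1)
    loss = float(per_item.mean())
    dnet = (2.0 / n) * w_eff[:, None] * resid
    grads = model._backward(cache, dnet)
    return loss, grads


def dsm_loss(model, batch: Sequence, schedule: NoiseSchedule, weight: WeightFn, rng):
    """Monte-Carlo denoising score-matching loss on a batch of ``(x0, d)`` pairs.

    One uniform time draw and one kernel noise draw per item; the target is the
    conditional score of the forward kernel.
    """
    if len(batch) == 0:
        raise ValueError("dsm_loss: empty batch")
    x0 = np.stack([np.asarray(b[0], dtype=float) for b in batch])
    d = np.stack([np.asarray(b[1], dtype=float) for b in batch])
    if hasattr(model, "_net"):
        loss, _ = _dsm_terms(model, x0, d, schedule, weight, rng)
        return loss
    # generic model: evaluate the score function directly
    n = x0.shape[0]
    t = rng.uniform(0.0, 1.0, size=n)
    sig = sigma_of_t(schedule, t)
    eps = rng.standard_normal(x0.shape)
    x_t = x0 + sig[:, None] * eps
    target = -eps / sig[:, None]
    s = np.stack([model.score(x_t[i], t[i], d[i]) for i in range(n)])
    w = weight(t, schedule)
    return float(np.mean(w * np.sum((s - target) ** 2, axis=1)))


class Adam:
    """Adam optimizer over a dict of numpy parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.step_count = 0

    def step(self, params, grads):
        self.step_count += 1
        b1t = 1.0 - self.b1**self.step_count
        b2t = 1.0 - self.b2**self.step_count
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_score_model(
    model: ScoreMLP,
    data: Sequence,
    schedule: NoiseSchedule,
    weight: WeightFn | None = None,
    n_steps: int = 3000,
    batch_size: int = 64,
    lr: float = 1e-3,
    rng: np.random.Generator | None = None,
    optimizer: Adam | None = None,
    context_dropout: float = 0.0,
):
    """Plain DSM training loop over ``(x0, d)`` pairs; returns the model.

    ``context_dropout`` zeroes the context of a random fraction of each batch
    so the model also learns the unconditional pose distribution; on contexts
    far outside the training distribution the sampler then falls back to a
    broad multimodal spread instead of a confidently wrong point mass.
    """
    if weight is None:
        weight = WeightFn("sigma_sq")
    if rng is None:
        rng = np.random.default_rng(0)
    model.attach_schedule(schedule)
    x0 = np.stack([np.asarray(b[0], dtype=float) for b in data])
    d = np.stack([np.asarray(b[1], dtype=float) for b in data])
    opt = optimizer if optimizer is not None else Adam(model.params, lr=lr)
    n = x0.shape[0]
    for _ in range(n_steps):
        idx = rng.integers(0, n, size=min(batch_size, n))
        db = d[idx]
        if context_dropout > 0.0:
            db = db.copy()
            db[rng.uniform(size=len(idx)) < context_dropout] = 0.0
        _, grads = _dsm_terms(model, x0[idx], db, schedule, weight, rng)
        opt.step(model.params, grads)
    return model


# ---------------------------------------------------------------------------
# sampling


def reverse_sample(
    model,
    d,
    schedule: NoiseSchedule,
    n_steps: int = 20,
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
    dim: int | None = None,
):
    """Euler--Maruyama integration of the reverse SDE from t=1 to t=0.

    Starts from the VE prior ``N(0, sigma_max^2 I)``.  The final step is a
    pure denoising step (no noise injection).  With ``n_samples`` given, that
    many independent chains are run vectorized and an array of shape
    ``(n_samples, dim)`` is returned; otherwise a single pose vector.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    if dim is None:
        dim = model.dim
    single = n_samples is None
    m = 1 if single else int(n_samples)
    x = schedule.sigma_max * rng.standard_normal((m, dim))
    ts = np.linspace(1.0, 0.0, n_steps + 1)
    for k in range(n_steps):
        t, t_next = ts[k], ts[k + 1]
        s = np.atleast_2d(model.score(x, t, d))
        if not np.all(np.isfinite(s)):
            raise RuntimeError(
                f"reverse_sample: non-finite score at t={t:.4f} (context={d!r:.80})"
            )
        dt = t - t_next
        g2 = schedule.g_squared(t)
        x = x + g2 * dt * s
        if k < n_steps - 1:  # last step: deterministic denoise
            x = x + math.sqrt(g2 * dt) * rng.standard_normal(x.shape)
    return x[0] if single else x
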