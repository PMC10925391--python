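"""Confidence Bootstrapping: self-training a diffusion generator from a
frozen confidence model.

The loop runs K iterations.  Each iteration (i) *rolls out* the reverse
diffusion on the target complexes (their contexts only — never their poses),
(ii) scores every sampled pose with the confidence model, forming a buffer,
and (iii) performs a fixed number of SGD steps on a mixed score-matching
objective: half of each batch comes from the real training set weighted by
``lambda(t)`` (emphasis on small t, preserving fine denoising), half from the
buffer resampled with probability proportional to ``exp(c/temperature)`` and
weighted by ``lambda'(t)`` (emphasis on large t, steering the coarse pocket
choice).  Only the score-model weights move; the confidence model is frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import softmax

from .diffusion import (
    Adam,
    NoiseSchedule,
    ScoreMLP,
    WeightFn,
    _dsm_terms,
    reverse_sample,
)
from .toytask import TAU

__all__ = [
    "Buffer",
    "BootstrapConfig",
    "rollout",
    "buffer_sample",
    "update",
    "run_bootstrapping",
    "evaluate_model",
]


@dataclass
class Buffer:
    """Confidence-annotated rollout poses — the empirical self-training pool."""

    entries: list = field(default_factory=list)  # (x, d, c) triples
    capacity: int = 10_000

    def add(self, x, d, c: float) -> None:
        self.entries.append((np.asarray(x, float), np.asarray(d, float), float(c)))
        if len(self.entries) > self.capacity:
            del self.entries[0 : len(self.entries) - self.capacity]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def confidences(self) -> np.ndarray:
        return np.array([c for _, _, c in self.entries])


@dataclass
class BootstrapConfig:
    K: int = 30
    rollouts_per_complex: int = 8
    sgd_steps_per_iter: int = 50
    batch_size: int = 32
    buffer_policy: str = "reset"  # or "accumulate"
    temperature: float = 1.0
    lambda_train: WeightFn = field(default_factory=lambda: WeightFn("train_weight"))
    lambda_buffer: WeightFn = field(default_factory=lambda: WeightFn("buffer_weight"))
    inference_samples: int = 8
    n_sampler_steps: int = 20
    lr: float = 1e-3
    no_real_samples: bool = False  # ablation: buffer-only objective
    time_alpha: float = 1.0  # ablation: t ~ density prop. to t^(alpha-1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 0 or self.inference_samples < 1 or self.temperature <= 0:
            raise ValueError("invalid bootstrap configuration")
        if self.buffer_policy not in ("reset", "accumulate"):
            raise ValueError(f"unknown buffer_policy {self.buffer_policy!r}")


def rollout(
    model,
    complexes,
    conf,
    n_per: int,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    n_steps: int = 20,
    buffer: Buffer | None = None,
) -> Buffer:
    """Sample ``n_per`` poses per complex and score each with ``conf``.

    Only the context ``d`` of each complex is consumed by the sampler; the
    confidence model sees the pose and whatever its own contract allows.
    """
    if not complexes or n_per < 1:
        raise ValueError("rollout needs complexes and n_per >= 1")
    buf = buffer if buffer is not None else Buffer()
    for cplx in complexes:
        try:
            X = reverse_sample(model, cplx.d, schedule, n_steps=n_steps, rng=rng,
                               n_samples=n_per)
        except RuntimeError as err:
            raise RuntimeError(f"rollout failed on complex {cplx.complex_id}: {err}") from err
        cs = conf.score_batch(X, cplx)
        for x, c in zip(X, cs):
            buf.add(x, cplx.d, c)
    return buf


def buffer_sample(buffer: Buffer, m: int, temperature: float, rng: np.random.Generator):
    """Draw ``m`` entries with replacement, P(j) = softmax(c_j / temperature)."""
    if len(buffer) == 0:
        raise ValueError("cannot sample from an empty buffer")
    if m < 1:
        raise ValueError("m must be >= 1")
    p = softmax(buffer.confidences / temperature)
    idx = rng.choice(len(buffer), size=m, replace=True, p=p)
    return [(buffer.entries[j][0], buffer.entries[j][1]) for j in idx]


def update(
    model: ScoreMLP,
    train_set,
    buffer: Buffer,
    cfg: BootstrapConfig,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    optimizer: Adam | None = None,
) -> ScoreMLP:
    """One update stage: ``sgd_steps_per_iter`` mixed-objective Adam steps.

    Each batch is half real training pairs under ``lambda_train`` and half
    exp-weighted buffer draws under ``lambda_buffer``.  With
    ``no_real_samples`` the real half is replaced by further buffer draws.
    """
    if cfg.sgd_steps_per_iter < 1:
        raise ValueError("sgd_steps_per_iter must be >= 1")
    use_train = bool(train_set) and not cfg.no_real_samples
    if not use_train and len(buffer) == 0:
        raise ValueError("update has no data: empty train set and empty buffer")
    opt = optimizer if optimizer is not None else Adam(model.params, lr=cfg.lr)
    half = max(1, cfg.batch_size // 2)
    if use_train:
        tx = np.stack([np.asarray(x, float) for x, _ in train_set])
        td = np.stack([np.asarray(d, float) for _, d in train_set])
    for _ in range(cfg.sgd_steps_per_iter):
        grads = None
        if use_train:
            idx = rng.integers(0, len(train_set), size=half)
            _, g_tr = _dsm_terms(model, tx[idx], td[idx], schedule, cfg.lambda_train,
                                 rng, cfg.time_alpha)
            grads = g_tr
        if len(buffer) > 0 and (cfg.lambda_buffer.scale > 0 or not use_train):
            pairs = buffer_sample(buffer, half if use_train else 2 * half,
                                  cfg.temperature, rng)
            bx = np.stack([p[0] for p in pairs])
            bd = np.stack([p[1] for p in pairs])
            _, g_buf = _dsm_terms(model, bx, bd, schedule, cfg.lambda_buffer,
                                  rng, cfg.time_alpha)
            grads = g_buf if grads is None else {k: grads[k] + g_buf[k] for k in grads}
        opt.step(model.params, grads)
    return model


def evaluate_model(model, complexes, conf, schedule: NoiseSchedule,
                   inference_samples: int = 8, n_steps: int = 20,
                   rng: np.random.Generator | None = None):
    """Top-1 protocol: sample ``inference_samples`` poses per complex, rank by
    confidence, report success rate (top-1 distance < tau) and the median
    top-1 distance, with a per-cluster breakdown."""
    if rng is None:
        rng = np.random.default_rng(0)
    dists, succ, per_cluster = [], [], {}
    for cplx in complexes:
        X = reverse_sample(model, cplx.d, schedule, n_steps=n_steps, rng=rng,
                           n_samples=inference_samples)
        top1 = X[int(np.argmax(conf.score_batch(X, cplx)))]
        dist = float(np.linalg.norm(top1 - cplx.x_star))
        dists.append(dist)
        succ.append(dist < TAU)
        per_cluster.setdefault(cplx.cluster_id, []).append(dist)
    return {
        "success_rate": float(np.mean(succ)),
        "median_distance": float(np.median(dists)),
        "per_cluster": {
            cid: {"success_rate": float(np.mean(np.array(v) < TAU)),
                  "median_distance": float(np.median(v))}
            for cid, v in per_cluster.items()
        },
    }


def run_bootstrapping(model: ScoreMLP, conf, task, cfg: BootstrapConfig,
                      schedule: NoiseSchedule | None = None,
                      eval_conf=None):
    """Run K bootstrapping iterations; returns (fine-tuned model, history).

    ``task`` is ``(clusters, complexes)``; held-out complexes provide the
    target contexts D, training complexes the real half of the objective.
    History records per iteration the median buffer confidence and the
    held-out top-1 metrics.  Training and evaluation use independent RNG
    streams so that evaluation never perturbs the learning trajectory.
    ``eval_conf`` optionally overrides the confidence model used for top-1
    ranking (defaults to the bootstrapping confidence model).
    """
    if schedule is None:
        schedule = model._default_schedule
    clusters, complexes = task
    role = {c.cluster_id: c.role for c in clusters}
    train_cplx = [x for x in complexes if role[x.cluster_id] == "train"]
    heldout = [x for x in complexes if role[x.cluster_id] == "heldout"]
    if not heldout:
        raise ValueError("task has no held-out complexes to bootstrap on")
    ranker = eval_conf if eval_conf is not None else conf

    model = model.copy()
    model.attach_schedule(schedule)
    train_set = [(x.x_star, x.d) for x in train_cplx]
    ss = np.random.SeedSequence(cfg.seed)
    train_seed, eval_seed = ss.spawn(2)
    train_rng = np.random.default_rng(train_seed)
    eval_rngs = [np.random.default_rng(s) for s in eval_seed.spawn(cfg.K + 1)]

    history = []
    baseline = evaluate_model(model, heldout, ranker, schedule,
                              cfg.inference_samples, cfg.n_sampler_steps, eval_rngs[0])
    opt = Adam(model.params, lr=cfg.lr)
    buffer = Buffer()
    for i in range(cfg.K):
        if cfg.buffer_policy == "reset":
            buffer = Buffer()
        try:
            buffer = rollout(model, heldout, conf, cfg.rollouts_per_complex,
                             schedule, train_rng, cfg.n_sampler_steps, buffer)
            model = update(model, train_set, buffer, cfg, schedule, train_rng, opt)
        except (ValueError, RuntimeError) as err:
            raise RuntimeError(f"bootstrapping failed at iteration {i}: {err}") from err
        metrics = evaluate_model(model, heldout, ranker, schedule,
                                 cfg.inference_samples, cfg.n_sampler_steps,
                                 eval_rngs[i + 1])
        history.append({
            "iteration": i,
            "median_confidence": float(np.median(buffer.confidences)),
            **{k: v for k, v in metrics.items() if k != "per_cluster"},
            "per_cluster": metrics["per_cluster"],
        })
    return model, {"baseline": baseline, "iterations": history}
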