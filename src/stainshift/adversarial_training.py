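"""Domain-adversarial training of two-head patch classifiers.

A shared convolutional trunk feeds two heads: a task head (e.g. mitotic /
non-mitotic) and a domain head that tries to recover the source center.  A
gradient reversal layer sits between the trunk and the domain head, so one
SGD step realizes the saddle-point updates

    theta_f <- theta_f - mu * (dL_y/dtheta_f - lambda * dL_d/dtheta_f)
    theta_y <- theta_y - mu * dL_y/dtheta_y
    theta_d <- theta_d - mu * lambda * dL_d/dtheta_d

i.e. the trunk descends the task loss while ascending the domain loss: if
training converges the features support the task but carry no usable
center signature.  With ``lambda = 0`` (also the warmup regime of the
first ``warmup_iters`` batches) the trunk + task head trajectory is
exactly that of the plain single-head baseline at the same seed.

The module also trains all non-adversarial baselines, provides the
domain-balanced batch stream the adversarial update needs, and the
hard-negative mining bootstrap used to build a challenging negative set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import augmentation as aug
from .nn import (
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    GradientReversal,
    MaxPool2,
    ReLU,
    Sequential,
    sgd_update,
    softmax,
    softmax_cross_entropy,
)
from .synthetic_cohort import PatchRecord

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "LossTerms",
    "TwoHeadNetwork",
    "build_model",
    "dann_step",
    "balanced_batches",
    "augment_minority_class",
    "records_to_arrays",
    "DannClassifier",
    "FitResult",
    "mine_hard_negatives",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Compact two-head convnet layout.

    The trunk is two convolutional layers, two blocks of
    convolution + batch normalization + max-pooling, dropout, and a final
    conv + batchnorm + pool block; the first convolution uses ``first_stride``
    to keep the desk-scale compute small.  Heads are dense branches on the
    flattened trunk output; ``feature_dim`` is the width of the task
    branch's first dense layer (the embedding layer, 128 by default).  The
    domain branch always attaches *after* the shared convolutional trunk —
    color-sensitive units concentrate in early conv layers, so that is
    where the reversed gradient must reach.  An empty ``conv_channels``
    collapses the trunk to a flatten, giving the small dense models used in
    gradient-correctness checks.
    """

    input_size: tuple[int, int, int] = (64, 64, 3)
    conv_channels: tuple[int, ...] = (8, 8, 16, 16, 32)
    first_stride: int = 2
    feature_dim: int = 128
    domain_hidden: int = 64
    dropout_rate: float = 0.25
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.conv_channels and len(self.conv_channels) != 5:
            raise ValueError("conv_channels must name 5 layers (or be empty)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    mu: base SGD learning rate (0.01, the compact-model value).
    lam: domain multiplier lambda after warmup; 0 disables the adversarial
        signal entirely.
    warmup_iters: batches with lambda forced to 0 before the adversarial
        update starts (stabilizes early training).
    batch_size: must be divisible by the number of domains so batches can
        be exactly domain-balanced.
    iterations: total SGD steps.
    momentum: optional classical momentum; 0 gives the plain SGD updates.
    balance_minority: oversample the positive class with rotated/flipped
        copies before training (counters class imbalance).
    eval_every: validation-F1 early-stopping cadence in iterations
        (0 disables; requires validation records).
    """

    mu: float = 0.01
    lam: float = 1.0
    warmup_iters: int = 100
    batch_size: int = 30
    iterations: int = 300
    momentum: float = 0.0
    balance_minority: bool = True
    eval_every: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.lam < 0 or self.warmup_iters < 0:
            raise ValueError("lam and warmup_iters must be non-negative")


@dataclass(frozen=True)
class LossTerms:
    """One iteration's objective pieces: L = L_y - lam * L_d over the
    N = n + n_prime samples (n task-labeled, n_prime domain-only)."""

    loss_task: float
    loss_domain: float
    lam: float
    n: int
    n_prime: int = 0

    @property
    def total(self) -> float:
        ld = 0.0 if np.isnan(self.loss_domain) else self.loss_domain
        return self.loss_task - self.lam * ld


class TwoHeadNetwork:
    """Shared trunk + task head (+ optional domain head behind a gradient
    reversal layer).  The trunk parameters are literally shared: both heads
    backpropagate into the same arrays."""

    def __init__(
        self,
        trunk: Sequential,
        task_head: Sequential,
        domain_head: Sequential | None,
        grl: GradientReversal | None,
    ) -> None:
        self.trunk = trunk
        self.task_head = task_head
        self.domain_head = domain_head
        self.grl = grl

    @property
    def adversarial(self) -> bool:
        return self.domain_head is not None

    def features(self, x: np.ndarray) -> np.ndarray:
        """Flattened trunk output (inference mode)."""
        return self.trunk.forward(x, train=False)

    def task_features(self, x: np.ndarray) -> np.ndarray:
        """Activations of the task branch's first dense layer (the
        ``feature_dim``-wide embedding)."""
        f = self.features(x)
        f = self.task_head.layers[0].forward(f)
        return self.task_head.layers[1].forward(f)  # ReLU

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Task-class probabilities; never looks at domain labels."""
        out = []
        for i in range(0, x.shape[0], batch):
            logits = self.task_head.forward(self.features(x[i : i + batch]))
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def predict_domain_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        if self.domain_head is None:
            raise ValueError("model has no domain head")
        out = []
        for i in range(0, x.shape[0], batch):
            logits = self.domain_head.forward(self.features(x[i : i + batch]))
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def state(self) -> list[np.ndarray]:
        arrays = self.trunk.state() + self.task_head.state()
        if self.domain_head is not None:
            arrays += self.domain_head.state()
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        n_t = len(self.trunk.state())
        n_y = len(self.task_head.state())
        self.trunk.load_state(arrays[:n_t])
        self.task_head.load_state(arrays[n_t : n_t + n_y])
        if self.domain_head is not None:
            self.domain_head.load_state(arrays[n_t + n_y :])


def build_model(
    spec: ArchitectureSpec,
    n_domains: int,
    adversarial: bool,
    init_rng: np.random.Generator,
    domain_init_rng: np.random.Generator | None = None,
    dropout_rng: np.random.Generator | None = None,
) -> TwoHeadNetwork:
    """Construct the two-head network.

    Trunk and task head draw their initial weights from ``init_rng``; the
    domain head (when present) draws from ``domain_init_rng``.  Keeping the
    streams separate makes a baseline and an adversarial model with the
    same seed start from identical shared parameters, which is what allows
    the lambda = 0 equivalence check.
    """
    if adversarial and n_domains < 2:
        raise ValueError("adversarial training needs at least 2 domains")
    h, w, c = spec.input_size
    dropout_rng = dropout_rng if dropout_rng is not None else np.random.default_rng(0)

    layers: list = []
    if spec.conv_channels:
        ch = spec.conv_channels
        layers += [Conv2D(c, ch[0], init_rng, stride=spec.first_stride), ReLU()]
        layers += [Conv2D(ch[0], ch[1], init_rng), ReLU()]
        for cin, cout in ((ch[1], ch[2]), (ch[2], ch[3])):
            layers += [Conv2D(cin, cout, init_rng), BatchNorm(cout), ReLU(), MaxPool2()]
        layers += [Dropout(spec.dropout_rate, dropout_rng)]
        layers += [Conv2D(ch[3], ch[4], init_rng), BatchNorm(ch[4]), ReLU(), MaxPool2()]
    layers += [Flatten()]
    trunk = Sequential(layers)
    flat_dim = trunk.forward(np.zeros((1, h, w, c))).shape[1]

    task_head = Sequential(
        [
            Dense(flat_dim, spec.feature_dim, init_rng),
            ReLU(),
            Dense(spec.feature_dim, spec.n_classes, init_rng),
        ]
    )
    domain_head, grl = None, None
    if adversarial:
        if domain_init_rng is None:
            raise ValueError("domain_init_rng required for an adversarial model")
        grl = GradientReversal(lam=1.0)
        domain_head = Sequential(
            [
                grl,
                Dense(flat_dim, spec.domain_hidden, domain_init_rng),
                ReLU(),
                Dense(spec.domain_hidden, n_domains, domain_init_rng),
            ]
        )
    return TwoHeadNetwork(trunk, task_head, domain_head, grl)


def dann_step(
    model: TwoHeadNetwork,
    x: np.ndarray,
    y: np.ndarray,
    d: np.ndarray | None,
    mu: float,
    lam: float,
    task_mask: np.ndarray | None = None,
    velocity: dict | None = None,
    momentum: float = 0.0,
) -> LossTerms:
    """One stochastic saddle-point update on a batch.

    ``d`` are one-hot domain rows (or integer indices); ``task_mask``
    optionally marks the samples whose task label is usable (domain-only
    samples contribute to the domain loss alone).  The trunk receives
    ``dL_y/dtheta_f - lam * dL_d/dtheta_f`` through the reversal layer, the
    task head trains at rate ``mu`` and the domain head at ``mu * lam``.
    """
    f = model.trunk.forward(x, train=True)
    task_logits = model.task_head.forward(f, train=True)
    if task_mask is not None and not task_mask.all():
        loss_y, dly = softmax_cross_entropy(task_logits[task_mask], y[task_mask])
        dlogits_y = np.zeros_like(task_logits)
        dlogits_y[task_mask] = dly
        n = int(task_mask.sum())
    else:
        loss_y, dlogits_y = softmax_cross_entropy(task_logits, y)
        n = x.shape[0]
    grad_f = model.task_head.backward(dlogits_y)

    loss_d = float("nan")
    if model.adversarial:
        model.grl.lam = lam
        dom_logits = model.domain_head.forward(f, train=True)
        loss_d, dlogits_d = softmax_cross_entropy(dom_logits, d)
        grad_f = grad_f + model.domain_head.backward(dlogits_d)
    model.trunk.backward(grad_f)

    nets_lrs = [(model.trunk, mu), (model.task_head, mu)]
    if model.adversarial:
        nets_lrs.append((model.domain_head, mu * lam))
    for net, lr in nets_lrs:
        if momentum > 0.0 and velocity is not None:
            for layer, name in net.parameters():
                key = (id(layer), name)
                v = velocity.get(key)
                g = layer.grads[name]
                v = momentum * v - lr * g if v is not None else -lr * g
                velocity[key] = v
                layer.params[name] += v
        else:
            sgd_update(net, lr)
    losses = LossTerms(loss_task=loss_y, loss_domain=loss_d, lam=lam, n=n,
                       n_prime=x.shape[0] - n)
    if not np.isfinite(losses.loss_task) or (
        model.adversarial and not np.isfinite(losses.loss_domain)
    ):
        raise RuntimeError(
            f"training diverged: task loss {losses.loss_task}, "
            f"domain loss {losses.loss_domain}"
        )
    return losses


def balanced_batches(
    domain_indices: np.ndarray,
    batch_size: int,
    n_domains: int,
    rng: np.random.Generator,
):
    """Infinite stream of index batches with exactly ``batch_size /
    n_domains`` samples per domain.

    Each domain's pool is shuffled and cycled independently, so minority
    domains repeat (sampling with reuse) while every sample is eventually
    visited.  Also yields the matching one-hot domain matrix.
    """
    if batch_size % n_domains != 0:
        raise ValueError(
            f"batch_size {batch_size} not divisible by {n_domains} domains"
        )
    per = batch_size // n_domains
    pools = []
    for k in range(n_domains):
        idx = np.nonzero(domain_indices == k)[0]
        if idx.size == 0:
            raise ValueError(f"domain {k} has no records")
        pools.append(idx)
    cursors = [np.array([], dtype=int)] * n_domains
    while True:
        batch = []
        for k in range(n_domains):
            while cursors[k].size < per:
                fresh = pools[k].copy()
                rng.shuffle(fresh)
                cursors[k] = np.concatenate([cursors[k], fresh])
            batch.append(cursors[k][:per])
            cursors[k] = cursors[k][per:]
        idx = np.concatenate(batch)
        onehot = np.zeros((batch_size, n_domains))
        onehot[np.arange(batch_size), np.repeat(np.arange(n_domains), per)] = 1.0
        yield idx, onehot


_DIHEDRAL = [
    lambda a: np.rot90(a, 1),
    lambda a: np.rot90(a, 2),
    lambda a: np.rot90(a, 3),
    lambda a: a[::-1],
    lambda a: a[:, ::-1],
    lambda a: np.rot90(a[::-1], 1),
    lambda a: np.rot90(a[:, ::-1], 1),
]


def augment_minority_class(records: list[PatchRecord]) -> list[PatchRecord]:
    """Oversample the positive class with rotated and flipped copies until
    its count is as close as possible to the negative count (without
    exceeding the 8 dihedral variants per patch)."""
    positives = [r for r in records if r.task_label == 1]
    negatives = [r for r in records if r.task_label == 0]
    if not positives or len(positives) >= len(negatives):
        return list(records)
    out = list(records)
    deficit = len(negatives) - len(positives)
    per_patch = min(7, int(np.ceil(deficit / len(positives))))
    added = 0
    for rec in positives:
        for t in range(per_patch):
            if added >= deficit:
                break
            img = np.ascontiguousarray(_DIHEDRAL[t](np.asarray(rec.image)))
            out.append(
                PatchRecord(
                    image=img,
                    x=rec.x,
                    y=rec.y,
                    task_label=1,
                    domain_label=rec.domain_label,
                    partition=rec.partition,
                )
            )
            added += 1
    return out


def records_to_arrays(
    records: list[PatchRecord], domains: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Stack records into (X, y, domain_index, domain_names); pixels are
    mapped to floats in [-0.5, 0.5].  Domains not in ``domains`` (e.g.
    external centers at prediction time) get index -1."""
    if domains is None:
        domains = sorted({r.domain_label for r in records})
    lookup = {name: k for k, name in enumerate(domains)}
    x = np.stack([np.asarray(r.image, dtype=float) for r in records]) / 255.0 - 0.5
    y = np.array([r.task_label for r in records], dtype=int)
    d = np.array([lookup.get(r.domain_label, -1) for r in records], dtype=int)
    return x, y, d, domains


class FitResult:
    """Outcome of a training run: the fitted network, per-iteration loss
    history, and prediction / feature-extraction entry points."""

    def __init__(
        self,
        model: TwoHeadNetwork,
        history: pd.DataFrame,
        config: TrainConfig,
        arch: ArchitectureSpec,
        domains: list[str],
        best_val_f1: float | None = None,
    ) -> None:
        self.model = model
        self.history = history
        self.config = config
        self.arch = arch
        self.domains = domains
        self.best_val_f1 = best_val_f1

    def _to_x(self, data) -> np.ndarray:
        if isinstance(data, np.ndarray) and data.ndim == 4:
            return data
        return records_to_arrays(list(data), self.domains)[0]

    def predict_proba(self, data) -> np.ndarray:
        """Positive-class probability per record; domain labels unused."""
        return self.model.predict_proba(self._to_x(data))[:, 1]

    def predict_domain_proba(self, data) -> np.ndarray:
        return self.model.predict_domain_proba(self._to_x(data))

    def task_features(self, data) -> np.ndarray:
        """Embedding-layer activations (task branch first dense layer)."""
        x = self._to_x(data)
        out = []
        for i in range(0, x.shape[0], 256):
            out.append(self.model.task_features(x[i : i + 256]))
        return np.concatenate(out, axis=0)

    @property
    def n_parameters(self) -> int:
        n = self.model.trunk.n_parameters() + self.model.task_head.n_parameters()
        if self.model.domain_head is not None:
            n += self.model.domain_head.n_parameters()
        return n

    def summary(self) -> str:
        h = self.history
        lines = [
            "Two-head patch classifier fit",
            "=" * 34,
            f"adversarial:        {self.model.adversarial}",
            f"domains:            {len(self.domains)} ({', '.join(self.domains)})",
            f"parameters:         {self.n_parameters}",
            f"iterations:         {len(h)}",
            f"mu / lambda:        {self.config.mu} / {self.config.lam}",
            f"warmup iterations:  {self.config.warmup_iters}",
            f"final task loss:    {h['loss_task'].iloc[-1]:.4f}",
        ]
        if self.model.adversarial:
            lines.append(f"final domain loss:  {h['loss_domain'].iloc[-1]:.4f}")
        if self.best_val_f1 is not None:
            lines.append(f"best validation F1: {self.best_val_f1:.4f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Persist parameters (npz) plus a JSON sidecar with the resolved
        config, seed and lambda schedule, and the training log as CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        state = self.model.state()
        np.savez(out / "params.npz", **{f"arr_{i}": a for i, a in enumerate(state)})
        sidecar = {
            "config": {k: getattr(self.config, k) for k in (
                "mu", "lam", "warmup_iters", "batch_size", "iterations",
                "momentum", "balance_minority", "eval_every", "seed")},
            "adversarial": self.model.adversarial,
            "domains": self.domains,
            "lam_schedule": self.history["lam"].tolist(),
        }
        (out / "model.json").write_text(json.dumps(sidecar, indent=2))
        self.history.to_csv(out / "training_log.csv", index=False)


class DannClassifier:
    """Model object for the strategy grid: built from labeled patch
    records, fitted with :meth:`fit`.

    Parameters
    ----------
    records : training patches (task + domain labels).
    config : TrainConfig.
    arch : ArchitectureSpec, defaults to the compact layout.
    adversarial : attach the gradient-reversal domain head.
    augmentation : optional AugmentationConfig applied online at training
        time (fresh parameters per presentation).
    validation_records : optional held-out patches for early stopping on
        task F1 (enabled by ``config.eval_every``).
    """

    def __init__(
        self,
        records: list[PatchRecord],
        config: TrainConfig = TrainConfig(),
        arch: ArchitectureSpec = ArchitectureSpec(),
        adversarial: bool = True,
        augmentation: aug.AugmentationConfig | None = None,
        validation_records: list[PatchRecord] | None = None,
    ) -> None:
        self.records = list(records)
        self.config = config
        self.arch = arch
        self.adversarial = adversarial
        self.augmentation = augmentation
        self.validation_records = validation_records

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, partition: str = "train",
                      **kwargs) -> "DannClassifier":
        from .synthetic_cohort import load_cohort

        records = [r for r in load_cohort(manifest_path) if r.partition == partition]
        return cls(records, **kwargs)

    def fit(self) -> FitResult:
        cfg = self.config
        streams = np.random.SeedSequence(cfg.seed).spawn(5)
        rng_init = np.random.default_rng(streams[0])
        rng_domain = np.random.default_rng(streams[1])
        rng_batch = np.random.default_rng(streams[2])
        rng_dropout = np.random.default_rng(streams[3])
        rng_augment = np.random.default_rng(streams[4])

        records = (
            augment_minority_class(self.records)
            if cfg.balance_minority
            else self.records
        )
        x, y, d_idx, domains = records_to_arrays(records)
        n_domains = len(domains)
        model = build_model(
            self.arch,
            n_domains,
            self.adversarial,
            init_rng=rng_init,
            domain_init_rng=rng_domain if self.adversarial else None,
            dropout_rng=rng_dropout,
        )
        batches = balanced_batches(d_idx, cfg.batch_size, n_domains, rng_batch)
        velocity: dict = {}
        rows = []
        best_state, best_f1 = None, -1.0
        val = self.validation_records
        val_x = val_y = None
        if val is not None and cfg.eval_every > 0:
            val_x, val_y, _, _ = records_to_arrays(val, domains=domains)

        for it in range(cfg.iterations):
            lam_t = 0.0 if it < cfg.warmup_iters else cfg.lam
            idx, onehot = next(batches)
            xb = x[idx]
            if self.augmentation is not None:
                xb = self._augment_batch(xb, rng_augment)
            losses = dann_step(
                model, xb, y[idx], onehot, cfg.mu, lam_t,
                velocity=velocity, momentum=cfg.momentum,
            )
            rows.append(
                {
                    "iteration": it,
                    "loss_task": losses.loss_task,
                    "loss_domain": losses.loss_domain,
                    "lam": lam_t,
                    "loss_total": losses.total,
                }
            )
            if val_x is not None and (it + 1) % cfg.eval_every == 0:
                f1 = _f1_at_half(model, val_x, val_y)
                if f1 > best_f1:
                    best_f1, best_state = f1, model.state()
        if best_state is not None:
            model.load_state(best_state)
        history = pd.DataFrame(rows)
        return FitResult(
            model, history, cfg, self.arch, domains,
            best_val_f1=None if best_state is None else best_f1,
        )

    def _augment_batch(self, xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        cfg = self.augmentation
        imgs = np.clip(np.rint((xb + 0.5) * 255.0), 0, 255).astype(np.uint8)
        if cfg.per_image:
            out = [aug.apply(im, aug.sample_params(cfg, rng)) for im in imgs]
        else:
            params = aug.sample_params(cfg, rng)
            out = [aug.apply(im, params) for im in imgs]
        return np.stack(out).astype(float) / 255.0 - 0.5


def _f1_at_half(model: TwoHeadNetwork, x: np.ndarray, y: np.ndarray) -> float:
    pred = (model.predict_proba(x)[:, 1] >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def mine_hard_negatives(
    positives: list[PatchRecord],
    candidate_negatives: list[PatchRecord],
    config: TrainConfig = TrainConfig(iterations=200, warmup_iters=0),
    arch: ArchitectureSpec = ArchitectureSpec(),
    threshold: float = 0.5,
    fallback_k: int | None = None,
) -> tuple[list[PatchRecord], np.ndarray]:
    """Bootstrap a challenging negative set.

    A task-only model is trained on the positives against an equally sized
    random subset of the candidates, every candidate is scored, and those
    with predicted positive probability above ``threshold`` are returned.
    Candidates must not overlap positive windows (caller's contract).  The
    mined set should be persisted and reused unchanged across strategy
    combinations.  If nothing clears the threshold the top-``fallback_k``
    scorers are returned under a warning.

    Returns the mined records and the per-candidate scores.
    """
    rng = np.random.default_rng(config.seed + 17)
    n_neg = min(len(candidate_negatives), max(len(positives), 1))
    sub = [candidate_negatives[i] for i in rng.choice(
        len(candidate_negatives), size=n_neg, replace=False)]
    train_records = [
        PatchRecord(r.image, r.x, r.y, 1, r.domain_label, "train") for r in positives
    ] + [
        PatchRecord(r.image, r.x, r.y, 0, r.domain_label, "train") for r in sub
    ]
    clf = DannClassifier(train_records, config=config, arch=arch, adversarial=False)
    result = clf.fit()
    scores = result.predict_proba(candidate_negatives)
    mask = scores > threshold
    if not mask.any():
        k = fallback_k if fallback_k is not None else max(len(positives) // 2, 1)
        k = min(k, len(candidate_negatives))
        warnings.warn(
            f"no candidate scored above {threshold}; falling back to top {k}"
        )
        top = np.argsort(scores)[::-1][:k]
        mask = np.zeros(len(scores), dtype=bool)
        mask[top] = True
    mined = [r for r, m in zip(candidate_negatives, mask) if m]
    return mined, scores
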