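"""Loss terms, reinforcement reward, and the joint training loop.

The three models are trained together from a single scalar objective.
Writing ``L_baseline = L_fcl + L_hsic`` (baseline head cross-entropy plus
the HSIC independence penalty) and ``L_prediction`` for the Critic's
cross-entropy, the pieces are

    R        = -(L_prediction - L_baseline)          (reward, detached)
    L_critic = L_baseline + L_prediction
    L_actor  = R * L_fs - lambda * mean(S_d)
    L_total  = L_actor + L_critic

where ``L_fs`` is the cross-entropy between the Actor's selection
probabilities and the Bernoulli mask actually sampled — i.e. the negative
log-likelihood of the sampled action, so ``R * L_fs`` is a REINFORCE
score-function objective: masks that let the Critic beat the baseline
(R > 0) have their log-probability increased. The reward is treated as a
constant (no gradient), keeping Actor and Critic updates separate; the
``-lambda * mean(S_d)`` term nudges selection probabilities upward and is
the knob trading sparsity against coverage.

Every step's loss bookkeeping is materialised as a :class:`LossBundle`,
whose constructor verifies all the defining identities to 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .autodiff import Adam, SGD, Tensor
from .cohort import CohortTable, TemporalSignals
from .hsic import hsic_loss
from .networks import ModelBundle, apply_mask, sample_mask
from .stat_features import FeatureScaler, build_feature_vector, compute_stat_features

_CLIP = 1e-12
_IDENTITY_TOL = 1e-9


def cross_entropy(p, y, *, pos_weight: float = 1.0):
    """Mean binary cross-entropy; probabilities clipped at 1e-12.

    Accepts a Tensor (differentiable) or an array. ``pos_weight`` rescales
    the positive-class term for imbalance-aware training.
    """
    t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=float))
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {y.shape}")
    pc = t.clip(_CLIP, 1.0 - _CLIP)
    w = np.where(y == 1, pos_weight, 1.0)
    terms = Tensor(y * w) * pc.log() + Tensor((1.0 - y) * w) * (1.0 - pc).log()
    return -terms.sum() * (1.0 / (w.sum() if pos_weight != 1.0 else y.size))


def cross_entropy_with_logits(z: Tensor, y, *, pos_weight: float = 1.0):
    """Mean binary cross-entropy computed from logits.

    Numerically stable for arbitrarily large logits (log1p form) and, unlike
    a clipped-probability formulation, keeps a nonzero gradient
    ``sigmoid(z) - y`` everywhere, so confidently wrong predictions can
    still recover. Agrees with :func:`cross_entropy` on the sigmoid of the
    logits up to the clipping threshold.
    """
    y = np.asarray(y, dtype=float)
    if z.shape != y.shape:
        raise ValueError(f"length mismatch: {z.shape} vs {y.shape}")
    zd = z.data
    w = np.where(y == 1, pos_weight, 1.0)
    denom = w.sum() if pos_weight != 1.0 else y.size
    per = np.maximum(zd, 0.0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    out = Tensor((w * per).sum() / denom, requires_grad=z.requires_grad,
                 parents=(z,))

    def bwd(g):
        if z.requires_grad:
            z._accum(g * w * (expit(zd) - y) / denom)
    out._backward = bwd
    return out


def selection_loss(S_d, M):
    """Cross-entropy between selection probabilities and the sampled mask.

    This is the negative log-likelihood of the sampled mask under the
    Actor's Bernoulli policy, averaged over instances and features.
    """
    s = S_d if isinstance(S_d, Tensor) else Tensor(np.asarray(S_d, dtype=float))
    M = np.asarray(M, dtype=float)
    if s.shape != M.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {M.shape}")
    sc = s.clip(_CLIP, 1.0 - _CLIP)
    terms = Tensor(M) * sc.log() + Tensor(1.0 - M) * (1.0 - sc).log()
    return -terms.mean()


def selection_loss_with_logits(z: Tensor, M) -> Tensor:
    """Mask negative log-likelihood computed from Actor logits.

    Same value as :func:`selection_loss` on ``sigmoid(z)`` but with the
    always-alive gradient ``(sigmoid(z) - M) / size``: even a saturated
    selector keeps receiving the reinforcement signal, which is what lets
    selection probabilities come back down once the reward turns against an
    over-selecting policy.
    """
    M = np.asarray(M, dtype=float)
    if z.shape != M.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {M.shape}")
    zd = z.data
    per = np.maximum(zd, 0.0) - zd * M + np.log1p(np.exp(-np.abs(zd)))
    out = Tensor(per.mean(), requires_grad=z.requires_grad, parents=(z,))

    def bwd(g):
        if z.requires_grad:
            z._accum(g * (expit(zd) - M) / M.size)
    out._backward = bwd
    return out


def compute_reward(L_prediction: float, L_baseline: float) -> float:
    """R = -(L_prediction - L_baseline); positive when the Critic wins."""
    return -(float(L_prediction) - float(L_baseline))


@dataclass
class LossBundle:
    """All loss terms of one step; the defining identities are asserted."""

    L_fcl: float
    L_hsic: float
    L_prediction: float
    L_fs: float
    lam: float
    S_d_mean: float
    R: float = field(init=False)
    L_baseline: float = field(init=False)
    L_actor: float = field(init=False)
    L_critic: float = field(init=False)
    L_total: float = field(init=False)

    def __post_init__(self) -> None:
        parts = (self.L_fcl, self.L_hsic, self.L_prediction, self.L_fs,
                 self.lam, self.S_d_mean)
        if not all(np.isfinite(parts)):
            raise FloatingPointError(f"non-finite loss part in {parts}")
        self.L_baseline = self.L_fcl + self.L_hsic
        self.R = compute_reward(self.L_prediction, self.L_baseline)
        self.L_actor = self.R * self.L_fs - self.lam * self.S_d_mean
        self.L_critic = self.L_baseline + self.L_prediction
        self.L_total = self.L_actor + self.L_critic
        self._check()

    def _check(self) -> None:
        t = _IDENTITY_TOL
        assert abs(self.L_baseline - (self.L_fcl + self.L_hsic)) <= t
        assert abs(self.R + (self.L_prediction - self.L_baseline)) <= t
        assert abs(self.L_critic - (self.L_baseline + self.L_prediction)) <= t
        assert abs(self.L_actor - (self.R * self.L_fs
                                   - self.lam * self.S_d_mean)) <= t
        assert abs(self.L_total - (self.L_actor + self.L_critic)) <= t
        expanded = (-(self.L_prediction - self.L_fcl - self.L_hsic) * self.L_fs
                    - self.lam * self.S_d_mean
                    + self.L_fcl + self.L_hsic + self.L_prediction)
        assert abs(self.L_total - expanded) <= t

    def to_dict(self) -> dict:
        return asdict(self)


def assemble_losses(L_fcl: float, L_hsic: float, L_prediction: float,
                    L_fs: float, lam: float, S_d_mean: float) -> LossBundle:
    """Build and verify the full loss bookkeeping for one step."""
    return LossBundle(float(L_fcl), float(L_hsic), float(L_prediction),
                      float(L_fs), float(lam), float(S_d_mean))


@dataclass
class TrainConfig:
    """Training protocol: 100 epochs, Adam at 0.01, exponential decay
    (x0.95 per epoch) from epoch 50, batches of 32."""

    epochs: int = 100
    lr: float = 0.01
    lr_decay: float = 0.95
    decay_start: int = 50
    batch_size: int = 32
    lam: float = 0.1
    seed: int = 0
    stratified_batches: bool = False
    class_weight: bool = False
    reward_sign: float = 1.0
    pretrain_baseline: int = 0
    optimizer: str = "adam"
    max_grad_norm: float | None = 5.0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (HSIC needs pairs)")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def _clip_grads(params, max_norm: float | None) -> None:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    if max_norm is None:
        return
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad * p.grad))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                if p._grad_borrowed:      # borrowed buffers must not mutate
                    p.grad = p.grad * scale
                    p._grad_borrowed = False
                else:
                    p.grad *= scale


def _batches(n: int, batch_size: int, rng: np.random.Generator,
             y: np.ndarray | None = None, stratified: bool = False):
    """Shuffled batch index lists; a trailing singleton is dropped."""
    if stratified and y is not None and 0 < y.sum() < n:
        pos = rng.permutation(np.flatnonzero(y == 1))
        neg = rng.permutation(np.flatnonzero(y == 0))
        n_batches = max(1, n // batch_size)
        order = np.empty(0, dtype=int)
        # deal positives round-robin so most batches see both classes
        chunks = [[] for _ in range(n_batches)]
        for i, p in enumerate(pos):
            chunks[i % n_batches].append(p)
        ni = 0
        per_batch = batch_size
        for b in range(n_batches):
            room = per_batch - len(chunks[b])
            chunks[b].extend(neg[ni:ni + room])
            ni += room
        if ni < len(neg):
            chunks[-1].extend(neg[ni:])
        idx_lists = [np.array(c) for c in chunks if len(c) >= 2]
        return idx_lists
    perm = rng.permutation(n)
    lists = [perm[i:i + batch_size] for i in range(0, n, batch_size)]
    return [b for b in lists if len(b) >= 2]


def train(bundle: ModelBundle, cohort: CohortTable, signals: TemporalSignals,
          cfg: TrainConfig) -> tuple[ModelBundle, dict]:
    """Joint Actor-Critic-baseline training.

    Fits the feature scaler on the given (training) cohort, then per batch:
    Actor probabilities, Bernoulli mask, Critic prediction on the masked
    features, TCN embedding and baseline prediction on the full inputs, all
    loss terms, one optimizer step on ``L_total`` with the reward detached.

    Returns the trained bundle (scaler attached) and a history dict with
    per-epoch summaries and the per-step loss bundles.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    stats = compute_stat_features(signals)
    scaler = FeatureScaler().fit(
        np.concatenate([cohort.X_s, stats.X_m], axis=1))
    fv = build_feature_vector(cohort, stats, scaler)
    # the TCN also needs standardized inputs: raw vitals live on scales of
    # 10-100 units, which would blow up the early conv activations
    sig_mean = signals.X_v.mean(axis=(0, 2), keepdims=True)
    sig_sd = signals.X_v.std(axis=(0, 2), keepdims=True)
    sig_sd[sig_sd < 1e-12] = 1.0
    X_d, y = fv.X_d, cohort.y.astype(float)
    X_v = (signals.X_v - sig_mean) / sig_sd
    p_s = cohort.X_s.shape[1]
    stat_block = X_d[:, p_s:]          # standardized statistical columns

    if X_d.shape[1] != bundle.d:
        raise ValueError(f"bundle expects d={bundle.d}, data has {X_d.shape[1]}")

    pos_weight = 1.0
    if cfg.class_weight and y.sum() > 0:
        pos_weight = float((len(y) - y.sum()) / y.sum())

    opt_cls = Adam if cfg.optimizer == "adam" else SGD
    opt = opt_cls(bundle.parameters(), lr=cfg.lr)
    baseline_params = set(map(id, bundle.tcn.parameters()
                              + bundle.baseline.parameters()))

    history: dict = {"epochs": [], "steps": [], "config": vars(cfg).copy(),
                     "feature_names": fv.feature_names}

    for epoch in range(cfg.pretrain_baseline + cfg.epochs):
        pretraining = epoch < cfg.pretrain_baseline
        joint_epoch = epoch - cfg.pretrain_baseline
        if not pretraining:
            opt.lr = cfg.lr * cfg.lr_decay ** max(0, joint_epoch - cfg.decay_start)

        step_bundles = []
        correct = total = 0
        for idx in _batches(len(y), cfg.batch_size, rng, y,
                            cfg.stratified_batches):
            xb = Tensor(X_d[idx])
            yb = y[idx]

            emb = bundle.tcn(Tensor(X_v[idx]))
            z_base = bundle.baseline.logits(xb, emb)
            L_fcl = cross_entropy_with_logits(z_base, yb,
                                              pos_weight=pos_weight)
            L_hsic = hsic_loss(Tensor(stat_block[idx]), emb)

            if pretraining:
                loss = L_fcl + L_hsic
                opt.zero_grad()
                loss.backward()
                _clip_grads(opt.params, cfg.max_grad_norm)
                opt.step()
                continue

            z_sel = bundle.actor.logits(xb)
            S_d = z_sel.sigmoid()
            M = sample_mask(S_d.data, "bernoulli", rng)
            x_star = apply_mask(xb, M)
            z_crit = bundle.critic.logits(x_star, train_mode=True, rng=rng)
            L_pred = cross_entropy_with_logits(z_crit, yb,
                                               pos_weight=pos_weight)

            L_fs = selection_loss_with_logits(z_sel, M)
            S_mean = S_d.mean()

            lb = assemble_losses(L_fcl.item(), L_hsic.item(), L_pred.item(),
                                 L_fs.item(), cfg.lam, S_mean.item())
            R = cfg.reward_sign * lb.R        # detached scalar reward

            L_actor = R * L_fs - cfg.lam * S_mean
            L_total = L_actor + L_fcl + L_hsic + L_pred

            opt.zero_grad()
            L_total.backward()
            _clip_grads(opt.params, cfg.max_grad_norm)
            opt.step()

            step_bundles.append(lb.to_dict())
            correct += int(((z_crit.data >= 0.0) == (yb == 1)).sum())
            total += len(yb)

        if pretraining:
            continue
        means = {k: float(np.mean([s[k] for s in step_bundles]))
                 for k in step_bundles[0]} if step_bundles else {}
        history["epochs"].append({
            "epoch": joint_epoch, "lr": opt.lr,
            "train_accuracy": correct / total if total else float("nan"),
            **means})
        history["steps"].extend(step_bundles)

    bundle.scaler = scaler
    bundle.signal_scaler = {"mean": sig_mean, "sd": sig_sd}
    return bundle, history


def predict_critic(bundle: ModelBundle, X_d: np.ndarray, *,
                   mask_mode: str = "threshold",
                   rng: np.random.Generator | None = None):
    """Evaluation-mode prediction: deterministic mask, dropout off.

    Returns (probabilities, selection probabilities, mask).
    """
    S_d = bundle.actor(Tensor(X_d)).data
    M = sample_mask(S_d, mask_mode, rng)
    p = bundle.critic(apply_mask(Tensor(X_d), M), train_mode=False).data
    return p, S_d, M


def predict_baseline(bundle: ModelBundle, X_d: np.ndarray,
                     X_v: np.ndarray) -> np.ndarray:
    ss = getattr(bundle, "signal_scaler", None)
    if ss is not None:
        X_v = (X_v - ss["mean"]) / ss["sd"]
    emb = bundle.tcn(Tensor(X_v))
    return bundle.baseline(Tensor(X_d), emb).data


def featurize(bundle: ModelBundle, cohort: CohortTable,
              signals: TemporalSignals) -> np.ndarray:
    """Standardized feature vector using the scaler fitted at training."""
    scaler = getattr(bundle, "scaler", None)
    if scaler is None:
        raise RuntimeError("bundle has no fitted scaler; train first")
    stats = compute_stat_features(signals)
    return build_feature_vector(cohort, stats, scaler).X_d
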