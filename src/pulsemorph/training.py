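"""Masked multitask losses, weight initialization, schedule, splits, training.

The training objective is ``MSE + lambda * CE`` with lambda = 0.01: a
masked mean-squared error on the scaled pressure values (each sample
averaged over its own mask length, then averaged over the batch) plus a
categorical cross-entropy on the cardiac-cycle classes evaluated over the
whole fixed-length target, unmasked, so the model is forced to emit the
"ended" class on repeated steps.

Optimization uses Adam at 1e-3 with halving after 25 epochs without
improvement and stopping after 50, batch size 48.  Dense/attention weights
start from U(-w, w) with w = 1/sqrt(fan-in), GRU input weights from
U(-k, k) with k = 1/sqrt(units), and the recurrent transition matrices are
random orthogonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .features import HomogenizedTarget, sample_window
from .seq2seq import Seq2SeqModel

logger = logging.getLogger(__name__)

LAMBDA_CE = 0.01
SCENARIOS = ("Mixno", "Mixno+DI", "Mixyes+DI")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _as2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None] if x.ndim == 1 else x


def masked_mse_t(truth: np.ndarray, pred: Tensor, mask: np.ndarray) -> Tensor:
    """Tensor masked MSE: per-sample mean over its mask, then batch mean."""
    truth, mask = _as2d(truth), _as2d(mask)
    m_len = mask.sum(axis=1)
    if np.any(m_len < 1):
        raise ValueError("every sample needs a nonempty mask")
    diff = pred - truth
    sq = diff * diff * mask
    per_sample = ad.reduce_sum(sq, axis=1) * (1.0 / m_len)
    return ad.reduce_mean(per_sample)


def masked_mse(truth, pred, mask) -> float:
    """Masked value loss on plain arrays (same formula as the training graph)."""
    with ad.no_grad():
        return masked_mse_t(truth, Tensor(_as2d(pred)), mask).item()


def class_ce_t(truth_onehot: np.ndarray, probs: Tensor, eps: float = 1e-8) -> Tensor:
    """Tensor categorical cross-entropy, mean over batch and all T steps."""
    truth_onehot = np.asarray(truth_onehot, dtype=float)
    if truth_onehot.ndim == 2:
        truth_onehot = truth_onehot[None]
    n, T, _ = truth_onehot.shape
    ll = truth_onehot * ad.log_clipped(probs, eps)
    return ad.reduce_sum(ll) * (-1.0 / (n * T))


def class_ce(truth_onehot, probs, eps: float = 1e-8) -> float:
    with ad.no_grad():
        p = np.asarray(probs, dtype=float)
        if p.ndim == 2:
            p = p[None]
        return class_ce_t(truth_onehot, Tensor(p), eps).item()


def total_loss(mse: float, ce: float, lam: float = LAMBDA_CE) -> float:
    return mse + lam * ce


def one_hot(classes: np.ndarray, n_classes: int = 4) -> np.ndarray:
    classes = np.asarray(classes, dtype=int)
    return np.eye(n_classes)[classes]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _orthogonal(rng, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


def init_weights(model: Seq2SeqModel, seed: int = 0) -> Seq2SeqModel:
    """Initialize all parameters in place; returns the model.

    Recurrent transition matrices (``Wh*``) are random orthogonal; GRU input
    matrices (``Wt*``) are U(-k, k) with k = 1/sqrt(units); attention and
    head weights are U(-w, w) with w = 1/sqrt(fan-in); biases are zero.
    """
    rng = np.random.default_rng(seed)
    for p in model.parameters():
        leaf = p.name.rsplit(".", 1)[-1]
        if leaf in ("Whz", "Whr", "Whh"):
            p.data = _orthogonal(rng, p.data.shape[0])
        elif leaf in ("Wtz", "Wtr", "Wth"):
            k = 1.0 / np.sqrt(p.data.shape[1])
            p.data = rng.uniform(-k, k, p.data.shape)
        elif leaf == "W":
            w = 1.0 / np.sqrt(p.data.shape[0])
            p.data = rng.uniform(-w, w, p.data.shape)
        else:  # biases
            p.data = np.zeros_like(p.data)
    return model


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

class LRSchedule:
    """Halve the LR after ``patience_decay`` epochs without improvement,
    stop after ``patience_stop``; any strictly lower loss resets the counter."""

    def __init__(self, lr: float, patience_decay: int = 25, patience_stop: int = 50):
        if patience_stop <= patience_decay:
            raise ValueError("patience_stop must exceed patience_decay")
        self.lr = lr
        self.patience_decay = patience_decay
        self.patience_stop = patience_stop
        self.best = np.inf
        self.counter = 0

    def update(self, loss: float):
        """Feed one epoch loss; returns (current lr, stop flag)."""
        if loss < self.best:
            self.best = loss
            self.counter = 0
            return self.lr, False
        self.counter += 1
        if self.counter == self.patience_decay:
            self.lr *= 0.5
        return self.lr, self.counter >= self.patience_stop


# ---------------------------------------------------------------------------
# scenario splits
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSplit:
    scenario: str
    folds: list  # list of (train manifest, test manifest) DataFrame pairs

    @property
    def use_di(self) -> bool:
        return self.scenario.endswith("+DI")


def make_splits(manifest: pd.DataFrame, scenario: str, seed: int = 0,
                n_folds: int = 5, resample: bool = False) -> ScenarioSplit:
    """Five cross-validation folds per scenario.

    Mixno / Mixno+DI: subject-disjoint folds, each test fold holding all the
    segments of ~20% of the subjects.  Mixyes+DI: segment-level folds, 20%
    of segments per test fold regardless of subject.  ``resample=True``
    draws five independent 80/20 splits instead of disjoint folds.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    rng = np.random.default_rng(seed)
    folds = []
    if scenario.startswith("Mixno"):
        subjects = np.array(sorted(manifest["subject_id"].unique()))
        if len(subjects) < n_folds:
            raise ValueError(f"need at least {n_folds} subjects, got {len(subjects)}")
        perm = rng.permutation(subjects)
        chunks = (np.array_split(perm, n_folds) if not resample
                  else [rng.permutation(subjects)[: max(1, len(subjects) // n_folds)]
                        for _ in range(n_folds)])
        for test_subjects in chunks:
            test_mask = manifest["subject_id"].isin(test_subjects)
            folds.append((manifest[~test_mask].reset_index(drop=True),
                          manifest[test_mask].reset_index(drop=True)))
    else:
        idx = rng.permutation(len(manifest))
        chunks = (np.array_split(idx, n_folds) if not resample
                  else [rng.permutation(len(manifest))[: max(1, len(manifest) // n_folds)]
                        for _ in range(n_folds)])
        for test_idx in chunks:
            test_mask = np.zeros(len(manifest), dtype=bool)
            test_mask[test_idx] = True
            folds.append((manifest[~test_mask].reset_index(drop=True),
                          manifest[test_mask].reset_index(drop=True)))
    return ScenarioSplit(scenario=scenario, folds=folds)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 48
    patience_decay: int = 25
    patience_stop: int = 50
    max_epochs: int = 500
    lambda_ce: float = LAMBDA_CE
    teacher_forcing: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.patience_stop <= self.patience_decay:
            raise ValueError("patience_stop must exceed patience_decay")


@dataclass
class TrainingSample:
    """One processed segment ready for the model."""

    prepared: np.ndarray          # (1625, 2) PPG + PPG'
    target: HomogenizedTarget
    di: np.ndarray | None
    subject_id: str = ""
    segment_id: str = ""


@dataclass
class TrainResult:
    history: list = field(default_factory=list)  # (epoch, loss, mse, ce, lr)
    best_loss: float = np.inf
    best_state: dict | None = None
    stopped_epoch: int = -1


def _batch_arrays(samples: list[TrainingSample], idx, epoch: int, seed: int, n_classes: int):
    """Assemble one batch: fresh random windows plus target/teacher arrays."""
    X, DI, V, C, M = [], [], [], [], []
    for j in idx:
        s = samples[j]
        win_rng = np.random.default_rng((seed * 1_000_003 + epoch * 1009 + int(j)) % (2**31 - 1))
        win, _ = sample_window(s.prepared, win_rng)
        X.append(win)
        DI.append(s.di)
        V.append(s.target.values)
        C.append(s.target.classes)
        M.append(s.target.mask)
    X = np.stack(X)
    V = np.stack(V)
    C = np.stack(C)
    M = np.stack(M)
    onehot = one_hot(C, n_classes)
    teacher = np.concatenate([V[:, :, None], onehot], axis=2)  # (N, T, 1+n_classes)
    di = None if DI[0] is None else np.stack(DI)
    return X, di, V, onehot, M, teacher


def train_step(model: Seq2SeqModel, optimizer: Adam, X, di, V, onehot, M, teacher,
               lam: float, teacher_forcing: float, rng) -> tuple[float, float, float]:
    """One optimization step; returns (total, mse, ce) for the batch."""
    T = V.shape[1]
    use_teacher = teacher_forcing >= 1.0 or rng.random() < teacher_forcing
    pred_v, pred_p, _att = model.forward_teacher(
        X, di, teacher if use_teacher else None, T
    )
    mse = masked_mse_t(V, pred_v, M)
    ce = class_ce_t(onehot, pred_p)
    loss = mse + lam * ce
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return loss.item(), mse.item(), ce.item()


def train(model: Seq2SeqModel, samples: list[TrainingSample],
          config: TrainConfig | None = None) -> TrainResult:
    """Run the optimization schedule; keeps the best-loss weights.

    The monitored quantity is the epoch-mean training loss (no validation
    split is carved out); improvement is any strictly lower value.
    """
    cfg = config or TrainConfig()
    if not samples:
        raise ValueError("no training samples")
    if model.config.use_di and samples[0].di is None:
        raise ValueError("DI-enabled model but samples carry no demographics")
    params = model.parameters()
    optimizer = Adam(params, lr=cfg.lr)
    schedule = LRSchedule(cfg.lr, cfg.patience_decay, cfg.patience_stop)
    rng = np.random.default_rng(cfg.seed)
    result = TrainResult()
    n = len(samples)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, mses, ces = [], [], []
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            X, di, V, onehot, M, teacher = _batch_arrays(
                samples, idx, epoch, cfg.seed, model.config.n_classes
            )
            if not model.config.use_di:
                di = None
            lt, lm, lc = train_step(model, optimizer, X, di, V, onehot, M, teacher,
                                    cfg.lambda_ce, cfg.teacher_forcing, rng)
            if not np.isfinite(lt):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={lt}); "
                    "lower the learning rate or check the inputs"
                )
            losses.append(lt)
            mses.append(lm)
            ces.append(lc)
        epoch_loss = float(np.mean(losses))
        lr, stop = schedule.update(epoch_loss)
        optimizer.lr = lr
        result.history.append((epoch, epoch_loss, float(np.mean(mses)), float(np.mean(ces)), lr))
        if epoch_loss < result.best_loss:
            result.best_loss = epoch_loss
            result.best_state = {k: v.copy() for k, v in model.state_dict().items()}
        logger.debug("epoch %d loss %.6f lr %.2e", epoch, epoch_loss, lr)
        if stop:
            result.stopped_epoch = epoch
            break
    if result.best_state is not None:
        model.load_state_dict(result.best_state)
    return result
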