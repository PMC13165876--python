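"""Sliding-window multiple-instance learning with gated attention.

A subject's per-task multichannel sequence is cut into overlapping windows
(the instances of a bag labeled with the subject's diagnosis). Training has
two phases: (1) the multi-scale encoder plus an instance-level MLP head are
fit on all windows with inherited labels, using a soft weighting
``w_i = exp(-gamma * loss_i)`` that down-weights instances the network finds
hard (likely label noise) and a restricted epoch budget; (2) the encoder is
frozen and a gated-attention pooling plus bag-level classifier are fit one
bag per step with cross-entropy at the bag level. Five task-specific models
vote by majority for the subject-level diagnosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..preprocess import PreprocessConfig, preprocess_recording
from ..session import SessionRecording, Task, segment_tasks, zero_fill_facial
from . import nn
from .encoder import EMBED_DIM, MLPHead, MSPCNNEncoder

TASKS = [Task.VSST, Task.MCT, Task.PRT, Task.ST, Task.FET]
N_CHANNELS = 17  # 11 oculomotor + 6 facial (zero-filled outside FET)
ATTN_DIM = 64    # K of the gated-attention projections


@dataclass
class WindowSpec:
    W: int = 150  # window size, samples
    S: int = 50   # stride, samples

    def __post_init__(self) -> None:
        if not 0 < self.S <= self.W:
            raise ValueError("stride must satisfy 0 < S <= W")

    def count(self, L: int) -> int:
        return (L - self.W) // self.S + 1 if L >= self.W else 0


@dataclass
class SubspaceBag:
    """Windowed instance set with the bag-level subject label."""

    instances: np.ndarray  # (N, C, W)
    bag_label: int
    task: Task | None = None
    subject_id: str = ""

    def __len__(self) -> int:
        return len(self.instances)


def make_subspaces(X: np.ndarray, spec: WindowSpec | None = None,
                   bag_label: int = 0, task: Task | None = None,
                   subject_id: str = "") -> SubspaceBag:
    """Decompose a (C, L) matrix into N overlapping windows.

    Window *n* (0-based) covers samples ``n*S .. n*S + W``; a tail shorter
    than a full window is discarded. A sequence shorter than one window
    yields an empty bag with a warning.
    """
    spec = spec or WindowSpec()
    C, L = X.shape
    n = spec.count(L)
    if n == 0:
        warnings.warn(f"sequence of length {L} shorter than window {spec.W}; "
                      "empty bag", stacklevel=2)
        inst = np.zeros((0, C, spec.W), dtype=X.dtype)
    else:
        starts = np.arange(n) * spec.S
        inst = np.stack([X[:, s:s + spec.W] for s in starts])
    return SubspaceBag(instances=inst, bag_label=bag_label, task=task,
                       subject_id=subject_id)


# ---------------------------------------------------------------------------
# Gated attention

def init_attention(rng: np.random.Generator, D: int = EMBED_DIM,
                   K: int = ATTN_DIM, n_classes: int = 2,
                   ) -> dict[str, np.ndarray]:
    return {
        "Wv": nn.he_init(rng, (K, D), D),
        "Wu": nn.he_init(rng, (K, D), D),
        "w": nn.he_init(rng, (K,), K),
        "Wc": nn.he_init(rng, (n_classes, D), D),
        "bc": np.zeros(n_classes, dtype=nn.DTYPE),
    }


def gated_attention(z: np.ndarray, params: dict[str, np.ndarray],
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Attention weights and bag embedding for instance embeddings z (N, D).

    ``e_n = w^T (tanh(Wv z_n) * sigmoid(Wu z_n))``, ``a = softmax(e)``,
    ``Z_bag = sum_n a_n z_n``.
    """
    if len(z) == 0:
        raise ValueError("empty bag")
    t = np.tanh(z @ params["Wv"].T)
    s = 1.0 / (1.0 + np.exp(-(z @ params["Wu"].T)))
    e = (t * s) @ params["w"]
    a = nn.softmax(e[None, :], axis=1)[0]
    z_bag = a @ z
    return a, z_bag


def _attn_forward_full(z: np.ndarray, params: dict[str, np.ndarray]):
    t = np.tanh(z @ params["Wv"].T)
    s = 1.0 / (1.0 + np.exp(-(z @ params["Wu"].T)))
    e = (t * s) @ params["w"]
    a = nn.softmax(e[None, :], axis=1)[0]
    z_bag = a @ z
    logits = params["Wc"] @ z_bag + params["bc"]
    return logits, (z, t, s, a, z_bag)


def _attn_backward(dlogits: np.ndarray, cache, params):
    """Analytic gradients of the bag logits wrt the attention parameters."""
    z, t, s, a, z_bag = cache
    grads = {
        "Wc": np.outer(dlogits, z_bag).astype(nn.DTYPE),
        "bc": dlogits.astype(nn.DTYPE),
    }
    dz_bag = params["Wc"].T @ dlogits            # (D,)
    da = z @ dz_bag                              # (N,)
    de = a * (da - float(a @ da))                # softmax Jacobian
    grads["w"] = ((t * s).T @ de).astype(nn.DTYPE)
    dts = np.outer(de, params["w"])              # (N, K)
    dt = dts * s
    ds = dts * t
    grads["Wv"] = ((dt * (1 - t * t)).T @ z).astype(nn.DTYPE)
    grads["Wu"] = ((ds * s * (1 - s)).T @ z).astype(nn.DTYPE)
    return grads


@dataclass
class BagPrediction:
    attention: np.ndarray    # a_n per instance, sums to 1
    bag_embedding: np.ndarray
    probabilities: np.ndarray  # class probabilities, sum to 1
    predicted: int


def predict_bag(z: np.ndarray, params: dict[str, np.ndarray]) -> BagPrediction:
    logits, (zc, t, s, a, z_bag) = _attn_forward_full(z, params)
    p = nn.softmax(logits[None, :], axis=1)[0]
    return BagPrediction(attention=a, bag_embedding=z_bag,
                         probabilities=p, predicted=int(p.argmax()))


# ---------------------------------------------------------------------------
# Training configuration

@dataclass
class SoftWeightConfig:
    gamma: float = 1.0        # decay rate of w_i = exp(-gamma * loss_i)
    epochs: int = 30          # phase-1 epoch cap (restricted on purpose)
    batch_size: int = 32
    lr: float = 1e-3

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class Phase2Config:
    epochs: int = 20
    lr: float = 1e-3


@dataclass
class TaskModel:
    """A trained single-task classifier: frozen encoder + attention head."""

    task: Task
    encoder: MSPCNNEncoder
    head: MLPHead
    attention: dict[str, np.ndarray]
    channel_stats: tuple[np.ndarray, np.ndarray]
    window: WindowSpec

    def predict(self, X_raw: np.ndarray) -> BagPrediction | None:
        """Predict from a raw (unstandardized) (C, L) task sequence."""
        mean, sd = self.channel_stats
        Xn = (X_raw - mean[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
        bag = make_subspaces(Xn.astype(nn.DTYPE), self.window)
        if len(bag) == 0:
            return None
        z = self.encoder.encode(bag.instances)
        return predict_bag(z, self.attention)


@dataclass
class VoteResult:
    votes: dict[Task, int | None]
    final: int
    tie_flag: bool = False


def majority_vote(votes: dict[Task, int | None]) -> VoteResult:
    """Subject-level diagnosis by plurality of per-task votes.

    Abstentions (missing task segments) are skipped; a post-abstention tie
    resolves screening-conservatively to the cognitive-decline class.
    """
    cast = [v for v in votes.values() if v is not None]
    n1 = sum(cast)
    n0 = len(cast) - n1
    if n1 == n0:
        return VoteResult(votes=votes, final=1, tie_flag=True)
    return VoteResult(votes=votes, final=int(n1 > n0))


# ---------------------------------------------------------------------------
# Phase 1 / phase 2 training

def phase1_train(instances: np.ndarray, labels: np.ndarray,
                 cfg: SoftWeightConfig, rng: np.random.Generator,
                 in_channels: int = N_CHANNELS,
                 ) -> tuple[MSPCNNEncoder, MLPHead]:
    """Fit encoder + instance head on windows with inherited subject labels.

    Every instance starts with weight 1; after each epoch the weights are
    refreshed from that epoch's recorded per-instance losses via
    ``exp(-gamma * loss)``, so persistently hard (likely mislabeled) windows
    fade from the objective. Training stops at the epoch cap.
    """
    if len(np.unique(labels)) < 2:
        raise ValueError("phase-1 training requires both classes")
    M = len(instances)
    encoder = MSPCNNEncoder(in_channels, rng)
    head = MLPHead(rng)
    opt = nn.Adam({**encoder.params, **head.params}, lr=cfg.lr)
    weights = np.ones(M, dtype=nn.DTYPE)
    losses = np.zeros(M, dtype=np.float64)
    X = instances.astype(nn.DTYPE, copy=False)
    y = np.asarray(labels, dtype=int)
    for _ in range(cfg.epochs):
        order = rng.permutation(M)
        for i in range(0, M, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            z, enc_cache = encoder.forward(X[idx])
            logits, head_cache = head.forward(z)
            _, dlogits, per = nn.softmax_xent(logits, y[idx], weights[idx])
            losses[idx] = per
            dz, head_grads = head.backward(dlogits, head_cache)
            enc_grads = encoder.backward(dz.astype(nn.DTYPE), enc_cache)
            opt.step({**enc_grads, **head_grads})
        weights = np.exp(-cfg.gamma * losses).astype(nn.DTYPE)
    return encoder, head


def phase2_train(bags: list[tuple[np.ndarray, int]], encoder: MSPCNNEncoder,
                 cfg: Phase2Config, rng: np.random.Generator,
                 val_bags: list[tuple[np.ndarray, int]] | None = None,
                 ) -> dict[str, np.ndarray]:
    """Fit gated attention + bag classifier over a frozen encoder.

    ``bags`` holds (instances, label) pairs of standardized windows. One bag
    per optimization step, bag-level cross-entropy. When validation bags are
    supplied, the parameters of the best-validation-accuracy epoch are
    returned (the encoder itself is never touched).
    """
    emb = [(encoder.encode(x), lab) for x, lab in bags if len(x)]
    skipped = len(bags) - len(emb)
    if skipped:
        warnings.warn(f"skipping {skipped} empty bag(s)", stacklevel=2)
    val_emb = [(encoder.encode(x), lab) for x, lab in (val_bags or []) if len(x)]
    params = init_attention(rng)
    opt = nn.Adam(params, lr=cfg.lr)
    best = {k: v.copy() for k, v in params.items()}
    best_acc = -1.0
    for _ in range(cfg.epochs):
        for j in rng.permutation(len(emb)):
            z, lab = emb[j]
            logits, cache = _attn_forward_full(z, params)
            _, dlogits, _ = nn.softmax_xent(logits[None, :], np.array([lab]))
            opt.step(_attn_backward(dlogits[0], cache, params))
        if val_emb:
            acc = np.mean([predict_bag(z, params).predicted == lab
                           for z, lab in val_emb])
            if acc > best_acc:
                best_acc = acc
                best = {k: v.copy() for k, v in params.items()}
    return best if val_emb else params


# ---------------------------------------------------------------------------
# Subject preparation and the evaluation protocol

@dataclass
class PreparedSubject:
    """Cached per-task raw windows and channel moments of one subject."""

    subject_id: str
    label: int  # CD = 1
    windows: dict[Task, np.ndarray]       # (N, 17, W) raw (unstandardized)
    moments: dict[Task, tuple[np.ndarray, np.ndarray, int]]  # sum, sumsq, n


def task_sequence(rec: SessionRecording, task: Task) -> np.ndarray:
    """(17, L) channel matrix of all samples labeled with ``task``."""
    sel = rec.task_label == task.value
    full = rec.full_matrix()
    return full[:, sel]


def prepare_subject(rec: SessionRecording, label: int,
                    window: WindowSpec | None = None,
                    preprocess_cfg: PreprocessConfig | None = None,
                    ) -> PreparedSubject:
    """Preprocess a recording and cache its per-task window tensors."""
    window = window or WindowSpec()
    clean, _ = preprocess_recording(rec, preprocess_cfg)
    clean = zero_fill_facial(clean, segment_tasks(clean))
    windows: dict[Task, np.ndarray] = {}
    moments: dict[Task, tuple[np.ndarray, np.ndarray, int]] = {}
    for task in TASKS:
        X = task_sequence(clean, task)
        if X.shape[1] == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bag = make_subspaces(X.astype(nn.DTYPE), window)
        windows[task] = bag.instances
        moments[task] = (X.sum(axis=1), (X ** 2).sum(axis=1), X.shape[1])
    return PreparedSubject(subject_id=rec.subject_id, label=label,
                           windows=windows, moments=moments)


def _pooled_stats(subjects: list[PreparedSubject], task: Task,
                  ) -> tuple[np.ndarray, np.ndarray]:
    s = sum(sub.moments[task][0] for sub in subjects if task in sub.moments)
    ss = sum(sub.moments[task][1] for sub in subjects if task in sub.moments)
    n = sum(sub.moments[task][2] for sub in subjects if task in sub.moments)
    mean = s / n
    var = np.maximum(ss / n - mean ** 2, 0.0)
    return mean, np.sqrt(var)


def _normalize(windows: np.ndarray, stats) -> np.ndarray:
    mean, sd = stats
    sd = np.where(sd > 0, sd, 1.0)
    return ((windows - mean[None, :, None]) / sd[None, :, None]).astype(nn.DTYPE)


def train_task_models(train: list[PreparedSubject],
                      val: list[PreparedSubject],
                      rng: np.random.Generator,
                      p1_cfg: SoftWeightConfig | None = None,
                      p2_cfg: Phase2Config | None = None,
                      window: WindowSpec | None = None,
                      ) -> dict[Task, TaskModel]:
    """Train the five single-task models on a train/validation split."""
    p1_cfg = p1_cfg or SoftWeightConfig()
    p2_cfg = p2_cfg or Phase2Config()
    window = window or WindowSpec()
    models: dict[Task, TaskModel] = {}
    for task in TASKS:
        tr = [s for s in train if task in s.windows and len(s.windows[task])]
        if not tr:
            continue
        stats = _pooled_stats(tr, task)
        inst = np.concatenate([_normalize(s.windows[task], stats) for s in tr])
        labels = np.concatenate([np.full(len(s.windows[task]), s.label)
                                 for s in tr])
        child = np.random.default_rng(rng.integers(2 ** 31))
        encoder, head = phase1_train(inst, labels, p1_cfg, child,
                                     in_channels=inst.shape[1])
        bags = [(_normalize(s.windows[task], stats), s.label) for s in tr]
        vbags = [(_normalize(s.windows[task], stats), s.label)
                 for s in val if task in s.windows and len(s.windows[task])]
        attn = phase2_train(bags, encoder, p2_cfg, child, vbags or None)
        models[task] = TaskModel(task=task, encoder=encoder, head=head,
                                 attention=attn, channel_stats=stats,
                                 window=window)
    return models


def predict_subject(sub: PreparedSubject, models: dict[Task, TaskModel],
                    ) -> VoteResult:
    """Majority vote of the per-task models for one prepared subject."""
    votes: dict[Task, int | None] = {}
    for task in TASKS:
        model = models.get(task)
        raw = sub.windows.get(task)
        if model is None or raw is None or len(raw) == 0:
            votes[task] = None
            continue
        z = model.encoder.encode(_normalize(raw, model.channel_stats))
        votes[task] = predict_bag(z, model.attention).predicted
    return majority_vote(votes)


def predict_recording(rec: SessionRecording, models: dict[Task, TaskModel],
                      preprocess_cfg: PreprocessConfig | None = None,
                      ) -> VoteResult:
    window = next(iter(models.values())).window if models else WindowSpec()
    sub = prepare_subject(rec, label=-1, window=window,
                          preprocess_cfg=preprocess_cfg)
    return predict_subject(sub, models)


@dataclass
class ProtocolConfig:
    """The split/repeat scheme for subject-level evaluation.

    Each repeat draws 15 + 15 subjects for train/validation (split 7:3,
    stratified), holds out the remaining 5 + 5 as an independent test set,
    trains the five task models and scores them plus the fused vote on the
    test subjects. All splits are re-drawn every repeat.
    """

    n_trainval_per_class: int = 15
    repeats: int = 10
    val_frac: float = 0.3
    phase1: SoftWeightConfig = field(default_factory=SoftWeightConfig)
    phase2: Phase2Config = field(default_factory=Phase2Config)
    window: WindowSpec = field(default_factory=WindowSpec)


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           ) -> dict[str, float]:
    """Accuracy, precision, recall (sensitivity), F1 with CD as positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / max(len(y_true), 1)
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def evaluate_protocol(subjects: list[PreparedSubject], seed: int,
                      cfg: ProtocolConfig | None = None) -> dict:
    """Run the repeated-split protocol; returns per-model metric summaries.

    The result maps each model name ("VSST", ..., "FET", "fused") to a dict
    of metric -> (mean, std) over repeats, plus a "per_repeat" record.
    """
    cfg = cfg or ProtocolConfig()
    rng = np.random.default_rng(seed)
    by_class = {0: [s for s in subjects if s.label == 0],
                1: [s for s in subjects if s.label == 1]}
    for lab, subs in by_class.items():
        if len(subs) <= cfg.n_trainval_per_class:
            raise ValueError(
                f"class {lab} has {len(subs)} subjects; need more than "
                f"{cfg.n_trainval_per_class} for the split")
    records: list[dict] = []
    for rep in range(cfg.repeats):
        train, val, test = [], [], []
        for subs in by_class.values():
            perm = rng.permutation(len(subs))
            tv = [subs[i] for i in perm[:cfg.n_trainval_per_class]]
            test += [subs[i] for i in perm[cfg.n_trainval_per_class:]]
            n_val = int(round(cfg.val_frac * len(tv)))
            val += tv[:n_val]
            train += tv[n_val:]
        models = train_task_models(train, val, rng, cfg.phase1, cfg.phase2,
                                   cfg.window)
        y_true = np.array([s.label for s in test])
        results = [predict_subject(s, models) for s in test]
        rec = {"repeat": rep}
        for task in TASKS:
            y_task = np.array([r.votes[task] if r.votes[task] is not None
                               else 1 - t for r, t in zip(results, y_true)])
            rec[task.value] = classification_metrics(y_true, y_task)
        rec["fused"] = classification_metrics(
            y_true, np.array([r.final for r in results]))
        records.append(rec)
    summary: dict = {"per_repeat": records}
    for name in [t.value for t in TASKS] + ["fused"]:
        summary[name] = {
            m: (float(np.mean([r[name][m] for r in records])),
                float(np.std([r[name][m] for r in records])))
            for m in ("accuracy", "precision", "recall", "f1")}
    return summary


# ---------------------------------------------------------------------------
# Persistence

def save_models(models: dict[Task, TaskModel], path: str | Path) -> None:
    """Serialize the five task models into one .npz checkpoint."""
    arrays: dict[str, np.ndarray] = {}
    for task, m in models.items():
        p = task.value
        for k, v in m.encoder.params.items():
            arrays[f"{p}/enc/{k}"] = v
        for k, v in m.head.params.items():
            arrays[f"{p}/head/{k}"] = v
        for k, v in m.attention.items():
            arrays[f"{p}/attn/{k}"] = v
        arrays[f"{p}/stats/mean"] = m.channel_stats[0]
        arrays[f"{p}/stats/sd"] = m.channel_stats[1]
        arrays[f"{p}/window"] = np.array([m.window.W, m.window.S])
    np.savez(path, **arrays)


def load_models(path: str | Path) -> dict[Task, TaskModel]:
    data = np.load(path)
    models: dict[Task, TaskModel] = {}
    tasks = {k.split("/")[0] for k in data.files}
    rng = np.random.default_rng(0)  # placeholder init, overwritten below
    for name in tasks:
        task = Task(name)
        stats_mean = data[f"{name}/stats/mean"]
        encoder = MSPCNNEncoder(int(len(stats_mean)), rng)
        for k in list(encoder.params):
            encoder.params[k] = data[f"{name}/enc/{k}"]
        head = MLPHead(rng)
        for k in list(head.params):
            head.params[k] = data[f"{name}/head/{k}"]
        attn = {k.split("/")[-1]: data[k] for k in data.files
                if k.startswith(f"{name}/attn/")}
        W, S = (int(v) for v in data[f"{name}/window"])
        models[task] = TaskModel(
            task=task, encoder=encoder, head=head, attention=attn,
            channel_stats=(stats_mean, data[f"{name}/stats/sd"]),
            window=WindowSpec(W, S))
    return models
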