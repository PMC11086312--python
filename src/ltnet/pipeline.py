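"""Dataset splitting, training, evaluation and benchmarking.

The experimental protocol: snapshots are GAF-encoded to images, split
6 train : 3 test : 1 validation (stratified by class), the network is
trained with Adam on cross-entropy (defaults: 30 epochs, batch 16, learning
rate 6e-4 for the in-house gas-mixture profile, 4e-4 for the UCI drift
profile), the weights with the best test-split accuracy are retained, and
the held-out validation split is the one reported via a confusion matrix
and overall accuracy.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .gaf import Snapshot, snapshot_to_tensor
from .model import LTNet, count_params_model, enumerate_model_params

SPLIT_NAMES = ("train", "test", "validation")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _allocate(n: int, ratios: tuple[float, float, float]) -> list[int]:
    """Floor-then-largest-remainder allocation of n items to the ratios."""
    raw = [n * r for r in ratios]
    counts = [int(np.floor(v)) for v in raw]
    rem = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


@dataclass
class SplitAssignment:
    assignment: np.ndarray             # index -> 0 train, 1 test, 2 validation
    ratios: tuple[float, float, float]
    seed: int
    stratified: bool

    def indices(self, split: str) -> np.ndarray:
        return np.where(self.assignment == SPLIT_NAMES.index(split))[0]

    def sizes(self) -> dict[str, int]:
        return {s: int((self.assignment == i).sum()) for i, s in enumerate(SPLIT_NAMES)}


def split_dataset(labels: list | np.ndarray,
                  ratios: tuple[float, float, float] = (0.6, 0.3, 0.1),
                  seed: int = 0, stratified: bool = True) -> SplitAssignment:
    """Deterministic 3-way split. Stratification allocates per class with
    floor + largest remainder, so per-class proportions are within one item
    of the ratios; classes with fewer items than splits fall to train first."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("nothing to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    groups = ([labels == c for c in np.unique(labels)] if stratified
              else [np.ones(labels.size, dtype=bool)])
    for mask in groups:
        idx = np.where(mask)[0]
        idx = idx[rng.permutation(idx.size)]
        n_tr, n_te, n_va = _allocate(idx.size, tuple(ratios))
        assignment[idx[:n_tr]] = 0
        assignment[idx[n_tr:n_tr + n_te]] = 1
        assignment[idx[n_tr + n_te:]] = 2
    return SplitAssignment(assignment=assignment, ratios=tuple(ratios),
                           seed=seed, stratified=stratified)


# ---------------------------------------------------------------------------
# Encoding snapshots to model inputs
# ---------------------------------------------------------------------------

CLASS_ORDER = ("acetone", "ethanol", "mixture")


def encode_snapshots(snapshots: list[Snapshot], method: str = "gasf",
                     channels: int = 3, colormap: str = "viridis",
                     class_order: tuple[str, ...] = CLASS_ORDER):
    """Encode snapshots into (X, y): X is (N, C, n, n) float32, y integer
    class indices in ``class_order``."""
    xs = [snapshot_to_tensor(s, method=method, channels=channels,
                             colormap=colormap) for s in snapshots]
    y = np.array([class_order.index(s.class_label) for s in snapshots])
    return np.stack(xs).astype(np.float32), y


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    optimizer: str = "adam"
    loss: str = "cross-entropy"
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 0.0006      # gas-mixture profile; UCI profile: 0.0004
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam" or self.loss != "cross-entropy":
            raise ValueError("only Adam + cross-entropy are supported")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError("invalid training hyperparameters")


def train(model: LTNet, x: np.ndarray, y: np.ndarray, splits: SplitAssignment,
          cfg: TrainConfig | None = None, verbose: bool = False):
    """Minibatch Adam on cross-entropy; retains the weights with the best
    test-split accuracy ("best-preserved weights on the test set").

    Returns ``(best_state, history)``; history has one dict per epoch with
    the mean train loss and test accuracy. Fully seeded: shuffling comes
    from ``cfg.seed`` only.
    """
    cfg = cfg or TrainConfig()
    tr = splits.indices("train")
    te = splits.indices("test")
    if tr.size == 0:
        raise ValueError("train split is empty")
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    best_acc, best_state = -1.0, model.state_dict()
    history = []
    for epoch in range(cfg.epochs):
        order = tr[rng.permutation(tr.size)]
        losses = []
        for i in range(0, order.size, cfg.batch_size):
            batch = order[i:i + cfg.batch_size]
            logits = model.forward(x[batch], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        test_acc = (float(np.mean(model.predict(x[te]) == y[te]))
                    if te.size else float("nan"))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "test_accuracy": test_acc})
        if te.size and test_acc > best_acc:
            best_acc, best_state = test_acc, model.state_dict()
        if verbose:
            print(f"epoch {epoch:3d}  loss {history[-1]['train_loss']:.4f}"
                  f"  test acc {test_acc:.4f}")
    if te.size:
        model.load_state_dict(best_state)
    else:
        best_state = model.state_dict()
    return best_state, history


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class Metrics:
    confusion: np.ndarray              # rows = true class, cols = predicted
    n_items: int = field(init=False)
    overall_accuracy: float = field(init=False)
    per_class_accuracy: np.ndarray = field(init=False)

    def __post_init__(self):
        c = np.asarray(self.confusion, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
            raise ValueError("confusion must be a square nonnegative matrix")
        self.confusion = c
        self.n_items = int(c.sum())
        if self.n_items == 0:
            raise ValueError("empty evaluation")
        self.overall_accuracy = float(np.trace(c) / self.n_items)
        row = c.sum(axis=1)
        self.per_class_accuracy = np.divide(
            np.diag(c), row, out=np.zeros(c.shape[0], dtype=float), where=row > 0)


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             n_classes: int) -> Metrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if np.any((y_true < 0) | (y_true >= n_classes)):
        raise ValueError("unknown true label")
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    return Metrics(confusion=conf)


def evaluate(model: LTNet, x: np.ndarray, y: np.ndarray,
             n_classes: int | None = None) -> Metrics:
    """Confusion matrix and accuracies; prediction is the argmax logit with
    ties broken to the lowest class index."""
    if len(x) == 0:
        raise ValueError("nothing to evaluate")
    n_classes = n_classes or model.cfg.n_classes
    return metrics_from_predictions(y, model.predict(x), n_classes)


def benchmark(model: LTNet, x: np.ndarray | None = None) -> dict:
    """Parameter counts plus (informational) wall-clock inference time."""
    report = count_params_model(model.cfg, flops_at=model.cfg.input_size)
    from .fusion import deployed_param_total
    out = {"trainable_params": enumerate_model_params(model),
           "trainable_params_analytic": report.total,
           "deployed_params": deployed_param_total(model),
           "flops_at_input": report.flops}
    if x is not None and len(x):
        t0 = time.perf_counter()
        model.predict(x)
        out["inference_s"] = time.perf_counter() - t0
        out["n_items"] = int(len(x))
    return out


# ---------------------------------------------------------------------------
# UCI drift-dataset dialect
# ---------------------------------------------------------------------------

UCI_N_FEATURES = 128                   # 16 sensors x 8 features, sensor-major
UCI_GAS_CODES = {1: "ethanol", 2: "acetone", 3: "ammonia", 4: "acetaldehyde",
                 5: "ethylene", 6: "toluene"}


def read_uci_drift(path, gas_filter: set[int] | None = None,
                   conc_range: tuple[float, float] | None = None,
                   feature_slot: int = 1) -> list[Snapshot]:
    """Read the sparse `gas;concentration index:value ...` record dialect.

    Each record carries 128 features (8 per sensor, sensor-major); the
    16-vector handed to GAF is feature slot ``feature_slot`` (1-based,
    default the steady-state resistance change) of each sensor. Records
    outside ``conc_range`` or not in ``gas_filter`` are dropped.
    """
    import warnings

    if not (1 <= feature_slot <= 8):
        raise ValueError("feature_slot must be 1..8")
    snapshots = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                head, *pairs = line.split()
                gas_s, conc_s = head.split(";")
                gas, conc = int(gas_s), float(conc_s)
                feats = np.full(UCI_N_FEATURES, np.nan)
                for p in pairs:
                    k_s, v_s = p.split(":")
                    feats[int(k_s) - 1] = float(v_s)
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path}: malformed record at line {lineno}: {e}")
            idx = (np.arange(16) * 8) + (feature_slot - 1)
            if np.any(np.isnan(feats[idx])):
                missing = int(idx[np.isnan(feats[idx])][0]) + 1
                raise ValueError(
                    f"{path}: line {lineno}: missing feature index {missing}")
            if gas_filter is not None and gas not in gas_filter:
                continue
            if conc_range is not None and not (conc_range[0] <= conc <= conc_range[1]):
                continue
            snapshots.append(Snapshot(
                values=feats[idx],
                class_label=UCI_GAS_CODES.get(gas, str(gas)),
                meta={"gas_code": gas, "concentration_ppm": conc, "line": lineno}))
    if not snapshots:
        warnings.warn("no records passed the filters", stacklevel=2)
    return snapshots
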