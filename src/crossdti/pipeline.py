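"""Prediction head, evaluation metrics, and the training protocol.

The fused drug and protein feature maps are globally max-pooled per channel,
concatenated (drug first), and passed through a fully connected network with
Leaky-ReLU activations and dropout after every hidden layer; a final sigmoid
yields the interaction probability. Training minimises binary cross-entropy
with Adam, under the study protocol: an 80:20 train/test split, 5-fold cross
validation inside the training portion, and early stopping on validation AUC.

Two ablation variants of the model are assembled here alongside the full one:
``without_mimm`` drops the substructure streams (self-attention runs over the
original sequences only), and ``without_cpa`` skips the attention cascade and
feeds the CNN feature maps straight into pooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from dataclasses import replace as dc_replace

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import precision_recall_curve, roc_auc_score

from . import autograd as ag
from .autograd import Adam, Tensor
from .attention import AttentionConfig, CpaStack, run_stack_features, _concat_fm
from .encoder import (
    DRUG_KERNELS,
    PROTEIN_KERNELS,
    PROTEIN_ALPHABET,
    SMILES_ALPHABET,
    CnnBranch,
    CnnBranchConfig,
    EmbeddingTable,
    EncodedPair,
    FeatureMap,
    StreamEncoder,
    encode_pair,
    encode_records,
)
from .tokenizer import Vocabulary

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "PredictionHeadConfig",
    "ConfusionCounts",
    "MetricsReport",
    "CrossValReport",
    "DTIModel",
    "TrainingDiverged",
    "global_max_pool",
    "concat_features",
    "fcn_predict",
    "bce_loss",
    "compute_metrics",
    "split_dataset",
    "make_cv_folds",
    "assemble_model",
    "train_model",
    "evaluate",
    "predict_probabilities",
    "run_training_protocol",
]

BCE_EPS = 1e-7

VARIANTS = ("full", "without_mimm", "without_cpa")


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PredictionHeadConfig:
    """Shape of the fully connected prediction head."""

    fcn_layer_sizes: tuple[int, ...] = (512, 128)
    dropout_rate: float = 0.1
    leaky_slope: float = 0.01
    decision_threshold: float = 0.5


@dataclass
class ModelConfig:
    """All architectural hyper-parameters of the interaction model.

    Maximum lengths default to values sized from typical protein/SMILES
    length distributions (longer inputs are right-truncated); embedding and
    channel widths are conventional defaults — none of these are forced by
    the method itself and all are configurable.
    """

    sub_embed_dim: int = 64
    ori_embed_dim: int = 64
    channels: tuple[int, int, int] = (64, 96, 128)
    drug_kernels: tuple[int, int, int] = DRUG_KERNELS
    protein_kernels: tuple[int, int, int] = PROTEIN_KERNELS
    activation: str = "relu"
    padding_mode: str = "same"
    max_drug_sub: int = 50
    max_drug_ori: int = 100
    max_protein_sub: int = 545
    max_protein_ori: int = 1000
    heads: int = 8
    head_dim: int = 16
    num_stacked_layers: int = 1
    attention_dropout: float = 0.1
    ffn_mult: int = 4
    head: PredictionHeadConfig = field(default_factory=PredictionHeadConfig)
    # substructure-vocabulary fitting defaults
    vocab_min_freq_drug: int = 8
    vocab_min_freq_protein: int = 30
    vocab_max_size: int = 10_000

    @property
    def max_lens(self) -> dict[str, int]:
        return {
            "drug_sub": self.max_drug_sub,
            "drug_ori": self.max_drug_ori,
            "protein_sub": self.max_protein_sub,
            "protein_ori": self.max_protein_ori,
        }


@dataclass
class TrainConfig:
    """Optimisation protocol; the seed fixes every stochastic choice."""

    variant: str = "full"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected {VARIANTS}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """AUC, AUPR, accuracy, precision and recall for one prediction set.

    AUC/AUPR are None when the labels contain a single class (undefined);
    precision falls back to 0 with ``precision_degenerate`` set when no
    positive prediction was made.
    """

    auc: float | None
    aupr: float | None
    acc: float
    precision: float
    recall: float
    counts: ConfusionCounts
    precision_degenerate: bool = False

    def as_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> MetricsReport:
    """Threshold the probabilities and compute the five study metrics.

    AUC is the area under the ROC curve; AUPR the trapezoidal area under the
    precision-recall curve.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have the same length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    counts = ConfusionCounts(tp, fp, tn, fn)
    degenerate = (tp + fp) == 0
    precision = 0.0 if degenerate else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    acc = (tp + tn) / counts.total
    if len(np.unique(y)) < 2:
        auc_val = aupr_val = None
    else:
        auc_val = float(roc_auc_score(y, p))
        prec_curve, rec_curve, _ = precision_recall_curve(y, p)
        aupr_val = float(_sk_auc(rec_curve, prec_curve))
    return MetricsReport(
        auc=auc_val,
        aupr=aupr_val,
        acc=acc,
        precision=precision,
        recall=recall,
        counts=counts,
        precision_degenerate=degenerate,
    )


@dataclass
class CrossValReport:
    """Per-fold metric reports plus their mean (None-aware)."""

    folds: list[MetricsReport]
    mean: dict[str, float | None]

    @staticmethod
    def from_folds(folds: list[MetricsReport]) -> "CrossValReport":
        mean = {}
        for key in ("auc", "aupr", "acc", "precision", "recall"):
            vals = [getattr(f, key) for f in folds if getattr(f, key) is not None]
            mean[key] = float(np.mean(vals)) if vals else None
        return CrossValReport(folds=folds, mean=mean)

    def as_dict(self) -> dict:
        return {"folds": [f.as_dict() for f in self.folds], "mean": self.mean}


# ---------------------------------------------------------------------------
# head operations
# ---------------------------------------------------------------------------

def global_max_pool(fmap: FeatureMap) -> Tensor:
    """Per-channel maximum over the unmasked positions of a feature map."""
    return ag.masked_max(fmap.values, fmap.mask)


def concat_features(d_pool: Tensor, p_pool: Tensor) -> Tensor:
    """Concatenate pooled drug and protein vectors, drug first."""
    if d_pool.shape[-1] != p_pool.shape[-1]:
        raise ValueError(
            f"pooled dims differ: drug {d_pool.shape[-1]} vs protein "
            f"{p_pool.shape[-1]}"
        )
    return ag.concat([d_pool, p_pool], axis=-1)


class PredictionHead:
    """Alternating affine / Leaky-ReLU / dropout layers ending in a sigmoid."""

    def __init__(self, in_dim: int, cfg: PredictionHeadConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        sizes = [in_dim, *cfg.fcn_layer_sizes, 1]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for nin, nout in zip(sizes, sizes[1:]):
            bound = np.sqrt(6.0 / (nin + nout))
            self.weights.append(ag.parameter(rng.uniform(-bound, bound, (nin, nout))))
            self.biases.append(ag.parameter(np.zeros(nout)))

    def parameters(self):
        return self.weights + self.biases


def fcn_predict(vc: Tensor, head: PredictionHead, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
    """Forward the concatenated feature vector to a probability in (0, 1)."""
    cfg = head.cfg
    x = ag.astensor(vc)
    n_layers = len(head.weights)
    for i, (w, b) in enumerate(zip(head.weights, head.biases)):
        x = ag.add(ag.matmul(x, w), b)
        if i < n_layers - 1:
            x = ag.leaky_relu(x, cfg.leaky_slope)
            if training and cfg.dropout_rate > 0.0:
                x = ag.dropout(x, cfg.dropout_rate, rng, training=True)
    prob = ag.sigmoid(x)
    if prob.ndim >= 1 and prob.shape[-1] == 1:
        prob = prob.reshape(prob.shape[:-1])
    return prob


def bce_loss(y_true, y_prob) -> Tensor:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(y_true, dtype=np.float64)
    p = ag.clip(ag.astensor(y_prob), BCE_EPS, 1.0 - BCE_EPS)
    ll = ag.add(ag.mul(ag.log(p), y), ag.mul(ag.log(1.0 - p), 1.0 - y))
    return ag.mean_(ag.mul(ll, -1.0))


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def split_dataset(records: list, ratio: float, seed: int) -> tuple[list, list]:
    """Disjoint, exhaustive random train/test partition under a seed."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(ratio * len(records)))
    n_train = min(max(n_train, 1), len(records) - 1)
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def make_cv_folds(records: list, k: int = 5, seed: int = 0
                  ) -> list[tuple[list, list]]:
    """k folds with pairwise-disjoint validation sets of near-equal size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"cannot make {k} folds from {len(records)} records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    parts = np.array_split(order, k)
    folds = []
    for i in range(k):
        valid_idx = set(parts[i].tolist())
        valid = [records[j] for j in parts[i]]
        train = [records[j] for j in order if j not in valid_idx]
        folds.append((train, valid))
    return folds


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

class DTIModel:
    """The assembled interaction predictor (full model or an ablation).

    ``full`` uses all four streams and the attention cascade;
    ``without_mimm`` keeps only the original-sequence streams (no vocabulary
    required) with self/cross attention over them; ``without_cpa`` keeps all
    four streams but feeds the concatenated CNN maps directly to pooling.
    """

    def __init__(self, variant: str, drug_vocab: Vocabulary | None,
                 protein_vocab: Vocabulary | None, cfg: ModelConfig,
                 seed: int = 0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if variant != "without_mimm":
            if drug_vocab is None or protein_vocab is None:
                raise ValueError(f"variant {variant!r} requires fitted vocabularies")
        self.variant = variant
        self.cfg = cfg
        self.drug_vocab = drug_vocab if variant != "without_mimm" else None
        self.protein_vocab = protein_vocab if variant != "without_mimm" else None
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

        c = cfg.channels[-1]
        drug_cnn = CnnBranchConfig(cfg.drug_kernels, cfg.channels,
                                   cfg.activation, cfg.padding_mode)
        prot_cnn = CnnBranchConfig(cfg.protein_kernels, cfg.channels,
                                   cfg.activation, cfg.padding_mode)

        def make_stream(vocab_size, max_len, dim, cnn_cfg):
            return StreamEncoder(
                EmbeddingTable(vocab_size, max_len, dim, rng),
                CnnBranch(cnn_cfg, dim, rng),
            )

        self.encoders: dict[str, StreamEncoder] = {
            "drug_ori": make_stream(len(SMILES_ALPHABET), cfg.max_drug_ori,
                                    cfg.ori_embed_dim, drug_cnn),
            "protein_ori": make_stream(len(PROTEIN_ALPHABET), cfg.max_protein_ori,
                                       cfg.ori_embed_dim, prot_cnn),
        }
        if self.variant != "without_mimm":
            self.encoders["drug_sub"] = make_stream(
                self.drug_vocab.size, cfg.max_drug_sub, cfg.sub_embed_dim, drug_cnn
            )
            self.encoders["protein_sub"] = make_stream(
                self.protein_vocab.size, cfg.max_protein_sub, cfg.sub_embed_dim,
                prot_cnn,
            )

        self.attention_cfg = AttentionConfig(
            model_dim=c,
            heads=cfg.heads,
            head_dim=cfg.head_dim,
            dropout_rate=cfg.attention_dropout,
            num_stacked_layers=cfg.num_stacked_layers,
            ffn_mult=cfg.ffn_mult,
        )
        self.stack = (
            CpaStack(self.attention_cfg, rng) if variant != "without_cpa" else None
        )
        self.head = PredictionHead(2 * c, cfg.head, rng)

    # -- parameters --------------------------------------------------------
    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out = []
        for name, enc in sorted(self.encoders.items()):
            for i, p in enumerate(enc.parameters()):
                out.append((f"encoder.{name}.{i}", p))
        if self.stack is not None:
            for li, layer in enumerate(self.stack.layers):
                for uname, unit in layer.items():
                    for i, p in enumerate(unit.parameters()):
                        out.append((f"cpa.{li}.{uname}.{i}", p))
        for i, p in enumerate(self.head.parameters()):
            out.append((f"head.{i}", p))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    # -- data encoding -----------------------------------------------------
    def encode_dataset(self, records) -> tuple[EncodedPair, np.ndarray]:
        smiles = [r.smiles for r in records]
        prots = [r.protein for r in records]
        labels = np.array([r.label for r in records], dtype=int)
        pair = encode_records(smiles, prots, self.drug_vocab,
                              self.protein_vocab, self.cfg.max_lens)
        return pair, labels

    # -- forward -----------------------------------------------------------
    def forward(self, pair: EncodedPair, training: bool = False) -> Tensor:
        rng = self._dropout_rng if training else None
        fmaps = encode_pair(pair, self.encoders)
        if self.variant == "without_mimm":
            pcnn, dcnn = fmaps["protein_ori"], fmaps["drug_ori"]
        else:
            pcnn = _concat_fm(fmaps["protein_sub"], fmaps["protein_ori"])
            dcnn = _concat_fm(fmaps["drug_sub"], fmaps["drug_ori"])
        if self.stack is None:
            pf, df = pcnn, dcnn
        else:
            pf, df = run_stack_features(pcnn, dcnn, self.stack,
                                        self.attention_cfg, training, rng)
        d_pool = global_max_pool(df)
        p_pool = global_max_pool(pf)
        vc = concat_features(d_pool, p_pool)
        return fcn_predict(vc, self.head, training=training, rng=rng)


def assemble_model(cfg: TrainConfig, vocabs: tuple[Vocabulary | None,
                                                   Vocabulary | None],
                   model_cfg: ModelConfig) -> DTIModel:
    """Build the model variant requested by the training configuration."""
    drug_vocab, protein_vocab = vocabs
    return DTIModel(cfg.variant, drug_vocab, protein_vocab, model_cfg,
                    seed=cfg.seed)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def _slice_pair(pair: EncodedPair, idx: np.ndarray) -> EncodedPair:
    return EncodedPair(
        drug_sub=pair.drug_sub[idx], drug_sub_mask=pair.drug_sub_mask[idx],
        drug_ori=pair.drug_ori[idx], drug_ori_mask=pair.drug_ori_mask[idx],
        protein_sub=pair.protein_sub[idx],
        protein_sub_mask=pair.protein_sub_mask[idx],
        protein_ori=pair.protein_ori[idx],
        protein_ori_mask=pair.protein_ori_mask[idx],
    )


def predict_probabilities(model: DTIModel, pair: EncodedPair,
                          batch_size: int = 64) -> np.ndarray:
    """Deterministic (eval-mode) forward pass over a dataset in batches."""
    n = pair.drug_ori.shape[0]
    out = np.empty(n)
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        out[idx] = model.forward(_slice_pair(pair, idx), training=False).data
    return out


def train_model(model: DTIModel, train_records, valid_records,
                cfg: TrainConfig, log_fn=None
                ) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Minimise BCE with Adam; early-stop on validation AUC.

    Stops once validation AUC has not improved for more than ``patience``
    consecutive epochs (patience=0 stops right after the first non-improving
    epoch). Returns the best-validation weights and the per-epoch history.
    """
    if not train_records or not valid_records:
        raise ValueError("train and validation sets must be non-empty")
    if cfg.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    rng = np.random.default_rng(cfg.seed)
    train_pair, train_y = model.encode_dataset(train_records)
    valid_pair, valid_y = model.encode_dataset(valid_records)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_auc = -np.inf
    best_state = model.state_dict()
    since_best = 0
    history: list[dict] = []
    n = len(train_records)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = model.forward(_slice_pair(train_pair, idx), training=True)
            loss = bce_loss(train_y[idx], probs)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_probs = predict_probabilities(model, valid_pair, cfg.batch_size)
        report = compute_metrics(valid_y, val_probs,
                                 model.cfg.head.decision_threshold)
        val_auc = report.auc if report.auc is not None else -report.acc
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_auc": float(val_auc),
        }
        history.append(entry)
        if log_fn is not None:
            log_fn(f"epoch {epoch}: loss={entry['train_loss']:.4f} "
                   f"val_auc={entry['val_auc']:.4f}")
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    model.load_state_dict(best_state)
    return best_state, history


def evaluate(model: DTIModel, weights: dict[str, np.ndarray] | None,
             test_records, cfg: TrainConfig,
             batch_size: int | None = None) -> MetricsReport:
    """Eval-mode forward pass over a held-out set, reporting all five metrics."""
    if weights is not None:
        model.load_state_dict(weights)
    pair, labels = model.encode_dataset(test_records)
    probs = predict_probabilities(model, pair,
                                  batch_size or cfg.batch_size)
    return compute_metrics(labels, probs, model.cfg.head.decision_threshold)


def run_training_protocol(records, train_cfg: TrainConfig,
                          model_cfg: ModelConfig, k: int = 5,
                          split_ratio: float = 0.8, log_fn=None) -> dict:
    """The full study protocol on one dataset.

    80:20 split; substructure vocabularies fitted once on the training split
    only (never on test); 5-fold cross validation with early stopping inside
    the training split; each fold's best model evaluated on the held-out test
    set; the final numbers are per-fold means.
    """
    from .tokenizer import fit_vocabulary  # local import to avoid cycle

    train, test = split_dataset(records, split_ratio, train_cfg.seed)
    if train_cfg.variant != "without_mimm":
        drug_vocab = fit_vocabulary(
            [r.smiles for r in train], model_cfg.vocab_min_freq_drug,
            model_cfg.vocab_max_size, kind="drug",
        )
        protein_vocab = fit_vocabulary(
            [r.protein for r in train], model_cfg.vocab_min_freq_protein,
            model_cfg.vocab_max_size, kind="protein",
        )
    else:
        drug_vocab = protein_vocab = None
    folds = make_cv_folds(train, k=k, seed=train_cfg.seed)
    val_reports, test_reports = [], []
    for fold_i, (fold_train, fold_valid) in enumerate(folds):
        fold_cfg = dc_replace(train_cfg, seed=train_cfg.seed + fold_i)
        model = assemble_model(fold_cfg, (drug_vocab, protein_vocab), model_cfg)
        weights, _ = train_model(model, fold_train, fold_valid, fold_cfg,
                                 log_fn=log_fn)
        val_pair, val_y = model.encode_dataset(fold_valid)
        val_probs = predict_probabilities(model, val_pair, fold_cfg.batch_size)
        val_reports.append(compute_metrics(val_y, val_probs,
                                           model_cfg.head.decision_threshold))
        test_reports.append(evaluate(model, weights, test, fold_cfg))
        if log_fn is not None:
            log_fn(f"fold {fold_i}: test_auc="
                   f"{test_reports[-1].auc}")
    return {
        "validation": CrossValReport.from_folds(val_reports),
        "test": CrossValReport.from_folds(test_reports),
        "vocabularies": (drug_vocab, protein_vocab),
    }


def report_to_json(report: dict, path) -> None:
    """Serialise a protocol result (per-fold and mean metrics) to JSON."""
    payload = {
        "validation": report["validation"].as_dict(),
        "test": report["test"].as_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
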