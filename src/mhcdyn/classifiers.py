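"""Immunogenicity classifiers: MD-graph convolutional network, reference
sequence CNN, and SASA-feature reference model, plus training and evaluation.

The MD-graph model encodes each of the LL (intramolecular peptide) and LP
(MHC-peptide) contact graphs through three convolutional modules; each module
holds one neighbor-convolution submodule per distance bin whose edge-weighted
messages are aggregated and pooled into the next node state. Final node states
pass through a fully connected layer, are gathered over peptide atoms, max-
and average-pooled into a per-graph embedding; the two embeddings are
concatenated, passed through a dense layer and a binary softmax.

The sequence model one-hot encodes the 9-mer with residue columns ordered by
six residue similarity classes and applies a 2-D convolution spanning both the
position and the ordered-residue axes. The SASA model is a small dense network
over per-position SASA window statistics.

Training uses cross-entropy; the graph and SASA models use an adaptive-moment
(Adam) optimizer, the sequence model plain stochastic gradient descent, which
is the more stable choice for that architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from . import nn
from .io import PeptideRecord, ValidationError
from .molgraphs import MolecularGraph
from .nn import Tensor

logger = logging.getLogger(__name__)


class ClassError(ValueError):
    """Both classes are required."""


class StateError(RuntimeError):
    """Model used before training."""


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

#: Six residue similarity classes fixing the one-hot column order.
RESIDUE_SIMILARITY_CLASSES: dict[str, str] = {
    "aliphatic": "AVLIMC",
    "aromatic": "FWYH",
    "polar": "STNQ",
    "positive": "KR",
    "negative": "DE",
    "special": "GP",
}

RESIDUE_ORDER: str = "".join(RESIDUE_SIMILARITY_CLASSES.values())  # 20 letters
_COL = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}


def encode_sequence(sequence: str) -> np.ndarray:
    """9 x 20 one-hot with residue columns ordered by similarity class."""
    if len(sequence) != 9:
        raise ValidationError("sequence must be a 9-mer")
    out = np.zeros((9, 20))
    for i, aa in enumerate(sequence):
        if aa not in _COL:
            raise ValidationError(f"unknown residue {aa!r}")
        out[i, _COL[aa]] = 1.0
    return out


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass
class GraphNetConfig:
    n_conv_modules: int = 3  # fixed by the architecture
    hidden_width: int = 16
    fc_width: int = 16
    dense_width: int = 32
    n_bins: int = 4
    dropout: float = 0.0
    optimizer: str = "adam"
    learning_rate: float = 3e-3
    batch_size: int = 100
    max_epochs: int = 140
    plateau_window: int = 5
    plateau_tol: float = 1e-3
    plateau_min_epochs: int = 30


@dataclass
class SequenceNetConfig:
    channels: int = 16
    kernel_positions: int = 3  # physical (residue index) axis
    kernel_residues: int = 20  # chemical (ordered similarity) axis
    dense_width: int = 32
    optimizer: str = "sgd"
    learning_rate: float = 0.1
    batch_size: int = 100
    max_epochs: int = 140
    plateau_window: int = 5
    plateau_tol: float = 1e-3
    plateau_min_epochs: int = 30


@dataclass
class SasaNetConfig:
    hidden_width: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-2
    batch_size: int = 100
    max_epochs: int = 200
    plateau_window: int = 5
    plateau_tol: float = 1e-3
    plateau_min_epochs: int = 30


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

N_NODE_FEATURES = 6  # element one-hot {C,N,O,S} + backbone flag + position scalar


class GraphConvNet:
    """Two-encoder (LL + LP) distance-binned graph convolutional classifier."""

    def __init__(self, config: GraphNetConfig | None = None, seed: int = 0):
        self.config = config or GraphNetConfig()
        rng = np.random.default_rng(seed)
        c = self.config
        self.encoders = {}
        for kind in ("LL", "LP"):
            widths = [N_NODE_FEATURES] + [c.hidden_width] * c.n_conv_modules
            modules = []
            for m in range(c.n_conv_modules):
                modules.append(
                    {
                        "self": nn.he_init(rng, widths[m], widths[m + 1]),
                        "bins": [nn.he_init(rng, widths[m], widths[m + 1])
                                 for _ in range(c.n_bins)],
                        "bias": nn.zeros(widths[m + 1]),
                    }
                )
            fc_w = nn.he_init(rng, c.hidden_width, c.fc_width)
            fc_b = nn.zeros(c.fc_width)
            self.encoders[kind] = {"modules": modules, "fc_w": fc_w, "fc_b": fc_b}
        self.dense_w = nn.he_init(rng, 4 * c.fc_width, c.dense_width)
        self.dense_b = nn.zeros(c.dense_width)
        self.out_w = nn.he_init(rng, c.dense_width, 2)
        self.out_b = nn.zeros(2)

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for enc in self.encoders.values():
            for mod in enc["modules"]:
                ps.append(mod["self"])
                ps.extend(mod["bins"])
                ps.append(mod["bias"])
            ps.extend([enc["fc_w"], enc["fc_b"]])
        ps.extend([self.dense_w, self.dense_b, self.out_w, self.out_b])
        return ps

    def _encode(self, graph: MolecularGraph, kind: str) -> Tensor:
        enc = self.encoders[kind]
        h = Tensor(graph.node_features)
        adj = [Tensor(a) for a in graph.adjacency_per_bin()]
        for mod in enc["modules"]:
            msg = h @ mod["self"]
            for a, w in zip(adj, mod["bins"]):
                msg = msg + a @ (h @ w)  # edge-weighted neighbor aggregation
            h = (msg + mod["bias"]).relu()
        z = (h @ enc["fc_w"] + enc["fc_b"]).relu()
        pep = z[graph.peptide_rows]  # gather over peptide atoms
        return nn.concat([pep.max(axis=0), pep.mean(axis=0)], axis=0)

    def forward(self, ll: MolecularGraph, lp: MolecularGraph) -> Tensor:
        """Logits (1, 2) for one frame's LL/LP graph pair."""
        emb = nn.concat([self._encode(ll, "LL"), self._encode(lp, "LP")], axis=0)
        d = (emb.reshape(1, -1) @ self.dense_w + self.dense_b).relu()
        return d @ self.out_w + self.out_b

    def forward_batch(self, samples: Sequence[tuple[MolecularGraph, MolecularGraph]]) -> Tensor:
        return nn.concat([self.forward(ll, lp) for ll, lp in samples], axis=0)

    def predict_proba(self, samples) -> np.ndarray:
        """P(immunogenic) per (ll, lp) sample."""
        logits = self.forward_batch(samples)
        return nn.softmax(logits.data)[:, 1]


class SequenceConvNet:
    """2-D convolutional classifier over the similarity-ordered one-hot."""

    def __init__(self, config: SequenceNetConfig | None = None, seed: int = 0):
        self.config = c = config or SequenceNetConfig()
        rng = np.random.default_rng(seed)
        kh, kw = c.kernel_positions, c.kernel_residues
        ph, pw = 9 - kh + 1, 20 - kw + 1
        # patch-extraction indices into the flattened (9*20,) encoding
        idx = np.empty((ph * pw, kh * kw), dtype=int)
        p = 0
        for i in range(ph):
            for j in range(pw):
                rows, cols = np.meshgrid(np.arange(i, i + kh), np.arange(j, j + kw),
                                         indexing="ij")
                idx[p] = (rows * 20 + cols).ravel()
                p += 1
        self.patch_idx = idx
        self.n_pos_patches = ph
        self.n_chem_patches = pw
        self.kernel = nn.he_init(rng, kh * kw, c.channels)
        self.kernel_b = nn.zeros(c.channels)
        # pooling runs over the chemical axis only: a position-specific motif
        # must stay localized on the physical (residue index) axis
        self.dense1_w = nn.he_init(rng, ph * c.channels, c.dense_width)
        self.dense1_b = nn.zeros(c.dense_width)
        self.dense2_w = nn.he_init(rng, c.dense_width, c.dense_width)
        self.dense2_b = nn.zeros(c.dense_width)
        self.out_w = nn.he_init(rng, c.dense_width, 2)
        self.out_b = nn.zeros(2)

    @property
    def params(self) -> list[Tensor]:
        return [self.kernel, self.kernel_b, self.dense1_w, self.dense1_b,
                self.dense2_w, self.dense2_b, self.out_w, self.out_b]

    def forward_batch(self, encodings: np.ndarray) -> Tensor:
        """Logits (B, 2) from encodings (B, 9, 20)."""
        enc = np.asarray(encodings, dtype=float)
        if enc.ndim == 2:
            enc = enc[None]
        if enc.shape[1:] != (9, 20):
            raise ValidationError(f"expected (B, 9, 20) encodings, got {enc.shape}")
        x = Tensor(enc.reshape(len(enc), -1))
        patches = x.take_axis1(self.patch_idx)  # (B, ph*pw, kh*kw)
        conv = (patches @ self.kernel + self.kernel_b).relu()  # (B, ph*pw, C)
        b = conv.shape[0]
        grid = conv.reshape(b, self.n_pos_patches, self.n_chem_patches, -1)
        pooled = grid.max(axis=2).reshape(b, -1)  # (B, ph*C), position kept
        h = (pooled @ self.dense1_w + self.dense1_b).relu()
        h = (h @ self.dense2_w + self.dense2_b).relu()
        return h @ self.out_w + self.out_b

    def predict_proba(self, sequences: Sequence[str]) -> np.ndarray:
        enc = np.stack([encode_sequence(s) for s in sequences])
        return nn.softmax(self.forward_batch(enc).data)[:, 1]


class SasaNet:
    """Small dense network over per-position SASA window statistics."""

    def __init__(self, n_features: int, config: SasaNetConfig | None = None, seed: int = 0):
        self.config = c = config or SasaNetConfig()
        self.n_features = n_features
        rng = np.random.default_rng(seed)
        self.w1 = nn.he_init(rng, n_features, c.hidden_width)
        self.b1 = nn.zeros(c.hidden_width)
        self.w2 = nn.he_init(rng, c.hidden_width, 2)
        self.b2 = nn.zeros(2)

    @property
    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def forward_batch(self, features: np.ndarray) -> Tensor:
        f = np.asarray(features, dtype=float)
        if f.ndim == 1:
            f = f[None]
        if f.shape[1] != self.n_features:
            raise ValidationError(f"expected {self.n_features} features, got {f.shape[1]}")
        h = (Tensor(f) @ self.w1 + self.b1).relu()
        return h @ self.w2 + self.b2

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward_batch(features).data)[:, 1]


def sasa_feature_vector(per_frame_sasa: Sequence) -> np.ndarray:
    """Per-position mean and SD of total and hydrophobic SASA over a window.

    ``per_frame_sasa`` is a sequence of :class:`~mhcdyn.observables.ResidueSASA`
    for one peptide; returns a fixed-length (9 * 4,) vector.
    """
    totals = np.stack([s.values for s in per_frame_sasa])  # (n_frames, 9)
    hydro = np.stack([np.where(s.hydrophobic_mask, s.values, 0.0) for s in per_frame_sasa])
    return np.concatenate([
        totals.mean(axis=0), totals.std(axis=0), hydro.mean(axis=0), hydro.std(axis=0)
    ])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainingLog:
    epoch_losses: list[float] = field(default_factory=list)
    stopped_early: bool = False

    @property
    def final_loss(self) -> float:
        return self.epoch_losses[-1]


@dataclass
class TrainedModel:
    kind: str  # "graph" | "sequence" | "sasa"
    model: object
    log: TrainingLog
    seed: int


@dataclass
class Prediction:
    """Per-frame and peptide-level P(immunogenic)."""

    peptide_id: str
    frame_probs: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.frame_probs = np.atleast_1d(np.asarray(self.frame_probs, dtype=float))
        if np.any((self.frame_probs < 0) | (self.frame_probs > 1)):
            raise ValidationError("probabilities must lie in [0, 1]")

    @property
    def p_immunogenic(self) -> float:
        """Peptide-level value: mean of the per-frame softmax outputs."""
        return float(self.frame_probs.mean())


def _label01(rec: PeptideRecord) -> int:
    return int(rec.is_immunogenic)


def _plateau(losses: list[float], window: int, tol: float, min_epochs: int = 0) -> bool:
    if len(losses) < max(2 * window, min_epochs):
        return False
    recent = np.mean(losses[-window:])
    prev = np.mean(losses[-2 * window : -window])
    return abs(prev - recent) <= tol * max(abs(prev), 1e-12)


def _fit(model, examples, labels, seed: int) -> TrainingLog:
    """Mini-batch cross-entropy loop with plateau-based early stopping."""
    c = model.config
    if c.optimizer == "adam":
        opt = nn.Adam(model.params, lr=c.learning_rate)
    elif c.optimizer == "sgd":
        opt = nn.SGD(model.params, lr=c.learning_rate)
    else:
        raise ValidationError(f"unknown optimizer {c.optimizer!r}")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    log = TrainingLog()
    n = len(labels)
    batched_input = isinstance(examples, np.ndarray)
    for _epoch in range(c.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, c.batch_size):
            sel = order[start : start + c.batch_size]
            if batched_input:
                logits = model.forward_batch(examples[sel])
            else:
                logits = model.forward_batch([examples[i] for i in sel])
            loss = nn.softmax_cross_entropy(logits, labels[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.epoch_losses.append(float(np.mean(losses)))
        if _plateau(log.epoch_losses, c.plateau_window, c.plateau_tol,
                    getattr(c, 'plateau_min_epochs', 0)):
            log.stopped_early = True
            break
    return log


def train(
    model_kind: str,
    records: Sequence[PeptideRecord],
    graphs: Mapping[str, Sequence[tuple[MolecularGraph, MolecularGraph]]] | None = None,
    sasa_features: Mapping[str, np.ndarray] | None = None,
    config=None,
    seed: int = 0,
) -> TrainedModel:
    """Train one classifier on the given training records.

    * ``sequence`` needs only the records;
    * ``graph`` needs ``graphs``: per-sequence lists of per-frame (LL, LP)
      pairs (built from production frames only — the equilibration window is
      excluded at graph-construction time); each frame inherits the peptide's
      label;
    * ``sasa`` needs ``sasa_features``: per-sequence fixed-length vectors.
    """
    records = list(records)
    y_pep = [_label01(r) for r in records]
    if len(set(y_pep)) < 2:
        raise ClassError("training set must contain both classes")

    if model_kind == "sequence":
        model = SequenceConvNet(config, seed=seed)
        x = np.stack([encode_sequence(r.sequence) for r in records])
        log = _fit(model, x, y_pep, seed)
    elif model_kind == "graph":
        if graphs is None:
            raise ValidationError("graph training requires per-peptide graph samples")
        samples, y = [], []
        for rec in records:
            for pair in graphs[rec.sequence]:
                samples.append(pair)
                y.append(_label01(rec))
        model = GraphConvNet(config, seed=seed)
        log = _fit(model, samples, y, seed)
    elif model_kind == "sasa":
        if sasa_features is None:
            raise ValidationError("sasa training requires per-peptide feature vectors")
        x = np.stack([np.asarray(sasa_features[r.sequence], float) for r in records])
        model = SasaNet(x.shape[1], config, seed=seed)
        log = _fit(model, x, y_pep, seed)
    else:
        raise ValidationError(f"unknown model kind {model_kind!r}")
    return TrainedModel(kind=model_kind, model=model, log=log, seed=seed)


def predict(trained: TrainedModel, inputs, labels: Mapping[str, str] | None = None) -> list[Prediction]:
    """Predictions for a batch of peptides.

    ``inputs`` is a mapping peptide id -> payload: a list of (LL, LP) frame
    pairs for the graph model, the 9-mer string for the sequence model, a
    feature vector for the SASA model. Peptide-level P(imm) is the mean of the
    per-frame values; single-valued models emit one value per peptide.
    """
    if not isinstance(trained, TrainedModel):
        raise StateError("predict() requires a TrainedModel")
    out = []
    for pid, payload in inputs.items():
        if trained.kind == "graph":
            probs = trained.model.predict_proba(payload)
        elif trained.kind == "sequence":
            probs = trained.model.predict_proba([payload])
        else:
            probs = trained.model.predict_proba(np.asarray(payload, float))
        out.append(Prediction(peptide_id=pid, frame_probs=probs,
                              label=None if labels is None else labels.get(pid)))
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_auc(predictions: Sequence[Prediction], labels: Mapping[str, str]) -> float:
    """AUROC of peptide-level P(imm) with ties counted 1/2."""
    y = np.array([1 if labels[p.peptide_id] == "immunogenic" else 0 for p in predictions])
    s = np.array([p.p_immunogenic for p in predictions])
    if len(set(y.tolist())) < 2:
        raise ClassError("AUROC needs both classes")
    return float(roc_auc_score(y, s))


def compare_models(
    preds_a: Sequence[Prediction], preds_b: Sequence[Prediction]
) -> dict[str, float]:
    """Pearson correlation between two models' peptide-level probabilities."""
    b_by_id = {p.peptide_id: p for p in preds_b}
    pairs = [(p.p_immunogenic, b_by_id[p.peptide_id].p_immunogenic)
             for p in preds_a if p.peptide_id in b_by_id]
    if len(pairs) < 3:
        raise ValidationError("need >= 3 paired predictions")
    a, b = np.array(pairs).T
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("degenerate (zero-variance) prediction set")
    r, p = sstats.pearsonr(a, b)
    return {"pearson_r": float(r), "r_squared": float(r**2), "p_r": float(p)}
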