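"""One-vs-all online linear classifiers over gapped k-mer features.

One binary scorer (sparse linear model with bias) is trained per EC label,
plus one for an explicit background class built from composition-preserving
shuffles of real proteins. Training is online — one encoded example in
memory at a time — with hinge-loss (linear SVM) stochastic gradient descent,
L2 regularization via a lazily applied weight-scale factor, and an
inverse-scaling learning rate. The background class gives the ensemble a
reject option: a fragment is left unassigned unless some EC score beats
both zero and the background score, which suppresses forced spurious labels
on reads that come from no modeled enzyme family.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .lsh import GallagerHashEnsemble, SparseFeatureVector, encode_sequence
from .reference_db import GoldStandard

logger = logging.getLogger(__name__)

NEGATIVE = "__negative__"
UNASSIGNED = "__unassigned__"


class TrainingError(ValueError):
    pass


@dataclass
class Hyperparameters:
    loss: str = "hinge"  # or "logistic"
    eta0: float = 0.5
    l2: float = 1e-6
    epochs: int = 5
    fragment_length: int = 30  # training fragment length, amino acids
    fragments_per_protein: int = 10
    negative_ratio: float = 1.0  # negatives per positive protein
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        return cls(**d)


@dataclass
class TrainingExample:
    features: SparseFeatureVector
    label: str


def generate_negatives(
    background: Sequence[str], n_per_seq: int, seed: int
) -> list[str]:
    """Composition-preserving shuffles of background sequences.

    Each output is a uniform random permutation (seeded Fisher-Yates) of one
    background sequence's residues, so the residue multiset is preserved
    while any positional signal is destroyed — the background class the
    ensemble trains against.
    """
    if not background:
        raise ValueError("background must be non-empty")
    if n_per_seq < 1:
        raise ValueError("n_per_seq must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for seq in background:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for _ in range(n_per_seq):
            out.append(rng.permutation(arr).tobytes().decode("ascii"))
    return out


class TrainingStream:
    """Re-iterable stream of encoded training examples in seeded shuffled order.

    The sampling plan (which protein, which fragment start, which label) is
    fixed at construction; encoding happens lazily during iteration so only
    a constant number of encoded examples is ever materialized.
    """

    def __init__(
        self,
        gold: GoldStandard,
        negatives: Sequence[str],
        ens: GallagerHashEnsemble,
        fragment_length: int = 30,
        fragments_per_protein: int = 10,
        seed: int = 0,
        fold_bits: int | None = None,
    ) -> None:
        if fragment_length < ens.k:
            raise ValueError(f"fragment_length {fragment_length} < k {ens.k}")
        self.ens = ens
        self.fold_bits = fold_bits
        rng = np.random.default_rng(seed)
        plan: list[tuple[str, int, int, str]] = []  # (sequence, start, length, label)
        for rec in gold.records:
            if len(rec.sequence) < ens.k:
                logger.warning("skipping %s: length %d < k=%d", rec.id, len(rec.sequence), ens.k)
                continue
            frag_len = min(fragment_length, len(rec.sequence))
            n_starts = len(rec.sequence) - frag_len + 1
            starts = rng.integers(0, n_starts, size=fragments_per_protein)
            for s in starts:
                plan.append((rec.sequence, int(s), frag_len, rec.ec_labels[0]))
        for neg in negatives:
            plan.append((neg, 0, len(neg), NEGATIVE))
        order = rng.permutation(len(plan))
        self._plan = [plan[i] for i in order]

    def __len__(self) -> int:
        return len(self._plan)

    def __iter__(self) -> Iterator[TrainingExample]:
        for seq, start, length, label in self._plan:
            fv = encode_sequence(seq[start : start + length], self.ens, self.fold_bits)
            yield TrainingExample(fv, label)

    def labels(self) -> list[str]:
        return [label for *_, label in self._plan]

    def fragments(self) -> list[tuple[str, str]]:
        """(fragment sequence, label) pairs in stream order, un-encoded."""
        return [(seq[s : s + length], label) for seq, s, length, label in self._plan]


def make_training_stream(
    gold: GoldStandard,
    negatives: Sequence[str],
    ens: GallagerHashEnsemble,
    fragment_length: int = 30,
    fragments_per_protein: int = 10,
    seed: int = 0,
    fold_bits: int | None = None,
) -> TrainingStream:
    return TrainingStream(
        gold, negatives, ens, fragment_length, fragments_per_protein, seed, fold_bits
    )


@dataclass
class OvaModel:
    """Weight matrix (one row per label, background row last) plus biases."""

    labels: list[str]  # sorted EC labels, then NEGATIVE
    weights: np.ndarray  # (n_labels, dim) float64
    bias: np.ndarray  # (n_labels,)
    hyper: Hyperparameters
    ensemble: GallagerHashEnsemble
    mean_protein_length: dict[str, float] = field(default_factory=dict)
    fold_bits: int | None = None

    @property
    def ec_labels(self) -> list[str]:
        return [l for l in self.labels if l != NEGATIVE]

    @property
    def dim(self) -> int:
        return self.weights.shape[1]


def _model_dim(ens: GallagerHashEnsemble, fold_bits: int | None) -> int:
    return (1 << fold_bits) if fold_bits is not None else ens.n_features


def train_online(
    stream: TrainingStream,
    epochs: int | None = None,
    hyper: Hyperparameters | None = None,
    model: OvaModel | None = None,
    mean_protein_length: dict[str, float] | None = None,
) -> OvaModel:
    """Train (or warm-start) the one-vs-all ensemble by online SGD.

    Each example updates every label's binary problem (y=+1 for its own
    label, -1 otherwise) under hinge or logistic loss with L2 shrinkage
    applied through a per-label scale factor, and learning rate
    eta_t = eta0 / (1 + eta0 * l2 * t). Deterministic given the stream seed.
    Passing an existing ``model`` warm-starts it: labels new to the stream
    get fresh weight rows, existing rows continue from their current state.
    """
    hyper = hyper or (model.hyper if model is not None else Hyperparameters())
    if epochs is not None:
        hyper = replace(hyper, epochs=epochs)
    ens = stream.ens
    stream_labels = sorted({l for l in stream.labels() if l != NEGATIVE})
    if not stream_labels and NEGATIVE not in stream.labels():
        raise TrainingError("empty training stream")
    if len(stream) == 0:
        raise TrainingError("empty training stream")

    dim = _model_dim(ens, stream.fold_bits)
    if model is None:
        labels = stream_labels + [NEGATIVE]
        V = np.zeros((len(labels), dim), dtype=np.float64)
        bias = np.zeros(len(labels), dtype=np.float64)
    else:
        if model.dim != dim:
            raise TrainingError(f"model dim {model.dim} != stream dim {dim}")
        new = [l for l in stream_labels if l not in model.labels]
        labels = sorted(set(model.ec_labels) | set(stream_labels)) + [NEGATIVE]
        old_index = {l: i for i, l in enumerate(model.labels)}
        V = np.zeros((len(labels), dim), dtype=np.float64)
        bias = np.zeros(len(labels), dtype=np.float64)
        for i, l in enumerate(labels):
            if l in old_index:
                V[i] = model.weights[old_index[l]]
                bias[i] = model.bias[old_index[l]]
        if new:
            logger.info("warm-start: adding %d new labels", len(new))

    label_index = {l: i for i, l in enumerate(labels)}
    L = len(labels)
    scale = np.ones(L, dtype=np.float64)
    eta0, lam = hyper.eta0, hyper.l2
    logistic = hyper.loss == "logistic"
    t = 0
    for _epoch in range(hyper.epochs):
        for ex in stream:
            t += 1
            eta = eta0 / (1.0 + eta0 * lam * t)
            idx = ex.features.indices
            y = np.full(L, -1.0)
            y[label_index[ex.label]] = 1.0
            if idx.size:
                cnt = ex.features.counts.astype(np.float64)
                scores = scale * (V[:, idx] @ cnt) + bias
            else:
                cnt = None
                scores = bias.copy()
            if logistic:
                g = y / (1.0 + np.exp(y * scores))  # d/ds log(1+e^{-ys}) * (-1)
                rows = np.nonzero(np.abs(g) > 1e-12)[0]
                step = eta * g[rows]
            else:
                rows = np.nonzero(y * scores < 1.0)[0]
                step = eta * y[rows]
            if rows.size and cnt is not None:
                V[np.ix_(rows, idx)] += (step / scale[rows])[:, None] * cnt[None, :]
            bias[rows] += step
            scale *= 1.0 - eta * lam
            low = scale < 1e-6
            if low.any():
                V[low] *= scale[low, None]
                scale[low] = 1.0
    W = V * scale[:, None]
    mpl = dict(mean_protein_length or (model.mean_protein_length if model else {}))
    return OvaModel(
        labels=labels,
        weights=W,
        bias=bias,
        hyper=hyper,
        ensemble=ens,
        mean_protein_length=mpl,
        fold_bits=stream.fold_bits,
    )


@dataclass
class Prediction:
    label: str  # EC label or UNASSIGNED
    margin: float
    reason: str | None = None


def predict(
    orfs: Sequence[str],
    model: OvaModel,
    ens: GallagerHashEnsemble | None = None,
) -> list[Prediction]:
    """Score amino-acid fragments against every label and apply the reject rule.

    The winning EC label is reported only if its score strictly exceeds both
    zero and the background score; otherwise the fragment is unassigned.
    Ties between EC labels break to the lexicographically smallest label.
    """
    ens = ens or model.ensemble
    if ens.to_json() != model.ensemble.to_json():
        raise ValueError("hash ensemble does not match the model manifest")
    neg_row = model.labels.index(NEGATIVE)
    ec_rows = [i for i in range(len(model.labels)) if i != neg_row]
    ec_names = [model.labels[i] for i in ec_rows]
    out: list[Prediction] = []
    for seq in orfs:
        if len(seq) < ens.k:
            out.append(Prediction(UNASSIGNED, 0.0, reason="shorter than k"))
            continue
        fv = encode_sequence(seq, ens, model.fold_bits)
        if fv.indices.size == 0:
            out.append(Prediction(UNASSIGNED, 0.0, reason="no valid windows"))
            continue
        cnt = fv.counts.astype(np.float64)
        scores = model.weights[:, fv.indices] @ cnt + model.bias
        ec_scores = scores[ec_rows]
        best = float(ec_scores.max())
        winners = [ec_names[i] for i in np.nonzero(ec_scores == best)[0]]
        label = min(winners)
        if best > 0.0 and best > float(scores[neg_row]):
            out.append(Prediction(label, best))
        else:
            out.append(Prediction(UNASSIGNED, best))
    return out


# ---------------------------------------------------------------------------
# model persistence: manifest.json + ensemble.json + one sparse weights file
# per label (`feature_id<TAB>weight` lines)

_MANIFEST_VERSION = 1


def _safe_name(label: str) -> str:
    return label.replace("/", "_")


def save_model(model: OvaModel, directory: str | Path) -> None:
    d = Path(directory)
    (d / "weights").mkdir(parents=True, exist_ok=True)
    ens_json = model.ensemble.to_json()
    (d / "ensemble.json").write_text(ens_json + "\n")
    manifest = {
        "version": _MANIFEST_VERSION,
        "labels": model.labels,
        "dim": model.dim,
        "fold_bits": model.fold_bits,
        "hyper": model.hyper.to_dict(),
        "mean_protein_length": model.mean_protein_length,
        "ensemble_sha256": hashlib.sha256(ens_json.encode()).hexdigest(),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    for i, label in enumerate(model.labels):
        nz = np.nonzero(model.weights[i])[0]
        with open(d / "weights" / f"{_safe_name(label)}.tsv", "w") as fh:
            fh.write(f"#bias\t{float(model.bias[i])!r}\n")
            for j in nz:
                fh.write(f"{j}\t{float(model.weights[i, j])!r}\n")


def load_model(directory: str | Path) -> OvaModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest["version"] != _MANIFEST_VERSION:
        raise ValueError(f"unsupported model manifest version {manifest['version']}")
    ens_json = (d / "ensemble.json").read_text().strip()
    if hashlib.sha256(ens_json.encode()).hexdigest() != manifest["ensemble_sha256"]:
        raise ValueError("ensemble.json does not match the manifest hash; refusing to load")
    ens = GallagerHashEnsemble.from_json(ens_json)
    labels = manifest["labels"]
    dim = manifest["dim"]
    W = np.zeros((len(labels), dim), dtype=np.float64)
    bias = np.zeros(len(labels), dtype=np.float64)
    for i, label in enumerate(labels):
        with open(d / "weights" / f"{_safe_name(label)}.tsv") as fh:
            for line in fh:
                key, val = line.rstrip("\n").split("\t")
                if key == "#bias":
                    bias[i] = float(val)
                else:
                    W[i, int(key)] = float(val)
    return OvaModel(
        labels=labels,
        weights=W,
        bias=bias,
        hyper=Hyperparameters.from_dict(manifest["hyper"]),
        ensemble=ens,
        mean_protein_length={k: float(v) for k, v in manifest["mean_protein_length"].items()},
        fold_bits=manifest["fold_bits"],
    )


# ---------------------------------------------------------------------------
# naive exact k-mer lookup baseline (evaluation comparator, not the method)


class ExactKmerIndex:
    """Assigns a fragment to the label sharing the most exact k-mers with it.

    A deliberately naive comparator for the gapped-feature classifier: exact
    contiguous k-mer matching has no tolerance for substitutions inside the
    window, so its recall collapses as sequence divergence grows.
    """

    def __init__(self, k: int = 8) -> None:
        self.k = k
        self._index: dict[str, set[str]] = {}

    def add(self, label: str, sequence: str) -> None:
        kmers = self._index.setdefault(label, set())
        for i in range(len(sequence) - self.k + 1):
            kmers.add(sequence[i : i + self.k])

    def predict(self, fragment: str) -> str:
        frag_kmers = {fragment[i : i + self.k] for i in range(len(fragment) - self.k + 1)}
        best_label, best_n = UNASSIGNED, 0
        for label in sorted(self._index):
            n = len(frag_kmers & self._index[label])
            if n > best_n:
                best_label, best_n = label, n
        return best_label
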