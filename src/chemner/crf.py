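"""First-order linear-chain conditional random field for chemical NER.

The model assigns one of the five boundary tags to every token.  Potentials
are linear in binary indicator features: per-position emission features
(the four token features of :mod:`chemner.tagging` for the current,
previous and next token, plus a bias and sequence-boundary markers) and
tag-bigram transition weights, with separate start/stop weights.  Training
maximises the penalised conditional log-likelihood

    L(theta) = sum_s log p(y_s | x_s; theta) - ||theta||^2 / (2 sigma^2)

by L-BFGS; the gradient comes from forward-backward marginals.  Decoding is
Viterbi.  Everything is deterministic given the configuration, and each
persisted model carries metadata (feature template version, hyperparameters,
seed, training document ids) sufficient to reproduce training exactly.

``leave_one_out`` runs the document-level cross-validation protocol: each
document is tagged by a model trained on all the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .tagging import TAGS, extract_features, spans_to_tags, tags_to_spans
from .text import AnnotatedDocument, EntityMention, Token, tokenize

__all__ = ["CrfConfig", "CrfModel", "train", "predict", "leave_one_out"]

FEATURE_TEMPLATE_VERSION = "stem-fix3-num-w1/1"

_K = len(TAGS)
_TAG_INDEX = {t: i for i, t in enumerate(TAGS)}


@dataclass(frozen=True)
class CrfConfig:
    """Training hyperparameters (all surfaced, none hidden).

    sigma : Gaussian prior width; the L2 penalty is ||w||^2 / (2 sigma^2).
    max_iterations : L-BFGS iteration cap.
    seed : base seed recorded in metadata and used to derive per-fold seeds.
    """

    sigma: float = 10.0
    max_iterations: int = 120
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CrfConfig":
        return cls(**{k: mapping[k] for k in ("sigma", "max_iterations", "seed") if k in mapping})


def _position_features(feats, i: int) -> list[str]:
    """Feature strings for position i with a +/-1 context window."""
    out = ["bias"]
    for off, prefix in ((-1, "p:"), (0, ""), (1, "n:")):
        j = i + off
        if j < 0:
            out.append("__BOS__")
        elif j >= len(feats):
            out.append("__EOS__")
        else:
            f = feats[j]
            out.extend(
                (
                    f"{prefix}stem={f.stem}",
                    f"{prefix}pre={f.prefix}",
                    f"{prefix}suf={f.suffix}",
                    f"{prefix}num={f.is_number}",
                )
            )
    return out


def _featurize_tokens(tokens: Sequence[Token]) -> list[list[str]]:
    feats = extract_features(tokens)
    return [_position_features(feats, i) for i in range(len(feats))]


@dataclass
class CrfModel:
    """Trained CRF weights plus reproducibility metadata."""

    feature_index: dict[str, int]
    emission: np.ndarray  # (n_features, K)
    transition: np.ndarray  # (K, K)
    start: np.ndarray  # (K,)
    stop: np.ndarray  # (K,)
    metadata: dict = field(default_factory=dict)

    # -- persistence: JSON weights with a metadata sidecar ------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "feature_index": self.feature_index,
            "emission": self.emission.tolist(),
            "transition": self.transition.tolist(),
            "start": self.start.tolist(),
            "stop": self.stop.tolist(),
        }
        path.write_text(json.dumps(payload), encoding="utf-8")
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.metadata, indent=2), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CrfModel":
        path = Path(path)
        payload = json.loads(path.read_text(encoding="utf-8"))
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = (
            json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
        )
        return cls(
            feature_index=payload["feature_index"],
            emission=np.asarray(payload["emission"]),
            transition=np.asarray(payload["transition"]),
            start=np.asarray(payload["start"]),
            stop=np.asarray(payload["stop"]),
            metadata=metadata,
        )


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return np.squeeze(m, axis=axis) + np.log(
        np.exp(a - m).sum(axis=axis)
    )


class _Objective:
    """Penalised negative log-likelihood and gradient over indexed sequences."""

    def __init__(self, sequences, labels, n_features: int, sigma: float):
        self.labels = labels  # list of np.ndarray tag indices
        self.n_features = n_features
        self.inv_var = 1.0 / (sigma * sigma)
        self.n_emission = n_features * _K
        # flatten feature activations once: per sequence, parallel arrays of
        # feature index and the position it fires at
        self.flat = []
        for seq in sequences:
            feat = np.fromiter(
                (f for idxs in seq for f in idxs), dtype=np.intp
            )
            pos = np.fromiter(
                (i for i, idxs in enumerate(seq) for _ in idxs), dtype=np.intp
            )
            self.flat.append((len(seq), feat, pos))

    def _unpack(self, theta: np.ndarray):
        e = theta[: self.n_emission].reshape(self.n_features, _K)
        t = theta[self.n_emission : self.n_emission + _K * _K].reshape(_K, _K)
        rest = theta[self.n_emission + _K * _K :]
        return e, t, rest[:_K], rest[_K:]

    def __call__(self, theta: np.ndarray):
        W, T, S, E = self._unpack(theta)
        gW = np.zeros_like(W)
        gT = np.zeros_like(T)
        gS = np.zeros_like(S)
        gE = np.zeros_like(E)
        nll = 0.0
        for (L, feat, pos), y in zip(self.flat, self.labels):
            M = np.zeros((L, _K))
            np.add.at(M, pos, W[feat])
            # forward
            alpha = np.empty((L, _K))
            alpha[0] = S + M[0]
            for i in range(1, L):
                alpha[i] = M[i] + _lse(alpha[i - 1][:, None] + T, axis=0)
            logZ = float(logsumexp(alpha[L - 1] + E))
            # backward
            beta = np.empty((L, _K))
            beta[L - 1] = E
            for i in range(L - 2, -1, -1):
                beta[i] = _lse(T + (M[i + 1] + beta[i + 1])[None, :], axis=1)
            # gold path score
            score = S[y[0]] + M[np.arange(L), y].sum() + E[y[L - 1]]
            score += T[y[:-1], y[1:]].sum()
            nll += logZ - score
            # expected minus empirical counts
            node = np.exp(alpha + beta - logZ)  # (L, K) tag marginals
            contrib = node.copy()
            contrib[np.arange(L), y] -= 1.0
            np.add.at(gW, feat, contrib[pos])
            gS += node[0]
            gS[y[0]] -= 1.0
            gE += node[L - 1]
            gE[y[L - 1]] -= 1.0
            if L > 1:
                pair = (
                    alpha[:-1, :, None]
                    + T[None, :, :]
                    + (M[1:] + beta[1:])[:, None, :]
                    - logZ
                )
                gT += np.exp(pair).sum(axis=0)
                np.add.at(gT, (y[:-1], y[1:]), -1.0)
        nll += 0.5 * self.inv_var * float(theta @ theta)
        grad = np.concatenate([gW.ravel(), gT.ravel(), gS, gE]) + self.inv_var * theta
        return nll, grad


def _viterbi(M: np.ndarray, T: np.ndarray, S: np.ndarray, E: np.ndarray) -> list[int]:
    L = M.shape[0]
    delta = S + M[0]
    back = np.zeros((L, _K), dtype=np.intp)
    for i in range(1, L):
        scores = delta[:, None] + T
        back[i] = scores.argmax(axis=0)
        delta = M[i] + scores.max(axis=0)
    delta = delta + E
    path = [int(delta.argmax())]
    for i in range(L - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    return path[::-1]


def _prepare_document(doc: AnnotatedDocument):
    tokens = tokenize(doc.text)
    try:
        tags = spans_to_tags(tokens, doc.entities)
    except ValueError as exc:
        raise ValueError(f"document {doc.doc_id}: {exc}") from exc
    return tokens, tags


def fold_seed(base_seed: int, doc_id: str) -> int:
    """Deterministic per-fold seed below 2^31, derived from base seed and doc id."""
    return (base_seed * 1_000_003 + zlib.crc32(doc_id.encode("utf-8"))) % (2**31)


def train(documents: Sequence[AnnotatedDocument], config: CrfConfig | None = None) -> CrfModel:
    """Train a CRF on annotated documents (entities must be token-aligned)."""
    if not documents:
        raise ValueError("training corpus is empty")
    config = config or CrfConfig()
    feature_index: dict[str, int] = {}
    sequences: list[list[list[int]]] = []
    labels: list[np.ndarray] = []
    for doc in documents:
        tokens, tags = _prepare_document(doc)
        if not tokens:
            continue
        seq = []
        for names in _featurize_tokens(tokens):
            idxs = [feature_index.setdefault(n, len(feature_index)) for n in names]
            seq.append(idxs)
        sequences.append(seq)
        labels.append(np.array([_TAG_INDEX[t] for t in tags], dtype=np.intp))
    if not sequences:
        raise ValueError("no non-empty documents to train on")

    n_features = len(feature_index)
    objective = _Objective(sequences, labels, n_features, config.sigma)
    theta0 = np.zeros(n_features * _K + _K * _K + 2 * _K)
    result = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iterations, "ftol": 1e-8, "gtol": 1e-6},
    )
    W, T, S, E = objective._unpack(result.x)
    metadata = {
        "feature_template_version": FEATURE_TEMPLATE_VERSION,
        "hyperparameters": asdict(config),
        "seed": config.seed,
        "training_doc_ids": [doc.doc_id for doc in documents],
        "n_features": n_features,
        "converged": bool(result.success),
        "final_nll": float(result.fun),
    }
    return CrfModel(feature_index, W.copy(), T.copy(), S.copy(), E.copy(), metadata)


def predict(
    model: CrfModel,
    document_text: str,
    doc_id: str = "doc",
    repairs: list[str] | None = None,
) -> list[EntityMention]:
    """Tag a document and decode the tag sequence into entity mentions.

    Mentions carry no lexicon id: recognition is dictionary-independent and
    resolution is a separate step.
    """
    version = model.metadata.get("feature_template_version", FEATURE_TEMPLATE_VERSION)
    if version != FEATURE_TEMPLATE_VERSION:
        raise ValueError(
            f"model feature template {version!r} != runtime {FEATURE_TEMPLATE_VERSION!r}"
        )
    tokens = tokenize(document_text)
    if not tokens:
        return []
    M = np.zeros((len(tokens), _K))
    for i, names in enumerate(_featurize_tokens(tokens)):
        idxs = [model.feature_index[n] for n in names if n in model.feature_index]
        if idxs:
            M[i] = model.emission[idxs].sum(axis=0)
    path = _viterbi(M, model.transition, model.start, model.stop)
    tags = [TAGS[i] for i in path]
    return tags_to_spans(tokens, tags, doc_id=doc_id, text=document_text, repairs=repairs)


def leave_one_out(
    corpus: Sequence[AnnotatedDocument], config: CrfConfig | None = None
) -> dict[str, list[EntityMention]]:
    """Leave-one-document-out cross-validation.

    Each document is tagged by a model trained on every other document; fold
    seeds derive deterministically from the base seed and the held-out doc id.
    Returns predictions keyed by doc_id.
    """
    if len(corpus) < 2:
        raise ValueError("leave-one-out needs at least 2 documents")
    config = config or CrfConfig()
    predictions: dict[str, list[EntityMention]] = {}
    for held_out in corpus:
        rest = [d for d in corpus if d.doc_id != held_out.doc_id]
        fold_config = CrfConfig(
            sigma=config.sigma,
            max_iterations=config.max_iterations,
            seed=fold_seed(config.seed, held_out.doc_id),
        )
        model = train(rest, fold_config)
        assert held_out.doc_id not in model.metadata["training_doc_ids"]
        predictions[held_out.doc_id] = predict(model, held_out.text, held_out.doc_id)
    return predictions
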