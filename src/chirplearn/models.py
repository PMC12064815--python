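"""Reference classifier architectures and the freeze/finetune contract.

Every model splits into a ``backbone`` (feature extractor) and a ``head``
(embedding -> per-class logits), so that shallow finetuning (train head
only), deep finetuning (train everything) and frozen teachers share one
contract. The architectures here are deliberately tiny stand-ins — a small
strided CNN and a small patch transformer — sized so that a full train/eval
cycle on a synthetic corpus runs in minutes on one CPU. A third model,
:class:`BandTemplateModel`, is a fixed matched-filter classifier over
time-averaged mel bands used as a constructed near-optimal teacher on
synthetic corpora and as a frozen backbone for fast shallow finetuning.

Checkpoints are single-file JSON: version, architecture kind and config,
class vocabulary, and weights as nested lists.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .audio import AudioClip
from .frontend import MelConfig, MelSpectrogram, PRESETS, compute_mel, frame_count
from .labels import ClassVocabulary
from .nn import Conv2d, LayerNorm, Linear, Tensor, init_rng

__all__ = [
    "ClassifierModel", "TinyCNN", "TinyTransformer", "BandTemplateModel",
    "set_trainable_scope", "softmax", "sigmoid", "save_checkpoint",
    "load_checkpoint", "parameter_checksum",
]

CHECKPOINT_VERSION = 1
SCOPES = ("all", "head_only", "frozen")


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(logits: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-logits))


class ClassifierModel:
    """Shared contract: backbone + head, activation kind, trainable scope."""

    kind: str = "base"

    def __init__(self, vocab: ClassVocabulary, activation_kind: str,
                 frontend_preset: str):
        if activation_kind not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown activation kind {activation_kind!r}")
        if frontend_preset not in PRESETS:
            raise ValueError(f"unknown front-end preset {frontend_preset!r}")
        self.vocab = vocab
        self.activation_kind = activation_kind
        self.frontend_preset = frontend_preset
        self.trainable_scope = "all"

    # -- architecture hooks ------------------------------------------------

    @property
    def n_classes(self) -> int:
        return len(self.vocab)

    @property
    def mel_config(self) -> MelConfig:
        cfg = PRESETS[self.frontend_preset]
        if not isinstance(cfg, MelConfig):
            raise ValueError(f"preset {self.frontend_preset!r} is not a mel front-end")
        return cfg

    def backbone_parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def head_parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def parameters(self) -> list[Tensor]:
        return self.backbone_parameters() + self.head_parameters()

    def forward_batch(self, x: np.ndarray) -> Tensor:
        """Batched graph forward; x is (B, n_mels, n_frames)."""
        raise NotImplementedError

    def _expected_shape(self) -> tuple[int, int | None]:
        raise NotImplementedError

    def _config_dict(self) -> dict:
        raise NotImplementedError

    # -- public API --------------------------------------------------------

    def forward(self, model_input) -> np.ndarray:
        """Logits for one input (MelSpectrogram, array, or AudioClip)."""
        if isinstance(model_input, AudioClip):
            model_input = compute_mel(model_input, self.mel_config)
        if isinstance(model_input, MelSpectrogram):
            x = model_input.standardized()
        else:
            x = np.asarray(model_input, dtype=np.float64)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        n_mels, n_frames = self._expected_shape()
        if x.shape[1] != n_mels or (n_frames is not None and x.shape[2] != n_frames):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match expected "
                f"({n_mels}, {n_frames if n_frames is not None else 'any'})")
        logits = self.forward_batch(x).data
        return logits[0] if squeeze else logits

    def activate(self, logits: np.ndarray) -> np.ndarray:
        return softmax(logits) if self.activation_kind == "softmax" else sigmoid(logits)


def set_trainable_scope(model: ClassifierModel, scope: str) -> ClassifierModel:
    """all: train everything; head_only: freeze backbone; frozen: freeze all."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    for p in model.backbone_parameters():
        p.requires_grad = scope == "all"
    for p in model.head_parameters():
        p.requires_grad = scope in ("all", "head_only")
    model.trainable_scope = scope
    return model


def parameter_checksum(params: list[Tensor]) -> str:
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


class TinyCNN(ClassifierModel):
    """Two strided 3x3 convolutions, global average pool, dense embedding."""

    kind = "tiny_cnn"

    def __init__(self, vocab: ClassVocabulary, activation_kind: str = "softmax",
                 frontend_preset: str = "tiny", channels: tuple[int, int] = (8, 16),
                 embed_dim: int = 64, seed: int = 0):
        super().__init__(vocab, activation_kind, frontend_preset)
        self.channels = tuple(channels)
        self.embed_dim = embed_dim
        self.seed = seed
        rng = init_rng(seed)
        c1, c2 = self.channels
        self.conv1 = Conv2d(1, c1, kernel=3, stride=2, rng=rng)
        self.conv2 = Conv2d(c1, c2, kernel=3, stride=2, rng=rng)
        # two stride-2 valid convs shrink the mel axis twice
        h1 = (self.mel_config.n_mels - 3) // 2 + 1
        self._h_out = (h1 - 3) // 2 + 1
        self.embed = Linear(c2 * self._h_out, embed_dim, rng=rng)
        self.head = Linear(embed_dim, self.n_classes, rng=rng)

    def backbone_parameters(self):
        return (self.conv1.parameters() + self.conv2.parameters()
                + self.embed.parameters())

    def head_parameters(self):
        return self.head.parameters()

    def _expected_shape(self):
        return self.mel_config.n_mels, None

    def forward_batch(self, x: np.ndarray) -> Tensor:
        t = Tensor(x[:, None, :, :])                 # (B,1,H,W)
        t = self.conv1(t).relu()
        t = self.conv2(t).relu()
        # pool over time only: frequency position carries the species cue
        t = t.mean(axis=3)                           # (B,C,H')
        t = t.reshape(x.shape[0], -1)
        t = self.embed(t).relu()
        return self.head(t)

    def _config_dict(self):
        return {"activation_kind": self.activation_kind,
                "frontend_preset": self.frontend_preset,
                "channels": list(self.channels),
                "embed_dim": self.embed_dim, "seed": self.seed}


class TinyTransformer(ClassifierModel):
    """Single-block patch transformer over non-overlapping mel patches."""

    kind = "tiny_transformer"

    def __init__(self, vocab: ClassVocabulary, activation_kind: str = "softmax",
                 frontend_preset: str = "tiny", patch: tuple[int, int] = (8, 16),
                 model_dim: int = 32, mlp_dim: int = 64, embed_dim: int = 64,
                 seed: int = 0):
        super().__init__(vocab, activation_kind, frontend_preset)
        self.patch = tuple(patch)
        self.model_dim = model_dim
        self.mlp_dim = mlp_dim
        self.embed_dim = embed_dim
        self.seed = seed
        cfg = self.mel_config
        self.n_frames = frame_count(cfg, 3.0)
        ph, pw = self.patch
        if cfg.n_mels % ph:
            raise ValueError(f"patch height {ph} does not divide n_mels {cfg.n_mels}")
        self.grid = (cfg.n_mels // ph, self.n_frames // pw)
        n_tokens = self.grid[0] * self.grid[1]
        rng = init_rng(seed)
        self.patch_proj = Linear(ph * pw, model_dim, rng=rng)
        self.pos = Tensor(rng.normal(0.0, 0.02, (n_tokens, model_dim)),
                          requires_grad=True)
        self.ln1 = LayerNorm(model_dim)
        self.q = Linear(model_dim, model_dim, rng=rng)
        self.k = Linear(model_dim, model_dim, rng=rng)
        self.v = Linear(model_dim, model_dim, rng=rng)
        self.attn_out = Linear(model_dim, model_dim, rng=rng)
        self.ln2 = LayerNorm(model_dim)
        self.mlp1 = Linear(model_dim, mlp_dim, rng=rng)
        self.mlp2 = Linear(mlp_dim, model_dim, rng=rng)
        self.embed = Linear(model_dim, embed_dim, rng=rng)
        self.head = Linear(embed_dim, self.n_classes, rng=rng)

    def backbone_parameters(self):
        params = [self.pos]
        for layer in (self.patch_proj, self.ln1, self.q, self.k, self.v,
                      self.attn_out, self.ln2, self.mlp1, self.mlp2, self.embed):
            params.extend(layer.parameters())
        return params

    def head_parameters(self):
        return self.head.parameters()

    def _expected_shape(self):
        return self.mel_config.n_mels, self.n_frames

    def forward_batch(self, x: np.ndarray) -> Tensor:
        b = x.shape[0]
        ph, pw = self.patch
        gh, gw = self.grid
        x = x[:, : gh * ph, : gw * pw]
        patches = (x.reshape(b, gh, ph, gw, pw).transpose(0, 1, 3, 2, 4)
                   .reshape(b, gh * gw, ph * pw))
        t = self.patch_proj(Tensor(patches)) + self.pos
        h = self.ln1(t)
        q, k, v = self.q(h), self.k(h), self.v(h)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.model_dim))
        attn = scores.softmax(axis=-1)
        t = t + self.attn_out(attn @ v)
        h = self.ln2(t)
        t = t + self.mlp2(self.mlp1(h).relu())
        pooled = t.mean(axis=1)
        return self.head(self.embed(pooled).relu())

    def _config_dict(self):
        return {"activation_kind": self.activation_kind,
                "frontend_preset": self.frontend_preset,
                "patch": list(self.patch), "model_dim": self.model_dim,
                "mlp_dim": self.mlp_dim, "embed_dim": self.embed_dim,
                "seed": self.seed}


class BandTemplateModel(ClassifierModel):
    """Matched-filter linear classifier over time-averaged mel features.

    The parameter-free backbone maps a standardized log-mel spectrogram to
    its time-mean band profile; the head is a single linear layer. With
    head weights set to (L2-normalized) clean-call band profiles of each
    class this is a near-optimal classifier on the synthetic generator; with
    a randomly initialized head it doubles as a fast shallow-finetuning
    model over a frozen "pretrained" feature extractor.
    """

    kind = "band_template"

    def __init__(self, vocab: ClassVocabulary, activation_kind: str = "softmax",
                 frontend_preset: str = "tiny", logit_scale: float = 10.0,
                 seed: int = 0):
        super().__init__(vocab, activation_kind, frontend_preset)
        self.logit_scale = logit_scale
        self.seed = seed
        rng = init_rng(seed)
        self.head = Linear(self.mel_config.n_mels, self.n_classes, rng=rng)

    def set_templates(self, templates: np.ndarray,
                      feature_mean: np.ndarray | None = None):
        """Install per-class band templates, rows indexed like the vocabulary.

        Rows are L2-normalized; when ``feature_mean`` is given the model
        scores centered features, ``W (f - mean)``, by folding the shift
        into the bias.
        """
        templates = np.asarray(templates, dtype=np.float64)
        if templates.shape != (self.n_classes, self.mel_config.n_mels):
            raise ValueError(
                f"templates must be ({self.n_classes}, {self.mel_config.n_mels})")
        norms = np.linalg.norm(templates, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        weight = self.logit_scale * templates / norms
        self.head.weight.data = weight.T
        if feature_mean is None:
            self.head.bias.data = np.zeros(self.n_classes)
        else:
            self.head.bias.data = -weight @ np.asarray(feature_mean, dtype=np.float64)
        return self

    @staticmethod
    def features(x: np.ndarray) -> np.ndarray:
        return x.mean(axis=-1)

    def backbone_parameters(self):
        return []

    def head_parameters(self):
        return self.head.parameters()

    def _expected_shape(self):
        return self.mel_config.n_mels, None

    def forward_batch(self, x: np.ndarray) -> Tensor:
        return self.head(Tensor(self.features(x)))

    def _config_dict(self):
        return {"activation_kind": self.activation_kind,
                "frontend_preset": self.frontend_preset,
                "logit_scale": self.logit_scale, "seed": self.seed}


_MODEL_KINDS = {cls.kind: cls for cls in (TinyCNN, TinyTransformer, BandTemplateModel)}


def _named_weights(model: ClassifierModel) -> dict[str, Tensor]:
    named = {}
    for i, p in enumerate(model.backbone_parameters()):
        named[f"backbone.{i}"] = p
    for i, p in enumerate(model.head_parameters()):
        named[f"head.{i}"] = p
    return named


def save_checkpoint(path: str | Path, model: ClassifierModel) -> None:
    payload = {
        "version": CHECKPOINT_VERSION,
        "kind": model.kind,
        "config": model._config_dict(),
        "classes": list(model.vocab.classes),
        "trainable_scope": model.trainable_scope,
        "weights": {name: p.data.tolist() for name, p in _named_weights(model).items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    if "version" not in payload:
        raise ValueError("checkpoint missing mandatory version field")
    if payload["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {payload['version']}")
    cls = _MODEL_KINDS[payload["kind"]]
    vocab = ClassVocabulary(tuple(payload["classes"]))
    model = cls(vocab, **payload["config"])
    for name, p in _named_weights(model).items():
        data = np.asarray(payload["weights"][name], dtype=np.float64)
        if data.shape != p.data.shape:
            raise ValueError(f"weight {name} shape mismatch: "
                             f"{data.shape} vs {p.data.shape}")
        p.data = data
    set_trainable_scope(model, payload.get("trainable_scope", "all"))
    return model
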