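"""Learnable parameters and the structure / category / description embeddings.

Three translational-family backbones are supported:

* TransE — the structure embedding of a fact is the residual ``h + r - t``.
* TransH — head and tail are first projected onto a relation-specific
  hyperplane (unit normal ``w_r``) so entities can take different roles
  under different relations.
* ConvKB — 1x3 filters slide over the rows of the stacked ``k x 3`` matrix
  ``[h; r; t]`` followed by a ReLU, yielding a ``k x n_f`` feature map.

Two modal entity embeddings complement structure: the category embedding
(mean of the learned vectors of an entity's annotation labels) and the
description embedding (a fixed precomputed text-feature vector mapped
through a learned ``d x k`` weight matrix).  A triplet's modal embedding is
the head-minus-tail difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigError, ShapeError, VocabularyError
from .kg_io import AnnotationSet

BACKBONES = ("transe", "transh", "convkb")
FUSIONS = ("none", "cross", "hp", "reverse_hp")


@dataclass
class HyperParams:
    """Model and optimization hyper-parameters.

    ``batch_fraction`` is fixed at 1/40 of the training-set size by protocol.
    ``init_mode`` selects the uniform initialization boundary: ``"literal"``
    uses (-6/k, 6/k); ``"classical"`` uses the usual Glorot bound
    ±sqrt(6)/sqrt(2k).
    """

    k: int = 32
    gamma: float = 1.0
    n_f: int = 10
    lr: float = 1e-3
    lambda_c: float = 0.0
    lambda_d: float = 0.0
    batch_fraction: float = 1.0 / 40.0
    max_epochs: int = 200
    backbone: str = "transe"
    fusion: str = "none"
    seed: int = 0
    init_mode: str = "literal"
    snorm: str = "unit"          # "unit" -> S/||S||; "squared" -> S/||S||^2
    cross_residual: str = "transe"  # "transe" -> h+r-t; "flipped" -> h-r+t
    eval_every: int = 50

    def validate(self) -> None:
        if self.k <= 0:
            raise ConfigError("embedding size k must be positive")
        if self.backbone not in BACKBONES:
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.fusion not in FUSIONS:
            raise ConfigError(f"unknown fusion {self.fusion!r}")
        if self.backbone == "convkb" and self.n_f <= 0:
            raise ConfigError("convkb requires n_f >= 1")
        if self.lambda_c < 0 or self.lambda_d < 0:
            raise ConfigError("lambda weights must be >= 0")
        if self.fusion == "none" and (self.lambda_c != 0 or self.lambda_d != 0):
            raise ConfigError(
                "fusion='none' (configuration S) forces lambda_c=lambda_d=0"
            )
        if self.init_mode not in ("literal", "classical"):
            raise ConfigError(f"unknown init_mode {self.init_mode!r}")
        if self.snorm not in ("unit", "squared"):
            raise ConfigError(f"unknown snorm {self.snorm!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        hp = cls(**d)
        hp.validate()
        return hp


@dataclass
class ModelParams:
    """All learnable tensors of one model.

    ``relation_normal`` rows are kept at unit Euclidean norm (TransH
    hyperplane normals).  ``conv_filters`` has shape ``(n_f, 3)`` and
    ``score_weight`` length ``k * n_f`` ordered filter-major, matching the
    column-major vectorization of the ``k x n_f`` ConvKB feature map.
    """

    entity_emb: np.ndarray
    relation_emb: np.ndarray
    relation_normal: np.ndarray
    category_emb: np.ndarray
    desc_weight: np.ndarray
    conv_filters: np.ndarray
    score_weight: np.ndarray

    def copy(self) -> "ModelParams":
        return ModelParams(**{k: v.copy() for k, v in self.arrays().items()})

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "entity_emb": self.entity_emb,
            "relation_emb": self.relation_emb,
            "relation_normal": self.relation_normal,
            "category_emb": self.category_emb,
            "desc_weight": self.desc_weight,
            "conv_filters": self.conv_filters,
            "score_weight": self.score_weight,
        }


@dataclass
class TripleEmbeddings:
    """Per-triplet embeddings: structure S (k-vector or k x n_f matrix),
    and optional category / description difference vectors C, D."""

    S: np.ndarray
    C: np.ndarray | None = None
    D: np.ndarray | None = None


def init_params(
    kg_sizes: tuple[int, int, int, int], hp: HyperParams
) -> ModelParams:
    """Initialize all tensors from the seeded generator.

    ``kg_sizes`` is (num_entities, num_relations, num_categories,
    description_dim).  Embeddings and weight matrices are drawn uniform on
    the Glorot boundary; every convolution filter starts at
    ``(0.1, 0.1, -0.1)``; TransH relation normals are normalized to unit
    length.
    """
    hp.validate()
    n_ent, n_rel, n_cat, d = kg_sizes
    if n_ent <= 0 or n_rel <= 0:
        raise ConfigError("entity and relation counts must be positive")
    k = hp.k
    if hp.init_mode == "classical":
        bound = np.sqrt(6.0) / np.sqrt(2.0 * k)
    else:
        bound = 6.0 / k
    rng = np.random.default_rng(hp.seed)

    def uni(*shape):
        return rng.uniform(-bound, bound, size=shape)

    relation_normal = uni(n_rel, k)
    norms = np.linalg.norm(relation_normal, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    relation_normal = relation_normal / norms

    return ModelParams(
        entity_emb=uni(n_ent, k),
        relation_emb=uni(n_rel, k),
        relation_normal=relation_normal,
        category_emb=uni(max(n_cat, 1), k),
        desc_weight=uni(max(d, 1), k),
        conv_filters=np.tile(np.array([0.1, 0.1, -0.1]), (hp.n_f, 1)),
        score_weight=uni(k * hp.n_f),
    )


# ---------------------------------------------------------------------------
# Structure embeddings (pure functions of their vector arguments)
# ---------------------------------------------------------------------------

def structure_transe(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """TransE residual ``h + r - t``."""
    h, r, t = map(np.asarray, (h, r, t))
    if not (h.shape == r.shape == t.shape):
        raise ShapeError(f"shape mismatch: {h.shape}, {r.shape}, {t.shape}")
    return h + r - t


def structure_transh(
    h: np.ndarray, r: np.ndarray, t: np.ndarray, w_r: np.ndarray
) -> np.ndarray:
    """TransH residual with head/tail projected onto the relation hyperplane.

    ``w_r`` must be a unit vector (tolerance 1e-6).
    """
    h, r, t, w_r = map(np.asarray, (h, r, t, w_r))
    if not (h.shape == r.shape == t.shape == w_r.shape):
        raise ShapeError("h, r, t, w_r must share one shape")
    nrm = np.linalg.norm(w_r)
    if abs(nrm - 1.0) > 1e-6:
        raise ShapeError(f"w_r must have unit norm, got {nrm}")
    h_p = h - np.dot(w_r, h) * w_r
    t_p = t - np.dot(w_r, t) * w_r
    return h_p + r - t_p


def structure_convkb(
    h: np.ndarray, r: np.ndarray, t: np.ndarray, filters: np.ndarray
) -> np.ndarray:
    """ConvKB feature map: ReLU of 1x3 filters slid over rows of [h;r;t].

    Returns a ``k x n_f`` matrix whose ``(i, j)`` entry is
    ``ReLU(h_i w_j1 + r_i w_j2 + t_i w_j3)``.
    """
    h, r, t = map(np.asarray, (h, r, t))
    filters = np.atleast_2d(np.asarray(filters))
    if not (h.shape == r.shape == t.shape):
        raise ShapeError("h, r, t must share one shape")
    if filters.shape[1] != 3:
        raise ShapeError(f"filters must be (n_f, 3), got {filters.shape}")
    stacked = np.stack([h, r, t], axis=-1)  # k x 3
    return np.maximum(stacked @ filters.T, 0.0)  # k x n_f


# ---------------------------------------------------------------------------
# Modal embeddings
# ---------------------------------------------------------------------------

def entity_category_embedding(
    entity: str, annotations: AnnotationSet, category_emb: np.ndarray
) -> np.ndarray:
    """Mean of the learned vectors of the entity's category labels.

    The null-annotation convention maps an empty category set to the zero
    vector, so unannotated entities contribute nothing to the modal term.
    """
    labels = annotations.categories_of(entity)
    k = category_emb.shape[1]
    if not labels:
        return np.zeros(k)
    rows = []
    for lab in labels:
        idx = annotations.category_vocab.get(lab)
        if idx is None:
            raise VocabularyError(f"unknown category label {lab!r}")
        rows.append(category_emb[idx])
    return np.mean(rows, axis=0)


def entity_description_embedding(
    entity: str, annotations: AnnotationSet, desc_weight: np.ndarray
) -> np.ndarray:
    """Fixed description feature mapped through ``W_D`` (shape d x k).

    Absent feature -> zero vector (null-annotation convention).
    """
    feat = annotations.feature_of(entity)
    if feat is None:
        return np.zeros(desc_weight.shape[1])
    if feat.shape[0] != desc_weight.shape[0]:
        raise ShapeError(
            f"feature length {feat.shape[0]} does not match W_D rows "
            f"{desc_weight.shape[0]}"
        )
    return desc_weight.T @ feat


def modal_difference(head_modal: np.ndarray, tail_modal: np.ndarray) -> np.ndarray:
    """Head-minus-tail modal difference vector."""
    head_modal = np.asarray(head_modal)
    tail_modal = np.asarray(tail_modal)
    if head_modal.shape != tail_modal.shape:
        raise ShapeError(
            f"shape mismatch: {head_modal.shape} vs {tail_modal.shape}"
        )
    return head_modal - tail_modal


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

def save_model(path, params: ModelParams, hp: HyperParams, meta: dict | None = None) -> None:
    """Serialize parameters + hyper-parameters (+ optional metadata such as
    vocabularies and split assignments) to one keyed array container.

    The container is npz-compatible but written with fixed zip timestamps
    and sorted keys, so identical inputs produce byte-identical files.
    """
    import io
    import zipfile

    payload = dict(params.arrays())
    payload["__hyperparams__"] = np.frombuffer(
        json.dumps(hp.to_dict(), sort_keys=True).encode(), dtype=np.uint8
    )
    if meta:
        payload["__meta__"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
        )
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for key in sorted(payload):
            buf = io.BytesIO()
            np.lib.format.write_array(
                buf, np.asanyarray(payload[key]), allow_pickle=False
            )
            info = zipfile.ZipInfo(key + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_model(path) -> tuple[ModelParams, HyperParams, dict]:
    with np.load(path) as npz:
        hp = HyperParams.from_dict(
            json.loads(bytes(npz["__hyperparams__"]).decode())
        )
        meta = (
            json.loads(bytes(npz["__meta__"]).decode())
            if "__meta__" in npz
            else {}
        )
        params = ModelParams(
            **{
                k: npz[k]
                for k in (
                    "entity_emb",
                    "relation_emb",
                    "relation_normal",
                    "category_emb",
                    "desc_weight",
                    "conv_filters",
                    "score_weight",
                )
            }
        )
    return params, hp, meta
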