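"""Plausibility scoring: fusing structure, category and description embeddings.

Higher score = more plausible triplet; all ranking sorts descending.

Four fusion schemes are implemented:

* ``none`` — structure only: ``f = -||S||^2`` (translational) or
  ``f = -W_S^T vec(S)`` (ConvKB).
* ``reverse_hp`` — the structure embedding acts as a hyperplane normal;
  the score penalizes the structure norm and rewards the components of the
  category / description difference vectors lying *on* that hyperplane:
  ``f = -||S||^2 + sum_M lambda_M ||M - S*^T M S*||^2``.
* ``hp`` — the classical baseline in which category / description vectors
  act as hyperplane normals onto which S is projected (sequentially, C then
  D, each weighted by its lambda) before the structure penalty.
* ``cross`` — modal endpoint vectors are substituted into the translational
  residual, one endpoint at a time, and the resulting base scores summed
  (modal terms weighted by their lambda).

``S*`` defaults to the unit normal ``S/||S||_2``; a ``snorm="squared"``
variant using ``S/||S||_2^2`` is retained for exact-formula comparisons.
For ConvKB the modal residual is computed per filter column (column ``j``
uses the unit column ``S_j`` as its hyperplane normal), the only reading
under which the ``vec`` dimensions agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .embedding import (
    HyperParams,
    ModelParams,
    entity_category_embedding,
    entity_description_embedding,
    modal_difference,
    structure_convkb,
    structure_transe,
    structure_transh,
)
from .errors import (
    ConfigError,
    ContractError,
    DegenerateHyperplaneError,
    ShapeError,
    VocabularyError,
)
from .kg_io import AnnotationSet, KnowledgeGraph, Triplet



@dataclass
class ScoreConfig:
    """Scoring-time configuration (a view of the model hyper-parameters)."""

    fusion: str = "none"
    lambda_c: float = 0.0
    lambda_d: float = 0.0
    backbone: str = "transe"
    snorm: str = "unit"
    cross_residual: str = "transe"

    def __post_init__(self):
        if self.fusion == "none" and (self.lambda_c != 0 or self.lambda_d != 0):
            raise ConfigError(
                "fusion='none' is the structure-only configuration; "
                "lambda_c and lambda_d must both be 0"
            )

    @classmethod
    def from_hyperparams(cls, hp: HyperParams) -> "ScoreConfig":
        return cls(
            fusion=hp.fusion,
            lambda_c=hp.lambda_c,
            lambda_d=hp.lambda_d,
            backbone=hp.backbone,
            snorm=hp.snorm,
            cross_residual=hp.cross_residual,
        )


# ---------------------------------------------------------------------------
# Scalar (per-triplet) operations
# ---------------------------------------------------------------------------

def unit_hyperplane(S: np.ndarray) -> np.ndarray:
    """Scale ``S`` to unit Euclidean norm; a zero vector has no direction."""
    S = np.asarray(S, dtype=np.float64)
    nrm = np.linalg.norm(S)
    if nrm == 0:
        raise DegenerateHyperplaneError("zero vector cannot define a hyperplane")
    return S / nrm


def _s_star(S: np.ndarray, snorm: str) -> np.ndarray:
    nrm = np.linalg.norm(S)
    if nrm == 0:
        raise DegenerateHyperplaneError("zero structure vector")
    if snorm == "unit":
        return S / nrm
    return S / nrm**2


def hyperplane_residual(M: np.ndarray, S: np.ndarray, snorm: str = "unit") -> np.ndarray:
    """Residual ``M - S*^T M S*`` — the part of ``M`` lying on the hyperplane
    whose normal is ``S*``.  With the unit normalization this is the exact
    orthogonal component of ``M`` with respect to ``S``."""
    M = np.asarray(M, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if M.shape != S.shape:
        raise ShapeError(f"shape mismatch: M {M.shape} vs S {S.shape}")
    star = _s_star(S, snorm)
    return M - np.dot(star, M) * star


def _modal_residual_or_zero(M: np.ndarray, S: np.ndarray, snorm: str) -> np.ndarray:
    """Residual of M against S; degenerate zero-S hyperplane -> zero residual."""
    if np.linalg.norm(S) == 0:
        return np.zeros_like(M)
    return hyperplane_residual(M, S, snorm)


def score_translational_reverse_hp(
    S: np.ndarray,
    C: np.ndarray | None,
    D: np.ndarray | None,
    cfg: ScoreConfig,
) -> float:
    """Reverse-HP score for TransE / TransH structure embeddings."""
    S = np.asarray(S, dtype=np.float64)
    f = -float(np.dot(S, S))
    for M, lam, name in ((C, cfg.lambda_c, "C"), (D, cfg.lambda_d, "D")):
        if lam == 0:
            continue
        if M is None:
            raise ContractError(
                f"lambda_{name.lower()} > 0 but modal vector {name} is absent; "
                "pass an explicit zero vector for unannotated entities"
            )
        R = _modal_residual_or_zero(np.asarray(M, dtype=np.float64), S, cfg.snorm)
        f += lam * float(np.dot(R, R))
    return f


def _vec(S: np.ndarray) -> np.ndarray:
    """Column-major (filter-major) vectorization of a k x n_f matrix."""
    return S.T.reshape(-1)


def score_convkb(
    S: np.ndarray,
    C: np.ndarray | None,
    D: np.ndarray | None,
    score_weight: np.ndarray,
    cfg: ScoreConfig,
) -> float:
    """Reverse-HP (or structure-only) score for the ConvKB feature map.

    ``f = -W_S^T vec(S) + sum_M lambda_M W_S^T vec(R_M)`` where column ``j``
    of the residual matrix ``R_M`` is the residual of the k-vector ``M``
    against the ``j``-th column of ``S``.
    """
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    if S.ndim != 2:
        raise ShapeError("ConvKB structure embedding must be k x n_f")
    k, n_f = S.shape
    score_weight = np.asarray(score_weight, dtype=np.float64)
    if score_weight.shape != (k * n_f,):
        raise ShapeError(
            f"score weight length {score_weight.shape} != k*n_f = {k * n_f}"
        )
    f = -float(score_weight @ _vec(S))
    for M, lam, name in ((C, cfg.lambda_c, "C"), (D, cfg.lambda_d, "D")):
        if lam == 0:
            continue
        if M is None:
            raise ContractError(f"lambda for {name} > 0 but {name} is absent")
        M = np.asarray(M, dtype=np.float64)
        R = np.empty_like(S)
        for j in range(n_f):
            R[:, j] = _modal_residual_or_zero(M, S[:, j], cfg.snorm)
        f += lam * float(score_weight @ _vec(R))
    return f


def score_forward_hp(
    S: np.ndarray,
    C: np.ndarray | None,
    D: np.ndarray | None,
    cfg: ScoreConfig,
    score_weight: np.ndarray | None = None,
) -> float:
    """Forward hyperplane-projection baseline.

    The structure embedding is projected sequentially onto the hyperplanes
    whose unit normals are the category then description difference vectors,
    each projection weighted by its lambda; zero modal vectors are skipped.
    Returns ``-||S'||^2`` (translational) or ``-W_S^T vec(S')`` (ConvKB).
    """
    S = np.asarray(S, dtype=np.float64).copy()
    for M, lam in ((C, cfg.lambda_c), (D, cfg.lambda_d)):
        if lam == 0 or M is None:
            continue
        M = np.asarray(M, dtype=np.float64)
        nrm = np.linalg.norm(M)
        if nrm == 0:
            continue
        m = M / nrm
        if S.ndim == 1:
            S = S - lam * np.dot(m, S) * m
        else:
            c = m @ S  # length n_f
            S = S - lam * np.outer(m, c)
    if S.ndim == 1:
        return -float(np.dot(S, S))
    if score_weight is None:
        raise ContractError("ConvKB forward-HP requires the score weight")
    return -float(np.asarray(score_weight) @ _vec(S))


def score_cross_embedding(
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    h_C: np.ndarray | None = None,
    t_C: np.ndarray | None = None,
    h_D: np.ndarray | None = None,
    t_D: np.ndarray | None = None,
    cfg: ScoreConfig | None = None,
) -> float:
    """Cross-embedding score (translational form).

    The base residual score is summed over the structure triple and the four
    modal-substituted triples (head or tail replaced by its category /
    description embedding), modal terms weighted by lambda.
    """
    cfg = cfg or ScoreConfig(fusion="cross", lambda_c=1.0, lambda_d=1.0)
    vecs = [v for v in (h, r, t, h_C, t_C, h_D, t_D) if v is not None]
    shapes = {np.asarray(v).shape for v in vecs}
    if len(shapes) != 1:
        raise ShapeError(f"all vectors must share one shape, got {shapes}")

    def residual(x, y):
        if cfg.cross_residual == "flipped":
            return np.asarray(x) - np.asarray(r) + np.asarray(y)
        return np.asarray(x) + np.asarray(r) - np.asarray(y)

    def base(x, y):
        d = residual(x, y)
        return -float(np.dot(d, d))

    f = base(h, t)
    for hm, tm, lam in ((h_C, t_C, cfg.lambda_c), (h_D, t_D, cfg.lambda_d)):
        if lam == 0:
            continue
        if hm is None or tm is None:
            raise ContractError("modal endpoint vectors absent but lambda > 0")
        f += lam * (base(hm, t) + base(h, tm))
    return f


def score_triplet(
    triplet: Triplet,
    params: ModelParams,
    annotations: AnnotationSet,
    cfg: ScoreConfig,
    kg: KnowledgeGraph,
) -> float:
    """Score one triplet by composing the module's primitive operations.

    This is the reference (non-vectorized) scoring path; the batch scorer
    must agree with it exactly.
    """
    h_i = kg.entities.get(triplet.head)
    t_i = kg.entities.get(triplet.tail)
    r_i = kg.relations.get(triplet.relation)
    if h_i is None or t_i is None:
        raise VocabularyError(f"unknown entity in {triplet}")
    if r_i is None:
        raise VocabularyError(f"unknown relation {triplet.relation!r}")

    h = params.entity_emb[h_i]
    t = params.entity_emb[t_i]
    r = params.relation_emb[r_i]

    use_c = cfg.lambda_c > 0
    use_d = cfg.lambda_d > 0
    C = D = None
    hc = tc = hd = td = None
    if use_c:
        hc = entity_category_embedding(triplet.head, annotations, params.category_emb)
        tc = entity_category_embedding(triplet.tail, annotations, params.category_emb)
        C = modal_difference(hc, tc)
    if use_d:
        hd = entity_description_embedding(triplet.head, annotations, params.desc_weight)
        td = entity_description_embedding(triplet.tail, annotations, params.desc_weight)
        D = modal_difference(hd, td)

    if cfg.fusion == "cross":
        return _cross_score_single(h, r, t, hc, tc, hd, td, r_i, params, cfg)

    if cfg.backbone == "transe":
        S = structure_transe(h, r, t)
    elif cfg.backbone == "transh":
        S = structure_transh(h, r, t, params.relation_normal[r_i])
    else:
        S = structure_convkb(h, r, t, params.conv_filters)

    if cfg.fusion == "hp":
        return score_forward_hp(S, C, D, cfg, score_weight=params.score_weight)
    if cfg.backbone == "convkb":
        return score_convkb(S, C, D, params.score_weight, cfg)
    if cfg.fusion == "reverse_hp":
        return score_translational_reverse_hp(S, C, D, cfg)
    return -float(np.dot(S, S))


def _cross_score_single(h, r, t, hc, tc, hd, td, r_i, params, cfg) -> float:
    """Cross-embedding dispatch covering all three backbones."""
    if cfg.backbone == "transe":
        return score_cross_embedding(h, r, t, hc, tc, hd, td, cfg)

    if cfg.backbone == "transh":
        w = params.relation_normal[r_i]

        def proj(x):
            return x - np.dot(w, x) * w

        def base(x, y):
            if cfg.cross_residual == "flipped":
                d = proj(x) - r + proj(y)
            else:
                d = proj(x) + r - proj(y)
            return -float(np.dot(d, d))

    else:  # convkb

        def base(x, y):
            S = structure_convkb(x, r, y, params.conv_filters)
            return -float(params.score_weight @ _vec(S))

    f = base(h, t)
    for hm, tm, lam in ((hc, tc, cfg.lambda_c), (hd, td, cfg.lambda_d)):
        if lam == 0:
            continue
        f += lam * (base(hm, t) + base(h, tm))
    return f


# ---------------------------------------------------------------------------
# Vectorized batch scorer
# ---------------------------------------------------------------------------

@dataclass
class ModalArrays:
    """Dense/sparse per-entity modal inputs aligned to the entity vocabulary.

    ``cat_matrix`` is a row-normalized sparse membership matrix
    (num_entities x num_categories), so ``cat_matrix @ category_emb`` yields
    every entity's mean-of-categories embedding; ``feat`` holds description
    features with zero rows for unannotated entities, so ``feat @ W_D``
    yields description embeddings under the null-annotation convention.
    """

    cat_matrix: sp.csr_matrix
    feat: np.ndarray
    d: int


def build_modal_arrays(kg: KnowledgeGraph, annotations: AnnotationSet) -> ModalArrays:
    n_ent = len(kg.entities)
    n_cat = max(len(annotations.category_vocab), 1)
    rows, cols, vals = [], [], []
    for entity, labels in annotations.categories.items():
        e_i = kg.entities.get(entity)
        if e_i is None or not labels:
            continue
        w = 1.0 / len(labels)
        for lab in labels:
            c_i = annotations.category_vocab.get(lab)
            if c_i is None:
                raise VocabularyError(f"unknown category label {lab!r}")
            rows.append(e_i)
            cols.append(c_i)
            vals.append(w)
    cat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_ent, n_cat), dtype=np.float64
    )
    d = annotations.d or 1
    feat = np.zeros((n_ent, d))
    for entity, vec in annotations.description_features.items():
        e_i = kg.entities.get(entity)
        if e_i is not None:
            feat[e_i] = vec
    return ModalArrays(cat_matrix=cat, feat=feat, d=d)


def score_batch(
    params: ModelParams,
    modal: ModalArrays,
    cfg: ScoreConfig,
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    need_cache: bool = False,
):
    """Score ``n`` triplets given integer index arrays.

    Returns ``scores`` (length-n array), or ``(scores, cache)`` when
    ``need_cache`` is set; the cache holds every intermediate the analytic
    backward pass in :mod:`kgfuse.training` needs.
    """
    h = np.asarray(h, dtype=np.int64)
    r = np.asarray(r, dtype=np.int64)
    t = np.asarray(t, dtype=np.int64)
    n = h.shape[0]
    cache: dict = {"h": h, "r": r, "t": t, "n": n}

    use_c = cfg.lambda_c > 0
    use_d = cfg.lambda_d > 0
    EC = ED = None
    C = D = None
    if use_c:
        EC = modal.cat_matrix @ params.category_emb
        C = EC[h] - EC[t]
    if use_d:
        ED = modal.feat @ params.desc_weight
        D = ED[h] - ED[t]
    cache.update(EC=EC, ED=ED, C=C, D=D)

    if cfg.fusion == "cross":
        scores = _cross_forward(params, cfg, cache)
    else:
        S = _backbone_forward(params, cfg, h, r, t, cache)
        if cfg.fusion == "none":
            scores = _plain_score(S, params, cfg, cache)
        elif cfg.fusion == "reverse_hp":
            scores = _reverse_hp_forward(S, params, cfg, cache)
        else:  # hp
            scores = _forward_hp_forward(S, params, cfg, cache)

    if need_cache:
        return scores, cache
    return scores


def _backbone_forward(params, cfg, h, r, t, cache) -> np.ndarray:
    Eh = params.entity_emb[h]
    Et = params.entity_emb[t]
    Rr = params.relation_emb[r]
    cache.update(Eh=Eh, Et=Et, Rr=Rr)
    if cfg.backbone == "transe":
        S = Eh + Rr - Et
    elif cfg.backbone == "transh":
        W = params.relation_normal[r]
        ah = np.einsum("nk,nk->n", Eh, W)
        at = np.einsum("nk,nk->n", Et, W)
        S = (Eh - ah[:, None] * W) + Rr - (Et - at[:, None] * W)
        cache.update(W=W, ah=ah, at=at)
    else:  # convkb
        pre = np.einsum(
            "nkc,fc->nkf",
            np.stack([Eh, Rr, Et], axis=2),
            params.conv_filters,
        )
        S = np.maximum(pre, 0.0)
        cache["relu_mask"] = pre > 0
    cache["S"] = S
    return S


def _vec_batch(X: np.ndarray) -> np.ndarray:
    """Batched filter-major vec of (n, k, n_f) -> (n, k*n_f)."""
    return X.transpose(0, 2, 1).reshape(X.shape[0], -1)


def _plain_score(S, params, cfg, cache) -> np.ndarray:
    if cfg.backbone == "convkb":
        return -(_vec_batch(S) @ params.score_weight)
    return -np.einsum("nk,nk->n", S, S)


def _reverse_hp_forward(S, params, cfg, cache) -> np.ndarray:
    if cfg.backbone == "convkb":
        return _reverse_hp_convkb_forward(S, params, cfg, cache)
    s2 = np.einsum("nk,nk->n", S, S)
    nrm = np.sqrt(s2)
    safe = nrm > 0
    inv = np.where(safe, 1.0 / np.where(safe, nrm, 1.0), 0.0)
    cache.update(s2=s2, nrm=nrm, safe=safe, inv=inv)
    f = -s2
    for name, lam in (("C", cfg.lambda_c), ("D", cfg.lambda_d)):
        if lam == 0:
            continue
        M = cache[name]
        if cfg.snorm == "unit":
            u = S * inv[:, None]
            a = np.einsum("nk,nk->n", u, M)
            R = np.where(safe[:, None], M - a[:, None] * u, 0.0)
            cache[f"a_{name}"] = a
        else:  # snorm == "squared": S* = S/||S||^2
            inv2 = np.where(safe, 1.0 / np.where(safe, s2, 1.0), 0.0)
            b = np.einsum("nk,nk->n", S, M) * inv2**2
            R = np.where(safe[:, None], M - b[:, None] * S, 0.0)
            cache[f"b_{name}"] = b
        cache[f"R_{name}"] = R
        f = f + lam * np.einsum("nk,nk->n", R, R)
    return f


def _reverse_hp_convkb_forward(S, params, cfg, cache) -> np.ndarray:
    # S: (n, k, n_f); hyperplane normal per filter column
    cn = np.linalg.norm(S, axis=1)  # (n, n_f)
    safe = cn > 0
    inv = np.where(safe, 1.0 / np.where(safe, cn, 1.0), 0.0)
    cache.update(cn=cn, col_safe=safe, col_inv=inv)
    W = params.score_weight
    f = -(_vec_batch(S) @ W)
    for name, lam in (("C", cfg.lambda_c), ("D", cfg.lambda_d)):
        if lam == 0:
            continue
        M = cache[name]  # (n, k)
        if cfg.snorm == "unit":
            U = S * inv[:, None, :]
            a = np.einsum("nkf,nk->nf", U, M)
            R = np.where(
                safe[:, None, :], M[:, :, None] - U * a[:, None, :], 0.0
            )
            cache[f"a_{name}"] = a
            cache[f"U_{name}"] = U
        else:
            inv2 = np.where(safe, 1.0 / np.where(safe, cn**2, 1.0), 0.0)
            b = np.einsum("nkf,nk->nf", S, M) * inv2**2
            R = np.where(
                safe[:, None, :], M[:, :, None] - S * b[:, None, :], 0.0
            )
            cache[f"b_{name}"] = b
        cache[f"R_{name}"] = R
        f = f + lam * (_vec_batch(R) @ W)
    return f


def _forward_hp_forward(S, params, cfg, cache) -> np.ndarray:
    Sp = S.copy()
    steps = []
    for name, lam in (("C", cfg.lambda_c), ("D", cfg.lambda_d)):
        if lam == 0:
            continue
        M = cache[name]  # (n, k)
        mn = np.linalg.norm(M, axis=1)
        mask = mn > 0
        minv = np.where(mask, 1.0 / np.where(mask, mn, 1.0), 0.0)
        m = M * minv[:, None]
        Sprev = Sp.copy()
        if Sp.ndim == 2:  # translational
            c = np.einsum("nk,nk->n", m, Sp)
            Sp = np.where(mask[:, None], Sp - lam * c[:, None] * m, Sp)
        else:  # convkb (n, k, n_f)
            c = np.einsum("nk,nkf->nf", m, Sp)
            Sp = np.where(
                mask[:, None, None], Sp - lam * m[:, :, None] * c[:, None, :], Sp
            )
        steps.append(
            {"name": name, "lam": lam, "m": m, "c": c, "mask": mask,
             "minv": minv, "Sprev": Sprev}
        )
    cache["hp_steps"] = steps
    cache["Sp"] = Sp
    if Sp.ndim == 2:
        return -np.einsum("nk,nk->n", Sp, Sp)
    return -(_vec_batch(Sp) @ params.score_weight)


def _cross_forward(params, cfg, cache) -> np.ndarray:
    h, r, t = cache["h"], cache["r"], cache["t"]
    Eh = params.entity_emb[h]
    Et = params.entity_emb[t]
    Rr = params.relation_emb[r]
    cache.update(Eh=Eh, Et=Et, Rr=Rr)
    if cfg.backbone == "transh":
        cache["W"] = params.relation_normal[r]

    EC, ED = cache["EC"], cache["ED"]
    terms = [("s", Eh, Et, 1.0)]
    if cfg.lambda_c > 0:
        terms += [("ch", EC[h], Et, cfg.lambda_c), ("ct", Eh, EC[t], cfg.lambda_c)]
    if cfg.lambda_d > 0:
        terms += [("dh", ED[h], Et, cfg.lambda_d), ("dt", Eh, ED[t], cfg.lambda_d)]

    f = np.zeros(cache["n"])
    cache["cross_terms"] = []
    for tag, X, Y, lam in terms:
        base, term_cache = _cross_base_forward(X, Y, Rr, params, cfg, cache)
        f = f + lam * base
        term_cache.update(tag=tag, lam=lam)
        cache["cross_terms"].append(term_cache)
    return f


def _cross_base_forward(X, Y, Rr, params, cfg, cache):
    sgn = -1.0 if cfg.cross_residual == "flipped" else 1.0
    tc: dict = {"X": X, "Y": Y}
    if cfg.backbone == "convkb":
        pre = np.einsum(
            "nkc,fc->nkf", np.stack([X, Rr, Y], axis=2), params.conv_filters
        )
        S = np.maximum(pre, 0.0)
        tc.update(relu_mask=pre > 0, S=S)
        return -(_vec_batch(S) @ params.score_weight), tc
    if cfg.backbone == "transh":
        W = cache["W"]
        ax = np.einsum("nk,nk->n", X, W)
        ay = np.einsum("nk,nk->n", Y, W)
        Xp = X - ax[:, None] * W
        Yp = Y - ay[:, None] * W
        dvec = Xp + sgn * Rr - Yp if sgn > 0 else Xp - Rr + Yp
        tc.update(ax=ax, ay=ay)
    else:
        dvec = X + Rr - Y if sgn > 0 else X - Rr + Y
    tc["dvec"] = dvec
    return -np.einsum("nk,nk->n", dvec, dvec), tc
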