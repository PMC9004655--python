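"""Negative sampling, losses, analytic gradients, the Adam loop, grid search.

Training minimizes a margin ranking loss (TransE/TransH) or a softplus
logistic loss (ConvKB) over positive triplets and Bernoulli-corrupted
negatives.  Gradients are derived analytically for every backbone x fusion
combination and flow through the hyperplane normalization ``S* = S/||S||``;
they are validated against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy.special import expit

from . import evaluation
from .embedding import HyperParams, ModelParams, init_params
from .errors import (
    ConfigError,
    ContractError,
    SamplingError,
    ShapeError,
    TrainingError,
    VocabularyError,
)
from .kg_io import (
    AnnotationSet,
    KnowledgeGraph,
    RelationStats,
    Triplet,
    TripletSplit,
    relation_stats,
)
from .scoring import ModalArrays, ScoreConfig, build_modal_arrays, score_batch

_MAX_CORRUPT_ATTEMPTS = 100


@dataclass
class Batch:
    """Aligned positive / negative triplet lists for one optimization step."""

    positives: list[Triplet]
    negatives: list[Triplet]


@dataclass
class TrainState:
    """Outcome of one training run."""

    params: ModelParams
    epoch: int
    loss_history: list[float]
    best_valid_mr: float
    rng_state: dict | None = None


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def bernoulli_head_probability(relation: str, stats: RelationStats) -> float:
    """Probability of corrupting the *head* under the Bernoulli trick:
    ``tph / (tph + hpt)``.  Relations with many tails per head get their
    heads corrupted preferentially, reducing false-negative corruptions."""
    if relation not in stats.tph:
        raise VocabularyError(f"unknown relation {relation!r}")
    tph = stats.tph[relation]
    hpt = stats.hpt[relation]
    return tph / (tph + hpt)


def corrupt_triplet(
    positive: Triplet,
    kg: KnowledgeGraph,
    stats: RelationStats,
    rng: np.random.Generator,
    known: frozenset[Triplet] | None = None,
) -> Triplet:
    """Corrupt head or tail of a positive triplet into a negative.

    The head is replaced with the Bernoulli probability, else the tail; the
    replacement entity is uniform over the vocabulary; the draw is repeated
    until the corrupted triplet is not a known true fact.
    """
    if len(kg.entities) < 2:
        raise SamplingError("need at least 2 entities to corrupt")
    if known is None:
        known = kg.triplet_set()
    p_head = bernoulli_head_probability(positive.relation, stats)
    n_ent = len(kg.entities)
    for _ in range(_MAX_CORRUPT_ATTEMPTS):
        corrupt_head = rng.random() < p_head
        repl = kg.entities.name(int(rng.integers(n_ent)))
        if corrupt_head:
            cand = Triplet(repl, positive.relation, positive.tail)
        else:
            cand = Triplet(positive.head, positive.relation, repl)
        if cand != positive and cand not in known:
            return cand
    raise SamplingError(
        f"no valid corruption found for {positive} in "
        f"{_MAX_CORRUPT_ATTEMPTS} attempts"
    )


def make_batch(
    positives: list[Triplet],
    kg: KnowledgeGraph,
    stats: RelationStats,
    rng: np.random.Generator,
    known: frozenset[Triplet] | None = None,
) -> Batch:
    """One negative per positive, aligned."""
    negatives = [corrupt_triplet(p, kg, stats, rng, known) for p in positives]
    return Batch(positives=list(positives), negatives=negatives)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def margin_ranking_loss(
    pos_scores: np.ndarray, neg_scores: np.ndarray, gamma: float
) -> float:
    """``sum max(0, gamma - f_pos + f_neg)`` over aligned pairs."""
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.shape != neg.shape:
        raise ShapeError(f"shape mismatch: {pos.shape} vs {neg.shape}")
    return float(np.sum(np.maximum(0.0, gamma - pos + neg)))


def _margin_grads(pos, neg, gamma):
    active = (gamma - pos + neg) > 0
    return -active.astype(np.float64), active.astype(np.float64)


def softplus_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """``sum log(1 + exp(-y f))`` with labels y in {-1, +1}, overflow-safe."""
    f = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if f.shape != y.shape:
        raise ShapeError(f"shape mismatch: {f.shape} vs {y.shape}")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ContractError("labels must be +1 or -1")
    return float(np.sum(np.logaddexp(0.0, -y * f)))


def _softplus_grads(f, y):
    return -y * expit(-y * f)


# ---------------------------------------------------------------------------
# Analytic backward pass for score_batch
# ---------------------------------------------------------------------------

def score_batch_backward(
    params: ModelParams,
    modal: ModalArrays,
    cfg: ScoreConfig,
    cache: dict,
    df: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of ``sum(df * scores)`` w.r.t. every learnable tensor.

    ``cache`` is the forward cache from :func:`kgfuse.scoring.score_batch`.
    Returns a dict with the same keys/shapes as ``ModelParams.arrays()``
    (only the tensors touched by the configuration are present).
    """
    df = np.asarray(df, dtype=np.float64)
    grads: dict[str, np.ndarray] = {}
    dC = dD = None

    if cfg.fusion == "cross":
        dC_entity, dD_entity = _cross_backward(params, cfg, cache, df, grads)
        _modal_backward(params, modal, cfg, cache, None, None, grads,
                        dEC_extra=dC_entity, dED_extra=dD_entity)
        return grads

    if cfg.fusion == "none":
        dS = _plain_backward(params, cfg, cache, df, grads)
    elif cfg.fusion == "reverse_hp":
        dS, dC, dD = _reverse_hp_backward(params, cfg, cache, df, grads)
    else:
        dS, dC, dD = _forward_hp_backward(params, cfg, cache, df, grads)

    _backbone_backward(params, cfg, cache, dS, grads)
    _modal_backward(params, modal, cfg, cache, dC, dD, grads)
    return grads


def _score_weight_matrix(params, cache):
    """score_weight as a (k, n_f) matrix G with G[:, j] = filter-j block."""
    k = params.entity_emb.shape[1]
    n_f = params.conv_filters.shape[0]
    return params.score_weight.reshape(n_f, k).T


def _plain_backward(params, cfg, cache, df, grads):
    S = cache["S"]
    if cfg.backbone == "convkb":
        G = _score_weight_matrix(params, cache)
        _acc(grads, "score_weight",
             -(df @ S.transpose(0, 2, 1).reshape(S.shape[0], -1)))
        return -df[:, None, None] * G[None]
    return -2.0 * df[:, None] * S


def _reverse_hp_backward(params, cfg, cache, df, grads):
    S = cache["S"]
    if cfg.backbone == "convkb":
        return _reverse_hp_convkb_backward(params, cfg, cache, df, grads)
    safe = cache["safe"]
    inv = cache["inv"]
    dS = -2.0 * df[:, None] * S
    out = {"C": None, "D": None}
    for name, lam in (("C", cfg.lambda_c), ("D", cfg.lambda_d)):
        if lam == 0:
            continue
        M = cache[name]
        R = cache[f"R_{name}"]
        if cfg.snorm == "unit":
            a = cache[f"a_{name}"]
            dM = 2.0 * lam * df[:, None] * R
            dS += np.where(
                safe[:, None],
                -2.0 * lam * (df * a * inv)[:, None] * R,
                0.0,
            )
        else:  # S* = S/||S||^2
            s2 = cache["s2"]
            b = cache[f"b_{name}"]
            inv2 = np.where(safe, 1.0 / np.where(safe, s2, 1.0), 0.0)
            SdotR = np.einsum("nk,nk->n", S, R)
            SdotM = np.einsum("nk,nk->n", S, M)
            dM = 2.0 * lam * df[:, None] * (
                R - (SdotR * inv2**2)[:, None] * S
            )
            dbdS = M * (inv2**2)[:, None] - (4.0 * SdotM * inv2**3)[:, None] * S
            dS += np.where(
                safe[:, None],
                -2.0 * lam * df[:, None] * (b[:, None] * R + SdotR[:, None] * dbdS),
                0.0,
            )
            dM = np.where(safe[:, None], dM, 0.0)
        out[name] = np.where(safe[:, None], dM, 0.0)
    return dS, out["C"], out["D"]


def _reverse_hp_convkb_backward(params, cfg, cache, df, grads):
    S = cache["S"]
    n, k, n_f = S.shape
    G = _score_weight_matrix(params, cache)  # (k, n_f)
    safe = cache["col_safe"]
    inv = cache["col_inv"]
    dW = -(df @ S.transpose(0, 2, 1).reshape(n, -1))
    dS = -df[:, None, None] * G[None]
    out = {"C": None, "D": None}
    for name, lam in (("C", cfg.lambda_c), ("D", cfg.lambda_d)):
        if lam == 0:
            continue
        M = cache[name]  # (n, k)
        R = cache[f"R_{name}"]  # (n, k, n_f)
        dW += lam * (df @ R.transpose(0, 2, 1).reshape(n, -1))
        if cfg.snorm == "unit":
            U = cache[f"U_{name}"]
            a = cache[f"a_{name}"]  # (n, n_f)
            ug = np.einsum("nkf,kf->nf", U, G)
            dM_cols = np.where(
                safe[:, None, :], G[None] - U * ug[:, None, :], 0.0
            )
            dM = lam * df[:, None] * dM_cols.sum(axis=2)
            term = -(
                ug[:, None, :] * R
                + a[:, None, :] * (G[None] - ug[:, None, :] * U)
            ) * inv[:, None, :]
            dS += np.where(
                safe[:, None, :], lam * df[:, None, None] * term, 0.0
            )
        else:
            cn2 = cache["cn"] ** 2
            inv2 = np.where(safe, 1.0 / np.where(safe, cn2, 1.0), 0.0)
            b = cache[f"b_{name}"]  # (n, n_f)
            gS = np.einsum("kf,nkf->nf", G, S)
            SdotM = np.einsum("nkf,nk->nf", S, M)
            dM_cols = np.where(
                safe[:, None, :],
                G[None] - (gS * inv2**2)[:, None, :] * S,
                0.0,
            )
            dM = lam * df[:, None] * dM_cols.sum(axis=2)
            dbdS = (
                M[:, :, None] * (inv2**2)[:, None, :]
                - (4.0 * SdotM * inv2**3)[:, None, :] * S
            )
            term = -(b[:, None, :] * G[None] + gS[:, None, :] * dbdS)
            dS += np.where(
                safe[:, None, :], lam * df[:, None, None] * term, 0.0
            )
        out[name] = dM
    _acc(grads, "score_weight", dW)
    return dS, out["C"], out["D"]


def _forward_hp_backward(params, cfg, cache, df, grads):
    Sp = cache["Sp"]
    if Sp.ndim == 2:
        g = -2.0 * df[:, None] * Sp
    else:
        n = Sp.shape[0]
        G = _score_weight_matrix(params, cache)
        _acc(grads, "score_weight",
             -(df @ Sp.transpose(0, 2, 1).reshape(n, -1)))
        g = -df[:, None, None] * G[None]
    dmods = {"C": None, "D": None}
    for step in reversed(cache["hp_steps"]):
        m, c, lam = step["m"], step["c"], step["lam"]
        mask, minv, Sprev = step["mask"], step["minv"], step["Sprev"]
        if Sp.ndim == 2:
            mg = np.einsum("nk,nk->n", m, g)
            g_prev = np.where(mask[:, None], g - lam * mg[:, None] * m, g)
            grad_m = -lam * (mg[:, None] * Sprev + c[:, None] * g)
        else:
            mg = np.einsum("nk,nkf->nf", m, g)
            g_prev = np.where(
                mask[:, None, None], g - lam * m[:, :, None] * mg[:, None, :], g
            )
            grad_m = -lam * (
                np.einsum("nf,nkf->nk", mg, Sprev)
                + np.einsum("nf,nkf->nk", c, g)
            )
        mgm = np.einsum("nk,nk->n", m, grad_m)
        dM = np.where(
            mask[:, None],
            (grad_m - mgm[:, None] * m) * minv[:, None],
            0.0,
        )
        name = step["name"]
        dmods[name] = dM if dmods[name] is None else dmods[name] + dM
        g = g_prev
    return g, dmods["C"], dmods["D"]


def _backbone_backward(params, cfg, cache, dS, grads):
    h, r, t = cache["h"], cache["r"], cache["t"]
    if cfg.backbone == "transe":
        dEh, dRr, dEt = dS, dS, -dS
    elif cfg.backbone == "transh":
        W = cache["W"]
        Eh, Et = cache["Eh"], cache["Et"]
        wg = np.einsum("nk,nk->n", dS, W)
        dEh = dS - wg[:, None] * W
        dEt = -dEh
        dRr = dS
        dWn = (
            -(wg[:, None] * Eh + cache["ah"][:, None] * dS)
            + (wg[:, None] * Et + cache["at"][:, None] * dS)
        )
        dWn_full = np.zeros_like(params.relation_normal)
        np.add.at(dWn_full, r, dWn)
        _acc(grads, "relation_normal", dWn_full)
    else:  # convkb
        dpre = dS * cache["relu_mask"]
        F = params.conv_filters
        dEh = np.einsum("nkf,f->nk", dpre, F[:, 0])
        dRr = np.einsum("nkf,f->nk", dpre, F[:, 1])
        dEt = np.einsum("nkf,f->nk", dpre, F[:, 2])
        stacked = np.stack([cache["Eh"], cache["Rr"], cache["Et"]], axis=2)
        _acc(grads, "conv_filters", np.einsum("nkf,nkc->fc", dpre, stacked))
    dE = np.zeros_like(params.entity_emb)
    np.add.at(dE, h, dEh)
    np.add.at(dE, t, dEt)
    _acc(grads, "entity_emb", dE)
    dR = np.zeros_like(params.relation_emb)
    np.add.at(dR, r, dRr)
    _acc(grads, "relation_emb", dR)


def _modal_backward(params, modal, cfg, cache, dC, dD, grads,
                    dEC_extra=None, dED_extra=None):
    h, t = cache["h"], cache["t"]
    if cfg.lambda_c > 0 and (dC is not None or dEC_extra is not None):
        dEC = np.zeros((params.entity_emb.shape[0], params.entity_emb.shape[1]))
        if dC is not None:
            np.add.at(dEC, h, dC)
            np.add.at(dEC, t, -dC)
        if dEC_extra is not None:
            dEC += dEC_extra
        _acc(grads, "category_emb",
             np.asarray(modal.cat_matrix.T @ dEC))
    if cfg.lambda_d > 0 and (dD is not None or dED_extra is not None):
        dED = np.zeros((params.entity_emb.shape[0], params.entity_emb.shape[1]))
        if dD is not None:
            np.add.at(dED, h, dD)
            np.add.at(dED, t, -dD)
        if dED_extra is not None:
            dED += dED_extra
        _acc(grads, "desc_weight", modal.feat.T @ dED)


def _cross_backward(params, cfg, cache, df, grads):
    h, r, t = cache["h"], cache["r"], cache["t"]
    n, k = cache["Eh"].shape
    dE = np.zeros_like(params.entity_emb)
    dR = np.zeros_like(params.relation_emb)
    dEC_full = np.zeros((params.entity_emb.shape[0], k)) if cfg.lambda_c > 0 else None
    dED_full = np.zeros((params.entity_emb.shape[0], k)) if cfg.lambda_d > 0 else None
    dWn_full = (
        np.zeros_like(params.relation_normal) if cfg.backbone == "transh" else None
    )
    dF = np.zeros_like(params.conv_filters) if cfg.backbone == "convkb" else None
    dWS = np.zeros_like(params.score_weight) if cfg.backbone == "convkb" else None
    sgn = -1.0 if cfg.cross_residual == "flipped" else 1.0

    for tc in cache["cross_terms"]:
        tag, lam = tc["tag"], tc["lam"]
        X, Y = tc["X"], tc["Y"]
        if cfg.backbone == "convkb":
            S = tc["S"]
            dWS += -lam * (df @ S.transpose(0, 2, 1).reshape(n, -1))
            G = _score_weight_matrix(params, cache)
            dpre = (-lam * df[:, None, None] * G[None]) * tc["relu_mask"]
            F = params.conv_filters
            dX = np.einsum("nkf,f->nk", dpre, F[:, 0])
            dRr = np.einsum("nkf,f->nk", dpre, F[:, 1])
            dY = np.einsum("nkf,f->nk", dpre, F[:, 2])
            stacked = np.stack([X, cache["Rr"], Y], axis=2)
            dF += np.einsum("nkf,nkc->fc", dpre, stacked)
        else:
            g = -2.0 * lam * df[:, None] * tc["dvec"]
            if cfg.backbone == "transh":
                W = cache["W"]
                gX, gY = g, (-g if sgn > 0 else g)
                # through the hyperplane projections of both endpoints
                def back_proj(gZ, Z, aZ):
                    wg = np.einsum("nk,nk->n", gZ, W)
                    dZ = gZ - wg[:, None] * W
                    dWn = -(wg[:, None] * Z + aZ[:, None] * gZ)
                    return dZ, dWn
                dX, dWn_x = back_proj(gX, X, tc["ax"])
                dY, dWn_y = back_proj(gY, Y, tc["ay"])
                np.add.at(dWn_full, r, dWn_x + dWn_y)
                dRr = sgn * g
            else:
                dX = g
                dY = -g if sgn > 0 else g
                dRr = sgn * g
        np.add.at(dR, r, dRr)
        # route endpoint gradients
        if tag == "s":
            np.add.at(dE, h, dX)
            np.add.at(dE, t, dY)
        elif tag == "ch":
            np.add.at(dEC_full, h, dX)
            np.add.at(dE, t, dY)
        elif tag == "ct":
            np.add.at(dE, h, dX)
            np.add.at(dEC_full, t, dY)
        elif tag == "dh":
            np.add.at(dED_full, h, dX)
            np.add.at(dE, t, dY)
        else:  # "dt"
            np.add.at(dE, h, dX)
            np.add.at(dED_full, t, dY)

    _acc(grads, "entity_emb", dE)
    _acc(grads, "relation_emb", dR)
    if dWn_full is not None:
        _acc(grads, "relation_normal", dWn_full)
    if dF is not None:
        _acc(grads, "conv_filters", dF)
        _acc(grads, "score_weight", dWS)
    return dEC_full, dED_full


def _acc(grads, key, val):
    if key in grads:
        grads[key] = grads[key] + val
    else:
        grads[key] = val


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        arrays = params.arrays()
        for key, g in grads.items():
            p = arrays[key]
            if key not in self.m:
                self.m[key] = np.zeros_like(p)
                self.v[key] = np.zeros_like(p)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _corrupt_batch(h, r, t, p_head, n_ent, known, rng):
    """Vectorized Bernoulli corruption with bounded per-item resampling."""
    n = h.shape[0]
    ch = np.array(h)
    ct = np.array(t)
    heads_flag = rng.random(n) < p_head
    repl = rng.integers(0, n_ent, n)
    ch = np.where(heads_flag, repl, ch)
    ct = np.where(heads_flag, ct, repl)
    for i in range(n):
        attempts = 0
        while (int(ch[i]), int(r[i]), int(ct[i])) in known or (
            ch[i] == h[i] and ct[i] == t[i]
        ):
            attempts += 1
            if attempts > _MAX_CORRUPT_ATTEMPTS:
                raise SamplingError(
                    "no valid corruption found within the retry budget"
                )
            e = int(rng.integers(n_ent))
            if heads_flag[i]:
                ch[i] = e
            else:
                ct[i] = e
    return ch, ct


def fit(
    split: TripletSplit,
    annotations: AnnotationSet,
    hp: HyperParams,
) -> TrainState:
    """Mini-batch Adam training, fully deterministic given ``hp.seed``.

    Batch size is ``max(1, floor(batch_fraction * |train|))``; one Bernoulli
    negative per positive; margin ranking loss for TransE/TransH, softplus
    loss for ConvKB.  Validation filtered mean rank is computed every
    ``hp.eval_every`` epochs (when a validation set exists) and the
    best-MR parameter snapshot is retained.
    """
    hp.validate()
    train = split.train
    if len(train) == 0:
        raise ContractError("empty training set")
    cfg = ScoreConfig.from_hyperparams(hp)
    modal = build_modal_arrays(train, annotations)
    n_cat = max(len(annotations.category_vocab), 1)
    params = init_params(
        (len(train.entities), len(train.relations), n_cat, modal.d), hp
    )
    rng = np.random.default_rng(hp.seed)

    h_all, r_all, t_all = train.index_arrays()
    n_train = len(train)
    known = {
        (int(a), int(b), int(c))
        for a, b, c in zip(h_all, r_all, t_all)
    }
    for part in (split.valid, split.test):
        for tr in part.triplets:
            known.add(
                (
                    train.entities[tr.head],
                    train.relations[tr.relation],
                    train.entities[tr.tail],
                )
            )

    stats = relation_stats(train)
    p_head_by_rel = np.array(
        [
            bernoulli_head_probability(train.relations.name(j), stats)
            for j in range(len(train.relations))
        ]
    )

    batch_size = max(1, int(np.floor(hp.batch_fraction * n_train)))
    use_softplus = hp.backbone == "convkb"
    n_ent = len(train.entities)

    loss_history: list[float] = []
    best_mr = np.inf
    best_params = params.copy()
    adam = _Adam(hp.lr)
    have_valid = len(split.valid) > 0
    full_set = split.full_triplet_set()

    for epoch in range(hp.max_epochs):
        perm = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, batch_size):
            idx = perm[start : start + batch_size]
            h, r, t = h_all[idx], r_all[idx], t_all[idx]
            ch, ct = _corrupt_batch(
                h, r, t, p_head_by_rel[r], n_ent, known, rng
            )
            hh = np.concatenate([h, ch])
            rr = np.concatenate([r, r])
            tt = np.concatenate([t, ct])
            scores, cache = score_batch(
                params, modal, cfg, hh, rr, tt, need_cache=True
            )
            m = len(idx)
            if use_softplus:
                labels = np.concatenate([np.ones(m), -np.ones(m)])
                loss = softplus_loss(scores, labels)
                df = _softplus_grads(scores, labels)
            else:
                pos, neg = scores[:m], scores[m:]
                loss = margin_ranking_loss(pos, neg, hp.gamma)
                dp, dn = _margin_grads(pos, neg, hp.gamma)
                df = np.concatenate([dp, dn])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss
            grads = score_batch_backward(params, modal, cfg, cache, df)
            adam.step(params, grads)
            if hp.backbone == "transh":
                norms = np.linalg.norm(
                    params.relation_normal, axis=1, keepdims=True
                )
                norms[norms == 0] = 1.0
                params.relation_normal /= norms
        loss_history.append(epoch_loss)

        if have_valid and (
            (epoch + 1) % hp.eval_every == 0 or epoch + 1 == hp.max_epochs
        ):
            report = evaluation.entity_prediction_mr(
                split.valid, params, annotations, cfg, train, full_set
            )
            if report.mean_rank < best_mr:
                best_mr = report.mean_rank
                best_params = params.copy()

    final_params = best_params if np.isfinite(best_mr) else params
    return TrainState(
        params=final_params,
        epoch=hp.max_epochs,
        loss_history=loss_history,
        best_valid_mr=float(best_mr),
        rng_state=rng.bit_generator.state,
    )


def grid_search(
    split: TripletSplit,
    annotations: AnnotationSet,
    grid: dict[str, list],
    base_hp: HyperParams,
) -> tuple[HyperParams, TrainState]:
    """Full factorial search minimizing validation filtered mean rank.

    Ties break toward the earliest grid point in iteration order.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigError("every grid axis needs at least one value")
    if len(split.valid) == 0:
        raise ConfigError("grid search requires a non-empty validation set")
    keys = list(grid)
    best: tuple[HyperParams, TrainState] | None = None
    best_mr = np.inf
    for values in product(*(grid[k] for k in keys)):
        hp = replace(base_hp, **dict(zip(keys, values)))
        hp.validate()
        state = fit(split, annotations, hp)
        if state.best_valid_mr < best_mr:
            best_mr = state.best_valid_mr
            best = (hp, state)
    assert best is not None
    return best
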