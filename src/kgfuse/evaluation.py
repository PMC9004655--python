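"""Filtered entity-prediction ranking and typed-pair knowledge-graph completion.

Entity prediction: given (head, relation) predict the tail (and vice
versa).  Every entity in the vocabulary is scored as a candidate; under the
*filtered* setting, candidates other than the answer that form a known true
triplet (train u valid u test) are removed before ranking.  The headline
metric is the mean rank (MR) over both query directions; lower is better.

Completion: for a pair of entity types, every cross-type pair is scored
with the best relation substituted; the top-scored pairs not already linked
in training — at a scale of 10% of the training-set size — are retained as
inferred knowledge, evaluated by the pooled Association Precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import ModelParams
from .errors import ContractError, VocabularyError
from .kg_io import AnnotationSet, KnowledgeGraph, Triplet, TripletSplit
from .scoring import ModalArrays, ScoreConfig, build_modal_arrays, score_batch


@dataclass
class RankQuery:
    """One entity-prediction query: complete (e, r, ?) or (?, r, e)."""

    known_entity: str
    relation: str
    direction: str  # "predict_head" | "predict_tail"
    answer: str


@dataclass
class EvaluationReport:
    ranks: list[int]
    mean_rank: float
    mean_rank_head: float
    mean_rank_tail: float

    def to_text(self) -> str:
        return (
            f"queries\t{len(self.ranks)}\n"
            f"mean_rank\t{self.mean_rank:.6f}\n"
            f"mean_rank_predict_head\t{self.mean_rank_head:.6f}\n"
            f"mean_rank_predict_tail\t{self.mean_rank_tail:.6f}\n"
        )


@dataclass
class InferredPair:
    head: str
    tail: str
    score: float
    best_relation: str


def _rank_from_scores(
    scores: np.ndarray, answer_idx: int, keep: np.ndarray
) -> int:
    """Mid-tie rank of the answer among kept candidates (floor-rounded)."""
    a = scores[answer_idx]
    others = keep.copy()
    others[answer_idx] = False
    greater = int(np.sum(scores[others] > a))
    equal = int(np.sum(scores[others] == a))
    return 1 + greater + equal // 2


def _candidate_scores(
    params: ModelParams,
    modal: ModalArrays,
    cfg: ScoreConfig,
    known_idx: int,
    rel_idx: int,
    direction: str,
    n_ent: int,
) -> np.ndarray:
    cand = np.arange(n_ent, dtype=np.int64)
    fixed = np.full(n_ent, known_idx, dtype=np.int64)
    rel = np.full(n_ent, rel_idx, dtype=np.int64)
    if direction == "predict_tail":
        return score_batch(params, modal, cfg, fixed, rel, cand)
    if direction == "predict_head":
        return score_batch(params, modal, cfg, cand, rel, fixed)
    raise ContractError(f"unknown direction {direction!r}")


def filtered_rank(
    query: RankQuery,
    params: ModelParams,
    annotations: AnnotationSet,
    cfg: ScoreConfig,
    kg: KnowledgeGraph,
    known_triplets: frozenset[Triplet],
    modal: ModalArrays | None = None,
    candidate_type: str | None = None,
) -> int:
    """Filtered rank of the answer entity for one query.

    ``candidate_type`` optionally restricts candidates to one entity type
    (the default scores the full vocabulary).
    """
    ents = kg.entities
    if query.known_entity not in ents or query.answer not in ents:
        raise VocabularyError(f"unknown entity in query {query}")
    if query.relation not in kg.relations:
        raise VocabularyError(f"unknown relation {query.relation!r}")
    if modal is None:
        modal = build_modal_arrays(kg, annotations)
    n_ent = len(ents)
    known_idx = ents[query.known_entity]
    answer_idx = ents[query.answer]
    rel_idx = kg.relations[query.relation]
    scores = _candidate_scores(
        params, modal, cfg, known_idx, rel_idx, query.direction, n_ent
    )
    keep = np.ones(n_ent, dtype=bool)
    for j in range(n_ent):
        if j == answer_idx:
            continue
        name = ents.name(j)
        if query.direction == "predict_tail":
            trip = Triplet(query.known_entity, query.relation, name)
        else:
            trip = Triplet(name, query.relation, query.known_entity)
        if trip in known_triplets:
            keep[j] = False
        elif candidate_type is not None and kg.entity_type[name] != candidate_type:
            keep[j] = False
    return _rank_from_scores(scores, answer_idx, keep)


def raw_rank(
    query: RankQuery,
    params: ModelParams,
    annotations: AnnotationSet,
    cfg: ScoreConfig,
    kg: KnowledgeGraph,
    modal: ModalArrays | None = None,
) -> int:
    """Unfiltered rank (all candidates kept); filtered rank never exceeds it."""
    ents = kg.entities
    if modal is None:
        modal = build_modal_arrays(kg, annotations)
    scores = _candidate_scores(
        params,
        modal,
        cfg,
        ents[query.known_entity],
        kg.relations[query.relation],
        query.direction,
        len(ents),
    )
    return _rank_from_scores(
        scores, ents[query.answer], np.ones(len(ents), dtype=bool)
    )


def entity_prediction_mr(
    test: KnowledgeGraph,
    params: ModelParams,
    annotations: AnnotationSet,
    cfg: ScoreConfig,
    kg: KnowledgeGraph,
    known_triplets: frozenset[Triplet],
) -> EvaluationReport:
    """Mean filtered rank over both query directions of every test triplet."""
    if len(test) == 0:
        raise ContractError("empty test set")
    modal = build_modal_arrays(kg, annotations)
    head_ranks: list[int] = []
    tail_ranks: list[int] = []
    for trip in test.triplets:
        tail_ranks.append(
            filtered_rank(
                RankQuery(trip.head, trip.relation, "predict_tail", trip.tail),
                params, annotations, cfg, kg, known_triplets, modal=modal,
            )
        )
        head_ranks.append(
            filtered_rank(
                RankQuery(trip.tail, trip.relation, "predict_head", trip.head),
                params, annotations, cfg, kg, known_triplets, modal=modal,
            )
        )
    ranks = tail_ranks + head_ranks
    return EvaluationReport(
        ranks=ranks,
        mean_rank=float(np.mean(ranks)),
        mean_rank_head=float(np.mean(head_ranks)),
        mean_rank_tail=float(np.mean(tail_ranks)),
    )


def infer_typed_pairs(
    head_type: str,
    tail_type: str,
    params: ModelParams,
    annotations: AnnotationSet,
    cfg: ScoreConfig,
    split: TripletSplit,
) -> list[InferredPair]:
    """Score all (head_type, tail_type) pairs with the best relation.

    Every relation is substituted and the highest score retained per pair;
    pairs already connected in the training set (under any relation) are
    excluded; the top ``floor(0.1 * |train|)`` pairs are returned sorted by
    descending score (head, tail lexicographic tie-break).
    """
    kg = split.train
    heads = kg.entities_of_type(head_type)
    tails = kg.entities_of_type(tail_type)
    if not heads:
        raise VocabularyError(f"no entities of type {head_type!r}")
    if not tails:
        raise VocabularyError(f"no entities of type {tail_type!r}")
    modal = build_modal_arrays(kg, annotations)

    h_idx = np.array([kg.entities[e] for e in heads], dtype=np.int64)
    t_idx = np.array([kg.entities[e] for e in tails], dtype=np.int64)
    H, T = np.meshgrid(h_idx, t_idx, indexing="ij")
    Hf, Tf = H.ravel(), T.ravel()
    n_pairs = Hf.shape[0]

    best = np.full(n_pairs, -np.inf)
    best_rel = np.zeros(n_pairs, dtype=np.int64)
    for j in range(len(kg.relations)):
        rel = np.full(n_pairs, j, dtype=np.int64)
        s = score_batch(params, modal, cfg, Hf, rel, Tf)
        upd = s > best
        best[upd] = s[upd]
        best_rel[upd] = j

    connected = {
        (kg.entities[tr.head], kg.entities[tr.tail]) for tr in kg.triplets
    }
    items: list[InferredPair] = []
    for i in range(n_pairs):
        hi, ti = int(Hf[i]), int(Tf[i])
        if hi == ti or (hi, ti) in connected:
            continue
        items.append(
            InferredPair(
                head=kg.entities.name(hi),
                tail=kg.entities.name(ti),
                score=float(best[i]),
                best_relation=kg.relations.name(int(best_rel[i])),
            )
        )
    items.sort(key=lambda p: (-p.score, p.head, p.tail))
    cutoff = int(np.floor(0.1 * len(kg)))
    return items[:cutoff]


def association_precision(
    predictions: dict[str, list[str]], test_sets: dict[str, set[str]]
) -> float:
    """Pooled precision: ``sum_d |T_d n P_d| / sum_d |T_d|`` with ``P_d``
    the top ``|T_d|`` predictions for disease ``d`` (a single pooled ratio,
    not a per-disease mean)."""
    hits = 0
    total = 0
    for d, T in test_sets.items():
        if d not in predictions:
            raise ContractError(f"no prediction list for {d!r}")
        preds = predictions[d]
        if len(preds) < len(T):
            raise ContractError(
                f"prediction list for {d!r} shorter than its test set"
            )
        P = set(preds[: len(T)])
        hits += len(P & set(T))
        total += len(T)
    return hits / total if total else 0.0


def export_edge_list(
    existing: list[Triplet], inferred: list[InferredPair], path
) -> None:
    """Write existent + inferred edges as a deterministic TSV.

    Columns: head, tail, score (empty for existent edges), status.
    Ordering: status, then descending score, then lexicographic.
    """
    rows = []
    for tr in existing:
        rows.append(("existent", None, tr.head, tr.tail))
    for p in inferred:
        rows.append(("inferred", p.score, p.head, p.tail))
    rows.sort(
        key=lambda r: (
            r[0],
            -(r[1] if r[1] is not None else 0.0),
            r[2],
            r[3],
        )
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("head\ttail\tscore\tstatus\n")
        for status, score, head, tail in rows:
            s = "" if score is None else f"{score:.6f}"
            fh.write(f"{head}\t{tail}\t{s}\t{status}\n")
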