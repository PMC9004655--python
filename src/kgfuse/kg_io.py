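"""Triplet and annotation I/O, vocabularies, splits, and relation statistics.

A knowledge graph is a set of directed facts ``(head, relation, tail)`` over
string identifiers.  Biomedical entities follow a ``type-serial`` naming
pattern such as ``gene-00001``; the prefix before the last dash is parsed as
the entity type and drives typed-pair inference downstream.

File dialects
-------------
* Triplets: UTF-8 TSV, no header, ``head<TAB>relation<TAB>tail`` per line.
* Categories: TSV, ``entity<TAB>label1,label2,...``.
* Description features: either a TSV (``entity<TAB>v1<TAB>v2...``) or an
  HDF5 container with one dataset per entity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import ConfigError, ContractError, FormatError, ParseError

logger = logging.getLogger(__name__)

_TYPE_SERIAL = re.compile(r"^(?P<type>\S+)-(?P<serial>\d+)$")


class Triplet(NamedTuple):
    """A directed fact (head entity, relation, tail entity)."""

    head: str
    relation: str
    tail: str


class Vocabulary:
    """Bidirectional identifier <-> contiguous integer index map.

    Indices are assigned in first-appearance order, starting at 0.
    """

    __slots__ = ("_items", "_index")

    def __init__(self, items: Iterable[str] = ()):
        self._items: list[str] = []
        self._index: dict[str, int] = {}
        for it in items:
            self.add(it)

    def add(self, item: str) -> int:
        idx = self._index.get(item)
        if idx is None:
            idx = len(self._items)
            self._items.append(item)
            self._index[item] = idx
        return idx

    def __getitem__(self, item: str) -> int:
        return self._index[item]

    def get(self, item: str, default=None):
        return self._index.get(item, default)

    def name(self, idx: int) -> str:
        return self._items[idx]

    def __contains__(self, item: str) -> bool:
        return item in self._index

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocabulary) and self._items == other._items

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self._items)


def parse_entity_type(identifier: str) -> str:
    """Return the type prefix of a ``type-serial`` identifier, else ``unknown``."""
    m = _TYPE_SERIAL.match(identifier)
    if m is None:
        return "unknown"
    # the type is everything before the *last* dash
    return identifier.rsplit("-", 1)[0]


@dataclass
class KnowledgeGraph:
    """An ordered, duplicate-free triplet store with shared vocabularies."""

    triplets: tuple[Triplet, ...]
    entities: Vocabulary
    relations: Vocabulary
    entity_type: dict[str, str]

    @classmethod
    def from_triplets(
        cls,
        triplets: Iterable[Triplet],
        entities: Vocabulary | None = None,
        relations: Vocabulary | None = None,
    ) -> "KnowledgeGraph":
        """Build a graph, deduplicating triplets and (unless supplied)
        growing vocabularies in first-appearance order."""
        seen: dict[Triplet, None] = {}
        ents = entities if entities is not None else Vocabulary()
        rels = relations if relations is not None else Vocabulary()
        own_vocab = entities is None
        for t in triplets:
            if t in seen:
                continue
            seen[t] = None
            if own_vocab:
                ents.add(t.head)
                rels.add(t.relation)
                ents.add(t.tail)
        uniq = tuple(seen)
        etype = {e: parse_entity_type(e) for e in ents}
        return cls(uniq, ents, rels, etype)

    def __len__(self) -> int:
        return len(self.triplets)

    def triplet_set(self) -> frozenset[Triplet]:
        return frozenset(self.triplets)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Integer index arrays (heads, relations, tails) in triplet order."""
        n = len(self.triplets)
        h = np.empty(n, dtype=np.int64)
        r = np.empty(n, dtype=np.int64)
        t = np.empty(n, dtype=np.int64)
        for i, tr in enumerate(self.triplets):
            h[i] = self.entities[tr.head]
            r[i] = self.relations[tr.relation]
            t[i] = self.entities[tr.tail]
        return h, r, t

    def entities_of_type(self, type_label: str) -> list[str]:
        return [e for e in self.entities if self.entity_type[e] == type_label]


@dataclass
class TripletSplit:
    """Disjoint train/valid/test views sharing one vocabulary.

    Every entity and every relation occurs in at least one training triplet.
    """

    train: KnowledgeGraph
    valid: KnowledgeGraph
    test: KnowledgeGraph

    def full_triplet_set(self) -> frozenset[Triplet]:
        return frozenset(
            self.train.triplets + self.valid.triplets + self.test.triplets
        )

    @property
    def entities(self) -> Vocabulary:
        return self.train.entities

    @property
    def relations(self) -> Vocabulary:
        return self.train.relations


@dataclass
class AnnotationSet:
    """Per-entity category labels and fixed-length description features.

    Either modality may be empty; entities missing from a file carry an
    empty category set / no description vector (the null-annotation
    convention for partially annotated graphs).
    """

    categories: dict[str, frozenset[str]] = field(default_factory=dict)
    category_vocab: Vocabulary = field(default_factory=Vocabulary)
    description_features: dict[str, np.ndarray] = field(default_factory=dict)
    d: int | None = None

    def categories_of(self, entity: str) -> frozenset[str]:
        return self.categories.get(entity, frozenset())

    def feature_of(self, entity: str) -> np.ndarray | None:
        return self.description_features.get(entity)


@dataclass
class RelationStats:
    """Per-relation mean tails-per-head (tph) and heads-per-tail (hpt).

    These drive Bernoulli negative sampling: relations with many tails per
    head are preferentially corrupted on the head side, which reduces false
    negatives for non-1-to-1 relations.
    """

    tph: dict[str, float]
    hpt: dict[str, float]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_triplets(path) -> KnowledgeGraph:
    """Read a TSV triplet file into a :class:`KnowledgeGraph`.

    Duplicate lines collapse to a single triplet.  Lines with a field count
    other than 3 raise :class:`ParseError` naming the line number.
    """
    triplets: list[Triplet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            h, r, t = (f.strip() for f in fields)
            if not h or not r or not t:
                raise ParseError(f"{path}: line {lineno}: empty identifier")
            triplets.append(Triplet(h, r, t))
    return KnowledgeGraph.from_triplets(triplets)


def write_triplets(kg: KnowledgeGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in kg.triplets:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def split_kg(
    kg: KnowledgeGraph,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    coverage_repair: bool = True,
) -> TripletSplit:
    """Random train/valid/test partition with coverage repair.

    After the random partition at the requested fractions, any valid/test
    triplet containing an entity or relation absent from train is moved
    greedily into train, so every identifier is seen during training.
    Deterministic given ``seed``.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ConfigError("fractions must be three positive reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {sum(fractions)!r}")
    if len(kg) == 0:
        raise ContractError("cannot split an empty knowledge graph")

    rng = np.random.default_rng(seed)
    n = len(kg)
    perm = rng.permutation(n)
    n_valid = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_valid - n_test
    order = [kg.triplets[i] for i in perm]
    train = order[:n_train]
    valid = order[n_train : n_train + n_valid]
    test = order[n_train + n_valid :]

    if coverage_repair:
        covered_e = {t.head for t in train} | {t.tail for t in train}
        covered_r = {t.relation for t in train}

        def repair(part: list[Triplet]) -> list[Triplet]:
            kept = []
            for t in part:
                if (
                    t.head not in covered_e
                    or t.tail not in covered_e
                    or t.relation not in covered_r
                ):
                    train.append(t)
                    covered_e.add(t.head)
                    covered_e.add(t.tail)
                    covered_r.add(t.relation)
                else:
                    kept.append(t)
            return kept

        valid = repair(valid)
        test = repair(test)

    def view(part: list[Triplet]) -> KnowledgeGraph:
        return KnowledgeGraph(
            tuple(part), kg.entities, kg.relations, kg.entity_type
        )

    return TripletSplit(view(train), view(valid), view(test))


def read_annotations(
    category_path=None, feature_path=None, kg: KnowledgeGraph | None = None
) -> AnnotationSet:
    """Read category and/or description annotation files.

    Entities present in a file but absent from ``kg`` are ignored with a
    logged warning.  Both paths absent yields an empty annotation set (the
    structure-only configuration).
    """
    ann = AnnotationSet()
    known = kg.entities if kg is not None else None

    if category_path is not None:
        with open(category_path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ParseError(
                        f"{category_path}: line {lineno}: expected "
                        f"'entity<TAB>labels', got {len(fields)} fields"
                    )
                entity, labels_str = fields[0].strip(), fields[1]
                labels = frozenset(
                    s.strip() for s in labels_str.split(",") if s.strip()
                )
                if known is not None and entity not in known:
                    logger.warning(
                        "category annotation for unknown entity %r ignored",
                        entity,
                    )
                    continue
                for lab in sorted(labels):
                    ann.category_vocab.add(lab)
                ann.categories[entity] = labels

    if feature_path is not None:
        feats = _read_features(feature_path)
        d = None
        for entity, vec in feats.items():
            if known is not None and entity not in known:
                logger.warning(
                    "description feature for unknown entity %r ignored", entity
                )
                continue
            if d is None:
                d = vec.shape[0]
            elif vec.shape[0] != d:
                raise FormatError(
                    f"{feature_path}: entity {entity!r} has a feature vector "
                    f"of length {vec.shape[0]}, expected {d}"
                )
            ann.description_features[entity] = vec
        ann.d = d

    return ann


def _read_features(path) -> dict[str, np.ndarray]:
    spath = str(path)
    if spath.endswith((".h5", ".hdf5")):
        import h5py

        out: dict[str, np.ndarray] = {}
        with h5py.File(spath, "r") as f:
            for key in f:
                out[key] = np.asarray(f[key], dtype=np.float64)
        return out
    out = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected entity + >=1 float"
                )
            try:
                vec = np.array([float(x) for x in fields[1:]], dtype=np.float64)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            out[fields[0].strip()] = vec
    return out


def write_annotations(
    ann: AnnotationSet, category_path=None, feature_path=None
) -> None:
    """Write annotation files in the dialects :func:`read_annotations` reads."""
    if category_path is not None:
        with open(category_path, "w", encoding="utf-8") as fh:
            for entity in sorted(ann.categories):
                labels = ",".join(sorted(ann.categories[entity]))
                fh.write(f"{entity}\t{labels}\n")
    if feature_path is not None:
        spath = str(feature_path)
        if spath.endswith((".h5", ".hdf5")):
            import h5py

            with h5py.File(spath, "w") as f:
                for entity in sorted(ann.description_features):
                    f.create_dataset(entity, data=ann.description_features[entity])
        else:
            with open(feature_path, "w", encoding="utf-8") as fh:
                for entity in sorted(ann.description_features):
                    vals = "\t".join(
                        repr(float(v)) for v in ann.description_features[entity]
                    )
                    fh.write(f"{entity}\t{vals}\n")


def relation_stats(kg: KnowledgeGraph) -> RelationStats:
    """Mean tails-per-head and heads-per-tail for every relation in ``kg``."""
    if len(kg) == 0:
        raise ContractError("relation_stats requires a non-empty graph")
    heads: dict[str, set[str]] = {}
    tails: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for h, r, t in kg.triplets:
        counts[r] = counts.get(r, 0) + 1
        heads.setdefault(r, set()).add(h)
        tails.setdefault(r, set()).add(t)
    tph = {r: counts[r] / len(heads[r]) for r in counts}
    hpt = {r: counts[r] / len(tails[r]) for r in counts}
    return RelationStats(tph=tph, hpt=hpt)
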