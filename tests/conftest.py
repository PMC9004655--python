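import numpy as np
import pytest

import kgfuse as kf
from kgfuse.embedding import HyperParams, init_params
from kgfuse.scoring import build_modal_arrays


@pytest.fixture(scope="session")
def tiny_sk():
    """Small dense synthetic graph for oracle tests (fast to score)."""
    return kf.generate_synthetic_kg(
        kf.SyntheticConfig(
            num_entities=15,
            num_relations=4,
            num_triplets=40,
            epsilon=3.0,
            desc_dim=4,
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def rank_sk():
    """30-entity, 3-relation graph for exhaustive ranking checks."""
    return kf.generate_synthetic_kg(
        kf.SyntheticConfig(
            num_entities=30,
            num_relations=3,
            num_triplets=120,
            epsilon=3.0,
            desc_dim=6,
            seed=11,
        )
    )


def random_params(kg, ann, hp: HyperParams, seed=9, scale=0.4):
    """Model parameters filled with Gaussian noise (normals re-normalized)."""
    params = init_params(
        (len(kg.entities), len(kg.relations), max(len(ann.category_vocab), 1),
         ann.d or 1),
        hp,
    )
    rng = np.random.default_rng(seed)
    for arr in params.arrays().values():
        arr[...] = rng.normal(0.0, scale, arr.shape)
    norms = np.linalg.norm(params.relation_normal, axis=1, keepdims=True)
    params.relation_normal /= norms
    return params


@pytest.fixture
def modal_of():
    return lambda sk: build_modal_arrays(sk.kg, sk.annotations)


ALL_CONFIGS = [
    (backbone, fusion, snorm)
    for backbone in ("transe", "transh", "convkb")
    for fusion in ("none", "reverse_hp", "hp", "cross")
    for snorm in (("unit", "squared") if fusion == "reverse_hp" else ("unit",))
]


def make_hp(backbone, fusion, snorm="unit", k=5, n_f=2, seed=7, **kw):
    lc, ld = (0.3, 0.2) if fusion != "none" else (0.0, 0.0)
    return HyperParams(
        k=k, n_f=n_f, backbone=backbone, fusion=fusion,
        lambda_c=kw.pop("lambda_c", lc), lambda_d=kw.pop("lambda_d", ld),
        snorm=snorm, seed=seed, **kw,
    )
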