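import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kgfuse as kf
from kgfuse.errors import ConfigError, ContractError, DegenerateHyperplaneError
from kgfuse.scoring import ScoreConfig, build_modal_arrays, score_batch

from conftest import ALL_CONFIGS, make_hp, random_params


# ---------------------------------------------------------------------------
# Independent direct-formula oracles (intentionally naive transcriptions)
# ---------------------------------------------------------------------------

def oracle_reverse_hp(S, C, D, lc, ld, snorm="unit"):
    S = np.asarray(S, float)
    f = -np.sum(S * S)
    for M, lam in ((C, lc), (D, ld)):
        if lam == 0:
            continue
        nrm = np.linalg.norm(S)
        if nrm == 0:
            continue
        star = S / nrm if snorm == "unit" else S / nrm**2
        R = M - np.dot(star, M) * star
        f += lam * np.sum(R * R)
    return f


def oracle_convkb(S, C, D, W, lc, ld, snorm="unit"):
    S = np.asarray(S, float)
    k, nf = S.shape
    vec = lambda X: np.concatenate([X[:, j] for j in range(nf)])
    f = -np.dot(W, vec(S))
    for M, lam in ((C, lc), (D, ld)):
        if lam == 0:
            continue
        R = np.zeros_like(S)
        for j in range(nf):
            col = S[:, j]
            nrm = np.linalg.norm(col)
            if nrm == 0:
                continue
            star = col / nrm if snorm == "unit" else col / nrm**2
            R[:, j] = M - np.dot(star, M) * star
        f += lam * np.dot(W, vec(R))
    return f


def oracle_forward_hp(S, C, D, lc, ld):
    S = np.asarray(S, float).copy()
    for M, lam in ((C, lc), (D, ld)):
        if lam == 0 or M is None or np.linalg.norm(M) == 0:
            continue
        m = M / np.linalg.norm(M)
        S = S - lam * np.dot(m, S) * m
    return -np.sum(S * S)


def oracle_cross(h, r, t, hc, tc, hd, td, lc, ld):
    base = lambda x, y: -np.sum((x + r - y) ** 2)
    f = base(h, t)
    if lc:
        f += lc * (base(hc, t) + base(h, tc))
    if ld:
        f += ld * (base(hd, t) + base(h, td))
    return f


def oracle_gram_schmidt_residual(M, S):
    u = S / np.linalg.norm(S)
    return M - np.dot(M, u) * u


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

class TestUnitHyperplane:
    def test_three_four_five(self):
        np.testing.assert_allclose(
            kf.unit_hyperplane(np.array([3.0, 4.0])), [0.6, 0.8]
        )

    def test_idempotent_on_unit_input(self):
        u = np.array([0.6, 0.8])
        np.testing.assert_allclose(kf.unit_hyperplane(u), u)

    def test_norm_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            S = rng.normal(size=int(rng.integers(1, 9)))
            if np.linalg.norm(S) == 0:
                continue
            assert abs(np.linalg.norm(kf.unit_hyperplane(S)) - 1) < 1e-12

    def test_zero_vector_degenerate(self):
        with pytest.raises(DegenerateHyperplaneError):
            kf.unit_hyperplane(np.zeros(4))


class TestHyperplaneResidual:
    def test_parallel_annihilated(self):
        np.testing.assert_allclose(
            kf.hyperplane_residual(np.array([5.0, 0.0]), np.array([2.0, 0.0])),
            [0.0, 0.0],
            atol=1e-12,
        )

    def test_on_plane_unchanged(self):
        np.testing.assert_allclose(
            kf.hyperplane_residual(np.array([0.0, 3.0]), np.array([2.0, 0.0])),
            [0.0, 3.0],
        )

    def test_gram_schmidt_oracle_and_orthogonality(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = int(rng.integers(2, 9))
            M, S = rng.normal(size=(2, k))
            R = kf.hyperplane_residual(M, S)
            np.testing.assert_allclose(R, oracle_gram_schmidt_residual(M, S), atol=1e-10)
            assert abs(np.dot(R, S)) < 1e-9 * max(1.0, np.linalg.norm(S))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(2, 8), st.integers(0, 10**6))
    def test_contraction(self, k, seed):
        rng = np.random.default_rng(seed)
        M, S = rng.normal(size=(2, k))
        R = kf.hyperplane_residual(M, S)
        assert np.linalg.norm(R) <= np.linalg.norm(M) + 1e-12


class TestReverseHpScore:
    def test_reduces_to_neg_norm(self):
        cfg = ScoreConfig(fusion="reverse_hp", backbone="transe")
        assert kf.score_translational_reverse_hp(
            np.array([1.0, 2.0]), None, None, cfg
        ) == pytest.approx(-5.0)

    def test_orthogonal_residual_closed_form(self):
        cfg = ScoreConfig(fusion="reverse_hp", lambda_c=0.5, backbone="transe")
        f = kf.score_translational_reverse_hp(
            np.array([1.0, 0.0]), np.array([0.0, 2.0]), None, cfg
        )
        assert f == pytest.approx(-1.0 + 0.5 * 4.0)

    def test_missing_modal_with_positive_lambda(self):
        cfg = ScoreConfig(fusion="reverse_hp", lambda_c=0.5, backbone="transe")
        with pytest.raises(ContractError):
            kf.score_translational_reverse_hp(np.ones(2), None, None, cfg)

    @pytest.mark.parametrize("snorm", ["unit", "squared"])
    def test_direct_formula_oracle(self, snorm):
        rng = np.random.default_rng(2)
        for _ in range(100):
            k = int(rng.integers(2, 9))
            S, C, D = rng.normal(size=(3, k))
            lc, ld = rng.uniform(0, 0.6, 2)
            cfg = ScoreConfig(
                fusion="reverse_hp", lambda_c=lc, lambda_d=ld,
                backbone="transe", snorm=snorm,
            )
            f = kf.score_translational_reverse_hp(S, C, D, cfg)
            assert f == pytest.approx(oracle_reverse_hp(S, C, D, lc, ld, snorm), abs=1e-9)

    def test_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        S, C, D = rng.normal(size=(3, 6))
        prev = -np.inf
        for lam in np.linspace(0, 1, 11):
            cfg = ScoreConfig(
                fusion="reverse_hp", lambda_c=lam, lambda_d=lam, backbone="transe"
            )
            f = kf.score_translational_reverse_hp(S, C, D, cfg)
            assert f >= prev - 1e-12
            prev = f


class TestConvkbScore:
    def test_plain_weighted_sum(self):
        cfg = ScoreConfig(fusion="reverse_hp", backbone="convkb")
        S = np.full((2, 1), 0.1)
        assert kf.score_convkb(S, None, None, np.array([1.0, 1.0]), cfg) == pytest.approx(-0.2)

    def test_zero_modal_annihilates(self):
        cfg = ScoreConfig(fusion="reverse_hp", lambda_c=0.7, backbone="convkb")
        S = np.array([[0.5], [0.2]])
        W = np.array([1.0, -1.0])
        f0 = kf.score_convkb(S, np.zeros(2), None, W, ScoreConfig(
            fusion="reverse_hp", lambda_c=0.7, backbone="convkb"))
        f1 = kf.score_convkb(S, None, None, W, ScoreConfig(
            fusion="reverse_hp", backbone="convkb"))
        assert f0 == pytest.approx(f1)

    def test_per_column_projection_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            k, nf = int(rng.integers(2, 7)), int(rng.integers(1, 4))
            S = rng.normal(size=(k, nf))
            C, D = rng.normal(size=(2, k))
            W = rng.normal(size=k * nf)
            lc, ld = rng.uniform(0, 0.5, 2)
            cfg = ScoreConfig(fusion="reverse_hp", lambda_c=lc, lambda_d=ld, backbone="convkb")
            f = kf.score_convkb(S, C, D, W, cfg)
            assert f == pytest.approx(oracle_convkb(S, C, D, W, lc, ld), abs=1e-9)


class TestForwardHpScore:
    def test_no_projection_at_zero_lambda(self):
        cfg = ScoreConfig(fusion="hp", backbone="transe")
        S = np.array([1.0, 2.0])
        assert kf.score_forward_hp(S, None, None, cfg) == pytest.approx(-5.0)

    def test_full_absorption_by_parallel_category(self):
        cfg = ScoreConfig(fusion="hp", lambda_c=1.0, backbone="transe")
        S = np.array([2.0, 0.0])
        C = np.array([4.0, 0.0])  # parallel to S
        assert kf.score_forward_hp(S, C, None, cfg) == pytest.approx(0.0)

    def test_sequential_projection_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 9))
            S, C, D = rng.normal(size=(3, k))
            lc, ld = rng.uniform(0, 0.8, 2)
            cfg = ScoreConfig(fusion="hp", lambda_c=lc, lambda_d=ld, backbone="transe")
            f = kf.score_forward_hp(S, C, D, cfg)
            assert f == pytest.approx(oracle_forward_hp(S, C, D, lc, ld), abs=1e-9)


class TestCrossScore:
    def test_all_zero(self):
        cfg = ScoreConfig(fusion="cross", lambda_c=1.0, lambda_d=1.0, backbone="transe")
        z = np.zeros(3)
        assert kf.score_cross_embedding(z, z, z, z, z, z, z, cfg) == 0.0

    def test_consistent_translations_vanish(self):
        cfg = ScoreConfig(fusion="cross", lambda_c=1.0, lambda_d=1.0, backbone="transe")
        r = np.array([1.0, -1.0])
        h = np.array([0.5, 0.5])
        t = h + r
        f = kf.score_cross_embedding(h, r, t, h, t, h, t, cfg)
        assert f == pytest.approx(0.0)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            k = int(rng.integers(2, 9))
            h, r, t, hc, tc, hd, td = rng.normal(size=(7, k))
            lc, ld = rng.uniform(0, 0.7, 2)
            cfg = ScoreConfig(fusion="cross", lambda_c=lc, lambda_d=ld, backbone="transe")
            f = kf.score_cross_embedding(h, r, t, hc, tc, hd, td, cfg)
            assert f == pytest.approx(oracle_cross(h, r, t, hc, tc, hd, td, lc, ld), abs=1e-9)


class TestScoreTriplet:
    def test_fusion_none_ignores_annotations(self, tiny_sk):
        hp = make_hp("transe", "none")
        params = random_params(tiny_sk.kg, tiny_sk.annotations, hp)
        cfg = ScoreConfig.from_hyperparams(hp)
        scrambled = kf.annotation_scramble(tiny_sk, seed=1)
        for trip in tiny_sk.kg.triplets[:10]:
            a = kf.score_triplet(trip, params, tiny_sk.annotations, cfg, tiny_sk.kg)
            b = kf.score_triplet(trip, params, scrambled, cfg, tiny_sk.kg)
            assert a == b

    def test_reverse_hp_zero_category_matrix_collapses(self, tiny_sk):
        hp = make_hp("transe", "reverse_hp", lambda_d=0.0)
        params = random_params(tiny_sk.kg, tiny_sk.annotations, hp)
        params.category_emb[...] = 0.0
        cfg = ScoreConfig.from_hyperparams(hp)
        cfg0 = ScoreConfig(fusion="none", backbone="transe")
        for trip in tiny_sk.kg.triplets[:10]:
            a = kf.score_triplet(trip, params, tiny_sk.annotations, cfg, tiny_sk.kg)
            b = kf.score_triplet(trip, params, tiny_sk.annotations, cfg0, tiny_sk.kg)
            assert a == pytest.approx(b, abs=1e-12)

    def test_compositional_oracle(self, tiny_sk):
        """score_triplet equals a manual composition of the primitives."""
        hp = make_hp("transh", "reverse_hp", k=5)
        params = random_params(tiny_sk.kg, tiny_sk.annotations, hp)
        cfg = ScoreConfig.from_hyperparams(hp)
        ann = tiny_sk.annotations
        kg = tiny_sk.kg
        for trip in kg.triplets[:10]:
            S = kf.structure_transh(
                params.entity_emb[kg.entities[trip.head]],
                params.relation_emb[kg.relations[trip.relation]],
                params.entity_emb[kg.entities[trip.tail]],
                params.relation_normal[kg.relations[trip.relation]],
            )
            C = kf.modal_difference(
                kf.entity_category_embedding(trip.head, ann, params.category_emb),
                kf.entity_category_embedding(trip.tail, ann, params.category_emb),
            )
            D = kf.modal_difference(
                kf.entity_description_embedding(trip.head, ann, params.desc_weight),
                kf.entity_description_embedding(trip.tail, ann, params.desc_weight),
            )
            expected = kf.score_translational_reverse_hp(S, C, D, cfg)
            got = kf.score_triplet(trip, params, ann, cfg, kg)
            assert got == pytest.approx(expected, abs=1e-10)


def test_forward_and_reverse_coincide_at_zero_lambda(tiny_sk):
    for backbone in ("transe", "convkb"):
        hp_f = make_hp(backbone, "hp", lambda_c=0.0, lambda_d=0.0)
        hp_r = make_hp(backbone, "reverse_hp", lambda_c=0.0, lambda_d=0.0)
        params = random_params(tiny_sk.kg, tiny_sk.annotations, hp_f)
        for trip in tiny_sk.kg.triplets[:8]:
            a = kf.score_triplet(trip, params, tiny_sk.annotations,
                                 ScoreConfig.from_hyperparams(hp_f), tiny_sk.kg)
            b = kf.score_triplet(trip, params, tiny_sk.annotations,
                                 ScoreConfig.from_hyperparams(hp_r), tiny_sk.kg)
            assert a == pytest.approx(b, abs=1e-12)


def test_config_s_forces_zero_lambdas():
    with pytest.raises(ConfigError):
        ScoreConfig(fusion="none", lambda_c=0.1)


@pytest.mark.parametrize("backbone,fusion,snorm", ALL_CONFIGS)
def test_batch_scorer_matches_per_triplet_path(tiny_sk, backbone, fusion, snorm):
    """The vectorized scorer agrees with the primitive-composition path for
    every backbone x fusion x normalization combination."""
    hp = make_hp(backbone, fusion, snorm)
    params = random_params(tiny_sk.kg, tiny_sk.annotations, hp)
    cfg = ScoreConfig.from_hyperparams(hp)
    modal = build_modal_arrays(tiny_sk.kg, tiny_sk.annotations)
    h, r, t = tiny_sk.kg.index_arrays()
    vec = score_batch(params, modal, cfg, h, r, t)
    scal = np.array([
        kf.score_triplet(trip, params, tiny_sk.annotations, cfg, tiny_sk.kg)
        for trip in tiny_sk.kg.triplets
    ])
    np.testing.assert_allclose(vec, scal, atol=1e-10)
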