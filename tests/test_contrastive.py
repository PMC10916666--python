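"""Patch NCE loss oracles, projection invariants and the momentum bank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noch import nn
from noch.contrastive import (DEFAULT_TAU, FeatureProjector, NegativeBank,
                              PatchFeatureSet, ProjectorConfig,
                              cross_contrastive_negatives, momentum_update,
                              nce_loss, patchnce_from_features,
                              patchnce_loss_X, patchnce_loss_Y,
                              project_and_sample)
from noch.generator import GeneratorConfig, ResnetGenerator, extract_features
from noch.imagedata import StainedImage


def brute_force_nce(q, p, negs, tau):
    """Independent oracle: explicit (N+1)-way softmax cross-entropy computed
    directly from exponentials at high precision."""
    logits = np.concatenate([[np.dot(q, p)], negs @ q]) / tau
    exps = np.exp(logits - logits.max())
    return float(-np.log(exps[0] / exps.sum()))


def unit_vectors(rng, n, k):
    v = rng.normal(size=(n, k))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# -- nce_loss -----------------------------------------------------------------

@pytest.mark.parametrize("N", [1, 8, 255])
def test_nce_uniform_logits_give_log_n_plus_1(N):
    k = 8
    q = np.zeros(k)
    q[0] = 1.0
    p = np.zeros(k)
    p[1] = 1.0            # q.p = 0
    negs = np.zeros((N, k))
    negs[:, 2] = 1.0      # q.neg = 0 for all negatives
    val = float(nce_loss(q, p, negs, tau=DEFAULT_TAU).data)
    assert val == pytest.approx(np.log(N + 1), abs=1e-12)


def test_nce_255_orthogonal_negatives_matches_brute_force():
    rng = np.random.default_rng(1)
    k = 256
    q = np.zeros(k)
    q[0] = 1.0
    negs = np.zeros((255, k))
    negs[np.arange(255), 1 + np.arange(255)] = 1.0   # all orthogonal to q
    val = float(nce_loss(q, q, negs, tau=0.07).data)
    assert val == pytest.approx(brute_force_nce(q, q, negs, 0.07), abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10**6), st.integers(1, 16))
def test_nce_matches_enumeration_oracle(seed, N):
    rng = np.random.default_rng(seed)
    vs = unit_vectors(rng, N + 2, 8)
    q, p, negs = vs[0], vs[1], vs[2:]
    val = float(nce_loss(q, p, negs, tau=0.07).data)
    assert val == pytest.approx(brute_force_nce(q, p, negs, 0.07), abs=1e-6)
    assert val >= 0.0


def test_nce_monotonicity_in_logits():
    """Loss strictly decreases in q.p and strictly increases in q.v_n."""
    k = 4
    base_p = np.array([1.0, 0, 0, 0])
    q = np.array([1.0, 0, 0, 0])
    negs = unit_vectors(np.random.default_rng(0), 5, k)

    def loss_with_pos(alpha):
        p = np.array([np.cos(alpha), np.sin(alpha), 0, 0])
        return float(nce_loss(q, p, negs, 0.07).data)

    assert loss_with_pos(0.1) < loss_with_pos(0.3) < loss_with_pos(0.6)

    def loss_with_neg(alpha):
        n2 = negs.copy()
        n2[0] = np.array([np.cos(alpha), np.sin(alpha), 0, 0])
        return float(nce_loss(q, base_p, n2, 0.07).data)

    assert loss_with_neg(0.6) > loss_with_neg(1.0) > loss_with_neg(1.4)


def test_nce_approaches_zero_for_perfect_match():
    k = 16
    q = np.zeros(k)
    q[0] = 1.0
    negs = -np.tile(q, (8, 1))   # strongly non-positive logits
    val = float(nce_loss(q, q, negs, 0.07).data)
    assert 0 <= val < 1e-8


def test_nce_rejects_bad_inputs():
    q = np.array([1.0, 0.0])
    with pytest.raises(ValueError):
        nce_loss(q, q, np.zeros((3, 2)), tau=0.0)
    with pytest.raises(ValueError):
        nce_loss(q, np.array([np.nan, 0.0]), np.zeros((3, 2)), tau=0.07)


# -- projection / sampling -----------------------------------------------------

def _feature_stacks(rng, shapes=((1, 3, 16, 16), (1, 8, 8, 8))):
    fx = [nn.Tensor(rng.normal(size=s)) for s in shapes]
    fy = [nn.Tensor(rng.normal(size=s)) for s in shapes]
    return fx, fy


def test_project_and_sample_unit_norm_and_pairing(rng):
    fx, fy = _feature_stacks(rng)
    proj = FeatureProjector(ProjectorConfig(K=16, hidden_width=16, seed=0))
    fs = project_and_sample(fx, fy, proj, n_locations=10,
                            rng=np.random.default_rng(3))
    assert len(fs.z) == len(fs.z_hat) == 2
    for norms in fs.norms():
        assert np.allclose(norms, 1.0, atol=1e-5)
    for z, zh, loc in zip(fs.z, fs.z_hat, fs.locations):
        assert z.shape == zh.shape == (10, 16)
        assert len(loc) == 10


def test_project_and_sample_deterministic_with_seed(rng):
    fx, fy = _feature_stacks(rng)
    proj = FeatureProjector(ProjectorConfig(K=16, hidden_width=16, seed=0))
    fs1 = project_and_sample(fx, fy, proj, 10, np.random.default_rng(42))
    fs2 = project_and_sample(fx, fy, proj, 10, np.random.default_rng(42))
    for a, b in zip(fs1.locations, fs2.locations):
        assert np.array_equal(a, b)
    for a, b in zip(fs1.z, fs2.z):
        assert np.array_equal(a.data, b.data)


def test_project_and_sample_rejects_oversampling(rng):
    fx, fy = _feature_stacks(rng)
    proj = FeatureProjector(ProjectorConfig(K=8, hidden_width=8, seed=0))
    with pytest.raises(ValueError, match="sample"):
        project_and_sample(fx, fy, proj, n_locations=100,
                           rng=np.random.default_rng(0))


def test_n_locations_256_gives_255_negatives_per_query(rng):
    """A 64x64 layer has 4096 spatial positions; sampling 256 pairs each
    query with exactly 255 within-image negatives."""
    fx = [nn.Tensor(rng.normal(size=(1, 4, 64, 64)))]
    fy = [nn.Tensor(rng.normal(size=(1, 4, 64, 64)))]
    proj = FeatureProjector(ProjectorConfig(K=8, hidden_width=8, seed=0))
    fs = project_and_sample(fx, fy, proj, 256, np.random.default_rng(0))
    assert fs.z[0].shape[0] == 256
    # uniform-similarity check: replacing all vectors with copies of one
    # vector gives exactly 256-way uniform logits -> loss = n * ln(256)
    one = fs.z[0].data[0]
    fs_uniform = PatchFeatureSet(
        [0], fs.locations,
        [nn.Tensor(np.tile(one, (256, 1)))],
        [nn.Tensor(np.tile(one, (256, 1)))])
    val = float(patchnce_from_features(fs_uniform, tau=0.07).data)
    assert val == pytest.approx(256 * np.log(256), rel=1e-9)


# -- patch NCE over layers -----------------------------------------------------

def two_location_oracle(q, k, tau):
    """Hand enumeration for n=2: each query has exactly one negative."""
    total = 0.0
    for s in range(2):
        pos = np.dot(q[s], k[s]) / tau
        neg = np.dot(q[s], k[1 - s]) / tau
        m = max(pos, neg)
        total += -(pos - m - np.log(np.exp(pos - m) + np.exp(neg - m)))
    return total


def test_patchnce_two_locations_matches_hand_computation(rng):
    q = unit_vectors(rng, 2, 8)
    k = unit_vectors(rng, 2, 8)
    fs = PatchFeatureSet([0], [np.array([0, 1])],
                         [nn.Tensor(k)], [nn.Tensor(q)])
    val = float(patchnce_from_features(fs, tau=0.07).data)
    assert val == pytest.approx(two_location_oracle(q, k, 0.07), abs=1e-9)


def test_patchnce_permutation_invariant(rng):
    q = unit_vectors(rng, 6, 8)
    k = unit_vectors(rng, 6, 8)
    perm = np.random.default_rng(0).permutation(6)
    fs = PatchFeatureSet([0], [np.arange(6)], [nn.Tensor(k)], [nn.Tensor(q)])
    fs_p = PatchFeatureSet([0], [np.arange(6)],
                           [nn.Tensor(k[perm])], [nn.Tensor(q[perm])])
    a = float(patchnce_from_features(fs).data)
    b = float(patchnce_from_features(fs_p).data)
    assert a == pytest.approx(b, rel=1e-12)


def test_matched_features_beat_shuffled_features(rng):
    z = unit_vectors(rng, 12, 8)
    fs_match = PatchFeatureSet([0], [np.arange(12)],
                               [nn.Tensor(z)], [nn.Tensor(z)])
    shuffled = z[np.random.default_rng(1).permutation(12)]
    fs_shuf = PatchFeatureSet([0], [np.arange(12)],
                              [nn.Tensor(z)], [nn.Tensor(shuffled)])
    assert float(patchnce_from_features(fs_match).data) < \
        float(patchnce_from_features(fs_shuf).data)


def test_mean_reduction_scales_sum_by_locations(rng):
    q = unit_vectors(rng, 5, 8)
    k = unit_vectors(rng, 5, 8)
    fs = PatchFeatureSet([0], [np.arange(5)], [nn.Tensor(k)], [nn.Tensor(q)])
    s = float(patchnce_from_features(fs, reduction="sum").data)
    m = float(patchnce_from_features(fs, reduction="mean").data)
    assert s == pytest.approx(5 * m, rel=1e-12)


# -- image-level losses --------------------------------------------------------

@pytest.fixture(scope="module")
def small_model():
    return ResnetGenerator(GeneratorConfig(in_channels=3, base_width=4,
                                           n_res_blocks=1, seed=0))


def _stained(rng, size=32):
    return StainedImage(rng.uniform(0, 255, (size, size, 3)),
                        pixel_size_um=0.65)


def test_patchnce_loss_Y_uses_identity_pass_per_definition(small_model, rng):
    """The Y-domain loss mirrors the X-domain loss with roles swapped:
    queries come from y itself, keys from G(y)."""
    y = _stained(rng)
    proj = FeatureProjector(ProjectorConfig(K=8, hidden_width=8, seed=0))
    val = float(patchnce_loss_Y(y, small_model, proj,
                                np.random.default_rng(5),
                                n_locations=16).data)
    # manual reconstruction with the same seed
    from noch.generator import translate
    y_idt = translate(y, small_model)
    feats_y = extract_features(y, small_model)
    feats_idt = extract_features(y_idt, small_model)
    fs = project_and_sample(feats_y, feats_idt, proj, 16,
                            np.random.default_rng(5),
                            layer_ids=list(small_model.cfg.chosen_layers))
    manual = float(patchnce_from_features(fs, query_side="z").data)
    assert val == pytest.approx(manual, rel=1e-9)


def test_patchnce_loss_X_finite_and_positive(small_model, rng):
    from noch.imagedata import MultichannelImage
    x = MultichannelImage(rng.uniform(0, 255, (32, 32, 3)),
                          ["3PA_NADH", "SHG", "2PA_FAD"])
    proj = FeatureProjector(ProjectorConfig(K=8, hidden_width=8, seed=0))
    val = float(patchnce_loss_X(x, small_model, proj,
                                np.random.default_rng(0),
                                n_locations=16).data)
    assert np.isfinite(val) and val > 0


def test_patchnce_loss_Y_rejects_wrong_channels(rng):
    model2 = ResnetGenerator(GeneratorConfig(in_channels=2, base_width=4,
                                             n_res_blocks=1, seed=0))
    proj = FeatureProjector(ProjectorConfig(K=8, hidden_width=8, seed=0))
    with pytest.raises(ValueError, match="in_channels"):
        patchnce_loss_Y(_stained(rng), model2, proj, np.random.default_rng(0))


# -- cross-contrastive ---------------------------------------------------------

def test_bank_fifo_semantics():
    bank = NegativeBank(capacity=1024, momentum_m=0.999)
    rng = np.random.default_rng(0)
    bank.push(0, unit_vectors(rng, 256, 8))
    assert bank.size(0) == 256
    for _ in range(4):
        bank.push(0, unit_vectors(rng, 256, 8))
    assert bank.size(0) == 1024
    marked = np.full((1, 8), 0.5)
    bank.push(0, marked)
    assert bank.size(0) == 1024
    assert np.allclose(bank.negatives(0)[-1], 0.5)   # newest at the tail


def test_momentum_one_is_a_fixed_point():
    rng = np.random.default_rng(0)
    main = nn.Linear(4, 4, rng)
    aux = nn.Linear(4, 4, rng)
    before = aux.state_dict()
    momentum_update(main, aux, m=1.0)
    after = aux.state_dict()
    for k in before:
        assert np.array_equal(before[k], after[k])


def test_momentum_update_moves_toward_main():
    rng = np.random.default_rng(0)
    main = nn.Linear(4, 4, rng)
    aux = nn.Linear(4, 4, rng)
    momentum_update(main, aux, m=0.0)
    assert np.allclose(aux.weight.data, main.weight.data)


def test_empty_bank_equals_self_contrastive(rng):
    q = unit_vectors(rng, 6, 8)
    k = unit_vectors(rng, 6, 8)
    fs = PatchFeatureSet([0], [np.arange(6)], [nn.Tensor(k)], [nn.Tensor(q)])
    bank = NegativeBank(capacity=16)
    with_bank = float(patchnce_from_features(fs, bank=bank).data)
    without = float(patchnce_from_features(fs).data)
    assert with_bank == without


def test_nonnegative_similarity_bank_entries_increase_loss(rng):
    q = unit_vectors(rng, 6, 8)
    k = unit_vectors(rng, 6, 8)
    fs = PatchFeatureSet([0], [np.arange(6)], [nn.Tensor(k)], [nn.Tensor(q)])
    base = float(patchnce_from_features(fs).data)
    bank = NegativeBank(capacity=16)
    bank.push(0, q.copy())   # bank entries with nonnegative similarity
    augmented = float(patchnce_from_features(fs, bank=bank).data)
    assert augmented >= base


def test_cross_contrastive_negatives_fetch_then_push(rng):
    q = unit_vectors(rng, 4, 8)
    fs = PatchFeatureSet([0], [np.arange(4)], [nn.Tensor(q)], [nn.Tensor(q)])
    bank = NegativeBank(capacity=8)
    first = cross_contrastive_negatives(bank, fs)
    assert first[0] is None            # warm-up: bank empty on first use
    second = cross_contrastive_negatives(bank, fs)
    assert second[0].shape == (4, 8)   # previous image's features now present
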