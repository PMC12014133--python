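"""Conditional likelihoods, calibration, mutual information, DTI, food pref."""

import numpy as np
import pytest

import ecohab_maxent as em
from ecohab_maxent.ensemble import StateSpace

from conftest import make_loc


@pytest.fixture(scope="module")
def coupled_pair():
    """Strongly coupled two-mouse model and a long i.i.d. sample of it."""
    J = np.zeros((2, 2))
    J[0, 1] = J[1, 0] = 2.0
    h = np.zeros((2, 4))
    gt = em.GroundTruth(h=h, J=J)
    loc, _ = em.simulate_cohort(
        gt, em.SimConfig(n_days=1, bins_per_day=20_000, dynamics="iid"),
        seed=101)
    return h, J, loc


def test_null_likelihood_is_log_quarter():
    loc = make_loc(np.ones((2, 50)))
    rep = em.conditional_loglikelihoods(np.zeros((2, 4)), np.zeros((2, 2)), loc)
    assert rep.l0 == pytest.approx(np.log(0.25))


def test_zero_coupling_factorizes_likelihood():
    rng = np.random.default_rng(0)
    loc = make_loc(rng.integers(1, 5, size=(3, 500)))
    occ = em.occupancy_frequencies(loc)
    h = em.fix_gauge(np.log(occ.m))
    rep = em.conditional_loglikelihoods(h, np.zeros((3, 3)), loc, occ=occ)
    assert np.allclose(rep.l12, rep.l1, atol=1e-12)


def test_interactions_add_predictive_power(coupled_pair):
    h, J, loc = coupled_pair
    rep = em.conditional_loglikelihoods(h, J, loc)
    # oracle gain for J=2, h=0: conditional concentrates e^2/(e^2+3) on the
    # partner's compartment while the marginal stays uniform
    p_same = np.exp(2) / (np.exp(2) + 3)
    gain = (p_same * np.log(4 * p_same)
            + (1 - p_same) * np.log(4 * (1 - p_same) / 3))
    assert rep.l12.mean() - rep.l1.mean() == pytest.approx(gain, abs=0.02)
    assert rep.l1.mean() == pytest.approx(rep.l0, abs=0.01)


def test_mutual_information_uniform_marginal_is_two_bits():
    loc = make_loc((np.arange(400) % 4 + 1)[None, :].repeat(2, 0))
    rep = em.mutual_information(np.zeros((2, 4)), np.zeros((2, 2)), loc, lam=0)
    assert np.allclose(rep.marginal_entropy_bits, 2.0)


def test_mutual_information_zero_without_couplings():
    rng = np.random.default_rng(1)
    loc = make_loc(rng.integers(1, 5, size=(3, 400)))
    occ = em.occupancy_frequencies(loc)
    h = em.fix_gauge(np.log(occ.m))
    rep = em.mutual_information(h, np.zeros((3, 3)), loc, occ=occ)
    assert np.allclose(rep.mi_bits, 0.0, atol=1e-12)


def test_mutual_information_bounds_and_strong_coupling():
    J = np.zeros((2, 2))
    J[0, 1] = J[1, 0] = 5.0
    h = np.zeros((2, 4))
    gt = em.GroundTruth(h=h, J=J)
    loc, _ = em.simulate_cohort(
        gt, em.SimConfig(n_days=1, bins_per_day=20_000, dynamics="iid"),
        seed=7)
    rep = em.mutual_information(h, J, loc, marginal="model")
    # oracle: I from the exact two-mouse joint distribution
    sp = StateSpace(2)
    p, _ = sp.distribution(h, J)
    joint = p.reshape(4, 4)
    pi = joint.sum(axis=1)
    oracle = float((joint * np.log2(joint / np.outer(pi, pi))).sum())
    assert ((rep.mi_bits >= 0) & (rep.mi_bits <= 2)).all()
    assert rep.mi_bits.mean() == pytest.approx(oracle, abs=0.02)
    assert oracle > 1.7            # J=5 approaches perfect predictability


def test_calibration_diagonal_for_self_consistent_model(coupled_pair):
    h, J, loc = coupled_pair
    good = em.in_state_calibration(h, J, loc, n_bins=8)
    bad = em.in_state_calibration(h, 2 * J, loc, n_bins=8)
    dev_good = np.abs(good.pred - good.obs).max()
    dev_bad = np.abs(bad.pred - bad.obs).max()
    assert dev_good < 0.015
    assert dev_bad > 3 * dev_good


def test_food_preference_values_and_gauge_invariance(ring):
    h = np.array([[0.0, 0.0, 0.0, 0.0], [-1.0, 1.0, -1.0, 1.0]])
    fp = em.food_preference(h, ring)
    assert fp.delta_h[0] == pytest.approx(0.0)
    assert fp.delta_h[1] == pytest.approx(4.0)
    shifted = em.food_preference(h + 3.7, ring)
    assert np.allclose(shifted.delta_h, fp.delta_h)


def _triangle(a, b, c):
    J = np.zeros((3, 3))
    J[0, 1] = J[1, 0] = a
    J[1, 2] = J[2, 1] = b
    J[2, 0] = J[0, 2] = c
    return J


@pytest.mark.parametrize("abc, expected", [
    ((1.0, 1.0, -1.0), 1.0),   # exactly one negative: frustrated
    ((1.0, 1.0, 1.0), 0.0),    # all positive: satisfiable
    ((1.0, -1.0, -1.0), 0.0),  # two negatives: satisfiable
    ((-1.0, -1.0, -1.0), 0.0),
])
def test_dti_definition_cases(abc, expected):
    rep = em.global_dti(_triangle(*abc))
    assert rep.f_global == pytest.approx(expected)
    assert (rep.f_triplets >= 0).all()


def test_dti_increases_when_frustrating_a_positive_triangle():
    base = em.global_dti(_triangle(1.0, 1.0, 2.0)).f_global
    flipped = em.global_dti(_triangle(1.0, 1.0, -2.0)).f_global
    assert base == 0.0 and flipped == 2.0


def test_dti_shuffle_preserves_unstructured_value():
    rng = np.random.default_rng(5)
    n = 12
    iu, ju = em.pair_index(n)
    vals = rng.normal(0.0, 0.2, len(iu))
    J = np.zeros((n, n))
    J[iu, ju] = vals
    J[ju, iu] = vals
    rep = em.global_dti(J, n_shuffles=200, seed=6)
    spread = rep.shuffled.std(ddof=1)
    assert abs(rep.f_global - rep.shuffled.mean()) < 3 * spread


def test_metrics_invariant_under_mouse_relabeling():
    rng = np.random.default_rng(9)
    gt = em.make_ground_truth(4, seed=10)
    loc, _ = em.simulate_cohort(
        gt, em.SimConfig(n_days=1, bins_per_day=1500), seed=11)
    perm = [2, 0, 3, 1]
    loc_p = loc.restrict_mice(perm)
    h_p, J_p = gt.h[perm], gt.J[np.ix_(perm, perm)]
    mi = em.mutual_information(gt.h, gt.J, loc)
    mi_p = em.mutual_information(h_p, J_p, loc_p)
    assert np.allclose(mi_p.mi_bits, mi.mi_bits[perm])
    assert em.global_dti(J_p).f_global == pytest.approx(
        em.global_dti(gt.J).f_global)
    ll = em.conditional_loglikelihoods(gt.h, gt.J, loc)
    ll_p = em.conditional_loglikelihoods(h_p, J_p, loc_p)
    assert np.allclose(ll_p.l12, ll.l12[perm])


def test_null_dominated_by_independent_model_on_training_data():
    rng = np.random.default_rng(13)
    p = np.array([0.5, 0.3, 0.1, 0.1])
    loc = make_loc((rng.choice(4, size=(2, 2000), p=p) + 1))
    occ = em.occupancy_frequencies(loc)
    h = em.fix_gauge(np.log(occ.m))
    rep = em.conditional_loglikelihoods(h, np.zeros((2, 2)), loc, occ=occ)
    assert rep.l1.mean() >= rep.l0
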