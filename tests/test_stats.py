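"""Empirical occupancy, sociability, triplet and K-occupancy statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecohab_maxent as em
from ecohab_maxent.stats import pseudocounted_frequencies

from conftest import make_loc


def test_pseudocount_prior_at_zero_data():
    m = pseudocounted_frequencies(np.zeros(4), 0, lam=8, q=4)
    assert np.allclose(m, 0.25)


def test_pseudocount_hand_value_single_compartment():
    # 100 bins all in compartment 1, lambda = 8
    loc = make_loc(np.ones((1, 100)))
    occ = em.occupancy_frequencies(loc, lam=8)
    assert np.isclose(occ.m[0, 0], 102 / 108)
    assert np.allclose(occ.m[0, 1:], 2 / 108)
    assert np.isclose(occ.f[0, 0], 1.0)


@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 50))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_pseudocount_normalization_any_input(seed, lam):
    rng = np.random.default_rng(seed)
    loc = make_loc(rng.integers(1, 5, size=(3, 50)))
    occ = em.occupancy_frequencies(loc, lam=lam)
    assert np.allclose(occ.m.sum(axis=1), 1.0)
    assert ((occ.m > 0) & (occ.m < 1)).all()
    gamma = em.pair_cooccupancy(loc, lam=lam).gamma
    iu, ju = em.pair_index(3)
    assert ((gamma[iu, ju] > 0) & (gamma[iu, ju] < 1)).all()


def test_pseudocount_continuity_to_raw():
    rng = np.random.default_rng(1)
    loc = make_loc(rng.integers(1, 5, size=(2, 200)))
    occ = em.occupancy_frequencies(loc, lam=1e-9)
    assert np.allclose(occ.m, occ.f, atol=1e-10)


def test_all_masked_mouse_rejected():
    loc = make_loc(np.ones((2, 50)))
    loc.valid[1] = False
    with pytest.raises(ValueError, match="no valid bins"):
        em.occupancy_frequencies(loc)


def test_sociability_of_perfectly_comoving_uniform_pair():
    s = (np.arange(400) % 4) + 1
    loc = make_loc(np.stack([s, s]))
    c = em.in_cohort_sociability(loc)
    assert np.isclose(c[0, 1], 0.75)           # sum_r (1/4 - 1/16)


def test_sociability_zero_for_shared_deterministic_preference():
    loc = make_loc(np.ones((2, 300)))
    c = em.in_cohort_sociability(loc)
    assert np.isclose(c[0, 1], 0.0)            # 1 - 1: no excess


def test_sociability_independent_pair_near_zero(uniform_pair_loc):
    c = em.in_cohort_sociability(uniform_pair_loc)
    assert abs(c[0, 1]) < 1e-12                # exactly balanced design
    assert np.isclose(c[0, 1], c[1, 0])


def test_sociability_matches_pair_cooccupancy(uniform_pair_loc):
    pair = em.pair_cooccupancy(uniform_pair_loc)
    c = em.in_cohort_sociability(uniform_pair_loc)
    assert np.allclose(pair.c[0, 1], c[0, 1], equal_nan=True)


def test_chain_correlation_without_direct_interaction():
    # i and k both follow j (with independent lapses): positive C_ik
    rng = np.random.default_rng(2)
    t = 4000
    j = rng.integers(1, 5, t)
    follow_i = rng.random(t) < 0.7
    follow_k = rng.random(t) < 0.7
    i = np.where(follow_i, j, rng.integers(1, 5, t))
    k = np.where(follow_k, j, rng.integers(1, 5, t))
    c = em.in_cohort_sociability(make_loc(np.stack([i, j, k])))
    assert c[0, 2] > 0.1


def test_triplet_comoving_uniform_value():
    s = (np.arange(400) % 4) + 1
    trip = em.triplet_correlations(make_loc(np.stack([s, s, s])))
    # sum over the four compartments of 1/4 - (1/4)^3
    assert np.isclose(trip.c3_star[0], 0.9375)
    assert np.isclose(trip.gamma3[0], 1.0)


def test_triplet_independent_near_zero():
    rng = np.random.default_rng(3)
    loc = make_loc(rng.integers(1, 5, size=(3, 8000)))
    trip = em.triplet_correlations(loc)
    assert abs(trip.c3_star[0]) < 0.02
    assert abs(trip.c3[0]) < 0.02


def test_triplet_permutation_symmetry():
    rng = np.random.default_rng(4)
    sig = rng.integers(1, 5, size=(4, 500))
    base = em.triplet_correlations(make_loc(sig))
    perm = [2, 0, 3, 1]                        # row p holds original mouse perm[p]
    permuted = em.triplet_correlations(make_loc(sig[perm]))
    ti, tj, tk = base.index()
    triplets = list(zip(ti, tj, tk))
    for p, (i, j, k) in enumerate(triplets):
        orig = tuple(sorted((perm[i], perm[j], perm[k])))
        p2 = triplets.index(orig)
        for a, b in ((permuted.c3_star, base.c3_star),
                     (permuted.c3, base.c3), (permuted.gamma3, base.gamma3)):
            assert np.isclose(a[p], b[p2])


def test_independent_correlations_shrink_with_time():
    rng = np.random.default_rng(5)
    mags = []
    for t in (500, 8000):
        loc = make_loc(rng.integers(1, 5, size=(4, t)))
        c = em.in_cohort_sociability(loc)
        iu, ju = em.pair_index(4)
        mags.append(np.abs(c[iu, ju]).mean())
    assert mags[1] < mags[0]                   # ~ T^(-1/2) decay


def test_k_distribution_binomial_pair(uniform_pair_loc):
    hist = em.k_occupancy_distribution(uniform_pair_loc)
    assert np.allclose(hist.per_compartment[0], [9 / 16, 6 / 16, 1 / 16])
    assert np.allclose(hist.per_compartment.sum(axis=1), 1.0)


def test_k_distribution_all_together():
    s = (np.arange(400) % 4) + 1
    hist = em.k_occupancy_distribution(make_loc(np.tile(s, (5, 1))))
    assert np.allclose(hist.per_compartment[:, 5], 0.25)
    assert np.isclose(hist.aggregated[0], 0.75)


def test_pair_statistics_use_jointly_valid_bins_only():
    sig = np.stack([np.ones(100), np.full(100, 2.0)]).astype(np.int8)
    sig[1, 50:] = 1
    valid = np.ones_like(sig, bool)
    valid[1, :50] = False                       # mouse 2 valid only when co-located
    loc = make_loc(sig, valid=valid)
    pair = em.pair_cooccupancy(loc, lam=0.0)
    assert np.isclose(pair.f_pair[0, 1, 0, 0], 1.0)
    assert pair.t_joint[0, 1] == 50
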