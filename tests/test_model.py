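"""Gauge fixing, moment engines, Boltzmann learning, cross-validation."""

import numpy as np
import pytest

import ecohab_maxent as em
from ecohab_maxent.ensemble import CapabilityError, StateSpace
from ecohab_maxent.model import conditional_distribution, joint_loglikelihood

from conftest import make_loc


def test_fix_gauge_examples():
    assert np.allclose(em.fix_gauge(np.ones((1, 4))), 0.0)
    out = em.fix_gauge(np.array([[2.0, 0.0, 0.0, 0.0]]))
    assert np.allclose(out, [[1.5, -0.5, -0.5, -0.5]])
    assert np.allclose(out.sum(axis=1), 0.0)


def test_gauge_shift_leaves_distribution_unchanged():
    sp = StateSpace(3)
    gt = em.make_ground_truth(3, seed=0)
    p1, _ = sp.distribution(gt.h, gt.J)
    p2, _ = sp.distribution(gt.h + np.array([[1.7], [-0.3], [5.0]]), gt.J)
    assert np.allclose(p1, p2, atol=1e-12)


def test_uniform_model_moments():
    mom = StateSpace(3).moments(np.zeros((3, 4)), np.zeros((3, 3)))
    assert np.allclose(mom.m, 0.25)
    assert np.allclose(mom.gamma[0, 1], 0.25)


def test_two_mouse_closed_form_gamma():
    J = np.array([[0.0, 1.0], [1.0, 0.0]])
    mom = StateSpace(2).moments(np.zeros((2, 4)), J)
    assert np.isclose(mom.gamma[0, 1], np.e / (np.e + 3), atol=1e-6)


def test_exact_enumeration_capability_limit():
    with pytest.raises(CapabilityError):
        StateSpace(11)


def test_gibbs_matches_enumeration_n4():
    gt = em.make_ground_truth(4, seed=3)
    ex = StateSpace(4).moments(gt.h, gt.J)
    gb = em.gibbs_moments(gt.h, gt.J, n_chains=48, n_samples=200,
                          burn_in=100, thin=2, seed=5)
    z_m = np.abs(gb.m - ex.m) / gb.se_m
    iu, ju = em.pair_index(4)
    z_g = np.abs((gb.gamma - ex.gamma)[iu, ju]) / gb.se_gamma[iu, ju]
    assert z_m.max() < 4.0 and z_g.max() < 4.0


def test_gibbs_error_shrinks_with_samples():
    gt = em.make_ground_truth(3, seed=9)
    ex = StateSpace(3).moments(gt.h, gt.J)
    errs = []
    for n_samples in (50, 800):
        gb = em.gibbs_moments(gt.h, gt.J, n_chains=32, n_samples=n_samples,
                              burn_in=100, thin=1, seed=7)
        errs.append(np.abs(gb.m - ex.m).mean())
    assert errs[1] < errs[0]


def test_fit_independent_data_recovers_log_m():
    rng = np.random.default_rng(11)
    # independent mice with distinct preferences
    probs = np.array([[0.55, 0.2, 0.15, 0.1], [0.1, 0.4, 0.3, 0.2],
                      [0.25, 0.25, 0.25, 0.25]])
    sig = np.stack([rng.choice(4, 6000, p=p) + 1 for p in probs])
    loc = make_loc(sig)
    mdl = em.PairwiseMaxEnt.from_location(loc, seed=1)
    res = mdl.fit(alpha=0.8)
    assert np.abs(res.coupling_values).max() < 0.05
    assert np.allclose(res.h, em.fix_gauge(np.log(mdl.m_data)), atol=0.05)


def test_fit_self_consistency_inversion():
    gt = em.make_ground_truth(4, s_h=0.4, mu_J=0.1, s_J=0.25, seed=7)
    ex = StateSpace(4).moments(gt.h, gt.J)
    mdl = em.PairwiseMaxEnt(ex.m, ex.gamma, tol_m=1e-6, tol_gamma=1e-6)
    res = mdl.fit(alpha=0.8)
    assert np.abs(res.h - em.fix_gauge(gt.h)).max() < 1e-3
    assert np.abs(res.J - gt.J).max() < 1e-3


def test_fit_reproduces_constrained_moments_within_tolerance():
    gt = em.make_ground_truth(5, seed=13)
    loc, _ = em.simulate_cohort(gt, em.SimConfig(n_days=1, bins_per_day=4000),
                                seed=14)
    mdl = em.PairwiseMaxEnt.from_location(loc, seed=2)
    res = mdl.fit(alpha=0.5)
    mom = res.moments()
    assert (np.abs(mom.m - mdl.m_data) <= mdl.tol_m).all()
    iu, ju = em.pair_index(5)
    tol_g = np.asarray(mdl.tol_gamma)
    tol_pairs = tol_g[iu, ju] if tol_g.ndim == 2 else tol_g
    assert (np.abs((mom.gamma - mdl.gamma_data)[iu, ju]) <= tol_pairs).all()


def test_fit_equivariant_under_mouse_relabeling():
    gt = em.make_ground_truth(4, seed=17)
    ex = StateSpace(4).moments(gt.h, gt.J)
    perm = [3, 1, 0, 2]
    res = em.PairwiseMaxEnt(ex.m, ex.gamma, tol_m=1e-6,
                            tol_gamma=1e-6).fit(alpha=0.8)
    resp = em.PairwiseMaxEnt(ex.m[perm], ex.gamma[np.ix_(perm, perm)],
                             tol_m=1e-6, tol_gamma=1e-6).fit(alpha=0.8)
    assert np.allclose(resp.h, res.h[perm], atol=1e-5)
    assert np.allclose(resp.J, res.J[np.ix_(perm, perm)], atol=1e-5)


def test_convergence_error_carries_history():
    gt = em.make_ground_truth(3, seed=19)
    ex = StateSpace(3).moments(gt.h, gt.J)
    mdl = em.PairwiseMaxEnt(ex.m, ex.gamma, tol_m=1e-12, tol_gamma=1e-12)
    with pytest.raises(em.ConvergenceError) as err:
        mdl.fit(alpha=0.25, max_iters=20)
    assert len(err.value.history["j_mean"]) == 20


def test_gibbs_fit_agrees_with_exact_fit():
    gt = em.make_ground_truth(5, seed=23)
    ex = StateSpace(5).moments(gt.h, gt.J)
    exact = em.PairwiseMaxEnt(ex.m, ex.gamma, tol_m=1e-5,
                              tol_gamma=1e-5).fit(alpha=0.8)
    mdl = em.PairwiseMaxEnt(ex.m, ex.gamma, tol_m=0.01, tol_gamma=0.01)
    noisy = mdl.fit(method="gibbs", alpha=0.4, seed=3, n_chains=128,
                    max_iters=3000, raise_on_failure=False)
    assert np.abs(noisy.J - exact.J).max() < 0.25
    assert np.corrcoef(noisy.coupling_values, exact.coupling_values)[0, 1] > 0.8


def test_triplet_strong_regularization_reduces_to_pairwise():
    gt = em.make_ground_truth(4, seed=29)
    ex = StateSpace(4).moments(gt.h, gt.J, want_triplets=True)
    pair = em.PairwiseMaxEnt(ex.m, ex.gamma, tol_m=1e-5,
                             tol_gamma=1e-5).fit(alpha=0.8)
    trip = em.TripletMaxEnt(ex.m, ex.gamma, ex.gamma3, beta_G=1e4,
                            tol_m=1e-5, tol_gamma=1e-5).fit(alpha=0.8)
    ti, tj, tk = em.triplet_index(4)
    assert np.abs(trip.G[ti, tj, tk]).max() < 1e-4
    assert np.allclose(trip.J, pair.J, atol=1e-3)


def test_triplet_ground_truth_recovery():
    gt = em.make_ground_truth(4, s_h=0.2, mu_J=0.0, s_J=0.1, seed=31)
    G = np.zeros((4, 4, 4))
    ti, tj, tk = em.triplet_index(4)
    gvec = np.zeros(len(ti))
    gvec[1] = 0.4
    for p in ((ti, tj, tk), (ti, tk, tj), (tj, ti, tk),
              (tj, tk, ti), (tk, ti, tj), (tk, tj, ti)):
        G[p] = gvec
    ex = StateSpace(4).moments(gt.h, gt.J, G, want_triplets=True)
    res = em.TripletMaxEnt(ex.m, ex.gamma, ex.gamma3, beta_G=1e-4,
                           tol_m=1e-6, tol_gamma=1e-6).fit(alpha=0.8)
    assert np.abs(res.G[ti, tj, tk] - gvec).max() < 1e-2


def test_factorized_model_conditional_equals_marginal():
    # with J = 0 the conditional distribution is the marginal softmax(h)
    rng = np.random.default_rng(37)
    h = em.fix_gauge(rng.normal(0, 0.5, (3, 4)))
    loc = make_loc(rng.integers(1, 5, size=(3, 200)))
    p = conditional_distribution(h, np.zeros((3, 3)), loc)
    expected = np.exp(h) / np.exp(h).sum(axis=1, keepdims=True)
    assert np.allclose(p, expected[:, :, None])


def test_joint_loglikelihood_uniform_model():
    loc = make_loc(np.ones((2, 50)))
    ll = joint_loglikelihood(np.zeros((2, 4)), np.zeros((2, 2)), loc)
    assert np.isclose(ll, 2 * np.log(0.25))


def test_cv_folds_partition_the_window():
    gt = em.make_ground_truth(3, seed=41)
    loc, _ = em.simulate_cohort(gt, em.SimConfig(n_days=2), seed=42)
    hour = ((loc.clock - loc.clock.min()) // 3600).astype(int)
    assert set(np.unique(hour)) == set(range(6))
    counts = [int((hour == f).sum()) for f in range(6)]
    assert sum(counts) == loc.n_bins and len(set(counts)) == 1


def test_cv_requires_enough_days():
    gt = em.make_ground_truth(3, seed=43)
    loc, _ = em.simulate_cohort(gt, em.SimConfig(n_days=1, bins_per_day=600),
                                seed=44)
    with pytest.raises(ValueError, match="days"):
        em.cross_validate(loc, day_counts=(5,))


def test_pairwise_cv_generalizes_on_pairwise_data():
    gt = em.make_ground_truth(5, seed=47)
    loc, _ = em.simulate_cohort(gt, em.SimConfig(n_days=1), seed=48)
    rep = em.cross_validate(loc, "pairwise", reg_grid=(0.0, 1.0),
                            day_counts=(1,), seed=6,
                            fit_kwargs={"alpha": 0.8, "max_iters": 20_000})
    s = rep.summary().set_index("beta")
    # heavy shrinkage of true couplings hurts held-out likelihood
    assert s.loc[0.0, "test_ll"] > s.loc[1.0, "test_ll"]
    assert len(rep.table) == 12 and rep.table["converged"].all()


def test_plotting_smoke(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from ecohab_maxent import plotting

    gt = em.make_ground_truth(4, seed=90)
    loc, _ = em.simulate_cohort(gt, em.SimConfig(n_days=1, bins_per_day=1200),
                                seed=91)
    res = em.PairwiseMaxEnt.from_location(loc, seed=92).fit(
        alpha=0.8, raise_on_failure=False)
    ax = plotting.plot_couplings(res)
    plotting.plot_calibration(res.in_state_calibration(loc, n_bins=5))
    plotting.plot_k_distribution(em.k_occupancy_distribution(loc))
    ax.figure.savefig(tmp_path / "fig.png")


def test_model_save_load_round_trip(tmp_path):
    gt = em.make_ground_truth(3, seed=95)
    ex = StateSpace(3).moments(gt.h, gt.J)
    res = em.PairwiseMaxEnt(ex.m, ex.gamma, tol_m=1e-5,
                            tol_gamma=1e-5).fit(alpha=0.8)
    p = tmp_path / "model.npz"
    res.save(p)
    h, J, G, meta = em.load_params(p)
    assert np.allclose(h, res.h) and np.allclose(J, res.J) and G is None
    assert meta["converged"] and meta["n_iter"] == res.n_iter
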