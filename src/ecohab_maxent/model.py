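"""Maximum-entropy models of mouse co-localization, statsmodels-style.

:class:`PairwiseMaxEnt` constrains each mouse's compartment occupancy and
every pair's same-compartment probability; its Boltzmann form has local
fields ``h_ir`` (intrinsic compartment preference) and couplings ``J_ij``
(pairwise attraction/avoidance).  :class:`TripletMaxEnt` adds
L2-regularized three-mouse couplings ``G_ijk``.

Fitting is Boltzmann learning: plain gradient descent on the moment
mismatch, ``J <- J - alpha * (gamma_model - gamma_data)`` and
``h <- h - alpha * (m_model - m_data)``, iterated until (a) every moment
is reproduced within the data's own resampling variability and (b) the
mean and SD of the couplings are stable (change below 0.005 over 100
steps).  Model moments come from exact enumeration for cohorts of up to
ten mice and from persistent Gibbs chains above that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import softmax

from . import metrics as _metrics
from .ensemble import (MomentSet, StateSpace, gibbs_moments, gibbs_sweeps,
                       pair_index, triplet_index, EXACT_MAX_MICE)
from .events import LocationMatrix
from .stats import (DEFAULT_PSEUDOCOUNT, occupancy_frequencies,
                    pair_cooccupancy, pseudocounted_frequencies)

__all__ = [
    "PairwiseMaxEnt",
    "TripletMaxEnt",
    "MaxEntResults",
    "ConvergenceError",
    "fix_gauge",
    "cross_validate",
    "CVReport",
    "joint_loglikelihood",
    "load_params",
]


def fix_gauge(h: np.ndarray) -> np.ndarray:
    """Remove the additive redundancy of the fields: sum_r h_ir = 0.

    The model probabilities are unchanged by any per-mouse constant shift
    of ``h``; the zero-sum gauge makes fields comparable across mice.
    """
    h = np.asarray(h, dtype=float)
    return h - h.mean(axis=-1, keepdims=True)


class ConvergenceError(RuntimeError):
    """Gradient descent hit the iteration cap; carries the fit history."""

    def __init__(self, message, history):
        super().__init__(message)
        self.history = history


def _moment_tolerance_from_loc(loc, lam, n_rep, seed, floor):
    """Per-moment data variability via 400-s-block random halves."""
    from .resampling import bootstrap_sigma

    bs_m = bootstrap_sigma(lambda l: occupancy_frequencies(l, lam).m,
                           loc, n_rep=n_rep, seed=seed)
    bs_g = bootstrap_sigma(lambda l: pair_cooccupancy(l, lam).gamma,
                           loc, n_rep=n_rep, seed=seed + 1)
    return np.maximum(bs_m.sigma, floor), np.maximum(bs_g.sigma, floor)


class PairwiseMaxEnt:
    """Pairwise maximum-entropy (Potts) model of a mouse cohort.

    Parameters
    ----------
    m_data : (N, q) array
        Target occupancy probabilities (pseudocounted).
    gamma_data : (N, N) array
        Target same-compartment probabilities (pseudocounted, symmetric).
    tol_m, tol_gamma : float or array, optional
        Convergence tolerance per moment — the data variability the fitted
        moments must reach.  Defaults to 1e-4.
    """

    def __init__(self, m_data: np.ndarray, gamma_data: np.ndarray, *,
                 lam: float = DEFAULT_PSEUDOCOUNT, q: int | None = None,
                 tol_m=None, tol_gamma=None, mouse_ids=None):
        self.m_data = np.asarray(m_data, dtype=float)
        self.gamma_data = np.asarray(gamma_data, dtype=float)
        self.n_mice, self.q = self.m_data.shape if q is None else (
            self.m_data.shape[0], q)
        if self.gamma_data.shape != (self.n_mice, self.n_mice):
            raise ValueError("gamma_data shape mismatch")
        if not np.allclose(self.gamma_data, self.gamma_data.T):
            raise ValueError("gamma_data must be symmetric")
        self.lam = lam
        self.tol_m = 1e-4 if tol_m is None else tol_m
        self.tol_gamma = 1e-4 if tol_gamma is None else tol_gamma
        self.mouse_ids = mouse_ids
        self._space: StateSpace | None = None

    @classmethod
    def from_location(cls, loc: LocationMatrix, *,
                      lam: float = DEFAULT_PSEUDOCOUNT,
                      tolerance: str | float = "bootstrap",
                      n_rep: int = 10, seed: int = 0,
                      tol_floor: float = 1e-4) -> "PairwiseMaxEnt":
        """Build the model from a discretized location matrix.

        With ``tolerance="bootstrap"`` the per-moment convergence tolerance
        is the data's own variability, estimated from random halves of
        400-s blocks and extrapolated to the full data.
        """
        occ = occupancy_frequencies(loc, lam)
        pair = pair_cooccupancy(loc, lam)
        if tolerance == "bootstrap":
            tol_m, tol_g = _moment_tolerance_from_loc(loc, lam, n_rep, seed,
                                                      tol_floor)
        else:
            tol_m = tol_g = float(tolerance)
        return cls(occ.m, pair.gamma, lam=lam, tol_m=tol_m, tol_gamma=tol_g,
                   mouse_ids=occ.mouse_ids)

    # -- machinery -------------------------------------------------------

    @property
    def space(self) -> StateSpace:
        if self._space is None:
            self._space = StateSpace(self.n_mice, self.q)
        return self._space

    def _target_gamma3(self):
        return None

    def _init_params(self, start):
        if start is not None:
            h0, J0 = start[0].copy(), start[1].copy()
        else:
            h0 = fix_gauge(np.log(self.m_data))
            J0 = np.zeros((self.n_mice, self.n_mice))
        return h0, J0, None

    def _model_moments(self, h, J, G, state):
        if state["method"] == "exact":
            mom = self.space.moments(h, J, G, want_triplets=G is not None)
            return mom.m, mom.gamma, mom.gamma3
        # persistent Gibbs chains (a few sweeps per gradient step) with an
        # exponential moving average over steps: the averaging window
        # trades gradient noise against a small lag behind the current
        # parameters
        sigma = state["chains"]
        gibbs_sweeps(sigma, h, J, G, n_sweeps=state["sweeps_per_step"],
                     rng=state["rng"], q=self.q)
        n, q = self.n_mice, self.q
        oh = np.zeros((sigma.shape[0], n, q))
        oh[np.arange(sigma.shape[0])[:, None], np.arange(n)[None, :], sigma] = 1.0
        iu, ju = pair_index(n)
        m_inst = oh.mean(axis=0)
        gamma_inst = np.eye(n)
        gvec = (sigma[:, iu] == sigma[:, ju]).mean(axis=0)
        gamma_inst[iu, ju] = gvec
        gamma_inst[ju, iu] = gvec
        g3_inst = None
        if G is not None:
            ti, tj, tk = triplet_index(n)
            g3_inst = ((sigma[:, ti] == sigma[:, tj])
                       & (sigma[:, ti] == sigma[:, tk])).mean(axis=0)
        eta = state["ema_rate"]
        for key, val in (("m", m_inst), ("gamma", gamma_inst),
                         ("gamma3", g3_inst)):
            if val is None:
                continue
            prev = state["ema"].get(key)
            state["ema"][key] = val if prev is None else (
                (1 - eta) * prev + eta * val)
        e = state["ema"]
        return e["m"], e["gamma"], e.get("gamma3")

    def fit(self, method: str = "exact", *, alpha: float = 0.5,
            alpha_h: float | None = None, alpha_J: float | None = None,
            beta_J: float = 0.0, max_iters: int = 50_000,
            stability_window: int = 100, stability_tol: float = 0.005,
            start=None, seed: int = 0, n_chains: int = 128,
            sweeps_per_step: int = 2, ema_rate: float = 0.05,
            raise_on_failure: bool = True) -> "MaxEntResults":
        """Boltzmann learning by gradient descent on moment mismatches."""
        if method not in ("exact", "gibbs"):
            raise ValueError(f"unknown method {method!r}")
        if method == "exact" and self.n_mice > EXACT_MAX_MICE:
            raise ValueError(
                f"exact moments need N<={EXACT_MAX_MICE}; use method='gibbs'")
        alpha_h = alpha if alpha_h is None else alpha_h
        alpha_J = alpha if alpha_J is None else alpha_J
        iu, ju = pair_index(self.n_mice)
        h, J, G = self._init_params(start)
        g3_data = self._target_gamma3()

        state = {"method": method}
        if method == "gibbs":
            rng = np.random.default_rng(seed)
            state.update(rng=rng, n_chains=n_chains,
                         sweeps_per_step=sweeps_per_step, ema_rate=ema_rate,
                         chains=rng.integers(0, self.q,
                                             size=(n_chains, self.n_mice)
                                             ).astype(np.int8),
                         ema={})

        hist_jmean, hist_jsd, hist_res = [], [], []
        converged = False
        n_iter = 0
        for k in range(max_iters):
            n_iter = k + 1
            m_mod, gamma_mod, g3_mod = self._model_moments(h, J, G, state)
            dm = m_mod - self.m_data
            dg = gamma_mod - self.gamma_data
            # under L2 regularization the stationary point keeps a moment
            # residual of -beta*J by construction, so convergence is judged
            # on the penalized gradient (the actual update step)
            grad_g = dg[iu, ju] + beta_J * J[iu, ju]
            h -= alpha_h * dm
            J[iu, ju] -= alpha_J * grad_g
            J[ju, iu] = J[iu, ju]
            if G is not None:
                self._update_triplets(G, g3_mod, g3_data)

            jvals = J[iu, ju]
            hist_jmean.append(jvals.mean())
            hist_jsd.append(jvals.std(ddof=1) if len(jvals) > 1 else 0.0)
            tol_g = np.asarray(self.tol_gamma)
            tol_g_pairs = tol_g[iu, ju] if tol_g.ndim == 2 else tol_g
            res_m = float(np.max(np.abs(dm) / self.tol_m))
            res_g = float(np.max(np.abs(grad_g) / tol_g_pairs))
            hist_res.append(max(res_m, res_g))

            if k + 1 >= stability_window and hist_res[-1] <= 1.0:
                w = stability_window
                if (abs(hist_jmean[-1] - hist_jmean[-w]) < stability_tol
                        and abs(hist_jsd[-1] - hist_jsd[-w]) < stability_tol):
                    converged = True
                    break

        history = {"j_mean": np.array(hist_jmean), "j_sd": np.array(hist_jsd),
                   "max_residual": np.array(hist_res)}
        if not converged and raise_on_failure:
            raise ConvergenceError(
                f"no convergence in {max_iters} iterations "
                f"(last residual {hist_res[-1]:.3g} tolerance units)", history)
        return MaxEntResults(model=self, h=fix_gauge(h), J=J, G=G,
                             converged=converged, n_iter=n_iter,
                             method=method, history=history, beta_J=beta_J)

    def _update_triplets(self, G, g3_mod, g3_data):  # overridden
        raise NotImplementedError


class TripletMaxEnt(PairwiseMaxEnt):
    """Pairwise model plus L2-regularized triplet couplings ``G_ijk``.

    Minimizes the penalized negative log-likelihood
    ``L = -<log P> + (beta_G / 2) * sum G^2``; the triplet gradient step is
    ``G <- G - alpha_G * (gamma3_model - gamma3_data + beta_G * G)``.
    With ``beta_G -> inf`` the couplings vanish and the pairwise model is
    recovered.
    """

    def __init__(self, m_data, gamma_data, gamma3_data, *, beta_G: float = 0.0,
                 alpha_G: float = 0.25, tol_gamma3=None, **kw):
        super().__init__(m_data, gamma_data, **kw)
        if self.n_mice < 3:
            raise ValueError("triplet model needs at least three mice")
        self.gamma3_data = np.asarray(gamma3_data, dtype=float)
        self.beta_G = beta_G
        # keep the regularized update contractive for large beta_G
        self.alpha_G = min(alpha_G, 0.5 / beta_G) if beta_G > 0 else alpha_G
        self.tol_gamma3 = (self.tol_gamma if tol_gamma3 is None
                           else tol_gamma3)

    @classmethod
    def from_location(cls, loc, *, lam=DEFAULT_PSEUDOCOUNT, beta_G=0.0,
                      alpha_G=0.25, tolerance="bootstrap", n_rep=10, seed=0,
                      tol_floor=1e-4):
        from .stats import triplet_correlations

        base = PairwiseMaxEnt.from_location(loc, lam=lam, tolerance=tolerance,
                                            n_rep=n_rep, seed=seed,
                                            tol_floor=tol_floor)
        trip = triplet_correlations(loc)
        # smoothed with the prior chance 1/q^2 of three mice coinciding
        t3 = loc.valid.sum(axis=1).min()
        g3 = pseudocounted_frequencies(trip.gamma3 * t3, t3, lam, loc.q,
                                       prior=1.0 / loc.q ** 2)
        tol3 = (np.median(base.tol_gamma) if np.ndim(base.tol_gamma)
                else base.tol_gamma)
        return cls(base.m_data, base.gamma_data, g3, beta_G=beta_G,
                   alpha_G=alpha_G, lam=lam, tol_m=base.tol_m,
                   tol_gamma=base.tol_gamma, tol_gamma3=tol3,
                   mouse_ids=base.mouse_ids)

    def _target_gamma3(self):
        return self.gamma3_data

    def _init_params(self, start):
        if start is not None and len(start) == 3:
            return start[0].copy(), start[1].copy(), start[2].copy()
        h, J, _ = super()._init_params(start)
        return h, J, np.zeros((self.n_mice,) * 3)

    def _update_triplets(self, G, g3_mod, g3_data):
        ti, tj, tk = triplet_index(self.n_mice)
        gvec = G[ti, tj, tk]
        gvec -= self.alpha_G * (g3_mod - g3_data + self.beta_G * gvec)
        for p in ((ti, tj, tk), (ti, tk, tj), (tj, ti, tk),
                  (tj, tk, ti), (tk, ti, tj), (tk, tj, ti)):
            G[p] = gvec


@dataclass
class MaxEntResults:
    """Fitted maximum-entropy model with diagnostics and derived metrics."""

    model: PairwiseMaxEnt
    h: np.ndarray
    J: np.ndarray
    G: np.ndarray | None
    converged: bool
    n_iter: int
    method: str
    history: dict = dc_field(repr=False, default_factory=dict)
    beta_J: float = 0.0

    @property
    def n_mice(self) -> int:
        return self.h.shape[0]

    @property
    def coupling_values(self) -> np.ndarray:
        iu, ju = pair_index(self.n_mice)
        return self.J[iu, ju]

    def moments(self, *, want_triplets: bool = False, seed: int = 0,
                **gibbs_kw) -> MomentSet:
        if self.n_mice <= EXACT_MAX_MICE:
            return self.model.space.moments(self.h, self.J, self.G,
                                            want_triplets=want_triplets)
        return gibbs_moments(self.h, self.J, self.G, seed=seed,
                             want_triplets=want_triplets, **gibbs_kw)

    # -- derived sociability metrics ------------------------------------

    def conditional_loglikelihoods(self, loc, occ=None):
        return _metrics.conditional_loglikelihoods(self.h, self.J, loc,
                                                   occ=occ, lam=self.model.lam)

    def mutual_information(self, loc, occ=None, marginal="empirical"):
        return _metrics.mutual_information(self.h, self.J, loc, occ=occ,
                                           lam=self.model.lam,
                                           marginal=marginal,
                                           space=(self.model.space if
                                                  marginal == "model" else None))

    def food_preference(self, topology):
        return _metrics.food_preference(self.h, topology)

    def dti(self, *, n_shuffles: int = 0, seed: int = 0):
        return _metrics.global_dti(self.J, n_shuffles=n_shuffles, seed=seed)

    def in_state_calibration(self, loc, n_bins: int = 10):
        return _metrics.in_state_calibration(self.h, self.J, loc,
                                             n_bins=n_bins)

    def predict_triplet_cstar(self) -> np.ndarray:
        """Model-predicted triplet excess coincidence C*_ijk (i<j<k)."""
        return self.model.space.triplet_cstar(self.h, self.J, self.G)

    def simulate(self, cfg=None, *, seed=None, topology=None, **kw):
        from .simulate import GroundTruth, SimConfig, simulate_cohort

        gt = GroundTruth(h=self.h, J=self.J, G=self.G)
        return simulate_cohort(gt, cfg or SimConfig(**kw), seed=seed,
                               topology=topology)

    def summary(self) -> str:
        j = self.coupling_values
        lines = [
            "Pairwise maximum-entropy model"
            + ("" if self.G is None else " with triplet couplings"),
            f"  mice: {self.n_mice}   compartments: {self.model.q}",
            f"  method: {self.method}   iterations: {self.n_iter}"
            f"   converged: {self.converged}",
            f"  pseudocount lambda: {self.model.lam}",
            f"  couplings J: mean {j.mean():+.4f}  sd {j.std(ddof=1):.4f}"
            f"  min {j.min():+.4f}  max {j.max():+.4f}",
            f"  fields h: sd {self.h.std():.4f} (zero-sum gauge)",
        ]
        if self.G is not None:
            ti, tj, tk = triplet_index(self.n_mice)
            g = self.G[ti, tj, tk]
            lines.append(f"  triplet G: mean {g.mean():+.5f}  sd {g.std():.5f}"
                         f"  (beta_G={getattr(self.model, 'beta_G', 0)})")
        if self.history:
            lines.append(
                f"  final max residual: "
                f"{self.history['max_residual'][-1]:.3f} tolerance units")
        return "\n".join(lines)

    def save(self, path) -> None:
        np.savez_compressed(
            path, h=self.h, J=self.J,
            G=(np.zeros(0) if self.G is None else self.G),
            meta=np.array([self.model.lam, float(self.converged),
                           self.n_iter, self.beta_J]))


def load_params(path):
    """Read back parameters written by :meth:`MaxEntResults.save`.

    Returns ``(h, J, G_or_None, meta)`` with ``meta`` a dict of the fit
    metadata.
    """
    d = np.load(path, allow_pickle=False)
    lam, conv, n_iter, beta_J = d["meta"]
    G = d["G"] if d["G"].size else None
    meta = {"lam": float(lam), "converged": bool(conv),
            "n_iter": int(n_iter), "beta_J": float(beta_J)}
    return d["h"], d["J"], G, meta


def joint_loglikelihood(h, J, loc: LocationMatrix, G=None, *,
                        space: StateSpace | None = None) -> float:
    """Mean joint log-likelihood (nats per 2-s observation) of the data.

    Uses only bins where every mouse is valid; requires exact
    normalization, hence cohorts within the enumeration limit.
    """
    n, q = h.shape
    if space is None:
        space = StateSpace(n, q)
    keep = loc.valid.all(axis=0)
    sig = loc.sigma[:, keep].astype(int) - 1
    iu, ju = pair_index(n)
    e = h[np.arange(n)[:, None], sig].sum(axis=0)
    e += J[iu, ju] @ (sig[iu] == sig[ju])
    if G is not None:
        ti, tj, tk = triplet_index(n)
        e += G[ti, tj, tk] @ ((sig[ti] == sig[tj]) & (sig[ti] == sig[tk]))
    _, log_z = space.distribution(h, J, G)
    return float(e.mean() - log_z)


@dataclass
class CVReport:
    """Cross-validation table: per-fold likelihoods over a parameter grid."""

    table: pd.DataFrame
    model_family: str

    def summary(self) -> pd.DataFrame:
        """Mean train/test log-likelihood per (n_days, beta)."""
        return self.table.groupby(["n_days", "beta"])[
            ["train_ll", "test_ll"]].mean().reset_index()

    def best_beta(self, n_days=None) -> float:
        s = self.summary()
        if n_days is not None:
            s = s[s["n_days"] == n_days]
        return float(s.loc[s["test_ll"].idxmax(), "beta"])


def _hour_folds(loc: LocationMatrix):
    clock = loc.clock
    hour = ((clock - clock.min()) // 3600).astype(int)
    return hour, np.unique(hour)


def cross_validate(loc: LocationMatrix, model_family: str = "pairwise",
                   reg_grid=(0.0,), day_counts=(1,), *, seed: int = 0,
                   lam: float = DEFAULT_PSEUDOCOUNT, tol_n_rep: int = 6,
                   tol_floor: float = 1e-4, fit_kwargs: dict | None = None
                   ) -> CVReport:
    """Hourly cross-validation of the model family over a penalty grid.

    Each day's analysis window is cut into hour-long chunks; each distinct
    hour serves once as the test set while the other hours train the
    model, giving six folds for the standard 6-h window.  ``reg_grid``
    sweeps the L2 strength on the couplings (``beta_J`` for the pairwise
    family, ``beta_G`` for the triplet family).
    """
    if model_family not in ("pairwise", "triplet"):
        raise ValueError(f"unknown model family {model_family!r}")
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("raise_on_failure", False)
    days_all = np.unique(loc.day_index)
    rows = []
    space = StateSpace(loc.n_mice, loc.q)
    for n_days in day_counts:
        if n_days > len(days_all):
            raise ValueError(f"requested {n_days} days, have {len(days_all)}")
        sub = loc.restrict_bins(np.isin(loc.day_index, days_all[:n_days]))
        hour, hours = _hour_folds(sub)
        for fold, test_hour in enumerate(hours):
            train = sub.restrict_bins(hour != test_hour)
            test = sub.restrict_bins(hour == test_hour)
            for beta in reg_grid:
                if model_family == "pairwise":
                    mdl = PairwiseMaxEnt.from_location(
                        train, lam=lam, n_rep=tol_n_rep,
                        seed=seed + fold, tol_floor=tol_floor)
                    res = mdl.fit(beta_J=beta, seed=seed, **fit_kwargs)
                else:
                    mdl = TripletMaxEnt.from_location(
                        train, lam=lam, beta_G=beta, n_rep=tol_n_rep,
                        seed=seed + fold, tol_floor=tol_floor)
                    res = mdl.fit(seed=seed, **fit_kwargs)
                rows.append({
                    "n_days": n_days, "beta": beta, "fold": fold,
                    "train_ll": joint_loglikelihood(res.h, res.J, train,
                                                    res.G, space=space),
                    "test_ll": joint_loglikelihood(res.h, res.J, test,
                                                   res.G, space=space),
                    "converged": res.converged, "n_iter": res.n_iter,
                })
                if not res.converged:
                    warnings.warn(
                        f"CV fit (K={n_days}, beta={beta}, fold={fold}) "
                        "stopped at the iteration cap")
    return CVReport(table=pd.DataFrame(rows), model_family=model_family)


def conditional_distribution(h, J, loc: LocationMatrix,
                             G=None) -> np.ndarray:
    """P(sigma_i = r | everyone else) for each mouse and bin, (N, q, T).

    Closed form: softmax over r of ``h_ir + sum_j J_ij d(sigma_j, r)``
    (plus triplet terms when present).  Invalid mice contribute nothing to
    their neighbors' fields.
    """
    n, q = h.shape
    onehot = np.zeros((n, q, loc.n_bins), dtype=np.float64)
    for r in range(q):
        onehot[:, r, :] = (loc.sigma == r + 1) & loc.valid
    field = h[:, :, None] + np.einsum("ij,jrt->irt", J, onehot)
    if G is not None:
        sig = loc.sigma.astype(int) - 1
        ok = loc.valid
        for i in range(n):
            for j in range(n):
                if j == i:
                    continue
                for k in range(j + 1, n):
                    if k == i or not np.any(G[i, j, k]):
                        continue
                    same = (sig[j] == sig[k]) & ok[j] & ok[k]
                    field[i, sig[j, same], np.flatnonzero(same)] += G[i, j, k]
    return softmax(field, axis=1)
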