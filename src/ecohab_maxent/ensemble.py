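"""Model-moment computation for Potts-type maximum-entropy models.

Two routes are provided and cross-check each other:

* exact enumeration of all ``q**N`` co-localization states (small cohorts),
  with log-sum-exp normalization;
* heat-bath Gibbs sampling vectorized over many independent chains, with
  Monte-Carlo standard errors taken across chains (large cohorts).

The model is ``P(sigma) ∝ exp(sum_ir h_ir d(sigma_i,r)
+ sum_{i<j} J_ij d(sigma_i,sigma_j) [+ sum_{i<j<k} G_ijk
d(sigma_i,sigma_j) d(sigma_i,sigma_k)])`` over compartment labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "MomentSet",
    "StateSpace",
    "gibbs_moments",
    "gibbs_sweeps",
    "pair_index",
    "triplet_index",
    "EXACT_MAX_MICE",
]

#: enumeration is refused above this cohort size (4**10 ~ 1e6 states).
EXACT_MAX_MICE = 10


class CapabilityError(ValueError):
    """Exact enumeration requested beyond the tractable cohort size."""


def pair_index(n: int):
    """Row/column arrays of the i<j pairs, in lexicographic order."""
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def triplet_index(n: int):
    """Index arrays (i<j<k) of all triplets, lexicographic order."""
    idx = [(i, j, k) for i in range(n) for j in range(i + 1, n) for k in range(j + 1, n)]
    if not idx:
        return (np.empty(0, int),) * 3
    a = np.array(idx, dtype=int)
    return a[:, 0], a[:, 1], a[:, 2]


def pack_triplets(G_full: np.ndarray) -> np.ndarray:
    ti, tj, tk = triplet_index(G_full.shape[0])
    return G_full[ti, tj, tk]


def unpack_triplets(g: np.ndarray, n: int) -> np.ndarray:
    """Fully symmetric (n, n, n) tensor from the i<j<k vector."""
    ti, tj, tk = triplet_index(n)
    G = np.zeros((n, n, n), dtype=float)
    for p in ((ti, tj, tk), (ti, tk, tj), (tj, ti, tk),
              (tj, tk, ti), (tk, ti, tj), (tk, tj, ti)):
        G[p] = g
    return G


@dataclass
class MomentSet:
    """Single-site and same-compartment coincidence moments of a model.

    ``gamma`` has ones on the diagonal (a mouse always shares a compartment
    with itself).  ``gamma3``, when present, is the i<j<k vector of
    three-mouse coincidence probabilities.  ``se_*`` are Monte-Carlo
    standard errors (zero for exact enumeration).
    """

    m: np.ndarray
    gamma: np.ndarray
    gamma3: np.ndarray | None = None
    se_m: np.ndarray | None = None
    se_gamma: np.ndarray | None = None
    se_gamma3: np.ndarray | None = None
    log_z: float | None = None
    n_samples: int = 0


class StateSpace:
    """Cached enumeration of all q**N states with one-hot and pair tables.

    The one-hot table ``M1h`` ((N*q, S)) and pair-coincidence table ``EQ``
    ((n_pairs, S)) reduce both the energy of every state and the model
    moments to single BLAS matrix-vector products, which keeps gradient
    descent with exact moments fast for cohorts up to N=10.
    """

    def __init__(self, n_mice: int, q: int = 4):
        if n_mice > EXACT_MAX_MICE:
            raise CapabilityError(
                f"exact enumeration limited to N<={EXACT_MAX_MICE} mice, got {n_mice}"
            )
        self.n_mice = n_mice
        self.q = q
        n_states = q ** n_mice
        self.n_states = n_states
        states = np.empty((n_states, n_mice), dtype=np.int8)
        idx = np.arange(n_states)
        for i in range(n_mice):
            states[:, i] = (idx // q ** i) % q
        self.states = states

        self.M1h = np.zeros((n_mice * q, n_states), dtype=np.float32)
        for i in range(n_mice):
            for r in range(q):
                self.M1h[i * q + r] = states[:, i] == r

        self.iu, self.ju = pair_index(n_mice)
        self.EQ = np.empty((len(self.iu), n_states), dtype=np.float32)
        for p, (i, j) in enumerate(zip(self.iu, self.ju)):
            self.EQ[p] = states[:, i] == states[:, j]

        self._T3 = None  # lazy triplet coincidence table

    @property
    def T3(self) -> np.ndarray:
        if self._T3 is None:
            ti, tj, tk = triplet_index(self.n_mice)
            T3 = np.empty((len(ti), self.n_states), dtype=np.float32)
            for p, (i, j, k) in enumerate(zip(ti, tj, tk)):
                T3[p] = (self.states[:, i] == self.states[:, j]) & (
                    self.states[:, i] == self.states[:, k]
                )
            self._T3 = T3
        return self._T3

    def log_weights(self, h: np.ndarray, J: np.ndarray,
                    G: np.ndarray | None = None) -> np.ndarray:
        """Unnormalized log-probability of every state."""
        e = h.astype(np.float32).ravel() @ self.M1h
        e += J[self.iu, self.ju].astype(np.float32) @ self.EQ
        if G is not None:
            ti, tj, tk = triplet_index(self.n_mice)
            e += G[ti, tj, tk].astype(np.float32) @ self.T3
        return e.astype(np.float64)

    def distribution(self, h, J, G=None):
        lw = self.log_weights(h, J, G)
        log_z = float(logsumexp(lw))
        return np.exp(lw - log_z), log_z

    def moments(self, h, J, G=None, *, want_triplets: bool = False) -> MomentSet:
        p, log_z = self.distribution(h, J, G)
        p32 = p.astype(np.float32)
        m = (self.M1h @ p32).reshape(self.n_mice, self.q).astype(np.float64)
        gvec = (self.EQ @ p32).astype(np.float64)
        gamma = np.eye(self.n_mice)
        gamma[self.iu, self.ju] = gvec
        gamma[self.ju, self.iu] = gvec
        g3 = None
        if want_triplets or G is not None:
            g3 = (self.T3 @ p32).astype(np.float64)
        return MomentSet(m=m, gamma=gamma, gamma3=g3, log_z=log_z,
                         se_m=np.zeros_like(m), se_gamma=np.zeros_like(gamma),
                         n_samples=self.n_states)

    def triplet_cstar(self, h, J, G=None) -> np.ndarray:
        """Model-predicted C*_ijk (same-compartment triplet probability
        minus the product of single-mouse marginals, summed over
        compartments), as an i<j<k vector."""
        p, _ = self.distribution(h, J, G)
        p32 = p.astype(np.float32)
        n, q = self.n_mice, self.q
        m = (self.M1h @ p32).reshape(n, q).astype(np.float64)
        ti, tj, tk = triplet_index(n)
        out = np.zeros(len(ti))
        for r in range(q):
            X = self.M1h.reshape(n, q, self.n_states)[:, r, :]
            f3 = np.einsum("s,is,js,ks->ijk", p32, X, X, X, optimize=True)
            out += f3[ti, tj, tk] - m[ti, r] * m[tj, r] * m[tk, r]
        return out

    def sample(self, h, J, G=None, *, size: int, rng) -> np.ndarray:
        """Independent draws of full co-localization states, (size, N)."""
        p, _ = self.distribution(h, J, G)
        idx = rng.choice(self.n_states, size=size, p=p)
        return self.states[idx].copy()


def _triplet_field(sigma, G, i, field):
    """Add triplet contributions to the conditional field of site i."""
    n = sigma.shape[1]
    for j in range(n):
        if j == i:
            continue
        for k in range(j + 1, n):
            if k == i:
                continue
            g = G[i, j, k]
            if g == 0.0:
                continue
            same = sigma[:, j] == sigma[:, k]
            if same.any():
                field[same, sigma[same, j]] += g


def gibbs_sweeps(sigma: np.ndarray, h: np.ndarray, J: np.ndarray,
                 G: np.ndarray | None = None, *, n_sweeps: int,
                 rng: np.random.Generator, q: int | None = None) -> None:
    """Run single-site heat-bath sweeps on chain states, in place.

    ``sigma`` is (n_chains, N) with labels in ``0..q-1``; each sweep
    updates every site once, in a fresh random order, drawing the new
    label from the exact conditional distribution given all other mice.
    """
    n_chains, n = sigma.shape
    q = h.shape[1] if q is None else q
    rows = np.arange(n_chains)
    for _ in range(n_sweeps):
        for i in rng.permutation(n):
            onehot = np.zeros((n_chains, n, q), dtype=np.float64)
            onehot[rows[:, None], np.arange(n)[None, :], sigma] = 1.0
            field = h[i] + np.tensordot(onehot, J[i], axes=([1], [0]))
            if G is not None:
                _triplet_field(sigma, G, i, field)
            p = softmax(field, axis=1)
            u = rng.random(n_chains)
            sigma[:, i] = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)


def gibbs_moments(h: np.ndarray, J: np.ndarray, G: np.ndarray | None = None, *,
                  n_chains: int = 64, n_samples: int = 500, burn_in: int = 200,
                  thin: int = 2, q: int | None = None, seed=None,
                  rng: np.random.Generator | None = None,
                  want_triplets: bool = False,
                  init: np.ndarray | None = None) -> MomentSet:
    """Heat-bath Gibbs estimate of model moments.

    Runs ``n_chains`` independent chains (vectorized single-site updates in
    random sweep order), keeps ``n_samples`` states per chain every ``thin``
    sweeps after ``burn_in`` sweeps, and reports moments with standard
    errors computed across chains — chains are independent, so the SE is
    valid despite within-chain autocorrelation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n, q_ = h.shape
    q = q_ if q is None else q
    iu, ju = pair_index(n)
    ti, tj, tk = triplet_index(n)
    track3 = want_triplets or G is not None

    sigma = rng.integers(0, q, size=(n_chains, n)).astype(np.int8) \
        if init is None else init.copy()

    sum_m = np.zeros((n_chains, n, q))
    sum_g = np.zeros((n_chains, len(iu)))
    sum_g3 = np.zeros((n_chains, len(ti))) if track3 else None

    gibbs_sweeps(sigma, h, J, G, n_sweeps=burn_in, rng=rng, q=q)
    for _ in range(n_samples):
        gibbs_sweeps(sigma, h, J, G, n_sweeps=thin, rng=rng, q=q)
        oh = np.zeros((n_chains, n, q))
        oh[np.arange(n_chains)[:, None], np.arange(n)[None, :], sigma] = 1.0
        sum_m += oh
        sum_g += sigma[:, iu] == sigma[:, ju]
        if track3:
            sum_g3 += (sigma[:, ti] == sigma[:, tj]) & (sigma[:, ti] == sigma[:, tk])

    def reduce(acc):
        chain_mean = acc / n_samples
        mean = chain_mean.mean(axis=0)
        se = chain_mean.std(axis=0, ddof=1) / np.sqrt(n_chains)
        return mean, se

    m, se_m = reduce(sum_m)
    gvec, se_gvec = reduce(sum_g)
    gamma = np.eye(n)
    gamma[iu, ju] = gvec
    gamma[ju, iu] = gvec
    se_gamma = np.zeros((n, n))
    se_gamma[iu, ju] = se_gvec
    se_gamma[ju, iu] = se_gvec
    g3 = se_g3 = None
    if track3:
        g3, se_g3 = reduce(sum_g3)
    return MomentSet(m=m, gamma=gamma, gamma3=g3, se_m=se_m, se_gamma=se_gamma,
                     se_gamma3=se_g3, n_samples=n_chains * n_samples)
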