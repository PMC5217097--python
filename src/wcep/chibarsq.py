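"""Chi-bar-squared machinery for cone-constrained simultaneous inference.

A closed convex cone of weight vectors is specified by ``s`` linear equality
constraints and ``K - s`` linear inequality constraints whose stacked
coefficient matrix is square and of full rank,

    C = {w : a_i' w = 0 (i <= s),  a_i' w >= 0 (i > s)}.

For a Gaussian vector with non-singular covariance ``V``, the squared maximal
standardized contrast over the cone follows a chi-bar-squared distribution: a
finite mixture of central chi-squared distributions with 0..K degrees of
freedom.  The mixing weight on ``i`` degrees of freedom is the probability
that the projection of a draw from N(0, V) onto the cone (in the V^{-1}
metric) lands on a face of dimension ``i``.

This module provides cone validation, the metric projection, exact and
Monte-Carlo mixing weights, and tail probabilities / quantiles of the
mixture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Cone",
    "ChiBarWeights",
    "CriticalValue",
    "cone_validate",
    "nonneg_cone",
    "ordered_cone",
    "project",
    "chibar_weights_exact",
    "chibar_weights_mc",
    "chibar_tail",
    "chibar_quantile",
]

_RANK_TOL = 1e-10
_ACTIVE_TOL = 1e-9


@dataclass(frozen=True)
class Cone:
    """Polyhedral cone in constraint form with a full-rank stacked matrix."""

    A_eq: np.ndarray  # (s, K)
    A_ineq: np.ndarray  # (K - s, K)

    @property
    def K(self) -> int:
        return self.A_ineq.shape[1]

    @property
    def s(self) -> int:
        return self.A_eq.shape[0]

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack([self.A_eq, self.A_ineq])

    def contains(self, w: np.ndarray, tol: float = 1e-10) -> bool:
        w = np.asarray(w, dtype=float)
        ok_eq = self.s == 0 or np.all(np.abs(self.A_eq @ w) <= tol)
        ok_in = np.all(self.A_ineq @ w >= -tol)
        return bool(ok_eq and ok_in)


@dataclass(frozen=True)
class ChiBarWeights:
    """Mixing weights of the chi-bar-squared distribution, indexed 0..K."""

    w_tilde: np.ndarray
    method: str  # "exact" | "monte_carlo"
    mc_se: np.ndarray | None = None

    @property
    def K(self) -> int:
        return len(self.w_tilde) - 1

    def __post_init__(self):
        w = np.asarray(self.w_tilde, dtype=float)
        if np.any(w < -1e-12):
            raise ValueError("mixing weights must be non-negative")
        tol = 1e-8 if self.method == "exact" else 1e-6 + 3.0 * float(
            np.sqrt(np.sum(self.mc_se**2)) if self.mc_se is not None else 0.0
        )
        if abs(w.sum() - 1.0) > max(tol, 1e-6):
            raise ValueError(f"mixing weights sum to {w.sum():.8f}, not 1")


@dataclass(frozen=True)
class CriticalValue:
    """Squared critical value eta used in interval (7)-style formulas."""

    eta: float
    level: float
    method: str  # "chibar" | "scheffe" | "unadjusted"
    weights: ChiBarWeights | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.eta > 0:
            raise ValueError("eta must be positive")


def cone_validate(A_eq, A_ineq) -> Cone:
    """Validate constraint matrices and return a :class:`Cone`.

    The stacked ``[A_eq; A_ineq]`` matrix must be square of full rank and
    there must be at least one inequality row.
    """
    A_ineq = np.atleast_2d(np.asarray(A_ineq, dtype=float))
    K = A_ineq.shape[1]
    if A_eq is None or np.size(A_eq) == 0:
        A_eq = np.zeros((0, K))
    A_eq = np.atleast_2d(np.asarray(A_eq, dtype=float))
    if A_eq.shape[0] == 1 and A_eq.size == 0:
        A_eq = np.zeros((0, K))
    if A_ineq.shape[0] == 0:
        raise ValueError("cone requires at least one inequality constraint")
    if A_eq.shape[1] != K:
        raise ValueError("A_eq and A_ineq must have the same number of columns")
    stacked = np.vstack([A_eq, A_ineq])
    if stacked.shape != (K, K):
        raise ValueError(
            f"stacked constraint matrix must be {K}x{K}, got {stacked.shape}"
        )
    if np.linalg.matrix_rank(stacked, tol=_RANK_TOL * max(1.0, np.abs(stacked).max())) < K:
        raise ValueError("stacked constraint matrix is rank deficient")
    return Cone(A_eq=A_eq, A_ineq=A_ineq)


def nonneg_cone(K: int) -> Cone:
    """Non-negativity cone {w >= 0} in dimension K."""
    return cone_validate(None, np.eye(K))


def ordered_cone(K: int, increasing: bool = False) -> Cone:
    """Monotone-ordered non-negative cone.

    By default {w_1 >= w_2 >= ... >= w_K >= 0}; with ``increasing=True``
    the reverse ordering {0 <= w_1 <= ... <= w_K}, which matches event
    types listed least to most severe.
    """
    rows = []
    for i in range(K - 1):
        r = np.zeros(K)
        r[i], r[i + 1] = 1.0, -1.0
        rows.append(r)
    last = np.zeros(K)
    last[K - 1] = 1.0
    rows.append(last)
    A = np.array(rows)
    if increasing:
        A = A[:, ::-1]
    return cone_validate(None, A)


def _check_pd(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    evals = np.linalg.eigvalsh((V + V.T) / 2.0)
    if evals[0] <= _RANK_TOL * max(evals[-1], 1e-300):
        raise np.linalg.LinAlgError(
            "covariance matrix is singular or nearly singular; remove "
            "redundant event types (e.g. the no-event category)"
        )
    return V


def _face_projectors(cone: Cone, V: np.ndarray):
    """Linear maps z -> candidate projection for each active set of
    inequality rows, ordered by increasing active-set size (so the first
    feasible minimiser has the largest face dimension)."""
    K, s = cone.K, cone.s
    m = K - s
    projectors = []
    for size in range(m + 1):
        for act in itertools.combinations(range(m), size):
            C = np.vstack([cone.A_eq, cone.A_ineq[list(act)]])
            if C.shape[0] == 0:
                P = np.eye(K)
            else:
                P = np.eye(K) - V @ C.T @ np.linalg.solve(C @ V @ C.T, C)
            projectors.append((act, P))
    return projectors


def project(z, V, cone: Cone):
    """V^{-1}-metric projection of ``z`` onto the cone.

    Returns ``(w_star, face_dim)`` where ``face_dim`` is the dimension of
    the smallest face of the cone containing the projection.  Solved by
    enumerating candidate active sets of the inequality constraints; for
    each candidate the equality-constrained minimiser is a linear map of
    ``z``, and the feasible candidate with the smallest objective wins
    (ties broken towards the larger face).
    """
    z = np.asarray(z, dtype=float)
    V = _check_pd(V)
    W = np.linalg.inv(V)
    best = None
    for act, P in _face_projectors(cone, V):
        w = P @ z
        if not cone.contains(w, tol=_ACTIVE_TOL):
            continue
        r = z - w
        obj = float(r @ W @ r)
        if best is None or obj < best[0] - 1e-12 * (1.0 + abs(best[0])):
            n_active = int(np.sum(np.abs(cone.A_ineq @ w) <= _ACTIVE_TOL))
            best = (obj, w, cone.K - cone.s - n_active)
    if best is None:  # pragma: no cover - full-rank cones always have a face
        raise RuntimeError("projection failed: no feasible face found")
    _, w_star, face_dim = best
    # Pythagoras sanity: ||z||^2 = ||w*||^2 + ||z-w*||^2 in the V^{-1} metric
    return w_star, face_dim


def _orthant_prob(Sigma: np.ndarray) -> float:
    """P(X >= 0) for X ~ N(0, Sigma); closed forms up to dim 2, numerical
    integration above."""
    d = Sigma.shape[0]
    if d == 0:
        return 1.0
    if d == 1:
        return 0.5
    sd = np.sqrt(np.diag(Sigma))
    R = Sigma / np.outer(sd, sd)
    if d == 2:
        return 0.25 + np.arcsin(np.clip(R[0, 1], -1.0, 1.0)) / (2.0 * np.pi)
    # fixed internal seed: the quasi-Monte-Carlo integrator is randomized,
    # and reproducible outputs matter more than its (tiny) seed-to-seed
    # wobble
    dist = stats.multivariate_normal(
        mean=np.zeros(d), cov=R, allow_singular=True, seed=1_234_567
    )
    return float(np.clip(dist.cdf(np.zeros(d)), 0.0, 1.0))


def chibar_weights_exact(cone: Cone, V) -> ChiBarWeights:
    """Exact chi-bar-squared mixing weights by face enumeration.

    The squared maximal standardized contrast over the cone equals the
    squared Euclidean norm of the projection of a standard normal vector
    onto the linearly transformed cone ``V^{1/2} C``; the mixing weight on
    ``i`` degrees of freedom is the probability that this projection lands
    on a face of dimension ``i``.  Equivalently, it is the face-dimension
    distribution of the V-metric projection of a draw from N(0, V^{-1})
    onto C.  In constraint coordinates ``u = M w`` (``M`` the stacked
    constraint matrix) each face's probability factorises into a product of
    two multivariate-normal orthant probabilities (Kudo-type formula) based
    on the matrix ``G = (M V^{-1} M')^{-1}``.
    """
    V = _check_pd(np.asarray(V, dtype=float))
    K, s = cone.K, cone.s
    m = K - s
    if m > 10:
        raise ValueError(
            "exact weights enumerate 2^(K-s) faces; use chibar_weights_mc "
            "for more than 10 inequality constraints"
        )
    M = cone.stacked
    G = np.linalg.inv(M @ np.linalg.solve(V, M.T))
    ineq = list(range(s, K))
    w_tilde = np.zeros(K + 1)
    for size in range(m + 1):
        for J in itertools.combinations(ineq, size):
            J = list(J)
            B = [i for i in ineq if i not in J]
            GJJ = G[np.ix_(J, J)]
            if J:
                p_pos = _orthant_prob(np.linalg.inv(GJJ))
            else:
                p_pos = 1.0
            if B:
                if J:
                    schur = G[np.ix_(B, B)] - G[np.ix_(B, J)] @ np.linalg.solve(
                        GJJ, G[np.ix_(J, B)]
                    )
                else:
                    schur = G[np.ix_(B, B)]
                p_dual = _orthant_prob(schur)
            else:
                p_dual = 1.0
            w_tilde[size] += p_pos * p_dual
    total = w_tilde.sum()
    if abs(total - 1.0) > 1e-4:
        raise RuntimeError(f"face probabilities sum to {total:.6f}; numerical failure")
    w_tilde /= total
    return ChiBarWeights(w_tilde=w_tilde, method="exact")


def chibar_weights_mc(cone: Cone, V, reps: int, seed) -> ChiBarWeights:
    """Monte-Carlo mixing weights by face counting.

    Draws y ~ N(0, V^{-1}) and projects onto the cone in the V metric (the
    face-dimension distribution of that projection is exactly the mixing
    distribution of the maximal-contrast statistic; see
    :func:`chibar_weights_exact`).  Vectorized over draws: each candidate
    active set defines a linear map, so all candidate projections are
    matrix products; per draw the feasible candidate with minimal objective
    is selected (ties to the larger face).
    """
    if reps < 1000:
        raise ValueError("use at least 1000 Monte-Carlo replications")
    V = _check_pd(np.asarray(V, dtype=float))
    rng = np.random.default_rng(seed)
    K, s = cone.K, cone.s
    Vinv = np.linalg.inv(V)
    Z = rng.multivariate_normal(np.zeros(K), Vinv, size=reps, method="cholesky")
    W = V  # projection metric is the inverse of the draw covariance
    projectors = _face_projectors(cone, Vinv)
    n_cand = len(projectors)
    objs = np.full((reps, n_cand), np.inf)
    dims = np.empty(n_cand, dtype=int)
    for j, (act, P) in enumerate(projectors):
        Wc = Z @ P.T  # candidate projections
        feas = np.ones(reps, dtype=bool)
        if s:
            feas &= np.all(np.abs(Wc @ cone.A_eq.T) <= _ACTIVE_TOL, axis=1)
        feas &= np.all(Wc @ cone.A_ineq.T >= -_ACTIVE_TOL, axis=1)
        R = Z - Wc
        obj = np.einsum("ij,jk,ik->i", R, W, R)
        objs[feas, j] = obj[feas]
        dims[j] = K - s - len(act)
    # candidates are ordered by decreasing face dimension; argmin takes the
    # first minimiser, i.e. the largest face, after rounding away fp noise
    choice = np.argmin(np.round(objs, 9), axis=1)
    face_dims = dims[choice]
    counts = np.bincount(face_dims, minlength=K + 1)
    w_tilde = counts / reps
    mc_se = np.sqrt(w_tilde * (1.0 - w_tilde) / reps)
    return ChiBarWeights(w_tilde=w_tilde, method="monte_carlo", mc_se=mc_se)


def chibar_tail(c: float, weights: ChiBarWeights) -> float:
    """P(chi-bar-squared >= c): the mixture's survival function on the
    squared scale (the 0-df component is a point mass at 0)."""
    if c < 0:
        raise ValueError("c must be non-negative")
    w = weights.w_tilde
    if c <= 0:
        return 1.0
    dfs = np.arange(1, len(w))
    return float(w[0] * 0.0 + np.sum(w[1:] * stats.chi2.sf(c, dfs)))


def chibar_quantile(p: float, weights: ChiBarWeights) -> float:
    """c such that the mixture CDF at c equals p (0 if p <= w_tilde_0)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    w = weights.w_tilde
    if p <= w[0]:
        return 0.0
    K = weights.K

    def f(c):
        return (1.0 - chibar_tail(c, weights)) - p

    hi = float(stats.chi2.isf(min(1.0 - p, 0.5), K)) + 1.0
    while f(hi) < 0:
        hi *= 2.0
    from scipy.optimize import brentq

    return float(brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12))
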