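"""Estimation of event-type probabilities and covariances per arm.

Two estimation paths are provided.  With complete follow-up through the
horizon tau, event-type probabilities are observed proportions and the
covariance is multinomial.  With right-censoring, state-occupation
probabilities of a directed-tree multistate model are estimated by the
Aalen-Johansen product-integral with a Greenwood-type covariance obtained
from the martingale representation of the estimator.  Both paths report the
exhaustive probabilities mapped through a scheme's linear transformation.

The integrated (restricted-mean-style) difference statistic is a Riemann sum
of the probability-difference path, with a leave-one-subject-out jackknife
covariance per arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .event_model import ComponentSet, EventTypeScheme, SubjectHistory, build_scheme, classify_subject

__all__ = [
    "MultistateTree",
    "ArmEstimate",
    "DifferenceEstimate",
    "IntegratedDifference",
    "estimate_binary_arm",
    "aalen_johansen_arm",
    "transform_estimate",
    "difference",
    "integrated_difference",
]

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class MultistateTree:
    """Directed tree of states with one node per exhaustive event type.

    Each non-root state corresponds to a distinct combination of component
    outcomes (``state_components``); every edge acquires exactly one new
    component.  ``hazards`` optionally attaches a constant transition rate
    (per unit time) to each edge, used by the simulator and the analytic
    probability oracle.
    """

    states: tuple
    edges: tuple  # ((from, to), ...)
    state_components: dict  # state -> frozenset of component labels
    hazards: dict | None = None  # (from, to) -> rate
    root: str = "initial"

    def __post_init__(self):
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "edges", tuple((a, b) for a, b in self.edges))
        if self.root not in states:
            raise ValueError("root state missing from state list")
        parents = {}
        for a, b in self.edges:
            if a not in states or b not in states:
                raise ValueError(f"edge ({a}, {b}) uses unknown state")
            if b in parents:
                raise ValueError(f"state {b!r} has more than one parent")
            if b == self.root:
                raise ValueError("root cannot have a parent")
            parents[b] = a
        for s in states:
            if s != self.root and s not in parents:
                raise ValueError(f"state {s!r} is unreachable")
        if self.hazards is not None:
            for e in self.edges:
                rate = self.hazards.get(e)
                if rate is None or not np.isfinite(rate) or rate < 0:
                    raise ValueError(f"edge {e} needs a finite non-negative hazard")

    @property
    def nonroot_states(self) -> tuple:
        return tuple(s for s in self.states if s != self.root)

    def children(self, state):
        return [b for a, b in self.edges if a == state]

    def is_absorbing(self, state) -> bool:
        return not self.children(state)

    def exhaustive_subsets(self) -> tuple:
        return tuple(frozenset(self.state_components[s]) for s in self.nonroot_states)

    def scheme(self, components: ComponentSet, setting: str) -> EventTypeScheme:
        """Event-type scheme whose exhaustive types are this tree's states."""
        return build_scheme(components, setting, subsets=self.exhaustive_subsets())

    def edge_component(self, a, b):
        """The single component acquired on edge (a, b)."""
        gained = frozenset(self.state_components[b]) - frozenset(self.state_components[a])
        if len(gained) != 1:
            raise ValueError(f"edge ({a}, {b}) must acquire exactly one component")
        return next(iter(gained))

    def generator(self) -> np.ndarray:
        """Intensity matrix over ``states`` (requires hazards)."""
        if self.hazards is None:
            raise ValueError("tree has no hazards")
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        Q = np.zeros((n, n))
        for (a, b), rate in self.hazards.items():
            Q[idx[a], idx[b]] = rate
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q


def _check_cov(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    cov = (cov + cov.T) / 2.0
    evals = np.linalg.eigvalsh(cov)
    if evals.size and evals[0] < -_PSD_TOL:
        raise ValueError(f"covariance not PSD (min eigenvalue {evals[0]:.2e})")
    return cov


@dataclass(frozen=True)
class ArmEstimate:
    """Estimated event-type probabilities for one arm at horizon tau."""

    probs: np.ndarray
    cov: np.ndarray
    n: int
    tau: float
    scheme: EventTypeScheme
    extrapolated: bool = False  # risk set exhausted before tau

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")
        if not self.scheme.overlapping and probs.sum() > 1 + 1e-8:
            raise ValueError("non-overlapping type probabilities exceed 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "cov", _check_cov(self.cov))


@dataclass(frozen=True)
class DifferenceEstimate:
    """Between-arm difference of event-type probabilities with covariance."""

    D: np.ndarray
    V: np.ndarray
    n_A: int
    n_B: int
    tau: float
    scheme: EventTypeScheme

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if np.any(np.abs(D) > 1 + 1e-12):
            raise ValueError("difference entries outside [-1, 1]")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "V", _check_cov(self.V))

    @property
    def K(self) -> int:
        return len(self.D)


@dataclass(frozen=True)
class IntegratedDifference:
    """Integrated probability difference with jackknife covariance."""

    Dprime: np.ndarray
    V: np.ndarray
    h_spec: str
    grid_step: float
    tau: float
    scheme: EventTypeScheme

    def __post_init__(self):
        object.__setattr__(self, "V", _check_cov(self.V))

    @property
    def K(self) -> int:
        return len(self.Dprime)


def estimate_binary_arm(
    records, scheme: EventTypeScheme, tau: float
) -> ArmEstimate:
    """Observed-proportion estimate with multinomial covariance.

    Every subject must be completely followed through ``tau`` (or have an
    absorbing event earlier).  Exhaustive-type counts are multinomial; the
    scheme-level probabilities and covariance are the linear images
    ``L p_ex`` and ``L V_ex L'``, which for non-overlapping schemes equals
    the multinomial covariance of the aggregated counts.
    """
    records = list(records)
    n = len(records)
    if n == 0:
        raise ValueError("no subjects in arm")
    K_ex = len(scheme.exhaustive_types)
    ex_scheme = build_scheme(
        scheme.components, "exhaustive", subsets=scheme.exhaustive_subsets
    )
    counts = np.zeros(K_ex)
    for rec in records:
        counts += classify_subject(rec, ex_scheme, tau)
    p_ex = counts / n
    V_ex = (np.diag(p_ex) - np.outer(p_ex, p_ex)) / n
    L = scheme.L
    return ArmEstimate(
        probs=L @ p_ex, cov=L @ V_ex @ L.T, n=n, tau=tau, scheme=scheme
    )


def _aj_path(records, tree: MultistateTree, tau: float, with_cov: bool = True):
    """Aalen-Johansen occupation probabilities over all tree states.

    Returns ``(times, probs_path, cov_at_tau, exhausted)`` where
    ``probs_path[j]`` is the occupation vector just after ``times[j]``.

    The covariance is the Greenwood-type plug-in from the martingale
    representation: at each event time the running covariance is transported
    by the transition factor ``B = I + dA`` and incremented by the
    conditional multinomial covariance of the observed transitions weighted
    by the squared occupation probabilities of the origin states.
    """
    states = tree.states
    idx = {s: i for i, s in enumerate(states)}
    m = len(states)
    root_i = idx[tree.root]
    # reconstruct each subject's state path from acquired components
    transitions = []  # (time, from_i, to_i)
    exits = []  # (time, state_i) censoring exits
    comp_to_child = {}
    for a, b in tree.edges:
        comp_to_child[(a, tree.edge_component(a, b))] = b
    for rec in records:
        state = tree.root
        for t, lab in rec.events:
            nxt = comp_to_child.get((state, lab))
            if nxt is None:
                raise ValueError(
                    f"subject {rec.subject_id!r}: transition {lab!r} from state "
                    f"{state!r} is not an edge of the tree"
                )
            transitions.append((t, idx[state], idx[nxt]))
            state = nxt
        if not tree.is_absorbing(state):
            ct = rec.censor_time
            if ct is None:
                ct = np.inf  # treated as observed beyond tau
            exits.append((min(ct, np.inf), idx[state]))
        # absorbed subjects stay in their absorbing state forever
    transitions.sort()
    exits.sort()

    # a subject's follow-up is complete once absorbed; otherwise it ends at
    # the censoring time
    follow_ups = []
    for rec in records:
        state = tree.root
        for _, lab in rec.events:
            state = comp_to_child[(state, lab)]
        if tree.is_absorbing(state):
            follow_ups.append(np.inf)
        else:
            follow_ups.append(rec.censor_time if rec.censor_time is not None else np.inf)
    exhausted = max(follow_ups) < tau

    counts = np.zeros(m)
    counts[root_i] = len(records)
    p = np.zeros(m)
    p[root_i] = 1.0
    Sigma = np.zeros((m, m))
    times_out = [0.0]
    path = [p.copy()]

    ti = ei = 0
    nT, nE = len(transitions), len(exits)
    while ti < nT and transitions[ti][0] <= tau:
        u = transitions[ti][0]
        # all transitions at this time; censoring at the same time is
        # processed afterwards (standard convention)
        dN = np.zeros((m, m))
        while ti < nT and transitions[ti][0] == u:
            _, a, b = transitions[ti]
            dN[a, b] += 1.0
            ti += 1
        # remove earlier censor exits from the risk sets first
        while ei < nE and exits[ei][0] < u:
            counts[exits[ei][1]] -= 1.0
            ei += 1
        Y = counts.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            dA = np.where(Y[:, None] > 0, dN / np.where(Y[:, None] > 0, Y[:, None], 1.0), 0.0)
        B = dA - np.diag(dA.sum(axis=1)) + np.eye(m)
        if with_cov:
            Wmat = np.zeros((m, m))
            for g in np.nonzero(dN.sum(axis=1) > 0)[0]:
                if Y[g] <= 0:
                    continue
                dg = dA[g]  # off-diagonal transition increments from g
                # full-row covariance including the diagonal (stay) entry
                C = (np.diag(dg) - np.outer(dg, dg)) / Y[g]
                C[g, :] = -C.sum(axis=0)
                C[:, g] = C[g, :]
                C[g, g] = -C[g, np.arange(m) != g].sum()
                Wmat += (p[g] ** 2) * C
            Sigma = B.T @ Sigma @ B + Wmat
        p = p @ B
        # apply the state moves and same-time censorings to the risk sets
        counts += dN.sum(axis=0) - dN.sum(axis=1)
        while ei < nE and exits[ei][0] == u:
            counts[exits[ei][1]] -= 1.0
            ei += 1
        times_out.append(u)
        path.append(p.copy())
    return np.array(times_out), np.array(path), Sigma, exhausted


def aalen_johansen_arm(
    records, tree: MultistateTree, tau: float, scheme: EventTypeScheme
) -> ArmEstimate:
    """Aalen-Johansen estimate of the scheme's event-type probabilities.

    State-occupation probabilities of the non-root states at ``tau`` are
    estimated by the product-integral over the arm's event times; the
    Greenwood-type covariance of the exhaustive vector is mapped through the
    scheme's ``L`` matrix.  Without censoring before ``tau`` this reduces
    exactly to the observed proportions.
    """
    records = list(records)
    if not records:
        raise ValueError("no subjects in arm")
    times, path, Sigma, exhausted = _aj_path(records, tree, tau)
    p_all = path[-1]
    if exhausted:
        warnings.warn(
            "risk set exhausted before tau; carrying last Aalen-Johansen "
            "value forward",
            RuntimeWarning,
        )
    nr = [i for i, s in enumerate(tree.states) if s != tree.root]
    # align tree states with the scheme's exhaustive types
    order = _state_order(tree, scheme)
    sel = [nr[j] for j in order]
    p_ex = p_all[sel]
    V_ex = Sigma[np.ix_(sel, sel)]
    # clip tiny negative eigenvalues from floating-point accumulation
    L = scheme.L
    return ArmEstimate(
        probs=np.clip(L @ p_ex, 0.0, 1.0),
        cov=_psd_clip(L @ V_ex @ L.T),
        n=len(records),
        tau=tau,
        scheme=scheme,
        extrapolated=exhausted,
    )


def _state_order(tree: MultistateTree, scheme: EventTypeScheme):
    subsets = tree.exhaustive_subsets()
    order = []
    for s in scheme.exhaustive_subsets:
        try:
            order.append(subsets.index(frozenset(s)))
        except ValueError:
            raise ValueError(
                "scheme exhaustive types do not match the tree's states"
            ) from None
    return order


def _psd_clip(cov: np.ndarray) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    evals, evecs = np.linalg.eigh(cov)
    if evals.size and evals[0] < 0:
        evals = np.clip(evals, 0.0, None)
        cov = evecs @ np.diag(evals) @ evecs.T
        cov = (cov + cov.T) / 2.0
    return cov


def transform_estimate(est: ArmEstimate, L, event_types=None, setting=None) -> ArmEstimate:
    """Apply a linear map: probs -> L probs, cov -> L cov L'."""
    L = np.asarray(L, dtype=float)
    if L.shape[1] != len(est.probs):
        raise ValueError("L columns must match the estimate dimension")
    scheme = est.scheme
    if event_types is not None:
        scheme = EventTypeScheme(
            setting or est.scheme.setting,
            tuple(event_types),
            L @ est.scheme.L,
            est.scheme.components,
            est.scheme.exhaustive_types,
            est.scheme.exhaustive_subsets,
        )
    return ArmEstimate(
        probs=L @ est.probs,
        cov=L @ est.cov @ L.T,
        n=est.n,
        tau=est.tau,
        scheme=scheme,
        extrapolated=est.extrapolated,
    )


def difference(estA: ArmEstimate, estB: ArmEstimate) -> DifferenceEstimate:
    """Independent-arms difference: D = p_A - p_B, V = V_A + V_B."""
    if estA.scheme.setting != estB.scheme.setting or estA.scheme.event_types != estB.scheme.event_types:
        raise ValueError("arm estimates use different schemes")
    if estA.tau != estB.tau:
        raise ValueError("arm estimates use different horizons")
    return DifferenceEstimate(
        D=estA.probs - estB.probs,
        V=estA.cov + estB.cov,
        n_A=estA.n,
        n_B=estB.n,
        tau=estA.tau,
        scheme=estA.scheme,
    )


def _integrated_probs(records, tree, tau, scheme, h, grid):
    """Left-endpoint Riemann sum of h(t) p_hat(t) over the grid, per arm."""
    times, path, _, _ = _aj_path(records, tree, tau, with_cov=False)
    nr = [i for i, s in enumerate(tree.states) if s != tree.root]
    order = _state_order(tree, scheme)
    sel = [nr[j] for j in order]
    # step-function lookup of the occupation path at the grid points
    pos = np.searchsorted(times, grid, side="right") - 1
    P = path[pos][:, sel]  # (len(grid), K_ex)
    hv = np.asarray([h(t) for t in grid], dtype=float)
    if np.any(hv < 0):
        raise ValueError("h must be non-negative on the grid")
    step = grid[1] - grid[0] if len(grid) > 1 else tau
    integ_ex = (hv[:, None] * P).sum(axis=0) * step
    return scheme.L @ integ_ex


def integrated_difference(
    recordsA,
    recordsB,
    tree: MultistateTree,
    tau: float,
    scheme: EventTypeScheme,
    h=None,
    grid_step: float | None = None,
) -> IntegratedDifference:
    """Integrated probability difference with jackknife covariance.

    ``Dprime_k = sum_grid h(t) (p_A,k(t) - p_B,k(t)) * step`` using a
    left-endpoint rule on a regular grid (default step tau/200).  The
    covariance is the sum over arms of leave-one-subject-out jackknife
    covariances of the integrated probability vector.
    """
    if grid_step is None:
        grid_step = tau / 200.0
    if grid_step <= 0 or grid_step >= tau:
        raise ValueError("grid_step must lie in (0, tau)")
    if h is None:
        h = lambda t: 1.0
        h_spec = "h == 1"
    else:
        h_spec = getattr(h, "__name__", "user h")
    grid = np.arange(0.0, tau, grid_step)

    recordsA, recordsB = list(recordsA), list(recordsB)
    intA = _integrated_probs(recordsA, tree, tau, scheme, h, grid)
    intB = _integrated_probs(recordsB, tree, tau, scheme, h, grid)

    def jack_cov(records):
        n = len(records)
        thetas = np.array(
            [
                _integrated_probs(records[:i] + records[i + 1 :], tree, tau, scheme, h, grid)
                for i in range(n)
            ]
        )
        centered = thetas - thetas.mean(axis=0)
        return (n - 1) / n * centered.T @ centered

    V = jack_cov(recordsA) + jack_cov(recordsB)
    return IntegratedDifference(
        Dprime=intA - intB,
        V=_psd_clip(V),
        h_spec=h_spec,
        grid_step=grid_step,
        tau=tau,
        scheme=scheme,
    )
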