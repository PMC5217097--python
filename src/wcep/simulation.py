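"""Multistate simulation, analytic oracles, coverage and power studies.

Trial data are generated from directed-tree multistate models with constant
transition hazards: at each state one exponential is drawn per outgoing edge
and the minimum wins, which is exact for constant hazards.  Closed-form
state-occupation probabilities (matrix exponential of the intensity matrix)
serve as the oracle for the true event-type probabilities.

The coverage study replays the simulation design used to validate the
chi-bar-squared method: replicate two-arm trials, estimate the event-type
probability difference and its covariance, and record how often two-sided
95% intervals cover the true weighted differences simultaneously over a
grid of cone weights.  The power/sample-size search replays the
trial-design use case with censoring and Aalen-Johansen estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy import stats

from .chibarsq import Cone, chibar_quantile, chibar_weights_exact, chibar_weights_mc
from .estimation import (
    ArmEstimate,
    MultistateTree,
    aalen_johansen_arm,
    difference,
    estimate_binary_arm,
)
from .event_model import ComponentSet, EventTypeScheme, SubjectHistory
from .inference import Z_UNADJ

__all__ = [
    "ScenarioSpec",
    "CoverageResult",
    "simulate_arm",
    "analytic_state_probs",
    "analytic_event_probs",
    "any_event_probability",
    "simplex_cone_grid",
    "coverage_study",
    "power_samplesize",
    "illness_death_tree",
    "two_transient_tree",
    "cardio_tree",
    "CARDIO_COMPONENTS",
]


# ---------------------------------------------------------------------------
# bundled scenario models

def illness_death_tree(
    rate_01: float = 0.05, rate_02: float = 0.02, rate_12: float = 0.2
) -> MultistateTree:
    """Illness-death model with a non-fatal state N and fatal state F.

    Expressed as a directed tree with one node per exhaustive event type:
    N only, F without prior N, and F after N.
    """
    return MultistateTree(
        states=("initial", "N+F-", "N-F+", "N+F+"),
        edges=(("initial", "N+F-"), ("initial", "N-F+"), ("N+F-", "N+F+")),
        state_components={
            "initial": frozenset(),
            "N+F-": frozenset({"N"}),
            "N-F+": frozenset({"F"}),
            "N+F+": frozenset({"N", "F"}),
        },
        hazards={
            ("initial", "N+F-"): rate_01,
            ("initial", "N-F+"): rate_02,
            ("N+F-", "N+F+"): rate_12,
        },
    )


def two_transient_tree(
    rate_01: float = 0.08,
    rate_02: float = 0.1,
    rate_03: float = 0.04,
    rate_13: float = 0.2,
    rate_23: float = 0.3,
) -> MultistateTree:
    """Two transient states N and M (M more severe) and a fatal state F,
    giving five exhaustive event types."""
    return MultistateTree(
        states=("initial", "N+M-F-", "N-M+F-", "N-M-F+", "N+M-F+", "N-M+F+"),
        edges=(
            ("initial", "N+M-F-"),
            ("initial", "N-M+F-"),
            ("initial", "N-M-F+"),
            ("N+M-F-", "N+M-F+"),
            ("N-M+F-", "N-M+F+"),
        ),
        state_components={
            "initial": frozenset(),
            "N+M-F-": frozenset({"N"}),
            "N-M+F-": frozenset({"M"}),
            "N-M-F+": frozenset({"F"}),
            "N+M-F+": frozenset({"N", "F"}),
            "N-M+F+": frozenset({"M", "F"}),
        },
        hazards={
            ("initial", "N+M-F-"): rate_01,
            ("initial", "N-M+F-"): rate_02,
            ("initial", "N-M-F+"): rate_03,
            ("N+M-F-", "N+M-F+"): rate_13,
            ("N-M+F-", "N-M+F+"): rate_23,
        },
    )


CARDIO_COMPONENTS = ComponentSet(("MI", "ST", "DE"), (False, False, True))

_CARDIO_RATES = {
    "control": dict(mi=0.04, st=0.06, de=0.015, mi_st=0.12, mi_de=0.03, st_de=0.03),
    "intervention": dict(mi=0.03, st=0.04, de=0.01, mi_st=0.08, mi_de=0.02, st_de=0.02),
}


def cardio_tree(arm: str = "control") -> MultistateTree:
    """Cardiovascular prevention-trial model: myocardial infarction (MI),
    stroke (ST) and vascular death (DE), with cause-specific rates doubling
    after an initial event.  A post-MI stroke patient continues to face the
    doubled death rate."""
    r = _CARDIO_RATES[arm]
    return MultistateTree(
        states=(
            "initial",
            "MI",
            "ST",
            "DE",
            "MI.ST",
            "MI.DE",
            "ST.DE",
            "MI.ST.DE",
        ),
        edges=(
            ("initial", "MI"),
            ("initial", "ST"),
            ("initial", "DE"),
            ("MI", "MI.ST"),
            ("MI", "MI.DE"),
            ("ST", "ST.DE"),
            ("MI.ST", "MI.ST.DE"),
        ),
        state_components={
            "initial": frozenset(),
            "MI": frozenset({"MI"}),
            "ST": frozenset({"ST"}),
            "DE": frozenset({"DE"}),
            "MI.ST": frozenset({"MI", "ST"}),
            "MI.DE": frozenset({"MI", "DE"}),
            "ST.DE": frozenset({"ST", "DE"}),
            "MI.ST.DE": frozenset({"MI", "ST", "DE"}),
        },
        hazards={
            ("initial", "MI"): r["mi"],
            ("initial", "ST"): r["st"],
            ("initial", "DE"): r["de"],
            ("MI", "MI.ST"): r["mi_st"],
            ("MI", "MI.DE"): r["mi_de"],
            ("ST", "ST.DE"): r["st_de"],
            ("MI.ST", "MI.ST.DE"): r["st_de"],
        },
    )


def scale_hazards(tree: MultistateTree, factor: float, edges=None) -> MultistateTree:
    """Return a copy with hazards multiplied by ``factor`` (all edges, or a
    subset)."""
    new = dict(tree.hazards)
    for e in edges if edges is not None else list(new):
        new[e] = new[e] * factor
    return MultistateTree(
        states=tree.states,
        edges=tree.edges,
        state_components=tree.state_components,
        hazards=new,
        root=tree.root,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Two-arm simulation scenario: control/intervention trees, per-arm
    sample size, horizon, and exponential censoring rate (0 = administrative
    censoring at tau only)."""

    tree_a: MultistateTree
    tree_b: MultistateTree
    n_per_arm: int
    tau: float
    censor_rate: float = 0.0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 subjects per arm")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")


# ---------------------------------------------------------------------------
# simulator and analytic oracle

def simulate_arm(
    tree: MultistateTree,
    n: int,
    tau: float,
    censor_rate: float = 0.0,
    seed=None,
    arm: str = "A",
) -> list:
    """Simulate ``n`` subjects along the tree with competing exponentials.

    Each subject advances by drawing one exponential per outgoing edge and
    taking the minimum, until absorption, censoring (exponential with rate
    ``censor_rate``), or administrative end of follow-up at ``tau``.
    """
    if tree.hazards is None:
        raise ValueError("tree has no hazards; cannot simulate")
    rng = np.random.default_rng(seed)
    out = []
    child_lists = {s: tree.children(s) for s in tree.states}
    for i in range(n):
        c_time = rng.exponential(1.0 / censor_rate) if censor_rate > 0 else np.inf
        end = min(tau, c_time)
        t, state = 0.0, tree.root
        events = []
        while True:
            children = child_lists[state]
            if not children:
                break
            rates = np.array([tree.hazards[(state, c)] for c in children])
            total = rates.sum()
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if t + wait > end:
                break
            t += wait
            prev, state = state, children[rng.choice(len(children), p=rates / total)]
            events.append((t, tree.edge_component(prev, state)))
        absorbed = not child_lists[state] or all(
            tree.hazards[(state, c)] == 0 for c in child_lists[state]
        )
        censor_time = None if (absorbed and events) else end
        out.append(
            SubjectHistory(
                subject_id=f"{arm}{i+1}",
                arm=arm,
                events=tuple(events),
                censor_time=censor_time,
            )
        )
    return out


def analytic_state_probs(tree: MultistateTree, t: float) -> np.ndarray:
    """Exact state-occupation probabilities at time ``t`` (root first,
    then non-root states in tree order), via the matrix exponential."""
    Q = tree.generator()
    return expm(Q * t)[tree.states.index(tree.root)]


def analytic_event_probs(
    tree: MultistateTree, t: float, scheme: EventTypeScheme | None = None
) -> np.ndarray:
    """Exact event-type probabilities at ``t``: non-root occupation
    probabilities, optionally mapped through a scheme's L matrix."""
    p = analytic_state_probs(tree, t)
    nonroot = np.array(
        [p[tree.states.index(s)] for s in tree.nonroot_states]
    )
    if scheme is None:
        return nonroot
    from .estimation import _state_order

    order = _state_order(tree, scheme)
    return scheme.L @ nonroot[order]


def any_event_probability(tree: MultistateTree, t: float) -> float:
    """Probability of leaving the initial state by time ``t``."""
    p = analytic_state_probs(tree, t)
    return float(1.0 - p[tree.states.index(tree.root)])


# ---------------------------------------------------------------------------
# weight grids

def simplex_cone_grid(cone: Cone, target_points: int) -> np.ndarray:
    """Approximately uniform grid on cone intersect {sum(w) = 1}.

    A regular integer lattice on the standard simplex is filtered by cone
    membership; the lattice resolution is chosen so the kept count is
    closest to ``target_points``.
    """
    K = cone.K

    def kept(m):
        pts = _simplex_lattice(K, m)
        ok = np.ones(len(pts), dtype=bool)
        if cone.s:
            ok &= np.all(np.abs(pts @ cone.A_eq.T) <= 1e-10, axis=1)
        ok &= np.all(pts @ cone.A_ineq.T >= -1e-10, axis=1)
        return pts[ok]

    # bracket the resolution: kept-count grows ~ m^(d) on the active face
    best = None
    m = max(1, int(round(target_points ** (1.0 / max(K - 1, 1)))))
    tried = {}
    for _ in range(60):
        pts = tried.get(m)
        if pts is None:
            pts = kept(m)
            tried[m] = pts
        c = len(pts)
        if best is None or abs(c - target_points) < abs(best[0] - target_points):
            best = (c, m, pts)
        if c < target_points:
            m_next = max(m + 1, int(m * 1.3))
        else:
            m_next = max(1, int(m / 1.3)) if c > target_points else m
        if m_next in tried or m_next == m:
            break
        m = m_next
    # local refinement around the best resolution
    _, m0, _ = best
    for m in range(max(1, m0 - 3), m0 + 4):
        if m not in tried:
            pts = kept(m)
            tried[m] = pts
            c = len(pts)
            if abs(c - target_points) < abs(best[0] - target_points):
                best = (c, m, pts)
    count, m, pts = best
    if count == 0:
        raise ValueError("cone does not intersect the weight simplex")
    return pts


def _simplex_lattice(K: int, m: int) -> np.ndarray:
    """All points (i_1/m, ..., i_K/m) with non-negative integers summing
    to m."""
    if K == 1:
        return np.ones((1, 1))
    out = []

    def rec(prefix, remaining, slots):
        if slots == 1:
            out.append(prefix + [remaining])
            return
        for i in range(remaining + 1):
            rec(prefix + [i], remaining - i, slots - 1)

    rec([], m, K)
    return np.array(out, dtype=float) / m


# ---------------------------------------------------------------------------
# coverage study

@dataclass(frozen=True)
class CoverageResult:
    simultaneous_coverage: dict  # method -> fraction covered
    relative_efficiencies: dict  # method -> mean sqrt(eta)/1.96
    reps: int
    dropped: int
    grid_size: int

    def mc_se(self, method: str) -> float:
        p = self.simultaneous_coverage[method]
        return float(np.sqrt(p * (1 - p) / self.reps))


def _estimate_difference(scenario, scheme, rng):
    """One replication: simulate both arms and estimate (D_hat, V_hat).

    With complete follow-up the exhaustive event-type counts of an arm are
    exactly multinomial with the analytic probabilities, so counts are drawn
    directly; with censoring, subject paths are simulated and the
    Aalen-Johansen estimator is applied.
    """
    if scenario.censor_rate == 0:
        ests = []
        for tree in (scenario.tree_a, scenario.tree_b):
            p_ex = analytic_event_probs(tree, scenario.tau)
            from .estimation import _state_order

            order = _state_order(tree, scheme)
            p_ex = p_ex[order]
            full = np.append(p_ex, max(0.0, 1.0 - p_ex.sum()))
            counts = rng.multinomial(scenario.n_per_arm, full / full.sum())[:-1]
            phat = counts / scenario.n_per_arm
            V_ex = (np.diag(phat) - np.outer(phat, phat)) / scenario.n_per_arm
            L = scheme.L
            ests.append(
                ArmEstimate(
                    probs=L @ phat,
                    cov=L @ V_ex @ L.T,
                    n=scenario.n_per_arm,
                    tau=scenario.tau,
                    scheme=scheme,
                )
            )
        return difference(ests[0], ests[1])
    recA = simulate_arm(
        scenario.tree_a, scenario.n_per_arm, scenario.tau, scenario.censor_rate,
        seed=rng, arm="A",
    )
    recB = simulate_arm(
        scenario.tree_b, scenario.n_per_arm, scenario.tau, scenario.censor_rate,
        seed=rng, arm="B",
    )
    estA = aalen_johansen_arm(recA, scenario.tree_a, scenario.tau, scheme)
    estB = aalen_johansen_arm(recB, scenario.tree_b, scenario.tau, scheme)
    return difference(estA, estB)


def coverage_study(
    scenario: ScenarioSpec,
    scheme: EventTypeScheme,
    cone: Cone,
    methods=("chibar", "scheffe", "unadjusted"),
    reps: int = 10_000,
    grid_points: int = 1000,
    seed=None,
) -> CoverageResult:
    """Simultaneous Monte-Carlo coverage of nominal two-sided 95% intervals.

    Per replication, every grid weight's interval covers its true value iff
    the maximal squared standardized deviation over the grid is below the
    method's squared critical value; the chi-bar critical value is
    recomputed from each replication's estimated covariance.
    """
    rng = np.random.default_rng(seed)
    grid = simplex_cone_grid(cone, grid_points)
    D_true = analytic_event_probs(
        scenario.tree_a, scenario.tau, scheme
    ) - analytic_event_probs(scenario.tree_b, scenario.tau, scheme)
    target = grid @ D_true

    K = scheme.K
    s95_eta = float(stats.chi2.ppf(0.95, K))
    unadj_eta = float(stats.chi2.ppf(0.95, 1))

    covered = {m: 0 for m in methods}
    rel_eff = {m: [] for m in methods}
    dropped = 0
    used = 0
    for _ in range(reps):
        diff_est = _estimate_difference(scenario, scheme, rng)
        V = diff_est.V
        evals = np.linalg.eigvalsh(V)
        if evals[0] <= 1e-12 * max(evals[-1], 1e-300):
            dropped += 1
            continue
        used += 1
        dev = grid @ (diff_est.D - D_true)
        var = np.einsum("ij,jk,ik->i", grid, V, grid)
        z2max = float(np.max(dev * dev / var))
        for m in methods:
            if m == "chibar":
                w = chibar_weights_exact(cone, V)
                eta = chibar_quantile(0.975, w)
            elif m == "scheffe":
                eta = s95_eta
            else:
                eta = unadj_eta
            if z2max <= eta:
                covered[m] += 1
            rel_eff[m].append(np.sqrt(eta) / Z_UNADJ)
    if used == 0:
        raise RuntimeError("all replications degenerate")
    return CoverageResult(
        simultaneous_coverage={m: covered[m] / used for m in methods},
        relative_efficiencies={m: float(np.mean(rel_eff[m])) for m in methods},
        reps=used,
        dropped=dropped,
        grid_size=len(grid),
    )


# ---------------------------------------------------------------------------
# power and sample size

def _rejects(diff_est, w, method, cone, alpha):
    num = float(w @ diff_est.D)
    var = float(w @ diff_est.V @ w)
    if var <= 0:
        return False
    t2 = num * num / var
    if method == "unadjusted":
        return t2 > stats.chi2.ppf(1 - alpha, 1)
    if method == "scheffe":
        return t2 > stats.chi2.ppf(1 - alpha, len(w))
    wts = chibar_weights_exact(cone, diff_est.V)
    return t2 > chibar_quantile(1 - alpha / 2.0, wts)


def power_samplesize(
    tree_a: MultistateTree,
    tree_b: MultistateTree,
    scheme: EventTypeScheme,
    weight,
    method: str = "unadjusted",
    cone: Cone | None = None,
    spanning_weights=None,
    alpha: float = 0.05,
    target_power: float = 0.9,
    n_candidates=(500, 700, 900),
    reps: int = 1000,
    tau: float = 3.0,
    censor_rate: float = 0.05,
    seed=None,
):
    """Simulated power across candidate per-arm sample sizes.

    The test is either a single ``weight`` with the unadjusted / Scheffe /
    chi-bar critical value, or -- when ``spanning_weights`` is given -- a
    simultaneous detection across the convex cone spanned by those weight
    vectors (rejection required at every generator with the spanning cone's
    chi-bar critical value).  Returns ``(n_star, curve)`` where ``curve``
    is a list of (n, power) pairs and ``n_star`` is the smallest candidate
    reaching the target power (with linear interpolation when bracketed).
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    if list(n_candidates) != sorted(n_candidates):
        raise ValueError("n_candidates must be increasing")
    rng = np.random.default_rng(seed)
    if spanning_weights is not None:
        gens = [np.asarray(g, dtype=float) for g in spanning_weights]
        if cone is None:
            cone = spanned_cone(gens)
    curve = []
    for n in n_candidates:
        scenario = ScenarioSpec(tree_a, tree_b, n, tau, censor_rate)
        hits = 0
        for _ in range(reps):
            diff_est = _estimate_difference(scenario, scheme, rng)
            if spanning_weights is not None:
                ok = all(
                    _rejects(diff_est, g, "chibar", cone, alpha) for g in gens
                )
            else:
                ok = _rejects(
                    diff_est, np.asarray(weight, dtype=float), method, cone, alpha
                )
            hits += ok
        curve.append((n, hits / reps))
    n_star = None
    for (n0, p0), (n1, p1) in zip([(None, None)] + curve[:-1], curve):
        if p1 >= target_power:
            if n0 is not None and p0 is not None and p0 < target_power and p1 > p0:
                n_star = n0 + (target_power - p0) / (p1 - p0) * (n1 - n0)
            else:
                n_star = float(n1)
            break
    return n_star, curve


def spanned_cone(generators) -> Cone:
    """Constraint-form cone spanned by linearly independent generators.

    For a full set of K independent generators G (columns), w = G x with
    x >= 0, so the constraint matrix is G^{-1} (all rows inequalities).
    """
    G = np.column_stack([np.asarray(g, dtype=float) for g in generators])
    if G.shape[0] != G.shape[1]:
        raise ValueError(
            "spanned_cone requires exactly K linearly independent generators"
        )
    A_ineq = np.linalg.inv(G)
    from .chibarsq import cone_validate

    return cone_validate(None, A_ineq)
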