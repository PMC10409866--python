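"""Branched kinetic scheme of aa-tRNA selection as a continuous-time Markov chain.

States
------
UNBOUND                 no ternary complex on the ribosome (dark)
IB                      codon-independent initial binding complex
CR                      codon-reading (codon-recognition) complex
POST_GTP                past GTPase activation / GTP hydrolysis
ACCOMMODATED_CLASSICAL  aa-tRNA accommodated; classical A/A, A/P states
HYBRID_APstar           hybrid A/P* state
DROPPED                 aa-tRNA rejected after GTP hydrolysis (drop-off)

Transitions (wildtype): UNBOUND <-> IB (k1_app, k_rev1), IB -> CR (k2),
CR -> UNBOUND (k_rev2; the codon-reading decay observed as loss of FRET is
full dissociation — the sub-frame IB passage on the way out is not
resolvable), CR -> POST_GTP (k_gtp), POST_GTP -> ACCOMMODATED (composite of
k4 and k5, optionally as two sequential states or with a parallel slow
route), POST_GTP -> DROPPED (k7), ACCOMMODATED <-> HYBRID (k_hyb_fwd,
k_hyb_rev).  The GTPase-deficient protocol (H84A) zeroes k_gtp so that
nothing beyond CR is reachable; the hybrid_only protocol restricts the
chain to the two post-decoding states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .rates import RateSet

__all__ = [
    "SchemeGraph",
    "StateTrajectory",
    "build_scheme",
    "simulate_trajectory",
    "mean_first_passage",
    "hitting_probability",
    "absorption_probability",
    "ensemble_timecourse",
    "chain_cycles",
    "PROTOCOLS",
]

PROTOCOLS = ("wildtype", "H84A", "hybrid_only")

STATE_ORDER = (
    "UNBOUND",
    "IB",
    "CR",
    "POST_GTP",
    "ACC_SLOW",
    "ACCOMMODATED_CLASSICAL",
    "HYBRID_APstar",
    "DROPPED",
)


@dataclass
class SchemeGraph:
    """A CTMC over mechanistic states: generator matrix + bookkeeping."""

    states: tuple[str, ...]
    generator: np.ndarray
    protocol: str = "wildtype"
    label: str = ""

    def __post_init__(self) -> None:
        Q = np.asarray(self.generator, dtype=float)
        n = len(self.states)
        if Q.shape != (n, n):
            raise ValueError("generator shape does not match state list")
        off = Q - np.diag(np.diag(Q))
        if (off < -1e-12).any():
            raise ValueError("off-diagonal generator entries must be >= 0")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("generator rows must sum to zero")
        self.generator = Q

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None

    @property
    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.generator)

    @property
    def absorbing(self) -> tuple[str, ...]:
        return tuple(s for s, r in zip(self.states, self.exit_rates) if r <= 0)

    def reachable_from(self, start: str) -> set[str]:
        n = len(self.states)
        adj = self.generator > 0
        seen = {self.index(start)}
        frontier = [self.index(start)]
        while frontier:
            i = frontier.pop()
            for j in range(n):
                if adj[i, j] and j not in seen:
                    seen.add(j)
                    frontier.append(j)
        return {self.states[i] for i in seen}


@dataclass
class StateTrajectory:
    """Piecewise-constant mechanistic state path of one ribosome complex.

    ``segments`` is an ordered list of (state, t_enter, t_exit); segments
    are contiguous and the last one ends at ``horizon`` (or earlier only if
    the path was absorbed and the absorbing tail spans the rest).
    """

    segments: list[tuple[str, float, float]]
    horizon: float
    seed: int | None = None
    rateset_label: str = ""

    def state_at(self, t: float) -> str:
        for state, t0, t1 in self.segments:
            if t0 <= t < t1:
                return state
        return self.segments[-1][0]

    def visited(self) -> list[str]:
        return [s for s, _, _ in self.segments]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["state", "t_enter", "t_exit"])


def build_scheme(
    rates: RateSet,
    protocol: str = "wildtype",
    two_step_accommodation: bool = False,
) -> SchemeGraph:
    """Assemble the generator matrix of the decoding scheme.

    ``two_step_accommodation`` keeps k4 and k5 as two sequential steps
    (POST_GTP -k4-> ACC_SLOW -k5-> ACCOMMODATED); otherwise the series
    composite rate is used.  A parallel slow accommodation route is enabled
    when the rate set carries nonzero ``k_slow``/``k5b``.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")

    if protocol == "hybrid_only":
        states = ("ACCOMMODATED_CLASSICAL", "HYBRID_APstar")
        Q = np.array(
            [
                [-rates.k_hyb_fwd, rates.k_hyb_fwd],
                [rates.k_hyb_rev, -rates.k_hyb_rev],
            ]
        )
        return SchemeGraph(states, Q, protocol=protocol, label=rates.label)

    k_gtp = 0.0 if protocol == "H84A" else rates.k_gtp

    slow_route = rates.k_slow > 0 and rates.k5b > 0
    use_intermediate = two_step_accommodation or slow_route

    states = ["UNBOUND", "IB", "CR"]
    if k_gtp > 0:
        states.append("POST_GTP")
        if use_intermediate:
            states.append("ACC_SLOW")
        states.append("ACCOMMODATED_CLASSICAL")
        states.append("HYBRID_APstar")
        states.append("DROPPED")
    states = tuple(states)

    n = len(states)
    Q = np.zeros((n, n))
    ix = {s: i for i, s in enumerate(states)}

    def link(a: str, b: str, rate: float) -> None:
        if rate > 0:
            Q[ix[a], ix[b]] += rate

    link("UNBOUND", "IB", rates.k1_app)
    link("IB", "UNBOUND", rates.k_rev1)
    link("IB", "CR", rates.k2)
    # codon-reading decay observed as direct loss of FRET (full dissociation)
    link("CR", "UNBOUND", rates.k_rev2)
    if k_gtp > 0:
        link("CR", "POST_GTP", k_gtp)
        if two_step_accommodation:
            link("POST_GTP", "ACC_SLOW", rates.k4)
            link("ACC_SLOW", "ACCOMMODATED_CLASSICAL", rates.k5)
        elif slow_route:
            link("POST_GTP", "ACCOMMODATED_CLASSICAL", rates.k_acc)
            link("POST_GTP", "ACC_SLOW", rates.k_slow)
            link("ACC_SLOW", "ACCOMMODATED_CLASSICAL", rates.k5b)
        else:
            link("POST_GTP", "ACCOMMODATED_CLASSICAL", rates.k_acc)
        link("POST_GTP", "DROPPED", rates.k7)
        link("ACCOMMODATED_CLASSICAL", "HYBRID_APstar", rates.k_hyb_fwd)
        link("HYBRID_APstar", "ACCOMMODATED_CLASSICAL", rates.k_hyb_rev)

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SchemeGraph(states, Q, protocol=protocol, label=rates.label)


def simulate_trajectory(
    scheme: SchemeGraph,
    horizon: float,
    seed: int | np.random.Generator,
    start: str | None = None,
) -> StateTrajectory:
    """Exact-stochastic (Gillespie) realization of the scheme.

    Exponential dwell in each state with rate = -Q[i, i]; the next state is
    drawn proportionally to the off-diagonal rates.  Reproducible given the
    seed.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = scheme.generator
    state = scheme.index(start) if start is not None else 0
    t = 0.0
    segments: list[tuple[str, float, float]] = []
    if horizon == 0:
        return StateTrajectory([(scheme.states[state], 0.0, 0.0)], 0.0,
                               rateset_label=scheme.label)
    while t < horizon:
        exit_rate = -Q[state, state]
        if exit_rate <= 0:  # absorbing: spans the rest of the window
            segments.append((scheme.states[state], t, horizon))
            break
        dwell = rng.exponential(1.0 / exit_rate)
        t_end = min(t + dwell, horizon)
        segments.append((scheme.states[state], t, t_end))
        if t + dwell >= horizon:
            break
        probs = Q[state].clip(min=0.0)
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = rng.choice(len(probs), p=probs)
        t = t_end
    return StateTrajectory(segments, horizon, rateset_label=scheme.label)


def _transient_partition(scheme: SchemeGraph, targets: set[str]):
    """Indices of target states vs the rest (treated as transient)."""
    tgt = {scheme.index(s) for s in targets}
    rest = [i for i in range(len(scheme.states)) if i not in tgt]
    return sorted(tgt), rest


def hitting_probability(scheme: SchemeGraph, targets) -> np.ndarray:
    """P(hit the target set eventually) from each state.

    Solves the standard linear system for hitting probabilities: h = 1 on
    the target set, Q h = 0 on the complement, with h = 0 enforced on
    states from which the target set is unreachable.
    """
    targets = {targets} if isinstance(targets, str) else set(targets)
    tgt, rest = _transient_partition(scheme, targets)
    n = len(scheme.states)
    h = np.zeros(n)
    h[tgt] = 1.0
    reach = [i for i in rest if targets & scheme.reachable_from(scheme.states[i])]
    if reach:
        Q = scheme.generator
        A = Q[np.ix_(reach, reach)]
        r = Q[np.ix_(reach, tgt)].sum(axis=1)
        # Q h = 0 on non-target states; h = 0 on states that cannot reach
        h[reach] = np.linalg.solve(A, -r)
    return h


def mean_first_passage(
    scheme: SchemeGraph,
    start: str,
    targets,
    conditional: bool = True,
) -> float:
    """Expected time to first reach the target set from ``start``.

    With competing absorption (drop-off), the unconditional mean is
    infinite whenever the target can be missed; the default therefore
    returns the mean conditioned on actually hitting the target
    (E[T * 1{hit}] / P(hit)).  Unreachable targets raise.
    """
    targets = {targets} if isinstance(targets, str) else set(targets)
    if not targets & scheme.reachable_from(start):
        raise ValueError(f"targets {sorted(targets)} unreachable from {start!r}")
    h = hitting_probability(scheme, targets)
    tgt, rest = _transient_partition(scheme, targets)
    Q = scheme.generator
    u = np.zeros(len(scheme.states))
    reach = [i for i in rest if targets & scheme.reachable_from(scheme.states[i])]
    if reach:
        A = Q[np.ix_(reach, reach)]
        # E[T 1{hit}] satisfies sum_j Q_ij u_j = -h_i on non-target states;
        # u = 0 on states that cannot reach the target
        u[reach] = np.linalg.solve(A, -h[reach])
    i = scheme.index(start)
    if not conditional:
        if h[i] < 1.0 - 1e-12:
            return float("inf")
        return float(u[i])
    if h[i] <= 0:
        raise ValueError("hitting probability is zero; conditional MFPT undefined")
    return float(u[i] / h[i])


def absorption_probability(scheme: SchemeGraph, absorbing_target: str, start: str | None = None) -> float:
    """Probability of ending in the given absorbing state (vs competitors).

    The target must be absorbing (no exit).  Because the accommodated and
    hybrid post-decoding states form a closed recurrent pair in the
    wildtype scheme, hitting either of them is permanent; use
    :func:`hitting_probability` directly for such closed-class questions.
    """
    if absorbing_target not in scheme.absorbing:
        raise ValueError(f"{absorbing_target!r} is not an absorbing state")
    start = start or scheme.states[0]
    h = hitting_probability(scheme, {absorbing_target})
    return float(h[scheme.index(start)])


def ensemble_timecourse(
    scheme: SchemeGraph,
    observable_states,
    t_grid,
    start: str | None = None,
) -> pd.DataFrame:
    """Deterministic occupancy of a state set over time.

    Matrix-exponential solution of dP/dt = P Q with all probability mass
    initially in ``start`` (default: the first state, UNBOUND).  Returns a
    DataFrame with columns (time, signal).
    """
    observable_states = (
        {observable_states} if isinstance(observable_states, str) else set(observable_states)
    )
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        return pd.DataFrame({"time": [], "signal": []})
    if (np.diff(t_grid) <= 0).any() or t_grid[0] < 0:
        raise ValueError("t_grid must be strictly increasing and start >= 0")
    i0 = scheme.index(start) if start is not None else 0
    obs = [scheme.index(s) for s in observable_states]
    Q = scheme.generator
    p0 = np.zeros(len(scheme.states))
    p0[i0] = 1.0
    sig = np.empty_like(t_grid)
    # step between grid points with expm of the increment (grid may be irregular)
    p = p0
    t_prev = 0.0
    for k, t in enumerate(t_grid):
        if t > t_prev:
            p = p @ expm(Q * (t - t_prev))
            t_prev = t
        sig[k] = p[obs].sum()
    return pd.DataFrame({"time": t_grid, "signal": sig})


def chain_cycles(
    ratesets: list[RateSet],
    final_hybrid: bool = True,
) -> SchemeGraph:
    """Concatenate decoding cycles: each cycle's accommodated state is the
    next cycle's unbound-equivalent.

    With no drop-off the conditional MFPT through the chain equals the sum
    of per-cycle MFPTs (series property of the strong Markov chain).
    Hybrid fluctuations are only attached to the last cycle (earlier
    cycles hand the ribosome on to the next round).  A single shared
    DROPPED sink collects drop-off from every cycle.
    """
    if not ratesets:
        raise ValueError("need at least one cycle")
    states: list[str] = []
    links: list[tuple[str, str, float]] = []
    any_drop = any(rs.k7 > 0 for rs in ratesets)
    prev_product = None
    n_cyc = len(ratesets)
    for c, rs in enumerate(ratesets):
        tag = f"_c{c + 1}" if n_cyc > 1 else ""
        unbound = prev_product if prev_product is not None else f"UNBOUND{tag}"
        ib, cr, pg = f"IB{tag}", f"CR{tag}", f"POST_GTP{tag}"
        acc = f"ACCOMMODATED_CLASSICAL{tag}"
        if prev_product is None:
            states.append(unbound)
        states += [ib, cr, pg, acc]
        links += [
            (unbound, ib, rs.k1_app),
            (ib, unbound, rs.k_rev1),
            (ib, cr, rs.k2),
            (cr, unbound, rs.k_rev2),
            (cr, pg, rs.k_gtp),
            (pg, acc, rs.k_acc),
        ]
        if rs.k7 > 0:
            links.append((pg, "DROPPED", rs.k7))
        last = c == n_cyc - 1
        if last and final_hybrid and rs.k_hyb_fwd > 0:
            hyb = f"HYBRID_APstar{tag}"
            states.append(hyb)
            links += [(acc, hyb, rs.k_hyb_fwd), (hyb, acc, rs.k_hyb_rev)]
        prev_product = acc
    if any_drop:
        states.append("DROPPED")
    n = len(states)
    ix = {s: i for i, s in enumerate(states)}
    Q = np.zeros((n, n))
    for a, b, rate in links:
        if rate > 0:
            Q[ix[a], ix[b]] += rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    label = "+".join(rs.label or f"cycle{c+1}" for c, rs in enumerate(ratesets))
    return SchemeGraph(tuple(states), Q, protocol="wildtype", label=label)
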