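"""The editing network as an explicit continuous-time Markov chain.

Fifteen labelled states, four of them absorbing (the editing outcomes
CTC / CTT / TTC / TTT).  Splitting probabilities are computed by an
exact first-step linear solve, and independently by Gillespie
simulation; the two serve as mutual oracles for the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import SingularModelError, ValidationError
from .params import RateSet

__all__ = [
    "STATE_LABELS",
    "ABSORBING_STATES",
    "N_STATES",
    "KineticNetwork",
    "SimulationResult",
    "build_editing_network",
    "splitting_probabilities",
    "simulate_gillespie",
    "network_to_dot",
    "network_to_edge_table",
]

N_STATES = 15

STATE_LABELS: dict[int, str] = {
    0: "free/unedited",
    1: "CTC (absorbing)",
    2: "Cas9 bound",
    3: "target engaged",
    4: "bystander engaged",
    5: "target edited, Cas9 bound",
    6: "bystander edited, Cas9 bound",
    7: "target edited, Cas9 off",
    8: "bystander edited, Cas9 off",
    9: "target edited, bystander engaged",
    10: "bystander edited, target engaged",
    11: "both edited, Cas9 bound",
    12: "TTT (absorbing)",
    13: "CTT (absorbing)",
    14: "TTC (absorbing)",
}

ABSORBING_STATES: dict[int, str] = {1: "CTC", 12: "TTT", 13: "CTT", 14: "TTC"}


@dataclass(frozen=True)
class KineticNetwork:
    """A labelled, directed, rate-weighted 15-state network."""

    edges: tuple[tuple[int, int, float], ...]
    states: Mapping[int, str] = field(default_factory=lambda: dict(STATE_LABELS))
    absorbing: Mapping[int, str] = field(default_factory=lambda: dict(ABSORBING_STATES))

    def __post_init__(self) -> None:
        if len(self.states) != N_STATES:
            raise ValidationError(f"expected {N_STATES} states, got {len(self.states)}")
        for src, dst, rate in self.edges:
            if src in self.absorbing:
                raise ValidationError(f"absorbing state {src} has an outgoing edge")
            if src not in self.states or dst not in self.states:
                raise ValidationError(f"edge ({src}, {dst}) references unknown state")
            if not np.isfinite(rate) or rate < 0:
                raise ValidationError(f"edge ({src}, {dst}) has invalid rate {rate!r}")

    @property
    def transient(self) -> tuple[int, ...]:
        return tuple(s for s in self.states if s not in self.absorbing)

    def rate_matrix(self) -> np.ndarray:
        """Dense matrix Q with Q[i, j] = rate of the i -> j transition."""
        q = np.zeros((N_STATES, N_STATES))
        for src, dst, rate in self.edges:
            q[src, dst] += rate
        return q


#: (source, target, rate-symbol) template of the editing network; the
#: rebinding edges carry m*u0 and are retained even when m == 0 so the
#: network shape is parameter-independent.
_EDGE_TEMPLATE: tuple[tuple[int, int, str], ...] = (
    (0, 2, "u0"),
    (0, 1, "u4"),
    (2, 0, "w0"),
    (2, 3, "u1"),
    (2, 4, "u2"),
    (3, 2, "w1"),
    (3, 5, "u3"),
    (4, 2, "w2"),
    (4, 6, "u3"),
    (5, 7, "w0"),
    (5, 9, "u2"),
    (7, 5, "m*u0"),
    (7, 13, "u4"),
    (9, 5, "w2"),
    (9, 11, "u3"),
    (6, 8, "w0"),
    (6, 10, "u1"),
    (8, 6, "m*u0"),
    (8, 14, "u4"),
    (10, 6, "w1"),
    (10, 11, "u3"),
    (11, 12, "w0"),
)


def build_editing_network(r: RateSet) -> KineticNetwork:
    """Instantiate the 15-state editing network for a rate set.

    The single exit of the both-edited state (11 -> TTT) carries w0
    (Cas9 release); having no competitor, its value does not affect any
    splitting probability.
    """
    symbols = {
        "u0": r.u0,
        "u1": r.u1,
        "u2": r.u2,
        "u3": r.u3,
        "u4": r.u4,
        "w0": r.w0,
        "w1": r.w1,
        "w2": r.w2,
        "m*u0": r.m * r.u0,
    }
    edges = tuple((src, dst, symbols[sym]) for src, dst, sym in _EDGE_TEMPLATE)
    return KineticNetwork(edges=edges)


def _reachable(net: KineticNetwork, start: int) -> set[int]:
    adj: dict[int, list[int]] = {}
    for src, dst, rate in net.edges:
        if rate > 0:
            adj.setdefault(src, []).append(dst)
    seen = {start}
    stack = [start]
    while stack:
        for nxt in adj.get(stack.pop(), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def splitting_probabilities(
    net: KineticNetwork, start: int = 0
) -> dict[str, float]:
    """Absorption probabilities per outcome label, by exact linear solve.

    Solves the first-step system ``h(i) = sum_j P(i -> j) h(j)`` over
    the transient states reachable from ``start``, for all absorbing
    outcomes at once.
    """
    if start in net.absorbing:
        raise ValidationError(f"start state {start} is absorbing")
    reachable = _reachable(net, start)
    transient = [s for s in net.transient if s in reachable]
    index = {s: k for k, s in enumerate(transient)}
    n = len(transient)
    absorbing = list(net.absorbing)

    q = net.rate_matrix()
    total = q.sum(axis=1)
    dead = [s for s in transient if total[s] <= 0.0]
    if dead:
        raise SingularModelError(
            f"transient state(s) {dead} are reachable but have zero total "
            "exit rate; absorption is not certain"
        )

    # (I - P) h = R with P the jump-chain restricted to transients and
    # R the one-step absorption probabilities.
    a = np.eye(n)
    rhs = np.zeros((n, len(absorbing)))
    for src, dst, rate in net.edges:
        if src not in index or rate == 0.0:
            continue
        prob = rate / total[src]
        if dst in index:
            a[index[src], index[dst]] -= prob
        elif dst in net.absorbing:
            rhs[index[src], absorbing.index(dst)] += prob
    try:
        h = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularModelError(f"first-step linear system is singular: {exc}") from exc

    probs = h[index[start]]
    if not np.all(np.isfinite(probs)) or abs(probs.sum() - 1.0) > 1e-9:
        raise SingularModelError(
            f"splitting probabilities sum to {probs.sum()!r}; degenerate network"
        )
    return {net.absorbing[s]: float(probs[k]) for k, s in enumerate(absorbing)}


@dataclass(frozen=True)
class SimulationResult:
    """Outcome counts of a batch of Gillespie trajectories."""

    counts: Mapping[str, int]
    n_trajectories: int
    seed: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_trajectories:
            raise ValidationError("outcome counts must sum to n_trajectories")

    @property
    def frequencies(self) -> dict[str, float]:
        if self.n_trajectories == 0:
            return {k: float("nan") for k in self.counts}
        return {k: v / self.n_trajectories for k, v in self.counts.items()}

    @property
    def standard_errors(self) -> dict[str, float]:
        """Binomial standard error of each outcome frequency."""
        n = self.n_trajectories
        if n == 0:
            return {k: float("nan") for k in self.counts}
        return {
            k: float(np.sqrt(f * (1.0 - f) / n)) for k, f in self.frequencies.items()
        }


def simulate_gillespie(
    net: KineticNetwork,
    n_traj: int,
    seed: int,
    start: int = 0,
    max_events: int = 1_000_000,
) -> SimulationResult:
    """Run ``n_traj`` trajectories to absorption.

    Standard Gillespie stepping: exponential waiting time at the total
    exit rate, next state chosen proportionally to edge rates.  One
    seeded generator per call; identical seeds give identical counts.
    """
    if n_traj < 0:
        raise ValidationError(f"n_traj must be >= 0, got {n_traj}")
    if start in net.absorbing:
        raise ValidationError(f"start state {start} is absorbing")
    rng = np.random.default_rng(seed)

    # Padded per-state jump tables (positive-rate edges only); all
    # trajectories are advanced synchronously so the per-event work is
    # vectorized over the still-active trajectories.
    outgoing: dict[int, list[tuple[int, float]]] = {s: [] for s in net.states}
    for src, dst, rate in net.edges:
        if rate > 0:
            outgoing[src].append((dst, rate))
    max_deg = max((len(v) for v in outgoing.values()), default=1)
    targets = np.zeros((N_STATES, max_deg), dtype=np.int64)
    cumprob = np.ones((N_STATES, max_deg))
    total_rate = np.full(N_STATES, np.nan)
    stuck = np.zeros(N_STATES, dtype=bool)
    for s in net.transient:
        out = outgoing[s]
        if not out:
            stuck[s] = True
            continue
        rates = np.array([rate for _, rate in out])
        total_rate[s] = rates.sum()
        cp = np.cumsum(rates) / rates.sum()
        cumprob[s, : len(out)] = cp
        cumprob[s, len(out):] = 1.0
        dsts = [dst for dst, _ in out]
        targets[s, : len(out)] = dsts
        targets[s, len(out):] = dsts[-1]

    counts = {label: 0 for label in net.absorbing.values()}
    absorbing_ids = np.array(sorted(net.absorbing))
    state = np.full(n_traj, start, dtype=np.int64)
    events = 0
    while state.size:
        if np.any(stuck[state]):
            bad = int(state[stuck[state]][0])
            raise SingularModelError(
                f"trajectory stuck in state {bad} (no positive exit rate)"
            )
        rng.exponential(1.0 / total_rate[state])  # waiting times (discarded)
        u = rng.random(state.size)
        choice = (u[:, None] > cumprob[state, :-1]).sum(axis=1) if max_deg > 1 else (
            np.zeros(state.size, dtype=np.int64)
        )
        state = targets[state, choice]
        done = np.isin(state, absorbing_ids)
        if done.any():
            for s, c in zip(*np.unique(state[done], return_counts=True)):
                counts[net.absorbing[int(s)]] += int(c)
            state = state[~done]
        events += 1
        if events > max_events:
            raise SingularModelError(
                f"trajectories exceeded {max_events} events; rates are "
                "likely degenerate (e.g. vanishing absorption rates)"
            )
    return SimulationResult(counts=counts, n_trajectories=n_traj, seed=seed)


def network_to_dot(net: KineticNetwork) -> str:
    """Render the network as GraphViz DOT."""
    lines = ["digraph editing_network {", "  rankdir=LR;"]
    for s, label in net.states.items():
        shape = "doublecircle" if s in net.absorbing else "circle"
        lines.append(f'  {s} [label="{s}: {label}", shape={shape}];')
    for src, dst, rate in net.edges:
        lines.append(f'  {src} -> {dst} [label="{rate:g}"];')
    lines.append("}")
    return "\n".join(lines)


def network_to_edge_table(net: KineticNetwork) -> "pandas.DataFrame":  # noqa: F821
    """Edge list as a DataFrame (source, target, rate, labels)."""
    import pandas as pd

    rows = [
        {
            "source": src,
            "target": dst,
            "rate": rate,
            "source_label": net.states[src],
            "target_label": net.states[dst],
        }
        for src, dst, rate in net.edges
    ]
    return pd.DataFrame(rows)
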