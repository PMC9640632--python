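"""Continuous-time Markov chain semantics of a pathway model.

A :class:`~metcheck.network_model.PathwayModel` plus a rate table induces a
CTMC: states are the reachable integer amount vectors, and each enabled
guarded command contributes a transition at its mass-action rate.  When
several commands map the same source to the same target their rates add
(race semantics); per-command provenance is kept so transition rewards can
still be attributed to individual reactions.

Transient analysis uses uniformization: the distribution at time ``t`` is a
Poisson(q·t)-weighted mixture of powers of the uniformized discrete chain
``P = I + Q/q`` with ``q`` at least the maximal exit rate.  Expected
instantaneous rewards, expected cumulative rewards on ``[0, t]`` and
time-bounded reachability probabilities are all computed from the same
recurrence; reachability makes the goal states absorbing first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import poisson

from .network_model import PathwayModel, compile_model

__all__ = [
    "CTMC",
    "EmbeddedDTMC",
    "RewardStructure",
    "TransientAmount",
    "CumulativeReward",
    "TimeBoundedReachability",
    "Query",
    "StateSpaceBoundError",
    "build_ctmc",
    "embed",
    "transient_distribution",
    "expected_amount",
    "cumulative_reward",
    "time_bounded_reachability",
    "step_bounded_reachability",
    "evaluate_query",
]

DEFAULT_POISSON_TOL = 1e-10


class StateSpaceBoundError(RuntimeError):
    """Reachable state space exceeded the configured bound.

    Reduce species caps (or raise ``max_states``) to make exhaustive
    enumeration feasible; simulation (:mod:`metcheck.stochastic_sim`)
    remains available for larger models.
    """


@dataclass
class CTMC:
    """Explicit-state CTMC with per-command transition provenance."""

    model: PathwayModel
    states: np.ndarray                       # (n_states, n_species) int16
    initial_indices: tuple[int, ...]
    rate_matrix: sp.csr_matrix               # off-diagonal rates, R(i,i) = 0
    exit_rates: np.ndarray                   # (n_states,)
    command_transitions: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    _index: dict[bytes, int] = field(repr=False, default_factory=dict)
    _labels: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def initial_index(self) -> int:
        return self.initial_indices[0]

    def state_tuple(self, i: int) -> tuple[int, ...]:
        return tuple(int(x) for x in self.states[i])

    def find_state(self, state: Sequence[int]) -> int:
        key = np.asarray(state, dtype=np.int16).tobytes()
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"state {tuple(state)} is not reachable") from None

    def add_label(
        self, name: str, predicate: Callable[[np.ndarray], np.ndarray]
    ) -> None:
        """Register an atomic proposition as a vectorized state predicate."""
        mask = np.asarray(predicate(self.states), dtype=bool)
        if mask.shape != (self.n_states,):
            raise ValueError("label predicate must return one boolean per state")
        self._labels[name] = mask

    def label_mask(self, name: str) -> np.ndarray:
        """Boolean mask of states satisfying a label.

        Built-in labels: ``<species>_saturated`` (amount equals the cap) and
        ``<species>_depleted`` (amount is zero).
        """
        if name in self._labels:
            return self._labels[name]
        return builtin_label_predicate(self.model, name)(self.states)

    def species_amounts(self, species: str) -> np.ndarray:
        return self.states[:, self.model.species_index(species)].astype(float)


def builtin_label_predicate(
    model: PathwayModel, name: str
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized predicate for the built-in saturation/depletion labels.

    ``<species>_saturated`` holds when the amount equals the species cap,
    ``<species>_depleted`` when it is zero.
    """
    for suffix, test in (
        ("_saturated", lambda col, cap: col == cap),
        ("_depleted", lambda col, cap: col == 0),
    ):
        if name.endswith(suffix):
            species = name[: -len(suffix)]
            if species in model.species_names:
                j = model.species_index(species)
                cap = model.get_species(species).max_amount
                return lambda states, j=j, cap=cap, test=test: test(
                    np.atleast_2d(states)[:, j], cap
                )
    raise KeyError(f"unknown label {name!r}")


@dataclass
class EmbeddedDTMC:
    """Jump chain of a CTMC: P(s,s') = R(s,s')/E(s), self-loop where E(s)=0."""

    states: np.ndarray
    initial_indices: tuple[int, ...]
    P: sp.csr_matrix
    exit_rates: np.ndarray


@dataclass(frozen=True)
class RewardStructure:
    """State and/or transition rewards.

    ``state_rewards`` maps species names to coefficients: the reward accrued
    per unit time in a state is the weighted sum of amounts.  ``transition
    rewards`` map command ids to the reward earned each time that command
    fires (1.0 to count reaction occurrences).
    """

    state_rewards: Mapping[str, float] = field(default_factory=dict)
    transition_rewards: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def count_command(cls, cmd_id: str) -> "RewardStructure":
        return cls(transition_rewards={cmd_id: 1.0})

    @classmethod
    def species_amount(cls, species: str) -> "RewardStructure":
        return cls(state_rewards={species: 1.0})


# --- query objects ---------------------------------------------------------


@dataclass(frozen=True)
class TransientAmount:
    """Expected amount of a species at one instant (R[species]=? [I=t])."""

    species: str
    t: float


@dataclass(frozen=True)
class CumulativeReward:
    """Expected reward accumulated on [0, t] (R[...]=? [C<=t])."""

    reward: RewardStructure
    t: float


@dataclass(frozen=True)
class TimeBoundedReachability:
    """Probability of hitting labeled states within t (P=? [true U<=t label])."""

    label: str
    t: float


Query = TransientAmount | CumulativeReward | TimeBoundedReachability


# ---------------------------------------------------------------------------
# State-space construction
# ---------------------------------------------------------------------------


def build_ctmc(
    model: PathwayModel,
    rates: Mapping[str, float],
    initial_states: Sequence[Sequence[int]] | None = None,
    max_states: int = 1_000_000,
) -> CTMC:
    """Enumerate the reachable CTMC by breadth-first closure.

    ``initial_states`` may list several start states (e.g. a nutrient grid);
    the union of their reachable sets is enumerated and every start state is
    recorded in ``initial_indices``.  Commands whose rate constant is zero
    generate no transitions and do not expand the space.
    """
    compiled = compile_model(model, rates)
    caps = model.caps
    n_species = len(model.species)
    if initial_states is None:
        initial_states = [model.initial_state()]
    init = np.asarray(initial_states, dtype=np.int16)
    if init.ndim != 2 or init.shape[1] != n_species:
        raise ValueError("initial states must be amount vectors over all species")
    if (init < 0).any() or (init > caps).any():
        raise ValueError("initial amounts must lie within [0, cap] per species")

    index: dict[bytes, int] = {}
    rows: list[np.ndarray] = []

    def intern(batch: np.ndarray) -> np.ndarray:
        out = np.empty(len(batch), dtype=np.int64)
        for i, row in enumerate(batch):
            key = row.tobytes()
            j = index.get(key)
            if j is None:
                j = len(rows)
                index[key] = j
                rows.append(row)
            out[i] = j
        return out

    initial_indices = tuple(int(i) for i in intern(init))
    trans: dict[str, list[list[np.ndarray]]] = {
        c.id: [[], [], []] for c in compiled
    }

    start = 0
    while start < len(rows):
        if len(rows) > max_states:
            raise StateSpaceBoundError(
                f"more than {max_states} reachable states; reduce species caps"
            )
        frontier = np.array(rows[start:], dtype=np.int16)
        frontier_idx = np.arange(start, len(rows), dtype=np.int64)
        start = len(rows)
        for c in compiled:
            mask = c.enabled_mask(frontier, caps)
            if not mask.any():
                continue
            src_rows = frontier[mask]
            src_idx = frontier_idx[mask]
            r = c.rates(src_rows)
            dst_rows = (src_rows + c.delta).astype(np.int16)
            dst_idx = intern(dst_rows)
            trans[c.id][0].append(src_idx)
            trans[c.id][1].append(dst_idx)
            trans[c.id][2].append(r)

    states = np.array(rows, dtype=np.int16)
    n = len(states)
    command_transitions = {
        cid: (
            np.concatenate(s) if s else np.empty(0, dtype=np.int64),
            np.concatenate(d) if d else np.empty(0, dtype=np.int64),
            np.concatenate(r) if r else np.empty(0, dtype=float),
        )
        for cid, (s, d, r) in trans.items()
    }

    srcs = [v[0] for v in command_transitions.values()]
    dsts = [v[1] for v in command_transitions.values()]
    vals = [v[2] for v in command_transitions.values()]
    if srcs and sum(len(s) for s in srcs):
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
        val = np.concatenate(vals)
        off = src != dst  # self-loops are semantically inert in a CTMC
        R = sp.coo_matrix((val[off], (src[off], dst[off])), shape=(n, n)).tocsr()
        R.sum_duplicates()
    else:
        R = sp.csr_matrix((n, n))
    exit_rates = np.asarray(R.sum(axis=1)).ravel()
    return CTMC(
        model=model,
        states=states,
        initial_indices=initial_indices,
        rate_matrix=R,
        exit_rates=exit_rates,
        command_transitions=command_transitions,
        _index=index,
    )


def embed(ctmc: CTMC) -> EmbeddedDTMC:
    """Embedded jump chain: divide each row of R by its exit rate.

    States with exit rate zero become self-loops with probability one.
    """
    R = ctmc.rate_matrix.tocsr(copy=True)
    E = ctmc.exit_rates
    n = ctmc.n_states
    nonzero = E > 0
    inv = np.zeros_like(E)
    inv[nonzero] = 1.0 / E[nonzero]
    P = sp.diags(inv) @ R
    if (~nonzero).any():
        absorbing = np.flatnonzero(~nonzero)
        P = P + sp.coo_matrix(
            (np.ones(absorbing.size), (absorbing, absorbing)), shape=(n, n)
        )
    return EmbeddedDTMC(
        states=ctmc.states,
        initial_indices=ctmc.initial_indices,
        P=P.tocsr(),
        exit_rates=E,
    )


# ---------------------------------------------------------------------------
# Uniformization
# ---------------------------------------------------------------------------


def _uniformized(
    R: sp.csr_matrix, exit_rates: np.ndarray, q: float | None = None
) -> tuple[sp.csr_matrix, float]:
    """Uniformized DTMC P = I + Q/q (rows sum to one)."""
    if q is None:
        q = float(exit_rates.max(initial=0.0))
    if q <= 0.0:
        n = R.shape[0]
        return sp.identity(n, format="csr"), 0.0
    P = R / q + sp.diags(1.0 - exit_rates / q)
    return P.tocsr(), q


def _poisson_terms(lam: float, tol: float) -> int:
    """Right truncation point K with Poisson tail mass below tol."""
    if lam <= 0.0:
        return 0
    return int(poisson.isf(tol, lam)) + 1


def _mix_backward(
    R: sp.csr_matrix,
    exit_rates: np.ndarray,
    r: np.ndarray,
    ts: np.ndarray,
    weight: str,
    tol: float,
) -> np.ndarray:
    """Poisson-weighted mixture of P^k r, evaluated at every state.

    weight='pmf' yields E[r(X_t) | X_0 = s] per state s; weight='sf' yields
    the time integral ∫_0^t E[r(X_u)] du (weights sf(k; qt)/q).
    """
    ts = np.asarray(ts, dtype=float)
    P, q = _uniformized(R, exit_rates)
    if q == 0.0:
        base = np.asarray(r, dtype=float)
        if weight == "pmf":
            return np.tile(base, (ts.size, 1))
        return ts[:, None] * base[None, :]
    lam_max = q * float(ts.max(initial=0.0))
    K = _poisson_terms(lam_max, tol) + (10 if weight == "sf" else 0)
    ks = np.arange(K + 1)
    lam = q * ts[:, None]
    if weight == "pmf":
        W = poisson.pmf(ks[None, :], lam)
    elif weight == "sf":
        W = poisson.sf(ks[None, :], lam) / q
    else:  # pragma: no cover
        raise ValueError(weight)
    out = np.zeros((ts.size, R.shape[0]))
    u = np.asarray(r, dtype=float).copy()
    for k in ks:
        w = W[:, k]
        if (w > 1e-18).any():
            out += w[:, None] * u[None, :]
        if k < K:
            u = P @ u
    return out


def _as_time_grid(t) -> tuple[np.ndarray, bool]:
    scalar = np.ndim(t) == 0
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if (ts < 0).any():
        raise ValueError("time bounds must be non-negative")
    return ts, scalar


def transient_distribution(
    ctmc: CTMC,
    t,
    tol: float = DEFAULT_POISSON_TOL,
    initial: int | None = None,
) -> np.ndarray:
    """State distribution at time(s) ``t`` starting from the initial state.

    Returns a vector over states for scalar ``t``, else a (len(t), n_states)
    array.  The result sums to one up to the Poisson truncation tolerance.
    """
    ts, scalar = _as_time_grid(t)
    i0 = ctmc.initial_index if initial is None else initial
    P, q = _uniformized(ctmc.rate_matrix, ctmc.exit_rates)
    v0 = np.zeros(ctmc.n_states)
    v0[i0] = 1.0
    if q == 0.0:
        out = np.tile(v0, (ts.size, 1))
        return out[0] if scalar else out
    lam_max = q * float(ts.max(initial=0.0))
    K = _poisson_terms(lam_max, tol)
    ks = np.arange(K + 1)
    W = poisson.pmf(ks[None, :], q * ts[:, None])
    PT = P.T.tocsr()
    out = np.zeros((ts.size, ctmc.n_states))
    v = v0
    for k in ks:
        w = W[:, k]
        if (w > 1e-18).any():
            out += w[:, None] * v[None, :]
        if k < K:
            v = PT @ v
    return out[0] if scalar else out


def _state_reward_vector(ctmc: CTMC, reward: RewardStructure) -> np.ndarray:
    g = np.zeros(ctmc.n_states)
    for species, coef in reward.state_rewards.items():
        g += float(coef) * ctmc.species_amounts(species)
    return g


def _transition_reward_rate(ctmc: CTMC, reward: RewardStructure) -> np.ndarray:
    """Expected transition-reward accrual rate per state: sum rho_c * rate_c."""
    g = np.zeros(ctmc.n_states)
    known = {c.id for c in ctmc.model.commands}
    for cmd_id, rho in reward.transition_rewards.items():
        if cmd_id not in known:
            raise KeyError(f"unknown command id {cmd_id!r} in transition rewards")
        if cmd_id in ctmc.command_transitions:
            src, _, rate = ctmc.command_transitions[cmd_id]
            np.add.at(g, src, float(rho) * rate)
    return g


def expected_amount(
    ctmc: CTMC,
    species: str,
    t,
    tol: float = DEFAULT_POISSON_TOL,
    initial: int | None = None,
):
    """Expected amount of one species at time(s) t (instantaneous reward)."""
    r = ctmc.species_amounts(species)  # raises KeyError for unknown species
    ts, scalar = _as_time_grid(t)
    i0 = ctmc.initial_index if initial is None else initial
    vals = _mix_backward(ctmc.rate_matrix, ctmc.exit_rates, r, ts, "pmf", tol)[:, i0]
    return float(vals[0]) if scalar else vals


def cumulative_reward(
    ctmc: CTMC,
    reward: RewardStructure,
    t,
    tol: float = DEFAULT_POISSON_TOL,
    initial: int | None = None,
):
    """Expected reward accumulated over [0, t].

    State rewards accrue at their per-state value per unit time; transition
    rewards accrue at rho(c) times the command's current rate, which equals
    the expected number of firings weighted by rho.
    """
    g = _state_reward_vector(ctmc, reward) + _transition_reward_rate(ctmc, reward)
    ts, scalar = _as_time_grid(t)
    i0 = ctmc.initial_index if initial is None else initial
    vals = _mix_backward(ctmc.rate_matrix, ctmc.exit_rates, g, ts, "sf", tol)[:, i0]
    return float(vals[0]) if scalar else vals


def reachability_values(
    ctmc: CTMC,
    label: str,
    t,
    tol: float = DEFAULT_POISSON_TOL,
) -> np.ndarray:
    """Time-bounded reachability from *every* state, shape (len(t), n_states).

    Goal states are made absorbing; the value at state s is the probability
    that a path from s enters the goal set within the time bound.
    """
    mask = ctmc.label_mask(label)
    ts, _ = _as_time_grid(t)
    keep = sp.diags((~mask).astype(float))
    R_abs = keep @ ctmc.rate_matrix
    exit_abs = ctmc.exit_rates * (~mask)
    vals = _mix_backward(R_abs, exit_abs, mask.astype(float), ts, "pmf", tol)
    # paths already in the goal set stay counted (absorbing), so clip noise
    return np.clip(vals, 0.0, 1.0)


def time_bounded_reachability(
    ctmc: CTMC,
    label: str,
    t,
    tol: float = DEFAULT_POISSON_TOL,
    initial: int | None = None,
):
    """P=? [true U<=t label] from the initial state."""
    i0 = ctmc.initial_index if initial is None else initial
    ts, scalar = _as_time_grid(t)
    vals = reachability_values(ctmc, label, ts, tol)[:, i0]
    return float(vals[0]) if scalar else vals


def step_bounded_reachability(
    ctmc: CTMC,
    label: str,
    steps: int,
    initial: int | None = None,
) -> float:
    """Discrete variant on the embedded jump chain: hit the label within k jumps."""
    if steps < 0:
        raise ValueError("step bound must be non-negative")
    mask = ctmc.label_mask(label)
    dtmc = embed(ctmc)
    keep = sp.diags((~mask).astype(float))
    P_abs = (keep @ dtmc.P).tocsr()
    u = mask.astype(float)
    for _ in range(steps):
        u = mask + (~mask) * (P_abs @ u)
    i0 = ctmc.initial_index if initial is None else initial
    return float(np.clip(u[i0], 0.0, 1.0))


def evaluate_query(ctmc: CTMC, query: Query, tol: float = DEFAULT_POISSON_TOL):
    """Dispatch one of the three query classes against the engine."""
    if isinstance(query, TransientAmount):
        return expected_amount(ctmc, query.species, query.t, tol)
    if isinstance(query, CumulativeReward):
        return cumulative_reward(ctmc, query.reward, query.t, tol)
    if isinstance(query, TimeBoundedReachability):
        return time_bounded_reachability(ctmc, query.label, query.t, tol)
    raise TypeError(f"unsupported query type {type(query).__name__}")
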