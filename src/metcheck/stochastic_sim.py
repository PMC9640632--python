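"""Exact Gillespie (SSA) simulation of a pathway model.

Serves two purposes: an independent statistical oracle for the uniformization
engine, and the fallback analysis mode when the reachable state space is too
large to enumerate.  Each trajectory draws its waiting times from the
exponential race between enabled commands and is fully reproducible from its
seed; a batch of ``n_runs`` trajectories derives one child seed per run from
the master seed via ``numpy``'s ``SeedSequence.spawn`` splitting scheme, so
runs are statistically independent yet replayable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ctmc_engine import (
    CumulativeReward,
    Query,
    TimeBoundedReachability,
    TransientAmount,
    builtin_label_predicate,
)
from .network_model import PathwayModel, compile_model

__all__ = ["Trajectory", "ssa_trajectory", "estimate_query", "MAX_EVENTS"]

MAX_EVENTS = 10**6


@dataclass
class Trajectory:
    """One SSA path: piecewise-constant states with jump times.

    ``states[i]`` holds on ``[times[i-1], times[i])`` (with ``times[-1]``
    read as 0); ``command_ids[i]`` caused the jump at ``times[i]``.
    """

    times: np.ndarray                    # (n_events,) strictly increasing
    command_ids: tuple[str, ...]
    states: np.ndarray                   # (n_events + 1, n_species)
    t_max: float
    seed: object

    @property
    def events(self) -> list[tuple[float, str]]:
        return list(zip(self.times.tolist(), self.command_ids))

    def state_at(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("time must be non-negative")
        idx = int(np.searchsorted(self.times, t, side="right"))
        return self.states[idx]


def ssa_trajectory(
    model: PathwayModel,
    rates: Mapping[str, float],
    t_max: float,
    seed: int | np.random.SeedSequence,
    initial: Sequence[int] | None = None,
    max_events: int = MAX_EVENTS,
) -> Trajectory:
    """Simulate one exact SSA trajectory up to ``t_max`` or absorption.

    The waiting time in a state is Exponential(E(s)) with E(s) the total
    enabled rate; the firing command is chosen with probability rate/E(s).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    compiled = compile_model(model, rates)
    caps = model.caps
    if initial is None:
        initial = model.initial_state()
    state = np.asarray(initial, dtype=np.int16).copy()
    if state.shape != (len(model.species),):
        raise ValueError("initial state must cover all species")

    times: list[float] = []
    cmd_ids: list[str] = []
    states: list[np.ndarray] = [state.copy()]
    t = 0.0
    cmd_rates = np.zeros(len(compiled))
    batch = state[None, :]
    while True:
        if len(times) >= max_events:
            raise RuntimeError(
                f"trajectory exceeded {max_events} events; "
                "check the network for runaway loops"
            )
        for i, c in enumerate(compiled):
            if c.enabled_mask(batch, caps)[0]:
                cmd_rates[i] = c.rates(batch)[0]
            else:
                cmd_rates[i] = 0.0
        total = cmd_rates.sum()
        if total <= 0.0:
            break  # absorbing state
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        pick = rng.random() * total
        j = int(np.searchsorted(np.cumsum(cmd_rates), pick, side="right"))
        j = min(j, len(compiled) - 1)
        state = state + compiled[j].delta
        batch = state[None, :]
        times.append(t)
        cmd_ids.append(compiled[j].id)
        states.append(state.copy())

    return Trajectory(
        times=np.asarray(times, dtype=float),
        command_ids=tuple(cmd_ids),
        states=np.asarray(states, dtype=np.int16),
        t_max=float(t_max),
        seed=seed,
    )


def _trajectory_statistic(
    traj: Trajectory, query: Query, model: PathwayModel
) -> float:
    if isinstance(query, TransientAmount):
        j = model.species_index(query.species)
        return float(traj.state_at(query.t)[j])
    if isinstance(query, TimeBoundedReachability):
        pred = builtin_label_predicate(model, query.label)
        mask = np.asarray(pred(traj.states), dtype=bool)
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            return 0.0
        entry = 0.0 if hits[0] == 0 else float(traj.times[hits[0] - 1])
        return 1.0 if entry <= query.t else 0.0
    if isinstance(query, CumulativeReward):
        total = 0.0
        for rho_id, rho in query.reward.transition_rewards.items():
            fired = [
                1.0
                for tm, cid in zip(traj.times, traj.command_ids)
                if cid == rho_id and tm <= query.t
            ]
            total += float(rho) * sum(fired)
        if query.reward.state_rewards:
            # integrate the piecewise-constant state reward over [0, t]
            cuts = np.concatenate([[0.0], traj.times, [np.inf]])
            cuts = np.clip(cuts, 0.0, query.t)
            durations = np.diff(cuts)
            for species, coef in query.reward.state_rewards.items():
                amounts = traj.states[:, model.species_index(species)].astype(float)
                total += float(coef) * float((durations * amounts).sum())
        return total
    raise TypeError(f"unsupported query type {type(query).__name__}")


def estimate_query(
    model: PathwayModel,
    rates: Mapping[str, float],
    query: Query,
    n_runs: int,
    seed: int,
    initial: Sequence[int] | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of a query with its standard error.

    Child seeds are spawned from ``seed`` so the ``n_runs`` trajectories are
    independent; rerunning with the same arguments reproduces the estimate
    bit for bit.
    """
    if n_runs < 2:
        raise ValueError("need at least two runs for a standard error")
    t_max = float(query.t)
    if t_max <= 0.0:
        # degenerate bound: the statistic is determined by the initial state
        t_max = np.finfo(float).tiny
    children = np.random.SeedSequence(seed).spawn(n_runs)
    vals = np.empty(n_runs)
    for i, child in enumerate(children):
        traj = ssa_trajectory(model, rates, t_max, child, initial=initial)
        vals[i] = _trajectory_statistic(traj, query, model)
    est = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n_runs))
    return est, se


def trajectory_frame(traj: Trajectory, model: PathwayModel):
    """Tidy export: one row per epoch with time, species amounts, last command."""
    import pandas as pd

    times = np.concatenate([[0.0], traj.times])
    data = {"time": times}
    for j, name in enumerate(model.species_names):
        data[name] = traj.states[:, j]
    data["last_command"] = ("",) + traj.command_ids
    return pd.DataFrame(data)
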