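"""Guarded-command representation of a metabolic reaction network.

Species are discrete molecule counts with saturation caps; reactions are
guarded commands: the guard states when a reaction is possible (all
substrates present, no product saturated, plus any extra side conditions
such as the presence of mutant IDH), the rate follows mass-action kinetics
(rate constant times the product of substrate counts), and the update moves
stoichiometric amounts from substrates to products.

The module parses/serializes a plain-text reaction table and evaluates
guards, rates, and updates on integer states.  It is deliberately agnostic
about where rate constants come from: any mapping ``rate_key -> float``
works (see :mod:`metcheck.rate_instantiation`).
"""

from __future__ import annotations

import operator
import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Guard",
    "GuardedCommand",
    "PathwayModel",
    "NetworkParseError",
    "RateConfigurationError",
    "parse_network",
    "serialize_network",
    "load_default_network",
    "is_enabled",
    "mass_action_rate",
    "rate_constant",
    "apply_update",
    "CompiledCommand",
    "compile_model",
]

_GUARD_OPS = {
    ">": operator.gt,
    "<": operator.lt,
    ">=": operator.ge,
    "<=": operator.le,
    "=": operator.eq,
}


class NetworkParseError(ValueError):
    """Raised when a reaction-table document is malformed."""


class RateConfigurationError(KeyError):
    """Raised when a command's rate constant is missing from the rate table."""


@dataclass(frozen=True)
class Species:
    """A molecular species with a saturation cap.

    Amounts are interpreted on the fmol/cell scale used throughout the
    models; ``max_amount`` is the cap beyond which the species counts as
    saturated and any reaction producing more of it is disabled.
    """

    name: str
    initial_amount: int = 0
    max_amount: int = 5

    def __post_init__(self) -> None:
        if self.max_amount <= 0:
            raise ValueError(f"species {self.name}: max_amount must be positive")
        if not (0 <= self.initial_amount <= self.max_amount):
            raise ValueError(
                f"species {self.name}: initial amount {self.initial_amount} "
                f"outside [0, {self.max_amount}]"
            )


@dataclass(frozen=True)
class Guard:
    """Extra side condition of the form ``species <op> constant``."""

    species: str
    op: str
    value: int

    def __post_init__(self) -> None:
        if self.op not in _GUARD_OPS:
            raise ValueError(f"unknown guard operator {self.op!r}")

    def holds(self, amount: int) -> bool:
        return bool(_GUARD_OPS[self.op](amount, self.value))

    def __str__(self) -> str:
        return f"{self.species} {self.op} {self.value}"


@dataclass(frozen=True)
class GuardedCommand:
    """One reaction: ``substrates -> products`` at ``rate_keys`` kinetics.

    The implicit guard requires every substrate amount to be at least its
    stoichiometric count and every product to sit at least its count below
    the cap; ``extra_guards`` are conjoined on top.  ``rate_keys`` usually
    holds a single key; synchronized (label-composed) commands multiply the
    constants of all their keys.
    """

    id: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_keys: tuple[str, ...]
    extra_guards: tuple[Guard, ...] = ()
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.rate_keys:
            raise ValueError(f"command {self.id}: needs at least one rate key")
        for name, count in (*self.substrates, *self.products):
            if count < 1:
                raise ValueError(
                    f"command {self.id}: stoichiometric count for {name} must be >= 1"
                )

    @property
    def rate_key(self) -> str:
        if len(self.rate_keys) != 1:
            raise ValueError(f"command {self.id} is synchronized; use rate_keys")
        return self.rate_keys[0]


@dataclass(frozen=True)
class PathwayModel:
    """A validated set of species plus guarded commands."""

    species: tuple[Species, ...]
    commands: tuple[GuardedCommand, ...]

    def __post_init__(self) -> None:
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NetworkParseError(f"duplicate species: {', '.join(dup)}")
        if not self.commands:
            raise NetworkParseError("model has no commands")
        ids = [c.id for c in self.commands]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkParseError(f"duplicate command id: {', '.join(dup)}")
        known = set(names)
        for cmd in self.commands:
            for name, _ in (*cmd.substrates, *cmd.products):
                if name not in known:
                    raise NetworkParseError(
                        f"command {cmd.id}: unknown species {name!r}"
                    )
            for g in cmd.extra_guards:
                if g.species not in known:
                    raise NetworkParseError(
                        f"command {cmd.id}: unknown species {g.species!r} in guard"
                    )

    # -- indexing helpers -------------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def get_species(self, name: str) -> Species:
        return self.species[self.species_index(name)]

    @property
    def caps(self) -> np.ndarray:
        return np.array([sp.max_amount for sp in self.species], dtype=np.int64)

    def initial_state(self) -> tuple[int, ...]:
        return tuple(sp.initial_amount for sp in self.species)

    def command(self, cmd_id: str) -> GuardedCommand:
        for cmd in self.commands:
            if cmd.id == cmd_id:
                return cmd
        raise KeyError(f"unknown command {cmd_id!r}")

    def with_initial_amounts(self, amounts: Mapping[str, int]) -> "PathwayModel":
        """Return a copy with some species' initial amounts replaced."""
        unknown = set(amounts) - set(self.species_names)
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        new_species = tuple(
            replace(sp, initial_amount=amounts.get(sp.name, sp.initial_amount))
            for sp in self.species
        )
        return PathwayModel(new_species, self.commands)

    def with_caps(self, caps: Mapping[str, int]) -> "PathwayModel":
        """Return a copy with some species' saturation caps replaced."""
        unknown = set(caps) - set(self.species_names)
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        new_species = tuple(
            replace(
                sp,
                max_amount=caps.get(sp.name, sp.max_amount),
                initial_amount=min(sp.initial_amount, caps.get(sp.name, sp.max_amount)),
            )
            for sp in self.species
        )
        return PathwayModel(new_species, self.commands)


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

_SPECIES_RE = re.compile(
    r"^species\s+(?P<name>\S+)\s+init\s*=\s*(?P<init>\d+)\s+max\s*=\s*(?P<max>\d+)$"
)
_TERM_RE = re.compile(r"^(?:(\d+)\s*\*\s*)?(\S+)$")
_GUARD_RE = re.compile(r"^(\S+)\s*(>=|<=|>|<|=)\s*(-?\d+)$")


def _parse_side(text: str, lineno: int) -> tuple[tuple[str, int], ...]:
    terms = []
    for raw in text.split("+"):
        raw = raw.strip()
        if not raw:
            raise NetworkParseError(f"line {lineno}: empty term in reaction side")
        m = _TERM_RE.match(raw)
        if not m:
            raise NetworkParseError(f"line {lineno}: cannot parse term {raw!r}")
        count = int(m.group(1)) if m.group(1) else 1
        terms.append((m.group(2), count))
    return tuple(terms)


def _parse_command_line(line: str, lineno: int) -> GuardedCommand:
    label = None
    if line.startswith("["):
        close = line.index("]")
        label = line[1:close].strip() or None
        line = line[close + 1:].strip()
    if ":" not in line:
        raise NetworkParseError(f"line {lineno}: missing ':' after command id")
    cmd_id, rest = line.split(":", 1)
    cmd_id = cmd_id.strip()
    guards: tuple[Guard, ...] = ()
    if "|" in rest:
        rest, guard_text = rest.split("|", 1)
        parsed = []
        for g in guard_text.split(","):
            m = _GUARD_RE.match(g.strip())
            if not m:
                raise NetworkParseError(f"line {lineno}: cannot parse guard {g.strip()!r}")
            parsed.append(Guard(m.group(1), m.group(2), int(m.group(3))))
        guards = tuple(parsed)
    if "@" not in rest:
        raise NetworkParseError(f"line {lineno}: missing '@ rate_key'")
    reaction, rate_key = rest.rsplit("@", 1)
    rate_key = rate_key.strip()
    if not rate_key:
        raise NetworkParseError(f"line {lineno}: empty rate key")
    if "->" not in reaction:
        raise NetworkParseError(f"line {lineno}: missing '->'")
    lhs, rhs = reaction.split("->", 1)
    return GuardedCommand(
        id=cmd_id,
        substrates=_parse_side(lhs, lineno),
        products=_parse_side(rhs, lineno),
        rate_keys=(rate_key,),
        extra_guards=guards,
        label=label,
    )


def _compose_synchronized(commands: list[GuardedCommand]) -> list[GuardedCommand]:
    """Merge same-labeled commands into one joint command.

    Synchronization semantics: all guards must hold, the rate constants are
    multiplied (mass action then runs over the pooled substrates), and the
    updates happen simultaneously.
    """
    by_label: dict[str, list[GuardedCommand]] = {}
    order: list[GuardedCommand | str] = []
    for cmd in commands:
        if cmd.label is None:
            order.append(cmd)
        else:
            if cmd.label not in by_label:
                order.append(cmd.label)
            by_label.setdefault(cmd.label, []).append(cmd)
    out: list[GuardedCommand] = []
    for item in order:
        if isinstance(item, GuardedCommand):
            out.append(item)
            continue
        group = by_label[item]
        if len(group) == 1:
            out.append(group[0])
            continue
        subs: list[tuple[str, int]] = []
        prods: list[tuple[str, int]] = []
        keys: list[str] = []
        guards: list[Guard] = []
        for cmd in group:
            subs.extend(cmd.substrates)
            prods.extend(cmd.products)
            keys.extend(cmd.rate_keys)
            guards.extend(cmd.extra_guards)
        out.append(
            GuardedCommand(
                id="+".join(c.id for c in group),
                substrates=tuple(subs),
                products=tuple(prods),
                rate_keys=tuple(keys),
                extra_guards=tuple(dict.fromkeys(guards)),
                label=item,
            )
        )
    return out


def parse_network(text: str) -> PathwayModel:
    """Parse a reaction-table document into a :class:`PathwayModel`.

    Format (UTF-8 text, ``#`` starts a comment)::

        species NAME init=I max=M
        ID: n1*SubA + SubB -> m1*ProdC @ rate_key | SpeciesX > 0, SpeciesY < 2

    Commands sharing an optional leading ``[label]`` are composed into one
    synchronized command.
    """
    species: list[Species] = []
    commands: list[GuardedCommand] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("species"):
            m = _SPECIES_RE.match(line)
            if not m:
                raise NetworkParseError(f"line {lineno}: bad species line {line!r}")
            species.append(
                Species(m.group("name"), int(m.group("init")), int(m.group("max")))
            )
        else:
            commands.append(_parse_command_line(line, lineno))
    return PathwayModel(tuple(species), tuple(_compose_synchronized(commands)))


def _format_side(side: Iterable[tuple[str, int]]) -> str:
    return " + ".join(name if c == 1 else f"{c}*{name}" for name, c in side)


def serialize_network(model: PathwayModel) -> str:
    """Serialize a model to the reaction-table text format (round-trips)."""
    lines = []
    for sp in model.species:
        lines.append(f"species {sp.name} init={sp.initial_amount} max={sp.max_amount}")
    lines.append("")
    for cmd in model.commands:
        prefix = f"[{cmd.label}] " if cmd.label else ""
        line = (
            f"{prefix}{cmd.id}: {_format_side(cmd.substrates)} -> "
            f"{_format_side(cmd.products)} @ {'*'.join(cmd.rate_keys)}"
        )
        if cmd.extra_guards:
            line += " | " + ", ".join(str(g) for g in cmd.extra_guards)
        lines.append(line)
    return "\n".join(lines) + "\n"


def load_default_network() -> PathwayModel:
    """Load the packaged glycolysis + TCA network (see data/default_network.txt)."""
    text = (
        resources.files("metcheck.data").joinpath("default_network.txt").read_text()
    )
    return parse_network(text)


# ---------------------------------------------------------------------------
# Semantics on states
# ---------------------------------------------------------------------------


def _as_array(state: Sequence[int], model: PathwayModel) -> np.ndarray:
    arr = np.asarray(state, dtype=np.int64)
    if arr.shape != (len(model.species),):
        raise ValueError(
            f"state has {arr.shape} entries, model has {len(model.species)} species"
        )
    return arr


def is_enabled(cmd: GuardedCommand, state: Sequence[int], model: PathwayModel) -> bool:
    """True iff the implicit substrate/saturation guards and all extra guards hold."""
    arr = _as_array(state, model)
    idx = model.species_index
    for name, count in cmd.substrates:
        if arr[idx(name)] < count:
            return False
    for name, count in cmd.products:
        if arr[idx(name)] > model.get_species(name).max_amount - count:
            return False
    return all(g.holds(int(arr[idx(g.species)])) for g in cmd.extra_guards)


def rate_constant(cmd: GuardedCommand, rates: Mapping[str, float]) -> float:
    """Resolve a command's (possibly composite) rate constant."""
    k = 1.0
    for key in cmd.rate_keys:
        try:
            k *= float(rates[key])
        except (KeyError, TypeError):
            raise RateConfigurationError(
                f"command {cmd.id}: rate constant {key!r} missing from rate table"
            ) from None
    if k < 0:
        raise RateConfigurationError(
            f"command {cmd.id}: negative rate constant {k!r}"
        )
    return k


def mass_action_rate(
    cmd: GuardedCommand,
    state: Sequence[int],
    rates: Mapping[str, float],
    model: PathwayModel,
) -> float:
    """Mass-action rate: rate constant times the product of substrate amounts.

    Each substrate contributes ``amount ** stoichiometry``; a synchronized
    command multiplies the constants of all its rate keys.
    """
    arr = _as_array(state, model)
    rate = rate_constant(cmd, rates)
    for name, count in cmd.substrates:
        rate *= float(arr[model.species_index(name)]) ** count
    return rate


def apply_update(
    cmd: GuardedCommand, state: Sequence[int], model: PathwayModel
) -> tuple[int, ...]:
    """Fire a command: decrement substrates, increment products.

    The command must be enabled in ``state``; firing a disabled command is a
    contract violation and raises ``ValueError``.
    """
    if not is_enabled(cmd, state, model):
        raise ValueError(f"command {cmd.id} is not enabled in state {tuple(state)}")
    arr = _as_array(state, model).copy()
    for name, count in cmd.substrates:
        arr[model.species_index(name)] -= count
    for name, count in cmd.products:
        arr[model.species_index(name)] += count
    return tuple(int(x) for x in arr)


# ---------------------------------------------------------------------------
# Compiled (vectorized) form, shared by the CTMC builder and the SSA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompiledCommand:
    """Array form of one command for vectorized guard/rate evaluation."""

    id: str
    sub_idx: np.ndarray      # substrate species indices
    sub_cnt: np.ndarray      # substrate stoichiometric counts
    prod_idx: np.ndarray
    prod_cnt: np.ndarray
    guard_idx: np.ndarray    # extra-guard species indices
    guard_op: tuple[str, ...]
    guard_val: np.ndarray
    delta: np.ndarray        # net state change, full species vector
    k: float                 # resolved rate constant

    def enabled_mask(self, states: np.ndarray, caps: np.ndarray) -> np.ndarray:
        """Vectorized guard over an (m, n_species) batch of states."""
        ok = np.ones(len(states), dtype=bool)
        if self.sub_idx.size:
            ok &= (states[:, self.sub_idx] >= self.sub_cnt).all(axis=1)
        if self.prod_idx.size:
            ok &= (states[:, self.prod_idx] <= caps[self.prod_idx] - self.prod_cnt).all(
                axis=1
            )
        for i, op in enumerate(self.guard_op):
            ok &= _GUARD_OPS[op](states[:, self.guard_idx[i]], self.guard_val[i])
        return ok

    def rates(self, states: np.ndarray) -> np.ndarray:
        """Vectorized mass-action rate over an (m, n_species) batch."""
        r = np.full(len(states), self.k, dtype=float)
        for j, c in zip(self.sub_idx, self.sub_cnt):
            r *= states[:, j].astype(float) ** int(c)
        return r


def compile_model(
    model: PathwayModel, rates: Mapping[str, float]
) -> list[CompiledCommand]:
    """Compile commands to array form; commands with zero constant are dropped."""
    idx = model.species_index
    n = len(model.species)
    out = []
    for cmd in model.commands:
        k = rate_constant(cmd, rates)
        if k == 0.0:
            continue
        delta = np.zeros(n, dtype=np.int16)
        for name, count in cmd.substrates:
            delta[idx(name)] -= count
        for name, count in cmd.products:
            delta[idx(name)] += count
        out.append(
            CompiledCommand(
                id=cmd.id,
                sub_idx=np.array([idx(n_) for n_, _ in cmd.substrates], dtype=np.intp),
                sub_cnt=np.array([c for _, c in cmd.substrates], dtype=np.int16),
                prod_idx=np.array([idx(n_) for n_, _ in cmd.products], dtype=np.intp),
                prod_cnt=np.array([c for _, c in cmd.products], dtype=np.int16),
                guard_idx=np.array(
                    [idx(g.species) for g in cmd.extra_guards], dtype=np.intp
                ),
                guard_op=tuple(g.op for g in cmd.extra_guards),
                guard_val=np.array([g.value for g in cmd.extra_guards], dtype=np.int16),
                delta=delta,
                k=k,
            )
        )
    return out
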