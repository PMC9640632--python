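"""Guarded-command semantics: parsing, guards, mass action, updates."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metcheck.network_model import (
    NetworkParseError,
    RateConfigurationError,
    apply_update,
    is_enabled,
    load_default_network,
    mass_action_rate,
    parse_network,
    serialize_network,
)

TOY = """
species A init=2 max=3
species B init=1 max=2
species C init=0 max=3
species D init=0 max=2
U: A -> B @ kU
V: A + B -> C @ kV
W: C -> D @ kW | A < 3
X: 2*A -> D @ kX
"""


class TestParsing:
    def test_simple_line_parses_substrates_and_products(self):
        model = parse_network(
            "species Gluc init=5 max=5\nspecies G6P init=0 max=5\n"
            "R1: Gluc -> G6P @ k_R1\n"
        )
        (cmd,) = model.commands
        assert cmd.substrates == (("Gluc", 1),)
        assert cmd.products == (("G6P", 1),)
        assert cmd.rate_keys == ("k_R1",)

    def test_extra_guard_line(self):
        model = parse_network(
            "species aKG init=1 max=5\nspecies 2HG init=0 max=5\n"
            "species IDHmut init=1 max=1\n"
            "R13: aKG -> 2HG @ k_2HG | IDHmut > 0\n"
        )
        (cmd,) = model.commands
        (guard,) = cmd.extra_guards
        assert (guard.species, guard.op, guard.value) == ("IDHmut", ">", 0)

    def test_stoichiometric_counts(self):
        model = parse_network(TOY)
        assert model.command("X").substrates == (("A", 2),)

    def test_round_trip_identity(self):
        for text in (TOY, None):
            model = load_default_network() if text is None else parse_network(text)
            assert parse_network(serialize_network(model)) == model

    def test_default_network_reconstruction(self, default_model):
        ids = [c.id for c in default_model.commands]
        assert ids == [f"R{i}" for i in range(1, 14)]
        r13 = default_model.command("R13")
        assert r13.substrates == (("aKG", 1),)
        assert r13.products == (("2HG", 1),)
        (guard,) = r13.extra_guards
        assert (guard.species, guard.op, guard.value) == ("IDHmut", ">", 0)
        # bimolecular citrate synthase edge
        r7 = default_model.command("R7")
        assert set(r7.substrates) == {("ACoA", 1), ("Oac", 1)}

    @pytest.mark.parametrize(
        "text, message",
        [
            ("species A init=0 max=1\n", "no commands"),
            ("species A init=0 max=1\nR: A -> Z @ k\n", "unknown species"),
            (
                "species A init=1 max=1\nspecies B init=0 max=1\n"
                "R: A -> B @ k\nR: B -> A @ k\n",
                "duplicate command id",
            ),
            ("species A init=2 max=1\nR: A -> A @ k\n", "initial amount"),
            ("species A init=0 max=1\nR: A -> @ k\n", "empty term"),
        ],
    )
    def test_malformed_documents_raise(self, text, message):
        with pytest.raises((NetworkParseError, ValueError), match=message):
            parse_network(text)

    def test_synchronized_commands_compose(self):
        model = parse_network(
            "species A init=1 max=2\nspecies B init=1 max=2\n"
            "species C init=0 max=2\nspecies D init=0 max=2\n"
            "[s] R1: A -> C @ k1\n[s] R2: B -> D @ k2\n"
        )
        (cmd,) = model.commands
        assert cmd.rate_keys == ("k1", "k2")
        assert set(cmd.substrates) == {("A", 1), ("B", 1)}
        # joint rate = k1*k2*A*B and joint update moves both tokens
        assert mass_action_rate(cmd, (1, 1, 0, 0), {"k1": 2.0, "k2": 3.0}, model) == 6.0
        assert apply_update(cmd, (1, 1, 0, 0), model) == (0, 0, 1, 1)


class TestGuards:
    def test_enabled_with_substrate_and_headroom(self, default_model):
        state = default_model.initial_state()
        assert is_enabled(default_model.command("R1"), state, default_model)

    def test_all_zero_state_is_absorbing(self, default_model):
        zero = (0,) * len(default_model.species)
        assert not any(
            is_enabled(c, zero, default_model) for c in default_model.commands
        )

    def test_saturated_product_disables(self, default_model):
        state = dict.fromkeys(default_model.species_names, 0)
        state.update({"Gluc": 5, "G6P": 5})
        vec = tuple(state[n] for n in default_model.species_names)
        assert not is_enabled(default_model.command("R1"), vec, default_model)

    def test_mutant_guard_gates_2hg(self, default_model):
        state = dict.fromkeys(default_model.species_names, 0)
        state["aKG"] = 2
        vec = tuple(state[n] for n in default_model.species_names)
        assert not is_enabled(default_model.command("R13"), vec, default_model)
        state["IDHmut"] = 1
        vec = tuple(state[n] for n in default_model.species_names)
        assert is_enabled(default_model.command("R13"), vec, default_model)


class TestMassAction:
    def test_unimolecular_rate(self, default_model):
        state = dict.fromkeys(default_model.species_names, 0)
        state["Gluc"] = 5
        vec = tuple(state[n] for n in default_model.species_names)
        rate = mass_action_rate(
            default_model.command("R1"), vec, {"k_R1": 1.0}, default_model
        )
        assert rate == 5.0

    def test_zero_substrate_gives_zero_rate(self, default_model):
        zero = (0,) * len(default_model.species)
        r1 = default_model.command("R1")
        assert mass_action_rate(r1, zero, {"k_R1": 1.0}, default_model) == 0.0
        assert not is_enabled(r1, zero, default_model)

    def test_bimolecular_product_of_counts(self, default_model):
        state = dict.fromkeys(default_model.species_names, 0)
        state.update({"ACoA": 3, "Oac": 2})
        vec = tuple(state[n] for n in default_model.species_names)
        r7 = default_model.command("R7")
        # independent oracle: explicit product loop over substrate amounts
        expected = 2.0
        for name, count in r7.substrates:
            expected *= state[name] ** count
        assert expected == 12.0
        assert mass_action_rate(r7, vec, {"k_R7": 2.0}, default_model) == expected

    def test_missing_rate_key_raises(self, default_model):
        state = default_model.initial_state()
        with pytest.raises(RateConfigurationError, match="k_R1"):
            mass_action_rate(default_model.command("R1"), state, {}, default_model)


class TestUpdates:
    def test_glycolysis_first_step(self, default_model):
        state = dict.fromkeys(default_model.species_names, 0)
        state["Gluc"] = 5
        before = tuple(state[n] for n in default_model.species_names)
        after = apply_update(default_model.command("R1"), before, default_model)
        diff = {
            n: a - b
            for n, a, b in zip(default_model.species_names, after, before)
            if a != b
        }
        assert diff == {"Gluc": -1, "G6P": 1}

    def test_identity_multiset_is_identity(self):
        model = parse_network(
            "species A init=1 max=2\nR: A -> A @ k\n"
        )
        assert apply_update(model.command("R"), (1,), model) == (1,)

    def test_bimolecular_merge(self, default_model):
        state = dict.fromkeys(default_model.species_names, 0)
        state.update({"ACoA": 1, "Oac": 1})
        before = tuple(state[n] for n in default_model.species_names)
        after = apply_update(default_model.command("R7"), before, default_model)
        after_d = dict(zip(default_model.species_names, after))
        assert (after_d["ACoA"], after_d["Oac"], after_d["Cit"]) == (0, 0, 1)

    def test_disabled_command_is_contract_violation(self, default_model):
        zero = (0,) * len(default_model.species)
        with pytest.raises(ValueError, match="not enabled"):
            apply_update(default_model.command("R1"), zero, default_model)


class TestExhaustiveSmallModel:
    """Enumerate every state of the toy model (caps <= 3) and check invariants."""

    model = parse_network(TOY)

    def all_states(self):
        ranges = [range(sp.max_amount + 1) for sp in self.model.species]
        return itertools.product(*ranges)

    def test_enabled_implies_valid_update(self):
        caps = self.model.caps
        for state in self.all_states():
            for cmd in self.model.commands:
                if is_enabled(cmd, state, self.model):
                    after = np.array(apply_update(cmd, state, self.model))
                    assert (after >= 0).all() and (after <= caps).all()

    def test_molecule_count_change_equals_stoichiometry(self):
        for state in self.all_states():
            for cmd in self.model.commands:
                if not is_enabled(cmd, state, self.model):
                    continue
                after = apply_update(cmd, state, self.model)
                expected = sum(c for _, c in cmd.products) - sum(
                    c for _, c in cmd.substrates
                )
                assert sum(after) - sum(state) == expected


@settings(max_examples=200, derandomize=True, deadline=None)
@given(data=st.data())
def test_default_network_update_bounds(data):
    """Random states of the full network: enabled commands stay within caps."""
    model = load_default_network()
    state = tuple(
        data.draw(st.integers(0, sp.max_amount), label=sp.name)
        for sp in model.species
    )
    caps = model.caps
    for cmd in model.commands:
        if is_enabled(cmd, state, model):
            after = np.array(apply_update(cmd, state, model))
            assert (after >= 0).all() and (after <= caps).all()
            # unimolecular 1 -> 1 commands conserve the total molecule count
            if len(cmd.substrates) == len(cmd.products) == 1:
                assert sum(after) == sum(state)
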