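"""End-to-end phenotype experiments over the metabolic CTMC.

Reproduces the study designs of the analysis at the level of tidy tables:
time courses of expected species amounts per phenotype, nutrient sweeps
(varying one initial nutrient over a grid with the other fixed), and
lactate-saturation probability surfaces over the glucose x glutamine initial
grid.  Every experiment is a pure function of (network, rate tables,
grids), so rerunning with identical inputs produces byte-identical CSVs.

The mutant-IDH indicator species is switched on automatically for rate
tables whose neomorphic 2HG rate constant is positive; wild-type tables run
with the indicator at zero, which disables the guarded 2HG command.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ctmc_engine import (
    CTMC,
    CumulativeReward,
    Query,
    RewardStructure,
    TimeBoundedReachability,
    TransientAmount,
    build_ctmc,
    evaluate_query,
    reachability_values,
    transient_distribution,
)
from .network_model import PathwayModel
from .rate_instantiation import TWOHG_KEY, PhenotypeRateTable

__all__ = [
    "ExperimentSpec",
    "mutant_indicator",
    "run_timecourse",
    "run_nutrient_sweep",
    "run_saturation_surface",
    "run_experiments",
    "load_queries",
    "run_query_file",
    "export_prism",
    "write_tidy_csv",
]

CSV_FLOAT_FORMAT = "%.10g"

GLUCOSE = "Gluc"
GLUTAMINE = "Gln"
MUTANT_INDICATOR = "IDHmut"


def write_tidy_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV export used by all experiments."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def mutant_indicator(rates: Mapping[str, float]) -> int:
    """1 when the table carries positive neomorphic 2HG activity, else 0."""
    return 1 if float(rates.get(TWOHG_KEY, 0.0)) > 0 else 0


def _prepare(
    model: PathwayModel,
    rates: Mapping[str, float],
    nutrient_grid: Sequence[tuple[int, int]],
) -> tuple[CTMC, dict[tuple[int, int], int]]:
    """Build one CTMC whose state space covers all nutrient initializations."""
    if MUTANT_INDICATOR in model.species_names:
        model = model.with_initial_amounts(
            {MUTANT_INDICATOR: mutant_indicator(rates)}
        )
    initials = []
    for gluc, gln in nutrient_grid:
        m = model.with_initial_amounts({GLUCOSE: gluc, GLUTAMINE: gln})
        initials.append(m.initial_state())
    ctmc = build_ctmc(model, rates, initial_states=initials)
    index = {
        pair: ctmc.initial_indices[i] for i, pair in enumerate(nutrient_grid)
    }
    return ctmc, index


def _table_meta(rates: Mapping[str, float]) -> tuple[str, str]:
    phenotype = getattr(rates, "phenotype", "custom")
    condition = getattr(rates, "condition", "")
    return phenotype, condition


def run_timecourse(
    model: PathwayModel,
    tables: Iterable[PhenotypeRateTable],
    time_grid: Sequence[float],
    glucose: int | None = None,
    glutamine: int | None = None,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Expected amount of each species over a time grid, per phenotype.

    Nutrients start at the given amounts (default: at their saturation caps,
    i.e. the maximum quantity) and every other species at zero.
    """
    if glucose is None:
        glucose = model.get_species(GLUCOSE).max_amount
    if glutamine is None:
        glutamine = model.get_species(GLUTAMINE).max_amount
    ts = np.asarray(time_grid, dtype=float)
    rows = []
    for rates in tables:
        phenotype, condition = _table_meta(rates)
        ctmc, idx = _prepare(model, rates, [(glucose, glutamine)])
        dist = transient_distribution(ctmc, ts, initial=idx[(glucose, glutamine)])
        amounts = dist @ ctmc.states.astype(float)  # (T, n_species)
        names = species or ctmc.model.species_names
        for name in names:
            j = ctmc.model.species_index(name)
            for t, value in zip(ts, amounts[:, j]):
                rows.append(
                    {
                        "phenotype": phenotype,
                        "condition": condition,
                        "species": name,
                        "t": float(t),
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows)


def run_nutrient_sweep(
    model: PathwayModel,
    tables: Iterable[PhenotypeRateTable],
    t_eval: float,
    vary: str = GLUCOSE,
    grid: Sequence[int] | None = None,
    fixed_amount: int | None = None,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Expected amounts at a fixed time over a grid of one nutrient's start.

    ``vary`` is ``"Gluc"`` or ``"Gln"``; the other nutrient starts at
    ``fixed_amount`` (default: its saturation cap).  The default grid runs
    from 1 to the varied nutrient's cap.
    """
    if vary not in (GLUCOSE, GLUTAMINE):
        raise ValueError(f"vary must be {GLUCOSE!r} or {GLUTAMINE!r}")
    other = GLUTAMINE if vary == GLUCOSE else GLUCOSE
    if fixed_amount is None:
        fixed_amount = model.get_species(other).max_amount
    if grid is None:
        grid = tuple(range(1, model.get_species(vary).max_amount + 1))
    pairs = [
        (v, fixed_amount) if vary == GLUCOSE else (fixed_amount, v) for v in grid
    ]
    rows = []
    for rates in tables:
        phenotype, condition = _table_meta(rates)
        ctmc, idx = _prepare(model, rates, pairs)
        names = species or ctmc.model.species_names
        for v, pair in zip(grid, pairs):
            dist = transient_distribution(ctmc, float(t_eval), initial=idx[pair])
            amounts = dist @ ctmc.states.astype(float)
            for name in names:
                j = ctmc.model.species_index(name)
                rows.append(
                    {
                        "phenotype": phenotype,
                        "condition": condition,
                        "varied": vary,
                        "initial_amount": int(v),
                        "species": name,
                        "t": float(t_eval),
                        "value": float(amounts[j]),
                    }
                )
    return pd.DataFrame(rows)


def run_saturation_surface(
    model: PathwayModel,
    tables: Iterable[PhenotypeRateTable],
    time_grid: Sequence[float],
    glucose_grid: Sequence[int] | None = None,
    glutamine_grid: Sequence[int] | None = None,
    label: str = "Lac_saturated",
) -> pd.DataFrame:
    """Probability of reaching a labeled state over the nutrient grid.

    Grids default to 1..cap for each nutrient.  For each phenotype the whole
    glucose x glutamine grid shares one state space, so the time-bounded
    reachability of (by default) lactate saturation is computed for all
    starts in a single pass per phenotype.
    """
    if glucose_grid is None:
        glucose_grid = tuple(range(1, model.get_species(GLUCOSE).max_amount + 1))
    if glutamine_grid is None:
        glutamine_grid = tuple(range(1, model.get_species(GLUTAMINE).max_amount + 1))
    ts = np.asarray(time_grid, dtype=float)
    pairs = [(g, q) for g in glucose_grid for q in glutamine_grid]
    rows = []
    for rates in tables:
        phenotype, condition = _table_meta(rates)
        ctmc, idx = _prepare(model, rates, pairs)
        values = reachability_values(ctmc, label, ts)  # (T, n_states)
        for g, q in pairs:
            col = values[:, idx[(g, q)]]
            for t, p in zip(ts, col):
                rows.append(
                    {
                        "phenotype": phenotype,
                        "condition": condition,
                        "glucose": int(g),
                        "glutamine": int(q),
                        "t": float(t),
                        "probability": float(p),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExperimentSpec:
    """One reproducible experiment bundle.

    ``surface_time`` is the evaluation horizon of the saturation surface; it
    must be chosen explicitly because the analysis is reported in normalized
    time units with no canonical absolute scale.
    """

    model: PathwayModel
    tables: tuple[PhenotypeRateTable, ...]
    time_grid: tuple[float, ...] = tuple(float(t) for t in range(0, 16))
    glucose_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    glutamine_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    surface_time: float = 15.0
    sweep_time: float = 10.0
    label: str = "Lac_saturated"
    seed: int = 0
    outdir: Path = Path("results")
    plots: bool = True


def run_experiments(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    """Run time course, both sweeps and the saturation surface.

    Writes one tidy CSV per experiment under ``spec.outdir`` (plus PNG
    figures when ``spec.plots`` is set) and returns the frames.
    """
    out: dict[str, pd.DataFrame] = {}
    out["timecourse"] = run_timecourse(spec.model, spec.tables, spec.time_grid)
    out["sweep_glucose"] = run_nutrient_sweep(
        spec.model, spec.tables, spec.sweep_time, GLUCOSE, spec.glucose_grid
    )
    out["sweep_glutamine"] = run_nutrient_sweep(
        spec.model, spec.tables, spec.sweep_time, GLUTAMINE, spec.glutamine_grid
    )
    surface_grid = sorted(set(list(spec.time_grid) + [spec.surface_time]))
    out["surface"] = run_saturation_surface(
        spec.model,
        spec.tables,
        surface_grid,
        spec.glucose_grid,
        spec.glutamine_grid,
        spec.label,
    )
    for name, df in out.items():
        write_tidy_csv(df, Path(spec.outdir) / f"{name}.csv")
    if spec.plots:
        plot_timecourse(out["timecourse"], Path(spec.outdir) / "timecourse.png")
        plot_saturation_surface(
            out["surface"], Path(spec.outdir) / "surface.png", t=spec.surface_time
        )
    return out


# ---------------------------------------------------------------------------
# Plots (rendered from the tidy frames; raw model-checked values, no smoothing)
# ---------------------------------------------------------------------------


def plot_timecourse(df: pd.DataFrame, path: str | Path) -> None:
    """One panel per phenotype: expected amount of each species over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(df.groupby(["phenotype", "condition"]))
    fig, axes = plt.subplots(
        1, len(groups), figsize=(4.2 * len(groups), 3.4), squeeze=False, sharey=True
    )
    for ax, ((phenotype, condition), grp) in zip(axes[0], groups):
        for species, sub in grp.groupby("species"):
            sub = sub.sort_values("t")
            ax.plot(sub["t"], sub["value"], label=species, lw=1.2)
        ax.set_title(f"{phenotype} {condition}".strip())
        ax.set_xlabel("time (normalized units)")
    axes[0][0].set_ylabel("expected amount (fmol/cell)")
    axes[0][-1].legend(fontsize=6, ncol=2, frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_saturation_surface(
    df: pd.DataFrame, path: str | Path, t: float | None = None
) -> None:
    """3D surface of saturation probability over the nutrient grid.

    ``t`` selects the evaluation horizon when the frame holds a time grid
    (default: the largest time present).  Values are plotted raw.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if t is None:
        t = float(df["t"].max())
    sel = df[df["t"] == t]
    groups = list(sel.groupby(["phenotype", "condition"]))
    fig = plt.figure(figsize=(4.2 * len(groups), 3.6))
    for i, ((phenotype, condition), grp) in enumerate(groups, start=1):
        ax = fig.add_subplot(1, len(groups), i, projection="3d")
        piv = grp.pivot(index="glucose", columns="glutamine", values="probability")
        gluc, gln = np.meshgrid(piv.index, piv.columns, indexing="ij")
        ax.plot_surface(gluc, gln, piv.to_numpy(), cmap="viridis")
        ax.set_xlabel("initial glucose")
        ax.set_ylabel("initial glutamine")
        ax.set_zlabel("P(saturation)")
        ax.set_title(f"{phenotype} {condition} (t={t:g})".strip())
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Query files
# ---------------------------------------------------------------------------


def load_queries(path: str | Path) -> list[Query]:
    """Parse a YAML/JSON query file into engine query objects.

    Each entry is a mapping with ``type`` in {``transient``, ``cumulative``,
    ``reachability``}, a ``species``/``command``/``label`` field, and a
    ``time`` (scalar or list; lists expand to one query per time point).
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError("query file must contain a list of query mappings")
    queries: list[Query] = []
    for entry in entries:
        times = entry["time"]
        if np.ndim(times) == 0:
            times = [times]
        for t in times:
            kind = entry["type"]
            if kind == "transient":
                queries.append(TransientAmount(entry["species"], float(t)))
            elif kind == "cumulative":
                queries.append(
                    CumulativeReward(
                        RewardStructure.count_command(entry["command"]), float(t)
                    )
                )
            elif kind == "reachability":
                queries.append(TimeBoundedReachability(entry["label"], float(t)))
            else:
                raise ValueError(f"unknown query type {kind!r}")
    return queries


def run_query_file(
    model: PathwayModel,
    tables: Iterable[PhenotypeRateTable],
    queries: Sequence[Query],
) -> pd.DataFrame:
    """Evaluate queries per phenotype; tidy columns phenotype/condition/query/t/value."""
    rows = []
    for rates in tables:
        phenotype, condition = _table_meta(rates)
        ctmc, idx = _prepare(
            model,
            rates,
            [(model.get_species(GLUCOSE).initial_amount,
              model.get_species(GLUTAMINE).initial_amount)],
        )
        for query in queries:
            value = evaluate_query(ctmc, query)
            if isinstance(query, TransientAmount):
                desc = f"transient[{query.species}]"
            elif isinstance(query, CumulativeReward):
                keys = ",".join(query.reward.transition_rewards) or "state"
                desc = f"cumulative[{keys}]"
            else:
                desc = f"reachability[{query.label}]"
            rows.append(
                {
                    "phenotype": phenotype,
                    "condition": condition,
                    "query": desc,
                    "t": float(query.t),
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PRISM export (best-effort syntax compatibility, for external cross-checks)
# ---------------------------------------------------------------------------


def _prism_ident(name: str) -> str:
    ident = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in name)
    if ident[0].isdigit():
        ident = "x" + ident
    return ident


def export_prism(
    model: PathwayModel,
    rates: Mapping[str, float],
    model_path: str | Path,
    props_path: str | Path | None = None,
) -> None:
    """Write a ctmc-dialect model file (and optionally a property file).

    Commands are exported with their id as the action label so transition
    rewards can be attached per reaction.  Identifiers are sanitized (a
    leading digit gets an ``x`` prefix).
    """
    lines = ["ctmc", ""]
    for key in sorted({k for c in model.commands for k in c.rate_keys}):
        lines.append(f"const double {_prism_ident(key)} = {float(rates[key])!r};")
    lines.append("")
    lines.append("module metabolism")
    for sp in model.species:
        lines.append(
            f"  {_prism_ident(sp.name)} : [0..{sp.max_amount}] "
            f"init {sp.initial_amount};"
        )
    for cmd in model.commands:
        guard_parts = []
        for name, count in cmd.substrates:
            guard_parts.append(f"{_prism_ident(name)}>={count}")
        for name, count in cmd.products:
            cap = model.get_species(name).max_amount
            guard_parts.append(f"{_prism_ident(name)}<={cap - count}")
        for g in cmd.extra_guards:
            op = "=" if g.op == "=" else g.op
            guard_parts.append(f"{_prism_ident(g.species)}{op}{g.value}")
        rate_parts = [_prism_ident(k) for k in cmd.rate_keys]
        rate_parts += [
            _prism_ident(name) if count == 1 else f"pow({_prism_ident(name)},{count})"
            for name, count in cmd.substrates
        ]
        updates = []
        for name, count in cmd.substrates:
            updates.append(f"({_prism_ident(name)}'={_prism_ident(name)}-{count})")
        for name, count in cmd.products:
            updates.append(f"({_prism_ident(name)}'={_prism_ident(name)}+{count})")
        lines.append(
            f"  [{_prism_ident(cmd.id)}] {' & '.join(guard_parts)} -> "
            f"{'*'.join(rate_parts)} : {' & '.join(updates)};"
        )
    lines.append("endmodule")
    lines.append("")
    for sp in model.species:
        lines.append(f'rewards "{_prism_ident(sp.name)}"')
        lines.append(f"  true : {_prism_ident(sp.name)};")
        lines.append("endrewards")
    for cmd in model.commands:
        lines.append(f'rewards "{_prism_ident(cmd.id)}_count"')
        lines.append(f"  [{_prism_ident(cmd.id)}] true : 1;")
        lines.append("endrewards")
    Path(model_path).write_text("\n".join(lines) + "\n")

    if props_path is not None:
        lac_cap = (
            model.get_species("Lac").max_amount
            if "Lac" in model.species_names
            else 5
        )
        props = [
            f"P=? [ true U<=15 {_prism_ident('Lac')}={lac_cap} ]",
            'R{"Cit"}=? [ I=10 ]',
            'R{"R4_count"}=? [ C<=100 ]',
        ]
        Path(props_path).write_text("\n".join(props) + "\n")
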