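"""Turn measured metabolic fluxes and expression fold changes into rate tables.

Two routes produce the per-phenotype rate constants the CTMC needs:

* **MFA route** — raw fluxes (fmol/cell/hour) measured per reaction,
  phenotype and oxygen condition are first normalized to a reference flux
  (the first glycolysis reaction of the wild-type phenotype under normoxia),
  then lumped onto model reactions: a model reaction standing for a chain of
  measured reactions takes the *minimum* of the chain, the rate-limiting
  step.

* **Expression route** — the wild-type normoxia table doubles as the Warburg
  phenotype; rates for other cohorts are obtained by dividing each Warburg
  rate by the Warburg/cohort enzyme-expression fold change.  The neomorphic
  aKG→2HG rate has no wild-type counterpart and is copied from the measured
  mutant table instead of being rescaled.

Raw flux tables are tidy :class:`pandas.DataFrame` objects with columns
``reaction, phenotype, condition, flux``; chain maps are plain
``rate_key -> [measured reaction ids]`` mappings (shipped as editable YAML).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "RAW_FLUX_COLUMNS",
    "TWOHG_KEY",
    "PhenotypeRateTable",
    "normalize",
    "lump_chain",
    "derive_from_foldchange",
    "tables_from_raw",
    "load_chain_map",
    "load_default_chain_map",
    "read_rate_tables",
    "write_rate_tables",
]

RAW_FLUX_COLUMNS = ("reaction", "phenotype", "condition", "flux")

#: rate key of the neomorphic aKG -> 2HG conversion (mutant-only gain of function)
TWOHG_KEY = "k_2HG"


@dataclass(frozen=True)
class PhenotypeRateTable(Mapping):
    """Normalized rate constants for one phenotype/condition.

    Behaves as a read-only mapping ``rate_key -> float`` so it can be passed
    directly to the engine and the simulator.
    """

    phenotype: str
    condition: str
    rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.rates.items() if v < 0}
        if bad:
            raise ValueError(f"negative rate constants: {bad}")

    def __getitem__(self, key: str) -> float:
        return self.rates[key]

    def __iter__(self):
        return iter(self.rates)

    def __len__(self) -> int:
        return len(self.rates)

    def replace_rates(self, **updates: float) -> "PhenotypeRateTable":
        merged = dict(self.rates)
        merged.update(updates)
        return PhenotypeRateTable(self.phenotype, self.condition, merged)

    def covers(self, rate_keys: Iterable[str]) -> bool:
        return set(rate_keys) <= set(self.rates)


def _validate_raw(raw: pd.DataFrame) -> pd.DataFrame:
    missing = set(RAW_FLUX_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"raw flux table lacks columns: {sorted(missing)}")
    if (raw["flux"] < 0).any():
        raise ValueError("raw flux table contains negative fluxes")
    return raw


def normalize(
    raw: pd.DataFrame, reference: tuple[str, str, str]
) -> pd.DataFrame:
    """Divide every flux by the reference flux; the reference entry becomes 1.

    ``reference`` is a ``(phenotype, condition, reaction)`` triple, e.g. the
    first glycolytic reaction of the wild-type line under normoxia.
    """
    _validate_raw(raw)
    phenotype, condition, reaction = reference
    sel = (
        (raw["phenotype"] == phenotype)
        & (raw["condition"] == condition)
        & (raw["reaction"] == reaction)
    )
    if not sel.any():
        raise ValueError(f"reference entry {reference} missing from raw flux table")
    ref_flux = float(raw.loc[sel, "flux"].iloc[0])
    if ref_flux <= 0:
        raise ValueError(f"reference flux must be positive, got {ref_flux}")
    out = raw.copy()
    out["flux"] = out["flux"] / ref_flux
    return out


def lump_chain(
    raw: pd.DataFrame,
    chains: Mapping[str, list[str]],
    phenotype: str,
    condition: str,
) -> PhenotypeRateTable:
    """Build one phenotype's rate table by the rate-limiting (min) rule.

    Each model rate key takes the minimum flux over its chain of measured
    reactions; singleton chains pass through unchanged.  ``raw`` should
    already be normalized.
    """
    _validate_raw(raw)
    sub = raw[(raw["phenotype"] == phenotype) & (raw["condition"] == condition)]
    fluxes = sub.set_index("reaction")["flux"]
    rates: dict[str, float] = {}
    for key, members in chains.items():
        if not members:
            raise ValueError(f"chain for {key!r} is empty")
        missing = [m for m in members if m not in fluxes.index]
        if missing:
            raise KeyError(
                f"rate key {key!r}: measured reactions {missing} missing for "
                f"({phenotype}, {condition})"
            )
        rates[key] = float(min(fluxes[m] for m in members))
    return PhenotypeRateTable(phenotype, condition, rates)


def tables_from_raw(
    raw: pd.DataFrame,
    chains: Mapping[str, list[str]],
    reference: tuple[str, str, str],
) -> dict[tuple[str, str], PhenotypeRateTable]:
    """Normalize then lump every (phenotype, condition) pair present in ``raw``."""
    norm = normalize(raw, reference)
    pairs = norm[["phenotype", "condition"]].drop_duplicates().itertuples(index=False)
    return {
        (p, c): lump_chain(norm, chains, p, c) for p, c in pairs
    }


def derive_from_foldchange(
    warburg: PhenotypeRateTable,
    fold_changes: pd.DataFrame,
    target: str,
    mut_2hg_rate: float | None = None,
    twohg_key: str = TWOHG_KEY,
) -> PhenotypeRateTable:
    """Rescale the Warburg table to a target cohort by expression fold changes.

    ``fold_changes`` is an enzyme-level table with columns ``rate_key,
    comparison, fold_change`` where ``comparison`` equals ``"Warburg/<target>"``
    and the fold change is the Warburg-over-target expression ratio; each
    target rate is the Warburg rate divided by that ratio.  The neomorphic
    ``twohg_key`` is exempt: it is set to ``mut_2hg_rate`` when given (the
    measured mutant rate), else copied from the Warburg table.
    """
    comparison = f"Warburg/{target}"
    fc = fold_changes[fold_changes["comparison"] == comparison]
    if fc.empty:
        raise ValueError(f"no fold changes for comparison {comparison!r}")
    if (fc["fold_change"] <= 0).any():
        bad = fc.loc[fc["fold_change"] <= 0, "rate_key"].tolist()
        raise ValueError(f"non-positive fold changes for keys: {bad}")
    # several enzymes may rescale the same model reaction; average their ratios
    per_key = fc.groupby("rate_key")["fold_change"].mean()
    rates: dict[str, float] = {}
    for key, value in warburg.rates.items():
        if key == twohg_key:
            rates[key] = float(mut_2hg_rate) if mut_2hg_rate is not None else value
            continue
        if key not in per_key.index:
            raise KeyError(f"no {comparison} fold change for rate key {key!r}")
        rates[key] = value / float(per_key[key])
    return PhenotypeRateTable(target, warburg.condition, rates)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_chain_map(path: str | Path) -> dict[str, list[str]]:
    """Load a rate_key -> [measured reaction ids] chain map from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _check_chain_map(data)


def load_default_chain_map() -> dict[str, list[str]]:
    """The packaged chain map matching the default network's rate keys."""
    text = resources.files("metcheck.data").joinpath("default_chains.yaml").read_text()
    return _check_chain_map(yaml.safe_load(text))


def _check_chain_map(data) -> dict[str, list[str]]:
    if not isinstance(data, dict):
        raise ValueError("chain map must be a mapping of rate_key -> list")
    out = {}
    for key, members in data.items():
        if isinstance(members, str):
            members = [members]
        if not members:
            raise ValueError(f"chain for {key!r} is empty")
        out[str(key)] = [str(m) for m in members]
    return out


def write_rate_tables(
    tables: Iterable[PhenotypeRateTable], path: str | Path
) -> None:
    """Write tables to a tidy TSV (phenotype, condition, rate_key, value)."""
    rows = [
        {
            "phenotype": t.phenotype,
            "condition": t.condition,
            "rate_key": key,
            "value": value,
        }
        for t in tables
        for key, value in sorted(t.rates.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_rate_tables(path: str | Path) -> dict[tuple[str, str], PhenotypeRateTable]:
    """Read a tidy rates TSV back into tables keyed by (phenotype, condition)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], PhenotypeRateTable] = {}
    for (phenotype, condition), grp in df.groupby(["phenotype", "condition"]):
        out[(str(phenotype), str(condition))] = PhenotypeRateTable(
            str(phenotype),
            str(condition),
            dict(zip(grp["rate_key"], grp["value"].astype(float))),
        )
    return out
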