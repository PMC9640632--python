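"""Seed-deterministic generators for every input the pipeline consumes.

Two generators stand in for data that cannot be shipped:

* :func:`simulate_mfa_table` emulates the measured metabolic-flux table of
  the isogenic wild-type/mutant cell-line experiment (four phenotypes:
  IDHwt/IDHmut under normoxia/hypoxia).  The values are **synthetic
  stand-ins**, not the published measurements; only the qualitative
  structure is enforced: glycolytic fluxes rise under hypoxia, the
  mutant-hypoxia condition elevates glutaminolysis and oxidative-TCA flux,
  the malic-enzyme (TCA-to-pyruvate) route carries flux only there, the
  neomorphic 2HG flux exists only in the mutant, and the reference flux
  (first glycolysis step, wild type, normoxia) is 302 fmol/cell/hour.

* :func:`simulate_counts` emulates cohort-structured RNA-seq count matrices
  (Warburg / IDHmut / Normal cohorts) with negative-binomial noise and
  known, planted enzyme-level fold changes, so the expression stage can be
  tested for parameter recovery without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expression_foldchange import load_default_gene_map

__all__ = [
    "ExpressionSimSpec",
    "simulate_counts",
    "simulate_mfa_table",
    "MFA_REFERENCE",
    "MFA_REFERENCE_FLUX",
]

#: (phenotype, condition, reaction) whose flux anchors the normalization
MFA_REFERENCE = ("IDHwt", "normoxia", "HK")
MFA_REFERENCE_FLUX = 302.0  # fmol/cell/hour

# Baseline wild-type normoxia fluxes (fmol/cell/hour) for the measured
# reactions of the default chain map.  Synthetic stand-ins with a Warburg-like
# profile: strong glycolysis/lactate flux, slower TCA, no malic-enzyme or
# neomorphic flux in the wild type.
_BASE_FLUX = {
    "HK": 302.0,
    "G6PD": 45.0,
    "PGI": 290.0,
    "PFK": 280.0,
    "GAPD_PK": 270.0,
    "LDH": 240.0,
    "PDH": 60.0,
    "FASN": 25.0,
    "CS": 55.0,
    "ACO_IDH": 50.0,
    "AKGDH": 45.0,
    "SDH": 42.0,
    "FH": 40.0,
    "MDH": 38.0,
    "ME": 0.0,
    "GLS": 35.0,
    "GDH": 33.0,
    "IDHmut_neo": 0.0,
}

_GLYCOLYTIC = ("HK", "PGI", "PFK", "GAPD_PK", "LDH", "G6PD")
_GLUTAMINOLYTIC = ("GLS", "GDH")
_TCA_OXIDATIVE = ("AKGDH", "SDH", "FH", "MDH")


def simulate_mfa_table(seed: int = 0, jitter: float = 0.03) -> pd.DataFrame:
    """Synthetic four-phenotype raw flux table (stand-in for measured MFA).

    Returns a tidy frame with columns ``reaction, phenotype, condition,
    flux``.  A seeded multiplicative jitter (±``jitter``) is applied to every
    non-reference, non-zero entry; the enforced orderings use margins well
    above the jitter so they hold for every seed:

    * hypoxia glycolytic fluxes exceed their normoxia counterparts,
    * mutant-hypoxia glutaminolysis and oxidative-TCA fluxes exceed the
      wild-type-hypoxia ones,
    * the malic-enzyme route is active only under mutant hypoxia,
    * the neomorphic 2HG flux is non-zero only in the mutant.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for phenotype in ("IDHwt", "IDHmut"):
        for condition in ("normoxia", "hypoxia"):
            hyp = condition == "hypoxia"
            mut = phenotype == "IDHmut"
            for reaction, base in _BASE_FLUX.items():
                flux = base
                if hyp and reaction in _GLYCOLYTIC:
                    flux *= 1.6 if reaction != "LDH" else 1.8
                if hyp and reaction in ("PDH", "CS", "ACO_IDH"):
                    flux *= 0.6  # oxygen-limited entry into the TCA cycle
                if hyp and reaction in _TCA_OXIDATIVE:
                    flux *= 0.8
                if mut and hyp and reaction in _GLUTAMINOLYTIC:
                    flux *= 1.8
                if mut and hyp and reaction in _TCA_OXIDATIVE:
                    flux *= 1.5
                if reaction == "ME":
                    flux = 20.0 if (mut and hyp) else 0.0
                if reaction == "IDHmut_neo":
                    flux = (10.0 if hyp else 8.0) if mut else 0.0
                is_reference = (phenotype, condition, reaction) == MFA_REFERENCE
                if flux > 0 and not is_reference:
                    flux *= 1.0 + rng.uniform(-jitter, jitter)
                rows.append(
                    {
                        "reaction": reaction,
                        "phenotype": phenotype,
                        "condition": condition,
                        "flux": float(flux),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of the cohort-structured RNA-seq count simulation.

    Defaults mirror the cohort structure of the glioma expression analysis
    (140 Warburg-phenotype glioblastomas, 419 IDH-mutant lower-grade
    gliomas, 5 normal brain samples); tests use smaller cohorts.  Fold
    changes are planted per enzyme on the Warburg/Normal and Warburg/IDHmut
    comparisons; unmapped background genes stay at fold change 1.
    """

    n_genes: int = 200
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"Warburg": 140, "IDHmut": 419, "Normal": 5}
    )
    fc_warburg_vs_normal: Mapping[str, float] = field(default_factory=dict)
    fc_warburg_vs_idhmut: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 0.1
    base_mean: float = 200.0
    library_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(n < 1 for n in self.cohort_sizes.values()):
            raise ValueError("cohort sizes must be >= 1")
        for fcs in (self.fc_warburg_vs_normal, self.fc_warburg_vs_idhmut):
            if any(v <= 0 for v in fcs.values()):
                raise ValueError("planted fold changes must be positive")


def simulate_counts(
    spec: ExpressionSimSpec,
    gene_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples count matrix with planted fold changes.

    Returns ``(counts, metadata, truth)``: the integer count matrix, the
    sample -> cohort metadata, and the truth table with one row per enzyme
    and comparison recording the planted fold change.

    Counts for gene g in sample s are negative binomial with mean
    ``base_g * cohort_fc_g * lib_s`` and variance ``mu + dispersion * mu^2``.
    Genes of the same enzyme share the enzyme's planted fold change; the
    Normal cohort is the baseline, Warburg means are ``base * FC(W/N)`` and
    IDHmut means are ``base * FC(W/N) / FC(W/IDHmut)``.
    """
    if gene_map is None:
        gene_map = load_default_gene_map()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    mapped_genes = gene_map["gene"].tolist()
    n_background = spec.n_genes - len(mapped_genes)
    if n_background < 0:
        raise ValueError(
            f"n_genes={spec.n_genes} smaller than the {len(mapped_genes)} mapped genes"
        )
    genes = mapped_genes + [f"BG{i:04d}" for i in range(n_background)]

    enzyme_of = dict(zip(gene_map["gene"], gene_map["enzyme"]))
    fc_wn = {
        g: float(spec.fc_warburg_vs_normal.get(enzyme_of.get(g, ""), 1.0))
        for g in genes
    }
    fc_wm = {
        g: float(spec.fc_warburg_vs_idhmut.get(enzyme_of.get(g, ""), 1.0))
        for g in genes
    }

    base = spec.base_mean * rng.lognormal(mean=0.0, sigma=0.8, size=len(genes))
    cohort_mean = {
        "Normal": base,
        "Warburg": base * np.array([fc_wn[g] for g in genes]),
    }
    cohort_mean["IDHmut"] = cohort_mean["Warburg"] / np.array(
        [fc_wm[g] for g in genes]
    )

    samples, cohorts, columns = [], [], []
    lo, hi = spec.library_size_range
    n_nb = 1.0 / spec.dispersion
    for cohort, size in spec.cohort_sizes.items():
        if cohort not in cohort_mean:
            raise ValueError(f"unknown cohort {cohort!r}")
        for i in range(size):
            lib = rng.uniform(lo, hi)
            mu = np.maximum(cohort_mean[cohort] * lib, 1e-12)
            p = n_nb / (n_nb + mu)
            columns.append(rng.negative_binomial(n_nb, p))
            samples.append(f"{cohort}_{i:03d}")
            cohorts.append(cohort)

    counts = pd.DataFrame(
        np.column_stack(columns), index=genes, columns=samples
    ).astype(np.int64)
    counts.index.name = "gene"
    metadata = pd.DataFrame({"sample": samples, "cohort": cohorts})

    truth_rows = []
    enzymes = gene_map[["enzyme", "rate_key"]].drop_duplicates()
    for _, row in enzymes.iterrows():
        for comparison, planted in (
            ("Warburg/Normal", spec.fc_warburg_vs_normal),
            ("Warburg/IDHmut", spec.fc_warburg_vs_idhmut),
        ):
            truth_rows.append(
                {
                    "enzyme": row["enzyme"],
                    "rate_key": row["rate_key"],
                    "comparison": comparison,
                    "true_fold_change": float(planted.get(row["enzyme"], 1.0)),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return counts, metadata, truth
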