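"""Enzyme-level expression fold changes between patient cohorts.

Gene expression serves as a proxy for relative enzyme activity: the ratio of
a gene's expression between two cohorts approximates the ratio of the
corresponding reaction's rate.  Genes coding for isoenzymes (one reaction,
several gene products) are aggregated by averaging their fold changes to a
single enzyme-level value.

The gene-level estimator here is a deliberately simple, documented one:
counts are library-size normalized to counts-per-million with a small
pseudocount, and the fold change is the ratio of cohort mean CPMs.  It is a
plain-ratio estimator, not a differential-expression model; significance
testing is out of scope.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "load_gene_map",
    "load_default_gene_map",
    "aggregate_isoenzymes",
    "estimate_gene_foldchanges",
    "enzyme_foldchanges_from_counts",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
]

GENE_MAP_COLUMNS = ("gene", "enzyme", "rate_key")


def load_gene_map(path: str | Path) -> pd.DataFrame:
    """Read a gene -> enzyme -> rate_key map (TSV) and validate its shape."""
    df = pd.read_csv(path, sep="\t")
    return _check_gene_map(df)


def load_default_gene_map() -> pd.DataFrame:
    """Packaged gene map covering the default network's rescalable reactions."""
    text = resources.files("metcheck.data").joinpath("default_gene_map.tsv").read_text()
    return _check_gene_map(pd.read_csv(StringIO(text), sep="\t"))


def _check_gene_map(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(GENE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene map lacks columns: {sorted(missing)}")
    keys_per_enzyme = df.groupby("enzyme")["rate_key"].nunique()
    multi = keys_per_enzyme[keys_per_enzyme > 1]
    if not multi.empty:
        raise ValueError(
            f"enzymes mapped to more than one rate key: {multi.index.tolist()}"
        )
    return df


def aggregate_isoenzymes(
    gene_fc: pd.DataFrame,
    gene_map: pd.DataFrame,
    method: str = "arithmetic",
) -> pd.DataFrame:
    """Average gene-level fold changes up to the enzyme level.

    ``gene_fc`` has columns ``gene, comparison, fold_change``.  Every mapped
    gene must be present for every comparison; isoenzyme fold changes are
    combined with the arithmetic mean on the ratio scale (``method=
    "geometric"`` switches to the geometric mean).  Returns columns
    ``enzyme, rate_key, comparison, fold_change``.
    """
    _check_gene_map(gene_map)
    if method not in {"arithmetic", "geometric"}:
        raise ValueError(f"unknown aggregation method {method!r}")
    out_rows = []
    for comparison, grp in gene_fc.groupby("comparison"):
        fc = grp.set_index("gene")["fold_change"]
        missing = sorted(set(gene_map["gene"]) - set(fc.index))
        if missing:
            raise KeyError(
                f"comparison {comparison!r}: no fold change for genes {missing}"
            )
        merged = gene_map.assign(fold_change=gene_map["gene"].map(fc).astype(float))
        if method == "arithmetic":
            agg = merged.groupby(["enzyme", "rate_key"])["fold_change"].mean()
        else:
            agg = merged.groupby(["enzyme", "rate_key"])["fold_change"].apply(
                lambda x: float(np.exp(np.log(x).mean()))
            )
        for (enzyme, rate_key), value in agg.items():
            out_rows.append(
                {
                    "enzyme": enzyme,
                    "rate_key": rate_key,
                    "comparison": comparison,
                    "fold_change": float(value),
                }
            )
    return pd.DataFrame(out_rows)


def estimate_gene_foldchanges(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: tuple[str, str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene expression ratio cohortA/cohortB from a count matrix.

    ``counts`` is genes x samples (non-negative integers); ``metadata`` maps
    each sample to a cohort (columns ``sample, cohort``).  Counts are scaled
    to counts-per-million of their library with ``pseudocount`` added to
    every count, then the fold change is the ratio of cohort mean CPMs, so
    estimate(A, B) is exactly 1/estimate(B, A).
    """
    cohort_a, cohort_b = comparison
    meta = metadata.set_index("sample")["cohort"]
    unknown = set(counts.columns) - set(meta.index)
    if unknown:
        raise ValueError(f"samples without cohort label: {sorted(unknown)}")
    lib = counts.sum(axis=0).astype(float)
    groups = {}
    for cohort in comparison:
        cols = [s for s in counts.columns if meta[s] == cohort]
        if not cols:
            raise ValueError(f"cohort {cohort!r} has no samples")
        if (lib[cols] <= 0).any():
            raise ValueError(f"cohort {cohort!r} has samples with zero total counts")
        cpm = (counts[cols] + pseudocount).div(lib[cols], axis=1) * 1e6
        groups[cohort] = cpm.mean(axis=1)
    fc = groups[cohort_a] / groups[cohort_b]
    return pd.DataFrame(
        {
            "gene": counts.index,
            "comparison": f"{cohort_a}/{cohort_b}",
            "fold_change": fc.to_numpy(dtype=float),
        }
    )


def enzyme_foldchanges_from_counts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_map: pd.DataFrame,
    comparisons: tuple[tuple[str, str], ...] = (
        ("Warburg", "Normal"),
        ("Warburg", "IDHmut"),
    ),
    pseudocount: float = 0.5,
    method: str = "arithmetic",
) -> pd.DataFrame:
    """End-to-end: count matrix -> enzyme-level fold-change table.

    Library sizes are taken over the full count matrix (subsetting first
    would distort the CPM scale); only mapped genes enter the aggregation.
    The returned table has one row per enzyme and comparison.
    """
    frames = []
    for comparison in comparisons:
        gene_fc = estimate_gene_foldchanges(counts, metadata, comparison, pseudocount)
        frames.append(aggregate_isoenzymes(gene_fc, gene_map, method=method))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Count-matrix I/O
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with the gene id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(
    mtx_path: str | Path, genes_path: str | Path, samples_path: str | Path
) -> pd.DataFrame:
    """MatrixMarket triplet plus one-column gene and sample files."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    genes = pd.read_csv(genes_path, header=None)[0].tolist()
    samples = pd.read_csv(samples_path, header=None)[0].tolist()
    if mat.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(samples)} samples"
        )
    return pd.DataFrame(mat.astype(np.int64), index=genes, columns=samples)
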