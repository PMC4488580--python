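"""Differential expression, FDR control, normalization and enrichment.

This module is the statistical substrate of the pipeline.  It provides the
two-condition differential-expression signature (Welch t-test per gene,
Benjamini-Hochberg q-values, joint fold-change/FDR selection), quantile
normalization, the cross-species probe cross-hybridization filter, and
hypergeometric gene-set enrichment.

Conventions
-----------
Expression values are log2 scale throughout.  The log2 fold change of a
two-condition contrast is ``mean(condition B) - mean(condition A)``, so
with A = low grade and B = high grade, positive values mean "up in the
high-grade tumour".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gliomanet._util import InputError, ParameterError

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "de_signature",
    "bh_fdr",
    "quantile_normalize",
    "crosshyb_filter",
    "enrichment",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes in rows and samples in columns.

    Parameters
    ----------
    data:
        ``genes x samples`` DataFrame; index = gene ids, columns = sample ids.
    conditions:
        Mapping sample id -> condition label.  May cover only a subset of
        samples (e.g. a time course carries no conditions).
    """

    data: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise InputError("duplicate gene identifiers")
        if self.data.columns.has_duplicates:
            raise InputError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise InputError("expression values must be finite")
        unknown = set(self.conditions) - set(self.data.columns)
        if unknown:
            raise InputError(f"condition labels for unknown samples: {sorted(unknown)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.data.columns if self.conditions.get(s) == condition]

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV: first column gene id, header = samples."""
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, conditions: dict[str, str] | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, conditions or {})


@dataclass
class GeneSignature:
    """Per-gene differential-expression results and the selection call.

    ``table`` columns: ``log2_fc`` (condition B minus A), ``t_stat``,
    ``p_value``, ``q_value``, ``selected``, ``zero_variance``.  A gene is
    selected iff ``|log2_fc| > fc_threshold`` and ``q_value < fdr_threshold``.
    """

    table: pd.DataFrame
    condition_a: str
    condition_b: str
    fc_threshold: float
    fdr_threshold: float

    def __post_init__(self) -> None:
        t = self.table
        bad = t["selected"] & ~(
            (t["log2_fc"].abs() > self.fc_threshold) & (t["q_value"] < self.fdr_threshold)
        )
        if bad.any():
            raise InputError("selection flag inconsistent with thresholds")

    @property
    def selected_genes(self) -> set[str]:
        return set(self.table.index[self.table["selected"]])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Order-preserving with input positions, clipped to 1.  NaN entries are
    rejected: a missing p-value has no defensible rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if np.isnan(p).any():
        raise InputError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def de_signature(
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.01,
) -> GeneSignature:
    """Two-condition differential-expression signature.

    Welch (unequal-variance) two-sample t-test per gene, BH q-values, and
    selection at ``|log2FC| > fc_threshold`` and ``q < fdr_threshold``
    (the defaults are the clinical-contrast thresholds: log2 fold change
    above 1.5 at FDR below 1%).

    Genes with zero variance in both groups get p = 1 and are flagged in
    the ``zero_variance`` column rather than raising.
    """
    samples_a = expr.samples_for(cond_a)
    samples_b = expr.samples_for(cond_b)
    if not samples_a or not samples_b:
        raise InputError(f"condition label missing from matrix: {cond_a!r} or {cond_b!r}")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise InputError("need at least two samples per condition")

    a = expr.data[samples_a].to_numpy(dtype=float)
    b = expr.data[samples_b].to_numpy(dtype=float)
    log2_fc = b.mean(axis=1) - a.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t_stat = np.where(zero_var, 0.0, t_stat)
    p = np.where(zero_var, 1.0, p)
    # identical group means with zero pooled variance yield NaN from the
    # t-test even when only one group is degenerate; treat as no evidence
    p = np.where(np.isnan(p), 1.0, p)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)

    q = bh_fdr(p)
    selected = (np.abs(log2_fc) > fc_threshold) & (q < fdr_threshold)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t_stat": t_stat,
            "p_value": p,
            "q_value": q,
            "selected": selected,
            "zero_variance": zero_var,
        },
        index=expr.data.index,
    )
    return GeneSignature(table, cond_a, cond_b, fc_threshold, fdr_threshold)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to a common distribution.

    Every column is mapped onto the across-sample mean of the sorted
    columns; ties within a column receive the average of the reference
    values over the tied ranks.  A single-sample matrix is returned
    unchanged with a warning.
    """
    x = expr.data.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input unchanged")
        return ExpressionMatrix(expr.data.copy(), dict(expr.conditions))
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        ranks = stats.rankdata(x[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns),
        dict(expr.conditions),
    )


def crosshyb_filter(
    table: pd.DataFrame,
    abs_threshold: float = 64.0,
    frac_threshold: float = 0.15,
) -> tuple[pd.Index, pd.Index]:
    """Cross-species probe cross-hybridization filter.

    ``table`` has one row per probe with columns ``own_species_signal``
    and ``other_species_signal`` (background-subtracted net fluorescence).
    A probe is removed iff the other-species signal exceeds
    ``abs_threshold`` (default 64 units) OR its relative contribution
    ``other / (own + other)`` exceeds ``frac_threshold`` (default 15%).
    A probe with zero total signal carries no evidence and is kept.

    Returns ``(kept, removed)`` as index objects.
    """
    own = table["own_species_signal"].to_numpy(dtype=float)
    other = table["other_species_signal"].to_numpy(dtype=float)
    if (own < 0).any() or (other < 0).any():
        raise InputError("signals must be non-negative")
    total = own + other
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, other / np.where(total > 0, total, 1.0), 0.0)
    removed = (other > abs_threshold) | (frac > frac_threshold)
    return table.index[~removed], table.index[removed]


def enrichment(
    query: set[str],
    collections: dict[str, set[str]],
    universe: set[str],
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Hypergeometric gene-set over-representation with BH control.

    One-sided upper-tail hypergeometric p per annotation set (each set is
    intersected with the universe first), BH across sets, and an
    ``enriched`` flag at ``q < fdr_threshold`` (default FDR 10%).

    Returns a DataFrame indexed by set name with columns ``overlap``,
    ``set_size``, ``query_size``, ``universe_size``, ``p_value``,
    ``q_value``, ``enriched``.
    """
    if not universe:
        raise InputError("empty universe")
    if not set(query) <= set(universe):
        raise InputError("query must be a subset of the universe")
    m = len(universe)
    n_query = len(query)
    names, rows = [], []
    for name, members in collections.items():
        members_in = set(members) & set(universe)
        k = len(set(query) & members_in)
        # P(X >= k) for X ~ Hypergeom(M=m, n=|set|, N=|query|)
        p = float(stats.hypergeom.sf(k - 1, m, len(members_in), n_query))
        names.append(name)
        rows.append((k, len(members_in), n_query, m, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        index=pd.Index(names, name="set_name"),
        columns=["overlap", "set_size", "query_size", "universe_size", "p_value"],
    )
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out["enriched"] = out["q_value"] < fdr_threshold
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (set name, description, members)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
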