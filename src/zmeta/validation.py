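"""Proof-of-principle and validation statistics for a signed Z table.

A candidate ranking is only trustworthy if independently known gene sets
score high on it.  The checks here quantify that in several complementary
ways: the relative Z of a gene set (its mean |Z| over the genome-wide mean
|Z|; > 1 means enrichment), an equal-variance t-test of member vs
non-member |Z|, Pearson correlation between two Z vectors (e.g. two cancer
types) with a Fisher r-to-z test for comparing two such correlations,
Spearman rank agreement between Z scores and an external experiment's
per-gene log-ratios, and signed mean Z of externally defined up/down sets.
Also included: the per-gene pooled-variance t-test used to reduce a
two-group expression matrix to (p, log-ratio, direction) summaries, and
Bonferroni adjustment.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignedZTable
from .synthetic import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "RelativeZ",
    "relative_z",
    "enrichment_ttest",
    "pearson_z_correlation",
    "compare_correlations",
    "spearman_rank_validation",
    "set_mean_z",
    "per_gene_ttest",
    "bonferroni",
]


class GeneSet(NamedTuple):
    """A named set of gene symbols (uppercased on construction)."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        members = frozenset(str(g).upper() for g in genes)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        return cls(name, members)


class RelativeZ(NamedTuple):
    ratio: float
    set_mean_abs_z: float
    overall_mean_abs_z: float
    n_members: int


def _members_in_table(table: SignedZTable, gene_set: GeneSet) -> pd.Index:
    members = table.genes.intersection(pd.Index(sorted(gene_set.genes)))
    if len(members) == 0:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the table")
    return members


def relative_z(table: SignedZTable, gene_set: GeneSet) -> RelativeZ:
    """Mean |Z| of the set's members divided by the genome-wide mean |Z|."""
    members = _members_in_table(table, gene_set)
    abs_z = table.z.abs()
    set_mean = float(abs_z.loc[members].mean())
    overall = float(abs_z.mean())
    return RelativeZ(set_mean / overall, set_mean, overall, len(members))


def enrichment_ttest(
    table: SignedZTable, gene_set: GeneSet
) -> tuple[float, int, float]:
    """Equal-variance two-sample t of member vs non-member |Z|.

    Returns ``(t, df, p)`` with ``df = n_members + n_nonmembers - 2``.
    """
    members = _members_in_table(table, gene_set)
    abs_z = table.z.abs()
    in_set = abs_z.loc[members].to_numpy()
    out_set = abs_z.drop(members).to_numpy()
    if len(in_set) < 2 or len(out_set) < 2:
        raise ValueError("need >= 2 genes inside and outside the set")
    t, p = stats.ttest_ind(in_set, out_set, equal_var=True)
    return float(t), len(in_set) + len(out_set) - 2, float(p)


def pearson_z_correlation(
    table_a: SignedZTable, table_b: SignedZTable
) -> tuple[float, int]:
    """Pearson correlation of two Z vectors over their shared genes."""
    shared = table_a.genes.intersection(table_b.genes)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes for a correlation")
    r, _ = stats.pearsonr(table_a.z.loc[shared], table_b.z.loc[shared])
    return float(r), len(shared)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Fisher r-to-z test statistic for two independent correlations.

    ``Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``.  Assumes the
    two correlations come from independent samples; when they share one
    vector the statistic is approximate.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3 in both samples")
    return (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )


def spearman_rank_validation(
    table: SignedZTable, per_gene_logratio: pd.Series
) -> tuple[float, int, float]:
    """Spearman rank correlation between Z scores and external log-ratios.

    ``per_gene_logratio`` is indexed by gene symbol (e.g. case-minus-control
    mean log-intensity from an independent experiment).  Ties receive
    average ranks.  Returns ``(rho, n_shared, p)``.
    """
    lr = per_gene_logratio.copy()
    lr.index = lr.index.astype(str).str.upper()
    shared = table.genes.intersection(lr.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    rho, p = stats.spearmanr(table.z.loc[shared], lr.loc[shared])
    return float(rho), len(shared), float(p)


def set_mean_z(
    table: SignedZTable, up_set: GeneSet, down_set: GeneSet
) -> dict[str, tuple[float, float]]:
    """Signed mean Z (with standard error) for up/down sets and overall.

    If the table agrees with the external experiment that defined the
    sets, the up set's mean is positive, the down set's negative, and the
    overall mean near zero.  Returns ``{"up"|"down"|"all": (mean, se)}``.
    """
    out: dict[str, tuple[float, float]] = {}
    for key, genes in (
        ("up", _members_in_table(table, up_set)),
        ("down", _members_in_table(table, down_set)),
        ("all", table.genes),
    ):
        values = table.z.loc[genes]
        se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
        out[key] = (float(values.mean()), se)
    return out


def per_gene_ttest(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pooled-variance two-sample t-test per gene on a two-group matrix.

    The matrix is on a log scale, so ``log_ratio`` is the case-minus-control
    mean difference.  Genes with zero pooled variance get p = 1 with a
    logged warning.  Returns a DataFrame indexed by gene with columns
    ``p_value``, ``log_ratio``, ``direction``, ``t``.
    """
    groups = sorted(matrix.sample_groups.unique())
    case_label = "case" if "case" in groups else groups[0]
    control_label = [g for g in groups if g != case_label][0]
    case = matrix.values[matrix.group_columns(case_label)].to_numpy()
    control = matrix.values[matrix.group_columns(control_label)].to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=True)
    log_ratio = case.mean(axis=1) - control.mean(axis=1)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.warning(
            "%d genes with zero pooled variance: p set to 1", int(degenerate.sum())
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "p_value": p,
            "log_ratio": log_ratio,
            "direction": np.where(log_ratio >= 0, "up", "down"),
            "t": t,
        },
        index=matrix.values.index,
    )


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` over the m supplied tests."""
    arr = np.asarray(p_values, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, arr * arr.size)
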