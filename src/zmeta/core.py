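"""Signed Z-score arithmetic for p-value based meta-analysis.

A study's evidence for one gene is a p-value plus a direction of change
(up- or down-regulated in the more adverse phenotype).  The pair is mapped
to a signed standard-normal deviate: up-regulated genes get
``z = Phi^-1(1 - p)`` (positive for small p), down-regulated genes get
``z = Phi^-1(p)`` (negative for small p).  Deviates are combined across
studies by Stouffer's method (Rosenthal's extension): ``Z = sum(z_j) / sqrt(N)``
over the ``N`` studies in which the gene was measured.

On top of the per-gene combination this module provides the group-level
operations the multi-level pipeline is built from:

* :func:`balance_groups` — rescale each group's Z table so every group has
  the same mean \\|Z\\|, preventing a single cancer type (with more or larger
  studies) from dominating a pooled score;
* :func:`contrast` — elementwise subtraction of two tables (e.g. bone minus
  non-bone metastasizing cancers);
* :func:`average_tables` — elementwise mean of two tables, the nesting
  primitive of the multi-level design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EPS = 1e-15

__all__ = [
    "EPS",
    "StudySummary",
    "SignedZTable",
    "DegenerateGroupError",
    "clamp_p",
    "p_to_signed_z",
    "study_to_z",
    "combine_stouffer",
    "combine_studies",
    "balance_groups",
    "contrast",
    "average_tables",
    "mean_tables",
]


class DegenerateGroupError(ValueError):
    """A group whose mean |Z| is zero cannot be rescaled to a common target."""


def clamp_p(p, eps: float = EPS):
    """Clamp p-values into ``[eps, 1 - eps]`` so the normal quantile stays finite.

    Accepts scalars or array-likes; raises ``ValueError`` for values outside
    ``[0, 1]``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    if np.isscalar(p) or arr.ndim == 0:
        return float(clamped)
    return clamped


def p_to_signed_z(p, direction):
    """Convert a (p, direction) pair to a signed standard-normal deviate.

    Parameters
    ----------
    p : float or array-like
        Two-sided p-value(s) in the open interval (0, 1); values of exactly
        0 or 1 must be clamped first (see :func:`clamp_p`).
    direction : {"up", "down"} or array-like of those
        "up" gives ``Phi^-1(1-p)`` (positive for p < 0.5), "down" gives
        ``Phi^-1(p)`` (negative for p < 0.5).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("p must lie strictly inside (0, 1); clamp first")
    dirs = np.asarray(direction)
    scalar = np.isscalar(p) or arr.ndim == 0
    dirs_norm = np.char.lower(dirs.astype(str))
    if not np.all(np.isin(dirs_norm, ("up", "down"))):
        raise ValueError("direction must be 'up' or 'down'")
    sign = np.where(dirs_norm == "up", 1.0, -1.0)
    # Phi^-1(1-p) = -Phi^-1(p): one quantile call covers both directions.
    z = sign * stats.norm.isf(arr)
    return float(z) if scalar else z


@dataclass
class StudySummary:
    """One study's per-gene differential-expression summary.

    ``data`` is indexed by gene symbol (uppercased, unique) with columns
    ``p_value`` (clamped into ``[eps, 1-eps]`` on construction) and
    ``direction`` ("up"/"down").  ``n1``/``n2`` are the two group sample
    sizes when known; they are metadata only — the combination uses the
    p-values as supplied.
    """

    study_id: str
    cancer_type: str
    contrast: str
    data: pd.DataFrame
    n1: int | None = None
    n2: int | None = None

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str).str.upper()
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(
                f"study {self.study_id!r}: duplicate gene symbols {dups}"
            )
        df["direction"] = df["direction"].astype(str).str.lower()
        bad = ~df["direction"].isin(["up", "down"])
        if bad.any():
            raise ValueError(
                f"study {self.study_id!r}: malformed direction tokens "
                f"{sorted(df.loc[bad, 'direction'].unique())}"
            )
        raw = df["p_value"].to_numpy(dtype=float)
        clamped = clamp_p(raw)
        n_clamped = int(np.sum(raw != clamped))
        if n_clamped:
            logger.info(
                "study %s: clamped %d p-values into (0, 1)", self.study_id, n_clamped
            )
        df["p_value"] = clamped
        self.data = df

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SignedZTable:
    """Per-gene signed Z scores with contributing-study counts.

    ``data`` is indexed by gene symbol with columns ``z`` (finite float)
    and ``n_studies`` (>= 1).  ``label`` records provenance, e.g. a cancer
    type or a pipeline level.
    """

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if not {"z", "n_studies"}.issubset(df.columns):
            raise ValueError("SignedZTable requires columns 'z' and 'n_studies'")
        df = df[["z", "n_studies"]].copy()
        df.index = pd.Index(df.index.astype(str).str.upper(), name="gene")
        df["z"] = df["z"].astype(float)
        df["n_studies"] = df["n_studies"].astype(int)
        if not np.all(np.isfinite(df["z"])):
            raise ValueError("non-finite z score in table")
        if (df["n_studies"] < 1).any():
            raise ValueError("n_studies must be >= 1 for every gene")
        self.data = df

    @classmethod
    def from_series(
        cls, z: pd.Series, n_studies, label: str = ""
    ) -> "SignedZTable":
        n = (
            n_studies
            if isinstance(n_studies, pd.Series)
            else pd.Series(n_studies, index=z.index)
        )
        return cls(pd.DataFrame({"z": z, "n_studies": n}), label=label)

    @property
    def z(self) -> pd.Series:
        return self.data["z"]

    @property
    def n_studies(self) -> pd.Series:
        return self.data["n_studies"]

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def mean_abs_z(self) -> float:
        return float(self.z.abs().mean())

    def __len__(self) -> int:
        return len(self.data)


def study_to_z(study: StudySummary) -> pd.Series:
    """Per-gene signed deviates for one study (index = gene symbols)."""
    z = p_to_signed_z(
        study.data["p_value"].to_numpy(), study.data["direction"].to_numpy()
    )
    return pd.Series(z, index=study.data.index, name=study.study_id)


def combine_stouffer(
    z_lists: Mapping[str, Sequence[float]], label: str = ""
) -> SignedZTable:
    """Stouffer-combine per-study deviates: ``Z = sum(z_j) / sqrt(N)``.

    ``N`` is the per-gene count of contributing studies, so genes measured
    on fewer platforms are combined over their own N.  Genes mapped to an
    empty list are omitted with a logged warning.
    """
    genes, zs, ns = [], [], []
    for gene, values in z_lists.items():
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            logger.warning("gene %s: no contributing studies, omitted", gene)
            continue
        genes.append(str(gene).upper())
        zs.append(values.sum() / math.sqrt(values.size))
        ns.append(values.size)
    return SignedZTable(
        pd.DataFrame({"z": zs, "n_studies": ns}, index=pd.Index(genes, name="gene")),
        label=label,
    )


def combine_studies(studies: Sequence[StudySummary], label: str = "") -> SignedZTable:
    """Convert each study's (p, direction) rows to deviates and Stouffer-combine.

    Genes absent from a study's platform simply do not contribute to that
    gene's N; the per-gene denominator adapts to the platform overlap.
    """
    if not studies:
        raise ValueError("combine_studies requires at least one study")
    series = [study_to_z(s) for s in studies]
    stacked = pd.concat(series, axis=1)  # genes x studies, NaN off-platform
    n = stacked.notna().sum(axis=1)
    z = stacked.sum(axis=1, skipna=True) / np.sqrt(n)
    keep = n >= 1
    return SignedZTable.from_series(z[keep], n[keep].astype(int), label=label)


def balance_groups(
    tables: Mapping[str, SignedZTable],
) -> tuple[dict[str, SignedZTable], dict[str, float], float]:
    """Rescale each group's Z scores to a common mean absolute Z.

    The target is the unweighted mean over groups of each group's mean |Z|;
    group g's scores are multiplied by ``target / mean|Z|_g``.  After the
    adjustment every group's mean |Z| equals the target (to ~1e-9), so each
    group contributes equally to any pooled score.

    Returns ``(adjusted_tables, factors, target)``.
    """
    if not tables:
        raise ValueError("balance_groups requires at least one group")
    means = {}
    for name, table in tables.items():
        if len(table) == 0:
            raise ValueError(f"group {name!r} is empty")
        m = table.mean_abs_z()
        if m == 0:
            raise DegenerateGroupError(f"group {name!r} has mean |Z| = 0")
        means[name] = m
    target = float(np.mean(list(means.values())))
    factors = {name: target / m for name, m in means.items()}
    adjusted = {
        name: SignedZTable.from_series(
            tables[name].z * factors[name],
            tables[name].n_studies,
            label=tables[name].label,
        )
        for name in tables
    }
    return adjusted, factors, target


def contrast(
    zA: SignedZTable,
    zB: SignedZTable,
    missing: str = "intersect",
    label: str = "",
) -> SignedZTable:
    """Elementwise difference ``zA - zB`` of two Z tables.

    ``missing`` controls genes present on one side only: ``"intersect"``
    (default) drops them — a difference needs both sides — logging the
    dropped count; ``"carry"`` keeps ``zA`` (resp. ``-zB``) for one-sided
    genes.  ``n_studies`` sums the inputs' counts.
    """
    if missing not in ("intersect", "carry"):
        raise ValueError(f"unknown missing-gene policy {missing!r}")
    if missing == "intersect":
        shared = zA.genes.intersection(zB.genes)
        dropped = len(zA.genes.union(zB.genes)) - len(shared)
        if dropped:
            logger.info("contrast: dropped %d one-sided genes", dropped)
        z = zA.z.loc[shared] - zB.z.loc[shared]
        n = zA.n_studies.loc[shared] + zB.n_studies.loc[shared]
    else:
        z = zA.z.sub(zB.z, fill_value=0.0)
        n = zA.n_studies.add(zB.n_studies, fill_value=0).astype(int)
    return SignedZTable.from_series(z, n, label=label)


def average_tables(
    zX: SignedZTable,
    zY: SignedZTable,
    missing: str = "carry",
    label: str = "",
) -> SignedZTable:
    """Elementwise mean ``(zX + zY) / 2`` of two Z tables.

    Default policy ``"carry"`` keeps the available value for genes present
    in only one table (platforms overlap only partially); ``"intersect"``
    restricts to shared genes.
    """
    if missing not in ("intersect", "carry"):
        raise ValueError(f"unknown missing-gene policy {missing!r}")
    if missing == "intersect":
        shared = zX.genes.intersection(zY.genes)
        z = (zX.z.loc[shared] + zY.z.loc[shared]) / 2.0
        n = zX.n_studies.loc[shared] + zY.n_studies.loc[shared]
    else:
        both = zX.genes.intersection(zY.genes)
        only_x = zX.genes.difference(zY.genes)
        only_y = zY.genes.difference(zX.genes)
        z = pd.concat(
            [
                (zX.z.loc[both] + zY.z.loc[both]) / 2.0,
                zX.z.loc[only_x],
                zY.z.loc[only_y],
            ]
        )
        n = pd.concat(
            [
                zX.n_studies.loc[both] + zY.n_studies.loc[both],
                zX.n_studies.loc[only_x],
                zY.n_studies.loc[only_y],
            ]
        )
    return SignedZTable.from_series(z, n.astype(int), label=label)


def mean_tables(tables: Iterable[SignedZTable], label: str = "") -> SignedZTable:
    """Unweighted elementwise mean of several Z tables.

    Each gene is averaged over the tables in which it appears (carry
    policy), so partially overlapping platforms still yield one value per
    gene.  ``n_studies`` sums contributing counts.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("mean_tables requires at least one table")
    z = pd.concat([t.z for t in tables], axis=1)
    n = pd.concat([t.n_studies for t in tables], axis=1)
    return SignedZTable.from_series(
        z.mean(axis=1, skipna=True),
        n.sum(axis=1, skipna=True).astype(int),
        label=label,
    )
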