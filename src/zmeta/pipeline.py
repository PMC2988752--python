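"""The three-level meta-analysis that nests study groups into one ranking.

Level 1 contrasts bone-metastasizing cancers (breast, lung) against
non-bone metastasizing ones (colon, ovarian) on their normal-vs-tumor
signatures: per cancer type the studies are Stouffer-combined, the
per-type tables are balanced to a common mean |Z| so no type dominates,
each side is averaged over its types, and the non-bone side is subtracted
from the bone side.  Level 2 averages that contrast with the combined
normal-vs-localized prostate studies; level 3 averages the level-2 table
with the combined localized-vs-metastatic prostate studies.

Because each level is a plain mean with the previous level, a gene present
everywhere ends up weighted 1/4 (level-1 contrast) + 1/4 (normal-vs-tumor
prostate) + 1/2 (localized-vs-metastatic): the nesting deliberately
up-weights the metastasis comparison, the most disease-specific evidence.

The final ranking takes the k largest (top up-regulated) and k smallest
(top down-regulated) signed Z scores, k = 250 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    SignedZTable,
    StudySummary,
    average_tables,
    balance_groups,
    combine_studies,
    contrast,
    mean_tables,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "MetaRunResult",
    "run_level1",
    "run_level2",
    "run_level3",
    "rank_candidates",
    "run_pipeline",
]

DEFAULT_K = 250


class ConfigurationError(ValueError):
    """A required study role is missing or empty."""


@dataclass
class MetaRunResult:
    """All artifacts of one pipeline run."""

    level1: SignedZTable
    level2: SignedZTable
    level3: SignedZTable
    factors_by_group: dict[str, float]
    balance_target: float
    top_up: pd.DataFrame
    top_down: pd.DataFrame
    config_echo: dict = field(default_factory=dict)


def run_level1(
    bone_studies: Mapping[str, Sequence[StudySummary]],
    nonbone_studies: Mapping[str, Sequence[StudySummary]],
    missing: str = "intersect",
) -> tuple[SignedZTable, dict[str, float], float]:
    """Bone-vs-non-bone contrast of normal-vs-tumor signatures.

    Returns the contrast table together with the per-cancer-type adjustment
    factors and the common mean-|Z| target they enforce.
    """
    if not bone_studies or not any(bone_studies.values()):
        raise ConfigurationError("bone side has no studies")
    if not nonbone_studies or not any(nonbone_studies.values()):
        raise ConfigurationError("non-bone side has no studies")
    overlap = set(bone_studies) & set(nonbone_studies)
    if overlap:
        raise ConfigurationError(f"cancer types on both sides: {sorted(overlap)}")

    per_type: dict[str, SignedZTable] = {}
    for ct, studies in {**bone_studies, **nonbone_studies}.items():
        if not studies:
            raise ConfigurationError(f"cancer type {ct!r} has no studies")
        per_type[ct] = combine_studies(studies, label=ct)
        logger.info("level1: %s combined over %d studies, %d genes",
                    ct, len(studies), len(per_type[ct]))

    # One joint balancing across all cancer types: a single common target.
    adjusted, factors, target = balance_groups(per_type)
    bone = mean_tables([adjusted[ct] for ct in bone_studies], label="bone")
    nonbone = mean_tables([adjusted[ct] for ct in nonbone_studies], label="nonbone")
    level1 = contrast(bone, nonbone, missing=missing, label="level1")
    logger.info("level1: contrast over %d genes (target mean |Z| %.4f)",
                len(level1), target)
    return level1, factors, target


def run_level2(
    level1: SignedZTable,
    prostate_nt_studies: Sequence[StudySummary],
    missing: str = "carry",
) -> SignedZTable:
    """Average level 1 with the combined normal-vs-localized prostate studies."""
    if not prostate_nt_studies:
        raise ConfigurationError("no prostate normal-vs-tumor studies")
    prostate = combine_studies(prostate_nt_studies, label="prostate_nt")
    level2 = average_tables(level1, prostate, missing=missing, label="level2")
    logger.info("level2: %d genes", len(level2))
    return level2


def run_level3(
    level2: SignedZTable,
    loc_vs_met_studies: Sequence[StudySummary],
    missing: str = "carry",
) -> SignedZTable:
    """Average level 2 with the combined localized-vs-metastatic studies.

    Through the nesting this gives the metastasis comparison an effective
    weight of one half for genes present at every stage.
    """
    if not loc_vs_met_studies:
        raise ConfigurationError("no localized_vs_metastatic studies")
    met = combine_studies(loc_vs_met_studies, label="loc_vs_met")
    level3 = average_tables(level2, met, missing=missing, label="level3")
    logger.info("level3: %d genes", len(level3))
    return level3


def rank_candidates(
    table: SignedZTable, k: int = DEFAULT_K
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k up-regulated (largest z) and down-regulated (smallest z) genes.

    Ties at a list boundary are broken by lexicographic gene symbol so the
    output is reproducible across runs and platforms.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = table.data.reset_index().rename(columns={df_index_name(table): "gene"})
    up = df.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    down = df.sort_values(["z", "gene"], ascending=[True, True], kind="mergesort")
    return (
        up.head(k).set_index("gene"),
        down.head(k).set_index("gene"),
    )


def df_index_name(table: SignedZTable) -> str:
    return table.data.index.name or "index"


def run_pipeline(
    bone_studies: Mapping[str, Sequence[StudySummary]],
    nonbone_studies: Mapping[str, Sequence[StudySummary]],
    prostate_nt_studies: Sequence[StudySummary],
    loc_vs_met_studies: Sequence[StudySummary],
    k: int = DEFAULT_K,
    contrast_missing: str = "intersect",
    average_missing: str = "carry",
    config_echo: dict | None = None,
) -> MetaRunResult:
    """Run all three levels and rank candidates.

    Deterministic given the input tables; every stage logs its gene count
    so platform-overlap attrition is auditable.
    """
    level1, factors, target = run_level1(
        bone_studies, nonbone_studies, missing=contrast_missing
    )
    level2 = run_level2(level1, prostate_nt_studies, missing=average_missing)
    level3 = run_level3(level2, loc_vs_met_studies, missing=average_missing)
    top_up, top_down = rank_candidates(level3, k=k)
    return MetaRunResult(
        level1=level1,
        level2=level2,
        level3=level3,
        factors_by_group=factors,
        balance_target=target,
        top_up=top_up,
        top_down=top_down,
        config_echo=dict(config_echo or {}, k=k),
    )
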