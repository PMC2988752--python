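"""Synthetic multi-study differential-expression data with known ground truth.

Real inputs to a cross-study meta-analysis are per-study gene tables of
p-values and regulation directions, produced on heterogeneous microarray
platforms (partial gene overlap) with widely varying sample sizes.  This
module emulates exactly that granularity: instead of simulating probe-level
intensities, each study draws one two-sample t-statistic per measured gene
from the noncentral t distribution implied by a planted standardized effect
and the study's group sizes, and reports the two-sided p-value plus the
sign of the drawn statistic.  That is the level of information the
meta-analysis consumes, and it gives every downstream stage a known answer
key (:class:`SyntheticTruth`).

Also generated: gene-interaction networks with planted hubs, and small
two-group expression matrices for rank-validation of a Z table against an
independent experiment.

All generators take explicit integer seeds; :func:`spawn_seeds` fans a
master seed out deterministically so that the order in which components
draw does not couple their streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import StudySummary

__all__ = [
    "SyntheticTruth",
    "StudyDesign",
    "ExpressionMatrix",
    "spawn_seeds",
    "generate_truth",
    "simulate_study",
    "generate_interactome",
    "generate_expression_matrix",
    "bone_metastasis_scenario",
]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated multi-study collection.

    ``effect`` maps a contrast name to a per-gene signed standardized mean
    difference (unitless); genes without a planted effect carry exactly 0.
    ``hub_genes`` are the nodes that :func:`generate_interactome` wires as
    high-degree hubs.
    """

    gene_ids: list[str]
    effect: dict[str, pd.Series]
    hub_genes: set[str] = field(default_factory=set)
    seed: int = 0

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        for name, eff in self.effect.items():
            if not set(eff.index).issubset(universe):
                raise ValueError(f"effect map {name!r} references unknown genes")
            if not np.all(np.isfinite(eff.to_numpy(dtype=float))):
                raise ValueError(f"effect map {name!r} has non-finite values")
        if not self.hub_genes.issubset(universe):
            raise ValueError("hub_genes not contained in gene_ids")

    def effect_genes(self, contrast: str | None = None) -> set[str]:
        """Genes with a nonzero planted effect (in one contrast, or any)."""
        names = [contrast] if contrast is not None else list(self.effect)
        out: set[str] = set()
        for name in names:
            eff = self.effect[name]
            out |= set(eff.index[eff != 0])
        return out


@dataclass
class StudyDesign:
    """Design of one simulated study.

    ``platform_fraction`` is the fraction of the gene universe measured by
    the study's platform.  ``effect_keys`` names the truth effect maps this
    study responds to (summed); by default a study responds to the map
    named after its own contrast.
    """

    study_id: str
    cancer_type: str
    contrast: str
    n1: int
    n2: int
    platform_fraction: float = 1.0
    effect_keys: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes n1, n2 must be >= 2")
        if not (0 < self.platform_fraction <= 1):
            raise ValueError("platform_fraction must lie in (0, 1]")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized log-intensities, two groups."""

    values: pd.DataFrame
    sample_groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.sample_groups.index):
            raise ValueError("sample_groups index must match matrix columns")
        counts = self.sample_groups.value_counts()
        if len(counts) != 2 or (counts < 2).any():
            raise ValueError("need exactly two groups with >= 2 samples each")
        if self.values.isna().any().any():
            raise ValueError("expression matrix must not contain missing values")

    def group_columns(self, label: str) -> pd.Index:
        return self.sample_groups.index[self.sample_groups == label]


def _gene_symbols(n_genes: int) -> list[str]:
    width = len(str(max(n_genes - 1, 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def generate_truth(
    n_genes: int,
    n_effect_per_contrast: int | Mapping[str, int],
    effect_size_mean: float = 1.0,
    n_hubs: int = 0,
    seed: int = 0,
    contrasts: Sequence[str] = ("normal_vs_tumor", "localized_vs_metastatic"),
    hub_contrasts: Sequence[str] | None = None,
) -> SyntheticTruth:
    """Plant signed effects and hub genes over a synthetic gene universe.

    For each contrast, ``n_effect`` genes are sampled without replacement
    and given a constant-magnitude effect of ``effect_size_mean``, half up
    and half down (an odd count resolves the extra gene toward up).  Hubs
    are drawn preferentially from planted effect genes (restricted to
    ``hub_contrasts`` when given) so that hub wiring lands inside the
    top-candidate lists a downstream ranking produces.
    """
    if n_genes < 0 or n_hubs < 0:
        raise ValueError("counts must be non-negative")
    per_contrast = (
        dict(n_effect_per_contrast)
        if isinstance(n_effect_per_contrast, Mapping)
        else {c: int(n_effect_per_contrast) for c in contrasts}
    )
    for name, k in per_contrast.items():
        if k < 0:
            raise ValueError(f"negative effect count for contrast {name!r}")
        if k > n_genes:
            raise ValueError(f"contrast {name!r}: more effects than genes")
    if n_hubs > n_genes:
        raise ValueError("more hubs than genes")

    genes = _gene_symbols(n_genes)
    rng = np.random.default_rng(seed)
    effect: dict[str, pd.Series] = {}
    for name in per_contrast:
        eff = pd.Series(0.0, index=pd.Index(genes, name="gene"))
        k = per_contrast[name]
        if k:
            chosen = rng.choice(n_genes, size=k, replace=False)
            n_up = (k + 1) // 2  # ties resolved toward up
            signs = np.array([1.0] * n_up + [-1.0] * (k - n_up))
            eff.iloc[chosen] = signs * effect_size_mean
        effect[name] = eff

    pool_contrasts = list(hub_contrasts) if hub_contrasts is not None else list(effect)
    hub_pool = sorted(
        set().union(
            *(set(effect[c].index[effect[c] != 0]) for c in pool_contrasts)
        )
        if pool_contrasts
        else set()
    )
    hubs: set[str] = set()
    if n_hubs:
        if len(hub_pool) >= n_hubs:
            hubs = set(rng.choice(hub_pool, size=n_hubs, replace=False))
        else:
            hubs = set(hub_pool)
            rest = sorted(set(genes) - hubs)
            hubs |= set(rng.choice(rest, size=n_hubs - len(hubs), replace=False))
    return SyntheticTruth(gene_ids=genes, effect=effect, hub_genes=hubs, seed=seed)


def simulate_study(
    truth: SyntheticTruth, design: StudyDesign, seed: int
) -> StudySummary:
    """Simulate one study's per-gene (p-value, direction) table.

    The platform is a seeded uniform subsample of
    ``round(platform_fraction * n_genes)`` genes.  For each measured gene a
    two-sample t-statistic is drawn from the noncentral t with
    noncentrality ``effect * sqrt(n1*n2/(n1+n2))`` and ``n1+n2-2`` degrees
    of freedom; the study reports the two-sided p-value and the sign of the
    drawn statistic (a zero statistic counts as "up").
    """
    rng = np.random.default_rng(seed)
    n_genes = len(truth.gene_ids)
    n_platform = int(round(design.platform_fraction * n_genes))
    idx = np.sort(rng.choice(n_genes, size=n_platform, replace=False))
    genes = pd.Index([truth.gene_ids[i] for i in idx], name="gene")

    keys = design.effect_keys if design.effect_keys is not None else (design.contrast,)
    effect = np.zeros(n_platform)
    for key in keys:
        if key in truth.effect:
            effect = effect + truth.effect[key].iloc[idx].to_numpy(dtype=float)

    df = design.n1 + design.n2 - 2
    nc = effect * np.sqrt(design.n1 * design.n2 / (design.n1 + design.n2))
    # noncentral t draw: (Z + nc) / sqrt(ChiSq_df / df)
    t = (rng.standard_normal(n_platform) + nc) / np.sqrt(rng.chisquare(df, n_platform) / df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    direction = np.where(t >= 0, "up", "down")
    return StudySummary(
        study_id=design.study_id,
        cancer_type=design.cancer_type,
        contrast=design.contrast,
        data=pd.DataFrame({"p_value": p, "direction": direction}, index=genes),
        n1=design.n1,
        n2=design.n2,
    )


def generate_interactome(
    truth: SyntheticTruth,
    n_background_edges: int,
    hub_degree_min: int = 5,
    seed: int = 0,
    hub_effect_bias: float = 0.9,
    partner_contrasts: Sequence[str] | None = None,
) -> nx.Graph:
    """Generate an undirected simple interaction graph with planted hubs.

    Every planted hub is wired to at least ``hub_degree_min`` distinct
    partners; partners are drawn from planted effect genes (of
    ``partner_contrasts`` when given, else any contrast) with probability
    ``hub_effect_bias``, falling back to the full universe.  This keeps
    hub neighborhoods inside top-candidate gene lists.  Background edges
    are uniform random pairs.  No self-loops, no duplicate edges.
    """
    if hub_degree_min < 1:
        raise ValueError("hub_degree_min must be >= 1")
    if n_background_edges < 0:
        raise ValueError("n_background_edges must be non-negative")
    n = len(truth.gene_ids)
    capacity = n * (n - 1) // 2
    needed = n_background_edges + len(truth.hub_genes) * hub_degree_min
    if needed > capacity:
        raise ValueError("requested edges exceed simple-graph capacity")

    rng = np.random.default_rng(seed)
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(truth.gene_ids)
    if partner_contrasts is not None:
        effect_pool = sorted(
            set().union(*(truth.effect_genes(c) for c in partner_contrasts))
        )
    else:
        effect_pool = sorted(truth.effect_genes())
    all_genes = truth.gene_ids

    for hub in sorted(truth.hub_genes):
        while graph.degree(hub) < hub_degree_min:
            pool = (
                effect_pool
                if effect_pool and rng.random() < hub_effect_bias
                else all_genes
            )
            partner = pool[rng.integers(len(pool))]
            if partner != hub and not graph.has_edge(hub, partner):
                graph.add_edge(hub, partner)

    added = 0
    while added < n_background_edges:
        i, j = rng.integers(n, size=2)
        if i == j:
            continue
        u, v = all_genes[i], all_genes[j]
        if not graph.has_edge(u, v):
            graph.add_edge(u, v)
            added += 1
    return graph


def generate_expression_matrix(
    truth: SyntheticTruth,
    contrast: str,
    n_case: int,
    n_control: int,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate a two-group log-intensity matrix with the planted effects.

    Case samples get a per-gene mean shift equal to the contrast's effect;
    both groups share unit-variance-scaled Gaussian noise (``noise_sd``).
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 samples per group")
    if contrast not in truth.effect:
        raise ValueError(f"unknown contrast {contrast!r}")
    rng = np.random.default_rng(seed)
    n_genes = len(truth.gene_ids)
    n_samples = n_case + n_control
    effect = truth.effect[contrast].to_numpy(dtype=float)
    values = noise_sd * rng.standard_normal((n_genes, n_samples))
    values[:, :n_case] += effect[:, None]
    samples = [f"CASE_{i + 1}" for i in range(n_case)] + [
        f"CTRL_{i + 1}" for i in range(n_control)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control,
        index=pd.Index(samples, name="sample"),
        name="group",
    )
    return ExpressionMatrix(
        values=pd.DataFrame(
            values, index=pd.Index(truth.gene_ids, name="gene"), columns=samples
        ),
        sample_groups=groups,
    )


# -- Scenario builder -------------------------------------------------------

BONE_TYPES = ("breast", "lung")
NONBONE_TYPES = ("colon", "ovarian")

# Sample-size ranges per class, mirroring typical published study designs:
# normal-vs-tumor cohorts run a few to dozens of normals against larger
# tumor groups; metastasis cohorts pair sizable primary-tumor groups with
# small metastatic groups.
_NT_N1, _NT_N2 = (3, 41), (7, 64)
_MET_N1, _MET_N2 = (23, 64), (5, 25)
_PLATFORM = (0.6, 1.0)


def bone_metastasis_scenario(
    n_genes: int = 10_000,
    n_effect_per_contrast: int = 100,
    effect_size_mean: float = 1.0,
    n_hubs: int = 10,
    n_studies_per_role: int = 5,
    seed: int = 0,
) -> tuple[SyntheticTruth, dict[str, object]]:
    """Build the full multi-study collection the 3-level pipeline consumes.

    Plants three independent effect layers: ``shared_nt`` (tumor signature
    common to all cancer types, cancelled by the bone-vs-non-bone
    contrast), ``bone_nt`` (bone-metastasizing-specific signature carried
    by breast/lung/prostate) and ``localized_vs_metastatic`` (the
    metastasis signature, which the nesting up-weights).  Returns the truth
    plus a dict of study lists keyed by pipeline role.
    """
    truth = generate_truth(
        n_genes,
        n_effect_per_contrast,
        effect_size_mean,
        n_hubs=n_hubs,
        seed=seed,
        contrasts=("shared_nt", "bone_nt", "localized_vs_metastatic"),
        hub_contrasts=("localized_vs_metastatic",),
    )
    # composite signature of clinically advanced disease vs benign tissue,
    # for simulating an independent validation experiment
    truth.effect["advanced_vs_benign"] = (
        truth.effect["bone_nt"] + truth.effect["localized_vs_metastatic"]
    )
    rng = np.random.default_rng(spawn_seeds(seed, 2)[1])

    def _design(study_id, cancer_type, contrast, keys, n_rng):
        (a1, b1), (a2, b2) = n_rng
        return StudyDesign(
            study_id=study_id,
            cancer_type=cancer_type,
            contrast=contrast,
            n1=int(rng.integers(a1, b1 + 1)),
            n2=int(rng.integers(a2, b2 + 1)),
            platform_fraction=float(rng.uniform(*_PLATFORM)),
            effect_keys=keys,
        )

    designs: list[StudyDesign] = []
    per_type = max(1, n_studies_per_role // len(BONE_TYPES))
    for side_types, keys in (
        (BONE_TYPES, ("shared_nt", "bone_nt")),
        (NONBONE_TYPES, ("shared_nt",)),
    ):
        count = 0
        for ct in side_types:
            k = per_type if ct != side_types[-1] else n_studies_per_role - count
            for i in range(k):
                designs.append(
                    _design(f"{ct}_{i + 1}", ct, "normal_vs_tumor", keys, (_NT_N1, _NT_N2))
                )
                count += 1
    for i in range(n_studies_per_role):
        designs.append(
            _design(
                f"prostate_nt_{i + 1}",
                "prostate",
                "normal_vs_tumor",
                ("shared_nt", "bone_nt"),
                (_NT_N1, _NT_N2),
            )
        )
    for i in range(n_studies_per_role):
        designs.append(
            _design(
                f"prostate_met_{i + 1}",
                "prostate",
                "localized_vs_metastatic",
                ("localized_vs_metastatic",),
                (_MET_N1, _MET_N2),
            )
        )

    seeds = spawn_seeds(seed + 1, len(designs))
    studies = [simulate_study(truth, d, s) for d, s in zip(designs, seeds)]

    bone: dict[str, list[StudySummary]] = {ct: [] for ct in BONE_TYPES}
    nonbone: dict[str, list[StudySummary]] = {ct: [] for ct in NONBONE_TYPES}
    prostate_nt: list[StudySummary] = []
    loc_vs_met: list[StudySummary] = []
    for study in studies:
        if study.cancer_type in bone:
            bone[study.cancer_type].append(study)
        elif study.cancer_type in nonbone:
            nonbone[study.cancer_type].append(study)
        elif study.contrast == "normal_vs_tumor":
            prostate_nt.append(study)
        else:
            loc_vs_met.append(study)
    roles = {
        "bone": bone,
        "nonbone": nonbone,
        "prostate_normal_vs_tumor": prostate_nt,
        "localized_vs_metastatic": loc_vs_met,
    }
    return truth, roles
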