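"""File formats and run configuration.

Plain-text carriers for every object in the pipeline:

* study summaries — TSV with header ``gene  p_value  direction  [n1  n2]``;
* signed Z tables — TSV with ``gene  z  n_studies  label``;
* gene sets — standard GMT (name, description, then members, tab-separated);
* interactomes — 2-column TSV edge lists;
* expression matrices — TSV whose first line annotates sample groups;
* run configuration — YAML or JSON.

Gene symbols are uppercased at every boundary.  Readers validate what the
writers produce (round-trip closure) and fail loudly on malformed rows.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import SignedZTable, StudySummary
from .pipeline import ConfigurationError, MetaRunResult
from .synthetic import ExpressionMatrix
from .validation import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_study_tsv",
    "write_study_tsv",
    "read_ztable_tsv",
    "write_ztable_tsv",
    "read_gmt",
    "write_gmt",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "load_config",
    "load_studies_from_config",
    "write_report",
]


class ParseError(ValueError):
    """A file violates its format contract (includes the offending location)."""


def read_study_tsv(path, study_id=None, cancer_type="", contrast="") -> StudySummary:
    """Read one study's per-gene summary from TSV.

    Required columns: ``gene``, ``p_value``, ``direction``; optional
    ``n1``/``n2``.  Directions are case-normalized; anything other than
    up/down raises :class:`ParseError` with the line number.  Duplicate
    gene symbols raise an error naming them.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str})
    required = {"gene", "p_value", "direction"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    dirs = df["direction"].str.lower()
    bad = ~dirs.isin(["up", "down"])
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ParseError(
            f"{path}:{line}: malformed direction {df.loc[bad, 'direction'].iloc[0]!r}"
        )
    genes = df["gene"].str.upper()
    if genes.duplicated().any():
        dups = sorted(genes[genes.duplicated()].unique())
        raise ParseError(f"{path}: duplicate gene symbols {dups}")
    n1 = int(df["n1"].iloc[0]) if "n1" in df.columns else None
    n2 = int(df["n2"].iloc[0]) if "n2" in df.columns else None
    data = pd.DataFrame(
        {"p_value": df["p_value"].to_numpy(dtype=float), "direction": dirs.to_numpy()},
        index=pd.Index(genes, name="gene"),
    )
    return StudySummary(
        study_id=study_id or path.stem,
        cancer_type=cancer_type,
        contrast=contrast,
        data=data,
        n1=n1,
        n2=n2,
    )


def write_study_tsv(study: StudySummary, path) -> None:
    df = study.data.reset_index()
    if study.n1 is not None and study.n2 is not None:
        df["n1"], df["n2"] = study.n1, study.n2
    df.to_csv(path, sep="\t", index=False)


def read_ztable_tsv(path) -> SignedZTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "z", "n_studies"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns gene, z, n_studies")
    label = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else ""
    return SignedZTable(df.set_index("gene")[["z", "n_studies"]], label=label)


def write_ztable_tsv(table: SignedZTable, path) -> None:
    df = table.data.reset_index()
    df.columns = ["gene", "z", "n_studies"]
    df["label"] = table.label
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (one set per line: name, description, members)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                logger.warning("%s:%d: gene set %r has no members, skipped",
                               path, lineno, fields[0])
                continue
            members = [f for f in fields[2:] if f.strip()]
            sets.append(GeneSet.from_iterable(fields[0], members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


def read_edgelist_tsv(path) -> nx.Graph:
    """Read an undirected simple graph from a 2-column TSV edge list."""
    graph: nx.Graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            u, v = fields[0].upper(), fields[1].upper()
            if u == v:
                raise ParseError(f"{path}:{lineno}: self-loop on {u}")
            graph.add_edge(u, v)
    return graph


def write_edgelist_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples matrix whose first line annotates groups.

    Line 1: ``#groups<TAB>label1<TAB>label2...`` (one per sample, matching
    the column order of the header on line 2).
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#groups\t"):
            raise ParseError(f"{path}: first line must start with '#groups\\t'")
        labels = first.split("\t")[1:]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if len(labels) != df.shape[1]:
        raise ParseError(f"{path}: {len(labels)} group labels for {df.shape[1]} samples")
    df.index = df.index.astype(str).str.upper()
    groups = pd.Series(labels, index=df.columns, name="group")
    return ExpressionMatrix(values=df, sample_groups=groups)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#groups\t" + "\t".join(matrix.sample_groups) + "\n")
        matrix.values.rename_axis("gene").to_csv(fh, sep="\t")


REQUIRED_ROLES = ("bone", "nonbone", "prostate_normal_vs_tumor", "localized_vs_metastatic")


def load_config(path) -> dict:
    """Load a run configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    config = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    studies = config.get("studies", {})
    for role in REQUIRED_ROLES:
        if role not in studies or not studies[role]:
            raise ConfigurationError(f"{path}: missing study role {role!r}")
    base = path.parent

    def _check(p):
        resolved = (base / p) if not Path(p).is_absolute() else Path(p)
        if not resolved.exists():
            raise ConfigurationError(f"{path}: study file not found: {p}")
        return resolved

    for role in ("bone", "nonbone"):
        for ct, paths in studies[role].items():
            studies[role][ct] = [str(_check(p)) for p in paths]
    for role in ("prostate_normal_vs_tumor", "localized_vs_metastatic"):
        studies[role] = [str(_check(p)) for p in studies[role]]
    config.setdefault("k", 250)
    if config["k"] < 1:
        raise ConfigurationError(f"{path}: k must be >= 1")
    config.setdefault("seed", 0)
    return config


def load_studies_from_config(config: dict):
    """Materialize the four study roles from a validated configuration."""
    studies = config["studies"]
    bone = {
        ct: [read_study_tsv(p, cancer_type=ct, contrast="normal_vs_tumor") for p in paths]
        for ct, paths in studies["bone"].items()
    }
    nonbone = {
        ct: [read_study_tsv(p, cancer_type=ct, contrast="normal_vs_tumor") for p in paths]
        for ct, paths in studies["nonbone"].items()
    }
    prostate_nt = [
        read_study_tsv(p, cancer_type="prostate", contrast="normal_vs_tumor")
        for p in studies["prostate_normal_vs_tumor"]
    ]
    loc_met = [
        read_study_tsv(p, cancer_type="prostate", contrast="localized_vs_metastatic")
        for p in studies["localized_vs_metastatic"]
    ]
    return bone, nonbone, prostate_nt, loc_met


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(
    result: MetaRunResult,
    outdir,
    validations: dict | None = None,
    hubs: pd.DataFrame | None = None,
) -> dict:
    """Write all run artifacts to ``outdir`` and return a checksum manifest.

    Emits level{1,2,3}.tsv, factors.json, top_up.tsv, top_down.tsv, plus
    validation.json / hubs.tsv when supplied; manifest.json lists every
    file with its SHA-256 so identical runs are verifiably identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in (
        ("level1", result.level1),
        ("level2", result.level2),
        ("level3", result.level3),
    ):
        write_ztable_tsv(table, outdir / f"{name}.tsv")
    (outdir / "factors.json").write_text(
        json.dumps(
            {"factors": result.factors_by_group, "target": result.balance_target},
            indent=2,
            sort_keys=True,
        )
    )
    result.top_up.to_csv(outdir / "top_up.tsv", sep="\t")
    result.top_down.to_csv(outdir / "top_down.tsv", sep="\t")
    sections = {"validation": validations is not None, "hubs": hubs is not None}
    if validations is not None:
        (outdir / "validation.json").write_text(
            json.dumps(validations, indent=2, sort_keys=True, default=float)
        )
    if hubs is not None:
        hubs.to_csv(outdir / "hubs.tsv", sep="\t")
    files = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": {name: _sha256(outdir / name) for name in files},
        "sections": sections,
        "config_echo": result.config_echo,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
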