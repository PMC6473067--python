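"""Readers and writers for expression matrices, sample labels and GMT gene
set collections, plus probe collapsing, gene-set size filtering and run
configuration.

Expression TSV dialect: first column = feature identifier, header row =
sample identifiers, tab-separated. Labels TSV: two columns, sample
identifier and group (exactly two distinct values). GMT: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import GeneSetCollection
from .frameworks import StudyBundle

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression and labels
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Genes-by-samples expression matrix from TSV."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample identifiers")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        raise ValueError(f"{path}: expression values must be numeric and finite")
    return frame


def write_expression(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="feature")


def read_labels(path) -> pd.Series:
    """Sample -> group mapping with exactly two groups."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    series = frame.iloc[:, 0]
    if series.nunique() != 2:
        raise ValueError(f"{path}: labels must contain exactly two groups")
    return series


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("group").to_csv(path, sep="\t", index_label="sample")


def bundle_from_frames(
    expressions: Sequence[pd.DataFrame],
    labels: Sequence[pd.Series],
    dataset_ids: Sequence[str],
    case_group: str | None = None,
) -> StudyBundle:
    """Assemble a study bundle, intersecting gene universes if they differ.

    ``case_group`` names the case level of the labels; by default the
    lexicographically larger of the two levels is treated as case (the
    direction does not affect two-sided tests).
    """
    shared = expressions[0].index
    for frame in expressions[1:]:
        shared = shared.intersection(frame.index)
    if len(shared) == 0:
        raise ValueError("datasets share no genes")
    if any(len(shared) < len(f.index) for f in expressions):
        logger.info("gene universes differ; intersected to %d genes", len(shared))
    shared = sorted(shared)
    mats, masks = [], []
    for frame, lab in zip(expressions, labels):
        frame = frame.loc[shared, lab.index]
        case = case_group if case_group is not None else sorted(lab.unique())[-1]
        mats.append(frame.to_numpy(dtype=float))
        masks.append((lab == case).to_numpy())
    return StudyBundle(
        expressions=mats,
        case_masks=masks,
        gene_ids=list(shared),
        dataset_ids=list(dataset_ids),
    )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets from a GMT file; the description column is discarded."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs >= 3 fields")
            name, _description, *genes = parts
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def collapse_probes(
    expression: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse probe-level rows to gene level by the per-sample maximum.

    Probes without a gene mapping are dropped (count logged). For each gene
    and each sample independently the value is the maximum over that gene's
    probes.
    """
    mapped = expression.index.map(lambda p: probe_to_gene.get(p))
    unmapped = mapped.isna()
    if unmapped.any():
        logger.warning("dropping %d unmapped probes", int(unmapped.sum()))
    kept = expression.loc[~unmapped]
    genes = pd.Index(mapped[~unmapped], name="gene")
    collapsed = kept.groupby(genes, sort=True).max()
    return collapsed


def filter_gene_sets(
    sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect sets with the universe, then keep sizes in [min, max].

    Bounds are inclusive: a 15-member or a 500-member set survives the
    default filter.
    """
    universe = list(universe)
    in_universe = set(universe)
    filtered: dict[str, list[str]] = {}
    for name, members in sets.items():
        kept = sorted(set(members) & in_universe)
        if min_size <= len(kept) <= max_size:
            filtered[name] = kept
    if not filtered:
        raise ValueError(
            "no gene sets survive filtering; check the universe overlap and "
            f"size bounds [{min_size}, {max_size}]"
        )
    return GeneSetCollection(filtered, universe)


def significant_pathways(table: pd.DataFrame, cutoff: float = 0.1) -> pd.DataFrame:
    """Rows with FDR strictly below the cutoff, ordered ascending by FDR."""
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    hits = table[table["fdr"] < cutoff]
    return hits.sort_values(["fdr", "pathway"], kind="stable").reset_index(drop=True)


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Options shared by the command-line pipelines."""

    expression_paths: list[str] = field(default_factory=list)
    label_paths: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    method: str = "jointnormks"
    n_permutations: int = 100
    seed: int = 0
    fdr_cutoff: float = 0.1
    min_set_size: int = 15
    max_set_size: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValueError("fdr_cutoff must lie in (0, 1)")
        if not 0 < self.min_set_size < self.max_set_size:
            raise ValueError("set-size bounds must be positive with min < max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
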