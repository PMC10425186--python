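"""Build per-stage snapshot graphs from expression data and an interaction network.

This convenience stage reproduces a common construction for disease-stage
dynamic graphs: take a physical protein-interaction network, and for each
stage keep an interaction edge only when the two genes' expression
profiles are highly correlated over that stage's samples. One snapshot
per stage, ordered by stage label, gives a SnapshotGraphSet ready for
collapsing. The correlation statistic (absolute Pearson by default,
Spearman optional) and the threshold (default 0.7) are configurable; the
core algorithm never requires this module.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError
from .io import SnapshotGraphSet

logger = logging.getLogger(__name__)

__all__ = ["load_expression_tsv", "build_stage_snapshots"]


def load_expression_tsv(
    path: str | Path, stages_path: str | Path | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Load a genes-by-samples expression TSV plus per-sample stage labels.

    The first row holds sample IDs. Stage labels come either from a row
    indexed ``#stage`` inside the matrix or from a two-column side file
    (sample, stage).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if stages_path is not None:
        side = pd.read_csv(stages_path, sep="\t", header=None,
                           names=["sample", "stage"], index_col=0)
        stages = side["stage"].reindex(df.columns)
        if stages.isna().any():
            missing = list(stages[stages.isna()].index)
            raise InputError(f"{stages_path}: no stage label for samples {missing}")
    elif "#stage" in df.index:
        stages = df.loc["#stage"].astype(str)
        df = df.drop(index="#stage")
    else:
        raise InputError(
            f"{path}: stage labels required (a '#stage' row or a side file)"
        )
    return df.astype(float), stages.astype(str)


def _stage_correlations(values: np.ndarray, method: str) -> np.ndarray:
    """Row-standardise a genes-by-samples block for correlation by dot product."""
    if method == "spearman":
        values = pd.DataFrame(values).rank(axis=1).to_numpy()
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms > 0, centred / norms, np.nan)
    return unit


def build_stage_snapshots(
    expr: pd.DataFrame,
    stages: pd.Series | Mapping[str, str],
    net: nx.Graph,
    corr_threshold: float = 0.7,
    method: str = "pearson",
) -> SnapshotGraphSet:
    """One snapshot per stage: interaction edges with |corr| >= threshold.

    For each stage, the correlation between the two endpoint genes is
    computed over that stage's samples only; edges whose genes are missing
    from the matrix are skipped with a logged count, and a constant
    expression profile never passes the threshold (its correlation is
    undefined). Snapshots are ordered by the lexical order of stage labels.
    """
    if not 0.0 < corr_threshold <= 1.0:
        raise ConfigError(f"corr_threshold must lie in (0, 1], got {corr_threshold}")
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"method must be 'pearson' or 'spearman', got {method!r}")
    stages = pd.Series(stages)
    stages = stages.reindex(expr.columns)
    if stages.isna().any():
        raise ConfigError("every sample column needs a stage label")
    stage_labels = sorted(stages.unique())
    if len(stage_labels) < 2:
        raise ConfigError(f"need at least 2 stages, got {len(stage_labels)}")

    genes = set(expr.index)
    edges = [tuple(sorted((str(a), str(b)))) for a, b in net.edges() if a != b]
    usable = [(a, b) for a, b in edges if a in genes and b in genes]
    n_skipped = len(edges) - len(usable)
    if n_skipped:
        logger.warning("%d interaction edge(s) skipped: gene absent from the matrix",
                       n_skipped)
    needed_genes = sorted({g for e in usable for g in e})
    gene_row = {g: i for i, g in enumerate(needed_genes)}

    snapshots = []
    for label in stage_labels:
        cols = stages.index[stages == label]
        if len(cols) < 3:
            raise ConfigError(
                f"stage {label!r} has {len(cols)} sample(s); correlation needs >= 3"
            )
        block = expr.loc[needed_genes, cols].to_numpy(dtype=float) if needed_genes \
            else np.empty((0, len(cols)))
        unit = _stage_correlations(block, method)
        g = nx.Graph()
        for a, b in usable:
            r = float(np.dot(unit[gene_row[a]], unit[gene_row[b]]))
            if np.isfinite(r) and abs(r) >= corr_threshold - 1e-12:
                g.add_edge(a, b)
        snapshots.append(g)
    return SnapshotGraphSet(snapshots, [str(s) for s in stage_labels])
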