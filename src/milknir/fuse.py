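"""Unsupervised exploration and two-block data fusion.

Hierarchical cluster analysis (Ward or average linkage) is run either on
autoscaled PCA scores or on the full pre-treated data, and the k=3 cut is
compared against the EU fat classes (skimmed / semi-skimmed / whole) via a
majority-label agreement score; "no class" samples take part in the
clustering but are excluded from the score.

Fusion combines the two instruments before a single PLS model: low-level
fusion concatenates the pre-treated spectra column-wise and autoscales the
combined matrix; mid-level fusion concatenates the first few PCA scores of
each block (two per block by default) and autoscales those.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .exceptions import ConfigurationError, DegenerateDataError
from .io import SpectralBlock
from .multivariate import fit_pca
from .preprocess import PreprocessRecipe


@dataclass
class Dendrogram:
    """Agglomerative merge tree plus the representation it was built on."""

    merge_tree: np.ndarray         # scipy linkage matrix (n-1, 4)
    method: str
    representation: str
    sample_ids: list[str]

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (0-based) for a k-cluster cut."""
        if not 1 <= k <= len(self.sample_ids):
            raise ConfigurationError(f"k must be in [1, {len(self.sample_ids)}]")
        return fcluster(self.merge_tree, k, criterion="maxclust") - 1


def hca(X, method: str = "ward", metric: str = "euclidean",
        representation: str = "raw",
        sample_ids: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative hierarchical clustering of samples.

    Ward linkage requires the Euclidean metric.  ``X`` may be a matrix or a
    SpectralBlock; pass PCA scores for a scores-space clustering.
    """
    if method not in ("ward", "average"):
        raise ConfigurationError(f"unsupported linkage {method!r}")
    if method == "ward" and metric != "euclidean":
        raise ConfigurationError("Ward linkage requires the Euclidean metric")
    block = X if isinstance(X, SpectralBlock) else None
    M = np.atleast_2d(np.asarray(
        block.reflectance if block is not None else X, float))
    if M.shape[0] < 2:
        raise ConfigurationError("need at least 2 samples to cluster")
    ids = (block.sample_ids if block is not None else
           list(sample_ids) if sample_ids is not None else
           [str(i) for i in range(M.shape[0])])
    Z = linkage(M, method=method, metric=metric)
    return Dendrogram(Z, method, representation, ids)


def class_agreement(cluster_labels: np.ndarray, classes: Sequence[str],
                    exclude: str = "no-class") -> float:
    """Fraction of classed samples whose cluster majority matches their class.

    Each cluster is assigned the majority EU class among its classed
    members; samples of the excluded label do not count in majorities or in
    the score.
    """
    cluster_labels = np.asarray(cluster_labels)
    classes = np.asarray(classes)
    keep = classes != exclude
    if not keep.any():
        raise DegenerateDataError("no classed samples to score")
    correct = 0
    for c in np.unique(cluster_labels[keep]):
        members = keep & (cluster_labels == c)
        if not members.any():
            continue
        values, counts = np.unique(classes[members], return_counts=True)
        majority = values[np.argmax(counts)]
        correct += int(np.sum(classes[members] == majority))
    return correct / int(keep.sum())


def pca_scores_representation(block: SpectralBlock, n_pc: int = 2,
                              autoscale: bool = True) -> np.ndarray:
    """First n_pc PCA scores of a block, optionally autoscaled per column."""
    model = fit_pca(block.reflectance, n_pc)
    scores = model.scores
    if autoscale:
        sd = scores.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise DegenerateDataError("zero-variance score column")
        scores = scores / sd
    return scores


# ---------------------------------------------------------------------------
# Fusion

@dataclass
class FusedBlock:
    """Column-wise combination of several source blocks.

    ``column_map`` lists, per source, the column indices it occupies in the
    fused matrix; together they partition the columns.
    """

    mode: str                      # "low" | "mid"
    matrix: np.ndarray             # (n, p_total), autoscaled
    sample_ids: list[str]
    sources: list[str]
    column_map: dict[str, np.ndarray] = field(default_factory=dict)
    column_scale: np.ndarray | None = None
    column_mean: np.ndarray | None = None


def _check_alignment(blocks: Sequence[SpectralBlock]) -> list[str]:
    ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ids:
            raise ConfigurationError(
                "blocks are not row-aligned; run align_blocks first")
    return list(ids)


def _autoscale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    tol = 100 * np.finfo(float).eps * np.maximum(1.0, np.abs(mean))
    if np.any(sd <= tol):
        raise DegenerateDataError("zero-variance column in fused matrix")
    return (M - mean) / sd, mean, sd


def fuse_low(blocks: Sequence[SpectralBlock],
             recipes: Sequence[PreprocessRecipe | None] | None = None,
             ) -> FusedBlock:
    """Low-level fusion: per-block pre-treatment, concatenation, autoscaling.

    Each block is pre-treated by its own recipe (fitted on the block), the
    treated matrices are concatenated column-wise and the combined matrix is
    autoscaled as one — scaling after concatenation puts the instruments'
    different reflectance scales on an equal footing.
    """
    if len(blocks) < 2:
        raise ConfigurationError("fusion needs at least two blocks")
    ids = _check_alignment(blocks)
    recipes = recipes or [None] * len(blocks)
    if len(recipes) != len(blocks):
        raise ConfigurationError("one recipe (or None) per block required")
    treated = []
    for block, recipe in zip(blocks, recipes):
        treated.append(block if recipe is None else recipe.fit_apply(block))
    parts = [b.reflectance for b in treated]
    fused, mean, sd = _autoscale(np.hstack(parts))
    column_map, start = {}, 0
    for block, part in zip(blocks, parts):
        column_map[block.instrument] = np.arange(start, start + part.shape[1])
        start += part.shape[1]
    return FusedBlock("low", fused, ids, [b.instrument for b in blocks],
                      column_map, sd, mean)


def fuse_mid(blocks: Sequence[SpectralBlock],
             recipes: Sequence[PreprocessRecipe | None] | None = None,
             n_pc_per_block: int = 2) -> FusedBlock:
    """Mid-level fusion: per-block PCA scores concatenated, then autoscaled."""
    if n_pc_per_block < 1:
        raise ConfigurationError("n_pc_per_block must be >= 1")
    if len(blocks) < 2:
        raise ConfigurationError("fusion needs at least two blocks")
    ids = _check_alignment(blocks)
    recipes = recipes or [None] * len(blocks)
    if len(recipes) != len(blocks):
        raise ConfigurationError("one recipe (or None) per block required")
    parts = []
    for block, recipe in zip(blocks, recipes):
        treated = block if recipe is None else recipe.fit_apply(block)
        rank = np.linalg.matrix_rank(
            treated.reflectance - treated.reflectance.mean(axis=0))
        if n_pc_per_block > rank:
            raise DegenerateDataError(
                f"block {block.instrument!r} rank {rank} below "
                f"{n_pc_per_block} requested PCs")
        parts.append(fit_pca(treated.reflectance, n_pc_per_block).scores)
    fused, mean, sd = _autoscale(np.hstack(parts))
    column_map = {b.instrument: np.arange(i * n_pc_per_block,
                                          (i + 1) * n_pc_per_block)
                  for i, b in enumerate(blocks)}
    return FusedBlock("mid", fused, ids, [b.instrument for b in blocks],
                      column_map, sd, mean)
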