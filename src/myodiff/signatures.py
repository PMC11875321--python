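"""Marker-correlation matrices and type-1/2/3 inflammation summaries.

For each group, the top-k called overexpressed genes (ascending q versus
all samples) are correlated with the fixed muscle/leukocyte marker panels
across that group's samples. The inflammation summary is the per-group
median log-expression of the type-1/2/3 panel genes, with an optional
per-gene z-score view across group columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panels import GenePanel
from .types import GroupHierarchy, GeneSets, SampleAnnotation, ValidationError

logger = logging.getLogger(__name__)


def top_genes(sets: GeneSets, group: str, k: int = 15) -> list[str]:
    """First min(k, n) overexpressed genes of a group, in stored (q) order."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    over = sets.get(group, "over")
    if not over:
        logger.warning("group %s has an empty overexpressed set", group)
    return over[:k]


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # markers x genes; NaN marks undefined (constant input)
    group: str
    method: str
    n_samples: int


def _group_sample_ids(
    annotations: Sequence[SampleAnnotation], group: str, hierarchy: GroupHierarchy | None
) -> list[str]:
    if hierarchy is not None:
        return hierarchy.group_members(annotations, group)
    return [
        a.sample_id
        for a in annotations
        if a.clinical_group == group or a.autoantibody_subgroup == group
    ]


def marker_correlation(
    log_cpm: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    group: str,
    gene_list: Sequence[str],
    marker_sets: dict[str, tuple[str, ...]],
    method: str = "pearson",
    hierarchy: GroupHierarchy | None = None,
    within_group: bool = True,
) -> CorrelationMatrix:
    """Correlate each gene with each marker across the group's samples.

    Constant expression vectors give NaN (undefined), never 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    ids = (
        _group_sample_ids(annotations, group, hierarchy)
        if within_group
        else [a.sample_id for a in annotations]
    )
    if len(ids) < 3:
        raise ValidationError(f"group {group!r} has {len(ids)} samples; need >= 3")
    markers = []
    for genes in marker_sets.values():
        markers.extend(g for g in genes if g not in markers)
    missing = [g for g in list(gene_list) + markers if g not in log_cpm.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing}")
    sub = log_cpm.loc[:, ids]
    x = sub.loc[markers].to_numpy(float)
    y = sub.loc[list(gene_list)].to_numpy(float)
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
        y = np.apply_along_axis(stats.rankdata, 1, y)
    xs = x.std(axis=1)
    ys = y.std(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xc @ yc.T) / len(ids) / np.outer(xs, ys)
    corr[xs == 0, :] = np.nan
    corr[:, ys == 0] = np.nan
    values = pd.DataFrame(corr, index=markers, columns=list(gene_list))
    return CorrelationMatrix(
        values=values, group=group, method=method, n_samples=len(ids)
    )


@dataclass
class MedianExpressionMatrix:
    medians: pd.DataFrame       # genes x groups, median log-CPM
    zscores: pd.DataFrame       # per-gene z across group columns (0 when constant)
    gene_type: pd.Series        # inflammation type per gene row


def inflammation_median_matrix(
    log_cpm: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    panel: GenePanel,
    groups: Sequence[str],
    hierarchy: GroupHierarchy | None = None,
) -> MedianExpressionMatrix:
    """Median log-expression of the type-1/2/3 panel genes per group."""
    if not groups:
        raise ValidationError("no groups requested")
    genes: list[str] = []
    types: list[str] = []
    for t in ("type1", "type2", "type3"):
        for g in panel.type_genes(t):
            if g in log_cpm.index:
                genes.append(g)
                types.append(t)
    if not genes:
        raise ValidationError("panel contributes no typed genes present in the matrix")
    cols = {}
    for group in groups:
        ids = _group_sample_ids(annotations, group, hierarchy)
        if not ids:
            raise ValidationError(f"group {group!r} has zero samples")
        cols[group] = log_cpm.loc[genes, ids].median(axis=1)
    medians = pd.DataFrame(cols, index=genes)
    mu = medians.mean(axis=1)
    sd = medians.std(axis=1, ddof=0)
    z = medians.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return MedianExpressionMatrix(
        medians=medians, zscores=z, gene_type=pd.Series(types, index=genes)
    )
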