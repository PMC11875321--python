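"""Readers and writers for the pipeline's tabular artifacts.

All tables are plain text: counts as TSV (gene rows x sample columns) or
MatrixMarket with gene/sample index sidecars, annotations and gene-set
tables as TSV. UTF-8, tab delimited, no quoting; missing subgroup encoded
as the empty string. Floats are written with 6 significant digits.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    CountMatrix,
    GeneSets,
    GroupHierarchy,
    SampleAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.samples.txt")


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a genes x samples count matrix.

    ``tsv``: header row of sample ids, first column gene ids.
    ``mtx``: MatrixMarket file with ``<stem>.genes.txt`` / ``<stem>.samples.txt``
    sidecars (one id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
        if df.columns.size == 0 or df.index.name is None and df.empty:
            raise ValidationError(f"{path}: malformed header")
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ValidationError(f"{path}: non-numeric column {col!r}")
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(s) for s in df.columns]
        counts = df.to_numpy()
    elif format in ("mtx", "mtx+indices"):
        genes_path, samples_path = _mtx_sidecars(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise FileNotFoundError(f"missing index sidecar {p}")
        mat = scipy.io.mmread(path)
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids = genes_path.read_text().splitlines()
        sample_ids = samples_path.read_text().splitlines()
    else:
        raise ValueError(f"unknown count format {format!r}")
    return CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts)


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
    elif format in ("mtx", "mtx+indices"):
        genes_path, samples_path = _mtx_sidecars(path)
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(cm.counts), field="integer")
        genes_path.write_text("\n".join(cm.gene_ids) + "\n")
        samples_path.write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count format {format!r}")


ANNOTATION_COLUMNS = ["sample_id", "clinical_group", "autoantibody_subgroup"]


def read_annotations(
    path: str | Path, hierarchy: GroupHierarchy
) -> list[SampleAnnotation]:
    """Read and validate a sample annotation TSV against the hierarchy."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing annotation columns {missing}")
    annotations = []
    for row in df.itertuples(index=False):
        sub = row.autoantibody_subgroup or None
        ann = SampleAnnotation(
            sample_id=row.sample_id,
            clinical_group=row.clinical_group,
            autoantibody_subgroup=sub,
        )
        hierarchy.validate_annotation(ann)
        annotations.append(ann)
    ids = [a.sample_id for a in annotations]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s, n in Counter(ids).items() if n > 1})
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    sizes = Counter(a.clinical_group for a in annotations)
    logger.info("annotation group sizes: %s (total %d)", dict(sizes), len(annotations))
    return annotations


def write_annotations(
    annotations: Sequence[SampleAnnotation], path: str | Path
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "clinical_group": [a.clinical_group for a in annotations],
            "autoantibody_subgroup": [a.autoantibody_subgroup or "" for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_gene_set_table(sets: GeneSets, path: str | Path) -> None:
    """Write per-group gene sets as TSV (group, direction, rank, gene).

    Rank is the 1-based position within a cell and preserves the input
    ordering (ascending q-value where the sets came from a DE run).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for group in sets.groups():
        for direction in ("over", "under"):
            for rank, gene in enumerate(sets.get(group, direction), start=1):
                rows.append((group, direction, rank, gene))
    df = pd.DataFrame(rows, columns=["group", "direction", "rank", "gene"])
    df.to_csv(path, sep="\t", index=False)


def read_gene_set_table(path: str | Path) -> GeneSets:
    df = pd.read_csv(Path(path), sep="\t", dtype={"group": str, "gene": str})
    expected = ["group", "direction", "rank", "gene"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    sets = GeneSets()
    for (group, direction), sub in df.groupby(["group", "direction"], sort=False):
        genes = list(sub.sort_values("rank")["gene"])
        if direction == "over":
            sets.over[group] = genes
        elif direction == "under":
            sets.under[group] = genes
        else:
            raise ValidationError(f"{path}: unknown direction {direction!r}")
    return GeneSets(over=sets.over, under=sets.under)


def write_matrix(
    df: pd.DataFrame, path: str | Path, index_name: str = "gene"
) -> None:
    """Write a real-valued matrix (e.g. log-CPM) with 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=0)
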