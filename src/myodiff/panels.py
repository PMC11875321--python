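"""Gene panel configuration: the analyzed gene list with category labels,
optional type-1/2/3 inflammation flags, and the named marker panels used by
the correlation heatmaps.

The full 338-gene panel is study configuration supplied by the user; the
packaged default is a stand-in built from the published differential
expression tables plus the marker genes, with heuristic category labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .types import CountMatrix, ValidationError, _duplicates

logger = logging.getLogger(__name__)

CATEGORIES = ("cytokine", "cytokine_receptor", "immune_checkpoint")
INFLAMMATION_TYPES = ("type1", "type2", "type3")

#: Marker panels in display order (correlation heatmap row order).
MARKER_SETS: dict[str, tuple[str, ...]] = {
    "mature_muscle": ("ACTA1", "MYH1", "MYH2"),
    "regeneration": ("NCAM1", "MYOG", "PAX7", "MYH3", "MYH8"),
    "mitochondrial": ("MT-CO1", "MT-CO2"),
    "B_cell": ("CD19", "MS4A1"),
    "T_cell": ("CD3E", "CD4", "CD8A"),
    "macrophage": ("CD14", "CD68"),
    "dendritic": ("CD1C", "CD1E"),
    "type1_markers": ("TBX21", "STAT1"),
    "type2_markers": ("GATA3", "STAT6"),
    "type3_markers": ("RORC", "STAT3"),
}


@dataclass
class GenePanel:
    """The analyzed gene list plus marker panels."""

    genes: list[str]
    category: dict[str, str] = field(default_factory=dict)
    inflammation_type: dict[str, str] = field(default_factory=dict)
    marker_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(MARKER_SETS)
    )

    def __post_init__(self) -> None:
        dup = _duplicates(self.genes)
        if dup:
            raise ValidationError(f"duplicate genes in panel: {sorted(dup)}")
        universe = set(self.genes)
        for g, c in self.category.items():
            if c not in CATEGORIES:
                raise ValidationError(f"unknown category {c!r} for gene {g!r}")
            if g not in universe:
                raise ValidationError(f"category assigned to non-panel gene {g!r}")
        for g, t in self.inflammation_type.items():
            if t not in INFLAMMATION_TYPES:
                raise ValidationError(f"unknown inflammation type {t!r} for gene {g!r}")

    def type_genes(self, inflammation_type: str) -> list[str]:
        return [g for g in self.genes if self.inflammation_type.get(g) == inflammation_type]

    def marker_genes(self) -> list[str]:
        """All marker genes in panel display order (markers need not be panel members)."""
        out: list[str] = []
        for genes in self.marker_sets.values():
            out.extend(g for g in genes if g not in out)
        return out

    def missing_from(self, counts: CountMatrix) -> list[str]:
        """Panel genes absent from a count matrix; reported, never silently dropped."""
        present = set(counts.gene_ids)
        missing = [g for g in self.genes if g not in present]
        if missing:
            logger.warning("%d panel genes missing from count matrix: %s", len(missing), missing)
        return missing


def _guess_category(gene: str) -> str:
    checkpoints = {
        "CD274", "PDCD1", "PDCD1LG2", "CTLA4", "CD80", "CD86", "CD28",
        "CD40", "CD40LG", "CD70", "CD27",
    }
    if gene in checkpoints:
        return "immune_checkpoint"
    if (
        gene.endswith(("R", "RA", "RB", "RG", "R1", "R2", "R3", "RAP", "RL1", "RL2"))
        or "RSF" in gene
        or gene.startswith(("CCR", "CXCR", "XCR", "ACKR", "IFNAR", "IFNGR", "IL10RB"))
        or gene.endswith(("RB1", "RB2", "RA1"))
    ):
        return "cytokine_receptor"
    return "cytokine"


# Type-1/2/3 stand-in flags, drawn from the published marker discussion.
_TYPE_FLAGS = {
    "type1": (
        "CCL4", "CCL5", "CCR5", "CXCL9", "CXCL10", "CXCL11", "CXCR3", "IFNG",
        "IL27", "LTA", "IL12RB2", "TNFRSF1A", "IL18", "IL18R1", "EBI3", "IL12B",
    ),
    "type2": (
        "TNFRSF25", "TNFRSF4", "AREG", "CCL11", "IL13RA1", "CCL17", "IL5RA",
        "TSLP", "IL1RL1",
    ),
    "type3": ("IL22RA1", "CCL20", "IL17B", "IL23A", "IL17RA"),
}


def default_panel(extra_genes: Sequence[str] = ()) -> GenePanel:
    """Stand-in analysis panel: published DE-table genes plus markers."""
    from .fixtures import load_table2_fixture

    t2 = load_table2_fixture()
    genes: list[str] = []
    for group in t2.groups():
        for direction in ("over", "under"):
            for g in t2.get(group, direction):
                if g not in genes:
                    genes.append(g)
    for g in extra_genes:
        if g not in genes:
            genes.append(g)
    category = {g: _guess_category(g) for g in genes}
    inflammation_type = {
        g: t for t, gs in _TYPE_FLAGS.items() for g in gs if g in genes
    }
    return GenePanel(genes=genes, category=category, inflammation_type=inflammation_type)


def read_panel(path: str | Path) -> GenePanel:
    """Read a panel config (YAML): per-gene category/type plus marker sets."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "genes" not in raw:
        raise ValidationError(f"{path}: panel config must map 'genes' to a list")
    genes, category, itype = [], {}, {}
    for entry in raw["genes"]:
        if isinstance(entry, str):
            genes.append(entry)
            continue
        name = entry["gene"]
        genes.append(name)
        if entry.get("category"):
            category[name] = entry["category"]
        if entry.get("inflammation_type"):
            itype[name] = entry["inflammation_type"]
    marker_sets = {
        k: tuple(v) for k, v in raw.get("marker_sets", MARKER_SETS).items()
    }
    return GenePanel(
        genes=genes, category=category, inflammation_type=itype, marker_sets=marker_sets
    )


def write_panel(panel: GenePanel, path: str | Path) -> None:
    entries = []
    for g in panel.genes:
        entry: dict[str, Optional[str]] = {"gene": g}
        if g in panel.category:
            entry["category"] = panel.category[g]
        if g in panel.inflammation_type:
            entry["inflammation_type"] = panel.inflammation_type[g]
        entries.append(entry)
    payload = {
        "genes": entries,
        "marker_sets": {k: list(v) for k, v in panel.marker_sets.items()},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
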