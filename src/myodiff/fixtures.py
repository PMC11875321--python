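"""Packaged reference gene-set tables.

``table2.tsv`` holds the published per-group differentially over/under
expressed gene lists (in printed q-value order); ``table3.tsv`` holds the
published group-specific subsets. Both are packaged verbatim, including the
opaque identifier ``ENSG00000198223.17``.
"""

from __future__ import annotations

from importlib import resources

from .io import read_gene_set_table
from .types import GeneSets


def _load(name: str) -> GeneSets:
    ref = resources.files("myodiff.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_gene_set_table(path)


def load_table2_fixture() -> GeneSets:
    """Per-group called DE gene lists (all analyzed groups + NT)."""
    return _load("table2.tsv")


def load_table3_fixture() -> GeneSets:
    """Published group-specific gene lists (analyzed groups only)."""
    return _load("table3.tsv")
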