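"""Hierarchy-aware group-specificity classification of DE results.

A gene is called for a myositis group when it passes q < alpha in both the
one-vs-rest and vs-control contrasts with the same fold-change sign; the
control group's own set uses the single vs-rest contrast. Called sets are
then collapsed to families (clinical group union its subgroups), carved
into exclusive Venn regions, and reduced to group-specific sets: a clinical
group keeps a gene only if no group outside its family also calls it, and a
subgroup keeps a gene only if no group other than itself and its parent
calls it (sibling subgroups disqualify). Control-group sets never
disqualify, and over/under directions are classified independently.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .de import DEResult
from .types import GeneSets, GroupHierarchy, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecificityConfig:
    alpha: float = 0.001
    require_sign_agreement: bool = True
    nt_excluded_from_specificity: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")


def _ordered_calls(
    result: DEResult, mask: np.ndarray, ascending_by: np.ndarray
) -> list[str]:
    idx = np.flatnonzero(mask)
    return [result.genes[i] for i in idx[np.argsort(ascending_by[idx], kind="mergesort")]]


def call_group_sets(
    de_vs_rest: DEResult,
    de_vs_nt: DEResult,
    config: SpecificityConfig = SpecificityConfig(),
) -> tuple[list[str], list[str]]:
    """(over, under) gene lists passing both contrasts, ordered by q vs rest."""
    if de_vs_rest.genes != de_vs_nt.genes:
        raise ValidationError("contrast results cover different gene universes")
    a = config.alpha
    sig = (de_vs_rest.q < a) & (de_vs_nt.q < a)
    over = sig & (de_vs_rest.log2fc > 0) & (de_vs_nt.log2fc > 0)
    under = sig & (de_vs_rest.log2fc < 0) & (de_vs_nt.log2fc < 0)
    if config.require_sign_agreement:
        discordant = sig & ~over & ~under
        if discordant.any():
            genes = [de_vs_rest.genes[i] for i in np.flatnonzero(discordant)]
            logger.info(
                "%s: %d significant genes with discordant fold-change signs "
                "excluded: %s", de_vs_rest.contrast, len(genes), genes,
            )
    return (
        _ordered_calls(de_vs_rest, over, de_vs_rest.q),
        _ordered_calls(de_vs_rest, under, de_vs_rest.q),
    )


def call_nt_sets(
    de_vs_rest: DEResult, config: SpecificityConfig = SpecificityConfig()
) -> tuple[list[str], list[str]]:
    """Control-group sets from the single vs-rest contrast."""
    a = config.alpha
    over = (de_vs_rest.q < a) & (de_vs_rest.log2fc > 0)
    under = (de_vs_rest.q < a) & (de_vs_rest.log2fc < 0)
    return (
        _ordered_calls(de_vs_rest, over, de_vs_rest.q),
        _ordered_calls(de_vs_rest, under, de_vs_rest.q),
    )


def collapse_families(
    sets: GeneSets, hierarchy: GroupHierarchy
) -> dict[str, dict[str, frozenset[str]]]:
    """Family label -> {'over': union set, 'under': union set}."""
    out: dict[str, dict[str, frozenset[str]]] = {}
    for clinical, members in hierarchy.families().items():
        out[clinical] = {
            direction: frozenset(
                g for m in members for g in sets.get(m, direction)
            )
            for direction in ("over", "under")
        }
    return out


def venn_exclusive_regions(
    family_sets: Mapping[str, frozenset[str] | set[str]],
) -> dict[frozenset[str], frozenset[str]]:
    """Exclusive region per nonempty family subset S:
    (intersection over S) minus (union outside S)."""
    names = list(family_sets)
    regions: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = frozenset.intersection(
                *(frozenset(family_sets[f]) for f in combo)
            )
            outside = frozenset(
                g for f in names if f not in combo for g in family_sets[f]
            )
            regions[frozenset(combo)] = inside - outside
    return regions


def extract_specific(
    sets: GeneSets,
    hierarchy: GroupHierarchy,
    config: SpecificityConfig = SpecificityConfig(),
) -> GeneSets:
    """Group-specific gene sets, per direction independently.

    Input ordering (ascending q) is preserved within each output cell.
    Control-group sets are ignored when ``nt_excluded_from_specificity``.
    """
    families = hierarchy.families()
    specific = GeneSets()
    for group in hierarchy.analyzed_groups:
        if hierarchy.is_clinical(group):
            allowed = set(families[group])
        else:
            allowed = {group, hierarchy.parent_of[group]}
        disqualifiers = [h for h in hierarchy.analyzed_groups if h not in allowed]
        if not config.nt_excluded_from_specificity:
            disqualifiers.append(hierarchy.control_group)
        for direction, target in (("over", specific.over), ("under", specific.under)):
            own = sets.get(group, direction)
            if not own:
                continue
            blocked = {g for h in disqualifiers for g in sets.get(h, direction)}
            kept = [g for g in own if g not in blocked]
            if kept:
                target[group] = kept
    return GeneSets(over=specific.over, under=specific.under)
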