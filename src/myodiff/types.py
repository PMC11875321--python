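"""Core domain types: count matrices, sample annotations, the group hierarchy,
and per-group gene sets.

The group hierarchy models myositis clinical groups (DM, IMNM, ASyS, IBM,
PM/Scl), their autoantibody subgroups (Mi2/MDA5/NXP2/TIF1 under DM,
HMGCR/SRP under IMNM, Jo1 under ASyS, PM/Scl under itself), two
background-only groups that contribute samples to "all samples" contrasts
but are never analyzed on their own, and the normal-tissue control group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input artifact violates a documented invariant."""


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValidationError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {sorted(dup_s)}")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.isnan(self.counts.astype(float)).any():
            g, s = np.argwhere(np.isnan(self.counts.astype(float)))[0]
            raise ValidationError(
                f"NaN count for gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if not np.allclose(self.counts, np.round(self.counts.astype(float))):
            raise ValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            j = int(np.argmax(totals == 0))
            raise ValidationError(f"sample {self.sample_ids[j]!r} has total count 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}


@dataclass(frozen=True)
class SampleAnnotation:
    """One biopsy sample: its clinical group and optional autoantibody subgroup."""

    sample_id: str
    clinical_group: str
    autoantibody_subgroup: Optional[str] = None


# Canonical group labels.
DM, IMNM, ASYS, IBM, PMSCL = "DM", "IMNM", "ASyS", "IBM", "PM/Scl"
MI2, MDA5, NXP2, TIF1 = "Mi2", "MDA5", "NXP2", "TIF1"
HMGCR, SRP, JO1 = "HMGCR", "SRP", "Jo1"
OTHER_INFLAMMATORY, GENETIC, NT = "OTHER_INFLAMMATORY", "GENETIC", "NT"
OTHER_SUBGROUP = "other"


@dataclass(frozen=True)
class GroupHierarchy:
    """Analyzed groups, subgroup->parent mapping, background groups, control."""

    analyzed_groups: tuple[str, ...] = (
        DM, MI2, MDA5, NXP2, TIF1, IMNM, HMGCR, SRP, ASYS, JO1, IBM, PMSCL,
    )
    parent_of: Mapping[str, str] = field(
        default_factory=lambda: {
            MI2: DM, MDA5: DM, NXP2: DM, TIF1: DM,
            HMGCR: IMNM, SRP: IMNM, JO1: ASYS, PMSCL: PMSCL,
        }
    )
    background_groups: frozenset[str] = frozenset({OTHER_INFLAMMATORY, GENETIC})
    control_group: str = NT

    def __post_init__(self) -> None:
        for sub, parent in self.parent_of.items():
            if sub not in self.analyzed_groups or parent not in self.analyzed_groups:
                raise ValidationError(f"subgroup mapping {sub}->{parent} outside analyzed groups")
        bad = (set(self.background_groups) | {self.control_group}) & set(self.analyzed_groups)
        if bad:
            raise ValidationError(f"background/control groups cannot be analyzed: {sorted(bad)}")
        # every analyzed group is either a clinical group or maps to one
        for g in self.analyzed_groups:
            if g not in self.clinical_groups and g not in self.parent_of:
                raise ValidationError(f"group {g!r} is neither clinical nor a mapped subgroup")

    @property
    def clinical_groups(self) -> tuple[str, ...]:
        subs_only = {s for s, p in self.parent_of.items() if s != p}
        return tuple(g for g in self.analyzed_groups if g not in subs_only)

    @property
    def subgroups(self) -> tuple[str, ...]:
        return tuple(g for g in self.analyzed_groups if g in self.parent_of)

    def families(self) -> dict[str, frozenset[str]]:
        """Clinical group -> {itself} | its subgroups."""
        fams = {g: {g} for g in self.clinical_groups}
        for sub, parent in self.parent_of.items():
            fams[parent].add(sub)
        return {g: frozenset(ms) for g, ms in fams.items()}

    def family_of(self, group: str) -> str:
        if group in self.parent_of:
            return self.parent_of[group]
        if group in self.clinical_groups:
            return group
        raise KeyError(group)

    def is_clinical(self, group: str) -> bool:
        return group in self.clinical_groups

    def all_groups(self) -> frozenset[str]:
        return frozenset(self.analyzed_groups) | self.background_groups | {self.control_group}

    def validate_annotation(self, ann: SampleAnnotation) -> None:
        known_clinical = set(self.clinical_groups) | self.background_groups | {self.control_group}
        if ann.clinical_group not in known_clinical:
            raise ValidationError(
                f"sample {ann.sample_id!r}: unknown clinical group {ann.clinical_group!r}"
            )
        sub = ann.autoantibody_subgroup
        if sub is None or sub == OTHER_SUBGROUP:
            return
        if sub not in self.parent_of:
            raise ValidationError(f"sample {ann.sample_id!r}: unknown subgroup {sub!r}")
        if self.parent_of[sub] != ann.clinical_group:
            raise ValidationError(
                f"sample {ann.sample_id!r}: subgroup {sub!r} is inconsistent with "
                f"clinical group {ann.clinical_group!r} (parent is {self.parent_of[sub]!r})"
            )

    def group_members(
        self, annotations: Sequence[SampleAnnotation], group: str
    ) -> list[str]:
        """Sample ids belonging to a group.

        Clinical-group membership includes the group's subgroup samples
        (they carry the clinical group label); subgroup membership matches
        the subgroup field.
        """
        if group in self.parent_of and group not in self.clinical_groups:
            return [a.sample_id for a in annotations if a.autoantibody_subgroup == group]
        return [a.sample_id for a in annotations if a.clinical_group == group]


DEFAULT_HIERARCHY = GroupHierarchy()


@dataclass
class GeneSets:
    """Per-group over/underexpressed gene lists, ordered (ascending q where known).

    Shared shape for called DE sets (Table-2 style) and specificity tables
    (Table-3 style).
    """

    over: dict[str, list[str]] = field(default_factory=dict)
    under: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for direction, mapping in (("over", self.over), ("under", self.under)):
            for group, genes in mapping.items():
                dup = _duplicates(genes)
                if dup:
                    raise ValidationError(
                        f"duplicate genes in {group} {direction} set: {sorted(dup)}"
                    )
        for group in set(self.over) & set(self.under):
            clash = set(self.over[group]) & set(self.under[group])
            if clash:
                raise ValidationError(
                    f"genes in both over and under sets for {group}: {sorted(clash)}"
                )

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in list(self.over) + list(self.under):
            seen.setdefault(g)
        return list(seen)

    def get(self, group: str, direction: str) -> list[str]:
        if direction not in ("over", "under"):
            raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
        return (self.over if direction == "over" else self.under).get(group, [])


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups
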