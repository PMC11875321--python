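from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from myodiff import (
    DEFAULT_HIERARCHY,
    GeneSets,
    PlantedEffect,
    SpecificityConfig,
    build_contrasts,
    call_group_sets,
    call_nt_sets,
    extract_specific,
    fit_moderated,
    load_table2_fixture,
    load_table3_fixture,
    make_table1_scenario,
    normalize,
    simulate_counts,
)


@pytest.fixture(scope="session")
def hierarchy():
    return DEFAULT_HIERARCHY


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def table3():
    return load_table3_fixture()


@pytest.fixture(scope="session")
def scenario_run():
    """One default study-shaped scenario with normalized expression."""
    config = make_table1_scenario(scale=0.25, seed=1)
    counts, annotations, truth = simulate_counts(config)
    result = normalize(counts)
    return config, counts, annotations, truth, result


def run_classifier_pipeline(config, hierarchy=DEFAULT_HIERARCHY,
                            alpha: float = 0.001):
    """simulate -> TMM log-CPM -> dual contrasts -> called sets -> specific sets."""
    counts, annotations, truth = simulate_counts(config)
    logcpm = normalize(counts).log_cpm
    spec_config = SpecificityConfig(alpha=alpha)
    sets = GeneSets()
    for group in hierarchy.analyzed_groups:
        vs_rest, vs_nt = build_contrasts(annotations, hierarchy, group)
        over, under = call_group_sets(
            fit_moderated(logcpm, vs_rest), fit_moderated(logcpm, vs_nt), spec_config
        )
        sets.over[group], sets.under[group] = over, under
    nt_rest, _ = build_contrasts(annotations, hierarchy, hierarchy.control_group)
    nt_over, nt_under = call_nt_sets(fit_moderated(logcpm, nt_rest), spec_config)
    sets.over[hierarchy.control_group] = nt_over
    sets.under[hierarchy.control_group] = nt_under
    specific = extract_specific(sets, hierarchy, spec_config)
    return truth, sets, specific


def planted_lfc3_config(seed: int):
    """Study-shaped scenario, planted effects raised to log2FC = 3 and the
    latent factors disabled: unplanted genes are genuinely null and the
    planted signal is not masked by infiltration/regeneration variance."""
    config = make_table1_scenario(scale=0.25, seed=seed)
    effects = [replace(e, log2fc=3.0) for e in config.planted_effects]
    return replace(
        config,
        planted_effects=effects,
        infiltration_loadings={},
        regeneration_loadings={},
        infiltration_group_shift={},
        regeneration_group_shift={},
    )


@pytest.fixture(scope="session")
def specificity_runs():
    """20-seed end-to-end classifier runs at planted log2FC = 3, scale 0.25."""
    return [run_classifier_pipeline(planted_lfc3_config(seed)) for seed in range(20)]


#: family membership of each planting target label
FAMILY_OF_LABEL = {
    "IBM": "IBM", "DM": "DM", "Jo1": "ASyS", "PM/Scl": "PM/Scl", "IMNM": "IMNM",
}


def single_family_planted(truth):
    """gene -> target label, for genes planted in exactly one family."""
    fam_by_gene: dict[str, set[str]] = {}
    label_by_gene: dict[str, str] = {}
    for label, genes in truth.planted.items():
        for g in genes:
            fam_by_gene.setdefault(g, set()).add(FAMILY_OF_LABEL[label])
            label_by_gene[g] = label
    return {g: label_by_gene[g] for g, fams in fam_by_gene.items() if len(fams) == 1}
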