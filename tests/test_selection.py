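import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acadscreen import (SimulationConfig, SubgroupConsensusSelector,
                        consensus_select, expand_ratios, generate_cohort,
                        partition_subgroups, plant_marker_scenario,
                        split_model_testing)
from acadscreen.errors import ValidationError


def test_split_sizes_disjoint_exhaustive(small_cohort):
    model, testing = split_model_testing(small_cohort, 300, seed=4)
    assert len(model) == 300 and len(testing) == 200
    ids_m, ids_t = set(model.data["id"]), set(testing.data["id"])
    assert not ids_m & ids_t
    assert ids_m | ids_t == set(small_cohort.data["id"])


def test_split_determinism_and_seed_sensitivity(small_cohort):
    m1, _ = split_model_testing(small_cohort, 250, seed=8)
    m2, _ = split_model_testing(small_cohort, 250, seed=8)
    m3, _ = split_model_testing(small_cohort, 250, seed=9)
    assert m1.data["id"].tolist() == m2.data["id"].tolist()
    assert m1.data["id"].tolist() != m3.data["id"].tolist()


def test_split_rejects_oversized_model(small_cohort):
    with pytest.raises(ValidationError):
        split_model_testing(small_cohort, len(small_cohort), seed=0)


def test_stratified_split_forces_single_case():
    cfg = SimulationConfig(n=60, prevalence={}, seed=2)
    cohort = generate_cohort(cfg)
    cohort.data.loc[0, "label"] = "VLCAD"  # exactly one case
    for seed in range(10):
        model, _ = split_model_testing(cohort, 30, seed=seed, stratify=True)
        assert (model.labels == "VLCAD").sum() == 1


def test_partition_exact_sizes_disjoint(small_cohort):
    subs = partition_subgroups(small_cohort, 20, 10, seed=3)
    assert len(subs) == 20
    all_ids = [i for s in subs for i in s.data["id"]]
    assert len(all_ids) == len(set(all_ids)) == 200
    assert all(len(s) == 10 for s in subs)


def test_partition_leftovers_and_infeasible(small_cohort):
    subs = partition_subgroups(small_cohort, 10, 41, seed=1)
    assert sum(len(s) for s in subs) == 410  # 90 leftover unused
    with pytest.raises(ValidationError):
        partition_subgroups(small_cohort, 10, 51, seed=1)


def test_partition_determinism(small_cohort):
    a = partition_subgroups(small_cohort, 5, 20, seed=6)
    b = partition_subgroups(small_cohort, 5, 20, seed=6)
    for s1, s2 in zip(a, b):
        assert s1.data["id"].tolist() == s2.data["id"].tolist()


# ----------------------------------------------------------------------
# consensus filter


def test_consensus_examples():
    sel, counts = consensus_select([{"A", "B"}, {"A"}, {"C"}], 2)
    assert sel == ["A"] and counts == {"A": 2, "B": 1, "C": 1}
    union, _ = consensus_select([{"A", "B"}, {"A"}, {"C"}], 1)
    assert set(union) == {"A", "B", "C"}


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    membership=st.lists(
        st.lists(st.integers(min_value=0, max_value=8), max_size=6),
        min_size=1, max_size=8),
    k=st.integers(min_value=1, max_value=5),
)
def test_consensus_matches_brute_force_count(membership, k):
    sets = [set(m) for m in membership]
    got, counts = consensus_select(sets, k)
    everything = {f for s in sets for f in s}
    expected = {f for f in everything
                if sum(f in s for s in sets) >= k}
    assert set(got) == expected
    for f in everything:
        assert counts[f] == sum(f in s for s in sets)


# ----------------------------------------------------------------------
# full protocol


def _planted_cohort(seed, n=8000, cases=16):
    cfg = plant_marker_scenario(SimulationConfig(n=n, seed=seed),
                                "C4", "C5DC+C6-OH", fold=10.0)
    cfg.prevalence = {"SCAD": cases / n}
    return generate_cohort(cfg)


def test_pipeline_nesting_invariant():
    cohort = _planted_cohort(seed=31)
    fm = expand_ratios(cohort, scale="log")
    y = (cohort.labels != "none").astype(int).to_numpy()
    sel = SubgroupConsensusSelector(n_subgroups=4, subgroup_size=2000,
                                    seed=31).fit(fm.values, y)
    assert set(sel.final_features_) <= set(sel.consensus_)
    assert set(sel.consensus_) <= set(sel.union_)
    union_check = {f for s in sel.subgroup_selections_ for f in s}
    assert set(sel.union_) == union_check


def test_degenerate_subgroups_do_not_abort():
    """With very few cases most subgroups contain none; they contribute
    empty selections and the run completes."""
    cohort = _planted_cohort(seed=13, n=6000, cases=3)
    fm = expand_ratios(cohort, scale="log")
    y = (cohort.labels != "none").astype(int).to_numpy()
    sel = SubgroupConsensusSelector(n_subgroups=6, subgroup_size=1000,
                                    seed=13).fit(fm.values, y)
    assert len(sel.degenerate_subgroups_) >= 1
    for g in sel.degenerate_subgroups_:
        assert sel.subgroup_selections_[g] == []


def test_orientation_invariance_under_log_scale():
    """Reversing panel order flips every canonical ratio; the selected
    channel pairs must be identical."""
    from acadscreen.cohort import CohortTable
    from acadscreen.panel import AnalytePanel, Channel

    cohort = _planted_cohort(seed=77, n=6000, cases=14)
    rev_panel = AnalytePanel(tuple(reversed(cohort.panel.channels)),
                             version="reversed")
    rev_data = cohort.data.copy()
    cohort_rev = CohortTable(panel=rev_panel, data=rev_data)

    y = (cohort.labels != "none").astype(int).to_numpy()

    def pairs(cohort_):
        fm = expand_ratios(cohort_, scale="log")
        sel = SubgroupConsensusSelector(n_subgroups=3, subgroup_size=2000,
                                        seed=5).fit(fm.values, y)
        return {frozenset(_split_ratio(f, cohort_.panel))
                for f in sel.final_features_}

    assert pairs(cohort) == pairs(cohort_rev)


def _split_ratio(name, panel):
    from acadscreen.features import parse_feature_name
    parsed = parse_feature_name(name, panel)
    if parsed[0] == "channel":
        return (name,)
    _, i, j, _ = parsed
    return (panel.names[i], panel.names[j])


def test_per_condition_recovery_and_assignment_three_planted_markers():
    """Three conditions, each with its own planted ratio: one-vs-rest
    selection recovers each condition's marker, and the standardized-
    separation heuristic attributes each marker to its condition."""
    from acadscreen import EffectProfile
    from acadscreen.selection import assign_conditions

    cfg = SimulationConfig(
        n=18_000,
        prevalence={"SCAD": 1.2e-3, "MCAD": 1.2e-3, "VLCAD": 1.2e-3},
        effect_profiles={
            "SCAD": EffectProfile("SCAD",
                                  {"C4": 10 ** 0.5, "C5DC+C6-OH": 10 ** -0.5},
                                  dispersion=0.2),
            "MCAD": EffectProfile("MCAD",
                                  {"C8": 10 ** 0.5, "C8:1": 10 ** -0.5},
                                  dispersion=0.2),
            "VLCAD": EffectProfile("VLCAD",
                                   {"C14:1": 10 ** 0.5, "C16-OH": 10 ** -0.5},
                                   dispersion=0.2),
        },
        seed=55,
    )
    cohort = generate_cohort(cfg)
    fm = expand_ratios(cohort, scale="log")
    labels = cohort.labels.to_numpy()
    expected = {"C4/C5DC+C6-OH": "SCAD", "C8/C8:1": "MCAD",
                "C14:1/C16-OH": "VLCAD"}
    for marker, cond in expected.items():
        y = (labels == cond).astype(int)
        sel = SubgroupConsensusSelector(n_subgroups=9, subgroup_size=2000,
                                        seed=55).fit(fm.values, y)
        assert marker in sel.final_features_, cond
    assignment = assign_conditions(fm.values[list(expected)], labels)
    assert assignment == expected
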