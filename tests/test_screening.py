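import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from acadscreen import (confusion_metrics, default_rules, expand_ratios,
                        incidence_string, mcnemar_paired, optimal_ppv_cutoff,
                        reference_cases, round_half_up)
from acadscreen.errors import ValidationError
from acadscreen.screening import (OptimalPPVCutoff, evaluate_indicators,
                                  parse_incidence, rules_from_yaml)


# ----------------------------------------------------------------------
# rule engine on the confirmed-case fixture values


def test_all_vlcad_cases_positive_via_criterion_one():
    rule = default_rules()["VLCAD"]
    for case in reference_cases("VLCAD"):
        crit = rule.criterion_results(case.initial)
        assert crit[0], f"case {case.case_no} should satisfy criterion I"


def test_scad_case8_positive_via_criterion_two_only():
    rule = default_rules()["SCAD"]
    case8 = reference_cases("SCAD")[7]
    assert case8.initial["C4"] == 0.51
    crit = rule.criterion_results(case8.initial)
    assert crit == [False, True]


def test_mcad_case4_flips_with_boundary_mode():
    """The case sitting exactly on the C6 cutoff is screen-positive only
    under inclusive boundary comparison."""
    case4 = reference_cases("MCAD")[3]
    assert case4.initial["C6"] == 0.09
    strict = default_rules("strict")["MCAD"]
    inclusive = default_rules("inclusive")["MCAD"]
    assert strict.criterion_results(case4.initial) == [False, False]
    assert inclusive.criterion_results(case4.initial) == [False, True]


def test_all_zero_panel_negative_under_every_rule(panel):
    zeros = {name: 0.0 for name in panel.names}
    for rule in default_rules().values():
        assert not rule.apply(zeros)


def test_ratio_clause_derivable_from_channels():
    rule = default_rules()["SCAD"]
    # C4/C2 not given directly; derived from the channel values
    assert rule.apply({"C4": 0.6, "C2": 10.0})          # ratio 0.06 > 0.03
    assert not rule.apply({"C4": 0.6, "C2": 30.0})      # ratio 0.02


def test_rules_yaml_round_trip(tmp_path):
    import yaml
    doc = {
        "SCAD": {"criteria": [
            [{"feature": "C4", "comparator": ">", "threshold": 0.7}],
            [{"feature": "C4", "comparator": ">", "threshold": 0.5},
             {"feature": "C4/C2", "comparator": ">", "threshold": 0.03}],
        ]},
    }
    path = tmp_path / "rules.yaml"
    path.write_text(yaml.safe_dump(doc))
    rules = rules_from_yaml(path)
    assert rules["SCAD"].apply({"C4": 0.8, "C4/C2": 0.01})


# ----------------------------------------------------------------------
# optimal PPV at 100% sensitivity


def test_cutoff_clean_separation():
    res = optimal_ppv_cutoff([5, 6, 1, 2, 3], [1, 1, 0, 0, 0])
    assert (res.threshold, res.tp, res.fp, res.ppv) == (5.0, 2, 0, 1.0)
    assert res.fn == 0 and res.sensitivity == 1.0


def test_cutoff_overlapping_values():
    res = optimal_ppv_cutoff([2, 5, 1, 3, 4, 6], [1, 1, 0, 0, 0, 0])
    assert (res.threshold, res.tp, res.fp) == (2.0, 2, 3)
    assert res.ppv == pytest.approx(0.4)


def _brute_force_best_ppv(values, case):
    """Exhaustive search over observed thresholds under the zero-FN
    constraint (the independent oracle)."""
    best = None
    for t in np.unique(values):
        calls = values >= t
        tp = int(np.sum(calls & case))
        fn = int(np.sum(~calls & case))
        if fn > 0:
            continue
        fp = int(np.sum(calls & ~case))
        ppv = tp / (tp + fp)
        if best is None or ppv > best[0]:
            best = (ppv, t)
    return best


def test_cutoff_matches_brute_force_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(5, 120))
        values = np.round(rng.normal(size=n), 2)
        case = rng.random(n) < 0.2
        if case.sum() == 0:
            case[int(rng.integers(n))] = True
        res = optimal_ppv_cutoff(values, case)
        best_ppv, _ = _brute_force_best_ppv(values, case)
        assert res.ppv == pytest.approx(best_ppv)
        assert res.fn == 0
        # reported threshold is an observed case value, every case called
        assert res.threshold in values[case]


def test_cutoff_lower_is_disease_mirror():
    res = optimal_ppv_cutoff([5, 6, 1, 2, 3], [0, 0, 1, 1, 0],
                             direction="lower")
    assert res.threshold == 2.0
    assert res.tp == 2 and res.fp == 0 and res.fn == 0


def test_cutoff_requires_cases():
    with pytest.raises(ValidationError, match="case"):
        optimal_ppv_cutoff([1, 2, 3], [0, 0, 0])


def test_cutoff_estimator_api():
    est = OptimalPPVCutoff().fit([[5], [6], [1], [2], [3]], [1, 1, 0, 0, 0])
    assert est.threshold_ == 5.0 and est.ppv_ == 1.0
    assert est.predict([[4.9], [5.0], [7.0]]).tolist() == [0, 1, 1]


# ----------------------------------------------------------------------
# confusion metrics


def test_perfect_calls_give_unit_metrics():
    cm = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
    assert cm.sensitivity == cm.specificity == cm.ppv == 1.0


def test_undefined_ratios_are_flagged_not_zero():
    cm = confusion_metrics([0, 0, 0], [0, 0, 0])
    assert cm.sensitivity is None and cm.ppv is None
    assert cm.specificity == 1.0


def test_ppv_monotone_in_fp():
    ppvs = [confusion_metrics([1] * (4 + fp), [1] * 4 + [0] * fp).ppv
            for fp in range(1, 30)]
    assert all(a > b for a, b in zip(ppvs, ppvs[1:]))


# ----------------------------------------------------------------------
# McNemar paired comparison


def test_mcnemar_simple_statistics():
    a = np.array([1] * 8 + [0] * 12, dtype=bool)
    b = np.zeros(20, dtype=bool)
    res = mcnemar_paired(a, b)
    assert res.statistic == 8.0  # (8-0)^2 / 8
    res2 = mcnemar_paired(
        np.array([1] * 5 + [0] * 3 + [0] * 10, dtype=bool),
        np.array([0] * 5 + [1] * 3 + [0] * 10, dtype=bool))
    assert res2.statistic == pytest.approx(0.5)
    assert res2.p_value == pytest.approx(0.4795, abs=1e-4)


def test_mcnemar_identical_calls_degenerate():
    a = np.array([1, 0, 1, 0], dtype=bool)
    res = mcnemar_paired(a, a.copy())
    assert res.degenerate
    assert res.display() == ("–", "–")


def test_mcnemar_matches_statsmodels(rng):
    for _ in range(25):
        a = rng.random(60) < 0.3
        b = rng.random(60) < 0.3
        res = mcnemar_paired(a, b)
        table = [[res.both, res.a_only], [res.b_only, res.neither]]
        if res.degenerate:
            continue
        ref = sm_mcnemar(table, exact=False, correction=False)
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))


def test_mcnemar_symmetry(rng):
    a = rng.random(80) < 0.4
    b = rng.random(80) < 0.4
    r1, r2 = mcnemar_paired(a, b), mcnemar_paired(b, a)
    assert r1.statistic == r2.statistic
    assert r1.both + r1.a_only + r1.b_only + r1.neither == 80


# ----------------------------------------------------------------------
# incidence formatting


def test_incidence_strings():
    assert incidence_string(20, 352_119) == "1/17,606"
    assert incidence_string(11, 352_119) == "1/32,011"
    assert incidence_string(1, 1) == "1/1"
    with pytest.raises(ValidationError):
        incidence_string(0, 100)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(cases=st.integers(min_value=1, max_value=500),
       total=st.integers(min_value=1, max_value=10**6))
def test_incidence_inversion(cases, total):
    if total < cases:
        total = cases
    n = parse_incidence(incidence_string(cases, total))
    # n * cases recovers total within rounding
    assert abs(n * cases - total) <= cases / 2 + 1e-9


def test_round_half_up_behaviour():
    assert round_half_up(20.75) == 20.8
    assert round_half_up(0.65) == 0.7
    assert round_half_up(2.04) == 2.0


# ----------------------------------------------------------------------
# indicator evaluation table


def test_evaluate_indicators_layout_and_planted_advantage():
    from acadscreen import SimulationConfig, generate_cohort, plant_marker_scenario
    cfg = plant_marker_scenario(SimulationConfig(n=6000, seed=19),
                                "C4", "C5DC+C6-OH", fold=10.0)
    cfg.prevalence = {"SCAD": 0.003}
    cohort = generate_cohort(cfg)
    fm = expand_ratios(cohort, scale="raw")
    labels = cohort.labels.to_numpy()
    table = evaluate_indicators(
        {"model": (fm, labels)},
        {"SCAD": ["C4/C5DC+C6-OH", "C4"]},
    )
    assert set(table.columns) >= {"part", "condition", "indicator", "tp",
                                  "fp", "ppv_percent", "statistic", "p"}
    assert len(table) == 2
    row_ratio = table[table.indicator == "C4/C5DC+C6-OH"].iloc[0]
    row_raw = table[table.indicator == "C4"].iloc[0]
    # the planted ratio is the better discriminator by construction
    assert row_ratio.ppv_percent >= row_raw.ppv_percent
    # comparison column filled for the non-reference indicator only
    assert row_ratio.statistic == "" and row_raw.statistic != ""


def test_evaluate_identical_call_sets_render_dash():
    from acadscreen import SimulationConfig, generate_cohort
    cfg = SimulationConfig(n=500, prevalence={"VLCAD": 0.02}, seed=23)
    cohort = generate_cohort(cfg)
    fm = expand_ratios(cohort, scale="raw")
    labels = cohort.labels.to_numpy()
    table = evaluate_indicators({"model": (fm, labels)},
                                {"VLCAD": ["C14:1", "C14:1"]})
    assert table.iloc[1].statistic == "–"


def test_evaluate_flags_condition_without_cases():
    from acadscreen import SimulationConfig, generate_cohort
    cohort = generate_cohort(SimulationConfig(n=200, prevalence={}, seed=3))
    fm = expand_ratios(cohort, scale="raw")
    table = evaluate_indicators({"model": (fm, cohort.labels.to_numpy())},
                                {"MCAD": ["C8"]})
    assert table.iloc[0].flag == "no cases"
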