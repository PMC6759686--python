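import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acadscreen import (SimulationConfig, default_rules, expand_ratios,
                        generate_cohort, plant_marker_scenario,
                        run_two_stage_flow)
from acadscreen.errors import ConfigurationError, ValidationError
from acadscreen.screening import ScreeningRule, ThresholdClause


def test_determinism_field_for_field():
    cfg = SimulationConfig(n=400, prevalence={"SCAD": 0.01}, seed=9)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.data, b.data)
    c = generate_cohort(SimulationConfig(n=400, prevalence={"SCAD": 0.01},
                                         seed=10))
    assert not a.concentrations.equals(c.concentrations)


def test_zero_prevalence_all_healthy():
    cfg = SimulationConfig(n=1000, prevalence={}, seed=7)
    cohort = generate_cohort(cfg)
    assert len(cohort) == 1000
    assert (cohort.labels == "none").all()


def test_case_count_in_binomial_interval():
    """At n=200,000 and the default SCAD prevalence (~1/32,011) the drawn
    case count must fall in the central 99% binomial interval."""
    n, p = 200_000, 1.0 / 32_011
    cfg = SimulationConfig(n=n, prevalence={"SCAD": p}, seed=12)
    cohort = generate_cohort(cfg)
    count = int((cohort.labels == "SCAD").sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
    assert lo <= count <= hi


def test_vlcad_case_median_in_observed_span():
    """Median simulated VLCAD case C14:1 lies inside the span of the
    confirmed cases' printed initial values, 0.63-4.27."""
    cfg = SimulationConfig(n=3000, prevalence={"VLCAD": 0.5}, seed=3)
    cohort = generate_cohort(cfg)
    cases = cohort.data.loc[cohort.labels == "VLCAD", "C14:1"]
    assert len(cases) > 1000
    assert 0.63 <= cases.median() <= 4.27


def test_healthy_background_converges():
    cfg = SimulationConfig(n=50_000, prevalence={}, seed=21)
    cohort = generate_cohort(cfg)
    logs = np.log(cohort.concentrations.to_numpy())
    for j, name in enumerate(cohort.panel.names):
        med, sd = cfg.background[name]
        se = sd / np.sqrt(len(cohort))
        assert abs(logs[:, j].mean() - np.log(med)) < 3 * se, name


def test_invalid_configs_name_the_field(panel):
    with pytest.raises(ValidationError, match="prevalence"):
        SimulationConfig(n=10, prevalence={"SCAD": -0.1}).validate(panel)
    with pytest.raises(ValidationError, match="retest_rho"):
        SimulationConfig(n=10, retest_rho=1.5).validate(panel)
    with pytest.raises(ValidationError, match="unknown channel"):
        from acadscreen import EffectProfile
        SimulationConfig(
            n=10, effect_profiles={"SCAD": EffectProfile("SCAD", {"Zz": 2.0})}
        ).validate(panel)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(n=123, prevalence={"MCAD": 0.01}, seed=6)
    path = tmp_path / "sim.yaml"
    cfg.to_yaml(path)
    loaded = SimulationConfig.from_yaml(path)
    assert loaded.n == 123
    assert loaded.prevalence == {"MCAD": 0.01}
    assert loaded.effect_profiles["MCAD"].folds == cfg.effect_profiles["MCAD"].folds


# ----------------------------------------------------------------------
# planted-marker scenarios


def test_planted_ratio_stochastically_dominates(rng):
    cfg = plant_marker_scenario(
        SimulationConfig(n=4000, seed=17), "C4", "C5DC+C6-OH", fold=8.0)
    cfg.prevalence = {"SCAD": 0.01}
    cohort = generate_cohort(cfg)
    fm = expand_ratios(cohort, scale="raw")
    vals, _ = fm.lookup("C4/C5DC+C6-OH")
    case = (cohort.labels == "SCAD").to_numpy()
    assert case.sum() >= 10
    u = stats.mannwhitneyu(vals[case], vals[~case], alternative="greater")
    assert u.pvalue < 1e-6


def test_plant_rejects_fold_one_and_self_ratio():
    cfg = SimulationConfig(n=10)
    with pytest.raises(ValidationError, match="fold"):
        plant_marker_scenario(cfg, "C4", "C2", fold=1.0)
    with pytest.raises(ValidationError, match="differ"):
        plant_marker_scenario(cfg, "C4", "C4", fold=8.0)


# ----------------------------------------------------------------------
# two-stage flow


def _flow(n=2000, prevalence=None, seed=5, **kw):
    cfg = SimulationConfig(n=n, prevalence=prevalence or {"SCAD": 0.01},
                           seed=seed, **kw)
    cohort = generate_cohort(cfg)
    return run_two_stage_flow(cohort, list(default_rules().values()), cfg), cfg


def test_perfect_retest_reproduces_initial_calls():
    flowed, _ = _flow(retest_rho=1.0, recall_compliance=1.0)
    df = flowed.data
    assert df["suspect_positive"].fillna(False).tolist() == \
        df["initial_positive"].fillna(False).tolist()


def test_zero_compliance_kills_downstream():
    flowed, _ = _flow(recall_compliance=0.0)
    df = flowed.data
    assert int(df["initial_positive"].sum()) > 0
    assert int(df["recalled"].sum()) == 0
    assert int(df["suspect_positive"].sum()) == 0
    assert int(df["confirmed"].sum()) == 0


def test_flow_conservation_and_confirmation_semantics():
    flowed, _ = _flow(n=35_000, prevalence=None, seed=11)
    df = flowed.data
    initial = df["initial_positive"].fillna(False).to_numpy(dtype=bool)
    recalled = df["recalled"].fillna(False).to_numpy(dtype=bool)
    suspect = df["suspect_positive"].fillna(False).to_numpy(dtype=bool)
    confirmed = df["confirmed"].fillna(False).to_numpy(dtype=bool)
    assert len(df) >= initial.sum() >= recalled.sum() >= suspect.sum() >= confirmed.sum()
    assert np.array_equal(confirmed,
                          suspect & (df["label"] != "none").to_numpy())
    # not-recalled + recalled partitions the initial positives
    assert initial.sum() == recalled.sum() + int((initial & ~recalled).sum())


def test_flow_rejects_flagged_cohort():
    flowed, cfg = _flow()
    with pytest.raises(ValidationError, match="stage flags"):
        run_two_stage_flow(flowed, list(default_rules().values()), cfg)


def test_flow_rejects_rule_with_unknown_channel():
    cfg = SimulationConfig(n=50, prevalence={}, seed=1)
    cohort = generate_cohort(cfg)
    bad_rule = ScreeningRule("SCAD",
                             ((ThresholdClause("Qx", ">", 1.0),),))
    with pytest.raises(ConfigurationError):
        run_two_stage_flow(cohort, bad_rule, cfg)
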