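"""Screening values of the 20 confirmed ACAD-deficiency cases.

Initial and recall dried-blood-spot values (nmol/L and unitless ratios) for
the 11 SCAD, 4 MCAD and 5 VLCAD cases confirmed in the retrospective
352,119-newborn screening cohort that this package's defaults emulate.
They serve two roles: exact fixtures for the rule engine (every value a
rule clause needs is given directly, so no assay modelling intervenes) and
anchors for the simulator's case effect profiles (e.g. initial C14:1 in
VLCAD cases spans 0.63-4.27).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceCase:
    condition: str
    case_no: int
    initial: dict[str, float]
    second: dict[str, float]


_SCAD = [
    ({"C4": 0.89, "C4/C2": 0.18, "C4/C5DC+C6-OH": 22.25},
     {"C4": 0.91, "C4/C2": 0.09, "C4/C5DC+C6-OH": 30.33}),
    ({"C4": 1.42, "C4/C2": 0.06, "C4/C5DC+C6-OH": 11.83},
     {"C4": 0.80, "C4/C2": 0.10, "C4/C5DC+C6-OH": 13.33}),
    ({"C4": 1.47, "C4/C2": 0.09, "C4/C5DC+C6-OH": 12.25},
     {"C4": 1.18, "C4/C2": 0.17, "C4/C5DC+C6-OH": 19.67}),
    ({"C4": 1.08, "C4/C2": 0.14, "C4/C5DC+C6-OH": 27.00},
     {"C4": 0.98, "C4/C2": 0.12, "C4/C5DC+C6-OH": 16.33}),
    ({"C4": 2.03, "C4/C2": 0.08, "C4/C5DC+C6-OH": 12.69},
     {"C4": 1.78, "C4/C2": 0.08, "C4/C5DC+C6-OH": 25.43}),
    ({"C4": 2.01, "C4/C2": 0.08, "C4/C5DC+C6-OH": 12.56},
     {"C4": 1.38, "C4/C2": 0.18, "C4/C5DC+C6-OH": 15.33}),
    ({"C4": 1.43, "C4/C2": 0.12, "C4/C5DC+C6-OH": 17.88},
     {"C4": 1.58, "C4/C2": 0.20, "C4/C5DC+C6-OH": 19.75}),
    ({"C4": 0.51, "C4/C2": 0.04, "C4/C5DC+C6-OH": 8.50},
     {"C4": 0.54, "C4/C2": 0.06, "C4/C5DC+C6-OH": 10.80}),
    ({"C4": 1.10, "C4/C2": 0.13, "C4/C5DC+C6-OH": 22.00},
     {"C4": 1.30, "C4/C2": 0.17, "C4/C5DC+C6-OH": 21.67}),
    ({"C4": 1.35, "C4/C2": 0.09, "C4/C5DC+C6-OH": 12.27},
     {"C4": 1.07, "C4/C2": 0.17, "C4/C5DC+C6-OH": 15.29}),
    ({"C4": 0.88, "C4/C2": 0.05, "C4/C5DC+C6-OH": 8.80},
     {"C4": 1.19, "C4/C2": 0.15, "C4/C5DC+C6-OH": 13.22}),
]

_MCAD = [
    ({"C6": 0.92, "C8": 14.52, "C8/C2": 0.70, "C4DC+C5-OH/C8": 0.01,
      "C8/C14:1": 132.0},
     {"C6": 0.68, "C8": 3.44, "C8/C2": 0.42, "C4DC+C5-OH/C8": 0.05,
      "C8/C14:1": 114.7}),
    ({"C6": 0.47, "C8": 1.18, "C8/C2": 0.09, "C4DC+C5-OH/C8": 0.13,
      "C8/C14:1": 29.5},
     {"C6": 0.52, "C8": 1.36, "C8/C2": 0.17, "C4DC+C5-OH/C8": 0.18,
      "C8/C14:1": 34.0}),
    ({"C6": 0.55, "C8": 1.99, "C8/C2": 0.06, "C4DC+C5-OH/C8": 0.08,
      "C8/C14:1": 15.3},
     {"C6": 0.27, "C8": 0.78, "C8/C2": 0.02, "C4DC+C5-OH/C8": 0.17,
      "C8/C14:1": 4.5}),
    ({"C6": 0.09, "C8": 0.17, "C8/C2": 0.01, "C4DC+C5-OH/C8": 1.00,
      "C8/C14:1": 3.4},
     {"C6": 0.13, "C8": 0.22, "C8/C2": 0.02, "C4DC+C5-OH/C8": 0.86,
      "C8/C14:1": 5.5}),
]

_VLCAD = [
    ({"C14:1": 1.71, "C14:1/C16": 0.60, "C14:1/C2": 0.51,
      "C14:1/C16-OH": 171.0},
     {"C14:1": 1.95, "C14:1/C16": 1.10, "C14:1/C2": 0.78,
      "C14:1/C16-OH": 195.0}),
    ({"C14:1": 1.51, "C14:1/C16": 0.62, "C14:1/C2": 0.55,
      "C14:1/C16-OH": 151.0},
     {"C14:1": 1.95, "C14:1/C16": 0.71, "C14:1/C2": 0.61,
      "C14:1/C16-OH": 97.5}),
    ({"C14:1": 2.10, "C14:1/C16": 1.13, "C14:1/C2": 0.33,
      "C14:1/C16-OH": 210.0},
     {"C14:1": 2.91, "C14:1/C16": 1.39, "C14:1/C2": 0.55,
      "C14:1/C16-OH": 145.5}),
    ({"C14:1": 4.27, "C14:1/C16": 0.50, "C14:1/C2": 0.25,
      "C14:1/C16-OH": 61.0},
     {"C14:1": 2.91, "C14:1/C16": 1.39, "C14:1/C2": 0.55,
      "C14:1/C16-OH": 170.5}),
    ({"C14:1": 0.63, "C14:1/C16": 0.53, "C14:1/C2": 0.06,
      "C14:1/C16-OH": 63.0},
     {"C14:1": 1.42, "C14:1/C16": 1.15, "C14:1/C2": 0.16,
      "C14:1/C16-OH": 142.0}),
]


def reference_cases(condition: str | None = None) -> list[ReferenceCase]:
    """All 20 confirmed cases, optionally filtered by condition."""
    cases = (
        [ReferenceCase("SCAD", i + 1, ini, sec) for i, (ini, sec) in enumerate(_SCAD)]
        + [ReferenceCase("MCAD", i + 1, ini, sec) for i, (ini, sec) in enumerate(_MCAD)]
        + [ReferenceCase("VLCAD", i + 1, ini, sec) for i, (ini, sec) in enumerate(_VLCAD)]
    )
    if condition is None:
        return cases
    return [c for c in cases if c.condition == condition]


def initial_value_span(condition: str, feature: str) -> tuple[float, float]:
    """(min, max) of a feature's initial values across a condition's cases."""
    vals = [c.initial[feature] for c in reference_cases(condition)
            if feature in c.initial]
    return min(vals), max(vals)
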