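"""Screening-rule engine and indicator-performance evaluation.

Implements the routine compound screening criteria for ACAD deficiencies
(disjunctions of threshold conjunctions over channels and channel ratios,
e.g. SCAD positive iff ``C4 > 0.7`` or ``C4 > 0.5 and C4/C2 > 0.03``), the
"optimal PPV at 100% sensitivity" threshold search used to benchmark
candidate single-ratio indicators, standard confusion metrics, paired
McNemar comparison of two screening calls on the same newborns, and the
``1/n`` incidence formatting used in screening reports.

The optimal-PPV search places the threshold at the extreme case value (the
minimum for higher-is-disease markers), the unique choice that keeps every
case positive; among all zero-false-negative thresholds it maximizes PPV
because any higher threshold loses a case and any lower one can only add
false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError, ValidationError
from .features import DEFAULT_FLOOR, FeatureMatrix, parse_feature_name
from .panel import AnalytePanel

COMPARATORS = (">", ">=", "<", "<=")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching how screening tables print PPVs."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ----------------------------------------------------------------------
# Rules


@dataclass(frozen=True)
class ThresholdClause:
    """One comparison, e.g. ``C4 > 0.7`` or ``C4DC+C5-OH/C8 < 1.3``."""

    feature: str
    comparator: str
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValidationError(f"unknown comparator {self.comparator!r}")
        if not np.isfinite(self.threshold):
            raise ValidationError(f"threshold for {self.feature} must be finite")

    def holds(self, value: float, boundary_mode: str = "strict") -> bool:
        comp = self.comparator
        if boundary_mode == "inclusive":
            comp = {">": ">=", "<": "<=", ">=": ">=", "<=": "<="}[comp]
        if comp == ">":
            return value > self.threshold
        if comp == ">=":
            return value >= self.threshold
        if comp == "<":
            return value < self.threshold
        return value <= self.threshold


@dataclass(frozen=True)
class ScreeningRule:
    """Compound positive criterion: fires if ANY criterion's clauses ALL hold.

    ``boundary_mode`` governs equality at thresholds printed with strict
    comparators: ``"strict"`` applies them as printed, ``"inclusive"``
    widens ``>``/``<`` to ``>=``/``<=`` (a documented alternative, since a
    case sitting exactly on a printed cutoff is screen-positive only under
    inclusive comparison).
    """

    condition: str
    criteria: tuple[tuple[ThresholdClause, ...], ...]
    boundary_mode: str = "strict"

    def __post_init__(self) -> None:
        if not self.criteria or any(len(c) == 0 for c in self.criteria):
            raise ValidationError("rule needs >= 1 criterion, each with >= 1 clause")
        if self.boundary_mode not in ("strict", "inclusive"):
            raise ValidationError(f"unknown boundary_mode {self.boundary_mode!r}")

    def features(self) -> list[str]:
        return sorted({cl.feature for crit in self.criteria for cl in crit})

    # -- evaluation on a single feature map -----------------------------
    def apply(self, values: dict[str, float],
              floor: float = DEFAULT_FLOOR) -> bool:
        """Evaluate on a name -> value map (ratios may be given directly or
        derived from channel values present in the map)."""
        return any(
            all(cl.holds(_map_value(values, cl.feature, floor),
                         self.boundary_mode) for cl in crit)
            for crit in self.criteria
        )

    def criterion_results(self, values: dict[str, float],
                          floor: float = DEFAULT_FLOOR) -> list[bool]:
        """Per-criterion truth values (criterion I, II, ... in order)."""
        return [
            all(cl.holds(_map_value(values, cl.feature, floor),
                         self.boundary_mode) for cl in crit)
            for crit in self.criteria
        ]

    # -- vectorized evaluation on a concentrations frame ----------------
    def positive_on_frame(self, frame: pd.DataFrame, panel: AnalytePanel,
                          floor: float = DEFAULT_FLOOR) -> np.ndarray:
        result = np.zeros(len(frame), dtype=bool)
        for crit in self.criteria:
            crit_ok = np.ones(len(frame), dtype=bool)
            for cl in crit:
                vals = _frame_values(frame, cl.feature, panel, floor)
                crit_ok &= _vector_holds(vals, cl, self.boundary_mode)
            result |= crit_ok
        return result


def _vector_holds(vals: np.ndarray, cl: ThresholdClause,
                  boundary_mode: str) -> np.ndarray:
    comp = cl.comparator
    if boundary_mode == "inclusive":
        comp = {">": ">=", "<": "<=", ">=": ">=", "<=": "<="}[comp]
    if comp == ">":
        return vals > cl.threshold
    if comp == ">=":
        return vals >= cl.threshold
    if comp == "<":
        return vals < cl.threshold
    return vals <= cl.threshold


def _map_value(values: dict[str, float], feature: str, floor: float) -> float:
    if feature in values:
        return float(values[feature])
    if "/" in feature:
        # try any split whose sides are both present in the map
        pos = len(feature)
        while True:
            pos = feature.rfind("/", 0, pos)
            if pos < 0:
                break
            num, den = feature[:pos], feature[pos + 1:]
            if num in values and den in values:
                return max(float(values[num]), floor) / max(float(values[den]), floor)
    raise ConfigurationError(f"feature {feature!r} not resolvable from record values")


def _frame_values(frame: pd.DataFrame, feature: str, panel: AnalytePanel,
                  floor: float) -> np.ndarray:
    try:
        parsed = parse_feature_name(feature, panel)
    except KeyError:
        raise ConfigurationError(
            f"rule feature {feature!r} not resolvable against panel"
        ) from None
    if parsed[0] == "channel":
        return frame[panel.names[parsed[1]]].to_numpy(dtype=float)
    _, i, j, inverted = parsed
    num_idx, den_idx = (j, i) if inverted else (i, j)
    num = np.maximum(frame[panel.names[num_idx]].to_numpy(dtype=float), floor)
    den = np.maximum(frame[panel.names[den_idx]].to_numpy(dtype=float), floor)
    return num / den


def apply_rule(rule: ScreeningRule, values: dict[str, float],
               floor: float = DEFAULT_FLOOR) -> bool:
    """Module-level wrapper over :meth:`ScreeningRule.apply`."""
    return rule.apply(values, floor=floor)


def default_rules(boundary_mode: str = "strict") -> dict[str, ScreeningRule]:
    """The routine compound positive criteria for the three deficiencies."""
    C = ThresholdClause
    return {
        "SCAD": ScreeningRule("SCAD", (
            (C("C4", ">", 0.7),),
            (C("C4", ">", 0.5), C("C4/C2", ">", 0.03)),
        ), boundary_mode),
        "MCAD": ScreeningRule("MCAD", (
            (C("C8", ">", 0.3),),
            (C("C6", ">", 0.09), C("C8", ">", 0.15),
             C("C8/C2", ">=", 0.01), C("C4DC+C5-OH/C8", "<", 1.3)),
        ), boundary_mode),
        "VLCAD": ScreeningRule("VLCAD", (
            (C("C14:1", ">", 0.5),),
            (C("C14:1", ">", 0.29), C("C14:1/C2", ">=", 0.02),
             C("C14:1/C16", ">", 0.1)),
        ), boundary_mode),
    }


def rules_from_yaml(path, boundary_mode: str = "strict") -> dict[str, ScreeningRule]:
    """Load rules from YAML: ``{condition: {criteria: [[{feature, comparator,
    threshold}, ...], ...]}}``."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError("rules YAML must map condition -> rule")
    out = {}
    for cond, spec in doc.items():
        try:
            criteria = tuple(
                tuple(ThresholdClause(cl["feature"], cl["comparator"],
                                      float(cl["threshold"])) for cl in crit)
                for crit in spec["criteria"]
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed rule for {cond!r}: {exc}") from exc
        out[cond] = ScreeningRule(cond, criteria,
                                  spec.get("boundary_mode", boundary_mode))
    return out


# ----------------------------------------------------------------------
# Optimal PPV at 100% sensitivity


@dataclass
class CutoffResult:
    feature: str
    direction: str  # "higher" | "lower"
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    ppv: float | None
    sensitivity: float

    @property
    def ppv_percent(self) -> float | None:
        return None if self.ppv is None else round_half_up(100.0 * self.ppv)


def optimal_ppv_cutoff(values, case_flags, direction: str = "higher",
                       feature: str = "") -> CutoffResult:
    """Best-PPV threshold subject to calling every case positive.

    For a higher-is-disease marker the threshold is the minimum case value
    with inclusive comparison (``value >= threshold``); mirror-image for
    lower-is-disease.  FN = 0 and sensitivity = 1 by construction.
    """
    values = np.asarray(values, dtype=float)
    case = np.asarray(case_flags, dtype=bool)
    if values.shape != case.shape:
        raise ValidationError("values and case flags must align")
    if not np.isfinite(values).all():
        raise ValidationError("values must be finite")
    if case.sum() == 0:
        raise ValidationError("optimal-PPV search requires at least one case")
    if direction not in ("higher", "lower"):
        raise ValidationError(f"unknown direction {direction!r}")

    if direction == "higher":
        threshold = float(values[case].min())
        calls = values >= threshold
    else:
        threshold = float(values[case].max())
        calls = values <= threshold
    tp = int(np.sum(calls & case))
    fp = int(np.sum(calls & ~case))
    tn = int(np.sum(~calls & ~case))
    return CutoffResult(
        feature=feature, direction=direction, threshold=threshold,
        tp=tp, fp=fp, fn=0, tn=tn,
        ppv=tp / (tp + fp), sensitivity=1.0,
    )


class OptimalPPVCutoff(BaseEstimator, ClassifierMixin):
    """Single-marker threshold classifier fitted at 100% sensitivity.

    ``fit(X, y)`` with a one-column X learns the optimal-PPV zero-FN
    threshold; ``predict`` applies it.  Fitted attributes: ``threshold_``,
    ``tp_``, ``fp_``, ``ppv_``, ``result_``.
    """

    def __init__(self, direction: str = "higher"):
        self.direction = direction

    def fit(self, X, y):
        values = np.asarray(X, dtype=float).reshape(len(np.asarray(y)), -1)
        if values.shape[1] != 1:
            raise ValidationError("OptimalPPVCutoff expects a single feature")
        res = optimal_ppv_cutoff(values[:, 0], np.asarray(y).astype(bool),
                                 direction=self.direction)
        self.result_ = res
        self.threshold_ = res.threshold
        self.tp_, self.fp_ = res.tp, res.fp
        self.ppv_ = res.ppv
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        values = np.asarray(X, dtype=float).reshape(-1)
        if self.direction == "higher":
            return (values >= self.threshold_).astype(int)
        return (values <= self.threshold_).astype(int)


# ----------------------------------------------------------------------
# Metrics and paired comparison


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    fp_rate: float | None

    @property
    def ppv_percent(self) -> float | None:
        return None if self.ppv is None else round_half_up(100.0 * self.ppv)


def confusion_metrics(calls, labels) -> ConfusionMetrics:
    """Standard confusion metrics; undefined ratios are None, never 0."""
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if calls.shape != labels.shape:
        raise ValidationError("calls and labels must align")
    tp = int(np.sum(calls & labels))
    fp = int(np.sum(calls & ~labels))
    fn = int(np.sum(~calls & labels))
    tn = int(np.sum(~calls & ~labels))

    def _ratio(a: int, b: int) -> float | None:
        return a / b if b > 0 else None

    return ConfusionMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        fp_rate=_ratio(fp, fp + tn),
    )


@dataclass
class ComparisonResult:
    """McNemar paired comparison of two screening calls."""

    rule_a: str
    rule_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    statistic: float | None
    p_value: float | None
    degenerate: bool

    def display(self) -> tuple[str, str]:
        """(statistic, p) strings; discordant-free pairs print as em-dashes."""
        if self.degenerate:
            return "–", "–"
        return f"{self.statistic:.2f}", (
            "<0.001" if self.p_value < 0.001 else f"{self.p_value:.3f}"
        )


def mcnemar_paired(calls_a, calls_b, rule_a: str = "A", rule_b: str = "B",
                   correction: bool = False) -> ComparisonResult:
    """McNemar test on discordant paired calls.

    statistic = (b - c)^2 / (b + c) with b = A-only, c = B-only positives,
    chi-square df = 1.  Identical call sets (b + c = 0) are degenerate and
    reported without a statistic.
    """
    a = np.asarray(calls_a, dtype=bool)
    b_arr = np.asarray(calls_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValidationError("paired call vectors must align")
    both = int(np.sum(a & b_arr))
    a_only = int(np.sum(a & ~b_arr))
    b_only = int(np.sum(~a & b_arr))
    neither = int(np.sum(~a & ~b_arr))
    if a_only + b_only == 0:
        return ComparisonResult(rule_a, rule_b, both, a_only, b_only, neither,
                                None, None, True)
    diff = abs(a_only - b_only) - (1 if correction else 0)
    stat = max(diff, 0) ** 2 / (a_only + b_only)
    p = float(stats.chi2.sf(stat, df=1))
    return ComparisonResult(rule_a, rule_b, both, a_only, b_only, neither,
                            float(stat), p, False)


def incidence_string(cases: int, total: int) -> str:
    """Express confirmed cases as "1/n" of the screened population.

    ``n`` is total/cases rounded half-up; thousands grouping is applied for
    n >= 10,000, matching report style (e.g. "1/17,606" but "1/4242").
    """
    if cases < 1:
        raise ValidationError("incidence undefined for zero cases")
    if total < cases:
        raise ValidationError("total must be >= cases")
    n = int((Decimal(total) / Decimal(cases)).quantize(
        Decimal(1), rounding=ROUND_HALF_UP))
    return f"1/{n:,}" if n >= 10_000 else f"1/{n}"


def parse_incidence(s: str) -> int:
    """Inverse of :func:`incidence_string`: returns n from "1/n"."""
    if not s.startswith("1/"):
        raise ValidationError(f"not an incidence string: {s!r}")
    return int(s[2:].replace(",", ""))


# ----------------------------------------------------------------------
# Indicator evaluation tables


def evaluate_indicators(parts: dict[str, tuple[FeatureMatrix, "pd.Series"]],
                        indicators: dict[str, list],
                        floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Benchmark indicators per condition per data part.

    Parameters
    ----------
    parts : dict
        Part name ("model", "testing") -> (raw-scale FeatureMatrix,
        condition labels aligned to its rows).
    indicators : dict
        Condition -> list of indicator specs; a ``str`` names a single
        feature (optimal-PPV cutoff search), a :class:`ScreeningRule` is
        applied at its fixed thresholds.  The first-listed indicator is the
        reference for the paired McNemar comparison.

    Returns a tidy frame with one row per (part, condition, indicator):
    TP, FP, PPV (percent, one decimal), threshold where applicable, and
    the McNemar statistic/p against the reference indicator ("–" when the
    call sets are identical, blank for the reference itself).
    """
    rows = []
    for part_name, (matrix, labels) in parts.items():
        if matrix.scale != "raw":
            raise ValidationError("evaluate_indicators needs a raw-scale matrix")
        labels = np.asarray(labels)
        for condition, specs in indicators.items():
            case = labels == condition
            if case.sum() == 0:
                for spec in specs:
                    rows.append({
                        "part": part_name, "condition": condition,
                        "indicator": _spec_name(spec), "flag": "no cases",
                    })
                continue
            ref_calls = None
            for k, spec in enumerate(specs):
                calls, threshold = _indicator_calls(spec, matrix, case, floor)
                cm = confusion_metrics(calls, case)
                row = {
                    "part": part_name, "condition": condition,
                    "indicator": _spec_name(spec),
                    "tp": cm.tp, "fp": cm.fp, "ppv_percent": cm.ppv_percent,
                    "sensitivity": cm.sensitivity, "threshold": threshold,
                    "statistic": "", "p": "", "flag": "",
                }
                if k == 0:
                    ref_calls = calls
                else:
                    comp = mcnemar_paired(ref_calls, calls,
                                          _spec_name(specs[0]), _spec_name(spec))
                    row["statistic"], row["p"] = comp.display()
                rows.append(row)
    return pd.DataFrame(rows)


def _indicator_calls(spec, matrix: FeatureMatrix, case: np.ndarray,
                     floor: float):
    if isinstance(spec, ScreeningRule):
        frame = matrix.values[matrix.panel.names]
        calls = spec.positive_on_frame(frame, matrix.panel, floor=floor)
        return calls, None
    values, _ = matrix.lookup(spec)
    res = optimal_ppv_cutoff(values, case, feature=spec)
    return values >= res.threshold, res.threshold


def _spec_name(spec) -> str:
    if isinstance(spec, ScreeningRule):
        return f"rule:{spec.condition}"
    return str(spec)
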