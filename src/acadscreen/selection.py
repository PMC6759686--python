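"""Subgroup-consensus marker selection.

The selection protocol for a rare-disease screening cohort:

1. split the cohort into model-building and testing parts;
2. partition the model-building part into disjoint subgroups
   (default 20 x 10,000);
3. run stepwise multivariate logistic regression over all candidate
   features independently in every subgroup (subgroups without a single
   case contribute an empty set and never abort the run);
4. keep features selected in at least ``consensus_min`` subgroups — a
   stability-selection filter;
5. refit the stepwise model on the full model-building data restricted to
   the consensus set; the survivors are the final marker panel, each
   assigned to the condition whose cases drive its signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CONDITIONS, CohortTable
from .errors import ValidationError
from .stepwise import SelectionConfig, StepwiseLogisticSelector

__all__ = [
    "split_model_testing", "partition_subgroups", "consensus_select",
    "SubgroupConsensusSelector", "SelectionReport", "fit_final_model",
    "SelectionConfig",
]


def split_model_testing(cohort: CohortTable, n_model: int, seed: int,
                        stratify: bool = False) -> tuple[CohortTable, CohortTable]:
    """Random disjoint exhaustive split into model-building and testing parts.

    With ``stratify=True`` at least one case of every condition present in
    the cohort is forced into the model-building part (swapping with a
    random control if needed).
    """
    n = len(cohort)
    if not (0 < n_model < n):
        raise ValidationError(f"n_model must be in (0, {n}), got {n_model}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    model_idx, test_idx = perm[:n_model], perm[n_model:]

    if stratify:
        labels = cohort.labels.to_numpy()
        model_set = set(model_idx.tolist())
        model_idx = model_idx.tolist()
        test_idx = test_idx.tolist()
        for cond in CONDITIONS:
            cond_pos = np.flatnonzero(labels == cond)
            if len(cond_pos) == 0 or any(i in model_set for i in cond_pos):
                continue
            incoming = int(rng.choice(cond_pos))
            # swap with a random non-case in the model part
            controls = [i for i in model_idx if labels[i] == "none"]
            outgoing = int(rng.choice(controls))
            model_idx[model_idx.index(outgoing)] = incoming
            test_idx[test_idx.index(incoming)] = outgoing
            model_set.discard(outgoing)
            model_set.add(incoming)
        model_idx, test_idx = np.asarray(model_idx), np.asarray(test_idx)

    return _take(cohort, model_idx, "model"), _take(cohort, test_idx, "testing")


def partition_subgroups(model: CohortTable, n_subgroups: int,
                        subgroup_size: int, seed: int) -> list[CohortTable]:
    """Disjoint random subgroups of exact size; leftovers unused."""
    needed = n_subgroups * subgroup_size
    if needed > len(model):
        raise ValidationError(
            f"{n_subgroups} x {subgroup_size} exceeds model size {len(model)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(model))
    return [
        _take(model, perm[g * subgroup_size:(g + 1) * subgroup_size],
              f"subgroup-{g}")
        for g in range(n_subgroups)
    ]


def _take(cohort: CohortTable, idx, part: str) -> CohortTable:
    data = cohort.data.iloc[np.sort(np.asarray(idx))].reset_index(drop=True)
    prov = dict(cohort.provenance)
    prov["part"] = part
    return CohortTable(panel=cohort.panel, data=data, provenance=prov)


def consensus_select(per_subgroup: list[set | list],
                     consensus_min: int) -> tuple[list, dict]:
    """Features appearing in >= consensus_min subgroup selections.

    Returns the consensus list (in first-appearance order) and the full
    appearance-count map.
    """
    if not per_subgroup:
        raise ValidationError("per-subgroup selection list is empty")
    counts: dict = {}
    for sel in per_subgroup:
        for f in sel:
            counts[f] = counts.get(f, 0) + 1
    consensus = [f for f in counts if counts[f] >= consensus_min]
    return consensus, counts


@dataclass
class SelectionReport:
    """Serializable record of a full selection run."""

    config: dict
    subgroup_selections: list[list[str]]
    subgroup_traces: list[list[dict]]
    degenerate_subgroups: list[int]
    union: list[str]
    appearance_counts: dict
    consensus: list[str]
    final_features: list[str]
    final_coefficients: dict
    final_intercept: float | None
    final_loglik: float | None
    separation_flag: bool
    condition_assignment: dict = field(default_factory=dict)
    split_sizes: dict = field(default_factory=dict)
    n_leftover: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SelectionReport":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


class SubgroupConsensusSelector(BaseEstimator):
    """Stability-selection estimator over subgroup-wise stepwise fits.

    Parameters mirror :class:`~acadscreen.stepwise.SelectionConfig`; sizes
    refer to rows of the feature table passed to :meth:`fit` (the
    model-building data).  ``subgroup_size=None`` uses ``n // n_subgroups``.

    Attributes
    ----------
    consensus_ : list of str
        Features selected in >= ``consensus_min`` subgroups.
    final_features_ : list of str
        Survivors of the consensus-set stepwise refit on all rows.
    report_ : SelectionReport
    """

    def __init__(self, n_subgroups: int = 20, subgroup_size: int | None = None,
                 entry_p: float = 0.05, removal_p: float = 0.10,
                 max_steps: int = 20, consensus_min: int = 2,
                 penalty: str = "firth", prescreen_k: int | None = 50,
                 seed: int = 0):
        self.n_subgroups = n_subgroups
        self.subgroup_size = subgroup_size
        self.entry_p = entry_p
        self.removal_p = removal_p
        self.max_steps = max_steps
        self.consensus_min = consensus_min
        self.penalty = penalty
        self.prescreen_k = prescreen_k
        self.seed = seed

    def fit(self, X, y, conditions=None):
        """Run the full protocol.

        Parameters
        ----------
        X : DataFrame or ndarray, shape (n, n_features)
            Candidate feature table for the model-building data.
        y : array-like of 0/1
            Case indicator.
        conditions : array-like of str, optional
            Per-record condition labels ("none", "SCAD", ...) used to assign
            each final marker to the condition driving it.
        """
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(X_arr.shape[1])]
        y = np.asarray(y).astype(int)
        n = X_arr.shape[0]
        size = self.subgroup_size if self.subgroup_size is not None else n // self.n_subgroups
        if self.n_subgroups * size > n:
            raise ValidationError("subgroup layout exceeds data size")

        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        n_leftover = n - self.n_subgroups * size

        selections: list[list[str]] = []
        traces: list[list[dict]] = []
        degenerate: list[int] = []
        for g in range(self.n_subgroups):
            rows = perm[g * size:(g + 1) * size]
            sel = StepwiseLogisticSelector(
                entry_p=self.entry_p, removal_p=self.removal_p,
                max_steps=self.max_steps, penalty=self.penalty,
                prescreen_k=self.prescreen_k,
            ).fit(_named(X_arr[rows], names), y[rows])
            if sel.degenerate_:
                degenerate.append(g)
            selections.append(list(sel.selected_features_))
            traces.append([asdict_step(s) for s in sel.step_trace_])

        union = sorted({f for sel in selections for f in sel},
                       key=names.index)
        consensus, counts = consensus_select(selections, self.consensus_min)
        consensus = sorted(consensus, key=names.index)

        if consensus and y.sum() > 0:
            cols = [names.index(f) for f in consensus]
            final = StepwiseLogisticSelector(
                entry_p=self.entry_p, removal_p=self.removal_p,
                max_steps=self.max_steps, penalty=self.penalty,
                prescreen_k=None,
            ).fit(_named(X_arr[:, cols], consensus), y)
            final_features = list(final.selected_features_)
            coefs = {f: float(c) for f, c in
                     zip(final_features,
                         [final.fit_.coef_[final.selected_features_.index(f)]
                          for f in final_features])}
            intercept = final.fit_.intercept_ if final.fit_ else None
            loglik = final.fit_.loglik if final.fit_ else None
            separation = bool(final.fit_.separation) if final.fit_ else False
            self.final_selector_ = final
        else:
            final_features, coefs = [], {}
            intercept = loglik = None
            separation = False
            self.final_selector_ = None

        assignment = {}
        if conditions is not None and final_features:
            assignment = assign_conditions(
                _named(X_arr, names)[final_features], np.asarray(conditions)
            )

        self.feature_names_in_ = names
        self.subgroup_selections_ = selections
        self.degenerate_subgroups_ = degenerate
        self.union_ = union
        self.appearance_counts_ = counts
        self.consensus_ = consensus
        self.final_features_ = final_features
        self.condition_assignment_ = assignment
        self.report_ = SelectionReport(
            config={
                "n_subgroups": self.n_subgroups, "subgroup_size": size,
                "entry_p": self.entry_p, "removal_p": self.removal_p,
                "consensus_min": self.consensus_min, "penalty": self.penalty,
                "prescreen_k": self.prescreen_k, "seed": self.seed,
            },
            subgroup_selections=selections,
            subgroup_traces=traces,
            degenerate_subgroups=degenerate,
            union=union,
            appearance_counts=counts,
            consensus=consensus,
            final_features=final_features,
            final_coefficients=coefs,
            final_intercept=intercept,
            final_loglik=loglik,
            separation_flag=separation,
            condition_assignment=assignment,
            n_leftover=n_leftover,
        )
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.final_features_]
        cols = [self.feature_names_in_.index(f) for f in self.final_features_]
        return np.asarray(X, dtype=float)[:, cols]


def assign_conditions(features: pd.DataFrame, conditions: np.ndarray) -> dict:
    """Assign each feature to the condition with the largest standardized
    case-vs-control separation of its values."""
    out = {}
    ctrl = conditions == "none"
    for f in features.columns:
        vals = features[f].to_numpy(dtype=float)
        mu0, sd0 = vals[ctrl].mean(), vals[ctrl].std()
        sd0 = sd0 if sd0 > 0 else 1.0
        best_cond, best_sep = None, -np.inf
        for cond in CONDITIONS:
            mask = conditions == cond
            if not mask.any():
                continue
            sep = abs(vals[mask].mean() - mu0) / sd0
            if sep > best_sep:
                best_cond, best_sep = cond, sep
        out[f] = best_cond
    return out


def fit_final_model(features, outcome, config: SelectionConfig,
                    consensus: list[str] | None = None):
    """Stepwise refit on the consensus set over the full model-building data.

    Returns the fitted StepwiseLogisticSelector; an empty consensus set
    yields an empty selection (reported, never raised).
    """
    values = getattr(features, "values", features)
    if consensus is not None:
        if not consensus:
            sel = StepwiseLogisticSelector(prescreen_k=None)
            sel.selected_features_ = []
            sel.selected_idx_ = []
            sel.step_trace_ = []
            sel.degenerate_ = True
            sel.fit_ = None
            return sel
        values = values[consensus] if isinstance(values, pd.DataFrame) else values
    sel = StepwiseLogisticSelector(
        entry_p=config.entry_p, removal_p=config.removal_p,
        max_steps=config.max_steps, penalty=config.penalty, prescreen_k=None,
    )
    return sel.fit(values, outcome)


def _named(arr: np.ndarray, names: list[str]) -> pd.DataFrame:
    return pd.DataFrame(arr, columns=names)


def asdict_step(step) -> dict:
    return {"step": step.step, "action": step.action, "feature": step.feature,
            "p_value": step.p_value, "loglik": step.loglik}
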