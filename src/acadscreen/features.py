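"""Pairwise-ratio feature expansion.

A panel of *m* analyte channels expands into ``m + m(m-1)/2`` candidate
marker features: every raw channel plus one ratio per unordered channel
pair.  For the default 43-channel panel this is 43 + 903 = 946 features.

Canonical ratio orientation follows panel order — the earlier channel is
the numerator — and names are ``"NUM/DEN"``.  Compound isobaric channels
use ``+`` in their names (``C5DC+C6-OH``), so ``/`` unambiguously separates
numerator from denominator; a name in the inverse orientation (e.g.
``C16-OH/C14:1`` when the canonical column is ``C14:1/C16-OH``) resolves to
the canonical column with an inversion flag.

Denominators at or below the detection limit are floored before division so
every ratio is finite and positive; on the (default) log scale the inverse
orientation is then exactly a sign flip.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortTable
from .errors import FeatureLookupError, ValidationError
from .panel import AnalytePanel

#: Default detection-limit floor, in the panel's concentration units.
DEFAULT_FLOOR = 0.01

Scale = Literal["raw", "log"]


def canonical_pairs(panel: AnalytePanel) -> list[tuple[int, int]]:
    """All unordered channel pairs (i, j) with i < j in panel order."""
    m = len(panel)
    iu = np.triu_indices(m, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def ratio_name(numerator: str, denominator: str) -> str:
    return f"{numerator}/{denominator}"


def parse_feature_name(name: str, panel: AnalytePanel):
    """Resolve a feature name against a panel.

    Returns ``("channel", index)`` for a raw channel, or
    ``("ratio", i, j, inverted)`` where (i, j) is the canonical pair
    (i < j in panel order) and ``inverted`` is True when ``name`` was
    written denominator-first.

    Channel names may contain ``+`` but never ``/``, so candidate split
    points are tried right-to-left and a split is accepted only when both
    sides are panel channels.
    """
    if name in panel:
        return ("channel", panel.index(name))
    pos = len(name)
    while True:
        pos = name.rfind("/", 0, pos)
        if pos < 0:
            break
        num, den = name[:pos], name[pos + 1:]
        if num in panel and den in panel:
            i, j = panel.index(num), panel.index(den)
            if i == j:
                raise FeatureLookupError(f"degenerate ratio {name!r}")
            if i < j:
                return ("ratio", i, j, False)
            return ("ratio", j, i, True)
    near = difflib.get_close_matches(name, panel.names, n=3, cutoff=0.4)
    hint = f"; close channel names: {near}" if near else ""
    raise FeatureLookupError(f"unknown feature {name!r}{hint}")


@dataclass
class FeatureMatrix:
    """Records × features matrix with ratio provenance.

    Column order is fixed: the *m* raw channels in panel order, then the
    ``m(m-1)/2`` canonical ratios in row-major upper-triangle order.
    """

    panel: AnalytePanel
    values: pd.DataFrame
    floor: float
    scale: Scale
    pairs: list[tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        m = len(self.panel)
        expected = m + m * (m - 1) // 2
        if self.values.shape[1] != expected:
            raise ValidationError(
                f"feature matrix has {self.values.shape[1]} columns, "
                f"expected {expected} for a {m}-channel panel"
            )

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_ratio_features(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.values)

    def lookup(self, name: str) -> tuple[np.ndarray, dict]:
        """Resolve ``name`` (raw channel, canonical ratio or its inverse).

        Returns the column values in the orientation *requested* (inverse
        names are sign-flipped on the log scale, reciprocated on the raw
        scale) plus a provenance dict with the canonical column name, the
        numerator/denominator and the inversion flag.
        """
        parsed = parse_feature_name(name, self.panel)
        if parsed[0] == "channel":
            idx = parsed[1]
            col = self.values.iloc[:, idx].to_numpy()
            return col, {"kind": "channel", "canonical": self.panel.names[idx],
                         "inverted": False}
        _, i, j, inverted = parsed
        canonical = ratio_name(self.panel.names[i], self.panel.names[j])
        col = self.values[canonical].to_numpy()
        if inverted:
            col = -col if self.scale == "log" else 1.0 / col
        return col, {
            "kind": "ratio",
            "canonical": canonical,
            "numerator": self.panel.names[j if inverted else i],
            "denominator": self.panel.names[i if inverted else j],
            "inverted": inverted,
        }


class RatioExpander(BaseEstimator, TransformerMixin):
    """Transformer expanding panel concentrations into the full feature set.

    Parameters
    ----------
    panel : AnalytePanel
        Channel catalogue fixing feature identity and order.
    floor : float, default 0.01
        Detection-limit floor applied before any division or log.
    scale : {"log", "raw"}, default "log"
        ``log`` emits natural-log features (the numerically robust choice
        for logistic modelling of heavy-tailed positive ratios); ``raw``
        emits concentrations and plain ratios.
    """

    def __init__(self, panel: AnalytePanel | None = None,
                 floor: float = DEFAULT_FLOOR, scale: Scale = "log"):
        self.panel = panel
        self.floor = floor
        self.scale = scale

    def fit(self, X, y=None):
        if self.floor is None or not (self.floor > 0):
            raise ValidationError("floor must be a positive real")
        if self.scale not in ("raw", "log"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        panel = self.panel
        if panel is None:
            if not isinstance(X, pd.DataFrame):
                raise ValidationError("panel required when X is not a DataFrame")
            panel = AnalytePanel.from_names(list(X.columns))
        self.panel_ = panel
        self.pairs_ = canonical_pairs(panel)
        names = list(panel.names)
        self.feature_names_out_ = names + [
            ratio_name(names[i], names[j]) for i, j in self.pairs_
        ]
        self.n_features_in_ = len(panel)
        return self

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)

    def transform(self, X) -> pd.DataFrame:
        panel = self.panel_
        if isinstance(X, pd.DataFrame):
            arr = X[panel.names].to_numpy(dtype=float)
            index = X.index
        else:
            arr = np.asarray(X, dtype=float)
            index = None
        if arr.shape[1] != len(panel):
            raise ValidationError(
                f"expected {len(panel)} channels, got {arr.shape[1]}"
            )
        if not np.isfinite(arr).all():
            row = int(np.where(~np.isfinite(arr).all(axis=1))[0][0])
            raise ValidationError(f"non-finite concentration at row {row}")

        floored = np.maximum(arr, self.floor)
        m = len(panel)
        out = np.empty((arr.shape[0], m + m * (m - 1) // 2))
        # ratio columns are written block-wise in upper-triangle row-major
        # order, matching canonical_pairs
        if self.scale == "log":
            logs = np.log(floored)
            out[:, :m] = logs
            off = m
            for i in range(m - 1):
                cnt = m - 1 - i
                np.subtract(logs[:, i][:, None], logs[:, i + 1:],
                            out=out[:, off:off + cnt])
                off += cnt
        else:
            out[:, :m] = np.maximum(arr, 0.0)
            off = m
            for i in range(m - 1):
                cnt = m - 1 - i
                np.divide(floored[:, i][:, None], floored[:, i + 1:],
                          out=out[:, off:off + cnt])
                off += cnt
        return pd.DataFrame(out, columns=self.feature_names_out_, index=index)


def expand_ratios(cohort: CohortTable, floor: float = DEFAULT_FLOOR,
                  scale: Scale = "log") -> FeatureMatrix:
    """Expand a cohort's first-specimen concentrations into a FeatureMatrix."""
    expander = RatioExpander(panel=cohort.panel, floor=floor, scale=scale)
    values = expander.fit(cohort.concentrations).transform(cohort.concentrations)
    return FeatureMatrix(panel=cohort.panel, values=values, floor=floor,
                         scale=scale, pairs=expander.pairs_)


def lookup_feature(matrix: FeatureMatrix, name: str) -> tuple[np.ndarray, dict]:
    """Module-level convenience wrapper over :meth:`FeatureMatrix.lookup`."""
    return matrix.lookup(name)
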