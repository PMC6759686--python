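"""Cohort container and delimited-text I/O.

A :class:`CohortTable` is a pandas DataFrame of newborn records bound to an
:class:`~acadscreen.panel.AnalytePanel`.  One row per newborn:

``id, <43 channel columns>, sex, ga_category, bw_category, age_days,
fetus_count, label, initial_positive, recalled, suspect_positive,
confirmed`` plus, for recalled newborns, second-specimen channel columns
named ``<channel>_2``.

Screening-stage flags follow the monotone two-stage logic of an expanded
newborn-screening programme: a confirmed case must have been suspect
positive, a suspect positive must have been recalled, and a recalled
newborn must have had a positive initial screen.  This is validated on
every construction and on every load.

The CSV dialect is fixed (comma separator, ``.`` decimal, UTF-8, header
required) so that write → load is the identity on valid cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .panel import AnalytePanel

SEX_CATEGORIES = ("male", "female", "unrecorded")
GA_CATEGORIES = ("<32", "32-36", ">=37", "unrecorded")
BW_CATEGORIES = ("<1500", "1500-1999", "2000-2499", ">=2500", "unrecorded")
CONDITIONS = ("SCAD", "MCAD", "VLCAD")
LABELS = ("none",) + CONDITIONS

COVARIATE_COLUMNS = ("sex", "ga_category", "bw_category", "age_days", "fetus_count")
STAGE_COLUMNS = ("initial_positive", "recalled", "suspect_positive", "confirmed")


def _second_col(channel: str) -> str:
    return f"{channel}_2"


@dataclass
class CohortTable:
    """Per-newborn analyte concentrations, covariates, label and stage flags.

    Parameters
    ----------
    panel : AnalytePanel
        The measurement panel all records share.
    data : pandas.DataFrame
        One row per newborn with the canonical column layout.
    provenance : dict
        Free-form origin record, e.g. ``{"source": "simulated", "seed": 7}``.
    """

    panel: AnalytePanel
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def concentrations(self) -> pd.DataFrame:
        """First-specimen concentration block, in panel order."""
        return self.data[self.panel.names]

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    def second_specimens(self) -> pd.DataFrame | None:
        cols = [_second_col(n) for n in self.panel.names]
        if not all(c in self.data.columns for c in cols):
            return None
        out = self.data[cols].copy()
        out.columns = self.panel.names
        return out

    def has_stage_flags(self) -> bool:
        return bool(self.data[list(STAGE_COLUMNS)].notna().any().any())

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        required = ["id", *self.panel.names, *COVARIATE_COLUMNS, "label",
                    *STAGE_COLUMNS]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicate record id {dup!r}")

        conc = df[self.panel.names].to_numpy(dtype=float)
        if not np.isfinite(conc).all():
            bad = df["id"].iloc[int(np.where(~np.isfinite(conc).all(axis=1))[0][0])]
            raise ValidationError(f"non-finite concentration in record {bad!r}")
        if (conc < 0).any():
            bad = df["id"].iloc[int(np.where((conc < 0).any(axis=1))[0][0])]
            raise ValidationError(f"negative concentration in record {bad!r}")

        bad_label = ~df["label"].isin(LABELS)
        if bad_label.any():
            raise ValidationError(
                f"unknown condition label {df.loc[bad_label, 'label'].iloc[0]!r}"
            )
        if (df["age_days"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("age_days must be >= 0")

        self._validate_stages(df)

    def _validate_stages(self, df: pd.DataFrame) -> None:
        # NA flags (stage not yet run) are treated as False for monotonicity.
        flags = {c: df[c].fillna(False).astype(bool).to_numpy()
                 for c in STAGE_COLUMNS}
        chain = ("confirmed", "suspect_positive", "recalled", "initial_positive")
        for narrow, wide in zip(chain[:-1], chain[1:]):
            viol = flags[narrow] & ~flags[wide]
            if viol.any():
                bad = df["id"].iloc[int(np.argmax(viol))]
                raise ValidationError(
                    f"stage monotonicity violated in record {bad!r}: "
                    f"{narrow} set without {wide}"
                )
        # Second specimens present iff recalled.
        second_cols = [c for c in df.columns if c.endswith("_2")]
        if second_cols:
            present = df[second_cols].notna().any(axis=1).to_numpy()
            mismatch = present != flags["recalled"]
            if mismatch.any():
                bad = df["id"].iloc[int(np.argmax(mismatch))]
                raise ValidationError(
                    f"second-specimen values must be present iff recalled "
                    f"(record {bad!r})"
                )


# ----------------------------------------------------------------------
# Delimited-text I/O

_BOOL_OUT = {True: "True", False: "False"}


def write_cohort(cohort: CohortTable, path) -> None:
    """Serialize a cohort as CSV such that :func:`load_cohort` round-trips.

    Floats are written at full (repr) precision; unset stage flags become
    empty cells.
    """
    df = cohort.data.copy()
    for col in STAGE_COLUMNS:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else _BOOL_OUT[bool(v)])
    df.to_csv(path, index=False)


def load_cohort(cohort_path, panel: AnalytePanel,
                on_missing: Literal["error", "drop"] = "error",
                provenance: dict | None = None) -> CohortTable:
    """Read a cohort CSV written in the canonical layout.

    Columns are matched by name, so their order need not follow the panel.

    Parameters
    ----------
    on_missing : {"error", "drop"}
        What to do with rows that have empty analyte cells: raise a
        validation error naming the record, or drop the rows (count kept in
        provenance).
    """
    df = pd.read_csv(cohort_path, dtype=str, keep_default_na=False)
    for col in ("id", *panel.names, *COVARIATE_COLUMNS, "label", *STAGE_COLUMNS):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")

    n_dropped = 0
    chan_cols = list(panel.names)
    missing_mask = (df[chan_cols] == "").any(axis=1)
    if missing_mask.any():
        if on_missing == "drop":
            n_dropped = int(missing_mask.sum())
            df = df.loc[~missing_mask].reset_index(drop=True)
        else:
            bad = df.loc[missing_mask, "id"].iloc[0]
            raise ValidationError(f"missing analyte value in record {bad!r}")

    out = pd.DataFrame({"id": df["id"].astype(str)})
    second_cols = [c for c in df.columns
                   if c.endswith("_2") and c[:-2] in panel._index]
    for col in chan_cols + second_cols:
        try:
            out[col] = _to_float(df[col])
        except ValueError as exc:
            raise FormatError(f"non-numeric value in column {col!r}: {exc}") from exc
    neg = out[chan_cols].lt(0).any(axis=1)
    if neg.any():
        bad = out.loc[neg, "id"].iloc[0]
        raise ValidationError(f"negative concentration in record {bad!r}")

    out["sex"] = df["sex"]
    out["ga_category"] = df["ga_category"]
    out["bw_category"] = df["bw_category"]
    out["age_days"] = df["age_days"].astype(int)
    out["fetus_count"] = df["fetus_count"].astype(int)
    out["label"] = df["label"]
    for col in STAGE_COLUMNS:
        out[col] = df[col].map(
            {"True": True, "False": False, "": pd.NA}
        ).astype("boolean")

    prov = dict(provenance or {})
    prov.setdefault("source", "loaded")
    prov["path"] = str(cohort_path)
    if n_dropped:
        prov["rows_dropped_missing"] = n_dropped
    return CohortTable(panel=panel, data=out, provenance=prov)


def _to_float(col: pd.Series) -> pd.Series:
    vals = col.where(col != "", other=np.nan)
    return vals.astype(float)


def empty_frame(panel: AnalytePanel, n: int, with_second: bool = False) -> pd.DataFrame:
    """Canonical empty record frame used by the simulator."""
    cols: dict[str, object] = {"id": [f"NB{i + 1:06d}" for i in range(n)]}
    for name in panel.names:
        cols[name] = np.zeros(n)
    cols.update(
        sex=np.full(n, "unrecorded", dtype=object),
        ga_category=np.full(n, "unrecorded", dtype=object),
        bw_category=np.full(n, "unrecorded", dtype=object),
        age_days=np.zeros(n, dtype=int),
        fetus_count=np.ones(n, dtype=int),
        label=np.full(n, "none", dtype=object),
    )
    df = pd.DataFrame(cols)
    for c in STAGE_COLUMNS:
        df[c] = pd.Series([pd.NA] * n, dtype="boolean")
    if with_second:
        for name in panel.names:
            df[_second_col(name)] = np.nan
    return df
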