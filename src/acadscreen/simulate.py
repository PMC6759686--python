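"""Synthetic newborn-screening cohort generator.

Emulates the statistical structure a marker-selection analysis of acyl-CoA
dehydrogenase (ACAD) deficiencies assumes:

* healthy analyte concentrations are log-normal per channel (optionally
  correlated on the log scale), calibrated so the routine screening
  thresholds for C4, C8 and C14:1 sit in the far upper tail of the healthy
  distribution (exceedance ~1e-3 to 1e-4, i.e. hundreds of initial false
  positives per ~350,000 newborns);
* rare cases — combined prevalence of order 1/17,000, split across SCAD
  (1/32,011), MCAD (1/88,030) and VLCAD (1/70,424) — carry multiplicative
  elevations of their enzyme's substrate acylcarnitines (SCAD: C4; MCAD:
  C6, C8; VLCAD: C14:1), with fold anchors chosen so simulated case values
  cover the observed case-value spans;
* covariates follow marginal frequencies typical of a large regional
  screening programme and are independent of the analytes;
* a two-stage screen/recall flow: initial positives are recalled with
  compliance ~96.1%, second specimens regress toward the record's latent
  mean with test–retest correlation rho, screen-positive repeats become
  suspect positives, and diagnostic confirmation is treated as perfect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cohort import CONDITIONS, CohortTable, empty_frame
from .errors import ConfigurationError, ValidationError
from .panel import AnalytePanel, default_panel

#: Default condition prevalences (confirmed cases per screened newborn).
DEFAULT_PREVALENCE = {
    "SCAD": 1.0 / 32_011,
    "MCAD": 1.0 / 88_030,
    "VLCAD": 1.0 / 70_424,
}

#: Fraction of initial screen-positives whose parents return for recall.
DEFAULT_RECALL_COMPLIANCE = 0.961

# Healthy background: per-channel (median concentration, log-scale sd).
# Acylcarnitine medians/sds are set so that the routine thresholds
# (C4 > 0.7, C8 > 0.3, C14:1 > 0.5) fall at z ~ 3.4-3.6 on the log scale.
_BACKGROUND = {
    "Ala": (250.0, 0.30), "Arg": (10.0, 0.30), "Cit": (12.0, 0.30),
    "Gly": (400.0, 0.30), "Leu": (120.0, 0.30), "Met": (25.0, 0.30),
    "Orn": (70.0, 0.30), "Phe": (55.0, 0.30), "Pro": (160.0, 0.30),
    "Tyr": (70.0, 0.30), "Val": (110.0, 0.30),
    "C2": (25.0, 0.35), "C3": (2.0, 0.40), "C3DC+C4-OH": (0.08, 0.40),
    "C4": (0.15, 0.45), "C4DC+C5-OH": (0.20, 0.40), "C5": (0.10, 0.40),
    "C5:1": (0.02, 0.40), "C5DC+C6-OH": (0.07, 0.40), "C6": (0.04, 0.35),
    "C6DC": (0.05, 0.40), "C8": (0.05, 0.50), "C8:1": (0.08, 0.40),
    "C10": (0.08, 0.40), "C10:1": (0.07, 0.40), "C10:2": (0.02, 0.40),
    "C12": (0.06, 0.40), "C12:1": (0.05, 0.40), "C14": (0.15, 0.40),
    "C14:1": (0.07, 0.55), "C14:2": (0.03, 0.40), "C14-OH": (0.02, 0.40),
    "C16": (2.5, 0.35), "C16:1": (0.15, 0.40), "C16:1-OH": (0.03, 0.40),
    "C16-OH": (0.02, 0.40), "C18": (0.8, 0.35), "C18:1": (1.2, 0.35),
    "C18:1-OH": (0.02, 0.40), "C18:2": (0.3, 0.35), "C18-OH": (0.02, 0.40),
    "C0": (30.0, 0.30), "SA": (0.8, 0.30),
}

# Covariate marginals of a large regional screening cohort.
_SEX_P = {"male": 0.5262, "female": 0.4737, "unrecorded": 0.0001}
_GA_P = {"<32": 0.0043, "32-36": 0.0487, ">=37": 0.9438, "unrecorded": 0.0032}
_BW_P = {"<1500": 0.0016, "1500-1999": 0.0049, "2000-2499": 0.0224,
         ">=2500": 0.9418, "unrecorded": 0.0293}
_FETUS_P = {1: 0.99222, 2: 0.00773, 3: 0.00005}


@dataclass(frozen=True)
class EffectProfile:
    """Condition-specific multiplicative elevation of substrate channels.

    ``folds`` maps channel name -> anchor fold-change (> 0); each case draws
    its personal fold log-normally around the anchor with the given
    log-scale ``dispersion``.  Channels not listed follow the healthy
    background.
    """

    condition: str
    folds: dict[str, float]
    dispersion: float = 0.4

    def __post_init__(self) -> None:
        if not self.folds:
            raise ValidationError(
                f"effect profile for {self.condition} perturbs no channel"
            )
        for ch, f in self.folds.items():
            if not (f > 0):
                raise ValidationError(
                    f"effect profile fold for {ch} must be positive"
                )


#: Default case effect anchors.  Fold anchors place the median simulated
#: case value inside the observed case-value spans for each condition
#: (e.g. VLCAD initial C14:1 between 0.63 and 4.27).
DEFAULT_EFFECTS = {
    "SCAD": EffectProfile("SCAD", {"C4": 8.0}, dispersion=0.35),
    "MCAD": EffectProfile("MCAD", {"C8": 30.0, "C6": 10.0}, dispersion=0.80),
    "VLCAD": EffectProfile("VLCAD", {"C14:1": 23.0}, dispersion=0.45),
}


@dataclass
class SimulationConfig:
    """Full specification of a synthetic screening cohort.

    Parameters
    ----------
    n : int
        Number of newborns.
    prevalence : dict
        Condition -> probability of a confirmed case (i.i.d. per record).
    background : dict
        Channel -> (median, log_sd) of the healthy log-normal background.
    correlation : ndarray or None
        Optional log-scale channel correlation matrix (PSD, symmetric).
    effect_profiles : dict
        Condition -> EffectProfile.
    retest_rho : float
        Test-retest correlation of log concentrations between specimens.
    recall_compliance : float
        Probability an initial screen-positive returns for recall.
    seed : int
        Master seed; identical config + seed => identical cohort.
    """

    n: int
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    background: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_BACKGROUND))
    correlation: np.ndarray | None = None
    effect_profiles: dict[str, EffectProfile] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    retest_rho: float = 0.70
    recall_compliance: float = DEFAULT_RECALL_COMPLIANCE
    seed: int = 0

    def validate(self, panel: AnalytePanel) -> None:
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        total_prev = 0.0
        for cond, p in self.prevalence.items():
            if cond not in CONDITIONS:
                raise ValidationError(f"unknown condition {cond!r} in prevalence")
            if p < 0:
                raise ValidationError(f"prevalence for {cond} must be >= 0")
            total_prev += p
        if total_prev >= 1:
            raise ValidationError("prevalences must sum to < 1")
        if not (0.0 <= self.retest_rho <= 1.0):
            raise ValidationError("retest_rho must be in [0, 1]")
        if not (0.0 <= self.recall_compliance <= 1.0):
            raise ValidationError("recall_compliance must be in [0, 1]")
        for name in panel.names:
            if name not in self.background:
                raise ValidationError(f"background missing channel {name!r}")
            med, sd = self.background[name]
            if not (med > 0 and sd > 0):
                raise ValidationError(
                    f"background for {name!r} needs median > 0 and log_sd > 0"
                )
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (len(panel), len(panel)):
                raise ValidationError("correlation matrix has wrong shape")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValidationError("correlation matrix must be symmetric")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ValidationError("correlation matrix must be PSD")
        for cond, prof in self.effect_profiles.items():
            for ch in prof.folds:
                if ch not in panel:
                    raise ValidationError(
                        f"effect profile for {cond} names unknown channel {ch!r}"
                    )

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n": self.n,
            "prevalence": dict(self.prevalence),
            "background": {k: [float(v[0]), float(v[1])]
                           for k, v in self.background.items()},
            "effect_profiles": {
                c: {"folds": dict(p.folds), "dispersion": p.dispersion}
                for c, p in self.effect_profiles.items()
            },
            "retest_rho": self.retest_rho,
            "recall_compliance": self.recall_compliance,
            "seed": self.seed,
        }
        if self.correlation is not None:
            doc["correlation"] = np.asarray(self.correlation).tolist()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        effects = {
            c: EffectProfile(c, d["folds"], d.get("dispersion", 0.4))
            for c, d in doc.get("effect_profiles", {}).items()
        }
        return cls(
            n=int(doc["n"]),
            prevalence=doc.get("prevalence", dict(DEFAULT_PREVALENCE)),
            background={k: (float(v[0]), float(v[1]))
                        for k, v in doc.get("background", _BACKGROUND).items()},
            correlation=(np.asarray(doc["correlation"], dtype=float)
                         if "correlation" in doc else None),
            effect_profiles=effects or dict(DEFAULT_EFFECTS),
            retest_rho=float(doc.get("retest_rho", 0.70)),
            recall_compliance=float(doc.get("recall_compliance",
                                            DEFAULT_RECALL_COMPLIANCE)),
            seed=int(doc.get("seed", 0)),
        )


# ----------------------------------------------------------------------


def generate_cohort(config: SimulationConfig,
                    panel: AnalytePanel | None = None) -> CohortTable:
    """Draw a synthetic cohort; stage flags are left unset.

    Deterministic given ``config.seed``: labels first, then log-scale
    concentrations, then case effects, then covariates.
    """
    panel = panel or default_panel()
    config.validate(panel)
    rng = np.random.default_rng(config.seed)
    n, m = config.n, len(panel)

    conds = list(CONDITIONS)
    probs = [config.prevalence.get(c, 0.0) for c in conds]
    p_all = np.array(probs + [1.0 - sum(probs)])
    labels = rng.choice(np.array(conds + ["none"], dtype=object), size=n, p=p_all)

    log_mean = np.array([math.log(config.background[c][0]) for c in panel.names])
    log_sd = np.array([config.background[c][1] for c in panel.names])
    z = rng.standard_normal((n, m))
    if config.correlation is not None:
        # PSD factor via eigen-decomposition (tolerates semi-definiteness)
        vals, vecs = np.linalg.eigh(np.asarray(config.correlation, dtype=float))
        factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
        z = z @ factor.T
    logx = log_mean + log_sd * z

    for cond in conds:
        rows = np.flatnonzero(labels == cond)
        prof = config.effect_profiles.get(cond)
        if prof is None or len(rows) == 0:
            continue
        for ch, fold in prof.folds.items():
            j = panel.index(ch)
            logx[rows, j] += math.log(fold) + prof.dispersion * rng.standard_normal(len(rows))

    df = empty_frame(panel, n)
    df[panel.names] = np.exp(logx)
    df["label"] = labels
    df["sex"] = rng.choice(np.array(list(_SEX_P), dtype=object), size=n,
                           p=_normalize(list(_SEX_P.values())))
    df["ga_category"] = rng.choice(np.array(list(_GA_P), dtype=object), size=n,
                                   p=_normalize(list(_GA_P.values())))
    df["bw_category"] = rng.choice(np.array(list(_BW_P), dtype=object), size=n,
                                   p=_normalize(list(_BW_P.values())))
    df["age_days"] = 3 + np.minimum(rng.poisson(1.0, size=n), 25)
    df["fetus_count"] = rng.choice(np.array(list(_FETUS_P)), size=n,
                                   p=_normalize(list(_FETUS_P.values())))
    return CohortTable(
        panel=panel, data=df,
        provenance={"source": "simulated", "seed": config.seed, "n": n},
    )


def run_two_stage_flow(cohort: CohortTable, rule,
                       config: SimulationConfig) -> CohortTable:
    """Apply the screen -> recall -> repeat -> confirm flow to a fresh cohort.

    ``rule`` is a ScreeningRule (or anything with ``positive_on_frame``),
    or a list of them (positive = any rule fires).  Second specimens are
    drawn with log-scale autoregression toward the record's latent mean:
    ``log x2 = mu + rho (log x1 - mu) + sigma sqrt(1 - rho^2) z``, so
    ``rho = 1`` reproduces the first specimen exactly and smaller ``rho``
    lets upper-tail false positives regress back under threshold.
    Confirmation equals suspect-positive AND a true condition label.
    """
    if cohort.has_stage_flags():
        raise ValidationError("cohort already carries stage flags")
    panel = cohort.panel
    rules = rule if isinstance(rule, (list, tuple)) else [rule]
    rng = np.random.default_rng(config.seed + 0x5F10)

    conc1 = cohort.concentrations
    initial = np.zeros(len(cohort), dtype=bool)
    for r in rules:
        initial |= _apply_rule_frame(r, conc1, panel)

    recalled = initial & (rng.random(len(cohort)) < config.recall_compliance)

    df = cohort.data.copy()
    # latent per-record mean: background + case-effect anchor
    log_mu = np.tile(
        np.array([math.log(config.background[c][0]) for c in panel.names]),
        (len(cohort), 1),
    )
    log_sd = np.tile(
        np.array([config.background[c][1] for c in panel.names]),
        (len(cohort), 1),
    )
    labels = cohort.labels.to_numpy()
    for cond, prof in config.effect_profiles.items():
        rows = np.flatnonzero(labels == cond)
        for ch, fold in prof.folds.items():
            j = panel.index(ch)
            log_mu[rows, j] += math.log(fold)
            log_sd[rows, j] = np.hypot(log_sd[rows, j], prof.dispersion)

    rho = config.retest_rho
    log_x1 = np.log(np.maximum(conc1.to_numpy(dtype=float), 1e-12))
    noise = rng.standard_normal(log_x1.shape)
    log_x2 = log_mu + rho * (log_x1 - log_mu) + log_sd * math.sqrt(1.0 - rho ** 2) * noise
    if rho == 1.0:
        log_x2 = log_x1
    x2 = np.exp(log_x2)

    second = pd.DataFrame(x2, columns=panel.names, index=conc1.index)
    suspect = np.zeros(len(cohort), dtype=bool)
    if recalled.any():
        pos2 = np.zeros(len(cohort), dtype=bool)
        for r in rules:
            pos2 |= _apply_rule_frame(r, second, panel)
        suspect = recalled & pos2
    confirmed = suspect & (labels != "none")

    for name in panel.names:
        col = np.full(len(cohort), np.nan)
        col[recalled] = x2[recalled, panel.index(name)]
        df[f"{name}_2"] = col
    df["initial_positive"] = pd.array(initial, dtype="boolean")
    df["recalled"] = pd.array(recalled, dtype="boolean")
    df["suspect_positive"] = pd.array(suspect, dtype="boolean")
    df["confirmed"] = pd.array(confirmed, dtype="boolean")

    prov = dict(cohort.provenance)
    prov["two_stage_flow"] = {"retest_rho": rho,
                              "recall_compliance": config.recall_compliance}
    return CohortTable(panel=panel, data=df, provenance=prov)


def _apply_rule_frame(rule, frame: pd.DataFrame, panel) -> np.ndarray:
    try:
        return np.asarray(rule.positive_on_frame(frame, panel), dtype=bool)
    except KeyError as exc:
        raise ConfigurationError(
            f"screening rule references a feature unavailable in the panel: {exc}"
        ) from exc


def plant_marker_scenario(config: SimulationConfig, numerator: str,
                          denominator: str, fold: float,
                          condition: str = "SCAD",
                          panel: AnalytePanel | None = None) -> SimulationConfig:
    """Config whose single condition makes NUM/DEN the best single marker.

    The numerator is elevated by sqrt(fold) and the denominator depressed
    by sqrt(fold), so the planted ratio shifts by the full fold while each
    raw channel moves only half as far on the log scale — by construction
    the ratio dominates every raw channel and every other pair as a single
    discriminator.
    """
    panel = panel or default_panel()
    if numerator == denominator:
        raise ValidationError("numerator and denominator must differ")
    if not (fold > 1):
        raise ValidationError("fold must be > 1")
    for ch in (numerator, denominator):
        if ch not in panel:
            raise ValidationError(f"channel {ch!r} not in panel")
    half = math.sqrt(fold)
    profile = EffectProfile(condition,
                            {numerator: half, denominator: 1.0 / half},
                            dispersion=0.20)
    prev_total = sum(config.prevalence.values()) or sum(DEFAULT_PREVALENCE.values())
    return replace(
        config,
        prevalence={condition: prev_total},
        effect_profiles={condition: profile},
    )


def _normalize(p: list[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    return arr / arr.sum()
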