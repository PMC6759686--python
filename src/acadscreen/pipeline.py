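"""End-to-end orchestration and flow reporting.

``run_pipeline`` chains simulate -> two-stage flow -> split -> expand ->
subgroup-consensus selection -> indicator evaluation, writing every stage
output plus a run manifest under one directory.  A single master seed fans
out to per-stage seeds through ``numpy.random.SeedSequence`` so stages can
be rerun in isolation yet the whole run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CONDITIONS, CohortTable, write_cohort
from .errors import AcadScreenError
from .features import expand_ratios
from .screening import default_rules, evaluate_indicators, incidence_string, round_half_up
from .selection import SubgroupConsensusSelector, split_model_testing
from .simulate import SimulationConfig, generate_cohort, run_two_stage_flow
from .stepwise import SelectionConfig

logger = logging.getLogger("acadscreen")


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds (< 2^31) derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFF_FFFF) for s in state]


def render_flow_summary(cohort: CohortTable) -> dict:
    """Stage counts of a screened cohort, with per-condition confirmations.

    Requires stage flags (the two-stage flow must have run).  The recall
    fraction is rendered as "recalled (pct%)" with one decimal.
    """
    if not cohort.has_stage_flags():
        raise AcadScreenError("cohort has no stage flags; run the flow first")
    df = cohort.data
    flags = {c: df[c].fillna(False).astype(bool) for c in
             ("initial_positive", "recalled", "suspect_positive", "confirmed")}
    initial = int(flags["initial_positive"].sum())
    recalled = int(flags["recalled"].sum())
    suspect = int(flags["suspect_positive"].sum())
    confirmed = int(flags["confirmed"].sum())
    pct = round_half_up(100.0 * recalled / initial) if initial else None
    per_condition = {}
    for cond in CONDITIONS:
        mask = df["label"] == cond
        n_conf = int((flags["confirmed"] & mask).sum())
        per_condition[cond] = {
            "cases": int(mask.sum()),
            "confirmed": n_conf,
            "incidence": incidence_string(n_conf, len(df)) if n_conf else None,
        }
    return {
        "screened": len(df),
        "initial_positive": initial,
        "recalled": recalled,
        "recalled_display": (f"{recalled} ({pct:.1f}%)" if pct is not None
                             else f"{recalled}"),
        "suspect_positive": suspect,
        "confirmed": confirmed,
        "confirmed_incidence": (incidence_string(confirmed, len(df))
                                if confirmed else None),
        "per_condition": per_condition,
    }


@dataclass
class RunManifest:
    """Traceability record tying outputs to configs and the master seed."""

    tool_version: str
    seed: int
    stage_seeds: list[int]
    config_digests: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(sim_config: SimulationConfig,
                 select_config: SelectionConfig,
                 outdir,
                 seed: int | None = None,
                 rules: dict | None = None) -> dict:
    """Execute every stage in order, writing outputs and a manifest.

    Returns a dict of output paths plus the in-memory selection report and
    flow summary.  Any stage error aborts with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = sim_config.seed if seed is None else seed
    seeds = stage_seeds(seed)
    rules = rules or default_rules()
    manifest = RunManifest(tool_version=__version__, seed=seed, stage_seeds=seeds)
    manifest.config_digests["sim"] = hashlib.sha256(
        repr(sorted(asdict_sim(sim_config).items())).encode()).hexdigest()

    stage = "simulate"
    try:
        cfg = SimulationConfig(**{**asdict_sim(sim_config), "seed": seeds[0]})
        cohort = generate_cohort(cfg)
        logger.info("simulate: n=%d cases=%d", len(cohort),
                    int((cohort.labels != "none").sum()))

        stage = "two-stage-flow"
        flowed = run_two_stage_flow(cohort, list(rules.values()), cfg)
        cohort_path = outdir / "cohort.csv"
        write_cohort(flowed, cohort_path)
        summary = render_flow_summary(flowed)
        flow_path = outdir / "flow_summary.json"
        flow_path.write_text(json.dumps(summary, indent=2))

        stage = "split"
        model, testing = split_model_testing(
            cohort, select_config.n_model, seed=seeds[1], stratify=True)

        stage = "select"
        feats_log = expand_ratios(model, scale="log")
        y = (model.labels != "none").astype(int).to_numpy()
        selector = SubgroupConsensusSelector(
            n_subgroups=select_config.n_subgroups,
            subgroup_size=select_config.subgroup_size,
            entry_p=select_config.entry_p,
            removal_p=select_config.removal_p,
            max_steps=select_config.max_steps,
            consensus_min=select_config.consensus_min,
            penalty=select_config.penalty,
            prescreen_k=select_config.prescreen_k,
            seed=seeds[2],
        ).fit(feats_log.values, y, conditions=model.labels.to_numpy())
        selection_path = outdir / "selection.json"
        selector.report_.to_json(selection_path)
        logger.info("select: final=%s", selector.final_features_)

        stage = "evaluate"
        parts = {
            "model": (expand_ratios(model, scale="raw"),
                      model.labels.to_numpy()),
            "testing": (expand_ratios(testing, scale="raw"),
                        testing.labels.to_numpy()),
        }
        assignment = selector.condition_assignment_
        indicators = {}
        for cond in CONDITIONS:
            new = [f for f, c in assignment.items() if c == cond]
            if not new and not rules.get(cond):
                continue
            indicators[cond] = new + ([rules[cond]] if cond in rules else [])
        table = evaluate_indicators(parts, indicators) if indicators else None
        tables_path = outdir / "tables.csv"
        if table is not None:
            table.to_csv(tables_path, index=False)

        stage = "manifest"
        for p in (cohort_path, flow_path, selection_path, tables_path):
            if p.exists():
                manifest.output_checksums[p.name] = _sha256(p)
        manifest.timestamps["completed"] = time.strftime(
            "%Y-%m-%dT%H:%M:%S", time.gmtime())
        manifest_path = outdir / "manifest.json"
        manifest.write(manifest_path)
    except Exception as exc:
        raise AcadScreenError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "cohort": cohort_path, "flow_summary": flow_path,
        "selection": selection_path, "tables": tables_path,
        "manifest": manifest_path,
        "selector": selector, "summary": summary,
    }


def asdict_sim(cfg: SimulationConfig) -> dict:
    """Plain-dict view of a SimulationConfig (numpy arrays listed)."""
    return {
        "n": cfg.n,
        "prevalence": dict(cfg.prevalence),
        "background": {k: tuple(v) for k, v in cfg.background.items()},
        "correlation": (np.asarray(cfg.correlation).tolist()
                        if cfg.correlation is not None else None),
        "effect_profiles": dict(cfg.effect_profiles),
        "retest_rho": cfg.retest_rho,
        "recall_compliance": cfg.recall_compliance,
        "seed": cfg.seed,
    }
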