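"""End-to-end pipeline: configuration, stage orchestration, run manifests.

A run is declared by a YAML configuration (see :class:`RunConfig`): either
three input tables or a ``simulate`` block, the eligibility rules per arm,
matching and screen settings, an output directory and one global seed.  The
global seed fans out to per-stage seeds by a fixed derivation, so a config +
seed pair fully determines every output byte, and every stage logs its counts
(selected, matched, screened, filtered) so the cohort funnel is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import claims as cm
from .cohort import CohortSpec, demographic_summary, select_cohort
from .errors import ComoscreenError, ConfigError
from .matching import PropensityModel, balance_report, greedy_digit_match
from .screen import ComorbidityScreen, ScreenConfig
from .simulate import (default_truth, read_truth_manifest, simulate_dataset,
                       write_truth_manifest)

__all__ = ["RunConfig", "run_simulate", "run_screen", "derive_seed"]

log = logging.getLogger(__name__)

CASE_PATTERNS = ["714.0*", "714.1*", "714.2*", "714.3*"]
CONTROL_PATTERNS = ["690.*", "691.*", "692.*"]

_STAGE_IDS = {"population": 0, "claims": 1, "match": 2}


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from the global one (fixed derivation, < 2**31)."""
    import numpy as np
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    seed: int = 0
    outdir: Path = Path("comoscreen_out")
    inputs: "dict | None" = None          # persons/claims/enrollment paths
    simulate: "dict | None" = None        # kwargs for default_truth()
    case: dict = field(default_factory=dict)
    control: dict = field(default_factory=dict)
    matching: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}") from None
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config {path}: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.outdir = Path(cfg.outdir)
        if cfg.inputs is not None:
            missing = {"persons", "claims", "enrollment"} - set(cfg.inputs)
            if missing:
                raise ConfigError(f"inputs block missing {sorted(missing)}")
        return cfg

    def cohort_spec(self, arm: str) -> CohortSpec:
        block = dict(self.case if arm == "case" else self.control)
        block.setdefault("patterns",
                         CASE_PATTERNS if arm == "case" else CONTROL_PATTERNS)
        try:
            return CohortSpec(**block)
        except TypeError as exc:
            raise ConfigError(f"bad {arm} cohort spec: {exc}") from exc

    def screen_config(self) -> ScreenConfig:
        try:
            return ScreenConfig(**self.screen)
        except TypeError as exc:
            raise ConfigError(f"bad screen config: {exc}") from exc


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate the synthetic tables declared by the config's simulate block.

    Writes persons.csv, claims.csv, enrollment.csv and truth.yaml into the
    output directory; returns their paths.
    """
    block = dict(config.simulate or {})
    block.setdefault("seed", derive_seed(config.seed, "population"))
    truth = default_truth(**block)
    data = simulate_dataset(truth)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.csv" for k in ("persons", "claims", "enrollment")}
    cm.write_persons(data["persons"], paths["persons"])
    cm.write_claims(data["claims"], paths["claims"])
    cm.write_enrollment(data["enrollment"], paths["enrollment"])
    paths["truth"] = outdir / "truth.yaml"
    write_truth_manifest(truth, paths["truth"])
    log.info("stage=simulate persons=%d claims=%d codes=%d outdir=%s",
             len(data["persons"]), len(data["claims"]), len(truth.entries),
             outdir)
    return paths


def run_screen(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline: select, match, screen, report.

    Reads the configured input tables (simulating them first when the config
    has a ``simulate`` block and no ``inputs``), then writes, in order:
    cohort.csv, demographics.json, matches.csv, balance.csv, ranked.csv,
    top_k.txt and run_manifest.json.
    """
    if config.inputs is None:
        if config.simulate is None:
            raise ConfigError("config needs either an inputs or a simulate block")
        sim_paths = run_simulate(config)
        inputs = {k: sim_paths[k] for k in ("persons", "claims", "enrollment")}
    else:
        inputs = {k: Path(v) for k, v in config.inputs.items()}
        for k, p in inputs.items():
            if not p.exists():
                raise ConfigError(f"input table {k!r} not found: {p}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons = cm.read_persons(inputs["persons"])
    claim_df = cm.read_claims(inputs["claims"])
    enrollment = cm.read_enrollment(inputs["enrollment"])
    log.info("stage=load persons=%d claims=%d spells=%d",
             len(persons), len(claim_df), len(enrollment))

    cases = select_cohort(claim_df, enrollment, persons,
                          config.cohort_spec("case"), arm="case")
    controls = select_cohort(claim_df, enrollment, persons,
                             config.cohort_spec("control"), arm="control")
    # arms stay disjoint: a person qualifying for both goes to the case arm
    overlap = controls["person_id"].isin(set(cases["person_id"]))
    controls = controls[~overlap].reset_index(drop=True)
    log.info("stage=cohort cases=%d controls=%d overlap_removed=%d",
             len(cases), len(controls), int(overlap.sum()))
    members = pd.concat([cases, controls], ignore_index=True)
    if cases.empty or controls.empty:
        raise ComoscreenError(
            f"stage=cohort: empty arm (cases={len(cases)}, controls={len(controls)})")

    paths: dict[str, Path] = {"cohort": outdir / "cohort.csv"}
    out = members.copy()
    out["index_date"] = out["index_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(paths["cohort"], index=False)

    demo = demographic_summary(cases)
    paths["demographics"] = outdir / "demographics.json"
    hist = demo.pop("histogram")
    demo["histogram"] = hist.to_dict("records")
    paths["demographics"].write_text(json.dumps(demo, indent=2, sort_keys=True))

    results = PropensityModel(members).fit()
    scores = results.score(members)
    case_scores = scores[members["arm"].to_numpy() == "case"]
    control_scores = scores[members["arm"].to_numpy() == "control"]
    match_cfg = dict(config.matching)
    match_seed = match_cfg.pop("seed", None)
    if match_seed is None:
        match_seed = derive_seed(config.seed, "match")
    match = greedy_digit_match(case_scores, control_scores,
                               seed=int(match_seed), **match_cfg)
    log.info("stage=match pairs=%d unmatched_cases=%d iterations=%d",
             len(match), len(match.unmatched_cases), results.iterations)
    paths["matches"] = outdir / "matches.csv"
    match.pairs.to_csv(paths["matches"], index=False, float_format="%.10g")
    paths["propensity"] = outdir / "propensity.txt"
    paths["propensity"].write_text(results.summary() + "\n")

    paths["balance"] = outdir / "balance.csv"
    balance_report(members, match.pairs).to_csv(paths["balance"],
                                                float_format="%.10g")

    matched_ids = pd.concat([match.pairs["case_id"], match.pairs["control_id"]])
    matched_members = members[members["person_id"].isin(set(matched_ids))]
    screen_res = ComorbidityScreen(claim_df, matched_members,
                                   config.screen_config()).fit()
    if screen_res.n_codes_ranked == 0:
        log.info("stage=screen event=empty_ranked_output dropped=%s",
                 screen_res.dropped)
    log.info("stage=screen codes_recorded=%d codes_ranked=%d dropped=%s",
             screen_res.n_codes_recorded, screen_res.n_codes_ranked,
             screen_res.dropped)
    paths["ranked"] = outdir / "ranked.csv"
    screen_res.to_csv(paths["ranked"])
    paths["top_k"] = outdir / "top_k.txt"
    paths["top_k"].write_text(screen_res.top().to_string(index=False) + "\n")

    manifest = {
        "seed": int(config.seed),
        "funnel": {
            "persons": len(persons),
            "cases_selected": len(cases),
            "controls_selected": len(controls),
            "pairs_matched": len(match),
            "cases_unmatched": len(match.unmatched_cases),
            "codes_recorded": screen_res.n_codes_recorded,
            "codes_ranked": screen_res.n_codes_ranked,
            "codes_dropped": screen_res.dropped,
        },
        "artifacts": {k: str(v) for k, v in paths.items()},
    }
    paths["run_manifest"] = outdir / "run_manifest.json"
    paths["run_manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
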