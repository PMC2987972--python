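"""Synthetic administrative-claims generator with planted ground truth.

Real US commercial-claims databases (the setting this package targets) are
proprietary, so every downstream stage is exercised against simulated claims
whose statistical structure is known exactly:

* a **population** with the demographic profile of a chronic-disease cohort —
  age from a truncated normal (default mean 59 y, bounds 16-100), sex and plan
  (Medicare vs commercial) as Bernoulli draws (defaults 73.8% female, 35%
  Medicare);
* **defining-condition claims**: every case receives two encounter-kind claims
  carrying the case-condition code (default 714.0, rheumatoid arthritis), one
  dated before the pre-cutoff date and one inside the observation window, so
  the cohort-selection rules are satisfiable by construction; controls receive
  the same structure with the control-condition code (default 692.0,
  dermatitis);
* **comorbidity events**: each code book entry is a per-person Bernoulli event
  — probability ``p0`` in controls, ``min(rr * p0, 1)`` in cases — emitted at
  most once per person and dated uniformly inside the one-year window.
  A nonzero ``confounder_slope`` adds ``slope * (age - mean_age) / 10`` to the
  log-odds, and ``case_age_shift`` moves the case arm's mean age, which
  together create classical age confounding for the matching stage to remove;
* **enrollment spells** covering the reference date for everyone.

The generator is fully deterministic given its seed, and the planted scenario
(`SimulationTruth`) serializes losslessly to a YAML manifest so that recovery
of the planted relative risks can be tested end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import truncnorm

from ._codebook import CODE_DESCRIPTIONS, DEFAULT_CODEBOOK
from .errors import ConfigError, ManifestError

__all__ = [
    "DemographicSpec",
    "CodeBookEntry",
    "SimulationTruth",
    "default_truth",
    "generate_population",
    "generate_cohort_claims",
    "simulate_dataset",
    "write_truth_manifest",
    "read_truth_manifest",
]

MANIFEST_SCHEMA_VERSION = 1

REFERENCE_DATE = pd.Timestamp("2007-06-30")   # active-enrollment reference
WINDOW_START = pd.Timestamp("2006-07-01")     # one-year observation window
WINDOW_END = pd.Timestamp("2007-06-30")
PRE_WINDOW_START = pd.Timestamp("2005-07-01")  # earliest defining-claim date

CASE_CONDITION_CODE = "7140"
CONTROL_CONDITION_CODE = "6920"


@dataclass(frozen=True)
class DemographicSpec:
    """Marginal demographic structure of a simulated cohort.

    ``mean_age``/``sd_age`` parameterize the underlying normal before
    truncation to [min_age, max_age]; ages are measured at the reference date.
    """

    mean_age: float = 59.0
    sd_age: float = 15.0
    female_frac: float = 0.738
    medicare_frac: float = 0.35
    min_age: float = 16.0
    max_age: float = 100.0

    def __post_init__(self) -> None:
        for name in ("female_frac", "medicare_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not self.min_age < self.mean_age < self.max_age:
            raise ConfigError("mean_age must lie inside (min_age, max_age)")
        if self.sd_age <= 0:
            raise ConfigError("sd_age must be positive")


@dataclass(frozen=True)
class CodeBookEntry:
    """One comorbidity code with its planted baseline prevalence and RR.

    ``p0`` is the one-year event probability in controls; cases use
    ``p1 = min(rr * p0, 1)``. ``confounder_slope`` is the additive log-odds
    change per decade of age above the population mean (0 = no confounding).
    """

    icd9: str
    p0: float
    rr: float = 1.0
    description: str = ""
    confounder_slope: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ConfigError(f"p0 must be in (0, 1), got {self.p0} for {self.icd9}")
        if self.rr < 0:
            raise ConfigError(f"rr must be >= 0, got {self.rr} for {self.icd9}")

    @property
    def p1(self) -> float:
        """Case-arm event probability, capped at 1."""
        return min(self.rr * self.p0, 1.0)


@dataclass(frozen=True)
class SimulationTruth:
    """Complete planted scenario: demographics, arm sizes, code book, seed."""

    entries: tuple[CodeBookEntry, ...]
    n_cases: int
    n_controls: int
    seed: int
    demographics: DemographicSpec = field(default_factory=DemographicSpec)
    case_age_shift: float = 0.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigError("code book is empty")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("n_cases and n_controls must be >= 1")
        object.__setattr__(self, "entries", tuple(self.entries))


def default_truth(n_cases: int = 5000, n_controls: int = 5000, seed: int = 0,
                  case_age_shift: float = 0.0,
                  confounder_slope: float = 0.0) -> SimulationTruth:
    """The shipped default scenario: a code book mixing strongly
    case-associated, common, control-associated and excluded-chapter codes."""
    entries = tuple(
        CodeBookEntry(icd9=c, p0=p0, rr=rr,
                      description=CODE_DESCRIPTIONS.get(c, ""),
                      confounder_slope=confounder_slope)
        for c, p0, rr in DEFAULT_CODEBOOK
    )
    return SimulationTruth(entries=entries, n_cases=n_cases, n_controls=n_controls,
                           seed=seed, case_age_shift=case_age_shift)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_population(n: int, demo: DemographicSpec = DemographicSpec(),
                        seed: int = 0, id_prefix: str = "P",
                        mean_age: "float | None" = None) -> pd.DataFrame:
    """Draw *n* persons: truncated-normal age, Bernoulli sex and plan.

    ``mean_age`` overrides the spec's mean (used to age-shift one arm).
    Returns a persons table (person_id, birth_year, sex, plan); birth_year is
    the reference year minus the integer age at the reference date.
    """
    if n < 1:
        raise ConfigError(f"population size must be >= 1, got {n}")
    rng = _rng(seed)
    loc = demo.mean_age if mean_age is None else mean_age
    a = (demo.min_age - loc) / demo.sd_age
    b = (demo.max_age - loc) / demo.sd_age
    ages = truncnorm.rvs(a, b, loc=loc, scale=demo.sd_age, size=n, random_state=rng)
    width = len(str(n))
    return pd.DataFrame({
        "person_id": [f"{id_prefix}{i:0{width}d}" for i in range(n)],
        "birth_year": REFERENCE_DATE.year - np.rint(ages).astype(int),
        "sex": np.where(rng.random(n) < demo.female_frac, "F", "M"),
        "plan": np.where(rng.random(n) < demo.medicare_frac, "medicare", "commercial"),
    })


def _uniform_dates(rng: np.random.Generator, start: pd.Timestamp,
                   end: pd.Timestamp, n: int) -> np.ndarray:
    days = (end - start).days + 1  # closed interval
    return (start.to_datetime64() +
            rng.integers(0, days, size=n).astype("timedelta64[D]"))


def generate_cohort_claims(cases: pd.DataFrame, controls: pd.DataFrame,
                           truth: SimulationTruth, seed: int = 0,
                           case_code: str = CASE_CONDITION_CODE,
                           control_code: str = CONTROL_CONDITION_CODE,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit claims and enrollment spells for designated case/control persons.

    Every person gets two encounter claims of their defining-condition code
    (one before the pre-cutoff, one in-window) plus at most one claim per code
    book entry, Bernoulli with the arm's planted probability (age-modulated
    when the entry has a confounder slope). Enrollment covers the reference
    date for everyone.
    """
    rng = _rng(seed)
    mean_age = truth.demographics.mean_age

    person_col: list[np.ndarray] = []
    date_col: list[np.ndarray] = []
    code_col: list[np.ndarray] = []

    def emit(ids: np.ndarray, dates: np.ndarray, code: str) -> None:
        person_col.append(ids)
        date_col.append(dates)
        code_col.append(np.repeat(code, len(ids)))

    pre_end = WINDOW_START - pd.Timedelta(days=1)
    for arm_df, code in ((cases, case_code), (controls, control_code)):
        ids = arm_df["person_id"].to_numpy()
        emit(ids, _uniform_dates(rng, PRE_WINDOW_START, pre_end, len(ids)), code)
        emit(ids, _uniform_dates(rng, WINDOW_START, WINDOW_END, len(ids)), code)

    for entry in truth.entries:
        for arm_df, p_arm in ((cases, entry.p1), (controls, entry.p0)):
            n = len(arm_df)
            if entry.confounder_slope != 0.0 and 0.0 < p_arm < 1.0:
                age = (REFERENCE_DATE.year - arm_df["birth_year"].to_numpy())
                p = expit(logit(p_arm) +
                          entry.confounder_slope * (age - mean_age) / 10.0)
            else:
                p = np.full(n, p_arm)
            hit = rng.random(n) < p
            ids = arm_df["person_id"].to_numpy()[hit]
            emit(ids, _uniform_dates(rng, WINDOW_START, WINDOW_END, len(ids)),
                 entry.icd9)

    claims = pd.DataFrame({
        "person_id": np.concatenate(person_col),
        "service_date": pd.to_datetime(np.concatenate(date_col)),
        "icd9": np.concatenate(code_col),
        "claim_kind": "encounter",
    })
    all_ids = np.concatenate([cases["person_id"].to_numpy(),
                              controls["person_id"].to_numpy()])
    enrollment = pd.DataFrame({
        "person_id": all_ids,
        "start": pd.Timestamp("2005-01-01"),
        "end": pd.Timestamp("2007-12-31"),
    })
    return claims, enrollment


def simulate_dataset(truth: SimulationTruth) -> dict[str, pd.DataFrame]:
    """Generate a full dataset from a planted scenario.

    Returns ``{"persons", "claims", "enrollment", "arms"}``; ``arms`` holds the
    designated (ground-truth) arm of each person, before any eligibility
    filtering downstream.
    """
    ss = np.random.SeedSequence(truth.seed)
    s_case, s_ctrl, s_claims = (int(s) for s in ss.generate_state(3) % (2**31))
    demo = truth.demographics
    cases = generate_population(truth.n_cases, demo, seed=s_case, id_prefix="RA",
                                mean_age=demo.mean_age + truth.case_age_shift)
    controls = generate_population(truth.n_controls, demo, seed=s_ctrl,
                                   id_prefix="CT")
    claims, enrollment = generate_cohort_claims(cases, controls, truth,
                                                seed=s_claims)
    persons = pd.concat([cases, controls], ignore_index=True)
    arms = pd.DataFrame({
        "person_id": persons["person_id"],
        "arm": np.repeat(["case", "control"], [len(cases), len(controls)]),
    })
    return {"persons": persons, "claims": claims, "enrollment": enrollment,
            "arms": arms}


# ---------------------------------------------------------------------------
# truth manifest serialization

def write_truth_manifest(truth: SimulationTruth, path: "str | Path") -> None:
    """Serialize a planted scenario to a YAML manifest (lossless round-trip)."""
    doc = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "seed": truth.seed,
        "n_cases": truth.n_cases,
        "n_controls": truth.n_controls,
        "case_age_shift": truth.case_age_shift,
        "demographics": dataclasses.asdict(truth.demographics),
        "entries": [dataclasses.asdict(e) for e in truth.entries],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truth_manifest(path: "str | Path") -> SimulationTruth:
    """Load a manifest written by :func:`write_truth_manifest`."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ManifestError(f"unreadable manifest {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ManifestError(f"manifest {path} is not a mapping")
    version = doc.get("schema_version")
    if version != MANIFEST_SCHEMA_VERSION:
        raise ManifestError(
            f"manifest schema version {version!r} != {MANIFEST_SCHEMA_VERSION}")
    for key in ("seed", "n_cases", "n_controls", "entries", "demographics"):
        if key not in doc:
            raise ManifestError(f"manifest {path} missing required key {key!r}")
    return SimulationTruth(
        entries=tuple(CodeBookEntry(**e) for e in doc["entries"]),
        n_cases=int(doc["n_cases"]),
        n_controls=int(doc["n_controls"]),
        seed=int(doc["seed"]),
        demographics=DemographicSpec(**doc["demographics"]),
        case_age_shift=float(doc.get("case_age_shift", 0.0)),
    )
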