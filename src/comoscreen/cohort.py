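"""Cohort eligibility rules and index dates.

A person enters an arm of the study when, for that arm's defining code
patterns, they have

(a) at least ``min_claims`` claims of an eligible kind (encounter claims, not
    lab/radiology service lines) matching the patterns,
(b) an enrollment spell covering the active-status reference date,
(c) at least one matching eligible claim strictly before the pre-cutoff date
    (establishing the condition existed before the observation window), and
(d) age at the index date of at least ``min_age`` years.

The **index date** is the earliest matching eligible claim. Ages are computed
at calendar-year resolution (age = year of date - birth year), the finest
resolution de-identified claims extracts support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .icd9 import Icd9Pattern

__all__ = ["CohortSpec", "age_at", "select_cohort", "demographic_summary"]

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["person_id", "arm", "index_date", "age_at_index", "sex", "plan"]


@dataclass(frozen=True)
class CohortSpec:
    """Eligibility rules for one arm (defaults mirror a 2006-07 / 2007-06 study)."""

    patterns: Sequence["Icd9Pattern | str"]
    min_claims: int = 2
    eligible_claim_kinds: frozenset = frozenset({"encounter"})
    active_on: pd.Timestamp = pd.Timestamp("2007-06-30")
    pre_cutoff: pd.Timestamp = pd.Timestamp("2006-07-01")
    min_age: int = 16

    def __post_init__(self) -> None:
        if self.min_claims < 1:
            raise DataError(f"min_claims must be >= 1, got {self.min_claims}")
        object.__setattr__(self, "active_on", pd.Timestamp(self.active_on))
        object.__setattr__(self, "pre_cutoff", pd.Timestamp(self.pre_cutoff))
        if self.pre_cutoff > self.active_on:
            raise DataError("pre_cutoff must be on or before active_on")
        pats = tuple(p if isinstance(p, Icd9Pattern) else Icd9Pattern(p)
                     for p in self.patterns)
        if not pats:
            raise DataError("CohortSpec needs at least one code pattern")
        object.__setattr__(self, "patterns", pats)
        object.__setattr__(self, "eligible_claim_kinds",
                           frozenset(self.eligible_claim_kinds))


def age_at(birth_year: int, on: pd.Timestamp) -> int:
    """Age in years at a date, at calendar-year resolution.

    Raises on a birth year after the target date's year (negative age).
    """
    age = pd.Timestamp(on).year - int(birth_year)
    if age < 0:
        raise DataError(f"negative age: birth_year {birth_year} is after {on}")
    return age


def _pattern_mask(codes: pd.Series, patterns: Sequence[Icd9Pattern]) -> pd.Series:
    mask = pd.Series(False, index=codes.index)
    for p in patterns:
        if p.wildcard:
            mask |= codes.str.startswith(p.prefix)
        else:
            mask |= codes.eq(p.prefix)
    return mask


def select_cohort(claims: pd.DataFrame, enrollment: pd.DataFrame,
                  persons: pd.DataFrame, spec: CohortSpec,
                  arm: str = "case") -> pd.DataFrame:
    """Apply the four eligibility rules; returns the cohort table.

    Output columns: person_id, arm, index_date, age_at_index, sex, plan.
    An empty cohort is a valid result (logged, not an error).
    """
    eligible = claims[claims["claim_kind"].isin(spec.eligible_claim_kinds)]
    eligible = eligible[_pattern_mask(eligible["icd9"], spec.patterns)]

    if eligible.empty:
        log.info("cohort arm=%s: no matching eligible claims", arm)
        return pd.DataFrame(columns=COHORT_COLUMNS)

    per_person = eligible.groupby("person_id").agg(
        n_matching=("service_date", "size"),
        index_date=("service_date", "min"))
    pre = (eligible[eligible["service_date"] < spec.pre_cutoff]
           .groupby("person_id").size())
    per_person["any_pre"] = per_person.index.isin(pre.index)

    active = enrollment[(enrollment["start"] <= spec.active_on) &
                        (spec.active_on <= enrollment["end"])]["person_id"].unique()

    cand = per_person[(per_person["n_matching"] >= spec.min_claims) &
                      per_person["any_pre"] &
                      per_person.index.isin(active)].reset_index()
    cand = cand.merge(persons[["person_id", "birth_year", "sex", "plan"]],
                      on="person_id", how="inner")
    cand["age_at_index"] = (cand["index_date"].dt.year
                            - cand["birth_year"].astype(int))
    if (cand["age_at_index"] < 0).any():
        bad = cand.loc[cand["age_at_index"] < 0, "person_id"].tolist()[:5]
        raise DataError(f"negative age at index for person(s) {bad}")
    out = cand[cand["age_at_index"] >= spec.min_age].copy()
    out["arm"] = arm
    out = out.loc[:, COHORT_COLUMNS].sort_values("person_id").reset_index(drop=True)
    log.info("cohort arm=%s: %d candidates with >=%d matching claims, "
             "%d selected", arm, len(per_person), spec.min_claims, len(out))
    return out


def demographic_summary(members: pd.DataFrame, bin_width: int = 5) -> dict:
    """Mean age, percent female, percent per plan, and an age/sex histogram.

    Histogram bins are ``bin_width``-year intervals [b, b + bin_width) keyed by
    their lower edge; ``histogram`` has one row per (bin, sex) cell present.
    """
    if members.empty:
        raise DataError("demographic summary of an empty cohort")
    ages = members["age_at_index"].astype(float)
    bins = (np.floor(ages / bin_width) * bin_width).astype(int)
    hist = (members.assign(age_bin=bins)
            .groupby(["age_bin", "sex"], observed=True).size()
            .rename("n").reset_index())
    n = len(members)
    plan_pct = (members["plan"].value_counts(normalize=True) * 100).to_dict()
    return {
        "n": n,
        "mean_age": float(ages.mean()),
        "pct_female": float((members["sex"] == "F").mean() * 100),
        "pct_plan": plan_pct,
        "histogram": hist,
    }
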