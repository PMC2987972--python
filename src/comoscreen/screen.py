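"""Per-code period prevalence, relative risks and rank-ordering.

For every distinct level-5 ICD-9 code recorded in either arm during the
observation window, the screen computes the one-year period prevalence in each
arm (each person counted once per code, however many claims repeat it), the
prevalence ratio

    RR = p_case / p_control = (n_case / N_case) / (n_control / N_control),

its 95% CI by the Katz log method

    exp( ln RR +/- z * sqrt(1/n_case - 1/N_case + 1/n_control - 1/N_control) ),

and the odds ratio with its Woolf (log) interval.  Index-condition-related
chapters (stems 710-729, 996.4x) are excluded, codes with fewer than
``min_control_count`` affected controls are dropped as unstable, and the
survivors are rank-ordered by descending RR (ties: larger n_case, then code).

No multiplicity adjustment is applied to the per-code intervals; the screen is
a hypothesis-generating rank-ordering, not a family of tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._codebook import CODE_DESCRIPTIONS
from .errors import DataError
from .icd9 import is_excluded_code

__all__ = ["ScreenConfig", "ComorbidityScreen", "ScreenResults",
           "period_prevalence", "relative_risk", "rr_confidence_interval",
           "odds_ratio", "apply_filters", "rank_order", "top_k_report",
           "round_half_up"]

log = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile, as conventionally tabulated

RANKED_COLUMNS = ["icd9", "description", "n_case", "pct_case", "rr",
                  "ci_low", "ci_high", "odds_ratio", "or_ci_low", "or_ci_high",
                  "n_control", "rank"]


@dataclass(frozen=True)
class ScreenConfig:
    """Observation window, stability filter and reporting options."""

    window_start: pd.Timestamp = pd.Timestamp("2006-07-01")
    window_end: pd.Timestamp = pd.Timestamp("2007-06-30")
    min_control_count: int = 20
    top_k: int = 30
    alpha: float = 0.05
    exclude: Callable[[str], bool] = is_excluded_code

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_start", pd.Timestamp(self.window_start))
        object.__setattr__(self, "window_end", pd.Timestamp(self.window_end))
        if self.window_start > self.window_end:
            raise DataError("window_start must be on or before window_end")
        if not 0 < self.alpha < 1:
            raise DataError(f"alpha must be in (0, 1), got {self.alpha}")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at a decimal place (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def period_prevalence(claims: pd.DataFrame, members: pd.DataFrame,
                      config: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Per-code one-year period prevalence in each arm.

    ``members`` needs columns ``person_id`` and ``arm``; every distinct code
    with at least one in-window claim in either arm yields a row with columns
    ``icd9, n_case, N_case, n_control, N_control, p_case, p_control``.
    All diagnosis-bearing claims count here, whatever their kind — the
    claim-kind restriction applies only to cohort-defining claims.
    """
    if members.empty:
        raise DataError("period prevalence over an empty cohort")
    arms = members[["person_id", "arm"]].drop_duplicates()
    N = arms["arm"].value_counts()
    N_case, N_control = int(N.get("case", 0)), int(N.get("control", 0))
    if N_case == 0 or N_control == 0:
        raise DataError("both arms must be non-empty for a two-arm screen")

    in_window = claims[(claims["service_date"] >= config.window_start) &
                       (claims["service_date"] <= config.window_end)]
    hits = (in_window[["person_id", "icd9"]].drop_duplicates()
            .merge(arms, on="person_id", how="inner"))
    counts = (hits.groupby(["icd9", "arm"], observed=True).size()
              .unstack(fill_value=0))
    for col in ("case", "control"):
        if col not in counts.columns:
            counts[col] = 0
    out = pd.DataFrame({
        "icd9": counts.index,
        "n_case": counts["case"].to_numpy(),
        "N_case": N_case,
        "n_control": counts["control"].to_numpy(),
        "N_control": N_control,
    }).reset_index(drop=True)
    out["p_case"] = out["n_case"] / N_case
    out["p_control"] = out["n_control"] / N_control
    return out


def relative_risk(df: pd.DataFrame) -> pd.Series:
    """Prevalence ratio p_case / p_control; NaN (flagged) where n_control = 0.

    Computed as the cross product ``(n_case * N_control) / (n_control * N_case)``
    so that with equal-size arms the denominators cancel exactly and the ratio
    is bit-identical to ``n_case / n_control``.
    """
    num = df["n_case"].to_numpy(float) * df["N_control"].to_numpy(float)
    den = df["n_control"].to_numpy(float) * df["N_case"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(df["n_control"] > 0, num / den, np.nan)
    return pd.Series(rr, index=df.index, name="rr")


def rr_confidence_interval(df: pd.DataFrame, alpha: float = 0.05
                           ) -> tuple[pd.Series, pd.Series]:
    """Katz log-method CI for the prevalence ratio; NaN where a cell is zero."""
    z = Z_95 if alpha == 0.05 else float(norm.ppf(1 - alpha / 2))
    n1, N1 = df["n_case"].to_numpy(float), df["N_case"].to_numpy(float)
    n0, N0 = df["n_control"].to_numpy(float), df["N_control"].to_numpy(float)
    ok = (n1 > 0) & (n0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rr = np.log((n1 / N1) / (n0 / N0))
        se = np.sqrt(1 / n1 - 1 / N1 + 1 / n0 - 1 / N0)
        low = np.where(ok, np.exp(log_rr - z * se), np.nan)
        high = np.where(ok, np.exp(log_rr + z * se), np.nan)
    return (pd.Series(low, index=df.index, name="ci_low"),
            pd.Series(high, index=df.index, name="ci_high"))


def odds_ratio(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Odds ratio with Woolf log CI; NaN where any 2x2 cell is zero.

    No continuity correction is applied: zero-cell rows are flagged rather
    than patched.
    """
    z = Z_95 if alpha == 0.05 else float(norm.ppf(1 - alpha / 2))
    a = df["n_case"].to_numpy(float)
    b = df["N_case"].to_numpy(float) - a
    c = df["n_control"].to_numpy(float)
    d = df["N_control"].to_numpy(float) - c
    ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        or_ = np.where(ok, (a * d) / (c * b), np.nan)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        low = np.where(ok, np.exp(np.log(or_) - z * se), np.nan)
        high = np.where(ok, np.exp(np.log(or_) + z * se), np.nan)
    return pd.DataFrame({"odds_ratio": or_, "or_ci_low": low, "or_ci_high": high},
                        index=df.index)


def apply_filters(df: pd.DataFrame, config: ScreenConfig = ScreenConfig()
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop excluded-chapter codes and codes rare in the control group.

    Returns the surviving rows and a drop log keyed by reason. The two
    filters commute: the surviving set does not depend on their order.
    """
    excluded = df["icd9"].map(config.exclude).astype(bool)
    rare = df["n_control"] < config.min_control_count
    kept = df[~excluded & ~rare].reset_index(drop=True)
    dropped = {"excluded_code": int(excluded.sum()),
               "rare_in_controls": int((rare & ~excluded).sum())}
    log.info("screen filters: %d excluded-chapter, %d rare (<%d controls), "
             "%d of %d rows kept", dropped["excluded_code"],
             dropped["rare_in_controls"], config.min_control_count,
             len(kept), len(df))
    return kept, dropped


def rank_order(df: pd.DataFrame) -> pd.DataFrame:
    """Sort descending by RR (ties: larger n_case, then code); add 1-based rank."""
    out = df.sort_values(["rr", "n_case", "icd9"],
                         ascending=[False, False, True],
                         kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _fmt1(x: float) -> str:
    return f"{round_half_up(x, 1):.1f}"


def top_k_report(ranked: pd.DataFrame, k: int = 30,
                 descriptions: "Mapping[str, str] | None" = None) -> pd.DataFrame:
    """Top-*k* rows formatted for display: percent and RR to 1 decimal,
    CI as ``"low-high"``. Asking for more rows than exist returns them all."""
    if k > len(ranked):
        log.info("top-k report: only %d row(s) available (k=%d)", len(ranked), k)
    rows = ranked.head(max(k, 0))
    desc = descriptions or CODE_DESCRIPTIONS
    out = pd.DataFrame({
        "rank": rows.get("rank", pd.Series(dtype=int)),
        "icd9": rows["icd9"] if len(rows) else pd.Series(dtype=str),
        "description": [
            (rows["description"].iloc[i] if "description" in rows and
             isinstance(rows["description"].iloc[i], str) and
             rows["description"].iloc[i]
             else desc.get(rows["icd9"].iloc[i], ""))
            for i in range(len(rows))],
        "n_case": rows.get("n_case", pd.Series(dtype=int)),
        "pct": [f"{_fmt1(100 * p)}%" for p in rows.get("p_case", [])],
        "rr": [_fmt1(r) for r in rows.get("rr", [])],
        "ci_95": [f"{_fmt1(lo)}-{_fmt1(hi)}"
                  for lo, hi in zip(rows.get("ci_low", []), rows.get("ci_high", []))],
    })
    return out.reset_index(drop=True)


class ComorbidityScreen:
    """Model object: a two-arm cohort plus claims, screened code by code.

    Parameters
    ----------
    claims : DataFrame
        Validated claims table (all claim kinds; the window filter is applied
        here).
    members : DataFrame
        Cohort membership with ``person_id`` and ``arm`` (``case``/``control``)
        — typically the matched arms, so the two denominators are equal.
    config : ScreenConfig, optional
    descriptions : mapping, optional
        icd9 -> human-readable label; defaults to the embedded subset.
    """

    def __init__(self, claims: pd.DataFrame, members: pd.DataFrame,
                 config: "ScreenConfig | None" = None,
                 descriptions: "Mapping[str, str] | None" = None):
        self.claims = claims
        self.members = members
        self.config = config or ScreenConfig()
        self.descriptions = dict(descriptions or CODE_DESCRIPTIONS)

    def fit(self) -> "ScreenResults":
        cfg = self.config
        prev = period_prevalence(self.claims, self.members, cfg)
        prev["rr"] = relative_risk(prev)
        prev["ci_low"], prev["ci_high"] = rr_confidence_interval(prev, cfg.alpha)
        ors = odds_ratio(prev, cfg.alpha)
        prev = pd.concat([prev, ors], axis=1)
        prev["description"] = prev["icd9"].map(self.descriptions).fillna("")
        kept, dropped = apply_filters(prev, cfg)
        ranked = rank_order(kept)
        return ScreenResults(prevalence=prev, table=ranked, dropped=dropped,
                             config=cfg, descriptions=self.descriptions)


class ScreenResults:
    """Fitted screen: the ranked table, the unfiltered prevalences, drop log."""

    def __init__(self, prevalence: pd.DataFrame, table: pd.DataFrame,
                 dropped: dict, config: ScreenConfig, descriptions: dict):
        self.prevalence = prevalence
        self.table = table
        self.dropped = dropped
        self.config = config
        self.descriptions = descriptions

    @property
    def n_codes_recorded(self) -> int:
        """Distinct codes seen in either arm inside the window."""
        return len(self.prevalence)

    @property
    def n_codes_ranked(self) -> int:
        """Codes surviving the exclusion and stability filters."""
        return len(self.table)

    def top(self, k: "int | None" = None) -> pd.DataFrame:
        return top_k_report(self.table, k if k is not None else self.config.top_k,
                            self.descriptions)

    def summary(self) -> str:
        top = self.top()
        lines = [
            "Comorbidity screen "
            f"({self.config.window_start.date()} .. {self.config.window_end.date()})",
            f"  arms: {int(self.prevalence['N_case'].iloc[0]) if len(self.prevalence) else 0} cases / "
            f"{int(self.prevalence['N_control'].iloc[0]) if len(self.prevalence) else 0} controls",
            f"  codes recorded: {self.n_codes_recorded}   ranked: {self.n_codes_ranked}   "
            f"dropped: {self.dropped}",
            "",
            top.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_csv(self, path: "str | Path") -> None:
        """Full ranked table (one row per surviving code) as CSV."""
        out = self.table.copy()
        out["pct_case"] = [round_half_up(100 * p, 1) for p in out["p_case"]]
        out.loc[:, RANKED_COLUMNS].to_csv(path, index=False, float_format="%.10g")
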