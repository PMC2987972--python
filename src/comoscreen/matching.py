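"""Propensity model and greedy digit-truncation matching.

The propensity score is the modeled probability of case-arm membership given
age (years, linear), sex and plan, from a logistic regression fitted by
maximum likelihood (Newton/IRLS).  Each case is then paired with one control
whose score agrees on the first *d* decimal digits, with *d* relaxed from 8
down to 0 — the classic greedy "digit match" of the SAS propensity-matching
macro family.  Each control is used at most once; the final 0-digit pass pairs
every leftover case with an arbitrary remaining control, so with equally sized
pools no case stays unmatched.

Digit agreement is evaluated by *truncation* of the decimal expansion, not
rounding, on a fixed 12-decimal rendering of the score (exact for every
d <= 8; floating-point integer tricks like ``floor(x * 10**d)`` are not).
"""

from __future__ import annotations

import logging
from collections import defaultdict, deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, RankDeficiencyError, SeparationError

__all__ = ["PropensityModel", "PropensityResults", "MatchResult",
           "greedy_digit_match", "balance_report"]

log = logging.getLogger(__name__)

COVARIATES = ["age_at_index", "sex_f", "plan_medicare"]


def _design(members: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({
        "intercept": 1.0,
        "age_at_index": members["age_at_index"].astype(float),
        "sex_f": (members["sex"] == "F").astype(float),
        "plan_medicare": (members["plan"] == "medicare").astype(float),
    }, index=members.index)
    return X


class PropensityModel:
    """Logistic model of P(case | age, sex, plan) over a two-arm cohort.

    Parameters
    ----------
    members : DataFrame
        Cohort table with columns ``person_id, arm, age_at_index, sex, plan``;
        ``arm`` must contain both ``"case"`` and ``"control"``.
    """

    def __init__(self, members: pd.DataFrame):
        arms = set(members["arm"].unique())
        if not {"case", "control"} <= arms:
            raise DataError(f"both arms required to fit a propensity model, got {arms}")
        self.members = members.reset_index(drop=True)
        self.endog = (self.members["arm"] == "case").astype(float).to_numpy()
        exog = _design(self.members)
        # constant covariates carry no information; drop them (an intercept-only
        # model is legitimate and scores everyone at the case proportion)
        constant = [c for c in COVARIATES if exog[c].nunique() <= 1]
        if constant:
            log.warning("dropping constant covariate(s): %s", constant)
        self.covariates = [c for c in COVARIATES if c not in constant]
        self.exog = exog[["intercept"] + self.covariates]
        self._check_identifiable()

    def _check_identifiable(self) -> None:
        X = self.exog.to_numpy()
        y = self.endog
        for c in self.covariates:
            x = self.exog[c].to_numpy()
            if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
                raise SeparationError(
                    f"covariate {c!r} completely separates cases from controls")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficiencyError("design matrix is rank deficient "
                                      "(collinear covariates)")

    def fit(self, tol: float = 1e-10, maxiter: int = 100) -> "PropensityResults":
        """Maximum-likelihood fit by Newton iterations (IRLS)."""
        model = sm.Logit(self.endog, self.exog)
        res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=False)
        grad_norm = float(np.abs(model.score(res.params.to_numpy())).max())
        return PropensityResults(self, res,
                                 iterations=int(res.mle_retvals.get("iterations", -1)),
                                 gradient_norm=grad_norm)


class PropensityResults:
    """Fitted propensity model: coefficients, SEs, score function, summary."""

    def __init__(self, model: PropensityModel, smres, iterations: int,
                 gradient_norm: float):
        self.model = model
        self._smres = smres
        self.params: pd.Series = smres.params
        self.bse: pd.Series = smres.bse
        self.iterations = iterations
        self.gradient_norm = gradient_norm
        self.converged = bool(smres.mle_retvals.get("converged", False))
        self.llf = float(smres.llf)

    def score(self, members: pd.DataFrame) -> pd.Series:
        """Propensity scores in (0, 1), indexed by person_id."""
        p = self._smres.predict(_design(members)[list(self.model.exog.columns)])
        return pd.Series(np.asarray(p), index=members["person_id"].to_numpy(),
                         name="propensity")

    def summary(self) -> str:
        lines = ["Propensity model: logit P(case) ~ age + sex + plan",
                 f"  n={len(self.model.members)}  log-likelihood={self.llf:.3f}  "
                 f"iterations={self.iterations}  converged={self.converged}",
                 f"  {'term':<14}{'coef':>12}{'std err':>12}"]
        for name in self.params.index:
            lines.append(f"  {name:<14}{self.params[name]:>12.6f}{self.bse[name]:>12.6f}")
        return "\n".join(lines)


@dataclass
class MatchResult:
    """1:1 pairing of cases to controls.

    ``pairs`` columns: case_id, control_id, case_score, control_score,
    digits_used (the truncation level at which the pair agreed, 8..0).
    """

    pairs: pd.DataFrame
    unmatched_cases: list

    def __len__(self) -> int:
        return len(self.pairs)


def _truncate_key(score: float, digits: int) -> str:
    # fixed 12-decimal rendering; first `digits` decimals, truncated not rounded
    return f"{score:.12f}"[:2 + digits]


def greedy_digit_match(case_scores: pd.Series, control_scores: pd.Series,
                       max_digits: int = 8, seed: int = 0) -> MatchResult:
    """Greedy 1:1 digit-truncation matching on propensity scores.

    For ``d = max_digits .. 0``, unmatched cases (in seeded-random order) are
    paired with an unmatched control whose score agrees on the first *d*
    decimal digits; each control is used at most once.  Scores must lie in
    (0, 1), so the d=0 pass pairs all leftovers while controls remain; cases
    are left unmatched only when controls run out (logged).
    """
    for name, s in (("case", case_scores), ("control", control_scores)):
        arr = np.asarray(s, dtype=float)
        if len(arr) and not ((arr > 0) & (arr < 1)).all():
            raise DataError(f"{name} scores must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)

    unmatched = list(case_scores.index)
    control_ids = list(control_scores.index)
    records = []
    for d in range(max_digits, -1, -1):
        if not unmatched or len(records) == len(control_ids):
            break
        pools: dict[str, deque] = defaultdict(deque)
        used = {r[1] for r in records}
        remaining_controls = [c for c in control_ids if c not in used]
        order = rng.permutation(len(remaining_controls))
        for i in order:
            cid = remaining_controls[i]
            pools[_truncate_key(float(control_scores[cid]), d)].append(cid)
        order = rng.permutation(len(unmatched))
        still = []
        for i in order:
            case_id = unmatched[i]
            key = _truncate_key(float(case_scores[case_id]), d)
            pool = pools.get(key)
            if pool:
                control_id = pool.popleft()
                records.append((case_id, control_id, d))
            else:
                still.append(case_id)
        unmatched = still
    if unmatched:
        log.warning("digit match: %d case(s) left unmatched (control pool "
                    "exhausted)", len(unmatched))
    pairs = pd.DataFrame(records, columns=["case_id", "control_id", "digits_used"])
    pairs["case_score"] = pairs["case_id"].map(case_scores).astype(float)
    pairs["control_score"] = pairs["control_id"].map(control_scores).astype(float)
    pairs = pairs[["case_id", "control_id", "case_score", "control_score",
                   "digits_used"]]
    return MatchResult(pairs=pairs, unmatched_cases=sorted(map(str, unmatched)))


def balance_report(members: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Standardized mean differences per covariate, before and after matching.

    SMD = (mean_case - mean_control) / pooled SD with the pooled SD taken from
    the *pre-match* arms (so before/after are on one scale). A zero pooled SD
    yields SMD 0 when the means agree and +/-inf otherwise (flagged).
    """
    if pairs.empty:
        raise DataError("balance report requires at least one matched pair")
    X = _design(members)[COVARIATES]
    is_case = members["arm"] == "case"
    ids = members["person_id"]
    matched_ids = set(pairs["case_id"]) | set(pairs["control_id"])

    def smd(case_mask, control_mask, col, sd):
        diff = X.loc[case_mask, col].mean() - X.loc[control_mask, col].mean()
        if sd == 0:
            return 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
        return float(diff / sd)

    rows = {}
    post_case = is_case & ids.isin(matched_ids)
    post_control = ~is_case & ids.isin(matched_ids)
    for col in COVARIATES:
        sd = float(np.sqrt((X.loc[is_case, col].var(ddof=1) +
                            X.loc[~is_case, col].var(ddof=1)) / 2.0))
        rows[col] = {"smd_before": smd(is_case, ~is_case, col, sd),
                     "smd_after": smd(post_case, post_control, col, sd)}
    return pd.DataFrame.from_dict(rows, orient="index")
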