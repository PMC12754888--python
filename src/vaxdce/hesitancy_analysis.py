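"""Opt-out based hesitancy analysis.

A respondent is scored by the number of tasks answered with the opt-out; a
threshold (default 3 of 6) defines the hesitant flag.  Predictors are
examined with 2x2 contingency odds ratios (Woolf intervals) and a
from-scratch multivariate logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .choice_simulation import ChoiceDataset

__all__ = [
    "TwoByTwo",
    "LogisticFit",
    "score_optout",
    "optout_task_proportion",
    "cumulative_optout_curve",
    "two_by_two_or",
    "fit_logistic",
    "univariate_or_table",
]

DEFAULT_PREDICTORS = (
    "age",
    "male",
    "married",
    "city",
    "healthcare_worker",
    "ses_upper",
    "ses_middle",
    "prior_covid",
    "diabetes",
    "hypertension",
    "heart",
    "asthma",
    "family_covid",
)


def score_optout(
    data: ChoiceDataset, threshold: int = 3, n_tasks: int = 6
) -> pd.DataFrame:
    """Per-respondent opt-out counts and the hesitant flag (count >= threshold).

    Every respondent must have exactly ``n_tasks`` recorded tasks (the trap is
    counted by default).
    """
    chosen = data.choices[data.choices["chosen"] == 1]
    per_resp = chosen.groupby("respondent_id").agg(
        n_tasks_seen=("task_id", "size"),
        optout_count=("alternative", lambda s: int((s == "optout").sum())),
    )
    wrong = per_resp[per_resp["n_tasks_seen"] != n_tasks]
    if len(wrong):
        raise ValueError(
            f"{len(wrong)} respondent(s) have a task count != {n_tasks}"
        )
    out = per_resp.reset_index()[["respondent_id", "optout_count"]]
    out["hesitant"] = (out["optout_count"] >= threshold).astype(int)
    return out


def optout_task_proportion(data: ChoiceDataset) -> float:
    """Percent of all recorded tasks answered with the opt-out."""
    chosen = data.choices[data.choices["chosen"] == 1]
    if chosen.empty:
        raise ValueError("empty dataset")
    return 100.0 * float((chosen["alternative"] == "optout").mean())


def cumulative_optout_curve(scores: pd.DataFrame, n_tasks: int = 6) -> pd.DataFrame:
    """Percent of respondents with opt-out count >= k, for k = 1..n_tasks."""
    if scores.empty:
        raise ValueError("no scores supplied")
    counts = scores["optout_count"].to_numpy()
    ks = np.arange(1, n_tasks + 1)
    pct = [100.0 * float((counts >= k).mean()) for k in ks]
    return pd.DataFrame({"k": ks, "percent_at_least_k": pct})


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome contingency counts: a = exposed cases,
    b = exposed controls, c = unexposed cases, d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def two_by_two_or(
    t: TwoByTwo, z: float = 1.96, continuity: bool = False
) -> tuple[float, float, float]:
    """Cross-product odds ratio with the Woolf log-scale interval."""
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ZeroDivisionError(
                "zero cell; pass continuity=True for the 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    half = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-half), or_ * math.exp(half)


@dataclass
class LogisticFit:
    """Fitted logistic regression with Wald adjusted-OR intervals."""

    columns: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.columns, name="coef")

    def aor_table(self, z: float = 1.96) -> pd.DataFrame:
        se = self.se
        zval = np.divide(self.beta, se, out=np.zeros_like(self.beta), where=se > 0)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": se,
                "aor": np.exp(self.beta),
                "ci_low": np.exp(self.beta - z * se),
                "ci_high": np.exp(self.beta + z * se),
                "p_value": 2.0 * stats.norm.sf(np.abs(zval)),
            },
            index=self.columns,
        )


def fit_logistic(
    covariates: pd.DataFrame,
    outcome: Sequence[int],
    predictors: Sequence[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Newton-Raphson logistic MLE from zero with step-halving.

    ``predictors`` selects covariate columns (all numeric); convergence is a
    gradient max-norm below ``tol``.  Raises when a predictor is constant or
    the fit diverges (perfect separation), naming the offending column.
    """
    if predictors is None:
        predictors = [c for c in covariates.columns]
    X = covariates[list(predictors)].to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("outcome length must match covariate rows")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    const = [p for p, col in zip(predictors, X.T) if np.ptp(col) == 0]
    if const:
        raise ValueError(f"constant predictor(s): {const}")
    cols = list(predictors)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        cols = ["intercept"] + cols
    scale = np.abs(X).max(axis=0)

    def loglik(b: np.ndarray):
        eta = X @ b
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        hess = -(X.T * w) @ X
        return ll, grad, hess

    beta = np.zeros(X.shape[1])
    ll, grad, hess = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix") from exc
        slack = 1e-10 * (1.0 + abs(ll))
        new_beta, new = beta + step, None
        for _ in range(50):
            cand = loglik(new_beta)
            if np.isfinite(cand[0]) and cand[0] >= ll - slack:
                new = cand
                break
            new_beta = beta + (new_beta - beta) / 2.0
        if new is None:
            break
        beta, (ll, grad, hess) = new_beta, new
        drift = np.abs(beta) * scale
        if drift.max() > 15.0:
            worst = cols[int(np.argmax(drift))]
            raise ValueError(f"perfect separation suspected on predictor {worst!r}")
    if not converged and np.abs(grad).max() < tol:
        converged = True
    vcov = np.linalg.inv(-hess)
    return LogisticFit(
        columns=cols, beta=beta, vcov=vcov, loglik=ll,
        converged=converged, n_iterations=it,
    )


def univariate_or_table(
    covariates: pd.DataFrame,
    outcome: Sequence[int],
    predictors: Sequence[str],
    z: float = 1.96,
    continuity: bool = False,
) -> pd.DataFrame:
    """Contingency-table ORs (binary predictors) against the hesitant flag."""
    y = np.asarray(outcome, dtype=int)
    rows = []
    for p in predictors:
        x = covariates[p].to_numpy()
        if set(np.unique(x)) - {0, 1}:
            raise ValueError(f"predictor {p!r} is not binary")
        t = TwoByTwo(
            a=int(((x == 1) & (y == 1)).sum()),
            b=int(((x == 1) & (y == 0)).sum()),
            c=int(((x == 0) & (y == 1)).sum()),
            d=int(((x == 0) & (y == 0)).sum()),
        )
        or_, lo, hi = two_by_two_or(t, z=z, continuity=continuity)
        rows.append({"predictor": p, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "or": or_, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows).set_index("predictor")
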