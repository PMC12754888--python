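"""Conditional-logit maximum likelihood on long-format choice data.

The likelihood is the McFadden choice model: within each respondent-task
group, P(alternative j) = exp(x_j' beta) / sum_k exp(x_k' beta).  Estimation
is Newton-Raphson with analytic gradient/Hessian and step-halving; standard
errors come from the inverse observed information (an optional
cluster-robust sandwich by respondent is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .choice_simulation import ChoiceDataset
from .design_space import CATEGORICAL, AttributeSpec

__all__ = [
    "CodedDesignMatrix",
    "ClogitFit",
    "code_dataset",
    "clogit_loglik",
    "fit_clogit",
    "odds_ratios",
]

OPTOUT_ASC_COLUMN = "optout_asc"


@dataclass
class CodedDesignMatrix:
    """Row-grouped design matrix for conditional logit.

    Rows are sorted by group; ``group_ids`` is a dense 0..G-1 index and
    ``group_starts`` the first-row offsets.  Exactly one chosen row per group.
    """

    X: np.ndarray
    y: np.ndarray
    group_ids: np.ndarray
    columns: list[str]
    respondent_ids: np.ndarray | None = None
    group_starts: np.ndarray = field(init=False)
    n_groups: int = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.group_ids = np.asarray(self.group_ids, dtype=int)
        if not (np.diff(self.group_ids) >= 0).all():
            raise ValueError("rows must be sorted by group")
        is_start = np.ones(len(self.group_ids), dtype=bool)
        is_start[1:] = np.diff(self.group_ids) > 0
        self.group_starts = np.flatnonzero(is_start)
        self.n_groups = len(self.group_starts)
        sizes = np.diff(np.append(self.group_starts, len(self.group_ids)))
        if (sizes < 2).any():
            raise ValueError("every group needs at least two alternatives")
        chosen_per_group = np.add.reduceat(self.y, self.group_starts)
        if (chosen_per_group != 1).any():
            raise ValueError("every group must have exactly one chosen row")
        if self.X.shape != (len(self.y), len(self.columns)):
            raise ValueError("X shape inconsistent with y/columns")


@dataclass
class ClogitFit:
    """Fitted conditional logit: point estimates, covariance and diagnostics."""

    columns: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    loglik_null: float
    n_groups: int
    converged: bool
    n_iterations: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.columns, name="coef")

    def summary_frame(self, z: float = 1.96) -> pd.DataFrame:
        se = self.se
        zval = np.divide(self.beta, se, out=np.zeros_like(self.beta), where=se > 0)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": se,
                "or": np.exp(self.beta),
                "or_ci_low": np.exp(self.beta - z * se),
                "or_ci_high": np.exp(self.beta + z * se),
                "p_value": 2.0 * stats.norm.sf(np.abs(zval)),
            },
            index=self.columns,
        )


def code_dataset(
    data: ChoiceDataset,
    attrs: Sequence[AttributeSpec],
    include_optout_asc: bool = True,
    *,
    drop_optout: bool = False,
    include_trap: bool = False,
) -> CodedDesignMatrix:
    """Dummy-code a long-format dataset against the attribute grid.

    Categorical levels are coded against each attribute's reference level,
    continuous attributes use their numeric values, and opt-out rows carry
    all-zero attribute columns plus (by default) an alternative-specific
    constant.  ``drop_optout`` removes opt-out rows and any group whose chosen
    row was the opt-out; trap tasks are excluded unless ``include_trap``.
    """
    ch = data.choices
    if not include_trap and "is_trap" in ch:
        ch = ch[ch["is_trap"] == 0]
    is_opt = ch["alternative"] == "optout"
    if drop_optout:
        opt_chosen_groups = ch.loc[is_opt & (ch["chosen"] == 1), ["respondent_id", "task_id"]]
        bad = set(map(tuple, opt_chosen_groups.to_numpy()))
        keys = list(zip(ch["respondent_id"], ch["task_id"]))
        keep = np.array([k not in bad for k in keys]) & ~is_opt.to_numpy()
        ch = ch[keep]
        is_opt = ch["alternative"] == "optout"

    alt_rank = ch["alternative"].map({"A": 0, "B": 1, "optout": 2})
    ch = ch.assign(_alt_rank=alt_rank).sort_values(
        ["respondent_id", "task_id", "_alt_rank"], kind="stable"
    )
    is_opt = (ch["alternative"] == "optout").to_numpy()

    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for a in attrs:
        labels = ch[a.name].astype(object).to_numpy()
        known = set(a.levels)
        bad_labels = {l for l, o in zip(labels, is_opt) if not o and l not in known}
        if bad_labels:
            raise ValueError(f"unknown level(s) {sorted(map(str, bad_labels))} for attribute {a.name!r}")
        if a.coding == CATEGORICAL:
            for lvl in a.levels:
                if lvl == a.reference_level:
                    continue
                cols.append(f"{a.name}:{lvl}")
                blocks.append((labels == lvl).astype(float))
        else:
            cols.append(a.name)
            vals = np.array([0.0 if o else a.numeric_values[l] for l, o in zip(labels, is_opt)])
            blocks.append(vals)
    if include_optout_asc and not drop_optout:
        cols.append(OPTOUT_ASC_COLUMN)
        blocks.append(is_opt.astype(float))

    X = np.column_stack(blocks)
    resp = ch["respondent_id"].to_numpy()
    task = ch["task_id"].to_numpy()
    new_group = np.ones(len(ch), dtype=bool)
    new_group[1:] = (resp[1:] != resp[:-1]) | (task[1:] != task[:-1])
    group_ids = np.cumsum(new_group) - 1
    return CodedDesignMatrix(
        X=X,
        y=ch["chosen"].to_numpy(),
        group_ids=group_ids,
        columns=cols,
        respondent_ids=resp,
    )


def clogit_loglik(
    beta: Sequence[float], xm: CodedDesignMatrix
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood, analytic gradient and Hessian at ``beta``.

    Log-sum-exp stabilised; the Hessian is the negative Fisher information of
    the grouped multinomial choice probabilities.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(xm.columns),):
        raise ValueError(f"beta has length {beta.size}, expected {len(xm.columns)}")
    X, y, starts, gid = xm.X, xm.y, xm.group_starts, xm.group_ids
    eta = X @ beta
    gmax = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - gmax[gid])
    denom = np.add.reduceat(z, starts)
    p = z / denom[gid]
    ll = float(eta @ y - (np.log(denom) + gmax).sum())
    grad = X.T @ (y - p)
    pX = X * p[:, None]
    S = np.add.reduceat(pX, starts, axis=0)
    hess = -(X.T @ pX - S.T @ S)
    return ll, grad, hess


def _check_contrast(xm: CodedDesignMatrix) -> None:
    firsts = xm.X[xm.group_starts][xm.group_ids]
    varies = (xm.X != firsts).any(axis=0)
    dead = [c for c, v in zip(xm.columns, varies) if not v]
    if dead:
        raise ValueError(
            f"column(s) {dead} are constant within every group and cannot be identified"
        )


def fit_clogit(
    xm: CodedDesignMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
    *,
    cluster: bool = False,
) -> ClogitFit:
    """Newton-Raphson MLE from beta = 0 with step-halving.

    Converged when the gradient max-norm falls below ``tol``.  ``cluster=True``
    replaces the classical covariance with a respondent-clustered sandwich.
    Raises on non-identified columns, apparent separation, or a singular
    Hessian.
    """
    _check_contrast(xm)
    k = len(xm.columns)
    beta = np.zeros(k)
    scale = np.abs(xm.X).max(axis=0)
    scale[scale == 0] = 1.0
    ll, grad, hess = clogit_loglik(beta, xm)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular Hessian; model not identified") from exc
        # acceptance slack scales with |LL|: late steps improve by less than
        # the evaluation's floating-point noise
        slack = 1e-10 * (1.0 + abs(ll))
        new_beta, new = beta + step, None
        for _ in range(50):
            cand = clogit_loglik(new_beta, xm)
            if np.isfinite(cand[0]) and cand[0] >= ll - slack:
                new = cand
                break
            new_beta = beta + (new_beta - beta) / 2.0
        if new is None:
            break
        beta, (ll, grad, hess) = new_beta, new
        drift = np.abs(beta) * scale
        if not np.isfinite(ll) or drift.max() > 15.0:
            worst = xm.columns[int(np.argmax(drift))]
            raise ValueError(
                f"estimates diverging (suspected perfect separation) on column {worst!r}"
            )
    else:
        it = max_iter
    if not converged and np.abs(grad).max() < tol:
        converged = True

    try:
        vcov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Hessian at the optimum") from exc

    if cluster:
        if xm.respondent_ids is None:
            raise ValueError("clustered errors need respondent ids")
        X, y = xm.X, xm.y
        eta = X @ beta
        gmax = np.maximum.reduceat(eta, xm.group_starts)
        z = np.exp(eta - gmax[xm.group_ids])
        denom = np.add.reduceat(z, xm.group_starts)
        p = z / denom[xm.group_ids]
        scores = X * (y - p)[:, None]
        frame = pd.DataFrame(scores)
        frame["_c"] = xm.respondent_ids
        G = frame.groupby("_c").sum().to_numpy()
        meat = G.T @ G
        vcov = vcov @ meat @ vcov

    return ClogitFit(
        columns=list(xm.columns),
        beta=beta,
        vcov=vcov,
        loglik=ll,
        loglik_null=ll_null,
        n_groups=xm.n_groups,
        converged=converged,
        n_iterations=it,
    )


def odds_ratios(fit: ClogitFit, z: float = 1.96) -> pd.DataFrame:
    """OR = exp(beta) with Wald interval exp(beta +/- z se)."""
    se = fit.se
    return pd.DataFrame(
        {
            "or": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z * se),
            "ci_high": np.exp(fit.beta + z * se),
        },
        index=fit.columns,
    )
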