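"""Synthetic respondent and choice generation.

Respondents carry demographic covariates drawn at configurable marginal
prevalences, a latent hesitancy propensity tied to those covariates through a
logistic model, and an attentiveness flag.  Attentive respondents choose among
{A, B, opt-out} by conditional logit with configurable true part-worths;
inattentive respondents answer uniformly at random (and therefore fail the
dominant-pair trap task two times in three).  The trap filter partitions a
simulated dataset by trap performance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from . import defaults
from .design_space import (
    AttributeSpec,
    ChoiceTask,
    Design,
    code_profile,
    coded_columns,
    is_dominant_pair,
)

__all__ = [
    "SimulationConfig",
    "ChoiceDataset",
    "generate_population",
    "simulate_choices",
    "apply_trap_filter",
    "calibrate_optout_asc",
]

BINARY_COVARIATES = (
    "male",
    "married",
    "city",
    "healthcare_worker",
    "prior_covid",
    "family_covid",
    "diabetes",
    "hypertension",
    "heart",
    "asthma",
)


@dataclass
class SimulationConfig:
    """Knobs for the synthetic data generator; defaults mirror the study."""

    n_respondents: int = 10_000
    true_beta: dict[str, float] = field(
        default_factory=lambda: dict(defaults.STUDY_PART_WORTHS)
    )
    optout_asc: float = defaults.DEFAULT_OPTOUT_ASC
    hesitant_optout_shift: float = defaults.DEFAULT_HESITANT_OPTOUT_SHIFT
    p_inattentive: float = defaults.DEFAULT_P_INATTENTIVE
    hesitant_fraction_target: float = defaults.STUDY_HESITANT_FRACTION
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(defaults.STUDY_PREVALENCES)
    )
    hesitancy_log_odds: dict[str, float] = field(
        default_factory=lambda: dict(defaults.STUDY_HESITANCY_LOG_ODDS)
    )
    age_mean: float = defaults.STUDY_AGE_MEAN
    age_sd: float = defaults.STUDY_AGE_SD
    deterministic_trap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be >= 0")
        if not 0.0 <= self.p_inattentive <= 1.0:
            raise ValueError("p_inattentive must lie in [0, 1]")
        if not 0.0 < self.hesitant_fraction_target < 1.0:
            raise ValueError("hesitant_fraction_target must lie in (0, 1)")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent named substream of the master seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class ChoiceDataset:
    """Long-format choices (one row per respondent-task-alternative) plus a
    respondent-level covariate table keyed by ``respondent_id``."""

    choices: pd.DataFrame
    respondents: pd.DataFrame

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    def validate(self) -> None:
        per_task = self.choices.groupby(["respondent_id", "task_id"])["chosen"].sum()
        if not (per_task == 1).all():
            raise ValueError("every respondent-task must have exactly one chosen row")

    def to_csv(self, choices_path, respondents_path) -> None:
        self.choices.to_csv(choices_path, index=False, lineterminator="\n")
        self.respondents.to_csv(respondents_path, index=False, lineterminator="\n")

    @classmethod
    def read_csv(cls, choices_path, respondents_path) -> "ChoiceDataset":
        choices = pd.read_csv(choices_path, keep_default_na=False, na_values=[])
        resp = pd.read_csv(respondents_path)
        for col in ("chosen", "is_trap", "is_dominant"):
            if col in choices:
                choices[col] = choices[col].astype(int)
        return cls(choices=choices, respondents=resp)

    def subset(self, respondent_ids) -> "ChoiceDataset":
        ids = set(respondent_ids)
        return ChoiceDataset(
            choices=self.choices[self.choices["respondent_id"].isin(ids)].reset_index(drop=True),
            respondents=self.respondents[self.respondents["respondent_id"].isin(ids)].reset_index(drop=True),
        )


def _hesitancy_intercept(linpred: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + linpred)) == target."""
    f = lambda c: expit(c + linpred).mean() - target
    return brentq(f, -40.0, 40.0, xtol=1e-12)


def generate_population(config: SimulationConfig, n_blocks: int = defaults.STUDY_N_BLOCKS) -> pd.DataFrame:
    """Draw a respondent table with independent covariates at the configured
    prevalences, a covariate-linked hesitancy propensity whose mean equals the
    configured hesitant-fraction target, an attentiveness flag, and a uniform
    random block assignment."""
    n = config.n_respondents
    rng = config.rng(0)
    prev = config.covariate_prevalences
    df = pd.DataFrame({"respondent_id": np.arange(1, n + 1)})

    a = (18.0 - config.age_mean) / config.age_sd
    df["age"] = truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    for cov in BINARY_COVARIATES:
        df[cov] = (rng.random(n) < prev.get(cov, 0.0)).astype(int)

    u = rng.random(n)
    p_up, p_mid = prev.get("ses_upper", 0.0), prev.get("ses_middle", 0.0)
    df["ses"] = np.where(u < p_up, "upper", np.where(u < p_up + p_mid, "middle", "lower"))
    df["ses_upper"] = (df["ses"] == "upper").astype(int)
    df["ses_middle"] = (df["ses"] == "middle").astype(int)

    v = rng.random(n)
    p2, p1 = prev.get("vaccinated_two_doses", 0.0), prev.get("vaccinated_one_dose", 0.0)
    df["vaccination"] = np.where(v < p2, "two_doses", np.where(v < p2 + p1, "one_dose", "none"))

    lin = np.zeros(n)
    for name, lo in config.hesitancy_log_odds.items():
        if name not in df.columns:
            raise KeyError(f"hesitancy log-odds refers to unknown covariate {name!r}")
        lin += lo * df[name].to_numpy(dtype=float)
    if n > 0:
        intercept = _hesitancy_intercept(lin, config.hesitant_fraction_target)
        df["hesitancy_propensity"] = expit(intercept + lin)
    else:
        df["hesitancy_propensity"] = np.zeros(0)

    df["attentive"] = (rng.random(n) >= config.p_inattentive).astype(int)
    df["block_id"] = rng.integers(1, n_blocks + 1, size=n)
    return df


def _task_table(design: Design, attrs: Sequence[AttributeSpec], beta: np.ndarray):
    """Per-task utilities, level labels and trap dominance bookkeeping."""
    tasks = list(design.nontrap_tasks)
    traps = design.trap_tasks
    if len(traps) != 1:
        raise ValueError(f"design must contain exactly one trap task, found {len(traps)}")
    trap = traps[0]
    all_tasks = tasks + [trap]
    u_a = np.array([code_profile(t.profile_a, attrs) @ beta for t in all_tasks])
    u_b = np.array([code_profile(t.profile_b, attrs) @ beta for t in all_tasks])
    verdict = is_dominant_pair(trap.profile_a, trap.profile_b, attrs)
    if verdict == "none":
        raise ValueError("trap task is not a dominant pair")
    dominant_side = 0 if verdict == "a_dominates" else 1
    return all_tasks, trap, u_a, u_b, dominant_side


def simulate_choices(
    pop: pd.DataFrame,
    design: Design,
    attrs: Sequence[AttributeSpec],
    config: SimulationConfig,
) -> ChoiceDataset:
    """Simulate every respondent's choices on their block's tasks plus the trap.

    Attentive respondents follow the conditional-logit choice law with
    utilities ``U_A = x_A' beta``, ``U_B = x_B' beta`` and
    ``U_optout = asc + shift * hesitancy_propensity``; inattentive respondents
    pick uniformly among the three alternatives.  Reproducible from the config
    seed.
    """
    cols = coded_columns(attrs)
    missing = [c for c in cols if c not in config.true_beta]
    if missing:
        raise KeyError(f"true_beta missing coefficients for {missing}")
    beta = np.array([config.true_beta[c] for c in cols])
    all_tasks, trap, u_a, u_b, dominant_side = _task_table(design, attrs, beta)
    trap_idx = len(all_tasks) - 1

    tasks_by_block: dict[int, list[int]] = {}
    for i, t in enumerate(all_tasks[:-1]):
        if t.block_id is None:
            raise ValueError(f"task {t.task_id} has no block assignment")
        tasks_by_block.setdefault(t.block_id, []).append(i)

    blocks = pop["block_id"].to_numpy()
    missing_blocks = sorted(set(blocks) - set(tasks_by_block))
    if missing_blocks:
        raise ValueError(f"respondent blocks {missing_blocks} absent from design")

    r_idx_parts, t_idx_parts = [], []
    for b, members in sorted(tasks_by_block.items()):
        rs = np.flatnonzero(blocks == b)
        per_resp = members + [trap_idx]
        r_idx_parts.append(np.repeat(rs, len(per_resp)))
        t_idx_parts.append(np.tile(per_resp, len(rs)))
    r_idx = np.concatenate(r_idx_parts) if r_idx_parts else np.zeros(0, dtype=int)
    t_idx = np.concatenate(t_idx_parts) if t_idx_parts else np.zeros(0, dtype=int)
    order = np.lexsort((t_idx, r_idx))
    r_idx, t_idx = r_idx[order], t_idx[order]
    n_rt = r_idx.size

    prop = pop["hesitancy_propensity"].to_numpy()
    attentive = pop["attentive"].to_numpy().astype(bool)
    U = np.column_stack([
        u_a[t_idx],
        u_b[t_idx],
        config.optout_asc + config.hesitant_optout_shift * prop[r_idx],
    ])
    U -= U.max(axis=1, keepdims=True)
    P = np.exp(U)
    P /= P.sum(axis=1, keepdims=True)
    P[~attentive[r_idx]] = 1.0 / 3.0

    rng = config.rng(1)
    draws = rng.random(n_rt)
    cum = np.cumsum(P, axis=1)
    choice = (draws[:, None] > cum).sum(axis=1)

    if config.deterministic_trap:
        on_trap = t_idx == trap_idx
        choice[on_trap & attentive[r_idx]] = dominant_side

    resp_ids = pop["respondent_id"].to_numpy()
    task_ids = np.array([t.task_id for t in all_tasks])
    is_trap_flags = np.array([int(t.is_trap) for t in all_tasks])

    alt_labels = np.array(["A", "B", "optout"])
    n_rows = n_rt * 3
    frame = {
        "respondent_id": np.repeat(resp_ids[r_idx], 3),
        "task_id": np.repeat(task_ids[t_idx], 3),
        "alternative": np.tile(alt_labels, n_rt),
        "is_trap": np.repeat(is_trap_flags[t_idx], 3),
        "chosen": (np.tile(np.arange(3), n_rt) == np.repeat(choice, 3)).astype(int),
    }
    dom = np.zeros((n_rt, 3), dtype=int)
    dom[t_idx == trap_idx, dominant_side] = 1
    frame["is_dominant"] = dom.reshape(-1)

    for a in attrs:
        lv_a = np.array([t.profile_a.level(a.name) for t in all_tasks], dtype=object)
        lv_b = np.array([t.profile_b.level(a.name) for t in all_tasks], dtype=object)
        tri = np.empty((n_rt, 3), dtype=object)
        tri[:, 0] = lv_a[t_idx]
        tri[:, 1] = lv_b[t_idx]
        tri[:, 2] = ""
        frame[a.name] = tri.reshape(-1)

    return ChoiceDataset(choices=pd.DataFrame(frame), respondents=pop.copy())


def apply_trap_filter(data: ChoiceDataset) -> tuple[ChoiceDataset, ChoiceDataset, float]:
    """Partition respondents by trap performance.

    A respondent passes iff the dominant alternative was chosen on the trap
    task (choosing opt-out counts as a failure).  Returns
    ``(passed, failed, fail_fraction)``; both partitions carry a
    ``trap_failed`` respondent column.
    """
    ch = data.choices
    trap_chosen = ch[(ch["is_trap"] == 1) & (ch["chosen"] == 1)]
    counts = trap_chosen.groupby("respondent_id").size()
    all_ids = data.respondents["respondent_id"]
    bad = set(all_ids) - set(counts.index)
    if bad or (counts != 1).any():
        raise ValueError("every respondent must have exactly one trap response")

    passed_ids = set(trap_chosen.loc[trap_chosen["is_dominant"] == 1, "respondent_id"])
    resp = data.respondents.copy()
    resp["trap_failed"] = (~resp["respondent_id"].isin(passed_ids)).astype(int)

    annotated = ChoiceDataset(choices=ch, respondents=resp)
    passed = annotated.subset(passed_ids)
    failed = annotated.subset(set(all_ids) - passed_ids)
    fail_fraction = 1.0 - len(passed_ids) / len(all_ids)
    return passed, failed, fail_fraction


def calibrate_optout_asc(
    design: Design,
    attrs: Sequence[AttributeSpec],
    config: SimulationConfig,
    target_share: float = defaults.STUDY_OPTOUT_TASK_SHARE,
    n_mc: int = 20_000,
) -> float:
    """Solve for the opt-out constant giving an expected task-level opt-out
    share of ``target_share``, by Monte-Carlo expectation over a seeded
    respondent draw (no choice sampling noise)."""
    cfg = dataclasses.replace(config, n_respondents=n_mc)
    pop = generate_population(cfg, n_blocks=max(design.n_blocks, 1))
    cols = coded_columns(attrs)
    beta = np.array([cfg.true_beta[c] for c in cols])
    all_tasks, _, u_a, u_b, _ = _task_table(design, attrs, beta)
    prop = pop["hesitancy_propensity"].to_numpy()
    blocks = pop["block_id"].to_numpy()

    tasks_by_block: dict[int, list[int]] = {}
    for i, t in enumerate(all_tasks[:-1]):
        tasks_by_block.setdefault(t.block_id, []).append(i)
    trap_idx = len(all_tasks) - 1

    r_parts, t_parts = [], []
    for b, members in sorted(tasks_by_block.items()):
        rs = np.flatnonzero(blocks == b)
        per_resp = members + [trap_idx]
        r_parts.append(np.repeat(rs, len(per_resp)))
        t_parts.append(np.tile(per_resp, len(rs)))
    r_idx = np.concatenate(r_parts)
    t_idx = np.concatenate(t_parts)
    ua, ub = u_a[t_idx], u_b[t_idx]
    shift_term = cfg.hesitant_optout_shift * prop[r_idx]
    p_in = cfg.p_inattentive

    def share(asc: float) -> float:
        uo = asc + shift_term
        m = np.maximum(np.maximum(ua, ub), uo)
        eo = np.exp(uo - m)
        p_opt = eo / (np.exp(ua - m) + np.exp(ub - m) + eo)
        return p_in / 3.0 + (1.0 - p_in) * p_opt.mean()

    return brentq(lambda a: share(a) - target_share, -30.0, 30.0, xtol=1e-10)
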