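"""Attribute grids and experimental design construction for paired-choice studies.

A design is a collection of choice tasks, each pairing two hypothetical
profiles (plus an always-available opt-out).  This module provides the full
factorial over an attribute grid, candidate-pair enumeration and sampling,
the conditional-logit Fisher information of a design, a modified Fedorov
exchange for D-optimal subset selection, random blocking with a chi-square
balance check, dominance classification (used to build trap tasks), and the
Johnson-Orme sample-size rule of thumb.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

__all__ = [
    "AttributeSpec",
    "Profile",
    "ChoiceTask",
    "Design",
    "chain",
    "enumerate_full_factorial",
    "count_unique_pairs",
    "sample_candidate_pairs",
    "coded_columns",
    "code_profile",
    "decode_row",
    "information_matrix",
    "d_optimal_select",
    "assign_blocks",
    "block_balance_test",
    "is_dominant_pair",
    "johnson_orme_min_n",
    "design_to_frame",
    "design_from_frame",
    "write_design_csv",
    "read_design_csv",
]


def chain(levels_best_to_worst: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Strict-preference pairs for a totally ordered set of levels, best first."""
    pairs = []
    for i, better in enumerate(levels_best_to_worst):
        for worse in levels_best_to_worst[i + 1 :]:
            pairs.append((better, worse))
    return tuple(pairs)


def _transitive_closure(pairs: Iterable[tuple[str, str]]) -> frozenset[tuple[str, str]]:
    closed = set(pairs)
    changed = True
    while changed:
        changed = False
        for (a, b) in list(closed):
            for (c, d) in list(closed):
                if b == c and (a, d) not in closed:
                    closed.add((a, d))
                    changed = True
    return frozenset(closed)


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of a hypothetical alternative: its levels, its coding for
    estimation, and an optional strict partial preference order used only for
    dominance checks.

    ``preference_order`` is a collection of (better, worse) level pairs; the
    transitive closure is taken at construction and antisymmetry is enforced.
    Levels not related by any pair are incomparable.
    """

    name: str
    levels: tuple[str, ...]
    coding: str = CATEGORICAL
    reference_level: str | None = None
    numeric_values: Mapping[str, float] | None = None
    preference_order: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ValueError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"attribute {self.name!r} has duplicate levels")
        if self.coding not in (CATEGORICAL, CONTINUOUS):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.coding == CATEGORICAL:
            ref = self.reference_level if self.reference_level is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(
                    f"reference level {ref!r} not a level of {self.name!r}"
                )
            object.__setattr__(self, "reference_level", ref)
            if self.numeric_values is not None:
                raise ValueError("numeric_values only valid for continuous coding")
        else:
            if self.numeric_values is None:
                raise ValueError(f"continuous attribute {self.name!r} needs numeric_values")
            missing = set(self.levels) - set(self.numeric_values)
            if missing:
                raise ValueError(f"numeric_values missing for levels {sorted(missing)}")
            object.__setattr__(self, "numeric_values", dict(self.numeric_values))
        for a, b in self.preference_order:
            if a not in self.levels or b not in self.levels:
                raise ValueError(f"preference pair ({a!r}, {b!r}) uses unknown level")
        closed = _transitive_closure(self.preference_order)
        for a, b in closed:
            if a == b or (b, a) in closed:
                raise ValueError(
                    f"preference order of {self.name!r} is not a strict partial order"
                )
        object.__setattr__(self, "preference_order", tuple(sorted(closed)))
        object.__setattr__(self, "_strict", closed)

    def prefers(self, a: str, b: str) -> bool:
        """True when level ``a`` is strictly preferred to level ``b``."""
        return (a, b) in self._strict  # type: ignore[attr-defined]

    def weakly_prefers(self, a: str, b: str) -> bool:
        return a == b or self.prefers(a, b)


@dataclass(frozen=True)
class Profile:
    """One hypothetical alternative: exactly one level per attribute."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    def level(self, name: str) -> str:
        return self.assignment[name]

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.assignment.items())))


def validate_profile(profile: Profile, attrs: Sequence[AttributeSpec]) -> None:
    names = {a.name for a in attrs}
    if set(profile.assignment) != names:
        raise ValueError(
            f"profile covers {sorted(profile.assignment)} but grid has {sorted(names)}"
        )
    for a in attrs:
        lvl = profile.level(a.name)
        if lvl not in a.levels:
            raise ValueError(f"{lvl!r} is not a level of attribute {a.name!r}")


@dataclass
class ChoiceTask:
    """A pair of profiles shown together with an opt-out alternative."""

    task_id: int
    profile_a: Profile
    profile_b: Profile
    is_trap: bool = False
    block_id: int | None = None
    has_optout: bool = True

    def __post_init__(self) -> None:
        if self.profile_a == self.profile_b:
            raise ValueError("a choice task needs two distinct profiles")


@dataclass
class Design:
    """A set of choice tasks, optionally blocked, with its D-criterion value."""

    tasks: list[ChoiceTask]
    n_blocks: int = 0
    criterion_value: float = math.nan
    criterion_history: list[float] | None = None

    @property
    def nontrap_tasks(self) -> list[ChoiceTask]:
        return [t for t in self.tasks if not t.is_trap]

    @property
    def trap_tasks(self) -> list[ChoiceTask]:
        return [t for t in self.tasks if t.is_trap]


# ---------------------------------------------------------------------------
# enumeration


def enumerate_full_factorial(attrs: Sequence[AttributeSpec]) -> list[Profile]:
    """Every distinct full assignment, in lexicographic order of the grid."""
    if not attrs:
        raise ValueError("empty attribute list")
    names = [a.name for a in attrs]
    out = []
    for combo in itertools.product(*(a.levels for a in attrs)):
        out.append(Profile(dict(zip(names, combo))))
    return out


def count_unique_pairs(n_profiles: int) -> int:
    """Number of unordered profile pairs."""
    if n_profiles < 2:
        raise ValueError("need at least 2 profiles to form a pair")
    return n_profiles * (n_profiles - 1) // 2


def sample_candidate_pairs(
    profiles: Sequence[Profile],
    n_pairs: int | None,
    seed: int = 0,
    start_task_id: int = 1,
) -> list[ChoiceTask]:
    """A seeded without-replacement sample of distinct unordered profile pairs.

    ``n_pairs=None`` (or >= the total pair count) enumerates every pair.
    """
    m = len(profiles)
    total = count_unique_pairs(m)
    i_all, j_all = np.triu_indices(m, k=1)
    if n_pairs is None or n_pairs >= total:
        chosen = np.arange(total)
    else:
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(total, size=n_pairs, replace=False))
    return [
        ChoiceTask(task_id=start_task_id + k, profile_a=profiles[i_all[c]], profile_b=profiles[j_all[c]])
        for k, c in enumerate(chosen)
    ]


# ---------------------------------------------------------------------------
# coding


def coded_columns(attrs: Sequence[AttributeSpec]) -> list[str]:
    """Design-matrix column names: one dummy per non-reference categorical
    level (``name:level``), one numeric column per continuous attribute."""
    cols: list[str] = []
    for a in attrs:
        if a.coding == CATEGORICAL:
            cols.extend(f"{a.name}:{lvl}" for lvl in a.levels if lvl != a.reference_level)
        else:
            cols.append(a.name)
    return cols


def code_profile(profile: Profile, attrs: Sequence[AttributeSpec]) -> np.ndarray:
    validate_profile(profile, attrs)
    row: list[float] = []
    for a in attrs:
        lvl = profile.level(a.name)
        if a.coding == CATEGORICAL:
            row.extend(1.0 if lvl == other else 0.0 for other in a.levels if other != a.reference_level)
        else:
            row.append(float(a.numeric_values[lvl]))
    return np.asarray(row)


def decode_row(values: Sequence[float], attrs: Sequence[AttributeSpec]) -> Profile:
    """Inverse of :func:`code_profile` for rows produced by it."""
    values = list(values)
    assignment: dict[str, str] = {}
    pos = 0
    for a in attrs:
        if a.coding == CATEGORICAL:
            nonref = [lvl for lvl in a.levels if lvl != a.reference_level]
            block = values[pos : pos + len(nonref)]
            pos += len(nonref)
            hits = [lvl for lvl, v in zip(nonref, block) if v == 1.0]
            if len(hits) > 1:
                raise ValueError(f"ambiguous dummy block for {a.name!r}")
            assignment[a.name] = hits[0] if hits else a.reference_level
        else:
            val = values[pos]
            pos += 1
            inverse = {v: k for k, v in a.numeric_values.items()}
            if val not in inverse:
                raise ValueError(f"{val} is not a coded value of {a.name!r}")
            assignment[a.name] = inverse[val]
    return Profile(assignment)


# ---------------------------------------------------------------------------
# information and D-optimality


def information_matrix(
    tasks: Sequence[ChoiceTask],
    beta: Sequence[float],
    attrs: Sequence[AttributeSpec],
) -> np.ndarray:
    """Conditional-logit Fisher information of a paired design at ``beta``.

    Per task the contribution is sum_j p_j x_j x_j' - (sum_j p_j x_j)(.)',
    with p the logit choice probabilities over the two profiles.
    """
    cols = coded_columns(attrs)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(cols),):
        raise ValueError(f"beta has length {beta.size}, expected {len(cols)}")
    M = np.zeros((len(cols), len(cols)))
    for t in tasks:
        X = np.vstack([code_profile(t.profile_a, attrs), code_profile(t.profile_b, attrs)])
        u = X @ beta
        u -= u.max()
        p = np.exp(u)
        p /= p.sum()
        mean = p @ X
        M += (X.T * p) @ X - np.outer(mean, mean)
    return M


def _pair_diffs(
    tasks: Sequence[ChoiceTask], beta: np.ndarray, attrs: Sequence[AttributeSpec]
) -> tuple[np.ndarray, np.ndarray]:
    # two-alternative information is rank one: p_a * p_b * (x_a - x_b)(x_a - x_b)'
    Xa = np.vstack([code_profile(t.profile_a, attrs) for t in tasks])
    Xb = np.vstack([code_profile(t.profile_b, attrs) for t in tasks])
    du = (Xa - Xb) @ beta
    pa = 1.0 / (1.0 + np.exp(-du))
    return Xa - Xb, pa * (1.0 - pa)


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    return ld if sign > 0 else -math.inf


def d_optimal_select(
    candidates: Sequence[ChoiceTask],
    attrs: Sequence[AttributeSpec],
    n_sets: int,
    beta0: Sequence[float] | None = None,
    seed: int = 0,
    n_candidate_sample: int | None = None,
    *,
    ridge: float = 1e-8,
    max_passes: int = 200,
    improvement_tol: float = 1e-10,
) -> Design:
    """Modified Fedorov exchange maximising log-det of the design information.

    Starts from a seeded random ``n_sets``-subset of the (optionally seeded,
    subsampled) candidate tasks and repeatedly swaps one included task for the
    excluded candidate giving the largest log-det improvement, stopping after a
    full pass with no accepted swap.  A small ridge stabilises log-det during
    the search only; the returned ``criterion_value`` is ridge-free and must be
    finite.  Deterministic for a given ``(seed, n_candidate_sample)``.
    """
    cand = list(candidates)
    rng = np.random.default_rng(seed)
    if n_candidate_sample is not None and n_candidate_sample < len(cand):
        keep = np.sort(rng.choice(len(cand), size=n_candidate_sample, replace=False))
        cand = [cand[i] for i in keep]
    if n_sets < 1 or n_sets > len(cand):
        raise ValueError(f"n_sets={n_sets} out of range for {len(cand)} candidates")

    cols = coded_columns(attrs)
    k = len(cols)
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float)
    if beta.shape != (k,):
        raise ValueError(f"beta0 has length {beta.size}, expected {k}")
    D, w = _pair_diffs(cand, beta, attrs)

    def subset_info(mask: np.ndarray) -> np.ndarray:
        Ds = D[mask]
        return (Ds.T * w[mask]) @ Ds

    if n_sets == len(cand):
        mask = np.ones(len(cand), dtype=bool)
        ld = _logdet(subset_info(mask))
        if not math.isfinite(ld):
            raise ValueError("candidate set is singular; supply more varied candidates")
        return Design(tasks=cand, criterion_value=ld, criterion_history=[ld])

    R = ridge * np.eye(k)
    mask = np.zeros(len(cand), dtype=bool)
    mask[rng.choice(len(cand), size=n_sets, replace=False)] = True

    history: list[float] = []
    for _ in range(max_passes):
        M = subset_info(mask) + R
        cur = _logdet(M)
        if not history:
            history.append(cur)
        improved = False
        for i in np.flatnonzero(mask):
            Mi = M - w[i] * np.outer(D[i], D[i])
            ldi = _logdet(Mi)
            if not math.isfinite(ldi):
                continue
            Ai = np.linalg.inv(Mi)
            out = np.flatnonzero(~mask)
            q = np.einsum("ij,jk,ik->i", D[out], Ai, D[out])
            gains = ldi + np.log1p(np.maximum(w[out] * q, -0.999999999))
            j_rel = int(np.argmax(gains))
            if gains[j_rel] - cur > improvement_tol:
                j = int(out[j_rel])
                mask[i] = False
                mask[j] = True
                M = Mi + w[j] * np.outer(D[j], D[j])
                cur = gains[j_rel]
                history.append(cur)
                improved = True
        if not improved:
            break

    final = _logdet(subset_info(mask))
    if not math.isfinite(final):
        raise ValueError(
            "exchange terminated on a singular design; "
            "increase n_sets or the candidate sample"
        )
    tasks = [cand[i] for i in np.flatnonzero(mask)]
    return Design(tasks=tasks, criterion_value=final, criterion_history=history)


# ---------------------------------------------------------------------------
# blocking


def assign_blocks(design: Design, n_blocks: int, seed: int = 0) -> Design:
    """Seeded random partition of the non-trap tasks into equal blocks 1..n."""
    nontrap = design.nontrap_tasks
    if n_blocks < 1 or len(nontrap) % n_blocks != 0:
        raise ValueError(
            f"{len(nontrap)} tasks cannot be split into {n_blocks} equal blocks"
        )
    per_block = len(nontrap) // n_blocks
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(nontrap))
    new_tasks: list[ChoiceTask] = []
    slot = {int(task_idx): pos for pos, task_idx in enumerate(order)}
    i_nontrap = 0
    for t in design.tasks:
        if t.is_trap:
            new_tasks.append(replace(t))
        else:
            new_tasks.append(replace(t, block_id=slot[i_nontrap] // per_block + 1))
            i_nontrap += 1
    return Design(
        tasks=new_tasks,
        n_blocks=n_blocks,
        criterion_value=design.criterion_value,
        criterion_history=design.criterion_history,
    )


def block_balance_test(block_counts: Sequence[int]) -> tuple[float, float]:
    """Pearson goodness-of-fit of observed block counts against uniformity."""
    counts = np.asarray(block_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two blocks")
    if counts.sum() <= 0:
        raise ValueError("expected counts are zero")
    res = stats.chisquare(counts)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# dominance and sample size


def is_dominant_pair(
    a: Profile, b: Profile, attrs: Sequence[AttributeSpec]
) -> str:
    """Classify a pair as ``a_dominates``, ``b_dominates`` or ``none``.

    A profile dominates when it is weakly preferred on every attribute under
    that attribute's partial order (incomparable levels must be equal) and
    strictly preferred on at least one.
    """
    validate_profile(a, attrs)
    validate_profile(b, attrs)
    a_weak = all(s.weakly_prefers(a.level(s.name), b.level(s.name)) for s in attrs)
    b_weak = all(s.weakly_prefers(b.level(s.name), a.level(s.name)) for s in attrs)
    a_strict = any(s.prefers(a.level(s.name), b.level(s.name)) for s in attrs)
    b_strict = any(s.prefers(b.level(s.name), a.level(s.name)) for s in attrs)
    if a_weak and a_strict:
        return "a_dominates"
    if b_weak and b_strict:
        return "b_dominates"
    return "none"


def johnson_orme_min_n(c: int, t: int, a: int) -> int:
    """Rule-of-thumb minimum respondents: ceil(500 c / (t a))."""
    if c < 1 or t < 1 or a < 1:
        raise ValueError("all inputs must be >= 1")
    return -(-500 * c // (t * a))


# ---------------------------------------------------------------------------
# CSV round trip


def design_to_frame(design: Design, attrs: Sequence[AttributeSpec]) -> pd.DataFrame:
    """One row per task-alternative: task_id, block_id, is_trap, alternative,
    then one level-label column per attribute."""
    rows = []
    for t in design.tasks:
        for alt, prof in (("A", t.profile_a), ("B", t.profile_b)):
            row = {
                "task_id": t.task_id,
                "block_id": -1 if t.block_id is None else t.block_id,
                "is_trap": int(t.is_trap),
                "alternative": alt,
            }
            row.update({a.name: prof.level(a.name) for a in attrs})
            rows.append(row)
    return pd.DataFrame(rows)


def design_from_frame(frame: pd.DataFrame, attrs: Sequence[AttributeSpec]) -> Design:
    tasks = []
    n_blocks = 0
    for task_id, grp in frame.groupby("task_id", sort=True):
        profs = {}
        for _, row in grp.iterrows():
            profs[row["alternative"]] = Profile({a.name: row[a.name] for a in attrs})
        block = int(grp["block_id"].iloc[0])
        tasks.append(
            ChoiceTask(
                task_id=int(task_id),
                profile_a=profs["A"],
                profile_b=profs["B"],
                is_trap=bool(grp["is_trap"].iloc[0]),
                block_id=None if block < 0 else block,
            )
        )
        if block > n_blocks:
            n_blocks = block
    return Design(tasks=tasks, n_blocks=n_blocks)


def write_design_csv(design: Design, attrs: Sequence[AttributeSpec], path) -> None:
    design_to_frame(design, attrs).to_csv(path, index=False, lineterminator="\n")


def read_design_csv(path, attrs: Sequence[AttributeSpec]) -> Design:
    return design_from_frame(pd.read_csv(path), attrs)
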