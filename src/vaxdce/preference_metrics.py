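"""Post-estimation preference metrics: willingness-to-pay ratios with
delta-method (or parametric-bootstrap) intervals, relative attribute
importance, and a fixed-rate currency helper."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .clogit_estimation import ClogitFit
from .design_space import CATEGORICAL, AttributeSpec

__all__ = [
    "WtpEstimate",
    "wtp",
    "wtp_table",
    "wtp_bootstrap",
    "rai",
    "convert_inr_usd",
]


@dataclass(frozen=True)
class WtpEstimate:
    """Monetary valuation of one attribute level relative to its reference."""

    level: str
    wtp: float
    se: float
    ci_low: float
    ci_high: float
    usd: float


def wtp(
    fit: ClogitFit,
    level: str,
    cost_name: str = "cost",
    z: float = 1.96,
    rate: float = defaults.INR_PER_USD,
) -> WtpEstimate:
    """WTP(level) = -beta(level) / beta(cost), with a delta-method interval.

    The variance uses the gradient (-1/bc, bl/bc^2) against the 2x2
    sub-covariance of (beta_level, beta_cost).
    """
    if level not in fit.columns or cost_name not in fit.columns:
        raise KeyError(f"{level!r} or {cost_name!r} not among fitted coefficients")
    il, ic = fit.columns.index(level), fit.columns.index(cost_name)
    bl, bc = fit.beta[il], fit.beta[ic]
    if abs(bc) < 1e-12:
        raise ZeroDivisionError("cost coefficient is (numerically) zero; WTP undefined")
    point = -bl / bc
    g = np.array([-1.0 / bc, bl / bc**2])
    sub = fit.vcov[np.ix_([il, ic], [il, ic])]
    var = float(g @ sub @ g)
    se = float(np.sqrt(max(var, 0.0)))
    return WtpEstimate(
        level=level,
        wtp=float(point),
        se=se,
        ci_low=float(point - z * se),
        ci_high=float(point + z * se),
        usd=convert_inr_usd(point, rate),
    )


def wtp_table(
    fit: ClogitFit,
    cost_name: str = "cost",
    z: float = 1.96,
    rate: float = defaults.INR_PER_USD,
    skip: Sequence[str] = ("optout_asc",),
) -> pd.DataFrame:
    rows = []
    for col in fit.columns:
        if col == cost_name or col in skip:
            continue
        est = wtp(fit, col, cost_name=cost_name, z=z, rate=rate)
        rows.append(
            {"level": col, "wtp_inr": est.wtp, "se": est.se,
             "ci_low": est.ci_low, "ci_high": est.ci_high, "wtp_usd": est.usd}
        )
    return pd.DataFrame(rows).set_index("level")


def wtp_bootstrap(
    fit: ClogitFit,
    level: str,
    cost_name: str = "cost",
    n_draws: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Parametric bootstrap alternative: draw coefficients from the fitted
    multivariate normal and take percentile bounds of the WTP ratio."""
    rng = np.random.default_rng(seed)
    il, ic = fit.columns.index(level), fit.columns.index(cost_name)
    draws = rng.multivariate_normal(fit.beta, fit.vcov, size=n_draws)
    ratios = -draws[:, il] / draws[:, ic]
    lo, hi = np.quantile(ratios, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(-fit.beta[il] / fit.beta[ic]), float(lo), float(hi)


def rai(
    fit: ClogitFit | Mapping[str, float],
    attrs: Sequence[AttributeSpec],
    exclude: set[str] = frozenset({"cost"}),
) -> pd.DataFrame:
    """Relative attribute importance from part-worth ranges.

    Each attribute's utility range is max minus min over {0 (reference)} and
    its level coefficients; RAI is the range as a percent of the summed ranges
    over non-excluded attributes.  Continuous attributes (cost) are excluded
    by default.
    """
    coefs = fit.coef.to_dict() if isinstance(fit, ClogitFit) else dict(fit)
    rows = []
    for a in attrs:
        if a.name in exclude or a.coding != CATEGORICAL:
            continue
        values = [0.0]
        for lvl in a.levels:
            if lvl == a.reference_level:
                continue
            key = f"{a.name}:{lvl}"
            if key not in coefs:
                raise KeyError(f"no coefficient for {key!r}")
            values.append(float(coefs[key]))
        rows.append({"attribute": a.name, "utility_range": max(values) - min(values)})
    if not rows:
        raise ValueError("no attributes left after exclusion")
    table = pd.DataFrame(rows).set_index("attribute")
    total = table["utility_range"].sum()
    if total <= 0:
        raise ValueError("all utility ranges are zero")
    table["rai_percent"] = 100.0 * table["utility_range"] / total
    return table.sort_values("rai_percent", ascending=False)


def convert_inr_usd(amount: float, rate: float = defaults.INR_PER_USD) -> float:
    """INR to USD at a fixed rate, reported to 2 decimals."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return round(amount / rate, 2)
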