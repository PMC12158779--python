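"""Simultaneous-choice kin-bias analysis.

A *choice day* is a helper-day on which the helper was a possible helper at at
least one kin nest and at least one non-kin nest under observation (kin defined
by closest-parent relatedness strictly above a threshold).  The per-day paired
difference is the exposure-weighted helping rate at kin nests minus the rate at
non-kin nests; per-helper biases average over the helper's choice days, and
uncertainty comes from a percentile bootstrap resampling helpers (the helper is
the independent unit).  A threshold sweep repeats the estimate across kinship
cut-offs; estimates are withheld for cells with fewer than five helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
MIN_HELPERS = 5


@dataclass
class ChoiceDay:
    """One helper-day with simultaneous kin and non-kin nests under observation."""

    helper_id: str
    day: int
    kin_help: float
    kin_exposure: float
    nonkin_help: float
    nonkin_exposure: float
    threshold: float

    @property
    def paired_difference(self) -> float:
        return self.kin_help / self.kin_exposure - self.nonkin_help / self.nonkin_exposure


@dataclass
class BiasEstimate:
    """Mean paired kin-vs-non-kin difference with bootstrap CI at one threshold."""

    threshold: float
    helper_type: str
    n_helpers: int
    mean_bias: float | None
    ci_lo: float | None
    ci_hi: float | None


def find_choice_days(table: pd.DataFrame, threshold: float) -> list[ChoiceDay]:
    """Enumerate helper-days offering both kin and non-kin nests.

    Multiple nests on one side of the threshold are aggregated by summing help
    and exposure minutes.  Days with zero exposure on either side are dropped
    with a warning (cannot form a rate).
    """
    out: list[ChoiceDay] = []
    for (helper, day), sub in table.groupby(["helper_id", "day"], sort=True):
        kin = sub[sub["kinship_r"] > threshold]
        nonkin = sub[sub["kinship_r"] <= threshold]
        if not len(kin) or not len(nonkin):
            continue
        ke, ne = kin["exposure_minutes"].sum(), nonkin["exposure_minutes"].sum()
        if ke <= 0 or ne <= 0:
            logger.warning("choice day (%s, %s) dropped: zero exposure on one side", helper, day)
            continue
        out.append(
            ChoiceDay(
                helper_id=helper,
                day=int(day),
                kin_help=float(kin["help_minutes"].sum()),
                kin_exposure=float(ke),
                nonkin_help=float(nonkin["help_minutes"].sum()),
                nonkin_exposure=float(ne),
                threshold=threshold,
            )
        )
    return out


def helper_bias(days: list[ChoiceDay]) -> float:
    """Average paired difference over one helper's choice days."""
    if not days:
        raise ValueError("helper_bias requires at least one choice day")
    return float(np.mean([d.paired_difference for d in days]))


def per_helper_biases(days: list[ChoiceDay]) -> pd.Series:
    by_helper: dict[str, list[ChoiceDay]] = {}
    for d in days:
        by_helper.setdefault(d.helper_id, []).append(d)
    return pd.Series({h: helper_bias(ds) for h, ds in sorted(by_helper.items())})


def bootstrap_mean_ci(
    values, B: int = 10_000, seed: int = 0, min_n: int = MIN_HELPERS
) -> tuple[float, float, float] | None:
    """Percentile bootstrap CI for a mean, resampling subjects with replacement.

    Returns ``None`` (absent estimate, not an error) when fewer than ``min_n``
    values are available, following the convention of withholding estimates for
    cells with fewer than five helpers.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < min_n:
        return None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(B, len(values)))
    means = values[idx].mean(axis=1)
    return float(values.mean()), float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))


HELPER_TYPES = (
    ("male", "resident"),
    ("female", "resident"),
    ("male", "immigrant"),
    ("female", "immigrant"),
)


def _type_mask(table: pd.DataFrame, helper_type) -> pd.Series:
    if helper_type == "all":
        return pd.Series(True, index=table.index)
    sex, disp = helper_type
    return (table["helper_sex"] == sex) & (table["helper_dispersal"] == disp)


def threshold_sweep(
    table: pd.DataFrame,
    grid=DEFAULT_GRID,
    helper_types=(("all",) + HELPER_TYPES)[0:],
    B: int = 10_000,
    seed: int = 0,
) -> list[BiasEstimate]:
    """Kin-bias estimate per kinship threshold and helper type."""
    estimates: list[BiasEstimate] = []
    for threshold in grid:
        if not (0 < threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        for helper_type in helper_types:
            sub = table[_type_mask(table, helper_type)]
            days = find_choice_days(sub, threshold)
            biases = per_helper_biases(days) if days else pd.Series(dtype=float)
            label = helper_type if helper_type == "all" else ":".join(helper_type)
            ci = bootstrap_mean_ci(biases.to_numpy(), B=B, seed=seed)
            if ci is None:
                estimates.append(BiasEstimate(threshold, label, len(biases), None, None, None))
            else:
                mean, lo, hi = ci
                estimates.append(BiasEstimate(threshold, label, len(biases), mean, lo, hi))
    return estimates


def sweep_to_frame(estimates: list[BiasEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.threshold, e.helper_type, e.n_helpers, e.mean_bias, e.ci_lo, e.ci_hi)
            for e in estimates
        ],
        columns=["threshold", "helper_type", "n_helpers", "mean_bias", "ci_lo", "ci_hi"],
    )


def nonkin_choice_probability(days: list[ChoiceDay]) -> float:
    """Fraction of choice days on which any help went to a non-kin nest."""
    if not days:
        raise ValueError("no choice days supplied")
    return float(np.mean([d.nonkin_help > 0 for d in days]))


def nonkin_choice_by_type(table: pd.DataFrame, threshold: float) -> dict:
    """Non-kin-choice probability per helper type and pooled across individuals."""
    out = {}
    for helper_type in ("all",) + HELPER_TYPES:
        sub = table[_type_mask(table, helper_type)]
        days = find_choice_days(sub, threshold)
        label = helper_type if helper_type == "all" else ":".join(helper_type)
        out[label] = nonkin_choice_probability(days) if days else None
    return out
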