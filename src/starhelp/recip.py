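"""Reciprocal-pair detection, role-switch tallies and exact binomial intervals.

Helping is directed: a visit by helper A at a nest credits help from A to each
of the nest's two breeders.  A pair has *reciprocated* when help flowed in both
directions at any time during the study (the atemporal definition used by the
rate models; a strictly-prior variant is available for the model covariate).
Return help is *observable* for a pair when, in a season other than one in
which A helped B, the one-time helper held a breeding nest while the partner
was present in the group and not breeding — only such pairs enter the
denominator of reciprocal-pair proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "directed_help",
    "attach_reciprocal",
    "reciprocity_possible",
    "detect_reciprocal_pairs",
    "reciprocal_latency",
    "tally_role_switches",
    "exact_binomial_ci",
]


def directed_help(ledger, nests: pd.DataFrame) -> pd.DataFrame:
    """Directed giver->breeder help records with first season and first day.

    One row per ordered (giver, receiver) pair that was ever seen helping:
    ``giver, receiver, first_season, first_day, total_minutes``.
    """
    visits = ledger.visits if hasattr(ledger, "visits") else ledger
    if not len(visits):
        return pd.DataFrame(
            columns=["giver", "receiver", "first_season", "first_day", "total_minutes"]
        )
    merged = visits.merge(
        nests[["nest_id", "season", "mother_id", "father_id"]], on="nest_id", how="left"
    )
    long = pd.concat(
        [
            merged.rename(columns={"mother_id": "receiver"})[
                ["helper_id", "receiver", "season", "day", "help_minutes"]
            ],
            merged.rename(columns={"father_id": "receiver"})[
                ["helper_id", "receiver", "season", "day", "help_minutes"]
            ],
        ]
    ).rename(columns={"helper_id": "giver"})
    out = (
        long.groupby(["giver", "receiver"], as_index=False)
        .agg(
            first_season=("season", "min"),
            first_day=("day", "min"),
            total_minutes=("help_minutes", "sum"),
        )
        .sort_values(["giver", "receiver"], ignore_index=True)
    )
    return out


def attach_reciprocal(table: pd.DataFrame, ledger, nests: pd.DataFrame,
                      mode: str = "atemporal") -> pd.DataFrame:
    """Fill the ``reciprocal`` covariate on an analysis table.

    A row is flagged when either breeder of its nest helped the focal helper
    (acted as the helper's helper).  ``mode="atemporal"`` flags help at any
    time during the study; ``mode="prior"`` requires the received help to fall
    in a season strictly before the row's season (no future information).
    """
    if mode not in ("atemporal", "prior"):
        raise ValueError("mode must be 'atemporal' or 'prior'")
    dh = directed_help(ledger, nests)
    first = {(g, r): s for g, r, s in zip(dh["giver"], dh["receiver"], dh["first_season"])}
    flags = np.zeros(len(table), dtype=int)
    for k, (h, m, f, season) in enumerate(
        zip(table["helper_id"], table["mother_id"], table["father_id"], table["season"])
    ):
        sm = first.get((m, h))
        sf = first.get((f, h))
        if mode == "atemporal":
            flags[k] = int(sm is not None or sf is not None)
        else:
            flags[k] = int(
                (sm is not None and sm < season) or (sf is not None and sf < season)
            )
    table = table.copy()
    table["reciprocal"] = flags
    return table


@dataclass
class DyadReciprocity:
    """Reciprocity record for an unordered pair."""

    id_a: str
    id_b: str
    observable: bool
    reciprocated: bool
    first_give_day: float | None
    first_return_day: float | None
    latency_days: float | None
    sex_pair: str
    dispersal_pair: str


def _pair_label(values: tuple) -> str:
    return "-".join(sorted(values))


def reciprocity_possible(
    ledger, nests: pd.DataFrame, roles: pd.DataFrame, presence: pd.DataFrame
) -> pd.DataFrame:
    """Flag, per unordered helped pair, whether return help was observable.

    For each directed record "A helped B", the return direction is observable
    if in some other season A bred while B was present in A's breeding group
    and not itself breeding.  The unordered-pair flag is the union over the
    two directions, matching the denominator convention for reciprocal-pair
    proportions.
    """
    dh = directed_help(ledger, nests)
    breeder_seasons: dict = {}
    for r in nests.itertuples(index=False):
        breeder_seasons.setdefault(r.mother_id, []).append((int(r.season), r.group))
        breeder_seasons.setdefault(r.father_id, []).append((int(r.season), r.group))
    breeding = {
        (i, s) for i, seasons in breeder_seasons.items() for (s, _) in seasons
    }
    present = set(zip(presence["individual"], presence["group"], presence["season"]))

    def return_observable(giver, receiver, help_season) -> bool:
        # the original giver must later-or-earlier breed with the receiver available
        for s, grp in breeder_seasons.get(giver, []):
            if s == help_season:
                continue
            if (receiver, grp, s) in present and (receiver, s) not in breeding:
                return True
        return False

    flags: dict[tuple, bool] = {}
    for rec in dh.itertuples(index=False):
        pair = tuple(sorted((rec.giver, rec.receiver)))
        obs = return_observable(rec.giver, rec.receiver, int(rec.first_season))
        flags[pair] = flags.get(pair, False) or obs
    return pd.DataFrame(
        [(a, b, v) for (a, b), v in sorted(flags.items())],
        columns=["id_a", "id_b", "observable"],
    )


def detect_reciprocal_pairs(
    ledger,
    nests: pd.DataFrame,
    individuals: pd.DataFrame | None = None,
    observable: pd.DataFrame | None = None,
) -> tuple[list[DyadReciprocity], dict]:
    """Find pairs with help in both directions, plus summary counts.

    Returns the per-pair records (for every unordered pair with at least one
    directed help record) and a summary dict with pair counts split by sex and
    dispersal composition.  Detection is exact given full observation: a pair
    is reciprocated iff both directed records exist, in either temporal order.
    """
    dh = directed_help(ledger, nests)
    directed = {
        (g, r): (d, s)
        for g, r, s, d in zip(dh["giver"], dh["receiver"], dh["first_season"], dh["first_day"])
    }
    obs_map = {}
    if observable is not None:
        obs_map = {
            (a, b): bool(v)
            for a, b, v in zip(observable["id_a"], observable["id_b"], observable["observable"])
        }
    meta = (
        individuals.set_index("id")[["sex", "dispersal"]].to_dict("index")
        if individuals is not None
        else {}
    )

    pairs: list[DyadReciprocity] = []
    seen = set()
    for (g, r) in directed:
        pair = tuple(sorted((g, r)))
        if pair in seen or g == r:
            continue
        seen.add(pair)
        a, b = pair
        fwd = directed.get((a, b))
        rev = directed.get((b, a))
        reciprocated = fwd is not None and rev is not None
        first_give = first_return = latency = None
        if reciprocated:
            # first-give is the chronologically earlier direction
            d_ab, d_ba = fwd[0], rev[0]
            first_give, first_return = min(d_ab, d_ba), max(d_ab, d_ba)
            latency = float(first_return - first_give)
        sex_pair = _pair_label(
            tuple(meta.get(i, {}).get("sex", "unknown") for i in pair)
        )
        disp_pair = _pair_label(
            tuple(meta.get(i, {}).get("dispersal", "unknown") for i in pair)
        )
        pairs.append(
            DyadReciprocity(
                id_a=a,
                id_b=b,
                observable=obs_map.get(pair, reciprocated),
                reciprocated=reciprocated,
                first_give_day=first_give,
                first_return_day=first_return,
                latency_days=latency,
                sex_pair=sex_pair,
                dispersal_pair=disp_pair,
            )
        )

    recip = [p for p in pairs if p.reciprocated]
    summary = {
        "n_pairs_with_help": len(pairs),
        "n_observable": sum(p.observable for p in pairs),
        "n_reciprocated": len(recip),
        "mean_latency_days": float(np.mean([p.latency_days for p in recip])) if recip else None,
        "by_sex_pair": dict(pd.Series([p.sex_pair for p in recip]).value_counts()) if recip else {},
        "by_dispersal_pair": dict(pd.Series([p.dispersal_pair for p in recip]).value_counts())
        if recip
        else {},
    }
    return pairs, summary


def reciprocal_latency(pair: DyadReciprocity) -> float | None:
    """Days between the first help given and the first return help; None if
    the pair never reciprocated."""
    if not pair.reciprocated:
        return None
    return pair.latency_days


def pairs_to_frame(pairs: list[DyadReciprocity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.id_a, p.id_b, p.observable, p.reciprocated,
                p.first_give_day, p.first_return_day, p.latency_days,
                p.sex_pair, p.dispersal_pair,
            )
            for p in pairs
        ],
        columns=[
            "id_a", "id_b", "observable", "reciprocated",
            "first_give_day", "first_return_day", "latency_days",
            "sex_pair", "dispersal_pair",
        ],
    )


def tally_role_switches(
    roles: pd.DataFrame,
    individuals: pd.DataFrame | None = None,
    complete_lifetimes_only: bool = False,
) -> dict:
    """Per-lifetime breeder/helper switch counts and next-role transition tables.

    A *switch* is a change between breeder and helper states across the ordered
    sequence of seasons in which an individual held either role; seasons as
    non-breeder-non-helper are transparent for switch counting.  The next-role
    transition tables after failed and successful breeding attempts treat all
    three destinations (breeder, neither, helper) as outcomes, using each
    individual's next season with any recorded role.

    With ``complete_lifetimes_only`` individuals still present in the final
    recorded season are excluded (their lifetimes are right-censored).
    """
    max_season = int(roles["season"].max())
    switch_counts: dict = {}
    transitions = {"failure": {r: 0 for r in ("breeder", "helper", "neither")},
                   "success": {r: 0 for r in ("breeder", "helper", "neither")}}
    for ind, sub in roles.sort_values("season").groupby("individual"):
        if complete_lifetimes_only and int(sub["season"].max()) >= max_season:
            continue
        seq = sub["role"].tolist()
        active = [r for r in seq if r in ("breeder", "helper")]
        switches = sum(a != b for a, b in zip(active, active[1:]))
        switch_counts[ind] = switches
        outcomes = sub["attempt_outcome"].tolist() if "attempt_outcome" in sub else ["n/a"] * len(seq)
        for k in range(len(seq) - 1):
            if seq[k] == "breeder" and outcomes[k] in ("failure", "success"):
                transitions[outcomes[k]][seq[k + 1]] += 1

    counts = pd.Series(switch_counts, dtype=float)
    result = {
        "n_individuals": len(counts),
        "mean_switches": float(counts.mean()) if len(counts) else np.nan,
        "sem_switches": float(counts.sem()) if len(counts) > 1 else np.nan,
        "prop_switching_at_least_once": float((counts >= 1).mean()) if len(counts) else np.nan,
        "switch_counts": switch_counts,
        "transitions_after_failure": transitions["failure"],
        "transitions_after_success": transitions["success"],
    }
    if individuals is not None and len(counts):
        meta = individuals.set_index("id")
        by_type = {}
        for (sex, disp), ids in meta.groupby(["sex", "dispersal"]).groups.items():
            sel = counts.index.intersection(ids)
            if not len(sel):
                continue
            x = int((counts.loc[sel] >= 1).sum())
            n = len(sel)
            lo, hi = exact_binomial_ci(x, n)
            by_type[f"{sex}:{disp}"] = {
                "n": n, "switched": x, "proportion": x / n, "ci_lo": lo, "ci_hi": hi
            }
        result["by_sex_dispersal"] = by_type
    return result


def exact_binomial_ci(
    x: int, n: int, conf: float = 0.95, one_sided: bool = False
) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval for x successes of n.

    With ``one_sided`` the full error probability goes into one tail (an upper
    bound when x = 0, a lower bound when x = n).
    """
    if n < 1 or not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n and n >= 1")
    alpha = 1.0 - conf
    if one_sided:
        lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha, x, n - x + 1))
        hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha, x + 1, n - x))
        return lo, hi
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi
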