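"""Domain tables, CSV ingestion, presence inference and the dyad-day analysis table.

All tabular data are held as :class:`pandas.DataFrame` objects with fixed column
schemas (see the ``*_COLUMNS`` constants).  The central product is the
*analysis table*: one row per (possible helper, nest, day), where a zero row
exists only for non-helping group members that were present in the group that
breeding season.  Helping is measured in whole minutes against an exposure
(observation-time) denominator, so count models can use ``log(exposure)`` as an
offset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "unknown")
DISPERSALS = ("resident", "immigrant", "unknown")

INDIVIDUAL_COLUMNS = ["id", "sex", "dispersal", "group", "first_season", "last_season"]
NEST_COLUMNS = ["nest_id", "group", "season", "mother_id", "father_id"]
EXPOSURE_COLUMNS = ["nest_id", "day", "exposure_minutes"]
VISIT_COLUMNS = ["helper_id", "nest_id", "day", "help_minutes"]
ANALYSIS_COLUMNS = [
    "helper_id",
    "nest_id",
    "day",
    "help_minutes",
    "exposure_minutes",
    "kinship_r",
    "kinship_z",
    "reciprocal",
    "helper_sex",
    "helper_dispersal",
    "group",
    "season",
    "mother_id",
    "father_id",
    "cross_group",
]


class SchemaError(ValueError):
    """A CSV file does not conform to the documented column schema."""


class ReferentialError(ValueError):
    """A table references identifiers that do not exist in its companion tables."""


@dataclass
class HelpingLedger:
    """Raw per-visit help observations plus per nest-day observation exposure.

    ``visits`` has columns ``helper_id, nest_id, day, help_minutes`` with
    ``help_minutes >= 1`` (zeros are never stored as visits); ``exposure`` has
    columns ``nest_id, day, exposure_minutes`` with strictly positive minutes.
    """

    visits: pd.DataFrame
    exposure: pd.DataFrame

    def __post_init__(self) -> None:
        self.visits = self.visits[VISIT_COLUMNS].copy()
        self.exposure = self.exposure[EXPOSURE_COLUMNS].copy()
        if len(self.visits) and (self.visits["help_minutes"] < 1).any():
            raise ValueError("ledger visits must have help_minutes >= 1")
        if len(self.exposure) and (self.exposure["exposure_minutes"] <= 0).any():
            raise ValueError("exposure minutes must be strictly positive")

    @property
    def total_help_minutes(self) -> int:
        return int(self.visits["help_minutes"].sum())


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {missing}")


def score_help_minutes(attendance_seconds: float, provisioning_seconds: float) -> int:
    """Convert raw attendance + provisioning seconds to whole help minutes.

    Seconds are combined and rounded *up* to the nearest minute, so any
    strictly positive observation scores at least one minute of help (a visit
    of under 30 s counts as one minute rather than zero).
    """
    if attendance_seconds < 0 or provisioning_seconds < 0:
        raise ValueError("seconds of help must be nonnegative")
    total = attendance_seconds + provisioning_seconds
    return int(math.ceil(total / 60.0))


def load_ledger(
    observations_csv, nests_csv, individuals_csv, exposure_csv=None
) -> tuple[HelpingLedger, pd.DataFrame, pd.DataFrame]:
    """Load and cross-reference the observation, nest and individual tables.

    ``observations.csv`` may carry either a pre-scored ``help_minutes`` column
    or raw ``attendance_seconds``/``provisioning_seconds`` (scored through
    :func:`score_help_minutes`).  Exposure rows may live in a separate
    ``exposure.csv`` or be provided in the observations file.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ReferentialError
        if a visit references a nest absent from ``nests.csv``, naming the
        offending identifiers.
    """
    obs = pd.read_csv(observations_csv)
    nests = pd.read_csv(nests_csv)
    individuals = pd.read_csv(individuals_csv)

    _require_columns(nests, NEST_COLUMNS, "nests.csv")
    _require_columns(individuals, INDIVIDUAL_COLUMNS, "individuals.csv")

    if "help_minutes" in obs.columns:
        _require_columns(obs, VISIT_COLUMNS, "observations.csv")
        visits = obs[VISIT_COLUMNS].copy()
    else:
        _require_columns(
            obs,
            ["helper_id", "nest_id", "day", "attendance_seconds", "provisioning_seconds"],
            "observations.csv",
        )
        visits = obs[["helper_id", "nest_id", "day"]].copy()
        visits["help_minutes"] = [
            score_help_minutes(a, p)
            for a, p in zip(obs["attendance_seconds"], obs["provisioning_seconds"])
        ]
        visits = visits[visits["help_minutes"] >= 1]

    if exposure_csv is not None:
        exposure = pd.read_csv(exposure_csv)
        _require_columns(exposure, EXPOSURE_COLUMNS, "exposure.csv")
        exposure = exposure[EXPOSURE_COLUMNS]
    else:
        _require_columns(obs, EXPOSURE_COLUMNS, "observations.csv (exposure)")
        exposure = obs[EXPOSURE_COLUMNS].drop_duplicates()

    unknown_nests = sorted(set(visits["nest_id"]) - set(nests["nest_id"]))
    if unknown_nests:
        raise ReferentialError(
            f"visits reference unknown nest id(s): {unknown_nests}"
        )
    unknown_ids = sorted(set(visits["helper_id"]) - set(individuals["id"]))
    if unknown_ids:
        logger.warning("visits reference %d unknown helper id(s): %s",
                       len(unknown_ids), unknown_ids)

    bad_sex = set(individuals["sex"]) - set(SEXES)
    bad_disp = set(individuals["dispersal"]) - set(DISPERSALS)
    if bad_sex or bad_disp:
        raise SchemaError(
            f"invalid sex values {sorted(bad_sex)} / dispersal values {sorted(bad_disp)}"
        )
    if (individuals["first_season"] > individuals["last_season"]).any():
        raise SchemaError("individuals with first_season > last_season")
    same_parent = nests["mother_id"] == nests["father_id"]
    if same_parent.any():
        raise SchemaError(
            f"nests with identical mother and father: {nests.loc[same_parent, 'nest_id'].tolist()}"
        )

    return HelpingLedger(visits=visits, exposure=exposure), nests, individuals


def infer_presence(
    sightings: pd.DataFrame, death_gap: int = 5
) -> pd.DataFrame:
    """Infer per-season availability to help from per-individual sightings.

    An individual is assumed present in its group for every season between its
    first and last sighting.  A gap of ``death_gap`` or more seasons without a
    sighting truncates presence at the last sighting before the gap: the bird
    is assumed dead, and later isolated sightings are dropped as
    misidentifications.

    Parameters
    ----------
    sightings : DataFrame with columns ``individual, group, season``.
    death_gap : minimum number of absent seasons taken to imply death.

    Returns
    -------
    DataFrame with columns ``individual, group, season`` containing one row
    per present individual-season.
    """
    _require_columns(sightings, ["individual", "group", "season"], "sightings")
    rows: list[tuple] = []
    for (ind, grp), sub in sightings.groupby(["individual", "group"], sort=True):
        seasons = np.sort(sub["season"].unique())
        # truncate at the first gap of >= death_gap seasons
        end = seasons[0]
        for s in seasons[1:]:
            if s - end >= death_gap:
                break
            end = s
        for s in range(int(seasons[0]), int(end) + 1):
            rows.append((ind, grp, s))
    return pd.DataFrame(rows, columns=["individual", "group", "season"])


def presence_from_individuals(individuals: pd.DataFrame) -> pd.DataFrame:
    """Expand first/last season spans in an individuals table into a presence table."""
    rows = []
    for rec in individuals.itertuples(index=False):
        for s in range(int(rec.first_season), int(rec.last_season) + 1):
            rows.append((rec.id, rec.group, s))
    return pd.DataFrame(rows, columns=["individual", "group", "season"])


@dataclass
class BuildReport:
    """Exclusion tallies accumulated while building the analysis table."""

    dropped_zero_exposure: int = 0
    dropped_no_presence: int = 0
    empty_nest_days: int = 0
    cross_group_rows: int = 0
    missing_relatedness_pairs: int = 0
    notes: list[str] = field(default_factory=list)


def build_analysis_table(
    ledger: HelpingLedger,
    presence: pd.DataFrame,
    nests: pd.DataFrame,
    individuals: pd.DataFrame,
    relatedness=None,
    reciprocity_flags: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, BuildReport]:
    """Build the dyad-day analysis table with presence-based zero coding.

    For every observed nest-day, one row is produced per *possible helper*:
    each group member present that breeding season, excluding the nest's two
    breeders.  Possible helpers that were not seen helping get
    ``help_minutes = 0``; observed helpers keep their scored minutes.  Visitors
    from other groups are retained as observed rows (flagged ``cross_group``)
    but never zero-filled into groups they do not belong to.

    Parameters
    ----------
    relatedness : optional :class:`starhelp.kinship.RelatednessMatrix`; when
        given, ``kinship_r`` is the helper's relatedness to the closer of the
        nest's two parents and ``kinship_z`` its standardization over the
        whole table (models re-standardize on their fitting subset).
    reciprocity_flags : optional DataFrame ``helper_id, breeder_id, reciprocal``
        marking helper rows whose nest has a breeder that ever helped the
        focal helper (see :mod:`starhelp.recip`).

    Returns
    -------
    (table, report) where ``table`` has the columns in ``ANALYSIS_COLUMNS``
    and ``report`` tallies the exclusions applied.
    """
    report = BuildReport()
    nest_info = nests.set_index("nest_id")
    ind_info = individuals.set_index("id")
    presence_sets: dict[tuple, set] = {
        (grp, season): set(sub["individual"])
        for (grp, season), sub in presence.groupby(["group", "season"])
    }
    ind_group = individuals.set_index("id")["group"].to_dict()

    visits = (
        ledger.visits.groupby(["helper_id", "nest_id", "day"], as_index=False)[
            "help_minutes"
        ].sum()
    )
    visit_map: dict[tuple, int] = {
        (r.helper_id, r.nest_id, r.day): int(r.help_minutes)
        for r in visits.itertuples(index=False)
    }

    exposure = (
        ledger.exposure.groupby(["nest_id", "day"], as_index=False)[
            "exposure_minutes"
        ].sum()
    )

    rows: list[dict] = []
    for exp_row in exposure.itertuples(index=False):
        nest_id, day, expo = exp_row.nest_id, exp_row.day, exp_row.exposure_minutes
        if expo <= 0:
            report.dropped_zero_exposure += 1
            logger.warning("nest-day (%s, %s) has zero exposure; excluded", nest_id, day)
            continue
        nest = nest_info.loc[nest_id]
        group, season = nest["group"], int(nest["season"])
        breeders = {nest["mother_id"], nest["father_id"]}
        possible = presence_sets.get((group, season), set()) - breeders
        observed_here = {
            h for (h, n, d) in visit_map if n == nest_id and d == day
        }
        helpers = sorted(possible | observed_here, key=str)
        if not possible:
            report.empty_nest_days += 1
            logger.warning(
                "nest-day (%s, %s): no present non-breeders in group %s", nest_id, day, group
            )
        for h in helpers:
            if h in breeders:
                continue  # a breeder never helps its own nest
            minutes = visit_map.get((h, nest_id, day), 0)
            in_group = h in possible
            if not in_group:
                helper_group = ind_group.get(h)
                if helper_group is None or (
                    h not in presence_sets.get((helper_group, season), set())
                ):
                    # observed helper with no presence record anywhere this season
                    if minutes > 0:
                        report.dropped_no_presence += 1
                        logger.warning(
                            "helper %s at (%s, %s) has no presence record; excluded",
                            h, nest_id, day,
                        )
                    continue
                report.cross_group_rows += 1
            sex = ind_info["sex"].get(h, "unknown")
            dispersal = ind_info["dispersal"].get(h, "unknown")
            rows.append(
                dict(
                    helper_id=h,
                    nest_id=nest_id,
                    day=day,
                    help_minutes=minutes,
                    exposure_minutes=float(expo),
                    kinship_r=np.nan,
                    kinship_z=np.nan,
                    reciprocal=0,
                    helper_sex=sex,
                    helper_dispersal=dispersal,
                    group=group,
                    season=season,
                    mother_id=nest["mother_id"],
                    father_id=nest["father_id"],
                    cross_group=int(not in_group),
                )
            )

    table = pd.DataFrame(rows, columns=ANALYSIS_COLUMNS)
    if relatedness is not None:
        from .kinship import attach_kinship

        table, n_missing = attach_kinship(table, relatedness)
        report.missing_relatedness_pairs = n_missing
    if reciprocity_flags is not None and len(table):
        flagged = set(
            zip(reciprocity_flags["helper_id"], reciprocity_flags["breeder_id"])
        )
        recip = [
            int((h, m) in flagged or (h, f) in flagged)
            for h, m, f in zip(table["helper_id"], table["mother_id"], table["father_id"])
        ]
        table["reciprocal"] = recip
    return table, report


def offset_term(table: pd.DataFrame) -> np.ndarray:
    """The model offset: natural log of exposure minutes per row."""
    return np.log(table["exposure_minutes"].to_numpy(float))


def write_analysis_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_analysis_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _require_columns(table, ANALYSIS_COLUMNS, "analysis table")
    return table[ANALYSIS_COLUMNS]
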