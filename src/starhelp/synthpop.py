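"""Synthetic plural-cooperative-breeder populations with known ground truth.

The generator emulates the structure of a long-term field study of a plural
breeder: several social groups of 7-60 members followed over two breeding
seasons per year, each group holding up to seven concurrent breeding pairs,
with nests watched for roughly two-hour focal observations on a day or two per
nest.  Demography is agent-based (births recorded into a pedigree, immigration
of unrelated adults, per-season survival), per-season roles follow a
sex-by-dispersal Markov kernel over {breeder, helper, neither} with resident
females structurally barred from breeding, and helping minutes are drawn from
the same negative-binomial rate model the analyses fit:

    minutes ~ NB(mean mu, shape rho)
    log mu = log(exposure) + beta0 + beta_kin * z(kinship)
             + beta_recip * received_before + u_helper + u_nest + u_dyad

where ``received_before`` flags rows whose nest has a breeder that helped the
focal helper's own nest in an earlier season.  Receiving help thereby raises
the rate of returning it, which injects true reciprocal relationships whose
identity is recorded in the truth report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import HelpingLedger
from .kinship import RelatednessMatrix, pedigree_relatedness

__all__ = ["SimConfig", "SyntheticDataset", "simulate_population", "simulate_helping", "truth_report"]

ROLES = ("breeder", "helper", "neither")


def default_role_transition() -> dict:
    """Per sex-and-dispersal Markov kernels over {breeder, helper, neither}.

    Rows (previous role) map to probabilities over next roles.  Defaults give
    frequent bidirectional breeder/helper switching for males and immigrant
    females; resident females are handled by the structural breeding bar, so
    their kernel mass on "breeder" is redirected to "helper" at draw time.
    """
    common = {
        "breeder": {"breeder": 0.40, "helper": 0.28, "neither": 0.32},
        "helper": {"breeder": 0.22, "helper": 0.53, "neither": 0.25},
        "neither": {"breeder": 0.18, "helper": 0.42, "neither": 0.40},
    }
    return {
        ("male", "resident"): common,
        ("male", "immigrant"): common,
        ("female", "resident"): common,  # breeder mass redirected at draw time
        ("female", "immigrant"): common,
    }


@dataclass
class SimConfig:
    """Generating parameters; defaults are the study conditions being emulated."""

    n_groups: int = 9
    group_size_range: tuple = (7, 60)
    n_seasons: int = 40
    mean_helpers_per_nest: float = 5.0
    nests_per_group_season: tuple = (1, 7)
    # rate-model truth
    beta0: float = -7.0
    beta_kin: float = 0.6
    beta_recip: float = 1.0
    sd_helper: float = 0.5
    sd_nest: float = 0.5
    sd_dyad: float = 0.5
    nb_dispersion: float = 1.0
    role_transition: dict = field(default_factory=default_role_transition)
    p_resident_female_breeds: float = 0.0
    # demography
    founders_per_group: tuple = (12, 22)
    immigration_rate: float = 0.4
    survival: float = 0.93
    recruits_per_nest: float = 2.0
    p_nest_success: float = 0.65
    breeding_age: int = 2
    # observation process
    mean_observed_nests: float = 1.2
    mean_obs_days_per_nest: float = 1.8
    exposure_minutes_mean: float = 120.0
    exposure_minutes_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_resident_female_breeds <= 1):
            raise ValueError("p_resident_female_breeds must be a probability")
        if self.nests_per_group_season[0] < 1:
            raise ValueError("need at least one breeding pair per group-season")
        if self.group_size_range[0] > self.group_size_range[1]:
            raise ValueError("invalid group size range")
        for key, kernel in self.role_transition.items():
            for prev, row in kernel.items():
                total = sum(row.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"transition row {key}/{prev} sums to {total}")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["role_transition"] = {
            f"{sex}:{disp}": kernel for (sex, disp), kernel in self.role_transition.items()
        }
        return d


@dataclass
class SyntheticDataset:
    """A full simulated study: demography, roles, observation schedule, helping."""

    individuals: pd.DataFrame
    pedigree: pd.DataFrame
    nests: pd.DataFrame
    exposure: pd.DataFrame
    ledger: HelpingLedger
    roles: pd.DataFrame
    relatedness: RelatednessMatrix
    truth: dict
    config: SimConfig


class _Bird:
    __slots__ = ("id", "sex", "dispersal", "group", "birth_season", "mother", "father",
                 "first_season", "last_season", "alive", "role")

    def __init__(self, id, sex, dispersal, group, season, mother=None, father=None):
        self.id = id
        self.sex = sex
        self.dispersal = dispersal
        self.group = group
        self.birth_season = season
        self.mother = mother
        self.father = father
        self.first_season = season
        self.last_season = season
        self.alive = True
        self.role = "neither"


def simulate_population(config: SimConfig | None = None) -> SyntheticDataset:
    """Simulate demography, roles, nest observation and helping for all seasons.

    Fully reproducible from ``config.seed``: the same configuration yields a
    byte-identical dataset.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    size_cap = config.group_size_range[1]
    max_pairs = config.nests_per_group_season[1]

    birds: dict[str, _Bird] = {}
    groups: dict[str, list[str]] = {}
    counter = [0]

    def new_bird(sex, dispersal, group, season, mother=None, father=None):
        counter[0] += 1
        b = _Bird(f"I{counter[0]:05d}", sex, dispersal, group, season, mother, father)
        birds[b.id] = b
        groups[group].append(b.id)
        return b

    # founders: unrelated immigrant adults of breeding age
    for g in range(config.n_groups):
        gid = f"G{g + 1}"
        groups[gid] = []
        n0 = int(rng.integers(config.founders_per_group[0], config.founders_per_group[1] + 1))
        for _ in range(n0):
            sex = "male" if rng.random() < 0.5 else "female"
            b = new_bird(sex, "immigrant", gid, season=1)
            b.birth_season = 1 - config.breeding_age  # founders start mature

    role_rows: list[tuple] = []
    nest_rows: list[tuple] = []
    exposure_rows: list[tuple] = []
    nest_counter = [0]
    season_length_days = 183  # two seasons per year

    for t in range(1, config.n_seasons + 1):
        for gid, members in groups.items():
            alive = [birds[i] for i in members if birds[i].alive]

            # immigration of unrelated adults
            if len(alive) < size_cap:
                for _ in range(rng.poisson(config.immigration_rate)):
                    sex = "male" if rng.random() < 0.5 else "female"
                    b = new_bird(sex, "immigrant", gid, season=t)
                    b.birth_season = t - config.breeding_age
                    alive.append(b)

            # per-season roles from the sex x dispersal kernel
            aspiring_m, aspiring_f = [], []
            for b in alive:
                age = t - b.birth_season
                if age < 1:
                    continue  # nestlings of this season do not hold a role yet
                key = (b.sex, b.dispersal)
                kernel = config.role_transition[key]
                probs = kernel[b.role]
                draw = rng.choice(ROLES, p=[probs[r] for r in ROLES])
                if age < config.breeding_age and draw == "breeder":
                    draw = "helper"
                if (
                    b.sex == "female"
                    and b.dispersal == "resident"
                    and draw == "breeder"
                    and rng.random() >= config.p_resident_female_breeds
                ):
                    draw = "helper"
                b.role = draw
                if draw == "breeder":
                    (aspiring_m if b.sex == "male" else aspiring_f).append(b)

            # form breeding pairs; unmatched aspirants revert to helping
            rng.shuffle(aspiring_m)
            rng.shuffle(aspiring_f)
            n_pairs = min(len(aspiring_m), len(aspiring_f), max_pairs)
            pairs = list(zip(aspiring_m[:n_pairs], aspiring_f[:n_pairs]))
            for b in aspiring_m[n_pairs:] + aspiring_f[n_pairs:]:
                b.role = "helper"

            # nests, observation schedule, recruitment
            observed = set()
            if pairs:
                n_obs = min(len(pairs), rng.poisson(config.mean_observed_nests))
                observed = set(rng.choice(len(pairs), size=n_obs, replace=False)) if n_obs else set()
            for k, (male, female) in enumerate(pairs):
                nest_counter[0] += 1
                nest_id = f"N{nest_counter[0]:05d}"
                success = bool(rng.random() < config.p_nest_success)
                nest_rows.append((nest_id, gid, t, female.id, male.id, success, k in observed))
                if k in observed:
                    n_days = 1 + rng.poisson(config.mean_obs_days_per_nest - 1.0)
                    day_offsets = np.sort(
                        rng.choice(np.arange(20, 110), size=n_days, replace=False)
                    )
                    for off in day_offsets:
                        day = (t - 1) * season_length_days + int(off)
                        expo = float(
                            np.clip(
                                rng.normal(config.exposure_minutes_mean, config.exposure_minutes_sd),
                                30.0,
                                240.0,
                            )
                        )
                        exposure_rows.append((nest_id, day, round(expo, 1)))
                if success and len(alive) < size_cap:
                    for _ in range(rng.poisson(config.recruits_per_nest)):
                        sex = "male" if rng.random() < 0.5 else "female"
                        new_bird(sex, "resident", gid, season=t, mother=female.id, father=male.id)

            # record roles and survival
            for b in alive:
                age = t - b.birth_season
                if age >= 1:
                    role_rows.append((b.id, gid, t, b.role))
                b.last_season = t
                if rng.random() > config.survival:
                    b.alive = False
            for i in members:
                b = birds[i]
                if b.birth_season == t and b.alive:
                    b.last_season = t
                    if rng.random() > config.survival:
                        b.alive = False

    # residents enter the possible-helper pool the season after hatching
    ind_rows = []
    for b in birds.values():
        fs = b.birth_season + 1 if b.dispersal == "resident" else max(b.first_season, 1)
        if b.last_season >= fs:
            ind_rows.append((b.id, b.sex, b.dispersal, b.group, fs, b.last_season))
    individuals = pd.DataFrame(
        ind_rows,
        columns=["id", "sex", "dispersal", "group", "first_season", "last_season"],
    ).sort_values("id", ignore_index=True)
    pedigree = pd.DataFrame(
        [(b.id, b.father or "", b.mother or "") for b in birds.values()],
        columns=["id", "sire_id", "dam_id"],
    ).sort_values("id", ignore_index=True)
    nests = pd.DataFrame(
        nest_rows,
        columns=["nest_id", "group", "season", "mother_id", "father_id", "success", "observed"],
    )
    exposure = pd.DataFrame(exposure_rows, columns=["nest_id", "day", "exposure_minutes"])
    roles = pd.DataFrame(role_rows, columns=["individual", "group", "season", "role"])
    succ_map = {}
    for r in nests.itertuples(index=False):
        succ_map[(r.mother_id, r.season)] = "success" if r.success else "failure"
        succ_map[(r.father_id, r.season)] = "success" if r.success else "failure"
    roles["attempt_outcome"] = [
        succ_map.get((i, s), "n/a") if role == "breeder" else "n/a"
        for i, s, role in zip(roles["individual"], roles["season"], roles["role"])
    ]

    relatedness = pedigree_relatedness(pedigree)

    dataset = SyntheticDataset(
        individuals=individuals,
        pedigree=pedigree,
        nests=nests,
        exposure=exposure,
        ledger=HelpingLedger(
            visits=pd.DataFrame(columns=["helper_id", "nest_id", "day", "help_minutes"]),
            exposure=exposure,
        ),
        roles=roles,
        relatedness=relatedness,
        truth={},
        config=config,
    )
    helping_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    dataset.ledger = simulate_helping(dataset, config, rng=helping_rng)
    dataset.truth = truth_report(dataset)
    return dataset


def simulate_helping(dataset: SyntheticDataset, config: SimConfig, rng=None) -> HelpingLedger:
    """Draw helping minutes for every possible helper on every observed nest-day.

    Rows are processed season by season so the reciprocity flag for a row can
    only depend on help drawn in strictly earlier seasons.  Zero draws are kept
    implicit: only visits with at least one minute enter the ledger.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if (dataset.exposure["exposure_minutes"] <= 0).any():
        raise ValueError("nonpositive exposure in observation schedule")

    individuals = dataset.individuals
    R = dataset.relatedness
    present: dict[tuple, list] = {}
    for rec in individuals.itertuples(index=False):
        for s in range(int(rec.first_season), int(rec.last_season) + 1):
            present.setdefault((rec.group, s), []).append(rec.id)

    nest_info = dataset.nests.set_index("nest_id")
    # enumerate candidate rows in chronological order
    rows = []
    for e in dataset.exposure.sort_values(["day", "nest_id"]).itertuples(index=False):
        nest = nest_info.loc[e.nest_id]
        season = int(nest["season"])
        mother, father = nest["mother_id"], nest["father_id"]
        for h in present.get((nest["group"], season), []):
            if h in (mother, father):
                continue
            r_max = max(R.get(h, mother, 0.0), R.get(h, father, 0.0))
            rows.append((season, e.day, e.nest_id, h, mother, father, e.exposure_minutes, r_max))
    if not rows:
        return HelpingLedger(
            visits=pd.DataFrame(columns=["helper_id", "nest_id", "day", "help_minutes"]),
            exposure=dataset.exposure,
        )

    r_values = np.array([r[-1] for r in rows])
    sd = r_values.std(ddof=1)
    z_values = (r_values - r_values.mean()) / sd if sd > 0 else np.zeros_like(r_values)

    u_helper: dict = {}
    u_nest: dict = {}
    u_dyad: dict = {}

    def re_draw(store, key, sdv):
        if key not in store:
            store[key] = rng.normal(0.0, sdv) if sdv > 0 else 0.0
        return store[key]

    helped_first_season: dict[tuple, int] = {}  # (giver, breeder) -> first season
    rho = config.nb_dispersion
    visits = []
    for (season, day, nest_id, h, mother, father, expo, _), z in zip(rows, z_values):
        received = int(
            helped_first_season.get((mother, h), 10**9) < season
            or helped_first_season.get((father, h), 10**9) < season
        )
        eta = (
            np.log(expo)
            + config.beta0
            + config.beta_kin * z
            + config.beta_recip * received
            + re_draw(u_helper, h, config.sd_helper)
            + re_draw(u_nest, nest_id, config.sd_nest)
            + re_draw(u_dyad, (h, mother, father), config.sd_dyad)
        )
        mu = np.exp(eta)
        y = int(rng.negative_binomial(rho, rho / (rho + mu)))
        if y >= 1:
            y = min(y, int(expo))  # cannot help longer than the nest was watched
            visits.append((h, nest_id, day, y))
            for breeder in (mother, father):
                key = (h, breeder)
                if key not in helped_first_season or season < helped_first_season[key]:
                    helped_first_season[key] = season

    visits_df = pd.DataFrame(visits, columns=["helper_id", "nest_id", "day", "help_minutes"])
    return HelpingLedger(visits=visits_df, exposure=dataset.exposure)


def _ledger_checksum(dataset: SyntheticDataset) -> str:
    payload = dataset.ledger.visits.to_csv(index=False) + dataset.exposure.to_csv(index=False)
    return hashlib.sha256(payload.encode()).hexdigest()


def truth_report(dataset: SyntheticDataset) -> dict:
    """All generating parameters plus derived ground truths.

    Derived truths come from a brute-force scan of the simulated record:
    directed first-help seasons per (giver, breeder) pair, the set of true
    reciprocal pairs (help observed in both directions), and true kin pairs at
    the conventional r > 0.125 cut.  A checksum over the ledger lets callers
    detect external mutation.
    """
    if dataset.truth and dataset.truth.get("checksum") != _ledger_checksum(dataset):
        raise ValueError("dataset ledger was mutated after simulation (checksum mismatch)")

    nest_info = dataset.nests.set_index("nest_id")
    first_help: dict[tuple, int] = {}
    for v in dataset.ledger.visits.itertuples(index=False):
        nest = nest_info.loc[v.nest_id]
        season = int(nest["season"])
        for breeder in (nest["mother_id"], nest["father_id"]):
            key = (v.helper_id, breeder)
            if key not in first_help or season < first_help[key]:
                first_help[key] = season

    reciprocal_pairs = sorted(
        {tuple(sorted((a, b))) for (a, b) in first_help if (b, a) in first_help and a != b}
    )
    R = dataset.relatedness
    kin_pairs = []
    ids = R.ids
    iu, ju = np.triu_indices(len(ids), k=1)
    kin_mask = R.values[iu, ju] > 0.125
    kin_pairs = [(ids[i], ids[j]) for i, j in zip(iu[kin_mask], ju[kin_mask])]

    return {
        "config": dataset.config.to_jsonable(),
        "beta0": dataset.config.beta0,
        "beta_kin": dataset.config.beta_kin,
        "beta_recip": dataset.config.beta_recip,
        "sd_helper": dataset.config.sd_helper,
        "sd_nest": dataset.config.sd_nest,
        "sd_dyad": dataset.config.sd_dyad,
        "nb_dispersion": dataset.config.nb_dispersion,
        "first_help_seasons": {f"{a}->{b}": s for (a, b), s in sorted(first_help.items())},
        "reciprocal_pairs": [list(p) for p in reciprocal_pairs],
        "n_kin_pairs": len(kin_pairs),
        "checksum": _ledger_checksum(dataset),
    }


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write the CSV bundle plus truth.json; returns path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    tables = {
        "individuals.csv": dataset.individuals,
        "pedigree.csv": dataset.pedigree,
        "nests.csv": dataset.nests,
        "exposure.csv": dataset.exposure,
        "observations.csv": dataset.ledger.visits,
        "roles.csv": dataset.roles,
        "relatedness.csv": dataset.relatedness.to_frame(),
    }
    for name, df in tables.items():
        p = os.path.join(outdir, name)
        df.to_csv(p, index=False)
        paths[name] = p
    tp = os.path.join(outdir, "truth.json")
    with open(tp, "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
    paths["truth.json"] = tp
    return paths
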