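"""Stage orchestration: seeds, configuration, manifests and reproducible runs.

A run is described by a :class:`RunConfig` (YAML-serializable).  One master
seed derives an independent substream per stage through
``numpy.random.SeedSequence`` spawning, so any stage can be rerun in isolation
with an identical stream.  Every file written is listed in ``manifest.json``
with a SHA-256 content hash, and the configuration is echoed verbatim so a run
can be replayed exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import datamodel, kinchoice, permnet, powerscan, ratemodel, recip, synthpop
from .kinship import load_relatedness_csv, load_pedigree, pedigree_relatedness

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "build", "fit", "choice", "recip", "permtest", "power")


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # inputs: either a directory of CSVs or a simulation config
    input_dir: str | None = None
    sim: dict = field(default_factory=dict)
    # analysis settings
    n_perm: int = 5000
    n_boot: int = 10_000
    chains: int = 4
    iterations: int = 5000
    warmup: int = 1000
    kin_threshold: float = permnet.DEFAULT_NONKIN_THRESHOLD
    reciprocal_mode: str = "atemporal"
    power_max_seasons: int | None = None
    power_season_step: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        k = ALL_STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(ALL_STAGES))[k]
        return int(child.generate_state(1)[0] % (2**31))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Mutable run state shared across stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outputs: list[str] = []
        self.dataset = None
        self.table = None
        self.ledger = None
        self.nests = None
        self.individuals = None
        self.relatedness = None

    def write_df(self, df: pd.DataFrame, name: str) -> str:
        path = os.path.join(self.config.outdir, name)
        df.to_csv(path, index=False)
        self.outputs.append(path)
        return path

    def write_json(self, obj, name: str) -> str:
        path = os.path.join(self.config.outdir, name)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=_jsonify)
        self.outputs.append(path)
        return path


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    return str(x)


def stage_simulate(run: PipelineRun) -> None:
    cfg = synthpop.SimConfig(seed=run.config.stage_seed("simulate"), **run.config.sim)
    dataset = synthpop.simulate_population(cfg)
    run.dataset = dataset
    run.ledger = dataset.ledger
    run.nests = dataset.nests
    run.individuals = dataset.individuals
    run.relatedness = dataset.relatedness
    simdir = os.path.join(run.config.outdir, "simulated")
    paths = synthpop.write_dataset(dataset, simdir)
    run.outputs.extend(paths.values())


def stage_build(run: PipelineRun) -> None:
    cfg = run.config
    if run.ledger is None:
        if cfg.input_dir is None:
            raise ValueError("build stage needs simulated data or an input_dir")
        d = cfg.input_dir
        ledger, nests, individuals = datamodel.load_ledger(
            os.path.join(d, "observations.csv"),
            os.path.join(d, "nests.csv"),
            os.path.join(d, "individuals.csv"),
            exposure_csv=os.path.join(d, "exposure.csv"),
        )
        run.ledger, run.nests, run.individuals = ledger, nests, individuals
        ped_path = os.path.join(d, "pedigree.csv")
        rel_path = os.path.join(d, "relatedness.csv")
        if os.path.exists(ped_path):
            run.relatedness = pedigree_relatedness(load_pedigree(ped_path))
        elif os.path.exists(rel_path):
            run.relatedness = load_relatedness_csv(rel_path)
    presence = datamodel.presence_from_individuals(run.individuals)
    table, report = datamodel.build_analysis_table(
        run.ledger, presence, run.nests, run.individuals, relatedness=run.relatedness
    )
    table = recip.attach_reciprocal(
        table, run.ledger, run.nests, mode=cfg.reciprocal_mode
    )
    run.table = table
    run.write_df(table, "analysis_table.csv")
    run.write_json(asdict(report) if hasattr(report, "__dataclass_fields__") else vars(report),
                   "build_report.json")


def stage_fit(run: PipelineRun) -> None:
    cfg = run.config
    results = ratemodel.run_model_suite(
        run.table,
        subsets=[None],
        chains=cfg.chains,
        iterations=cfg.iterations,
        warmup=cfg.warmup,
        seed=cfg.stage_seed("fit"),
    )
    run.write_df(ratemodel.suite_coefficient_table(results), "model_coefficients.csv")
    run.write_json([r.to_jsonable() for r in results], "model_fits.json")


def stage_choice(run: PipelineRun) -> None:
    cfg = run.config
    estimates = kinchoice.threshold_sweep(
        run.table, B=cfg.n_boot, seed=cfg.stage_seed("choice")
    )
    run.write_df(kinchoice.sweep_to_frame(estimates), "kin_bias_sweep.csv")
    run.write_json(
        kinchoice.nonkin_choice_by_type(run.table, threshold=0.1),
        "nonkin_choice_probability.json",
    )


def stage_recip(run: PipelineRun) -> None:
    presence = datamodel.presence_from_individuals(run.individuals)
    observable = recip.reciprocity_possible(
        run.ledger, run.nests, roles=None, presence=presence
    )
    pairs, summary = recip.detect_reciprocal_pairs(
        run.ledger, run.nests, run.individuals, observable=observable
    )
    run.write_df(recip.pairs_to_frame(pairs), "reciprocity.csv")
    roles = getattr(run.dataset, "roles", None) if run.dataset is not None else None
    if roles is not None:
        summary["role_switches"] = {
            k: v
            for k, v in recip.tally_role_switches(
                roles, run.individuals, complete_lifetimes_only=True
            ).items()
            if k != "switch_counts"
        }
    run.write_json(summary, "reciprocity_summary.json")


def stage_permtest(run: PipelineRun) -> None:
    cfg = run.config
    res = permnet.permute_nonkin_help(
        run.table,
        n_perm=cfg.n_perm,
        seed=cfg.stage_seed("permtest"),
        kin_threshold=cfg.kin_threshold,
    )
    dp = permnet.double_permutation_pipeline(
        run.table,
        run.relatedness,
        n_perm_adjust=cfg.n_perm,
        n_perm_test=cfg.n_perm,
        n_boot=cfg.n_boot,
        seed=cfg.stage_seed("permtest") + 1,
    )
    run.write_json(
        {
            "cv_observed": res.observed,
            "cv_p": res.p,
            "cv_null_quantiles": res.null_quantiles,
            "n_permutations": res.n_permutations,
            "double_permutation": {
                k: v for k, v in dp.items() if k != "mrqap"
            },
            "mrqap": dp.get("mrqap"),
        },
        "permutation_tests.json",
    )


def stage_power(run: PipelineRun) -> None:
    cfg = run.config
    max_s = cfg.power_max_seasons or int(run.table["season"].max())
    grid = list(range(1, max_s + 1, cfg.power_season_step))
    series = []
    for effect in ("kinship", "reciprocal"):
        series.append(
            powerscan.cumulative_estimates(
                run.table,
                effect,
                max_seasons=max_s,
                ledger=run.ledger,
                nests=run.nests,
                season_grid=grid,
                chains=2,
                iterations=1100,
                warmup=350,
                seed=cfg.stage_seed("power"),
                reciprocal_mode=cfg.reciprocal_mode,
            )
        )
    out = pd.concat(series, ignore_index=True)
    run.write_df(out, "power_series.csv")
    fig_path = os.path.join(cfg.outdir, "power_series.png")
    powerscan.plot_power_series(series, path=fig_path)
    run.outputs.append(fig_path)
    detections = {
        s["effect"].iloc[0]: powerscan.detection_season(s) for s in series
    }
    run.write_json(detections, "detection_seasons.json")


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "build": stage_build,
    "fit": stage_fit,
    "choice": stage_choice,
    "recip": stage_recip,
    "permtest": stage_permtest,
    "power": stage_power,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; returns the manifest.

    A stage failure aborts the run with the stage name while keeping outputs
    of completed stages on disk.
    """
    if config.input_dir is not None and not os.path.isdir(config.input_dir):
        raise FileNotFoundError(f"input_dir does not exist: {config.input_dir}")
    os.makedirs(config.outdir, exist_ok=True)
    run = PipelineRun(config)
    stages = [s for s in ALL_STAGES if s in config.stages]
    needs_table = any(s in stages for s in ("fit", "choice", "recip", "permtest", "power"))
    if needs_table and "build" not in stages:
        stages = ["build"] + stages
    if "build" in stages and config.input_dir is None and "simulate" not in stages:
        stages = ["simulate"] + stages
    stages = [s for s in ALL_STAGES if s in stages]

    for stage in stages:
        logger.info("pipeline stage: %s", stage)
        try:
            STAGE_FUNCS[stage](run)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        if run.table is not None and stage == "build":
            logger.info("analysis table: %d rows", len(run.table))

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "stages": stages,
        "outputs": {os.path.relpath(p, config.outdir): _sha256(p) for p in run.outputs},
    }
    path = os.path.join(config.outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=_jsonify)
    return manifest
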