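"""Bayesian negative-binomial multilevel helping-rate models.

The response is minutes of help per possible-helper per nest per day; the
offset is log observation minutes; helper, nest and helper-breeder-pair
identities are always random intercepts.  Fixed effects are drawn from
{kinship_z, reciprocal, their interaction, standardized total/mean help
received}; covariates are standardized on the fitting subset, so coefficients
are per-model standardized regression coefficients.  Posterior summaries are
means with equal-tailed 95% credible intervals; every fit carries R-hat and
bulk/tail effective-sample-size diagnostics and refuses summarization when
R-hat exceeds the threshold (unless explicitly fitted in non-strict mode, as
the power scan does).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .kinship import standardize_kinship
from .nbglmm import NBGLMMPriors, PosteriorDraws, sample_nbglmm

logger = logging.getLogger(__name__)

FIXED_EFFECTS = (
    "kinship_z",
    "reciprocal",
    "kinship_z:reciprocal",
    "total_received_z",
    "mean_received_z",
)

RESIDENT_FEMALE = ("female", "resident")


class ConvergenceError(RuntimeError):
    """Potential-scale-reduction exceeded the acceptable threshold."""


@dataclass
class ModelSpec:
    """Specification of one helping-rate model.

    ``subset`` is None for all helpers or a (sex, dispersal) pair; rows with
    unknown sex/dispersal enter only the all-helpers analyses.  Models with a
    reciprocal term always exclude resident females, who can never reciprocate.
    """

    fixed_effects: tuple = ("kinship_z",)
    subset: tuple | None = None
    reciprocal_mode: str = "atemporal"
    name: str = ""
    # None = automatic: exclude resident females whenever a reciprocal term is
    # present (they can never reciprocate).  Recovery studies against a
    # generator truth expressed in whole-table standardized units set False.
    exclude_resident_females: bool | None = None

    def __post_init__(self) -> None:
        unknown = [f for f in self.fixed_effects if f not in FIXED_EFFECTS]
        if unknown:
            raise ValueError(f"unknown fixed effect(s): {unknown}")
        if not self.name:
            self.name = "+".join(self.fixed_effects) or "intercept-only"

    @property
    def has_reciprocal(self) -> bool:
        return any("reciprocal" in f or f == "reciprocal" for f in self.fixed_effects)


@dataclass
class ModelFitResult:
    """Posterior summary of one fitted model."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index: effect; columns: mean, ci_lo, ci_hi, rhat, ess_bulk, ess_tail
    diagnostics: dict
    priors: dict
    seed: int
    n_rows: int
    converged: bool
    draws: PosteriorDraws
    notes: list[str] = field(default_factory=list)

    def coefficient(self, effect: str) -> dict:
        row = self.coefficients.loc[effect]
        return {"mean": row["mean"], "ci_lo": row["ci_lo"], "ci_hi": row["ci_hi"]}

    def to_jsonable(self) -> dict:
        return {
            "model": self.spec.name,
            "subset": list(self.spec.subset) if self.spec.subset else "all",
            "n_rows": self.n_rows,
            "coefficients": self.coefficients.reset_index().to_dict(orient="records"),
            "diagnostics": self.diagnostics,
            "priors": self.priors,
            "seed": self.seed,
            "converged": self.converged,
            "notes": self.notes,
        }


def irr(coefficient: float) -> float:
    """Incidence rate ratio for a log-link coefficient, to 3 decimals."""
    return round(float(np.exp(coefficient)), 3)


def subset_table(table: pd.DataFrame, subset: tuple | None) -> pd.DataFrame:
    if subset is None:
        return table
    sex, dispersal = subset
    out = table[(table["helper_sex"] == sex) & (table["helper_dispersal"] == dispersal)]
    return out


def help_received_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-helper total and mean rate of help received at their own nests.

    For a focal individual, each possible partner's directed rate is the
    partner's summed help minutes at the focal's breeding nests divided by the
    summed observation minutes of those nest-days.  ``total_received_rate``
    sums the rates over partners; ``mean_received_rate`` divides the total by
    the number of possible partners (group members with at least one
    possible-helper row at the focal's nests).  Individuals never observed
    breeding get (0, 0) by convention.
    """
    received: dict = {}
    for parent_col in ("mother_id", "father_id"):
        grp = table.groupby([parent_col, "helper_id"]).agg(
            help=("help_minutes", "sum"), expo=("exposure_minutes", "sum")
        )
        for (focal, partner), row in grp.iterrows():
            received.setdefault(focal, {}).setdefault(partner, [0.0, 0.0])
            received[focal][partner][0] += row["help"]
            received[focal][partner][1] += row["expo"]

    rows = []
    for helper in table["helper_id"].unique():
        partners = received.get(helper)
        if not partners:
            rows.append((helper, 0.0, 0.0, 0))
            continue
        rates = [h / e for h, e in partners.values() if e > 0]
        total = float(np.sum(rates))
        n_possible = len(partners)
        rows.append((helper, total, total / n_possible, n_possible))
    out = pd.DataFrame(
        rows, columns=["helper_id", "total_received_rate", "mean_received_rate", "n_partners"]
    )
    never = (out["n_partners"] == 0).sum()
    if never:
        logger.info("help_received_covariates: %d individuals never bred; rates set to 0", never)
    return out


def _design(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["intercept"]
    need_received = any(f in spec.fixed_effects for f in ("total_received_z", "mean_received_z"))
    if need_received:
        recv = help_received_covariates(table).set_index("helper_id")
        total = table["helper_id"].map(recv["total_received_rate"]).to_numpy(float)
        mean = table["helper_id"].map(recv["mean_received_rate"]).to_numpy(float)
    for f in spec.fixed_effects:
        if f == "kinship_z":
            cols.append(standardize_kinship(table["kinship_r"].to_numpy(float)))
        elif f == "reciprocal":
            cols.append(table["reciprocal"].to_numpy(float))
        elif f == "kinship_z:reciprocal":
            z = standardize_kinship(table["kinship_r"].to_numpy(float))
            cols.append(z * table["reciprocal"].to_numpy(float))
        elif f == "total_received_z":
            cols.append(standardize_kinship(total))
        elif f == "mean_received_z":
            cols.append(standardize_kinship(mean))
        names.append(f)
    return np.column_stack(cols), names


def fit_rate_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int = 1000,
    seed: int = 0,
    priors: NBGLMMPriors | None = None,
    rhat_threshold: float = 1.01,
    strict: bool = True,
) -> ModelFitResult:
    """Fit one NB multilevel helping-rate model by MCMC.

    ``iterations`` counts total iterations per chain including ``warmup``
    discarded ones.  Raises :class:`ConvergenceError` when any fixed effect's
    potential-scale-reduction exceeds ``rhat_threshold`` and ``strict`` is on.
    """
    data = subset_table(table, spec.subset)
    exclude_rf = (
        spec.exclude_resident_females
        if spec.exclude_resident_females is not None
        else spec.has_reciprocal
    )
    if spec.has_reciprocal and spec.subset == RESIDENT_FEMALE:
        raise ValueError(
            "reciprocal models cannot be fitted to resident females: "
            "they never breed and so can never reciprocate"
        )
    if exclude_rf:
        rf = (data["helper_sex"] == RESIDENT_FEMALE[0]) & (
            data["helper_dispersal"] == RESIDENT_FEMALE[1]
        )
        if rf.any():
            data = data[~rf]
    if not len(data):
        raise ValueError(f"no rows after subset filter {spec.subset!r}")
    y = data["help_minutes"].to_numpy(float)
    if not (y > 0).any():
        raise ValueError("all-zero response after subsetting; model cannot be fitted")

    X, names = _design(data, spec)
    offset = np.log(data["exposure_minutes"].to_numpy(float))
    factors = {
        "helper": pd.factorize(data["helper_id"])[0],
        "nest": pd.factorize(data["nest_id"])[0],
        "dyad": pd.factorize(
            data["helper_id"].astype(str)
            + "|"
            + data["mother_id"].astype(str)
            + "|"
            + data["father_id"].astype(str)
        )[0],
    }
    priors = priors or NBGLMMPriors()
    draws = sample_nbglmm(
        y,
        X,
        offset,
        factors,
        chains=chains,
        draws=iterations - warmup,
        warmup=warmup,
        seed=seed,
        priors=priors,
        beta_names=names,
    )
    idata = az.from_dict(draws.to_arviz_dict())
    rhat = az.rhat(idata)
    ess_bulk = az.ess(idata, method="bulk")
    ess_tail = az.ess(idata, method="tail")

    rows = []
    for k, name in enumerate(names):
        samples = draws.beta[:, :, k].ravel()
        rows.append(
            dict(
                effect=name,
                mean=float(samples.mean()),
                ci_lo=float(np.quantile(samples, 0.025)),
                ci_hi=float(np.quantile(samples, 0.975)),
                rhat=float(rhat[f"b_{name}"]),
                ess_bulk=float(ess_bulk[f"b_{name}"]),
                ess_tail=float(ess_tail[f"b_{name}"]),
            )
        )
    coef = pd.DataFrame(rows).set_index("effect")
    max_rhat = float(coef["rhat"].max())
    converged = bool(max_rhat <= rhat_threshold)
    diagnostics = {
        "max_rhat_fixed": max_rhat,
        "min_ess_bulk": float(coef["ess_bulk"].min()),
        "min_ess_tail": float(coef["ess_tail"].min()),
        "accept_rates": draws.accept_rates,
        "chains": chains,
        "iterations": iterations,
        "warmup": warmup,
    }
    if strict and not converged:
        raise ConvergenceError(
            f"model {spec.name!r}: max fixed-effect R-hat {max_rhat:.4f} exceeds "
            f"{rhat_threshold}; increase iterations"
        )
    notes = []
    if "kinship_z" in spec.fixed_effects and spec.has_reciprocal:
        notes.append(
            "kinship coefficient from a joint kinship+reciprocal model; not "
            "comparable to kinship-only coefficients (different subsample and "
            "confounded pathways)"
        )
    return ModelFitResult(
        spec=spec,
        coefficients=coef,
        diagnostics=diagnostics,
        priors=priors.describe(),
        seed=seed,
        n_rows=len(data),
        converged=converged,
        draws=draws,
        notes=notes,
    )


SUITE_MODELS = (
    ("kinship", ("kinship_z",)),
    ("reciprocal", ("reciprocal",)),
    ("kinship+reciprocal", ("kinship_z", "reciprocal")),
    ("kinship_x_reciprocal", ("kinship_z", "reciprocal", "kinship_z:reciprocal")),
    ("reciprocal+total_received", ("reciprocal", "total_received_z")),
    ("reciprocal+mean_received", ("reciprocal", "mean_received_z")),
)


def run_model_suite(
    table: pd.DataFrame,
    subsets: list | None = None,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int = 1000,
    seed: int = 0,
    models: tuple = SUITE_MODELS,
    strict: bool = True,
) -> list[ModelFitResult]:
    """Fit the full model suite per subset; returns the collected results.

    Reciprocal models on the resident-female subset are skipped with a logged
    reason (resident females never breed, so reciprocation is impossible for
    them).  The coefficient table across results mirrors a per-model,
    per-subset summary of standardized coefficients with 95% CrIs.
    """
    subsets = subsets if subsets is not None else [None]
    results = []
    fit_seed = seed
    for subset in subsets:
        for name, effects in models:
            spec = ModelSpec(fixed_effects=effects, subset=subset, name=name)
            if spec.has_reciprocal and subset == RESIDENT_FEMALE:
                logger.info(
                    "skipping %s for resident females: reciprocation impossible", name
                )
                continue
            fit_seed += 1
            results.append(
                fit_rate_model(
                    table, spec, chains=chains, iterations=iterations,
                    warmup=warmup, seed=fit_seed, strict=strict,
                )
            )
    return results


def suite_coefficient_table(results: list[ModelFitResult]) -> pd.DataFrame:
    """Long-format coefficient table over a collection of fits."""
    rows = []
    for res in results:
        for effect, row in res.coefficients.iterrows():
            rows.append(
                dict(
                    model=res.spec.name,
                    subset="all" if res.spec.subset is None else ":".join(res.spec.subset),
                    effect=effect,
                    mean=row["mean"],
                    ci_lo=row["ci_lo"],
                    ci_hi=row["ci_hi"],
                    irr=irr(row["mean"]),
                    rhat=row["rhat"],
                    n_rows=res.n_rows,
                )
            )
    return pd.DataFrame(rows)
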