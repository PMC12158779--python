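"""Data-stream permutation tests and the double-permutation network pipeline.

Two null models operate on the *pre-network* data stream (the dyad-day table),
so sampling structure — who was present, which nests were watched, for how
long — is conserved exactly:

* the dyadic-preference test shuffles observed non-kin help within each
  (group, nest, day) among that nest-day's possible non-kin helpers and
  compares the observed coefficient of variation (CV) of directed dyadic
  helping rates against the permuted distribution;
* the double-permutation pipeline first converts rates to *adjusted helping
  scores* (observed rate minus the median rate over permuted datasets, the
  permutation now spanning all possible helpers), then tests give-versus-
  receive association per group with a node-label Mantel test and an MRQAP
  with double semi-partialling (give score and kinship predicting received
  score), summarizing across groups with a bootstrap of the group mean.

Permutations conserve per-nest-day total help and the multiset of help
amounts by construction.  Empirical p-values use (k + 1) / (n + 1), so the
smallest attainable p with 5,000 permutations is 1/5001 < 0.0002.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_NONKIN_THRESHOLD = 0.125


class PermutationError(ValueError):
    pass


@dataclass
class PermutationResult:
    """Observed statistic against its permutation null."""

    observed: float
    null_draws: np.ndarray
    p: float
    tail: str
    n_permutations: int
    seed: int
    extras: dict = field(default_factory=dict)

    @property
    def null_mean(self) -> float:
        return float(np.nanmean(self.null_draws))

    @property
    def null_quantiles(self) -> tuple[float, float]:
        return (
            float(np.nanquantile(self.null_draws, 0.025)),
            float(np.nanquantile(self.null_draws, 0.975)),
        )


def empirical_p(observed: float, null_draws, tail: str = "upper") -> float:
    """Permutation p-value (k + 1) / (n + 1); never returns 0."""
    null_draws = np.asarray(null_draws, dtype=float)
    null_draws = null_draws[~np.isnan(null_draws)]
    if null_draws.size == 0:
        raise PermutationError("need at least one null draw")
    if tail == "upper":
        k = int(np.sum(null_draws >= observed))
    elif tail == "lower":
        k = int(np.sum(null_draws <= observed))
    elif tail == "two-sided":
        center = null_draws.mean()
        k = int(np.sum(np.abs(null_draws - center) >= abs(observed - center)))
    else:
        raise ValueError("tail must be 'upper', 'lower' or 'two-sided'")
    return (k + 1) / (null_draws.size + 1)


class _BlockShuffler:
    """Within-block (group, nest, day) value shuffling over a row subset.

    Rows are re-ordered so blocks are contiguous; a draw produces a permutation
    of the help vector that moves amounts only within their own nest-day block,
    leaving blocks with a single possible helper fixed.
    """

    def __init__(self, block_ids: np.ndarray, help_minutes: np.ndarray):
        order = np.argsort(block_ids, kind="stable")
        self.order = order
        self.block = np.asarray(block_ids)[order]
        self.help = np.asarray(help_minutes, dtype=float)[order]
        self.n = len(self.help)

    def draw(self, rng) -> np.ndarray:
        keys = rng.random(self.n)
        perm = np.lexsort((keys, self.block))
        return self.help[perm]


def _directed_dyads(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Map each row to its two directed helper->breeder dyads.

    Returns integer dyad codes for the mother-directed and father-directed
    dyad of every row plus a dyad index frame (helper, breeder, summed
    exposure).
    """
    d1 = table["helper_id"].astype(str) + ">" + table["mother_id"].astype(str)
    d2 = table["helper_id"].astype(str) + ">" + table["father_id"].astype(str)
    all_codes, uniques = pd.factorize(pd.concat([d1, d2], ignore_index=True))
    c1 = all_codes[: len(table)]
    c2 = all_codes[len(table):]
    expo = np.bincount(c1, weights=table["exposure_minutes"], minlength=len(uniques))
    expo += np.bincount(c2, weights=table["exposure_minutes"], minlength=len(uniques))
    pairs = pd.DataFrame(
        {
            "dyad": uniques,
            "helper": [u.split(">")[0] for u in uniques],
            "breeder": [u.split(">")[1] for u in uniques],
            "exposure": expo,
        }
    )
    return c1, c2, pairs


def _dyad_rates(c1, c2, expo, help_minutes, n_dyads) -> np.ndarray:
    sums = np.bincount(c1, weights=help_minutes, minlength=n_dyads)
    sums += np.bincount(c2, weights=help_minutes, minlength=n_dyads)
    return sums / expo


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return np.nan
    return float(values.std(ddof=1) / mean)


def dyadic_cv(table: pd.DataFrame, kin_threshold: float = DEFAULT_NONKIN_THRESHOLD) -> float:
    """Coefficient of variation of directed non-kin dyadic helping rates.

    The dyad universe is every helper->breeder pair with at least one day of
    co-observation on non-kin rows (closest-parent r at or below the
    threshold), zeros included; rates pool help and exposure over all such
    days, and the CV uses the n-1 s.d. convention, pooled across groups.
    Returns NaN when the mean rate is zero (undefined CV).
    """
    nonkin = table[table["kinship_r"] <= kin_threshold]
    if not len(nonkin):
        return np.nan
    c1, c2, pairs = _directed_dyads(nonkin)
    rates = _dyad_rates(c1, c2, pairs["exposure"].to_numpy(), nonkin["help_minutes"].to_numpy(float), len(pairs))
    return _cv(rates)


def permute_nonkin_help(
    table: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    kin_threshold: float = DEFAULT_NONKIN_THRESHOLD,
    tail: str = "upper",
) -> PermutationResult:
    """Dyadic-preference CV test against the within-nest-day non-kin null.

    Each permutation reassigns the observed non-kin help amounts of every
    nest-day uniformly at random among that nest-day's possible non-kin
    helpers, conserving per-nest-day totals exactly, then recomputes the CV
    of directed dyadic rates.
    """
    nonkin = table[table["kinship_r"] <= kin_threshold].reset_index(drop=True)
    if not len(nonkin):
        raise PermutationError("no non-kin rows at this threshold")
    c1, c2, pairs = _directed_dyads(nonkin)
    expo = pairs["exposure"].to_numpy()
    help_minutes = nonkin["help_minutes"].to_numpy(float)
    observed = _cv(_dyad_rates(c1, c2, expo, help_minutes, len(pairs)))

    block = pd.factorize(nonkin["nest_id"].astype(str) + "@" + nonkin["day"].astype(str))[0]
    shuffler = _BlockShuffler(block, help_minutes)
    order = shuffler.order
    c1o, c2o = c1[order], c2[order]

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        h = shuffler.draw(rng)
        null[b] = _cv(_dyad_rates(c1o, c2o, expo, h, len(pairs)))
    p = empirical_p(observed, null, tail=tail)
    return PermutationResult(
        observed=observed, null_draws=null, p=p, tail=tail, n_permutations=n_perm, seed=seed
    )


@dataclass
class AdjustedHelpMatrix:
    """Directed adjusted helping scores for one group (zero diagonal)."""

    group: str
    ids: list
    values: np.ndarray  # square; entry (i, j) = adjusted rate of i helping j

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")


def adjusted_help_scores(
    table: pd.DataFrame, n_perm: int = 5000, seed: int = 0, return_raw: bool = False
):
    """Per-group adjusted helping scores: observed rate minus median null rate.

    The null swaps help amounts between all possible group members within each
    group, nest and day (kin and non-kin alike — unlike the non-kin preference
    null).  Each directed helper->breeder dyad's observed rate is compared to
    the median of its rate across ``n_perm`` permuted datasets; a nest
    contributes to the columns of both of its parents.  Groups with fewer than
    three members among the rows are skipped with a warning.

    With ``return_raw`` a second mapping is returned carrying, per group, the
    dyad bookkeeping plus the adjusted scores of every permuted dataset
    (``null_adjusted``).  Because the per-dyad median depends only on the
    multiset of help amounts per nest-day — which every within-block
    permutation conserves — the permuted datasets are themselves draws from
    the no-preference null of the *adjusted-score* pipeline, and downstream
    network statistics can be calibrated against them.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, AdjustedHelpMatrix] = {}
    raw: dict[str, dict] = {}
    for group, sub in table.groupby("group", sort=True):
        sub = sub.reset_index(drop=True)
        ids = sorted(
            set(sub["helper_id"]) | set(sub["mother_id"]) | set(sub["father_id"]), key=str
        )
        if len(ids) < 3:
            logger.warning("group %s has < 3 members in the table; skipped", group)
            continue
        c1, c2, pairs = _directed_dyads(sub)
        expo = pairs["exposure"].to_numpy()
        help_minutes = sub["help_minutes"].to_numpy(float)
        observed = _dyad_rates(c1, c2, expo, help_minutes, len(pairs))

        block = pd.factorize(sub["nest_id"].astype(str) + "@" + sub["day"].astype(str))[0]
        shuffler = _BlockShuffler(block, help_minutes)
        c1o, c2o = c1[shuffler.order], c2[shuffler.order]
        null_rates = np.empty((n_perm, len(pairs)), dtype=np.float32)
        for b in range(n_perm):
            h = shuffler.draw(rng)
            null_rates[b] = _dyad_rates(c1o, c2o, expo, h, len(pairs))
        median = np.median(null_rates, axis=0)
        adjusted = observed - median

        index = {i: k for k, i in enumerate(ids)}
        rows_idx = np.array([index[h] for h in pairs["helper"]])
        cols_idx = np.array([index[b] for b in pairs["breeder"]])
        keep = rows_idx != cols_idx
        M = np.zeros((len(ids), len(ids)))
        M[rows_idx[keep], cols_idx[keep]] = adjusted[keep]
        out[str(group)] = AdjustedHelpMatrix(group=str(group), ids=ids, values=M)
        if return_raw:
            raw[str(group)] = dict(
                ids=ids,
                rows=rows_idx,
                cols=cols_idx,
                keep=keep,
                observed_adjusted=adjusted,
                null_adjusted=null_rates - median[None, :],
            )
    if return_raw:
        return out, raw
    return out


def _offdiag(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    return M[~np.eye(n, dtype=bool)]


def mantel_test(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str = "upper",
) -> tuple[float, float]:
    """Matrix correlation with node-label permutation significance.

    Pearson's r over the off-diagonal cells of A and B; the null permutes the
    node labels of B (rows and columns simultaneously), appropriate for dyadic
    matrices whose rows/columns refer to the same individuals.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("mantel_test needs two square matrices of equal shape")
    a = _offdiag(A)
    if a.std() == 0 or _offdiag(B).std() == 0:
        return np.nan, np.nan  # constant matrix: correlation undefined
    observed = float(np.corrcoef(a, _offdiag(B))[0, 1])
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    null = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        null[k] = np.corrcoef(a, _offdiag(B[np.ix_(p, p)]))[0, 1]
    return observed, empirical_p(observed, null, tail=tail)


def mrqap_dsp(
    Y: np.ndarray,
    X: list[np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
    condition_limit: float = 1e8,
    return_null: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Multiple regression on dyadic matrices with double-semi-partialling tests.

    Coefficients are the OLS fit of vectorized off-diagonals of ``Y`` on those
    of the predictor matrices (plus an intercept).  Significance per predictor
    follows Dekker's double semi-partialling: the predictor's residual matrix
    (after regressing it on the remaining predictors) has its node labels
    permuted, the regression is refitted with the permuted residual in the
    predictor's place, and the observed |coefficient| is compared to the
    permuted ones.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    Xs = [np.asarray(x, dtype=float) for x in X]
    for x in Xs:
        if x.shape != Y.shape:
            raise ValueError("all matrices must share Y's shape")
    mask = ~np.eye(n, dtype=bool)
    y = Y[mask]
    cols = [np.ones_like(y)] + [x[mask] for x in Xs]
    D = np.column_stack(cols)
    gram = D.T @ D
    cond = np.linalg.cond(gram)
    if cond > condition_limit:
        corr = np.corrcoef(D[:, 1:].T)
        worst = np.unravel_index(
            np.argmax(np.abs(corr - np.eye(len(Xs)))), corr.shape
        )
        raise ValueError(
            f"collinear predictors (condition number {cond:.2e}); "
            f"worst pair: predictors {worst[0]} and {worst[1]}"
        )
    beta = np.linalg.lstsq(D, y, rcond=None)[0]

    rng = np.random.default_rng(seed)
    rows = []
    null_draws = np.empty((len(Xs), n_perm))
    for k in range(len(Xs)):
        others = [np.ones_like(y)] + [x[mask] for j, x in enumerate(Xs) if j != k]
        Do = np.column_stack(others)
        gamma = np.linalg.lstsq(Do, Xs[k][mask], rcond=None)[0]
        resid_vec = Xs[k][mask] - Do @ gamma
        E = np.zeros((n, n))
        E[mask] = resid_vec
        count = 0
        obs_abs = abs(beta[k + 1])
        for b in range(n_perm):
            p = rng.permutation(n)
            Ep = E[np.ix_(p, p)]
            Dk = D.copy()
            Dk[:, k + 1] = Ep[mask]
            bp = np.linalg.lstsq(Dk, y, rcond=None)[0]
            null_draws[k, b] = bp[k + 1]
            if abs(bp[k + 1]) >= obs_abs:
                count += 1
        rows.append(
            dict(
                predictor=k,
                coefficient=float(beta[k + 1]),
                p=(count + 1) / (n_perm + 1),
            )
        )
    result = pd.DataFrame(rows)
    if return_null:
        return result, null_draws
    return result


def bootstrap_group_mean(
    group_stats, B: int = 10_000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for a mean across groups (groups resampled)."""
    values = np.asarray(group_stats, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two groups to bootstrap the group mean")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(B, len(values)))
    means = values[idx].mean(axis=1)
    return float(values.mean()), float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))


def _scale(M: np.ndarray) -> np.ndarray:
    v = _offdiag(M)
    sd = v.std(ddof=1)
    return (M - v.mean()) / sd if sd > 0 else M - v.mean()


def double_permutation_pipeline(
    table: pd.DataFrame,
    relatedness,
    n_perm_adjust: int = 5000,
    n_perm_test: int = 5000,
    n_boot: int = 10_000,
    seed: int = 0,
    mrqap: bool = True,
    n_perm_mrqap: int = 1000,
) -> dict:
    """The full double-permutation reciprocity robustness check.

    Builds per-group adjusted helping matrices and reports the per-group
    node-label Mantel correlation between scores given and received (and,
    optionally, a per-group node-label MRQAP-DSP of received scores on given
    scores and kinship, both scaled to unit off-diagonal variance).

    The pipeline-level conclusions — the cross-group mean give-receive
    correlation and the cross-group mean MRQAP give coefficient — are tested
    against the *data-stream* null: each within-nest-day permutation of the
    help amounts is itself a dataset drawn from the no-preference null, and
    the full statistic (adjusted matrix, then network statistic, then group
    mean) is recomputed on every permuted dataset.  Node-label nulls are kept
    for the per-group reports, but they test exchangeability of individuals
    rather than randomness of help allocation, and their type-I error against
    the allocation null drifts with the observation structure; the data-stream
    reference is exactly calibrated for it.
    """
    ss = np.random.SeedSequence(seed)
    s_adjust, s_mantel, s_null, s_boot, s_mrqap = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    adjusted, raw = adjusted_help_scores(
        table, n_perm=n_perm_adjust, seed=s_adjust, return_raw=True
    )
    # groups with a constant score matrix carry no give-receive information
    degenerate = [g for g, m in adjusted.items() if _offdiag(m.values).std() == 0]
    for g in degenerate:
        logger.warning("group %s: constant adjusted-score matrix; skipped", g)
        del adjusted[g]
        del raw[g]
    if not adjusted:
        raise PermutationError("no group yielded a usable adjusted helping matrix")

    def _as_matrix(entry: dict, values: np.ndarray) -> np.ndarray:
        n = len(entry["ids"])
        M = np.zeros((n, n))
        M[entry["rows"][entry["keep"]], entry["cols"][entry["keep"]]] = values[entry["keep"]]
        return M

    def _give_receive_r(M: np.ndarray) -> float:
        a, b = _offdiag(M), _offdiag(M.T)
        if a.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    per_group = {}
    rs = []
    for group, mat in adjusted.items():
        give = mat.values
        receive = give.T
        r, p = mantel_test(give, receive, n_perm=n_perm_test, seed=s_mantel, tail="upper")
        per_group[group] = {"mantel_r": r, "mantel_p": p, "n_members": len(mat.ids)}
        rs.append(_give_receive_r(give))

    # stream-null draws of the group-mean give-receive correlation
    n_null = min(n_perm_test, n_perm_adjust)
    null_means = np.zeros(n_null)
    for group, entry in raw.items():
        for b in range(n_null):
            null_means[b] += _give_receive_r(_as_matrix(entry, entry["null_adjusted"][b]))
    null_means /= len(raw)
    mean_r = float(np.mean(rs))
    p_mean = empirical_p(mean_r, null_means, tail="upper")

    if len(rs) >= 2:
        boot = bootstrap_group_mean(rs, B=n_boot, seed=s_boot)
    else:
        boot = (mean_r, np.nan, np.nan)

    result = {
        "per_group": per_group,
        "mean_mantel_r": mean_r,
        "mean_mantel_p": p_mean,
        "bootstrap_mean": boot[0],
        "bootstrap_ci": (boot[1], boot[2]),
        "n_groups": len(adjusted),
        "seed": seed,
    }

    if mrqap:
        idx = {i: k for k, i in enumerate(relatedness.ids)} if relatedness is not None else {}
        kin_mats = {}
        for group, mat in adjusted.items():
            K = np.zeros_like(mat.values)
            if relatedness is not None:
                for a, ida in enumerate(mat.ids):
                    for b, idb in enumerate(mat.ids):
                        if a != b and ida in idx and idb in idx:
                            K[a, b] = relatedness.values[idx[ida], idx[idb]]
            if _offdiag(K).std() > 0:
                kin_mats[group] = K
            else:
                logger.warning(
                    "group %s: constant kinship matrix; MRQAP fitted without it", group
                )
                kin_mats[group] = None

        def _give_coef(M: np.ndarray, K: np.ndarray | None) -> float:
            give = _offdiag(M)
            if give.std() == 0:
                return 0.0
            cols = [np.ones_like(give), (give - give.mean()) / give.std(ddof=1)]
            if K is not None:
                kin = _offdiag(K)
                cols.append((kin - kin.mean()) / kin.std(ddof=1))
            D = np.column_stack(cols)
            return float(np.linalg.lstsq(D, _offdiag(M.T), rcond=None)[0][1])

        mr_rows = []
        for group, mat in adjusted.items():
            K = kin_mats[group]
            predictors = [_scale(mat.values)] + ([_scale(K)] if K is not None else [])
            try:
                res = mrqap_dsp(
                    mat.values.T, predictors, n_perm=n_perm_mrqap, seed=s_mrqap
                )
            except ValueError as err:
                logger.warning("MRQAP skipped for group %s: %s", group, err)
                continue
            mr_rows.append(
                dict(
                    group=group,
                    coef_give=res.loc[0, "coefficient"],
                    p_give=res.loc[0, "p"],
                    coef_kinship=res.loc[1, "coefficient"] if K is not None else np.nan,
                    p_kinship=res.loc[1, "p"] if K is not None else np.nan,
                )
            )
        mr = pd.DataFrame(mr_rows)
        result["mrqap"] = mr

        # stream-null test of the cross-group mean give coefficient
        obs_coefs = [
            _give_coef(adjusted[g].values, kin_mats[g]) for g in adjusted
        ]
        null_coef = np.zeros(n_null)
        for group, entry in raw.items():
            K = kin_mats[group]
            for b in range(n_null):
                null_coef[b] += _give_coef(
                    _as_matrix(entry, entry["null_adjusted"][b]), K
                )
        null_coef /= len(raw)
        mean_coef = float(np.mean(obs_coefs))
        k_cnt = int(np.sum(np.abs(null_coef) >= abs(mean_coef)))
        result["mrqap_mean_coef_give"] = mean_coef
        result["mrqap_mean_coef_p"] = (k_cnt + 1) / (len(null_coef) + 1)
        if len(mr) >= 2:
            bg = bootstrap_group_mean(mr["coef_give"], B=n_boot, seed=s_boot + 1)
            result["mrqap_ci_coef_give"] = (bg[1], bg[2])
    return result
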