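"""Pedigree relatedness, marker merging, closest-parent kinship and kin classes.

Relatedness is reported throughout on the *r* scale (numerator relationship:
parent-offspring r = 0.5), i.e. twice the kinship coefficient, with founders
assumed unrelated and non-inbred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, self-ancestry)."""


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise relatedness with an id index.

    ``values`` is a dense symmetric matrix with unit diagonal and entries in
    [0, 1]; ``ids`` maps row/column positions to individual identifiers.
    ``source`` optionally tags each entry ``pedigree`` (0) or ``marker`` (1).
    """

    ids: list
    values: np.ndarray
    source: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relatedness matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relatedness matrix must be symmetric")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def get(self, a, b, default: float = 0.0) -> float:
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return default
        return float(self.values[ia, ib])

    def __contains__(self, a) -> bool:
        return a in self._index

    def mean_offdiagonal(self) -> float:
        n = len(self.ids)
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        """Long-format upper triangle: id_i, id_j, r."""
        n = len(self.ids)
        iu, ju = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "id_i": [self.ids[i] for i in iu],
                "id_j": [self.ids[j] for j in ju],
                "r": self.values[iu, ju],
            }
        )


def _toposort(pedigree: pd.DataFrame) -> list:
    """Order ids so parents precede offspring; raise PedigreeError on cycles."""
    parents = {
        r.id: tuple(p for p in (r.sire_id, r.dam_id) if pd.notna(p) and p != "")
        for r in pedigree.itertuples(index=False)
    }
    order: list = []
    state: dict = {}  # 0 in-progress, 1 done

    for start in parents:
        if state.get(start) == 1:
            continue
        stack = [(start, iter(parents.get(start, ())))]
        state[start] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if p not in parents:
                    continue  # founder parent outside the table
                if state.get(p) == 0:
                    raise PedigreeError(f"pedigree cycle involving {p!r}")
                if state.get(p) != 1:
                    state[p] = 0
                    stack.append((p, iter(parents.get(p, ()))))
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                order.append(node)
                stack.pop()
    return order


def pedigree_relatedness(pedigree: pd.DataFrame) -> RelatednessMatrix:
    """Numerator relationship matrix from a pedigree via the tabular method.

    ``pedigree`` has columns ``id, sire_id, dam_id``; an empty/NaN parent cell
    marks an unknown (founder) parent.  Founders are assumed unrelated and
    non-inbred.  The recursion is the standard one: for individual ``i`` with
    parents ``s, d`` listed before it,

    ``A[i, j] = (A[s, j] + A[d, j]) / 2`` for prior ``j`` and
    ``A[i, i] = 1 + A[s, d] / 2``.

    Parent-offspring relatedness is 0.5, full siblings 0.5, half siblings 0.25.
    """
    order = _toposort(pedigree)
    idx = {i: k for k, i in enumerate(order)}
    rec = pedigree.set_index("id")
    n = len(order)
    A = np.zeros((n, n))
    for i in order:
        ii = idx[i]
        s, d = rec.loc[i, "sire_id"], rec.loc[i, "dam_id"]
        si = idx.get(s) if pd.notna(s) and s != "" else None
        di = idx.get(d) if pd.notna(d) and d != "" else None
        for jj in range(ii):
            a = 0.0
            if si is not None:
                a += A[si, jj]
            if di is not None:
                a += A[di, jj]
            A[ii, jj] = A[jj, ii] = a / 2.0
        inb = A[si, di] if (si is not None and di is not None) else 0.0
        A[ii, ii] = 1.0 + inb / 2.0
    A = np.clip(A, 0.0, 1.0)
    np.fill_diagonal(A, np.minimum(np.diag(A), 1.0))
    return RelatednessMatrix(ids=order, values=A)


def load_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype={"id": str, "sire_id": str, "dam_id": str})
    missing = [c for c in ("id", "sire_id", "dam_id") if c not in ped.columns]
    if missing:
        raise ValueError(f"pedigree.csv missing column(s): {missing}")
    return ped


def merge_relatedness(
    pedigree_r: RelatednessMatrix,
    marker_r: RelatednessMatrix | None,
    individuals: pd.DataFrame,
) -> RelatednessMatrix:
    """Combine pedigree and marker relatedness using the immigrant-helper rule.

    Pairs involving at least one immigrant take the marker estimate (clipped to
    [0, 1]); all other pairs take the pedigree value.  Marker entries missing
    for an immigrant pair fall back to the pedigree value (0 for pedigree
    founders), with the substitutions counted and logged.
    """
    ids = pedigree_r.ids
    values = pedigree_r.values.copy()
    source = np.zeros_like(values, dtype=np.int8)
    if marker_r is None:
        return RelatednessMatrix(ids=ids, values=values, source=source)

    dispersal = individuals.set_index("id")["dispersal"].to_dict()
    immigrant = np.array([dispersal.get(i) == "immigrant" for i in ids])
    n_missing = 0
    n_clipped = 0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if not (immigrant[a] or immigrant[b]):
                continue
            if ids[a] in marker_r and ids[b] in marker_r:
                r = marker_r.get(ids[a], ids[b])
                if r < 0:
                    n_clipped += 1
                    r = 0.0
                r = min(r, 1.0)
                values[a, b] = values[b, a] = r
                source[a, b] = source[b, a] = 1
            else:
                n_missing += 1  # keep pedigree value
    if n_missing:
        logger.info("merge_relatedness: %d immigrant pairs lacked marker estimates; "
                    "pedigree value used", n_missing)
    if n_clipped:
        logger.info("merge_relatedness: %d negative marker estimates clipped to 0",
                    n_clipped)
    return RelatednessMatrix(ids=ids, values=values, source=source)


def closest_parent_relatedness(helper_id, nest, R: RelatednessMatrix) -> dict:
    """Kinship covariate for a helper at a nest: relatedness to the closer parent.

    ``nest`` is any mapping with ``mother_id`` and ``father_id``.  A parent
    absent from ``R`` contributes 0 (with a warning).  Raises if the helper is
    itself a parent of the nest, since breeders are never their own helpers.
    """
    mother, father = nest["mother_id"], nest["father_id"]
    if helper_id in (mother, father):
        raise ValueError(f"{helper_id!r} is a breeder of this nest, not a possible helper")
    for p in (mother, father):
        if p not in R:
            logger.warning("parent %r missing from relatedness matrix; r treated as 0", p)
    r_mother = R.get(helper_id, mother, 0.0)
    r_father = R.get(helper_id, father, 0.0)
    return {
        "r_mother": r_mother,
        "r_father": r_father,
        "r_max": max(r_mother, r_father),
    }


def attach_kinship(table: pd.DataFrame, R: RelatednessMatrix) -> tuple[pd.DataFrame, int]:
    """Fill ``kinship_r`` (closest-parent r) and ``kinship_z`` on an analysis table."""
    n_missing = 0
    r = np.empty(len(table))
    for k, (h, m, f) in enumerate(
        zip(table["helper_id"], table["mother_id"], table["father_id"])
    ):
        if h not in R or (m not in R and f not in R):
            n_missing += 1
        r[k] = max(R.get(h, m, 0.0), R.get(h, f, 0.0))
    table = table.copy()
    table["kinship_r"] = r
    if len(table) >= 2 and np.std(r, ddof=1) > 0:
        table["kinship_z"] = standardize_kinship(r)
    return table, n_missing


def standardize_kinship(values) -> np.ndarray:
    """Center and scale relatedness by the sample (n-1) standard deviation.

    The sample must be the rows entering the model being fitted: standardized
    coefficients are per-model, so subsets are re-standardized before fitting.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("standardization needs at least two values")
    sd = values.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(values.mean())):
        raise ValueError(
            "zero variance in relatedness; use the unstandardized covariate"
        )
    return (values - values.mean()) / sd


def classify_kin(r: float, threshold: float):
    """Binary kin / nonkin classification: kin iff ``r`` strictly above threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    return "kin" if r > threshold else "nonkin"


def load_relatedness_csv(path) -> RelatednessMatrix:
    """Read a long-format relatedness CSV (id_i, id_j, r; upper triangle sufficient)."""
    long = pd.read_csv(path)
    ids = sorted(set(long["id_i"]) | set(long["id_j"]), key=str)
    idx = {i: k for k, i in enumerate(ids)}
    values = np.eye(len(ids))
    for rec in long.itertuples(index=False):
        a, b = idx[rec.id_i], idx[rec.id_j]
        values[a, b] = values[b, a] = rec.r
    return RelatednessMatrix(ids=ids, values=values)
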