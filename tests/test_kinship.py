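"""Pedigree relatedness against a gene-dropping oracle, merging and kin classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from starhelp.kinship import (
    PedigreeError,
    RelatednessMatrix,
    classify_kin,
    closest_parent_relatedness,
    merge_relatedness,
    pedigree_relatedness,
    standardize_kinship,
)


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire_id", "dam_id"])


def gene_drop_relatedness(pedigree: pd.DataFrame, n_rep: int, seed: int) -> dict:
    """Monte-Carlo identity-by-descent oracle, independent of the recursion.

    Founders get two unique alleles; alleles drop through the pedigree; the
    relatedness estimate for (i, j) is twice the probability that one random
    allele from each is identical by descent.
    """
    rng = np.random.default_rng(seed)
    parents = {r.id: (r.sire_id, r.dam_id) for r in pedigree.itertuples(index=False)}
    ids = list(parents)
    acc = {(a, b): 0.0 for i, a in enumerate(ids) for b in ids[i + 1:]}
    for _ in range(n_rep):
        alleles = {}
        counter = [0]

        def fill(i):
            if i in alleles:
                return alleles[i]
            s, d = parents.get(i, (None, None))
            out = []
            for p in (s, d):
                if p is None or (isinstance(p, float) and np.isnan(p)) or p == "":
                    counter[0] += 1
                    out.append(counter[0])
                else:
                    out.append(fill(p)[rng.integers(2)])
            alleles[i] = tuple(out)
            return alleles[i]

        for i in ids:
            fill(i)
        for (a, b) in acc:
            ibd = alleles[a][rng.integers(2)] == alleles[b][rng.integers(2)]
            acc[(a, b)] += ibd
    return {k: 2 * v / n_rep for k, v in acc.items()}


class TestPedigreeRelatedness:
    def test_parent_offspring(self):
        R = pedigree_relatedness(_ped([("P", "", ""), ("Q", "", ""), ("C", "P", "Q")]))
        assert R.get("C", "P") == pytest.approx(0.5)

    def test_half_siblings(self):
        R = pedigree_relatedness(
            _ped([("S", "", ""), ("D1", "", ""), ("D2", "", ""),
                  ("A", "S", "D1"), ("B", "S", "D2")])
        )
        assert R.get("A", "B") == pytest.approx(0.25)

    def test_full_siblings_and_first_cousins(self):
        ped = _ped([
            ("G1", "", ""), ("G2", "", ""),
            ("P1", "G1", "G2"), ("P2", "G1", "G2"),
            ("S1", "", ""), ("S2", "", ""),
            ("C1", "S1", "P1"), ("C2", "S2", "P2"),
        ])
        R = pedigree_relatedness(ped)
        assert R.get("P1", "P2") == pytest.approx(0.5)
        assert R.get("C1", "C2") == pytest.approx(0.125)

    def test_matches_gene_dropping_oracle(self):
        # a 12-member, 3-generation pedigree with mixed founder/known parents
        ped = _ped([
            ("A", "", ""), ("B", "", ""), ("C", "", ""), ("D", "", ""),
            ("E", "A", "B"), ("F", "A", "B"), ("G", "C", "D"),
            ("H", "E", "G"), ("I", "F", "G"), ("J", "", ""),
            ("K", "H", "J"), ("L", "I", "J"),
        ])
        R = pedigree_relatedness(ped)
        oracle = gene_drop_relatedness(ped, n_rep=20_000, seed=1)
        for (a, b), r_mc in oracle.items():
            assert R.get(a, b) == pytest.approx(r_mc, abs=0.02)

    def test_symmetry_and_unit_diagonal(self):
        ped = _ped([("A", "", ""), ("B", "", ""), ("C", "A", "B"), ("D", "A", "B")])
        R = pedigree_relatedness(ped)
        assert np.allclose(R.values, R.values.T)
        assert np.allclose(np.diag(R.values), 1.0)

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            pedigree_relatedness(_ped([("A", "B", ""), ("B", "A", "")]))


class TestMergeRelatedness:
    def _setup(self):
        ped = _ped([("R1", "", ""), ("R2", "", ""), ("IM", "", "")])
        pedigree_r = pedigree_relatedness(ped)
        marker = RelatednessMatrix(
            ids=["R1", "R2", "IM"],
            values=np.array([[1, 0.4, 0.31], [0.4, 1, -0.07], [0.31, -0.07, 1.0]]),
        )
        individuals = pd.DataFrame(
            {"id": ["R1", "R2", "IM"], "sex": ["male"] * 3,
             "dispersal": ["resident", "resident", "immigrant"],
             "group": ["G"] * 3, "first_season": [1] * 3, "last_season": [1] * 3}
        )
        return pedigree_r, marker, individuals

    def test_resident_pair_uses_pedigree(self):
        pr, marker, ind = self._setup()
        merged = merge_relatedness(pr, marker, ind)
        assert merged.get("R1", "R2") == 0.0  # pedigree founders, not marker 0.4

    def test_immigrant_pair_uses_marker(self):
        pr, marker, ind = self._setup()
        merged = merge_relatedness(pr, marker, ind)
        assert merged.get("R1", "IM") == pytest.approx(0.31)

    def test_negative_marker_clipped(self):
        pr, marker, ind = self._setup()
        merged = merge_relatedness(pr, marker, ind)
        assert merged.get("R2", "IM") == 0.0


class TestClosestParent:
    def test_max_of_parents(self):
        R = RelatednessMatrix(
            ids=["H", "M", "F"],
            values=np.array([[1, 0.25, 0.5], [0.25, 1, 0], [0.5, 0, 1]]),
        )
        cov = closest_parent_relatedness("H", {"mother_id": "M", "father_id": "F"}, R)
        assert cov["r_max"] == 0.5

    def test_breeder_cannot_be_own_helper(self):
        R = RelatednessMatrix(ids=["M", "F"], values=np.eye(2))
        with pytest.raises(ValueError, match="breeder"):
            closest_parent_relatedness("M", {"mother_id": "M", "father_id": "F"}, R)

    def test_missing_parent_treated_as_zero(self):
        R = RelatednessMatrix(ids=["H", "M"], values=np.array([[1, 0.3], [0.3, 1]]))
        cov = closest_parent_relatedness("H", {"mother_id": "M", "father_id": "Z"}, R)
        assert cov["r_max"] == pytest.approx(0.3)


class TestStandardize:
    def test_one_sd_step(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.1, 0.19, 500)
        z = standardize_kinship(vals)
        sd = vals.std(ddof=1)
        # two values one sample s.d. apart differ by exactly one in z
        np.testing.assert_allclose(z, (vals - vals.mean()) / sd)
        assert (z[3] - z[7]) * sd == pytest.approx(vals[3] - vals[7])

    def test_two_point_sample(self):
        z = standardize_kinship([0.0, 1.0])
        assert z == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError, match="variance"):
            standardize_kinship([0.2, 0.2, 0.2])


class TestClassifyKin:
    @pytest.mark.parametrize(
        "r,threshold,expected",
        [(0.25, 0.1, "kin"), (0.1, 0.1, "nonkin"), (0.0, 0.3, "nonkin")],
    )
    def test_strict_threshold(self, r, threshold, expected):
        assert classify_kin(r, threshold) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(r=st.floats(0, 1), t1=st.floats(0.01, 0.98), dt=st.floats(0.001, 0.5))
    def test_monotone_in_threshold(self, r, t1, dt):
        t2 = min(t1 + dt, 0.99)
        if classify_kin(r, t1) == "nonkin":
            assert classify_kin(r, t2) == "nonkin"
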