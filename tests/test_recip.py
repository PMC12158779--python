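"""Reciprocal-pair logic, role switches and exact binomial intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starhelp.datamodel import HelpingLedger
from starhelp.recip import (
    detect_reciprocal_pairs,
    directed_help,
    exact_binomial_ci,
    pairs_to_frame,
    reciprocal_latency,
    reciprocity_possible,
    tally_role_switches,
)


def _ledger(visits):
    v = pd.DataFrame(visits, columns=["helper_id", "nest_id", "day", "help_minutes"])
    e = v[["nest_id", "day"]].drop_duplicates()
    e["exposure_minutes"] = 120.0
    return HelpingLedger(visits=v, exposure=e)


def _nests(rows):
    return pd.DataFrame(rows, columns=["nest_id", "group", "season", "mother_id", "father_id"])


class TestReciprocityPossible:
    def _presence(self, rows):
        return pd.DataFrame(rows, columns=["individual", "group", "season"])

    def test_return_observable(self):
        # A helps B in season 1; in season 3, A breeds while B is present and
        # not breeding -> return help was observable
        ledger = _ledger([("A", "N1", 10, 5)])
        nests = _nests([("N1", "G", 1, "B", "C"), ("N2", "G", 3, "D", "A")])
        presence = self._presence(
            [("A", "G", s) for s in (1, 2, 3)] + [("B", "G", s) for s in (1, 2, 3)]
        )
        out = reciprocity_possible(ledger, nests, roles=None, presence=presence)
        assert out.set_index(["id_a", "id_b"]).loc[("A", "B"), "observable"]

    def test_not_observable_when_giver_never_breeds(self):
        ledger = _ledger([("A", "N1", 10, 5)])
        nests = _nests([("N1", "G", 1, "B", "C")])
        presence = self._presence([("A", "G", 1), ("B", "G", 1)])
        out = reciprocity_possible(ledger, nests, roles=None, presence=presence)
        assert not out["observable"].any()

    def test_not_observable_when_partner_absent(self):
        ledger = _ledger([("A", "N1", 10, 5)])
        nests = _nests([("N1", "G", 1, "B", "C"), ("N2", "G", 3, "D", "A")])
        presence = self._presence([("A", "G", 1), ("A", "G", 3), ("B", "G", 1)])
        out = reciprocity_possible(ledger, nests, roles=None, presence=presence)
        assert not out["observable"].any()


class TestDetectReciprocalPairs:
    def test_mutual_cross_season_help(self):
        ledger = _ledger([("A", "N1", 10, 5), ("B", "N2", 372, 4)])
        nests = _nests([("N1", "G", 1, "B", "C"), ("N2", "G", 3, "A", "D")])
        pairs, summary = detect_reciprocal_pairs(ledger, nests)
        assert summary["n_reciprocated"] == 1
        rec = [p for p in pairs if p.reciprocated][0]
        assert reciprocal_latency(rec) == pytest.approx(362.0)

    def test_one_way_help_not_reciprocated(self):
        ledger = _ledger([("A", "N1", 10, 5)])
        nests = _nests([("N1", "G", 1, "B", "C")])
        pairs, summary = detect_reciprocal_pairs(ledger, nests)
        assert summary["n_reciprocated"] == 0
        assert reciprocal_latency(pairs[0]) is None

    def test_same_day_mutual_help_has_zero_latency(self):
        ledger = _ledger([("A", "N1", 10, 5), ("B", "N2", 10, 2)])
        nests = _nests([("N1", "G", 1, "B", "C"), ("N2", "G", 1, "A", "D")])
        pairs, _ = detect_reciprocal_pairs(ledger, nests)
        rec = [p for p in pairs if p.reciprocated][0]
        assert rec.latency_days == 0.0

    def test_detection_equals_simulator_truth(self, small_dataset):
        pairs, _ = detect_reciprocal_pairs(small_dataset.ledger, small_dataset.nests)
        detected = sorted(
            [p.id_a, p.id_b] for p in pairs if p.reciprocated
        )
        assert detected == small_dataset.truth["reciprocal_pairs"]

    def test_reciprocated_implies_observable(self, small_dataset):
        from starhelp.datamodel import presence_from_individuals

        presence = presence_from_individuals(small_dataset.individuals)
        observable = reciprocity_possible(
            small_dataset.ledger, small_dataset.nests, roles=None, presence=presence
        )
        pairs, _ = detect_reciprocal_pairs(
            small_dataset.ledger, small_dataset.nests,
            small_dataset.individuals, observable=observable,
        )
        df = pairs_to_frame(pairs)
        assert (df.loc[df["reciprocated"], "observable"]).all()

    def test_summary_invariant_to_row_order(self):
        visits = [("A", "N1", 10, 5), ("B", "N2", 372, 4), ("C", "N1", 11, 2)]
        nests = _nests([("N1", "G", 1, "B", "C2"), ("N2", "G", 3, "A", "D")])
        _, s1 = detect_reciprocal_pairs(_ledger(visits), nests)
        _, s2 = detect_reciprocal_pairs(_ledger(visits[::-1]), nests)
        assert s1["n_reciprocated"] == s2["n_reciprocated"]
        assert s1["n_pairs_with_help"] == s2["n_pairs_with_help"]


class TestRoleSwitches:
    def _roles(self, seq, outcomes=None, individual="A"):
        outcomes = outcomes or ["n/a"] * len(seq)
        return pd.DataFrame(
            {
                "individual": [individual] * len(seq),
                "group": ["G"] * len(seq),
                "season": range(1, len(seq) + 1),
                "role": seq,
                "attempt_outcome": outcomes,
            }
        )

    def test_breeder_helper_breeder_is_two_switches(self):
        out = tally_role_switches(self._roles(["breeder", "helper", "breeder"]))
        assert out["switch_counts"]["A"] == 2

    def test_neither_is_transparent_for_switches(self):
        # B, N, H counts as one switch; the next-role after the breeding
        # attempt is "neither"
        out = tally_role_switches(
            self._roles(["breeder", "neither", "helper"], ["failure", "n/a", "n/a"])
        )
        assert out["switch_counts"]["A"] == 1
        assert out["transitions_after_failure"]["neither"] == 1

    def test_transition_table_matches_enumeration(self):
        rng = np.random.default_rng(5)
        frames = []
        expected = {"failure": {"breeder": 0, "helper": 0, "neither": 0},
                    "success": {"breeder": 0, "helper": 0, "neither": 0}}
        for i in range(30):
            seq = rng.choice(["breeder", "helper", "neither"], size=6).tolist()
            outcomes = [
                rng.choice(["failure", "success"]) if r == "breeder" else "n/a"
                for r in seq
            ]
            for k in range(5):
                if seq[k] == "breeder":
                    expected[outcomes[k]][seq[k + 1]] += 1
            frames.append(self._roles(seq, outcomes, individual=f"I{i}"))
        out = tally_role_switches(pd.concat(frames, ignore_index=True))
        assert out["transitions_after_failure"] == expected["failure"]
        assert out["transitions_after_success"] == expected["success"]

    def test_complete_lifetimes_excludes_final_season(self):
        roles = pd.concat(
            [self._roles(["breeder", "helper"], individual="A"),
             self._roles(["breeder", "helper", "breeder"], individual="B")],
            ignore_index=True,
        )
        out = tally_role_switches(roles, complete_lifetimes_only=True)
        assert "B" not in out["switch_counts"] and "A" in out["switch_counts"]


class TestExactBinomialCI:
    def test_study_interval_rounds_to_printed_percentages(self):
        lo, hi = exact_binomial_ci(68, 112)
        assert round(lo * 100) == 51 and round(hi * 100) == 70

    def test_zero_successes(self):
        lo, hi = exact_binomial_ci(0, 152)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 152), abs=1e-9)
        # the one-sided 95% upper bound is tighter
        _, hi1 = exact_binomial_ci(0, 152, one_sided=True)
        assert hi1 == pytest.approx(1 - 0.05 ** (1 / 152), abs=1e-9)
        assert hi1 < hi

    def test_matches_scipy_binomtest(self):
        for x, n in [(5, 20), (0, 10), (10, 10), (68, 112)]:
            lo, hi = exact_binomial_ci(x, n)
            ci = stats.binomtest(x, n).proportion_ci(confidence_level=0.95, method="exact")
            assert (lo, hi) == pytest.approx((ci.low, ci.high), abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_ci(-1, 4)


class TestDirectedHelp:
    def test_credits_both_parents(self):
        ledger = _ledger([("A", "N1", 10, 5)])
        nests = _nests([("N1", "G", 1, "B", "C")])
        dh = directed_help(ledger, nests)
        assert set(zip(dh["giver"], dh["receiver"])) == {("A", "B"), ("A", "C")}
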