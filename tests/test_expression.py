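from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from parasitome.annotation import GeneFlags
from parasitome.expression import (
    ExpressionTable,
    OrthologPair,
    RegulationSets,
    enrichment_test,
    infection_report,
    normalize_counts,
    ortholog_compare,
    regulation_sets,
    top_expressed,
)
from parasitome.fixtures import focal_set_fixture, ortholog_fixture


def make_table(data: dict[str, list[int]], conditions: dict[str, str]) -> ExpressionTable:
    genes = [f"g{i + 1:03d}" for i in range(len(next(iter(data.values()))))]
    return ExpressionTable(
        counts=pd.DataFrame(data, index=genes), conditions=conditions
    )


COND2 = {"knob_1": "knob", "inf_1": "infection"}


class TestNormalizeCounts:
    def test_identical_samples_unit_factors(self):
        t = make_table({"knob_1": [10, 20, 30], "inf_1": [10, 20, 30]}, COND2)
        t = normalize_counts(t)
        assert list(t.size_factors) == [1.0, 1.0]

    def test_doubled_sample(self):
        counts = list(range(1, 101))
        t = make_table(
            {"knob_1": counts, "inf_1": [2 * c for c in counts]}, COND2
        )
        t = normalize_counts(t)
        ratio = t.size_factors["inf_1"] / t.size_factors["knob_1"]
        assert ratio == pytest.approx(2.0)

    def test_scale_invariance_of_fold_changes(self):
        rngc = np.random.default_rng(0)
        base = rngc.integers(1, 500, size=50).tolist()
        infect = rngc.integers(1, 500, size=50).tolist()
        t1 = make_table({"knob_1": base, "inf_1": infect}, COND2)
        t3 = make_table(
            {"knob_1": [3 * c for c in base], "inf_1": [3 * c for c in infect]}, COND2
        )
        s1 = regulation_sets(t1, "knob", "infection")
        s3 = regulation_sets(t3, "knob", "infection")
        assert s1.up2 == s3.up2 and s1.down2 == s3.down2
        for gid in s1.fold_change:
            assert s1.fold_change[gid] == pytest.approx(s3.fold_change[gid])

    def test_all_zero_sample_errors(self):
        t = make_table({"knob_1": [0, 0], "inf_1": [1, 2]}, COND2)
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(t)

    def test_normalized_is_counts_over_size_factor(self):
        t = make_table({"knob_1": [10, 20], "inf_1": [40, 80]}, COND2)
        t = normalize_counts(t)
        expected = t.counts / t.size_factors
        assert np.allclose(t.normalized.values, expected.values)


class TestRegulationSets:
    def make(self, control, infection):
        # pad with stable genes so size factors stay at 1
        stable = [50] * 20
        t = make_table(
            {"knob_1": control + stable, "inf_1": infection + stable}, COND2
        )
        return regulation_sets(t, "knob", "infection")

    def test_up10_and_up2(self):
        sets = self.make([10, 10], [101, 10])
        assert "g001" in sets.up10 and "g001" in sets.up2

    def test_exact_twofold_excluded(self):
        sets = self.make([10], [20])
        assert "g001" not in sets.up2

    def test_zero_infection_down10(self):
        sets = self.make([5], [0])
        assert "g001" in sets.down10 and "g001" in sets.down2

    def test_zero_control_infinite_up(self):
        sets = self.make([0, 10], [7, 10])
        assert "g001" in sets.up10
        assert math.isinf(sets.fold_change["g001"])

    def test_both_zero_excluded(self):
        sets = self.make([0, 10], [0, 10])
        assert "g001" not in sets.fold_change

    def test_invariants(self):
        rngc = np.random.default_rng(4)
        control = rngc.integers(0, 300, 200).tolist()
        infect = rngc.integers(0, 300, 200).tolist()
        sets = self.make(control, infect)
        assert sets.up10 <= sets.up2
        assert sets.down10 <= sets.down2
        assert not sets.up2 & sets.down2

    def test_unknown_label_errors(self):
        t = make_table({"knob_1": [1], "inf_1": [2]}, COND2)
        with pytest.raises(ValueError):
            regulation_sets(t, "nope", "infection")


class TestTopExpressed:
    def test_forced_size(self):
        data = {"inf_1": list(range(1, 21)), "knob_1": [1] * 20}
        t = make_table(data, COND2)
        top = top_expressed(t, "infection", 0.1)
        assert top == {"g019", "g020"}

    def test_tie_break_lexicographic(self):
        t = make_table({"inf_1": [5] * 20, "knob_1": [5] * 20}, COND2)
        top = top_expressed(t, "infection", 0.1)
        assert top == {"g001", "g002"}

    def test_floor_rule_property(self):
        rngc = np.random.default_rng(3)
        for _ in range(20):
            n = int(rngc.integers(5, 80))
            data = {
                "inf_1": rngc.integers(1, 100, n).tolist(),
                "knob_1": rngc.integers(1, 100, n).tolist(),
            }
            t = make_table(data, COND2)
            assert len(top_expressed(t, "infection", 0.1)) == math.floor(0.1 * n)

    def test_zero_mean_excluded_from_universe(self):
        data = {"inf_1": [0] * 10 + [5] * 10, "knob_1": [1] * 20}
        t = make_table(data, COND2)
        top = top_expressed(t, "infection", 0.5)
        assert len(top) == 5  # floor(0.5 * 10 expressed)

    def test_fraction_validation(self):
        t = make_table({"inf_1": [1], "knob_1": [1]}, COND2)
        with pytest.raises(ValueError):
            top_expressed(t, "infection", 0.0)


def hypergeom_oracle(k: int, set_size: int, hits: int, n: int) -> float:
    """Exhaustive subset enumeration of P(X >= k)."""
    universe = range(n)
    hit_set = set(range(hits))
    good = total = 0
    for combo in itertools.combinations(universe, set_size):
        total += 1
        good += len(hit_set.intersection(combo)) >= k
    return good / total


class TestEnrichment:
    def test_hand_enumeration(self):
        assert enrichment_test(3, 3, 5, 10) == pytest.approx(10 / 120)

    def test_zero_hits_certain(self):
        assert enrichment_test(0, 4, 6, 12) == pytest.approx(1.0)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            enrichment_test(5, 3, 5, 10)
        with pytest.raises(ValueError):
            enrichment_test(2, 3, 1, 10)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_enumeration(self, n):
        for hits in range(n + 1):
            for set_size in range(1, n + 1):
                for k in range(0, min(hits, set_size) + 1):
                    expected = hypergeom_oracle(k, set_size, hits, n)
                    assert enrichment_test(k, set_size, hits, n) == pytest.approx(
                        expected, abs=1e-12
                    )


class TestInfectionReport:
    def test_secreted_percentage(self):
        sets, flags = focal_set_fixture(n_focal=117, n_secreted=75)
        report = infection_report(sets, flags)
        assert report["n_focal"] == 117
        assert report["secreted"]["n"] == 75
        assert report["secreted"]["pct"] == 64.0

    def test_expanded_percentage(self):
        sets, flags = focal_set_fixture(n_focal=117, n_expanded=36)
        assert infection_report(sets, flags)["expanded_family"]["pct"] == 31.0

    def test_empty_focal_set(self):
        flags = {"g1": GeneFlags("g1", protein_length=10)}
        sets = RegulationSets(
            frozenset(), frozenset(), frozenset(), frozenset(), {}, frozenset()
        )
        report = infection_report(sets, flags)
        assert report["n_focal"] == 0
        assert report["secreted"]["pct"] is None

    def test_enrichment_flagged(self):
        sets, flags = focal_set_fixture()
        report = infection_report(sets, flags, alpha=0.001)
        assert report["secreted"]["significant"] is True


class TestOrthologCompare:
    def test_exact_threshold_not_up(self):
        pairs = [OrthologPair("a", "b", 100.0, 10.0)]
        classes, _ = ortholog_compare(pairs, fold_threshold=10)
        assert classes[("a", "b")] == "neither"

    def test_up_and_down(self):
        pairs = [
            OrthologPair("a1", "b1", 101.0, 10.0),
            OrthologPair("a2", "b2", 1.0, 11.0),
        ]
        classes, summary = ortholog_compare(pairs)
        assert classes[("a1", "b1")] == "a_up"
        assert classes[("a2", "b2")] == "b_up"
        assert summary["n_significant"] is None

    def test_all_equal_neither(self):
        pairs = [OrthologPair(f"a{i}", f"b{i}", 5.0, 5.0) for i in range(10)]
        classes, summary = ortholog_compare(pairs)
        assert set(classes.values()) == {"neither"}
        assert summary["n_pairs"] == 10

    def test_double_zero_excluded_with_warning(self, caplog):
        pairs = [OrthologPair("a", "b", 0.0, 0.0)]
        with caplog.at_level("WARNING"):
            classes, summary = ortholog_compare(pairs)
        assert summary["n_pairs"] == 0
        assert any("excluded" in r.message for r in caplog.records)

    def test_zero_denominator_is_a_up(self):
        classes, _ = ortholog_compare([OrthologPair("a", "b", 3.0, 0.0)])
        assert classes[("a", "b")] == "a_up"

    def test_significant_fraction(self):
        _, summary = ortholog_compare(ortholog_fixture(8121, 2599))
        assert summary["n_significant"] == 2599
        assert summary["pct_significant"] == 32.0
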