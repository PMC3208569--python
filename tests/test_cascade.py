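"""Filtering cascade: stage semantics, attrition arithmetic, brute-force oracles."""

import pytest
from hypothesis import given, strategies as stn

from ancl_exome.cascade import (
    CascadeConfig,
    FilterTrace,
    attrition_table,
    filter_functional,
    filter_known_common,
    filter_quality,
    format_percent,
    run_cascade,
    shared_in_affecteds,
    subtract_samples,
    validation_fdr,
)
from ancl_exome.variant_io import SampleExome
from conftest import make_call, random_exome

CFG = CascadeConfig()


class TestQualityFilter:
    def test_depth_boundary_five(self):
        exome = SampleExome(
            "s", "affected",
            [make_call(1, depth=4), make_call(2, depth=5), make_call(3, depth=6)],
        )
        kept = filter_quality(exome, CFG)
        assert [c.depth for c in kept.calls] == [5, 6]

    def test_high_depth_identity(self):
        exome = SampleExome("s", "affected", [make_call(i, depth=100) for i in range(5)])
        assert len(filter_quality(exome, CFG)) == 5

    def test_missing_depth_kept_with_warning(self, caplog):
        exome = SampleExome("s", "affected", [make_call(1, depth=None, qual=None)])
        with caplog.at_level("WARNING"):
            kept = filter_quality(exome, CFG)
        assert len(kept) == 1
        assert "missing depth/qual" in caplog.text

    def test_matches_bruteforce_predicate(self, rng):
        exome = random_exome(rng, 300)
        kept = filter_quality(exome, CFG)
        brute = [c for c in exome.calls
                 if c.depth >= CFG.min_depth and c.qual >= CFG.min_qual]
        assert kept.key_set() == {c.key for c in brute}


class TestKnownCommonFilter:
    def test_het_five_percent_boundary(self):
        exome = SampleExome(
            "s", "affected",
            [
                make_call(1, db_flags={"dbSNP": 0.06}),
                make_call(2, db_flags={"dbSNP": 0.04}),
                make_call(3, db_flags={"dbSNP": 0.05}),  # equality keeps
            ],
        )
        kept = filter_known_common(exome, {}, CFG)
        assert [c.pos for c in kept.calls] == [1002, 1003]

    def test_hom_thirty_percent_threshold(self):
        exome = SampleExome(
            "s", "affected",
            [
                make_call(1, zygosity="hom", db_flags={"KG": 0.29}),
                make_call(2, zygosity="hom", db_flags={"KG": 0.31}),
                make_call(3, zygosity="het", db_flags={"KG": 0.29}),
            ],
        )
        kept = filter_known_common(exome, {}, CFG)
        assert [c.pos for c in kept.calls] == [1001]

    def test_empty_db_and_novel_calls_identity(self):
        exome = SampleExome("s", "affected", [make_call(i) for i in range(10)])
        assert len(filter_known_common(exome, {}, CFG)) == 10

    def test_external_db_overrides(self):
        call = make_call(1)
        exome = SampleExome("s", "affected", [call])
        assert len(filter_known_common(exome, {call.key: 0.5}, CFG)) == 0


class TestFunctionalFilter:
    def test_keeps_declared_classes_only(self):
        exome = SampleExome(
            "s", "affected",
            [
                make_call(1, var_class="missense"),
                make_call(2, var_class="intronic"),
                make_call(3, var_class="nonsense"),
            ],
        )
        kept = filter_functional(exome, CFG)
        assert {c.var_class for c in kept.calls} == {"missense", "nonsense"}

    def test_all_synonymous_gives_empty(self):
        exome = SampleExome("s", "affected",
                            [make_call(i, var_class="synonymous") for i in range(4)])
        assert len(filter_functional(exome, CFG)) == 0

    def test_matches_bruteforce_predicate(self, rng):
        exome = random_exome(rng, 300)
        kept = filter_functional(exome, CFG)
        brute = {c.key for c in exome.calls if c.var_class in CFG.functional_classes}
        assert kept.key_set() == brute


class TestSetStages:
    def test_disjoint_sets_intersect_empty(self):
        a = SampleExome("a", "affected", [make_call(i) for i in range(5)])
        b = SampleExome("b", "affected", [make_call(i + 10) for i in range(5)])
        assert shared_in_affecteds([a, b]) == set()

    def test_implanted_variant_in_intersection(self):
        shared_call = make_call(99)
        a = SampleExome("a", "affected", [make_call(1), shared_call])
        b = SampleExome("b", "affected", [make_call(11), shared_call])
        assert shared_call.key in shared_in_affecteds([a, b])

    def test_three_sets_equal_fold_of_pairwise(self, rng):
        exomes = [random_exome(rng, 150, sample_id=f"s{i}") for i in range(3)]
        result = shared_in_affecteds(exomes)
        fold = (exomes[0].key_set() & exomes[1].key_set()) & exomes[2].key_set()
        assert result == fold

    def test_subtract_removes_control_half(self):
        calls = [make_call(i) for i in range(10)]
        shared = {c.key for c in calls}
        control = SampleExome("c", "unaffected", calls[:5])
        assert subtract_samples(shared, [control]) == {c.key for c in calls[5:]}

    def test_empty_panel_identity(self):
        shared = {make_call(i).key for i in range(5)}
        assert subtract_samples(shared, []) == shared

    def test_subtraction_matches_bruteforce_difference(self, rng):
        shared = random_exome(rng, 200).key_set()
        cohort = [random_exome(rng, 100, sample_id=f"p{i}") for i in range(4)]
        result = subtract_samples(shared, cohort)
        brute = set(shared)
        for ex in cohort:
            brute = brute - ex.key_set()
        assert result == brute

    def test_subtraction_order_independent(self, rng):
        shared = random_exome(rng, 200).key_set()
        control = [random_exome(rng, 80, sample_id="ctl")]
        panel = [random_exome(rng, 80, sample_id="pnl")]
        ab = subtract_samples(subtract_samples(shared, control), panel)
        ba = subtract_samples(subtract_samples(shared, panel), control)
        assert ab == ba


class TestAttrition:
    def test_published_percent_cells(self):
        trace = FilterTrace()
        trace.add("total", 38179)
        trace.add("shared", 96)
        trace.add("unique", 24)
        pct = attrition_table(trace, 38179)
        assert format_percent(pct[0]) == "100"
        assert format_percent(pct[1]) == "0.25"
        assert format_percent(pct[2]) == "0.06"

    def test_one_decimal_above_one_percent(self):
        assert format_percent(100.0 * 674 / 38179) == "1.8"
        assert format_percent(100.0 * 9202 / 38142) == "24.1"

    def test_denominator_equal_gives_100(self):
        trace = FilterTrace()
        trace.add("only", 7)
        assert attrition_table(trace, 7) == [100.0]

    def test_trace_rejects_increasing_counts(self):
        trace = FilterTrace()
        trace.add("a", 10)
        with pytest.raises(ValueError, match="exceeds"):
            trace.add("b", 11)

    def test_percent_series_non_increasing(self, rng):
        trace = FilterTrace()
        n = 1000
        while n > 0:
            trace.add(f"s{n}", n)
            n = int(n * rng.random())
        pct = trace.percent_remaining(1000)
        assert all(a >= b for a, b in zip(pct, pct[1:]))
        assert all(0 <= p <= 100 for p in pct)


class TestValidationFdr:
    @pytest.mark.parametrize(
        "tested,failed,expected",
        [(22, 1, 0.045), (10, 0, 0.0), (7, 7, 1.0)],
    )
    def test_examples(self, tested, failed, expected):
        assert round(validation_fdr(tested, failed), 3) == expected

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            validation_fdr(0, 0)
        with pytest.raises(ValueError):
            validation_fdr(5, 6)


class TestFullCascadeOracle:
    @given(stn.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_bruteforce_on_random_cohorts(self, seed):
        """Whole-cascade output equals direct set algebra over predicates."""
        import numpy as np

        rng = np.random.default_rng(seed)
        n = 330
        exomes = [random_exome(rng, n, sample_id=f"a{i}") for i in range(2)]
        ctrl = [random_exome(rng, n, sample_id="c", status="unaffected")]
        final, trace = run_cascade(exomes, ctrl, [], {}, CFG)

        def survives(c):
            return (
                c.depth >= CFG.min_depth
                and c.qual >= CFG.min_qual
                and c.var_class in CFG.functional_classes
                and not (
                    c.max_db_freq() is not None
                    and c.max_db_freq()
                    > (CFG.hom_freq_max if c.zygosity == "hom" else CFG.het_freq_max)
                )
            )

        brute = {c.key for c in exomes[0].calls if survives(c)}
        brute &= {c.key for c in exomes[1].calls if survives(c)}
        brute -= ctrl[0].key_set()
        assert final == brute
        assert trace.counts() == sorted(trace.counts(), reverse=True)
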