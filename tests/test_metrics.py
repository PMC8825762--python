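"""Primary metrics M1-M12, secondary groups and rank totalling."""

import itertools

import pytest

from orfeval import (
    Annotation,
    GenomeSequence,
    MetricsBundle,
    compute_primary,
    compute_secondary,
    match_annotations,
    percentage_difference,
    rank_tools,
)
from orfeval.core import UndefinedValueError

from conftest import F


def evaluate(reference, predictions, **kw):
    report = match_annotations(reference, predictions)
    return compute_primary(report, reference, predictions, **kw), report


class TestPercentageDifference:
    @pytest.mark.parametrize("pred,ref,expected", [
        (5, 5, 0.0),
        (2073, 1251, 65.71),   # over- vs reference overlap counts
        (71, 2478, -97.13),    # severe underprediction
    ])
    def test_worked_values(self, pred, ref, expected):
        assert percentage_difference(pred, ref) == pytest.approx(expected, abs=0.005)

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedValueError):
            percentage_difference(5, 0)


def identity_reference(n=10):
    """Spaced genes plus one short gene overlapping the first, so every
    percentage-difference metric has a defined reference count."""
    feats = [F(1 + 400 * i, 400 * i + 300, strand="+-"[i % 2]) for i in range(n)]
    feats.append(F(150, 299, strand="-"))
    return Annotation(feats)


class TestComputePrimary:
    def test_reference_vs_itself_identity_values(self):
        ref = identity_reference()
        bundle, _ = evaluate(ref, ref)
        expected = dict(m1=100, m2=100, m3=0, m4=0, m5=100, m6=0,
                        m7=0, m8=0, m9=0, m10=100, m11=100, m12=0)
        for name, value in expected.items():
            assert getattr(bundle, name) == pytest.approx(value), name

    def test_planted_80_exact_20_missed_10_spurious(self):
        genes = [F(1 + 1000 * i, 1000 * i + 600) for i in range(100)]
        preds = [F(g.start, g.end) for g in genes[:80]]
        preds += [F(100_201 + 1000 * i, 100_201 + 1000 * i + 599, strand="-")
                  for i in range(10)]
        bundle, _ = evaluate(Annotation(genes), Annotation(preds))
        assert bundle.m1 == pytest.approx(80.0)
        assert bundle.m2 == pytest.approx(88.89, abs=0.005)
        assert bundle.m5 == pytest.approx(100.0)
        assert bundle.m10 == pytest.approx(88.89, abs=0.005)
        assert bundle.m11 == pytest.approx(80.0)
        assert bundle.m12 == pytest.approx(11.11, abs=0.005)

    def test_uniform_plus_six_start_shift_gives_m6_two_codons(self):
        genes = [F(1000 + 1000 * i, 1000 * i + 1599) for i in range(20)]
        preds = [F(g.start - 6, g.end) for g in genes]
        bundle, _ = evaluate(Annotation(genes), Annotation(preds))
        assert bundle.m6 == pytest.approx(2.0)
        assert bundle.m7 == pytest.approx(0.0)
        assert bundle.m5 == pytest.approx(0.0)

    def test_precision_plus_fdr_is_100(self):
        genes = Annotation([F(1, 300), F(400, 699)])
        preds = Annotation([F(1, 300), F(900, 1199)])
        bundle, _ = evaluate(genes, preds)
        assert bundle.m10 + bundle.m12 == pytest.approx(100.0)

    def test_m1_equals_m11_under_one_to_one_matching(self):
        genes = [F(1 + 500 * i, 500 * i + 300) for i in range(30)]
        preds = [F(g.start + (3 if i % 3 == 0 else 0), g.end)
                 for i, g in enumerate(genes[:25])]
        bundle, _ = evaluate(Annotation(genes), Annotation(preds))
        assert bundle.m1 == pytest.approx(bundle.m11)

    def test_spurious_predictions_degrade_precision_monotonically(self):
        genes = [F(1 + 500 * i, 500 * i + 300) for i in range(10)]
        base = [F(g.start, g.end) for g in genes]
        prev_m10, prev_m12 = 100.0, 0.0
        for n_spurious in (0, 3, 6):
            spurious = [F(20_001 + 500 * i, 20_001 + 500 * i + 299, strand="-")
                        for i in range(n_spurious)]
            bundle, _ = evaluate(Annotation(genes), Annotation(base + spurious))
            assert bundle.m10 <= prev_m10 + 1e-9
            assert bundle.m12 >= prev_m12 - 1e-9
            prev_m10, prev_m12 = bundle.m10, bundle.m12

    def test_matched_overlapping_all_detected_gives_m8_zero(self):
        # 5 overlapping pairs (opposite strands), every gene hit exactly
        genes = []
        for i in range(5):
            a = F(1 + 2000 * i, 2000 * i + 900)
            b = F(a.end - 29, a.end - 29 + 599, strand="-")
            genes += [a, b]
        ref = Annotation(genes)
        bundle, report = evaluate(ref, ref)
        assert bundle.m8 == pytest.approx(0.0)
        sec = compute_secondary(report, ref, ref)
        assert sec.matched_overlapping_count == 10
        assert sec.overlapping_ref_count == 10

    def test_m9_short_counts(self):
        short = [F(1 + 400 * i, 400 * i + 150) for i in range(4)]   # 150 nt
        long = [F(10_001 + 1000 * i, 10_001 + 1000 * i + 899) for i in range(6)]
        ref = Annotation(short + long)
        preds = Annotation([F(f.start, f.end) for f in short[:2] + long])
        bundle, _ = evaluate(ref, preds)
        # 2 matched short predictions vs 4 short reference genes
        assert bundle.m9 == pytest.approx(-50.0)

    def test_zero_predictions_propagate_na_not_zero(self):
        bundle, _ = evaluate(identity_reference(3), Annotation())
        assert bundle.m2 is None and bundle.m10 is None and bundle.m12 is None
        assert bundle.m5 is None  # nothing detected
        assert bundle.m1 == 0.0

    def test_m5_all_genes_variant(self):
        genes = [F(1 + 500 * i, 500 * i + 300) for i in range(4)]
        preds = [F(genes[0].start, genes[0].end), F(genes[1].start - 3, genes[1].end)]
        bundle, _ = evaluate(Annotation(genes), Annotation(preds))
        assert bundle.m5 == pytest.approx(50.0)  # 1 perfect of 2 detected
        bundle_all, _ = evaluate(Annotation(genes), Annotation(preds),
                                 m5_denominator="all")
        assert bundle_all.m5 == pytest.approx(25.0)


class TestComputeSecondary:
    def test_all_perfect_categories(self):
        ref = identity_reference(4)
        _, report = evaluate(ref, ref)
        sec = compute_secondary(report, ref, ref)
        assert set(sec.length_by_category) == {"PERFECT", "detected"}

    def test_missed_genes_lower_gc_is_recovered(self):
        # plant detected genes GC-rich and missed genes GC-poor
        seq = ["A"] * 10_000
        genes, preds = [], []
        for i in range(10):
            start = 1 + 600 * i
            rich = i < 5
            body = ("GGCC" if rich else "ATAT") * 75
            seq[start - 1 : start - 1 + 300] = list(body)
            g = F(start, start + 299)
            genes.append(g)
            if rich:
                preds.append(F(g.start, g.end))
        genome = GenomeSequence({"c": "".join(seq)})
        ref = Annotation(genes)
        _, report = evaluate(ref, Annotation(preds))
        sec = compute_secondary(report, ref, Annotation(preds), genome)
        assert sec.gc_by_category["MISSED"] < sec.gc_by_category["detected"]

    def test_encompassed_missed_genes_counted(self):
        genes = Annotation([F(100, 399), F(502, 699)])
        preds = Annotation([F(100, 699)])
        _, report = evaluate(genes, preds)
        sec = compute_secondary(report, genes, preds)
        assert sec.count_genes_encompassed == 1


def bundle_of(**kw):
    values = dict.fromkeys(MetricsBundle().as_dict(), 0.0)
    values.update(kw)
    return MetricsBundle(**values)


class TestRankTools:
    def test_single_tool_summed_rank(self):
        bundles = {"only": {"g1": bundle_of(), "g2": bundle_of()}}
        table = rank_tools(bundles)
        assert table.summed["only"] == 12 * 2

    def test_dominated_tool_ranks_second_everywhere(self):
        good = bundle_of(m1=99, m2=99, m5=95, m10=99, m11=99,
                         m3=1, m4=-1, m8=-2, m9=2, m6=1, m7=0, m12=1)
        bad = bundle_of(m1=50, m2=60, m5=40, m10=60, m11=50,
                        m3=40, m4=-30, m8=-60, m9=80, m6=9, m7=4, m12=40)
        table = rank_tools({"good": {"g": good}, "bad": {"g": bad}})
        assert table.summed == {"good": 12.0, "bad": 24.0}
        assert table.ordering == ["good", "bad"]

    def test_matches_sort_based_oracle_and_permutation_invariance(self):
        bundles = {
            "a": {"g": bundle_of(m1=90, m3=-5, m6=2, m12=10)},
            "b": {"g": bundle_of(m1=95, m3=8, m6=1, m12=5)},
            "c": {"g": bundle_of(m1=90, m3=2, m6=4, m12=20)},
        }
        table = rank_tools(bundles)

        def oracle(metric, key):
            vals = {t: key(getattr(bundles[t]["g"], metric)) for t in bundles}
            out = {}
            for t, v in vals.items():
                less = sum(1 for w in vals.values() if w < v)
                eq = sum(1 for w in vals.values() if w == v)
                out[t] = less + (eq + 1) / 2
            return out

        assert table.ranks[("g", "m1")] == oracle("m1", lambda v: -v)
        assert table.ranks[("g", "m3")] == oracle("m3", abs)
        assert table.ranks[("g", "m6")] == oracle("m6", lambda v: v)
        assert table.ranks[("g", "m12")] == oracle("m12", lambda v: v)

        for perm in itertools.permutations(bundles):
            assert rank_tools({t: bundles[t] for t in perm}).summed == table.summed

    def test_missing_genome_and_na_rank_worst(self):
        bundles = {
            "full": {"g1": bundle_of(m1=80), "g2": bundle_of(m1=80)},
            "partial": {"g1": bundle_of(m1=90)},  # no g2 bundle at all
        }
        table = rank_tools(bundles)
        assert table.ranks[("g2", "m1")]["partial"] == 2.0
        assert table.ranks[("g1", "m1")]["partial"] == 1.0
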