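"""Evaluation measures, continuous mode, permutation null, summary output."""

from __future__ import annotations

import math

import numpy as np
import pytest

from crmscan.evaluate import (
    EvaluationInput,
    evaluate_continuous,
    evaluate_fixed,
    expression_pattern_precision,
    expression_pattern_recall,
    permutation_null,
    prepare_reference,
    redfly_recall,
    redfly_recovery,
    training_set_sensitivity,
    write_summary,
)
from crmscan.intervals import (
    CrmRecord,
    GenomeSpace,
    GenomicInterval,
    shuffle_intervals,
)


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


def rec(chrom, start, end, *terms):
    return CrmRecord(iv(chrom, start, end), frozenset(terms))


SPACE = GenomeSpace({"c1": 100_000, "c2": 100_000})


class TestPrepareReference:
    def test_two_kb_records_dropped(self):
        # the database inclusion rule is strictly "< 2 kb"
        refs = [rec("c1", 0, 2000), rec("c1", 5000, 6999)]
        merged, expr = prepare_reference(refs)
        assert merged == [iv("c1", 5000, 6999)]
        assert [r.interval.length for r in expr] == [1999]

    def test_training_crms_filtered(self):
        refs = [rec("c1", 0, 1000), rec("c1", 5000, 6000)]
        merged, _ = prepare_reference(refs, training_crms=[iv("c1", 0, 1000)])
        assert merged == [iv("c1", 5000, 6000)]

    def test_half_length_sharing_rule(self):
        # 40% of the reference CRM's own length shared: retained
        refs = [rec("c1", 0, 1000)]
        merged, _ = prepare_reference(refs, training_crms=[iv("c1", 600, 2000)])
        assert merged == [iv("c1", 0, 1000)]
        merged2, _ = prepare_reference(refs, training_crms=[iv("c1", 500, 2000)])
        assert merged2 == []

    def test_no_training_set(self):
        refs = [rec("c1", 0, 1000)]
        merged, expr = prepare_reference(refs)
        assert merged == [iv("c1", 0, 1000)] and len(expr) == 1


class TestMeasures:
    def test_recovery_is_fraction_of_predictions(self):
        preds = [iv("c1", 0, 500), iv("c1", 5000, 5500), iv("c2", 0, 500)]
        merged = [iv("c1", 0, 500)]
        assert redfly_recovery(preds, merged, 0.10) == pytest.approx(100 / 3)

    def test_recovery_identity_is_100(self):
        preds = [iv("c1", 0, 500), iv("c2", 0, 400)]
        assert redfly_recovery(preds, preds, 0.10) == 100.0

    def test_recovery_empty_predictions_na(self):
        assert math.isnan(redfly_recovery([], [iv("c1", 0, 10)], 0.1))

    def test_recall_counts_distinct_reference(self):
        preds = [iv("c1", 0, 500)]
        merged = [iv("c1", 0, 500), iv("c2", 0, 500)]
        assert redfly_recall(preds, merged, 0.10) == 50.0
        assert math.isnan(redfly_recall(preds, [], 0.1))

    def test_sensitivity_counts_distinct_training_crms(self):
        # three predictions tiling one of two training CRMs: 50%, not 150%
        training = [iv("c1", 0, 1000), iv("c2", 0, 1000)]
        preds = [iv("c1", 0, 500), iv("c1", 250, 750), iv("c1", 500, 1000)]
        assert training_set_sensitivity(preds, training, 0.10) == 50.0

    def test_sensitivity_extremes(self):
        training = [iv("c1", 0, 500)]
        assert training_set_sensitivity(training, training, 0.1) == 100.0
        assert training_set_sensitivity([iv("c2", 0, 500)], training, 0.1) == 0.0

    def test_precision_counts_each_prediction_once(self):
        expr = [rec("c1", 0, 1000, "gut"), rec("c1", 500, 1500, "cns")]
        # one prediction hits both records; correct if ANY hit carries the term
        preds = [iv("c1", 400, 900)]
        assert expression_pattern_precision(preds, expr, "gut", 0.1) == 100.0
        assert expression_pattern_precision(preds, expr, "wing", 0.1) == 0.0

    def test_precision_na_when_no_annotated_hit(self):
        expr = [rec("c1", 0, 1000, "gut")]
        assert math.isnan(
            expression_pattern_precision([iv("c2", 0, 500)], expr, "gut", 0.1)
        )

    def test_precision_denominator_ignores_unannotated(self):
        expr = [rec("c1", 0, 1000, "gut"), rec("c2", 0, 1000)]  # second has no terms
        preds = [iv("c1", 0, 500), iv("c2", 0, 500)]
        assert expression_pattern_precision(preds, expr, "gut", 0.1) == 100.0

    def test_recall_of_target_term_records(self):
        expr = [rec("c1", 0, 1000, "gut"), rec("c2", 0, 1000, "gut"), rec("c2", 5000, 6000, "cns")]
        preds = [iv("c1", 0, 500)]
        assert expression_pattern_recall(preds, expr, "gut", 0.1) == 50.0
        assert math.isnan(expression_pattern_recall(preds, expr, "wing", 0.1))

    def test_hand_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        expr = [
            rec("c1", int(s), int(s) + 300, t)
            for s, t in zip(rng.integers(0, 5000, 12), ["gut", "cns"] * 6)
        ]
        preds = [iv("c1", int(s), int(s) + 200) for s in rng.integers(0, 5000, 15)]
        got = expression_pattern_precision(preds, expr, "gut", 0.5)
        num = den = 0
        for p in preds:
            hits = [r for r in expr if p.overlap_len(r.interval) / p.length >= 0.5 and r.terms]
            if hits:
                den += 1
                if any("gut" in r.terms for r in hits):
                    num += 1
        expected = 100 * num / den if den else math.nan
        assert got == pytest.approx(expected)


class TestEvaluateFixed:
    def _input(self, **kw):
        refs = [rec("c1", 0, 800, "gut"), rec("c1", 5000, 5800, "cns"), rec("c2", 0, 800)]
        defaults = dict(
            predictions=[iv("c1", 0, 500), iv("c1", 5100, 5600), iv("c2", 9000, 9500)],
            reference_crms=refs,
            space=SPACE,
            training_crms=[iv("c1", 0, 800)],
            target_term="gut",
        )
        defaults.update(kw)
        return EvaluationInput(**defaults)

    def test_component_consistency(self):
        inp = self._input()
        ms = evaluate_fixed(inp)
        merged, expr = prepare_reference(inp.reference_crms, inp.training_crms)
        assert ms.redfly_recovery == redfly_recovery(inp.predictions, merged, 0.1)
        assert ms.training_set_sensitivity == 100.0
        assert ms.n_predictions == 3

    def test_missing_inputs_yield_na(self):
        ms = evaluate_fixed(self._input(training_crms=None, target_term=None))
        assert math.isnan(ms.training_set_sensitivity)
        assert math.isnan(ms.expression_pattern_precision)
        assert not math.isnan(ms.redfly_recovery)

    def test_duplicate_predictions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            self._input(predictions=[iv("c1", 0, 500), iv("c1", 0, 500)])

    def test_measure_monotone_in_min_frac(self):
        rng = np.random.default_rng(8)
        preds = [iv("c1", int(s), int(s) + 400) for s in rng.integers(0, 50_000, 40)]
        preds = list({(p.chrom, p.start): p for p in preds}.values())
        refs = [rec("c1", int(s), int(s) + 600, "gut") for s in rng.integers(0, 50_000, 30)]
        lo = evaluate_fixed(self._input(predictions=preds, reference_crms=refs, min_frac=0.1))
        hi = evaluate_fixed(self._input(predictions=preds, reference_crms=refs, min_frac=0.5))
        for name in ("redfly_recovery", "redfly_recall"):
            a, b = getattr(hi, name), getattr(lo, name)
            if not (math.isnan(a) or math.isnan(b)):
                assert a <= b


class TestEvaluateContinuous:
    def test_every_250_to_1000(self):
        preds = [iv("c1", i * 600, i * 600 + 500) for i in range(166)] + [
            iv("c2", i * 600, i * 600 + 500) for i in range(166)
        ]
        preds = preds[:1000] if len(preds) >= 1000 else preds
        inp = EvaluationInput(
            predictions=preds,
            reference_crms=[rec("c1", 0, 800, "gut")],
            space=SPACE,
        )
        rows = evaluate_continuous(inp, step=250, max_n=7000)
        # 332 predictions -> buckets at 250 plus the final partial bucket
        assert [n for n, _ in rows] == [250, len(preds)]

    def test_bucket_equals_fixed_on_prefix(self):
        rng = np.random.default_rng(4)
        preds = list(
            {
                (int(s)): iv("c1", int(s), int(s) + 300)
                for s in rng.integers(0, 90_000, 120)
            }.values()
        )
        refs = [rec("c1", int(s), int(s) + 500, "gut") for s in rng.integers(0, 90_000, 40)]
        inp = EvaluationInput(predictions=preds, reference_crms=refs, space=SPACE)
        rows = evaluate_continuous(inp, step=50, max_n=100)
        for n, ms in rows:
            fixed = evaluate_fixed(
                EvaluationInput(predictions=preds[:n], reference_crms=refs, space=SPACE)
            )
            assert ms.redfly_recovery == fixed.redfly_recovery

    def test_bad_step(self):
        inp = EvaluationInput(predictions=[], reference_crms=[], space=SPACE)
        with pytest.raises(ValueError):
            evaluate_continuous(inp, step=0)


class TestPermutationNull:
    def test_degenerate_reference_covers_genome(self):
        # every placement scores 100%: sd 0, z undefined
        space = GenomeSpace({"c1": 10_000})
        inp = EvaluationInput(
            predictions=[iv("c1", 0, 500)],
            reference_crms=[rec("c1", 0, 1999), *(rec("c1", s, s + 1999) for s in range(1999, 10_000 - 1999, 1999))],
            space=space,
        )
        # reference tiles nearly the whole chromosome; use full overlap of tiny frac
        null = permutation_null(inp, "redfly_recovery", n_perm=20, seed=0)
        assert null.null_sd == 0.0
        assert math.isnan(null.z)

    def test_deterministic_given_seed(self):
        inp = EvaluationInput(
            predictions=[iv("c1", 0, 500), iv("c1", 8000, 8600)],
            reference_crms=[rec("c1", 0, 800, "gut")],
            space=SPACE,
        )
        a = permutation_null(inp, "redfly_recovery", n_perm=25, seed=3)
        b = permutation_null(inp, "redfly_recovery", n_perm=25, seed=3)
        assert (a.null_mean, a.null_sd, a.z) == (b.null_mean, b.null_sd, b.z)

    def test_unknown_measure(self):
        inp = EvaluationInput(predictions=[], reference_crms=[], space=SPACE)
        with pytest.raises(ValueError):
            permutation_null(inp, "f1_score")

    def test_random_predictions_are_calibrated(self, small_fixture):
        """Shuffled predictions should score like their own null: |z| small."""
        genome, truth = small_fixture
        space = GenomeSpace(
            {c: len(s) for c, s in genome.items()}, list(truth.exons)
        )
        base = [r.interval for r in truth.planted[:40]]
        rng = np.random.default_rng(99)
        zs = []
        for _ in range(20):
            drawn = shuffle_intervals(base, space, rng)
            drawn = list({(d.chrom, d.start, d.end): d for d in drawn}.values())
            inp = EvaluationInput(
                predictions=drawn, reference_crms=truth.database, space=space
            )
            null = permutation_null(
                inp, "redfly_recovery", n_perm=100, seed=int(rng.integers(2**31))
            )
            if not math.isnan(null.z):
                zs.append(abs(null.z))
        assert np.mean(zs) < 1.5


class TestWriteSummary:
    def test_round_trip_bit_exact(self, tmp_path):
        import pandas as pd

        rows = [
            {"set": "a", "n": 100, "recovery": 32.125, "z": float("nan")},
            {"set": "b", "n": 200, "recovery": 15.0, "z": 3.25},
        ]
        p = tmp_path / "summary.tsv"
        write_summary(rows, p, header=["seed=1"])
        df = pd.read_csv(p, sep="\t", comment="#")
        assert df.loc[0, "recovery"] == 32.125
        assert pd.isna(df.loc[0, "z"])
        assert df.loc[1, "z"] == 3.25
        assert (p.read_text().splitlines()[1]).startswith("set\t")
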