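"""Markov scorer: training closed forms, window scores, scanning, elbow."""

from __future__ import annotations

import math

import numpy as np
import pytest

from crmscan.intervals import GenomicInterval
from crmscan.scoring import (
    MarkovModel,
    ScanConfig,
    ScoredWindow,
    default_top_predictions,
    elbow_index,
    extract_noncoding,
    scan,
    score_window,
    take_top,
    train_markov,
)


def uniform_model(order=0):
    k = order
    log_cond = np.full((4**k, 4), math.log(0.25))
    return MarkovModel(order=k, log_cond=log_cond, pseudocount=1.0)


class TestTrainMarkov:
    def test_order0_closed_form(self):
        # "AAAA" gives 4 A observations; with pseudocount 1 per cell,
        # P(A) = (4+1)/(4+4)
        m = train_markov(["AAAA"], order=0, pseudocount=1.0)
        assert m.probs[0, 0] == pytest.approx(5 / 8)
        assert m.probs[0, 1] == pytest.approx(1 / 8)

    def test_law_of_large_numbers_on_uniform_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        m = train_markov([seq], order=0)
        assert np.all(np.abs(m.probs - 0.25) < 0.01)

    def test_empty_training_is_pure_pseudocount(self):
        m = train_markov([], order=2)
        assert np.allclose(m.probs, 0.25)

    def test_revcomp_pooling(self):
        # with reverse-complement pooling "AAAA" also contributes "TTTT"
        m = train_markov(["AAAA"], order=0, include_revcomp=True)
        assert m.probs[0, 0] == pytest.approx(5 / 12)
        assert m.probs[0, 3] == pytest.approx(5 / 12)

    def test_contexts_with_n_excluded(self):
        m = train_markov(["ANAA"], order=1)
        # only the (A->?) transitions not involving N are counted: none fully valid
        # except... "AN" invalid, "NA" invalid, "AA" valid -> one count for A|A
        assert m.probs[0, 0] == pytest.approx(2 / 5)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            train_markov(["ACGT"], order=-1)

    def test_short_training_warns(self):
        with pytest.warns(UserWarning, match="pseudocount"):
            train_markov(["ACGT"], order=4)


class TestScoreWindow:
    def test_identical_models_score_zero(self):
        m = train_markov(["ACGTACGTGGCC"], order=1)
        assert score_window("ACGTACGT", m, m) == 0.0

    def test_swapping_models_negates(self):
        a = train_markov(["AAAACCCC"], order=0)
        b = train_markov(["GGGGTTTT"], order=0)
        s = score_window("ACGTAACC", a, b)
        assert score_window("ACGTAACC", b, a) == pytest.approx(-s)

    def test_all_n_window_is_na(self):
        m = uniform_model()
        assert math.isnan(score_window("NNNNNNNN", m, m))

    def test_too_short_sequence(self):
        m = uniform_model(order=3)
        with pytest.raises(ValueError, match="order"):
            score_window("AC", m, m)

    def test_sequences_from_crm_model_score_positive(self):
        # KL divergence positivity: data drawn from the CRM model scores > 0
        rng = np.random.default_rng(1)
        probs = np.array([0.4, 0.3, 0.2, 0.1])
        bg = np.array([0.25, 0.25, 0.25, 0.25])
        crm_m = MarkovModel(0, np.log(probs)[None, :], 1.0)
        bg_m = MarkovModel(0, np.log(bg)[None, :], 1.0)
        scores = []
        for _ in range(100):
            seq = "".join(np.array(list("ACGT"))[rng.choice(4, 200, p=probs)])
            scores.append(score_window(seq, crm_m, bg_m))
        assert np.mean(scores) > 0


class TestExtractNoncoding:
    def test_exon_splits_chromosome(self):
        genome = {"c1": "A" * 1000}
        segs = extract_noncoding(genome, [GenomicInterval("c1", 400, 600)])
        assert [(s[0].start, s[0].end) for s in segs] == [(0, 400), (600, 1000)]
        assert all(len(seq) == seg.length for seg, seq in segs)

    def test_no_exons(self):
        segs = extract_noncoding({"c1": "ACGT" * 10}, [])
        assert [(s[0].start, s[0].end) for s in segs] == [(0, 40)]

    def test_fully_exonic(self):
        segs = extract_noncoding({"c1": "ACGT"}, [GenomicInterval("c1", 0, 4)])
        assert segs == []


class TestScan:
    def _genome(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return {"c1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])}

    def test_window_starts_default(self):
        m = uniform_model()
        wins = scan(self._genome(), [], m, m, ScanConfig(window=500, shift=250, offset=0))
        assert [w.interval.start for w in wins] == [0, 250, 500]

    def test_window_starts_offset_125(self):
        m = uniform_model()
        wins = scan(self._genome(), [], m, m, ScanConfig(window=500, shift=250, offset=125))
        assert [w.interval.start for w in wins] == [125, 375]

    def test_union_of_hd_offsets_covers_every_10bp_position(self):
        m = uniform_model()
        genome = self._genome(3000)
        starts = set()
        for off in range(0, 250, 10):
            wins = scan(genome, [], m, m, ScanConfig(window=500, shift=250, offset=off))
            for w in wins:
                assert w.offset == off
                assert (w.interval.start - off) % 250 == 0
            starts.update(w.interval.start for w in wins)
        assert starts == set(range(0, 3000 - 500 + 1, 10))

    def test_offset_counted_from_segment_start(self):
        m = uniform_model()
        genome = self._genome(2000)
        exons = [GenomicInterval("c1", 0, 730)]
        wins = scan(genome, exons, m, m, ScanConfig(window=500, shift=250, offset=20))
        assert [w.interval.start for w in wins] == [750, 1000, 1250, 1500]

    def test_n_heavy_windows_dropped(self):
        rng = np.random.default_rng(3)
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)]))
        seq[250:350] = "N" * 100  # 100 N in the [0,500) and [250,750) windows
        genome = {"c1": "".join(seq)}
        m = uniform_model()
        wins = scan(genome, [], m, m, ScanConfig(window=500, shift=250, offset=0))
        # windows with >10% N (here 20%) are dropped
        assert [w.interval.start for w in wins] == [500]


class TestTakeTop:
    def test_descending_order(self):
        wins = [
            ScoredWindow(GenomicInterval("c1", s, s + 500), sc, 0)
            for s, sc in [(0, 1.0), (250, 3.0), (500, 2.0)]
        ]
        top = take_top(wins, 3)
        assert [w.score for w in top] == [3.0, 2.0, 1.0]

    def test_truncation(self):
        wins = [
            ScoredWindow(GenomicInterval("c1", i * 250, i * 250 + 500), float(i), 0)
            for i in range(6000)
        ]
        assert len(take_top(wins, 5000)) == 5000

    def test_tie_broken_by_coordinates(self):
        wins = [
            ScoredWindow(GenomicInterval(c, s, s + 500), 1.0, 0)
            for c, s in [("c2", 0), ("c1", 250), ("c1", 0)]
        ]
        top = take_top(wins, 2)
        assert [(w.interval.chrom, w.interval.start) for w in top] == [("c1", 0), ("c1", 250)]


class TestElbow:
    def test_linear_curve_ties_to_first(self):
        assert elbow_index([10, 8, 6, 4, 2]) == 0

    def test_hand_computed_knee(self):
        assert elbow_index([10, 9, 8, 1, 0.9, 0.8]) == 3

    def test_flat_curve(self):
        assert elbow_index([2.0, 2.0, 2.0, 2.0]) == 0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            elbow_index([3, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = np.sort(rng.random(rng.integers(3, 60)))[::-1]
        got = elbow_index(v)
        # independent oracle: explicit point-to-chord distance on the
        # normalized curve
        x = np.arange(len(v)) / (len(v) - 1)
        rngv = v.max() - v.min()
        y = (v - v.min()) / rngv if rngv else np.zeros_like(v)
        p1 = np.array([x[0], y[0]])
        p2 = np.array([x[-1], y[-1]])
        d = []
        for xi, yi in zip(x, y):
            num = abs(
                (p2[1] - p1[1]) * xi - (p2[0] - p1[0]) * yi + p2[0] * p1[1] - p2[1] * p1[0]
            )
            d.append(num / np.hypot(*(p2 - p1)))
        assert got == int(np.argmax(d))


class TestDefaultTopPredictions:
    def _wins(self, scores):
        return [
            ScoredWindow(GenomicInterval("c1", i * 250, i * 250 + 500), s, 0)
            for i, s in enumerate(scores)
        ]

    def test_flat_scores_keep_everything(self):
        got = default_top_predictions(self._wins([1.0, 1.0, 1.0, 1.0]))
        assert len(got) == 4

    def test_two_regime_curve_keeps_high_plateau(self):
        got = default_top_predictions(self._wins([5.0, 5.0, 5.0, 0.1, 0.1, 0.1]))
        assert len(got) == 3
        assert all(g.score == 5.0 for g in got)

    def test_result_is_prefix_of_ranked_list(self):
        rng = np.random.default_rng(7)
        wins = self._wins(list(rng.random(50)))
        got = default_top_predictions(wins)
        ranked = take_top(wins, len(wins))
        assert [g.start for g in got] == [w.interval.start for w in ranked[: len(got)]]
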