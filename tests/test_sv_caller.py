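"""Window-based discordant-pair SV detection and breakpoint refinement."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from invseek import sv_caller as svc
from invseek.synthetic_data import InsertSizeModel, simulate_matepairs


def _records(pos1, pos2, strand1="+", strand2="+", mapped=True):
    n = len(pos1)
    pos1 = np.asarray(pos1)
    pos2 = np.asarray(pos2)
    rl = 50
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(n)],
            "source_allele": "x",
            "truth_span": 0,
            "a1": 0,
            "a2": 0,
            "mapped1": mapped,
            "pos1": pos1,
            "strand1": strand1,
            "mapped2": mapped,
            "pos2": pos2,
            "strand2": strand2,
            "inferred_span": np.maximum(pos1, pos2) + rl - np.minimum(pos1, pos2),
        }
    )


class TestEstimateInsertModel:
    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(21)
        spans = rng.normal(3900, 300, 10_000)
        pos1 = rng.integers(0, 1_000_000, 10_000)
        rec = _records(pos1, pos1 + spans.astype(int) - 50)
        model = svc.estimate_insert_model(rec)
        assert 3850 <= model.mean <= 3950
        assert 270 <= model.sd <= 330

    def test_roundtrip_on_simulated_wildtype(self, toy_arch, alleles, insert_model):
        rec = simulate_matepairs({"r": 2}, alleles, 300_000, insert_model, 2.0, seed=22)
        model = svc.estimate_insert_model(rec)
        assert abs(model.mean - insert_model.mean) / insert_model.mean < 0.02

    def test_constant_spans_flagged_degenerate(self):
        pos1 = np.arange(2000) * 100
        rec = _records(pos1, pos1 + 3850)
        with pytest.raises(svc.InsertEstimationError, match="degenerate"):
            svc.estimate_insert_model(rec)

    def test_too_few_pairs(self):
        rec = _records([0, 100], [3900, 4000])
        with pytest.raises(svc.InsertEstimationError):
            svc.estimate_insert_model(rec)


class TestClassifyPair:
    model = InsertSizeModel(3900, 300)

    def _one(self, **kw):
        defaults = dict(
            mapped1=True, mapped2=True, strand1="+", strand2="+", inferred_span=3900
        )
        defaults.update(kw)
        return pd.Series(defaults)

    def test_span_at_mean_is_concordant(self):
        assert svc.classify_pair(self._one(), self.model) == svc.CONCORDANT

    def test_exactly_ten_sd_is_concordant(self):
        # the threshold is strict: "exceeding" ten standard deviations
        rec = self._one(inferred_span=3900 + 10 * 300)
        assert svc.classify_pair(rec, self.model) == svc.CONCORDANT

    def test_beyond_ten_sd_is_distance_anomaly(self):
        rec = self._one(inferred_span=3900 + 10 * 300 + 1)
        assert svc.classify_pair(rec, self.model) == svc.DISTANCE_ANOMALY

    def test_short_span_symmetric_and_switchable(self):
        rec = self._one(inferred_span=101)
        assert svc.classify_pair(rec, self.model) == svc.DISTANCE_ANOMALY
        assert svc.classify_pair(rec, self.model, symmetric=False) == svc.CONCORDANT

    def test_strand_mismatch_is_orientation_anomaly(self):
        rec = self._one(strand2="-", inferred_span=3900)
        assert svc.classify_pair(rec, self.model) == svc.ORIENTATION_ANOMALY

    def test_opposite_strand_dialect(self):
        model = InsertSizeModel(3900, 300, expected_orientation="opposite_strand")
        rec = self._one(strand1="+", strand2="-")
        assert svc.classify_pair(rec, model) == svc.CONCORDANT

    def test_unmapped_mate(self):
        rec = self._one(mapped2=False)
        assert svc.classify_pair(rec, self.model) == svc.ONE_END_UNMAPPED

    def test_vectorised_classification_matches_scalar(self):
        rng = np.random.default_rng(23)
        pos1 = rng.integers(0, 100_000, 500)
        spans = rng.choice([3900, 8000, 120], 500)
        rec = _records(pos1, pos1 + spans)
        rec.loc[::7, "strand2"] = "-"
        rec.loc[::11, "mapped2"] = False
        vec = svc.classify_pairs(rec, self.model)
        for i in range(0, 500, 13):
            assert vec.iloc[i] == svc.classify_pair(rec.iloc[i], self.model)


class TestWindowRule:
    model = InsertSizeModel(3900, 300)

    def _tile(self, n_disc, n_total, partner_spread=100):
        """One 1.5 kb tile with clustered discordant partners."""
        lefts = np.linspace(30_000, 31_400, n_total).astype(int)
        partners = np.full(n_total, 30_000 + 3900 - 50)
        disc_idx = np.arange(n_disc)
        partners[disc_idx] = 130_000 + np.arange(n_disc) * partner_spread
        return _records(lefts, partners)

    def test_twenty_percent_discordant_is_no_candidate(self):
        calls, stats = svc.call_sv_windows(self._tile(2, 10), self.model)
        assert not stats["candidate"].any()
        assert calls == []

    def test_twentyfive_percent_clustered_is_candidate(self):
        calls, stats = svc.call_sv_windows(self._tile(3, 10), self.model, min_pairs=3)
        tile = stats[stats["window"] == 20]
        assert tile["candidate"].all()

    def test_scattered_partners_fail_cluster_test(self):
        rec = self._tile(3, 10, partner_spread=5000)
        calls, stats = svc.call_sv_windows(rec, self.model, min_pairs=3)
        assert not stats["candidate"].any()

    def test_min_pairs_filters_sparse_tiles(self):
        rec = self._tile(3, 3)
        calls, stats = svc.call_sv_windows(rec, self.model, min_pairs=4)
        assert not stats["candidate"].any()

    def test_empty_input_yields_empty_call_set(self):
        calls, stats = svc.call_sv_windows(_records([], []), self.model)
        assert calls == [] and len(stats) == 0


class TestFullPipeline:
    def test_homozygous_pool_recovers_both_junctions(self, toy_arch, hom_r1_calls):
        _, calls, _ = hom_r1_calls
        assert len(calls) == 2
        assert all(c.svtype == "inversion" for c in calls)
        for call in calls:
            assert abs(call.size - toy_arch.inversion_span) <= 1500

    def test_carrier_pool_recovers_both_junctions(self, toy_arch, alleles, insert_model):
        for seed in (31, 32):
            rec = simulate_matepairs(
                {"R1": 1, "r": 1}, alleles, 300_000, insert_model, 10.0, seed=seed
            )
            model = svc.estimate_insert_model(rec)
            calls, _ = svc.call_sv_windows(rec, model)
            assert len(calls) == 2
            assert all(c.svtype == "inversion" for c in calls)

    def test_wildtype_pool_yields_no_calls(self, alleles, insert_model):
        for seed in (41, 42, 43):
            rec = simulate_matepairs({"r": 2}, alleles, 300_000, insert_model, 10.0, seed=seed)
            model = svc.estimate_insert_model(rec)
            calls, _ = svc.call_sv_windows(rec, model)
            assert calls == []

    def test_call_intervals_bracket_true_breakpoints(self, toy_arch, hom_r1_calls):
        # interval edges come from read placements, so the nearest read may
        # stop up to ~a read length short of the junction
        _, calls, _ = hom_r1_calls
        slack = 60
        proximal = min(calls, key=lambda c: c.breakpoint_a[0])
        lo, hi = proximal.breakpoint_a
        assert lo - slack <= toy_arch.proximal <= hi + slack
        lo, hi = proximal.breakpoint_b
        assert lo - slack <= toy_arch.distal <= hi + slack


class TestRefineBreakpoints:
    def test_twenty_pair_refinement_contains_truth(
        self, toy_arch, hom_r1_records, hom_r1_calls
    ):
        est, calls, _ = hom_r1_calls
        call = min(calls, key=lambda c: c.breakpoint_a[0])  # proximal junction
        sub = dataclasses.replace(
            call, pair_index=tuple(call.pair_index[:20]), support=20
        )
        refined = svc.refine_breakpoints(sub, hom_r1_records, est)
        lo, hi = refined.breakpoint_a
        assert hi - lo <= est.mean + 3 * est.sd
        assert lo <= toy_arch.proximal <= hi
        # never wider than the input interval
        assert lo >= call.breakpoint_a[0] and hi <= call.breakpoint_a[1]

    def test_perfect_information_narrows_to_clip_tolerance(self):
        model = InsertSizeModel(3900, 300)
        max_frag = 3900 + 3 * 300
        j_a, j_b = 10_000, 50_000
        rl, n = 50, 5
        lefts, rights = [], []
        # fragments of exactly max_frag whose A-side extents span the range,
        # so reads abut the junction on both sides
        for a_side in np.linspace(rl, max_frag - rl, n):
            lefts.append(int(j_a - a_side))
            rights.append(int(j_b - (max_frag - a_side)))
        rec = _records(np.array(lefts), np.array(rights), strand1="+", strand2="-")
        call = svc.SVCall(
            svtype="inversion",
            breakpoint_a=(j_a - 5000, j_a + 5000),
            breakpoint_b=(j_b - 5000, j_b + 5000),
            size=j_b - j_a,
            support=n,
            windows=(),
            pair_index=tuple(rec.index),
        )
        refined = svc.refine_breakpoints(call, rec, model, clip_tol=5)
        assert not refined.fallback
        for (lo, hi), j in ((refined.breakpoint_a, j_a), (refined.breakpoint_b, j_b)):
            assert hi - lo <= 2 * 5
            assert lo <= j <= hi

    def test_single_pair_violates_precondition(self, hom_r1_records, hom_r1_calls):
        est, calls, _ = hom_r1_calls
        call = dataclasses.replace(
            calls[0], pair_index=tuple(calls[0].pair_index[:1]), support=1
        )
        with pytest.raises(ValueError):
            svc.refine_breakpoints(call, hom_r1_records, est)


def test_calls_to_bedpe(hom_r1_calls):
    _, calls, _ = hom_r1_calls
    table = svc.calls_to_bedpe(calls, "chr7T")
    assert len(table) == 2
    assert set(table["chrom1"]) == {"chr7T"}
    assert (table["start1"] < table["end1"]).all()
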