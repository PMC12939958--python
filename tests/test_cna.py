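"""CN-LOH cutoff derivation, event-calling rules and haplotype assignment."""

import numpy as np
import pandas as pd
import pytest

from lesionevo.cna import (
    assign_haplotype,
    assign_haplotypes,
    call_events,
    derive_cnloh_cutoff,
    mutual_events,
)
from lesionevo.records import CnlohCutoff

from .conftest import make_segments, make_variants


class TestDeriveCnlohCutoff:
    def test_zero_variance_gives_common_value(self):
        mafs = {f"n{i}": [0.47] * 5 for i in range(7)}
        cutoff = derive_cnloh_cutoff(mafs)
        assert cutoff.value == pytest.approx(0.47, abs=1e-12)
        assert cutoff.n_normals == 7

    def test_hand_arithmetic(self):
        p10s = [0.48, 0.47, 0.46, 0.47, 0.48, 0.46, 0.47]
        mafs = {f"n{i}": [v] for i, v in enumerate(p10s)}
        expected = np.mean(p10s) - 3 * np.std(p10s, ddof=1)
        cutoff = derive_cnloh_cutoff(mafs)
        assert cutoff.value == pytest.approx(expected, abs=1e-12)
        assert sorted(cutoff.per_sample_p10) == sorted(p10s)

    def test_percentile_is_linear_interpolation(self):
        mafs = {"a": [0.40, 0.50], "b": [0.40, 0.50]}
        cutoff = derive_cnloh_cutoff(mafs)
        assert cutoff.value == pytest.approx(np.percentile([0.40, 0.50], 10), abs=1e-12)

    def test_single_normal_rejected(self):
        with pytest.raises(ValueError):
            derive_cnloh_cutoff({"only": [0.5, 0.4]})

    def test_permutation_invariance(self, rng):
        samples = {f"s{i}": rng.uniform(0.3, 0.5, size=20).tolist() for i in range(5)}
        base = derive_cnloh_cutoff(samples).value
        shuffled = {k: rng.permutation(v).tolist() for k, v in reversed(list(samples.items()))}
        assert derive_cnloh_cutoff(shuffled).value == pytest.approx(base, abs=1e-12)

    def test_realistic_normals_land_near_044(self, rng):
        # neutral MAFs hug 0.5 from below; seven normals give a cutoff in the
        # low-to-mid 0.4s (qualitative anchor only)
        mafs = {
            f"n{i}": (0.5 - np.abs(rng.normal(0, 0.02, size=22))).tolist() for i in range(7)
        }
        cutoff = derive_cnloh_cutoff(mafs)
        assert 0.38 < cutoff.value < 0.49


class TestCallEvents:
    def test_threshold_arms(self):
        segs = make_segments(
            [
                {"start": 1, "end": 10, "copy_ratio": 1.2, "minor_allele_fraction": 0.5},
                {"start": 11, "end": 20, "copy_ratio": 0.85, "minor_allele_fraction": 0.5},
                {"start": 21, "end": 30, "copy_ratio": 1.0, "minor_allele_fraction": 0.30},
                {"start": 31, "end": 40, "copy_ratio": 1.0, "minor_allele_fraction": 0.48},
            ]
        )
        events = call_events(segs, cnloh_cutoff=0.44)
        assert events["event_type"].tolist() == ["GAIN", "LOSS", "CNLOH"]

    def test_boundaries_are_strict_for_gain_loss(self):
        segs = make_segments(
            [
                {"start": 1, "end": 10, "copy_ratio": 1.1, "minor_allele_fraction": 0.5},
                {"start": 11, "end": 20, "copy_ratio": 0.9, "minor_allele_fraction": 0.5},
            ]
        )
        assert len(call_events(segs, cnloh_cutoff=0.44)) == 0

    def test_adjacent_same_type_merged(self):
        segs = make_segments(
            [
                {"start": 1, "end": 10, "copy_ratio": 1.3, "minor_allele_fraction": 0.5},
                {"start": 11, "end": 20, "copy_ratio": 1.25, "minor_allele_fraction": 0.5},
                {"start": 21, "end": 30, "copy_ratio": 1.0, "minor_allele_fraction": 0.5},
                {"start": 31, "end": 40, "copy_ratio": 1.4, "minor_allele_fraction": 0.5},
            ]
        )
        events = call_events(segs, cnloh_cutoff=0.44)
        assert [(e.start, e.end) for e in events.itertuples()] == [(1, 20), (31, 40)]

    def test_matches_rule_oracle_on_random_segments(self, rng):
        n = 300
        segs = make_segments(
            [
                {
                    "chrom": f"chr{rng.integers(1, 4)}",
                    "start": 1 + 100 * i,
                    "end": 100 * (i + 1),
                    "copy_ratio": float(rng.uniform(0.5, 1.6)),
                    "minor_allele_fraction": float(rng.uniform(0.0, 0.5)),
                }
                for i in range(n)
            ]
        )
        cutoff = 0.44
        events = call_events(segs, cnloh_cutoff=cutoff)
        # oracle: per-segment rule, then merge bookended same-type runs
        def rule(r):
            if r.copy_ratio > 1.1:
                return "GAIN"
            if r.copy_ratio < 0.9:
                return "LOSS"
            return "CNLOH" if r.minor_allele_fraction < cutoff else None

        expected = []
        for chrom, grp in segs.groupby("chrom"):
            grp = grp.sort_values("start")
            run = None
            for r in grp.itertuples(index=False):
                t = rule(r)
                if t is None:
                    if run:
                        expected.append(run)
                    run = None
                elif run and run[3] == t and r.start == run[2] + 1:
                    run = (chrom, run[1], r.end, t)
                else:
                    if run:
                        expected.append(run)
                    run = (chrom, r.start, r.end, t)
            if run:
                expected.append(run)
        got = [(e.chrom, e.start, e.end, e.event_type) for e in events.itertuples()]
        assert sorted(got) == sorted(expected)

    def test_cnloh_never_called_at_or_above_cutoff(self, rng):
        segs = make_segments(
            [
                {"start": 1 + 10 * i, "end": 10 * (i + 1), "copy_ratio": 1.0,
                 "minor_allele_fraction": float(rng.uniform(0.44, 0.5))}
                for i in range(50)
            ]
        )
        assert len(call_events(segs, cnloh_cutoff=0.44)) == 0

    def test_gain_cutoff_monotonicity(self, rng):
        segs = make_segments(
            [
                {"start": 1 + 10 * i, "end": 10 * (i + 1),
                 "copy_ratio": float(rng.uniform(0.8, 1.6)), "minor_allele_fraction": 0.5}
                for i in range(60)
            ]
        )
        lo = call_events(segs, gain_cutoff=1.1, cnloh_cutoff=0.44)
        hi = call_events(segs, gain_cutoff=1.3, cnloh_cutoff=0.44)
        assert (hi["event_type"] == "GAIN").sum() <= (lo["event_type"] == "GAIN").sum()

    def test_malformed_segment_rejected(self):
        segs = make_segments([{"start": 100, "end": 1}])
        with pytest.raises(ValueError, match="start > end"):
            call_events(segs, cnloh_cutoff=0.44)

    def test_bad_cutoff_ordering_rejected(self):
        with pytest.raises(ValueError):
            call_events(make_segments([]), gain_cutoff=0.8, loss_cutoff=0.9)


class TestAssignHaplotype:
    def event(self, etype="CNLOH"):
        return {
            "case_id": "case1",
            "sample_id": "case1_G",
            "chrom": "chr1",
            "start": 1000,
            "end": 2000,
            "event_type": etype,
            "affected_haplotype": pd.NA,
        }

    def test_unanimous_vote(self):
        v = make_variants([{"pos": 1000 + i, "phase": 0, "vaf": 0.2} for i in range(10)])
        assert assign_haplotype(self.event(), v) == 0

    def test_no_informative_variants_unknown(self):
        assert assign_haplotype(self.event(), make_variants([])) is pd.NA
        v = make_variants([{"pos": 5000, "phase": 0, "vaf": 0.2}])  # outside interval
        assert assign_haplotype(self.event(), v) is pd.NA

    def test_tie_is_unknown(self):
        v = make_variants(
            [{"pos": 1001, "phase": 0, "vaf": 0.2}, {"pos": 1002, "phase": 0, "vaf": 0.8}]
        )
        assert assign_haplotype(self.event(), v) is pd.NA

    def test_gain_votes_for_elevated_haplotype(self):
        v = make_variants([{"pos": 1000 + i, "phase": 1, "vaf": 0.62} for i in range(5)])
        assert assign_haplotype(self.event("GAIN"), v) == 1

    def test_recovery_against_ledger(self, sim_case):
        bundle, truth = sim_case
        phased = bundle.variants[bundle.variants["phase"].notna()]
        true_events = truth.segments[truth.segments["event_type"] != "NEUTRAL"]
        n_checked = n_correct = 0
        for ev in true_events.itertuples(index=False):
            got = assign_haplotype(
                {
                    "case_id": ev.case_id,
                    "sample_id": ev.sample_id,
                    "chrom": ev.chrom,
                    "start": ev.start,
                    "end": ev.end,
                    "event_type": ev.event_type,
                },
                phased[phased["sample_id"] == ev.sample_id],
            )
            n_checked += 1
            if got is not pd.NA and int(got) == int(ev.affected_haplotype):
                n_correct += 1
        assert n_checked > 0
        assert n_correct == n_checked  # noiseless phase: full recovery

    def test_recovery_with_phase_switch_noise(self, gene_table):
        from lesionevo.synthetic_data import SimConfig, simulate_case

        cfg = SimConfig(seed=5, phase_switch_rate=0.1)
        bundle, truth = simulate_case(cfg, 0, gene_table)
        phased = bundle.variants[bundle.variants["phase"].notna()]
        true_events = truth.segments[truth.segments["event_type"] != "NEUTRAL"]
        correct = total = 0
        for ev in true_events.itertuples(index=False):
            got = assign_haplotype(
                dict(
                    sample_id=ev.sample_id, chrom=ev.chrom, start=ev.start,
                    end=ev.end, event_type=ev.event_type,
                ),
                phased[phased["sample_id"] == ev.sample_id],
            )
            if got is not pd.NA:
                total += 1
                correct += int(got) == int(ev.affected_haplotype)
        assert total > 0 and correct / total >= 0.9


class TestMutualEvents:
    def events(self, sample, rows):
        base = {
            "case_id": "case1",
            "sample_id": sample,
            "chrom": "chr1",
            "start": 1,
            "end": 100,
            "event_type": "GAIN",
            "affected_haplotype": pd.NA,
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_identical_events_match(self):
        a = self.events("case1_L", [{}])
        b = self.events("case1_G", [{}])
        assert len(mutual_events(a, b)) == 1

    def test_type_mismatch_no_match(self):
        a = self.events("case1_L", [{"event_type": "GAIN"}])
        b = self.events("case1_G", [{"event_type": "LOSS"}])
        assert len(mutual_events(a, b)) == 0

    def test_reciprocal_overlap_threshold(self):
        a = self.events("case1_L", [{"start": 1, "end": 100}])
        b = self.events("case1_G", [{"start": 90, "end": 190}])  # 11% overlap
        assert len(mutual_events(a, b)) == 0
        assert len(mutual_events(a, b, min_reciprocal_overlap=0.1)) == 1

    def test_cross_case_rejected(self):
        a = self.events("case1_L", [{}])
        b = self.events("case2_G", [{}]).assign(case_id="case2")
        with pytest.raises(ValueError):
            mutual_events(a, b)

    def test_shared_trunk_events_recovered_from_simulation(self, sim_case):
        bundle, truth = sim_case
        events = call_events(
            bundle.segments[~bundle.segments["sample_id"].str.endswith("_Nm")],
            cnloh_cutoff=0.44,
        )
        ev_l = events[events["sample_id"] == "case1_L"]
        ev_g = events[events["sample_id"] == "case1_G"]
        matched = mutual_events(ev_l, ev_g)
        shared_truth = truth.segments[
            (truth.segments["origin"] == "shared")
            & (truth.segments["sample_id"] == "case1_L")
        ]
        got = set(zip(matched["chrom"], matched["event_type"]))
        want = set(zip(shared_truth["chrom"], shared_truth["event_type"]))
        assert want <= got
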