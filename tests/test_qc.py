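"""Interplate calibration, cutoff, melt review, spike QC and accounting."""

import numpy as np
import pandas as pd
import pytest

from mirstab import (
    CpMatrix,
    QcRules,
    ReactionRecord,
    WorkflowStage,
    apply_cp_cutoff,
    build_complete_cases,
    calibrate_interplate,
    categorize_reactions,
    classify_melt_curve,
    combine_groups,
    generate_melt_curve,
    hemolysis_delta,
    spike_in_qc,
    summarize_workflow,
)
from mirstab.io import SampleRecord
from mirstab.qc import iqr_fences

from _oracles import oracle_classify


def _rec(plate, well, cp, assay, status="approved"):
    return ReactionRecord(
        plate_id=plate, well=well, cp=cp,
        cp_status="absent" if cp is None else status, assay=assay,
    )


class TestCalibration:
    def test_equal_calibrator_means_is_identity(self):
        records = [
            _rec("p1", "A1", 19.0, "UniSp3"),
            _rec("p1", "A2", 25.0, "miR-x"),
            _rec("p2", "A1", 19.0, "UniSp3"),
            _rec("p2", "A2", 27.0, "miR-x"),
        ]
        adjusted, offsets = calibrate_interplate(records)
        assert offsets == {"p1": 0.0, "p2": 0.0}
        assert [r.cp for r in adjusted] == [19.0, 25.0, 19.0, 27.0]

    def test_two_plate_offset_formula(self):
        # calibrator means 19.0 and 20.0 -> grand mean 19.5; a Cp of 25.0 on
        # plate 1 moves half a cycle up
        records = [
            _rec("p1", "A1", 19.0, "UniSp3"),
            _rec("p1", "A2", 25.0, "miR-x"),
            _rec("p2", "A1", 20.0, "UniSp3"),
            _rec("p2", "A2", 25.0, "miR-x"),
        ]
        adjusted, _ = calibrate_interplate(records)
        assert adjusted[1].cp == pytest.approx(25.5)
        assert adjusted[3].cp == pytest.approx(24.5)

    def test_missing_calibrator_names_plate(self):
        records = [_rec("p7", "A2", 25.0, "miR-x")]
        with pytest.raises(ValueError, match="p7"):
            calibrate_interplate(records)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        records = []
        for p in range(4):
            offset = rng.normal(0, 1)
            records.append(_rec(f"p{p}", "A1", 19.0 + offset, "UniSp3"))
            for w in range(5):
                records.append(_rec(f"p{p}", f"B{w + 1}", 25.0 + offset + rng.normal(0, 0.1), "miR-x"))
        once, _ = calibrate_interplate(records)
        twice, offsets2 = calibrate_interplate(once)
        assert all(abs(v) < 1e-12 for v in offsets2.values())
        for a, b in zip(once, twice):
            assert b.cp == pytest.approx(a.cp, abs=1e-12)

    def test_known_plate_offsets_removed(self):
        """A constant assay plus injected plate shifts is flat after calibration."""
        rng = np.random.default_rng(42)
        offsets = rng.normal(0, 0.5, size=6)
        records = []
        for p, off in enumerate(offsets):
            records.append(_rec(f"p{p}", "A1", 19.0 + off, "UniSp3"))
            records.append(_rec(f"p{p}", "A2", 27.0 + off, "miR-const"))
        adjusted, _ = calibrate_interplate(records)
        values = [r.cp for r in adjusted if r.assay == "miR-const"]
        assert np.ptp(values) < 1e-9


class TestCpCutoff:
    @staticmethod
    def _matrix():
        return CpMatrix(pd.DataFrame(
            {
                "S1": [34.0, 35.0, 35.2],
                "S2": [33.0, 35.01, 36.0],
            },
            index=["a", "b", "c"],
        ))

    def test_boundary_and_assay_drop(self):
        cut, dropped = apply_cp_cutoff(self._matrix(), QcRules())
        # 35.00 retained, 35.01 censored, assay with all values censored dropped
        assert dropped == ["c"]
        assert cut.values.at["b", "S1"] == pytest.approx(35.0)
        assert np.isnan(cut.values.at["b", "S2"])

    def test_monotone_in_cutoff(self):
        m = self._matrix()
        retained = [
            apply_cp_cutoff(m, QcRules(cp_cutoff=c))[0].n_datapoints()
            for c in (36.0, 35.0, 34.5, 33.5)
        ]
        assert retained == sorted(retained, reverse=True)


class TestCategorisation:
    @pytest.mark.parametrize(
        "cp_status,tm_status,expected",
        [
            ("approved", "approved", "auto_approved"),
            ("approved", "inconclusive", "manual_review"),
            ("approved", "absent", "manual_review"),
            ("uncertain", "approved", "manual_review"),
            ("uncertain", "inconclusive", "manual_review"),
            ("late", "approved", "rejected"),
            ("absent", "absent", "rejected"),
        ],
    )
    def test_decision_matrix(self, cp_status, tm_status, expected):
        rec = ReactionRecord(
            plate_id="p", well="A1",
            cp=None if cp_status == "absent" else 30.0,
            cp_status=cp_status, tm_status=tm_status,
        )
        (out,) = categorize_reactions([rec])
        assert out.qc_category == expected

    def test_unpopulated_tm_status_raises(self):
        rec = ReactionRecord(plate_id="p", well="A1", cp=30.0, cp_status="approved")
        with pytest.raises(ValueError):
            categorize_reactions([rec])

    def test_override_matrix(self):
        rec = ReactionRecord(plate_id="p", well="A1", cp=30.0,
                             cp_status="uncertain", tm_status="approved")
        table = {("uncertain", "approved"): "auto_approved"}
        (out,) = categorize_reactions([rec], matrix=table)
        assert out.qc_category == "auto_approved"


GRID = np.arange(65.0, 95.0, 0.2)


def _curve(peaks):
    return generate_melt_curve([(tm, 0.8, h) for tm, h in peaks], GRID)


class TestMeltClassification:
    def test_good_single_peak_approved(self):
        verdict, _ = classify_melt_curve(_curve([(74.0, 2.0)]), [74.1], QcRules())
        assert verdict == "approved"

    def test_sub_threshold_peak_rejected(self):
        verdict, reason = classify_melt_curve(_curve([(74.0, 0.4)]), [74.0], QcRules())
        assert verdict == "rejected" and "0.5" in reason

    def test_half_height_double_peak_rejected(self):
        verdict, reason = classify_melt_curve(
            _curve([(74.0, 1.0), (66.0, 0.6)]), [74.0], QcRules())
        assert verdict == "rejected" and "secondary" in reason

    def test_three_peaks_rejected(self):
        verdict, reason = classify_melt_curve(
            _curve([(74.0, 2.0), (68.0, 0.8), (80.0, 0.7)]), [74.0], QcRules())
        assert verdict == "rejected" and "more than" in reason

    def test_tm_proximity_rejected(self):
        verdict, reason = classify_melt_curve(_curve([(70.0, 2.0)]), [74.0], QcRules())
        assert verdict == "rejected" and "reference" in reason

    def test_empty_reference_skips_proximity_and_flags_reason(self):
        verdict, reason = classify_melt_curve(_curve([(70.0, 2.0)]), [], QcRules())
        assert verdict == "approved" and "no auto-approved" in reason

    def test_matches_rule_oracle_on_planted_curves(self):
        """Detector + rules agree with a rule-by-rule oracle on curves with
        planted peak structure kept clear of the thresholds."""
        rng = np.random.default_rng(7)
        rules = QcRules()
        n_checked = 0
        for _ in range(60):
            n_peaks = rng.integers(1, 4)
            tms = 68.0 + np.cumsum(rng.uniform(4, 8, size=n_peaks))
            heights = []
            for k in range(n_peaks):
                # stay away from the 0.5 FU and half-height decision edges
                heights.append(float(rng.choice([0.25, 0.8, 2.0, 3.0])))
            peaks = list(zip(tms.tolist(), heights))
            primary = max(peaks, key=lambda p: p[1])
            ratios = sorted((h / primary[1] for _, h in peaks), reverse=True)
            if len(ratios) > 1 and abs(ratios[1] - 0.5) < 0.12:
                continue  # too close to the half-height edge for a detector test
            reference = primary[0] + float(rng.uniform(-0.5, 0.5))
            curve = generate_melt_curve([(tm, 0.8, h) for tm, h in peaks], GRID)
            verdict, _ = classify_melt_curve(curve, [reference], rules)
            assert verdict == oracle_classify(peaks, reference)
            n_checked += 1
        assert n_checked >= 40


class TestSpikeQc:
    @staticmethod
    def _sample(sid, group, cp2, cp4):
        return SampleRecord(sid, group, spike_cp={"UniSp2": cp2, "UniSp4": cp4})

    def test_delta_window(self):
        samples = [self._sample(f"S{i}", "HGSOC", 19.0, 19.0 + d)
                   for i, d in enumerate([4.8, 6.6, 8.3, 5.0, 8.0])]
        out = spike_in_qc(samples, QcRules())
        flags = [s.excluded for s in out]
        # 4.8 below and 8.3 above the window; 5.0 and 8.0 on the closed bounds
        assert flags == [True, False, True, False, False]

    def test_iqr_outlier_brute_force(self):
        cps = [19.0 + 0.01 * i for i in range(10)] + [25.0]
        samples = [self._sample(f"S{i}", "benign", cp, cp + 6.6)
                   for i, cp in enumerate(cps)]
        out = spike_in_qc(samples, QcRules())
        lo, hi = iqr_fences(cps, 1.5)
        expected = [not (lo <= cp <= hi) for cp in cps]
        assert [s.excluded for s in out] == expected
        assert out[-1].excluded  # the 25.0 sample is the outlier

    def test_outlier_rule_is_within_group(self):
        # identical UniSp2 distributions per group; one group's outlier must
        # not drag the other group's fences
        a = [self._sample(f"A{i}", "HGSOC", 19.0 + 0.02 * i, 25.6 + 0.02 * i)
             for i in range(8)]
        b = [self._sample(f"B{i}", "benign", 23.0 + 0.02 * i, 29.6 + 0.02 * i)
             for i in range(8)]
        out = spike_in_qc(a + b, QcRules())
        assert not any(s.excluded for s in out)

    def test_missing_spike_excluded_with_reason(self):
        s = SampleRecord("S1", "HGSOC", spike_cp={"UniSp2": 19.0})
        others = [self._sample(f"S{i + 2}", "HGSOC", 19.0, 25.6) for i in range(4)]
        out = spike_in_qc([s] + others, QcRules())
        assert out[0].excluded and "spike missing" in out[0].exclusion_reason

    def test_single_pass_order_independence(self):
        """IQR rule and delta-window exclude the same set in either order
        when fences come from the pre-exclusion group."""
        rng = np.random.default_rng(12)
        cps2 = list(19.0 + rng.uniform(-0.4, 0.4, size=30)) + [24.0, 15.5]
        deltas = list(rng.uniform(5.8, 7.4, size=30)) + [4.0, 6.6]
        samples = [self._sample(f"S{i}", "HGSOC", c, c + d)
                   for i, (c, d) in enumerate(zip(cps2, deltas))]
        combined = {s.sample_id for s in spike_in_qc(samples, QcRules()) if s.excluded}
        lo, hi = iqr_fences(cps2, 1.5)
        iqr_first = {s.sample_id for s in samples
                     if not (lo <= s.spike_cp["UniSp2"] <= hi)}
        delta_first = {s.sample_id for s in samples
                       if not (5 <= s.spike_cp["UniSp4"] - s.spike_cp["UniSp2"] <= 8)}
        assert combined == iqr_first | delta_first


class TestHemolysis:
    @pytest.mark.parametrize(
        "delta,flag",
        [(2.0, "ok"), (6.0, "borderline"), (7.5, "hemolysed")],
    )
    def test_flags(self, delta, flag):
        d, f = hemolysis_delta(20.0 + delta, 20.0)
        assert d == pytest.approx(delta) and f == flag

    def test_missing_input(self):
        assert hemolysis_delta(None, 20.0) == (None, "not assessed")


class TestCompleteCases:
    def test_partition_toy(self):
        df = pd.DataFrame(
            [[24.0, 25.0, 26.0], [27.0, np.nan, 28.0], [np.nan] * 3],
            index=["a", "b", "c"], columns=["S1", "S2", "S3"],
        )
        complete, summary, excluded = build_complete_cases(CpMatrix(df), ["S1", "S2", "S3"])
        assert complete.assays == ["a"]
        assert summary.loc["b", "status"] == "incomplete"
        assert summary.loc["b", "pct_missing"] == pytest.approx(100 / 3)
        assert excluded == ["c"]

    def test_no_samples_raises(self):
        df = pd.DataFrame([[1.0]], index=["a"], columns=["S1"])
        with pytest.raises(ValueError):
            build_complete_cases(CpMatrix(df), [])

    def test_combine_on_intersection(self):
        a = CpMatrix(pd.DataFrame(np.ones((3, 2)), index=["A", "B", "C"], columns=["S1", "S2"]))
        b = CpMatrix(pd.DataFrame(np.ones((3, 2)), index=["B", "C", "D"], columns=["T1", "T2"]))
        merged = combine_groups(a, b)
        assert merged.assays == ["B", "C"]
        assert merged.samples == ["S1", "S2", "T1", "T2"]

    def test_combine_empty_intersection_raises(self):
        a = CpMatrix(pd.DataFrame(np.ones((1, 1)), index=["A"], columns=["S1"]))
        b = CpMatrix(pd.DataFrame(np.ones((1, 1)), index=["B"], columns=["T1"]))
        with pytest.raises(ValueError, match="common"):
            combine_groups(a, b)


class TestWorkflowSummary:
    def test_noop_stage(self):
        summary = summarize_workflow([WorkflowStage("only", 100, 0)])
        assert summary.stages[0].datapoints_out == 100

    def test_conservation_enforced(self):
        stages = [WorkflowStage("a", 100, 10), WorkflowStage("b", 95, 5)]
        with pytest.raises(ValueError, match="conservation"):
            summarize_workflow(stages)

    def test_ordering_preserved(self):
        stages = [WorkflowStage("a", 100, 10), WorkflowStage("b", 90, 0)]
        summary = summarize_workflow(stages)
        assert [s.name for s in summary.stages] == ["a", "b"]
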