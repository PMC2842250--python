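"""Fold-change calling, dependency classification, overlaps, timecourse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stressarray import calling as rc
from stressarray.errors import ClassificationError, DesignError


def matrix_from(values: dict, condition: str = "NaCl_t120_wt") -> pd.DataFrame:
    return pd.DataFrame({condition: pd.Series(values)}).rename_axis("gene_id")


class TestCallThresholds:
    def test_up_boundary_inclusive(self):
        m = matrix_from({"G1": np.log2(2.5), "G2": 1.0, "G3": 2.0})
        called = rc.call_up(m, "NaCl_t120_wt")
        assert list(called["gene_id"]) == ["G1", "G3"]

    def test_down_boundary_inclusive(self):
        m = matrix_from({"G1": -2.0, "G2": -1.9, "G3": -3.0})
        called = rc.call_down(m, "NaCl_t120_wt")
        assert list(called["gene_id"]) == ["G1", "G3"]

    def test_unknown_condition_errors(self):
        with pytest.raises(DesignError):
            rc.call_up(matrix_from({"G1": 2.0}), "missing_condition")

    def test_output_sorted_by_gene_id(self):
        m = matrix_from({"G9": 2.0, "G1": 2.0, "G5": 2.0})
        assert list(rc.call_up(m, "NaCl_t120_wt")["gene_id"]) == ["G1", "G5", "G9"]

    @given(st.floats(2.5, 20.0), st.floats(0.0, 5.0))
    def test_raising_threshold_never_adds_genes(self, thr, bump):
        m = matrix_from({f"G{i}": v for i, v in enumerate(np.linspace(-1, 4, 30))})
        low = set(rc.call_up(m, "NaCl_t120_wt", thr)["gene_id"])
        high = set(rc.call_up(m, "NaCl_t120_wt", thr + bump)["gene_id"])
        assert high <= low


class TestClassifyDependency:
    def test_two_thirds_reduction_is_dependent(self):
        call = rc.classify_dependency("G1", fc_wt=4.0, fc_sb=2.0)
        assert call.dependent_sb is True and call.dependent_any is True

    def test_small_reductions_everywhere_are_independent(self):
        call = rc.classify_dependency("G1", fc_wt=3.0, fc_sb=2.9, fc_ko=2.8)
        assert call.dependent_any is False and call.dependent_two is False

    def test_exact_half_reduction_inclusive(self):
        call = rc.classify_dependency("G1", fc_wt=4.0, fc_sb=2.5)
        assert call.dependent_sb is True  # induction 3.0 -> 1.5, exactly 50%

    def test_ratio_mode_uses_raw_fold_change(self):
        # fc 4 -> 2.2: induction rule says dependent (1.2 <= 1.5), the raw
        # fold-change ratio rule does not (2.2 > 2.0)
        ind = rc.classify_dependency("G1", fc_wt=4.0, fc_sb=2.2, mode="induction")
        rat = rc.classify_dependency("G1", fc_wt=4.0, fc_sb=2.2, mode="ratio")
        assert ind.dependent_sb is True and rat.dependent_sb is False

    def test_down_gene_mirrored_through_reciprocal(self):
        # repression 1/8 relaxing to 1/2: reciprocal excess 7 -> 1 (dependent)
        call = rc.classify_dependency("G1", fc_wt=0.125, fc_sb=0.5, status="down")
        assert call.dependent_sb is True
        weak = rc.classify_dependency("G1", fc_wt=0.125, fc_sb=0.15, status="down")
        assert weak.dependent_sb is False

    def test_no_perturbed_measurement_errors(self):
        with pytest.raises(ClassificationError, match="no perturbed"):
            rc.classify_dependency("G1", fc_wt=4.0)

    def test_wt_below_calling_threshold_errors(self):
        with pytest.raises(ClassificationError, match="below"):
            rc.classify_dependency("G1", fc_wt=2.0, fc_sb=1.0)

    def test_single_perturbation_leaves_two_verdict_undefined(self):
        call = rc.classify_dependency("G1", fc_wt=4.0, fc_sb=1.5)
        assert call.dependent_two is None

    @given(st.floats(2.5, 16.0), st.floats(1.0, 16.0), st.floats(0.01, 2.0))
    def test_lowering_perturbed_fc_never_unflips_dependency(self, fc_wt, fc_sb, drop):
        before = rc.classify_dependency("G", fc_wt, fc_sb=fc_sb).dependent_sb
        after = rc.classify_dependency("G", fc_wt, fc_sb=max(fc_sb - drop, 0.01)).dependent_sb
        assert not (before and not after)


class TestDependencyFraction:
    def make_calls(self, flags):
        return [rc.DependencyCall(gene_id=f"G{i}", status="up", fc_wt=4.0,
                                  fc_sb=1.0 if f else 4.0, dependent_sb=f)
                for i, f in enumerate(flags)]

    def test_all_and_none(self):
        assert rc.dependency_fraction(self.make_calls([True] * 5), "sb").fraction == 1.0
        assert rc.dependency_fraction(self.make_calls([False] * 5), "sb").fraction == 0.0

    def test_empty_list_errors(self):
        with pytest.raises(ClassificationError):
            rc.dependency_fraction([], "any")

    def test_undefined_mode_verdicts_error(self):
        with pytest.raises(ClassificationError):
            rc.dependency_fraction(self.make_calls([True]), "ko")

    def test_counts_reported(self):
        res = rc.dependency_fraction(self.make_calls([True, True, False]), "sb")
        assert (res.n_dependent, res.n_total) == (2, 3)
        assert res.fraction == pytest.approx(2 / 3)


class TestOverlap:
    def test_identical_singletons(self):
        report = rc.overlap({"S1": {"A"}, "S2": {"A"}, "S3": {"A"}})
        assert report.counts[("S1", "S2", "S3")] == 1
        assert report.union_size == 1
        assert all(c == 0 for r, c in report.counts.items() if len(r) < 3)

    def test_pairwise_disjoint(self):
        report = rc.overlap({"A": {"a1", "a2"}, "B": {"b1"}, "C": {"c1"}})
        assert all(c == 0 for r, c in report.counts.items() if len(r) > 1)
        assert report.union_size == 4

    def test_duplicate_names_rejected(self):
        with pytest.raises(DesignError):
            rc.overlap([("A", {"x"}), ("A", {"y"})])

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(DesignError):
            rc.overlap({"A": {"x"}})

    @given(st.lists(st.sets(st.integers(0, 40)), min_size=2, max_size=4))
    def test_partition_conserves_union_and_matches_brute_force(self, sets):
        named = {f"S{i}": {str(x) for x in s} for i, s in enumerate(sets)}
        report = rc.overlap(named)
        union = set().union(*named.values())
        assert report.union_size == len(union)
        # brute force: each element falls in exactly the region of its sets
        for el in union:
            region = tuple(k for k in report.labels if el in named[k])
            assert el in report.members[region]


class TestCommonCore:
    def make_call(self, gene, sb, ko):
        return rc.classify_dependency(gene, fc_wt=4.0, fc_sb=1.0 if sb else 4.0,
                                      fc_ko=1.0 if ko else 4.0)

    def test_dependent_in_both_perturbations(self):
        sets = {"T1": {"G1"}, "T2": {"G1"}, "T3": {"G1"}}
        calls = {t: {"G1": self.make_call("G1", True, True)} for t in sets}
        core = rc.common_core(sets, calls)
        assert core["dependent_two_T1"].iloc[0] == True  # noqa: E712

    def test_dependent_only_in_sb_is_not_two(self):
        sets = {"T1": {"G1"}, "T2": {"G1"}, "T3": {"G1"}}
        calls = {t: {"G1": self.make_call("G1", True, False)} for t in sets}
        core = rc.common_core(sets, calls)
        assert core["dependent_two_T1"].iloc[0] == False  # noqa: E712

    def test_missing_dependency_flagged_not_dropped(self):
        sets = {"T1": {"G1"}, "T2": {"G1"}, "T3": {"G1"}}
        calls = {"T1": {"G1": self.make_call("G1", True, True)}, "T2": {}, "T3": {}}
        core = rc.common_core(sets, calls)
        assert len(core) == 1
        assert bool(core["missing_dependency_data"].iloc[0])

    def test_empty_intersection_is_empty_frame(self):
        core = rc.common_core({"T1": {"a"}, "T2": {"b"}, "T3": {"c"}}, {})
        assert len(core) == 0


class TestTimecourse:
    def make_matrix(self, deps_by_time):
        """One up gene per entry; dependent entries get fc_sb = 1."""
        cols = {}
        for t, flags in deps_by_time.items():
            wt, sb = {}, {}
            for i, dep in enumerate(flags):
                g = f"G{i}"
                wt[g] = 2.0  # FC 4
                sb[g] = 0.0 if dep else 2.0
            cols[f"NaCl_t{t}_wt"] = pd.Series(wt)
            cols[f"NaCl_t{t}_sb"] = pd.Series(sb)
        return pd.DataFrame(cols).rename_axis("gene_id")

    def test_all_dependent_fraction_one(self):
        m = self.make_matrix({45: [True, True], 120: [True, True]})
        points, _ = rc.timecourse(m, "NaCl", [45, 120])
        assert all(p.dependency_fraction == 1.0 for p in points)

    def test_mixed_fractions_and_overlap(self):
        m = self.make_matrix({45: [True, False], 120: [True, True, False, False]})
        points, ov = rc.timecourse(m, "NaCl", [45, 120])
        assert points[0].dependency_fraction == pytest.approx(0.5)
        assert points[1].n_up == 4
        assert ov.union_size == 4

    def test_tf_subset_never_exceeds_global(self):
        m = self.make_matrix({45: [True, False, True], 120: [True] * 3})
        points, _ = rc.timecourse(m, "NaCl", [45, 120], tf_genes=["G0", "G2", "GX"])
        for p in points:
            assert p.tf_n_up <= p.n_up
            assert p.tf_n_dependent <= p.n_dependent

    def test_missing_perturbed_condition_names_timepoint(self):
        m = self.make_matrix({45: [True]})
        with pytest.raises(DesignError, match="480"):
            rc.timecourse(m, "NaCl", [45, 480])

    def test_single_timepoint_rejected(self):
        m = self.make_matrix({45: [True]})
        with pytest.raises(DesignError):
            rc.timecourse(m, "NaCl", [45])


class TestZeroNoiseIdentity:
    def test_calls_and_verdicts_match_truth(self, zero_noise_small_run):
        """On noise-free synthetic data the called sets and dependency
        verdicts equal the planted truth table exactly."""
        run = zero_noise_small_run
        m = run.matrix.table
        for ctx in run.config.contexts:
            wt = f"{ctx.stimulus}_t{ctx.time_min}_wt"
            up = set(rc.call_up(m, wt)["gene_id"])
            down = set(rc.call_down(m, wt)["gene_id"])
            assert up == run.truth.genes_with_status(ctx.stimulus, ctx.time_min, "up")
            assert down == run.truth.genes_with_status(ctx.stimulus, ctx.time_min, "down")
            flags = run.truth.dependent_flags(ctx.stimulus, ctx.time_min)
            for call in rc.dependency_calls(m, ctx.stimulus, ctx.time_min):
                assert call.dependent_any == bool(flags.loc[call.gene_id])
                assert call.dependent_two == bool(flags.loc[call.gene_id])

    def test_recovered_log2fc_equals_planted(self, zero_noise_small_run):
        run = zero_noise_small_run
        m = run.matrix.table
        for ctx in run.config.contexts:
            for arm in ctx.arms:
                col = f"{ctx.stimulus}_t{ctx.time_min}_{arm}"
                expected = run.truth.expected_log2fc(ctx.stimulus, ctx.time_min, arm)
                got = m[col].loc[expected.index]
                assert np.allclose(got.to_numpy(), expected.to_numpy(), atol=1e-9)
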