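"""Probe-level processing: parsing, glog stabilization, ratios, QC,
replicate averaging and the probe->gene collapse."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stressarray import array_core as ac
from stressarray import conditions as cond
from stressarray.errors import (
    CorrelationError,
    DesignError,
    ParseError,
    ScaleEstimationError,
)


def make_probe_tsv(rows):
    header = "\t".join(ac.PROBE_COLUMNS)
    body = "\n".join("\t".join(str(v) for v in row) for row in rows)
    return io.StringIO(header + "\n" + body + "\n")


class TestReadProbeTable:
    def test_well_formed_file(self):
        src = make_probe_tsv([
            ("P1", "s1", 1000, 100, 2000, 100),
            ("P2", "s1", 500, 50, 400, 50),
            ("P1", "s2", 900, 90, 1800, 90),
        ])
        table = ac.read_probe_table(src)
        assert len(table) == 3
        assert table["ch2_fg"].iloc[0] == 2000.0

    def test_duplicate_key_rejected(self):
        src = make_probe_tsv([
            ("P1", "s1", 1, 0, 1, 0),
            ("P1", "s1", 2, 0, 2, 0),
        ])
        with pytest.raises(ParseError, match="duplicate"):
            ac.read_probe_table(src)

    def test_negative_intensity_rejected(self):
        src = make_probe_tsv([("P1", "s1", -5, 0, 1, 0)])
        with pytest.raises(ParseError, match="negative"):
            ac.read_probe_table(src)

    def test_missing_column_rejected(self):
        src = io.StringIO("probe_id\tsample_id\tch1_fg\nP1\ts1\t10\n")
        with pytest.raises(ParseError, match="missing column"):
            ac.read_probe_table(src)

    def test_non_numeric_intensity_rejected(self):
        src = make_probe_tsv([("P1", "s1", "abc", 0, 1, 0)])
        with pytest.raises(ParseError, match="non-numeric"):
            ac.read_probe_table(src)


class TestBackgroundCorrect:
    def test_subtraction_and_negative_retained(self):
        table = ac.validate_probe_table(pd.DataFrame({
            "probe_id": ["P1", "P2"], "sample_id": ["s1", "s1"],
            "ch1_fg": [1000.0, 50.0], "ch1_bg": [100.0, 100.0],
            "ch2_fg": [1000.0, 80.0], "ch2_bg": [0.0, 0.0],
        }))
        out = ac.background_correct(table)
        assert out["ch1_fg"].tolist() == [900.0, -50.0]  # not floored
        assert out["ch2_fg"].tolist() == [1000.0, 80.0]  # bg = 0 is identity
        assert (out["ch1_bg"] == 0).all()


class TestGlog:
    def test_at_zero_equals_log2_half_c(self):
        assert ac.glog2(0.0, 8.0) == pytest.approx(np.log2(4.0))

    def test_asymptotic_identity(self):
        c = 10.0
        x = np.array([50 * c, 100 * c, 1000 * c])
        rel = np.abs(ac.glog2(x, c) - np.log2(x)) / np.log2(x)
        assert (rel < 0.01).all()

    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    def test_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert ac.glog2(lo, 5.0) <= ac.glog2(hi, 5.0)
        if hi - lo > 1e-6:  # strict once beyond float resolution
            assert ac.glog2(lo, 5.0) < ac.glog2(hi, 5.0)

    def test_scale_estimation_constant_channel_errors(self):
        with pytest.raises(ScaleEstimationError):
            ac.estimate_glog_scale(np.full(100, 7.0))

    def test_scale_zero_without_negatives(self):
        assert ac.estimate_glog_scale(np.array([10.0, 100.0, 1000.0])) == 0.0

    def test_variance_stabilized_across_intensity_deciles(self):
        """Additive + multiplicative noise with known parameters: after the
        glog transform the within-signal variance is near-constant across
        intensity deciles (max/min < 2), unlike plain log2."""
        rng = np.random.default_rng(0)
        sigma_add, sd_log2, reps = 30.0, 0.25, 800
        mu_grid = 2.0 ** np.linspace(0, 14, 40)
        mu = np.repeat(mu_grid, reps)
        x = (mu * 2.0 ** rng.normal(0, sd_log2, mu.size)
             + rng.normal(0, sigma_add, mu.size))
        c = ac.estimate_glog_scale(x, sd_log2)
        assert c > 0
        y = ac.glog2(x, c).reshape(len(mu_grid), reps)
        decile_var = np.array([d.mean() for d in np.array_split(y.var(axis=1), 10)])
        assert decile_var.max() / decile_var.min() < 2.0
        ylog = np.log2(np.maximum(x, 1e-9)).reshape(len(mu_grid), reps)
        raw_var = np.array([d.mean() for d in np.array_split(ylog.var(axis=1), 10)])
        assert raw_var.max() / raw_var.min() > 10.0


def two_sample_design():
    return cond.build_design([
        cond.descriptor_for_arm("NaCl", 120, "wt", 1),
        cond.descriptor_for_arm("NaCl", 120, "wt", 2),
    ])


class TestLogRatios:
    def test_equal_channels_give_zero_and_offset_gives_one(self):
        design = two_sample_design()
        stab = pd.DataFrame({
            "probe_id": ["P1", "P2"],
            "sample_id": ["NaCl_t120_wt_r1"] * 2,
            "ch1_fg": [5.0, 7.0], "ch1_bg": 0.0,
            "ch2_fg": [5.0, 8.0], "ch2_bg": 0.0,
        })
        ratios = ac.log_ratios(stab, design)
        assert ratios["M"].tolist() == [0.0, 1.0]
        assert ratios["A"].tolist() == [5.0, 7.5]

    def test_unknown_sample_rejected(self):
        design = two_sample_design()
        stab = pd.DataFrame({
            "probe_id": ["P1"], "sample_id": ["mystery"],
            "ch1_fg": [1.0], "ch1_bg": 0.0, "ch2_fg": [1.0], "ch2_bg": 0.0,
        })
        with pytest.raises(DesignError, match="mystery"):
            ac.log_ratios(stab, design)


class TestReplicatePcc:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert ac.replicate_pcc(v, v) == pytest.approx(1.0)

    def test_negated_vector(self):
        v = np.array([1.0, 2.0, 3.0])
        assert ac.replicate_pcc(v, -v) == pytest.approx(-1.0)

    def test_constant_vector_errors(self):
        with pytest.raises(CorrelationError):
            ac.replicate_pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_probes_errors(self):
        with pytest.raises(CorrelationError):
            ac.replicate_pcc([1.0, 2.0], [1.0, 2.0])


class TestAverageReplicates:
    def make_ratios(self, m1, m2):
        return pd.DataFrame({
            "probe_id": ["P1", "P1"],
            "sample_id": ["NaCl_t120_wt_r1", "NaCl_t120_wt_r2"],
            "M": [m1, m2], "A": [1.0, 1.0],
        })

    def test_mean_of_two_replicates(self):
        avg = ac.average_replicates(self.make_ratios(1.0, 2.0), two_sample_design())
        assert avg.loc["P1", "NaCl_t120_wt"] == pytest.approx(1.5)

    def test_missing_replicate_uses_the_other(self):
        avg = ac.average_replicates(self.make_ratios(np.nan, 2.0), two_sample_design())
        assert avg.loc["P1", "NaCl_t120_wt"] == pytest.approx(2.0)

    def test_all_missing_propagates(self):
        avg = ac.average_replicates(self.make_ratios(np.nan, np.nan), two_sample_design())
        assert np.isnan(avg.loc["P1", "NaCl_t120_wt"])


class TestCollapseToGenes:
    def test_mean_single_and_ambiguous(self):
        per_probe = pd.DataFrame(
            {"c1": [1.0, 3.0, 5.0, 9.0]},
            index=pd.Index(["P1", "P2", "P3", "P4"], name="probe_id"))
        pmap = pd.DataFrame({
            "probe_id": ["P1", "P2", "P3", "P4", "P4"],
            "gene_id": ["G1", "G1", "G2", "G3", "G4"],
        })
        rm = ac.collapse_to_genes(per_probe, pmap)
        assert rm.table.loc["G1", "c1"] == pytest.approx(2.0)
        assert rm.table.loc["G2", "c1"] == pytest.approx(5.0)  # single probe
        assert "G3" not in rm.table.index and "G4" not in rm.table.index
        assert rm.n_ambiguous == 1

    def test_unmapped_probe_counted(self):
        per_probe = pd.DataFrame({"c1": [1.0, 2.0]},
                                 index=pd.Index(["P1", "PX"], name="probe_id"))
        pmap = pd.DataFrame({"probe_id": ["P1"], "gene_id": ["G1"]})
        rm = ac.collapse_to_genes(per_probe, pmap)
        assert rm.n_unmapped == 1
        assert list(rm.table.index) == ["G1"]

    def test_empty_map_errors(self):
        per_probe = pd.DataFrame({"c1": [1.0]}, index=pd.Index(["P1"], name="probe_id"))
        with pytest.raises(DesignError):
            ac.collapse_to_genes(per_probe, pd.DataFrame(columns=["probe_id", "gene_id"]))


class TestQCReport:
    def make_noise_only_run(self, shuffle_one=False, seed=0):
        rng = np.random.default_rng(seed)
        design = two_sample_design()
        n = 500
        baseline = 2.0 ** rng.normal(10, 1.5, n)
        frames = []
        for sample in design["sample_id"]:
            ch1 = baseline * 2.0 ** rng.normal(0, 0.25, n)
            ch2 = baseline * 2.0 ** rng.normal(0, 0.25, n)
            frames.append(pd.DataFrame({
                "probe_id": [f"P{i}" for i in range(n)], "sample_id": sample,
                "ch1_fg": ch1, "ch1_bg": 0.0, "ch2_fg": ch2, "ch2_bg": 0.0,
            }))
        probes = pd.concat(frames, ignore_index=True)
        if shuffle_one:
            mask = probes["sample_id"] == design["sample_id"].iloc[1]
            probes.loc[mask, "ch2_fg"] = rng.permutation(
                probes.loc[mask, "ch2_fg"].to_numpy())
            probes.loc[mask, "ch1_fg"] = rng.permutation(
                probes.loc[mask, "ch1_fg"].to_numpy())
        stab = ac.stabilize(probes)
        ratios = ac.log_ratios(stab, design)
        return ac.qc_report(ratios, stab, design), design

    def test_symmetric_noise_has_near_zero_median_m(self):
        report, _ = self.make_noise_only_run()
        for summary in report.samples.values():
            assert abs(summary["median_M"]) < 0.05

    def test_correlated_replicates_not_flagged(self):
        report, _ = self.make_noise_only_run()
        assert report.flags == []
        assert all(e["min_treated_pcc"] > 0.9 for e in report.conditions.values())

    def test_shuffled_replicate_flagged(self):
        report, _ = self.make_noise_only_run(shuffle_one=True)
        assert any("below" in f for f in report.flags)
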