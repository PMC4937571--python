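"""Coupling resolution, normalisation and activity calling."""

import numpy as np
import pandas as pd
import pytest

import tp53cistrome as t
from tp53cistrome import reporter_quant as rq
from tp53cistrome.io import read_bed

from conftest import recovery_rates, run_activity_pipeline


def reads(*rows):
    return pd.DataFrame(rows, columns=["barcode", "region_id", "n_reads"])


class TestCouplingDictionary:
    def test_single_clean_barcode_unique(self):
        table = rq.build_coupling_dictionary(reads(("B1", "A", 5)))
        assert table.iloc[0]["status"] == "unique"
        assert table.iloc[0]["region_id"] == "A"

    @pytest.mark.parametrize("mix,expected", [
        ({"A": 6, "B": 4}, "ambiguous"),       # majority 0.6 < 0.9 purity
        ({"A": 9, "B": 1}, "unique"),          # majority 0.9 passes
        ({"A": 2}, "low_support"),             # below min_support 3
        ({"A": 19, "B": 1}, "unique"),
        ({"A": 1, "B": 1, "C": 1}, "ambiguous"),
    ])
    def test_majority_rule_enumeration(self, mix, expected):
        rows = [(f"B1", region, n) for region, n in mix.items()]
        table = rq.build_coupling_dictionary(reads(*rows))
        assert table.iloc[0]["status"] == expected

    def test_simulated_chimeras_resolved_against_truth(self):
        cfg = t.SimConfig(n_regions=500, chimera_rate=0.05, seed=13)
        _, truth = t.synth_data.simulate_regions(cfg)
        lib = t.synth_data.simulate_library(truth, cfg)
        table = rq.build_coupling_dictionary(lib)
        retained = table[table["status"] == "unique"]
        agree = np.mean([truth.barcode_region[b] == r for b, r in
                         zip(retained["barcode"], retained["region_id"])])
        assert agree >= 0.99

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            table = rq.build_coupling_dictionary(reads())
        assert table.empty


class TestNormalizeCounts:
    def toy(self):
        counts = pd.DataFrame({"plasmid_1": [10, 990], "cdna_1": [20, 980]},
                              index=["u1", "u2"])
        samples = pd.DataFrame({
            "sample_id": ["plasmid_1", "cdna_1"],
            "material": ["plasmid", "cDNA"],
            "condition": ["input", "p53_high"], "replicate": [1, 1]})
        return counts, samples

    def test_hand_arithmetic(self):
        # ((20+1)/1000) / ((10+1)/1000) = 1.909...
        counts, samples = self.toy()
        norm, low = rq.normalize_counts(counts, samples)
        assert norm.loc["u1", "cdna_1"] == pytest.approx(21 / 11)
        assert not low.any()

    def test_equal_cpm_gives_unity(self):
        counts = pd.DataFrame({"p": [50, 50], "c": [50, 50]}, index=["a", "b"])
        samples = pd.DataFrame({"sample_id": ["p", "c"],
                                "material": ["plasmid", "cDNA"],
                                "condition": ["input", "p53_high"],
                                "replicate": [1, 1]})
        norm, _ = rq.normalize_counts(counts, samples)
        assert np.allclose(norm["c"], 1.0)

    def test_zero_plasmid_flags_low_coverage(self):
        counts, samples = self.toy()
        counts.loc["u1", "plasmid_1"] = 0
        _, low = rq.normalize_counts(counts, samples)
        assert bool(low["u1"]) and not bool(low["u2"])

    def test_requires_plasmid_sample(self):
        counts, samples = self.toy()
        with pytest.raises(ValueError, match="plasmid"):
            rq.normalize_counts(counts, samples.assign(material="cDNA"))

    def test_null_simulation_medians_match_across_conditions(self):
        cfg = t.SimConfig(n_regions=300, activity_fold=1.0, seed=21)
        _, truth = t.synth_data.simulate_regions(cfg)
        lib = t.synth_data.simulate_library(truth, cfg)
        counts, samples = t.synth_data.simulate_counts(lib, truth, cfg)
        norm, _ = rq.normalize_counts(counts, samples)
        high = samples.loc[samples["condition"] == "p53_high", "sample_id"]
        off = samples.loc[samples["condition"] == "p53_off", "sample_id"]
        m_high = norm[list(high)].median().median()
        m_off = norm[list(off)].median().median()
        assert m_high == pytest.approx(m_off, rel=0.05)


class TestReplicateQC:
    def samples(self):
        return pd.DataFrame({
            "sample_id": ["p1", "h1", "h2", "o1", "o2"],
            "material": ["plasmid"] + ["cDNA"] * 4,
            "condition": ["input", "p53_high", "p53_high",
                          "p53_off", "p53_off"],
            "replicate": [1, 1, 2, 1, 2]})

    def test_duplicated_sample_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(0, 1, 100)
        other = rng.lognormal(0, 1, 100)
        norm = pd.DataFrame({"h1": vals, "h2": vals,
                             "o1": other, "o2": other})
        qc = rq.replicate_qc(norm, self.samples())
        assert (qc["r2"] > 0.999999).all()

    def test_permuted_replicate_destroys_correlation(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, 2000)
        norm = pd.DataFrame({"h1": vals, "h2": rng.permutation(vals),
                             "o1": vals, "o2": vals})
        qc = rq.replicate_qc(norm, self.samples())
        r2 = qc.set_index(["condition", "a", "b"])["r2"]
        assert r2[("p53_high", "h1", "h2")] < 0.01

    def test_single_replicate_not_applicable(self):
        samples = self.samples().iloc[[0, 1, 3]]
        norm = pd.DataFrame({"h1": [1.0, 2.0], "o1": [1.0, 2.0]})
        qc = rq.replicate_qc(norm, samples)
        assert qc.empty


class TestCallActivity:
    def test_classification_rule_enumeration(self):
        th = rq.Thresholds()
        cases = [
            (2.5, 0.01, "positive"),
            (-2.5, 0.01, "down"),
            (2.5, 0.2, "grayzone"),    # large but nonsignificant
            (1.0, 0.01, "grayzone"),   # significant but small
            (0.2, 0.01, "negative"),
            (1.0, 0.2, "negative"),
        ]
        for lfc, padj, expected in cases:
            assert rq._classify(lfc, padj, th) == expected

    def test_identical_conditions_called_negative(self):
        rng = np.random.default_rng(3)
        samples = pd.DataFrame({
            "sample_id": ["h1", "h2", "o1", "o2"],
            "material": ["cDNA"] * 4,
            "condition": ["p53_high", "p53_high", "p53_off", "p53_off"],
            "replicate": [1, 2, 1, 2]})
        norm = pd.DataFrame(rng.lognormal(0, 0.2, size=(50, 4)),
                            columns=samples["sample_id"],
                            index=[f"r{i}" for i in range(50)])
        calls = t.call_activity(norm, None, samples)
        assert (calls["class"] == "negative").mean() > 0.9

    def test_parameter_recovery_on_planted_screen(self):
        cfg = t.SimConfig(n_regions=300, seed=17)
        calls, truth = run_activity_pipeline(cfg)
        sens, fpr = recovery_rates(calls, truth)
        assert sens >= 0.95 and fpr <= 0.02

    def test_sample_column_order_invariance(self):
        cfg = t.SimConfig(n_regions=100, seed=19)
        _, truth = t.synth_data.simulate_regions(cfg)
        lib = t.synth_data.simulate_library(truth, cfg)
        counts, samples = t.synth_data.simulate_counts(lib, truth, cfg)
        coup = t.build_coupling_dictionary(lib)
        norm, low = rq.normalize_counts(counts, samples)
        a = t.call_activity(norm, coup, samples, low_coverage=low)
        shuffled = samples.sample(frac=1.0, random_state=0)
        b = t.call_activity(norm[list(norm.columns[::-1])], coup, shuffled,
                            low_coverage=low)
        pd.testing.assert_frame_equal(a, b)

    def test_classes_partition_regions(self):
        cfg = t.SimConfig(n_regions=150, seed=23)
        calls, _ = run_activity_pipeline(cfg)
        assert calls["class"].isin(rq.CLASSES).all()
        assert calls["class"].value_counts().sum() == len(calls)

    def test_null_simulation_controls_positive_rate(self):
        cfg = t.SimConfig(n_regions=300, activity_fold=1.0, seed=29)
        calls, _ = run_activity_pipeline(cfg)
        tested = calls[calls["class"] != "low_coverage"]
        assert (tested["class"] == "positive").mean() <= 0.05

    def test_sensitivity_monotone_in_activity_fold(self):
        sens = []
        for fold in (1.5, 4.0, 16.0):
            cfg = t.SimConfig(n_regions=200, activity_fold=fold, seed=31)
            calls, truth = run_activity_pipeline(cfg)
            sens.append(recovery_rates(calls, truth)[0])
        assert sens == sorted(sens)


class TestCollapseToPeaks:
    def regions_bed(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 500],
            "end": [400, 900], "name": ["rA", "rB"],
            "score": ["0", "0"], "strand": [".", "."]})

    def calls(self):
        return pd.DataFrame({
            "region_id": ["rA", "rB"], "base_mean": [1.0, 1.0],
            "log2FC": [2.5, 0.1], "p_value": [0.001, 0.9],
            "n_barcodes": [3, 5], "class": ["positive", "negative"],
            "p_adj": [0.01, 0.95]})

    def test_contained_peak_inherits_class(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                              "end": [200], "name": ["p1"],
                              "score": ["0"], "strand": ["."]})
        out = rq.collapse_to_peaks(self.calls(), self.regions_bed(), peaks)
        assert out.iloc[0]["covered"]
        assert out.iloc[0]["class"] == "positive"

    def test_half_overlap_below_threshold_not_covered(self):
        # peak [200, 600): region rA covers [200,400) = 50% < 60%
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [200],
                              "end": [600], "name": ["p1"],
                              "score": ["0"], "strand": ["."]})
        calls = self.calls().iloc[[0]]
        out = rq.collapse_to_peaks(calls, self.regions_bed().iloc[[0]], peaks)
        assert not out.iloc[0]["covered"]

    def test_best_supported_region_wins(self):
        # both regions overlap >= 60% of the peak; rB has more barcodes
        regions = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 50],
            "end": [400, 450], "name": ["rA", "rB"],
            "score": ["0", "0"], "strand": [".", "."]})
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                              "end": [300], "name": ["p1"],
                              "score": ["0"], "strand": ["."]})
        out = rq.collapse_to_peaks(self.calls(), regions, peaks)
        assert out.iloc[0]["class"] == "negative"
        assert out.iloc[0]["n_barcodes"] == 5

    def test_malformed_bed_reports_line(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t0\t100\nchr1\tfoo\t200\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(bad)


class TestCompareAssays:
    def peak_calls(self, classes):
        return pd.DataFrame({"peak_id": [f"p{i}" for i in range(len(classes))],
                             "class": classes})

    def test_identical_sets_fully_concordant(self):
        calls = self.peak_calls(["positive"] * 5 + ["negative"] * 5)
        out = rq.compare_assays(calls, calls)
        assert out["pct_a_pos_concordant"] == 100.0

    def test_printed_concordance_fraction(self):
        # 190 of 231 assay-A positives positive-or-grayzone in assay B
        a = self.peak_calls(["positive"] * 231 + ["negative"] * 100)
        b_classes = (["positive"] * 150 + ["grayzone"] * 40
                     + ["negative"] * 41 + ["negative"] * 100)
        b = self.peak_calls(b_classes)
        out = rq.compare_assays(a, b)
        assert out["pct_a_pos_concordant"] == pytest.approx(100 * 190 / 231)
        assert round(out["pct_a_pos_concordant"], 1) == 82.3

    def test_diagonal_table_significant_chi2(self):
        a = self.peak_calls(["positive"] * 10 + ["negative"] * 10)
        out = rq.compare_assays(a, a)
        assert out["chi2_p"] < 0.01

    def test_no_shared_peaks_raises(self):
        a = self.peak_calls(["positive"])
        b = self.peak_calls(["positive"])
        b["peak_id"] = ["other"]
        with pytest.raises(ValueError, match="shared"):
            rq.compare_assays(a, b)
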