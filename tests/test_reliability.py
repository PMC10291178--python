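"""Replicate agreement, CV, and abundance-bin summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings

from otufilter import (
    AbundanceBinScheme,
    OtuTableError,
    abundance_bin_summary,
    cv_by_abundance_bin,
    filter_none,
    filter_sample_min_copies,
    otu_cv,
    percent_reads_removed,
    reliability_by_abundance_bin,
    replicate_agreement,
)
from conftest import make_table, triplicate_table, triplicate_tables


def brute_force_agreement(table, design):
    """Independent recount by explicit enumeration over detection
    patterns, pure-python."""
    df = table.to_dataframe()
    out = {}
    for spec, samples in design.groups().items():
        samples = [s for s in samples if s in df.columns]
        tally = {1: 0, 2: 0, 3: 0}
        for otu in df.index:
            n = sum(1 for s in samples if df.loc[otu, s] >= 1)
            if n:
                tally[n] += 1
        union = sum(tally.values())
        if union:
            out[spec] = tuple(100.0 * tally[k] / union for k in (3, 2, 1))
    return out


class TestReplicateAgreement:
    def test_three_way_split(self):
        t, design = triplicate_table(
            [[1, 1, 1], [1, 1, 0], [1, 0, 0]], 1, otu_ids=["A", "B", "C"])
        rep = replicate_agreement(t, design)
        assert rep.per_specimen["Ind01"] == pytest.approx(
            (100 / 3, 100 / 3, 100 / 3))

    def test_all_present_everywhere(self):
        t, design = triplicate_table([[2, 3, 4], [5, 6, 7]], 1)
        rep = replicate_agreement(t, design)
        assert rep.mean == (100.0, 0.0, 0.0)
        assert rep.se == (0.0, 0.0, 0.0)

    def test_empty_specimen_flagged_not_counted(self):
        t, design = triplicate_table([[1, 1, 1, 0, 0, 0]], 2)
        rep = replicate_agreement(t, design)
        assert rep.empty_specimens == ["Ind02"]
        assert "Ind02" not in rep.per_specimen

    @settings(max_examples=40, deadline=None)
    @given(table=triplicate_tables())
    def test_matches_brute_force_and_sums_to_100(self, table):
        t, design = table
        expected = brute_force_agreement(t, design)
        if not expected:
            with pytest.raises(OtuTableError):
                replicate_agreement(t, design)
            return
        rep = replicate_agreement(t, design)
        assert set(rep.per_specimen) == set(expected)
        for spec, pct in expected.items():
            assert rep.per_specimen[spec] == pytest.approx(pct)
            assert sum(rep.per_specimen[spec]) == pytest.approx(100.0)


class TestPercentReadsRemoved:
    def test_identity_filter_removes_nothing(self):
        t, _ = triplicate_table([[4, 5, 6]], 1)
        mean, se, _ = percent_reads_removed(filter_none(t), t)
        assert (mean, se) == (0.0, 0.0)

    def test_per_sample_percentages(self):
        t = make_table([[99, 50], [1, 50]], otu_ids=["A", "B"])
        r = filter_sample_min_copies(t, 2)  # removes the single 1-copy cell
        mean, se, per_sample = percent_reads_removed(r, t)
        assert per_sample == {"S1": 1.0, "S2": 0.0}
        assert mean == pytest.approx(0.5)

    def test_zero_baseline_total_rejected(self):
        t = make_table([[0, 5]])
        with pytest.raises(OtuTableError):
            percent_reads_removed(filter_none(t), t)


class TestOtuCv:
    def test_no_dispersion(self):
        t, design = triplicate_table([[7, 7, 7]], 1, otu_ids=["A"])
        assert otu_cv(t, design, "Ind01", "A") == 0.0

    def test_single_detection_closed_form(self):
        t, design = triplicate_table([[10, 0, 0]], 1, otu_ids=["A"])
        assert otu_cv(t, design, "Ind01", "A") == pytest.approx(math.sqrt(3))
        assert otu_cv(t, design, "Ind01", "A", ddof=0) == pytest.approx(
            math.sqrt(2))

    def test_two_detection_closed_form(self):
        t, design = triplicate_table([[10, 10, 0]], 1, otu_ids=["A"])
        assert otu_cv(t, design, "Ind01", "A") == pytest.approx(
            math.sqrt(3) / 2)

    def test_absent_otu_rejected(self):
        t, design = triplicate_table([[0, 0, 0], [1, 2, 3]], 1,
                                     otu_ids=["A", "B"])
        with pytest.raises(OtuTableError):
            otu_cv(t, design, "Ind01", "A")

    @pytest.mark.parametrize("scale", [2, 10, 1000])
    def test_scale_invariance(self, scale):
        base = [3, 8, 1]
        t1, design = triplicate_table([base], 1, otu_ids=["A"])
        t2, _ = triplicate_table([[scale * x for x in base]], 1,
                                 otu_ids=["A"])
        assert otu_cv(t1, design, "Ind01", "A") == pytest.approx(
            otu_cv(t2, design, "Ind01", "A"))


class TestCvBins:
    def test_high_abundance_bin_and_zero_cv(self):
        t, design = triplicate_table([[2000, 2000, 2000]], 1, otu_ids=["A"])
        assert cv_by_abundance_bin(t, design) == {">1000": 0.0}

    def test_sporadic_assignment(self):
        t, design = triplicate_table([[3, 0, 0]], 1, otu_ids=["A"])
        assert list(cv_by_abundance_bin(t, design)) == ["sporadic"]

    def test_two_replicates_at_threshold_not_sporadic(self):
        # max copies 10 is not < 10: binned by its mean instead
        t, design = triplicate_table([[10, 0, 0]], 1, otu_ids=["A"])
        assert list(cv_by_abundance_bin(t, design)) == ["1-10"]

    def test_no_sporadic_after_min_copy_filter(self, default_dataset):
        filtered = filter_sample_min_copies(default_dataset.table, 10)
        bins = cv_by_abundance_bin(filtered.table, default_dataset.design)
        assert "sporadic" not in bins

    def test_bad_scheme_rejected(self):
        with pytest.raises(OtuTableError):
            AbundanceBinScheme(copy_edges=(10.0, 100.0))


class TestReliabilityBins:
    def test_all_triple_detected_is_100(self):
        t, design = triplicate_table([[50, 60, 70], [900, 950, 800]], 1)
        assert all(v == 100.0
                   for v in reliability_by_abundance_bin(t, design).values())

    def test_empty_bins_absent(self):
        t, design = triplicate_table([[5, 5, 5]], 1)
        out = reliability_by_abundance_bin(t, design)
        assert list(out) == [">1%"]  # the single OTU is 100% of each sample

    def test_decreases_with_abundance_on_synthetic_data(self, default_dataset):
        out = reliability_by_abundance_bin(default_dataset.table,
                                           default_dataset.design)
        scheme = AbundanceBinScheme()
        values = [out[lab] for lab in scheme.relative_labels() if lab in out]
        assert values == sorted(values, reverse=True)
        assert out[">1%"] == pytest.approx(100.0, abs=1.0)


class TestAbundanceBinSummary:
    def test_partition_of_detected_otus(self):
        t = make_table([[9600], [300], [80], [16], [4]])
        df = abundance_bin_summary(t)
        assert df["mean_otus"].sum() == 5
        assert df["mean_pct_reads"].sum() == pytest.approx(100.0)
        assert df.loc[">1%", "mean_otus"] == 2          # 96% and 3%
        assert df.loc["0.1-1%", "mean_otus"] == 2       # 0.8% and 0.16%
        assert df.loc["0.01-0.1%", "mean_otus"] == 1    # 0.04%

    def test_single_otu_sample(self):
        t = make_table([[42]])
        df = abundance_bin_summary(t)
        assert df.loc[">1%", "mean_pct_reads"] == pytest.approx(100.0)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(OtuTableError):
            abundance_bin_summary(make_table([[0]]))

    def test_detected_otus_partition_on_synthetic(self, default_dataset):
        table = default_dataset.table
        df = abundance_bin_summary(table)
        mean_detected = (table.counts >= 1).sum(axis=0).mean()
        assert df["mean_otus"].sum() == pytest.approx(mean_detected)
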