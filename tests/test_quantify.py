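"""Counts matrix construction, high-confidence filtering, usage statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from capiso import simulate as csim
from capiso.filters import FilterConfig, apply_filters
from capiso.locus import TranscriptModel
from capiso.quantify import (
    FeatureAnnotation,
    QuantConfig,
    acceptor_site_usage,
    assign_reads,
    end_class_usage,
    high_confidence_filter,
    isoform_proportions,
    junction_count_table,
    junction_prevalence,
    start_exon_usage,
)

from conftest import chain, read

CFG = QuantConfig()


def model(mid, exons, strand="-"):
    return TranscriptModel(mid, chain(strand, *exons))


class TestAssignReads:
    MODELS = [
        model("A", [(100, 200), (300, 400)]),
        model("B", [(100, 200), (300, 400), (500, 600)]),
    ]

    def test_fsm_end_freedom(self):
        r = read("r1", chain("-", (50, 200), (300, 1400)))  # ends ~1 kb away
        counts, unassigned = assign_reads([r], self.MODELS, samples=["s1"])
        assert counts.loc["A", "s1"] == 1
        assert unassigned["s1"] == 0

    def test_missing_junction_unassigned(self):
        r = read("r1", chain("-", (100, 250), (350, 400)))
        counts, unassigned = assign_reads([r], self.MODELS, samples=["s1"])
        assert counts.values.sum() == 0 and unassigned["s1"] == 1

    def test_truncated_read_not_counted_without_rescue(self):
        # chain equals B's two 3'-most junctions: an incomplete match, not FSM
        r = read("r1", chain("-", (100, 200), (300, 400), (500, 560)))
        counts, _ = assign_reads([r], [model("B3", [(90, 200), (300, 400), (500, 600)])],
                                 samples=["s1"])
        assert counts.loc["B3", "s1"] == 1  # same junctions: assigned
        r2 = read("r2", chain("-", (100, 200), (300, 360)))
        counts, unassigned = assign_reads(
            [r2], [model("B3", [(90, 200), (300, 400), (500, 600)])], samples=["s1"]
        )
        assert unassigned["s1"] == 1
        counts, unassigned = assign_reads(
            [r2], [model("B3", [(90, 200), (300, 400), (500, 600)])],
            samples=["s1"], ism_rescue=True,
        )
        assert counts.loc["B3", "s1"] == 1 and unassigned["s1"] == 0

    def test_mono_exon_unassigned(self):
        r = read("r1", chain("-", (100, 400)))
        counts, unassigned = assign_reads([r], self.MODELS, samples=["s1"])
        assert unassigned["s1"] == 1

    def test_conservation_per_sample(self, zero_truth, zero_reads):
        fcfg = FilterConfig(target_region=zero_truth.locus, target_strand="-")
        kept, _ = apply_filters(zero_reads.reads, fcfg)
        counts, unassigned = assign_reads(kept, zero_truth.isoforms,
                                          samples=zero_truth.samples)
        per_sample_kept = pd.Series([r.sample for r in kept]).value_counts()
        for s in zero_truth.samples:
            assert counts[s].sum() + unassigned[s] == per_sample_kept[s]

    def test_zero_noise_matrix_equals_drawn_counts(self, zero_truth, zero_reads):
        fcfg = FilterConfig(target_region=zero_truth.locus, target_strand="-")
        kept, _ = apply_filters(zero_reads.reads, fcfg)
        counts, unassigned = assign_reads(kept, zero_truth.isoforms,
                                          samples=zero_truth.samples)
        assert int(unassigned.sum()) == 0
        for s in zero_truth.samples:
            for iso in zero_truth.isoforms:
                assert counts.loc[iso.id, s] == zero_reads.drawn_counts[s][iso.id]


class TestHighConfidence:
    def _counts(self, rows):
        return pd.DataFrame(rows).T.fillna(0).astype(int)

    def test_exactly_100_in_one_sample_dropped(self):
        counts = pd.DataFrame({"s1": [100], "s2": [0]}, index=["a"])
        assert high_confidence_filter(counts, CFG) == []

    def test_110_total_in_two_samples_kept(self):
        counts = pd.DataFrame({"s1": [60], "s2": [50]}, index=["a"])
        assert high_confidence_filter(counts, CFG) == ["a"]

    def test_single_sample_dropped_despite_count(self):
        counts = pd.DataFrame({"s1": [150], "s2": [0]}, index=["a"])
        assert high_confidence_filter(counts, CFG) == []

    def test_101_in_two_samples_kept(self):
        counts = pd.DataFrame({"s1": [100], "s2": [1]}, index=["a"])
        assert high_confidence_filter(counts, CFG) == ["a"]


class TestProportions:
    def test_simple_split(self):
        counts = pd.DataFrame({"s1": [30, 70]}, index=["a", "b"])
        props = isoform_proportions(counts)
        assert props["s1"].tolist() == [0.3, 0.7]

    def test_zero_sample_is_nan(self):
        counts = pd.DataFrame({"s1": [10], "s2": [0]}, index=["a"])
        props = isoform_proportions(counts)
        assert props["s1"].iloc[0] == 1.0 and np.isnan(props["s2"].iloc[0])

    @given(
        arrays(
            np.int64,
            (4, 3),
            elements=st.integers(min_value=0, max_value=1000),
        )
    )
    def test_columns_sum_to_one(self, values):
        counts = pd.DataFrame(values, index=list("abcd"), columns=list("xyz"))
        props = isoform_proportions(counts)
        for col in counts.columns:
            total = counts[col].sum()
            if total > 0:
                assert props[col].sum() == pytest.approx(1.0)
            else:
                assert props[col].isna().all()


ANNOT = FeatureAnnotation(
    chrom="c",
    strand="-",
    start_exons={"E3": (1000, 1300), "E3.1": (1500, 1800)},
    acceptors={"site1": 700, "site3": 640},
    polya_classes={"pA1": 400, "pA2": 100},
)


class TestStartExonUsage:
    def test_single_start_exon_takes_all_reads(self):
        m = model("a", [(100, 300), (500, 700), (900, 1250)])
        counts = pd.DataFrame({"s1": [40], "s2": [10]}, index=["a"])
        usage = start_exon_usage([m], counts, ANNOT, CFG)
        assert usage.proportions.loc["E3"].tolist() == [1.0, 1.0]

    def test_cutoff_500_is_strict(self):
        m1 = model("a", [(100, 300), (900, 1250)])
        m2 = model("b", [(100, 300), (1500, 1700)])
        counts = pd.DataFrame({"s1": [500, 501]}, index=["a", "b"])
        usage = start_exon_usage([m1, m2], counts, ANNOT, CFG)
        assert usage.reported == ["E3.1"]  # 500 exactly is not "more than 500"

    def test_unmatched_tss_goes_to_other(self):
        m = model("a", [(100, 300), (2500, 2700)])
        counts = pd.DataFrame({"s1": [7]}, index=["a"])
        usage = start_exon_usage([m], counts, ANNOT, CFG)
        assert usage.totals.loc["other", "s1"] == 7

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            FeatureAnnotation(
                chrom="c", strand="-",
                start_exons={"a": (0, 100), "b": (50, 150)},
            )

    def test_switch_recovered_from_simulation(self, switch_truth, switch_reads):
        fcfg = FilterConfig(target_region=switch_truth.locus, target_strand="-")
        kept, _ = apply_filters(switch_reads.reads, fcfg)
        counts, _ = assign_reads(kept, switch_truth.isoforms,
                                 samples=switch_truth.samples)
        usage = start_exon_usage(switch_truth.isoforms, counts,
                                 switch_truth.annotation, CFG)
        e31 = usage.proportions.loc["E3.1", ["D0", "D1", "D3", "D9"]].tolist()
        e3 = usage.proportions.loc["E3", ["D0", "D1", "D3", "D9"]].tolist()
        assert all(a > b for a, b in zip(e31, e31[1:]))  # planted decrease
        assert all(a < b for a, b in zip(e3, e3[1:]))  # compensating increase
        assert set(usage.reported) >= {"E3", "E3.1"}


class TestAcceptorUsage:
    def test_all_reads_one_site(self):
        m = model("a", [(100, 300), (500, 700), (900, 1250)])  # acceptor 700
        counts = pd.DataFrame({"s1": [10]}, index=["a"])
        props = acceptor_site_usage([m], counts, ANNOT)
        assert props.loc["site1", "s1"] == 1.0

    def test_unnamed_acceptor_goes_to_other_and_sums_to_one(self):
        m1 = model("a", [(100, 300), (500, 700), (900, 1250)])
        m2 = model("b", [(100, 300), (500, 660), (900, 1250)])
        counts = pd.DataFrame({"s1": [6, 4]}, index=["a", "b"])
        props = acceptor_site_usage([m1, m2], counts, ANNOT)
        assert props.loc["site1", "s1"] == 0.6
        assert props.loc["other", "s1"] == 0.4
        assert props["s1"].sum() == pytest.approx(1.0)

    def test_planted_split_recovered_within_3_sigma(self):
        truth = csim.make_locus(
            n_start_exons=1, n_polya_sites=1, n_isoforms=2, seed=3,
            samples=["s1"], noise=csim.NoiseParams.zero(),
        )
        # the first two variants differ only by the E5-analogue acceptor
        truth.abundance = {"s1": {"T01": 600.0, "T02": 400.0}}
        simset = csim.simulate_reads(truth, seed=4)
        counts, _ = assign_reads(simset.reads, truth.isoforms, samples=["s1"])
        props = acceptor_site_usage(truth.isoforms, counts, truth.annotation)
        n = counts.values.sum()
        sigma = np.sqrt(0.6 * 0.4 / n)
        assert abs(props.loc["site1", "s1"] - 0.6) <= 3 * sigma


class TestEndClassUsage:
    def test_all_reads_distal_class(self):
        m = model("a", [(395, 700), (900, 1250)])
        counts = pd.DataFrame({"s1": [10]}, index=["a"])
        props = end_class_usage([m], counts, ANNOT)
        assert props.loc["pA1", "s1"] == 1.0

    def test_upstream_end_goes_to_other(self):
        m = model("a", [(520, 700), (900, 1250)])  # 120 bp upstream of pA1
        counts = pd.DataFrame({"s1": [5]}, index=["a"])
        props = end_class_usage([m], counts, ANNOT, upstream_slack=100)
        assert props.loc["other", "s1"] == 1.0

    def test_planted_mixture_recovered_within_3_sigma(self):
        truth = csim.make_locus(
            n_start_exons=1, n_polya_sites=3, n_isoforms=3, seed=8,
            samples=["s1"], noise=csim.NoiseParams.zero(),
        )
        planted = {"T01": 500.0, "T02": 300.0, "T03": 200.0}
        truth.abundance = {"s1": planted}
        simset = csim.simulate_reads(truth, seed=9)
        counts, _ = assign_reads(simset.reads, truth.isoforms, samples=["s1"])
        props = end_class_usage(truth.isoforms, counts, truth.annotation)
        n = counts.values.sum()
        for iso_id, expected in planted.items():
            label = truth.isoform_meta[iso_id]["polya"]
            p = expected / 1000.0
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(props.loc[label, "s1"] - p) <= 3 * sigma

    def test_class_proportions_sum_to_one(self):
        m1 = model("a", [(395, 700), (900, 1250)])
        m2 = model("b", [(95, 700), (900, 1250)])
        counts = pd.DataFrame({"s1": [3, 7]}, index=["a", "b"])
        props = end_class_usage([m1, m2], counts, ANNOT)
        assert props["s1"].sum() == pytest.approx(1.0)


class TestJunctionPrevalence:
    def test_hand_counts(self):
        table = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "junction": ["j"] * 3,
             "count": [9, 10, 11]}
        )
        assert junction_prevalence(table, CFG)["j"] == 2

    def test_strict_variant(self):
        table = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "junction": ["j"] * 3,
             "count": [9, 10, 11]}
        )
        cfg = QuantConfig(prevalence_strict=True)
        assert junction_prevalence(table, cfg)["j"] == 1

    def test_empty_table_gives_zero(self):
        table = pd.DataFrame(columns=["sample_id", "junction", "count"])
        out = junction_prevalence(table, CFG, junctions=["jX"])
        assert out["jX"] == 0

    def test_threshold_zero_counts_any_record(self):
        table = pd.DataFrame(
            {"sample_id": ["a", "b"], "junction": ["j", "j"], "count": [1, 3]}
        )
        cfg = QuantConfig(junction_prevalence_min_reads=0)
        assert junction_prevalence(table, cfg)["j"] == 2

    def test_table_from_reads(self):
        reads = [
            read("r1", chain("-", (100, 200), (300, 400))),
            read("r2", chain("-", (100, 200), (300, 400)), sample="s2"),
        ]
        table = junction_count_table(reads)
        assert len(table) == 2
        assert set(table["count"]) == {1}
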