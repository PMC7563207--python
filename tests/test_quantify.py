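"""Labeling ratios, isotopomer distributions and aggregations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isotrace.chem import get_adduct
from isotrace.quantify import (
    LabelingSummary,
    aggregate_fatty_acid,
    aggregate_lipid_class,
    compare_conditions,
    isotopomer_distribution,
    labeling_ratio,
    summarize,
    timecourse_table,
)
from isotrace.reference import ReferenceEntry


def hits_frame(intensities, ref_id="R0", sample_id="S1"):
    """Result-table fragment for one molecule in one sample."""
    return pd.DataFrame(
        {
            "ref_id": ref_id,
            "sample_id": sample_id,
            "n": list(intensities),
            "Intensity": list(intensities.values()),
        }
    )


def summary(ref_id, sample_id, ratio):
    return LabelingSummary(ref_id, sample_id, 0.0, {}, ratio, {})


def lipid(ref_id, name, lipid_class, chains):
    return ReferenceEntry(
        ref_id=ref_id, name=name, mode="lipid", mz=700.0, rt=100.0,
        polarity="negative", adduct=get_adduct("+HCOO"),
        lipid_class=lipid_class, fatty_acids=chains,
    )


class TestLabelingRatio:
    def test_heavy_over_total(self):
        ratio, flags = labeling_ratio(hits_frame({0: 100.0, 3: 50.0, 5: 50.0}))
        assert ratio == 0.5 and flags == []

    def test_only_m0_means_unlabeled(self):
        ratio, flags = labeling_ratio(hits_frame({0: 1e6}))
        assert ratio == 0.0 and flags == []

    def test_missing_m0_is_fully_labeled_with_flag(self):
        ratio, flags = labeling_ratio(hits_frame({4: 100.0, 5: 300.0}))
        assert ratio == 1.0 and "m0_missing" in flags

    def test_no_hits_undefined(self):
        with pytest.raises(ValueError):
            labeling_ratio(hits_frame({}))

    @given(st.floats(0.1, 1e6))
    def test_invariant_to_uniform_intensity_scaling(self, c):
        base = {0: 120.0, 2: 30.0, 6: 50.0}
        r1, _ = labeling_ratio(hits_frame(base))
        r2, _ = labeling_ratio(hits_frame({n: v * c for n, v in base.items()}))
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_mixed_groups_rejected(self):
        df = pd.concat([hits_frame({0: 1.0}), hits_frame({0: 1.0}, ref_id="R1")])
        with pytest.raises(ValueError):
            labeling_ratio(df)


class TestDistribution:
    def test_normalizes_to_one(self):
        dist = isotopomer_distribution(hits_frame({0: 0.0, 5: 900.0, 6: 100.0}))
        assert dist == {0: 0.0, 5: 0.9, 6: 0.1}
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_isotopomer(self):
        assert isotopomer_distribution(hits_frame({3: 42.0})) == {3: 1.0}

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            isotopomer_distribution(hits_frame({0: 0.0, 1: 0.0}))

    def test_ratio_from_distribution_equals_ratio_from_intensities(self):
        raw = {0: 200.0, 1: 50.0, 4: 250.0}
        dist = isotopomer_distribution(hits_frame(raw))
        r_dist = sum(v for n, v in dist.items() if n >= 1)
        r_raw, _ = labeling_ratio(hits_frame(raw))
        assert r_dist == pytest.approx(r_raw, abs=1e-12)

    def test_envelope_dominated_by_m5_peaks_at_5(self):
        """A ribonucleotide-like envelope concentrated at M+5 (pentose carbons)."""
        dist = isotopomer_distribution(
            hits_frame({0: 100.0, 1: 40.0, 3: 60.0, 5: 700.0, 6: 100.0})
        )
        assert max(dist, key=dist.get) == 5


class TestSummaries:
    def test_summarize_groups_by_ref_and_sample(self):
        df = pd.concat([
            hits_frame({0: 100.0, 2: 100.0}),
            hits_frame({0: 100.0, 2: 300.0}, sample_id="S2"),
            hits_frame({0: 50.0}, ref_id="R1"),
        ])
        out = summarize(df)
        assert len(out) == 3
        by_key = {(s.ref_id, s.sample_id): s for s in out}
        assert by_key[("R0", "S1")].labeling_ratio == 0.5
        assert by_key[("R0", "S2")].labeling_ratio == 0.75
        assert by_key[("R1", "S1")].labeling_ratio == 0.0

    def test_empty_result_gives_no_summaries(self):
        assert summarize(pd.DataFrame()) == []


class TestClassAggregation:
    def test_means_per_class(self):
        refs = [lipid("R0", "PC(16:0/16:0)", "PC", ["16:0", "16:0"]),
                lipid("R1", "PC(16:0/18:1)", "PC", ["16:0", "18:1"]),
                lipid("R2", "TG(16:0/18:1/18:1)", "TG", ["16:0", "18:1", "18:1"])]
        sums = [summary("R0", "S1", 0.4), summary("R1", "S1", 0.6),
                summary("R2", "S1", 0.2)]
        agg = aggregate_lipid_class(sums, refs).set_index("lipid_class")
        assert agg.loc["PC", "mean_ratio"] == pytest.approx(0.5)
        assert agg.loc["TG", "mean_ratio"] == pytest.approx(0.2)
        assert agg.loc["PC", "n_lipids"] == 2

    def test_class_without_summaries_omitted(self):
        refs = [lipid("R0", "PC(16:0/16:0)", "PC", ["16:0"])]
        agg = aggregate_lipid_class([], refs)
        assert len(agg) == 0

    def test_class_mean_within_member_range(self):
        refs = [lipid(f"R{i}", f"PC({i})", "PC", []) for i in range(5)]
        ratios = [0.1, 0.3, 0.5, 0.7, 0.2]
        sums = [summary(f"R{i}", "S1", r) for i, r in enumerate(ratios)]
        agg = aggregate_lipid_class(sums, refs)
        assert min(ratios) <= agg["mean_ratio"].iloc[0] <= max(ratios)


class TestFattyAcidAggregation:
    def test_chain_grouping(self):
        refs = [lipid("R0", "PC(16:0/16:0)", "PC", ["16:0", "16:0"]),
                lipid("R1", "PC(16:0/18:1)", "PC", ["16:0", "18:1"])]
        sums = [summary("R0", "S1", 0.4), summary("R1", "S1", 0.6)]
        agg = aggregate_fatty_acid(sums, refs).set_index("fatty_acid")
        assert agg.loc["16:0", "mean_ratio"] == pytest.approx(0.5)
        assert agg.loc["18:1", "mean_ratio"] == pytest.approx(0.6)
        # duplicated chain within one lipid counts once
        assert agg.loc["16:0", "n_lipids"] == 2

    def test_refs_without_chains_skipped_and_counted(self):
        refs = [lipid("R0", "cholesterol", "ST", [])]
        agg = aggregate_fatty_acid([summary("R0", "S1", 0.3)], refs)
        assert len(agg) == 0
        assert agg.attrs["skipped_no_chains"] == 1

    def test_empty_input(self):
        assert len(aggregate_fatty_acid([], [])) == 0


class TestTimecourse:
    def test_cross_layout_row_count(self):
        sums = [
            summary(ref, s, 0.5)
            for ref in ("R0", "R1")
            for s in ("veh_2", "veh_16", "veh_24", "drug_2", "drug_16", "drug_24")
        ]
        sample_map = {
            f"{cond}_{t}": (cond, float(t))
            for cond in ("veh", "drug") for t in (2, 16, 24)
        }
        table = timecourse_table(sums, sample_map)
        assert len(table) == 12

    def test_missing_summary_row_absent_not_zero(self):
        sums = [summary("R0", "S1", 0.5)]
        table = timecourse_table(sums, {"S1": ("veh", 2.0), "S2": ("veh", 16.0)})
        assert len(table) == 1

    def test_duplicate_sample_mapping_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            timecourse_table(
                [summary("R0", "S1", 0.5)],
                [("S1", "veh", 2.0), ("S1", "drug", 2.0)],
            )

    def test_unmapped_sample_errors(self):
        with pytest.raises(ValueError, match="unmapped"):
            timecourse_table([summary("R0", "SX", 0.5)], {"S1": ("veh", 2.0)})

    def test_compare_conditions_log2(self):
        sums = [summary("R0", "A", 0.8), summary("R0", "B", 0.2)]
        tc = timecourse_table(sums, {"A": ("drug", 24.0), "B": ("veh", 24.0)})
        cmp = compare_conditions(tc, "drug", "veh")
        assert len(cmp) == 1
        assert cmp.iloc[0]["log2_ratio"] == pytest.approx(np.log2(0.8 / 0.2), abs=1e-4)
        assert cmp.iloc[0]["difference"] == pytest.approx(0.6)
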