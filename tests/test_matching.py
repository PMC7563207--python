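"""Joint m/z–RT scoring, gating, grading and the full search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isotrace.chem import get_adduct, isotopomer_mz
from isotrace.matching import (
    MatchParams,
    assign_grade,
    flux_result,
    match_candidates,
    score,
    write_result_csv,
    TABLE_COLUMNS,
)
from isotrace.reference import IsotopomerCandidate, ReferenceEntry, build_candidates

from conftest import brute_force_match, hits_as_set, random_match_instance


def lipid_ref(mz=778.5598, rt=600.0, name="PC(16:0/16:0)"):
    return ReferenceEntry(
        ref_id="R00000", name=name, mode="lipid", mz=mz, rt=rt,
        polarity="negative", adduct=get_adduct("+HCOO"), lipid_class="PC",
        fatty_acids=["16:0", "16:0"],
    )


def feature_df(rows):
    df = pd.DataFrame(rows, columns=["mz", "rt_s", "intensity"])
    df["sample_id"] = "S1"
    df["polarity"] = "negative"
    return df


class TestScore:
    def test_perfect_match(self):
        assert score(0.0, 0.0, 0.1) == 1.0

    def test_orbitrap_typical_deviations(self):
        # ~1.4 ppm at m/z 500 (0.0007 Th) and 0.14 s
        assert score(0.0007, 0.14, 0.1) == pytest.approx(0.86, abs=1e-4)

    def test_cutoff_boundary(self):
        assert score(0.0, 0.39, 0.1) == pytest.approx(0.61, abs=1e-12)

    def test_sum_of_squares_variant(self):
        assert score(0.0, 0.5, 0.1, score_form="sum_of_squares") == pytest.approx(0.75)

    @given(
        st.floats(0, 1), st.floats(0, 10), st.floats(0, 1), st.floats(0, 10)
    )
    def test_strictly_decreasing_in_both_deviations(self, dmz1, drt1, dmz2, drt2):
        s1 = score(dmz1, drt1)
        s2 = score(max(dmz1, dmz2), max(drt1, drt2))
        assert s2 <= s1 <= 1.0

    def test_signs_ignored(self):
        assert score(-0.001, -0.2) == score(0.001, 0.2)


class TestGrades:
    @pytest.mark.parametrize(
        "s,grade", [(1.0, "A"), (0.95, "A"), (0.86, "B"), (0.75, "C"), (0.61, "D")]
    )
    def test_bins(self, s, grade):
        assert assign_grade(s) == grade

    def test_below_cutoff_never_graded(self):
        with pytest.raises(ValueError):
            assign_grade(0.5)


class TestMatchCandidates:
    def test_overlapping_lipid_interferer_rejected_by_ppm_gate(self):
        """An M+0 ion of a heavier co-eluting lipid, 0.0716 Th (~89 ppm) from
        the M+26 candidate, must not steal the assignment."""
        ref = lipid_ref()
        m26 = isotopomer_mz(ref.mz, 26)  # 804.6470
        cands = [IsotopomerCandidate(ref.ref_id, 26, m26)]
        feats = feature_df([
            (m26, 600.0, 2e5),        # planted isotopomer
            (804.5755, 600.0, 8e5),   # interferer (heavier lipid M+0)
        ])
        hits = match_candidates(cands, [ref], feats)
        assert len(hits) == 1
        assert hits.iloc[0]["mz2"] == pytest.approx(m26)
        assert hits.iloc[0]["Score"] == pytest.approx(1.0)

    def test_no_feature_inside_gates_no_hit(self):
        ref = lipid_ref()
        cands = [IsotopomerCandidate(ref.ref_id, 0, ref.mz)]
        feats = feature_df([(ref.mz + 1.0, 600.0, 1e5),     # outside ppm gate
                            (ref.mz, 700.0, 1e5)])           # outside RT gate
        assert len(match_candidates(cands, [ref], feats)) == 0

    def test_score_tie_broken_by_intensity(self):
        ref = lipid_ref(mz=500.0)
        cands = [IsotopomerCandidate(ref.ref_id, 0, 500.0)]
        feats = feature_df([
            (500.001, 600.0, 1e5),
            (499.999, 600.0, 1e6),
        ])
        hits = match_candidates(cands, [ref], feats)
        assert hits.iloc[0]["Intensity"] == 1e6

    def test_one_feature_may_serve_multiple_candidates(self):
        ref_a = lipid_ref(mz=500.0, name="A")
        ref_b = ReferenceEntry(
            ref_id="R00001", name="B", mode="lipid", mz=499.0, rt=600.0,
            polarity="negative", adduct=get_adduct("+HCOO"), lipid_class="PC",
        )
        cands = [
            IsotopomerCandidate("R00000", 0, 500.0),
            IsotopomerCandidate("R00001", 1, isotopomer_mz(499.0, 1)),
        ]
        feats = feature_df([(500.0017, 600.0, 1e5)])
        hits = match_candidates(cands, [ref_a, ref_b], feats)
        assert len(hits) == 2
        assert hits["feature_shared"].all()

    def test_mixed_polarity_rejected(self):
        ref = lipid_ref()
        cands = [IsotopomerCandidate(ref.ref_id, 0, ref.mz)]
        feats = feature_df([(ref.mz, 600.0, 1e5)])
        feats.loc[0, "polarity"] = "positive"
        with pytest.raises(ValueError, match="polarity"):
            match_candidates(cands, [ref], feats)

    def test_hits_satisfy_gates_and_score_recomputes(self):
        rng = np.random.default_rng(11)
        refs, cands, fdf = random_match_instance(rng, n_refs=10, n_features=400)
        params = MatchParams()
        hits = match_candidates(cands, refs, fdf, params)
        assert len(hits) > 0
        for _, h in hits.iterrows():
            assert h["dmz_ppm"] <= params.mz_window_ppm
            assert abs(h["rt2"] - h["rt1"]) <= params.rt_window
            s = score(h["mz2"] - h["Theoretical_mz"], h["rt2"] - h["rt1"], params.beta)
            assert s == pytest.approx(h["Score"], abs=1e-9)
            assert h["Score"] >= params.score_min

    def test_raising_cutoff_only_removes_hits(self):
        rng = np.random.default_rng(5)
        refs, cands, fdf = random_match_instance(rng, n_refs=10, n_features=400)
        loose = hits_as_set(match_candidates(cands, refs, fdf, MatchParams(score_min=0.61)))
        strict = hits_as_set(match_candidates(cands, refs, fdf, MatchParams(score_min=0.9)))
        assert strict <= loose

    def test_common_rt_shift_leaves_hits_unchanged(self):
        rng = np.random.default_rng(9)
        refs, cands, fdf = random_match_instance(rng, n_refs=10, n_features=400)
        base = match_candidates(cands, refs, fdf, MatchParams())

        shifted_refs = []
        for r in refs:
            shifted_refs.append(ReferenceEntry(
                ref_id=r.ref_id, name=r.name, mode=r.mode, mz=r.mz,
                rt=r.rt + 111.0, polarity=r.polarity, adduct=r.adduct))
        fdf2 = fdf.copy()
        fdf2["rt_s"] = fdf2["rt_s"] + 111.0
        shifted = match_candidates(cands, shifted_refs, fdf2, MatchParams())
        assert len(base) == len(shifted)
        assert list(base["Score"]) == pytest.approx(list(shifted["Score"]), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_search(self, seed):
        rng = np.random.default_rng(seed)
        refs, cands, fdf = random_match_instance(rng, n_refs=10, n_features=500)
        params = MatchParams()
        fast = hits_as_set(match_candidates(cands, refs, fdf, params))
        slow = brute_force_match(cands, refs, fdf, params)
        assert fast == slow and len(fast) > 0


class TestFluxResult:
    def test_table_headers_and_determinism(self, tmp_path):
        rng = np.random.default_rng(3)
        refs, _, fdf = random_match_instance(rng, n_refs=8, n_features=300)
        out1, out2 = tmp_path / "r1.csv", tmp_path / "r2.csv"
        flux_result(refs, {"S1": fdf}, out_csv=str(out1))
        flux_result(refs, {"S1": fdf}, out_csv=str(out2))
        assert out1.read_bytes() == out2.read_bytes()
        header = out1.read_text().splitlines()[0].split(",")
        assert header[1:18] == TABLE_COLUMNS

    def test_empty_feature_lists_give_header_only(self, tmp_path, caplog):
        import logging

        refs = [lipid_ref()]
        out = tmp_path / "empty.csv"
        with caplog.at_level(logging.WARNING):
            res = flux_result(refs, {"S1": pd.DataFrame(columns=["sample_id", "polarity", "mz", "rt_s", "intensity"])}, out_csv=str(out))
        assert len(res) == 0
        assert "zero features" in caplog.text
        assert out.read_text().splitlines()[0].split(",")[1:18] == TABLE_COLUMNS

    def test_metabolite_hits_leave_lipid_columns_empty(self):
        ref = ReferenceEntry(
            ref_id="R00000", name="lactate", mode="metabolite", mz=89.0244,
            rt=150.0, polarity="negative", adduct=get_adduct("-H"))
        fdf = feature_df([(89.0244, 150.0, 5e5)])
        res = flux_result([ref], {"S1": fdf})
        assert len(res) == 1
        assert res.iloc[0]["fattyAcid"] == "" and res.iloc[0]["lipidClass"] == ""

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            flux_result([], {})

    def test_params_validation(self):
        with pytest.raises(ValueError):
            MatchParams(score_min=0.0)
        with pytest.raises(ValueError):
            MatchParams(beta=-1)
        with pytest.raises(ValueError):
            MatchParams(rt_unit="hours")
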