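"""POA rule, category mapping/hierarchy, exclusion algorithm, frequency
filter and the seven design-matrix schemes."""

import numpy as np
import pandas as pd
import pytest

import payrisk as pr


def dx_frame(rows):
    return pd.DataFrame(rows, columns=["admission_id", "code", "role",
                                       "poa", "window"])


class TestPoaRule:
    # full truth table for secondary diagnoses; D002 is exempt, D003 not
    @pytest.mark.parametrize("poa,code,kept", [
        ("Y", "D003", True),
        ("Y", "D002", True),
        ("N", "D003", False),
        ("N", "D002", False),          # exemption does not rescue an explicit N
        ("missing", "D002", True),
        ("missing", "D003", False),
    ])
    def test_secondary_truth_table(self, toy_maps, poa, code, kept):
        dx = dx_frame([(1, code, "secondary", poa, "index")])
        out = pr.poa_eligible(dx, toy_maps)
        assert (len(out) == 1) == kept

    def test_principal_always_kept(self, toy_maps):
        dx = dx_frame([(1, "D003", "principal", "Y", "index")])
        assert len(pr.poa_eligible(dx, toy_maps)) == 1

    def test_unknown_token_rejected(self, toy_maps):
        dx = dx_frame([(1, "D003", "secondary", "yes", "index")])
        with pytest.raises(ValueError, match="POA"):
            pr.poa_eligible(dx, toy_maps)

    def test_idempotent(self, toy_maps):
        dx = dx_frame([
            (1, "D001", "principal", "Y", "index"),
            (1, "D002", "secondary", "missing", "index"),
            (1, "D003", "secondary", "N", "index"),
        ])
        once = pr.poa_eligible(dx, toy_maps)
        assert pr.poa_eligible(once, toy_maps).equals(once)


class TestCategoryMapping:
    def test_hierarchy_suppression(self, toy_maps):
        # D001 -> CC01 outranks D005 -> CC02 within group G1
        assert pr.map_to_ccs(["D001", "D005"], toy_maps) == {"CC01"}
        assert pr.map_to_ccs(["D005"], toy_maps) == {"CC02"}
        assert pr.map_to_ccs([], toy_maps) == set()

    def test_unmapped_counted_not_raised(self, toy_maps):
        counter = {}
        out = pr.map_to_ccs(["D057", "D001"], toy_maps, counter)
        assert out == {"CC01"} and counter["unmapped"] == 1


class TestBaseModelExclusion:
    def make(self, history_code=None):
        # D029 -> CC08 (excludable); principal D001
        idx = dx_frame([(1, "D001", "principal", "Y", "index"),
                        (1, "D029", "secondary", "N", "index")])
        his = dx_frame([] if history_code is None else
                       [(1, history_code, "secondary", None, "history")])
        return idx, his

    def test_index_only_excludable_dropped(self, toy_maps):
        idx, his = self.make()
        out = pr.base_model_exclusion(idx, his, toy_maps)
        assert "D029" not in set(out["code"])

    def test_same_category_in_history_rescues(self, toy_maps):
        # D030 also maps to CC08
        idx, his = self.make(history_code="D030")
        out = pr.base_model_exclusion(idx, his, toy_maps)
        assert "D029" in set(out["code"])

    def test_non_excludable_kept_without_history(self, toy_maps):
        idx = dx_frame([(1, "D005", "secondary", "N", "index")])
        out = pr.base_model_exclusion(idx, idx.iloc[0:0], toy_maps)
        assert len(out) == 1


class TestFrequencyFilter:
    def test_strict_inequality_at_half_percent(self):
        dx = dx_frame([(i, "D001", "secondary", "Y", "index")
                       for i in range(5)])
        assert pr.frequency_filter(dx, 1000) == []          # 0.5% not > 0.5%
        dx6 = dx_frame([(i, "D001", "secondary", "Y", "index")
                        for i in range(6)])
        assert pr.frequency_filter(dx6, 1000) == ["D001"]

    def test_duplicate_code_in_one_admission_counts_once(self):
        dx = dx_frame([(1, "D001", "secondary", "Y", "index"),
                       (1, "D001", "secondary", "Y", "index"),
                       (2, "D002", "secondary", "Y", "index")])
        # counted twice, D001 would clear 0.5; once, it does not
        assert pr.frequency_filter(dx, 3, threshold=0.5) == []
        assert pr.frequency_filter(dx, 3, threshold=0.3) == ["D001", "D002"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            pr.frequency_filter(dx_frame([]), 10, threshold=1.0)


class TestBuildDesign:
    def test_history_only_category_by_scheme(self, small_bundle, toy_maps):
        """CC07 appears only in admission 1's history: absent from
        hcc_index, present in hcc_pooled, history-side of hcc_separate."""
        coh = pr.build_cohort(small_bundle, "HF")
        get = lambda s: pr.build_design(coh, small_bundle,
                                        pr.Scheme(s, toy_maps)).X.loc[1]
        assert "CC07" not in get("hcc_index").index
        assert get("hcc_pooled")["CC07"] == 1
        sep = get("hcc_separate")
        assert sep["CC07__history"] == 1 and "CC07__index" not in sep.index

    def test_no_diagnoses_row_has_age_columns_only(self, small_bundle, toy_maps):
        coh = pr.build_cohort(small_bundle, "HF")
        d = pr.build_design(coh, small_bundle, pr.Scheme("hcc_pooled", toy_maps))
        row3 = d.X.loc[3]
        comorb = [c for c in d.X.columns if c not in d.forced]
        assert row3[comorb].sum() == 0 and row3["age_85p"] == 1

    def test_code_in_both_windows_gives_two_columns(self, toy_maps):
        adm = pd.DataFrame({
            "admission_id": range(1, 11), "patient_id": range(1, 11),
            "hospital_id": 1, "condition": "HF", "age_years": 70,
            "payment_30d": 100.0, "died_30d": 0})
        rows = [(1, "D001", "secondary", "Y", "index"),
                (1, "D001", "secondary", None, "history")]
        rows += [(i, "D001", "principal", "Y", "index") for i in range(2, 11)]
        dx = dx_frame(rows)
        enr = pd.DataFrame({"patient_id": range(1, 11),
                            "prior_ffs_months": 24})
        b = pr.ClaimsBundle(adm, dx, enr).validate()
        coh = pr.build_cohort(b, "HF")
        d = pr.build_design(coh, b, pr.Scheme("codes_index_history", toy_maps,
                                              freq_threshold=0.0))
        assert d.X.loc[1, "D001__index"] == 1
        assert d.X.loc[1, "D001__history"] == 1

    def test_pooled_equals_or_of_separate(self, hf_bundle_5k, hf_cohort_5k,
                                          toy_maps):
        dp = pr.build_design(hf_cohort_5k, hf_bundle_5k,
                             pr.Scheme("hcc_pooled", toy_maps))
        ds = pr.build_design(hf_cohort_5k, hf_bundle_5k,
                             pr.Scheme("hcc_separate", toy_maps))
        for cc in [c for c in dp.X.columns if c.startswith("CC")]:
            i = ds.X.get(cc + "__index")
            h = ds.X.get(cc + "__history")
            orv = np.zeros(len(dp.X), dtype=int)
            if i is not None:
                orv |= i.to_numpy().astype(int)
            if h is not None:
                orv |= h.to_numpy().astype(int)
            np.testing.assert_array_equal(dp.X[cc].to_numpy(), orv)

    def test_row_order_invariance(self, hf_bundle_5k, hf_cohort_5k, toy_maps):
        shuffled = pr.ClaimsBundle(
            hf_bundle_5k.index_admissions,
            hf_bundle_5k.diagnoses.sample(frac=1.0, random_state=0),
            hf_bundle_5k.enrollment,
        )
        for name in ("cms_base", "codes_index_history"):
            a = pr.build_design(hf_cohort_5k, hf_bundle_5k,
                                pr.Scheme(name, toy_maps)).X
            b = pr.build_design(hf_cohort_5k, shuffled,
                                pr.Scheme(name, toy_maps)).X
            pd.testing.assert_frame_equal(a, b)

    def test_unknown_scheme_rejected(self, toy_maps):
        with pytest.raises(ValueError, match="unknown scheme"):
            pr.Scheme("hcc_everything", toy_maps)

    def test_provenance_tags(self, small_bundle, toy_maps):
        coh = pr.build_cohort(small_bundle, "HF")
        d = pr.build_design(coh, small_bundle,
                            pr.Scheme("hcc_separate", toy_maps))
        assert d.provenance["CC07__history"] == {"channel": "history",
                                                 "unit": "cc"}
        assert d.provenance["age_85p"]["unit"] == "age"
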