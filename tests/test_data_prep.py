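"""Record preparation: SCS transform, trait collapsing, class coding,
stacking filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thresholdsire as ts

TABLE1_COUNTS = np.array([7078, 2687, 838, 173])  # observed score histogram


class TestScsTransform:
    @pytest.mark.parametrize(
        "scc,expected", [(100_000, 3.0), (400_000, 5.0), (50_000, 2.0)]
    )
    def test_known_values(self, scc, expected):
        assert ts.scs_from_scc(scc) == pytest.approx(expected)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            ts.scs_from_scc(0.0)

    @given(st.floats(min_value=1e2, max_value=1e8))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_and_monotone(self, scc):
        scs = ts.scs_from_scc(scc)
        assert ts.scc_from_scs(scs) == pytest.approx(scc, rel=1e-9)
        assert ts.scs_from_scc(scc * 2) > scs


class TestCollapse:
    def test_definitions(self):
        assert ts.collapse_ts(2, "a") == 1
        assert ts.collapse_ts(2, "b") == 0
        assert ts.collapse_ts(1, "a") == 0
        assert ts.collapse_ts(3, "b") == 1

    def test_observed_histogram_shares(self):
        # the published score histogram: 65.7% absent callosity; 9.4% rough
        # or very rough ring
        scores = np.repeat([1, 2, 3, 4], TABLE1_COUNTS)
        share_low_a = (ts.collapse_ts(scores, "a") == 0).mean()
        share_high_b = (ts.collapse_ts(scores, "b") == 1).mean()
        assert share_low_a * 100 == pytest.approx(65.7, abs=0.05)
        assert share_high_b * 100 == pytest.approx(9.4, abs=0.05)
        assert (1 - share_high_b) * 100 == pytest.approx(90.6, abs=0.05)

    def test_counts_preserved_vs_direct_tabulation(self):
        scores = np.repeat([1, 2, 3, 4], TABLE1_COUNTS)
        a = ts.collapse_ts(scores, "a")
        assert np.bincount(a).tolist() == [7078, 2687 + 838 + 173]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ts.collapse_ts(5, "a")
        with pytest.raises(ValueError):
            ts.collapse_ts(2, "c")


class TestParityStageClass:
    def test_first_cell(self):
        assert ts.parity_stage_class(1, 1) == 1

    def test_capping(self):
        assert ts.parity_stage_class(5, 14) == ts.parity_stage_class(3, 12)

    def test_all_36_classes_reachable(self):
        seen = {
            ts.parity_stage_class(p, m)
            for p in range(1, 5)
            for m in range(1, 16)
        }
        assert seen == set(range(1, 37))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ts.parity_stage_class(0, 1)
        with pytest.raises(ValueError):
            ts.parity_stage_class(1, 0)


def _toy_records():
    teat = pd.DataFrame(
        {
            "cow": ["c1"] * 4 + ["c2"] * 3 + ["c3"] * 4,
            "herd": 1,
            "parity": 1,
            "month": 2,
            "hygiene": 1,
            "quarter": ["FL", "FR", "RL", "RR"] * 2 + ["FL", "FR", "RL"],
            "score": 1,
        }
    )
    prod = pd.DataFrame(
        {
            "cow": ["c1", "c1", "c2", "c3", "c3"],
            "herd": 1,
            "parity": [1, 1, 1, 1, 2],
            "month": [1, 2, 1, 1, 3],
            "my": 30.0,
            "scc": 200_000.0,
        }
    )
    sire_of = {"c1": "s1", "c2": "s1", "c3": "s2"}
    return teat, prod, sire_of


class TestStacking:
    def test_incomplete_quarters_dropped(self):
        teat, prod, sire_of = _toy_records()
        out = ts.stack_datasets(teat, prod, sire_of)
        # c2 has 3 quarters -> dropped entirely; c3's parity-2 record is from
        # another lactation -> dropped
        assert out.n_teat == 8
        assert out.n_prod == 3
        assert out.filter_log["cows_incomplete_quarters"] == 1
        assert out.filter_log["prod_rows_other_lactation"] == 1

    def test_no_row_carries_both_blocks(self):
        teat, prod, sire_of = _toy_records()
        df = ts.stack_datasets(teat, prod, sire_of).df
        teat_rows = df[df["block"] == "teat"]
        prod_rows = df[df["block"] == "prod"]
        assert teat_rows["my"].isna().all() and teat_rows["scs"].isna().all()
        assert prod_rows["score"].isna().all()

    def test_empty_production(self):
        teat, prod, sire_of = _toy_records()
        out = ts.stack_datasets(teat, prod.iloc[0:0], sire_of)
        assert out.n_prod == 0 and out.n_teat == 8

    def test_cow_absent_from_pedigree_dropped(self):
        teat, prod, sire_of = _toy_records()
        del sire_of["c1"]
        out = ts.stack_datasets(teat, prod, sire_of)
        assert out.filter_log["teat_cows_not_in_pedigree"] == 1
        assert out.n_teat == 4

    def test_scs_computed_and_missing_flagged(self):
        teat, prod, sire_of = _toy_records()
        prod.loc[0, "scc"] = np.nan
        out = ts.stack_datasets(teat, prod, sire_of)
        prod_rows = out.df[out.df["block"] == "prod"]
        assert prod_rows["scs"].isna().sum() == 1
        assert prod_rows["scs"].dropna().iloc[0] == pytest.approx(4.0)

    def test_roundtrip_write_read(self, tmp_path):
        teat, prod, sire_of = _toy_records()
        out = ts.stack_datasets(teat, prod, sire_of)
        out.write(tmp_path / "stacked.tsv")
        back = ts.StackedData.read(tmp_path / "stacked.tsv")
        assert back.n_teat == out.n_teat and back.n_prod == out.n_prod
        assert back.sire_levels == [str(s) for s in out.sire_levels]
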