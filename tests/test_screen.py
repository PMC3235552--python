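"""Hit calling, classification, and screen summary statistics."""

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fragxscreen import labels
from fragxscreen.screen import (
    HitClassification,
    call_hits,
    class_property_distributions,
    classify,
    fold_selectivity,
    hit_rate,
    ligand_efficiency,
    overlap_percentages,
)


def screen_frame(rows):
    return pd.DataFrame(rows, columns=["fragment_id", "target_id", "percent_effect", "pki"])


def make_classification(n_a: int, n_b: int, n_dual: int, n_total: int) -> HitClassification:
    """Synthetic id partition with |hits A| = n_a, |hits B| = n_b, |dual| = n_dual."""
    ids = [f"f{i}" for i in range(n_total)]
    dual = ids[:n_dual]
    a_only = ids[n_dual:n_a]
    b_only = ids[n_a : n_a + (n_b - n_dual)]
    inactive = ids[n_a + (n_b - n_dual):]
    return HitClassification(
        target_a="A",
        target_b="B",
        a_selective=frozenset(a_only),
        b_selective=frozenset(b_only),
        dual=frozenset(dual),
        inactive=frozenset(inactive),
    )


class TestCallHits:
    def test_boundary_at_cutoff(self):
        table = call_hits(
            screen_frame(
                [("x", "A", 50.0, None), ("y", "A", 49.9, None), ("z", "A", 0.0, None)]
            )
        )
        assert table.set_index("fragment_id")["is_hit"].to_dict() == {
            "x": True,
            "y": False,
            "z": False,
        }

    def test_all_zero_screen_has_no_hits(self):
        table = call_hits(screen_frame([(f"f{i}", "A", 0.0, None) for i in range(20)]))
        assert not table["is_hit"].any()

    def test_out_of_range_effect_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            call_hits(screen_frame([("x", "A", 101.0, None)]))
        with pytest.raises(ValueError, match="outside"):
            call_hits(screen_frame([("x", "A", -1.0, None)]))

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            call_hits(screen_frame([("x", "A", 10.0, None), ("x", "A", 20.0, None)]))

    def test_configurable_cutoff(self):
        table = call_hits(screen_frame([("x", "A", 80.0, None)]), cutoff=90.0)
        assert not table["is_hit"].any()


class TestClassify:
    def _screens(self, hits_a, hits_b, lib):
        a = screen_frame([(i, "A", 100.0 if i in hits_a else 0.0, None) for i in lib])
        b = screen_frame([(i, "B", 100.0 if i in hits_b else 0.0, None) for i in lib])
        return call_hits(a), call_hits(b)

    def test_shared_hit_is_dual(self):
        a, b = self._screens({"x"}, {"x"}, ["x", "y"])
        c = classify(a, b, ["x", "y"])
        assert c.dual == {"x"} and c.inactive == {"y"}
        assert c.a_selective == c.b_selective == frozenset()

    def test_single_target_hit_is_selective(self):
        a, b = self._screens({"x"}, set(), ["x", "y"])
        c = classify(a, b, ["x", "y"])
        assert c.a_selective == {"x"}

    def test_partition_covers_library(self, default_screen, default_library):
        screen_a, screen_b, truth = default_screen
        lib_ids = [m.identifier for m in default_library]
        c = classify(screen_a, screen_b, lib_ids)
        sizes = [len(c.a_selective), len(c.b_selective), len(c.dual), len(c.inactive)]
        assert sum(sizes) == len(lib_ids)
        assert c.as_mapping() == truth.as_mapping()

    def test_row_order_invariance(self):
        lib = [f"f{i}" for i in range(30)]
        a, b = self._screens({"f1", "f2"}, {"f2", "f9"}, lib)
        shuffled = classify(a.sample(frac=1, random_state=3), b.sample(frac=1, random_state=4), lib)
        assert shuffled.as_mapping() == classify(a, b, lib).as_mapping()

    def test_missing_fragment_reported(self):
        a, b = self._screens({"x"}, set(), ["x"])
        with pytest.raises(ValueError, match=r"missing from screen A: \['ghost'\]"):
            classify(a, b, ["x", "ghost"])


class TestRates:
    @pytest.mark.parametrize(
        "n_hits,n_lib,expected", [(56, 1010, 6), (70, 1010, 7), (0, 1010, 0), (1010, 1010, 100)]
    )
    def test_printed_count_arithmetic(self, n_hits, n_lib, expected):
        assert hit_rate(n_hits, n_lib) == expected

    def test_half_up_rounding(self):
        assert hit_rate(5, 200) == 3  # 2.5 rounds up
        assert hit_rate(1, 200) == 1  # 0.5 rounds up

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hit_rate(1, 0)
        with pytest.raises(ValueError):
            hit_rate(5, 4)

    @given(st.integers(min_value=1, max_value=5000), st.data())
    def test_matches_decimal_oracle(self, n_lib, data):
        n_hits = data.draw(st.integers(min_value=0, max_value=n_lib))
        expected = int(
            (Decimal(100) * n_hits / n_lib).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        )
        assert hit_rate(n_hits, n_lib) == expected


class TestOverlap:
    def test_screen_counts_give_24_and_30(self):
        c = make_classification(n_a=56, n_b=70, n_dual=17, n_total=1010)
        assert overlap_percentages(c) == (24, 30)

    def test_full_overlap_and_none(self):
        assert overlap_percentages(make_classification(5, 5, 5, 20)) == (100, 100)
        assert overlap_percentages(make_classification(5, 5, 0, 20)) == (0, 0)

    def test_empty_hit_set_rejected(self):
        with pytest.raises(ValueError, match="no hits"):
            overlap_percentages(make_classification(0, 5, 0, 20))


class TestFoldSelectivity:
    def test_printed_affinity_pairs(self):
        fs9 = fold_selectivity(8.8, 6.1)
        assert fs9.raw == pytest.approx(501.2, abs=0.1)
        assert fs9.rounded == 500
        fs10 = fold_selectivity(8.2, 5.9)
        assert fs10.raw == pytest.approx(199.5, abs=0.1)
        assert fs10.rounded == 200

    def test_equal_affinities_fold_one(self):
        assert fold_selectivity(6.5, 6.5).raw == 1.0

    @given(
        st.floats(min_value=0.5, max_value=12, allow_nan=False),
        st.floats(min_value=0.5, max_value=12, allow_nan=False),
    )
    def test_reciprocal_product_is_one(self, x, y):
        assert fold_selectivity(x, y).raw * fold_selectivity(y, x).raw == pytest.approx(1.0)


class TestLigandEfficiency:
    def test_reference_value(self):
        assert ligand_efficiency(7.0, 13) == pytest.approx(1.364 * 7.0 / 13, abs=1e-3)

    def test_zero_affinity_limit_and_scaling(self):
        assert ligand_efficiency(0.0, 10) == 0.0
        assert ligand_efficiency(6.0, 20) == pytest.approx(ligand_efficiency(6.0, 10) / 2)

    def test_invalid_heavy_atoms(self):
        with pytest.raises(ValueError):
            ligand_efficiency(6.0, 0)


class TestClassDistributions:
    def test_single_member_class_mean(self):
        c = HitClassification(
            target_a="A",
            target_b="B",
            a_selective=frozenset({"x"}),
            b_selective=frozenset(),
            dual=frozenset(),
            inactive=frozenset({"y"}),
        )
        desc = pd.DataFrame(
            {"identifier": ["x", "y"], "hbd": [2, 0], "clogp": [1.0, 2.0]}
        )
        summary, hists = class_property_distributions(c, desc, columns=["hbd", "clogp"])
        row = summary[(summary["hit_class"] == labels.A_SELECTIVE) & (summary["descriptor"] == "hbd")]
        assert row.iloc[0]["mean"] == 2.0 and row.iloc[0]["n"] == 1
        assert sum(hists["hbd"][labels.A_SELECTIVE]["counts"]) == 1

    def test_histogram_counts_cover_class(self, default_screen, default_library):
        from fragxscreen.chem import descriptor_table

        _sa, _sb, truth = default_screen
        desc = descriptor_table(default_library)
        summary, hists = class_property_distributions(truth, desc, columns=["hbd", "heavy_atoms"])
        for cls_hist in hists["hbd"].values():
            assert sum(cls_hist["counts"]) > 0
        totals = summary[summary["descriptor"] == "hbd"]["n"].sum()
        assert totals == len(default_library)
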