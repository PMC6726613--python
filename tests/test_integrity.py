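import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnkit.integrity import (
    DEFAULT_WEIGHTS,
    RegulatoryWeights,
    direction_of,
    integrity_score,
    overlap_summary,
    rank_and_select,
    regulatory_fold_change,
    rfc_table,
    score_all,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestIntegrityScore:
    def test_unit_expression_default_weights(self):
        # 0.5 + 0.375 + 0.75
        assert integrity_score(1, 1, 1) == pytest.approx(1.625)

    def test_tf_doubled(self):
        # 1.0 + 0.375 + 1.5
        assert integrity_score(2, 1, 1) == pytest.approx(2.875)

    def test_matches_second_implementation_on_random_draws(self):
        # DERIVED: dual-path check via an independent pairwise-product sum
        rng = np.random.default_rng(41)
        w = DEFAULT_WEIGHTS
        for _ in range(50):
            e_tf, e_gene, e_mir = rng.uniform(0.1, 50, size=3)
            weighted = [w.r_tf * e_tf, w.r_gene * e_gene, w.r_mir * e_mir]
            expected = sum(
                weighted[i] * weighted[j]
                for i in range(3) for j in range(i + 1, 3)
            )
            assert integrity_score(e_tf, e_gene, e_mir, w) == pytest.approx(expected)

    @pytest.mark.parametrize("role,args", [
        ("tf", (0, 1, 1)), ("gene", (1, -2, 1)), ("mir", (1, 1, 0)),
    ])
    def test_nonpositive_expression_names_role(self, role, args):
        with pytest.raises(ValueError, match=role):
            integrity_score(*args)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="r_mir"):
            RegulatoryWeights(r_mir=0)

    @settings(max_examples=100, deadline=None)
    @given(e_tf=positive, e_gene=positive, e_mir=positive, c=positive)
    def test_scale_law(self, e_tf, e_gene, e_mir, c):
        n = integrity_score(e_tf, e_gene, e_mir)
        scaled = integrity_score(c * e_tf, c * e_gene, c * e_mir)
        assert scaled == pytest.approx(c * c * n, rel=1e-12)


def grn_frame(n, prefix="GRN"):
    return pd.DataFrame(
        {
            "grn_id": [f"{prefix}{i}" for i in range(n)],
            "motif_type": ["G"] * n,
            "tf": [f"TF{i}" for i in range(n)],
            "gene": [f"G{i}" for i in range(n)],
            "mirna": [f"hsa-miR-{i}" for i in range(n)],
        }
    )


def summaries_for(grns, rng=None, conditions=("CONTROL", "RRMS", "PPMS", "SPMS")):
    rng = rng or np.random.default_rng(0)
    entities = pd.unique(grns[["tf", "gene", "mirna"]].to_numpy().ravel())
    return pd.DataFrame(
        rng.uniform(1, 10, size=(len(entities), len(conditions))),
        index=entities,
        columns=list(conditions),
    )


class TestScoreAll:
    def test_two_grns_four_conditions_eight_records(self):
        grns = grn_frame(2)
        records, dropped = score_all(grns, summaries_for(grns))
        assert len(records) == 8 and dropped == 0

    def test_record_count_is_4k(self):
        k = 37
        grns = grn_frame(k)
        records, _ = score_all(grns, summaries_for(grns))
        assert len(records) == 4 * k

    def test_missing_summary_grns_dropped_with_count(self):
        grns = grn_frame(3)
        summ = summaries_for(grns).drop(index="TF1")
        with pytest.warns(UserWarning, match="dropped 1"):
            records, dropped = score_all(grns, summ)
        assert dropped == 1 and len(records) == 8

    def test_spot_check_against_integrity_score(self):
        # DERIVED: 10 random rows recomputed one at a time
        grns = grn_frame(20)
        summ = summaries_for(grns)
        records, _ = score_all(grns, summ)
        rng = np.random.default_rng(2)
        for _, row in records.sample(10, random_state=3).iterrows():
            expected = integrity_score(row.e_tf, row.e_gene, row.e_mir)
            assert row.N == pytest.approx(expected)


class TestRfc:
    def test_down(self):
        rfc = regulatory_fold_change(1.625, 3.25)
        assert rfc == pytest.approx(0.5) and direction_of(rfc) == "DOWN"

    def test_up(self):
        rfc = regulatory_fold_change(3.25, 1.625)
        assert rfc == pytest.approx(2.0) and direction_of(rfc) == "UP"

    def test_equal_is_unclassified(self):
        assert direction_of(regulatory_fold_change(2.0, 2.0)) is None

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            regulatory_fold_change(1.0, 0.0)


def records_from_rfc(rfc_by_grn, motif_types=None):
    """Score table with N_control = 1 so N_MS == desired RFC, all contrasts."""
    rows = []
    for i, (grn_id, rfc) in enumerate(rfc_by_grn.items()):
        mt = (motif_types or {}).get(grn_id, "G")
        for cond, n in [("CONTROL", 1.0), ("RRMS", rfc), ("PPMS", rfc), ("SPMS", rfc)]:
            rows.append({"grn_id": grn_id, "motif_type": mt, "condition": cond,
                         "e_tf": 1, "e_gene": 1, "e_mir": 1, "N": n})
    return pd.DataFrame(rows)


class TestRankAndSelect:
    def test_240_selected_with_sufficient_candidates(self):
        rng = np.random.default_rng(50)
        rfcs, types = {}, {}
        for mt in ("CL1", "G", "TFC", "MIR"):
            for i in range(12):
                gid = f"{mt}_up{i}"
                rfcs[gid], types[gid] = float(rng.uniform(1.5, 4)), mt
                gid = f"{mt}_dn{i}"
                rfcs[gid], types[gid] = float(rng.uniform(0.2, 0.7)), mt
        records = records_from_rfc(rfcs, types)
        total = sum(
            len(rank_and_select(records, c))
            for c in ("RRMS_vs_CONTROL", "PPMS_vs_CONTROL", "SPMS_vs_CONTROL")
        )
        assert total == 240

    def test_degenerate_direction_returns_all_with_warning(self):
        rfcs = {f"up{i}": 2.0 + i for i in range(5)}
        rfcs.update({f"dn{i}": 0.5 for i in range(12)})
        records = records_from_rfc(rfcs)
        with pytest.warns(UserWarning, match="only 5"):
            sel = rank_and_select(records, "RRMS_vs_CONTROL")
        assert (sel["direction"] == "UP").sum() == 5
        assert (sel["direction"] == "DOWN").sum() == 10

    def test_rfc_exactly_one_excluded(self):
        records = records_from_rfc({"flat": 1.0, "up": 2.0, "dn": 0.5})
        sel = rank_and_select(records, "RRMS_vs_CONTROL", k_up=5, k_down=5)
        assert "flat" not in set(sel["grn_id"])

    def test_matches_full_sort_oracle(self):
        # DERIVED: brute-force sort-then-slice
        rng = np.random.default_rng(51)
        rfcs = {f"g{i}": float(rng.uniform(0.1, 5)) for i in range(200)}
        records = records_from_rfc(rfcs)
        sel = rank_and_select(records, "SPMS_vs_CONTROL")
        ups = sorted(((r, g) for g, r in rfcs.items() if r > 1), key=lambda t: (-t[0], t[1]))
        downs = sorted(((r, g) for g, r in rfcs.items() if r < 1), key=lambda t: (t[0], t[1]))
        expected_up = [g for _, g in ups[:10]]
        expected_down = [g for _, g in downs[:10]]
        assert list(sel.loc[sel["direction"] == "UP", "grn_id"]) == expected_up
        assert list(sel.loc[sel["direction"] == "DOWN", "grn_id"]) == expected_down
        assert list(sel.loc[sel["direction"] == "UP", "rank"]) == list(range(1, 11))

    def test_ties_break_by_grn_id(self):
        records = records_from_rfc({"b": 2.0, "a": 2.0, "c": 2.0})
        sel = rank_and_select(records, "RRMS_vs_CONTROL", k_up=2, k_down=0)
        assert list(sel["grn_id"]) == ["a", "b"]

    def test_unknown_contrast_errors(self):
        records = records_from_rfc({"a": 2.0})
        with pytest.raises(ValueError, match="contrast"):
            rank_and_select(records, "RRMS_vs_PPMS")

    def test_rfc_invariant_under_common_rescaling(self):
        grns = grn_frame(5)
        summ = summaries_for(grns)
        r1, _ = score_all(grns, summ)
        r2, _ = score_all(grns, summ * 3.7)
        t1 = rfc_table(r1, "RRMS_vs_CONTROL").set_index("grn_id")["rfc"]
        t2 = rfc_table(r2, "RRMS_vs_CONTROL").set_index("grn_id")["rfc"]
        pd.testing.assert_series_equal(t1, t2, rtol=1e-12)


def selection(ids, motif_type="G", contrast="RRMS_vs_CONTROL"):
    return pd.DataFrame(
        {
            "grn_id": list(ids),
            "motif_type": motif_type,
            "contrast": contrast,
            "rfc": 2.0,
            "direction": "UP",
            "rank": range(1, len(ids) + 1),
        }
    )


class TestOverlapSummary:
    CONTRASTS = ("RRMS_vs_CONTROL", "PPMS_vs_CONTROL", "SPMS_vs_CONTROL")

    def test_identical_selections_all_common(self):
        sels = {c: selection(["a", "b"], contrast=c) for c in self.CONTRASTS}
        regions = overlap_summary(sels)["G"]
        assert regions["ALL"] == {"a", "b"}
        assert regions["RRMS_only"] == set()
        assert regions["PPMS_SPMS"] == set()

    def test_disjoint_selections_singleton_regions(self):
        ids = {"RRMS_vs_CONTROL": ["a"], "PPMS_vs_CONTROL": ["b"], "SPMS_vs_CONTROL": ["c"]}
        sels = {c: selection(ids[c], contrast=c) for c in self.CONTRASTS}
        regions = overlap_summary(sels)["G"]
        assert regions["RRMS_only"] == {"a"}
        assert regions["PPMS_only"] == {"b"}
        assert regions["SPMS_only"] == {"c"}
        assert regions["ALL"] == set()

    def test_matches_bruteforce_set_algebra(self):
        # DERIVED: regions recomputed by explicit set expressions
        rng = np.random.default_rng(60)
        pools = {c: [f"g{i}" for i in rng.choice(30, size=12, replace=False)]
                 for c in self.CONTRASTS}
        sels = {c: selection(pools[c], contrast=c) for c in self.CONTRASTS}
        regions = overlap_summary(sels)["G"]
        r, p, s = (set(pools[c]) for c in self.CONTRASTS)
        assert regions["RRMS_only"] == r - p - s
        assert regions["PPMS_only"] == p - r - s
        assert regions["SPMS_only"] == s - r - p
        assert regions["PPMS_RRMS"] == (r & p) - s
        assert regions["RRMS_SPMS"] == (r & s) - p
        assert regions["PPMS_SPMS"] == (p & s) - r
        assert regions["ALL"] == r & p & s

    def test_missing_contrast_errors(self):
        with pytest.raises(ValueError, match="missing"):
            overlap_summary({"RRMS_vs_CONTROL": selection(["a"])})
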