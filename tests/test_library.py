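"""Construct library: allocation, classification, enumeration, decision trees."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprar.errors import ConfigurationError
from crisprar.library import (
    CrisprarConstruct,
    SgRNAModule,
    allocate_concentrations,
    classify_construct,
    decision_tree_select,
    default_library,
    default_modules,
    enumerate_library,
    library_from_config,
)


def _module(name="A1", role="activator", strand="coding", pam=70, promoter="pStr", strength=12.0):
    if role == "repressor":
        pam = 50
    return SgRNAModule(
        name=name, role=role, target_strand=strand, pam_position=pam,
        promoter=promoter, promoter_strength=strength,
    )


def _construct(act_strand="non_coding", rep_strand="coding", s_a=12.0, s_r=12.0,
               pa="pStr", pr="pStr"):
    act = _module("A", "activator", act_strand, 70, pa, s_a)
    rep = _module("R", "repressor", rep_strand, 50, pr, s_r)
    conc_A, conc_R = allocate_concentrations(s_a, s_r)
    return CrisprarConstruct("A+R", act, rep, conc_A, conc_R)


class TestAllocation:
    @pytest.mark.parametrize(
        "s_a,s_r,expected",
        [
            (1.0, 1.0, (0.5, 0.5)),
            (12.0, 1.0, (12 / 13, 1 / 13)),
            (12.0, 2.4, (12 / 14.4, 2.4 / 14.4)),
        ],
    )
    def test_proportional_split(self, s_a, s_r, expected):
        assert allocate_concentrations(s_a, s_r) == pytest.approx(expected, rel=1e-12)

    @given(
        s_a=st.floats(min_value=1e-3, max_value=1e3),
        s_r=st.floats(min_value=1e-3, max_value=1e3),
        c=st.floats(min_value=1e-2, max_value=1e2),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariant_and_sums_to_one(self, s_a, s_r, c):
        a1, r1 = allocate_concentrations(s_a, s_r)
        a2, r2 = allocate_concentrations(c * s_a, c * s_r)
        assert a1 + r1 == pytest.approx(1.0)
        assert (a1, r1) == pytest.approx((a2, r2), rel=1e-9)

    def test_non_positive_strength_rejected(self):
        with pytest.raises(ConfigurationError):
            allocate_concentrations(0.0, 1.0)


class TestClassification:
    def test_group_definitions(self):
        c = _construct(act_strand="non_coding", rep_strand="coding")
        labels = classify_construct(c)
        assert (labels.rule1, labels.rule2, labels.rule3) == (
            "a_noncoding", "opposite_strand", "equal_conc",
        )
        c = _construct(act_strand="coding", rep_strand="coding", s_a=12.0, s_r=1.0,
                       pa="pStr", pr="pWeak")
        labels = classify_construct(c)
        assert (labels.rule1, labels.rule2, labels.rule3) == (
            "a_coding", "same_strand", "unequal_conc",
        )

    def test_deterministic(self):
        c = _construct()
        assert classify_construct(c) == classify_construct(c)

    def test_every_construct_gets_one_label_per_rule(self):
        for c in default_library():
            labels = classify_construct(c)
            assert labels.rule1 in ("a_noncoding", "a_coding")
            assert labels.rule2 in ("same_strand", "opposite_strand")
            assert labels.rule3 in ("equal_conc", "unequal_conc")

    def test_pam_window_enforced(self):
        with pytest.raises(ConfigurationError):
            SgRNAModule("X", "repressor", "coding", 80, "pStr", 12.0)
        with pytest.raises(ConfigurationError):
            SgRNAModule("X", "activator", "coding", 45, "pStr", 12.0)


class TestEnumeration:
    def test_default_library_counts(self):
        lib = default_library()
        assert len(lib) == 48
        unique_pairs = {(c.act_module.key, c.rep_module.key) for c in lib}
        assert len(unique_pairs) == 36
        swapped = [c for c in lib if c.transcription_order == "rep_first"]
        assert len(swapped) == 12
        assert len({c.construct_id for c in lib}) == 48

    def test_capacity_constraint(self):
        for c in default_library():
            assert c.conc_A + c.conc_R == pytest.approx(1.0, abs=1e-12)
            assert c.conc_A > 0 and c.conc_R > 0

    def test_single_pair_no_swaps(self):
        lib = enumerate_library([_module("A")], [_module("R", role="repressor")],
                                n_order_swaps=0)
        assert len(lib) == 1

    def test_deterministic(self):
        ids1 = [c.construct_id for c in default_library()]
        ids2 = [c.construct_id for c in default_library()]
        assert ids1 == ids2

    def test_duplicate_modules_rejected(self):
        a = _module("A")
        with pytest.raises(ConfigurationError):
            enumerate_library([a, a], [_module("R", role="repressor")], 0)


class TestLibraryConfig:
    def test_round_trip_enumerate(self):
        cfg = {
            "promoters": [{"name": "pStr", "strength": 12}, {"name": "pWeak", "strength": 1}],
            "sgrnas": [
                {"name": "A1", "role": "activator", "strand": "coding",
                 "pam_position": 70, "promoter": "pStr"},
                {"name": "R2", "role": "repressor", "strand": "coding",
                 "pam_position": 50, "promoter": "pWeak"},
            ],
            "enumerate": True,
        }
        lib = library_from_config(cfg)
        assert len(lib) == 1
        assert lib[0].conc_A == pytest.approx(12 / 13)

    def test_missing_keys_rejected(self):
        with pytest.raises(ConfigurationError):
            library_from_config({"promoters": []})


def _leaf_summaries():
    """One construct per leaf of the same-mean tree, identical means, in the
    low-expression region."""
    rows = [
        ("opp_eq", "opposite_strand", "equal_conc", 0.5),
        ("opp_ne", "opposite_strand", "unequal_conc", 0.8),
        ("same_eq", "same_strand", "equal_conc", 1.1),
        ("same_ne", "same_strand", "unequal_conc", 1.7),
    ]
    return pd.DataFrame(
        {
            "construct_id": [r[0] for r in rows],
            "mean": 50.0,
            "noise": [r[3] for r in rows],
            "inv_norm_mean": 2.0,
            "rule1": "a_coding",
            "rule2": [r[1] for r in rows],
            "rule3": [r[2] for r in rows],
        }
    )


class TestDecisionTree:
    def test_one_construct_per_leaf_ordered_by_noise(self):
        sel = decision_tree_select(_leaf_summaries(), "same_mean_diff_noise")
        assert list(sel["construct_id"]) == ["opp_eq", "opp_ne", "same_eq", "same_ne"]
        assert sel["noise"].is_monotonic_increasing
        assert list(sel["selection_rank"]) == [1, 2, 3, 4]

    def test_identical_summaries_all_qualify_in_input_order(self):
        df = _leaf_summaries().assign(noise=1.0, rule2="same_strand", rule3="equal_conc")
        sel = decision_tree_select(df, "same_mean_diff_noise")
        assert list(sel["construct_id"]) == list(df["construct_id"])

    def test_high_expression_excluded(self):
        df = _leaf_summaries()
        df.loc[df["construct_id"] == "same_ne", "inv_norm_mean"] = 0.5
        sel = decision_tree_select(df, "same_mean_diff_noise")
        assert "same_ne" not in set(sel["construct_id"])

    def test_empty_selection_is_signal_not_error(self):
        df = _leaf_summaries().assign(inv_norm_mean=0.2)  # all high expression
        sel = decision_tree_select(df, "same_mean_diff_noise")
        assert sel.empty

    def test_mean_tolerance_gates_matching(self):
        df = _leaf_summaries()
        df.loc[df["construct_id"] == "same_ne", "mean"] = 80.0  # 60% away
        sel = decision_tree_select(df, "same_mean_diff_noise", mean_tolerance=0.05)
        assert "same_ne" not in set(sel["construct_id"])
        assert len(sel) == 3

    def test_same_noise_mode_orders_by_mean(self):
        df = pd.DataFrame(
            {
                "construct_id": ["c0", "c1", "c2", "c3", "noisy"],
                "mean": [30.0, 45.0, 60.0, 75.0, 50.0],
                "noise": [0.50, 0.51, 0.52, 0.53, 5.0],
                "inv_norm_mean": 2.0,
                "rule1": ["a_coding", "a_coding", "a_noncoding", "a_noncoding", "a_coding"],
                "rule2": ["opposite_strand", "same_strand", "opposite_strand",
                          "same_strand", "same_strand"],
                "rule3": "equal_conc",
            }
        )
        sel = decision_tree_select(df, "same_noise_diff_mean", noise_tolerance=0.10,
                                   noise_region_quantile=0.8)
        assert list(sel["construct_id"]) == ["c0", "c1", "c2", "c3"]
        assert sel["mean"].is_monotonic_increasing

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            decision_tree_select(_leaf_summaries(), "nope")
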