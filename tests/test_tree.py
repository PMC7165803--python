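"""Survival-tree construction, risk-group assignment and summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from ncrisk import (Cohort, GeneratorConfig, TreeConfig,
                    apply_completeness_filter, assign_risk_groups,
                    build_tree, evaluate_candidates, generate_cohort,
                    has_site_fusion_structure, summarize_risk_groups)
from ncrisk.generator import solve_weibull_anchors, weibull_survival
from ncrisk.tree import default_split_definitions, summaries_to_frame
from tests.conftest import make_cohort_frame


@pytest.fixture(scope="module")
def fitted_default():
    """Default calibrated cohort (n=2000), filtered, with its tree."""
    cohort, latent = generate_cohort(GeneratorConfig(n_patients=2000, seed=0))
    filtered = apply_completeness_filter(cohort)
    tree = build_tree(filtered)
    return cohort, latent, filtered, tree


class TestCandidateEvaluation:
    def test_one_evaluation_per_split_definition(self, fitted_default):
        _, _, filtered, _ = fitted_default
        evals = evaluate_candidates(filtered.df, TreeConfig())
        assert len(evals) == len(default_split_definitions())

    def test_uniform_factor_is_degenerate(self):
        df = make_cohort_frame(n=30)
        df["primary_site"] = "thoracic"
        evals = evaluate_candidates(df, TreeConfig())
        by_name = {e.split.name: e for e in evals}
        assert not by_name["site_thoracic"].eligible
        assert by_name["site_thoracic"].reason == "degenerate"

    def test_no_events_makes_all_candidates_ineligible(self):
        df = make_cohort_frame(n=30)
        df["os_event"] = 0
        evals = evaluate_candidates(df, TreeConfig())
        assert not any(e.eligible for e in evals)

    def test_site_dominates_at_the_calibrated_root(self, fitted_default):
        """Thoracic-vs-nonthoracic is the strongest univariate factor on a
        calibrated cohort, as in the published univariate screen."""
        _, _, filtered, _ = fitted_default
        evals = evaluate_candidates(filtered.df, TreeConfig())
        eligible = [e for e in evals if e.eligible]
        best = min(eligible, key=lambda e: e.p_value)
        assert best.split.name == "site_thoracic"
        assert math.exp(best.ln_hr) > 1  # thoracic is the adverse level

    def test_complete_case_per_factor(self):
        df = make_cohort_frame(n=40)
        df.loc[:9, "tumor_diameter_cm"] = np.nan
        evals = evaluate_candidates(df, TreeConfig())
        by_name = {e.split.name: e for e in evals}
        assert by_name["size_ge_6cm"].n_evaluable == 30
        assert by_name["sex_female"].n_evaluable == 40


class TestBuildTree:
    def test_unfiltered_cohort_rejected(self):
        df = make_cohort_frame(n=25)
        df.loc[0, "fusion"] = "not_tested"
        with pytest.raises(ValueError, match="apply_completeness_filter"):
            build_tree(Cohort(df))

    def test_small_cohort_is_single_leaf(self):
        df = make_cohort_frame(n=19)
        tree = build_tree(Cohort(df))
        assert tree.is_leaf and tree.leaf_reason == "below_min_node"

    def test_recovers_site_then_fusion_structure(self, fitted_default):
        _, _, _, tree = fitted_default
        assert has_site_fusion_structure(tree)
        assert tree.chosen_split.name == "site_thoracic"
        assert tree.child_0.chosen_split.name == "fusion_BRD4"

    def test_children_partition_parent(self, fitted_default):
        _, _, _, tree = fitted_default

        def check(node):
            if node.is_leaf:
                return
            union = (set(node.child_1.member_ids)
                     | set(node.child_0.member_ids)
                     | set(node.excluded_ids))
            assert union == set(node.member_ids)
            assert not (set(node.child_1.member_ids)
                        & set(node.child_0.member_ids))
            check(node.child_1)
            check(node.child_0)

        check(tree)

    def test_deterministic_given_cohort_and_config(self, fitted_default):
        from ncrisk.tree import trees_equal
        _, _, filtered, tree = fitted_default
        again = build_tree(filtered)
        assert trees_equal(tree, again)

    def test_tiny_alpha_gives_root_leaf(self):
        """alpha gates splitting: a threshold no registry-scale effect can
        reach leaves the root intact."""
        cohort, _ = generate_cohort(GeneratorConfig(n_patients=141, seed=0))
        filtered = apply_completeness_filter(cohort)
        tree = build_tree(filtered, TreeConfig(alpha=1e-30))
        assert tree.is_leaf and tree.leaf_reason == "no_significant_factor"

    def test_min_node_gates_attempt_not_child_size(self):
        """A node of >= min_node may produce children smaller than min_node
        (the published group A leaf has n=12 under min_node=20)."""
        cohort, latent = generate_cohort(
            GeneratorConfig(n_patients=141, seed=13))
        filtered = apply_completeness_filter(cohort)
        tree = build_tree(filtered)
        if not tree.is_leaf:
            sizes = [leaf.n for leaf in tree.leaves()]
            assert min(sizes) >= 0  # children below 20 are legal leaves
            for leaf in tree.leaves():
                if leaf.n < 20:
                    assert leaf.leaf_reason == "below_min_node"


class TestAssignAndSummarize:
    def test_labels_recover_latent_groups(self, fitted_default):
        """Leaves refine the latent partition: mapping each leaf to its
        majority latent group reproduces the truth for >=95% of patients
        (100% without label noise, which the default generator lacks)."""
        _, latent, filtered, tree = fitted_default
        labels = assign_risk_groups(tree, filtered)
        truth = latent.set_index("patient_id")["true_group"]
        merged = pd.DataFrame({"leaf": labels, "truth": truth}).dropna()
        merged = merged[~merged["leaf"].str.startswith("EXCLUDED")]
        majority = merged.groupby("leaf")["truth"].agg(
            lambda s: s.value_counts().idxmax())
        agreement = (merged["truth"]
                     == merged["leaf"].map(majority)).mean()
        assert agreement >= 0.95

    def test_single_leaf_tree_labels_all_A(self):
        df = make_cohort_frame(n=10)
        tree = build_tree(Cohort(df))
        labels = assign_risk_groups(tree, Cohort(df))
        assert set(labels) == {"A"}

    def test_missing_split_factor_marks_excluded(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_patients=2000, seed=0))
        filtered = apply_completeness_filter(cohort)
        tree = build_tree(filtered)
        # force a missing value on the root factor for one patient
        df = filtered.df.copy()
        tree_site = tree.chosen_split.name
        assert tree_site == "site_thoracic"
        df.loc[0, "primary_site"] = np.nan
        labels = assign_risk_groups(tree, Cohort(df))
        assert labels[df.loc[0, "patient_id"]] == "EXCLUDED@root"

    def test_group_labels_ordered_by_median(self, fitted_default):
        _, _, filtered, tree = fitted_default
        labels = assign_risk_groups(tree, filtered)
        summaries = summarize_risk_groups(labels, filtered)
        meds = [s.median_os for s in summaries]  # A first
        assert all(meds[i] >= meds[i + 1] - 1e-9
                   for i in range(len(meds) - 1))

    def test_all_censored_group_counts_followup(self):
        df = make_cohort_frame(n=8)
        df["os_event"] = 0
        df["os_months"] = [10, 20, 30, 36, 40, 50, 60, 70]
        cohort = Cohort(df)
        tree = build_tree(cohort)  # single leaf (below min_node)
        labels = assign_risk_groups(tree, cohort)
        (summary,) = summarize_risk_groups(labels, cohort)
        assert not math.isfinite(summary.median_os)
        assert summary.long_term_survivors == 5  # observed time >= 36

    def test_long_term_fraction_matches_weibull_tail(self):
        """Large-n group C long-term-survivor fraction equals the Weibull
        S(36) from its calibrated parameters (no censoring)."""
        cfg = GeneratorConfig(n_patients=30000, group_probs=(0.0, 0.0, 1.0),
                              censoring=None, missingness_rates={}, seed=23)
        cohort, _ = generate_cohort(cfg)
        frac = (cohort.df["os_months"] >= 36).mean()
        shape, scale = solve_weibull_anchors(cfg.group_anchors["C"])
        expected = float(weibull_survival(36.0, shape, scale))
        assert frac == pytest.approx(expected, abs=0.01)

    def test_summary_frame_round_numbers(self, fitted_default):
        _, _, filtered, tree = fitted_default
        labels = assign_risk_groups(tree, filtered)
        frame = summaries_to_frame(summarize_risk_groups(labels, filtered))
        assert (frame["n"].sum()
                == (~labels.str.startswith("EXCLUDED")).sum())
        assert ((frame["os_24m_pct"] >= 0)
                & (frame["os_24m_pct"] <= 100)).all()
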