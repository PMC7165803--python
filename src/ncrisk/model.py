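"""Model/Results interface over the risk-classification pipeline.

`NCRiskModel` holds a cohort and a tree configuration; `fit()` runs the
survival-tree search and returns an `NCRiskResults` carrying the tree, the
per-patient risk-group labels, group outcome summaries and the univariate
screen, with a printable `summary()`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort, apply_completeness_filter, read_cohort
from .multivariable import (AdjustedModelResult, adjusted_models_to_frame,
                            fit_adjusted_models)
from .reporting import make_univariate_table
from .tree import (RiskGroupSummary, TreeConfig, TreeNode,
                   assign_risk_groups, build_tree, summaries_to_frame,
                   summarize_risk_groups)


class NCRiskModel:
    """Survival-tree prognostic risk model for a patient cohort.

    Parameters
    ----------
    cohort : Cohort
        Registry cohort; the completeness filter is applied on fit unless
        the cohort is already analyzable.
    config : TreeConfig, optional
        Split significance level, minimum node size and selection rule.
    """

    def __init__(self, cohort: Cohort, config: TreeConfig | None = None):
        self.cohort = cohort
        self.config = config or TreeConfig()

    @classmethod
    def from_csv(cls, path, config: TreeConfig | None = None) -> "NCRiskModel":
        return cls(read_cohort(path), config=config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: TreeConfig | None = None) -> "NCRiskModel":
        return cls(Cohort(df.copy()), config=config)

    def fit(self) -> "NCRiskResults":
        filtered = apply_completeness_filter(self.cohort)
        tree = build_tree(filtered, self.config)
        labels = assign_risk_groups(tree, filtered)
        summaries = summarize_risk_groups(labels, filtered)
        models = fit_adjusted_models(filtered)
        return NCRiskResults(model=self, cohort=filtered, tree=tree,
                             labels=labels, group_summaries=summaries,
                             adjusted_models=models)


def _fmt_t(x: float) -> str:
    return "NR" if not math.isfinite(x) else f"{x:.1f}"


@dataclass
class NCRiskResults:
    """Fitted risk classification: tree, labels, summaries, adjusted models."""

    model: NCRiskModel
    cohort: Cohort
    tree: TreeNode
    labels: pd.Series
    group_summaries: list[RiskGroupSummary]
    adjusted_models: list[AdjustedModelResult]
    _univariate: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def univariate_table(self) -> pd.DataFrame:
        if self._univariate is None:
            self._univariate = make_univariate_table(self.cohort)
        return self._univariate

    def predict(self, df: pd.DataFrame) -> pd.Series:
        """Risk-group labels for new patients (walk the fitted tree)."""
        fitted_labels = {}  # leaf node_id -> group label
        for pid, lab in self.labels.items():
            if not lab.startswith("EXCLUDED"):
                fitted_labels.setdefault(self._leaf_id_of(pid), lab)
        out = []
        for _, row in df.iterrows():
            node = self.tree
            while not node.is_leaf:
                z = node.chosen_split.evaluate(df.loc[[row.name]])[0]
                if math.isnan(z):
                    out.append(f"EXCLUDED@{node.node_id}")
                    break
                node = node.child_1 if z == 1.0 else node.child_0
            else:
                out.append(fitted_labels.get(node.node_id, node.node_id))
        return pd.Series(out, index=df.index, name="risk_group")

    def _leaf_id_of(self, pid: str) -> str:
        node = self.tree
        df = self.cohort.df.set_index("patient_id", drop=False)
        while not node.is_leaf:
            z = node.chosen_split.evaluate(df.loc[[pid]])[0]
            node = node.child_1 if z == 1.0 else node.child_0
        return node.node_id

    def summary(self) -> str:
        """Plain-text summary: tree structure and group outcome table."""
        lines = ["Survival-tree risk classification",
                 "=" * 48,
                 f"analyzable patients: {self.cohort.n}",
                 "", "Tree:"]

        def render(node: TreeNode, indent: int, tag: str) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}{tag} leaf n={node.n} "
                             f"({node.leaf_reason})")
            else:
                s = node.chosen_split
                lines.append(f"{pad}{tag} split on {s.name} "
                             f"[{s.level_1} vs {s.level_0}] n={node.n}")
                render(node.child_1, indent + 1, f"({s.level_1})")
                render(node.child_0, indent + 1, f"({s.level_0})")

        render(self.tree, 1, "root:")
        lines += ["", "Risk groups (A = best prognosis):",
                  f"{'group':>6} {'n':>5} {'median OS':>10} "
                  f"{'95% CI':>14} {'2-y OS %':>9} {'>=3-y n':>8}"]
        for s in self.group_summaries:
            ci = f"({_fmt_t(s.median_ci_low)}-{_fmt_t(s.median_ci_high)})"
            lines.append(
                f"{s.label:>6} {s.n:>5} {_fmt_t(s.median_os):>10} "
                f"{ci:>14} {100 * s.surv_24:>9.1f} "
                f"{s.long_term_survivors:>8}")
        lines += ["", "Adjusted Cox models:"]
        frame = adjusted_models_to_frame(self.adjusted_models)
        lines.append(frame.to_string(index=False,
                                     float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def group_table(self) -> pd.DataFrame:
        return summaries_to_frame(self.group_summaries)
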