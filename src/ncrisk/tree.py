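"""Survival-tree risk classification by recursive univariate Cox splits.

At each node every candidate prognostic factor is dichotomized and tested
with a univariate Cox proportional-hazards model on the node's members
(complete cases per factor). The node is split on the factor with the
lowest statistically significant Wald p-value (or, alternatively, the
strongest significant effect size |ln HR|), and the procedure recurses into
both children until no significant factor remains or a subgroup has fewer
than ``min_node`` patients. Leaves are the risk groups, labelled A, B, C,
... in decreasing order of Kaplan-Meier median overall survival.

No pruning, surrogate splits or multiplicity correction are applied: the
procedure tests every factor at the nominal two-sided level at every node.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import Cohort, MODEL_FUSIONS
from .survival import (CoxModelFit, KaplanMeierEstimate, NOT_REACHED,
                       cox_fit, km_fit)


# ---------------------------------------------------------------------------
# Split definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitDefinition:
    """A named dichotomization of patient records.

    ``rule`` maps a cohort DataFrame to a float array: 1.0 for the risk
    level, 0.0 for the reference level, NaN for not-evaluable (missing).
    """

    name: str
    level_1: str
    level_0: str
    rule: Callable[[pd.DataFrame], np.ndarray]

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.rule(df), dtype=float)


def _indicator(series: pd.Series, one_levels: set, zero_levels: set
               ) -> np.ndarray:
    out = np.full(len(series), np.nan)
    vals = series.to_numpy(dtype=object)
    for i, v in enumerate(vals):
        if isinstance(v, str):
            if v in one_levels:
                out[i] = 1.0
            elif v in zero_levels:
                out[i] = 0.0
    return out


def default_split_definitions() -> list[SplitDefinition]:
    """The eight candidate factors of the risk model, as printed dichotomies:

    age >=18 vs <18; female vs male; thoracic vs nonthoracic site;
    tumor >=6 cm vs <6 cm; non-squamous/other vs squamous histology;
    BRD4 vs BRD3/NSD3 fusion; baseline metastasis yes vs no;
    bone/soft-tissue primary yes vs no.
    """
    return [
        SplitDefinition(
            "age_ge_18", ">=18 y", "<18 y",
            lambda df: np.where(df["age_years"].isna(), np.nan,
                                (df["age_years"] >= 18).astype(float))),
        SplitDefinition(
            "sex_female", "female", "male",
            lambda df: _indicator(df["sex"], {"female"}, {"male"})),
        SplitDefinition(
            "site_thoracic", "thoracic", "nonthoracic",
            lambda df: _indicator(df["primary_site"], {"thoracic"},
                                  {"head_neck", "bone_soft_tissue",
                                   "other"})),
        SplitDefinition(
            "size_ge_6cm", ">=6 cm", "<6 cm",
            lambda df: np.where(df["tumor_diameter_cm"].isna(), np.nan,
                                (df["tumor_diameter_cm"] >= 6).astype(float))),
        SplitDefinition(
            "histology_nonsquamous", "non-squamous or other", "squamous",
            lambda df: _indicator(df["histology"],
                                  {"non_squamous", "other"}, {"squamous"})),
        SplitDefinition(
            "fusion_BRD4", "BRD4", "BRD3 or NSD3",
            lambda df: _indicator(df["fusion"], {"BRD4"},
                                  {"BRD3", "NSD3"})),
        SplitDefinition(
            "metastasis", "metastasis", "no metastasis",
            lambda df: _indicator(df["metastasis_baseline"], {"yes"},
                                  {"no"})),
        SplitDefinition(
            "bone_soft_tissue_primary", "bone/soft tissue", "other site",
            lambda df: _indicator(df["primary_site"], {"bone_soft_tissue"},
                                  {"thoracic", "head_neck", "other"})),
    ]


def treatment_split_definitions() -> list[SplitDefinition]:
    """Descriptive treatment-exposure dichotomies (reporting only; the tree
    never uses them)."""
    return [
        SplitDefinition(
            "ever_surgery", "surgery", "no surgery",
            lambda df: _indicator(df["ever_surgery"], {"yes"}, {"no"})),
        SplitDefinition(
            "ever_radiation", "radiation", "no radiation",
            lambda df: _indicator(df["ever_radiation"], {"yes"}, {"no"})),
        SplitDefinition(
            "ever_chemo", "chemotherapy", "no chemotherapy",
            lambda df: _indicator(df["ever_chemo"], {"yes"}, {"no"})),
    ]


# ---------------------------------------------------------------------------
# Tree configuration and node structure
# ---------------------------------------------------------------------------

@dataclass
class TreeConfig:
    """Stopping and selection rules of the recursive partition.

    ``alpha`` is the two-sided significance threshold for a split;
    ``min_node`` gates *attempting* a split (children may end up smaller);
    ``selection_criterion`` picks among significant candidates by lowest
    Wald p ("lowest_p") or largest |ln HR| ("strongest_hr").
    """

    alpha: float = 0.05
    min_node: int = 20
    selection_criterion: str = "lowest_p"
    split_definitions: list[SplitDefinition] = field(
        default_factory=default_split_definitions)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")
        if self.selection_criterion not in ("lowest_p", "strongest_hr"):
            raise ValueError("selection_criterion must be "
                             "'lowest_p' or 'strongest_hr'")


@dataclass
class CandidateEvaluation:
    """One candidate factor's univariate Cox evaluation at a node."""

    split: SplitDefinition
    n_evaluable: int
    n_events: int
    cox: CoxModelFit | None
    eligible: bool
    reason: str = ""  # ineligibility reason when not eligible

    @property
    def p_value(self) -> float:
        return float(self.cox.wald_p[0]) if self.cox is not None else math.nan

    @property
    def ln_hr(self) -> float:
        return float(self.cox.ln_hr[0]) if self.cox is not None else math.nan


@dataclass
class TreeNode:
    """One node of the risk-classification tree."""

    node_id: str
    member_ids: list[str]
    candidates: list[CandidateEvaluation] = field(default_factory=list)
    chosen_split: SplitDefinition | None = None
    leaf_reason: str | None = None
    excluded_ids: list[str] = field(default_factory=list)
    child_1: "TreeNode | None" = None  # risk level of the chosen split
    child_0: "TreeNode | None" = None  # reference level

    @property
    def is_leaf(self) -> bool:
        return self.chosen_split is None

    @property
    def n(self) -> int:
        return len(self.member_ids)

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.child_1.leaves() + self.child_0.leaves()

    def to_dict(self) -> dict:
        d: dict = {"node_id": self.node_id, "n": self.n,
                   "member_ids": list(self.member_ids)}
        d["candidates"] = [
            {"factor": c.split.name, "n_evaluable": c.n_evaluable,
             "n_events": c.n_events, "eligible": c.eligible,
             "reason": c.reason,
             "hr": (float(np.exp(c.ln_hr)) if c.cox is not None else None),
             "p": (c.p_value if c.cox is not None else None)}
            for c in self.candidates]
        if self.is_leaf:
            d["leaf_reason"] = self.leaf_reason
        else:
            d["split"] = {"factor": self.chosen_split.name,
                          "level_1": self.chosen_split.level_1,
                          "level_0": self.chosen_split.level_0}
            d["excluded_ids"] = list(self.excluded_ids)
            d["child_1"] = self.child_1.to_dict()
            d["child_0"] = self.child_0.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

def evaluate_candidates(df: pd.DataFrame, config: TreeConfig
                        ) -> list[CandidateEvaluation]:
    """Univariate Cox evaluation of every split definition on a node.

    Complete-case per factor: rows not evaluable on a factor are dropped for
    that factor only. Degenerate (one-sided), event-free or non-converged
    candidates are marked ineligible, never fatal.
    """
    if len(df) == 0:
        raise ValueError("empty node")
    out = []
    times = df["os_months"].to_numpy(dtype=float)
    events = df["os_event"].to_numpy(dtype=float)
    for split in config.split_definitions:
        z = split.evaluate(df)
        mask = ~np.isnan(z)
        n_eval = int(mask.sum())
        n_ev = int(events[mask].sum())
        zc, tc, ec = z[mask], times[mask], events[mask]
        if n_eval == 0 or len(np.unique(zc)) < 2:
            out.append(CandidateEvaluation(split, n_eval, n_ev, None,
                                           False, "degenerate"))
            continue
        if n_ev == 0:
            out.append(CandidateEvaluation(split, n_eval, n_ev, None,
                                           False, "too_few_events"))
            continue
        try:
            fit = cox_fit(zc, tc, ec, names=[split.name])
        except ValueError as err:
            out.append(CandidateEvaluation(split, n_eval, n_ev, None,
                                           False, str(err)))
            continue
        if not fit.converged:
            out.append(CandidateEvaluation(split, n_eval, n_ev, fit,
                                           False, "non_converged"))
            continue
        out.append(CandidateEvaluation(split, n_eval, n_ev, fit, True))
    return out


def _select_winner(evals: list[CandidateEvaluation], config: TreeConfig
                   ) -> CandidateEvaluation | None:
    sig = [c for c in evals if c.eligible and c.p_value <= config.alpha]
    if not sig:
        return None
    if config.selection_criterion == "lowest_p":
        # ties on p broken by larger |ln HR|, then declaration order
        key = lambda i: (sig[i].p_value, -abs(sig[i].ln_hr), i)
    else:  # strongest_hr
        key = lambda i: (-abs(sig[i].ln_hr), sig[i].p_value, i)
    return sig[min(range(len(sig)), key=key)]


def build_tree(cohort: Cohort, config: TreeConfig | None = None) -> TreeNode:
    """Build the risk-classification tree on a completeness-filtered cohort.

    Raises ``ValueError`` if the cohort still contains patients with an
    unknown primary site or a fusion outside {BRD4, BRD3, NSD3} — run
    ``apply_completeness_filter`` first.
    """
    config = config or TreeConfig()
    df = cohort.df
    if df["primary_site"].isna().any() or \
            (~df["fusion"].isin(list(MODEL_FUSIONS))).any():
        raise ValueError(
            "cohort contains unknown sites or non-model fusions; apply "
            "apply_completeness_filter before building the tree")
    df = df.set_index("patient_id", drop=False)

    def build(ids: list[str], node_id: str) -> TreeNode:
        node = TreeNode(node_id=node_id, member_ids=list(ids))
        sub = df.loc[ids]
        if len(ids) < config.min_node:
            node.leaf_reason = "below_min_node"
            return node
        node.candidates = evaluate_candidates(sub, config)
        if not any(c.eligible for c in node.candidates):
            node.leaf_reason = "no_evaluable_candidate"
            return node
        winner = _select_winner(node.candidates, config)
        if winner is None:
            node.leaf_reason = "no_significant_factor"
            return node
        z = winner.split.evaluate(sub)
        ids_arr = sub["patient_id"].to_numpy(dtype=object)
        node.chosen_split = winner.split
        node.excluded_ids = list(ids_arr[np.isnan(z)])
        node.child_1 = build(list(ids_arr[z == 1.0]), node_id + ".1")
        node.child_0 = build(list(ids_arr[z == 0.0]), node_id + ".0")
        return node

    return build(list(df["patient_id"]), "root")


# ---------------------------------------------------------------------------
# Risk-group assignment and summaries
# ---------------------------------------------------------------------------

def assign_risk_groups(tree: TreeNode, cohort: Cohort) -> pd.Series:
    """Map every patient to a leaf label (A = best median OS, then B, ...).

    Patients not evaluable on a chosen split factor along their path are
    labelled ``EXCLUDED@<node_id>``. Leaves are ordered by decreasing
    Kaplan-Meier median OS of their members (unreached medians first),
    ties broken by survival at the 24-month horizon.
    """
    df = cohort.df.set_index("patient_id", drop=False)
    leaf_of: dict[str, TreeNode] = {}
    excluded: dict[str, str] = {}

    def walk(node: TreeNode, ids: list[str]) -> None:
        if node.is_leaf:
            for pid in ids:
                leaf_of[pid] = node
            return
        sub = df.loc[ids]
        z = node.chosen_split.evaluate(sub)
        arr = sub["patient_id"].to_numpy(dtype=object)
        for pid in arr[np.isnan(z)]:
            excluded[pid] = node.node_id
        walk(node.child_1, list(arr[z == 1.0]))
        walk(node.child_0, list(arr[z == 0.0]))

    walk(tree, list(df["patient_id"]))

    # order leaves by prognosis (best first)
    def leaf_key(leaf: TreeNode):
        ids = [p for p in leaf.member_ids if p in leaf_of]
        sub = df.loc[ids]
        km = km_fit(sub["os_months"], sub["os_event"])
        med = km.median if math.isfinite(km.median) else 1e12
        return (-med, -km.survival_at(24.0), leaf.node_id)

    leaves = sorted(tree.leaves(), key=leaf_key)
    labels = {leaf.node_id: chr(ord("A") + i) for i, leaf in enumerate(leaves)}

    out = {}
    for pid in df["patient_id"]:
        if pid in excluded:
            out[pid] = f"EXCLUDED@{excluded[pid]}"
        else:
            out[pid] = labels[leaf_of[pid].node_id]
    return pd.Series(out, name="risk_group")


@dataclass
class RiskGroupSummary:
    """Per-group outcome summary: KM median, horizon survival, long-term
    survivors (observed time >= 36 months)."""

    label: str
    n: int
    median_os: float
    median_ci_low: float
    median_ci_high: float
    surv_24: float
    surv_24_ci_low: float
    surv_24_ci_high: float
    long_term_survivors: int
    km: KaplanMeierEstimate


def summarize_risk_groups(labels: pd.Series, cohort: Cohort
                          ) -> list[RiskGroupSummary]:
    """Table-style summaries of assigned risk groups (EXCLUDED labels are
    skipped)."""
    df = cohort.df.set_index("patient_id", drop=False)
    out = []
    groups = sorted(l for l in labels.unique() if not l.startswith("EXCLUDED"))
    for lab in groups:
        ids = labels.index[labels == lab]
        sub = df.loc[ids]
        if len(sub) == 0:
            continue
        km = km_fit(sub["os_months"], sub["os_event"])
        s, lo, hi = km.survival_ci_at(24.0)
        out.append(RiskGroupSummary(
            label=lab, n=len(sub),
            median_os=km.median, median_ci_low=km.median_ci_low,
            median_ci_high=km.median_ci_high,
            surv_24=s, surv_24_ci_low=lo, surv_24_ci_high=hi,
            long_term_survivors=int((sub["os_months"] >= 36.0).sum()),
            km=km))
    return out


def summaries_to_frame(summaries: list[RiskGroupSummary]) -> pd.DataFrame:
    def fmt(x):
        return math.nan if not math.isfinite(x) else x
    return pd.DataFrame([{
        "group": s.label, "n": s.n,
        "median_os_months": fmt(s.median_os),
        "median_ci_low": fmt(s.median_ci_low),
        "median_ci_high": fmt(s.median_ci_high),
        "os_24m_pct": 100 * s.surv_24,
        "os_24m_ci_low_pct": 100 * s.surv_24_ci_low,
        "os_24m_ci_high_pct": 100 * s.surv_24_ci_high,
        "long_term_survivors": s.long_term_survivors,
    } for s in summaries])


# ---------------------------------------------------------------------------
# Structure helpers
# ---------------------------------------------------------------------------

def has_site_fusion_structure(tree: TreeNode) -> bool:
    """True when the tree's top structure matches the published model:
    root splits thoracic vs nonthoracic, and the nonthoracic child splits
    BRD4 vs BRD3/NSD3."""
    if tree.is_leaf or tree.chosen_split.name != "site_thoracic":
        return False
    nonthor = tree.child_0
    return (not nonthor.is_leaf
            and nonthor.chosen_split.name == "fusion_BRD4")


def is_exact_three_leaf_structure(tree: TreeNode) -> bool:
    """Strict variant: site split, fusion split below it, and no further
    splits anywhere (exactly the published three-leaf tree)."""
    return (has_site_fusion_structure(tree)
            and tree.child_1.is_leaf
            and tree.child_0.child_1.is_leaf
            and tree.child_0.child_0.is_leaf)


def trees_equal(a: TreeNode, b: TreeNode) -> bool:
    """Structural equality: same splits and same member partition."""
    if a.is_leaf != b.is_leaf or set(a.member_ids) != set(b.member_ids):
        return False
    if a.is_leaf:
        return True
    if a.chosen_split.name != b.chosen_split.name:
        return False
    return (trees_equal(a.child_1, b.child_1)
            and trees_equal(a.child_0, b.child_0))
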