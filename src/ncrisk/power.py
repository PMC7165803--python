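"""Monte-Carlo power of a prospective validation cohort.

A future registry cohort "validates" the risk classification when the three
predefined risk groups separate statistically. Two validation predicates
are offered:

* ``pairwise_separation`` (default): all three pairwise log-rank tests are
  significant at two-sided ``alpha`` AND the observed Kaplan-Meier group
  medians are strictly ordered A > B > C (an unreached median counts as
  infinite);
* ``tree_recovery`` (stricter): re-running the survival-tree search on the
  simulated cohort reproduces the site-then-fusion split structure.

Validation cohorts are drawn with the published group proportions and the
calibrated per-group Weibull survival, complete data on site / fusion / OS
(no missingness), and independent administrative censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, apply_completeness_filter
from .generator import GeneratorConfig, generate_cohort
from .survival import km_fit, logrank_test
from .tree import TreeConfig, build_tree, has_site_fusion_structure

NOT_FOUND = None


@dataclass(frozen=True)
class ValidationCriterion:
    """Predicate applied to one simulated validation cohort."""

    kind: str = "pairwise_separation"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("pairwise_separation", "tree_recovery"):
            raise ValueError("kind must be 'pairwise_separation' or "
                             "'tree_recovery'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def classify_predefined_groups(df: pd.DataFrame) -> pd.Series:
    """Apply the published classification rule to observed covariates:
    A = nonthoracic & BRD3/NSD3, B = nonthoracic & BRD4, C = thoracic."""
    site = df["primary_site"]
    fusion = df["fusion"]
    lab = pd.Series(index=df.index, dtype=object)
    lab[site == "thoracic"] = "C"
    nonthor = site.notna() & (site != "thoracic")
    lab[nonthor & fusion.isin(["BRD3", "NSD3"])] = "A"
    lab[nonthor & (fusion == "BRD4")] = "B"
    return lab


def _validation_config(n: int, config: GeneratorConfig, seed: int
                       ) -> GeneratorConfig:
    # complete data on fusion, site and OS: a validation cohort is accrued
    # prospectively with these fields required
    return replace(config, n_patients=n, missingness_rates={}, seed=int(seed))


def simulate_validation(n: int, config: GeneratorConfig,
                        criterion: ValidationCriterion, seed: int) -> bool:
    """Simulate one validation cohort of size n and apply the criterion."""
    if n < 3:
        raise ValueError("validation cohort must have n >= 3")
    cohort, _ = generate_cohort(_validation_config(n, config, seed))
    df = cohort.df
    if criterion.kind == "tree_recovery":
        try:
            filtered = apply_completeness_filter(cohort)
            tree = build_tree(filtered, TreeConfig(alpha=criterion.alpha))
        except ValueError:
            return False
        return has_site_fusion_structure(tree)

    labels = classify_predefined_groups(df)
    known = labels.notna()
    df, labels = df[known], labels[known]
    medians = {}
    for g in ("A", "B", "C"):
        sub = df[labels == g]
        if len(sub) == 0:
            return False  # an empty risk group cannot validate the model
        medians[g] = km_fit(sub["os_months"], sub["os_event"]).median
    if not (medians["A"] > medians["B"] > medians["C"]):
        return False
    t = df["os_months"].to_numpy(dtype=float)
    e = df["os_event"].to_numpy(dtype=float)
    g = labels.to_numpy(dtype=object)
    for pair in (("A", "B"), ("A", "C"), ("B", "C")):
        m = np.isin(g, pair)
        if len(np.unique(g[m])) < 2:
            return False
        if logrank_test(t[m], e[m], g[m]).p_value >= criterion.alpha:
            return False
    return True


@dataclass
class PowerEstimate:
    """Monte-Carlo power at one cohort size."""

    n: int
    reps: int
    successes: int
    criterion: ValidationCriterion
    seed: int

    @property
    def power(self) -> float:
        return self.successes / self.reps

    @property
    def se(self) -> float:
        p = self.power
        return math.sqrt(p * (1 - p) / self.reps)


def estimate_power(n: int, config: GeneratorConfig,
                   criterion: ValidationCriterion | None = None,
                   reps: int = 1000, seed: int = 0) -> PowerEstimate:
    """Fraction of simulated validation cohorts satisfying the criterion."""
    if reps < 100:
        raise ValueError("reps must be >= 100 for a usable estimate")
    criterion = criterion or ValidationCriterion()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=reps)
    successes = sum(
        simulate_validation(n, config, criterion, int(s)) for s in sub_seeds)
    return PowerEstimate(n=n, reps=reps, successes=int(successes),
                         criterion=criterion, seed=seed)


@dataclass
class PowerSimResult:
    """Power curve over a cohort-size grid plus the minimal adequate n."""

    entries: list[PowerEstimate]
    target_power: float
    minimal_n: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n": e.n, "reps": e.reps, "power": e.power, "se": e.se,
            "criterion": e.criterion.kind} for e in self.entries])


def minimal_validation_n(target_power: float, n_grid, config: GeneratorConfig,
                         criterion: ValidationCriterion | None = None,
                         reps: int = 1000, seed: int = 0) -> PowerSimResult:
    """Smallest grid n whose estimated power reaches the target.

    ``minimal_n`` is None (NOT_FOUND) when no grid point reaches it.
    """
    grid = list(n_grid)
    if not grid:
        raise ValueError("empty n grid")
    if sorted(grid) != grid:
        raise ValueError("n_grid must be ascending")
    criterion = criterion or ValidationCriterion()
    entries = []
    minimal = NOT_FOUND
    for i, n in enumerate(grid):
        est = estimate_power(n, config, criterion, reps=reps,
                             seed=seed + 1000 * i)
        entries.append(est)
        if minimal is NOT_FOUND and est.power >= target_power:
            minimal = n
    return PowerSimResult(entries=entries, target_power=target_power,
                          minimal_n=minimal)
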