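"""Post hoc multivariable Cox models for confounding among site, fusion
and metastasis.

Three fixed main-effects specifications probe whether the tree's selected
factors are independent predictors:

* model 1: site + metastasis,
* model 2: site + fusion,
* model 3: site + fusion + metastasis.

Each model is fitted on its own complete cases (n varies across models).
Collinear or within-sample-constant indicators make a model ineligible; it
is skipped with a recorded reason rather than silently refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .survival import CoxModelFit, cox_fit
from .tree import SplitDefinition, default_split_definitions


def _factor_registry() -> dict[str, SplitDefinition]:
    return {s.name: s for s in default_split_definitions()}


@dataclass(frozen=True)
class AdjustedModelSpec:
    """One multivariable specification: a model id and its factor names."""

    model_id: int
    factors: tuple[str, ...]


def default_model_specs() -> list[AdjustedModelSpec]:
    return [
        AdjustedModelSpec(1, ("site_thoracic", "metastasis")),
        AdjustedModelSpec(2, ("site_thoracic", "fusion_BRD4")),
        AdjustedModelSpec(3, ("site_thoracic", "fusion_BRD4", "metastasis")),
    ]


@dataclass
class AdjustedModelResult:
    spec: AdjustedModelSpec
    fit: CoxModelFit | None
    skipped_reason: str = ""


def fit_adjusted_models(cohort: Cohort,
                        specs: list[AdjustedModelSpec] | None = None,
                        ties_method: str = "efron"
                        ) -> list[AdjustedModelResult]:
    """Fit the multivariable Cox models on their per-model complete cases."""
    specs = specs if specs is not None else default_model_specs()
    registry = _factor_registry()
    df = cohort.df
    times = df["os_months"].to_numpy(dtype=float)
    events = df["os_event"].to_numpy(dtype=float)
    out = []
    for spec in specs:
        if len(set(spec.factors)) != len(spec.factors):
            out.append(AdjustedModelResult(
                spec, None, "duplicate covariate in specification"))
            continue
        cols = []
        for name in spec.factors:
            if name not in registry:
                raise KeyError(f"unknown factor {name!r}")
            cols.append(registry[name].evaluate(df))
        X = np.column_stack(cols)
        complete = ~np.isnan(X).any(axis=1)
        Xc, tc, ec = X[complete], times[complete], events[complete]
        if Xc.shape[0] == 0:
            out.append(AdjustedModelResult(spec, None, "no complete cases"))
            continue
        centered = Xc - Xc.mean(axis=0)
        if (centered.std(axis=0) == 0).any() or \
                np.linalg.matrix_rank(centered) < Xc.shape[1]:
            out.append(AdjustedModelResult(
                spec, None, "collinear or constant covariates within "
                "complete cases"))
            continue
        try:
            fit = cox_fit(Xc, tc, ec, ties_method=ties_method,
                          names=list(spec.factors))
        except ValueError as err:
            out.append(AdjustedModelResult(spec, None, str(err)))
            continue
        out.append(AdjustedModelResult(spec, fit))
    return out


def adjusted_models_to_frame(results: list[AdjustedModelResult]
                             ) -> pd.DataFrame:
    """Flat per-(model, covariate) table of HRs, CIs and Wald p-values."""
    rows = []
    for res in results:
        if res.fit is None:
            rows.append({"model": res.spec.model_id, "factor": None,
                         "n": None, "hr": None, "ci_low": None,
                         "ci_high": None, "p": None,
                         "note": res.skipped_reason})
            continue
        f = res.fit
        for j, name in enumerate(f.names):
            rows.append({"model": res.spec.model_id, "factor": name,
                         "n": f.n_used, "hr": float(f.hr[j]),
                         "ci_low": float(f.ci_low[j]),
                         "ci_high": float(f.ci_high[j]),
                         "p": float(f.wald_p[j]), "note": ""})
    return pd.DataFrame(rows)
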