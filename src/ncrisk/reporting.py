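"""Registry-style tables and the end-to-end pipeline.

``make_baseline_table`` reproduces the descriptive-table convention of
clinical registry reports: counts over the *known* denominator ("99 of 127
(78)") with unknowns listed separately, and median (range) rows for
continuous characteristics. ``make_univariate_table`` is the univariate Cox
screen of every candidate factor against both endpoints (OS and EFS),
complete-case per row. ``run_pipeline`` chains generation, filtering,
tables, tree, multivariable models and the power grid into one reproducible
run keyed by (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, apply_completeness_filter, write_cohort
from .generator import GeneratorConfig, generate_cohort
from .multivariable import adjusted_models_to_frame, fit_adjusted_models
from .survival import cox_fit
from .tree import (TreeConfig, assign_risk_groups, build_tree,
                   default_split_definitions, summaries_to_frame,
                   summarize_risk_groups, treatment_split_definitions)
from .power import ValidationCriterion, estimate_power

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Table 1-style baseline table
# ---------------------------------------------------------------------------

def _cat_rows(series: pd.Series, characteristic: str,
              levels: list[str]) -> list[dict]:
    known = series.isin(levels)
    denom = int(known.sum())
    unknown = int(len(series) - denom)
    rows = []
    for lev in levels:
        cnt = int((series == lev).sum())
        rows.append({"characteristic": characteristic, "level": lev,
                     "count": cnt, "denominator": denom,
                     "percent": (round(100 * cnt / denom) if denom else None),
                     "unknown": unknown})
    return rows


def _cont_row(series: pd.Series, characteristic: str) -> dict:
    vals = pd.to_numeric(series, errors="coerce").dropna()
    return {"characteristic": characteristic, "level": "median (range)",
            "count": None, "denominator": int(vals.size),
            "percent": None, "unknown": int(series.isna().sum()),
            "median": (float(vals.median()) if vals.size else None),
            "min": (float(vals.min()) if vals.size else None),
            "max": (float(vals.max()) if vals.size else None)}


def make_baseline_table(cohort: Cohort) -> pd.DataFrame:
    """Descriptive baseline table with known-case denominators."""
    df = cohort.df
    rows: list[dict] = []
    rows.append(_cont_row(df["age_years"], "age_years"))
    age_band = pd.Series(
        np.where(df["age_years"].isna(), None,
                 np.where(df["age_years"] >= 18, ">=18", "<18")),
        index=df.index, dtype=object)
    rows += _cat_rows(age_band, "age_band", ["<18", ">=18"])
    rows += _cat_rows(df["sex"], "sex", ["male", "female"])
    rows += _cat_rows(df["primary_site"], "primary_site",
                      ["thoracic", "head_neck", "bone_soft_tissue", "other"])
    # identified fusions form the denominator; unknown_tested / not_tested
    # count as unknown, mirroring the registry convention
    fusion = df["fusion"].where(
        ~df["fusion"].isin(["unknown_tested", "not_tested"]), np.nan)
    rows += _cat_rows(fusion, "fusion",
                      ["BRD4", "BRD3", "NSD3", "ZNF532", "ZNF592"])
    rows += _cat_rows(df["histology"], "histology",
                      ["squamous", "non_squamous", "other"])
    rows.append(_cont_row(df["tumor_diameter_cm"], "tumor_diameter_cm"))
    size_band = pd.Series(
        np.where(df["tumor_diameter_cm"].isna(), None,
                 np.where(df["tumor_diameter_cm"] >= 6, ">=6 cm", "<6 cm")),
        index=df.index, dtype=object)
    rows += _cat_rows(size_band, "tumor_size_band", ["<6 cm", ">=6 cm"])
    rows += _cat_rows(df["metastasis_baseline"], "metastasis_baseline",
                      ["yes", "no"])
    for col in ("ever_surgery", "ever_radiation", "ever_chemo"):
        rows += _cat_rows(df[col], col, ["yes", "no"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table 2-style univariate Cox table
# ---------------------------------------------------------------------------

def make_univariate_table(cohort: Cohort, split_definitions=None,
                          endpoints: tuple[str, ...] = ("OS", "EFS")
                          ) -> pd.DataFrame:
    """Univariate Cox screen: one row per (factor, endpoint), complete-case
    per row. Degenerate factors produce a row with a note instead of a fit."""
    if split_definitions is None:
        split_definitions = (default_split_definitions()
                             + treatment_split_definitions())
    df = cohort.df
    rows = []
    for endpoint in endpoints:
        if endpoint == "OS":
            t_all = df["os_months"].to_numpy(dtype=float)
            e_all = df["os_event"].to_numpy(dtype=float)
        elif endpoint == "EFS":
            t_all = df["efs_months"].to_numpy(dtype=float)
            e_all = df["efs_event"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        for split in split_definitions:
            z = split.evaluate(df)
            mask = ~(np.isnan(z) | np.isnan(t_all) | np.isnan(e_all))
            row = {"endpoint": endpoint, "factor": split.name,
                   "level": split.level_1, "reference": split.level_0,
                   "n": int(mask.sum())}
            try:
                fit = cox_fit(z[mask], t_all[mask], e_all[mask],
                              names=[split.name])
                row.update(hr=float(fit.hr[0]),
                           ci_low=float(fit.ci_low[0]),
                           ci_high=float(fit.ci_high[0]),
                           p=float(fit.wald_p[0]),
                           note="" if fit.converged else fit.diagnostics)
            except ValueError as err:
                row.update(hr=None, ci_low=None, ci_high=None, p=None,
                           note=str(err))
            rows.append(row)
    return pd.DataFrame(rows)


def format_display(table: pd.DataFrame) -> pd.DataFrame:
    """Round a univariate table for display: HR/CI to 1 decimal, p to two
    significant figures (registry-report convention)."""
    out = table.copy()
    for col in ("hr", "ci_low", "ci_high"):
        if col in out:
            out[col] = out[col].map(
                lambda v: None if v is None or pd.isna(v) else round(v, 1))
    if "p" in out:
        out["p"] = out["p"].map(
            lambda v: None if v is None or pd.isna(v)
            else float(f"{v:.2g}"))
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULT_PIPELINE_CONFIG = {
    "generator": {},          # overrides of GeneratorConfig fields
    "tree": {},               # overrides of TreeConfig fields
    "power": {"grid": [100, 198, 300], "reps": 200,
              "criterion": "pairwise_separation", "target_power": 0.8},
    "seed": 0,
}


def run_pipeline(config_path: str | Path | None, output_dir: str | Path,
                 seed: int | None = None) -> int:
    """Run generate -> filter -> tables -> tree -> models -> power.

    Returns 0 on success, 1 on failure (partial outputs preserved; the run
    log records the failing stage). The pipeline is a pure function of
    (config, seed): identical inputs give byte-identical CSV outputs.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        logger.info(msg)

    cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    if config_path is not None:
        with open(config_path) as fh:
            user = json.load(fh)
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)

    stage = "configure"
    try:
        from . import __version__
        gen_cfg = GeneratorConfig.from_dict(
            {**cfg["generator"], "seed": cfg["seed"]})
        tree_cfg = TreeConfig(**cfg["tree"])
        log(f"ncrisk {__version__}; seed={cfg['seed']}")
        with open(outdir / "config.json", "w") as fh:
            json.dump({**cfg, "generator": gen_cfg.to_dict()}, fh, indent=1)

        stage = "generate"
        t0 = time.perf_counter()
        cohort, latent = generate_cohort(gen_cfg)
        write_cohort(cohort, outdir / "cohort.csv")
        latent.to_csv(outdir / "latent_truth.csv", index=False)
        log(f"generate: n={cohort.n} ({time.perf_counter() - t0:.2f}s)")

        stage = "filter"
        filtered = apply_completeness_filter(cohort)
        log(filtered.provenance[-1])

        stage = "baseline_table"
        make_baseline_table(cohort).to_csv(outdir / "table1.csv", index=False)

        stage = "univariate_table"
        make_univariate_table(cohort).to_csv(outdir / "table2.csv",
                                             index=False)

        stage = "tree"
        t0 = time.perf_counter()
        tree = build_tree(filtered, tree_cfg)
        tree.to_json(outdir / "tree.json")
        labels = assign_risk_groups(tree, filtered)
        labels.rename_axis("patient_id").to_csv(outdir / "labels.csv")
        summaries = summarize_risk_groups(labels, filtered)
        summaries_to_frame(summaries).to_csv(outdir / "groups.csv",
                                             index=False)
        log(f"tree: {len(tree.leaves())} leaves "
            f"({time.perf_counter() - t0:.2f}s)")

        stage = "multivariable_models"
        models = fit_adjusted_models(filtered)
        adjusted_models_to_frame(models).to_csv(outdir / "models.csv",
                                                index=False)

        stage = "power"
        t0 = time.perf_counter()
        pw = cfg["power"]
        criterion = ValidationCriterion(kind=pw["criterion"])
        entries = []
        for i, n in enumerate(pw["grid"]):
            est = estimate_power(int(n), gen_cfg, criterion,
                                 reps=int(pw["reps"]),
                                 seed=cfg["seed"] + 1000 * i)
            entries.append({"n": est.n, "reps": est.reps,
                            "power": est.power, "se": est.se,
                            "criterion": criterion.kind})
        pd.DataFrame(entries).to_csv(outdir / "power.csv", index=False)
        log(f"power grid {pw['grid']} reps={pw['reps']} "
            f"({time.perf_counter() - t0:.2f}s)")
    except Exception:
        log(f"FAILED at stage {stage}:\n{traceback.format_exc()}")
        log_path.write_text("\n".join(log_lines) + "\n")
        return 1
    log("pipeline complete")
    log_path.write_text("\n".join(log_lines) + "\n")
    return 0
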