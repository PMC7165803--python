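"""Patient cohort container, CSV round-trip and the analyzable-cohort filter.

A cohort is one row per patient. Overall survival (time + event flag) is
mandatory; every other field may be missing, encoded as an empty cell in CSV
and as NaN/None in memory. The completeness filter reduces a registry cohort
to the patients usable by the risk-classification tree: known overall
survival, known primary tumor site, and one of the three common NUTM1 fusion
partners (BRD4, BRD3, NSD3). Rare ZNF fusions and unidentified fusions are
excluded rather than pooled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of the cohort CSV schema.
COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "primary_site",
    "fusion",
    "histology",
    "tumor_diameter_cm",
    "metastasis_baseline",
    "ever_surgery",
    "ever_radiation",
    "ever_chemo",
    "os_months",
    "os_event",
    "efs_months",
    "efs_event",
]

MANDATORY_COLUMNS = ["patient_id", "os_months", "os_event"]

SEX_LEVELS = {"male", "female"}
SITE_LEVELS = {"thoracic", "head_neck", "bone_soft_tissue", "other"}
FUSION_LEVELS = {"BRD4", "BRD3", "NSD3", "ZNF532", "ZNF592",
                 "unknown_tested", "not_tested"}
HISTOLOGY_LEVELS = {"squamous", "non_squamous", "other"}
YESNO_LEVELS = {"yes", "no"}

#: Fusion partners retained by the completeness filter.
MODEL_FUSIONS = {"BRD4", "BRD3", "NSD3"}

_CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS,
    "primary_site": SITE_LEVELS,
    "fusion": FUSION_LEVELS,
    "histology": HISTOLOGY_LEVELS,
    "metastasis_baseline": YESNO_LEVELS,
    "ever_surgery": YESNO_LEVELS,
    "ever_radiation": YESNO_LEVELS,
    "ever_chemo": YESNO_LEVELS,
}

_NUMERIC_COLUMNS = ["age_years", "tumor_diameter_cm", "os_months", "os_event",
                    "efs_months", "efs_event"]


class CohortError(ValueError):
    """Raised when a cohort violates its schema or invariants."""


@dataclass
class Cohort:
    """An ordered collection of patient records plus a provenance trail.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per patient, columns per :data:`COLUMNS`. Missing values are
        NaN. ``os_months`` and ``os_event`` must be complete.
    provenance : list of str
        Free-text trail (source, seed, filter steps).
    """

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise CohortError("empty cohort")
        for col in MANDATORY_COLUMNS:
            if col not in self.df.columns:
                raise CohortError(f"missing mandatory column: {col}")
        ids = self.df["patient_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate patient_id: {dup}")
        os_m = pd.to_numeric(self.df["os_months"], errors="coerce")
        if os_m.isna().any() or (os_m < 0).any():
            raise CohortError("os_months must be a non-negative number for every patient")
        ev = pd.to_numeric(self.df["os_event"], errors="coerce")
        if ev.isna().any() or not ev.isin([0, 1]).all():
            raise CohortError("os_event must be 0 or 1 for every patient")
        # fill any absent optional columns so downstream code can rely on them
        for col in COLUMNS:
            if col not in self.df.columns:
                self.df[col] = np.nan
        self.df = self.df[COLUMNS].reset_index(drop=True)
        both = self.df["efs_months"].notna() & self.df["os_months"].notna()
        bad = both & (self.df["efs_months"] > self.df["os_months"] + 1e-9)
        if bad.any():
            raise CohortError("efs_months exceeds os_months for some patients")

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), list(self.provenance))


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce raw string cells to typed values; unparseable -> NaN + warning."""
    out = df.copy()
    for col in _NUMERIC_COLUMNS:
        if col not in out.columns:
            continue
        raw = out[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any() and col not in MANDATORY_COLUMNS:
            for i in out.index[bad]:
                logger.warning("unparseable %s=%r in row %s set to missing",
                               col, raw[i], i)
        out[col] = num
    for col, levels in _CATEGORICAL_LEVELS.items():
        if col not in out.columns:
            continue
        vals = out[col].astype("object")
        vals = vals.where(vals.notna(), np.nan)
        stripped = vals.map(lambda v: v.strip() if isinstance(v, str) else v)
        stripped = stripped.replace("", np.nan)
        bad = stripped.notna() & ~stripped.isin(list(levels))
        if bad.any():
            for i in out.index[bad]:
                logger.warning("invalid %s=%r in row %s set to missing",
                               col, stripped[i], i)
            stripped = stripped.where(~bad, np.nan)
        out[col] = stripped
    return out


def read_cohort(path: str | Path, dialect: dict | None = None) -> Cohort:
    """Read a cohort CSV.

    Empty cells are missing values. Unparseable non-mandatory cells become
    missing with a logged warning. Missing mandatory columns or duplicate
    patient ids are hard errors.
    """
    path = Path(path)
    kwargs = dict(dtype=str, keep_default_na=False, na_values=[""])
    if dialect:
        kwargs.update(dialect)
    df = pd.read_csv(path, **kwargs)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CohortError(f"missing mandatory column: {col}")
    missing_optional = [c for c in COLUMNS if c not in df.columns]
    if missing_optional:
        logger.warning("columns absent from %s treated as all-missing: %s",
                       path.name, ", ".join(missing_optional))
    df = _coerce(df)
    provenance = [f"read from {path}"]
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = json.load(fh) + provenance
    return Cohort(df, provenance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV (empty cell = missing) plus a provenance JSON side-car.

    ``read_cohort(write_cohort(c))`` reproduces every field, including
    missing markers.
    """
    path = Path(path)
    cohort.df.to_csv(path, index=False, na_rep="")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump(cohort.provenance, fh, indent=1)


def apply_completeness_filter(cohort: Cohort) -> Cohort:
    """Reduce a registry cohort to the analyzable (tree-model) cohort.

    Retains patients with (i) known overall survival — guaranteed by the
    schema, (ii) known primary tumor site, and (iii) a BRD4, BRD3 or NSD3
    fusion. Exclusion counts by reason are appended to provenance. The
    operation is idempotent.
    """
    df = cohort.df
    known_site = df["primary_site"].notna()
    model_fusion = df["fusion"].isin(list(MODEL_FUSIONS))
    keep = known_site & model_fusion
    n_site = int((~known_site).sum())
    n_rare = int((df["fusion"].isin(["ZNF532", "ZNF592"])).sum())
    n_unid = int((df["fusion"].isin(["unknown_tested", "not_tested"])
                  | df["fusion"].isna()).sum())
    if not keep.any():
        raise CohortError("no analyzable patients after completeness filter")
    trail = (f"completeness filter: kept {int(keep.sum())}/{len(df)} "
             f"(excluded: unknown site {n_site}, rare ZNF fusion {n_rare}, "
             f"missing/unidentified fusion {n_unid})")
    return Cohort(df[keep].reset_index(drop=True),
                  list(cohort.provenance) + [trail])
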