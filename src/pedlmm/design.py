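"""Longitudinal phenotype tables and fixed-effect design construction.

Phenotype data are long-format tables with one row per (individual,
time point): columns IID, TIME, PHENO, AGE, SEX, SMOKE, MED.  The four
analysis modes differ only in how this table is collapsed into the
stage-1 outcome and design:

``baseline``
    one row per individual, time-1 phenotype and covariates;
``mean``
    one row per individual, outcome = mean phenotype across time points,
    covariates = mean age, sex, time-1 smoking, time-1 medication;
``longitudinal_A``
    one row per observation with time-varying covariates;
``longitudinal_B``
    longitudinal_A plus a numeric time-score column (1, 2, 3, ...)
    giving a common linear time trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("IID", "TIME", "PHENO", "AGE", "SEX", "SMOKE", "MED")
MODES = ("baseline", "mean", "longitudinal_A", "longitudinal_B")

_BINARY = {"0": 0, "1": 1, "no": 0, "yes": 1, "n": 0, "y": 1, "false": 0, "true": 1}
# accepts PLINK 1/2 coding, labels, or an already-coded male indicator
_SEX_MALE = {"1": 1, "m": 1, "male": 1, "2": 0, "f": 0, "female": 0, "0": 0}


class DesignError(ValueError):
    """Raised for invalid phenotype tables or design requests."""


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited long-format phenotype table (header required)."""
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", engine="python")
    df.columns = [c.upper() for c in df.columns]
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def _coerce_binary(col: pd.Series, name: str) -> pd.Series:
    def conv(v):
        key = str(v).strip().lower()
        if key in _BINARY:
            return _BINARY[key]
        raise DesignError(f"column {name}: cannot interpret {v!r} as yes/no")
    return col.map(conv).astype(int)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, coerce types, enforce uniqueness of
    (individual, time point) rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"phenotype table is missing columns: {missing}")
    out = df.copy()
    out["IID"] = out["IID"].astype(str)
    out["TIME"] = out["TIME"].astype(int)
    out["PHENO"] = out["PHENO"].astype(float)
    out["AGE"] = out["AGE"].astype(float)
    out["SEX"] = out["SEX"].map(lambda v: _SEX_MALE.get(str(v).strip().lower()))
    if out["SEX"].isna().any():
        raise DesignError("column SEX: expected 1/2, M/F or male/female")
    out["SEX"] = out["SEX"].astype(int)  # 1 = male indicator
    out["SMOKE"] = _coerce_binary(out["SMOKE"], "SMOKE")
    out["MED"] = _coerce_binary(out["MED"], "MED")
    dup = out.duplicated(subset=["IID", "TIME"])
    if dup.any():
        bad = out.loc[dup, ["IID", "TIME"]].head(5).to_records(index=False)
        raise DesignError(f"duplicate (IID, TIME) rows, e.g. {list(bad)}")
    sex_levels = out.groupby("IID")["SEX"].nunique()
    if (sex_levels > 1).any():
        raise DesignError("SEX varies over time for some individuals")
    return out


@dataclass
class DesignMatrices:
    """Stage-1 regression pieces for one analysis mode.

    ``y`` (n_obs,), ``X`` (n_obs, p) with leading intercept column,
    ``Z`` (n_obs, n_individuals) incidence mapping observations to
    individuals; ``ids`` orders the individuals (columns of Z),
    ``obs_ids`` gives the individual of each observation row.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    ids: list[str]
    obs_ids: list[str]
    exog_names: list[str]
    mode: str


def build_design(
    pheno: pd.DataFrame,
    mode: str,
    ids: Sequence[str] | None = None,
) -> DesignMatrices:
    """Collapse a long-format phenotype table into (y, X, Z) for a mode.

    ``ids`` optionally restricts and orders the individuals (e.g. to a
    pedigree's ordering); individuals in the table but not in ``ids``
    are dropped.  In baseline/mean modes, individuals lacking a time-1
    row are dropped with a warning (time-1 smoking and medication are
    required covariates).  In longitudinal modes, individuals with a
    single time point are retained (the model tolerates unbalanced
    data) with a log note.
    """
    if mode not in MODES:
        raise DesignError(f"unknown mode {mode!r}; expected one of {MODES}")
    pt = validate_phenotypes(pheno)
    if ids is not None:
        keep = set(ids)
        pt = pt[pt["IID"].isin(keep)]
    pt = pt.sort_values(["IID", "TIME"], kind="stable")

    if mode in ("baseline", "mean"):
        t1 = pt[pt["TIME"] == pt["TIME"].min()].set_index("IID")
        have_t1 = set(t1.index)
        all_ids = pd.unique(pt["IID"])
        lacking = [i for i in all_ids if i not in have_t1]
        if lacking:
            warnings.warn(
                f"dropping {len(lacking)} individual(s) without time-1 data "
                f"in mode {mode!r}: {lacking[:5]}",
                UserWarning,
                stacklevel=2,
            )
            pt = pt[~pt["IID"].isin(set(lacking))]
        if mode == "baseline":
            frame = pt[pt["TIME"] == pt["TIME"].min()].copy()
            y = frame["PHENO"].to_numpy()
            cov = frame[["AGE", "SEX", "SMOKE", "MED"]].to_numpy(dtype=float)
            row_ids = frame["IID"].tolist()
        else:
            grouped = pt.groupby("IID", sort=False)
            agg = grouped.agg(PHENO=("PHENO", "mean"), AGE=("AGE", "mean")).reset_index()
            first = pt[pt["TIME"] == pt["TIME"].min()].set_index("IID")
            agg["SEX"] = agg["IID"].map(first["SEX"]).astype(float)
            agg["SMOKE"] = agg["IID"].map(first["SMOKE"]).astype(float)
            agg["MED"] = agg["IID"].map(first["MED"]).astype(float)
            y = agg["PHENO"].to_numpy()
            cov = agg[["AGE", "SEX", "SMOKE", "MED"]].to_numpy(dtype=float)
            row_ids = agg["IID"].tolist()
        names = ["const", "age", "male", "smoke", "med"]
        X = np.column_stack([np.ones(len(y)), cov])
        obs_ids = row_ids
    else:
        counts = pt.groupby("IID")["TIME"].size()
        singles = counts[counts < 2]
        if len(singles):
            logger.info(
                "%d individual(s) contribute fewer than 2 time points in mode %s",
                len(singles), mode,
            )
        y = pt["PHENO"].to_numpy()
        cov = pt[["AGE", "SEX", "SMOKE", "MED"]].to_numpy(dtype=float)
        names = ["const", "age", "male", "smoke", "med"]
        X = np.column_stack([np.ones(len(y)), cov])
        if mode == "longitudinal_B":
            X = np.column_stack([X, pt["TIME"].to_numpy(dtype=float)])
            names = names + ["time"]
        obs_ids = pt["IID"].tolist()

    seen: dict[str, int] = {}
    if ids is not None:
        present = set(obs_ids)
        id_order = [i for i in ids if i in present]
    else:
        id_order = []
        for i in obs_ids:
            if i not in seen:
                seen[i] = 1
                id_order.append(i)
    idx = {iid: k for k, iid in enumerate(id_order)}
    Z = np.zeros((len(y), len(id_order)))
    rows = np.arange(len(y))
    cols = np.array([idx[i] for i in obs_ids])
    Z[rows, cols] = 1.0
    return DesignMatrices(
        y=y, X=X, Z=Z, ids=id_order, obs_ids=obs_ids, exog_names=names, mode=mode
    )
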