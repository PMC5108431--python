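"""Readers and writers for cohort data.

Two text dialects are supported:

- ``tsv``: one self-contained table with outcome, exposure, covariate and
  genotype columns.
- ``plink_raw``: a PLINK additive-coded export (header ``FID IID PAT MAT
  SEX PHENOTYPE <id>_A ...``, PHENOTYPE coded 1=control / 2=case).  RAW
  files carry no exposure, so the dialect pairs the .raw file with a
  companion phenotype TSV (columns FID, IID, exposure, covariates) written
  next to it; this mirrors how PLINK users supply exposures via covariate
  files.

Rows with missing values are rejected outright with an actionable message
rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, ParameterError

__all__ = ["CohortFileSpec", "read_cohort", "write_cohort", "phenotype_companion_path"]

RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class CohortFileSpec:
    format: str = "tsv"  # "tsv" | "plink_raw"
    outcome_col: str = "outcome"
    exposure_col: str = "exposure"
    covariate_cols: tuple[str, ...] = ()
    genotype_prefix: str | None = None  # None: all remaining columns are genotypes
    exposure_kind: str = "binary"

    def __post_init__(self) -> None:
        if self.format not in ("tsv", "plink_raw"):
            raise ParameterError(f"unknown format {self.format!r}")
        named = [self.outcome_col, self.exposure_col, *self.covariate_cols]
        if len(set(named)) != len(named):
            raise ParameterError("outcome/exposure/covariate column names overlap")


def phenotype_companion_path(path) -> Path:
    return Path(str(path) + ".pheno.tsv")


def _check_genotypes(g: pd.DataFrame) -> np.ndarray:
    vals = g.to_numpy()
    if np.isnan(vals.astype(float)).any():
        r, c = np.argwhere(np.isnan(vals.astype(float)))[0]
        raise ParameterError(
            f"missing genotype at row {r}, column {g.columns[c]!r}; "
            "remove or impute incomplete rows before loading"
        )
    bad = ~np.isin(vals, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParameterError(
            f"genotype value {vals[r, c]!r} at row {r}, column {g.columns[c]!r} "
            "is not in {0, 1, 2}"
        )
    return vals.astype(np.int8)


def read_cohort(path, spec: CohortFileSpec) -> Cohort:
    path = Path(path)
    if spec.format == "tsv":
        df = pd.read_csv(path, sep="\t")
        for col in (spec.outcome_col, spec.exposure_col, *spec.covariate_cols):
            if col not in df.columns:
                raise ParameterError(f"column {col!r} missing from {path}")
        named = (spec.outcome_col, spec.exposure_col, *spec.covariate_cols)
        geno_cols = [
            c
            for c in df.columns
            if c not in named
            and (spec.genotype_prefix is None or c.startswith(spec.genotype_prefix))
        ]
        if not geno_cols:
            raise ParameterError(f"no genotype columns found in {path}")
        if df[[spec.outcome_col, spec.exposure_col, *spec.covariate_cols]].isna().any().any():
            raise ParameterError(f"missing phenotype values in {path}")
        outcome = df[spec.outcome_col].to_numpy()
        exposure = df[spec.exposure_col].to_numpy(dtype=float)
        cov = df[list(spec.covariate_cols)].to_numpy(dtype=float)
        marker_ids = geno_cols
        genotypes = _check_genotypes(df[geno_cols])
    else:
        df = pd.read_csv(path, sep=r"\s+")
        for col in RAW_META:
            if col not in df.columns:
                raise ParameterError(f"malformed RAW header: column {col!r} missing")
        pheno = df["PHENOTYPE"].to_numpy()
        if np.isin(pheno, (-9,)).any() or pd.isna(pheno).any():
            rows = np.flatnonzero(np.isin(pheno, (-9,)) | pd.isna(pheno))
            raise ParameterError(
                f"missing PHENOTYPE (-9/NA) for rows {rows.tolist()[:10]}; "
                "remove these subjects first"
            )
        if not np.isin(pheno, (1, 2)).all():
            raise ParameterError("PHENOTYPE must be coded 1 (control) / 2 (case)")
        outcome = (pheno == 2).astype(int)
        geno_cols = [c for c in df.columns if c not in RAW_META]
        marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno_cols]
        genotypes = _check_genotypes(df[geno_cols])
        companion = phenotype_companion_path(path)
        if not companion.exists():
            raise ParameterError(
                f"RAW dialect needs the phenotype companion file {companion} "
                "(columns FID, IID, exposure, covariates)"
            )
        ph = pd.read_csv(companion, sep="\t")
        if spec.exposure_col not in ph.columns:
            raise ParameterError(
                f"column {spec.exposure_col!r} missing from {companion}"
            )
        ph = ph.set_index(["FID", "IID"]).loc[
            list(zip(df["FID"], df["IID"]))
        ]
        if ph[[spec.exposure_col, *spec.covariate_cols]].isna().any().any():
            raise ParameterError(f"missing phenotype values in {companion}")
        exposure = ph[spec.exposure_col].to_numpy(dtype=float)
        cov = ph[list(spec.covariate_cols)].to_numpy(dtype=float)
    return Cohort(
        genotypes=genotypes,
        exposure=exposure,
        outcome=outcome,
        covariates=cov,
        marker_ids=list(marker_ids),
        exposure_kind=spec.exposure_kind,
    )


def write_cohort(cohort: Cohort, path, spec: CohortFileSpec) -> None:
    """Write a cohort; output is byte-stable for a fixed input."""
    path = Path(path)
    if spec.format == "tsv":
        data = {spec.outcome_col: cohort.outcome, spec.exposure_col: cohort.exposure}
        cov_names = spec.covariate_cols or tuple(
            f"cov{i + 1}" for i in range(cohort.n_covariates)
        )
        for i, name in enumerate(cov_names):
            data[name] = cohort.covariates[:, i]
        frame = pd.DataFrame(data)
        geno = pd.DataFrame(cohort.genotypes, columns=cohort.marker_ids)
        pd.concat([frame, geno], axis=1).to_csv(path, sep="\t", index=False)
        return
    # PLINK RAW
    n = cohort.n_subjects
    meta = pd.DataFrame(
        {
            "FID": [f"S{i + 1}" for i in range(n)],
            "IID": [f"S{i + 1}" for i in range(n)],
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": cohort.outcome + 1,
        }
    )
    geno = pd.DataFrame(
        cohort.genotypes, columns=[f"{m}_A" for m in cohort.marker_ids]
    )
    pd.concat([meta, geno], axis=1).to_csv(path, sep=" ", index=False)
    ph = pd.DataFrame(
        {
            "FID": meta["FID"],
            "IID": meta["IID"],
            spec.exposure_col: cohort.exposure,
        }
    )
    cov_names = spec.covariate_cols or tuple(
        f"cov{i + 1}" for i in range(cohort.n_covariates)
    )
    for i, name in enumerate(cov_names):
        ph[name] = cohort.covariates[:, i]
    ph.to_csv(phenotype_companion_path(path), sep="\t", index=False)
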