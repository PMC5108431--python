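"""Case-control cohort container with additive-coded genotypes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """Invalid parameter or precondition violation."""


@dataclass
class Cohort:
    """A case-control study with genotypes, exposure, outcome and covariates.

    Attributes
    ----------
    genotypes : (n, p) array of minor-allele counts in {0, 1, 2}.
    exposure : (n,) vector; binary {0, 1} or continuous depending on
        ``exposure_kind``.
    outcome : (n,) binary case/control indicator in {0, 1}.
    covariates : (n, c) matrix of additional adjustment variables (c may be 0).
    marker_ids : p unique marker identifiers.
    exposure_kind : "binary" or "continuous".
    """

    genotypes: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    covariates: np.ndarray | None = None
    marker_ids: list[str] = field(default_factory=list)
    exposure_kind: str = "binary"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.covariates is None:
            self.covariates = np.empty((self.genotypes.shape[0], 0), dtype=float)
        else:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.genotypes.shape[0]:
                self.covariates = self.covariates.T
        if not self.marker_ids:
            width = max(4, len(str(self.genotypes.shape[1])))
            self.marker_ids = [
                f"snp{j + 1:0{width}d}" for j in range(self.genotypes.shape[1])
            ]
        self.validate()

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def validate(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise ParameterError("genotypes must be a 2-d (subjects x markers) matrix")
        n = g.shape[0]
        if self.exposure.shape != (n,):
            raise ParameterError(
                f"exposure length {self.exposure.shape} does not match n={n}"
            )
        if self.outcome.shape != (n,):
            raise ParameterError(
                f"outcome length {self.outcome.shape} does not match n={n}"
            )
        if np.isnan(self.exposure).any() or np.isnan(g.astype(float)).any():
            raise ParameterError("cohort contains missing values")
        bad = ~np.isin(g, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParameterError(
                f"genotype value {g[i, j]!r} at subject {i}, marker {j} "
                "is not in {0, 1, 2}"
            )
        if not np.isin(self.outcome, (0, 1)).all():
            raise ParameterError("outcome values must be 0/1")
        if self.exposure_kind not in ("binary", "continuous"):
            raise ParameterError(f"unknown exposure_kind {self.exposure_kind!r}")
        if self.exposure_kind == "binary" and not np.isin(self.exposure, (0, 1)).all():
            raise ParameterError("binary exposure must take values 0/1")
        if len(self.marker_ids) != g.shape[1]:
            raise ParameterError("marker_ids length does not match marker count")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ParameterError("marker_ids must be unique")

    def subset(self, rows: np.ndarray) -> "Cohort":
        """Return the cohort restricted to the given subject rows."""
        rows = np.asarray(rows)
        return Cohort(
            genotypes=self.genotypes[rows],
            exposure=self.exposure[rows],
            outcome=self.outcome[rows],
            covariates=self.covariates[rows],
            marker_ids=list(self.marker_ids),
            exposure_kind=self.exposure_kind,
        )
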