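"""Core domain types for the digital-marker pipeline.

A *digital marker* is a short ordered list of genes whose transcription
levels jointly predict the sensitivity of one cancer type to one drug.
The types here carry the three kinds of raw input the pipeline consumes —
gene-by-sample TPM expression matrices, per-sample drug-response tables
(continuous IC50/Z or binary effective/ineffective labels), and qRT-PCR
Cq tables — plus the paired-cohort container used for cross-dataset
screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

EFFECTIVE = "effective"
INEFFECTIVE = "ineffective"


class DigitalMarkerError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DigitalMarkerError):
    """A domain object or argument violates its contract."""


class DataError(DigitalMarkerError):
    """An input file or table cannot be parsed or is inconsistent."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample TPM matrix for one cohort.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample
        identifiers as columns; entries are TPM (non-negative).
    cancer_type, dataset_tag
        Free-text cohort metadata (e.g. ``"colorectal"``, ``"GDSC"``).
    """

    values: pd.DataFrame
    cancer_type: str = ""
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample identifiers: {list(dups)[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        finite = np.isfinite(arr)
        if np.any(arr[finite] < 0):
            raise ValidationError("TPM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)].copy(),
            cancer_type=self.cancer_type,
            dataset_tag=self.dataset_tag,
        )


@dataclass
class DrugResponse:
    """Per-sample response of one cohort to one drug.

    ``mode`` is ``"continuous"`` (IC50 in uM plus Z-scores of log IC50)
    or ``"binary"`` (effective/ineffective labels).  Exactly the fields
    matching the mode are populated.  ``z`` built by
    :func:`DrugResponse.from_ic50` is standardized to mean 0 / SD 1
    (population SD) over the cohort it was computed on; a slice of a
    cohort keeps the parent cohort's standardization.
    """

    drug: str
    samples: list[str]
    mode: str
    ic50: np.ndarray | None = None
    z: np.ndarray | None = None
    label: np.ndarray | None = None  # strings EFFECTIVE / INEFFECTIVE

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers in response")
        n = len(self.samples)
        if self.mode == "continuous":
            if self.ic50 is None or self.z is None or self.label is not None:
                raise ValidationError("continuous mode requires ic50 and z, no labels")
            self.ic50 = np.asarray(self.ic50, dtype=float)
            self.z = np.asarray(self.z, dtype=float)
            if self.ic50.shape != (n,) or self.z.shape != (n,):
                raise ValidationError("ic50/z length must match samples")
            if np.any(self.ic50 <= 0):
                raise ValidationError("IC50 concentrations must be positive")
        elif self.mode == "binary":
            if self.label is None or self.ic50 is not None or self.z is not None:
                raise ValidationError("binary mode requires labels only")
            self.label = np.asarray(self.label, dtype=object)
            if self.label.shape != (n,):
                raise ValidationError("label length must match samples")
            bad = set(self.label) - {EFFECTIVE, INEFFECTIVE}
            if bad:
                raise ValidationError(
                    f"unknown labels {sorted(bad)}; accepted: "
                    f"{EFFECTIVE!r}, {INEFFECTIVE!r}"
                )
        else:
            raise ValidationError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_ic50(
        cls, drug: str, samples: Sequence[str], ic50: Sequence[float],
        scale: str = "ln",
    ) -> "DrugResponse":
        """Build a continuous response, standardizing IC50 into Z-scores.

        ``scale`` selects the transform standardized over the cohort:
        ``"ln"`` (default, GDSC-style log IC50), ``"log10"``, or
        ``"raw"``.  Population SD is used.
        """
        ic50 = np.asarray(ic50, dtype=float)
        if np.any(ic50 <= 0):
            raise ValidationError("IC50 concentrations must be positive")
        if len(ic50) < 2:
            raise ValidationError("cannot standardize IC50 over fewer than 2 samples")
        if scale == "ln":
            v = np.log(ic50)
        elif scale == "log10":
            v = np.log10(ic50)
        elif scale == "raw":
            v = ic50.astype(float)
        else:
            raise ValidationError(f"unknown IC50 scale {scale!r}")
        sd = v.std()  # population SD
        if sd == 0:
            raise ValidationError("IC50 values are constant; Z-scores undefined")
        z = (v - v.mean()) / sd
        return cls(drug=drug, samples=list(samples), mode="continuous",
                   ic50=ic50, z=z)

    def subset_samples(self, samples: Sequence[str]) -> "DrugResponse":
        idx = pd.Index(self.samples).get_indexer(list(samples))
        if np.any(idx < 0):
            missing = [s for s, i in zip(samples, idx) if i < 0]
            raise ValidationError(f"samples not in response: {missing[:5]}")
        if self.mode == "continuous":
            return DrugResponse(self.drug, list(samples), "continuous",
                                ic50=self.ic50[idx], z=self.z[idx])
        return DrugResponse(self.drug, list(samples), "binary",
                            label=self.label[idx])

    def z_series(self) -> pd.Series:
        return pd.Series(self.z, index=self.samples)

    def label_series(self) -> pd.Series:
        return pd.Series(self.label, index=self.samples)


@dataclass
class CqTable:
    """Sample-by-gene qRT-PCR quantification cycles.

    ``cq`` has sample identifiers as index and gene identifiers as
    columns; ``reference_gene`` (e.g. GAPDH) must be one of the columns
    and measured (finite) for every sample, since every dCq is taken
    relative to it.
    """

    cq: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        if self.reference_gene not in self.cq.columns:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} not measured"
            )
        ref = self.cq[self.reference_gene].to_numpy(dtype=float)
        if not np.all(np.isfinite(ref)):
            raise ValidationError("reference gene Cq missing for some samples")

    @property
    def samples(self) -> list[str]:
        return list(self.cq.index)

    @property
    def genes(self) -> list[str]:
        return list(self.cq.columns)

    def delta_cq(self) -> pd.DataFrame:
        """dCq = Cq(target) - Cq(reference), per sample; reference column dropped."""
        ref = self.cq[self.reference_gene]
        out = self.cq.sub(ref, axis=0)
        return out.drop(columns=[self.reference_gene])


@dataclass
class CohortPair:
    """Two cohorts (e.g. GDSC + CCLE) profiled for the same drug and cancer type."""

    expression_a: ExpressionMatrix
    response_a: DrugResponse
    expression_b: ExpressionMatrix
    response_b: DrugResponse

    def __post_init__(self) -> None:
        if self.response_a.drug != self.response_b.drug:
            raise ValidationError("paired cohorts must share the drug")
        if self.expression_a.cancer_type != self.expression_b.cancer_type:
            raise ValidationError("paired cohorts must share the cancer type")

    @property
    def shared_genes(self) -> list[str]:
        in_b = set(self.expression_b.genes)
        return [g for g in self.expression_a.genes if g in in_b]


def align_expression_response(
    x: ExpressionMatrix, r: DrugResponse
) -> tuple[pd.DataFrame, DrugResponse]:
    """Inner-join samples of an expression matrix and a response.

    Returns the expression values restricted to the shared samples (in
    the expression matrix's column order) and the response subset in the
    same order.
    """
    shared = [s for s in x.samples if s in set(r.samples)]
    if not shared:
        raise ValidationError("expression and response share no samples")
    return x.values.loc[:, shared], r.subset_samples(shared)
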