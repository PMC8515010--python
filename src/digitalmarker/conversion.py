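"""dCq <-> TPM conversion, qPCR-path prediction, and drug recommendation.

qRT-PCR quantification cycles relate linearly to log abundance: with
dCq = Cq(target) - Cq(reference gene, e.g. GAPDH), the calibration

    log10(TPM + 1) = slope * dCq + intercept

converts a panel of dCq measurements into TPM so the same KNN marker
trained on RNA-seq data can score a qPCR readout.  The default
coefficients (slope -0.3995, intercept 5.6974) come from an SW620
calibration; :func:`fit_conversion` refits them from paired
measurements.  The recommendation layer standardizes a predicted log
IC50 against the cancer-type cohort ("relative Z") and calls a drug
sensitive below -1, non-sensitive above +1, neutral otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CqTable, ValidationError
from .selection import DigitalMarker, knn_classify, knn_regress

DEFAULT_SLOPE = -0.3995
DEFAULT_INTERCEPT = 5.6974
DEFAULT_REFERENCE_GENE = "GAPDH"


@dataclass
class ConversionModel:
    """Linear dCq -> log10(TPM+1) calibration.

    ``slope`` is in log10(TPM+1) units per cycle and must be negative
    for a physically meaningful fit (more cycles = rarer transcript).
    """

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    reference_gene: str = DEFAULT_REFERENCE_GENE
    fit_r2: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ConversionModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def fit_conversion(dcq: Sequence[float], tpm: Sequence[float],
                   reference_gene: str = DEFAULT_REFERENCE_GENE
                   ) -> ConversionModel:
    """Ordinary least squares of log10(TPM+1) on dCq.

    The +1 pseudo-count keeps zero-TPM genes finite.  Two distinct
    points produce the interpolating line (R^2 = 1); constant dCq is a
    degenerate design and a hard error.
    """
    dcq = np.asarray(dcq, dtype=float)
    tpm = np.asarray(tpm, dtype=float)
    if dcq.shape != tpm.shape or dcq.ndim != 1:
        raise ValidationError("dcq and tpm must be equal-length vectors")
    if len(dcq) < 2:
        raise ValidationError("need at least 2 paired measurements")
    if np.any(tpm < 0):
        raise ValidationError("TPM must be non-negative")
    if not np.all(np.isfinite(dcq)):
        raise ValidationError("dCq values must be finite")
    if np.ptp(dcq) == 0:
        raise ValidationError("constant dCq: calibration fit is degenerate")
    y = np.log10(tpm + 1.0)
    res = stats.linregress(dcq, y)
    r2 = float(res.rvalue ** 2) if np.std(y) > 0 else 1.0
    return ConversionModel(slope=float(res.slope),
                           intercept=float(res.intercept),
                           reference_gene=reference_gene, fit_r2=r2)


def dcq_to_tpm(dcq, model: ConversionModel | None = None):
    """TPM = 10^(slope*dCq + intercept) - 1, floored at 0."""
    model = model or ConversionModel()
    dcq = np.asarray(dcq, dtype=float)
    if not np.all(np.isfinite(dcq)):
        raise ValidationError("dCq values must be finite")
    return np.maximum(10.0 ** (model.slope * dcq + model.intercept) - 1.0, 0.0)


def tpm_to_dcq(tpm, model: ConversionModel | None = None):
    """Inverse calibration: dCq = (log10(TPM+1) - intercept) / slope."""
    model = model or ConversionModel()
    if model.slope == 0:
        raise ValidationError("conversion slope is zero; inverse undefined")
    tpm = np.asarray(tpm, dtype=float)
    if np.any(tpm < 0):
        raise ValidationError("TPM must be non-negative")
    return (np.log10(tpm + 1.0) - model.intercept) / model.slope


def zone_of(p_ineffective: float,
            cuts: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)) -> str:
    """Map an ineffectiveness probability onto the three decision zones.

    p < cuts[0] -> "effective"; p > cuts[1] -> "ineffective"; boundary
    and middle values -> "intermediate".
    """
    low, high = cuts
    if not 0 < low < high < 1:
        raise ValidationError("zone cuts must satisfy 0 < low < high < 1")
    if not 0 <= p_ineffective <= 1:
        raise ValidationError("probability must lie in [0, 1]")
    if p_ineffective < low:
        return "effective"
    if p_ineffective > high:
        return "ineffective"
    return "intermediate"


def relative_z(value: float, cohort: Sequence[float]) -> float:
    """Standardize ``value`` against a cohort (population SD)."""
    cohort = np.asarray(cohort, dtype=float)
    if len(cohort) < 2:
        raise ValidationError("cohort must contain at least 2 values")
    sd = cohort.std()
    if sd == 0:
        raise ValidationError("cohort SD is zero; relative Z undefined")
    return float((value - cohort.mean()) / sd)


_CALLS = {  # relative-Z band -> (call, display color)
    "sensitive": "green",
    "neutral": "black",
    "non-sensitive": "red",
}


@dataclass
class Recommendation:
    """Per-drug three-way call derived from the relative Z-score."""

    drug: str
    predicted_value: float
    relative_z: float
    call: str
    display_color: str
    zone: str | None = None


def _call_of(rz: float) -> str:
    if rz < -1.0:
        return "sensitive"
    if rz > 1.0:
        return "non-sensitive"
    return "neutral"


def recommend(predictions: Mapping[str, float],
              cohort_stats: Mapping[str, Sequence[float]]
              ) -> list[Recommendation]:
    """Turn per-drug predicted log IC50 values into three-way calls.

    ``predictions`` maps drug -> predicted log IC50; ``cohort_stats``
    maps drug -> the cancer-type cohort's log IC50 values used for
    standardization.  Inequalities at +-1 are strict, so a relative Z of
    exactly +-1 stays neutral.
    """
    out = []
    for drug, value in predictions.items():
        if drug not in cohort_stats:
            raise ValidationError(f"no cohort statistics for drug {drug!r}")
        rz = relative_z(value, cohort_stats[drug])
        call = _call_of(rz)
        out.append(Recommendation(drug=drug, predicted_value=float(value),
                                  relative_z=rz, call=call,
                                  display_color=_CALLS[call]))
    return out


@dataclass
class PredictionResult:
    """Per-sample prediction from one marker, with decision annotations.

    ``values`` holds the predicted Z-score (regression) or
    ineffectiveness probability (classification) per sample; ``zones``
    is populated on the classification path.
    """

    drug: str
    task: str
    samples: list[str]
    values: pd.Series
    labels: pd.Series | None = None
    zones: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"predicted": self.values}
        if self.labels is not None:
            cols["label"] = self.labels
        if self.zones is not None:
            cols["zone"] = self.zones
        df = pd.DataFrame(cols)
        df.index.name = "sample"
        return df


def predict_from_tpm(tpm: pd.DataFrame, marker: DigitalMarker
                     ) -> PredictionResult:
    """Predict directly from a gene-by-sample TPM table."""
    if marker.task == "regression":
        preds = knn_regress(marker, tpm)
        return PredictionResult(drug=marker.drug, task=marker.task,
                                samples=list(preds.index), values=preds)
    cls = knn_classify(marker, tpm)
    return PredictionResult(drug=marker.drug, task=marker.task,
                            samples=list(cls.index),
                            values=cls["p_ineffective"],
                            labels=cls["label"], zones=cls["zone"])


def predict_from_qpcr(cq: CqTable, marker: DigitalMarker,
                      model: ConversionModel | None = None
                      ) -> PredictionResult:
    """Predict drug sensitivity from a qPCR Cq table.

    dCq = Cq(target) - Cq(reference) per sample is converted to TPM via
    the calibration, then scored by the marker's KNN model exactly as a
    TPM-path query would be.
    """
    model = model or ConversionModel()
    missing = [g for g in marker.genes if g not in cq.genes]
    if missing:
        raise ValidationError(f"Cq table lacks marker genes: {missing}")
    dcq = cq.delta_cq()
    tpm = pd.DataFrame(dcq_to_tpm(dcq.to_numpy(), model),
                       index=dcq.index, columns=dcq.columns)
    return predict_from_tpm(tpm.T, marker)
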