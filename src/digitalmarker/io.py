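"""Readers and writers for the delimited-text exchange formats.

All tables are UTF-8 delimited text (tab by default, comma auto-detected),
"." decimal separator, gene and sample identifiers treated as opaque
strings.  Expression matrices have a leading gene-identifier column and a
header row of sample identifiers; response tables are two/three column
(sample, ic50-or-label[, z]); Cq tables are sample-by-gene with a header
row of gene names.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    EFFECTIVE,
    INEFFECTIVE,
    CqTable,
    DataError,
    DrugResponse,
    ExpressionMatrix,
)

logger = logging.getLogger(__name__)

_REPLICATE_RE = re.compile(r"^(.*)_(\d+)$")


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_table(path, delimiter: str | None,
                check_header_dupes: bool = False) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    sep = delimiter or _detect_delimiter(path)
    if check_header_dupes:
        # pandas silently renames duplicate header fields, so check raw text
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dupes = sorted({h for h in header if header.count(h) > 1})
        if dupes:
            raise DataError(f"duplicate sample identifiers: {dupes}")
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                       keep_default_na=False)


def _to_numeric(df: pd.DataFrame, na_values: frozenset = frozenset({"", "NA", "NaN", "nan", "null"})) -> pd.DataFrame:
    """Convert a string-typed table to float, naming the first bad cell."""
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        cleaned = raw.where(~raw.isin(na_values), np.nan)
        try:
            # python float() parsing is exact (round-trips repr output)
            vals = cleaned.astype(float)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(cleaned, errors="coerce")
            bad = coerced.isna() & cleaned.notna()
            row = bad.idxmax()
            raise DataError(
                f"non-numeric value {raw.loc[row]!r} at row {row!r}, "
                f"column {col!r}"
            ) from None
        out[col] = vals.to_numpy(dtype=float)
    return out


def load_expression(path, cancer_type: str = "", dataset_tag: str = "",
                    delimiter: str | None = None) -> ExpressionMatrix:
    """Load a gene-by-sample TPM matrix from delimited text.

    Duplicate gene rows are collapsed by their mean (with a logged
    warning); genes with any missing value are dropped (logged count).
    Duplicate sample identifiers are a hard error.
    """
    df = _read_table(path, delimiter, check_header_dupes=True)
    values = _to_numeric(df)
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.warning(
            "%s: %d duplicate gene rows collapsed by mean", path, n_dup
        )
        values = values.groupby(level=0, sort=False).mean()
    n_before = len(values)
    values = values.dropna(axis=0, how="any")
    n_dropped = n_before - len(values)
    if n_dropped:
        logger.warning("%s: dropped %d genes with missing values", path, n_dropped)
    return ExpressionMatrix(values, cancer_type=cancer_type,
                            dataset_tag=dataset_tag)


def write_expression(x: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    x.values.to_csv(path, sep=delimiter)


DEFAULT_LABEL_MAP: Mapping[str, str] = {
    "effective": EFFECTIVE,
    "ineffective": INEFFECTIVE,
}


def load_response(path, drug: str, mode: str, delimiter: str | None = None,
                  ic50_scale: str = "ln",
                  label_map: Mapping[str, str] = DEFAULT_LABEL_MAP,
                  ) -> DrugResponse:
    """Load a per-sample drug-response table.

    Continuous mode expects columns (sample, ic50[, z]); when the z
    column is absent, Z-scores are computed by standardizing the
    ``ic50_scale``-transformed IC50 (natural-log by default) over the
    loaded samples with population SD.  Binary mode expects
    (sample, label) where labels map through ``label_map``.
    """
    df = _read_table(path, delimiter)
    samples = [str(s) for s in df.index]
    if len(set(samples)) != len(samples):
        raise DataError("duplicate sample identifiers in response table")
    if mode == "continuous":
        if df.shape[1] < 1:
            raise DataError("continuous response needs an IC50 column")
        num = _to_numeric(df.iloc[:, : min(2, df.shape[1])])
        ic50 = num.iloc[:, 0].to_numpy(dtype=float)
        if np.any(ic50 <= 0):
            raise DataError("IC50 concentrations must be positive")
        if df.shape[1] >= 2:
            z = num.iloc[:, 1].to_numpy(dtype=float)
            return DrugResponse(drug, samples, "continuous", ic50=ic50, z=z)
        if len(ic50) < 2:
            raise DataError("cannot standardize IC50 for a single sample")
        return DrugResponse.from_ic50(drug, samples, ic50, scale=ic50_scale)
    if mode == "binary":
        raw = df.iloc[:, 0].astype(str)
        unknown = sorted(set(raw) - set(label_map))
        if unknown:
            raise DataError(
                f"unknown response labels {unknown}; accepted: "
                f"{sorted(label_map)}"
            )
        labels = raw.map(label_map).to_numpy(dtype=object)
        return DrugResponse(drug, samples, "binary", label=labels)
    raise DataError(f"unknown response mode {mode!r}")


def write_response(r: DrugResponse, path, delimiter: str = "\t") -> None:
    if r.mode == "continuous":
        df = pd.DataFrame({"ic50": r.ic50, "z": r.z}, index=r.samples)
    else:
        df = pd.DataFrame({"label": r.label}, index=r.samples)
    df.index.name = "sample"
    df.to_csv(path, sep=delimiter)


def _collapse_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns named ``<gene>_<int>`` into ``<gene>``."""
    groups: dict[str, list[str]] = {}
    for col in df.columns:
        m = _REPLICATE_RE.match(col)
        base = m.group(1) if m else col
        groups.setdefault(base, []).append(col)
    out = {}
    for base, cols in groups.items():
        out[base] = df[cols].mean(axis=1) if len(cols) > 1 or cols[0] != base \
            else df[base]
    return pd.DataFrame(out, index=df.index)


def load_cq(path, reference_gene: str, delimiter: str | None = None,
            collapse_replicates: bool = True) -> CqTable:
    """Load a sample-by-gene Cq table.

    Replicate columns following the ``<gene>_<number>`` suffix
    convention are collapsed to their mean before dCq computation.  The
    reference gene (e.g. GAPDH) must be present after collapsing.
    """
    df = _to_numeric(_read_table(path, delimiter))
    if collapse_replicates:
        df = _collapse_replicates(df)
    if reference_gene not in df.columns:
        raise DataError(
            f"reference gene {reference_gene!r} missing from Cq table"
        )
    return CqTable(cq=df, reference_gene=reference_gene)


def write_cq(table: CqTable, path, delimiter: str = "\t") -> None:
    df = table.cq.copy()
    df.index.name = "sample"
    df.to_csv(path, sep=delimiter)
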